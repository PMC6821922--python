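"""Model parameters for the (globally coupled) resource budget model.

The resource budget model (RBM) describes a tree that accumulates an
annual photosynthetic surplus ``P_0`` into a reserve pool and spends the
excess over a threshold ``L_T`` on flowering and fruiting.  The globally
coupled map (GCM) links ``N`` such trees through outcross-pollen
availability with coupling exponent ``beta``, and perturbs the annual
surplus with common (``e_C``) and individual (``e_I``) multiplicative
Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Any, Mapping

__all__ = ["ModelParams"]


@dataclass(frozen=True)
class ModelParams:
    """Constants of the GCM-RBM plus run controls.

    Parameters
    ----------
    P_0:
        Intrinsic annual surplus (resource units). Default 10.
    L_T:
        Reserve threshold above which the tree flowers (resource units).
        Default 100.
    R_C:
        Cost ratio C_a/C_f of fruiting to flowering cost (dimensionless,
        >= 0).  It is also the slope magnitude at the fixed point of the
        uncoupled map, which makes it the primary bifurcation parameter.
    beta:
        Pollen-coupling exponent (dimensionless, >= 0).  beta = 0
        decouples the trees.
    e_I, e_C:
        Individual and common noise amplitudes on the annual surplus
        (dimensionless, >= 0).
    N:
        Population size.  Must be >= 2 whenever beta > 0 because the
        coupling term averages over the other trees.
    T_transient, T_record:
        Iterations discarded before recording, and recorded years.  The
        default record length of 15 matches a typical masting survey
        span.
    seed:
        Seed for reserve initialisation and the noise stream.
    """

    P_0: float = 10.0
    L_T: float = 100.0
    R_C: float = 2.0
    beta: float = 6.0
    e_I: float = 0.0
    e_C: float = 0.0
    N: int = 106
    T_transient: int = 1000
    T_record: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.P_0 > 0:
            raise ValueError(f"P_0 must be positive, got {self.P_0}")
        if not self.L_T > 0:
            raise ValueError(f"L_T must be positive, got {self.L_T}")
        if self.R_C < 0:
            raise ValueError(f"R_C must be >= 0, got {self.R_C}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.e_I < 0 or self.e_C < 0:
            raise ValueError("noise amplitudes must be >= 0")
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")
        if self.beta > 0 and self.N < 2:
            raise ValueError("pollen coupling (beta > 0) requires N >= 2")
        if self.T_transient < 0 or self.T_record < 1:
            raise ValueError("T_transient >= 0 and T_record >= 1 required")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ModelParams":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown ModelParams fields: {sorted(unknown)}")
        kwargs: dict[str, Any] = {}
        for k, v in d.items():
            typ = cls.__dataclass_fields__[k].type
            kwargs[k] = int(v) if typ == "int" else float(v)
        return cls(**kwargs)

    def with_(self, **kwargs: Any) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)
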