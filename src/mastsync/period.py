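"""Period-composition and in-phase synchrony statistics.

``FP(Q)`` measures how much of a binary on/off train is occupied by
clean period-Q motifs: an on-year, Q-1 off-years, then an on-year.  It
is a combinatorial statistic, deliberately not a spectral one, so it
remains meaningful on the short (T ~ 15) records of masting surveys.

``F_IN`` is the average fraction of tree pairs whose year-on-year
production changes share sign -- the in-phase fraction -- and serves as
the synchrony order statistic for parameter scans.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .phase import OnOffFlags

__all__ = [
    "PeriodFractions",
    "SyncFractions",
    "fraction_period_individual",
    "fraction_period_population",
    "in_phase_fraction",
]

DEFAULT_Q_RANGE = (2, 3, 4, 5, 6)


@dataclass
class PeriodFractions:
    """Per-tree (N, len(Q_range)) and population period fractions."""

    per_tree: NDArray[np.float64]
    population: NDArray[np.float64]
    Q_range: tuple[int, ...]

    def __getitem__(self, Q: int) -> float:
        """Population FP(Q) for a period in Q_range."""
        return float(self.population[self.Q_range.index(Q)])


@dataclass
class SyncFractions:
    """Yearly in-phase fractions f_IN(t) (length T-1) and their mean F_IN."""

    f_in_t: NDArray[np.float64]
    F_IN: float


def fraction_period_individual(
    flags_i: ArrayLike, Q: int, *, strict_printed_product: bool = False
) -> float:
    """Fraction of period-Q motifs in one binary on/off train.

    A motif is an on-year at t, off-years at t+1 .. t+Q-1, and an
    on-year at t+Q.  The motif count is scaled by
    ``Q / ((T-1) - (T-1) mod Q)`` so a perfect period-Q train scores 1,
    and the result is clipped to [0, 1].

    ``strict_printed_product=True`` switches to a variant that does not
    require the year t+1 to be off (the off-run check starts at t+2).
    That variant admits on-on adjacencies into the motif and is kept
    only for comparison; the default matches the verbal definition
    ("one on-year followed by Q-1 off-years").
    """
    f = np.asarray(flags_i, dtype=int).ravel()
    T = f.size
    if Q < 2:
        raise ValueError(f"Q must be >= 2, got {Q}")
    if T <= Q:
        warnings.warn(f"record length {T} <= Q={Q}; FP set to 0", stacklevel=2)
        return 0.0
    norm = Q / ((T - 1) - (T - 1) % Q)
    start = 2 if strict_printed_product else 1
    count = 0
    for t in range(T - Q):
        if f[t] == 1 and f[t + Q] == 1 and not f[t + start : t + Q].any():
            count += 1
    return float(min(count * norm, 1.0))


def fraction_period_population(
    flags: OnOffFlags | ArrayLike,
    Q_range: tuple[int, ...] = DEFAULT_Q_RANGE,
    *,
    reducer: str = "mean",
    strict_printed_product: bool = False,
) -> PeriodFractions:
    """Population period fractions FP(Q) over a range of periods.

    The population value is the mean of the per-tree fractions by
    default; ``reducer`` may also be "median" or "mode" (the most
    common per-tree value).
    """
    mat = flags.flags if isinstance(flags, OnOffFlags) else np.asarray(flags, int)
    if mat.ndim == 1:
        mat = mat[None, :]
    per_tree = np.array(
        [
            [
                fraction_period_individual(
                    row, Q, strict_printed_product=strict_printed_product
                )
                for Q in Q_range
            ]
            for row in mat
        ]
    )
    if reducer == "mean":
        pop = per_tree.mean(axis=0)
    elif reducer == "median":
        pop = np.median(per_tree, axis=0)
    elif reducer == "mode":
        pop = np.array(
            [
                max(zip(*np.unique(col, return_counts=True)), key=lambda vc: vc[1])[0]
                for col in per_tree.T
            ]
        )
    else:
        raise ValueError(f"unknown reducer {reducer!r}")
    return PeriodFractions(per_tree=per_tree, population=pop, Q_range=tuple(Q_range))


def in_phase_fraction(series: ArrayLike) -> SyncFractions:
    """In-phase fraction of a population of production series.

    For each year-to-year step, a pair of trees is in phase when the
    product of their production increments is positive, or when both
    increments are exactly zero (two dormant trees move together).  A
    single zero increment against a nonzero one counts as out of phase.
    The per-tree fractions average over the other N-1 trees, then over
    trees and finally over time.

    Implemented in O(N T) by counting increment signs per year; an
    O(N^2 T) literal pair loop is used as the oracle in the tests.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 2:
        raise ValueError(f"expected (N, T) matrix, got shape {x.shape}")
    N, T = x.shape
    if N < 2 or T < 2:
        raise ValueError("in_phase_fraction requires N >= 2 and T >= 2")
    D = np.diff(x, axis=1)  # (N, T-1)
    pos = D > 0
    neg = D < 0
    zero = D == 0
    n_pos = pos.sum(axis=0)
    n_neg = neg.sum(axis=0)
    n_zero = zero.sum(axis=0)
    # matches for a tree = (# same-sign others); self excluded
    matches = (
        pos * (n_pos - 1) + neg * (n_neg - 1) + zero * (n_zero - 1)
    )
    f_in_i = matches / (N - 1)  # (N, T-1)
    f_in_t = f_in_i.mean(axis=0)
    return SyncFractions(f_in_t=f_in_t, F_IN=float(f_in_t.mean()))
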