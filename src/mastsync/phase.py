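"""Hilbert-transform phases and on/off-year flags for ensemble series.

Each tree's annual production series is mean-centred and converted to a
discrete analytic signal (one-sided FFT spectrum over the full record,
no padding, detrending or tapering); the argument of the analytic
signal is the instantaneous phase.  For a period-3 masting cycle the
phase visits the three fundamental values 0 (on-year), 2pi/3 (first
off-year) and -2pi/3 (second off-year).

On-years can be flagged either from the phase (|theta| < pi/2) or from
the amplitude (production strictly above the tree's temporal mean); on
model output the two rules agree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.signal import hilbert

__all__ = [
    "PhaseEnsemble",
    "OnOffFlags",
    "hilbert_phase",
    "on_flags_amplitude",
    "on_flags_phase",
    "flag_agreement",
    "population_phase",
    "order_parameter",
    "FUNDAMENTAL_PHASES",
]

#: The three phase values of a clean period-3 cycle: on-year, first and
#: second off-year.
FUNDAMENTAL_PHASES = (0.0, 2.0 * np.pi / 3.0, -2.0 * np.pi / 3.0)


@dataclass
class PhaseEnsemble:
    """Wrapped phases theta in (-pi, pi] and analytic amplitudes, (N, T).

    ``valid`` marks trees whose phase is meaningful; a constant
    (zero-variance) series has no phase and is flagged invalid with
    theta set to 0 by convention.
    """

    theta: NDArray[np.float64]
    amplitude: NDArray[np.float64]
    valid: NDArray[np.bool_]


@dataclass
class OnOffFlags:
    """Binary on-year flags, (N, T), with the rule that produced them."""

    flags: NDArray[np.int_]
    rule: str  # "amplitude" or "phase"


def _as_matrix(series: ArrayLike) -> NDArray[np.float64]:
    x = np.asarray(series, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.ndim != 2:
        raise ValueError(f"expected (N, T) series matrix, got shape {x.shape}")
    return x


def hilbert_phase(series: ArrayLike) -> PhaseEnsemble:
    """Instantaneous Hilbert phase of each tree's production series.

    Mirrors the standard MATLAB/`scipy.signal.hilbert` analytic-signal
    construction applied to the mean-centred series over the full
    record length.  Requires T >= 3.  Constant trees are flagged
    invalid (phase 0) with a warning.
    """
    x = _as_matrix(series)
    if x.shape[1] < 3:
        raise ValueError("hilbert_phase requires at least 3 years")
    centred = x - x.mean(axis=1, keepdims=True)
    constant = np.all(centred == 0.0, axis=1)
    if np.any(constant):
        warnings.warn(
            f"{int(constant.sum())} constant series have no defined phase; "
            "flagged invalid",
            stacklevel=2,
        )
    analytic = hilbert(centred, axis=1)
    theta = np.angle(analytic)
    amplitude = np.abs(analytic)
    valid = np.broadcast_to(~constant[:, None], x.shape).copy()
    theta = np.where(valid, theta, 0.0)
    return PhaseEnsemble(theta=theta, amplitude=amplitude, valid=valid)


def on_flags_amplitude(series: ArrayLike) -> OnOffFlags:
    """Flag years strictly above the tree's temporal mean as on-years.

    Ties resolve to off, so an all-equal series is all off-years.
    """
    x = _as_matrix(series)
    flags = (x > x.mean(axis=1, keepdims=True)).astype(int)
    return OnOffFlags(flags=flags, rule="amplitude")


def on_flags_phase(phases: PhaseEnsemble) -> OnOffFlags:
    """Flag years with |theta| strictly below pi/2 as on-years.

    The boundary |theta| = pi/2 and invalid phase entries resolve to
    off (invalid entries with a warning).
    """
    if np.any(~phases.valid):
        warnings.warn("invalid phase entries propagate as off-years", stacklevel=2)
    flags = ((np.abs(phases.theta) < np.pi / 2) & phases.valid).astype(int)
    return OnOffFlags(flags=flags, rule="phase")


def flag_agreement(a: OnOffFlags, b: OnOffFlags) -> float:
    """Fraction of matching entries between two flag matrices."""
    if a.flags.shape != b.flags.shape:
        raise ValueError(
            f"flag shape mismatch: {a.flags.shape} vs {b.flags.shape}"
        )
    return float(np.mean(a.flags == b.flags))


def population_phase(phases: PhaseEnsemble) -> NDArray[np.float64]:
    """Representative population phase Theta(t): per-year median of theta.

    The median is the ordinary median of the wrapped values on
    (-pi, pi], not a circular median; for a tightly synchronised
    population away from the +/-pi seam the two coincide.
    """
    return np.median(phases.theta, axis=0)


def order_parameter(phases_at_t: ArrayLike) -> tuple[float, float]:
    """Kuramoto order parameter of a set of phases.

    Returns ``(r, psi)`` where ``r`` in [0, 1] is the modulus of the
    mean unit phasor (1 = perfect synchrony, 0 = incoherence) and
    ``psi`` its mean angle.
    """
    th = np.asarray(phases_at_t, dtype=float).ravel()
    if th.size == 0:
        raise ValueError("order_parameter needs at least one phase")
    z = np.exp(1j * th).mean()
    return float(np.abs(z)), float(np.angle(z))
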