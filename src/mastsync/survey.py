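"""Synthetic survey generator with masting-survey statistical structure.

Field surveys of masting score each tree's crop on an ordinal scale
(ten classes here) by visual inspection; published summary statistics
describe a dominant on/off/off period-3 cycle, occasional period-2
slips, roughly 70% of all scores in the two lowest classes, and at
least one year in which the population loses phase coherence.  Raw
survey tables of this kind are rarely deposited, so this module
emulates an ensemble with exactly that controlled structure.  It is a
test fixture with known statistics, not a fitted generative model of
any particular species.

Design notes
------------
* Trees share a common period-3 clock; a tree can start one year out
  of phase (``phase_jitter``) and any cycle can shorten to two years
  (``p_slip``), after which the tree's clock stays shifted -- slips
  accumulate, as they do in real ensembles.
* Off-year scores are drawn once per year and shared by all off trees,
  so a perfectly clean configuration (no jitter, no slips, no
  desynchronisation) has in-phase fraction exactly 1.  On-year scores
  are drawn per tree from the upper half of the scale, with a small
  crop-failure probability that lands in the second-lowest class and
  lifts the lowest-two-class mass to about 70%.
* A desynchronised year scrambles each tree's clock by a random
  0/1/2-year shift inside a window of ``desync_halfwidth`` years on
  each side.  The window is needed because the Hilbert phase at a year
  is estimated from the oscillation around it: a single scrambled year
  cannot decohere the phase estimate.  Inside the window off-year
  scores are drawn per tree.  With the default five-year window the
  order parameter in the desynchronised year collapses to the
  incoherent-ensemble floor of order 1/sqrt(N).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = ["SurveyConfig", "generate_survey", "quantize_to_classes"]


@dataclass(frozen=True)
class SurveyConfig:
    """Shape of the synthetic survey.

    ``p_slip`` is the per-tree probability that any one cycle is a
    period-2 slip (on/off instead of on/off/off); ``phase_jitter`` the
    probability that a tree starts one year out of phase with the
    population; ``desync_years`` are years around which per-tree
    phases are scrambled so the population order parameter collapses.
    """

    N: int = 106
    T: int = 15
    n_classes: int = 10
    p_slip: float = 0.1
    phase_jitter: float = 0.1
    desync_years: tuple[int, ...] = (7,)
    desync_halfwidth: int = 2
    #: probability an on-year crop fails into the second-lowest class;
    #: with 2/3 of years off this lifts the lowest-two-class mass to
    #: about 0.67 + 0.33 * 0.1 ~ 0.70.
    p_crop_failure: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        for name in ("p_slip", "phase_jitter", "p_crop_failure"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if any(t < 0 or t >= self.T for t in self.desync_years):
            raise ValueError("desync_years must lie inside the record")
        if self.desync_halfwidth < 0:
            raise ValueError("desync_halfwidth must be >= 0")


def generate_survey(config: SurveyConfig) -> NDArray[np.int_]:
    """Generate an (N, T) ordinal class matrix with period-3 structure.

    Identical seeds give identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    X = np.zeros((cfg.N, cfg.T), dtype=int)

    # common yearly off-year score: the two lowest classes only
    off_common = np.where(rng.random(cfg.T) < 0.55, 0, 1)
    # on-year score distribution: upper half of the scale, peaked mid-high
    top = cfg.n_classes
    highs = np.arange(top // 2, top)
    w = np.minimum(highs - top // 2 + 1, top - highs).astype(float)
    w /= w.sum()

    block: set[int] = set()
    for d in cfg.desync_years:
        block.update(
            range(max(0, d - cfg.desync_halfwidth),
                  min(cfg.T, d + cfg.desync_halfwidth + 1))
        )

    for i in range(cfg.N):
        offset = int(rng.choice([-1, 1])) if rng.random() < cfg.phase_jitter else 0
        # phase 0 = on-year, 1 = first off, 2 = second off
        phase = (-offset) % 3
        cycle_len = 3
        shifts = {d: int(rng.integers(0, 3)) for d in cfg.desync_years}
        for t in range(cfg.T):
            shift = 0
            if t in block:
                nearest = min(cfg.desync_years, key=lambda d: abs(t - d))
                shift = shifts[nearest]
            ph = (phase + shift) % 3
            if ph == 0:
                if rng.random() < cfg.p_crop_failure:
                    X[i, t] = 1
                else:
                    X[i, t] = int(rng.choice(highs, p=w))
            elif t in block:
                X[i, t] = int(rng.integers(0, 2))
            else:
                X[i, t] = off_common[t]
            phase += 1
            if phase >= cycle_len:
                phase = 0
                cycle_len = 2 if rng.random() < cfg.p_slip else 3
    return X


def quantize_to_classes(values: ArrayLike, n_classes: int = 10) -> NDArray[np.int_]:
    """Quantize non-negative values into equal-width ordinal classes.

    Bins cover [0, max] with the maximum mapped into the top class;
    an all-zero input maps to class 0 everywhere.
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)) or np.any(v < 0):
        raise ValueError("values must be finite and non-negative")
    vmax = v.max()
    if vmax == 0.0:
        return np.zeros(v.shape, dtype=int)
    cls = np.floor(v / vmax * n_classes).astype(int)
    return np.minimum(cls, n_classes - 1)
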