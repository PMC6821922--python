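"""End-to-end analysis of an ensemble series: statistics plus figure.

Given an (N, T) ensemble -- survey classes, synthetic survey output or
simulated seed production -- the pipeline computes Hilbert phases,
on-year flags under both rules, period fractions, the in-phase
fraction and the yearly order parameter, and can render the standard
six-panel summary (production traces, production histogram, period
fractions, phase traces, phase histogram with the three fundamental
phase guide lines, and the circle map with the order-parameter arrow).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np

from .io import EnsembleSeries, write_metadata
from .period import DEFAULT_Q_RANGE, fraction_period_population, in_phase_fraction
from .phase import (
    FUNDAMENTAL_PHASES,
    flag_agreement,
    hilbert_phase,
    on_flags_amplitude,
    on_flags_phase,
    order_parameter,
    population_phase,
)

__all__ = ["run_pipeline", "save_stats"]


def run_pipeline(
    series: EnsembleSeries,
    Q_range: tuple[int, ...] = DEFAULT_Q_RANGE,
    figure_path: str | Path | None = None,
) -> dict[str, Any]:
    """Compute the full statistics bundle for one ensemble.

    Returns a JSON-serialisable dict; optionally renders the six-panel
    figure to ``figure_path``.  Stage failures propagate with the
    stage name prepended.
    """
    x = series.values
    stats: dict[str, Any] = {
        "n_trees": series.n_trees,
        "n_years": series.n_years,
        "years": series.years,
    }

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    phases = stage("hilbert_phase", hilbert_phase, x)
    flags_p = stage("on_flags_phase", on_flags_phase, phases)
    flags_a = stage("on_flags_amplitude", on_flags_amplitude, x)
    fp = stage("period_fractions", fraction_period_population, flags_p, Q_range)
    sync = stage("in_phase_fraction", in_phase_fraction, x)
    theta_pop = population_phase(phases)
    r_psi = [order_parameter(phases.theta[:, t]) for t in range(series.n_years)]

    stats.update(
        {
            "FP_population": {str(q): float(v) for q, v in zip(fp.Q_range, fp.population)},
            "FP_per_tree": fp.per_tree.tolist(),
            "F_IN": sync.F_IN,
            "f_in_t": sync.f_in_t.tolist(),
            "flag_agreement": flag_agreement(flags_a, flags_p),
            "population_phase": theta_pop.tolist(),
            "order_parameter_r": [r for r, _ in r_psi],
            "order_parameter_psi": [psi for _, psi in r_psi],
        }
    )

    if figure_path is not None:
        _render_figure(series, phases, fp, r_psi, theta_pop, Path(figure_path))
        stats["figure"] = str(figure_path)
    return stats


def save_stats(stats: dict[str, Any], path: str | Path, meta: dict | None = None) -> None:
    p = Path(path)
    p.write_text(json.dumps(stats, indent=2))
    if meta is not None:
        write_metadata(p.with_suffix(".meta.json"), meta)


def _render_figure(series, phases, fp, r_psi, theta_pop, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = series.values
    years = np.asarray(series.years)
    fig, axes = plt.subplots(2, 3, figsize=(15, 8))

    ax = axes[0, 0]
    ax.plot(years, x.T, color="0.7", lw=0.5)
    ax.plot(years, x.mean(axis=0), color="m", lw=2, label="ensemble mean")
    ax.set(xlabel="year", ylabel="production", title="seed production")
    ax.legend(loc="upper right", fontsize=8)

    ax = axes[0, 1]
    ax.hist(x.ravel(), bins=min(20, max(5, len(np.unique(x)))), color="r", alpha=0.7)
    ax.set(xlabel="production level", ylabel="count", title="production histogram")

    ax = axes[0, 2]
    for i, q in enumerate(fp.Q_range):
        ax.bar(q, fp.population[i], color=f"C{i}")
    ax.set(xlabel="period Q", ylabel="FP(Q)", title="period fractions", ylim=(0, 1))

    ax = axes[1, 0]
    ax.plot(years, phases.theta.T, color="0.7", lw=0.5)
    ax.plot(years, theta_pop, color="m", lw=2)
    for ph in FUNDAMENTAL_PHASES:
        ax.axhline(ph, ls="--", color="k", lw=0.5)
    ax.set(xlabel="year", ylabel=r"$\theta$", title="phase traces")

    ax = axes[1, 1]
    ax.hist(phases.theta.ravel(), bins=36, range=(-np.pi, np.pi), color="r", alpha=0.7)
    for ph in FUNDAMENTAL_PHASES:
        ax.axvline(ph, ls="--", color="k", lw=0.5)
    ax.set(xlabel=r"$\theta$", ylabel="count", title="phase histogram")

    ax = axes[1, 2]
    last = phases.theta[:, -1]
    ax.scatter(np.cos(last), np.sin(last), s=8, color="b")
    r, psi = r_psi[-1]
    ax.annotate(
        "", xy=(r * np.cos(psi), r * np.sin(psi)), xytext=(0, 0),
        arrowprops=dict(arrowstyle="->", color="r", lw=2),
    )
    circ = np.linspace(-np.pi, np.pi, 200)
    ax.plot(np.cos(circ), np.sin(circ), color="0.8", lw=0.5)
    ax.set(title=f"circle map, final year (r={r:.2f})", aspect="equal",
           xlim=(-1.1, 1.1), ylim=(-1.1, 1.1))

    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
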