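"""End-to-end pipeline driver and two-panel survival/LD reporting.

The figure convention follows standard tolerance-assay reports: the upper
panel shows mean c.f.u.·mL⁻¹ against dose with the fitted mean curves and
LD50/LD10 markers (log or square-root count axis); the lower panel shows
the LD values per strain and, with two strains, their differences, as
horizontal 95% intervals around a dashed zero reference.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .assay import read_counts_csv
from .lddose import (
    LethalDoseEstimate,
    StrainContrast,
    ld_confidence_intervals,
    parametric_bootstrap,
    strain_difference,
)
from .model import ModelSpec, NBFit, fit_penalized_nb, predict_mean

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "render_figure"]


@dataclass
class RunConfig:
    """One reproducible analysis run (input table → results bundle)."""

    input: Path
    stress: str = ""
    dose_unit: str = ""
    levels: tuple[float, ...] = (0.5, 0.1)
    n_boot: int = 1000
    seed: int | None = None
    outdir: Path = Path("results")
    plot_format: str = "png"
    scale: str = "log"
    truth: Path | None = None
    model_spec: ModelSpec = field(default_factory=ModelSpec)

    def __post_init__(self) -> None:
        if not all(0.0 < p < 1.0 for p in self.levels):
            raise ValueError("levels must lie in (0, 1)")
        if self.seed is None:
            raise ValueError("a seed is mandatory for bootstrap runs")
        if self.scale not in ("log", "sqrt"):
            raise ValueError("scale must be 'log' or 'sqrt'")
        self.input = Path(self.input)
        self.outdir = Path(self.outdir)


@dataclass
class PipelineResult:
    fit: NBFit
    estimates: list[LethalDoseEstimate]
    contrasts: list[StrainContrast]
    paths: dict[str, Path]
    n_failed: int
    warnings: list[str]


def _estimates_frame(estimates, stress, n_boot, n_failed) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "strain": e.strain,
                "stress": stress,
                "level": e.level,
                "ld": e.ld_value,
                "censored": e.censored,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "n_boot": n_boot,
                "n_failed": n_failed,
            }
            for e in estimates
        ]
    )


def _contrasts_frame(contrasts) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "strain_a": c.strain_a,
                "strain_b": c.strain_b,
                "level": c.level,
                "delta": c.delta,
                "ci_low": c.ci_low,
                "ci_high": c.ci_high,
                "significant": c.significant,
            }
            for c in contrasts
        ]
    )


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Fit, bootstrap, and write the full results bundle.

    Supports one- or two-strain inputs; strain contrasts are produced only
    with two strains.  Outputs: ``ld_estimates.csv``, ``contrasts.csv``
    (two strains), a two-panel figure, a run-manifest JSON, and — when a
    ground-truth JSON is supplied — a truth-comparison table.
    """
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    captured: list[str] = []
    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")
        ds = read_counts_csv(cfg.input, dose_unit=cfg.dose_unit, stress_name=cfg.stress)
        if len(ds.strains) > 2:
            raise ValueError(
                f"{len(ds.strains)} strains found; runs support one test strain "
                "plus at most one control"
            )
        fit = fit_penalized_nb(ds, cfg.model_spec)
        boot = parametric_bootstrap(ds, fit, levels=cfg.levels, n_boot=cfg.n_boot, seed=cfg.seed)
        estimates = ld_confidence_intervals(boot)
        contrasts = []
        if len(ds.strains) == 2:
            a, b = ds.strains
            contrasts = [strain_difference(boot, a, b, p) for p in cfg.levels]
        captured = [str(w.message) for w in wrec]

    paths: dict[str, Path] = {}
    est_path = cfg.outdir / "ld_estimates.csv"
    _estimates_frame(estimates, cfg.stress, boot.n_boot, boot.n_failed).to_csv(
        est_path, index=False
    )
    paths["estimates"] = est_path
    if contrasts:
        con_path = cfg.outdir / "contrasts.csv"
        _contrasts_frame(contrasts).to_csv(con_path, index=False)
        paths["contrasts"] = con_path

    fig = render_figure(fit, estimates, contrasts, scale=cfg.scale)
    fig_path = cfg.outdir / f"survival.{cfg.plot_format}"
    fig.savefig(fig_path, dpi=150)
    plt.close(fig)
    paths["figure"] = fig_path

    if cfg.truth is not None:
        paths["truth_comparison"] = _truth_comparison(
            Path(cfg.truth), estimates, cfg.outdir
        )

    manifest = {
        "input": str(cfg.input),
        "stress": cfg.stress,
        "dose_unit": cfg.dose_unit,
        "levels": list(cfg.levels),
        "n_boot": boot.n_boot,
        "n_failed": boot.n_failed,
        "seed": cfg.seed,
        "lambdas": fit.lambdas,
        "theta": fit.theta,
        "edf": fit.edf,
        "deviance": fit.deviance,
        "converged": fit.converged,
        "warnings": captured,
        "outputs": {k: str(v) for k, v in paths.items()},
    }
    man_path = cfg.outdir / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2))
    paths["manifest"] = man_path
    return PipelineResult(fit, estimates, contrasts, paths, boot.n_failed, captured)


def _truth_comparison(truth_path: Path, estimates, outdir: Path) -> Path:
    truth = json.loads(truth_path.read_text())["true_ld"]
    rows = []
    for e in estimates:
        t = truth.get(e.strain, {}).get(str(e.level))
        if t is None:
            continue
        rows.append(
            {
                "strain": e.strain,
                "level": e.level,
                "true_ld": t,
                "estimated": e.ld_value,
                "rel_error": abs(e.ld_value - t) / t,
                "ci_covers_truth": (e.ci_low <= t <= e.ci_high)
                if e.ci_low is not None
                else None,
            }
        )
    path = outdir / "truth_comparison.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def _sqrt_scale(ax) -> None:
    ax.set_yscale(
        "function",
        functions=(lambda v: np.sqrt(np.clip(v, 0, None)), lambda v: v**2),
    )


def render_figure(
    fit: NBFit,
    estimates: list[LethalDoseEstimate],
    contrasts: list[StrainContrast] | None = None,
    scale: str = "log",
) -> plt.Figure:
    """Two-panel survival/LD figure; returns the matplotlib Figure.

    LD markers in the upper panel are vertical lines whose artists carry
    gid ``ld-<strain>-<level>`` so their positions can be read back and
    checked against the results table.
    """
    if not estimates:
        raise ValueError("estimates must be non-empty")
    contrasts = contrasts or []
    fig, (ax_top, ax_bot) = plt.subplots(
        2, 1, figsize=(7, 8), height_ratios=[2, 1], constrained_layout=True
    )
    colors = {s: f"C{i}" for i, s in enumerate(fit.strains)}

    for s in fit.strains:
        rows = fit.design.strain_rows == s
        d_row = fit.design.dose_rows[rows]
        y_row = fit.design.counts[rows]
        means = pd.Series(y_row).groupby(pd.Series(d_row)).mean()
        ax_top.plot(means.index, means.values, "o", color=colors[s], label=s)
        ref_exp = fit.design.exp_levels[s][0]
        grid = np.linspace(0.0, fit.d_max.get(s, float(d_row.max())), 200)
        curve = predict_mean(fit, s, ref_exp, grid)
        ax_top.plot(grid, curve, "-", color=colors[s])
    for e in estimates:
        ax_top.axvline(
            e.ld_value,
            color=colors.get(e.strain, "k"),
            linestyle="--" if e.level == 0.5 else ":",
            alpha=0.7,
            gid=f"ld-{e.strain}-{e.level}",
        )
    if scale == "log":
        ax_top.set_yscale("log")
    else:
        _sqrt_scale(ax_top)
    ax_top.set_xlabel(f"dose ({fit.dose_unit})" if fit.dose_unit else "dose")
    ax_top.set_ylabel("mean c.f.u. mL$^{-1}$")
    if fit.stress_name:
        ax_top.set_title(fit.stress_name)
    ax_top.legend()

    labels, centers, lows, highs, cols = [], [], [], [], []
    for e in estimates:
        labels.append(f"LD{int(round(e.level * 100))} {e.strain}")
        centers.append(e.ld_value)
        lows.append(e.ci_low if e.ci_low is not None else e.ld_value)
        highs.append(e.ci_high if e.ci_high is not None else e.ld_value)
        cols.append(colors.get(e.strain, "k"))
    for c in contrasts:
        labels.append(f"ΔLD{int(round(c.level * 100))} {c.strain_a}−{c.strain_b}")
        centers.append(c.delta)
        lows.append(c.ci_low)
        highs.append(c.ci_high)
        cols.append("k")
    ypos = np.arange(len(labels))[::-1]
    for yp, ctr, lo, hi, col in zip(ypos, centers, lows, highs, cols):
        ax_bot.plot([lo, hi], [yp, yp], "-", color=col)
        ax_bot.plot([ctr], [yp], "o", color=col)
    ax_bot.axvline(0.0, color="grey", linestyle="--")
    ax_bot.set_yticks(ypos)
    ax_bot.set_yticklabels(labels)
    ax_bot.set_xlabel(
        f"dose ({fit.dose_unit})" if fit.dose_unit else "dose"
    )
    return fig
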