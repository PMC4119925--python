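"""Lethal-dose estimation: model-based survival curves, LDp inversion, and
parametric-bootstrap confidence intervals.

The survival fraction at dose d is the ratio of the model's predicted mean
count at d to its prediction at dose 0, so the unknown inoculum (intercept
and experiment effects) cancels.  LDp is the smallest dose at which that
fraction drops to p; values beyond the tested range are reported as
right-censored bounds rather than extrapolated.  Confidence intervals come
from a full parametric bootstrap: counts are redrawn from the fitted
NB(μ̂, θ̂) at the original design points and the entire fit — smoothing
selection and dispersion included — is repeated per replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .assay import ToleranceDataset
from .model import DegenerateFitError, NBFit, _fit_from_design
from .simulate import _rnbinom

__all__ = [
    "LethalDoseEstimate",
    "StrainContrast",
    "BootstrapSummary",
    "survival_curve",
    "estimate_ld",
    "parametric_bootstrap",
    "ld_confidence_intervals",
    "strain_difference",
]


@dataclass
class LethalDoseEstimate:
    """LDp point estimate (and, after bootstrap, its percentile CI).

    ``censored`` means the fitted curve never reaches p within the tested
    dose range: the value is a lower bound, read "LDp > ld_value".
    """

    strain: str
    level: float
    ld_value: float
    censored: bool
    ci_low: float | None = None
    ci_high: float | None = None
    ci_low_censored: bool = False
    ci_high_censored: bool = False
    n_boot: int = 0


@dataclass
class StrainContrast:
    """Bootstrap contrast LDp(a) − LDp(b); significant iff CI excludes 0."""

    strain_a: str
    strain_b: str
    level: float
    delta: float
    ci_low: float
    ci_high: float
    significant: bool
    boot_deltas: np.ndarray = field(repr=False)
    n_excluded: int = 0


@dataclass
class BootstrapSummary:
    """Per-replicate LD draws for every strain and level.

    Failed replicates (non-convergent or degenerate refits) are counted in
    ``n_failed`` and excluded from the draw arrays; censored draws are kept
    at the censoring bound d_max so they enter the order statistics.
    """

    n_boot: int
    n_failed: int
    seed: int
    levels: tuple[float, ...]
    strains: list[str]
    draws: dict[tuple[str, float], np.ndarray]
    censored: dict[tuple[str, float], np.ndarray]
    d_max: dict[str, float]
    point: dict[tuple[str, float], LethalDoseEstimate]


def survival_curve(fit: NBFit, strain: str, dose_grid) -> np.ndarray:
    """Model-based survival fractions μ̂(d)/μ̂(0) for one strain.

    Experiment effects cancel in the ratio under the nested fixed-effect
    design, so the curve is experiment-free; the fraction at dose 0 is 1
    exactly.
    """
    d = np.asarray(dose_grid, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be >= 0")
    f = fit.smooth_value(strain, np.sqrt(d))
    f0 = fit.smooth_value(strain, np.zeros(1))[0]
    return np.exp(f - f0)


def _invert_survival(curve, p: float, d_max: float, n_grid: int = 512):
    """Smallest d in [0, d_max] with curve(d) <= p, or None if no crossing.

    Scan on a uniform grid in √dose, then bisection to |Δd| < d_max·1e-6.
    ``curve`` maps a dose array to survival fractions.
    """
    d = np.linspace(0.0, np.sqrt(d_max), n_grid) ** 2
    frac = np.asarray(curve(d))
    below = np.flatnonzero(frac <= p)
    if below.size == 0:
        return None
    i = int(below[0])
    if i == 0:
        return 0.0
    lo, hi = d[i - 1], d[i]
    # vectorized bracket refinement (64-way per round ~ 6 bisection steps)
    while hi - lo > d_max * 1e-6:
        dd = np.linspace(lo, hi, 65)
        fr = np.asarray(curve(dd))
        j = int(np.flatnonzero(fr <= p)[0])
        lo, hi = dd[j - 1], dd[j]
    return float(hi)


def estimate_ld(
    fit: NBFit, strain: str, p: float, d_max: float | None = None
) -> LethalDoseEstimate:
    """Point estimate of LDp by inverting the fitted survival curve.

    ``d_max`` defaults to the maximum observed dose for the strain; when
    the curve never crosses p within [0, d_max] the estimate is censored
    at d_max (LDp > d_max).
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    if d_max is None:
        if strain not in fit.d_max:
            raise KeyError(f"no observed dose range recorded for strain {strain!r}")
        d_max = fit.d_max[strain]
    ld = _invert_survival(lambda d: survival_curve(fit, strain, d), p, d_max)
    if ld is None:
        return LethalDoseEstimate(strain, p, float(d_max), censored=True)
    return LethalDoseEstimate(strain, p, ld, censored=False)


def parametric_bootstrap(
    ds: ToleranceDataset,
    fit: NBFit,
    levels=(0.5, 0.1),
    n_boot: int = 1000,
    seed: int | None = None,
) -> BootstrapSummary:
    """Full parametric bootstrap of the LD estimates.

    Each replicate redraws counts from NB(μ̂, θ̂) at the original design
    points and refits the whole model, re-selecting the smoothing
    parameters and re-estimating θ, so the intervals carry smoothing
    uncertainty.  Reproducible given ``seed``; replicates whose refit
    fails or does not converge are counted in ``n_failed`` and dropped
    (with a warning above 5%, a hard error above 50%).
    """
    if seed is None:
        raise ValueError("a seed is required for the bootstrap")
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if not fit.converged:
        raise ValueError("refusing to bootstrap a non-convergent fit")
    levels = tuple(levels)
    rng = np.random.default_rng(seed)
    strains = fit.strains
    d_max = dict(fit.d_max)
    vals: dict[tuple[str, float], list[float]] = {(s, p): [] for s in strains for p in levels}
    cens: dict[tuple[str, float], list[bool]] = {(s, p): [] for s in strains for p in levels}
    n_failed = 0
    for _ in range(n_boot):
        y_star = _rnbinom(rng, fit.fitted, fit.theta)
        try:
            refit = _fit_from_design(
                fit.design, y_star, fit.spec, d_max=d_max,
                dose_unit=fit.dose_unit, stress_name=fit.stress_name,
                beta0=fit.coefficients, theta0=fit.theta,
            )
        except (DegenerateFitError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        if not refit.converged:
            n_failed += 1
            continue
        for s in strains:
            for p in levels:
                est = estimate_ld(refit, s, p, d_max=d_max[s])
                vals[(s, p)].append(est.ld_value)
                cens[(s, p)].append(est.censored)
    if n_failed > 0.5 * n_boot:
        raise RuntimeError(
            f"{n_failed}/{n_boot} bootstrap replicates failed; "
            "model too unstable for interval estimation"
        )
    if n_failed > 0.05 * n_boot:
        warnings.warn(
            f"{n_failed}/{n_boot} bootstrap replicates failed to refit",
            stacklevel=2,
        )
    point = {
        (s, p): estimate_ld(fit, s, p, d_max=d_max[s]) for s in strains for p in levels
    }
    return BootstrapSummary(
        n_boot=n_boot,
        n_failed=n_failed,
        seed=seed,
        levels=levels,
        strains=strains,
        draws={k: np.asarray(v) for k, v in vals.items()},
        censored={k: np.asarray(v, dtype=bool) for k, v in cens.items()},
        d_max=d_max,
        point=point,
    )


def ld_confidence_intervals(
    boot: BootstrapSummary, level: float = 0.95
) -> list[LethalDoseEstimate]:
    """Percentile CIs from the bootstrap draws, per strain and LD level.

    Censored draws sit at d_max in the order statistics; a CI bound that
    lands on such a value is itself flagged censored.
    """
    out = []
    q = np.array([(1.0 - level) / 2.0, 1.0 - (1.0 - level) / 2.0])
    for s in boot.strains:
        for p in boot.levels:
            values = boot.draws[(s, p)]
            if values.size < 2:
                raise ValueError("need at least 2 successful replicates for a CI")
            lo, hi = np.quantile(values, q)
            any_cens = bool(boot.censored[(s, p)].any())
            bound = boot.d_max[s]
            est = boot.point[(s, p)]
            out.append(
                LethalDoseEstimate(
                    strain=s,
                    level=p,
                    ld_value=est.ld_value,
                    censored=est.censored,
                    ci_low=float(lo),
                    ci_high=float(hi),
                    ci_low_censored=any_cens and lo >= bound * (1 - 1e-12),
                    ci_high_censored=any_cens and hi >= bound * (1 - 1e-12),
                    n_boot=boot.n_boot,
                )
            )
    return out


def strain_difference(
    boot: BootstrapSummary, strain_a: str, strain_b: str, p: float, level: float = 0.95
) -> StrainContrast:
    """Bootstrap distribution and CI of LDp(a) − LDp(b).

    Replicates censored for exactly one of the two strains carry no usable
    difference and are excluded (their number is reported); a CI excluding
    zero is flagged significant.
    """
    va, vb = boot.draws[(strain_a, p)], boot.draws[(strain_b, p)]
    ca, cb = boot.censored[(strain_a, p)], boot.censored[(strain_b, p)]
    keep = ~(ca ^ cb)
    deltas = va[keep] - vb[keep]
    n_excluded = int((~keep).sum())
    if n_excluded:
        warnings.warn(
            f"{n_excluded} replicate(s) censored for exactly one strain "
            "excluded from the contrast",
            stacklevel=2,
        )
    if deltas.size < 2:
        raise ValueError("fewer than 2 usable replicates for the contrast")
    lo, hi = np.quantile(deltas, [(1.0 - level) / 2.0, 1.0 - (1.0 - level) / 2.0])
    delta = boot.point[(strain_a, p)].ld_value - boot.point[(strain_b, p)].ld_value
    return StrainContrast(
        strain_a=strain_a,
        strain_b=strain_b,
        level=p,
        delta=float(delta),
        ci_low=float(lo),
        ci_high=float(hi),
        significant=bool(lo > 0.0 or hi < 0.0),
        boot_deltas=deltas,
        n_excluded=n_excluded,
    )
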