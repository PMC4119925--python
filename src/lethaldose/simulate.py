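"""Synthetic tolerance-assay generator with known ground-truth LD values.

Radiation-resistant actinobacteria typically show a "shoulder of
resistance": survival stays near 1 up to a threshold dose and then declines
log-linearly.  The generator uses a softplus-shoulder survival family that
nests pure exponential decay (shoulder 0), has a closed-form LD limit
(LDp → D₀ + ln(1/p)/k as the transition sharpens), and feeds NB count noise
with an unknown multiplicative inoculum per experiment — the features the
count model must cope with on real assay data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .assay import ToleranceDataset

__all__ = [
    "ShoulderCurveParams",
    "SimulationConfig",
    "shoulder_survival",
    "true_ld",
    "simulate_dataset",
    "default_config",
    "DOSE_GRIDS",
]

# dose grids mirroring common assay designs (a leading 0 is always included)
DOSE_GRIDS: dict[str, tuple[float, ...]] = {
    "chemical": (0, 1, 5, 10, 20, 40, 60, 120),  # minutes of exposure
    "desiccation": (0, 20, 40, 60, 80, 100),  # days
    "radiation": (0, 2.5, 5, 7.5, 10, 12.5),  # kGy
}


@dataclass(frozen=True)
class ShoulderCurveParams:
    """Ground-truth survival curve S(d).

    log S(d) = −k·softplus_s(d − D₀) + k·softplus_s(−D₀), where
    softplus_s(u) = s·log(1 + exp(u/s)).  ``shoulder`` D₀ is the dose below
    which survival stays near 1; ``decay_rate`` k is the log-survival slope
    beyond it; ``smoothness`` s is the transition width.  S(0) = 1 exactly,
    S is strictly decreasing past the shoulder, and S → 0 as d → ∞.
    """

    shoulder: float
    decay_rate: float
    smoothness: float = 0.1

    def __post_init__(self) -> None:
        if self.shoulder < 0:
            raise ValueError("shoulder must be >= 0")
        if self.decay_rate <= 0 or self.smoothness <= 0:
            raise ValueError("decay_rate and smoothness must be > 0")


def _softplus(u: np.ndarray, s: float) -> np.ndarray:
    return s * np.logaddexp(0.0, u / s)


def shoulder_survival(params: ShoulderCurveParams, dose) -> np.ndarray:
    """Survival fraction S(d) in (0, 1] for doses ``dose`` >= 0."""
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be >= 0")
    k, d0, s = params.decay_rate, params.shoulder, params.smoothness
    log_s = -k * _softplus(d - d0, s) + k * _softplus(-d0, s)
    return np.exp(log_s)


def true_ld(params: ShoulderCurveParams, p: float) -> float:
    """Dose at which S(d) = p, by root bracketing to 1e-10 relative.

    Approaches the closed form D₀ + ln(1/p)/k as smoothness → 0.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    k, d0, s = params.decay_rate, params.shoulder, params.smoothness
    target = np.log(p)

    def f(d: float) -> float:
        return float(-k * _softplus(np.asarray(d - d0), s) + k * _softplus(np.asarray(-d0), s) - target)

    hi = d0 + np.log(1.0 / p) / k + 10.0 * s + 1.0
    while f(hi) > 0:
        hi *= 2.0
    return float(brentq(f, 0.0, hi, rtol=1e-12, xtol=1e-12))


@dataclass
class SimulationConfig:
    """Study design for one synthetic assay.

    Defaults emulate a two-strain chemical-stress assay: two independent
    experiment repetitions per strain, duplicate plates, an expected
    baseline inoculum of 1e4 c.f.u.·mL⁻¹, NB dispersion θ = 5, and
    log-normal experiment-to-experiment inoculum variation (sd 0.3 on the
    log scale).
    """

    strains: list[tuple[str, ShoulderCurveParams]]
    dose_grid: tuple[float, ...] = DOSE_GRIDS["chemical"]
    experiments_per_strain: int = 2
    plate_replicates: int = 2
    experiment_effect_sd: float = 0.3
    baseline_count: float = 1e4
    theta: float = 5.0
    seed: int = 0
    dose_unit: str = "min"
    stress_name: str = "simulated"

    def __post_init__(self) -> None:
        if self.baseline_count <= 0 or self.theta <= 0:
            raise ValueError("baseline_count and theta must be > 0")
        if self.experiments_per_strain < 1 or self.plate_replicates < 1:
            raise ValueError("need at least one experiment and one plate")
        d = np.asarray(self.dose_grid, dtype=float)
        if np.any(d < 0) or np.any(np.diff(d) <= 0):
            raise ValueError("dose_grid must be non-negative and strictly increasing")

    def true_ld_table(self, levels=(0.5, 0.1)) -> dict[str, dict[str, float]]:
        """Closed ground truth, e.g. {"strainA": {"0.5": ld50, "0.1": ld10}}."""
        return {
            name: {str(p): true_ld(params, p) for p in levels}
            for name, params in self.strains
        }

    def to_json(self, path, levels=(0.5, 0.1)) -> None:
        payload = {
            "true_ld": self.true_ld_table(levels),
            "config": {
                "strains": {n: asdict(p) for n, p in self.strains},
                "dose_grid": list(map(float, self.dose_grid)),
                "experiments_per_strain": self.experiments_per_strain,
                "plate_replicates": self.plate_replicates,
                "experiment_effect_sd": self.experiment_effect_sd,
                "baseline_count": self.baseline_count,
                "theta": self.theta,
                "dose_unit": self.dose_unit,
                "stress_name": self.stress_name,
            },
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _rnbinom(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    """NB(mean μ, dispersion θ) draws via the gamma–Poisson mixture."""
    mu = np.asarray(mu, dtype=float)
    if not np.isfinite(theta) or theta > 1e12:
        return rng.poisson(mu).astype(float)
    lam = rng.gamma(shape=theta, scale=mu / theta)
    return rng.poisson(lam).astype(float)


def simulate_dataset(cfg: SimulationConfig) -> ToleranceDataset:
    """Draw one synthetic assay dataset; same seed → identical data."""
    rng = np.random.default_rng(cfg.seed)
    doses = np.asarray(cfg.dose_grid, dtype=float)
    rows = []
    for name, params in cfg.strains:
        surv = shoulder_survival(params, doses)
        for e in range(cfg.experiments_per_strain):
            shift = rng.normal(0.0, cfg.experiment_effect_sd)
            means = cfg.baseline_count * np.exp(shift) * surv
            for _rep in range(cfg.plate_replicates):
                counts = _rnbinom(rng, means, cfg.theta)
                for d, c in zip(doses, counts):
                    rows.append((name, f"exp{e + 1}", float(d), float(c)))
    frame = pd.DataFrame(rows, columns=["strain", "experiment", "dose", "count"])
    return ToleranceDataset(frame, dose_unit=cfg.dose_unit, stress_name=cfg.stress_name)


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Two identical shoulder-curve strains on the chemical dose grid.

    Shoulder 2, decay rate 0.5, smoothness 0.1 (arbitrary dose units):
    survival holds near 1 over the first couple of doses, then falls
    exponentially — the canonical resistant-strain phenotype.
    """
    params = ShoulderCurveParams(shoulder=2.0, decay_rate=0.5, smoothness=0.1)
    cfg = SimulationConfig(
        strains=[("strainA", params), ("strainB", params)],
        seed=seed,
    )
    for key, val in overrides.items():
        setattr(cfg, key, val)
    cfg.__post_init__()
    return cfg
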