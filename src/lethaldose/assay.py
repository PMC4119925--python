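"""Tolerance-assay data model, CSV I/O, survival fractions and MIC calls.

A tolerance assay exposes a bacterial suspension to increasing doses of a
stressor (gamma/UV radiation, mitomycin C, hydrogen peroxide, desiccation
time) and plates aliquots; the observable is the recovered colony count in
c.f.u.·mL⁻¹ at each dose.  Because the initial inoculum is unknown, all
downstream survival quantities are ratios to a within-group baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ToleranceDataset",
    "MICTable",
    "MICResult",
    "SchemaError",
    "ValidationError",
    "read_counts_csv",
    "write_counts_csv",
    "compute_survival_fractions",
    "read_mic_csv",
    "compute_mic",
]

COUNT_COLUMNS = ["strain", "experiment", "dose", "count"]


class SchemaError(ValueError):
    """Input table lacks a required column."""


class ValidationError(ValueError):
    """A row violates the assay-data invariants."""


@dataclass
class ToleranceDataset:
    """Tidy table of (strain, experiment, dose, count) observations.

    Parameters
    ----------
    frame
        DataFrame with columns ``strain``, ``experiment``, ``dose``,
        ``count``.  Plate duplicates are separate rows and are never
        averaged here; row order is preserved.
    dose_unit
        Free-text unit of the dose axis (``"min"``, ``"days"``, ``"kGy"``,
        ``"mM"``...).
    stress_name
        Free-text stressor label (``"UV"``, ``"mitomycin C"``...).
    """

    frame: pd.DataFrame
    dose_unit: str = ""
    stress_name: str = ""

    def __post_init__(self) -> None:
        self.frame = _validate_counts(self.frame)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def strains(self) -> list[str]:
        """Strain labels in order of first appearance."""
        return list(dict.fromkeys(self.frame["strain"]))

    def experiments(self, strain: str) -> list[str]:
        sub = self.frame[self.frame["strain"] == strain]
        return list(dict.fromkeys(sub["experiment"]))

    def max_dose(self, strain: str) -> float:
        return float(self.frame.loc[self.frame["strain"] == strain, "dose"].max())


def _validate_counts(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COUNT_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    frame = frame.loc[:, COUNT_COLUMNS].reset_index(drop=True)
    frame["strain"] = frame["strain"].astype(str)
    frame["experiment"] = frame["experiment"].astype(str)
    for col in ("dose", "count"):
        try:
            frame[col] = pd.to_numeric(frame[col])
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"column {col!r} is not numeric: {exc}") from exc
    for i, row in enumerate(frame.itertuples(index=False)):
        if not row.strain or not row.experiment:
            raise ValidationError(f"row {i}: empty strain/experiment label")
        if not np.isfinite(row.dose) or row.dose < 0:
            raise ValidationError(f"row {i}: dose must be finite and >= 0, got {row.dose}")
        if not np.isfinite(row.count) or row.count < 0:
            raise ValidationError(f"row {i}: count must be finite and >= 0, got {row.count}")
    for strain, sub in frame.groupby("strain", sort=False):
        if sub["dose"].nunique() < 2:
            raise ValidationError(
                f"strain {strain!r} has fewer than 2 distinct doses; no curve can be fit"
            )
    return frame


def read_counts_csv(path, dose_unit: str = "", stress_name: str = "") -> ToleranceDataset:
    """Read a comma-separated assay table with header strain,experiment,dose,count."""
    frame = pd.read_csv(path)
    return ToleranceDataset(frame, dose_unit=dose_unit, stress_name=stress_name)


def write_counts_csv(ds: ToleranceDataset, path) -> None:
    """Write the dataset back out; full float precision, row order preserved."""
    ds.frame.to_csv(path, index=False)


def compute_survival_fractions(ds: ToleranceDataset) -> pd.DataFrame:
    """Observed survival fractions per (strain, experiment, dose).

    The baseline for each (strain, experiment) group is the mean count at
    the group's minimum tested dose (dose 0 where plated, else the first
    sampling point, as in desiccation series that start at 20 days).  The
    fraction at the minimum dose is exactly 1, and all fractions are
    invariant under rescaling every count in the group by a positive
    constant — the property that motivates modelling raw counts when the
    initial inoculum is unknown.
    """
    rows = []
    for (strain, experiment), sub in ds.frame.groupby(["strain", "experiment"], sort=False):
        means = sub.groupby("dose", sort=True)["count"].mean()
        d_min = means.index[0]
        baseline = means.iloc[0]
        if baseline <= 0:
            raise ValidationError(
                f"group ({strain!r}, {experiment!r}): zero mean count at minimum dose "
                f"{d_min}; survival fractions undefined"
            )
        for dose, m in means.items():
            rows.append((strain, experiment, float(dose), float(m / baseline)))
    return pd.DataFrame(rows, columns=["strain", "experiment", "dose", "fraction"])


# ---------------------------------------------------------------------------
# Minimum inhibitory concentration
# ---------------------------------------------------------------------------


@dataclass
class MICTable:
    """Growth/no-growth calls over a concentration ladder for one agent."""

    agent: str
    concentrations: np.ndarray
    growth: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.concentrations.ndim != 1 or len(self.concentrations) == 0:
            raise ValidationError("concentrations must be a non-empty 1-D array")
        if np.any(self.concentrations <= 0):
            raise ValidationError("concentrations must be positive")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValidationError("concentrations must be strictly increasing")
        self.growth = {
            s: np.asarray(g, dtype=bool) for s, g in self.growth.items()
        }
        for s, g in self.growth.items():
            if g.shape != self.concentrations.shape:
                raise ValidationError(
                    f"strain {s!r}: growth calls do not cover every tested concentration"
                )


@dataclass(frozen=True)
class MICResult:
    """MIC call for one strain; ``censored`` means growth at every tested level."""

    strain: str
    agent: str
    mic: float
    censored: bool

    def __str__(self) -> str:
        rel = ">" if self.censored else "="
        return f"MIC({self.strain}, {self.agent}) {rel} {self.mic:g} mM"


def compute_mic(table: MICTable, strain: str) -> MICResult:
    """Smallest tested concentration at and above which no growth occurs.

    Growth at every tested concentration returns a right-censored result at
    the maximum.  A non-monotone pattern (growth above a no-growth level)
    is resolved conservatively — the smallest concentration above the last
    growth call — with a warning, since inhibition is assumed monotone.
    """
    if strain not in table.growth:
        raise KeyError(f"no growth calls for strain {strain!r}")
    g = table.growth[strain]
    conc = table.concentrations
    grown = np.flatnonzero(g)
    if grown.size == len(conc):
        return MICResult(strain, table.agent, float(conc[-1]), censored=True)
    if grown.size == 0:
        return MICResult(strain, table.agent, float(conc[0]), censored=False)
    first_no_growth = np.flatnonzero(~g)[0]
    if grown[-1] > first_no_growth:
        warnings.warn(
            f"strain {strain!r}, agent {table.agent!r}: growth at "
            f"{conc[grown[-1]]:g} mM above no-growth at {conc[first_no_growth]:g} mM; "
            "using the smallest concentration above which all calls are no-growth",
            stacklevel=2,
        )
    i = grown[-1] + 1
    if i >= len(conc):  # unreachable given grown.size < len(conc) handled above
        return MICResult(strain, table.agent, float(conc[-1]), censored=True)
    return MICResult(strain, table.agent, float(conc[i]), censored=False)


def read_mic_csv(path) -> dict[str, MICTable]:
    """Read growth calls (header strain,agent,concentration_mM,growth) into per-agent tables."""
    frame = pd.read_csv(path)
    required = ["strain", "agent", "concentration_mM", "growth"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    tables: dict[str, MICTable] = {}
    for agent, sub in frame.groupby("agent", sort=False):
        conc = np.sort(sub["concentration_mM"].unique())
        growth = {}
        for strain, ssub in sub.groupby("strain", sort=False):
            ssub = ssub.set_index("concentration_mM").reindex(conc)
            if ssub["growth"].isna().any():
                raise ValidationError(
                    f"strain {strain!r}, agent {agent!r}: growth call missing for some concentration"
                )
            growth[str(strain)] = ssub["growth"].astype(int).to_numpy().astype(bool)
        tables[str(agent)] = MICTable(str(agent), conc, growth)
    return tables
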