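"""Preprocessing of body-mass trajectories.

Implements the corrections applied before model fitting: adding back excreted
mass (urine/stool) so that mass change reflects evaporation only, imputing
sporadically missing weighings, excluding animals that lost too much mass,
and coding the regression table (ln mass on time, water, temperature and
ln snout--vent length).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

STATUS_OBSERVED = "observed"
STATUS_IMPUTED_REGRESSION = "imputed_regression"
STATUS_IMPUTED_ADJACENT = "imputed_adjacent"
STATUS_MASKED = "masked"
STATUS_TRUNCATED = "truncated"

VALID_STATUS = {
    STATUS_OBSERVED,
    STATUS_IMPUTED_REGRESSION,
    STATUS_IMPUTED_ADJACENT,
    STATUS_MASKED,
    STATUS_TRUNCATED,
}

#: statuses whose mass value enters the model frame
_USABLE = {STATUS_OBSERVED, STATUS_IMPUTED_REGRESSION, STATUS_IMPUTED_ADJACENT}


@dataclass
class MassSeries:
    """One individual's timed body-mass observations with provenance flags.

    Masses are grams, times are minutes from treatment start.  Entries whose
    status is ``masked`` or ``truncated`` carry NaN mass; all other masses
    must be strictly positive.  ``excreted_g[i]`` records urine/stool mass
    shed at ``times[i]`` (zero when no event).
    """

    individual_id: str
    times: np.ndarray
    masses: np.ndarray
    excreted_g: np.ndarray | None = None
    status: np.ndarray | None = None
    dropout: bool = False
    manual_exclude: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.excreted_g is None:
            self.excreted_g = np.zeros_like(self.masses)
        else:
            self.excreted_g = np.asarray(self.excreted_g, dtype=float)
        if self.status is None:
            self.status = np.array([STATUS_OBSERVED] * len(self.times), dtype=object)
        else:
            self.status = np.asarray(self.status, dtype=object)
        self.validate()

    def validate(self) -> None:
        n = len(self.times)
        if not (len(self.masses) == len(self.excreted_g) == len(self.status) == n):
            raise ValueError(
                f"{self.individual_id}: per-time vectors have unequal lengths"
            )
        if n and np.any(np.diff(self.times) <= 0):
            raise ValueError(f"{self.individual_id}: times must be strictly increasing")
        bad = set(self.status) - VALID_STATUS
        if bad:
            raise ValueError(f"{self.individual_id}: unknown status values {bad}")
        usable = np.array([s in _USABLE for s in self.status], dtype=bool)
        if np.any(~np.isfinite(self.masses[usable])) or np.any(
            self.masses[usable] <= 0
        ):
            raise ValueError(f"{self.individual_id}: masses must be > 0")

    def copy(self) -> "MassSeries":
        return MassSeries(
            individual_id=self.individual_id,
            times=self.times.copy(),
            masses=self.masses.copy(),
            excreted_g=self.excreted_g.copy(),
            status=self.status.copy(),
            dropout=self.dropout,
            manual_exclude=self.manual_exclude,
        )

    @property
    def n_obs(self) -> int:
        return len(self.times)

    def usable_mask(self) -> np.ndarray:
        return np.array([s in _USABLE for s in self.status], dtype=bool)

    def loss_fraction(self) -> float:
        """Largest fractional mass loss relative to the starting mass."""
        usable = self.usable_mask()
        if not usable.any():
            return 0.0
        m = self.masses[usable]
        return float((m[0] - m.min()) / m[0])


@dataclass
class CodingConfig:
    """Covariate coding for the regression table.

    Water is 0/1 with the no-water baseline; temperature enters in deg C
    centered at ``temp_center`` so the intercept refers to that temperature;
    ln SVL is centered per species (``svl_centers`` maps species label to the
    centering constant on the ln-mm scale, or is computed as the
    within-species mean of ln SVL when left empty).
    """

    temp_center: float = 26.0
    svl_centers: dict[str, float] = field(default_factory=dict)
    baseline_species: str = "Xenopus_tropicalis"
    nugget: float = 1e-8

    def resolve_svl_centers(self, individuals: Sequence["object"]) -> dict[str, float]:
        if self.svl_centers:
            return dict(self.svl_centers)
        by_species: dict[str, list[float]] = {}
        for ind in individuals:
            by_species.setdefault(ind.species, []).append(math.log(ind.svl_mm))
        return {sp: float(np.mean(v)) for sp, v in by_species.items()}


@dataclass
class ModelFrame:
    """The fully coded regression table.

    ``data`` has one row per retained observation with columns
    ``ln_mass, time_min, water, temp_c, temp_centered, ln_svl_centered,
    species, frog, housing, date, status``.  ``coding`` records the applied
    coding (centering constants included) so the frame is self-describing.
    """

    data: pd.DataFrame
    coding: CodingConfig
    metadata: dict = field(default_factory=dict)

    REQUIRED = (
        "ln_mass",
        "time_min",
        "water",
        "temp_c",
        "temp_centered",
        "ln_svl_centered",
        "species",
        "frog",
        "housing",
        "date",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"model frame missing columns {missing}")
        if self.data[list(self.REQUIRED)].isna().any().any():
            raise ValueError("model frame contains missing values")
        if not set(self.data["water"].unique()) <= {0, 1}:
            raise ValueError("water must be coded 0/1")

    def __len__(self) -> int:
        return len(self.data)


def load_tabular(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Optional loader for externally archived tabular data.

    Reads a CSV/TSV and renames columns to the package's long-format
    dialect via ``column_map`` (mapping source name -> target name, e.g.
    ``{"frog_id": "id", "mass": "mass_g"}``); columns the map does not
    mention are kept as-is.  Returns the renamed DataFrame for downstream
    conversion with :func:`ewlphylo.synthgen.read_long_csv` semantics.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    if column_map:
        missing = set(column_map) - set(df.columns)
        if missing:
            raise ValueError(f"columns not found in {path}: {sorted(missing)}")
        df = df.rename(columns=column_map)
    return df


def correct_excretion(series: MassSeries) -> MassSeries:
    """Add excreted mass back onto all masses at and after each event.

    Mass shed as urine or stool is not evaporative, so the recorded event
    mass ``w`` at time ``t*`` is added to every mass at times >= ``t*``
    (cumulatively across events), leaving first differences away from event
    times unchanged.
    """
    if np.any(series.excreted_g < 0):
        raise ValueError(f"{series.individual_id}: negative excreted mass")
    out = series.copy()
    out.masses = out.masses + np.cumsum(out.excreted_g)
    out.excreted_g = np.zeros_like(out.excreted_g)
    return out


def impute_missing(
    series: MassSeries,
    mode: Literal["regression", "adjacent"] = "regression",
    fallback_to_regression: bool = False,
) -> MassSeries:
    """Fill masked entries either by a per-individual linear fit or by the
    mean of the two adjacent observed masses.

    Regression mode predicts mass at the missing time from a straight-line
    fit of mass on time through all usable points of the same individual.
    Adjacent mode requires an observed immediate neighbour on each side
    (interior single gaps); with ``fallback_to_regression`` endpoint or
    double gaps fall back to the regression rule instead of raising.
    """
    out = series.copy()
    masked = [i for i, s in enumerate(out.status) if s == STATUS_MASKED]
    if not masked:
        return out
    usable = out.usable_mask()

    def _regress(i: int) -> float:
        t = out.times[usable]
        m = out.masses[usable]
        if len(t) < 2:
            raise ValueError(
                f"{out.individual_id}: regression imputation needs >=2 observed points"
            )
        slope, intercept = np.polyfit(t, m, 1)
        return float(intercept + slope * out.times[i])

    for i in masked:
        if mode == "regression":
            value, status = _regress(i), STATUS_IMPUTED_REGRESSION
        elif mode == "adjacent":
            left_ok = i > 0 and usable[i - 1]
            right_ok = i < out.n_obs - 1 and usable[i + 1]
            if left_ok and right_ok:
                value = float(0.5 * (out.masses[i - 1] + out.masses[i + 1]))
                status = STATUS_IMPUTED_ADJACENT
            elif fallback_to_regression:
                value, status = _regress(i), STATUS_IMPUTED_REGRESSION
            else:
                raise ValueError(
                    f"{out.individual_id}: adjacent imputation needs an observed "
                    f"neighbour on each side of index {i}"
                )
        else:
            raise ValueError(f"unknown imputation mode {mode!r}")
        out.masses[i] = value
        out.status[i] = status
    return out


def apply_exclusions(
    series_set: Iterable[MassSeries], max_loss_fraction: float = 0.20
) -> tuple[list[MassSeries], pd.DataFrame]:
    """Remove individuals losing more than ``max_loss_fraction`` of starting
    mass (euthanasia rule) or carrying a manual exclusion flag.

    Returns the retained series and an exclusion report listing each removed
    individual with its reason and observed loss fraction.
    """
    if not (0 < max_loss_fraction < 1):
        raise ValueError("max_loss_fraction must be in (0, 1)")
    retained: list[MassSeries] = []
    rows = []
    for s in series_set:
        loss = s.loss_fraction()
        if s.manual_exclude:
            rows.append(
                {"individual_id": s.individual_id, "reason": "manual", "loss_fraction": loss}
            )
        elif loss > max_loss_fraction:
            rows.append(
                {
                    "individual_id": s.individual_id,
                    "reason": "mass_loss",
                    "loss_fraction": loss,
                }
            )
        else:
            retained.append(s)
    report = pd.DataFrame(rows, columns=["individual_id", "reason", "loss_fraction"])
    return retained, report


def missing_value_report(series_set: Iterable[MassSeries]) -> dict:
    """Count masked entries over all scheduled measurements.

    ``percent`` is ``100 * n_masked / n_total`` over every entry in the
    series set, the bookkeeping quantity quoted alongside the exclusions.
    """
    n_masked = 0
    n_total = 0
    for s in series_set:
        n_total += s.n_obs
        n_masked += int(np.sum(s.status == STATUS_MASKED))
    percent = 100.0 * n_masked / n_total if n_total else 0.0
    return {"n_masked": n_masked, "n_total": n_total, "percent": percent}


def build_model_frame(
    series_set: Sequence[MassSeries],
    individuals: Sequence["object"],
    coding: CodingConfig | None = None,
) -> ModelFrame:
    """Assemble the coded regression table from corrected series.

    Response is ln(mass g); covariates follow ``coding``.  Rows with masked
    or truncated status are dropped; row order is stable (individual order
    as given, then time).
    """
    coding = coding or CodingConfig()
    index = {ind.id: ind for ind in individuals}
    svl_centers = coding.resolve_svl_centers(individuals)
    resolved = dataclasses.replace(coding, svl_centers=svl_centers)
    rows = []
    for s in series_set:
        if s.individual_id not in index:
            raise ValueError(f"no individual record for series {s.individual_id!r}")
        ind = index[s.individual_id]
        usable = s.usable_mask()
        for i in np.flatnonzero(usable):
            mass = s.masses[i]
            if not (np.isfinite(mass) and mass > 0):
                raise ValueError(f"{s.individual_id}: nonpositive mass at index {i}")
            rows.append(
                {
                    "ln_mass": math.log(mass),
                    "time_min": float(s.times[i]),
                    "water": int(ind.treatment.water_present),
                    "temp_c": float(ind.treatment.temperature_c),
                    "temp_centered": float(ind.treatment.temperature_c) - coding.temp_center,
                    "ln_svl_centered": math.log(ind.svl_mm) - svl_centers[ind.species],
                    "species": ind.species,
                    "frog": ind.id,
                    "housing": ind.housing_group,
                    "date": ind.date,
                    "status": s.status[i],
                }
            )
    data = pd.DataFrame(rows)
    meta = {
        "n_series": len(series_set),
        "svl_centers": svl_centers,
        "temp_center": coding.temp_center,
        "baseline_species": coding.baseline_species,
    }
    return ModelFrame(data=data, coding=resolved, metadata=meta)
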