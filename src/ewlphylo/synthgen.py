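"""Synthetic evaporative-water-loss experiments.

Emulates the study design the analysis assumes: three frog species
(Xenopus tropicalis, Phyllobates terribilis, Rhinella marina) crossed with
water presence/absence and 26/36 deg C, ~8 animals per treatment cell,
weighings roughly every 20 min for an hour with timing jitter.  Trajectories
follow the log-linear model with species-specific loss and uptake rates,
four nested random-effect sources (frog, housing tank, date, species --- the
species effects drawn jointly under the phylogenetic correlation), and
Gaussian-kernel-correlated residuals.  A corruption stage adds urination/
defecation mass drops, euthanasia dropout past 20% mass loss, and sporadic
missing weighings, so the preprocessing rules are exercised end to end.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from . import prep
from .hmodel import (
    BASELINE_SPECIES,
    COEFFICIENT_NAMES,
    SPECIES_FULL_TO_SHORT,
    design_matrix,
)
from .phylocov import CorrelationMatrix, KernelParams, temporal_correlation
from .prep import CodingConfig, MassSeries


@dataclass
class Treatment:
    water_present: bool
    temperature_c: float

    def __post_init__(self) -> None:
        if self.temperature_c <= 0:
            raise ValueError("temperature must be positive (deg C)")


@dataclass
class SpeciesProfile:
    """Per-species generator constants: size range, typical mass, and the
    true loss/uptake/temperature slopes on the ln scale."""

    name: str
    svl_range_mm: tuple[float, float]
    baseline_mass_g: float
    loss_rate: float  # ln g/min, slope without water (<= 0)
    uptake_rate: float  # ln g/min, added in water (>= 0)
    temp_slope: float  # ln g/degC

    def __post_init__(self) -> None:
        lo, hi = self.svl_range_mm
        if not (0 < lo < hi):
            raise ValueError(f"{self.name}: invalid SVL range")
        if self.baseline_mass_g <= 0:
            raise ValueError(f"{self.name}: baseline mass must be positive")
        if self.loss_rate > 0:
            raise ValueError(f"{self.name}: loss rate must be <= 0")
        if self.uptake_rate < 0:
            raise ValueError(f"{self.name}: uptake rate must be >= 0")


@dataclass
class Individual:
    id: str
    species: str
    svl_mm: float
    housing_group: str
    date: str
    treatment: Treatment


@dataclass
class TruthTable:
    """Ground-truth parameter values for recovery experiments.

    ``coefficients`` holds the 19 fixed-effect terms; ``variances`` the five
    variance components (zero allowed here so deterministic trajectories can
    be generated, unlike the fitted model where variances are positive);
    ``rho`` the temporal correlation at the 20-min reference lag.
    """

    coefficients: dict[str, float]
    variances: dict[str, float]
    rho: float = 0.7

    def __post_init__(self) -> None:
        missing = set(COEFFICIENT_NAMES) - set(self.coefficients)
        if missing:
            raise ValueError(f"truth table missing coefficients {sorted(missing)}")
        for k, v in self.variances.items():
            if v < 0:
                raise ValueError(f"{k} variance must be nonnegative")
        if not (0.0 < self.rho < 1.0):
            raise ValueError("rho must lie in (0, 1)")

    def beta(self) -> np.ndarray:
        return np.array([self.coefficients[n] for n in COEFFICIENT_NAMES])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "coefficients": self.coefficients,
                    "variances": self.variances,
                    "rho": self.rho,
                },
                fh,
                indent=1,
                sort_keys=True,
            )

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


# Fitted posterior means from the real experiment, used as the standard
# ground truth for parameter-recovery simulations.
TABLE1_COEFFICIENTS: dict[str, float] = {
    "Intercept": 0.0887,
    "Time": -0.0019,
    "Water": 0.0373,
    "Temp": -0.0092,
    "SVL": 0.1383,
    "R.marina": 3.1515,
    "P.terribilis": -1.9741,
    "R.marina-Temp": -0.0057,
    "P.terribilis-Temp": -0.0092,
    "Water-Temp": 0.0028,
    "P.terribilis-Water": 0.0139,
    "R.marina-Water": -0.2219,
    "P.terribilis-Water-Temp": 0.0051,
    "R.marina-Water-Temp": 0.0074,
    "P.terribilis-Time": -0.0002,
    "R.marina-Time": 0.0017,
    "Water-Time": 0.0023,
    "P.terribilis-Water-Time": 0.0001,
    "R.marina-Water-Time": -0.0023,
}

TABLE1_VARIANCES: dict[str, float] = {
    "frog": 0.0787,
    "housing": 0.2555,
    "date": 0.1280,
    "species": 5.1479,
    "error": 0.0174,
}

DEFAULT_PROFILES: list[SpeciesProfile] = [
    SpeciesProfile(
        name="Xenopus_tropicalis",
        svl_range_mm=(28.0, 40.0),
        baseline_mass_g=13.5,
        loss_rate=-0.0019,
        uptake_rate=0.0023,
        temp_slope=-0.0092,
    ),
    SpeciesProfile(
        name="Phyllobates_terribilis",
        svl_range_mm=(41.0, 51.0),
        baseline_mass_g=4.0,
        loss_rate=-0.0021,
        uptake_rate=0.0024,
        temp_slope=-0.0184,
    ),
    SpeciesProfile(
        name="Rhinella_marina",
        svl_range_mm=(85.0, 225.0),
        baseline_mass_g=165.0,
        loss_rate=-0.0002,
        uptake_rate=0.0,
        temp_slope=-0.0149,
    ),
]

_FIG1_SLOPES = {
    # (Time, Water-Time, Temp): see classify_outcome for the rule semantics
    "fig1:O1": (-0.002, 0.003, 0.0),
    "fig1:O2": (-0.002, 0.0, -0.003),
    "fig1:O3": (-0.004, 0.0045, -0.006),
    "fig1:O4": (-0.003, 0.001, 0.0),
    "fig1:O5": (-0.003, 0.002, -0.006),
}

_SCENARIO_VARIANCES = {
    "frog": 1e-3,
    "housing": 1e-4,
    "date": 1e-4,
    "species": 1e-4,
    "error": 1e-4,
}


def truth_parameters(preset: str) -> TruthTable:
    """Named ground-truth configurations.

    ``table1`` uses the real experiment's posterior means as truth; ``null``
    zeroes every slope; ``fig1:O1``..``fig1:O5`` encode the conceptual
    outcome taxonomy (water/temperature slope configurations).
    """
    if preset == "table1":
        return TruthTable(
            coefficients=dict(TABLE1_COEFFICIENTS),
            variances=dict(TABLE1_VARIANCES),
            rho=0.7,
        )
    if preset == "null":
        coef = {n: 0.0 for n in COEFFICIENT_NAMES}
        coef["Intercept"] = TABLE1_COEFFICIENTS["Intercept"]
        return TruthTable(
            coefficients=coef, variances=dict(TABLE1_VARIANCES), rho=0.7
        )
    if preset in _FIG1_SLOPES:
        time, water_time, temp = _FIG1_SLOPES[preset]
        coef = {n: 0.0 for n in COEFFICIENT_NAMES}
        coef["Intercept"] = 1.5
        coef["Time"] = time
        coef["Water-Time"] = water_time
        coef["Temp"] = temp
        return TruthTable(
            coefficients=coef, variances=dict(_SCENARIO_VARIANCES), rho=0.7
        )
    raise ValueError(f"unknown truth preset {preset!r}")


def truth_from_profiles(
    profiles: Sequence[SpeciesProfile],
    intercept: float = TABLE1_COEFFICIENTS["Intercept"],
    svl_coef: float = TABLE1_COEFFICIENTS["SVL"],
    variances: dict[str, float] | None = None,
    rho: float = 0.7,
) -> TruthTable:
    """Translate per-species loss/uptake/temperature rates into the
    19-term coefficient vector (baseline X. tropicalis)."""
    by_name = {p.name: p for p in profiles}
    if BASELINE_SPECIES not in by_name:
        raise ValueError(f"profiles must include the baseline {BASELINE_SPECIES}")
    base = by_name[BASELINE_SPECIES]
    coef = {n: 0.0 for n in COEFFICIENT_NAMES}
    coef["Intercept"] = intercept
    coef["SVL"] = svl_coef
    coef["Time"] = base.loss_rate
    coef["Water-Time"] = base.uptake_rate
    coef["Temp"] = base.temp_slope
    for full, short in (("Rhinella_marina", "R.marina"), ("Phyllobates_terribilis", "P.terribilis")):
        if full in by_name:
            p = by_name[full]
            coef[f"{short}-Time"] = p.loss_rate - base.loss_rate
            coef[f"{short}-Water-Time"] = p.uptake_rate - base.uptake_rate
            coef[f"{short}-Temp"] = p.temp_slope - base.temp_slope
    return TruthTable(
        coefficients=coef,
        variances=dict(variances) if variances else dict(TABLE1_VARIANCES),
        rho=rho,
    )


def scenario_slopes(truth: TruthTable, session_min: float = 60.0) -> dict:
    """Baseline-species net ln-mass slopes per (water, temperature) cell,
    folding the temperature level effect into an average per-minute slope
    over the session (10 deg C spread over ``session_min``)."""
    c = truth.coefficients
    out = {}
    for water in (0, 1):
        for temp in (26.0, 36.0):
            slope = c["Time"] + water * c["Water-Time"]
            slope += (temp - 26.0) / session_min * (c["Temp"] + water * c["Water-Temp"])
            out[(water, temp)] = slope
    return out


# ---------------------------------------------------------------------------
# design and simulation

DEFAULT_TREATMENTS = (
    Treatment(False, 26.0),
    Treatment(False, 36.0),
    Treatment(True, 26.0),
    Treatment(True, 36.0),
)


def make_design(
    n_per_treatment: int,
    species_profiles: Sequence[SpeciesProfile],
    seed: int,
    temperature_levels: tuple[float, float] = (26.0, 36.0),
    housing_per_species: int = 2,
    frogs_per_date: int = 4,
) -> list[Individual]:
    """Balanced 2x2 design: ``n_per_treatment`` animals per water x
    temperature cell per species, SVL uniform within the species range,
    dates cycling every ``frogs_per_date`` animals (8 dates at the default
    size) and housing tanks cycling within species."""
    if n_per_treatment < 1:
        raise ValueError("n_per_treatment must be >= 1")
    profiles = list(species_profiles)
    if not profiles:
        raise ValueError("at least one species profile is required")
    t_lo, t_hi = temperature_levels
    treatments = [
        Treatment(False, t_lo),
        Treatment(False, t_hi),
        Treatment(True, t_lo),
        Treatment(True, t_hi),
    ]
    rng = np.random.default_rng(seed)
    out: list[Individual] = []
    for profile in profiles:
        short = SPECIES_FULL_TO_SHORT.get(profile.name, profile.name)
        n_total = n_per_treatment * 4
        svls = rng.uniform(*profile.svl_range_mm, size=n_total)
        for i in range(n_total):
            out.append(
                Individual(
                    id=f"{short}_{i + 1:03d}",
                    species=profile.name,
                    svl_mm=float(svls[i]),
                    housing_group=f"{profile.name}_tank{i % housing_per_species + 1}",
                    date=f"d{i // frogs_per_date + 1:02d}",
                    treatment=treatments[i % 4],
                )
            )
    return out


def _covariate_frame(
    individuals: Sequence[Individual],
    times_by_id: dict[str, np.ndarray],
    coding: CodingConfig,
) -> prep.ModelFrame:
    """A model frame with the design covariates and placeholder response,
    used to evaluate the true linear predictor through the same design
    matrix the fitted model uses."""
    svl_centers = coding.resolve_svl_centers(individuals)
    rows = []
    for ind in individuals:
        for t in times_by_id[ind.id]:
            rows.append(
                {
                    "ln_mass": 0.0,
                    "time_min": float(t),
                    "water": int(ind.treatment.water_present),
                    "temp_c": ind.treatment.temperature_c,
                    "temp_centered": ind.treatment.temperature_c - coding.temp_center,
                    "ln_svl_centered": math.log(ind.svl_mm) - svl_centers[ind.species],
                    "species": ind.species,
                    "frog": ind.id,
                    "housing": ind.housing_group,
                    "date": ind.date,
                    "status": prep.STATUS_OBSERVED,
                }
            )
    import dataclasses as _dc

    resolved = _dc.replace(coding, svl_centers=svl_centers)
    return prep.ModelFrame(data=pd.DataFrame(rows), coding=resolved)


def simulate_series(
    individual: Individual,
    truth: TruthTable,
    times: Sequence[float],
    seed: int,
    coding: CodingConfig | None = None,
    group_effects: dict | None = None,
    reference_lag: float = 20.0,
) -> MassSeries:
    """Simulate one trajectory: ln mass = design row x true coefficients
    + frog/housing/date/species effects + Gaussian-kernel-correlated noise.

    When ``group_effects`` is not given, each group effect is drawn fresh
    from its variance (species effect independent; use
    :func:`simulate_experiment` for phylogenetically joint species draws).
    With all variances zero the trajectory is the exact linear predictor.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0 or times[0] != 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must start at 0 and increase strictly")
    if coding is None:
        coding = CodingConfig(
            svl_centers={individual.species: math.log(individual.svl_mm)}
        )
    frame = _covariate_frame([individual], {individual.id: times}, coding)
    X, _ = design_matrix(frame)
    lnm = X @ truth.beta()

    rng = np.random.default_rng(seed)
    v = truth.variances
    if group_effects is None:
        group_effects = {}
        for kind, label, var in (
            ("frog", individual.id, v["frog"]),
            ("housing", individual.housing_group, v["housing"]),
            ("date", individual.date, v["date"]),
            ("species", individual.species, v["species"]),
        ):
            group_effects[(kind, label)] = (
                rng.normal(0.0, math.sqrt(var)) if var > 0 else 0.0
            )
    lnm = lnm + (
        group_effects.get(("frog", individual.id), 0.0)
        + group_effects.get(("housing", individual.housing_group), 0.0)
        + group_effects.get(("date", individual.date), 0.0)
        + group_effects.get(("species", individual.species), 0.0)
    )
    if v["error"] > 0:
        params = KernelParams(rho=truth.rho, reference_lag=reference_lag)
        K = temporal_correlation(np.abs(times[:, None] - times[None, :]), params)
        L = np.linalg.cholesky(v["error"] * K + 1e-12 * np.eye(len(times)))
        lnm = lnm + L @ rng.standard_normal(len(times))
    return MassSeries(individual_id=individual.id, times=times, masses=np.exp(lnm))


@dataclass
class SimulatedExperiment:
    individuals: list[Individual]
    series: list[MassSeries]
    truth: TruthTable
    coding: CodingConfig
    group_effects: dict = field(default_factory=dict)


def simulate_experiment(
    individuals: Sequence[Individual],
    truth: TruthTable,
    seed: int,
    phylo: CorrelationMatrix | None = None,
    coding: CodingConfig | None = None,
    base_times: Sequence[float] = (0.0, 20.0, 40.0, 60.0),
    jitter_min: float = 3.0,
    reference_lag: float = 20.0,
) -> SimulatedExperiment:
    """Simulate a full experiment with shared group effects.

    Species effects are drawn jointly as MVN(0, sigma2_species * Phi) when a
    phylogenetic correlation is supplied (matching the fitted model's
    assumption), independently otherwise.  Weighing times are the 20-min
    grid plus uniform +-``jitter_min`` jitter (t=0 exact).
    """
    individuals = list(individuals)
    rng = np.random.default_rng(seed)
    coding = coding or CodingConfig()
    v = truth.variances

    effects: dict = {}
    species = sorted({ind.species for ind in individuals})
    if v["species"] > 0:
        if phylo is not None:
            missing = set(species) - set(phylo.species)
            if missing:
                raise ValueError(f"species missing from Phi: {sorted(missing)}")
            order = [phylo.species.index(s) for s in species]
            cov = v["species"] * phylo.values[np.ix_(order, order)]
            draw = rng.multivariate_normal(np.zeros(len(species)), cov, method="cholesky")
        else:
            draw = rng.normal(0.0, math.sqrt(v["species"]), size=len(species))
        for s, u in zip(species, draw):
            effects[("species", s)] = float(u)
    else:
        for s in species:
            effects[("species", s)] = 0.0
    for kind, labels, var in (
        ("housing", sorted({i.housing_group for i in individuals}), v["housing"]),
        ("date", sorted({i.date for i in individuals}), v["date"]),
        ("frog", [i.id for i in individuals], v["frog"]),
    ):
        for lb in labels:
            effects[(kind, lb)] = (
                float(rng.normal(0.0, math.sqrt(var))) if var > 0 else 0.0
            )

    base = np.asarray(base_times, dtype=float)
    svl_centers = coding.resolve_svl_centers(individuals)
    import dataclasses as _dc

    coding = _dc.replace(coding, svl_centers=svl_centers)
    series = []
    child_seeds = np.random.SeedSequence(seed).spawn(len(individuals))
    for ind, child in zip(individuals, child_seeds):
        crng = np.random.default_rng(child)
        times = base.copy()
        if jitter_min > 0 and len(times) > 1:
            times[1:] += crng.uniform(-jitter_min, jitter_min, size=len(times) - 1)
        sub_seed = int(crng.integers(0, 2**31 - 1))
        series.append(
            simulate_series(
                ind,
                truth,
                times,
                seed=sub_seed,
                coding=coding,
                group_effects=effects,
                reference_lag=reference_lag,
            )
        )
    return SimulatedExperiment(
        individuals=individuals,
        series=series,
        truth=truth,
        coding=coding,
        group_effects=effects,
    )


# ---------------------------------------------------------------------------
# corruption


def corrupt_series(
    series: MassSeries,
    excretion_prob: float = 0.08,
    excretion_frac_range: tuple[float, float] = (0.005, 0.03),
    missing_prob: float = 0.05,
    dropout_threshold: float = 0.20,
    seed: int = 0,
    excretion_events: Sequence[tuple[int, float]] | None = None,
) -> MassSeries:
    """Overlay realistic measurement artefacts on a clean trajectory.

    With probability ``excretion_prob`` one urination/defecation event is
    placed at a random non-initial weighing: a fraction of the current mass
    (uniform in ``excretion_frac_range``, the observed 0.5--3% range) is
    shed, lowering that and all later masses, with the shed mass recorded.
    Observations after cumulative loss exceeds ``dropout_threshold`` are
    truncated (euthanasia rule) and non-endpoint weighings are masked with
    probability ``missing_prob``.  ``excretion_events`` pins events
    explicitly as (index, fraction) pairs for deterministic use.
    """
    if not (0 <= excretion_prob <= 1 and 0 <= missing_prob <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    lo, hi = excretion_frac_range
    if not (0 < lo < hi < 1):
        raise ValueError("excretion_frac_range must satisfy 0 < lo < hi < 1")
    if dropout_threshold <= 0:
        raise ValueError("dropout_threshold must be positive")
    rng = np.random.default_rng(seed)
    out = series.copy()
    n = out.n_obs

    events: list[tuple[int, float]] = list(excretion_events or [])
    if excretion_events is None and n > 1 and rng.random() < excretion_prob:
        events.append((int(rng.integers(1, n)), float(rng.uniform(lo, hi))))
    for idx, frac in events:
        if not (0 < idx < n):
            raise ValueError("excretion event index out of range")
        shed = frac * out.masses[idx]
        out.masses[idx:] -= shed
        out.excreted_g[idx] += shed

    m0 = out.masses[0]
    loss = (m0 - out.masses) / m0
    exceeded = np.flatnonzero(loss > dropout_threshold)
    if exceeded.size:
        cut = int(exceeded[0])
        out.status[cut:] = prep.STATUS_TRUNCATED
        out.masses[cut:] = np.nan
        out.dropout = True
        n_active = cut
    else:
        n_active = n

    if missing_prob > 0:
        for i in range(1, n_active - 1):
            if rng.random() < missing_prob:
                out.status[i] = prep.STATUS_MASKED
                out.masses[i] = np.nan
    return out


def corrupt_experiment(
    series_list: Sequence[MassSeries],
    seed: int,
    n_missing_exact: int | None = None,
    **kwargs,
) -> list[MassSeries]:
    """Apply :func:`corrupt_series` across an experiment.

    ``n_missing_exact`` masks exactly that many interior weighings over the
    whole set (instead of per-observation coin flips), which pins the
    missing-value bookkeeping for tests and worked examples.
    """
    seeds = np.random.SeedSequence(seed).spawn(len(series_list))
    missing_prob = kwargs.pop("missing_prob", 0.05)
    per_series_missing = 0.0 if n_missing_exact is not None else missing_prob
    out = [
        corrupt_series(
            s,
            missing_prob=per_series_missing,
            seed=int(np.random.default_rng(cs).integers(0, 2**31 - 1)),
            **kwargs,
        )
        for s, cs in zip(series_list, seeds)
    ]
    if n_missing_exact is not None:
        candidates = [
            (si, i)
            for si, s in enumerate(out)
            for i in range(1, s.n_obs - 1)
            if s.status[i] == prep.STATUS_OBSERVED
        ]
        if n_missing_exact > len(candidates):
            raise ValueError("not enough interior observations to mask")
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x3A5C]))
        chosen = rng.choice(len(candidates), size=n_missing_exact, replace=False)
        for c in chosen:
            si, i = candidates[int(c)]
            out[si].status[i] = prep.STATUS_MASKED
            out[si].masses[i] = np.nan
    return out


# ---------------------------------------------------------------------------
# trees and I/O

_TREE_TAXA = ["Xenopus_tropicalis", "Rhinella_marina", "Phyllobates_terribilis"]


def sample_trees(
    n_trees: int = 100,
    seed: int = 0,
    root_age: float = 205.0,
    split_age: float = 75.0,
    age_sd_frac: float = 0.08,
) -> dendropy.TreeList:
    """A synthetic pseudo-posterior sample of ultrametric trees for the
    three study species: ((R. marina, P. terribilis), X. tropicalis), with
    node ages jittered log-normally around the given means (My)."""
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace(_TREE_TAXA)
    trees = dendropy.TreeList(taxon_namespace=taxa)
    sd = np.sqrt(np.log1p(age_sd_frac**2))
    for _ in range(n_trees):
        root = root_age * float(rng.lognormal(-0.5 * sd**2, sd))
        inner = split_age * float(rng.lognormal(-0.5 * sd**2, sd))
        inner = min(inner, 0.95 * root)
        nwk = (
            f"((Rhinella_marina:{inner:.6f},Phyllobates_terribilis:{inner:.6f})"
            f":{root - inner:.6f},Xenopus_tropicalis:{root:.6f});"
        )
        trees.append(
            dendropy.Tree.get(
                data=nwk,
                schema="newick",
                taxon_namespace=taxa,
                preserve_underscores=True,
            )
        )
    return trees


CSV_COLUMNS = [
    "id",
    "species",
    "housing",
    "date",
    "water",
    "temp_c",
    "svl_mm",
    "time_min",
    "mass_g",
    "excreted_g",
    "observed",
    "dropout",
    "status",
]


def write_long_csv(
    series_list: Sequence[MassSeries],
    individuals: Sequence[Individual],
    path,
) -> None:
    """Write the long-format CSV dialect (one row per weighing; ``status``
    is the provenance flag, ``observed`` its 0/1 summary)."""
    idx = {ind.id: ind for ind in individuals}
    rows = []
    for s in series_list:
        ind = idx[s.individual_id]
        for i in range(s.n_obs):
            rows.append(
                {
                    "id": ind.id,
                    "species": ind.species,
                    "housing": ind.housing_group,
                    "date": ind.date,
                    "water": int(ind.treatment.water_present),
                    "temp_c": ind.treatment.temperature_c,
                    "svl_mm": ind.svl_mm,
                    "time_min": s.times[i],
                    "mass_g": s.masses[i],
                    "excreted_g": s.excreted_g[i],
                    "observed": int(s.status[i] in prep._USABLE),
                    "dropout": int(s.dropout),
                    "status": s.status[i],
                }
            )
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(
        path, index=False, float_format="%.10g"
    )


def read_long_csv(path) -> tuple[list[MassSeries], list[Individual]]:
    """Read the long-format CSV back into series and individual records."""
    df = pd.read_csv(path, comment="#")
    missing = set(CSV_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise ValueError(f"long-format CSV missing columns {sorted(missing)}")
    series, individuals = [], []
    for frog_id, g in df.groupby("id", sort=False):
        g = g.sort_values("time_min")
        first = g.iloc[0]
        individuals.append(
            Individual(
                id=str(frog_id),
                species=first["species"],
                svl_mm=float(first["svl_mm"]),
                housing_group=str(first["housing"]),
                date=str(first["date"]),
                treatment=Treatment(bool(first["water"]), float(first["temp_c"])),
            )
        )
        status = (
            g["status"].to_numpy(dtype=object)
            if "status" in g
            else np.where(g["observed"] == 1, prep.STATUS_OBSERVED, prep.STATUS_MASKED)
        )
        series.append(
            MassSeries(
                individual_id=str(frog_id),
                times=g["time_min"].to_numpy(float),
                masses=g["mass_g"].to_numpy(float),
                excreted_g=g["excreted_g"].to_numpy(float),
                status=status,
                dropout=bool(g["dropout"].iloc[0]),
            )
        )
    return series, individuals
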