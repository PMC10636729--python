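"""Synthetic observation tables with known ground-truth variance components.

The generator emulates the data structure of a marked wild kangaroo
population study: adult females measured repeatedly for flight initiation
distance (FID), each with 1-3 offspring measured for pouch-young (PY)
movement during handling, repeated subadult FID trials, and survival to
weaning.  Mother-level effect vectors are drawn from a configurable
multivariate normal across the four traits, so every downstream estimate of
a variance component can be checked against its generating value.

Scales: FID traits and their components are in metres (squared metres for
variances); PY movement components are on the latent stage-propensity logit
scale (the observed score is the fraction of handling stages with movement);
survival components are on the latent liability (logit) scale with residual
variance 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import poisson

from .io import COLUMNS, COMPANION_CLASSES, TRAITS

__all__ = [
    "CountDistribution",
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_dataset",
    "simulate_py_stage_scores",
    "assign_adoptions",
    "default_fixed_effects",
    "zero_fixed_effects",
]


class ConfigurationError(ValueError):
    pass


@dataclass
class CountDistribution:
    """Truncated Poisson on {min..max} calibrated to a target mean."""

    min: int
    max: int
    mean: float

    def probabilities(self) -> np.ndarray:
        ks = np.arange(self.min, self.max + 1)
        if self.min == self.max:
            return np.ones(1)
        if not self.min < self.mean < self.max:
            raise ConfigurationError(
                f"mean {self.mean} outside open interval ({self.min}, {self.max})"
            )

        def trunc_mean(lam):
            p = poisson.pmf(ks, lam)
            return (ks * p).sum() / p.sum() - self.mean

        lam = brentq(trunc_mean, 1e-6, 100.0)
        p = poisson.pmf(ks, lam)
        return p / p.sum()

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        ks = np.arange(self.min, self.max + 1)
        return rng.choice(ks, size=n, p=self.probabilities())


def default_fixed_effects() -> dict:
    """Generating fixed-effect coefficients, chosen to mirror the scale of
    effects a field study of this design reports (year and sex contrasts of
    a metre or two for FID, mild habituation with test number, a shallow
    east-west gradient)."""
    return {
        "py_movement": {  # latent stage-propensity (logit) scale
            "intercept": 0.0,
            "age_months": 0.15,  # centred at 8 months
            "sex_female": 0.1,
            "year": {2017: 0.0, 2018: -0.3, 2019: 0.2},
        },
        "subadult_fid": {  # metres
            "intercept": 5.6,
            "sex_female": 0.5,
            "age_months": 0.02,  # centred at 24 months
            "year": {2017: 0.0, 2018: 1.6, 2019: 2.5},
            "gps_east_m": 0.0003,
            "group_size": 0.2,
            "test_number": -0.15,
            "days_since_prev_test": 0.0,
            "companion_class": {"alone": 0.0, "mother_present": 0.3},
        },
        "subadult_survival": {  # latent liability (logit) scale
            "intercept": 1.0,
            "sex_female": -0.4,
            "year": {2016: 0.0, 2017: -0.4, 2018: 1.0, 2019: 0.3},
        },
        "adult_female_fid": {  # metres
            "intercept": 6.6,
            "gps_east_m": 0.0003,
            "group_size": 0.2,
            "test_number": -0.1,
            "days_since_prev_test": 0.0,
            "year": {2017: 0.0, 2018: 0.1, 2019: 1.0},
            "observer_B": 0.5,
            "companion_class": {
                "alone": 0.0,
                "small_py": -0.3,
                "medium_py": -0.2,
                "large_py": 0.2,
                "yearling": 0.1,
            },
        },
    }


def zero_fixed_effects(keep_intercepts: bool = True) -> dict:
    """The default coefficient structure with every contrast zeroed (and
    optionally the intercepts kept), for clean parameter-recovery studies."""
    fx = default_fixed_effects()

    def wipe(d):
        for k, v in d.items():
            if isinstance(v, dict):
                wipe(v)
            elif k != "intercept" or not keep_intercepts:
                d[k] = 0.0

    wipe(fx)
    return fx


def _default_mother_cov() -> np.ndarray:
    g = np.zeros((4, 4))
    np.fill_diagonal(g, [1.2, 4.97, 1.54, 4.78])
    g[1, 3] = g[3, 1] = 4.14  # subadult FID x adult female FID
    return g


@dataclass
class SimulationConfig:
    """Study-structure and generating-parameter configuration.

    Defaults emulate the published study design: 156 adult females measured
    for FID (1-14 trials, mean 5.6), 111 of them with 1-3 offspring in the
    focal cohorts (mean 1.6), survival scored for every offspring (~67%
    survive), PY movement scored for ~70% and subadult FID (1-10 trials,
    mean 4.6) for ~59% of them.
    """

    n_mothers: int = 156
    n_mothers_with_offspring: int = 111
    offspring_per_mother: CountDistribution = field(
        default_factory=lambda: CountDistribution(1, 3, 1.6)
    )
    fid_trials_per_subadult: CountDistribution = field(
        default_factory=lambda: CountDistribution(1, 10, 4.6)
    )
    fid_trials_per_mother: CountDistribution = field(
        default_factory=lambda: CountDistribution(1, 14, 5.6)
    )
    n_py_stages: int = 8
    # variance components; trait order follows io.TRAITS
    mother_cov: np.ndarray = field(default_factory=_default_mother_cov)
    offspring_var_subadult_fid: float = 3.61
    resid_var_subadult_fid: float = 8.11
    resid_var_adult_fid: float = 8.50
    py_resid_sd_latent: float = 0.7
    fixed_effects: dict = field(default_factory=default_fixed_effects)
    p_py_measured: float = 0.70
    p_subadult_fid_measured: float = 0.59
    p_observer_b: float = 0.09
    companion_freq_adult: dict = field(
        default_factory=lambda: {
            "alone": 0.443,
            "small_py": 0.209,
            "medium_py": 0.066,
            "large_py": 0.187,
            "yearling": 0.094,
        }
    )
    p_subadult_with_mother: float = 0.314
    years: tuple = (2017, 2018, 2019)
    cohorts: tuple = (2016, 2017, 2018, 2019)
    gps_east_range: tuple = (0.0, 4000.0)
    group_size_range: tuple = (1, 6)
    sentinel_days: float = 500.0
    truncate_fid: bool = False
    adoption_pairs: int = 0
    seed: int = 0

    def validate(self) -> None:
        g = np.asarray(self.mother_cov, dtype=float)
        if g.shape != (4, 4) or not np.allclose(g, g.T):
            raise ConfigurationError("mother_cov must be a symmetric 4x4 matrix")
        if np.linalg.eigvalsh(g).min() < -1e-9:
            raise ConfigurationError(
                "mother_cov is not positive semidefinite"
            )
        if self.n_mothers <= 0:
            raise ConfigurationError("empty design: n_mothers must be positive")
        if not 0 < self.n_mothers_with_offspring <= self.n_mothers:
            raise ConfigurationError(
                "n_mothers_with_offspring must be in (0, n_mothers]"
            )
        for v in (
            self.offspring_var_subadult_fid,
            self.resid_var_subadult_fid,
            self.resid_var_adult_fid,
            self.py_resid_sd_latent,
        ):
            if v < 0:
                raise ConfigurationError("variances must be non-negative")
        for p in (self.p_py_measured, self.p_subadult_fid_measured,
                  self.p_observer_b, self.p_subadult_with_mother):
            if not 0 <= p <= 1:
                raise ConfigurationError("probabilities must lie in [0, 1]")
        if self.n_py_stages < 1:
            raise ConfigurationError("n_py_stages must be >= 1")


@dataclass
class SyntheticTruth:
    """Realised generating values for a simulated table."""

    seed: int
    variance_components: dict
    fixed_effects: dict
    mother_effects: dict  # mother_id -> 4-vector (trait order io.TRAITS)
    offspring_effects: dict  # individual_id -> subadult FID deviation

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=float))


def simulate_py_stage_scores(
    n_individuals: int,
    mother_effects,
    resid_sd: float,
    n_stages: int = 8,
    rng_state=None,
    intercept: float = 0.0,
):
    """PY movement scores from per-stage Bernoulli movement indicators.

    Each individual has one latent logit propensity (intercept + its
    mother's latent effect + an individual residual); movement at each of
    ``n_stages`` handling stages is an independent Bernoulli draw with that
    propensity, and the score is the fraction of stages with movement.
    """
    if n_stages < 1:
        raise ValueError("n_stages must be >= 1")
    rng = (
        rng_state
        if isinstance(rng_state, np.random.Generator)
        else np.random.default_rng(rng_state)
    )
    mother_effects = np.broadcast_to(
        np.asarray(mother_effects, dtype=float), (n_individuals,)
    )
    propensity = intercept + mother_effects + rng.normal(0, resid_sd, n_individuals)
    p = expit(propensity)
    moves = rng.random((n_individuals, n_stages)) < p[:, None]
    return moves.sum(axis=1) / n_stages


def simulate_dataset(config: SimulationConfig):
    """Generate an observation table and its ground truth.

    Deterministic under a fixed seed: the same config yields an identical
    table.  Returns ``(table, truth)``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fx = config.fixed_effects
    g = np.asarray(config.mother_cov, dtype=float)

    mother_ids = [f"F{i:03d}" for i in range(config.n_mothers)]
    # svd factorisation tolerates semidefinite matrices (zero components)
    u = rng.multivariate_normal(np.zeros(4), g, size=config.n_mothers)
    mother_fx = dict(zip(TRAITS, range(4)))

    rows: list[dict] = []
    obs_counter = [0]

    def add_row(**kw):
        obs_counter[0] += 1
        base = {c: np.nan for c in COLUMNS}
        base["observation_id"] = f"obs{obs_counter[0]:05d}"
        base.update(kw)
        rows.append(base)

    # ---- offspring ---------------------------------------------------
    counts = config.offspring_per_mother.sample(
        config.n_mothers_with_offspring, rng
    )
    offspring = []
    for mi in range(config.n_mothers_with_offspring):
        for _ in range(int(counts[mi])):
            offspring.append(mi)
    offspring_idx = np.array(offspring)
    n_off = offspring_idx.size
    off_ids = [f"J{i:03d}" for i in range(n_off)]
    sexes = rng.choice(["male", "female"], size=n_off)
    cohorts = rng.choice(config.cohorts, size=n_off)
    off_fid_dev = rng.normal(
        0, np.sqrt(config.offspring_var_subadult_fid), size=n_off
    )

    # PY movement: one handling score per measured offspring
    py_measured = rng.random(n_off) < config.p_py_measured
    age_py = np.clip(rng.normal(8.0, 0.8, size=n_off), 6.4, 10.8)
    pyfx = fx["py_movement"]
    py_year = np.minimum(np.maximum(cohorts, min(config.years)), max(config.years))
    py_offset = (
        pyfx["intercept"]
        + pyfx["age_months"] * (age_py - 8.0)
        + pyfx["sex_female"] * (sexes == "female")
        + np.array([pyfx["year"].get(int(y), 0.0) for y in py_year])
        + u[offspring_idx, mother_fx["py_movement"]]
    )
    scores = simulate_py_stage_scores(
        n_off, py_offset, config.py_resid_sd_latent, config.n_py_stages, rng
    )
    for i in range(n_off):
        if not py_measured[i]:
            continue
        add_row(
            individual_id=off_ids[i],
            biological_mother_id=mother_ids[offspring_idx[i]],
            rearing_mother_id=mother_ids[offspring_idx[i]],
            trait="py_movement",
            value=scores[i],
            age_months=age_py[i],
            sex=sexes[i],
            year=int(py_year[i]),
            cohort=int(cohorts[i]),
        )

    # subadult FID: repeated trials
    fid_measured = rng.random(n_off) < config.p_subadult_fid_measured
    sfx = fx["subadult_fid"]
    for i in range(n_off):
        if not fid_measured[i]:
            continue
        n_trials = int(config.fid_trials_per_subadult.sample(1, rng)[0])
        base_age = rng.uniform(13, 30)
        for t in range(n_trials):
            age = min(base_age + t * rng.uniform(0.2, 2.0), 35.0)
            year = int(rng.choice(config.years))
            gps = rng.uniform(*config.gps_east_range)
            gsize = int(rng.integers(config.group_size_range[0],
                                     config.group_size_range[1] + 1))
            comp = (
                "mother_present"
                if rng.random() < config.p_subadult_with_mother
                else "alone"
            )
            days = config.sentinel_days if t == 0 else float(rng.integers(5, 200))
            mean = (
                sfx["intercept"]
                + sfx["sex_female"] * (sexes[i] == "female")
                + sfx["age_months"] * (age - 24.0)
                + sfx["year"].get(year, 0.0)
                + sfx["gps_east_m"] * (gps - np.mean(config.gps_east_range))
                + sfx["group_size"] * (gsize - 3.5)
                + sfx["test_number"] * (t + 1)
                + sfx["days_since_prev_test"] * days
                + sfx["companion_class"].get(comp, 0.0)
                + u[offspring_idx[i], mother_fx["subadult_fid"]]
                + off_fid_dev[i]
            )
            value = mean + rng.normal(0, np.sqrt(config.resid_var_subadult_fid))
            if config.truncate_fid:
                value = max(value, 0.0)
            add_row(
                individual_id=off_ids[i],
                biological_mother_id=mother_ids[offspring_idx[i]],
                rearing_mother_id=mother_ids[offspring_idx[i]],
                trait="subadult_fid",
                value=value,
                age_months=age,
                sex=sexes[i],
                year=year,
                cohort=int(cohorts[i]),
                gps_east_m=gps,
                group_size=gsize,
                companion_class=comp,
                test_number=t + 1,
                days_since_prev_test=days,
            )

    # survival: binary outcome for every offspring
    vfx = fx["subadult_survival"]
    latent = (
        vfx["intercept"]
        + vfx["sex_female"] * (sexes == "female")
        + np.array([vfx["year"].get(int(c), 0.0) for c in cohorts])
        + u[offspring_idx, mother_fx["subadult_survival"]]
        + rng.normal(0, 1.0, size=n_off)
    )
    p_surv = expit(latent)
    survived = (rng.random(n_off) < p_surv).astype(float)
    for i in range(n_off):
        add_row(
            individual_id=off_ids[i],
            biological_mother_id=mother_ids[offspring_idx[i]],
            rearing_mother_id=mother_ids[offspring_idx[i]],
            trait="subadult_survival",
            value=survived[i],
            sex=sexes[i],
            year=int(cohorts[i]),
            cohort=int(cohorts[i]),
        )

    # adult female FID: repeated trials for every mother
    afx = fx["adult_female_fid"]
    comp_levels = list(config.companion_freq_adult)
    comp_p = np.array([config.companion_freq_adult[c] for c in comp_levels])
    comp_p = comp_p / comp_p.sum()
    n_trials_mother = config.fid_trials_per_mother.sample(config.n_mothers, rng)
    for mi in range(config.n_mothers):
        for t in range(int(n_trials_mother[mi])):
            year = int(rng.choice(config.years))
            gps = rng.uniform(*config.gps_east_range)
            gsize = int(rng.integers(config.group_size_range[0],
                                     config.group_size_range[1] + 1))
            comp = str(rng.choice(comp_levels, p=comp_p))
            days = config.sentinel_days if t == 0 else float(rng.integers(5, 200))
            observer = "B" if rng.random() < config.p_observer_b else "A"
            mean = (
                afx["intercept"]
                + afx["gps_east_m"] * (gps - np.mean(config.gps_east_range))
                + afx["group_size"] * (gsize - 3.5)
                + afx["test_number"] * (t + 1)
                + afx["days_since_prev_test"] * days
                + afx["year"].get(year, 0.0)
                + afx["observer_B"] * (observer == "B")
                + afx["companion_class"].get(comp, 0.0)
                + u[mi, mother_fx["adult_female_fid"]]
            )
            value = mean + rng.normal(0, np.sqrt(config.resid_var_adult_fid))
            if config.truncate_fid:
                value = max(value, 0.0)
            add_row(
                individual_id=mother_ids[mi],
                trait="adult_female_fid",
                value=value,
                sex="female",
                year=year,
                gps_east_m=gps,
                group_size=gsize,
                companion_class=comp,
                test_number=t + 1,
                days_since_prev_test=days,
                observer_id=observer,
            )

    table = pd.DataFrame(rows, columns=COLUMNS)
    truth = SyntheticTruth(
        seed=config.seed,
        variance_components={
            "mother_cov": np.asarray(config.mother_cov, dtype=float).tolist(),
            "trait_order": list(TRAITS),
            "offspring_var_subadult_fid": config.offspring_var_subadult_fid,
            "resid_var_subadult_fid": config.resid_var_subadult_fid,
            "resid_var_adult_fid": config.resid_var_adult_fid,
            "py_resid_sd_latent": config.py_resid_sd_latent,
            "resid_var_survival_latent": 1.0,
        },
        fixed_effects=fx,
        mother_effects={mid: u[i].tolist() for i, mid in enumerate(mother_ids)},
        offspring_effects={oid: float(off_fid_dev[i])
                           for i, oid in enumerate(off_ids)},
    )
    if config.adoption_pairs:
        table = assign_adoptions(table, config.adoption_pairs, rng)
    return table, truth


def assign_adoptions(
    table: pd.DataFrame,
    n_pairs: int,
    rng_state=None,
    n_singletons: int = 0,
) -> pd.DataFrame:
    """Reciprocally swap rearing mothers between random offspring pairs.

    For each of ``n_pairs`` pairs of offspring with distinct biological
    mothers, the rearing_mother_id values are exchanged;
    biological_mother_id is untouched.  ``n_singletons`` further offspring
    are optionally moved to a random foster mother (emulating mothers whose
    own young disappeared), which does not conserve the rearing multiset.
    """
    rng = (
        rng_state
        if isinstance(rng_state, np.random.Generator)
        else np.random.default_rng(rng_state)
    )
    if n_pairs == 0 and n_singletons == 0:
        return table
    out = table.copy()
    kids = out.dropna(subset=["biological_mother_id"])[
        ["individual_id", "biological_mother_id"]
    ].drop_duplicates("individual_id")
    need = 2 * n_pairs + n_singletons
    if len(kids) < need or kids["biological_mother_id"].nunique() < 2:
        raise ValueError(
            f"need at least {need} offspring with >= 2 distinct mothers "
            f"for {n_pairs} adoption pairs and {n_singletons} singletons"
        )
    order = kids.sample(frac=1.0, random_state=rng).reset_index(drop=True)
    used: list[int] = []
    pairs = []
    for _ in range(n_pairs):
        i = next(k for k in range(len(order)) if k not in used)
        j = next(
            k
            for k in range(len(order))
            if k not in used
            and k != i
            and order["biological_mother_id"][k] != order["biological_mother_id"][i]
        )
        used += [i, j]
        pairs.append((order["individual_id"][i], order["individual_id"][j]))
    for a, b in pairs:
        ma = out.loc[out["individual_id"] == a, "rearing_mother_id"].iloc[0]
        mb = out.loc[out["individual_id"] == b, "rearing_mother_id"].iloc[0]
        out.loc[out["individual_id"] == a, "rearing_mother_id"] = mb
        out.loc[out["individual_id"] == b, "rearing_mother_id"] = ma
    if n_singletons:
        remaining = [k for k in range(len(order)) if k not in used]
        mothers = sorted(set(kids["biological_mother_id"]))
        for k in remaining[:n_singletons]:
            kid = order["individual_id"][k]
            own = order["biological_mother_id"][k]
            foster = rng.choice([m for m in mothers if m != own])
            out.loc[out["individual_id"] == kid, "rearing_mother_id"] = foster
    return out
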