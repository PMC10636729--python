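"""End-to-end analysis procedures for behavior/survival tables.

Two model structures are encoded.  Model I is a four-trait analysis of
pouch-young movement, averaged subadult FID, subadult survival (binary on a
latent logit scale) and adult female FID, with a shared mother-level random
factor carrying an unstructured 4x4 covariance; residual covariances
between the adult trait and the three offspring traits are fixed to zero
because they are measured on disjoint units.  Model II is a bivariate
repeated-measures analysis of subadult and adult female FID with mother-
and offspring-level random effects, the basis for the repeatability
partition and the upper-limit heritability 2 cov(M, O) / var_M.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import summaries as smy
from .io import TRAITS, validate_observations
from .model import MCMCConfig, ModelSpec, TraitSpec, fit_model

__all__ = [
    "average_subadult_fid",
    "build_model_I_spec",
    "build_model_II_spec",
    "run_full_analysis",
    "adoption_regression",
    "mother_offspring_means",
    "AnalysisReport",
]

_TRIAL_COVARIATES = [
    "test_number",
    "group_size",
    "companion_class",
    "days_since_prev_test",
]


def average_subadult_fid(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse each offspring's repeated subadult FID trials to their mean.

    Trial-varying covariates (test number, group size, companion class,
    days since previous test) are dropped for the averaged rows; all other
    traits pass through untouched.
    """
    sub = table[table["trait"] == "subadult_fid"]
    if sub.empty:
        return table.copy()
    rest = table[table["trait"] != "subadult_fid"]
    rows = []
    for _, grp in sub.groupby("individual_id", sort=True):
        row = grp.iloc[0].copy()
        row["value"] = grp["value"].mean()
        row["age_months"] = grp["age_months"].mean()
        for c in _TRIAL_COVARIATES:
            row[c] = np.nan
        rows.append(row)
    out = pd.concat([rest, pd.DataFrame(rows)], ignore_index=True)
    return out.reset_index(drop=True)


def _require(table: pd.DataFrame, needed) -> None:
    present = set(table["trait"])
    missing = [t for t in needed if t not in present]
    if missing:
        raise ValueError(f"table lacks required trait(s): {missing}")


def build_model_I_spec(table: pd.DataFrame, overrides: dict | None = None) -> ModelSpec:
    """Four-trait model: PY movement, averaged subadult FID, subadult
    survival (binary) and adult female FID, all with a mother-level random
    term; residual covariance free among the three offspring traits and
    fixed to zero against the adult trait."""
    _require(table, TRAITS)
    overrides = overrides or {}
    traits = [
        TraitSpec(
            "py_movement",
            "gaussian",
            tuple(overrides.get("py_movement", ("age_months", "sex", "year"))),
            ("mother",),
            unit_mode="individual",
        ),
        TraitSpec(
            "subadult_fid",
            "gaussian",
            tuple(overrides.get("subadult_fid", ("sex", "year"))),
            ("mother",),
            unit_mode="individual",
        ),
        TraitSpec(
            "subadult_survival",
            "binary_logit",
            tuple(overrides.get("subadult_survival", ("sex", "year"))),
            ("mother",),
            unit_mode="individual",
        ),
        TraitSpec(
            "adult_female_fid",
            "gaussian",
            tuple(
                overrides.get(
                    "adult_female_fid",
                    (
                        "gps_east_m",
                        "group_size",
                        "companion_class",
                        "test_number",
                        "days_since_prev_test",
                        "year",
                        "observer_id",
                    ),
                )
            ),
            ("mother",),
            mother_column="individual_id",
            unit_mode="observation",
        ),
    ]
    mask = np.zeros((4, 4), dtype=bool)
    mask[:3, 3] = mask[3, :3] = True  # offspring traits x adult trait
    return ModelSpec(traits=traits, residual_zero_mask=mask)


def build_model_II_spec(table: pd.DataFrame, overrides: dict | None = None) -> ModelSpec:
    """Bivariate repeated-measures FID model with mother effects on both
    traits (unstructured 2x2 covariance) and an offspring-level effect on
    subadult FID; residual cross-covariance fixed to zero."""
    _require(table, ["subadult_fid", "adult_female_fid"])
    overrides = overrides or {}
    shared = (
        "gps_east_m",
        "group_size",
        "companion_class",
        "test_number",
        "days_since_prev_test",
        "year",
    )
    traits = [
        TraitSpec(
            "subadult_fid",
            "gaussian",
            tuple(overrides.get("subadult_fid", shared + ("age_months", "sex"))),
            ("mother", "individual"),
            unit_mode="observation",
        ),
        TraitSpec(
            "adult_female_fid",
            "gaussian",
            tuple(overrides.get("adult_female_fid", shared + ("observer_id",))),
            ("mother",),
            mother_column="individual_id",
            unit_mode="observation",
        ),
    ]
    mask = ~np.eye(2, dtype=bool)
    return ModelSpec(traits=traits, residual_zero_mask=mask)


# ---------------------------------------------------------------------------


@dataclass
class AnalysisReport:
    """Assembled results of the full two-model analysis."""

    models: dict
    heritability: dict | None
    adoption: dict | None
    metadata: dict = field(default_factory=dict)

    def to_json(self, path=None):
        text = json.dumps(dataclasses.asdict(self), indent=2, default=_json_default)
        if path is not None:
            Path(path).write_text(text)
        return text


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not serialisable: {type(obj)}")


def _covariance_summaries(samples, prefix: str) -> dict:
    out = {}
    for name in samples.names():
        if name.startswith(prefix):
            chain = samples.get(name)
            if np.ptp(chain) == 0:
                out[name] = {
                    "posterior_mode": float(chain[0]),
                    "hpd_low": float(chain[0]),
                    "hpd_high": float(chain[0]),
                }
            else:
                out[name] = smy.summarize(chain)
    return out


def _decomposition_payload(decomps) -> list:
    return [
        {"trait": d.trait, "scale": d.scale, "ratios": d.ratios} for d in decomps
    ]


def run_full_analysis(
    table: pd.DataFrame,
    mcmc: MCMCConfig | None = None,
    models=("I", "II"),
    quadrature_order: int = 31,
) -> AnalysisReport:
    """Fit the requested model structures and assemble a full report.

    Executes Model I on the trial-averaged table and Model II on the raw
    repeated measures, computes latent- and data-scale repeatability
    decompositions, the upper-limit heritability (from Model II), and the
    adoption regression when rearing and biological mothers differ.
    Deterministic for a fixed MCMCConfig seed.
    """
    mcmc = mcmc or MCMCConfig()
    validate_observations(table, strict_scores=False)
    report_models: dict = {}
    heritability = None
    captured: list = []

    def fit_and_summarise(kind: str):
        seed_shift = 0 if kind == "I" else 1
        cfg = dataclasses.replace(mcmc, seed=mcmc.seed + seed_shift)
        if kind == "I":
            spec = build_model_I_spec(average_subadult_fid(table))
            data = average_subadult_fid(table)
        else:
            spec = build_model_II_spec(table)
            data = table
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            samples = fit_model(spec, data, cfg)
        captured.extend(str(w.message) for w in wlist)
        entry = {
            "fixed_effects": {
                t.name: smy.fixed_effect_summary(samples, t.name).coefficients
                for t in spec.traits
            },
            "mother_covariance": _covariance_summaries(samples, "G.motherCov["),
            "offspring_variance": _covariance_summaries(samples, "G.offspringVar["),
            "residual": _covariance_summaries(samples, "R.resid["),
            "decompositions": {},
        }
        for t in spec.traits:
            model_kind = "II" if "individual" in t.random_terms else "I"
            kwargs = {}
            if t.family == "binary_logit":
                kwargs["latent_means"] = samples.linear_predictor_samples(t.name)
                kwargs["quadrature_order"] = quadrature_order
            decomps = smy.decompose_variance(
                samples, t.name, model_kind=model_kind, **kwargs
            )
            entry["decompositions"][t.name] = _decomposition_payload(decomps)
        return spec, samples, entry

    samples_by_kind = {}
    for kind in models:
        spec, samples, entry = fit_and_summarise(kind)
        report_models[kind] = entry
        samples_by_kind[kind] = samples

    if "II" in samples_by_kind:
        est = smy.upper_limit_h2(samples_by_kind["II"])
        heritability = {
            "upper_h2": est.upper_h2,
            "n_excluded_samples": est.n_excluded,
            "source_model": "II",
        }

    adoption = None
    adopted = table.dropna(subset=["rearing_mother_id", "biological_mother_id"])
    adopted = adopted[
        adopted["rearing_mother_id"] != adopted["biological_mother_id"]
    ]
    if len(adopted):
        try:
            adoption = dataclasses.asdict(adoption_regression(table))
        except ValueError as err:
            adoption = {"error": str(err)}

    meta = {
        "seed": mcmc.seed,
        "mcmc": dataclasses.asdict(mcmc),
        "models_run": list(models),
        "warnings": captured,
    }
    return AnalysisReport(
        models=report_models,
        heritability=heritability,
        adoption=adoption,
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# adoption (cross-fostering) regression
# ---------------------------------------------------------------------------


@dataclass
class AdoptionRegression:
    """Offspring-on-mother mean-FID regressions for adopted offspring."""

    n_cases: int
    biological: dict
    rearing: dict


def _mean_fid(table: pd.DataFrame, trait: str) -> pd.Series:
    rows = table[(table["trait"] == trait) & table["value"].notna()]
    return rows.groupby("individual_id")["value"].mean()


def mother_offspring_means(table: pd.DataFrame) -> pd.DataFrame:
    """Per-pair mean FIDs of offspring and their (rearing) mothers: the
    underlying data of a mother-offspring FID scatter."""
    off = _mean_fid(table, "subadult_fid")
    mom = _mean_fid(table, "adult_female_fid")
    pairs = (
        table.dropna(subset=["rearing_mother_id"])[
            ["individual_id", "rearing_mother_id", "biological_mother_id"]
        ]
        .drop_duplicates("individual_id")
        .set_index("individual_id")
    )
    rows = []
    for ind, pair in pairs.iterrows():
        if ind in off.index and pair["rearing_mother_id"] in mom.index:
            rows.append(
                {
                    "offspring_id": ind,
                    "mother_id": pair["rearing_mother_id"],
                    "offspring_mean_fid": off[ind],
                    "mother_mean_fid": mom[pair["rearing_mother_id"]],
                }
            )
    return pd.DataFrame(rows)


def adoption_regression(table: pd.DataFrame, min_cases: int = 3) -> AdoptionRegression:
    """OLS of adopted offspring mean FID on biological- and rearing-mother
    mean FID; slopes are doubled to give upper-limit heritabilities.

    Uses per-animal mean FIDs rather than the mixed model because the
    handful of adoption cases forecloses hierarchical estimation.
    """
    off = _mean_fid(table, "subadult_fid")
    mom = _mean_fid(table, "adult_female_fid")
    pairs = (
        table.dropna(subset=["rearing_mother_id", "biological_mother_id"])[
            ["individual_id", "rearing_mother_id", "biological_mother_id"]
        ]
        .drop_duplicates("individual_id")
    )
    pairs = pairs[pairs["rearing_mother_id"] != pairs["biological_mother_id"]]
    y, x_bio, x_rear = [], [], []
    for _, row in pairs.iterrows():
        ind = row["individual_id"]
        if (
            ind in off.index
            and row["biological_mother_id"] in mom.index
            and row["rearing_mother_id"] in mom.index
        ):
            y.append(off[ind])
            x_bio.append(mom[row["biological_mother_id"]])
            x_rear.append(mom[row["rearing_mother_id"]])
    n = len(y)
    if n < min_cases:
        raise ValueError(
            f"adoption regression needs at least {min_cases} offspring with "
            f"FID for the young and both mothers; found {n}"
        )

    def ols(x):
        x = np.asarray(x, dtype=float)
        if np.ptp(x) == 0:
            return {
                "slope": 0.0,
                "slope_ci": [0.0, 0.0],
                "upper_h2": 0.0,
                "upper_h2_ci": [0.0, 0.0],
            }
        fit = sm.OLS(np.asarray(y, dtype=float), sm.add_constant(x)).fit()
        lo, hi = fit.conf_int()[1]
        return {
            "slope": float(fit.params[1]),
            "slope_ci": [float(lo), float(hi)],
            "upper_h2": float(2 * fit.params[1]),
            "upper_h2_ci": [float(2 * lo), float(2 * hi)],
        }

    return AdoptionRegression(
        n_cases=n, biological=ols(x_bio), rearing=ols(x_rear)
    )
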