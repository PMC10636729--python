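"""Multi-trait Bayesian mixed models fitted by Gibbs sampling.

The sampler targets the posterior of a multivariate generalized linear
mixed model in which each trait is either Gaussian or binary on a latent
logit liability scale:

    y_tij = x'b_t + u_{mother(i), t} + a_{ind(i), t} + e_tij

with mother-level effect vectors u ~ N(0, G) carrying an unstructured
covariance across traits, optional trait-specific individual-level effects
a ~ N(0, v_t), and residuals correlated within an observational unit
according to a residual covariance matrix whose cross-trait elements can be
masked to exactly zero (traits measured on disjoint unit sets) and whose
diagonal can be fixed (1 for the binary liability).  Priors: improper flat
on fixed effects, inverse-Wishart on every unmasked covariance block; the
block holding a fixed diagonal element uses the inverse-Wishart conditioned
on that element.

All Gaussian conditionals are conjugate; binary liabilities are updated by
single-site Metropolis steps whose proposal scale adapts during burn-in
only, so detailed balance holds for every retained sample.
"""

from __future__ import annotations

import io as _io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular

# -- module-wide configuration ---------------------------------------------
DEFAULT_NU_OFFSET = 0.002  # nu = dim + offset: weakly informative, proper
MIN_ESS = 200  # below this, fit_model emits a convergence warning
TARGET_ACCEPT = 0.44  # single-site Metropolis target acceptance
FACTOR_COLUMNS = {"sex", "year", "cohort", "companion_class", "observer_id"}
FACTOR_BASELINES = {"sex": "male", "year": 2017, "companion_class": "alone"}

_log = logging.getLogger("matrep.model")

__all__ = [
    "TraitSpec",
    "ModelSpec",
    "MCMCConfig",
    "PosteriorSamples",
    "fit_model",
    "gibbs_update_covariance",
    "update_binary_latents",
    "effective_sample_size",
]


@dataclass
class TraitSpec:
    """Declarative description of one response trait."""

    name: str
    family: str = "gaussian"  # "gaussian" | "binary_logit"
    fixed_effects: tuple = ()
    random_terms: tuple = ("mother",)
    residual_variance_fixed: float | None = None
    mother_column: str = "rearing_mother_id"
    unit_mode: str = "individual"  # "individual" | "observation"

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "binary_logit"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "binary_logit":
            if self.residual_variance_fixed not in (None, 1.0):
                raise ValueError(
                    "binary_logit traits must have residual variance fixed at 1"
                )
            self.residual_variance_fixed = 1.0
        bad = set(self.random_terms) - {"mother", "individual"}
        if bad:
            raise ValueError(f"unknown random terms {sorted(bad)}")


@dataclass
class ModelSpec:
    """A multi-trait model: traits, residual zero-mask and priors.

    ``residual_zero_mask[i, j] = True`` forces the residual covariance
    between traits i and j to exactly zero (diagonal entries can never be
    masked).  ``priors`` may provide ``(V, nu)`` pairs under keys
    "mother", "individual" and "residual"; defaults are identity scale with
    nu = dim + 0.002 per block.
    """

    traits: list
    residual_zero_mask: np.ndarray | None = None
    priors: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = len(self.traits)
        if self.residual_zero_mask is None:
            self.residual_zero_mask = ~np.eye(t, dtype=bool)
        self.residual_zero_mask = np.asarray(self.residual_zero_mask, dtype=bool)
        if self.residual_zero_mask.shape != (t, t):
            raise ValueError("residual_zero_mask shape must match trait count")
        if not np.array_equal(self.residual_zero_mask, self.residual_zero_mask.T):
            raise ValueError("residual_zero_mask must be symmetric")
        if self.residual_zero_mask.diagonal().any():
            raise ValueError("diagonal residual elements cannot be masked to zero")

    @property
    def trait_names(self) -> list:
        return [t.name for t in self.traits]


@dataclass
class MCMCConfig:
    """Chain length and tuning; defaults are the test-scale settings."""

    n_iterations: int = 20_000
    burn_in: int = 5_000
    thinning_interval: int = 10
    seed: int = 0
    proposal_scale: float = 1.5
    adapt: bool = True

    def validate(self) -> None:
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.thinning_interval < 1:
            raise ValueError("thinning_interval must be >= 1")


# ---------------------------------------------------------------------------
# elementary samplers
# ---------------------------------------------------------------------------


def _sample_invwishart(psi: np.ndarray, nu: float, rng: np.random.Generator):
    """Draw from IW(psi, nu) via a Bartlett-decomposed Wishart on psi^-1."""
    psi = np.atleast_2d(np.asarray(psi, dtype=float))
    p = psi.shape[0]
    if nu <= p - 1:
        raise ValueError(f"inverse-Wishart needs nu > dim - 1 (got {nu}, dim {p})")
    l_psi = np.linalg.cholesky(psi)
    # factor of psi^-1: M = L^-T satisfies M M' = psi^-1
    m = solve_triangular(l_psi, np.eye(p), lower=True).T
    a = np.zeros((p, p))
    for i in range(p):
        a[i, i] = np.sqrt(rng.chisquare(nu - i))
        for j in range(i):
            a[i, j] = rng.standard_normal()
    f = m @ a
    w = f @ f.T  # ~ Wishart(nu, psi^-1)
    return np.linalg.inv(w)


def _sample_invwishart_fixed(psi, nu, fixed_idx, fixed_block, rng):
    """Draw from IW(psi, nu) conditioned on a fixed diagonal sub-block.

    Uses the partition property of the inverse-Wishart: with free indices a
    and fixed indices b, the Schur complement S_aa.b ~ IW(psi_aa.b, nu) and
    the regression B = S_ab S_bb^-1 is matrix-normal, both independent of
    S_bb, so conditioning on S_bb = F leaves their laws unchanged.
    """
    psi = np.atleast_2d(np.asarray(psi, dtype=float))
    p = psi.shape[0]
    fixed_idx = list(fixed_idx)
    free_idx = [i for i in range(p) if i not in fixed_idx]
    f = np.atleast_2d(np.asarray(fixed_block, dtype=float))
    if not free_idx:
        return f
    a, b = np.ix_(free_idx, free_idx), np.ix_(fixed_idx, fixed_idx)
    ab = np.ix_(free_idx, fixed_idx)
    psi_bb_inv = np.linalg.inv(psi[b])
    psi_ab = psi[ab]
    psi_cond = psi[a] - psi_ab @ psi_bb_inv @ psi_ab.T
    s_cond = _sample_invwishart(psi_cond, nu, rng)
    mean_b = psi_ab @ psi_bb_inv
    l_row = np.linalg.cholesky(s_cond)
    l_col = np.linalg.cholesky(psi_bb_inv)
    z = rng.standard_normal((len(free_idx), len(fixed_idx)))
    breg = mean_b + l_row @ z @ l_col.T
    out = np.empty((p, p))
    out[b] = f
    out[ab] = breg @ f
    out[np.ix_(fixed_idx, free_idx)] = out[ab].T
    out[a] = s_cond + breg @ f @ breg.T
    return out


def _mask_blocks(mask: np.ndarray):
    """Connected components of the free-covariance graph implied by a mask."""
    t = mask.shape[0]
    seen, blocks = set(), []
    for s in range(t):
        if s in seen:
            continue
        comp, stack = [], [s]
        while stack:
            i = stack.pop()
            if i in seen:
                continue
            seen.add(i)
            comp.append(i)
            stack.extend(j for j in range(t) if j != i and not mask[i, j])
        blocks.append(sorted(comp))
    return blocks


def gibbs_update_covariance(
    scaled_crossproduct: np.ndarray,
    n_levels: int,
    prior: tuple,
    mask: np.ndarray | None = None,
    rng_state=None,
) -> np.ndarray:
    """One conditional inverse-Wishart draw for a (possibly masked) matrix.

    ``scaled_crossproduct`` is the sum of outer products of the effect (or
    residual) vectors; the conditional for each unmasked block is
    IW(V_block + S_block, nu + n_levels).  Masked cross-block elements are
    returned as exactly zero.
    """
    rng = (
        rng_state
        if isinstance(rng_state, np.random.Generator)
        else np.random.default_rng(rng_state)
    )
    s = np.atleast_2d(np.asarray(scaled_crossproduct, dtype=float))
    p = s.shape[0]
    v, nu = prior
    v = np.atleast_2d(np.asarray(v, dtype=float))
    if mask is None:
        mask = np.zeros((p, p), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros((p, p))
    for block in _mask_blocks(mask):
        ix = np.ix_(block, block)
        out[ix] = _sample_invwishart(v[ix] + s[ix], nu + n_levels, rng)
    return out


def update_binary_latents(
    current_liabilities,
    linear_predictors,
    outcomes,
    tuning: float = 1.5,
    rng_state=None,
    resid_var=1.0,
):
    """One vectorised single-site Metropolis update of logit liabilities.

    Target for each site: N(l | predictor, resid_var) * Bernoulli(y |
    logistic(l)).  Returns ``(liabilities, acceptance_fraction)``.
    """
    rng = (
        rng_state
        if isinstance(rng_state, np.random.Generator)
        else np.random.default_rng(rng_state)
    )
    l = np.asarray(current_liabilities, dtype=float)
    eta = np.broadcast_to(np.asarray(linear_predictors, dtype=float), l.shape)
    y = np.broadcast_to(np.asarray(outcomes, dtype=float), l.shape)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcomes must be 0/1")
    v = np.broadcast_to(np.asarray(resid_var, dtype=float), l.shape)
    prop = l + tuning * rng.standard_normal(l.shape)

    def logp(x):
        # log N(x | eta, v) + y log sigma(x) + (1-y) log sigma(-x)
        return -0.5 * (x - eta) ** 2 / v - np.logaddexp(0.0, -x) * y - (
            np.logaddexp(0.0, x) * (1.0 - y)
        )

    log_ratio = logp(prop) - logp(l)
    accept = np.log(rng.random(l.shape)) < log_ratio
    out = np.where(accept, prop, l)
    return out, float(np.mean(accept))


def effective_sample_size(chain) -> float:
    """Autocorrelation-based effective sample size of a single chain.

    Delegates to arviz; a constant chain reports 0 (with a warning) and
    estimates exceeding the nominal length are flagged and capped there.
    """
    x = np.asarray(chain, dtype=float).ravel()
    if x.size < 10:
        raise ValueError("need at least 10 samples for an ESS estimate")
    if np.ptp(x) == 0:
        warnings.warn("constant chain: effective sample size reported as 0")
        return 0.0
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ess = float(az.ess(x[None, :]))
    if not np.isfinite(ess):
        warnings.warn("ESS estimate undefined; reporting 0")
        return 0.0
    if ess > x.size:
        warnings.warn(
            f"ESS estimate {ess:.0f} exceeds chain length {x.size}; capped"
        )
        ess = float(x.size)
    return ess


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


def _build_design(df: pd.DataFrame, terms, trait_name: str):
    """Design matrix with an intercept, centred numeric covariates and
    baseline-dropped factor dummies.  Returns (X, term_names)."""
    n = len(df)
    cols = [np.ones(n)]
    names = ["intercept"]
    for term in terms:
        if term not in df.columns:
            raise ValueError(
                f"unknown covariate {term!r} for trait {trait_name!r}"
            )
        col = df[term]
        if term in FACTOR_COLUMNS or col.dtype == object:
            values = col.dropna()
            levels = sorted(values.unique(), key=str)
            if not levels:
                continue
            base = FACTOR_BASELINES.get(term)
            if base not in levels:
                base = levels[0]
            for lev in levels:
                if lev == base:
                    continue
                lev_label = int(lev) if isinstance(lev, float) else lev
                cols.append((col == lev).to_numpy(dtype=float))
                names.append(f"{term}_{lev_label}")
        else:
            x = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
            center = np.nanmean(x) if np.isfinite(x).any() else 0.0
            x = np.where(np.isfinite(x), x - center, 0.0)
            cols.append(x)
            names.append(term)
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError(
            f"design matrix for trait {trait_name!r} is rank deficient; "
            "drop collinear covariates"
        )
    return x, names


# ---------------------------------------------------------------------------
# posterior container
# ---------------------------------------------------------------------------


class PosteriorSamples:
    """Thinned post-burn-in samples, addressable by canonical names.

    Naming convention: ``G.motherCov[traitA,traitB]``,
    ``G.offspringVar[trait]``, ``R.resid[traitA,traitB]`` and
    ``B.fixed[trait:term]``.
    """

    def __init__(self, data: dict, iterations, trait_names, binary_traits,
                 designs=None):
        self._data = {k: np.asarray(v, dtype=float) for k, v in data.items()}
        self.iterations = np.asarray(iterations, dtype=int)
        self.trait_names = list(trait_names)
        self.binary_traits = set(binary_traits)
        self._designs = designs or {}

    @property
    def n_samples(self) -> int:
        return self.iterations.size

    def names(self):
        return list(self._data)

    def is_binary(self, trait: str) -> bool:
        return trait in self.binary_traits

    def get(self, name: str) -> np.ndarray:
        if name in self._data:
            return self._data[name]
        # covariance names are symmetric in the trait pair
        for head in ("G.motherCov", "R.resid"):
            if name.startswith(head + "["):
                a, b = name[len(head) + 1 : -1].split(",")
                alt = f"{head}[{b},{a}]"
                if alt in self._data:
                    return self._data[alt]
        raise KeyError(name)

    def linear_predictor_samples(self, trait: str) -> np.ndarray:
        """Per-sample fixed-effect predictors (n_samples, n_units)."""
        x, terms = self._designs[trait]
        b = np.column_stack(
            [self._data[f"B.fixed[{trait}:{t}]"] for t in terms]
        )
        return b @ x.T

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for name, vals in self._data.items():
            frames.append(
                pd.DataFrame(
                    {
                        "iteration": self.iterations,
                        "parameter_name": name,
                        "value": vals,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def write_csv(self, path) -> None:
        meta = (
            "# traits="
            + ",".join(self.trait_names)
            + " binary="
            + ",".join(sorted(self.binary_traits))
            + "\n"
        )
        with open(path, "w") as fh:
            fh.write(meta)
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def read_csv(cls, path) -> "PosteriorSamples":
        with open(path) as fh:
            first = fh.readline()
            traits, binary = [], []
            if first.startswith("#"):
                body = fh.read()
                for part in first[1:].strip().split():
                    key, _, val = part.partition("=")
                    if key == "traits":
                        traits = [v for v in val.split(",") if v]
                    elif key == "binary":
                        binary = [v for v in val.split(",") if v]
            else:
                body = first + fh.read()
        df = pd.read_csv(_io.StringIO(body))
        data, iterations = {}, None
        for name, group in df.groupby("parameter_name", sort=False):
            data[name] = group["value"].to_numpy()
            iterations = group["iteration"].to_numpy()
        return cls(data, iterations, traits, binary)

    def equals(self, other: "PosteriorSamples") -> bool:
        return (
            set(self._data) == set(other._data)
            and np.array_equal(self.iterations, other.iterations)
            and all(np.allclose(self._data[k], other._data[k]) for k in self._data)
        )


# ---------------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------------


class _Block:
    """One residual-covariance block: units x traits with aligned designs."""

    __slots__ = (
        "traits", "k", "y", "obs", "binary", "outcome", "a",
        "gram", "mother_idx", "ind_codes", "r", "fixed_cols", "tau",
        "mother_cols", "n_units",
    )


def _prepare(spec: ModelSpec, table: pd.DataFrame):
    names = spec.trait_names
    t_index = {n: i for i, n in enumerate(names)}
    sub = table[table["trait"].isin(names)]
    missing = [n for n in names if n not in set(sub["trait"])]
    if missing:
        raise ValueError(f"table lacks trait(s): {missing}")

    # mother levels shared across traits carrying a mother term
    mother_traits = [i for i, t in enumerate(spec.traits) if "mother" in t.random_terms]
    levels: list = []
    for i in mother_traits:
        t = spec.traits[i]
        rows = sub[sub["trait"] == t.name]
        vals = rows[t.mother_column]
        if vals.isna().any():
            raise ValueError(
                f"trait {t.name!r}: missing {t.mother_column} for some rows"
            )
        levels.extend(vals.unique())
    mother_levels = sorted(set(levels), key=str)
    mcode = {m: i for i, m in enumerate(mother_levels)}

    blocks = []
    designs = {}
    ind_levels = {}
    for traits_ix in _mask_blocks(spec.residual_zero_mask):
        blk = _Block()
        blk.traits = traits_ix
        blk.k = len(traits_ix)
        tspecs = [spec.traits[i] for i in traits_ix]
        if blk.k > 1:
            if any(t.unit_mode != "individual" for t in tspecs):
                raise ValueError(
                    "traits sharing free residual covariance must use "
                    "individual observational units"
                )
            units = sorted(
                set(sub[sub["trait"].isin([t.name for t in tspecs])]["individual_id"]),
                key=str,
            )
            ucode = {u: i for i, u in enumerate(units)}
            n_u = len(units)
            blk.y = np.zeros((n_u, blk.k))
            blk.obs = np.zeros((n_u, blk.k), dtype=bool)
            blk.outcome = np.zeros((n_u, blk.k))
            blk.a = []
            blk.mother_idx = np.full(n_u, -1, dtype=int)
            blk.ind_codes = [None] * blk.k
            for j, t in enumerate(tspecs):
                rows = sub[sub["trait"] == t.name]
                if rows["individual_id"].duplicated().any():
                    raise ValueError(
                        f"trait {t.name!r} has repeated measures but shares "
                        "residual covariance; average or mask first"
                    )
                x_rows, terms = _build_design(rows, t.fixed_effects, t.name)
                # scatter design rows into unit order; absent units get the
                # reference row (intercept only, numerics centred at zero)
                x = np.zeros((n_u, x_rows.shape[1]))
                x[:, 0] = 1.0
                ridx = [ucode[u] for u in rows["individual_id"]]
                x[ridx] = x_rows
                blk.a.append(x)
                designs[t.name] = (x_rows, terms)
                vals = rows["value"].to_numpy(dtype=float)
                blk.y[ridx, j] = np.where(np.isfinite(vals), vals, 0.0)
                blk.obs[ridx, j] = np.isfinite(vals)
                if t.family == "binary_logit":
                    blk.outcome[ridx, j] = np.where(np.isfinite(vals), vals, 0.0)
                if "mother" in t.random_terms:
                    midx = np.array([mcode[m] for m in rows[t.mother_column]])
                    blk.mother_idx[ridx] = midx
                if "individual" in t.random_terms:
                    lev = sorted(set(rows["individual_id"]), key=str)
                    ind_levels[t.name] = lev
                    icode = {u: i for i, u in enumerate(lev)}
                    codes = np.full(n_u, -1, dtype=int)
                    codes[ridx] = [icode[u] for u in rows["individual_id"]]
                    blk.ind_codes[j] = codes
        else:
            t = tspecs[0]
            rows = sub[sub["trait"] == t.name]
            rows = rows[rows["value"].notna() | (t.family == "binary_logit")]
            n_u = len(rows)
            x_rows, terms = _build_design(rows, t.fixed_effects, t.name)
            blk.a = [x_rows]
            designs[t.name] = (x_rows, terms)
            vals = rows["value"].to_numpy(dtype=float)
            blk.y = vals.reshape(-1, 1).copy()
            blk.obs = np.isfinite(vals).reshape(-1, 1)
            blk.y[~blk.obs] = 0.0
            blk.outcome = np.where(np.isfinite(vals), vals, 0.0).reshape(-1, 1)
            if "mother" in t.random_terms:
                blk.mother_idx = np.array(
                    [mcode[m] for m in rows[t.mother_column]], dtype=int
                )
            else:
                blk.mother_idx = np.full(n_u, -1, dtype=int)
            blk.ind_codes = [None]
            if "individual" in t.random_terms:
                lev = sorted(set(rows["individual_id"]), key=str)
                ind_levels[t.name] = lev
                icode = {u: i for i, u in enumerate(lev)}
                blk.ind_codes[0] = np.array(
                    [icode[u] for u in rows["individual_id"]], dtype=int
                )
        blk.n_units = blk.y.shape[0]
        blk.binary = np.array(
            [spec.traits[i].family == "binary_logit" for i in traits_ix]
        )
        blk.fixed_cols = [
            (j, spec.traits[i].residual_variance_fixed)
            for j, i in enumerate(traits_ix)
            if spec.traits[i].residual_variance_fixed is not None
        ]
        blk.gram = [
            [blk.a[j1].T @ blk.a[j2] for j2 in range(blk.k)] for j1 in range(blk.k)
        ]
        blk.mother_cols = [
            mother_traits.index(i) if i in mother_traits else -1 for i in traits_ix
        ]
        blk.tau = np.full(blk.k, 1.5)
        blocks.append(blk)

    return blocks, designs, mother_levels, mother_traits, ind_levels, t_index


def fit_model(
    spec: ModelSpec, table: pd.DataFrame, mcmc: MCMCConfig | None = None
) -> PosteriorSamples:
    """Gibbs-sample the posterior of a multi-trait mixed model.

    Returns thinned post-burn-in samples of all fixed effects, the
    mother-level covariance matrix, individual-level variances and residual
    (co)variances.  Missing responses inside multi-trait residual blocks
    are integrated out by per-iteration augmentation, which leaves the
    posterior identical to omitting their likelihood contributions.
    """
    mcmc = mcmc or MCMCConfig()
    mcmc.validate()
    rng = np.random.default_rng(mcmc.seed)
    blocks, designs, mother_levels, mother_traits, ind_levels, t_index = _prepare(
        spec, table
    )
    names = spec.trait_names
    n_m = len(mother_levels)
    t_m = len(mother_traits)
    ind_traits = [t.name for t in spec.traits if "individual" in t.random_terms]

    # identifiability heuristic: a single observation per mother everywhere
    if n_m:
        counts = np.zeros(n_m)
        for blk in blocks:
            idx = blk.mother_idx[blk.mother_idx >= 0]
            counts += np.bincount(idx, minlength=n_m)
        if counts.max() <= 1:
            warnings.warn(
                "every mother level has at most one observation; mother-level "
                "variance is weakly identified"
            )

    # priors
    v_g, nu_g = spec.priors.get(
        "mother", (np.eye(max(t_m, 1)), max(t_m, 1) + DEFAULT_NU_OFFSET)
    )
    v_i, nu_i = spec.priors.get("individual", (1.0, 1.0 + DEFAULT_NU_OFFSET))
    res_prior = spec.priors.get("residual", None)

    # state initialisation
    beta, offsets = [], {}
    off = 0
    for t in spec.traits:
        x, terms = designs[t.name]
        rows = np.arange(x.shape[0])
        offsets[t.name] = (off, off + len(terms))
        b0 = np.zeros(len(terms))
        # intercept at the observed mean (logit-ish for binary)
        blk = next(b for b in blocks if t_index[t.name] in b.traits)
        j = blk.traits.index(t_index[t.name])
        yobs = blk.y[blk.obs[:, j], j]
        if yobs.size:
            m = float(np.mean(yobs))
            b0[0] = (2 * m - 1) if t.family == "binary_logit" else m
        beta.append(b0)
        off += len(terms)
        del rows
    beta = np.concatenate(beta) if beta else np.zeros(0)
    u = np.zeros((n_m, t_m))
    g = np.eye(t_m)
    u_ind = {t: np.zeros(len(ind_levels[t])) for t in ind_traits}
    var_ind = {t: 1.0 for t in ind_traits}
    for blk in blocks:
        blk.r = np.eye(blk.k)
        for j, t_ix in enumerate(blk.traits):
            t = spec.traits[t_ix]
            if t.residual_variance_fixed is not None:
                blk.r[j, j] = t.residual_variance_fixed
            else:
                yo = blk.y[blk.obs[:, j], j]
                blk.r[j, j] = max(float(np.var(yo)) if yo.size > 1 else 1.0, 1e-3)
        # liabilities start at signed half-units
        for j in np.where(blk.binary)[0]:
            blk.y[:, j] = np.where(
                blk.obs[:, j], 2.0 * blk.outcome[:, j] - 1.0, 0.0
            )

    p_total = beta.size
    n_keep = (mcmc.n_iterations - mcmc.burn_in) // mcmc.thinning_interval
    keep_iter = np.zeros(n_keep, dtype=int)
    keep_beta = np.zeros((n_keep, p_total))
    keep_g = np.zeros((n_keep, t_m, t_m))
    keep_vi = {t: np.zeros(n_keep) for t in ind_traits}
    keep_r = {bi: np.zeros((n_keep, blk.k, blk.k)) for bi, blk in enumerate(blocks)}

    def fixed_mat(blk):
        out = np.empty((blk.n_units, blk.k))
        for j, t_ix in enumerate(blk.traits):
            lo, hi = offsets[names[t_ix]]
            out[:, j] = blk.a[j] @ beta[lo:hi]
        return out

    def mother_mat(blk):
        out = np.zeros((blk.n_units, blk.k))
        if t_m == 0:
            return out
        valid = blk.mother_idx >= 0
        for j, mc in enumerate(blk.mother_cols):
            if mc >= 0:
                out[valid, j] = u[blk.mother_idx[valid], mc]
        return out

    def ind_mat(blk):
        out = np.zeros((blk.n_units, blk.k))
        for j, t_ix in enumerate(blk.traits):
            codes = blk.ind_codes[j]
            if codes is not None:
                ok = codes >= 0
                out[ok, j] = u_ind[names[t_ix]][codes[ok]]
        return out

    accept_acc = {}
    kept = 0
    progress_every = max(1, mcmc.n_iterations // 4)
    for it in range(mcmc.n_iterations):
        in_burn = it < mcmc.burn_in
        if (it + 1) % progress_every == 0:
            _log.info("iteration %d/%d", it + 1, mcmc.n_iterations)

        # -- 1. latent liabilities and augmented missing responses --------
        for blk in blocks:
            mu = fixed_mat(blk) + mother_mat(blk) + ind_mat(blk)
            for j in range(blk.k):
                needs_binary = blk.binary[j] and blk.obs[:, j].any()
                needs_aug = not blk.obs[:, j].all()
                if not (needs_binary or needs_aug):
                    continue
                if blk.k == 1:
                    cmean = mu[:, 0]
                    cvar = blk.r[0, 0]
                else:
                    others = [m for m in range(blk.k) if m != j]
                    w = np.linalg.solve(blk.r[np.ix_(others, others)],
                                        blk.r[others, j])
                    cmean = mu[:, j] + (blk.y[:, others] - mu[:, others]) @ w
                    cvar = float(blk.r[j, j] - blk.r[j, others] @ w)
                if blk.binary[j]:
                    cells = blk.obs[:, j]
                    if cells.any():
                        new, acc = update_binary_latents(
                            blk.y[cells, j],
                            cmean[cells],
                            blk.outcome[cells, j],
                            tuning=blk.tau[j],
                            rng_state=rng,
                            resid_var=cvar,
                        )
                        blk.y[cells, j] = new
                        if mcmc.adapt and in_burn:
                            blk.tau[j] *= float(
                                np.exp(0.05 * (acc - TARGET_ACCEPT))
                            )
                        else:
                            key = (id(blk), j)
                            accept_acc[key] = accept_acc.get(key, 0.0) + acc
                    miss = ~blk.obs[:, j]
                    if miss.any():
                        blk.y[miss, j] = cmean[miss] + np.sqrt(cvar) * (
                            rng.standard_normal(int(miss.sum()))
                        )
                elif needs_aug:
                    miss = ~blk.obs[:, j]
                    blk.y[miss, j] = cmean[miss] + np.sqrt(cvar) * (
                        rng.standard_normal(int(miss.sum()))
                    )

        # -- 2. fixed effects (joint GLS draw, flat prior) ----------------
        if p_total:
            prec = np.zeros((p_total, p_total))
            rhs = np.zeros(p_total)
            for blk in blocks:
                w = np.linalg.inv(blk.r)
                resid = blk.y - mother_mat(blk) - ind_mat(blk)
                for j1 in range(blk.k):
                    lo1, hi1 = offsets[names[blk.traits[j1]]]
                    for j2 in range(blk.k):
                        lo2, hi2 = offsets[names[blk.traits[j2]]]
                        prec[lo1:hi1, lo2:hi2] += w[j1, j2] * blk.gram[j1][j2]
                        rhs[lo1:hi1] += w[j1, j2] * (blk.a[j1].T @ resid[:, j2])
            cf = cho_factor(prec, lower=True)
            mean = cho_solve(cf, rhs)
            z = rng.standard_normal(p_total)
            beta = mean + solve_triangular(cf[0].T, z, lower=False)

        # -- 3. mother-level effect vectors -------------------------------
        if t_m:
            prec = np.broadcast_to(
                np.linalg.inv(g), (n_m, t_m, t_m)
            ).copy()
            rhs = np.zeros((n_m, t_m))
            for blk in blocks:
                valid = blk.mother_idx >= 0
                if not valid.any():
                    continue
                w = np.linalg.inv(blk.r)
                wt = np.zeros((t_m, t_m))
                cols = blk.mother_cols
                for j1 in range(blk.k):
                    for j2 in range(blk.k):
                        if cols[j1] >= 0 and cols[j2] >= 0:
                            wt[cols[j1], cols[j2]] += w[j1, j2]
                counts = np.bincount(blk.mother_idx[valid], minlength=n_m)
                prec += counts[:, None, None] * wt[None]
                resid = (blk.y - fixed_mat(blk) - ind_mat(blk))[valid]
                q = resid @ w.T
                for j in range(blk.k):
                    if cols[j] >= 0:
                        np.add.at(
                            rhs[:, cols[j]], blk.mother_idx[valid], q[:, j]
                        )
            cov = np.linalg.inv(prec)
            mean = np.einsum("mij,mj->mi", cov, rhs)
            chol = np.linalg.cholesky(cov)
            u = mean + np.einsum(
                "mij,mj->mi", chol, rng.standard_normal((n_m, t_m))
            )

        # -- 4. individual-level effects ----------------------------------
        for tname in ind_traits:
            a_cur = u_ind[tname]
            lvl = len(a_cur)
            acc_p = np.zeros(lvl)
            acc_r = np.zeros(lvl)
            t_ix = t_index[tname]
            for blk in blocks:
                if t_ix not in blk.traits:
                    continue
                j = blk.traits.index(t_ix)
                codes = blk.ind_codes[j]
                ok = codes >= 0
                w = np.linalg.inv(blk.r)
                resid = blk.y - fixed_mat(blk) - mother_mat(blk) - ind_mat(blk)
                q = resid @ w.T
                contrib = q[ok, j] + w[j, j] * a_cur[codes[ok]]
                acc_r += np.bincount(codes[ok], weights=contrib, minlength=lvl)
                acc_p += w[j, j] * np.bincount(codes[ok], minlength=lvl)
            prec = 1.0 / var_ind[tname] + acc_p
            mean = acc_r / prec
            u_ind[tname] = mean + rng.standard_normal(lvl) / np.sqrt(prec)

        # -- 5. covariance updates ----------------------------------------
        if t_m:
            g = _sample_invwishart(
                np.atleast_2d(v_g) + u.T @ u, nu_g + n_m, rng
            )
        for tname in ind_traits:
            a_cur = u_ind[tname]
            var_ind[tname] = float(
                _sample_invwishart(
                    np.atleast_2d(v_i) + np.sum(a_cur**2),
                    nu_i + a_cur.size,
                    rng,
                )[0, 0]
            )
        for bi, blk in enumerate(blocks):
            fixed = blk.fixed_cols
            if len(fixed) == blk.k:
                continue  # fully fixed block (e.g. univariate binary)
            resid = blk.y - fixed_mat(blk) - mother_mat(blk) - ind_mat(blk)
            s = resid.T @ resid
            if res_prior is not None:
                v_r, nu_r = res_prior
                v_r = np.atleast_2d(np.asarray(v_r, dtype=float))
                vb = v_r[np.ix_(blk.traits, blk.traits)] if v_r.shape[0] == len(
                    names
                ) else np.eye(blk.k) * float(v_r.ravel()[0])
            else:
                vb = np.eye(blk.k)
                nu_r = blk.k + DEFAULT_NU_OFFSET
            psi = vb + s
            nu_post = nu_r + blk.n_units
            if fixed:
                fixed_ix = [j for j, _ in fixed]
                fixed_block = np.diag([val for _, val in fixed])
                blk.r = _sample_invwishart_fixed(
                    psi, nu_post, fixed_ix, fixed_block, rng
                )
            else:
                blk.r = _sample_invwishart(psi, nu_post, rng)

        # -- retention -----------------------------------------------------
        if not in_burn and (it - mcmc.burn_in) % mcmc.thinning_interval == 0:
            if kept < n_keep:
                keep_iter[kept] = it
                keep_beta[kept] = beta
                if t_m:
                    keep_g[kept] = g
                for tname in ind_traits:
                    keep_vi[tname][kept] = var_ind[tname]
                for bi, blk in enumerate(blocks):
                    keep_r[bi][kept] = blk.r
                kept += 1

    # -- assemble named samples -------------------------------------------
    data = {}
    for t in spec.traits:
        lo, hi = offsets[t.name]
        terms = designs[t.name][1]
        for c, term in enumerate(terms):
            data[f"B.fixed[{t.name}:{term}]"] = keep_beta[:, lo + c]
    for a_i, gi in enumerate(mother_traits):
        for b_i, gj in enumerate(mother_traits):
            if a_i <= b_i:
                data[f"G.motherCov[{names[gi]},{names[gj]}]"] = keep_g[:, a_i, b_i]
    for tname in ind_traits:
        data[f"G.offspringVar[{tname}]"] = keep_vi[tname]
    full_r = np.zeros((n_keep, len(names), len(names)))
    for bi, blk in enumerate(blocks):
        for j1, t1 in enumerate(blk.traits):
            for j2, t2 in enumerate(blk.traits):
                full_r[:, t1, t2] = keep_r[bi][:, j1, j2]
    for i in range(len(names)):
        for j in range(i, len(names)):
            data[f"R.resid[{names[i]},{names[j]}]"] = full_r[:, i, j]

    out = PosteriorSamples(
        data,
        keep_iter,
        names,
        [t.name for t in spec.traits if t.family == "binary_logit"],
        designs={k: v for k, v in designs.items()},
    )

    # convergence heuristics on the variance parameters
    for name in out.names():
        if name.startswith("G.") or name.startswith("R."):
            chain = out.get(name)
            if np.ptp(chain) == 0:
                continue
            ess = effective_sample_size(chain)
            if 0 < ess < MIN_ESS:
                warnings.warn(
                    f"low effective sample size for {name}: {ess:.0f} < {MIN_ESS}"
                )
    return out
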