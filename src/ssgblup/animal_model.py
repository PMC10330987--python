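"""Bayesian animal model y = Xβ + Z₁c + Z₂a + e fitted by Gibbs sampling.

The three evaluation methods differ only in the covariance structure Δ of
the additive genetic effects, Var(a) = Δσ²ₐ: the pedigree matrix A (BLUP),
the genomic matrix G over genotyped animals (GBLUP), or the single-step
matrix H (ssGBLUP).  Contemporary-group effects are iid, Var(c) = Iσ²_cg,
and residuals iid, Var(e) = Iσ²ₑ.  Fixed effects get a flat prior and the
three variances scaled-inverse-chi-square priors.

Sampling strategy
-----------------
The sampler reparameterises the model through the genetic values of the
recorded animals, g = Z₂a, whose prior covariance is K σ²ₐ with
K = Δ[rec, rec].  A one-time eigendecomposition K = UΛU′ and rotation of
the whole system by U′ turns the genetic full conditional into independent
univariate normals, and because indicator blocks keep orthogonal columns
under rotation, the CG full conditional stays diagonal too.  Each Gibbs
sweep is therefore a handful of vectorised O(n·n_cg) operations.  Breeding
values of animals without records are recovered exactly by the linear
back-solve â = Δ[:, rec] K⁺ ĝ (conditional-mean property of the
multivariate normal).  The posterior is identical to that of any other
exact Gibbs scheme for the same model; only the mechanism differs.

One record per animal is assumed (true of the growth traits this pipeline
targets); repeated records raise a clear error.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import ConfigError, DataError, NumericalError
from .relmat import RelationshipMatrix

logger = logging.getLogger(__name__)

METHODS = ("BLUP", "GBLUP", "ssGBLUP")

#: which relationship-matrix kinds may serve as Δ for each method
METHOD_KINDS = {"BLUP": ("A",), "GBLUP": ("G", "G_a"), "ssGBLUP": ("H",)}

#: default fixed-effect terms per trait: birth weight uses sex and dam age;
#: weaning/yearling weight add management group and an age covariate
TRAIT_FIXED_TERMS = {
    "BW": ("sex", "dam_age"),
    "WW": ("sex", "dam_age", "mgmt", "age"),
    "YW": ("sex", "dam_age", "mgmt", "age"),
}


@dataclass
class McmcConfig:
    """Chain length settings.  ``n_iterations`` counts post-burn-in sweeps;
    every ``thin``-th of them is stored."""

    n_iterations: int = 25_000
    burn_in: int = 25_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations <= 0:
            raise ConfigError("n_iterations must be positive")
        if self.burn_in < 0 or self.thin < 1:
            raise ConfigError("burn_in must be >= 0 and thin >= 1")

    @property
    def n_samples(self) -> int:
        return self.n_iterations // self.thin


@dataclass
class Priors:
    """Scaled-inverse-chi-square priors for (σ²ₐ, σ²_cg, σ²ₑ).

    Each scale is set so the prior mode equals R²ₖ · var(y), with the
    default R² split 0.25/0.25/0.5 across the additive, CG and residual
    components and df = 5 — the documented automatic-hyperparameter
    convention this pipeline adopts.  A component of ``fixed_variances``
    pins that variance instead of sampling it (0 switches the effect off).
    """

    df: float = 5.0
    r2: tuple[float, float, float] = (0.25, 0.25, 0.5)
    fixed_variances: tuple[float | None, float | None, float | None] = (
        None,
        None,
        None,
    )

    def scales(self, var_y: float) -> tuple[float, float, float]:
        return tuple(
            r * var_y * (self.df + 2.0) / self.df for r in self.r2
        )


@dataclass
class ModelSpec:
    """Trait, fixed-effect terms and evaluation method for one analysis."""

    trait: str
    method: str = "BLUP"
    fixed_terms: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ConfigError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.fixed_terms is None:
            if self.trait not in TRAIT_FIXED_TERMS:
                raise ConfigError(
                    f"no default fixed terms for trait {self.trait!r}; pass fixed_terms"
                )
            self.fixed_terms = TRAIT_FIXED_TERMS[self.trait]


# ---------------------------------------------------------------------- #
# design construction
# ---------------------------------------------------------------------- #
class DesignBuilder:
    """Builds X and Z₁ for training records and replays the same coding
    (factor levels, covariate centring) on new records.

    Categorical terms are dummy-coded against their first observed level;
    covariates are centred on the training mean.  A contemporary group
    unseen in training maps to an all-zero Z₁ row, so its effect estimate
    is implicitly 0 (logged as a warning when it happens).
    """

    def __init__(self, fixed_terms: tuple[str, ...]):
        self.fixed_terms = tuple(fixed_terms)
        self.sex_levels: list = []
        self.mgmt_levels: list = []
        self.centers: dict[str, float] = {}
        self.cg_levels: list = []
        self.fitted = False

    def fit(self, records: pd.DataFrame) -> "DesignBuilder":
        if "cg" not in records.columns:
            raise DataError("records lack CG labels; run build_contemporary_groups")
        if "sex" in self.fixed_terms:
            self.sex_levels = sorted(records["sex"].unique())
        if "mgmt" in self.fixed_terms:
            self.mgmt_levels = sorted(records["mgmt"].unique())
        for cov in ("dam_age", "age"):
            if cov in self.fixed_terms:
                self.centers[cov] = float(records[cov].mean())
        self.cg_levels = sorted(records["cg"].unique())
        self.fitted = True
        return self

    @property
    def x_names(self) -> list[str]:
        names = ["intercept"]
        names += [f"sex_{s}" for s in self.sex_levels[1:]]
        if "dam_age" in self.fixed_terms:
            names.append("dam_age")
        names += [f"mgmt_{m}" for m in self.mgmt_levels[1:]]
        if "age" in self.fixed_terms:
            names.append("age")
        return names

    def transform(self, records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """(X, Z₁) for any records using the training coding."""
        if not self.fitted:
            raise DataError("DesignBuilder.transform called before fit")
        n = len(records)
        cols = [np.ones(n)]
        for level in self.sex_levels[1:]:
            cols.append((records["sex"] == level).to_numpy(dtype=float))
        if "dam_age" in self.fixed_terms:
            cols.append(records["dam_age"].to_numpy(dtype=float) - self.centers["dam_age"])
        for level in self.mgmt_levels[1:]:
            cols.append((records["mgmt"] == level).to_numpy(dtype=float))
        if "age" in self.fixed_terms:
            cols.append(records["age"].to_numpy(dtype=float) - self.centers["age"])
        x = np.column_stack(cols)

        z1 = np.zeros((n, len(self.cg_levels)))
        level_pos = {g: j for j, g in enumerate(self.cg_levels)}
        unseen = set()
        for i, g in enumerate(records["cg"]):
            j = level_pos.get(g)
            if j is None:
                unseen.add(g)
            else:
                z1[i, j] = 1.0
        if unseen:
            logger.warning(
                "%d record(s) in CGs unseen during training (effect taken as 0): %s",
                sum(g in unseen for g in records["cg"]),
                sorted(unseen)[:5],
            )
        return x, z1


@dataclass
class Design:
    """Response and incidence matrices for one fit."""

    y: np.ndarray
    X: np.ndarray
    Z1: np.ndarray
    Z2: np.ndarray  # dense record × Δ-animal incidence, one 1 per row
    delta_ids: np.ndarray
    builder: DesignBuilder
    animals: np.ndarray  # record animal ids


def build_design(
    records: pd.DataFrame,
    spec: ModelSpec,
    delta_ids,
    builder: DesignBuilder | None = None,
) -> Design:
    """Assemble (y, X, Z₁, Z₂) for the given records and method.

    Z₂ maps each record to its animal's position in the Δ id set: all
    pedigree animals for BLUP/ssGBLUP, genotyped animals only for GBLUP
    (a phenotyped but ungenotyped animal under GBLUP is an error).
    """
    delta_ids = np.asarray(delta_ids)
    pos = {int(a): j for j, a in enumerate(delta_ids)}
    animals = records["animal"].to_numpy(dtype=np.int64)
    missing = [int(a) for a in animals if int(a) not in pos]
    if missing:
        raise DataError(
            f"{len(missing)} record animal(s) absent from the {spec.method} "
            f"animal set, e.g. {missing[:5]}"
        )
    if builder is None:
        builder = DesignBuilder(spec.fixed_terms).fit(records)
    x, z1 = builder.transform(records)
    n = len(records)
    z2 = np.zeros((n, len(delta_ids)))
    for i, a in enumerate(animals):
        z2[i, pos[int(a)]] = 1.0
    y = records["value"].to_numpy(dtype=float)
    return Design(
        y=y, X=x, Z1=z1, Z2=z2, delta_ids=delta_ids, builder=builder, animals=animals
    )


# ---------------------------------------------------------------------- #
# posterior container
# ---------------------------------------------------------------------- #
@dataclass
class PosteriorFit:
    """MCMC summaries of one animal-model fit.

    ``var_samples`` holds the stored (σ²ₐ, σ²_cg, σ²ₑ) draws; the reported
    "SE" of each variance component is its posterior standard deviation.
    """

    var_samples: np.ndarray  # (S, 3): additive, cg, residual
    beta_samples: np.ndarray  # (S, p)
    beta_names: list[str]
    cg_mean: pd.Series
    cg_sd: pd.Series
    ebv: pd.Series  # posterior-mean breeding values, all Δ animals
    h2_samples: np.ndarray
    design: Design | None = None

    @property
    def n_samples(self) -> int:
        return self.var_samples.shape[0]

    @property
    def var_mean(self) -> dict[str, float]:
        m = self.var_samples.mean(axis=0)
        return {"sigma_a": float(m[0]), "sigma_cg": float(m[1]), "sigma_e": float(m[2])}

    @property
    def var_sd(self) -> dict[str, float]:
        s = self.var_samples.std(axis=0, ddof=1)
        return {"sigma_a": float(s[0]), "sigma_cg": float(s[1]), "sigma_e": float(s[2])}

    @property
    def beta_mean(self) -> pd.Series:
        return pd.Series(self.beta_samples.mean(axis=0), index=self.beta_names)


# ---------------------------------------------------------------------- #
# the sampler
# ---------------------------------------------------------------------- #
def fit_gibbs(
    y: np.ndarray,
    X: np.ndarray,
    Z1: np.ndarray,
    Z2: np.ndarray,
    delta: np.ndarray,
    mcmc: McmcConfig,
    priors: Priors | None = None,
    delta_ids=None,
) -> PosteriorFit:
    """Run the conjugate Gibbs sampler; deterministic given ``mcmc.seed``.

    Parameters are the model matrices of y = Xβ + Z₁c + Z₂a + e plus the
    genetic covariance Δ (dense, over the animals indexed by Z₂'s
    columns).  ``X`` and ``Z1`` may have zero columns.
    """
    priors = priors or Priors()
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z1 = np.atleast_2d(np.asarray(Z1, dtype=float))
    delta = np.asarray(delta, dtype=float)
    n = len(y)
    if X.shape[0] != n or Z1.shape[0] != n or Z2.shape[0] != n:
        raise DataError("design matrices not conformable with y")
    m = delta.shape[0]
    if delta.shape != (m, m) or Z2.shape[1] != m:
        raise DataError("Δ not conformable with Z₂")
    p, k = X.shape[1], Z1.shape[1]

    rec = np.asarray(Z2).argmax(axis=1)
    row_ok = (np.abs(np.asarray(Z2).sum(axis=1) - 1.0) < 1e-12) & (
        np.abs(np.asarray(Z2)[np.arange(n), rec] - 1.0) < 1e-12
    )
    if not row_ok.all():
        raise DataError("Z₂ must have exactly one unit entry per record")
    if len(np.unique(rec)) != n:
        raise DataError(
            "repeated records per animal are not supported by this sampler"
        )

    # one-time spectral setup of K = Δ[rec, rec]
    K = delta[np.ix_(rec, rec)]
    lam, U = scipy.linalg.eigh(K)
    tol = max(lam.max(), 0.0) * 1e-10 + 1e-12
    pos = lam > tol
    if not pos.any():
        raise NumericalError("genetic covariance of recorded animals is zero")
    n_pos = int(pos.sum())
    lam_pos = lam[pos]

    yt = U.T @ y
    Xt = U.T @ X if p else X
    Z1t = U.T @ Z1 if k else Z1
    nk = Z1.sum(axis=0)  # records per CG level

    if p:
        xtx = X.T @ X
        try:
            L = scipy.linalg.cholesky(xtx, lower=True)
        except scipy.linalg.LinAlgError as exc:
            raise DataError(f"fixed-effect design is rank deficient: {exc}") from exc

    var_y = float(np.var(y, ddof=1)) if n > 1 else float(max(y[0] ** 2, 1.0))
    s_a, s_cg, s_e = priors.scales(var_y)
    nu = priors.df
    fix_a, fix_cg, fix_e = priors.fixed_variances

    def _mode(scale: float) -> float:
        return nu * scale / (nu + 2.0)

    sa2 = fix_a if fix_a is not None else _mode(s_a)
    scg2 = fix_cg if fix_cg is not None else _mode(s_cg)
    se2 = fix_e if fix_e is not None else _mode(s_e)
    if se2 <= 0:
        raise ConfigError("residual variance must be positive")

    rng = np.random.default_rng(mcmc.seed)
    beta = np.zeros(p)
    c = np.zeros(k)
    d = np.zeros(n)

    n_store = mcmc.n_samples
    var_samples = np.empty((n_store, 3))
    beta_samples = np.empty((n_store, p))
    c_sum = np.zeros(k)
    c_sq = np.zeros(k)
    d_sum = np.zeros(n)
    store = 0

    for it in range(mcmc.burn_in + mcmc.n_iterations):
        # fixed effects (flat prior)
        if p:
            r = yt - d
            if k:
                r = r - Z1t @ c
            mean = scipy.linalg.cho_solve((L, True), Xt.T @ r)
            z = rng.standard_normal(p)
            beta = mean + np.sqrt(se2) * scipy.linalg.solve_triangular(
                L, z, lower=True, trans="T"
            )
        # contemporary groups
        if k:
            if scg2 > 0:
                r = yt - d
                if p:
                    r = r - Xt @ beta
                prec = nk / se2 + 1.0 / scg2
                c = (Z1t.T @ r) / se2 / prec + rng.standard_normal(k) / np.sqrt(prec)
            else:
                c = np.zeros(k)
        # genetic coordinates
        r = yt.copy()
        if p:
            r -= Xt @ beta
        if k:
            r -= Z1t @ c
        if sa2 > 0:
            prec = 1.0 / se2 + 1.0 / (lam_pos * sa2)
            d_pos = (r[pos] / se2) / prec + rng.standard_normal(n_pos) / np.sqrt(prec)
            d = np.zeros(n)
            d[pos] = d_pos
        else:
            d = np.zeros(n)
        # variances
        if fix_a is None:
            ss = float(np.sum(d[pos] ** 2 / lam_pos)) if sa2 > 0 else 0.0
            sa2 = (ss + nu * s_a) / rng.chisquare(n_pos + nu)
        if fix_cg is None and k:
            scg2 = (float(c @ c) + nu * s_cg) / rng.chisquare(k + nu)
        resid = r - d
        if fix_e is None:
            se2 = (float(resid @ resid) + nu * s_e) / rng.chisquare(n + nu)
        if not np.isfinite(se2) or se2 <= 0:
            raise NumericalError(f"non-finite residual variance at iteration {it}")

        post = it - mcmc.burn_in
        if post >= 0 and (post + 1) % mcmc.thin == 0:
            var_samples[store] = (sa2, scg2, se2)
            beta_samples[store] = beta
            c_sum += c
            c_sq += c * c
            d_sum += d
            store += 1

    var_samples = var_samples[:store]
    beta_samples = beta_samples[:store]
    c_mean = c_sum / max(store, 1)
    c_var = np.maximum(c_sq / max(store, 1) - c_mean**2, 0.0)
    d_mean = d_sum / max(store, 1)

    # exact back-solve to breeding values of every Δ animal
    w = np.zeros(n)
    w[pos] = d_mean[pos] / lam_pos
    ebv_values = delta[:, rec] @ (U @ w)
    ids = np.asarray(delta_ids) if delta_ids is not None else np.arange(m)

    totals = var_samples.sum(axis=1)
    h2_samples = np.divide(
        var_samples[:, 0], totals, out=np.zeros(store), where=totals > 0
    )
    return PosteriorFit(
        var_samples=var_samples,
        beta_samples=beta_samples,
        beta_names=[f"b{j}" for j in range(p)],
        cg_mean=pd.Series(c_mean),
        cg_sd=pd.Series(np.sqrt(c_var)),
        ebv=pd.Series(ebv_values, index=ids),
        h2_samples=h2_samples,
    )


def fit_animal_model(
    design: Design,
    delta: RelationshipMatrix,
    spec: ModelSpec,
    mcmc: McmcConfig,
    priors: Priors | None = None,
) -> PosteriorFit:
    """Method-aware wrapper: checks the Δ kind, runs the sampler, labels
    the outputs with animal ids, CG labels and fixed-effect names."""
    if delta.kind not in METHOD_KINDS[spec.method]:
        raise ConfigError(
            f"{spec.method} requires Δ of kind {METHOD_KINDS[spec.method]}, "
            f"got {delta.kind}"
        )
    if not np.array_equal(np.asarray(design.delta_ids), np.asarray(delta.ids)):
        raise DataError("design Δ id set does not match the relationship matrix")
    fit = fit_gibbs(
        design.y,
        design.X,
        design.Z1,
        design.Z2,
        delta.values,
        mcmc,
        priors,
        delta_ids=delta.ids,
    )
    fit.beta_names = design.builder.x_names
    fit.cg_mean.index = design.builder.cg_levels
    fit.cg_sd.index = design.builder.cg_levels
    fit.design = design
    return fit


# ---------------------------------------------------------------------- #
# derived quantities
# ---------------------------------------------------------------------- #
def h2_from_components(sigma_a: float, sigma_cg: float, sigma_e: float) -> float:
    """Heritability σ²ₐ / (σ²ₐ + σ²_cg + σ²ₑ)."""
    total = sigma_a + sigma_cg + sigma_e
    if total <= 0:
        raise ZeroDivisionError("total phenotypic variance is zero")
    return sigma_a / total


def shares_from_components(
    sigma_a: float, sigma_cg: float, sigma_e: float
) -> dict[str, float]:
    """Percentage of phenotypic variance per component (sums to 100)."""
    total = sigma_a + sigma_cg + sigma_e
    if total <= 0:
        raise ZeroDivisionError("total phenotypic variance is zero")
    return {
        "sigma_a": 100.0 * sigma_a / total,
        "sigma_cg": 100.0 * sigma_cg / total,
        "sigma_e": 100.0 * sigma_e / total,
    }


def heritability(fit: PosteriorFit, per_sample: bool = False) -> float:
    """h² from posterior means (default) or the mean of per-sample h²."""
    if per_sample:
        return float(fit.h2_samples.mean())
    m = fit.var_mean
    return h2_from_components(m["sigma_a"], m["sigma_cg"], m["sigma_e"])


def variance_shares(fit: PosteriorFit) -> dict[str, float]:
    """Posterior-mean variance shares, in percent."""
    m = fit.var_mean
    return shares_from_components(m["sigma_a"], m["sigma_cg"], m["sigma_e"])
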