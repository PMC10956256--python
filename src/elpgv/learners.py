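"""Base genomic-prediction methods: GBLUP and the Bayesian alphabet.

All four learners fit the standard whole-genome linear model

    y = X alpha + Z beta + e,   e ~ N(0, sigma_e^2 I)

where ``Z`` holds additive marker codes (0/1/2 for biallelic SNPs, 0/1 for
dominant presence/absence markers) and ``X`` is an intercept plus optional
covariates.  GBLUP treats all marker-effect variances as equal and works on
the marker-derived kinship (genomic relationship) matrix; BayesA, BayesB and
BayesC-pi place heavier-tailed or spike-and-slab priors on the effects and
are fit by single-site Gibbs sampling (see :mod:`elpgv._gibbs`).

Held-out individuals are masked in the phenotype table; every learner returns
genetic values for *all* individuals, fitted for the training set and
predicted for the masked set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from . import _gibbs

__all__ = [
    "GenotypeMatrix",
    "PhenotypeTable",
    "ChainConfig",
    "LearnerFit",
    "build_grm",
    "fit_gblup",
    "fit_bayes",
    "fit_method",
    "BAYES_VARIANTS",
]

BAYES_VARIANTS = {"A": _gibbs.VARIANT_A, "B": _gibbs.VARIANT_B, "Cpi": _gibbs.VARIANT_CPI}


@dataclass
class GenotypeMatrix:
    """Individuals x markers additive genotype codes with identifiers."""

    individual_ids: np.ndarray
    marker_ids: np.ndarray
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.individual_ids = np.asarray(self.individual_ids)
        self.marker_ids = np.asarray(self.marker_ids)
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.ndim != 2:
            raise ValueError("codes must be individuals x markers")
        if self.codes.shape[0] != len(self.individual_ids):
            raise ValueError("id / row count mismatch")
        if self.codes.shape[1] != len(self.marker_ids):
            raise ValueError("marker id / column count mismatch")
        if len(set(self.individual_ids.tolist())) != len(self.individual_ids):
            raise ValueError("duplicate individual ids")
        if np.isnan(self.codes).any():
            raise ValueError(
                "genotype codes contain missing values; impute on load"
            )
        if self.codes.min() < 0 or self.codes.max() > 2:
            raise ValueError("additive codes must lie in [0, 2]")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]


@dataclass
class PhenotypeTable:
    """Trait values with optional covariates; masked records are held out."""

    individual_ids: np.ndarray
    values: np.ndarray
    covariates: np.ndarray | None = None   # n x c, without intercept
    mask: np.ndarray | None = None         # True = held out

    def __post_init__(self) -> None:
        self.individual_ids = np.asarray(self.individual_ids)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.individual_ids.tolist())) != len(self.individual_ids):
            raise ValueError("duplicate individual ids")
        if self.mask is None:
            self.mask = np.isnan(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if self.covariates is not None:
            self.covariates = np.asarray(self.covariates, dtype=float)
            if self.covariates.shape[0] != len(self.individual_ids):
                raise ValueError("covariate rows must match individuals")
        if np.isnan(self.values[~self.mask]).any():
            raise ValueError("unmasked phenotypes contain NaN")

    @property
    def train_index(self) -> np.ndarray:
        return np.flatnonzero(~self.mask)


@dataclass(frozen=True)
class ChainConfig:
    """MCMC settings for the Bayesian-alphabet samplers.

    ``r2`` fixes the prior scales: the marker-variance prior is chosen so the
    prior-expected genetic variance is ``r2`` times the phenotypic variance
    (split over the expected number of non-null markers), and the residual
    prior expects the remaining ``1 - r2`` share.
    """

    n_iter: int = 5000
    burn_in: int = 1000
    pi: float = 0.1            # fixed inclusion probability for BayesB
    df_marker: float = 5.0
    df_resid: float = 5.0
    r2: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter <= self.burn_in or self.burn_in < 0:
            raise ValueError("need n_iter > burn_in >= 0")
        if not 0.0 < self.pi <= 1.0:
            raise ValueError("pi must lie in (0, 1]")
        if self.df_marker <= 2 or self.df_resid <= 0:
            raise ValueError("degrees of freedom out of range")


@dataclass
class LearnerFit:
    """Result of fitting one base method."""

    method: str
    genetic_values: np.ndarray            # length n, all individuals
    predictions: np.ndarray               # fixed effects + genetic values
    fixed_effects: np.ndarray
    marker_effects: np.ndarray | None = None
    variance_components: dict = field(default_factory=dict)
    chain: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# GBLUP


def build_grm(genotypes: GenotypeMatrix) -> np.ndarray:
    """Genomic relationship matrix, VanRaden method 1.

    Columns are centered by twice the allele frequency (half the mean code)
    and the cross-product is scaled by ``2 * sum p_k (1 - p_k)``.  For 0/1/2
    SNP codes the average diagonal is close to 1; other codings only change
    the overall scale, which REML absorbs.
    """
    Z = genotypes.codes
    if Z.shape[0] < 2:
        raise ValueError("kinship needs at least 2 individuals")
    if not np.any(Z.var(axis=0) > 0):
        raise ValueError("all markers are monomorphic; kinship undefined")
    p = Z.mean(axis=0) / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    Zc = Z - 2.0 * p
    return (Zc @ Zc.T) / denom


def _design(phenotypes: PhenotypeTable, n: int) -> np.ndarray:
    X = np.ones((n, 1))
    if phenotypes.covariates is not None and phenotypes.covariates.size:
        X = np.hstack([X, phenotypes.covariates])
    return X


def fit_gblup(
    kinship: np.ndarray,
    phenotypes: PhenotypeTable,
    jitter: float = 1e-6,
) -> LearnerFit:
    """GBLUP with REML variance components via eigendecomposition.

    The restricted likelihood is profiled over ``lambda = sigma_e^2 /
    sigma_g^2`` on the eigenbasis of the training-block kinship; masked
    individuals are predicted through their kinship with the training set
    (the conditional mean of the joint normal).
    """
    K = np.asarray(kinship, dtype=float)
    tr = phenotypes.train_index
    if tr.size < 3:
        raise ValueError("need at least 3 training individuals")
    n_all = K.shape[0]
    y = phenotypes.values[tr]
    X_all = _design(phenotypes, n_all)
    X = X_all[tr]

    K_tr = K[np.ix_(tr, tr)].copy()
    w_min = np.linalg.eigvalsh(K_tr)[0]
    if w_min < 1e-8:
        K_tr[np.diag_indices_from(K_tr)] += jitter
    s, U = np.linalg.eigh(K_tr)
    yt = U.T @ y
    Xt = U.T @ X
    n, c = X.shape
    _, logdet_xx = np.linalg.slogdet(X.T @ X)

    def neg_reml(log_lam: float) -> float:
        lam = 10.0 ** log_lam
        d = s + lam
        Xd = Xt / d[:, None]
        XtHX = Xt.T @ Xd
        try:
            beta = np.linalg.solve(XtHX, Xd.T @ yt)
        except np.linalg.LinAlgError:
            return np.inf
        resid = yt - Xt @ beta
        ypy = float(resid @ (resid / d))
        if ypy <= 0:
            return np.inf
        _, logdet_xhx = np.linalg.slogdet(XtHX)
        ll = -0.5 * (
            (n - c) * np.log(2.0 * np.pi * ypy / (n - c))
            + (n - c)
            + np.sum(np.log(d))
            + logdet_xhx
            - logdet_xx
        )
        return -ll

    grid = np.linspace(-5.0, 5.0, 41)
    vals = np.array([neg_reml(g) for g in grid])
    g0 = grid[int(np.argmin(vals))]
    res = minimize_scalar(
        neg_reml, bounds=(g0 - 0.5, g0 + 0.5), method="bounded",
        options={"xatol": 1e-6},
    )
    if not np.isfinite(res.fun):
        raise RuntimeError("REML optimization failed to find a finite optimum")
    lam = 10.0 ** float(res.x)

    d = s + lam
    Xd = Xt / d[:, None]
    XtHX = Xt.T @ Xd
    beta = np.linalg.solve(XtHX, Xd.T @ yt)
    resid = yt - Xt @ beta
    sigma_g = float(resid @ (resid / d)) / (n - c)
    sigma_e = lam * sigma_g

    # BLUP of genetic values: g = K[:, train] (K_tr + lam I)^{-1} (y - X beta)
    alpha = U @ (resid / d)
    g_all = K[:, tr] @ alpha
    predictions = X_all @ beta + g_all
    return LearnerFit(
        method="GBLUP",
        genetic_values=g_all,
        predictions=predictions,
        fixed_effects=beta,
        variance_components={
            "sigma_g2": sigma_g,
            "sigma_e2": sigma_e,
            "lambda": lam,
            "reml_loglik": -float(res.fun),
        },
    )


# ---------------------------------------------------------------------------
# Bayesian alphabet


def _prior_scales(y: np.ndarray, Z: np.ndarray, chain: ChainConfig, pi_frac: float):
    """Scale hyperparameters so the prior-expected genetic / residual variance
    split matches ``chain.r2``."""
    vy = float(np.var(y))
    if vy <= 0:
        vy = 1.0
    msx = float(np.sum(np.var(Z, axis=0)))
    if msx <= 0:
        msx = 1.0
    nu_b, nu_e = chain.df_marker, chain.df_resid
    e_var_marker = chain.r2 * vy / (msx * pi_frac)
    s_b = e_var_marker * (nu_b - 2.0) / nu_b
    s_e = (1.0 - chain.r2) * vy * max(nu_e - 2.0, 1.0) / nu_e
    return s_b, s_e


def fit_bayes(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    variant: str = "A",
    chain: ChainConfig | None = None,
) -> LearnerFit:
    """Fit BayesA / BayesB / BayesC-pi by single-site Gibbs sampling.

    Returns posterior-mean marker effects and the implied genetic values for
    every individual (``Z @ beta_mean``); masked individuals are predicted by
    the same linear rule.  ``variant`` is one of ``"A"``, ``"B"``, ``"Cpi"``.
    """
    if chain is None:
        chain = ChainConfig()
    if variant not in BAYES_VARIANTS:
        raise ValueError(f"unknown Bayes variant {variant!r}")
    code = BAYES_VARIANTS[variant]

    tr = phenotypes.train_index
    if tr.size < 3:
        raise ValueError("need at least 3 training individuals")
    y = phenotypes.values[tr]
    X_all = _design(phenotypes, genotypes.n_individuals)[:, 1:]  # kernel adds mu
    Z_tr = np.asfortranarray(genotypes.codes[tr])
    X_tr = np.asfortranarray(X_all[tr]) if X_all.size else np.zeros((tr.size, 0), order="F")

    if variant == "A":
        pi0, update_pi, pi_frac = 1.0, False, 1.0
    elif variant == "B":
        pi0, update_pi, pi_frac = chain.pi, False, chain.pi
    else:  # Cpi: uniform prior on pi, start at 0.5
        pi0, update_pi, pi_frac = 0.5, True, 0.5

    s_b, s_e = _prior_scales(y, Z_tr, chain, pi_frac)
    beta, alpha, mu, pi_post, sigma_e = _gibbs.gibbs_chain(
        Z_tr,
        np.ascontiguousarray(y),
        X_tr,
        chain.n_iter,
        chain.burn_in,
        code,
        pi0,
        update_pi,
        chain.df_marker,
        s_b,
        chain.df_resid,
        s_e,
        chain.seed,
    )
    g_all = genotypes.codes @ beta
    predictions = mu + g_all
    if X_all.size:
        predictions = predictions + X_all @ alpha
    fit = LearnerFit(
        method=f"Bayes{variant}" if variant != "Cpi" else "BayesCpi",
        genetic_values=g_all,
        predictions=predictions,
        fixed_effects=np.concatenate([[mu], alpha]),
        marker_effects=beta,
        variance_components={"sigma_e2": float(sigma_e)},
        chain={
            "n_iter": chain.n_iter,
            "burn_in": chain.burn_in,
            "seed": chain.seed,
        },
    )
    if variant == "Cpi":
        fit.chain["pi_posterior_mean"] = float(pi_post)
    elif variant == "B":
        fit.chain["pi"] = chain.pi
    return fit


def fit_method(
    method: str,
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    chain: ChainConfig | None = None,
    kinship: np.ndarray | None = None,
) -> LearnerFit:
    """Dispatch by method name: GBLUP, BayesA, BayesB or BayesCpi."""
    name = method.lower()
    if name == "gblup":
        if kinship is None:
            kinship = build_grm(genotypes)
        return fit_gblup(kinship, phenotypes)
    for key in BAYES_VARIANTS:
        if name == f"bayes{key}".lower():
            return fit_bayes(genotypes, phenotypes, variant=key, chain=chain)
    raise ValueError(f"unknown method {method!r}")
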