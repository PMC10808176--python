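"""Genomic prediction models: G-BLUP, EG-BLUP, Bayes A, Bayesian Lasso.

G-BLUP treats genetic values as draws from N(0, G sigma_g^2) with G the
VanRaden additive relationship matrix; variance components are estimated
by REML with the likelihood profiled over the genetic-to-residual
variance ratio on the eigenbasis of the training kernel.  EG-BLUP adds an
additive-by-additive term with covariance H = G∘G and a second variance
ratio (derivative-free 2-D REML).  Bayes A and the Bayesian Lasso are
whole-genome marker regressions fitted by Gibbs sampling (numba-compiled
kernels) with scaled-t and double-exponential effect priors respectively;
prior scales follow the usual heuristic of splitting the phenotypic
variance by an a-priori R².

All fits expose genetic values for every accession present in the
kinship/marker space, so unphenotyped accessions are predicted by the
same conditional-expectation step used in cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize, minimize_scalar

from .curation import TraitBLUEs
from .genomics import GenotypeMatrix, KinshipMatrix

__all__ = [
    "ModelSpec",
    "FittedModel",
    "fit_gblup",
    "fit_egblup",
    "fit_bayes_a",
    "fit_bayesian_lasso",
    "predict",
]

_LOG_RATIO_BOUNDS = (-12.0, 12.0)


@dataclass
class ModelSpec:
    """Choice of prediction model plus sampler settings for Bayesian fits."""

    model: str = "gblup"  # gblup | egblup | bayes_a | bayesian_lasso
    chain_length: int = 12000
    burn_in: int = 2000
    thin: int = 5
    prior_df: float = 5.0
    prior_r2: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("gblup", "egblup", "bayes_a", "bayesian_lasso"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.burn_in >= self.chain_length:
            raise ValueError("burn_in must be smaller than chain_length")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.prior_df <= 2:
            raise ValueError("prior_df must exceed 2 for a finite prior variance")

    def with_seed(self, seed: int) -> "ModelSpec":
        return replace(self, seed=int(seed) % (2**31 - 1))


@dataclass
class FittedModel:
    model: str
    mu_hat: float
    genetic_values: pd.Series  # total genetic value per accession (deviation from mu)
    variance_components: dict[str, float]
    marker_effect_means: pd.Series | None = None
    epistatic_values: pd.Series | None = None
    convergence_diagnostics: dict = field(default_factory=dict)
    training_accessions: list[str] = field(default_factory=list)


def _training_view(blues: TraitBLUEs, labels: list[str]) -> tuple[list[str], np.ndarray]:
    have = set(blues.estimates.index)
    train = [a for a in labels if a in have]
    if len(train) < 3:
        raise ValueError("need at least 3 phenotyped accessions in the genomic space")
    y = blues.estimates.loc[train].to_numpy(dtype=float)
    if np.var(y) == 0:
        raise ValueError("phenotypes are constant; variance components undefined")
    return train, y


def fit_gblup(blues: TraitBLUEs, G: KinshipMatrix) -> FittedModel:
    """REML + BLUP under y = 1 mu + g + e with g ~ N(0, G sigma_g^2).

    The restricted likelihood is profiled over kappa = sigma_g^2/sigma_e^2
    on the eigenbasis of the training block of G (1-D bounded search), and
    genetic values for all accessions follow from the BLUP conditional
    expectation.
    """
    train, y = _training_view(blues, G.labels)
    g_tt = G.block(train, train)
    lam, q = np.linalg.eigh(g_tt)
    if lam.min() < -1e-6 * max(abs(lam.max()), 1.0):
        raise ValueError(f"G is not PSD on the training set (min eigenvalue {lam.min():.3g})")
    lam = np.maximum(lam, 0.0)
    n = len(y)
    yt = q.T @ y
    xt = q.T @ np.ones(n)

    def neg_ll(log_kappa: float) -> float:
        kappa = np.exp(log_kappa)
        d = kappa * lam + 1.0
        xtd = np.sum(xt**2 / d)
        mu = np.sum(xt * yt / d) / xtd
        r = yt - xt * mu
        s2 = np.sum(r**2 / d) / (n - 1)
        return 0.5 * (
            (n - 1) * (np.log(s2) + 1.0 + np.log(2.0 * np.pi))
            + np.sum(np.log(d))
            + np.log(xtd)
        )

    res = minimize_scalar(neg_ll, bounds=_LOG_RATIO_BOUNDS, method="bounded",
                          options={"xatol": 1e-8})
    kappa = float(np.exp(res.x))
    d = kappa * lam + 1.0
    xtd = np.sum(xt**2 / d)
    mu = float(np.sum(xt * yt / d) / xtd)
    r = yt - xt * mu
    sigma_e2 = float(np.sum(r**2 / d) / (n - 1))
    sigma_g2 = kappa * sigma_e2

    # ghat_all = sigma_g2 * G[all, train] V^-1 (y - mu), V = sigma_g2 G_tt + sigma_e2 I
    vinv_r = q @ (r / (sigma_g2 * lam + sigma_e2))
    g_all = sigma_g2 * G.block(G.labels, train) @ vinv_r
    return FittedModel(
        model="gblup",
        mu_hat=mu,
        genetic_values=pd.Series(g_all, index=G.labels),
        variance_components={"sigma_g2": sigma_g2, "sigma_e2": sigma_e2},
        convergence_diagnostics={"neg_restricted_ll": float(res.fun), "success": True},
        training_accessions=train,
    )


def fit_egblup(
    blues: TraitBLUEs,
    G: KinshipMatrix,
    H: KinshipMatrix,
    fix_sigma_g1: float | None = None,
) -> FittedModel:
    """Two-kernel REML + BLUP: y = 1 mu + g + g1 + e, g1 ~ N(0, H sigma_g1^2).

    The restricted likelihood is maximized over the two log variance
    ratios by Nelder-Mead with three starts.  ``fix_sigma_g1=0`` reduces
    exactly to the G-BLUP fit (same code path).
    """
    if list(G.labels) != list(H.labels):
        raise ValueError("G and H must carry identical accession labels")
    if fix_sigma_g1 == 0.0:
        base = fit_gblup(blues, G)
        base.model = "egblup"
        base.variance_components["sigma_g1_2"] = 0.0
        base.epistatic_values = pd.Series(0.0, index=G.labels)
        return base

    train, y = _training_view(blues, G.labels)
    g_tt = G.block(train, train)
    h_tt = H.block(train, train)
    n = len(y)
    ones = np.ones(n)

    def neg_ll(x: np.ndarray) -> float:
        k1, k2 = np.exp(x)
        m = np.eye(n) + k1 * g_tt + k2 * h_tt
        try:
            cf = cho_factor(m, lower=True)
        except np.linalg.LinAlgError:
            return 1e12
        minv_y = cho_solve(cf, y)
        minv_1 = cho_solve(cf, ones)
        xtd = float(ones @ minv_1)
        mu = float(ones @ minv_y) / xtd
        r = y - mu
        quad = float(r @ cho_solve(cf, r))
        s2 = quad / (n - 1)
        log_det = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        return 0.5 * (
            (n - 1) * (np.log(s2) + 1.0 + np.log(2.0 * np.pi)) + log_det + np.log(xtd)
        )

    if fix_sigma_g1 is not None:
        raise NotImplementedError("only fix_sigma_g1=0 (the G-BLUP nesting) is supported")

    starts = [np.array(s) for s in ((0.0, -0.7), (0.0, -3.0), (-3.0, 0.0))]
    best = None
    for x0 in starts:
        res = minimize(
            neg_ll, x0, method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 400},
        )
        if best is None or res.fun < best.fun:
            best = res
    k1, k2 = np.exp(np.clip(best.x, *_LOG_RATIO_BOUNDS))
    m = np.eye(n) + k1 * g_tt + k2 * h_tt
    cf = cho_factor(m, lower=True)
    minv_1 = cho_solve(cf, ones)
    mu = float(ones @ cho_solve(cf, y)) / float(ones @ minv_1)
    r = y - mu
    sigma_e2 = float(r @ cho_solve(cf, r)) / (n - 1)
    sigma_g2 = k1 * sigma_e2
    sigma_g1_2 = k2 * sigma_e2

    vinv_r = cho_solve(cf, r) / sigma_e2
    g_add = sigma_g2 * G.block(G.labels, train) @ vinv_r
    g_epi = sigma_g1_2 * H.block(H.labels, train) @ vinv_r
    return FittedModel(
        model="egblup",
        mu_hat=mu,
        genetic_values=pd.Series(g_add + g_epi, index=G.labels),
        epistatic_values=pd.Series(g_epi, index=G.labels),
        variance_components={
            "sigma_g2": sigma_g2,
            "sigma_g1_2": sigma_g1_2,
            "sigma_e2": sigma_e2,
        },
        convergence_diagnostics={
            "neg_restricted_ll": float(best.fun),
            "success": bool(best.success),
        },
        training_accessions=train,
    )


@njit(cache=False)
def _chi2(df: float) -> float:
    return 2.0 * np.random.gamma(df / 2.0, 1.0)


@njit(cache=False)
def _rinvgauss(mu: float, lam: float) -> float:
    # Michael-Schucany-Haas
    v = np.random.normal() ** 2
    x = mu + (mu * mu * v) / (2.0 * lam) - (mu / (2.0 * lam)) * np.sqrt(
        4.0 * mu * lam * v + mu * mu * v * v
    )
    if x <= 0.0:
        x = 1e-12
    if np.random.random() <= mu / (mu + x):
        return x
    return mu * mu / x


@njit(cache=False)
def _gibbs_bayes_a(Z, y, n_iter, burn, thin, nu, S, nue, Se, seed):
    np.random.seed(seed)
    n, m = Z.shape
    ck = np.empty(m)
    for k in range(m):
        ck[k] = np.dot(Z[:, k], Z[:, k])
    beta = np.zeros(m)
    var_k = np.full(m, S)
    mu = np.mean(y)
    sigma_e2 = np.var(y) / 2.0
    r = y - mu  # residual with beta = 0

    beta_sum = np.zeros(m)
    mu_sum = 0.0
    se_sum = 0.0
    se_sq_sum = 0.0
    n_samp = 0
    for it in range(n_iter):
        # intercept
        r += mu
        mu = np.mean(r) + np.random.normal() * np.sqrt(sigma_e2 / n)
        r -= mu
        # marker effects with marker-specific variances
        for k in range(m):
            if ck[k] == 0.0:
                beta[k] = 0.0
                continue
            b_old = beta[k]
            rhs = np.dot(Z[:, k], r) + ck[k] * b_old
            cinv = 1.0 / (ck[k] + sigma_e2 / var_k[k])
            b_new = rhs * cinv + np.random.normal() * np.sqrt(sigma_e2 * cinv)
            r += Z[:, k] * (b_old - b_new)
            beta[k] = b_new
            var_k[k] = (nu * S + b_new * b_new) / _chi2(nu + 1.0)
        sigma_e2 = (np.dot(r, r) + nue * Se) / _chi2(n + nue)
        if it >= burn and (it - burn) % thin == 0:
            beta_sum += beta
            mu_sum += mu
            se_sum += sigma_e2
            se_sq_sum += sigma_e2 * sigma_e2
            n_samp += 1
    return beta_sum / n_samp, mu_sum / n_samp, se_sum / n_samp, se_sq_sum / n_samp, n_samp


@njit(cache=False)
def _gibbs_bl(Z, y, n_iter, burn, thin, nue, Se, lam2_init, lam2_shape, lam2_rate, fix_lambda, seed):
    np.random.seed(seed)
    n, m = Z.shape
    ck = np.empty(m)
    for k in range(m):
        ck[k] = np.dot(Z[:, k], Z[:, k])
    beta = np.zeros(m)
    tau2 = np.ones(m)
    lam2 = lam2_init
    mu = np.mean(y)
    sigma_e2 = np.var(y) / 2.0
    r = y - mu

    beta_sum = np.zeros(m)
    mu_sum = 0.0
    se_sum = 0.0
    se_sq_sum = 0.0
    lam2_sum = 0.0
    n_samp = 0
    for it in range(n_iter):
        r += mu
        mu = np.mean(r) + np.random.normal() * np.sqrt(sigma_e2 / n)
        r -= mu
        for k in range(m):
            if ck[k] == 0.0:
                beta[k] = 0.0
                continue
            b_old = beta[k]
            rhs = np.dot(Z[:, k], r) + ck[k] * b_old
            cinv = 1.0 / (ck[k] + 1.0 / tau2[k])
            b_new = rhs * cinv + np.random.normal() * np.sqrt(sigma_e2 * cinv)
            r += Z[:, k] * (b_old - b_new)
            beta[k] = b_new
            # 1/tau_k^2 ~ InvGauss(sqrt(lam2 sigma_e2 / beta^2), lam2)
            b2 = b_new * b_new
            if b2 < 1e-12 * sigma_e2:
                b2 = 1e-12 * sigma_e2
            mu_ig = np.sqrt(lam2 * sigma_e2 / b2)
            if mu_ig > 1e8:
                mu_ig = 1e8
            inv_tau2 = _rinvgauss(mu_ig, lam2)
            tau2[k] = 1.0 / inv_tau2
        if fix_lambda == 0:
            lam2 = np.random.gamma(m + lam2_shape, 1.0 / (np.sum(tau2) / 2.0 + lam2_rate))
        ss_beta = 0.0
        for k in range(m):
            ss_beta += beta[k] * beta[k] / tau2[k]
        sigma_e2 = (np.dot(r, r) + ss_beta + nue * Se) / _chi2(n + m + nue)
        if it >= burn and (it - burn) % thin == 0:
            beta_sum += beta
            mu_sum += mu
            se_sum += sigma_e2
            se_sq_sum += sigma_e2 * sigma_e2
            lam2_sum += lam2
            n_samp += 1
    return (
        beta_sum / n_samp,
        mu_sum / n_samp,
        se_sum / n_samp,
        se_sq_sum / n_samp,
        lam2_sum / n_samp,
        n_samp,
    )


def _centered_markers(markers: GenotypeMatrix) -> np.ndarray:
    if not markers.is_imputed:
        raise ValueError("marker matrix must be imputed")
    p = markers.allele_freqs
    if p is None:
        p = markers.codes.mean(axis=0) / 2.0
    return markers.codes - 2.0 * p


def _marker_fit_common(
    blues: TraitBLUEs, markers: GenotypeMatrix
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    zc_all = _centered_markers(markers)
    train, y = _training_view(blues, markers.accession_ids)
    pos = {a: i for i, a in enumerate(markers.accession_ids)}
    z_train = zc_all[[pos[a] for a in train]]
    return train, y, z_train, zc_all


def fit_bayes_a(
    blues: TraitBLUEs, markers: GenotypeMatrix, spec: ModelSpec | None = None
) -> FittedModel:
    """Bayes A: marker effects with marker-specific scaled-inv-chi2 variances.

    Prior scales are set from the sample phenotypic variance: the residual
    scale targets (1 - prior_r2) * var(y) and the common marker-variance
    scale S targets prior_r2 * var(y) spread over the realized marker
    variance sum.
    """
    spec = spec or ModelSpec(model="bayes_a")
    train, y, z, zc_all = _marker_fit_common(blues, markers)
    n = len(y)
    var_y = float(np.var(y, ddof=1))
    nu = float(spec.prior_df)
    nue = 5.0
    se_scale = var_y * (1.0 - spec.prior_r2) * (nue - 2.0) / nue
    msx = float(np.sum(z**2)) / n
    s_marker = spec.prior_r2 * var_y * (nu - 2.0) / (nu * max(msx, 1e-12))

    beta, mu, se_mean, se_sq, n_samp = _gibbs_bayes_a(
        np.asfortranarray(z), y, spec.chain_length, spec.burn_in, spec.thin,
        nu, s_marker, nue, se_scale, spec.seed % (2**31 - 1),
    )
    g_all = zc_all @ beta
    se_sd = float(np.sqrt(max(se_sq - se_mean**2, 0.0)))
    return FittedModel(
        model="bayes_a",
        mu_hat=float(mu),
        genetic_values=pd.Series(g_all, index=markers.accession_ids),
        variance_components={
            "sigma_e2": float(se_mean),
            "sigma_g2": float(np.var(g_all[[markers.accession_ids.index(a) for a in train]], ddof=1)),
        },
        marker_effect_means=pd.Series(beta, index=markers.marker_ids),
        convergence_diagnostics={
            "n_samples": int(n_samp),
            "sigma_e2_posterior_sd": se_sd,
        },
        training_accessions=train,
    )


def fit_bayesian_lasso(
    blues: TraitBLUEs,
    markers: GenotypeMatrix,
    spec: ModelSpec | None = None,
    fix_lambda: float | None = None,
) -> FittedModel:
    """Bayesian Lasso (Park-Casella hierarchy) via Gibbs sampling.

    Marker effects get a double-exponential prior through exponential
    mixing variances; the squared regularization parameter carries a gamma
    hyperprior unless ``fix_lambda`` pins it.
    """
    spec = spec or ModelSpec(model="bayesian_lasso")
    train, y, z, zc_all = _marker_fit_common(blues, markers)
    var_y = float(np.var(y, ddof=1))
    n = len(y)
    nue = 5.0
    se_scale = var_y * (1.0 - spec.prior_r2) * (nue - 2.0) / nue
    # center the lambda^2 hyperprior so the implied marker variance
    # (2 sigma_e2 / lambda^2 per effect) spreads prior_r2 * var(y) over the
    # realized marker variance sum; weak gamma(1.1) around that mode
    msx = float(np.sum(z**2)) / n
    lam2_mode = max(2.0 * (1.0 - spec.prior_r2) / spec.prior_r2 * msx, 1e-8)
    lam2_shape = 1.1
    lam2_rate = (lam2_shape - 1.0) / lam2_mode
    if fix_lambda is not None:
        lam2_init, fixed = float(fix_lambda) ** 2, 1
        if lam2_init <= 0:
            lam2_init = 1e-8
    else:
        lam2_init, fixed = lam2_mode, 0

    beta, mu, se_mean, se_sq, lam2_mean, n_samp = _gibbs_bl(
        np.asfortranarray(z), y, spec.chain_length, spec.burn_in, spec.thin,
        nue, se_scale, lam2_init, lam2_shape, lam2_rate, fixed,
        spec.seed % (2**31 - 1),
    )
    g_all = zc_all @ beta
    return FittedModel(
        model="bayesian_lasso",
        mu_hat=float(mu),
        genetic_values=pd.Series(g_all, index=markers.accession_ids),
        variance_components={
            "sigma_e2": float(se_mean),
            "sigma_g2": float(np.var(g_all[[markers.accession_ids.index(a) for a in train]], ddof=1)),
            "lambda2": float(lam2_mean),
        },
        marker_effect_means=pd.Series(beta, index=markers.marker_ids),
        convergence_diagnostics={
            "n_samples": int(n_samp),
            "sigma_e2_posterior_sd": float(np.sqrt(max(se_sq - se_mean**2, 0.0))),
        },
        training_accessions=train,
    )


def predict(model: FittedModel, target_accessions) -> pd.Series:
    """Predicted phenotype mu_hat + genetic value for the requested labels."""
    targets = list(target_accessions)
    missing = [a for a in targets if a not in model.genetic_values.index]
    if missing:
        raise KeyError(f"accessions absent from the fitted genomic space: {missing[:10]}")
    return model.mu_hat + model.genetic_values.loc[targets]
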