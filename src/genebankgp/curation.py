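"""Curation of unbalanced multi-year phenotype records.

The historical design has at most one measurement per accession and year,
strongly unequal year sizes and year-specific error variances.  Records
are first trimmed to a connected, replicated core (years without overlap
dropped, single-record accessions dropped, iterated to a fixed point).
The two-way model

    y_ij = mu + g_i + a_j + e_i(j),   Var(e_i(j)) = sigma_j^2

is then fitted by REML with the genotype term fixed (for outlier testing
and BLUEs) or random (for variance components and heritability).  The
year term is always random.  Outliers are flagged from standardized
residuals with Holm familywise correction and removed iteratively until
no record is flagged.

Variance components are estimated by EM-REML on Henderson's mixed-model
equations, followed by a quasi-Newton polish of the restricted
log-likelihood on the log-variance scale.  The restricted log-likelihood
is evaluated through the standard identity
-2 lR = log|R| + log|G| + log|C| + y'Py + (n - p) log 2*pi,
with C the MME coefficient matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import LinAlgError
from scipy.optimize import minimize
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CurationReport",
    "MixedModelFit",
    "TraitBLUEs",
    "HeritabilityStats",
    "trim_records",
    "fit_year_model",
    "detect_outliers",
    "compute_blues",
    "estimate_heritability",
]

_VAR_FLOOR = 1e-10


@dataclass
class CurationReport:
    n_records_in: int
    n_single_datapoint_accessions_removed: int
    years_removed_for_no_overlap: list[str]
    n_records_out: int
    mean_records_per_accession: float

    def as_dict(self) -> dict:
        return {
            "n_records_in": self.n_records_in,
            "n_single_datapoint_accessions_removed": self.n_single_datapoint_accessions_removed,
            "years_removed_for_no_overlap": list(self.years_removed_for_no_overlap),
            "n_records_out": self.n_records_out,
            "mean_records_per_accession": self.mean_records_per_accession,
        }


@dataclass
class MixedModelFit:
    mode: str  # "fixed" or "random" genotype term
    mu: float
    genotype_effects: pd.Series  # entry means (fixed mode) or BLUPs (random mode)
    genotype_se: pd.Series
    year_effects: dict[str, float]
    sigma_g2: float | None  # genetic variance (random mode only)
    sigma_a2: float  # year variance
    sigma_e2_by_year: dict[str, float]
    restricted_log_likelihood: float
    converged: bool
    n_iter: int
    residuals: pd.Series = field(repr=False, default=None)
    record_years: pd.Series = field(repr=False, default=None)

    @property
    def sigma_e2_bar(self) -> float:
        return float(np.mean(list(self.sigma_e2_by_year.values())))


@dataclass
class TraitBLUEs:
    """Per-accession adjusted entry means for one trait."""

    trait: str
    estimates: pd.Series
    standard_errors: pd.Series
    n_years_mean: float
    outliers_removed: int = 0

    @property
    def accessions(self) -> list[str]:
        return list(self.estimates.index)

    def subset(self, labels) -> "TraitBLUEs":
        labels = [a for a in labels if a in self.estimates.index]
        return TraitBLUEs(
            trait=self.trait,
            estimates=self.estimates.loc[labels],
            standard_errors=self.standard_errors.loc[labels],
            n_years_mean=self.n_years_mean,
            outliers_removed=self.outliers_removed,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "accession_id": self.estimates.index,
                "trait": self.trait,
                "blue": self.estimates.to_numpy(),
                "se": self.standard_errors.to_numpy(),
                "n_years": self.n_years_mean,
            }
        )


@dataclass
class HeritabilityStats:
    h2: float
    h2_pb: float
    sigma_g2: float
    sigma_e2_bar: float
    n_bar: float

    def as_dict(self) -> dict:
        return {
            "h2": self.h2,
            "h2_pb": self.h2_pb,
            "sigma_g2": self.sigma_g2,
            "sigma_e2_bar": self.sigma_e2_bar,
            "n_bar": self.n_bar,
        }


def _check_table(table: pd.DataFrame) -> None:
    required = {"accession_id", "year", "trait", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"phenotype table needs columns {sorted(required)}")
    traits = table["trait"].unique()
    if len(traits) != 1:
        raise ValueError(f"expected a single trait, got {sorted(traits)}")
    if table["value"].isna().any() or not np.isfinite(table["value"]).all():
        raise ValueError("phenotype values must be finite")
    dup = table.duplicated(subset=["accession_id", "year"])
    if dup.any():
        pairs = table.loc[dup, ["accession_id", "year"]].head(3).to_records(index=False)
        raise ValueError(f"duplicated (accession, year) records, e.g. {list(pairs)}")


def trim_records(table: pd.DataFrame) -> tuple[pd.DataFrame, CurationReport]:
    """Trim to a connected, replicated record set (fixed point).

    Iteratively: (1) drop every year whose accession set shares no
    accession with any other retained year; (2) drop accessions left with
    a single record.  Repeats until stable.
    """
    if table.empty:
        raise ValueError("empty phenotype table")
    _check_table(table)
    current = table.copy()
    n_in = len(current)
    years_removed: list[str] = []
    acc_removed: set[str] = set()

    while True:
        changed = False
        year_groups = current.groupby("year")["accession_id"].agg(set)
        if len(year_groups) > 1:
            drop_years = []
            for y, accs in year_groups.items():
                others = set().union(
                    *(s for yy, s in year_groups.items() if yy != y)
                )
                if not accs & others:
                    drop_years.append(y)
            if drop_years:
                years_removed.extend(str(y) for y in drop_years)
                current = current[~current["year"].isin(drop_years)]
                changed = True
        elif len(year_groups) == 1:
            # a lone year has no overlap partner by definition
            years_removed.extend(str(y) for y in year_groups.index)
            current = current.iloc[0:0]

        counts = current["accession_id"].value_counts()
        singles = counts[counts < 2].index
        if len(singles):
            acc_removed.update(singles)
            current = current[~current["accession_id"].isin(singles)]
            changed = True
        if not changed or current.empty:
            break

    if current.empty:
        raise ValueError("no connected replicated data remains after trimming")

    report = CurationReport(
        n_records_in=n_in,
        n_single_datapoint_accessions_removed=len(acc_removed),
        years_removed_for_no_overlap=years_removed,
        n_records_out=len(current),
        mean_records_per_accession=len(current) / current["accession_id"].nunique(),
    )
    return current, report


class _YearModelDesign:
    """Index bookkeeping for the MME of the genotype + year model."""

    def __init__(self, table: pd.DataFrame, mode: str) -> None:
        if mode not in ("fixed", "random"):
            raise ValueError("genotype_mode must be 'fixed' or 'random'")
        self.mode = mode
        self.y = table["value"].to_numpy(dtype=float)
        self.n = len(self.y)
        self.accessions = sorted(table["accession_id"].unique())
        self.years = sorted(table["year"].astype(str).unique())
        acc_pos = {a: i for i, a in enumerate(self.accessions)}
        yr_pos = {y: j for j, y in enumerate(self.years)}
        self.acc_idx = table["accession_id"].map(acc_pos).to_numpy()
        self.year_idx = table["year"].astype(str).map(yr_pos).to_numpy()
        self.n_acc = len(self.accessions)
        self.n_year = len(self.years)
        if mode == "fixed":
            # cell-means coding: one column per accession, year random
            self.p_fixed = self.n_acc
            self.acc_cols = self.acc_idx
            self.year_cols = self.n_acc + self.year_idx
            self.cols = np.column_stack([self.acc_cols, self.year_cols])
        else:
            self.p_fixed = 1
            self.acc_cols = 1 + self.acc_idx
            self.year_cols = 1 + self.n_acc + self.year_idx
            self.cols = np.column_stack(
                [np.zeros(self.n, dtype=int), self.acc_cols, self.year_cols]
            )
        self.dim = self.p_fixed + (self.n_acc if mode == "random" else 0) + self.n_year

    def year_block(self) -> slice:
        start = self.dim - self.n_year
        return slice(start, self.dim)

    def acc_block(self) -> slice:
        # random-genotype block (random mode only)
        return slice(1, 1 + self.n_acc)


def _mme_solve(design: _YearModelDesign, params: dict) -> dict:
    """Assemble and solve the MME; return estimates and likelihood pieces."""
    sds = np.array([params["sigma_e2_by_year"][j] for j in range(design.n_year)])
    w = 1.0 / sds[design.year_idx]
    k = design.cols.shape[1]
    c = np.zeros((design.dim, design.dim))
    rhs = np.zeros(design.dim)
    for a in range(k):
        np.add.at(rhs, design.cols[:, a], w * design.y)
        for b in range(k):
            np.add.at(c, (design.cols[:, a], design.cols[:, b]), w)

    log_det_g = design.n_year * np.log(params["sigma_a2"])
    yb = design.year_block()
    c[yb, yb] += np.eye(design.n_year) / params["sigma_a2"]
    if design.mode == "random":
        ab = design.acc_block()
        c[ab, ab] += np.eye(design.n_acc) / params["sigma_g2"]
        log_det_g += design.n_acc * np.log(params["sigma_g2"])

    try:
        theta = np.linalg.solve(c, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate designs
        raise LinAlgError(
            "singular mixed-model equations; the fixed-effects design is aliased"
        ) from exc

    fitted = theta[design.cols].sum(axis=1)
    resid = design.y - fitted
    ytr_y = float(np.sum(w * design.y**2))
    y_p_y = ytr_y - float(rhs @ theta)
    sign, log_det_c = np.linalg.slogdet(c)
    if sign <= 0:
        raise LinAlgError("mixed-model coefficient matrix not positive definite")
    log_det_r = float(np.sum(np.log(sds[design.year_idx])))
    ll = -0.5 * (
        log_det_r
        + log_det_g
        + log_det_c
        + y_p_y
        + (design.n - design.p_fixed) * np.log(2.0 * np.pi)
    )
    return {
        "theta": theta,
        "resid": resid,
        "C": c,
        "ll": ll,
        "w": w,
    }


def _reml(
    design: _YearModelDesign,
    max_iter: int = 500,
    tol: float = 1e-8,
    polish: bool = True,
) -> tuple[dict, dict, bool, int]:
    """EM-REML with a quasi-Newton polish; returns (params, solve, converged, iters)."""
    var_y = float(np.var(design.y, ddof=1)) or 1.0
    params = {
        "sigma_a2": var_y / 4.0,
        "sigma_e2_by_year": {j: var_y / 2.0 for j in range(design.n_year)},
    }
    if design.mode == "random":
        params["sigma_g2"] = var_y / 4.0

    year_counts = np.bincount(design.year_idx, minlength=design.n_year).astype(float)
    last_ll = -np.inf
    converged = False
    it = 0
    sol = None
    for it in range(1, max_iter + 1):
        sol = _mme_solve(design, params)
        cinv = np.linalg.inv(sol["C"])
        theta = sol["theta"]
        # prediction-error contribution per record
        diag = cinv[design.cols[:, :, None], design.cols[:, None, :]].sum(axis=(1, 2))

        yb = design.year_block()
        a_hat = theta[yb]
        params["sigma_a2"] = max(
            (float(a_hat @ a_hat) + float(np.trace(cinv[yb, yb]))) / design.n_year,
            _VAR_FLOOR,
        )
        if design.mode == "random":
            ab = design.acc_block()
            g_hat = theta[ab]
            params["sigma_g2"] = max(
                (float(g_hat @ g_hat) + float(np.trace(cinv[ab, ab]))) / design.n_acc,
                _VAR_FLOOR,
            )
        ss = np.bincount(design.year_idx, weights=sol["resid"] ** 2, minlength=design.n_year)
        dd = np.bincount(design.year_idx, weights=diag, minlength=design.n_year)
        for j in range(design.n_year):
            params["sigma_e2_by_year"][j] = max((ss[j] + dd[j]) / year_counts[j], _VAR_FLOOR)

        if abs(sol["ll"] - last_ll) < tol:
            converged = True
            break
        last_ll = sol["ll"]

    if polish:
        params, sol, polished = _polish(design, params)
        converged = converged or polished
    else:
        sol = _mme_solve(design, params)
    return params, sol, converged, it


def _pack(params: dict, mode: str, n_year: int) -> np.ndarray:
    x = [params["sigma_a2"]] + [params["sigma_e2_by_year"][j] for j in range(n_year)]
    if mode == "random":
        x.append(params["sigma_g2"])
    return np.log(np.asarray(x))


def _unpack(x: np.ndarray, mode: str, n_year: int) -> dict:
    v = np.exp(x)
    params = {
        "sigma_a2": float(v[0]),
        "sigma_e2_by_year": {j: float(v[1 + j]) for j in range(n_year)},
    }
    if mode == "random":
        params["sigma_g2"] = float(v[1 + n_year])
    return params


def _polish(design: _YearModelDesign, params: dict) -> tuple[dict, dict, bool]:
    """L-BFGS-B refinement of the restricted log-likelihood on log-variances."""

    def neg_ll(x: np.ndarray) -> float:
        try:
            return -_mme_solve(design, _unpack(x, design.mode, design.n_year))["ll"]
        except LinAlgError:
            return 1e12

    x0 = _pack(params, design.mode, design.n_year)
    bounds = [(np.log(_VAR_FLOOR), 30.0)] * len(x0)
    res = minimize(neg_ll, x0, method="L-BFGS-B", bounds=bounds, options={"maxiter": 500})
    best = res.x if res.fun <= neg_ll(x0) else x0
    params = _unpack(best, design.mode, design.n_year)
    return params, _mme_solve(design, params), bool(res.success)


def fit_year_model(
    table: pd.DataFrame,
    genotype_mode: str = "fixed",
    max_iter: int = 500,
    tol: float = 1e-8,
    polish: bool = True,
) -> MixedModelFit:
    """REML fit of y_ij = mu + g_i + a_j + e_i(j) with per-year error variances.

    ``genotype_mode='fixed'`` yields genotype BLUEs (entry means, via
    cell-means coding so the general mean is absorbed); ``'random'``
    yields genotype BLUPs and the genetic variance used for heritability.
    """
    _check_table(table)
    design = _YearModelDesign(table, genotype_mode)
    if design.n_year < 2:
        raise ValueError("need records from at least two years; trim_records first")
    params, sol, converged, it = _reml(design, max_iter=max_iter, tol=tol, polish=polish)

    cinv_diag = np.diag(np.linalg.inv(sol["C"]))
    theta = sol["theta"]
    if genotype_mode == "fixed":
        est = pd.Series(theta[: design.n_acc], index=design.accessions)
        se = pd.Series(np.sqrt(np.maximum(cinv_diag[: design.n_acc], 0.0)), index=design.accessions)
        mu = float(est.mean())
        sigma_g2 = None
    else:
        mu = float(theta[0])
        ab = design.acc_block()
        est = pd.Series(theta[ab], index=design.accessions)
        se = pd.Series(np.sqrt(np.maximum(cinv_diag[ab], 0.0)), index=design.accessions)
        sigma_g2 = params["sigma_g2"]

    yb = design.year_block()
    year_effects = dict(zip(design.years, theta[yb]))
    sigma_e2_by_year = {
        design.years[j]: params["sigma_e2_by_year"][j] for j in range(design.n_year)
    }
    return MixedModelFit(
        mode=genotype_mode,
        mu=mu,
        genotype_effects=est,
        genotype_se=se,
        year_effects=year_effects,
        sigma_g2=sigma_g2,
        sigma_a2=params["sigma_a2"],
        sigma_e2_by_year=sigma_e2_by_year,
        restricted_log_likelihood=float(sol["ll"]),
        converged=converged,
        n_iter=it,
        residuals=pd.Series(sol["resid"], index=table.index),
        record_years=table["year"].astype(str),
    )


def detect_outliers(table: pd.DataFrame, fit: MixedModelFit, alpha: float = 0.05) -> list:
    """Flag outlier records via standardized residuals with Holm correction.

    Residuals are standardized by the year-specific residual SD; two-sided
    standard-normal p-values are corrected familywise by Holm's step-down
    at ``alpha``.  Returns flagged table index labels sorted by
    |standardized residual|, descending.
    """
    if fit.residuals is None or not fit.residuals.index.equals(table.index):
        raise ValueError("fit does not correspond to this table")
    if not fit.converged:
        raise ValueError("refusing to test outliers on a non-converged fit")
    sds = fit.record_years.map(lambda y: np.sqrt(fit.sigma_e2_by_year[y]))
    if (sds < 1e-9).any():
        bad = sorted(fit.record_years[sds < 1e-9].unique())
        raise ValueError(f"zero residual variance in year(s) {bad}; records untestable")
    z = fit.residuals / sds.to_numpy()
    pvals = 2.0 * norm.sf(np.abs(z))
    reject, *_ = multipletests(pvals, alpha=alpha, method="holm")
    flagged = z.index[reject]
    order = np.argsort(-np.abs(z.loc[flagged].to_numpy()), kind="stable")
    return list(flagged[order])


def estimate_heritability(
    sigma_g2: float, sigma_e2_bar: float, n_bar: float
) -> HeritabilityStats:
    """Entry-mean and plot-based heritability from variance components.

    h2 = sigma_g2 / (sigma_g2 + sigma_e2_bar / n_bar) with n_bar the
    average number of years an accession was tested; the plot-based form
    omits the division by n_bar.
    """
    if sigma_g2 < 0 or sigma_e2_bar < 0:
        raise ValueError("variance components must be non-negative")
    if n_bar < 1:
        raise ValueError("n_bar must be >= 1")
    if sigma_g2 == 0 and sigma_e2_bar == 0:
        raise ValueError("heritability undefined when both variances are zero")
    h2 = sigma_g2 / (sigma_g2 + sigma_e2_bar / n_bar)
    h2_pb = sigma_g2 / (sigma_g2 + sigma_e2_bar)
    return HeritabilityStats(
        h2=float(h2),
        h2_pb=float(h2_pb),
        sigma_g2=float(sigma_g2),
        sigma_e2_bar=float(sigma_e2_bar),
        n_bar=float(n_bar),
    )


def _n_bar(table: pd.DataFrame) -> float:
    return len(table) / table["accession_id"].nunique()


def compute_blues(
    table: pd.DataFrame,
    alpha: float = 0.05,
    max_rounds: int = 10,
) -> tuple[pd.DataFrame, TraitBLUEs, HeritabilityStats, HeritabilityStats]:
    """Outlier-corrected BLUEs with before/after heritabilities.

    Loop: fit (fixed genotype), flag outliers, drop them, re-trim, refit —
    until no record is flagged (capped at ``max_rounds``).  Heritabilities
    come from random-genotype REML fits before the first removal and after
    the last.  Returns (curated table, BLUEs, before stats, after stats).
    """
    current, _ = trim_records(table)
    trait = str(current["trait"].iloc[0])

    rand0 = fit_year_model(current, "random")
    before = estimate_heritability(rand0.sigma_g2, rand0.sigma_e2_bar, _n_bar(current))

    removed = 0
    fixed = None
    for _ in range(max_rounds):
        fixed = fit_year_model(current, "fixed")
        flags = detect_outliers(current, fixed, alpha=alpha)
        if not flags:
            break
        removed += len(flags)
        current = current.drop(index=flags)
        current, _ = trim_records(current)
    else:
        fixed = fit_year_model(current, "fixed")
        flags = detect_outliers(current, fixed, alpha=alpha)
        if flags:
            raise RuntimeError(
                f"outlier loop did not stabilize in {max_rounds} rounds; "
                f"{len(flags)} records still flagged"
            )

    rand1 = fit_year_model(current, "random")
    after = estimate_heritability(rand1.sigma_g2, rand1.sigma_e2_bar, _n_bar(current))

    blues = TraitBLUEs(
        trait=trait,
        estimates=fixed.genotype_effects,
        standard_errors=fixed.genotype_se,
        n_years_mean=_n_bar(current),
        outliers_removed=removed,
    )
    return current, blues, before, after
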