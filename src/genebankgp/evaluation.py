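"""Model evaluation by replicated cross-validation, whole-collection
prediction, culling-level donor selection and passport associations.

Prediction ability is the Pearson correlation between BLUEs and the
pooled test-set predictions of a five-fold cross-validation; the whole
procedure is repeated with independent random partitions, and all models
within a repeat share the same folds so the comparison is paired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, pearsonr

from .adjustment import adjust_lysine, fit_adjustment
from .curation import TraitBLUEs
from .genomics import GenotypeMatrix, KinshipMatrix
from .models import (
    FittedModel,
    ModelSpec,
    fit_bayes_a,
    fit_bayesian_lasso,
    fit_egblup,
    fit_gblup,
    predict,
)

__all__ = [
    "FoldPlan",
    "CVResult",
    "SelectionResult",
    "make_folds",
    "cross_validate",
    "compare_derived_strategies",
    "predict_collection",
    "culling_select",
    "altitude_association",
]

logger = logging.getLogger(__name__)


@dataclass
class FoldPlan:
    repeat_index: int
    assignments: pd.Series  # accession -> fold number (1..k)
    seed: int

    @property
    def k(self) -> int:
        return int(self.assignments.max())

    def split(self, fold: int) -> tuple[list[str], list[str]]:
        test = list(self.assignments.index[self.assignments == fold])
        train = list(self.assignments.index[self.assignments != fold])
        return train, test


@dataclass
class CVResult:
    abilities: pd.DataFrame  # columns: model, trait, repeat, ability

    def summary(self) -> pd.DataFrame:
        ok = self.abilities.dropna(subset=["ability"])
        return (
            ok.groupby(["model", "trait"])["ability"]
            .agg(["mean", "median", "std", "count"])
            .reset_index()
        )


@dataclass
class SelectionResult:
    level: float
    thresholds: dict[str, float]
    selected: list[str]

    def as_dict(self) -> dict:
        return {
            "level": self.level,
            "thresholds": self.thresholds,
            "selected": list(self.selected),
        }


def make_folds(accessions, k: int = 5, repeats: int = 100, seed: int = 0) -> list[FoldPlan]:
    """Balanced random k-fold partitions, one per repeat.

    Fold sizes differ by at most one; the remainder is spread over the
    first folds after shuffling.  Deterministic under ``seed``; repeats
    are drawn sequentially from one generator and hence mutually
    independent but jointly reproducible.
    """
    accessions = list(accessions)
    n = len(accessions)
    if k > n:
        raise ValueError(f"cannot split {n} accessions into {k} folds")
    if len(set(accessions)) != n:
        raise ValueError("duplicate accession labels")
    rng = np.random.default_rng(seed)
    plans = []
    base, rem = divmod(n, k)
    sizes = [base + (1 if f < rem else 0) for f in range(k)]
    for r in range(1, repeats + 1):
        perm = rng.permutation(n)
        folds = np.empty(n, dtype=int)
        start = 0
        for f, size in enumerate(sizes, start=1):
            folds[perm[start : start + size]] = f
            start += size
        plans.append(
            FoldPlan(
                repeat_index=r,
                assignments=pd.Series(folds, index=accessions),
                seed=seed,
            )
        )
    return plans


def _fit_one(
    spec: ModelSpec,
    train_blues: TraitBLUEs,
    G: KinshipMatrix | None,
    H: KinshipMatrix | None,
    markers: GenotypeMatrix | None,
    seed: int,
) -> FittedModel:
    if spec.model == "gblup":
        if G is None:
            raise ValueError("gblup requires G")
        return fit_gblup(train_blues, G)
    if spec.model == "egblup":
        if G is None or H is None:
            raise ValueError("egblup requires G and H")
        return fit_egblup(train_blues, G, H)
    if spec.model == "bayes_a":
        if markers is None:
            raise ValueError("bayes_a requires a marker matrix")
        return fit_bayes_a(train_blues, markers, spec.with_seed(seed))
    if markers is None:
        raise ValueError("bayesian_lasso requires a marker matrix")
    return fit_bayesian_lasso(train_blues, markers, spec.with_seed(seed))


def _model_label(model, i: int) -> str:
    if callable(model):
        return getattr(model, "__name__", f"custom_{i}")
    return model.model


def _ability(observed: pd.Series, predicted: pd.Series) -> float:
    pred = predicted.loc[observed.index]
    if np.std(pred.to_numpy()) == 0.0 or np.std(observed.to_numpy()) == 0.0:
        logger.warning("constant predictions; ability undefined for this repeat")
        return np.nan
    return float(pearsonr(observed.to_numpy(), pred.to_numpy())[0])


def cross_validate(
    blues: TraitBLUEs,
    models,
    folds: list[FoldPlan],
    G: KinshipMatrix | None = None,
    H: KinshipMatrix | None = None,
    markers: GenotypeMatrix | None = None,
) -> CVResult:
    """Replicated k-fold cross-validation sharing folds across models.

    Each fold is predicted once from the remaining folds; test-set
    predictions are pooled within a repeat and correlated with the BLUEs,
    giving one prediction ability per (model, repeat).  ``models`` may mix
    ``ModelSpec`` instances with callables ``f(train_blues, test_labels)
    -> pd.Series`` (used for oracle baselines).
    """
    accessions = list(folds[0].assignments.index)
    missing = [a for a in accessions if a not in blues.estimates.index]
    if missing:
        raise ValueError(f"fold accessions lack BLUEs: {missing[:5]}")
    observed = blues.estimates.loc[accessions]
    labels = [_model_label(m, i) for i, m in enumerate(models)]
    rows = []
    for plan in folds:
        pooled: dict[str, list[pd.Series]] = {lb: [] for lb in labels}
        for fold in range(1, plan.k + 1):
            train, test = plan.split(fold)
            train_blues = blues.subset(train)
            for lb, model in zip(labels, models):
                if callable(model):
                    pred = model(train_blues, test)
                else:
                    seed = (model.seed * 9973 + plan.repeat_index * 101 + fold) % (2**31 - 1)
                    fitted = _fit_one(model, train_blues, G, H, markers, seed)
                    pred = predict(fitted, test)
                pooled[lb].append(pred)
        for lb in labels:
            pred_all = pd.concat(pooled[lb])
            if len(pred_all) != len(accessions):
                raise RuntimeError("cross-validation did not test each accession exactly once")
            rows.append(
                {
                    "model": lb,
                    "trait": blues.trait,
                    "repeat": plan.repeat_index,
                    "ability": _ability(observed, pred_all),
                }
            )
    return CVResult(abilities=pd.DataFrame(rows))


def compare_derived_strategies(
    lysine: TraitBLUEs,
    protein: TraitBLUEs,
    tgw: TraitBLUEs,
    adjusted: TraitBLUEs,
    folds: list[FoldPlan],
    model: ModelSpec | None = None,
    G: KinshipMatrix | None = None,
    H: KinshipMatrix | None = None,
    markers: GenotypeMatrix | None = None,
) -> CVResult:
    """Direct vs component-wise prediction of adjusted lysine content.

    Strategy ``direct``: refit the adjustment on each training fold,
    adjust the training lysine BLUEs and predict the derived trait.
    Strategy ``component``: predict lysine, protein and TGW separately
    and apply the fold-fitted adjustment to the predictions.  Both are
    scored against the supplied full-data adjusted BLUEs.
    """
    model = model or ModelSpec(model="gblup")
    accessions = list(folds[0].assignments.index)
    observed = adjusted.estimates.loc[accessions]
    rows = []
    for plan in folds:
        preds: dict[str, list[pd.Series]] = {"direct": [], "component": []}
        for fold in range(1, plan.k + 1):
            train, test = plan.split(fold)
            adj_model = fit_adjustment(
                lysine.subset(train), protein.subset(train), tgw.subset(train)
            )
            train_adj = adjust_lysine(
                lysine.subset(train), protein.subset(train), tgw.subset(train), adj_model
            )
            seed = (model.seed * 9973 + plan.repeat_index * 101 + fold) % (2**31 - 1)
            fitted = _fit_one(model, train_adj, G, H, markers, seed)
            preds["direct"].append(predict(fitted, test))

            comp = {}
            for name, tb in (("lysine", lysine), ("protein", protein), ("tgw", tgw)):
                fitted_c = _fit_one(model, tb.subset(train), G, H, markers, seed + 1)
                comp[name] = predict(fitted_c, test)
            derived = (
                comp["lysine"]
                - adj_model.b_protein * (comp["protein"] - adj_model.mean_protein)
                - adj_model.b_tgw * (comp["tgw"] - adj_model.mean_tgw)
            )
            preds["component"].append(derived)
        for strategy in ("direct", "component"):
            pred_all = pd.concat(preds[strategy])
            rows.append(
                {
                    "model": strategy,
                    "trait": "lysine_adjusted",
                    "repeat": plan.repeat_index,
                    "ability": _ability(observed, pred_all),
                }
            )
    return CVResult(abilities=pd.DataFrame(rows))


def predict_collection(
    training_blues: dict[str, TraitBLUEs],
    spec: ModelSpec,
    G: KinshipMatrix | None = None,
    H: KinshipMatrix | None = None,
    markers: GenotypeMatrix | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Predict every genotyped accession for each trait with one model.

    Returns (predictions, summary): predictions indexed by accession with
    one column per trait; summary gives mean/SD/median/count per trait
    split by training membership (phenotyped vs genomic-only).
    """
    space = G.labels if G is not None else markers.accession_ids
    preds = {}
    summaries = []
    for trait, blues in training_blues.items():
        fitted = _fit_one(spec, blues, G, H, markers, spec.seed)
        p = predict(fitted, space)
        preds[trait] = p
        in_train = p.index.isin(fitted.training_accessions)
        for group, mask in (("training", in_train), ("unphenotyped", ~in_train)):
            vals = p[mask]
            summaries.append(
                {
                    "trait": trait,
                    "group": group,
                    "n": int(mask.sum()),
                    "mean": float(vals.mean()) if len(vals) else np.nan,
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                    "median": float(vals.median()) if len(vals) else np.nan,
                }
            )
    return pd.DataFrame(preds), pd.DataFrame(summaries)


def culling_select(
    predictions: pd.DataFrame,
    level: float,
    empirical: bool = False,
) -> SelectionResult:
    """Independent culling-level selection across the prediction columns.

    Per trait the threshold is mean + Phi^-1(level) * SD of the predicted
    values over all accessions (or the empirical quantile with
    ``empirical=True``); selected accessions exceed every threshold.
    A more stringent level always selects a subset of a more relaxed one.
    """
    if not 0.5 < level < 1.0:
        raise ValueError("culling level must be in (0.5, 1)")
    thresholds = {}
    mask = pd.Series(True, index=predictions.index)
    for col in predictions.columns:
        vals = predictions[col]
        if empirical:
            thr = float(vals.quantile(level))
        else:
            sd = float(vals.std(ddof=1))
            if sd == 0.0 or not np.isfinite(sd):
                raise ValueError(f"zero variance in predictions for {col!r}")
            thr = float(vals.mean()) + norm.ppf(level) * sd
        thresholds[col] = thr
        mask &= vals > thr
    return SelectionResult(
        level=level,
        thresholds=thresholds,
        selected=sorted(predictions.index[mask]),
    )


def altitude_association(
    predictions: pd.DataFrame,
    altitude: pd.Series,
) -> pd.DataFrame:
    """Pearson correlation of each predicted trait with collecting-site altitude.

    Only accessions with known altitude contribute; their count is
    reported per trait.
    """
    common = predictions.index.intersection(altitude.dropna().index)
    if len(common) < 3:
        raise ValueError(f"need >= 3 accessions with altitude, got {len(common)}")
    alt = altitude.loc[common].to_numpy(dtype=float)
    if np.std(alt) == 0.0:
        raise ValueError("altitude is constant; correlation undefined")
    rows = []
    for col in predictions.columns:
        r, p = pearsonr(predictions.loc[common, col].to_numpy(), alt)
        rows.append({"trait": col, "r": float(r), "p_value": float(p), "n": len(common)})
    return pd.DataFrame(rows)
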