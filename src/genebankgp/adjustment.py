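"""Partial-regression adjustment of lysine content.

Lysine content (‰) correlates strongly with protein content (%) and
negatively with thousand grain weight (g), so raw lysine BLUEs partly
re-express protein level and seed size.  The adjustment removes both by
genotype-wise partial regression:

    lysine_adj = lysine - b_P (protein - mean(protein)) - b_T (tgw - mean(tgw))

with b_P, b_T from an ordinary least-squares fit of lysine on protein and
TGW over the accessions carrying all three traits.  On the fitting set the
adjusted trait is exactly orthogonal to both predictors and keeps the raw
lysine mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .curation import TraitBLUEs

__all__ = ["AdjustmentModel", "fit_adjustment", "adjust_lysine"]

logger = logging.getLogger(__name__)


@dataclass
class AdjustmentModel:
    b_protein: float
    b_tgw: float
    mean_protein: float
    mean_tgw: float
    n_accessions_fit: int
    r2: float

    def as_dict(self) -> dict:
        return {
            "b_protein": self.b_protein,
            "b_tgw": self.b_tgw,
            "mean_protein": self.mean_protein,
            "mean_tgw": self.mean_tgw,
            "n_accessions_fit": self.n_accessions_fit,
            "r2": self.r2,
        }


def _common_accessions(*blues: TraitBLUEs) -> list[str]:
    common = set(blues[0].estimates.index)
    for b in blues[1:]:
        common &= set(b.estimates.index)
    return sorted(common)


def fit_adjustment(
    lysine: TraitBLUEs, protein: TraitBLUEs, tgw: TraitBLUEs
) -> AdjustmentModel:
    """OLS of lysine BLUEs on protein and TGW BLUEs (with intercept)."""
    common = _common_accessions(lysine, protein, tgw)
    if len(common) < 3:
        raise ValueError(
            f"need >= 3 accessions with all three traits, got {len(common)}"
        )
    y = lysine.estimates.loc[common].to_numpy()
    p = protein.estimates.loc[common].to_numpy()
    t = tgw.estimates.loc[common].to_numpy()
    if abs(np.corrcoef(p, t)[0, 1]) > 1.0 - 1e-12:
        raise ValueError("protein and TGW BLUEs are collinear; adjustment undefined")
    x = sm.add_constant(np.column_stack([p, t]))
    res = sm.OLS(y, x).fit()
    return AdjustmentModel(
        b_protein=float(res.params[1]),
        b_tgw=float(res.params[2]),
        mean_protein=float(p.mean()),
        mean_tgw=float(t.mean()),
        n_accessions_fit=len(common),
        r2=float(res.rsquared),
    )


def adjust_lysine(
    lysine: TraitBLUEs,
    protein: TraitBLUEs,
    tgw: TraitBLUEs,
    model: AdjustmentModel,
) -> TraitBLUEs:
    """Apply the adjustment genotype-wise; output trait ``lysine_adjusted``.

    Accessions missing any predictor are excluded (count logged).  The
    stored fitting-set means are reused, so the adjustment acts as a fixed
    transformation even outside the fitting set.
    """
    common = _common_accessions(lysine, protein, tgw)
    dropped = len(lysine.estimates) - len(common)
    if dropped:
        logger.info("adjust_lysine: %d accessions lack a predictor trait", dropped)
    lys = lysine.estimates.loc[common]
    adj = (
        lys
        - model.b_protein * (protein.estimates.loc[common] - model.mean_protein)
        - model.b_tgw * (tgw.estimates.loc[common] - model.mean_tgw)
    )
    return TraitBLUEs(
        trait="lysine_adjusted",
        estimates=adj,
        standard_errors=lysine.standard_errors.loc[common],
        n_years_mean=lysine.n_years_mean,
        outliers_removed=lysine.outliers_removed,
    )
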