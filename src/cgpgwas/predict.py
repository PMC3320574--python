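"""Multi-SNP genomic prediction from GWAS-detected SNPs.

A multiple regression on the detected SNPs is fitted on the training split
and used to predict the test split; explained variance is the R² from
regressing observed on predicted values over the test individuals (the
squared Pearson correlation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .qc import SplitDataset

__all__ = ["PredictionResult", "fit_predict_r2", "cross_level_prediction"]


@dataclass
class PredictionResult:
    trait: str
    predictors: np.ndarray
    coefficients: np.ndarray | None
    r2: float
    mode: str = "detected-causal-only"
    source: str = "own-GWAS"
    warning: str = ""


def _test_r2(observed: np.ndarray, predicted: np.ndarray) -> tuple[float, str]:
    if np.std(predicted) == 0.0 or np.std(observed) == 0.0:
        return 0.0, "constant predictions"
    r = np.corrcoef(observed, predicted)[0, 1]
    return float(r * r), ""


def fit_predict_r2(
    y: np.ndarray,
    codes: np.ndarray,
    predictor_set: np.ndarray,
    split: SplitDataset,
    trait: str = "trait",
    mode: str = "detected-causal-only",
    source: str = "own-GWAS",
) -> PredictionResult:
    """OLS with intercept on training genotypes; R² on the test split.

    Rank-deficient designs are resolved by the minimum-norm least-squares
    solution.  An empty predictor set gives R² = 0 by convention.
    """
    predictor_set = np.asarray(predictor_set, dtype=np.int64)
    if predictor_set.size == 0:
        return PredictionResult(trait, predictor_set, None, 0.0, mode, source,
                                "empty predictor set")
    tr, te = split.training_ids, split.test_ids
    Xtr = np.column_stack(
        [np.ones(tr.size), codes[np.ix_(tr, predictor_set)].astype(float)]
    )
    coef, _, rank, _ = np.linalg.lstsq(Xtr, np.asarray(y, float)[tr], rcond=None)
    warn = "rank-deficient design, minimum-norm solution" if rank < Xtr.shape[1] else ""
    Xte = np.column_stack(
        [np.ones(te.size), codes[np.ix_(te, predictor_set)].astype(float)]
    )
    r2, w2 = _test_r2(np.asarray(y, float)[te], Xte @ coef)
    return PredictionResult(trait, predictor_set, coef, r2, mode, source,
                            warn or w2)


def cross_level_prediction(
    y: np.ndarray,
    codes: np.ndarray,
    parameter_detected: list[np.ndarray],
    split: SplitDataset,
    trait: str = "trait",
    mode: str = "detected-causal-only",
) -> PredictionResult:
    """Predict a cellular trait from the union of the SNPs detected by the
    parameter-level GWAS (the cross-level predictor set)."""
    if parameter_detected:
        union = np.unique(np.concatenate([np.asarray(d) for d in parameter_detected]))
    else:
        union = np.array([], dtype=np.int64)
    res = fit_predict_r2(y, codes, union, split, trait, mode,
                         source="parameter-GWAS-union")
    return res
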