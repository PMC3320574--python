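"""Linear global sensitivity analysis and its concordance with GWAS results.

Sensitivity of each phenotype to each parameter is the R² of a univariate
regression of the phenotype on that parameter over the training individuals;
the matrix is compared with the GWAS attribution matrix (causal SNPs per
parameter detected via each phenotype) by Spearman rank correlation.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

__all__ = ["sensitivity_scan", "concordance", "column_entropy"]


def sensitivity_scan(
    param_values: np.ndarray,
    phen_values: np.ndarray,
) -> np.ndarray:
    """Parameters x phenotypes matrix of univariate regression R².

    Rows of both tables index the same (training) individuals.  A
    zero-variance parameter or phenotype gives a zero entry (with a warning
    for parameters).  NaN phenotype entries are ignored pairwise.
    """
    P = np.atleast_2d(np.asarray(param_values, float))
    Y = np.atleast_2d(np.asarray(phen_values, float))
    if P.shape[0] != Y.shape[0]:
        raise ValueError("parameter and phenotype tables must align on individuals")
    n_par, n_phen = P.shape[1], Y.shape[1]
    out = np.zeros((n_par, n_phen))
    p_sd = P.std(axis=0)
    if np.any(p_sd == 0.0):
        warnings.warn("zero-variance parameter; sensitivity entries set to 0")
    for j in range(n_phen):
        y = Y[:, j]
        ok = np.isfinite(y)
        if ok.sum() < 3 or np.std(y[ok]) == 0.0:
            continue
        yc = y[ok] - y[ok].mean()
        Pc = P[ok] - P[ok].mean(axis=0)
        ssp = (Pc**2).sum(axis=0)
        ssy = (yc**2).sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = (Pc.T @ yc) ** 2 / (ssp * ssy)
        out[:, j] = np.where(ssp > 0.0, r2, 0.0)
    return out


def concordance(sens: np.ndarray, attribution: np.ndarray) -> float:
    """Spearman rank correlation between the vectorised matrices.

    NaN (flagged) when either matrix is constant.
    """
    a, b = np.ravel(sens), np.ravel(attribution)
    if a.shape != b.shape:
        raise ValueError("matrices must share shape")
    if np.all(a == a[0]) or np.all(b == b[0]):
        warnings.warn("constant matrix: concordance undefined")
        return float("nan")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


def column_entropy(matrix: np.ndarray, cols: np.ndarray | list[int]) -> float:
    """Mean Shannon entropy (nats) of the selected columns, each normalised to
    a distribution over parameters.  Lower entropy = sensitivity mass
    concentrated on fewer parameters."""
    ent = []
    M = np.asarray(matrix, float)
    for c in cols:
        col = M[:, c]
        s = col.sum()
        if s <= 0:
            continue
        p = col / s
        p = p[p > 0]
        ent.append(float(-(p * np.log(p)).sum()))
    return float(np.mean(ent)) if ent else float("nan")
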