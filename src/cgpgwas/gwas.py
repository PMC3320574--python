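"""Single-SNP quantitative-trait association with Bonferroni control.

The test is the standard quantitative-trait association: per SNP, ordinary
least squares of the trait on the {-1, 0, +1} genotype code, a Wald t test
on the slope with n-2 residual degrees of freedom, and a Bonferroni
correction over the full SNP panel.  Implemented vectorised over SNPs (and
optionally over traits); numerically identical to fitting each SNP with a
standard regression routine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .gpmap import EffectMap

__all__ = [
    "GwasResult",
    "CausalMetrics",
    "assoc_scan",
    "assoc_scan_multi",
    "significant_set",
    "causal_metrics",
    "attribution_matrix",
]


@dataclass
class GwasResult:
    trait: str
    slope: np.ndarray
    tstat: np.ndarray
    p_raw: np.ndarray
    p_bonf: np.ndarray
    m_tests: int
    n: int


@dataclass
class CausalMetrics:
    detected: np.ndarray          # D = S intersect C
    false_positives: np.ndarray   # F = S \ C
    discovery_rate: float         # |D| / |C|
    fpr: float                    # |F| / |S|; 0 by convention when S empty
    fpr_defined: bool


def _scan_stats(codes: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-SNP OLS slope and t statistic for each trait column."""
    n = codes.shape[0]
    n_pos = (codes == 1).sum(axis=0).astype(np.float64)
    n_neg = (codes == -1).sum(axis=0).astype(np.float64)
    s1 = n_pos - n_neg                                        # sum g
    s2 = n_pos + n_neg                                        # sum g^2 (codes in {-1,0,1})
    ssg = s2 - s1 * s1 / n                                    # centred SS of g
    Yc = Y - Y.mean(axis=0)
    sxy = codes.astype(np.float64).T @ Yc                     # centred cross product
    ssy = (Yc**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / ssg[:, None]
        r2 = sxy**2 / (ssg[:, None] * ssy[None, :])
        r2 = np.clip(r2, 0.0, 1.0)
        t2 = (n - 2) * r2 / (1.0 - r2)
    t = np.sign(beta) * np.sqrt(t2)
    mono = ssg <= 0.0
    beta[mono] = np.nan
    t[mono] = np.nan
    return beta, t


def assoc_scan(
    y: np.ndarray,
    codes: np.ndarray,
    m_tests: int | None = None,
    trait: str = "trait",
) -> GwasResult:
    """Per-SNP linear regression of trait ``y`` on genotype codes.

    Monomorphic SNPs get NaN statistics (never significant).  ``m_tests``
    defaults to the full panel size (the Bonferroni convention on a fixed
    panel); corrected p = min(1, p * m_tests).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 individuals")
    if not np.all(np.isfinite(y)):
        raise ValueError("trait values must be finite")
    m = codes.shape[1] if m_tests is None else int(m_tests)
    if np.var(y) == 0.0:
        nanarr = np.full(codes.shape[1], np.nan)
        return GwasResult(trait, nanarr, nanarr.copy(), nanarr.copy(), nanarr.copy(), m, n)
    beta, t = _scan_stats(codes, y[:, None])
    beta, t = beta[:, 0], t[:, 0]
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p_bonf = np.minimum(1.0, p * m)
    return GwasResult(trait, beta, t, p, p_bonf, m, n)


def assoc_scan_multi(
    Y: np.ndarray,
    codes: np.ndarray,
    trait_names: list[str],
    m_tests: int | None = None,
) -> list[GwasResult]:
    """Scan several traits against the same panel in one pass (shared GEMM)."""
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    m = codes.shape[1] if m_tests is None else int(m_tests)
    const = Y.std(axis=0) == 0.0
    beta, t = _scan_stats(codes, Y)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    results = []
    for k, name in enumerate(trait_names):
        if const[k]:
            nanarr = np.full(codes.shape[1], np.nan)
            results.append(GwasResult(name, nanarr, nanarr.copy(), nanarr.copy(), nanarr.copy(), m, n))
        else:
            results.append(
                GwasResult(name, beta[:, k], t[:, k], p[:, k],
                           np.minimum(1.0, p[:, k] * m), m, n)
            )
    return results


def significant_set(result: GwasResult, threshold: float = 1e-5) -> np.ndarray:
    """SNP indices with Bonferroni-corrected p below the threshold."""
    with np.errstate(invalid="ignore"):
        mask = result.p_bonf < threshold
    return np.flatnonzero(np.nan_to_num(mask, nan=False))


def causal_metrics(S: np.ndarray, C: np.ndarray) -> CausalMetrics:
    """Detected set D = S∩C, false positives F = S\\C, discovery rate |D|/|C|
    and false-positive rate |F|/|S| (0, flagged undefined, when S is empty)."""
    S = np.asarray(S, dtype=np.int64)
    C = np.asarray(C, dtype=np.int64)
    D = np.intersect1d(S, C)
    F = np.setdiff1d(S, C)
    d = D.size / C.size if C.size else 0.0
    if S.size:
        return CausalMetrics(D, F, d, F.size / S.size, True)
    return CausalMetrics(D, F, d, 0.0, False)


def attribution_matrix(
    phenotype_detected: dict[str, np.ndarray],
    effect_map: EffectMap,
) -> np.ndarray:
    """Counts of each parameter's causal SNPs among each phenotype's detected
    SNPs: entry (param, phenotype) = |D_phen ∩ C_param|."""
    phen_names = list(phenotype_detected)
    out = np.zeros((effect_map.n_params, len(phen_names)), dtype=float)
    for c, name in enumerate(phen_names):
        D = np.asarray(phenotype_detected[name])
        for r, C in enumerate(effect_map.causal_sets):
            out[r, c] = np.intersect1d(D, C).size
    return out
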