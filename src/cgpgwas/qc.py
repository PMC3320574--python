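"""Outlier removal and training/test split.

Individuals with any phenotype more than twice the inter-quartile range
above the third quartile or below the first quartile are excluded, as are
individuals whose simulation failed; the survivors are split uniformly at
random into a 2,500-individual training set and a test set of the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SplitDataset", "iqr_filter", "train_test_split"]


class PipelineError(RuntimeError):
    pass


@dataclass
class SplitDataset:
    training_ids: np.ndarray
    test_ids: np.ndarray
    exclusion_log: list[tuple[int, str, str]] = field(default_factory=list)


def iqr_filter(
    values: np.ndarray,
    failed: np.ndarray | None = None,
    k: float = 2.0,
    names: list[str] | None = None,
) -> tuple[np.ndarray, list[tuple[int, str, str]]]:
    """Single-pass whole-individual IQR fence filter.

    Quartiles are computed per trait with linear interpolation (the type-7
    convention) over non-failed individuals, ignoring NaN entries.  An
    individual is excluded if flagged failed or if ANY trait lies above
    Q3 + k*IQR or below Q1 - k*IQR.  Returns (keep mask, exclusion log).
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 0:
        raise PipelineError("empty phenotype table")
    n, m = values.shape
    names = names or [f"trait{j}" for j in range(m)]
    failed = np.zeros(n, dtype=bool) if failed is None else np.asarray(failed, bool)
    keep = ~failed
    log: list[tuple[int, str, str]] = [
        (int(i), "", "simulation failure") for i in np.flatnonzero(failed)
    ]
    ok_rows = values[~failed]
    if ok_rows.shape[0] == 0:
        raise PipelineError("all individuals failed")
    with np.errstate(invalid="ignore"):
        q1 = np.nanpercentile(ok_rows, 25, axis=0)
        q3 = np.nanpercentile(ok_rows, 75, axis=0)
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    for j in range(m):
        out = (~failed) & ((values[:, j] > hi[j]) | (values[:, j] < lo[j]))
        for i in np.flatnonzero(out & keep):
            log.append((int(i), names[j], "outside IQR fences"))
        keep &= ~out
    if not keep.any():
        raise PipelineError("IQR filter excluded every individual")
    return keep, log


def train_test_split(
    retained_ids: np.ndarray,
    n_train: int = 2500,
    seed: int | np.random.Generator = 0,
    exclusion_log: list | None = None,
) -> SplitDataset:
    """Uniform random split of the retained individuals without replacement."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    retained_ids = np.asarray(retained_ids)
    if retained_ids.size < n_train + 1:
        raise PipelineError(
            f"need at least {n_train + 1} retained individuals, have {retained_ids.size}"
        )
    perm = rng.permutation(retained_ids.size)
    train = np.sort(retained_ids[perm[:n_train]])
    test = np.sort(retained_ids[perm[n_train:]])
    return SplitDataset(train, test, exclusion_log or [])
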