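"""Median-of-ratios size factors and log2 fold-change summaries.

The size factor of sample *j* is the median, over circRNAs *i* whose counts
are positive in every sample, of the ratio ``k_ij / geomean_i`` where
``geomean_i`` is the geometric mean of row *i* across samples. Dividing each
column by its factor makes libraries comparable without letting a handful of
highly expressed circRNAs dominate (as total-count scaling would). Rows
containing any zero are excluded from estimation because their log-space
geometric mean is undefined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import NumericError
from .io_formats import JunctionCountMatrix, SampleTable

logger = logging.getLogger("circage")


@dataclass
class SizeFactors:
    factors: pd.Series  # sample_id -> s_j > 0

    def __post_init__(self) -> None:
        v = self.factors.to_numpy(dtype=float)
        if not np.all(np.isfinite(v)) or np.any(v <= 0):
            raise NumericError("size factors must be positive and finite")


def size_factors(matrix: JunctionCountMatrix) -> SizeFactors:
    """Median-of-ratios size factor per sample."""
    counts = matrix.values.astype(float)
    pos = (counts > 0).all(axis=1)
    if not pos.any():
        raise NumericError(
            "no row with all-positive counts; apply the expression filter "
            "(or a minimal prevalence filter) before estimating size factors"
        )
    logc = np.log(counts[pos])
    ratios = np.exp(logc - logc.mean(axis=1, keepdims=True))  # k_ij / geomean_i
    sf = np.median(ratios, axis=0)
    logger.info(
        "size factors from %d all-positive rows: range %.4g-%.4g",
        int(pos.sum()), sf.min(), sf.max(),
    )
    return SizeFactors(factors=pd.Series(sf, index=matrix.sample_ids))


def normalize(matrix: JunctionCountMatrix, sf: SizeFactors) -> JunctionCountMatrix:
    """Divide each sample's counts by its size factor."""
    missing = set(matrix.sample_ids) - set(sf.factors.index)
    if missing:
        raise NumericError(f"missing size factor(s) for sample(s): {sorted(missing)}")
    norm = matrix.counts.astype(float).div(sf.factors[matrix.sample_ids], axis=1)
    return JunctionCountMatrix(counts=norm, row_meta=matrix.row_meta)


def log2_transform(matrix: JunctionCountMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(normalized + pseudocount); the default working scale for
    downstream tests (variance stabilization)."""
    return np.log2(matrix.counts + pseudocount)


_FACTOR_LEVELS = {"age": "age_years", "sex": "sex"}


def log2_fold_change(
    norm_matrix: JunctionCountMatrix,
    samples: SampleTable,
    factor: str,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-row log2 fold change of group2 over group1 plus a Welch t-test.

    Groups are the sorted levels of ``factor`` (age: 10 -> group1, 20 ->
    group2; sex: F -> group1, M -> group2). The fold change is computed on
    mean normalized expression with a pseudocount; the t-test runs on
    log2(normalized + pseudocount). ``direction`` is the higher group's
    label, or ``none`` at exactly equal means.

    Returns a DataFrame indexed by circ_id with columns log2fc, t_stat,
    p_value, direction; ``df.attrs["direction_counts"]`` tallies directions.
    """
    if factor not in _FACTOR_LEVELS:
        raise ValueError(f"factor must be one of {sorted(_FACTOR_LEVELS)}")
    levels = samples.levels(factor)
    if len(levels) != 2:
        raise NumericError(f"factor {factor!r} needs exactly 2 levels, got {levels}")
    g1, g2 = levels
    mask1 = samples.group_mask(factor, g1)[
        [samples.sample_ids.index(s) for s in norm_matrix.sample_ids]
    ]
    mask2 = ~mask1
    if mask1.sum() == 0 or mask2.sum() == 0:
        raise NumericError(f"empty group for factor {factor!r}")

    vals = norm_matrix.values.astype(float)
    m1 = vals[:, mask1].mean(axis=1)
    m2 = vals[:, mask2].mean(axis=1)
    log2fc = np.log2((m2 + pseudocount) / (m1 + pseudocount))

    x = np.log2(vals + pseudocount)
    t, p = _row_welch(x[:, mask2], x[:, mask1])

    direction = np.where(log2fc > 0, str(g2), np.where(log2fc < 0, str(g1), "none"))
    out = pd.DataFrame(
        {"log2fc": log2fc, "t_stat": t, "p_value": p, "direction": direction},
        index=norm_matrix.circ_ids,
    )
    counts = out["direction"].value_counts().to_dict()
    out.attrs["direction_counts"] = {str(g1): counts.get(str(g1), 0),
                                     str(g2): counts.get(str(g2), 0),
                                     "none": counts.get("none", 0)}
    logger.info("log2FC by %s (%s over %s): %s", factor, g2, g1,
                out.attrs["direction_counts"])
    return out


def _row_welch(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch t-test with deterministic degenerate handling:
    both groups constant -> t=0, p=1 at equal means, else t=+/-inf, p=0."""
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant rows trigger scipy's catastrophic-cancellation warning;
        # their statistics are overwritten deterministically below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    bad = ~np.isfinite(t)
    if bad.any():
        ma, mb = a[bad].mean(axis=1), b[bad].mean(axis=1)
        eq = np.isclose(ma, mb)
        t[bad] = np.where(eq, 0.0, np.where(ma > mb, np.inf, -np.inf))
        p[bad] = np.where(eq, 1.0, 0.0)
    return t, p
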