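"""Pearson correlation between circRNA and host-mRNA expression.

Each (circRNA, host gene) pair contributes one correlation across the
shared, identically ordered sample set; several circRNA isoforms of one
gene yield several pairs. The two-sided p-value comes from the standard
t-transform ``t = r sqrt((n-2)/(1-r^2))`` with n - 2 degrees of freedom.
Pairs with |PCC| >= 0.3 and p <= 0.1 (boundaries inclusive) are classified
positive or negative by the sign of the coefficient; everything else is
uncorrelated. Correlation is unit-free, so mRNA expression may be counts,
FPKM or TPM; callers typically pass log-transformed matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import NumericError

logger = logging.getLogger("circage")


@dataclass(frozen=True)
class CorrelationSummary:
    n_total: int  # classifiable pairs
    n_positive: int
    n_negative: int
    n_uncorrelated: int
    n_skipped_no_host: int
    n_undefined: int
    fraction_correlated: float


def pair_correlations(
    circ_matrix: pd.DataFrame,
    mrna_matrix: pd.DataFrame,
    host_map: dict[str, str] | pd.Series,
) -> pd.DataFrame:
    """PCC and p-value for every (circRNA, host gene) pair in ``host_map``.

    Both matrices must carry the same sample set; ``mrna_matrix`` is
    reordered to the circRNA matrix's column order. circRNAs absent from
    ``host_map`` / genes absent from the mRNA matrix are skipped with a
    logged count. Zero-variance profiles yield ``undefined=True`` with NaN
    statistics and are excluded from classification.
    """
    if isinstance(host_map, pd.Series):
        host_map = host_map.dropna().to_dict()
    if set(circ_matrix.columns) != set(mrna_matrix.columns):
        raise NumericError("circRNA and mRNA matrices carry different sample sets")
    mrna = mrna_matrix[circ_matrix.columns]
    n = circ_matrix.shape[1]
    if n < 3:
        raise NumericError("need at least 3 shared samples for correlation")

    rows = []
    n_skipped = 0
    for cid in circ_matrix.index:
        gene = host_map.get(cid)
        if gene is None or gene not in mrna.index:
            n_skipped += 1
            continue
        x = circ_matrix.loc[cid].to_numpy(dtype=float)
        y = mrna.loc[gene].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            rows.append((cid, gene, np.nan, np.nan, True))
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        r = min(1.0, max(-1.0, r))
        if abs(r) == 1.0:
            p = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1.0 - r * r))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
        rows.append((cid, gene, r, p, False))
    out = pd.DataFrame(
        rows, columns=["circ_id", "host_gene", "pcc", "p_value", "undefined"]
    )
    logger.info(
        "correlated %d circRNA-host pairs (%d skipped without usable host)",
        len(out), n_skipped,
    )
    out.attrs["n_skipped_no_host"] = n_skipped
    return out


def classify_pairs(
    pairs: pd.DataFrame,
    min_abs_pcc: float = 0.3,
    max_p: float = 0.1,
) -> tuple[pd.DataFrame, CorrelationSummary]:
    """Label pairs positive / negative / uncorrelated at inclusive
    thresholds and summarize the split."""
    if not (0.0 < min_abs_pcc < 1.0):
        raise ValueError(f"min_abs_pcc must lie in (0, 1), got {min_abs_pcc}")
    if not (0.0 <= max_p <= 1.0):
        raise ValueError(f"max_p must lie in [0, 1], got {max_p}")
    out = pairs.copy()
    usable = ~out["undefined"].fillna(False) & out["pcc"].notna()
    sig = usable & (out["pcc"].abs() >= min_abs_pcc) & (out["p_value"] <= max_p)
    cls = np.where(
        sig & (out["pcc"] > 0), "positive",
        np.where(sig & (out["pcc"] < 0), "negative", "uncorrelated"),
    )
    cls = np.where(usable, cls, "undefined")
    out["class"] = cls

    n_pos = int((out["class"] == "positive").sum())
    n_neg = int((out["class"] == "negative").sum())
    n_unc = int((out["class"] == "uncorrelated").sum())
    n_total = n_pos + n_neg + n_unc
    summary = CorrelationSummary(
        n_total=n_total,
        n_positive=n_pos,
        n_negative=n_neg,
        n_uncorrelated=n_unc,
        n_skipped_no_host=int(pairs.attrs.get("n_skipped_no_host", 0)),
        n_undefined=int((out["class"] == "undefined").sum()),
        fraction_correlated=(n_pos + n_neg) / n_total if n_total else 0.0,
    )
    logger.info(
        "classified pairs: %d positive, %d negative, %d uncorrelated "
        "(%.1f%% correlated)",
        n_pos, n_neg, n_unc, 100 * summary.fraction_correlated,
    )
    return out, summary
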