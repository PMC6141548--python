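"""Spatial, sex- and age-biased circRNA calling.

Three screens over the normalized matrix (tested on log2(norm + 1) by
default):

* :func:`spatial_specific` — one-vs-rest Welch t-test per brain region;
  a circRNA is called for a region when p < alpha and the region's mean is
  strictly higher. ``mode="vs_each"`` is the stricter "consistently higher
  than every other area" screen: the one-vs-rest criteria plus a pairwise
  Welch test against each other region (each p < alpha with a strictly
  higher mean). A circRNA is assigned to at most one region — the smallest
  one-vs-rest p among its passing regions, ties broken lexicographically.
* :func:`group_biased` — two-group Welch t-test between the two levels of
  sex or age; the enriched group is the higher-mean level.
* :func:`permutation_test` — empirical null for the same two-group
  contrasts: the per-row difference of group means is recomputed under
  label permutations shared across rows, with the add-one estimator
  ``p = (1 + #{|stat_perm| >= |stat_obs|}) / (1 + n_perm)``.

No multiple-testing correction is applied to the ``called`` columns (the
screens report raw-threshold sets); Benjamini-Hochberg q-values are emitted
alongside for FDR-controlled use.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import NumericError
from .io_formats import JunctionCountMatrix, SampleTable
from .normalization import _row_welch

logger = logging.getLogger("circage")


@dataclass(frozen=True)
class SpecificityResult:
    circ_id: str
    contrast: str
    t_stat: float
    p_t: float
    enriched_group: str
    called: bool
    p_perm: float | None = None


@dataclass(frozen=True)
class SetComparison:
    size_a: int
    size_b: int
    intersection: int
    overlap_ratio: float  # intersection / size_b


def two_group_t_test(x, y, paired: bool = False) -> tuple[float, float]:
    """Two-sided t-test between two samples.

    Unpaired uses the Welch statistic; paired tests the matched differences
    (equal lengths, matched order). Degenerate zero-variance cases resolve
    deterministically: equal means -> (0, 1), unequal constant groups ->
    (+/-inf, 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired and len(x) != len(y):
        raise ValueError("paired test needs equal-length, matched samples")
    if len(x) < 2 or len(y) < 2:
        raise NumericError("each group needs n >= 2")
    if paired:
        d = x - y
        if np.allclose(d.std(ddof=1), 0):
            return (0.0, 1.0) if np.isclose(d.mean(), 0) else (
                np.copysign(np.inf, d.mean()), 0.0)
        t, p = stats.ttest_rel(x, y)
        return float(t), float(p)
    t, p = _row_welch(x[None, :], y[None, :])
    return float(t[0]), float(p[0])


def _working_matrix(norm_matrix: JunctionCountMatrix, log_transform: bool) -> np.ndarray:
    vals = norm_matrix.values.astype(float)
    return np.log2(vals + 1.0) if log_transform else vals


def _aligned_column(samples: SampleTable, norm_matrix: JunctionCountMatrix, col: str):
    return samples.data.loc[norm_matrix.sample_ids, col].to_numpy()


def spatial_specific(
    norm_matrix: JunctionCountMatrix,
    samples: SampleTable,
    alpha: float = 0.01,
    mode: str = "one_vs_rest",
    log_transform: bool = True,
) -> pd.DataFrame:
    """One-vs-rest (or consistently-higher pairwise) regional screen.

    Returns one row per (circRNA, region) test with columns contrast
    (``"<region>-vs-rest"``), t_stat, p_t, q_t (BH within each region's
    contrast), enriched_group and called. ``called`` marks at most one
    region per circRNA.
    """
    if mode not in ("one_vs_rest", "vs_each"):
        raise ValueError(f"unknown mode {mode!r}")
    regions = _aligned_column(samples, norm_matrix, "region")
    levels = [r for r in pd.unique(regions)]
    for r in levels:
        if (regions == r).sum() < 2:
            raise NumericError(f"region {r!r} has fewer than 2 samples")

    x = _working_matrix(norm_matrix, log_transform)
    n_rows = x.shape[0]
    region_means = {r: x[:, regions == r].mean(axis=1) for r in levels}

    p_mat = np.ones((n_rows, len(levels)))
    t_mat = np.zeros((n_rows, len(levels)))
    pass_mat = np.zeros((n_rows, len(levels)), dtype=bool)
    for j, r in enumerate(levels):
        mask = regions == r
        t, p = _row_welch(x[:, mask], x[:, ~mask])
        higher = region_means[r] > x[:, ~mask].mean(axis=1)
        ok = (p < alpha) & higher
        if mode == "vs_each":
            for other in levels:
                if other == r:
                    continue
                if not ok.any():
                    break
                to, po = _row_welch(x[:, mask], x[:, regions == other])
                ok &= (po < alpha) & (region_means[r] > region_means[other])
        p_mat[:, j], t_mat[:, j], pass_mat[:, j] = p, t, ok

    # assign each circRNA to its smallest-p passing region (ties: first in
    # lexicographic region order)
    order = np.argsort(levels, kind="stable")
    called_mat = np.zeros_like(pass_mat)
    any_pass = pass_mat.any(axis=1)
    p_masked = np.where(pass_mat, p_mat, np.inf)[:, order]
    best = order[np.argmin(p_masked, axis=1)]
    called_mat[np.arange(n_rows)[any_pass], best[any_pass]] = True

    frames = []
    for j, r in enumerate(levels):
        q = multipletests(p_mat[:, j], method="fdr_bh")[1]
        frames.append(
            pd.DataFrame(
                {
                    "circ_id": norm_matrix.circ_ids,
                    "contrast": f"{r}-vs-rest",
                    "t_stat": t_mat[:, j],
                    "p_t": p_mat[:, j],
                    "q_t": q,
                    "enriched_group": r,
                    "called": called_mat[:, j],
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    logger.info(
        "spatial screen (%s, alpha=%g): %d circRNAs called across %d regions",
        mode, alpha, int(out["called"].sum()), len(levels),
    )
    return out


def group_biased(
    norm_matrix: JunctionCountMatrix,
    samples: SampleTable,
    factor: str,
    alpha: float = 0.05,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Two-group screen for sex- or age-biased circRNAs.

    Returns a DataFrame indexed by circ_id with contrast (e.g. ``"M-vs-F"``
    or ``"20y-vs-10y"``), t_stat, p_t, q_t (BH), enriched_group (the
    higher-mean level) and called (p_t < alpha).
    """
    col = {"sex": "sex", "age": "age_years"}.get(factor)
    if col is None:
        raise ValueError("factor must be 'sex' or 'age'")
    labels = _aligned_column(samples, norm_matrix, col)
    levels = sorted(pd.unique(labels).tolist())
    if len(levels) != 2:
        raise NumericError(f"factor {factor!r} needs exactly 2 levels, got {levels}")
    g1, g2 = levels  # g2 tested against g1
    x = _working_matrix(norm_matrix, log_transform)
    mask2 = labels == g2
    t, p = _row_welch(x[:, mask2], x[:, ~mask2])
    q = multipletests(p, method="fdr_bh")[1]
    m2, m1 = x[:, mask2].mean(axis=1), x[:, ~mask2].mean(axis=1)
    suffix = "y" if factor == "age" else ""
    enriched = np.where(m2 >= m1, f"{g2}{suffix}", f"{g1}{suffix}")
    out = pd.DataFrame(
        {
            "contrast": f"{g2}{suffix}-vs-{g1}{suffix}",
            "t_stat": t,
            "p_t": p,
            "q_t": q,
            "enriched_group": enriched,
            "called": p < alpha,
        },
        index=norm_matrix.circ_ids,
    )
    logger.info(
        "%s screen (alpha=%g): %d called (%s)",
        factor, alpha, int(out["called"].sum()),
        out.loc[out["called"], "enriched_group"].value_counts().to_dict(),
    )
    return out


def permutation_test(
    norm_matrix: JunctionCountMatrix,
    samples: SampleTable,
    factor: str,
    n_perm: int = 10000,
    seed: int = 0,
    exact: bool = False,
    log_transform: bool = True,
) -> pd.Series:
    """Permutation p-value per row for a two-group contrast.

    The statistic is the difference of group means. Labels are permuted
    jointly across rows, so one shared set of ``n_perm`` permutations serves
    the whole matrix. ``exact=True`` enumerates every distinct label split
    instead (p = #{|stat| >= |obs|} / #splits, the identity split included);
    it refuses designs with more than 200,000 splits.
    """
    if not exact and n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    col = {"sex": "sex", "age": "age_years"}.get(factor)
    if col is None:
        raise ValueError("factor must be 'sex' or 'age'")
    labels = _aligned_column(samples, norm_matrix, col)
    levels = sorted(pd.unique(labels).tolist())
    if len(levels) != 2:
        raise NumericError(f"factor {factor!r} needs exactly 2 levels, got {levels}")
    mask2 = labels == levels[1]
    n, n2 = len(labels), int(mask2.sum())
    x = _working_matrix(norm_matrix, log_transform)

    # mean-difference statistic as a single matrix product: x @ w
    w_obs = np.where(mask2, 1.0 / n2, -1.0 / (n - n2))
    obs = x @ w_obs

    if exact:
        from math import comb

        n_splits = comb(n, n2)
        if n_splits > 200_000:
            raise NumericError(
                f"exact enumeration infeasible: C({n},{n2}) = {n_splits} splits"
            )
        W = np.empty((n, n_splits))
        for k, idx in enumerate(itertools.combinations(range(n), n2)):
            m = np.zeros(n, dtype=bool)
            m[list(idx)] = True
            W[:, k] = np.where(m, 1.0 / n2, -1.0 / (n - n2))
        perm = x @ W
        p = (np.abs(perm) >= np.abs(obs)[:, None] - 1e-12).sum(axis=1) / n_splits
    else:
        rng = np.random.default_rng(seed)
        W = np.empty((n, n_perm))
        for k in range(n_perm):
            W[:, k] = w_obs[rng.permutation(n)]
        perm = x @ W
        exceed = (np.abs(perm) >= np.abs(obs)[:, None] - 1e-12).sum(axis=1)
        p = (1.0 + exceed) / (1.0 + n_perm)
    return pd.Series(p, index=norm_matrix.circ_ids, name="p_perm")


def compare_sets(a, b) -> SetComparison:
    """Exact overlap of two id sets; the ratio is relative to ``b``."""
    a, b = set(a), set(b)
    inter = len(a & b)
    return SetComparison(
        size_a=len(a),
        size_b=len(b),
        intersection=inter,
        overlap_ratio=inter / len(b) if b else 0.0,
    )
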