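"""Synthetic junction-count experiments with planted ground truth.

The generator emulates the study design the pipeline targets: 8 brain
regions x 2 sexes x 2 age groups, one pooled library per cell (32 samples).
Junction counts are negative binomial — overdispersed and sparse, matching
back-splice read behaviour — with

    count_ij ~ NB(mean = lambda_i * s_j * f_ij, dispersion = alpha)

where ``lambda_i`` is a log-normal baseline per circRNA, ``s_j`` a per-
sample library size factor, and ``f_ij`` the planted fold for sample *j*'s
factor level (region, sex or age). Baseline abundance defaults describe a
*filtered, well-expressed* circRNA set (median ~55 junction reads), not the
raw candidate pool. Every planted effect is recorded in a truth table, so
recovery of spatial/sex/age calls and host-gene correlations can be scored
exactly.

Host mRNA profiles are planted on the log scale: the host's log profile is
a ``rho``-weighted copy of the standardized circRNA log profile plus
``sqrt(1 - rho^2)``-weighted independent noise, then back-transformed to a
positive expression scale. Correlating the two *log* matrices therefore
recovers ``rho`` up to sampling error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io_formats import (
    AGES,
    REGIONS,
    SEXES,
    JunctionCountMatrix,
    SampleTable,
    format_circ_id,
)

logger = logging.getLogger("circage")


@dataclass(frozen=True)
class Spike:
    """Planted effect: ``n_spiked`` circRNAs at ``fold_change`` in every
    sample carrying ``level`` (a region name, a sex, or an age)."""

    level: str
    n_spiked: int
    fold_change: float

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ConfigError(f"fold_change must be > 0, got {self.fold_change}")
        if self.n_spiked < 0:
            raise ConfigError("n_spiked must be >= 0")


@dataclass
class SimConfig:
    n_circ: int = 2000
    regions: Sequence[str] = REGIONS
    sexes: Sequence[str] = SEXES
    ages: Sequence[int] = AGES
    replicates: int = 1
    baseline_log_mean: float = 4.0  # natural-log scale; median ~55 reads
    baseline_log_sd: float = 1.0
    nb_dispersion: float = 0.1
    library_size_factors: Sequence[float] | None = None  # None -> lognormal
    library_size_log_sd: float = 0.2
    spikes: Sequence[Spike] = field(
        default_factory=lambda: (
            Spike("CB", 50, 4.0),
            Spike("OC", 50, 4.0),
            Spike("M", 100, 4.0),
            Spike("20", 100, 4.0),
        )
    )
    host_rho_sets: Sequence[tuple[int, float]] = ((300, 0.8), (300, -0.8), (300, 0.0))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_circ < 1 or self.replicates < 1:
            raise ConfigError("n_circ and replicates must be >= 1")
        if not self.regions or not self.sexes or not self.ages:
            raise ConfigError("design must have at least one level per factor")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")
        total = sum(s.n_spiked for s in self.spikes)
        if total > self.n_circ:
            raise ConfigError(f"{total} spiked rows exceed n_circ={self.n_circ}")
        for _, rho in self.host_rho_sets:
            if not -1.0 <= rho <= 1.0:
                raise ConfigError(f"host rho must lie in [-1, 1], got {rho}")

    @property
    def n_samples(self) -> int:
        return len(self.regions) * len(self.sexes) * len(self.ages) * self.replicates


def _sample_design(cfg: SimConfig) -> pd.DataFrame:
    rows = []
    for region in cfg.regions:
        for sex in cfg.sexes:
            for age in cfg.ages:
                for rep in range(cfg.replicates):
                    sid = f"{region}_{sex}_{age}"
                    if cfg.replicates > 1:
                        sid += f"_r{rep + 1}"
                    rows.append((sid, region, sex, age))
    return pd.DataFrame(
        rows, columns=["sample_id", "region", "sex", "age_years"]
    ).set_index("sample_id")


def _level_mask(design: pd.DataFrame, level: str, cfg: SimConfig) -> np.ndarray:
    if level in cfg.regions:
        return (design["region"] == level).to_numpy()
    if level in cfg.sexes:
        return (design["sex"] == level).to_numpy()
    try:
        age = int(level)
    except ValueError:
        age = None
    if age is not None and age in cfg.ages:
        return (design["age_years"] == age).to_numpy()
    raise ConfigError(f"spike level {level!r} is not a region, sex or age")


def _synthetic_loci(n: int, rng: np.random.Generator) -> list[str]:
    """Plausible, unique circRNA loci for ids and BED/annotation plumbing."""
    ids: list[str] = []
    seen: set[str] = set()
    while len(ids) < n:
        chrom = f"chr{rng.integers(1, 21)}"
        start = int(rng.integers(1_000, 50_000_000))
        length = int(rng.integers(200, 20_000))
        strand = "+" if rng.random() < 0.5 else "-"
        cid = format_circ_id(chrom, start, start + length, strand)
        if cid not in seen:
            seen.add(cid)
            ids.append(cid)
    return ids


def simulate_counts(
    cfg: SimConfig,
) -> tuple[JunctionCountMatrix, SampleTable, pd.DataFrame]:
    """Draw one experiment: counts, sample table, and the truth table
    (circ_id -> spike label or None, true fold, host rho placeholder)."""
    design = _sample_design(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 11]))

    circ_ids = _synthetic_loci(cfg.n_circ, rng)
    lam = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_circ)
    if cfg.library_size_factors is not None:
        s = np.asarray(cfg.library_size_factors, dtype=float)
        if len(s) != cfg.n_samples or np.any(s <= 0):
            raise ConfigError(
                f"library_size_factors must be {cfg.n_samples} positive values"
            )
    else:
        s = rng.lognormal(0.0, cfg.library_size_log_sd, cfg.n_samples)

    fold = np.ones((cfg.n_circ, cfg.n_samples))
    spike_label = np.array([None] * cfg.n_circ, dtype=object)
    true_fold = np.ones(cfg.n_circ)
    order = rng.permutation(cfg.n_circ)
    cursor = 0
    for spike in cfg.spikes:
        rows = order[cursor : cursor + spike.n_spiked]
        cursor += spike.n_spiked
        mask = _level_mask(design, spike.level, cfg)
        fold[np.ix_(rows, np.flatnonzero(mask))] = spike.fold_change
        spike_label[rows] = spike.level
        true_fold[rows] = spike.fold_change

    mu = lam[:, None] * s[None, :] * fold
    r = 1.0 / cfg.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))

    matrix = JunctionCountMatrix(
        counts=pd.DataFrame(counts, index=circ_ids, columns=design.index)
    )
    truth = pd.DataFrame(
        {"spike_label": spike_label, "true_fold": true_fold, "host_rho": np.nan},
        index=circ_ids,
    )
    samples = SampleTable(data=design)
    logger.info(
        "simulated %d circRNAs x %d samples (%d spiked rows)",
        cfg.n_circ, cfg.n_samples, int((spike_label != None).sum()),  # noqa: E711
    )
    return matrix, samples, truth


def simulate_host_mrna(
    circ_norm_matrix: JunctionCountMatrix,
    truth: pd.DataFrame,
    cfg: SimConfig,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Matched host-mRNA matrix with planted circRNA-host correlations.

    Takes the *normalized* circRNA matrix (post-filter). For each planted
    pair the host's log2 profile is ``rho * z + sqrt(1-rho^2) * eps`` with
    ``z`` the standardized log2 circRNA profile, scaled and shifted to a
    positive expression range. Returns (mRNA matrix on the expression
    scale, host_map circ_id -> gene_id, updated truth table).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 23]))
    ids = list(circ_norm_matrix.circ_ids)
    n_pairs_total = sum(n for n, _ in cfg.host_rho_sets)
    if n_pairs_total > len(ids):
        raise ConfigError(
            f"{n_pairs_total} host pairs exceed {len(ids)} available circRNAs"
        )
    x = np.log2(circ_norm_matrix.values.astype(float) + 1.0)
    sd = x.std(axis=1)
    usable = np.flatnonzero(sd > 0)
    if len(usable) < n_pairs_total:
        raise ConfigError("not enough non-constant circRNA profiles for host pairs")
    chosen = rng.permutation(usable)[:n_pairs_total]

    truth = truth.copy()
    n_samples = x.shape[1]
    host_rows, host_ids, host_map = [], [], {}
    cursor = 0
    for n_pairs, rho in cfg.host_rho_sets:
        rows = chosen[cursor : cursor + n_pairs]
        cursor += n_pairs
        for i in rows:
            cid = ids[i]
            z = (x[i] - x[i].mean()) / sd[i]
            eps = rng.standard_normal(n_samples)
            eps -= eps.mean()
            norm = np.linalg.norm(eps)
            if norm > 0:
                eps /= norm / np.sqrt(n_samples)
            mixed = rho * z + np.sqrt(max(0.0, 1.0 - rho * rho)) * eps
            mu_h = rng.normal(8.0, 1.0)  # log2 expression baseline
            gene = f"GENE{len(host_ids):05d}"
            host_ids.append(gene)
            # exp2 minus one, so log2(mrna + 1) is exactly mu_h + mixed and
            # planted correlations survive the standard log transform
            host_rows.append(np.maximum(2.0 ** (mu_h + mixed) - 1.0, 0.0))
            host_map[cid] = gene
            truth.loc[cid, "host_rho"] = rho
    mrna = pd.DataFrame(
        np.asarray(host_rows), index=host_ids, columns=circ_norm_matrix.sample_ids
    )
    logger.info("simulated %d host mRNA profiles", len(host_ids))
    return mrna, pd.Series(host_map, name="gene_id"), truth


def simulate_module_matrix(
    sizes: Sequence[int],
    n_noise: int,
    n_samples: int = 32,
    within_cor: float = 0.9,
    seed: int = 0,
) -> tuple[JunctionCountMatrix, pd.Series]:
    """Expression matrix with planted co-expression modules.

    Rows of module *m* share a latent sample profile with weight
    ``sqrt(within_cor)`` (pairwise correlation ~``within_cor`` within a
    module, ~0 across); ``n_noise`` unstructured rows are appended. Values
    are exponentiated from the latent log2 scale so the matrix is positive
    and ``log2(x + 1)`` downstream recovers the planted correlations.
    Returns the matrix and the truth labels (module number, 0 for noise).
    """
    rng = np.random.default_rng(seed)
    w = np.sqrt(within_cor)
    profiles, labels = [], []
    for m, size in enumerate(sizes, start=1):
        latent = rng.standard_normal(n_samples)
        for _ in range(size):
            profiles.append(w * latent + np.sqrt(1 - w * w) * rng.standard_normal(n_samples))
            labels.append(m)
    for _ in range(n_noise):
        profiles.append(rng.standard_normal(n_samples))
        labels.append(0)
    z = np.asarray(profiles)
    counts = 2.0 ** (z + 10.0) - 1.0  # positive; log2(.+1) == z + 10
    ids = [f"circ{m:05d}" for m in range(len(labels))]
    matrix = JunctionCountMatrix(
        counts=pd.DataFrame(counts, index=ids, columns=[f"S{j:02d}" for j in range(n_samples)])
    )
    return matrix, pd.Series(labels, index=ids, name="module")
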