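"""End-to-end orchestration: ingest -> filter -> normalize -> specificity
-> co-expression -> host correlation -> enrichment, with seeded
determinism and a machine-readable run report.

A single global seed fans out to per-stage seeds through fixed
``SeedSequence`` offsets, so each stage is individually reproducible and
two runs with the same configuration produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coexpression import adjacency, detect_modules, module_eigengene, tom_similarity
from .enrichment import enrich_gene_sets, read_gene_sets
from .errors import ConfigError
from .filtering import FilterConfig, apply_filter, expression_filter, outcomes_frame
from .host_correlation import classify_pairs, pair_correlations
from .io_formats import (
    JunctionCountMatrix,
    read_count_matrix,
    read_sample_table,
    write_count_matrix,
)
from .normalization import log2_fold_change, normalize, size_factors
from .specificity import compare_sets, group_biased, permutation_test, spatial_specific

logger = logging.getLogger("circage")


@dataclass
class PipelineConfig:
    count_matrix: str
    sample_table: str
    out_dir: str
    mrna_matrix: str | None = None
    host_map: str | None = None
    gene_sets: str | None = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    spatial_alpha: float = 0.01
    spatial_mode: str = "one_vs_rest"
    group_alpha: float = 0.05
    n_perm: int = 10000
    beta: int = 3
    min_module_size: int = 30
    cut_height: float = 0.25
    min_abs_pcc: float = 0.3
    max_p: float = 0.1
    log2_pseudocount: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("count_matrix", "sample_table"):
            path = getattr(self, name)
            if path is None or not Path(path).exists():
                raise ConfigError(f"{name} path missing or does not exist: {path}")
        for name in ("mrna_matrix", "host_map", "gene_sets"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ConfigError(f"{name} path does not exist: {path}")
        if not (0 < self.spatial_alpha < 1) or not (0 < self.group_alpha < 1):
            raise ConfigError("alphas must lie in (0, 1)")
        if self.n_perm < 1:
            raise ConfigError("n_perm must be >= 1")


def _stage_seed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence([int(seed), stage]).generate_state(1)[0] % (2**31))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and return the run report (also written to
    ``out_dir/run_report.json``)."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "parameters": asdict(cfg),
        "stages": {},
    }

    def stage(name):
        logger.info("=== stage: %s ===", name)
        return report["stages"].setdefault(name, {})

    # ingest -----------------------------------------------------------
    st = stage("ingest")
    matrix = read_count_matrix(cfg.count_matrix)
    samples = read_sample_table(cfg.sample_table)
    missing = set(matrix.sample_ids) - set(samples.sample_ids)
    if missing:
        raise ConfigError(f"matrix samples missing from sample table: {sorted(missing)}")
    st["n_circ"], st["n_samples"] = len(matrix.circ_ids), len(matrix.sample_ids)

    # expression filter ------------------------------------------------
    st = stage("expression_filter")
    outcomes = expression_filter(matrix, samples, cfg.filter)
    outcomes_frame(outcomes).to_csv(out / "filter_report.tsv", sep="\t")
    filtered = apply_filter(matrix, outcomes)
    st["n_kept"] = len(filtered.circ_ids)

    # normalization ----------------------------------------------------
    st = stage("normalization")
    sf = size_factors(filtered)
    sf.factors.rename("size_factor").to_csv(out / "size_factors.tsv", sep="\t")
    norm = normalize(filtered, sf)
    write_count_matrix(norm, out / "normalized_matrix.tsv")
    st["size_factor_range"] = [float(sf.factors.min()), float(sf.factors.max())]

    # specificity ------------------------------------------------------
    st = stage("specificity")
    spatial = spatial_specific(norm, samples, alpha=cfg.spatial_alpha, mode=cfg.spatial_mode)
    spatial.to_csv(out / "spatial_specific.tsv", sep="\t", index=False)
    st["n_spatial_called"] = int(spatial["called"].sum())
    for factor in ("sex", "age"):
        res = group_biased(norm, samples, factor, alpha=cfg.group_alpha)
        res["p_perm"] = permutation_test(
            norm, samples, factor, n_perm=cfg.n_perm,
            seed=_stage_seed(cfg.seed, {"sex": 41, "age": 42}[factor]),
        )
        res.index.name = "circ_id"
        res.to_csv(out / f"{factor}_biased.tsv", sep="\t")
        t_set = set(res.index[res["called"]])
        perm_set = set(res.index[res["p_perm"] < cfg.group_alpha])
        comp = compare_sets(t_set, perm_set)
        st[f"n_{factor}_called"] = len(t_set)
        st[f"n_{factor}_perm_called"] = len(perm_set)
        st[f"{factor}_overlap_ratio"] = comp.overlap_ratio
        fc = log2_fold_change(norm, samples, factor, pseudocount=cfg.log2_pseudocount)
        fc.index.name = "circ_id"
        fc.to_csv(out / f"{factor}_log2fc.tsv", sep="\t")
        st[f"{factor}_direction_counts"] = fc.attrs["direction_counts"]

    # co-expression ----------------------------------------------------
    st = stage("coexpression")
    x = np.log2(norm.values + 1.0)
    keep = x.std(axis=1) > 0
    nz = JunctionCountMatrix(counts=norm.counts.loc[np.asarray(keep)])
    adj = adjacency(nz, beta=cfg.beta)
    tom = tom_similarity(adj)
    assignment = detect_modules(tom, cfg.min_module_size, cfg.cut_height)
    assignment = module_eigengene(nz, assignment)
    assignment.labels.rename("module").to_csv(out / "modules.tsv", sep="\t")
    if len(assignment.eigengenes):
        assignment.eigengenes.to_csv(out / "eigengenes.tsv", sep="\t")
        assignment.eigengenes.T.corr().to_csv(out / "eigengene_correlation.tsv", sep="\t")
    st["n_modules"] = len(assignment.module_ids())
    st["n_unassigned"] = int((assignment.labels == 0).sum())

    # host correlation -------------------------------------------------
    age_called_hosts: set[str] = set()
    if cfg.mrna_matrix is not None and cfg.host_map is not None:
        st = stage("host_correlation")
        mrna = pd.read_csv(cfg.mrna_matrix, sep="\t", index_col=0)
        host_map = pd.read_csv(cfg.host_map, sep="\t", index_col=0)["gene_id"]
        circ_log = np.log2(norm.counts + cfg.log2_pseudocount)
        mrna_log = np.log2(mrna + cfg.log2_pseudocount)
        pairs = pair_correlations(circ_log, mrna_log, host_map)
        classified, summary = classify_pairs(pairs, cfg.min_abs_pcc, cfg.max_p)
        classified.to_csv(out / "host_correlation.tsv", sep="\t", index=False)
        st.update(asdict(summary) if hasattr(summary, "__dict__") else summary.__dict__)
        age_res = pd.read_csv(out / "age_biased.tsv", sep="\t", index_col="circ_id")
        age_called_hosts = set(
            host_map.reindex(age_res.index[age_res["called"]]).dropna()
        )

    # enrichment -------------------------------------------------------
    if cfg.gene_sets is not None and cfg.mrna_matrix is not None:
        st = stage("enrichment")
        host_map = pd.read_csv(cfg.host_map, sep="\t", index_col=0)["gene_id"]
        universe = set(host_map.dropna())
        query = age_called_hosts & universe
        if query:
            sets = read_gene_sets(cfg.gene_sets)
            enr = enrich_gene_sets(query, universe, sets)
            enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            st["n_sets_tested"] = len(enr)
            st["n_significant"] = int((enr["q_value"] <= 0.05).sum())
        else:
            st["n_sets_tested"] = 0

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete; report at %s", out / "run_report.json")
    return report
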