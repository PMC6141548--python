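"""Candidate read threshold and the five-rule expression-filter cascade.

The cascade defines which circRNAs are "well expressed" enough for
downstream analysis, removing loci seen only in sporadic samples at low
abundance:

1. a circRNA is *expressed in a sample* if it has >= 3 junction reads there;
2. a brain area is *expressed* if >= 2 of its samples pass rule 1;
3. keep the circRNA if >= 2 areas are expressed (route ``rule3``);
4. else keep it if exactly one area is expressed and >= 6 samples overall
   pass rule 1 (route ``rule4``);
5. else keep it if its total junction reads across all samples are >= 30
   (route ``rule5``).

Keeping is the disjunction of the three routes; the reported route label is
the first rule that fires in the order 3 -> 4 -> 5. Rule 4's sample count is
taken across all areas — with 4 samples per area, requiring 6 within a
single area would be unsatisfiable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError
from .io_formats import CircRecord, JunctionCountMatrix, SampleTable

logger = logging.getLogger("circage")


@dataclass(frozen=True)
class FilterConfig:
    min_candidate_reads: int = 2
    min_expressed_reads: int = 3
    min_samples_per_area: int = 2
    min_expressed_areas: int = 2
    min_expressed_samples_single_area: int = 6
    min_total_reads: int = 30

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")


@dataclass(frozen=True)
class FilterOutcome:
    circ_id: str
    kept: bool
    route: str  # rule3 | rule4 | rule5 | dropped
    expressed_samples: int
    expressed_areas: int
    total_reads: int


def candidate_filter(
    records: Iterable[CircRecord], min_reads: int = 2
) -> list[CircRecord]:
    """Retain per-sample calls with at least ``min_reads`` junction reads
    (the candidate threshold applied to each sample's predictions)."""
    out = [r for r in records if r.junction_reads >= min_reads]
    logger.info("candidate filter (>=%d reads): kept %d records", min_reads, len(out))
    return out


def expression_filter(
    matrix: JunctionCountMatrix,
    samples: SampleTable,
    cfg: FilterConfig = FilterConfig(),
) -> list[FilterOutcome]:
    """Evaluate the five-rule cascade for every row of the count matrix."""
    missing = set(matrix.sample_ids) - set(samples.sample_ids)
    if missing:
        raise FormatError(f"matrix sample(s) missing from sample table: {sorted(missing)}")

    counts = matrix.counts[matrix.sample_ids].to_numpy()
    regions = samples.data.loc[matrix.sample_ids, "region"].to_numpy()
    region_levels = pd.unique(regions)

    expressed = counts >= cfg.min_expressed_reads  # rule 1, per cell
    n_expr_samples = expressed.sum(axis=1)
    area_expressed = np.column_stack(
        [
            expressed[:, regions == area].sum(axis=1) >= cfg.min_samples_per_area
            for area in region_levels
        ]
    )  # rule 2, per area
    n_expr_areas = area_expressed.sum(axis=1)
    total = counts.sum(axis=1)

    via3 = n_expr_areas >= cfg.min_expressed_areas
    via4 = (n_expr_areas == 1) & (
        n_expr_samples >= cfg.min_expressed_samples_single_area
    )
    via5 = total >= cfg.min_total_reads

    outcomes = []
    for i, cid in enumerate(matrix.circ_ids):
        if via3[i]:
            route = "rule3"
        elif via4[i]:
            route = "rule4"
        elif via5[i]:
            route = "rule5"
        else:
            route = "dropped"
        outcomes.append(
            FilterOutcome(
                circ_id=cid,
                kept=route != "dropped",
                route=route,
                expressed_samples=int(n_expr_samples[i]),
                expressed_areas=int(n_expr_areas[i]),
                total_reads=int(total[i]),
            )
        )
    n_kept = sum(o.kept for o in outcomes)
    logger.info(
        "expression filter: kept %d/%d circRNAs (%s)",
        n_kept,
        len(outcomes),
        {r: sum(o.route == r for o in outcomes) for r in ("rule3", "rule4", "rule5")},
    )
    return outcomes


def kept_ids(outcomes: Sequence[FilterOutcome]) -> list[str]:
    return [o.circ_id for o in outcomes if o.kept]


def apply_filter(
    matrix: JunctionCountMatrix, outcomes: Sequence[FilterOutcome]
) -> JunctionCountMatrix:
    """Subset the matrix to kept rows, preserving order and row metadata."""
    keep = kept_ids(outcomes)
    meta = matrix.row_meta.loc[keep] if matrix.row_meta is not None else None
    return JunctionCountMatrix(counts=matrix.counts.loc[keep], row_meta=meta)


def outcomes_frame(outcomes: Sequence[FilterOutcome]) -> pd.DataFrame:
    """Tabular report: circ_id, kept, route, expressed_samples,
    expressed_areas, total_reads."""
    return pd.DataFrame([o.__dict__ for o in outcomes]).set_index("circ_id")
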