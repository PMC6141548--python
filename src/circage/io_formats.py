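"""Readers, writers and validated containers for every external table.

Coordinate convention
---------------------
Internally every interval is 0-based half-open, ``[start, end)``. The two
1-based inclusive dialects (CIRI2 back-splice tables, GTF gene models) are
converted at the boundary: printed ``start`` becomes ``start - 1``, printed
``end`` is kept (a 1-based inclusive end equals a 0-based exclusive end).
BED output needs no conversion.

A circRNA's identity is the exact tuple ``(chrom, start, end, strand)``,
rendered as the string ``"chrom:start|end:strand"`` with internal
coordinates. Strand ``.`` is permitted and is distinct from ``+``/``-``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, VocabularyError

logger = logging.getLogger("circage")

#: Closed vocabulary of the eight sampled brain compartments.
REGIONS = ("PFC", "PCC", "TC", "PC", "OC", "CA1", "DG", "CB")
SEXES = ("M", "F")
AGES = (10, 20)

STRANDS = ("+", "-", ".")


def format_circ_id(chrom: str, start: int, end: int, strand: str) -> str:
    return f"{chrom}:{start}|{end}:{strand}"


def parse_circ_id(circ_id: str) -> tuple[str, int, int, str]:
    """Invert :func:`format_circ_id`. Raises :class:`FormatError` on any
    malformed id."""
    try:
        chrom, span, strand = circ_id.rsplit(":", 2)
        start_s, end_s = span.split("|")
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise FormatError(f"malformed circ_id {circ_id!r}") from exc
    if strand not in STRANDS:
        raise FormatError(f"malformed circ_id {circ_id!r}: bad strand {strand!r}")
    if not (0 <= start < end):
        raise FormatError(f"malformed circ_id {circ_id!r}: need 0 <= start < end")
    return chrom, start, end, strand


@dataclass(frozen=True)
class CircRecord:
    """One back-splice junction call in one sample.

    ``junction_reads`` is the number of reads spanning the head-to-tail
    junction — the raw expression level of the circRNA in that sample.
    """

    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive, end > start
    strand: str
    junction_reads: int
    sample_id: str
    host_gene: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval [{self.start}, {self.end}) for {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise FormatError(f"invalid strand {self.strand!r}")
        if self.junction_reads < 0:
            raise FormatError("junction_reads must be >= 0")

    @property
    def circ_id(self) -> str:
        return format_circ_id(self.chrom, self.start, self.end, self.strand)


@dataclass
class SampleTable:
    """sample -> (region, sex, age) design with closed-vocabulary validation."""

    data: pd.DataFrame  # index sample_id; columns region, sex, age_years

    def __post_init__(self) -> None:
        df = self.data
        required = {"region", "sex", "age_years"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"sample table missing columns: {sorted(missing)}")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample_id(s): {dups}")
        for col, vocab in (("region", REGIONS), ("sex", SEXES), ("age_years", AGES)):
            bad = sorted(set(df[col]) - set(vocab))
            if bad:
                raise VocabularyError(
                    f"unknown {col} value(s) {bad}; allowed: {list(vocab)}"
                )
        df.index.name = "sample_id"

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def group_mask(self, factor: str, level) -> np.ndarray:
        """Boolean mask over samples (in table order) for one factor level."""
        col = {"region": "region", "sex": "sex", "age": "age_years"}[factor]
        return (self.data[col] == level).to_numpy()

    def levels(self, factor: str) -> list:
        col = {"region": "region", "sex": "sex", "age": "age_years"}[factor]
        return sorted(self.data[col].unique().tolist())


@dataclass
class JunctionCountMatrix:
    """circRNA x sample matrix of back-splice junction read counts.

    ``counts`` carries circ_ids on the index and sample_ids on the columns;
    values are non-negative and finite (integers for raw counts, reals after
    normalization). ``row_meta`` optionally carries per-circRNA annotation
    (host gene, genomic category) aligned to the index.
    """

    counts: pd.DataFrame
    row_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            raise FormatError("duplicate circ_id rows in count matrix")
        if c.columns.has_duplicates:
            raise FormatError("duplicate sample_id columns in count matrix")
        vals = c.to_numpy()
        if vals.size and (not np.isfinite(vals).all() or (vals < 0).any()):
            raise FormatError("counts must be finite and >= 0")
        if self.row_meta is not None and not self.row_meta.index.equals(c.index):
            raise FormatError("row_meta index does not match count matrix rows")
        c.index.name = "circ_id"
        c.columns.name = None

    @property
    def circ_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def values(self) -> np.ndarray:
        return self.counts.to_numpy()


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # 0-based half-open, sorted

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class GeneModelSet:
    """Gene models with a per-chromosome interval index over gene spans."""

    genes: dict[str, GeneModel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        from intervaltree import IntervalTree

        self._index: dict[str, "IntervalTree"] = {}
        for g in self.genes.values():
            tree = self._index.setdefault(g.chrom, IntervalTree())
            s, e = g.span
            tree.addi(s, e, g.gene_id)

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        tree = self._index.get(chrom)
        if tree is None:
            return []
        return [self.genes[iv.data] for iv in sorted(tree.overlap(start, end))]

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self._index

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# CIRI2-style per-sample junction tables
# ---------------------------------------------------------------------------

#: Column names required from each dialect. CIRI2 prints 1-based inclusive
#: coordinates; the minimal 6-column dialect does the same so that hand-made
#: tables follow the convention of the tool they stand in for.
_CIRI2_COLUMNS = {
    "circRNA_ID": "circ_id",
    "chr": "chrom",
    "circRNA_start": "start",
    "circRNA_end": "end",
    "#junction_reads": "junction_reads",
    "gene_id": "host_gene",
    "strand": "strand",
}
_MINIMAL_COLUMNS = {
    "chrom": "chrom",
    "start": "start",
    "end": "end",
    "strand": "strand",
    "junction_reads": "junction_reads",
    "gene_id": "host_gene",
}


def read_ciri_table(path, sample_id: str, dialect: str = "ciri2") -> list[CircRecord]:
    """Read one sample's back-splice junction calls.

    ``dialect="ciri2"`` expects CIRI2's tab-separated output (any extra
    columns are ignored); ``dialect="minimal"`` expects exactly the columns
    chrom, start, end, strand, junction_reads, gene_id. Both dialects print
    1-based inclusive coordinates, converted here to 0-based half-open.
    """
    colmaps = {"ciri2": _CIRI2_COLUMNS, "minimal": _MINIMAL_COLUMNS}
    if dialect not in colmaps:
        raise ValueError(f"unknown dialect {dialect!r}; use 'ciri2' or 'minimal'")
    colmap = colmaps[dialect]
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file (no header)") from exc
    missing = set(colmap) - set(df.columns)
    if missing:
        raise FormatError(
            f"{path}: missing column(s) {sorted(missing)} for dialect {dialect!r}"
        )
    if dialect == "minimal" and set(df.columns) != set(colmap):
        extra = sorted(set(df.columns) - set(colmap))
        raise FormatError(f"{path}: unexpected column(s) {extra} in minimal dialect")

    records: list[CircRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        rd = dict(zip(df.columns, row))
        try:
            start = int(rd[_key(colmap, "start")])
            end = int(rd[_key(colmap, "end")])
            reads = int(rd[_key(colmap, "junction_reads")])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}, line {i}: non-integer field ({exc})") from exc
        host = rd[_key(colmap, "host_gene")]
        if host is None or pd.isna(host) or host in ("", "n/a", "NA", "-"):
            host = None
        try:
            records.append(
                CircRecord(
                    chrom=str(rd[_key(colmap, "chrom")]),
                    start=start - 1,  # 1-based inclusive -> 0-based
                    end=end,
                    strand=str(rd[_key(colmap, "strand")]),
                    junction_reads=reads,
                    sample_id=sample_id,
                    host_gene=host,
                )
            )
        except FormatError as exc:
            raise FormatError(f"{path}, line {i}: {exc}") from exc
    logger.info("read %d junction records from %s (%s)", len(records), path, dialect)
    return records


def _key(colmap: dict, internal: str) -> str:
    return next(k for k, v in colmap.items() if v == internal)


def write_ciri_table(records: Sequence[CircRecord], path) -> None:
    """Write records in the minimal dialect (1-based inclusive coordinates)."""
    rows = [
        {
            "chrom": r.chrom,
            "start": r.start + 1,
            "end": r.end,
            "strand": r.strand,
            "junction_reads": r.junction_reads,
            "gene_id": r.host_gene if r.host_gene is not None else "NA",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(_MINIMAL_COLUMNS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Count matrix assembly and round-trip
# ---------------------------------------------------------------------------


def build_count_matrix(
    records: Iterable[CircRecord], samples: SampleTable
) -> JunctionCountMatrix:
    """Unify per-sample calls into one circRNA x sample count matrix.

    Rows are keyed by the exact locus tuple; loci are never merged across
    coordinate offsets here (tolerant matching lives in
    :func:`circage.annotation.match_circ_sets`). Absent cells are 0; rows are
    ordered lexicographically by circ_id, columns follow the sample table.
    """
    known = set(samples.sample_ids)
    cells: dict[tuple[str, str], int] = {}
    hosts: dict[str, str] = {}
    for r in records:
        if r.sample_id not in known:
            raise FormatError(f"record sample_id {r.sample_id!r} not in sample table")
        key = (r.circ_id, r.sample_id)
        if key in cells and cells[key] != r.junction_reads:
            raise FormatError(
                f"conflicting counts for {key[0]} in sample {key[1]}: "
                f"{cells[key]} vs {r.junction_reads}"
            )
        cells[key] = r.junction_reads
        if r.host_gene is not None:
            hosts.setdefault(r.circ_id, r.host_gene)

    row_ids = sorted({cid for cid, _ in cells})
    col_ids = samples.sample_ids
    mat = pd.DataFrame(0, index=row_ids, columns=col_ids, dtype=np.int64)
    for (cid, sid), n in cells.items():
        mat.at[cid, sid] = n
    meta = pd.DataFrame(
        {"host_gene": [hosts.get(cid) for cid in row_ids]}, index=row_ids
    )
    logger.info(
        "built count matrix: %d circRNAs x %d samples", len(row_ids), len(col_ids)
    )
    return JunctionCountMatrix(counts=mat, row_meta=meta)


def write_count_matrix(matrix: JunctionCountMatrix, path) -> None:
    """TSV with circ_id as first column; integers for counts, 6 significant
    digits for normalized values."""
    df = matrix.counts
    vals = df.to_numpy()
    is_int = np.issubdtype(vals.dtype, np.integer) or (
        vals.size > 0 and np.allclose(vals, np.round(vals))
    ) or vals.size == 0
    out = df.copy()
    out.index.name = "circ_id"
    if is_int:
        out = out.astype(np.int64)
        out.to_csv(path, sep="\t")
    else:
        out.to_csv(path, sep="\t", float_format="%.6g")


def read_count_matrix(path) -> JunctionCountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="circ_id")
    vals = df.to_numpy()
    if vals.size and np.allclose(vals, np.round(vals)):
        df = df.astype(np.int64)
    for cid in df.index:
        parse_circ_id(cid)  # validates every row id
    return JunctionCountMatrix(counts=df)


# ---------------------------------------------------------------------------
# Sample table
# ---------------------------------------------------------------------------


def read_sample_table(path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "region", "sex", "age_years"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    df = df.set_index("sample_id")
    table = SampleTable(data=df[["region", "sex", "age_years"]])
    logger.info("read sample table: %d samples from %s", len(df), path)
    return table


def write_sample_table(samples: SampleTable, path) -> None:
    out = samples.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Gene models (GTF)
# ---------------------------------------------------------------------------


def read_gene_models(path) -> GeneModelSet:
    """Load exon features from a GTF into per-gene sorted exon lists.

    GTF coordinates (1-based inclusive) are converted to 0-based half-open.
    Multiple transcripts per gene are flattened: duplicate exon intervals are
    kept once.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        if _gtf_is_empty(path):
            return GeneModelSet(genes={})
        raise FormatError(f"{path}: cannot parse GTF ({exc})") from exc

    per_gene: dict[str, dict] = {}
    for ex in db.features_of_type("exon"):
        if "gene_id" not in ex.attributes or not ex.attributes["gene_id"]:
            raise FormatError(f"{path}: exon at {ex.seqid}:{ex.start} missing gene_id")
        gid = ex.attributes["gene_id"][0]
        if ex.end < ex.start:
            raise FormatError(
                f"{path}: exon of {gid} has end < start ({ex.start}-{ex.end})"
            )
        entry = per_gene.setdefault(
            gid, {"chrom": ex.seqid, "strand": ex.strand or ".", "exons": set()}
        )
        entry["exons"].add((ex.start - 1, ex.end))  # GTF -> 0-based half-open
    genes = {
        gid: GeneModel(
            gene_id=gid,
            chrom=e["chrom"],
            strand=e["strand"],
            exons=tuple(sorted(e["exons"])),
        )
        for gid, e in per_gene.items()
    }
    logger.info("read %d gene models from %s", len(genes), path)
    return GeneModelSet(genes=genes)


def _gtf_is_empty(path) -> bool:
    try:
        with open(path) as fh:
            return all(not line.strip() or line.startswith("#") for line in fh)
    except OSError:
        return False


# ---------------------------------------------------------------------------
# BED output
# ---------------------------------------------------------------------------


def write_bed(records: Sequence[CircRecord] | Sequence[str], path, names=None) -> None:
    """Write circRNA loci as BED6 (0-based half-open, no conversion needed).

    Accepts CircRecords or circ_id strings; ``names`` optionally overrides
    the BED name field (e.g. a genomic category per circRNA).
    """
    lines = []
    for i, r in enumerate(records):
        if isinstance(r, CircRecord):
            chrom, start, end, strand = r.chrom, r.start, r.end, r.strand
            default_name = r.circ_id
        else:
            chrom, start, end, strand = parse_circ_id(r)
            default_name = r
        name = names[i] if names is not None else default_name
        lines.append(f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}\n")
    with open(path, "w") as fh:
        fh.writelines(lines)
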