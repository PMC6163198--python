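"""Readers and writers for every external table the pipeline touches.

All genomic coordinates are 1-based inclusive inside the package; the BED
convention (0-based, half-open) exists only at these I/O boundaries, so the
conversion happens in exactly one place in each direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

logger = logging.getLogger("cilioprior")

VARIANT_CLASSES = frozenset({"substitution", "indel"})


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """A parsed table violates one of its invariants."""


@dataclass(frozen=True)
class SnpRecord:
    """One risk variant: rsid, chromosome, 1-based position, variant class."""

    rsid: str
    chrom: str
    pos: int
    vclass: str = "substitution"

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError(f"{self.rsid}: position {self.pos} < 1")
        if self.vclass not in VARIANT_CLASSES:
            raise ValidationError(
                f"{self.rsid}: variant class {self.vclass!r} not in {sorted(VARIANT_CLASSES)}"
            )


@dataclass
class SnpTable:
    """A panel of risk SNPs with unique rsids."""

    records: list[SnpRecord] = field(default_factory=list)

    def __post_init__(self):
        seen: set[str] = set()
        for rec in self.records:
            if rec.rsid in seen:
                raise ValidationError(f"duplicate rsid {rec.rsid!r}")
            seen.add(rec.rsid)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class AnnotationTable:
    """Probe -> gene symbol -> genomic span mapping.

    One row per probe; a gene symbol may map to several probes, and a
    multi-locus symbol may carry one span per row.
    """

    frame: pd.DataFrame  # columns: probe_id, gene_symbol, chrom, gene_start, gene_end

    REQUIRED = ("probe_id", "gene_symbol", "chrom", "gene_start", "gene_end")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"annotation table missing columns {missing}")
        if self.frame["probe_id"].duplicated().any():
            dup = self.frame.loc[self.frame["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise ValidationError(f"duplicate probe_id {dup!r} in annotation")
        bad = self.frame["gene_start"] > self.frame["gene_end"]
        if bad.any():
            probe = self.frame.loc[bad, "probe_id"].iloc[0]
            raise ValidationError(f"probe {probe!r}: gene_start > gene_end")

    def __len__(self) -> int:
        return len(self.frame)


def read_snp_bed(path) -> SnpTable:
    """Read a BED file of risk SNPs into a 1-based :class:`SnpTable`.

    Columns: chrom, start (0-based), end (half-open), name; an optional fifth
    column flags the variant class (``indel`` or ``substitution``).  The
    1-based position of a record is ``start + 1`` (first affected base for
    indels).
    """
    path = Path(path)
    records: list[SnpRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected >=4 fields, got {len(fields)}")
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end <= start:
                raise ValidationError(f"{path}:{lineno}: end {end} <= start {start}")
            if len(fields) >= 5 and fields[4] in VARIANT_CLASSES:
                vclass = fields[4]
            else:
                # single-base records are substitutions unless flagged
                vclass = "substitution" if end - start == 1 else "indel"
            records.append(SnpRecord(rsid=name, chrom=chrom, pos=start + 1, vclass=vclass))
    if not records:
        logger.warning("SNP BED %s is empty", path)
    return SnpTable(records)


def write_snp_bed(snps: SnpTable, path) -> None:
    """Write SNPs back to BED (single-base interval per substitution)."""
    with open(path, "w") as fh:
        for rec in snps:
            span = 2 if rec.vclass == "indel" else 1
            fh.write(f"{rec.chrom}\t{rec.pos - 1}\t{rec.pos - 1 + span}\t{rec.rsid}\t{rec.vclass}\n")


def write_blocks_bed(blocks, path) -> None:
    """Write merged candidate blocks as BED, sorted by (chrom, start).

    Block coordinates are 1-based inclusive in memory, so the BED line is
    ``start - 1 .. end``.
    """
    if not blocks:
        raise ValidationError("refusing to write an empty block list")
    from .intervals import chrom_sort_key

    ordered = sorted(blocks, key=lambda b: (chrom_sort_key(b.chrom), b.start))
    with open(path, "w") as fh:
        for blk in ordered:
            fh.write(f"{blk.chrom}\t{blk.start - 1}\t{blk.end}\t{blk.label}\n")


def read_blocks_bed(path) -> list:
    """Read blocks written by :func:`write_blocks_bed` (member SNPs are not
    recoverable from BED and come back empty)."""
    from .intervals import GenomicBlock

    blocks = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected >=4 fields")
            chrom, start_s, end_s, label = fields[:4]
            blocks.append(
                GenomicBlock(label=label, chrom=chrom, start=int(start_s) + 1, end=int(end_s), member_snps=[])
            )
    return blocks


def read_expression_tsv(matrix_path, groups_path, name: str = ""):
    """Read a probes x samples log-expression TSV plus a sample->group table.

    The groups file has two columns (sample id, group label in {FTE, HGSOC}).
    Probe rows containing any missing value are dropped and counted in the
    log, so downstream testing sees finite values only.
    """
    from .de import ExpressionDataset

    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    try:
        mat = mat.astype(float)
    except ValueError as exc:
        raise ParseError(f"{matrix_path}: non-numeric expression cell ({exc})") from exc
    groups = pd.read_csv(groups_path, sep="\t", index_col=0).iloc[:, 0]
    missing_samples = [s for s in mat.columns if s not in groups.index]
    if missing_samples:
        raise ValidationError(f"{groups_path}: no group label for sample(s) {missing_samples}")
    extra = [s for s in groups.index if s not in mat.columns]
    if extra:
        raise ValidationError(f"{groups_path}: group file names absent sample(s) {extra}")
    n_before = len(mat)
    mat = mat.dropna(axis=0, how="any")
    dropped = n_before - len(mat)
    if dropped:
        logger.info("%s: dropped %d probe rows with missing values", matrix_path, dropped)
    return ExpressionDataset(matrix=mat, groups=groups.loc[mat.columns], name=name or str(matrix_path))


def write_expression_tsv(ds, matrix_path, groups_path) -> None:
    ds.matrix.to_csv(matrix_path, sep="\t", index_label="probe_id")
    ds.groups.rename("group").to_csv(groups_path, sep="\t", index_label="sample_id")


def read_annotation_tsv(path) -> AnnotationTable:
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return AnnotationTable(frame)


def write_annotation_tsv(annot: AnnotationTable, path) -> None:
    annot.frame.to_csv(path, sep="\t", index=False)


def read_ld_proxies_tsv(path) -> pd.DataFrame:
    """LD-proxy table: index_rsid, proxy_rsid, chrom, pos, r2 (r2 in [0, 1])."""
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"index_rsid", "proxy_rsid", "chrom", "pos", "r2"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"LD proxy table missing columns {sorted(missing)}")
    if ((frame["r2"] < 0) | (frame["r2"] > 1)).any():
        raise ValidationError("r2 outside [0, 1] in LD proxy table")
    return frame


def read_tissue_table_tsv(path, resource: str = "") -> pd.DataFrame:
    """Gene x tissue expression table; values must be nonnegative."""
    frame = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    if frame.columns.duplicated().any():
        raise ValidationError(f"{path}: duplicate tissue column")
    if (frame.to_numpy() < 0).any():
        raise ValidationError(f"{path}: negative expression value")
    frame.attrs["resource"] = resource or str(path)
    return frame


def read_reviewer_labels_tsv(path) -> pd.DataFrame:
    """Per-gene localization calls: gene_symbol, reviewer_a, reviewer_b,
    optional adjudication (empty when not adjudicated)."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene_symbol", "reviewer_a", "reviewer_b"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"reviewer label table missing columns {sorted(missing)}")
    if "adjudication" not in frame.columns:
        frame["adjudication"] = ""
    return frame


def load_table1() -> pd.DataFrame:
    """Load the packaged 28-gene candidate summary fixture.

    Columns: block_label, block_coords, gene_symbol, hpa_validation,
    localization (verbatim wording), subcellular.
    """
    with resources.files("cilioprior.data").joinpath("table1.tsv").open() as fh:
        frame = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    if len(frame) != 28:
        raise ValidationError(f"candidate fixture must have 28 rows, got {len(frame)}")
    return frame
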