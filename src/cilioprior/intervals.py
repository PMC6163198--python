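"""Merged candidate genomic blocks around risk SNPs, plus LD-proxy containment.

A block is the union of +/- ``flank`` windows around a single-linkage cluster
of SNPs: two SNPs on the same chromosome join one cluster iff they are
strictly less than ``merge_threshold`` bases apart (directly or through a
chain of intermediates).  Clusters are never merged merely because their
flanked blocks overlap — overlapping blocks are legitimate output.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .io import SnpTable, ValidationError

logger = logging.getLogger("cilioprior")


@dataclass(frozen=True)
class IntervalConfig:
    """Window and merge constants; defaults give the 2-Mb windows (1 Mb up-
    and downstream) and <1 Mb grouping used for the ovarian-cancer risk loci."""

    flank: int = 1_000_000
    merge_threshold: int = 1_000_000
    label_prefix: str = "GWAS_EOC_"

    def __post_init__(self):
        if self.flank <= 0:
            raise ValidationError("flank must be > 0")
        if self.merge_threshold <= 0:
            raise ValidationError("merge_threshold must be > 0")


@dataclass
class GenomicBlock:
    """A merged candidate interval (1-based inclusive) with its member SNPs."""

    label: str
    chrom: str
    start: int
    end: int
    member_snps: list[str] = field(default_factory=list)

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


_CHROM_RE = re.compile(r"^(chr)?(\d+|[XYM]|MT)$", re.IGNORECASE)


def chrom_sort_key(chrom: str):
    """Natural chromosome order: chr1 < chr2 < ... < chr10 < chrX < chrY."""
    m = _CHROM_RE.match(chrom)
    if m:
        body = m.group(2).upper()
        if body.isdigit():
            return (0, int(body), "")
        return (1, {"X": 0, "Y": 1, "M": 2, "MT": 2}[body], "")
    return (2, 0, chrom)


def build_blocks(snps: SnpTable, cfg: IntervalConfig = IntervalConfig()) -> list[GenomicBlock]:
    """Group SNPs by single-linkage on |pos_i - pos_j| < merge_threshold and
    flank each group to a block [min - flank, max + flank].

    On a per-chromosome sorted list, single-linkage reduces to chaining
    adjacent SNPs whose gap is strictly below the threshold, which equals the
    transitive closure of the pairwise relation.  Labels are assigned in
    genome order (chromosome, then start) for determinism.
    """
    if len(snps) == 0:
        raise ValidationError("cannot build blocks from an empty SNP table")
    by_chrom: dict[str, list] = {}
    for rec in snps:
        by_chrom.setdefault(rec.chrom, []).append(rec)

    raw_blocks = []
    for chrom in by_chrom:
        recs = sorted(by_chrom[chrom], key=lambda r: (r.pos, r.rsid))
        cluster = [recs[0]]
        for rec in recs[1:]:
            if rec.pos - cluster[-1].pos < cfg.merge_threshold:
                cluster.append(rec)
            else:
                raw_blocks.append((chrom, cluster))
                cluster = [rec]
        raw_blocks.append((chrom, cluster))

    raw_blocks.sort(key=lambda cb: (chrom_sort_key(cb[0]), cb[1][0].pos))
    blocks = []
    for ordinal, (chrom, cluster) in enumerate(raw_blocks, start=1):
        lo = min(r.pos for r in cluster)
        hi = max(r.pos for r in cluster)
        start = lo - cfg.flank
        if start < 1:
            logger.warning("block %s%d start clamped to 1 (flank ran off the chromosome)",
                           cfg.label_prefix, ordinal)
            start = 1
        blocks.append(
            GenomicBlock(
                label=f"{cfg.label_prefix}{ordinal}",
                chrom=chrom,
                start=start,
                end=hi + cfg.flank,
                member_snps=[r.rsid for r in cluster],
            )
        )
    return blocks


def check_ld_containment(
    blocks: list[GenomicBlock], proxies: pd.DataFrame, r2_min: float = 0.5
) -> pd.DataFrame:
    """Verify that every LD proxy (r2 >= r2_min) of an index SNP lies inside
    that SNP's block.

    Returns the proxy table restricted to proxies at or above the threshold,
    with a boolean ``contained`` column and the index SNP's block label;
    proxies below the threshold are ignored.
    """
    snp_to_block: dict[str, GenomicBlock] = {}
    for blk in blocks:
        for rsid in blk.member_snps:
            snp_to_block[rsid] = blk

    unknown = sorted(set(proxies["index_rsid"]) - set(snp_to_block))
    if unknown:
        raise ValidationError(f"index SNP(s) not in any block: {unknown}")

    kept = proxies.loc[proxies["r2"] >= r2_min].copy()
    labels, contained = [], []
    for row in kept.itertuples(index=False):
        blk = snp_to_block[row.index_rsid]
        labels.append(blk.label)
        contained.append(blk.contains(row.chrom, int(row.pos)))
    kept["block_label"] = labels
    kept["contained"] = contained
    n_viol = int((~pd.Series(contained, dtype=bool)).sum()) if contained else 0
    if n_viol:
        logger.warning("%d LD proxies fall outside their index SNP's block", n_viol)
    return kept
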