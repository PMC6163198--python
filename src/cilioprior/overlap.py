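"""Intersect concordant DE genes with the candidate blocks.

A concordant probe becomes a candidate hit for every block its gene span
overlaps by at least one base (1-based inclusive intervals on both sides);
overlapping blocks therefore yield one hit each, and a gene can legitimately
appear under two block labels.
"""

from __future__ import annotations

import logging

import pandas as pd
from intervaltree import IntervalTree

from .intervals import GenomicBlock
from .io import AnnotationTable

logger = logging.getLogger("cilioprior")

HIT_COLUMNS = [
    "probe_id", "gene_symbol", "block_label", "chrom", "gene_start", "gene_end",
    "logFC_a", "logFC_b", "q_a",
]


def assign_to_blocks(
    concordant: pd.DataFrame,
    annot: AnnotationTable,
    blocks: list[GenomicBlock],
) -> tuple[pd.DataFrame, list[str]]:
    """Map concordant probes to the blocks their gene spans overlap.

    Parameters
    ----------
    concordant
        Frame indexed by probe id with columns logFC_a, logFC_b, q_a (output
        of :func:`cilioprior.de.concordant_probes`).
    annot
        Probe -> gene -> span annotation; probes without a row are excluded
        with a warning and returned in the second element.

    Returns
    -------
    (hits, unannotated) where hits has one row per (probe, block) pair with
    >= 1-base overlap.
    """
    # interval trees per chromosome; +1 on end because IntervalTree is half-open
    trees: dict[str, IntervalTree] = {}
    for blk in blocks:
        trees.setdefault(blk.chrom, IntervalTree()).addi(blk.start, blk.end + 1, blk)

    ann = annot.frame.set_index("probe_id")
    rows, unannotated = [], []
    for probe in concordant.index:
        if probe not in ann.index:
            unannotated.append(probe)
            continue
        a = ann.loc[probe]
        tree = trees.get(str(a["chrom"]))
        if tree is None:
            continue
        for iv in sorted(tree.overlap(int(a["gene_start"]), int(a["gene_end"]) + 1),
                         key=lambda iv: iv.data.label):
            blk = iv.data
            rows.append({
                "probe_id": probe,
                "gene_symbol": a["gene_symbol"],
                "block_label": blk.label,
                "chrom": a["chrom"],
                "gene_start": int(a["gene_start"]),
                "gene_end": int(a["gene_end"]),
                "logFC_a": concordant.at[probe, "logFC_a"],
                "logFC_b": concordant.at[probe, "logFC_b"],
                "q_a": concordant.at[probe, "q_a"],
            })
    if unannotated:
        logger.warning("%d concordant probe(s) lack annotation and were excluded", len(unannotated))
    hits = pd.DataFrame(rows, columns=HIT_COLUMNS)
    return hits.sort_values(["block_label", "gene_symbol", "probe_id"]).reset_index(drop=True), unannotated


def dedupe_by_gene(hits: pd.DataFrame) -> pd.DataFrame:
    """Collapse probe-level hits to one record per (gene_symbol, block_label).

    The representative probe is the one with the smallest q in dataset A,
    ties broken by larger |logFC_a|, then lexicographic probe id.
    """
    if hits.empty:
        return hits.copy()
    ranked = hits.assign(_abs_lfc=-hits["logFC_a"].abs()).sort_values(
        ["q_a", "_abs_lfc", "probe_id"]
    )
    out = ranked.drop_duplicates(subset=["gene_symbol", "block_label"], keep="first")
    return (
        out.drop(columns="_abs_lfc")
        .sort_values(["block_label", "gene_symbol"])
        .reset_index(drop=True)
    )
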