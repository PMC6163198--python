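"""Two-reviewer subcellular-localization consensus and the block-level summary.

Immunohistochemistry images are read independently by two reviewers; each
calls one localization class per gene.  Agreement stands as-is; disagreement
is resolved by a joint adjudication label when one exists, and falls back to
"ambiguous" (flagged unresolved) when it does not.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum

logger = logging.getLogger("cilioprior")


class LocalizationClass(str, Enum):
    CILIATED = "ciliated"
    CILIATED_SUBSET = "ciliated_subset"  # positive in only some ciliated cells
    SEROUS = "serous"
    CILIATED_AND_SEROUS = "ciliated_and_serous"
    NOT_EXPRESSED = "not_expressed"
    AMBIGUOUS = "ambiguous"
    NOT_AVAILABLE = "not_available"


#: classes counting as "expressed in ciliated cells"
CILIATED_POSITIVE = frozenset({
    LocalizationClass.CILIATED,
    LocalizationClass.CILIATED_SUBSET,
    LocalizationClass.CILIATED_AND_SEROUS,
})

#: classes excluded from the "definite localization" tally
INDEFINITE = frozenset({
    LocalizationClass.AMBIGUOUS,
    LocalizationClass.NOT_AVAILABLE,
    LocalizationClass.NOT_EXPRESSED,
})

# free-text vocabulary of the published candidate table -> enum
_TEXT_TO_CLASS = {
    "ciliated cells": LocalizationClass.CILIATED,
    "ciliated cells (not all)": LocalizationClass.CILIATED_SUBSET,
    "serous": LocalizationClass.SEROUS,
    "serous cells": LocalizationClass.SEROUS,
    "serous and ciliated cells": LocalizationClass.CILIATED_AND_SEROUS,
    "ciliated and serous cells": LocalizationClass.CILIATED_AND_SEROUS,
    "not detected": LocalizationClass.NOT_EXPRESSED,
    "not expressed": LocalizationClass.NOT_EXPRESSED,
    "ambiguous": LocalizationClass.AMBIGUOUS,
    "not available": LocalizationClass.NOT_AVAILABLE,
}


def parse_localization(text: str) -> LocalizationClass:
    """Map a free-text localization call (table vocabulary or enum value) to
    its class."""
    key = text.strip().lower()
    if key in _TEXT_TO_CLASS:
        return _TEXT_TO_CLASS[key]
    try:
        return LocalizationClass(key)
    except ValueError:
        raise ValueError(f"unrecognized localization label {text!r}") from None


@dataclass(frozen=True)
class ConsensusRecord:
    gene_symbol: str
    cls: LocalizationClass
    block_label: str | None = None
    adjudicated: bool = False


@dataclass(frozen=True)
class SummaryCounts:
    """The headline tallies over consensus records.

    n_definite counts genes whose class is a definite localization (neither
    ambiguous, unavailable nor unexpressed); pct_blocks_ciliated is the
    percentage of all candidate blocks containing at least one
    ciliated-positive gene, truncated to a whole percent.
    """

    n_genes: int
    n_ambiguous: int
    n_not_available: int
    n_not_detected: int
    n_definite: int
    n_ciliated_positive: int
    n_distinct_blocks_ciliated: int
    pct_blocks_ciliated: int

    def __post_init__(self):
        if self.n_ambiguous + self.n_not_available + self.n_not_detected + self.n_definite != self.n_genes:
            raise ValueError("summary classes do not partition the gene set")
        if self.n_ciliated_positive > self.n_definite:
            raise ValueError("ciliated-positive genes must be a subset of definite ones")


def consensus_merge(
    labels_a: dict, labels_b: dict, adjudications: dict | None = None,
    block_labels: dict | None = None,
) -> tuple[list[ConsensusRecord], list[str]]:
    """Merge two reviewers' per-gene calls into consensus records.

    Inputs are gene -> LocalizationClass mappings (strings are parsed).
    Returns (records, unresolved) where unresolved lists genes on which the
    reviewers disagreed with no adjudication available.
    """
    adjudications = adjudications or {}
    block_labels = block_labels or {}
    only_a = set(labels_a) - set(labels_b)
    only_b = set(labels_b) - set(labels_a)
    if only_a or only_b:
        raise ValueError(
            f"reviewer tables cover different genes (only A: {sorted(only_a)}, only B: {sorted(only_b)})"
        )

    def _cls(v):
        return v if isinstance(v, LocalizationClass) else parse_localization(str(v))

    records, unresolved = [], []
    for gene in sorted(labels_a):
        a, b = _cls(labels_a[gene]), _cls(labels_b[gene])
        if a == b:
            cls, adjudicated = a, False
        elif gene in adjudications and str(adjudications[gene]).strip():
            cls, adjudicated = _cls(adjudications[gene]), True
        else:
            cls, adjudicated = LocalizationClass.AMBIGUOUS, False
            unresolved.append(gene)
        records.append(ConsensusRecord(gene, cls, block_labels.get(gene), adjudicated))
    if unresolved:
        logger.warning("%d gene(s) unresolved after review; classed ambiguous", len(unresolved))
    return records, unresolved


def summarize_localization(records: list[ConsensusRecord], total_blocks: int) -> SummaryCounts:
    """Tally consensus classes and the fraction of blocks hosting a
    ciliated-positive gene (floor of the whole percentage)."""
    if total_blocks <= 0:
        raise ValueError("total_blocks must be positive")
    n_amb = sum(r.cls is LocalizationClass.AMBIGUOUS for r in records)
    n_na = sum(r.cls is LocalizationClass.NOT_AVAILABLE for r in records)
    n_nd = sum(r.cls is LocalizationClass.NOT_EXPRESSED for r in records)
    n_def = sum(r.cls not in INDEFINITE for r in records)
    cil = [r for r in records if r.cls in CILIATED_POSITIVE]
    blocks = {r.block_label for r in cil if r.block_label is not None}
    missing_block = sum(1 for r in cil if r.block_label is None)
    if missing_block:
        logger.warning("%d ciliated-positive gene(s) lack a block label; excluded from block stats",
                       missing_block)
    return SummaryCounts(
        n_genes=len(records),
        n_ambiguous=n_amb,
        n_not_available=n_na,
        n_not_detected=n_nd,
        n_definite=n_def,
        n_ciliated_positive=len(cil),
        n_distinct_blocks_ciliated=len(blocks),
        pct_blocks_ciliated=math.floor(100 * len(blocks) / total_blocks),
    )
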