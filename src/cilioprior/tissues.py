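"""Tissue-specificity rank filter over two independent expression resources.

A candidate survives when, in each resource separately, at least one female
genital-tract tissue (cervix, endometrium, fallopian tube, ovary) occupies a
top-k expression rank for that gene.  Ranking is within-resource, so the two
resources' units (TPM-like vs FPKM-like) never need to be comparable.

Tie rule: a target tissue "occupies a top-k position" iff strictly fewer than
k non-target tissues exceed it; exact ties therefore never demote a target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("cilioprior")

DEFAULT_TARGETS = frozenset({"cervix", "endometrium", "fallopian tube", "ovary"})


@dataclass(frozen=True)
class RankConfig:
    """The shared tissue panel, the target (genital-tract) subset, and the
    rank cut-off k (the study used 25 shared tissues and k = 2)."""

    shared_tissues: tuple
    target_tissues: frozenset = DEFAULT_TARGETS
    k: int = 2

    def __post_init__(self):
        shared = set(self.shared_tissues)
        if len(shared) != len(self.shared_tissues):
            raise ValueError("shared_tissues contains duplicates")
        missing = set(self.target_tissues) - shared
        if missing:
            raise ValueError(f"target tissue(s) {sorted(missing)} not in shared_tissues")
        if not 1 <= self.k <= len(self.shared_tissues):
            raise ValueError("k must satisfy 1 <= k <= |shared_tissues|")


def align_tissues(
    tab_a: pd.DataFrame, tab_b: pd.DataFrame, cfg: RankConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict both gene x tissue tables to cfg.shared_tissues, identically
    column-ordered.  Errors name any tissue missing from either table."""
    for name, tab in (("first", tab_a), ("second", tab_b)):
        missing = [t for t in cfg.shared_tissues if t not in tab.columns]
        if missing:
            raise ValueError(f"{name} resource lacks shared tissue(s) {missing}")
    cols = list(cfg.shared_tissues)
    return tab_a[cols].copy(), tab_b[cols].copy()


def _target_top_k(row: pd.Series, cfg: RankConfig) -> tuple[bool, int]:
    """(passes, best_rank) for one aligned gene row in one resource.

    best_rank = 1 + the smallest count of non-target tissues strictly greater
    than some target tissue.
    """
    targets = [t for t in cfg.shared_tissues if t in cfg.target_tissues]
    non_targets = [t for t in cfg.shared_tissues if t not in cfg.target_tissues]
    nt_vals = row[non_targets].to_numpy(dtype=float)
    best = min(int((nt_vals > float(row[t])).sum()) for t in targets) + 1
    return best <= cfg.k, best


def passes_specificity(row_a: pd.Series, row_b: pd.Series, cfg: RankConfig) -> bool:
    """True iff a target tissue holds a top-k rank in BOTH resources.

    An all-zero row in either resource fails outright (the gene is
    unexpressed there, so "rank" would be meaningless)."""
    for row in (row_a, row_b):
        if float(np.max(row[list(cfg.shared_tissues)].to_numpy(dtype=float))) == 0.0:
            logger.info("gene %s unexpressed in one resource", row.name)
            return False
    return _target_top_k(row_a, cfg)[0] and _target_top_k(row_b, cfg)[0]


def specificity_filter(
    candidates, tab_a: pd.DataFrame, tab_b: pd.DataFrame, cfg: RankConfig
) -> tuple[list[str], pd.DataFrame]:
    """Filter candidate genes to those passing :func:`passes_specificity`.

    Genes absent from either table are logged and dropped.  Returns the
    surviving gene list plus a per-gene report with the best target-tissue
    rank in each resource.
    """
    tab_a, tab_b = align_tissues(tab_a, tab_b, cfg)
    passed, rows = [], []
    for gene in candidates:
        if gene not in tab_a.index or gene not in tab_b.index:
            logger.warning("gene %s missing from a tissue resource; dropped", gene)
            rows.append({"gene_symbol": gene, "rank_a": None, "rank_b": None,
                         "passed": False, "note": "missing"})
            continue
        row_a, row_b = tab_a.loc[gene], tab_b.loc[gene]
        ok = passes_specificity(row_a, row_b, cfg)
        _, rank_a = _target_top_k(row_a, cfg)
        _, rank_b = _target_top_k(row_b, cfg)
        rows.append({"gene_symbol": gene, "rank_a": rank_a, "rank_b": rank_b,
                     "passed": ok, "note": ""})
        if ok:
            passed.append(gene)
    report = pd.DataFrame(rows, columns=["gene_symbol", "rank_a", "rank_b", "passed", "note"])
    return passed, report
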