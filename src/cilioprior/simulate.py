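"""Synthetic inputs with planted ground truth for the whole funnel.

Every generator emulates one of the pipeline's external inputs at the scale
of the motivating study — a 76-SNP risk panel clustering into 54 blocks, a
10v10 and a 24v11 FTE/HGSOC expression pair with inverse-chi-square probe
variances, two 25-tissue expression resources with planted genital-tract-
specific genes, and two reviewers whose localization calls disagree at a
controlled rate.  One master seed drives everything through deterministic
per-generator substreams, so regenerating one input never perturbs another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .consensus import LocalizationClass
from .de import ExpressionDataset
from .intervals import GenomicBlock, IntervalConfig, build_blocks
from .io import AnnotationTable, SnpRecord, SnpTable

# substream ids: one per generator so streams are independent under one seed
_STREAM_SNP, _STREAM_EXPR, _STREAM_TISSUE, _STREAM_REVIEW, _STREAM_CLASS = range(1, 6)


def _default_cluster_sizes() -> tuple:
    # 54 clusters over 76 SNPs, like the study panel: mostly singletons with
    # a tail of multi-SNP loci
    return tuple([4, 3] + [2] * 17 + [1] * 35)


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic study; defaults mirror the real one."""

    seed: int = 0
    # SNP panel
    cluster_sizes: tuple = field(default_factory=_default_cluster_sizes)
    n_indels: int = 6
    chrom_lengths: dict = field(default_factory=lambda: {f"chr{i}": 200_000_000 for i in range(1, 23)})
    merge_threshold: int = 1_000_000
    flank: int = 1_000_000
    # expression pair
    n_probes: int = 2000
    frac_de: float = 0.05
    logfc_effect: float = 2.0
    d0: float = 4.0
    s0_sq: float = 0.05
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    dataset_sizes: tuple = ((10, 10), (24, 11))  # (n FTE, n HGSOC) per dataset
    frac_de_in_blocks: float = 0.5
    # tissue resources
    n_tissues: int = 25
    n_target_specific: int = 28
    rank_k: int = 2
    # reviewers
    discordance_rate: float = 0.3

    @property
    def n_snps(self) -> int:
        return int(sum(self.cluster_sizes))

    def __post_init__(self):
        if not 0 <= self.frac_de <= 1:
            raise ValueError("frac_de must be in [0, 1]")
        if not 0 <= self.discordance_rate <= 1:
            raise ValueError("discordance_rate must be in [0, 1]")
        if any(s < 1 for s in self.cluster_sizes):
            raise ValueError("cluster sizes must be >= 1")


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


TARGET_TISSUES = ("cervix", "endometrium", "fallopian tube", "ovary")
OTHER_TISSUES = (
    "adipose", "adrenal gland", "bladder", "brain", "breast", "colon",
    "esophagus", "heart", "kidney", "liver", "lung", "pancreas", "pituitary",
    "prostate", "salivary gland", "skeletal muscle", "skin", "small intestine",
    "spleen", "stomach", "thyroid", "testis", "whole blood",
)


def tissue_panel(cfg: SimConfig) -> tuple:
    if cfg.n_tissues < len(TARGET_TISSUES) + cfg.rank_k:
        raise ValueError("need at least |targets| + k tissues")
    extra = cfg.n_tissues - len(TARGET_TISSUES)
    if extra > len(OTHER_TISSUES):
        raise ValueError("tissue panel too large for the built-in name pool")
    return TARGET_TISSUES + OTHER_TISSUES[:extra]


def gen_snp_panel(cfg: SimConfig = SimConfig()) -> tuple[SnpTable, list[list[str]]]:
    """Place SNP clusters so that single-linkage grouping at the merge
    threshold recovers exactly the planted partition.

    Intra-cluster gaps are drawn strictly below the merge threshold;
    consecutive clusters on a chromosome are separated by at least the
    threshold, so no two clusters ever merge.
    """
    rng = _rng(cfg, _STREAM_SNP)
    chroms = sorted(cfg.chrom_lengths, key=lambda c: int(c.replace("chr", "")))
    cursors = {c: 2_000_000 for c in chroms}
    records: list[SnpRecord] = []
    partition: list[list[str]] = []
    counter = 0
    for ci, size in enumerate(cfg.cluster_sizes):
        chrom = chroms[ci % len(chroms)]
        pos = cursors[chrom] + int(rng.integers(0, 3_000_000))
        members = []
        for _ in range(size):
            counter += 1
            rsid = f"rs{100000 + counter}"
            records.append(SnpRecord(rsid=rsid, chrom=chrom, pos=pos))
            members.append(rsid)
            pos += int(rng.integers(1, cfg.merge_threshold))  # strictly < threshold
        if pos > cfg.chrom_lengths[chrom]:
            raise ValueError(f"cluster spec infeasible: ran past the end of {chrom}")
        # >= threshold to the next cluster on this chromosome: never merges
        cursors[chrom] = pos + cfg.merge_threshold
        partition.append(members)
    if cfg.n_indels > len(records):
        raise ValueError("more indels requested than SNPs")
    indel_idx = rng.choice(len(records), size=cfg.n_indels, replace=False)
    for i in indel_idx:
        r = records[i]
        records[i] = SnpRecord(rsid=r.rsid, chrom=r.chrom, pos=r.pos, vclass="indel")
    return SnpTable(records), partition


def gen_expression_pair(
    cfg: SimConfig = SimConfig(), blocks: list[GenomicBlock] | None = None
) -> tuple[list[ExpressionDataset], AnnotationTable, dict]:
    """Two log2 expression datasets with a shared planted DE set, plus the
    probe annotation and the ground truth.

    Per-probe variances follow the scaled inverse chi-square prior
    sigma^2 = s0^2 * d0 / chi2_{d0}; planted DE probes are shifted by
    +/- logfc_effect in the HGSOC group, with the same sign in both datasets.
    Gene coordinates are laid out so that a configured fraction of DE genes
    falls inside the candidate blocks (when blocks are supplied).
    """
    rng = _rng(cfg, _STREAM_EXPR)
    probes = [f"P{i:05d}" for i in range(1, cfg.n_probes + 1)]
    genes = [f"G{i:05d}" for i in range(1, cfg.n_probes + 1)]

    n_de = int(round(cfg.frac_de * cfg.n_probes))
    de_idx = rng.choice(cfg.n_probes, size=n_de, replace=False)
    signs = rng.choice([-1, 1], size=n_de)
    de_signs = {probes[i]: int(s) for i, s in zip(de_idx, signs)}

    datasets = []
    for d, (n1, n2) in enumerate(cfg.dataset_sizes):
        baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_probes)
        sigma2 = cfg.s0_sq * cfg.d0 / rng.chisquare(cfg.d0, size=cfg.n_probes)
        shift = np.zeros(cfg.n_probes)
        shift[de_idx] = signs * cfg.logfc_effect
        n = n1 + n2
        noise = rng.normal(size=(cfg.n_probes, n)) * np.sqrt(sigma2)[:, None]
        mat = baseline[:, None] + noise
        mat[:, n1:] += shift[:, None]
        samples = [f"D{d}_FTE_{i}" for i in range(n1)] + [f"D{d}_HGSOC_{i}" for i in range(n2)]
        groups = pd.Series(["FTE"] * n1 + ["HGSOC"] * n2, index=samples)
        datasets.append(
            ExpressionDataset(
                matrix=pd.DataFrame(mat, index=pd.Index(probes, name="probe_id"), columns=samples),
                groups=groups,
                name=f"synthetic_ds{d}",
            )
        )

    # gene placement: chosen DE genes inside blocks, everything else well away
    in_block_probes: set[str] = set()
    rows = []
    blocks = blocks or []
    max_end_per_chrom: dict[str, int] = {}
    for blk in blocks:
        max_end_per_chrom[blk.chrom] = max(max_end_per_chrom.get(blk.chrom, 0), blk.end)
    if blocks:
        n_in = int(round(cfg.frac_de_in_blocks * n_de))
        chosen = rng.choice(n_de, size=n_in, replace=False)
        in_block_probes = {probes[de_idx[j]] for j in chosen}
    outside_chroms = sorted({b.chrom for b in blocks}) or ["chr1"]
    out_counter = 0
    for i, probe in enumerate(probes):
        if probe in in_block_probes:
            blk = blocks[int(rng.integers(0, len(blocks)))]
            start = int(rng.integers(blk.start, blk.end - 10_000))
            rows.append((probe, genes[i], blk.chrom, start, start + 10_000))
        else:
            chrom = outside_chroms[out_counter % len(outside_chroms)]
            base = max_end_per_chrom.get(chrom, 0) + 5_000_000 + 20_000 * (out_counter // len(outside_chroms))
            rows.append((probe, genes[i], chrom, base, base + 10_000))
            out_counter += 1
    annot = AnnotationTable(
        pd.DataFrame(rows, columns=["probe_id", "gene_symbol", "chrom", "gene_start", "gene_end"])
    )
    truth = {
        "de_signs": de_signs,
        "de_in_blocks": sorted(in_block_probes),
        "probe_to_gene": dict(zip(probes, genes)),
    }
    return datasets, annot, truth


def gen_tissue_tables(
    cfg: SimConfig, genes: list[str], specific_genes: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Two gene x tissue tables with a planted genital-tract-specific set.

    Planted genes carry a target tissue as the row maximum in BOTH resources;
    background genes have every target tissue below all non-target tissues,
    so their best target rank is k+1 or worse everywhere.
    """
    rng = _rng(cfg, _STREAM_TISSUE)
    tissues = tissue_panel(cfg)
    targets = [t for t in tissues if t in TARGET_TISSUES]
    non_targets = [t for t in tissues if t not in TARGET_TISSUES]
    if specific_genes is None:
        n_spec = min(cfg.n_target_specific, len(genes))
        specific_genes = [genes[i] for i in sorted(rng.choice(len(genes), size=n_spec, replace=False))]
    spec_set = set(specific_genes)

    tables = []
    for _ in range(2):
        vals = rng.gamma(2.0, 5.0, size=(len(genes), len(tissues)))
        tab = pd.DataFrame(vals, index=pd.Index(genes, name="gene_symbol"), columns=list(tissues))
        for gene in genes:
            if gene in spec_set:
                t = targets[int(rng.integers(0, len(targets)))]
                tab.loc[gene, t] = float(tab.loc[gene].max()) * 1.5 + 1.0
            else:
                floor = float(tab.loc[gene, non_targets].min())
                tab.loc[gene, targets] = floor * rng.uniform(0.1, 0.9, size=len(targets))
        tables.append(tab)
    return tables[0], tables[1], sorted(spec_set)


_CLASS_WEIGHTS = {
    # composition of the published 28-gene candidate table
    LocalizationClass.CILIATED: 7,
    LocalizationClass.CILIATED_SUBSET: 3,
    LocalizationClass.CILIATED_AND_SEROUS: 2,
    LocalizationClass.SEROUS: 1,
    LocalizationClass.NOT_EXPRESSED: 1,
    LocalizationClass.AMBIGUOUS: 11,
    LocalizationClass.NOT_AVAILABLE: 3,
}


def gen_true_classes(cfg: SimConfig, genes: list[str]) -> dict:
    """Draw a true localization class per gene with the frequency profile of
    the published candidate set."""
    rng = _rng(cfg, _STREAM_CLASS)
    classes = list(_CLASS_WEIGHTS)
    w = np.array([_CLASS_WEIGHTS[c] for c in classes], dtype=float)
    draw = rng.choice(len(classes), size=len(genes), p=w / w.sum())
    return {g: classes[i] for g, i in zip(genes, draw)}


def gen_reviewer_labels(cfg: SimConfig, true_classes: dict) -> tuple[dict, dict, dict]:
    """Reviewer A reports the truth; reviewer B flips each call to a random
    other class at the discordance rate; every flip carries an adjudication
    equal to the truth, so consensus always recovers it."""
    rng = _rng(cfg, _STREAM_REVIEW)
    all_classes = list(LocalizationClass)
    labels_a, labels_b, adjudications = {}, {}, {}
    for gene in sorted(true_classes):
        truth = true_classes[gene]
        labels_a[gene] = truth
        if rng.random() < cfg.discordance_rate:
            others = [c for c in all_classes if c is not truth]
            labels_b[gene] = others[int(rng.integers(0, len(others)))]
            adjudications[gene] = truth
        else:
            labels_b[gene] = truth
    return labels_a, labels_b, adjudications


def write_simulated_inputs(cfg: SimConfig, outdir) -> dict:
    """Generate every pipeline input under ``outdir`` in the exact file
    formats the pipeline consumes, plus the ground truth as JSON.

    Returns a manifest of the written paths and the ground truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    snps, partition = gen_snp_panel(cfg)
    icfg = IntervalConfig(flank=cfg.flank, merge_threshold=cfg.merge_threshold)
    blocks = build_blocks(snps, icfg)
    datasets, annot, truth = gen_expression_pair(cfg, blocks)

    de_in_block_genes = sorted(truth["probe_to_gene"][p] for p in truth["de_in_blocks"])
    n_spec = min(cfg.n_target_specific, len(de_in_block_genes))
    rng = _rng(cfg, _STREAM_TISSUE)
    spec_genes = [de_in_block_genes[i]
                  for i in sorted(rng.choice(len(de_in_block_genes), size=n_spec, replace=False))]
    genes = sorted(set(annot.frame["gene_symbol"]))
    tab_a, tab_b, specific = gen_tissue_tables(cfg, genes, specific_genes=spec_genes)

    true_classes = gen_true_classes(cfg, genes)
    labels_a, labels_b, adjudications = gen_reviewer_labels(cfg, true_classes)

    cio.write_snp_bed(snps, outdir / "snps.bed")
    paths = {"snps": str(outdir / "snps.bed"), "expression": []}
    for i, ds in enumerate(datasets):
        mp, gp = outdir / f"expr_{i}.tsv", outdir / f"groups_{i}.tsv"
        cio.write_expression_tsv(ds, mp, gp)
        paths["expression"].append({"name": ds.name, "matrix": str(mp), "groups": str(gp)})
    cio.write_annotation_tsv(annot, outdir / "annot.tsv")
    paths["annotation"] = str(outdir / "annot.tsv")
    tab_a.to_csv(outdir / "tissue_a.tsv", sep="\t")
    tab_b.to_csv(outdir / "tissue_b.tsv", sep="\t")
    paths["tissue_a"], paths["tissue_b"] = str(outdir / "tissue_a.tsv"), str(outdir / "tissue_b.tsv")
    labels = pd.DataFrame({
        "gene_symbol": sorted(labels_a),
        "reviewer_a": [labels_a[g].value for g in sorted(labels_a)],
        "reviewer_b": [labels_b[g].value for g in sorted(labels_a)],
        "adjudication": [adjudications.get(g, LocalizationClass.AMBIGUOUS).value
                         if g in adjudications else "" for g in sorted(labels_a)],
    })
    labels.to_csv(outdir / "labels.tsv", sep="\t", index=False)
    paths["ihc_labels"] = str(outdir / "labels.tsv")
    with open(outdir / "tissues.yaml", "w") as fh:
        yaml.safe_dump({
            "shared_tissues": list(tissue_panel(cfg)),
            "target_tissues": list(TARGET_TISSUES),
            "k": cfg.rank_k,
        }, fh)
    paths["tissues"] = str(outdir / "tissues.yaml")

    ground_truth = {
        "snp_partition": partition,
        "n_clusters": len(partition),
        "de_signs": truth["de_signs"],
        "de_in_blocks": truth["de_in_blocks"],
        "specific_genes": specific,
        "true_classes": {g: c.value for g, c in true_classes.items()},
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(ground_truth, fh, indent=1)
    paths["truth"] = str(outdir / "truth.json")
    return {"paths": paths, "truth": ground_truth}
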