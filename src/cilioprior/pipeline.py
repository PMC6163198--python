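"""End-to-end orchestration: SNPs -> blocks -> DE x2 -> concordance ->
block overlap -> tissue-rank filter -> localization summary.

Everything is driven by one YAML config; every effective threshold is echoed
into the machine-readable funnel report, and the run is fully deterministic
given the same inputs and config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as cio
from .consensus import consensus_merge, summarize_localization
from .de import DeThresholds, concordant_probes, fit_moderated_t
from .intervals import IntervalConfig, build_blocks, check_ld_containment
from .overlap import assign_to_blocks, dedupe_by_gene
from .tissues import RankConfig, specificity_filter

logger = logging.getLogger("cilioprior")

__version__ = "0.1.0"

ALL_STAGES = ("blocks", "de", "concord", "overlap", "rankfilter", "ihc")

DEFAULT_THRESHOLDS = {
    "flank": 1_000_000,
    "merge_lt": 1_000_000,
    "r2_min": 0.5,
    "alpha_q": 0.05,
    "min_abs_logfc": 1.0,
    "k": 2,
    "de_method": "moderated",
}


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class FunnelReport:
    """Per-stage record counts plus full provenance (config echo, version,
    input digests)."""

    counts: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    version: str = __version__

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"version": self.version, "counts": self.counts,
                 "thresholds": self.thresholds, "config": self.config,
                 "input_digests": self.input_digests, "warnings": self.warnings},
                fh, indent=1, sort_keys=True,
            )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "inputs" not in cfg:
        raise ValueError(f"{path}: config must be a mapping with an 'inputs' section")
    return cfg


def run_pipeline(config, outdir=None) -> FunnelReport:
    """Run the requested stages in order and write every stage output.

    ``config`` is a mapping (or a YAML path) with sections ``inputs``,
    optional ``thresholds`` (defaults are the study's constants) and optional
    ``stages`` (default: all).  Later stages requiring an earlier stage's
    output fail with a :class:`StageError` naming the missing piece.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    inputs = config["inputs"]
    th = {**DEFAULT_THRESHOLDS, **(config.get("thresholds") or {})}
    stages = tuple(config.get("stages") or ALL_STAGES)
    outdir = Path(outdir or config.get("outdir") or "cilioprior_out")
    outdir.mkdir(parents=True, exist_ok=True)

    report = FunnelReport(thresholds=th, config=config)
    for key, val in inputs.items():
        if isinstance(val, str) and Path(val).is_file():
            report.input_digests[key] = _sha256(val)
        elif isinstance(val, list):
            for entry in val:
                for sub, p in entry.items():
                    if sub != "name" and Path(str(p)).is_file():
                        report.input_digests[f"{key}.{entry.get('name', '?')}.{sub}"] = _sha256(p)

    blocks = None
    concordant = None
    candidates = None
    shortlist_genes = None
    gene_to_block: dict[str, str] = {}

    def _stage(name):
        return name in stages

    try:
        if _stage("blocks"):
            snps = cio.read_snp_bed(inputs["snps"])
            icfg = IntervalConfig(flank=int(th["flank"]), merge_threshold=int(th["merge_lt"]))
            blocks = build_blocks(snps, icfg)
            cio.write_blocks_bed(blocks, outdir / "blocks.bed")
            report.counts["n_snps"] = len(snps)
            report.counts["n_blocks"] = len(blocks)
            if inputs.get("ld"):
                proxies = cio.read_ld_proxies_tsv(inputs["ld"])
                ld = check_ld_containment(blocks, proxies, r2_min=float(th["r2_min"]))
                n_viol = int((~ld["contained"]).sum())
                report.counts["n_ld_proxies_checked"] = int(len(ld))
                report.counts["n_ld_violations"] = n_viol
                ld.to_csv(outdir / "ld_containment.tsv", sep="\t", index=False)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage 'blocks' failed on {inputs.get('snps')}: {exc}") from exc

    sig_tables = []
    if _stage("de"):
        try:
            shrink = th["de_method"] != "plain"
            dth = DeThresholds(alpha_q=float(th["alpha_q"]), min_abs_logfc=float(th["min_abs_logfc"]))
            for i, entry in enumerate(inputs["expression"]):
                ds = cio.read_expression_tsv(entry["matrix"], entry["groups"],
                                             name=entry.get("name", f"ds{i}"))
                res = fit_moderated_t(ds, shrink=shrink)
                res.table.to_csv(outdir / f"de_{i}.tsv", sep="\t")
                sig = res.significant(dth)
                sig_tables.append(sig)
                report.counts[f"n_significant_{ds.name}"] = int(len(sig))
        except Exception as exc:
            raise StageError(f"stage 'de' failed: {exc}") from exc

    if _stage("concord"):
        try:
            if len(sig_tables) != 2:
                raise ValueError("concordance needs exactly two DE datasets")
            concordant = concordant_probes(sig_tables[0], sig_tables[1])
            concordant.to_csv(outdir / "concordant.tsv", sep="\t")
            report.counts["n_concordant"] = int(len(concordant))
        except Exception as exc:
            raise StageError(f"stage 'concord' failed: {exc}") from exc

    if _stage("overlap"):
        try:
            if blocks is None or concordant is None:
                raise ValueError("overlap requires the blocks and concord stages")
            annot = cio.read_annotation_tsv(inputs["annotation"])
            hits, unannotated = assign_to_blocks(concordant, annot, blocks)
            candidates = dedupe_by_gene(hits)
            candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
            report.counts["n_block_resident_genes"] = int(candidates["gene_symbol"].nunique())
            report.counts["n_block_resident_records"] = int(len(candidates))
            if unannotated:
                report.warnings.append(f"{len(unannotated)} unannotated probes excluded")
            gene_to_block = dict(zip(candidates["gene_symbol"], candidates["block_label"]))
        except Exception as exc:
            raise StageError(f"stage 'overlap' failed: {exc}") from exc

    if _stage("rankfilter"):
        try:
            if candidates is None:
                raise ValueError("rankfilter requires the overlap stage")
            with open(inputs["tissues"]) as fh:
                tcfg_raw = yaml.safe_load(fh)
            rcfg = RankConfig(
                shared_tissues=tuple(tcfg_raw["shared_tissues"]),
                target_tissues=frozenset(tcfg_raw.get("target_tissues",
                                                      ("cervix", "endometrium", "fallopian tube", "ovary"))),
                k=int(tcfg_raw.get("k", th["k"])),
            )
            tab_a = cio.read_tissue_table_tsv(inputs["tissue_a"], "resource_a")
            tab_b = cio.read_tissue_table_tsv(inputs["tissue_b"], "resource_b")
            genes = sorted(candidates["gene_symbol"].unique())
            shortlist_genes, rank_report = specificity_filter(genes, tab_a, tab_b, rcfg)
            rank_report.to_csv(outdir / "shortlist.tsv", sep="\t", index=False)
            report.counts["n_shortlist"] = len(shortlist_genes)
        except Exception as exc:
            raise StageError(f"stage 'rankfilter' failed: {exc}") from exc

    if _stage("ihc"):
        try:
            labels = cio.read_reviewer_labels_tsv(inputs["ihc_labels"])
            if shortlist_genes is not None:
                labels = labels.loc[labels["gene_symbol"].isin(shortlist_genes)]
            labels_a = dict(zip(labels["gene_symbol"], labels["reviewer_a"]))
            labels_b = dict(zip(labels["gene_symbol"], labels["reviewer_b"]))
            adj = {g: a for g, a in zip(labels["gene_symbol"], labels["adjudication"]) if a.strip()}
            if not gene_to_block and "block_label" in labels.columns:
                gene_to_block = dict(zip(labels["gene_symbol"], labels["block_label"]))
            records, unresolved = consensus_merge(labels_a, labels_b, adj, gene_to_block or None)
            total_blocks = int(inputs.get("total_blocks") or report.counts.get("n_blocks") or 0)
            summary = summarize_localization(records, total_blocks)
            report.counts["localization_summary"] = summary.__dict__
            with open(outdir / "summary.json", "w") as fh:
                json.dump(summary.__dict__, fh, indent=1)
            if unresolved:
                report.warnings.append(f"{len(unresolved)} unresolved reviewer disagreements")
        except Exception as exc:
            raise StageError(f"stage 'ihc' failed: {exc}") from exc

    report.to_json(outdir / "report.json")
    return report
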