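"""End-to-end orchestration: synth -> classify -> synteny -> features ->
relationship statistics, driven by one YAML config, with a reproducible
report directory."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import OriginCall, classify_bundle
from .config import PipelineConfig
from .features import (
    build_feature_table,
    build_group_table,
    build_system_table,
    predict_targets,
)
from .report import accuracy_matrix, fig1_counts, intersection_matrix
from .synteny import (
    build_anchors,
    chain_anchors,
    cluster_protein_families,
    protein_family_ids,
    segmental_mirna_pairs,
    tandem_gene_arrays,
)
from .synth import Bundle, SynthConfig, generate_genome

log = logging.getLogger("mirorigin")

__all__ = ["PipelineResult", "run_bundle", "run_all", "load_run_config"]

REPORT_FILES = (
    "calls.tsv",
    "blocks.tsv",
    "features.tsv",
    "fig1_counts.tsv",
    "fig2A.tsv",
    "fig2B.tsv",
    "table1.tsv",
    "table2.tsv",
)


@dataclass
class PipelineResult:
    bundle: Bundle
    calls: list[OriginCall]
    chains: list
    features: pd.DataFrame
    fig1: pd.DataFrame
    fig2a: pd.DataFrame
    fig2b: pd.DataFrame
    table1: pd.DataFrame
    table2: pd.DataFrame
    blocks: pd.DataFrame


def _stage(name: str):
    log.info("stage: %s", name)
    return time.time()


def run_bundle(bundle: Bundle, cfg: PipelineConfig = PipelineConfig()) -> PipelineResult:
    """Run every analysis stage over an annotation bundle."""
    t = _stage("targets")
    target_sites = {
        m.id: predict_targets(m.mature_seq, bundle.genes, cfg.target_max_score)
        for m in bundle.mirnas
    }

    _stage("synteny")
    family_sizes = cluster_protein_families(bundle.genes)
    family_ids = protein_family_ids(bundle.genes)
    anchors = build_anchors(bundle.genes, cfg)
    chains = chain_anchors(
        anchors,
        cfg.chain_gap_penalty,
        cfg.min_anchors,
        cfg.max_gap_genes,
        cfg.min_chain_score,
    )
    sd_pairs = segmental_mirna_pairs(bundle.mirnas, chains, bundle.genes, cfg)
    arrays = tandem_gene_arrays(family_ids, bundle.genes, cfg.tandem_rank_window)
    gene_index = {g.id: g for g in bundle.genes}
    genes_in_blocks: set[str] = set()
    for ch in chains:
        for a in ch.anchors:
            genes_in_blocks.update((a.gene_a, a.gene_b))
        (a_lo, a_hi), (b_lo, b_hi) = ch.spans(gene_index)
        for g in bundle.genes:
            if (a_lo <= g.interval.start and g.interval.end <= a_hi) or (
                b_lo <= g.interval.start and g.interval.end <= b_hi
            ):
                genes_in_blocks.add(g.id)
    genes_in_arrays = {g for arr in arrays for g in arr}

    _stage("classify")
    calls = classify_bundle(bundle, target_sites, sd_pairs, family_ids, cfg)

    _stage("features")
    feats = build_feature_table(bundle, target_sites, family_sizes)
    table1 = build_group_table(feats, calls) if not feats.empty else pd.DataFrame()
    table2 = build_system_table(
        calls, target_sites, bundle.genes, family_sizes, genes_in_blocks, genes_in_arrays
    )

    _stage("relationships")
    fig1 = fig1_counts(calls)
    fig2a = intersection_matrix(calls, reps=cfg.mc_reps, seed=cfg.seed, cfg=cfg)
    fig2b = accuracy_matrix(feats, calls, seed=cfg.seed) if not feats.empty else pd.DataFrame()

    blocks = pd.DataFrame(
        [
            {
                "chain_id": i,
                "n_anchors": len(ch.anchors),
                "chain_score": round(ch.chain_score, 3),
                "anchors": ";".join(f"{a.gene_a}|{a.gene_b}" for a in ch.anchors),
            }
            for i, ch in enumerate(chains)
        ]
    )
    log.info("pipeline done in %.1fs", time.time() - t)
    return PipelineResult(
        bundle=bundle,
        calls=calls,
        chains=chains,
        features=feats,
        fig1=fig1,
        fig2a=fig2a,
        fig2b=fig2b,
        table1=table1,
        table2=table2,
        blocks=blocks,
    )


def calls_frame(calls: list[OriginCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna_id": c.mirna_id,
                "labels": ";".join(sorted(c.labels)),
                "primary_label": c.primary_label,
                "mechanism": c.mechanism,
                "evidence": json.dumps(c.evidence),
            }
            for c in calls
        ]
    )


def load_run_config(path: str | Path) -> tuple[SynthConfig | None, Path | None, PipelineConfig]:
    """Parse a run config: either a `synth:` section or a `bundle_dir:`."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    synth_cfg = None
    bundle_dir = None
    if "synth" in data:
        known = {f.name for f in fields(SynthConfig)}
        unknown = set(data["synth"]) - known
        if unknown:
            raise ValueError(f"unknown synth keys: {sorted(unknown)}")
        synth_cfg = SynthConfig(**data["synth"])
    elif "bundle_dir" in data:
        bundle_dir = Path(data["bundle_dir"])
        if not bundle_dir.is_dir():
            raise FileNotFoundError(f"bundle_dir not found: {bundle_dir}")
    else:
        raise ValueError("config needs a 'synth' section or a 'bundle_dir'")
    pcfg = PipelineConfig(**data.get("pipeline", {}))
    return synth_cfg, bundle_dir, pcfg


def run_all(config_path: str | Path, outdir: str | Path) -> Path:
    """Full pipeline run emitting the eight report tables and a manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    synth_cfg, bundle_dir, pcfg = load_run_config(config_path)
    if synth_cfg is not None:
        bundle = generate_genome(synth_cfg)
        bundle.write(out / "bundle")
    else:
        bundle = Bundle.load(bundle_dir)

    res = run_bundle(bundle, pcfg)

    calls_frame(res.calls).to_csv(out / "calls.tsv", sep="\t", index=False)
    res.blocks.to_csv(out / "blocks.tsv", sep="\t", index=False)
    res.features.to_csv(out / "features.tsv", sep="\t")
    res.fig1.to_csv(out / "fig1_counts.tsv", sep="\t")
    res.fig2a.to_csv(out / "fig2A.tsv", sep="\t", index=False)
    res.fig2b.to_csv(out / "fig2B.tsv", sep="\t", index=False)
    res.table1.to_csv(out / "table1.tsv", sep="\t")
    res.table2.to_csv(out / "table2.tsv", sep="\t")

    cfg_bytes = Path(config_path).read_bytes()
    manifest = {
        "version": __version__,
        "config_sha256": hashlib.sha256(cfg_bytes).hexdigest(),
        "pipeline_config": asdict(pcfg),
        "synth_config": asdict(synth_cfg) if synth_cfg else None,
        "bundle_dir": str(bundle_dir) if bundle_dir else "bundle",
        "outputs": list(REPORT_FILES),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
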