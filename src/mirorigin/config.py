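"""Single YAML-backed schema for every tunable threshold in the pipeline.

Defaults follow the published rules where they exist (50% coverage,
E < 0.05 / identity > 0.8 for inverted duplication, 15 kb / E < 1e-10 for
tandem pairs, E < 1e-10 anchors, < 20 genes for tandem arrays, > 80%
copy similarity); the remaining knobs are declared artifact conventions.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class PipelineConfig:
    # TE / pseudogene overlap rule
    te_coverage: float = 0.5
    any_overlap: bool = False
    # inverted duplication rule
    id_evalue: float = 0.05
    id_identity: float = 0.8
    # tandem duplication rule (miRNA pairs)
    td_max_gap: int = 15_000
    td_evalue: float = 1e-10
    # segmental duplication / synteny
    anchor_evalue: float = 1e-10
    tandem_rank_window: int = 20
    min_anchors: int = 3
    max_gap_genes: int = 25
    chain_gap_penalty: float = 1.0
    min_chain_score: float = 20.0
    # mechanism typing
    similarity_min: float = 0.8
    adjacent_pseudogene_gap: int = 2_000
    # target matcher
    target_max_score: float = 4.0
    # alignment statistics (Karlin-Altschul constants)
    ka_k: float = 0.1
    ka_lambda: float = 1.037
    # relationship statistics
    mc_reps: int = 100_000
    paper_literal_tail: bool = False
    seed: int = 0


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)
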