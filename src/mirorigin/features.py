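"""Per-miRNA and per-regulatory-system feature extraction.

Includes a transparent complementarity target matcher (mismatch +1,
G:U wobble +0.5, gap +2, penalties doubled at mature positions 2-13,
default cutoff 4.0) that substitutes for external target-prediction
servers.  The matcher is ungapped: the gap term is part of the declared
scoring scheme but gapped sites are not searched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import re

from .annotation_io import (
    GeneModel,
    GenomicInterval,
    MirnaGene,
    overlap_bp,
    revcomp,
)
from .hairpin import fold, structural_features

__all__ = [
    "TargetSite",
    "scan_target_sites",
    "predict_targets",
    "count_sirnas",
    "find_ssrs",
    "count_flank_ssrs",
    "track_density",
    "count_track_overlaps",
    "conservation_count",
    "build_feature_table",
    "build_group_table",
    "build_system_table",
]

SEED_START, SEED_END = 1, 13  # mature positions 2..13, 0-based half-open
DEFAULT_MAX_SCORE = 4.0
CLEAVE_POSITIONS = (9, 10)  # mature positions 10 and 11, 0-based


@dataclass
class TargetSite:
    gene_id: str
    start: int  # 0-based half-open on the cDNA
    end: int
    score: float
    pairing_profile: tuple[bool, ...]  # Watson-Crick pairing per mature position

    @property
    def cleaving_site_pairings(self) -> int:
        return sum(self.pairing_profile[k] for k in CLEAVE_POSITIONS)


def scan_target_sites(
    mature: str, cdna: str, max_score: float = DEFAULT_MAX_SCORE
) -> list[tuple[int, int, float, tuple[bool, ...]]]:
    """Ungapped scan of a cDNA for mature binding sites.

    Returns (start, end, score, wc_profile) tuples, ascending by position.
    The duplex is antiparallel: mature position k pairs site position
    L-1-k, so a perfect site is the reverse complement of the mature.
    """
    L = len(mature)
    n = len(cdna)
    if n < L:
        return []
    mature = mature.upper().replace("U", "T")
    cdna = cdna.upper().replace("U", "T")
    rc = np.frombuffer(revcomp(mature).encode(), dtype=np.uint8)
    # base of the mature facing each site position j (= mature[L-1-j])
    mat = np.frombuffer(mature.encode(), dtype=np.uint8)[::-1]
    seq = np.frombuffer(cdna.encode(), dtype=np.uint8)
    win = np.lib.stride_tricks.sliding_window_view(seq, L)

    wc = win == rc
    G, T = ord("G"), ord("T")
    gu = ((mat == G) & (win == T)) | ((mat == T) & (win == G))
    gu &= ~wc
    mism = ~wc & ~gu

    weight = np.ones(L)
    # mature positions 2..13 (1-based) map to site positions L-13..L-2
    kpos = L - 1 - np.arange(L)  # mature position for each site column
    weight[(kpos >= SEED_START) & (kpos < SEED_END)] = 2.0

    scores = mism @ weight + 0.5 * (gu @ weight)
    hits = np.nonzero(scores <= max_score)[0]
    out = []
    for i in hits:
        profile = tuple(bool(x) for x in wc[i][::-1])  # index by mature position
        out.append((int(i), int(i) + L, float(scores[i]), profile))
    return out


def predict_targets(
    mature: str,
    genes: Sequence[GeneModel],
    max_score: float = DEFAULT_MAX_SCORE,
) -> list[TargetSite]:
    """Predicted binding sites of a mature miRNA on a cDNA catalogue."""
    if not 19 <= len(mature) <= 24:
        raise ValueError(f"mature length {len(mature)} outside 19-24 nt")
    sites = []
    for g in genes:
        if not g.cdna_seq:
            continue
        for s, e, score, profile in scan_target_sites(mature, g.cdna_seq, max_score):
            sites.append(TargetSite(g.id, s, e, score, profile))
    return sites


# ---------------------------------------------------------------------------
# track aggregations

def count_sirnas(
    mirna: MirnaGene, sirna_track: Iterable[tuple[GenomicInterval, str]]
) -> int:
    """siRNAs inside the precursor, discarding those overlapping the mature."""
    pre = mirna.precursor
    mat = mirna.mature_interval
    count = 0
    for iv, _ in sirna_track:
        if overlap_bp(iv, pre) > 0 and overlap_bp(iv, mat) == 0:
            count += 1
    return count


def count_track_overlaps(
    interval: GenomicInterval, track: Iterable[tuple[GenomicInterval, str]]
) -> int:
    return sum(1 for iv, _ in track if overlap_bp(iv, interval) > 0)


def track_density(
    interval: GenomicInterval, track: Iterable[tuple[GenomicInterval, str]]
) -> float:
    """Overlapping site count divided by interval length."""
    return count_track_overlaps(interval, track) / interval.length


def _is_primitive(unit: str) -> bool:
    for p in range(1, len(unit)):
        if len(unit) % p == 0 and unit == unit[:p] * (len(unit) // p):
            return False
    return True


def find_ssrs(
    seq: str, min_total: int = 12, min_units: int = 4, max_motif: int = 6
) -> list[tuple[int, int, str]]:
    """Simple sequence repeats: motif 1-6 bp, >=4 units, >=12 bp total."""
    found: list[tuple[int, int, str]] = []
    for k in range(1, max_motif + 1):
        for m in re.finditer(rf"(.{{{k}}})\1{{{min_units - 1},}}", seq):
            s, e = m.span()
            unit = m.group(1)
            if e - s < min_total or not _is_primitive(unit):
                continue
            if any(s < fe and e > fs for fs, fe, _ in found):
                continue
            found.append((s, e, unit))
    return sorted(found)


def count_flank_ssrs(
    genome: Mapping[str, str], interval: GenomicInterval, flank: int = 1000
) -> int:
    """SSRs in the two flanks within `flank` bp (truncated at chrom edges)."""
    chrom = genome[interval.chrom]
    left = chrom[max(0, interval.start - flank) : interval.start]
    right = chrom[interval.end : interval.end + flank]
    return len(find_ssrs(left)) + len(find_ssrs(right))


def conservation_count(
    mature: str, catalogs: Mapping[str, Sequence[str]], max_subs: int = 2
) -> int:
    """Number of other-species catalogues containing the mature (<=2 subs)."""
    mature = mature.upper().replace("U", "T")
    L = len(mature)
    n_species = 0
    for _, seqs in catalogs.items():
        for s in seqs:
            s = s.upper().replace("U", "T")
            if len(s) < L:
                continue
            for off in range(len(s) - L + 1):
                if sum(a != b for a, b in zip(mature, s[off : off + L])) <= max_subs:
                    break
            else:
                continue
            n_species += 1
            break
    return n_species


# ---------------------------------------------------------------------------
# feature table

def build_feature_table(
    bundle,
    target_sites: Mapping[str, list[TargetSite]],
    protein_families: Mapping[str, int] | None = None,
    catalogs: Mapping[str, Sequence[str]] | None = None,
    max_fold_len: int = 400,
) -> pd.DataFrame:
    """One row per miRNA with the comparative feature panel."""
    expr_mean = (
        bundle.expression.mean(axis=1) if not bundle.expression.empty else pd.Series(dtype=float)
    )
    fam_sizes = pd.Series([m.family for m in bundle.mirnas]).value_counts()
    gene_spans = [g.interval for g in bundle.genes]
    sirna = bundle.tracks.get("sirna", [])
    promoter = bundle.tracks.get("promoter", [])
    methyl = bundle.tracks.get("methylcytosine", [])
    poly = bundle.tracks.get("polymorphic", [])

    pre_counts = pd.Series([m.precursor.start for m in bundle.mirnas]).value_counts()

    rows = []
    for m in bundle.mirnas:
        pre = m.precursor
        if len(m.precursor_seq) <= max_fold_len:
            f = fold(m.precursor_seq)
            sf = structural_features(f, m.mature_offset, m.mature_len)
        else:  # pragma: no cover - guard for pathological inputs
            sf = {
                "precursor_length": float(len(m.precursor_seq)),
                "mirna_length": float(m.mature_len),
                "stem_length": float("nan"),
                "loop_length": float("nan"),
                "match_ratio": float("nan"),
                "mir_loop_distance": float("nan"),
            }
        sites = target_sites.get(m.id, [])
        target_genes = sorted({t.gene_id for t in sites})
        texpr = [expr_mean[g] for g in target_genes if g in expr_mean.index]
        upstream = None
        if pre.start > 0:
            upstream = GenomicInterval(pre.chrom, max(0, pre.start - 1000), pre.start)
        row = {
            "mirna_id": m.id,
            "first_nt_is_A": m.mature_seq[:1] == "A",
            "mirna_length": float(m.mature_len),
            "precursor_length": sf["precursor_length"],
            "stem_length": sf["stem_length"],
            "loop_length": sf["loop_length"],
            "mir_loop_distance": sf["mir_loop_distance"],
            "match_ratio": sf["match_ratio"],
            "sirna_count": count_sirnas(m, sirna),
            "multi_mirna": pre_counts.get(pre.start, 1) > 1,
            "genic_location": any(g.contains(pre) for g in gene_spans),
            "promoter_count": (
                count_track_overlaps(upstream, promoter) if upstream else 0
            ),
            "ssr_count_1kb": count_flank_ssrs(bundle.genome, pre),
            "target_number": len(target_genes),
            "target_expression_mean": float(np.mean(texpr)) if texpr else float("nan"),
            "cleaving_site_pairings": (
                float(np.mean([t.cleaving_site_pairings for t in sites]))
                if sites
                else float("nan")
            ),
            "family_size": int(fam_sizes.get(m.family, 1)),
            "conservation": conservation_count(m.mature_seq, catalogs or {}),
            "methylcytosine_density": track_density(pre, methyl),
            "polymorphic_density_pre": track_density(pre, poly),
            "polymorphic_density_mature": track_density(m.mature_interval, poly),
            "mirna_expression_mean": float("nan"),
        }
        if protein_families is not None and target_genes:
            row["target_copy_number_mean"] = float(
                np.mean([protein_families.get(g, 1) for g in target_genes])
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("mirna_id") if rows else pd.DataFrame()


_BINARY_FEATURES = {"first_nt_is_A", "multi_mirna", "genic_location"}

DE_NOVO_LABELS = {"TR", "PR", "ID"}
CONSERVED_LABELS = {"TD", "SD"}


def split_groups(calls) -> tuple[list[str], list[str]]:
    """de novo = TR|PR|ID members; conserved = TD|SD members."""
    de_novo = [c.mirna_id for c in calls if c.labels & DE_NOVO_LABELS]
    conserved = [
        c.mirna_id
        for c in calls
        if c.labels & CONSERVED_LABELS and not c.labels & DE_NOVO_LABELS
    ]
    return de_novo, conserved


def build_group_table(features_df: pd.DataFrame, calls) -> pd.DataFrame:
    """Two-group comparison of the feature panel with per-row tests.

    Numeric rows use Welch's t-test; binary rows use a 2x2 chi-square.
    Rows with an empty group are emitted with P marked not-applicable (NaN).
    """
    from .stats import chi_square_2x2, welch_t

    de_novo, conserved = split_groups(calls)
    g1 = features_df.loc[features_df.index.intersection(de_novo)]
    g2 = features_df.loc[features_df.index.intersection(conserved)]
    rows = []
    for col in features_df.columns:
        x1 = g1[col].dropna() if not g1.empty else pd.Series(dtype=float)
        x2 = g2[col].dropna() if not g2.empty else pd.Series(dtype=float)
        if col in _BINARY_FEATURES:
            test = "chi-square"
            m1 = float(x1.mean()) if len(x1) else float("nan")
            m2 = float(x2.mean()) if len(x2) else float("nan")
            if len(x1) and len(x2):
                a, b = int(x1.sum()), int(len(x1) - x1.sum())
                c, d = int(x2.sum()), int(len(x2) - x2.sum())
                try:
                    _, p = chi_square_2x2(a, b, c, d)
                except ValueError:
                    p = float("nan")
            else:
                p = float("nan")
        else:
            test = "welch-t"
            m1 = float(x1.mean()) if len(x1) else float("nan")
            m2 = float(x2.mean()) if len(x2) else float("nan")
            if len(x1) > 1 and len(x2) > 1 and (x1.std() > 0 or x2.std() > 0):
                _, p = welch_t(x1.to_numpy(), x2.to_numpy())
            else:
                p = float("nan")
        rows.append(
            {
                "feature": col,
                "de_novo_mean": m1,
                "conserved_mean": m2,
                "p_value": p,
                "test": test,
                "n_de_novo": len(x1),
                "n_conserved": len(x2),
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def build_system_table(
    calls,
    target_sites: Mapping[str, list[TargetSite]],
    genes: Sequence[GeneModel],
    protein_families: Mapping[str, int],
    genes_in_blocks: set[str],
    genes_in_arrays: set[str],
) -> pd.DataFrame:
    """Regulatory-system comparison: target copy number, splice number and
    duplication-context percentages for de novo vs conserved vs all genes."""
    splice = {g.id: g.isoform_count for g in genes}
    de_novo, conserved = split_groups(calls)

    def _targets(ids: Iterable[str]) -> list[str]:
        out = []
        for mid in ids:
            out.extend(sorted({t.gene_id for t in target_sites.get(mid, [])}))
        return out

    def _row(gene_ids: list[str]) -> dict[str, float]:
        if not gene_ids:
            return {
                "target_copy_number_mean": float("nan"),
                "target_splice_number_mean": float("nan"),
                "pct_in_segmental_blocks": float("nan"),
                "pct_in_tandem_arrays": float("nan"),
                "n": 0,
            }
        return {
            "target_copy_number_mean": float(
                np.mean([protein_families.get(g, 1) for g in gene_ids])
            ),
            "target_splice_number_mean": float(
                np.mean([splice.get(g, 1) for g in gene_ids])
            ),
            "pct_in_segmental_blocks": 100.0
            * sum(g in genes_in_blocks for g in gene_ids)
            / len(gene_ids),
            "pct_in_tandem_arrays": 100.0
            * sum(g in genes_in_arrays for g in gene_ids)
            / len(gene_ids),
            "n": len(gene_ids),
        }

    all_ids = [g.id for g in genes]
    df = pd.DataFrame(
        {
            "de_novo_targets": _row(_targets(de_novo)),
            "conserved_targets": _row(_targets(conserved)),
            "all_genes": _row(all_ids),
        }
    ).T
    return df
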