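"""Origin-mode labelling and de novo mechanism subtyping.

Each miRNA gene receives a label set over {TR, PR, ID, TD, SD, OT} (OT
assigned iff nothing else applies) and, where the structural evidence
supports it, one of the four de novo generation mechanisms:

A  two inverted-orientation copies of one non-MITE family overlap the
   precursor with >80% similarity between the copies;
B  one MITE family entirely covers both the precursor and at least one
   predicted target site, and the target gene fits the inverted-duplication
   criteria;
C  two adjacent inverted pseudogene copies of one parent overlap the
   precursor and the parent is a predicted target;
D  two pseudogene copies whose parents are paralogous (same protein
   family) overlap the precursor.

Ties resolve A > C > D > B (declared, arbitrary).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .annotation_io import (
    GeneModel,
    MirnaGene,
    Pseudogene,
    RepeatFeature,
    overlap_bp,
    revcomp,
    union_coverage_bp,
)
from .config import PipelineConfig
from .features import TargetSite
from .homology import (
    SEARCH_SCHEME,
    AlignmentHit,
    evalue,
    local_score,
    min_score_for_evalue,
    percent_similarity,
    smith_waterman,
)

__all__ = [
    "OriginCall",
    "classify_te_related",
    "classify_pseudogene_related",
    "detect_inverted_duplication",
    "detect_tandem_duplication",
    "assign_mechanism",
    "finalize",
    "classify_bundle",
]

LABELS = ("TR", "PR", "ID", "TD", "SD", "OT")
PRIMARY_PRECEDENCE = ("TR", "PR", "ID", "TD", "SD", "OT")


@dataclass
class OriginCall:
    mirna_id: str
    labels: set[str] = field(default_factory=set)
    mechanism: str = "none"
    evidence: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def primary_label(self) -> str:
        for lab in PRIMARY_PRECEDENCE:
            if lab in self.labels:
                return lab
        return "OT"


def _coverage(mirna: MirnaGene, intervals) -> tuple[int, float]:
    pre = mirna.precursor
    covered = union_coverage_bp(pre, intervals)
    return covered, covered / pre.length


def classify_te_related(
    mirna: MirnaGene,
    repeats: Sequence[RepeatFeature],
    min_coverage: float = 0.5,
    any_overlap: bool = False,
) -> tuple[bool, int]:
    """TE-related iff the union of TE overlaps covers >= 50% of the
    precursor (or any overlap at all with ``any_overlap``)."""
    covered, frac = _coverage(mirna, [r.interval for r in repeats])
    flag = covered > 0 if any_overlap else frac >= min_coverage
    return flag, covered


def classify_pseudogene_related(
    mirna: MirnaGene,
    pseudogenes: Sequence[Pseudogene],
    min_coverage: float = 0.5,
    any_overlap: bool = False,
) -> tuple[bool, int]:
    covered, frac = _coverage(mirna, [p.interval for p in pseudogenes])
    flag = covered > 0 if any_overlap else frac >= min_coverage
    return flag, covered


def detect_inverted_duplication(
    mirna: MirnaGene,
    genes: Sequence[GeneModel],
    cfg: PipelineConfig = PipelineConfig(),
) -> list[tuple[str, AlignmentHit, AlignmentHit]]:
    """Genes where both the forward and reverse-complemented precursor align
    to the cDNA (E < cutoff, identity > cutoff) and the mature lies within a
    matched precursor region.

    Returns (gene_id, forward_hit, revcomp_hit) tuples.
    """
    pre = mirna.precursor_seq
    rc_pre = revcomp(pre)
    mat_span = (mirna.mature_offset, mirna.mature_offset + mirna.mature_len)
    L = len(pre)
    hits = []
    for g in genes:
        if not g.cdna_seq:
            continue
        smin = min_score_for_evalue(cfg.id_evalue, L, len(g.cdna_seq), cfg.ka_k, cfg.ka_lambda)
        fwd_score = local_score(pre, g.cdna_seq, SEARCH_SCHEME)
        if fwd_score < smin:
            continue
        rev_score = local_score(rc_pre, g.cdna_seq, SEARCH_SCHEME)
        if rev_score < smin:
            continue
        fwd = smith_waterman(pre, g.cdna_seq, SEARCH_SCHEME, min_score=smin)
        rev = smith_waterman(rc_pre, g.cdna_seq, SEARCH_SCHEME, min_score=smin)
        if fwd is None or rev is None:
            continue
        fwd.evalue = evalue(fwd.raw_score, L, len(g.cdna_seq), cfg.ka_k, cfg.ka_lambda)
        rev.evalue = evalue(rev.raw_score, L, len(g.cdna_seq), cfg.ka_k, cfg.ka_lambda)
        if fwd.evalue >= cfg.id_evalue or rev.evalue >= cfg.id_evalue:
            continue
        if fwd.identity <= cfg.id_identity or rev.identity <= cfg.id_identity:
            continue
        # the revcomp hit's query span mapped back to precursor coordinates
        rev_span = (L - rev.query_span[1], L - rev.query_span[0])
        in_fwd = fwd.query_span[0] <= mat_span[0] and mat_span[1] <= fwd.query_span[1]
        in_rev = rev_span[0] <= mat_span[0] and mat_span[1] <= rev_span[1]
        if in_fwd or in_rev:
            hits.append((g.id, fwd, rev))
    return hits


def detect_tandem_duplication(
    mirnas: Sequence[MirnaGene], cfg: PipelineConfig = PipelineConfig()
) -> list[tuple[str, str]]:
    """miRNA pairs < 15 kb apart that share a family or align at E < 1e-10."""
    pairs = []
    by_chrom: dict[str, list[MirnaGene]] = {}
    for m in mirnas:
        by_chrom.setdefault(m.precursor.chrom, []).append(m)
    for chrom_mirnas in by_chrom.values():
        ms = sorted(chrom_mirnas, key=lambda m: m.precursor.start)
        for i, a in enumerate(ms):
            for b in ms[i + 1 :]:
                gap = b.precursor.start - a.precursor.end
                if gap >= cfg.td_max_gap:
                    break
                if a.family == b.family:
                    pairs.append((a.id, b.id))
                    continue
                score = local_score(a.precursor_seq, b.precursor_seq, SEARCH_SCHEME)
                e = evalue(
                    score,
                    len(a.precursor_seq),
                    len(b.precursor_seq),
                    cfg.ka_k,
                    cfg.ka_lambda,
                )
                if e < cfg.td_evalue:
                    pairs.append((a.id, b.id))
    return pairs


def _repeat_seq(repeat: RepeatFeature, genome: Mapping[str, str]) -> str:
    return repeat.interval.sequence(genome)


def assign_mechanism(
    mirna: MirnaGene,
    repeats: Sequence[RepeatFeature],
    pseudogenes: Sequence[Pseudogene],
    genes: Sequence[GeneModel],
    target_sites: Sequence[TargetSite],
    id_gene_ids: set[str],
    genome: Mapping[str, str],
    protein_family_of: Mapping[str, int] | None = None,
    cfg: PipelineConfig = PipelineConfig(),
) -> tuple[str, list[tuple[str, str, float]]]:
    """Mechanism subtype and supporting evidence for one miRNA."""
    pre = mirna.precursor
    gene_by_id = {g.id: g for g in genes}
    over_repeats = [r for r in repeats if overlap_bp(r.interval, pre) > 0]
    over_pseudos = [p for p in pseudogenes if overlap_bp(p.interval, pre) > 0]

    # A: two inverted copies of one non-MITE family, copies > 80% similar
    fams: dict[str, list[RepeatFeature]] = {}
    for r in over_repeats:
        if not r.is_mite:
            fams.setdefault(r.family, []).append(r)
    for fam, copies in sorted(fams.items()):
        plus = [r for r in copies if r.interval.strand == "+"]
        minus = [r for r in copies if r.interval.strand == "-"]
        for rp in plus:
            for rm in minus:
                sim = percent_similarity(_repeat_seq(rp, genome), _repeat_seq(rm, genome))
                if sim > cfg.similarity_min:
                    return "A", [("inverted_non_mite_copies", fam, sim)]

    # C: adjacent inverted pseudogene pair of one parent; parent is a target
    target_gene_ids = {t.gene_id for t in target_sites}
    for i, p1 in enumerate(over_pseudos):
        for p2 in over_pseudos[i + 1 :]:
            if p1.parent_gene != p2.parent_gene or p1.parent_gene == "unknown":
                continue
            if p1.interval.strand == p2.interval.strand:
                continue
            gap = max(
                p2.interval.start - p1.interval.end,
                p1.interval.start - p2.interval.end,
            )
            if gap > cfg.adjacent_pseudogene_gap:
                continue
            if p1.parent_gene in target_gene_ids:
                return "C", [("inverted_pseudogene_pair", p1.parent_gene, float(gap))]

    # D: two pseudogenes whose (distinct) parents are paralogous
    if protein_family_of is not None:
        for i, p1 in enumerate(over_pseudos):
            for p2 in over_pseudos[i + 1 :]:
                pa, pb = p1.parent_gene, p2.parent_gene
                if pa == pb or "unknown" in (pa, pb):
                    continue
                if pa in protein_family_of and protein_family_of.get(pa) == protein_family_of.get(pb):
                    return "D", [("paralogous_parent_pseudogenes", f"{pa}|{pb}", 0.0)]

    # B: one MITE family covers precursor and a target site entirely;
    # the target gene also fits the inverted-duplication criteria
    mite_cover = [r for r in over_repeats if r.is_mite and r.interval.contains(pre)]
    for r in mite_cover:
        same_fam = [x for x in repeats if x.family == r.family and x.is_mite]
        for t in target_sites:
            g = gene_by_id.get(t.gene_id)
            if g is None or t.gene_id not in id_gene_ids:
                continue
            if g.interval.strand != "+":
                continue
            site_start = g.interval.start + t.start
            site_end = g.interval.start + t.end
            for x in same_fam:
                if (
                    x.interval.chrom == g.interval.chrom
                    and x.interval.start <= site_start
                    and site_end <= x.interval.end
                ):
                    return "B", [("mite_shared_with_target", f"{r.family}|{t.gene_id}", t.score)]

    return "none", []


def finalize(
    mirnas: Sequence[MirnaGene],
    te_flags: Mapping[str, bool],
    pr_flags: Mapping[str, bool],
    id_hits: Mapping[str, list],
    td_pairs: Sequence[tuple[str, str]],
    sd_pairs: Sequence[tuple[str, str]],
    mechanisms: Mapping[str, tuple[str, list]] | None = None,
) -> list[OriginCall]:
    """Assemble per-miRNA label sets; OT iff no other label applies."""
    in_td = {m for pair in td_pairs for m in pair}
    in_sd = {m for pair in sd_pairs for m in pair}
    calls = []
    for m in mirnas:
        labels = set()
        if te_flags.get(m.id):
            labels.add("TR")
        if pr_flags.get(m.id):
            labels.add("PR")
        if id_hits.get(m.id):
            labels.add("ID")
        if m.id in in_td:
            labels.add("TD")
        if m.id in in_sd:
            labels.add("SD")
        if not labels:
            labels.add("OT")
        mech, ev = ("none", [])
        if mechanisms and m.id in mechanisms:
            mech, ev = mechanisms[m.id]
        # mechanism calls require inverted-duplication (or TE for B) support
        if mech != "none":
            if not ("ID" in labels or (mech == "B" and "TR" in labels)):
                mech, ev = "none", []
        calls.append(OriginCall(mirna_id=m.id, labels=labels, mechanism=mech, evidence=ev))
    return calls


def classify_bundle(
    bundle,
    target_sites: Mapping[str, list[TargetSite]],
    sd_pairs: Sequence[tuple[str, str]] = (),
    protein_family_of: Mapping[str, int] | None = None,
    cfg: PipelineConfig = PipelineConfig(),
) -> list[OriginCall]:
    """Run every labelling rule over an annotation bundle."""
    te_flags, pr_flags, id_hits, mechanisms = {}, {}, {}, {}
    for m in bundle.mirnas:
        te_flags[m.id], _ = classify_te_related(
            m, bundle.repeats, cfg.te_coverage, cfg.any_overlap
        )
        pr_flags[m.id], _ = classify_pseudogene_related(
            m, bundle.pseudogenes, cfg.te_coverage, cfg.any_overlap
        )
        hits = detect_inverted_duplication(m, bundle.genes, cfg)
        id_hits[m.id] = hits
        mechanisms[m.id] = assign_mechanism(
            m,
            bundle.repeats,
            bundle.pseudogenes,
            bundle.genes,
            target_sites.get(m.id, []),
            {g for g, _, _ in hits},
            bundle.genome,
            protein_family_of,
            cfg,
        )
    td_pairs = detect_tandem_duplication(bundle.mirnas, cfg)
    return finalize(
        bundle.mirnas, te_flags, pr_flags, id_hits, td_pairs, sd_pairs, mechanisms
    )
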