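"""Segmental-duplication block detection, tandem gene arrays, and protein
family clustering.

Block detection chains collinear anchor gene pairs by sparse dynamic
programming: chain score = sum of log-scaled anchor scores minus one gap
penalty per skipped gene rank, anchors strictly increasing on one axis and
monotonic (either direction) on the other.  Self pairs and pairs within
the tandem rank window are excluded before chaining, so blocks do not
re-capture tandem arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .annotation_io import GeneModel, MirnaGene
from .config import PipelineConfig
from .homology import SEARCH_SCHEME, alignable_identity, evalue, local_score

__all__ = [
    "AnchorPair",
    "SyntenyChain",
    "family_similarity_threshold",
    "build_anchors",
    "chain_anchors",
    "segmental_mirna_pairs",
    "cluster_protein_families",
    "tandem_gene_arrays",
]


@dataclass(frozen=True)
class AnchorPair:
    gene_a: str
    gene_b: str
    pos_a: int  # gene rank along the chromosome
    pos_b: int
    score: float

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError("self anchor")


@dataclass
class SyntenyChain:
    anchors: list[AnchorPair]
    chain_score: float

    def spans(self, gene_index: Mapping[str, GeneModel]) -> tuple[tuple[int, int], tuple[int, int]]:
        """Genomic (start, end) spans of the two block sides."""
        a_iv = [gene_index[a.gene_a].interval for a in self.anchors]
        b_iv = [gene_index[a.gene_b].interval for a in self.anchors]
        return (
            (min(i.start for i in a_iv), max(i.end for i in a_iv)),
            (min(i.start for i in b_iv), max(i.end for i in b_iv)),
        )


def family_similarity_threshold(L: float, n: int = 6) -> float:
    """Required identity for two proteins with alignable length L (aa).

    0.30 for L >= 150; 0.01*n + 4.8 * L^(-0.32*(1+exp(-L/1000))) below.
    The short-length branch is continuous with the 30% rule at L = 150.
    """
    if L >= 150:
        return 0.30
    if L <= 0:
        return 1.0
    return 0.01 * n + 4.8 * L ** (-0.32 * (1.0 + math.exp(-L / 1000.0)))


# ---------------------------------------------------------------------------
# anchors and chaining

def gene_ranks(genes: Sequence[GeneModel]) -> dict[str, int]:
    """Rank of each gene along its chromosome (position order)."""
    ranks: dict[str, int] = {}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    for chrom_genes in by_chrom.values():
        for i, g in enumerate(sorted(chrom_genes, key=lambda g: g.interval.start)):
            ranks[g.id] = i
    return ranks


def build_anchors(
    genes: Sequence[GeneModel], cfg: PipelineConfig = PipelineConfig()
) -> list[AnchorPair]:
    """Qualifying protein pairs (alignment E < cutoff), deduplicated, with
    self pairs and tandem-range pairs removed."""
    ranks = gene_ranks(genes)
    anchors = []
    for i, ga in enumerate(genes):
        for gb in genes[i + 1 :]:
            if not ga.protein_seq or not gb.protein_seq:
                continue
            same_chrom = ga.interval.chrom == gb.interval.chrom
            if same_chrom and abs(ranks[ga.id] - ranks[gb.id]) < cfg.tandem_rank_window:
                continue
            score = local_score(ga.protein_seq, gb.protein_seq)
            e = evalue(
                score, len(ga.protein_seq), len(gb.protein_seq), cfg.ka_k, cfg.ka_lambda
            )
            if e < cfg.anchor_evalue:
                a, b = sorted((ga.id, gb.id), key=lambda x: ranks[x])
                anchors.append(AnchorPair(a, b, ranks[a], ranks[b], score))
    return anchors


def chain_score(
    anchors: Sequence[AnchorPair], gap_penalty: float = 1.0
) -> float:
    """Objective shared by the chainer and the exhaustive oracle."""
    total = sum(math.log1p(max(a.score, 0.0)) for a in anchors)
    for prev, cur in zip(anchors, anchors[1:]):
        total -= gap_penalty * (abs(cur.pos_a - prev.pos_a) - 1)
        total -= gap_penalty * (abs(cur.pos_b - prev.pos_b) - 1)
    return total


def _chain_dp(
    anchors: list[AnchorPair],
    sign: int,
    gap_penalty: float,
    max_gap: int,
    min_anchors: int,
) -> tuple[float, list[int]] | None:
    """Best chain with >= min_anchors anchors, pos_a strictly increasing and
    pos_b strictly monotonic in direction `sign`.

    dp state is (anchor, chain length capped at min_anchors) so the
    cardinality constraint cannot be starved by a shorter higher-scoring
    prefix.  Returns (score, anchor indices) or None.
    """
    order = sorted(range(len(anchors)), key=lambda i: (anchors[i].pos_a, anchors[i].pos_b))
    cap = min_anchors
    # dp[i][c] = best (score, chain) ending at i with capped length c
    dp: dict[int, dict[int, tuple[float, list[int]]]] = {}
    best: tuple[float, list[int]] | None = None
    for oi, i in enumerate(order):
        ai = anchors[i]
        base = math.log1p(max(ai.score, 0.0))
        states: dict[int, tuple[float, list[int]]] = {1: (base, [i])}
        for j in order[:oi]:
            aj = anchors[j]
            da = ai.pos_a - aj.pos_a
            db = sign * (ai.pos_b - aj.pos_b)
            if da <= 0 or db <= 0 or da - 1 > max_gap or db - 1 > max_gap:
                continue
            step = base - gap_penalty * (da - 1 + db - 1)
            for c, (sc, idx) in dp[j].items():
                nc = min(c + 1, cap)
                cand = (sc + step, idx + [i])
                if nc not in states or cand[0] > states[nc][0]:
                    states[nc] = cand
        dp[i] = states
        if cap in states:
            cur = states[cap]
            if best is None or cur[0] > best[0] or (
                cur[0] == best[0] and len(cur[1]) > len(best[1])
            ):
                best = cur
    return best


def chain_anchors(
    anchors: Sequence[AnchorPair],
    gap_penalty: float = 1.0,
    min_anchors: int = 3,
    max_gap_genes: int = 25,
    min_chain_score: float = 20.0,
) -> list[SyntenyChain]:
    """Non-overlapping maximal collinear chains with >= min_anchors anchors
    and chain score >= min_chain_score.

    The score cutoff plays the role of an alignment-significance threshold:
    short monotone runs that arise by chance in shuffled anchor sets score
    below it, while genuine multi-anchor blocks score well above.  Chains
    are extracted greedily best-first; anchors of an accepted chain are
    removed before re-running the DP.  Deterministic given input order.
    """
    remaining = list(dict.fromkeys(anchors))
    chains = []
    while len(remaining) >= min_anchors:
        cands = []
        for sign in (1, -1):
            got = _chain_dp(remaining, sign, gap_penalty, max_gap_genes, min_anchors)
            if got and got[0] >= min_chain_score:
                cands.append(got)
        if not cands:
            break
        score, idx = max(
            cands, key=lambda c: (c[0], len(c[1]), -remaining[c[1][0]].pos_a)
        )
        chain = [remaining[i] for i in idx]
        chains.append(SyntenyChain(anchors=chain, chain_score=score))
        used = set(idx)
        remaining = [a for i, a in enumerate(remaining) if i not in used]
    return chains


def segmental_mirna_pairs(
    mirnas: Sequence[MirnaGene],
    chains: Sequence[SyntenyChain],
    genes: Sequence[GeneModel],
    cfg: PipelineConfig = PipelineConfig(),
) -> list[tuple[str, str]]:
    """miRNA pairs lying inside the paired spans of one chain and related by
    family or precursor alignment E < cutoff."""
    gene_index = {g.id: g for g in genes}
    pairs = []
    for chain in chains:
        (a_lo, a_hi), (b_lo, b_hi) = chain.spans(gene_index)
        in_a = [m for m in mirnas if a_lo <= m.precursor.start and m.precursor.end <= a_hi]
        in_b = [m for m in mirnas if b_lo <= m.precursor.start and m.precursor.end <= b_hi]
        for ma in in_a:
            for mb in in_b:
                if ma.id == mb.id:
                    continue
                related = ma.family == mb.family
                if not related:
                    score = local_score(ma.precursor_seq, mb.precursor_seq, SEARCH_SCHEME)
                    e = evalue(
                        score,
                        len(ma.precursor_seq),
                        len(mb.precursor_seq),
                        cfg.ka_k,
                        cfg.ka_lambda,
                    )
                    related = e < cfg.td_evalue
                if related:
                    pairs.append(tuple(sorted((ma.id, mb.id))))
    return sorted(set(pairs))


# ---------------------------------------------------------------------------
# protein families and tandem arrays

class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller id becomes the root
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo


def protein_pair_qualifies(a: str, b: str, n: int = 6) -> bool:
    """Family criterion: (1) identity >= I(L) over the alignable region and
    (2) alignable region length >= 80% of the longer protein."""
    if not a or not b:
        return False
    sim, L = alignable_identity(a, b)
    if L < 0.8 * max(len(a), len(b)):
        return False
    return sim >= family_similarity_threshold(L, n)


def cluster_protein_families(genes: Sequence[GeneModel]) -> dict[str, int]:
    """Single-linkage protein families; returns gene_id -> family size."""
    ids = [g.id for g in genes]
    uf = _UnionFind(ids)
    for i, ga in enumerate(genes):
        for gb in genes[i + 1 :]:
            if protein_pair_qualifies(ga.protein_seq, gb.protein_seq):
                uf.union(ga.id, gb.id)
    sizes: dict[str, int] = {}
    for gid in ids:
        root = uf.find(gid)
        sizes[root] = sizes.get(root, 0) + 1
    return {gid: sizes[uf.find(gid)] for gid in ids}


def protein_family_ids(genes: Sequence[GeneModel]) -> dict[str, int]:
    """gene_id -> family index (stable across input permutations)."""
    ids = [g.id for g in genes]
    uf = _UnionFind(ids)
    for i, ga in enumerate(genes):
        for gb in genes[i + 1 :]:
            if protein_pair_qualifies(ga.protein_seq, gb.protein_seq):
                uf.union(ga.id, gb.id)
    roots = sorted({uf.find(g) for g in ids})
    index = {r: i for i, r in enumerate(roots)}
    return {g: index[uf.find(g)] for g in ids}


def tandem_gene_arrays(
    family_of: Mapping[str, int],
    genes: Sequence[GeneModel],
    max_separation: int = 20,
) -> list[list[str]]:
    """Arrays of paralogs separated by fewer than `max_separation` genes.

    Tandem relations close transitively: A-B and B-C tandem puts {A,B,C}
    in one array.
    """
    ranks = gene_ranks(genes)
    uf = _UnionFind([g.id for g in genes])
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    linked = set()
    for chrom_genes in by_chrom.values():
        for i, ga in enumerate(chrom_genes):
            for gb in chrom_genes[i + 1 :]:
                if family_of.get(ga.id) != family_of.get(gb.id):
                    continue
                between = abs(ranks[ga.id] - ranks[gb.id]) - 1
                if between < max_separation:
                    uf.union(ga.id, gb.id)
                    linked.update((ga.id, gb.id))
    groups: dict[str, list[str]] = {}
    for gid in sorted(linked):
        groups.setdefault(uf.find(gid), []).append(gid)
    return [sorted(v) for _, v in sorted(groups.items()) if len(v) >= 2]
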