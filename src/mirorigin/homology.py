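"""Local alignment, identity and E-value machinery.

The alignment engine wraps Bio.Align.PairwiseAligner (C implementation)
with a fixed nucleotide scheme: match +1, mismatch -1, gap open -2,
gap extend -1; N scores as a mismatch against everything, itself included.
E-values use the Karlin-Altschul form E = K * m * n * exp(-lambda * S)
with declared constants, standing in for external search-tool statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .annotation_io import revcomp

__all__ = [
    "AlignmentHit",
    "ScoringScheme",
    "smith_waterman",
    "local_score",
    "evalue",
    "min_score_for_evalue",
    "percent_similarity",
]

DEFAULT_K = 0.1
DEFAULT_LAMBDA = 1.037

_NT_ALPHABET = "ACGTN"
_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX*"


@dataclass(frozen=True)
class ScoringScheme:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0


#: harsher scheme for homology-search rules (BLASTN-like mismatch/gap
#: weighting): random extensions score strongly negative, so local hits
#: stop at the homologous segment instead of absorbing noisy flanks
SEARCH_SCHEME = ScoringScheme(match=1.0, mismatch=-2.0, gap_open=-4.0, gap_extend=-2.0)


@dataclass
class AlignmentHit:
    query_span: tuple[int, int]  # 0-based half-open on the query
    subject_span: tuple[int, int]
    raw_score: float
    identity: float  # matches / aligned columns (gap columns included)
    n_columns: int
    evalue: float | None = None


@lru_cache(maxsize=16)
def _aligner(scheme: ScoringScheme, mode: str, alphabet: str) -> Align.PairwiseAligner:
    aln = Align.PairwiseAligner()
    aln.mode = mode
    mat = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            ambiguous = a in "NX*" or b in "NX*"
            mat[a, b] = scheme.mismatch if (a != b or ambiguous) else scheme.match
    aln.substitution_matrix = mat
    aln.open_gap_score = scheme.gap_open
    aln.extend_gap_score = scheme.gap_extend
    return aln


def _alphabet_for(seq: str) -> str:
    return _NT_ALPHABET if set(seq) <= set(_NT_ALPHABET) else _AA_ALPHABET


def local_score(
    query: str, subject: str, scheme: ScoringScheme = ScoringScheme()
) -> float:
    """Best local alignment score only (no traceback; fast pre-filter)."""
    if not query or not subject:
        raise ValueError("empty sequence")
    alphabet = _alphabet_for(query.upper() + subject.upper())
    return _aligner(scheme, "local", alphabet).score(subject.upper(), query.upper())


def _hit_from_alignment(aln, query: str) -> AlignmentHit:
    # biopython convention: target is the first sequence passed to align()
    blocks_t, blocks_q = aln.aligned
    matches = 0
    cols = 0
    target, qry = str(aln.target), str(aln.query)
    prev_t_end = prev_q_end = None
    for (ts, te), (qs, qe) in zip(blocks_t, blocks_q):
        if prev_t_end is not None:
            cols += (ts - prev_t_end) + (qs - prev_q_end)  # gap columns
        for a, b in zip(target[ts:te], qry[qs:qe]):
            cols += 1
            if a == b and a not in "NX":
                matches += 1
        prev_t_end, prev_q_end = te, qe
    qspan = (int(blocks_q[0][0]), int(blocks_q[-1][1]))
    tspan = (int(blocks_t[0][0]), int(blocks_t[-1][1]))
    return AlignmentHit(
        query_span=qspan,
        subject_span=tspan,
        raw_score=float(aln.score),
        identity=matches / cols if cols else 0.0,
        n_columns=cols,
    )


def smith_waterman(
    query: str,
    subject: str,
    scheme: ScoringScheme = ScoringScheme(),
    min_score: float = 1.0,
) -> AlignmentHit | None:
    """Best local alignment of query vs subject, or None when no positive-
    scoring alignment of at least `min_score` exists."""
    if not query or not subject:
        raise ValueError("empty sequence")
    query, subject = query.upper(), subject.upper()
    alphabet = _alphabet_for(query + subject)
    aln = _aligner(scheme, "local", alphabet)
    score = aln.score(subject, query)
    if score < min_score or score <= 0:
        return None
    best = aln.align(subject, query)[0]
    return _hit_from_alignment(best, query)


def evalue(
    raw_score: float,
    query_len: int,
    subject_len: int,
    K: float = DEFAULT_K,
    lam: float = DEFAULT_LAMBDA,
) -> float:
    """Karlin-Altschul expectation E = K * m * n * exp(-lambda * S)."""
    if query_len < 1 or subject_len < 1:
        raise ValueError("sequence lengths must be >= 1")
    if K <= 0 or lam <= 0:
        raise ValueError("K and lambda must be positive")
    return K * query_len * subject_len * math.exp(-lam * raw_score)


def min_score_for_evalue(
    max_evalue: float,
    query_len: int,
    subject_len: int,
    K: float = DEFAULT_K,
    lam: float = DEFAULT_LAMBDA,
) -> float:
    """Smallest score whose E-value is below `max_evalue`."""
    return math.log(K * query_len * subject_len / max_evalue) / lam


def alignable_identity(
    a: str, b: str, scheme: ScoringScheme = ScoringScheme()
) -> tuple[float, int]:
    """Identity over the ungapped columns of a global alignment.

    Returns (matches / aligned_columns, aligned_columns) where columns with
    a gap on either side are excluded; the column count is the alignable
    region length used by the gene-family criterion.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    a, b = a.upper(), b.upper()
    alphabet = _alphabet_for(a + b)
    aln = _aligner(scheme, "global", alphabet).align(a, b)[0]
    blocks_a, blocks_b = aln.aligned
    matches = 0
    cols = 0
    for (as_, ae), (bs, be) in zip(blocks_a, blocks_b):
        for x, y in zip(a[as_:ae], b[bs:be]):
            cols += 1
            if x == y and x not in "NX":
                matches += 1
    return (matches / cols if cols else 0.0, cols)


def percent_similarity(a: str, b: str, scheme: ScoringScheme = ScoringScheme()) -> float:
    """Global identity of two copies, gap-compressed.

    Matches divided by aligned columns, with each run of gaps counted as a
    single column (so one indel event costs one column regardless of size).
    """
    if not a or not b:
        raise ValueError("empty sequence")
    a, b = a.upper(), b.upper()
    alphabet = _alphabet_for(a + b)
    aln = _aligner(scheme, "global", alphabet).align(a, b)[0]
    blocks_a, blocks_b = aln.aligned
    matches = 0
    cols = 0
    gap_runs = 0
    prev_a = prev_b = 0
    for (as_, ae), (bs, be) in zip(blocks_a, blocks_b):
        if as_ > prev_a:
            gap_runs += 1
        if bs > prev_b:
            gap_runs += 1
        for x, y in zip(a[as_:ae], b[bs:be]):
            cols += 1
            if x == y and x not in "NX":
                matches += 1
        prev_a, prev_b = ae, be
    if prev_a < len(a):
        gap_runs += 1
    if prev_b < len(b):
        gap_runs += 1
    total = cols + gap_runs
    return matches / total if total else 0.0
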