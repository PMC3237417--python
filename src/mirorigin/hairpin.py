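"""Nested secondary-structure folding and hairpin validity criteria.

The folding engine maximises base pairing (AU, GC and GU wobble allowed,
minimum loop of 3 nt) over all pseudoknot-free structures.  It deliberately
counts pairings rather than free energies: the downstream validity filter
and the structural feature panel only consume pairing geometry.  Tie-breaks
in the traceback prefer closing the outermost pair, which favours long
stacked helices and is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HairpinFold", "MircheckVerdict", "fold", "mircheck", "structural_features"]

MIN_LOOP = 3
_MIN_SEQ = 5

# allowed pairs on {A,C,G,T/U}; N never pairs
_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def _encode(seq: str) -> str:
    return seq.upper().replace("U", "T")


def can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRS


@dataclass
class HairpinFold:
    """Nested pairing of a sequence plus its hairpin anatomy.

    pair_table[i] is the partner index of position i, or -1 if unpaired.
    """

    seq: str
    pair_table: list[int]

    @property
    def n_pairs(self) -> int:
        return sum(1 for i, j in enumerate(self.pair_table) if j > i)

    @property
    def match_ratio(self) -> float:
        paired = sum(1 for j in self.pair_table if j >= 0)
        return paired / len(self.seq) if self.seq else 0.0

    def _main_loop(self) -> tuple[int, int] | None:
        """(i, j) of the innermost pair of the principal stem, or None.

        The principal stem is read from the 5' side: the last position i
        whose partner lies downstream closes the loop [i+1, pair[i]).
        """
        best = None
        for i, j in enumerate(self.pair_table):
            if j > i:
                best = (i, j)
        return best

    @property
    def loop_span(self) -> tuple[int, int] | None:
        """0-based half-open span of the terminal loop, or None if unpaired."""
        ml = self._main_loop()
        if ml is None:
            return None
        i, j = ml
        return (i + 1, j)

    @property
    def loop_length(self) -> int:
        span = self.loop_span
        return 0 if span is None else span[1] - span[0]

    @property
    def stem_length(self) -> int:
        """Number of paired positions on the 5' arm (before the loop)."""
        span = self.loop_span
        if span is None:
            return 0
        return sum(
            1 for i in range(span[0]) if self.pair_table[i] > i
        )

    @property
    def dot_bracket(self) -> str:
        out = []
        for i, j in enumerate(self.pair_table):
            out.append("." if j < 0 else ("(" if j > i else ")"))
        return "".join(out)


def fold(seq: str) -> HairpinFold:
    """Maximum-base-pairing nested fold with GU pairs and min loop 3.

    Raises ValueError for sequences shorter than 5 nt or with letters
    outside {A,C,G,T,U,N}.
    """
    s = _encode(seq)
    n = len(s)
    if n < _MIN_SEQ:
        raise ValueError(f"sequence too short to fold ({n} nt)")
    if set(s) - set("ACGTN"):
        raise ValueError(f"bad alphabet: {sorted(set(s) - set('ACGTN'))}")

    enc = np.frombuffer(s.encode(), dtype=np.uint8)
    # pairable[i, j]: s[i] can pair s[j]
    lut = np.zeros((256, 256), dtype=bool)
    for a, b in _PAIRS:
        lut[ord(a), ord(b)] = True
    pairable = lut[enc[:, None], enc[None, :]]

    # dp[i, j] = max pairs on s[i..j] inclusive
    dp = np.zeros((n, n), dtype=np.int32)
    for L in range(MIN_LOOP + 1, n):  # j - i = L
        i = np.arange(n - L)
        j = i + L
        best = dp[i + 1, j]  # i unpaired
        np.maximum(best, dp[i, j - 1], out=best)  # j unpaired
        paired = dp[i + 1, j - 1] + pairable[i, j]
        np.maximum(best, paired, out=best)
        for k in range(L - 1):  # bifurcation at i+k
            np.maximum(best, dp[i, i + k] + dp[i + k + 1, j], out=best)
        dp[i, j] = best

    pair_table = [-1] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= MIN_LOOP:
            continue
        v = dp[i, j]
        if v == 0:
            continue
        if pairable[i, j] and v == dp[i + 1, j - 1] + 1:
            pair_table[i] = j
            pair_table[j] = i
            stack.append((i + 1, j - 1))
            continue
        if v == dp[i + 1, j]:
            stack.append((i + 1, j))
            continue
        if v == dp[i, j - 1]:
            stack.append((i, j - 1))
            continue
        for k in range(i, j):
            if dp[i, k] + dp[k + 1, j] == v:
                stack.append((i, k))
                stack.append((k + 1, j))
                break
    return HairpinFold(seq=s, pair_table=pair_table)


@dataclass
class MircheckVerdict:
    passed: bool
    reason: str
    mismatches_mir: int
    mismatches_star: int
    max_consecutive_mismatches: int
    asymmetric_unpaired: int


def _runs(flags: list[bool]) -> int:
    """Longest run of True."""
    best = cur = 0
    for f in flags:
        cur = cur + 1 if f else 0
        best = max(best, cur)
    return best


def mircheck(
    fold_: HairpinFold,
    mature_offset: int,
    mature_len: int,
    max_mismatch: int = 4,
    max_consecutive: int = 2,
    max_asymmetric: int = 2,
) -> MircheckVerdict:
    """Hairpin validity verdict over the miRNA/miRNA* duplex.

    Pass requires <= 4 mismatches and <= 2 consecutive mismatches in both
    the miRNA and the inferred miRNA*, and <= 2 asymmetrically unpaired
    nucleotides in the miRNA.  A "mismatch" is an unpaired duplex position;
    asymmetric unpaired positions are mature bulges without a facing gap on
    the star side.  A mature spanning the terminal loop fails with a reason
    rather than raising.
    """
    pt = fold_.pair_table
    s, e = mature_offset, mature_offset + mature_len
    if s < 0 or e > len(pt):
        raise ValueError("mature outside precursor")

    def _fail(reason: str, mm: int = 0) -> MircheckVerdict:
        return MircheckVerdict(False, reason, mm, mm, mm, mm)

    span = fold_.loop_span
    if span is None:
        return _fail("no pairs in fold", mature_len)
    loop_s, loop_e = span
    on5 = e <= loop_s
    on3 = s >= loop_e
    if not (on5 or on3):
        return _fail("mature spans the loop", mature_len)

    mature_pos = list(range(s, e))
    partners = [pt[i] for i in mature_pos]
    paired = [(i, p) for i, p in zip(mature_pos, partners) if p >= 0]
    if not paired:
        return _fail("mature entirely unpaired", mature_len)

    star_lo = min(p for _, p in paired)
    star_hi = max(p for _, p in paired) + 1

    mm_flags = [pt[i] < 0 or not (star_lo <= pt[i] < star_hi) for i in mature_pos]
    mismatches_mir = sum(mm_flags)

    star_pos = list(range(star_lo, star_hi))
    star_flags = [pt[i] < 0 or not (s <= pt[i] < e) for i in star_pos]
    mismatches_star = sum(star_flags)

    max_run = max(_runs(mm_flags), _runs(star_flags))

    # bulge asymmetry: between consecutive paired mature positions, compare
    # the unpaired count on the mature side against the facing star gap
    asym = 0
    for (i1, p1), (i2, p2) in zip(paired, paired[1:]):
        gap_m = i2 - i1 - 1
        gap_s = p1 - p2 - 1  # star runs antiparallel
        asym += max(0, gap_m - max(0, gap_s))

    passed = (
        mismatches_mir <= max_mismatch
        and mismatches_star <= max_mismatch
        and _runs(mm_flags) <= max_consecutive
        and _runs(star_flags) <= max_consecutive
        and asym <= max_asymmetric
    )
    return MircheckVerdict(
        passed=passed,
        reason="" if passed else "duplex criteria not met",
        mismatches_mir=mismatches_mir,
        mismatches_star=mismatches_star,
        max_consecutive_mismatches=max_run,
        asymmetric_unpaired=asym,
    )


def structural_features(
    fold_: HairpinFold, mature_offset: int, mature_len: int
) -> dict[str, float]:
    """Measurements used by the comparative feature panel."""
    span = fold_.loop_span
    e = mature_offset + mature_len
    if span is None:
        mir_loop = float("nan")
    else:
        loop_s, loop_e = span
        if e <= loop_s:  # 5' arm
            mir_loop = loop_s - e
        elif mature_offset >= loop_e:  # 3' arm
            mir_loop = mature_offset - loop_e
        else:
            mir_loop = float("nan")
    return {
        "precursor_length": float(len(fold_.seq)),
        "mirna_length": float(mature_len),
        "stem_length": float(fold_.stem_length),
        "loop_length": float(fold_.loop_length),
        "match_ratio": fold_.match_ratio,
        "mir_loop_distance": float(mir_loop),
    }
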