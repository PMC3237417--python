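"""Independent brute-force oracles used by the unit and acceptance suites.

These implementations are deliberately naive (memoised exhaustive
recursion) and share no code with the production paths they check.
"""

from functools import lru_cache

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def max_pairs_exhaustive(seq: str, min_loop: int = 3) -> int:
    """Maximum pair count over all nested structures (exhaustive)."""
    s = seq.upper().replace("U", "T")
    n = len(s)

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if j - i <= min_loop:
            return 0
        b = best(i + 1, j)  # i unpaired
        for k in range(i + min_loop + 1, j + 1):
            if (s[i], s[k]) in _PAIRS:
                b = max(b, 1 + best(i + 1, k - 1) + best(k + 1, j))
        return b

    return best(0, n - 1) if n else 0


def sw_score_exhaustive(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
) -> float:
    """Best local alignment score by exhaustive suffix recursion.

    State 0 = last column aligned a residue pair, 1 = gap in a, 2 = gap
    in b; the alignment may stop anywhere (score floor 0 via the empty
    alignment).
    """
    n, m = len(a), len(b)

    @lru_cache(maxsize=None)
    def from_(i: int, j: int, state: int) -> float:
        opts = [0.0]  # stop here
        if i < n and j < m:
            sub = match if a[i] == b[j] else mismatch
            opts.append(sub + from_(i + 1, j + 1, 0))
        if i < n:
            opts.append((gap_extend if state == 1 else gap_open) + from_(i + 1, j, 1))
        if j < m:
            opts.append((gap_extend if state == 2 else gap_open) + from_(i, j + 1, 2))
        return max(opts)

    best = 0.0
    for i in range(n):
        for j in range(m):
            best = max(best, from_(i, j, 0))
    from_.cache_clear()
    return best


def best_chain_exhaustive(anchors, gap_penalty=1.0, min_anchors=3, max_gap=25):
    """Best collinear chain by enumerating every anchor subset.

    Valid chains have strictly increasing pos_a and strictly monotonic
    pos_b (either direction) with per-step rank gaps <= max_gap.
    Returns (score, tuple_of_anchors) or None.
    """
    import itertools
    import math

    def score(chain):
        total = sum(math.log1p(max(a.score, 0.0)) for a in chain)
        for p, c in zip(chain, chain[1:]):
            total -= gap_penalty * (abs(c.pos_a - p.pos_a) - 1)
            total -= gap_penalty * (abs(c.pos_b - p.pos_b) - 1)
        return total

    def valid(chain):
        for sign in (1, -1):
            ok = True
            for p, c in zip(chain, chain[1:]):
                da = c.pos_a - p.pos_a
                db = sign * (c.pos_b - p.pos_b)
                if da <= 0 or db <= 0 or da - 1 > max_gap or db - 1 > max_gap:
                    ok = False
                    break
            if ok:
                return True
        return False

    best = None
    items = sorted(anchors, key=lambda a: (a.pos_a, a.pos_b))
    for r in range(min_anchors, len(items) + 1):
        for combo in itertools.combinations(items, r):
            if valid(combo):
                sc = score(combo)
                if best is None or sc > best[0]:
                    best = (sc, combo)
    return best
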