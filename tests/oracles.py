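"""Independent brute-force oracles used to verify the implementation.

These deliberately share no code with the package: a quadratic
Smith-Waterman/Gotoh DP with traceback, an all-pairs reverse-complement
substring scan, a per-column census for parsimony-informative sites, and
an exhaustive bait-window enumerator.
"""

from __future__ import annotations

from itertools import combinations

NEG = float("-inf")

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def sw_local(
    a: str,
    b: str,
    match: int = 2,
    mismatch: int = -3,
    gap_open: int = 5,
    gap_extend: int = 2,
) -> tuple[int, int]:
    """Optimal local alignment score and its longest exact-match run.

    Affine gaps: the first gap position costs gap_open + gap_extend, each
    further position gap_extend.  Returns (score, max run of consecutive
    identical aligned pairs on one optimal alignment); (0, 0) when no
    positive-scoring alignment exists.
    """
    n, m = len(a), len(b)
    oe = gap_open + gap_extend
    M = [[0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(M[i - 1][j] - oe, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - oe, Y[i][j - 1] - gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            diag = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = max(0, diag + s)
            if M[i][j] > best:
                best, bi, bj = M[i][j], i, j
    if best == 0:
        return 0, 0

    # traceback from the best M cell, tracking consecutive-match runs
    i, j, state = bi, bj, "M"
    run = max_run = 0
    while i > 0 and j > 0:
        if state == "M":
            if M[i][j] == 0:
                break
            if a[i - 1] == b[j - 1]:
                run += 1
                max_run = max(max_run, run)
            else:
                run = 0
            s = match if a[i - 1] == b[j - 1] else mismatch
            prev = M[i][j] - s
            if prev == 0 and M[i - 1][j - 1] == 0:
                break
            if prev == M[i - 1][j - 1]:
                state = "M"
            elif prev == X[i - 1][j - 1]:
                state = "X"
            else:
                state = "Y"
            i, j = i - 1, j - 1
        elif state == "X":
            run = 0
            if X[i][j] == M[i - 1][j] - oe:
                state = "M"
            i -= 1
        else:
            run = 0
            if Y[i][j] == M[i][j - 1] - oe:
                state = "M"
            j -= 1
    return best, max_run


def rc_flags(sequences: list[tuple[str, str]], k: int) -> set[str]:
    """All-pairs reverse-complement substring scan (the self-hyb oracle).

    ``sequences`` is [(bait_id, sequence)] in input order; the later bait
    of a flagged pair is reported, as is any palindromic bait.
    """

    def share_run(x: str, y: str) -> bool:
        words = {x[i : i + k] for i in range(len(x) - k + 1)}
        return any(y[i : i + k] in words for i in range(len(y) - k + 1))

    flagged = set()
    for idx, (bid, seq) in enumerate(sequences):
        if share_run(seq, rc(seq)):
            flagged.add(bid)
        for _, earlier_seq in sequences[:idx]:
            if share_run(earlier_seq, rc(seq)):
                flagged.add(bid)
                break
    return flagged


MISSING = set("-?NX")


def pi_sites(rows: list[str]) -> int:
    """Per-column census of parsimony-informative sites."""
    if not rows:
        return 0
    count = 0
    for col in zip(*rows):
        tally: dict[str, int] = {}
        for ch in col:
            if ch not in MISSING:
                tally[ch] = tally.get(ch, 0) + 1
        if sum(1 for v in tally.values() if v >= 2) >= 2:
            count += 1
    return count


def missing_pct(rows: list[str]) -> float:
    cells = sum(len(r) for r in rows)
    gone = sum(r.count("-") + r.count("?") for r in rows)
    return 100.0 * gone / cells if cells else 0.0


def mean_pairwise_identity(rows: list[str], start: int, end: int) -> float:
    """Naive all-pairs identity over a window (gap columns count as columns)."""
    pairs = list(combinations(rows, 2))
    if not pairs or end <= start:
        return 0.0
    total = 0.0
    for x, y in pairs:
        same = sum(
            1
            for c in range(start, end)
            if x[c] == y[c] and x[c] != "-" and y[c] != "-"
        )
        total += same / (end - start)
    return total / len(pairs)


def enumerate_windows(
    rows: list[str],
    exon_ids: list[int],
    window_lengths: tuple[int, ...] = (240, 200, 160, 120),
) -> tuple[int, int] | None:
    """Exhaustive bait-window search: longest length first, gap-free
    columns, single exon, max mean pairwise identity, leftmost tie-break."""
    n_cols = len(rows[0])
    for w in window_lengths:
        candidates = []
        for start in range(0, n_cols - w + 1):
            cols = range(start, start + w)
            if any(any(r[c] == "-" for r in rows) for c in cols):
                continue
            if len({exon_ids[c] for c in cols}) != 1:
                continue
            candidates.append((start, mean_pairwise_identity(rows, start, start + w)))
        if candidates:
            best = max(candidates, key=lambda c: (c[1], -c[0]))
            return best[0], best[0] + w
    return None
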