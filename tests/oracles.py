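"""Independent brute-force reference implementations used to check the
package's algorithms on small instances.  These deliberately favor
obviousness over speed and share no code with the implementations they
check.
"""

from __future__ import annotations

_COMP = dict(zip("ACGTN", "TGCAN"))


def revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def n50_bruteforce(lengths: list[int]) -> int:
    """Largest candidate L with sum(lengths >= L) >= half, by full scan."""
    total = sum(lengths)
    best = 0
    for cand in sorted(set(lengths)):
        if sum(x for x in lengths if x >= cand) >= total / 2:
            best = max(best, cand)
    return best


def union_find_loci(genes: list[tuple[str, int, int]], max_gap: int):
    """Cluster (replicon, start, end) genes by gap <= max_gap, via union-find.

    Returns a sorted list of frozensets of gene indices.
    """
    n = len(genes)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            ri, si, ei = genes[i]
            rj, sj, ej = genes[j]
            if ri != rj:
                continue
            gap = max(sj - ei, si - ej)
            if gap <= max_gap:
                parent[find(i)] = find(j)
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return sorted(
        (frozenset(g) for g in groups.values()),
        key=lambda g: min(g),
    )


def enumerate_tcs_runs(
    positions: list[tuple[int, int]], roles: list[str], pair_gap: int
) -> list[str]:
    """Organization labels by explicit run enumeration.

    ``positions`` are (start, end) sorted by start on one replicon; returns
    one label per gene.
    """
    runs: list[list[int]] = []
    for i in range(len(positions)):
        if runs and positions[i][0] - positions[runs[-1][-1]][1] <= pair_gap:
            runs[-1].append(i)
        else:
            runs.append([i])
    labels = [""] * len(positions)
    for run in runs:
        rr = [roles[i] for i in run]
        hk_like = sum(1 for r in rr if r in ("HK", "hybrid"))
        n_rr = sum(1 for r in rr if r == "RR")
        if len(run) == 2 and hk_like == 1 and n_rr == 1:
            lab = "paired"
        elif len(run) >= 3:
            lab = "complex"
        else:
            lab = "orphan"
        for i in run:
            labels[i] = lab
    return labels


def global_repeats_bruteforce(seq: str, min_len: int) -> set[tuple[int, int]]:
    """Intervals of pair-maximal repeated matches >= min_len, nested dropped."""
    n = len(seq)
    intervals: set[tuple[int, int]] = set()
    for p in range(n):
        for q in range(p + 1, n):
            if seq[p] != seq[q]:
                continue
            if p > 0 and q > 0 and seq[p - 1] == seq[q - 1]:
                continue  # not left-maximal
            length = 0
            while q + length < n and seq[p + length] == seq[q + length]:
                length += 1
            if length >= min_len:
                intervals.add((p, p + length))
                intervals.add((q, q + length))
    kept = set()
    for s, e in intervals:
        if not any(
            (s2 <= s and e <= e2) and (s2, e2) != (s, e) for s2, e2 in intervals
        ):
            kept.add((s, e))
    return kept


def inverted_repeats_bruteforce(
    seq: str, min_arm: int, loop_max: int
) -> set[tuple[int, int, int, int]]:
    """All maximal (a, b, c, d) with revcomp arms and bounded loop."""
    n = len(seq)
    out = set()
    for arm in range(min_arm, n // 2 + 1):
        for a in range(n - 2 * arm + 1):
            b = a + arm
            for loop in range(0, loop_max + 1):
                c = b + loop
                d = c + arm
                if d > n:
                    break
                if seq[c:d] != revcomp(seq[a:b]):
                    continue
                # outward maximality
                if a > 0 and d < n and seq[a - 1] == _COMP[seq[d]]:
                    continue
                # inward maximality
                if b < c and seq[b] == _COMP[seq[c - 1]]:
                    continue
                out.add((a, b, c, d))
    return out


def tandem_repeats_bruteforce(
    seq: str, period_min: int, period_max: int, min_copies: int
) -> set[tuple[int, int, int, int]]:
    """All maximal smallest-period runs as (start, end, period, copies)."""
    n = len(seq)
    out = set()
    for p in range(period_min, period_max + 1):
        for s in range(n):
            # maximal run at period p starting at s
            if s + p >= n or seq[s + p] != seq[s]:
                continue
            if s >= 1 and s + p - 1 < n and seq[s - 1] == seq[s - 1 + p]:
                continue  # not left-maximal
            e = s + p
            while e < n and seq[e] == seq[e - p]:
                e += 1
            copies = (e - s) // p
            if copies < min_copies:
                continue
            smaller = False
            for q in range(1, p):
                if all(seq[x] == seq[x - q] for x in range(s + q, e)):
                    smaller = True
                    break
            if not smaller:
                out.add((s, e, p, copies))
    return out
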