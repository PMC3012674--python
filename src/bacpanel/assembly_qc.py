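"""Assembly reconciliation, coverage QC and repeat catalogues.

Reconciliation places one technology's contigs onto the hybrid scaffolds of
another (k-mer seeded, mismatch-bounded) and summarizes coverage fraction,
signed inter-contig distances (negative = overlap), missing bases and mean
identity.  Coverage QC tiles a depth track into fixed windows, flags windows
outside mean +/- n*sd, and turns depth ratios into copy-number estimates for
collapsed repeats.  The repeat catalogue finds global repeats (a sequence
present at two or more distinct positions), local inverted repeats
(reverse-complement arms around a bounded loop) and tandem repeats
(short-period runs), all verified exact.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_SEED_K = 31
DEFAULT_MAX_MISMATCH_FRAC = 0.01
DEFAULT_WINDOW_BP = 5000
DEFAULT_FLAG_N_SD = 2.0


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# N50
# ---------------------------------------------------------------------------

def compute_n50(lengths: list[int]) -> int:
    """Largest L such that sequences of length >= L hold >= half the total."""
    if not lengths:
        raise ValueError("compute_n50 needs at least one length")
    if any(x <= 0 for x in lengths):
        raise ValueError("lengths must be positive")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for x in ordered:
        acc += x
        if acc >= half:
            return x
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# contig placement onto scaffolds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Placement:
    """A contig aligned onto a scaffold interval (0-based half-open)."""

    contig_id: str
    scaffold_id: str
    start: int
    end: int
    orientation: str  # "forward" or "reverse-complement"
    identity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be in [0, 1]")

    @property
    def span(self) -> int:
        return self.end - self.start


def _as_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def place_contigs(
    contigs: dict[str, str],
    scaffolds: dict[str, str],
    k: int = DEFAULT_SEED_K,
    max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
) -> tuple[list[Placement], dict[str, str]]:
    """Place each contig on the scaffolds by k-mer seeding + full extension.

    A k-mer index of the scaffolds proposes (scaffold, offset) candidates
    for both orientations of each contig; each in-bounds candidate is scored
    by full-length mismatch count and accepted when
    mismatches / span <= ``max_mismatch_frac``.  When several distinct
    candidates tie at the minimal mismatch count the contig is reported
    unplaced as ambiguous (determinism over guessing).

    Returns (placements, unplaced) where ``unplaced`` maps contig id to a
    reason string.
    """
    if k < 11:
        raise ValueError("seed k must be >= 11")
    if not 0 <= max_mismatch_frac < 0.1:
        raise ValueError("max_mismatch_frac must be in [0, 0.1)")

    index: dict[str, list[tuple[str, int]]] = {}
    scaf_bytes = {}
    for sid, seq in scaffolds.items():
        scaf_bytes[sid] = _as_bytes(seq)
        for pos in range(len(seq) - k + 1):
            index.setdefault(seq[pos:pos + k], []).append((sid, pos))

    placements: list[Placement] = []
    unplaced: dict[str, str] = {}
    for cid in contigs:
        seq = contigs[cid]
        if len(seq) < k:
            unplaced[cid] = f"shorter than seed k={k}"
            continue
        candidates: dict[tuple[str, int, str], int] = {}
        for orient, oseq in (
            ("forward", seq),
            ("reverse-complement", reverse_complement(seq)),
        ):
            # sample ~25 seed k-mers across the contig
            step = max(1, (len(oseq) - k) // 24) if len(oseq) > k else 1
            seed_positions = list(range(0, len(oseq) - k + 1, step))
            for i in seed_positions:
                for sid, pos in index.get(oseq[i:i + k], ()):
                    offset = pos - i
                    if offset < 0 or offset + len(oseq) > len(scaffolds[sid]):
                        continue
                    candidates[(sid, offset, orient)] = (
                        candidates.get((sid, offset, orient), 0) + 1
                    )
        if not candidates:
            unplaced[cid] = "no seed match"
            continue
        scored: list[tuple[int, str, int, str]] = []
        for (sid, offset, orient) in sorted(candidates):
            oseq = seq if orient == "forward" else reverse_complement(seq)
            mism = int(np.count_nonzero(
                scaf_bytes[sid][offset:offset + len(oseq)] != _as_bytes(oseq)
            ))
            scored.append((mism, sid, offset, orient))
        scored.sort()
        best = scored[0]
        if best[0] / len(seq) > max_mismatch_frac:
            unplaced[cid] = "mismatch fraction above threshold"
            continue
        if len(scored) > 1 and scored[1][0] == best[0]:
            unplaced[cid] = "ambiguous placement"
            continue
        mism, sid, offset, orient = best
        placements.append(
            Placement(
                contig_id=cid,
                scaffold_id=sid,
                start=offset,
                end=offset + len(seq),
                orientation=orient,
                identity=1.0 - mism / len(seq),
            )
        )
    return placements, unplaced


# ---------------------------------------------------------------------------
# reconciliation report
# ---------------------------------------------------------------------------

@dataclass
class ReconciliationReport:
    """Panel-wide placement summary.

    ``mean_signed_distance`` averages next.start - prev.end over consecutive
    placements within each scaffold (negative = overlap); scaffolds with
    fewer than two placements contribute no distances (None when no scaffold
    has two).
    """

    coverage_fraction: float
    mean_signed_distance: float | None
    missing_bp: int
    mean_identity: float
    total_scaffold_bp: int
    n_placements: int

    def as_dict(self) -> dict:
        return {
            "coverage_fraction": self.coverage_fraction,
            "mean_signed_distance": self.mean_signed_distance,
            "missing_bp": self.missing_bp,
            "mean_identity": self.mean_identity,
            "total_scaffold_bp": self.total_scaffold_bp,
            "n_placements": self.n_placements,
        }


def reconcile(
    placements: list[Placement], scaffolds: dict[str, str]
) -> ReconciliationReport:
    """Aggregate placements into coverage / distance / identity statistics."""
    for p in placements:
        if p.scaffold_id not in scaffolds:
            raise KeyError(f"placement references unknown scaffold {p.scaffold_id!r}")
    total_bp = sum(len(s) for s in scaffolds.values())
    covered = 0
    distances: list[int] = []
    ident_weighted = 0.0
    ident_bp = 0
    by_scaffold: dict[str, list[Placement]] = {sid: [] for sid in scaffolds}
    for p in placements:
        by_scaffold[p.scaffold_id].append(p)
        ident_weighted += p.identity * p.span
        ident_bp += p.span
    for sid, plist in by_scaffold.items():
        plist.sort(key=lambda p: (p.start, p.end))
        # merged interval coverage
        cur_start = cur_end = None
        for p in plist:
            if cur_end is None or p.start > cur_end:
                if cur_end is not None:
                    covered += cur_end - cur_start
                cur_start, cur_end = p.start, p.end
            else:
                cur_end = max(cur_end, p.end)
        if cur_end is not None:
            covered += cur_end - cur_start
        for prev, nxt in zip(plist, plist[1:]):
            distances.append(nxt.start - prev.end)
    coverage = covered / total_bp if total_bp else 0.0
    return ReconciliationReport(
        coverage_fraction=coverage,
        mean_signed_distance=(sum(distances) / len(distances)) if distances else None,
        missing_bp=total_bp - covered,
        mean_identity=(ident_weighted / ident_bp) if ident_bp else 0.0,
        total_scaffold_bp=total_bp,
        n_placements=len(placements),
    )


# ---------------------------------------------------------------------------
# coverage windows, flags and copy number
# ---------------------------------------------------------------------------

@dataclass
class CoverageTrack:
    """Windowed mean depth over one replicon.

    Windows are non-overlapping tiles of ``window_bp``; the last window may
    be partial.  ``mean``/``sd`` are the genome-wide mean and population sd
    of the window means.
    """

    window_bp: int
    window_means: np.ndarray
    length_bp: int
    replicon_id: str = "genome"

    def __post_init__(self) -> None:
        self.window_means = np.asarray(self.window_means, dtype=float)
        expected = math.ceil(self.length_bp / self.window_bp)
        if len(self.window_means) != expected:
            raise ValueError(
                f"expected {expected} windows for {self.length_bp} bp at "
                f"{self.window_bp} bp, got {len(self.window_means)}"
            )

    @classmethod
    def from_depths(
        cls,
        depths: np.ndarray,
        window_bp: int = DEFAULT_WINDOW_BP,
        replicon_id: str = "genome",
    ) -> "CoverageTrack":
        depths = np.asarray(depths, dtype=float)
        n_windows = math.ceil(len(depths) / window_bp)
        means = np.array([
            depths[i * window_bp:(i + 1) * window_bp].mean()
            for i in range(n_windows)
        ])
        return cls(window_bp, means, len(depths), replicon_id)

    @property
    def mean(self) -> float:
        return float(self.window_means.mean())

    @property
    def sd(self) -> float:
        return float(self.window_means.std(ddof=0))

    def window_bounds(self, i: int) -> tuple[int, int]:
        return i * self.window_bp, min((i + 1) * self.window_bp, self.length_bp)

    def to_bedgraph(self, path) -> None:
        """bedGraph-style TSV (0-based half-open, as is standard for bedGraph)."""
        with open(path, "w") as fh:
            for i, m in enumerate(self.window_means):
                s, e = self.window_bounds(i)
                fh.write(f"{self.replicon_id}\t{s}\t{e}\t{m:.4f}\n")

    @classmethod
    def from_bedgraph(cls, path) -> "CoverageTrack":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip()
                if not line or line.startswith(("#", "track")):
                    continue
                rep, s, e, d = line.split("\t")
                rows.append((rep, int(s), int(e), float(d)))
        if not rows:
            raise ValueError("empty bedGraph")
        window_bp = rows[0][2] - rows[0][1]
        return cls(
            window_bp=window_bp,
            window_means=np.array([r[3] for r in rows]),
            length_bp=rows[-1][2],
            replicon_id=rows[0][0],
        )


def coverage_flags(track: CoverageTrack, n_sd: float = DEFAULT_FLAG_N_SD) -> list[str]:
    """Per-window flags: 'high' above mean + n_sd*sd, 'low' below, else 'normal'."""
    if n_sd <= 0:
        raise ValueError("n_sd must be > 0")
    hi = track.mean + n_sd * track.sd
    lo = track.mean - n_sd * track.sd
    return [
        "high" if m > hi else "low" if m < lo else "normal"
        for m in track.window_means
    ]


def estimate_copy_number(
    track: CoverageTrack,
    region: tuple[int, int],
    genome_mean_depth: float | None = None,
) -> tuple[float, int]:
    """Copy number of a region as its depth ratio to the genome mean.

    ``region`` is (start_bp, end_bp); windows overlapping it are averaged.
    Returns (ratio, nearest-integer copy estimate).
    """
    if genome_mean_depth is None:
        genome_mean_depth = track.mean
    if genome_mean_depth <= 0:
        raise ValueError("genome mean depth must be > 0")
    start, end = region
    sel = [
        m for i, m in enumerate(track.window_means)
        if track.window_bounds(i)[1] > start and track.window_bounds(i)[0] < end
    ]
    if not sel:
        raise ValueError("region overlaps no coverage window")
    ratio = float(np.mean(sel)) / genome_mean_depth
    return ratio, round(ratio)


# ---------------------------------------------------------------------------
# scaffold-end repeat statistics
# ---------------------------------------------------------------------------

def _longest_common_substring(a: str, b: str) -> int:
    """Length of the longest exact substring shared by a and b (DP)."""
    best = 0
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        ai = a[i - 1]
        for j in range(1, len(b) + 1):
            if ai == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def scaffold_end_repeat_stats(
    scaffolds: dict[str, str],
    end_len: int = 100,
    min_match: int = 20,
) -> dict[str, float]:
    """Shared-sequence statistics over scaffold ends.

    Both termini of every scaffold contribute an ``end_len`` bp end (the
    whole scaffold, logged, when shorter).  For each end the longest exact
    substring of length >= ``min_match`` shared with any other end is sought
    on both strands.  Returns the fraction of ends with a match (over all
    ends), the mean longest-match length and the mean number of other ends
    matched (both over matched ends only).
    """
    if not (end_len >= min_match >= 8):
        raise ValueError("need end_len >= min_match >= 8")
    ends: list[str] = []
    for sid, seq in scaffolds.items():
        if len(seq) < end_len:
            logger.warning(
                "scaffold %s shorter than end_len %d; whole scaffold used",
                sid, end_len,
            )
            ends.extend([seq, seq])
        else:
            ends.extend([seq[:end_len], seq[-end_len:]])

    n = len(ends)
    best_len = [0] * n
    n_matched_ends = [0] * n
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            m = max(
                _longest_common_substring(ends[i], ends[j]),
                _longest_common_substring(ends[i], reverse_complement(ends[j])),
            )
            if m >= min_match:
                n_matched_ends[i] += 1
                best_len[i] = max(best_len[i], m)
    matched = [i for i in range(n) if n_matched_ends[i] > 0]
    frac = len(matched) / n if n else 0.0
    mean_len = float(np.mean([best_len[i] for i in matched])) if matched else 0.0
    mean_mult = float(np.mean([n_matched_ends[i] for i in matched])) if matched else 0.0
    return {
        "n_ends": n,
        "fraction_with_repeat": frac,
        "mean_repeat_length": mean_len,
        "mean_ends_matched": mean_mult,
    }


# ---------------------------------------------------------------------------
# repeat catalogue
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GlobalRepeat:
    """A maximal interval whose sequence occurs at >= 2 distinct positions."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class InvertedRepeat:
    """Two reverse-complement arms around a loop: arms [left_start, left_end)
    and [right_start, right_end), loop = right_start - left_end."""

    left_start: int
    left_end: int
    right_start: int
    right_end: int

    @property
    def arm_length(self) -> int:
        return self.left_end - self.left_start

    @property
    def loop_length(self) -> int:
        return self.right_start - self.left_end


@dataclass(frozen=True)
class TandemRepeat:
    """Maximal run of a short period: region [start, end), unit ``period``,
    ``copies`` = floor(region length / period)."""

    start: int
    end: int
    period: int
    copies: int


@dataclass
class RepeatConfig:
    min_global_len: int = 25      # L_g
    min_arm_len: int = 10         # L_i
    loop_max: int = 100
    period_min: int = 1
    period_max: int = 6
    min_copies: int = 3           # c_min


@dataclass
class RepeatCatalog:
    global_repeats: list[GlobalRepeat] = field(default_factory=list)
    inverted_repeats: list[InvertedRepeat] = field(default_factory=list)
    tandem_repeats: list[TandemRepeat] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        return {
            "global": len(self.global_repeats),
            "inverted": len(self.inverted_repeats),
            "tandem": len(self.tandem_repeats),
        }


def find_global_repeats(seq: str, min_len: int = 25) -> list[GlobalRepeat]:
    """Maximal non-nested intervals whose sequence recurs elsewhere.

    Pairs of occurrences are seeded by repeated ``min_len``-mers and
    extended to pair-maximal matches; the intervals of all such matches of
    length >= ``min_len`` are pooled and nested intervals dropped.
    """
    n = len(seq)
    positions: dict[str, list[int]] = {}
    for i in range(n - min_len + 1):
        positions.setdefault(seq[i:i + min_len], []).append(i)

    pair_max: set[tuple[int, int, int]] = set()
    for pos_list in positions.values():
        if len(pos_list) < 2:
            continue
        for ai in range(len(pos_list)):
            for bi in range(ai + 1, len(pos_list)):
                p, q = pos_list[ai], pos_list[bi]
                length = min_len
                while p > 0 and q > 0 and seq[p - 1] == seq[q - 1]:
                    p -= 1
                    q -= 1
                    length += 1
                while q + length < n and seq[p + length] == seq[q + length]:
                    length += 1
                pair_max.add((p, q, length))

    intervals: set[tuple[int, int]] = set()
    for p, q, length in pair_max:
        intervals.add((p, p + length))
        intervals.add((q, q + length))
    return [GlobalRepeat(s, e) for s, e in _drop_nested(intervals)]


def _drop_nested(intervals: set[tuple[int, int]]) -> list[tuple[int, int]]:
    kept = []
    ordered = sorted(intervals, key=lambda iv: (iv[0], -iv[1]))
    max_end = -1
    for s, e in ordered:
        if e <= max_end:
            continue  # nested in a previously kept interval
        kept.append((s, e))
        max_end = e
    return kept


def find_inverted_repeats(
    seq: str, min_arm: int = 10, loop_max: int = 100
) -> list[InvertedRepeat]:
    """Maximal local inverted repeats: exact reverse-complement arms of
    length >= ``min_arm`` separated by a loop of at most ``loop_max`` bp."""
    n = len(seq)
    positions: dict[str, list[int]] = {}
    for i in range(n - min_arm + 1):
        positions.setdefault(seq[i:i + min_arm], []).append(i)

    comp = dict(zip("ACGTN", "TGCAN"))
    found: set[tuple[int, int, int, int]] = set()
    for i in range(n - min_arm + 1):
        rc = reverse_complement(seq[i:i + min_arm])
        for j in positions.get(rc, ()):
            if j < i + min_arm or j - (i + min_arm) > loop_max:
                continue
            a, b, c, d = i, i + min_arm, j, j + min_arm
            while a > 0 and d < n and seq[a - 1] == comp.get(seq[d], "?"):
                a -= 1
                d += 1
            while b < c and seq[b] == comp.get(seq[c - 1], "?"):
                b += 1
                c -= 1
            if c - b <= loop_max and b - a >= min_arm:
                found.add((a, b, c, d))
    return [
        InvertedRepeat(*t)
        for t in sorted(found)
    ]


def find_tandem_repeats(
    seq: str,
    period_min: int = 1,
    period_max: int = 6,
    min_copies: int = 3,
) -> list[TandemRepeat]:
    """Maximal tandem runs of periods in [period_min, period_max].

    A run is reported at its smallest period only (a poly-A tract appears
    once, at period 1, not again at periods 2..6).
    """
    n = len(seq)
    runs: list[TandemRepeat] = []
    for p in range(period_min, period_max + 1):
        i = p
        while i < n:
            if seq[i] == seq[i - p]:
                s = i - p
                while i < n and seq[i] == seq[i - p]:
                    i += 1
                e = i
                copies = (e - s) // p
                if copies >= min_copies and not _has_smaller_period(seq, s, e, p):
                    runs.append(TandemRepeat(s, e, p, copies))
            else:
                i += 1
    runs.sort(key=lambda r: (r.start, r.period))
    return runs


def _has_smaller_period(seq: str, s: int, e: int, p: int) -> bool:
    for q in range(1, p):
        if all(seq[x] == seq[x - q] for x in range(s + q, e)):
            return True
    return False


def find_repeats(seq: str, config: RepeatConfig | None = None) -> RepeatCatalog:
    """Full repeat catalogue of one sequence under one config."""
    if config is None:
        config = RepeatConfig()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
    return RepeatCatalog(
        global_repeats=find_global_repeats(seq, config.min_global_len),
        inverted_repeats=find_inverted_repeats(
            seq, config.min_arm_len, config.loop_max
        ),
        tandem_repeats=find_tandem_repeats(
            seq, config.period_min, config.period_max, config.min_copies
        ),
    )


def write_repeats_bed(catalog: RepeatCatalog, path, replicon_id: str = "genome") -> None:
    """Repeat intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for r in catalog.global_repeats:
            fh.write(f"{replicon_id}\t{r.start}\t{r.end}\tglobal_repeat\n")
        for r in catalog.inverted_repeats:
            fh.write(
                f"{replicon_id}\t{r.left_start}\t{r.right_end}\t"
                f"inverted_repeat;arm={r.arm_length};loop={r.loop_length}\n"
            )
        for r in catalog.tandem_repeats:
            fh.write(
                f"{replicon_id}\t{r.start}\t{r.end}\t"
                f"tandem_repeat;period={r.period};copies={r.copies}\n"
            )
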