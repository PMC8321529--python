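"""EM reallocation of multi-mapping reads across near-identical loci.

Each multi-mapping read starts with a uniform posterior over its candidate
placements.  Iterations redistribute posterior mass in proportion to local
"support": uniquely-mapped coverage in a window around each candidate plus the
current posterior mass of OTHER multi-reads placed nearby, plus a small
pseudo-support epsilon.  A read's own mass is excluded from its support so a
placement cannot justify itself in a coverage desert.  After convergence the
highest-posterior candidate becomes the primary placement, with deterministic
lexicographic tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_WINDOW = 101
DEFAULT_EPSILON = 0.1
DEFAULT_MAX_ITER = 200
DEFAULT_TOL = 1e-6


@dataclass(frozen=True)
class Candidate:
    chrom: str
    pos: int  # 0-based start
    strand: str = "+"

    def key(self):
        return (self.chrom, self.pos, self.strand)


@dataclass
class MultiMapping:
    read_id: str
    candidates: list  # of Candidate
    scores: list | None = None  # optional per-candidate alignment scores

    def __post_init__(self):
        if len(self.candidates) < 1:
            raise ValueError(f"read {self.read_id}: needs >=1 candidate")
        keys = [c.key() for c in self.candidates]
        if len(set(keys)) != len(keys):
            raise ValueError(f"read {self.read_id}: duplicate candidates")
        if self.scores is not None and len(self.scores) != len(self.candidates):
            raise ValueError(f"read {self.read_id}: score/candidate length mismatch")


@dataclass
class AllocationResult:
    read_id: str
    candidates: list
    posteriors: np.ndarray
    iterations: int
    converged: bool
    zero_support: bool = False


class UniqueCoverageTrack:
    """Per-position counts of uniquely mapped reads, one array per chromosome."""

    def __init__(self, coverage: dict[str, np.ndarray]):
        self.coverage = {}
        self._cumsum = {}
        for chrom, arr in coverage.items():
            arr = np.asarray(arr)
            if (arr < 0).any():
                raise ValueError(f"{chrom}: negative coverage")
            self.coverage[chrom] = arr
            self._cumsum[chrom] = np.concatenate([[0], np.cumsum(arr, dtype=float)])

    @classmethod
    def empty(cls, genome: dict[str, int]) -> "UniqueCoverageTrack":
        return cls({c: np.zeros(n, dtype=int) for c, n in genome.items()})

    @classmethod
    def from_reads(
        cls, genome: dict[str, int], reads, read_length: int
    ) -> "UniqueCoverageTrack":
        """Pile up coverage from (chrom, start) unique placements."""
        cov = {c: np.zeros(n, dtype=int) for c, n in genome.items()}
        for chrom, start in reads:
            arr = cov[chrom]
            lo = max(0, start)
            hi = min(len(arr), start + read_length)
            arr[lo:hi] += 1
        return cls(cov)

    def window_sum(self, chrom: str, pos: int, window: int) -> float:
        """Total unique coverage in the window of length ``window`` centered
        on ``pos`` (clipped at chromosome bounds)."""
        if chrom not in self._cumsum:
            return 0.0
        cs = self._cumsum[chrom]
        half = window // 2
        lo = max(0, pos - half)
        hi = min(len(cs) - 1, pos + half + 1)
        if hi <= lo:
            return 0.0
        return float(cs[hi] - cs[lo])


def em_allocate(
    reads: list[MultiMapping],
    unique: UniqueCoverageTrack,
    window_w: int = DEFAULT_WINDOW,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    epsilon: float = DEFAULT_EPSILON,
    use_scores: bool = False,
) -> list[AllocationResult]:
    """Iteratively allocate multi-mapping reads by local support.

    support(read i, candidate j) =
        unique coverage within window_w of j
      + posterior mass of other multi-reads with candidates within window_w
      + epsilon
    optionally multiplied by exp(alignment score) when ``use_scores`` is set.
    Responsibilities are renormalized per read each iteration; iteration stops
    when the largest posterior change drops below ``tol``.
    """
    if window_w <= 0:
        raise ValueError("window_w must be positive")
    if tol <= 0:
        raise ValueError("tol must be positive")
    half = window_w // 2

    posts = [np.full(len(r.candidates), 1.0 / len(r.candidates)) for r in reads]
    uniq_support = [
        np.array([unique.window_sum(c.chrom, c.pos, window_w) for c in r.candidates])
        for r in reads
    ]
    score_w = []
    for r in reads:
        if use_scores and r.scores is not None:
            s = np.asarray(r.scores, dtype=float)
            score_w.append(np.exp(s - s.max()))
        else:
            score_w.append(np.ones(len(r.candidates)))

    # per-chromosome sorted candidate positions for windowed multi-read mass
    chrom_entries: dict[str, list] = {}
    for i, r in enumerate(reads):
        for j, c in enumerate(r.candidates):
            chrom_entries.setdefault(c.chrom, []).append((c.pos, i, j))
    chrom_pos = {}
    chrom_idx = {}
    for chrom, entries in chrom_entries.items():
        entries.sort()
        chrom_pos[chrom] = np.array([e[0] for e in entries])
        chrom_idx[chrom] = [(e[1], e[2]) for e in entries]

    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        # mass contributed by each multiread candidate at its position
        mass = {
            chrom: np.array([posts[i][j] for (i, j) in idx])
            for chrom, idx in chrom_idx.items()
        }
        mass_cum = {c: np.concatenate([[0.0], np.cumsum(m)]) for c, m in mass.items()}
        max_delta = 0.0
        new_posts = []
        for i, r in enumerate(reads):
            support = uniq_support[i] + epsilon
            for j, c in enumerate(r.candidates):
                pos_arr = chrom_pos[c.chrom]
                lo = np.searchsorted(pos_arr, c.pos - half, side="left")
                hi = np.searchsorted(pos_arr, c.pos + half, side="right")
                total = mass_cum[c.chrom][hi] - mass_cum[c.chrom][lo]
                # exclude this read's own candidates falling in the window
                own = sum(
                    posts[i][jj]
                    for jj, cc in enumerate(r.candidates)
                    if cc.chrom == c.chrom and abs(cc.pos - c.pos) <= half
                )
                support[j] += max(total - own, 0.0)
            support = support * score_w[i]
            tot = support.sum()
            newp = support / tot if tot > 0 else np.full_like(support, 1.0 / support.size)
            max_delta = max(max_delta, float(np.abs(newp - posts[i]).max()))
            new_posts.append(newp)
        posts = new_posts
        if max_delta < tol:
            converged = True
            break

    results = []
    for r, p, us in zip(reads, posts, uniq_support):
        results.append(
            AllocationResult(
                read_id=r.read_id,
                candidates=list(r.candidates),
                posteriors=p,
                iterations=iterations,
                converged=converged,
                zero_support=bool(us.sum() == 0),
            )
        )
    return results


def select_primary(alloc: AllocationResult) -> Candidate:
    """Highest-posterior candidate; exact ties resolved lexicographically by
    (chrom, pos, strand)."""
    best_p = alloc.posteriors.max()
    tied = [
        c for c, p in zip(alloc.candidates, alloc.posteriors) if p == best_p
    ]
    return min(tied, key=lambda c: c.key())
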