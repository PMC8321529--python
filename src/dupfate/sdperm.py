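"""Interval arithmetic and the permutation depletion test.

All coordinates are BED-convention 0-based half-open.  The depletion test
compares the observed fraction of region bases covered by peaks against a
null built by re-placing the regions uniformly at random (length-preserving),
with the empirical p-value P = (M + 1)/(N + 1) where M counts null replicates
strictly below the observed value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_N_PERMUTATIONS = 1000
DEFAULT_IDENTITY_THRESHOLD = 0.98


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Genome:
    """Chromosome names and lengths."""

    lengths: dict  # chrom -> length

    def __post_init__(self):
        for chrom, n in self.lengths.items():
            if n <= 0:
                raise ValueError(f"chromosome {chrom}: non-positive length")

    def validate(self, intervals):
        for iv in intervals:
            if iv.chrom not in self.lengths:
                raise ValueError(f"unknown chromosome {iv.chrom}")
            if iv.end > self.lengths[iv.chrom]:
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                    f"chromosome length {self.lengths[iv.chrom]}"
                )


@dataclass
class NullDistribution:
    observed: float
    null_values: np.ndarray
    M: int
    empirical_p: float


def merge_intervals(intervals) -> list[GenomicInterval]:
    """Sort and merge overlapping or bookended (end == start) intervals."""
    by_chrom: dict[str, list] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda v: (v.start, v.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def total_length(intervals) -> int:
    return sum(len(iv) for iv in intervals)


def _chrom_arrays(intervals):
    out = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {
        c: (np.array([s for s, _ in v]), np.array([e for _, e in v]))
        for c, v in ((c, sorted(v)) for c, v in out.items())
    }


def intersect_length(a_merged, b_merged) -> int:
    """Total overlapping bases between two merged interval sets."""
    b_arr = _chrom_arrays(b_merged)
    total = 0
    for iv in a_merged:
        if iv.chrom not in b_arr:
            continue
        starts, ends = b_arr[iv.chrom]
        lo = np.searchsorted(ends, iv.start, side="right")
        hi = np.searchsorted(starts, iv.end, side="left")
        if hi > lo:
            ov = np.minimum(ends[lo:hi], iv.end) - np.maximum(starts[lo:hi], iv.start)
            total += int(ov.clip(min=0).sum())
    return total


def fraction_covered(regions, peaks) -> float:
    """Fraction of region bases covered by peaks (both sets are merged first)."""
    regions = merge_intervals(regions)
    if not regions:
        raise ValueError("empty region set")
    peaks = merge_intervals(peaks) if peaks else []
    denom = total_length(regions)
    if not peaks:
        return 0.0
    return intersect_length(regions, peaks) / denom


def permute_regions(
    regions,
    genome: Genome,
    n: int,
    seed,
    same_chromosome: bool = True,
    allow_overlap: bool = True,
    max_tries: int = 1000,
) -> list[list[GenomicInterval]]:
    """Length-preserving uniform re-placement of regions, ``n`` replicates.

    By default each region stays on its own chromosome and permuted regions
    may overlap one another (the marginal-uniform null).  With
    ``allow_overlap=False`` placements are rejection-sampled until disjoint.
    With ``same_chromosome=False`` a destination chromosome is drawn with
    probability proportional to its length among those long enough.
    """
    regions = list(regions)
    genome.validate(regions)
    rng = np.random.default_rng(seed)
    chrom_names = list(genome.lengths)
    chrom_len = np.array([genome.lengths[c] for c in chrom_names], dtype=float)
    replicates = []
    for _ in range(n):
        for _try in range(max_tries):
            placed = []
            for iv in regions:
                length = len(iv)
                if same_chromosome:
                    chrom = iv.chrom
                else:
                    ok = chrom_len >= length
                    w = np.where(ok, chrom_len, 0.0)
                    chrom = chrom_names[rng.choice(len(chrom_names), p=w / w.sum())]
                max_start = genome.lengths[chrom] - length
                start = int(rng.integers(0, max_start + 1))
                placed.append(GenomicInterval(chrom, start, start + length))
            if allow_overlap or len(merge_intervals(placed)) == len(placed):
                replicates.append(placed)
                break
        else:
            raise RuntimeError("could not place non-overlapping regions")
    return replicates


def empirical_p(observed: float, null_values, side: str = "depletion") -> NullDistribution:
    """P = (M + 1)/(N + 1) with M = #{null < observed} (depletion side)."""
    if side != "depletion":
        raise ValueError("only the depletion side is defined")
    null = np.asarray(null_values, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    m = int((null < observed).sum())
    return NullDistribution(
        observed=float(observed),
        null_values=null,
        M=m,
        empirical_p=(m + 1) / (null.size + 1),
    )


def depletion_test(
    regions,
    peaks,
    genome: Genome,
    n: int = DEFAULT_N_PERMUTATIONS,
    seed=0,
    **permute_kwargs,
) -> NullDistribution:
    """Observed peak-coverage fraction of ``regions`` vs. a permutation null."""
    regions = merge_intervals(regions)
    peaks = merge_intervals(peaks)
    observed = fraction_covered(regions, peaks)
    nulls = np.array(
        [
            fraction_covered(rep, peaks)
            for rep in permute_regions(regions, genome, n, seed, **permute_kwargs)
        ]
    )
    return empirical_p(observed, nulls)


def filter_hsd(
    sd_table: pd.DataFrame,
    threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    identity_column: str = "fracMatch",
) -> list[GenomicInterval]:
    """Retain SD rows with fractional identity strictly above ``threshold``
    and return their merged intervals (UCSC genomicSuperDups dialect)."""
    for col in ("chrom", "chromStart", "chromEnd", identity_column):
        if col not in sd_table.columns:
            raise ValueError(f"missing column {col!r} in SD table")
    ident = sd_table[identity_column].astype(float)
    if ((ident < 0) | (ident > 1)).any():
        raise ValueError("fractional identity must lie in [0, 1]")
    kept = sd_table.loc[ident > threshold]
    intervals = [
        GenomicInterval(str(r.chrom), int(r.chromStart), int(r.chromEnd))
        for r in kept.itertuples()
    ]
    return merge_intervals(intervals)
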