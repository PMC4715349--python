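"""Random non-SV region generation and interval-set comparison.

Random regions are the training class for one-class classification: random
genomic coordinates are unlikely to sit near a true SV breakpoint, so their
annotation vectors define "normal".  Two samplers are provided — one with
log-uniform sizes over a configurable range, one matching an observed size
distribution — plus repeat-element subsampling, overlap deduplication and
reciprocal-overlap matching between call sets.

All samplers are pure functions of (inputs, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from intervaltree import IntervalTree

from .core import GenomicInterval, SVCall, SVType, interval_overlap
from .io import RepeatTrack

__all__ = [
    "GenomeLayout",
    "sample_random_regions_loguniform",
    "sample_random_regions_matched",
    "sample_repeat_elements",
    "deduplicate_calls",
    "reciprocal_overlap_match",
]

#: Size range of the published 4000-region training set (bp).
DEFAULT_SIZE_RANGE = (50, 997527)

_MAX_ATTEMPTS = 1000  # rejection-sampling cap per region


@dataclass
class GenomeLayout:
    """Sampling frame: ordered (chrom, length) pairs and optional exclusions."""

    chroms: Sequence[tuple[str, int]]
    excluded: Sequence[GenomicInterval] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.chroms:
            raise ValueError("empty genome layout")
        for name, length in self.chroms:
            if length <= 0:
                raise ValueError(f"non-positive length for {name}")
        self._lengths = np.array([l for _, l in self.chroms], dtype=float)
        self._excl: dict[str, IntervalTree] = {}
        for iv in self.excluded:
            self._excl.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)

    @property
    def total_length(self) -> int:
        return int(self._lengths.sum())

    def is_allowed(self, iv: GenomicInterval) -> bool:
        tree = self._excl.get(iv.chrom)
        return tree is None or not tree.overlap(iv.start, iv.end)


def _place_region(layout: GenomeLayout, size: int, rng: np.random.Generator) -> GenomicInterval:
    """Uniform placement on chromosomes weighted by length; rejection on
    contig fit and exclusion overlap."""
    probs = layout._lengths / layout._lengths.sum()
    for _ in range(_MAX_ATTEMPTS):
        ci = rng.choice(len(layout.chroms), p=probs)
        chrom, length = layout.chroms[ci]
        if size > length:
            continue
        start = int(rng.integers(0, length - size + 1))
        iv = GenomicInterval(chrom, start, start + size)
        if layout.is_allowed(iv):
            return iv
    raise RuntimeError(
        f"could not place a region of {size} bp after {_MAX_ATTEMPTS} attempts "
        "(contigs too short or exclusions too dense)"
    )


def sample_random_regions_loguniform(
    layout: GenomeLayout,
    n: int,
    min_size: int = DEFAULT_SIZE_RANGE[0],
    max_size: int = DEFAULT_SIZE_RANGE[1],
    seed: int | np.random.Generator = 0,
    source: str = "random",
) -> list[SVCall]:
    """Sample ``n`` random regions with log-uniform sizes in [min, max]."""
    if min_size < 1 or max_size <= min_size:
        raise ValueError("require 1 <= min_size < max_size")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    log_sizes = rng.uniform(np.log(min_size), np.log(max_size), size=n)
    sizes = np.clip(np.rint(np.exp(log_sizes)).astype(int), min_size, max_size)
    return [
        SVCall(_place_region(layout, int(s), rng), SVType.RANDOM, source=source)
        for s in sizes
    ]


def sample_random_regions_matched(
    layout: GenomeLayout,
    template_sizes: Sequence[int],
    seed: int | np.random.Generator = 0,
    source: str = "random_matched",
) -> list[SVCall]:
    """One random region per template size (exact size copy, random placement)."""
    if len(template_sizes) == 0:
        raise ValueError("empty size template")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return [
        SVCall(_place_region(layout, int(s), rng), SVType.RANDOM, source=source)
        for s in template_sizes
    ]


def sample_repeat_elements(
    track: RepeatTrack,
    repeat_class: str,
    n: int,
    seed: int | np.random.Generator = 0,
) -> list[SVCall]:
    """Uniform sample without replacement of ``n`` elements of one class."""
    elements = track.elements(repeat_class)
    if n > len(elements):
        raise ValueError(
            f"requested {n} {repeat_class} elements but track has {len(elements)}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(len(elements), size=n, replace=False) if n else []
    return [
        SVCall(elements[i][0], SVType.REPEAT_ELEMENT, source=repeat_class)
        for i in sorted(int(i) for i in idx)
    ]


def deduplicate_calls(
    sets: Sequence[Sequence[SVCall]], min_overlap: int = 1
) -> list[SVCall]:
    """Merge call sets (ordered by priority) into a non-overlapping list.

    Within a set, any call overlapping another call of the same set by at
    least ``min_overlap`` bp is discarded (both members — overlapping calls
    may be compound-heterozygous or imprecise).  Across sets, a
    lower-priority call overlapping any retained higher-priority call is
    dropped.
    """
    if not sets:
        raise ValueError("need at least one call set")
    retained: list[SVCall] = []
    kept_trees: dict[str, IntervalTree] = {}
    for call_set in sets:
        survivors = []
        for i, a in enumerate(call_set):
            clash = False
            for j, b in enumerate(call_set):
                if i != j and interval_overlap(a.interval, b.interval) >= min_overlap:
                    clash = True
                    break
            if not clash:
                survivors.append(a)
        for call in survivors:
            tree = kept_trees.get(call.interval.chrom)
            if tree is not None:
                hit = any(
                    min(call.interval.end, iv.end) - max(call.interval.start, iv.begin)
                    >= min_overlap
                    for iv in tree.overlap(call.interval.start, call.interval.end)
                )
                if hit:
                    continue
            retained.append(call)
            kept_trees.setdefault(call.interval.chrom, IntervalTree()).addi(
                call.interval.start, call.interval.end
            )
    return retained


def reciprocal_overlap_match(
    query: SVCall, targets: Sequence[SVCall], fraction: float
) -> SVCall | None:
    """Best reciprocal-overlap match of ``query`` among ``targets``.

    A target matches iff the overlap covers at least ``fraction`` of BOTH
    intervals (inclusive boundary).  Among multiple matches the one with
    the largest overlap wins; ties break to the smallest target start.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    best: SVCall | None = None
    best_key: tuple[float, int] | None = None
    for t in targets:
        ov = interval_overlap(query.interval, t.interval)
        if ov >= fraction * query.interval.length and ov >= fraction * t.interval.length:
            key = (-ov, t.interval.start)
            if best_key is None or key < best_key:
                best, best_key = t, key
    return best
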