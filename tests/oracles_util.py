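"""Naive brute-force recomputations of every annotation, used as oracles.

Deliberately written with different primitives than the implementation:
full-BAM scans instead of indexed fetches, per-base reference-position
sets instead of aligned-block arithmetic, and plain Python loops.
"""

from __future__ import annotations

import numpy as np
import pysam

from svarbiter.core import GenomicInterval


def scan_reads(bam_path: str, region: GenomicInterval) -> list:
    """All primary, QC-pass, non-duplicate reads overlapping the region,
    found by scanning every record in the file."""
    out = []
    with pysam.AlignmentFile(bam_path) as bam:
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.is_duplicate or read.is_qcfail:
                continue
            if read.reference_name != region.chrom:
                continue
            if read.reference_start < region.end and read.reference_end > region.start:
                out.append(read)
    return out


def naive_depth(reads, region: GenomicInterval) -> float:
    counts = np.zeros(region.length)
    for read in reads:
        for pos in read.get_reference_positions():
            if region.start <= pos < region.end:
                counts[pos - region.start] += 1
    return float(counts.mean())


def naive_clip_fraction(reads, min_clip: int = 5):
    if not reads:
        return None
    n = 0
    for read in reads:
        cigar = read.cigarstring or ""
        lengths = []
        ct = read.cigartuples or []
        if ct and ct[0][0] in (4, 5):
            lengths.append(ct[0][1])
        if len(ct) > 1 and ct[-1][0] in (4, 5):
            lengths.append(ct[-1][1])
        if any(l >= min_clip for l in lengths):
            n += 1
    return n / len(reads)


def naive_mapq(reads):
    if not reads:
        return None
    return sum(r.mapping_quality for r in reads) / len(reads)


def naive_insert_stats(reads):
    vals = []
    for r in reads:
        if (
            r.is_paired
            and not r.mate_is_unmapped
            and r.reference_id == r.next_reference_id
            and r.is_reverse != r.mate_is_reverse
            and r.template_length > 0
        ):
            vals.append(abs(r.template_length))
    if not vals:
        return None, None
    mean = sum(vals) / len(vals)
    if len(vals) < 2:
        return mean, None
    var = sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)
    return mean, var**0.5


def naive_discordance(reads, cutoff: float):
    paired = [r for r in reads if r.is_paired]
    if not paired:
        return None, None
    mu = sum(1 for r in paired if r.mate_is_unmapped) / len(paired)
    mapped = [r for r in paired if not r.mate_is_unmapped]
    if not mapped:
        return None, mu
    disc = sum(
        1
        for r in mapped
        if r.reference_id != r.next_reference_id
        or r.is_reverse == r.mate_is_reverse
        or abs(r.template_length) > cutoff
    )
    return disc / len(mapped), mu


def naive_longread_rates(reads, baseline):
    dels, inss = [], []
    for r in reads:
        q = r.query_length or 0
        if q <= 0:
            continue
        d = sum(l for op, l in (r.cigartuples or []) if op == 2)
        i = sum(l for op, l in (r.cigartuples or []) if op == 1)
        dels.append(d / q)
        inss.append(i / q)
    if not dels:
        return None, None, None
    nd = sum(dels) / len(dels) - baseline[0]
    ni = sum(inss) / len(inss) - baseline[1]
    return nd, ni, nd - ni


def naive_gc(sequence: str):
    seq = sequence.upper()
    denom = sum(seq.count(b) for b in "ACGT")
    if denom == 0:
        return None
    return (seq.count("G") + seq.count("C")) / denom


def naive_repeat_fraction(records, region: GenomicInterval) -> dict[str, float]:
    """Per-class covered fraction via a per-base boolean array (linear scan)."""
    out = {}
    for iv, cls in records:
        if iv.chrom != region.chrom:
            continue
        covered = out.setdefault(cls, np.zeros(region.length, dtype=bool))
        s = max(iv.start, region.start)
        e = min(iv.end, region.end)
        if e > s:
            covered[s - region.start : e - region.start] = True
    return {cls: float(arr.mean()) for cls, arr in out.items()}
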