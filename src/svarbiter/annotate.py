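"""Per-site, per-dataset read-evidence and reference-context annotations.

For every candidate site the neighbourhood is split into the five windows
L/LM/M/RM/R and, per window, summaries of the overlapping reads are
computed: mean depth, read count, soft/hard-clipped fraction, mean mapping
quality, and — technology permitting — insert-size mean/sd, discordant and
mate-unmapped proportions (paired short reads) or per-base deletion and
insertion rates (long single-end reads, normalised against a random-region
baseline).  Reference-context columns (GC, repeat coverage by class, SNP
genotype counts, SV length) are computed over M only.

Counting conventions: a read belongs to a window when its aligned span
overlaps it by at least 1 bp (partially mapped reads included; one read
may count in several windows); secondary/supplementary alignments,
duplicates and QC-fail reads are excluded; MAPQ-0 reads stay in all
denominators since low mapping quality is itself a signal downstream.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

from .core import (
    AnnotationTable,
    DatasetSpec,
    GenomicInterval,
    RegionPartition,
    SVCall,
    Technology,
    partition_site,
)
from .io import RepeatTrack, SnpGenotypeSet

__all__ = [
    "collect_reads",
    "region_depth",
    "insert_size_stats",
    "clipping_fraction",
    "discordance_fractions",
    "longread_indel_rates",
    "reference_context",
    "estimate_insert_cutoff",
    "compute_longread_baseline",
    "annotate_sites",
    "oneclass_columns",
    "clustering_columns",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_CLIP = 5  # bases of soft/hard clip required to count a read as clipped

REFERENCE_COLUMNS = (
    "GC_Content",
    "Repeat_SINE",
    "Repeat_LINE",
    "Repeat_LTR",
    "Repeat_LowComplexity",
    "Repeat_SimpleRepeat",
    "Repeat_Other",
    "Het_SNPs",
    "Hom_SNPs",
    "SV_Length",
)

_REPEAT_COLUMN = {
    "SINE": "Repeat_SINE",
    "LINE": "Repeat_LINE",
    "LTR": "Repeat_LTR",
    "low_complexity": "Repeat_LowComplexity",
    "simple_repeat": "Repeat_SimpleRepeat",
    "other": "Repeat_Other",
}


def _region_metrics(technology: Technology) -> list[str]:
    base = ["Cov", "ReadCount", "SoftClip", "MapQ"]
    if technology is Technology.PAIRED_SHORT:
        base += ["InsertMean", "InsertSD", "Discordant", "MateUnmapped"]
    else:
        base += ["Del", "Ins", "DelMinusIns"]
    return base


def full_columns(technology: Technology) -> list[str]:
    cols = [
        f"{r}_{m}"
        for r in ("L", "LM", "M", "RM", "R")
        for m in _region_metrics(technology)
    ]
    return cols + list(REFERENCE_COLUMNS)


def oneclass_columns(technology: Technology) -> list[str]:
    """Technology-appropriate evidence-only columns for one-class models.

    Reference-only annotations (GC, repeats, SNPs, SV length) and mapping
    quality are excluded: atypical values there can mark hard-to-sequence
    regions rather than SVs, and they are not technology-specific evidence.
    """
    if technology is Technology.PAIRED_SHORT:
        return [
            "LM_Cov", "M_Cov", "RM_Cov",
            "L_SoftClip", "R_SoftClip",
            "L_InsertMean", "R_InsertMean",
            "L_InsertSD", "R_InsertSD",
            "L_Discordant", "R_Discordant",
            "L_MateUnmapped", "R_MateUnmapped",
        ]
    return ["LM_Cov", "M_Cov", "RM_Cov", "L_SoftClip", "R_SoftClip", "M_DelMinusIns"]


def clustering_columns(technology: Technology) -> list[str]:
    """One-class evidence plus flank depth, mapping quality, size and
    reference context — helpful for separating SV types even where they do
    not separate SVs from non-SVs."""
    extra = ["L_Cov", "R_Cov", "L_MapQ", "M_MapQ", "R_MapQ"]
    return oneclass_columns(technology) + extra + list(REFERENCE_COLUMNS)


# ---------------------------------------------------------------------------
# per-region primitives
# ---------------------------------------------------------------------------

def collect_reads(bam: pysam.AlignmentFile, region: GenomicInterval) -> list:
    """Primary, non-duplicate reads whose aligned span overlaps the region.

    Partially overlapping reads are included; half-open semantics mean a
    read abutting the region end is not.
    """
    if region.is_empty():
        return []
    if not bam.has_index():
        raise ValueError(f"{bam.filename!r} has no index")
    out = []
    for read in bam.fetch(region.chrom, region.start, region.end):
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        if read.is_duplicate or read.is_qcfail:
            continue
        out.append(read)
    return out


def region_depth(reads: Iterable, region: GenomicInterval) -> float:
    """Mean per-base aligned coverage over the region.

    Sums, over reads, the aligned (M/=/X) bases falling inside the region
    and divides by the region length; deletion/skip CIGAR segments
    contribute nothing.
    """
    if region.is_empty():
        raise ValueError("depth of an empty region is undefined")
    total = 0
    for read in reads:
        for bstart, bend in read.get_blocks():
            total += max(0, min(bend, region.end) - max(bstart, region.start))
    return total / region.length


def clipping_fraction(reads: Sequence, min_clip: int = DEFAULT_MIN_CLIP) -> float | None:
    """Fraction of reads with a soft or hard clip of >= min_clip bases on
    either end; None (masked) when there are no reads."""
    if not reads:
        return None
    clipped = 0
    for read in reads:
        ct = read.cigartuples
        if not ct:
            continue
        head = ct[0][1] if ct[0][0] in (4, 5) else 0
        tail = ct[-1][1] if ct[-1][0] in (4, 5) else 0
        if head >= min_clip or tail >= min_clip:
            clipped += 1
    return clipped / len(reads)


def mean_mapq(reads: Sequence) -> float | None:
    if not reads:
        return None
    return float(np.mean([r.mapping_quality for r in reads]))


def insert_size_stats(reads: Sequence) -> tuple[float | None, float | None]:
    """(mean, sd) of the end-to-end insert over proper pairs in the region.

    The insert is the end-to-end distance — both read lengths plus the gap
    separating them (negative gap for overlapping mates) — i.e. |TLEN|.
    Pairs must be primary, both mates mapped to the same chromosome in
    forward/reverse orientation; each pair is counted once at its leftmost
    mate.  The aligner's proper-pair flag is NOT required: pairs stretched
    across a deletion are precisely the insert-size signal.  With no
    usable pairs both values are masked; with one pair the sd is masked.
    """
    inserts = [
        abs(r.template_length)
        for r in reads
        if r.is_paired
        and not r.mate_is_unmapped
        and r.reference_id == r.next_reference_id
        and r.is_reverse != r.mate_is_reverse
        and r.template_length > 0
    ]
    if not inserts:
        return None, None
    mean = float(np.mean(inserts))
    sd = float(np.std(inserts, ddof=1)) if len(inserts) >= 2 else None
    return mean, sd


def discordance_fractions(
    reads: Sequence, insert_cutoff: float
) -> tuple[float | None, float | None]:
    """(discordant fraction, mate-unmapped fraction) among paired reads.

    Discordant = mate on a different chromosome, same-strand orientation,
    or |insert| beyond ``insert_cutoff``; assessed among reads whose mate
    is mapped.  The mate-unmapped fraction is over all paired reads.
    """
    paired = [r for r in reads if r.is_paired]
    if not paired:
        return None, None
    mate_unmapped = sum(1 for r in paired if r.mate_is_unmapped)
    mu_frac = mate_unmapped / len(paired)
    with_mate = [r for r in paired if not r.mate_is_unmapped]
    if not with_mate:
        return None, mu_frac
    disc = 0
    for r in with_mate:
        if r.reference_id != r.next_reference_id:
            disc += 1
        elif r.is_reverse == r.mate_is_reverse:
            disc += 1
        elif abs(r.template_length) > insert_cutoff:
            disc += 1
    return disc / len(with_mate), mu_frac


def longread_indel_rates(
    reads: Sequence, baseline: tuple[float, float]
) -> tuple[float | None, float | None, float | None]:
    """(norm_del, norm_ins, del-ins difference) for long single-end reads.

    Per read, deleted/inserted bases are summed from CIGAR D/I operations
    and divided by the read length; means over reads are normalised by
    subtracting the baseline rates measured on random regions.
    """
    dels, inss = [], []
    for read in reads:
        qlen = read.query_length or read.infer_query_length() or 0
        if qlen <= 0:
            continue
        d = i = 0
        for op, length in read.cigartuples or []:
            if op == 2:
                d += length
            elif op == 1:
                i += length
        dels.append(d / qlen)
        inss.append(i / qlen)
    if not dels:
        return None, None, None
    norm_del = float(np.mean(dels)) - baseline[0]
    norm_ins = float(np.mean(inss)) - baseline[1]
    return norm_del, norm_ins, norm_del - norm_ins


def reference_context(
    sv: SVCall,
    fasta: Fasta,
    repeats: RepeatTrack | None,
    snps: SnpGenotypeSet | None,
) -> dict[str, float | None]:
    """GC, repeat coverage by class, SNP genotype counts and length over M."""
    m = sv.interval
    seq = str(fasta[m.chrom][m.start : m.end]).upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    gc = (seq.count("G") + seq.count("C")) / acgt if acgt else None
    out: dict[str, float | None] = {"GC_Content": gc, "SV_Length": float(m.length)}
    fractions = (
        repeats.coverage_fraction(m)
        if repeats is not None
        else {cls: 0.0 for cls in _REPEAT_COLUMN}
    )
    for cls, col in _REPEAT_COLUMN.items():
        out[col] = fractions.get(cls, 0.0)
    het, hom = snps.count_in(m) if snps is not None else (0, 0)
    out["Het_SNPs"] = float(het)
    out["Hom_SNPs"] = float(hom)
    return out


# ---------------------------------------------------------------------------
# dataset-level calibration
# ---------------------------------------------------------------------------

def estimate_insert_cutoff(
    bam: pysam.AlignmentFile, n_pairs: int = 1000, n_sd: float = 4.0
) -> float:
    """Discordance insert cutoff = mean + n_sd * sd of |insert| over up to
    ``n_pairs`` proper pairs sampled from the start of the BAM."""
    inserts = []
    for read in bam.fetch():
        if read.is_proper_pair and read.template_length > 0 and not read.is_secondary:
            inserts.append(read.template_length)
            if len(inserts) >= n_pairs:
                break
    if len(inserts) < 2:
        raise ValueError("too few proper pairs to estimate an insert cutoff")
    arr = np.asarray(inserts, dtype=float)
    return float(arr.mean() + n_sd * arr.std(ddof=1))


def compute_longread_baseline(
    bam: pysam.AlignmentFile, regions: Sequence[SVCall]
) -> tuple[float, float]:
    """Mean per-base deletion and insertion rates over reads overlapping a
    set of random regions — the normalisation baseline for long reads."""
    dels, inss = [], []
    for call in regions:
        for read in collect_reads(bam, call.interval):
            qlen = read.query_length or 0
            if qlen <= 0:
                continue
            d = sum(l for op, l in read.cigartuples or [] if op == 2)
            i = sum(l for op, l in read.cigartuples or [] if op == 1)
            dels.append(d / qlen)
            inss.append(i / qlen)
    if not dels:
        raise ValueError("no usable long reads over the baseline regions")
    return float(np.mean(dels)), float(np.mean(inss))


# ---------------------------------------------------------------------------
# the annotation table builder
# ---------------------------------------------------------------------------

def _unique_site_ids(sites: Sequence[SVCall]) -> list[str]:
    seen: dict[str, int] = {}
    ids = []
    for sv in sites:
        sid = sv.site_id
        if sid in seen:
            seen[sid] += 1
            sid = f"{sid}#{seen[sv.site_id]}"
        else:
            seen[sid] = 1
        ids.append(sid)
    return ids


def annotate_sites(
    sites: Sequence[SVCall],
    dataset: DatasetSpec,
    fasta_path: str | None = None,
    repeats: RepeatTrack | None = None,
    snps: SnpGenotypeSet | None = None,
    flank_size: int = 100,
    subset: str = "full",
    min_clip: int = DEFAULT_MIN_CLIP,
) -> AnnotationTable:
    """Annotation table (sites x columns) for one dataset.

    ``subset``: ``full`` (all window metrics plus reference context),
    ``clustering`` or ``oneclass`` (see the column helpers).  A site whose
    window partition fails (e.g. falls off its contig) gets a fully masked
    row and a ``partition_failed`` flag.  The reference context requires
    ``fasta_path``; when omitted those columns are masked.
    """
    if subset not in ("full", "clustering", "oneclass"):
        raise ValueError(f"unknown subset {subset!r}")
    tech = dataset.technology
    columns = {
        "full": full_columns,
        "clustering": clustering_columns,
        "oneclass": oneclass_columns,
    }[subset](tech)
    want = set(columns)
    need_reference = any(c in want for c in REFERENCE_COLUMNS)

    fasta = Fasta(fasta_path) if (fasta_path and need_reference) else None
    rows: list[dict[str, float | None]] = []
    flags: dict[str, tuple[str, ...]] = {}
    site_ids = _unique_site_ids(sites)

    with pysam.AlignmentFile(dataset.bam_path) as bam:
        contig_len = {name: length for name, length in zip(bam.references, bam.lengths)}
        cutoff = dataset.discordant_insert_cutoff
        if tech is Technology.PAIRED_SHORT and cutoff is None:
            cutoff = estimate_insert_cutoff(bam)
            dataset.discordant_insert_cutoff = cutoff
        for sid, sv in zip(site_ids, sites):
            row: dict[str, float | None] = {c: None for c in columns}
            chrom = sv.interval.chrom
            if chrom not in contig_len:
                flags[sid] = ("partition_failed", f"unknown contig {chrom}")
                rows.append(row)
                continue
            try:
                part = partition_site(sv, flank_size, contig_len[chrom])
            except ValueError as exc:
                flags[sid] = ("partition_failed", str(exc))
                rows.append(row)
                continue
            site_flags = []
            if part.truncated_left or part.truncated_right:
                site_flags.append("truncated")
            for rname, region in part.items():
                prefix = f"{rname}_"
                if not any(c.startswith(prefix) for c in want):
                    continue
                if region.is_empty():
                    continue  # metrics stay masked
                reads = collect_reads(bam, region)
                _maybe(row, want, f"{rname}_Cov", region_depth(reads, region))
                _maybe(row, want, f"{rname}_ReadCount", float(len(reads)))
                _maybe(row, want, f"{rname}_SoftClip", clipping_fraction(reads, min_clip))
                _maybe(row, want, f"{rname}_MapQ", mean_mapq(reads))
                if tech is Technology.PAIRED_SHORT:
                    imean, isd = insert_size_stats(reads)
                    disc, mu = discordance_fractions(reads, cutoff)
                    _maybe(row, want, f"{rname}_InsertMean", imean)
                    _maybe(row, want, f"{rname}_InsertSD", isd)
                    _maybe(row, want, f"{rname}_Discordant", disc)
                    _maybe(row, want, f"{rname}_MateUnmapped", mu)
                else:
                    nd, ni, diff = longread_indel_rates(
                        reads, dataset.long_read_indel_baseline
                    )
                    _maybe(row, want, f"{rname}_Del", nd)
                    _maybe(row, want, f"{rname}_Ins", ni)
                    _maybe(row, want, f"{rname}_DelMinusIns", diff)
            if need_reference and fasta is not None:
                row.update(
                    {
                        k: v
                        for k, v in reference_context(sv, fasta, repeats, snps).items()
                        if k in want
                    }
                )
            if site_flags:
                flags[sid] = tuple(site_flags)
            rows.append(row)

    df = pd.DataFrame(rows, index=site_ids, columns=columns, dtype=float)
    return AnnotationTable(df, None, flags)


def _maybe(row: dict, want: set, key: str, value) -> None:
    if key in want and value is not None:
        row[key] = float(value)
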