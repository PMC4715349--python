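"""Synthetic genomes, SV truth sets and aligned reads for hermetic testing.

The simulator builds a random reference contig, plants non-overlapping
deletions and replacement insertions on a diploid donor (hom = both
haplotypes, het = one), and samples reads from the donor haplotypes.
Alignments are computed analytically by lifting donor coordinates back to
the reference — no aligner runs — so every BAM record's position, flags
and CIGAR are exact consequences of the planted variants:

* short paired reads crossing a planted deletion are soft-clipped at the
  breakpoint (the policy for large reference gaps), and pairs straddling
  it acquire inserts stretched by the deletion length;
* long single-end reads span planted deletions as CIGAR ``D`` operations
  and carry per-base insertion/deletion sequencing errors at configurable
  rates, so the long-read indel-rate normalisation is exercised;
* reads falling inside planted insertion sequence lose their anchor and
  are emitted unmapped (with a mapped mate where applicable), feeding the
  mate-unmapped annotation.

``make_fixture_suite`` emits a complete input bundle — FASTA, BAMs for two
paired and one long dataset, truth BED, RepeatMasker-style track, SNP VCF
— deterministic in its seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pysam
from pyfaidx import Faidx

from .core import (
    DatasetSpec,
    GenomicInterval,
    SVCall,
    SVType,
    Technology,
    Zygosity,
)
from .regions import GenomeLayout, sample_random_regions_loguniform

__all__ = [
    "PairedReadModel",
    "LongReadModel",
    "SimulationConfig",
    "SimulatedGenome",
    "simulate_genome",
    "simulate_reads",
    "make_fixture_suite",
    "FixtureSuite",
]

_BASES = np.array(list("ACGT"))
MIN_ANCHOR = 20  # aligned bases required to place a read at all


@dataclass(frozen=True)
class PairedReadModel:
    """Illumina-like paired-end model (both mates the same length)."""

    name: str = "paired"
    read_length: int = 100
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    depth: float = 30.0
    mapq: int = 60
    max_del_op: int = 50  # reference gaps above this are soft-clipped
    # background artefact rates so noise annotations are non-degenerate
    clip_noise_rate: float = 0.01      # reads with a spurious 5-20 bp clip
    discordant_noise_rate: float = 0.005  # pairs with same-strand orientation
    mate_unmapped_noise_rate: float = 0.003
    # smooth coverage bias along the genome (GC/mappability-like waves):
    # local depth multiplier 1 + A*sin(2*pi*x/wavelength + phase)
    coverage_bias_amplitude: float = 0.25
    coverage_bias_wavelength: float = 20_000.0

    @property
    def technology(self) -> Technology:
        return Technology.PAIRED_SHORT


@dataclass(frozen=True)
class LongReadModel:
    """PacBio-like long single-end model with per-base indel errors."""

    name: str = "long"
    read_min: int = 1000
    read_max: int = 8000
    depth: float = 12.0
    del_rate: float = 0.0428
    ins_rate: float = 0.0948
    mean_indel_size: float = 3.0
    mapq: int = 60
    max_del_op: int = 5000  # long reads span planted deletions as D ops
    clip_noise_rate: float = 0.02
    coverage_bias_amplitude: float = 0.25
    coverage_bias_wavelength: float = 20_000.0

    @property
    def technology(self) -> Technology:
        return Technology.UNPAIRED_LONG


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic genome."""

    chrom: str = "chr1"
    genome_length: int = 300_000
    gc: float = 0.41
    n_hom_del: int = 10
    n_het_del: int = 10
    n_insertion: int = 4
    del_size: tuple[int, int] = (300, 2000)
    ins_replaced_span: tuple[int, int] = (50, 150)
    ins_alt_size: tuple[int, int] = (150, 800)
    min_separation: int = 400   # >= 2 x flank keeps evaluation windows disjoint
    edge_margin: int = 2000
    datasets: tuple = (PairedReadModel(),)
    seed: int = 0


@dataclass
class _Haplotype:
    """Donor haplotype: spliced sequence plus donor->reference segment map."""

    seq: str
    # (donor_start, donor_end, ref_start or None); None = inserted sequence
    segments: list[tuple[int, int, int | None]]

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class SimulatedGenome:
    config: SimulationConfig
    reference: str
    truth: list[SVCall]
    haplotypes: tuple[_Haplotype, _Haplotype]

    @property
    def chrom(self) -> str:
        return self.config.chrom

    def layout(self, exclude_truth_pad: int | None = None) -> GenomeLayout:
        """Sampling frame for random regions.

        With ``exclude_truth_pad`` set, truth intervals padded by that many
        bases are excluded — on a real genome random coordinates rarely
        fall near an SV breakpoint, but a desk-scale contig is dense enough
        in planted SVs that unexcluded sampling would contaminate the
        "likely non-SV" training class.  A pad of the order of the longest
        read keeps read-carried SV evidence out of the training windows.
        """
        excluded: list[GenomicInterval] = []
        if exclude_truth_pad is not None:
            for sv in self.truth:
                excluded.append(
                    GenomicInterval(
                        self.chrom,
                        max(0, sv.interval.start - exclude_truth_pad),
                        min(len(self.reference), sv.interval.end + exclude_truth_pad),
                    )
                )
        return GenomeLayout([(self.chrom, len(self.reference))], excluded)

    def write_fasta(self, path: str) -> str:
        with open(path, "w") as fh:
            fh.write(f">{self.chrom}\n")
            for i in range(0, len(self.reference), 80):
                fh.write(self.reference[i : i + 80] + "\n")
        Faidx(path)  # writes the .fai alongside
        return path

    def write_truth(self, path: str) -> str:
        with open(path, "w") as fh:
            fh.write("#chrom\tstart\tend\ttype\talt\tzygosity\n")
            for sv in self.truth:
                alt = sv.alt_sequence or "."
                zyg = sv.zygosity.value if sv.zygosity else "."
                fh.write(
                    f"{sv.interval.chrom}\t{sv.interval.start}\t{sv.interval.end}"
                    f"\t{sv.sv_type.value}\t{alt}\t{zyg}\n"
                )
        return path


def _random_seq(n: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _build_haplotype(reference: str, events: list[tuple[int, int, str]]) -> _Haplotype:
    """Splice events (ref_start, ref_end, alt) into the reference."""
    parts: list[str] = []
    segments: list[tuple[int, int, int | None]] = []
    donor_pos = 0
    ref_pos = 0
    for s, e, alt in sorted(events):
        if s > ref_pos:
            block = reference[ref_pos:s]
            segments.append((donor_pos, donor_pos + len(block), ref_pos))
            parts.append(block)
            donor_pos += len(block)
        if alt:
            segments.append((donor_pos, donor_pos + len(alt), None))
            parts.append(alt)
            donor_pos += len(alt)
        ref_pos = e
    tail = reference[ref_pos:]
    if tail:
        segments.append((donor_pos, donor_pos + len(tail), ref_pos))
        parts.append(tail)
    return _Haplotype("".join(parts), segments)


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Random reference plus a donor haplotype pair realising each planted SV."""
    rng = np.random.default_rng(config.seed)
    reference = _random_seq(config.genome_length, config.gc, rng)

    n_sv = config.n_hom_del + config.n_het_del + config.n_insertion
    spans: list[tuple[int, int]] = []
    truth: list[SVCall] = []
    events_h0: list[tuple[int, int, str]] = []
    events_h1: list[tuple[int, int, str]] = []

    kinds = (
        [("del", Zygosity.HOM)] * config.n_hom_del
        + [("del", Zygosity.HET)] * config.n_het_del
        + [("ins", None)] * config.n_insertion
    )
    rng.shuffle(kinds)
    lo = config.edge_margin
    hi = config.genome_length - config.edge_margin
    for kind, zyg in kinds:
        if kind == "del":
            size = int(rng.integers(config.del_size[0], config.del_size[1] + 1))
            alt = ""
        else:
            size = int(
                rng.integers(config.ins_replaced_span[0], config.ins_replaced_span[1] + 1)
            )
            alt = _random_seq(
                int(rng.integers(config.ins_alt_size[0], config.ins_alt_size[1] + 1)),
                config.gc,
                rng,
            )
        placed = False
        for _ in range(2000):
            start = int(rng.integers(lo, hi - size))
            end = start + size
            if all(
                end + config.min_separation <= s or start >= e + config.min_separation
                for s, e in spans
            ):
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"genome of {config.genome_length} bp too crowded for {n_sv} SVs"
            )
        spans.append((start, end))
        iv = GenomicInterval(config.chrom, start, end)
        if kind == "del":
            truth.append(SVCall(iv, SVType.DELETION, None, "truth", zyg))
            events_h0.append((start, end, ""))
            if zyg is Zygosity.HOM:
                events_h1.append((start, end, ""))
            elif bool(rng.integers(0, 2)):
                # het: move the event to the other haplotype half the time
                events_h1.append(events_h0.pop())
        else:
            zyg_ins = Zygosity.HOM if bool(rng.integers(0, 2)) else Zygosity.HET
            truth.append(SVCall(iv, SVType.INSERTION, alt, "truth", zyg_ins))
            events_h0.append((start, end, alt))
            if zyg_ins is Zygosity.HOM:
                events_h1.append((start, end, alt))
            elif bool(rng.integers(0, 2)):
                events_h1.append(events_h0.pop())

    hap0 = _build_haplotype(reference, events_h0)
    hap1 = _build_haplotype(reference, events_h1)
    truth.sort(key=lambda sv: sv.interval.start)
    return SimulatedGenome(config, reference, truth, (hap0, hap1))


# ---------------------------------------------------------------------------
# donor -> reference alignment
# ---------------------------------------------------------------------------

def _donor_ops_with_errors(
    length: int, model: LongReadModel, rng: np.random.Generator
) -> list[tuple[str, int]]:
    """Donor-space CIGAR of a long read: M consumes donor+query, I query
    only (sequencing insertion), D donor only (sequencing deletion).
    Event starts are Bernoulli per base; sizes geometric."""
    p_del = model.del_rate / model.mean_indel_size
    p_ins = model.ins_rate / model.mean_indel_size
    p_event = p_del + p_ins
    mean_size = model.mean_indel_size
    ops: list[tuple[str, int]] = []
    q = 0
    while q < length:
        gap = int(rng.geometric(p_event)) - 1  # match bases before next event
        gap = min(gap, length - q)
        if gap:
            ops.append(("M", gap))
            q += gap
        if q >= length:
            break
        if rng.random() < p_del / p_event:
            ops.append(("D", max(1, int(rng.geometric(1.0 / mean_size)))))
        else:
            size = min(max(1, int(rng.geometric(1.0 / mean_size))), length - q)
            ops.append(("I", size))
            q += size
    return _merge_ops(ops)


def _merge_ops(ops: list[tuple[str, int]]) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for op, ln in ops:
        if ln <= 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + ln)
        else:
            out.append((op, ln))
    return out


def _lift_ops(
    hap: _Haplotype, donor_start: int, donor_ops: Sequence[tuple[str, int]]
) -> list[tuple[str, int, int | None]]:
    """Compose donor-space ops with the donor->reference map.

    Returns reference-space ops: ('M', qlen, ref_start), ('I', qlen, None)
    for unaligned query (sequencing insertions and planted insertion
    sequence), ('D', reflen, None) for reference gaps (sequencing and
    planted deletions).
    """
    segs = hap.segments
    # locate starting segment
    si = 0
    while si < len(segs) and segs[si][1] <= donor_start:
        si += 1
    dpos = donor_start
    out: list[tuple[str, int, int | None]] = []
    last_ref_end: int | None = None

    def emit_ref_gap(ref_start: int) -> None:
        nonlocal last_ref_end
        if last_ref_end is not None and ref_start > last_ref_end:
            out.append(("D", ref_start - last_ref_end, None))

    for op, ln in donor_ops:
        if op == "I":
            out.append(("I", ln, None))
            continue
        remaining = ln
        while remaining > 0:
            ds, de, rs = segs[si]
            take = min(remaining, de - dpos)
            if rs is None:
                if op == "M":  # match over inserted donor sequence: unaligned query
                    out.append(("I", take, None))
                # donor-space deletion over inserted sequence: nothing to emit
            else:
                ref_start = rs + (dpos - ds)
                if op == "M":
                    emit_ref_gap(ref_start)
                    out.append(("M", take, ref_start))
                    last_ref_end = ref_start + take
                else:  # donor-space deletion: reference advances, no query
                    emit_ref_gap(ref_start)
                    out.append(("D", take, None))
                    last_ref_end = ref_start + take
            dpos += take
            remaining -= take
            if dpos >= de:
                si += 1
                if si >= len(segs) and remaining > 0:
                    remaining = 0  # read ran off the donor end; truncate
    return _merge_lifted(out)


def _merge_lifted(ops):
    out = []
    for item in ops:
        if item[1] <= 0:
            continue
        if out and out[-1][0] == item[0] == "M":
            prev = out[-1]
            if prev[2] + prev[1] == item[2]:
                out[-1] = ("M", prev[1] + item[1], prev[2])
                continue
        if out and out[-1][0] == item[0] and item[0] in ("I", "D"):
            out[-1] = (item[0], out[-1][1] + item[1], None)
            continue
        out.append(item)
    return out


def _choose_alignment(
    lifted: Sequence[tuple[str, int, int | None]],
    max_del_op: int,
    max_ins_op: int = 50,
):
    """Pick the best contiguous run of ops and soft-clip the rest.

    Runs break at reference gaps larger than ``max_del_op`` and unaligned
    stretches larger than ``max_ins_op`` (an aligner would not bridge
    those).  The run with the most aligned bases wins; it is trimmed to
    start and end on M.  Returns (cigartuples, ref_start, qstart, qlen_total)
    or None when no run has a usable anchor.
    """
    # query offset of each op
    qoff = []
    q = 0
    for op, ln, _ in lifted:
        qoff.append(q)
        if op in ("M", "I"):
            q += ln
    total_q = q

    runs: list[list[int]] = [[]]
    for idx, (op, ln, _) in enumerate(lifted):
        if (op == "D" and ln > max_del_op) or (op == "I" and ln > max_ins_op):
            if runs[-1]:
                runs.append([])
            continue
        runs[-1].append(idx)
    runs = [r for r in runs if r]

    best: list[int] | None = None
    best_aligned = 0
    for run in runs:
        aligned = sum(lifted[i][1] for i in run if lifted[i][0] == "M")
        if aligned > best_aligned:
            best, best_aligned = run, aligned
    if best is None or best_aligned < MIN_ANCHOR:
        return None
    # trim to M at both ends
    while best and lifted[best[0]][0] != "M":
        best = best[1:]
    while best and lifted[best[-1]][0] != "M":
        best = best[:-1]
    if not best:
        return None
    qstart = qoff[best[0]]
    qend = qoff[best[-1]] + lifted[best[-1]][1]  # last op is M (consumes query)
    ref_start = lifted[best[0]][2]

    cig: list[tuple[int, int]] = []
    if qstart > 0:
        cig.append((4, qstart))
    opcode = {"M": 0, "I": 1, "D": 2}
    for i in best:
        op, ln, _ = lifted[i]
        cig.append((opcode[op], ln))
    if total_q - qend > 0:
        cig.append((4, total_q - qend))
    return cig, ref_start, qstart, total_q


def _clip_noise(aln, rng: np.random.Generator):
    """Convert 5-20 aligned bases at one read end into a spurious soft clip."""
    cig, ref_start, qstart, total_q = aln
    k = int(rng.integers(5, 21))
    cig = list(cig)
    if rng.random() < 0.5:
        i, lead = (1, cig[0][1]) if cig[0][0] == 4 else (0, 0)
        if i < len(cig) and cig[i][0] == 0 and cig[i][1] > k + MIN_ANCHOR:
            return (
                [(4, lead + k), (0, cig[i][1] - k)] + cig[i + 1 :],
                ref_start + k,
                qstart + k,
                total_q,
            )
    else:
        j = len(cig) - 1
        tail = 0
        if cig[j][0] == 4:
            tail = cig[j][1]
            j -= 1
        if j >= 0 and cig[j][0] == 0 and cig[j][1] > k + MIN_ANCHOR:
            return (
                cig[:j] + [(0, cig[j][1] - k), (4, tail + k)],
                ref_start,
                qstart,
                total_q,
            )
    return aln


# ---------------------------------------------------------------------------
# read generation
# ---------------------------------------------------------------------------

def _make_segment(
    name: str,
    seq: str,
    chrom_id: int,
    aln,
    mapq: int,
    header: pysam.AlignmentHeader,
) -> pysam.AlignedSegment:
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.query_sequence = seq
    a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
    if aln is None:
        a.is_unmapped = True
        a.reference_id = -1
        a.reference_start = -1
        a.mapping_quality = 0
    else:
        cig, ref_start, _, _ = aln
        a.reference_id = chrom_id
        a.reference_start = ref_start
        a.cigartuples = cig
        a.mapping_quality = mapq
    return a


def _pair_up(
    r1: pysam.AlignedSegment,
    r2: pysam.AlignedSegment,
    model: PairedReadModel,
    same_strand: bool = False,
):
    r1.is_paired = r2.is_paired = True
    r1.is_read1, r2.is_read2 = True, True
    r1.is_reverse, r2.is_reverse = False, not same_strand
    for a, b in ((r1, r2), (r2, r1)):
        a.mate_is_reverse = b.is_reverse
        a.mate_is_unmapped = b.is_unmapped
        if b.is_unmapped:
            a.next_reference_id = a.reference_id
            a.next_reference_start = a.reference_start
        else:
            a.next_reference_id = b.reference_id
            a.next_reference_start = b.reference_start
    if r1.is_unmapped and not r2.is_unmapped:
        r1.reference_id, r1.reference_start = r2.reference_id, r2.reference_start
    if r2.is_unmapped and not r1.is_unmapped:
        r2.reference_id, r2.reference_start = r1.reference_id, r1.reference_start
    if not r1.is_unmapped and not r2.is_unmapped:
        left, right = (r1, r2) if r1.reference_start <= r2.reference_start else (r2, r1)
        span = right.reference_end - left.reference_start
        left.template_length = span
        right.template_length = -span
        cutoff = model.insert_mean + 4 * model.insert_sd
        proper = span <= cutoff and r1.is_reverse != r2.is_reverse
        r1.is_proper_pair = r2.is_proper_pair = proper


def simulate_reads(
    genome: SimulatedGenome,
    model: PairedReadModel | LongReadModel,
    seed: int,
    out_path: str,
) -> str:
    """Sample reads from the donor haplotypes and write a sorted, indexed BAM."""
    rng = np.random.default_rng(seed)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": genome.chrom, "LN": len(genome.reference)}],
        }
    )
    records: list[pysam.AlignedSegment] = []
    ref_len = len(genome.reference)

    bias_amp = model.coverage_bias_amplitude
    bias_wl = model.coverage_bias_wavelength
    bias_phase = rng.uniform(0, 2 * np.pi)

    def keep_at(donor_pos: int) -> bool:
        if bias_amp <= 0:
            return True
        m = 1 + bias_amp * np.sin(2 * np.pi * donor_pos / bias_wl + bias_phase)
        return rng.random() < m / (1 + bias_amp)

    if isinstance(model, PairedReadModel):
        rl = model.read_length
        n_frags = int(model.depth * ref_len / (2 * rl) * (1 + bias_amp))
        for i in range(n_frags):
            hap = genome.haplotypes[int(rng.integers(0, 2))]
            frag = int(round(rng.normal(model.insert_mean, model.insert_sd)))
            frag = max(rl, min(frag, hap.length))
            start = int(rng.integers(0, hap.length - frag + 1))
            if not keep_at(start):
                continue
            seq1 = hap.seq[start : start + rl]
            seq2 = hap.seq[start + frag - rl : start + frag]
            aln1 = _choose_alignment(
                _lift_ops(hap, start, [("M", rl)]), model.max_del_op
            )
            aln2 = _choose_alignment(
                _lift_ops(hap, start + frag - rl, [("M", rl)]), model.max_del_op
            )
            if aln1 is not None and rng.random() < model.clip_noise_rate:
                aln1 = _clip_noise(aln1, rng)
            if aln2 is not None and rng.random() < model.clip_noise_rate:
                aln2 = _clip_noise(aln2, rng)
            if aln2 is not None and rng.random() < model.mate_unmapped_noise_rate:
                aln2 = None
            if aln1 is None and aln2 is None:
                continue  # fragment entirely without anchor: pair lost
            r1 = _make_segment(f"{model.name}.{i}", seq1, 0, aln1, model.mapq, header)
            r2 = _make_segment(f"{model.name}.{i}", seq2, 0, aln2, model.mapq, header)
            same_strand = rng.random() < model.discordant_noise_rate
            _pair_up(r1, r2, model, same_strand=same_strand)
            records.extend([r1, r2])
    else:
        mean_len = (model.read_min + model.read_max) / 2
        n_reads = int(model.depth * ref_len / mean_len * (1 + bias_amp))
        for i in range(n_reads):
            hap = genome.haplotypes[int(rng.integers(0, 2))]
            length = int(rng.integers(model.read_min, model.read_max + 1))
            length = min(length, hap.length)
            start = int(rng.integers(0, hap.length - length + 1))
            if not keep_at(start):
                continue
            donor_ops = _donor_ops_with_errors(length, model, rng)
            aln = _choose_alignment(_lift_ops(hap, start, donor_ops), model.max_del_op)
            if aln is None:
                continue
            if rng.random() < model.clip_noise_rate:
                aln = _clip_noise(aln, rng)
            seq = hap.seq[start : start + length]
            # query length must equal the CIGAR's query consumption
            _, _, _, total_q = aln
            seq = seq[:total_q].ljust(total_q, "A")
            rec = _make_segment(f"{model.name}.{i}", seq, 0, aln, model.mapq, header)
            records.append(rec)

    records.sort(key=lambda r: (r.reference_start if r.reference_start >= 0 else 1 << 60))
    with pysam.AlignmentFile(out_path, "wb", header=header) as fh:
        for rec in records:
            fh.write(rec)
    pysam.index(out_path)
    return out_path


# ---------------------------------------------------------------------------
# fixture suite
# ---------------------------------------------------------------------------

@dataclass
class FixtureSuite:
    """Paths of one complete synthetic input bundle."""

    genome: SimulatedGenome
    fasta: str
    truth_bed: str
    repeats_tsv: str
    snps_vcf: str
    datasets: list[DatasetSpec]
    models: list


DEFAULT_FIXTURE_MODELS = (
    PairedReadModel(name="ill100", read_length=100, insert_mean=300, insert_sd=30, depth=30),
    PairedReadModel(name="ill250", read_length=250, insert_mean=800, insert_sd=80, depth=20),
    LongReadModel(name="pac", read_min=1000, read_max=4000, depth=12),
)


def _write_repeat_fixture(path: str, genome: SimulatedGenome, rng: np.random.Generator) -> str:
    classes = ["SINE/Alu", "LINE/L1", "LTR/ERVL", "Low_complexity", "Simple_repeat"]
    n = 60
    L = len(genome.reference)
    with open(path, "w") as fh:
        for _ in range(n):
            size = int(rng.integers(100, 2000))
            start = int(rng.integers(0, max(1, L - size)))
            cls = classes[int(rng.integers(0, len(classes)))]
            fh.write(f"{genome.chrom}\t{start}\t{start + size}\t{cls}\n")
    return path


def _write_snp_fixture(path: str, genome: SimulatedGenome, rng: np.random.Generator) -> str:
    n = 300
    L = len(genome.reference)
    positions = sorted(int(p) for p in rng.choice(L, size=n, replace=False))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={genome.chrom},length={L}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for pos in positions:
            ref = genome.reference[pos]
            alts = [b for b in "ACGT" if b != ref]
            alt = alts[int(rng.integers(0, 3))]
            gt = "0/1" if rng.random() < 0.5 else "1/1"
            fh.write(
                f"{genome.chrom}\t{pos + 1}\t.\t{ref}\t{alt}\t50\tPASS\t.\tGT\t{gt}\n"
            )
    return path


def make_fixture_suite(
    seed: int,
    out_dir: str,
    config: SimulationConfig | None = None,
    models: Sequence = DEFAULT_FIXTURE_MODELS,
) -> FixtureSuite:
    """Deterministic bundle: FASTA + BAM per dataset + truth BED + repeat
    track + SNP VCF, small enough for full-pipeline runs in well under two
    minutes."""
    os.makedirs(out_dir, exist_ok=True)
    if config is None:
        config = SimulationConfig(seed=seed)
    else:
        config = replace(config, seed=seed)
    genome = simulate_genome(config)
    rng = np.random.default_rng(seed + 1)
    fasta = genome.write_fasta(os.path.join(out_dir, "ref.fa"))
    truth = genome.write_truth(os.path.join(out_dir, "truth.bed"))
    repeats = _write_repeat_fixture(os.path.join(out_dir, "repeats.tsv"), genome, rng)
    snps = _write_snp_fixture(os.path.join(out_dir, "snps.vcf"), genome, rng)
    specs = []
    for j, model in enumerate(models):
        bam = os.path.join(out_dir, f"{model.name}.bam")
        simulate_reads(genome, model, seed + 100 + j, bam)
        specs.append(
            DatasetSpec(
                name=model.name,
                technology=model.technology,
                bam_path=bam,
                mean_coverage=model.depth,
                long_read_indel_baseline=(
                    (model.del_rate, model.ins_rate)
                    if isinstance(model, LongReadModel)
                    else None
                ),
            )
        )
    return FixtureSuite(genome, fasta, truth, repeats, snps, specs, list(models))
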