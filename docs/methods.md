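# Methods

## The one-class framing

The classifier never sees labelled SVs.  Its training class is a sample
of random genomic regions: random coordinates are very unlikely to sit
near a real SV breakpoint, so their annotation vectors define what
"ordinary genome" looks like for each sequencing dataset.  A candidate is
judged by how far outside that class it falls.  This avoids the bias of
training on curated SV sets, which over-represent easy, mid-size events;
the price is that the model can only say "unlike random regions", not
"which kind of SV".

## Windows and annotations

Each site is split into L / LM / M / RM / R windows.  Flanks default to
100 bp (the order of a short-read length; configurable), and the inner
windows LM/RM are capped at half the SV length so they never overlap.
Windows truncated at a contig edge may be empty; their metrics are masked
rather than fabricated.

Read counting rules: a read belongs to a window when its aligned span
overlaps it by ≥ 1 bp (partially mapped reads included, so one read can
count in several windows); secondary/supplementary alignments, duplicates
and QC-fail reads are excluded; MAPQ-0 reads stay in every denominator,
because low mapping quality is itself used as a clustering signal.  Depth
is aligned-base (M/=/X) coverage — CIGAR deletion segments contribute
nothing, so a long read spanning a deletion with a `D` op adds no depth
inside it.

Insert size is the end-to-end distance: both read lengths plus the gap
between them (negative for overlapping mates), i.e. |TLEN| of a
well-formed pair (both mates mapped, same chromosome, forward/reverse
orientation), counted once at the leftmost mate.  The aligner's
proper-pair flag is deliberately *not* required — pairs stretched across
a deletion are exactly the signal the annotation exists to capture.

Discordant pairs are those with a mate on another chromosome, same-strand
orientation, or |insert| above a cutoff estimated per dataset as
mean + 4·sd over 1000 sampled proper pairs.  The clip annotation counts
reads with ≥ 5 soft/hard-clipped bases on either end (configurable).
Long-read deletion/insertion rates are per-read CIGAR D/I bases divided by
read length, averaged over reads, minus a baseline measured on random
regions; the shipped default baseline (0.0428 deleted, 0.0948 inserted
bases per base) corresponds to uncorrected PacBio-like error rates and is
recomputed from the training regions whenever they are provided.

Annotation subsets:

* `oneclass` — technology-specific evidence only.  Paired short reads:
  LM/M/RM depth, L/R clipping, L/R insert mean/sd, L/R discordant, L/R
  mate-unmapped (13 columns).  Long reads: LM/M/RM depth, L/R clipping,
  M del−ins difference (6 columns).  Reference-only columns (GC, repeats,
  SNP counts, SV length) and mapping quality are excluded: atypical values
  there can mark hard-to-sequence regions rather than SVs, and they are
  not independent evidence across technologies.
* `clustering` — the above plus flank depth, mapping quality, SV length
  and the reference-context columns, which help separate SV *types*.
* `full` — the closure of every defined metric over all five windows plus
  the reference context; this is the documented membership of the "all
  annotations" table.

## Transform and standardisation

All model inputs pass through y = asinh(x) = log(x + √(x²+1)) — log-like
for large values but defined through zero and for negatives (the del−ins
difference is signed) — then z = (y − μ)/σ with μ, σ computed on the
*training* table only and frozen.  Anchoring to training keeps a
candidate's score independent of whatever other candidates share the
batch.  Columns constant on training carry no usable information and are
dropped with a warning.  Masked cells are imputed with 0, the
standardised training mean: neutral under L1 distance from the training
centroid.  The transform model serialises to CSV (annotation, mu, sigma).

## L1 one-class classifier

With transformed training vectors z_i and mean M, the sorted distances
d_i = ‖z_i − M‖₁ define everything: t_p is the order-statistic quantile
(smallest d with ≥ p·n of the d_i ≤ it, no interpolation), the acceptance
region is the L1 ball of radius t_p (a multidimensional rhombus), and a
new site with distance d is an SV iff d > t_p.  Its score
ρ = #{d_i < d}/n uses a strict inequality, so ties resolve conservatively
toward non-SV and a site at the centroid has ρ = 0.  Two consequences are
construction-forced and serve as sanity anchors: the model labels exactly
⌈p·n⌉ of its own training sites non-SV at level p, and held-out draws
from the training process satisfy P(ρ > p) ≈ 1 − p.

The combined "all datasets" model concatenates the per-dataset one-class
vectors (each dataset standardised by its own training moments) into one
model; sites missing any dataset are excluded from combined scoring.

## One-class SVM

Each annotation is first mapped by its deviation direction of interest —
depth: low is deviant; clipping/insert/discordance/mate-unmapped: high is
deviant; del−ins difference: two-sided around the training median — to
u = 1 − F(deviation), where F is the training ECDF with strict
inequality, so u ∈ (0, 1] and the most deviant training value maps to
1/n.  A linear-kernel ν-SVM (Schölkopf formulation) is trained on the
u-matrix at each ν in {0.01, 0.02, 0.05, 0.1, 0.2, 0.32, 0.5}; ν
approximately upper-bounds the training outlier fraction.  A site's score
is the smallest training true-negative rate 1 − ν whose boundary still
contains it, and 1.0 when it is outside every boundary — maximally
outlying — so the score runs in the same direction as ρ and the two
methods can be compared at matched thresholds.  The per-annotation
deviation-direction table is configuration with the defaults above, not a
claim about any particular dataset.

## Ensemble, pre-filters, strata

The k-of-n ensemble calls a site an SV when at least k per-technology
classifiers do (default k = 3, requiring independent evidence from three
datasets).  For stratification the ensemble ρ is the k-th largest
per-dataset ρ — thresholding it at p reproduces the vote at every p
simultaneously (order statistics).  Before stratification, sites are
flagged when flank depth exceeds 300 (≈1.5x a 200x genome; alternatively
1.5x the dataset mean) in *both* flanks — likely duplicated sequence — or
mean flank MAPQ falls below 30 in *either* flank.  Strata boundaries are
0.68 / 0.9 / 0.97 / 0.99 / 0.997 / 0.999 with half-open bins and the top
bin closed at 1.

## Clustering

Pairwise Manhattan distances (less outlier-dominated than Euclidean) feed
a hand-written Ward agglomeration in the `ward.D` convention: the
Lance–Williams update runs on the dissimilarities as given, without
pre-squaring.  Ward's variance derivation formally assumes squared
Euclidean input, so this pairing is heterodox — but it is the long-standing
behaviour of R's `hclust` and separates SV classes well; we keep it and
verify against `hclust(method="ward.D")` output frozen into the tests.
SciPy's own `ward` linkage implements the D2 convention and would produce
different heights, hence the hand-written loop (output uses scipy's
linkage-matrix layout so standard tooling still applies).  Dendrogram
order puts the tighter subtree left (ties to the smallest member index);
cut labels are numbered left-to-right.  Cutting by cluster count is the
primary interface — absolute heights are data-scale-specific and not
portable across runs.  Classical (Torgerson) MDS embeds the distance
matrix for visualisation: double-centred squared distances,
eigendecomposition, coordinates by decreasing eigenvalue, first nonzero
loading positive, rounding-level eigenvalues zeroed.

## The simulator

The generator emulates the statistical structure the annotations exploit,
not sequencing chemistry.  A random reference contig (GC 0.41) hosts
non-overlapping deletions and replacement insertions on a diploid donor
(hom on both haplotypes, het on one, separation ≥ 2x flank).  Reads are
sampled from donor haplotypes and *lifted analytically* to reference
coordinates — no aligner runs — so positions, flags, CIGARs and TLEN are
exact consequences of the planted variants: short reads crossing a
deletion soft-clip at the breakpoint (reference gaps > 50 bp are never
bridged; smaller ones become `D` ops), straddling pairs acquire inserts
stretched by the deletion length, long reads span deletions as `D`
operations and carry per-base indel sequencing errors (geometric sizes,
mean 3 bp; default rates equal to the shipped long-read baselines so the
normalisation centres at zero on random regions), and reads stranded
inside insertion sequence lose their anchor (< 20 aligned bases) and are
emitted unmapped with a mapped mate.  Background artefacts keep the noise
annotations non-degenerate: spurious 5–20 bp clips (1–2% of reads),
same-strand pairs (0.5%), lost mates (0.3%), and a smooth sinusoidal
coverage-bias field (default amplitude 0.25, wavelength 20 kb) standing in
for GC/mappability bias.

What the simulator does *not* model: base-call errors and quality
strings, chimeras, repeat-mediated mismapping, real GC bias coupled to
sequence content, multiple chromosomes.  Tests passing on simulated data
therefore certify the *pipeline logic and its statistical calibration*,
not performance on real genomes; in particular MAPQ is constant by
default, so the MAPQ pre-filter is exercised with hand-built fixtures.

Because a desk-scale contig is dense in planted SVs (a real genome is
not), the sampling frame for random regions can exclude truth intervals
padded by about the longest read length (`layout(exclude_truth_pad=...)`),
preserving the "random coordinates are unlikely to be near SVs" premise.

## Study conditions used by the checks

All sizes below are the package's chosen desk-scale study conditions.

* **Calibration** — null genome (no SVs), 200 kb, one 10x 2x100 bp
  paired-end dataset; 4000 training and 2000 held-out random regions,
  log-uniform 50–5000 bp (the published-scale upper bound of ~1 Mb cannot
  fit a desk-scale contig; the range preserves two orders of magnitude of
  size heterogeneity).  Checked: training self-coverage ⌈p·n⌉/n exactly,
  and held-out P(ρ > 0.99) within 3 binomial SEs of 1%.
* **Zygosity ordering** — 800 kb genome; 50 hom + 50 het deletions of
  100–400 bp; three datasets (2x100 bp at 8x, 2x250 bp at 6x, 1–4 kb long
  reads at 3x; coverage-bias amplitude 0.15); 600 training regions,
  100 random candidates; ensemble k = 3.  Modest coverage and small
  deletions keep heterozygous events genuinely marginal, so the median-ρ
  ordering hom > het > random is informative rather than saturated at 1.
* **Cluster recovery** — ten seeds of 500 kb genomes with 20 hom + 20 het
  deletions and 40 random regions under the same three read models;
  clustering the concatenated three-dataset one-class table at 3 clusters
  against the planted labels (ARI).
* **Method concordance** — L1 vs SVM calls at matched p on the ordering
  study's sites, per technology.

## Numerical choices and degenerate inputs

* Empirical quantiles are order statistics (no interpolation); all
  boundary comparisons are strict in the directions stated above.
* Constant/near-constant training columns (σ below a relative 1e-12
  floor) are dropped; fewer than two unmasked training values also drops
  the column.
* Zero-length windows (contig-edge truncation, SVs shorter than 2 bp of
  inner window) yield masked metrics; windows with no reads yield depth 0
  and masked fractions.
* Random placement uses rejection sampling with a 1000-attempt cap and a
  clear error naming the constraint.
* Reciprocal-overlap matching uses an inclusive ≥ boundary; ties break to
  the largest overlap, then the smallest target start.  Deduplication
  discards *both* members of a within-set overlap (possible compound hets
  or imprecise calls) and keeps the higher-priority set's call across
  sets.
* VCF parsing considers the first ALT of multi-allelic records only;
  indel records are ignored for SNP counts.
* The one-class SVM inherits sklearn's deterministic linear-kernel
  solver; every sampler takes an explicit seed and the pipeline logs all
  seeds and thresholds.

## Known limitations

* Ward-on-L1 has no variance-minimisation interpretation; it is used for
  continuity with established practice and validated empirically.
* ρ saturates at 1 for sites beyond every training distance, so candidate
  sets dominated by overwhelming events are not rank-ordered among
  themselves beyond the top stratum.
* The combined model drops sites missing any dataset rather than
  imputing.
* The simulator's MAPQ is uniform unless configured otherwise, so
  low-MAPQ pre-filtering on simulated data is a no-op by default.
* Single-sample, deletion/insertion-only scope: inversions, duplications
  and translocations are out of scope by design.
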