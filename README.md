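# svarbiter

Read-evidence annotation and one-class classification of candidate
structural variants (SVs) across sequencing technologies.

## The problem

Structural-variant callers disagree wildly, so building a *benchmark* set
of deletions and insertions for a well-characterised genome requires a way
to ask, for every candidate site: does the aligned read evidence — from
several independent sequencing technologies at once — actually look the
way a true SV should?  svarbiter answers this without a curated truth set
for training.  It computes per-site *annotations* from one or more BAM
files and classifies candidates against the only class that can be sampled
without bias: random genomic regions, which are overwhelmingly non-SV.

## Method

For each candidate site the neighbourhood is split into five windows —
left flank **L**, left-inner **LM**, the SV interval **M**, right-inner
**RM**, right flank **R** — and per window, per dataset, the tool
summarises: mean depth, soft-clipped read fraction, mapping quality, and
(for paired short reads) end-to-end insert-size mean/SD, discordant-pair
and mate-unmapped proportions, or (for long single-end reads) per-base
deletion/insertion rates normalised against a random-region baseline.
Reference context (GC, RepeatMasker coverage, SNP genotype counts) is
added for clustering.

Annotations x are transformed with the inverse hyperbolic sine,

    y = asinh(x) = log_e(x + sqrt(x^2 + 1)),

standardised with moments frozen on the training set, and fed to two
one-class models trained on n random regions:

* **L1 classifier** — with training mean vector M and the empirical
  distribution of L1 distances d_i = ||z_i − M||_1, the acceptance region
  at level p is the L1 ball of radius t_p (the empirical p-quantile of the
  d_i): a site is an SV if its distance exceeds t_p.  Each site gets a
  score ρ = (fraction of training sites strictly closer to M), so ρ is
  uniform on training-like data and high ρ means strong SV evidence.
* **one-class SVM** — the Schölkopf ν-formulation with a linear kernel on
  directionally ECDF-transformed annotations, scored by the smallest
  training true-negative rate whose boundary still contains the site.

Per-technology classifiers are combined by a k-of-n ensemble (a site is an
SV when ≥ k datasets call it; the ensemble ρ is the k-th largest
per-dataset ρ), sites in suspect regions are pre-filtered (flank coverage
high in *both* flanks, or flank MAPQ low in *either*), and calls are
stratified by ρ.  Hierarchical clustering (Manhattan distance, Ward's
method in the `ward.D` convention, classical MDS for visualisation)
separates SV types for exploratory analysis.

A bundled simulator generates reference genomes, diploid donor haplotypes
with planted hom/het deletions and insertions, and fully consistent
aligned BAMs (reads lifted analytically from donor to reference), so every
stage is testable hermetically.

## Worked example

```python
from svarbiter.simulate import SimulationConfig, make_fixture_suite
from svarbiter.annotate import annotate_sites
from svarbiter.regions import sample_random_regions_loguniform
from svarbiter.oneclass import fit_l1_model, stratify

config = SimulationConfig(seed=7, genome_length=150_000,
                          n_hom_del=5, n_het_del=5, n_insertion=2)
suite = make_fixture_suite(7, "scratch/demo", config)

layout = suite.genome.layout(exclude_truth_pad=1000)
training = sample_random_regions_loguniform(layout, 400, 50, 3000, seed=1)

dataset = suite.datasets[0]                       # 30x 2x100 bp paired-end
train_tab = annotate_sites(training, dataset, subset="oneclass")
cand_tab = annotate_sites(suite.genome.truth, dataset, subset="oneclass")

model = fit_l1_model(train_tab)
print(model.summary())

rho = model.rho(cand_tab)
for sv, r, s in zip(suite.genome.truth[:5], rho, stratify(rho)):
    print(f"{sv.site_id:<22} {sv.sv_type.value:<9} {sv.zygosity.value:<4} rho={r:.3f}  {s}")
```

prints

```
L1 one-class classifier
=======================
training sites      : 400
annotations         : 13
median train L1 dist: 9.818
thresholds t_p      : p=0.9: 13.27, p=0.95: 14.59, p=0.99: 18.14
chr1:5231-5949         deletion  hom  rho=1.000  >0.999
chr1:38755-40319       deletion  hom  rho=1.000  >0.999
chr1:54161-55981       deletion  hom  rho=1.000  >0.999
chr1:58672-59650       deletion  het  rho=1.000  >0.999
chr1:60615-62270       deletion  hom  rho=1.000  >0.999
```

Every planted deletion sits far outside the random-region class (ρ in the
top stratum): at 30x, depth loss, breakpoint clipping and stretched
inserts are unmistakable.  The thresholds line gives the L1 radii t_p of
the acceptance region at common levels.

The same flow is available from the shell:

```sh
svarbiter simulate --seed 7 --out-dir demo
svarbiter annotate --bam demo/ill100.bam --tech paired_short \
    --sv demo/truth.bed --subset oneclass --out cand.csv
svarbiter classify --train train.csv --candidates cand.csv --out scored.tsv
svarbiter run --config run.yaml        # full pipeline, every intermediate saved
```

## Layout

| module | contents |
| --- | --- |
| `svarbiter.core` | coordinate types, five-window partition, annotation table |
| `svarbiter.io` | BED/TSV dialects, RepeatMasker track, SNP VCF, CSV tables |
| `svarbiter.regions` | random-region samplers, dedup, reciprocal-overlap matching |
| `svarbiter.annotate` | per-window read evidence and reference context from BAMs |
| `svarbiter.transform` | asinh + training-anchored standardisation |
| `svarbiter.cluster` | L1 distances, ward.D linkage, tree cutting, classical MDS |
| `svarbiter.oneclass` | L1 and SVM one-class models, ensembles, strata, ROC |
| `svarbiter.simulate` | genome/haplotype/read simulator, fixture bundles |
| `svarbiter.cli` | `svarbiter` command and the YAML-driven pipeline |

See `docs/methods.md` for the modelling details, parameter defaults and
known limitations.
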