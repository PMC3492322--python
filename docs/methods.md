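# Methods

## Gene-level quantification

Transcript-level records (id, gene name, length, mean per-base coverage,
FPKM) are aggregated by gene name: raw count = Σ coverage·length/read_length
and gene FPKM = Σ transcript FPKM. Gene identity is keyed by the gene
symbol, not locus coordinates; distinct loci sharing a symbol collapse into
one row (accepted and logged — the upstream tables carry no coordinates).
Raw counts are non-integer by construction and are kept as reals; they are
rounded half-up only where a read-count threshold is applied (the screen's
≥ 10-read rule). Gene–sample pairs missing from a sample's table are 0:
the upstream quantifier omits unexpressed transcripts.

## Coverage QC

The positional profile uses 101 bins (relative positions 0…100, 5'→3').
Each transcript is divided by its own mean depth before binning, so
transcripts of unequal expression contribute equally; transcripts ≥ 101
bases are partitioned into 101 contiguous base intervals and averaged per
interval, shorter ones are linearly interpolated (and logged). Bins are
aggregated across transcripts by median (mean available via numpy on the
stacked rows); all-zero vectors carry no positional information and are
excluded with a warning.

Per-gene CV uses the population (ddof 0) standard deviation: per-base depth
is a census of the transcript, not a sample from it. The median CV is taken
over panel genes with FPKM strictly > 1 by default; an alternative filter
on mean per-base coverage strictly > 1× is provided because both
conventions are in circulation and they are not equivalent (a 1×-coverage
gene can sit on either side of 1 FPKM depending on length and library
size). Panel selection keeps genes with > 90 % fully mappable bases and
> 1× reference-RNA coverage, both strict.

The 3'-bias score is (mean of bins 81–100)/(mean of bins 0–20 + 1e−6):
≈ 1 for flat coverage, ≫ 1 for 3'-concentrated coverage. The three-way
degradation call (good / partially degraded / degraded) thresholds this
score at 1.5 and 4.0 by default; the original classification of such
libraries was made by eye from cDNA size traces, so these cut-points are
this package's own operational surrogate and are configurable.

Verdicts use the bulk-data expectations median CV < 65 % and % aligned
> 60 % (both strict, as conventionally printed), and the looser % aligned
> 5 % rule for admitting a sample to downstream analysis.

## Over-expression screen

Using the 2nd-highest FPKM among CTCs as the numerator makes the call
robust to a single aberrant cell; the rank is configurable. The normal
reference is the mean FPKM of the normal-tissue profiles. A zero normal
FPKM is floored at ε = 0.01 FPKM (configurable, surfaced in the result
table) so genes absent from normal tissue can pass. Comparisons follow
printed strictness: ratio ≥ 100, reads ≥ 10 (per-CTC counts rounded
half-up first), marker positivity strictly > 1 FPKM, transcript richness
non-strictly ≥ 10 FPKM, variable-gene bounds strictly > 10 and < 0.1.

## Clustering

The gene pool is the union of each sample's top-k (default 100) genes by
FPKM, with ties broken by descending FPKM then lexicographic gene name for
cross-platform determinism. Samples are clustered agglomeratively
(complete linkage by default) on Euclidean distance over the pooled
submatrix. Distances are computed on raw FPKM by default — in the R
heatmap idiom this stage mirrors, scaling affects colors, not the
dissimilarity — with a log2(FPKM+1) option. Patient concordance of a flat
k-cut is reported as the adjusted Rand index plus per-cluster
majority-patient purity. Trees serialize to Newick with branch lengths
equal to height differences, so tip-to-tip distance is twice the cophenetic
merge height.

## Capture metrics

Efficiency = recovered live / spiked; purity counts dead recovered cells in
the numerator (the bench protocol counts "spiked cells recovered";
`live_only` restricts to live). Replicate summaries use the sample (n−1)
standard deviation, the usual error-bar convention for replicate
experiments. Enumeration comparisons keep raw counts and add plot columns
with 0 → 1 substitution for log axes; the low-count stratum summary
(reference count ≤ 5 by default) reflects where platform differences are
most consequential. Attrition is reported as recovered-dead fraction minus
the pre-spike dead fraction — an interpretation, since the exact
bookkeeping behind published attrition figures is rarely printed.

## Synthetic cohorts

The generator's default cohort emulates a single-CTC prostate-cancer
study design: 20 CTCs over 4 patients (3/9/4/4), 4 fresh + 4
immunomagnetically isolated LNCaP cells, 3 bulk normal-prostate profiles,
and 1 white blood cell; 1000 genes; 50-base reads; per-sample library
sizes uniform in 1–3 million mapped fragments; gene lengths uniform in
0.5–5 kb.

* **Expression.** Baseline FPKM per gene is log-normal (ln-mean 0.5,
  ln-sd 1.5), shared across groups. Cell-to-cell heterogeneity is
  multiplicative log-normal noise with ln-sd 1.0 by default —
  order-of-magnitude swings, the simplest generative model consistent with
  the heterogeneity seen between single cells. CTC background genes
  additionally carry a per-(gene, patient) log-normal effect (ln-sd 1.0
  default) so patients are separable; marker and planted genes are exempt
  so their planted values stay exact in noiseless runs.
* **Markers.** AR (20 FPKM), KLK3 (150), TMPRSS2 (40) in prostate-lineage
  groups; CD45 (50) in the WBC and — because bulk normal prostate contains
  resident leukocytes — the normal-tissue profiles. Markers are exactly 0
  outside their groups.
* **Planted over-expression.** Ten genes at fold 200 and ten decoys at
  fold 50 over a 2-FPKM normal baseline, each expressed in 3 randomly
  chosen CTCs (≥ 2, so the rank-2 screen can see them).
* **Counts.** count = FPKM · (length/1000) · (library/10⁶), exactly, kept
  real-valued.
* **Coverage.** A fragment's 3'-end lands at distance d from the
  transcript 3' end with probability ∝ e^(−λd), truncated so the read fits;
  the read covers the read_length bases 5' of that point. λ = 0 is uniform
  up to edge ramps of one read length at both ends. Default λ classes
  {0, 0.002, 0.01} per base with frequencies {0.21, 0.37, 0.42} mirror a
  good / partially degraded / degraded breakout; λ can be drawn per cell
  (default) or per patient (RNA quality tends to be patient-correlated),
  with neither mode canonical.
* **Spike-ins.** The spike splits binomially into live/dead; each class is
  recovered binomially with the same capture probability (epitope-based
  capture is indifferent to viability); leukocyte carryover is Poisson with
  the given mean (the binomial limit for a large leukocyte pool).

All randomness in a call flows through one `numpy` generator seeded per
call; identical configs and seeds give byte-identical written output.

What the generator does **not** emulate: read-level errors, PCR and
library-prep bias, isoform structure (one length per gene), dropout beyond
log-normal noise, mitochondrial/rRNA contamination, doublets, and any
coupling between degradation and measured FPKM (coverage shape and
expression level are generated independently). Passing tests therefore
show the analysis correct under the stated statistical structure, not that
it is robust to every artifact of real single-cell libraries.

## Evaluation choices and problem sizes

The screen is validated two ways: exact agreement with an exhaustive
plain-python re-computation on 200 random matrices (≤ 50 genes × ≤ 6
CTCs), and exact recovery of planted fold-200 genes — with fold-50 decoys
rejected — on a noiseless 1000-gene cohort. Degradation ordering is
checked over 100 seeded runs of 500 transcripts (1 kb, 200 fragments each)
per λ; at these depths (~10× mean coverage) undegraded median CV is ≈ 35 %,
comfortably under the 65 % expectation.

Clustering recovery is evaluated on log2(FPKM+1) distances: with
multiplicative (log-additive) effects, raw-scale Euclidean distance is
dominated by the single heaviest-tailed gene, and patient recovery on the
raw scale is not stable even when the planted between-patient effect is
large — the standard log transform is the appropriate scale for this
generative model, and the raw default remains for mirroring the R-heatmap
behavior on real data. The "strong effect" regime uses patient-effect
ln-sd 2.5 with heterogeneity ln-sd 0.5 (between-patient spread 5× the
within-patient spread); the null regime sets the patient effect to 0 and
averages the adjusted Rand index over 100 seeds.

Capture metrics use 54 replicates of 100 spiked cells at capture
probability 0.81, matching a realistic validation campaign for an
immunomagnetic isolation platform.

## Known limitations

Gene-name keyed aggregation conflates same-named loci. The QC panel's
mappability and reference-coverage attributes are inputs, not computed
from sequence. The degradation trichotomy cut-points are operational, not
calibrated against physical RNA-integrity measurements. The screen's ε
floor makes ratios for genes absent from normal tissue depend on ε;
results carry the floor explicitly so such calls are auditable.
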