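# Methods

This note documents the models and procedures implemented in `ago2seed`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmark does and does not show.

## 1. Array processing

### Probe model and QC

A probe table row is `(probe_id, feature_id, cy5, cy3, flag)`; miRNA arrays
are single-channel (Cy5 only), whole-genome arrays two-color (Cy5 =
treated, Cy3 = control RNA). Spots with a negative QC flag are removed
per array before any normalization (`filter_flags`). Features may
consequently have fewer replicates than the design nominally provides;
downstream statistics use the per-feature replicate count and drop features
with fewer than two finite replicate ratios.

### 75th-percentile scaling (miRNA arrays)

Each array's intensities are multiplied by a scalar chosen so that its 75th
percentile (linear-interpolation quantile) equals a cohort reference. The
reference is the geometric mean of the per-array 75th percentiles; this
choice makes the transform idempotent and symmetric in the cohort, but it
is one of several defensible readings of upper-quartile scaling, so the
reference is configurable (e.g. a fixed constant). Scaling preserves
within-array intensity ratios exactly.

### Rank-consistency-filtered LOWESS (two-color arrays)

Per spot, M = log₂(cy5/cy3) and A = ½·log₂(cy5·cy3). The intensity-dependent
dye trend is estimated by LOWESS of M on A (statsmodels, default span 0.3)
fitted on a *fit set* of spots presumed non-differential, and subtracted
from every spot's M; channels are reconstituted from corrected M and
unchanged A, so A is invariant.

The fit set contains spots that are **rank-consistent** — ordinal ranks of
cy5 and cy3 (ties broken by probe id) differ by at most `rank_tolerance`
(default 0.05) of the array size — **and** whose mean rank lies inside the
central band of the intensity distribution (`edge_exclusion` = 0.05 per
tail). The second condition exists because rank consistency is vacuous at
the extremes: the dimmest spot remains the dimmest however strongly it is
repressed, so without trimming, a genuinely repressed low-intensity
transcript enters the fit set and the local trend nulls its own signal.
Beyond the fit range the correction is held constant at the boundary value.
Fewer than 10 fit spots is an error advising a larger tolerance; on small
panels (tens of spots) a proportionally larger `rank_tolerance` (e.g. 0.1)
is appropriate, since 5% of a 50-spot array is below rank noise.

### Ratios

miRNA arrays are ratioed **between** arrays — each treatment array against
the sham array of the same genotype, timepoint and replicate — because the
platform reports a single channel. Whole-genome arrays are ratioed
**within** array (Cy5/Cy3). Duplicate probes per feature are collapsed to
the per-channel median after normalization, before ratio computation.
Features with non-positive intensities are dropped and reported.

## 2. Differential statistics and responsiveness

Per feature, the mean log₂ ratio across replicates is tested against 0 with
a two-sided one-sample t-test (a Wilcoxon signed-rank option exists for
robustness checks). Selection requires |mean log₂| ≥ 1 (closed threshold,
i.e. exactly 2-fold passes) and P < 0.05. No multiple-testing correction is
applied by default — matching the analysis style this package reproduces —
but a Benjamini–Hochberg flag is available.

With 3 replicates the t-test has 2 degrees of freedom (critical t ≈ 4.30),
and with 2 remaining replicates just 1 (critical t ≈ 12.7): a feature that
loses one replicate to QC flags rarely reaches P < 0.05 no matter how large
its fold. This is a property of the analysis design, not of the
implementation, and it dominates sensitivity losses when flag rates are
appreciable.

2-fold transcript lists for the mRNA arms threshold the mean log₂ ratio at
±1, boundary inclusive.

Responsiveness classification takes a feature × genotype table of log₂
folds and selects features with wild-type fold ≥ `wt_min` (default 1, with
the wild-type P < 0.05 clause when P values are available) and both
knockout folds ≤ `ko_max` (default −1). The knockout threshold is a
parameter because "decreased expression" in the knockouts was
operationalized here as at-least-2-fold-down, symmetric with the up rule;
whether knockout rows were additionally P-filtered in the original
analysis is unknowable from the printed record, so P filtering applies to
the wild-type arm only by default.

## 3. Hierarchical clustering

Profiles are compared with Pearson correlation distance d = 1 − r and
agglomerated by average linkage (UPGMA, via scipy). Zero-variance vectors
are an error naming the offending feature. Merge heights are invariant to
adding a constant to all values (shift invariance of r), and permuting the
input yields an isomorphic tree. Dendrograms export to Newick with
merge-height differences as branch lengths.

The pipeline clusters the selected-differential feature set by default.
The genotype-separation benchmark instead clusters samples on the full
simulated ratio matrix: with a single planted effect size, the
selected-differential profile of a wild-type sample is nearly constant
across features, which makes its Pearson correlations noise-driven — an
artifact of the simulator's homogeneous effect sizes, not of real data,
where induced miRNAs span a range of folds.

## 4. The duplex aligner

The aligner is a Gotoh (affine-gap) local dynamic program of the reversed
miRNA (3′→5′) against the UTR (5′→3′), so the alignment is antiparallel as
in a physical duplex. Default pair scores: Watson–Crick +5, G:U wobble +1,
mismatch −3; gap open −8, gap extend −2; pair scores at miRNA positions
2–8 (1-based from the 5′ end — the seed) are multiplied by 2. The score
scale is dimensionless; the default site threshold is 80. These defaults
mimic published miRanda behavior but are this package's own definition and
are fully configurable (`ScoringParams`). No thermodynamic (free-energy)
filter is applied; that is a noted extension point.

All non-overlapping sites above threshold are reported best-first: the
best-scoring alignment is taken, its UTR interval removed, and the flanks
searched recursively (greedy suppression by score; ties break toward the
smaller end coordinate, hence leftmost sites). UTR coordinates are 0-based
half-open. Each site records a pair-state trace (`|` Watson–Crick, `:`
wobble, `.` mismatch, `-` gap) that re-scores to the reported score under
the active parameters.

`seed_match_scan` reports exact 7mer sites (reverse complement of positions
2–8) and 7mer-A1 sites (reverse complement of positions 2–7 with an A
opposite position 1). A site is `seed_matched` when its interval overlaps
a scanned seed match; since a qualifying prediction must be seed-matched,
UTRs with no seed hit are skipped without running the full DP — an exact
prefilter that makes genome-scale scans cheap. Equivalence of the
production DP with an independently coded exhaustive brute-force DP is
asserted over hundreds of random instances in the test suite.

## 5. Evidence intersection

A (miRNA, gene) pair is called iff predicted ∧ Ago2-IP-up ∧ total-down.
Gene symbols are matched case-insensitively; when an accession map is
supplied, a symbol mapping to conflicting accessions is reported and
excluded from calls rather than silently merged. The Ago2 arm uses
IRI-IP vs sham-IP ratios (not IP-vs-input). Multiplicity counts distinct
calling miRNAs per gene; `genes_at_k` is sorted by (count desc, gene id).

One realistic false-call mode survives triangulation: a miRNA with a
*chance* seed-complementary site in a gene that is genuinely repressed as
another miRNA's target passes all three arms. The original method shares
this failure mode; on synthetic panels it bounds precision around 0.95
rather than 1.0.

## 6. The synthetic study generator

`SimDesign` defaults mirror the emulated design: genotypes (wild type,
Tlr4-KO, NF-κB-KO), four reperfusion timepoints, 3 miRNA replicates, 2
whole-genome replicates, a 4-fold (log₂ = 2) planted effect and log₂-scale
noise sd 0.2. Probe intensity is log-normal: log₂ intensity = per-feature
baseline N(10, 1.5) + planted effect + per-array scale offset U(−0.5, 0.5)
+ N(0, noise_sd); the scale offsets exist so that normalization is
genuinely exercised. Bad spots get flag −50 (default 2% of spots), good
spots 0. Sham arrays are simulated explicitly. An optional `lowess_curvature`
adds an intensity-dependent dye trend to the two-color arrays for
normalization testing. Background correction is not simulated (the
emulated platform's processing chain does not document one); intensities
are background-free.

Planted truth: responsive miRNAs are +effect in wild type and −effect in
both knockouts at the 1-day timepoint; non-responsive upregulated miRNAs
are +effect in all genotypes; target genes are −effect in the total-mRNA
arm and +effect in the Ago2-IP arm; decoy classes satisfy exactly one
expression criterion (down-only, IP-only) or carry only a sequence site
(site-only). Each planted site is the reverse complement of the miRNA's
first 13 nucleotides — containing the seed complement — because a bare
7-nt seed duplex scores 70, below the 80 threshold, and real functional
sites pair beyond the seed; the 13-nt plant scores 100 in isolation. UTR
backgrounds are i.i.d. uniform nucleotides. All randomness derives from a
single master seed through named per-purpose streams, making study output
byte-deterministic.

Problem sizes used in the benchmark suite — 100–500 miRNA probes, 100-gene
panels, 100 simulations per property — are chosen so each property is
measured with adequate Monte-Carlo resolution while the whole suite stays
interactive. The planted-recovery benchmark runs with flags disabled so it
measures effect recovery at the stated effect/noise/replicate conditions
rather than QC attrition (which is exercised separately); all other
benchmarks use the default 2% flag rate.

## 7. What the synthetic benchmark does not show

Uniform random UTRs lack composition bias, repeats and conservation
structure, so the aligner's false-positive rate on real 3′UTRs will differ.
Planted effects are homogeneous in magnitude; real induction spans orders
of magnitude and partial knockout attenuation rather than clean sign flips.
Probe noise is i.i.d. Gaussian in log space with no spatial artifacts, dye
bias beyond the optional curvature, or cross-hybridization. Passing
recovery benchmarks therefore demonstrates correctness of the analysis
chain under its own assumptions, not field performance on deposited raw
arrays.

## 8. Numerical conventions

Percentiles use linear interpolation between order statistics. Rank ties
break deterministically by probe id. Zero-variance replicate vectors get
P = 1 (mean 0) or P = 0 (mean ≠ 0) rather than NaN. Alignment scores are
exact floats (integer-valued under default parameters); score ties in site
enumeration break toward the smaller UTR end coordinate. All thresholds on
folds are closed; P-value thresholds are open.
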