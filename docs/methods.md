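# Methods

This note documents the models, parameter choices and numerical decisions
behind `ctcfrep`, and what the synthetic scenario does and does not emulate.

## Atlas construction

Peaks enter as summits with a fold-enrichment value; peaks with fold
enrichment < 4 are dropped and datasets with fewer than
`min_peaks_per_dataset` surviving peaks (default 2000; the bundled
desk-scale config uses 100) are excluded rather than erroring, mirroring
how heterogeneous public compendia are curated. Summits are extended
±`merge_halfwidth` (75 bp) and merged by a single sorted sweep; windows
that merely touch are *not* merged, so summits exactly 150 bp apart found
distinct sites, consistent with 150 bp being the cutoff between same-site
and different-site summit gaps. Merged sites can exceed 150 bp (the union
envelope). Coordinates are 0-based half-open everywhere; only the
VCF-like mutation table is 1-based and converted on read.

Occupancy counts *datasets*, not peaks: a dataset contributes at most one
to a site's score however many of its summits fall inside. The
conservation identity (sum of scores = number of dataset-site incidences)
is asserted against brute force in the tests.

## Constitutive-site model

`O_i`, the number of sites at occupancy score `i`, is fitted by
`E_i = a·(i − b)^(−c)`. The fitting procedure is ordinary least squares of
`log O_i` on `log(i − b)` with `b` optimized by bounded 1-D search over
`[0, min(fit_range) − 0.01]`; log-space regression was chosen over a direct
nonlinear fit because the counts span orders of magnitude and the log
residuals are closer to homoscedastic on heavy-tailed data. The cutoff
`A` is the smallest score whose observed-minus-expected tail exceeds
`excess_factor` (default 5) times the expected tail; constitutive sites
have score ≥ A + 1, and when no score qualifies the frequency rule
`score ≥ ⌈constitutive_frequency · n⌉` fires instead (logged).

Sensitivity of `A` to the planted excess: for a distribution `O = E + bump`
with the bump starting at score `K`, the tail ratio below `K` is
`bump / tail_E(i)`, which shrinks by only a few percent per score, so `A`
tracks the bump *mass*, not merely its start. The recovery study therefore
plants excess mass between `5·tail_E(K)` and `5·tail_E(K−2)`, the regime
in which the crossing is pinned to `{K−1, K}`; steeper decay exponents
(2.5–4) widen that window. This is a property of the cutoff definition
itself, not of the implementation.

At desk scale the occupancy distribution of the synthetic scenario is a
mixture of binomial modes rather than a power law; the cutoff stage still
runs end to end but yields a permissive `A` there. Domain boundaries
additionally require an oriented motif, which contains the effect in the
demo pipeline. This is a known limitation of exercising a
compendium-scale model on 40 datasets, not of the model.

## Lost/gained calling

RPKM = count / (site length in kb × library size in millions), followed by
quantile normalization: each column is rank-mapped onto the vector of row
means of the column-sorted matrix, ties receiving the mean of the reference
values at the tied ranks (so tied inputs stay tied). "Student's t" is the
pooled-variance unpaired two-tailed test (Welch available behind a flag);
Cohen's d uses the pooled sd. Zero pooled variance with equal means gives
t = 0, p = 1; with unequal means the row is flagged degenerate with p = 0.
BH-FDR is computed per comparison family, defined as all sites of one call
for one cancer type and one comparison group. The lost criteria use only
the sign of t while the gained criteria require FDR ≤ 0.01 — the asymmetry
is preserved exactly as specified, and each criterion's pass/fail is a
column of the output so calls are auditable. The "all other samples"
stratum excludes only the cancer type's own datasets (matched normals
remain in it).

## Domains and expression

A domain needs, on each side of the anchor, a constitutive site at
100 kb–1 Mb (per-side interpretation of the size constraint) whose motif
strand fits the orientation mode: `divergent` (left −, right +, the
default), `convergent`, or `opposite_any`. Constitutive sites failing
orientation or distance are skipped, not blockers; motif-less sites cannot
be boundaries. Gene membership is by TSS position. Candidate targets:
genes whose TSS ± 2 kb window overlaps the site are promoter targets and
take precedence; otherwise genes with TSS inside the domain are
intra-domain targets; everything else on the chromosome is inter-domain
(for pair classification only). Correlation uses Pearson r across cell
types on sqrt-RPKM (quantile normalized) versus sqrt-TPM; R² > 0.25
strictly defines "highly correlated", and zero-variance vectors are
flagged undefined and excluded. DE enrichment is a two-tailed Fisher test
of {target} × {|log₂FC| > 1 and FDR < 1e−5} over a user-supplied universe.

## Hi-C

Each bin pair at distance k is divided by the mean count over all
`n_bins − k` pairs at that distance (zeros included); the diagonal is
excluded, and distances with zero mean stay zero and are dropped from
flank vectors. No matrix balancing is applied — the normalization is
expected-by-distance only. Flank vectors collect both sides of the anchor
bin up to L = 500 kb (5-kb bins), matching the "bins located within 500 kb
from the site" reading; a one-sided variant is a config choice away.
The paired two-tailed t test runs on the common flank bins; at least 3
bins with a nonzero value in either condition are required, all-zero
difference vectors give t = 0, p = 1, and log₂ fold changes use an
ε = 0.01 pseudocount on normalized values. Differential intra-domain
regions require |log₂ FC| > 1 *and* mean log₂ interaction > 0, which
suppresses fold changes between near-zero values.

## Methylation

The 300-bp window centered on the site pairs CpGs across conditions by
exact position; a CpG is used only with coverage ≥ 5 in both conditions,
at least 3 such CpGs are required (else status `insufficient`), and the
mean per-CpG difference (cancer − normal, percentage points) is
thresholded strictly at ±20. The association profile drops insufficient
sites, ranks the rest by the differential-binding t statistic and splits
them into 100 equal-count bins (remainder to the first bins); per bin the
hypo/unchanged/hyper fractions sum to 1 and the median t is reported.

## Mutations and motifs

The mutation-rate profile counts events from all samples at each offset of
the 400-bp centered window, divided by the number of sites; events are
counted per (sample, position). Motif scores are sums of per-position
log-likelihood ratios against the background [0.275, 0.225, 0.225, 0.275]
(A, C, G, T); PFM counts get a +0.5 pseudocount per cell. Log-odds are
quantized to a 1e-3 lattice so the null score distribution — and hence
FIMO-style p-values — is computed *exactly* by dynamic programming over
per-position score offsets; a query score maps to the smallest lattice
point at or above it. Disruption deltas score the PWM-width window at the
site's motif hit on the annotated strand (reverse complement for −),
alt minus ref; variants outside the window are 0 by definition and indels
are profiled but never motif-scored.

## TF enrichment

The repertoire is any sorted, non-overlapping element set standing in for
a genome-wide catalog of candidate cis-regulatory elements; each TF is a
binary bound/unbound profile over it. Query regions select elements by
≥ 1 bp overlap and each TF is tested with the two-tailed Fisher exact
test, ranked by ascending p (ties: descending odds ratio, then name).
The Fisher p is computed in-package as the hypergeometric tail sum with a
1e-7 relative tie tolerance; the tests verify it against independent
enumeration for every table with total ≤ 60 and against
`scipy.stats.fisher_exact` on random tables. Odds ratios are sample odds
ratios; a zero margin gives 1 by convention and a single zero cell gets
the Haldane 0.5 correction, both logged.

## The synthetic scenario

Defaults: 2,000 sites on two 10-Mb chromosomes (≥ 1 kb spacing), 8 cancer
+ 8 matched-normal + 24 other datasets, class fractions 10% constitutive /
55% common / 2.5% lost / 2.5% gained / 30% sample-specific (counts exact by
largest remainder). Presence probabilities per class and cohort are the
study conditions; matched normals never carry gained sites, so the
"matched-normal score = 0" criterion is satisfiable by construction.
Summits jitter around site centers (sd 10 bp); every emitted peak passes
the fold filter.

Signal follows peak presence (bound cells at background × 2^4 = 8 RPKM,
unbound at 0.5 RPKM, lognormal noise sd 0.15, Poisson counts at a 40
M-read library), except in cancer columns where the planted class rules:
gained sites are elevated in every cancer column and lost sites sit at
background there — the class effect, not the per-dataset peak draw,
defines a planted site's cancer binding level. The depth and noise levels
describe a clean, well-powered compendium; real ChIP-seq cohorts are
noisier, so the recovery rates measured here are upper bounds on real-data
performance, and passing tests demonstrate correctness of the procedure,
not field sensitivity.

Hi-C expected counts decay as `60·k^(−1)` with Poisson sampling;
interactions between a planted site's bin and its flanks within 500 kb are
multiplied by the boost (2×) in the cancer map for gained sites and in the
normal map for lost sites. Methylation: CpGs every 20–60 bp within
±150 bp, coverage Poisson(25) (a 10% fraction of sites at Poisson(1.5) to
exercise the insufficiency filter), baseline 25%, per-CpG noise sd 6.
Planted lost sites shift +`meth_shift` (30) points in cancer and gained
sites −30; all other sites shift by −(2/3)·meth_shift per standard unit of
their realized cancer-vs-rest binding difference (clipped at ±3 sd), which
is the genome-wide anti-correlation between binding change and methylation
change that the association profile recovers. With `meth_shift = 0` every
shift vanishes, giving the null scenario. Expression: a 12-cell-type
panel; each planted site gets a target gene whose expression is built from
the site's standardized panel signal at correlation r = 0.7. The DE table
marks genes in gained domains up- and in lost domains down-regulated. The
repertoire has one element per site plus inter-site elements; one TF
profile ("NOTCH1_like") is bound at 80% of elements inside gained-site
domains versus 2% elsewhere, the other 19 TFs are uniform.

All randomness flows from one integer seed through named substreams (one
per modality), so adding or regenerating a modality never perturbs the
others and outputs are byte-reproducible across platforms. The generator
does not emulate read-level data, fragment-level Hi-C, chromatin-state
segmentation, batch structure or copy-number variation.

## Problem sizes

The test suite and the acceptance script run the full default scenario
(2,000 sites, 40 datasets, 2 × 2,000-bin contact maps, ~1,000 Hi-C anchors
for calibration, 100 cutoff-recovery distributions, 20 PWMs against 4^w
enumeration, and the exhaustive Fisher sweep to total 60); the end-to-end
pipeline test uses a 300-site single-chromosome scenario. These sizes were
chosen so the whole validation completes in well under a minute on one CPU
while every statistical check retains the sample sizes stated above.
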