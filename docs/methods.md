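# Methods

`clipsplice` re-implements, as a reusable and fully testable pipeline, the
computational analyses used to characterise how a spliceosomal protein's
RNA contacts and downstream splicing outcomes change between conditions:
iCLIP crosslink-site calling and snRNA binding profiling, maximum-entropy
splice-site strength scoring with weak/strong stratification, differential
binding statistics, and PSI-based alternative/cryptic splicing
quantification. Every stage can be exercised on synthetic data with
recorded ground truth, so the statistical behaviour of each estimator is
verifiable without any external dataset.

## Crosslink evidence model

iCLIP reads report protein–RNA contacts in two ways. Most cDNAs truncate
at the crosslinked nucleotide, so the crosslink site is taken as the
position immediately 5' of the read's alignment start (the standard iCLIP
truncation convention; reads starting at reference position 0 have no
upstream nucleotide and are dropped with an explicit count, preserving tag
conservation: truncation tags + drops = reads). A minority of reads read
through the crosslink and instead carry a deletion at the crosslinked
nucleotide; each CIGAR-deleted reference position contributes one deletion
tag. The two evidence classes are never mixed: binding profiles and region
proportions use truncation tags only, while the crosslinked-nucleotide
analysis uses the deletion fraction — among reads whose alignment spans a
position, the fraction whose alignment deletes it. Zero-coverage positions
are flagged undefined rather than reported as 0, and the across-sample
summary is the unweighted mean of per-sample fractions.

"Proportion of total hits" over a window is per-reference (window
truncation tags / reference truncation tags), so proportions over a
disjoint exhaustive partition of a reference sum to 1. Windows are
reported 1-based inclusive and converted once, at the interface, to the
0-based half-open convention used internally (`clipsplice.coords`
centralises every conversion). Whether per-position counts should be
library-scaled is an open analysis choice, so profiles emit both raw
counts and counts-per-million.

## Maximum-entropy splice-site models

A splice-site model is the maximum-entropy distribution over fixed-length
windows subject to matching the training set's marginals on a constraint
family. Windows follow the maxent framework's convention: donors are
9-mers (last 3 exonic + first 6 intronic nt), acceptors 23-mers (last 20
intronic + 3 exonic nt). The default constraint family is all
single-position marginals plus all adjacent-pair marginals. This is
deliberately not the full MaxEntScan constraint hierarchy (non-adjacent
subsets, fragment decomposition): scores here are used for *relative*
stratification, the chain family is exactly computable at desk scale, and
the simplification is recorded in every model's metadata.

Fitting: for enumerable spaces (4^9 donor windows) the distribution is
fitted by iterative proportional fitting (IPF) from a uniform start;
convergence is declared when the largest absolute marginal deviation
falls below 1e-6 (cap 500 sweeps). Because the single+adjacent-pair
family is decomposable, IPF converges essentially in one sweep. For
23-mer acceptors the same family admits the exact first-order Markov
chain factorisation p(x) = p(x1,x2) ∏ p(x_i,x_{i+1})/p(x_i), which is
used directly — no enumeration, with identical maximum-entropy semantics.

Smoothing: a Laplace pseudocount of 0.5 is applied per cell of each
*maximal* constrained subset (the adjacent pairs under the default
family); targets for contained subsets (the singles) are derived by
marginalising the smoothed pair tables. Smoothing each subset
independently would make the single- and pair-implied marginals mutually
inconsistent — ((c+0.5)/(n+2) vs (c+2)/(n+8)) — and IPF cannot converge
onto inconsistent targets; deriving contained targets restores exact
consistency while preserving the "0.5 per cell" smoothing intent.

A window's score is log2 p_signal − log2 p_background, with a uniform
background unless a decoy-trained model is supplied (the appropriate
background is itself an open choice; both are supported). Scores are
stratified as weak (< 3), intermediate ([3, 8], boundaries inclusive) and
strong (> 8). The thresholds are the conventional defaults for
human-donor maxent scores and are configurable because a re-trained
model's scale need not match any published scorer's. The score
distribution summary (histogram + Gaussian-KDE local maxima/minima, with
configurable bandwidth) is the diagnostic for the biphasic two-maximum
shape characteristic of bound 5' splice sites.

## Differential binding

Counts are normalised to counts-per-million; replicates are summarised by
mean CPM per condition. Fold changes are log2(cpm_case + c) −
log2(cpm_control + c) with pseudocount c = 0.5 (finite at zero counts;
computed as a difference of logarithms so that swapping case and control
negates the value bit-exactly). Sites with |log2FC| > 1 are selected as
up/down; features with combined raw coverage below 10 tags are dropped
before fold-change reporting to suppress noise-driven extremes. All
cutoffs are configurable.

Distribution shape is summarised by Fisher excess kurtosis on population
moments (m4/m2² − 3; appropriate at the large n of genome-wide fold-change
sets, with a bias-corrected flag for small samples) plus a seeded
1000-replicate bootstrap 95% CI. Note that "flatter with more mass in the
tails" relative to a sharply peaked distribution means *lower* excess
kurtosis: a uniform-like flattened distribution scores around −1.2 while a
Laplace-like peak scores +3.

Windowed region differences use a label-permutation test on per-sample
region proportions, statistic = mean(case) − mean(control). When the
number of distinct case/control assignments C(n, n_case) is at most
n_perm the test enumerates them all and the observed assignment counts
itself — the exact analogue of the add-one convention, guaranteeing p ≥
1/N and never 0; otherwise n_perm random relabelings are drawn with
p = (1 + #extreme)/(1 + n_perm). The default is two-sided by absolute
value. At very small group sizes the two-sided granularity is coarse: at
3v3 there are 20 distinct assignments and the mirror assignment always
ties the observed absolute statistic, so the smallest attainable
two-sided p is 2/20 = 0.1. When the direction of the effect is specified
in advance — as it is for a claimed *increase* of binding over a region —
the one-sided alternative (`alternative="greater"`) is the appropriate
test and attains p = 1/20 at 3v3. Calibration checks in the test suite
therefore use 5v5 groups (252 assignments), where the empirical type-I
error at α = 0.05 can actually reach its nominal value.

## Splicing events

PSI per sample is mean(inclusion-junction counts)/(mean(inclusion) +
skipping); events with zero total support are flagged undefined and
excluded downstream. PSI uses junction counts only — no effective-length
normalisation (a documented flag could add it; length normalisation
changes absolute PSI but not the group contrasts tested here).

Variability: per event, a two-sided variance-ratio F test
(F = var_case/var_control, df (n₁−1, n₂−1)); events with zero control
variance are flagged and excluded from the global summary with a logged
count. Globally, the two groups' per-event PSI standard deviations are
compared by an independent two-sample Student t test (Welch by flag).

Differential events: a binomial likelihood-ratio test of a common versus
group-specific inclusion proportion on counts pooled within condition
(χ², df = 1), BH-adjusted across events; an event is called at p_adj <
0.05 AND |ΔPSI| > 0.05 (both configurable). Limitation: pooling ignores
replicate-to-replicate biological variability, so under substantial
overdispersion the LRT is anti-conservative (at beta-binomial ρ = 0.05
and depth 100, ~46% of null events reach p ≤ 0.05). The test is
calibrated only under its own binomial sampling model (ρ → 0), which is
what the suite verifies; analyses of strongly overdispersed data should
rely on the effect-size filter and treat the p-values as a ranking. The
replicate-aware likelihood models of dedicated splicing tools are out of
scope here by design.

Cryptic classification is pure set membership: a junction is cryptic iff
its donor OR acceptor coordinate (strand-aware) is absent from the
annotated site sets; an event is cryptic iff any constituent junction is.

## Gene-set enrichment and composition

Fisher's exact test (two-sided) per gene set on the 2×2 table of
set-membership × selection, BH-adjusted across the sets tested within one
direction stratum; odds ratios use the Haldane 0.5 correction when a cell
is zero. The enrichment background is the detectable universe (boundaries
with minimum coverage), not all annotated genes, to condition on
detectability. Composition contrasts emit per-position base frequencies,
their differences and pseudocounted log-odds (both, since either is a
reasonable effect scale), plus aggregate thymidine/cytidine fractions
with bootstrap CIs over sequences.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *data shapes* the pipeline consumes, under a
single hierarchically split seed (one substream per consumer and sample;
byte-identical outputs under a fixed seed):

- **iCLIP reads**: crosslink positions drawn per read from a per-reference
  binding profile; the read starts one nucleotide 3' of the crosslink;
  reads spanning a designated crosslink nucleotide carry a 1–2 nt CIGAR
  deletion there with a set probability. Reads are emitted pre-aligned as
  SAM (references are short snRNA-scale sequences; alignment itself is not
  the subject here). The binding profile must put zero mass on the final
  nucleotide — a crosslink there leaves no room for a read — which keeps
  read-count conservation exact. Not modelled: sequencing errors beyond
  the crosslink deletion, PCR duplicates, UMIs.
- **Junction counts**: per event and sample, inclusion counts are
  beta-binomial with a condition-specific mean PSI and intraclass
  overdispersion ρ ∈ (0, 1) (latent PSI variance = μ(1−μ)ρ); totals equal
  the requested depth exactly.
- **Splice-site sets**: signal windows from a position-specific model hit
  a requested per-position information content (0–2 bits, consensus base
  probability solved by bisection); decoys are uniform.
- **Annotations**: multi-gene, alternating-strand toy loci with canonical
  GT…AG intron dinucleotides (strand-corrected) and planted junctions
  guaranteed absent from the emitted GTF.

Because the generators draw from exactly the models the estimators
assume, passing recovery tests demonstrates correctness of the
implementations and calibration under model conditions — not robustness
to the non-idealities of real libraries (crosslinking biases, mappability,
annotation incompleteness, overdispersion beyond the beta-binomial).

Default study-scale conditions used by the test-suite and the
reproduction script: a 106-nt U6-like reference; 8 samples × 50,000 reads
with per-read deletion probability 0.043 at (1-based) positions 64–65 for
the deletion-fraction recovery; 3v3 samples × 50,000 reads for the
planted 2-fold window-25–47 enrichment; 3v3 replicates, 200–500 events at
depth 100 for the PSI analyses; 50 genes × 5 exons with 20 planted
cryptic junctions for the cryptic caller. Where the replicate structure
is not dictated by the scenario, 2 replicates per condition is the CLI
default.

## Numerical and degenerate-input choices

- IPF tolerance 1e-6 on the max marginal deviation, 500-sweep cap; table
  models are enumerated up to 2^20 cells, larger windows require the
  chain family.
- Boundary maxent thresholds 3/8 map boundary values to intermediate.
- Constant score sets: the KDE summary degenerates gracefully to a single
  maximum; kurtosis of constant input raises (zero variance).
- Permutation p-values can never be 0 (add-one / observed-included
  enumeration).
- Zero-coverage deletion sites and zero-support PSI are undefined and
  flagged, never silently 0.
- Minus-strand windows are reverse-complemented; window extraction skips
  (with a logged warning) sites whose intron or contig cannot supply the
  full window.
- Tags equidistant between two boundaries are assigned to both, with the
  double-assignment count reported.
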