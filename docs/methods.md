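# Methods

This package re-implements, as a tested pipeline over synthetic data, a
bait-centric screen for genes that are both spatially associated with the
astrocyte marker locus *Gfap* (by enhanced circular chromosome conformation
capture, e4C, read out on a tiling microarray) and specifically expressed in
LIF-induced astrocytes (by spike-in-calibrated expression arrays), followed
by 3D DNA-FISH spatial-association statistics. Three cell states are
modelled throughout: neural precursor cells (NPC), NPCs differentiated with
leukemia inhibitory factor (LIF+), and extended NPC culture without LIF
(LIF−).

## e4C hit calling

Each array probe carries two channel intensities: the e4C capture sample
and a genomic-DNA control from competitive hybridization. The per-probe
statistic is

    log2((e4c + c) / (control + c)),

with a pseudocount c = 1 intensity unit guarding zero channels
(competitive-hybridization arrays have positive floors; with c = 0 a
double-zero probe raises instead of propagating NaN). Ratios are smoothed
over a 200-bp sliding window, interpreted probe-centrically: each probe's
smoothed value is the mean over all same-chromosome probes whose midpoints
lie within ±100 bp of its own. Probe-centred windows avoid committing to an
arbitrary genome-grid phase; a probe with no neighbours keeps its own
ratio. A probe is positive when its smoothed ratio is ≥ 2 (the cutoff is
inclusive so that the boundary case is deterministic), and an e4C hit when
it is positive in both biological replicates — replicates share the array
design, so reproducibility is identity of probe ids, not positional
overlap. Runs of adjacent hits merge into peaks with a merge gap of 0 bp
(the most conservative choice; configurable). Peak densities are reported
per chromosome as peaks per Mb, zero-filled.

## Peak-to-gene mapping

A gene is bait-associated when the gap between its body (TSS–TES span) and
any peak is ≤ 50 kb, with 0 for overlap. For reporting, the distance from
the nearest peak's midpoint to the closer of the gene's TSS or TES is
binned as <2 kb / 2–5 kb / 5–10 kb / 10–30 kb / >30 kb, from TSS or from
TES; bins are half-open and lower-inclusive, and a TSS/TES tie resolves to
the TSS (the anchor used for the promoter-motif analysis). Inclusion is
body-based while binning is anchor-based because the two serve different
purposes: inclusion asks "is this gene near a contact", the bin reports
"where relative to the transcription unit". A gene supported by several
peaks appears once, with its minimum distance. Distance enrichment
contrasts, per bin, the fraction of hit probes against the fraction of all
array probes at that anchor distance.

## Per-cell expression quantification

Absolute mRNA copies per cell are obtained Percellome-style: external spike
mRNAs at known copies per cell are present on every array, and each
sample's calibration is an ordinary least-squares line of log10 intensity
against log10 known copies (zero-dose spikes are excluded; at least two
distinct positive doses are required). Intensities invert through this line
to copies; zero intensity maps to zero copies. OLS on logs is the minimal
model consistent with dose-proportional spikes; the residual sd is kept as
a fit diagnostic. A gene is upregulated in a condition versus NPCs when its
copies are at least two-fold higher (inclusive) and its copy number in the
numerator condition is ≥ 1 copy per cell — the floor applies to the
numerator because a gene below one copy per cell is not considered
expressed, and this reading keeps published candidate rows with
sub-one-copy NPC values admissible. The denominator is guarded at 0.01
copies, far below any observed floor. Copies stay at full precision
internally and are rounded to two decimals only in formatted tables.

## Candidate integration and promoter scanning

Condition-exclusive association sets are computed as set differences
(e.g. LIF+-exclusive = associated in LIF+ and in neither other condition),
and the candidate table is the intersection of the LIF+-exclusive
association set with the LIF+-exclusive upregulated set, sorted by
LIF+/NPC fold descending. STAT3 promoter scanning slides a position weight
matrix over both strands of TSS ± 5 kb (symmetric, since neither direction
is privileged a priori; configurable) and flags the gene when any window
scores ≥ 0.8 of the PWM's maximum log2-odds score against a uniform
background — a fraction-of-maximum threshold is scale-free where no
absolute threshold is given. `N` bases score as background. The packaged
`stat3_like_pwm()` is a synthetic stand-in built from the canonical GAS
palindrome TTCnnnGAA and exists for tests and demonstrations only; real
analyses should load a curated matrix through the JASPAR reader.

## FISH association statistics

Within a nucleus, the association score for a gene pair is the minimum
Euclidean distance over all allele pairs; the pair is associated when that
distance is ≤ 500 nm, inclusive (the boundary must be fixed for
determinism). Nuclei missing a probe signal are dropped and logged —
hybridization dropout is routine. Frequencies across conditions feed a
chi-squared independence test with Haberman adjusted standardized
residuals,

    (O − E) / sqrt(E (1 − row/N) (1 − col/N)),

flagged at |z| > 1.96 and > 2.58 — the standard "residual analysis of
chi-squared" when per-cell significance is reported without a formula.
Allele-level analyses (active versus inactive bait alleles) call each bait
allele associated by its own nearest-partner distance and use Fisher's
exact test (two-sided by probability ordering; odds ratio
Haldane-corrected when a cell is zero). Distance distributions are
compared with the two-sample Kolmogorov–Smirnov test, exact when both
samples have ≤ 25 observations and asymptotic otherwise; nuclear diameters
with classical one-way ANOVA. The chi-squared/Fisher/KS/ANOVA machinery is
delegated to scipy.stats behind this module's interface (residuals are
computed here); the test suite checks each against an independent
enumeration or direct-arithmetic oracle.

## The synthetic study

The generator produces every input with known ground truth, at a scale
that runs on a desk: 3 chromosomes × 10 Mb of uniform-random sequence,
300 non-overlapping genes of 5–30 kb, and a probe array built by in-silico
double digestion — every maximal fragment running from a BglII cut
(AGATCT) to the nearest downstream NlaIII cut (CATG) with no intervening
cut, scanned on both strands, kept when longer than 100 bp (cut position =
the recognition site's 5′ coordinate; overlapping site occurrences all
count). Each qualifying fragment contributes one 60-bp probe anchored at
its BglII end. This yields ≈ 9,000 probes, about one per 3.3 kb.

The e4C signal model is additive Gaussian noise on the log2 ratio scale
(the simplest model matching a two-channel ratio readout): probes
overlapping a planted contact draw their ratio around 3 log2 units,
background probes around 0, with independent replicate noise of sd 0.5;
intensities are reconstructed as control × 2^ratio around a flat control
of 500. Planted contacts comprise (i) a cis cluster of 100 regions of
10 kb within ±1 Mb of the bait locus (mid-chr1), present in every
condition — near-bait cis signal dominates real 4C profiles, and this
cluster makes the bait chromosome the densest in peaks, as observed for
the chromosome encoding the bait in vivo; and (ii) condition-specific
contacts covering each planted gene ±20 kb. The planting plan samples
genes that are mutually separated by more than the peak-capture reach
(planted pad + mapping distance) and lie outside the bait cluster's reach;
without this, truth labels would contradict themselves, since a gene
within capture distance of another condition's planted contact genuinely
is associated there. By default 30 genes are planted as LIF+-exclusively
associated and 40 as LIF+-upregulated (30 exclusive + 10 shared with
LIF−), overlapping in 20 genes — the truth candidate set; NPC and LIF−
receive their own exclusive and shared contact sets so the Venn logic is
exercised.

Expression: true copies per gene are log10-normal (median ≈ 4 copies per
cell, sd 0.5 dex), identical across conditions except planted genes, whose
upregulated condition is multiplied by a five-fold effect (planted genes'
baseline is floored at 0.5 copies so the effect clears the one-copy
filter). Intensities are gain × copies (gain 50/copy) with multiplicative
log2-Gaussian noise of sd 0.25 — in the range of replicate variability
reported for expression arrays — clipped from below at a scanner floor of
5 units. Spikes at seven doses (0.3–300 copies per cell) pass through the
same model.

FISH: each nucleus is a sphere (the source data report only diameters)
whose diameter is drawn per condition from 10.4 ± 1.5 µm (NPC),
10.1 ± 1.1 µm (LIF+), 10.2 ± 1.2 µm (LIF−); signals are points, two
alleles per gene, uniform in the sphere. With the planted association
probability, one partner allele is instead placed uniformly within 500 nm
of a randomly chosen bait allele (rejection-sampled to stay inside the
nucleus). Chance proximity of uniform alleles adds a small positive bias
(≈ 0.4% per pair for a 10-µm nucleus at 500 nm) to recovered fractions.
In activity mode, bait alleles carry random-monoallelic active/inactive
labels and the planted partner anchors on the active allele.

All generators are deterministic given the configuration seed; independent
named substreams per generator keep outputs stable when one stage's draws
change.

## What the synthetic data does and does not show

The generator emulates the study's design constants, not its biology:
flat genomic-control intensities, independent Gaussian probe noise, a
single block-shaped interaction strength, dose-perfect spikes, spherical
nuclei and point signals. It omits probe GC/affinity effects, spatially
correlated array artefacts, digestion-efficiency differences between
conditions, overdispersed expression noise, and chromatin-scale distance
structure. Passing tests therefore demonstrate that the pipeline's logic
is correct and self-consistent and that parameters are recovered under
the stated noise model — not that the thresholds are optimal for real
arrays. The published genome-wide set sizes (hundreds of associated
genes per condition) require the deposited 1.4M-probe arrays and are out
of reach at this scale; the set logic is instead verified exhaustively
against brute-force oracles.

## Numerical choices and degenerate inputs

Coordinates are 0-based half-open (BED-compatible) everywhere. Boundary
comparisons are inclusive at the calling cutoff, the two-fold filter, the
50-kb mapping distance and the 500-nm threshold. Degenerate inputs raise
rather than warn: empty probe tables, double-zero channels at zero
pseudocount, calibration with fewer than two distinct positive spike
doses, contingency tables with a zero margin, ANOVA with zero variance
everywhere, nuclei below 1 µm. The KS p-value switches from exact to
asymptotic above n = 25 per sample. Fold ratios guard the denominator at
0.01 copies. PWM columns must be normalized to 1e-9.

## Problem sizes

Default test and acceptance runs use the 3 × 10 Mb / 300-gene study
(≈ 9,000 probes, 55,000 signal rows), 300 nuclei per condition for FISH
recovery, exhaustive Fisher enumeration to N = 60, and 1,000-replicate
null calibrations; the whole suite completes in about a minute on one
core.

## Known limitations

- The published candidate table contains printed fold values inconsistent
  with its printed copies at the second decimal for some rows (unrounded
  source values are unrecoverable); recomputation checks cover the
  internally consistent rows and the discrepancy is preserved as-is.
- The promoter scan's 0.8 fraction-of-maximum threshold and the synthetic
  GAS-palindrome PWM are conventions, not calibrated operating points.
- `integrate_candidates` takes its two exclusive input sets as given and
  does not re-derive exclusivity rules that could admit borderline rows.
- Condition labels ("NPC", "LIF+", "LIF−") are fixed strings throughout;
  the three-state design is assumed by the pipeline orchestration, though
  individual operations are label-agnostic.
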