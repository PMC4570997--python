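# Methods

This note documents the models, algorithms and numerical choices behind
`cladedelim`, and what its synthetic-data tests do and do not demonstrate
about real barcode surveys.

## Distances

K2P distances are computed under pairwise deletion: for each pair, a column
enters the comparison only when both sequences carry a plain A/C/G/T there;
gaps, N and all IUPAC ambiguity codes are treated as missing. With P and Q
the transition and transversion proportions over the m comparable sites,
d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q). Pairs with m = 0 or with a
non-positive log argument (saturation) get an undefined (NaN) distance;
such pairs are excluded from every summary, listed for QC, and are fatal
only where an operation genuinely needs a complete matrix (NJ).

Distances are held as fractions internally and printed as percentages with
one decimal, the standard presentation in barcode studies.

Histograms use a 0.005 bin width by default (0.002 is more appropriate for
gap detection on desk-scale simulations); an empty interval is only
reported when at least two consecutive internal bins are empty, which
suppresses single-bin artifacts of the discrete Hamming scale.

## OTU delimitation

### Refined single linkage

Three phases over the K2P matrix:

1. **Single linkage** at a fixed threshold (default 0.022). Links are
   strict (`d < t`): a pair at exactly the threshold is not linked, which
   makes edge cases deterministic. Undefined distances never link.
2. **Markov clustering** within each coarse cluster, at inflation values
   {1.4, 2.0, 2.8, 4.0}. The similarity transform is
   s_ij = max(0, 1 − d_ij / scale) with self-loops set to the column
   maximum before column normalization. The scale defaults to the linkage
   threshold itself: within a coarse cluster, pairs at or beyond the
   linkage scale should contribute no similarity, so the Markov flow
   re-examines exactly the structure that single linkage chained together.
   (A looser scale leaves near-threshold sister groups connected by
   mid-strength edges that the flow cannot cut.) MCL iterates expansion
   (squaring) and inflation (entrywise power + renormalization) to flow
   convergence; clusters are read off attractor rows, with a node claimed
   by several attractors assigned to the first — this resolves perfectly
   symmetric bridge sequences deterministically instead of leaving the
   clusters fused.
3. **Silhouette selection** among the coarse partition and all MCL
   candidates: highest mean s(i) = (b−a)/max(a,b) on the raw (unsquared)
   distances wins; members of singleton OTUs score 0; ties keep the
   earliest (coarsest) candidate.

OTU labels are deterministic: clusters are numbered by their
lexicographically smallest member id.

### Barcode-gap partitioning

For each prior maximal intraspecific distance P in the sweep
{0.001, 0.0017, 0.0028, 0.0077, 0.0129, 0.0215, 0.0359, 0.1}, the sorted
pairwise distances are scanned for the first significant gap whose upper
shoulder exceeds P. Significance is an operationalization (the original
recursion is not fully specified in the descriptions this follows): the
local spacing rate is the mean of the nonzero successive differences over
a trailing window of 10% of the pair count (at least 5; tied ranks carry
no slope information), and a jump is a gap when it exceeds
X · rate · (ln m + 0.5772), the relative gap width X (default 1.5) times
the expected maximum of m exponential spacings at that rate. Comparing
against the expected extreme rather than the mean is essential: the
maximum of m exponential spacings routinely exceeds 1.5× the mean, so a
mean-based rule finds "gaps" in structureless data. A jump off a pure tie
plateau (at least two tied values below, no spread) separates discrete
modes and is always a gap; fewer than five informative spacings below a
candidate are treated as insufficient evidence. The partition links pairs
below the midpoint of the detected jump; recursive partitioning re-applies
the same detection inside each group until no gap remains. With no
detectable gap the data are one OTU. At very low priors the method
over-splits haplotype clusters — the known and intended ABGD behaviour —
so analyses should read the partition count across the sweep's stable
plateau; the estimator default P = 0.0077 sits mid-sweep, between typical
within-clade diversity and the smallest between-clade distances.

A Jukes–Cantor metric toggle exists only as an alternative input matrix;
partitions on these data are insensitive to the choice.

### Concordance

Method agreement is summarized by OTU counts per method and pairwise
adjusted Rand indices (scikit-learn), which equal the closed-form
contingency expression to machine precision.

## Trees

NJ follows the Q-criterion with the Studier–Keppler update. Ties in Q are
broken by the lexicographically smallest pair of subtree representative
labels, making output deterministic; on any additive matrix the generating
topology and branch lengths are recovered exactly (property-tested to
1e−10 against randomly generated trees, and cross-checked against
scikit-bio's NJ). Negative branch lengths are retained internally —
preserving additivity — and floored at zero for display.

Bootstrap resamples alignment columns with replacement; replicate r uses
the r-th block of one seeded stream, so results are independent of
execution order. A replicate with an undefined distance is skipped and the
denominator adjusted. Supports are the percentage of kept replicates
containing each internal bipartition, matched via orientation-free
bipartition keys.

The calibrated-age estimator is a deliberate simplification: a strict
clock linearized on one calibration split. The per-lineage rate is
r = D_cal / (2 T_cal) with D_cal the mean between-side K2P distance; any
split's age is its mean between-group distance over 2r. It is
scale-invariant and transparent, and it will disagree with relaxed-clock
Bayesian estimates whenever rates vary among lineages — e.g. linearizing
the deep split between the two chimpanzee-louse lineages against a 6 Ma
calibration gives ≈ 4.1 Ma where a relaxed-clock analysis gives ≈ 2.4 Ma.
No age produced here should be read as a substitute for a full dating
analysis.

## Population genetics

Haplotype collapsing and all diversity indices use complete deletion (any
column with a gap/N/ambiguity in any sequence is removed first) — the
convention of haplotype software — which intentionally differs from the
pairwise deletion used for K2P distances.

k is the mean number of pairwise differences, π = k / analyzed sites,
Hd = n(1 − Σf²)/(n−1). Tajima's D uses the standard a₁…e₂ constants and is
NA when S = 0 or n < 4; it matches dendropy's implementation to 1e−9.
Fu & Li's D uses outgroup-polarized external (derived-singleton) mutation
counts η_e against total mutations η (alleles − 1 summed over sites); D*
uses unpolarized singletons with the corrected u*/v* constants. Both are
reported because the exact variant used by any given DnaSP run is rarely
stated; under neutral simulations the D statistics are centred near the
known slightly-negative null mean (≈ −0.07 at n = 20, verified against an
msprime-based oracle during development).

AMOVA is the standard three-level decomposition on squared pairwise
difference distances (groups = clades, populations = countries):
sums of squares from within-set averages, variance components via the
n′, n″, n‴ coefficients, Φ_CT = σ²_a/σ²_T, Φ_SC = σ²_b/(σ²_b+σ²_c),
Φ_ST = (σ²_a+σ²_b)/σ²_T. A level with a single unit yields NA for its
component; with every population its own group, Φ_SC is undefined and
Φ_CT = Φ_ST. Significance uses label permutations (default 1,000):
individuals across the whole structure for Φ_ST, individuals within their
group for Φ_SC, whole populations among groups for Φ_CT;
p = (hits + 1)/(perms + 1). Null calibration is property-tested: on
panmictic simulations with arbitrary labels the Φ_CT p-values are
indistinguishable from uniform (KS at α = 0.01).

The minimum spanning network includes an edge (u, v, w) iff w does not
exceed the minimax path weight between u and v on an MST by more than
epsilon; with epsilon = 0 this is exactly the union of all MSTs (ties
produce loops, as in standard network software).

## Host–parasite comparison

Panel divergences reuse the K2P machinery verbatim. Amino-acid
substitution counts translate with NCBI table 5 (invertebrate
mitochondrial) for lice and table 2 (vertebrate mitochondrial) for hosts;
a frame with internal stops is an error directing the user to the
translation QC, which auto-detects the frame minimizing stops. Host
mitogenome records are sliced to a gene window by an exhaustive ungapped
offset scan against a reference sequence (first best match on ties —
deterministic). The known chimera accession AY316793 ships in the default
exclusion list; `flag_contaminants` generalizes that filter with a 0.30
minimum-distance ceiling, far above intraspecific maxima and far below a
cross-family contaminant.

## Synthetic data

The generator composes three standard pieces: an ultrametric backbone over
clades (caterpillar topology; default split depths 0.0115, 0.02, 0.035,
0.0515 substitutions/site, i.e. tip-to-tip clade separations of 2.3–10.3%
matching the observed spread of between-clade distances), a neutral Kingman
coalescent within each clade (waiting times Exp(C(k,2)); branch lengths
scaled by θ/2 so a pair of tips is separated by θ in expectation), and K80
evolution (closed-form transition probabilities; α + 2β = 1 so branch
lengths are expected substitutions/site; default κ = 4). Each clade
genealogy's height is absorbed into its backbone branch, so the stated
split depths are the expected tip-to-tip separations — the quantity the
NN-distance checks use. K80 (rather than a richer model) is deliberate:
the generator exactly matches the K2P estimator's model, making parameter
recovery a clean correctness surface.

θ defaults to 0.001/site. Real louse clades are expansion-shaped — one
dominant haplotype at 57–98% frequency and strongly negative Tajima's D —
so a constant-size coalescent cannot match both their mean diversity and
their maximum intra-clade distances at once; the default is set to
reproduce the observed *maximum* intra-clade distances (realized
0.5–1.1% per clade, against observed per-clade maxima of 0.7–1.9%),
because that upper tail, not the mean, is what stresses delimitation.
Country labels are nested within clades: one dominant country per clade
(fraction 0.8) plus minority countries, echoing the geography of real
surveys. Per-clade RNG sub-streams derive from one seed; identical seeds
give byte-identical datasets.

What passing tests show — and don't. The simulations demonstrate that the
delimiters recover truth when clades are coalescent clusters separated by
a backbone of the observed depth, that the distance estimator is unbiased
under its own generating model, and that the AMOVA permutation test is
calibrated under a true null. They do not demonstrate robustness to
demographic expansion, rate heterogeneity across sites, indels, alignment
error, or contamination — real-data features the generator deliberately
omits (expansion in particular makes real clades *easier* to delimit than
the neutral-coalescent clades simulated here, since it concentrates
haplotypes and shrinks the intra-clade tail).

## Problem sizes

Default test and acceptance runs use 5 clades × 20 sequences of 658 nt
(the scale at which every distributional feature of interest — the
bimodal histogram, the gap, the NN structure — is already present), 50
replicates for delimitation power, 500 neutral simulations for the
Tajima's D null (its Monte Carlo error must sit well inside the ±0.15
acceptance band), 200 simulations × 99 permutations for AMOVA calibration,
and 10 kb pairs for distance-estimator accuracy. These sizes were chosen
so the full suite characterizes the statistics sharply while remaining
desk-scale.

## Known limitations

* The ABGD gap-significance rule is an operationalization; exact partition
  counts at extreme priors will differ from the original web
  implementation (partition counts across the sweep's plateau are the
  robust output).
* The internal MCL parameters of the production BIN/RESL system are
  unpublished; `ReslConfig` exposes ours.
* The strict-clock age estimator ignores rate variation (see above).
* Fu & Li significance thresholds (the tabulated critical values) are not
  reimplemented; the statistics are reported raw.
* AMOVA assumes the squared-difference distance; other distances can be
  supplied as a precomputed matrix but are the caller's responsibility.
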