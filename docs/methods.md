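# Methods

`motuforge` implements the analysis chain used to validate a DNA-barcode
reference library for a regional fish fauna: distance-based barcode-gap
assessment, four independent DNA-based species delimitations, a
majority-rule consensus against morphological species, and
sampling-completeness curves.  A coalescent-within-Yule sequence
simulator with known truth ties every stage to a testable expectation.

## Distances and the barcode gap

Pairwise distances use the Kimura 2-parameter model: with P and Q the
transition and transversion proportions among the m jointly resolved
sites of a pair,

    d = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q)).

Sites with a gap, an N, or any other IUPAC ambiguity in either sequence
are excluded pair by pair (pairwise deletion), which maximises the
usable sites per comparison.  Cells where the logarithm domain fails are
flagged as saturated (NaN), excluded from every summary with a logged
count, and imputed with the matrix maximum only where tree building
requires a complete matrix.  Output tables round distances to four
decimals.

Per species the package reports the maximum conspecific distance
(undefined for singletons), the nearest-neighbour (NN) distance — the
minimum over all heterospecific pairs involving the species — the
species attaining it, the NN/max-intra fold ratio (only where max-intra
is positive), and a boolean barcode gap (NN > max-intra).  Rank-level
summaries pool pairwise distances within species, among species within
genera, and among genera within families.  Two poolings are emitted side
by side: *exclusive* (the three pools are disjoint: conspecific pairs do
not enter the genus pool, congeneric pairs do not enter the family pool)
and *inclusive* (lower-rank pairs are retained, which drags genus- and
family-level minima toward zero).  Published summary tables do not
always state which pooling they use, so both are first-class outputs.
The standard error reported is the pooled-distance standard deviation
divided by the square root of the pool size.

## Trees

The metric tree for PTP is neighbour joining on the K2P matrix
(scikit-bio's Saitou–Nei implementation; negative branch-length
estimates are clamped to zero), midpoint-rooted.  The ultrametric tree
for GMYC is UPGMA (average linkage; node height = half the merge
distance); an externally inferred chronogram in Newick can be supplied
wherever an ultrametric tree is accepted, and a helper converts
substitutions/site to million years at the conventional COI clock of
1.2% pairwise divergence per Myr for reporting.  Bayesian or
maximum-likelihood tree inference is deliberately out of scope; the
delimitation results are therefore tree-input-sensitive and the tree
counts from UPGMA/NJ stand-ins should be read as approximations of what
a dated Bayesian tree would give.  Sequences identical at all jointly
resolved sites are collapsed to haplotypes before tree building (first
id in input order represents the group; identity with missing data is
not transitive, so each sequence joins the first representative it
matches), and all partitions are re-expanded to the full sequence set
before being returned.

## Delimitation

**SLC** — single-linkage clustering at a 2.2% threshold, the
conventional barcode seed threshold.  This is an explicit stand-in for
the proprietary Refined Single Linkage behind BIN assignment and is
always labelled SLC, never BIN.  An optional refinement pass splits a
cluster at its widest internal gap when the split's mean silhouette
exceeds 0.25; it is off by default because the plain threshold is
transparent and the refinement heuristic is not the published algorithm.

**ASAP-style ranking** — candidate partitions are the levels of the
single-linkage dendrogram.  Each merge is scored for panmixia against
the pooled scale of the merges made so far: a merge whose height jump
(h − h_int) is large relative to the running mean merge height (plus the
distance quantum, the smallest positive pairwise distance ≈ one
substitution) gets p = exp(−(h − h_int)/μ) ≈ 0, i.e. it bridges a
barcode gap.  A partition inherits (i) the p of the merge that would
destroy it (low is good), and (ii) a veto: because single-linkage levels
are nested, any rejected merge (Bonferroni-adjusted running minimum
below 0.05) is lumped by every coarser partition, which is then ranked
after all non-vetoed candidates.  The relative gap width W divides the
gap between the partition's largest intra-group distance and the next
pairwise distance by the mean spacing of the distinct distance values in
a ±25-value window, so a wide gap in a sparse region of the distance
distribution earns little.  The asap-score is the mean of the p-rank and
the W-rank; the published method's exact constants are not public, so
every rule is logged in the per-partition notes.

**PTP / mPTP** — on a rooted metric tree, a delimitation is an antichain
of crown nodes covering all leaves; edges above the crowns follow a
speciation exponential, edges below follow one shared (single-rate) or
per-species (multi-rate) coalescent exponentials.  Rate MLEs are closed
form, so the greedy crown-flipping search with seeded
simulated-annealing restarts (default 10) evaluates states in O(1).
Branches below 1e-4 substitutions/site carry no usable length signal and
are excluded from the likelihood (the same reasoning as mPTP's `minbr`);
zero-length branches are perturbed to 1e-8 first.  Single vs multi rate
is chosen by AIC.  Because the partition is itself searched, the naive
likelihood-ratio test against the one-species null is strongly
anti-conservative; the decision is therefore made by parametric
bootstrap: branch lengths are redrawn from the fitted null exponential
on the same topology, the search is re-run on each of 39 replicates, and
the Monte-Carlo p-value of the observed likelihood gain is compared with
alpha = 0.05.

**GMYC / mGMYC** — on a rooted, binary, ultrametric tree (checked to a
1e-6 tolerance; equal node ages are separated by a seeded 1e-10 jitter),
a threshold age T classifies nodes older than T as Yule speciation
events and younger nodes as coalescent events within the clusters cut
out by T.  Conditioning on the root, each inter-node interval
contributes an exponential waiting time with pooled rate
λ_yule(n_yule^p_yule − 1) + λ_coal Σ_k n_k(n_k − 1)^p_coal.  The λs are
profiled per candidate and the exponents fitted by Nelder–Mead
(warm-started along the scan), so an exhaustive scan over all node ages
is cheap and the reported optimum is a true maximum over candidates.
The multiple-threshold mode greedily promotes cluster roots to
speciation events while AIC improves (one extra parameter per added
threshold).  The likelihood-ratio test against the single-coalescent
null uses the 50:50 chi-square(df)/chi-square(df+1) mixture with
df = n_params − 2; when it does not reject at 0.05 the one-species
partition is returned.

## Consensus and conflicts

Two sequences share a consensus MOTU when they co-occur in more than
m·(number of schemes) input partitions (default m = 0.5); an exact tie
yields no edge, leaning toward splitting, which is the conservative
choice when flagging candidate cryptic lineages.  Morphological species
labels vote as one scheme by default; a flag excludes them for a
strictly molecular consensus.  Consensus MOTUs are connected components;
intransitive components are kept whole but counted.  The conflict report
classifies each species as match, split (members in >1 consensus MOTU)
or lump (its MOTU holds >1 species); in the pathological case where a
species is both, split takes priority so the three categories partition
the species exactly.

## Accumulation curves

Expected richness versus sampling effort is estimated by randomising the
sequence order (default 100 permutations, seeded) and averaging the
running distinct-label count, with empirical 2.5/97.5 percentile bands.
A curve is declared plateaued when the mean richness gained over the
last 10% of the effort falls below 0.01 labels per sequence — a
programmatic stand-in for the visual judgement usually applied to such
curves.

## The simulator and what it does (not) show

The generator draws a Yule tree over species, rescales it so the root
sits at `crown_depth`/2 (default 0.30 deepest pairwise divergence,
family-level scale) and floors shallow splits at `stem_scale`/2 (default
0.05 minimum between-species divergence, giving the easy preset its
barcode gap); grafts a Kingman coalescent under each species tip scaled
so the expected conspecific pairwise divergence equals `theta` (default
0.0036); and evolves 652-bp sequences by closed-form K80 transition
probabilities (kappa = 8, a low-divergence transition/transversion ratio
of about 4, typical of fish COI).  Sequences per species follow a
truncated geometric on 1..23 with mean 4.  Genus and family labels come
from fixed divergence cuts of the species tree (6% and 12.5%).  Because
the generative substitution model equals the distance model, the K2P
estimator is exactly matched and distance expectations are analytic.

Feature injection edits a simulated library post hoc.  A cryptic split
takes the two deepest clades of one species' genealogy and applies one
shared K80 substitution pattern to one clade, sized so the realized
between-clade divergence is approximately the requested depth (default
0.086); nominal (morphology-like) labels keep one species while the
molecular truth records two.  A shallow pair regroups the target
species' sequences around the first member's nearest relatives and
shifts that group by the remainder to the requested divergence (default
0.008), relabelling it as a genuine sister species.  A singleton prunes
a species to one sequence.  The stored genealogy is not re-estimated
after injection.

What the simulator does not emulate: alignment gaps and ambiguity codes
(sequences are clean, so pairwise deletion is exercised only by unit
fixtures), rate variation across sites, selection, introgression,
geographic structure within species, and sequencing error.  Passing
recovery tests therefore show that the methods work when their model
assumptions hold at realistic parameter values — not that they are
robust to real-data artefacts.

Realized divergences fluctuate around their expectations: a species pair
floored at 5% expected divergence occasionally realizes near or below
the 2.2% threshold at 652 bp (shared-stem Poisson noise), so occasional
lumping by SLC/ASAP on the easy preset is expected behaviour, which is
why the recovery criteria are medians over seeds.

## Problem sizes and defaults

Default analysis conditions: 20 species, ~80 sequences (easy preset).
The validation suites use 50 seeds for recovery and feature-injection
rates and 100 replicates for null calibration; `scripts/acceptance.py`
reports the same quantities from 15 recovery/feature seeds and 20 null
replicates, sizes chosen to give stable medians and rates for a quick
reproduction run.  All randomness flows from a single seed per run,
recorded in the pipeline manifest together with input digests, stage
record counts and per-stage timings, so a manifest suffices to re-run a
pipeline identically.

## Known limitations

* RESL and ASAP are re-derivations from their published descriptions,
  not ports; their counts on real libraries are approximate.
* PTP and GMYC operate on NJ/UPGMA stand-in trees unless the user
  supplies better trees; counts inherit that approximation.
* The GMYC multiple-threshold greedy adds thresholds only at current
  cluster roots, a restriction of the full per-lineage threshold space.
* Haplotype collapsing with missing data is order-dependent (first-match
  rule); with clean simulated data this has no effect.
* `ReferenceLibrary` requires at least one record; taxon-coverage tables
  are only defined for non-empty libraries.
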