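# Methods

This note documents the models implemented in `mitophylo`, the defaults
chosen where the design was open, and what the synthetic-data tests do
and do not demonstrate about real data.

## Variant nomenclature and scoring

Variants are scored by direct comparison of pre-aligned, equal-length
sequences against the reference; the toolkit deliberately contains no
aligner, because mtDNA practice names mutations at fixed reference
coordinates. Labels follow the PhyloTree convention: uppercase derived
allele = transition, lowercase = transversion, `d` suffix = deletion,
`.k` = insertion ordinal. The parser is strict: a label whose case
contradicts its base pair (e.g. `G3T` for a transversion) is rejected
rather than silently reinterpreted, and heteroplasmy codes are
unsupported. `N` masks a site on either side; any other ambiguity code
is an error, not a guess. Coordinates are 1-based closed intervals; an
`N` in the reference itself (the spacer convention at position 3107 of
the human references) is excluded from scoring automatically.

The annotation is total: every position carries exactly one of six
labels (control, rRNA_tRNA, codon1/2/3, other). Protein-coding intervals
declare their reading frame (`gene:NAME` rows in the BED-like input,
0-based half-open, converted internally), from which codon positions and
synonymous status follow; synonymous calls substitute the derived allele
into the reference codon and translate both under the vertebrate
mitochondrial code. Control-region bounds for real mitogenomes default
to 16024–16569 ∪ 1–576 and are configurable.

## Tree construction

Published mtDNA haplogroup trees are curated by hand. The builder
formalizes that practice as a deterministic, reproducible surrogate:
each distinct variant is a binary character; characters are laid down in
order of descending weight, then descending carrier count, then
position; each profile's ordered character list becomes a root-to-tip
path and the paths are merged into a tree. Consequences:

- A conflict-free matrix yields the unique perfect phylogeny, including
  hard polytomies (basal radiations stay unresolved rather than being
  arbitrarily dichotomized).
- Under conflict, the minority character recurs on several edges as a
  repeat event; the total event count is therefore at least the number
  of distinct characters, with equality exactly in the conflict-free
  case. For a single conflicting character this greedy resolution
  attains the exhaustive parsimony minimum (verified against full
  topology enumeration in the tests); with many interacting conflicts it
  is a heuristic, which mirrors its role as a stand-in for manual
  curation. General heuristic MP search (ratchet, TBR) is out of scope.
- The weight table is configuration, not canon: known hypermutable sites
  (in real data, positions such as 152 or 16311) can be down-weighted so
  they do not distort the backbone.

`parsimony_score` is a separate exact primitive: per-site minimum-change
counting by dynamic programming over states (unit costs, arbitrary node
degrees, additive over sites, root state free). It is used to audit the
builder and is tested against brute-force enumeration of internal state
assignments on small instances.

Clade naming is automatic and deterministic: the root clade gets the
user's root name; children receive letter/digit suffixes on alternating
levels, ordered by descending subtree size then lowest defining
position. Because size order need not match any external labelling,
truth comparisons in the tests locate clades by their defining motif
(`node_for_variants`), never by name equality.

## Haplogroup assignment

A profile is scored against every named clade over the sites its
coverage can actually see: (motif-chain variants observed) − (expected
but absent). The maximizing clade wins, ties go to the shallower clade,
and a profile covering no motif site at all is `unassigned` — the same
outcome the basal "unlabelled single lineage" samples of real surveys
receive. The report lists matched, missing and extra variants so a
curator can audit each call. Control-region-only profiles are assignable
exactly when the relevant motifs contain control-region positions, which
real haplogroup motifs almost always do; the synthetic generator
reproduces this by placing at least one control-region variant per
motif.

## ρ dating

ρ is the mean number of mutations from a clade's root to its tips,
computed edge-wise as Σ m_e n_e / n; the standard error is the
Poisson-model estimator σ = √(Σ m_e n_e²)/n. Both accept a mutation
filter (all sites vs synonymous-only; synonymous ρ can never exceed
all-site ρ). Calibration divides by μ·L of a clock model:

- `complete`: μ = 1.6865e-8 substitutions/site/year — the arithmetic
  mean of the two published whole-mtDNA rates 1.665e-8 and 1.708e-8 —
  over L = 16,569 sites.
- `synonymous`: rate and effective length are external calibration
  inputs (they live in the published calculator, not here), so they are
  config entries with no baked-in default.
- Any clock carries a monotone correction function (identity by
  default). Because the published purifying-selection/nonlinearity
  correction is defined by an external calculator rather than a closed
  formula, it is deliberately *not* reinvented: a strictly increasing
  piecewise-linear table (two-column TSV through (0,0), linear
  extrapolation beyond the last knot) lets the published curve drop in
  verbatim. The same object rescales skyline time axes, so ages and
  skylines can never disagree about the correction.

Confidence intervals map ρ ± 1.96σ through the clock and correction,
floored at zero. σ is propagated to years through the linear part of the
clock only (delta method); the correction is applied to the point and
interval endpoints, not to σ. Clade-age comparisons use
z = (t_a − t_b)/√(σ_a² + σ_b²) against the standard normal — the
practical reading of the informal "t-test" used for such contrasts —
and the implementation labels it as a normal z-comparison.

Calibration behaviour, measured by the acceptance script on 200
simulated star clades of true age 18,600 y with 30 tips each at the
complete clock (λ ≈ 5.2 mutations per lineage): the mean ρ-based age is
within Monte-Carlo error of the truth and the nominal-95% interval
covers it ~93–95% of the time. The corresponding clade-age contrast
experiment (18 ky vs 10 ky, n = 30 each, 100 replicates) yields
p < 0.001 in roughly 85–90 replicates; that is the *statistical power*
of the design at these sample sizes (analytically ≈ 0.87), not an
implementation artefact — larger clades separate essentially always.

## Skyline post-processing

Skyline exports are validated on read: required columns named on
absence, non-numeric rows and HPD bounds that fail to bracket the median
rejected with line numbers, strictly increasing time grid, positive N_e.
Corrections map the time grid pointwise and never touch N_e; applying f
then g equals applying g∘f. Plotting is intentionally out of scope —
the corrected TSV is the product.

## Spatial statistics

Frequencies are simple per-population carrier percentages; a sample
counts toward a clade when assigned to it or any of its descendants
(passed explicitly, since letter names alone cannot express tree
structure). Populations sampled below a configurable floor (default
n < 5) are flagged rather than dropped. Gene diversity is Nei's
unbiased H.

Kriging is ordinary kriging: at each grid node the weights solve the
semivariogram system with the Lagrange unbiasedness constraint
Σw = 1, making the interpolator exact at data points when the nugget is
zero. Distances are great-circle (haversine, km) for geographic data;
a planar metric exists for synthetic grids and makes translation
invariance exactly testable. Variogram models: spherical, exponential
(practical range), linear; fitting is weighted least squares on a
binned empirical semivariogram with pair counts as weights (10 bins by
default). The original maps' software defaults are unknown, so every
variogram parameter is explicit configuration and the fitted values are
logged; surfaces are comparable to published maps qualitatively, not
numerically. Predictions are clipped to [0, 100] % and clipping is
logged. Duplicate coordinates with conflicting values are an error; a
singular system suggests adding a nugget.

## Synthetic data

The generator emulates the structure of a continental haplogroup
survey: a root motif shared by all carriers, major branches with their
own motifs and TMRCAs, basal lineages attaching directly to the root (a
hard polytomy, so basal samples are generated on a star genealogy), and
populations with coordinates and region-dependent clade composition.
Defaults: a 2,000 bp reference (400 bp control region, one 1,200 bp
protein gene, rRNA/tRNA filler); 12 populations × 25 samples across
four regions; three clades aged 18,000 / 10,000 / 6,000 years with an
old widespread branch, a younger Europe-biased branch and a
region-specific branch plus basal remainder; root age 18,600 y; 38% of
samples reduced to control-region-only coverage; Kingman genealogies
within clades rescaled to their TMRCA; Poisson mutations at
μ = 2.5e-8/site/year with 20:1 transition:transversion odds.

Two deliberate realism choices:

- μ is kept at the whole-mtDNA *per-site* scale even though the genome
  is compressed 8-fold. Per-site substitution probability is what
  controls homoplasy (recurrent and back mutation at motif sites), and
  inflating it fragments motif edges in ways real mitogenome data does
  not show; the price is proportionally fewer private mutations per
  lineage on the small genome.
- Clade motif sizes are design constants (emulating the defining-motif
  tables of real surveys), not clock draws. Stem branches of the
  default cohort are therefore longer in mutation units than the clock
  implies, so ρ-dating the default cohort's root overestimates its age
  by construction. Clock-consistent dating experiments use
  `simulate_clade`, where every mutation is a clock draw on a
  mitogenome-length reference.

What passing tests show: the estimators are unbiased and correctly
calibrated under their own model (Poisson clock, ultrametric
genealogies, pre-aligned sequences), assignment recovers generating
branches under realistic homoplasy, and the machinery is deterministic
given a seed. What they do not show: robustness to alignment error,
sequencing artefacts, rate heterogeneity beyond the partition scheme,
or selection — real-data phenomena the generator does not model.

## Numerical and degenerate-input choices

Poisson edge counts are truncated at the number of mutable sites (an
edge cannot carry more distinct variants than sites). Kriging grid
nodes coinciding with observations use a zero semivariance to the
coincident point, making exactness hold to machine precision. Empty
clades, empty interval sets, zero joint variance in age comparisons,
non-monotone correction tables, and annotation gaps are all hard errors
rather than warnings. All randomness flows through
`numpy.random.default_rng` seeded explicitly; the CLI derives every
stage's seed from one master seed, and identical configuration plus
seed reproduces outputs byte for byte.

## Problem sizes

The shipped test suite and acceptance script use: 100 random parsimony
instances (≤7 leaves, ≤12 sites) against exhaustive enumeration; 40
conflict-free matrices for perfect-phylogeny recovery; 200 star clades
(30 tips) for calibration and coverage; 10⁵ Poisson resampling
replicates for the σ check; 100 replicate pairs for the age contrast;
three 300-sample cohorts for assignment rates. These sizes make the
Monte-Carlo error small relative to every tolerance tested while the
whole suite runs in well under a minute.
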