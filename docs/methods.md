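# Methods

This note documents the models and conventions behind `saprolens`, the
choices made where field practice is genuinely open, and what the
synthetic-data tests do and do not demonstrate.

## Enumeration

A Sedgwick-Rafter cell holds 1 mL over a 1000-square grid. Counting `C`
organisms in `N` squares of a `V_C` mL concentrate prepared from a `V_T` mL
grab gives `ind mL⁻¹ = C·V_C·1000 / (V_T·N)`; concentrations are stored per
litre (×1000) from ingestion onward and never mixed across units. The
chamber constant 1000 is exposed as `total_squares` because the formula
generalises to other chamber geometries. A zero count is reported as 0 —
no detection-limit censoring — matching how plankton surveys treat
absences. No subsampling-error model (e.g. Poisson confidence intervals)
is attached to point concentrations; the synthetic count-sheet generator
is the place where Poisson counting error is modelled explicitly.

## Biovolume and biomass

Each taxon is assigned one of five solids with fixed full dimensions
(µm, diameters rather than semi-axes): sphere `π/6·l³`, oval (prolate
spheroid) `π/6·l·w²`, ellipsoid `π/12·l·w²`, cone `π/12·l·w²`, cylinder
`π/4·l·w²`. Two conventions deserve comment. First, a "spherical" cell is
described by its diameter `l` alone; the cubic exponent follows from
dimensional analysis. Second, the ellipsoid class is defined with a
flattened third axis of half the width (`1/6·π·l·w·(w/2)`), which makes it
numerically identical to the cone; both tokens are nevertheless kept
distinct so registries remain faithful to their sources. At equal `l = w`
the solids order cylinder > sphere = oval > cone = ellipsoid by their
coefficients.

Dry weight uses a fixed density of 0.524 pg µm⁻³ (a standard protist
conversion; overridable via `BiomassParams`), and biomass concentration is
abundance × per-cell dry weight, reported in µg L⁻¹. Morphology is one
fixed (length, width) pair per taxon from the registry — per-sample cell
measurements are rarely published — so biomass inherits that
approximation. No fixation-shrinkage or carbon-content corrections are
applied.

## Community indices

Richness counts strictly positive taxa. Shannon diversity is reported as
the positive quantity `−Σ pᵢ ln pᵢ` in natural-log units. Dominance
follows the frequency-weighted convention `(nᵢ/N)·fᵢ` with `nᵢ` the
taxon's total abundance over a declared sample collection (whole campaign
by default, per site on request), `N` the grand total and `fᵢ` the
occurrence frequency; the conventional threshold 0.02 is inclusive at the
boundary. Summaries report the arithmetic mean and *sample* standard
deviation (n−1) of per-sample totals and index values — sources seldom
state their SD convention; this matches the usual "±" reporting — plus
pooled indices of the level's mean profile, which is how campaign-level
community figures are usually quoted.

## Saprobity

The Pantle–Buck index is the abundance-weighted mean valence
`SI = Σ Sᵢhᵢ / Σ hᵢ` over taxa that carry a saprobity code; it is
invariant to uniform rescaling of abundances and bounded by the extreme
contributing valences. Classification uses seven contiguous half-open
bands `[lower, upper)` covering [1.0, 4.0), lower-inclusive exactly as the
band scheme prints them ("1.0 to < 1.5").

The valence table is data, not code. The bundled default maps the
code-level scale o→1.0, o-b→1.5, b→2.0, b-a/a-b→2.5, a→3.0,
a-p/p-a→3.5, p→4.0, with o-a→2.0 (a wide-tolerance form centred on
β-mesosaprobic) and the transitional forms p-i and p-m→3.5 (poly-leaning;
flagged in the config file as deliberate, overridable choices). Unknown
codes raise rather than being silently skipped, and every result carries
the number of classified taxa and the classified fraction of abundance so
that users can judge representativity. Species-level literature valences
can be supplied via `species_overrides`. Two aggregation modes are
provided because survey software differs silently on this point: SI of
the group's mean abundance profile (default) and the mean of per-sample
SI values; they coincide for single-sample groups.

On the bundled study fixture the generic code-level valences compress the
between-site SI range relative to the survey's published per-site values,
which were produced from monthly raw data and species-level valences that
are not public; the bundled fixture supports the band-level conclusions
(all sites critically loaded, site IV cleanest) rather than exact
reproduction of the published per-site index values.

## Multivariate procedures

Abundances are square-root transformed before dissimilarity computation
to damp the influence of very abundant taxa; the transform is recorded on
the matrix and a second application raises. Dissimilarities: Euclidean;
Bray–Curtis `Σ|x−y|/Σ(x+y)` (bounded in [0, 1]; an all-zero pair is
defined as 0 and flagged); and normalised Euclidean (per-variable
z-scores, sample SD). Ward clustering uses the Lance–Williams update on
the supplied distances; merge heights are non-decreasing for
Euclidean-compatible input, and partitions at every step agree with an
exhaustive agglomeration that minimises the within-cluster sum-of-squares
increase (verified by a brute-force oracle in the tests). Similarity-level
cuts define similarity against the final merge height,
`100·(1 − h/h_max)` — the convention of the originating survey software is
undocumented, so this definition is fixed and stated here.

RELATE computes the Spearman correlation of the two condensed
(row-major upper-triangle) distance vectors; the null distribution
relabels one matrix's samples jointly in rows and columns, and the
one-sided p-value is `(1 + #{ρ_perm ≥ ρ_obs}) / (n_perm + 1)` with a
10⁻¹² tolerance so permutations tied with the observed statistic count
(small label sets produce exact ties that float noise would otherwise
drop). The default 999 permutations give 0.001 resolution. BIOENV fixes
the biotic dissimilarity (Bray–Curtis on square-root abundances by
default) and rank-correlates it against the normalised-Euclidean
dissimilarity of every environmental-variable subset up to `k_max`
(guarded at 10⁶ subsets), returning the ranked list; with `k_max = 1` it
reduces to the best single-variable Spearman correlation. These
biotic/environmental metric choices follow the documented defaults of the
PRIMER family of routines and are parameters, not assumptions baked into
the code. Log-transformation of environmental variables is left to the
caller (variables are standardised in any case).

## Synthetic campaigns

The generator emulates a balanced 6-site × 12-month survey of 54 species
(phylum mix 10/4/4/5/1/30). Log mean abundances are drawn from a normal
with SD 1.4, chosen so the top ~7 species carry ~55–60 % of total
abundance — the "few species dominate" pattern of real plankton
communities. Expected abundance of species *i* in sample *s* is

    λ_is = exp(μ_i + site_i(s) + A_i·sin(2π·month/12 + φ_i) + β_i·g(site))

thinned by per-species occupancy (0.25–1.0, rising with base abundance)
and multiplied by lognormal noise (log-SD 0.6, i.e. typical month-to-month
count variation of ±80 %). Saprobity codes are assigned to half the
species with probability rising with abundance — indicator lists cover the
common taxa first; in the emulated study every dominant ciliate carries a
code — and the gradient coupling is `β_i = strength·(S_i − 2.5)/1.5`, so
pollution-tolerant taxa rise along the planted gradient and the site-level
saprobic index tracks it. The default strength 2.0 spans 4 log-units
between the valence extremes, a strong organic gradient along which
sensitive taxa all but vanish. Environmental variables are deterministic
functions of the gradient (planted drivers; Gaussian noise SD 0.1),
season (temperature), or pure noise.

The generator is a single seeded NumPy stream per campaign: identical
seeds give byte-identical outputs. What passing recovery tests show: under
a strong planted gradient the pipeline's site saprobic indices rank-order
the sites correctly (Spearman > 0.9) in ≥ 95 % of replicates, BIOENV's
top subset contains the planted driver in ≥ 90 %, and RELATE's type-I
error under a decoupled null campaign is 5 % within binomial error. What
they do not show: robustness to taxonomic misidentification, detection
non-linearity at high densities, temporally autocorrelated noise, or
unbalanced designs — none of which the generator models.

## Problem sizes and numerical choices

Fixture-based checks run on the bundled 54 × 6 tables in milliseconds.
Simulation suites use 100 replicates of the full 72-sample campaign for
gradient and driver recovery, and 500 replicates of a reduced 24-sample
null campaign with 199 permutations for the type-I check — sizes at which
the binomial error of the measured rates is well inside the asserted
bands. Distances and ranks are double precision throughout; Ward
tie-breaks follow label order (continuous data make exact ties
probability-zero); CSV round-trips write 17 significant digits and parse
with round-trip float precision, so write-then-read is exact.

## Known limitations

- The bundled species table's per-site cell placements are partly
  reconstructed from marginal totals (see the data file's
  `site_assignment` and `note` columns); row averages and all
  campaign-level quantities are unaffected.
- Generic code-level valences cannot reproduce index values computed with
  unpublished species-level valences; supply overrides for that purpose.
- One fixed morphology per taxon; no per-sample size structure.
- BIOENV is exhaustive by design; very large variable menus require
  lowering `k_max`.
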