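# Methods

## Absolute quantification from emPAI

The exponentially modified protein abundance index (emPAI) is treated as a
relative *molar* abundance, so emPAI·Mw is proportional to mass and each
protein's mass fraction in a sample is emPAI_i·Mw_i / Σ_j emPAI_j·Mw_j.
Multiplying by M_total — the total corona protein mass per particle, i.e.
the BCA mass concentration (g ml⁻¹) divided by the particle number
concentration (ml⁻¹) — gives grams per particle, and dividing by Mw and
multiplying by Avogadro's number gives copies per particle. Two conventions
are deliberate:

* N_A = 6.023×10²³ mol⁻¹, the rounded constant used when corona copy
  numbers of this kind were introduced, so outputs are directly comparable
  with published values; it is a keyword argument wherever it enters.
* A protein with no emPAI entry for a sample is *absent* (emPAI = 0), not
  missing data — downstream SC logic depends on "zero copies in a control"
  being meaningful.

Because the mass fractions are scale-free in emPAI, any per-sample
rescaling of emPAI values (different injection amounts, different search
runs) cancels exactly; this invariance is asserted by property tests.
Internally masses are grams, concentrations g ml⁻¹ and ml⁻¹; the CLI and
config readers accept µg ml⁻¹ with explicit unit-tagged keys. emPAI values
are consumed as produced upstream; one table per condition, no replicate
renormalization.

The degree of labeling of a conjugate follows from its UV spectrum as
DOL = A_max·ε₂₈₀ / ((A₂₈₀ − A_max·CF)·ε_max); the corrected protein
absorbance must be positive or the measurement is rejected.

## SC identification and classification

The study design has four hard-corona controls (HC, HC-N3, D Ctrl, N3 Ctrl)
and one captured sample (HC+SC) in which weakly bound proteins have been
covalently trapped. The published analysis reads the SC cluster off a
two-way clustered heatmap, restricted to proteins consistently lower in
*all* controls without large variation among them. This package
operationalizes that restriction as an explicit rule so it is reproducible
and parameterizable:

    SC  ⇔  copies(HC+SC) ≥ f · max(control copies)
           and (CV(controls) ≤ c  or  all controls = 0)

with defaults f = 1.5 and c = 0.5, both CLI-configurable. The CV uses the
sample standard deviation (n−1), as do the z-scores. Proteins with zero
copies in every control and positive capture are SC of type "new".

Typing compares hard-state copies (the mean over the four controls — the
published averaging convention; configurable) with soft-state copies
(capture excess, floored at zero): type 1 when hard/soft exceeds the
similarity ratio ρ, type 3 when soft/hard exceeds it, type 2 in the band
between. "Similar copy numbers" has no published definition; ρ = 1.5 is
this package's declared convention and is carried in all outputs. Note a
structural consequence: a type-1 protein (soft/hard < 1/ρ) is enriched by
less than 1 + 1/ρ ≈ 1.67×, so with the default enrichment factor the rule
can only admit type-1 proteins whose controls are very tight; the
published workflow, reading the dendrogram, had the same tension.

Heatmap analytics follow the standard omics recipe: square-root transform,
per-protein (row-wise) centering and scaling — row-wise because heatmap
z-scores compare one protein across samples — then Ward's minimum-variance
linkage on Euclidean distances for rows and columns (scipy's deterministic
nearest-neighbor-chain implementation, so identical inputs give identical
trees). Zero-variance rows are set to zero and flagged rather than dropped.
For visual parity with a dendrogram reading, the row-tree cut whose best
cluster maximizes Jaccard overlap with the rule-based SC set is reported
alongside the rule's output.

## Sequence parameters

Molecular weight sums average (isotope-abundance-weighted) residue masses
plus one water; GRAVY is the mean Kyte–Doolittle hydropathy; the
instability index is Guruprasad's (10/L)·Σ DIWV over adjacent dipeptides
(the 400-entry published weight table is taken from Biopython's ProtParam
data; the statistic itself is computed here — note the table contains
negative entries, so the index can be negative for short stable peptides);
the isoelectric point is found by bisection on the Henderson–Hasselbalch
net charge over the Bjellqvist pKa set (termini plus D, E, C, Y, H, K, R)
to 0.01 pH. These reproduce the ExPASy ProtParam conventions; tests
cross-check MW, GRAVY and pI against Biopython's independent
implementation on random sequences, and all four parameters against a
frozen reference fixture of well-known peptide sequences plus synthetic
ones (reference values recorded once from Biopython's ProtParam; very
acidic sequences with pI below ~4.05 are excluded because that oracle
clamps its search there). Non-standard residues (B, Z, X, U) abort by
default or are skipped with a counted warning on request, since real FASTA
files contain them. Corona-level averages weight each protein's parameters
by its per-particle copy number.

## Footprints and coverage

Without structural data a protein of mass M (Da) is a sphere of volume
V = 1.212×10⁻³ nm³/Da · M (partial specific volume 0.73 cm³ g⁻¹) and
radius R = 0.066·M^⅓ nm; the two rounded constants describe the same
sphere only to ~1.5%, and that tolerance is part of the contract tests.
With coordinates (PDB ATOM records, first model, first alternate
location), the footprint range comes from projecting the atom cloud onto
planes orthogonal to 256 Fibonacci-sphere directions, taking the 2-D
convex-hull area per direction, and polishing the minimum and maximum with
a local Nelder–Mead search over the direction angles (a pure direction
scan misses narrow extrema — a regular tetrahedron's true min/max ratio is
≈1.41, with the minimum at an oblique direction). The coverage ratio of a
sample divides the copy-weighted footprint sum by the bare-particle
surface π·d², giving an orientation-dependent (min, max) range; values
near 1 indicate a monolayer. Quaternary structure and lipoprotein
assemblies are out of scope, as is fetching structures.

## SPR affinity-distribution fitting

Each injection cycle is a 1:1 Langmuir site: association
θ(t) = θ_eq + (θ₀−θ_eq)·e^−(k_a·C+k_off)(t−t₀) with θ_eq = C/(C+K_D),
dissociation θ(t) = θ(t_off)·e^−k_off(t−t_off). The default schedule is
the published one — 20, 100, 300, 1000, 3000 nM injected for 800 s, cycles
recorded to 2400 s, association fitted over [2, 798] s and dissociation
over [1400, 2400] s (data around the rinse are omitted). Cycles are fitted
jointly; by default each cycle starts from zero occupancy
(`independent_cycles`), with a `sequential_titration` mode that carries
occupancy across cycles, since the published description supports either
reading. A linear drift correction subtracts the line whose slope is the
mean of the pre- and post-injection baseline slopes, anchored at the
pre-injection baseline.

The measured response is modelled as R(t) = Σ_j P_j·θ_j(t) over a 21×21
log-uniform grid with K_D ∈ [10⁻⁹, 10⁻³] M and k_off ∈ [10⁻⁵, 10⁰] s⁻¹
(the published bounds; the printed off-rate interval carries rate units
and is interpreted as k_off), k_a = k_off/K_D derived. The weights solve

    min_{P ≥ 0}  ‖A·P − r‖² + α‖P‖²

— zeroth-order Tikhonov, chosen for convexity; the penalty operator is an
implementation seam. The solver factorizes the normal equations
(AᵀA + αI = LLᵀ) and runs NNLS on the small triangular system, identical
to the augmented-matrix formulation but much faster per α; a jitter of
10⁻¹²·tr(AᵀA)/441 keeps the factorization positive definite as α → 0
while preserving noiseless residuals below 10⁻⁸ RU. α is scanned over 34
log-spaced multiples of the mean Gram diagonal and the largest α is kept
whose residual sum of squares satisfies the F-statistic consistency bound

    S(α) ≤ S_min · (1 + q·F⁻¹(p; q, n−q)/(n−q)),   q = 441,

at confidence p = 0.95 — the most parsimonious distribution statistically
consistent with the best fit. Population fractions sum grid weights over
disjoint (K_D, k_off) rectangles, with off-region mass reported as
"unassigned", and the distribution's mass-weighted centroid is computed in
log space.

**Known limitation.** For sites with K_D well above the top analyte
concentration, occupancy is ≪ 1 and only the product P·θ is constrained by
the data: the minimal-norm penalty then resolves the degeneracy toward
small weights at better-saturated nodes, so the RU *weight* (and hence the
weight fraction) of a weak-affinity population is a lower-bound estimate.
Concretely, a 30 RU site at K_D = 10⁻⁴ M contributes ≤ 0.9 RU of signal
under the default schedule and is statistically removable at σ = 1 RU
under the 0.95-parsimony rule; recovered weak-site weight fractions are
severely biased low at realistic noise. Single-site *centroids* are
reliable within the assay's addressable window, taken here as
K_D ∈ [C_min/2, C_max/3] = [10⁻⁸, 10⁻⁶] M and k_off ∈ [10⁻³·⁵, 10⁻¹·⁵] s⁻¹
(decay measurable within the dissociation window); the acceptance checks
place single-site truths at the nine grid nodes spanning that window.

## Synthetic data

The corona generator reproduces the five-sample study layout: 80 proteins
(20 SC: five type 1, five type 2, six type 3, four "new", matching the
scale of the silica-particle experiment), per-protein hard-state copies
log-normal with median 5 copies/particle and σ_log = 1 (a particle then
carries a few hundred copies in total, consistent with monolayer-scale
coverage of a 70-nm sphere), molecular weights log-normal with median
50 kDa, and multiplicative log-normal noise of CV 0.1 across the four
controls. The captured sample carries hard·(1 + g) copies with per-type
soft/hard gains g drawn uniformly from (0.2, 0.5), (0.8, 1.25) and
(2.5, 6.0) for types 1–3 — bands consistent with the ρ = 1.5 typing rule —
and "new" proteins draw fresh copies with zero controls. The *planted*
copy numbers are the realized noisy values; emPAI values are derived from
them on an arbitrary positive per-sample scale and M_total follows from
the planted masses, so quantification round-trips exactly and mass
conservation holds by construction. What the generator does *not* emulate:
emPAI's saturation at high coverage, correlated noise between controls
sharing a preparation step, shared-peptide ambiguity, and protein–protein
interaction structure — so passing recovery tests demonstrate the
analytics, not MS-level robustness.

The sensorgram generator evaluates the same closed-form Langmuir basis as
the fitter on the default schedule, sampled at 1 Hz (instrument-class
acquisition rate), plus optional linear drift and Gaussian noise
(default σ = 1 RU); the true sites are also rasterized onto the nearest
grid nodes for recovery scoring. Sequence generation draws uniformly over
the 20 standard amino acids, with optional composition bias (hydrophobic
I/V/L/F or hydrophilic D/E/K/R/N/Q weighted 4×) to shift expected GRAVY.
All generators are pure functions of (config, seed).

## Problem sizes and defaults used by the reproduction script

`scripts/acceptance.py` uses 20 corona experiments of 80 proteins for the
round-trip and recovery metrics, the 14-sequence reference fixture for the
sequence parameters, 500 masses in [10³, 10⁷] Da and a 10⁴-direction
oracle for the geometry checks, and for SPR the published 5-concentration
schedule with nine single-site fits, ten two-site fits and one noiseless
fit. The two-site decomposition reports the measured strong/weak signal
fractions; per the limitation above, the weak-site fraction is expected to
be near zero at σ = 1 RU even though the planted split is 70:30.
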