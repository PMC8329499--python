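# Methods

`sedom` re-implements, as a tested pipeline, the computational chain from
negative-ion FT-ICR MS peak lists and a 16S ASV table to (i) a stratified
molecular description of sediment porewater DOM and (ii) a microbe–DOM
association network. This note documents the models, the defaults and why
they were chosen, the synthetic data generator's assumptions, and the known
limitations.

## Formula assignment

Peaks are singly charged deprotonated molecules, so the neutral monoisotopic
mass is `m/z + 1.00727646` Da (the proton mass; both electrons stay on the
anion). A peak is retained when its signal-to-noise ratio strictly exceeds 4
and its m/z lies in the inclusive window 200–800 Da. Candidate neutral
formulas C_c H_h N_n O_o S_s P_p are drawn from an element grid (defaults
C 4–60, H 4–120, N 0–4, O 0–30, S 0–2, P 0 — P is in the index formulas but
off by default because CHO/CHON/CHOS/CHONS are the families of interest) and
filtered by standard DOM plausibility rules, all configurable:

* 0.3 ≤ H/C ≤ 2.5 and 0 ≤ O/C ≤ 1.2;
* DBE = 1 + (2C − H + N + P)/2 a non-negative integer for the neutral
  molecule;
* −10 ≤ DBE − O ≤ 10. This window rejects exact-mass twins of common DOM
  compositions that are chemically implausible (e.g. near-carbon-cluster CHO
  formulas with DBE ≈ 30 that sit 0.1–0.7 mDa from ordinary CHOS molecules).
  Without it, mass error alone cannot separate such doublets at sub-ppm
  accuracy, and no isotope-pattern check is available from a peak list.

The grid is precomputed once per configuration, mass-sorted and cached, so a
full peak list is assigned by windowed binary search. The mass-accuracy
criterion (default 1 ppm) is applied to the **ion** m/z; a candidate within
tolerance is scored by |relative error|.

**Tie handling.** With continuous mass errors, two candidates are never
*exactly* tied, yet measurement error makes error differences below the
instrument's accuracy uninformative. Candidates whose |error| lies within
`tie_window_ppm` (default 0.5, half the tolerance) of the best candidate are
therefore treated as equivalent in accuracy and ranked by heteroatom
parsimony (fewest N+S+P), then |error|, then Hill order. This is the usual
practical reading of "prefer the parsimonious formula among ties"; a strict
lowest-error rule flips a coin whenever a heteroatom-swap twin sits within
~2σ of the measurement error.

Each retained peak receives at most one formula; duplicate formulas within a
sample keep the lower-|error| peak and log a `collision`. Every rejected peak
carries exactly one reason code (`s/n`, `mass range`, `unassigned`,
`collision`). Assignment is deterministic. Not implemented (v1 limitations):
internal recalibration, ¹³C isotopologue verification, homologous-series
(CH₂/Kendrick) constraints.

## Molecular indices and bulk parameters

Per formula: DBE = 1 + (2C − H + N + P)/2;
AI-mod = (1 + C − O/2 − S − H/2)/(C − O/2 − S − N − P), clamped to [0, 1]
(non-positive denominator or negative value → 0); NOSC = 4 − (4C + H − 3N −
2O − 2S)/C; plus O/C, H/C, neutral mass. Per-sample bulk parameters (MW_wa,
C_wa, O/C_wa, H/C_wa, NOSC_wa, DBE_wa, AI-mod_wa) are magnitude-weighted
means, with weights the within-sample relative intensities (so they are
invariant to rescaling raw intensities).

The degradation index I_DEG is the summed relative intensity of five
formulas whose share rises with degradation divided by the summed intensity
of all ten reference formulas; it lies in [0, 1] and is undefined (reported
as missing) when none of the ten is detected. The ten formulas ship as
editable package data (`sedom/data/ideg_flerus2012.yaml`), transcribed from
the literature convention; the transcription has not been verified against
the original source here, so absolute I_DEG values should be treated with
care (relative depth trends are unaffected by orientation errors within a
list).

## Compound classes

Seven van Krevelen windows over (O/C, H/C), with explicit open/closed
endpoint flags, evaluated in a fixed priority order (lipids →
aliphatic/proteins → lignins/CRAM-like → carbohydrates → unsaturated
hydrocarbons → aromatic → tannins); the first matching window wins, and
formulas matching none are `unassigned`. Adjacent windows share boundary
lines (e.g. H/C = 1.5), which is why deterministic priority is required. The
unsaturated-hydrocarbons window (0.7 ≤ O/C ≤ 1.5, 0 < H/C ≤ 0.1) is kept
exactly as published although it looks like a transposition of the usual
convention (unsaturated hydrocarbons are normally low-O/C); the whole scheme
is YAML-overridable. Class abundance per sample is the sum of member-molecule
fractions, so classes plus the unassigned remainder sum to 1.

## Stratification statistics

Samples split into an upper (depth ≤ 100 cm) and a deep (≥ 110 cm) stratum;
depths strictly between are an error, as none exist in the sectioning design.
Depth trends of bulk parameters are fit by least-squares linear regression
(Pearson r and its p) and by nonlinear least squares to
`y = a + b·exp(k·depth)`, multi-started over rate constants of both signs
(log-linear seeding is unreliable when the asymptote is unknown); the
exponential fit reports r = √(R²) and an F-test p against the intercept-only
model, and nonconvergence is flagged, never silently dropped.

Group-unique molecules use detection (> 0 in at least one sample of the
group); unique sets are disjoint from each other and from the shared set by
construction.

LEfSe is reduced to its two-class core — the design has exactly two strata,
so the published tool's subclass/one-against-all stages have no role. Each
molecule is screened by a Kruskal–Wallis test (midranks, tie correction)
across the strata; survivors get an effect size from bootstrapped
one-dimensional LDA on abundances scaled to one million per sample. For a
single feature the LDA discriminant direction is the feature axis itself, so
the effect reduces to the absolute between-class difference of bootstrap
means on the per-million scale; the reported score is its log10, thresholded
at 2 by convention. Results are deterministic given the seed. Type-I control
lives in the KW screen; the LDA score is an effect-size filter, not a test.

## Ordination and constrained analysis

All distances are Bray–Curtis between samples. PCoA is classical scaling
(double-centred −D²/2, eigendecomposition); negative eigenvalues are reported
but not corrected (no Lingoes/Cailliez), coordinates come from positive
eigenvalues, and percent variance is relative to the positive sum. NMDS
minimizes Kruskal stress-1 by majorization (Guttman transform) with
isotonic-regression disparities; the best of 20 restarts is kept, one seeded
from PCoA, the rest random from the seed; iteration stops when stress-1
decreases by less than the tolerance or would increase, so the reported
trajectory is non-increasing, and nonconvergence is flagged on the result.

envfit regresses each external variable onto the ordination axes; r² is the
squared multiple correlation and the direction vector has unit norm;
significance is by permuting the variable across samples. CCorA computes
canonical correlations from the SVD of Qx'Qy (orthonormal bases of the
column-centred tables), Pillai's trace = Σρ², and a permutation p by row
permutation of one table; rank-deficient input is an error advising fewer
axes. Following the source design, CCorA is run on the first five PCoA axes
of each table.

dbRDA regresses the PCoA coordinates (eigenvalue-scaled, positive axes) on
predictors. Forward selection considers environmental variables and community
axes jointly; each step tests the best candidate by permuting its values
(pseudo-F equivalent, add-one p) and enters it if p < α = 0.05, with a
double stop once the selected model's adjusted R² exceeds the full model's —
evaluated on the *already-selected* model, not the candidate, so a single
strong predictor is never blocked by noise candidates diluting the full
model's adjusted R². Variance is partitioned between the selected
environmental block E and community block C as env-only = R²(E∪C) − R²(C),
community-only = R²(E∪C) − R²(E), shared = R²(E) + R²(C) − R²(E∪C),
unexplained = 1 − R²(E∪C); the identity env + community + shared = total is
algebraic and asserted. Raw and Ezekiel-adjusted fractions are both emitted
(which one a study reports is often ambiguous). All permutation p-values use
p = (b + 1)/(m + 1) and are deterministic under a seed.

## Association network

Features are filtered by prevalence — present in strictly more than one third
of samples ("over one third" read literally) — and molecules additionally by
mean relative abundance > 0.05%. Edges are Pearson correlations between all
remaining ASV × molecule profile pairs on the shared samples, retained when
r ≥ 0.65 and the two-sided p from the t transform (n − 2 df) is < 0.01;
only positive correlations qualify, constant features are excluded with a log
entry, and — matching the source thresholds — no multiple-testing correction
is applied (a documented caveat: at these n the r ≥ 0.65 cut is the binding
constraint). The graph is simple, undirected and bipartite; the summary's
average-neighbors statistic is 2E/N. Grouped views collapse nodes by taxon
class or compound class; grouped edge weight is the count of underlying
significant pairs (conserved in total), node weight the summed degree.

MCODE follows the published algorithm with its default parameters: vertex
weight = k × density of the highest k-core of the closed neighborhood;
complexes grow greedily from the highest-weight unused seed, admitting
neighbors whose weight exceeds seed × (1 − 0.2); complexes must contain a
2-core, haircut trims to the 2-core, fluff is off; score = density × size;
modules are vertex-disjoint and ranked by score. Two properties matter for
interpretation: (i) greedy growth does not globally maximize density × size,
so MCODE's top module can score below the exhaustive optimum on adversarial
graphs (it equals it on graphs with a single dense core plus sparse
periphery, which is what module detection is for); (ii) on a bipartite graph
the closed neighborhood of any vertex is a star, so vertex weight reduces to
2/(degree + 1) and only near-square dense pockets (similar degrees on both
sides) are recoverable — large uniform bicliques are invisible to it.

The Table-1-style summary tags each molecule bacteria- and/or
archaea-correlated through its edges' ASV domains, then reports per domain
the unweighted mean/SD over distinct molecules and the weighted mean/SD
(weights = mean relative abundance) of DBE, MW, AI-mod, H/C and O/C.
Edge-count weighting is available behind the same interface by passing edge
multiplicities as weights.

## Synthetic data generator

The generator produces the study conditions every test and the acceptance
script run on. Defaults: 40 depths (5–100 cm in 5-cm steps, 110–300 cm in
10-cm steps); 5,000 unique formulas in 200–800 Da with heteroatom families
drawn once from a multinomial at CHO/CHON/CHOS/CHONS = 58.1/28.2/11.1/2.6%;
compositions rejection-sampled within the assignment grid's own plausibility
rules (so every planted formula is assignable); 1,000 ASVs.

* **Depth structure.** Each background molecule gets an exponential depth
  coefficient proportional to a recalcitrance score (standardized DBE minus
  standardized H/C, clipped), so deep samples up-weight high-DBE / low-H/C,
  aromatic and tannin-like molecules; multiplicative lognormal noise
  (log-sd 0.5) is applied per molecule-sample. The result is the expected
  bulk-parameter stratification (DBE_wa and AI-mod_wa rise, H/C_wa falls).
* **Detection.** Intensities below a per-sample detection limit (the 0.2
  quantile of that sample's intensities, emulating the instrument's s/n
  floor) are censored to zero. Censoring was chosen over iid dropout because
  independent zero patterns create heavy-tailed Pearson nulls that no real
  detection process produces.
* **Planted differentials.** 100 molecules (half per stratum) get a 4-fold
  step between strata, drawn from the upper half of base intensity — a fold
  change planted below the detection floor is unobservable and would not be
  ground truth. 50 + 50 molecules are upper-/deep-unique.
* **Peak lists.** Each detected molecule yields one peak at its [M−H]⁻ m/z
  with Gaussian 0.3 ppm relative error; 5% of true peaks are planted below
  s/n 4; uniform-random noise peaks are added at 5% of the detected count.
* **Guild couplings.** A guild couples a set of ASVs to a set of molecules.
  Guild molecules are abundant compounds (fixed high base intensity, so they
  pass the 0.05% filter the way real network molecules do) whose relative
  variation shares a latent factor (within-set correlation 0.94, CV 0.3),
  optionally loaded on depth (±0.4). Guild ASVs track the set's realized mean
  profile plus independent noise; the noise level is calibrated so the
  ASV–molecule Pearson correlation lands on the target (0.9), compensating
  analytically for Poisson counting noise at the expected read depth and
  empirically for compositional closure. Defaults plant two broad guilds
  (40 ASVs × 25 molecules each; archaea ↔ DBE 11–18 molecules, bacteria ↔
  DBE < 10) carrying the domain-level DBE contrast, plus two small tight
  guilds (4 × 4 and 3 × 3 at r = 0.95) that form the near-square bicliques
  MCODE can recover (scores 4.57 and 3.60). Background ASVs are unstructured
  lognormal noise observed through Poisson sequencing at 50,000 reads per
  sample.
* **Metadata.** Depth plus six geochemical covariates with smooth depth
  profiles (sulfate decay, ammonium accumulation, DIC increase, an Fe(II)
  hump, δ¹³C drifts) and noise.

Determinism: stage *k* draws from `default_rng([seed, k])`, so a config
reproduces every table byte-identically; every planted effect is recorded in
the `GroundTruth` object.

**What the generator does not emulate**, hence what passing tests do not
show about real data: background taxa have no depth structure (real
communities are strongly depth-stratified, which adds correlated-but-uncoupled
ASV–molecule pairs a ground-truth precision score would count as false);
there is no instrument drift, no isotopologues, no contaminant series, no
compositional coupling between DOM concentration and community size; guild
membership is exactly block-structured. Recovery rates measured here are
upper bounds for field data.

## Problem sizes and numerical choices

Tests and the acceptance script run the full 40-sample, 5,000-molecule,
1,000-ASV study for the pipeline-level checks, and scaled-down studies
(120–800 molecules, 50–250 ASVs) where many replicates are needed; the
planted-coupling recovery check uses 34 samples with 200 planted pairs among
roughly 5,000 tested pairs. NMDS uses 20 restarts, tolerance 1e-9, 300 max
iterations; permutation tests use 199–999 permutations with the add-one rule;
eigenvalue positivity uses a relative 1e-10 threshold; Bray–Curtis requires
no all-zero sample and class fractions are checked to 1e-12.
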