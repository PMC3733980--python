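# Methods

`msilac` reimplements, as a tested pipeline, the analysis of a dynamic
proteomics experiment: pancreatic cancer cells (MIA PaCa-2) treated with the
transketolase inhibitor oxythiamine (OT) while growing in a medium in which
half of the amino-acid supply is ¹⁵N-enriched to 98 atom %. The package
covers four computations: peptide isotopomer modeling, estimation of the
fraction of newly synthesized protein from MALDI-TOF envelopes, 2-DE spot
statistics (normalization, differential selection, dose classification), and
temporal expression-shape analysis.

## Isotopomer model

A peptide's envelope at unit (nominal-mass) resolution is the convolution of
per-element isotope distributions, each expressed over integer mass offsets
above the lightest isotope. For an element with single-atom distribution *d*
and *n* atoms the contribution is *d* convolved with itself *n* times
(computed by exponentiation-by-squaring; truncation to the first *k* bins is
exact because offsets only grow). Bin 0 is anchored at the monoisotopic
mass. Fine structure within a nominal mass is aggregated deliberately: the
instrument data being modeled are reflector-mode MALDI-TOF envelopes, and
unit-mass bins keep the downstream regression well-posed.

Constants (atomic masses, isotope abundances, residue formulas,
modification deltas) live in one versioned table (`constants.py`), IUPAC
values to six significant figures. Only C, H, N, O, S occur; ambiguity
codes (B, Z, X, U) are rejected rather than approximated, since a silent
approximation would corrupt turnover fits. Spectra are matched as [M+H]⁺
(charge a parameter, default 1); successive bins are spaced 1.00335 Da; the
default bin count is N-count + 6, covering a fully ¹⁵N-shifted envelope plus
the natural tail.

## Labeling and turnover model

The labeling design has two parameters: the pool fraction *q* (probability
that an amino acid incorporated during synthesis comes from the labeled
supply; 0.50 here) and the atom enrichment *p* (¹⁵N fraction within a
labeled amino acid; 0.98). Amino acids are incorporated intact, so in a
peptide synthesized during labeling each residue is independently labeled
(nitrogen binomial at *p*) with probability *q* or unlabeled (natural
isotopes) otherwise. The new-protein envelope is the convolution over
residues of this two-component per-residue mixture, convolved with the
natural pattern of the non-residue atoms — the terminal water and any
modification deltas, whose atoms (e.g. the carbamidomethyl nitrogen, which
comes from iodoacetamide) are never metabolically labeled.

An observed spectrum is modeled as a two-population mixture: pre-existing
protein with the natural envelope, newly synthesized protein with the
labeled envelope. After aligning observed peaks to the theoretical grid
(nearest bin within ±0.5 Da by default, intensities of co-assigned peaks
summed), the fraction of new synthesis is estimated by nonnegative least
squares with the two envelopes as regressors: obs ≈ a·old + b·new, with
f = b/(a+b). The regression form is a design choice — the source analysis
says only "multiple linear regression" — and is the simplest model
consistent with a two-population mixture and the observed bimodal
envelopes.

Numerical choices:

* The observation is normalized to unit total before the solve, and f is
  reported rounded to 12 decimals. The rounding is far below any attainable
  measurement precision; its purpose is to absorb the last-ulp perturbation
  introduced by rescaling a spectrum, making f exactly invariant under
  multiplication of the intensities by any positive constant.
* No baseline regressor by default (inputs are assumed centroided and
  baseline-subtracted); none of the fixtures need one.
* *q* is treated as known. A profile-fit mode
  (`fit_fraction_new_profile_q`) grid-searches *q*, since amino-acid
  recycling can dilute the nominal medium fraction, but it is off by
  default.
* Fits with f below 0.05 are flagged "not detected" — roughly twice the
  recovery error of the estimator at 5% bin noise — mirroring the absent
  12 h entries of the source table (no measurable mass shift).
* Identifiability: as q → 0 the old and new envelopes converge and f
  becomes unidentifiable; the test suite asserts the monotone degradation
  on q ∈ {0.5, 0.2, 0.05}.

## 2-DE spot statistics

Each gel is normalized to the summed intensity of all its spots.
Differential selection between replicated conditions (≥2 replicates; the
study used 4) requires both a >2-fold mean ratio (in either direction) and
a two-sided two-sample Student's t-test p < 0.05 on the normalized values
(Welch by flag; no multiple-testing correction by default, matching the
per-spot α of the source — Benjamini–Hochberg by flag). Zero-variance
identical groups get p = 1 and are never selected.

Dose-response profiles (ratios at 5, 50, 500 μM vs control) are classified
*induced* if the highest-dose ratio exceeds 1, else *suppressed*. The rule
is reverse-engineered — the narrative names the classes without a formula —
and reproduces the printed 14-suppressed / 4-induced split exactly.

Protein accounting uses protein names by default; the printed tables assign
two proteins (transketolase, alpha-enolase) different accessions in the two
experiments, so accession-keyed counting gives 54 where name-keyed counting
gives the published 52. Both keys are available.

## Temporal shapes

Profiles are ratio triplets (baseline ≡ 1, two later times; time labels are
caller-supplied because the source's own headers disagree on the middle
point, 12 h vs 24 h). The canonical classifier is a deterministic rule:

* rise-then-fall ("downright V") if the middle ratio exceeds 1;
* otherwise monotone down if the late ratio does not exceed the middle;
* otherwise dip-then-recover ("upright V").

Ties resolve toward the monotone/dip classes; no fixture row sits on a
boundary. The rule reproduces all 46 printed cluster letters, which is why
it, and not K-means, is canonical. K-means (k = 9 default, 100 restarts,
distance 1 − Pearson on log₂ profiles, Lloyd iterations with mean-centroid
updates) is provided for fidelity with the original exploratory analysis;
centroids collapse onto the three shapes through the same rule.
Initialization draws centroids from the canonically sorted profile list, so
the partition is deterministic given the seed and invariant to input order.
Flat (zero-variance) log profiles are defined to have correlation 0 with
everything. scikit-learn's K-means is Euclidean-only, so this ~40-line
Lloyd variant is implemented in-package.

Concordance between a protein's total and phospho profiles is agreement of
the shape rule on both. On the printed pairs this yields 4 concordant / 8
discordant; the source narrative counts 6/6, but two of its "concordant"
proteins contradict its own printed ratios (one phospho profile clearly
recovers, one total row is printed as dip-then-recover). The code follows
the ratios and does not reconcile the narrative.

## Synthetic data

The generator states the study's world: 4 replicates, 3 time points,
q = 0.5, p = 0.98, 5% spectral bin noise (multiplicative Gaussian, clipped
at zero), 10% replicate CV on spot intensities (log-normal — densitometry
is positive and right-skewed). Temporal archetype magnitudes default to the
medians of the printed clusters (down 1→0.61→0.28, V-up 1→0.37→0.795,
V-down 1→2.13→0.77); an effect-size parameter rescales the log-deviations,
preserving shape class at any magnitude, with the default
(1/0.28 ≈ 3.57-fold) reproducing the medians exactly.

80% of simulated spots are null (flat). This is a modeling requirement, not
a convenience: normalizing spots to the entire gel intensity presumes that
most spots are unchanged, as on a real 2-DE gel where the published tables
list only the differential minority of the ~10³ detected spots. A world in
which most spots change breaks the normalization itself.

What a green test does and does not establish: the generator produces
peaks exactly on the theoretical m/z grid (no mass-calibration error), no
chemical background or overlapping envelopes, independent bin noise, and
log-normal replicate noise without gel-to-gel spatial artifacts. Recovery
results therefore bound estimator error under the stated noise model only,
not under real instrument drift or spot-matching failures. The archetype
recovery metric is computed over non-null proteins, since the three-class
shape rule has no "null" output; false selection of nulls is covered by the
differential filter's specificity instead.

## Known limitations

* The published per-protein synthesis rates (e.g. Annexin A1 55% → 37%)
  cannot be recomputed: the underlying spectra exist only as figure images.
  The printed rate table is shipped as data, used for direction
  classification; the estimator itself is validated by simulation and
  enumeration oracles.
* Fine isotope structure, charge states > 1, adducts other than H⁺ and
  MS/MS fragment modeling are out of scope.
* The digest-based lookup of the 1702.5 m/z fragment exposes *all* tryptic
  candidates within tolerance (two, when one missed cleavage is allowed)
  rather than asserting a unique match, as a search engine would.
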