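# Methods

## Mass arithmetic

All masses are monoisotopic. Peptide neutral mass is the sum of residue
masses (the 20 standard residues, five-decimal monoisotopic values) plus one
water (18.010565 Da); m/z of a z+ ion is (M + z·1.007276)/z, using the
proton mass rather than the hydrogen atomic weight because the charged
species has lost an electron. The methyl delta is fixed at +14.015650 Da
(CH₂), the exact form of the nominal "+14 Da" shift; dimethyl, trimethyl
and carbamidomethyl are available as built-ins. No fixed cysteine
alkylation is applied by default — the workflow this package models digests
without reduction/alkylation. Average masses are deliberately not offered:
reflectron MALDI and Orbitrap data are monoisotopic-resolved, and offering
both invites silent unit mixing.

One known discrepancy is intentional: monoisotopic arithmetic puts the
doubly charged methylated GIGCYMFR precursor at m/z 480.73, while the value
conventionally quoted for that spectrum is 480.8 (rounding/calibration of
the original instrument is unknown). Matching tolerances absorb this; the
precursor-consistency check records a warning instead of failing.

## Digestion and fingerprinting

Trypsin cleaves after K/R unless the next residue is proline. Peptides with
up to `max_missed` missed cleavages are formed by joining consecutive runs
of fully cleaved fragments; coordinates are 1-based inclusive within the
construct, and `parent_offset` maps construct position 1 to the
full-protein residue number (so construct position 138 of a construct
starting at residue 3745 reports as residue 3882). Variable-modification
expansion enumerates target-residue subsets per modification, capped at
`max_per_peptide` (default 2 — observed automethylation is mono-methyl;
the cap bounds combinatorics). No minimum-length filter by default; a
`min_length` option exists.

## Fingerprint matching and delta scan

MS1 peaks are assumed singly protonated (MALDI overwhelmingly produces 1+
ions). Matching is greedy nearest-mass per peak within a tolerance (default
0.3 Da, the scale appropriate to externally calibrated reflectron MALDI of
the period; it is a design choice, not a measured value) — fingerprint
spectra are sparse enough that global optimal assignment would change
nothing in practice, and greedy matching mirrors how such spectra are read
by eye; this is documented as a limitation. Ties break toward fewer
modifications, then fewer missed cleavages, then lower m/z. Intensities are
carried through reports but never influence matching. The delta scan tests
every *unmodified* theoretical mass for peaks at base + k·Δ (k ≥ 1), so an
unanticipated modification is found even when no modification-aware
fingerprint was built.

## Fragment prediction and site localization

Only b/y series at 1+ are predicted by default (CID in a linear ion trap;
the assignment logic needs nothing else). b_i is the first-i residue sum
plus a proton (no water); y_j the last-j sum plus water plus a proton, so
b_i + y_{n−i} = M + 2·m_p exactly — asserted as a property test. Default
MS2 tolerance is 0.5 Da (ion-trap fragments), with a 0.05 Da precursor
check (Orbitrap full scans).

Localization places the modification at each candidate residue (the
modification's targets by default; every residue with `any_site`), predicts
each ladder, annotates the spectrum (nearest fragment within tolerance,
ties to lower index, b before y), and scores placements by explained peaks.
Fragments whose m/z differs between placements — site-determining ions —
carry weight 2 (configurable): they are the only ions that can discriminate,
and the doubling mirrors the decisive role of a shifted/unshifted bracket
(e.g. unshifted b3 next to shifted b4) in manual assignment. A unique
argmax names the site; any tie for the top score returns `ambiguous`. The
localizer therefore cannot return a silently wrong site when no
discriminating evidence survived — verified on 1000 simulated spectra with
jitter and dropout.

## Kinetics

* **Initial rates.** OLS of signal on time over the full provided window;
  time courses in the regime modelled are linear, so no curvature
  correction is applied — users must pre-truncate windows that leave the
  linear phase. Densitometry (relative intensity) and scintillation (cpm)
  series are treated identically after unit tagging; no conversion between
  the two is attempted.
* **Reaction order.** OLS of log₁₀(rate) on log₁₀(concentration); the slope
  is n in v = k·[E]^n. Any log base gives the same slope; base 10 is used
  for display convention. Multiplicative noise biases only the intercept
  (E[log(1+cv·ε)] is constant across the design), so the slope estimator is
  unbiased — asserted across 500 seeded replicates. A configurable band
  n ∈ [0.6, 1.3] (spanning the two observed first-order-like exponents,
  0.7 and 0.99) is reported as "consistent with first order"; the package
  makes no mechanistic call beyond that boolean, since an exponent of 0.7
  may reflect enzyme inactivation or measurement error rather than
  fractional molecularity.
* **Apparent Km.** Nonlinear least squares of v = Vmax·S/(Km+S)
  (scipy `curve_fit`, non-negative bounds), initialized at Vmax₀ = max
  observed rate and Km₀ = S at half-max by interpolation; standard errors
  from the fit covariance. Fits with Km below 0.1% of the smallest design
  concentration (the zero boundary, typical of saturated designs) or with
  non-finite covariance are flagged ill-conditioned; a design that does not
  span the fitted Km triggers a warning.
* **Substrate inhibition.** The qualitative high-[S] rate drop is modelled
  with the canonical uncompetitive form v = Vmax·S/(Km + S·(1+S/Ki)) — the
  functional form is a design choice, as only the *pattern* of inhibition
  is established. Both this and the plain hyperbola are fitted and compared
  by least-squares AIC (n·ln(SSR/n) + 2k, with k counting mean parameters
  plus σ); inhibition is called only when ΔAIC > 2, turning a qualitative
  observation into a falsifiable criterion.

The estimators follow the scikit-learn protocol (`fit`, `predict`,
`get_params`/`set_params`, trailing-underscore fitted attributes) so they
compose with sklearn model-selection utilities; `fit_rate`,
`fit_reaction_order`, `fit_mm`, `fit_substrate_inhibition` are thin
functional wrappers returning frozen result dataclasses.

## Synthetic data

The simulators define the study conditions the tests and the acceptance
script exercise:

* **Spectra.** Theoretical peaks (digest [M+H]⁺, or the full 1+ b/y ladder)
  receive Gaussian m/z jitter (σ in Da), Bernoulli dropout, and uniform-m/z
  noise peaks with exponential (or uniform) intensities — enough structure
  to exercise tolerances, dropout handling, and false-peak rejection.
  A ground-truth modified parent emits only the modified peptide mass
  (complete modification), matching the observed disappearance of the
  unmodified peak.
* **Kinetics.** Deterministic mean structure (linear in time; power-law in
  enzyme concentration over 1–30 μM; Michaelis–Menten over 1–100 μM AdoMet,
  or 1–20 μM for the restricted design, with optional substrate inhibition)
  times multiplicative Gaussian noise (CV-style) — densitometry and
  scintillation error scale with signal, which is why the noise is
  multiplicative rather than additive. Default designs: 6 time points over
  0–4 h at 5% CV for time courses; 10% CV for rate tables.

Every generator is a pure function of (parameters, seed); zero-noise
generators invert exactly through the corresponding fits, which is the core
parameter-recovery suite. What the simulators deliberately do not emulate:
isotope envelopes, chromatographic elution, detector/band saturation,
ragged baselines. Passing tests therefore demonstrate correctness of the
arithmetic, matching, scoring and fitting logic under realistic tolerances
and noise — not robustness to every artifact of real spectra or gels.

## Problem sizes

Replicate counts used by the test suite and the acceptance script — 200
seeded replicates per Michaelis–Menten recovery, 500 per slope/order
recovery, 1000 simulated spectra for the localization property — are the
package's chosen desk-scale defaults: large enough that medians/means are
stable to well within the acceptance bands, small enough to run in seconds.

## Known limitations

Greedy (not globally optimal) peak assignment; 1+ b/y ions only (no a/x,
c/z, neutral losses, ETD); no probabilistic localization score (no
Ascore-style p-value — ambiguity is reported, not quantified); no
deisotoping or recalibration (inputs must be centroided); no kcat (active
enzyme concentration is not modelled); no global progress-curve fitting.
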