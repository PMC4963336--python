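# Methods

## The measurement model

The package works in the *reconstructed, calibrated image domain*: it
assumes counts per voxel are already corrected for attenuation, scatter and
resolution losses (as they are after a quantitative OSEM reconstruction),
so a single linear calibration factor S (counts·s⁻¹ per kBq in a voxel)
relates counts to activity. The chain for one study is

1. **Counts → concentration.** C_acq = counts / (v_vox[mL] · S · T), with T
   the dwell time in seconds.
2. **Decay correction.** All activities are referenced to injection time:
   C_inj = C_acq · 2^(Δt/T½) with Δt = t_acquisition − t_injection. The
   Tc-99m half-life defaults to 360.4 min (6.0067 h) and is configurable on
   `AcquisitionMeta`. Referencing SUVs to injection time (rather than scan
   time, the PET habit) makes studies with different injection-to-scan
   delays comparable.
3. **Net injected activity.** A_net = A_prepared·2^(−(t_inj−t_prep)/T½) −
   A_residual·2^(−(t_inj−t_res)/T½): the prepared syringe activity decayed
   to injection time minus the post-injection residual decayed back to
   injection time. A non-positive A_net is an error.
4. **SUV.** SUV = C_inj[kBq/mL] · W[g] / A_net[kBq], the body-weight
   convention with 1 g/mL tissue density.

## VOI metrics

VOIs are axis-aligned ellipsoids in world millimetres; a voxel belongs to a
VOI when its **centre** satisfies Σ((x_i − c_i)/a_i)² ≤ 1. Centre-inclusion
membership (no partial volumes) keeps every metric exactly reproducible by
exhaustive enumeration, which the test suite exploits.

* **SUV_mean / SUV_max** — arithmetic mean / maximum over the mask.
* **SUV_peak** — the mean over a sphere of fixed volume (default 1 mL,
  radius (3V/4π)^{1/3} ≈ 6.204 mm) centred on the centre of the hottest
  voxel in the mask. The sphere may extend beyond the VOI (it is not
  constrained to lie inside it) but is clipped at the grid border.
* **Uptake ratio** — lesion SUV_peak divided by the reference vertebra's
  SUV_mean at the same time point.

**Tie-breaking at the maximum.** When several voxels tie exactly at the VOI
maximum — the generic case in noiseless synthetic data, measure-zero in real
data — the peak sphere is centred on the tied voxel whose sphere average is
greatest, with any remaining tie going to the lowest C-order linear index.
This makes the natural identity "homogeneous lesion much larger than the
sphere ⇒ SUV_peak = lesion value" hold (a boundary-voxel centre would dilute
the sphere with background), stays deterministic, and coincides with the
plain hottest-voxel rule whenever the maximum is unique.

## Response classification

Fractional change δ = (v₂ − v₁)/v₁ of the per-lesion value (SUV_peak in
absolute mode; uptake ratio in ratio mode) is thresholded at ±30 % with
*strict* inequalities: δ = ±0.30 exactly is stable. The threshold is
configurable; 0.30 is the default used throughout. In ratio mode, lesions
whose subject has no usable reference region are excluded with a logged
count rather than failing the run, mirroring clinical practice where some
fields of view contain no uninvolved vertebra.

Ratio-mode classification is invariant to any global per-time-point uptake
rescaling applied to lesion and reference alike — the reason ratios are used
at all — and both modes are invariant under a common positive rescaling of
(v₁, v₂). Both invariances are property-tested.

## Agreement statistics

Cohen's unweighted kappa k = (p0 − pe)/(1 − pe), with p0 the observed
agreement fraction and pe = Σᵢ p_{A,i}·p_{B,i} the chance agreement implied
by the two raters' marginal category frequencies (category order fixed as
progressive, stable, regressive). Because k depends only on the diagonal
sum and the marginals, it can be recomputed *exactly* from published
marginal counts plus a discrepancy count; `kappa_from_marginals` and
`kappa_from_table` are verified to agree identically on random tables. Both
raters unanimous in the same single category gives pe = 1 and an error
(kappa undefined). Verbal labels follow Landis–Koch with inclusive upper
bounds (k = 0.20 → "slight", 0.40 → "fair", …); labels are applied to the
unrounded kappa. A large-sample (Fleiss) standard-error p-value is provided
for reporting but is not part of any reconstruction. Mann–Whitney U uses the
exact null distribution for tie-free samples with min(n) ≤ 8 and the
tie-corrected normal approximation otherwise; Spearman's rho is the Pearson
correlation of midranks. Both wrap scipy.stats and are cross-checked against
enumeration/first-principles oracles in the tests.

Rounding of reported kappas is decimal half-up to 2 dp, applied only at
report time; all internal arithmetic is unrounded.

## The synthetic-data generator

`phantom` emulates the structure of a 19-patient longitudinal cohort: per
subject a 64³ grid of 2.4 mm isotropic voxels (desk-scale, near clinical
SPECT sampling), up to six homogeneous ellipsoidal lesions (a seventh is an
error), one vertebral reference ellipsoid, and soft-tissue background.
Painting precedence is lesion > reference > background (a metastasis
replaces marrow uptake); overlapping lesions are an error naming the
colliding ids. Default intensities and acquisition parameters are the
cohort's observed means: lesion SUV_peak 20.4 at baseline declining to 16.4
at follow-up, reference SUV_mean 5.6 / 4.9, injected activity 573 / 542 MBq,
acquisition 231 / 234 min post injection, 73 kg body weight (the cohort-mean
weight), S = 1.0 counts·s⁻¹/kBq with a 15 s dwell (≈20 counts in a hot
lesion voxel, a plausible reconstructed-domain level). Counts are Poisson
with `numpy.random.default_rng(seed)`; identical seeds give bit-identical
volumes. Visual readers are simulated by a 3×3 row-stochastic confusion
matrix over the true change categories.

What the phantom does **not** model: attenuation, scatter, detector PSF,
reconstruction artefacts, intra-lesion heterogeneity (lesions are uniform;
an optional texture hook was considered and deliberately left out as
unvalidatable), patient motion, or VOI placement variability between time
points (follow-up VOIs are identical to baseline). Passing tests therefore
demonstrate the correctness of the quantification/classification/agreement
arithmetic, not robustness to those physical effects.

## Numerical and design notes

* **Noiseless checks** use `expected_counts` (the Poisson mean) in place of
  a draw; the painted SUV map is then recovered to < 1e-9 everywhere, and
  end-to-end classification of true changes {+0.5, 0, −0.5} is exact in both
  modes. With Poisson noise the max-centred SUV_peak of a *homogeneous*
  lesion is intrinsically high-variance — the argmax falls uniformly over
  the lesion, and a boundary-adjacent sphere dilutes into background — so
  noisy end-to-end classification is demonstrated but not asserted exact.
* Decay correction composed with its inverse is the identity to 1e-12; SUV
  is invariant to the (dose, weight) pair used to simulate, to 1e-9.
* World coordinates: volumes are stored (nx, ny, nz) with a diagonal
  voxel-to-world affine (spacing on the diagonal, origin in the last
  column); NIfTI I/O via nibabel preserves grid and unit tag.
* The published cohort's per-reader marginal counts ship as in-package
  fixtures (they are small printed tables), so reconstruction of the four
  aggregated inter-method kappas needs no network and no patient data. The
  cohort's *inter-observer* kappas (0.46, 0.35, 0.94, 0.87) and SUV
  correlations (0.99, 0.92) are not reconstructible from printed data (no
  inter-reader cross-tabulations were published) and are not claimed.
* Problem sizes: the default grid is 64³ (tests use 16³–32³ where an
  exhaustive oracle re-derives the result); the reader-independence check
  uses 10⁴ simulated lesions.
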