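# Methods

This note documents the models, algorithms, parameter choices, and known
limitations behind `lipidphase`. It is written for users who want to know
what the numbers mean and how far to trust them, in the spirit of the
methods documentation of packages like `statsmodels` or `msprime`.

## Forward lineshape model

A deuterated chain segment in a fluid bilayer undergoes fast axial
reorientation; its quadrupolar interaction is scaled by the segmental
order parameter S_CD. For an unoriented (powder) multilamellar sample the
time-domain signal of one segment is the orientational average

    FID_i(t) = ∫₀^{90°} cos( 2π · (3/4) χ · P₂(cos θ) · S_i · t ) sin θ dθ
               × exp(−π · LB_i · t),

with χ = 167 kHz the quadrupolar coupling constant of aliphatic C–²H
bonds, P₂ the second Legendre polynomial, and LB_i a Lorentzian line
broadening in Hz. A perdeuterated palmitoyl chain contributes one such
component per carbon: weight 2 for each CD₂, weight 3 for the terminal
CD₃, i.e. 31 deuterons for palmitoyl-d31. Fourier transformation (with
first-point scaling, optional zero filling) yields the superposition of
Pake doublets whose perpendicular-edge horns sit at ±(3/8)χ|S| — horn
separation (3/4)χ|S|, the quadrupolar splitting.

Numerical choices:

* The powder integral is discretized on a uniform θ grid (0.00625°
  increment, trapezoid rule with sin θ weights). By the Euler–Maclaurin
  formula this trapezoid sum equals the exact integral minus
  h²/12·cos φ (h the grid step in radians, φ the total phase), which we
  verified against the direct sum to 4·10⁻¹⁵; the fast evaluation path
  therefore computes the kernel from the Fresnel-integral closed form
  with this analytic correction, tabulates it densely (5·10⁻⁴ rad step),
  and interpolates with Catmull–Rom cubics (error ≲ 10⁻¹²). Direct
  trapezoid and Gauss–Legendre quadratures remain available and agree
  with each other and with the 10× finer brute-force grid to < 10⁻⁸ on
  whole FIDs.
* Default acquisition: 4096 points at 1 µs dwell (±500 kHz bandwidth;
  display conventionally cropped to ±250 kHz), no apodization, no
  symmetrization. The frequency axis drops the unmatched −Nyquist DFT
  sample so it is exactly symmetric about zero; noiseless spectra are
  even-symmetric to machine precision.
* The printed growing exponential of the broadening factor is implemented
  as a decaying exponential exp(−π·LB·t); a growing exponential is
  unphysical and produces no broadened lines. The angular 2π is included
  so that the frequency axis is in true frequency units (the horn
  separation of an |S| = 0.2 doublet is then 25.05 kHz, as it must be).
* The quadrupolar echo sequence is not simulated: the FID is ideal from
  t = 0 (perfect refocusing assumed). Methyl groups are ordinary Pake
  components with their own small |S|; the threefold-rotation physics is
  absorbed into the fitted methyl order.
* The two C-2 deuterons are treated as equivalent (one splitting).

## Two-phase spectral decomposition

In slow exchange (large domains), each lipid species shows the
superposition of one complete lineshape per phase. The fit recovers the
phase fractions, one per-carbon order profile per phase, per-phase
Lorentzian broadenings, and optionally an isotropic line (fast-tumbling,
unbound molecules).

Each phase's profile is parameterized as a plateau with an exponential
decay toward the methyl end:

    S(c) = S_plat                      for c ≤ c_knee
         = S_plat · exp(−(c−c_knee)/λ) beyond,

with an independent methyl order expressed as a fraction of the last
methylene's order. This is the shape real chain profiles take and keeps
the fit well conditioned for noisy data. A free-per-carbon mode (orders
parameterized by non-negative decrements, monotone by construction) is
available for noiseless spectra.

The least-squares objective is comb-like: tens of sharp doublet horns
make the global minimum a funnel roughly 1 % wide in every parameter,
surrounded by barriers wherever two doublets misalign. Plain multi-start
local optimization (Latin-hypercube starts) converges to local minima
with order-0.1 fraction errors even on noiseless data; we verified this
before adopting the pipeline below.

1. **Convex dictionary inversion.** The spectrum is decomposed by
   non-negative least squares over single-doublet lineshapes on a fine
   |S| grid (step 0.002, reference broadening 120 Hz), restricted to
   orders whose horns lie inside the fitted window. This convex, global
   step yields the spectral mass distribution over order parameters; the
   per-carbon orders of both phases appear as resolved mass spikes.
2. **Ladder enumeration.** For every pair of integer knee positions and
   every plateau-pair hypothesis read off the distribution's peaks, the
   smooth parameters are fitted to the Gaussian-smoothed distribution by
   Nelder–Mead (microsecond evaluations). This removes the genuinely
   discrete direction (which carbons sit on the plateau) from the
   continuous optimization.
3. **Polish and rank by polished misfit.** Every distinct knee
   interpretation is refined against the raw spectrum by bounded
   trust-region least squares (variable projection: the phase amplitudes
   and a constant baseline offset are solved by NNLS at every step),
   warm-started through a short Gaussian smoothing anneal applied
   identically to data and model. Each interpretation starts from the
   distribution winner's smooth parameters transplanted onto its knees.
   Only the polished raw-spectrum misfit ranks these near-degenerate
   interpretations reliably, so the leaders receive uncapped finishing
   polishes along two routes (annealed and direct); the lowest-cost
   interpretation wins. A memoized ±1 hill climb around the winner guards
   against boundary effects of the candidate set.

Further choices: order bounds [0, 0.5]; LB bounds [10, 3000] Hz; a
constant baseline offset (split into ± columns for the NNLS) and no
polynomial baseline; fit window ±2.5·(3/8)χ·0.5 + 10 kHz (all physically
reachable horns plus their tails); convergence at relative objective
change < 10⁻¹⁰ or the per-stage evaluation budget; phase labels assigned
after fitting — "I" is the phase with the lower plateau order
(disordered), "II" the higher (ordered). Ties between equal-cost
candidates break toward the lower ordered-phase fraction. Fractions are
spectral intensity fractions, which equal molar fractions for a uniformly
labelled species. The procedure contains no randomness: identical inputs
give bit-identical results.

At the study scale used in the tests (C16 chains, 4096-point spectra,
signal-to-noise ratio 50), recovered fractions are typically within
±0.01–0.02 and per-carbon orders within ±0.005. For noise draws where one
phase's fraction is small, the maximum-likelihood estimate itself can
place a mid-chain carbon ~0.015 off truth (verified by polishing from the
true parameters); this is an estimator-variance limit, not an
optimization failure.

The temperature-series driver fits spectra in order of increasing
temperature and warm-starts each fit from the previous solution; failures
are recorded per row and the series continues.

## Chain structure (mean-torque model)

The first-order mean-torque map from segmental order magnitude to average
segment tilt is

    ⟨cos β⟩ = (1 + sqrt((8|S| − 1)/3)) / 2     for |S| ≥ 1/8,

clamped at the free-rotor floor 1/2 below the |S| = 1/8 branch point
(where the square root turns complex); the clamp keeps the map continuous
and affects only the last few carbons of disordered chains. Each C–C
segment projects 1.27 Å·⟨cos β⟩ onto the bilayer normal; a C16 chain has
15 segments, so the all-trans length is 19.05 Å. The terminal methyl's
effective segmental order is 3·|S_methyl| (capped at 0.5), the standard
correction for its extra threefold rotation. The mean gauche-defect count
is the length deficit divided by 1.1 Å. The all-trans reference length is
overridable because published (length, defect-count) pairs imply slightly
different reference conventions (19.0–19.7 Å); the geometric default is
1.27·(n_carbons − 1). All order parameters are handled as magnitudes.

## Order parameters from trajectories

S_CD per carbon is the average of P₂(cos θ) over frames, lipids, and
equivalent hydrogens, with θ the angle between the C–H bond vector and a
fixed bilayer normal (z by default; membranes are planar here, so no
local-normal estimation). Signed values are returned; the NMR comparison
uses magnitudes and, when comparing with experiment, the chain average.
The per-lipid order observable — the instantaneous mean of P₂ over one
lipid's chain segments, optionally boxcar-smoothed — is the scalar time
series fed to the state classifier. Trajectory input is a pre-extracted
bond-vector table; a raw-trajectory adapter is a documented extension
point. Whether a companion analysis would use C–C or C–H segment vectors
is left open; both can be expressed through the same table format.

## Hidden Markov state classification

Per-lipid order series are modelled by a hidden Markov chain with one
Gaussian emission per state (default three states: disordered,
intermediate, ordered — the intermediate state is always reported
separately). All lipids share one model (pooled estimation). Baum–Welch,
Viterbi decoding, and forward–backward posteriors are implemented as
scaled recursions vectorized across the equal-length lipid series, which
keeps a 200-lipid × 2000-frame fit in the tens of seconds on one core
(per-sequence implementations iterate over lipids in Python and are an
order of magnitude slower at this shape). Emission means are initialized
by seeded k-means++ (pooled values sorted first, making the fit invariant
to lipid relabelling); the best of five restarts by final log-likelihood
wins; EM stops when the relative log-likelihood gain falls below 10⁻⁸
(an absolute tolerance would never trigger on a ~10⁵-magnitude pooled
log-likelihood) or after 500 iterations. States are sorted by ascending
emission mean. Model order is fixed at three by default; a BIC utility is
provided for comparison but never chooses the order silently.
Correctness anchors: the forward likelihood and Viterbi paths are tested
against brute-force path enumeration and against an independent HMM
library on small instances.

## Synthetic data

The generator produces every input with known ground truth: two-phase
spectra (plateau+decay profiles, per-phase broadenings, optional
isotropic line), cone-geometry bond-vector trajectories with closed-form
order parameters, and Markov-switching Gaussian order series with their
true state paths. All randomness flows from explicit integer seeds;
identical seeds give bit-identical outputs.

Noise is additive white Gaussian in the frequency domain with standard
deviation max(intensity)/SNR — the simplest stand-in for an experimental
noise floor. Real spectra additionally show correlated (T₂-dependent)
noise, baseline roll, and pulse-sequence artifacts that this generator
does not emulate; passing round-trip tests therefore demonstrates the
estimator's correctness and precision under ideal noise, not performance
on raw spectrometer output.

Named presets bundle scenario conveniences for a raft-forming
POPC/PSM/Chol (4/4/2) mixture with and without 9 mol% serotonin:
`popc_no5ht` (single disordered phase, plateau 0.21), `popc_5ht`
(60/40 disordered/ordered, plateaus 0.19/0.34), `psm_5ht` (37/63,
plateaus 0.23/0.38), and `5ht_d4` (two-site serotonin chain, 28/65/7
with an isotropic component). Plateau levels, knee positions (8 and 10),
decay constants (~3 carbons), methyl orders, and broadenings
(100/150 Hz) are chosen at values typical for liquid-disordered and
liquid-ordered phases at 30 °C; the percentages parameterize scenarios
with known ground truth and are not re-derivations of any experimental
dataset.

## Problem sizes used in tests

The shipped test suite and the acceptance script run the full pipeline at
the default acquisition size (4096-point spectra) with 20 and 12 noisy
mixture fits respectively, 10–20 isotropic-recovery replicates, a
200 × 2000 HMM recovery, and 10⁵-vector isotropic trajectory checks;
these sizes give statistically meaningful recovery checks in a few
minutes per module.

## Known limitations

* Exchange-broadened lineshapes (critical fluctuations near the miscibility
  transition), gel phases, magic-angle spinning spectra, and de-Pake-ing
  are out of scope; the package always fits the forward powder model.
* Relaxation (T₁/T₂) and the quadrupolar echo sequence are not modelled.
* The two-phase fit assumes at most two anisotropic phases plus one
  isotropic line, and a flat baseline.
* The per-carbon ±0.01 recovery guarantee degrades for phases holding
  less than ~25 % of the signal at SNR 50 (estimator variance, see above).
* The HMM assumes Gaussian emissions and a scalar per-lipid observable;
  mixture emissions and vector observables are extension points.
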