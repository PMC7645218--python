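# lipidphase

Analysis of lipid phase coexistence from solid-state ²H NMR lineshapes and
molecular-dynamics observables.

Ternary "raft" membranes (an unsaturated phosphatidylcholine, a
sphingomyelin, and cholesterol) separate into coexisting liquid-ordered
(L_o) and liquid-disordered (L_d) phases. When domains are large, lateral
lipid exchange is slow on the NMR timescale and the ²H NMR spectrum of a
perdeuterated lipid is the superposition of one complete lineshape per
phase. This package provides the computational toolchain for that
situation, for spectroscopists and simulators working on membrane domain
structure:

* **Forward simulation** of quadrupolar-echo ²H NMR powder spectra as
  superpositions of Pake doublets: per deuterated carbon, the free
  induction decay is the powder average
  `∫₀^90° cos(2π·(3/4)χ·P₂(cosθ)·S_CD·t)·sinθ dθ · exp(−π·LB·t)` with
  χ = 167 kHz, giving horns at ±(3/8)χ|S_CD| (splitting (3/4)χ|S_CD|).
* **Two-phase spectral decomposition**: a global, deterministic fit that
  recovers phase fractions, per-carbon order profiles |S_CD(c)| for each
  phase, line broadenings, and an optional isotropic line
  (convex dictionary inversion → knee-position enumeration → annealed
  trust-region polish; see `docs/methods.md`).
* **Chain structure** from order profiles via the first-order mean-torque
  model: projected chain length ⟨L⟩ = Σ 1.27 Å·⟨cosβ⟩ with
  ⟨cosβ⟩ = (1 + √((8|S|−1)/3))/2, and mean gauche-defect counts at
  1.1 Å of shortening per defect.
* **Trajectory order parameters**: per-carbon S_CD = ⟨P₂(cosθ_CH)⟩ and
  per-lipid instantaneous chain order from C–H bond-vector tables.
* **Hidden-Markov state classification** of per-lipid order time series
  into disordered / intermediate / ordered states (pooled Gaussian HMM,
  batched Baum–Welch/Viterbi).
* **Synthetic data generators** with exact ground truth for all of the
  above, including presets that emulate POPC/PSM/cholesterol (4/4/2)
  spectra with and without 9 mol% serotonin.

## Worked example

Generate a synthetic two-phase spectrum (60 % disordered / 40 % ordered
palmitoyl-d31, the serotonin-containing POPC scenario), decompose it, and
derive chain structure:

```bash
lipidphase synth --preset popc_5ht --seed 7 --out-dir demo
lipidphase fit --spectrum demo/spectrum.txt --chain palmitoyl-d31 --out-dir demo
lipidphase structure --profile demo/profile_II.csv --out demo/structure_II.csv
```

which prints

```
         phase  fraction  percent
I (disordered)       0.6       60
  II (ordered)       0.4       40
     isotropic       0.0        0
fractions (I / II / iso): 60 / 40 / 0
<L> = 14.41 A of 19.05 A all-trans; 4.22 gauche defects
```

The fit recovered the generator's phase fractions (60/40) exactly; the
ordered-phase palmitoyl chain (plateau |S_CD| = 0.34) has a projected
length of 14.41 Å out of the 19.05 Å all-trans maximum, i.e. on average
4.2 gauche defects per chain — the ordered phase is extended, while the
same derivation on the disordered profile (`profile_I.csv`, plateau 0.19)
gives 11.49 Å and 6.9 defects. Everything is also available as a library:

```python
from lipidphase import PRESETS, FitConfig, fit_two_phase, gen_two_phase_spectrum

spectrum, truth = gen_two_phase_spectrum(PRESETS["popc_5ht"])
fit = fit_two_phase(spectrum, FitConfig(chain="palmitoyl-d31"))
print(fit.fraction_I, fit.profile_II.orders)
```

The other subcommands: `simulate` (forward spectra), `series`
(temperature series of fits), `mdorder` (order parameters from
bond-vector tables), `hmm` (state classification of per-lipid order
series).

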