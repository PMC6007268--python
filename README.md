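# nnmelt

RNA nearest-neighbor (NN) thermodynamic parameters fit **directly to optical
melting curves** with a no-slip duplex partition function, instead of the
classical two-state (all-or-none) assumption.

An RNA duplex in solution populates an ensemble of pairing states: fully
paired, frayed at the ends, or interrupted by symmetric disordered internal
loops. `nnmelt` models each melting curve as the ensemble-averaged fraction
of maximal base pairs — a partition function over all no-slip pairing states
combined with the bimolecular strand-association mass balance — and fits the
40 NN parameters (ΔH°, ΔS° for 10 Watson-Crick stacks, intermolecular
initiation, terminal A-U pairs, and 8 disordered-loop lengths) to all curves
at once by trust-region nonlinear least squares. The classical two-state
analyses (per-curve van't Hoff fits and the error-weighted linear NN
regression) are included as the comparison baseline, along with multistart
convergence checks, leave-one-duplex-out jackknife resampling, RMSD/Tm
benchmarking with paired one-tailed t-tests, and a seeded synthetic-melt
generator so the whole pipeline is testable end to end.

## Layout

| module | what it does |
| --- | --- |
| `nnmelt.melt_io` | melt-curve CSV I/O, linear baseline fitting, absorbance → fraction-paired transform, experimental Tm by interpolation |
| `nnmelt.thermo_model` | duplex/parameter data model, canonical stack naming, NN decomposition, per-structure energies, brute-force state enumerator (the oracle) |
| `nnmelt.partition` | partition function via left/right recursions, conditional pair probabilities, probability of ≥1 pair at strand concentration C_T, model curves, predicted Tm |
| `nnmelt.fitting` | ensemble NLLS fit, multistart protocol, two-state NN regression and per-curve fits, jackknife, RMSD, t-tests, benchmark report |
| `nnmelt.synthetic_data` | seeded synthetic melting corpora (transition + sloping baselines + noise) |
| `nnmelt.cli` | `nnmelt` command-line interface |
| `nnmelt.datasets` | bundled 34-duplex benchmark top strands and the published two-state literature NN set |

## CLI

```bash
# generate a synthetic corpus (melt CSVs + manifest + generating truth)
nnmelt simulate --out work/sim --seed 1 --n-duplexes 12 --n-concentrations 4

# transform absorbance curves to fractions and tabulate experimental Tm
nnmelt convert --manifest work/sim/manifest.csv --out work/conv

# fit the 40 NN parameters to the corpus
nnmelt fit --manifest work/sim/manifest.csv --params work/sim/truth_params.csv \
           --out work/fit --seed 1

# multistart convergence check (perturb the initialization by +/-20%)
nnmelt multistart --manifest work/sim/manifest.csv --n-starts 20 --perturb 0.2 \
                  --out work/ms --seed 1

# leave-one-duplex-out jackknife
nnmelt jackknife --manifest work/sim/manifest.csv --out work/jk

# compare parameter sets (two-state sets get the loop-forbidding preset
# dH = 10.0 kcal/mol, dS = -1.0 cal/(mol.K) via --two-state-preset)
nnmelt benchmark --manifest work/sim/manifest.csv \
                 --params fitted work/fit/fitted_params.csv \
                 --params literature lit.csv --two-state-preset --out work/bench

# NN feature occurrence totals (bundled 34-duplex benchmark set)
nnmelt count --builtin
```

Melt files are two-column CSV (`temperature_C,absorbance_AU`, `#` comments);
the manifest CSV has columns `curve_id,duplex_id,top_strand,path,c_t` with
optional per-curve baseline-window overrides `lower_frac,upper_frac`.
NN parameter tables are CSV with columns `feature,dH_kcal_mol,dS_cal_mol_K`.

## Notes

* Temperatures are °C at every interface and kelvin internally.
* Fractions are deliberately **not** clamped to [0, 1]; the fit must see real
  noise excursions.
* Self-complementary duplexes are detected from the sequence and carry a
  fixed symmetry entropy ΔS = −1.377 cal/(mol·K) (−R ln 2) per structure,
  plus the self-complementary form of the strand-association mass balance.
* ΔH°/ΔS° from melting data are strongly correlated; compare parameter sets
  through ΔG°37, which the fit reports alongside the raw parameters.
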