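# holostim

Modeling and analysis of two-photon holographic **ensemble photostimulation**
experiments in mouse primary visual cortex (V1), layer 2/3.

In these experiments, small groups ("ensembles", typically ten cells) of
opsin-expressing excitatory neurons are photoactivated while the surrounding
population is read out with calcium imaging across three 800 × 800 µm planes.
Because no visual stimulus is shown, the measured modulation of nontargeted
cells isolates the *recurrent* circuit response: who gets amplified, who gets
suppressed, and how that depends on (i) physical distance to the stimulated
ensemble, (ii) the ensemble's spatial spread, and (iii) the match between the
orientation preference of a cell and that of the ensemble.

`holostim` provides, for researchers working with such read/write datasets or
modeling recurrent cortical circuits:

* **A linearized 2-D neural-field model** of L2/3 with joint space- and
  feature-dependent wiring.  Connectivity between populations α, β is
  separable, `W_αβ = w_αβ · g(r; σ_β, κ_β) · h_β(Δθ) / z`, with a two-scale
  spatial profile `g(r) = (1−κ)/(2πσ_b²)·e^{−r²/(2σ_b²)} +
  κ/(2πσ_n²)·e^{−r²/(2σ_n²)}` and an orientation profile
  `h(Δθ) = r₀ + r_p·e^{−Δθ²/(2σ_θ²)}`.  Photostimulation enters as point
  masses `r_stim = 10·δ(x−x_i)` at the targeted locations, and the
  steady-state rate perturbation is solved per Fourier mode,
  `Δr̃ = (I − W̃)⁻¹·W̃·r̃_stim`, or through the synaptic-pathway expansion
  `Δr_e ≈ (W_ee + W_ee∗W_ee)∗r_stim + W_ei∗W_ie∗r_stim`
  (monosynaptic E→E, disynaptic E→E→E, disynaptic E→I→E).
* **The trace-level analysis pipeline**: ΔF/F with neuropil subtraction and a
  rolling 10th-percentile baseline; orientation tuning and OSI
  (`(PO − OO)/(PO + OO)`); the full FOV → ensemble → trial → cell exclusion
  cascade with an audit log; distance-resolved response curves (15 µm bins of
  the minimal 3-D distance to any target); sum-of-two-Gaussians
  (center–surround) fits `f(d) = A₁e^{−(d/σ₁)²} + A₂e^{−(d/σ₂)²}` with their
  zero crossing and activation/suppression ratio; bootstrap-CI + FDR
  significance calls; and PPSF (photostimulation point-spread function)
  Gaussian fits.
* **An ensemble-design optimizer** that picks target groups matching
  requested spread and tuning windows by seeded greedy swaps under a 30 µm
  minimum pair-distance constraint.
* **A synthetic-data generator** that emulates the full experiment (cell
  tables, tuning blocks, stimulation trials, suite2p-style F/Fneu traces at
  ~6 Hz) from a known ground truth, so every stage is testable end to end.

## Worked example

```python
from holostim import DoGFit, dog_summary
from holostim.config import GeneratorConfig
from holostim.pipeline import run_end_to_end

# Center-surround summary of a fitted spatial response curve
fit = DoGFit(0.196, 22.1, -0.021, 147.3)
crossing, ratio = dog_summary(fit)
print(f"zero crossing: {crossing:.1f} um   activation/suppression ratio: {ratio:.2f}")

# Full synthetic session -> analysis -> recovery of the generating profile
report = run_end_to_end(
    GeneratorConfig(n_cells_per_plane=300, n_ensembles=8, random_seed=7)
)
f, t = report["fit"], report["truth"]
print(f"recovered A1={f['a1']:.3f} s1={f['sigma1']:.1f} A2={f['a2']:.4f} s2={f['sigma2']:.1f}")
print(f"true      A1={t['a1']:.3f} s1={t['sigma1']:.1f} A2={t['a2']:.4f} s2={t['sigma2']:.1f}")
```

prints

```
zero crossing: 33.4 um   activation/suppression ratio: 9.79
recovered A1=0.208 s1=19.9 A2=-0.0207 s2=149.4
true      A1=0.200 s1=20.0 A2=-0.0200 s2=150.0
```

The first line summarizes the canonical center–surround response: nontarget
cells closer than ~33 µm to the stimulated ensemble are activated and cells
beyond are suppressed, with peak activation ~10× the deepest suppression.
The remaining lines show the analysis pipeline recovering the generating
center–surround parameters from noisy synthetic traces after the exclusion
cascade.

### Command line

```bash
holostim simulate --seed 1 --out data/          # synthetic experiment
holostim analyze --data data/ --out results/    # curves.csv, fits.json, audit.json
holostim design --cells data/cells.csv --out ensembles.csv
holostim model sweep --values 0.1,0.2,0.3 --kappas 0,0.3 --out sweep.csv
holostim model respond --ensemble targets.csv --out field.h5
holostim compare --truth data/truth.json --results results/ --out report.json
```

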