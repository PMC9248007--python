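# endorkit

Pulsed-EPR distance analysis for radical pairs at a protein subunit
interface: **¹⁹F Mims ENDOR** simulation and conformer-population fitting,
and **PELDOR/DEER** inversion to distance distributions.

## The problem

In class Ia ribonucleotide reductase, radical transfer between the β and α
subunits passes through a chain of tyrosines (…Y₃₅₆•–Y₇₃₁–Y₇₃₀…). Whether
Y₇₃₁ stacks against Y₇₃₀ or flips toward the subunit interface decides
between competing proton-coupled electron-transfer mechanisms. Labelling
Y₇₃₁ with two ring fluorines turns this geometric question into a
spectroscopic one: each ¹⁹F couples to the trapped Y₃₅₆• radical through
the dipolar hyperfine interaction, whose size encodes distance and whose
orientation (relative to the radical's g frame) is read out by
orientation-selective ENDOR at high field. A companion PELDOR measurement
fixes the long diagonal radical–radical distance in the complex.

The toolkit implements the full inference chain on synthetic data with
known ground truth:

* **Point-dipole distances** — `T = C/R³` with
  `C = (μ0/4π)·g_e·μB·g_n·μN/h ≈ 7.44·10⁴ kHz·Å³` for ¹⁹F, referenced to
  the radical ring centroid (O, C1, C3, C5). A 250 kHz coupling ↦ 6.7 Å;
  150 kHz ↦ 7.9 Å.
* **Pake patterns** — powder lineshapes of axial tensors; perpendicular
  singularities split by `|a_iso − T|`, parallel shoulders by
  `|a_iso + 2T|`, with a splitting reader that corrects the known
  convolution bias of powder edges.
* **Mims ENDOR** — first-order powder simulation with Gaussian orientation
  selection (g anisotropy + strongly coupled β proton) and the
  `½ sin²(π a τ)` blind-spot response; 25/250 kHz linewidth rule;
  observer-position and two-τ composition.
* **Conformer-ratio fit** — a single flipped-fraction parameter fitted
  globally across all observer positions and τ settings by an rmsd scan
  with parabolic refinement.
* **DEER** — Fresnel-form dipolar kernel, exponential-background
  correction, nonnegative Tikhonov inversion with L-curve α selection.

## Worked example

```python
import numpy as np
from endorkit import (NucleusSpec, build_axial_hyperfine, distance_from_coupling,
                      pake_pattern, read_splitting)

f19 = NucleusSpec.from_isotope("19F")

# measured perpendicular splittings -> centroid distances
print(round(distance_from_coupling(250.0, f19), 1))   # 6.7  (A)
print(round(distance_from_coupling(150.0, f19), 1))   # 7.9  (A)

# proximal-fluorine parameters (T = 1.0 MHz, a_iso = -0.8 MHz): what
# splitting does the powder spectrum show?
pattern = pake_pattern(build_axial_hyperfine(1000.0, -800.0), f19,
                       linewidth_khz=250.0, axis_mhz=np.arange(-4, 4.001, 0.02))
print(round(read_splitting(pattern.axis_mhz, pattern.intensity,
                           linewidth_khz=250.0), 2))  # 1.79 (MHz)
```

The three printed numbers are the two fluorine–radical distances implied by
the measured 250/150 kHz couplings and the ~1.8 MHz peak separation that
the strongly coupled proximal fluorine produces in the wide-window spectra.

The same chain is packaged as a CLI:

```
endorkit distance --coupling-khz 250 --nucleus 19F     # -> 6.7
endorkit gen-synthetic --kind deer --noise-sigma 0 --outdir out/
endorkit invert-deer --trace out/deer_trace.dat --out report.json
```

## Analysis scripts

`analysis/` holds the numbered drivers that reproduce the individual
analyses end to end, writing tables under `results/`:

1. `01_point_dipole_distances.py` — couplings → distances with error
   propagation;
2. `02_pake_patterns.py` — powder patterns and splitting read-back;
3. `03_simulate_endor.py` — orientation-selective spectra of both
   conformers at three observers × two τ, plus EPR-weighted sums;
4. `04_fit_conformer_ratio.py` — synthetic 25%-flipped dataset with 5%
   noise and contaminant background → background subtraction → global
   ratio fit;
5. `05_invert_deer.py` — synthetic PELDOR trace (3.03 nm / 0.12 nm truth)
   → Tikhonov distance distribution.

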