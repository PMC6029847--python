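# fibromech

Multiscale structure-function analysis of fibrillar collagen in fibrotic
tissue, for researchers doing tissue biomechanics and extracellular-matrix
biochemistry. The package covers the full measurement chain used to show
that tissue stiffening in lung fibrosis tracks mature collagen cross-linking
rather than collagen amount:

- **AFM force-curve analysis** — contact-point detection, force-indentation
  conversion, Hertz sphere fits for tissue microindentation
  (F = (4/3)·(E/(1−ν²))·√R·δ^{3/2}), Oliver–Pharr analysis of single-fibril
  nanoindentation unloading (P = α(h−h_f)^m, S = dP/dh at h_max,
  h_c = h_max − ε·P_max/S, M = √π·S / (2β·√A(h_c)) with a blunted-cone area
  function), and elastograph (stiffness map) statistics including the
  coefficient of variation.
- **Fibril morphometry** — axial D-period estimation (~67 nm type-I collagen
  repeat) by normalised autocorrelation with sub-pixel refinement, fibril
  diameter as background-corrected height, hydrated/dry swelling ratio,
  diameter distributions, and TEM-style shortest-axis (minimum caliper)
  measurement of segmented cross-sections.
- **Spheroid compression** — segmentation of five-cycle parallel-plate
  tests (15 s compression to 25% engineering strain, 2 s hold, 15 s
  recovery, 2 s rest), engineering stress/strain, toe-region exclusion via
  the 10–20% strain window, and Young's modulus by inverting the two-plate
  Hertz sphere relation F = (4/3)·(E/(1−ν²))·√R·(δ/2)^{3/2} for both sample
  radii and averaging (ν = 0.5 by default).
- **Biochemistry** — hydroxyproline→collagen conversion (300 residues,
  300 kDa per triple helix), DHLNL/HLNL/PYD/DPD cross-link densities per mole
  of collagen with immature/mature and DHLNL/HLNL ratios, sequential-
  extraction solubility fractions, and ΔΔCt relative gene expression
  (2^(−ΔΔCt), housekeeping-normalised, group geometric means).
- **Statistics** — Welch/Student/one-sample t and exact or tie-corrected
  Mann–Whitney tests, step-down Holm–Šidák adjustment, one-way and
  repeated-measures ANOVA with Dunnett's post-test, Kruskal–Wallis with
  Dunn's test, four-parameter-logistic IC50 fitting, and correlation
  matrices that tolerate missing cells via an EM-estimated
  multivariate-normal covariance.
- **Synthetic data** — seeded generators for every input class, each built
  on the same physical forward model its analysis inverts, with ground-truth
  sidecars; they make the whole pipeline testable by round trip.

## Worked example

```python
from fibromech import (IndenterSpec, SynthProtocol, fit_hertz_sphere,
                       synth_indentation_curve, to_force_indentation)

indenter = IndenterSpec(shape="sphere", radius_um=7.5, poisson=0.5)
curve = synth_indentation_curve(10.0, indenter, SynthProtocol(seed=1),
                                max_depth_nm=1000.0)
delta, force = to_force_indentation(curve)
result = fit_hertz_sphere(delta, force, indenter)
print(f"{curve.force_nn.max():.2f} nN, {result.modulus_kpa:.3f} kPa")
```

prints `48.69 nN, 10.000 kPa`: the force at 1 μm depth matches the Hertz
closed form for a 10 kPa sample under a 15 μm bead, and the fit recovers the
generator's modulus. The `examples/` directory holds one short script per
capability; for instance `python examples/05_cohort_statistics.py` builds a
32-donor synthetic cohort (within-group log-scale correlation 0.72 between
stiffness and mature cross-links) and reports

```
stiffness vs mature cross-links (EM-MVN): r = 0.946, p = 1e-11, n_eff = 23
stiffness vs collagen concentration     : r = 0.054, p = 0.82
```

— stiffness tracks mature pyridinoline cross-link density, not collagen
concentration (the pooled r exceeds the within-group 0.72 because both
variables also shift between groups).

A thin CLI wraps the pipeline: `fibromech simulate --kind cohort --seed 1
--out cohort.tsv`, `fibromech report-cohort --seed 1 --out report/`.

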