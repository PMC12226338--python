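# tripletrep

Analysis toolkit for **ribozyme-catalysed RNA replication with
trinucleotide (triplet) substrates under pH/freeze–thaw cycling**.

RNA replication cycles are blocked by the *strand separation problem*:
complementary product strands reanneal within minutes
(second-order, f(t) = 1/(1 + k·S0·t) at equal strand concentrations S0),
far faster than ribozyme copying. Triplet substrates hybridise to
dissociated strands and kinetically trap them single-stranded, while acid
denaturation, neutralisation and freezing into the eutectic brine phase
supply the conflicting conditions for strand separation and synthesis in
alternation. `tripletrep` implements the quantitative analyses around such
experiments, for researchers modelling or re-analysing triplet-based
replication:

- **kinetics** — the second-order reannealing closed form, least-squares
  rate fitting, and an occupancy-window model of triplet coating
  (k_eff = k · P(free window)₊ · P(free window)₋, exact DP, calibrated by
  root-finding to an observed fold-slowdown);
- **cycling** — KCl accumulation from pH switching, eutectic
  freeze-concentration factors, serial-dilution ledgers, effective
  amplification (band fold × dilution fold), per-cycle exponents, and
  log-linear growth fits with automatic plateau exclusion;
- **pools** — exact longest-common-substring classification of emergent
  sequences against ribozyme (+)/(−) strands, positional footprint
  mapping with seeded multi-mapper assignment, per-cycle class
  proportions, Chargaff composition statistics and uniqueness;
- **codons** — the 32 family-box codons derived from the standard genetic
  code, longest family-box stretch per sequence, and matched-length
  uniform-codon null comparisons;
- **simulate** — seeded generators for all of the above, so every stage is
  testable without the original sequencing data.

## Worked example

```python
from tripletrep.kinetics import fit_k, calibrate_occupancy
from tripletrep.simulate import gen_delay_series

series = gen_delay_series(k=0.7, s0=1.0,
                          delays=[0, 0.5, 1, 2, 4, 8, 15, 30, 60, 120],
                          noise_sd=0.01, seed=1)
fit = fit_k(series, s0=1.0)
print(f"k = {fit.k:.3f} /(uM min), R^2 = {fit.r_squared:.4f}")
theta = calibrate_occupancy(1/200, n_sites=10, w_sites=2)
print(f"theta for 200-fold slowdown: {theta:.3f}")
```

prints

```
k = 0.695 /(uM min), R^2 = 0.9996
theta for 200-fold slowdown: 0.976
```

— the fitted rate constant recovers the generating 0.7 µM⁻¹ min⁻¹ within
1%, and a per-site triplet occupancy of 0.976 on one strand suffices to
slow reannealing 200-fold in the window model (both strands coated:
200² = 40,000-fold).

The `examples/` directory holds one narrative script per capability
(`reannealing_kinetics.py`, `cycle_accounting.py`,
`pool_classification.py`, `codon_drift.py`); each builds a small input,
runs the method and explains the numbers it prints. A `tripletrep` CLI
exposes the same operations from a shell (`tripletrep --help`), and
`tripletrep run --seed N --out DIR` executes the full demo pipeline with a
reproducibility manifest.

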