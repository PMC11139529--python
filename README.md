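# herbqc

Multicomponent quality evaluation of herbal materials, built around four
analysis stages plus a synthetic-data generator:

- **annotation** — theoretical monoisotopic masses and negative-mode adduct
  m/z ([M−H]⁻, [M+HCOO]⁻) from elemental formulas; peak annotation scored as
  mass error in mDa (electron-inclusive ion masses).
- **qams** — calibration fitting, slope-ratio relative correction factors
  (f = F_reference / F_analyte), relative-retention-time peak location,
  external-standard and single-marker (QAMS) content calculation, and
  method-validation statistics (spike recovery, RSD, durability).
- **network** — target-set intersection, six PPI centralities (DC, CC, BC,
  EC, LAC, NC) with inclusive median-threshold screening, and a
  hypergeometric over-representation test with Benjamini–Hochberg
  adjustment.
- **chemometrics** — autoscaling, hierarchical clustering (squared
  Euclidean, between-groups linkage), correlation PCA with
  contribution-weighted composite scores and ranks, OPLS-DA with 7-fold
  cross-validated Q², permutation testing, VIP, and pooled-variance
  t-tests.
- **simulate** — seeded generators for calibration series, multi-batch
  content tables with planted group structure and outliers, spike-recovery
  designs, and random interaction graphs.
- **datasets** — a bundled published Turkish gall (*Quercus infectoria*)
  reference dataset (compound table, calibration lines, recovery rows,
  durability series, batch contents, PCA summaries) used by the tests and
  example workflows.

## Command-line interface

The `herbqc` entry point exposes one subcommand per stage; every run logs
its seed and settings to `run.log` in the output directory.

```sh
# generate a complete synthetic dataset
herbqc simulate --seed 1 --noise-cv 0.01 --out-dir out/sim

# fit calibration curves and correction factors
herbqc calibrate --calibration out/sim/calibration.csv --reference GA --out-dir out

# quantify batches by both methods
herbqc quantify --calibration out/sim/calibration.csv \
    --batches out/sim/batch_peaks.csv --reference GA --out-dir out

# method validation
herbqc validate --calibration out/sim/calibration.csv --out-dir out

# annotate a compound table (peak_no,rt_min,observed_mz,adduct,formula,...)
herbqc annotate --peaks peaks.csv --tolerance-mda 5 --out-dir out

# centralities + median screening of an edge list
herbqc network --edges edges.txt --out-dir out

# clustering, PCA scoring and OPLS-DA of a batch matrix
herbqc chemometrics --matrix out/sim/batch_matrix.csv \
    --groups groups.csv --n-perm 200 --seed 1 --out-dir out
```

## Layout

```
src/herbqc/        annotation, qams, network, chemometrics, simulate,
                   datasets, cli
tests/             unit + property tests per module, test_acceptance.py
scripts/           acceptance.py
```
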