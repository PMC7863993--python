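# ffbench

Benchmarking pipeline for comparing force-field-minimized conformer
ensembles against QM reference ensembles:

- **Molecule identity & grouping** (`ffbench.io_dataset`): V2000 SDF I/O with
  per-record energy tags, canonical connectivity keys (tautomers are distinct
  molecules), grouping of conformers into molecules with the lowest-QM-energy
  member as reference.
- **Geometry metrics** (`ffbench.geometry_metrics`): symmetry-aware minimum
  RMSD (Kabsch over graph automorphisms, hydrogens included) and a torsion
  fingerprint deviation (TFD) in [0, 1] with Gaussian topological weighting.
- **Energy metrics** (`ffbench.energy_metrics`): per-structure relative energy
  differences (ddE) anchored at the lowest-QM-energy conformer, per-molecule
  mean signed deviation (MSD) over matched conformers, fraction-within
  summaries with binomial errors, extrema/pathology reporting.
- **Conformer matching** (`ffbench.conformer_matching`): nearest-reference
  pairing under an RMSD threshold (default 1.0 Å) with lowest-RMSD
  deduplication; optional optimal bipartite assignment.
- **Parameter enrichment** (`ffbench.parameter_enrichment`): representation
  ratios of force-field parameters among high-TFD molecules (cutoff 0.12),
  one-sample Z-test for proportions with Wald 95% CIs, small-sample
  exclusion (≤ 20 subset molecules), substructure tagging (N–N single bond,
  azetidine).
- **Synthetic data** (`ffbench.synthetic_data`): seeded generator of complete
  benchmark datasets with known ground truth — valence-legal molecules,
  toy 3-D conformers, per-force-field geometry perturbations and energy
  biases, tautomer flips, hydrogen-collapse pathologies, planted parameter
  enrichment.
- **Pipeline & CLI** (`ffbench.cli_reporting`): orchestration and CSV/JSON
  report export (histograms, MSD tables, ddE-vs-TFD scatter densities,
  enrichment reports, accounting metadata).

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (RMSD oracle
equivalence, metric contracts, closed-form energy checks, matching
accounting, planted bias/enrichment/pathology recovery, Z-test closed form,
end-to-end determinism). The full suite takes a few minutes on one CPU.

## CLI

Generate a synthetic benchmark dataset (writes `qm.sdf`, `ff_<name>.sdf`,
`assignments.csv`, `truth.json`):

```bash
ffbench synth --seed 7 --out data/            # default config
ffbench synth --config cfg.yaml --out data/   # explicit config
```

Run the full analysis:

```bash
ffbench run --qm data/qm.sdf \
    --ff ffA=data/ff_ffA.sdf --ff ffB=data/ff_ffB.sdf --ff ffC=data/ff_ffC.sdf \
    --assignments data/assignments.csv \
    --rmsd-threshold 1.0 --tfd-cutoff 0.12 --within 1.0 \
    --alpha 0.05 --min-subset 21 \
    --out report/ -v
```

The report directory contains `group_manifest.csv`, `geometry_metrics.csv`,
per-force-field `energy_*.csv`, `matches_*.csv`, `msd_*.csv`,
`dde_histogram_*.csv`, `dde_vs_tfd_*.csv`, `enrichment_*.csv`, plus
`summary.csv`, `pathological.csv`, `substructure_tags.csv` and
`metadata.json`.

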