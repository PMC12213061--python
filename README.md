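# mockforge

Toolkit for designing, quantifying and quality-controlling bacterial
mock communities (defined cell or DNA mixtures used as ground-truth
controls for metagenomic sequencing).

It covers the full desk-side workflow:

* **strain_registry** — strain metadata (genome size, GC content, 16S
  copy number) with a packaged 15-strain fixture, plus derived constants
  (adenines per genome, genome mass via the 660 g/mol/bp convention).
* **enumeration** — converts raw measurements into concentrations:
  adenine-HPLC readings to genome copies (residue-count reference route
  and a dNMP-mass cross-check route), bead-calibrated flow-cytometry
  events and microscope field counts to cell concentrations, with OD600
  normalization and replicate aggregation.
* **mix_design** — mixing recipes by exact mass balance: cell mocks
  (default 4×10¹⁰ copies mL⁻¹ community total, 100 × 100 µL aliquots)
  and equimolar-genome DNA mocks (default 50 ng µL⁻¹ total, 50 × 30 µL),
  with independent recipe verification.
* **readout** — assay outputs to relative abundances: ddPCR droplet
  counts via Poisson estimation (λ = −ln(1 − positive fraction)) and
  kallisto `abundance.tsv` count tables (genome-normalized or raw).
* **qc_stats** — per-strain coefficient of variation across batches,
  absolute fold difference against the theoretical composition
  (fold ≥ 1 or |log2| modes), and Welch's t-tests between labeled
  conditions.
* **synthetic_data** — seeded generators for every input (adenine,
  cytometry, ddPCR wells, sequencing counts) plus an end-to-end study
  simulator with per-channel noise and extraction bias; exact
  round-trips at zero noise.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (registry
fidelity, recipe mass balance, adenine route equivalence, ddPCR
estimator recovery, end-to-end parameter recovery, and the two-condition
reproducibility comparison).

## CLI

```sh
mockforge registry                            # validate/show the packaged registry
mockforge quantify hplc --input hplc.tsv --out conc.tsv
mockforge quantify fcm --input fcm.tsv --out conc.tsv --od600 1.0
mockforge design cell-mock --stocks stocks.tsv --design design.yaml --out recipe.tsv
mockforge design dna-mock  --stocks dna.tsv --design design.yaml --out recipe.tsv
mockforge ddpcr --input wells.tsv --out abundance.tsv
mockforge seqabund --input abundance.tsv --map targets.tsv --out ab.tsv
mockforge qc --abundance ab.tsv --expected 0.066667 \
    --compare cell_hplc:shotgun/cell_fcm:shotgun --out report.json
mockforge simulate --config sim.yaml --out simdir/
```

All tables are UTF-8 tab-separated with a header row. Design and
simulation configs are flat YAML documents mirroring the `MockDesign`
and `SimulationConfig` fields.

A typical pipeline smoke test:

```sh
printf 'seed: 1\n' > sim.yaml
mockforge simulate --config sim.yaml --out simdir
mockforge qc --abundance simdir/abundance.tsv --expected 0.0666667 \
    --compare cell_hplc:shotgun/cell_fcm:shotgun --out report.json
```

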