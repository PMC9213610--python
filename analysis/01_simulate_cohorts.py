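#!/usr/bin/env python
"""Simulate the two synthetic cohorts used throughout the analysis.

Cohort A (pan-tissue): one opossum-like species (4.2-year lifespan), two
tissues, 80 samples, 2000 probes, 10% age-related — the substrate for QC,
the pan-tissue clock and the per-tissue EWAS.

Cohort B (dual-species): a short-lived (4.2 y) and a long-lived (122.5 y)
species with a 12-vs-36 sample imbalance and weak (20%) cross-species
sharing of age-related probes — the substrate for the two dual-species
clocks.

Writes both cohorts as TSV sets under results/data/.
"""

from pathlib import Path

from crossclock.synthetic_data import simulate_dataset, export_fixture
from crossclock.validation import dual_species_config, strong_signal_config

OUT = Path("results/data")

for name, cfg in (
    ("cohort_a_pan_tissue", strong_signal_config(seed=11)),
    ("cohort_b_dual_species", dual_species_config(seed=11)),
):
    dataset = simulate_dataset(cfg)
    paths = export_fixture(dataset, OUT / name)
    matrix, sheet, _, truth = dataset
    n_aging = (truth.probes["true_slope"] != 0).sum()
    print(
        f"{name}: {matrix.n_probes} probes x {matrix.n_samples} samples, "
        f"{n_aging} age-related probes -> {OUT / name}"
    )
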