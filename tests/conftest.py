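import numpy as np
import pandas as pd
import pytest

from crossclock.io_formats import (
    ANNOTATION_COLUMNS,
    MethylationMatrix,
    ProbeAnnotation,
    SampleSheet,
)
from crossclock.synthetic_data import SimulationConfig, SpeciesSpec, simulate_dataset


def make_annotation(records: list[dict]) -> ProbeAnnotation:
    """Build a ProbeAnnotation from partial per-probe dicts with defaults."""
    defaults = {
        "assembly": "TestGenome.v1",
        "chrom": "chr1",
        "pos": 100,
        "strand": "+",
        "mappable_species": frozenset({"opossum"}),
        "island_flag": False,
        "tss_category": "distal",
        "chromatin_state": "Quies",
        "prc2_bound": False,
        "gene_symbol": "GENE1",
    }
    rows = []
    for i, rec in enumerate(records):
        row = {"probe_id": f"cg{i:03d}", **defaults, **rec}
        row["mappable_species"] = frozenset(row["mappable_species"])
        rows.append(row)
    return ProbeAnnotation(pd.DataFrame(rows)[ANNOTATION_COLUMNS])


def make_sheet(ages, species="opossum", tissue="ear", lifespan=4.2, maturity=0.5):
    ages = list(ages)
    n = len(ages)
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "species": species,
            "tissue": tissue,
            "sex": (["F", "M"] * (n // 2 + 1))[:n],
            "age_years": ages,
        }
    )
    constants = pd.DataFrame(
        {
            "species": [species] if isinstance(species, str) else sorted(set(species)),
            "max_lifespan_years": lifespan,
            "maturity_years": maturity,
        }
    )
    return SampleSheet(samples, constants)


def make_matrix(values, probe_ids=None, sample_ids=None) -> MethylationMatrix:
    values = np.asarray(values, dtype=float)
    probe_ids = probe_ids or [f"cg{i:03d}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return MethylationMatrix(list(probe_ids), list(sample_ids), values)


@pytest.fixture(scope="session")
def small_dataset():
    """One-species, two-tissue dataset with known age effects (fast)."""
    cfg = SimulationConfig(
        species_specs=[SpeciesSpec("opossum", 4.2, 0.5, 15)],
        tissues=["ear", "liver"],
        n_probes=250,
        frac_age_related=0.2,
        frac_shared_age=1.0,
        seed=11,
    )
    return simulate_dataset(cfg)
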