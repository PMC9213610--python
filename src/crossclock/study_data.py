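"""Published study constants shipped with the package.

Two small tables travel with the code: the sample inventory of the marsupial
and mouse methylation study (per species × tissue: sample count and the
mean / min / max age in years) and the anAge maximum-lifespan constants used
for relative age.  They support worked examples and the reproduction
script's in-study arithmetic; none of the statistics depend on them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    with resources.files("crossclock.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh, sep="\t")


def load_study_inventory() -> pd.DataFrame:
    """Per species × tissue sample counts and age ranges of the study."""
    return _read("study_inventory.tsv")


def load_anage_lifespans() -> pd.DataFrame:
    """anAge maximum lifespans (years) for the dual-species clock pair."""
    return _read("anage_lifespans.tsv")


def species_sample_total(species: str) -> int:
    """Total samples for one species, summed over its tissue rows."""
    inv = load_study_inventory()
    rows = inv.loc[inv["species"] == species]
    if rows.empty:
        raise KeyError(f"species {species!r} not in the study inventory")
    return int(rows["n_samples"].sum())


def lifespan_ratio(species_long: str = "Human", species_short: str = "Opossum") -> float:
    """Ratio of two species' maximum lifespans (long / short)."""
    t = load_anage_lifespans().set_index("species")["max_lifespan_years"]
    return float(t[species_long] / t[species_short])
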