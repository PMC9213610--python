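"""Tabular I/O for methylation matrices, sample sheets and probe annotations.

All on-disk formats are plain TSV (UTF-8, ``.`` decimal).  The beta matrix is
stored probes-as-rows / samples-as-columns, mirroring the array-export
convention (probe count is typically orders of magnitude above sample count).
Coordinates in annotation tables are 1-based inclusive; BED export converts to
0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: tolerance for the [0, 1] bound check on beta values (float round-trip slack)
BETA_BOUND_TOL = 1e-9

TSS_CATEGORIES = frozenset(
    {"promoter", "5'UTR", "exon", "intron", "3'UTR", "downstream", "distal"}
)

ANNOTATION_COLUMNS = [
    "probe_id",
    "assembly",
    "chrom",
    "pos",
    "strand",
    "mappable_species",
    "island_flag",
    "tss_category",
    "chromatin_state",
    "prc2_bound",
    "gene_symbol",
]


class ValidationError(ValueError):
    """Raised when an on-disk table violates its schema or invariants."""


@dataclass
class MethylationMatrix:
    """Beta values (methylated fraction, in [0, 1]) for probes × samples.

    ``values`` is a float array of shape ``(n_probes, n_samples)``; missing
    cells are ``NaN``.  Downstream statistics use pairwise-complete samples
    and record the n actually used.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.probe_ids)} probes, {len(self.sample_ids)} samples)"
            )
        for name, ids in (("probe", self.probe_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = pd.Index(ids)[pd.Index(ids).duplicated()].tolist()
                raise ValidationError(f"duplicate {name} ids: {dupes[:5]}")
        _check_beta_range(self.values, self.probe_ids, self.sample_ids)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.probe_ids, name="probe_id"),
            columns=self.sample_ids,
        )

    def subset_probes(self, probe_ids: list[str]) -> "MethylationMatrix":
        """Return the sub-matrix for ``probe_ids``, preserving their order."""
        idx = pd.Index(self.probe_ids).get_indexer(probe_ids)
        if (idx < 0).any():
            missing = [p for p, i in zip(probe_ids, idx) if i < 0]
            raise KeyError(f"probes not in matrix: {missing[:5]}")
        return MethylationMatrix(list(probe_ids), list(self.sample_ids), self.values[idx])

    def subset_samples(self, sample_ids: list[str]) -> "MethylationMatrix":
        idx = pd.Index(self.sample_ids).get_indexer(sample_ids)
        if (idx < 0).any():
            missing = [s for s, i in zip(sample_ids, idx) if i < 0]
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return MethylationMatrix(list(self.probe_ids), list(sample_ids), self.values[:, idx])

    def equals(self, other: "MethylationMatrix", tol: float = 1e-12) -> bool:
        return (
            self.probe_ids == other.probe_ids
            and self.sample_ids == other.sample_ids
            and np.allclose(self.values, other.values, atol=tol, equal_nan=True)
        )


@dataclass
class SampleSheet:
    """Per-sample metadata joined with per-species lifespan constants.

    ``samples`` columns: sample_id, species, tissue, sex, age_years.
    ``species_constants`` columns: species, max_lifespan_years, maturity_years.
    """

    samples: pd.DataFrame
    species_constants: pd.DataFrame
    n_dropped_missing_age: int = 0

    def __post_init__(self) -> None:
        s = self.samples
        if s["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in sample sheet")
        if (s["age_years"] < 0).any():
            bad = s.loc[s["age_years"] < 0, "sample_id"].tolist()
            raise ValidationError(f"negative age for samples {bad[:5]}")
        c = self.species_constants
        if not ((c["max_lifespan_years"] > 0) & (c["maturity_years"] > 0)).all():
            raise ValidationError("lifespan constants must be positive")
        if not (c["maturity_years"] < c["max_lifespan_years"]).all():
            raise ValidationError("maturity_years must be below max_lifespan_years")
        missing = set(s["species"]) - set(c["species"])
        if missing:
            raise ValidationError(f"species without lifespan constants: {sorted(missing)}")

    @property
    def sample_ids(self) -> list[str]:
        return self.samples["sample_id"].tolist()

    def constants_for(self, species: str) -> tuple[float, float]:
        """Return (max_lifespan_years, maturity_years) for ``species``."""
        row = self.species_constants.loc[self.species_constants["species"] == species]
        if row.empty:
            raise KeyError(f"no constants for species {species!r}")
        return float(row["max_lifespan_years"].iloc[0]), float(row["maturity_years"].iloc[0])

    def subset(self, mask_or_ids) -> "SampleSheet":
        if isinstance(mask_or_ids, (list, pd.Index)):
            sub = self.samples.set_index("sample_id").loc[list(mask_or_ids)].reset_index()
        else:
            sub = self.samples.loc[mask_or_ids].reset_index(drop=True)
        return SampleSheet(sub, self.species_constants)


@dataclass
class ProbeAnnotation:
    """Per-probe genomic and regulatory annotation.

    ``table`` columns follow :data:`ANNOTATION_COLUMNS`; ``mappable_species``
    holds frozensets of species labels, ``pos`` is 1-based.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t["probe_id"].duplicated().any():
            raise ValidationError("duplicate probe_id in annotation")
        if (t["pos"] < 1).any():
            raise ValidationError("annotation pos must be >= 1 (1-based)")
        bad = set(t["tss_category"]) - TSS_CATEGORIES
        if bad:
            raise ValidationError(f"unknown tss_category value(s): {sorted(bad)}")
        if (t["assembly"].astype(str).str.len() == 0).any():
            raise ValidationError("assembly string must be non-empty")

    @property
    def probe_ids(self) -> list[str]:
        return self.table["probe_id"].tolist()

    def indexed(self) -> pd.DataFrame:
        return self.table.set_index("probe_id")

    def mappable_to(self, species: set[str] | frozenset[str]) -> list[str]:
        """Probe ids whose mappable-species set covers every requested species."""
        want = frozenset(species)
        keep = self.table["mappable_species"].map(lambda s: want <= s)
        return self.table.loc[keep, "probe_id"].tolist()


def _check_beta_range(values: np.ndarray, probe_ids, sample_ids) -> None:
    with np.errstate(invalid="ignore"):
        bad = (values < -BETA_BOUND_TOL) | (values > 1 + BETA_BOUND_TOL)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"beta value {values[i, j]!r} outside [0, 1] at probe "
            f"{probe_ids[i]!r}, sample {sample_ids[j]!r}"
        )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_beta_matrix(path: str | Path) -> MethylationMatrix:
    """Read a probes × samples beta-value TSV (first column ``probe_id``)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "probe_id":
        raise ValidationError(
            f"{path}: first column must be 'probe_id', got {df.columns[0]!r}"
        )
    sample_ids = [str(c) for c in df.columns[1:]]
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    return MethylationMatrix(df["probe_id"].tolist(), sample_ids, values)


def read_sample_sheet(path: str | Path, species_constants: str | Path) -> SampleSheet:
    """Read the sample sheet and join per-species lifespan constants.

    Samples with a missing age are dropped with a logged warning; the count of
    drops is recorded on the returned sheet.
    """
    s = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = ["sample_id", "species", "tissue", "sex", "age_years"]
    missing_cols = [c for c in required if c not in s.columns]
    if missing_cols:
        raise ValidationError(f"{path}: missing columns {missing_cols}")
    n_missing = int(s["age_years"].isna().sum())
    if n_missing:
        logger.warning("%s: dropping %d sample(s) with missing age", path, n_missing)
        s = s.loc[s["age_years"].notna()].reset_index(drop=True)
    c = pd.read_csv(species_constants, sep="\t")
    return SampleSheet(s[required], c, n_dropped_missing_age=n_missing)


def _parse_bool(col: pd.Series) -> pd.Series:
    return col.astype(str).str.upper().isin({"TRUE", "1", "T", "YES"})


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    """Read a probe annotation TSV (``mappable_species`` semicolon-separated)."""
    t = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[""])
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in t.columns]
    if missing_cols:
        raise ValidationError(f"{path}: missing columns {missing_cols}")
    t = t[ANNOTATION_COLUMNS].copy()
    t["pos"] = t["pos"].astype(int)
    t["mappable_species"] = t["mappable_species"].map(
        lambda s: frozenset(x for x in str(s).split(";") if x)
    )
    t["island_flag"] = _parse_bool(t["island_flag"])
    t["prc2_bound"] = _parse_bool(t["prc2_bound"])
    return ProbeAnnotation(t)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_beta_matrix(matrix: MethylationMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t")


def write_sample_sheet(sheet: SampleSheet, path: str | Path, constants_path: str | Path) -> None:
    sheet.samples.to_csv(path, sep="\t", index=False)
    sheet.species_constants.to_csv(constants_path, sep="\t", index=False)


def write_probe_annotation(annotation: ProbeAnnotation, path: str | Path) -> None:
    t = annotation.table.copy()
    t["mappable_species"] = t["mappable_species"].map(lambda s: ";".join(sorted(s)))
    t["island_flag"] = t["island_flag"].map({True: "TRUE", False: "FALSE"})
    t["prc2_bound"] = t["prc2_bound"].map({True: "TRUE", False: "FALSE"})
    t.to_csv(path, sep="\t", index=False)


def export_bed(annotation: ProbeAnnotation, path: str | Path) -> None:
    """Export probe coordinates as BED6 (0-based half-open: start = pos - 1)."""
    t = annotation.table
    bed = pd.DataFrame(
        {
            "chrom": t["chrom"],
            "start": t["pos"] - 1,
            "end": t["pos"],
            "name": t["probe_id"],
            "score": 0,
            "strand": t["strand"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_bed_positions(path: str | Path) -> pd.DataFrame:
    """Read a BED6 export back to 1-based coordinates (pos = start + 1)."""
    bed = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    return pd.DataFrame(
        {"probe_id": bed["name"], "chrom": bed["chrom"], "pos": bed["start"] + 1,
         "strand": bed["strand"]}
    )
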