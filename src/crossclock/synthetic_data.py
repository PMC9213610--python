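"""Synthetic multi-species, multi-tissue methylation data with known age effects.

The generator emulates the structure of conserved-probe mammalian array data:
bounded beta values, species/tissue baseline separation, a fraction of probes
whose methylation moves monotonically with age, and two annotation-coupled
aging regimes:

* ``placental_like`` — age-related probes inside CpG islands that are also
  PRC2-bound are forced to *gain* methylation with age, the pattern seen in
  placental mammals (and in kangaroos, wallabies and Tasmanian devils);
* ``opossum_like`` — island∧PRC2 probes carry no age signal at all, the
  pattern reported for opossum.

The age signal enters through relative age ``g(age) = age / max_lifespan`` on
the logit scale, so the trajectories of *shared* age-related probes coincide
across species when plotted against relative age — the premise a
relative-age clock exploits.  Sharing is partial, as in real conserved-probe
data: a fraction ``frac_shared_age`` (default 0.5) of age-related probes
carry their slope in every species, the remainder in a single species only.
Observed betas are drawn ``Beta(μφ, (1−μ)φ)``, which respects the [0, 1]
support; φ is the precision (default 50, i.e. a beta-value s.d. of ~0.07 at
μ = 0.5).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .io_formats import (
    ANNOTATION_COLUMNS,
    MethylationMatrix,
    ProbeAnnotation,
    SampleSheet,
    write_beta_matrix,
    write_probe_annotation,
    write_sample_sheet,
)

AGING_MODES = ("placental_like", "opossum_like")

#: chromatin-state vocabulary used for simulated annotations; the two
#: polycomb-associated states are assigned to PRC2-bound probes.
PRC2_STATES = ("BivProm", "ReprPC")
OTHER_STATES = ("TSS", "Enh", "Tx", "Quies")

_MU_EPS = 1e-6


@dataclass
class SpeciesSpec:
    """One simulated species: label, lifespan constants, samples per tissue."""

    label: str
    max_lifespan_years: float
    maturity_years: float
    n_samples_per_tissue: int

    def __post_init__(self) -> None:
        if self.max_lifespan_years <= 0 or self.maturity_years <= 0:
            raise ValueError("lifespan constants must be positive")
        if self.maturity_years >= self.max_lifespan_years:
            raise ValueError("maturity must be below max lifespan")
        if self.n_samples_per_tissue < 1:
            raise ValueError("need at least one sample per tissue")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic dataset; defaults give a desk-scale
    two-species, three-tissue study with a 29-fold lifespan contrast."""

    species_specs: list[SpeciesSpec] = field(
        default_factory=lambda: [
            SpeciesSpec("shortlived", 4.2, 0.5, 16),
            SpeciesSpec("longlived", 122.5, 15.0, 16),
        ]
    )
    tissues: list[str] = field(default_factory=lambda: ["ear", "liver", "tail"])
    n_probes: int = 4000
    frac_age_related: float = 0.2
    frac_shared_age: float = 0.5
    slope_range: tuple[float, float] = (1.0, 3.0)
    frac_island: float = 0.3
    frac_prc2: float = 0.3
    island_aging_mode: str = "placental_like"
    noise_precision: float = 50.0
    baseline_logit_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_age_related", "frac_shared_age", "frac_island", "frac_prc2"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        lo, hi = self.slope_range
        if not 0 < lo <= hi:
            raise ValueError("slope_range must satisfy 0 < low <= high")
        if self.noise_precision <= 0:
            raise ValueError("noise_precision must be positive")
        if self.baseline_logit_sd <= 0:
            raise ValueError("baseline_logit_sd must be positive")
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        if self.island_aging_mode not in AGING_MODES:
            raise ValueError(f"unknown island_aging_mode {self.island_aging_mode!r}")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "tissues", "n_probes", "frac_age_related", "frac_shared_age",
            "frac_island", "frac_prc2",
            "island_aging_mode", "noise_precision", "baseline_logit_sd", "seed",
        )}
        d["slope_range"] = list(self.slope_range)
        d["species_specs"] = [
            [s.label, s.max_lifespan_years, s.maturity_years, s.n_samples_per_tissue]
            for s in self.species_specs
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["species_specs"] = [SpeciesSpec(*row) for row in d.get("species_specs", [])]
        if "slope_range" in d:
            d["slope_range"] = tuple(d["slope_range"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class GroundTruth:
    """What the generator knows: per-probe true logit-scale age slopes
    (0 for null probes), the species in which each slope acts
    ('*' = all species), and per-sample true ages."""

    probes: pd.DataFrame  # probe_id, true_slope, slope_species, island_flag, prc2_bound
    samples: pd.DataFrame  # sample_id, true_age_years

    @property
    def age_related_probes(self) -> list[str]:
        return self.probes.loc[self.probes["true_slope"] != 0, "probe_id"].tolist()


def _simulate_annotation(cfg: SimulationConfig, rng: np.random.Generator):
    n = cfg.n_probes
    probe_ids = [f"cg{i:06d}" for i in range(n)]
    island = rng.random(n) < cfg.frac_island
    prc2 = rng.random(n) < cfg.frac_prc2
    tss = rng.choice(
        ["promoter", "5'UTR", "exon", "intron", "3'UTR", "downstream", "distal"],
        size=n, p=[0.15, 0.05, 0.15, 0.25, 0.05, 0.05, 0.30],
    )
    state = np.where(
        prc2,
        rng.choice(PRC2_STATES, size=n),
        rng.choice(OTHER_STATES, size=n),
    )
    chrom = rng.choice([f"chr{i}" for i in range(1, 9)], size=n)
    # positions unique within the genome: deterministic spacing with jitter
    pos = 1 + np.arange(n) * 1000 + rng.integers(0, 500, size=n)
    all_species = frozenset(s.label for s in cfg.species_specs)
    table = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "assembly": "SimGenome.v1.0",
            "chrom": chrom,
            "pos": pos,
            "strand": rng.choice(["+", "-"], size=n),
            "mappable_species": [all_species] * n,
            "island_flag": island,
            "tss_category": tss,
            "chromatin_state": state,
            "prc2_bound": prc2,
            "gene_symbol": [f"GENE{i // 4:05d}" for i in range(n)],
        }
    )[ANNOTATION_COLUMNS]
    return ProbeAnnotation(table)


def _assign_slopes(cfg: SimulationConfig, island: np.ndarray, prc2: np.ndarray,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-probe logit-scale slopes honoring the aging mode.

    placental_like: age-related probes drawn from all probes; those in
    island∧PRC2 get positive sign, others Rademacher.  opossum_like:
    island∧PRC2 probes are excluded from the age-related pool (their slope is
    exactly 0); the pool is drawn from the remaining probes, signs Rademacher.

    Returns (slopes, slope_species); slope_species is '*' for probes whose
    slope acts in every species (a ``frac_shared_age`` fraction of the
    age-related probes) and a species label for the rest.
    """
    n = cfg.n_probes
    n_related = int(round(cfg.frac_age_related * n))
    slopes = np.zeros(n)
    slope_species = np.full(n, "*", dtype=object)
    if n_related == 0:
        return slopes, slope_species
    both = island & prc2
    if cfg.island_aging_mode == "opossum_like":
        pool = np.flatnonzero(~both)
        n_related = min(n_related, pool.size)
        chosen = rng.choice(pool, size=n_related, replace=False)
    else:
        chosen = rng.choice(n, size=n_related, replace=False)
    lo, hi = cfg.slope_range
    mag = rng.uniform(lo, hi, size=n_related)
    sign = rng.choice([-1.0, 1.0], size=n_related)
    slopes[chosen] = sign * mag
    if cfg.island_aging_mode == "placental_like":
        forced = both[chosen]
        slopes[chosen[forced]] = np.abs(slopes[chosen[forced]])
    specific = rng.random(n_related) >= cfg.frac_shared_age
    labels = [s.label for s in cfg.species_specs]
    slope_species[chosen[specific]] = rng.choice(labels, size=int(specific.sum()))
    return slopes, slope_species


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[MethylationMatrix, SampleSheet, ProbeAnnotation, GroundTruth]:
    """Simulate a dataset; identical config + seed gives identical output.

    For sample *i* of species *sp*, tissue *ti*, and probe *j*:
    ``μ_ij = expit(b0_j(sp, ti) + s_j · g(age_i))`` with ``g`` the relative
    age and ``b0_j`` a Normal(0, baseline_logit_sd) baseline per probe and
    species × tissue; observed betas are Beta(μφ, (1−μ)φ).
    """
    rng = np.random.default_rng(config.seed)
    annotation = _simulate_annotation(config, rng)
    island = annotation.table["island_flag"].to_numpy()
    prc2 = annotation.table["prc2_bound"].to_numpy()
    slopes, slope_species = _assign_slopes(config, island, prc2, rng)

    rows = []
    g_all, group_keys = [], []
    idx = 0
    for sp in config.species_specs:
        for tissue in config.tissues:
            ages = rng.uniform(0.0, sp.max_lifespan_years, size=sp.n_samples_per_tissue)
            sexes = rng.choice(["F", "M"], size=sp.n_samples_per_tissue)
            for a, sex in zip(ages, sexes):
                rows.append(
                    {"sample_id": f"s{idx:04d}", "species": sp.label,
                     "tissue": tissue, "sex": sex, "age_years": a}
                )
                g_all.append(a / sp.max_lifespan_years)
                group_keys.append((sp.label, tissue))
                idx += 1
    samples = pd.DataFrame(rows)
    g_all = np.asarray(g_all)

    baselines = {
        key: rng.normal(0.0, config.baseline_logit_sd, size=config.n_probes)
        for key in dict.fromkeys(group_keys)
    }
    b0 = np.column_stack([baselines[key] for key in group_keys])
    # species-specific slopes act only in samples of their species
    sample_species = np.asarray([key[0] for key in group_keys])
    acts = (slope_species[:, None] == "*") | (
        slope_species[:, None] == sample_species[None, :]
    )
    mu = expit(b0 + np.outer(slopes, g_all) * acts)
    mu = np.clip(mu, _MU_EPS, 1 - _MU_EPS)
    phi = config.noise_precision
    betas = rng.beta(mu * phi, (1 - mu) * phi)
    betas = np.clip(betas, 1e-12, 1 - 1e-12)

    matrix = MethylationMatrix(annotation.probe_ids, samples["sample_id"].tolist(), betas)
    constants = pd.DataFrame(
        {
            "species": [s.label for s in config.species_specs],
            "max_lifespan_years": [s.max_lifespan_years for s in config.species_specs],
            "maturity_years": [s.maturity_years for s in config.species_specs],
        }
    )
    sheet = SampleSheet(samples, constants)
    truth = GroundTruth(
        probes=pd.DataFrame(
            {"probe_id": annotation.probe_ids, "true_slope": slopes,
             "slope_species": slope_species, "island_flag": island,
             "prc2_bound": prc2}
        ),
        samples=pd.DataFrame(
            {"sample_id": samples["sample_id"], "true_age_years": samples["age_years"]}
        ),
    )
    return matrix, sheet, annotation, truth


def export_fixture(
    dataset: tuple[MethylationMatrix, SampleSheet, ProbeAnnotation, GroundTruth],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the dataset as the canonical TSV set; re-reading reproduces it."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, sheet, annotation, truth = dataset
    paths = {
        "beta": out / "beta_matrix.tsv",
        "samples": out / "sample_sheet.tsv",
        "constants": out / "species_constants.tsv",
        "annotation": out / "probe_annotation.tsv",
        "truth_probes": out / "ground_truth_probes.tsv",
        "truth_samples": out / "ground_truth_samples.tsv",
    }
    write_beta_matrix(matrix, paths["beta"])
    write_sample_sheet(sheet, paths["samples"], paths["constants"])
    write_probe_annotation(annotation, paths["annotation"])
    truth.probes.to_csv(paths["truth_probes"], sep="\t", index=False)
    truth.samples.to_csv(paths["truth_samples"], sep="\t", index=False)
    return paths
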