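"""Desk-scale validation studies run on synthetic data.

The consortium methylation data behind the marsupial aging study are not
deposited with an accession, so the package validates its machinery on
synthetic datasets whose generative truth is known.  Each function here
fixes one study's conditions (sample sizes, probe counts, noise level,
sharing structure) and runs the corresponding pipeline stage end to end;
the acceptance script and the acceptance test suite both call these.

Problem sizes are chosen for single-CPU desk-scale runs: the clock
recovery study uses n = 80 samples × 2000 probes, the permuted-age null
uses n = 60 × 120, the dual-species study 48 samples × 400 conserved
probes, and the annotation-mode studies 50 samples × 4000 probes.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .age_models import AgeTransformSpec
from .clock import evaluate_predictions, loocv_evaluate
from .enrichment import island_shift_test
from .ewas import correlation_screen, select_top_cpgs
from .io_formats import SampleSheet
from .synthetic_data import SimulationConfig, SpeciesSpec, simulate_dataset


def strong_signal_config(seed: int) -> SimulationConfig:
    """Single-species pan-tissue dataset with a clear aging signal:
    n = 80 (two tissues × 40), 2000 probes, 10% age-related."""
    return SimulationConfig(
        species_specs=[SpeciesSpec("opossum", 4.2, 0.5, 40)],
        tissues=["ear", "liver"],
        n_probes=2000,
        frac_age_related=0.1,
        frac_shared_age=1.0,
        seed=seed,
    )


def clock_recovery_study(seed: int) -> dict:
    """LOOCV accuracy of the pan-tissue clock on the strong-signal dataset."""
    matrix, sheet, _, _ = simulate_dataset(strong_signal_config(seed))
    transform = AgeTransformSpec.from_sample_sheet("identity", sheet)
    _, ev = loocv_evaluate(matrix, sheet, transform, seed=seed)
    return {"loocv_r": ev.pearson_r, "loocv_mae_years": ev.median_abs_error,
            "n": len(sheet.sample_ids)}


def permuted_age_null_study(n_seeds: int, base_seed: int) -> dict:
    """LOOCV under the null: ages permuted before every run.

    One fixed dataset (n = 60, 120 probes, single stratum); each seed
    permutes the age labels, destroying any methylation-age association,
    and runs the full LOOCV.  Reports the per-seed out-of-sample r values.
    """
    cfg = SimulationConfig(
        species_specs=[SpeciesSpec("opossum", 4.2, 0.5, 60)],
        tissues=["ear"],
        n_probes=120,
        frac_age_related=0.1,
        frac_shared_age=1.0,
        seed=base_seed,
    )
    matrix, sheet, _, _ = simulate_dataset(cfg)
    transform = AgeTransformSpec.from_sample_sheet("identity", sheet)
    rng = np.random.default_rng(base_seed)
    rs = []
    for _ in range(n_seeds):
        permuted = sheet.samples.copy()
        permuted["age_years"] = rng.permutation(
            permuted["age_years"].to_numpy()
        )
        perm_sheet = SampleSheet(permuted, sheet.species_constants)
        _, ev = loocv_evaluate(
            matrix, perm_sheet, transform, seed=int(rng.integers(0, 2**31 - 1))
        )
        rs.append(ev.pearson_r)
    rs = np.asarray(rs)
    return {"r_values": rs, "mean_r": float(rs.mean()),
            "mean_abs_r": float(np.abs(rs).mean()), "n": 60}


def dual_species_config(seed: int) -> SimulationConfig:
    """Two species with the study's 4.2 / 122.5-year lifespans, a minority
    short-lived cohort (12 vs 36 samples, echoing the real imbalance), 600
    conserved probes of which 10% are age-related and only 20% of those act
    in both species (cross-species aging conservation is weak)."""
    return SimulationConfig(
        species_specs=[
            SpeciesSpec("shortlived", 4.2, 0.5, 12),
            SpeciesSpec("longlived", 122.5, 15.0, 36),
        ],
        tissues=["blood"],
        n_probes=600,
        frac_age_related=0.1,
        frac_shared_age=0.2,
        noise_precision=25.0,
        seed=seed,
    )


def dual_species_contrast_study(seed: int) -> dict:
    """Short-lived-species LOOCV R of the relative-age clock vs the
    log-linear chronological clock on one dual-species dataset."""
    matrix, sheet, _, _ = simulate_dataset(dual_species_config(seed))
    short = (sheet.samples["species"] == "shortlived").to_numpy()
    age_short = sheet.samples["age_years"].to_numpy()[short]
    out = {}
    for label, kind in (("relative", "relative"), ("chronological", "loglinear")):
        transform = AgeTransformSpec.from_sample_sheet(kind, sheet)
        preds, _ = loocv_evaluate(matrix, sheet, transform, seed=seed)
        ev = evaluate_predictions(preds[short], age_short)
        out[f"{label}_r"] = ev.pearson_r
    out["relative_wins"] = out["relative_r"] > out["chronological_r"]
    out["n_short"] = int(short.sum())
    return out


def mode_config(mode: str, seed: int) -> SimulationConfig:
    """Single-stratum dataset for the island / PRC2 aging-mode contrast:
    n = 50, 4000 probes, 20% age-related."""
    return SimulationConfig(
        species_specs=[SpeciesSpec("opossum", 4.2, 0.5, 50)],
        tissues=["liver"],
        n_probes=4000,
        frac_age_related=0.2,
        frac_shared_age=1.0,
        island_aging_mode=mode,
        seed=seed,
    )


def aging_mode_study(mode: str, seed: int, p_threshold: float = 1e-4) -> dict:
    """Island z-shift and PRC2 enrichment among methylation-gaining probes.

    Under the placental-like regime island∧PRC2 probes gain methylation
    with age, so islands shift toward positive Fisher z and PRC2-bound
    probes are enriched among the top gaining probes; under the
    opossum-like regime neither effect exists.
    """
    matrix, sheet, annotation, _ = simulate_dataset(mode_config(mode, seed))
    res = correlation_screen(matrix, sheet)
    t = res.table
    valid = t["valid"].to_numpy()
    ann = annotation.indexed()
    island = ann.loc[t.loc[valid, "probe_id"], "island_flag"].to_numpy()
    t_stat, p_island, _ = island_shift_test(t.loc[valid, "z"], island)
    up, _ = select_top_cpgs(res, 500, p_threshold=p_threshold)
    background = t.loc[valid, "probe_id"].tolist()
    prc2 = ann["prc2_bound"]
    K = int(prc2.loc[background].sum())
    k = int(prc2.loc[up].sum())
    p_prc2 = float(stats.hypergeom.sf(k - 1, len(background), K, len(up)))
    return {
        "island_shift_t": t_stat,
        "island_shift_p": p_island,
        "prc2_up_enrichment_p": p_prc2,
        "n_top_up": len(up),
    }


def null_calibration_study(seed: int, n_probes_small: int = 2000,
                           n_probes_large: int = 100_000,
                           n_replicates: int = 5) -> dict:
    """EWAS p-value calibration with no age-related probes.

    The p < 0.005 fraction is measured on a 2000-probe screen, the
    p < 1e-4 fraction pooled over ``n_replicates`` independent 100k-probe
    screens (the rare tail needs many draws); uniformity is checked by a
    KS test against Uniform(0, 1).  Binomial bands use three sigma so that
    a deterministic fixed-seed run keeps its false-alarm rate at the
    per-mille level.
    """
    rng = np.random.default_rng(seed)

    def null_screen(n_probes: int):
        cfg = SimulationConfig(
            species_specs=[SpeciesSpec("opossum", 4.2, 0.5, 50)],
            tissues=["ear"],
            n_probes=n_probes,
            frac_age_related=0.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        matrix, sheet, _, _ = simulate_dataset(cfg)
        res = correlation_screen(matrix, sheet)
        return res.table.loc[res.table["valid"], "p"].to_numpy()

    out = {}
    p_small = null_screen(n_probes_small)
    out["fraction_p_lt_005"] = float((p_small < 0.005).mean())
    out["nominal_p_lt_005"] = 0.005
    out["binom_band_p_lt_005"] = float(
        3.0 * np.sqrt(0.005 * 0.995 / len(p_small))
    )
    out["ks_uniform_p"] = float(stats.kstest(p_small, "uniform").pvalue)
    out["n_probes_small"] = len(p_small)

    hits = total = 0
    for _ in range(n_replicates):
        p = null_screen(n_probes_large)
        hits += int((p < 1e-4).sum())
        total += len(p)
    out["fraction_p_lt_1e4"] = hits / total
    out["nominal_p_lt_1e4"] = 1e-4
    out["binom_band_p_lt_1e4"] = float(3.0 * np.sqrt(1e-4 * (1 - 1e-4) / total))
    out["n_probes_large"] = total
    return out
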