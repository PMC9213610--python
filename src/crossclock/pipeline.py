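"""End-to-end orchestration: simulate/load → QC → clocks → EWAS → meta →
sectors/Venn → enrichment → summary, under one configuration and one seed.

Every stage writes its tables under the output directory; the summary JSON
collects the headline statistics so downstream checks can recompute any of
them from the emitted per-sample / per-probe files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .age_models import AgeTransformSpec
from .clock import evaluate_predictions, fit_clock, loocv_evaluate, predict_age
from .enrichment import (
    enrichment_table,
    feature_fisher_enrichment,
    hypergeom_state_enrichment,
    island_shift_test,
)
from .ewas import (
    EwasResult,
    correlation_screen,
    manhattan_table,
    overlap_counts,
    sector_classify,
    select_top_cpgs,
    stouffer_meta,
    zscore_concordance,
)
from .io_formats import (
    MethylationMatrix,
    ProbeAnnotation,
    SampleSheet,
    read_beta_matrix,
    read_probe_annotation,
    read_sample_sheet,
)
from .qc import cluster_purity, oob_classifier_error
from .synthetic_data import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

#: significance threshold for within-species, full-lifespan EWAS
P_STRICT_WITHIN = 1e-4
#: threshold for conserved-probe cross-species EWAS
P_STRICT_CROSS = 0.005
#: "development" samples are at most this old (6 weeks, in years)
DEVELOPMENT_CUTOFF_YEARS = 6 / 52


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    simulation: SimulationConfig | None = None
    input_paths: dict[str, str] | None = None  # beta, samples, constants, annotation
    clock_specs: list[str] = field(default_factory=lambda: ["identity", "relative"])
    p_strict: float = P_STRICT_WITHIN
    p_lenient: float = 0.05
    k_per_direction: int = 500
    enrichment_features: list[str] = field(
        default_factory=lambda: ["tss_category", "island_flag", "prc2_bound"]
    )
    run_loocv: bool = False
    out_dir: str = "results/run"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p_strict < self.p_lenient < 1:
            raise ValueError("need 0 < p_strict < p_lenient < 1")
        if self.simulation is None and self.input_paths is None:
            raise ValueError("either a simulation config or input paths required")


def _load(config: RunConfig):
    if config.simulation is not None:
        matrix, sheet, annotation, _ = simulate_dataset(config.simulation)
        return matrix, sheet, annotation
    p = config.input_paths
    return (
        read_beta_matrix(p["beta"]),
        read_sample_sheet(p["samples"], p["constants"]),
        read_probe_annotation(p["annotation"]),
    )


def _strata(sheet: SampleSheet):
    for (species, tissue), group in sheet.samples.groupby(
        ["species", "tissue"], sort=True
    ):
        yield (species, tissue), sheet.subset(group["sample_id"].tolist())


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage and return the machine-readable summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, sheet, annotation = _load(config)
    summary: dict = {
        "config": {
            "p_strict": config.p_strict,
            "p_lenient": config.p_lenient,
            "k_per_direction": config.k_per_direction,
            "seed": config.seed,
        },
        "version": __version__,
        "n_probes": matrix.n_probes,
        "n_samples": matrix.n_samples,
    }

    # --- QC ----------------------------------------------------------------
    stage = "qc"
    try:
        qc = {}
        for label_col in ("tissue", "sex"):
            labels = sheet.samples[label_col].tolist()
            if len(set(labels)) >= 2:
                qc[f"cluster_purity_{label_col}"] = cluster_purity(matrix, labels)
                qc[f"oob_error_{label_col}"] = oob_classifier_error(
                    matrix, labels, n_trees=200, seed=config.seed
                )
        summary["qc"] = qc

        # --- per-stratum EWAS ----------------------------------------------
        stage = "ewas"
        results: dict[tuple[str, str], EwasResult] = {}
        for key, sub in _strata(sheet):
            if len(sub.sample_ids) < 4:
                logger.warning("skipping stratum %s with <4 samples", key)
                continue
            res = correlation_screen(matrix, sub)
            results[key] = res
            tag = f"{key[0]}_{key[1]}"
            res.with_adjustments().to_csv(out / f"ewas_{tag}.tsv", sep="\t", index=False)
            manhattan_table(res, annotation).to_csv(
                out / f"manhattan_{tag}.tsv", sep="\t", index=False
            )
        summary["ewas"] = {
            f"{k[0]}/{k[1]}": {
                "n_significant": int(
                    (res.table["valid"] & (res.table["p"] < config.p_strict)).sum()
                )
            }
            for k, res in results.items()
        }

        # --- meta-analysis per species -------------------------------------
        stage = "meta"
        by_species: dict[str, list[EwasResult]] = {}
        for (species, _), res in results.items():
            by_species.setdefault(species, []).append(res)
        meta_by_species = {}
        for species, res_list in by_species.items():
            meta = stouffer_meta(res_list)
            meta.table.to_csv(out / f"meta_{species}.tsv", sep="\t", index=False)
            meta_by_species[species] = meta
        summary["meta"] = {
            sp: {"n_significant": int((m.table["p_meta"] < config.p_strict).sum())}
            for sp, m in meta_by_species.items()
        }

        # --- top sets, sectors, Venn ---------------------------------------
        stage = "sectors"
        tops = {
            k: select_top_cpgs(res, config.k_per_direction, config.p_strict)
            for k, res in results.items()
        }
        sector_rows = []
        concordances = {}
        for (ka, kb) in combinations(sorted(results), 2):
            ra = results[ka].table.set_index("probe_id")
            rb = results[kb].table.set_index("probe_id")
            common = ra.index.intersection(rb.index)
            sc = sector_classify(
                ra.loc[common, "z"], rb.loc[common, "z"], list(common),
                p_strict=config.p_strict, p_lenient=config.p_lenient,
            )
            name = f"{ka[0]}_{ka[1]}__vs__{kb[0]}_{kb[1]}"
            sc.table.to_csv(out / f"sectors_{name}.tsv", sep="\t", index=False)
            sector_rows.append({"pair": name, **sc.counts()})
            valid = (ra.loc[common, "valid"] & rb.loc[common, "valid"]).to_numpy()
            r, degenerate = zscore_concordance(
                ra.loc[common, "z"][valid], rb.loc[common, "z"][valid]
            )
            concordances[name] = {"r": r, "degenerate": degenerate}
        summary["sector_counts"] = sector_rows
        summary["z_concordance"] = concordances

        venn_sets = {
            f"{k[0]}_{k[1]}": list(dict.fromkeys(up + down))
            for k, (up, down) in tops.items()
        }
        if 2 <= len(venn_sets) <= 4:
            venn = overlap_counts(venn_sets)
            venn_df = pd.DataFrame(
                [{"region": "&".join(sorted(k)), "count": v} for k, v in venn.items()]
            )
            venn_df.to_csv(out / "venn_counts.tsv", sep="\t", index=False)
            summary["venn"] = {
                "&".join(sorted(k)): v for k, v in venn.items()
            }
            full = frozenset(venn_sets)
            summary["n_shared_all_strata"] = venn[full]

        # --- enrichment -----------------------------------------------------
        stage = "enrichment"
        enrich_summary = {}
        for k, res in results.items():
            tag = f"{k[0]}_{k[1]}"
            t = res.table
            valid = t["valid"].to_numpy()
            tstat, p_island, means = island_shift_test(
                t.loc[valid, "z"], annotation.indexed().loc[
                    t.loc[valid, "probe_id"], "island_flag"
                ],
            )
            enrich_summary[tag] = {
                "island_shift_t": tstat, "island_shift_p": p_island,
                "island_mean_z": means[0], "non_island_mean_z": means[1],
            }
            up, down = tops[k]
            background = t.loc[valid, "probe_id"].tolist()
            for direction, top in (("up", up), ("down", down)):
                if not top:
                    continue
                frames = []
                for feature in config.enrichment_features:
                    rows = feature_fisher_enrichment(
                        top, background, annotation, feature, direction=direction
                    )
                    frames.append(enrichment_table(rows).assign(feature=feature))
                rows = hypergeom_state_enrichment(
                    top, background, annotation, direction=direction
                )
                frames.append(enrichment_table(rows).assign(feature="chromatin_state"))
                pd.concat(frames, ignore_index=True).to_csv(
                    out / f"enrichment_{tag}_{direction}.tsv", sep="\t", index=False
                )
        summary["enrichment"] = enrich_summary

        # --- clocks ----------------------------------------------------------
        stage = "clock"
        clock_summary = {}
        for kind in config.clock_specs:
            transform = AgeTransformSpec.from_sample_sheet(kind, sheet)
            model = fit_clock(matrix, sheet, transform, seed=config.seed)
            model.to_json(out / f"clock_{kind}.json")
            pred = predict_age(model, matrix, sheet)
            train_eval = evaluate_predictions(
                pred, sheet.samples["age_years"].to_numpy()
            )
            entry = {
                "n_nonzero": model.n_nonzero,
                "lambda": model.lambda_,
                "training_r": train_eval.pearson_r,
                "training_mae_years": train_eval.median_abs_error,
            }
            if config.run_loocv:
                loocv_pred, ev = loocv_evaluate(
                    matrix, sheet, transform, seed=config.seed
                )
                pd.DataFrame(
                    {
                        "sample_id": sheet.sample_ids,
                        "actual_age_years": sheet.samples["age_years"],
                        "predicted_age_years": loocv_pred,
                    }
                ).to_csv(out / f"loocv_{kind}.tsv", sep="\t", index=False)
                entry.update(
                    {"loocv_r": ev.pearson_r, "loocv_mae_years": ev.median_abs_error}
                )
            clock_summary[kind] = entry
        summary["clocks"] = clock_summary
    except Exception as err:  # partial outputs stay on disk for diagnosis
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=float)
    with open(out / "run_log.txt", "w") as fh:
        fh.write(f"crossclock {__version__}\nseed={config.seed}\n")
        fh.write(json.dumps(summary["config"], sort_keys=True) + "\n")
    return summary


def split_by_age_epoch(
    sheet: SampleSheet,
    development_cutoff_years: float = DEVELOPMENT_CUTOFF_YEARS,
) -> tuple[SampleSheet, SampleSheet]:
    """Split samples into a development epoch (age ≤ cutoff, default 6 weeks)
    and a later-aging epoch (past the species' age at sexual maturity)."""
    s = sheet.samples
    dev = sheet.subset((s["age_years"] <= development_cutoff_years).to_numpy())
    maturity = s["species"].map(
        dict(
            zip(
                sheet.species_constants["species"],
                sheet.species_constants["maturity_years"].astype(float),
            )
        )
    )
    adult = sheet.subset((s["age_years"] > maturity).to_numpy())
    return dev, adult


def compare_development_vs_aging(
    ewas_dev: EwasResult,
    ewas_aging: EwasResult,
    k: int = 500,
    p_threshold: float = P_STRICT_CROSS,
) -> dict:
    """Percent of top aging CpGs that are also top development CpGs.

    Top sets are selected per :func:`select_top_cpgs` (up to k per
    direction); the overlap denominator is the aging set, per direction and
    combined.  Raw counts travel alongside every percentage.
    """
    out = {}
    dev_up, dev_down = select_top_cpgs(ewas_dev, k, p_threshold)
    age_up, age_down = select_top_cpgs(ewas_aging, k, p_threshold)
    dev_all = set(dev_up) | set(dev_down)
    age_all = list(dict.fromkeys(age_up + age_down))
    if not age_all or not dev_all:
        raise ValueError("empty top set in one of the screens")
    for name, dev_set, age_set in (
        ("up", set(dev_up), age_up),
        ("down", set(dev_down), age_down),
        ("combined", dev_all, age_all),
    ):
        if not age_set:
            continue
        n_overlap = len(set(age_set) & dev_set)
        out[name] = {
            "n_overlap": n_overlap,
            "n_top_aging": len(age_set),
            "percent": round(100.0 * n_overlap / len(age_set), 1),
        }
    return out
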