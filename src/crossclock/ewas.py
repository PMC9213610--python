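"""Epigenome-wide association of age and cross-stratum comparison.

Per stratum (one species × tissue), each probe's beta values are screened
against age by pairwise-complete Pearson correlation.  Two statistics are
reported per probe, mirroring the dual use in methylation-aging studies:

* the correlation-test p-value from Student's t with n − 2 df,
  ``t = r·√(n−2)/√(1−r²)`` (the classic numeric-trait screen);
* the Fisher z effect statistic ``z = atanh(r)·√(n−3)``, approximately
  standard normal under the null, which is what meta-analysis combines and
  what the sector plots compare across strata.

Strata are combined by Stouffer's weighted method,
``z_meta = Σ wᵢ zᵢ / √(Σ wᵢ²)`` with default weights ``√nᵢ``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MethylationMatrix, SampleSheet

#: |r| is clipped here before atanh so z stays finite for perfect correlations
R_CLIP = 1 - 1e-12

SECTOR_CATEGORIES = ("shared_up", "shared_down", "divergent", "x_only", "y_only", "null")


@dataclass
class EwasResult:
    """Per-probe age-correlation statistics for one (species, tissue) stratum.

    ``table`` columns: probe_id, n_used, r, z, p, valid; invalid probes
    (n_used < 4 or constant beta) carry r = 0, z = 0, p = 1.
    """

    stratum: tuple[str, str]
    table: pd.DataFrame

    def with_adjustments(self) -> pd.DataFrame:
        """Table plus BH-FDR and Bonferroni columns (valid probes only count)."""
        from .enrichment import adjust_pvalues

        t = self.table.copy()
        t["fdr_bh"] = np.nan
        t["bonferroni"] = np.nan
        mask = t["valid"].to_numpy()
        if mask.any():
            p = t.loc[mask, "p"].tolist()
            t.loc[mask, "fdr_bh"] = adjust_pvalues(p, "bh")
            t.loc[mask, "bonferroni"] = adjust_pvalues(p, "bonferroni")
        return t


@dataclass
class MetaEwasResult:
    """Stouffer-combined statistics; ``k_strata`` counts actual contributions."""

    table: pd.DataFrame  # probe_id, z_meta, p_meta, k_strata
    weights: dict[tuple[str, str], float] | None = None


@dataclass
class SectorClassification:
    """Pairwise cross-stratum classification of probes into sector categories."""

    table: pd.DataFrame  # probe_id, category
    p_strict: float
    p_lenient: float

    def counts(self) -> dict[str, int]:
        c = self.table["category"].value_counts()
        return {k: int(c.get(k, 0)) for k in SECTOR_CATEGORIES}


def _pairwise_pearson(values: np.ndarray, x: np.ndarray):
    """Vectorized per-row Pearson r of ``values`` (probes × samples) against
    ``x`` using pairwise-complete observations.  Returns (r, n_used, valid)."""
    mask = ~np.isnan(values)
    n = mask.sum(axis=1)
    xm = np.where(mask, x, 0.0)
    vm = np.where(mask, values, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sx = xm.sum(axis=1)
        sv = vm.sum(axis=1)
        sxx = (xm**2).sum(axis=1)
        svv = (vm**2).sum(axis=1)
        sxv = (xm * vm).sum(axis=1)
        cov = sxv - sx * sv / n
        varx = sxx - sx**2 / n
        varv = svv - sv**2 / n
        r = cov / np.sqrt(varx * varv)
    valid = (n >= 4) & (varx > 1e-300) & (varv > 1e-300) & np.isfinite(r)
    r = np.where(valid, np.clip(r, -1.0, 1.0), 0.0)
    return r, n, valid


def correlation_screen(
    matrix: MethylationMatrix,
    sheet: SampleSheet,
    age: np.ndarray | None = None,
) -> EwasResult:
    """Screen every probe against age within one homogeneous stratum.

    ``age`` defaults to chronological age in years; pass a transformed age
    vector (aligned to the sheet) to screen against transformed age.
    """
    species = set(sheet.samples["species"])
    tissues = set(sheet.samples["tissue"])
    if len(species) != 1 or len(tissues) != 1:
        raise ValueError("stratum must be one species and one tissue")
    if len(sheet.sample_ids) < 4:
        raise ValueError("stratum needs at least 4 samples")
    m = matrix.subset_samples(sheet.sample_ids)
    x = (
        sheet.samples["age_years"].to_numpy(dtype=float)
        if age is None
        else np.asarray(age, dtype=float)
    )
    r, n, valid = _pairwise_pearson(m.values, x)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(np.maximum(n - 2, 0)) / np.sqrt(1 - r**2)
        p = 2 * stats.t.sf(np.abs(t), np.maximum(n - 2, 1))
        z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP)) * np.sqrt(np.maximum(n - 3, 0))
    p = np.where(valid, np.clip(p, np.nextafter(0, 1), 1.0), 1.0)
    z = np.where(valid, z, 0.0)
    table = pd.DataFrame(
        {"probe_id": m.probe_ids, "n_used": n.astype(int), "r": r, "z": z,
         "p": p, "valid": valid}
    )
    return EwasResult(
        stratum=(next(iter(species)), next(iter(tissues))), table=table
    )


def stouffer_meta(
    results: list[EwasResult],
    weights: dict[tuple[str, str], float] | None = None,
) -> MetaEwasResult:
    """Combine per-stratum z statistics with Stouffer's weighted method.

    Default weights are √n per probe per stratum (n = samples actually used);
    explicit per-stratum weights override.  Probes invalid in a stratum
    contribute nothing there; the normalization runs over contributing strata
    only, and a probe invalid everywhere is an invalid meta record
    (z = 0, p = 1, k = 0).
    """
    if not results:
        raise ValueError("need at least one stratum")
    universe: list[str] = []
    seen = set()
    for res in results:
        for pid in res.table["probe_id"]:
            if pid not in seen:
                universe.append(pid)
                seen.add(pid)
    idx = pd.Index(universe)
    num = np.zeros(len(idx))
    den = np.zeros(len(idx))
    k = np.zeros(len(idx), dtype=int)
    for res in results:
        t = res.table.set_index("probe_id").reindex(idx)
        valid = t["valid"].fillna(False).to_numpy(dtype=bool)
        z = t["z"].fillna(0.0).to_numpy()
        if weights is None:
            w = np.sqrt(t["n_used"].fillna(0.0).to_numpy(dtype=float))
        else:
            w = np.full(len(idx), float(weights[res.stratum]))
        w = np.where(valid, w, 0.0)
        num += w * z
        den += w**2
        k += valid.astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        z_meta = np.where(den > 0, num / np.sqrt(den), 0.0)
    p_meta = np.where(k > 0, 2 * stats.norm.sf(np.abs(z_meta)), 1.0)
    p_meta = np.clip(p_meta, np.nextafter(0, 1), 1.0)
    table = pd.DataFrame(
        {"probe_id": universe, "z_meta": z_meta, "p_meta": p_meta, "k_strata": k}
    )
    return MetaEwasResult(table=table, weights=weights)


def _as_zp(result) -> pd.DataFrame:
    t = result.table
    if "z_meta" in t.columns:
        out = t.rename(columns={"z_meta": "z", "p_meta": "p"})[
            ["probe_id", "z", "p"]
        ].copy()
        out["valid"] = t["k_strata"] > 0
        return out
    return t[["probe_id", "z", "p", "valid"]].copy()


def select_top_cpgs(
    result, k_per_direction: int = 500, p_threshold: float = 1e-4
) -> tuple[list[str], list[str]]:
    """Up-to-k most significant probes per direction among p < threshold.

    Ordering: ascending p, ties by descending |z|, then probe_id. Returns
    (gain list, loss list); fewer than k come back when fewer qualify.
    """
    if k_per_direction <= 0:
        raise ValueError("k_per_direction must be positive")
    t = _as_zp(result)
    t = t.loc[t["valid"] & (t["p"] < p_threshold)].copy()
    t["abs_z"] = t["z"].abs()
    t = t.sort_values(["p", "abs_z", "probe_id"], ascending=[True, False, True])
    up = t.loc[t["z"] > 0, "probe_id"].head(k_per_direction).tolist()
    down = t.loc[t["z"] < 0, "probe_id"].head(k_per_direction).tolist()
    return up, down


def overlap_counts(sets: dict[str, list[str] | set[str]]) -> dict[frozenset, int]:
    """Exact Venn-region counts for 2–4 named sets.

    Keys are frozensets of set names identifying the exclusive region
    (members of exactly those sets); region counts sum to |union|.
    """
    if not 2 <= len(sets) <= 4:
        raise ValueError("overlap_counts supports 2 to 4 sets")
    named = {k: set(v) for k, v in sets.items()}
    names = list(named)
    out: dict[frozenset, int] = {}
    for size in range(1, len(names) + 1):
        for combo in combinations(names, size):
            inside = set.intersection(*(named[c] for c in combo))
            outside = set.union(set(), *(named[c] for c in names if c not in combo))
            out[frozenset(combo)] = len(inside - outside)
    return out


def sector_classify(
    zx: pd.Series | np.ndarray,
    zy: pd.Series | np.ndarray,
    probe_ids: list[str],
    p_strict: float = 1e-4,
    p_lenient: float = 0.05,
) -> SectorClassification:
    """Classify probes by joint significance in two strata.

    Thresholds are two-sided normal quantiles: ``z* = Φ⁻¹(1 − p/2)``.
    shared_up/down: both beyond strict in the same direction; divergent:
    both beyond strict, opposite directions; x_only / y_only: one beyond
    strict while the other is inside the lenient band; else null.
    """
    if not 0 < p_strict < p_lenient < 1:
        raise ValueError("need 0 < p_strict < p_lenient < 1")
    zs = float(stats.norm.isf(p_strict / 2))
    zl = float(stats.norm.isf(p_lenient / 2))
    zx = np.asarray(zx, dtype=float)
    zy = np.asarray(zy, dtype=float)
    cat = np.full(len(zx), "null", dtype=object)
    cat[(zx > zs) & (zy > zs)] = "shared_up"
    cat[(zx < -zs) & (zy < -zs)] = "shared_down"
    cat[(np.abs(zx) > zs) & (np.abs(zy) > zs) & (np.sign(zx) != np.sign(zy))] = "divergent"
    cat[(np.abs(zx) > zs) & (np.abs(zy) < zl)] = "x_only"
    cat[(np.abs(zy) > zs) & (np.abs(zx) < zl)] = "y_only"
    return SectorClassification(
        table=pd.DataFrame({"probe_id": probe_ids, "category": cat}),
        p_strict=p_strict,
        p_lenient=p_lenient,
    )


def zscore_concordance(zx, zy) -> tuple[float, bool]:
    """Pearson correlation of paired per-probe z scores across two strata.

    Returns (r, degenerate); a zero-variance input is flagged and reported
    as r = 0 rather than raising mid-pipeline.
    """
    zx = np.asarray(zx, dtype=float)
    zy = np.asarray(zy, dtype=float)
    ok = np.isfinite(zx) & np.isfinite(zy)
    zx, zy = zx[ok], zy[ok]
    if len(zx) < 3:
        raise ValueError("need at least 3 aligned probes")
    if np.ptp(zx) == 0 or np.ptp(zy) == 0:
        return 0.0, True
    return float(stats.pearsonr(zx, zy)[0]), False


def manhattan_table(result, annotation) -> pd.DataFrame:
    """Plot-ready table: probe, chrom, pos, signed −log10 p."""
    t = _as_zp(result)
    ann = annotation.indexed()
    t = t.join(ann[["chrom", "pos"]], on="probe_id")
    t["signed_neglog10_p"] = -np.log10(t["p"]) * np.sign(t["z"])
    return t[["probe_id", "chrom", "pos", "z", "p", "signed_neglog10_p"]]
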