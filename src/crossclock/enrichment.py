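"""Annotation-level statistics on EWAS output.

Four statistics recur in methylation-aging studies and are implemented here
over an array-conditioned background (all probes mappable to the species
under study, which conditions out the array's design bias):

* a two-sample Student t of Fisher z between CpG-island and non-island
  probes (the island "shift" boxplot statistic);
* per-category 2×2 Fisher exact tests of top-probe membership vs background
  (TSS location, island flag, PRC2 binding), with the sample (cross-product)
  odds ratio and figure-style significance stars;
* one-sided hypergeometric enrichment of chromatin states among top probes;
* hypergeometric gene-set enrichment over the background's gene universe,
  restricted to sets of 10–3000 genes, with Bonferroni and Benjamini–
  Hochberg adjustments side by side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ProbeAnnotation

DEFAULT_GENE_SET_SIZE_BOUNDS = (10, 3000)

STAR_LEVELS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for level, stars in STAR_LEVELS:
        if p < level:
            return stars
    return ""


@dataclass
class EnrichmentRow:
    """One category's 2×2 enrichment summary against the background."""

    category: str
    direction: str  # up / down / combined
    k_in: int       # top-set members in the category
    n_top: int
    K_in: int       # background members in the category
    N_bg: int
    odds_ratio: float  # sample (cross-product) OR; inf on a zero cell
    p: float
    fdr_bh: float = np.nan
    bonferroni: float = np.nan

    def __post_init__(self) -> None:
        if not (self.k_in <= min(self.n_top, self.K_in) and self.N_bg >= self.n_top):
            raise ValueError("inconsistent 2x2 margins")

    @property
    def stars(self) -> str:
        return significance_stars(self.p)

    @property
    def fold(self) -> float:
        exp = self.K_in / self.N_bg if self.N_bg else np.nan
        return (self.k_in / self.n_top) / exp if self.n_top and exp else np.nan


def fisher_exact_two_sided_p(k_in: int, n_top: int, K_in: int, N_bg: int) -> float:
    """Two-sided Fisher exact p (hypergeometric-sum definition) for the
    2×2 table with top-set size n_top, category size K_in, background N_bg
    and overlap k_in."""
    table = [[k_in, n_top - k_in], [K_in - k_in, N_bg - K_in - n_top + k_in]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def hypergeom_enrichment_p(k_in: int, n_top: int, K_in: int, N_bg: int) -> float:
    """One-sided enrichment tail P(X >= k_in), X ~ Hypergeom(N_bg, K_in, n_top)."""
    return float(stats.hypergeom.sf(k_in - 1, N_bg, K_in, n_top))


def sample_odds_ratio(k_in: int, n_top: int, K_in: int, N_bg: int) -> float:
    """Cross-product OR of the top-vs-rest × in-category-vs-not table.

    Zero-cell conventions: a zero in the 'miss' diagonal gives inf, a zero
    in the 'hit' diagonal gives 0, and 0/0 gives NaN.
    """
    a = k_in
    b = n_top - k_in
    c = K_in - k_in
    d = N_bg - K_in - n_top + k_in
    num, den = a * d, b * c
    if den == 0:
        return np.nan if num == 0 else np.inf
    return num / den


def island_shift_test(z, island_flag) -> tuple[float, float, tuple[float, float]]:
    """Pooled-variance two-sample t of island vs non-island Fisher z.

    Returns (t, two-sided p, (island mean, non-island mean)); positive t
    means islands gain methylation with age relative to non-islands.
    """
    z = np.asarray(z, dtype=float)
    flag = np.asarray(island_flag, dtype=bool)
    zi, zo = z[flag], z[~flag]
    if len(zi) < 2 or len(zo) < 2:
        raise ValueError("need at least 2 probes in each island group")
    if np.ptp(z) == 0:
        raise ValueError("all z identical: t test undefined")
    t, p = stats.ttest_ind(zi, zo, equal_var=True)
    return float(t), float(p), (float(zi.mean()), float(zo.mean()))


def _category_rows(
    top: set[str], background: set[str], member_of: pd.Series, direction: str,
    test: str,
) -> list[EnrichmentRow]:
    if not top:
        raise ValueError("top set is empty")
    if not top <= background:
        raise ValueError("top set must be a subset of the background")
    bg = member_of.loc[member_of.index.isin(background)]
    n_top, N_bg = len(top), len(bg)
    rows = []
    for category, members in bg.groupby(bg).groups.items():
        K_in = len(members)
        k_in = len(top & set(members))
        if test == "fisher":
            p = fisher_exact_two_sided_p(k_in, n_top, K_in, N_bg)
        else:
            p = hypergeom_enrichment_p(k_in, n_top, K_in, N_bg)
        rows.append(
            EnrichmentRow(
                category=str(category), direction=direction, k_in=k_in,
                n_top=n_top, K_in=K_in, N_bg=N_bg,
                odds_ratio=sample_odds_ratio(k_in, n_top, K_in, N_bg), p=p,
            )
        )
    return _with_adjustments(sorted(rows, key=lambda r: r.category))


def _with_adjustments(rows: list[EnrichmentRow]) -> list[EnrichmentRow]:
    if rows:
        p = [r.p for r in rows]
        bh = adjust_pvalues(p, "bh")
        bf = adjust_pvalues(p, "bonferroni")
        for r, b, f in zip(rows, bh, bf):
            r.fdr_bh, r.bonferroni = b, f
    return rows


def feature_fisher_enrichment(
    top_probes, background, annotation: ProbeAnnotation, feature: str,
    direction: str = "combined",
) -> list[EnrichmentRow]:
    """Two-sided Fisher exact enrichment of an annotation feature's
    categories among top probes, against the array background."""
    if feature not in ("tss_category", "island_flag", "prc2_bound"):
        raise ValueError(f"unsupported feature {feature!r}")
    member_of = annotation.indexed()[feature].astype(str)
    return _category_rows(set(top_probes), set(background), member_of, direction, "fisher")


def hypergeom_state_enrichment(
    top_probes, background, annotation: ProbeAnnotation,
    states: list[str] | None = None, direction: str = "combined",
) -> list[EnrichmentRow]:
    """One-sided hypergeometric enrichment of chromatin states among top
    probes; the depletion tail is P(X <= k), recoverable from the pmf."""
    member_of = annotation.indexed()["chromatin_state"].astype(str)
    bg_states = set(member_of.loc[member_of.index.isin(set(background))])
    if states is not None:
        missing = set(states) - bg_states
        if missing:
            raise ValueError(f"state(s) absent from background: {sorted(missing)}")
    rows = _category_rows(set(top_probes), set(background), member_of, direction, "hypergeom")
    if states is not None:
        rows = _with_adjustments([r for r in rows if r.category in set(states)])
    return rows


def hypergeom_depletion_p(row: EnrichmentRow) -> float:
    """Lower-tail companion of the enrichment p: P(X <= k_in)."""
    return float(stats.hypergeom.cdf(row.k_in, row.N_bg, row.K_in, row.n_top))


def adjust_pvalues(p, method: str = "bh") -> list[float]:
    """Benjamini–Hochberg step-up or Bonferroni adjustment, order preserved."""
    p = np.asarray(list(p), dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if method == "bh":
        adj = multipletests(p, method="fdr_bh")[1]
    elif method == "bonferroni":
        adj = np.minimum(p * len(p), 1.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    return [float(x) for x in adj]


def gene_set_enrichment(
    top_probes, background, annotation: ProbeAnnotation,
    gene_sets: dict[str, set[str]],
    size_bounds: tuple[int, int] = DEFAULT_GENE_SET_SIZE_BOUNDS,
) -> list[EnrichmentRow]:
    """Hypergeometric gene-set enrichment over the background gene universe.

    Probes map to their single annotated gene; sets outside ``size_bounds``
    (after intersecting nothing — bounds apply to the raw set size) are
    excluded, which keeps the multiple-testing burden bounded.
    """
    ann = annotation.indexed()["gene_symbol"].dropna()
    bg_genes = set(ann.loc[ann.index.isin(set(background))])
    if not bg_genes:
        raise ValueError("empty background gene universe")
    top_genes = set(ann.loc[ann.index.isin(set(top_probes))])
    lo, hi = size_bounds
    rows = []
    for name in sorted(gene_sets):
        genes = set(gene_sets[name])
        if not lo <= len(genes) <= hi:
            continue
        K_in = len(genes & bg_genes)
        k_in = len(genes & top_genes)
        p = hypergeom_enrichment_p(k_in, len(top_genes), K_in, len(bg_genes))
        rows.append(
            EnrichmentRow(
                category=name, direction="combined", k_in=k_in,
                n_top=len(top_genes), K_in=K_in, N_bg=len(bg_genes),
                odds_ratio=sample_odds_ratio(k_in, len(top_genes), K_in, len(bg_genes)),
                p=p,
            )
        )
    return _with_adjustments(rows)


def enrichment_table(rows: list[EnrichmentRow]) -> pd.DataFrame:
    """Flat TSV-ready table of enrichment rows."""
    return pd.DataFrame(
        [
            {
                "category": r.category, "direction": r.direction, "k_in": r.k_in,
                "n_top": r.n_top, "K_in": r.K_in, "N_bg": r.N_bg,
                "odds_ratio": r.odds_ratio, "fold": r.fold, "p": r.p,
                "fdr_bh": r.fdr_bh, "bonferroni": r.bonferroni, "stars": r.stars,
            }
            for r in rows
        ]
    )
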