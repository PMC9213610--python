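#!/usr/bin/env python
"""Per-tissue EWAS of age, Stouffer meta-analysis and cross-tissue overlap.

For each tissue of cohort A: per-probe Pearson correlation with age,
Student-t p and Fisher z.  Tissues are then combined with Stouffer's
√n-weighted method, the top CpGs (up to 500 per direction at p < 1e-4) are
selected per tissue, and cross-tissue agreement is summarized three ways:
Venn overlap of the top sets, sector classification of the z-z plane and
the z-score concordance correlation.
"""

from pathlib import Path

import pandas as pd

from crossclock.ewas import (
    correlation_screen,
    manhattan_table,
    overlap_counts,
    sector_classify,
    select_top_cpgs,
    stouffer_meta,
    zscore_concordance,
)
from crossclock.synthetic_data import simulate_dataset
from crossclock.validation import strong_signal_config

OUT = Path("results")
OUT.mkdir(exist_ok=True)

matrix, sheet, annotation, _ = simulate_dataset(strong_signal_config(seed=11))
P_STRICT = 1e-4

results = {}
for tissue in sorted(set(sheet.samples["tissue"])):
    sub = sheet.subset((sheet.samples["tissue"] == tissue).to_numpy())
    res = correlation_screen(matrix, sub)
    results[tissue] = res
    res.with_adjustments().to_csv(OUT / f"ewas_{tissue}.tsv", sep="\t", index=False)
    manhattan_table(res, annotation).to_csv(
        OUT / f"manhattan_{tissue}.tsv", sep="\t", index=False
    )
    n_sig = int((res.table["valid"] & (res.table["p"] < P_STRICT)).sum())
    print(f"{tissue}: {n_sig} CpGs at p < {P_STRICT:g} (n={len(sub.sample_ids)})")

meta = stouffer_meta(list(results.values()))
meta.table.to_csv(OUT / "ewas_meta.tsv", sep="\t", index=False)
n_meta = int((meta.table["p_meta"] < P_STRICT).sum())
print(f"meta-analysis: {n_meta} CpGs at p < {P_STRICT:g}")

tops = {t: select_top_cpgs(r, 500, P_STRICT) for t, r in results.items()}
venn = overlap_counts({t: up + down for t, (up, down) in tops.items()})
shared = venn[frozenset(tops)]
print(f"top CpGs shared by all tissues: {shared}")
pd.DataFrame(
    [{"region": "&".join(sorted(k)), "count": v} for k, v in venn.items()]
).to_csv(OUT / "venn_counts.tsv", sep="\t", index=False)

tissues = sorted(results)
a, b = results[tissues[0]].table, results[tissues[1]].table
sc = sector_classify(a["z"], b["z"], a["probe_id"].tolist(), p_strict=P_STRICT)
sc.table.to_csv(OUT / f"sectors_{tissues[0]}_vs_{tissues[1]}.tsv", sep="\t", index=False)
r, _ = zscore_concordance(a["z"], b["z"])
print(f"{tissues[0]}-{tissues[1]} aging z concordance r = {r:.2f}")
print(f"sector counts: {sc.counts()}")
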