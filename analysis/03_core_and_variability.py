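"""Core catalogs, rank summaries and variability rankings across the cohorts.

For each feature class: per-dataset mean abundance and CV averaged across
datasets, pooled rank summaries (median, IQR), detection frequencies and the
two core definitions (detected in all subjects / in all datasets).  Writes
summary TSVs plus the lowest/highest-CV rankings among well-detected features.
"""

from pathlib import Path

import pandas as pd

from mpmeta.aggregate import read_feature_table
from mpmeta.core_rank import summarize_features, variability_ranking, write_summary

ROOT = Path(__file__).resolve().parent.parent / "results"
TABLES = ROOT / "tables"

CLASSES = ("phylum", "genus", "KO", "pathway")


def main():
    for cls in CLASSES:
        tables = [read_feature_table(p) for p in sorted(TABLES.glob(f"{cls}_D*.tsv"))]
        s = summarize_features(tables)
        write_summary(s, cls, ROOT / f"summary_{cls}.tsv")
        n_cs = int(s["core_subjects"].sum())
        n_cd = int(s["core_datasets"].sum())
        print(f"{cls}: {len(s)} features; core all-subjects {n_cs}, "
              f"core all-datasets {n_cd}")
        if cls == "phylum":
            top = s.sort_values("mean_pct", ascending=False).head(4)
            print("  top phyla (mean %):",
                  {i: round(v, 1) for i, v in top["mean_pct"].items()})
        if cls in ("genus", "KO"):
            low, high = variability_ranking(s, min_mean_pct=0.01, n_top=10)
            pd.DataFrame({"lowest_cv": pd.Series(low), "highest_cv": pd.Series(high)}
                         ).to_csv(ROOT / f"variability_{cls}.tsv", sep="\t", index=False)
            print(f"  most stable {cls}: {low[:3]}; most variable: {high[:3]}")


if __name__ == "__main__":
    main()
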