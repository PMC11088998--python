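"""Threshold-coded integration across stages: uORF/CDS coupling classes with
the transcript-level guards, eIF4G2-bound intersections, cross-dataset
correlations, distribution comparisons, reporter quantification and
transcript-feature statistics.

All printed threshold boundaries are strict exactly as coded here (>, <).
Classification is a pure function of its input tables; no additional
multiple-testing step is applied at this stage (lists are intersected after
thresholding upstream).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ORFRecord, Thresholds, TranscriptModel


# ---------------------------------------------------------------------------
# uORF/CDS coupling classes
# ---------------------------------------------------------------------------

def classify_uorf_cds(utr5: pd.DataFrame, cds: pd.DataFrame,
                      plclip_diff: pd.DataFrame,
                      thresholds: Thresholds | None = None) -> pd.DataFrame:
    """Per-gene coupling classes from differential 5'UTR/CDS translation.

    * utr5_up: 5'UTR log2fc > 0 and p < 0.05 (basemean rule applied upstream)
    * cds_class 'up': CDS log2fc > 0, p < 0.05 and differential PL-CLIP t < 2
    * cds_class 'down': CDS log2fc < 0, p < 0.05 and t > -2
    * otherwise 'flat'

    Input tables need gene_id, log2fc and p_z (or p) columns; the PL-CLIP
    table needs gene-keyed feature_id and stat.
    """
    th = thresholds or Thresholds()

    def _prep(df: pd.DataFrame, prefix: str) -> pd.DataFrame:
        p_col = "p_z" if "p_z" in df.columns else "p"
        out = df[["gene_id", "log2fc", p_col]].rename(
            columns={"log2fc": f"{prefix}_log2fc", p_col: f"{prefix}_p"})
        if out["gene_id"].duplicated().any():
            raise ValueError(f"{prefix} table: duplicate gene_id")
        return out

    merged = _prep(utr5, "utr5").merge(_prep(cds, "cds"), on="gene_id", how="inner")
    if merged.empty:
        raise ValueError("no shared genes between utr5 and cds tables "
                         f"({len(utr5)} vs {len(cds)} rows)")
    guard = plclip_diff.rename(columns={"feature_id": "gene_id"})
    guard = guard[["gene_id", "stat"]].rename(columns={"stat": "t_diff"})
    merged = merged.merge(guard, on="gene_id", how="left")

    p = th.p_cds
    merged["utr5_up"] = (merged["utr5_log2fc"] > 0) & (merged["utr5_p"] < p)
    t = merged["t_diff"]
    up = ((merged["cds_log2fc"] > 0) & (merged["cds_p"] < p)
          & (t < th.guard_t_up) & t.notna())
    down = ((merged["cds_log2fc"] < 0) & (merged["cds_p"] < p)
            & (t > th.guard_t_down) & t.notna())
    merged["plclip_guard_pass"] = np.where(
        merged["cds_log2fc"] > 0, (t < th.guard_t_up) & t.notna(),
        (t > th.guard_t_down) & t.notna())
    merged["cds_class"] = np.select([up, down], ["up", "down"], "flat")
    merged["final_class"] = np.select(
        [merged["utr5_up"] & up, merged["utr5_up"] & down, merged["utr5_up"]],
        ["uorf_up_cds_up", "uorf_up_cds_down", "uorf_up_cds_flat"], "none")
    return merged


def intersect_eif4g2(class_table: pd.DataFrame, clip_table: pd.DataFrame,
                     uorfs: list[ORFRecord], tx_to_gene: dict[str, str],
                     thresholds: Thresholds | None = None) -> dict[str, set[str]]:
    """Intersect eIF4G2-bound transcripts (fold change > 1, no p filter) with
    the uORF-bearing and translation-coupled gene sets (uORF score > 0.6)."""
    from .clip4g2 import call_bound
    from .plribo import filter_uorfs

    th = thresholds or Thresholds()
    bound_tx = call_bound(clip_table, mode="intersect", thresholds=th)
    bound_genes = {tx_to_gene.get(tx, tx) for tx in bound_tx}
    uorf_genes = {tx_to_gene.get(o.tx_id, o.tx_id)
                  for o in filter_uorfs(uorfs, score_min=th.orf_score_intersect)}
    utr5_up = set(class_table.loc[class_table["utr5_up"], "gene_id"])
    cds_up = set(class_table.loc[class_table["cds_class"] == "up", "gene_id"])
    cds_down = set(class_table.loc[class_table["cds_class"] == "down", "gene_id"])
    return {
        "bound": bound_genes,
        "uorf": uorf_genes,
        "bound_uorf_up": bound_genes & uorf_genes & utr5_up,
        "bound_cds_up": bound_genes & cds_up,
        "bound_cds_down": bound_genes & cds_down,
        "bound_uorf_cds_up": bound_genes & uorf_genes & utr5_up & cds_up,
    }


# ---------------------------------------------------------------------------
# Distribution comparisons and correlations
# ---------------------------------------------------------------------------

def ks_compare(values_a, values_b) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov-Smirnov D and asymptotic p."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("need at least one value per sample")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def correlate_datasets(table_a: pd.DataFrame, table_b: pd.DataFrame,
                       key: str = "feature_id", value: str = "log2fc"
                       ) -> dict[str, float]:
    """Pearson (and Spearman) correlation of matched log-scale values."""
    merged = table_a[[key, value]].merge(table_b[[key, value]], on=key,
                                         suffixes=("_a", "_b")).dropna()
    if len(merged) < 3:
        raise ValueError(f"need >= 3 shared keys, got {len(merged)}")
    r, p = stats.pearsonr(merged[f"{value}_a"], merged[f"{value}_b"])
    rho, p_s = stats.spearmanr(merged[f"{value}_a"], merged[f"{value}_b"])
    return {"pearson_r": float(r), "pearson_p": float(p),
            "spearman_rho": float(rho), "spearman_p": float(p_s),
            "n": len(merged)}


# ---------------------------------------------------------------------------
# Reporter quantification
# ---------------------------------------------------------------------------

def reporter_fold_change(flag_dep, actin_dep, flag_rest, actin_rest):
    """(Flag_dep/Actin_dep) / (Flag_rest/Actin_rest), elementwise."""
    arrays = [np.asarray(x, dtype=float) for x in
              (flag_dep, actin_dep, flag_rest, actin_rest)]
    if any(np.any(a <= 0) for a in arrays):
        raise ValueError("reporter inputs must be positive")
    fd, ad, fr, ar = arrays
    return (fd / ad) / (fr / ar)


def reporter_summary(flag_dep, actin_dep, flag_rest, actin_rest,
                     reference_fc=None) -> dict[str, float]:
    """Per-replicate fold changes with mean +/- sd and, when a reference
    construct's fold changes are given, a two-tailed paired t against it."""
    fc = np.atleast_1d(reporter_fold_change(flag_dep, actin_dep,
                                            flag_rest, actin_rest))
    out = {"mean": float(fc.mean()),
           "sd": float(fc.std(ddof=1)) if len(fc) > 1 else float("nan"),
           "n": len(fc)}
    if reference_fc is not None:
        ref = np.asarray(reference_fc, dtype=float)
        if len(ref) != len(fc):
            raise ValueError("reference fold changes must pair with replicates")
        t, p = stats.ttest_rel(fc, ref)
        out["t_vs_reference"] = float(t)
        out["p_vs_reference"] = float(p)
    return out


# ---------------------------------------------------------------------------
# Transcript feature comparisons
# ---------------------------------------------------------------------------

def compare_transcript_features(set_a: set[str], set_b: set[str],
                                models: list[TranscriptModel]) -> pd.DataFrame:
    """Wilcoxon rank-sum comparison of region lengths and 5'UTR GC between two
    transcript sets; medians and effect direction per feature."""
    if not set_a or not set_b:
        raise ValueError("both transcript sets must be nonempty")
    model_of = {m.tx_id: m for m in models}

    def values(ids: set[str], attr: str) -> np.ndarray:
        vals = [getattr(model_of[t], attr) for t in ids if t in model_of]
        return np.array([v for v in vals if v is not None], dtype=float)

    rows = []
    for attr in ("utr5_len", "cds_len", "utr3_len", "gc_frac"):
        a = values(set_a, attr)
        b = values(set_b, attr)
        if len(a) == 0 or len(b) == 0:
            continue
        stat, p = stats.ranksums(a, b)
        rows.append({"feature": attr,
                     "median_a": float(np.median(a)), "median_b": float(np.median(b)),
                     "direction": "a>b" if np.median(a) > np.median(b) else
                     ("a<b" if np.median(a) < np.median(b) else "a=b"),
                     "stat": float(stat), "p": float(p),
                     "n_a": len(a), "n_b": len(b)})
    return pd.DataFrame(rows)
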