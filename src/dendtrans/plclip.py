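"""Dendritic RNA enrichment from the bait x fraction x condition count design.

The inference follows the nested-contrast design: per-condition enrichment
contrasts (PSD95 pulldown minus Pan pulldown) and their difference across
conditions, fit by per-gene ordinary least squares on log-cpm values with
optional fixed-df empirical-Bayes variance moderation. Precision/quality
weighting is deliberately not reproduced; recovery of planted effects is the
validation target, not replication of any third-party tool's gene lists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CountMatrix, Thresholds, logger

VAR_FLOOR = 1e-8


@dataclass
class DesignMatrix:
    """Sample x coefficient matrix with named columns (full rank required)."""

    matrix: np.ndarray
    colnames: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.sample_ids), len(self.colnames)):
            raise ValueError("design shape inconsistent")

    @property
    def full_rank(self) -> bool:
        return np.linalg.matrix_rank(self.matrix) == self.matrix.shape[1]

    def contrast(self, weights: dict[str, float]) -> np.ndarray:
        """Build a coefficient contrast vector from group-coefficient weights."""
        c = np.zeros(len(self.colnames))
        for name, w in weights.items():
            if name not in self.colnames:
                raise ValueError(f"unknown design column {name!r}")
            c[self.colnames.index(name)] = w
        return c


def build_design(meta: pd.DataFrame, include_batch: bool = True) -> DesignMatrix:
    """Group-means design over condition x bait with additive batch indicators.

    Groups are coded as one indicator per condition.bait combination (no
    intercept), so a group coefficient is that group's adjusted mean; batch
    is coded with treatment indicators dropping the first level.
    """
    meta = meta.reset_index(drop=True)
    groups = meta["condition"].astype(str) + "." + meta["bait"].astype(str)
    group_levels = sorted(groups.unique())
    cols, names = [], []
    for g in group_levels:
        cols.append((groups == g).to_numpy(float))
        names.append(g)
    if include_batch:
        batches = sorted(meta["batch"].astype(str).unique())
        for b in batches[1:]:
            cols.append((meta["batch"].astype(str) == b).to_numpy(float))
            names.append(f"batch.{b}")
    X = np.column_stack(cols)
    design = DesignMatrix(X, names, meta["sample_id"].tolist())
    if not design.full_rank:
        raise ValueError("design matrix is rank deficient")
    return design


# ---------------------------------------------------------------------------
# Filtering and transforms
# ---------------------------------------------------------------------------

def filter_low_expression(cm: CountMatrix, meta: pd.DataFrame,
                          min_cpm: float = 1.0) -> CountMatrix:
    """Keep features with cpm >= min_cpm in at least k samples.

    k is the smallest condition x bait group size among the matrix's samples;
    all-zero features are always removed.
    """
    sub = meta[meta["sample_id"].isin(cm.sample_ids)]
    group_sizes = sub.groupby(["condition", "bait"]).size()
    k = int(group_sizes.min()) if len(group_sizes) else 1
    lib = np.where(cm.lib_sizes > 0, cm.lib_sizes, np.nan)
    cpm = cm.counts / lib * 1e6
    keep = (np.nansum(cpm >= min_cpm, axis=1) >= k) & (cm.counts.sum(axis=1) > 0)
    if not keep.any():
        raise ValueError("all features removed by expression filter; lower min_cpm")
    kept = [f for f, k_ in zip(cm.feature_ids, keep) if k_]
    logger.info("expression filter kept %d/%d features (k=%d, min_cpm=%g)",
                len(kept), len(cm.feature_ids), k, min_cpm)
    return cm.subset_features(kept)


def log_cpm(cm: CountMatrix) -> np.ndarray:
    """log2((count + 0.5) / (lib_size + 1) * 1e6)."""
    if np.any(cm.lib_sizes <= 0):
        raise ValueError("log_cpm requires positive library sizes")
    return np.log2((cm.counts + 0.5) / (cm.lib_sizes + 1.0) * 1e6)


# ---------------------------------------------------------------------------
# Linear-model contrasts
# ---------------------------------------------------------------------------

def fit_contrast(logmat: np.ndarray, design: DesignMatrix, contrast: np.ndarray,
                 feature_ids: list[str] | None = None, moderate: bool = True,
                 prior_df: float = 4.0, basemean: np.ndarray | None = None) -> pd.DataFrame:
    """Per-feature OLS estimate of a contrast with (optionally moderated) t.

    Per-feature residual variances may be shrunk toward their grand mean with
    ``prior_df`` pseudo-observations; the t reference df grows accordingly.
    """
    Y = np.asarray(logmat, dtype=float)
    X = design.matrix
    n, p = X.shape
    if Y.shape[1] != n:
        raise ValueError("logmat columns must match design rows")
    df_resid = n - p
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    if not design.full_rank:
        raise ValueError("design matrix is rank deficient")
    c = np.asarray(contrast, dtype=float)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = Y @ X @ xtx_inv.T                    # features x p
    resid = Y - beta @ X.T
    s2 = np.maximum((resid ** 2).sum(axis=1) / df_resid, VAR_FLOOR)
    est = beta @ c
    c_var = float(c @ xtx_inv @ c)
    if moderate and len(s2) > 1:
        s2_prior = float(np.mean(s2))
        s2_post = (prior_df * s2_prior + df_resid * s2) / (prior_df + df_resid)
        df_t = df_resid + prior_df
    else:
        s2_post = s2
        df_t = df_resid
    se = np.sqrt(np.maximum(s2_post * c_var, VAR_FLOOR))
    t = est / se
    p_val = 2.0 * stats.t.sf(np.abs(t), df_t)
    out = pd.DataFrame({
        "feature_id": feature_ids if feature_ids is not None else np.arange(len(est)),
        "log2fc": est, "stat": t, "p": p_val,
        "basemean": basemean if basemean is not None else Y.mean(axis=1),
    })
    out["p_adj"] = adjust_bh(out["p"].to_numpy())
    out.attrs["moderated"] = bool(moderate and len(s2) > 1)
    out.attrs["df"] = float(df_t)
    return out


def adjust_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def call_localized(rest: pd.DataFrame, dep: pd.DataFrame, diff: pd.DataFrame,
                   thresholds: Thresholds | None = None) -> pd.DataFrame:
    """Flag localized transcripts by raw t-statistic cutoffs (strict >)."""
    th = thresholds or Thresholds()
    merged = (rest[["feature_id", "stat"]].rename(columns={"stat": "t_rest"})
              .merge(dep[["feature_id", "stat"]].rename(columns={"stat": "t_dep"}),
                     on="feature_id")
              .merge(diff[["feature_id", "stat"]].rename(columns={"stat": "t_diff"}),
                     on="feature_id"))
    merged["localized_rest"] = merged["t_rest"] > th.t_loc_single
    merged["localized_dep"] = merged["t_dep"] > th.t_loc_single
    merged["localized_diff"] = merged["t_diff"] > th.t_loc_diff
    return merged


# ---------------------------------------------------------------------------
# Full stage
# ---------------------------------------------------------------------------

CONTRASTS = {
    "rest": {"rest.PSD95": 1.0, "rest.Pan": -1.0},
    "dep": {"dep.PSD95": 1.0, "dep.Pan": -1.0},
    "diff": {"dep.PSD95": 1.0, "dep.Pan": -1.0, "rest.PSD95": -1.0, "rest.Pan": 1.0},
}


def run_plclip(cm: CountMatrix, meta: pd.DataFrame,
               thresholds: Thresholds | None = None,
               moderate: bool = True) -> dict[str, pd.DataFrame]:
    """Full PL-CLIP stage on pulldown samples: filter, fit all three contrasts,
    and emit localization calls keyed by the contrast names rest/dep/diff."""
    th = thresholds or Thresholds()
    pulldown = meta[(meta["fraction"] == "pulldown") & (meta["biotin"] == "plus")]
    cm_pd = cm.subset_samples([s for s in cm.sample_ids
                               if s in set(pulldown["sample_id"])])
    cm_f = filter_low_expression(cm_pd, pulldown, min_cpm=th.min_cpm)
    logmat = log_cpm(cm_f)
    sub = pulldown.set_index("sample_id").loc[cm_f.sample_ids].reset_index()
    design = build_design(sub)
    basemean = (cm_f.counts / cm_f.lib_sizes * 1e6).mean(axis=1)
    results = {}
    for name, weights in CONTRASTS.items():
        results[name] = fit_contrast(
            logmat, design, design.contrast(weights),
            feature_ids=cm_f.feature_ids, moderate=moderate, basemean=basemean)
    results["calls"] = call_localized(results["rest"], results["dep"],
                                      results["diff"], th)
    return results


def pca_qc(logmat: np.ndarray, top_n: int = 500) -> tuple[np.ndarray, np.ndarray]:
    """PCA of samples on the top_n most variable features.

    Returns (sample coordinates, variance-explained fractions).
    """
    Y = np.asarray(logmat, dtype=float)
    if Y.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    if Y.shape[0] < 2:
        raise ValueError("PCA needs at least 2 features")
    var = Y.var(axis=1)
    top = np.argsort(var)[::-1][: min(top_n, len(var))]
    Z = Y[top] - Y[top].mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    coords = (vt.T * s)  # samples x components
    total_var = (Z ** 2).sum()
    var_explained = (s ** 2) / total_var if total_var > 0 else np.zeros_like(s)
    return coords, var_explained
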