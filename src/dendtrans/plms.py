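"""Proximity proteomics processing: log2 transform, detection filter,
downshifted-normal imputation, quartile-based width adjustment, minus-biotin
subtraction and enrichment t-tests.

Fixed pipeline order (logged per run):
log2 -> filter -> impute -> width_adjust -> subtract -> test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import logger


def log2_intensities(table: pd.DataFrame) -> pd.DataFrame:
    """log2 of positive intensities; nonpositive/missing entries become NaN."""
    values = table.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(values > 0, np.log2(np.where(values > 0, values, 1.0)), np.nan)
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def filter_detection(table: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Keep proteins observed in >= ceil(2n/3) replicates of >= 1 condition.

    Conditions are condition x bait x biotin cells of the design; n is the
    number of replicates in that cell.
    """
    keep = np.zeros(len(table), dtype=bool)
    groups = meta.groupby(["condition", "bait", "biotin"])["sample_id"]
    for _, sample_ids in groups:
        cols = [s for s in sample_ids if s in table.columns]
        if not cols:
            continue
        n = len(cols)
        need = int(np.ceil(2 * n / 3))
        keep |= (table[cols].notna().sum(axis=1) >= need).to_numpy()
    logger.info("detection filter kept %d/%d proteins", int(keep.sum()), len(table))
    return table.loc[keep]


def impute_downshift(table: pd.DataFrame, width: float = 0.3,
                     downshift: float = 1.8, seed: int | None = None) -> pd.DataFrame:
    """Perseus-style imputation: per column, missing entries are drawn from
    Normal(mean = m - downshift*s, sd = width*s) with m, s from observed values."""
    rng = np.random.default_rng(seed)
    out = table.copy()
    for col in table.columns:
        observed = table[col].dropna()
        missing = table[col].isna()
        if not missing.any():
            continue
        if len(observed) < 2:
            raise ValueError(f"column {col!r}: < 2 observed values, cannot impute")
        m, s = observed.mean(), observed.std(ddof=1)
        out.loc[missing, col] = rng.normal(m - downshift * s, width * s,
                                           size=int(missing.sum()))
    return out


def width_adjust(table: pd.DataFrame) -> pd.DataFrame:
    """Equalize location and interquartile width across sample columns.

    Per column: subtract the median, divide by the IQR, rescale by the median
    IQR across columns and re-center at the median of column medians.
    """
    values = table.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("width_adjust requires a complete table")
    med = np.median(values, axis=0)
    q75 = np.percentile(values, 75, axis=0)
    q25 = np.percentile(values, 25, axis=0)
    iqr = q75 - q25
    if np.any(iqr == 0):
        raise ValueError("zero IQR column; cannot width-adjust")
    target_iqr = np.median(iqr)
    target_med = np.median(med)
    out = (values - med) / iqr * target_iqr + target_med
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def subtract_minus_biotin(table: pd.DataFrame, meta: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subtract each plus-biotin sample's matched minus-biotin counterpart
    (same condition, bait, replicate), in log2 space.

    Returns (corrected table keyed by the plus-biotin sample ids, metadata of
    the retained samples)."""
    meta = meta.set_index("sample_id")
    plus = meta[meta["biotin"] == "plus"]
    minus = meta[meta["biotin"] == "minus"]
    key_cols = ["condition", "bait", "replicate"]
    minus_lookup = {tuple(r[key_cols]): sid for sid, r in minus.iterrows()}
    corrected = {}
    pairs = []
    for sid, r in plus.iterrows():
        if sid not in table.columns:
            continue
        partner = minus_lookup.get(tuple(r[key_cols]))
        if partner is None or partner not in table.columns:
            raise ValueError(f"sample {sid!r}: no matched minus-biotin sample")
        corrected[sid] = table[sid] - table[partner]
        pairs.append((sid, partner))
    logger.info("minus-biotin subtraction pairs: %s", pairs)
    out_meta = plus.loc[[sid for sid, _ in pairs]].reset_index()
    return pd.DataFrame(corrected, index=table.index), out_meta


def _paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    d = np.asarray(x, float) - np.asarray(y, float)
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0:
        return mean, 0.0, 1.0  # degenerate: flagged via p = 1
    t = mean / (sd / np.sqrt(len(d)))
    p = 2.0 * stats.t.sf(abs(t), len(d) - 1)
    return mean, float(t), float(p)


def test_enrichment(corrected: pd.DataFrame, meta: pd.DataFrame,
                    contrast: str = "rest", p_cut: float = 0.05) -> pd.DataFrame:
    """Enrichment t-tests on minus-biotin-corrected log2 intensities.

    contrast 'rest'/'dep': paired two-tailed t of PSD95 vs Pan replicates in
    that condition. contrast 'diff': unpaired two-tailed t of dep vs rest
    PSD95-minus-Pan replicate differences. Enriched iff mean log2 diff > 0
    and p < p_cut (strict).
    """
    meta = meta[meta["sample_id"].isin(corrected.columns)]

    def replicate_pairs(cond: str) -> pd.DataFrame:
        sub = meta[meta["condition"] == cond]
        psd = sub[sub["bait"] == "PSD95"].set_index("replicate")["sample_id"]
        pan = sub[sub["bait"] == "Pan"].set_index("replicate")["sample_id"]
        reps = sorted(set(psd.index) & set(pan.index))
        if len(reps) < 2:
            raise ValueError(f"condition {cond!r}: < 2 replicate pairs")
        return corrected[psd.loc[reps]].to_numpy() - corrected[pan.loc[reps]].to_numpy()

    rows = []
    if contrast in ("rest", "dep"):
        diffs = replicate_pairs(contrast)
        for i, pid in enumerate(corrected.index):
            est, t, p = _paired_t(diffs[i], np.zeros(diffs.shape[1]))
            rows.append({"feature_id": pid, "log2fc": est, "stat": t, "p": p})
    elif contrast == "diff":
        d_rest = replicate_pairs("rest")
        d_dep = replicate_pairs("dep")
        for i, pid in enumerate(corrected.index):
            t, p = stats.ttest_ind(d_dep[i], d_rest[i], equal_var=True)
            est = d_dep[i].mean() - d_rest[i].mean()
            if np.isnan(t):
                t, p = 0.0, 1.0
            rows.append({"feature_id": pid, "log2fc": est,
                         "stat": float(t), "p": float(p)})
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    out = pd.DataFrame(rows)
    out["enriched"] = (out["log2fc"] > 0) & (out["p"] < p_cut)
    out["basemean"] = corrected.mean(axis=1).to_numpy()
    return out


def run_plms(intensities: pd.DataFrame, meta: pd.DataFrame,
             width: float = 0.3, downshift: float = 1.8,
             p_cut: float = 0.05, seed: int | None = None) -> dict[str, pd.DataFrame]:
    """Full PL-MS stage in the fixed order; returns per-contrast ResultTables."""
    logger.info("plms order: log2 -> filter -> impute(width=%g, downshift=%g) "
                "-> width_adjust -> subtract -> test", width, downshift)
    logged = log2_intensities(intensities)
    filtered = filter_detection(logged, meta)
    imputed = impute_downshift(filtered, width=width, downshift=downshift, seed=seed)
    adjusted = width_adjust(imputed)
    corrected, plus_meta = subtract_minus_biotin(adjusted, meta)
    return {c: test_enrichment(corrected, plus_meta, contrast=c, p_cut=p_cut)
            for c in ("rest", "dep", "diff")}
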