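"""Region-resolved ribosome occupancy: P-site assignment, 5'UTR/CDS counting,
RPKM + quantile normalization, dendritic translation enrichment, NB-GLM LRT,
z-score differential testing with a basemean fallback, permutation tests and
uORF filtering.

Notes on the statistical choices
--------------------------------
* The negative binomial is parameterized mean/dispersion: Var = mu + alpha*mu^2.
  Dispersion is shared between the null and alternative fits and estimated by
  method of moments (floored at 1e-8), so at the floor the LRT converges to the
  Poisson deviance difference.
* The differential significance procedure z-transforms observed log2 fold
  changes over all admitted transcripts and flags |z| > 1.96 (2.5% per tail),
  with two-sided normal p-values.
* Permutation p-values use +1 smoothing and an exhaustive enumeration of
  labelings whenever their number is <= ``max_exhaustive``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .core_io import CountMatrix, ORFRecord, Thresholds, TranscriptModel, logger

DISP_FLOOR = 1e-8
REGIONS = ("utr5", "cds")


# ---------------------------------------------------------------------------
# P-sites and region counting
# ---------------------------------------------------------------------------

def assign_psites(read_3prime_positions: np.ndarray, offset: int = 12) -> np.ndarray:
    """P-site = 3'-end position - offset; reads mapping before 0 are dropped."""
    pos = np.asarray(read_3prime_positions, dtype=np.int64)
    psites = pos - offset
    n_dropped = int((psites < 0).sum())
    if n_dropped:
        logger.info("assign_psites dropped %d read(s) with negative P-site", n_dropped)
    return psites[psites >= 0]


def count_regions(psites_by_sample: dict[str, dict[str, np.ndarray]],
                  models: list[TranscriptModel]) -> CountMatrix:
    """Count P-sites into 5'UTR/CDS regions per transcript.

    ``psites_by_sample`` maps sample_id -> {tx_id: psite position array}.
    Positions in [0, utr5_len) count to utr5, [utr5_len, utr5_len+cds_len) to
    cds; the remainder (3'UTR) is discarded.
    """
    model_of = {m.tx_id: m for m in models}
    sample_ids = list(psites_by_sample)
    unknown = sorted({tx for s in psites_by_sample.values() for tx in s}
                     - set(model_of))
    if unknown:
        raise ValueError(f"unknown transcript id(s): {unknown}")
    tx_ids = sorted({tx for s in psites_by_sample.values() for tx in s})
    feature_ids = [f"{tx}:{region}" for tx in tx_ids for region in REGIONS]
    row = {f: i for i, f in enumerate(feature_ids)}
    counts = np.zeros((len(feature_ids), len(sample_ids)), dtype=np.int64)
    discarded = 0
    for j, sid in enumerate(sample_ids):
        for tx, pos in psites_by_sample[sid].items():
            m = model_of[tx]
            pos = np.asarray(pos, dtype=np.int64)
            in_utr5 = int(((pos >= 0) & (pos < m.utr5_len)).sum())
            in_cds = int(((pos >= m.utr5_len) & (pos < m.utr5_len + m.cds_len)).sum())
            counts[row[f"{tx}:utr5"], j] += in_utr5
            counts[row[f"{tx}:cds"], j] += in_cds
            discarded += len(pos) - in_utr5 - in_cds
    if discarded:
        logger.info("count_regions discarded %d P-site(s) outside 5'UTR/CDS", discarded)
    return CountMatrix(feature_ids, sample_ids, counts)


def split_region_matrix(cm: CountMatrix) -> dict[str, CountMatrix]:
    """Split a '<tx>:<region>' matrix into per-region matrices sharing lib sizes."""
    out = {}
    for region in REGIONS:
        suffix = f":{region}"
        feats = [f for f in cm.feature_ids if f.endswith(suffix)]
        sub = cm.subset_features(feats)
        sub.feature_ids = [f[: -len(suffix)] for f in feats]
        sub.lib_sizes = cm.lib_sizes.copy()  # depth = total mapped, not per-region
        out[region] = sub
    return out


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def rpkm(counts: np.ndarray, lengths: np.ndarray, lib_sizes: np.ndarray) -> np.ndarray:
    """Reads per kilobase per million mapped reads."""
    lengths = np.asarray(lengths, dtype=float)
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("rpkm requires positive region lengths")
    if np.any(lib_sizes <= 0):
        raise ValueError("rpkm requires positive library sizes")
    return np.asarray(counts, float) / (lengths[:, None] / 1e3) / (lib_sizes[None, :] / 1e6)


def quantile_normalize(mat: np.ndarray) -> np.ndarray:
    """Classic quantile normalization: each column's sorted values are replaced
    by the cross-column means of sorted values; ties receive the mean of the
    reference values they span."""
    X = np.asarray(mat, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("quantile_normalize needs a matrix with >= 2 columns")
    if np.isnan(X).any():
        raise ValueError("quantile_normalize requires a complete matrix")
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        ranks = stats.rankdata(X[:, j], method="average") - 1.0
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        out[:, j] = (ref[lo] + ref[hi]) / 2.0
    return out


# ---------------------------------------------------------------------------
# Dendritic translation enrichment
# ---------------------------------------------------------------------------

def dendritic_translation(norm_rpkm: pd.DataFrame, meta: pd.DataFrame,
                          condition: str, eps: float = 0.1) -> pd.Series:
    """log2(mean PSD95-pulldown + eps) - log2(mean of all inputs + eps),
    restricted to one condition's samples."""
    sub = meta[(meta["condition"] == condition) & (meta["biotin"] == "plus")]
    pd_ids = sub[(sub["bait"] == "PSD95") & (sub["fraction"] == "pulldown")]["sample_id"]
    in_ids = sub[sub["fraction"] == "input"]["sample_id"]
    pd_ids = [s for s in pd_ids if s in norm_rpkm.columns]
    in_ids = [s for s in in_ids if s in norm_rpkm.columns]
    if not pd_ids or not in_ids:
        raise ValueError(f"condition {condition!r}: missing PSD95-pulldown or input samples")
    pulldown_mean = norm_rpkm[pd_ids].mean(axis=1)
    input_mean = norm_rpkm[in_ids].mean(axis=1)
    return np.log2(pulldown_mean + eps) - np.log2(input_mean + eps)


# ---------------------------------------------------------------------------
# NB GLM likelihood-ratio test
# ---------------------------------------------------------------------------

def _nb_loglik_mu_terms(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB log-likelihood terms depending on mu (y-only terms cancel in LRTs)."""
    mu = np.maximum(mu, 1e-300)
    return float(np.sum(y * np.log(alpha * mu / (1.0 + alpha * mu))
                        - np.log1p(alpha * mu) / alpha))


def _nb_fit_scalar(y: np.ndarray, exposure: np.ndarray, alpha: float) -> float:
    """MLE of b in mu_i = exp(b) * exposure_i for NB with fixed dispersion."""
    if y.sum() == 0:
        return -np.inf
    b = np.log(y.sum() / exposure.sum())
    for _ in range(100):
        mu = np.exp(b) * exposure
        f = np.sum((y - mu) / (1.0 + alpha * mu))
        fprime = -np.sum(mu * (1.0 + alpha * y) / (1.0 + alpha * mu) ** 2)
        step = f / fprime
        b -= step
        if abs(step) < 1e-13:
            break
    return b


def nb_dispersion_mom(y: np.ndarray, mu: np.ndarray) -> float:
    """Method-of-moments dispersion: solves Var = mu + alpha mu^2, floored."""
    denom = float(np.sum(mu ** 2))
    if denom == 0:
        return DISP_FLOOR
    alpha = float(np.sum((y - mu) ** 2 - mu) / denom)
    return max(alpha, DISP_FLOOR)


def nb_glm_lrt(y: np.ndarray, lib_sizes: np.ndarray, indicator: np.ndarray,
               alpha: float | None = None) -> tuple[float, float]:
    """LRT of a binary group indicator in a NB GLM with log(lib_size) offset.

    Null: common rate. Alternative: separate rate per indicator level.
    Dispersion, unless given, is method-of-moments from the alternative
    Poisson fit and shared between the two models. Returns (stat, p).
    """
    y = np.asarray(y, dtype=float)
    exposure = np.asarray(lib_sizes, dtype=float)
    ind = np.asarray(indicator, dtype=bool)
    if y.shape != exposure.shape or y.shape != ind.shape:
        raise ValueError("y, lib_sizes and indicator must align")
    if ind.all() or (~ind).all():
        raise ValueError("indicator must have two levels")
    if alpha is None:
        mu_hat = np.empty_like(y)
        for level in (True, False):
            mask = ind == level
            rate = y[mask].sum() / exposure[mask].sum()
            mu_hat[mask] = rate * exposure[mask]
        alpha = nb_dispersion_mom(y, mu_hat)

    def group_ll(mask: np.ndarray) -> float:
        b = _nb_fit_scalar(y[mask], exposure[mask], alpha)
        mu = np.exp(b) * exposure[mask] if np.isfinite(b) else np.zeros(mask.sum())
        return _nb_loglik_mu_terms(y[mask], mu, alpha)

    ll_alt = group_ll(ind) + group_ll(~ind)
    ll_null = group_ll(np.ones_like(ind, dtype=bool))
    stat = max(0.0, 2.0 * (ll_alt - ll_null))
    return stat, float(stats.chi2.sf(stat, df=1))


def test_translation_lrt(cds_cm: CountMatrix, meta: pd.DataFrame, condition: str,
                         basemean_min: float = 1.0) -> pd.DataFrame:
    """Per-transcript NB-GLM LRT of PSD95-pulldown vs input samples within a
    condition; transcripts at or below the basemean floor get NaN stats."""
    sub = meta[(meta["condition"] == condition) & (meta["biotin"] == "plus")
               & (meta["sample_id"].isin(cds_cm.sample_ids))]
    keep = sub[(sub["fraction"] == "input")
               | ((sub["fraction"] == "pulldown") & (sub["bait"] == "PSD95"))]
    cm = cds_cm.subset_samples(keep["sample_id"].tolist())
    indicator = (keep.set_index("sample_id").loc[cm.sample_ids, "fraction"]
                 == "pulldown").to_numpy()
    if indicator.sum() < 2 or (~indicator).sum() < 2:
        raise ValueError("need >= 2 samples per class for the LRT")
    norm = cm.counts / cm.lib_sizes * cm.lib_sizes.mean()
    basemean = norm.mean(axis=1)
    stats_, ps, flags = [], [], []
    for i in range(len(cm.feature_ids)):
        if basemean[i] <= basemean_min:
            stats_.append(np.nan); ps.append(np.nan); flags.append("low_basemean")
            continue
        try:
            s, p = nb_glm_lrt(cm.counts[i], cm.lib_sizes, indicator)
            stats_.append(s); ps.append(p); flags.append("ok")
        except (ValueError, FloatingPointError):
            stats_.append(np.nan); ps.append(np.nan); flags.append("fit_failed")
    return pd.DataFrame({"feature_id": cm.feature_ids, "lrt_stat": stats_,
                         "lrt_p": ps, "basemean": basemean, "lrt_flag": flags})


# ---------------------------------------------------------------------------
# Differential z procedure and basemean fallback
# ---------------------------------------------------------------------------

def differential_translation_z(log2fc: np.ndarray, z_cut: float = 1.96,
                               min_n: int = 30) -> pd.DataFrame:
    """z-transform observed fold changes; flag |z| > z_cut, two-sided normal p."""
    fc = np.asarray(log2fc, dtype=float)
    finite = np.isfinite(fc)
    if finite.sum() < min_n:
        raise ValueError(f"need >= {min_n} finite fold changes, got {finite.sum()}")
    mean = fc[finite].mean()
    sd = fc[finite].std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate input: zero fold-change dispersion")
    z = np.where(finite, (fc - mean) / sd, np.nan)
    p = 2.0 * stats.norm.sf(np.abs(z))
    sig = np.abs(z) > z_cut
    direction = np.sign(fc)
    return pd.DataFrame({"log2fc": fc, "z": z, "p_z": p,
                         "significant": np.where(finite, sig, False),
                         "direction": direction})


def apply_basemean_fallback(diff: pd.DataFrame, rest: pd.DataFrame,
                            dep: pd.DataFrame, basemean_min: float = 1.0) -> pd.DataFrame:
    """Admit transcripts to the differential set by basemean, with the
    highest-expressed-transcript fallback.

    All three tables need ``feature_id``, ``gene_id``, ``basemean`` and
    ``log2fc`` columns keyed identically. A transcript below the floor in the
    differential but at/above it in both single-condition tables inherits the
    differential value of its gene's highest-expressed transcript.
    """
    merged = diff.merge(rest[["feature_id", "basemean"]], on="feature_id",
                        suffixes=("", "_rest"))
    merged = merged.merge(dep[["feature_id", "basemean"]], on="feature_id",
                          suffixes=("", "_dep"))
    best_idx = merged.groupby("gene_id")["basemean"].idxmax()
    best_fc = merged.loc[best_idx].set_index("gene_id")["log2fc"]

    direct = merged["basemean"] >= basemean_min
    rescue = (~direct & (merged["basemean_rest"] >= basemean_min)
              & (merged["basemean_dep"] >= basemean_min))
    out = merged.copy()
    out["admitted"] = direct | rescue
    out["source"] = np.select([direct, rescue], ["direct", "fallback"], "excluded")
    out.loc[rescue, "log2fc"] = out.loc[rescue, "gene_id"].map(best_fc).to_numpy()
    return out


# ---------------------------------------------------------------------------
# Permutation t-test
# ---------------------------------------------------------------------------

def _welch_t(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    denom = np.sqrt(va / na + vb / nb)
    if denom == 0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def permutation_t_test(a: np.ndarray, b: np.ndarray, n_perm: int = 10_000,
                       seed: int | None = None,
                       max_exhaustive: int = 10_000) -> tuple[float, float, bool]:
    """Two-sample permutation test with a Welch t statistic.

    Exhaustive over all C(n, len(a)) labelings when that number is
    <= max_exhaustive, else n_perm random labelings. p uses +1 smoothing:
    (1 + #{|t_perm| >= |t_obs|}) / (1 + N). Returns (t_obs, p, exhaustive?).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        return 0.0, 1.0, True
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    t_obs = _welch_t(a, b)
    n_labelings = comb(n, na)
    tol = 1e-12
    if n_labelings <= max_exhaustive:
        count = 0
        for idx in itertools.combinations(range(n), na):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            if abs(_welch_t(pooled[mask], pooled[~mask])) >= abs(t_obs) - tol:
                count += 1
        return t_obs, (1 + count) / (1 + n_labelings), True
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if abs(_welch_t(pooled[perm[:na]], pooled[perm[na:]])) >= abs(t_obs) - tol:
            count += 1
    return t_obs, (1 + count) / (1 + n_perm), False


def permutation_region_test(region_rpkm: dict[str, pd.DataFrame], meta: pd.DataFrame,
                            n_perm: int = 10_000, seed: int | None = None) -> pd.DataFrame:
    """Permutation Welch-t of per-sample mean region RPKM, rest vs dep, one test
    per region class; Bonferroni over the number of regions tested."""
    rows = []
    for region, mat in region_rpkm.items():
        sample_means = mat.mean(axis=0)
        rest_ids = meta[(meta["condition"] == "rest")
                        & meta["sample_id"].isin(mat.columns)]["sample_id"]
        dep_ids = meta[(meta["condition"] == "dep")
                       & meta["sample_id"].isin(mat.columns)]["sample_id"]
        t, p, exhaustive = permutation_t_test(
            sample_means[rest_ids].to_numpy(), sample_means[dep_ids].to_numpy(),
            n_perm=n_perm, seed=seed)
        rows.append({"region": region, "t": t, "p": p, "exhaustive": exhaustive})
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = np.minimum(out["p"] * len(out), 1.0)
    return out


# ---------------------------------------------------------------------------
# uORF filtering
# ---------------------------------------------------------------------------

def filter_uorfs(orfs: list[ORFRecord], score_min: float = 0.7,
                 min_len_exclusive: int = 9) -> list[ORFRecord]:
    """Keep uORFs strictly longer than 9 nt (incl. stop) with score strictly
    above score_min; start-codon class is retained for reporting."""
    return [o for o in orfs
            if o.orf_class == "uORF"
            and o.length_nt > min_len_exclusive
            and o.score > score_min]


# ---------------------------------------------------------------------------
# Stage orchestration
# ---------------------------------------------------------------------------

@dataclass
class PlriboResult:
    cds: pd.DataFrame           # per-transcript TranslationResult for CDS
    utr5: pd.DataFrame          # per-transcript TranslationResult for 5'UTR
    region_perm: pd.DataFrame   # pooled permutation test per region class


def run_plribo(region_cm: CountMatrix, meta: pd.DataFrame,
               models: list[TranscriptModel],
               thresholds: Thresholds | None = None,
               n_perm: int = 2_000, seed: int | None = None) -> PlriboResult:
    """Run the full region-resolved translation stage from a region count
    matrix (feature ids '<tx>:utr5' / '<tx>:cds')."""
    th = thresholds or Thresholds()
    model_of = {m.tx_id: m for m in models}
    gene_of = {m.tx_id: m.gene_id for m in models}
    by_region = split_region_matrix(region_cm)

    # RPKM, merged quantile normalization across regions
    region_len = {"utr5": lambda m: m.utr5_len, "cds": lambda m: m.cds_len}
    rpkm_mats, row_labels = [], []
    for region in REGIONS:
        cm = by_region[region]
        keep = [i for i, tx in enumerate(cm.feature_ids)
                if tx in model_of and region_len[region](model_of[tx]) > 0]
        feats = [cm.feature_ids[i] for i in keep]
        lengths = np.array([region_len[region](model_of[tx]) for tx in feats])
        rpkm_mats.append(rpkm(cm.counts[keep], lengths, cm.lib_sizes))
        row_labels.extend((region, tx) for tx in feats)
    stacked = quantile_normalize(np.vstack(rpkm_mats))
    norm = pd.DataFrame(stacked, columns=region_cm.sample_ids,
                        index=pd.MultiIndex.from_tuples(row_labels,
                                                        names=["region", "tx_id"]))

    results = {}
    for region, basemean_min in (("cds", th.basemean_min_cds),
                                 ("utr5", th.basemean_min_utr5)):
        mat = norm.loc[region]
        enr = {cond: dendritic_translation(mat, meta, cond, eps=th.dendritic_eps)
               for cond in ("rest", "dep")}
        diff_fc = enr["dep"] - enr["rest"]

        def _basemean(cond_mask_meta: pd.DataFrame) -> pd.Series:
            ids = [s for s in cond_mask_meta["sample_id"] if s in mat.columns]
            return mat[ids].mean(axis=1)

        plus = meta[meta["biotin"] == "plus"]
        tabs = {}
        for name, fc, sub in (
                ("rest", enr["rest"], plus[plus["condition"] == "rest"]),
                ("dep", enr["dep"], plus[plus["condition"] == "dep"]),
                ("diff", diff_fc, plus)):
            tabs[name] = pd.DataFrame({
                "feature_id": mat.index,
                "gene_id": [gene_of[tx] for tx in mat.index],
                "log2fc": fc.to_numpy(),
                "basemean": _basemean(sub).to_numpy(),
            })
        admitted = apply_basemean_fallback(tabs["diff"], tabs["rest"], tabs["dep"],
                                           basemean_min=basemean_min)
        adm = admitted[admitted["admitted"]].reset_index(drop=True)
        ztab = differential_translation_z(adm["log2fc"].to_numpy(), z_cut=th.z_cut)
        res = pd.concat([adm[["feature_id", "gene_id", "basemean", "source"]],
                         ztab], axis=1)
        res["enrichment_rest"] = res["feature_id"].map(enr["rest"])
        res["enrichment_dep"] = res["feature_id"].map(enr["dep"])
        results[region] = res

    # condition-wise NB-GLM LRT on CDS counts
    lrt = {cond: test_translation_lrt(by_region["cds"], meta, cond,
                                      basemean_min=th.basemean_min_cds)
           for cond in ("rest", "dep")}
    for cond in ("rest", "dep"):
        cols = lrt[cond].set_index("feature_id")
        results["cds"][f"lrt_p_{cond}"] = results["cds"]["feature_id"].map(cols["lrt_p"])

    region_rpkm = {region: norm.loc[region] for region in REGIONS}
    perm = permutation_region_test(region_rpkm, meta, n_perm=n_perm, seed=seed)
    return PlriboResult(cds=results["cds"], utr5=results["utr5"], region_perm=perm)
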