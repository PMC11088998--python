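"""eIF4G2 CLIP 5'UTR binding: depth normalization, pseudocount log2 fold
change, exact binomial testing and bound-set calls.

The binomial null is proportion 0.5 on depth-normalized tags rounded to
integers; two-sided p-values use the minimum-likelihood method (sum over all
outcomes whose pmf does not exceed the observed one). Both choices are logged
per run and configurable where ambiguity exists.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import Thresholds, logger


def normalize_depth(raw_tags: np.ndarray, lib_size: float | np.ndarray) -> np.ndarray:
    """Tags per million mapped reads."""
    lib = np.asarray(lib_size, dtype=float)
    if np.any(lib <= 0):
        raise ValueError("library size must be positive")
    return np.asarray(raw_tags, dtype=float) * 1e6 / lib


def clip_log2fc(norm_dep, norm_rest, pseudocount: float = 0.1):
    """log2((dep + pc) / (rest + pc)); (0, 0) maps to 0 by construction."""
    return np.log2((np.asarray(norm_dep, float) + pseudocount)
                   / (np.asarray(norm_rest, float) + pseudocount))


def binom_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial p by minimum-likelihood summation."""
    if n == 0:
        return 1.0
    if not 0 <= k <= n:
        raise ValueError("k outside [0, n]")
    pmf = stats.binom.pmf(np.arange(n + 1), n, p0)
    # relative tolerance guards against float noise at exactly-equal pmfs
    return float(min(1.0, pmf[pmf <= pmf[k] * (1.0 + 1e-7)].sum()))


def clip_binomial_test(norm_dep: float, norm_rest: float, p0: float = 0.5) -> float:
    """Two-sided exact binomial test on rounded normalized tag values.

    Each side is rounded separately (n = round(dep) + round(rest)), which
    makes the p-value exactly invariant under a dep/rest swap.
    """
    k = int(round(norm_dep))
    n = k + int(round(norm_rest))
    return binom_two_sided(k, n, p0)


def build_utr_tag_table(raw_rest: np.ndarray, raw_dep: np.ndarray,
                        feature_ids: list[str],
                        lib_rest: float | None = None, lib_dep: float | None = None,
                        pseudocount: float = 0.1) -> pd.DataFrame:
    """Assemble the per-transcript 5'UTR tag table with normalized tags,
    fold changes and binomial p-values."""
    raw_rest = np.asarray(raw_rest, dtype=float)
    raw_dep = np.asarray(raw_dep, dtype=float)
    if np.any(raw_rest < 0) or np.any(raw_dep < 0):
        raise ValueError("raw tag counts must be nonnegative")
    lib_rest = float(raw_rest.sum()) if lib_rest is None else lib_rest
    lib_dep = float(raw_dep.sum()) if lib_dep is None else lib_dep
    norm_rest = normalize_depth(raw_rest, lib_rest)
    norm_dep = normalize_depth(raw_dep, lib_dep)
    logger.info("clip4g2: null proportion 0.5 on rounded normalized tags, "
                "pseudocount %g", pseudocount)
    p_binom = np.array([clip_binomial_test(d, r)
                        for d, r in zip(norm_dep, norm_rest)])
    return pd.DataFrame({
        "feature_id": feature_ids,
        "raw_rest": raw_rest, "raw_dep": raw_dep,
        "norm_rest": norm_rest, "norm_dep": norm_dep,
        "log2fc": clip_log2fc(norm_dep, norm_rest, pseudocount),
        "p_binom": p_binom,
    })


def table_from_count_matrix(cm, rest: str = "rest", dep: str = "dep",
                            pseudocount: float = 0.1) -> pd.DataFrame:
    """Build the tag table from a two-column CountMatrix; '__'-prefixed rows
    (e.g. unassigned background) count toward depth but are not tested."""
    i_r, i_d = cm.sample_ids.index(rest), cm.sample_ids.index(dep)
    keep = [i for i, f in enumerate(cm.feature_ids) if not f.startswith("__")]
    feats = [cm.feature_ids[i] for i in keep]
    return build_utr_tag_table(cm.counts[keep, i_r], cm.counts[keep, i_d], feats,
                               lib_rest=float(cm.lib_sizes[i_r]),
                               lib_dep=float(cm.lib_sizes[i_d]),
                               pseudocount=pseudocount)


def call_bound(table: pd.DataFrame, mode: str = "bound",
               thresholds: Thresholds | None = None) -> set[str]:
    """'bound': log2fc > 0 and p < 0.2. 'intersect': fold change > 1 only."""
    th = thresholds or Thresholds()
    if mode == "bound":
        mask = (table["log2fc"] > 0) & (table["p_binom"] < th.clip_p)
    elif mode == "intersect":
        mask = table["log2fc"] > 0
    else:
        raise ValueError(f"unknown mode {mode!r} (expected 'bound' or 'intersect')")
    return set(table.loc[mask, "feature_id"])
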