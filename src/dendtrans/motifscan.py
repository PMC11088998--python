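"""PWM scanning of 5'UTR sequences and hypergeometric enrichment of motif
presence in a foreground transcript set versus an expressed background.

Scoring: per window, sum of log(matrix[base, pos] + 1e-6); a window hits when
its score reaches min_possible + frac * (max_possible - min_possible), the
"minimum score = 95%" convention. Sense strand only (5'UTRs are mRNA).
Enrichment unit is transcript presence (>= 1 hit), matching the
hypergeometric sampling model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .plclip import adjust_bh

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
SCORE_FLOOR = 1e-6


@dataclass
class PWM:
    """Position probability matrix, rows A/C/G/T (U mapped to T)."""

    motif_id: str
    rbp_name: str
    matrix: np.ndarray  # 4 x L

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4:
            raise ValueError(f"{self.motif_id}: PWM must have 4 rows (A,C,G,T)")
        if self.matrix.shape[1] < 3:
            raise ValueError(f"{self.motif_id}: PWM must have length >= 3")
        col_sums = self.matrix.sum(axis=0)
        if np.any(np.abs(col_sums - 1.0) > 1e-6):
            raise ValueError(f"{self.motif_id}: PWM columns must each sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @classmethod
    def from_consensus(cls, motif_id: str, rbp_name: str, consensus: str,
                       match_p: float = 0.997) -> "PWM":
        """Near-deterministic matrix from a consensus string (fixture helper)."""
        consensus = consensus.upper().replace("U", "T")
        L = len(consensus)
        off = (1.0 - match_p) / 3.0
        mat = np.full((4, L), off)
        for j, base in enumerate(consensus):
            mat[BASE_INDEX[base], j] = match_p
        return cls(motif_id, rbp_name, mat)


def read_pwm_file(path: str | Path, motif_id: str | None = None,
                  rbp_name: str = "") -> PWM:
    """Read an RBPmap-style 4-row matrix: lines '<base>[:] p1 p2 ...'."""
    path = Path(path)
    rows: dict[str, list[float]] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", ">", "Pos")):
            continue
        head, *vals = line.replace(":", " ").split()
        base = head.upper().replace("U", "T")
        if base in BASE_INDEX:
            rows[base] = [float(v) for v in vals]
    if set(rows) != set(BASES):
        raise ValueError(f"{path}: expected rows A, C, G, U/T; got {sorted(rows)}")
    mat = np.array([rows[b] for b in BASES])
    return PWM(motif_id or path.stem, rbp_name, mat)


def read_pwm_manifest(path: str | Path) -> list[PWM]:
    """Manifest TSV with columns motif_id, rbp_name, file (relative paths ok)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    pwms = []
    for r in df.itertuples(index=False):
        pwm_path = Path(r.file)
        if not pwm_path.is_absolute():
            pwm_path = path.parent / pwm_path
        pwms.append(read_pwm_file(pwm_path, motif_id=str(r.motif_id),
                                  rbp_name=str(r.rbp_name)))
    return pwms


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def scan_pwm(seq: str, pwm: PWM, min_score_frac: float = 0.95) -> int:
    """Count sense-strand windows scoring >= the interpolated threshold.

    Windows containing a non-ACGT base are skipped (counted in the log).
    A degenerate motif (max == min achievable score) hits every window.
    """
    seq = seq.upper().replace("U", "T")
    L = pwm.length
    if len(seq) < L:
        return 0
    logm = np.log(pwm.matrix + SCORE_FLOOR)
    max_score = logm.max(axis=0).sum()
    min_score = logm.min(axis=0).sum()
    if max_score == min_score:
        warnings.warn(f"{pwm.motif_id}: degenerate motif, every window hits")
    threshold = min_score + min_score_frac * (max_score - min_score)
    idx = np.array([BASE_INDEX.get(b, -1) for b in seq])
    hits = 0
    for start in range(len(seq) - L + 1):
        window = idx[start:start + L]
        if (window < 0).any():
            continue
        score = logm[window, np.arange(L)].sum()
        if score >= threshold - 1e-12:
            hits += 1
    return hits


def presence_matrix(seqs: dict[str, str], pwms: list[PWM],
                    min_score_frac: float = 0.95) -> pd.DataFrame:
    """Binary transcript x motif presence table (1 iff >= 1 hit)."""
    data = {pwm.motif_id: [int(scan_pwm(s, pwm, min_score_frac) >= 1)
                           for s in seqs.values()]
            for pwm in pwms}
    return pd.DataFrame(data, index=list(seqs))


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def hypergeom_enrichment(fg_ids: set[str] | list[str], bg_ids: set[str] | list[str],
                         presence: pd.DataFrame, fdr_cut: float = 0.1) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of motif presence in fg vs bg,
    BH-corrected across motifs; enriched iff fdr < fdr_cut (strict)."""
    fg = set(fg_ids)
    bg = set(bg_ids)
    outside = sorted(fg - bg)
    if outside:
        raise ValueError(f"foreground ids not in background: {outside[:10]}")
    missing = sorted(bg - set(presence.index))
    if missing:
        raise ValueError(f"background ids without sequences: {missing[:10]}")
    fg_list = sorted(fg)
    bg_list = sorted(bg)
    rows = []
    for motif_id in presence.columns:
        col = presence[motif_id]
        fg_hits = int(col.loc[fg_list].sum())
        bg_hits = int(col.loc[bg_list].sum())
        # P(X >= fg_hits) drawing fg_total from bg_total with bg_hits successes
        p = float(stats.hypergeom.sf(fg_hits - 1, len(bg_list), bg_hits, len(fg_list)))
        rows.append({"motif_id": motif_id, "fg_hits": fg_hits,
                     "fg_total": len(fg_list), "bg_hits": bg_hits,
                     "bg_total": len(bg_list), "p_hyper": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["fdr"] = adjust_bh(out["p_hyper"].to_numpy())
    out["enriched"] = out["fdr"] < fdr_cut
    return out
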