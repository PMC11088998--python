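"""Synthetic inputs with the statistical structure the analysis assumes,
plus a truth table, so every downstream stage is testable without downloads.

Each output file draws from its own RNG stream (seed + fixed per-file offset),
so regenerating one file never perturbs the others. Negative binomial counts
use the mean/dispersion parameterization Var = mu + alpha*mu^2. Translation
effects are planted on footprint means only, leaving RNA means fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core_io import (CountMatrix, ORFRecord, TranscriptModel, logger,
                      write_counts, write_fasta, write_orfs, write_sample_sheet)
from .motifscan import PWM

# per-file RNG stream offsets
_STREAM = {"truth": 0, "transcriptome": 1, "rna": 2, "ribo": 3, "clip": 4, "ms": 5}

UORF_CLASSES = ("none", "uorf_up_cds_up", "uorf_up_cds_down", "uorf_up_cds_flat")


@dataclass
class SimParams:
    n_genes: int = 2000
    n_reps_rna: int = 4
    n_reps_ribo: int = 3
    n_reps_ms: int = 5
    # planted fractions (of all genes); cds classes partition part of uorf_up
    frac_dendritic: float = 0.15
    frac_uorf: float = 0.30
    frac_uorf_up: float = 0.12
    frac_cds_up: float = 0.04
    frac_cds_down: float = 0.04
    frac_bound: float = 0.20
    frac_motif: float = 0.30
    motif_coupling: float = 0.9     # P(bound gene carries the motif)
    bound_cds_coupling: float = 0.0  # P(uorf_up_cds_up gene is also bound)
    # planted effect sizes (log2)
    enrich_log2fc: float = 2.0
    uorf_log2fc: float = 2.0
    cds_log2fc: float = 2.0
    clip_log2fc: float = 1.5
    # count/intensity models
    nb_dispersion: float = 0.05
    mean_log_expression: float = 5.0
    sd_log_expression: float = 1.0
    batch_sd: float = 0.1
    lib_size_sd: float = 0.2
    clip_mean_tags: float = 30.0
    # proteomics
    n_proteins: int = 1500
    frac_dendritic_protein: float = 0.15
    frac_background_protein: float = 0.1  # no specific labeling signal at all
    ms_effect: float = 2.0
    ms_noise_sd: float = 0.4
    ms_missing_rate: float = 0.2
    # sequence model
    motif_seqs: list[str] = field(default_factory=lambda: ["CGCGGC"])
    utr5_len_logmean: float = 5.3   # ~200 nt median
    utr5_len_logsd: float = 0.5
    cds_len_logmean: float = 7.0
    cds_len_logsd: float = 0.5
    utr3_len_logmean: float = 6.0
    utr3_len_logsd: float = 0.6
    dendritic_len_shift: float = 0.4   # log-scale shift for dendritic genes
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if name.startswith("frac_") and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.frac_cds_up + self.frac_cds_down > self.frac_uorf_up + 1e-12:
            raise ValueError("frac_cds_up + frac_cds_down must be <= frac_uorf_up")
        if self.frac_uorf_up > self.frac_uorf + 1e-12:
            raise ValueError("frac_uorf_up must be <= frac_uorf")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")


PRESETS: dict[str, dict] = {
    "null": dict(frac_dendritic=0.0, frac_uorf=0.3, frac_uorf_up=0.0,
                 frac_cds_up=0.0, frac_cds_down=0.0, frac_bound=0.0,
                 enrich_log2fc=0.0, uorf_log2fc=0.0, cds_log2fc=0.0,
                 clip_log2fc=0.0, frac_dendritic_protein=0.0, ms_effect=0.0),
    "strong": dict(enrich_log2fc=2.5, uorf_log2fc=3.5, cds_log2fc=3.5,
                   clip_log2fc=2.0, ms_effect=3.0, ms_missing_rate=0.1,
                   nb_dispersion=0.02, bound_cds_coupling=0.8,
                   frac_uorf_up=0.05, frac_cds_up=0.02, frac_cds_down=0.02),
    "paperlike": dict(enrich_log2fc=1.5, uorf_log2fc=1.5, cds_log2fc=1.5,
                      clip_log2fc=1.0, ms_effect=1.5, nb_dispersion=0.1),
}


def preset_params(name: str, **overrides) -> SimParams:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return SimParams(**kwargs)


def _rng(params: SimParams, stream: str) -> np.random.Generator:
    return np.random.default_rng(params.seed + _STREAM[stream])


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB with Var = mu + alpha mu^2; Poisson in the small-dispersion limit."""
    mu = np.maximum(mu, 1e-12)
    if alpha < 1e-6:
        return rng.poisson(mu)
    n = 1.0 / alpha
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


# ---------------------------------------------------------------------------
# Truth
# ---------------------------------------------------------------------------

def make_truth(params: SimParams) -> pd.DataFrame:
    """Assign planted feature classes; one row per gene/transcript."""
    rng = _rng(params, "truth")
    n = params.n_genes
    gene_ids = [f"gene{i:05d}" for i in range(n)]
    tx_ids = [f"tx{i:05d}" for i in range(n)]

    dendritic = rng.random(n) < params.frac_dendritic
    has_uorf = rng.random(n) < params.frac_uorf

    uorf_class = np.array(["none"] * n, dtype=object)
    uorf_idx = np.flatnonzero(has_uorf)
    n_up = int(round(params.frac_uorf_up * n))
    up_idx = rng.choice(uorf_idx, size=min(n_up, len(uorf_idx)), replace=False)
    n_cds_up = int(round(params.frac_cds_up * n))
    n_cds_down = int(round(params.frac_cds_down * n))
    shuffled = rng.permutation(up_idx)
    uorf_class[shuffled[:n_cds_up]] = "uorf_up_cds_up"
    uorf_class[shuffled[n_cds_up:n_cds_up + n_cds_down]] = "uorf_up_cds_down"
    uorf_class[shuffled[n_cds_up + n_cds_down:]] = "uorf_up_cds_flat"

    has_motif = rng.random(n) < params.frac_motif
    n_bound = int(round(params.frac_bound * n))
    motif_pool = np.flatnonzero(has_motif)
    other_pool = np.flatnonzero(~has_motif)
    from_motif = (rng.random(n_bound) < params.motif_coupling) if n_bound else np.array([], bool)
    n_from_motif = min(int(from_motif.sum()), len(motif_pool))
    picks = list(rng.choice(motif_pool, size=n_from_motif, replace=False))
    n_other = min(n_bound - n_from_motif, len(other_pool))
    picks += list(rng.choice(other_pool, size=n_other, replace=False))
    is_bound = np.zeros(n, dtype=bool)
    is_bound[picks] = True
    if params.bound_cds_coupling > 0:
        cds_up_idx = np.flatnonzero(uorf_class == "uorf_up_cds_up")
        is_bound[cds_up_idx[rng.random(len(cds_up_idx))
                            < params.bound_cds_coupling]] = True

    return pd.DataFrame({
        "gene_id": gene_ids, "tx_id": tx_ids,
        "is_dendritic_rest": dendritic, "is_dendritic_dep": dendritic,
        "has_uorf": has_uorf, "uorf_class": uorf_class,
        "is_eif4g2_bound": is_bound, "has_motif": has_motif,
        "enrich_log2fc": np.where(dendritic, params.enrich_log2fc, 0.0),
        "uorf_log2fc": np.where(uorf_class != "none", params.uorf_log2fc, 0.0),
        "cds_log2fc": np.select(
            [uorf_class == "uorf_up_cds_up", uorf_class == "uorf_up_cds_down"],
            [params.cds_log2fc, -params.cds_log2fc], 0.0),
        "clip_log2fc": np.where(is_bound, params.clip_log2fc, 0.0),
    })


# ---------------------------------------------------------------------------
# Transcriptome
# ---------------------------------------------------------------------------

_STOPS = ("TAA", "TAG", "TGA")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def simulate_transcriptome(params: SimParams, truth: pd.DataFrame
                           ) -> tuple[list[TranscriptModel], dict[str, str], list[ORFRecord]]:
    """Transcript models with 5'UTR sequences, planted motifs and uORFs."""
    rng = _rng(params, "transcriptome")
    models, seqs, orfs = [], {}, []
    motif = params.motif_seqs[0] if params.motif_seqs else ""
    n_resampled = 0
    for row in truth.itertuples(index=False):
        shift = params.dendritic_len_shift if row.is_dendritic_rest else 0.0
        need = 0
        if row.has_uorf:
            need += 18
        if row.has_motif and motif:
            need += len(motif)
        utr5_len = 0
        for _ in range(100):
            utr5_len = int(rng.lognormal(params.utr5_len_logmean + shift,
                                         params.utr5_len_logsd))
            if utr5_len >= max(need + 6, 20):
                break
            n_resampled += 1
        cds_len = 3 * max(int(rng.lognormal(params.cds_len_logmean + shift,
                                            params.cds_len_logsd)) // 3, 30)
        utr3_len = max(int(rng.lognormal(params.utr3_len_logmean,
                                         params.utr3_len_logsd)), 20)
        seq = list(_random_seq(rng, utr5_len))

        start = end = -1
        if row.has_uorf:
            orf_len = 3 * int(rng.integers(4, 21))  # 12..60 nt incl. stop
            max_len = ((utr5_len - len(motif)) // 3) * 3 if row.has_motif else \
                (utr5_len // 3) * 3
            orf_len = min(orf_len, max_len)
            if row.has_motif and motif:
                # leave room for the motif on one side of the uORF
                starts = [s for s in range(utr5_len - orf_len + 1)
                          if s >= len(motif)
                          or s + orf_len <= utr5_len - len(motif)]
                start = int(starts[rng.integers(0, len(starts))])
            else:
                start = int(rng.integers(0, utr5_len - orf_len + 1))
            end = start + orf_len
        if row.has_motif and motif:
            # keep the motif clear of the planted uORF so neither overwrites
            allowed = [p for p in range(utr5_len - len(motif) + 1)
                       if start < 0 or p + len(motif) <= start or p >= end]
            pos = int(allowed[rng.integers(0, len(allowed))])
            seq[pos:pos + len(motif)] = list(motif)
        if row.has_uorf:
            seq[start:start + 3] = list("ATG")
            seq[end - 3:end] = list(_STOPS[rng.integers(0, 3)])
            # avoid interior in-frame stops so the planted ORF is well-formed
            for j in range(start + 3, end - 3, 3):
                if "".join(seq[j:j + 3]) in _STOPS:
                    seq[j] = "C"
            score = float(rng.uniform(0.75, 0.99))
            orfs.append(ORFRecord(row.tx_id, start, end, "ATG", "uORF", score))
            if rng.random() < 0.3:  # decoy: low-score or short uORFs
                if rng.random() < 0.5 and start >= 9:
                    orfs.append(ORFRecord(row.tx_id, start - start % 3, start - start % 3 + 9,
                                          "ATG", "uORF", float(rng.uniform(0.75, 0.99))))
                else:
                    orfs.append(ORFRecord(row.tx_id, start, end, "CTG", "uORF",
                                          float(rng.uniform(0.1, 0.69))))
        utr5_seq = "".join(seq)
        seqs[row.tx_id] = utr5_seq
        models.append(TranscriptModel(row.gene_id, row.tx_id, utr5_len,
                                      cds_len, utr3_len, utr5_seq=utr5_seq))
    if n_resampled:
        logger.info("simulate_transcriptome resampled %d 5'UTR length draw(s)",
                    n_resampled)
    return models, seqs, orfs


# ---------------------------------------------------------------------------
# Sequencing counts
# ---------------------------------------------------------------------------

def _factorial_sheet(prefix: str, n_reps: int, biotin_levels=("plus",)) -> pd.DataFrame:
    rows = []
    for cond in ("rest", "dep"):
        for bait in ("Pan", "PSD95"):
            for frac in ("input", "pulldown"):
                for bio in biotin_levels:
                    for rep in range(1, n_reps + 1):
                        tag = f"_{bio}" if len(biotin_levels) > 1 else ""
                        rows.append({
                            "sample_id": f"{prefix}_{cond}_{bait}_{frac}{tag}_{rep}",
                            "condition": cond, "bait": bait, "fraction": frac,
                            "biotin": bio, "replicate": rep, "batch": f"b{rep}",
                        })
    return pd.DataFrame(rows)


def simulate_rna_counts(params: SimParams, truth: pd.DataFrame
                        ) -> tuple[CountMatrix, pd.DataFrame]:
    """NB RNA counts over the 2x2x2 factorial with planted dendritic enrichment
    in PSD95-pulldown samples."""
    rng = _rng(params, "rna")
    meta = _factorial_sheet("rna", params.n_reps_rna)
    n, s = params.n_genes, len(meta)
    base = rng.normal(params.mean_log_expression, params.sd_log_expression, size=n)
    batch_shift = {b: rng.normal(0, params.batch_sd)
                   for b in meta["batch"].unique()}
    lib_scale = rng.lognormal(0, params.lib_size_sd, size=s)
    log_mu = np.tile(base[:, None], (1, s))
    for j, row in meta.iterrows():
        if row["bait"] == "PSD95" and row["fraction"] == "pulldown":
            flag = truth["is_dendritic_rest" if row["condition"] == "rest"
                         else "is_dendritic_dep"].to_numpy()
            log_mu[:, j] += np.where(flag, params.enrich_log2fc, 0.0)
        log_mu[:, j] += batch_shift[row["batch"]]
    mu = (2.0 ** log_mu) * lib_scale[None, :]
    counts = _nb_draw(rng, mu, params.nb_dispersion)
    return CountMatrix(truth["gene_id"].tolist(), meta["sample_id"].tolist(),
                       counts), meta


def simulate_footprints(params: SimParams, models: list[TranscriptModel],
                        truth: pd.DataFrame, per_read: bool = False
                        ) -> tuple[CountMatrix, pd.DataFrame,
                                   dict[str, dict[str, np.ndarray]] | None]:
    """Region-structured footprint counts with translation-only planted effects.

    uORF-up classes gain ``uorf_log2fc`` on the 5'UTR of dep PSD95-pulldown
    samples; CDS-up/down gain +/- ``cds_log2fc`` on the CDS. RNA abundance
    (input samples) is left untouched for these features. When ``per_read``,
    also emits read 3'-end positions placed 12 nt downstream of each P-site.
    """
    rng = _rng(params, "ribo")
    meta = _factorial_sheet("ribo", params.n_reps_ribo)
    model_of = {m.tx_id: m for m in models}
    tx_ids = truth["tx_id"].tolist()
    n, s = len(tx_ids), len(meta)
    base = rng.normal(params.mean_log_expression, params.sd_log_expression, size=n)
    lib_scale = rng.lognormal(0, params.lib_size_sd, size=s)
    utr5_effect = truth["uorf_log2fc"].to_numpy()
    cds_effect = truth["cds_log2fc"].to_numpy()
    dendritic = truth["is_dendritic_rest"].to_numpy()

    feature_ids, mu_rows = [], []
    for region, effect in (("utr5", utr5_effect), ("cds", cds_effect)):
        len_of = np.array([getattr(model_of[tx], f"{region}_len") for tx in tx_ids])
        log_mu = np.tile(base[:, None], (1, s)) + np.log2(np.maximum(len_of, 1) / 300.0)[:, None]
        if region == "utr5":
            log_mu -= 1.0  # 5'UTR occupancy below CDS at baseline
        for j, row in meta.iterrows():
            is_psd_pd = row["bait"] == "PSD95" and row["fraction"] == "pulldown"
            if is_psd_pd and dendritic.any():
                log_mu[:, j] += np.where(dendritic, params.enrich_log2fc / 2.0, 0.0)
            if is_psd_pd and row["condition"] == "dep":
                log_mu[:, j] += effect
        mu_rows.append((2.0 ** log_mu))
        feature_ids.extend(f"{tx}:{region}" for tx in tx_ids)
    mu = np.vstack(mu_rows) * lib_scale[None, :]
    counts = _nb_draw(rng, mu, params.nb_dispersion)
    cm = CountMatrix(feature_ids, meta["sample_id"].tolist(), counts)

    reads = None
    if per_read:
        reads = {}
        for j, sid in enumerate(meta["sample_id"]):
            per_tx: dict[str, np.ndarray] = {}
            for i, fid in enumerate(feature_ids):
                tx, region = fid.rsplit(":", 1)
                m = model_of[tx]
                k = int(counts[i, j])
                if k == 0:
                    continue
                lo, hi = (0, m.utr5_len) if region == "utr5" else \
                    (m.utr5_len, m.utr5_len + m.cds_len)
                psites = rng.integers(lo, hi, size=k)
                ends = psites + 12
                per_tx[tx] = np.concatenate([per_tx.get(tx, np.empty(0, np.int64)), ends])
            reads[sid] = per_tx
    return cm, meta, reads


def simulate_clip_tags(params: SimParams, truth: pd.DataFrame,
                       background_reads: float = 1e6) -> CountMatrix:
    """Poisson 5'UTR CLIP tags, rest/dep, with planted binding fold change.

    A ``__background__`` row models reads mapping outside the 5'UTR universe,
    so that library depth (column sums) is realistic relative to tag counts.
    """
    rng = _rng(params, "clip")
    lam_base = rng.lognormal(np.log(params.clip_mean_tags), 0.6, size=params.n_genes)
    lam_rest = lam_base
    lam_dep = lam_base * 2.0 ** truth["clip_log2fc"].to_numpy()
    counts = np.column_stack([rng.poisson(lam_rest), rng.poisson(lam_dep)])
    counts = np.vstack([counts, rng.poisson(background_reads, size=(1, 2))])
    return CountMatrix(truth["tx_id"].tolist() + ["__background__"],
                       ["rest", "dep"], counts)


# ---------------------------------------------------------------------------
# Proteomics
# ---------------------------------------------------------------------------

def simulate_proteins(params: SimParams
                      ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Log-normal protein intensities with MNAR dropout.

    Returns (intensity table with NaN for missing, sample sheet, protein
    truth). Minus-biotin samples carry background only.
    """
    rng = _rng(params, "ms")
    meta_rows = []
    for cond in ("rest", "dep"):
        for bait in ("Pan", "PSD95"):
            for bio in ("plus", "minus"):
                for rep in range(1, params.n_reps_ms + 1):
                    meta_rows.append({
                        "sample_id": f"ms_{cond}_{bait}_{bio}_{rep}",
                        "condition": cond, "bait": bait, "fraction": "pulldown",
                        "biotin": bio, "replicate": rep, "batch": f"b{rep}",
                    })
    meta = pd.DataFrame(meta_rows)
    n, s = params.n_proteins, len(meta)
    protein_ids = [f"prot{i:05d}" for i in range(n)]
    dendritic = rng.random(n) < params.frac_dendritic_protein
    is_background = (rng.random(n) < params.frac_background_protein) & ~dendritic
    base = rng.normal(25.0, 2.0, size=n)
    background = rng.normal(20.0, 2.0, size=n)  # minus-biotin: no labeling signal
    base = np.where(is_background, background, base)

    log2_int = np.tile(base[:, None], (1, s)) + rng.normal(0, params.ms_noise_sd, (n, s))
    for j, row in meta.iterrows():
        if row["biotin"] == "minus":
            log2_int[:, j] = background + rng.normal(0, params.ms_noise_sd, n)
        elif row["bait"] == "PSD95":
            log2_int[:, j] += np.where(dendritic, params.ms_effect, 0.0)

    if params.ms_missing_rate > 0:
        # dropout concentrated at low intensities (logistic MNAR)
        center = np.quantile(log2_int, params.ms_missing_rate)
        p_missing = 0.9 / (1.0 + np.exp((log2_int - center) / 1.0))
        mask = rng.random((n, s)) < np.clip(p_missing, 0, 1)
    else:
        mask = np.zeros((n, s), dtype=bool)
    intensities = 2.0 ** log2_int
    table = pd.DataFrame(np.where(mask, np.nan, intensities),
                         index=protein_ids, columns=meta["sample_id"])
    truth = pd.DataFrame({"protein_id": protein_ids, "is_dendritic": dendritic,
                          "is_background": is_background,
                          "true_log2_intensity_mean": base})
    table.attrs["true_log2"] = pd.DataFrame(log2_int, index=protein_ids,
                                            columns=meta["sample_id"])
    return table, meta, truth


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def write_all(params: SimParams, out_dir: str | Path, per_read: bool = False) -> dict[str, Path]:
    """Generate every downstream input under ``out_dir`` and return the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = make_truth(params)
    models, seqs, orfs = simulate_transcriptome(params, truth)
    rna_cm, rna_meta = simulate_rna_counts(params, truth)
    ribo_cm, ribo_meta, _ = simulate_footprints(params, models, truth, per_read=per_read)
    clip_cm = simulate_clip_tags(params, truth)
    prot, ms_meta, prot_truth = simulate_proteins(params)

    paths = {}

    def save(name, fn):
        paths[name] = out / name
        fn(paths[name])

    save("truth.tsv", lambda p: truth.to_csv(p, sep="\t", index=False))
    save("protein_truth.tsv", lambda p: prot_truth.to_csv(p, sep="\t", index=False))
    save("annotation.bed", lambda p: _write_bed12(models, p))
    save("utr5.fa", lambda p: write_fasta(seqs, p))
    save("orfs.tsv", lambda p: write_orfs(orfs, p))
    save("rna_counts.tsv", lambda p: write_counts(rna_cm, p))
    save("rna_samples.tsv", lambda p: write_sample_sheet(rna_meta, p))
    save("region_counts.tsv", lambda p: write_counts(ribo_cm, p))
    save("ribo_samples.tsv", lambda p: write_sample_sheet(ribo_meta, p))
    save("clip_tags.tsv", lambda p: write_counts(clip_cm, p))
    save("proteins.tsv", lambda p: prot.reset_index(names="protein_id")
         .to_csv(p, sep="\t", index=False))
    save("ms_samples.tsv", lambda p: write_sample_sheet(ms_meta, p))
    save("params.yaml", lambda p: p.write_text(yaml.safe_dump(asdict(params))))

    pwm_dir = out / "pwms"
    pwm_dir.mkdir(exist_ok=True)
    manifest = []
    for i, consensus in enumerate(params.motif_seqs):
        pwm = PWM.from_consensus(f"motif{i}", f"RBP{i}", consensus)
        fname = f"motif{i}.txt"
        _write_pwm(pwm, pwm_dir / fname)
        manifest.append({"motif_id": pwm.motif_id, "rbp_name": pwm.rbp_name,
                         "file": f"pwms/{fname}"})
    # decoy motif never planted
    decoy = PWM.from_consensus("decoy", "RBPdecoy", "ATATCGCGAT")
    _write_pwm(decoy, pwm_dir / "decoy.txt")
    manifest.append({"motif_id": "decoy", "rbp_name": "RBPdecoy",
                     "file": "pwms/decoy.txt"})
    pd.DataFrame(manifest).to_csv(out / "pwm_manifest.tsv", sep="\t", index=False)
    paths["pwm_manifest.tsv"] = out / "pwm_manifest.tsv"
    return paths


def _write_bed12(models: list[TranscriptModel], path: Path) -> None:
    """Single-exon BED12, one transcript per line, name = gene|tx."""
    with open(path, "w") as fh:
        for m in models:
            total = m.total_len
            thick_start, thick_end = m.utr5_len, m.utr5_len + m.cds_len
            fh.write("\t".join(map(str, [
                "chrSim", 0, total, f"{m.gene_id}|{m.tx_id}", 0, "+",
                thick_start, thick_end, 0, 1, f"{total},", "0,",
            ])) + "\n")


def _write_pwm(pwm: PWM, path: Path) -> None:
    lines = []
    for base, row in zip("ACGU", pwm.matrix):
        lines.append(base + ": " + " ".join(f"{v:.6f}" for v in row))
    path.write_text("\n".join(lines) + "\n")
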