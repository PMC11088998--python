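"""Domain types, file readers/writers and configuration shared by all stages.

Conventions
-----------
* Coordinates are 0-based, half-open throughout. ORFs live in
  transcript-local coordinates; genomic BED12 coordinates are handled only
  at parse time.
* Non-coding transcripts (no CDS) get ``utr5_len = cds_len = utr3_len = 0``
  and are excluded from region-level analyses.
* Counts are nonnegative integers; library sizes default to column sums.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("dendtrans")

CONDITIONS = ("rest", "dep")
BAITS = ("Pan", "PSD95")
FRACTIONS = ("input", "pulldown")
BIOTIN = ("plus", "minus")

SAMPLE_COLUMNS = ["sample_id", "condition", "bait", "fraction", "biotin", "replicate", "batch"]


class ParseError(ValueError):
    """Raised when an input file violates its declared dialect."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class TranscriptModel:
    """Per-transcript region lengths plus optional 5'UTR sequence."""

    gene_id: str
    tx_id: str
    utr5_len: int
    cds_len: int
    utr3_len: int
    utr5_seq: str | None = None
    gc_frac: float | None = None

    def __post_init__(self) -> None:
        if min(self.utr5_len, self.cds_len, self.utr3_len) < 0:
            raise ValueError(f"{self.tx_id}: negative region length")
        if self.cds_len > 0 and self.cds_len % 3 != 0:
            warnings.warn(f"{self.tx_id}: CDS length {self.cds_len} not divisible by 3")
        if self.utr5_seq is not None:
            if len(self.utr5_seq) != self.utr5_len:
                raise ValueError(
                    f"{self.tx_id}: utr5_seq length {len(self.utr5_seq)} != utr5_len {self.utr5_len}"
                )
            if self.gc_frac is None and self.utr5_len > 0:
                s = self.utr5_seq.upper()
                self.gc_frac = (s.count("G") + s.count("C")) / len(s)

    @property
    def total_len(self) -> int:
        return self.utr5_len + self.cds_len + self.utr3_len

    @property
    def is_coding(self) -> bool:
        return self.cds_len > 0


@dataclass
class ORFRecord:
    """A candidate ORF in transcript-local, 0-based half-open coordinates."""

    tx_id: str
    start: int
    end: int
    start_codon: str
    orf_class: str  # uORF | start_overlap | other
    score: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.tx_id}: ORF end {self.end} <= start {self.start}")
        if (self.end - self.start) % 3 != 0:
            raise ValueError(f"{self.tx_id}: ORF length not divisible by 3")

    @property
    def length_nt(self) -> int:
        return self.end - self.start


@dataclass
class CountMatrix:
    """Nonnegative integer counts of features x samples."""

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    lib_sizes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("counts shape inconsistent with feature/sample ids")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if self.lib_sizes is None:
            self.lib_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.lib_sizes = np.asarray(self.lib_sizes, dtype=float)
            if self.lib_sizes.shape != (len(self.sample_ids),):
                raise ValueError("lib_sizes length inconsistent with sample ids")
        if np.any(self.lib_sizes == 0):
            warnings.warn("one or more libraries have zero total counts")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(
            list(self.feature_ids), list(sample_ids),
            self.counts[:, idx], self.lib_sizes[idx],
        )

    def subset_features(self, feature_ids: Sequence[str]) -> "CountMatrix":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        idx = [pos[f] for f in feature_ids]
        return CountMatrix(list(feature_ids), list(self.sample_ids),
                           self.counts[idx, :], self.lib_sizes.copy())


@dataclass
class Thresholds:
    """Every numeric cutoff used by the pipeline, in one auditable record."""

    t_loc_single: float = 1.0       # localization call per condition
    t_loc_diff: float = 1.25        # differential localization call
    z_cut: float = 1.96             # two-sided z cutoff (2.5% per tail)
    p_cds: float = 0.05             # CDS/5'UTR translation significance
    basemean_min_cds: float = 1.0
    basemean_min_utr5: float = 3.0
    orf_min_len_nt: int = 10        # strictly > 9 nt incl. stop
    orf_score: float = 0.7
    orf_score_intersect: float = 0.6
    clip_pseudocount: float = 0.1
    clip_p: float = 0.2
    motif_min_score_frac: float = 0.95
    motif_fdr: float = 0.1
    ms_impute_width: float = 0.3
    ms_impute_downshift: float = 1.8
    ms_p: float = 0.05
    guard_t_up: float = 2.0         # CDS-up guard: differential PL-CLIP t < 2
    guard_t_down: float = -2.0      # CDS-down guard: differential PL-CLIP t > -2
    psite_offset_nt: int = 12
    pca_top_n: int = 500
    min_cpm: float = 1.0
    dendritic_eps: float = 0.1

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Thresholds":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        return cls(**data)

    def log_values(self) -> None:
        for key, value in asdict(self).items():
            logger.info("threshold %s = %s", key, value)


# ---------------------------------------------------------------------------
# Sample sheets
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read the factorial design sheet (TSV), validating factor levels."""
    meta = pd.read_csv(path, sep="\t", dtype={"batch": str})
    missing = [c for c in SAMPLE_COLUMNS if c not in meta.columns and c != "biotin"]
    if missing:
        raise ParseError(f"sample sheet missing columns: {missing}")
    if "biotin" not in meta.columns:
        meta["biotin"] = "plus"
    if meta["sample_id"].duplicated().any():
        dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ParseError(f"duplicate sample_id: {dupes}")
    for col, levels in [("condition", CONDITIONS), ("bait", BAITS),
                        ("fraction", FRACTIONS), ("biotin", BIOTIN)]:
        bad = set(meta[col]) - set(levels)
        if bad:
            raise ParseError(f"invalid {col} level(s): {sorted(bad)}")
    if (meta["replicate"] < 1).any():
        raise ParseError("replicate must be a positive integer")
    return meta


def write_sample_sheet(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def read_counts(path: str | Path, sample_sheet: pd.DataFrame | None = None,
                feature_col: str | None = None) -> CountMatrix:
    """Read a features x samples TSV into a CountMatrix.

    First column (or ``feature_col``) holds feature ids; remaining columns
    must each be listed in ``sample_sheet`` when one is supplied.
    """
    df = pd.read_csv(path, sep="\t")
    if feature_col is None:
        feature_col = df.columns[0]
    features = df[feature_col].astype(str).tolist()
    mat = df.drop(columns=[feature_col])
    if sample_sheet is not None:
        known = set(sample_sheet["sample_id"])
        extra = [c for c in mat.columns if c not in known]
        if extra:
            raise ParseError(f"sample column(s) absent from sample sheet: {extra}")
    values = mat.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        if not np.allclose(values, np.round(values)):
            raise ParseError(f"{path}: non-integer counts")
        values = np.round(values).astype(np.int64)
    if np.any(values < 0):
        raise ParseError(f"{path}: negative counts")
    return CountMatrix(features, list(mat.columns), values.astype(np.int64))


def write_counts(cm: CountMatrix, path: str | Path, feature_col: str = "feature_id") -> None:
    df = cm.to_frame().reset_index(names=feature_col)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

RESULT_COLUMNS = ["feature_id", "log2fc", "stat", "p", "p_adj", "basemean", "flag"]


def validate_result_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check ResultTable invariants: p in [0,1], p_adj >= p, unique features."""
    if df["feature_id"].duplicated().any():
        raise ValueError("duplicate feature_id in result table")
    for col in ("p", "p_adj"):
        if col in df.columns:
            vals = df[col].dropna()
            if ((vals < 0) | (vals > 1)).any():
                raise ValueError(f"{col} outside [0, 1]")
    if "p" in df.columns and "p_adj" in df.columns:
        ok = df["p_adj"].fillna(1.0) >= df["p"].fillna(0.0) - 1e-12
        if not ok.all():
            raise ValueError("p_adj < p")
    return df


def write_result_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_result_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Annotation parsing
# ---------------------------------------------------------------------------

def _split_regions_bed12(line_no: int, line: str) -> TranscriptModel:
    parts = line.rstrip("\n").split("\t")
    if len(parts) < 12:
        raise ParseError(f"line {line_no}: expected 12 BED fields, got {len(parts)}")
    try:
        chrom_start = int(parts[1])
        name = parts[3]
        strand = parts[5]
        thick_start = int(parts[6])
        thick_end = int(parts[7])
        n_blocks = int(parts[9])
        sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
        starts = [int(x) for x in parts[11].rstrip(",").split(",")]
    except ValueError as exc:
        raise ParseError(f"line {line_no}: {exc}") from exc
    if len(sizes) != n_blocks or len(starts) != n_blocks:
        raise ParseError(f"line {line_no}: blockCount disagrees with block lists")
    if strand not in ("+", "-"):
        raise ParseError(f"line {line_no}: bad strand {strand!r}")
    gene_id = name.split("|")[0] if "|" in name else name
    tx_id = name.split("|")[1] if "|" in name else name

    total = sum(sizes)
    if thick_start == thick_end:  # non-coding
        return TranscriptModel(gene_id, tx_id, 0, 0, 0)
    left = right = cds = 0  # exonic bases left of CDS, inside, right of CDS
    for size, rel_start in zip(sizes, starts):
        b0 = chrom_start + rel_start
        b1 = b0 + size
        left += max(0, min(b1, thick_start) - b0)
        right += max(0, b1 - max(b0, thick_end))
        cds += max(0, min(b1, thick_end) - max(b0, thick_start))
    assert left + cds + right == total
    if strand == "+":
        return TranscriptModel(gene_id, tx_id, left, cds, right)
    return TranscriptModel(gene_id, tx_id, right, cds, left)


def _parse_gtf_attrs(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in attr.strip().strip(";").split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, value = item.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def _read_gtf(path: Path) -> list[TranscriptModel]:
    exons: dict[str, list[tuple[int, int]]] = {}
    cdss: dict[str, list[tuple[int, int]]] = {}
    strand_of: dict[str, str] = {}
    gene_of: dict[str, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ParseError(f"line {line_no}: expected 9 GTF fields")
            feature = parts[2]
            if feature not in ("exon", "CDS"):
                continue
            try:
                start = int(parts[3]) - 1  # GTF is 1-based closed
                end = int(parts[4])
            except ValueError as exc:
                raise ParseError(f"line {line_no}: {exc}") from exc
            attrs = _parse_gtf_attrs(parts[8])
            tx = attrs.get("transcript_id")
            if tx is None:
                raise ParseError(f"line {line_no}: missing transcript_id")
            strand_of[tx] = parts[6]
            gene_of[tx] = attrs.get("gene_id", tx)
            (exons if feature == "exon" else cdss).setdefault(tx, []).append((start, end))
    models = []
    for tx, ex in exons.items():
        ex.sort()
        total = sum(e - s for s, e in ex)
        cds_iv = sorted(cdss.get(tx, []))
        if not cds_iv:
            models.append(TranscriptModel(gene_of[tx], tx, 0, 0, 0))
            continue
        cds_len = sum(e - s for s, e in cds_iv)
        cds_lo, cds_hi = cds_iv[0][0], cds_iv[-1][1]
        left = sum(max(0, min(e, cds_lo) - s) for s, e in ex)
        right = sum(max(0, e - max(s, cds_hi)) for s, e in ex)
        if left + right + cds_len != total:
            raise ParseError(f"{tx}: CDS intervals not contained in exons")
        if strand_of[tx] == "+":
            models.append(TranscriptModel(gene_of[tx], tx, left, cds_len, right))
        else:
            models.append(TranscriptModel(gene_of[tx], tx, right, cds_len, left))
    return models


def read_annotation(path: str | Path, fmt: str | None = None) -> list[TranscriptModel]:
    """Parse transcript annotation from BED12 or minimal GTF.

    BED12 ``name`` may encode ``gene|transcript``; otherwise the name serves
    as both ids. ``fmt`` is auto-detected from the extension when omitted.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gtf" if path.suffix.lower() in (".gtf", ".gff") else "bed"
    if fmt == "gtf":
        models = _read_gtf(path)
    elif fmt == "bed":
        models = []
        with open(path) as fh:
            for line_no, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                models.append(_split_regions_bed12(line_no, line))
    else:
        raise ValueError(f"unknown annotation format: {fmt}")
    seen: set[str] = set()
    for m in models:
        if m.tx_id in seen:
            raise ParseError(f"duplicate transcript id {m.tx_id}")
        seen.add(m.tx_id)
    return models


def select_longest_transcript(models: Iterable[TranscriptModel]) -> list[TranscriptModel]:
    """Keep one transcript per gene: the longest, ties broken by smaller tx_id."""
    best: dict[str, TranscriptModel] = {}
    for m in models:
        cur = best.get(m.gene_id)
        if (cur is None or m.total_len > cur.total_len
                or (m.total_len == cur.total_len and m.tx_id < cur.tx_id)):
            best[m.gene_id] = m
    return sorted(best.values(), key=lambda m: m.tx_id)


# ---------------------------------------------------------------------------
# Sequences and ORF tables
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper().replace("U", "T")
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def attach_utr5_seqs(models: Sequence[TranscriptModel],
                     seqs: Mapping[str, str]) -> list[TranscriptModel]:
    out = []
    for m in models:
        seq = seqs.get(m.tx_id)
        out.append(TranscriptModel(m.gene_id, m.tx_id, m.utr5_len, m.cds_len,
                                   m.utr3_len, utr5_seq=seq))
    return out


ORF_COLUMNS = ["tx_id", "start", "end", "start_codon", "orf_class", "score"]


def read_orfs(path: str | Path) -> list[ORFRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ORF_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"ORF table missing columns: {missing}")
    return [ORFRecord(str(r.tx_id), int(r.start), int(r.end), str(r.start_codon),
                      str(r.orf_class), float(r.score))
            for r in df.itertuples(index=False)]


def write_orfs(orfs: Sequence[ORFRecord], path: str | Path) -> None:
    pd.DataFrame([asdict(o) for o in orfs], columns=ORF_COLUMNS).to_csv(
        path, sep="\t", index=False)


def models_to_frame(models: Sequence[TranscriptModel]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_id": m.gene_id, "tx_id": m.tx_id, "utr5_len": m.utr5_len,
        "cds_len": m.cds_len, "utr3_len": m.utr3_len, "gc_frac": m.gc_frac,
    } for m in models])


def setup_logging(out_dir: str | Path | None = None, name: str = "run") -> logging.Logger:
    """Attach a file handler under ``out_dir`` plus stderr, idempotently."""
    log = logging.getLogger("dendtrans")
    log.setLevel(logging.INFO)
    for handler in [h for h in log.handlers if isinstance(h, logging.FileHandler)]:
        log.removeHandler(handler)
        handler.close()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out_dir / f"{name}.log")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(handler)
    return log
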