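"""Probe-profile and promoter-annotation I/O, validation, and normalization.

All genomic coordinates are 0-based half-open throughout the package; BED
writers follow the BED convention unchanged.  Probe profiles are tab-separated
(``probe_id  chrom  start  end  log2_ratio``) holding scaled log2(IP/Input)
values, one pooled hybridization per condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PROFILE_COLUMNS = ["probe_id", "chrom", "start", "end", "log2_ratio"]
ANNOTATION_COLUMNS = ["gene_symbol", "accession", "chrom", "tss", "strand", "start", "end"]

#: promoter window relative to the TSS, in transcription orientation (bp)
PROMOTER_UPSTREAM = 2200
PROMOTER_DOWNSTREAM = 500


@dataclass
class ArrayProfile:
    """One pooled hybridization: position-sorted probe-level log2(IP/Input).

    ``probes`` has columns ``probe_id, chrom, start, end, log2_ratio``,
    sorted by (chrom, start), with unique probe_ids and finite values.
    ``provenance`` records transformations applied (e.g. normalization).
    """

    condition: str
    probes: pd.DataFrame
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.probes = validate_probes(self.probes)

    @property
    def values(self) -> np.ndarray:
        return self.probes["log2_ratio"].to_numpy()

    def __len__(self) -> int:
        return len(self.probes)


def validate_probes(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"probe table missing columns: {missing}")
    df = df.loc[:, PROFILE_COLUMNS].copy()
    try:
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"unparseable probe coordinates: {exc}") from exc
    bad = df["start"] >= df["end"]
    if bad.any():
        offender = df.loc[bad, "probe_id"].iloc[0]
        raise ValueError(f"probe {offender!r} has start >= end")
    if (df["start"] < 0).any():
        offender = df.loc[df["start"] < 0, "probe_id"].iloc[0]
        raise ValueError(f"probe {offender!r} has negative start")
    dup = df["probe_id"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate probe_id {df.loc[dup, 'probe_id'].iloc[0]!r}")
    df["log2_ratio"] = pd.to_numeric(df["log2_ratio"], errors="coerce")
    nonfinite = ~np.isfinite(df["log2_ratio"])
    if nonfinite.any():
        logger.warning("dropping %d probes with non-finite values", int(nonfinite.sum()))
        df = df.loc[~nonfinite]
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def read_profile(path, condition: str) -> ArrayProfile:
    """Read a probe-level TSV into a validated, sorted :class:`ArrayProfile`.

    Rows with non-finite log-ratios are dropped with a logged count; missing
    columns, duplicate probe_ids or malformed coordinates raise ``ValueError``.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    profile = ArrayProfile(condition=condition, probes=df)
    profile.provenance.append(f"read_profile:{path}")
    return profile


def write_profile(profile: ArrayProfile, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out = profile.probes.copy()
    out["log2_ratio"] = out["log2_ratio"].map(lambda v: f"{v:.6f}")
    with open(path, "w") as fh:
        fh.write("# medipchip probe profile; coordinates 0-based half-open\n")
        fh.write(f"# condition={profile.condition}\n")
        out.to_csv(fh, sep="\t", index=False)


def _tukey_biweight_location(x: np.ndarray, c: float = 9.0, tol: float = 1e-13,
                             max_iter: int = 200) -> float:
    """Tukey biweight (bisquare) one-dimensional location estimate.

    Iteratively reweighted mean with weights (1-u^2)^2 for |u| < 1,
    u = (x - t)/(c * MAD), starting from the median.  Falls back to the
    median when the MAD is zero (more than half the data identical).
    """
    t = float(np.median(x))
    mad = float(np.median(np.abs(x - t)))
    if mad == 0.0:
        return t
    for _ in range(max_iter):
        u = (x - t) / (c * mad)
        w = np.zeros_like(u)
        inside = np.abs(u) < 1.0
        w[inside] = (1.0 - u[inside] ** 2) ** 2
        if w.sum() == 0.0:
            return t
        t_new = float(np.sum(w * x) / w.sum())
        if abs(t_new - t) < tol:
            return t_new
        t = t_new
    return t


def normalize(profile: ArrayProfile, method: str = "biweight") -> ArrayProfile:
    """Center a profile so its robust location estimate is zero.

    ``method`` is ``"biweight"`` (Tukey biweight mean, the NimbleGen-style
    default for scaled log2 ratios), ``"median"``, or ``"none"``.  Returns a
    new profile; the input is unmodified.  An all-equal profile centers to
    all-zero with a warning.
    """
    if method not in ("biweight", "median", "none"):
        raise ValueError(f"unknown normalization method {method!r}")
    probes = profile.probes.copy()
    values = probes["log2_ratio"].to_numpy(dtype=float)
    if method != "none":
        if len(values) < 2:
            raise ValueError("normalization requires at least 2 probes")
        if np.ptp(values) == 0.0:
            logger.warning("degenerate all-equal profile; centering to zero")
        center = (
            _tukey_biweight_location(values)
            if method == "biweight"
            else float(np.median(values))
        )
        probes["log2_ratio"] = values - center
    out = ArrayProfile(condition=profile.condition, probes=probes,
                       provenance=list(profile.provenance))
    out.provenance.append(f"normalize:{method}")
    return out


def validate_annotation(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation missing columns: {missing}")
    df = df.loc[:, ANNOTATION_COLUMNS].copy()
    if len(df) == 0:
        return df
    for col in ("tss", "start", "end"):
        df[col] = df[col].astype(np.int64)
    if not df["strand"].isin(["+", "-"]).all():
        bad = df.loc[~df["strand"].isin(["+", "-"]), "strand"].iloc[0]
        raise ValueError(f"malformed strand {bad!r}")
    if (df["start"] < 0).any():
        raise ValueError("negative promoter coordinates")
    dup = df["accession"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate accession {df.loc[dup, 'accession'].iloc[0]!r}")
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def promoter_interval(tss: int, strand: str,
                      upstream: int = PROMOTER_UPSTREAM,
                      downstream: int = PROMOTER_DOWNSTREAM) -> tuple[int, int]:
    """Half-open promoter window around a TSS in transcription orientation.

    Plus strand: [tss - upstream, tss + downstream); minus strand mirrored.
    """
    if strand == "+":
        return tss - upstream, tss + downstream
    if strand == "-":
        return tss - downstream, tss + upstream
    raise ValueError(f"malformed strand {strand!r}")


def read_annotation(path) -> pd.DataFrame:
    """Read a promoter annotation TSV (gene, accession, chrom, TSS, strand, interval)."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError:
        logger.warning("empty annotation file %s", path)
        return pd.DataFrame(columns=ANNOTATION_COLUMNS)
    if len(df) == 0:
        logger.warning("empty annotation file %s", path)
    return validate_annotation(df)


def write_annotation(annotation: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# medipchip promoter annotation; coordinates 0-based half-open\n")
        annotation.to_csv(fh, sep="\t", index=False)


def write_bed(intervals: pd.DataFrame, path, name_col: str = "name",
              score_col: str | None = None, strand_col: str | None = None) -> None:
    """Write intervals as BED6 (0-based half-open; score clipped to [0, 1000]).

    Peakscores are carried in the BED score column multiplied by 100 (so a
    peakscore of 3.2 becomes 320), the usual convention for -log10 scores.
    """
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df = intervals.copy()
    if (df["start"] < 0).any():
        raise ValueError("negative coordinates in BED output")
    name = df[name_col] if name_col in df else [f"feature_{i}" for i in range(len(df))]
    if score_col is not None and score_col in df:
        score = (df[score_col] * 100).round().clip(0, 1000).astype(int)
    else:
        score = np.zeros(len(df), dtype=int)
    strand = df[strand_col] if strand_col and strand_col in df else ["."] * len(df)
    bed = pd.DataFrame({
        "chrom": df["chrom"], "start": df["start"], "end": df["end"],
        "name": name, "score": score, "strand": strand,
    })
    bed.to_csv(path, sep="\t", index=False, header=False)
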