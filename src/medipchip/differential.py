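"""Two-condition peakscore classification of testis/epididymis-specific promoters.

A promoter's peakscore per condition is the best peakscore among overlapping
peaks (0 when none overlaps — a vasectomy-abolished signal counts as absent).
Classification follows the study's criteria with strict inequalities:

* TE-specific hypomethylated: peakscore > 3.0 in PV *and* < 2.0 in Nor
  (the methylation peak exists only where the unmethylated TE-derived DNA
  is missing);
* TE-specific hypermethylated: peakscore > 3.0 in Nor *and* < 2.0 in PV.

Scores in [2.0, 3.0] are indeterminate by design.  Promoters of the same
gene are then summarized: a gene takes the unique differential class among
its promoters, and conflicting differential classes neutralize to
unclassified with a conflict flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

TE_HYPO = "te_hypomethylated"
TE_HYPER = "te_hypermethylated"
UNCLASSIFIED = "unclassified"


@dataclass
class ClassificationThresholds:
    """Peakscore criteria: present if > present_min, absent if < absent_max."""

    present_min: float = 3.0  # -log10 p, i.e. P < 0.001
    absent_max: float = 2.0  # -log10 p, i.e. P > 0.01

    def __post_init__(self) -> None:
        if not self.present_min > self.absent_max > 0:
            raise ValueError("require present_min > absent_max > 0")


def assign_promoter_scores(
    peaks_nor: pd.DataFrame,
    peaks_pv: pd.DataFrame,
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Assign each promoter its per-condition peakscore by interval overlap.

    A peak is assigned to a promoter iff their intervals overlap by >= 1 bp;
    a promoter's score per condition is the max peakscore over assigned
    peaks, 0 if none.  Every annotated promoter appears in the output.
    Peaks on chromosomes absent from the annotation are ignored with a
    warning.
    """
    trees: dict[str, IntervalTree] = {}
    for i, rec in enumerate(annotation.itertuples(index=False)):
        trees.setdefault(rec.chrom, IntervalTree()).addi(rec.start, rec.end, i)

    scores = {
        "nor": np.zeros(len(annotation)),
        "pv": np.zeros(len(annotation)),
    }
    for label, peaks in (("nor", peaks_nor), ("pv", peaks_pv)):
        unknown = set()
        for pk in peaks.itertuples(index=False):
            tree = trees.get(pk.chrom)
            if tree is None:
                unknown.add(pk.chrom)
                continue
            for hit in tree.overlap(pk.start, pk.end):
                i = hit.data
                scores[label][i] = max(scores[label][i], pk.peakscore)
        if unknown:
            logger.warning(
                "%s peaks on chromosomes absent from annotation ignored: %s",
                label, sorted(unknown),
            )
    return pd.DataFrame({
        "accession": annotation["accession"],
        "gene_symbol": annotation["gene_symbol"],
        "peakscore_nor": scores["nor"],
        "peakscore_pv": scores["pv"],
    })


def classify_promoter(
    peakscore_nor: float,
    peakscore_pv: float,
    thresholds: ClassificationThresholds | None = None,
) -> str:
    """Class of one promoter from its two peakscores (strict inequalities)."""
    t = thresholds or ClassificationThresholds()
    if peakscore_nor < 0 or peakscore_pv < 0:
        raise ValueError("peakscores must be non-negative")
    if peakscore_pv > t.present_min and peakscore_nor < t.absent_max:
        return TE_HYPO
    if peakscore_nor > t.present_min and peakscore_pv < t.absent_max:
        return TE_HYPER
    return UNCLASSIFIED


def classify_promoters(
    promoter_scores: pd.DataFrame,
    thresholds: ClassificationThresholds | None = None,
) -> pd.DataFrame:
    """Vectorized :func:`classify_promoter` over a promoter-score table."""
    t = thresholds or ClassificationThresholds()
    nor = promoter_scores["peakscore_nor"].to_numpy(dtype=float)
    pv = promoter_scores["peakscore_pv"].to_numpy(dtype=float)
    if (nor < 0).any() or (pv < 0).any():
        raise ValueError("peakscores must be non-negative")
    klass = np.full(len(promoter_scores), UNCLASSIFIED, dtype=object)
    klass[(pv > t.present_min) & (nor < t.absent_max)] = TE_HYPO
    klass[(nor > t.present_min) & (pv < t.absent_max)] = TE_HYPER
    out = promoter_scores.copy()
    out["klass"] = klass
    return out


def summarize_genes(promoter_calls: pd.DataFrame) -> pd.DataFrame:
    """Summarize promoter calls to one call per gene.

    A gene takes the unique differential class carried by any of its
    promoters; genes whose promoters carry both differential classes are
    unclassified with ``conflict_flag = True``.
    """
    rows = []
    for gene, grp in promoter_calls.groupby("gene_symbol", sort=True):
        classes = set(grp["klass"]) - {UNCLASSIFIED}
        conflict = classes == {TE_HYPO, TE_HYPER}
        if conflict or not classes:
            klass = UNCLASSIFIED
            supporting = []
        else:
            klass = classes.pop()
            supporting = sorted(grp.loc[grp["klass"] == klass, "accession"])
        rows.append({
            "gene_symbol": gene,
            "klass": klass,
            "supporting_accessions": ",".join(supporting),
            "conflict_flag": conflict,
        })
    return pd.DataFrame(rows)


def tabulate(
    promoter_calls: pd.DataFrame,
    bin_edges: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Class-proportion table and peakscore histograms of the differential classes.

    The proportion table reports each class's count with two denominators:
    ``pct_of_scored`` uses promoters overlapped by at least one peak in
    either condition (the "identified in cfsDNA" denominator) and
    ``pct_of_all`` uses every annotated promoter.  Histograms bin the
    "present"-condition peakscore of each differential class on
    [3.0, 3.5, 4.0, ...).
    """
    if len(promoter_calls) == 0:
        raise ValueError("promoter_calls is empty")
    n_all = len(promoter_calls)
    scored = (promoter_calls["peakscore_nor"] > 0) | (promoter_calls["peakscore_pv"] > 0)
    n_scored = int(scored.sum())
    rows = []
    for klass in (TE_HYPO, TE_HYPER):
        k = int((promoter_calls["klass"] == klass).sum())
        rows.append({
            "klass": klass,
            "count": k,
            "n_scored": n_scored,
            "n_promoters": n_all,
            "pct_of_scored": 100.0 * k / n_scored if n_scored else 0.0,
            "pct_of_all": 100.0 * k / n_all,
        })
    proportions = pd.DataFrame(rows)

    present_col = {TE_HYPO: "peakscore_pv", TE_HYPER: "peakscore_nor"}
    hist_rows = []
    for klass, col in present_col.items():
        s = promoter_calls.loc[promoter_calls["klass"] == klass, col].to_numpy()
        if len(s) == 0:
            continue
        edges = bin_edges
        if edges is None:
            top = max(4.0, np.ceil(s.max() * 2) / 2 + 0.5)
            edges = np.arange(3.0, top + 1e-9, 0.5)
        counts, edges = np.histogram(s, bins=edges)
        for lo, hi, c in zip(edges[:-1], edges[1:], counts):
            hist_rows.append({
                "klass": klass,
                "bin_lo": float(lo),
                "bin_hi": float(hi),
                "count": int(c),
                "pct": 100.0 * c / len(s),
            })
    histogram = pd.DataFrame(
        hist_rows, columns=["klass", "bin_lo", "bin_hi", "count", "pct"]
    )
    return proportions, histogram


def write_calls(calls: pd.DataFrame, path, float_cols=("peakscore_nor", "peakscore_pv")) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out = calls.copy()
    for col in float_cols:
        if col in out:
            out[col] = out[col].map(lambda v: f"{v:.6f}")
    with open(path, "w") as fh:
        fh.write("# medipchip promoter/gene calls; peakscore = -log10 p; "
                 "absent peak scored 0; gene rule: unique differential class "
                 "wins, conflicts neutralize\n")
        out.to_csv(fh, sep="\t", index=False)
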