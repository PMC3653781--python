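"""Promoter classification criteria, gene summarization, and tabulation."""

import numpy as np
import pandas as pd
import pytest

from medipchip import (
    ClassificationThresholds,
    assign_promoter_scores,
    classify_promoter,
    classify_promoters,
    summarize_genes,
    tabulate,
)
from medipchip.differential import TE_HYPER, TE_HYPO, UNCLASSIFIED


@pytest.mark.parametrize("nor, pv, expected", [
    (1.0, 3.5, TE_HYPO),        # peak only in PV: TE DNA unmethylated
    (2.5, 3.5, UNCLASSIFIED),   # Nor not clearly absent
    (1.0, 3.0, UNCLASSIFIED),   # boundary: "more than 3.0" is strict
    (2.0, 3.5, UNCLASSIFIED),   # boundary: "less than 2.0" is strict
    (4.0, 0.0, TE_HYPER),       # peak only in Nor
    (0.0, 0.0, UNCLASSIFIED),
    (3.5, 3.5, UNCLASSIFIED),   # methylated in both
])
def test_classification_criteria(nor, pv, expected):
    assert classify_promoter(nor, pv) == expected


def test_classify_rejects_negative_scores():
    with pytest.raises(ValueError):
        classify_promoter(-0.1, 1.0)
    with pytest.raises(ValueError):
        ClassificationThresholds(present_min=1.0, absent_max=2.0)


def test_vectorized_classification_matches_scalar():
    rng = np.random.default_rng(0)
    scores = pd.DataFrame({
        "accession": [f"NM_{i}" for i in range(200)],
        "gene_symbol": [f"G{i}" for i in range(200)],
        "peakscore_nor": rng.uniform(0, 5, 200),
        "peakscore_pv": rng.uniform(0, 5, 200),
    })
    calls = classify_promoters(scores)
    for rec in calls.itertuples(index=False):
        assert rec.klass == classify_promoter(rec.peakscore_nor, rec.peakscore_pv)


def test_label_swap_symmetry():
    """Swapping the two conditions swaps hypo and hyper counts exactly."""
    rng = np.random.default_rng(1)
    scores = pd.DataFrame({
        "accession": [f"NM_{i}" for i in range(500)],
        "gene_symbol": [f"G{i}" for i in range(500)],
        "peakscore_nor": rng.uniform(0, 5, 500),
        "peakscore_pv": rng.uniform(0, 5, 500),
    })
    fwd = classify_promoters(scores)["klass"].value_counts()
    swapped = scores.rename(columns={"peakscore_nor": "peakscore_pv",
                                     "peakscore_pv": "peakscore_nor"})
    rev = classify_promoters(swapped)["klass"].value_counts()
    assert fwd.get(TE_HYPO, 0) == rev.get(TE_HYPER, 0)
    assert fwd.get(TE_HYPER, 0) == rev.get(TE_HYPO, 0)


def _annotation():
    return pd.DataFrame({
        "gene_symbol": ["GA", "GA", "GB"],
        "accession": ["NM_1", "NM_2", "NM_3"],
        "chrom": ["chrS1", "chrS1", "chrS2"],
        "tss": [10000, 30000, 10000],
        "strand": ["+", "+", "+"],
        "start": [7800, 27800, 7800],
        "end": [10500, 30500, 10500],
    })


def _peaks(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "probe_count",
                                       "d_statistic", "p_value", "peakscore"])


def test_peak_to_promoter_assignment_max_rule(caplog):
    ann = _annotation()
    peaks_nor = _peaks([
        ("chrS1", 8000, 8500, 3, 0.9, 1e-4, 3.2),   # inside NM_1
        ("chrS1", 10400, 11000, 3, 0.9, 1e-5, 4.1),  # 1-bp-style overlap of NM_1
        ("chrS1", 15000, 15500, 3, 0.9, 1e-4, 3.0),  # overlaps nothing
        ("chrUnknown", 100, 200, 2, 0.5, 1e-3, 3.0),
    ])
    peaks_pv = _peaks([])
    with caplog.at_level("WARNING"):
        scores = assign_promoter_scores(peaks_nor, peaks_pv, ann)
    assert "chrUnknown" in caplog.text
    byacc = scores.set_index("accession")
    assert byacc.loc["NM_1", "peakscore_nor"] == pytest.approx(4.1)  # max of 3.2, 4.1
    assert byacc.loc["NM_2", "peakscore_nor"] == 0.0
    assert byacc.loc["NM_3", "peakscore_nor"] == 0.0
    assert (byacc["peakscore_pv"] == 0.0).all()
    assert len(scores) == len(ann)  # every promoter appears


def test_gene_summarization_rules():
    calls = pd.DataFrame({
        "accession": ["NM_1", "NM_2", "NM_3", "NM_4", "NM_5", "NM_6"],
        "gene_symbol": ["GA", "GA", "GB", "GB", "GC", "GC"],
        "peakscore_nor": [0.0] * 6,
        "peakscore_pv": [0.0] * 6,
        "klass": [TE_HYPO, UNCLASSIFIED,     # any differential promoter wins
                  TE_HYPO, TE_HYPER,         # conflict neutralizes
                  UNCLASSIFIED, UNCLASSIFIED],
    })
    genes = summarize_genes(calls).set_index("gene_symbol")
    assert genes.loc["GA", "klass"] == TE_HYPO
    assert genes.loc["GA", "supporting_accessions"] == "NM_1"
    assert not genes.loc["GA", "conflict_flag"]
    assert genes.loc["GB", "klass"] == UNCLASSIFIED
    assert genes.loc["GB", "conflict_flag"]
    assert genes.loc["GC", "klass"] == UNCLASSIFIED
    assert not genes.loc["GC", "conflict_flag"]


def test_tabulate_counts_and_histogram():
    n = 100
    klass = np.array([UNCLASSIFIED] * n, dtype=object)
    klass[:10] = TE_HYPO
    klass[10:14] = TE_HYPER
    pv = np.zeros(n)
    pv[:10] = [3.2, 3.4, 3.1, 3.3, 3.2, 3.6, 3.8, 4.2, 3.1, 3.4]
    nor = np.zeros(n)
    nor[10:14] = [3.2, 3.6, 4.1, 4.6]
    nor[50:] = 1.0  # scored but unclassified promoters
    calls = pd.DataFrame({
        "accession": [f"NM_{i}" for i in range(n)],
        "gene_symbol": [f"G{i}" for i in range(n)],
        "peakscore_nor": nor,
        "peakscore_pv": pv,
        "klass": klass,
    })
    prop, hist = tabulate(calls)
    prop = prop.set_index("klass")
    assert prop.loc[TE_HYPO, "count"] == 10
    assert prop.loc[TE_HYPER, "count"] == 4
    assert prop.loc[TE_HYPO, "pct_of_all"] == pytest.approx(10.0)
    assert prop.loc[TE_HYPER, "pct_of_all"] == pytest.approx(4.0)
    n_scored = prop.loc[TE_HYPO, "n_scored"]
    assert n_scored == 10 + 4 + 50
    assert prop.loc[TE_HYPO, "pct_of_scored"] == pytest.approx(100 * 10 / n_scored)
    # histogram: hypo present-condition scores, 7/10 in [3.0, 3.5)
    h = hist[(hist["klass"] == TE_HYPO) & (hist["bin_lo"] == 3.0)]
    assert h["count"].iloc[0] == 7
    assert h["pct"].iloc[0] == pytest.approx(70.0)


def test_tabulate_with_no_differential_promoters():
    calls = pd.DataFrame({
        "accession": ["NM_1"], "gene_symbol": ["GA"],
        "peakscore_nor": [0.0], "peakscore_pv": [0.0], "klass": [UNCLASSIFIED],
    })
    prop, hist = tabulate(calls)
    assert (prop["count"] == 0).all()
    assert len(hist) == 0
    with pytest.raises(ValueError):
        tabulate(calls.iloc[0:0])


def test_profile_swap_symmetry_end_to_end(small_study):
    """Swapping the Nor/PV peak sets swaps the two differential classes exactly."""
    ann = small_study["annotation"]
    fwd = classify_promoters(assign_promoter_scores(
        small_study["peaks_nor"], small_study["peaks_pv"], ann))
    rev = classify_promoters(assign_promoter_scores(
        small_study["peaks_pv"], small_study["peaks_nor"], ann))
    f = fwd["klass"].value_counts()
    r = rev["klass"].value_counts()
    assert f.get(TE_HYPO, 0) == r.get(TE_HYPER, 0)
    assert f.get(TE_HYPER, 0) == r.get(TE_HYPO, 0)
    hypo_fwd = set(fwd.loc[fwd["klass"] == TE_HYPO, "accession"])
    hyper_rev = set(rev.loc[rev["klass"] == TE_HYPER, "accession"])
    assert hypo_fwd == hyper_rev
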