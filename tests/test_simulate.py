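"""Generator determinism, planted-truth bookkeeping, and mixture means."""

import numpy as np
import pandas as pd
import pytest

from medipchip import (
    AssayParams,
    MixtureModel,
    SimulationConfig,
    generate_annotation,
    plant_truth,
    simulate_arrays,
    simulate_cohort,
    simulate_ct_tables,
)
from medipchip.arrayio import promoter_interval
from medipchip.simulate import METH_BOTH, TE_HYPER, TE_HYPO, UNMETH_BOTH


def test_promoter_interval_orientation():
    assert promoter_interval(10000, "+") == (7800, 10500)
    assert promoter_interval(10000, "-") == (9500, 12200)


@pytest.mark.parametrize("n_genes", [1, 37, 500])
def test_annotation_is_deterministic_and_nonoverlapping(n_genes):
    cfg = SimulationConfig(n_genes=n_genes, seed=1)
    a1 = generate_annotation(cfg)
    a2 = generate_annotation(cfg)
    pd.testing.assert_frame_equal(a1, a2)
    assert len(a1) == n_genes
    for _, grp in a1.groupby("chrom"):
        grp = grp.sort_values("start")
        assert (grp["start"].to_numpy()[1:] >= grp["end"].to_numpy()[:-1]).all()
    # intervals follow the strand-oriented window arithmetic
    for rec in a1.itertuples(index=False):
        assert (rec.start, rec.end) == promoter_interval(rec.tss, rec.strand)


def test_annotation_rejects_bad_config():
    with pytest.raises(ValueError):
        SimulationConfig(n_genes=0)
    with pytest.raises(ValueError):
        SimulationConfig(n_genes=10, probe_spacing=5000)
    with pytest.raises(ValueError):
        SimulationConfig(n_genes=10, fraction_te_hypo=0.6, fraction_te_hyper=0.5)


def test_planted_class_counts_follow_rounding():
    cfg = SimulationConfig(n_genes=1000, seed=2)
    truth = plant_truth(generate_annotation(cfg), cfg)
    counts = truth["true_class"].value_counts()
    assert counts[TE_HYPO] == 97  # round(1000 * 0.0971)
    assert counts[TE_HYPER] == 35  # round(1000 * 0.0353)
    assert counts[METH_BOTH] == 96
    # states are consistent with the class definitions
    hypo = truth[truth["true_class"] == TE_HYPO]
    assert (hypo["state_te"] == "unmethylated").all()
    assert (hypo["state_bg"] == "methylated").all()
    hyper = truth[truth["true_class"] == TE_HYPER]
    assert (hyper["state_te"] == "methylated").all()
    assert (hyper["state_bg"] == "unmethylated").all()


def test_zero_fractions_plant_nothing_and_truth_is_deterministic():
    cfg = SimulationConfig(n_genes=50, fraction_te_hypo=0.0, fraction_te_hyper=0.0,
                           fraction_methylated_background=0.0, seed=3)
    ann = generate_annotation(cfg)
    t1 = plant_truth(ann, cfg)
    t2 = plant_truth(ann, cfg)
    pd.testing.assert_frame_equal(t1, t2)
    assert (t1["true_class"] == UNMETH_BOTH).all()


def test_mixture_endpoints_and_reproducibility():
    cfg = SimulationConfig(n_genes=12, seed=4)
    ann = generate_annotation(cfg)
    truth = plant_truth(ann, cfg)
    # f=1: Nor reads the TE state; f=0 (PV) reads the background state
    mix = MixtureModel(fraction_te=1.0, sigma_probe=1e-9, seed=4)
    nor, pv = simulate_arrays(ann, truth, mix, cfg)
    by_gene = truth.set_index("gene_symbol")
    probes = nor.probes.merge(
        ann[["chrom", "start", "end", "gene_symbol"]].rename(
            columns={"start": "pstart", "end": "pend"}),
        on="chrom")
    probes = probes[(probes["start"] >= probes["pstart"]) & (probes["end"] <= probes["pend"])]
    for gene, grp in probes.groupby("gene_symbol"):
        mu_te = 1.5 if by_gene.loc[gene, "state_te"] == "methylated" else 0.0
        assert np.allclose(grp["log2_ratio"], mu_te, atol=1e-6)
    # determinism
    nor2, pv2 = simulate_arrays(ann, truth, mix, cfg)
    pd.testing.assert_frame_equal(nor.probes, nor2.probes)
    pd.testing.assert_frame_equal(pv.probes, pv2.probes)


def test_nor_mean_over_hypo_promoters_matches_mixture_closed_form():
    """At f=0.73 the hypo-promoter Nor mean is 0.27 * 1.5 = 0.405."""
    cfg = SimulationConfig(n_genes=1000, seed=6)
    ann = generate_annotation(cfg)
    truth = plant_truth(ann, cfg)
    mix = MixtureModel(seed=6)
    nor, pv = simulate_arrays(ann, truth, mix, cfg)
    hypo_genes = set(truth.loc[truth["true_class"] == TE_HYPO, "gene_symbol"])
    hypo_ann = ann[ann["gene_symbol"].isin(hypo_genes)]
    mask = np.zeros(len(nor.probes), dtype=bool)
    for rec in hypo_ann.itertuples(index=False):
        mask |= ((nor.probes["chrom"] == rec.chrom)
                 & (nor.probes["start"] >= rec.start)
                 & (nor.probes["end"] <= rec.end)).to_numpy()
    vals = nor.values[mask]
    mc_err = 4 * mix.sigma_probe / np.sqrt(mask.sum())
    assert vals.mean() == pytest.approx(0.27 * 1.5, abs=mc_err)
    # PV mean at those promoters equals the background-state mean exactly in expectation
    pv_vals = pv.values[mask]
    assert pv_vals.mean() == pytest.approx(1.5, abs=4 * mix.sigma_probe / np.sqrt(mask.sum()))


def test_simulate_arrays_rejects_empty_annotation():
    cfg = SimulationConfig(n_genes=1, seed=0)
    truth = pd.DataFrame(columns=["gene_symbol", "state_te", "state_bg", "true_class"])
    with pytest.raises(ValueError):
        simulate_arrays(pd.DataFrame(columns=["chrom", "start", "end"]), truth,
                        MixtureModel(), cfg)


def test_ct_tables_invert_the_quantification_formulas():
    cfg = SimulationConfig(n_genes=30, seed=7)
    truth = plant_truth(generate_annotation(cfg), cfg)
    params = AssayParams(noise_sd=0.0, dilution_factor=0.25, seed=7)
    qpcr, ml = simulate_ct_tables(truth, params)
    # noise-free: the percent formulas recover the planted values exactly
    pct = 2.0 ** -(qpcr["ct_ip"] - qpcr["ct_input"]) * qpcr["dilution_factor"] * 100
    assert np.allclose(pct, qpcr["true_enrichment"] * 100, atol=1e-9)
    ddct = (ml["ct_target_sample"] - ml["ct_reference_sample"]) - (
        ml["ct_target_fullmeth"] - ml["ct_reference_fullmeth"])
    assert np.allclose(2.0 ** -ddct * 100, ml["true_methylation"] * 100, atol=1e-9)
    # determinism
    qpcr2, ml2 = simulate_ct_tables(truth, params)
    pd.testing.assert_frame_equal(qpcr, qpcr2)
    pd.testing.assert_frame_equal(ml, ml2)


def test_ct_tables_simple_identities():
    truth = pd.DataFrame({
        "gene_symbol": ["G1"], "state_te": ["methylated"],
        "state_bg": ["methylated"], "true_class": [METH_BOTH],
    })
    # true enrichment 100%, dilution 1, no noise -> Ct_IP == Ct_Input
    q, _ = simulate_ct_tables(truth, AssayParams(
        noise_sd=0.0, enrichment_methylated=1.0, dilution_factor=1.0))
    assert q["ct_ip"].iloc[0] == pytest.approx(q["ct_input"].iloc[0], abs=1e-12)
    # true methylation 50%, no noise -> ddCt = 1
    _, ml = simulate_ct_tables(truth, AssayParams(noise_sd=0.0, pmr_methylated=0.5))
    ddct = (ml["ct_target_sample"] - ml["ct_reference_sample"]) - (
        ml["ct_target_fullmeth"] - ml["ct_reference_fullmeth"])
    assert ddct.iloc[0] == pytest.approx(1.0, abs=1e-12)


def test_zero_methylation_is_censored_not_errored():
    truth = pd.DataFrame({
        "gene_symbol": ["G1"], "state_te": ["unmethylated"],
        "state_bg": ["methylated"], "true_class": [TE_HYPO],
    })
    _, ml = simulate_ct_tables(truth, AssayParams(noise_sd=0.0, pmr_unmethylated=0.0))
    assert bool(ml["censored"].iloc[0])
    assert np.isnan(ml["ct_target_sample"].iloc[0])


def test_cohort_generator_tracks_planted_means():
    cohort = simulate_cohort(seed=9)
    assert len(cohort["Nor"]) == 12 and len(cohort["PV"]) == 11
    assert (cohort["Nor"] > 0).all() and (cohort["PV"] > 0).all()
    assert cohort["Nor"].mean() == pytest.approx(1.23, abs=4 * 0.32 / np.sqrt(12))
    assert cohort["PV"].mean() == pytest.approx(0.33, abs=4 * 0.09 / np.sqrt(11))
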