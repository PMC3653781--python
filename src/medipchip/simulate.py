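"""Seeded generative model of the cell-free seminal DNA MeDIP-chip study.

Generates promoter annotations, probe tilings, two-condition probe-level
array profiles and validation-assay Ct tables with *known planted truth*, so
that every downstream stage can be tested for recovery.

The biology emulated: cell-free seminal DNA of normozoospermic men (Nor) is
a mixture in which ~73% derives from testis/epididymis (TE) and the rest
from accessory glands; post-vasectomy (PV) semen contains no TE-derived DNA.
Each promoter has one methylation state per source.  A probe's expected
log2(IP/Input) is the mixture of the per-state means weighted by the TE
fraction (f = 0.73 for Nor, f = 0 for PV), with Gaussian probe noise:
a simplification on the log-ratio scale that keeps every expectation in
closed form for testing.

Planted class proportions default to the study's reported promoter classes
(9.71% TE-specific hypomethylated, 3.53% TE-specific hypermethylated).  The
fraction of remaining genes methylated in both sources defaults to 0.096 so
that ~22.8% of promoters carry methylation signal in at least one condition,
matching the fraction of array promoters with detectable peaks (4111/18028).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .arrayio import ArrayProfile, promoter_interval, validate_annotation

METHYLATED = "methylated"
UNMETHYLATED = "unmethylated"

TE_HYPO = "te_hypomethylated"
TE_HYPER = "te_hypermethylated"
METH_BOTH = "methylated_both"
UNMETH_BOTH = "unmethylated_both"


@dataclass
class MixtureModel:
    """Two-source mixture of the Nor cfsDNA signal.

    fraction_te : proportion of Nor cfsDNA from testis/epididymis (0.73,
    from the ~quadruple Nor/PV concentration ratio).  PV uses
    ``fraction_te_pv`` (0: vasectomy removes all TE-derived DNA).
    """

    fraction_te: float = 0.73
    fraction_te_pv: float = 0.0
    mu_methylated: float = 1.5
    mu_unmethylated: float = 0.0
    sigma_probe: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_te <= 1.0:
            raise ValueError("fraction_te must be in [0, 1]")
        if not 0.0 <= self.fraction_te_pv <= 1.0:
            raise ValueError("fraction_te_pv must be in [0, 1]")
        if not self.mu_methylated > self.mu_unmethylated:
            raise ValueError("mu_methylated must exceed mu_unmethylated")
        if not self.sigma_probe > 0:
            raise ValueError("sigma_probe must be positive")

    def state_mean(self, state: str) -> float:
        return self.mu_methylated if state == METHYLATED else self.mu_unmethylated


@dataclass
class SimulationConfig:
    """Layout and planted-truth parameters of the synthetic promoter array."""

    n_genes: int = 1000
    promoter_upstream: int = 2200
    promoter_downstream: int = 500
    probe_spacing: int = 100
    probe_length: int = 50
    fraction_te_hypo: float = 0.0971
    fraction_te_hyper: float = 0.0353
    fraction_methylated_background: float = 0.096
    genes_per_chromosome: int = 100
    intergenic_gap: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.fraction_te_hypo + self.fraction_te_hyper >= 1.0:
            raise ValueError("planted class fractions must sum to < 1")
        for name in ("fraction_te_hypo", "fraction_te_hyper",
                     "fraction_methylated_background"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        window = self.promoter_upstream + self.promoter_downstream
        if not 0 < self.probe_spacing < window:
            raise ValueError("probe_spacing must be positive and smaller than "
                             "the promoter window")
        if self.intergenic_gap < 0:
            raise ValueError("intergenic_gap must be non-negative")


@dataclass
class AssayParams:
    """Generative parameters for MeDIP-qPCR and MethyLight Ct tables.

    Perfect PCR doubling (efficiency 2) is assumed throughout, matching the
    2^-dCt quantification formulas.  Default planted levels follow the
    validation assays' observed scale: IP/Input ~10% at methylated loci vs
    ~0.2% at unmethylated ones; percent-of-methylated-reference ~59% vs
    ~2.6e-5 (the H19 / GAPDH scale).
    """

    ct_input: float = 30.0
    ct_reference: float = 25.0
    delta_ct_fullmeth: float = 1.0
    dilution_factor: float = 1.0
    noise_sd: float = 0.1
    enrichment_methylated: float = 0.10
    enrichment_unmethylated: float = 0.002
    pmr_methylated: float = 0.593
    pmr_unmethylated: float = 2.6e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dilution_factor <= 0:
            raise ValueError("dilution_factor must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def generate_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Place ``n_genes`` non-overlapping promoters on synthetic chromosomes.

    Chromosomes are named ``chrS1..chrSk`` holding ``genes_per_chromosome``
    genes each; TSSs are spaced so promoter windows ([-2200, +500) around the
    TSS in transcription orientation) never overlap.  Strand is drawn per
    gene from the seed.  Deterministic given the config.
    """
    rng = np.random.default_rng(config.seed)
    window = config.promoter_upstream + config.promoter_downstream
    step = window + config.intergenic_gap
    records = []
    for i in range(config.n_genes):
        chrom = f"chrS{i // config.genes_per_chromosome + 1}"
        slot = i % config.genes_per_chromosome
        strand = "+" if rng.random() < 0.5 else "-"
        # anchor each slot so the interval fits regardless of strand
        tss = config.promoter_upstream + config.intergenic_gap + slot * step
        start, end = promoter_interval(
            tss, strand, config.promoter_upstream, config.promoter_downstream
        )
        records.append({
            "gene_symbol": f"GENE{i:05d}",
            "accession": f"NM_{i:06d}",
            "chrom": chrom,
            "tss": tss,
            "strand": strand,
            "start": start,
            "end": end,
        })
    return validate_annotation(pd.DataFrame(records))


def plant_truth(annotation: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Assign each gene a per-source methylation state (the planted truth).

    Class counts equal round(n_genes * fraction); the assignment of classes
    to genes is a seeded permutation.  Returns one row per gene with columns
    ``gene_symbol, state_te, state_bg, true_class``.
    """
    genes = annotation["gene_symbol"].drop_duplicates().to_numpy()
    n = len(genes)
    n_hypo = round(n * config.fraction_te_hypo)
    n_hyper = round(n * config.fraction_te_hyper)
    n_meth = round(n * config.fraction_methylated_background)
    n_meth = min(n_meth, n - n_hypo - n_hyper)
    rng = np.random.default_rng(config.seed + 1)
    order = rng.permutation(n)
    true_class = np.full(n, UNMETH_BOTH, dtype=object)
    true_class[order[:n_hypo]] = TE_HYPO
    true_class[order[n_hypo:n_hypo + n_hyper]] = TE_HYPER
    true_class[order[n_hypo + n_hyper:n_hypo + n_hyper + n_meth]] = METH_BOTH
    state_te = np.where(np.isin(true_class, [TE_HYPER, METH_BOTH]),
                        METHYLATED, UNMETHYLATED)
    state_bg = np.where(np.isin(true_class, [TE_HYPO, METH_BOTH]),
                        METHYLATED, UNMETHYLATED)
    return pd.DataFrame({
        "gene_symbol": genes,
        "state_te": state_te,
        "state_bg": state_bg,
        "true_class": true_class,
    })


def _tile_probes(annotation: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for rec in annotation.itertuples(index=False):
        starts = np.arange(rec.start, rec.end - config.probe_length + 1,
                           config.probe_spacing, dtype=np.int64)
        for s in starts:
            rows.append((rec.chrom, int(s), int(s) + config.probe_length,
                         rec.gene_symbol))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_symbol"])
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    df.insert(0, "probe_id", [f"PR{i:07d}" for i in range(len(df))])
    return df


def simulate_arrays(
    annotation: pd.DataFrame,
    truth: pd.DataFrame,
    mixture: MixtureModel,
    config: SimulationConfig | None = None,
) -> tuple[ArrayProfile, ArrayProfile]:
    """Draw the two pooled array profiles (Nor, PV) from the mixture model.

    Each probe value is Normal(mu_mix, sigma_probe) with
    mu_mix = f * mu(state_te) + (1 - f) * mu(state_bg), f = fraction_te for
    Nor and fraction_te_pv (0) for PV.  Probe layouts are identical between
    conditions; noise draws are independent.  Seeded and reproducible.
    """
    if len(annotation) == 0:
        raise ValueError("annotation is empty")
    config = config or SimulationConfig(n_genes=max(len(annotation), 1))
    probes = _tile_probes(annotation, config)
    states = truth.set_index("gene_symbol")
    mu_te = states.loc[probes["gene_symbol"], "state_te"].map(
        mixture.state_mean).to_numpy(dtype=float)
    mu_bg = states.loc[probes["gene_symbol"], "state_bg"].map(
        mixture.state_mean).to_numpy(dtype=float)

    seeds = np.random.SeedSequence(mixture.seed).spawn(2)
    profiles = []
    for label, f, seed in (("Nor", mixture.fraction_te, seeds[0]),
                           ("PV", mixture.fraction_te_pv, seeds[1])):
        mu_mix = f * mu_te + (1.0 - f) * mu_bg
        rng = np.random.default_rng(seed)
        values = rng.normal(mu_mix, mixture.sigma_probe)
        df = probes[["probe_id", "chrom", "start", "end"]].copy()
        df["log2_ratio"] = values
        prof = ArrayProfile(condition=label, probes=df)
        prof.provenance.append(f"simulate_arrays:fraction_te={f}:seed={mixture.seed}")
        profiles.append(prof)
    return profiles[0], profiles[1]


def simulate_ct_tables(
    truth: pd.DataFrame, assay_params: AssayParams
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate MeDIP-qPCR and MethyLight Ct tables consistent with the truth.

    The Ct construction inverts the quantification formulas exactly, so at
    ``noise_sd = 0`` the calculators recover the planted levels to machine
    precision: a locus with IP/Input enrichment e gets
    ``ct_ip = ct_input + log2(dilution) - log2(e)`` and a locus with
    methylation fraction m gets ``ddCt = -log2(m)``.  A planted methylation
    fraction of exactly 0 cannot be expressed as a finite Ct; such rows are
    emitted with ``censored = True`` and missing target Ct.
    """
    p = assay_params
    rng = np.random.default_rng(p.seed)
    meth_te = truth["state_te"].to_numpy() == METHYLATED

    qpcr_rows, ml_rows = [], []
    for i, rec in enumerate(truth.itertuples(index=False)):
        e = p.enrichment_methylated if meth_te[i] else p.enrichment_unmethylated
        ct_ip = (p.ct_input + np.log2(p.dilution_factor) - np.log2(e)
                 + rng.normal(0.0, p.noise_sd))
        qpcr_rows.append({
            "locus_id": rec.gene_symbol,
            "ct_ip": ct_ip,
            "ct_input": p.ct_input,
            "dilution_factor": p.dilution_factor,
            "true_enrichment": e,
        })

        m = p.pmr_methylated if meth_te[i] else p.pmr_unmethylated
        ct_ref_sample = p.ct_reference + rng.normal(0.0, p.noise_sd)
        if m == 0.0:
            ml_rows.append({
                "locus_id": rec.gene_symbol,
                "ct_target_sample": np.nan,
                "ct_reference_sample": ct_ref_sample,
                "ct_target_fullmeth": p.ct_reference + p.delta_ct_fullmeth,
                "ct_reference_fullmeth": p.ct_reference,
                "censored": True,
                "true_methylation": 0.0,
            })
            continue
        ct_target = (ct_ref_sample + p.delta_ct_fullmeth - np.log2(m)
                     + rng.normal(0.0, p.noise_sd))
        ml_rows.append({
            "locus_id": rec.gene_symbol,
            "ct_target_sample": ct_target,
            "ct_reference_sample": ct_ref_sample,
            "ct_target_fullmeth": p.ct_reference + p.delta_ct_fullmeth,
            "ct_reference_fullmeth": p.ct_reference,
            "censored": False,
            "true_methylation": m,
        })
    return pd.DataFrame(qpcr_rows), pd.DataFrame(ml_rows)


def simulate_cohort(
    n_nor: int = 12,
    n_pv: int = 11,
    mean_nor: float = 1.23,
    sd_nor: float = 0.32,
    mean_pv: float = 0.33,
    sd_pv: float = 0.09,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Draw per-subject cfsDNA concentrations (ug/ml seminal plasma).

    Defaults reproduce the study cohort: Nor 1.23 +/- 0.32 (n=12) and PV
    0.33 +/- 0.09 (n=11).  Values are truncated at a small positive floor.
    """
    rng = np.random.default_rng(seed)
    nor = np.maximum(rng.normal(mean_nor, sd_nor, size=n_nor), 1e-3)
    pv = np.maximum(rng.normal(mean_pv, sd_pv, size=n_pv), 1e-3)
    return {"Nor": nor, "PV": pv}


def recovery_metrics(gene_calls: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Sensitivity/precision of TE-specific gene calls against planted truth.

    A planted TE-specific gene counts as recovered when called with its
    planted class; precision is the fraction of TE-specific calls that are
    correct.  Returns a dict with tp/fp/fn counts alongside.
    """
    te_classes = {TE_HYPO, TE_HYPER}
    t = truth.set_index("gene_symbol")["true_class"]
    c = gene_calls.set_index("gene_symbol")["klass"]
    c = c.reindex(t.index, fill_value="unclassified")
    planted = t.isin(te_classes)
    called = c.isin(te_classes)
    tp = int((planted & (c == t)).sum())
    fp = int((called & (c != t)).sum())
    fn = int(planted.sum()) - tp
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "n_planted": int(planted.sum()),
        "n_called": int(called.sum()),
        "sensitivity": tp / planted.sum() if planted.any() else float("nan"),
        "precision": tp / called.sum() if called.any() else float("nan"),
    }


def write_truth(truth: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    truth.to_csv(path, sep="\t", index=False)
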