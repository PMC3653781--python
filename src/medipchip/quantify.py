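"""Validation-assay calculators: MeDIP-qPCR enrichment and MethyLight PMR.

Both assume perfect PCR doubling (efficiency 2), as the 2^-dCt formulas do.

* MeDIP-qPCR: percent IP/Input = 2^-(Ct_IP - Ct_Input) x dilution x 100,
  the recovery of a locus in the immunoprecipitate relative to input DNA.
* MethyLight: percent of methylated reference = 2^-ddCt x 100 with
  ddCt = (Ct_target - Ct_reference)_sample - (Ct_target - Ct_reference)_fully-methylated,
  i.e. methylation relative to a fully methylated control DNA.

Control checks mirror the study's assay QC: a constitutively unmethylated
negative-control locus (GAPDH-like) must quantify near zero, and each
MethyLight reaction must discriminate unmethylated from fully methylated
DNA by a Ct margin of at least 5 cycles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CT_RANGE = (0.0, 45.0)


@dataclass
class QpcrCtRecord:
    locus_id: str
    ct_ip: float
    ct_input: float
    dilution_factor: float

    def __post_init__(self) -> None:
        for name in ("ct_ip", "ct_input"):
            v = getattr(self, name)
            if not CT_RANGE[0] < v < CT_RANGE[1]:
                raise ValueError(f"{name}={v} outside plausible Ct range {CT_RANGE}")
        if not self.dilution_factor > 0:
            raise ValueError("dilution_factor must be positive")


@dataclass
class MethylightCtRecord:
    locus_id: str
    ct_target_sample: float
    ct_reference_sample: float
    ct_target_fullmeth: float
    ct_reference_fullmeth: float

    def __post_init__(self) -> None:
        for name in ("ct_target_sample", "ct_reference_sample",
                     "ct_target_fullmeth", "ct_reference_fullmeth"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v):
                raise ValueError(f"missing Ct value {name}")
            if not CT_RANGE[0] < v < CT_RANGE[1]:
                raise ValueError(f"{name}={v} outside plausible Ct range {CT_RANGE}")


@dataclass
class ControlExpectation:
    """Assay-QC thresholds for the control loci."""

    negative_control_id: str = "GAPDH"
    positive_control_id: str = "H19"
    max_negative_pct: float = 0.01
    min_delta_ct_specificity: float = 5.0

    def __post_init__(self) -> None:
        if self.max_negative_pct <= 0 or self.min_delta_ct_specificity <= 0:
            raise ValueError("control thresholds must be positive")


def medip_percent(record: QpcrCtRecord) -> float:
    """Percent IP/Input enrichment: 2^-(Ct_IP - Ct_Input) x dilution x 100."""
    return 2.0 ** -(record.ct_ip - record.ct_input) * record.dilution_factor * 100.0


def methylight_pmr(record: MethylightCtRecord) -> float:
    """Percent of methylated reference: 2^-ddCt x 100.

    Values above 100% (possible with noisy Cts) are returned as computed;
    callers flag them via :func:`quantify_methylight`.
    """
    ddct = (record.ct_target_sample - record.ct_reference_sample) - (
        record.ct_target_fullmeth - record.ct_reference_fullmeth
    )
    return 2.0 ** -ddct * 100.0


def quantify_medip(table: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`medip_percent` to a qPCR Ct table.

    Replicate rows for the same locus are averaged on the Ct scale first.
    Requires columns ``locus_id, ct_ip, ct_input, dilution_factor``.
    """
    agg = table.groupby("locus_id", sort=False).agg(
        ct_ip=("ct_ip", "mean"),
        ct_input=("ct_input", "mean"),
        dilution_factor=("dilution_factor", "first"),
    ).reset_index()
    agg["percent_ip_input"] = [
        medip_percent(QpcrCtRecord(r.locus_id, r.ct_ip, r.ct_input, r.dilution_factor))
        for r in agg.itertuples(index=False)
    ]
    return agg


def quantify_methylight(table: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`methylight_pmr` to a MethyLight Ct table.

    Rows flagged ``censored`` (no amplification of the methylated target)
    get ``percent_methylation = 0`` and keep the flag; computed values above
    100% are flagged ``over_range`` rather than clipped.
    """
    rows = []
    for r in table.itertuples(index=False):
        censored = bool(getattr(r, "censored", False)) or not np.isfinite(r.ct_target_sample)
        if censored:
            pmr = 0.0
        else:
            pmr = methylight_pmr(MethylightCtRecord(
                r.locus_id, r.ct_target_sample, r.ct_reference_sample,
                r.ct_target_fullmeth, r.ct_reference_fullmeth,
            ))
        rows.append({
            "locus_id": r.locus_id,
            "percent_methylation": pmr,
            "censored": censored,
            "over_range": pmr > 100.0,
        })
    return pd.DataFrame(rows)


def check_assay_controls(
    quantified: pd.DataFrame,
    expectation: ControlExpectation | None = None,
    specificity_margins: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Report-only QC against the control expectations.

    ``quantified`` carries ``locus_id`` plus a percent column
    (``percent_methylation`` or ``percent_ip_input``); ``specificity_margins``
    optionally carries per-locus ``delta_ct_margin`` =
    Ct(unmethylated DNA) - Ct(fully methylated DNA), which must exceed the
    expectation's minimum.  Returns one row per performed check with a
    pass/fail flag; empty inputs yield an empty report.
    """
    exp = expectation or ControlExpectation()
    pct_col = ("percent_methylation" if "percent_methylation" in quantified
               else "percent_ip_input")
    checks = []
    neg = quantified[quantified["locus_id"] == exp.negative_control_id]
    for r in neg.itertuples(index=False):
        value = getattr(r, pct_col)
        checks.append({
            "check": "negative_control_pct",
            "locus_id": exp.negative_control_id,
            "value": value,
            "threshold": exp.max_negative_pct,
            "passed": value <= exp.max_negative_pct,
        })
    if specificity_margins is not None:
        for r in specificity_margins.itertuples(index=False):
            checks.append({
                "check": "specificity_margin",
                "locus_id": r.locus_id,
                "value": r.delta_ct_margin,
                "threshold": exp.min_delta_ct_specificity,
                "passed": r.delta_ct_margin > exp.min_delta_ct_specificity,
            })
    return pd.DataFrame(
        checks, columns=["check", "locus_id", "value", "threshold", "passed"]
    )
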