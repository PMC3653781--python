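"""Sliding-window one-sided KS peak calling on probe-level profiles.

One window is centered at every probe (probe midpoint), spanning
``window_width`` bp; the window's probes are tested for being stochastically
greater than the array-wide background (all other probes) with the exact
one-sided KS test of :mod:`medipchip.kstest`.  Probes belonging to any
window scoring at least ``score_cutoff`` (on the -log10 p scale) are
significant; maximal runs of significant probes with inter-probe spacing at
most ``max_probe_spacing`` and at least ``min_probes_per_peak`` members
become peaks, scored by the best window centered on a member probe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .arrayio import ArrayProfile
from .kstest import EXACT_MAX_MIN_SIZE, _asymptotic_p, _exact_p_cached

logger = logging.getLogger(__name__)

MIN_PROFILE_PROBES = 10


@dataclass
class PeakCallingParams:
    """Sliding-window KS parameters (defaults are the study's settings)."""

    window_width: int = 750
    min_probes_per_peak: int = 2
    score_cutoff: float = 2.0
    max_probe_spacing: int = 500

    def __post_init__(self) -> None:
        if self.window_width <= 0 or self.min_probes_per_peak <= 0:
            raise ValueError("window_width and min_probes_per_peak must be positive")
        if self.score_cutoff <= 0 or self.max_probe_spacing <= 0:
            raise ValueError("score_cutoff and max_probe_spacing must be positive")


@dataclass
class WindowScores:
    """Per-window KS scores plus the probe table they were computed from.

    ``windows`` columns: chrom, start, end (window span), center_probe_id,
    member_start, member_end (chromosome-local probe index span, half-open),
    n_probes, d_statistic, p_value, score (-log10 p).  ``probes`` is the
    position-sorted probe table of the scanned profile.
    """

    windows: pd.DataFrame
    probes: pd.DataFrame
    params: PeakCallingParams


def scan_windows(profile: ArrayProfile, params: PeakCallingParams | None = None) -> WindowScores:
    """Score one window per probe against the array-wide background.

    The background for each window is every other probe on the array; with
    few probes per window the exact permutation p is used (see
    :mod:`medipchip.kstest`).  Requires at least 10 probes so the background
    defines a meaningful null.
    """
    params = params or PeakCallingParams()
    probes = profile.probes
    N = len(probes)
    if N < MIN_PROFILE_PROBES:
        raise ValueError(
            f"profile holds {N} probes; at least {MIN_PROFILE_PROBES} are "
            "needed to define a background null"
        )
    half = params.window_width / 2.0
    values = probes["log2_ratio"].to_numpy(dtype=float)
    all_sorted = np.sort(values)
    uniq, counts = np.unique(all_sorted, return_counts=True)
    tie_groups = None if len(uniq) == N else tuple(int(c) for c in counts)

    mids = ((probes["start"].to_numpy() + probes["end"].to_numpy()) / 2.0)
    chrom_codes, chrom_index = pd.factorize(probes["chrom"], sort=False)

    rows = []
    for ci, chrom in enumerate(chrom_index):
        idx = np.flatnonzero(chrom_codes == ci)
        cmids = mids[idx]
        cvals = values[idx]
        left = np.searchsorted(cmids, cmids - half, side="left")
        right = np.searchsorted(cmids, cmids + half, side="right")
        for j in range(len(idx)):
            lo, hi = int(left[j]), int(right[j])
            m = hi - lo
            n = N - m
            win_sorted = np.sort(cvals[lo:hi])
            # background = all probes minus the window; counts by subtraction
            tot_lt = np.searchsorted(all_sorted, win_sorted, side="left")
            tot_le = np.searchsorted(all_sorted, win_sorted, side="right")
            win_lt = np.searchsorted(win_sorted, win_sorted, side="left")
            win_le = np.searchsorted(win_sorted, win_sorted, side="right")
            cand = np.maximum(
                ((tot_lt - win_lt) * m - win_lt * n).max(),
                ((tot_le - win_le) * m - win_le * n).max(),
            )
            d_num = max(int(cand), 0)
            if min(m, n) <= EXACT_MAX_MIN_SIZE:
                p = _exact_p_cached(tie_groups, m, n, d_num)
            else:
                p = _asymptotic_p(d_num / (m * n), m, n)
            center = cmids[j]
            rows.append((
                chrom, int(np.floor(center - half)), int(np.ceil(center + half)),
                probes["probe_id"].iat[idx[j]], lo, hi, m,
                d_num / (m * n), p, -np.log10(p),
            ))
    windows = pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "center_probe_id", "member_start",
        "member_end", "n_probes", "d_statistic", "p_value", "score",
    ])
    return WindowScores(windows=windows, probes=probes, params=params)


def call_peaks(window_scores: WindowScores, params: PeakCallingParams | None = None) -> pd.DataFrame:
    """Merge significant probes into scored peaks.

    Returns a DataFrame with columns ``chrom, start, end, probe_count,
    d_statistic, p_value, peakscore`` where the peak interval spans the
    first to last member probe and the peakscore is the best (-log10 p)
    among windows centered on member probes.  Empty input yields an empty
    frame.
    """
    params = params or window_scores.params
    win = window_scores.windows
    probes = window_scores.probes
    cols = ["chrom", "start", "end", "probe_count", "d_statistic", "p_value", "peakscore"]
    if len(win) == 0:
        return pd.DataFrame(columns=cols)

    mids = (probes["start"].to_numpy() + probes["end"].to_numpy()) / 2.0
    chrom_codes, chrom_index = pd.factorize(probes["chrom"], sort=False)
    peaks = []
    for ci, chrom in enumerate(chrom_index):
        idx = np.flatnonzero(chrom_codes == ci)
        cwin = win[win["chrom"] == chrom]
        nloc = len(idx)
        sig = np.zeros(nloc, dtype=bool)
        center_score = np.zeros(nloc)
        center_d = np.zeros(nloc)
        center_p = np.ones(nloc)
        for k, w in enumerate(cwin.itertuples(index=False)):
            center_score[k] = w.score
            center_d[k] = w.d_statistic
            center_p[k] = w.p_value
            if w.score >= params.score_cutoff:
                sig[w.member_start:w.member_end] = True
        sig_local = np.flatnonzero(sig)
        if len(sig_local) == 0:
            continue
        cmids = mids[idx]
        gaps = np.diff(cmids[sig_local])
        breaks = np.flatnonzero(gaps > params.max_probe_spacing)
        run_bounds = np.concatenate([[0], breaks + 1, [len(sig_local)]])
        for a, b in zip(run_bounds[:-1], run_bounds[1:]):
            members = sig_local[a:b]
            if len(members) < params.min_probes_per_peak:
                continue
            best = int(members[np.argmax(center_score[members])])
            peakscore = float(center_score[best])
            if peakscore < params.score_cutoff:
                # possible only in degenerate geometries (max_probe_spacing
                # far below window_width); such runs carry no qualifying window
                continue
            first, last = idx[members[0]], idx[members[-1]]
            peaks.append((
                chrom,
                int(probes["start"].iat[first]),
                int(probes["end"].iat[last]),
                len(members),
                float(center_d[best]),
                float(center_p[best]),
                peakscore,
            ))
    out = pd.DataFrame(peaks, columns=cols)
    return out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def validate_peaks(peaks: pd.DataFrame, window_scores: WindowScores,
                   params: PeakCallingParams | None = None) -> None:
    """Assert the peak postconditions; raises AssertionError on violation.

    Every peak must hold >= min_probes_per_peak significant probes,
    consecutive member probes <= max_probe_spacing apart, and a peakscore
    >= score_cutoff equal to the best window centered on a member probe.
    """
    params = params or window_scores.params
    win = window_scores.windows
    probes = window_scores.probes
    mids = (probes["start"].to_numpy() + probes["end"].to_numpy()) / 2.0
    chrom_codes, chrom_index = pd.factorize(probes["chrom"], sort=False)
    for pk in peaks.itertuples(index=False):
        assert pk.peakscore >= params.score_cutoff, "peakscore below cutoff"
        assert pk.probe_count >= params.min_probes_per_peak, "too few probes"
        ci = list(chrom_index).index(pk.chrom)
        idx = np.flatnonzero(chrom_codes == ci)
        cwin = win[win["chrom"] == pk.chrom]
        sig = np.zeros(len(idx), dtype=bool)
        for w in cwin.itertuples(index=False):
            if w.score >= params.score_cutoff:
                sig[w.member_start:w.member_end] = True
        cmids = mids[idx]
        member = sig & (cmids >= pk.start) & (cmids <= pk.end)
        assert member.sum() == pk.probe_count, "probe_count mismatch"
        gaps = np.diff(cmids[member])
        assert len(gaps) == 0 or gaps.max() <= params.max_probe_spacing, \
            "member spacing exceeded"
        center_scores = cwin["score"].to_numpy()
        assert np.isclose(pk.peakscore, center_scores[member].max()), \
            "peakscore is not the best member-centered window"


def write_peaks(peaks: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out = peaks.copy()
    for col in ("d_statistic", "peakscore"):
        out[col] = out[col].map(lambda v: f"{v:.6f}")
    out["p_value"] = out["p_value"].map(lambda v: f"{v:.6e}")
    with open(path, "w") as fh:
        fh.write("# medipchip peaks; coordinates 0-based half-open; "
                 "peakscore = -log10 p of best constituent window\n")
        out.to_csv(fh, sep="\t", index=False)
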