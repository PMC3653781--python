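import numpy as np
import pytest

from medipchip import (
    MixtureModel,
    PeakCallingParams,
    SimulationConfig,
    call_peaks,
    generate_annotation,
    normalize,
    plant_truth,
    scan_windows,
    simulate_arrays,
)


@pytest.fixture(scope="session")
def small_study():
    """A 60-gene synthetic study with planted truth, scanned in both conditions."""
    cfg = SimulationConfig(n_genes=60, seed=5)
    mix = MixtureModel(seed=5)
    annotation = generate_annotation(cfg)
    truth = plant_truth(annotation, cfg)
    nor, pv = simulate_arrays(annotation, truth, mix, cfg)
    nor, pv = normalize(nor), normalize(pv)
    params = PeakCallingParams()
    ws_nor = scan_windows(nor, params)
    ws_pv = scan_windows(pv, params)
    return {
        "config": cfg,
        "mixture": mix,
        "annotation": annotation,
        "truth": truth,
        "nor": nor,
        "pv": pv,
        "params": params,
        "ws_nor": ws_nor,
        "ws_pv": ws_pv,
        "peaks_nor": call_peaks(ws_nor, params),
        "peaks_pv": call_peaks(ws_pv, params),
    }


def ks_enumeration_oracle(window, background):
    """Brute-force permutation-null one-sided KS, independent of the package.

    Enumerates all C(m+n, m) window/background label assignments of the
    pooled values and returns (D_obs, P(D >= D_obs)).
    """
    import itertools
    from math import comb

    pooled = list(window) + list(background)
    m, n = len(window), len(background)

    def d_num(widx):
        wset = set(widx)
        win = [pooled[i] for i in widx]
        bg = [pooled[i] for i in range(m + n) if i not in wset]
        best = 0
        for v in sorted(set(pooled)):
            bg_le = sum(1 for x in bg if x <= v)
            win_le = sum(1 for x in win if x <= v)
            best = max(best, bg_le * m - win_le * n)
        return max(best, 0)

    d_obs = d_num(range(m))
    count = sum(
        1 for c in itertools.combinations(range(m + n), m) if d_num(c) >= d_obs
    )
    return d_obs / (m * n), count / comb(m + n, m)


@pytest.fixture(scope="session")
def oracle():
    return ks_enumeration_oracle
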