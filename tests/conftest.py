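import numpy as np
import pytest

from dosechrom.dose_response import DoseSeries


@pytest.fixture
def hill_series():
    """Factory for noiseless Hill dose series on the default titration design."""

    def make(e, h, a_min=0.0, a_max=1.0, doses=(100.0, 60.0, 30.0, 12.0, 0.0), reps=4):
        d = np.repeat(doses, reps).astype(float)
        g = np.where(d == 0, 0.0, d**h / (d**h + e**h))
        v = a_min + (a_max - a_min) * g
        return DoseSeries("toy", d, v, np.ones_like(d, dtype=bool))

    return make


@pytest.fixture(scope="session")
def track_benchmark():
    """Default synthetic track set (200 regions) with planted-motif truth."""
    from dosechrom.simulate import (SimTrackConfig, cwm_from_pwm,
                                    simulate_contribution_tracks)

    cfg = SimTrackConfig(n_regions=200, seed=11)
    tracks, truth = simulate_contribution_tracks(cfg)
    cwms = [cwm_from_pwm(p, cls, amp) for p, cls, amp in cfg.motif_library]
    return cfg, tracks, truth, cwms


def match_counts(instances, truth):
    """True positives: called instance overlaps >= half of a same-motif truth row."""
    tset: dict = {}
    for _, r in truth.iterrows():
        tset.setdefault((r.region_id, r.motif_id), []).append((r.start, r.end))
    matched = set()
    tp = 0
    for inst in instances:
        for k, (s, e) in enumerate(tset.get((inst.region_id, inst.cwm_id), [])):
            key = (inst.region_id, inst.cwm_id, k)
            if min(e, inst.end) - max(s, inst.start) >= (e - s) // 2 and key not in matched:
                matched.add(key)
                tp += 1
                break
    return tp
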