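import numpy as np
import pytest

import smsbs as s


def truth_sources(sim, reads):
    """Map read_id -> synthesis track for reads whose anchor is a molecule."""
    pos_of = {
        (m.fov_id, int(np.round(m.x)), int(np.round(m.y))): m for m in sim.molecules
    }
    out = {}
    for r in reads:
        m = pos_of.get((r.fov_id, r.x_px, r.y_px))
        if m is not None:
            out[r.read_id] = m
    return out


def reads_from_truth(sim):
    """Build ideal CalledReads straight from the simulator's event logs
    (no registration/assignment), for analytics tests that only need the
    chemistry-level ground truth."""
    reads = []
    for m in sim.molecules:
        prov = [(e.quad, e.flow) for e in m.event_log if e.detected]
        reads.append(
            s.CalledRead(
                anchor_id=m.molecule_id,
                fov_id=m.fov_id,
                x_px=int(np.round(m.x)),
                y_px=int(np.round(m.y)),
                seq=m.true_read,
                base_provenance=prov,
                stopped_at_quad=prov[-1][0] if prov else 0,
            )
        )
    return reads


@pytest.fixture(scope="session")
def clean_run():
    """Noise-free run with planted drift: 1 FOV, 60 molecules, 12 quads."""
    refs = s.make_barcode_library(10, 25, seed=5)
    cfg = s.RunConfig(
        n_fovs=1, density=60, n_quads=12, p_pause=0, p_dark=0, p_mis=0,
        p_detach=0, p_cleavefail=0, nonspecific_rate=0,
        drift=s.DriftModel(max_abs_px=3), edge_margin_px=4, seed=17,
    )
    return s.simulate_run(cfg, refs), refs


@pytest.fixture(scope="session")
def noisy_run():
    """Run at benchmark error levels: 30 barcodes x 25 nt, 1,000 molecules,
    24 quads, drift +-2 px, 4% planted per-base error (2% mis + 2% dark)."""
    refs = s.make_barcode_library(30, 25, seed=11)
    cfg = s.RunConfig(
        n_fovs=4, density=250, n_quads=24, p_pause=0.10, p_dark=0.02,
        p_mis=0.02, p_detach=0.04, p_cleavefail=0.01, nonspecific_rate=5,
        drift=s.DriftModel(max_abs_px=2), seed=42,
    )
    return s.simulate_run(cfg, refs), refs


@pytest.fixture(scope="session")
def noisy_pipeline(noisy_run):
    """The noisy run pushed through register -> basecall -> filter."""
    sim, refs = noisy_run
    anchors = s.anchors_from_spots(sim.spots)
    corrected, drift = s.correct_run(sim.spots, anchors)
    assignments = s.assign_spots(corrected, anchors)
    reads = s.call_reads(assignments, sim.schedule, anchors)
    kept, removed = s.filter_reads(reads, 5)
    return {
        "sim": sim,
        "refs": refs,
        "anchors": anchors,
        "corrected": corrected,
        "drift": drift,
        "reads": reads,
        "kept": kept,
        "removed": removed,
    }
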