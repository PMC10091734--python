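"""Shared fixtures: protocols, schedules, and the four-protocol SNR study.

The SNR study reconstructs matched synthetic acquisitions of the same
digital phantom under all four protocol/flip-angle combinations (plus a
2x angularly undersampled time-encoded scan and a single-average
sequential scan) at the package's frozen study conditions, and is shared
session-wide because the component k-space synthesis dominates its cost.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import teangio as tg
from teangio import phantom as ph

# frozen study conditions (see docs/methods.md)
STUDY = dict(
    matrix=96,
    n_coils=8,
    segments=13,
    undersampled_segments=7,
    vessel_radius_px=1.2,
    arrival_times=(0.30, 0.55, 0.80),
    noise_sd=0.08,
    b0_drift_rate=0.01,
    phantom_seed=7,
)


@pytest.fixture(scope="session")
def seq_protocol():
    return tg.build_protocol("seq-ll")


@pytest.fixture(scope="session")
def tenc_protocol():
    return tg.build_protocol("tenc-ll")


@pytest.fixture(scope="session")
def vfa108():
    return tg.vfa_schedule(108, np.radians(30.0))


@pytest.fixture(scope="session")
def vfa36():
    return tg.vfa_schedule(36, np.radians(30.0))


@pytest.fixture(scope="session")
def cfa108():
    return tg.cfa_schedule(108)


@pytest.fixture(scope="session")
def cfa36():
    return tg.cfa_schedule(36)


@pytest.fixture(scope="session")
def snr_study(seq_protocol, tenc_protocol, vfa108, vfa36, cfa108, cfa36):
    """Reconstructed series and SNR reports for the matched protocol study."""
    m = STUDY["matrix"]
    phantom = ph.make_phantom(
        ph.PhantomConfig(
            matrix=m,
            vessel_radius_px=STUDY["vessel_radius_px"],
            arrival_times=STUDY["arrival_times"],
        ),
        seed=STUDY["phantom_seed"],
    )
    traj = ph.radial_trajectory(12 * STUDY["segments"], m)
    maps = ph.make_coil_maps(m, STUDY["n_coils"])
    cache = ph.component_kspace_cache(phantom, traj, maps, dtype=np.complex64)

    schedules = {
        ("seq-ll", "cfa"): cfa108,
        ("seq-ll", "vfa"): vfa108,
        ("tenc-ll", "cfa"): cfa36,
        ("tenc-ll", "vfa"): vfa36,
    }
    protocols = {"seq-ll": seq_protocol, "tenc-ll": tenc_protocol}

    def scan(proto_name, scheme, n_averages, kcache, trajectory, seed):
        return ph.synthesize_kspace(
            phantom,
            protocols[proto_name],
            schedules[(proto_name, scheme)],
            trajectory,
            coil_maps=maps,
            component_kspace=kcache,
            n_averages=n_averages,
            noise_sd=STUDY["noise_sd"],
            b0_drift_rate=STUDY["b0_drift_rate"],
            seed=seed,
            dtype=np.complex64,
        )

    series = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, key in enumerate(schedules):
            proto_name, scheme = key
            n_avg = 2 if proto_name == "seq-ll" else 1  # scan-time matching
            series[key] = tg.reconstruct_series(
                scan(proto_name, scheme, n_avg, cache, traj, seed=100 + i)
            )
        keep = np.arange(STUDY["undersampled_segments"])
        traj_u = traj.subset(keep)
        cache_u = cache[:, np.isin(traj.segment_of_spoke, keep)]
        series["tenc-vfa-undersampled"] = tg.reconstruct_series(
            scan("tenc-ll", "vfa", 1, cache_u, traj_u, seed=200)
        )
        series["seq-vfa-1avg"] = tg.reconstruct_series(
            scan("seq-ll", "vfa", 1, cache, traj, seed=201)
        )

    temporal_mean = np.mean(
        [series[k].images.mean(axis=0) for k in schedules], axis=0
    )
    vmask = tg.vessel_mask(temporal_mean, phantom.brain_mask)
    rois = tg.corner_noise_rois((m, m), phantom.brain_mask)
    snr = {k: tg.compute_snr(s, vmask, rois) for k, s in series.items()}
    return dict(
        phantom=phantom,
        series=series,
        vessel_mask=vmask,
        noise_rois=rois,
        snr={k: r.snr for k, r in snr.items()},
        reports=snr,
        temporal_mean=temporal_mean,
    )
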