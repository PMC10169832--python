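"""Shared fixtures: small phantom subjects reused across the suite."""

import numpy as np
import pytest

from octacov.covmap import compute_cov_map
from octacov.phantom import TemporalModel, generate_phantom, simulate_sequence
from octacov.registration import FrameSequence, upscale


@pytest.fixture(scope="session")
def small_phantom():
    return generate_phantom(
        (160, 160), n_arterioles=4, n_venules=4, faz_radius=18, seed=7
    )


@pytest.fixture(scope="session")
def small_sequence(small_phantom):
    seq, true_cov = simulate_sequence(
        small_phantom, TemporalModel(n_frames=12, rng_seed=11)
    )
    return seq, true_cov


@pytest.fixture(scope="session")
def small_cov(small_sequence):
    seq, _ = small_sequence
    return compute_cov_map(seq)


@pytest.fixture(scope="session")
def small_mean_frame(small_sequence):
    seq, _ = small_sequence
    return seq.frames.mean(axis=0)


@pytest.fixture(scope="session")
def upscaled_sequence(small_sequence):
    seq, _ = small_sequence
    up = FrameSequence.from_frames(
        np.stack([upscale(f, 2) for f in seq.frames]), aligned=True
    )
    up.upscale_factor = 2
    return up


def upscale_mask(mask, factor):
    return np.kron(np.asarray(mask, bool), np.ones((factor, factor), bool))


@pytest.fixture(scope="session")
def upscaled_roi_truth(small_phantom):
    from octacov.roi import build_roi_set

    roi = small_phantom.roi_truth
    primaries = {
        n: upscale_mask(roi.masks[n], 2)
        for n in roi.masks
        if not n.endswith("-net") and not n.startswith("Q") and n != "F-cp"
    }
    return build_roi_set(
        {n: m for n, m in primaries.items() if n.startswith("a")},
        {n: m for n, m in primaries.items() if n.startswith("v")},
        upscale_mask(roi.faz_mask, 2),
        foveola_centre=tuple(2 * c for c in small_phantom.fovea_centre),
    )
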