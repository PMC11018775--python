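import numpy as np
import pytest

from condquant import synthgen


@pytest.fixture(scope="session")
def default_optics():
    return synthgen.OpticsConfig()


@pytest.fixture(scope="session")
def quiet_noise():
    """Low-noise camera model for recovery-style tests."""
    return synthgen.NoiseConfig(read_noise_sd=1.0, background_level=50.0)


@pytest.fixture(scope="session")
def fish_scene():
    """One mid-density FISH scene shared by read-only tests."""
    return synthgen.make_fish_scene(12, 60, 0.5, seed=42, shape_yx=(300, 300))


def analyse_fish_scene(stack):
    """Full detection pipeline on a generated scene: returns (spots, condensates)."""
    from condquant import puncta

    fish = stack.channel("fish")
    cond = stack.channel("cond")
    per_plane = []
    for z in range(fish.shape[0]):
        cand = puncta.detect_spots(fish[z])
        per_plane.append(
            [s for s in puncta.localize_gaussian(fish[z], cand, z_index=z) if s.fit_ok])
    spots = puncta.assign_z(per_plane)
    regs = [puncta.segment_condensates(cond[z], z_index=z) for z in range(cond.shape[0])]
    condensates = puncta.collapse_regions_z(regs)
    return spots, condensates


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
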