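import numpy as np
import pytest

from cdakit import phantom as ph


@pytest.fixture(scope="session")
def model():
    return ph.default_model()


@pytest.fixture(scope="session")
def wedge():
    return ph.default_wedge()


@pytest.fixture(scope="session")
def small_wedge():
    return ph.default_wedge((128, 128))


@pytest.fixture(scope="session")
def knee():
    return ph.default_knee()


@pytest.fixture(scope="session")
def clean_render_50(model, wedge, knee):
    """Noisy render of the default scene at 50 kV; 1.2 mAs."""
    return ph.render_radiograph(wedge, knee, ph.STUDY_PRESETS[0], model, seed=101)


@pytest.fixture(scope="session")
def noise_free_renders(model, wedge, knee):
    """Noise-free renders of the default scene at all five presets."""
    return {
        preset.label: ph.render_radiograph(
            wedge, knee, preset, model, seed=0, noise=False
        )
        for preset in ph.STUDY_PRESETS
    }


@pytest.fixture(scope="session")
def study():
    """The full synthetic cohort: nine limbs, five presets, default clutter."""
    from cdakit.cohort import run_study

    return run_study(seed=7)


def random_palette_image(rng, shape=(40, 50), extra_colors=3):
    """RGB image mixing palette colors, perturbed colors and black."""
    from cdakit.decomposition import TABLE1_PALETTE, hex_to_rgb

    pool = [hex_to_rgb(c) for c in TABLE1_PALETTE.step_colors.values()]
    pool += [hex_to_rgb(TABLE1_PALETTE.white), (0, 0, 0), (64, 64, 64)]
    pool += [tuple(rng.integers(0, 256, 3).tolist()) for _ in range(extra_colors)]
    idx = rng.integers(0, len(pool), size=shape)
    return np.array(pool, dtype=np.uint8)[idx]
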