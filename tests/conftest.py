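import numpy as np
import pytest

import pamvasc as pv


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def pitch_512():
    """Instrument-like pitch: 2 mm field over 512 px."""
    return 2000.0 / 512.0


@pytest.fixture
def quiet_spec():
    """Empty-scene phantom spec (background + noise only)."""
    return pv.PhantomSpec(
        n_trees=0, noise_sigma=5.0, background_level=50.0, psf_fwhm_um=0.0, seed=7
    )


def straight_tube(diameter_um, length_um=1000.0, angle_deg=0.0, center=(1000.0, 1000.0)):
    """Centerline of a straight tube through ``center`` at the given angle."""
    import math

    a = math.radians(angle_deg)
    d = np.array([math.sin(a), math.cos(a)])
    c0 = np.asarray(center) - 0.5 * length_um * d
    pts = c0 + np.linspace(0.0, length_um, 200)[:, None] * d
    return pv.Centerline(pts, np.full(200, diameter_um))


@pytest.fixture
def make_tube_phantom():
    """Factory: render straight-tube scenes with exact truth."""

    def _make(diameters, angles=None, psf_fwhm_um=0.0, noise_sigma=0.0, seed=1, **kw):
        from pamvasc.phantom import phantom_from_centerlines

        angles = angles or [0.0] * len(diameters)
        spec = pv.PhantomSpec(
            n_trees=0,
            psf_fwhm_um=psf_fwhm_um,
            noise_sigma=noise_sigma,
            background_level=20.0,
            seed=seed,
            **kw,
        )
        offsets = np.linspace(400.0, 1600.0, len(diameters))
        cls = [
            straight_tube(d, angle_deg=a, center=(off, 1000.0))
            for d, a, off in zip(diameters, angles, offsets)
        ]
        return phantom_from_centerlines(spec, cls)

    return _make
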