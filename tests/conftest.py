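import math

import numpy as np
import pytest

from terrafoci import foci3d, synthetic_data as sd


@pytest.fixture(scope="session")
def small_stack():
    """One ~2.8 µm nucleus with 5 well-separated SNR-10 foci plus truth tables."""
    stack, nuclei, truth, clean = sd.generate_nuclei_stack(
        1,
        shape=(36, 120, 120),
        radius_range=(2.8, 2.9),
        foci_per_channel={"terra": {"n": 5, "amplitude": 100.0}},
        noise_sd=10.0,
        seed=42,
        return_clean=True,
    )
    return stack, nuclei, truth, clean


def make_focus(focus_id, nucleus_id, centroid, radius=0.2, channel="terra",
               integrated_density=100.0, volume=None, average_intensity=10.0):
    """Hand-built measured Focus for colocalization tests."""
    if volume is None:
        volume = 4.0 / 3.0 * math.pi * radius**3
    return foci3d.Focus(
        focus_id=focus_id, nucleus_id=nucleus_id, channel=channel,
        centroid=tuple(centroid), volume=volume,
        integrated_density=integrated_density, average_intensity=average_intensity,
        compartment="nuclear" if nucleus_id is not None else "cytoplasmic",
    )


def uniform_point_in_sphere(center, radius, rng):
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    return np.asarray(center) + v * radius * rng.uniform() ** (1.0 / 3.0)
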