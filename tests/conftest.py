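import numpy as np
import pytest

from pelletpop import AlignedLocus, LandmarkConfiguration


@pytest.fixture
def tiny_locus():
    """Three diploid individuals, 10 bp, one heterozygote."""
    return AlignedLocus(
        locus_name="intronA",
        alleles={
            "s1": ("ACGTACGTAC", "ACGTACGTAC"),
            "s2": ("ACGTACGTAC", "ACGTTCGTAC"),
            "s3": ("ACGTTCGTAC", "ACGTTCGTAC"),
        },
    )


@pytest.fixture
def unit_square_config():
    pts = np.full((4, 2), np.nan)
    pts[:] = [(0, 0), (1, 0), (1, 1), (0, 1)]
    return LandmarkConfiguration(sample_id="sq", points=pts, scale=1.0)


def make_config(sample_id, points, scale=1.0, n_landmarks=16):
    """Full 16-landmark configuration from a short point list padded by a ring."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < n_landmarks:
        t = np.linspace(0, 2 * np.pi, n_landmarks - len(pts), endpoint=False)
        ring = np.c_[3 * np.cos(t), 3 * np.sin(t)] + 10.0
        pts = np.vstack([pts, ring])
    return LandmarkConfiguration(sample_id=sample_id, points=pts, scale=scale)
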