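import numpy as np
import pytest
from hypothesis import settings

from omegaqpcr import (
    MarkerLadder,
    ProbeGeometry,
    default_probe,
    fit_marker_curve,
)
from omegaqpcr.trf_densitometry import DEFAULT_LADDER_KBP

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

# Table-printed worked-example constants used across the suite
PROBE_88MER = (
    "AACCCTAACCCTAACCCCGCGCTAGACTAAGCGCTCCAGTGACTCAGCAGCTACCCG"
    "GCAACTAGATGCCGCCCCTAACCCTAACCCT"
)
ORF_88MER = (
    "CAGTGACTCAGCAGCTACCCGGCAACTAGATGCCGCCCCTAACC"
    "CTAACCCTAACCCTAACCCTAACCCCGCGCTAGACTAAGCGCTC"
)


@pytest.fixture(scope="session")
def probe():
    return default_probe()


@pytest.fixture(scope="session")
def geometry():
    return ProbeGeometry()


@pytest.fixture(scope="session")
def marker_curve():
    """Exactly log-linear default ladder positions and the fitted curve."""
    positions = [100.0 - 40.0 * np.log10(L) for L in DEFAULT_LADDER_KBP]
    ladder = MarkerLadder(entries=tuple(zip(DEFAULT_LADDER_KBP, positions)))
    return ladder, fit_marker_curve(ladder)
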