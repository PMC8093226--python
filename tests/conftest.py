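"""Shared fixtures: small synthetic regions and cohorts, generated at
test time (no stored data)."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "scripts"))

from tests_helpers import build_region  # noqa: E402

from histotyping.synthetic_data import render_region  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def clean_render():
    """A clean rendered region (no boundary noise) with its truth mask."""
    ls = build_region(seed=3, n_glands=20, canvas=512.0)
    rng = np.random.default_rng(3)
    img, mask = render_region(ls.lumens, (512, 512), 1.0, rng=rng)
    return img, mask, ls


@pytest.fixture(scope="session")
def mixed_region():
    """A mixed-shape noisy region for descriptor-level tests."""
    return build_region(seed=7, n_glands=16, canvas=448.0, mixed=True,
                        boundary_noise=0.06)
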