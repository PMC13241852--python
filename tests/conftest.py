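"""Shared fixtures: small synthetic bundles, slides and bag cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from ibdmil.synthetic import BagSpec, BundleSpec, GlandSpec, gen_bags, gen_bundle
from ibdmil.vocab import default_vocabulary


@pytest.fixture(scope="session")
def vocab():
    return default_vocabulary()


@pytest.fixture(scope="session")
def standard_bundle():
    """A 256-px bundle with known composition, glands and nuclei."""
    spec = BundleSpec(
        tile_size=256,
        composition={"stroma": 0.4, "normal_epithelium": 0.2, "inflammatory": 0.1},
        glands=GlandSpec(count=3, shape="disc", size=12),
        nuclei={"lymphocyte": (8, "stroma"), "neutrophil": (3, "inflammatory"),
                "epithelial": (5, "normal_epithelium")},
        surface_rows=10,
    )
    return gen_bundle(spec, seed=42)


@pytest.fixture(scope="session")
def small_cohort():
    """A small 3-class bag cohort with planted signal instances."""
    spec = BagSpec(n_classes=3, n_per_class=12, bag_size=(8, 15), signal_rate=0.2, dim=16)
    return gen_bags(spec, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
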