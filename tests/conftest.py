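"""Shared fixtures: small deterministic synthetic worlds, reused across
test modules (session-scoped where generation is not free)."""

from __future__ import annotations

import numpy as np
import pytest

from cyclehic import contacts as ct
from cyclehic.genome import BinTable, ChromSizes
from cyclehic.simulate import SyntheticSpec, demo_spec, generate

LOOP_ANCHORS = [(10, 50), (90, 150), (170, 230), (250, 330), (350, 410), (430, 470)]
INTER_ANCHORS = [(30, 70), (110, 190), (210, 270), (290, 370), (390, 450)]


def loop_world_spec(fold: float = 5.0, seed: int = 0, **kw) -> SyntheticSpec:
    loops = [(c, a, b, fold) for c in ("chr1", "chrX") for a, b in LOOP_ANCHORS]
    return SyntheticSpec(loops=loops, seed=seed, **kw)


def interaction_world_spec(fold: float = 5.0, seed: int = 0, **kw) -> SyntheticSpec:
    inters = [(c, a, b, fold) for c in ("chr1", "chrX") for a, b in INTER_ANCHORS]
    return SyntheticSpec(interactions=inters, seed=seed, **kw)


def combined(ds, cond: str) -> ct.ContactMap:
    """Replicates of one condition summed into the analysis map."""
    return ct.sum_maps(ds.maps[cond])


@pytest.fixture(scope="session")
def tiny_bins() -> BinTable:
    sizes = ChromSizes([("chr1", 500_000), ("chrX", 400_000)])
    return BinTable(sizes, 10_000)


@pytest.fixture(scope="session")
def demo_ds():
    """The standard three-group demo dataset (Die/Pro/Male)."""
    return generate(demo_spec(seed=1))


@pytest.fixture(scope="session")
def loop_ds():
    """Loops-only world, fold 5, three replicates."""
    return generate(loop_world_spec(seed=0))


@pytest.fixture(scope="session")
def loop_analysis(loop_ds):
    """Combined condition-A map of the loop world, balanced + normalised."""
    m = combined(loop_ds, "A")
    balanced, expected, z = ct.prepare(m)
    return {"raw": m, "balanced": balanced, "expected": expected, "z": z}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
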