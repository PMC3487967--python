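import numpy as np
import pytest

from abmtki import signaling as sig
from abmtki.config import SimConfig, small_test_config


@pytest.fixture(scope="session")
def default_spec() -> sig.PathwaySpec:
    return sig.default_pathway()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_config() -> SimConfig:
    """10x10 lattice, a couple of cells: fast enough for per-step tests."""
    return small_test_config(
        lattice_size=12,
        horizon=5.0,
        tumor={"n_cells": 2, "cluster_radius": 2, "center": (0.6, 0.5)},
        vessels={"column": 1, "n_tips": 2},
    )


class ScriptedRng:
    """Deterministic stand-in for a Generator: replays scripted draws."""

    def __init__(self, normals=(), uniforms=()):
        self._normals = list(normals)
        self._uniforms = list(uniforms)

    def standard_normal(self):
        return self._normals.pop(0)

    def uniform(self, *args, **kwargs):
        return self._uniforms.pop(0)


@pytest.fixture()
def scripted_rng():
    return ScriptedRng
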