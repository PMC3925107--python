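from dataclasses import replace
from importlib.resources import files

import pytest

import habtile as h

EXAMPLES = files("habtile") / "examples"


@pytest.fixture(scope="session")
def simple_spec() -> h.TileSpec:
    """Packaged 'simple' seawall tile: fixed 32 mm square pits, ordered grid."""
    return h.read_spec(EXAMPLES / "simple_tile.yaml")


@pytest.fixture(scope="session")
def complex_spec() -> h.TileSpec:
    """Packaged 'complex' tile: 8-56 mm lattice pits, random arrangement."""
    return h.read_spec(EXAMPLES / "complex_tile.yaml")


def make_spec(
    k: int = 1,
    n: int = 4,
    tile: float = 100.0,
    footprint=None,
    depth=None,
    shape: str = "circle",
    arrangement: str = "random",
    buffer: float = 0.0,
    seed: int = 0,
    abundances="uniform",
) -> h.TileSpec:
    """Small factory for ad-hoc specs in tests."""
    footprint = footprint or h.SizeDistribution.fixed(8.0)
    depth = depth or h.SizeDistribution.fixed(4.0)
    types = tuple(
        h.ObjectTypeSpec(f"t{i}", colour=f"#00000{i}", footprint=footprint,
                         depth=depth, shape=shape)
        for i in range(k))
    if abundances == "uniform":
        abundances = tuple(1.0 / k for _ in range(k))
    return h.TileSpec(tile_width=tile, tile_length=tile, object_types=types,
                      total_count=n, arrangement=arrangement, buffer=buffer,
                      seed=seed, abundances=abundances)


def with_seed(spec: h.TileSpec, seed: int) -> h.TileSpec:
    return replace(spec, seed=seed)
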