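import numpy as np
import pytest

from paleosdm.grids import EnvSample, EnvStack, GridSpec, Occurrence, OccurrenceSet, Raster


@pytest.fixture
def small_spec():
    return GridSpec(n_rows=4, n_cols=5, x_origin=-60.0, y_origin=2.0, cell_size=0.5)


@pytest.fixture
def small_stack(small_spec):
    """4x5 two-layer stack with one masked (ocean) cell at (1, 2)."""
    rng = np.random.default_rng(7)
    a = rng.uniform(0, 100, size=(4, 5))
    b = rng.uniform(-10, 10, size=(4, 5))
    a[1, 2] = small_spec.nodata_value
    return EnvStack(
        [Raster(small_spec, a, "alpha"), Raster(small_spec, b, "beta")],
        scenario_name="current",
    )


def random_stack(n_rows, n_cols, n_layers, seed, mask_fraction=0.1):
    """Random stack on a unit-degree grid, a few cells masked."""
    rng = np.random.default_rng(seed)
    spec = GridSpec(n_rows, n_cols, x_origin=-50.0, y_origin=5.0, cell_size=0.25)
    layers = []
    mask = rng.uniform(size=(n_rows, n_cols)) < mask_fraction
    for i in range(n_layers):
        vals = rng.normal(50 * (i + 1), 10, size=(n_rows, n_cols))
        vals[mask] = spec.nodata_value
        layers.append(Raster(spec, vals, f"var{i}"))
    return EnvStack(layers, scenario_name="random")


def random_env_sample(n_points, variable_names, seed, scale=100.0):
    rng = np.random.default_rng(seed)
    return EnvSample(
        point_ids=list(range(n_points)),
        matrix=rng.uniform(0, scale, size=(n_points, len(variable_names))),
        variable_names=list(variable_names),
    )


def occurrences_at(points, species="test"):
    return OccurrenceSet(
        species=species, records=[Occurrence(lon, lat) for lon, lat in points]
    )
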