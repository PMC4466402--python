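"""Virtual-species data: synthetic climate scenarios and presence-only sampling.

The generator emulates the statistical structure a presence-only
paleodistribution analysis assumes, with known ground truth so that every
downstream stage (environmental filtering, envelope and maximum-entropy
models, hindcasting, host-coupled sampling) can be validated by parameter
recovery instead of against unavailable climate archives.

Each climate layer is a smooth field: a linear spatial trend (distinct
direction per variable) plus moving-average-smoothed white noise, over a
bounded grid with a contiguous "ocean" nodata mask. Past scenarios are
additive shifts of the present fields — the qualitative glacial-vs-modern
contrast with a controllable effect size. True niches are independent
Gaussian (bell) responses per variable; a cleptoparasite can be coupled to
its host by multiplying its climatic suitability by host suitability raised
to a coupling power.

Default units follow the WorldClim raw-integer conventions used throughout
the package: temperature seasonality as standard deviation x 100, quarter
temperatures as deg C x 10, quarter precipitation in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import EnvStack, GridSpec, Occurrence, OccurrenceSet, Raster

__all__ = [
    "ClimateSimConfig",
    "TrueNiche",
    "BioticCoupling",
    "generate_scenarios",
    "true_suitability",
    "sample_occurrences",
    "sample_host_parasite",
]

#: Trend/noise defaults per variable, in raw layer units. Trend magnitudes are
#: the total change across the grid along (north-south, east-west); seasonality
#: grows away from the equator (southward here), rainfall declines eastward.
_DEFAULT_FIELD_PARAMS: dict[str, dict[str, float | tuple[float, float]]] = {
    "bio4": {"base": 2600.0, "trend": (3200.0, 400.0), "noise": 300.0},
    "bio8": {"base": 240.0, "trend": (-60.0, 20.0), "noise": 15.0},
    "bio9": {"base": 220.0, "trend": (-90.0, -30.0), "noise": 20.0},
    "bio16": {"base": 1600.0, "trend": (200.0, -1600.0), "noise": 220.0},
    "bio17": {"base": 420.0, "trend": (-60.0, -300.0), "noise": 60.0},
}

#: Glacial shifts per circulation-model stand-in: cooler, drier, more seasonal.
_DEFAULT_LGM_OFFSETS: dict[str, dict[str, float]] = {
    "lgm_ccsm": {"bio4": 250.0, "bio8": -25.0, "bio9": -30.0, "bio16": -200.0, "bio17": -60.0},
    "lgm_miroc": {"bio4": 160.0, "bio8": -15.0, "bio9": -20.0, "bio16": -130.0, "bio17": -40.0},
}


@dataclass
class ClimateSimConfig:
    """Configuration for one synthetic climate-scenario set.

    ``gradient_strengths`` maps variable name -> (north-south, east-west)
    trend magnitude in layer units across the whole grid; ``lgm_offsets``
    maps past-scenario name -> per-variable additive shift. ``noise_scale``
    is the moving-average smoothing radius in cells; ``mask_fraction`` is the
    share of cells masked as ocean.
    """

    grid: GridSpec = field(
        default_factory=lambda: GridSpec(
            n_rows=100, n_cols=100, x_origin=-80.0, y_origin=10.0, cell_size=0.5
        )
    )
    variable_names: tuple[str, ...] = ("bio4", "bio8", "bio9", "bio16", "bio17")
    base_levels: dict[str, float] | None = None
    gradient_strengths: dict[str, tuple[float, float]] | None = None
    noise_amplitudes: dict[str, float] | None = None
    noise_scale: int = 3
    lgm_offsets: dict[str, dict[str, float]] | None = None
    mask_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mask_fraction < 1.0):
            raise ValueError("mask_fraction must be in [0, 1)")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if self.base_levels is None:
            self.base_levels = {
                v: float(_DEFAULT_FIELD_PARAMS.get(v, {"base": 0.0})["base"])
                for v in self.variable_names
            }
        if self.gradient_strengths is None:
            self.gradient_strengths = {
                v: tuple(_DEFAULT_FIELD_PARAMS.get(v, {"trend": (1.0, 0.0)})["trend"])  # type: ignore[arg-type]
                for v in self.variable_names
            }
        if self.noise_amplitudes is None:
            self.noise_amplitudes = {
                v: float(_DEFAULT_FIELD_PARAMS.get(v, {"noise": 0.1})["noise"])
                for v in self.variable_names
            }
        if self.lgm_offsets is None:
            self.lgm_offsets = {
                name: {v: offs.get(v, 0.0) for v in self.variable_names}
                for name, offs in _DEFAULT_LGM_OFFSETS.items()
            }


@dataclass(frozen=True)
class TrueNiche:
    """Ground-truth Gaussian niche: per-variable optimum and tolerance.

    Suitability at environment x is
    ``max_suitability * prod_v exp(-0.5 ((x_v - optimum_v) / breadth_v)^2)``.
    Variables absent from ``optima`` do not constrain the species (decoys).
    """

    optima: dict[str, float]
    breadths: dict[str, float]
    max_suitability: float = 1.0

    def __post_init__(self) -> None:
        if set(self.optima) != set(self.breadths):
            raise ValueError("optima and breadths must cover the same variables")
        if any(b <= 0 for b in self.breadths.values()):
            raise ValueError("breadths must be positive")
        if not (0.0 < self.max_suitability <= 1.0):
            raise ValueError("max_suitability must be in (0, 1]")

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.optima)


@dataclass(frozen=True)
class BioticCoupling:
    """Host-parasite link: parasite suitability is scaled by host suitability
    raised to ``coupling_strength`` (0 = climate-only parasite)."""

    host_niche: TrueNiche
    parasite_niche: TrueNiche
    coupling_strength: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.coupling_strength <= 1.0):
            raise ValueError("coupling_strength must be in [0, 1]")


def _smooth_field(shape: tuple[int, int], radius: int,
                  generator: np.random.Generator) -> np.ndarray:
    noise = generator.standard_normal(shape)
    if radius > 0:
        size = 2 * radius + 1
        noise = ndimage.uniform_filter(noise, size=size, mode="nearest")
        # moving average shrinks the variance; restore unit scale
        noise /= noise.std() if noise.std() > 0 else 1.0
    return noise


def _ocean_mask(grid: GridSpec, mask_fraction: float,
                generator: np.random.Generator) -> np.ndarray:
    """Boolean 'is ocean' array with approximately the requested fraction,
    contiguous-ish thanks to smoothing."""
    if mask_fraction == 0.0:
        return np.zeros((grid.n_rows, grid.n_cols), dtype=bool)
    fld = ndimage.uniform_filter(
        generator.standard_normal((grid.n_rows, grid.n_cols)), size=7, mode="nearest"
    )
    cutoff = np.quantile(fld, mask_fraction)
    return fld < cutoff


def generate_scenarios(cfg: ClimateSimConfig) -> dict[str, EnvStack]:
    """Generate the "current" stack plus one past stack per LGM offset vector.

    All scenarios share one ocean mask; past layers are the current layers
    plus their configured additive offsets. Bit-reproducible from the config
    (including its seed).
    """
    grid = cfg.grid
    if grid.n_rows < 4 or grid.n_cols < 4:
        raise ValueError("grid too small for a meaningful landscape (need >= 4x4)")
    generator = np.random.default_rng(cfg.seed)
    ocean = _ocean_mask(grid, cfg.mask_fraction, generator)

    rows = np.linspace(0.0, 1.0, grid.n_rows)[:, None]  # 0 = north edge
    cols = np.linspace(0.0, 1.0, grid.n_cols)[None, :]  # 0 = west edge

    current_fields: dict[str, np.ndarray] = {}
    for var in cfg.variable_names:
        ns, ew = cfg.gradient_strengths[var]
        trend = cfg.base_levels[var] + ns * (rows - 0.5) + ew * (cols - 0.5)
        noise = _smooth_field((grid.n_rows, grid.n_cols), cfg.noise_scale, generator)
        current_fields[var] = trend + cfg.noise_amplitudes[var] * noise

    def build_stack(offsets: dict[str, float], name: str) -> EnvStack:
        layers = []
        for var in cfg.variable_names:
            vals = current_fields[var] + offsets.get(var, 0.0)
            vals = vals.copy()
            vals[ocean] = grid.nodata_value
            layers.append(Raster(grid, vals, var))
        return EnvStack(layers, scenario_name=name)

    scenarios = {"current": build_stack({}, "current")}
    for name, offsets in cfg.lgm_offsets.items():
        scenarios[name] = build_stack(offsets, name)
    return scenarios


def true_suitability(niche: TrueNiche, stack: EnvStack) -> Raster:
    """Evaluate the ground-truth niche on every valid cell of a scenario."""
    for var in niche.variables:
        if var not in stack.layer_names:
            raise KeyError(f"niche variable {var!r} missing from stack {stack.layer_names}")
    spec = stack.spec
    suit = np.full((spec.n_rows, spec.n_cols), float(niche.max_suitability))
    for var in niche.variables:
        x = stack.get(var).values
        z = (x - niche.optima[var]) / niche.breadths[var]
        suit *= np.exp(-0.5 * z**2)
    suit[~stack.valid_mask] = spec.nodata_value
    return Raster(spec, suit, name="true_suitability")


def sample_occurrences(
    suit: Raster,
    n: int,
    seed: int,
    bias: Raster | None = None,
    species: str = "virtual",
) -> OccurrenceSet:
    """Draw ``n`` presence points, cells with probability proportional to
    suitability x bias, position uniform within the drawn cell, with
    replacement. Masked cells are never drawn."""
    if n < 1:
        raise ValueError("n must be >= 1")
    weights = suit.values.copy()
    valid = suit.valid_mask
    if bias is not None:
        if not bias.spec.aligned_with(suit.spec):
            raise ValueError("bias raster not aligned with suitability raster")
        weights = weights * np.where(bias.valid_mask, bias.values, 0.0)
        valid &= bias.valid_mask
    weights[~valid] = 0.0
    if np.any(weights < 0):
        raise ValueError("sampling weights must be non-negative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("all sampling weights are zero; nothing to sample from")
    flat = weights.ravel() / total
    generator = np.random.default_rng(seed)
    drawn = generator.choice(flat.size, size=n, replace=True, p=flat)
    rows, cols = np.unravel_index(drawn, weights.shape)
    u = generator.uniform(0.0, 1.0, size=n)
    v = generator.uniform(0.0, 1.0, size=n)
    spec = suit.spec
    lons = spec.x_origin + (cols + u) * spec.cell_size
    lats = spec.y_origin - (rows + v) * spec.cell_size
    records = [
        Occurrence(float(lon), float(lat), source="synthetic")
        for lon, lat in zip(lons, lats)
    ]
    return OccurrenceSet(species=species, records=records, role="raw")


def sample_host_parasite(
    coupling: BioticCoupling,
    stack: EnvStack,
    n_host: int,
    n_parasite: int,
    seed: int,
    bias: Raster | None = None,
) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Sample host and parasite occurrences on one scenario.

    The host follows its own climatic suitability; the parasite follows
    (parasite climatic suitability) x (host suitability ** coupling_strength),
    so at coupling 0 the parasite draw is identical in law — and, for a fixed
    seed, identical in value — to climate-only sampling.
    """
    host_suit = true_suitability(coupling.host_niche, stack)
    para_clim = true_suitability(coupling.parasite_niche, stack)
    # 0**0 == 1 by numpy convention, which is exactly the uncoupled limit.
    combined_vals = np.where(
        para_clim.valid_mask,
        para_clim.values * np.power(np.clip(host_suit.values, 0.0, None),
                                    coupling.coupling_strength),
        para_clim.spec.nodata_value,
    )
    para_suit = Raster(para_clim.spec, combined_vals, name="parasite_suitability")
    host = sample_occurrences(host_suit, n_host, seed=seed, bias=bias, species="host")
    parasite = sample_occurrences(
        para_suit, n_parasite, seed=seed + 1, bias=bias, species="parasite"
    )
    return host, parasite
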