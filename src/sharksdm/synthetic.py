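"""Seeded synthetic study scenarios: bathymetry, environment, truth, sightings.

Real basking-shark sightings in the lower Bay of Fundy are unpublished survey
and whale-watch records, so the pipeline is exercised on generated scenarios
that carry the statistical structure the analysis assumes:

* a ~7.5·10³ km² coastal domain gridded at 2.5 × 2.5 km (6.25 km² cells),
  with a land margin along one coast, a monotone shelf and a >200 m basin so
  the 0/50/100/150/200 m isobaths all exist;
* smooth monthly chlorophyll-a (lognormal, 0.5–6 mg m⁻³ means) and SST
  (~8–16 °C, warmer in July than October) fields;
* a known true raw suitability surface — a Gibbs density over cells driven by
  distance-to-shore, distance to the 150/200 m contours, chlorophyll and SST,
  the variables the habitat model should find important;
* monthly presences of realistic size (default 90/554/221/19 individuals for
  July–October) drawn from truth × sampling effort, where effort can be
  spatially clustered near one coast to emulate whale-watch survey bias.

Everything is driven by a single integer seed; scenarios can be written to a
directory of ESRI ASCII rasters + CSV so the pipeline runs file-to-file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import (
    ENV_VARIABLES,
    MONTHS,
    EnvStack,
    Grid,
    distance_to_contour,
    slope_aspect,
    write_ascii_grid,
)
from .sightings import SightingTable

__all__ = [
    "ScenarioConfig",
    "Scenario",
    "DEFAULT_MONTHLY_N",
    "DEFAULT_TRUTH_COEFFS",
    "synth_bathymetry",
    "synth_env",
    "synth_effort",
    "synth_truth",
    "synth_sightings",
    "make_scenario",
]

#: Default per-month presence counts (July–October individuals).
DEFAULT_MONTHLY_N = {"July": 90, "August": 554, "September": 221, "October": 19}

#: True-suitability coefficients on [0,1]-scaled variables: habitat close to
#: shore-adjacent deep water (near the 150/200 m isobaths), productive and warm.
DEFAULT_TRUTH_COEFFS = {
    "dist_0": -2.0,
    "dist_150": -4.0,
    "dist_200": -2.0,
    "chl_a": 2.0,
    "sst": 1.5,
}

_MONTH_CHL_MEAN = {"July": 2.8, "August": 3.6, "September": 3.0, "October": 1.6}
_MONTH_SST_MEAN = {"July": 13.5, "August": 15.2, "September": 14.0, "October": 11.0}


@dataclass
class ScenarioConfig:
    rows: int = 36
    cols: int = 42
    cell_size: float = 2500.0
    months: tuple[str, ...] = MONTHS
    monthly_n: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_MONTHLY_N))
    coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUTH_COEFFS)
    )
    effort_bias: bool = True
    effort_strength: float = 3.0

    def __post_init__(self) -> None:
        if self.rows < 20 or self.cols < 20:
            raise ValueError("scenario grids must be at least 20x20")
        bad = [m for m in self.months if m not in MONTHS]
        if bad:
            raise ValueError(f"unknown months: {bad}")
        bad_n = {m: n for m, n in self.monthly_n.items() if n < 1}
        if bad_n:
            raise ValueError(f"monthly_n must be >= 1, got {bad_n}")
        unknown = set(self.coefficients) - set(ENV_VARIABLES)
        if unknown:
            raise ValueError(f"coefficients for unknown variables: {sorted(unknown)}")


@dataclass
class Scenario:
    stacks: dict[str, EnvStack]
    truths: dict[str, Grid]
    sightings: SightingTable
    effort: Grid | None
    seed: int
    config: ScenarioConfig


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Unit-variance smooth Gaussian random field."""
    z = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="nearest")
    s = z.std()
    return z / s if s > 0 else z


def synth_bathymetry(
    rows: int = 36, cols: int = 42, cell_size: float = 2500.0, seed: int = 0
) -> tuple[Grid, np.ndarray]:
    """Synthetic depth grid (m, positive down) and an analysis land mask.

    The field is a west-coast-to-east shelf: slightly negative (land) along
    the west margin rising monotonically past 200 m, plus seeded Gaussian
    bumps including a >200 m basin, so every isobath from 0 to 200 m exists.
    The returned grid is fully unmasked (terrain derivatives and contour
    distances need the land values); the boolean mask marks land cells plus a
    2-cell near-shore exclusion ring and is applied by the stack builder.
    """
    if rows < 20 or cols < 20:
        raise ValueError("synth_bathymetry needs rows, cols >= 20")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    jj = np.arange(cols) / (cols - 1)
    base = -30.0 + 300.0 * jj[None, :] ** 1.1
    base = np.repeat(base, rows, axis=0)

    bumps = 25.0 * _smooth_field(rng, (rows, cols), sigma=4.0)
    # a deep basin in the east-central part of the domain
    ii = np.arange(rows)[:, None] / (rows - 1)
    basin = 70.0 * np.exp(
        -(((jj[None, :] - 0.72) / 0.18) ** 2) - (((ii - 0.45) / 0.25) ** 2)
    )
    depth = base + bumps + basin

    grid = Grid(
        values=depth,
        mask=np.zeros((rows, cols), dtype=bool),
        x_origin=0.0,
        y_origin=0.0,
        cell_size=cell_size,
        crs_label="synthetic-utm-like",
    )
    land = depth <= 0.0
    excluded = ndimage.binary_dilation(land, iterations=2)
    return grid, excluded


def synth_env(depth: Grid, month: str, seed: int = 0) -> tuple[Grid, Grid]:
    """Monthly chlorophyll-a (mg m⁻³) and SST (°C) climatology fields.

    Chl-a is a lognormal smooth field whose mean follows a seasonal cycle
    (bloom-like peak in August, low in October) and which is slightly
    elevated over shallow water; SST is a smooth meridional gradient plus a
    seasonal offset, warmest in August and coldest in October.
    """
    if month not in MONTHS:
        raise ValueError(f"month must be one of {MONTHS}")
    midx = MONTHS.index(month)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202, midx]))
    shape = depth.shape

    shallow = np.clip(1.0 - depth.values / 250.0, 0.0, 1.5)
    z = _smooth_field(rng, shape, sigma=3.0)
    sigma_log = 0.35
    log_mu = np.log(_MONTH_CHL_MEAN[month]) - 0.5 * sigma_log**2
    chl = np.exp(log_mu + sigma_log * z + 0.25 * (shallow - shallow.mean()))

    ii = np.arange(shape[0])[:, None] / (shape[0] - 1)
    sst = (
        _MONTH_SST_MEAN[month]
        + 1.2 * (0.5 - ii)  # cooler toward the north edge (row 0)
        + 0.8 * _smooth_field(rng, shape, sigma=4.0)
    )
    sst = np.broadcast_to(sst, shape) if sst.shape != shape else sst
    return depth.like(chl, depth.mask.copy()), depth.like(np.array(sst), depth.mask.copy())


def synth_effort(template: Grid, seed: int = 0, strength: float = 3.0) -> Grid:
    """Sampling-effort field peaked near the western coast (a 'port').

    Effort decays with distance from a port located on the west margin at
    mid-latitude, emulating whale-watch trips concentrated near one harbour;
    a small uniform floor keeps all cells reachable (survey coverage).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    x, y = template.cell_centers()
    port_x = template.x_origin + 2.5 * template.cell_size
    port_y = template.y_origin + (0.5 + 0.1 * rng.uniform(-1, 1)) * template.nrows * template.cell_size
    scale = 0.25 * max(
        template.ncols * template.cell_size, template.nrows * template.cell_size
    )
    d = np.hypot(x - port_x, y - port_y)
    effort = np.exp(-strength * d / scale) + 0.02
    return template.like(effort, template.mask.copy())


def synth_truth(stack: EnvStack, coefficients: Mapping[str, float]) -> Grid:
    """True raw suitability: Gibbs density over unmasked cells.

    ``raw ∝ exp(Σ_v c_v · scaled(v))`` with each variable min–max scaled over
    unmasked cells; normalized to sum to 1.  Empty coefficients give the
    uniform distribution.
    """
    template = stack.template
    ok = ~stack.mask
    eta = np.zeros(template.shape)
    for var, coef in coefficients.items():
        if var not in stack.layers:
            raise ValueError(f"coefficient for variable {var!r} not in stack")
        v = stack.layers[var].values
        vals = v[ok]
        lo, hi = vals.min(), vals.max()
        if hi > lo:
            eta[ok] += coef * (v[ok] - lo) / (hi - lo)
    raw = np.zeros(template.shape)
    e = np.exp(eta[ok] - eta[ok].max())
    raw[ok] = e / e.sum()
    vals = np.where(ok, raw, np.nan)
    return template.like(vals, ~ok)


def synth_sightings(
    truth: Grid,
    n: int,
    month: str,
    effort_bias: Grid | None = None,
    seed: int = 0,
    years: tuple[int, int] = (2002, 2011),
    source: str = "synthetic",
) -> SightingTable:
    """Draw n presences from truth × effort and jitter them within cells."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if month not in MONTHS:
        raise ValueError(f"month must be one of {MONTHS}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404, MONTHS.index(month)]))
    ok = ~truth.mask
    w = truth.values[ok].astype(float).copy()
    if effort_bias is not None:
        if not effort_bias.same_registration(truth):
            raise ValueError("effort grid is not co-registered with truth")
        w *= effort_bias.values[ok]
    if w.sum() <= 0:
        raise ValueError("truth × effort has zero total mass")
    p = w / w.sum()
    rows, cols = np.nonzero(ok)
    draws = rng.choice(len(rows), size=n, p=p)
    u = rng.uniform(0.02, 0.98, size=n)
    v = rng.uniform(0.02, 0.98, size=n)
    x = truth.x_origin + (cols[draws] + u) * truth.cell_size
    y = truth.y_origin + (truth.nrows - rows[draws] - 1 + v) * truth.cell_size
    frame = pd.DataFrame(
        {
            "x": x,
            "y": y,
            "year": rng.integers(years[0], years[1] + 1, size=n),
            "month": month,
            "count": 1,
            "source": source,
        }
    )
    return SightingTable(frame)


def make_scenario(
    config: ScenarioConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> Scenario:
    """Compose a full multi-month scenario; optionally write it to disk.

    The directory layout is ``<var>_<month>.asc`` for predictors,
    ``truth_<month>.asc``, ``effort.asc``, ``sightings.csv`` and a plain-text
    ``manifest.txt`` recording the seed and generator settings.
    """
    cfg = config or ScenarioConfig()
    depth, land_mask = synth_bathymetry(cfg.rows, cfg.cols, cfg.cell_size, seed)
    slope, aspect = slope_aspect(depth)
    dist_layers = {
        f"dist_{level}": distance_to_contour(depth, float(level))
        for level in (0, 50, 100, 150, 200)
    }

    def _masked(g: Grid) -> Grid:
        return g.like(g.values, g.mask | land_mask)

    static = {"depth": depth, "slope": slope, "aspect": aspect, **dist_layers}
    effort = None

    stacks: dict[str, EnvStack] = {}
    truths: dict[str, Grid] = {}
    tables: list[pd.DataFrame] = []
    for month in cfg.months:
        chl, sst = synth_env(depth, month, seed)
        layers = {name: _masked(g) for name, g in static.items()}
        layers["chl_a"] = _masked(chl)
        layers["sst"] = _masked(sst)
        stack = EnvStack(month, layers)
        truth = synth_truth(stack, cfg.coefficients)
        if cfg.effort_bias and effort is None:
            effort = synth_effort(truth, seed, cfg.effort_strength)
        table = synth_sightings(
            truth,
            int(cfg.monthly_n.get(month, 50)),
            month,
            effort_bias=effort if cfg.effort_bias else None,
            seed=seed,
        )
        stacks[month] = stack
        truths[month] = truth
        tables.append(table.frame)

    sightings = SightingTable(pd.concat(tables, ignore_index=True))
    scenario = Scenario(stacks, truths, sightings, effort, seed, cfg)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for month, stack in stacks.items():
            for name, g in stack.layers.items():
                write_ascii_grid(g, out / f"{name}_{month}.asc")
            write_ascii_grid(truths[month], out / f"truth_{month}.asc")
        if effort is not None:
            write_ascii_grid(effort, out / "effort.asc")
        sightings.to_csv(out / "sightings.csv")
        manifest = [
            f"seed: {seed}",
            f"rows: {cfg.rows}",
            f"cols: {cfg.cols}",
            f"cell_size_m: {cfg.cell_size}",
            f"months: {','.join(cfg.months)}",
            f"monthly_n: {dict(cfg.monthly_n)}",
            f"coefficients: {dict(cfg.coefficients)}",
            f"effort_bias: {cfg.effort_bias}",
            f"effort_strength: {cfg.effort_strength}",
        ]
        (out / "manifest.txt").write_text("\n".join(manifest) + "\n")
    return scenario
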