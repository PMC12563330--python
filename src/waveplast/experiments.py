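"""Scenario presets, protocol runners, parameter sweeps and serialization.

A :class:`ScenarioConfig` fully describes one simulation: the grid, the
driving waveform, the plasticity parameters, duration/step, snapshot
cadence, the master seed and the spectral-entropy convention. Runs are
deterministic given (config, seed).

Seeding rule: a run's master seed feeds its single stochastic component
(frozen background noise on the drive). Sweeps derive per-cell seeds as
``SeedSequence([master, value_index, replicate]).generate_state(1) %
2**31`` so that cells are independent but reproducible.

Driver specification (the ``driver`` dict of a config)::

    {"type": "soliton",  "alpha": 0.8, "beta": -1.2, "c": 1.0}
    {"type": "cnoidal",  "alpha": 0.8, "beta": -1.2, "m": 0.9, "c": 1.0,
     "x0": 0.0}
    {"type": "multi_cnoidal", "components": [<cnoidal>, ...],
     "noise_sigma": 0.05}
    {"type": "theta_gamma", "omega_gamma": 1.0, "c": 1.0,
     "amplitude": 0.5, "f_theta": 0.02}
    {"type": "plane_waves_2d", "angles": [0, 60, 120], "k": 1.0,
     "amplitude": 1.0, "speed": 1.0}
    {"type": "gaussian_place", <soliton keys>, "envelope_width": 10.0,
     "envelope_center": 0.0}
    {"type": "zero"}

``noise_sigma`` adds a frozen (drawn once per run, then time-independent)
complex Gaussian background field to the drive, modeling quenched
environmental fluctuations; it may be attached to any 1D driver type.
"""

from __future__ import annotations

import importlib.metadata
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .fields import ComplexField, RealField, SpatialGrid, make_grid
from .metrics import (
    EntropyConvention,
    HysteresisResult,
    InsufficientStructureError,
    cross_correlation,
    field_summary,
    hysteresis_metrics,
    lattice_peak_spacing,
    spectral_entropy,
)
from .plasticity import CoupledTrajectory, PlasticityParams, evolve_coupled
from .waveforms import (
    CnoidalParams,
    NoiseParams,
    PlaneWaveSpec2D,
    ThetaGammaParams,
    TravelingWaveParams,
    add_gaussian_noise,
    interference_field_2d,
    soliton_profile,
    superpose,
    theta_gamma_field,
    traveling_field,
    cnoidal_profile,
)

__all__ = [
    "ScenarioConfig",
    "SweepConfig",
    "RunRecord",
    "ConfigError",
    "PRESETS",
    "SWEEP_PRESETS",
    "list_scenarios",
    "load_config",
    "build_driver",
    "run_scenario",
    "run_hysteresis_protocol",
    "run_sweep",
    "save_run",
    "load_run",
]


class ConfigError(ValueError):
    """Invalid or unknown scenario configuration."""


_GRID_KEYS = {"dims", "extent", "n", "boundary"}
_CONFIG_KEYS = {
    "name",
    "grid",
    "driver",
    "plasticity",
    "T",
    "dt",
    "snapshot_every",
    "seed",
    "entropy_convention",
    "w0",
    "protocol",
}
_PLASTICITY_KEYS = {"rho", "K", "alpha_plast", "D_W", "coupling_sign"}


@dataclass
class ScenarioConfig:
    """Complete, seedable description of one simulation."""

    name: str
    grid: dict
    driver: dict
    plasticity: dict = field(default_factory=dict)
    T: float = 50.0
    dt: float = 0.01
    snapshot_every: int = 100
    seed: int = 0
    entropy_convention: dict = field(default_factory=dict)
    w0: float = 0.1  # uniform initial weight
    protocol: dict = field(default_factory=dict)  # hysteresis options

    def make_grid(self) -> SpatialGrid:
        g = self.grid
        return make_grid(
            g.get("dims", 1),
            g.get("extent", (-50.0, 50.0)),
            g.get("n", 500),
            g.get("boundary", "periodic"),
        )

    def plasticity_params(self) -> PlasticityParams:
        bad = set(self.plasticity) - _PLASTICITY_KEYS
        if bad:
            raise ConfigError(f"unknown plasticity keys: {sorted(bad)}")
        return PlasticityParams(**self.plasticity)

    def convention(self) -> EntropyConvention:
        return EntropyConvention(**self.entropy_convention)

    def to_dict(self) -> dict:
        grid = dict(self.grid)
        if "extent" in grid:  # normalize for YAML round-trips
            ext = np.asarray(grid["extent"], dtype=float)
            grid["extent"] = ext.tolist()
        return {
            "name": self.name,
            "grid": grid,
            "driver": dict(self.driver),
            "plasticity": dict(self.plasticity),
            "T": self.T,
            "dt": self.dt,
            "snapshot_every": self.snapshot_every,
            "seed": self.seed,
            "entropy_convention": dict(self.entropy_convention),
            "w0": self.w0,
            "protocol": dict(self.protocol),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        bad = set(d) - _CONFIG_KEYS
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.T < 0 or self.dt <= 0:
            raise ConfigError("require T >= 0 and dt > 0")
        if self.snapshot_every < 1:
            raise ConfigError("snapshot_every must be >= 1")
        bad = set(self.grid) - _GRID_KEYS
        if bad:
            raise ConfigError(f"unknown grid keys: {sorted(bad)}")
        if self.w0 < 0:
            raise ConfigError("w0 must be non-negative")
        self.make_grid()
        self.plasticity_params()
        self.convention()
        if "type" not in self.driver:
            raise ConfigError("driver spec needs a 'type'")


# ---------------------------------------------------------------------------
# presets — the named scenarios of the simulation study
# ---------------------------------------------------------------------------

_GRID_1D = {"dims": 1, "extent": (-50.0, 50.0), "n": 500, "boundary": "periodic"}
_GRID_2D = {"dims": 2, "extent": (-10.0, 10.0), "n": 200, "boundary": "periodic"}

_CN_MAIN = {"alpha": 0.8, "beta": -1.2, "m": 0.9, "c": 1.0, "x0": 0.0}
_CN_SECOND = {"alpha": 0.8, "beta": -1.2, "m": 0.5, "c": 1.0, "x0": 5.0}


def _preset_defs() -> dict[str, dict]:
    return {
        # localized potentiation (place-field-like imprint)
        "soliton_1d": dict(
            grid=dict(_GRID_1D),
            driver={"type": "soliton", "alpha": 0.8, "beta": -1.2, "c": 1.0},
            plasticity={"coupling_sign": 1},
        ),
        # periodic potentiation (grid-like imprint)
        "cnoidal_1d": dict(
            grid=dict(_GRID_1D),
            driver={"type": "cnoidal", **_CN_MAIN},
            plasticity={"coupling_sign": 1},
        ),
        # two interfering cnoidal waves + frozen background noise
        "interference_noise_1d": dict(
            grid=dict(_GRID_1D),
            driver={
                "type": "multi_cnoidal",
                "components": [dict(_CN_MAIN), dict(_CN_SECOND)],
                "noise_sigma": 0.05,
            },
        ),
        # gradual buildup / saturation time course
        "temporal_snapshots": dict(
            grid=dict(_GRID_1D),
            driver={"type": "cnoidal", **_CN_MAIN},
            plasticity={"coupling_sign": 1},
            T=100.0,
            snapshot_every=500,
        ),
        # forward-reverse drive loop; starts at the resting fixed point W=K
        # so the loop reflects drive path-dependence, not the logistic
        # transient from a sub-capacity start (R is only meaningful when
        # the baseline is an equilibrium of the undriven dynamics)
        "hysteresis_reversal": dict(
            grid=dict(_GRID_1D),
            driver={"type": "cnoidal", **_CN_MAIN},
            T=50.0,
            snapshot_every=50,
            w0=1.0,
            protocol={"mode": "ramp"},
        ),
        # nested slow-envelope / fast-carrier drive
        "theta_gamma": dict(
            grid=dict(_GRID_1D),
            driver={
                "type": "theta_gamma",
                "omega_gamma": 1.0,
                "c": 1.0,
                "amplitude": 1.0,
                "f_theta": 0.02,
            },
        ),
        # orthogonal plane waves -> square lattice
        "grid_2wave_2d": dict(
            grid=dict(_GRID_2D),
            driver={
                "type": "plane_waves_2d",
                "angles": [0.0, 90.0],
                "k": 1.0,
                "amplitude": 1.0,
                "speed": 1.0,
            },
            plasticity={"coupling_sign": 1},
            T=10.0,
        ),
        # three waves at 60 degrees -> hexagonal lattice
        "grid_3wave_2d": dict(
            grid=dict(_GRID_2D),
            driver={
                "type": "plane_waves_2d",
                "angles": [0.0, 60.0, 120.0],
                "k": 1.0,
                "amplitude": 1.0,
                "speed": 1.0,
            },
            plasticity={"coupling_sign": 1},
            T=10.0,
        ),
        # soliton under a static Gaussian envelope (place-field analogue)
        "gaussian_place_1d": dict(
            grid=dict(_GRID_1D),
            driver={
                "type": "gaussian_place",
                "alpha": 0.8,
                "beta": -1.2,
                "c": 1.0,
                "envelope_width": 10.0,
                "envelope_center": 0.0,
            },
            plasticity={"coupling_sign": 1},
        ),
    }


def _make_preset(name: str, seed: int = 0) -> ScenarioConfig:
    defs = _preset_defs()
    if name not in defs:
        raise ConfigError(
            f"unknown scenario {name!r}; available: {sorted(defs)}"
        )
    cfg = ScenarioConfig(name=name, **defs[name])
    cfg.seed = seed
    cfg.validate()
    return cfg


PRESETS = tuple(sorted(_preset_defs()))


@dataclass
class SweepConfig:
    """A one-parameter sweep around a base scenario."""

    base: ScenarioConfig
    param: str  # noise_sigma | D_W | angle | phase_shift | speed_mismatch | driver
    values: Sequence
    replicates: int = 1

    def __post_init__(self) -> None:
        if len(self.values) < 2 and self.param != "driver":
            pass  # single-value sweeps are allowed and equal a plain run
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")


def _sweep_preset_defs() -> dict[str, SweepConfig]:
    two_cn = _make_preset("interference_noise_1d")
    return {
        # encoding erased as background noise grows
        "noise_sweep": SweepConfig(
            base=two_cn, param="noise_sigma", values=[0.0, 0.05, 0.2, 1.0],
            replicates=5,
        ),
        # input complexity ladder: single wave -> interference -> nested
        "complexity_sweep": SweepConfig(
            base=two_cn,
            param="driver",
            values=["cnoidal_1d", "interference_noise_1d", "theta_gamma"],
        ),
        # wave-speed mismatch between the two interfering components
        "phase_speed_sweep": SweepConfig(
            base=two_cn, param="speed_mismatch", values=[0.0, 0.2, 0.5]
        ),
    }


SWEEP_PRESETS = tuple(sorted(_sweep_preset_defs()))


def list_scenarios() -> dict[str, tuple[str, ...]]:
    return {"scenarios": PRESETS, "sweeps": SWEEP_PRESETS}


def load_config(source: str | Path, seed: Optional[int] = None) -> ScenarioConfig:
    """Resolve a preset name, a YAML file path, or inline YAML text.

    A YAML document may set ``preset: <name>`` and override any subset of
    the config fields; unknown keys raise a :class:`ConfigError`.
    """
    text = None
    if isinstance(source, Path) or (
        isinstance(source, str) and source.endswith((".yml", ".yaml"))
    ):
        text = Path(source).read_text()
    elif isinstance(source, str) and source in _preset_defs():
        cfg = _make_preset(source)
        if seed is not None:
            cfg.seed = int(seed)
        return cfg
    else:
        text = str(source)
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError("config document must be a mapping")
    preset = data.pop("preset", None)
    if preset is not None:
        base = _make_preset(preset).to_dict()
        for k, v in data.items():
            if k not in _CONFIG_KEYS:
                raise ConfigError(f"unknown config keys: [{k!r}]")
            if isinstance(v, dict) and isinstance(base.get(k), dict):
                base[k].update(v)
            else:
                base[k] = v
        data = base
    data.setdefault("name", preset or "custom")
    cfg = ScenarioConfig.from_dict(data)
    if seed is not None:
        cfg.seed = int(seed)
    return cfg


# ---------------------------------------------------------------------------
# driver construction
# ---------------------------------------------------------------------------


def _cnoidal_fn(spec: dict) -> tuple[Callable[[np.ndarray], np.ndarray], float]:
    p = CnoidalParams.from_modulus(
        spec.get("alpha", 0.8), spec.get("beta", -1.2), spec.get("m", 0.9),
        c=spec.get("c", 1.0),
    )
    x0 = spec.get("x0", 0.0)
    return (lambda xi: cnoidal_profile(xi - x0, p)), p.c


def build_driver(
    config: ScenarioConfig, grid: Optional[SpatialGrid] = None
) -> Callable[[float], ComplexField]:
    """Turn a driver spec into a callable ``t -> ComplexField``.

    Any frozen background noise is drawn here, once, from the config's
    master seed.
    """
    grid = grid if grid is not None else config.make_grid()
    spec = dict(config.driver)
    kind = spec.pop("type")
    sigma = spec.pop("noise_sigma", 0.0)

    if kind == "zero":
        base = lambda t: ComplexField(grid, np.zeros(grid.shape, dtype=complex))
    elif kind == "soliton":
        p = TravelingWaveParams(
            spec.get("alpha", 0.8), spec.get("beta", -1.2), c=spec.get("c", 1.0)
        )
        base = lambda t: traveling_field(
            lambda xi: soliton_profile(xi, p), grid, t, p.c
        )
    elif kind == "cnoidal":
        fn, c = _cnoidal_fn(spec)
        base = lambda t: traveling_field(fn, grid, t, c)
    elif kind == "multi_cnoidal":
        comps = [_cnoidal_fn(s) for s in spec["components"]]

        def base(t: float) -> ComplexField:
            return superpose(
                [traveling_field(fn, grid, t, c) for fn, c in comps]
            )

    elif kind == "theta_gamma":
        p = ThetaGammaParams(
            omega_gamma=spec.get("omega_gamma", 1.0),
            c=spec.get("c", 1.0),
            amplitude=spec.get("amplitude", 0.5),
            f_theta=spec.get("f_theta", 0.02),
        )
        base = lambda t: theta_gamma_field(grid, t, p)
    elif kind == "plane_waves_2d":
        specs = [
            PlaneWaveSpec2D(
                angle_deg=a,
                k=spec.get("k", 1.0),
                amplitude=spec.get("amplitude", 1.0),
                speed=spec.get("speed", 1.0),
            )
            for a in spec["angles"]
        ]
        base = lambda t: interference_field_2d(grid, specs, t)
    elif kind == "gaussian_place":
        p = TravelingWaveParams(
            spec.get("alpha", 0.8), spec.get("beta", -1.2), c=spec.get("c", 1.0)
        )
        width = spec.get("envelope_width", 10.0)
        center = spec.get("envelope_center", 0.0)
        envelope = np.exp(-((grid.x - center) ** 2) / (2.0 * width**2))

        def base(t: float) -> ComplexField:
            f = traveling_field(lambda xi: soliton_profile(xi, p), grid, t, p.c)
            return ComplexField(grid, f.values * envelope)

    else:
        raise ConfigError(f"unknown driver type {kind!r}")

    if sigma > 0:
        noise_seed = int(
            np.random.SeedSequence([config.seed, 0]).generate_state(1)[0] % 2**31
        )
        zero = ComplexField(grid, np.zeros(grid.shape, dtype=complex))
        frozen = add_gaussian_noise(zero, NoiseParams(sigma, noise_seed))

        inner = base

        def base(t: float) -> ComplexField:  # noqa: F811 - deliberate wrap
            f = inner(t)
            return ComplexField(grid, f.values + frozen.values)

    return base


# ---------------------------------------------------------------------------
# runners
# ---------------------------------------------------------------------------


@dataclass
class RunRecord:
    """Everything one scenario run produced."""

    config: ScenarioConfig
    trajectory: CoupledTrajectory
    metrics: pd.DataFrame
    version: str = ""
    wall_time: float = 0.0
    hysteresis: Optional[HysteresisResult] = None


def _version() -> str:
    try:
        return importlib.metadata.version("waveplast")
    except importlib.metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


def _metric_rows(config: ScenarioConfig, pairs: dict[str, float]) -> pd.DataFrame:
    conv = config.convention().as_dict()
    rows = [
        {
            "scenario": config.name,
            "seed": config.seed,
            **conv,
            "metric": k,
            "value": v,
        }
        for k, v in pairs.items()
    ]
    return pd.DataFrame(rows)


def _standard_metrics(
    config: ScenarioConfig, traj: CoupledTrajectory
) -> pd.DataFrame:
    conv = config.convention()
    W = traj.final_W
    pairs: dict[str, float] = {}
    mean, mx, sd = field_summary(W)
    pairs.update({"W_mean": mean, "W_max": mx, "W_sd": sd})
    if W.grid.dims == 1:
        # degenerate (constant / zero-power) fields have no defined
        # spectral entropy; those rows are simply omitted
        try:
            pairs["spectral_entropy_W"] = spectral_entropy(W, conv)
        except ValueError:
            pass
        try:
            pairs["spectral_entropy_intensity"] = spectral_entropy(
                traj.mean_intensity, conv
            )
        except ValueError:
            pass
        peak, lag = cross_correlation(traj.mean_intensity, W, mode="raw_mean")
        pairs["xcorr_raw_peak"] = peak
        pairs["xcorr_raw_lag"] = lag
        try:
            ppeak, plag = cross_correlation(traj.mean_intensity, W, mode="pearson")
            pairs["xcorr_pearson_peak"] = ppeak
            pairs["xcorr_pearson_lag"] = plag
        except ValueError:
            pass
    else:
        try:
            spacing, npeaks = lattice_peak_spacing(W)
            pairs["lattice_spacing_W"] = spacing
            pairs["lattice_peak_count_W"] = npeaks
        except InsufficientStructureError:
            pass
    return _metric_rows(config, pairs)


def run_scenario(config: ScenarioConfig) -> RunRecord:
    """Build the driver, evolve the coupled system, compute metrics."""
    t0 = time.perf_counter()
    config.validate()
    if config.protocol:
        return run_hysteresis_protocol(config)
    grid = config.make_grid()
    driver = build_driver(config, grid)
    W0 = RealField(grid, np.full(grid.shape, config.w0))
    traj = evolve_coupled(
        driver,
        W0,
        config.plasticity_params(),
        config.T,
        config.dt,
        config.snapshot_every,
    )
    metrics = _standard_metrics(config, traj)
    return RunRecord(config, traj, metrics, _version(), time.perf_counter() - t0)


def run_hysteresis_protocol(config: ScenarioConfig) -> RunRecord:
    """Forward-reverse drive loop and its hysteresis quantification.

    Ramp mode (default): the drive amplitude I ramps 0 -> 1 over one epoch
    of length ``T`` (wave direction +c throughout), then 1 -> 0 over a
    second epoch of the same length. Direction mode: constant unit
    amplitude, +c then -c, with I the signed direction +-1 — the loop
    area is then computed against the ramp variable of each epoch.
    """
    t0 = time.perf_counter()
    config.validate()
    mode = config.protocol.get("mode", "ramp")
    if mode not in ("ramp", "direction"):
        raise ConfigError(f"unknown hysteresis mode {mode!r}")
    grid = config.make_grid()
    base = build_driver(config, grid)
    T = config.T
    params = config.plasticity_params()
    W0 = RealField(grid, np.full(grid.shape, config.w0))

    if mode == "ramp":
        fwd_driver = lambda t: _scale(base(t), t / T)
        rev_driver = lambda t: _scale(base(T + t), 1.0 - t / T)
        i_of_t_fwd = lambda t: t / T
        i_of_t_rev = lambda t: 1.0 - t / T
    else:
        spec = dict(config.driver)
        rev_cfg = replace(config, driver={**spec, "c": -abs(spec.get("c", 1.0))})
        rev_base = build_driver(rev_cfg, grid)
        fwd_driver = base
        rev_driver = lambda t: rev_base(T + t)
        i_of_t_fwd = lambda t: t / T
        i_of_t_rev = lambda t: 1.0 - t / T

    fwd = evolve_coupled(
        fwd_driver, W0, params, T, config.dt, config.snapshot_every
    )
    rev = evolve_coupled(
        rev_driver, fwd.final_W, params, T, config.dt, config.snapshot_every
    )

    times = np.concatenate([fwd.times, T + rev.times[1:]])
    wbar = np.concatenate([fwd.mean_W, rev.mean_W[1:]])
    I = np.concatenate(
        [
            [i_of_t_fwd(t) for t in fwd.times],
            [i_of_t_rev(t) for t in rev.times[1:]],
        ]
    )
    w_traj = fwd.W_snapshots + rev.W_snapshots[1:]
    hyst = hysteresis_metrics(
        wbar, I, fwd.final_W, rev.final_W, W0, w_traj=w_traj
    )
    traj = CoupledTrajectory(
        times,
        w_traj,
        fwd.intensity_snapshots + rev.intensity_snapshots[1:],
        wbar,
        np.concatenate([fwd.max_W, rev.max_W[1:]]),
        np.concatenate([fwd.sd_W, rev.sd_W[1:]]),
        RealField(
            grid,
            0.5 * (fwd.mean_intensity.values + rev.mean_intensity.values),
        ),
    )
    pairs = {
        "H_signed": hyst.h_signed,
        "H_abs": hyst.h_abs,
        "H_norm": hyst.h_norm,
        "R": hyst.r,
        "Omega": hyst.omega,
    }
    metrics = pd.concat(
        [_standard_metrics(config, traj), _metric_rows(config, pairs)],
        ignore_index=True,
    )
    return RunRecord(
        config, traj, metrics, _version(), time.perf_counter() - t0, hyst
    )


def _scale(f: ComplexField, a: float) -> ComplexField:
    return ComplexField(f.grid, a * f.values)


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------


def _apply_sweep_value(base: ScenarioConfig, param: str, value) -> ScenarioConfig:
    cfg = ScenarioConfig.from_dict(base.to_dict())
    if param == "noise_sigma":
        cfg.driver["noise_sigma"] = float(value)
    elif param == "D_W":
        cfg.plasticity["D_W"] = float(value)
    elif param == "angle":
        th = float(value)
        cfg.driver["angles"] = [0.0, th, 2.0 * th]
    elif param == "phase_shift":
        cfg.driver["components"][1]["x0"] = float(value)
    elif param == "speed_mismatch":
        cfg.driver["components"][1]["c"] = cfg.driver["components"][1].get(
            "c", 1.0
        ) + float(value)
    elif param == "driver":
        cfg.driver = dict(_make_preset(str(value)).driver)
        cfg.name = f"{base.name}[{value}]"
    else:
        raise ConfigError(f"unknown sweep parameter {param!r}")
    return cfg


def _cell_seed(master: int, value_index: int, replicate: int) -> int:
    return int(
        np.random.SeedSequence([master, value_index, replicate]).generate_state(1)[0]
        % 2**31
    )


def run_sweep(sweep: SweepConfig | str) -> pd.DataFrame:
    """Run every (value, replicate) cell; one wide metric row per cell.

    For noise sweeps a noiseless reference run (same drive) is computed
    first and each cell additionally reports ``ref_pearson``, the Pearson
    correlation of its final weight field with the reference one. Failed
    cells are flagged in an ``error`` column and the sweep continues.
    """
    if isinstance(sweep, str):
        defs = _sweep_preset_defs()
        if sweep not in defs:
            raise ConfigError(f"unknown sweep {sweep!r}; available: {sorted(defs)}")
        sweep = defs[sweep]
    ref_W = None
    if sweep.param == "noise_sigma":
        ref_cfg = _apply_sweep_value(sweep.base, "noise_sigma", 0.0)
        ref_W = run_scenario(ref_cfg).trajectory.final_W
    rows = []
    for iv, value in enumerate(sweep.values):
        for rep in range(sweep.replicates):
            cfg = _apply_sweep_value(sweep.base, sweep.param, value)
            cfg.seed = _cell_seed(sweep.base.seed, iv, rep)
            row = {
                "scenario": cfg.name,
                "param": sweep.param,
                "value": value,
                "replicate": rep,
                "seed": cfg.seed,
            }
            try:
                rec = run_scenario(cfg)
                wide = dict(
                    zip(rec.metrics["metric"], rec.metrics["value"])
                )
                row.update(wide)
                if ref_W is not None:
                    w = rec.trajectory.final_W.values.ravel()
                    r = ref_W.values.ravel()
                    row["ref_pearson"] = float(np.corrcoef(w, r)[0, 1])
                if sweep.param == "angle":
                    try:
                        spacing, npk = lattice_peak_spacing(
                            rec.trajectory.final_W
                        )
                        row["lattice_spacing_W"] = spacing
                        row["lattice_peak_count_W"] = npk
                    except InsufficientStructureError as exc:
                        row["error"] = f"lattice: {exc}"
            except Exception as exc:  # noqa: BLE001 - sweep must continue
                row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_run(record: RunRecord, directory: str | Path) -> Path:
    """Write config (YAML), metric table (CSV) and fields (HDF5)."""
    import h5py

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "config.yaml").write_text(
        yaml.safe_dump(record.config.to_dict(), sort_keys=False)
    )
    record.metrics.to_csv(directory / "metrics.csv", index=False)
    traj = record.trajectory
    with h5py.File(directory / "fields.h5", "w") as h5:
        h5.attrs["version"] = record.version
        h5.attrs["wall_time"] = record.wall_time
        h5.create_dataset("times", data=traj.times)
        h5.create_dataset(
            "W", data=np.stack([w.values for w in traj.W_snapshots])
        )
        h5.create_dataset(
            "intensity",
            data=np.stack([f.values for f in traj.intensity_snapshots]),
        )
        h5.create_dataset("mean_W", data=traj.mean_W)
        h5.create_dataset("max_W", data=traj.max_W)
        h5.create_dataset("sd_W", data=traj.sd_W)
        h5.create_dataset("mean_intensity", data=traj.mean_intensity.values)
        if record.hysteresis is not None:
            hy = record.hysteresis
            grp = h5.create_group("hysteresis")
            for k in ("h_signed", "h_abs", "h_norm", "r", "omega"):
                grp.attrs[k] = getattr(hy, k)
            if hy.h_x is not None:
                grp.create_dataset("h_x", data=hy.h_x.values)
    return directory


def load_run(directory: str | Path) -> RunRecord:
    """Exact numeric inverse of :func:`save_run`."""
    import h5py

    directory = Path(directory)
    cfg_path = directory / "config.yaml"
    if not cfg_path.exists():
        raise FileNotFoundError(
            f"{directory} has no config.yaml; not a saved run directory"
        )
    config = ScenarioConfig.from_dict(yaml.safe_load(cfg_path.read_text()))
    metrics = pd.read_csv(directory / "metrics.csv")
    if "log_base" in metrics.columns:  # "2" round-trips as an integer
        metrics["log_base"] = metrics["log_base"].astype(str)
    grid = config.make_grid()
    with h5py.File(directory / "fields.h5", "r") as h5:
        times = h5["times"][:]
        Ws = [RealField(grid, w) for w in h5["W"][:]]
        intens = [RealField(grid, f) for f in h5["intensity"][:]]
        traj = CoupledTrajectory(
            times,
            Ws,
            intens,
            h5["mean_W"][:],
            h5["max_W"][:],
            h5["sd_W"][:],
            RealField(grid, h5["mean_intensity"][:]),
        )
        hyst = None
        if "hysteresis" in h5:
            grp = h5["hysteresis"]
            h_x = (
                RealField(grid, grp["h_x"][:]) if "h_x" in grp else None
            )
            hyst = HysteresisResult(
                grp.attrs["h_signed"],
                grp.attrs["h_abs"],
                grp.attrs["h_norm"],
                grp.attrs["r"],
                grp.attrs["omega"],
                h_x,
            )
        version = h5.attrs.get("version", "")
        wall = float(h5.attrs.get("wall_time", 0.0))
    return RunRecord(config, traj, metrics, version, wall, hyst)
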