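"""Run configuration: TOML parsing with explicit unit suffixes in key names.

Every physical quantity in a config file carries its unit in the key name
(``thickness_mm``, ``d_gel_e10_m2_s``, ``duration_min``) so a config can be
read without consulting the docs; values are converted to SI on load.  The
defaults describe the sulphapyridine bench scenario: a 5 mm x 40 mm slab
between 50 cm3 reservoirs, 25 mg/dm3 donor solution, with an optional
reactive (humic-enriched) gel whose binding constant retards transport.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ValidationError
from .simulate import CellGeometry, IsothermParams, NoiseModel, TransportParams

__all__ = ["EstimatorOptions", "SimulationOptions", "SorptionConfig", "RunConfig", "load_config"]


@dataclass(frozen=True)
class EstimatorOptions:
    method: str = "extrapolation"
    threshold_multiple: float = 3.0
    slope_tol: float = 0.01
    min_points: int = 10
    flux_side: str = "donor"
    epsilon_evaluation: str = "window"
    n_noise_replicates: int = 25


@dataclass(frozen=True)
class SimulationOptions:
    duration_s: float = 1.2e5
    output_interval_s: float = 60.0
    n_nodes: int = 101
    max_dt_s: float | None = None


@dataclass(frozen=True)
class SorptionConfig:
    isotherm: IsothermParams = field(
        default_factory=lambda: IsothermParams(q_max=2.0, k_l=0.1, strong_fraction=0.5)
    )
    c0_list: tuple[float, ...] = (1.0, 3.25, 5.5, 7.75, 10.0)
    solution_volume_dm3: float = 5.0e-3
    sorbent_mass_g: float = 0.100


@dataclass(frozen=True)
class RunConfig:
    geometry: CellGeometry = field(default_factory=CellGeometry)
    transport: TransportParams = field(
        default_factory=lambda: TransportParams(d_gel=5.20e-10, c0_donor=25.0)
    )
    transport_reactive: TransportParams | None = field(
        default_factory=lambda: TransportParams(d_gel=5.20e-10, c0_donor=25.0, k_binding=1.92)
    )
    noise: NoiseModel = field(default_factory=NoiseModel)
    simulation: SimulationOptions = field(default_factory=SimulationOptions)
    estimator: EstimatorOptions = field(default_factory=EstimatorOptions)
    sorption: SorptionConfig = field(default_factory=SorptionConfig)


def _section(data: dict, name: str) -> dict:
    sec = data.get(name, {})
    if not isinstance(sec, dict):
        raise ValidationError(f"config section [{name}] must be a table")
    return dict(sec)


def _pop(sec: dict, key: str, default):
    return sec.pop(key, default)


def _check_empty(sec: dict, name: str) -> None:
    if sec:
        raise ValidationError(f"unknown keys in config section [{name}]: {sorted(sec)}")


def _geometry(sec: dict) -> CellGeometry:
    g = CellGeometry(
        thickness_L=float(_pop(sec, "thickness_mm", 5.0)) * 1e-3,
        diameter=float(_pop(sec, "diameter_mm", 40.0)) * 1e-3,
        donor_volume=float(_pop(sec, "donor_volume_cm3", 50.0)) * 1e-6,
        acceptor_volume=float(_pop(sec, "acceptor_volume_cm3", 50.0)) * 1e-6,
    )
    _check_empty(sec, "geometry")
    return g


def _transport(sec: dict, name: str, default_c0: float = 25.0) -> TransportParams:
    t = TransportParams(
        d_gel=float(_pop(sec, "d_gel_e10_m2_s", 5.20)) * 1e-10,
        c0_donor=float(_pop(sec, "c0_mg_dm3", default_c0)),
        k_binding=float(_pop(sec, "k_binding", 0.0)),
        epsilon=float(_pop(sec, "epsilon", 1.0)),
    )
    _check_empty(sec, name)
    return t


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a TOML run configuration.

    All sections are optional; omitted values fall back to the default
    bench scenario.  Unknown keys are rejected so unit typos cannot pass
    silently.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"config file not found: {path}")
    try:
        data = tomllib.loads(path.read_text())
    except tomllib.TOMLDecodeError as exc:
        raise ValidationError(f"{path}: invalid TOML: {exc}") from None

    geometry = _geometry(_section(data, "geometry"))
    transport = _transport(_section(data, "transport"), "transport")
    if "transport_reactive" in data:
        sec = _section(data, "transport_reactive")
        if sec.pop("enabled", True):
            # the reactive gel inherits the inert drug/diffusivity unless overridden
            defaults = {
                "d_gel_e10_m2_s": transport.d_gel * 1e10,
                "c0_mg_dm3": transport.c0_donor,
                "epsilon": transport.epsilon,
            }
            for key, val in defaults.items():
                sec.setdefault(key, val)
            transport_reactive = _transport(sec, "transport_reactive")
        else:
            transport_reactive = None
    else:
        transport_reactive = None

    sec = _section(data, "noise")
    noise = NoiseModel(
        relative_sd=float(_pop(sec, "relative_sd", 0.01)),
        absolute_sd=float(_pop(sec, "absolute_sd_mg_dm3", 0.02)),
        seed=int(_pop(sec, "seed", 0)),
    )
    _check_empty(sec, "noise")

    sec = _section(data, "simulation")
    duration = _pop(sec, "duration_min", None)
    duration_s = float(duration) * 60.0 if duration is not None else 1.2e5
    max_dt = _pop(sec, "max_dt_s", None)
    simulation = SimulationOptions(
        duration_s=duration_s,
        output_interval_s=float(_pop(sec, "output_interval_s", 60.0)),
        n_nodes=int(_pop(sec, "n_nodes", 101)),
        max_dt_s=float(max_dt) if max_dt is not None else None,
    )
    _check_empty(sec, "simulation")

    sec = _section(data, "estimator")
    estimator = EstimatorOptions(
        method=str(_pop(sec, "method", "extrapolation")),
        threshold_multiple=float(_pop(sec, "threshold_multiple", 3.0)),
        slope_tol=float(_pop(sec, "slope_tol", 0.01)),
        min_points=int(_pop(sec, "min_points", 10)),
        flux_side=str(_pop(sec, "flux_side", "donor")),
        epsilon_evaluation=str(_pop(sec, "epsilon_evaluation", "window")),
        n_noise_replicates=int(_pop(sec, "n_noise_replicates", 25)),
    )
    _check_empty(sec, "estimator")
    if estimator.method not in ("extrapolation", "threshold"):
        raise ValidationError(f"estimator.method must be extrapolation|threshold, got {estimator.method!r}")

    sec = _section(data, "sorption")
    isotherm = IsothermParams(
        q_max=float(_pop(sec, "q_max_mg_g", 2.0)),
        k_l=float(_pop(sec, "k_l_dm3_mg", 0.1)),
        strong_fraction=float(_pop(sec, "strong_fraction", 0.5)),
        strong_fraction_slope=float(_pop(sec, "strong_fraction_slope_dm3_mg", 0.0)),
    )
    sorption = SorptionConfig(
        isotherm=isotherm,
        c0_list=tuple(float(x) for x in _pop(sec, "c0_list_mg_dm3", [1.0, 3.25, 5.5, 7.75, 10.0])),
        solution_volume_dm3=float(_pop(sec, "solution_volume_cm3", 5.0)) * 1e-3,
        sorbent_mass_g=float(_pop(sec, "sorbent_mass_mg", 100.0)) * 1e-3,
    )
    _check_empty(sec, "sorption")

    return RunConfig(
        geometry=geometry,
        transport=transport,
        transport_reactive=transport_reactive,
        noise=noise,
        simulation=simulation,
        estimator=estimator,
        sorption=sorption,
    )
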