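"""Forward models of the diffusion-cell and batch-sorption experiments.

The physical system is a thin hydrogel slab (agarose, optionally enriched
with humic acids) clamped between two stirred reservoirs.  The donor
reservoir starts loaded with drug, the acceptor with pure water.  Free drug
diffuses through the gel; humic binding sites immobilise part of it through
a fast linear equilibrium, ``c_bound = K * c_free``, which retards the
transient by a factor ``1 + K`` while leaving the steady flux unchanged.  A
partition coefficient ``epsilon`` relates the free gel concentration at each
face to the adjacent reservoir, ``c_free(face) = epsilon * c_reservoir``.

Governing equations for the free concentration ``u(x, t)`` in a slab of
thickness ``L`` with exposed area ``A``::

    (1 + K) du/dt = D d2u/dx2          0 < x < L
    u(0, t) = eps * c_d(t)             donor face
    u(L, t) = eps * c_a(t)             acceptor face
    V_d dc_d/dt = +A D du/dx |x=0      well-mixed donor reservoir
    V_a dc_a/dt = -A D du/dx |x=L      well-mixed acceptor reservoir

Concentrations are carried in g/m3 throughout, numerically identical to the
mg/dm3 used on the bench.  Lengths and times are SI.

The batch sorption model is a Langmuir uptake ``q(c) = q_max K_L c /
(1 + K_L c)`` solved against the closed mass balance of a vial (solution
volume ``V``, sorbent mass ``m``), followed by a water desorption step in
which only the mobile share of the sorbed drug re-equilibrates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import solve_banded

from .errors import SolverError, ValidationError

__all__ = [
    "CellGeometry",
    "TransportParams",
    "SimulationState",
    "ConcentrationTrace",
    "NoiseModel",
    "IsothermParams",
    "SorptionRecord",
    "DEFAULT_GEOMETRY",
    "simulate_cell",
    "closed_form_lag",
    "add_noise",
    "simulate_sorption",
]


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ValidationError(message)


@dataclass(frozen=True)
class CellGeometry:
    """Geometry of the two-compartment cell and the gel slab separating it.

    Parameters
    ----------
    thickness_L : float
        Gel slab thickness in metres (diffusion length).
    diameter : float
        Diameter of the exposed circular gel face, metres.
    donor_volume, acceptor_volume : float
        Reservoir volumes in cubic metres.
    """

    thickness_L: float = 5.0e-3
    diameter: float = 40.0e-3
    donor_volume: float = 50.0e-6
    acceptor_volume: float = 50.0e-6

    def __post_init__(self) -> None:
        for name in ("thickness_L", "diameter", "donor_volume", "acceptor_volume"):
            _require(getattr(self, name) > 0, f"CellGeometry.{name} must be > 0")

    @property
    def exposed_area(self) -> float:
        """Exposed circular gel face area, m2."""
        return math.pi * (self.diameter / 2.0) ** 2

    @property
    def gel_volume(self) -> float:
        """Volume of the gel slab, m3."""
        return self.exposed_area * self.thickness_L


#: The bench cell: 5 mm x 40 mm-diameter slab between 50 cm3 reservoirs.
DEFAULT_GEOMETRY = CellGeometry()


@dataclass(frozen=True)
class TransportParams:
    """Transport and binding parameters of one gel/drug combination.

    ``d_gel`` is the diffusivity of the *free* drug in the gel (m2/s);
    ``k_binding`` the dimensionless apparent equilibrium constant of the
    instantaneous linear immobilisation (0 for the inert gel); ``epsilon``
    the gel/solution interface partition coefficient; ``c0_donor`` the
    initial donor concentration in g/m3 (= mg/dm3).
    """

    d_gel: float
    c0_donor: float
    k_binding: float = 0.0
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        _require(self.d_gel > 0, "TransportParams.d_gel must be > 0")
        _require(self.k_binding >= 0, "TransportParams.k_binding must be >= 0")
        _require(self.epsilon > 0, "TransportParams.epsilon must be > 0")
        _require(self.c0_donor >= 0, "TransportParams.c0_donor must be >= 0")

    @property
    def retardation(self) -> float:
        """The factor 1 + K slowing the diffusive transient."""
        return 1.0 + self.k_binding


@dataclass(frozen=True)
class SimulationState:
    """Spatial snapshot of the gel interior plus reservoir concentrations."""

    x_grid: np.ndarray
    c_free: np.ndarray
    c_bound: np.ndarray
    c_donor: float
    c_acceptor: float


@dataclass
class ConcentrationTrace:
    """A (time, donor, acceptor) series as produced by the cell experiment.

    ``meta`` carries provenance: the label and, for synthetic traces, the
    true parameters that generated them.  ``final_state`` holds the last
    simulated gel profile when the trace came from :func:`simulate_cell`.
    """

    times: np.ndarray
    c_donor: np.ndarray
    c_acceptor: np.ndarray
    meta: dict = field(default_factory=dict)
    final_state: SimulationState | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.c_donor = np.asarray(self.c_donor, dtype=float)
        self.c_acceptor = np.asarray(self.c_acceptor, dtype=float)
        n = self.times.size
        _require(n >= 1, "trace must contain at least one sample")
        _require(
            self.c_donor.size == n and self.c_acceptor.size == n,
            "trace series must have equal lengths",
        )
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("trace times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)

    def scaled(self, factor: float) -> "ConcentrationTrace":
        """Return a copy with all concentrations multiplied by ``factor``."""
        return ConcentrationTrace(
            self.times.copy(),
            self.c_donor * factor,
            self.c_acceptor * factor,
            dict(self.meta),
        )


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian measurement noise: sd = relative_sd * value + absolute_sd."""

    relative_sd: float = 0.01
    absolute_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.relative_sd >= 0, "NoiseModel.relative_sd must be >= 0")
        _require(self.absolute_sd >= 0, "NoiseModel.absolute_sd must be >= 0")


@dataclass(frozen=True)
class IsothermParams:
    """Langmuir sorption parameters of a drug on humic acid.

    ``q_max`` is the saturation load (mg drug per g sorbent), ``k_l`` the
    Langmuir affinity (dm3/mg).  ``strong_fraction`` is the share of sorbed
    drug that does not desorb in water; ``strong_fraction_slope`` lets that
    share grow (or shrink) linearly with the initial concentration, which
    reproduces drugs whose strongly bound share rises as loading increases.
    """

    q_max: float
    k_l: float
    strong_fraction: float = 0.0
    strong_fraction_slope: float = 0.0

    def __post_init__(self) -> None:
        _require(self.q_max > 0, "IsothermParams.q_max must be > 0")
        _require(self.k_l > 0, "IsothermParams.k_l must be > 0")
        _require(
            0.0 <= self.strong_fraction <= 1.0,
            "IsothermParams.strong_fraction must lie in [0, 1]",
        )

    def strong_fraction_at(self, c0: float) -> float:
        """Effective strongly-bound share for a batch started at ``c0``."""
        return float(np.clip(self.strong_fraction + self.strong_fraction_slope * c0, 0.0, 1.0))


@dataclass(frozen=True)
class SorptionRecord:
    """One batch adsorption/desorption measurement triple.

    Concentrations in mg/dm3, ``solution_volume`` in dm3, ``sorbent_mass``
    in g.  ``c_leach`` is the concentration found in the fresh-water
    desorption step (same volume as the adsorption step).
    """

    c0: float
    c_eq_ads: float
    c_leach: float
    solution_volume: float = 5.0e-3
    sorbent_mass: float = 0.100

    def __post_init__(self) -> None:
        _require(self.solution_volume > 0, "SorptionRecord.solution_volume must be > 0")
        _require(self.sorbent_mass > 0, "SorptionRecord.sorbent_mass must be > 0")
        _require(self.c0 >= 0, "SorptionRecord.c0 must be >= 0")
        tol = 1e-9 * max(self.c0, 1.0)
        _require(
            -tol <= self.c_eq_ads <= self.c0 + tol,
            "SorptionRecord: c_eq_ads must lie between 0 and c0",
        )
        _require(self.c_leach >= -tol, "SorptionRecord.c_leach must be >= 0")
        _require(
            self.c_leach <= (self.c0 - self.c_eq_ads) + tol,
            "SorptionRecord: leached amount exceeds adsorbed amount",
        )

    @property
    def adsorbed_amount(self) -> float:
        """Drug mass taken up in the adsorption step, mg."""
        return (self.c0 - self.c_eq_ads) * self.solution_volume

    @property
    def leached_amount(self) -> float:
        """Drug mass released in the desorption step, mg."""
        return self.c_leach * self.solution_volume


def closed_form_lag(thickness_L: float, d_gel: float, k_binding: float = 0.0) -> float:
    """Lag time of a slab with linear binding: ``L^2 (1 + K) / (6 D)``.

    This is the classical membrane time-lag result; binding stretches the
    transient by the retardation factor ``1 + K`` without changing the
    steady flux.
    """
    _require(thickness_L > 0, "thickness_L must be > 0")
    _require(d_gel > 0, "d_gel must be > 0")
    _require(k_binding >= 0, "k_binding must be >= 0")
    return thickness_L**2 * (1.0 + k_binding) / (6.0 * d_gel)


def simulate_cell(
    geometry: CellGeometry,
    params: TransportParams,
    duration: float,
    output_interval: float,
    *,
    n_nodes: int = 101,
    max_dt: float | None = None,
    label: str = "synthetic",
) -> ConcentrationTrace:
    """Integrate the coupled slab/reservoir model and sample both reservoirs.

    The slab is discretised on a uniform vertex-centred grid; time stepping
    is implicit (backward Euler), unconditionally stable for the stiff
    reservoir coupling.  Face nodes are slaved to ``epsilon`` times the
    adjacent reservoir; reservoirs evolve from the discrete face flux.  The
    discretisation conserves the discrete total drug mass (reservoirs +
    trapezoidal gel content, free plus bound) to rounding error.

    Parameters
    ----------
    duration, output_interval : float
        Total simulated time and sampling interval, seconds.
    n_nodes : int
        Grid nodes across the slab (default 101).
    max_dt : float, optional
        Cap on the internal time step.  Defaults to 1/2000 of the retarded
        diffusion time ``L^2 (1 + K) / D``, which keeps the first-order
        time-stepping error well below the estimators' tolerances.
    """
    _require(duration > 0, "duration must be > 0")
    _require(output_interval > 0, "output_interval must be > 0")
    if n_nodes < 5:
        raise SolverError(f"n_nodes={n_nodes} too coarse: need at least 5 grid nodes")
    if max_dt is not None and max_dt <= 0:
        raise SolverError(f"max_dt={max_dt} must be positive")

    L = geometry.thickness_L
    area = geometry.exposed_area
    v_d = geometry.donor_volume
    v_a = geometry.acceptor_volume
    D = params.d_gel
    eps = params.epsilon
    retard = params.retardation
    c0 = params.c0_donor

    tau = L**2 * retard / D
    if max_dt is None:
        max_dt = tau / 2000.0
    n_sub = max(1, math.ceil(output_interval / max_dt))
    dt = output_interval / n_sub
    n_out = max(1, int(math.floor(duration / output_interval + 1e-9)))

    n = n_nodes
    h = L / (n - 1)
    g = dt * area * D / h               # face-flux factor (m3)
    r = dt * D / (retard * h * h)       # interior diffusion number
    half = retard * area * h / 2.0      # mass capacity of a half face node (m3)

    # Unknown ordering [c_d, u_1 .. u_{n-2}, c_a] makes the system tridiagonal.
    ab = np.zeros((3, n))
    ab[1, 0] = v_d + half * eps + g * eps
    ab[0, 1] = -g
    ab[1, 1:-1] = 1.0 + 2.0 * r
    ab[0, 2:] = -r
    ab[0, -1] = -r * eps
    ab[2, :-2] = -r
    ab[2, 0] = -r * eps
    ab[1, -1] = v_a + half * eps + g * eps
    ab[2, -2] = -g

    u = np.zeros(n)  # free concentration; the gel starts drug-free
    c_d = float(c0)
    c_a = 0.0

    times = np.arange(n_out + 1) * output_interval
    out_d = np.empty(n_out + 1)
    out_a = np.empty(n_out + 1)
    gel_mass = np.empty(n_out + 1)  # free + bound drug in the slab, g
    out_d[0], out_a[0] = c_d, c_a
    gel_mass[0] = retard * area * np.trapezoid(u, dx=h)

    rhs = np.empty(n)
    neg_tol = -1e-9 * max(c0, 1.0)
    for k in range(1, n_out + 1):
        for _ in range(n_sub):
            rhs[0] = v_d * c_d + half * u[0]
            rhs[1:-1] = u[1:-1]
            rhs[-1] = v_a * c_a + half * u[-1]
            y = solve_banded((1, 1), ab, rhs)
            c_d = float(y[0])
            c_a = float(y[-1])
            u[1:-1] = y[1:-1]
            u[0] = eps * c_d
            u[-1] = eps * c_a
        if c_d < neg_tol or c_a < neg_tol or u.min() < neg_tol:
            raise SolverError(
                "negative concentrations detected: refine n_nodes/max_dt "
                f"(n_nodes={n_nodes}, dt={dt:.3g} s)"
            )
        out_d[k], out_a[k] = c_d, c_a
        gel_mass[k] = retard * area * np.trapezoid(u, dx=h)

    x_grid = np.linspace(0.0, L, n)
    state = SimulationState(
        x_grid=x_grid,
        c_free=u.copy(),
        c_bound=params.k_binding * u,
        c_donor=c_d,
        c_acceptor=c_a,
    )
    meta = {
        "label": label,
        "true_params": params,
        "geometry": geometry,
        "solver": {"n_nodes": n_nodes, "dt": dt, "n_sub": n_sub},
        "gel_mass_g": gel_mass,
    }
    return ConcentrationTrace(times, out_d, out_a, meta, final_state=state)


def total_mass(
    trace_or_state: SimulationState, geometry: CellGeometry, k_binding: float
) -> float:
    """Total drug mass (g) in reservoirs plus gel (free + bound) for a state."""
    s = trace_or_state
    gel = (1.0 + k_binding) * geometry.exposed_area * np.trapezoid(
        s.c_free, dx=float(s.x_grid[1] - s.x_grid[0])
    )
    return geometry.donor_volume * s.c_donor + geometry.acceptor_volume * s.c_acceptor + gel


def add_noise(trace: ConcentrationTrace, noise: NoiseModel) -> ConcentrationTrace:
    """Perturb both reservoir series with heteroscedastic Gaussian noise.

    Each reading gets independent noise with standard deviation
    ``relative_sd * value + absolute_sd``; results are clipped at zero.
    Identical seeds give identical output.
    """
    rng = np.random.default_rng(noise.seed)

    def perturb(series: np.ndarray) -> np.ndarray:
        sd = noise.relative_sd * series + noise.absolute_sd
        return np.clip(series + rng.standard_normal(series.size) * sd, 0.0, None)

    meta = dict(trace.meta)
    meta["noise"] = noise
    return ConcentrationTrace(trace.times.copy(), perturb(trace.c_donor), perturb(trace.c_acceptor), meta)


def _langmuir_batch_equilibrium(
    total_mg: float, volume: float, mass: float, q_max: float, k_l: float
) -> float:
    """Solution concentration equilibrating ``total_mg`` of drug in a vial.

    Solves ``total = c V + m q_max K_L c / (1 + K_L c)`` for the unique
    non-negative root of the resulting quadratic.
    """
    if total_mg <= 0:
        return 0.0
    a = volume * k_l
    b = volume + mass * q_max * k_l - total_mg * k_l
    disc = b * b + 4.0 * a * total_mg
    if disc < 0:  # impossible for valid parameters
        raise SolverError("Langmuir batch balance has no real root")
    sqrt_disc = math.sqrt(disc)
    # cancellation-free form of the positive quadratic root
    c = 2.0 * total_mg / (b + sqrt_disc) if b >= 0 else (-b + sqrt_disc) / (2.0 * a)
    return min(max(c, 0.0), total_mg / volume)


def simulate_sorption(
    isotherm: IsothermParams,
    c0_list: Sequence[float],
    solution_volume: float = 5.0e-3,
    sorbent_mass: float = 0.100,
) -> list[SorptionRecord]:
    """Generate batch adsorption/desorption records for a series of doses.

    Adsorption equilibrates ``c0 * V`` of drug against the Langmuir
    isotherm; the desorption step re-equilibrates only the mobile share
    ``1 - strong_fraction`` of the sorbed amount with fresh water of the
    same volume, using the same isotherm.  Defaults mirror the bench ratio
    of 5 cm3 of solution per 100 mg of humic acid.
    """
    _require(solution_volume > 0, "solution_volume must be > 0")
    _require(sorbent_mass > 0, "sorbent_mass must be > 0")
    records: list[SorptionRecord] = []
    for c0 in c0_list:
        _require(c0 >= 0, "initial concentrations must be >= 0")
        total = c0 * solution_volume
        c_eq = _langmuir_batch_equilibrium(
            total, solution_volume, sorbent_mass, isotherm.q_max, isotherm.k_l
        )
        c_eq = min(c_eq, c0)
        sorbed = total - c_eq * solution_volume
        mobile = (1.0 - isotherm.strong_fraction_at(c0)) * sorbed
        c_leach = _langmuir_batch_equilibrium(
            mobile, solution_volume, sorbent_mass, isotherm.q_max, isotherm.k_l
        )
        records.append(
            SorptionRecord(
                c0=c0,
                c_eq_ads=c_eq,
                c_leach=c_leach,
                solution_volume=solution_volume,
                sorbent_mass=sorbent_mass,
            )
        )
    return records
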