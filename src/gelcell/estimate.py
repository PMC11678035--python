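"""Estimators recovering transport parameters from diffusion-cell traces.

The experiment has two stages.  Before the lag time the drug front is still
crossing the slab and nothing has reached the acceptor; the lag time ``t_L``
of the quasi-steady cumulative-permeation line gives the first-stage
diffusivity ``D_L = L^2 / (6 t_L)``.  After breakthrough the gel is
saturated and the per-record flux together with the donor/acceptor
concentration difference gives the effective (second-stage) diffusivity
``D_E = -j L / dc`` with ``dc = c_acceptor - c_donor``.

Comparing an inert gel with a reactive (humic-enriched) one at either stage
yields the apparent binding equilibrium constant ``K = D_inert /
D_reactive - 1``, because linear instantaneous binding retards transport by
``1 + K``.  Finally, the mass balance of the closed cell gives the mean
drug concentration inside the gel and hence the gel/solution partition
coefficient ``epsilon = c_gel / c_solution``; for reactive gels the bound
drug cannot be separated from the free drug by mass balance, so this
estimator returns ``epsilon * (1 + K)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, NamedTuple

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .errors import EstimationError, ValidationError
from .simulate import CellGeometry, ConcentrationTrace, NoiseModel, add_noise

__all__ = [
    "Estimate",
    "StageSplit",
    "FluxSeries",
    "DiffusionEstimates",
    "EquilibriumConstantEstimate",
    "estimate_lag_time",
    "lag_time_uncertainty",
    "d_from_lag",
    "flux_series",
    "effective_diffusivity",
    "apparent_equilibrium_constant",
    "partition_coefficient",
    "analyze_single",
    "analyze_trace_pair",
]


class Estimate(NamedTuple):
    """A point estimate with a standard deviation (0 when not resolvable)."""

    value: float
    sd: float


@dataclass
class StageSplit:
    """Lag time plus the induced partition of a trace into the two stages."""

    t_L: float
    n_samples: int
    split_index: int  # first sample with time > t_L
    method: str
    diagnostics: dict = field(default_factory=dict)

    @property
    def first_stage(self) -> range:
        return range(0, self.split_index)

    @property
    def second_stage(self) -> range:
        return range(self.split_index, self.n_samples)


@dataclass
class FluxSeries:
    """Per-record flux, concentration difference and effective diffusivity.

    One entry per consecutive pair of trace samples.  ``delta_c`` follows
    the acceptor-minus-donor convention, so ``d_e = -flux_j * L / delta_c``
    is positive for transport toward the acceptor.  Records whose
    ``|delta_c|`` falls below the degeneracy floor are flagged invalid and
    excluded from averages.
    """

    midpoint_times: np.ndarray
    flux_j: np.ndarray
    delta_c: np.ndarray
    d_e: np.ndarray
    valid: np.ndarray
    delta_c_floor: float


@dataclass
class EquilibriumConstantEstimate:
    """Apparent binding constant from an inert/reactive diffusivity ratio."""

    k_hat: float
    stage: str
    d_inert: float
    d_reactive: float


@dataclass
class DiffusionEstimates:
    """The full per-trace estimate set in SI units."""

    t_l: Estimate
    d_l: Estimate
    d_e: Estimate
    epsilon_hat: Estimate
    split: StageSplit
    lag_method: str
    epsilon_evaluation: str


def _noise_floor(trace: ConcentrationTrace) -> float:
    """Acceptor noise floor estimated from the pre-breakthrough baseline."""
    n = len(trace)
    k = max(5, n // 20)
    if n < 3:
        return 0.0
    return float(np.std(trace.c_acceptor[: min(k, n)], ddof=1))


def estimate_lag_time(
    trace: ConcentrationTrace,
    geometry: CellGeometry,
    method: Literal["extrapolation", "threshold"] = "extrapolation",
    *,
    noise_floor: float | None = None,
    threshold_multiple: float = 3.0,
    slope_tol: float = 0.01,
    min_points: int = 10,
    drive_correction: bool = True,
) -> StageSplit:
    """Locate the lag time and split the trace into its two stages.

    ``extrapolation`` (default) is the classical time-lag construction: the
    cumulative acceptor amount ``Q(t) = V_a c_a(t)`` is fitted with a
    straight line over its quasi-steady window and the positive time-axis
    intercept is returned.  Two refinements make the construction robust on
    finite cells:

    * the quasi-steady window is the contiguous run of records whose
      (smoothed) permeation rate lies within ``slope_tol`` of its maximum —
      the region where the flux has genuinely plateaued.  If that run has
      fewer than ``min_points`` records (noisy traces), the trailing 30% of
      post-breakthrough records is used instead;
    * with ``drive_correction`` (default) the fit abscissa is the
      driving-force-corrected time ``theta(t) = int_0^t (c_d - c_a) ds /
      (c_d(0) - c_a(0))``, which undoes the curvature caused by donor
      depletion in finite reservoirs; the intercept is mapped back to real
      time.  For a near-constant donor ``theta`` equals ``t``.

    ``threshold`` returns the first time the acceptor concentration exceeds
    ``threshold_multiple`` times the noise floor (estimated from the early
    baseline when not given).
    """
    n = len(trace)
    if n < 3:
        raise EstimationError("trace too short to estimate a lag time")
    nf = _noise_floor(trace) if noise_floor is None else float(noise_floor)
    c_ref = max(float(trace.c_donor[0]), float(trace.c_acceptor.max()), 1e-300)
    floor = max(threshold_multiple * nf, 1e-9 * c_ref)

    above = trace.c_acceptor > floor
    if not above.any():
        raise EstimationError(
            "no breakthrough: acceptor concentration never exceeds "
            f"{floor:.3g} g/m3 within the trace"
        )
    i_break = int(np.argmax(above))

    if method == "threshold":
        if i_break == 0:
            raise EstimationError("acceptor already above the noise floor at t=0")
        t_l = float(trace.times[i_break])
        diag = {"i_break": i_break, "floor": floor}
        return _make_split(trace, t_l, "threshold", diag)

    if method != "extrapolation":
        raise ValidationError(f"unknown lag-time method: {method!r}")

    t = trace.times
    q = geometry.acceptor_volume * trace.c_acceptor
    if drive_correction:
        drive = trace.c_donor - trace.c_acceptor
        drive0 = float(drive[0])
        if drive0 <= 0:
            raise EstimationError("no initial donor/acceptor driving force")
        theta = cumulative_trapezoid(drive, t, initial=0.0) / drive0
    else:
        theta = t

    rate = np.gradient(q, theta)
    w = max(3, (n - i_break) // 10)
    w += (w + 1) % 2  # odd window
    smoothed = np.convolve(rate, np.ones(w) / w, mode="same")
    interior = np.arange(i_break, max(n - w // 2, i_break + 1))
    i_peak = int(interior[np.argmax(smoothed[interior])])
    peak = smoothed[i_peak]
    if not np.isfinite(peak) or peak <= 0:
        raise EstimationError("quasi-steady permeation rate is non-positive")
    ok = smoothed >= (1.0 - slope_tol) * peak
    lo = i_peak
    while lo > i_break and ok[lo - 1]:
        lo -= 1
    hi = i_peak
    while hi < n - 1 and ok[hi + 1]:
        hi += 1
    window_rule = "plateau"
    if hi - lo + 1 < min_points:
        lo = max(i_break, n - max(min_points, int(0.3 * (n - i_break))))
        hi = n - 1
        window_rule = "trailing30"
    if hi - lo + 1 < 2:
        raise EstimationError("quasi-steady window has fewer than 2 records")
    a, b = np.polyfit(theta[lo : hi + 1], q[lo : hi + 1], 1)
    if not np.isfinite(a) or a <= 0:
        raise EstimationError("quasi-steady fit has non-positive slope; no usable window")
    theta_l = -b / a
    if theta_l <= 0:
        raise EstimationError(
            f"time-lag intercept is non-positive (theta_L = {theta_l:.3g} s); "
            "the trace may start after breakthrough"
        )
    t_l = float(np.interp(theta_l, theta, t))
    diag = {
        "i_break": i_break,
        "floor": floor,
        "window": (int(lo), int(hi)),
        "window_rule": window_rule,
        "window_points": int(hi - lo + 1),
        "slope": float(a),
        "intercept": float(b),
        "drive_correction": drive_correction,
    }
    return _make_split(trace, t_l, "extrapolation", diag)


def _make_split(trace: ConcentrationTrace, t_l: float, method: str, diag: dict) -> StageSplit:
    split_index = int(np.searchsorted(trace.times, t_l, side="right"))
    return StageSplit(
        t_L=t_l,
        n_samples=len(trace),
        split_index=split_index,
        method=method,
        diagnostics=diag,
    )


def lag_time_uncertainty(
    trace: ConcentrationTrace,
    geometry: CellGeometry,
    noise: NoiseModel,
    n_replicates: int = 25,
    **kwargs,
) -> tuple[Estimate, np.ndarray]:
    """Monte-Carlo spread of the lag estimate under the given noise model.

    Adds ``n_replicates`` independent noise realisations (seeds derived from
    ``noise.seed``) to the trace, re-estimates the lag each time, and
    returns (median, sd) together with the replicate values.
    """
    if n_replicates < 2:
        raise ValidationError("n_replicates must be >= 2")
    values = []
    for i in range(n_replicates):
        rep = add_noise(
            trace,
            NoiseModel(noise.relative_sd, noise.absolute_sd, seed=noise.seed + i),
        )
        try:
            values.append(estimate_lag_time(rep, geometry, **kwargs).t_L)
        except EstimationError:
            values.append(np.nan)
    arr = np.asarray(values)
    ok = arr[np.isfinite(arr)]
    if ok.size < 2:
        raise EstimationError("lag estimation failed on nearly all noise replicates")
    return Estimate(float(np.median(ok)), float(np.std(ok, ddof=1))), arr


def d_from_lag(t_l: float, thickness_L: float) -> float:
    """First-stage diffusivity from the lag time: ``D_L = L^2 / (6 t_L)``."""
    if t_l <= 0:
        raise ValidationError("t_l must be > 0")
    if thickness_L <= 0:
        raise ValidationError("thickness_L must be > 0")
    return thickness_L**2 / (6.0 * t_l)


def flux_series(
    trace: ConcentrationTrace,
    geometry: CellGeometry,
    *,
    side: Literal["donor", "acceptor", "both"] = "donor",
    delta_c_floor: float | None = None,
) -> FluxSeries:
    """Per-record flux and effective diffusivity from consecutive samples.

    The flux is computed from donor depletion by default (``j = -V_d dc_d /
    (dt A)``, positive toward the acceptor); ``side`` switches to acceptor
    accumulation or the average of both.  ``delta_c`` is the acceptor-minus-
    donor difference at the record midpoint.  The degeneracy floor defaults
    to 1% of the initial donor concentration: as the cell approaches
    equilibrium ``delta_c -> 0`` and the per-record diffusivity diverges, so
    such records are flagged and excluded.
    """
    n = len(trace)
    if n < 2:
        raise ValidationError("flux_series needs at least 2 records")
    area = geometry.exposed_area
    if area <= 0:
        raise ValidationError("exposed area must be positive")
    if delta_c_floor is None:
        c_ref = float(trace.c_donor[0])
        if c_ref <= 0:
            c_ref = float(max(trace.c_donor.max(), trace.c_acceptor.max(), 1.0))
        delta_c_floor = 0.01 * c_ref

    dt = np.diff(trace.times)
    mid_t = 0.5 * (trace.times[:-1] + trace.times[1:])
    j_donor = -geometry.donor_volume * np.diff(trace.c_donor) / (dt * area)
    j_acceptor = geometry.acceptor_volume * np.diff(trace.c_acceptor) / (dt * area)
    if side == "donor":
        j = j_donor
    elif side == "acceptor":
        j = j_acceptor
    elif side == "both":
        j = 0.5 * (j_donor + j_acceptor)
    else:
        raise ValidationError(f"unknown flux side: {side!r}")

    mid_d = 0.5 * (trace.c_donor[:-1] + trace.c_donor[1:])
    mid_a = 0.5 * (trace.c_acceptor[:-1] + trace.c_acceptor[1:])
    delta_c = mid_a - mid_d
    valid = np.abs(delta_c) >= delta_c_floor
    d_e = np.full(n - 1, np.nan)
    L = geometry.thickness_L
    d_e[valid] = -j[valid] * L / delta_c[valid]
    return FluxSeries(mid_t, j, delta_c, d_e, valid, float(delta_c_floor))


def effective_diffusivity(flux: FluxSeries, split: StageSplit) -> Estimate:
    """Mean and sd of the per-record diffusivity over the second stage."""
    sel = flux.valid & (flux.midpoint_times > split.t_L) & np.isfinite(flux.d_e)
    if not sel.any():
        raise EstimationError(
            "no valid second-stage records: the trace may end before "
            "breakthrough or sit entirely below the delta-c floor"
        )
    vals = flux.d_e[sel]
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return Estimate(float(np.mean(vals)), sd)


def apparent_equilibrium_constant(
    d_inert: float, d_reactive: float, stage: str = ""
) -> EquilibriumConstantEstimate:
    """Apparent binding constant ``K = D_inert / D_reactive - 1``.

    With instantaneous linear binding the reactive-gel diffusivity is the
    inert one divided by the retardation factor ``1 + K``, so the ratio of
    the two diffusivities measured at the same stage recovers ``K``.
    """
    if d_inert <= 0 or d_reactive <= 0:
        raise ValidationError("diffusivities must be positive")
    return EquilibriumConstantEstimate(
        k_hat=d_inert / d_reactive - 1.0,
        stage=stage,
        d_inert=d_inert,
        d_reactive=d_reactive,
    )


def partition_coefficient(
    trace: ConcentrationTrace,
    geometry: CellGeometry,
    c0: float,
    evaluation: Literal["final", "window"] = "final",
    *,
    split: StageSplit | None = None,
    window_fraction: float = 0.25,
    negative_mass_tol: float = 0.02,
) -> Estimate:
    """Gel/solution partition coefficient from the closed-cell mass balance.

    The drug amount inside the gel is what the reservoirs no longer hold,
    ``m_h = V_d c0 - V_d c_d - V_a c_a``; dividing by the gel volume gives
    the mean gel concentration and ``epsilon_hat = c_h / ((c_d + c_a)/2)``.
    The balance cannot distinguish bound from free drug, so for a reactive
    gel this estimates ``epsilon * (1 + K)``.

    ``evaluation='final'`` uses the last record; ``'window'`` averages over
    the trailing ``window_fraction`` of the second stage (of the whole trace
    when no split is given).
    """
    if c0 <= 0:
        raise ValidationError("c0 must be > 0")
    v_d, v_a = geometry.donor_volume, geometry.acceptor_volume
    m_h = v_d * c0 - v_d * trace.c_donor - v_a * trace.c_acceptor
    if m_h.min() < -negative_mass_tol * v_d * c0:
        raise ValidationError(
            "mass balance violation: reservoirs hold more drug than was "
            "loaded (beyond noise tolerance); check c0 and the volumes"
        )
    c_h = m_h / geometry.gel_volume
    denom = 0.5 * (trace.c_donor + trace.c_acceptor)
    with np.errstate(divide="ignore", invalid="ignore"):
        eps_series = np.where(denom > 0, c_h / denom, np.nan)

    if evaluation == "final":
        val = eps_series[-1]
        if not np.isfinite(val):
            raise EstimationError("partition coefficient undefined at the final record")
        return Estimate(float(max(val, 0.0)), 0.0)
    if evaluation != "window":
        raise ValidationError(f"unknown evaluation mode: {evaluation!r}")

    start = split.split_index if split is not None else 0
    lo = start + int((1.0 - window_fraction) * (len(trace) - start))
    lo = min(max(lo, start), len(trace) - 1)
    window = eps_series[lo:]
    window = window[np.isfinite(window)]
    if window.size == 0:
        raise EstimationError("no finite records in the partition evaluation window")
    sd = float(np.std(window, ddof=1)) if window.size > 1 else 0.0
    return Estimate(float(max(np.mean(window), 0.0)), sd)


def analyze_single(
    trace: ConcentrationTrace,
    geometry: CellGeometry,
    *,
    c0: float | None = None,
    method: Literal["extrapolation", "threshold"] = "extrapolation",
    epsilon_evaluation: Literal["final", "window"] = "window",
    flux_side: Literal["donor", "acceptor", "both"] = "donor",
    noise: NoiseModel | None = None,
    n_replicates: int = 0,
    **lag_kwargs,
) -> DiffusionEstimates:
    """Run the full estimation chain on one trace.

    When a noise model and ``n_replicates >= 2`` are supplied, the lag-time
    uncertainty is measured by Monte-Carlo replication; otherwise the sd is
    reported as 0.  ``c0`` defaults to the first donor sample.
    """
    if c0 is None:
        c0 = float(trace.c_donor[0])
    split = estimate_lag_time(trace, geometry, method, **lag_kwargs)
    t_l_sd = 0.0
    if noise is not None and n_replicates >= 2:
        (_, t_l_sd), _ = lag_time_uncertainty(
            trace, geometry, noise, n_replicates, method=method, **lag_kwargs
        )
    d_l = d_from_lag(split.t_L, geometry.thickness_L)
    d_l_sd = d_l * t_l_sd / split.t_L
    flux = flux_series(trace, geometry, side=flux_side)
    d_e = effective_diffusivity(flux, split)
    eps = partition_coefficient(trace, geometry, c0, epsilon_evaluation, split=split)
    return DiffusionEstimates(
        t_l=Estimate(split.t_L, t_l_sd),
        d_l=Estimate(d_l, d_l_sd),
        d_e=d_e,
        epsilon_hat=eps,
        split=split,
        lag_method=method,
        epsilon_evaluation=epsilon_evaluation,
    )


def estimates_row(est: DiffusionEstimates, sample: str) -> dict:
    """One tidy results row with bench units (minutes, 1e-10 m2/s)."""
    return {
        "sample": sample,
        "t_L_min": est.t_l.value / 60.0,
        "t_L_sd_min": est.t_l.sd / 60.0,
        "D_L_e10": est.d_l.value * 1e10,
        "D_E_e10": est.d_e.value * 1e10,
        "D_E_sd_e10": est.d_e.sd * 1e10,
        "epsilon": est.epsilon_hat.value,
        "epsilon_sd": est.epsilon_hat.sd,
    }


def analyze_trace_pair(
    inert_trace: ConcentrationTrace,
    reactive_trace: ConcentrationTrace,
    geometry: CellGeometry,
    *,
    c0_inert: float | None = None,
    c0_reactive: float | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Full estimate table for an inert/reactive gel pair.

    Returns a tidy frame with one row per gel; the apparent equilibrium
    constants (first stage from the lag diffusivities, second stage from the
    effective diffusivities) are attached to the reactive row, mirroring the
    usual presentation of such experiments (lag in minutes, diffusivities in
    1e-10 m2/s).
    """
    est_i = analyze_single(inert_trace, geometry, c0=c0_inert, **kwargs)
    est_r = analyze_single(reactive_trace, geometry, c0=c0_reactive, **kwargs)
    k1 = apparent_equilibrium_constant(est_i.d_l.value, est_r.d_l.value, "first")
    k2 = apparent_equilibrium_constant(est_i.d_e.value, est_r.d_e.value, "second")
    rows = []
    for sample, est, kk1, kk2 in (
        ("inert", est_i, np.nan, np.nan),
        ("reactive", est_r, k1.k_hat, k2.k_hat),
    ):
        row = estimates_row(est, sample)
        row["K_first"] = kk1
        row["K_second"] = kk2
        rows.append(row)
    columns = [
        "sample",
        "t_L_min",
        "D_L_e10",
        "D_E_e10",
        "K_first",
        "K_second",
        "epsilon",
        "t_L_sd_min",
        "D_E_sd_e10",
        "epsilon_sd",
    ]
    return pd.DataFrame(rows)[columns]
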