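"""Two-tracer non-steady-state glucagon turnover (Steele formalism).

The systemic rate of appearance of endogenous glucagon is estimated by
isotope dilution: a labeled glucagon tracer (FF) is infused, its dilution
by endogenously secreted glucagon is tracked through the tracer-tracee
ratio TTR = C_FF / C_total, and the non-steady-state equations correct for
the changing pool content:

    Ra = F_FF / TTR - F_FF - F_FFLA - Vd * C * (dTTR/dt) / TTR
    Rd = Ra + F_FF + F_FFLA - Vd * (dC/dt)

Units convention (applied throughout): infusion rates F and turnover rates
Ra/Rd in pg/kg/min, concentrations in pg/ml, volume of distribution Vd in
ml/kg.  With these units every term of both equations is pg/kg/min and no
explicit body-weight factor appears (it is absorbed into Vd being per kg).

Derivatives are two-point finite differences over consecutive sampling
intervals; TTR and C enter as interval means and the result is assigned to
the interval midpoint (the classic discretization for non-steady-state
turnover).  The pool fraction multiplying the volume term defaults to 1,
with an optional multiplier for sensitivity analysis.

Vd itself comes from the decay of a tracer bolus, which follows a linear
one-compartment model C(t) = C0 * exp(-k t); Vd = (dose / C0) / TBW.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "InfusionSegment",
    "InfusionProtocol",
    "PlasmaTimeSeries",
    "KineticsResult",
    "VdFit",
    "compute_ttr",
    "rate_of_appearance",
    "rate_of_disappearance",
    "fit_volume_of_distribution",
    "endogenous_conc",
    "read_timeseries_csv",
    "write_kinetics_csv",
]


@dataclass(frozen=True)
class InfusionSegment:
    """One piecewise-constant infusion step: rate on [t_start, t_end)."""

    t_start: float
    t_end: float
    rate_pg_kg_min: float

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("segment must have t_end > t_start")
        if self.rate_pg_kg_min < 0:
            raise ValueError("infusion rate must be >= 0")


@dataclass(frozen=True)
class InfusionProtocol:
    """Tracer dosing: FF bolus plus piecewise-constant FF/FFLA infusions."""

    f_ff: tuple[InfusionSegment, ...] = ()
    f_ffla: tuple[InfusionSegment, ...] = ()
    bolus_pg: float = 0.0
    tbw_kg: float = 70.0

    def __post_init__(self) -> None:
        if self.tbw_kg <= 0:
            raise ValueError("total body weight must be > 0")
        if self.bolus_pg < 0:
            raise ValueError("bolus dose must be >= 0")

    @staticmethod
    def _rate(segments: tuple[InfusionSegment, ...], t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.zeros_like(t)
        for seg in segments:
            mask = (t >= seg.t_start) & (t < seg.t_end)
            out[mask] = seg.rate_pg_kg_min
        return out

    def f_ff_at(self, t) -> np.ndarray:
        """FF infusion rate (pg/kg/min) at time(s) t."""
        return self._rate(self.f_ff, t)

    def f_ffla_at(self, t) -> np.ndarray:
        return self._rate(self.f_ffla, t)

    def to_json(self) -> str:
        return json.dumps(
            {
                "bolus_pg": self.bolus_pg,
                "tbw_kg": self.tbw_kg,
                "f_ff": [
                    [s.t_start, s.t_end, s.rate_pg_kg_min] for s in self.f_ff
                ],
                "f_ffla": [
                    [s.t_start, s.t_end, s.rate_pg_kg_min] for s in self.f_ffla
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "InfusionProtocol":
        data = json.loads(text)
        required = {"bolus_pg", "tbw_kg", "f_ff", "f_ffla"}
        missing = required - set(data)
        if missing:
            raise ValueError(f"protocol JSON missing keys: {sorted(missing)}")
        return cls(
            f_ff=tuple(InfusionSegment(*row) for row in data["f_ff"]),
            f_ffla=tuple(InfusionSegment(*row) for row in data["f_ffla"]),
            bolus_pg=float(data["bolus_pg"]),
            tbw_kg=float(data["tbw_kg"]),
        )


@dataclass
class PlasmaTimeSeries:
    """Sampled plasma concentrations of tracers and total glucagon.

    ``c_total`` is the immunoassay (ELISA) total — endogenous plus both
    tracers, since the antibody cannot distinguish them.  Negative measured
    values are kept (assay noise) but flagged by consumers rather than
    silently dropped.
    """

    time_min: np.ndarray
    c_ff_pg_ml: np.ndarray
    c_ffla_pg_ml: np.ndarray | None = None
    c_total_pg_ml: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.c_ff_pg_ml = np.asarray(self.c_ff_pg_ml, dtype=float)
        if self.c_ffla_pg_ml is not None:
            self.c_ffla_pg_ml = np.asarray(self.c_ffla_pg_ml, dtype=float)
        if self.c_total_pg_ml is not None:
            self.c_total_pg_ml = np.asarray(self.c_total_pg_ml, dtype=float)
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError("sampling times must be strictly increasing")
        for name in ("c_ff_pg_ml", "c_ffla_pg_ml", "c_total_pg_ml"):
            arr = getattr(self, name)
            if arr is not None and arr.shape != self.time_min.shape:
                raise ValueError(f"{name} length differs from time grid")

    def __len__(self) -> int:
        return len(self.time_min)


def endogenous_conc(series: PlasmaTimeSeries) -> tuple[np.ndarray, np.ndarray]:
    """Endogenous glucagon = total (ELISA) minus both tracers.

    Returns ``(c_endo, below_zero_flags)``; negative differences (assay
    noise near the detection limit) are reported as-is and flagged.
    """
    if series.c_total_pg_ml is None or series.c_ffla_pg_ml is None:
        raise ValueError(
            "endogenous concentration needs c_total and c_ffla channels"
        )
    c_endo = series.c_total_pg_ml - series.c_ff_pg_ml - series.c_ffla_pg_ml
    return c_endo, c_endo < 0


def compute_ttr(
    c_ff: np.ndarray,
    c_total: np.ndarray,
    c_ffla: np.ndarray | None = None,
    denominator: str = "total",
) -> np.ndarray:
    """Tracer-tracee ratio series.

    Default definition is FF tracer over *total* glucagon (the operational
    definition used with an ELISA total that includes the tracers).  With
    ``denominator="tracee"`` the classical TTR over endogenous glucagon
    (total minus both tracers) is returned instead; that mode requires the
    FFLA channel.  Points with a non-positive denominator yield NaN.
    """
    c_ff = np.asarray(c_ff, dtype=float)
    c_total = np.asarray(c_total, dtype=float)
    if denominator == "total":
        denom = c_total
    elif denominator == "tracee":
        if c_ffla is None:
            raise ValueError("tracee mode requires the FFLA channel")
        denom = c_total - c_ff - np.asarray(c_ffla, dtype=float)
    else:
        raise ValueError("denominator must be 'total' or 'tracee'")
    with np.errstate(divide="ignore", invalid="ignore"):
        ttr = np.where(denom > 0, c_ff / denom, np.nan)
    return ttr


@dataclass
class KineticsResult:
    """Midpoint-grid turnover estimates with per-interval flags."""

    t_mid_min: np.ndarray
    ttr_mid: np.ndarray
    ra_pg_kg_min: np.ndarray
    rd_pg_kg_min: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        data = {
            "t_mid_min": self.t_mid_min,
            "ttr": self.ttr_mid,
            "ra_pg_kg_min": self.ra_pg_kg_min,
        }
        if self.rd_pg_kg_min is not None:
            data["rd_pg_kg_min"] = self.rd_pg_kg_min
        df = pd.DataFrame(data)
        df["flags"] = self.flags
        return df


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(values, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad : pad + len(values)]
    return out


def rate_of_appearance(
    protocol: InfusionProtocol,
    series: PlasmaTimeSeries,
    vd_ml_kg: float,
    ttr_denominator: str = "total",
    pool_fraction: float = 1.0,
    smoothing_window: int = 1,
) -> KineticsResult:
    """Endogenous glucagon rate of appearance on interval midpoints.

    Per consecutive-sample interval::

        Ra = F_FF / TTR_bar - F_FF - F_FFLA
             - pool_fraction * Vd * C_bar * (dTTR/dt) / TTR_bar

    with two-point means TTR_bar and C_bar, the two-point finite difference
    dTTR/dt, and infusion rates evaluated at the interval midpoint.
    Intervals with undefined or non-positive TTR produce NaN and a flag.
    """
    if vd_ml_kg <= 0:
        raise ValueError("volume of distribution must be > 0")
    if series.c_total_pg_ml is None:
        raise ValueError("rate of appearance needs the total-glucagon channel")
    t = series.time_min
    ttr = compute_ttr(
        series.c_ff_pg_ml,
        series.c_total_pg_ml,
        series.c_ffla_pg_ml,
        denominator=ttr_denominator,
    )
    ttr = _smooth(ttr, smoothing_window)
    c = _smooth(series.c_total_pg_ml.astype(float), smoothing_window)

    t_mid = 0.5 * (t[:-1] + t[1:])
    dt = np.diff(t)
    ttr_bar = 0.5 * (ttr[:-1] + ttr[1:])
    c_bar = 0.5 * (c[:-1] + c[1:])
    dttr_dt = np.diff(ttr) / dt
    f_ff = protocol.f_ff_at(t_mid)
    f_ffla = protocol.f_ffla_at(t_mid)

    if np.all(f_ff == 0) and protocol.bolus_pg == 0 and np.nanmax(ttr) > 0:
        raise ValueError(
            "zero FF tracer administration but nonzero TTR: inconsistent input"
        )

    ra = np.full_like(t_mid, np.nan)
    flags = []
    valid = np.isfinite(ttr_bar) & (ttr_bar > 0)
    ra[valid] = (
        f_ff[valid] / ttr_bar[valid]
        - f_ff[valid]
        - f_ffla[valid]
        - pool_fraction * vd_ml_kg * c_bar[valid] * dttr_dt[valid] / ttr_bar[valid]
    )
    for i in range(len(t_mid)):
        if not valid[i]:
            flags.append("undefined_ttr")
        elif ra[i] < 0:
            flags.append("negative_ra")
        else:
            flags.append("")
    return KineticsResult(
        t_mid_min=t_mid, ttr_mid=ttr_bar, ra_pg_kg_min=ra, flags=flags
    )


def rate_of_disappearance(
    ra: KineticsResult,
    protocol: InfusionProtocol,
    series: PlasmaTimeSeries,
    vd_ml_kg: float,
    smoothing_window: int = 1,
) -> KineticsResult:
    """Rate of disappearance on the same midpoint grid as ``ra``.

    Rd = Ra + F_FF + F_FFLA - Vd * (dC/dt), with C the total glucagon
    concentration; Vd in ml/kg makes the volume term pg/kg/min directly.
    """
    if series.c_total_pg_ml is None:
        raise ValueError("rate of disappearance needs the total-glucagon channel")
    t = series.time_min
    t_mid = 0.5 * (t[:-1] + t[1:])
    if len(t_mid) != len(ra.t_mid_min) or not np.allclose(t_mid, ra.t_mid_min):
        raise ValueError("Ra grid does not match the supplied time series")
    c = _smooth(series.c_total_pg_ml.astype(float), smoothing_window)
    dc_dt = np.diff(c) / np.diff(t)
    f_ff = protocol.f_ff_at(t_mid)
    f_ffla = protocol.f_ffla_at(t_mid)
    rd = ra.ra_pg_kg_min + f_ff + f_ffla - vd_ml_kg * dc_dt
    flags = [
        f0 if f0 else ("negative_rd" if np.isfinite(v) and v < 0 else "")
        for f0, v in zip(ra.flags, rd)
    ]
    return KineticsResult(
        t_mid_min=ra.t_mid_min,
        ttr_mid=ra.ttr_mid,
        ra_pg_kg_min=ra.ra_pg_kg_min,
        rd_pg_kg_min=rd,
        flags=flags,
    )


@dataclass(frozen=True)
class VdFit:
    """Mono-exponential bolus-decay fit and the derived distribution volume."""

    vd_ml_kg: float
    k_elim_per_min: float
    c0_pg_ml: float
    c0_se: float
    k_se: float
    residual_sd: float

    @property
    def half_life_min(self) -> float:
        return np.log(2.0) / self.k_elim_per_min


def fit_volume_of_distribution(
    bolus_pg: float,
    time_min: Sequence[float],
    c_ff_pg_ml: Sequence[float],
    tbw_kg: float,
) -> VdFit:
    """Fit C(t) = C0 exp(-k t) to post-bolus tracer decay.

    Nonlinear least squares (Levenberg-Marquardt via
    :func:`scipy.optimize.curve_fit`); Vd = (bolus / C0) / TBW in ml/kg.
    Standard errors come from the fit covariance; a non-decaying profile is
    reported as a fit failure.
    """
    if bolus_pg <= 0:
        raise ValueError("bolus dose must be > 0")
    if tbw_kg <= 0:
        raise ValueError("total body weight must be > 0")
    t = np.asarray(time_min, dtype=float)
    c = np.asarray(c_ff_pg_ml, dtype=float)
    if len(t) < 3:
        raise ValueError("need >= 3 post-bolus samples to fit the decay")
    if np.any(c <= 0):
        raise RuntimeError("non-positive concentrations: cannot fit decay")

    def model(tt, c0, k):
        return c0 * np.exp(-k * tt)

    # Log-linear start values; slope sign screens out non-decaying input.
    slope, logc0 = np.polyfit(t, np.log(c), 1)
    if slope >= 0:
        raise RuntimeError(
            "concentrations do not decay over time; one-compartment bolus "
            "model does not apply"
        )
    popt, pcov = optimize.curve_fit(
        model, t, c, p0=[np.exp(logc0), -slope], maxfev=10000
    )
    c0, k = popt
    if c0 <= 0 or k <= 0:
        raise RuntimeError("fit converged to non-physical parameters")
    se = np.sqrt(np.diag(pcov))
    resid = c - model(t, *popt)
    dof = max(len(t) - 2, 1)
    return VdFit(
        vd_ml_kg=(bolus_pg / c0) / tbw_kg,
        k_elim_per_min=float(k),
        c0_pg_ml=float(c0),
        c0_se=float(se[0]),
        k_se=float(se[1]),
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
    )


TIMESERIES_COLUMNS = ["time_min", "c_ff_pg_ml", "c_ffla_pg_ml", "c_total_pg_ml"]


def read_timeseries_csv(path) -> PlasmaTimeSeries:
    df = pd.read_csv(path)
    missing = [c for c in TIMESERIES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"time-series CSV missing columns: {missing}")
    return PlasmaTimeSeries(
        time_min=df["time_min"].to_numpy(),
        c_ff_pg_ml=df["c_ff_pg_ml"].to_numpy(),
        c_ffla_pg_ml=df["c_ffla_pg_ml"].to_numpy(),
        c_total_pg_ml=df["c_total_pg_ml"].to_numpy(),
    )


def write_kinetics_csv(result: KineticsResult, path) -> None:
    result.to_frame().to_csv(path, index=False)
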