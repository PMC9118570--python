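"""Forward simulation of tracer studies and assay peak-area tables.

The plasma simulator integrates the one-compartment model underlying the
turnover analysis: each glucagon pool (endogenous, FF tracer, FFLA tracer)
obeys

    dC/dt = input(t) / Vd - k * C            [pg/ml/min]

where input is the endogenous rate of appearance or a tracer infusion rate
(pg/kg/min), Vd is the distribution volume (ml/kg) and k the first-order
elimination constant (1/min).  A tracer bolus appears instantaneously as
C(0+) = dose / (Vd * TBW).  The ELISA "total" channel is the sum of all
three pools, since the immunoassay cannot distinguish tracer from
endogenous glucagon.

Measurement noise is multiplicative Gaussian per channel (assay precision
is quoted as CV%, i.e. scale-proportional error), with draws truncated at
-3 sigma by default so noisy concentrations stay positive.

Default study conditions: Vd = 40 ml/kg (the cohort estimate from bolus
decay), k = 0.1/min (a ~7 min glucagon half-life), basal endogenous Ra
sized so fasting endogenous glucagon sits near 70 pg/ml, tracer infusions
sized for ~5% enrichment, and channel CVs at the assay's validated
intra-day precision (tracers ~5%, ELISA total ~7%).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from glucagon_idms.kinetics import (
    InfusionProtocol,
    InfusionSegment,
    PlasmaTimeSeries,
)

__all__ = [
    "TABLE_DESIGNS",
    "QC_DESIGN",
    "DEFAULT_NOISE_CV",
    "SimulationTruth",
    "SyntheticDataset",
    "postprandial_ra_profile",
    "simulate_kinetics",
    "simulate_calibration",
    "bolus_decay_truth",
    "postprandial_truth",
]

# Calibration ladders (pg/ml): seven levels per species; the unlabeled
# species spans 3.125-200, the heavy tracers 1.56-100.
TABLE_DESIGNS: Mapping[str, tuple[float, ...]] = {
    "light": (3.125, 6.25, 12.5, 25.0, 50.0, 100.0, 200.0),
    "FF": (1.56, 3.125, 6.25, 12.5, 25.0, 50.0, 100.0),
    "FFLA": (1.56, 3.125, 6.25, 12.5, 25.0, 50.0, 100.0),
}

# Plasma QC levels (pg/ml): heavy tracers at QC1/QC2, light at 2x those.
QC_DESIGN: Mapping[str, Mapping[str, float]] = {
    "light": {"QC1": 26.67, "QC2": 80.0},
    "FF": {"QC1": 13.33, "QC2": 40.0},
    "FFLA": {"QC1": 13.33, "QC2": 40.0},
}

# Per-channel assay CVs (fractions): tracers at the LC-MS assay's intra-day
# precision, total at the ELISA's intra-assay precision.
DEFAULT_NOISE_CV: Mapping[str, float] = {"ff": 0.055, "ffla": 0.045, "total": 0.07}

# Between-day multiplicative batch effect for multi-day QC simulation,
# sized so total inter-day CV lands near the validated inter-day figures.
DEFAULT_DAY_CV = 0.13

# Default arterialized-blood sampling schedule (min): dense immediately
# after the bolus to capture the decay, then sparse to the 350-min end
# point of a postprandial study.
DEFAULT_SAMPLE_TIMES = (
    1.0, 2.0, 3.0, 5.0, 7.0, 10.0, 15.0, 20.0, 30.0, 45.0, 60.0,
    90.0, 120.0, 150.0, 180.0, 210.0, 240.0, 270.0, 300.0, 330.0, 350.0,
)


def postprandial_ra_profile(
    basal: float, peak: float, t_peak: float, decay: float | None = None
):
    """Gamma-like endogenous Ra pulse: basal rise to ``peak`` at ``t_peak``.

    Returns a vectorized function of time (min) giving Ra in pg/kg/min::

        Ra(t) = basal + (peak - basal) * (t/t_peak)^a * exp(a * (1 - t/t_peak))

    with shape a = t_peak/decay (a = 1 when ``decay`` is omitted, i.e. the
    falling limb shares the rise time constant).  The pulse equals basal at
    t = 0, peaks exactly at t_peak, and relaxes back to basal.
    """
    if basal < 0 or peak < basal:
        raise ValueError("need 0 <= basal <= peak")
    if t_peak <= 0:
        raise ValueError("t_peak must be > 0")
    if decay is None:
        decay = t_peak
    if decay <= 0:
        raise ValueError("decay must be > 0")
    a = t_peak / decay

    def ra(t):
        t = np.asarray(t, dtype=float)
        u = np.clip(t / t_peak, 0.0, None)
        with np.errstate(invalid="ignore"):
            pulse = np.where(u > 0, u**a * np.exp(a * (1.0 - u)), 0.0)
        return basal + (peak - basal) * pulse

    return ra


@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth parameters of a simulated tracer study.

    ``ra_endo_params`` are the :func:`postprandial_ra_profile` arguments
    (a constant basal Ra is peak == basal); keeping them as plain numbers
    keeps the truth JSON-serializable for recovery tests.
    """

    vd_ml_kg: float
    k_elim_per_min: float
    ra_endo_params: Mapping[str, float]
    protocol: InfusionProtocol
    sample_times_min: tuple[float, ...] = DEFAULT_SAMPLE_TIMES
    noise_cv: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NOISE_CV)
    )
    seed: int = 0
    solver_dt_min: float = 0.1
    start_at_steady_state: bool = False
    allow_negative: bool = False

    def __post_init__(self) -> None:
        if self.vd_ml_kg <= 0 or self.k_elim_per_min <= 0:
            raise ValueError("Vd and k must be > 0")
        if any(cv < 0 for cv in self.noise_cv.values()):
            raise ValueError("noise CVs must be >= 0")

    @property
    def ra_endo(self):
        return postprandial_ra_profile(**self.ra_endo_params)

    def to_json(self) -> str:
        data = asdict(self)
        data["protocol"] = json.loads(self.protocol.to_json())
        return json.dumps(data, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimulationTruth":
        data = json.loads(text)
        data["protocol"] = InfusionProtocol.from_json(
            json.dumps(data["protocol"])
        )
        data["sample_times_min"] = tuple(data["sample_times_min"])
        return cls(**data)


@dataclass
class SyntheticDataset:
    """Simulator output: matched noiseless and noisy sampled series."""

    noiseless: PlasmaTimeSeries
    noisy: PlasmaTimeSeries
    truth: SimulationTruth
    fine_time_min: np.ndarray
    fine_c_endo: np.ndarray
    fine_c_ff: np.ndarray
    fine_c_ffla: np.ndarray

    def true_ra(self, t) -> np.ndarray:
        """Ground-truth endogenous Ra (pg/kg/min) at arbitrary times."""
        return self.truth.ra_endo(t)

    def write(self, outdir) -> None:
        """Write noisy/noiseless CSVs plus the truth JSON to a directory."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, series in (("noisy", self.noisy), ("noiseless", self.noiseless)):
            pd.DataFrame(
                {
                    "time_min": series.time_min,
                    "c_ff_pg_ml": series.c_ff_pg_ml,
                    "c_ffla_pg_ml": series.c_ffla_pg_ml,
                    "c_total_pg_ml": series.c_total_pg_ml,
                }
            ).to_csv(outdir / f"plasma_{name}.csv", index=False)
        (outdir / "truth.json").write_text(self.truth.to_json())
        (outdir / "protocol.json").write_text(self.truth.protocol.to_json())


def _rk4(rate_fn, c0: float, t_grid: np.ndarray, k: float, vd: float) -> np.ndarray:
    """Integrate dC/dt = rate(t)/Vd - k*C with classic fixed-step RK4."""
    c = np.empty_like(t_grid)
    c[0] = c0

    def f(t, y):
        return rate_fn(t) / vd - k * y

    for i in range(len(t_grid) - 1):
        t, h = t_grid[i], t_grid[i + 1] - t_grid[i]
        y = c[i]
        k1 = f(t, y)
        k2 = f(t + h / 2, y + h / 2 * k1)
        k3 = f(t + h / 2, y + h / 2 * k2)
        k4 = f(t + h, y + h * k3)
        c[i + 1] = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    return c


def simulate_kinetics(truth: SimulationTruth) -> SyntheticDataset:
    """Forward-simulate plasma concentration channels for a tracer study.

    Solves the three pool ODEs on a fine grid (RK4, ``solver_dt_min``),
    samples at ``truth.sample_times_min`` and applies per-channel
    multiplicative Gaussian noise.  With ``start_at_steady_state`` the
    initial pools equal their infusion/basal steady states (an ideally
    primed protocol); the FF bolus always adds dose/(Vd*TBW) to C_FF(0).
    """
    times = np.asarray(truth.sample_times_min, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("sample times must be strictly increasing")
    dt = truth.solver_dt_min
    if dt > np.min(np.diff(times)):
        raise ValueError(
            "solver step exceeds the smallest sampling interval; "
            "reduce solver_dt_min"
        )
    t_end = times[-1]
    n_steps = int(np.ceil(t_end / dt))
    grid = np.linspace(0.0, n_steps * dt, n_steps + 1)

    vd, k = truth.vd_ml_kg, truth.k_elim_per_min
    proto = truth.protocol
    ra_endo = truth.ra_endo

    def scalar(fn):
        return lambda t: float(np.asarray(fn(t)).reshape(-1)[0])

    c_endo0 = float(ra_endo(0.0)) / (k * vd) if truth.start_at_steady_state else 0.0
    c_ff0 = proto.bolus_pg / (vd * proto.tbw_kg)
    c_ffla0 = 0.0
    if truth.start_at_steady_state:
        c_ff0 += float(proto.f_ff_at(0.0)[0]) / (k * vd)
        c_ffla0 += float(proto.f_ffla_at(0.0)[0]) / (k * vd)

    c_endo = _rk4(scalar(ra_endo), c_endo0, grid, k, vd)
    c_ff = _rk4(scalar(proto.f_ff_at), c_ff0, grid, k, vd)
    c_ffla = _rk4(scalar(proto.f_ffla_at), c_ffla0, grid, k, vd)

    s_endo = np.interp(times, grid, c_endo)
    s_ff = np.interp(times, grid, c_ff)
    s_ffla = np.interp(times, grid, c_ffla)
    s_total = s_endo + s_ff + s_ffla

    noiseless = PlasmaTimeSeries(
        time_min=times,
        c_ff_pg_ml=s_ff,
        c_ffla_pg_ml=s_ffla,
        c_total_pg_ml=s_total,
    )

    rng = np.random.default_rng(truth.seed)

    def noisy_channel(values, cv):
        z = rng.standard_normal(len(values))
        if not truth.allow_negative:
            z = np.maximum(z, -3.0)
        return values * (1.0 + cv * z)

    noisy = PlasmaTimeSeries(
        time_min=times,
        c_ff_pg_ml=noisy_channel(s_ff, truth.noise_cv.get("ff", 0.0)),
        c_ffla_pg_ml=noisy_channel(s_ffla, truth.noise_cv.get("ffla", 0.0)),
        c_total_pg_ml=noisy_channel(s_total, truth.noise_cv.get("total", 0.0)),
    )
    return SyntheticDataset(
        noiseless=noiseless,
        noisy=noisy,
        truth=truth,
        fine_time_min=grid,
        fine_c_endo=c_endo,
        fine_c_ff=c_ff,
        fine_c_ffla=c_ffla,
    )


def simulate_calibration(
    concentrations: Sequence[float],
    slope: float,
    noise_cv: float,
    seed: int,
    species: str = "FF",
    n_replicates: int = 3,
    days: Sequence[int] = (1,),
    day_cv: float = 0.0,
    is_area: float = 2.0e5,
    is_cv: float = 0.02,
    noise_floor_area: float | None = None,
    include_blank: bool = True,
) -> pd.DataFrame:
    """Simulate a calibration/QC peak-area table.

    The analyte response is linear in concentration relative to the
    internal standard (spiked at 50 pg/ml): analyte_area =
    slope * conc * IS_area * (1 + cv * z), with an optional multiplicative
    day (batch) effect shared by all replicates of a day.  ``snr`` is the
    analyte area over a constant noise-floor area (default: the area a
    0.1 pg/ml analyte would give), and blank rows carry the noise floor
    itself.  Output follows the calibration CSV schema.
    """
    if slope <= 0:
        raise ValueError("response slope must be > 0")
    if noise_cv < 0 or day_cv < 0:
        raise ValueError("CVs must be >= 0")
    rng = np.random.default_rng(seed)
    if noise_floor_area is None:
        noise_floor_area = slope * 0.1 * is_area
    rows = []
    for day in days:
        day_factor = 1.0 + day_cv * max(rng.standard_normal(), -3.0)
        for level_idx, conc in enumerate(concentrations, start=1):
            for rep in range(1, n_replicates + 1):
                z = max(rng.standard_normal(), -3.0)
                z_is = max(rng.standard_normal(), -3.0)
                a_is = is_area * (1.0 + is_cv * z_is)
                a_analyte = slope * conc * a_is * day_factor * (1.0 + noise_cv * z)
                rows.append(
                    {
                        "species": species,
                        "level_id": f"Std{level_idx}",
                        "nominal_pg_ml": conc,
                        "day": day,
                        "replicate": rep,
                        "analyte_area": a_analyte,
                        "is_area": a_is,
                        "snr": a_analyte / noise_floor_area,
                    }
                )
        if include_blank:
            for rep in range(1, n_replicates + 1):
                z_is = max(rng.standard_normal(), -3.0)
                a_is = is_area * (1.0 + is_cv * z_is)
                a_blank = noise_floor_area * abs(
                    rng.standard_normal()
                ) * 0.3 + 0.1 * noise_floor_area
                rows.append(
                    {
                        "species": species,
                        "level_id": "blank",
                        "nominal_pg_ml": 0.0,
                        "day": day,
                        "replicate": rep,
                        "analyte_area": a_blank,
                        "is_area": a_is,
                        "snr": a_blank / noise_floor_area,
                    }
                )
    return pd.DataFrame(rows)


def bolus_decay_truth(
    seed: int = 0,
    vd_ml_kg: float = 40.0,
    k_elim_per_min: float = 0.1,
    tbw_kg: float = 70.0,
    bolus_pg: float = 7.0e5,
    noise_cv_ff: float = 0.10,
    n_samples: int = 12,
) -> SimulationTruth:
    """Bolus-only decay scenario for volume-of-distribution recovery.

    An FF bolus with no infusions; the FF channel then decays
    mono-exponentially from C0 = bolus/(Vd*TBW) regardless of endogenous
    secretion, which is held at basal.
    """
    sample_times = (1.0, 2.0, 3.0, 5.0, 7.0, 10.0, 15.0, 20.0, 25.0, 30.0, 40.0, 50.0)
    basal = 70.0 * k_elim_per_min * vd_ml_kg  # fasting C_endo ~ 70 pg/ml
    return SimulationTruth(
        vd_ml_kg=vd_ml_kg,
        k_elim_per_min=k_elim_per_min,
        ra_endo_params={"basal": basal, "peak": basal, "t_peak": 60.0},
        protocol=InfusionProtocol(bolus_pg=bolus_pg, tbw_kg=tbw_kg),
        sample_times_min=sample_times[:n_samples],
        noise_cv={"ff": noise_cv_ff, "ffla": 0.0, "total": 0.07},
        seed=seed,
        start_at_steady_state=True,
    )


def postprandial_truth(
    seed: int = 0,
    vd_ml_kg: float = 40.0,
    k_elim_per_min: float = 0.1,
    tbw_kg: float = 70.0,
    f_ff_pg_kg_min: float = 14.0,
    f_ffla_pg_kg_min: float = 14.0,
    basal_ra: float = 280.0,
    peak_ra: float = 560.0,
    t_peak_min: float = 60.0,
    t_end_min: float = 350.0,
    sample_times_min: Sequence[float] | None = None,
    noise_cv: Mapping[str, float] | None = None,
) -> SimulationTruth:
    """Postprandial turnover scenario: primed-continuous two-tracer study.

    Both tracers are infused at constant rates sized for ~5% enrichment
    (steady-state tracer ~3.5 pg/ml against basal endogenous ~70 pg/ml)
    and the study starts at the primed steady state.  A meal doubles
    endogenous Ra with a gamma-like pulse peaking at ``t_peak_min``.
    """
    if sample_times_min is None:
        sample_times_min = tuple(
            t for t in DEFAULT_SAMPLE_TIMES if t <= t_end_min
        )
    segments = lambda rate: (InfusionSegment(0.0, t_end_min + 1.0, rate),)
    return SimulationTruth(
        vd_ml_kg=vd_ml_kg,
        k_elim_per_min=k_elim_per_min,
        ra_endo_params={
            "basal": basal_ra,
            "peak": peak_ra,
            "t_peak": t_peak_min,
        },
        protocol=InfusionProtocol(
            f_ff=segments(f_ff_pg_kg_min),
            f_ffla=segments(f_ffla_pg_kg_min),
            bolus_pg=0.0,
            tbw_kg=tbw_kg,
        ),
        sample_times_min=tuple(sample_times_min),
        noise_cv=dict(noise_cv) if noise_cv is not None else dict(DEFAULT_NOISE_CV),
        seed=seed,
        start_at_steady_state=True,
    )
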