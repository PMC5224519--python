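"""1:1 Langmuir SPR kinetics: sensorgram simulation and global fitting.

The pseudo-first-order surface-binding model is

    dR/dt = kon * C * (Rmax - R) - koff * R

with analyte concentration ``C`` held constant during the association phase
and zero after the buffer switch.  The closed-form solution used throughout:

    association:   R(t) = Req * (1 - exp(-(kon*C + koff) * t)),
                   Req  = Rmax * C / (C + KD),   KD = koff / kon
    dissociation:  R(t) = R(t_switch) * exp(-koff * (t - t_switch))

Fitting is global: one (kon, koff, Rmax) triplet is shared across all
concentrations of a dilution series, which is the standard analysis for
multi-channel biosensor data.  KD is always derived from the fitted rates,
never fit as a free parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "LangmuirModel",
    "InjectionSchedule",
    "Sensorgram",
    "KineticFitResult",
    "simulate_sensorgram",
    "fit_langmuir",
    "kd_from_rates",
    "read_sensorgram_table",
    "write_sensorgram_table",
    "doubling_dilutions",
]


@dataclass(frozen=True)
class LangmuirModel:
    """Rate constants and surface capacity of a 1:1 interaction.

    kon in M^-1 s^-1, koff in s^-1, Rmax in response units (RU).
    """

    kon: float
    koff: float
    rmax: float

    def __post_init__(self) -> None:
        if self.kon <= 0:
            raise ValueError("kon must be positive")
        if self.koff < 0:
            raise ValueError("koff must be non-negative")
        if self.rmax <= 0:
            raise ValueError("Rmax must be positive")

    @property
    def kd(self) -> float:
        """Equilibrium dissociation constant KD = koff / kon, in M."""
        return self.koff / self.kon

    def req(self, concentration: float) -> float:
        """Equilibrium response at a given analyte concentration."""
        return self.rmax * concentration / (concentration + self.kd)

    def response(self, t: np.ndarray, concentration: float, t_switch: float) -> np.ndarray:
        """Closed-form response over ``t`` with buffer switch at ``t_switch``."""
        t = np.asarray(t, dtype=float)
        kobs = self.kon * concentration + self.koff
        req = self.rmax * self.kon * concentration / kobs if kobs > 0 else 0.0
        assoc = req * -np.expm1(-kobs * np.clip(t, 0.0, None))
        r_switch = req * -np.expm1(-kobs * t_switch)
        dissoc = r_switch * np.exp(-self.koff * np.clip(t - t_switch, 0.0, None))
        return np.where(t <= t_switch, assoc, dissoc)


@dataclass(frozen=True)
class InjectionSchedule:
    """Concentration series and timing of one multi-channel injection."""

    concentrations: tuple[float, ...]
    t_switch: float = 300.0
    t_end: float = 600.0
    dt: float = 1.0
    t_start: float = 0.0

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be positive")
        if len(set(self.concentrations)) != len(self.concentrations):
            raise ValueError("concentrations must be distinct")
        if not (self.t_start < self.t_switch < self.t_end):
            raise ValueError("require t_start < t_switch < t_end")
        if self.dt <= 0:
            raise ValueError("sampling interval must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.t_start, self.t_end + 0.5 * self.dt, self.dt)


def doubling_dilutions(top_concentration: float, n: int) -> tuple[float, ...]:
    """Doubling-dilution series: top, top/2, ..., top/2**(n-1)."""
    if top_concentration <= 0 or n < 1:
        raise ValueError("need positive top concentration and n >= 1")
    return tuple(top_concentration / 2**i for i in range(n))


@dataclass
class Sensorgram:
    """One response curve at one analyte concentration."""

    times: np.ndarray
    responses: np.ndarray
    concentration: float
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.times.shape != self.responses.shape:
            raise ValueError("times and responses must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


def simulate_sensorgram(
    model: LangmuirModel,
    schedule: InjectionSchedule,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> list[Sensorgram]:
    """One noiseless-or-noisy curve per scheduled concentration.

    ``noise_sd`` (RU) adds i.i.d. Gaussian noise from a generator seeded with
    ``seed``; 0 gives the exact closed form.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    t = schedule.times
    curves = []
    for c in schedule.concentrations:
        r = model.response(t, c, schedule.t_switch)
        if noise_sd > 0:
            r = r + rng.normal(0.0, noise_sd, size=r.shape)
        curves.append(Sensorgram(times=t, responses=r, concentration=c, noise_sd=noise_sd))
    return curves


@dataclass
class KineticFitResult:
    """Globally fitted rates; KD is derived, never independently fitted."""

    kon: float
    koff: float
    rmax: float
    converged: bool
    residual_rms: dict[float, float]
    n_points: int
    message: str = ""

    @property
    def kd(self) -> float:
        return self.koff / self.kon


def _initial_guess(curves: list[Sensorgram], t_switch: float) -> tuple[float, float, float]:
    """Data-driven starting point: plateau -> Rmax, dissociation slope -> koff."""
    top = max(curves, key=lambda c: c.concentration)
    rmax0 = max(float(np.max(c.responses)) for c in curves)
    rmax0 = max(rmax0, 1e-6) * 1.2
    # log-linear dissociation slope of the top-concentration curve
    mask = top.times > t_switch
    koff0 = 1e-3
    if mask.sum() >= 3:
        r = top.responses[mask]
        t = top.times[mask]
        pos = r > max(1e-9, 0.01 * np.max(np.abs(r)))
        if pos.sum() >= 3:
            slope = np.polyfit(t[pos], np.log(r[pos]), 1)[0]
            if slope < 0:
                koff0 = min(max(-slope, 1e-8), 10.0)
    # half-saturation heuristic for kon: assume KD near the median concentration
    kd0 = float(np.median([c.concentration for c in curves]))
    kon0 = koff0 / kd0 if kd0 > 0 else 1e3
    return max(kon0, 1e-3), koff0, rmax0


def fit_langmuir(
    curves: list[Sensorgram],
    schedule: InjectionSchedule | None = None,
    initial_guess: tuple[float, float, float] | None = None,
) -> KineticFitResult:
    """Global least-squares fit of (kon, koff, Rmax) to a dilution series.

    Rates are optimised on a log scale to enforce positivity.  Non-convergence
    is reported in the result flag, not raised; all-zero responses are a
    degenerate-data error.
    """
    if not curves:
        raise ValueError("no sensorgrams to fit")
    if all(np.allclose(c.responses, 0.0) for c in curves):
        raise ValueError("degenerate data: all responses are zero")
    import warnings

    if len(curves) == 1:
        warnings.warn("single-concentration fit; rate constants may be poorly determined")
    t_switch = schedule.t_switch if schedule is not None else _infer_t_switch(curves)

    kon0, koff0, rmax0 = initial_guess or _initial_guess(curves, t_switch)
    params = lmfit.Parameters()
    params.add("log_kon", value=math.log(kon0), min=math.log(1e-6), max=math.log(1e12))
    params.add("log_koff", value=math.log(max(koff0, 1e-12)), min=math.log(1e-12), max=math.log(1e3))
    params.add("rmax", value=rmax0, min=1e-9)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        model = LangmuirModel(
            kon=math.exp(p["log_kon"].value),
            koff=math.exp(p["log_koff"].value),
            rmax=p["rmax"].value,
        )
        res = [model.response(c.times, c.concentration, t_switch) - c.responses for c in curves]
        return np.concatenate(res)

    minim = lmfit.minimize(
        residual, params, method="leastsq", xtol=1e-12, ftol=1e-12, max_nfev=10000
    )
    kon = math.exp(minim.params["log_kon"].value)
    koff = math.exp(minim.params["log_koff"].value)
    rmax = minim.params["rmax"].value
    fitted = LangmuirModel(kon=kon, koff=koff, rmax=rmax)
    rms = {
        c.concentration: float(
            np.sqrt(np.mean((fitted.response(c.times, c.concentration, t_switch) - c.responses) ** 2))
        )
        for c in curves
    }
    return KineticFitResult(
        kon=kon,
        koff=koff,
        rmax=rmax,
        converged=bool(minim.success),
        residual_rms=rms,
        n_points=sum(len(c.times) for c in curves),
        message=str(minim.message),
    )


def _infer_t_switch(curves: list[Sensorgram]) -> float:
    """Buffer-switch time taken as the argmax of the top-concentration curve."""
    top = max(curves, key=lambda c: c.concentration)
    return float(top.times[int(np.argmax(top.responses))])


def kd_from_rates(kon: float, koff: float) -> float:
    """KD = koff / kon, in M."""
    if kon <= 0:
        raise ValueError("kon must be positive")
    if koff < 0:
        raise ValueError("koff must be non-negative")
    return koff / kon


# ---------------------------------------------------------------------------
# delimited-text I/O (long format: time_s, response_RU, concentration_M)


def write_sensorgram_table(curves: list[Sensorgram], path, sep: str = "\t") -> None:
    frames = [
        pd.DataFrame(
            {"time_s": c.times, "response_RU": c.responses, "concentration_M": c.concentration}
        )
        for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False, float_format="%.10g")


def read_sensorgram_table(path, sep: str = "\t") -> list[Sensorgram]:
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty sensorgram table") from exc
    required = {"time_s", "response_RU", "concentration_M"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    curves = []
    for conc, grp in df.groupby("concentration_M", sort=True):
        grp = grp.sort_values("time_s")
        curves.append(
            Sensorgram(
                times=grp["time_s"].to_numpy(),
                responses=grp["response_RU"].to_numpy(),
                concentration=float(conc),
            )
        )
    return curves
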