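"""Proteolytic decay and two-state equilibrium unfolding fits.

Two quantitative models are fit here:

* Single-exponential proteolytic decay, ``f(t) = A0 * exp(-k t)``, fit
  globally across biological replicates with one shared (A0, k); used to
  quantify protease-resistance differences between S100 proteins, which can
  span several orders of magnitude in k.

* Two-state chemical denaturation with linear baselines (linear extrapolation
  model),

      y(x) = [b_f + m_f x + (b_u + m_u x) * exp(-(dG - m x)/RT)]
             / [1 + exp(-(dG - m x)/RT)]

  where b_f, m_f, b_u, m_u are folded/unfolded baseline intercepts and
  slopes, dG the unfolding free energy (kcal/mol), m the m-value
  (kcal/mol/M), x the denaturant concentration (M). The midpoint is
  C_m = dG/m. R = 0.001987 kcal/K/mol, T = 298.15 K by default.

Parameter uncertainties are the square roots of the diagonal of the
covariance matrix at the optimum; sd(C_m) is propagated from sd(dG), sd(m)
and their covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

R_KCAL = 0.001987  # kcal / (K mol)
T_STANDARD = 298.15  # K

__all__ = [
    "FitError",
    "DecayDataset",
    "DecayFit",
    "DenaturationCurve",
    "TwoStateFit",
    "KineticTrace",
    "KineticsFit",
    "fit_exponential_decay",
    "fit_two_state",
    "two_state_signal",
    "fit_unfolding_kinetics",
    "compare_rates",
]


class FitError(RuntimeError):
    pass


# ---------------------------------------------------------------- decay fit


@dataclass
class DecayDataset:
    """Replicate (time, fraction-intact) series for one protein/protease."""

    table: pd.DataFrame  # columns: replicate, time_min, fraction_intact
    protein: str = ""
    protease: str = "proteinase K"

    def __post_init__(self) -> None:
        req = {"replicate", "time_min", "fraction_intact"}
        if not req <= set(self.table.columns):
            raise FitError(f"decay table needs columns {sorted(req)}")
        if (self.table["time_min"] < 0).any():
            raise FitError("negative time points")
        counts = self.table.groupby("replicate").size()
        if (counts < 3).any():
            raise FitError("every replicate needs at least 3 points")

    @classmethod
    def from_csv(cls, path, protein: str = "", protease: str = "proteinase K"):
        return cls(pd.read_csv(path), protein=protein, protease=protease)


@dataclass
class DecayFit:
    """Globally fitted amplitude and decay rate with 1-sigma uncertainties."""

    amplitude: float
    rate: float  # 1/min
    sd_amplitude: float
    sd_rate: float
    rss: float
    n_points: int
    protein: str = ""
    per_replicate_amplitudes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise FitError(f"fitted rate must be positive, got {self.rate}")


def fit_exponential_decay(
    data: DecayDataset, shared_amplitude: bool = True
) -> DecayFit:
    """Global nonlinear least-squares fit of A0*exp(-k t).

    One (A0, k) pair is shared across all replicates (fractions are
    pre-normalized to the undigested band, so A0 is near 1). With
    ``shared_amplitude=False`` each replicate floats its own amplitude while
    k remains global.
    """
    t = data.table["time_min"].to_numpy(dtype=float)
    f = data.table["fraction_intact"].to_numpy(dtype=float)
    if np.unique(t).size < 4:
        raise FitError("need at least 4 distinct time points")
    if np.allclose(f, 0.0):
        raise FitError("all fractions are zero; nothing to fit")

    # initial rate from the log-linear slope of positive points
    pos = f > 0
    slope = np.polyfit(t[pos], np.log(f[pos]), 1)[0] if pos.sum() >= 2 else -1e-3
    k0 = max(-slope, 1e-9)

    params = lmfit.Parameters()
    params.add("k", value=k0, min=1e-12)
    reps = sorted(data.table["replicate"].unique())
    if shared_amplitude:
        params.add("A0", value=max(f.max(), 1e-6))
    else:
        for r in reps:
            params.add(f"A0_{r}", value=max(f.max(), 1e-6))
    rep_idx = data.table["replicate"].to_numpy()

    def residual(p):
        k = p["k"].value
        if shared_amplitude:
            model = p["A0"].value * np.exp(-k * t)
        else:
            amps = np.array([p[f"A0_{r}"].value for r in rep_idx])
            model = amps * np.exp(-k * t)
        return model - f

    result = lmfit.minimize(
        residual, params, method="leastsq", xtol=1e-10, ftol=1e-10, max_nfev=10000
    )
    if not result.success or result.covar is None:
        raise FitError(f"decay fit did not converge: {result.message}")
    k = result.params["k"].value
    sd_k = result.params["k"].stderr or float("nan")
    if shared_amplitude:
        A0 = result.params["A0"].value
        sd_A0 = result.params["A0"].stderr or float("nan")
        per_rep = {}
    else:
        per_rep = {r: result.params[f"A0_{r}"].value for r in reps}
        A0 = float(np.mean(list(per_rep.values())))
        sd_A0 = float(np.std(list(per_rep.values()), ddof=1)) if len(reps) > 1 else 0.0
    return DecayFit(
        amplitude=A0,
        rate=k,
        sd_amplitude=sd_A0,
        sd_rate=sd_k,
        rss=float(np.sum(result.residual**2)),
        n_points=t.size,
        protein=data.protein,
        per_replicate_amplitudes=per_rep,
    )


def compare_rates(fits: list[DecayFit]) -> pd.DataFrame:
    """Pairwise log10 rate ratios with propagated uncertainties.

    sd(log10(k_i/k_j)) = sqrt((sd_i/k_i)^2 + (sd_j/k_j)^2) / ln(10).
    """
    if len(fits) < 2:
        raise FitError("need at least two fits to compare")
    rows = []
    for i, a in enumerate(fits):
        for b in fits[i + 1 :]:
            ratio = np.log10(a.rate / b.rate)
            sd = (
                np.sqrt((a.sd_rate / a.rate) ** 2 + (b.sd_rate / b.rate) ** 2)
                / np.log(10)
            )
            rows.append(
                {
                    "protein_a": a.protein,
                    "protein_b": b.protein,
                    "rate_a_per_min": a.rate,
                    "rate_b_per_min": b.rate,
                    "log10_ratio": float(ratio),
                    "sd_log10_ratio": float(sd),
                }
            )
    return pd.DataFrame(rows)


# ------------------------------------------------------------ two-state fit


@dataclass
class DenaturationCurve:
    """CD signal at 222 nm vs denaturant concentration for one protein."""

    x_molar: np.ndarray
    signal: np.ndarray
    protein: str = ""
    temperature: float = T_STANDARD
    gas_constant: float = R_KCAL

    def __post_init__(self) -> None:
        self.x_molar = np.asarray(self.x_molar, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.x_molar.shape != self.signal.shape:
            raise FitError("x and y differ in length")
        if self.x_molar.size < 8:
            raise FitError("need at least 8 points spanning both baselines")
        if (self.x_molar < 0).any():
            raise FitError("denaturant concentrations must be >= 0")

    @classmethod
    def from_csv(cls, path, protein: str = "") -> "DenaturationCurve":
        df = pd.read_csv(path)
        return cls(df["x_molar"].to_numpy(), df["signal_mdeg"].to_numpy(), protein)


def two_state_signal(x, b_f, m_f, b_u, m_u, dG, m, RT=R_KCAL * T_STANDARD):
    """Observed signal of the two-state linear-extrapolation model."""
    arg = -(dG - m * np.asarray(x, dtype=float)) / RT
    # split by sign for overflow-free evaluation
    out = np.empty_like(arg)
    folded = b_f + m_f * np.asarray(x, dtype=float)
    unfolded = b_u + m_u * np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):
        e = np.exp(np.clip(arg, -700, 700))
    out = (folded + unfolded * e) / (1.0 + e)
    return out


@dataclass
class TwoStateFit:
    """Two-state fit results: baselines, dG, m-value, midpoint, uncertainties."""

    b_f: float
    m_f: float
    b_u: float
    m_u: float
    dG: float  # kcal/mol
    m: float  # kcal/mol/M
    sd_b_f: float
    sd_m_f: float
    sd_b_u: float
    sd_m_u: float
    sd_dG: float
    sd_m: float
    cov_dG_m: float
    temperature: float = T_STANDARD
    gas_constant: float = R_KCAL
    protein: str = ""
    covariance: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.m <= 0:
            raise FitError(f"m-value must be positive at the optimum, got {self.m}")

    @property
    def c_m(self) -> float:
        """Midpoint denaturant concentration C_m = dG/m (M)."""
        return self.dG / self.m

    @property
    def sd_c_m(self) -> float:
        """First-order propagation including the dG-m covariance."""
        d_dG = 1.0 / self.m
        d_m = -self.dG / self.m**2
        var = (
            d_dG**2 * self.sd_dG**2
            + d_m**2 * self.sd_m**2
            + 2 * d_dG * d_m * self.cov_dG_m
        )
        return float(np.sqrt(max(var, 0.0)))

    def to_dict(self) -> dict:
        return {
            "protein": self.protein,
            "b_f": self.b_f, "m_f": self.m_f, "b_u": self.b_u, "m_u": self.m_u,
            "dG_kcal_mol": self.dG, "m_kcal_mol_M": self.m, "Cm_M": self.c_m,
            "sd_b_f": self.sd_b_f, "sd_m_f": self.sd_m_f,
            "sd_b_u": self.sd_b_u, "sd_m_u": self.sd_m_u,
            "sd_dG": self.sd_dG, "sd_m": self.sd_m, "sd_Cm": self.sd_c_m,
        }


def _initial_guesses(curve: DenaturationCurve) -> np.ndarray:
    x, y = curve.x_molar, curve.signal
    order = np.argsort(x)
    x, y = x[order], y[order]
    bf, mf = _linefit(x[:3], y[:3])
    bu, mu = _linefit(x[-3:], y[-3:])
    # midpoint: x where y crosses halfway between the two baseline lines
    mid = ((bf + mf * x) + (bu + mu * x)) / 2.0
    cross = np.argmin(np.abs(y - mid))
    cm0 = max(x[cross], 1e-3)
    # m from the central slope of the transition, mapped through the model:
    # dy/dx at Cm = -(m / 4RT) * (baseline separation) + baseline mean slope
    RT = curve.gas_constant * curve.temperature
    sep = (bu + mu * cm0) - (bf + mf * cm0)
    i = max(1, min(cross, x.size - 2))
    central_slope = (y[i + 1] - y[i - 1]) / (x[i + 1] - x[i - 1])
    m0 = 4 * RT * (central_slope - (mf + mu) / 2.0) / sep if sep else 1.0
    m0 = abs(m0) if m0 else 1.0
    return np.array([bf, mf, bu, mu, m0 * cm0, m0])


def _linefit(x, y):
    slope, intercept = np.polyfit(x, y, 1)
    return intercept, slope


def fit_two_state(
    curve: DenaturationCurve,
    initial: np.ndarray | None = None,
    max_nfev: int = 10000,
    n_restarts: int = 5,
    seed: int = 0,
) -> TwoStateFit:
    """Fit the six-parameter two-state unfolding model to one curve.

    Initial guesses default to baselines from the 3 lowest-/highest-x points,
    the midpoint from the baseline-midline crossing, and the m-value from the
    central slope. If the first start fails, up to ``n_restarts`` jittered
    restarts are attempted. Warns when the fitted midpoint falls outside the
    sampled denaturant range.
    """
    x, y = curve.x_molar, curve.signal
    RT = curve.gas_constant * curve.temperature
    p0 = np.asarray(initial, dtype=float) if initial is not None else _initial_guesses(curve)

    def model(x, b_f, m_f, b_u, m_u, dG, m):
        return two_state_signal(x, b_f, m_f, b_u, m_u, dG, m, RT=RT)

    rng = np.random.default_rng(seed)
    last_err = None
    for attempt in range(n_restarts + 1):
        guess = p0 if attempt == 0 else p0 * rng.normal(1.0, 0.2, size=p0.size)
        try:
            popt, pcov = curve_fit(
                model, x, y, p0=guess, maxfev=max_nfev, xtol=1e-12, ftol=1e-12
            )
        except RuntimeError as err:
            last_err = err
            continue
        if popt[5] > 0 and np.all(np.isfinite(pcov)):
            break
        last_err = FitError(f"non-physical optimum (m = {popt[5]:.3g})")
    else:
        raise FitError(f"two-state fit failed after restarts: {last_err}")

    sds = np.sqrt(np.diag(pcov))
    fit = TwoStateFit(
        b_f=popt[0], m_f=popt[1], b_u=popt[2], m_u=popt[3],
        dG=popt[4], m=popt[5],
        sd_b_f=sds[0], sd_m_f=sds[1], sd_b_u=sds[2], sd_m_u=sds[3],
        sd_dG=sds[4], sd_m=sds[5],
        cov_dG_m=float(pcov[4, 5]),
        temperature=curve.temperature,
        gas_constant=curve.gas_constant,
        protein=curve.protein,
        covariance=pcov,
    )
    if not (x.min() <= fit.c_m <= x.max()):
        warnings.warn(
            f"fitted midpoint C_m = {fit.c_m:.2f} M lies outside the sampled "
            "denaturant range; uncertainties will be wide",
            stacklevel=2,
        )
    return fit


# ----------------------------------------------------------- unfolding rate


@dataclass
class KineticTrace:
    """CD signal vs time after a denaturant spike."""

    t_seconds: np.ndarray
    signal: np.ndarray
    dead_time: float  # s
    protein: str = ""

    def __post_init__(self) -> None:
        self.t_seconds = np.asarray(self.t_seconds, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.t_seconds.size < 10:
            raise FitError("need at least 10 points")
        if np.any(np.diff(self.t_seconds) <= 0):
            raise FitError("time must be strictly increasing")
        if self.dead_time <= 0:
            raise FitError("dead time must be positive")


@dataclass
class KineticsFit:
    """Single-exponential unfolding rate; flagged when unresolvable."""

    rate: float  # 1/s
    sd_rate: float
    amplitude: float
    y_inf: float
    within_dead_time: bool
    protein: str = ""


def fit_unfolding_kinetics(trace: KineticTrace) -> KineticsFit:
    """Fit y(t) = y_inf + dy * exp(-k t) to an unfolding trace.

    When the fitted relaxation time 1/k is shorter than the instrument dead
    time — or no amplitude is resolvable at all (already-unfolded protein) —
    the ``within_dead_time`` flag is set, mirroring proteins that unfold
    faster than the measurement can follow.
    """
    t, y = trace.t_seconds, trace.signal
    span = y.max() - y.min()
    noise = float(np.std(np.diff(y))) / np.sqrt(2) if y.size > 1 else 0.0
    if span <= max(3 * noise, 1e-12):
        # flat trace: no resolvable unfolding amplitude
        return KineticsFit(
            rate=float("inf"), sd_rate=float("nan"),
            amplitude=0.0, y_inf=float(np.mean(y)),
            within_dead_time=True, protein=trace.protein,
        )
    params = lmfit.Parameters()
    params.add("y_inf", value=float(y[-1]))
    params.add("dy", value=float(y[0] - y[-1]))
    params.add("k", value=1.0 / max(t[-1] / 3.0, 1e-9), min=1e-12)

    def residual(p):
        return p["y_inf"] + p["dy"] * np.exp(-p["k"] * t) - y

    result = lmfit.minimize(residual, params, method="leastsq", max_nfev=10000)
    if not result.success:
        raise FitError(f"kinetics fit did not converge: {result.message}")
    k = result.params["k"].value
    return KineticsFit(
        rate=k,
        sd_rate=result.params["k"].stderr or float("nan"),
        amplitude=result.params["dy"].value,
        y_inf=result.params["y_inf"].value,
        within_dead_time=bool(1.0 / k < trace.dead_time),
        protein=trace.protein,
    )
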