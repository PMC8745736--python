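"""Thermal stability analysis: CD melt curves and activity-decay kinetics.

Two complementary stability readouts are modelled:

* **Melting temperature** (T_m): the ellipticity at 222 nm recorded during a
  temperature ramp is fitted with a two-state Boltzmann sigmoid between
  linear folded/unfolded baselines,

      y(T) = y_f(T) + (y_u(T) - y_f(T)) / (1 + exp((T_m - T)/w)),

  where y_f, y_u are linear in T and w sets the transition width.  T_m is
  the inflection point (half-unfolded temperature).

* **Irreversible inactivation** at a fixed incubation temperature: residual
  activity a(t), normalised to 1 at t = 0, is fitted with first-order loss
  a(t) = exp(-k_in * t), yielding the inactivation constant k_in (1/h) and
  half-life ln2/k_in.

`stability_report` collates fits across enzyme variants against a reference
variant (Delta-T_m and fold-changes of k_in).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, least_squares

from ._fitting import covariance_from_jacobian, format_summary, rsquared

__all__ = [
    "MeltCurve", "MeltFit", "ActivitySeries", "InactivationFit",
    "MeltCurveModel", "InactivationModel",
    "fit_melting_curve", "fit_inactivation_decay",
    "stability_report", "StabilityComparison",
    "read_melt_csv", "read_activity_csv",
]


@dataclass(frozen=True)
class MeltCurve:
    """Ellipticity-vs-temperature ramp (CD at 222 nm, arbitrary units)."""

    temperatures: np.ndarray
    signal: np.ndarray
    warnings: tuple[str, ...] = ()

    def __post_init__(self):
        temp = np.asarray(self.temperatures, dtype=float)
        sig = np.asarray(self.signal, dtype=float)
        if temp.ndim != 1 or sig.shape != temp.shape:
            raise ValueError("temperatures and signal must be 1-D and match")
        if temp.size < 10:
            raise ValueError("melt curve needs >= 10 points")
        if not np.all(np.diff(temp) > 0):
            raise ValueError("temperatures must be strictly increasing")
        object.__setattr__(self, "temperatures", temp)
        object.__setattr__(self, "signal", sig)


@dataclass(frozen=True)
class ActivitySeries:
    """Residual activity versus incubation time, normalised to a(0) = 1."""

    times: np.ndarray
    activity: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.activity, dtype=float)
        if t.ndim != 1 or a.shape != t.shape:
            raise ValueError("times and activity must be 1-D and match")
        if np.any(t < 0):
            raise ValueError("times must be non-negative")
        if np.any(a < 0) or np.any(a > 1.5):
            raise ValueError("activity values must lie in [0, 1.5]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "activity", a)


def _boltzmann(T, t_m, width, bf, mf, bu, mu):
    folded = bf + mf * T
    unfolded = bu + mu * T
    frac = 1.0 / (1.0 + np.exp(np.clip((t_m - T) / width, -500, 500)))
    return folded + (unfolded - folded) * frac


class MeltCurveModel:
    """Two-state sigmoid model for a thermal unfolding curve.

    The six parameters are T_m, the transition width and intercept/slope of
    each linear baseline.  Initialisation takes the baselines from the
    outer 15% of the temperature range and T_m from the half-unfolded
    point; the width starts at 2 degC.
    """

    def __init__(self, curve: MeltCurve):
        self.curve = curve

    def _initial_guess(self):
        T, y = self.curve.temperatures, self.curve.signal
        n_edge = max(3, T.size * 15 // 100)
        bf_m, bf_b = np.polyfit(T[:n_edge], y[:n_edge], 1)
        bu_m, bu_b = np.polyfit(T[-n_edge:], y[-n_edge:], 1)
        folded = bf_b + bf_m * T
        unfolded = bu_b + bu_m * T
        denom = unfolded - folded
        denom = np.where(np.abs(denom) < 1e-12, np.nan, denom)
        with np.errstate(invalid="ignore"):
            frac = (y - folded) / denom
        if np.all(np.isnan(frac)):
            idx = T.size // 2  # coincident baselines: no transition signal
        else:
            idx = int(np.nanargmin(np.abs(frac - 0.5)))
        return [float(T[idx]), 2.0, bf_b, bf_m, bu_b, bu_m]

    def fit(self) -> "MeltFit":
        """Fit the sigmoid; raises if no transition is present.

        Raises
        ------
        ValueError
            "monotone baseline only" when the fitted transition amplitude
            is negligible relative to the signal range, or when the fitted
            T_m falls outside the temperature range.
        """
        T, y = self.curve.temperatures, self.curve.signal
        p0 = self._initial_guess()
        span = float(T[-1] - T[0])
        lo = [T[0] - span, 1e-3, -np.inf, -np.inf, -np.inf, -np.inf]
        hi = [T[-1] + span, span, np.inf, np.inf, np.inf, np.inf]
        p0[0] = min(max(p0[0], lo[0]), hi[0])
        try:
            popt, pcov = curve_fit(_boltzmann, T, y, p0=p0,
                                   bounds=(lo, hi), maxfev=20000)
        except RuntimeError as exc:
            raise ValueError(f"melt fit did not converge: {exc}") from exc
        t_m, width, bf, mf, bu, mu = popt
        amplitude = abs((bu + mu * t_m) - (bf + mf * t_m))
        sig_range = float(np.ptp(y))
        if sig_range == 0 or amplitude < 0.1 * sig_range:
            raise ValueError("no transition detected: monotone baseline only")
        if not (T[0] <= t_m <= T[-1]):
            raise ValueError("no transition detected: monotone baseline only")
        t_m_se = float(np.sqrt(max(pcov[0, 0], 0.0)))
        yhat = _boltzmann(T, *popt)
        return MeltFit(
            t_m=float(t_m), t_m_se=t_m_se, transition_width=float(width),
            folded_baseline=(float(bf), float(mf)),
            unfolded_baseline=(float(bu), float(mu)),
            rsquared=rsquared(y, yhat), curve=self.curve,
        )


@dataclass(frozen=True)
class MeltFit:
    """Fitted two-state melt: T_m (degC), width and baselines."""

    t_m: float
    t_m_se: float
    transition_width: float
    folded_baseline: tuple[float, float]   # intercept, slope
    unfolded_baseline: tuple[float, float]
    rsquared: float
    curve: MeltCurve | None = None

    def predict(self, temperatures):
        bf, mf = self.folded_baseline
        bu, mu = self.unfolded_baseline
        return _boltzmann(np.asarray(temperatures, dtype=float),
                          self.t_m, self.transition_width, bf, mf, bu, mu)

    def summary(self) -> str:
        return format_summary(
            "Two-state thermal melt",
            [("model", "Boltzmann sigmoid + linear baselines"),
             ("R^2", f"{self.rsquared:.4f}")],
            [("T_m (degC)", self.t_m, self.t_m_se),
             ("width (degC)", self.transition_width, float("nan"))],
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.curve is not None:
            ax.plot(self.curve.temperatures, self.curve.signal, "o", ms=3,
                    label="data")
            grid = np.linspace(self.curve.temperatures[0],
                               self.curve.temperatures[-1], 300)
            ax.plot(grid, self.predict(grid), "-", label="two-state fit")
        ax.axvline(self.t_m, ls="--", color="grey",
                   label=f"$T_m$ = {self.t_m:.1f} °C")
        ax.set_xlabel("temperature (°C)")
        ax.set_ylabel("ellipticity (a.u.)")
        ax.legend()
        return ax


def fit_melting_curve(curve: MeltCurve) -> MeltFit:
    """Fit a two-state sigmoid to a melt curve (see :class:`MeltCurveModel`)."""
    return MeltCurveModel(curve).fit()


class InactivationModel:
    """First-order activity-loss model a(t) = exp(-k_in * t).

    The amplitude is fixed at 1 (the series is normalised to its t = 0
    value).  A log-linear regression on points above the detection floor
    initialises a direct nonlinear fit, which avoids the bias that log
    transformation imparts to noisy low-activity points.
    """

    #: activity fraction below which points are treated as unmeasurable
    detection_floor = 0.01

    def __init__(self, series: ActivitySeries):
        self.series = series
        if series.times.size < 3:
            raise ValueError("need >= 3 time points")

    def fit(self) -> "InactivationFit":
        t, a = self.series.times, self.series.activity
        keep = a > self.detection_floor
        if not np.any(keep):
            raise ValueError("all points below the detection floor")
        # ln-linear initialiser (slope forced non-negative)
        k0 = max(0.0, -float(np.polyfit(t[keep], np.log(a[keep]), 1)[0])) \
            if np.unique(t[keep]).size >= 2 else 0.0

        def resid(logit_k):
            return np.exp(-np.exp(logit_k[0]) * t[keep]) - a[keep]

        if k0 > 0:
            sol = least_squares(resid, x0=[np.log(k0)], method="lm",
                                xtol=1e-14, ftol=1e-14)
            k = float(np.exp(sol.x[0]))
            cov = covariance_from_jacobian(sol.jac, sol.fun, 1)
            k_se = k * float(np.sqrt(max(cov[0, 0], 0.0)))
        else:
            # constant series: the decay constant is exactly zero
            k, k_se = 0.0, 0.0
        half_life = math.log(2) / k if k > 0 else math.inf
        yhat = np.exp(-k * t[keep])
        return InactivationFit(
            k_in=k, k_in_se=k_se, half_life=half_life,
            rsquared=rsquared(a[keep], yhat),
            n_points=int(np.count_nonzero(keep)), series=self.series,
        )


@dataclass(frozen=True)
class InactivationFit:
    """First-order inactivation constant k_in (1/h) and half-life (h)."""

    k_in: float
    k_in_se: float
    half_life: float
    rsquared: float
    n_points: int
    series: ActivitySeries | None = None

    @property
    def half_life_is_infinite(self) -> bool:
        return math.isinf(self.half_life)

    def predict(self, times):
        return np.exp(-self.k_in * np.asarray(times, dtype=float))

    def summary(self) -> str:
        hl = "inf" if self.half_life_is_infinite else f"{self.half_life:.4g} h"
        return format_summary(
            "First-order thermal inactivation",
            [("model", "a(t) = exp(-k_in t)"),
             ("n points", str(self.n_points)),
             ("half-life", hl),
             ("R^2", f"{self.rsquared:.4f}")],
            [("k_in (1/h)", self.k_in, self.k_in_se)],
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.series is not None:
            ax.plot(self.series.times, self.series.activity, "o", label="data")
            grid = np.linspace(0, self.series.times[-1], 200)
            ax.plot(grid, self.predict(grid), "-", label="exponential fit")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("residual activity (fraction)")
        ax.legend()
        return ax


def fit_inactivation_decay(series: ActivitySeries) -> InactivationFit:
    """Fit first-order activity loss (see :class:`InactivationModel`)."""
    return InactivationModel(series).fit()


@dataclass(frozen=True)
class StabilityComparison:
    """Per-variant stability metrics relative to a reference variant.

    ``table`` has one row per variant with columns t_m, delta_t_m (variant
    minus reference), k_in, fold_vs_reference (k_variant / k_reference) and
    fold_reference_vs_variant (the reciprocal), so both directions of the
    fold-change are explicit.
    """

    reference: str
    table: pd.DataFrame

    def summary(self) -> str:
        return (f"Stability comparison (reference: {self.reference})\n"
                + self.table.to_string(float_format=lambda v: f"{v:.4g}"))


def stability_report(
    melts: dict[str, MeltFit | None],
    decays: dict[str, InactivationFit | None],
    reference: str,
) -> StabilityComparison:
    """Compare melting temperatures and inactivation constants across variants.

    Raises
    ------
    ValueError
        If the reference variant is absent from both mappings.
    """
    variants = list(dict.fromkeys([*melts, *decays]))
    if reference not in variants:
        raise ValueError(f"reference variant {reference!r} not present")
    ref_melt = melts.get(reference)
    ref_decay = decays.get(reference)
    rows = []
    for name in variants:
        melt, decay = melts.get(name), decays.get(name)
        t_m = melt.t_m if melt else np.nan
        d_tm = (melt.t_m - ref_melt.t_m) if (melt and ref_melt) else np.nan
        k = decay.k_in if decay else np.nan
        if decay and ref_decay and ref_decay.k_in > 0:
            fold = decay.k_in / ref_decay.k_in
            fold_inv = np.inf if decay.k_in == 0 else ref_decay.k_in / decay.k_in
        else:
            fold = fold_inv = np.nan
        rows.append({"variant": name, "t_m": t_m, "delta_t_m": d_tm,
                     "k_in": k, "fold_vs_reference": fold,
                     "fold_reference_vs_variant": fold_inv})
    table = pd.DataFrame(rows).set_index("variant")
    return StabilityComparison(reference=reference, table=table)


# ---------------------------------------------------------------------------
# CSV interface


def read_melt_csv(path) -> MeltCurve:
    """Read a melt curve CSV with columns temp_C, signal ('#' lines skipped)."""
    df = pd.read_csv(path, comment="#")
    return MeltCurve(df["temp_C"].to_numpy(), df["signal"].to_numpy())


def read_activity_csv(path) -> ActivitySeries:
    """Read an activity CSV with columns time_h, activity_frac."""
    df = pd.read_csv(path, comment="#")
    return ActivitySeries(df["time_h"].to_numpy(),
                          df["activity_frac"].to_numpy())
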