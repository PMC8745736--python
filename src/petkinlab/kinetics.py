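"""Turbidimetric kinetics of enzymatic PET-nanoparticle hydrolysis.

Hydrolysis of suspended PET nanoparticles is followed as a decrease in
turbidity (OD600).  The blank-corrected, normalised turbidity tau/tau0 is a
proxy for the remaining particle cross-section; for surface erosion its
square root declines linearly in time, and the initial decline rate

    v([E]) = -d(tau/tau0)^(1/2)/dt = k_tau * K_A * [E] / (1 + K_A * [E])

saturates hyperbolically in enzyme concentration [E] (heterogeneous
Langmuir-type catalysis): K_A (mL/mg) is the enzyme-particle adsorption
equilibrium constant and k_tau (1/min) the maximal square-root-turbidity
decline rate once the particle surface is saturated.

The module turns raw OD600 traces into relative-turbidity series, extracts
initial rates from the linear region, and fits the saturation model with
:class:`LangmuirKinetics` / :class:`LangmuirResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from ._fitting import covariance_from_jacobian, format_summary, rsquared

__all__ = [
    "TurbidityTrace",
    "RelativeTurbiditySeries",
    "RateMeasurement",
    "LangmuirKinetics",
    "LangmuirResults",
    "langmuir_rate",
    "compute_relative_turbidity",
    "estimate_initial_rate",
    "fit_langmuir_kinetics",
    "read_turbidity_csv",
    "write_turbidity_csv",
]


@dataclass(frozen=True)
class TurbidityTrace:
    """One OD600 time course at a single enzyme concentration.

    Parameters
    ----------
    times : array-like
        Sampling times in seconds, strictly increasing, starting at the
        first reading after mixing.
    od600 : array-like
        Raw absorbance at 600 nm, same length as ``times``.
    od600_blank : float
        OD600 of the buffer-only cuvette (the reference subtracted before
        normalisation).
    enzyme_conc : float
        Enzyme concentration in mg/mL (>= 0).
    substrate_load : float
        Nanoparticle load in ug/mL (informational; the assay is run in the
        range where rates are independent of it).
    """

    times: np.ndarray
    od600: np.ndarray
    od600_blank: float
    enzyme_conc: float
    substrate_load: float = 94.0
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        od600 = np.asarray(self.od600, dtype=float)
        if times.ndim != 1 or od600.shape != times.shape:
            raise ValueError("times and od600 must be 1-D arrays of equal length")
        if times.size >= 2 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.enzyme_conc < 0:
            raise ValueError(f"enzyme_conc must be >= 0, got {self.enzyme_conc}")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "od600", od600)


@dataclass(frozen=True)
class RelativeTurbiditySeries:
    """Blank-corrected turbidity normalised to its initial value.

    ``tau_rel[0] == 1`` by construction; times are in minutes.
    """

    times: np.ndarray
    tau_rel: np.ndarray
    enzyme_conc: float = 0.0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        tau = np.asarray(self.tau_rel, dtype=float)
        if t.shape != tau.shape or t.ndim != 1:
            raise ValueError("times and tau_rel must be 1-D arrays of equal length")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "tau_rel", tau)


@dataclass(frozen=True)
class RateMeasurement:
    """Initial square-root-turbidity decline rate at one enzyme concentration.

    ``rate`` is -d(tau/tau0)^(1/2)/dt in 1/min over the selected linear
    window; ``window_r2`` is the R^2 of the within-window line.  ``flags``
    records anomalies ("clamped" when a positive slope was clamped to zero,
    "non-monotone" when the series rises anywhere).
    """

    enzyme_conc: float
    rate: float
    window: tuple[float, float]
    window_r2: float
    rate_sd: float | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError("rate must be >= 0 (clamp before constructing)")


def compute_relative_turbidity(trace: TurbidityTrace) -> RelativeTurbiditySeries:
    """Normalise a trace to relative turbidity tau/tau0.

    tau/tau0 at time t is |OD600(t) - OD600_blank| / |OD600(0) - OD600_blank|;
    the first element is exactly 1.  Times are converted from seconds to
    minutes.

    Raises
    ------
    ValueError
        If the initial blank-corrected signal is zero (no particles to
        follow; the normalisation is undefined).
    """
    corrected = np.abs(trace.od600 - trace.od600_blank)
    if corrected[0] == 0:
        raise ValueError(
            "degenerate trace: initial OD600 equals the blank, "
            "relative turbidity is undefined"
        )
    tau_rel = corrected / corrected[0]
    return RelativeTurbiditySeries(
        times=trace.times / 60.0, tau_rel=tau_rel, enzyme_conc=trace.enzyme_conc
    )


def _window_regressions(t: np.ndarray, y: np.ndarray, min_points: int):
    """Slope, intercept and R^2 for every contiguous window of >= min_points.

    Runs in O(n^2) using prefix sums; yields (i, j, slope, r2) with the
    window spanning indices i..j inclusive.
    """
    n = t.size
    c = np.concatenate  # prefix sums with leading zero
    S1 = c(([0.0], np.cumsum(t)))
    S2 = c(([0.0], np.cumsum(t * t)))
    Sy = c(([0.0], np.cumsum(y)))
    Syy = c(([0.0], np.cumsum(y * y)))
    Sty = c(([0.0], np.cumsum(t * y)))
    for i in range(0, n - min_points + 1):
        ends = np.arange(i + min_points - 1, n)
        m = (ends - i + 1).astype(float)
        st = S1[ends + 1] - S1[i]
        stt = S2[ends + 1] - S2[i]
        sy = Sy[ends + 1] - Sy[i]
        syy = Syy[ends + 1] - Syy[i]
        sty = Sty[ends + 1] - Sty[i]
        sxx = stt - st * st / m
        sxy = sty - st * sy / m
        syy_c = syy - sy * sy / m
        slope = sxy / sxx
        ss_res = syy_c - slope * sxy
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where(syy_c > 0, 1.0 - ss_res / syy_c, 1.0)
        # guard tiny negative residuals from cancellation
        r2 = np.clip(r2, 0.0, 1.0)
        yield i, ends, slope, r2


def estimate_initial_rate(
    series: RelativeTurbiditySeries,
    lag: float = 1.5,
    min_points: int = 5,
    r2_threshold: float = 0.98,
    min_fraction: float = 0.2,
) -> RateMeasurement:
    """Extract the initial decline rate of sqrt(tau/tau0) in the linear region.

    The square root of the relative turbidity is scanned with sliding
    windows of at least ``min_points`` points starting at or after ``lag``
    minutes (the mixing/lag phase is excluded); points where the turbidity
    has fully decayed to zero carry no kinetic information and are dropped
    from the search.  A linear region is a contiguous stretch, not a lucky
    handful of points, so only windows covering at least ``min_fraction``
    of the post-lag span (and >= ``min_points``) may qualify; among those
    whose linear R^2 reaches ``r2_threshold`` the longest is chosen (ties:
    earliest start, then higher R^2).  If no window qualifies the whole
    post-lag span is used.  The rate is the negated slope, clamped at zero
    (flagged) if the series rises.

    Raises
    ------
    ValueError
        If fewer than ``min_points`` points remain after the lag.
    """
    t = series.times
    tau = series.tau_rel
    y = np.sqrt(np.clip(tau, 0.0, None))
    start_idx = int(np.searchsorted(t, lag, side="left"))
    # drop the fully-degraded tail (clamped at zero turbidity)
    zero = np.nonzero(tau[start_idx:] <= 1e-9)[0]
    stop_idx = start_idx + int(zero[0]) if zero.size else t.size
    t_w, y_w = t[start_idx:stop_idx], y[start_idx:stop_idx]
    if t_w.size < min_points:
        raise ValueError(
            f"need >= {min_points} points after the {lag} min lag, "
            f"got {t_w.size}"
        )
    flags: list[str] = []
    if np.any(np.diff(series.tau_rel) > 1e-12):
        flags.append("non-monotone")

    min_len = max(min_points, int(np.ceil(min_fraction * t_w.size)))
    best = None  # (length, -start, r2) maximised over qualifying windows
    chosen = None
    for i, ends, slopes, r2s in _window_regressions(t_w, y_w, min_len):
        ok = np.nonzero(r2s >= r2_threshold)[0]
        if ok.size:
            k = ok[np.lexsort((np.round(r2s[ok], 10), ends[ok]))][-1]
            cand = (int(ends[k] - i), -i, round(float(r2s[k]), 10))
            if best is None or cand > best:
                best = cand
                chosen = (i, int(ends[k]), slopes[k], r2s[k])
    if chosen is None:
        # no clean linear sub-window stands out: use the whole span
        n = t_w.size
        slope, intercept = np.polyfit(t_w, y_w, 1)
        yhat = slope * t_w + intercept
        chosen = (0, n - 1, slope, rsquared(y_w, yhat))
    i, j, slope, r2 = chosen
    rate = -float(slope)
    if rate < 0:
        rate = 0.0
        flags.append("clamped")
    return RateMeasurement(
        enzyme_conc=series.enzyme_conc,
        rate=rate,
        window=(float(t_w[i]), float(t_w[j])),
        window_r2=float(r2),
        flags=tuple(flags),
    )


def langmuir_rate(e_conc, k_tau: float, k_a: float):
    """Saturation rate law v = k_tau * K_A * [E] / (1 + K_A * [E])."""
    e_conc = np.asarray(e_conc, dtype=float)
    return k_tau * k_a * e_conc / (1.0 + k_a * e_conc)


class LangmuirKinetics:
    """Model for initial rates versus enzyme concentration.

    Fits v([E]) = k_tau * K_A * [E] / (1 + K_A * [E]) by nonlinear least
    squares with positivity enforced through a log-parameterisation.

    Parameters
    ----------
    rates : array-like
        Initial sqrt-turbidity decline rates (1/min), one per measurement.
    enzyme_concs : array-like
        Matching enzyme concentrations (mg/mL).
    weights : array-like, optional
        Per-point weights (1/SD); uniform when omitted.

    Examples
    --------
    >>> model = LangmuirKinetics(rates, concs)
    >>> res = model.fit()
    >>> res.k_tau, res.K_A, res.rsquared
    """

    def __init__(self, rates, enzyme_concs, weights=None):
        self.rates = np.asarray(rates, dtype=float)
        self.enzyme_concs = np.asarray(enzyme_concs, dtype=float)
        if self.rates.shape != self.enzyme_concs.shape or self.rates.ndim != 1:
            raise ValueError("rates and enzyme_concs must be 1-D and match")
        if np.any(self.enzyme_concs < 0):
            raise ValueError("enzyme_concs must be non-negative")
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")
        self.weights = (
            np.ones_like(self.rates) if weights is None
            else np.asarray(weights, dtype=float)
        )

    @classmethod
    def from_measurements(cls, points: list[RateMeasurement],
                          use_sd_weights: bool = False) -> "LangmuirKinetics":
        """Build the model from :func:`estimate_initial_rate` outputs."""
        rates = [p.rate for p in points]
        concs = [p.enzyme_conc for p in points]
        weights = None
        if use_sd_weights and all(p.rate_sd for p in points):
            weights = [1.0 / p.rate_sd for p in points]
        return cls(rates, concs, weights=weights)

    def _initial_guess(self) -> tuple[float, float]:
        k0 = float(np.max(self.rates))
        half = k0 / 2.0
        above = self.enzyme_concs[self.rates >= half]
        e_half = float(np.min(above)) if above.size else float(
            np.median(self.enzyme_concs[self.enzyme_concs > 0]))
        if e_half <= 0:
            e_half = 1.0
        return k0, 1.0 / e_half

    def fit(self, exclude_above: float | None = None) -> "LangmuirResults":
        """Fit the saturation model.

        Parameters
        ----------
        exclude_above : float, optional
            Drop points with [E] above this cutoff (mg/mL) before fitting.
            High enzyme loads can exceed the adsorption monolayer and fall
            off the Langmuir curve; exclusion is explicit, never automatic.

        Raises
        ------
        ValueError
            With fewer than 3 distinct concentrations, all-zero rates, or
            non-convergence.
        """
        mask = np.ones(self.rates.size, dtype=bool)
        if exclude_above is not None:
            mask &= self.enzyme_concs <= exclude_above
        e, r, w = self.enzyme_concs[mask], self.rates[mask], self.weights[mask]
        if np.unique(e).size < 3:
            raise ValueError("need >= 3 distinct enzyme concentrations")
        if np.all(r == 0):
            raise ValueError("no activity: all rates are zero")

        k0, ka0 = self._initial_guess()

        def resid(theta):
            k_tau, k_a = np.exp(theta)
            return w * (langmuir_rate(e, k_tau, k_a) - r)

        sol = least_squares(resid, x0=np.log([k0, ka0]), method="lm",
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if not sol.success:
            raise ValueError(f"Langmuir fit did not converge: {sol.message}")
        k_tau, k_a = np.exp(sol.x)
        cov_log = covariance_from_jacobian(sol.jac, sol.fun, 2)
        # delta method: SE(k) = k * SE(log k)
        k_tau_se = k_tau * float(np.sqrt(max(cov_log[0, 0], 0.0)))
        k_a_se = k_a * float(np.sqrt(max(cov_log[1, 1], 0.0)))
        yhat = langmuir_rate(e, k_tau, k_a)
        return LangmuirResults(
            model=self, k_tau=float(k_tau), k_tau_se=k_tau_se,
            K_A=float(k_a), K_A_se=k_a_se, rsquared=rsquared(r, yhat),
            n_points=int(e.size), excluded_above=exclude_above,
            enzyme_concs=e, rates=r,
        )


@dataclass(frozen=True)
class LangmuirResults:
    """Fitted saturation-kinetics parameters for one enzyme variant."""

    model: LangmuirKinetics
    k_tau: float
    k_tau_se: float
    K_A: float
    K_A_se: float
    rsquared: float
    n_points: int
    excluded_above: float | None
    enzyme_concs: np.ndarray
    rates: np.ndarray

    def predict(self, e_conc):
        """Model rate at the given enzyme concentration(s)."""
        return langmuir_rate(e_conc, self.k_tau, self.K_A)

    def summary(self) -> str:
        rows = [
            ("model", "v = k_tau*K_A*[E]/(1+K_A*[E])"),
            ("n points", str(self.n_points)),
            ("R^2", f"{self.rsquared:.4f}"),
        ]
        if self.excluded_above is not None:
            rows.append(("excluded [E] >", f"{self.excluded_above} mg/mL"))
        return format_summary(
            "Langmuir turbidimetric kinetics", rows,
            [("k_tau (1/min)", self.k_tau, self.k_tau_se),
             ("K_A (mL/mg)", self.K_A, self.K_A_se)],
        )

    def plot(self, ax=None):
        """Rate-vs-[E] scatter with the fitted saturation curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.enzyme_concs, self.rates, "o", label="measured")
        grid = np.linspace(0, float(self.enzyme_concs.max()) * 1.1, 200)
        ax.plot(grid, self.predict(grid), "-", label="Langmuir fit")
        ax.set_xlabel("[E] (mg/mL)")
        ax.set_ylabel(r"$-d(\tau/\tau_0)^{1/2}/dt$ (1/min)")
        ax.legend()
        return ax


def fit_langmuir_kinetics(points: list[RateMeasurement],
                          exclude_above: float | None = None,
                          use_sd_weights: bool = False) -> LangmuirResults:
    """Fit the saturation model to a set of rate measurements."""
    model = LangmuirKinetics.from_measurements(points, use_sd_weights)
    return model.fit(exclude_above=exclude_above)


# ---------------------------------------------------------------------------
# CSV interface


def write_turbidity_csv(trace: TurbidityTrace, path) -> None:
    """Write a trace as CSV with '#'-prefixed metadata lines."""
    with open(path, "w") as fh:
        fh.write(f"# od600_blank={trace.od600_blank}\n")
        fh.write(f"# enzyme_conc_mg_ml={trace.enzyme_conc}\n")
        fh.write(f"# substrate_load_ug_ml={trace.substrate_load}\n")
        for key, val in trace.meta.items():
            fh.write(f"# {key}={val}\n")
        fh.write("time_s,od600\n")
        for t, od in zip(trace.times, trace.od600):
            fh.write(f"{t:.6g},{od:.8g}\n")


def read_turbidity_csv(path) -> TurbidityTrace:
    """Read a trace written by :func:`write_turbidity_csv`."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh)
    known = {"od600_blank", "enzyme_conc_mg_ml", "substrate_load_ug_ml"}
    return TurbidityTrace(
        times=df["time_s"].to_numpy(),
        od600=df["od600"].to_numpy(),
        od600_blank=float(meta["od600_blank"]),
        enzyme_conc=float(meta["enzyme_conc_mg_ml"]),
        substrate_load=float(meta.get("substrate_load_ug_ml", 94.0)),
        meta={k: v for k, v in meta.items() if k not in known},
    )
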