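"""Quantification of PET bioconversion from UV absorbance.

Soluble aromatic hydrolysis products (MHET, TPA and traces of BHET all
carry the terephthalate chromophore) are quantified jointly from the
absorbance at 240 nm via Beer-Lambert with epsilon_240 = 13.8 /mM/cm.
From the product concentration the module derives depolymerization yields
(molar repeat-unit basis or mass basis) and enzyme-specific rates, plus
the conversion between the two common specific-rate units.

The single-wavelength assay cannot resolve the product mixture, so all
products are treated as one aromatic-equivalent pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EPSILON_240_MM_CM", "EPSILON_405_MM_CM",
    "MW_PET_REPEAT_UNIT", "MW_TPA",
    "BioconversionCourse", "YieldResult", "SpecificRate",
    "absorbance_to_concentration", "depolymerization_yield",
    "convert_specific_rate", "analyze_course", "read_bioconversion_csv",
]

#: molar extinction of the soluble aromatic products at 240 nm (1/mM/cm)
EPSILON_240_MM_CM = 13.8
#: molar extinction of p-nitrophenolate at 405 nm (1/mM/cm), used by the
#: colorimetric esterase assay on p-nitrophenyl acetate
EPSILON_405_MM_CM = 11.6
#: PET repeat unit C10H8O4 (g/mol); the default basis for molar yields
MW_PET_REPEAT_UNIT = 192.17
#: terephthalic acid (g/mol), the aromatic-equivalent mass for rate conversion
MW_TPA = 166.13


@dataclass(frozen=True)
class BioconversionCourse:
    """A240 time course of a PET depolymerization reaction."""

    times: np.ndarray            # hours
    a240: np.ndarray
    path_length: float = 1.0     # cm
    dilution: np.ndarray | float = 1.0
    enzyme_conc: float = 100.0   # ug/mL
    substrate_load: float = 9.0  # mg/mL
    temperature: float = 45.0    # degC

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.a240, dtype=float)
        if t.ndim != 1 or a.shape != t.shape:
            raise ValueError("times and a240 must be 1-D and match")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if self.substrate_load <= 0:
            raise ValueError("substrate_load must be > 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "a240", a)


@dataclass(frozen=True)
class YieldResult:
    """Depolymerization yield with its basis.

    Yields above 100% are physically impossible and flagged rather than
    clamped (they usually indicate a wrong substrate load or basis MW).
    """

    yield_pct: float
    basis: str                       # "molar" | "mass"
    products_mm: float | None = None
    product_mass: float | None = None
    over_100_flag: bool = False


@dataclass(frozen=True)
class SpecificRate:
    """Enzyme-specific product accumulation rate in uM/ug/day."""

    value: float
    window: tuple[float, float]  # hours


def absorbance_to_concentration(a, epsilon: float = EPSILON_240_MM_CM,
                                path: float = 1.0,
                                dilution=1.0):
    """Beer-Lambert: concentration (mM) = A * dilution / (epsilon * path)."""
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if path <= 0:
        raise ValueError("path length must be > 0")
    dilution = np.asarray(dilution, dtype=float)
    if np.any(dilution < 1):
        raise ValueError("dilution factor must be >= 1")
    out = np.asarray(a, dtype=float) * dilution / (epsilon * path)
    return float(out) if out.ndim == 0 else out


def depolymerization_yield(products: float, substrate: float,
                           basis: str = "molar",
                           mw_repeat_unit: float = MW_PET_REPEAT_UNIT
                           ) -> YieldResult:
    """Fraction of the PET substrate converted to soluble products.

    Parameters
    ----------
    products : float
        Product pool: mM of aromatic equivalents (molar basis) or degraded
        mass in mg (mass basis).
    substrate : float
        Substrate load: mg/mL (molar basis) or initial mass in mg (mass
        basis); must be > 0.
    basis : {"molar", "mass"}
        On the molar basis the substrate is converted to repeat-unit
        concentration, substrate / mw_repeat_unit * 1000 (mM), and the
        yield is products / that * 100.  On the mass basis it is simply
        degraded/initial * 100.
    mw_repeat_unit : float
        Repeat-unit molar mass in g/mol (default 192.17 for C10H8O4).
        Configurable because the assay's aromatic-equivalent pool mixes
        MHET and TPA, whose effective monomer masses differ.
    """
    if substrate <= 0:
        raise ValueError("substrate must be > 0")
    if basis == "molar":
        repeat_mm = substrate / mw_repeat_unit * 1000.0
        pct = products / repeat_mm * 100.0
        return YieldResult(yield_pct=pct, basis="molar", products_mm=products,
                           over_100_flag=pct > 100.0)
    if basis == "mass":
        pct = products / substrate * 100.0
        return YieldResult(yield_pct=pct, basis="mass", product_mass=products,
                           over_100_flag=pct > 100.0)
    raise ValueError(f"unknown basis {basis!r}; use 'molar' or 'mass'")


def convert_specific_rate(rate: float, mw_product_equiv: float = MW_TPA
                          ) -> float:
    """Convert uM_products/ug_enzyme/day to g/L per g_enzyme per hour.

    uM per ug (on a common volume) equals mol per g; multiplying by the
    product-equivalent molar mass gives g/L per g_enzyme per day, and /24
    puts it per hour: out = rate * mw / 24.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if mw_product_equiv <= 0:
        raise ValueError("molar mass must be > 0")
    return rate * mw_product_equiv / 24.0


@dataclass(frozen=True)
class BioconversionReport:
    """Per-timepoint concentrations plus final yield and specific rate."""

    concentrations_mm: np.ndarray
    yield_result: YieldResult
    specific_rate: SpecificRate
    course: BioconversionCourse

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_h": self.course.times,
                             "a240": self.course.a240,
                             "products_mM": self.concentrations_mm})

    def summary(self) -> str:
        lines = [
            "PET bioconversion report",
            f"  final products: {self.concentrations_mm[-1]:.3g} mM",
            f"  depolymerization yield ({self.yield_result.basis}): "
            f"{self.yield_result.yield_pct:.1f}%"
            + (" [>100% flagged]" if self.yield_result.over_100_flag else ""),
            f"  specific rate ({self.specific_rate.window[0]:g}-"
            f"{self.specific_rate.window[1]:g} h): "
            f"{self.specific_rate.value:.3g} uM/ug/day",
        ]
        return "\n".join(lines)


def analyze_course(course: BioconversionCourse,
                   epsilon: float = EPSILON_240_MM_CM,
                   rate_window: tuple[float, float] | None = None,
                   mw_repeat_unit: float = MW_PET_REPEAT_UNIT
                   ) -> BioconversionReport:
    """Full course analysis: concentrations, molar yield and specific rate.

    The specific rate is products at the window end (minus the window
    start) divided by enzyme load and elapsed days, over ``rate_window``
    (hours; defaults to the whole course).
    """
    conc = absorbance_to_concentration(course.a240, epsilon,
                                       course.path_length, course.dilution)
    conc = np.atleast_1d(conc)
    yres = depolymerization_yield(float(conc[-1]), course.substrate_load,
                                  basis="molar",
                                  mw_repeat_unit=mw_repeat_unit)
    if rate_window is None:
        rate_window = (float(course.times[0]), float(course.times[-1]))
    t0, t1 = rate_window
    if t1 <= t0:
        raise ValueError("rate window must have t_end > t_start")
    c0 = float(np.interp(t0, course.times, conc))
    c1 = float(np.interp(t1, course.times, conc))
    days = (t1 - t0) / 24.0
    rate = max(0.0, (c1 - c0) * 1000.0) / (course.enzyme_conc * days)
    return BioconversionReport(
        concentrations_mm=conc, yield_result=yres,
        specific_rate=SpecificRate(value=rate, window=(t0, t1)),
        course=course,
    )


def read_bioconversion_csv(path, **kwargs) -> BioconversionCourse:
    """Read a course CSV with columns time_h, a240 and optional dilution."""
    df = pd.read_csv(path, comment="#")
    dilution = df["dilution"].to_numpy() if "dilution" in df else 1.0
    return BioconversionCourse(times=df["time_h"].to_numpy(),
                               a240=df["a240"].to_numpy(),
                               dilution=dilution, **kwargs)
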