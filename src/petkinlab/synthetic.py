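"""Synthetic measurement generator for the whole analysis pipeline.

Every input the analysis modules consume can be generated here from
explicit ground-truth parameters and a seed, with the statistical
structure the analysis assumes:

* turbidity traces with a lag phase followed by a square-root-linear
  decline whose initial rate saturates in enzyme concentration
  (Langmuir-type heterogeneous catalysis);
* two-state sigmoidal CD melt curves;
* first-order residual-activity decays;
* 96-well PSP screening plates with positive/negative controls;
* a toy receptor/pose/energy/conservation fixture with controllable
  hotspot structure for the SSM-selection triage.

Noise is additive Gaussian with standard deviation proportional to the
signal (default 2% relative), the typical behaviour of plate readers and
spectrophotometers.  All randomness flows through one seeded
``numpy.random.Generator``; the seed is recorded in output metadata, and
seeded generation is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.structure.io import pdb as pdbio

from .kinetics import RateMeasurement, TurbidityTrace, langmuir_rate
from .stability import ActivitySeries, MeltCurve
from .screening import PlateLayout, PlateReading
from .hotspots import PoseSet

__all__ = [
    "SimulationConfig", "KineticGroundTruth", "MeltGroundTruth",
    "DecayGroundTruth", "ResidueSpec", "PoseSpec", "HotspotScenario",
    "simulate_turbidity", "simulate_rate_dataset", "simulate_melt",
    "simulate_decay",
    "simulate_plate", "simulate_structures_and_tables",
    "default_plate_layout", "write_melt_csv", "write_activity_csv",
    "write_plate_csv", "write_hotspot_fixture",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Shared simulation settings.

    ``noise_sd_rel`` is the Gaussian noise SD as a fraction of the local
    signal; ``lag_time`` (minutes) models the mixing/settling phase before
    the turbidity decline becomes linear; ``sampling_interval`` is in
    seconds and ``duration`` in minutes.
    """

    seed: int = 0
    noise_sd_rel: float = 0.02
    lag_time: float = 1.5
    sampling_interval: float = 10.0
    duration: float = 20.0

    def __post_init__(self):
        if self.noise_sd_rel < 0:
            raise ValueError("noise_sd_rel must be >= 0")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be > 0")
        if self.lag_time < 0:
            raise ValueError("lag_time must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class KineticGroundTruth:
    """True Langmuir parameters and the concentration series to probe."""

    k_tau: float = 0.076    # 1/min
    K_A: float = 37.95      # mL/mg
    enzyme_concs: tuple[float, ...] = (0.002, 0.005, 0.01, 0.02, 0.04, 0.08)

    def __post_init__(self):
        if self.k_tau <= 0 or self.K_A <= 0:
            raise ValueError("k_tau and K_A must be > 0")
        concs = tuple(float(c) for c in self.enzyme_concs)
        if any(c < 0 for c in concs) or any(
                b <= a for a, b in zip(concs, concs[1:])):
            raise ValueError("enzyme_concs must be non-negative, increasing")
        object.__setattr__(self, "enzyme_concs", concs)

    def rate_at(self, e_conc: float) -> float:
        return float(langmuir_rate(e_conc, self.k_tau, self.K_A))


@dataclass(frozen=True)
class MeltGroundTruth:
    """True two-state melt: T_m, width and linear baselines."""

    t_m: float = 55.3
    transition_width: float = 2.0
    folded_baseline: tuple[float, float] = (0.0, 0.0)    # intercept, slope
    unfolded_baseline: tuple[float, float] = (-1.0, 0.0)

    def __post_init__(self):
        if self.transition_width <= 0:
            raise ValueError("transition_width must be > 0")

    def signal_at(self, temperatures) -> np.ndarray:
        T = np.asarray(temperatures, dtype=float)
        bf, mf = self.folded_baseline
        bu, mu = self.unfolded_baseline
        folded, unfolded = bf + mf * T, bu + mu * T
        frac = 1.0 / (1.0 + np.exp(
            np.clip((self.t_m - T) / self.transition_width, -500, 500)))
        return folded + (unfolded - folded) * frac


@dataclass(frozen=True)
class DecayGroundTruth:
    """True first-order inactivation: a(t) = a0 * exp(-k_in * t)."""

    k_in: float = 2.46  # 1/h
    a0: float = 1.0

    def __post_init__(self):
        if self.k_in < 0:
            raise ValueError("k_in must be >= 0")

    def activity_at(self, times) -> np.ndarray:
        return self.a0 * np.exp(-self.k_in * np.asarray(times, dtype=float))


def simulate_turbidity(gt: KineticGroundTruth, cfg: SimulationConfig,
                       e_conc: float, tau0: float = 1.0,
                       blank: float = 0.05,
                       rng: np.random.Generator | None = None
                       ) -> TurbidityTrace:
    """Forward-simulate one OD600 trace at enzyme concentration ``e_conc``.

    After the lag, (tau/tau0)(t) = max(0, 1 - v * (t - lag))^2 with
    v = k_tau * K_A * [E] / (1 + K_A * [E]); the observed OD600 is
    blank + tau0 * tau_rel plus relative Gaussian noise.  With zero noise
    the trace passes exactly through the forward model.
    """
    if e_conc < 0:
        raise ValueError(f"e_conc must be >= 0, got {e_conc}")
    rng = cfg.rng() if rng is None else rng
    times = np.arange(0.0, cfg.duration * 60.0 + 1e-9, cfg.sampling_interval)
    t_min = times / 60.0
    v = gt.rate_at(e_conc)
    decline = 1.0 - v * np.clip(t_min - cfg.lag_time, 0.0, None)
    tau_rel = np.clip(decline, 0.0, None) ** 2
    signal = tau0 * tau_rel
    noise = rng.normal(0.0, 1.0, times.size) * cfg.noise_sd_rel * signal
    return TurbidityTrace(
        times=times, od600=blank + signal + noise, od600_blank=blank,
        enzyme_conc=float(e_conc),
        meta={"seed": cfg.seed, "k_tau_true": gt.k_tau, "K_A_true": gt.K_A,
              "lag_time_min": cfg.lag_time},
    )


def simulate_rate_dataset(gt: KineticGroundTruth, cfg: SimulationConfig,
                          n_replicates: int = 3,
                          rng: np.random.Generator | None = None
                          ) -> list[RateMeasurement]:
    """Draw noisy initial-rate measurements directly from the rate law.

    This bypasses the trace level (used by the parameter-recovery suite,
    where thousands of fits are run): each measurement is the true
    Langmuir rate perturbed by relative Gaussian noise, and the known
    per-point noise SD is carried along in ``rate_sd`` so the fit can
    weight points the way a practitioner would weight replicate SDs.
    """
    rng = cfg.rng() if rng is None else rng
    out = []
    for e in gt.enzyme_concs:
        true = gt.rate_at(e)
        sd = cfg.noise_sd_rel * true
        for _ in range(n_replicates):
            rate = max(0.0, true + rng.normal(0.0, 1.0) * sd)
            out.append(RateMeasurement(
                enzyme_conc=e, rate=rate, window=(cfg.lag_time, cfg.duration),
                window_r2=1.0, rate_sd=sd if sd > 0 else None))
    return out


def simulate_melt(gt: MeltGroundTruth, cfg: SimulationConfig,
                  temperatures=None,
                  rng: np.random.Generator | None = None) -> MeltCurve:
    """Simulate a CD melt ramp; flags (not fails) a T_m outside the grid.

    The noise SD is ``noise_sd_rel`` times the transition amplitude (the
    baseline separation at T_m), since raw ellipticity can cross zero.
    """
    rng = cfg.rng() if rng is None else rng
    if temperatures is None:
        temperatures = np.arange(30.0, 75.0 + 1e-9, 0.5)
    T = np.asarray(temperatures, dtype=float)
    warnings = ()
    if not (T[0] <= gt.t_m <= T[-1]):
        warnings = ("t_m outside temperature range",)
    signal = gt.signal_at(T)
    bf, mf = gt.folded_baseline
    bu, mu = gt.unfolded_baseline
    amplitude = abs((bu + mu * gt.t_m) - (bf + mf * gt.t_m))
    noise = rng.normal(0.0, 1.0, T.size) * cfg.noise_sd_rel * amplitude
    return MeltCurve(temperatures=T, signal=signal + noise,
                     warnings=warnings)


def simulate_decay(gt: DecayGroundTruth, times, cfg: SimulationConfig
                   | None = None,
                   rng: np.random.Generator | None = None) -> ActivitySeries:
    """Simulate a residual-activity time course (times in hours)."""
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    activity = gt.activity_at(times)
    if cfg is not None and cfg.noise_sd_rel > 0:
        rng = cfg.rng() if rng is None else rng
        activity = activity + rng.normal(0.0, 1.0, times.size) \
            * cfg.noise_sd_rel * activity
        activity = np.clip(activity, 0.0, 1.5)
    return ActivitySeries(times=times, activity=activity)


def default_plate_layout(n_parent: int = 4, n_negative: int = 4
                         ) -> PlateLayout:
    """Controls down column 12, samples everywhere else."""
    roles = {}
    rows = "ABCDEFGH"
    for i, row in enumerate(rows):
        for col in range(1, 13):
            well = f"{row}{col}"
            if col == 12:
                if i < n_parent:
                    roles[well] = "parent_control"
                elif i < n_parent + n_negative:
                    roles[well] = "negative_control"
                else:
                    roles[well] = "empty"
            else:
                roles[well] = "sample"
    return PlateLayout(roles)


def simulate_plate(layout: PlateLayout, effect_spec: dict[str, float],
                   cfg: SimulationConfig, neg_mean: float = 0.80,
                   parent_mean: float = 0.40,
                   rng: np.random.Generator | None = None) -> PlateReading:
    """Simulate PSP endpoint absorbances for a plate.

    ``effect_spec`` maps each sample well to its relative activity (1 =
    parent-like, 0 = inactive, >1 improved).  The expected A540
    interpolates linearly between the negative-control mean (activity 0)
    and the parent-control mean (activity 1) and extrapolates beyond for
    improved clones; the true dye response is sigmoidal in pH, but over
    the screened range a linear map is adequate and keeps the scoring
    round-trip exact.
    """
    rng = cfg.rng() if rng is None else rng
    a540 = {}
    for well, role in layout.roles.items():
        if role == "empty":
            continue
        if role == "parent_control":
            mean = parent_mean
        elif role == "negative_control":
            mean = neg_mean
        elif role == "blank":
            mean = neg_mean
        else:
            if well not in effect_spec:
                raise ValueError(f"effect_spec missing sample well {well}")
            mean = neg_mean - effect_spec[well] * (neg_mean - parent_mean)
        val = mean + rng.normal(0.0, 1.0) * cfg.noise_sd_rel * abs(mean)
        a540[well] = max(val, 0.0)
    return PlateReading(layout=layout, a540=a540,
                        meta={"seed": cfg.seed, "neg_mean": neg_mean,
                              "parent_mean": parent_mean})


# ---------------------------------------------------------------------------
# Hotspot fixture generator


@dataclass(frozen=True)
class ResidueSpec:
    """Target mean binding-energy contribution and conservation rate."""

    res_id: int
    mean_dg: float
    rate: float
    sd: float = 0.1
    res_name: str = "ALA"


@dataclass(frozen=True)
class PoseSpec:
    """Controlled catalytic-geometry distances (Angstrom) for one pose.

    ``d_ester_og``: ester carbon to Ser gamma-O; ``d_o_tyr`` /
    ``d_o_met``: carbonyl oxygen to the two oxyanion-hole backbone
    nitrogens.  ``shift`` rigidly translates the whole pose (used to
    construct clustering scenarios; it also moves the ester atoms).
    """

    d_ester_og: float = 3.5
    d_o_tyr: float = 3.0
    d_o_met: float = 3.0
    score: float = 0.0
    shift: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass(frozen=True)
class HotspotScenario:
    """Residue tables plus docked-pose geometry for a triage fixture."""

    residues: tuple[ResidueSpec, ...] = ()
    poses: tuple[PoseSpec, ...] = (PoseSpec(),)

    def __post_init__(self):
        ids = [r.res_id for r in self.residues]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate residue identifiers in scenario")


# receptor anchor geometry: Ser OG at the origin, the two oxyanion-hole
# backbone nitrogens 1.5 A away on the x axis
_OG = np.array([0.0, 0.0, 0.0])
_TYR_N = np.array([1.5, 0.0, 0.0])
_MET_N = np.array([-1.5, 0.0, 0.0])


def _build_receptor(scenario: HotspotScenario,
                    ser_res: int = 160, tyr_res: int = 87,
                    met_res: int = 161) -> struc.AtomArray:
    names = {r.res_id: r.res_name for r in scenario.residues}
    atoms = [
        struc.Atom(_TYR_N, chain_id="A", res_id=tyr_res,
                   res_name=names.get(tyr_res, "TYR"), atom_name="N",
                   element="N"),
        struc.Atom([2.9, 0.8, 0.0], chain_id="A", res_id=tyr_res,
                   res_name=names.get(tyr_res, "TYR"), atom_name="CA",
                   element="C"),
        struc.Atom([0.0, -1.4, 1.0], chain_id="A", res_id=ser_res,
                   res_name=names.get(ser_res, "SER"), atom_name="CA",
                   element="C"),
        struc.Atom(_OG, chain_id="A", res_id=ser_res,
                   res_name=names.get(ser_res, "SER"), atom_name="OG",
                   element="O"),
        struc.Atom(_MET_N, chain_id="A", res_id=met_res,
                   res_name=names.get(met_res, "MET"), atom_name="N",
                   element="N"),
        struc.Atom([-2.9, 0.8, 0.0], chain_id="A", res_id=met_res,
                   res_name=names.get(met_res, "MET"), atom_name="CA",
                   element="C"),
    ]
    special = {ser_res, tyr_res, met_res}
    for i, spec in enumerate(r for r in scenario.residues
                             if r.res_id not in special):
        atoms.append(struc.Atom([10.0 + 3.8 * i, 6.0, 6.0], chain_id="A",
                                res_id=spec.res_id, res_name=spec.res_name,
                                atom_name="CA", element="C"))
    arr = struc.array(sorted(atoms, key=lambda a: a.res_id))
    return arr


def _build_pose(spec: PoseSpec) -> struc.AtomArray:
    dc, dot, dom = spec.d_ester_og, spec.d_o_tyr, spec.d_o_met
    # carbonyl O constrained by its distances to the two fixed nitrogens
    x = (dom ** 2 - dot ** 2) / 6.0
    y2 = dot ** 2 - (x - _TYR_N[0]) ** 2
    if y2 < 0:
        raise ValueError(
            f"infeasible pose geometry: d_o_tyr={dot}, d_o_met={dom}"
        )
    o_pos = np.array([x, np.sqrt(y2), 0.0])
    c_pos = np.array([0.0, 0.0, dc])  # ester C straight above the Ser OG
    shift = np.asarray(spec.shift, dtype=float)
    coords = [c_pos, o_pos, o_pos + [0.0, 0.0, 1.4], c_pos + [1.4, 0.0, 0.0]]
    names = ["C1", "O1", "C2", "C3"]
    elements = ["C", "O", "C", "C"]
    return struc.array([
        struc.Atom(xyz + shift, chain_id="B", res_id=1, res_name="LIG",
                   atom_name=nm, element=el, hetero=True)
        for xyz, nm, el in zip(coords, names, elements)
    ])


def simulate_structures_and_tables(scenario: HotspotScenario):
    """Build (PoseSet, energy table, conservation table) for a scenario.

    The receptor is a minimal PDB-style structure carrying the catalytic
    Ser OG and the two oxyanion-hole backbone N atoms at fixed anchor
    coordinates plus one CA per scenario residue; each pose realises its
    specified catalytic distances exactly (ester group = atoms C1/O1).
    An empty scenario yields empty tables and the default single pose.
    """
    import pandas as pd

    pose_set = PoseSet(
        receptor=_build_receptor(scenario),
        poses=struc.stack([_build_pose(p) for p in scenario.poses]),
        ester_groups=[(0, 1)],
        scores=np.array([p.score for p in scenario.poses]),
    )
    energy = pd.DataFrame(
        [{"residue": r.res_id, "mean_dg": r.mean_dg, "sd": r.sd}
         for r in scenario.residues],
        columns=["residue", "mean_dg", "sd"])
    conservation = pd.DataFrame(
        [{"position": r.res_id, "rate": r.rate} for r in scenario.residues],
        columns=["position", "rate"])
    return pose_set, energy, conservation


# ---------------------------------------------------------------------------
# CSV / PDB writers


def _write_csv(path, meta: dict, header: str, rows) -> None:
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}={val}\n")
        fh.write(header + "\n")
        for row in rows:
            fh.write(",".join(f"{v:.8g}" if isinstance(v, float) else str(v)
                              for v in row) + "\n")


def write_melt_csv(curve: MeltCurve, path, meta: dict | None = None) -> None:
    _write_csv(path, meta or {}, "temp_C,signal",
               zip(curve.temperatures.tolist(), curve.signal.tolist()))


def write_activity_csv(series: ActivitySeries, path,
                       meta: dict | None = None) -> None:
    _write_csv(path, meta or {}, "time_h,activity_frac",
               zip(series.times.tolist(), series.activity.tolist()))


def write_plate_csv(reading: PlateReading, path) -> None:
    rows = [(w, float(v)) for w, v in sorted(reading.a540.items())]
    _write_csv(path, dict(reading.meta), "well,a540", rows)


def write_hotspot_fixture(scenario: HotspotScenario, out_dir) -> dict:
    """Write receptor.pdb, poses.pdb, esters.csv, scores.csv and tables.

    Returns the mapping of logical names to file paths.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pose_set, energy, conservation = simulate_structures_and_tables(scenario)
    paths = {name: out / fname for name, fname in [
        ("receptor", "receptor.pdb"), ("poses", "poses.pdb"),
        ("esters", "esters.csv"), ("scores", "scores.csv"),
        ("energy", "energy.csv"), ("conservation", "conservation.csv")]}
    f = pdbio.PDBFile()
    f.set_structure(pose_set.receptor)
    f.write(str(paths["receptor"]))
    f = pdbio.PDBFile()
    f.set_structure(pose_set.poses)
    f.write(str(paths["poses"]))
    # PDB serials are 1-based atom indices within each MODEL
    _write_csv(paths["esters"], {}, "c_serial,o_serial",
               [(c + 1, o + 1) for c, o in pose_set.ester_groups])
    _write_csv(paths["scores"], {}, "pose,score",
               [(i, float(s)) for i, s in enumerate(pose_set.scores)])
    energy.to_csv(paths["energy"], index=False)
    conservation.to_csv(paths["conservation"], index=False)
    return paths
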