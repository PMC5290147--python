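"""Synthetic single-cell force spectroscopy (SCFS) data with known ground truth.

This module emulates the measurement structure of an AFM-based SCFS study of
integrin-mediated fibroblast adhesion to fibronectin fragments:

* per-condition adhesion forces that strengthen and saturate over contact
  times (default grid 5, 20, 50 and 120 s), with cell-to-cell and within-cell
  variability;
* full force-distance retract curves whose baseline-corrected global minimum
  encodes the adhesion force, with optional discrete rupture events, Gaussian
  force noise and a linear baseline drift;
* single-molecule curves (low setpoint, near-zero contact time) that contain
  one specific rupture event with a per-condition binding probability;
* thermal-noise cantilever deflection traces obeying equipartition.

Every emitted curve carries a :class:`TruthRecord`, so downstream estimators
(adhesion-force extraction, event detection, binding-probability and
spring-constant estimation, slope and interaction statistics) can be validated
against ground truth.  A fixed master seed makes every output reproducible
bit for bit; per-cell random substreams are derived from
``SeedSequence([seed, condition_index, cell_index])`` so adding a condition
never perturbs the draws of existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.constants import k as BOLTZMANN_K

from .processing import ForceCurve, Segment

__all__ = [
    "ConditionSpec",
    "AcquisitionParams",
    "SimulationConfig",
    "CELL_SCALE_SETPOINT",
    "SINGLE_MOLECULE_SETPOINT",
    "mean_adhesion_force",
    "sample_cell_adhesion",
    "simulate_retract_curve",
    "simulate_single_molecule_curve",
    "simulate_single_molecule_batch",
    "simulate_adhesion_table",
    "simulate_dataset",
    "simulate_thermal_noise",
    "default_study_config",
    "additive_config",
    "single_molecule_acquisition",
]

#: cell-scale contact setpoint (2 nN)
CELL_SCALE_SETPOINT = 2e-9
#: single-molecule contact setpoint (200 pN)
SINGLE_MOLECULE_SETPOINT = 2e-10

#: default rupture-force model for a single integrin-ligand bond:
#: truncated normal, mean 60 pN, s.d. 15 pN, floor 20 pN
RUPTURE_MEAN = 60e-12
RUPTURE_SD = 15e-12
RUPTURE_FLOOR = 20e-12

# geometry of the synthetic retract trace (fractions of retract travel)
_DETACH_FRACTION = 0.40   # cell-detachment ramp relaxes to baseline here
_EVENT_MAX_FRACTION = 0.70  # events must end before this point: clean tail
_EVENT_LOAD_SAMPLES = 50  # samples of negative loading ramp before a rupture


@dataclass(frozen=True)
class ConditionSpec:
    """Generative model of one experimental condition (one cell line/treatment).

    The mean adhesion force follows a saturating exponential
    ``f_floor + f_max * (1 - exp(-t / tau))``; a floor-only condition
    (``f_max == 0``) models the negligible-adhesion control.  ``p_bind`` is the
    probability that a single-molecule contact yields a specific rupture event.
    """

    name: str
    f_max: float            # N, saturating plateau above the floor
    tau: float              # s, saturation timescale
    f_floor: float = 0.0    # N, nonspecific adhesion level
    cell_sd_rel: float = 0.25   # relative s.d. of per-cell multiplicative effect
    meas_sd: float = 1.5e-10    # N, within-cell measurement s.d.
    p_bind: float = 0.0     # single-molecule specific-binding probability

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("condition name must be non-empty")
        if self.f_max < 0 or self.f_floor < 0:
            raise ValueError("f_max and f_floor must be >= 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if not 0.0 <= self.p_bind <= 1.0:
            raise ValueError("p_bind must be in [0, 1]")
        if self.cell_sd_rel < 0 or self.meas_sd < 0:
            raise ValueError("cell_sd_rel and meas_sd must be >= 0")


@dataclass(frozen=True)
class AcquisitionParams:
    """AFM acquisition parameters shared by all synthetic curves.

    Defaults follow common SCFS practice: 0.06 N/m cantilevers retracted at
    5 um/s after a 2 nN contact, at 37 C (310 K).  ``retract_length`` and
    ``sampling_rate`` set the number of retract samples
    (``retract_length / retract_speed * sampling_rate``).
    """

    spring_constant: float = 0.06    # N/m
    retract_speed: float = 5e-6      # m/s
    sampling_rate: float = 2000.0    # Hz
    setpoint_force: float = CELL_SCALE_SETPOINT  # N
    noise_sd: float = 1e-11          # N, per-sample Gaussian force noise (10 pN)
    drift_slope: float = 0.0         # N/m, linear baseline tilt vs height
    temperature: float = 310.0       # K
    retract_length: float = 5e-6     # m

    def __post_init__(self) -> None:
        if self.spring_constant <= 0:
            raise ValueError("spring_constant must be > 0")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.retract_speed <= 0 or self.retract_length <= 0:
            raise ValueError("retract geometry must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")

    @property
    def n_retract_samples(self) -> int:
        return max(2, int(round(self.retract_length / self.retract_speed
                                * self.sampling_rate)))


def single_molecule_acquisition(**overrides) -> AcquisitionParams:
    """Acquisition preset for single-molecule sensitivity (200 pN setpoint,
    short retract range appropriate for molecular rupture lengths)."""
    params = dict(setpoint_force=SINGLE_MOLECULE_SETPOINT, retract_length=2e-6)
    params.update(overrides)
    return AcquisitionParams(**params)


@dataclass(frozen=True)
class SimulationConfig:
    """Full generative specification of one synthetic SCFS experiment."""

    conditions: tuple[ConditionSpec, ...]
    contact_times: tuple[float, ...] = (5.0, 20.0, 50.0, 120.0)
    n_cells: int = 10
    curves_per_cell_per_time: int = 1
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "conditions", tuple(self.conditions))
        object.__setattr__(self, "contact_times", tuple(self.contact_times))
        names = [c.name for c in self.conditions]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate condition names: {dupes}")
        times = np.asarray(self.contact_times, dtype=float)
        if times.size == 0 or np.any(times <= 0) or np.any(np.diff(times) <= 0):
            raise ValueError("contact_times must be positive and strictly increasing")
        if self.n_cells < 1 or self.curves_per_cell_per_time < 1:
            raise ValueError("n_cells and curves_per_cell_per_time must be >= 1")


def mean_adhesion_force(cond: ConditionSpec, t: float) -> float:
    """Mean adhesion force of ``cond`` at contact time ``t`` (seconds).

    Saturating exponential ``f_floor + f_max * (1 - exp(-t/tau))``:
    non-decreasing in ``t``, equal to the nonspecific floor at ``t = 0`` and
    approaching ``f_floor + f_max`` as ``t`` grows.
    """
    t = float(t)
    if t < 0:
        raise ValueError("contact time must be >= 0")
    return cond.f_floor + cond.f_max * (-math.expm1(-t / cond.tau))


def sample_cell_adhesion(cond: ConditionSpec, t: float, cell_effect: float,
                         rng: np.random.Generator) -> float:
    """Draw one adhesion force for a cell with multiplicative ``cell_effect``.

    ``max(0, cell_effect * mean + Normal(0, meas_sd))`` — the truncation at
    zero mirrors that adhesion forces are reported as non-negative magnitudes.
    """
    if cell_effect <= 0:
        raise ValueError("cell_effect must be > 0")
    value = cell_effect * mean_adhesion_force(cond, t)
    if cond.meas_sd > 0:
        value += rng.normal(0.0, cond.meas_sd)
    return max(0.0, value)


def _lognormal_cell_effects(rel_sd: float, n: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Unit-mean lognormal multipliers with relative s.d. ``rel_sd``."""
    if rel_sd == 0:
        return np.ones(n)
    s2 = math.log1p(rel_sd ** 2)
    return rng.lognormal(mean=-s2 / 2.0, sigma=math.sqrt(s2), size=n)


# ---------------------------------------------------------------------------
# force-distance curve construction
# ---------------------------------------------------------------------------

def simulate_retract_curve(true_adhesion_force: float,
                           events: list[tuple[float, float]],
                           acq: AcquisitionParams,
                           rng: np.random.Generator,
                           *,
                           curve_id: str = "curve",
                           cell_id: str = "",
                           condition: str = "",
                           contact_time: float = 0.0) -> ForceCurve:
    """Construct a synthetic force-distance curve with a retract segment.

    The retract force is the pointwise minimum of a cell-detachment ramp
    (force ``-true_adhesion_force`` at the surface, relaxing linearly to the
    baseline within the first 40% of travel) and per-event loading ramps that
    dip to ``-step`` just before each event position and jump back to the
    baseline there.  Gaussian noise (``acq.noise_sd``) and a linear baseline
    drift (``acq.drift_slope * height``) are added on top.  Before noise, the
    baseline-corrected global minimum therefore equals
    ``-max(true_adhesion_force, largest event step)``; with no events it is
    exactly ``-true_adhesion_force``.  The last 30% of travel is event-free
    baseline, available for tail fitting.
    """
    if true_adhesion_force < 0:
        raise ValueError("true_adhesion_force must be >= 0")
    n = acq.n_retract_samples
    length = acq.retract_length
    height = np.linspace(0.0, length, n)
    force = np.zeros(n)

    if true_adhesion_force > 0:
        h_detach = _DETACH_FRACTION * length
        ramp = -true_adhesion_force * np.clip(1.0 - height / h_detach, 0.0, None)
        force = np.minimum(force, ramp)

    dx = length / (n - 1)
    for pos, step in events:
        if not 0.0 <= pos <= length:
            raise ValueError(f"event position {pos!r} outside retract range "
                             f"[0, {length!r}]")
        if pos > _EVENT_MAX_FRACTION * length:
            raise ValueError("event position lies in the reserved baseline tail "
                             f"(beyond {_EVENT_MAX_FRACTION:.0%} of travel)")
        if step <= 0:
            raise ValueError("event step must be > 0")
        j = int(np.searchsorted(height, pos))          # first index at/after pos
        j0 = max(0, j - _EVENT_LOAD_SAMPLES)
        contrib = np.zeros(n)
        if j > j0:
            depth = np.arange(1, j - j0 + 1) / (j - j0)
            contrib[j0:j] = -step * depth
        force = np.minimum(force, contrib)

    force = force + acq.drift_slope * height
    if acq.noise_sd > 0:
        force = force + rng.normal(0.0, acq.noise_sd, n)

    # minimal approach/dwell segments for structural completeness
    n_app = 200
    app_height = np.linspace(2e-6, 0.0, n_app)
    app_force = np.linspace(0.0, acq.setpoint_force, n_app)
    n_dwell = int(np.clip(contact_time * acq.sampling_rate, 2, 200))
    dwell_height = np.zeros(n_dwell)
    dwell_force = np.full(n_dwell, acq.setpoint_force)

    meta = {
        "spring_constant": acq.spring_constant,
        "retract_speed": acq.retract_speed,
        "setpoint_force": acq.setpoint_force,
        "contact_time_s": float(contact_time),
    }
    return ForceCurve(
        curve_id=curve_id,
        segments={
            "approach": Segment(app_height, app_force),
            "dwell": Segment(dwell_height, dwell_force),
            "retract": Segment(height, force),
        },
        meta=meta,
        condition=condition,
        cell_id=cell_id,
    )


def _draw_rupture_force(rng: np.random.Generator) -> float:
    """Rupture force from the truncated normal (60 +/- 15 pN, floor 20 pN)."""
    while True:
        f = rng.normal(RUPTURE_MEAN, RUPTURE_SD)
        if f >= RUPTURE_FLOOR:
            return f


def simulate_single_molecule_curve(cond: ConditionSpec, acq: AcquisitionParams,
                                   rng: np.random.Generator,
                                   *, curve_id: str = "sm",
                                   cell_id: str = "") -> tuple[ForceCurve, dict]:
    """One single-molecule curve: with probability ``cond.p_bind`` it contains
    one rupture event (truncated-normal rupture force), otherwise it is bare
    noisy baseline.  Returns the curve and its truth record (dict)."""
    bound = bool(rng.random() < cond.p_bind)
    events: list[tuple[float, float]] = []
    rupture = math.nan
    if bound:
        rupture = _draw_rupture_force(rng)
        pos = rng.uniform(0.2, 0.6) * acq.retract_length
        events.append((pos, rupture))
    curve = simulate_retract_curve(
        0.0, events, acq, rng, curve_id=curve_id, cell_id=cell_id,
        condition=cond.name, contact_time=0.0)
    truth = {
        "curve_id": curve_id,
        "cell_id": cell_id,
        "condition": cond.name,
        "contact_time_s": 0.0,
        "true_adhesion_force_N": rupture if bound else 0.0,
        "bound": bound,
        "true_rupture_force_N": rupture,
    }
    return curve, truth


def simulate_single_molecule_batch(cond: ConditionSpec, n_cells: int,
                                   curves_per_cell: int, seed: int,
                                   acq: AcquisitionParams | None = None,
                                   ) -> tuple[list[ForceCurve], pd.DataFrame]:
    """Batch of single-molecule curves for ``n_cells`` cells, with truth table."""
    if acq is None:
        acq = single_molecule_acquisition()
    curves: list[ForceCurve] = []
    truths: list[dict] = []
    for ci in range(n_cells):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0, ci]))
        cell_id = f"cell{ci:03d}"
        for k in range(curves_per_cell):
            cid = f"{cond.name}-{cell_id}-sm{k:04d}"
            curve, truth = simulate_single_molecule_curve(
                cond, acq, rng, curve_id=cid, cell_id=cell_id)
            curves.append(curve)
            truths.append(truth)
    return curves, pd.DataFrame(truths)


# ---------------------------------------------------------------------------
# dataset-level simulation
# ---------------------------------------------------------------------------

def _cell_rng(seed: int, cond_index: int, cell_index: int) -> np.random.Generator:
    """Documented substream scheme: one generator per (condition, cell)."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, cond_index, cell_index]))


def simulate_adhesion_table(config: SimulationConfig) -> pd.DataFrame:
    """Tidy adhesion-force table (cell_id, condition, contact_time_s,
    adhesion_force_N) drawn from the hierarchical force model, without
    constructing force-distance curves.  Fast path for statistical studies;
    :func:`simulate_dataset` emits the same forces as full curves."""
    rows = []
    for gi, cond in enumerate(config.conditions):
        for ci in range(config.n_cells):
            rng = _cell_rng(config.seed, gi, ci)
            effect = float(_lognormal_cell_effects(cond.cell_sd_rel, 1, rng)[0])
            cell_id = f"{cond.name}-cell{ci:03d}"
            for t in config.contact_times:
                for _ in range(config.curves_per_cell_per_time):
                    force = sample_cell_adhesion(cond, t, effect, rng)
                    rows.append((cell_id, cond.name, float(t), force))
    return pd.DataFrame(
        rows, columns=["cell_id", "condition", "contact_time_s",
                       "adhesion_force_N"])


def simulate_dataset(config: SimulationConfig
                     ) -> tuple[list[ForceCurve], pd.DataFrame]:
    """Simulate the full experiment: per condition, ``n_cells`` cells, each
    probed at every contact time.  Returns (curves, truth table); the truth
    table has exactly one record per curve and is deterministic under a fixed
    seed (byte-identical when written with :mod:`scfskit.io`)."""
    curves: list[ForceCurve] = []
    truths: list[dict] = []
    for gi, cond in enumerate(config.conditions):
        for ci in range(config.n_cells):
            rng = _cell_rng(config.seed, gi, ci)
            effect = float(_lognormal_cell_effects(cond.cell_sd_rel, 1, rng)[0])
            cell_id = f"{cond.name}-cell{ci:03d}"
            for ti, t in enumerate(config.contact_times):
                for k in range(config.curves_per_cell_per_time):
                    force = sample_cell_adhesion(cond, t, effect, rng)
                    cid = f"{cond.name}-cell{ci:03d}-t{ti}-r{k}"
                    curve = simulate_retract_curve(
                        force, [], config.acquisition, rng, curve_id=cid,
                        cell_id=cell_id, condition=cond.name, contact_time=t)
                    curves.append(curve)
                    truths.append({
                        "curve_id": cid,
                        "cell_id": cell_id,
                        "condition": cond.name,
                        "contact_time_s": float(t),
                        "true_adhesion_force_N": force,
                        "bound": True,
                        "true_rupture_force_N": math.nan,
                    })
    return curves, pd.DataFrame(truths)


def simulate_thermal_noise(k: float, T: float, n: int,
                           rng: np.random.Generator,
                           drift_slope: float = 0.0) -> np.ndarray:
    """Thermal cantilever deflection trace: i.i.d. Gaussian samples with
    equipartition variance ``k_B * T / k`` (metres), plus optional linear
    drift ``drift_slope * i / n`` across the trace."""
    if k <= 0 or T <= 0:
        raise ValueError("spring constant and temperature must be > 0")
    if n < 2:
        raise ValueError("need at least 2 samples")
    sd = math.sqrt(BOLTZMANN_K * T / k)
    trace = rng.normal(0.0, sd, n)
    if drift_slope != 0.0:
        trace = trace + drift_slope * np.linspace(0.0, 1.0, n)
    return trace


# ---------------------------------------------------------------------------
# study presets
# ---------------------------------------------------------------------------

def default_study_config(seed: int = 0, n_cells: int = 10,
                         acq: AcquisitionParams | None = None
                         ) -> SimulationConfig:
    """The four fibroblast lines of the adhesion study.

    pKO (pan-integrin knockout) shows only a nonspecific floor; the three
    reconstituted lines strengthen adhesion over contact time.  The line
    expressing only a5b1 (pKO-b1) reaches roughly twice the 120 s adhesion of
    the lines carrying aV-class integrins (the competition signature).
    Single-molecule binding probabilities follow the reported regimes: 0.10
    nonspecific, 0.40 for aV-class alone, 0.12 for a5b1 alone, 0.25 for the
    double-reconstituted line.
    """
    conditions = (
        ConditionSpec("pKO", f_max=0.0, tau=50.0, f_floor=1.5e-10,
                      p_bind=0.10),
        ConditionSpec("pKO-aV", f_max=1.6e-9, tau=60.0, f_floor=1.5e-10,
                      p_bind=0.40),
        ConditionSpec("pKO-b1", f_max=3.6e-9, tau=45.0, f_floor=1.5e-10,
                      p_bind=0.12),
        ConditionSpec("pKO-aV-b1", f_max=1.8e-9, tau=60.0, f_floor=1.5e-10,
                      p_bind=0.25),
    )
    return SimulationConfig(conditions=conditions, n_cells=n_cells, seed=seed,
                            acquisition=acq or AcquisitionParams())


def additive_config(seed: int = 0, n_cells: int = 10,
                    acq: AcquisitionParams | None = None) -> SimulationConfig:
    """Quartet of conditions built to satisfy the additive null exactly in
    expectation: mean F_AB(t) + mean F_0(t) = mean F_A(t) + mean F_B(t) at
    every contact time (shared tau, floors and plateaus adding up), so the
    interaction statistic epsilon is centred at zero downstream."""
    floor = 1.5e-10
    tau = 50.0
    a = ConditionSpec("A", f_max=1.5e-9, tau=tau, f_floor=floor)
    b = ConditionSpec("B", f_max=2.0e-9, tau=tau, f_floor=floor)
    null = ConditionSpec("0", f_max=0.0, tau=tau, f_floor=floor)
    ab = ConditionSpec("AB", f_max=a.f_max + b.f_max, tau=tau,
                       f_floor=a.f_floor + b.f_floor - null.f_floor)
    return SimulationConfig(conditions=(ab, a, b, null), n_cells=n_cells,
                            seed=seed, acquisition=acq or AcquisitionParams())
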