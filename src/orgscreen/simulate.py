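"""Seeded generative model of a 384-well organoid drug screen.

The simulator plants known ground truth so every downstream stage —
control-anchored response metrics, single-organoid classification, invasion
scoring, embedding/trajectory mapping — can be tested without real imaging
data. The generative model is deliberately minimal:

* Each organoid belongs to a clone with a growth rate ``k`` (h⁻¹), per-compound
  EC50s, a maximal cytostatic effect and a maximal death rate.
* Drug occupancy is a Hill function of concentration; multiple compounds
  combine by independent action. Occupancy scales both growth inhibition
  ``e`` and the death rate ``δ``.
* Two area compartments: live area follows ``dL/dt = (k·(1−e) − δ)·L`` and
  dead debris accumulates as ``dD/dt = δ·L`` (dead organoids stay visible
  in the brightfield mask). The emitted brightfield area is ``L + D`` and
  the dead-signal overlap is ``D``, so the net well signal ``bf − green``
  is exactly the live area and the fraction affected ``D/(L+D)`` saturates
  at 1 under a killing dose.
* The invasive annulus is fed by live cells — it grows at a rate
  proportional to the live area — gated by clone propensity × treatment
  induction (a per-compound factor lets a paclitaxel-like arm drive
  invasion); a killed organoid stops invading.
* Seeding density is Poisson on organoid count, log-normal on initial area;
  measurement noise is multiplicative log-normal on every channel.

Two technical replicates per condition and vehicle / staurosporine control
wells mirror the screen layout the analysis expects.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import PlateLayout, WellEntry

__all__ = [
    "CloneParams",
    "SimConfig",
    "GroundTruth",
    "organoid_trajectory",
    "simulate_plate",
    "default_scenarios",
    "STAUROSPORINE",
]

#: positive-control compound; 2 µM staurosporine kills everything it touches
STAUROSPORINE = ("staurosporine", 2000.0)

DEFAULT_TIMES = (0.0, 24.0, 48.0, 72.0, 96.0, 120.0)


@dataclass(frozen=True)
class CloneParams:
    """Growth and response parameters of one subclone.

    Rates are per hour. ``ec50`` maps compound name to EC50 in the same
    concentration units as the dose series (nM by convention). Compounds
    absent from the map do not affect the clone (an EC50 of infinity).
    """

    name: str
    fraction: float
    growth_rate: float = np.log(2) / 72.0  # one doubling per 72 h
    ec50: dict[str, float] = field(default_factory=dict)
    hill: float = 2.0
    max_growth_inhibition: float = 0.0  # cytostatic e_max in [0, 1]
    max_death_rate: float = 0.0  # cytotoxic δ_max, h⁻¹
    invasion_propensity: float = 0.0

    def validate(self) -> None:
        if not (0 <= self.fraction <= 1):
            raise ConfigError(f"clone {self.name}: fraction must be in [0,1]")
        if not np.isfinite(self.growth_rate):
            raise ConfigError(f"clone {self.name}: growth_rate must be finite")
        if any(e <= 0 or not np.isfinite(e) for e in self.ec50.values()):
            raise ConfigError(f"clone {self.name}: EC50 values must be finite and > 0")
        if not (0 <= self.max_growth_inhibition <= 1):
            raise ConfigError(f"clone {self.name}: max_growth_inhibition must be in [0,1]")
        if self.max_death_rate < 0 or self.invasion_propensity < 0 or self.hill <= 0:
            raise ConfigError(f"clone {self.name}: rates must be non-negative, hill > 0")

    def occupancy(self, dose: dict[str, float]) -> float:
        """Combined Hill occupancy of a multi-compound dose (independent action)."""
        free = 1.0
        for compound, conc in dose.items():
            ec50 = self.ec50.get(compound)
            if ec50 is None or conc <= 0:
                continue
            free *= 1.0 - conc**self.hill / (conc**self.hill + ec50**self.hill)
        return 1.0 - free


#: staurosporine-response parameters shared by every clone: complete growth
#: arrest plus a fast death rate so positive-control wells are fully dead
#: (green/bf ≈ 1, net live signal ≈ 0) by the end of a 120 h screen.
STAURO_EC50 = 50.0
STAURO_DEATH_RATE = 0.2


@dataclass(frozen=True)
class SimConfig:
    """Full description of one simulated screen."""

    clones: tuple[CloneParams, ...]
    regimens: dict[str, list[dict[str, float]]] = field(default_factory=dict)
    invasion_induction: dict[str, float] = field(default_factory=dict)  # per-compound factor
    n_replicates: int = 2
    n_control_wells: int = 2
    organoids_per_well: float = 200.0
    times: tuple[float, ...] = DEFAULT_TIMES
    init_area: float = 2000.0  # µm², log-normal median
    init_area_sd: float = 0.4  # log-sd of initial area
    noise_sd: float = 0.05  # multiplicative log-normal sd, all channels
    invasion_rate: float = 0.02  # h⁻¹, annulus growth rate
    invasion_scale: float = 0.05  # annulus area at t→0+ relative to A0
    brightness0: float = 100.0
    texture0: float = 10.0
    plate_id: str = "simplate"
    patient_id: str = "SIM001"
    seed: int = 0

    def validate(self) -> None:
        total = sum(c.fraction for c in self.clones)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"clone fractions must sum to 1 (got {total})")
        for clone in self.clones:
            clone.validate()
        if list(self.times) != sorted(self.times) or self.times[0] != 0:
            raise ConfigError("time grid must be sorted ascending and start at 0")
        if any(f < 0 for f in self.invasion_induction.values()):
            raise ConfigError("invasion induction factors must be >= 0")
        if self.noise_sd < 0 or self.organoids_per_well <= 0:
            raise ConfigError("noise_sd must be >= 0 and organoids_per_well > 0")


def _effect(clone: CloneParams, dose: dict[str, float]) -> tuple[float, float]:
    """(growth inhibition e, death rate δ) for a clone under a dose.

    Staurosporine acts on every clone through a shared EC50 regardless of
    its chemotherapy resistance (it is the plate's kill control).
    """
    chemo = {c: v for c, v in dose.items() if c != STAUROSPORINE[0]}
    u = clone.occupancy(chemo)
    e = clone.max_growth_inhibition * u
    delta = clone.max_death_rate * u
    stauro = dose.get(STAUROSPORINE[0], 0.0)
    if stauro > 0:
        u_s = stauro**clone.hill / (stauro**clone.hill + STAURO_EC50**clone.hill)
        e = max(e, u_s)  # complete growth arrest
        delta = delta + STAURO_DEATH_RATE * u_s
    return e, delta


def _invasion_induction(dose: dict[str, float], factors: dict[str, float],
                        clone: CloneParams) -> float:
    """Treatment- and concentration-dependent multiplier on invasion propensity."""
    ind = 1.0
    for compound, factor in factors.items():
        conc = dose.get(compound, 0.0)
        if conc > 0:
            occ = conc**clone.hill / (conc**clone.hill + clone.ec50.get(compound, conc) ** clone.hill)
            ind += factor * occ
    return ind


def organoid_trajectory(
    clone: CloneParams,
    dose: dict[str, float],
    times,
    rng: np.random.Generator | None = None,
    *,
    init_area: float = 2000.0,
    noise_sd: float = 0.05,
    invasion_induction: dict[str, float] | None = None,
    invasion_rate: float = 0.02,
    invasion_scale: float = 0.05,
    brightness0: float = 100.0,
    texture0: float = 10.0,
) -> dict[str, np.ndarray]:
    """Simulate one organoid's per-timepoint measurements.

    Returns arrays ``bf_area, green_area, inv_area, inv_green_area,
    brightness, texture, true_death_fraction`` over ``times`` (hours, sorted,
    starting at 0). With ``rng=None`` the trajectory is noise-free.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or len(t) == 0 or t[0] != 0 or np.any(np.diff(t) <= 0):
        raise ConfigError("times must be sorted ascending starting at 0")
    clone.validate()
    e, delta = _effect(clone, dose)
    g = clone.growth_rate * (1.0 - e)

    live = init_area * np.exp((g - delta) * t)
    # cumulative live-area integral I(t) = ∫₀ᵗ L(s) ds (closed form, with the
    # g → δ limit handled); dead debris D = δ·I persists in the mask
    r = g - delta
    if abs(r) > 1e-12:
        live_integral = init_area * np.expm1(r * t) / r
    else:
        live_integral = init_area * t
    dead = delta * live_integral
    bf = live + dead
    green = dead
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.where(bf > 0, green / np.where(bf > 0, bf, 1.0), 0.0)

    prop = clone.invasion_propensity * _invasion_induction(
        dose, invasion_induction or {}, clone
    )
    inv = prop * invasion_scale * invasion_rate * live_integral
    inv_green = inv * fa

    brightness = brightness0 * (1.0 + 0.5 * fa) * np.ones_like(t)
    texture = texture0 * (1.0 + fa) * np.ones_like(t)

    out = {
        "bf_area": bf,
        "green_area": green,
        "inv_area": inv,
        "inv_green_area": inv_green,
        "brightness": brightness,
        "texture": texture,
    }
    if rng is not None and noise_sd > 0:
        for key, values in out.items():
            out[key] = values * rng.lognormal(0.0, noise_sd, size=len(t))
        # noise must not break containment of the dead-signal overlaps
        out["green_area"] = np.minimum(out["green_area"], out["bf_area"])
        out["inv_green_area"] = np.minimum(out["inv_green_area"], out["inv_area"])
    out["true_death_fraction"] = fa
    return out


@dataclass
class GroundTruth:
    """Planted truth emitted alongside a simulated plate.

    ``organoids``: one row per organoid (clone label, true growth rate,
    invasive propensity flag) plus its true death fraction per timepoint in
    long form. ``wells``: one row per well with the condition and the
    noise-free expected NDR at the final timepoint.
    """

    organoids: pd.DataFrame
    wells: pd.DataFrame
    config: SimConfig


def _well_names():
    for row, col in itertools.product("ABCDEFGHIJKLMNOP", range(1, 25)):
        yield f"{row}{col:02d}"


def _expected_well_ndr(cfg: SimConfig, dose: dict[str, float]) -> float:
    """Noise-free expected NDR of a condition (population-level closed form)."""
    from .wellmetrics import ndr_metric

    def fold(d):
        s0 = s1 = 0.0
        for clone in cfg.clones:
            traj = organoid_trajectory(
                clone, d, cfg.times, None, init_area=cfg.init_area,
                invasion_induction=cfg.invasion_induction,
                invasion_rate=cfg.invasion_rate, invasion_scale=cfg.invasion_scale,
            )
            s0 += clone.fraction * (traj["bf_area"][0] - traj["green_area"][0])
            s1 += clone.fraction * (traj["bf_area"][-1] - traj["green_area"][-1])
        return s1 / s0

    return ndr_metric(fold(dose), fold({}), fold(dict([STAUROSPORINE])))


def _expected_cell_death(cfg: SimConfig, dose: dict[str, float]) -> float:
    bf = green = 0.0
    for clone in cfg.clones:
        traj = organoid_trajectory(clone, dose, cfg.times, None, init_area=cfg.init_area)
        bf += clone.fraction * traj["bf_area"][-1]
        green += clone.fraction * traj["green_area"][-1]
    return 100.0 * green / bf


def simulate_plate(cfg: SimConfig) -> tuple[pd.DataFrame, PlateLayout, GroundTruth]:
    """Simulate a full plate: measurements, layout, and planted ground truth.

    Reproducible: the same config (including seed) yields identical tables.
    """
    from .wellmetrics import classify_signature

    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    names = _well_names()

    # (well, dose, role, regimen_label, replicate)
    conditions: list[tuple[str, dict[str, float], str, str, int]] = []
    for rep in range(1, cfg.n_control_wells + 1):
        conditions.append((next(names), {}, "negative_control", "vehicle", rep))
    for rep in range(1, cfg.n_control_wells + 1):
        conditions.append((next(names), dict([STAUROSPORINE]), "positive_control",
                           STAUROSPORINE[0], rep))
    for regimen, doses in cfg.regimens.items():
        for dose in doses:
            for rep in range(1, cfg.n_replicates + 1):
                conditions.append((next(names), dose, "treatment", regimen, rep))

    clone_fracs = np.array([c.fraction for c in cfg.clones])
    meas_rows, org_rows = [], []
    layout_wells: dict[str, WellEntry] = {}
    well_rows = []
    expected_cache: dict[str, tuple[float, float]] = {}

    for well, dose, role, regimen, rep in conditions:
        layout_wells[well] = WellEntry(
            role=role,
            drugs=tuple((c, v) for c, v in dose.items()),
            replicate_id=rep,
            patient_id=cfg.patient_id,
        )
        n_org = max(1, rng.poisson(cfg.organoids_per_well))
        clone_idx = rng.choice(len(cfg.clones), size=n_org, p=clone_fracs)
        for oid in range(1, n_org + 1):
            clone = cfg.clones[clone_idx[oid - 1]]
            a0 = cfg.init_area * rng.lognormal(0.0, cfg.init_area_sd)
            traj = organoid_trajectory(
                clone, dose, cfg.times, rng,
                init_area=a0, noise_sd=cfg.noise_sd,
                invasion_induction=cfg.invasion_induction,
                invasion_rate=cfg.invasion_rate, invasion_scale=cfg.invasion_scale,
                brightness0=cfg.brightness0, texture0=cfg.texture0,
            )
            for j, t in enumerate(cfg.times):
                meas_rows.append((
                    cfg.plate_id, well, t, oid,
                    traj["bf_area"][j], traj["green_area"][j],
                    traj["inv_area"][j], traj["inv_green_area"][j],
                    traj["brightness"][j], traj["texture"][j],
                ))
                org_rows.append((
                    cfg.plate_id, well, oid, t, clone.name,
                    clone.growth_rate, traj["true_death_fraction"][j],
                    clone.invasion_propensity > 0,
                ))
        dose_key = regimen + "|" + repr(sorted(dose.items()))
        if dose_key not in expected_cache:
            expected_cache[dose_key] = (
                _expected_well_ndr(cfg, dose),
                _expected_cell_death(cfg, dose),
            )
        exp_ndr, exp_death = expected_cache[dose_key]
        well_rows.append({
            "well": well, "role": role, "regimen": regimen, "replicate_id": rep,
            "total_conc": sum(dose.values()),
            "expected_ndr": exp_ndr,
            "expected_cell_death_pct": exp_death,
            "expected_ndr_class": classify_signature(exp_ndr, exp_death).label,
        })

    measurements = pd.DataFrame(
        meas_rows,
        columns=["plate_id", "well", "time_h", "organoid_id", "bf_area", "green_area",
                 "inv_area", "inv_green_area", "brightness", "texture"],
    )
    organoids = pd.DataFrame(
        org_rows,
        columns=["plate_id", "well", "organoid_id", "time_h", "clone", "true_growth_rate",
                 "true_death_fraction", "invasive_flag"],
    )
    layout = PlateLayout(plate_id=cfg.plate_id, wells=layout_wells)
    layout.validate()
    truth = GroundTruth(organoids=organoids, wells=pd.DataFrame(well_rows), config=cfg)
    return measurements, layout, truth


def _gem_pac_doses(scales=(1.0, 5.0, 20.0, 80.0)) -> list[dict[str, float]]:
    """Gemcitabine:paclitaxel dose series at the clinical 5:1 molar ratio (nM)."""
    return [{"gemcitabine": 5.0 * s, "paclitaxel": 1.0 * s} for s in scales]


def default_scenarios(seed: int = 0) -> dict[str, SimConfig]:
    """Named screen scenarios covering the response taxonomy the pipeline resolves.

    * ``cytotoxic_responder`` — drug kills; NDR driven well below −0.5.
    * ``cytostatic_responder`` — drug arrests growth without killing; NDR ≈ 0.
    * ``heterogeneous`` — 70% sensitive / 30% resistant subclone mixture.
    * ``invasion_inducer`` — paclitaxel-like arm carries an invasion-induction
      factor, planting a treatment-driven invasive phenotype.
    """
    sensitive = CloneParams(
        name="sensitive", fraction=1.0,
        ec50={"gemcitabine": 20.0, "paclitaxel": 4.0},
        max_growth_inhibition=1.0, max_death_rate=0.04,
    )
    cytostatic = replace(sensitive, name="arrested", max_death_rate=0.0)
    resistant = CloneParams(
        name="resistant", fraction=0.3,
        ec50={"gemcitabine": 2e5, "paclitaxel": 4e4},
        max_growth_inhibition=1.0, max_death_rate=0.04,
    )
    invasive = replace(
        sensitive, name="invasive", fraction=0.4,
        max_death_rate=0.02, invasion_propensity=1.0,
    )

    return {
        "cytotoxic_responder": SimConfig(
            clones=(sensitive,), regimens={"gem-pac": _gem_pac_doses()}, seed=seed,
        ),
        "cytostatic_responder": SimConfig(
            clones=(cytostatic,), regimens={"gem-pac": _gem_pac_doses()}, seed=seed,
        ),
        "heterogeneous": SimConfig(
            clones=(replace(sensitive, fraction=0.7), resistant),
            regimens={"gem-pac": _gem_pac_doses()}, seed=seed,
        ),
        "invasion_inducer": SimConfig(
            clones=(replace(sensitive, fraction=0.6), invasive),
            regimens={
                "gemcitabine": [{"gemcitabine": 400.0}],
                "paclitaxel": [{"paclitaxel": 80.0}],
                "gem-pac": [{"gemcitabine": 400.0, "paclitaxel": 80.0}],
            },
            invasion_induction={"paclitaxel": 4.0},
            seed=seed,
        ),
    }
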