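"""Compartmental biokinetics and cumulated activities (MIRD residence times).

The central quantity is the cumulated activity Ã of each source region: the
time integral of its activity per unit administered activity, in hours
(MBq·h/MBq).  For a linear compartment system

    dA/dt = K A - λ_p A,        A(0) = A0,

the integral has the closed form Ã = (λ_p I - K)^{-1} A0, which is how this
module computes it; adaptive ODE integration is kept only as an independent
test oracle.

The iodide-in-pregnancy model implemented here follows the published
compartment structure for radioiodine kinetics during pregnancy: an
inorganic iodide pool (blood + extracellular fluid) cleared competitively by
the thyroid and the kidneys, salivary/gastric secretion into the gut with
reabsorption, organification in the thyroid with slow hormone release to an
organic pool exchanging with the liver, transplacental exchange with a fetal
pool, and avid fetal-thyroid trapping.  The governing parameter is the
maximum thyroid uptake F: the blood→thyroid rate is solved at run time so
that, with radioactive decay switched off and the thyroid treated as a trap,
the asymptotic fraction of administered iodide accumulated by the thyroid
equals F.  Rate constants live in an editable bundle
(``data/iodide_rates.json``).

Urinary-bladder contents are handled with the classical voiding-bladder
model: urine inflow accumulates in the bladder, decays physically, and the
bladder empties at fixed clock intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import integrate, linalg, optimize

__all__ = [
    "CompartmentModel", "CumulatedActivitySet", "VoidingSchedule",
    "cumulated_activities", "build_iodide_pregnancy_model",
    "bladder_cumulated_activity", "gen_time_activity", "fit_rates",
    "load_fixture_activities", "pregnancy_activity_set",
    "nuclide_half_life_h", "UPTAKE_LEVELS",
]

UPTAKE_LEVELS = (0.05, 0.15, 0.25, 0.35, 0.45, 0.55, 0.95)

_UNIT_TO_H = {"d": 24.0, "h": 1.0, "min": 1.0 / 60.0, "s": 1.0 / 3600.0}


def _data(name: str):
    return resources.files("pregdose.data").joinpath(name)


def nuclide_half_life_h(nuclide: str) -> float:
    with _data("nuclides.json").open() as fh:
        table = json.load(fh)
    try:
        return float(table[nuclide]["half_life_h"])
    except KeyError:
        raise KeyError(f"unknown nuclide {nuclide!r}") from None


@dataclass(frozen=True)
class VoidingSchedule:
    """Bladder voiding clock: first void at ``first_void`` h, then every
    ``interval`` h."""

    interval: float = 3.5
    first_void: float = 3.5

    def __post_init__(self):
        if self.interval <= 0:
            raise ValueError("voiding interval must be positive")


@dataclass
class CompartmentModel:
    """Linear biokinetic system.

    ``K[i, j]`` (i != j) is the transfer rate from compartment j to i in
    1/day; diagonal entries are minus the column outflows, so columns sum to
    zero (all sinks are explicit compartments).  ``lambda_phys`` is the
    physical decay constant (1/day).  ``A0`` is the initial distribution per
    unit administered activity.
    """

    compartments: Tuple[str, ...]
    K: np.ndarray
    lambda_phys: float
    A0: np.ndarray
    excreta: Tuple[str, ...] = ()
    region_map: Dict[str, str] = field(default_factory=dict)
    nuclide: Optional[str] = None
    uptake: Optional[float] = None

    def __post_init__(self):
        n = len(self.compartments)
        self.K = np.asarray(self.K, dtype=float)
        self.A0 = np.asarray(self.A0, dtype=float)
        if self.K.shape != (n, n):
            raise ValueError("K shape mismatch")
        off = self.K.copy()
        np.fill_diagonal(off, 0.0)
        if (off < 0).any():
            raise ValueError("off-diagonal transfer rates must be >= 0")
        col = self.K.sum(axis=0)
        if np.max(np.abs(col)) > 1e-9 * max(1.0, np.abs(self.K).max()):
            raise ValueError("K columns must sum to 0 (explicit sinks only)")
        if self.lambda_phys <= 0:
            raise ValueError("lambda_phys must be positive")
        if (self.A0 < 0).any() or abs(self.A0.sum() - 1.0) > 1e-9:
            raise ValueError("A0 must be nonnegative and sum to 1")

    def index(self, name: str) -> int:
        return self.compartments.index(name)

    def activities(self, times_d: np.ndarray) -> np.ndarray:
        """Activity in each compartment at the given times (days); shape
        (n_times, n_compartments)."""
        M = self.K - self.lambda_phys * np.eye(len(self.compartments))
        return np.array([linalg.expm(M * t) @ self.A0 for t in
                         np.atleast_1d(times_d)])


@dataclass
class CumulatedActivitySet:
    """Per-source-region cumulated activities in hours per unit administered."""

    nuclide: str
    provenance: str                  # computed | russell | icrp53
    entries: Dict[str, float]        # region -> Ã (h)
    uptake: Optional[float] = None   # maximum thyroid uptake fraction

    def __post_init__(self):
        for region, val in self.entries.items():
            if val < -1e-12:
                raise ValueError(f"negative cumulated activity for {region}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"region": r, "A_tilde_h": v, "nuclide": self.nuclide,
              "uptake": self.uptake, "provenance": self.provenance}
             for r, v in sorted(self.entries.items())])

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CumulatedActivitySet":
        df = pd.read_csv(path)
        up = df["uptake"].iloc[0]
        return cls(nuclide=str(df["nuclide"].iloc[0]),
                   provenance=str(df["provenance"].iloc[0]),
                   entries=dict(zip(df["region"], df["A_tilde_h"])),
                   uptake=None if pd.isna(up) else float(up))


# ---------------------------------------------------------------------------
# core solver
# ---------------------------------------------------------------------------

def cumulated_activities(model: CompartmentModel) -> CumulatedActivitySet:
    """Ã = (λ_p I − K)^{-1} A0, summed into source regions (hours)."""
    n = len(model.compartments)
    M = model.lambda_phys * np.eye(n) - model.K
    if abs(np.linalg.det(M)) < 1e-300:
        raise np.linalg.LinAlgError("singular system despite lambda_phys > 0")
    a_days = np.linalg.solve(M, model.A0)
    entries: Dict[str, float] = {}
    for name, val in zip(model.compartments, a_days * 24.0):
        region = model.region_map.get(name, name)
        entries[region] = entries.get(region, 0.0) + float(val)
    return CumulatedActivitySet(nuclide=model.nuclide or "generic",
                                provenance="computed", entries=entries,
                                uptake=model.uptake)


def cumulated_activities_ode(model: CompartmentModel, rtol: float = 1e-10,
                             n_half_lives: float = 60.0) -> Dict[str, float]:
    """Independent oracle: adaptive ODE integration of the same system."""
    n = len(model.compartments)
    M = model.K - model.lambda_phys * np.eye(n)
    t_end = n_half_lives * np.log(2.0) / model.lambda_phys

    def rhs(_t, y):
        return np.concatenate([M @ y[:n], y[:n]])

    sol = integrate.solve_ivp(rhs, (0.0, t_end),
                              np.concatenate([model.A0, np.zeros(n)]),
                              method="LSODA", rtol=rtol, atol=1e-14)
    integral = sol.y[n:, -1] * 24.0
    entries: Dict[str, float] = {}
    for name, val in zip(model.compartments, integral):
        region = model.region_map.get(name, name)
        entries[region] = entries.get(region, 0.0) + float(val)
    return entries


# ---------------------------------------------------------------------------
# iodide-in-pregnancy model
# ---------------------------------------------------------------------------

_IODIDE_COMPARTMENTS = (
    "blood", "ecf", "thyroid", "organic", "liver", "salivary", "stomach",
    "si", "kidneys", "urine", "feces", "fetal_body", "fetal_thyroid")

_IODIDE_REGIONS = {
    "blood": "remaining tissues", "ecf": "remaining tissues",
    "organic": "remaining tissues", "thyroid": "thyroid", "liver": "liver",
    "salivary": "salivary glands", "stomach": "stomach",
    "si": "small intestine", "kidneys": "kidneys", "urine": "urine",
    "feces": "feces", "fetal_body": "fetus remainder",
    "fetal_thyroid": "fetus thyroid"}


def load_rate_constants(path=None) -> Dict[str, float]:
    if path is None:
        with _data("iodide_rates.json").open() as fh:
            raw = json.load(fh)
    else:
        with open(path) as fh:
            raw = json.load(fh)
    return {k: float(v) for k, v in raw.items() if not k.startswith("_")}


def _iodide_K(k_thy: float, c: Dict[str, float]) -> np.ndarray:
    idx = {name: i for i, name in enumerate(_IODIDE_COMPARTMENTS)}
    n = len(idx)
    K = np.zeros((n, n))

    def rate(src, dst, val):
        K[idx[dst], idx[src]] += val
        K[idx[src], idx[src]] -= val

    rate("blood", "thyroid", k_thy)
    rate("blood", "kidneys", c["blood_to_kidneys"])
    rate("blood", "salivary", c["blood_to_salivary"])
    rate("blood", "stomach", c["blood_to_stomach"])
    rate("blood", "ecf", c["blood_to_ecf"])
    rate("ecf", "blood", c["ecf_to_blood"])
    rate("blood", "fetal_body", c["blood_to_fetus"])
    rate("kidneys", "urine", c["kidneys_to_urine"])
    rate("salivary", "stomach", c["salivary_to_stomach"])
    rate("stomach", "si", c["stomach_to_si"])
    rate("si", "blood", c["si_to_blood"])
    rate("thyroid", "organic", c["thyroid_to_organic"])
    rate("organic", "liver", c["organic_to_liver"])
    rate("liver", "organic", c["liver_to_organic"])
    rate("organic", "blood", c["organic_to_blood"])
    rate("organic", "feces", c["organic_to_feces"])
    rate("fetal_body", "fetal_thyroid", c["fetus_to_fetal_thyroid"])
    rate("fetal_body", "blood", c["fetus_to_blood"])
    rate("fetal_thyroid", "fetal_body", c["fetal_thyroid_to_fetus"])
    return K


def _asymptotic_thyroid_uptake(k_thy: float, c: Dict[str, float]) -> float:
    """Fraction of administered iodide eventually trapped by the thyroid with
    decay off and the thyroid treated as absorbing (its release switched
    off).  This is the operational definition of maximum thyroid uptake."""
    c_trap = dict(c)
    c_trap["thyroid_to_organic"] = 0.0
    K = _iodide_K(k_thy, c_trap)
    idx = {name: i for i, name in enumerate(_IODIDE_COMPARTMENTS)}
    absorbing = [idx["thyroid"], idx["urine"], idx["feces"],
                 idx["fetal_thyroid"]]
    # treat fetal thyroid as a trap too on the uptake timescale
    transient = [i for i in range(len(idx)) if i not in absorbing]
    Kt = K[np.ix_(transient, transient)]
    a0 = np.zeros(len(transient))
    a0[transient.index(idx["blood"])] = 1.0
    occupancy = np.linalg.solve(-Kt, a0)  # total time spent per compartment
    return float(k_thy * occupancy[transient.index(idx["blood"])])


def build_iodide_pregnancy_model(F: float, nuclide: str = "I-131",
                                 constants: Optional[Dict[str, float]] = None
                                 ) -> CompartmentModel:
    """Iodide kinetics at maximum thyroid uptake ``F`` for I-131 or I-123."""
    if not 0.0 < F < 1.0:
        raise ValueError("maximum thyroid uptake F must be in (0, 1)")
    if nuclide not in ("I-131", "I-123"):
        raise ValueError(f"iodide model does not apply to {nuclide!r}")
    c = dict(load_rate_constants() if constants is None else constants)
    missing = [k for k in
               ("blood_to_kidneys", "blood_to_salivary", "blood_to_stomach",
                "blood_to_ecf", "ecf_to_blood", "blood_to_fetus",
                "kidneys_to_urine", "salivary_to_stomach", "stomach_to_si",
                "si_to_blood", "thyroid_to_organic", "organic_to_liver",
                "liver_to_organic", "organic_to_blood", "organic_to_feces",
                "fetus_to_fetal_thyroid", "fetus_to_blood",
                "fetal_thyroid_to_fetus") if k not in c]
    if missing:
        raise KeyError(f"rate-constant bundle missing {missing}")

    k_thy = optimize.brentq(
        lambda k: _asymptotic_thyroid_uptake(k, c) - F, 1e-9, 1e6,
        xtol=1e-12, rtol=1e-12)
    lam = np.log(2.0) / (nuclide_half_life_h(nuclide) / 24.0)  # 1/day
    A0 = np.zeros(len(_IODIDE_COMPARTMENTS))
    A0[_IODIDE_COMPARTMENTS.index("blood")] = 1.0
    return CompartmentModel(
        compartments=_IODIDE_COMPARTMENTS, K=_iodide_K(k_thy, c),
        lambda_phys=lam, A0=A0, excreta=("urine", "feces"),
        region_map=dict(_IODIDE_REGIONS), nuclide=nuclide, uptake=F)


# ---------------------------------------------------------------------------
# voiding bladder (ICRP-style)
# ---------------------------------------------------------------------------

def bladder_cumulated_activity(urine_inflow: Callable[[float], float],
                               lambda_phys_h: float,
                               schedule: VoidingSchedule = VoidingSchedule(),
                               horizon_h: Optional[float] = None,
                               rtol: float = 1e-10) -> float:
    """Ã of bladder contents (hours) under periodic voiding.

    ``urine_inflow(t)`` is the activity flow rate into the bladder at time t
    (per hour, per unit administered); the bladder content decays physically
    and resets to zero at each void.
    """
    if lambda_phys_h <= 0:
        raise ValueError("lambda_phys must be positive")
    if horizon_h is None:
        horizon_h = 15.0 * np.log(2.0) / lambda_phys_h

    def rhs(t, y):
        r = urine_inflow(t)
        if r < 0:
            raise ValueError("negative urine inflow")
        return [r - lambda_phys_h * y[0], y[0]]

    voids = np.arange(schedule.first_void, horizon_h, schedule.interval)
    edges = np.concatenate([[0.0], voids, [horizon_h]])
    total = 0.0
    for t0, t1 in zip(edges[:-1], edges[1:]):
        if t1 <= t0:
            continue
        sol = integrate.solve_ivp(rhs, (t0, t1), [0.0, 0.0], method="LSODA",
                                  rtol=rtol, atol=1e-14)
        total += float(sol.y[1, -1])
    return total


def urine_inflow_from_model(model: CompartmentModel) -> Callable[[float], float]:
    """Activity flow rate into urine (per hour) as a function of time (h)."""
    i_kid = model.index("kidneys")
    i_urine = model.index("urine")
    k_ku = float(model.K[i_urine, i_kid])  # 1/day
    M = model.K - model.lambda_phys * np.eye(len(model.compartments))
    evals, vecs = np.linalg.eig(M)
    coef = np.linalg.solve(vecs, model.A0)

    def inflow(t_h: float) -> float:
        a_kid = np.real(vecs[i_kid] @ (coef * np.exp(evals * t_h / 24.0)))
        return max(k_ku * a_kid / 24.0, 0.0)  # per hour

    return inflow


def pregnancy_activity_set(F: float, nuclide: str = "I-131",
                           constants: Optional[Dict[str, float]] = None,
                           schedule: VoidingSchedule = VoidingSchedule()
                           ) -> CumulatedActivitySet:
    """Full computed Ã set for the pregnancy model: linear-solve residence
    times with the urine sink replaced by the voiding-bladder contents."""
    model = build_iodide_pregnancy_model(F, nuclide, constants)
    base = cumulated_activities(model)
    entries = dict(base.entries)
    lam_h = np.log(2.0) / nuclide_half_life_h(nuclide)
    bladder = bladder_cumulated_activity(urine_inflow_from_model(model),
                                         lam_h, schedule)
    urine_total = entries.pop("urine")
    entries["urinary bladder contents"] = min(bladder, urine_total)
    return CumulatedActivitySet(nuclide=nuclide, provenance="computed",
                                entries=entries, uptake=F)


# ---------------------------------------------------------------------------
# synthetic time-activity data and rate fitting
# ---------------------------------------------------------------------------

def gen_time_activity(model: CompartmentModel, times_h: Sequence[float],
                      cv: float = 0.0, seed: int = 0) -> np.ndarray:
    """Noisy per-compartment activity curves.

    Multiplicative lognormal noise with coefficient of variation ``cv``,
    mean-preserving; shape (n_times, n_compartments); seed-reproducible.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    times_h = np.asarray(times_h, dtype=float)
    if np.any(np.diff(times_h) < 0):
        raise ValueError("times must be sorted")
    clean = model.activities(times_h / 24.0)
    if cv == 0:
        return clean
    sigma = np.sqrt(np.log1p(cv * cv))
    rng = np.random.default_rng(seed)
    noise = rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma,
                          size=clean.shape)
    return clean * noise


def fit_rates(times_h: Sequence[float], curves: np.ndarray,
              build_model: Callable[[Dict[str, float]], CompartmentModel],
              free_params: Dict[str, float],
              bounds: Tuple[float, float] = (1e-6, 1e4)) -> Dict[str, object]:
    """Least squares on log-activities over a declared identifiable subset.

    ``build_model`` maps a parameter dict (the free parameters merged over
    any fixed ones it closes over) to a CompartmentModel.  Returns estimates,
    the residual norm and the raw optimizer result; non-convergence is
    reported via ``success``.
    """
    times_h = np.asarray(times_h, dtype=float)
    names = sorted(free_params)
    floor = 1e-12

    def residuals(x):
        model = build_model(dict(zip(names, x)))
        pred = model.activities(times_h / 24.0)
        return (np.log(np.maximum(pred, floor))
                - np.log(np.maximum(curves, floor))).ravel()

    x0 = np.array([free_params[n] for n in names])
    res = optimize.least_squares(residuals, x0, bounds=bounds,
                                 xtol=1e-12, ftol=1e-12)
    return {"estimates": dict(zip(names, res.x)),
            "residual_norm": float(np.linalg.norm(res.fun)),
            "success": bool(res.success), "result": res}


# ---------------------------------------------------------------------------
# table fixtures
# ---------------------------------------------------------------------------

def load_fixture_activities(source: str, nuclide: str,
                            uptake: Optional[float] = None
                            ) -> CumulatedActivitySet:
    """Cumulated activities transcribed from the published comparison tables
    (units converted to hours).  ``source``: this_study | russell | icrp53.
    ``uptake`` is the maximum-thyroid-uptake fraction (e.g. 0.25) for the
    iodide tables; the pertechnetate tables carry none."""
    if source not in ("this_study", "russell", "icrp53"):
        raise ValueError(f"unknown provenance {source!r}")
    df = pd.read_csv(_data("cumulated_activities.csv"))
    sel = (df["nuclide"] == nuclide) & (df["provenance"] == source)
    if uptake is not None:
        sel &= df["uptake_pct"] == round(uptake * 100)
    sub = df[sel]
    if sub.empty:
        raise KeyError(
            f"no fixture for ({source}, {nuclide}, uptake={uptake})")
    entries = {row.region: float(row.value) * _UNIT_TO_H[row.unit]
               for row in sub.itertuples()}
    return CumulatedActivitySet(nuclide=nuclide, provenance=source,
                                entries=entries, uptake=uptake)
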