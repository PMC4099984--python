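"""Radionuclide emission inventories with the spectrum policies used for
dose estimation.

A decay scheme is a list of discrete photon/electron lines plus beta
branches.  Before transport the scheme is conditioned:

- lines and branches with yields at or below a cutoff (default 0.1% per
  decay, applied per line) are dropped;
- Auger electrons are represented by one line per group at the group's
  yield-weighted *average* energy;
- conversion electrons are represented, per subshell, by one line at the
  *maximum* energy in the subshell carrying the subshell's total yield;
- beta branches are expanded into Fermi-shaped continuous spectra
  w(E) ∝ F(Z, W) · p · W · (E_max − E)^2, with the nonrelativistic
  point-charge Coulomb factor F = 2πη / (1 − e^{−2πη}),
  η = ± Z_daughter α W / p (attractive for β−), in natural units
  (W total energy, p momentum, m_e c² = 1).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .biokinetics import nuclide_half_life_h

__all__ = [
    "EmissionLine", "BetaBranch", "DecayScheme", "load_scheme",
    "apply_yield_cutoff", "beta_spectrum", "collapse_electron_lines",
    "beta_mean_energy", "sample_beta", "mean_energy_per_decay",
]

_ALPHA = 7.2973525693e-3   # fine-structure constant
_MEC2 = 0.51099895         # electron rest energy, MeV

NUCLIDES = ("I-131", "I-123", "Tc-99m")


@dataclass(frozen=True)
class EmissionLine:
    particle: str        # photon | electron
    energy: float        # MeV
    yield_: float        # emissions per decay
    origin: str          # gamma | xray | auger | conversion
    tag: str = ""        # subshell / Auger group

    def __post_init__(self):
        if self.energy <= 0 or self.yield_ <= 0:
            raise ValueError("line energy and yield must be positive")
        if self.particle not in ("photon", "electron"):
            raise ValueError(f"bad particle {self.particle!r}")


@dataclass(frozen=True)
class BetaBranch:
    E_max: float         # MeV
    yield_: float        # per decay
    Z_daughter: int
    sign: str = "minus"  # beta-minus | beta-plus

    def __post_init__(self):
        if self.E_max <= 0:
            raise ValueError("E_max must be positive")
        if not 0 < self.yield_ <= 1:
            raise ValueError("branch yield must be in (0, 1]")
        if self.sign not in ("minus", "plus"):
            raise ValueError(f"bad beta sign {self.sign!r}")


@dataclass(frozen=True)
class DecayScheme:
    nuclide: str
    half_life_h: float
    lines: Tuple[EmissionLine, ...]
    betas: Tuple[BetaBranch, ...]
    cutoff_applied: bool = False
    removed_yield: float = 0.0

    def __post_init__(self):
        if self.half_life_h <= 0:
            raise ValueError("half-life must be positive")

    @property
    def lambda_h(self) -> float:
        return np.log(2.0) / self.half_life_h

    def photons(self) -> List[EmissionLine]:
        return [l for l in self.lines if l.particle == "photon"]

    def electrons(self) -> List[EmissionLine]:
        return [l for l in self.lines if l.particle == "electron"]


def _fixture_path(nuclide: str):
    return resources.files("pregdose.data").joinpath(f"decay_{nuclide}.csv")


def fixture_checksum(nuclide: str) -> str:
    return hashlib.sha256(_fixture_path(nuclide).read_bytes()).hexdigest()


def load_scheme(nuclide: str, verify: bool = True) -> DecayScheme:
    """Load the packaged emission inventory for one of the three agents."""
    if nuclide not in NUCLIDES:
        raise KeyError(f"unknown nuclide {nuclide!r}; expected {NUCLIDES}")
    if verify:
        with resources.files("pregdose.data").joinpath(
                "fixture_checksums.json").open() as fh:
            recorded = json.load(fh)[f"decay_{nuclide}.csv"]
        actual = fixture_checksum(nuclide)
        if actual != recorded:
            raise RuntimeError(
                f"decay fixture for {nuclide} was modified "
                f"(sha256 {actual} != recorded {recorded})")
    with _fixture_path(nuclide).open() as fh:
        df = pd.read_csv(fh, comment="#")
    lines, betas = [], []
    for row in df.itertuples():
        if row.particle == "beta":
            betas.append(BetaBranch(float(row.energy_MeV),
                                    float(row.yield_per_decay),
                                    int(row.z_daughter),
                                    str(row.sign)))
        else:
            lines.append(EmissionLine(row.particle, float(row.energy_MeV),
                                      float(row.yield_per_decay),
                                      str(row.origin), str(row.tag)))
    return DecayScheme(nuclide=nuclide,
                       half_life_h=nuclide_half_life_h(nuclide),
                       lines=tuple(lines), betas=tuple(betas))


def apply_yield_cutoff(scheme: DecayScheme,
                       threshold: float = 0.001) -> DecayScheme:
    """Drop lines/branches with yield <= threshold (per decay, per line)."""
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must be in [0, 1)")
    if threshold == 0.0:
        return scheme
    keep_l = tuple(l for l in scheme.lines if l.yield_ > threshold)
    keep_b = tuple(b for b in scheme.betas if b.yield_ > threshold)
    removed = (sum(l.yield_ for l in scheme.lines)
               + sum(b.yield_ for b in scheme.betas)
               - sum(l.yield_ for l in keep_l)
               - sum(b.yield_ for b in keep_b))
    return replace(scheme, lines=keep_l, betas=keep_b, cutoff_applied=True,
                   removed_yield=scheme.removed_yield + removed)


def collapse_electron_lines(scheme: DecayScheme) -> DecayScheme:
    """Apply the Auger-average / conversion-subshell-maximum policy.

    Auger groups (keyed by tag) collapse to a single line at the group's
    yield-weighted average energy; conversion subshells collapse to a single
    line at the maximum energy within the subshell, carrying the total
    yield.  Yield is conserved per group; the operation is idempotent.
    """
    out: List[EmissionLine] = [l for l in scheme.lines
                               if l.origin not in ("auger", "conversion")]
    for origin in ("auger", "conversion"):
        groups = {}
        for l in scheme.lines:
            if l.origin == origin:
                groups.setdefault(l.tag, []).append(l)
        for tag in sorted(groups):
            ls = groups[tag]
            total = sum(l.yield_ for l in ls)
            if origin == "auger":
                energy = sum(l.energy * l.yield_ for l in ls) / total
            else:
                energy = max(l.energy for l in ls)
            out.append(EmissionLine("electron", energy, total, origin, tag))
    return replace(scheme, lines=tuple(out))


# ---------------------------------------------------------------------------
# beta spectra
# ---------------------------------------------------------------------------

def _fermi_shape(E: np.ndarray, branch: BetaBranch) -> np.ndarray:
    """Unnormalized allowed-shape spectrum with the nonrelativistic Coulomb
    Fermi factor, on kinetic energies E in (0, E_max) MeV."""
    W = 1.0 + E / _MEC2               # total energy, units of mec^2
    p = np.sqrt(np.maximum(W * W - 1.0, 1e-300))
    shape = p * W * (branch.E_max - E) ** 2
    eta = _ALPHA * branch.Z_daughter * W / p
    if branch.sign == "plus":
        eta = -eta
    x = 2.0 * np.pi * eta
    small = np.abs(x) < 1e-12
    with np.errstate(over="ignore", under="ignore", invalid="ignore"):
        fermi = np.where(small, 1.0,
                         x / np.where(small, 1.0, 1.0 - np.exp(-x)))
    return shape * fermi


def beta_spectrum(branch: BetaBranch, n_bins: Optional[int] = None
                  ) -> Tuple[np.ndarray, np.ndarray]:
    """Binned beta spectrum: (bin center energies MeV, weights per decay).

    Default binning is 1 keV; weights sum to the branch yield.
    """
    if n_bins is None:
        n_bins = max(10, int(round(branch.E_max / 0.001)))
    if n_bins < 10:
        raise ValueError("n_bins must be >= 10")
    edges = np.linspace(0.0, branch.E_max, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = _fermi_shape(centers, branch)
    w = w / w.sum() * branch.yield_
    return centers, w


def beta_mean_energy(branch: BetaBranch, n_bins: int = 2000) -> float:
    """Mean kinetic energy of the branch spectrum (MeV)."""
    e, w = beta_spectrum(branch, n_bins)
    return float((e * w).sum() / w.sum())


def sample_beta(branch: BetaBranch, n: int,
                rng: np.random.Generator) -> np.ndarray:
    """Draw beta kinetic energies from the binned spectrum."""
    e, w = beta_spectrum(branch)
    idx = rng.choice(len(e), size=n, p=w / w.sum())
    half = branch.E_max / len(e) / 2.0
    return e[idx] + rng.uniform(-half, half, size=n)


def mean_energy_per_decay(scheme: DecayScheme) -> float:
    """Total emitted energy per decay (MeV): discrete lines + beta means."""
    total = sum(l.energy * l.yield_ for l in scheme.lines)
    total += sum(beta_mean_energy(b) * b.yield_ for b in scheme.betas)
    return float(total)
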