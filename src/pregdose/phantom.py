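"""Synthetic pregnant-anatomy scenes.

The real phantom this package emulates was segmented from MR images of a
9-months pregnant patient and merged with a reference adult-female voxel
phantom.  Neither image set is distributable, so this module builds a fully
synthetic stand-in: every organ is an analytic primitive (ellipsoid, capsule,
box, shell) placed in a simplified trunk + gravid-uterus layout, carrying the
reference target mass, density and material of the organ it represents.
Downstream stages (voxelization, mass adjustment, transport, dose assembly)
are geometry-agnostic, so they exercise exactly the same code paths they
would on a segmented phantom.

Two profiles are provided:

``reference_9mo``
    The full roster: ~10 maternal source regions plus a 20-organ fetus at
    reference masses (fetal thyroid 1.3 g, brain 370 g, ...), a uterus /
    placenta / amniotic-fluid block, and a trunk envelope of residual soft
    tissue.  Organ placement constants live in one editable layout file
    (``data/layout_reference_9mo.json``).

``minimal_test``
    A <=5-organ scene (envelope, thyroid, stomach wall+contents, liver) for
    fast tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional

import numpy as np

from .geometry import Primitive, primitive_from_dict, scale_to_volume

__all__ = [
    "MaterialSpec", "WallSpec", "OrganSpec", "PhantomScene",
    "build_reference_scene", "material_table", "sample_inside",
]

PROFILES = ("reference_9mo", "minimal_test")


@dataclass(frozen=True)
class MaterialSpec:
    """A tissue material: density and elemental mass fractions."""

    material_id: str
    density: float  # g/cm^3
    elemental_fractions: Dict[str, float]

    def __post_init__(self):
        if self.density <= 0:
            raise ValueError(f"{self.material_id}: density must be positive")
        s = sum(self.elemental_fractions.values())
        if abs(s - 1.0) > 1e-6:
            raise ValueError(
                f"{self.material_id}: elemental fractions sum to {s}, not 1")


# Densities: adult-female reference tissue values for maternal organs; fetal
# lungs are fluid-filled (never aerated in utero) so they carry a soft-tissue
# like density rather than the adult inflated-lung value.
_MATERIALS = [
    MaterialSpec("air", 0.0012, {"N": 0.755, "O": 0.232, "Ar": 0.013}),
    MaterialSpec("water", 1.00, {"H": 0.112, "O": 0.888}),
    MaterialSpec("soft_tissue", 1.03,
                 {"H": 0.105, "C": 0.256, "N": 0.027, "O": 0.602, "P": 0.010}),
    MaterialSpec("thyroid", 1.05,
                 {"H": 0.104, "C": 0.119, "N": 0.024, "O": 0.743, "P": 0.010}),
    MaterialSpec("brain", 1.04,
                 {"H": 0.107, "C": 0.145, "N": 0.022, "O": 0.712, "P": 0.014}),
    MaterialSpec("skin", 1.09,
                 {"H": 0.100, "C": 0.204, "N": 0.042, "O": 0.645, "P": 0.009}),
    MaterialSpec("skeleton", 1.40,
                 {"H": 0.064, "C": 0.278, "N": 0.027, "O": 0.410, "P": 0.070,
                  "Ca": 0.151}),
    MaterialSpec("lung", 0.382,
                 {"H": 0.103, "C": 0.105, "N": 0.031, "O": 0.749, "P": 0.012}),
    MaterialSpec("lung_fetal", 1.04,
                 {"H": 0.103, "C": 0.105, "N": 0.031, "O": 0.749, "P": 0.012}),
    MaterialSpec("gi_content", 1.04,
                 {"H": 0.100, "C": 0.222, "N": 0.022, "O": 0.644, "P": 0.012}),
    MaterialSpec("placenta", 1.02,
                 {"H": 0.106, "C": 0.114, "N": 0.026, "O": 0.745, "P": 0.009}),
    MaterialSpec("blood", 1.06,
                 {"H": 0.102, "C": 0.110, "N": 0.033, "O": 0.745, "P": 0.010}),
]


def material_table(profile: str = "reference_9mo") -> List[MaterialSpec]:
    """Materials used by the synthetic scenes (same set for every profile)."""
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; expected {PROFILES}")
    return list(_MATERIALS)


def materials_by_id(profile: str = "reference_9mo") -> Dict[str, MaterialSpec]:
    return {m.material_id: m for m in material_table(profile)}


@dataclass(frozen=True)
class WallSpec:
    """Wall to be produced by layer peeling after voxelization."""

    n_layers: int
    wall_label: int
    name: str
    material: str
    region: str
    target_mass: Optional[float] = None
    reference_mass: Optional[float] = None
    adjust: bool = True
    source_flag: bool = False

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("wall n_layers must be >= 1")


@dataclass(frozen=True)
class OrganSpec:
    label: int
    name: str
    shape: Primitive
    material: str
    region: str
    target_mass: Optional[float] = None     # g; None = no mass adjustment
    reference_mass: Optional[float] = None  # g; None = "no reference" flag
    nesting_parent: Optional[int] = None    # parent label (None = envelope child)
    wall: Optional[WallSpec] = None
    source_flag: bool = False
    fetal: bool = False
    adjust: bool = True

    def __post_init__(self):
        if self.label <= 0:
            raise ValueError("labels must be positive integers")
        if self.target_mass is not None and self.target_mass <= 0:
            raise ValueError(f"{self.name}: target_mass must be positive")


@dataclass
class PhantomScene:
    profile: str
    envelope: OrganSpec                  # body outline; its label fills the trunk
    organs: List[OrganSpec]
    fetus_labels: frozenset
    grid_hint: tuple = (2.0, 2.0, 2.0)   # mm
    materials: Dict[str, MaterialSpec] = field(default_factory=dict)

    # -- lookups ---------------------------------------------------------
    def organ(self, label: int) -> OrganSpec:
        for o in self.organs:
            if o.label == label:
                return o
        raise KeyError(f"no organ with label {label}")

    def all_labels(self) -> List[int]:
        labels = [self.envelope.label]
        for o in self.organs:
            labels.append(o.label)
            if o.wall is not None:
                labels.append(o.wall.wall_label)
        return labels

    def label_names(self) -> Dict[int, str]:
        names = {self.envelope.label: self.envelope.name}
        for o in self.organs:
            names[o.label] = o.name
            if o.wall is not None:
                names[o.wall.wall_label] = o.wall.name
        return names

    def label_materials(self) -> Dict[int, str]:
        mats = {self.envelope.label: self.envelope.material}
        for o in self.organs:
            mats[o.label] = o.material
            if o.wall is not None:
                mats[o.wall.wall_label] = o.wall.material
        return mats

    def label_regions(self) -> Dict[int, str]:
        regs = {self.envelope.label: self.envelope.region}
        for o in self.organs:
            regs[o.label] = o.region
            if o.wall is not None:
                regs[o.wall.wall_label] = o.wall.region
        return regs

    def nesting_depth(self, label: int) -> int:
        depth, cur = 0, label
        seen = set()
        while True:
            if cur in seen:
                raise ValueError("nesting cycle detected")
            seen.add(cur)
            if cur == self.envelope.label:
                return depth
            parent = self.organ(cur).nesting_parent
            depth += 1
            if parent is None:
                return depth
            cur = parent

    def validate(self):
        labels = self.all_labels()
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate labels in scene")
        mats = materials_by_id(self.profile) if not self.materials \
            else self.materials
        for lab, mid in self.label_materials().items():
            if mid not in mats:
                raise ValueError(f"label {lab}: unresolved material {mid!r}")
        for lab in self.fetus_labels:
            if lab not in labels:
                raise ValueError(f"fetus label {lab} not in scene")
        for o in self.organs:
            self.nesting_depth(o.label)  # raises on cycles / bad parents

    def fetal_target_mass(self) -> float:
        """Sum of fetal target masses (walls included)."""
        total = 0.0
        for o in self.organs:
            if o.label in self.fetus_labels and o.target_mass is not None:
                total += o.target_mass
            if (o.wall is not None and o.wall.wall_label in self.fetus_labels
                    and o.wall.target_mass is not None):
                total += o.wall.target_mass
        return total

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        def organ_dict(o: OrganSpec) -> dict:
            d = {
                "label": o.label, "name": o.name, "shape": o.shape.to_dict(),
                "material": o.material, "region": o.region,
                "target_mass_g": o.target_mass,
                "reference_mass_g": o.reference_mass,
                "nesting_parent": o.nesting_parent,
                "source": o.source_flag, "fetal": o.fetal, "adjust": o.adjust,
            }
            if o.wall is not None:
                w = o.wall
                d["wall"] = {
                    "n_layers": w.n_layers, "label": w.wall_label,
                    "name": w.name, "material": w.material, "region": w.region,
                    "target_mass_g": w.target_mass,
                    "reference_mass_g": w.reference_mass,
                    "adjust": w.adjust, "source": w.source_flag,
                }
            return d

        payload = {
            "profile": self.profile,
            "grid_hint_mm": list(self.grid_hint),
            "envelope": organ_dict(self.envelope),
            "fetus_labels": sorted(self.fetus_labels),
            "materials": [
                {"material_id": m.material_id, "density_g_cm3": m.density,
                 "elemental_fractions": m.elemental_fractions}
                for m in (self.materials.values() or _MATERIALS)
            ],
            "organs": [organ_dict(o) for o in self.organs],
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PhantomScene":
        payload = json.loads(text)

        def organ_from(d: dict) -> OrganSpec:
            wall = None
            if d.get("wall"):
                w = d["wall"]
                wall = WallSpec(w["n_layers"], w["label"], w["name"],
                                w["material"], w["region"],
                                w.get("target_mass_g"),
                                w.get("reference_mass_g"),
                                w.get("adjust", True), w.get("source", False))
            return OrganSpec(
                label=d["label"], name=d["name"],
                shape=primitive_from_dict(d["shape"]),
                material=d["material"], region=d["region"],
                target_mass=d.get("target_mass_g"),
                reference_mass=d.get("reference_mass_g"),
                nesting_parent=d.get("nesting_parent"),
                wall=wall, source_flag=d.get("source", False),
                fetal=d.get("fetal", False), adjust=d.get("adjust", True))

        mats = {m["material_id"]: MaterialSpec(m["material_id"],
                                               m["density_g_cm3"],
                                               m["elemental_fractions"])
                for m in payload.get("materials", [])}
        scene = cls(profile=payload["profile"],
                    envelope=organ_from(payload["envelope"]),
                    organs=[organ_from(d) for d in payload["organs"]],
                    fetus_labels=frozenset(payload["fetus_labels"]),
                    grid_hint=tuple(payload["grid_hint_mm"]),
                    materials=mats)
        scene.validate()
        return scene


# ---------------------------------------------------------------------------
# scene construction from the layout file
# ---------------------------------------------------------------------------

def _load_layout(name: str) -> dict:
    with resources.files("pregdose.data").joinpath(name).open() as fh:
        return json.load(fh)


def build_reference_scene(profile: str = "reference_9mo") -> PhantomScene:
    """Construct a synthetic scene for the requested profile.

    Organ primitives whose layout entry sets ``size_from_mass`` are
    isotropically rescaled (keeping the layout's aspect ratio) so that the
    primitive volume equals ``sizing_mass / density``; the remaining few
    (containers such as the uterus, amniotic sac and fetus body, whose bulk
    masses are emergent) use the layout dimensions as-is.
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; expected {PROFILES}")
    layout = _load_layout(f"layout_{profile}.json")
    mats = materials_by_id(profile)

    def build_organ(d: dict) -> OrganSpec:
        prim = primitive_from_dict(d["shape"])
        if d.get("size_from_mass", False):
            mass = d.get("sizing_mass_g") or d.get("target_mass_g")
            if mass is None:
                raise ValueError(f"{d['name']}: size_from_mass without a mass")
            density = mats[d["material"]].density
            prim = scale_to_volume(prim, mass / density * 1000.0)  # g->mm^3
        wall = None
        if d.get("wall"):
            w = d["wall"]
            wall = WallSpec(w["n_layers"], w["label"], w["name"], w["material"],
                            w["region"], w.get("target_mass_g"),
                            w.get("reference_mass_g"), w.get("adjust", True),
                            w.get("source", False))
        return OrganSpec(
            label=d["label"], name=d["name"], shape=prim,
            material=d["material"], region=d["region"],
            target_mass=d.get("target_mass_g"),
            reference_mass=d.get("reference_mass_g"),
            nesting_parent=d.get("nesting_parent"),
            wall=wall, source_flag=d.get("source", False),
            fetal=d.get("fetal", False), adjust=d.get("adjust", True))

    envelope = build_organ(layout["envelope"])
    organs = [build_organ(d) for d in layout["organs"]]
    scene = PhantomScene(profile=profile, envelope=envelope, organs=organs,
                         fetus_labels=frozenset(layout["fetus_labels"]),
                         grid_hint=tuple(layout["grid_hint_mm"]),
                         materials=mats)
    scene.validate()
    if profile == "reference_9mo":
        total = scene.fetal_target_mass()
        if abs(total - 3500.0) / 3500.0 > 0.01:
            raise AssertionError(
                f"fetal target-mass closure violated: {total:.2f} g vs 3500 g")
    return scene


# ---------------------------------------------------------------------------
# geometry diagnostics
# ---------------------------------------------------------------------------

def sample_inside(prim: Primitive, n: int, rng: np.random.Generator
                  ) -> np.ndarray:
    """Uniform points inside a primitive by bounding-box rejection."""
    lo, hi = prim.bounding_box()
    out = np.empty((0, 3))
    while len(out) < n:
        cand = rng.uniform(lo, hi, size=(max(4 * n, 256), 3))
        keep = cand[prim.contains(cand)]
        out = np.vstack([out, keep])
    return out[:n]


def check_containment(scene: PhantomScene, n: int = 2000, seed: int = 0
                      ) -> dict:
    """Sampled geometric audit of a scene.

    Returns, per organ, the fraction of interior sample points that fall
    outside the envelope and outside the nesting parent's primitive.  Both
    should be 0 for a well-formed layout.
    """
    rng = np.random.default_rng(seed)
    report = {}
    prims = {o.label: o.shape for o in scene.organs}
    prims[scene.envelope.label] = scene.envelope.shape
    for o in scene.organs:
        pts = sample_inside(o.shape, n, rng)
        out_env = 1.0 - scene.envelope.shape.contains(pts).mean()
        parent = o.nesting_parent if o.nesting_parent is not None \
            else scene.envelope.label
        out_par = 1.0 - prims[parent].contains(pts).mean()
        report[o.name] = {"outside_envelope": float(out_env),
                          "outside_parent": float(out_par)}
    return report
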