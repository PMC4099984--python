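"""Pipeline orchestration, file formats and run manifests.

Workflow: phantom → voxelize → mass adjustment → biokinetics → transport →
dose assembly → report.  Every stage writes its intermediate under the run
directory; the manifest records configuration, content hashes and stage
timings so that a rerun with an identical configuration reproduces identical
outputs (timestamps excluded).

Lattice exchange format: a compressed ``.npz`` container (header JSON +
dense label array) with a gzip-text fallback (``.txt.gz``) for portability;
both round-trip bit-exactly.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from . import biokinetics as bk
from . import decay as dk
from . import dose as ds
from . import transport as tr
from .phantom import PROFILES, build_reference_scene
from .voxelize import (LabelLattice, adjust_scene_masses, scene_mass_report,
                       voxelize_scene)

__all__ = [
    "RunConfig", "run_pipeline", "write_lattice", "read_lattice",
    "write_lattice_text", "read_lattice_text",
]


# ---------------------------------------------------------------------------
# lattice container
# ---------------------------------------------------------------------------

def _header(lat: LabelLattice, label_names: Optional[Dict] = None) -> dict:
    return {"dims": list(lat.dims),
            "spacing_mm": list(lat.spacing),
            "origin_mm": list(lat.origin),
            "order": "x-fastest",
            "labels": {str(k): v for k, v in (label_names or {}).items()}}


def write_lattice(path, lat: LabelLattice, label_names=None) -> None:
    """Binary container: compressed npz with a JSON header."""
    np.savez_compressed(path,
                        header=np.frombuffer(
                            json.dumps(_header(lat, label_names),
                                       sort_keys=True).encode(),
                            dtype=np.uint8),
                        labels=lat.labels)


def read_lattice(path) -> Tuple[LabelLattice, dict]:
    with np.load(path) as z:
        try:
            header = json.loads(bytes(z["header"]).decode())
            labels = z["labels"]
        except KeyError as exc:
            raise ValueError(f"malformed lattice container {path}: "
                             f"missing {exc}") from None
    lat = LabelLattice(tuple(header["dims"]), tuple(header["spacing_mm"]),
                       tuple(header["origin_mm"]), labels)
    return lat, header


def write_lattice_text(path, lat: LabelLattice, label_names=None) -> None:
    """Gzip text fallback: header JSON line, then flat labels (x fastest)."""
    flat = lat.labels.ravel(order="F")
    with gzip.open(path, "wt") as fh:
        fh.write(json.dumps(_header(lat, label_names), sort_keys=True) + "\n")
        for i in range(0, len(flat), 4096):
            fh.write(" ".join(map(str, flat[i:i + 4096])) + "\n")


def read_lattice_text(path) -> Tuple[LabelLattice, dict]:
    with gzip.open(path, "rt") as fh:
        header = json.loads(fh.readline())
        data = np.array(fh.read().split(), dtype=np.int16)
    dims = tuple(header["dims"])
    if data.size != int(np.prod(dims)):
        raise ValueError(f"lattice text container {path}: expected "
                         f"{np.prod(dims)} voxels, found {data.size}")
    labels = data.reshape(dims, order="F")
    lat = LabelLattice(dims, tuple(header["spacing_mm"]),
                       tuple(header["origin_mm"]), labels)
    return lat, header


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    profile: str = "minimal_test"
    spacing_mm: float = 4.0
    nuclide: str = "I-131"
    uptake_levels: Tuple[float, ...] = (0.25,)
    n_histories: int = 2000
    seed: int = 1
    electron_mode: str = "local"
    activities: str = "computed"         # computed | russell | icrp53
    outdir: str = "pregdose_run"

    def validate(self) -> None:
        """Fail fast: every referenced profile/fixture must resolve before
        any stage runs."""
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")
        bk.nuclide_half_life_h(self.nuclide)        # raises if unknown
        dk.load_scheme(self.nuclide)                # checksum-verified
        for F in self.uptake_levels:
            if not 0 < F < 1:
                raise ValueError(f"uptake level {F} outside (0, 1)")
        if self.activities not in ("computed", "russell", "icrp53"):
            raise ValueError(f"unknown activity provenance "
                             f"{self.activities!r}")
        if self.activities != "computed":
            up = self.uptake_levels[0] if self.nuclide != "Tc-99m" else None
            bk.load_fixture_activities(self.activities, self.nuclide, up)
        if self.nuclide == "Tc-99m" and self.activities == "computed":
            raise ValueError("no computed biokinetic model for Tc-99m; "
                             "use the russell or icrp53 fixture set")

    def content_key(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if "uptake_levels" in raw:
            cfg.uptake_levels = tuple(raw["uptake_levels"])
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config),
                      "content_key": config.content_key(),
                      "stages": {}}
    stage_t0 = time.time()

    def mark(stage: str):
        nonlocal stage_t0
        manifest["stages"][stage] = round(time.time() - stage_t0, 3)
        stage_t0 = time.time()

    try:
        scene = build_reference_scene(config.profile)
        (out / "scene.json").write_text(scene.to_json())
        mark("phantom")

        lat = voxelize_scene(scene, config.spacing_mm)
        adjust_scene_masses(scene, lat)
        write_lattice(out / "lattice.npz", lat, scene.label_names())
        report = scene_mass_report(scene, lat)
        report.to_csv(out / "mass_report.csv", index=False)
        mark("voxelize")

        if config.activities == "computed":
            act_sets = [bk.pregnancy_activity_set(F, config.nuclide)
                        for F in config.uptake_levels]
        else:
            up = (config.uptake_levels[0]
                  if config.nuclide != "Tc-99m" else None)
            act_sets = [bk.load_fixture_activities(config.activities,
                                                   config.nuclide, up)]
        for i, acts in enumerate(act_sets):
            acts.to_csv(out / f"activities_{i}.csv")
        mark("biokinetics")

        scheme = dk.collapse_electron_lines(
            dk.apply_yield_cutoff(dk.load_scheme(config.nuclide)))
        prob = tr.TransportProblem.from_scene(scene, lat)
        cfg = tr.TransportConfig(config.n_histories, config.seed,
                                 config.electron_mode)
        source_regions = sorted({o.region for o in scene.organs
                                 if o.source_flag}
                                | {scene.envelope.region})
        sources = {r: r for r in source_regions}
        if any("fetus" in a.entries for a in act_sets):
            fetal = [lab for lab in scene.fetus_labels
                     if lab in lat.label_index]
            sources["fetus"] = fetal
        tallies = ds.run_scheme_tallies(prob, scheme, sources, cfg)
        sv = ds.assemble_svalues(tallies, scheme, list(sources))
        sv.to_frame().to_csv(out / "svalues.csv", index=False)
        mark("transport")

        tables = [ds.organ_doses(sv, acts, fold_unmapped=True)
                  for acts in act_sets]
        dose_df = None
        for i, t in enumerate(tables):
            df = t.to_frame()
            dose_df = df if dose_df is None else dose_df.merge(
                df, on=["target", "nuclide"], suffixes=("", f"_{i}"))
            df.to_csv(out / f"doses_{i}.csv", index=False)
        mark("dose")

        _render_dose_map(prob, scheme, cfg, out / "dose_map.png")
        mark("report")
    except Exception as exc:
        stage = list(manifest["stages"])[-1] if manifest["stages"] else \
            "validate"
        raise RuntimeError(
            f"pipeline aborted after stage {stage!r}: {exc}") from exc

    manifest["outputs"] = {p.name: _sha256(p) for p in sorted(out.iterdir())
                           if p.name not in ("manifest.json",
                                             "dose_map.png")}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return manifest


def _render_dose_map(prob: tr.TransportProblem, scheme, cfg,
                     path: Path) -> None:
    """Sagittal dose-distribution map (log color scale) for the scheme's
    dominant photon line emitted from the thyroid region."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LogNorm

    photons = [l for l in scheme.lines if l.particle == "photon"]
    if not photons or "thyroid" not in prob.regions:
        return
    main = max(photons, key=lambda l: l.yield_ * l.energy)
    _, mesh = tr.transport_photons(prob, "thyroid", main.energy, cfg,
                                   want_mesh=True)
    dosemap = tr.mesh_dose_map(mesh)
    ix = dosemap.shape[0] // 2
    sl = dosemap[ix, :, :].T
    fig, ax = plt.subplots(figsize=(4, 6))
    pos = sl[sl > 0]
    vmax = float(pos.max()) if pos.size else 1.0
    im = ax.imshow(sl, origin="lower", cmap="inferno",
                   norm=LogNorm(vmin=max(vmax * 1e-6, 1e-300), vmax=vmax),
                   aspect=mesh.spacing[2] / mesh.spacing[1])
    ax.set_xlabel("y (voxel)")
    ax.set_ylabel("z (voxel)")
    ax.set_title(f"{scheme.nuclide} {main.energy*1e3:.0f} keV photons, "
                 "thyroid source\nMeV/g per particle (sagittal)")
    fig.colorbar(im, ax=ax, shrink=0.7)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
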