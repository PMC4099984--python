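"""Monte Carlo transport: attenuation physics, scoring, determinism,
conservation, reciprocity."""

import numpy as np
import pytest

from pregdose import transport as tr
from pregdose.geometry import Box, Ellipsoid
from pregdose.phantom import OrganSpec, PhantomScene, materials_by_id
from pregdose.voxelize import voxelize_scene


@pytest.fixture(scope="module")
def xs():
    return tr.build_xs(materials_by_id().values())


def _uniform_water_problem(xs, half_mm=400.0, spacing_mm=20.0):
    """A large water cube with a small central source organ."""
    c = half_mm
    env = OrganSpec(label=1, name="water", region="water",
                    shape=Box((c, c, c), (2 * c, 2 * c, 2 * c)),
                    material="water", adjust=False)
    srcorg = OrganSpec(label=2, name="origin", region="origin",
                       shape=Box((c, c, c), (spacing_mm,) * 3),
                       material="water", nesting_parent=1)
    scene = PhantomScene("minimal_test", env, [srcorg], frozenset(),
                         materials=materials_by_id())
    lat = voxelize_scene(scene, spacing_mm)
    return tr.TransportProblem.from_scene(scene, lat, xs)


def _two_organ_problem(xs, m_small=True):
    env = OrganSpec(label=1, name="medium", region="medium",
                    shape=Box((100, 100, 100), (200, 200, 200)),
                    material="soft_tissue", adjust=False)
    a = OrganSpec(label=2, name="a", region="a",
                  shape=Ellipsoid((60, 100, 100), (25, 25, 25)),
                  material="soft_tissue", nesting_parent=1)
    b = OrganSpec(label=3, name="b", region="b",
                  shape=Ellipsoid((140, 100, 100), (25, 25, 25)),
                  material="soft_tissue", nesting_parent=1)
    scene = PhantomScene("minimal_test", env, [a, b], frozenset(),
                         materials=materials_by_id())
    lat = voxelize_scene(scene, 5.0)
    return tr.TransportProblem.from_scene(scene, lat, xs)


# -- cross sections ---------------------------------------------------------

def test_xs_invariants(xs):
    assert np.all(np.diff(xs.energies) > 0)
    assert np.all(xs.muen <= xs.mu_pe + xs.mu_inc + 1e-15)
    assert np.all(xs.mu_pe > 0) and np.all(xs.mu_inc > 0)


def test_water_attenuation_magnitude(xs):
    """Water total mass attenuation at 0.1–0.5 MeV sits in the textbook
    range (Compton-dominated, ~0.09–0.17 cm^2/g)."""
    for E, lo, hi in [(0.1, 0.12, 0.22), (0.364, 0.08, 0.13),
                      (0.5, 0.07, 0.11)]:
        assert lo < xs.mu_total("water", E) < hi


def test_kn_transfer_below_total():
    for E in (0.05, 0.364, 1.0):
        a = E / 0.51099895
        assert 0 < tr._kn_transfer(a) < tr._kn_total(np.array([a]))[0]


def test_csda_range_magnitudes():
    # ~0.44 g/cm^2 at 1 MeV, ~0.2 at 0.6 MeV (Katz-Penfold)
    assert tr.csda_range_gcm2(1.0) == pytest.approx(0.412, rel=0.01)
    assert 0.15 < float(tr.csda_range_gcm2(0.6)) < 0.30


# -- photon transport -------------------------------------------------------

def test_mean_free_path_matches_inverse_mu(xs):
    """Mean distance to first interaction in effectively infinite water
    agrees with 1/mu within 3 Monte Carlo standard errors."""
    prob = _uniform_water_problem(xs)
    E = 0.1
    cfg = tr.TransportConfig(n_histories=100_000, seed=13)
    d = tr.sample_first_flight(prob, "origin", E, cfg)
    assert len(d) > 0.99 * cfg.n_histories      # escapes negligible
    mu = xs.mu_total("water", E) * 1.0          # rho = 1
    se = d.std() / np.sqrt(len(d))
    assert abs(d.mean() - 1.0 / mu) < 3 * se


def test_total_kerma_bounded_by_emitted_energy(minimal_problem):
    cfg = tr.TransportConfig(n_histories=5000, seed=3)
    t, _ = tr.transport_photons(minimal_problem, "thyroid", 0.364, cfg)
    scored = float((t.specific_energy * minimal_problem.region_mass).sum())
    assert scored <= cfg.n_histories * 0.364


def test_same_seed_bit_identical(minimal_problem):
    cfg = tr.TransportConfig(n_histories=2000, seed=99)
    a, _ = tr.transport_photons(minimal_problem, "thyroid", 0.364, cfg)
    b, _ = tr.transport_photons(minimal_problem, "thyroid", 0.364, cfg)
    assert np.array_equal(a.specific_energy, b.specific_energy)
    assert np.array_equal(a.rel_err, b.rel_err)
    c, _ = tr.transport_photons(minimal_problem, "thyroid", 0.364,
                                tr.TransportConfig(2000, 100))
    assert not np.array_equal(a.specific_energy, c.specific_energy)


def test_energy_conservation_audit(minimal_problem):
    """Analog bookkeeping: emitted = deposited + escaped + discarded to
    1e-6 relative."""
    cfg = tr.TransportConfig(n_histories=20_000, seed=5)
    t, _ = tr.transport_photons(minimal_problem, "stomach", 0.14, cfg)
    assert abs(t.audit["balance"]) < 1e-6


def test_energy_outside_tables_rejected(minimal_problem):
    cfg = tr.TransportConfig(n_histories=10, seed=1)
    with pytest.raises(ValueError):
        tr.transport_photons(minimal_problem, "thyroid", 5.0, cfg)
    with pytest.raises(ValueError):
        tr.transport_photons(minimal_problem, "no such region", 0.1, cfg)


def test_photon_reciprocity_between_equal_organs(xs):
    """Equal-mass organs in a homogeneous phantom: mass-weighted cross
    doses agree within 3 combined standard errors."""
    prob = _two_organ_problem(xs)
    cfg = tr.TransportConfig(n_histories=40_000, seed=21)
    ia, ib = prob.regions.index("a"), prob.regions.index("b")
    ta, _ = tr.transport_photons(prob, "a", 0.364, cfg)
    tb, _ = tr.transport_photons(prob, "b", 0.364,
                                 tr.TransportConfig(40_000, 22))
    dab = ta.specific_energy[ib] * prob.region_mass[ib]
    dba = tb.specific_energy[ia] * prob.region_mass[ia]
    sig = np.hypot(dab * ta.rel_err[ib], dba * tb.rel_err[ia])
    assert abs(dab - dba) < 3 * sig


def test_self_dose_decreases_with_source_mass(xs):
    """Same shape family, same energy: specific self-absorbed energy per
    particle falls as the organ grows."""
    def sphere_problem(r):
        env = OrganSpec(label=1, name="m", region="m",
                        shape=Box((80, 80, 80), (160, 160, 160)),
                        material="soft_tissue", adjust=False)
        o = OrganSpec(label=2, name="s", region="s",
                      shape=Ellipsoid((80, 80, 80), (r, r, r)),
                      material="soft_tissue", nesting_parent=1)
        scene = PhantomScene("minimal_test", env, [o], frozenset(),
                             materials=materials_by_id())
        return tr.TransportProblem.from_scene(
            scene, voxelize_scene(scene, 4.0), xs)

    cfg = tr.TransportConfig(n_histories=20_000, seed=4)
    doses = []
    for r in (15.0, 30.0, 55.0):
        p = sphere_problem(r)
        t, _ = tr.transport_photons(p, "s", 0.364, cfg)
        doses.append(t.as_dict()["s"])
    assert doses[0] > doses[1] > doses[2]


def test_grid_refinement_stability(minimal_scene, xs):
    """Halving the voxel spacing changes the photon self-dose by < 2%."""
    from pregdose.voxelize import adjust_scene_masses
    cfg = tr.TransportConfig(n_histories=100_000, seed=8)
    vals = []
    for sp in (4.0, 2.0):
        lat = voxelize_scene(minimal_scene, sp)
        adjust_scene_masses(minimal_scene, lat)
        prob = tr.TransportProblem.from_scene(minimal_scene, lat, xs)
        t, _ = tr.transport_photons(prob, "thyroid", 0.364, cfg)
        vals.append(t.as_dict()["thyroid"])
    assert abs(vals[1] - vals[0]) / vals[0] < 0.02


# -- electron transport -----------------------------------------------------

def test_local_mode_self_dose_is_closed_form(minimal_problem):
    cfg = tr.TransportConfig(n_histories=1000, seed=1)
    E = 0.19
    t, _ = tr.transport_electrons(minimal_problem, "thyroid", E, cfg)
    m = minimal_problem.region_mass[minimal_problem.regions.index("thyroid")]
    assert t.as_dict()["thyroid"] == E / m           # exact
    assert t.as_dict()["liver"] == 0.0               # disjoint target
    assert np.all(t.rel_err == 0)


def test_csda_mode_conserves_energy_when_contained(minimal_problem):
    cfg = tr.TransportConfig(n_histories=2000, seed=9,
                             electron_mode="csda")
    t, _ = tr.transport_electrons(minimal_problem, "stomach", 0.3, cfg)
    assert t.audit["escaped"] == 0.0
    assert abs(t.audit["balance"]) < 1e-9


# -- mesh tallies and marrow weighting --------------------------------------

def test_mesh_dose_map_divides_by_density_and_masks_air():
    e = np.ones((2, 2, 2))
    rho = np.full((2, 2, 2), 2.0)
    rho[0, 0, 0] = 0.0012               # air voxel -> masked
    m = tr.mesh_dose_map(tr.MeshTally(e, rho, (1, 1, 1)))
    assert m.mask[0, 0, 0]
    assert m[1, 1, 1] == pytest.approx(0.5)


def test_mesh_dose_map_two_material_slab():
    e = np.array([[[1.0, 1.0]]])
    rho = np.array([[[1.0, 0.5]]])
    m = tr.mesh_dose_map(tr.MeshTally(e, rho, (1, 1, 1)))
    assert m[0, 0, 0] == pytest.approx(1.0)
    assert m[0, 0, 1] == pytest.approx(2.0)


def test_electron_mesh_total_energy(minimal_problem):
    cfg = tr.TransportConfig(n_histories=100, seed=2)
    t, mesh = tr.transport_electrons(minimal_problem, "thyroid", 0.5, cfg,
                                     want_mesh=True)
    vol = minimal_problem.lattice.voxel_volume_cm3
    assert float(mesh.energy_density.sum()) * vol == pytest.approx(0.5)


def test_marrow_weighting():
    assert tr.marrow_endosteal_dose({"spine": 2.0}, {"spine": 1.0}) == 2.0
    assert tr.marrow_endosteal_dose({"a": 3.0, "b": 3.0},
                                    {"a": 0.5, "b": 0.5}) == 3.0
    got = tr.marrow_endosteal_dose({"a": 1.0, "b": 4.0},
                                   {"a": 0.25, "b": 0.75})
    assert got == pytest.approx(0.25 * 1 + 0.75 * 4)
    with pytest.raises(ValueError):
        tr.marrow_endosteal_dose({"a": 1.0}, {"a": 0.5})
    fr = tr.load_marrow_fractions()
    assert sum(fr.values()) == pytest.approx(1.0, abs=1e-9)
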