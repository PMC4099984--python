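"""Compartment solver, pregnancy iodide model, voiding bladder, fitting,
and the transcribed activity tables."""

import numpy as np
import pytest

from pregdose import biokinetics as bk


def _single_compartment(half_life_d=8.02):
    lam = np.log(2) / half_life_d
    return bk.CompartmentModel(("pool",), np.zeros((1, 1)), lam,
                               np.array([1.0]))


def _chain(k=0.7, lam=0.1):
    K = np.array([[-k, 0.0], [k, 0.0]])
    return bk.CompartmentModel(("a", "b"), K, lam, np.array([1.0, 0.0]))


def test_single_compartment_residence_is_inverse_decay_constant():
    cs = bk.cumulated_activities(_single_compartment())
    assert cs.entries["pool"] == pytest.approx(8.02 / np.log(2) * 24,
                                               rel=1e-12)


def test_chain_matches_closed_form_and_ode_oracle():
    k, lam = 0.7, 0.1
    cs = bk.cumulated_activities(_chain(k, lam))
    assert cs.entries["b"] == pytest.approx(24 * k / (lam * (k + lam)),
                                            rel=1e-12)
    oracle = bk.cumulated_activities_ode(_chain(k, lam))
    for name in ("a", "b"):
        assert cs.entries[name] == pytest.approx(oracle[name], rel=1e-8)


def test_iodide_model_matches_ode_oracle():
    model = bk.build_iodide_pregnancy_model(0.25, "I-131")
    direct = bk.cumulated_activities(model).entries
    oracle = bk.cumulated_activities_ode(model)
    for region, val in direct.items():
        assert val == pytest.approx(oracle[region], rel=1e-7, abs=1e-10)


@pytest.mark.parametrize("F", bk.UPTAKE_LEVELS)
@pytest.mark.parametrize("nuclide", ["I-131", "I-123"])
def test_decay_count_conservation(F, nuclide):
    """Every administered atom decays exactly once: sum of A~ times the
    physical decay constant equals 1 to 1e-8."""
    model = bk.build_iodide_pregnancy_model(F, nuclide)
    cs = bk.cumulated_activities(model)
    lam_h = model.lambda_phys / 24.0
    assert sum(cs.entries.values()) * lam_h == pytest.approx(1.0, abs=1e-8)


def test_solver_is_linear_in_initial_distribution():
    K = np.array([[-0.7, 0.0], [0.7, 0.0]])
    lam = 0.1
    M = lam * np.eye(2) - K
    e0 = np.linalg.solve(M, [1.0, 0.0])
    e1 = np.linalg.solve(M, [0.0, 1.0])
    mix = bk.CompartmentModel(("a", "b"), K, lam, np.array([0.3, 0.7]))
    got = bk.cumulated_activities(mix)
    want = 0.3 * e0 + 0.7 * e1
    assert got.entries["a"] == pytest.approx(24 * want[0], rel=1e-12)
    assert got.entries["b"] == pytest.approx(24 * want[1], rel=1e-12)


def test_fast_decay_starves_downstream_compartments():
    slow = bk.cumulated_activities(_chain(lam=0.1)).entries["b"]
    fast = bk.cumulated_activities(_chain(lam=1e6)).entries["b"]
    assert fast < 1e-9 * slow


def test_uptake_parameter_controls_asymptotic_trapping():
    from pregdose.biokinetics import (_asymptotic_thyroid_uptake,
                                      load_rate_constants)
    c = load_rate_constants()
    for F in (0.05, 0.5, 0.95):
        model = bk.build_iodide_pregnancy_model(F, "I-131")
        i_b, i_t = model.index("blood"), model.index("thyroid")
        k_thy = model.K[i_t, i_b]
        assert _asymptotic_thyroid_uptake(k_thy, c) == pytest.approx(
            F, rel=1e-9)


def test_vanishing_uptake_gives_vanishing_thyroid_activity():
    cs = bk.cumulated_activities(
        bk.build_iodide_pregnancy_model(1e-6, "I-131"))
    assert cs.entries["thyroid"] < 1e-3  # hours; -> 0 as F -> 0


def test_uptake_trends_match_published_directions():
    """Across the 7 uptake levels: maternal thyroid rises; fetal thyroid,
    stomach fall; liver rises (I-131)."""
    series = {r: [] for r in ("thyroid", "fetus thyroid", "stomach", "liver")}
    for F in bk.UPTAKE_LEVELS:
        cs = bk.cumulated_activities(
            bk.build_iodide_pregnancy_model(F, "I-131"))
        for r in series:
            series[r].append(cs.entries[r])
    assert all(np.diff(series["thyroid"]) > 0)
    assert all(np.diff(series["liver"]) > 0)
    assert all(np.diff(series["fetus thyroid"]) < 0)
    assert all(np.diff(series["stomach"]) < 0)


def test_invalid_uptake_rejected():
    for F in (0.0, 1.0, -0.2, 1.7):
        with pytest.raises(ValueError):
            bk.build_iodide_pregnancy_model(F, "I-131")
    with pytest.raises(ValueError):
        bk.build_iodide_pregnancy_model(0.25, "Tc-99m")


# -- voiding bladder --------------------------------------------------------

def test_bladder_zero_inflow_gives_zero():
    assert bk.bladder_cumulated_activity(lambda t: 0.0, 0.1) == 0.0


def test_bladder_constant_inflow_triangle_area():
    """Constant rate r, negligible decay, voids every T: each interval
    contributes r T^2/2."""
    sched = bk.VoidingSchedule(interval=2.0, first_void=2.0)
    got = bk.bladder_cumulated_activity(lambda t: 1.0, 1e-9, sched,
                                        horizon_h=8.0)
    assert got == pytest.approx(4 * 1.0 * 2.0**2 / 2, rel=1e-6)


def test_bladder_decaying_inflow_matches_event_stepping_oracle():
    lam, sched = 0.05, bk.VoidingSchedule(3.5, 3.5)
    inflow = lambda t: 0.2 * np.exp(-0.3 * t)
    got = bk.bladder_cumulated_activity(inflow, lam, sched, horizon_h=60.0)
    # forward-Euler event-stepping oracle, dt = 1e-3 h
    dt, B, total = 1e-3, 0.0, 0.0
    voids = set(np.round(np.arange(3.5, 60.0, 3.5) / dt).astype(int))
    for i in range(int(60.0 / dt)):
        if i in voids:
            B = 0.0
        total += B * dt
        B += dt * (inflow(i * dt) - lam * B)
    assert got == pytest.approx(total, rel=1e-3)


def test_bladder_negative_inflow_rejected():
    with pytest.raises(ValueError):
        bk.bladder_cumulated_activity(lambda t: -1.0, 0.1, horizon_h=5.0)


def test_full_activity_set_includes_voided_bladder():
    cs = bk.pregnancy_activity_set(0.25, "I-131")
    assert "urinary bladder contents" in cs.entries
    assert "urine" not in cs.entries
    assert 0 < cs.entries["urinary bladder contents"] < 24.0


# -- synthetic curves and parameter recovery --------------------------------

def test_noiseless_curves_and_seed_reproducibility():
    model = _chain()
    times = np.linspace(0, 48, 20)
    clean = bk.gen_time_activity(model, times, cv=0.0)
    assert clean.shape == (20, 2)
    assert clean[0, 0] == pytest.approx(1.0)
    a = bk.gen_time_activity(model, times, cv=0.1, seed=5)
    b = bk.gen_time_activity(model, times, cv=0.1, seed=5)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, clean)


def test_noise_is_mean_preserving():
    model = _chain()
    times = np.array([6.0, 24.0])
    reps = np.stack([bk.gen_time_activity(model, times, cv=0.2, seed=s)
                     for s in range(1000)])
    clean = bk.gen_time_activity(model, times, cv=0.0)
    se = reps.std(axis=0) / np.sqrt(len(reps))
    assert np.all(np.abs(reps.mean(axis=0) - clean) < 3 * se + 1e-12)


def _chain_builder(params):
    return bk.CompartmentModel(
        ("a", "b", "c"),
        np.array([[-params["k_ab"], 0.0, 0.0],
                  [params["k_ab"], -params["k_bc"], 0.0],
                  [0.0, params["k_bc"], 0.0]]),
        0.2, np.array([1.0, 0.0, 0.0]))


def test_fit_recovers_rates_from_noiseless_data():
    truth = {"k_ab": 1.4, "k_bc": 0.5}
    times = np.linspace(1, 72, 20)
    curves = bk.gen_time_activity(_chain_builder(truth), times, cv=0.0)
    res = bk.fit_rates(times, curves, _chain_builder,
                       {"k_ab": 0.8, "k_bc": 1.0})
    assert res["success"]
    for name, val in truth.items():
        assert res["estimates"][name] == pytest.approx(val, rel=1e-3)


def test_fit_recovery_rate_under_noise():
    """cv = 0.05, 20 time points: every free rate within 10% of truth in at
    least 90% of seeded replicates."""
    truth = {"k_ab": 1.4, "k_bc": 0.5}
    times = np.linspace(1, 72, 20)
    ok = 0
    n_rep = 40
    for seed in range(n_rep):
        curves = bk.gen_time_activity(_chain_builder(truth), times, cv=0.05,
                                      seed=seed)
        res = bk.fit_rates(times, curves, _chain_builder,
                           {"k_ab": 0.8, "k_bc": 1.0})
        if all(abs(res["estimates"][k] - v) / v < 0.10
               for k, v in truth.items()):
            ok += 1
    assert ok / n_rep >= 0.90


def test_wrong_structure_fits_worse():
    truth = {"k_ab": 1.4, "k_bc": 0.5}
    times = np.linspace(1, 72, 20)
    curves = bk.gen_time_activity(_chain_builder(truth), times, cv=0.0)

    def wrong_builder(params):  # b feeds back to a: different topology
        k = params["k_ab"]
        return bk.CompartmentModel(
            ("a", "b", "c"),
            np.array([[-k, 0.3, 0.0], [k, -0.8, 0.0], [0.0, 0.5, 0.0]]),
            0.2, np.array([1.0, 0.0, 0.0]))

    good = bk.fit_rates(times, curves, _chain_builder,
                        {"k_ab": 0.8, "k_bc": 1.0})
    bad = bk.fit_rates(times, curves, wrong_builder, {"k_ab": 0.8})
    assert bad["residual_norm"] > 10 * good["residual_norm"]


# -- transcribed tables -----------------------------------------------------

def test_fixture_units_convert_to_hours():
    s = bk.load_fixture_activities("russell", "I-131", 0.25)
    assert s.entries["thyroid"] == pytest.approx(2.54 * 24)  # 60.96 h
    t = bk.load_fixture_activities("icrp53", "Tc-99m")
    assert t.entries["thyroid"] == pytest.approx(2.23 / 60)


def test_fixture_missing_combination_raises():
    with pytest.raises(KeyError):
        bk.load_fixture_activities("russell", "I-131", 0.40)
    with pytest.raises(ValueError):
        bk.load_fixture_activities("unpublished", "I-131", 0.25)


def test_activity_set_csv_round_trip(tmp_path):
    s = bk.load_fixture_activities("this_study", "I-131", 0.25)
    p = tmp_path / "acts.csv"
    s.to_csv(p)
    back = bk.CumulatedActivitySet.from_csv(p)
    assert back.entries == pytest.approx(s.entries)
    assert (back.nuclide, back.provenance, back.uptake) == \
        (s.nuclide, s.provenance, s.uptake)


def test_model_invariants_enforced():
    with pytest.raises(ValueError):   # columns must sum to zero
        bk.CompartmentModel(("a", "b"),
                            np.array([[-1.0, 0.0], [0.5, 0.0]]), 0.1,
                            np.array([1.0, 0.0]))
    with pytest.raises(ValueError):   # negative off-diagonal
        bk.CompartmentModel(("a", "b"),
                            np.array([[0.5, 0.0], [-0.5, 0.0]]), 0.1,
                            np.array([1.0, 0.0]))
    with pytest.raises(ValueError):   # A0 not normalized
        bk.CompartmentModel(("a",), np.zeros((1, 1)), 0.1, np.array([2.0]))
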