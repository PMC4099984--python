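"""S-value assembly, dose conversion, uptake sweep, provenance comparison,
fetal summary, and the published dose-table fixture."""

import numpy as np
import pytest

from pregdose import biokinetics as bk
from pregdose import decay
from pregdose import dose as ds
from pregdose import transport as tr


def _fake_tally(source, particle, energy, regions, values):
    return tr.TallyResult(source, particle, energy, tuple(regions),
                          np.asarray(values, float),
                          np.zeros(len(regions)), 1000)


def _fake_scheme(lines=(), betas=()):
    return decay.DecayScheme("I-131", 192.6, tuple(lines), tuple(betas))


@pytest.fixture(scope="module")
def small_svalues(coarse_reference_problem):
    """S-values on the coarse reference lattice for a reduced I-131 scheme
    (dominant gamma + dominant beta), for all published source regions plus
    the uniform fetus."""
    prob = coarse_reference_problem
    scheme = _fake_scheme(
        [decay.EmissionLine("photon", 0.364489, 0.815, "gamma", "g364")],
        [decay.BetaBranch(0.60631, 0.896, 54)])
    sources = {r: r for r in
               ("thyroid", "salivary glands", "stomach", "small intestine",
                "liver", "kidneys", "urinary bladder contents",
                "remaining tissues", "placenta", "fetus thyroid",
                "fetus remainder")}
    fetal = [lab for lab in prob.lattice.label_index
             if lab != 0 and prob.regions[prob.region_of_label[lab]]
             in ("fetus thyroid", "fetus remainder")]
    sources["fetus"] = fetal
    cfg = tr.TransportConfig(n_histories=1500, seed=17)
    tallies = ds.run_scheme_tallies(prob, scheme, sources, cfg)
    return ds.assemble_svalues(tallies, scheme, list(sources))


def test_dose_constant_dimensional_analysis():
    """Ã = 1 h with S = 1 MeV/g per decay gives 576.78 mGy/MBq."""
    assert round(ds.DOSE_CONSTANT, 2) == 576.78


def test_svalue_single_line_arithmetic():
    scheme = _fake_scheme([decay.EmissionLine("photon", 0.1, 0.5, "gamma")])
    tallies = {("src", "photon", 0.1):
               _fake_tally("src", "photon", 0.1, ["src", "tgt"], [2.0, 0.4])}
    sv = ds.assemble_svalues(tallies, scheme, ["src"])
    assert sv.S("src", "src") == pytest.approx(0.5 * 2.0)
    assert sv.S("src", "tgt") == pytest.approx(0.5 * 0.4)


def test_svalue_empty_scheme_gives_zero():
    sv = ds.assemble_svalues({}, _fake_scheme(), ["src"])
    assert sv.to_frame().empty


def test_svalue_two_line_hand_sum():
    scheme = _fake_scheme([
        decay.EmissionLine("photon", 0.1, 0.5, "gamma"),
        decay.EmissionLine("electron", 0.05, 0.2, "conversion", "K")])
    tallies = {
        ("s", "photon", 0.1): _fake_tally("s", "photon", 0.1, ["s"], [2.0]),
        ("s", "electron", 0.05): _fake_tally("s", "electron", 0.05, ["s"],
                                             [3.0])}
    sv = ds.assemble_svalues(tallies, scheme, ["s"])
    e = sv.entry("s", "s")
    assert e.S == pytest.approx(0.5 * 2.0 + 0.2 * 3.0)
    assert e.S_photon == pytest.approx(1.0)
    assert e.S_electron == pytest.approx(0.6)


def test_svalue_missing_coverage_raises():
    scheme = _fake_scheme([decay.EmissionLine("photon", 0.1, 0.5, "gamma")])
    with pytest.raises(KeyError, match="missing tallies"):
        ds.assemble_svalues({}, scheme, ["src"])


def test_dose_linearity_in_activities():
    scheme = _fake_scheme([decay.EmissionLine("photon", 0.1, 1.0, "gamma")])
    tallies = {("thyroid", "photon", 0.1):
               _fake_tally("thyroid", "photon", 0.1,
                           ["thyroid", "liver"], [2.0, 0.1])}
    sv = ds.assemble_svalues(tallies, scheme, ["thyroid"])
    a1 = bk.CumulatedActivitySet("I-131", "computed", {"thyroid": 3.0})
    a2 = bk.CumulatedActivitySet("I-131", "computed", {"thyroid": 6.0})
    a0 = bk.CumulatedActivitySet("I-131", "computed", {"thyroid": 0.0})
    d1 = ds.organ_doses(sv, a1).doses
    d2 = ds.organ_doses(sv, a2).doses
    d0 = ds.organ_doses(sv, a0).doses
    for t in d1:
        assert d2[t] == pytest.approx(2 * d1[t], rel=1e-12)
        assert d0[t] == 0.0
    assert d1["thyroid"] == pytest.approx(3.0 * ds.DOSE_CONSTANT * 2.0)


def test_region_mismatch_raises_unless_folded():
    scheme = _fake_scheme([decay.EmissionLine("photon", 0.1, 1.0, "gamma")])
    tallies = {("remaining tissues", "photon", 0.1):
               _fake_tally("remaining tissues", "photon", 0.1,
                           ["remaining tissues"], [1.0])}
    sv = ds.assemble_svalues(tallies, scheme, ["remaining tissues"])
    acts = bk.CumulatedActivitySet("I-131", "computed", {"uli wall": 1.0,
                                                         "spleen": 1.0})
    with pytest.raises(KeyError):
        ds.organ_doses(sv, acts)
    folded = ds.organ_doses(sv, acts, fold_unmapped=True)
    assert folded.doses["remaining tissues"] > 0


def test_fetal_summary_weighted_mean():
    assert ds.fetal_summary({"a": 5.0, "b": 5.0}, {"a": 1, "b": 9}) == 5.0
    assert ds.fetal_summary({"a": 4.0, "b": 0.0}, {"a": 1, "b": 3}) == 1.0
    with pytest.raises(KeyError):
        ds.fetal_summary({"a": 1.0}, {"a": 1, "b": 2})


def test_fetal_summary_equals_energy_over_mass(coarse_reference_problem):
    """Mass-weighted mean of fetal-region doses equals total fetal energy
    over total fetal mass (audit identity, electron source)."""
    prob = coarse_reference_problem
    cfg = tr.TransportConfig(n_histories=500, seed=3)
    t, _ = tr.transport_electrons(prob, "fetus thyroid", 0.3, cfg)
    fetal = ["fetus thyroid", "fetus remainder"]
    doses = {r: t.as_dict()[r] for r in fetal}
    masses = {r: prob.region_mass[prob.regions.index(r)] for r in fetal}
    summary = ds.fetal_summary(doses, masses)
    energy = sum(doses[r] * masses[r] for r in fetal)
    assert summary == pytest.approx(energy / sum(masses.values()),
                                    rel=1e-12)


# -- published dose table ---------------------------------------------------

def test_dose_fixture_fetal_thyroid_uptake_ratio_rounds_to_15():
    t5 = ds.load_dose_table_fixture("I-131")
    ratio = t5.loc["Fetus, thyroid", "u05"] / t5.loc["Fetus, thyroid", "u95"]
    assert round(ratio) == 15


def test_dose_fixture_monotone_trends():
    t5 = ds.load_dose_table_fixture("I-131")
    sweep = ["u05", "u15", "u25", "u35", "u45", "u55", "u95"]
    thy = t5.loc["Thyroid", sweep].astype(float).values
    fthy = t5.loc["Fetus, thyroid", sweep].astype(float).values
    assert np.all(np.diff(thy) > 0)
    assert np.all(np.diff(fthy) < 0)


def test_fetal_thyroid_share_of_fetal_activity_rounds_to_94_percent():
    acts = bk.load_fixture_activities("this_study", "I-131", 0.25)
    fthy = acts.entries["fetus thyroid"]
    fetus_total = bk.load_fixture_activities(
        "russell", "I-131", 0.25).entries["fetus"]
    assert round(100 * fthy / fetus_total) == 94


# -- sweeps and comparisons -------------------------------------------------

def test_uptake_sweep_monotone_and_single_level_consistency(small_svalues):
    tables = ds.uptake_sweep(small_svalues, "I-131", bk.UPTAKE_LEVELS)
    assert len(tables) == 7
    single = ds.uptake_sweep(small_svalues, "I-131", [0.25],
                             check_trends=False)[0]
    acts = bk.pregnancy_activity_set(0.25, "I-131")
    direct = ds.organ_doses(small_svalues, acts)
    assert single.doses == pytest.approx(direct.doses)


def test_compare_identical_sets_gives_zero_differences(small_svalues):
    acts = bk.load_fixture_activities("russell", "I-131", 0.25)
    df = ds.compare_activity_sets(small_svalues,
                                  {"x": acts, "y": acts}, base="y")
    assert np.allclose(df["pct_diff_x_vs_y"].fillna(0.0), 0.0)


def test_compare_three_provenances_no_missing_cells(small_svalues):
    sets = {"this_study": bk.load_fixture_activities("this_study", "I-131",
                                                     0.25),
            "russell": bk.load_fixture_activities("russell", "I-131", 0.25),
            "icrp53": bk.load_fixture_activities("icrp53", "I-131", 0.25)}
    df = ds.compare_activity_sets(small_svalues, sets)
    assert not df[["this_study", "russell", "icrp53"]].isna().any().any()
    assert len(df) > 5


def test_separate_fetal_thyroid_source_beats_uniform_fetus(small_svalues):
    """Concentrating the fetal activity in the 1.3 g fetal thyroid gives a
    far higher fetal-thyroid self-dose than spreading the same activity
    uniformly over the fetus (self-absorption)."""
    sv = small_svalues
    s_sep = sv.S("fetus thyroid", "fetus thyroid")
    s_uni = sv.S("fetus", "fetus thyroid")
    assert s_sep > 10 * s_uni


def test_region_canonicalization():
    assert ds.canonical_region("SI-wall") == "small intestine"
    assert ds.canonical_region("Stomach Wall") == "stomach"
    assert ds.canonical_region("thyroid") == "thyroid"
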