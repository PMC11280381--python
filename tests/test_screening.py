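"""Candidate ranking and the drug-likeness / pharmacokinetic rule engine."""

import pytest

from qsarflow import (
    ADMETProfile,
    Dataset,
    ScreeningConfig,
    admet_gate,
    bbb_cns_classify,
    lipinski_profile,
    load_fixture,
    screen_candidates,
)
from qsarflow.screening import LipinskiBounds
from qsarflow.synthetic_data import admet_profiles


@pytest.fixture(scope="module")
def eq1():
    return load_fixture("eq1_model")


@pytest.fixture(scope="module")
def candidates():
    return load_fixture("table4_candidates")


def test_designed_candidate_m1_ranks_first(eq1, candidates):
    report = screen_candidates(eq1, candidates)
    table = report.table
    assert len(table) == 11
    assert table.loc[0, "id"] == "M1"
    assert table.loc[0, "rank"] == 1
    assert table.loc[0, "predicted_pic50"] == table["predicted_pic50"].max()
    assert sorted(table["id"]) == sorted(candidates.ids)
    # all predictions beat the reference potency of 7.259? M7 does not
    assert bool(table.loc[table["id"] == "M1", "improved"].iloc[0])


def test_candidate_equal_to_reference_not_improved(eq1):
    from qsarflow import CompoundRecord, predict

    # pick descriptors whose prediction is exactly the reference
    cfg = ScreeningConfig()
    rec = CompoundRecord("ref", {"PSA": 0.0, "DM": 0.0, "MW": 0.0})
    rec.descriptors["MW"] = (cfg.reference_pic50 - eq1.intercept) / eq1.coefficients["MW"]
    assert predict(eq1, rec.descriptors) == pytest.approx(cfg.reference_pic50)
    report = screen_candidates(eq1, Dataset([rec], ["PSA", "DM", "MW"]), cfg)
    assert not bool(report.table.loc[0, "improved"])


def test_empty_candidate_set_is_not_an_error(eq1):
    report = screen_candidates(eq1, Dataset([], ["PSA", "DM", "MW"]))
    assert len(report.table) == 0


def test_ranking_ties_broken_by_id(eq1):
    from qsarflow import CompoundRecord

    desc = {"PSA": 10.0, "DM": 3.0, "MW": 400.0}
    ds = Dataset(
        [CompoundRecord("zz", dict(desc)), CompoundRecord("aa", dict(desc))],
        ["PSA", "DM", "MW"],
    )
    table = screen_candidates(eq1, ds).table
    assert list(table["id"]) == ["aa", "zz"]


# ---------------------------------------------------------------------------
# Lipinski


def test_lipinski_published_m1_one_violation():
    profile = ADMETProfile("M1", logp=6.86, mw=476.50, hba=7, hbd=0)
    violations, ok = lipinski_profile(profile)
    assert violations == 1  # logP only
    assert ok


def test_lipinski_bounds_are_inclusive():
    profile = ADMETProfile("edge", logp=5.0, mw=500.0, hba=10, hbd=5)
    assert lipinski_profile(profile) == (0, True)


def test_lipinski_all_four_violated_fails():
    profile = ADMETProfile("bad", logp=6.0, mw=501.0, hba=11, hbd=6)
    violations, ok = lipinski_profile(profile)
    assert violations == 4
    assert not ok


def test_lipinski_counts_match_brute_force(rng):
    cfg = ScreeningConfig()
    b = cfg.lipinski
    for _ in range(1000):
        p = ADMETProfile(
            "r",
            logp=float(rng.uniform(-2, 9)),
            mw=float(rng.uniform(100, 700)),
            hba=int(rng.integers(0, 15)),
            hbd=int(rng.integers(0, 9)),
        )
        expected = (
            (p.logp > b.logp_max)
            + (p.mw > b.mw_max)
            + (p.hbd > b.hbd_max)
            + (p.hba > b.hba_max)
        )
        violations, ok = lipinski_profile(p, cfg)
        assert violations == expected
        assert ok == (expected <= cfg.max_lipinski_violations)


def test_lipinski_monotone_in_thresholds():
    p = ADMETProfile("m", logp=4.9, mw=480.0, hba=8, hbd=2)
    loose = ScreeningConfig()
    tight = ScreeningConfig(lipinski=LipinskiBounds(mw_max=450, logp_max=4, hbd_max=1, hba_max=7))
    v_loose, _ = lipinski_profile(p, loose)
    v_tight, _ = lipinski_profile(p, tight)
    assert v_tight >= v_loose


# ---------------------------------------------------------------------------
# BBB / CNS


@pytest.mark.parametrize(
    "cid,expected_bbb,expected_cns",
    [
        ("M1", "permeant", "penetrant"),   # logBB 0.39, logPS -1.292
        ("M2", "intermediate", "penetrant"),  # logBB 0.001 sits between cutoffs
        ("M6", "intermediate", "penetrant"),
        ("M9", "intermediate", "penetrant"),
        ("M10", "poor", "intermediate"),   # logBB -1.299, logPS -2.193
    ],
)
def test_bbb_cns_published_rows(cid, expected_bbb, expected_cns):
    profile = admet_profiles()[cid]
    assert bbb_cns_classify(profile) == (expected_bbb, expected_cns)


def test_bbb_cns_between_cutoffs_is_intermediate():
    p = ADMETProfile("x", logp=1, mw=300, hba=2, hbd=1, logbb=0.0, logps=-2.5)
    assert bbb_cns_classify(p) == ("intermediate", "intermediate")


def test_bbb_cutoffs_are_strict():
    at_cut = ADMETProfile("y", logp=1, mw=300, hba=2, hbd=1, logbb=0.3, logps=-2.0)
    assert bbb_cns_classify(at_cut) == ("intermediate", "intermediate")


# ---------------------------------------------------------------------------
# ADMET gate


def test_admet_gate_published_m1_all_pass():
    verdicts = admet_gate(admet_profiles()["M1"])
    assert verdicts["overall"]
    assert all(verdicts.values())


def test_admet_gate_published_m10_fails_hepatotoxicity():
    verdicts = admet_gate(admet_profiles()["M10"])
    assert not verdicts["hepatotoxicity"]
    assert not verdicts["overall"]
    others = [k for k in verdicts if k not in ("hepatotoxicity", "overall")]
    assert all(verdicts[k] for k in others)


def test_admet_gate_published_m9_fails_caco2():
    verdicts = admet_gate(admet_profiles()["M9"])  # Caco-2 0.457 < 0.9
    assert not verdicts["caco2"]


def test_admet_gate_monotone_in_thresholds():
    """Tightening a cutoff can only turn pass into fail, never the reverse."""
    p = admet_profiles()["M1"]
    base = admet_gate(p)
    tight = admet_gate(p, ScreeningConfig(hia_min=95.0, caco2_min=1.5))
    for rule in ("hia", "caco2"):
        assert not (not base[rule] and tight[rule])
    assert not tight["hia"] and not tight["caco2"]
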