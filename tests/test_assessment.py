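"""Distribution summaries, overlap scoring, and the three-leg verdict."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gagmimic import (
    DistributionSummary,
    DockingEvidence,
    Leg,
    MimicryReport,
    Overall,
    Status,
    Thresholds,
    binding_site_check,
    bound_state_verdict,
    compile_report,
    free_state_verdict,
    overlap_index,
    rank_candidates,
    summary_stats,
)
from gagmimic.energetics import EnergyDecomposition
from gagmimic.errors import (
    EmptySeriesError,
    InvalidEvidenceError,
    MetricMismatchError,
    MissingMetricError,
    NothingToCompareError,
    ReferenceMismatchError,
)
from gagmimic.hbonds import HBondCriteria, OccupancyTable


# --- summary stats --------------------------------------------------------

def test_five_number_summary_linear_quartiles():
    s = summary_stats([1, 2, 3, 4, 5], "EED")
    assert (s.q1, s.median, s.q3) == (2.0, 3.0, 4.0)
    assert (s.min, s.max) == (1.0, 5.0)
    assert s.sd == pytest.approx(np.std([1, 2, 3, 4, 5], ddof=1))


def test_constant_series_summary():
    s = summary_stats([7.0] * 10, "EED")
    assert s.q1 == s.median == s.q3 == 7.0
    assert s.sd == 0.0


def test_large_normal_sample_matches_reference_oracle():
    rng = np.random.default_rng(2024)
    x = rng.standard_normal(10000)
    s = summary_stats(x, "EED")
    from scipy import stats

    assert s.median == pytest.approx(np.median(x), abs=1e-12)
    assert s.q1 == pytest.approx(stats.scoreatpercentile(x, 25), abs=1e-9)
    assert abs(s.mean) < 0.02 and abs(s.sd - 1.0) < 0.02


def test_empty_series_raises():
    with pytest.raises(EmptySeriesError):
        summary_stats([], "EED")


# --- overlap --------------------------------------------------------------

def mk_summary(metric, q1, q3, mean=None, sd=None, n=100):
    mean = mean if mean is not None else (q1 + q3) / 2.0
    if sd is None:
        sd = (q3 - q1) / 1.349 if q3 > q1 else 1.0  # normal IQR -> sd
    return DistributionSummary(
        metric_name=metric,
        n=n,
        min=q1 - 2.0,
        q1=q1,
        median=(q1 + q3) / 2.0,
        q3=q3,
        max=q3 + 2.0,
        mean=mean,
        sd=sd,
    )


def test_identical_summaries_fully_overlap():
    a = mk_summary("EED", 20.0, 26.0)
    score = overlap_index(a, a)
    assert score.iqr_overlap == 1.0
    assert score.standardized_mean_difference == 0.0
    assert score.similar


def test_partial_interval_overlap_is_jaccard():
    a = mk_summary("EED", 0.0, 2.0)
    b = mk_summary("EED", 1.0, 3.0)
    assert overlap_index(a, b).iqr_overlap == pytest.approx(1 / 3)


def test_disjoint_far_apart_not_similar():
    a = mk_summary("EED", 0.0, 2.0, mean=1.0, sd=1.0)
    b = mk_summary("EED", 10.0, 12.0, mean=11.0, sd=1.0)
    score = overlap_index(a, b)
    assert score.iqr_overlap == 0.0
    assert abs(score.standardized_mean_difference) > 2.0
    assert not score.similar


def test_metric_mismatch_raises():
    with pytest.raises(MetricMismatchError):
        overlap_index(mk_summary("EED", 0, 1), mk_summary("MVEE_volume", 0, 1))


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    a_lo=st.floats(-50, 50), a_w=st.floats(0.1, 20),
    b_lo=st.floats(-50, 50), b_w=st.floats(0.1, 20),
)
def test_overlap_symmetric_and_smd_antisymmetric(a_lo, a_w, b_lo, b_w):
    a = mk_summary("EED", a_lo, a_lo + a_w, sd=1.0)
    b = mk_summary("EED", b_lo, b_lo + b_w, sd=1.0)
    ab, ba = overlap_index(a, b), overlap_index(b, a)
    assert ab.iqr_overlap == pytest.approx(ba.iqr_overlap, abs=1e-12)
    assert ab.standardized_mean_difference == pytest.approx(
        -ba.standardized_mean_difference, abs=1e-12
    )
    assert 0.0 <= ab.iqr_overlap <= 1.0


# --- leg 1 ----------------------------------------------------------------

def free_summaries(eed_q1, eed_q3, vol_q1, vol_q3, **kw):
    return {
        "EED": mk_summary("EED", eed_q1, eed_q3, **kw),
        "MVEE_volume": mk_summary("MVEE_volume", vol_q1, vol_q3, **kw),
    }


def test_identical_free_state_passes_with_score_one():
    ref = free_summaries(22.0, 26.0, 600.0, 700.0)
    v = free_state_verdict(ref, ref)
    assert v.status is Status.PASS
    assert v.score == 1.0


def test_compact_candidate_fails_free_state():
    """A candidate whose EED and volume sit entirely below the reference
    IQRs (a rigid monomer against a hexasaccharide) fails leg 1."""
    ref = free_summaries(22.0, 26.0, 600.0, 700.0, sd=2.0)
    cand = free_summaries(8.0, 10.0, 150.0, 200.0, sd=2.0)
    v = free_state_verdict(cand, ref)
    assert v.status is Status.FAIL
    assert not v.components["EED"].similar


def test_missing_metric_raises():
    ref = free_summaries(22.0, 26.0, 600.0, 700.0)
    with pytest.raises(MissingMetricError):
        free_state_verdict({"EED": ref["EED"]}, ref)


# --- leg 2 ----------------------------------------------------------------

def test_binding_site_pass_on_stronger_candidate_score():
    cand = DockingEvidence("cand", 108.6, True)
    ref = DockingEvidence("ref", 100.8, True)
    v = binding_site_check(cand, ref)
    assert v.status is Status.PASS
    assert v.components["score_ratio"] == pytest.approx(108.6 / 100.8)


def test_wrong_site_fails_regardless_of_score():
    v = binding_site_check(
        DockingEvidence("cand", 999.0, False), DockingEvidence("ref", 100.0, True)
    )
    assert v.status is Status.FAIL


def test_absent_evidence_is_inconclusive():
    v = binding_site_check(None, DockingEvidence("ref", 100.0, True))
    assert v.status is Status.INCONCLUSIVE


def test_nonpositive_reference_score_raises():
    with pytest.raises(InvalidEvidenceError):
        binding_site_check(
            DockingEvidence("cand", 50.0, True), DockingEvidence("ref", 0.0, True)
        )


# --- leg 3 ----------------------------------------------------------------

def occupancy_from(d: dict[str, float]):
    rows = [
        {
            "residue": k,
            "occupancy_percent": v,
            "n_frames_observed": int(v * 10),
            "window_frames": 1000,
        }
        for k, v in d.items()
    ]
    return OccupancyTable(
        table=pd.DataFrame(
            rows,
            columns=[
                "residue", "occupancy_percent", "n_frames_observed",
                "window_frames",
            ],
        ),
        window_frames=1000,
        criteria=HBondCriteria(),
    )


def energy_from(total_mean, total_sd, residues):
    return EnergyDecomposition(
        table=pd.DataFrame(residues, columns=["residue", "mean", "sd"]),
        total_dg_mean=total_mean,
        total_dg_sd=total_sd,
    )


def test_identical_bound_state_passes_with_score_one():
    shape = free_summaries(20.0, 24.0, 550.0, 650.0)
    occ = occupancy_from({"A:ARG121": 95.0, "A:LYS126": 80.0})
    en = energy_from(-73.5, 10.0, [("Arg121", -11.1, 1.4), ("Lys126", -12.0, 3.7)])
    v = bound_state_verdict(shape, shape, occ, occ, en, en)
    assert v.status is Status.PASS
    assert v.score == pytest.approx(1.0)


def test_overlapping_total_dg_intervals_pass_energy_component():
    """ΔG −73.5±10.0 vs −74.0±11.1 kcal/mol: the intervals overlap, so the
    energy component passes even with different dominant residues."""
    shape = free_summaries(20.0, 24.0, 550.0, 650.0)
    en_c = energy_from(-73.5, 10.0, [("Lys126", -12.0, 3.7), ("Arg121", -11.1, 1.4)])
    en_r = energy_from(-74.0, 11.1, [("Gln135", -10.2, 1.6), ("Arg121", -9.0, 2.8)])
    v = bound_state_verdict(shape, shape, None, None, en_c, en_r)
    assert v.components["energy"]["similar"]
    assert v.components["energy"]["total_interval_overlap"] > 0
    assert v.status is Status.PASS


def test_disjoint_occupancy_residue_sets_fail_the_leg():
    shape = free_summaries(20.0, 24.0, 550.0, 650.0)
    occ_c = occupancy_from({"A:ARG45": 90.0})
    occ_r = occupancy_from({"A:LYS136": 88.0})
    v = bound_state_verdict(shape, shape, occ_c, occ_r)
    assert not v.components["occupancy"]["similar"]
    assert v.status is Status.FAIL


def test_nothing_to_compare_raises():
    with pytest.raises(NothingToCompareError):
        bound_state_verdict({}, {})


# --- reports, short-circuit, ranking --------------------------------------

def passing_legs(score=0.9):
    ref = free_summaries(22.0, 26.0, 600.0, 700.0)
    leg1 = free_state_verdict(ref, ref)
    leg2 = binding_site_check(
        DockingEvidence("c", 108.6, True), DockingEvidence("r", 100.8, True)
    )
    shape = free_summaries(20.0, 24.0, 550.0, 650.0)
    leg3 = bound_state_verdict(shape, shape)
    return [leg1, leg2, leg3]


def test_all_pass_gives_mimic():
    rep = compile_report("cand", "ref", passing_legs())
    assert rep.overall is Overall.MIMIC
    assert rep.n_passed == 3


def test_leg1_failure_short_circuits():
    ref = free_summaries(22.0, 26.0, 600.0, 700.0, sd=1.0)
    cand = free_summaries(5.0, 7.0, 100.0, 130.0, sd=1.0)
    leg1 = free_state_verdict(cand, ref)
    rep = compile_report("cand", "ref", [leg1, None, None])
    assert rep.overall is Overall.NON_MIMIC
    assert [v.status for v in rep.legs] == [
        Status.FAIL, Status.NOT_EVALUATED, Status.NOT_EVALUATED,
    ]


def test_inconclusive_leg_gives_inconclusive_overall():
    legs = passing_legs()
    legs[1] = None  # no docking evidence
    rep = compile_report("cand", "ref", legs)
    assert rep.overall is Overall.INCONCLUSIVE


def reference_like():
    """Reference free-state summaries for the ranking scenario."""
    return free_summaries(22.0, 26.0, 620.0, 700.0)


def candidate_reports():
    """Four candidates encoding the qualitative free/bound pattern: two
    extended dimer-like molecules straddle the reference IQRs and pass all
    legs (the better one scoring higher); a compact monomer-like candidate
    sits entirely below and a folded tetramer-like one entirely above the
    reference IQRs, both failing leg 1."""
    ref_free = reference_like()
    ref_shape = free_summaries(20.0, 24.0, 560.0, 640.0)
    ref_occ = occupancy_from({"A:ARG121": 90.0, "A:LYS126": 85.0, "A:LYS136": 70.0})
    ref_en = energy_from(-74.0, 11.1, [("Arg121", -9.0, 2.8), ("Gln135", -10.2, 1.6)])
    ref_dock = DockingEvidence("HS06-like", 100.8, True)

    specs = {
        # near-perfect overlap on every component
        "dimer2-like": dict(
            free=free_summaries(22.5, 26.2, 625.0, 698.0),
            dock=DockingEvidence("dimer2-like", 109.8, True),
            shape=free_summaries(20.2, 24.1, 565.0, 638.0),
            occ=occupancy_from(
                {"A:ARG121": 92.0, "A:LYS126": 83.0, "A:LYS136": 72.0}
            ),
            en=energy_from(-68.6, 5.8, [("Arg121", -11.1, 1.4), ("Gln135", -8.0, 1.2)]),
        ),
        # similar but smaller overlaps
        "dimer1-like": dict(
            free=free_summaries(23.5, 27.5, 650.0, 730.0),
            dock=DockingEvidence("dimer1-like", 108.6, True),
            shape=free_summaries(21.0, 25.5, 580.0, 660.0),
            occ=occupancy_from(
                {"A:ARG121": 88.0, "A:LYS126": 40.0, "A:LYS136": 75.0}
            ),
            en=energy_from(-73.5, 10.0, [("Lys126", -12.0, 3.7), ("Arg121", -11.1, 1.4)]),
        ),
        # entirely below the reference IQRs
        "monomer-like": dict(
            free=free_summaries(8.0, 10.0, 150.0, 200.0, sd=1.0),
            dock=DockingEvidence("monomer-like", 80.0, True),
        ),
        # entirely above the reference IQRs
        "tetramer-like": dict(
            free=free_summaries(30.0, 36.0, 900.0, 1100.0),
            dock=DockingEvidence("tetramer-like", 95.0, True),
        ),
    }
    reports = []
    for label, spec in specs.items():
        leg1 = free_state_verdict(spec["free"], ref_free)
        if leg1.status is Status.PASS:
            leg2 = binding_site_check(spec["dock"], ref_dock)
            leg3 = bound_state_verdict(
                spec["shape"], ref_shape, spec["occ"], ref_occ,
                spec["en"], ref_en,
            )
        else:
            leg2 = leg3 = None
        reports.append(compile_report(label, "HS06-like", [leg1, leg2, leg3]))
    return reports


def test_rank_order_matches_qualitative_pattern():
    ranked = rank_candidates(candidate_reports())
    assert [r.candidate for r in ranked] == [
        "dimer2-like", "dimer1-like", "monomer-like", "tetramer-like",
    ]
    for r in ranked[:2]:
        assert r.overall is Overall.MIMIC
    for r in ranked[2:]:
        assert r.overall is Overall.NON_MIMIC
        assert [v.status for v in r.legs[1:]] == [
            Status.NOT_EVALUATED, Status.NOT_EVALUATED,
        ]


def test_single_candidate_ranks_alone():
    reports = candidate_reports()[:1]
    assert rank_candidates(reports) == reports


def test_mixed_references_raise():
    a = compile_report("x", "ref1", passing_legs())
    b = compile_report("y", "ref2", passing_legs())
    with pytest.raises(ReferenceMismatchError):
        rank_candidates([a, b])


def test_improving_a_component_never_demotes_rank():
    """Verdict monotonicity: raising one candidate's docking score cannot
    lower its position in the ranking."""
    base = candidate_reports()
    ranked_before = [r.candidate for r in rank_candidates(base)]
    improved = []
    for rep in base:
        if rep.candidate == "dimer1-like":
            ref_free = reference_like()
            leg1 = rep.legs[0]
            leg2 = binding_site_check(
                DockingEvidence("dimer1-like", 150.0, True),
                DockingEvidence("HS06-like", 100.8, True),
            )
            improved.append(
                compile_report("dimer1-like", "HS06-like", [leg1, leg2, rep.legs[2]])
            )
        else:
            improved.append(rep)
    ranked_after = [r.candidate for r in rank_candidates(improved)]
    assert ranked_after.index("dimer1-like") <= ranked_before.index("dimer1-like")


def test_report_round_trips_through_json(tmp_path):
    rep = candidate_reports()[0]
    rep.provenance = {
        "hbond_convention": "deviation_from_linearity_DHA",
        "analysis_window": "final 50% of frames",
        "clustering": {"seed": 17, "radius": 2.0},
        "mvee_tolerance": 1e-6,
        "eed_endpoints": "auto_max_extent",
    }
    path = tmp_path / "report.json"
    rep.to_json(path)
    back = MimicryReport.from_json(path)
    assert back.to_dict() == rep.to_dict()
    assert back.overall is rep.overall
    assert [v.status for v in back.legs] == [v.status for v in rep.legs]


def test_aggregation_over_targets_weights_scores():
    """Combining one candidate's verdicts on two protein targets: scores
    average by the supplied weights and the overall is the worst outcome."""
    from gagmimic.assessment import aggregate_over_targets

    binary = compile_report("cand", "FGF2", passing_legs())
    legs = passing_legs()
    legs[1] = None
    ternary = compile_report("cand", "FGF2-FGFR1", legs)
    agg = aggregate_over_targets([binary, ternary], weights=[1.0, 3.0])
    expected = 0.25 * binary.overall_score + 0.75 * ternary.overall_score
    assert agg.overall_score == pytest.approx(expected)
    assert agg.overall is Overall.INCONCLUSIVE
    assert agg.provenance["target_weights"] == [0.25, 0.75]
    with pytest.raises(ReferenceMismatchError):
        aggregate_over_targets([binary, compile_report("other", "FGF2", passing_legs())])
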