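"""Matching, isotope verification, MS/MS annotation, confidence, screen."""

import numpy as np
import pytest

from pcbscreen.chem import ppm_difference
from pcbscreen.screening import (
    Annotation,
    Feature,
    Ms2Spectrum,
    ScreenConfig,
    annotate_ms2,
    assign_confidence,
    default_loss_library,
    match_features,
    score_isotope_pattern,
    screen,
)

OH_PCB2_MZ = 203.02637
SULFATE_MZ = 282.98318


def _feature(mz, rt=5.0, intensity=10.0, group="high", cluster="auto", n_cl=1):
    if cluster == "auto":
        cluster = [(mz, intensity)]
        if n_cl:
            cluster.append((mz + 1.99705, intensity * 0.32 * n_cl))
        cluster = tuple(cluster)
    return Feature(mz=mz, rt=rt, intensity=intensity, sample_id=f"{group}_1",
                   group=group, isotope_cluster=cluster)


def _candidate(class_id, candidates):
    return next(c for c in candidates if c.class_id == class_id)


# ---------------------------------------------------------------------------
# match_features


def test_match_within_window(pcb2_candidates):
    cand = [_candidate("1.1", pcb2_candidates)]
    hit = match_features([_feature(203.02696)], cand, window_ppm=10)
    assert len(hit) == 1
    assert hit[0][2] == pytest.approx(2.9, abs=0.05)


def test_no_match_outside_window(pcb2_candidates):
    cand = [_candidate("1.1", pcb2_candidates)]
    assert match_features([_feature(203.03100)], cand, window_ppm=10) == []


def test_exact_match_zero_ppm(pcb2_candidates):
    cand = [_candidate("1.1", pcb2_candidates)]
    f = _feature(cand[0].mz)
    assert match_features([f], cand)[0][2] == 0.0


def test_empty_candidate_list_is_not_an_error():
    assert match_features([_feature(203.0)], []) == []


def test_match_equals_all_pairs_brute_force(pcb2_candidates):
    """Oracle: exhaustive double loop over features x candidates."""
    rng = np.random.default_rng(7)
    features = [
        _feature(float(m), cluster=None)
        for m in rng.uniform(180, 420, size=50)
    ]
    cands = pcb2_candidates[:50]
    got = {
        (id(f), c.class_id, c.anion.hill())
        for f, c, _ in match_features(features, cands, 10)
    }
    expected = {
        (id(f), c.class_id, c.anion.hill())
        for f in features
        for c in cands
        if ppm_difference(f.mz, c.mz) <= 10
    }
    assert got == expected


def test_reported_ppm_recomputes_from_masses(pcb2_candidates):
    for f, c, ppm in match_features(
        [_feature(203.02696), _feature(282.98350)], pcb2_candidates, 10
    ):
        assert abs(ppm - ppm_difference(f.mz, c.mz)) < 0.05


# ---------------------------------------------------------------------------
# isotope scoring


def test_isotope_ratio_accepts_matching_chlorine_count():
    f = _feature(203.02696, cluster=((203.02696, 100.0), (205.02401, 32.0)))
    verdict = score_isotope_pattern(f, expected_cl=1)
    assert verdict.status == "pass"
    assert verdict.observed_ratio == pytest.approx(0.32)


def test_isotope_ratio_rejects_wrong_chlorine_count():
    f = _feature(203.02696, cluster=((203.02696, 100.0), (205.02401, 64.0)))
    assert score_isotope_pattern(f, expected_cl=1).status == "fail"
    assert score_isotope_pattern(f, expected_cl=2).status == "pass"


def test_isotope_missing_cluster_is_untested_not_false():
    verdict = score_isotope_pattern(_feature(203.0, cluster=None), 1)
    assert verdict.status == "untested"
    assert not verdict  # but still falsy


def test_isotope_zero_chlorine_checks_absence():
    clean = _feature(185.06, cluster=((185.06, 100.0),))
    dirty = _feature(185.06, cluster=((185.06, 100.0), (187.06, 30.0)))
    assert score_isotope_pattern(clean, 0).status == "pass"
    assert score_isotope_pattern(dirty, 0).status == "fail"


# ---------------------------------------------------------------------------
# loss library / MS2 annotation


def test_library_masses_are_computed_from_formulas():
    lib = {e.name: e.mass for e in default_loss_library()}
    assert lib["-SO3"] == pytest.approx(79.95682, abs=1e-5)
    assert lib["-C6H8O6"] == pytest.approx(176.03209, abs=1e-5)
    assert lib["-CH3-SO3"] == pytest.approx(94.98030, abs=1e-4)
    assert lib["SO3-"] == pytest.approx(79.95682, abs=1e-5)


def test_sulfate_loss_assignment(pcb2_candidates):
    cand = _candidate("1.2", pcb2_candidates)
    s = Ms2Spectrum(precursor_mz=SULFATE_MZ, fragments=((203.03, 100.0),))
    matches = annotate_ms2(s, cand)
    assert [m.name for m in matches] == ["-SO3"]
    assert matches[0].calculated_mz == pytest.approx(203.02637, abs=1e-4)


def test_methoxy_sulfate_sequential_losses(pcb2_candidates):
    cand = _candidate("3.2", pcb2_candidates)
    s = Ms2Spectrum(
        precursor_mz=312.99377,
        fragments=((233.04, 100.0), (218.01, 50.0)),
    )
    names = {m.name for m in annotate_ms2(s, cand)}
    assert names == {"-SO3", "-CH3-SO3"}


def test_no_library_hits_gives_empty_list(pcb2_candidates):
    cand = _candidate("1.2", pcb2_candidates)
    s = Ms2Spectrum(precursor_mz=SULFATE_MZ, fragments=((150.55, 10.0),))
    assert annotate_ms2(s, cand) == []


def test_precursor_candidate_mismatch_is_rejected(pcb2_candidates):
    cand = _candidate("1.2", pcb2_candidates)
    s = Ms2Spectrum(precursor_mz=290.0, fragments=((203.03, 100.0),))
    with pytest.raises(ValueError):
        annotate_ms2(s, cand)


# ---------------------------------------------------------------------------
# confidence


def _annotation(pcb2_candidates, fragments, isotope_status="pass"):
    from pcbscreen.screening import FragmentMatch, IsotopeVerdict

    cand = _candidate("1.1", pcb2_candidates)
    return Annotation(
        candidate=cand,
        feature=_feature(cand.mz),
        mass_error_ppm=0.0,
        isotope=IsotopeVerdict(isotope_status),
        matched_fragments=[
            FragmentMatch(m, "-HCl", m) for m in fragments
        ],
    )


def test_confidence_levels(pcb2_candidates):
    with_ms2 = _annotation(pcb2_candidates, [167.05])
    without_ms2 = _annotation(pcb2_candidates, [])
    failed = _annotation(pcb2_candidates, [167.05], isotope_status="fail")
    assert assign_confidence(with_ms2) == 2
    assert assign_confidence(without_ms2) == 3
    assert assign_confidence(failed) is None
    assert assign_confidence(with_ms2, has_standard=True) == 1


def test_untested_isotope_does_not_block_level_2(pcb2_candidates):
    ann = _annotation(pcb2_candidates, [167.05], isotope_status="untested")
    assert assign_confidence(ann) == 2


# ---------------------------------------------------------------------------
# end-to-end screen


def test_empty_feature_list_gives_empty_report(pcb2_candidates):
    report = screen([], [], pcb2_candidates)
    assert report.n_metabolites == 0 and report.classes == []


def test_isomers_counted_by_distinct_retention_time(pcb2_candidates):
    cand_mz = _candidate("3.2", pcb2_candidates).mz
    features = [
        _feature(cand_mz, rt=rt) for rt in (4.09, 4.19, 4.30)
    ]
    report = screen(features, [], pcb2_candidates)
    hits = [m for m in report.metabolites if m.class_id == "3.2"]
    assert len(hits) == 3


def test_same_rt_across_groups_is_one_metabolite(pcb2_candidates):
    cand_mz = _candidate("1.1", pcb2_candidates).mz
    features = [
        _feature(cand_mz, rt=5.43, group="high"),
        _feature(cand_mz, rt=5.43, group="low"),
    ]
    report = screen(features, [], pcb2_candidates)
    hits = [m for m in report.metabolites if m.class_id == "1.1"]
    assert len(hits) == 1
    assert set(hits[0].intensity_by_group) == {"high", "low"}


def test_background_exclusion_by_control_group(pcb2_candidates):
    cand_mz = _candidate("1.1", pcb2_candidates).mz
    features = [
        _feature(cand_mz, rt=5.43, intensity=100.0, group="high"),
        _feature(cand_mz, rt=5.43, intensity=50.0, group="DMSO"),
    ]
    report = screen(features, [], pcb2_candidates)
    assert all(m.class_id != "1.1" for m in report.metabolites)
    assert any(r.reason == "background" for r in report.rejections)


def test_trace_control_signal_is_not_background(pcb2_candidates):
    cand_mz = _candidate("1.1", pcb2_candidates).mz
    features = [
        _feature(cand_mz, rt=5.43, intensity=100.0, group="high"),
        _feature(cand_mz, rt=5.43, intensity=1.0, group="DMSO"),
    ]
    report = screen(features, [], pcb2_candidates)
    assert any(m.class_id == "1.1" for m in report.metabolites)


def test_isotope_failures_are_logged_and_rejected(pcb2_candidates):
    cand_mz = _candidate("1.1", pcb2_candidates).mz
    bad = _feature(cand_mz, cluster=((cand_mz, 100.0), (cand_mz + 2, 90.0)))
    report = screen([bad], [], pcb2_candidates)
    assert report.n_metabolites == 0
    assert any(r.reason == "isotope_fail" for r in report.rejections)


def test_missing_ms2_degrades_to_level_3(pcb2_candidates):
    f = _feature(_candidate("1.2", pcb2_candidates).mz, rt=4.22)
    report = screen([f], [], pcb2_candidates)
    hit = next(m for m in report.metabolites if m.class_id == "1.2")
    assert hit.confidence == 3


def test_config_validation():
    with pytest.raises(ValueError):
        ScreenConfig(window_ppm=0)
    with pytest.raises(ValueError):
        ScreenConfig(frag_tol=-1)
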