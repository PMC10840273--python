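"""Detection rules: BSI confirmation, CVC attribution, RIT, HA classification."""

import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cvcsurv import (
    Admission,
    AlgorithmVariant,
    CvcTipCulture,
    Site,
    SurveillanceConfig,
    VitalKind,
    VitalObservation,
    apply_rit,
    classify_ha,
    confirm_bsi,
    cvc_attribution_dtp,
    cvc_attribution_tip,
    detect_cvc_bsi,
    enumerate_potential_episodes,
    has_bsi_symptoms,
    run_surveillance,
)
from cvcsurv.simulate import CohortSimConfig, generate_cohort
from cvcsurv.surveillance import (
    DTP_MATCH,
    PATHOGEN_BSI,
    TIP_MATCH,
    AnchorKind,
)

from conftest import T0, make_bundle, make_draw

ALG1 = AlgorithmVariant.WITH_SYMPTOMS
ALG2 = AlgorithmVariant.MICROBIOLOGY_ONLY
PATH = "STAPHYLOCOCCUS_AUREUS"
COM = "STAPHYLOCOCCUS_EPIDERMIDIS"
H = dt.timedelta


def _adm(aid="A1", days=10):
    return Admission(aid, f"P_{aid}", T0, T0 + H(days=days))


class TestEnumeration:
    def test_admission_without_draws_counts_once(self, commensals):
        bundle = make_bundle(commensals, [_adm()])
        eps = enumerate_potential_episodes(bundle)
        assert len(eps) == 1
        assert eps[0].anchor is AnchorKind.ADMISSION_WITHOUT_BCX
        assert eps[0].anchor_ts == T0

    def test_one_episode_per_draw(self, commensals):
        draws = [make_draw(commensals, f"D{i}", "A1", T0 + H(hours=i)) for i in range(3)]
        bundle = make_bundle(commensals, [_adm()], draws)
        eps = enumerate_potential_episodes(bundle)
        assert len(eps) == 3
        assert all(e.anchor is AnchorKind.BCX_DRAW for e in eps)


class TestSymptoms:
    @pytest.mark.parametrize(
        "kind,value,offset,expected",
        [
            (VitalKind.TEMPERATURE, 38.5, H(hours=24), True),
            (VitalKind.TEMPERATURE, 38.0, H(0), False),  # strictly greater
            (VitalKind.DBP, 60.0, -H(days=2), True),  # less-or-equal
            (VitalKind.DBP, 61.0, H(0), False),
            (VitalKind.SBP, 85.0, H(days=3), True),  # closed window edge
            (VitalKind.SBP, 85.0, H(days=3, minutes=1), False),  # just outside
            (VitalKind.SBP, 90.0, H(0), False),  # strictly less
            (VitalKind.TEMPERATURE, 39.0, -H(days=3, minutes=1), False),
        ],
    )
    def test_window_and_threshold_boundaries(self, config, kind, value, offset, expected):
        obs = [VitalObservation("A1", T0 + offset, kind, value)]
        assert has_bsi_symptoms(obs, T0, config) is expected


def _fever(ts):
    return VitalObservation("A1", ts, VitalKind.TEMPERATURE, 39.0)


class TestConfirmBsi:
    def test_single_pathogen_draw_suffices_both_variants(self, commensals, config):
        d = make_draw(commensals, "D1", "A1", T0, (PATH,))
        for variant in (ALG1, ALG2):
            conf = confirm_bsi(d, [d], variant, config)
            assert conf.confirmed
            assert PATHOGEN_BSI in conf.evidence

    @pytest.mark.parametrize(
        "gap_h,fever,alg1_ok,alg2_ok",
        [
            (47, True, True, True),
            (47, False, False, True),  # symptom conjunct only under variant 1
            (49, True, False, False),  # outside pair window for both
        ],
    )
    def test_commensal_pair_window_and_symptoms(self, commensals, config, gap_h, fever, alg1_ok, alg2_ok):
        d1 = make_draw(commensals, "D1", "A1", T0, (COM,))
        d2 = make_draw(commensals, "D2", "A1", T0 + H(hours=gap_h), (COM,))
        vitals = [_fever(T0 + H(hours=2))] if fever else []
        assert confirm_bsi(d1, [d1, d2], ALG1, config, vitals).confirmed is alg1_ok
        assert confirm_bsi(d1, [d1, d2], ALG2, config, vitals).confirmed is alg2_ok

    def test_different_commensal_species_never_pair(self, commensals, config):
        d1 = make_draw(commensals, "D1", "A1", T0, (COM,))
        d2 = make_draw(commensals, "D2", "A1", T0 + H(hours=2), ("CUTIBACTERIUM_ACNES",))
        assert not confirm_bsi(d1, [d1, d2], ALG2, config).confirmed

    def test_negative_draw_is_contract_violation(self, commensals, config):
        d = make_draw(commensals, "D1", "A1", T0)
        with pytest.raises(ValueError, match="negative draw"):
            confirm_bsi(d, [d], ALG2, config)


class TestTipAttribution:
    @pytest.mark.parametrize(
        "cfu,offset_h,expected",
        [
            (1000.0, 24, True),  # CFU threshold inclusive
            (500.0, 24, False),
            (10_000.0, -2, False),  # collected before the draw
            (10_000.0, 48, True),  # window upper bound inclusive
            (10_000.0, 48.5, False),
        ],
    )
    def test_cfu_and_window_boundaries(self, commensals, config, cfu, offset_h, expected):
        d = make_draw(commensals, "D1", "A1", T0, (PATH,))
        tip = CvcTipCulture("A1", T0 + H(hours=offset_h), PATH, cfu)
        assert cvc_attribution_tip(d, [tip], config) is expected

    def test_species_must_match(self, commensals, config):
        d = make_draw(commensals, "D1", "A1", T0, (PATH,))
        tip = CvcTipCulture("A1", T0 + H(hours=5), "ESCHERICHIA_COLI", 5000.0)
        assert not cvc_attribution_tip(d, [tip], config)


class TestDtpAttribution:
    def _pair(self, commensals, ttp_c, ttp_p, gap_min=10, code=PATH):
        c = make_draw(commensals, "DC", "A1", T0, (code,), Site.CENTRAL, ttp_c)
        p = make_draw(commensals, "DP", "A1", T0 + H(minutes=gap_min), (code,), Site.PERIPHERAL, ttp_p)
        return c, p

    def test_differential_two_hours_inclusive(self, commensals, config):
        c, p = self._pair(commensals, 10.0, 12.0)
        assert cvc_attribution_dtp(c, [c, p], config)
        assert cvc_attribution_dtp(p, [c, p], config)

    def test_wrong_direction_fails(self, commensals, config):
        c, p = self._pair(commensals, 12.0, 10.0)
        assert not cvc_attribution_dtp(c, [c, p], config)

    def test_draw_gap_over_15_minutes_fails(self, commensals, config):
        c, p = self._pair(commensals, 10.0, 15.0, gap_min=16)
        assert not cvc_attribution_dtp(c, [c, p], config)

    def test_missing_ttp_fails_without_imputation(self, commensals, config):
        c = make_draw(commensals, "DC", "A1", T0, (PATH,), Site.CENTRAL, 10.0)
        p = make_draw(commensals, "DP", "A1", T0 + H(minutes=5), (PATH,), Site.PERIPHERAL, None)
        assert not cvc_attribution_dtp(c, [c, p], config)

    def test_unspecified_site_never_pairs(self, commensals, config):
        c = make_draw(commensals, "DC", "A1", T0, (PATH,), Site.UNSPECIFIED, 10.0)
        p = make_draw(commensals, "DP", "A1", T0 + H(minutes=5), (PATH,), Site.PERIPHERAL, 14.0)
        assert not cvc_attribution_dtp(c, [c, p], config)
        assert not cvc_attribution_dtp(p, [c, p], config)


class TestDetect:
    def test_pathogen_with_tip_composes_evidence(self, commensals):
        d = make_draw(commensals, "D1", "A1", T0 + H(hours=1), (PATH,))
        tip = CvcTipCulture("A1", T0 + H(hours=10), PATH, 5000.0)
        bundle = make_bundle(commensals, [_adm()], [d], [tip])
        labels = detect_cvc_bsi(bundle, ALG2)
        (lab,) = labels
        assert lab.cvc_bsi
        assert PATHOGEN_BSI in lab.evidence and TIP_MATCH in lab.evidence

    def test_confirmed_bsi_without_attribution_is_negative(self, commensals):
        d = make_draw(commensals, "D1", "A1", T0 + H(hours=1), (PATH,))
        bundle = make_bundle(commensals, [_adm()], [d])
        (lab,) = detect_cvc_bsi(bundle, ALG2)
        assert not lab.cvc_bsi
        assert PATHOGEN_BSI in lab.evidence  # evidence trail still records it

    def test_both_attribution_tags_recorded_once(self, commensals):
        c = make_draw(commensals, "DC", "A1", T0 + H(hours=1), (PATH,), Site.CENTRAL, 8.0)
        p = make_draw(commensals, "DP", "A1", T0 + H(hours=1, minutes=5), (PATH,), Site.PERIPHERAL, 12.0)
        tip = CvcTipCulture("A1", T0 + H(hours=6), PATH, 5000.0)
        bundle = make_bundle(commensals, [_adm()], [c, p], [tip])
        lab = next(l for l in detect_cvc_bsi(bundle, ALG2) if l.episode_id == "BCX:DC")
        assert TIP_MATCH in lab.evidence and DTP_MATCH in lab.evidence
        assert lab.cvc_bsi


def _positive_bundle(commensals, day_offsets):
    """One admission; one pathogen+tip positive per offset (days from T0)."""
    adm = Admission("A1", "P1", T0, T0 + H(days=max(day_offsets) + 3))
    draws, tips = [], []
    for i, off in enumerate(day_offsets):
        ts = T0 + H(days=off, hours=1)
        draws.append(make_draw(commensals, f"D{i}", "A1", ts, (PATH,)))
        tips.append(CvcTipCulture("A1", ts + H(hours=2), PATH, 5000.0))
    return make_bundle(commensals, [adm], draws, tips)


class TestRit:
    @pytest.mark.parametrize(
        "offsets,kept",
        [
            ([0, 13], ["D0"]),  # day 13 inside the 14-day window
            ([0, 14], ["D0", "D1"]),  # window expired
            ([0, 10, 20], ["D0", "D2"]),  # anchored on FIRST positive, not rolling
            ([0, 10, 12, 14], ["D0", "D3"]),
        ],
    )
    def test_window_arithmetic(self, commensals, config, offsets, kept):
        bundle = _positive_bundle(commensals, offsets)
        eps = enumerate_potential_episodes(bundle)
        labels = apply_rit(detect_cvc_bsi(bundle, ALG2, config), eps, config)
        got = sorted(l.episode_id for l in labels if l.cvc_bsi)
        assert got == sorted(f"BCX:{d}" for d in kept)
        suppressed = [l for l in labels if l.suppressed_by_rit]
        assert all(l.index_episode_id == "BCX:D0" for l in suppressed)
        assert all(not l.cvc_bsi for l in suppressed)

    def test_idempotent_and_harmless_for_single_positives(self, commensals, config):
        bundle = _positive_bundle(commensals, [0])
        eps = enumerate_potential_episodes(bundle)
        once = apply_rit(detect_cvc_bsi(bundle, ALG2, config), eps, config)
        twice = apply_rit(once, eps, config)
        assert once == twice

    @given(st.lists(st.integers(min_value=0, max_value=40), min_size=1, max_size=8, unique=True))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_matches_explicit_scan_oracle(self, offsets):
        commensals = __import__("cvcsurv").CommensalList.default()
        config = SurveillanceConfig()
        offsets = sorted(offsets)
        bundle = _positive_bundle(commensals, offsets)
        eps = enumerate_potential_episodes(bundle)
        labels = apply_rit(detect_cvc_bsi(bundle, ALG2, config), eps, config)
        # independent replay: first positive opens [d, d+13]; positives inside
        # are absorbed; first positive past the window opens the next episode
        kept, rit_end = [], None
        for i, off in enumerate(offsets):
            if rit_end is None or off > rit_end:
                kept.append(f"BCX:D{i}")
                rit_end = off + 13
        assert sorted(l.episode_id for l in labels if l.cvc_bsi) == kept


class TestHaClassification:
    def test_day_three_onset_is_ha(self, config):
        adm = _adm()
        ha, tags = classify_ha(T0 + H(days=2, hours=3), adm, [adm], config)
        assert ha and tags == ("ha_day3",)

    def test_day_one_without_prior_admission_is_not_ha(self, config):
        adm = _adm()
        ha, _ = classify_ha(T0 + H(hours=5), adm, [adm], config)
        assert not ha

    @pytest.mark.parametrize("gap_h,expected", [(24, True), (48, True), (72, False)])
    def test_readmission_lookback_window(self, config, gap_h, expected):
        adm = _adm()
        prior = Admission("A0", "P_A1", T0 - H(days=20), T0 - H(hours=gap_h))
        ha, tags = classify_ha(T0 + H(days=1, hours=2), adm, [prior, adm], config)
        assert ha is expected
        if expected:
            assert tags == ("ha_readmission",)


class TestRunSurveillance:
    def test_empty_cohort_yields_empty_labels(self, commensals):
        bundle = make_bundle(commensals, [])
        assert run_surveillance(bundle, ALG2) == []

    def test_ha_implies_cvc_bsi(self, edge_cohort):
        bundle, _ = edge_cohort
        for variant in (ALG1, ALG2):
            for lab in run_surveillance(bundle, variant):
                assert not lab.ha or lab.cvc_bsi

    @pytest.mark.parametrize("seed", [0, 3, 11])
    def test_symptom_variant_positives_subset_of_microbiology_only(self, seed):
        bundle, _ = generate_cohort(
            CohortSimConfig(n_admissions=250, seed=seed, symptom_recording_rate=0.5)
        )
        pos1 = {l.episode_id for l in run_surveillance(bundle, ALG1) if l.cvc_bsi}
        pos2 = {l.episode_id for l in run_surveillance(bundle, ALG2) if l.cvc_bsi}
        assert pos1 <= pos2

    def test_tightening_thresholds_never_adds_positives(self, edge_cohort):
        bundle, _ = edge_cohort
        base = {l.episode_id for l in run_surveillance(bundle, ALG2) if l.cvc_bsi}
        tighter = [
            SurveillanceConfig(contaminant_pair_window_hours=24),
            SurveillanceConfig(tip_window_hours=24),
            SurveillanceConfig(symptom_window_days=1),
            SurveillanceConfig(tip_cfu_threshold=10_000),
            SurveillanceConfig(dtp_min_hours=4),
            SurveillanceConfig(paired_draw_max_minutes=5),
        ]
        for cfg in tighter:
            pos = {l.episode_id for l in run_surveillance(bundle, ALG2, cfg) if l.cvc_bsi}
            assert pos <= base, cfg


class TestBruteForceOracle:
    """Exhaustive re-derivation of the pre-RIT labels on small cohorts."""

    @staticmethod
    def _oracle(bundle, variant, config):
        from cvcsurv.ehr_model import OrganismClass, normalise_code

        draws_by_adm = bundle.draws_by_admission()
        vitals = bundle.vitals_by_admission()
        tips = bundle.tips_by_admission()
        expected = {}
        for d in bundle.blood_cultures:
            eid = f"BCX:{d.draw_id}"
            if not d.isolates:
                expected[eid] = False
                continue
            sympt = has_bsi_symptoms(vitals[d.admission_id], d.draw_ts, config)
            qualifying = set()
            for iso in d.isolates:
                code = normalise_code(iso.organism_code)
                if iso.organism_class is OrganismClass.PATHOGEN:
                    qualifying.add(code)
                else:
                    for other in draws_by_adm[d.admission_id]:
                        if other.draw_id == d.draw_id:
                            continue
                        if abs((other.draw_ts - d.draw_ts).total_seconds()) > 48 * 3600:
                            continue
                        if code in other.species() and (
                            variant is ALG2 or sympt
                        ):
                            qualifying.add(code)
            attributed = False
            for tip in tips[d.admission_id]:
                dt_h = (tip.collect_ts - d.draw_ts).total_seconds() / 3600
                if (tip.cfu_per_ml >= 1000 and 0 <= dt_h <= 48
                        and normalise_code(tip.organism_code) in qualifying):
                    attributed = True
            for a in draws_by_adm[d.admission_id]:
                for b in draws_by_adm[d.admission_id]:
                    if a.draw_id >= b.draw_id or d.draw_id not in (a.draw_id, b.draw_id):
                        continue
                    sites = {a.site, b.site}
                    if sites != {Site.CENTRAL, Site.PERIPHERAL}:
                        continue
                    if abs((a.draw_ts - b.draw_ts).total_seconds()) > 15 * 60:
                        continue
                    c, p = (a, b) if a.site is Site.CENTRAL else (b, a)
                    if c.ttp_hours is None or p.ttp_hours is None:
                        continue
                    if p.ttp_hours - c.ttp_hours < 2:
                        continue
                    if qualifying & c.species() & p.species():
                        attributed = True
            expected[eid] = bool(qualifying) and attributed
        for adm_id, ds in draws_by_adm.items():
            if not ds:
                expected[f"ADM:{adm_id}"] = False
        return expected

    @pytest.mark.parametrize("variant", [ALG1, ALG2])
    @pytest.mark.parametrize("seed", [1, 4])
    def test_detect_equals_exhaustive_enumerator(self, config, variant, seed):
        bundle, _ = generate_cohort(
            CohortSimConfig(n_admissions=120, seed=seed, symptom_recording_rate=0.6)
        )
        got = {l.episode_id: l.cvc_bsi for l in detect_cvc_bsi(bundle, variant, config)}
        assert got == self._oracle(bundle, variant, config)

    @pytest.mark.parametrize("variant", [ALG1, ALG2])
    def test_detect_equals_enumerator_on_boundary_fixtures(self, config, variant, edge_cohort):
        bundle, _ = edge_cohort
        got = {l.episode_id: l.cvc_bsi for l in detect_cvc_bsi(bundle, variant, config)}
        assert got == self._oracle(bundle, variant, config)
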