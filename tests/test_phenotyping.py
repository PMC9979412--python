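import itertools
import math

import pandas as pd
import pytest
from hypothesis import given, strategies as st

from sleeplife.phenotyping import (
    DEFAULT_CODELIST,
    CodedEvent,
    CodeEntry,
    CodeList,
    UnknownVocabularyError,
    confusion_matrix,
    extract_disorders,
    extract_disorders_frame,
    score_frame,
    score_sleep,
)

HEALTHY = dict(
    chronotype="definitely_morning",
    sleep_duration=8,
    insomnia="never_rarely",
    snoring="no",
    sleepiness="never_rarely",
)


class TestScoreSleep:
    def test_all_healthy_scores_five(self):
        profile = score_sleep(**HEALTHY)
        assert profile.score == 5
        assert profile.category == "healthy"

    def test_duration_interval_half_open(self):
        # 9 h/day falls outside 7 <= h < 9
        profile = score_sleep(**{**HEALTHY, "sleep_duration": 9})
        assert profile.adequate_duration is False
        assert profile.score == 4
        assert profile.category == "healthy"

    @pytest.mark.parametrize("hours,healthy", [(6, False), (7, True), (8, True), (9, False)])
    def test_duration_boundaries(self, hours, healthy):
        assert score_sleep(**{**HEALTHY, "sleep_duration": hours}).adequate_duration is healthy

    def test_single_healthy_trait_is_poor(self):
        profile = score_sleep(
            chronotype="definitely_evening",
            sleep_duration=5,
            insomnia="usually",
            snoring="yes",
            sleepiness="never_rarely",
        )
        assert profile.score == 1
        assert profile.category == "poor"

    @pytest.mark.parametrize("score,category", [(0, "poor"), (1, "poor"), (2, "intermediate"), (3, "intermediate"), (4, "healthy"), (5, "healthy")])
    def test_category_thresholds(self, score, category):
        unhealthy = dict(
            chronotype="definitely_evening",
            sleep_duration=5,
            insomnia="usually",
            snoring="yes",
            sleepiness="always",
        )
        for combo in itertools.combinations(HEALTHY.keys(), score):
            responses = {**unhealthy, **{k: HEALTHY[k] for k in combo}}
            profile = score_sleep(**responses)
            assert profile.score == score
            assert profile.category == category

    def test_missing_response_unscorable(self):
        profile = score_sleep(**{**HEALTHY, "snoring": None})
        assert not profile.scorable
        assert profile.category == "unscorable"
        assert profile.score is None

    def test_nan_duration_unscorable(self):
        assert not score_sleep(**{**HEALTHY, "sleep_duration": float("nan")}).scorable

    def test_invalid_response_rejected(self):
        with pytest.raises(ValueError, match="chronotype"):
            score_sleep(**{**HEALTHY, "chronotype": "night owl"})

    @given(st.lists(st.booleans(), min_size=5, max_size=5))
    def test_score_depends_only_on_trait_count(self, traits):
        """Permutation invariance: any assignment with k healthy traits scores k."""
        choices = {
            "chronotype": ("definitely_morning", "definitely_evening"),
            "sleep_duration": (8, 5),
            "insomnia": ("never_rarely", "usually"),
            "snoring": ("no", "yes"),
            "sleepiness": ("sometimes", "always"),
        }
        responses = {
            name: choices[name][0] if flag else choices[name][1]
            for name, flag in zip(choices, traits)
        }
        assert score_sleep(**responses).score == sum(traits)

    def test_score_frame_matches_scalar(self):
        df = pd.DataFrame(
            [HEALTHY, {**HEALTHY, "sleep_duration": 9}, {**HEALTHY, "snoring": None},
             dict(chronotype="definitely_evening", sleep_duration=5, insomnia="usually",
                  snoring="yes", sleepiness="always")]
        )
        out = score_frame(df)
        assert out["sleep_score"].tolist()[0] == 5
        assert out["sleep_score"].tolist()[1] == 4
        assert pd.isna(out["sleep_score"].tolist()[2])
        assert out["sleep_category"].tolist() == ["healthy", "healthy", "unscorable", "poor"]


class TestExtractDisorders:
    def test_srbd_code_inside_window(self):
        events = [CodedEvent(1, -1.5, "ICD10", "G47.3")]
        flags = extract_disorders(events, enrollment=0.0)
        assert flags.srbd and flags.any and not flags.insomnia

    def test_event_outside_window_ignored(self):
        events = [CodedEvent(1, -3.0, "ICD10", "G47.0")]
        flags = extract_disorders(events, enrollment=0.0)
        assert not flags.any

    def test_window_closed_at_both_ends(self):
        for offset in (-2.0, 0.0):
            flags = extract_disorders([CodedEvent(1, offset, "ICD10", "G47.0")], enrollment=0.0)
            assert flags.insomnia, f"offset {offset} should be inside the closed window"

    def test_prescription_without_clinical_code_maps_to_other(self):
        events = [CodedEvent(1, -0.5, "BNF", "0401")]
        flags = extract_disorders(events, enrollment=0.0)
        assert flags.other and not flags.insomnia

    def test_prescription_with_clinical_code_adds_nothing(self):
        events = [
            CodedEvent(1, -0.5, "BNF", "0401"),
            CodedEvent(1, -0.4, "ICD10", "G47.0"),
        ]
        flags = extract_disorders(events, enrollment=0.0)
        assert flags.insomnia and not flags.other

    def test_prefix_matching_for_icd(self):
        flags = extract_disorders([CodedEvent(1, -0.1, "ICD10", "G47.33")], enrollment=0.0)
        assert flags.srbd

    def test_exact_matching_for_bnf(self):
        flags = extract_disorders([CodedEvent(1, -0.1, "BNF", "04011")], enrollment=0.0)
        assert not flags.any  # 0401 entry is exact-match

    def test_date_based_window(self):
        import datetime

        enrollment = datetime.date(2008, 6, 1)
        inside = CodedEvent(1, datetime.date(2007, 1, 1), "ICD10", "G47.3")
        outside = CodedEvent(1, datetime.date(2005, 1, 1), "ICD10", "G47.3")
        assert extract_disorders([inside], enrollment).srbd
        assert not extract_disorders([outside], enrollment).any

    def test_unknown_vocabulary_rejected(self):
        with pytest.raises(UnknownVocabularyError):
            CodedEvent(1, -0.5, "SNOMED", "12345")

    def test_empty_codelist_warns_and_flags_nothing(self):
        empty = CodeList({})
        with pytest.warns(UserWarning, match="empty code list"):
            flags = extract_disorders([CodedEvent(1, -0.5, "ICD10", "G47.0")], 0.0, empty)
        assert not flags.any

    def test_monotone_in_events(self):
        base = [CodedEvent(1, -0.5, "ICD10", "G47.0")]
        more = base + [CodedEvent(1, -0.2, "ICD10", "G47.3"), CodedEvent(1, -1.0, "BNF", "0401")]
        f_base = extract_disorders(base, 0.0)
        f_more = extract_disorders(more, 0.0)
        for flag in ("insomnia", "srbd", "other"):
            assert getattr(f_more, flag) >= getattr(f_base, flag)

    def test_evidence_recorded(self):
        ev = CodedEvent(1, -0.5, "ICD10", "G47.0")
        flags = extract_disorders([ev], 0.0)
        assert flags.evidence["insomnia"] == [ev]

    def test_duplicate_code_across_disorders_rejected(self):
        with pytest.raises(ValueError, match="assigned to both"):
            CodeList({
                "insomnia": [CodeEntry("ICD10", "G47.0")],
                "other": [CodeEntry("ICD10", "G47.0")],
            })

    def test_frame_variant_agrees(self):
        participants = pd.DataFrame({"person_id": [0, 1, 2]})
        events = pd.DataFrame(
            {
                "person_id": [0, 1, 2],
                "age_offset": [-1.5, -3.0, -0.5],
                "vocabulary": ["ICD10", "ICD10", "BNF"],
                "code": ["G47.3", "G47.0", "0401"],
            }
        )
        out = extract_disorders_frame(participants, events)
        assert out["dx_srbd"].tolist() == [True, False, False]
        assert out["dx_insomnia"].tolist() == [False, False, False]
        assert out["dx_other"].tolist() == [False, False, True]
        assert out["dx_any"].tolist() == [True, False, True]


class TestConfusionMatrix:
    def test_perfect_agreement(self):
        flags = pd.Series([True, False, True], index=[1, 2, 3])
        m = confusion_matrix(flags, flags.copy())
        assert m["sensitivity"] == m["specificity"] == m["ppv"] == m["npv"] == 1.0

    def test_two_by_two_arithmetic(self):
        # TP=10, FP=5, FN=20, TN=65 -> NPV = 65/85
        self_flag = pd.Series([True] * 15 + [False] * 85)
        dx_flag = pd.Series([True] * 10 + [False] * 5 + [True] * 20 + [False] * 65)
        m = confusion_matrix(self_flag, dx_flag)
        assert (m["tp"], m["fp"], m["fn"], m["tn"]) == (10, 5, 20, 65)
        assert m["n"] == 100
        assert m["npv"] == pytest.approx(65 / 85)
        assert m["sensitivity"] == pytest.approx(10 / 30)
        assert m["ppv"] == pytest.approx(10 / 15)

    def test_degenerate_column_gives_nan_not_zero(self):
        self_flag = pd.Series([False, False, False])
        dx_flag = pd.Series([False, True, False])
        m = confusion_matrix(self_flag, dx_flag)
        assert math.isnan(m["ppv"])
        assert m["npv"] == pytest.approx(2 / 3)

    def test_id_mismatch_rejected(self):
        with pytest.raises(ValueError, match="different id sets"):
            confusion_matrix(
                pd.Series([True], index=[1]), pd.Series([True], index=[2])
            )

    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=50))
    def test_counts_always_sum_to_n(self, pairs):
        sf = pd.Series([a for a, _ in pairs])
        dx = pd.Series([b for _, b in pairs])
        m = confusion_matrix(sf, dx)
        assert m["tp"] + m["fp"] + m["fn"] + m["tn"] == len(pairs)


def test_default_codelist_covers_all_vocabularies():
    vocabs = {e.vocabulary for items in DEFAULT_CODELIST.entries.values() for e in items}
    assert vocabs == {"ICD9", "ICD10", "ReadV2", "CTV3", "BNF"}


def test_codelist_yaml_round_trip(tmp_path):
    path = tmp_path / "codes.yaml"
    DEFAULT_CODELIST.to_yaml(path)
    loaded = CodeList.from_yaml(path)
    assert loaded.entries == DEFAULT_CODELIST.entries
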