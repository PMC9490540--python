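"""The 3-stage rule classifier: per-rule behaviour and oracle equivalence."""

from dataclasses import replace
from datetime import datetime, timezone

import numpy as np
import pytest
from sklearn.base import clone

from medtweet import (
    AccountProfile,
    PhysicianTweetClassifier,
    RuleSet,
    TweetRecord,
    apply_profile_exclusions,
    classify_accounts,
    corpus_to_frame,
    geo_language_filter,
    match_inclusion,
    text_stage_filter,
)
from medtweet.identify import load_specialty_corpus

from ._reference import naive_classify


def account(**kwargs) -> AccountProfile:
    base = dict(
        account_id="A1",
        handle="@someone",
        display_name="Some One",
        bio="",
        verified=False,
        country="US",
    )
    base.update(kwargs)
    return AccountProfile(**base)


def tweet(**kwargs) -> TweetRecord:
    base = dict(
        tweet_id="T1",
        account_id="A1",
        text="hello",
        timestamp=datetime(2019, 6, 1, tzinfo=timezone.utc),
        language="en",
        country="US",
        verified=False,
    )
    base.update(kwargs)
    return TweetRecord(**base)


class TestGeoLanguageFilter:
    def test_all_us_english_is_identity(self):
        tweets = [tweet(tweet_id=f"T{i}") for i in range(5)]
        assert geo_language_filter(tweets) == tweets

    def test_non_us_tweet_removed(self):
        keep = tweet(tweet_id="T1")
        drop_gb = tweet(tweet_id="T2", country="GB")
        drop_es = tweet(tweet_id="T3", language="es")
        assert geo_language_filter([keep, drop_gb, drop_es]) == [keep]

    def test_matches_linear_scan_oracle(self, corpus):
        _, tweets = corpus
        expected = [
            t for t in tweets if t.language == "en" and t.country == "US"
        ]
        assert geo_language_filter(tweets) == expected


class TestMatchInclusion:
    @pytest.mark.parametrize(
        "display_name, bio, expect",
        [
            ("Jane Doe, MD", "", True),
            ("Jane Doe,MD", "", True),
            ("Jane Doe,M.D.", "", True),
            ("John Roe,D.O.", "", True),
            ("MD Zeki", "", False),          # MD stands for Muhammad
            ("Doctor Jones", "", False),     # bare Doctor never included
            ("Jane Doe, md", "", False),     # credentials are case-sensitive
            ("Some One", "I am a physician in Ohio", True),
            ("Some One", "Physician, educator", True),
            ("Some One", "working on my physicianship", False),  # token bound
            ("Some One", "plastic surgery fellow", True),        # specialty
            ("Some One", "loves dogs", False),
        ],
    )
    def test_examples(self, display_name, bio, expect):
        matched, fired = match_inclusion(
            account(display_name=display_name, bio=bio)
        )
        assert matched is expect
        assert bool(fired) is expect  # fired non-empty iff matched

    def test_fired_rule_identifiers_are_stable(self):
        _, fired = match_inclusion(account(display_name="Jane Doe, MD"))
        assert "name_credential:, MD" in fired
        _, fired = match_inclusion(account(bio="ID physician here"))
        assert "bio_incl:physician" in fired


class TestProfileExclusions:
    @pytest.mark.parametrize(
        "handle, bio, expect",
        [
            ("@MDJobs", "", True),                       # jobs in handle
            ("@clean", "physician jobs weekly", True),   # jobs in bio
            ("@clean", "Aspiring Infectious Disease Physician", True),
            ("@clean", "future physician", True),
            ("@clean", "Board-certified cardiologist, physician", False),
            ("@clean", "", False),
        ],
    )
    def test_examples(self, handle, bio, expect):
        excluded, fired = apply_profile_exclusions(
            account(handle=handle, bio=bio)
        )
        assert excluded is expect
        assert bool(fired) is expect


class TestTextStageFilter:
    def test_medical_name_with_jobs_tweet_is_excluded(self):
        goldfish = account(account_id="A1", display_name="Goldfish Medical")
        tweets = [tweet(account_id="A1", text="#jobs opening, apply now")]
        assert text_stage_filter(tweets, [goldfish]) == {"A1"}

    def test_medical_name_without_jobs_tweet_survives(self):
        goldfish = account(account_id="A1", display_name="Goldfish Medical")
        tweets = [tweet(account_id="A1", text="we are hiring")]
        assert text_stage_filter(tweets, [goldfish]) == set()

    def test_jobs_tweet_without_name_term_survives(self):
        plain = account(account_id="A1", display_name="Jane Doe, MD")
        tweets = [tweet(account_id="A1", text="#jobs are scarce")]
        assert text_stage_filter(tweets, [plain]) == set()

    def test_hashtag_match_is_exact_not_prefix(self):
        surgery = account(account_id="A1", display_name="Visage Surgery")
        tweets = [tweet(account_id="A1", text="#jobsearch tips")]
        assert text_stage_filter(tweets, [surgery]) == set()

    def test_matches_double_loop_oracle(self, corpus):
        accounts, tweets = corpus
        name_terms = ("medical", "surgery")
        expected = set()
        for a in accounts:
            has_jobs_tweet = False
            for t in tweets:
                if t.account_id != a.account_id:
                    continue
                from ._reference import hashtags

                if any(tag in ("job", "jobs") for tag in hashtags(t.text)):
                    has_jobs_tweet = True
                    break
            if has_jobs_tweet and any(
                term in a.display_name.lower() for term in name_terms
            ):
                expected.add(a.account_id)
        assert text_stage_filter(tweets, accounts) == expected


class TestClassifyAccounts:
    def test_single_clean_physician(self):
        jane = account(display_name="Jane Doe, MD")
        outcomes = classify_accounts([tweet()], [jane])
        assert len(outcomes) == 1
        assert outcomes[0].final_label == "physician"
        assert outcomes[0].matched_rules

    def test_future_physician_bio_flips_label(self):
        jane = account(display_name="Jane Doe, MD", bio="future physician")
        outcomes = classify_accounts([tweet()], [jane])
        assert outcomes[0].final_label == "non_physician"
        assert outcomes[0].matched_inclusion and outcomes[0].excluded_profile

    def test_account_without_geo_tweet_not_in_funnel(self):
        jane = account(display_name="Jane Doe, MD")
        outcomes = classify_accounts([tweet(country="GB")], [jane])
        assert outcomes == []

    def test_label_composition_invariant(self, corpus):
        accounts, tweets = corpus
        for o in classify_accounts(tweets, accounts):
            expected = (
                o.passed_geo
                and o.matched_inclusion
                and not o.excluded_profile
                and not o.excluded_text_stage
            )
            assert (o.final_label == "physician") is expected

    def test_compositional_oracle(self, corpus):
        """Pipeline output equals applying the three stages independently."""
        accounts, tweets = corpus
        geo = geo_language_filter(tweets)
        by_id = {a.account_id: a for a in accounts}
        text_excluded = text_stage_filter(geo, accounts)
        expected = {}
        for aid in {t.account_id for t in geo}:
            a = by_id[aid]
            label = (
                match_inclusion(a)[0]
                and not apply_profile_exclusions(a)[0]
                and aid not in text_excluded
            )
            expected[aid] = "physician" if label else "non_physician"
        got = {
            o.account_id: o.final_label
            for o in classify_accounts(tweets, accounts)
        }
        assert got == expected

    def test_equals_naive_reference_implementation(self, corpus):
        accounts, tweets = corpus
        expected = naive_classify(accounts, tweets, load_specialty_corpus())
        got = {
            o.account_id: o.final_label
            for o in classify_accounts(tweets, accounts)
        }
        assert got == expected


class TestRuleMonotonicity:
    def test_adding_exclusion_term_never_grows_physician_set(self, corpus):
        accounts, tweets = corpus
        base = RuleSet()
        stricter = replace(
            base, bio_exclusion_terms=base.bio_exclusion_terms + ("parent",)
        )
        phys = lambda rules: {
            o.account_id
            for o in classify_accounts(tweets, accounts, rules)
            if o.final_label == "physician"
        }
        assert phys(stricter) <= phys(base)

    def test_adding_inclusion_term_never_shrinks_matched_set(self, corpus):
        accounts, _ = corpus
        base = RuleSet()
        wider = replace(
            base, bio_inclusion_terms=base.bio_inclusion_terms + ("clinician",)
        )
        matched = lambda rules: {
            a.account_id for a in accounts if match_inclusion(a, rules)[0]
        }
        assert matched(base) <= matched(wider)


class TestRuleSetSerialization:
    def test_round_trip(self, tmp_path):
        rules = RuleSet(bio_exclusion_terms=("aspiring", "future", "retired"))
        path = tmp_path / "rules.txt"
        rules.to_file(path)
        assert RuleSet.from_file(path) == rules

    def test_unknown_section_rejected(self, tmp_path):
        path = tmp_path / "rules.txt"
        path.write_text("[no_such_rule_list]\nterm\n")
        with pytest.raises(ValueError, match="no_such_rule_list"):
            RuleSet.from_file(path)


class TestSklearnEstimator:
    def test_fit_predict_agrees_with_classify_accounts(self, corpus):
        accounts, tweets = corpus
        X = corpus_to_frame(accounts, tweets)
        clf = PhysicianTweetClassifier().fit(X)
        preds = clf.predict(X)
        assert preds.shape == (len(X),)
        expected = {
            o.account_id: o.final_label
            for o in classify_accounts(tweets, accounts)
        }
        for aid, pred in zip(X["account_id"], preds):
            assert pred == expected[aid]

    def test_estimator_contract(self, corpus):
        accounts, tweets = corpus
        X = corpus_to_frame(accounts, tweets).head(50)
        clf = PhysicianTweetClassifier()
        assert "ruleset" in clf.get_params()
        cloned = clone(clf)
        cloned.fit(X)
        assert set(cloned.classes_) == {"physician", "non_physician"}
        assert cloned.n_features_in_ == X.shape[1]

    def test_missing_columns_rejected(self):
        import pandas as pd

        clf = PhysicianTweetClassifier()
        with pytest.raises(ValueError, match="missing required columns"):
            clf.fit(pd.DataFrame({"account_id": ["A1"]}))


class TestPrecisionRecovery:
    def test_precision_is_perfect_without_traps(self):
        from medtweet import GeneratorConfig, generate_corpus

        cfg = GeneratorConfig(n_accounts=300, trap_fractions={}, seed=21)
        accounts, tweets = generate_corpus(cfg)
        truth = {a.account_id: a.true_label == "physician" for a in accounts}
        flagged = {
            o.account_id
            for o in classify_accounts(tweets, accounts)
            if o.final_label == "physician"
        }
        assert flagged and all(truth[aid] for aid in flagged)

    def test_precision_below_one_with_overlapping_traps(self, corpus, truth):
        accounts, tweets = corpus
        flagged = {
            o.account_id
            for o in classify_accounts(tweets, accounts)
            if o.final_label == "physician"
        }
        assert any(not truth[aid] for aid in flagged)
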