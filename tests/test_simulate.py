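"""Synthetic participant simulator: agents, sessions and the full study."""

import numpy as np
import pytest

import searchprime as sp
from searchprime.simulate import (
    DEFAULT_AGENTS,
    AgentParams,
    PrimingParams,
    StudyConfig,
    simulate_anagram_session,
    simulate_delta_t,
    simulate_grid_search,
    simulate_study,
)


class TestGridAgent:
    def test_selects_distinct_tiles_with_matching_payoffs(self, rng, small_pools):
        ls = small_pools["clustered"][0]
        seq = simulate_grid_search(ls, AgentParams(), rng)
        seq.validate_full(80)
        assert all(
            p == ls.payoffs[r, c] for r, c, p in zip(seq.rows, seq.cols, seq.payoffs)
        )

    def test_fully_global_policy_is_uniform_sampling(self, rng, small_pools):
        # with both local probabilities 0 the agent is a uniform
        # without-replacement sampler; mean step ~ closed form 13.33
        agent = AgentParams(0.0, 0.0)
        means = [
            sp.mean_step(simulate_grid_search(small_pools["dispersed"][i % 12], agent, rng))
            for i in range(100)
        ]
        assert np.mean(means) == pytest.approx(13.33, abs=0.25)

    def test_always_local_after_hit_bounds_step(self, rng, small_pools):
        agent = AgentParams(p_local_after_hit=1.0, p_local_after_miss=0.0, local_radius=1)
        for i in range(5):
            seq = simulate_grid_search(small_pools["clustered"][i], agent, rng)
            steps = sp.step_distances(seq)
            after_hit = steps[seq.payoffs[:-1] > 0]
            local = after_hit[after_hit <= 2]  # Chebyshev radius 1 => Manhattan <= 2
            # the local fallback to global fires only when the neighbourhood
            # is exhausted, so the vast majority of after-hit steps are local
            assert len(local) / max(len(after_hit), 1) > 0.9

    def test_calibrated_agents_reproduce_condition_contrast(self, rng, small_pools):
        disp = {}
        contingent = {}
        for cond in ("clustered", "dispersed"):
            vals, hits, misses = [], [], []
            for _ in range(20):
                idx = rng.choice(12, 5, replace=False)
                seqs = [
                    simulate_grid_search(small_pools[cond][i], DEFAULT_AGENTS[cond], rng)
                    for i in idx
                ]
                rec = sp.GridSearchRecord("x", cond, seqs)
                vals.append(sp.participant_dispersion(rec))
                h, m = sp.participant_contingent_means(rec)
                hits.append(h)
                misses.append(m)
            disp[cond] = np.array(vals)
            contingent[cond] = (np.nanmean(hits), np.nanmean(misses))
        # clustered landscapes induce more clustered search, a large effect
        es = sp.cohens_d(disp["clustered"], disp["dispersed"])
        assert disp["clustered"].mean() < disp["dispersed"].mean()
        assert abs(es.d) > 1.0
        # area-restricted search in the clustered arm, win-shift in dispersed
        assert contingent["clustered"][0] < contingent["clustered"][1]
        assert contingent["dispersed"][0] >= contingent["dispersed"][1]


class TestAnagramSessions:
    def test_stops_at_30_correct_words(self, rng):
        for _ in range(20):
            s = simulate_anagram_session("pre", "clustered", PrimingParams(), rng)
            assert s.total_correct <= 30
            assert len(s.visits) <= 14
            if s.total_correct < 30:
                assert len(s.visits) == 14  # ran out of letter-sets

    def test_correct_words_are_valid_for_their_letterset(self, rng):
        sets = sp.generate_lettersets(14, rng)
        s = simulate_anagram_session("pre", "clustered", PrimingParams(), rng, lettersets=sets)
        for v in s.visits:
            allowed = sets[v.letterset_index - 1].letters.lower()
            for w in v.words:
                if w.correct:
                    assert len(w.word) >= 4
                    assert all(w.word.count(ch) <= allowed.count(ch) for ch in w.word)

    def test_visits_are_ordered_without_revisits(self, rng):
        s = simulate_anagram_session("post", "dispersed", PrimingParams(), rng)
        indices = [v.letterset_index for v in s.visits]
        assert indices == sorted(set(indices))
        for prev, nxt in zip(s.visits, s.visits[1:]):
            assert nxt.enter_time >= prev.exit_time

    def test_practice_effect_gives_negative_delta_t_in_both_arms(self, rng):
        p = PrimingParams(practice_effect=0.7, delta=0.0)
        for cond in ("clustered", "dispersed"):
            dts = simulate_delta_t(4000, cond, p, rng)
            assert np.nanmean(dts) < -10.0

    def test_null_delta_means_symmetric_conditions(self, rng):
        p = PrimingParams(delta=0.0)
        a = simulate_delta_t(20_000, "clustered", p, rng)
        b = simulate_delta_t(20_000, "dispersed", p, rng)
        se = np.sqrt(np.nanvar(a) / len(a) + np.nanvar(b) / len(b))
        assert abs(np.nanmean(a) - np.nanmean(b)) < 4 * se

    def test_injected_priming_raises_clustered_delta_t(self, rng):
        p = PrimingParams(delta=0.3)
        a = simulate_delta_t(5000, "clustered", p, rng)
        b = simulate_delta_t(5000, "dispersed", p, rng)
        assert np.nanmean(a) > np.nanmean(b) + 10.0

    def test_vectorized_sampler_agrees_with_session_path(self, rng):
        p = PrimingParams()
        session_dts = []
        for _ in range(1500):
            pre = simulate_anagram_session("pre", "clustered", p, rng, generate_words=False)
            post = simulate_anagram_session("post", "clustered", p, rng, generate_words=False)
            session_dts.append(sp.delta_t(pre, post))
        fast = simulate_delta_t(30_000, "clustered", p, rng)
        se = np.sqrt(np.nanvar(session_dts) / 1500 + np.nanvar(fast) / 30_000)
        assert abs(np.nanmean(session_dts) - np.nanmean(fast)) < 4 * se

    def test_anchor_persistence_lowers_consecutive_similarity(self, rng):
        p = PrimingParams()
        sims = {}
        for name, wp in (
            ("persevering", sp.WordStreamParams(anchor_persistence=0.9)),
            ("chaining", sp.WordStreamParams(anchor_persistence=0.0)),
        ):
            vals = []
            for _ in range(300):
                s = simulate_anagram_session("post", "clustered", p, rng, words=wp)
                vals.append(sp.session_bigram_similarity(s))
            sims[name] = np.nanmean(vals)
        assert sims["persevering"] < sims["chaining"]


class TestStudy:
    def test_fixed_seed_is_byte_identical(self):
        cfg = StudyConfig(n_per_condition=4, seed=99, pool_size=6)
        a, b = simulate_study(cfg), simulate_study(cfg)
        for name in ("participants", "clicks", "anagram"):
            assert getattr(a, name).to_csv(index=False) == getattr(b, name).to_csv(index=False)

    def test_balanced_assignment(self, study_tables):
        counts = study_tables.participants["condition"].value_counts()
        assert counts["clustered"] == counts["dispersed"] == 20

    def test_clean_cohort_has_no_exclusions(self, study_tables):
        _, report = sp.apply_exclusions(study_tables.participants)
        assert report.triggered == {}
        assert report.retained_n == {"clustered": 20, "dispersed": 20}

    def test_low_word_rate_excludes_everyone(self):
        cfg = StudyConfig(n_per_condition=3, seed=5, pool_size=6, p_low_words=1.0)
        tables = simulate_study(cfg)
        retained, report = sp.apply_exclusions(tables.participants)
        assert len(retained) == 0
        assert all("3" in hits for hits in report.triggered.values())

    def test_tables_follow_event_schemas(self, study_tables):
        assert set(study_tables.clicks.columns) == {
            "participant_id", "condition", "grid_index", "trial", "row", "col", "payoff",
        }
        assert study_tables.clicks.groupby(["participant_id", "grid_index"]).size().eq(80).all()
        assert set(study_tables.anagram["event"]) == {"enter", "submit", "exit"}
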