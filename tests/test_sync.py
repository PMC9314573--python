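import numpy as np
import pytest

from mdsync import sync
from mdsync.embedding import DYAD_DEFAULTS, TRIAD_DEFAULTS, EmbeddingParams, calibrate_threshold
from mdsync.preprocess import GroupRecord, IBISeries, assemble_level_inputs
from mdsync.rqa import RecurrenceMeasures
from mdsync.synthetic import SimConfig, generate_triad

from conftest import make_group


def _score(uid, level, phase, lam, mv, xv, rec=2.0, surrogate=False):
    return sync.SyncScore(
        unit_id=uid,
        level=level,
        phase=phase,
        measures=RecurrenceMeasures(rec, lam, mv, xv),
        is_surrogate=surrogate,
    )


class TestGroupLevelSync:
    def test_identical_constant_members_full_recurrence(self):
        vals = np.full(60, 0.8)
        series = {
            (m, p): IBISeries(vals, "g1", m, p)
            for m in (1, 2, 3)
            for p in ("baseline", "task")
        }
        g = GroupRecord("g1", "1", "A", series)
        params = EmbeddingParams(delay=1, dimension=1, radius=1e-9, level="triad")
        assert sync.group_level_sync(g, params, "task").measures.rec_pct == 100.0

    def test_member_order_invariance(self):
        g = make_group()
        reordered = GroupRecord(
            g.group_id,
            g.study,
            g.condition,
            {
                (new, p): g.series[(old, p)]
                for new, old in zip((1, 2, 3), (3, 1, 2))
                for p in ("baseline", "task")
            },
        )
        a = sync.group_level_sync(g, TRIAD_DEFAULTS, "task")
        b = sync.group_level_sync(reordered, TRIAD_DEFAULTS, "task")
        assert a.measures == b.measures


class TestIndividualLevelSync:
    def test_mean_of_two_dyads(self):
        g = make_group()
        scores = {s.unit_id: s for s in sync.individual_level_sync(g, DYAD_DEFAULTS, "task")}
        dyads = {
            pair: sync._run_mdrqa(arr, DYAD_DEFAULTS)
            for pair, arr in assemble_level_inputs(g, "dyad", "task")
        }
        for member in (1, 2, 3):
            own = [m for pair, m in dyads.items() if member in pair]
            expected = np.mean([m.rec_pct for m in own])
            assert scores[f"g1:{member}"].measures.rec_pct == pytest.approx(expected)

    def test_sum_identity_members_vs_dyads(self):
        # each dyad contributes to exactly 2 members, so summed member
        # scores equal 2x the summed dyad scores / ... per measure
        g = make_group()
        scores = sync.individual_level_sync(g, DYAD_DEFAULTS, "task")
        dyads = [
            sync._run_mdrqa(arr, DYAD_DEFAULTS)
            for _, arr in assemble_level_inputs(g, "dyad", "task")
        ]
        member_sum = sum(s.measures.rec_pct for s in scores)
        dyad_sum = sum(m.rec_pct for m in dyads)
        assert member_sum == pytest.approx(dyad_sum)  # (2 * sum) / 2


class TestVerticalSyncComposite:
    def test_two_units_antisymmetric(self):
        scores = [
            _score("a", "group", "task", 10, 2, 3),
            _score("b", "group", "task", 20, 4, 5),
        ]
        out = sync.vertical_sync_composite(scores)
        assert out[0].vertical_sync == pytest.approx(-out[1].vertical_sync)

    def test_unit_at_stratum_mean_is_zero(self):
        scores = [
            _score("a", "group", "task", 10, 2, 3),
            _score("b", "group", "task", 20, 4, 5),
            _score("c", "group", "task", 15, 3, 4),
        ]
        out = sync.vertical_sync_composite(scores)
        assert out[2].vertical_sync == pytest.approx(0.0, abs=1e-12)

    def test_stratum_mean_zero_invariant(self):
        rng = np.random.default_rng(0)
        scores = [
            _score(f"u{i}", "group", phase, *rng.uniform(1, 50, size=3))
            for i in range(10)
            for phase in ("baseline", "task")
        ]
        out = sync.vertical_sync_composite(scores)
        for phase in ("baseline", "task"):
            vals = [s.vertical_sync for s in out if s.phase == phase]
            assert abs(np.mean(vals)) < 1e-10

    def test_collinear_measures_high_correlation_with_constituents(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0, 1, size=40)
        scores = [
            _score(
                f"u{i}", "group", "task",
                lam=10 + 30 * base[i] + rng.normal(0, 1),
                mv=2 + 5 * base[i] + rng.normal(0, 0.2),
                xv=5 + 20 * base[i] + rng.normal(0, 0.8),
            )
            for i in range(40)
        ]
        out = sync.vertical_sync_composite(scores)
        comp = np.array([s.vertical_sync for s in out])
        for attr in ("lam_pct", "mean_v", "max_v"):
            vals = np.array([getattr(s.measures, attr) for s in out])
            assert np.corrcoef(comp, vals)[0, 1] > 0.9

    def test_location_invariance(self):
        rng = np.random.default_rng(2)
        scores = [
            _score(f"u{i}", "group", "task", *rng.uniform(1, 50, size=3))
            for i in range(8)
        ]
        shifted = [
            sync.SyncScore(
                s.unit_id, s.level, s.phase,
                RecurrenceMeasures(
                    s.measures.rec_pct, s.measures.lam_pct + 7.0,
                    s.measures.mean_v, s.measures.max_v,
                ),
            )
            for s in scores
        ]
        a = [s.vertical_sync for s in sync.vertical_sync_composite(scores)]
        b = [s.vertical_sync for s in sync.vertical_sync_composite(shifted)]
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_zero_variance_names_measure(self):
        scores = [_score(f"u{i}", "group", "task", 10 + i, 3.0, i + 1) for i in range(4)]
        with pytest.raises(ValueError, match="mean_v"):
            sync.vertical_sync_composite(scores)

    def test_surrogates_scored_against_real_stats(self):
        scores = [
            _score("a", "group", "task", 10, 2, 3),
            _score("b", "group", "task", 20, 4, 5),
            _score("s1", "group", "task", 15, 3, 4, surrogate=True),
        ]
        out = sync.vertical_sync_composite(scores)
        # surrogate sits exactly at the real-unit mean
        assert out[2].vertical_sync == pytest.approx(0.0, abs=1e-12)


class TestDeltaSync:
    def test_identical_phases_zero(self):
        task = sync.vertical_sync_composite(
            [_score(f"u{i}", "group", "task", 10 * i + 5, i + 1, 2 * i + 2) for i in range(3)]
        )
        base = [
            sync.SyncScore(s.unit_id, s.level, "baseline", s.measures, s.vertical_sync)
            for s in task
        ]
        for d in sync.delta_sync(task, base):
            assert d.delta == 0.0
            assert all(v == 0.0 for v in d.measure_deltas.values())

    def test_simple_subtraction(self):
        t = [_score("u", "group", "task", 1, 1, 1)]
        b = [_score("u", "group", "baseline", 1, 1, 1)]
        t = [sync.SyncScore("u", "group", "task", t[0].measures, 1.2)]
        b = [sync.SyncScore("u", "group", "baseline", b[0].measures, 0.5)]
        (d,) = sync.delta_sync(t, b)
        assert d.delta == pytest.approx(0.7)

    def test_unmatched_units_error(self):
        t = [sync.SyncScore("u1", "group", "task", RecurrenceMeasures(1, 1, 1, 1), 0.0)]
        b = [sync.SyncScore("u2", "group", "baseline", RecurrenceMeasures(1, 1, 1, 1), 0.0)]
        with pytest.raises(ValueError, match="u1.*u2|u2.*u1"):
            sync.delta_sync(t, b)

    def test_coupled_study_positive_rec_delta(self, coupled_groups):
        # raw %REC rises from baseline to task when coupling is on; the
        # radius is calibrated on the study so neither phase saturates
        datasets = [
            arr
            for g in coupled_groups
            for ph in ("baseline", "task")
            for _, arr in assemble_level_inputs(g, "triad", ph)
        ]
        r, _ = calibrate_threshold(datasets, d=2, m=7, r_grid=np.arange(0.005, 1.2, 0.005))
        params = EmbeddingParams(delay=2, dimension=7, radius=r, level="triad")
        scores = sync.vertical_sync_composite(
            sync.score_study(coupled_groups, level="group", params=params)
        )
        deltas = sync.delta_sync(
            [s for s in scores if s.phase == "task"],
            [s for s in scores if s.phase == "baseline"],
        )
        assert np.mean([d.measure_deltas["rec_pct"] for d in deltas]) > 0


class TestFalsePairSurrogates:
    def test_distinct_source_groups(self, coupled_groups):
        rng = np.random.default_rng(0)
        surrogates = sync.false_pair_surrogates(coupled_groups, rng=rng)
        assert len(surrogates) == len(coupled_groups)
        real_ids = {g.group_id for g in coupled_groups}
        for s in surrogates:
            assert s.is_surrogate
            sources = {
                s.member_phase(m, "task").study for m in s.member_ids
            }  # study label overwritten, check via values instead
            # members must come from 3 distinct real groups: values of any
            # two members cannot be identical
            arrays = [s.member_phase(m, "task").values for m in s.member_ids]
            for i in range(3):
                for j in range(i + 1, 3):
                    n = min(len(arrays[i]), len(arrays[j]))
                    assert not np.array_equal(arrays[i][:n], arrays[j][:n])

    def test_fixed_seed_reproducible(self, coupled_groups):
        a = sync.false_pair_surrogates(coupled_groups, rng=np.random.default_rng(7))
        b = sync.false_pair_surrogates(coupled_groups, rng=np.random.default_rng(7))
        for ga, gb in zip(a, b):
            for key in ga.series:
                np.testing.assert_array_equal(ga.series[key].values, gb.series[key].values)

    def test_too_few_groups(self):
        with pytest.raises(ValueError, match=">= 3"):
            sync.false_pair_surrogates([make_group()], rng=np.random.default_rng(0))

    def test_surrogates_less_recurrent_than_real_on_coupled_data(self, coupled_groups):
        datasets = [
            arr
            for g in coupled_groups
            for ph in ("baseline", "task")
            for _, arr in assemble_level_inputs(g, "triad", ph)
        ]
        r, _ = calibrate_threshold(datasets, d=2, m=7, r_grid=np.arange(0.005, 1.2, 0.005))
        params = EmbeddingParams(delay=2, dimension=7, radius=r, level="triad")
        real = sync.score_study(coupled_groups, level="group", phases=("task",), params=params)
        surr_groups = sync.false_pair_surrogates(
            coupled_groups, rng=np.random.default_rng(1)
        )
        surr = sync.score_study(surr_groups, level="group", phases=("task",), params=params)
        assert np.mean([s.measures.rec_pct for s in real]) > np.mean(
            [s.measures.rec_pct for s in surr]
        )


class TestCrossLevelCorrelation:
    def test_individual_and_group_deltas_positively_correlated(self):
        from scipy.stats import spearmanr

        cfg = SimConfig(
            n_groups=30,
            condition_layout=(("1", "A", 30),),
            coupling_task=0.15,
            length_range=(150, 180),
            seed=17,
        )
        groups = [generate_triad(cfg, i) for i in range(30)]
        tri = sync.calibrated_params(groups, level="group")
        dy = sync.calibrated_params(groups, level="individual")
        g_scores = sync.vertical_sync_composite(sync.score_study(groups, "group", params=tri))
        i_scores = sync.vertical_sync_composite(
            sync.score_study(groups, "individual", params=dy)
        )
        g_delta = {
            d.unit_id: d.delta
            for d in sync.delta_sync(
                [s for s in g_scores if s.phase == "task"],
                [s for s in g_scores if s.phase == "baseline"],
            )
        }
        i_delta = {
            d.unit_id: d.delta
            for d in sync.delta_sync(
                [s for s in i_scores if s.phase == "task"],
                [s for s in i_scores if s.phase == "baseline"],
            )
        }
        paired = [(g_delta[uid.rsplit(":", 1)[0]], v) for uid, v in i_delta.items()]
        rho, p = spearmanr(*zip(*paired))
        assert rho > 0
        assert p < 0.05
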