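import numpy as np
import pytest

from nacmap import (
    PreprocessSpec,
    SyntheticConfig,
    generate_cohort,
    generate_motion,
    read_cohort,
    session_exclusion,
    subject_map,
    write_cohort,
)
from nacmap.classification import REGION_CODES
from nacmap.connectivity import _lag1_autocorr_rows


def tiny_config(**kw):
    base = dict(n_per_group={"male": 2, "female": 2}, n_nodes=28, n_volumes=40,
                n_noise_nodes=4, seed=5)
    base.update(kw)
    return SyntheticConfig(**base)


class TestConfigValidation:
    def test_int_count_expands_to_default_groups(self):
        cfg = SyntheticConfig(n_per_group=3)
        assert cfg.n_per_group == {"male": 3, "female": 3}

    @pytest.mark.parametrize(
        "kw",
        [
            {"n_per_group": {"male": 0}},
            {"ar_coef": 1.0},
            {"ar_coef": -0.1},
            {"n_regions": 50, "n_nodes": 20},
            {"noise_std": 0.0},
            {"hub_regions_by_group": {"male": (99,)}},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            tiny_config(**kw)

    def test_regions_partition_nodes(self):
        cfg = SyntheticConfig(n_per_group=1, n_nodes=30, n_regions=14)
        regions = cfg.node_regions()
        assert regions.size == 30
        assert len(np.unique(regions)) == 14  # every region non-empty
        assert list(cfg.atlas().regions) == list(REGION_CODES)


class TestDeterminism:
    def test_same_seed_identical_cohort(self):
        c1 = generate_cohort(tiny_config())
        c2 = generate_cohort(tiny_config())
        for s1, s2 in zip(c1.subjects, c2.subjects):
            assert s1.subject_id == s2.subject_id
            assert s1.digit_ratio == s2.digit_ratio
            assert s1.days_since_menses == s2.days_since_menses
            for r1, r2 in zip(s1.runs, s2.runs):
                np.testing.assert_array_equal(r1.data, r2.data)
            for m1, m2 in zip(s1.motion, s2.motion):
                np.testing.assert_array_equal(m1.params, m2.params)

    def test_different_seed_differs(self):
        c1 = generate_cohort(tiny_config(seed=5))
        c2 = generate_cohort(tiny_config(seed=6))
        assert not np.array_equal(c1.subjects[0].runs[0].data, c2.subjects[0].runs[0].data)


class TestMotion:
    def test_zero_scale_gives_zero_trace(self):
        cfg = tiny_config(motion_scale=0.0)
        trace = generate_motion(cfg, np.random.default_rng(0))
        assert np.all(trace.params == 0)

    def test_spike_triggers_exclusion(self):
        cfg = tiny_config()
        trace = generate_motion(cfg, np.random.default_rng(0), spike_mm=2.5)
        assert session_exclusion(trace, PreprocessSpec())

    def test_reproducible(self):
        cfg = tiny_config()
        t1 = generate_motion(cfg, np.random.default_rng(7))
        t2 = generate_motion(cfg, np.random.default_rng(7))
        np.testing.assert_array_equal(t1.params, t2.params)

    def test_typical_scale_is_not_excluded(self):
        cfg = tiny_config(n_volumes=102)
        rng = np.random.default_rng(1)
        excluded = sum(
            session_exclusion(generate_motion(cfg, rng), PreprocessSpec())
            for _ in range(50)
        )
        assert excluded <= 2  # default motion is well within the limits


class TestSignalStructure:
    def test_noise_autocorrelation_matches_ar_coef(self):
        # loading 0 leaves pure AR(1) node noise
        cfg = SyntheticConfig(
            n_per_group={"male": 2}, n_nodes=60, n_volumes=102, ar_coef=0.3,
            module_loading=0.0, artifact_loading=0.0, n_noise_nodes=0,
            menses_groups=(), seed=8,
        )
        cohort = generate_cohort(cfg)
        acs = []
        for s in cohort.subjects:
            for run in s.runs:
                acs.append(_lag1_autocorr_rows(run.data))
        # pooled over 2 subjects x 3 runs x 60 nodes > 1e4 samples
        assert np.mean(acs) == pytest.approx(0.3, abs=0.05)

    def test_zero_loading_gives_independent_nodes(self):
        cfg = SyntheticConfig(
            n_per_group={"male": 1}, n_nodes=40, n_volumes=102,
            module_loading=0.0, artifact_loading=0.0, n_noise_nodes=0,
            menses_groups=(), seed=9,
        )
        s = generate_cohort(cfg).subjects[0]
        x = np.concatenate([r.data for r in s.runs], axis=1)  # 3 x 102 volumes
        r = np.corrcoef(x)
        iu = np.triu_indices(40, 1)  # 780 pairs
        assert abs(r[iu].mean()) < 0.02

    def test_within_module_correlation_exceeds_between(self):
        cfg = SyntheticConfig(n_per_group={"male": 2}, n_nodes=140, menses_groups=(), seed=10)
        cohort = generate_cohort(cfg)
        regions = cohort.atlas.indices()
        wins = 0
        x = np.concatenate([r.data for r in cohort.subjects[0].runs], axis=1)
        r = np.corrcoef(x)
        np.fill_diagonal(r, np.nan)
        for m in range(14):
            mask = regions == m
            within = np.nanmean(r[np.ix_(mask, mask)])
            between = np.nanmean(r[np.ix_(mask, ~mask)])
            wins += within > between
        # sign test over 14 modules: >= 12 wins gives p < .01
        assert wins >= 12


class TestMetadata:
    def test_digit_ratio_and_menses_marginals(self):
        cfg = SyntheticConfig(n_per_group=60, n_nodes=14, n_volumes=10,
                              n_noise_nodes=0, seed=12)
        cohort = generate_cohort(cfg)
        males = [s for s in cohort.subjects if s.group_label == "male"]
        females = [s for s in cohort.subjects if s.group_label == "female"]
        assert np.mean([s.digit_ratio for s in males]) == pytest.approx(0.938, abs=0.015)
        assert np.mean([s.digit_ratio for s in females]) == pytest.approx(0.951, abs=0.015)
        assert all(s.days_since_menses is None for s in males)
        days = np.array([s.days_since_menses for s in females])
        assert days.min() >= 1
        assert 0 < (days > 28).sum() < 15  # a small "unknown" stratum exists

    def test_truth_records_planted_hubs(self):
        cfg = tiny_config(hub_regions_by_group={"male": (3,)})
        cohort = generate_cohort(cfg)
        assert cohort.truth["hub_regions_by_group"] == {"male": [3]}


class TestCohortIO:
    def test_round_trip(self, tmp_path):
        cfg = tiny_config()
        cohort = generate_cohort(cfg)
        write_cohort(cohort, tmp_path / "c", cfg)
        back = read_cohort(tmp_path / "c")
        assert [s.subject_id for s in back.subjects] == [
            s.subject_id for s in cohort.subjects
        ]
        assert back.atlas.labels == cohort.atlas.labels
        assert back.truth == cohort.truth
        for s1, s2 in zip(cohort.subjects, back.subjects):
            assert s1.days_since_menses == s2.days_since_menses
            np.testing.assert_allclose(s1.runs[1].data, s2.runs[1].data, atol=1e-12)
            np.testing.assert_allclose(s1.motion[0].params, s2.motion[0].params, atol=1e-12)


class TestPlantedHubRecovery:
    def test_planted_region_has_higher_group_gc(self):
        # end-to-end: group A's mean GC in the planted region exceeds group B's
        import warnings

        cfg = SyntheticConfig(
            n_per_group={"A": 8, "B": 8}, n_nodes=140, menses_groups=(),
            hub_regions_by_group={"A": (5,)}, seed=21,
        )
        cohort = generate_cohort(cfg)
        spec = PreprocessSpec()
        gc_a, gc_b = [], []
        regions = cohort.atlas.indices()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for s in cohort.subjects:
                cmap, _ = subject_map(s, spec, 2.58)
                (gc_a if s.group_label == "A" else gc_b).append(cmap.gc[regions == 5].mean())
        assert np.mean(gc_a) > np.mean(gc_b) + 0.5
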