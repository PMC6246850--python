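import itertools

import numpy as np
import pytest
from scipy import stats

from connstim import (
    CohortData,
    FunctionalConnectome,
    OutcomeRecord,
    StimulationProtocol,
    TargetRanking,
    compute_discrimination_auc,
    connectomic_similarity,
    null_target_validation,
    occurrence_summary,
    optimize_strength,
    rank_connectome,
    rank_severity_correlation,
    rank_targets,
    relative_change,
    subsample_cross_validation,
)
from connstim.synthetic import (
    LesionSpec,
    SyntheticCohortSpec,
    generate_healthy_cohort,
    generate_patient_cohort,
    generate_prototype,
    synthetic_parcellation,
)
from conftest import random_admissible_matrix


def brute_force_kendall(x, y):
    """Oracle: exhaustive pair counting (no ties expected)."""
    concordant = discordant = 0
    for (xi, yi), (xj, yj) in itertools.combinations(zip(x, y), 2):
        s = np.sign((xi - xj) * (yi - yj))
        if s > 0:
            concordant += 1
        elif s < 0:
            discordant += 1
    return (concordant - discordant) / len(list(itertools.combinations(range(len(x)), 2)))


class TestConnectomicSimilarity:
    def test_self_similarity(self, connectome_factory):
        c = connectome_factory(5)
        assert connectomic_similarity(c, c) == pytest.approx(1.0)

    def test_anti_correlation(self, connectome_factory):
        c = connectome_factory(5)
        neg = FunctionalConnectome(-c.matrix, c.regions)
        assert connectomic_similarity(c, neg) == pytest.approx(-1.0)

    def test_three_point_hand_pearson(self):
        # upper triangles (1,2,3) vs (1,2,4): r = 3 / sqrt(2 * 14/3) ~ 0.98198
        a = np.array([[0.0, 1, 2], [1, 0, 3], [2, 3, 0.0]])
        b = np.array([[0.0, 1, 2], [1, 0, 4], [2, 4, 0.0]])
        r = connectomic_similarity(FunctionalConnectome(a), FunctionalConnectome(b))
        oracle = stats.pearsonr([1, 2, 3], [1, 2, 4]).statistic
        assert r == pytest.approx(oracle, abs=1e-12)
        assert r == pytest.approx(0.9819805060619659, abs=1e-9)

    def test_diagonal_excluded(self, connectome_factory):
        c = connectome_factory(5)
        other = FunctionalConnectome(
            c.matrix + np.diag(np.arange(5.0)), c.regions
        )
        assert connectomic_similarity(c, other) == pytest.approx(1.0)

    def test_errors(self, connectome_factory):
        c = connectome_factory(5)
        flat = FunctionalConnectome(np.zeros((5, 5)), c.regions)
        with pytest.raises(ValueError, match="zero-variance"):
            connectomic_similarity(c, flat)
        other = connectome_factory(5, regions=tuple("vwxyz"))
        with pytest.raises(ValueError, match="region order"):
            connectomic_similarity(c, other)


class TestRelativeChange:
    def test_no_change(self):
        assert relative_change(0.5, 0.5) == 0.0

    def test_plus_ten_percent(self):
        assert relative_change(0.50, 0.55) == pytest.approx(10.0)

    def test_minus_ten_percent(self):
        assert relative_change(0.50, 0.45) == pytest.approx(-10.0)

    def test_zero_pre_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            relative_change(0.0, 0.5)

    def test_negative_pre_warns(self):
        with pytest.warns(UserWarning, match="inverted"):
            relative_change(-0.5, -0.4)


def _record(pair, s, cc_pre, cc_post, feasible=True):
    rc = (cc_post - cc_pre) / cc_pre * 100.0 if feasible else float("nan")
    return OutcomeRecord("s1", pair, s, cc_pre, cc_post, rc, feasible)


class TestOptimizeStrength:
    def test_argmax(self):
        records = [_record(1, s, 0.5, cc) for s, cc in [(0.5, 0.6), (1.0, 0.5), (1.5, 0.55)]]
        assert optimize_strength(records) == (0.5, pytest.approx(20.0))

    def test_all_equal_tie_breaks_to_identity(self):
        records = [_record(1, s, 0.5, 0.5) for s in (0.5, 0.8, 1.0, 1.3)]
        s, rc = optimize_strength(records)
        assert s == 1.0 and rc == 0.0

    def test_tie_at_equal_distance_prefers_smaller(self):
        records = [_record(1, s, 0.5, 0.5) for s in (0.8, 1.2)]
        assert optimize_strength(records)[0] == 0.8

    def test_infeasible_excluded(self):
        records = [
            _record(1, 0.5, 0.5, 0.9),
            _record(1, 2.0, 0.5, float("nan"), feasible=False),
        ]
        assert optimize_strength(records)[0] == 0.5

    def test_no_feasible_errors(self):
        records = [_record(1, 0.5, 0.5, float("nan"), feasible=False)]
        with pytest.raises(ValueError, match="feasible"):
            optimize_strength(records)

    def test_mixed_targets_rejected(self):
        with pytest.raises(ValueError, match="several targets"):
            optimize_strength([_record(1, 1.0, 0.5, 0.5), _record(2, 1.0, 0.5, 0.5)])


class TestRankTargets:
    def test_single_target(self):
        ranking = rank_targets({3: (1.0, 0.0)})
        assert ranking.entries == ((3, 1.0, 0.0, 1),)

    def test_descending_with_pair_tiebreak(self):
        ranking = rank_targets({2: (0.5, 5.0), 1: (0.7, 5.0), 3: (1.0, 9.0)})
        assert [e[0] for e in sorted(ranking.entries, key=lambda e: e[3])] == [3, 1, 2]

    def test_insertion_order_irrelevant(self):
        optima = {1: (0.5, 2.0), 2: (0.6, 8.0), 3: (0.7, 4.0)}
        r1 = rank_targets(dict(sorted(optima.items())))
        r2 = rank_targets(dict(sorted(optima.items(), reverse=True)))
        assert r1.entries == r2.entries

    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="permutation"):
            TargetRanking("s", ((1, 1.0, 0.0, 1), (2, 1.0, 0.0, 3)))
        with pytest.raises(ValueError, match="non-increasing"):
            TargetRanking("s", ((1, 1.0, 0.0, 1), (2, 1.0, 5.0, 2)))


class TestOccurrenceSummary:
    def _ranking(self, sid, order):
        n = len(order)
        return TargetRanking(
            sid,
            tuple(
                (pid, 1.0, float(n - rank), rank)
                for rank, pid in enumerate(order, start=1)
            ),
        )

    def test_single_subject(self):
        summary = occurrence_summary([self._ranking("a", list(range(1, 11)))])
        assert summary["n_best"].sum() == 1
        assert summary["n_top5"].sum() == 5
        assert summary.loc[summary["target_pair_id"] == 1, "n_best"].item() == 1

    def test_identical_subjects_concentrate(self):
        rankings = [self._ranking(f"s{i}", [4, 2, 1, 3]) for i in range(7)]
        summary = occurrence_summary(rankings)
        assert summary.loc[summary["target_pair_id"] == 4, "n_best"].item() == 7
        assert summary["n_best"].sum() == 7

    def test_column_sums(self):
        rankings = [
            self._ranking("a", [1, 2, 3, 4, 5, 6]),
            self._ranking("b", [6, 5, 4, 3, 2, 1]),
        ]
        summary = occurrence_summary(rankings)
        assert summary["n_best"].sum() == 2
        assert summary["n_top5"].sum() == 10

    def test_mismatched_target_sets(self):
        with pytest.raises(ValueError, match="target set"):
            occurrence_summary(
                [self._ranking("a", [1, 2]), self._ranking("b", [1, 3])]
            )


@pytest.fixture(scope="module")
def lesioned_cohorts():
    """Noiseless cohort with an implanted lesion at pair 3, s0 = 0.5."""
    spec = SyntheticCohortSpec(
        n_regions=12,
        n_healthy=5,
        n_patients=4,
        subject_noise_sd=0.0,
        lesions=(LesionSpec(pair_id=3, strength=0.5, fraction=1.0),),
        seed=99,
    )
    prototype = generate_prototype(spec)
    healthy = generate_healthy_cohort(spec, prototype)
    patients, ledger = generate_patient_cohort(spec, prototype)
    return spec, healthy, patients, ledger


class TestExactRecovery:
    def test_implanted_lesion_recovered(self, lesioned_cohorts):
        spec, healthy, patients, ledger = lesioned_cohorts
        parc = synthetic_parcellation(spec.n_regions)
        grid = tuple(round(0.1 * k, 10) for k in range(1, 31))  # 0.1 ... 3.0
        protocol = StimulationProtocol(grid, parc.pair_ids)
        ref = healthy.connectomes("healthy")[0]  # noiseless: all identical
        sid, _, f_pat = patients.subjects[0]
        ranking, records = rank_connectome(f_pat, ref, parc, protocol, subject_id=sid)
        pair, best_s, best_rc = ranking.best()
        assert pair == 3
        assert best_s == pytest.approx(2.0)
        cc_pre = records[0].cc_pre
        assert best_rc == pytest.approx((1 - cc_pre) / cc_pre * 100, abs=1e-8)

    def test_best_change_nonnegative_with_identity_on_grid(self, lesioned_cohorts):
        spec, healthy, patients, _ = lesioned_cohorts
        parc = synthetic_parcellation(spec.n_regions)
        protocol = StimulationProtocol((0.5, 1.0, 2.0), parc.pair_ids)
        ref = healthy.connectomes("healthy")[0]
        ranking, _ = rank_connectome(patients.subjects[0][2], ref, parc, protocol)
        assert all(entry[2] >= -1e-12 for entry in ranking.entries[:1])


class TestCrossValidation:
    def _cohort(self, spec):
        prototype = generate_prototype(spec)
        healthy = generate_healthy_cohort(spec, prototype)
        patients, _ = generate_patient_cohort(spec, prototype)
        return CohortData(healthy.subjects + patients.subjects)

    def test_full_fraction_single_iteration_reproduces_group_ranking(self):
        spec = SyntheticCohortSpec(
            n_regions=10, n_healthy=3, n_patients=3, subject_noise_sd=0.02,
            lesions=(LesionSpec(2, 0.5, 1.0),), seed=5,
        )
        cohort = self._cohort(spec)
        parc = synthetic_parcellation(10)
        protocol = StimulationProtocol((0.5, 1.0, 1.5, 2.0), parc.pair_ids)
        result = subsample_cross_validation(
            cohort, parc, protocol, n_iter=1, fraction=1.0, seed=0
        )
        assert len(result.rankings) == 1
        assert result.rankings[0].best()[0] == 2

    def test_fixed_seed_bit_identical(self):
        spec = SyntheticCohortSpec(
            n_regions=8, n_healthy=4, n_patients=4, subject_noise_sd=0.05,
            lesions=(LesionSpec(1, 0.6, 1.0),), seed=6,
        )
        cohort = self._cohort(spec)
        parc = synthetic_parcellation(8)
        protocol = StimulationProtocol((0.5, 1.0, 2.0), parc.pair_ids)
        kwargs = dict(n_iter=5, fraction=0.5, seed=123)
        r1 = subsample_cross_validation(cohort, parc, protocol, **kwargs)
        r2 = subsample_cross_validation(cohort, parc, protocol, **kwargs)
        assert r1.occurrence.equals(r2.occurrence)
        assert r1.per_target.equals(r2.per_target)

    def test_planted_target_dominates(self):
        spec = SyntheticCohortSpec(
            n_regions=10, n_healthy=6, n_patients=6, subject_noise_sd=0.01,
            lesions=(LesionSpec(4, 0.5, 1.0),), seed=7,
        )
        cohort = self._cohort(spec)
        parc = synthetic_parcellation(10)
        protocol = StimulationProtocol((0.5, 1.0, 1.5, 2.0), parc.pair_ids)
        result = subsample_cross_validation(
            cohort, parc, protocol, n_iter=20, fraction=0.5, seed=1
        )
        wins = result.occurrence.set_index("target_pair_id")["n_best"]
        assert wins[4] >= 19

    def test_fraction_bounds(self):
        spec = SyntheticCohortSpec(n_regions=8, n_healthy=3, n_patients=3, seed=1)
        cohort = self._cohort(spec)
        parc = synthetic_parcellation(8)
        protocol = StimulationProtocol((1.0,), parc.pair_ids)
        with pytest.raises(ValueError, match="fraction"):
            subsample_cross_validation(
                cohort, parc, protocol, n_iter=1, fraction=1.5, seed=0
            )


class TestNullValidation:
    def test_no_planted_effect(self):
        spec = SyntheticCohortSpec(
            n_regions=10, n_healthy=12, n_patients=0, subject_noise_sd=0.02, seed=3
        )
        healthy = generate_healthy_cohort(spec)
        parc = synthetic_parcellation(10)
        protocol = StimulationProtocol((0.8, 0.9, 1.0, 1.1, 1.2), parc.pair_ids)
        result = null_target_validation(
            healthy, parc, protocol, n_iter=20, fraction=0.5, seed=9
        )
        assert result.per_target["mean_relative_change_pct"].abs().max() < 0.5

    def test_degenerate_fraction_guard(self):
        spec = SyntheticCohortSpec(n_regions=8, n_healthy=6, n_patients=0, seed=2)
        healthy = generate_healthy_cohort(spec)
        parc = synthetic_parcellation(8)
        protocol = StimulationProtocol((1.0,), parc.pair_ids)
        with pytest.raises(ValueError, match="fraction"):
            null_target_validation(
                healthy, parc, protocol, n_iter=1, fraction=1.0, seed=0
            )


class TestRankSeverityCorrelation:
    def _rankings(self, ranks_by_subject, pair=1, n_targets=4):
        rankings = {}
        for sid, rank in ranks_by_subject.items():
            others = [r for r in range(1, n_targets + 1) if r != rank]
            order = {pair: rank}
            rest = [p for p in range(1, n_targets + 1) if p != pair]
            for p, r in zip(rest, others):
                order[p] = r
            entries = tuple(
                (p, 1.0, float(n_targets - order[p]), order[p]) for p in sorted(order)
            )
            rankings[sid] = TargetRanking(sid, entries)
        return rankings

    def test_perfect_concordance(self):
        rankings = self._rankings({"a": 1, "b": 2, "c": 3})
        tau, _ = rank_severity_correlation(
            rankings, {"a": 10.0, "b": 20.0, "c": 30.0}, 1
        )
        assert tau == pytest.approx(1.0)

    def test_perfect_discordance(self):
        rankings = self._rankings({"a": 1, "b": 2, "c": 3})
        tau, _ = rank_severity_correlation(
            rankings, {"a": 30.0, "b": 20.0, "c": 10.0}, 1
        )
        assert tau == pytest.approx(-1.0)

    def test_four_point_example_matches_brute_force(self):
        ranks = [1, 2, 3, 4]
        scores = [12.0, 18.0, 15.0, 30.0]
        oracle = brute_force_kendall(ranks, scores)
        assert oracle == pytest.approx(2 / 3)  # 5 concordant - 1 discordant over 6
        rankings = self._rankings({"a": 1, "b": 2, "c": 3, "d": 4})
        tau, p = rank_severity_correlation(
            rankings, dict(zip("abcd", scores)), 1
        )
        assert tau == pytest.approx(oracle, abs=1e-12)
        assert 0.0 < p <= 1.0

    def test_all_tied_errors(self):
        rankings = self._rankings({"a": 2, "b": 2, "c": 2})
        with pytest.raises(ValueError, match="tied"):
            rank_severity_correlation(rankings, {"a": 1.0, "b": 2.0, "c": 3.0}, 1)

    def test_too_few_subjects(self):
        rankings = self._rankings({"a": 1, "b": 2})
        with pytest.raises(ValueError, match="3 subjects"):
            rank_severity_correlation(rankings, {"a": 1.0, "b": 2.0}, 1)


class TestDiscriminationAUC:
    def test_perfect_separation(self, rng):
        spec = SyntheticCohortSpec(
            n_regions=10, n_healthy=8, n_patients=8, subject_noise_sd=0.01,
            lesions=(LesionSpec(2, 0.3, 1.0),), seed=11,
        )
        prototype = generate_prototype(spec)
        healthy = generate_healthy_cohort(spec, prototype)
        patients, _ = generate_patient_cohort(spec, prototype)
        cohort = CohortData(healthy.subjects + patients.subjects)
        frame, auc = compute_discrimination_auc(cohort)
        sims = frame.set_index("group")["similarity"]
        assert sims.loc["healthy"].min() > sims.loc["patient"].max()
        assert auc == pytest.approx(1.0)

    def test_null_distribution_auc_half(self):
        spec = SyntheticCohortSpec(
            n_regions=10, n_healthy=500, n_patients=0, subject_noise_sd=0.05, seed=21
        )
        healthy = generate_healthy_cohort(spec)
        relabelled = tuple(
            (sid, "patient" if i % 2 else "healthy", c)
            for i, (sid, _, c) in enumerate(healthy.subjects)
        )
        frame, auc = compute_discrimination_auc(CohortData(relabelled))
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_monotone_transform_invariance(self):
        # AUC is a rank statistic: verify against sklearn on the same labels
        from sklearn.metrics import roc_auc_score

        spec = SyntheticCohortSpec(
            n_regions=10, n_healthy=10, n_patients=10, subject_noise_sd=0.05,
            lesions=(LesionSpec(3, 0.6, 1.0),), seed=31,
        )
        prototype = generate_prototype(spec)
        healthy = generate_healthy_cohort(spec, prototype)
        patients, _ = generate_patient_cohort(spec, prototype)
        cohort = CohortData(healthy.subjects + patients.subjects)
        frame, auc = compute_discrimination_auc(cohort)
        labels = (frame["group"] == "healthy").astype(int)
        assert auc == pytest.approx(roc_auc_score(labels, frame["similarity"]))
        transformed = np.exp(3.0 * frame["similarity"])
        assert auc == pytest.approx(roc_auc_score(labels, transformed))

    def test_empty_group_errors(self):
        spec = SyntheticCohortSpec(n_regions=8, n_healthy=3, n_patients=0, seed=1)
        healthy = generate_healthy_cohort(spec)
        with pytest.raises(ValueError, match="nonempty"):
            compute_discrimination_auc(healthy)
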