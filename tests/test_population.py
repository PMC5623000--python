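import numpy as np
import pandas as pd
import pytest

from genofp import (
    CohortModel,
    FingerprintMeta,
    NormalizedFingerprint,
    ParameterMismatchError,
    adjust_to_population,
    build_population,
    classify,
    compute_raw,
    find_related_outliers,
    normalize,
    simulate_cohort,
)


def _nf(values, L=None):
    values = np.asarray(values, dtype=np.float64)
    return NormalizedFingerprint(
        FingerprintMeta("normalized", L or values.shape[1], 20), values
    )


class TestBuildPopulation:
    def test_single_member_population_equals_the_member(self):
        v = np.random.default_rng(0).normal(size=(144, 4))
        pop = build_population({"solo": _nf(v)})
        np.testing.assert_array_equal(pop.values, v)
        assert pop.members == ["solo"]
        assert pop.meta.kind == "population"

    def test_symmetric_members_average_to_zero(self):
        v = np.random.default_rng(1).normal(size=(144, 4))
        pop = build_population({"a": _nf(v), "b": _nf(-v)})
        np.testing.assert_allclose(pop.values, 0, atol=1e-12)

    def test_mixed_parameters_are_rejected(self):
        with pytest.raises(ParameterMismatchError):
            build_population({"a": _nf(np.zeros((144, 20))), "b": _nf(np.zeros((144, 120)))})

    def test_empty_member_list_is_an_error(self):
        with pytest.raises(ValueError):
            build_population({})

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        fps = {f"g{i}": _nf(rng.normal(size=(144, 3))) for i in range(5)}
        forward = build_population(fps)
        backward = build_population(dict(reversed(list(fps.items()))))
        np.testing.assert_allclose(forward.values, backward.values, atol=1e-12)


class TestAdjust:
    def test_adjusting_to_own_singleton_population_zeroes_out(self):
        v = _nf(np.random.default_rng(3).normal(size=(144, 4)))
        pop = build_population({"me": v})
        adj = adjust_to_population(v, pop)
        np.testing.assert_array_equal(adj.values, 0 * v.values)
        assert adj.meta.kind == "adjusted"

    def test_member_mean_of_adjusted_fingerprints_is_zero(self):
        rng = np.random.default_rng(4)
        fps = {f"g{i}": _nf(rng.normal(size=(144, 3))) for i in range(7)}
        pop = build_population(fps)
        mean = np.mean(
            [adjust_to_population(fp, pop).values for fp in fps.values()], axis=0
        )
        np.testing.assert_allclose(mean, 0, atol=1e-9)

    def test_parameter_mismatch_is_rejected(self):
        pop = build_population({"a": _nf(np.zeros((144, 4)))})
        with pytest.raises(ParameterMismatchError):
            adjust_to_population(_nf(np.ones((144, 6))), pop)


def _cohort_fps(model, n, n_pops, divergence, seed):
    genomes, labels = simulate_cohort(model, n, n_pops, divergence, seed=seed)
    fps = {g.id: normalize(compute_raw(g.variant_table())) for g in genomes}
    return fps, dict(zip(fps, labels))


def _loo_accuracy(fps, labels):
    pops = {
        p: build_population({i: fps[i] for i, l in labels.items() if l == p}, name=p)
        for p in sorted(set(labels.values()))
    }
    hits = sum(
        classify(fps[i], pops, ind_id=i, leave_one_out=True)[0][0] == labels[i]
        for i in fps
    )
    return hits / len(fps)


class TestClassify:
    def test_well_separated_populations_classify_perfectly(self):
        model = CohortModel.create(n_chroms=6, n_loci=24000, seed=21)
        fps, labels = _cohort_fps(model, 30, 3, divergence=1.0, seed=22)
        assert _loo_accuracy(fps, labels) == 1.0

    def test_accuracy_degrades_as_divergence_shrinks(self):
        model = CohortModel.create(n_chroms=6, n_loci=24000, seed=21)
        accs = [
            _loo_accuracy(*_cohort_fps(model, 18, 3, div, seed=23))
            for div in (1.0, 0.3, 0.0)
        ]
        assert accs[0] >= accs[1] >= accs[2]

    def test_identical_population_fingerprints_tie_break_by_name(self):
        v = _nf(np.random.default_rng(5).normal(size=(144, 4)))
        pop_b = build_population({"m1": v}, name="b")
        pop_a = build_population({"m2": v}, name="a")
        ranked = classify(v, {"b": pop_b, "a": pop_a})
        assert [name for name, _ in ranked] == ["a", "b"]

    def test_single_candidate_population_is_returned(self):
        v = _nf(np.random.default_rng(6).normal(size=(144, 4)))
        ranked = classify(v, {"only": build_population({"x": v})})
        assert ranked[0][0] == "only"

    def test_leave_one_out_skips_singleton_own_population(self):
        v = _nf(np.random.default_rng(7).normal(size=(144, 4)))
        w = _nf(np.random.default_rng(8).normal(size=(144, 4)))
        pops = {
            "mine": build_population({"me": v}),
            "other": build_population({"x": w}),
        }
        with pytest.warns(UserWarning, match="only member"):
            ranked = classify(v, pops, ind_id="me", leave_one_out=True)
        assert [name for name, _ in ranked] == ["other"]


class TestOutliers:
    def _pairs(self, scores):
        n = len(scores)
        return pd.DataFrame(
            {
                "id_a": [f"a{i}" for i in range(n)],
                "id_b": [f"b{i}" for i in range(n)],
                "score": scores,
            }
        )

    def test_planted_relatives_are_exactly_the_flagged_pairs(self):
        rng = np.random.default_rng(9)
        background = rng.normal(0.0, 0.02, 200)
        planted = np.full(5, 0.6)
        table = self._pairs(np.concatenate([background, planted]))
        result = find_related_outliers(table, fdr=0.05)
        flagged = set(result.loc[result["flagged"], "id_a"])
        assert flagged == {f"a{i}" for i in range(200, 205)}

    def test_zero_mad_is_an_error(self):
        scores = np.full(50, 0.1)
        scores[0] = 0.9
        with pytest.raises(ValueError, match="MAD"):
            find_related_outliers(self._pairs(scores))

    def test_larger_fdr_flags_a_superset(self):
        rng = np.random.default_rng(10)
        scores = np.concatenate([rng.normal(0, 0.02, 150), [0.3, 0.5, 0.08]])
        table = self._pairs(scores)
        strict = find_related_outliers(table, fdr=0.05)
        loose = find_related_outliers(table, fdr=0.5)
        strict_ids = set(strict.loc[strict["flagged"], "id_a"])
        loose_ids = set(loose.loc[loose["flagged"], "id_a"])
        assert strict_ids <= loose_ids

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="10"):
            find_related_outliers(self._pairs(np.zeros(5)))
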