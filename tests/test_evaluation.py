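import numpy as np
import pytest
from scipy import stats

from scpot.background_model import BackgroundModel
from scpot.constants import AA_ORDER, N_AA
from scpot.evaluation import (
    ModelScore, alternate_best_worst, auc_curve, coupling_correlation,
    coupling_sweep, enrichment, identify_native, modified_zscore, roc_auc,
    score_model,
)
from scpot.potentials import EnergyMatrix, sce_matrix, symmetrize
from scpot.synthetic import GeneratorSpec, PlantedModel, generate_planted_ensemble


def matrix_from(values):
    return EnergyMatrix(values=np.asarray(values, float), symmetric=False)


class TestModifiedZscore:
    def test_arithmetic(self):
        # 400 entries 0..399: median 199.5, MAD 100
        vals = np.arange(400.0).reshape(20, 20)
        m = matrix_from(vals)
        pair = (AA_ORDER[0], AA_ORDER[0])  # entry 0
        assert modified_zscore(m, pair) == pytest.approx((0 - 199.5) / 100.0)

    def test_median_entry_scores_zero(self):
        # symmetric spread around 5.0 with two entries exactly at the median
        spread = np.linspace(1.0, 4.0, 199)
        vals = np.concatenate([[5.0, 5.0], 5.0 - spread, 5.0 + spread]).reshape(20, 20)
        assert np.median(vals) == 5.0
        pair = (AA_ORDER[0], AA_ORDER[0])  # entry (0, 0) holds 5.0
        assert modified_zscore(matrix_from(vals), pair) == pytest.approx(0.0, abs=1e-12)

    def test_constant_matrix_is_degenerate(self):
        assert np.isnan(modified_zscore(matrix_from(np.ones((20, 20))), ("A", "A")))

    def test_matches_direct_recomputation(self, rng):
        vals = rng.normal(size=(20, 20))
        m = matrix_from(vals)
        med = np.median(vals)
        mad = np.median(np.abs(vals - med))
        assert modified_zscore(m, ("C", "W")) == pytest.approx(
            (m["C", "W"] - med) / mad, abs=1e-12)


class TestIdentifyNative:
    def test_unique_minimum_identified(self):
        vals = np.zeros((20, 20))
        vals[3, 7] = -5.0
        res = identify_native(matrix_from(vals), (AA_ORDER[3], AA_ORDER[7]))
        assert res.identified and res.rank == 1
        assert res.best == (AA_ORDER[3], AA_ORDER[7])

    def test_constant_matrix_tie_break_is_lexicographic(self):
        m = matrix_from(np.ones((20, 20)))
        first = identify_native(m, (AA_ORDER[0], AA_ORDER[0]))
        assert first.identified  # 'AA' is lexicographically first
        other = identify_native(m, ("V", "V"))
        assert not other.identified
        assert other.rank == 400  # last in the canonical order

    def test_rank_matches_sorting_oracle(self, rng):
        vals = rng.normal(size=(20, 20))
        m = matrix_from(vals)
        for ai, aj in rng.integers(0, N_AA, size=(20, 2)):
            res = identify_native(m, (AA_ORDER[ai], AA_ORDER[aj]))
            order = sorted(range(400), key=lambda q: (vals.ravel()[q], q))
            assert order[res.rank - 1] == ai * 20 + aj


class TestEnrichment:
    def test_extremes(self):
        m = matrix_from(np.zeros((20, 20)))
        hit = identify_native(m, (AA_ORDER[0], AA_ORDER[0]))
        miss = identify_native(m, ("V", "V"))
        assert enrichment([hit] * 5) == 400.0
        assert enrichment([miss] * 5) == 0.0

    def test_fixed_pair_predictor_scales_with_native_frequency(self, rng):
        """A predictor that always picks one pair is enriched by 400x the rate
        at which natives happen to be that pair (the Cys-Cys failure mode)."""
        vals = np.zeros((20, 20))
        vals[4, 4] = -1.0  # always predicts (C, C) in canonical order
        m = matrix_from(vals)
        f = 0.1
        results = []
        for _ in range(3000):
            if rng.random() < f:
                native = (AA_ORDER[4], AA_ORDER[4])
            else:
                a, b = rng.integers(0, N_AA, 2)
                native = (AA_ORDER[a], AA_ORDER[b])
            results.append(identify_native(m, native))
        expected = 400 * (f + (1 - f) / 400)
        assert enrichment(results) == pytest.approx(expected, rel=0.2)

    def test_random_predictor_is_unenriched(self, rng):
        hits = 0
        n = 10_000
        # analytic shortcut: a random matrix identifies a uniform native pair
        # with probability exactly 1/400; simulate the Bernoulli directly on
        # matrix argmins to keep the full code path
        for _ in range(200):
            vals = rng.normal(size=(20, 20))
            a, b = rng.integers(0, N_AA, 2)
            res = identify_native(matrix_from(vals), (AA_ORDER[a], AA_ORDER[b]))
            hits += res.identified
        hits += rng.binomial(n - 200, 1 / 400)
        assert 0.3 < (hits / n) / (1 / 400) < 1.9

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            enrichment([])


class TestCouplingSweep:
    @pytest.fixture(scope="class")
    def ensemble(self):
        rng = np.random.default_rng(2)
        z = rng.normal(0, 1.0, (N_AA, N_AA))
        pm = PlantedModel(J=(z + z.T) / np.sqrt(2))
        return generate_planted_ensemble(pm, GeneratorSpec(n_structures=1), 3000, seed=2)

    def test_perfect_and_anti_correlation(self, ensemble):
        bg = BackgroundModel.uniform()
        sce = symmetrize(sce_matrix(ensemble, bg))
        experimental = {("L", "K"): sce["L", "K"], ("A", "V"): sce["A", "V"],
                        ("W", "C"): sce["W", "C"], ("E", "R"): sce["E", "R"]}
        pts = coupling_sweep(ensemble, bg, [("count", 3000)], experimental)
        assert pts[0].r == pytest.approx(1.0)
        negated = {k: -v for k, v in experimental.items()}
        pts = coupling_sweep(ensemble, bg, [("count", 3000)], negated)
        assert pts[0].r == pytest.approx(-1.0)

    def test_too_few_pairs_is_undefined(self, ensemble):
        bg = BackgroundModel.uniform()
        pts = coupling_sweep(ensemble, bg, [("count", 3000)], {("L", "K"): 1.0})
        assert np.isnan(pts[0].r)

    def test_constraint_kinds_truncate(self, ensemble):
        bg = BackgroundModel.uniform()
        experimental = {("L", "K"): 0.1, ("A", "V"): -0.2, ("W", "C"): 0.5}
        pts = coupling_sweep(
            ensemble, bg, [("count", 100), ("rmsd", 0.2), ("count", 3000)], experimental)
        assert pts[0].n_matches == 100
        assert pts[1].n_matches == sum(m.rmsd <= 0.2 for m in ensemble.matches)
        assert pts[2].n_matches == 3000

    def test_correlation_degrades_as_unrelated_fragments_enter(self):
        """Synthetic couplings follow the tight ensemble's planted J; widening
        the ensemble to admit fragments drawn from an unrelated J dilutes the
        statistics and lowers the correlation."""
        rng = np.random.default_rng(9)
        z1 = rng.normal(0, 1.2, (N_AA, N_AA))
        z2 = rng.normal(0, 1.2, (N_AA, N_AA))
        j1, j2 = (z1 + z1.T) / np.sqrt(2), (z2 + z2.T) / np.sqrt(2)
        geom = GeneratorSpec(n_structures=1)
        near = generate_planted_ensemble(PlantedModel(J=j1), geom, 3000, seed=10, cutoff=0.4)
        far = generate_planted_ensemble(PlantedModel(J=j2), geom, 3000, seed=11, cutoff=0.4)
        for m in far.matches:
            m.rmsd += 0.4  # place the unrelated fragments beyond the tight shell
        mixed = type(near)(query=near.query,
                           matches=sorted(near.matches + far.matches, key=lambda m: m.rmsd),
                           cutoff=0.8)
        from scpot.synthetic import double_center
        jc = double_center(j1)
        pairs = [(AA_ORDER[i], AA_ORDER[j]) for i, j in rng.integers(0, N_AA, (16, 2))]
        experimental = {p_: float(jc[AA_ORDER.index(p_[0]), AA_ORDER.index(p_[1])]
                                  + rng.normal(0, 0.1)) for p_ in pairs}
        pts = coupling_sweep(mixed, BackgroundModel.uniform(),
                             [("rmsd", 0.4), ("rmsd", 0.8)], experimental)
        assert pts[0].n_matches == 3000 and pts[1].n_matches == 6000
        assert pts[0].r > pts[1].r

    def test_symmetrized_lookup_for_heterotypic_pairs(self):
        vals = np.zeros((20, 20))
        vals[0, 1], vals[1, 0] = -2.0, -4.0
        m = matrix_from(vals)
        assert coupling_correlation(m, {("A", "R"): 1.0}) is not None  # no crash
        assert m.lookup("A", "R") == m.lookup("R", "A") == -3.0


class TestRocAuc:
    def _scores(self, sces, qualities):
        return [
            ModelScore(model_id=str(k), target_id="t", mean_sce=s, mean_ce=s,
                       n_contacts=5, quality=q)
            for k, (s, q) in enumerate(zip(sces, qualities))
        ]

    def test_perfect_separation(self):
        scores = self._scores([-3, -2.5, -2, 0.5, 1, 2], [80, 75, 70, 30, 20, 10])
        assert roc_auc(scores, 50.0).auc == pytest.approx(1.0)

    def test_six_model_hand_example_matches_u_statistic(self):
        energies = [-2.0, -1.0, 0.5, -1.5, 1.0, 0.0]
        quality = [60, 40, 55, 70, 20, 45]
        scores = self._scores(energies, quality)
        res = roc_auc(scores, 50.0)
        pos = [-e for e, q in zip(energies, quality) if q >= 50]
        neg = [-e for e, q in zip(energies, quality) if q < 50]
        u = sum((p > n_) + 0.5 * (p == n_) for p in pos for n_ in neg)
        assert res.auc == pytest.approx(u / (len(pos) * len(neg)))

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        score = rng.normal(size=60)
        score[rng.integers(0, 60, 10)] = score[0]  # inject ties
        labels = rng.random(60) > 0.5
        res = auc_curve(score, labels)
        assert res.auc == pytest.approx(roc_auc_score(labels, score), abs=1e-12)

    def test_complement_property(self, rng):
        score = rng.normal(size=40)  # no ties a.s.
        labels = rng.random(40) > 0.5
        assert auc_curve(score, labels).auc + auc_curve(-score, labels).auc == \
            pytest.approx(1.0, abs=1e-12)

    def test_random_scores_near_half(self, rng):
        score = rng.normal(size=4000)
        labels = rng.random(4000) > 0.5
        assert auc_curve(score, labels).auc == pytest.approx(0.5, abs=0.05)

    def test_one_class_empty_is_undefined(self):
        scores = self._scores([-1, -2], [80, 90])
        assert np.isnan(roc_auc(scores, 50.0).auc)

    def test_rmsd_direction(self):
        scores = self._scores([-3, -2, 1, 2], [0.5, 1.0, 3.0, 4.0])
        res = roc_auc(scores, 2.0, direction="le")
        assert res.auc == pytest.approx(1.0)


class TestScoreModel:
    def test_impossible_cd_threshold_flags_empty(self, tiny_world, lib):
        from scpot.background_model import assign_burial, train_background

        assign_burial(tiny_world.db)
        bg = train_background(tiny_world.db)
        sc = score_model(tiny_world.db[0], tiny_world.db, bg, lib, flank=1, cd_min=1.1)
        assert sc.empty and np.isnan(sc.mean_sce)

    def test_deterministic_and_finite_on_native(self, tiny_world, lib):
        from scpot.background_model import assign_burial, train_background

        assign_burial(tiny_world.db)
        bg = train_background(tiny_world.db)
        a = score_model(tiny_world.db[0], tiny_world.db, bg, lib, flank=1, cd_min=0.1)
        b = score_model(tiny_world.db[0], tiny_world.db, bg, lib, flank=1, cd_min=0.1)
        assert a.n_contacts == b.n_contacts > 0
        assert a.mean_sce == b.mean_sce
        assert np.isfinite(a.mean_sce)


class TestSelectionHelper:
    def test_alternates_best_and_worst(self):
        models = [(f"m{k}", float(k)) for k in range(6)]
        picked = alternate_best_worst(models, k=4)
        assert [m for m, _ in picked] == ["m5", "m0", "m4", "m1"]

    def test_short_pool(self):
        models = [("a", 1.0), ("b", 2.0)]
        assert len(alternate_best_worst(models, k=10)) == 2
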