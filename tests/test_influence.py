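"""Gene/pathway influence scores and regulator contrasts."""

import itertools

import numpy as np
import pytest

from hillode import (
    ArgumentError,
    DynamicsMatrix,
    InfluenceScores,
    PerturbationSpec,
    gene_influence_scores,
    init_parameters,
    pathway_scores,
    permutation_test,
    read_gmt,
    regulator_log_fold_change,
    regulator_strength,
)


def _scores(values, gene_ids=None):
    values = np.asarray(values, dtype=float)
    if gene_ids is None:
        gene_ids = tuple(f"g{i}" for i in range(values.size))
    return InfluenceScores(gene_ids, values)


class TestGeneInfluenceScores:
    def test_frozen_dynamics_have_zero_influence(self):
        p = init_parameters(("a", "b", "c"), m=2, seed=0).with_arrays(
            upsilon=-np.ones(3))
        s = gene_influence_scores(p, n_samples=5, times=[0, 1, 2], seed=1)
        np.testing.assert_array_equal(s.scores, np.zeros(3))

    def test_decoupled_decay_has_zero_influence(self):
        # W_combine = 0: every gene decays independently; perturbing j
        # never moves i != j
        p = init_parameters(("a", "b"), m=2, seed=0).with_arrays(
            W_combine=np.zeros((2, 4)), upsilon=np.ones(2))
        s = gene_influence_scores(p, n_samples=5, times=[0, 1], seed=1)
        np.testing.assert_allclose(s.scores, 0.0, atol=1e-6)

    def test_driver_gene_scores_high_and_matches_formula(self):
        """Gene 0 drives gene 1; IS_0 > 0, IS_1 ~ 0, and IS_0 equals a
        direct re-evaluation of the printed formula with the same seed."""
        n = 2
        # linear-ish coupling: dg1/dt depends on g0 through the sums block
        p = init_parameters(("a", "b"), m=2, seed=0).with_arrays(
            W_sums=np.array([[1.0, 0.0], [0.0, 0.0]]),
            b_sums=np.zeros(2),
            W_prods=np.zeros((2, 2)),
            b_prods=np.zeros(2),
            W_combine=np.array([[0.0, 0.0, 0.0, 0.0],
                                [1.0, 0.0, 0.0, 0.0]]),
            upsilon=np.ones(2),
        )
        times = [0.0, 1.0, 2.0]
        spec = PerturbationSpec("shift", 0.25)
        s = gene_influence_scores(p, n_samples=20, times=times, seed=7,
                                  perturbation=spec)
        assert s.scores[0] > 0.01
        assert s.scores[1] < 1e-6

        # independent re-evaluation of the formula
        from hillode.model import SolverSettings, predict_trajectory
        rng = np.random.default_rng(7)
        g0 = rng.uniform(size=(20, n))
        base = predict_trajectory(g0, times, p, SolverSettings()).values
        pert = g0.copy()
        pert[:, 0] = np.clip(pert[:, 0] + 0.25, 0, 1)
        ptraj = predict_trajectory(pert, times, p, SolverSettings()).values
        manual = 0.0
        for k in range(20):
            acc_t = 0.0
            for ti in (1, 2):
                acc_t += np.abs(base[k, ti, 1] - ptraj[k, ti, 1]) / n
            manual += acc_t / len(times)
        manual /= 20
        assert s.scores[0] == pytest.approx(manual, rel=1e-10)

    def test_permutation_equivariance(self):
        """Relabeling genes (with consistently permuted parameters)
        permutes the influence scores."""
        n = 4
        p = init_parameters(tuple(f"g{i}" for i in range(n)), m=3, seed=5)
        perm = np.array([2, 0, 3, 1])
        from hillode.model import ModelParameters
        p2 = ModelParameters(
            gene_ids=tuple(p.gene_ids[i] for i in perm),
            W_sums=p.W_sums[:, perm], b_sums=p.b_sums,
            W_prods=p.W_prods[:, perm], b_prods=p.b_prods,
            W_combine=p.W_combine[perm, :], upsilon=p.upsilon[perm],
        )
        # same underlying initial states: seed draws (S, n) uniforms, so
        # permuting columns of the draw needs identical sampling; use a
        # common sample by fixing the seed and permuting coordinates via
        # gene identity is not possible through the public API -> compare
        # through many samples instead
        a = gene_influence_scores(p, n_samples=400, times=[0, 1], seed=3)
        b = gene_influence_scores(p2, n_samples=400, times=[0, 1], seed=4)
        np.testing.assert_allclose(a.scores[perm], b.scores, atol=0.01)


class TestPathwayScores:
    def test_sum_and_drop_rules(self):
        s = _scores([0.1, 0.2, 0.3])
        db = {"all": {"g0", "g1", "g2"}, "pair": {"g0", "g2"},
              "alien": {"x", "y"}}
        with pytest.warns(UserWarning):
            res = {r.pathway_name: r.ps for r in pathway_scores(s, db)}
        assert res["all"] == pytest.approx(0.6)
        assert res["pair"] == pytest.approx(0.4)
        assert "alien" not in res

    def test_additive_over_disjoint_pathways(self, rng):
        s = _scores(rng.uniform(size=10))
        p1 = {f"g{i}" for i in range(0, 4)}
        p2 = {f"g{i}" for i in range(4, 7)}
        res = {r.pathway_name: r.ps
               for r in pathway_scores(s, {"a": p1, "b": p2, "ab": p1 | p2})}
        assert res["ab"] == pytest.approx(res["a"] + res["b"])


class TestPermutationTest:
    def test_equal_scores_are_degenerate(self):
        s = _scores(np.full(5, 0.2))
        with pytest.warns(UserWarning):
            res = permutation_test(s, {"p": {"g0", "g1"}}, K=50, seed=1)
        assert res[0].p_value == 0.0 and res[0].z is None

    def test_whole_system_pathway_degenerate(self, rng):
        s = _scores(rng.uniform(size=5))
        with pytest.warns(UserWarning):
            res = permutation_test(s, {"p": set(s.gene_ids)}, K=50, seed=1)
        assert res[0].p_value == 0.0 and res[0].z is None

    def test_exhaustive_mode_matches_enumeration_oracle(self, rng):
        """All-permutations p-value equals the fraction computed by an
        independent itertools enumeration."""
        vals = rng.uniform(size=5)
        s = _scores(vals)
        members = [0, 3]
        res = permutation_test(s, {"p": {"g0", "g3"}}, K=1, seed=0,
                               exhaustive=True)[0]
        ps = vals[members].sum()
        null = [sum(vals[list(perm)][members])
                for perm in itertools.permutations(range(5))]
        expect = np.mean([v > ps for v in null])
        assert res.p_value == pytest.approx(expect)
        assert res.K == 120
        assert res.z == pytest.approx((ps - np.mean(null)) / np.std(null))

    def test_smoothed_option_adds_one(self, rng):
        vals = rng.uniform(size=8)
        db = {"p": {"g1", "g2", "g5"}}
        plain = permutation_test(_scores(vals), db, K=200, seed=4)[0]
        smooth = permutation_test(_scores(vals), db, K=200, seed=4,
                                  smoothed=True)[0]
        assert smooth.p_value == pytest.approx(
            (plain.p_value * 200 + 1) / 201)
        assert smooth.p_value > 0

    def test_deterministic_given_seed(self, rng):
        s = _scores(rng.uniform(size=8))
        db = {"p": {"g1", "g2", "g5"}}
        a = permutation_test(s, db, K=200, seed=9)[0]
        b = permutation_test(s, db, K=200, seed=9)[0]
        assert a.p_value == b.p_value and a.z == b.z

    def test_z_invariant_under_positive_scaling(self, rng):
        vals = rng.uniform(size=8)
        db = {"p": {"g1", "g2", "g5"}}
        z1 = permutation_test(_scores(vals), db, K=300, seed=2)[0].z
        z2 = permutation_test(_scores(vals * 7.5), db, K=300, seed=2)[0].z
        assert z1 == pytest.approx(z2)


class TestRegulatorAnalysis:
    def test_strength_is_column_sum(self, rng):
        gene_ids = tuple("abcd")
        D = rng.normal(size=(4, 4))
        s = regulator_strength(DynamicsMatrix(gene_ids, D))
        np.testing.assert_allclose(s, [D[:, j].sum() for j in range(4)])

    def test_single_entry_matrix(self):
        D = np.zeros((3, 3))
        D[1, 0] = 0.7
        s = regulator_strength(DynamicsMatrix(("a", "b", "c"), D))
        np.testing.assert_allclose(s, [0.7, 0.0, 0.0])

    @pytest.mark.parametrize("st, sc, expected", [
        (2.0, 2.0, 0.0),
        (4.0, 1.0, 2.0),
        (0.5, 2.0, -2.0),
    ])
    def test_log_fold_change_identities(self, st, sc, expected):
        cmp_res = regulator_log_fold_change(("a",), np.array([st]),
                                            np.array([sc]))
        assert cmp_res.delta[0] == pytest.approx(expected)

    def test_nonpositive_strengths_flagged_missing(self):
        cmp_res = regulator_log_fold_change(
            ("a", "b"), np.array([1.0, -2.0]), np.array([1.0, 3.0]))
        assert np.isnan(cmp_res.delta[1]) and cmp_res.delta[0] == 0.0

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ArgumentError):
            regulator_log_fold_change(("a",), np.zeros(2), np.zeros(2))


class TestGMT:
    def test_reads_name_description_genes(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("apoptosis\tdesc\tg1\tg2\tg3\n"
                     "cycle\thttp://x\tg2\tg4\n")
        db = read_gmt(p)
        assert db == {"apoptosis": {"g1", "g2", "g3"}, "cycle": {"g2", "g4"}}

    def test_rejects_malformed_and_duplicate_rows(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("lonely\tdesc\n")
        with pytest.raises(ArgumentError):
            read_gmt(p)
        p.write_text("a\td\tg1\na\td\tg2\n")
        with pytest.raises(ArgumentError):
            read_gmt(p)
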