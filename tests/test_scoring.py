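"""Pocket perturbation, mode matching, eigenvalue shifts, and ranking."""

import warnings

import numpy as np
import pytest

from conftest import random_connected_structure, random_structure

from apop.errors import DegenerateVarianceWarning, NoSignalError, PocketResolutionWarning
from apop.gnm import GNMParameters, KirchhoffMatrix, build_kirchhoff, decompose
from apop.pockets import Pocket, PocketSet, parse_pocket_text
from apop.scoring import (
    PerturbationResult,
    ScoringParameters,
    eigenvalue_shift,
    match_modes,
    perturb_pocket,
    run_apop,
    score_pockets,
    top_k_success,
)
from apop.structure_io import ResidueId, StructureModel


def complete_graph_K(n):
    return KirchhoffMatrix(matrix=n * np.eye(n) - np.ones((n, n)))


def path_graph_K(n):
    m = np.zeros((n, n))
    for i in range(n - 1):
        m[i, i + 1] = m[i + 1, i] = -1.0
    np.fill_diagonal(m, 0.0)
    np.fill_diagonal(m, -m.sum(axis=1))
    return KirchhoffMatrix(matrix=m)


class TestPerturbPocket:
    def test_whole_complete_graph_is_uniform_rescale(self):
        k = complete_graph_K(4)
        kp = perturb_pocket(k, [0, 1, 2, 3], ScoringParameters(perturbed_gamma=10.0), 1.0)
        np.testing.assert_array_equal(kp.matrix, 10.0 * k.matrix)

    def test_spring_inserted_between_non_contacting_pair(self):
        # stiffened springs appear regardless of pair distance
        k = path_graph_K(3)
        kp = perturb_pocket(k, [0, 2], ScoringParameters(perturbed_gamma=10.0), 1.0)
        assert kp.matrix[0, 2] == -10.0
        assert kp.matrix[0, 0] == 11.0  # one contact spring + new 10x spring
        assert kp.matrix[1, 1] == 2.0  # untouched node keeps its degree

    def test_rank_one_sum_oracle(self, rng):
        # perturbation equals the original plus sum over pocket pairs of
        # (w_new - w_old) (e_i - e_j)(e_i - e_j)^T
        for _ in range(5):
            model = random_structure(rng, 20, box=18.0)
            k = build_kirchhoff(model)
            pocket = sorted(rng.choice(20, size=5, replace=False).tolist())
            kp = perturb_pocket(k, pocket, ScoringParameters(perturbed_gamma=10.0), 1.0)
            expected = k.matrix.copy()
            for a_i, i in enumerate(pocket):
                for j in pocket[a_i + 1:]:
                    w_old = -k.matrix[i, j]
                    e = np.zeros(20)
                    e[i], e[j] = 1.0, -1.0
                    expected += (10.0 - w_old) * np.outer(e, e)
            np.testing.assert_allclose(kp.matrix, expected, atol=1e-12)

    def test_row_sums_restored_to_zero(self, rng):
        model = random_structure(rng, 15, box=15.0)
        k = build_kirchhoff(model)
        kp = perturb_pocket(k, [0, 3, 7, 11])
        np.testing.assert_allclose(kp.matrix.sum(axis=1), 0.0, atol=1e-12)

    def test_single_node_pocket_rejected(self):
        with pytest.raises(ValueError, match="two nodes"):
            perturb_pocket(path_graph_K(3), [1])


class TestMatchModes:
    def test_null_perturbation_gives_identity_matching(self, rng):
        model = random_structure(rng, 20, box=16.0)
        s = decompose(build_kirchhoff(model))
        m = match_modes(s, s)
        assert m.matched_indices == list(range(min(5, s.n_modes)))
        np.testing.assert_allclose(m.overlaps, 1.0, atol=1e-12)

    def test_degenerate_complete_graph_overlaps_are_unity(self):
        # K4 has a triply degenerate spectrum; a uniform rescale preserves
        # the eigenspace, so subspace-aware overlaps must be 1
        k = complete_graph_K(4)
        s = decompose(k)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sp = decompose(perturb_pocket(k, [0, 1, 2, 3]))
            m = match_modes(s, sp)
        assert sorted(m.matched_indices) == [0, 1, 2]
        np.testing.assert_allclose(m.overlaps, 1.0, atol=1e-9)
        assert m.degenerate

    def test_matched_indices_are_distinct(self, rng):
        for _ in range(10):
            model = random_connected_structure(rng, 25, box=20.0)
            k = build_kirchhoff(model)
            s = decompose(k)
            pocket = sorted(rng.choice(25, size=4, replace=False).tolist())
            sp = decompose(perturb_pocket(k, pocket))
            m = match_modes(s, sp)
            assert len(set(m.matched_indices)) == len(m.matched_indices)

    def test_greedy_agrees_with_hungarian_oracle_mostly(self, rng):
        # optimal linear-sum assignment on the same |overlap| block is the
        # independent oracle; for spatially contiguous pockets (the regime
        # the method operates in) the greedy product path almost always
        # coincides with it, and never changes the mean shift by much
        from scipy.optimize import linear_sum_assignment

        from conftest import nearest_neighbor_pocket, random_chain_structure

        agree = 0
        trials = 50
        for _ in range(trials):
            model = random_chain_structure(rng, 100)
            k = build_kirchhoff(model)
            s = decompose(k)
            pocket = nearest_neighbor_pocket(rng, model.coords, 8)
            sp = decompose(perturb_pocket(k, pocket))
            m = match_modes(s, sp)
            ng = len(m.matched_indices)
            block = np.abs(s.eigenvectors[:, :ng].T @ sp.eigenvectors[:, :15])
            rows, cols = linear_sum_assignment(-block)
            hungarian = [int(c) for c in cols]
            if hungarian == m.matched_indices:
                agree += 1
            shift_greedy = np.mean(
                (sp.eigenvalues[m.matched_indices] - s.eigenvalues[:ng])
                / s.eigenvalues[:ng]
            )
            shift_optimal = np.mean(
                (sp.eigenvalues[hungarian] - s.eigenvalues[:ng]) / s.eigenvalues[:ng]
            )
            assert abs(shift_greedy - shift_optimal) * 100 < 0.5
        assert agree >= 0.95 * trials


class TestEigenvalueShift:
    def test_uniform_rescale_gives_900_percent(self):
        k = complete_graph_K(4)
        s = decompose(k)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sp = decompose(perturb_pocket(k, [0, 1, 2, 3]))
            m = match_modes(s, sp)
        res = eigenvalue_shift(s, sp, m, pocket_id=1, n_resolved=4)
        np.testing.assert_allclose(res.per_mode_shift, 900.0, atol=1e-8)
        assert res.mean_shift == pytest.approx(900.0)

    def test_null_perturbation_gives_zero_shift(self, rng):
        model = random_structure(rng, 20, box=16.0)
        s = decompose(build_kirchhoff(model))
        res = eigenvalue_shift(s, s, match_modes(s, s))
        np.testing.assert_allclose(res.per_mode_shift, 0.0, atol=1e-12)

    def test_path_graph_pocket_matches_dense_oracle(self):
        # 3-node path, pocket {0, 1}: hand-build the perturbed 3x3 matrix and
        # diagonalize it independently
        k = path_graph_K(3)
        s = decompose(k)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sp = decompose(perturb_pocket(k, [0, 1], ScoringParameters(perturbed_gamma=10.0)))
            m = match_modes(s, sp)
        res = eigenvalue_shift(s, sp, m)

        oracle_matrix = np.array(
            [[10.0, -10.0, 0.0], [-10.0, 11.0, -1.0], [0.0, -1.0, 1.0]]
        )
        w = np.linalg.eigvalsh(oracle_matrix)[1:]  # drop the zero mode
        lam = s.eigenvalues
        expected = np.mean((w[m.matched_indices] - lam) / lam * 100.0)
        assert res.mean_shift == pytest.approx(expected, abs=1e-9)


def make_results(shifts):
    return [
        PerturbationResult(
            pocket_id=i + 1,
            n_resolved=3,
            matched_mode_indices=[0],
            per_mode_shift=np.array([s]),
            mean_shift=float(s),
            min_overlap=1.0,
        )
        for i, s in enumerate(shifts)
    ]


def make_pocket_set(densities):
    return PocketSet(
        pockets=[
            Pocket(i + 1, frozenset({ResidueId("A", 3 * i + 1), ResidueId("A", 3 * i + 2)}), d)
            for i, d in enumerate(densities)
        ]
    )


class TestScorePockets:
    def test_two_point_population_z_scores_are_plus_minus_one(self):
        with pytest.warns(DegenerateVarianceWarning):
            ranking = score_pockets(make_results([10.0, 20.0]), make_pocket_set([4.0, 4.0]))
        t = ranking.table.set_index("pocket_id")
        assert t.loc[1, "z_dyn"] == pytest.approx(-1.0)
        assert t.loc[2, "z_dyn"] == pytest.approx(1.0)
        assert t.loc[1, "z_hyd"] == 0.0 and t.loc[2, "z_hyd"] == 0.0
        assert t.loc[1, "score"] == pytest.approx(-0.5)
        assert t.loc[2, "score"] == pytest.approx(0.5)
        assert t.loc[2, "rank"] == 1 and t.loc[1, "rank"] == 2

    def test_equal_weight_combination(self):
        # z_dyn = 1 with z_hyd = 0 must give score 0.5
        with pytest.warns(DegenerateVarianceWarning):
            ranking = score_pockets(make_results([0.0, 2.0]), make_pocket_set([7.0, 7.0]))
        assert ranking.table.set_index("pocket_id").loc[2, "score"] == pytest.approx(0.5)

    def test_matches_straight_line_recomputation(self, rng):
        shifts = rng.uniform(0.0, 50.0, size=10)
        densities = rng.uniform(0.0, 30.0, size=10)
        ranking = score_pockets(make_results(shifts), make_pocket_set(densities))

        # independent spreadsheet-style recomputation
        z1 = (shifts - shifts.mean()) / shifts.std()
        z2 = (densities - densities.mean()) / densities.std()
        s = (z1 + z2) / 2.0
        order = np.argsort(-s)
        expected_rank = {int(order[r]) + 1: r + 1 for r in range(10)}

        t = ranking.table.set_index("pocket_id")
        for pid in range(1, 11):
            assert t.loc[pid, "score"] == pytest.approx(s[pid - 1], abs=1e-8)
            assert t.loc[pid, "rank"] == expected_rank[pid]

    def test_z_columns_have_population_moments(self, rng):
        shifts = rng.uniform(0.0, 50.0, size=12)
        densities = rng.uniform(0.0, 30.0, size=12)
        ranking = score_pockets(make_results(shifts), make_pocket_set(densities))
        for col in ("z_dyn", "z_hyd"):
            v = ranking.table[col].to_numpy()
            assert abs(v.mean()) < 1e-9
            assert abs(v.std(ddof=0) - 1.0) < 1e-9

    def test_constant_columns(self):
        with pytest.warns(DegenerateVarianceWarning):
            ranking = score_pockets(make_results([5.0, 5.0]), make_pocket_set([1.0, 9.0]))
        assert (ranking.table["z_dyn"] == 0.0).all()
        with pytest.raises(NoSignalError):
            score_pockets(make_results([5.0, 5.0]), make_pocket_set([3.0, 3.0]))

    def test_ties_broken_by_z_dyn_then_pocket_id(self):
        # symmetric construction: two pockets with mirrored z-scores tie on score
        ranking = score_pockets(
            make_results([10.0, 20.0]), make_pocket_set([9.0, 3.0])
        )
        t = ranking.table.set_index("pocket_id")
        assert t.loc[1, "score"] == pytest.approx(t.loc[2, "score"])
        assert t.loc[2, "rank"] == 1  # larger z_dyn wins the tie


def demo_inputs(seed=0):
    from apop.fixtures import make_pockets, make_structure, multimer_ring_demo

    spec = multimer_ring_demo(seed=seed)
    model = make_structure(spec)
    pockets = make_pockets(spec, model)
    return model, pockets


class TestRunApop:
    def test_deterministic_ranking_bytes(self):
        model, pockets = demo_inputs()
        a = run_apop(model, pockets).to_csv_text()
        b = run_apop(model, pockets).to_csv_text()
        assert a == b

    def test_central_pocket_ranks_first(self):
        model, pockets = demo_inputs()
        ranking = run_apop(model, pockets)
        assert ranking.rank_of(1) == 1
        # and not because of hydrophobicity: pocket 2 is the most hydrophobic
        t = ranking.table.set_index("pocket_id")
        assert t.loc[2, "hydrophobic_density"] == t["hydrophobic_density"].max()

    def test_null_perturbation_limit_ranks_by_hydrophobicity(self):
        # perturbed gamma equal to base gamma: inserted springs between
        # already-contacting pairs change nothing; here every pocket is a
        # contact clique so all shifts vanish and z_hyd alone ranks
        coords = np.zeros((6, 3))
        coords[:, 0] = np.arange(6) * 3.0
        model = StructureModel(
            [ResidueId("A", i + 1) for i in range(6)], ["ALA"] * 6, coords, "t"
        )
        pockets = parse_pocket_text("1 2.0 A:1 A:2\n2 9.0 A:3 A:4\n3 5.0 A:5 A:6\n")
        with pytest.warns(DegenerateVarianceWarning):
            ranking = run_apop(
                model, pockets,
                GNMParameters(cutoff=10.0, gamma=1.0),
                ScoringParameters(perturbed_gamma=1.0),
            )
        t = ranking.table.set_index("pocket_id")
        np.testing.assert_allclose(t["mean_shift_pct"], 0.0, atol=1e-9)
        assert t.loc[2, "rank"] == 1 and t.loc[3, "rank"] == 2 and t.loc[1, "rank"] == 3

    def test_scale_invariance_of_gamma_pair(self):
        model, pockets = demo_inputs()
        a = run_apop(
            model, pockets, GNMParameters(gamma=1.0), ScoringParameters(perturbed_gamma=10.0)
        )
        b = run_apop(
            model, pockets, GNMParameters(gamma=2.5), ScoringParameters(perturbed_gamma=25.0)
        )
        np.testing.assert_allclose(
            a.table["score"].to_numpy(dtype=float),
            b.table["score"].to_numpy(dtype=float),
            atol=1e-9,
        )
        assert list(a.table["rank"]) == list(b.table["rank"])

    def test_permutation_equivariance(self):
        model, pockets = demo_inputs()
        reversed_set = PocketSet(pockets=list(reversed(pockets.pockets)),
                                 source_kind=pockets.source_kind)
        a = run_apop(model, pockets)
        b = run_apop(model, reversed_set)
        for pid in (1, 2, 3, 4):
            assert a.rank_of(pid) == b.rank_of(pid)
            ta = a.table.set_index("pocket_id")
            tb = b.table.set_index("pocket_id")
            assert ta.loc[pid, "score"] == pytest.approx(tb.loc[pid, "score"], abs=1e-12)

    def test_weyl_monotonicity_on_demo(self):
        # stiffening adds a PSD term: sorted perturbed eigenvalues dominate
        model, pockets = demo_inputs()
        k = build_kirchhoff(model)
        s = decompose(k)
        from apop.pockets import map_pockets_to_nodes

        node_map = map_pockets_to_nodes(pockets, model)
        for pid, nodes in node_map.resolved.items():
            sp = decompose(perturb_pocket(k, nodes))
            n = min(s.n_modes, sp.n_modes)
            assert (sp.eigenvalues[:n] - s.eigenvalues[:n] >= -1e-9).all()

    def test_unscorable_pocket_reported_without_rank(self):
        model, pockets = demo_inputs()
        extra = PocketSet(
            pockets=pockets.pockets
            + [Pocket(9, frozenset({ResidueId("Z", 1), ResidueId("Z", 2)}), 4.0)],
            source_kind="synthetic",
        )
        with pytest.warns(PocketResolutionWarning):
            ranking = run_apop(model, extra)
        row = ranking.table[ranking.table["pocket_id"] == 9]
        assert row["rank"].isna().all() and row["score"].isna().all()
        assert ranking.rank_of(9) is None


class TestTopKSuccess:
    def test_rank_three_counts_as_success(self):
        model, pockets = demo_inputs()
        ranking = run_apop(model, pockets)
        third = int(ranking.table.iloc[2]["pocket_id"])
        assert top_k_success(ranking, {third}, k=3)

    def test_highest_ranking_occurrence_governs(self):
        model, pockets = demo_inputs()
        ranking = run_apop(model, pockets)
        second = int(ranking.table.iloc[1]["pocket_id"])
        last = int(ranking.table.iloc[3]["pocket_id"])
        assert top_k_success(ranking, {second, last}, k=3)

    def test_rank_beyond_k_fails(self):
        model, pockets = demo_inputs()
        ranking = run_apop(model, pockets)
        last = int(ranking.table.iloc[3]["pocket_id"])
        assert not top_k_success(ranking, {last}, k=3)

    def test_absent_pocket_fails_with_warning(self):
        model, pockets = demo_inputs()
        ranking = run_apop(model, pockets)
        with pytest.warns(PocketResolutionWarning):
            assert not top_k_success(ranking, {777}, k=3)
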