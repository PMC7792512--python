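"""Bipartite architecture metrics: connectance, weighted NODF, Barber
modularity, Patefield nulls, robustness."""

import itertools
import subprocess

import numpy as np
import pytest

import habnet as hn
from habnet.bipartite import _barber_q

from conftest import random_matrix, small_spec


def naive_wnodf(w: np.ndarray, variant: str = "totals") -> float:
    """Independent pair-by-pair re-derivation of weighted NODF."""
    w = np.asarray(w)

    def rank_keys(mat):
        totals = mat.sum(axis=1)
        fills = (mat > 0).sum(axis=1)
        if variant == "totals":
            order = sorted(range(len(mat)), key=lambda i: -totals[i])
            rank = totals
        else:
            order = sorted(range(len(mat)), key=lambda i: (-fills[i], -totals[i]))
            rank = fills
        return order, rank, fills

    def axis_pairs(mat):
        order, rank, fills = rank_keys(mat)
        contribs = []
        for a, i in enumerate(order):
            for j in order[a + 1:]:
                if rank[j] < rank[i] and fills[j] > 0:
                    k = sum(1 for x, y in zip(mat[i], mat[j]) if 0 < y < x)
                    contribs.append(100.0 * k / fills[j])
                else:
                    contribs.append(0.0)
        return contribs

    contribs = axis_pairs(w) + axis_pairs(w.T)
    return sum(contribs) / len(contribs)


def net_of(w: np.ndarray) -> hn.BipartiteNetwork:
    w = np.asarray(w)
    return hn.BipartiteNetwork(
        tuple(f"p{i}" for i in range(w.shape[0])),
        tuple(f"s{j}" for j in range(w.shape[1])),
        w,
    )


class TestConnectance:
    def test_full_matrix(self):
        assert hn.connectance(net_of(np.ones((3, 4), dtype=int))) == 1.0

    def test_half_filled(self):
        assert hn.connectance(net_of([[1, 0], [0, 2]])) == 0.5


class TestWeightedNodf:
    def test_checkerboard_is_zero(self):
        assert hn.weighted_nodf(np.array([[1, 0], [0, 1]])) == 0.0

    def test_strictly_nested_decreasing_is_hundred(self):
        assert hn.weighted_nodf(np.array([[3, 2, 1], [2, 1, 0]])) == 100.0

    def test_agrees_with_naive_enumeration(self):
        """Vectorized implementation equals the pair-loop oracle on 200
        random small matrices, for both rank variants."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            w = random_matrix(rng)
            for variant in ("totals", "fill"):
                assert hn.weighted_nodf(w, variant=variant) == pytest.approx(
                    naive_wnodf(w, variant), abs=1e-9
                )

    def test_fill_variant_matches_vegan(self, tmp_path):
        """The fill-ranked variant reproduces vegan::nestednodf(weighted)."""
        rng = np.random.default_rng(42)
        w = random_matrix(rng, max_rows=6, max_cols=6)
        np.savetxt(tmp_path / "m.csv", w, fmt="%d", delimiter=",")
        script = (
            f"m <- as.matrix(read.csv('{tmp_path}/m.csv', header=FALSE));"
            "suppressMessages(library(vegan));"
            "cat(sprintf('%.10f', nestednodf(m, order=TRUE, weighted=TRUE)$statistic[3]))"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        assert hn.weighted_nodf(w, variant="fill") == pytest.approx(
            float(out.stdout.strip()), abs=1e-6
        )

    def test_invariant_under_permutation(self):
        rng = np.random.default_rng(3)
        w = random_matrix(rng, max_rows=6, max_cols=6)
        for _ in range(5):
            pr = rng.permutation(w.shape[0])
            pc = rng.permutation(w.shape[1])
            assert hn.weighted_nodf(w[pr][:, pc]) == pytest.approx(
                hn.weighted_nodf(w)
            )

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            hn.weighted_nodf(np.array([[1, 2, 3]]))


class TestBarberModularity:
    def test_single_module_is_zero(self, bipnet):
        part = hn.Partition(
            {n: 0 for n in bipnet.patch_nodes + bipnet.species_nodes}, 0.0, "hand"
        )
        assert hn.barber_modularity(bipnet, part) == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_blocks_score_half(self):
        net = net_of([[1, 0], [0, 1]])
        part = hn.Partition({"p0": 0, "s0": 0, "p1": 1, "s1": 1}, 0.0, "hand")
        assert hn.barber_modularity(net, part) == pytest.approx(0.5)

    def test_missing_node_rejected(self):
        net = net_of([[1, 0], [0, 1]])
        part = hn.Partition({"p0": 0, "s0": 0, "p1": 1}, 0.0, "hand")
        with pytest.raises(KeyError):
            hn.barber_modularity(net, part)


class TestOptimizeModularity:
    def test_recovers_two_blocks_at_exhaustive_optimum(self):
        """Best-of-restarts matches exhaustive search over all partitions
        of the 4 nodes of a 2-block toy."""
        w = np.array([[1, 0], [0, 1]])
        best = max(
            _barber_q(w, np.array(gr), np.array(gc))
            for gr in itertools.product(range(4), repeat=2)
            for gc in itertools.product(range(4), repeat=2)
        )
        assert best == pytest.approx(0.5)
        part = hn.optimize_modularity(net_of(w), seed=0, n_restarts=10)
        assert part.quality == pytest.approx(best)
        assert part.n_communities == 2

    def test_shuffled_toy_near_null_mean(self):
        """After a margin-preserving shuffle of a block matrix, the
        optimized Q sits inside the null distribution's range."""
        w = np.kron(np.eye(3, dtype=int), np.full((2, 2), 3))
        shuffled = hn.patefield_null(w, 1, seed=4)[0]
        q = hn.optimize_modularity(net_of(shuffled), seed=0, n_restarts=10).quality
        nulls = [
            hn.optimize_modularity(net_of(r), seed=i, n_restarts=10).quality
            for i, r in enumerate(hn.patefield_null(w, 30, seed=5))
        ]
        lo, hi = np.min(nulls), np.max(nulls)
        assert lo - 0.05 <= q <= hi + 0.05

    def test_planted_disconnected_modules_recovered(self):
        """With zero cross-habitat occupancy the matrix is block-diagonal:
        the searched partition never merges blocks (>= one module per
        block, every module inside one block) and scores at least the
        planted block partition, which weighted modularity may refine."""
        spec = small_spec(p_in=1.0, p_out=0.0, n_generalists=0)
        mat, truth = hn.generate_landscape(spec, seed=2)
        net = hn.build_bipartite(mat)
        part = hn.optimize_modularity(net, seed=0, n_restarts=10)
        assert part.n_communities >= 3
        block_of = dict(truth.habitat_of_site)
        block_of.update(
            {s: r.split(":")[1] for s, r in truth.role_of_species.items()}
        )
        module_blocks = {}
        for node, c in part.assignment.items():
            module_blocks.setdefault(c, set()).add(block_of[node])
        assert all(len(blocks) == 1 for blocks in module_blocks.values())
        planted = hn.Partition(
            {n: spec.habitats.index(b) for n, b in block_of.items()}, 0.0, "planted"
        )
        assert part.quality >= hn.barber_modularity(net, planted)

    def test_not_below_habitat_label_partition(self, bipnet):
        """The searched Q is at least the Q of the a-priori habitat
        partition (patches by habitat, species by dominant habitat)."""
        habitats = sorted(set(bipnet.habitat_of.values()))
        hidx = {h: i for i, h in enumerate(habitats)}
        assign = {p: hidx[bipnet.habitat_of[p]] for p in bipnet.patch_nodes}
        pmask = np.array([hidx[bipnet.habitat_of[p]] for p in bipnet.patch_nodes])
        for j, s in enumerate(bipnet.species_nodes):
            per_hab = [
                bipnet.weights[pmask == c, j].sum() for c in range(len(habitats))
            ]
            assign[s] = int(np.argmax(per_hab))
        baseline = hn.barber_modularity(
            bipnet, hn.Partition(assign, 0.0, "habitat-labels")
        )
        part = hn.optimize_modularity(bipnet, seed=0, n_restarts=10)
        assert part.quality >= baseline - 1e-12

    def test_deterministic_given_seed(self, bipnet):
        a = hn.optimize_modularity(bipnet, seed=9, n_restarts=5)
        b = hn.optimize_modularity(bipnet, seed=9, n_restarts=5)
        assert a.assignment == b.assignment
        assert a.quality == b.quality


class TestPatefieldNull:
    def test_margins_conserved_every_replicate(self, bipnet):
        reps = hn.patefield_null(bipnet, 50, seed=1)
        np.testing.assert_array_equal(
            reps.sum(axis=2), np.tile(bipnet.row_strengths, (50, 1))
        )
        np.testing.assert_array_equal(
            reps.sum(axis=1), np.tile(bipnet.col_strengths, (50, 1))
        )

    def test_connectance_varies_while_weight_conserved(self, bipnet):
        reps = hn.patefield_null(bipnet, 20, seed=2)
        fills = [(r > 0).sum() for r in reps]
        assert len(set(fills)) > 1
        assert all(r.sum() == bipnet.total_weight for r in reps)

    def test_two_by_two_configurations_equiprobable(self):
        """Margins (1,1)/(1,1) admit two tables; each ~50% of draws."""
        reps = hn.patefield_null(np.array([[1, 0], [0, 1]]), 10_000, seed=5)
        frac_diag = (reps[:, 0, 0] == 1).mean()
        assert frac_diag == pytest.approx(0.5, abs=0.02)
        assert np.all(reps.sum(axis=2) == 1) and np.all(reps.sum(axis=1) == 1)

    def test_single_cell_matrix_fixed(self):
        reps = hn.patefield_null(np.array([[7]]), 10, seed=0)
        assert np.all(reps == 7)

    def test_non_integer_weights_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            hn.patefield_null(np.array([[0.5, 1.0], [1.0, 0.5]]), 5, seed=0)


class TestZScore:
    def test_zero_when_observed_equals_mean(self):
        ens = hn.NullEnsemble("x", np.array([1.0, 2.0, 3.0]), observed=2.0)
        assert hn.z_score(2.0, ens) == 0.0

    def test_degenerate_null_flagged(self):
        ens = hn.NullEnsemble("x", np.array([2.0, 2.0]), observed=3.0)
        assert ens.degenerate
        assert np.isnan(hn.z_score(3.0, ens))

    def test_nodf_z_strongly_negative_on_landscape(self, bipnet):
        ens = hn.null_ensemble(
            bipnet, hn.weighted_nodf, "wnodf", n_replicates=50, seed=3
        )
        assert ens.z < -2


class TestRobustness:
    def test_hand_trapezoid_toy(self):
        net = net_of([[1, 0], [0, 10]])
        curve, r = hn.robustness(net)
        np.testing.assert_allclose(curve.x, [0, 0.5, 1])
        np.testing.assert_allclose(curve.y, [1, 0.5, 0])
        assert r == pytest.approx(0.5)
        assert curve.removal_order == ("s0", "s1")  # rarest first

    def test_all_species_everywhere_maximal(self):
        net = net_of(np.ones((3, 4), dtype=int))
        curve, r = hn.robustness(net)
        # patches survive until the very last removal
        np.testing.assert_allclose(curve.y[:-1], 1.0)
        assert r == pytest.approx(1 - 1 / (2 * 4))

    def test_curve_endpoints_and_monotonicity(self, bipnet):
        curve, r = hn.robustness(bipnet)
        assert curve.y[0] == 1.0 and curve.y[-1] == 0.0
        assert np.all(np.diff(curve.x) > 0)
        assert np.all(np.diff(curve.y) <= 0)
        assert 0.0 <= r <= 1.0

    def test_explicit_order_overrides_abundance(self):
        net = net_of([[1, 0], [0, 10]])
        curve, r = hn.robustness(net, order=["s1", "s0"])
        assert curve.removal_order == ("s1", "s0")
        assert r == pytest.approx(0.5)


class TestPermutationInvariance:
    def test_metrics_invariant_under_row_col_permutation(self, bipnet):
        rng = np.random.default_rng(0)
        pr = rng.permutation(len(bipnet.patch_nodes))
        pc = rng.permutation(len(bipnet.species_nodes))
        permuted = hn.BipartiteNetwork(
            tuple(bipnet.patch_nodes[i] for i in pr),
            tuple(bipnet.species_nodes[j] for j in pc),
            bipnet.weights[pr][:, pc],
            habitat_of=dict(bipnet.habitat_of),
        )
        assert hn.connectance(permuted) == hn.connectance(bipnet)
        assert hn.weighted_nodf(permuted) == pytest.approx(
            hn.weighted_nodf(bipnet)
        )
        assert hn.robustness(permuted)[1] == pytest.approx(
            hn.robustness(bipnet)[1]
        )
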