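import numpy as np
import pytest

from hposhuffle.coexpression import (
    CmapSignature,
    ExpressionMatrix,
    cluster_modules,
    load_expression,
    module_trait_association,
    pick_beta,
    read_grp,
    soft_adjacency,
    split_up_down,
    tom_similarity,
    write_grp,
)
from hposhuffle.errors import ValidationError


def tom_oracle(a):
    """Direct double-loop topological overlap (u != i, j summation)."""
    n = a.shape[0]
    out = np.eye(n)
    k = a.sum(axis=0) - 1.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            out[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return out


def random_adjacency(rng, n):
    a = rng.uniform(0, 1, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


def block_matrix(n_blocks, block_size, within, between):
    n = n_blocks * block_size
    m = np.full((n, n), between)
    for b in range(n_blocks):
        lo, hi = b * block_size, (b + 1) * block_size
        m[lo:hi, lo:hi] = within
    np.fill_diagonal(m, 1.0)
    return m


class TestSoftAdjacency:
    def test_perfect_correlation_fixed_point(self):
        cor = np.array([[1.0, 1.0], [1.0, 1.0]])
        for beta in (1, 3, 6):
            assert np.allclose(soft_adjacency(cor, beta), 1.0)

    def test_anticorrelation_sign_handling(self):
        cor = np.array([[1.0, -1.0], [-1.0, 1.0]])
        assert soft_adjacency(cor, 6)[0, 1] == pytest.approx(1.0)
        assert soft_adjacency(cor, 6, signed=True)[0, 1] == pytest.approx(0.0)

    def test_formula(self):
        cor = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert soft_adjacency(cor, 2)[0, 1] == pytest.approx(0.25)

    def test_beta_below_one_rejected(self):
        with pytest.raises(ValidationError):
            soft_adjacency(np.eye(2), 0)

    def test_monotone_decreasing_in_beta_below_unit_cor(self):
        rng = np.random.default_rng(2)
        cor = np.clip(random_adjacency(rng, 6) * 0.9, 0, 0.95)
        cor = (cor + cor.T) / 2
        np.fill_diagonal(cor, 1.0)
        prev = soft_adjacency(cor, 1)
        for beta in (2, 4, 8):
            cur = soft_adjacency(cor, beta)
            off = ~np.eye(6, dtype=bool)
            assert np.all(cur[off] <= prev[off] + 1e-12)
            prev = cur


class TestPickBeta:
    def test_single_candidate_returned(self):
        rng = np.random.default_rng(3)
        cor = np.clip(np.corrcoef(rng.normal(size=(30, 20))), -1, 1)
        np.fill_diagonal(cor, 1.0)
        beta, table, _ = pick_beta(cor, candidate_betas=[6])
        assert beta == 6
        assert list(table.beta) == [6]

    def test_fallback_flags_warning_when_target_unreachable(self):
        rng = np.random.default_rng(4)
        cor = np.clip(np.corrcoef(rng.normal(size=(20, 10))), -1, 1)
        np.fill_diagonal(cor, 1.0)
        beta, table, warned = pick_beta(cor, candidate_betas=[1, 2], r2_target=0.9999)
        assert warned
        assert beta == int(table.loc[table.signed_r2.idxmax(), "beta"])

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValidationError):
            pick_beta(np.eye(3), candidate_betas=[])


class TestTom:
    def test_identical_binary_neighbourhoods_give_unit_overlap(self):
        # genes 0 and 1 connected to each other and to the same partners
        a = np.array(
            [
                [1, 1, 1, 0],
                [1, 1, 1, 0],
                [1, 1, 1, 1],
                [0, 0, 1, 1],
            ],
            dtype=float,
        )
        tom = tom_similarity(a)
        assert tom[0, 1] == pytest.approx(1.0)

    def test_empty_network(self):
        tom = tom_similarity(np.eye(3))
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(tom[off], 0.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(3, 9))
            a = random_adjacency(rng, n)
            assert np.allclose(tom_similarity(a), tom_oracle(a), atol=1e-10)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(6)
        tom = tom_similarity(random_adjacency(rng, 12))
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0.0 and tom.max() <= 1.0

    def test_invalid_adjacency_rejected(self):
        with pytest.raises(ValidationError):
            tom_similarity(np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestClusterModules:
    def test_two_planted_blocks_recovered(self):
        tom = block_matrix(2, 6, within=0.9, between=0.1)
        genes = [f"G{i}" for i in range(12)]
        assignment = cluster_modules(tom, genes, min_module_size=3, cut_height=0.5)
        labels = assignment.labels
        assert len(set(labels.values())) == 2
        assert len({labels[f"G{i}"] for i in range(6)}) == 1
        assert len({labels[f"G{i}"] for i in range(6, 12)}) == 1

    def test_no_structure_all_unassigned(self):
        tom = np.eye(10)
        genes = [f"G{i}" for i in range(10)]
        assignment = cluster_modules(tom, genes, min_module_size=3, cut_height=0.5)
        assert set(assignment.labels.values()) == {"unassigned"}

    def test_single_block_single_module(self):
        tom = block_matrix(1, 8, within=0.9, between=0.9)
        assignment = cluster_modules(tom, [f"G{i}" for i in range(8)], 3, 0.5)
        assert set(assignment.labels.values()) == {"M1"}

    def test_invariant_to_gene_order(self):
        tom = block_matrix(2, 5, within=0.85, between=0.05)
        genes = [f"G{i}" for i in range(10)]
        base = cluster_modules(tom, genes, 3, 0.5).labels
        rng = np.random.default_rng(7)
        perm = rng.permutation(10)
        shuffled = cluster_modules(tom[np.ix_(perm, perm)], [genes[i] for i in perm], 3, 0.5).labels
        assert shuffled == base

    def test_min_size_below_two_rejected(self):
        with pytest.raises(ValidationError):
            cluster_modules(np.eye(4), list("abcd"), min_module_size=1, cut_height=0.5)


def make_matrix(values, trait):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        genes=[f"G{i}" for i in range(values.shape[0])],
        samples=[f"S{j}" for j in range(values.shape[1])],
        values=values,
        trait=np.asarray(trait),
    )


class TestModuleTraitAssociation:
    def test_planted_trait_module_detected(self):
        rng = np.random.default_rng(8)
        trait = np.array([1] * 10 + [0] * 10)
        values = np.vstack([trait + rng.normal(0, 1e-3, size=20) for _ in range(5)])
        matrix = make_matrix(values, trait)
        from hposhuffle.coexpression import ModuleAssignment

        assignment = ModuleAssignment(labels={g: "M1" for g in matrix.genes})
        stats = module_trait_association(matrix, assignment).module_stats["M1"]
        assert abs(stats.trait_correlation) > 0.99
        assert stats.p_value < 1e-6
        assert stats.size == 5

    def test_orthogonal_trait_gives_near_zero_correlation(self):
        trait = np.tile([1, 0], 10)
        # period-4 profiles: their dot product with the centered alternating
        # trait cancels exactly within every period
        base = np.tile([1.0, 1.0, -1.0, -1.0], 5)
        values = np.vstack([base * (i + 1) for i in range(4)])
        matrix = make_matrix(values, trait)
        from hposhuffle.coexpression import ModuleAssignment

        assignment = ModuleAssignment(labels={g: "M1" for g in matrix.genes})
        stats = module_trait_association(matrix, assignment).module_stats["M1"]
        assert abs(stats.trait_correlation) < 0.05

    def test_singleton_module_eigengene_is_standardized_row(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=(1, 12))
        trait = np.tile([0, 1], 6)
        matrix = make_matrix(values, trait)
        from hposhuffle.coexpression import ModuleAssignment
        from scipy.stats import pearsonr

        assignment = ModuleAssignment(labels={"G0": "M1"})
        stats = module_trait_association(matrix, assignment).module_stats["M1"]
        z = matrix.standardized()[0]
        assert stats.trait_correlation == pytest.approx(pearsonr(z, trait)[0])


class TestSplitUpDown:
    def test_sign_rule_and_zero_drop(self):
        trait = np.array([1, 1, 0, 0])
        values = np.array(
            [
                [2.0, 2.0, 0.0, 0.1],   # up in cases
                [0.0, 0.1, 2.0, 2.0],   # down in cases
                [1.0, 2.0, 1.0, 2.0],   # identical means -> dropped
            ]
        )
        matrix = make_matrix(values, trait)
        from hposhuffle.coexpression import ModuleAssignment

        assignment = ModuleAssignment(labels={g: "M1" for g in matrix.genes})
        sig = split_up_down(matrix, assignment, ["M1"])
        assert sig.up == {"G0"} and sig.down == {"G1"}

    def test_unknown_module_rejected(self):
        trait = np.array([1, 0])
        matrix = make_matrix([[1.0, 2.0]], trait)
        from hposhuffle.coexpression import ModuleAssignment

        assignment = ModuleAssignment(labels={"G0": "M1"})
        with pytest.raises(ValidationError):
            split_up_down(matrix, assignment, ["M9"])


class TestGrpExport:
    def test_sorted_uppercase_lines(self, tmp_path):
        sig = CmapSignature(up=frozenset({"b", "A"}), down=frozenset({"c"}))
        up, down = tmp_path / "up.grp", tmp_path / "down.grp"
        write_grp(sig, up, down)
        assert up.read_text() == "A\nB\n"
        assert down.read_text() == "C\n"

    def test_round_trip(self, tmp_path):
        sig = CmapSignature(up=frozenset({"X", "Y"}), down=frozenset({"Z"}))
        up, down = tmp_path / "u.grp", tmp_path / "d.grp"
        write_grp(sig, up, down)
        assert read_grp(up) == set(sig.up) and read_grp(down) == set(sig.down)

    def test_empty_set_is_export_error(self, tmp_path):
        sig = CmapSignature(up=frozenset({"A"}), down=frozenset())
        with pytest.raises(ValidationError):
            write_grp(sig, tmp_path / "u", tmp_path / "d")

    def test_overlap_rejected_at_construction(self):
        with pytest.raises(ValidationError):
            CmapSignature(up=frozenset({"A"}), down=frozenset({"A"}))


class TestLoadExpression:
    def test_zero_variance_row_rejected(self, tmp_path):
        (tmp_path / "expr.tsv").write_text(
            "gene\tS1\tS2\nG1\t1.0\t1.0\nG2\t1.0\t2.0\n"
        )
        (tmp_path / "trait.tsv").write_text("sample\ttrait\nS1\t1\nS2\t0\n")
        with pytest.raises(ValidationError, match="zero-variance"):
            load_expression(tmp_path / "expr.tsv", tmp_path / "trait.tsv")

    def test_round_trip(self, tmp_path):
        (tmp_path / "expr.tsv").write_text(
            "gene\tS1\tS2\tS3\nG1\t1.0\t2.0\t3.0\nG2\t3.0\t1.0\t2.0\n"
        )
        (tmp_path / "trait.tsv").write_text("sample\ttrait\nS1\t1\nS2\t0\nS3\t0\n")
        m = load_expression(tmp_path / "expr.tsv", tmp_path / "trait.tsv")
        assert m.genes == ["G1", "G2"]
        assert m.trait.tolist() == [1, 0, 0]
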