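import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from c4net.io import ValidationError
from c4net.network import (
    AdjacencyMatrix,
    CorrelationMatrix,
    attach_eigengenes,
    build_correlation,
    build_species_network,
    color_name,
    compute_tom,
    detect_modules,
    merge_modules,
    module_eigengene,
    scale_free_fit,
    select_soft_power,
    soft_threshold,
    tom_dissimilarity,
)

from conftest import make_matrix


def pearson_oracle(x, y):
    """Textbook covariance-over-sd formula, independent of np.corrcoef."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


def tom_oracle(a):
    """Direct triple-loop topological overlap."""
    a = np.asarray(a, float).copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = a.sum(axis=1)
    t = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n))
            t[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return t


def random_adjacency(rng, n):
    raw = rng.uniform(0, 1, size=(n, n))
    a = (raw + raw.T) / 2
    np.fill_diagonal(a, 0.0)
    return a


class TestCorrelation:
    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(11)
        vals = rng.exponential(3.0, size=(6, 9))
        cor = build_correlation(make_matrix(vals), transform="none")
        for i in range(6):
            for j in range(6):
                assert cor.values[i, j] == pytest.approx(
                    pearson_oracle(vals[i], vals[j]), abs=1e-12
                )

    def test_log_transform_applied(self):
        vals = np.array([[1.0, 3.0, 7.0, 15.0], [2.0, 2.0, 4.0, 6.0]])
        cor = build_correlation(make_matrix(vals), transform="log2p1")
        logged = np.log2(vals + 1.0)
        assert cor.values[0, 1] == pytest.approx(
            pearson_oracle(logged[0], logged[1]), abs=1e-12
        )

    def test_exact_negative_profile(self):
        vals = np.array([[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]])
        cor = build_correlation(make_matrix(vals), transform="none")
        assert cor.values[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_zero_variance_gene_rejected(self):
        with pytest.raises(ValidationError, match="g2"):
            build_correlation(make_matrix([[1, 2, 3], [5, 5, 5]]))

    def test_unknown_transform(self):
        with pytest.raises(ValueError):
            build_correlation(make_matrix([[1, 2, 3]]), transform="sqrt")


class TestSoftThreshold:
    def test_frozen_power_value(self):
        cor = CorrelationMatrix(["a", "b"], np.array([[1.0, -0.8], [-0.8, 1.0]]))
        adj = soft_threshold(cor, 10)
        assert adj.values[0, 1] == pytest.approx(0.1073741824, abs=1e-12)
        assert adj.values[0, 0] == 0.0

    def test_beta_one_is_absolute_r(self):
        cor = CorrelationMatrix(["a", "b"], np.array([[1.0, -0.37], [-0.37, 1.0]]))
        assert soft_threshold(cor, 1).values[0, 1] == pytest.approx(0.37)

    def test_invalid_beta(self):
        cor = CorrelationMatrix(["a", "b"], np.eye(2))
        with pytest.raises(ValueError):
            soft_threshold(cor, 0)

    @given(st.integers(min_value=1, max_value=19), st.integers(min_value=0, max_value=2**31 - 1))
    def test_monotone_in_beta(self, beta, seed):
        rng = np.random.default_rng(seed)
        r = np.clip(rng.uniform(-1, 1, size=(5, 5)), -1, 1)
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        cor = CorrelationMatrix([f"g{i}" for i in range(5)], r)
        lo = soft_threshold(cor, beta).values
        hi = soft_threshold(cor, beta + 1).values
        assert (hi <= lo + 1e-15).all()


class TestTOM:
    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            a = random_adjacency(rng, 12)
            assert np.abs(compute_tom(a) - tom_oracle(a)).max() < 1e-10

    def test_two_gene_closed_form(self):
        # n=2: shared neighbourhood empty, k_i = a_ij, so
        # TOM = a / (a + 1 - a) = a
        a = np.array([[0.0, 0.3], [0.3, 0.0]])
        assert compute_tom(a)[0, 1] == pytest.approx(0.3, abs=1e-12)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_symmetric_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        a = random_adjacency(rng, 8)
        t = compute_tom(a)
        assert np.allclose(t, t.T)
        assert (t >= -1e-12).all() and (t <= 1 + 1e-12).all()
        assert np.allclose(np.diag(t), 1.0)

    def test_dissimilarity_complement(self):
        rng = np.random.default_rng(6)
        a = random_adjacency(rng, 6)
        assert np.allclose(tom_dissimilarity(a), 1.0 - compute_tom(a))


class TestScaleFree:
    def test_power_law_network_scores_high(self):
        rng = np.random.default_rng(8)
        n = 300
        # preferential-attachment-like weights give a heavy-tailed degree
        w = rng.pareto(1.5, size=n) + 0.05
        a = np.sqrt(np.outer(w, w))
        a = np.clip(a / a.max(), 0, 1)
        np.fill_diagonal(a, 0.0)
        assert scale_free_fit(a) > 0.8

    def test_uniform_network_scores_low(self):
        n = 200
        a = np.full((n, n), 0.4)
        np.fill_diagonal(a, 0.0)
        assert scale_free_fit(a) <= 0.0

    @staticmethod
    def hub_correlation(n=300, floor=0.3, seed=9):
        """Hub weights over a uniform background: scale-free only once the
        soft power has suppressed the background correlation."""
        rng = np.random.default_rng(seed)
        w = rng.uniform(0, 1, n) ** 2
        r = floor + (1 - floor) * np.outer(w, w)
        np.clip(r, 0, 1, out=r)
        np.fill_diagonal(r, 1.0)
        return CorrelationMatrix([f"g{i}" for i in range(n)], r)

    def test_select_returns_smallest_passing(self):
        cor = self.hub_correlation()
        betas = list(range(1, 9))
        chosen = select_soft_power(cor, candidate_betas=betas)
        assert scale_free_fit(soft_threshold(cor, chosen).values) >= 0.8
        for b in betas:
            if b < chosen:
                assert scale_free_fit(soft_threshold(cor, b).values) < 0.8

    def test_select_falls_back_with_warning(self):
        # restrict the candidates to powers that all miss the target
        cor = self.hub_correlation()
        with pytest.warns(UserWarning, match="no candidate power"):
            chosen = select_soft_power(cor, candidate_betas=[1])
        assert chosen == 1

    def test_too_few_genes(self):
        cor = build_correlation(make_matrix(np.random.default_rng(0).uniform(
            0.0, 1.0, size=(5, 6))))
        with pytest.raises(ValidationError):
            select_soft_power(cor)


def two_block_dissim(n1=45, n2=40, within=0.05, between=0.95):
    n = n1 + n2
    d = np.full((n, n), between)
    d[:n1, :n1] = within
    d[n1:, n1:] = within
    np.fill_diagonal(d, 0.0)
    return d


class TestDetectModules:
    def test_two_clean_blocks(self):
        d = two_block_dissim()
        genes = [f"g{i:03d}" for i in range(85)]
        part = detect_modules(d, genes, min_module_size=30)
        assert part.modules == ["turquoise", "blue"]
        assert set(part.members("turquoise")) == set(genes[:45])
        assert set(part.members("blue")) == set(genes[45:])

    def test_small_branch_goes_grey(self):
        d = two_block_dissim(n1=50, n2=10)
        genes = [f"g{i:03d}" for i in range(60)]
        part = detect_modules(d, genes, min_module_size=30)
        assert part.modules == ["turquoise"]
        assert (part.labels[genes[50:]] == "grey").all()

    def test_everything_above_ceiling_is_grey(self):
        n = 40
        d = np.full((n, n), 0.999)
        np.fill_diagonal(d, 0.0)
        genes = [f"g{i:03d}" for i in range(n)]
        part = detect_modules(d, genes, min_module_size=30, cut_height=0.90)
        assert part.modules == []
        assert (part.labels == "grey").all()

    def test_colors_ordered_by_size(self):
        d = two_block_dissim(n1=35, n2=60)
        genes = [f"g{i:03d}" for i in range(95)]
        part = detect_modules(d, genes, min_module_size=30)
        assert part.members("turquoise") == genes[35:]
        assert part.members("blue") == genes[:35]

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(12)
        d = two_block_dissim()
        genes = [f"g{i:03d}" for i in range(85)]
        perm = rng.permutation(85)
        part1 = detect_modules(d, genes)
        part2 = detect_modules(d[np.ix_(perm, perm)], [genes[i] for i in perm])
        assert (part1.labels.sort_index() == part2.labels.sort_index()).all()

    def test_color_vocabulary(self):
        assert color_name(0) == "turquoise"
        assert color_name(1) == "blue"
        assert color_name(2) == "brown"
        assert color_name(100) == "module101"


class TestEigengene:
    def test_recovers_common_pattern(self):
        rng = np.random.default_rng(13)
        pattern = np.array([0.2, 0.5, 1.5, 4.0, 9.0, 14.0])
        vals = np.array(
            [pattern * s * rng.lognormal(0, 0.05, 6) for s in (1, 2, 5, 10)]
        )
        mat = make_matrix(vals)
        eig = module_eigengene(mat, mat.gene_ids)
        z = np.log2(vals + 1)
        z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, keepdims=True)
        for row in z:
            assert np.corrcoef(eig, row)[0, 1] > 0.95
        assert np.linalg.norm(eig) == pytest.approx(1.0, abs=1e-12)

    def test_eigendecomposition_oracle(self):
        rng = np.random.default_rng(14)
        vals = rng.exponential(4.0, size=(8, 7))
        mat = make_matrix(vals)
        eig = module_eigengene(mat, mat.gene_ids)
        z = np.log2(vals + 1)
        z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, keepdims=True)
        evals, evecs = np.linalg.eigh(z.T @ z)
        lead = evecs[:, np.argmax(evals)]
        assert min(np.abs(eig - lead).max(), np.abs(eig + lead).max()) < 1e-8

    def test_orientation_positive_mean_correlation(self):
        rng = np.random.default_rng(15)
        vals = rng.exponential(4.0, size=(10, 8))
        mat = make_matrix(vals)
        eig = module_eigengene(mat, mat.gene_ids)
        z = np.log2(vals + 1)
        z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, keepdims=True)
        assert np.mean([np.corrcoef(eig, r)[0, 1] for r in z]) >= 0

    def test_single_gene_rejected(self):
        mat = make_matrix([[1, 2, 3], [3, 2, 1]])
        with pytest.raises(ValidationError):
            module_eigengene(mat, ["g1"])


class TestMerge:
    @staticmethod
    def partition(mat, groups):
        labels = pd.Series("grey", index=pd.Index(mat.gene_ids, name="gene_id"))
        for color, members in groups.items():
            labels.loc[members] = color
        from c4net.network import ModulePartition

        return attach_eigengenes(ModulePartition("M", labels), mat)

    def make_data(self, seed=16):
        rng = np.random.default_rng(seed)
        up = np.array([0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 30.0, 50.0])
        down = up[::-1]
        rows, genes = [], []
        for i in range(6):
            rows.append(up * rng.lognormal(0, 0.02, 8))
            genes.append(f"u{i}")
        for i in range(6):
            rows.append(up * 3 * rng.lognormal(0, 0.02, 8))
            genes.append(f"v{i}")
        for i in range(6):
            rows.append(down * rng.lognormal(0, 0.02, 8))
            genes.append(f"w{i}")
        return make_matrix(np.array(rows), genes=genes)

    def test_correlated_pair_merges(self):
        mat = self.make_data()
        part = self.partition(mat, {
            "turquoise": [f"u{i}" for i in range(6)],
            "blue": [f"v{i}" for i in range(6)],
            "brown": [f"w{i}" for i in range(6)],
        })
        merged = merge_modules(part, mat, merge_cor=0.9)
        assert len(merged.modules) == 2
        assert merged.members("turquoise") == [f"u{i}" for i in range(6)] + [
            f"v{i}" for i in range(6)
        ]
        assert set(merged.members("blue")) == {f"w{i}" for i in range(6)}

    def test_no_merge_below_threshold(self):
        mat = self.make_data()
        part = self.partition(mat, {
            "turquoise": [f"u{i}" for i in range(6)],
            "blue": [f"w{i}" for i in range(6)],
        })
        merged = merge_modules(part, mat, merge_cor=0.9)
        assert len(merged.modules) == 2

    def test_never_increases_count_and_grey_untouched(self):
        mat = self.make_data(seed=17)
        part = self.partition(mat, {
            "turquoise": [f"u{i}" for i in range(6)],
            "blue": [f"v{i}" for i in range(6)],
        })
        merged = merge_modules(part, mat, merge_cor=0.5)
        assert len(merged.modules) <= len(part.modules)
        grey_before = set(part.labels.index[part.labels == "grey"])
        grey_after = set(merged.labels.index[merged.labels == "grey"])
        assert grey_before == grey_after


class TestBuildSpeciesNetwork:
    def test_end_to_end_two_planted_modules(self):
        rng = np.random.default_rng(18)
        grid = np.linspace(0, 1, 12)
        rising = 1.0 / (1.0 + np.exp(-10 * (grid - 0.5)))
        bump = np.exp(-0.5 * ((grid - 0.2) / 0.06) ** 2)
        rows, genes = [], []
        for i in range(45):
            rows.append(20 * (0.05 + rising) * rng.lognormal(0, 0.2, 12))
            genes.append(f"r{i:03d}")
        for i in range(40):
            rows.append(20 * (0.05 + bump) * rng.lognormal(0, 0.2, 12))
            genes.append(f"b{i:03d}")
        mat = make_matrix(np.array(rows), genes=genes)
        part, beta = build_species_network(mat, beta=10)
        assert beta == 10
        assert len(part.modules) == 2
        first = part.labels["r000"]
        assert (part.labels[[f"r{i:03d}" for i in range(45)]] == first).all()
        second = part.labels["b000"]
        assert first != second
        assert (part.labels[[f"b{i:03d}" for i in range(40)]] == second).all()
        assert part.eigengenes is not None
        assert list(part.eigengenes.index) == part.modules
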