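import numpy as np
import pytest

from intense.cohort_io import NormalizedMatrix, zscore
from intense.ipca import (
    compute_pcs,
    cumulative_dims,
    detect_interaction_zone,
    joint_correlation_map,
    run_ipca,
)


def _planted_cohort(rng, n=656, n_factors=10, block=(0, 1, 2, 3, 4), r=0.6, signs=None):
    """Continuous factors; ``block`` members share a latent at pairwise r."""
    X = rng.standard_normal((n, n_factors))
    g = rng.standard_normal(n)
    signs = signs or [1] * len(block)
    for idx, s in zip(block, signs):
        X[:, idx] = s * (np.sqrt(r) * g + np.sqrt(1 - r) * rng.standard_normal(n))
    return zscore(X)


class TestComputePcs:
    def test_rank_one_two_duplicated_columns(self, rng):
        x = rng.normal(size=20)
        nm = zscore(np.column_stack([x, 2 * x + 1]))
        pca = compute_pcs(nm)
        assert np.allclose(pca.explained_fraction, [1.0, 0.0], atol=1e-12)

    def test_explained_fractions_match_eigendecomposition_oracle(self, rng):
        X = rng.standard_normal((6, 4))
        nm = zscore(X)
        pca = compute_pcs(nm)
        corr = np.corrcoef(nm.values, rowvar=False)
        eigvals = np.sort(np.linalg.eigvalsh(corr))[::-1]
        assert np.allclose(pca.explained_fraction * 4, eigvals, atol=1e-8)

    def test_fractions_sum_to_one_and_monotone(self, normalized_seed1):
        frac = compute_pcs(normalized_seed1).explained_fraction
        assert abs(frac.sum() - 1) < 1e-10
        assert np.all(np.diff(frac) <= 1e-12)

    def test_scores_mutually_orthogonal(self, normalized_seed1):
        scores = compute_pcs(normalized_seed1).scores
        corr = np.corrcoef(scores[:, :10], rowvar=False)
        off = corr - np.diag(np.diag(corr))
        assert np.abs(off).max() < 1e-8

    def test_sign_convention_largest_loading_positive(self, rng):
        pca = compute_pcs(zscore(rng.standard_normal((30, 5))))
        for j in range(5):
            col = pca.loadings[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_independent_columns_near_equal_fractions(self, rng):
        nm = zscore(rng.standard_normal((20000, 4)))
        frac = compute_pcs(nm).explained_fraction
        assert np.all(np.abs(frac - 0.25) < 0.03)


class TestCumulativeDims:
    @pytest.mark.parametrize(
        "fractions, cutoff, expected",
        [((0.5, 0.2, 0.1, 0.1, 0.1), 0.70, 2), ((1.0, 0.0, 0.0), 0.5, 1), ((1.0, 0.0, 0.0), 1.0, 1)],
    )
    def test_examples(self, fractions, cutoff, expected):
        from intense.ipca import PCADecomposition

        dec = PCADecomposition(
            scores=np.zeros((2, len(fractions))),
            loadings=np.eye(len(fractions)),
            explained_fraction=np.array(fractions),
            factor_names=[f"f{i}" for i in range(len(fractions))],
        )
        assert cumulative_dims(dec, cutoff) == expected

    def test_random_simplex_matches_linear_scan_oracle(self, rng):
        from intense.ipca import PCADecomposition

        for _ in range(20):
            frac = np.sort(rng.dirichlet(np.ones(8)))[::-1]
            dec = PCADecomposition(
                scores=np.zeros((2, 8)),
                loadings=np.eye(8),
                explained_fraction=frac,
                factor_names=[f"f{i}" for i in range(8)],
            )
            total, oracle = 0.0, None
            for i, v in enumerate(frac):
                total += v
                if total >= 0.75 - 1e-12:
                    oracle = i + 1
                    break
            assert cumulative_dims(dec, 0.75) == oracle


class TestJointCorrelationMap:
    def test_pc_pc_block_identity(self, rng):
        nm = zscore(rng.standard_normal((40, 6)))
        jmap = joint_correlation_map(nm, compute_pcs(nm))
        assert np.allclose(jmap.pc_pc, np.eye(6), atol=1e-8)

    def test_duplicated_factor_correlates_at_one(self, rng):
        x = rng.normal(size=30)
        nm = zscore(np.column_stack([x, x, rng.normal(size=30)]))
        jmap = joint_correlation_map(nm, compute_pcs(nm))
        assert jmap.factor_factor[0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_factor_pc_block_matches_pairwise_pearson_oracle(self, rng):
        nm = zscore(rng.standard_normal((5, 3)))
        pca = compute_pcs(nm)
        jmap = joint_correlation_map(nm, pca)

        def pearson(a, b):
            am, bm = a - a.mean(), b - b.mean()
            return (am @ bm) / np.sqrt((am @ am) * (bm @ bm))

        for i in range(3):
            for j in range(3):
                if pca.scores[:, j].std() == 0:
                    continue
                expect = pearson(nm.values[:, i], pca.scores[:, j])
                assert jmap.factor_pc[i, j] == pytest.approx(expect, abs=1e-10)

    def test_zero_variance_pcs_flagged_and_zeroed(self, rng):
        x = rng.normal(size=25)
        nm = zscore(np.column_stack([x, -x]))  # rank 1: PC2 has no variance
        jmap = joint_correlation_map(nm, compute_pcs(nm))
        assert jmap.zero_variance_pcs == (1,)
        assert np.all(jmap.factor_pc[:, 1] == 0)


class TestDetectZone:
    def _map_from_block(self, block):
        """Build a JointCorrelationMap carrying a given factor-PC block."""
        from intense.ipca import JointCorrelationMap

        f, p = block.shape
        values = np.eye(f + p)
        values[:f, f:] = block
        values[f:, :f] = block.T
        return JointCorrelationMap(values=values, factor_names=[f"f{i}" for i in range(f)])

    def test_two_or_more_rule(self):
        block = np.zeros((5, 5))
        block[[0, 1, 2], 0] = 0.8  # PC1: three suprathreshold factors
        block[3, 1] = 0.9  # PC2: only one
        zone = detect_interaction_zone(self._map_from_block(block), 0.4, 5)
        assert zone.interaction_pcs == (0,)
        assert zone.selected_factors == ("f0", "f1", "f2")

    def test_all_subthreshold_gives_empty_zone(self):
        zone = detect_interaction_zone(self._map_from_block(np.full((4, 4), 0.2)), 0.4, 4)
        assert zone.is_empty and zone.selected_factors == ()

    def test_matches_brute_force_counting_oracle(self, rng):
        block = rng.uniform(-1, 1, size=(10, 10))
        jmap = self._map_from_block(block)
        zone = detect_interaction_zone(jmap, 0.4, 10)
        pcs, selected = [], set()
        for j in range(10):
            hits = [i for i in range(10) if abs(block[i, j]) >= 0.4]
            if len(hits) >= 2:
                pcs.append(j)
                selected.update(hits)
        assert zone.interaction_pcs == tuple(pcs)
        assert set(zone.selected_factors) == {f"f{i}" for i in selected}

    def test_monotone_in_tau(self, normalized_seed1):
        pca = compute_pcs(normalized_seed1)
        jmap = joint_correlation_map(normalized_seed1, pca)
        prev = None
        for tau in (0.3, 0.4, 0.5, 0.6):
            zone = detect_interaction_zone(jmap, tau, 13)
            if prev is not None:
                assert set(zone.selected_factors) <= set(prev)
            prev = zone.selected_factors


class TestRunIpca:
    def test_planted_block_recovered_across_seeds(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            nm = _planted_cohort(rng)
            result = run_ipca(nm)
            groups = [frozenset(n for n, _ in g) for g in result.interaction_groups.values()]
            hits += frozenset({"f0", "f1", "f2", "f3", "f4"}) in groups
        assert hits >= 19

    def test_anti_correlated_members_carry_opposite_sign(self):
        rng = np.random.default_rng(7)
        nm = _planted_cohort(rng, signs=[1, 1, 1, -1, -1])
        result = run_ipca(nm)
        signs = result.factor_signs
        assert {"f0", "f1", "f2", "f3", "f4"} <= set(signs)
        assert signs["f0"] == signs["f1"] == signs["f2"]
        assert signs["f3"] == signs["f4"] == -signs["f0"]

    def test_independent_factors_never_reach_strong_threshold(self):
        # pure-noise factor-PC correlations stay far below 0.9 at n = 656,
        # exercising the empty-zone path: no groups, all singletons
        rng = np.random.default_rng(0)
        nm = zscore(rng.standard_normal((656, 8)))
        result = run_ipca(nm, tau=0.9)
        assert result.interaction_groups == {}
        assert result.clustering.n_clusters == 8

    def test_planted_block_absent_from_independent_data(self):
        # at the default threshold noise can produce incidental small groups,
        # but never a coherent five-factor block
        for seed in range(5):
            rng = np.random.default_rng(seed)
            nm = zscore(rng.standard_normal((656, 10)))
            result = run_ipca(nm)
            sizes = [len(g) for g in result.interaction_groups.values()]
            assert max(sizes, default=0) < 5

    def test_second_pass_subset_of_first(self, normalized_seed1):
        result = run_ipca(normalized_seed1)
        assert result.second_zone is not None
        assert set(result.second_zone.selected_factors) <= set(
            result.first_zone.selected_factors
        )
        grouped = {n for g in result.interaction_groups.values() for n, _ in g}
        assert grouped <= set(result.first_zone.selected_factors)

    def test_invariant_to_subject_and_factor_order(self):
        rng = np.random.default_rng(3)
        nm = _planted_cohort(rng, n=300, n_factors=8)
        base = run_ipca(nm)

        perm_rows = np.random.default_rng(1).permutation(300)
        nm_rows = NormalizedMatrix(nm.values[perm_rows], nm.factor_names)
        assert run_ipca(nm_rows).clustering.clusters() == base.clustering.clusters()

        perm_cols = np.random.default_rng(2).permutation(8)
        nm_cols = NormalizedMatrix(
            nm.values[:, perm_cols], [nm.factor_names[i] for i in perm_cols]
        )
        shuffled = run_ipca(nm_cols)
        base_parts = {frozenset(v) for v in base.clustering.clusters().values()}
        shuf_parts = {frozenset(v) for v in shuffled.clustering.clusters().values()}
        assert base_parts == shuf_parts

    def test_result_serializes_to_json(self, normalized_seed1):
        import json

        payload = run_ipca(normalized_seed1).to_dict()
        assert json.loads(json.dumps(payload)) == payload
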