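"""Clustering, NMF factorization, background scoring, direct contrasts."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mirscreen import (
    AssayPanel,
    SampleMeta,
    ScreenConfig,
    clustering_purity,
    direct_contrast_screen,
    global_mean_normalize,
    hierarchical_cluster,
    nmf_factorize,
    triplicate_mean,
)
from mirscreen.normalize import NormalizedTable
from mirscreen.signature import (
    FactorModel,
    abundance_matrix,
    background_insensitivity_ranking,
)
from mirscreen.simulate import SimulationSpec, StrainSpec, simulate_screen


def norm_from_matrix(df: pd.DataFrame, strain_of: dict[str, str]) -> NormalizedTable:
    samples = tuple(
        SampleMeta(sample_id=c, strain=strain_of[c], aliquot_index=i + 1)
        for i, c in enumerate(df.columns)
    )
    return NormalizedTable(
        values=df.astype(float),
        scheme="global_mean",
        normalizer_per_sample=pd.Series(0.0, index=list(df.columns)),
        grand_normalizer=0.0,
        samples=samples,
        panel=AssayPanel(mirna_ids=tuple(df.index)),
    )


class TestHierarchicalClustering:
    def test_first_merge_joins_closest_pair(self):
        # three 1-D samples at 0, 1, 3: closest pair is (s0, s1)
        df = pd.DataFrame({"s0": [0.0], "s1": [1.0], "s2": [3.0]}, index=["m1"])
        norm = norm_from_matrix(df, {c: c for c in df.columns})
        tree = hierarchical_cluster(norm)
        a, b, h, n = tree.merges()[0]
        assert {a, b} == {0, 1} and h == 1.0 and n == 2

    def test_duplicate_columns_merge_at_height_zero(self):
        df = pd.DataFrame({"s0": [1.0, 2.0], "s1": [1.0, 2.0], "s2": [9.0, 9.0]},
                          index=["m1", "m2"])
        norm = norm_from_matrix(df, {c: c for c in df.columns})
        tree = hierarchical_cluster(norm)
        assert tree.merges()[0][2] == 0.0

    def test_average_linkage_heights_match_hand_dendrogram(self):
        """1-D points 0, 1, 5, 7: merges at 1, 2, then mean(5,7,4,6) = 5.5."""
        df = pd.DataFrame(
            {"p0": [0.0], "p1": [1.0], "p2": [5.0], "p3": [7.0]}, index=["m1"]
        )
        norm = norm_from_matrix(df, {c: c for c in df.columns})
        tree = hierarchical_cluster(norm, metric="euclidean", method="average")
        heights = [m[2] for m in tree.merges()]
        assert heights == pytest.approx([1.0, 2.0, 5.5])

    def test_rows_with_missing_values_are_dropped(self):
        df = pd.DataFrame(
            {"s0": [0.0, np.nan], "s1": [1.0, 2.0]}, index=["m1", "m2"]
        )
        norm = norm_from_matrix(df, {c: c for c in df.columns})
        tree = hierarchical_cluster(norm)
        assert tree.n_dropped_rows == 1

    def test_fewer_than_two_samples_rejected(self):
        df = pd.DataFrame({"s0": [0.0]}, index=["m1"])
        norm = norm_from_matrix(df, {"s0": "s0"})
        with pytest.raises(ValueError):
            hierarchical_cluster(norm)


class TestPurity:
    def two_cluster_tree(self, values: dict[str, list[float]]):
        df = pd.DataFrame(values, index=["m1"])
        norm = norm_from_matrix(df, {c: c for c in df.columns})
        return hierarchical_cluster(norm)

    def test_single_cluster_two_equal_strains_gives_half(self):
        tree = self.two_cluster_tree({"a1": [0.0], "a2": [0.1], "b1": [5.0], "b2": [5.1]})
        assign = clustering_purity(tree, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}, k=1)
        assert assign.purity == 0.5

    def test_same_strain_everywhere_is_pure_for_any_k(self):
        tree = self.two_cluster_tree({"a1": [0.0], "a2": [1.0], "a3": [5.0]})
        for k in (1, 2, 3):
            assert clustering_purity(tree, {s: "A" for s in ("a1", "a2", "a3")}, k).purity == 1.0

    def test_purity_invariant_to_strain_relabeling(self):
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        relabeled = {k: {"A": "X", "B": "Y"}[v] for k, v in labels.items()}
        tree = self.two_cluster_tree({"a1": [0.0], "a2": [0.1], "b1": [5.0], "b2": [5.1]})
        for k in (1, 2):
            assert (
                clustering_purity(tree, labels, k).purity
                == clustering_purity(tree, relabeled, k).purity
            )

    def test_perfect_strain_separation_on_structured_screens(self):
        """Strain effects well above replicate noise -> purity 1.0 at k = n_strains."""
        for seed in range(10):
            spec = _clusterable_spec(seed)
            table, _ = simulate_screen(spec)
            aliquot = triplicate_mean(table)
            norm = global_mean_normalize(aliquot)
            tree = hierarchical_cluster(norm)
            labels = {s.sample_id: s.strain for s in aliquot.samples}
            assign = clustering_purity(tree, labels, k=len(set(labels.values())))
            assert assign.purity == 1.0, f"seed {seed}"
            assert assign.perfect


def _clusterable_spec(seed: int) -> SimulationSpec:
    """Paper-style design: 3 background groups, per-strain disease effects
    (balanced up/down) well above replicate noise."""
    strains = (
        StrainSpec("d1", "g1", "pathological", "c1"),
        StrainSpec("d2", "g1", "pathological", "c1"),
        StrainSpec("c1", "g1", "control"),
        StrainSpec("d3", "g2", "pathological", "c2"),
        StrainSpec("c2", "g2", "control"),
        StrainSpec("d4", "g3", "pathological", "c3"),
        StrainSpec("c3", "g3", "control"),
    )
    inj: dict[tuple[int, str], float] = {}
    patho = ["d1", "d2", "d3", "d4"]
    for j, s in enumerate(patho):  # disjoint blocks of 6 assays per strain
        for i in range(6):
            m = j * 6 + i
            inj[(m, s)] = 3.0 if i % 2 == 0 else -3.0
    return SimulationSpec(
        n_mirnas=40,
        strains=strains,
        injected_log2fc=inj,
        base_cq_range=(20.0, 30.0),
        replicate_sd=0.1,
        background_sd=2.0,
        seed=seed,
    )


class TestNmf:
    def test_rank_one_matrix_recovered(self):
        rng = np.random.default_rng(1)
        w = rng.uniform(0.5, 2.0, size=15)
        h = rng.uniform(0.5, 2.0, size=8)
        X = pd.DataFrame(np.outer(w, h))
        X.index = [f"m{i}" for i in range(15)]
        X.columns = [f"s{j}" for j in range(8)]
        model = nmf_factorize(X, k=1, seed=0, tol=1e-12, max_iter=5000)
        rel = model.reconstruction_error / np.linalg.norm(X.to_numpy())
        assert rel <= 1e-6

    def test_error_trace_monotone_and_factors_nonnegative(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.uniform(0.0, 5.0, size=(20, 12)))
            model = nmf_factorize(X, k=3, seed=seed, max_iter=200, tol=0.0)
            trace = np.array(model.error_trace)
            assert np.all(np.diff(trace) <= 1e-8 * trace[0])
            assert (model.basis.to_numpy() >= 0).all()
            assert (model.coefficients.to_numpy() >= 0).all()

    def test_same_seed_identical_factors(self):
        X = pd.DataFrame(np.random.default_rng(4).uniform(0, 3, size=(10, 6)))
        m1 = nmf_factorize(X, k=2, seed=9)
        m2 = nmf_factorize(X, k=2, seed=9)
        pd.testing.assert_frame_equal(m1.basis, m2.basis, check_exact=True)

    def test_negative_input_rejected(self):
        X = pd.DataFrame([[1.0, -0.1], [0.5, 2.0]])
        with pytest.raises(ValueError, match="non-negative"):
            nmf_factorize(X, k=1)

    def test_final_error_comparable_to_sklearn(self):
        """Cross-check against an independent NMF implementation."""
        from sklearn.decomposition import NMF

        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.uniform(0.0, 5.0, size=(25, 10)))
        ours = nmf_factorize(X, k=3, seed=0, max_iter=3000, tol=1e-10)
        sk = NMF(n_components=3, solver="mu", init="random", random_state=0,
                 max_iter=3000, tol=1e-10).fit(X.to_numpy())
        sk_err = np.linalg.norm(X.to_numpy() - sk.transform(X.to_numpy()) @ sk.components_)
        assert ours.reconstruction_error <= sk_err * 1.1


class TestBackgroundScore:
    def constructed_model(self):
        """Factor 1 flat across backgrounds (disease axis), factor 2 aligned
        with the two background groups."""
        samples = [f"s{i}" for i in range(6)]
        coeff = pd.DataFrame(
            {
                s: [1.0, 5.0 if i < 3 else 0.5]  # factor2 differs by group
                for i, s in enumerate(samples)
            },
            index=["factor_1", "factor_2"],
        )
        basis = pd.DataFrame(
            {"factor_1": [1.0, 0.0, 0.5], "factor_2": [0.0, 1.0, 0.5]},
            index=["m_disease", "m_background", "m_mixed"],
        )
        return FactorModel(
            basis=basis, coefficients=coeff, rank=2,
            reconstruction_error=0.0, error_trace=[0.0], converged=True, seed=0,
        )

    def group_labels(self):
        return {f"s{i}": ("g1" if i < 3 else "g2") for i in range(6)}

    def test_background_free_ranks_first_background_bound_last(self):
        ranking = background_insensitivity_ranking(
            self.constructed_model(), self.group_labels(), n_select=1
        )
        assert ranking.iloc[0]["mirna_id"] == "m_disease"
        assert ranking.iloc[0]["background_score"] == pytest.approx(0.0)
        assert ranking.iloc[-1]["mirna_id"] == "m_background"
        assert ranking.iloc[-1]["background_score"] == pytest.approx(1.0)
        assert ranking["selected"].sum() == 1

    def test_rank_below_group_count_rejected(self):
        model = self.constructed_model()
        labels = {f"s{i}": f"g{i % 3}" for i in range(6)}
        with pytest.raises(ValueError, match="rank"):
            background_insensitivity_ranking(model, labels, n_select=1)

    def test_background_free_disease_assays_rank_in_top_half(self):
        """Assays driven by disease status (flat across backgrounds) land in
        the top (least background-bound) half; background-driven assays do
        not crowd them out.  >= 80% placement averaged over 20 seeds."""
        n_disease, n_background = 10, 20
        groups3 = ["g1"] * 4 + ["g2"] * 4 + ["g3"] * 4
        disease = [i % 2 == 0 for i in range(12)]  # alternating case/control
        placed = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            rows = {}
            for i in range(n_disease):
                rows[f"dis{i}"] = [
                    5.0 + 3.0 * d + rng.normal(0, 0.2) for d in disease
                ]
            bg_level = {"g1": 0.0, "g2": 4.0, "g3": 8.0}
            for i in range(n_background):
                rows[f"bg{i}"] = [
                    5.0 + bg_level[g] + rng.normal(0, 0.2) for g in groups3
                ]
            df = pd.DataFrame(rows).T
            df.columns = [f"s{j}" for j in range(12)]
            model = nmf_factorize(df, k=4, seed=seed)
            labels = {f"s{j}": groups3[j] for j in range(12)}
            ranking = background_insensitivity_ranking(model, labels, n_select=n_disease)
            top_half = set(ranking["mirna_id"].iloc[: len(ranking) // 2])
            placed.append(
                sum(f"dis{i}" in top_half for i in range(n_disease)) / n_disease
            )
        assert np.mean(placed) >= 0.8


class TestDirectContrast:
    def test_identical_strains_empty_signature(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(20, 30, size=12)
        cols = {}
        strain_of = {}
        for s in ("x", "y", "z"):
            for a in range(1, 4):
                sid = f"{s}:a{a}"
                cols[sid] = base + rng.normal(0, 0.15, size=12)
                strain_of[sid] = s
        df = pd.DataFrame(cols, index=[f"m{i}" for i in range(12)])
        norm = norm_from_matrix(df, strain_of)
        _, signature = direct_contrast_screen(norm, ["x", "y", "z"], ScreenConfig())
        assert signature == []

    def test_pairwise_effect_attributed_to_the_right_pair(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(22, 28, size=10)
        cols, strain_of = {}, {}
        for s in ("x", "y", "z"):
            for a in range(1, 4):
                sid = f"{s}:a{a}"
                vals = base + rng.normal(0, 0.1, size=10)
                if s == "y":
                    vals = vals.copy()
                    vals[0] -= 3.0  # m0 upregulated only in strain y
                cols[sid] = vals
                strain_of[sid] = s
        df = pd.DataFrame(cols, index=[f"m{i}" for i in range(10)])
        norm = norm_from_matrix(df, strain_of)
        result, signature = direct_contrast_screen(norm, ["x", "y", "z"], ScreenConfig())
        assert "m0" in signature
        hit = result[(result["mirna_id"] == "m0") & result["q_value"].le(0.05)]
        pairs = set(map(tuple, hit[["strain", "control_strain"]].to_numpy()))
        assert pairs <= {("x", "y"), ("y", "z")} and pairs

    def test_pair_results_are_antisymmetric(self):
        rng = np.random.default_rng(2)
        cols, strain_of = {}, {}
        base = rng.uniform(20, 30, size=8)
        for s in ("x", "y"):
            for a in range(1, 4):
                sid = f"{s}:a{a}"
                shift = 1.0 if s == "y" else 0.0
                cols[sid] = base + shift + rng.normal(0, 0.1, size=8)
                strain_of[sid] = s
        df = pd.DataFrame(cols, index=[f"m{i}" for i in range(8)])
        norm = norm_from_matrix(df, strain_of)
        fwd, _ = direct_contrast_screen(norm, ["x", "y"], ScreenConfig())
        rev, _ = direct_contrast_screen(norm, ["y", "x"], ScreenConfig())
        merged = fwd.merge(rev, on="mirna_id", suffixes=("_fwd", "_rev"))
        assert np.allclose(
            merged["signed_fc_fwd"].to_numpy(), -merged["signed_fc_rev"].to_numpy()
        )
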