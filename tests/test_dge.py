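import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import bh_stepup, fisher_exact_two_sided, wilcoxon_exact_two_sided
from conftest import make_adata
from ccatlas.dge import (
    DGEParams,
    annotate_by_reference_markers,
    benjamini_hochberg,
    dge_wilcoxon,
    export_rnk,
    find_markers,
    fisher_proportion_test,
    gene_inclusion_filter,
    load_tlr4_genes,
    rank_sum_test,
    signature_test,
)
from ccatlas.qc import sum_normalize
from ccatlas.synthetic import PlantedDE, SyntheticSpec, generate_atlas


class TestBenjaminiHochberg:
    def test_single_p_is_unchanged(self):
        assert benjamini_hochberg([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_matches_step_up_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 60))
            assert np.allclose(benjamini_hochberg(p), bh_stepup(p), atol=1e-12)

    def test_out_of_range_p_raises(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])


class TestRankSum:
    def test_separated_three_vs_three_gives_point_one(self):
        assert rank_sum_test([4, 5, 6], [1, 2, 3]) == pytest.approx(0.1)

    @pytest.mark.parametrize("n,m", [(3, 3), (4, 5), (6, 2), (8, 8)])
    def test_exact_mode_matches_enumeration(self, n, m):
        rng = np.random.default_rng(n * 10 + m)
        for _ in range(5):
            pooled = rng.permutation(np.arange(1, n + m + 1, dtype=float))
            x, y = pooled[:n], pooled[n:]
            assert rank_sum_test(x, y) == pytest.approx(
                wilcoxon_exact_two_sided(x, y), abs=1e-9
            )

    def test_asymptotic_agrees_with_exact_at_twenty_per_group(self):
        from _oracles import wilcoxon_exact_dp

        rng = np.random.default_rng(1)
        worst = 0.0
        for _ in range(10):
            pooled = rng.permutation(np.arange(1, 41, dtype=float))
            x, y = pooled[:20], pooled[20:]
            # group sizes above 8 take the tie-corrected normal approximation
            approx = rank_sum_test(x, y)
            worst = max(worst, abs(approx - wilcoxon_exact_dp(x, y)))
        assert worst < 0.02

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


def _two_condition_adata(case_block, ctrl_block, genes=None):
    X = np.vstack([case_block, ctrl_block])
    n_case, n_ctrl = len(case_block), len(ctrl_block)
    return make_adata(
        X,
        genes=genes,
        conditions=["case"] * n_case + ["control"] * n_ctrl,
        patients=[f"p{1 + i % 3}" for i in range(n_case)]
        + [f"q{1 + i % 3}" for i in range(n_ctrl)],
        cell_types=["t1"] * (n_case + n_ctrl),
    )


class TestInclusionFilter:
    def test_hand_enumerated_patterns(self):
        # 3 subjects x 4 cells each; gene columns crafted per rule
        patients = ["A"] * 5 + ["B"] * 5 + ["C"] * 5
        X = np.zeros((15, 4))
        X[:, 0] = 1.0  # expressed in 5 cells of all 3 subjects, high mean -> kept
        X[0:5, 1] = 1.0  # subject A only -> fails the 2-subject rule
        X[[0, 1, 2, 3, 5, 6, 7, 8], 2] = 1.0  # 4 cells in A, 4 in B -> fails 5-cell rule
        X[:, 3] = 1e-9  # everywhere but below the mean floor
        adata = make_adata(
            X / X.sum(axis=1, keepdims=True),
            patients=patients,
            conditions=["case"] * 8 + ["control"] * 7,
            cell_types=["t1"] * 15,
        )
        params = DGEParams(min_mean_expr=1e-4, min_subjects=2, min_cells_per_subject=5)
        kept = gene_inclusion_filter(adata, "t1", params)
        assert kept == ["g1"]

    def test_exactly_meeting_both_criteria_is_retained(self):
        patients = ["A"] * 5 + ["B"] * 5
        X = np.full((10, 2), 0.5)
        X[:, 0] = 2e-4  # expressed in exactly 5 cells of each of 2 subjects
        adata = make_adata(X, patients=patients, cell_types=["t1"] * 10)
        kept = gene_inclusion_filter(adata, "t1", DGEParams())
        assert "g1" in kept

    def test_absent_cell_type_raises(self):
        adata = make_adata(np.ones((3, 2)))
        with pytest.raises(ValueError, match="ghost"):
            gene_inclusion_filter(adata, "ghost")


class TestDGEWilcoxon:
    def _norm_atlas(self, seed, fold=4.0, n_planted=20):
        spec = SyntheticSpec(
            n_genes=800,
            n_cell_types=1,
            cells_per_type_per_patient=50,
            n_patients_case=3,
            n_patients_control=3,
            marker_genes_per_type=0,
            ambient_fraction=0.0,
            n_empty_droplets_per_patient=0,
            n_high_mito_per_patient=0,
            n_high_ery_per_patient=0,
            planted_de=[PlantedDE(f"G{i + 1:04d}", "type1", fold) for i in range(n_planted)],
            seed=seed,
        )
        adata, truth = generate_atlas(spec)
        return sum_normalize(adata), truth

    def test_identical_groups_have_unit_fold_and_no_selection(self):
        block = np.tile(np.linspace(0.1, 0.9, 9)[:, None], (1, 3))
        adata = _two_condition_adata(block, block)
        table = dge_wilcoxon(adata, "t1", DGEParams(min_cells_per_subject=1))
        assert np.allclose(table["fold_change"], 1.0)
        assert not table["selected"].any()

    def test_label_symmetry_inverts_fold_and_preserves_p(self):
        norm, _ = self._norm_atlas(seed=21)
        fwd = dge_wilcoxon(norm, "type1").set_index("gene")
        rev = dge_wilcoxon(norm, "type1", case="control", control="case").set_index("gene")
        shared = fwd.index.intersection(rev.index)
        assert np.allclose(fwd.loc[shared, "p"], rev.loc[shared, "p"], atol=1e-12)
        assert np.allclose(
            fwd.loc[shared, "fold_change"] * rev.loc[shared, "fold_change"], 1.0, rtol=1e-3
        )

    def test_planted_genes_recovered(self):
        norm, truth = self._norm_atlas(seed=22)
        table = dge_wilcoxon(norm, "type1").set_index("gene")
        planted = [p.gene for p in truth.planted_de]
        hits = table.loc[table.index.intersection(planted)]
        assert (hits["q"] < 0.02).mean() >= 0.9

    def test_missing_condition_names_the_offender(self):
        block = np.ones((4, 3))
        adata = make_adata(block, conditions=["case"] * 4)
        with pytest.raises(ValueError, match="control"):
            dge_wilcoxon(adata, "t1", DGEParams(min_cells_per_subject=1))

    def test_null_false_positive_rate_is_calibrated(self):
        """Under the global null the p < 0.05 fraction stays near nominal."""
        fractions = []
        for seed in (31, 32, 33):
            norm, _ = self._norm_atlas(seed=seed, n_planted=0)
            table = dge_wilcoxon(norm, "type1")
            fractions.append((table["p"] < 0.05).mean())
            assert len(table) >= 500
        assert 0.03 <= np.mean(fractions) <= 0.07


class TestMarkers:
    def test_exclusive_gene_marks_its_cluster_and_uniform_gene_does_not(self):
        X = np.zeros((6, 3))
        X[:3, 0] = 0.5  # exclusive to cluster a
        X[:, 1] = 0.3  # uniform
        X[:, 2] = 0.2
        adata = make_adata(X, cell_types=["a"] * 3 + ["b"] * 3)
        table = find_markers(adata, "cell_type")
        assert ("a", "g1") in set(zip(table["cluster"], table["gene"]))
        assert "g2" not in set(table["gene"])

    def test_single_cluster_raises(self):
        with pytest.raises(ValueError):
            find_markers(make_adata(np.ones((3, 2))), "cell_type")

    def test_planted_fold_eight_markers_recovered_at_defaults(self, small_atlas):
        spec, adata, truth = small_atlas
        real = (truth.droplet_label == "real") & (truth.qc_fail == "")
        norm = sum_normalize(adata[real.to_numpy()])
        table = find_markers(norm, "cell_type", logfc_min=1.0, min_pct=0.5)
        found = set(zip(table["cluster"], table["gene"]))
        from ccatlas.synthetic import _marker_assignment

        genes = spec.gene_names()
        for t, idxs in _marker_assignment(spec).items():
            for j in idxs:
                assert (t, genes[j]) in found


class TestAnnotationTransfer:
    def test_disjoint_markers_give_identity_mapping(self):
        X = np.zeros((4, 4))
        X[:2, :2] = 0.5
        X[2:, 2:] = 0.5
        adata = make_adata(X, cell_types=["A", "A", "B", "B"])
        ref = {"refA": ["g1", "g2"], "refB": ["g3", "g4"]}
        assert annotate_by_reference_markers(adata, "cell_type", ref) == {
            "A": "refA",
            "B": "refB",
        }

    def test_all_markers_missing_raises(self):
        adata = make_adata(np.ones((2, 2)), cell_types=["A", "B"])
        with pytest.raises(ValueError):
            annotate_by_reference_markers(adata, "cell_type", {"r": ["nope"]})

    def test_overlapping_markers_match_brute_force_scores(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(size=(9, 6))
        labels = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        adata = make_adata(X, cell_types=labels)
        ref = {"r1": ["g1", "g2", "g3"], "r2": ["g2", "g4"], "r3": ["g5", "g6", "g1"]}
        got = annotate_by_reference_markers(adata, "cell_type", ref)
        gene_pos = {f"g{j + 1}": j for j in range(6)}
        for c in ("A", "B", "C"):
            mean = X[np.array(labels) == c].mean(axis=0)
            scores = {r: sum(mean[gene_pos[g]] for g in gs) for r, gs in ref.items()}
            assert got[c] == min(
                [r for r, s in scores.items() if s == max(scores.values())]
            )


class TestSignature:
    def test_single_gene_score_equals_expression(self):
        X = np.array([[0.2, 0.8], [0.6, 0.4]])
        adata = make_adata(X, conditions=["case", "control"])
        scores, _ = signature_test(adata, ["g1"])
        assert np.allclose(scores.to_numpy(), X[:, 0])

    def test_absent_genes_do_not_change_scores(self):
        X = np.array([[0.2, 0.8], [0.6, 0.4], [0.3, 0.7]])
        adata = make_adata(X, conditions=["case", "control", "case"])
        s1, _ = signature_test(adata, ["g1", "g2"])
        s2, _ = signature_test(adata, ["g1", "g2", "not_a_gene"])
        assert np.allclose(s1.to_numpy(), s2.to_numpy())

    def test_empty_intersection_raises(self):
        adata = make_adata(np.ones((2, 2)), conditions=["case", "control"])
        with pytest.raises(ValueError):
            signature_test(adata, ["nope"])

    def test_two_fold_signature_shift_is_detected(self):
        rng = np.random.default_rng(7)
        n = 200
        base = rng.gamma(2.0, 0.001, size=(2 * n, 10))
        base[:n, :5] *= 2.0  # the set genes doubled in case cells
        adata = make_adata(base, conditions=["case"] * n + ["control"] * n)
        _, p = signature_test(adata, [f"g{j}" for j in range(1, 6)])
        assert p < 0.01

    def test_packaged_tlr4_list_loads(self):
        genes = load_tlr4_genes()
        assert len(genes) == 92
        assert "TLR4" in genes and "MYD88" in genes
        assert len(set(genes)) == len(genes)


class TestFisher:
    def test_equal_proportions_give_p_one(self):
        assert fisher_proportion_test(5, 50, 5, 50) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "k1,n1,k2,n2",
        [(3, 10, 0, 10), (5, 5, 0, 5), (2, 8, 6, 9), (0, 4, 0, 6), (7, 12, 1, 15)],
    )
    def test_matches_hypergeometric_enumeration(self, k1, n1, k2, n2):
        assert fisher_proportion_test(k1, n1, k2, n2) == pytest.approx(
            fisher_exact_two_sided(k1, n1, k2, n2), abs=1e-9
        )

    def test_invalid_counts_raise(self):
        with pytest.raises(ValueError):
            fisher_proportion_test(6, 5, 0, 5)


class TestRnkExport:
    def _records(self, genes, log2fc):
        return pd.DataFrame({"gene": genes, "log2fc": log2fc})

    def test_descending_order(self, tmp_path):
        path = tmp_path / "out.rnk"
        export_rnk(self._records(["dn", "up"], [-1.0, 1.0]), path)
        lines = path.read_text().splitlines()
        assert lines[0].split("\t")[0] == "up"
        assert lines[1].split("\t")[0] == "dn"

    def test_ties_break_lexicographically(self, tmp_path):
        path = tmp_path / "out.rnk"
        export_rnk(self._records(["zz", "aa", "mm"], [0.5, 0.5, 0.5]), path)
        assert [l.split("\t")[0] for l in path.read_text().splitlines()] == ["aa", "mm", "zz"]

    def test_round_trip_preserves_six_decimals(self, tmp_path):
        path = tmp_path / "out.rnk"
        values = [1.2345678, -0.7654321]
        export_rnk(self._records(["a", "b"], values), path)
        back = pd.read_csv(path, sep="\t", header=None, names=["gene", "log2fc"])
        assert np.allclose(back["log2fc"], np.round(values, 6), atol=5e-7)

    def test_empty_records_raise(self, tmp_path):
        with pytest.raises(ValueError):
            export_rnk(pd.DataFrame(columns=["gene", "log2fc"]), tmp_path / "x.rnk")
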