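"""Response signatures: per-line logFC, group contrast, target sets, overlaps."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chemoscreen.core_io import ExpressionMatrix
from chemoscreen.signature import (
    baseline_group_de,
    compute_cpm,
    compute_tpm,
    define_target_set,
    downregulated_overlap,
    group_response_contrast,
    panel_response,
    pca_scores,
    per_line_response,
)
from chemoscreen.simulate import ExpressionSimConfig, simulate_expression_panel


def panel_from_counts(cols, genes, meta_rows):
    counts = pd.DataFrame(cols, index=genes)
    meta = pd.DataFrame(
        meta_rows, columns=["sample", "cell_line", "group", "treatment", "replicate"]
    ).set_index("sample")
    return ExpressionMatrix(counts=counts, meta=meta)


class TestPerLineResponse:
    def test_identical_arms_give_zero_logfc_p_one(self):
        genes = [f"g{i}" for i in range(30)]
        y = np.arange(10, 40)
        panel = panel_from_counts(
            {"L_dmso": y, "L_treated": y},
            genes,
            [("L_dmso", "L", "sensitive", "dmso", 1), ("L_treated", "L", "sensitive", "treated", 1)],
        )
        out = per_line_response(panel, "L")
        assert np.allclose(out["logfc"], 0.0, atol=1e-12)
        assert np.allclose(out["pvalue"], 1.0)

    def test_vanishing_gene_has_finite_negative_logfc(self, rng):
        genes = [f"g{i}" for i in range(50)]
        base = rng.integers(100, 400, 50)
        treated = base.copy()
        treated[0] = 0
        base[0] = 2000
        panel = panel_from_counts(
            {"L_dmso": base, "L_treated": treated},
            genes,
            [("L_dmso", "L", "sensitive", "dmso", 1), ("L_treated", "L", "sensitive", "treated", 1)],
        )
        out = per_line_response(panel, "L")
        assert np.isfinite(out["logfc"].iloc[0]) and out["logfc"].iloc[0] < -2

    def test_missing_arm_rejected(self, tiny_panel):
        with pytest.raises(ValueError, match="lacks"):
            per_line_response(tiny_panel, "no_such_line")

    def test_replicated_line_uses_lrt(self, rng):
        genes = [f"g{i}" for i in range(40)]
        cols, meta = {}, []
        for rep in (1, 2):
            cols[f"L_d{rep}"] = rng.integers(50, 300, 40)
            cols[f"L_t{rep}"] = rng.integers(50, 300, 40)
            meta.append((f"L_d{rep}", "L", "sensitive", "dmso", rep))
            meta.append((f"L_t{rep}", "L", "sensitive", "treated", rep))
        panel = panel_from_counts(cols, genes, meta)
        out = per_line_response(panel, "L")
        assert out["pvalue"].between(0, 1).all()


class TestGroupContrast:
    def _logfc(self, sens, insens):
        lines = [f"s{i}" for i in range(len(sens.T))] + [f"i{i}" for i in range(len(insens.T))]
        mat = pd.DataFrame(
            np.column_stack([sens, insens]),
            columns=lines,
            index=[f"g{i}" for i in range(len(sens))],
        )
        groups = {c: ("sensitive" if c.startswith("s") else "insensitive") for c in lines}
        return mat, groups

    def test_all_zero_gives_delta_zero_p_one(self):
        mat, groups = self._logfc(np.zeros((5, 3)), np.zeros((5, 3)))
        out = group_response_contrast(mat, groups)
        assert (out["delta"] == 0).all()
        assert (out["pvalue"] == 1).all()

    def test_clear_shift_recovered(self, rng):
        sens = -1.0 + rng.normal(0, 1e-6, (10, 6))
        insens = rng.normal(0, 1e-6, (10, 6))
        mat, groups = self._logfc(sens, insens)
        out = group_response_contrast(mat, groups)
        assert np.allclose(out["delta"], -1.0, atol=1e-5)

    def test_matches_welch_oracle(self, rng):
        sens = rng.normal(size=(25, 6))
        insens = rng.normal(size=(25, 6))
        mat, groups = self._logfc(sens, insens)
        out = group_response_contrast(mat, groups)
        for i in range(25):
            t, p = stats.ttest_ind(sens[i], insens[i], equal_var=False)
            assert out["pvalue"].iloc[i] == pytest.approx(p, abs=1e-10)
            assert out["delta"].iloc[i] == pytest.approx(sens[i].mean() - insens[i].mean(), abs=1e-12)

    def test_delta_antisymmetric_under_group_swap(self, rng):
        sens = rng.normal(size=(10, 6))
        insens = rng.normal(size=(10, 6))
        mat, groups = self._logfc(sens, insens)
        fwd = group_response_contrast(mat, groups)
        swapped = {c: ("insensitive" if g == "sensitive" else "sensitive") for c, g in groups.items()}
        rev = group_response_contrast(mat, swapped)
        assert np.allclose(fwd["delta"], -rev["delta"], atol=1e-14)
        assert np.allclose(fwd["pvalue"], rev["pvalue"], atol=1e-14)

    def test_invariant_to_gene_order(self, rng):
        sens = rng.normal(size=(12, 6))
        insens = rng.normal(size=(12, 6))
        mat, groups = self._logfc(sens, insens)
        out = group_response_contrast(mat, groups)
        shuffled = mat.sample(frac=1, random_state=1)
        out2 = group_response_contrast(shuffled, groups)
        pd.testing.assert_frame_equal(out.loc[mat.index], out2.loc[mat.index])

    def test_degenerate_zero_variance_flagged(self):
        mat, groups = self._logfc(np.full((3, 2), -1.0), np.zeros((3, 2)))
        out = group_response_contrast(mat, groups)
        assert out["degenerate"].all()
        assert (out["pvalue"] == np.finfo(float).tiny).all()

    def test_small_group_rejected(self):
        mat, groups = self._logfc(np.zeros((3, 1)), np.zeros((3, 3)))
        with pytest.raises(ValueError, match="at least 2"):
            group_response_contrast(mat, groups)


class TestTargetSet:
    def _contrast(self, rows):
        return pd.DataFrame(rows, columns=["delta", "pvalue"], index=[f"g{i}" for i in range(len(rows))])

    def test_threshold_semantics(self):
        con = self._contrast(
            [
                (-0.9, 1e-12),  # in
                (-0.9, 1e-10),  # out: p strict
                (-0.7, 1e-12),  # in: lfc inclusive at 0.7
                (-0.5, 1e-12),  # out: lfc
                (0.9, 1e-12),  # out: wrong direction
            ]
        )
        got = define_target_set(con, lfc_threshold=0.7, p_threshold=1e-10).genes
        assert got == {"g0", "g2"}

    def test_five_gene_manual_evaluation(self):
        con = self._contrast(
            [(-1.2, 1e-15), (-0.68, 1e-11), (-0.67, 1e-15), (-2.0, 1e-9), (-3.0, 0.0)]
        )
        got = define_target_set(con, 0.68, 1e-10, "down").genes
        assert got == {"g0", "g1", "g4"}

    def test_monotone_in_thresholds(self, rng):
        con = self._contrast(
            np.column_stack([rng.normal(0, 1, 50), 10 ** -rng.uniform(0, 15, 50)])
        )
        tight = define_target_set(con, 0.9, 1e-8).genes
        loose_lfc = define_target_set(con, 0.5, 1e-8).genes
        loose_p = define_target_set(con, 0.9, 1e-3).genes
        assert tight <= loose_lfc and tight <= loose_p

    def test_up_direction(self):
        con = self._contrast([(0.9, 1e-12), (-0.9, 1e-12)])
        assert define_target_set(con, 0.7, 1e-10, "up").genes == {"g0"}


class TestBaselineDe:
    def test_identical_groups_give_empty_sets(self, rng):
        genes = [f"g{i}" for i in range(100)]
        cols, meta = {}, []
        base = rng.integers(50, 500, 100)
        for i in range(6):
            line = f"s{i}" if i < 3 else f"i{i}"
            group = "sensitive" if i < 3 else "insensitive"
            cols[line] = rng.poisson(base)
            meta.append((line, line, group, "dmso", 1))
        panel = panel_from_counts(cols, genes, meta)
        res = baseline_group_de(panel)
        assert res["up"] == set() and res["down"] == set()

    def test_planted_fold_changes_low_noise(self, rng):
        # 8-fold genes pass the 4-fold filter, 2-fold genes are excluded
        genes = [f"g{i}" for i in range(200)]
        base = np.full(200, 400.0)
        shift = np.zeros(200)
        shift[:10] = 3.0  # 8-fold up in sensitive
        shift[10:20] = 1.0  # 2-fold: excluded by the fold filter
        cols, meta = {}, []
        for i in range(12):
            sens = i < 6
            name = f"{'s' if sens else 'i'}{i}"
            mu = base * (2.0**shift if sens else 1.0)
            cols[name] = rng.poisson(mu)
            meta.append((name, name, "sensitive" if sens else "insensitive", "dmso", 1))
        panel = panel_from_counts(cols, genes, meta)
        res = baseline_group_de(panel, dispersion=0.01)
        assert set(genes[:10]) <= res["up"]
        assert res["up"].isdisjoint(genes[10:20])

    def test_exact_fourfold_boundary_included(self):
        # logfc exactly 2 and padj exactly at threshold are both inclusive
        table = pd.DataFrame(
            {"logfc": [2.0, 1.99], "pvalue": [1e-12, 1e-12], "padj": [1e-10, 1e-10]},
            index=["a", "b"],
        )
        lfc_cut = np.log2(4.0)
        up = set(table.index[(table["logfc"] >= lfc_cut) & (table["padj"] <= 1e-10)])
        assert up == {"a"}


class TestOverlap:
    def _results(self, sets, universe):
        out = {}
        for name, members in sets.items():
            out[name] = pd.DataFrame(
                {
                    "logfc": [-1.0 if g in members else 0.5 for g in universe],
                    "padj": [1e-3 if g in members else 0.5 for g in universe],
                },
                index=universe,
            )
        return out

    def test_disjoint_sets_have_empty_triple(self):
        uni = [f"g{i}" for i in range(9)]
        res = self._results({"a": uni[:3], "b": uni[3:6], "c": uni[6:]}, uni)
        out = downregulated_overlap(res)
        assert out["regions"]["111"] == 0

    def test_nested_sets_triple_equals_smallest(self):
        uni = [f"g{i}" for i in range(10)]
        res = self._results({"a": uni[:2], "b": uni[:5], "c": uni[:8]}, uni)
        out = downregulated_overlap(res)
        assert out["regions"]["111"] == 2

    def test_regions_satisfy_inclusion_exclusion(self, rng):
        uni = [f"g{i}" for i in range(60)]
        sets = {k: list(rng.choice(uni, size=rng.integers(5, 40), replace=False)) for k in "abc"}
        res = self._results(sets, uni)
        out = downregulated_overlap(res)
        regions = out["regions"]
        for name, mask in zip("abc", ["1..", ".1.", "..1"]):
            total = sum(v for k, v in regions.items() if all(m == "." or k[i] == m for i, m in enumerate(mask)))
            assert total == len(out["sets"][name])
        union = len(set().union(*out["sets"].values()))
        assert sum(regions.values()) == union

    def test_extra_fold_filter_restricts_last_condition(self):
        uni = ["a", "b"]
        res = self._results({"x": uni, "y": uni, "z": uni}, uni)
        res["z"].loc["a", "logfc"] = -0.3  # above -log2(1.5): filtered out
        out = downregulated_overlap(res, extra_fold=1.5)
        assert out["sets"]["z"] == {"b"}

    def test_padj_boundary_inclusive(self):
        uni = ["a"]
        res = self._results({"x": uni, "y": uni, "z": uni}, uni)
        for k in res:
            res[k]["padj"] = 0.01
        out = downregulated_overlap(res, padj_threshold=0.01)
        assert out["regions"]["111"] == 1


class TestCpmTpm:
    def test_cpm_example(self):
        counts = pd.DataFrame({"s": [1, 1, 2]}, index=list("abc"))
        out = compute_cpm(counts)
        assert list(out["s"]) == [250000.0, 250000.0, 500000.0]

    def test_tpm_columns_sum_to_million(self, rng):
        counts = pd.DataFrame(rng.integers(1, 500, (20, 4)), index=[f"g{i}" for i in range(20)])
        lengths = pd.Series(rng.integers(200, 5000, 20), index=counts.index)
        out = compute_tpm(counts, lengths)
        assert np.allclose(out.sum(axis=0), 1e6)

    def test_formula_oracle(self, rng):
        counts = pd.DataFrame(rng.integers(0, 500, (15, 3)), index=[f"g{i}" for i in range(15)])
        lengths = pd.Series(rng.integers(100, 2000, 15), index=counts.index)
        cpm = compute_cpm(counts)
        assert np.allclose(cpm.to_numpy(), counts.to_numpy() * 1e6 / counts.sum(axis=0).to_numpy())
        rate = counts.to_numpy() / lengths.to_numpy()[:, None]
        assert np.allclose(compute_tpm(counts, lengths).to_numpy(), rate * 1e6 / rate.sum(axis=0))

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError, match="library"):
            compute_cpm(pd.DataFrame({"s": [0, 0]}))


class TestPca:
    def test_duplicated_sample_gets_identical_coordinates(self, rng):
        x = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        x["e"] = x["a"]
        out = pca_scores(x, 2)
        assert np.allclose(out.loc["a"], out.loc["e"], atol=1e-10)

    def test_one_dimensional_structure_explains_everything(self):
        t = np.linspace(0, 1, 6)
        x = pd.DataFrame(np.outer(np.arange(10), t))
        out = pca_scores(x, 1)
        assert out.attrs["explained_variance_ratio"][0] == pytest.approx(1.0, abs=1e-12)

    def test_reconstruction_from_all_components(self, rng):
        x = pd.DataFrame(rng.normal(size=(12, 6)))
        centered = x.to_numpy().T - x.to_numpy().T.mean(axis=0, keepdims=True)
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        assert np.allclose(u @ np.diag(s) @ vt, centered, atol=1e-8)
        rank = 5  # centering removes one dimension from 6 samples
        out = pca_scores(x, rank)  # scores reproduce centered data in the V basis
        assert np.allclose(np.abs(out.to_numpy()), np.abs((u * s)[:, :rank]), atol=1e-8)

    def test_components_beyond_rank_rejected(self):
        x = pd.DataFrame(np.ones((5, 3)))
        with pytest.raises(ValueError, match="rank"):
            pca_scores(x, 2)


class TestEndToEndSignature:
    def test_module_delta_recovered_and_nulls_clean(self):
        panel, truth = simulate_expression_panel(ExpressionSimConfig(), seed=4)
        logfc = panel_response(panel, compute_p=False)
        groups = panel.meta.drop_duplicates("cell_line").set_index("cell_line")["group"]
        con = group_response_contrast(logfc, groups)
        assert con.loc[truth.module, "delta"].mean() == pytest.approx(-1.0, abs=0.15)
        nulls = con.index.difference(truth.module)
        target = define_target_set(con, 0.5, 1e-3, "down")
        contamination = np.mean([g in target.genes for g in nulls])
        assert contamination <= 0.01

    def test_no_planted_difference_t_test_calibrated(self):
        cfg = ExpressionSimConfig(n_genes=2000, module_effect=0.0, baseline_de_fraction=0.0)
        panel, _ = simulate_expression_panel(cfg, seed=13)
        logfc = panel_response(panel, compute_p=False)
        groups = panel.meta.drop_duplicates("cell_line").set_index("cell_line")["group"]
        con = group_response_contrast(logfc, groups)
        frac = (con["pvalue"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07
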