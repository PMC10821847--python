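"""Single-cell signature score and mutant-allele proportions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neoprior import (
    CellSiteCounts,
    ValidationError,
    compare_proportions,
    compare_scores,
    mutant_cell_proportion,
    signature_score,
)
from neoprior.sc_expression import (
    GroupProportion,
    read_cell_counts_tsv,
    read_expression_matrix,
    write_cell_counts_tsv,
)


def make_matrix(rng, n_cells=200, n_genes=120):
    baselines = rng.uniform(0, 3, size=n_genes)
    mat = baselines + rng.normal(0, 0.3, size=(n_cells, n_genes))
    return pd.DataFrame(mat,
                        index=[f"c{i:03d}" for i in range(n_cells)],
                        columns=[f"g{i:03d}" for i in range(n_genes)])


SIG = ["g005", "g030", "g055", "g080", "g105"]


class TestSignatureScore:
    def test_constant_matrix_scores_zero(self):
        expr = pd.DataFrame(np.full((50, 40), 1.7),
                            index=[f"c{i}" for i in range(50)],
                            columns=[f"g{i:03d}" for i in range(40)])
        scores = signature_score(expr, ["g001", "g002"], n_bins=4, seed=0)
        assert np.allclose(scores.values, 0.0)

    def test_global_shift_invariance(self):
        rng = np.random.default_rng(0)
        expr = make_matrix(rng)
        s1 = signature_score(expr, SIG, seed=1)
        s2 = signature_score(expr + 3.0, SIG, seed=1)
        assert np.allclose(s1.values, s2.values)

    def test_planted_shift_recovered(self):
        """+1 log-unit on the signature genes in half the cells moves the
        mean score difference between halves to ~1."""
        rng = np.random.default_rng(2)
        expr = make_matrix(rng, n_cells=400)
        shifted = expr.copy()
        half = expr.index[:200]
        shifted.loc[half, SIG] += 1.0
        scores = signature_score(shifted, SIG, seed=3)
        diff = scores[half].mean() - scores[expr.index[200:]].mean()
        assert diff == pytest.approx(1.0, abs=0.1)

    def test_cell_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        expr = make_matrix(rng, n_cells=80)
        perm = rng.permutation(expr.index)
        s1 = signature_score(expr, SIG, seed=5)
        s2 = signature_score(expr.loc[perm], SIG, seed=5)
        assert np.allclose(s1.loc[perm].values, s2.values)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        expr = make_matrix(rng)
        assert signature_score(expr, SIG, seed=7).equals(
            signature_score(expr, SIG, seed=7))

    def test_missing_genes_named(self):
        rng = np.random.default_rng(8)
        expr = make_matrix(rng, n_cells=20)
        with pytest.raises(ValidationError, match="gNOPE"):
            signature_score(expr, ["g001", "gNOPE"], seed=0)

    def test_agrees_with_scanpy_score_genes(self):
        """Independent cross-check against the binned-control module score
        in scanpy (same construction, different implementation)."""
        sc = pytest.importorskip("scanpy")
        import anndata as ad

        rng = np.random.default_rng(9)
        expr = make_matrix(rng, n_cells=300, n_genes=150)
        sig = ["g010", "g060", "g110"]
        # plant a gradient on the signature genes so both implementations
        # track a shared signal above their (different) control draws
        gradient = np.linspace(0.0, 2.0, len(expr))
        expr[sig] = expr[sig].add(gradient, axis=0)
        ours = signature_score(expr, sig, n_bins=25, n_ctrl=100, seed=0)
        adata = ad.AnnData(expr.values,
                           obs=pd.DataFrame(index=expr.index),
                           var=pd.DataFrame(index=expr.columns))
        sc.tl.score_genes(adata, sig, ctrl_size=100, n_bins=25,
                          score_name="sc_score", random_state=0)
        theirs = adata.obs["sc_score"].values
        r = np.corrcoef(ours.values, theirs)[0, 1]
        assert r > 0.95
        # both recover the planted gradient slope
        slope_ours = np.polyfit(gradient, ours.values, 1)[0]
        slope_theirs = np.polyfit(gradient, theirs, 1)[0]
        assert slope_ours == pytest.approx(1.0, abs=0.1)
        assert slope_theirs == pytest.approx(1.0, abs=0.1)


def cell(cid, group, **sites):
    return CellSiteCounts(cell=cid, group=group,
                          counts={k: tuple(v) for k, v in sites.items()})


SITES = ["Metap1_T84S", "Kat2a_V192I", "Dhrs9_L146P"]


class TestMutantCellProportion:
    def test_basic_proportion(self):
        cells = [cell(f"c{i}", "PBS", **{SITES[0]: (2, 1 if i < 3 else 0)})
                 for i in range(10)]
        res = mutant_cell_proportion(cells, SITES, {c.cell for c in cells})
        assert res["PBS"].covered == 10
        assert res["PBS"].mutant == 3
        assert res["PBS"].proportion == pytest.approx(0.3)

    def test_cell_covering_only_non_signature_site_excluded(self):
        cells = [
            cell("c0", "PBS", **{SITES[0]: (1, 0)}),
            cell("c1", "PBS", Other_G1A=(5, 2)),   # not a queried site
        ]
        res = mutant_cell_proportion(cells, SITES, {"c0", "c1"})
        assert res["PBS"].covered == 1

    def test_non_tumor_cells_excluded(self):
        cells = [cell("c0", "PBS", **{SITES[0]: (1, 1)}),
                 cell("c1", "PBS", **{SITES[0]: (1, 1)})]
        res = mutant_cell_proportion(cells, SITES, {"c0"})
        assert res["PBS"].covered == 1 and res["PBS"].mutant == 1

    def test_zero_coverage_group_undefined(self):
        cells = [cell("c0", "PBS", Other_G1A=(3, 0))]
        res = mutant_cell_proportion(cells, SITES, {"c0"})
        assert res["PBS"].covered == 0 and res["PBS"].proportion is None

    def test_invariant_to_cell_order_and_zero_count_sites(self):
        rng = np.random.default_rng(0)
        cells = []
        for i in range(60):
            c = cell(f"c{i}", "PBS",
                     **{SITES[i % 3]: (int(rng.integers(0, 3)),
                                       int(rng.integers(0, 2)))})
            c.counts["Zero_S1A"] = (0, 0)  # zero-count site: no coverage
            cells.append(c)
        tumor = {c.cell for c in cells}
        a = mutant_cell_proportion(cells, SITES, tumor)["PBS"]
        b = mutant_cell_proportion(list(reversed(cells)), SITES, tumor)["PBS"]
        assert (a.covered, a.mutant) == (b.covered, b.mutant)

    def test_min_alt_reads_threshold(self):
        cells = [cell("c0", "PBS", **{SITES[0]: (3, 1)})]
        tumor = {"c0"}
        assert mutant_cell_proportion(cells, SITES, tumor)["PBS"].mutant == 1
        assert mutant_cell_proportion(cells, SITES, tumor,
                                      min_alt_reads=2)["PBS"].mutant == 0


def fisher_by_enumeration(table):
    """Two-sided Fisher p by direct hypergeometric summation."""
    (a, b), (c, d) = table
    n, K, N = a + b + c + d, a + c, a + b
    rv = stats.hypergeom(n, K, N)
    p_obs = rv.pmf(a)
    return float(sum(rv.pmf(k) for k in range(max(0, N + K - n), min(K, N) + 1)
                     if rv.pmf(k) <= p_obs * (1 + 1e-9)))


class TestGroupComparison:
    def test_identical_groups_fisher_p_one(self):
        per_group = {"PBS": GroupProportion("PBS", 100, 30),
                     "combined": GroupProportion("combined", 100, 30)}
        res = compare_proportions(per_group, reference="PBS")
        assert res["combined"].p_value == pytest.approx(1.0)

    def test_fisher_matches_hypergeometric_enumeration(self):
        per_group = {"PBS": GroupProportion("PBS", 100, 30),
                     "combined": GroupProportion("combined", 100, 5)}
        res = compare_proportions(per_group, reference="PBS")
        expected = fisher_by_enumeration([[5, 95], [30, 70]])
        assert res["combined"].p_value == pytest.approx(expected, rel=1e-6)

    def test_label_swap_symmetry(self):
        a = {"PBS": GroupProportion("PBS", 80, 25),
             "tx": GroupProportion("tx", 90, 10)}
        b = {"PBS": GroupProportion("PBS", 90, 10),
             "tx": GroupProportion("tx", 80, 25)}
        pa = compare_proportions(a, "PBS")["tx"].p_value
        pb = compare_proportions(b, "PBS")["tx"].p_value
        assert pa == pytest.approx(pb)

    def test_degenerate_table_flagged(self):
        per_group = {"PBS": GroupProportion("PBS", 0, 0),
                     "tx": GroupProportion("tx", 10, 3)}
        res = compare_proportions(per_group, "PBS")
        assert res["tx"].p_value == 1.0
        assert "degenerate table" in res["tx"].flags

    def test_wilcoxon_type_one_error_under_null(self):
        """Random label splits of one distribution reject at ~alpha."""
        rng = np.random.default_rng(1)
        values = pd.Series(rng.normal(size=300),
                           index=[f"c{i}" for i in range(300)])
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            labels = pd.Series(
                np.where(rng.random(300) < 0.5, "a", "ref"),
                index=values.index)
            if (labels == "a").sum() < 2 or (labels == "ref").sum() < 2:
                continue
            p = compare_scores(values, labels, "ref")["a"].p_value
            rejections += p < 0.05
        assert 0.02 <= rejections / n_rep <= 0.08

    def test_score_comparison_detects_shift(self):
        rng = np.random.default_rng(2)
        values = pd.Series(
            np.concatenate([rng.normal(0, 1, 150), rng.normal(1, 1, 150)]),
            index=[f"c{i}" for i in range(300)])
        labels = pd.Series(["ref"] * 150 + ["tx"] * 150, index=values.index)
        assert compare_scores(values, labels, "ref")["tx"].p_value < 1e-6


class TestIO:
    def test_cell_counts_roundtrip(self, tmp_path):
        cells = [cell("c0", "PBS", **{SITES[0]: (2, 1)}),
                 cell("c1", "combined", **{SITES[1]: (1, 0), SITES[2]: (0, 2)})]
        path = tmp_path / "cc.tsv"
        write_cell_counts_tsv(cells, path)
        back = read_cell_counts_tsv(path)
        assert {c.cell: c.counts for c in back} == \
            {c.cell: c.counts for c in cells}

    def test_cell_in_two_groups_rejected(self, tmp_path):
        path = tmp_path / "cc.tsv"
        path.write_text("cell\tgroup\tsite_id\tref_reads\talt_reads\n"
                        "c0\tPBS\ts1\t1\t0\nc0\tcombined\ts2\t1\t0\n")
        with pytest.raises(ValidationError, match="two groups"):
            read_cell_counts_tsv(path)

    def test_mtx_matrix_reader(self, tmp_path):
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        rng = np.random.default_rng(3)
        dense = rng.uniform(0, 2, size=(4, 6))   # genes x cells on disk
        mmwrite(str(tmp_path / "m.mtx"), csr_matrix(dense))
        (tmp_path / "genes.txt").write_text("".join(f"g{i}\n" for i in range(4)))
        (tmp_path / "cells.txt").write_text("".join(f"c{i}\n" for i in range(6)))
        df = read_expression_matrix(tmp_path / "m.mtx",
                                    tmp_path / "genes.txt",
                                    tmp_path / "cells.txt")
        assert df.shape == (6, 4)  # cells x genes after transpose
        assert np.allclose(df.values, dense.T)
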