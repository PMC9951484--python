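"""PEM construction and K-S cell-type enrichment contracts."""

import numpy as np
import pandas as pd
import pytest

import braintx as bt
from braintx.containers import CellTypeProfiles
from braintx.simulate import planted_de_table


def _ks_brute_force(a, b):
    """Sup of |ECDF_a - ECDF_b| over the pooled points, by enumeration."""
    a = np.sort(np.asarray(a, float))
    b = np.sort(np.asarray(b, float))
    best = 0.0
    for x in np.concatenate([a, b]):
        fa = np.mean(a <= x)
        fb = np.mean(b <= x)
        best = max(best, abs(fa - fb))
    return best


class TestPseudobulk:
    def test_identical_cells_give_exact_means(self):
        import anndata as ad

        counts = np.array([[4, 0, 6], [4, 0, 6], [1, 2, 3], [1, 2, 3]])
        adata = ad.AnnData(
            X=counts,
            obs=pd.DataFrame({"class": ["t1", "t1", "t2", "t2"]},
                             index=[f"c{i}" for i in range(4)]),
            var=pd.DataFrame(index=["g1", "g2", "g3"]),
        )
        prof = bt.pseudobulk_means(adata, min_cells=1, normalize=None)
        assert np.allclose(prof.X["t1"], [4, 0, 6])
        assert np.allclose(prof.X["t2"], [1, 2, 3])
        assert np.allclose(prof.S, prof.X.sum(axis=0))

    def test_cp10k_normalization(self):
        import anndata as ad

        counts = np.array([[10, 10], [30, 10], [1, 1], [3, 1]])
        adata = ad.AnnData(
            X=counts,
            obs=pd.DataFrame({"class": ["t1", "t1", "t2", "t2"]},
                             index=[f"c{i}" for i in range(4)]),
            var=pd.DataFrame(index=["g1", "g2"]),
        )
        prof = bt.pseudobulk_means(adata, min_cells=1, normalize="cp10k")
        # each cell scaled to 10k first, then averaged:
        # t1: (5000,5000) and (7500,2500) -> (6250,3750); same for t2
        assert np.allclose(prof.X["t1"], [6250.0, 3750.0])
        assert np.allclose(prof.X["t2"], [6250.0, 3750.0])

    def test_small_types_dropped_with_warning(self, caplog):
        import anndata as ad

        adata = ad.AnnData(
            X=np.ones((5, 3), dtype=np.int64),
            obs=pd.DataFrame({"class": ["a", "a", "b", "b", "c"]},
                             index=[f"c{i}" for i in range(5)]),
            var=pd.DataFrame(index=["g1", "g2", "g3"]),
        )
        with caplog.at_level("WARNING", logger="braintx.enrichment"):
            prof = bt.pseudobulk_means(adata, min_cells=2)
        assert list(prof.cell_types) == ["a", "b"]
        assert any("dropped" in r.message for r in caplog.records)

    def test_unknown_level_rejected(self, small_reference):
        with pytest.raises(ValueError, match="unknown label level"):
            bt.pseudobulk_means(small_reference, level="lineage")

    def test_recovers_generator_profiles(self, small_reference, small_config):
        from braintx.simulate import type_profiles

        prof = bt.pseudobulk_means(small_reference, normalize="cp10k")
        P = type_profiles(small_config)
        for ctype in small_config.cell_types:
            expected = P[ctype] / P[ctype].sum() * 1e4
            observed = prof.X[ctype]
            keep = expected >= 1
            rel = (observed[keep] - expected[keep]).abs() / expected[keep]
            # 40 cells/type: means track the generating profiles closely
            assert rel.median() < 0.15


class TestComputePEM:
    def test_uniform_two_by_two_is_zero(self):
        prof = CellTypeProfiles(
            pd.DataFrame([[10.0, 10.0], [30.0, 30.0]],
                         index=["g1", "g2"], columns=["t1", "t2"])
        )
        pem = bt.compute_pem(prof, pseudocount=0.0)
        assert np.allclose(pem.pem.to_numpy(), 0.0, atol=1e-12)

    def test_hand_computed_asymmetric_case(self):
        prof = CellTypeProfiles(
            pd.DataFrame([[90.0, 10.0], [10.0, 90.0]],
                         index=["g1", "g2"], columns=["t1", "t2"])
        )
        pem = bt.compute_pem(prof, pseudocount=0.0)
        # S = [100, 100]; gene1: EE = (200/100)*(90/100) = 1.8 and 0.2
        assert pem.pem.loc["g1", "t1"] == pytest.approx(np.log10(1.8), abs=1e-12)
        assert pem.pem.loc["g1", "t2"] == pytest.approx(np.log10(0.2), abs=1e-12)
        assert pem.pem.loc["g2", "t1"] == pytest.approx(np.log10(0.2), abs=1e-12)

    def test_columns_proportional_to_totals_give_zero(self):
        rng = np.random.default_rng(3)
        c = rng.uniform(1, 5, size=8)
        S = np.array([1.0, 2.0, 4.0])
        prof = CellTypeProfiles(
            pd.DataFrame(np.outer(c, S), columns=["t1", "t2", "t3"])
        )
        pem = bt.compute_pem(prof, pseudocount=0.0)
        assert np.allclose(pem.pem.to_numpy(), 0.0, atol=1e-12)

    def test_conservation_identity_random_matrices(self):
        """sum_i 10^pem[g,i] * S_i / sum(S) == 1 for every gene."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            X = rng.gamma(0.6, 50, size=(rng.integers(3, 40),
                                         rng.integers(2, 12)))
            X[rng.uniform(size=X.shape) < 0.3] = 0.0
            prof = CellTypeProfiles(pd.DataFrame(X))
            pem = bt.compute_pem(prof, pseudocount=1e-3)
            weights = (pem.S / pem.S.sum()).to_numpy()
            cons = (10 ** pem.pem.to_numpy() * weights[None, :]).sum(axis=1)
            assert np.abs(cons - 1).max() < 1e-9

    def test_column_scaling_metamorphic(self):
        """Scaling one type's depth changes PEM exactly as re-evaluating the
        formula on the scaled matrix predicts."""
        rng = np.random.default_rng(5)
        X = rng.gamma(1.0, 20, size=(30, 4))
        scaled = X.copy()
        scaled[:, 2] *= 7.5
        pem_direct = bt.compute_pem(
            CellTypeProfiles(pd.DataFrame(scaled)), pseudocount=0.0
        )
        pem_manual = bt.compute_pem(
            CellTypeProfiles(pd.DataFrame(X)), pseudocount=0.0
        )
        S = X.sum(axis=0) * np.array([1, 1, 7.5, 1])
        expected = (
            np.log10(S.sum() / S)[None, :]
            + np.log10(scaled / scaled.sum(axis=1, keepdims=True))
        )
        assert np.allclose(pem_direct.pem.to_numpy(), expected, atol=1e-12)
        assert not np.allclose(
            pem_direct.pem.to_numpy(), pem_manual.pem.to_numpy()
        )

    def test_zero_pseudocount_with_zeros_rejected(self):
        prof = CellTypeProfiles(
            pd.DataFrame([[1.0, 0.0], [2.0, 3.0]], columns=["a", "b"])
        )
        with pytest.raises(ValueError, match="pseudocount"):
            bt.compute_pem(prof, pseudocount=0.0)
        with pytest.raises(ValueError, match="non-negative"):
            bt.compute_pem(prof, pseudocount=-1.0)


class TestKSEnrichment:
    def _pem_from(self, values: dict[str, list[float]]) -> pd.DataFrame:
        genes = [f"g{i}" for i in range(len(next(iter(values.values()))))]
        return pd.DataFrame(values, index=genes)

    def test_hand_case_sup_gap(self):
        # DEG PEM {0.15, 0.35} vs background {0.1, 0.2, 0.3}: the ECDF gap
        # peaks at 0.3 -> D = |1/2 - 3/3| = 0.5
        pem = self._pem_from({"t": [0.15, 0.35, 0.1, 0.2, 0.3]})
        res = bt.ks_enrichment(pem, ["g0", "g1"], ["g2", "g3", "g4"],
                               min_genes=2)
        assert res.table.loc["t", "D"] == pytest.approx(0.5)

    def test_complete_separation(self):
        pem = self._pem_from({"t": [5.0, 6.0, 7.0, 0.1, 0.2, 0.3, 0.4]})
        res = bt.ks_enrichment(pem, ["g0", "g1", "g2"],
                               ["g3", "g4", "g5", "g6"], min_genes=3)
        assert res.table.loc["t", "D"] == pytest.approx(1.0)
        assert res.table.loc["t", "shift_sign"] == 1
        assert res.table.loc["t", "p"] < 0.05

    def test_matches_brute_force_on_random_instances(self, small_pem):
        rng = np.random.default_rng(17)
        pem = small_pem.pem
        genes = list(pem.index)
        for _ in range(50):
            idx = rng.permutation(len(genes))[:50]
            cut = rng.integers(10, 40)
            deg = [genes[i] for i in idx[:cut]]
            bg = [genes[i] for i in idx[cut:]]
            res = bt.ks_enrichment(pem, deg, bg, min_genes=5)
            for ctype in pem.columns:
                expected = _ks_brute_force(
                    pem.loc[deg, ctype], pem.loc[bg, ctype]
                )
                assert res.table.loc[ctype, "D"] == pytest.approx(
                    expected, abs=1e-12
                )

    def test_overlapping_sets_rejected(self, small_pem):
        genes = list(small_pem.pem.index)
        with pytest.raises(ValueError, match="overlap"):
            bt.ks_enrichment(small_pem, genes[:20], genes[10:40])

    def test_too_few_genes_rejected(self, small_pem):
        genes = list(small_pem.pem.index)
        with pytest.raises(ValueError, match="at least"):
            bt.ks_enrichment(small_pem, genes[:3], genes[10:200])

    def test_missing_genes_dropped_and_counted(self, small_pem):
        genes = list(small_pem.pem.index)
        deg = genes[:20] + ["absent_1", "absent_2"]
        res = bt.ks_enrichment(small_pem, deg, genes[20:200])
        assert res.n_deg_missing == 2
        assert (res.table["n_deg_used"] == 20).all()

    def test_padj_bh_within_call(self, small_pem):
        genes = list(small_pem.pem.index)
        res = bt.ks_enrichment(small_pem, genes[:30], genes[30:300])
        assert np.allclose(
            res.table["padj"], bt.adjust_bh(res.table["p"].to_numpy())
        )

    def test_null_sets_calibrated(self, small_pem):
        rng = np.random.default_rng(23)
        genes = list(small_pem.pem.index)
        fp = []
        for _ in range(40):
            idx = rng.permutation(len(genes))
            deg = [genes[i] for i in idx[:40]]
            bg = [genes[i] for i in idx[40:]]
            res = bt.ks_enrichment(small_pem, deg, bg)
            fp.append((res.table["padj"] < 0.05).mean())
        assert np.mean(fp) <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / (40 * 16))


class TestPlantedSignalRecovery:
    def test_home_types_rank_top_for_both_directions(self, small_config,
                                                     small_cohort, small_pem):
        """Up-DEGs planted through radial glia and down-DEGs through neurons
        are recovered as the top-enriched types for their own direction."""
        _, truth = small_cohort
        de = truth.de_table
        background = [g for g in small_pem.pem.index
                      if g not in set(de["gene"])]
        for direction, home in (("up", "radial_glia"), ("down", "neuron")):
            genes = de.loc[de["direction"] == direction, "gene"].tolist()
            res = bt.ks_enrichment(small_pem, genes, background,
                                   alternative="greater", min_genes=5)
            assert res.table["padj"].idxmin() == home
            assert res.table.loc[home, "shift_sign"] == 1
            others = res.table.drop(index=home)
            assert (others["padj"] < 0.05).sum() == 0
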