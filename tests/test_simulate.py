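"""Generator contracts: determinism, planted structure, mixture identity."""

import numpy as np
import pandas as pd
import pytest

import braintx as bt
from braintx.simulate import (
    DEFAULT_CELL_TYPES,
    marker_table,
    planted_de_table,
    type_profiles,
)


class TestConfig:
    def test_default_fractions_match_study_composition(self):
        cfg = bt.SimulationConfig()
        frac = pd.Series(cfg.base_fractions, index=cfg.cell_types)
        assert frac.sum() == pytest.approx(1.0)
        assert frac["neuron"] == pytest.approx(0.5394)
        assert frac["neuroblast"] == pytest.approx(0.2423)
        assert frac["glioblast"] == pytest.approx(0.1375)
        assert len(cfg.cell_types) == 16

    def test_default_cohort_structure(self):
        meta = bt.SimulationConfig().sample_table()
        counts = meta.groupby(["condition", "sex"]).size()
        assert counts[("control", "M")] == 5 and counts[("control", "F")] == 4
        assert counts[("stress", "M")] == 3 and counts[("stress", "F")] == 4
        assert meta["batch"].nunique() == 2
        # sex and batch not confounded with condition
        assert meta.groupby("condition")["batch"].nunique().min() == 2

    @pytest.mark.parametrize(
        "kwargs, match",
        [
            (dict(nb_dispersion=0.0), "dispersion"),
            (dict(cell_depth_mean=-1.0), "positive"),
            (dict(base_fractions=[0.5] * 16), "sum to 1"),
            (
                dict(de_spec=[dict(name="x", n_genes=2, cell_types=("nope",),
                                   log2fc=1.0)]),
                "unknown cell types",
            ),
            (dict(fraction_shift={"nope": 0.1}), "unknown cell types"),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            bt.SimulationConfig(**kwargs)

    def test_unknown_config_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown configuration keys"):
            bt.SimulationConfig.from_dict({"n_genes": 100, "bogus": 1})

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("seed: 3\nn_genes: 120\nmarker_fold: 4.0\n")
        cfg = bt.SimulationConfig.from_yaml(path)
        assert (cfg.seed, cfg.n_genes, cfg.marker_fold) == (3, 120, 4.0)

    def test_oversized_region_sizes_rejected(self):
        with pytest.raises(ValueError, match="more voxel slabs"):
            bt.SimulationConfig(grid_shape=(8, 4, 4),
                                region_names=("a", "b"),
                                region_sizes=(6, 6),
                                ish_up_region="a", ish_down_region="b")


class TestReference:
    def test_determinism(self, small_config, small_reference):
        again = bt.simulate_reference(small_config)
        assert np.array_equal(small_reference.X, again.X)
        assert (small_reference.obs["class"] == again.obs["class"]).all()

    def test_all_types_labeled(self, small_reference):
        assert small_reference.obs["class"].nunique() == 16
        assert set(small_reference.obs["class"]) == set(DEFAULT_CELL_TYPES)

    def test_counts_nonnegative_integers(self, small_reference):
        X = np.asarray(small_reference.X)
        assert X.min() >= 0
        assert X.dtype.kind == "i"

    def test_marker_fold_one_gives_uniform_pem(self):
        cfg = bt.SimulationConfig(seed=2, n_genes=300, n_cells_per_type=60,
                                  marker_fold=1.0)
        ref = bt.simulate_reference(cfg)
        pem = bt.compute_pem(bt.pseudobulk_means(ref))
        # no planted preference: PEM hovers near 0 up to sampling noise
        assert np.abs(pem.pem.to_numpy()).mean() < 0.05

    def test_mean_recovery_at_large_n(self):
        cfg = bt.SimulationConfig(seed=5, n_genes=200, n_cell_types=3,
                                  n_cells_per_type=2000,
                                  de_spec=[], fraction_shift={})
        ref = bt.simulate_reference(cfg)
        profiles = bt.pseudobulk_means(ref, normalize=None)
        P = type_profiles(cfg)
        # empirical type means converge to depth x relative profile
        for j, ctype in enumerate(cfg.cell_types):
            cells = ref.obs["class"] == ctype
            depth = np.asarray(ref.X)[cells.to_numpy()].sum(axis=1).mean()
            expected = P[ctype].to_numpy() * depth
            observed = profiles.X[ctype].to_numpy()
            keep = expected >= 1
            rel = np.abs(observed[keep] - expected[keep]) / expected[keep]
            assert np.quantile(rel, 0.95) < 0.05


class TestBulkCohort:
    def test_determinism(self, small_config, small_reference, small_cohort):
        bulk, truth = small_cohort
        bulk2, truth2 = bt.simulate_bulk_cohort(small_config, small_reference)
        pd.testing.assert_frame_equal(bulk.counts, bulk2.counts)
        pd.testing.assert_frame_equal(truth.true_fractions, truth2.true_fractions)

    def test_truth_bookkeeping(self, small_config, small_cohort):
        bulk, truth = small_cohort
        assert np.allclose(truth.true_fractions.sum(axis=1), 1.0)
        assert set(truth.de_table["gene"]) <= set(bulk.counts.index)
        stress = truth.true_fractions[bulk.metadata["condition"] == "stress"]
        control = truth.true_fractions[bulk.metadata["condition"] == "control"]
        shift = stress.iloc[0] - control.iloc[0]
        assert shift["neuroblast"] == pytest.approx(0.03, abs=1e-12)
        assert shift["neuron"] == pytest.approx(-0.03, abs=1e-12)

    def test_mixture_identity_without_noise(self, small_config, small_reference):
        """With nuisance scales at zero and no DE, the expected expression is
        proportional to the fraction-weighted profile mixture."""
        cfg = bt.SimulationConfig(seed=7, n_genes=600, n_cells_per_type=40,
                                  de_spec=[], fraction_shift={},
                                  batch_effect_sd=0.0, sex_effect_sd=0.0)
        ref = bt.simulate_reference(cfg)
        _, truth = bt.simulate_bulk_cohort(cfg, ref)
        P = type_profiles(cfg)
        mix = P.to_numpy() @ cfg.base_fractions
        for col in truth.expected_means.columns:
            expected = truth.expected_means[col].to_numpy()
            ratio = expected / mix
            assert np.allclose(ratio, ratio[0], rtol=1e-12)

    def test_planted_fold_change_attenuated_in_bulk(self):
        """A +1 log2FC planted through a minority type only is diluted in the
        bulk mixture: the expected bulk fold change stays below 2x and above
        1x, matching the closed-form mixture expectation."""
        cfg = bt.SimulationConfig(
            seed=11, n_genes=800, n_cells_per_type=10,
            de_spec=[dict(name="up_rg", n_genes=10,
                          cell_types=("radial_glia",), log2fc=1.0)],
            fraction_shift={}, batch_effect_sd=0.0, sex_effect_sd=0.0,
        )
        ref = bt.simulate_reference(cfg)
        _, truth = bt.simulate_bulk_cohort(cfg, ref)
        P = type_profiles(cfg)
        f = cfg.base_fractions
        meta = cfg.sample_table()
        ctrl = meta.index[meta["condition"] == "control"][0]
        strs = meta.index[meta["condition"] == "stress"][0]
        norm = truth.expected_means.sum(axis=0)
        # closed-form mixture expectation, computed independently: the home
        # contribution is doubled, then the whole transcriptome renormalized
        # to the library (compositional effect of the planted genes)
        mix = P.to_numpy() @ f
        rg = list(cfg.cell_types).index("radial_glia")
        mix_strs = mix.copy()
        de_idx = [list(cfg.gene_names).index(g) for g in truth.de_table["gene"]]
        for g in de_idx:
            home_mass = P.iloc[g, rg] * f[rg]
            mix_strs[g] = mix[g] + home_mass * (2.0**1.0 - 1.0)
        for g, gene in zip(de_idx, truth.de_table["gene"]):
            obs_fc = (truth.expected_means.loc[gene, strs] / norm[strs]) / (
                truth.expected_means.loc[gene, ctrl] / norm[ctrl]
            )
            expected_fc = (mix_strs[g] / mix_strs.sum()) / (mix[g] / mix.sum())
            assert 1.0 < obs_fc < 2.0
            assert obs_fc == pytest.approx(expected_fc, rel=1e-9)

    def test_null_config_groups_exchangeable(self):
        cfg = bt.SimulationConfig(seed=3, n_genes=400, n_cells_per_type=20,
                                  de_spec=[], fraction_shift={})
        ref = bt.simulate_reference(cfg)
        bulk, truth = bt.simulate_bulk_cohort(cfg, ref)
        assert truth.de_table.empty
        assert (truth.true_fractions.nunique() == 1).all()

    def test_unknown_type_in_reference_rejected(self, small_reference):
        cfg = bt.SimulationConfig(
            seed=1, n_genes=600, cell_types=("neuron", "martian"),
            base_fractions=[0.5, 0.5], de_spec=[], fraction_shift={},
        )
        with pytest.raises(ValueError, match="lacks cell types"):
            bt.simulate_bulk_cohort(cfg, small_reference)


class TestPlantedDE:
    def test_de_genes_are_markers_of_home_types(self, small_config):
        de = planted_de_table(small_config)
        markers = marker_table(small_config)
        for _, row in de.iterrows():
            assert markers[row["gene"]] in row["home_types"].split(",")

    def test_directions_follow_sign(self, small_config):
        de = planted_de_table(small_config)
        assert (de.loc[de["log2fc"] > 0, "direction"] == "up").all()
        assert (de.loc[de["log2fc"] < 0, "direction"] == "down").all()


class TestVolume:
    def test_determinism(self, small_config):
        v1 = bt.simulate_ish_volume(small_config)
        v2 = bt.simulate_ish_volume(small_config)
        assert np.array_equal(v1.energy, v2.energy)
        assert np.array_equal(v1.region_labels, v2.region_labels)

    def test_home_region_fold_elevation(self):
        cfg = bt.SimulationConfig(seed=9, n_genes=300, ish_noise_shape=0.0)
        vol = bt.simulate_ish_volume(cfg)
        de = planted_de_table(cfg)
        up_gene = de.loc[de["direction"] == "up", "gene"].iloc[0]
        energy = vol.gene_energy(up_gene)
        home = vol.region_mask(cfg.ish_up_region)
        ratio = energy[home].mean() / energy[~home].mean()
        assert ratio == pytest.approx(cfg.ish_fold, rel=1e-9)

    def test_noisy_home_region_mean_near_fold(self):
        cfg = bt.SimulationConfig(seed=9, n_genes=300)
        vol = bt.simulate_ish_volume(cfg)
        de = planted_de_table(cfg)
        gene = de["gene"].iloc[0]
        home = vol.region_mask(cfg.ish_up_region if de["direction"].iloc[0] == "up"
                               else cfg.ish_down_region)
        energy = vol.gene_energy(gene)
        ratio = energy[home].mean() / energy[~home].mean()
        assert ratio == pytest.approx(cfg.ish_fold, rel=0.25)

    def test_fold_one_equalizes_regions(self):
        cfg = bt.SimulationConfig(seed=9, n_genes=200, ish_fold=1.0,
                                  ish_noise_shape=0.0)
        vol = bt.simulate_ish_volume(cfg)
        assert np.allclose(vol.energy, cfg.ish_background)

    def test_energies_nonnegative_and_panel_subset(self, small_config):
        vol = bt.simulate_ish_volume(small_config)
        assert vol.energy.min() >= 0
        assert set(vol.genes) <= set(small_config.gene_names)
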