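import json

import numpy as np
import pytest
from scipy import stats as sps

from omicreg.errors import ConfigError
from omicreg.io import read_gmt, write_gmt
from omicreg.simulate import (
    GroundTruth,
    SimulationConfig,
    simulate_dataset,
    simulate_function_sets,
    simulate_known_links,
)

from conftest import tiny_sim_config


class TestConfigValidation:
    def test_infeasible_k_rejected(self):
        with pytest.raises(ConfigError, match="mirna"):
            tiny_sim_config(m_mirna=6, k_planted=4, block_size=4)

    @pytest.mark.parametrize(
        "bad",
        [
            {"rho": 1.0},
            {"r_squared": 0.0},
            {"r_squared": 1.0},
            {"shared_fraction": 1.5},
            {"db_true_positive_fraction": -0.1},
            {"coef_min": 0.0},
            {"hub_sd": 0.0},
            {"normal_phenotype": "Missing"},
        ],
    )
    def test_invalid_rejected(self, bad):
        with pytest.raises(ConfigError):
            tiny_sim_config(**bad)

    def test_k_planted_mapping(self):
        cfg = tiny_sim_config(k_planted={"transcript": 2})
        assert cfg.k_by_omic == {"methylation": 0, "transcript": 2, "mirna": 0}


class TestSimulateDataset:
    def test_same_seed_bit_identical(self):
        cfg = tiny_sim_config()
        a, _ = simulate_dataset(cfg)
        b, _ = simulate_dataset(cfg)
        assert np.array_equal(a.values, b.values)
        assert a.feature_ids == b.feature_ids and a.sample_ids == b.sample_ids

    def test_shapes_and_labels(self):
        cfg = tiny_sim_config()
        ds, truth = simulate_dataset(cfg)
        assert ds.values.shape == (cfg.m_cpg + cfg.m_tx + cfg.m_mirna, sum(cfg.n_samples.values()))
        assert len(ds.target_genes) == cfg.n_target_genes
        assert all(ds.omic_of(g) == "transcript" for g in ds.target_genes)
        assert ds.omic_of(truth.tumor_hub_id) == "mirna"
        assert ds.omic_of(truth.normal_hub_id) == "mirna"

    def test_noiseless_limit_reproduces_linear_combination(self):
        cfg = tiny_sim_config(r_squared=1 - 1e-9, hub_scale=0.0)
        ds, truth = simulate_dataset(cfg)
        ph, gene = "A", ds.target_genes[0]
        idx = ds.samples_of(ph)
        y = ds.values[ds.feature_row(gene)][idx]
        pred = truth.intercepts[(ph, gene)] + sum(
            c * ds.values[ds.feature_row(f)][idx]
            for f, c in truth.planted_coefficients[(ph, gene)]
        )
        assert np.allclose(y, pred, atol=1e-3)

    def test_high_snr_single_predictor_correlation(self):
        # rho=0, R^2=0.99, one planted transcript, no hub: the planted
        # feature carries almost all the variance of its gene.
        cfg = SimulationConfig(
            n_samples={"A": 500, "Normal": 10},
            m_cpg=50,
            m_tx=50,
            m_mirna=20,
            n_target_genes=2,
            k_planted={"transcript": 1},
            rho=0.0,
            plant_within_blocks=False,
            r_squared=0.99,
            hub_scale=0.0,
            seed=5,
        )
        ds, truth = simulate_dataset(cfg)
        idx = ds.samples_of("A")
        for gene in ds.target_genes:
            (feat,) = truth.planted_features("A", gene)
            r = np.corrcoef(
                ds.values[ds.feature_row(gene)][idx], ds.values[ds.feature_row(feat)][idx]
            )[0, 1]
            assert abs(r) > 0.9

    def test_r_squared_calibration(self):
        # empirical R^2 of the true linear predictor within +-0.05 at n=2000
        cfg = tiny_sim_config(n_samples={"A": 2000, "Normal": 10}, seed=3)
        ds, truth = simulate_dataset(cfg)
        idx = ds.samples_of("A")
        for gene in ds.target_genes:
            y = ds.values[ds.feature_row(gene)][idx]
            pred = truth.intercepts[("A", gene)] + sum(
                c * ds.values[ds.feature_row(f)][idx]
                for f, c in truth.planted_coefficients[("A", gene)]
            )
            r2 = 1.0 - np.var(y - pred) / np.var(y)
            assert abs(r2 - cfg.r_squared) < 0.05

    def test_mean_equals_intercept(self):
        cfg = tiny_sim_config(n_samples={"A": 4000, "Normal": 10}, seed=9)
        ds, truth = simulate_dataset(cfg)
        idx = ds.samples_of("A")
        for gene in ds.target_genes:
            y = ds.values[ds.feature_row(gene)][idx]
            se = y.std() / np.sqrt(len(idx))
            assert abs(y.mean() - truth.intercepts[("A", gene)]) < 5 * se

    def test_exclusive_planting_across_phenotypes(self):
        cfg = tiny_sim_config(shared_fraction=0.0)
        _, truth = simulate_dataset(cfg)
        hubs = {truth.tumor_hub_id, truth.normal_hub_id}
        for gene in truth.target_genes:
            sets = [
                truth.planted_features(ph, gene) - hubs for ph in cfg.phenotype_order
            ]
            for i in range(len(sets)):
                for j in range(i + 1, len(sets)):
                    assert not sets[i] & sets[j]

    def test_full_sharing_across_phenotypes(self):
        cfg = tiny_sim_config(shared_fraction=1.0)
        _, truth = simulate_dataset(cfg)
        hubs = {truth.tumor_hub_id, truth.normal_hub_id}
        for gene in truth.target_genes:
            sets = [truth.planted_features(ph, gene) - hubs for ph in cfg.phenotype_order]
            assert all(s == sets[0] for s in sets)

    def test_own_transcript_never_planted(self):
        _, truth = simulate_dataset(tiny_sim_config())
        for (ph, gene), coefs in truth.planted_coefficients.items():
            assert gene not in {f for f, _ in coefs}

    def test_block_correlation_structure(self):
        cfg = tiny_sim_config(n_samples={"A": 3000, "Normal": 10}, rho=0.6, seed=2)
        ds, truth = simulate_dataset(cfg)
        idx = ds.samples_of("A")
        # two cpg features in the same block correlate ~rho; across blocks ~0
        by_block = {}
        for f, b in truth.block_assignments.items():
            if truth.feature_omic[f] == "methylation":
                by_block.setdefault(b, []).append(f)
        same = next(fs for fs in by_block.values() if len(fs) >= 2)
        r_in = np.corrcoef(
            ds.values[ds.feature_row(same[0])][idx], ds.values[ds.feature_row(same[1])][idx]
        )[0, 1]
        blocks = [fs[0] for fs in by_block.values()][:2]
        r_out = np.corrcoef(
            ds.values[ds.feature_row(blocks[0])][idx], ds.values[ds.feature_row(blocks[1])][idx]
        )[0, 1]
        assert abs(r_in - 0.6) < 0.05
        assert abs(r_out) < 0.06

    def test_logit_normal_methylation_bounded(self):
        cfg = tiny_sim_config(logit_normal_methylation=True)
        ds, _ = simulate_dataset(cfg)
        cpg_rows = [ds.feature_row(f) for f in ds.features_of("methylation")]
        vals = ds.values[cpg_rows, :]
        assert vals.min() > 0.0 and vals.max() < 1.0

    def test_hub_de_pattern(self):
        cfg = tiny_sim_config()
        ds, truth = simulate_dataset(cfg)
        t_row = ds.feature_row(truth.tumor_hub_id)
        n_row = ds.feature_row(truth.normal_hub_id)
        tumor = ds.samples_of("A")
        normal = ds.samples_of("Normal")
        assert ds.values[t_row, tumor].mean() > ds.values[t_row, normal].mean() + 1
        assert ds.values[n_row, tumor].mean() < ds.values[n_row, normal].mean() - 1


class TestGroundTruthJSON:
    def test_roundtrip(self, tmp_path):
        cfg = tiny_sim_config()
        _, truth = simulate_dataset(cfg)
        simulate_function_sets(truth, cfg)
        truth.to_json(tmp_path / "t.json")
        back = GroundTruth.from_json(tmp_path / "t.json")
        assert back.planted_coefficients == truth.planted_coefficients
        assert back.intercepts == truth.intercepts
        assert back.noise_sd == truth.noise_sd
        assert back.block_assignments == truth.block_assignments
        assert back.planted_function_sets == truth.planted_function_sets
        assert back.tumor_hub_id == truth.tumor_hub_id


class TestKnownLinks:
    def test_fraction_one_no_decoys_equals_planted(self):
        cfg = tiny_sim_config(db_true_positive_fraction=1.0, db_size=None)
        _, truth = simulate_dataset(cfg)
        db = simulate_known_links(truth, cfg)
        assert db.pairs() == truth.planted_pairs()

    def test_fraction_zero_disjoint_from_planted(self):
        cfg = tiny_sim_config(db_true_positive_fraction=0.0, db_size=200)
        _, truth = simulate_dataset(cfg)
        db = simulate_known_links(truth, cfg)
        assert len(db) == 200
        assert not db.pairs() & truth.planted_pairs()

    def test_fraction_half_exact_count(self):
        cfg = tiny_sim_config(db_true_positive_fraction=0.5)
        _, truth = simulate_dataset(cfg)
        db = simulate_known_links(truth, cfg)
        planted = truth.planted_pairs()
        assert len(db.pairs() & planted) == round(0.5 * len(planted))

    def test_evidence_alternates(self):
        cfg = tiny_sim_config()
        _, truth = simulate_dataset(cfg)
        db = simulate_known_links(truth, cfg)
        assert set(db.records["evidence"]) == {"predicted", "validated"}


class TestFunctionSets:
    def test_on_target_covers_planted_transcripts(self):
        cfg = tiny_sim_config(ontarget_coverage=0.8)
        _, truth = simulate_dataset(cfg)
        sets = simulate_function_sets(truth, cfg)
        for gene in truth.target_genes:
            planted_tx = {
                f
                for (ph, g), coefs in truth.planted_coefficients.items()
                if g == gene
                for f, _ in coefs
                if truth.feature_omic[f] == "transcript"
            }
            name = truth.planted_function_sets[gene]
            covered = len(planted_tx & sets[name]) / len(planted_tx)
            assert covered >= 0.8 - 1e-9

    def test_gmt_roundtrip(self, tmp_path):
        cfg = tiny_sim_config()
        _, truth = simulate_dataset(cfg)
        sets = simulate_function_sets(truth, cfg)
        write_gmt(sets, tmp_path / "f.gmt")
        assert read_gmt(tmp_path / "f.gmt") == sets

    def test_background_sets_have_null_overlap(self):
        # overlap of background sets with a fixed planted-like selection
        # follows the hypergeometric null
        cfg = tiny_sim_config(
            m_tx=300, n_background_sets=150, ontarget_set_size=40, seed=11
        )
        _, truth = simulate_dataset(cfg)
        sets = simulate_function_sets(truth, cfg)
        pool = sorted(
            f
            for f, o in truth.feature_omic.items()
            if o == "transcript" and f not in set(truth.target_genes)
        )
        rng = np.random.default_rng(0)
        selection = set(rng.choice(pool, size=60, replace=False))
        n_pool = len(pool)
        overlaps = [
            len(selection & sets[name]) for name in sets if name.startswith("BG_")
        ]
        expected = 60 * 40 / n_pool
        assert abs(np.mean(overlaps) - expected) < 1.0
        pvals = [
            float(sps.hypergeom.sf(o - 1, n_pool, 40, 60)) for o in overlaps
        ]
        # conservative discrete p-values: at least not concentrated low
        assert np.mean(np.array(pvals) < 0.05) < 0.12
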