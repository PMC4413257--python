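"""Synthetic-data generator: planted effects, determinism, null behavior."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from subtypenet._utils import BASAL, LUMINAL, ConfigurationError
from subtypenet.simulate import (
    GroundTruth,
    SimulationConfig,
    simulate_cna_cohort,
    simulate_dataset,
    simulate_expression,
    simulate_mirna_pairs,
)


class TestConfigValidation:
    @pytest.mark.parametrize("field,value", [
        ("n_luminal", 0), ("n_probes_per_chrom", -5), ("rho_luminal", 1.0),
        ("rho_basal", -1.2), ("cna_penetrance", 1.5),
        ("segment_mean_gain", -0.1),
    ])
    def test_invalid_field_is_named(self, field, value):
        cfg = dataclasses.replace(SimulationConfig(), **{field: value})
        with pytest.raises(ConfigurationError) as err:
            cfg.validate()
        assert field.split("_")[0] in str(err.value)


class TestCnaCohort:
    def test_zero_noise_gain_segment_is_exact(self):
        cfg = SimulationConfig(noise_sd_cn=0.0, n_luminal=6, n_basal=6,
                               cna_penetrance=1.0, seed=2)
        profiles, annotation, truth = simulate_cna_cohort(cfg)
        gain_genes = [g for g, grp in truth.subtype_specific_genes.items()
                      if grp == "luminalA_gain"]
        lum = [p for p in profiles if p.subtype == LUMINAL][0]
        row = annotation.set_index("gene").loc[gain_genes[0]]
        probes = lum.probes[(lum.probes["chrom"] == row["chrom"])
                            & (lum.probes["pos"] >= row["start"])
                            & (lum.probes["pos"] < row["end"])]
        assert np.allclose(probes["log_ratio"], cfg.segment_mean_gain)

    def test_fixed_seed_reproduces_byte_identical_profiles(self):
        cfg = SimulationConfig(n_luminal=4, n_basal=4, seed=1)
        a = simulate_cna_cohort(cfg)
        b = simulate_cna_cohort(cfg)
        for pa, pb in zip(a[0], b[0]):
            pd.testing.assert_frame_equal(pa.probes, pb.probes)
        assert a[2].true_states.equals(b[2].true_states)

    def test_noise_mean_obeys_clt_bound(self):
        """Residual (noise-only) probe mean stays within 4 sd/sqrt(n)."""
        cfg = SimulationConfig(n_luminal=3, n_basal=3, n_chroms=1,
                               n_probes_per_chrom=10_000, noise_sd_cn=0.2,
                               seed=7)
        profiles, annotation, truth = simulate_cna_cohort(cfg)
        mean_of = {1: cfg.segment_mean_gain, -1: cfg.segment_mean_loss, 0: 0.0}
        ann = annotation.set_index("gene")
        bound = 4 * 0.2 / np.sqrt(10_000)
        for p in profiles:
            planted = np.zeros(10_000)
            for gene, state in truth.true_states[p.sample_id].items():
                if state:
                    row = ann.loc[gene]
                    lo = int(row["start"]) // 100
                    hi = int(row["end"]) // 100
                    planted[lo:hi] = mean_of[state]
            resid = p.probes["log_ratio"].to_numpy() - planted
            assert abs(resid.mean()) < bound

    def test_cna_penetrance_contrast(self, tiny_dataset):
        """Dominant-subtype carrier rate >> background rate."""
        truth = tiny_dataset.truth
        labels = tiny_dataset.labels
        for gene, group in truth.subtype_specific_genes.items():
            dom = LUMINAL if group.startswith("luminalA") else BASAL
            st = truth.true_states.loc[gene]
            dom_rate = (st[labels[labels == dom].index] != 0).mean()
            oth_rate = (st[labels[labels != dom].index] != 0).mean()
            assert dom_rate >= 0.5
            assert oth_rate <= 0.25


class TestExpression:
    def test_dosage_effect_exact_without_noise(self):
        cfg = SimulationConfig(n_luminal=4, n_basal=4, expr_noise_sd=0.0,
                               dosage_beta=1.0, de_effect=0.0, seed=3)
        _, _, truth = simulate_cna_cohort(cfg)
        expr = simulate_expression(truth, cfg)
        gene = next(iter(truth.subtype_specific_genes))
        st = truth.true_states.loc[gene]
        carriers = st.index[st != 0]
        nulls = st.index[st == 0]
        if len(carriers) and len(nulls):
            diff = expr.loc[gene, carriers[0]] - expr.loc[gene, nulls[0]]
            assert diff == pytest.approx(float(st[carriers[0]]), abs=1e-12)

    def test_planted_gain_gene_shifts_subtype_mean(self):
        cfg = SimulationConfig(n_luminal=500, n_basal=500, seed=4)
        _, _, truth = simulate_cna_cohort(cfg)
        expr = simulate_expression(truth, cfg)
        labels = pd.Series(
            [LUMINAL] * 500 + [BASAL] * 500, index=expr.columns)
        for gene, group in truth.subtype_specific_genes.items():
            mean_l = expr.loc[gene, labels == LUMINAL].mean()
            mean_b = expr.loc[gene, labels == BASAL].mean()
            if group == "luminalA_gain":
                assert mean_l > mean_b
            elif group == "basal_loss":
                assert mean_b < mean_l

    def test_null_genes_have_uniform_p_values(self):
        """No DE, no dosage: two-sample t P-values are U(0,1) across genes."""
        cfg = SimulationConfig(n_luminal=30, n_basal=30, de_effect=0.0,
                               dosage_beta=0.0, n_chroms=4,
                               n_probes_per_chrom=600, seed=6)
        _, _, truth = simulate_cna_cohort(cfg)
        expr = simulate_expression(truth, cfg)
        x = expr.iloc[:, :30].to_numpy()
        y = expr.iloc[:, 30:].to_numpy()
        _, pvals = stats.ttest_ind(x, y, axis=1)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestMirnaPairs:
    def test_high_rho_recovered_within_fisher_ci(self):
        cfg = SimulationConfig(n_luminal=500, n_basal=40, rho_luminal=0.9,
                               seed=8)
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(10)]
        samples = [f"LumA_{i+1:02d}" for i in range(500)] + \
            [f"Basal_{i+1:02d}" for i in range(40)]
        mrna = pd.DataFrame(rng.standard_normal((10, 540)), index=genes,
                            columns=samples)
        truth = GroundTruth(
            true_pairs={(f"m{i}", genes[i], "luminal") for i in range(10)})
        mirna, _ = simulate_mirna_pairs(truth, mrna, cfg)
        for i in range(10):
            r = np.corrcoef(mirna.loc[f"m{i}", samples[:500]],
                            mrna.loc[genes[i], samples[:500]])[0, 1]
            assert abs(r - 0.9) < 0.05

    def test_zero_rho_pairs_center_at_zero(self):
        cfg = SimulationConfig(n_luminal=200, n_basal=200, rho_luminal=0.0,
                               rho_basal=0.0, seed=9)
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(30)]
        samples = [f"LumA_{i+1:02d}" for i in range(200)] + \
            [f"Basal_{i+1:02d}" for i in range(200)]
        mrna = pd.DataFrame(rng.standard_normal((30, 400)), index=genes,
                            columns=samples)
        truth = GroundTruth(
            true_pairs={(f"m{i}", genes[i], "both") for i in range(30)})
        mirna, _ = simulate_mirna_pairs(truth, mrna, cfg)
        rs = [np.corrcoef(mirna.loc[f"m{i}", samples[:200]],
                          mrna.loc[genes[i], samples[:200]])[0, 1]
              for i in range(30)]
        assert abs(np.mean(rs)) < 0.05

    def test_target_map_bookkeeping(self, tiny_dataset, tiny_config):
        expected = tiny_config.n_true_pairs + tiny_config.n_decoy_pairs
        assert len(tiny_dataset.target_map) == expected


class TestDatasetBundle:
    def test_default_bundle_satisfies_invariants(self, tiny_dataset):
        tiny_dataset.validate()
        assert set(tiny_dataset.truth.true_states.columns) == \
            set(tiny_dataset.labels.index)

    def test_seed_changes_noise_but_not_truth_structure(self, tiny_config):
        a = simulate_dataset(tiny_config)
        b = simulate_dataset(dataclasses.replace(tiny_config, seed=99))
        assert a.truth.subtype_specific_genes == \
            b.truth.subtype_specific_genes
        assert {p[:2] for p in a.truth.true_pairs} == \
            {p[:2] for p in b.truth.true_pairs}
        assert not np.allclose(a.mrna.to_numpy(), b.mrna.to_numpy())

    def test_round_trip_write_read(self, tiny_dataset, tmp_path):
        from subtypenet import io
        paths = io.write_dataset(tiny_dataset, tmp_path)
        back = io.read_dataset_inputs(paths)
        pd.testing.assert_frame_equal(
            back["mrna"].rename_axis(None), tiny_dataset.mrna,
            check_exact=False)
        pd.testing.assert_frame_equal(
            back["mirna"].rename_axis(None), tiny_dataset.mirna,
            check_exact=False)
        pd.testing.assert_series_equal(back["labels"], tiny_dataset.labels,
                                       check_names=False)
        assert back["target_map"].equals(tiny_dataset.target_map)
        for pa, pb in zip(back["profiles"], tiny_dataset.profiles):
            assert pa.sample_id == pb.sample_id
            np.testing.assert_allclose(
                pa.probes["log_ratio"], pb.probes["log_ratio"], rtol=1e-12)
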