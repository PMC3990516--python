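"""Generator behaviour: determinism, construction rules, ground-truth tallies."""

import numpy as np
import pandas as pd
import pytest

from cssmisreg import synthetic as syn
from cssmisreg.models import donor_strain, host_strain, substitution_strain


class TestGenerateGenome:
    def test_counts_and_x_presence(self):
        layout = syn.generate_genome(19, 50, seed=1)
        assert len(layout.genes) == 20 * 50
        assert set(layout.chromosomes) == {str(i) for i in range(1, 20)} | {"X"}

    def test_minimal_case(self):
        layout = syn.generate_genome(1, 1, seed=0)
        assert len(layout.genes) == 2
        assert sorted(layout.genes["chrom"]) == ["1", "X"]

    def test_deterministic(self):
        a = syn.generate_genome(3, 10, seed=42)
        b = syn.generate_genome(3, 10, seed=42)
        pd.testing.assert_frame_equal(a.genes, b.genes)
        assert a.chromosomes == b.chromosomes

    @pytest.mark.parametrize("bad", [(0, 5), (5, 0), (-1, 1)])
    def test_rejects_nonpositive_counts(self, bad):
        with pytest.raises(ValueError):
            syn.generate_genome(*bad, seed=0)

    def test_positions_inside_chromosomes(self):
        layout = syn.generate_genome(4, 25, seed=9)
        for _, row in layout.genes.iterrows():
            assert 1 <= row["pos_bp"] <= layout.chromosomes[row["chrom"]]


class TestExpressionStudy:
    def test_all_conserved_null_model(self, layout):
        arch = syn.assign_architecture(
            layout, cis_frac=0.0, incompat_frac=0.0, cascade_frac=0.0, seed=1
        )
        strains = [host_strain(), substitution_strain(layout, "CSSX", "X")]
        cfg = syn.SimulationConfig(seed=2, noise_sd=0.05)
        expr, truth = syn.generate_expression_study(layout, arch, strains, cfg)
        fc = np.log2(expr.group_mean("CSSX")) - np.log2(expr.group_mean("B6"))
        assert (truth["direction"] == "none").all()
        assert np.abs(fc).max() < 0.3  # pure replicate noise at sd 0.05

    def test_cis_gene_fold_change_construction(self, layout):
        # one cis gene with +1 log2 effect inside the donor region:
        # CSS tracks the donor level (FC vs host = 2, vs donor = 1)
        arch = syn.assign_architecture(
            layout, cis_frac=0.0, incompat_frac=0.0, cascade_frac=0.0, seed=1
        )
        x_gene = arch.table.index[arch.table["chrom"] == "X"][0]
        arch.table.loc[x_gene, ["reg_class", "effect_log2", "direction"]] = [
            syn.CLASS_CIS, 1.0, "up",
        ]
        strains = [
            host_strain(),
            donor_strain(layout),
            substitution_strain(layout, "CSSX", "X"),
        ]
        cfg = syn.SimulationConfig(seed=4, noise_sd=0.01, replicates=20)
        expr, _ = syn.generate_expression_study(layout, arch, strains, cfg)
        fc_host = expr.group_mean("CSSX")[x_gene] / expr.group_mean("B6")[x_gene]
        fc_donor = expr.group_mean("CSSX")[x_gene] / expr.group_mean("MSM")[x_gene]
        assert fc_host == pytest.approx(2.0, rel=0.05)
        assert fc_donor == pytest.approx(1.0, rel=0.05)

    def test_incompatible_gene_matches_neither_parent(self, layout):
        arch = syn.assign_architecture(
            layout, cis_frac=0.0, incompat_frac=0.0, cascade_frac=0.0, seed=1
        )
        x_gene = arch.table.index[arch.table["chrom"] == "X"][5]
        arch.table.loc[x_gene, ["reg_class", "effect_log2", "direction"]] = [
            syn.CLASS_INCOMPAT, -2.0, "down",
        ]
        strains = [
            host_strain(),
            donor_strain(layout),
            substitution_strain(layout, "CSSX", "X"),
        ]
        cfg = syn.SimulationConfig(seed=4, noise_sd=0.01, replicates=20)
        expr, _ = syn.generate_expression_study(layout, arch, strains, cfg)
        host = expr.group_mean("B6")[x_gene]
        donor = expr.group_mean("MSM")[x_gene]
        css = expr.group_mean("CSSX")[x_gene]
        assert donor == pytest.approx(host, rel=0.05)  # parents agree
        assert css / host == pytest.approx(0.25, rel=0.05)  # misregulated in CSS

    def test_downregulation_bias_tally(self):
        """Realized down fraction among incompatible genes matches the law."""
        layout = syn.generate_genome(19, 50, seed=11)
        arch = syn.assign_architecture(
            layout, cis_frac=0.0, incompat_frac=0.2, cascade_frac=0.0, seed=11
        )
        inc = arch.table[arch.table["reg_class"] == syn.CLASS_INCOMPAT]
        frac_down = (inc["direction"] == "down").mean()
        n = len(inc)
        se = np.sqrt(0.7 * 0.3 / n)
        assert abs(frac_down - 0.7) < 3 * se

    def test_cascade_only_in_cascade_mode(self, layout):
        arch = syn.assign_architecture(
            layout, cis_frac=0.0, incompat_frac=0.0, cascade_frac=0.3, seed=2
        )
        strains = [host_strain(), substitution_strain(layout, "CSSX", "X")]
        quiet = syn.SimulationConfig(seed=5, noise_sd=0.01, cascade=False)
        loud = syn.SimulationConfig(seed=5, noise_sd=0.01, cascade=True)
        expr0, truth0 = syn.generate_expression_study(layout, arch, strains, quiet)
        expr1, truth1 = syn.generate_expression_study(layout, arch, strains, loud)
        cas = arch.table["reg_class"] == syn.CLASS_CASCADE
        fc0 = np.log2(expr0.group_mean("CSSX")) - np.log2(expr0.group_mean("B6"))
        fc1 = np.log2(expr1.group_mean("CSSX")) - np.log2(expr1.group_mean("B6"))
        assert np.abs(fc0[cas.to_numpy()]).max() < 0.2
        assert np.abs(fc1[cas.to_numpy()]).min() > 0.5
        assert (truth0.loc[cas, "direction"] == "none").all()
        assert set(truth1.loc[cas, "direction"]) <= {"up", "down"}

    def test_seed_reproducibility(self, layout, architecture, strains):
        cfg = syn.SimulationConfig(seed=123)
        a, _ = syn.generate_expression_study(layout, architecture, strains, cfg)
        b, _ = syn.generate_expression_study(layout, architecture, strains, cfg)
        pd.testing.assert_frame_equal(a.values, b.values)


class TestProbeAnnotation:
    def test_zero_rates_all_perfect(self, layout, strains):
        ann = syn.generate_probe_annotation(layout, strains, 0.0, 0.0, seed=1)
        assert (ann["n_identified"] == 11).all()
        assert (ann["n_perfect"] == 11).all()
        assert (ann["polymorphism_score"] == 0).all()
        assert (ann["status"] == "conserved").all()

    def test_rate_one_in_donor_region(self, layout, strains):
        ann = syn.generate_probe_annotation(layout, strains, 1.0, 0.0, seed=1)
        on_x = ann["chrom"] == "X"
        assert (ann.loc[on_x, "n_perfect"] == 0).all()
        assert (ann.loc[on_x, "status"] == "polymorphic").all()
        assert (ann.loc[~on_x, "n_perfect"] == 11).all()

    def test_polymorphic_fraction_tally(self, layout, strains):
        rate = 0.3
        ann = syn.generate_probe_annotation(layout, strains, rate, 0.0, seed=9)
        on_x = ann["chrom"] == "X"
        frac = 1.0 - ann.loc[on_x, "n_perfect"].sum() / (11 * on_x.sum())
        n_probes = 11 * int(on_x.sum())
        se = np.sqrt(rate * (1 - rate) / n_probes)
        assert abs(frac - rate) < 4 * se

    def test_count_ordering_invariant(self, annotation):
        assert (annotation["n_perfect"] <= annotation["n_identified"]).all()
        assert (annotation["n_identified"] <= annotation["n_probes_total"]).all()

    def test_bad_rate_rejected(self, layout, strains):
        with pytest.raises(ValueError):
            syn.generate_probe_annotation(layout, strains, 1.5, 0.0, seed=0)


class TestBackcross:
    def test_no_recombination_uniform_progeny(self):
        data = syn.generate_backcross(
            n_progeny=50, n_markers=10, cm_per_mb=0.0, seed=3
        )
        g = data.genotypes.to_numpy()
        assert (g == g[:, [0]]).all()

    def test_haldane_recombinant_fraction(self):
        """Adjacent markers 10 cM apart recombine at the Haldane rate."""
        # 20 Mb spacing at 0.5 cM/Mb = 10 cM
        data = syn.generate_backcross(
            n_progeny=5000, n_markers=2, chrom_length_bp=21_000_000,
            cm_per_mb=0.5, qtl_pos_bp=1_000_000, qtl_effect=0.0, seed=17,
        )
        g = data.genotypes.to_numpy()
        obs = (g[:, 0] != g[:, 1]).mean()
        expected = 0.5 * (1 - np.exp(-0.2))
        se = np.sqrt(expected * (1 - expected) / 5000)
        assert abs(obs - expected) < 4 * se

    def test_null_effect_trait_independent(self):
        data = syn.generate_backcross(n_progeny=200, n_markers=20,
                                      qtl_effect=0.0, seed=5)
        g = data.qtl_truth["genotype"]
        y = data.traits.iloc[:, 0].to_numpy()
        diff = y[g == 1].mean() - y[g == 0].mean()
        assert abs(diff) < 4 * 20.0 * np.sqrt(2 / 100)

    def test_qtl_outside_chromosome_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_backcross(qtl_pos_bp=10**10)

    def test_haldane_limits(self):
        assert syn.haldane(0.0) == 0.0
        assert syn.haldane(1e9) == pytest.approx(0.5)
        d = np.linspace(0, 200, 50)
        assert (np.diff(syn.haldane(d)) > 0).all()


class TestF1Cohort:
    def test_restored_and_non_restored_geometry(self, expr):
        merged = syn.generate_f1_cohort(expr, "B6", "CSSX", n_restored=2,
                                        n_non_restored=3, seed=8, age_dpp=7)
        f1 = merged.sample_ids("F1")
        assert len(f1) == 5
        log_host = np.log2(merged.group_mean("B6", 7))
        log_css = np.log2(merged.group_mean("CSSX", 7))
        for sid in f1:
            v = np.log2(merged.values[sid])
            d_host = np.linalg.norm(v - log_host)
            d_css = np.linalg.norm(v - log_css)
            if "_r" in sid.rsplit("_", 1)[-1] or sid.split("_")[-1].startswith("r"):
                assert d_host < d_css
            else:
                assert d_css < d_host
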