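"""Correlation comparison, regulatory typing, and overlap summaries."""

import numpy as np
import pandas as pd
import pytest

from cssmisreg import classify, de, synthetic as syn
from cssmisreg.models import donor_strain, host_strain, substitution_strain


def _series(values, prefix="g"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))])


class TestCorrelationComparison:
    def test_identical_parents_symmetric(self):
        rng = np.random.default_rng(0)
        base = np.exp(rng.normal(4, 1, 100))
        css = base * np.exp(rng.normal(0, 0.1, 100))
        res = classify.correlation_comparison(
            _series(css), _series(base), _series(base)
        )
        assert res.z_stat == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(0.5)

    def test_fisher_z_formula_direct(self):
        """r = (0.90, 0.95) at n = 472 gives a strongly positive statistic."""
        z = (np.arctanh(0.95) - np.arctanh(0.90)) / np.sqrt(2 / (472 - 3))
        from scipy import stats

        assert z > 0
        assert stats.norm.sf(z) < 1e-4

    def test_donor_tracking_detected(self):
        rng = np.random.default_rng(1)
        n = 300
        host = np.exp(rng.normal(4, 1, n))
        donor = host * np.exp(rng.normal(0, 0.8, n))  # diverged from host
        css = donor * np.exp(rng.normal(0, 0.15, n))  # tracks donor
        res = classify.correlation_comparison(
            _series(css), _series(host), _series(donor)
        )
        assert res.r_donor > res.r_host
        assert res.p < 0.05

    def test_agrees_with_permutation_oracle(self):
        """Fisher-z p and a parent-label permutation p agree qualitatively."""
        rng = np.random.default_rng(2)
        n = 120
        host_mu = rng.normal(4, 1, n)
        donor_mu = host_mu + rng.normal(0, 0.9, n)
        css_mu = donor_mu + rng.normal(0, 0.35, n)  # css tracks the donor
        css = pd.Series(np.exp(css_mu))
        host = pd.Series(np.exp(host_mu + rng.normal(0, 0.2, n)))
        donor = pd.Series(np.exp(donor_mu + rng.normal(0, 0.2, n)))
        res = classify.correlation_comparison(css, host, donor)
        perm_p = classify.permutation_correlation_p(
            css, host, donor, n_perm=600, seed=3
        )
        # both must point the same way: strong evidence here
        assert res.p < 0.05
        assert perm_p < 0.05

    def test_small_subset_rejected(self):
        v = _series([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="at least 4"):
            classify.correlation_comparison(v, v, v)

    def test_zero_variance_rejected(self):
        v = _series([2.0] * 10)
        w = _series(np.arange(1.0, 11.0))
        with pytest.raises(ValueError, match="variance"):
            classify.correlation_comparison(w, v, w)


class TestRegulatoryTyping:
    def _calls(self, directions):
        idx = [f"g{i}" for i in range(len(directions))]
        return pd.DataFrame(
            {"direction": directions, "significant": [d != "none" for d in directions]},
            index=idx,
        )

    def test_equal_expression_is_cis(self):
        calls = self._calls(["up"])
        css = _series([100.0])
        donor = _series([100.0])
        typing, _ = classify.classify_regulatory_type(calls, css, donor)
        assert typing["reg_type"].iloc[0] == classify.TYPE_CIS
        assert typing["ratio_css_donor"].iloc[0] == 1.0

    @pytest.mark.parametrize("ratio", [1.5, 1 / 1.5])
    def test_band_boundary_is_incompatibility(self, ratio):
        """Exactly 1.5-fold is NOT 'converged within less than 1.5-fold'."""
        calls = self._calls(["up"])
        typing, _ = classify.classify_regulatory_type(
            calls, _series([100.0 * ratio]), _series([100.0])
        )
        assert typing["reg_type"].iloc[0] == classify.TYPE_INCOMPAT

    def test_converged_fraction_summary(self):
        """29 of 31 upregulated transcripts inside the band -> 93.5%."""
        directions = ["up"] * 31
        ratios = [1.1] * 29 + [2.0, 3.0]
        calls = self._calls(directions)
        typing, summary = classify.classify_regulatory_type(
            calls, _series([100.0 * r for r in ratios]), _series([100.0] * 31)
        )
        assert summary.loc["up", "n"] == 31
        assert summary.loc["up", "n_cis"] == 29
        assert summary.loc["up", "pct_cis"] == 93.55
        assert round(100.0 * 29 / 31, 1) == 93.5

    def test_zero_donor_mean_rejected(self):
        calls = self._calls(["up"])
        with pytest.raises(ValueError, match="zero"):
            classify.classify_regulatory_type(calls, _series([1.0]), _series([0.0]))

    def test_recovers_true_classes_on_synthetic_study(self):
        """cis vs incompatibility recovered with >= 0.9 accuracy at the stated
        effect sizes (|incompatibility effect| >= 1 log2 unit, noise sd <= 0.25)."""
        layout = syn.generate_genome(3, 120, seed=21)
        arch = syn.assign_architecture(
            layout,
            cis_frac=0.15,
            incompat_frac=0.15,
            cascade_frac=0.0,
            cis_law=syn.EffectLaw(shift=1.0, spread=0.4, down_prob=0.35),
            incompat_law=syn.EffectLaw(shift=1.0, spread=0.5, down_prob=0.7),
            seed=22,
        )
        strains = [
            host_strain(),
            donor_strain(layout),
            substitution_strain(layout, "CSSX", "X"),
        ]
        cfg = syn.SimulationConfig(seed=23, noise_sd=0.2)
        expr, truth = syn.generate_expression_study(layout, arch, strains, cfg)
        calls = de.de_table(expr, "CSSX", "B6")
        on_x = truth["chrom"] == "X"
        typing, _ = classify.classify_regulatory_type(
            calls.loc[on_x.index[on_x]],
            expr.group_mean("CSSX"),
            expr.group_mean("MSM"),
        )
        truth_x = truth.loc[typing.index]
        relevant = truth_x["reg_class"].isin(
            [syn.CLASS_CIS, syn.CLASS_INCOMPAT]
        )
        expected = truth_x.loc[relevant, "reg_class"].map(
            {
                syn.CLASS_CIS: classify.TYPE_CIS,
                syn.CLASS_INCOMPAT: classify.TYPE_INCOMPAT,
            }
        )
        got = typing.loc[relevant.index[relevant], "reg_type"]
        accuracy = (got == expected).mean()
        assert len(expected) >= 20
        assert accuracy >= 0.9


class TestOverlapAnalysis:
    def _calls(self, ids, sig_ids):
        return pd.DataFrame(
            {"significant": [i in set(sig_ids) for i in ids]}, index=ids
        )

    def _ann(self, ids):
        return pd.DataFrame(
            {"chrom": ["X"] * len(ids), "pos_bp": range(1, len(ids) + 1)}, index=ids
        )

    def test_identical_sets_full_overlap(self):
        ids = [f"g{i}" for i in range(10)]
        calls = self._calls(ids, ids[:4])
        res = classify.overlap_analysis(calls, calls, self._ann(ids))
        assert res.pct_of_b == 100.0
        assert res.n_common == 4

    def test_printed_ratio_reproduction(self):
        ids = [f"g{i}" for i in range(1500)]
        set_b = ids[:971]
        set_a = ids[:686] + [f"g{i}" for i in range(1000, 1314)]
        res = classify.overlap_analysis(
            self._calls(ids, set_a), self._calls(ids, set_b), self._ann(ids)
        )
        assert res.n_common == 686
        assert res.n_b == 971
        assert res.pct_of_b == 70.6

    def test_disjoint_significant_sets(self):
        ids = [f"g{i}" for i in range(10)]
        res = classify.overlap_analysis(
            self._calls(ids, ids[:3]), self._calls(ids, ids[5:8]), self._ann(ids)
        )
        assert res.n_common == 0
        assert res.pct_of_b == 0.0
        assert res.breakdown_pct == {}

    def test_breakdown_partitions_common_set(self):
        ids = [f"g{i}" for i in range(6)]
        ann = pd.DataFrame(
            {
                "chrom": ["X", "X", "1", "2", "X", "3"],
                "pos_bp": [100, 900, 50, 50, 950, 50],
            },
            index=ids,
        )
        calls = self._calls(ids, ids)
        res = classify.overlap_analysis(calls, calls, ann, x_split_bp=500)
        b = res.breakdown_pct
        assert b["distal_x_pct"] + b["autosome_pct"] + b["other_pct"] == 100.0
        assert b["distal_x_pct"] == pytest.approx(33.33)

    def test_disjoint_universes_rejected(self):
        a = self._calls(["g1"], ["g1"])
        b = self._calls(["h1"], ["h1"])
        with pytest.raises(ValueError, match="disjoint"):
            classify.overlap_analysis(a, b, self._ann(["g1", "h1"]))
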