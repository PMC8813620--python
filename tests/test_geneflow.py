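"""Gene-flow scaling: counts, OLS fits, ratio curve, COG profiles, fractions."""

import numpy as np
import pandas as pd
import pytest

from mobilome.geneflow import (
    cog_taxon_profile,
    count_by_group,
    enriched_categories,
    fit_scaling,
    mge_length_fractions,
    ratio_vs_size,
)
from mobilome.synth import gen_gene_tables


def _table(rows):
    return pd.DataFrame(
        rows, columns=["genome_id", "gene_id", "gene_length_nt", "taxon_group",
                       "cog_category"]
    )


class TestCounts:
    def test_partition(self):
        rows = [
            ("g1", f"x{i}", 300, grp, None)
            for i, grp in enumerate(
                ["Archaea"] * 4 + ["Bacteria"] * 3 + ["Eukaryota"] * 2 + ["Unassigned"]
            )
        ]
        counts = count_by_group(_table(rows))
        r = counts.iloc[0]
        assert (r.Archaea, r.Bacteria, r.Eukaryota, r.Unassigned) == (4, 3, 2, 1)
        assert r.G == 10

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="unknown taxon"):
            count_by_group(_table([("g1", "x", 100, "Viruses", None)]))

    def test_row_order_invariance(self):
        table, _, _ = gen_gene_tables(5, n_genomes=4)
        shuffled = table.sample(frac=1.0, random_state=0)
        c1 = count_by_group(table)
        c2 = count_by_group(shuffled)
        pd.testing.assert_frame_equal(c1, c2)


class TestScalingFit:
    def test_exact_recovery_on_collinear_inputs(self):
        table, _, man = gen_gene_tables(3, noise_sigma=0.0)
        fit = fit_scaling(count_by_group(table))
        assert fit.groups["Archaea"].slope == pytest.approx(0.0, abs=1e-9)
        assert fit.archaeal_base == pytest.approx(900.0, abs=1e-6)
        assert fit.groups["Bacteria"].slope == pytest.approx(0.45, abs=1e-9)
        assert fit.groups["Bacteria"].intercept == pytest.approx(-300.0, abs=1e-6)
        assert all(f.r2 == pytest.approx(1.0) for g, f in fit.groups.items()
                   if f.slope != 0 or g == "Archaea")

    def test_matches_statsmodels_normal_equations(self):
        sm = pytest.importorskip("statsmodels.api")
        table, _, _ = gen_gene_tables(9, noise_sigma=30.0)
        counts = count_by_group(table)
        fit = fit_scaling(counts)
        X = sm.add_constant(counts["G"].to_numpy(dtype=float))
        for grp in ("Archaea", "Bacteria", "Eukaryota", "Unassigned"):
            res = sm.OLS(counts[grp].to_numpy(dtype=float), X).fit()
            assert fit.groups[grp].intercept == pytest.approx(res.params[0])
            assert fit.groups[grp].slope == pytest.approx(res.params[1])
            assert fit.groups[grp].slope_se == pytest.approx(res.bse[1])
            assert fit.groups[grp].r2 == pytest.approx(res.rsquared)

    def test_ci_coverage_over_replicates(self):
        """95% CIs cover the generative slopes in >=90% of 100 replicates."""
        hits = {"Archaea": 0, "Bacteria": 0, "Eukaryota": 0}
        true = {"Archaea": 0.0, "Bacteria": 0.45, "Eukaryota": 0.10}
        n_rep = 100
        for r in range(n_rep):
            table, _, _ = gen_gene_tables(20000 + r, noise_sigma=30.0)
            fit = fit_scaling(count_by_group(table))
            for grp, t in true.items():
                lo, hi = fit.groups[grp].slope_ci()
                if lo <= t <= hi:
                    hits[grp] += 1
        for grp, n in hits.items():
            assert n >= 0.90 * n_rep, (grp, n)

    def test_degenerate_design_rejected(self):
        counts = pd.DataFrame(
            {"genome_id": ["a", "b", "c"], "Archaea": [1, 2, 3], "Bacteria": [1, 1, 1],
             "Eukaryota": [0, 0, 0], "Unassigned": [0, 1, 2], "G": [2, 2, 2]}
        )
        with pytest.raises(ValueError, match="degenerate|equal"):
            fit_scaling(counts)


class TestRatio:
    def test_constant_archaea_decreasing_ratio(self):
        table, sizes, _ = gen_gene_tables(8, noise_sigma=0.0)
        series = ratio_vs_size(count_by_group(table), sizes)
        diffs = series.ratio.diff().dropna()
        assert (diffs < 0).all()

    def test_hand_computed_quotients(self):
        rows = [("g1", "a", 100, "Archaea", None)] * 0
        rows = [("g1", f"a{i}", 100, "Archaea", None) for i in range(6)]
        rows += [("g1", f"b{i}", 100, "Bacteria", None) for i in range(3)]
        rows += [("g2", f"a{i}", 100, "Archaea", None) for i in range(4)]
        rows += [("g2", f"b{i}", 100, "Bacteria", None) for i in range(8)]
        series = ratio_vs_size(count_by_group(_table(rows)), {"g1": 1000, "g2": 2000})
        assert series.ratio.tolist() == [2.0, 0.5]

    def test_zero_bacteria_flagged(self):
        rows = [("g1", "a0", 100, "Archaea", None)]
        rows += [("g2", "a0", 100, "Archaea", None), ("g2", "b0", 100, "Bacteria", None)]
        series = ratio_vs_size(count_by_group(_table(rows)), {"g1": 500, "g2": 900})
        assert series.undefined.tolist() == [True, False]
        assert np.isnan(series.ratio.iloc[0])


class TestCogProfile:
    def test_two_category_fractions(self):
        rows = [("g1", f"x{i}", 100, "Archaea", "J") for i in range(3)]
        rows += [("g1", "y0", 100, "Archaea", "K")]
        prof = cog_taxon_profile(_table(rows))
        j = prof[(prof.taxon_group == "Archaea") & (prof.cog_category == "J")]
        assert j.fraction.iloc[0] == pytest.approx(0.75)

    def test_unknown_function_excluded(self):
        rows = [("g1", "x0", 100, "Archaea", "S"), ("g1", "x1", 100, "Archaea", None)]
        prof = cog_taxon_profile(_table(rows))
        assert prof.empty

    def test_fractions_sum_to_one_per_group(self):
        table, _, _ = gen_gene_tables(6)
        prof = cog_taxon_profile(table)
        sums = prof.groupby("taxon_group").fraction.sum()
        assert np.allclose(sums, 1.0)

    def test_enrichment_recovered(self):
        """Groups built Archaea-enriched in J/K/L etc. are recovered exactly."""
        table, _, _ = gen_gene_tables(13)
        top = enriched_categories(cog_taxon_profile(table), top=3)
        assert set(top["Archaea"]) == {"J", "K", "L"}
        assert set(top["Eukaryota"]) == {"U", "Z", "O"}
        assert set(top["Bacteria"]) <= {"C", "E", "G", "P"}


class TestLengthFractions:
    def test_30_70(self):
        rows = [("m", "x", 300, "Bacteria", None), ("m", "y", 700, "Unassigned", None)]
        frac = mge_length_fractions(_table(rows))
        assert frac["Bacteria"] == pytest.approx(30.0)
        assert frac["Unassigned"] == pytest.approx(70.0)

    def test_sums_to_100(self):
        table, _, _ = gen_gene_tables(4, n_genomes=3)
        assert mge_length_fractions(table).sum() == pytest.approx(100.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            mge_length_fractions(_table([]))
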