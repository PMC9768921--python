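"""Differential-expression unit tests: normalization, test behaviour, set logic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from epicanal.core import SampleMeta
from epicanal.diffexpr import (
    DEGSet,
    TransformedMatrix,
    bh_adjust,
    call_degs,
    consensus_and_universal_sets,
    expression_cv_compare,
    filter_low_count_genes,
    median_ratio_size_factors,
    nb_wald_contrast,
    partition_te,
    sharing_spectrum,
    transform_counts,
)


def _two_group_design(n_per_group=3, accession="A"):
    wt = [SampleMeta(f"{accession}_WT_r{i}", accession, "WT", "L0", i)
          for i in range(1, n_per_group + 1)]
    mut = [SampleMeta(f"{accession}_M_r{i}", accession, "HOM_G1", "L1", i)
           for i in range(1, n_per_group + 1)]
    return wt + mut


class TestFilter:
    def test_zero_row_removed(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [0, 3]}, index=["gz", "g1"])
        assert list(filter_low_count_genes(counts, min_total=1)) == ["g1"]

    def test_min_total_zero_is_identity(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [0, 3]}, index=["gz", "g1"])
        assert list(filter_low_count_genes(counts, min_total=0)) == ["gz", "g1"]

    def test_survivors_equal_brute_force(self, rng):
        counts = pd.DataFrame(rng.poisson(2, (100, 6)))
        kept = filter_low_count_genes(counts, min_total=10)
        brute = [i for i in counts.index if counts.loc[i].sum() >= 10]
        assert list(kept) == brute

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            filter_low_count_genes(pd.DataFrame())


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]})
        np.testing.assert_allclose(median_ratio_size_factors(counts), [1.0, 1.0])

    def test_doubled_sample_gives_sqrt2_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [20, 40, 10]})
        np.testing.assert_allclose(
            median_ratio_size_factors(counts), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12
        )

    def test_matches_brute_force_median_of_ratios(self, rng):
        counts = pd.DataFrame(rng.negative_binomial(5, 0.2, (200, 6)) + 1)
        got = median_ratio_size_factors(counts)
        log_geo = np.log(counts.to_numpy()).mean(axis=1)
        expected = [
            np.exp(np.median(np.log(counts.iloc[:, j]) - log_geo))
            for j in range(6)
        ]
        np.testing.assert_allclose(got.to_numpy(), expected, rtol=1e-12)

    def test_no_universal_gene_raises(self):
        counts = pd.DataFrame({"a": [0, 3], "b": [4, 0]})
        with pytest.raises(ValueError, match="pseudo-reference"):
            median_ratio_size_factors(counts)


class TestTransform:
    def test_closed_form_values(self):
        counts = pd.DataFrame({"s": [0, 7]})
        tm = transform_counts(counts, pd.Series({"s": 1.0}))
        np.testing.assert_allclose(tm.values["s"], [0.0, 3.0])

    def test_order_preserved_within_sample(self, rng):
        counts = pd.DataFrame(rng.poisson(20, (50, 4)))
        sf = pd.Series(rng.uniform(0.5, 2.0, 4), index=counts.columns)
        tm = transform_counts(counts, sf)
        for c in counts.columns:
            order = counts[c].argsort(kind="mergesort")
            assert tm.values[c].to_numpy()[order].argsort(kind="mergesort").tolist() == sorted(
                range(50)
            )


class TestBHAdjustment:
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=200))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_statsmodels(self, pvals):
        from statsmodels.stats.multitest import multipletests

        got = bh_adjust(np.array(pvals))
        expected = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(got, expected, rtol=1e-12, atol=1e-15)

    def test_nan_passthrough(self):
        got = bh_adjust(np.array([0.01, np.nan, 0.04]))
        assert np.isnan(got[1]) and not np.isnan(got[[0, 2]]).any()


class TestWaldContrast:
    def test_identical_groups_zero_lfc(self):
        design = _two_group_design()
        row = [13, 21, 8]
        counts = pd.DataFrame([row + row] * 5, columns=[s.sample_id for s in design])
        res = nb_wald_contrast(
            counts, design, "genotype_x_accession", {"type": "genotype"},
            size_factors=pd.Series(1.0, index=counts.columns),
        )
        assert (res["log2fc"].abs() < 1e-8).all()

    def test_empty_cell_named_in_error(self):
        design = [SampleMeta(f"A_WT_r{i}", "A", "WT", "L0", i) for i in (1, 2, 3)]
        counts = pd.DataFrame(
            np.ones((3, 3), dtype=int) * 5, columns=[s.sample_id for s in design]
        )
        with pytest.raises(ValueError, match="A"):
            nb_wald_contrast(counts, design, "genotype_x_accession", {"type": "genotype"})

    def test_matches_statsmodels_glm_fit(self, rng):
        # independent NB GLM route: same likelihood, different implementation
        import statsmodels.api as sm

        design = _two_group_design()
        mu = np.full((30, 6), 80.0)
        mu[:, 3:] *= 2.5
        counts = pd.DataFrame(
            rng.negative_binomial(10, 10 / (10 + mu)) + 1,
            columns=[s.sample_id for s in design],
        )
        sf = pd.Series(1.0, index=counts.columns)
        disp = pd.Series(0.1, index=counts.index)
        res = nb_wald_contrast(
            counts, design, "genotype_x_accession", {"type": "genotype"},
            size_factors=sf, dispersions=disp,
        )
        X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
        for g in counts.index:
            fit = sm.GLM(
                counts.loc[g].to_numpy(),
                X,
                family=sm.families.NegativeBinomial(alpha=0.1),
            ).fit()
            lfc_sm = fit.params[1] / np.log(2)
            se_sm = fit.bse[1] / np.log(2)
            assert res.loc[g, "log2fc"] == pytest.approx(lfc_sm, abs=1e-5)
            assert res.loc[g, "se"] == pytest.approx(se_sm, rel=1e-3)

    def test_planted_effect_recovered(self, rng):
        design = _two_group_design()
        mu = np.full((300, 6), 200.0)
        mu[:, 3:] *= 4.0  # log2fc = 2
        counts = pd.DataFrame(
            rng.negative_binomial(10, 10 / (10 + mu)),
            columns=[s.sample_id for s in design],
        )
        res = nb_wald_contrast(
            counts, design, "genotype_x_accession", {"type": "genotype"},
            size_factors=pd.Series(1.0, index=counts.columns),
        )
        assert abs(res["log2fc"].median() - 2.0) < 0.2


class TestDEGCalling:
    def _results(self):
        return pd.DataFrame(
            {
                "log2fc": [3.0, 1.0, -2.0, 0.5, 1.5],
                "padj": [0.5, 0.005, 0.001, 0.001, 0.002],
            },
            index=[f"g{i}" for i in range(5)],
        )

    def test_insignificant_excluded(self):
        degs = call_degs(self._results())
        assert "g0" not in degs.genes  # padj 0.5 despite |lfc| 3

    def test_boundary_lfc_exactly_one_excluded(self):
        degs = call_degs(self._results())
        assert "g1" not in degs.genes
        degs_inclusive = call_degs(self._results(), inclusive=True)
        assert "g1" in degs_inclusive.genes

    def test_equals_brute_force_refilter(self, rng):
        res = pd.DataFrame(
            {"log2fc": rng.normal(0, 2, 300), "padj": rng.uniform(0, 1, 300)},
            index=[f"g{i}" for i in range(300)],
        )
        degs = call_degs(res, lfc_min=1.0, alpha=0.05)
        brute = {
            g for g in res.index
            if res.loc[g, "padj"] < 0.05 and abs(res.loc[g, "log2fc"]) > 1.0
        }
        assert degs.genes == brute

    def test_antitone_in_alpha_and_lfc(self, rng):
        res = pd.DataFrame(
            {"log2fc": rng.normal(0, 2, 300), "padj": rng.uniform(0, 1, 300)},
            index=[f"g{i}" for i in range(300)],
        )
        loose = call_degs(res, lfc_min=0.5, alpha=0.1)
        tight_alpha = call_degs(res, lfc_min=0.5, alpha=0.01)
        tight_lfc = call_degs(res, lfc_min=2.0, alpha=0.1)
        assert tight_alpha.genes <= loose.genes
        assert tight_lfc.genes <= loose.genes


class TestSetLogic:
    def _sets(self, memberships):
        out = []
        for i, genes in enumerate(memberships):
            table = pd.DataFrame(
                {"log2fc": 1.5, "padj": 0.001, "direction": "up"},
                index=pd.Index(sorted(genes), name="gene_id"),
            )
            out.append(DEGSet(f"c{i}", table))
        return out

    def test_consensus_universal_examples(self):
        sets = self._sets([{"a", "b"}] * 18 + [{"b", "c"}])
        consensus, universal = consensus_and_universal_sets(sets)
        assert consensus.genes == {"a", "b"}  # c appears once only
        assert universal.genes == {"b"}
        assert universal.genes <= consensus.genes

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError, match="19"):
            consensus_and_universal_sets(self._sets([{"a"}] * 5))

    def test_random_membership_oracle(self, rng):
        genes = [f"g{i}" for i in range(50)]
        memberships = [
            {g for g in genes if rng.random() < 0.3} or {"g0"} for _ in range(19)
        ]
        consensus, universal = consensus_and_universal_sets(self._sets(memberships))
        count = {g: sum(g in m for m in memberships) for g in genes}
        assert consensus.genes == {g for g, n in count.items() if n >= 2}
        assert universal.genes == {g for g, n in count.items() if n == 19}

    def test_sharing_spectrum_counting_oracle(self, rng):
        genes = [f"g{i}" for i in range(40)]
        focal_genes = set(genes[:25])
        others = [{g for g in genes if rng.random() < 0.4} or {"g0"} for _ in range(6)]
        [focal], other_sets = self._sets([focal_genes]), self._sets(others)
        spectrum = sharing_spectrum(focal, other_sets)
        assert spectrum.sum() == len(focal_genes)
        brute = np.zeros(7, dtype=int)
        for g in focal_genes:
            brute[sum(g in m for m in others)] += 1
        assert np.array_equal(spectrum, brute)

    def test_partition_te(self):
        [ds] = self._sets([{"g1", "g2", "g3"}])
        annotation = pd.DataFrame(
            {"is_te_gene": [True, True, True]}, index=["g1", "g2", "g3"]
        )
        te, non_te = partition_te(ds, annotation)
        assert te.genes == {"g1", "g2", "g3"} and non_te.genes == set()
        with pytest.raises(ValueError, match="g9"):
            partition_te(self._sets([{"g9"}])[0], annotation)


class TestCVComparison:
    def _design(self, n_acc=4, reps=2):
        out = []
        for a in range(n_acc):
            acc = f"A{a}"
            for r in range(1, reps + 1):
                out.append(SampleMeta(f"{acc}_WT_r{r}", acc, "WT", "L0", r))
                out.append(SampleMeta(f"{acc}_M_r{r}", acc, "HOM_G1", "L1", r))
        return out

    def test_two_point_closed_form(self):
        # per-accession means {1, 3} -> CV = sqrt(2)/2
        design = self._design(n_acc=2, reps=1)
        values = pd.DataFrame(
            {s.sample_id: [1.0 if s.accession == "A0" else 3.0] for s in design}
        )
        tm = TransformedMatrix(values, pd.Series(1.0, index=values.columns))
        records, _ = expression_cv_compare(tm, design)
        assert records["cv_wt"].iloc[0] == pytest.approx(np.sqrt(2) / 2)
        assert records["cv_mut"].iloc[0] == pytest.approx(np.sqrt(2) / 2)

    def test_constant_expression_degenerate(self):
        design = self._design()
        values = pd.DataFrame(
            5.0, index=["g1", "g2"], columns=[s.sample_id for s in design]
        )
        tm = TransformedMatrix(values, pd.Series(1.0, index=values.columns))
        records, p = expression_cv_compare(tm, design)
        assert (records["cv_wt"] == 0).all()
        assert np.isnan(p)

    def test_planted_mutant_variance_inflation_detected(self, rng):
        design = self._design(n_acc=6, reps=3)
        cols = [s.sample_id for s in design]
        n_genes = 500
        base = rng.uniform(5, 8, n_genes)
        values = pd.DataFrame(index=range(n_genes), columns=cols, dtype=float)
        for s in design:
            acc_idx = int(s.accession[1:])
            acc_shift = rng.normal(0, 0.1, n_genes) * 0 + 0.0
            values[s.sample_id] = base + rng.normal(0, 0.05, n_genes)
        # accession-specific shifts: x4 spread in mutants
        acc_shifts = {f"A{a}": rng.normal(0, 0.2, n_genes) for a in range(6)}
        for s in design:
            shift = acc_shifts[s.accession]
            factor = 4.0 if s.genotype != "WT" else 1.0
            values[s.sample_id] = values[s.sample_id] + factor * shift
        tm = TransformedMatrix(values, pd.Series(1.0, index=cols))
        records, p = expression_cv_compare(tm, design)
        assert p < 1e-4
        assert records["cv_mut"].median() > records["cv_wt"].median()

    def test_single_accession_group_rejected(self):
        design = [
            SampleMeta("A_WT_r1", "A", "WT", "L0", 1),
            SampleMeta("A_M_r1", "A", "HOM_G1", "L1", 1),
            SampleMeta("B_M_r1", "B", "HOM_G1", "L1", 1),
        ]
        values = pd.DataFrame(1.0, index=["g"], columns=[s.sample_id for s in design])
        tm = TransformedMatrix(values, pd.Series(1.0, index=values.columns))
        with pytest.raises(ValueError):
            expression_cv_compare(tm, design)
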