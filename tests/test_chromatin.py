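"""Peak handling, TMM/CPM normalization, and ACR selection unit tests."""

import math

import numpy as np
import pandas as pd
import pytest

from epicanal.chromatin import (
    AccessibilityMatrix,
    cluster_hv_dacrs,
    consensus_peaks,
    frip,
    read_filtered_peaks,
    select_dacrs,
    select_hv_dacrs,
    tmm_cpm,
)
from epicanal.core import SampleMeta


def _narrowpeak_line(chrom, start, end, name, qneglog10):
    return "\t".join(
        [chrom, str(start), str(end), name, "100", ".", "5.0", "6.0",
         f"{qneglog10:.6f}", str((end - start) // 2)]
    )


class TestReadFilteredPeaks:
    def test_q_boundary_semantics(self, tmp_path):
        path = tmp_path / "peaks.narrowPeak"
        path.write_text(
            "\n".join(
                [
                    _narrowpeak_line("chr1", 0, 100, "keep_exact", 3.0),  # q = 0.001
                    _narrowpeak_line("chr1", 200, 300, "drop", -math.log10(0.0011)),
                    _narrowpeak_line("chr1", 400, 500, "keep_small", 5.0),
                ]
            )
            + "\n"
        )
        peaks = read_filtered_peaks(path, q_max=0.001)
        assert list(peaks["name"]) == ["keep_exact", "keep_small"]

    def test_retained_count_equals_file_scan(self, tmp_path, rng):
        qs = rng.uniform(1.5, 5.0, 50)
        lines = [
            _narrowpeak_line("chr1", 100 * i, 100 * i + 80, f"p{i}", q)
            for i, q in enumerate(qs)
        ]
        path = tmp_path / "peaks.narrowPeak"
        path.write_text("\n".join(lines) + "\n")
        peaks = read_filtered_peaks(path, q_max=0.001)
        expected = sum(10.0 ** (-q) <= 0.001 * (1 + 1e-9) for q in qs)
        assert len(peaks) == expected

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.narrowPeak"
        path.write_text(
            _narrowpeak_line("chr1", 0, 100, "ok", 4.0) + "\nchr1\t5\n"
        )
        with pytest.raises(ValueError, match=":2"):
            read_filtered_peaks(path)


class TestConsensusPeaks:
    def _df(self, intervals):
        return pd.DataFrame(intervals, columns=["chrom", "start", "end"])

    def test_unanimous_peak_in_consensus(self):
        reps = [self._df([("chr1", 100, 200)])] * 3
        cons = consensus_peaks({"g1": reps})
        assert len(cons) == 1
        assert (cons.iloc[0]["start"], cons.iloc[0]["end"]) == (100, 200)

    def test_single_replicate_peak_absent(self):
        reps = [
            self._df([("chr1", 100, 200)]),
            self._df([("chr1", 500, 600)]),
            self._df([("chr1", 800, 900)]),
        ]
        cons = consensus_peaks({"g1": reps})
        assert len(cons) == 0

    def test_matches_base_pair_pileup_oracle(self, rng):
        reps = []
        for _ in range(3):
            starts = np.sort(rng.choice(np.arange(0, 900, 10), 6, replace=False))
            reps.append(self._df([("chr1", s, s + int(rng.integers(20, 120))) for s in starts]))
        cons = consensus_peaks({"g1": reps}, min_replicates=2)
        # oracle: per-base occupancy over a small genome
        cover = np.zeros(1200, dtype=int)
        for rep in reps:
            rep_mask = np.zeros(1200, dtype=bool)
            for _, r in rep.iterrows():
                rep_mask[r["start"]:r["end"]] = True
            cover += rep_mask
        expected = cover >= 2
        got = np.zeros(1200, dtype=bool)
        for _, r in cons.iterrows():
            got[r["start"]:r["end"]] = True
        assert np.array_equal(got, expected)

    def test_single_replicate_group_warns(self):
        with pytest.warns(UserWarning, match="replicate"):
            cons = consensus_peaks({"g1": [self._df([("chr1", 0, 50)])]})
        assert len(cons) == 1


def _reference_tmm(counts: pd.DataFrame, trim_m=0.3, trim_a=0.05) -> np.ndarray:
    """Straightforward rank-based trimmed-mean-of-M oracle (independent code)."""
    arr = counts.to_numpy(float)
    lib = arr.sum(axis=0)
    uq = np.array([np.quantile(arr[arr[:, j] > 0, j], 0.75) / lib[j] for j in range(arr.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = []
    for j in range(arr.shape[1]):
        y, r = arr[:, j], arr[:, ref]
        ok = (y > 0) & (r > 0)
        y, r = y[ok], r[ok]
        m = np.log2((y / lib[j]) / (r / lib[ref]))
        a = 0.5 * np.log2((y / lib[j]) * (r / lib[ref]))
        w = (lib[j] - y) / (lib[j] * y) + (lib[ref] - r) / (lib[ref] * r)
        if len(m) == 0 or np.max(np.abs(m)) < 1e-6:
            factors.append(1.0)
            continue
        n = len(m)
        from scipy.stats import rankdata

        rm, ra = rankdata(m), rankdata(a)
        lo_l, hi_l = math.floor(n * trim_m) + 1, n - math.floor(n * trim_m)
        lo_s, hi_s = math.floor(n * trim_a) + 1, n - math.floor(n * trim_a)
        keep = (rm >= lo_l) & (rm <= hi_l) & (ra >= lo_s) & (ra <= hi_s)
        factors.append(2 ** (np.sum(m[keep] / w[keep]) / np.sum(1 / w[keep])))
    factors = np.array(factors)
    return factors / np.exp(np.mean(np.log(factors)))


class TestTMMCPM:
    def test_identical_samples_unit_factors_and_cpm_sums(self):
        counts = pd.DataFrame({"a": [10, 30, 60], "b": [10, 30, 60]})
        m = tmm_cpm(counts)
        np.testing.assert_allclose(m.tmm_factors, 1.0)
        np.testing.assert_allclose(m.cpm.sum(axis=0), 1e6)

    def test_scaled_sample_cpm_invariance(self, rng):
        base = rng.poisson(50, 40) + 1
        counts = pd.DataFrame({"a": base, "b": base * 3})
        m = tmm_cpm(counts)
        np.testing.assert_allclose(m.cpm["a"], m.cpm["b"], rtol=1e-10)

    def test_matches_independent_oracle(self, rng):
        counts = pd.DataFrame(rng.negative_binomial(8, 0.1, (20, 5)) + 1)
        m = tmm_cpm(counts)
        np.testing.assert_allclose(
            m.tmm_factors.to_numpy(), _reference_tmm(counts), atol=1e-10
        )

    def test_cpm_identity_exact(self, rng):
        counts = pd.DataFrame(rng.poisson(30, (50, 4)))
        m = tmm_cpm(counts)
        back = m.cpm * (m.lib_sizes * m.tmm_factors) / 1e6
        np.testing.assert_allclose(back.to_numpy(), counts.to_numpy(), atol=1e-9)

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError, match="all-zero"):
            tmm_cpm(counts)


class TestFRIP:
    def test_bounds(self):
        in_peak = pd.Series({"a": 100, "b": 0})
        totals = pd.Series({"a": 100, "b": 50})
        scores = frip(in_peak, totals)
        assert scores["a"] == 1.0 and scores["b"] == 0.0

    def test_arithmetic_oracle(self, rng):
        in_peak = pd.Series(rng.integers(10, 100, 8), index=[f"s{i}" for i in range(8)])
        totals = in_peak + rng.integers(0, 200, 8)
        scores = frip(in_peak, totals)
        for s in in_peak.index:
            assert scores[s] == in_peak[s] / totals[s]

    def test_total_below_in_peak_rejected(self):
        with pytest.raises(ValueError, match="total"):
            frip(pd.Series({"a": 10}), pd.Series({"a": 5}))


def _acc_design(n_acc=3, lines=2, reps=2):
    design = []
    for a in range(n_acc):
        acc = f"A{a}"
        for r in range(1, reps + 1):
            design.append(SampleMeta(f"{acc}_WT_r{r}", acc, "WT", "L0", r))
        for li in range(1, lines + 1):
            for r in range(1, reps + 1):
                design.append(
                    SampleMeta(f"{acc}_L{li}_r{r}", acc, "HOM_G1", f"L{li}", r)
                )
    return design


def _matrix_from_cpm(cpm: pd.DataFrame) -> AccessibilityMatrix:
    lib = pd.Series(1e6, index=cpm.columns)
    tmm = pd.Series(1.0, index=cpm.columns)
    return AccessibilityMatrix(counts=cpm, lib_sizes=lib, tmm_factors=tmm, cpm=cpm)


class TestSelectDACRs:
    def _cpm(self, design, peak_specs):
        """peak_specs: list of dicts accession -> (line1_mult, line2_mult)."""
        cols = [s.sample_id for s in design]
        rows = []
        for spec in peak_specs:
            row = []
            for s in design:
                base = 50.0
                if s.genotype != "WT":
                    mult = spec.get(s.accession, (1.0, 1.0))[int(s.line[1:]) - 1]
                    base *= mult
                row.append(base)
            rows.append(row)
        return pd.DataFrame(rows, columns=cols)

    def test_unchanged_peak_rejected(self):
        design = _acc_design()
        cpm = self._cpm(design, [{}])
        assert len(select_dacrs(_matrix_from_cpm(cpm), design)) == 0

    def test_sign_conflict_rejected(self):
        design = _acc_design()
        cpm = self._cpm(design, [{"A0": (2.83, 0.35), "A1": (4.0, 4.0), "A2": (4.0, 4.0)}])
        assert len(select_dacrs(_matrix_from_cpm(cpm), design)) == 0

    def test_gain_in_two_accessions_selected_one_rejected(self):
        design = _acc_design()
        cpm = self._cpm(
            design,
            [
                {"A0": (4.0, 4.0), "A1": (4.0, 4.0)},  # changed in 2 accessions
                {"A0": (4.0, 4.0)},  # changed in 1 accession only
            ],
        )
        got = select_dacrs(_matrix_from_cpm(cpm), design)
        assert list(got) == [0]

    def test_antitone_in_delta_and_min_accessions(self, rng):
        design = _acc_design()
        cols = [s.sample_id for s in design]
        cpm = pd.DataFrame(rng.uniform(10, 400, (60, len(cols))), columns=cols)
        m = _matrix_from_cpm(cpm)
        loose = set(select_dacrs(m, design, min_accessions=1, delta_log2=0.25))
        assert set(select_dacrs(m, design, min_accessions=2, delta_log2=0.25)) <= loose
        assert set(select_dacrs(m, design, min_accessions=1, delta_log2=1.0)) <= loose

    def test_missing_wt_rejected(self):
        design = [s for s in _acc_design() if not (s.accession == "A0" and s.genotype == "WT")]
        cpm = self._cpm(design, [{}])
        with pytest.raises(ValueError, match="A0"):
            select_dacrs(_matrix_from_cpm(cpm), design)


class TestSelectHVDACRs:
    def test_counting_and_union_bounds(self, rng):
        design = _acc_design()
        cols = [s.sample_id for s in design]
        cpm = pd.DataFrame(rng.uniform(5, 500, (8, len(cols))), columns=cols)
        hv, cvs = select_hv_dacrs(_matrix_from_cpm(cpm), design, cpm.index)
        assert 2 <= len(hv) <= 4  # each filter keeps ceil(0.25 * 8) = 2

    def test_equal_group_means_bottom_ranked(self):
        design = _acc_design()
        cols = [s.sample_id for s in design]
        cpm = pd.DataFrame(100.0, index=range(8), columns=cols)
        cpm.iloc[1:] += np.arange(1, 8)[:, None] * 37.0 * np.linspace(0.2, 1.8, len(cols))
        hv, cvs = select_hv_dacrs(_matrix_from_cpm(cpm), design, cpm.index)
        assert cvs.loc[0, "cv_group_diff"] == 0.0
        assert 0 not in hv

    def test_union_equals_sort_and_slice_oracle(self, rng):
        design = _acc_design()
        cols = [s.sample_id for s in design]
        cpm = pd.DataFrame(rng.uniform(5, 500, (40, len(cols))), columns=cols)
        hv, cvs = select_hv_dacrs(_matrix_from_cpm(cpm), design, cpm.index)
        n_keep = math.ceil(0.25 * 40)
        top_a = set(cvs["cv_group_diff"].sort_values(ascending=False).index[:n_keep])
        top_b = set(cvs["cv_samples"].sort_values(ascending=False).index[:n_keep])
        assert set(hv) == top_a | top_b

    def test_two_point_cv_formula(self):
        design = _acc_design()
        cols = [s.sample_id for s in design]
        cpm = pd.DataFrame(
            [[30.0 if s.genotype == "WT" else 90.0 for s in design]] * 4,
            columns=cols,
        )
        _, cvs = select_hv_dacrs(_matrix_from_cpm(cpm), design, cpm.index)
        expected = (90 - 30) / np.sqrt(2) / 60  # sample-SD two-point CV
        assert cvs["cv_group_diff"].iloc[0] == pytest.approx(expected)


class TestClusterHVDACRs:
    def _blobs(self, rng):
        cols = [f"s{i}" for i in range(12)]
        # three patterns that stay well separated after per-row z-scaling
        centers = np.array([
            [0.0] * 6 + [8.0] * 6,
            [8.0] * 6 + [0.0] * 6,
            [0.0, 8.0] * 6,
        ])
        rows, truth = [], []
        for c in range(3):
            for _ in range(20):
                rows.append(centers[c] + rng.normal(0, 0.05, 12))
                truth.append(c)
        cpm = pd.DataFrame(rows, columns=cols) + 10.0
        return _matrix_from_cpm(cpm), np.array(truth)

    def test_separable_blobs_recovered(self, rng):
        matrix, truth = self._blobs(rng)
        labels, means = cluster_hv_dacrs(matrix, matrix.cpm.index, k=3, seed=1)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, labels.to_numpy()) == 1.0
        assert set(means.index) == set(labels.unique())

    def test_deterministic_given_seed(self, rng):
        matrix, _ = self._blobs(rng)
        a, _ = cluster_hv_dacrs(matrix, matrix.cpm.index, k=3, seed=9)
        b, _ = cluster_hv_dacrs(matrix, matrix.cpm.index, k=3, seed=9)
        pd.testing.assert_series_equal(a, b)

    def test_wcss_beats_random_assignments(self, rng):
        matrix, _ = self._blobs(rng)
        labels, _ = cluster_hv_dacrs(matrix, matrix.cpm.index, k=3, seed=2)
        cpm = matrix.cpm
        z = cpm.sub(cpm.mean(axis=1), axis=0).div(cpm.std(axis=1, ddof=0), axis=0)

        def wcss(lbl):
            total = 0.0
            for c in np.unique(lbl):
                block = z.to_numpy()[lbl == c]
                total += ((block - block.mean(axis=0)) ** 2).sum()
            return total

        ours = wcss(labels.to_numpy())
        randoms = [wcss(rng.integers(1, 4, len(z))) for _ in range(100)]
        assert all(ours <= r for r in randoms)

    def test_zero_variance_rows_excluded_with_warning(self, rng):
        matrix, _ = self._blobs(rng)
        cpm = matrix.cpm.copy()
        cpm.iloc[0] = 42.0
        m = _matrix_from_cpm(cpm)
        with pytest.warns(UserWarning, match="zero-variance"):
            labels, _ = cluster_hv_dacrs(m, cpm.index, k=3, seed=3)
        assert 0 not in labels.index
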