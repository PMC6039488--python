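"""Plate-based swapped-fraction estimators and auxiliary regressions."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from barcodeswap import (
    CombinationCounts,
    CrossPlatformPair,
    DesignError,
    PlateDesign,
    available_reads,
    estimate_swap_crossplatform,
    estimate_swap_impossible,
    free_barcode_association,
    genewise_swap_test,
)
from barcodeswap.simulate import PlateSimConfig, simulate_plate
from barcodeswap.types import EstimationError


class TestAvailableReads:
    def test_matches_enumeration_on_toy_design(self, toy_counts):
        """(R1,C3) shares one barcode with exactly four expected combos."""
        sharers = [
            c
            for c in toy_counts.design.expected
            if PlateDesign.shares_one(("R1", "C3"), c)
        ]
        assert sorted(sharers) == [
            ("R1", "C1"), ("R1", "C2"), ("R3", "C3"), ("R4", "C3")
        ]
        assert available_reads(toy_counts, ("R1", "C3")) == 40

    def test_all_zero_library_sizes(self, toy_design):
        cc = CombinationCounts(toy_design, {})
        assert available_reads(cc, ("R1", "C3")) == 0

    def test_target_sharing_only_empty_combos(self, toy_design):
        # reads only in P2's (R3,C3); (R1,C4) shares a barcode only with
        # C4-column and R1-row combos, all empty
        cc = CombinationCounts(toy_design, {("R3", "C3"): 50})
        assert available_reads(cc, ("R1", "C4")) == 0
        assert available_reads(cc, ("R1", "C3")) == 50

    def test_expected_target_rejected(self, toy_counts):
        with pytest.raises(DesignError):
            available_reads(toy_counts, ("R1", "C1"))


def _exact_linear_counts(rate_inv: int = 1000):
    """Two 8x12 plates whose impossible counts are exactly available/1000."""
    design = PlateDesign.grid(2, 8, 12)
    lib = {c: rate_inv * (i % 7 + 1) for i, c in enumerate(design.expected)}
    cc = CombinationCounts(design, lib)
    for target in design.impossible:
        lib[target] = available_reads(cc, target) // rate_inv
    return CombinationCounts(design, lib)


class TestImpossibleRegression:
    def test_exact_linear_data_recovers_slope_analytically(self):
        """Impossible counts at exactly 0.001 x available reads, D = 38."""
        cc = _exact_linear_counts()
        est = estimate_swap_impossible(cc)
        assert est.diagnostics["n_destinations"] == 38
        assert est.fraction == pytest.approx(0.038, abs=1e-9)
        assert est.std_error == pytest.approx(0.0, abs=1e-9)
        assert est.diagnostics["intercept"] == pytest.approx(0.0, abs=1e-6)

    def test_no_swapped_reads_gives_zero_fraction(self):
        design = PlateDesign.grid(2, 8, 12)
        lib = {c: 1000 * (i % 7 + 1) for i, c in enumerate(design.expected)}
        est = estimate_swap_impossible(CombinationCounts(design, lib))
        assert est.fraction == pytest.approx(0.0, abs=1e-12)

    def test_constant_available_reads_unidentifiable(self, toy_counts):
        with pytest.raises(EstimationError):
            estimate_swap_impossible(toy_counts)

    def test_single_plate_design_rejected(self):
        design = PlateDesign.grid(1, 8, 12)
        with pytest.raises(DesignError):
            estimate_swap_impossible(CombinationCounts(design, {}))

    def test_invariance_under_relabelling_and_scaling(self):
        cc = _exact_linear_counts()
        base = estimate_swap_impossible(cc).fraction
        # relabel every barcode
        design = cc.design
        ren = lambda b: f"X_{b}"
        design2 = PlateDesign(
            design.plates,
            {p: tuple(ren(b) for b in design.row_barcodes[p]) for p in design.plates},
            {p: tuple(ren(b) for b in design.col_barcodes[p]) for p in design.plates},
        )
        lib2 = {(ren(r), ren(c)): 3 * n for (r, c), n in cc.library_size.items()}
        est2 = estimate_swap_impossible(CombinationCounts(design2, lib2))
        assert est2.fraction == pytest.approx(base, rel=1e-9)

    def test_recovers_injected_fraction_from_simulation(self):
        res = simulate_plate(PlateSimConfig(swap_fraction=0.02, seed=7))
        est = estimate_swap_impossible(res.counts)
        assert abs(est.fraction - 0.02) < 3 * est.std_error

    def test_precision_improves_with_depth(self):
        shallow = simulate_plate(PlateSimConfig(mean_reads=1000, seed=5))
        deep = simulate_plate(PlateSimConfig(mean_reads=20000, seed=5))
        est_s = estimate_swap_impossible(shallow.counts)
        est_d = estimate_swap_impossible(deep.counts)
        for est in (est_s, est_d):
            assert abs(est.fraction - 0.02) < 3 * est.std_error
        assert est_d.std_error < est_s.std_error


def _single_plate_pair(seed=0, n_rows=3, n_cols=4, n_genes=30, transform=None):
    rng = np.random.default_rng(seed)
    design = PlateDesign.grid(1, n_rows, n_cols)
    cells = design.expected
    ref = rng.integers(5, 100, size=(n_genes, len(cells))).astype(float)
    cols = pd.MultiIndex.from_tuples(cells)
    genes = [f"G{i}" for i in range(n_genes)]
    ref_df = pd.DataFrame(ref, index=genes, columns=cols)
    swapped = transform(ref_df, design) if transform else ref_df.copy()
    return CrossPlatformPair(ref_df, swapped, design)


def _share_one_sums(ref_df, design):
    cells = list(ref_df.columns)
    out = np.zeros_like(ref_df.to_numpy())
    for j, cj in enumerate(cells):
        for i, ci in enumerate(cells):
            if i != j and PlateDesign.shares_one(tuple(ci), tuple(cj)):
                out[:, j] += ref_df.to_numpy()[:, i]
    return pd.DataFrame(out, index=ref_df.index, columns=ref_df.columns)


class TestCrossPlatformModel:
    def test_identical_matrices_give_zero_fraction(self):
        pair = _single_plate_pair(seed=1)
        est = estimate_swap_crossplatform(pair, n_boot=0)
        assert est.fraction == pytest.approx(0.0, abs=1e-8)
        assert est.diagnostics["coef_self"] == pytest.approx(1.0, abs=1e-8)

    def test_model_generated_fraction_recovered_exactly(self):
        """swapped = 0.98 x + 0.02 (s X / S) makes the fraction 0.02."""

        def transform(ref_df, design):
            s = _share_one_sums(ref_df, design)
            scale = ref_df.to_numpy().sum() / s.to_numpy().sum()
            return 0.98 * ref_df + 0.02 * s * scale

        pair = _single_plate_pair(seed=2, transform=transform)
        est = estimate_swap_crossplatform(pair, n_boot=0)
        assert est.fraction == pytest.approx(0.02, abs=1e-8)

    def test_all_zero_reference_rejected(self):
        design = PlateDesign.grid(1, 2, 2)
        cols = pd.MultiIndex.from_tuples(design.expected)
        zero = pd.DataFrame(np.zeros((3, 4)), columns=cols)
        pair = CrossPlatformPair(zero, zero.copy(), design)
        with pytest.raises(EstimationError):
            estimate_swap_crossplatform(pair, n_boot=0)

    def test_bootstrap_se_is_positive_on_noisy_data(self):
        def transform(ref_df, design):
            rng = np.random.default_rng(9)
            noisy = ref_df + rng.normal(0, 5, size=ref_df.shape)
            return noisy.clip(lower=0)

        pair = _single_plate_pair(seed=3, n_rows=4, n_cols=6, transform=transform)
        est = estimate_swap_crossplatform(pair, n_boot=50, seed=4)
        assert est.std_error > 0

    def test_mismatched_gene_sets_rejected(self):
        pair_ok = _single_plate_pair(seed=1)
        other = pair_ok.counts_swapped.copy()
        other.index = [f"H{i}" for i in range(len(other))]
        with pytest.raises(DesignError):
            CrossPlatformPair(pair_ok.counts_ref, other, pair_ok.design)


def _genewise_pair(seed, n_genes=200, swap_coef=0.0, noise_sd=4.0):
    rng = np.random.default_rng(seed)
    design = PlateDesign.grid(1, 8, 12)
    cells = design.expected
    ref = rng.integers(20, 200, size=(n_genes, len(cells))).astype(float)
    cols = pd.MultiIndex.from_tuples(cells)
    ref_df = pd.DataFrame(ref, index=[f"G{i}" for i in range(n_genes)], columns=cols)
    s = _share_one_sums(ref_df, design)
    swapped = ref_df + swap_coef * s + rng.normal(0, noise_sd, size=ref.shape)
    swapped = swapped.clip(lower=0)
    return CrossPlatformPair(ref_df, swapped, design)


class TestGenewiseSwapTest:
    def test_identical_matrices_give_no_significant_genes(self):
        pair = _single_plate_pair(seed=5, n_genes=50)
        res = genewise_swap_test(pair, alpha=0.5)
        assert res.n_significant_positive == 0
        assert res.n_significant_negative == 0

    def test_type_one_error_calibrated_under_null(self):
        """Gaussian noise around a*x alone: ~5% of raw p below 0.05."""
        res = genewise_swap_test(_genewise_pair(seed=6, n_genes=200))
        pvals = res.table.loc[res.table["tested"], "p_value"]
        frac = (pvals < 0.05).mean()
        bound = 2.576 * np.sqrt(0.05 * 0.95 / len(pvals))
        assert 0.05 - bound < frac < 0.05 + bound

    def test_null_pvalues_uniform(self):
        """Kolmogorov-Smirnov on 1000 null genes at the 1% level."""
        res = genewise_swap_test(_genewise_pair(seed=7, n_genes=1000))
        pvals = res.table.loc[res.table["tested"], "p_value"].to_numpy()
        assert scipy.stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_large_injected_swapping_term_detected_everywhere(self):
        res = genewise_swap_test(_genewise_pair(seed=8, swap_coef=0.05, noise_sd=2.0))
        assert res.n_significant_positive >= 0.95 * res.n_tested
        assert res.n_significant_negative == 0

    def test_zero_reference_gene_reported_untested(self):
        pair = _single_plate_pair(seed=9, n_genes=20)
        pair.counts_ref.iloc[0, :] = 0.0
        res = genewise_swap_test(pair)
        row = res.table[res.table["gene"] == "G0"].iloc[0]
        assert not row["tested"] and np.isnan(row["p_value"])


class TestFreeBarcodeAssociation:
    def test_exact_linear_data_recovers_slope(self):
        x = np.array([0.1, 0.2, 0.3, 0.5, 0.8])
        y = 0.01 + 0.04 * x
        res = free_barcode_association(y, x)
        assert res.slope == pytest.approx(0.04, abs=1e-10)
        assert res.p_value < 1e-10

    def test_two_plates_rejected(self):
        with pytest.raises(DesignError):
            free_barcode_association([0.01, 0.02], [0.1, 0.2])

    def test_constant_ratios_rejected(self):
        with pytest.raises(EstimationError):
            free_barcode_association([0.01, 0.02, 0.03], [0.5, 0.5, 0.5])

    def test_permutation_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(10)
        x = np.linspace(0.1, 1.0, 8)
        y = np.array([0.018, 0.022, 0.025, 0.02, 0.03, 0.019, 0.027, 0.021])
        pvals = []
        for _ in range(300):
            pvals.append(free_barcode_association(rng.permutation(y), x).p_value)
        pvals = np.array(pvals)
        assert 0.0 <= (pvals < 0.05).mean() <= 0.12
        assert 0.35 <= (pvals < 0.5).mean() <= 0.65

    def test_confidence_band_brackets_fit(self):
        x = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        rng = np.random.default_rng(11)
        y = 0.02 + 0.01 * x + rng.normal(0, 0.002, size=5)
        res = free_barcode_association(y, x)
        lo, hi = res.confidence_band(x)
        assert (lo < res.predict(x)).all() and (res.predict(x) < hi).all()
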