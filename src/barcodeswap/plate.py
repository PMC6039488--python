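"""Estimators of the swapped-read fraction in plate-based experiments.

Two independent estimators are provided.

**Impossible-combination regression.**  When two plates with disjoint
barcode sets are multiplexed, combinations mixing barcodes across plates
("impossible" combinations) should contain zero reads; reads observed there
were mislabelled.  A single-barcode swap moves a read from an expected
combination into one of the combinations sharing exactly one barcode with
it, so the reads *available* to swap into an impossible combination are the
summed library sizes of expected combinations sharing exactly one barcode
with it.  Regressing observed impossible-combination library sizes on the
available reads gives a slope m, the per-destination swap rate; since every
read has D = (R_total - 1) + (C_total - 1) single-swap destinations, the
total swapped fraction is m * D.

**Cross-platform linear model.**  When the same libraries are sequenced on
a low-swapping platform (HiSeq 2500 role) and a patterned-flow-cell
platform (HiSeq 4000 role), each cell's profile on the swapping platform is
modelled as a nonnegative linear combination of, from the reference
platform, itself (x_i), the pooled cells sharing exactly one barcode (s_i),
and the pooled cells sharing no barcode (n_i).  The relative contribution
of other cells estimates the plate's swapped fraction.

Two auxiliary regressions accompany them: a gene-wise test for a non-zero
swapping term, and the association of per-plate swap fractions with the
free-barcode/cDNA concentration ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .types import (
    Combination,
    CombinationCounts,
    DesignError,
    EstimationError,
    PlateDesign,
    SwapEstimate,
)

__all__ = [
    "CrossPlatformPair",
    "GenewiseSwapResult",
    "AssociationResult",
    "available_reads",
    "estimate_swap_impossible",
    "estimate_swap_crossplatform",
    "genewise_swap_test",
    "free_barcode_association",
]


def available_reads(counts: CombinationCounts, target: Combination) -> int:
    """Reads available to swap into an impossible combination.

    The sum of library sizes of the *expected* combinations sharing exactly
    one barcode with ``target`` — the donor pool for single-barcode swaps
    into it.
    """
    design = counts.design
    if not design.is_impossible(target):
        raise DesignError(f"{target!r} is not an impossible combination")
    return int(
        sum(
            counts.library_size[combo]
            for combo in design.expected
            if PlateDesign.shares_one(target, combo)
        )
    )


def estimate_swap_impossible(counts: CombinationCounts) -> SwapEstimate:
    """Swapped-read fraction from the impossible-combination regression.

    Ordinary least squares (with intercept) of impossible-combination
    library sizes on their available reads.  The slope is the fraction of
    available reads swapping into each single destination; multiplying by
    the number of single-swap destinations per read,
    D = (R_total - 1) + (C_total - 1), yields the total swapped fraction.
    The intercept absorbs any constant contamination floor and is reported
    as a diagnostic.
    """
    design = counts.design
    impossible = design.impossible
    if len(design.plates) < 2 or not impossible:
        raise DesignError("need >= 2 plates so that impossible combinations exist")
    if len(impossible) < 3:
        raise DesignError("need >= 3 impossible combinations for a meaningful fit")
    y = counts.library_size_vector(impossible).astype(float)
    x = np.array([available_reads(counts, t) for t in impossible], dtype=float)
    if np.ptp(x) == 0:
        raise EstimationError(
            "available reads are constant across impossible combinations; "
            "the slope is unidentifiable"
        )
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    slope = float(fit.params[1])
    slope_se = float(fit.bse[1])
    if not np.isfinite(slope_se):  # zero residual dof etc.
        slope_se = 0.0
    d = design.n_destinations
    return SwapEstimate(
        fraction=slope * d,
        std_error=slope_se * d,
        method="impossible_regression",
        diagnostics={
            "slope": slope,
            "slope_std_error": slope_se,
            "intercept": float(fit.params[0]),
            "n_destinations": d,
            "n_impossible": len(impossible),
            "r_squared": float(fit.rsquared) if np.isfinite(fit.rsquared) else None,
        },
    )


# --------------------------------------------------------------------------- #
# cross-platform model


@dataclass(eq=False)
class CrossPlatformPair:
    """The same plate of libraries sequenced on two platforms.

    ``counts_ref`` holds gene x cell counts from the low-swapping platform,
    ``counts_swapped`` the matching matrix from the patterned-flow-cell
    platform.  Cells are identified by their (row, column) combination on a
    single plate; both matrices must share gene and cell sets exactly.
    """

    counts_ref: pd.DataFrame
    counts_swapped: pd.DataFrame
    design: PlateDesign

    def __post_init__(self) -> None:
        if len(self.design.plates) != 1:
            raise DesignError("cross-platform pair must cover exactly one plate")
        for name, df in (("counts_ref", self.counts_ref), ("counts_swapped", self.counts_swapped)):
            if not isinstance(df.columns, pd.MultiIndex):
                df = df.copy()
                df.columns = pd.MultiIndex.from_tuples([tuple(c) for c in df.columns])
                setattr(self, name, df)
        if not self.counts_ref.index.equals(self.counts_swapped.index):
            raise DesignError("gene sets differ between platforms")
        if list(self.counts_ref.columns) != list(self.counts_swapped.columns):
            raise DesignError("cell sets differ between platforms")
        expected = set(self.design.expected)
        for combo in self.counts_ref.columns:
            if tuple(combo) not in expected:
                raise DesignError(f"cell {tuple(combo)} is not on the plate")
        if (self.counts_ref.to_numpy() < 0).any() or (self.counts_swapped.to_numpy() < 0).any():
            raise DesignError("counts must be nonnegative")

    @property
    def cells(self) -> Tuple[Combination, ...]:
        return tuple(tuple(c) for c in self.counts_ref.columns)


def _crossplatform_predictors(pair: CrossPlatformPair) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-cell predictor matrices (genes x cells): self, share-one, share-none.

    The reference matrix is rescaled so its grand total matches the swapped
    matrix, removing sequencing-depth differences between platforms from
    the self-contribution coefficient.
    """
    ref = pair.counts_ref.to_numpy(dtype=float)
    swp_total = float(pair.counts_swapped.to_numpy(dtype=float).sum())
    ref_total = float(ref.sum())
    if ref_total == 0:
        raise EstimationError("reference matrix is all zero")
    ref = ref * (swp_total / ref_total) if swp_total > 0 else ref
    cells = pair.cells
    n = len(cells)
    share_one = np.zeros((n, n))
    share_none = np.zeros((n, n))
    for j, cj in enumerate(cells):
        for i, ci in enumerate(cells):
            if i == j:
                continue
            if PlateDesign.shares_one(ci, cj):
                share_one[j, i] = 1.0
            else:
                share_none[j, i] = 1.0
    x = ref
    s = ref @ share_one  # column i = sum of ref cells sharing one barcode with i
    nmat = ref @ share_none
    return x, s, nmat


def _fit_fraction(x: np.ndarray, s: np.ndarray, nmat: np.ndarray, y: np.ndarray,
                  cols: Optional[np.ndarray] = None) -> Tuple[float, np.ndarray]:
    """Nonnegative LS fit pooled over (gene, cell); returns (fraction, coefs)."""
    if cols is not None:
        x, s, nmat, y = x[:, cols], s[:, cols], nmat[:, cols], y[:, cols]
    design = np.column_stack([x.ravel(), s.ravel(), nmat.ravel()])
    coefs, _ = scipy.optimize.nnls(design, y.ravel())
    a, b, c = coefs
    totals = design.sum(axis=0)
    contrib = coefs * totals  # a*X, b*S, c*N
    denom = contrib.sum()
    if denom <= 0:
        raise EstimationError("fitted model explains no reads")
    frac = float((contrib[1] + contrib[2]) / denom)
    return frac, coefs


def estimate_swap_crossplatform(
    pair: CrossPlatformPair, n_boot: int = 200, seed: int = 0
) -> SwapEstimate:
    """Swapped-read fraction from the cross-platform linear model.

    Fits, pooled over all (gene, cell) pairs with nonnegative coefficients,

        swapped(g, i) = a * x_i(g) + b * s_i(g) + c * n_i(g)

    where x_i is cell i's reference profile, s_i the summed profiles of
    cells sharing exactly one barcode with i, and n_i of cells sharing no
    barcode.  The swapped fraction is the share of fitted reads contributed
    by other cells, (b S + c N) / (a X + b S + c N), with X, S, N the grand
    totals of the predictors.  The standard error comes from a
    nonparametric bootstrap over cells (``n_boot`` resamples; 0 skips it).
    """
    x, s, nmat, y = *_crossplatform_predictors(pair), pair.counts_swapped.to_numpy(float)
    n_cells = x.shape[1]
    if not (s.sum(axis=0) > 0).any():
        raise EstimationError("no cell has share-one neighbours with reads")
    frac, coefs = _fit_fraction(x, s, nmat, y)
    boot_se = 0.0
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        reps = []
        for _ in range(n_boot):
            cols = rng.integers(0, n_cells, size=n_cells)
            try:
                f_b, _ = _fit_fraction(x, s, nmat, y, cols=cols)
            except EstimationError:
                continue
            reps.append(f_b)
        if len(reps) >= 2:
            boot_se = float(np.std(reps, ddof=1))
    return SwapEstimate(
        fraction=frac,
        std_error=boot_se,
        method="crossplatform_model",
        diagnostics={
            "coef_self": float(coefs[0]),
            "coef_share_one": float(coefs[1]),
            "coef_share_none": float(coefs[2]),
            "n_cells": n_cells,
            "n_genes": x.shape[0],
            "n_boot": n_boot,
        },
    )


@dataclass(eq=False)
class GenewiseSwapResult:
    """Per-gene swapping-term tests from the cross-platform data.

    ``table`` has one row per gene: coefficients of the two-term model
    ``swapped(g, i) = a_g x_i(g) + b_g s_i(g)``, the two-sided p-value for
    b_g = 0, its Benjamini-Hochberg adjusted value and a ``tested`` flag
    (genes with an all-zero reference profile, or with too few cells or a
    degenerate design, are reported untested).
    """

    table: pd.DataFrame
    alpha: float
    n_significant_positive: int
    n_significant_negative: int

    @property
    def n_tested(self) -> int:
        return int(self.table["tested"].sum())


def genewise_swap_test(pair: CrossPlatformPair, alpha: float = 0.05) -> GenewiseSwapResult:
    """Gene-wise linear-model test for a non-zero swapping term.

    For each gene, ordinary least squares of the swapped-platform counts on
    the cell's own reference profile and the share-one neighbour sum (no
    intercept; share-none contributions are second order and omitted).
    Two-sided t-test of the swapping coefficient, Benjamini-Hochberg
    adjustment across tested genes, significance split by coefficient sign
    at adjusted p < ``alpha``.
    """
    x, s, _ = _crossplatform_predictors(pair)
    y = pair.counts_swapped.to_numpy(float)
    genes = list(pair.counts_ref.index)
    n_cells = x.shape[1]
    rows = []
    for g in range(len(genes)):
        xg, sg, yg = x[g], s[g], y[g]
        rec: Dict[str, object] = {"gene": genes[g], "tested": False,
                                  "coef_self": np.nan, "coef_swap": np.nan,
                                  "std_error": np.nan, "p_value": np.nan}
        if n_cells <= 2 or not np.any(xg > 0):
            rows.append(rec)
            continue
        design = np.column_stack([xg, sg])
        gram = design.T @ design
        if np.linalg.matrix_rank(gram) < 2:
            rows.append(rec)
            continue
        coef = np.linalg.solve(gram, design.T @ yg)
        resid = yg - design @ coef
        dof = n_cells - 2
        sigma2 = float(resid @ resid) / dof
        y_scale = float(yg @ yg) / n_cells
        if sigma2 <= 1e-12 * max(y_scale, 1e-300):
            # numerically perfect fit: the swapping term is exactly determined
            se_b = 0.0
            p = 0.0 if abs(coef[1]) > 1e-8 * max(abs(coef[0]), 1.0) else 1.0
        else:
            cov = sigma2 * np.linalg.inv(gram)
            se_b = float(np.sqrt(max(cov[1, 1], 0.0)))
            t = coef[1] / se_b
            p = float(2 * scipy.stats.t.sf(abs(t), dof))
        rec.update(tested=True, coef_self=float(coef[0]), coef_swap=float(coef[1]),
                   std_error=se_b, p_value=p)
        rows.append(rec)
    table = pd.DataFrame(rows)
    tested = table["tested"].to_numpy()
    table["adjusted_p"] = np.nan
    if tested.any():
        adj = multipletests(table.loc[tested, "p_value"], method="fdr_bh")[1]
        table.loc[tested, "adjusted_p"] = adj
    sig = tested & (table["adjusted_p"].to_numpy() < alpha)
    n_pos = int((sig & (table["coef_swap"].to_numpy() > 0)).sum())
    n_neg = int((sig & (table["coef_swap"].to_numpy() < 0)).sum())
    return GenewiseSwapResult(table, alpha, n_pos, n_neg)


# --------------------------------------------------------------------------- #
# free-barcode association


@dataclass
class AssociationResult:
    """OLS association of per-plate swap fractions with free-barcode ratios.

    ``slope`` carries the two-sided t-test p-value for slope = 0; the
    stored design moments allow the 95% confidence band of the fitted line
    to be reconstructed via :meth:`confidence_band`.
    """

    slope: float
    std_error: float
    p_value: float
    intercept: float
    residual_df: int
    x_mean: float
    sxx: float
    sigma2: float
    n: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def confidence_band(self, x: np.ndarray, level: float = 0.95) -> Tuple[np.ndarray, np.ndarray]:
        """Pointwise confidence band for the mean fitted line."""
        x = np.asarray(x, dtype=float)
        tcrit = scipy.stats.t.ppf(0.5 + level / 2, self.residual_df)
        half = tcrit * np.sqrt(self.sigma2 * (1 / self.n + (x - self.x_mean) ** 2 / self.sxx))
        fit = self.predict(x)
        return fit - half, fit + half


def free_barcode_association(
    swap_fractions: Sequence[float], ratios: Sequence[float]
) -> AssociationResult:
    """Test whether per-plate swap fractions track free-barcode abundance.

    Ordinary least squares of the swap fraction on the free-barcode /
    sequencable-cDNA concentration ratio, with intercept, and a two-sided
    t-test of the slope.  Requires at least three plates.
    """
    y = np.asarray(swap_fractions, dtype=float)
    x = np.asarray(ratios, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise DesignError("fractions and ratios must be equal-length 1-D sequences")
    if len(y) < 3:
        raise DesignError("need >= 3 plates to test the association")
    if np.ptp(x) == 0:
        raise EstimationError("ratios are constant; the slope is unidentifiable")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return AssociationResult(
        slope=float(fit.params[1]),
        std_error=float(fit.bse[1]),
        p_value=float(fit.pvalues[1]),
        intercept=float(fit.params[0]),
        residual_df=int(fit.df_resid),
        x_mean=float(x.mean()),
        sxx=float(((x - x.mean()) ** 2).sum()),
        sigma2=float(fit.mse_resid),
        n=len(x),
    )
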