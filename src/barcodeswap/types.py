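"""Core domain types shared across the package.

Barcode swapping (index hopping) mislabels multiplexed sequencing reads on
patterned flow cells: free sample-index primers extend on foreign library
molecules, so a read carries a sample barcode from a library it did not come
from.  The types here describe the two experimental settings in which this
package quantifies and corrects the effect:

* plate-based experiments, where each cell library is identified by a
  (row barcode, column barcode) combination on a microwell plate — described
  by :class:`PlateDesign` and :class:`CombinationCounts`;
* droplet-based (10x-style) experiments, where each molecule is a
  (cell barcode, UMI, gene) record with a read count — described by
  :class:`MoleculeTable`.

Barcodes, UMIs and gene IDs are opaque strings throughout: none of the
statistical methods use sequence content, only identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "BarcodeSwapError",
    "DesignError",
    "FormatError",
    "EstimationError",
    "Combination",
    "PlateDesign",
    "CombinationCounts",
    "MoleculeTable",
    "SwapEstimate",
    "SharingResult",
]


class BarcodeSwapError(Exception):
    """Base class for all errors raised by this package."""


class DesignError(BarcodeSwapError, ValueError):
    """A plate design or an argument referring to one is invalid."""


class FormatError(BarcodeSwapError, ValueError):
    """An input file does not conform to the documented format."""


class EstimationError(BarcodeSwapError, RuntimeError):
    """A model fit is unidentifiable or otherwise cannot proceed."""


#: A (row barcode, column barcode) pair identifying one library position.
Combination = Tuple[str, str]


@dataclass(eq=False)
class PlateDesign:
    """Row/column barcode layout of one or more multiplexed plates.

    Each plate has its own ordered sets of row and column barcodes, and no
    barcode is reused between plates or axes.  Combinations whose two
    barcodes come from the same plate are *expected* (used during library
    preparation); combinations mixing barcodes from different plates are
    *impossible* — any reads observed there must have been mislabelled.

    Parameters
    ----------
    plates
        Ordered plate identifiers.
    row_barcodes, col_barcodes
        Mapping from plate ID to its ordered row / column barcode IDs.
    """

    plates: Tuple[str, ...]
    row_barcodes: Mapping[str, Tuple[str, ...]]
    col_barcodes: Mapping[str, Tuple[str, ...]]

    def __post_init__(self) -> None:
        self.plates = tuple(self.plates)
        self.row_barcodes = {p: tuple(v) for p, v in self.row_barcodes.items()}
        self.col_barcodes = {p: tuple(v) for p, v in self.col_barcodes.items()}
        if not self.plates:
            raise DesignError("design must contain at least one plate")
        if len(set(self.plates)) != len(self.plates):
            raise DesignError("duplicate plate IDs in design")
        for p in self.plates:
            if not self.row_barcodes.get(p) or not self.col_barcodes.get(p):
                raise DesignError(f"plate {p!r} must have row and column barcodes")
        extra = (set(self.row_barcodes) | set(self.col_barcodes)) - set(self.plates)
        if extra:
            raise DesignError(f"barcode sets for unknown plates: {sorted(extra)}")
        seen: Dict[str, str] = {}
        for p in self.plates:
            for axis, bcs in (("row", self.row_barcodes[p]), ("col", self.col_barcodes[p])):
                for b in bcs:
                    if not b:
                        raise DesignError("empty barcode ID")
                    if b in seen:
                        raise DesignError(
                            f"barcode {b!r} reused ({seen[b]} and {p}/{axis}); "
                            "barcodes must be unique across plates and axes"
                        )
                    seen[b] = f"{p}/{axis}"

    @classmethod
    def grid(cls, n_plates: int = 2, n_rows: int = 8, n_cols: int = 12) -> "PlateDesign":
        """A regular design of ``n_plates`` plates of ``n_rows`` x ``n_cols``.

        Barcode IDs are generated as ``P{i}-R{j}`` / ``P{i}-C{j}``.  The
        default mirrors two multiplexed 96-well plates with disjoint barcode
        sets, the layout that makes swapped reads directly observable in the
        impossible combinations.
        """
        plates = tuple(f"P{i + 1}" for i in range(n_plates))
        rows = {p: tuple(f"{p}-R{j + 1}" for j in range(n_rows)) for p in plates}
        cols = {p: tuple(f"{p}-C{j + 1}" for j in range(n_cols)) for p in plates}
        return cls(plates, rows, cols)

    # ------------------------------------------------------------------ #
    # derived structure

    @cached_property
    def all_rows(self) -> Tuple[str, ...]:
        return tuple(b for p in self.plates for b in self.row_barcodes[p])

    @cached_property
    def all_cols(self) -> Tuple[str, ...]:
        return tuple(b for p in self.plates for b in self.col_barcodes[p])

    @cached_property
    def plate_of(self) -> Dict[str, str]:
        """Mapping barcode ID -> plate ID."""
        out: Dict[str, str] = {}
        for p in self.plates:
            for b in self.row_barcodes[p] + self.col_barcodes[p]:
                out[b] = p
        return out

    @cached_property
    def expected(self) -> Tuple[Combination, ...]:
        """All (row, col) combinations whose barcodes share a plate."""
        return tuple(
            (r, c)
            for p in self.plates
            for r in self.row_barcodes[p]
            for c in self.col_barcodes[p]
        )

    @cached_property
    def impossible(self) -> Tuple[Combination, ...]:
        """All (row, col) combinations mixing barcodes of different plates."""
        exp = set(self.expected)
        return tuple(
            (r, c) for r in self.all_rows for c in self.all_cols if (r, c) not in exp
        )

    @cached_property
    def combinations(self) -> Tuple[Combination, ...]:
        """All row x column pairs, expected and impossible, in grid order."""
        return tuple((r, c) for r in self.all_rows for c in self.all_cols)

    @property
    def n_destinations(self) -> int:
        """Number of single-swap destination combinations per read.

        A single-barcode swap replaces either the row barcode (R_total - 1
        alternatives) or the column barcode (C_total - 1 alternatives), so a
        read can land in (R - 1) + (C - 1) combinations other than its own.
        """
        return (len(self.all_rows) - 1) + (len(self.all_cols) - 1)

    def is_expected(self, combo: Combination) -> bool:
        r, c = combo
        return (
            self.plate_of.get(r) is not None
            and self.plate_of.get(r) == self.plate_of.get(c)
        )

    def is_impossible(self, combo: Combination) -> bool:
        r, c = combo
        if r not in self.plate_of or c not in self.plate_of:
            raise DesignError(f"combination {combo!r} uses barcodes not in the design")
        return self.plate_of[r] != self.plate_of[c]

    @staticmethod
    def shares_one(a: Combination, b: Combination) -> bool:
        """True iff the two combinations share exactly one barcode.

        These are the pairs connected by a single-barcode swap: a read in
        ``a`` that swaps one of its two barcodes can land in ``b`` only if
        the other barcode is retained.
        """
        return ((a[0] == b[0]) + (a[1] == b[1])) == 1

    def restrict(self, plate: str) -> "PlateDesign":
        """The sub-design containing a single plate."""
        if plate not in self.plates:
            raise DesignError(f"unknown plate {plate!r}")
        return PlateDesign(
            (plate,),
            {plate: self.row_barcodes[plate]},
            {plate: self.col_barcodes[plate]},
        )


@dataclass(eq=False)
class CombinationCounts:
    """Mapped-read counts per (row, column) barcode combination.

    ``library_size`` maps every combination of the design (expected and
    impossible) to its number of mapped reads; combinations not supplied are
    filled with zero.  ``gene_counts`` optionally carries a gene x
    combination matrix whose column sums must equal the library sizes.
    """

    design: PlateDesign
    library_size: Dict[Combination, int]
    gene_counts: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        valid = set(self.design.combinations)
        cleaned: Dict[Combination, int] = {}
        for combo, n in self.library_size.items():
            combo = (str(combo[0]), str(combo[1]))
            if combo not in valid:
                raise FormatError(
                    f"combination {combo!r} does not exist in the design"
                )
            n = int(n)
            if n < 0:
                raise FormatError(f"negative library size for {combo!r}")
            cleaned[combo] = n
        for combo in valid:
            cleaned.setdefault(combo, 0)
        self.library_size = cleaned
        if self.gene_counts is not None:
            gc = self.gene_counts
            if not isinstance(gc.columns, pd.MultiIndex):
                gc = gc.copy()
                gc.columns = pd.MultiIndex.from_tuples(list(gc.columns))
                self.gene_counts = gc
            bad = [c for c in gc.columns if tuple(c) not in valid]
            if bad:
                raise FormatError(f"gene-count columns not in design: {bad[:3]}")
            if (gc.to_numpy() < 0).any():
                raise FormatError("negative gene counts")
            sums = gc.sum(axis=0)
            for combo, s in sums.items():
                if int(s) != self.library_size[tuple(combo)]:
                    raise FormatError(
                        f"gene counts for {tuple(combo)} sum to {int(s)}, "
                        f"library size is {self.library_size[tuple(combo)]}"
                    )

    def library_size_vector(self, combos: Sequence[Combination]) -> np.ndarray:
        return np.array([self.library_size[c] for c in combos], dtype=np.int64)

    @property
    def total_reads(self) -> int:
        return int(sum(self.library_size.values()))


_MOLECULE_COLUMNS = ("cell_barcode", "umi", "gene", "reads")


@dataclass(eq=False)
class MoleculeTable:
    """Per-sample molecule records of a droplet experiment.

    Each record is one observed molecule — a (cell barcode, UMI, gene) key
    with the number of reads supporting it in this sample.  Keys are unique
    within a table (records for the same molecule are pre-aggregated) and
    every record has at least one read.  The key triple is what the
    molecule-exclusion algorithm matches across multiplexed samples: the
    cell barcode is attached in-droplet and never free in solution, so it
    does not swap, and a key recurring across samples is therefore almost
    certainly one molecule whose reads were mislabelled.
    """

    sample_id: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in _MOLECULE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"molecule table is missing columns {missing}")
        df = df.loc[:, list(_MOLECULE_COLUMNS)].reset_index(drop=True)
        df["reads"] = df["reads"].astype(np.int64)
        if len(df) and (df["reads"] < 1).any():
            raise FormatError("every molecule record needs reads >= 1")
        if len(df):
            for col in ("cell_barcode", "umi", "gene"):
                df[col] = df[col].astype(str)
                if (df[col] == "").any():
                    raise FormatError(f"empty {col} in molecule table")
            if df.duplicated(subset=["cell_barcode", "umi", "gene"]).any():
                raise FormatError(
                    "duplicate (cell_barcode, umi, gene) keys; aggregate reads first"
                )
        self.df = df

    @classmethod
    def from_records(
        cls, sample_id: str, records: Iterable[Tuple[str, str, str, int]]
    ) -> "MoleculeTable":
        """Build a table from (cell_barcode, umi, gene, reads) tuples.

        Records sharing a key are aggregated by summing their reads.
        """
        df = pd.DataFrame(list(records), columns=list(_MOLECULE_COLUMNS))
        if len(df):
            df["reads"] = df["reads"].astype(np.int64)
            if (df["reads"] < 1).any():
                raise FormatError("every molecule record needs reads >= 1")
            df = (
                df.groupby(["cell_barcode", "umi", "gene"], as_index=False, sort=True)[
                    "reads"
                ].sum()
            )
        return cls(sample_id, df)

    @property
    def n_molecules(self) -> int:
        return len(self.df)

    @property
    def total_reads(self) -> int:
        return int(self.df["reads"].sum()) if len(self.df) else 0

    def umi_counts(self) -> pd.Series:
        """Distinct-molecule (UMI) count per cell barcode."""
        if not len(self.df):
            return pd.Series(dtype=np.int64)
        return self.df.groupby("cell_barcode").size().astype(np.int64)


@dataclass
class SwapEstimate:
    """A swapped-read fraction estimate with its uncertainty.

    ``fraction`` is on the proportion scale (0.0218, not 2.18) and
    ``method`` names the estimator that produced it.  ``diagnostics``
    records the fitted coefficients and the conventions used (e.g. the
    per-destination slope and the destination-count multiplier for the
    impossible-combination regression) so alternative conventions remain
    auditable.
    """

    fraction: float
    std_error: float
    method: str
    diagnostics: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.fraction) or not np.isfinite(self.std_error):
            raise EstimationError("swap estimate must be finite")
        if self.std_error < 0:
            raise EstimationError("standard error must be nonnegative")


@dataclass(eq=False)
class SharingResult:
    """Pairwise cell-barcode overlap between samples, with hypergeometric
    upper-tail p-values and Benjamini-Hochberg adjusted p-values.

    ``table`` has one row per unordered sample pair with columns
    ``sample_a, sample_b, n_a, n_b, overlap, pool_size, p_value,
    adjusted_p``.
    """

    table: pd.DataFrame
    pool_size: int

    def __post_init__(self) -> None:
        t = self.table
        if len(t):
            if ((t["overlap"] > t[["n_a", "n_b"]].min(axis=1)) | (t["overlap"] < 0)).any():
                raise FormatError("overlap must satisfy 0 <= k <= min(n_a, n_b)")
            if ((t["p_value"] <= 0) | (t["p_value"] > 1)).any():
                raise FormatError("p-values must lie in (0, 1]")
            if (t["adjusted_p"] + 1e-12 < t["p_value"]).any():
                raise FormatError("adjusted p-values cannot undercut raw p-values")

    def significant_pairs(self, alpha: float = 0.05) -> pd.DataFrame:
        """Pairs with excess sharing at adjusted p < alpha."""
        return self.table[self.table["adjusted_p"] < alpha].reset_index(drop=True)
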