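"""Detection and removal of barcode swapping in multiplexed droplet data.

In droplet (10x-style) experiments the cell barcode is attached in-droplet
and never free in solution, so only the *sample* index swaps.  Swapping
between multiplexed samples has two visible consequences: samples share
more cell barcodes than chance predicts (detected by a hypergeometric
test), and molecules reappear across samples with identical
(cell barcode, UMI, gene) keys (removed by the molecule-exclusion
algorithm).  Discarding every cell library with a shared barcode instead
would be ruinous at scale — the expected cost of that strategy is computed
here both in closed form and by Monte-Carlo simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .types import BarcodeSwapError, FormatError, MoleculeTable, SharingResult

__all__ = [
    "ExclusionModel",
    "ExclusionSimResult",
    "CleaningReport",
    "sharing_test",
    "expected_exclusion_fraction",
    "simulate_cell_exclusion",
    "classify_molecules",
    "remove_swapped_molecules",
    "call_cells_threshold",
]


def sharing_test(barcode_sets: Dict[str, Set[str]], pool_size: int) -> SharingResult:
    """Test each sample pair for excess cell-barcode sharing.

    For samples A and B observing ``n_a`` and ``n_b`` barcodes out of a
    pool of ``pool_size`` possible sequences, the overlap k under
    independent random barcode assignment is hypergeometric; the reported
    p-value is the upper tail P(X >= k).  P-values are Benjamini-Hochberg
    adjusted across pairs.
    """
    for sample, bcs in barcode_sets.items():
        if len(bcs) > pool_size:
            raise FormatError(
                f"sample {sample!r} observes {len(bcs)} barcodes, "
                f"more than the pool size {pool_size}"
            )
    rows = []
    for a, b in combinations(barcode_sets, 2):
        set_a, set_b = barcode_sets[a], barcode_sets[b]
        k = len(set_a & set_b)
        # population pool_size, draws |A|, successes |B|: P(X >= k);
        # the exact tail is positive but can underflow, so floor at tiny
        p = float(scipy.stats.hypergeom.sf(k - 1, pool_size, len(set_b), len(set_a)))
        p = max(p, np.finfo(float).tiny)
        rows.append(
            {
                "sample_a": a,
                "sample_b": b,
                "n_a": len(set_a),
                "n_b": len(set_b),
                "overlap": k,
                "pool_size": pool_size,
                "p_value": min(p, 1.0),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["adjusted_p"] = multipletests(table["p_value"], method="fdr_bh")[1]
    else:
        table["adjusted_p"] = pd.Series(dtype=float)
    return SharingResult(table, pool_size)


@dataclass(frozen=True)
class ExclusionModel:
    """Parameters of the cell-exclusion cost calculation.

    ``n_samples`` multiplexed samples each capture ``cells_per_sample``
    cells, with cell barcodes drawn without replacement (within a sample)
    from a pool of ``pool_size`` possible sequences; samples draw
    independently.  The default pool size, 737,280, is the standard 10x
    cell-barcode whitelist size.
    """

    n_samples: int
    cells_per_sample: int
    pool_size: int = 737_280

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.cells_per_sample < 1 or self.pool_size < 1:
            raise FormatError("model parameters must be positive")
        if self.cells_per_sample > self.pool_size:
            raise FormatError("cannot draw more cells than the barcode pool holds")


def expected_exclusion_fraction(model: ExclusionModel) -> float:
    """Expected fraction of cell libraries lost to whole-cell exclusion.

    A barcode drawn in one sample is excluded if any of the other S - 1
    samples also draws it; each other sample does so with probability
    c / N, independently, giving 1 - (1 - c/N)^(S-1).
    """
    s, c, n = model.n_samples, model.cells_per_sample, model.pool_size
    return float(1.0 - (1.0 - c / n) ** (s - 1))


@dataclass
class ExclusionSimResult:
    """Monte-Carlo estimate of the cell-exclusion cost."""

    mean_fraction: float
    std_error: float  # Monte-Carlo standard error of the mean
    n_reps: int
    per_rep: np.ndarray


def simulate_cell_exclusion(
    model: ExclusionModel, n_reps: int = 10, seed: int = 0
) -> ExclusionSimResult:
    """Simulate random barcode draws and count shared-barcode exclusions.

    Each repetition draws ``cells_per_sample`` barcodes without replacement
    per sample; a cell library is excluded if its barcode occurs in two or
    more samples.  Returns the mean excluded fraction with its Monte-Carlo
    standard error.
    """
    if n_reps < 1:
        raise FormatError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    s, c, n = model.n_samples, model.cells_per_sample, model.pool_size
    fractions = np.empty(n_reps)
    for rep in range(n_reps):
        occupancy = np.zeros(n, dtype=np.int32)
        draws = np.empty((s, c), dtype=np.int64)
        for sample in range(s):
            draws[sample] = rng.choice(n, size=c, replace=False)
            occupancy[draws[sample]] += 1
        excluded = int((occupancy[draws.ravel()] >= 2).sum())
        fractions[rep] = excluded / (s * c)
    se = float(fractions.std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else 0.0
    return ExclusionSimResult(float(fractions.mean()), se, n_reps, fractions)


# --------------------------------------------------------------------------- #
# molecule-level cleaning


@dataclass
class CleaningReport:
    """Accounting of the molecule-exclusion pass.

    ``per_sample`` has one row per sample with columns ``sample_id,
    molecules_in, retained, removed_swapped, removed_unresolved``;
    ``removed_swapped`` counts molecules whose reads had a >= ``min_frac``
    majority in another sample, ``removed_unresolved`` those whose reads
    were spread too evenly to assign an origin (removed everywhere,
    including the would-be origin).
    """

    per_sample: pd.DataFrame
    n_multi_sample_groups: int
    min_frac: float

    def __post_init__(self) -> None:
        t = self.per_sample
        balance = t["retained"] + t["removed_swapped"] + t["removed_unresolved"]
        if not (balance == t["molecules_in"]).all():
            raise BarcodeSwapError("cleaning report does not balance")
        if (t[["molecules_in", "retained", "removed_swapped", "removed_unresolved"]] < 0).any().any():
            raise BarcodeSwapError("negative counts in cleaning report")

    def to_dict(self) -> Dict[str, object]:
        return {
            "schema_version": "1.0",
            "min_frac": self.min_frac,
            "n_multi_sample_groups": self.n_multi_sample_groups,
            "per_sample": self.per_sample.to_dict(orient="records"),
        }


RETAINED = "retained"
REMOVED_SWAPPED = "removed_swapped"
REMOVED_UNRESOLVED = "removed_unresolved"


def classify_molecules(
    tables: Sequence[MoleculeTable], min_frac: float = 0.8
) -> pd.DataFrame:
    """Label every molecule record as retained or removed.

    Records are grouped across samples by (cell_barcode, umi, gene).
    Single-sample groups are retained.  For a group spanning samples, let
    f_s be sample s's share of the group's reads: if max f_s >= ``min_frac``
    the molecule is kept only in that majority sample (removed as swapped
    elsewhere); otherwise no origin can be assigned and it is removed from
    all samples.  Returns the concatenated records with ``sample_id`` and
    ``action`` columns.

    ``min_frac`` must exceed 0.5, which also makes the majority sample
    unique: two samples tying at fraction >= min_frac > 0.5 would need more
    than all the group's reads, so no tie-breaking rule is required.
    """
    if not 0.5 < min_frac <= 1.0:
        raise FormatError("min_frac must lie in (0.5, 1]")
    if len(tables) < 2:
        raise FormatError("need at least two samples to clean")
    ids = [t.sample_id for t in tables]
    if len(set(ids)) != len(ids):
        raise FormatError(f"duplicate sample IDs: {ids}")
    frames = []
    for t in tables:
        df = t.df.copy()
        df["sample_id"] = t.sample_id
        frames.append(df)
    combined = pd.concat(frames, ignore_index=True)
    if not len(combined):
        combined["action"] = pd.Series(dtype=object)
        return combined
    key = ["cell_barcode", "umi", "gene"]
    grp = combined.groupby(key, sort=False)
    n_samples = grp["sample_id"].transform("size")  # keys unique within a sample
    total = grp["reads"].transform("sum")
    top = grp["reads"].transform("max")
    reads = combined["reads"]
    action = np.where(
        n_samples == 1,
        RETAINED,
        np.where(
            top / total >= min_frac,
            np.where(reads == top, RETAINED, REMOVED_SWAPPED),
            REMOVED_UNRESOLVED,
        ),
    )
    combined["action"] = action
    return combined


def remove_swapped_molecules(
    tables: Sequence[MoleculeTable], min_frac: float = 0.8
) -> Tuple[List[MoleculeTable], CleaningReport]:
    """Remove molecules that swapped between multiplexed samples.

    See :func:`classify_molecules` for the decision rule.  Returns cleaned
    tables in the input order (read counts of retained records unchanged)
    and a :class:`CleaningReport`.
    """
    combined = classify_molecules(tables, min_frac=min_frac)
    key = ["cell_barcode", "umi", "gene"]
    if len(combined):
        group_sizes = combined.groupby(key, sort=False)["sample_id"].transform("size")
        n_multi = int(
            combined.loc[group_sizes > 1, key].drop_duplicates().shape[0]
        )
    else:
        n_multi = 0
    cleaned: List[MoleculeTable] = []
    rows = []
    for t in tables:
        sub = combined[combined["sample_id"] == t.sample_id]
        keep = sub[sub["action"] == RETAINED]
        cleaned.append(
            MoleculeTable(t.sample_id, keep[["cell_barcode", "umi", "gene", "reads"]])
        )
        rows.append(
            {
                "sample_id": t.sample_id,
                "molecules_in": len(sub),
                "retained": int((sub["action"] == RETAINED).sum()),
                "removed_swapped": int((sub["action"] == REMOVED_SWAPPED).sum()),
                "removed_unresolved": int((sub["action"] == REMOVED_UNRESOLVED).sum()),
            }
        )
    report = CleaningReport(pd.DataFrame(rows), n_multi, min_frac)
    return cleaned, report


def call_cells_threshold(table: MoleculeTable, min_umis: int) -> Set[str]:
    """Call cell barcodes with at least ``min_umis`` distinct molecules.

    A simple UMI-count threshold: barcodes whose number of
    (cell_barcode, umi, gene) records reaches ``min_umis`` are considered
    cells.  This is the thresholding component of cell calling only — it
    makes no attempt to model the ambient-RNA profile of empty droplets.
    """
    if min_umis < 1:
        raise FormatError("min_umis must be a positive integer")
    counts = table.umi_counts()
    return set(counts.index[counts >= min_umis])
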