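"""Generative models of plate and droplet experiments with known swapping.

Both simulators implement the minimal mechanism consistent with
free-index-primer swapping: each read independently swaps with probability
f, single-barcode swaps only (double swaps are second order in f), and the
destination is uniform within the relevant choice set.  Destination
uniformity is an assumption of the simulator, not an observation — the
swapping mechanism gives no evidence on destination preferences.

Gene-expression structure is exchangeable negative-binomial with lognormal
gene abundances.  The estimators and the cleaning algorithm under test use
only totals, linear pooling and key identity, so realistic gene-gene
covariance is deliberately absent: this is a mechanism simulator, not a
biological model, and agreement on its output demonstrates correctness of
the swapping arithmetic, not robustness to real transcriptome structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .droplet import RETAINED, REMOVED_SWAPPED
from .plate import CrossPlatformPair
from .types import (
    Combination,
    CombinationCounts,
    FormatError,
    MoleculeTable,
    PlateDesign,
)

__all__ = [
    "PlateSimConfig",
    "PlateSimResult",
    "CrossPlatformSimConfig",
    "DropletSimConfig",
    "DropletSimResult",
    "simulate_plate",
    "simulate_crossplatform",
    "simulate_droplet",
    "cleaning_performance",
    "expected_chance_collisions",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _int_to_kmer(values: np.ndarray, k: int) -> np.ndarray:
    """Encode integers as base-4 DNA k-mers (vectorised)."""
    values = np.asarray(values, dtype=np.uint64)
    digits = np.empty((len(values), k), dtype=np.uint8)
    v = values.copy()
    for pos in range(k - 1, -1, -1):
        digits[:, pos] = (v & np.uint64(3)).astype(np.uint8)
        v >>= np.uint64(2)
    return _BASES[digits].reshape(-1).view(f"S{k}").astype(str)


def _nb_draw(rng: np.random.Generator, mean, shape: float, size) -> np.ndarray:
    """Negative binomial with mean ``mean`` and shape (size) parameter
    ``shape`` (variance = mean + mean^2 / shape)."""
    mean = np.asarray(mean, dtype=float)
    p = shape / (shape + mean)
    return rng.negative_binomial(shape, p, size=size)


def _gene_weights(rng: np.random.Generator, n_genes: int, sigma: float = 1.5) -> np.ndarray:
    w = rng.lognormal(mean=0.0, sigma=sigma, size=n_genes)
    return w / w.sum()


# --------------------------------------------------------------------------- #
# plate simulator


def _default_two_plate_design() -> PlateDesign:
    return PlateDesign.grid(n_plates=2, n_rows=8, n_cols=12)


@dataclass
class PlateSimConfig:
    """Conditions of a simulated two-plate experiment.

    Defaults model two multiplexed 96-well (8 x 12) plates with disjoint
    barcode sets and about one million mapped reads in total (mean 5208
    reads per expected combination, negative-binomial with shape 5, i.e. a
    realistic ~45% coefficient of variation in library sizes), with 2% of
    reads swapping — the patterned-flow-cell regime.
    """

    design: PlateDesign = field(default_factory=_default_two_plate_design)
    n_genes: int = 100
    mean_reads: float = 5208.0
    dispersion: float = 5.0
    swap_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.swap_fraction < 1:
            raise FormatError("swap_fraction must lie in [0, 1)")
        if self.n_genes < 1 or self.mean_reads <= 0 or self.dispersion <= 0:
            raise FormatError("all counts and rates must be positive")


@dataclass
class PlateSimResult:
    """Observed counts plus per-read ground truth of a plate simulation."""

    counts: CombinationCounts
    true_library_size: Dict[Combination, int]
    n_swapped_reads: int
    n_reads_total: int

    @property
    def realised_swap_fraction(self) -> float:
        if self.n_reads_total == 0:
            return 0.0
        return self.n_swapped_reads / self.n_reads_total


def simulate_plate(config: PlateSimConfig) -> PlateSimResult:
    """Simulate reads on a multi-plate design with single-barcode swapping.

    True reads are drawn per expected combination (negative-binomial
    library sizes, multinomial gene assignment).  Each read swaps with
    probability ``swap_fraction``; a swapping read replaces its row or
    column barcode (chosen with equal probability) with a uniformly chosen
    other barcode of the same axis, on any plate.  Swapped reads may land
    in expected combinations (of the same plate) or impossible ones; reads
    are conserved.
    """
    rng = np.random.default_rng(config.seed)
    design = config.design
    combos = design.combinations
    combo_idx = {c: i for i, c in enumerate(combos)}
    row_idx = {r: i for i, r in enumerate(design.all_rows)}
    col_idx = {c: i for i, c in enumerate(design.all_cols)}
    n_rows, n_cols = len(design.all_rows), len(design.all_cols)
    gene_probs = _gene_weights(rng, config.n_genes)
    observed = np.zeros((config.n_genes, len(combos)), dtype=np.int64)
    true_lib: Dict[Combination, int] = {}
    n_swapped = 0
    n_total = 0
    for combo in design.expected:
        t = int(_nb_draw(rng, config.mean_reads, config.dispersion, None))
        true_lib[combo] = t
        n_total += t
        if t == 0:
            continue
        genes = rng.multinomial(t, gene_probs)
        n_swap = rng.binomial(t, config.swap_fraction)
        n_swapped += n_swap
        if n_swap:
            swap_genes = rng.multivariate_hypergeometric(genes, n_swap)
            genes = genes - swap_genes
            gene_of_read = np.repeat(np.arange(config.n_genes), swap_genes)
            r0, c0 = row_idx[combo[0]], col_idx[combo[1]]
            swap_row = rng.random(n_swap) < 0.5
            dest = np.empty(n_swap, dtype=np.int64)
            # row swap: new row uniform among the other rows, column kept
            nr = int(swap_row.sum())
            if nr:
                new_rows = rng.integers(0, n_rows - 1, size=nr)
                new_rows[new_rows >= r0] += 1
                dest[swap_row] = new_rows * n_cols + c0
            nc = n_swap - nr
            if nc:
                new_cols = rng.integers(0, n_cols - 1, size=nc)
                new_cols[new_cols >= c0] += 1
                dest[~swap_row] = r0 * n_cols + new_cols
            np.add.at(observed, (gene_of_read, dest), 1)
        observed[:, combo_idx[combo]] += genes
    gene_names = [f"G{i:04d}" for i in range(config.n_genes)]
    gc = pd.DataFrame(observed, index=gene_names, columns=pd.MultiIndex.from_tuples(combos))
    lib = {c: int(n) for c, n in zip(combos, observed.sum(axis=0))}
    counts = CombinationCounts(design, lib, gene_counts=gc)
    return PlateSimResult(counts, true_lib, int(n_swapped), int(n_total))


# --------------------------------------------------------------------------- #
# cross-platform simulator


@dataclass
class CrossPlatformSimConfig:
    """Conditions for one plate sequenced on two platforms.

    The reference platform is taken as swap-free; on the swapping platform
    each read moves, with probability ``swap_fraction``, to a cell sharing
    exactly one barcode (single-barcode swaps stay within the plate's
    row/column grid; double swaps are neglected), chosen uniformly.  The
    default 8 x 12 plate with 500 genes at mean 5 counts per gene per cell
    gives ~2500 counts per cell.
    """

    n_rows: int = 8
    n_cols: int = 12
    n_genes: int = 500
    mean_counts: float = 5.0
    dispersion: float = 0.5
    swap_fraction: float = 0.0228
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.swap_fraction < 1:
            raise FormatError("swap_fraction must lie in [0, 1)")


def simulate_crossplatform(config: CrossPlatformSimConfig) -> CrossPlatformPair:
    """Simulate a reference/swapped platform pair for one plate."""
    rng = np.random.default_rng(config.seed)
    design = PlateDesign.grid(1, config.n_rows, config.n_cols)
    cells = design.expected
    n_cells = len(cells)
    weights = _gene_weights(rng, config.n_genes)
    # per-(gene, cell) means proportional to gene abundance, averaging mean_counts
    gene_means = config.mean_counts * weights * config.n_genes
    truth = _nb_draw(
        rng, gene_means[:, None] * np.ones(n_cells)[None, :], config.dispersion, None
    ).astype(np.int64)
    # neighbour structure: cells sharing exactly one barcode
    neighbours: List[np.ndarray] = []
    for i, ci in enumerate(cells):
        neighbours.append(
            np.array(
                [j for j, cj in enumerate(cells) if j != i and PlateDesign.shares_one(ci, cj)],
                dtype=np.int64,
            )
        )
    swapped = np.zeros_like(truth)
    for i in range(n_cells):
        out = rng.binomial(truth[:, i], config.swap_fraction)
        swapped[:, i] += truth[:, i] - out
        nb = neighbours[i]
        if len(nb) == 0:
            swapped[:, i] += out
            continue
        dest = rng.multinomial(out, np.full(len(nb), 1.0 / len(nb)))
        swapped[:, nb] += dest
    gene_names = [f"G{i:04d}" for i in range(config.n_genes)]
    cols = pd.MultiIndex.from_tuples(cells)
    return CrossPlatformPair(
        counts_ref=pd.DataFrame(truth, index=gene_names, columns=cols),
        counts_swapped=pd.DataFrame(swapped, index=gene_names, columns=cols),
        design=design,
    )


# --------------------------------------------------------------------------- #
# droplet simulator


@dataclass
class DropletSimConfig:
    """Conditions of a simulated multiplexed droplet experiment.

    Defaults model four 10x-style samples of 2000 cells each drawing cell
    barcodes from the standard 737,280-sequence whitelist, ~200 molecules
    per cell (negative binomial, shape 2), a mean of 6 reads per molecule
    (1 + Poisson, the typical saturation regime where most molecules are
    sequenced several times) and a 2% read-swapping fraction — the
    patterned-flow-cell regime.  ``donor_frac`` plants a fraction of sample
    1's cells as "donor-only" large cells (barcode unique to that sample,
    molecule count scaled by ``donor_size_factor``) whose swapped reads
    build artefactual cell libraries in the other samples.
    """

    n_samples: int = 4
    cells_per_sample: int = 2000
    pool_size: int = 737_280
    n_genes: int = 1000
    molecules_per_cell: float = 200.0
    molecule_dispersion: float = 2.0
    reads_per_molecule: float = 6.0
    swap_fraction: float = 0.02
    donor_frac: float = 0.0
    donor_size_factor: float = 10.0
    umi_length: int = 10
    barcode_length: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise FormatError("need at least one sample")
        if self.cells_per_sample > self.pool_size:
            raise FormatError("cells_per_sample cannot exceed the barcode pool")
        if not 0 <= self.swap_fraction < 1:
            raise FormatError("swap_fraction must lie in [0, 1)")
        if self.reads_per_molecule < 1:
            raise FormatError("reads_per_molecule must be >= 1")
        if 4 ** self.barcode_length < self.pool_size:
            raise FormatError("barcode_length too short for the pool size")


@dataclass
class DropletSimResult:
    """Per-sample molecule tables plus per-record ground truth.

    ``truth`` parallels the tables: one row per output record with its
    ``origin_sample`` and a ``swapped_in`` flag (True when the record sits
    in a sample other than the one that generated the molecule).
    ``donor_barcodes`` lists the planted donor-only large-cell barcodes.
    """

    tables: List[MoleculeTable]
    truth: pd.DataFrame
    donor_barcodes: FrozenSet[str]
    gene_probs: np.ndarray
    config: DropletSimConfig


def simulate_droplet(config: DropletSimConfig) -> DropletSimResult:
    """Simulate multiplexed droplet samples with read-level index swapping.

    Cell barcodes are drawn without replacement (within a sample) from the
    shared pool; molecules get genes from a fixed lognormal abundance
    profile, uniform random UMIs (collisions allowed and aggregated) and
    1 + Poisson read counts.  Each read keeps its (cell barcode, UMI, gene)
    identity but swaps its sample label with probability ``swap_fraction``,
    uniformly to one of the other samples.  Reads are re-aggregated into
    per-sample molecule records with truth labels.
    """
    rng = np.random.default_rng(config.seed)
    s_n, c, pool = config.n_samples, config.cells_per_sample, config.pool_size
    sample_ids = [f"S{i + 1}" for i in range(s_n)]
    barcodes = [rng.choice(pool, size=c, replace=False) for _ in range(s_n)]
    sizes = _nb_draw(rng, config.molecules_per_cell, config.molecule_dispersion, (s_n, c))
    donor_codes: np.ndarray = np.empty(0, dtype=np.int64)
    if config.donor_frac > 0 and s_n > 1:
        n_donor = int(round(config.donor_frac * c))
        others = np.unique(np.concatenate(barcodes[1:]))
        unique_mask = ~np.isin(barcodes[0], others)
        candidates = np.flatnonzero(unique_mask)
        if len(candidates) < n_donor:
            raise FormatError("not enough donor-only barcodes available")
        chosen = rng.choice(candidates, size=n_donor, replace=False)
        sizes[0, chosen] = np.round(sizes[0, chosen] * config.donor_size_factor).astype(
            sizes.dtype
        )
        donor_codes = barcodes[0][chosen]
    # molecule-level arrays
    origin = np.repeat(
        np.repeat(np.arange(s_n), c), sizes.reshape(-1)
    )
    cell_bc = np.repeat(np.concatenate(barcodes), sizes.reshape(-1))
    n_mol = len(origin)
    gene_probs = _gene_weights(rng, config.n_genes)
    gene = rng.choice(config.n_genes, size=n_mol, p=gene_probs)
    umi = rng.integers(0, 4 ** config.umi_length, size=n_mol)
    reads = 1 + rng.poisson(config.reads_per_molecule - 1.0, size=n_mol)
    if s_n > 1 and config.swap_fraction > 0:
        n_swap = rng.binomial(reads, config.swap_fraction)
    else:
        n_swap = np.zeros(n_mol, dtype=np.int64)
    retained = reads - n_swap
    parts = []  # (sample, cell_bc, umi, gene, reads, origin, swapped_in)

    def _part(mask, sample, nreads, swapped_in):
        parts.append(
            (
                np.full(int(mask.sum()), sample) if np.isscalar(sample) else sample[mask],
                cell_bc[mask],
                umi[mask],
                gene[mask],
                nreads[mask],
                origin[mask],
                np.full(int(mask.sum()), swapped_in),
            )
        )

    _part(retained > 0, origin, retained, False)
    if n_swap.sum() > 0:
        dest_counts = np.zeros((n_mol, s_n), dtype=np.int64)
        for s in range(s_n):
            mask = (origin == s) & (n_swap > 0)
            if not mask.any():
                continue
            pvals = np.full(s_n, 1.0 / (s_n - 1))
            pvals[s] = 0.0
            dest_counts[mask] = rng.multinomial(n_swap[mask], pvals)
        for t in range(s_n):
            mask = dest_counts[:, t] > 0
            if mask.any():
                _part(mask, t, dest_counts[:, t], True)
    cols = ["sample", "cell_bc", "umi", "gene", "reads", "origin", "swapped_in"]
    df = pd.DataFrame(
        {name: np.concatenate([p[i] for p in parts]) for i, name in enumerate(cols)}
    )
    # aggregate records sharing a (sample, barcode, umi, gene) key; the
    # largest contributor labels the merged record's origin
    df = df.sort_values("reads", ascending=False, kind="stable")
    agg = (
        df.groupby(["sample", "cell_bc", "umi", "gene"], sort=False)
        .agg(
            reads=("reads", "sum"),
            origin=("origin", "first"),
            swapped_in=("swapped_in", "first"),
        )
        .reset_index()
    )
    gene_names = np.array([f"G{i:04d}" for i in range(config.n_genes)])
    out = pd.DataFrame(
        {
            "sample_id": np.array(sample_ids)[agg["sample"].to_numpy()],
            "cell_barcode": _int_to_kmer(agg["cell_bc"].to_numpy(), config.barcode_length),
            "umi": _int_to_kmer(agg["umi"].to_numpy(), config.umi_length),
            "gene": gene_names[agg["gene"].to_numpy()],
            "reads": agg["reads"].to_numpy(np.int64),
            "origin_sample": np.array(sample_ids)[agg["origin"].to_numpy()],
            "swapped_in": agg["swapped_in"].to_numpy(bool),
        }
    )
    tables = []
    for sid in sample_ids:
        sub = out.loc[out["sample_id"] == sid, ["cell_barcode", "umi", "gene", "reads"]]
        tables.append(MoleculeTable(sid, sub.reset_index(drop=True)))
    donors = frozenset(_int_to_kmer(donor_codes, config.barcode_length).tolist())
    return DropletSimResult(tables, out, donors, gene_probs, config)


# --------------------------------------------------------------------------- #
# evaluation against truth labels


def cleaning_performance(classified: pd.DataFrame, truth: pd.DataFrame) -> Dict[str, float]:
    """Precision and recall of swapped-molecule removal against truth.

    *Recall* is the fraction of truth-labelled swapped-in records removed
    from their recipient sample (under either removal class).  *Precision*
    is, among records removed with an identified majority origin elsewhere
    (the ``removed_swapped`` class), the fraction that are truly
    swapped-in.  Unresolved-group removals of the origin's own record are a
    deliberate conservative discard and are reported separately by the
    cleaning report rather than counted as classification errors.
    """
    key = ["sample_id", "cell_barcode", "umi", "gene"]
    merged = classified.merge(
        truth[key + ["swapped_in"]], on=key, how="left", validate="one_to_one"
    )
    if merged["swapped_in"].isna().any():
        raise FormatError("classified records missing from the truth table")
    swapped = merged["swapped_in"].to_numpy(bool)
    removed = (merged["action"] != RETAINED).to_numpy()
    removed_as_swapped = (merged["action"] == REMOVED_SWAPPED).to_numpy()
    n_swapped = int(swapped.sum())
    recall = float(removed[swapped].mean()) if n_swapped else 1.0
    n_rs = int(removed_as_swapped.sum())
    precision = float(swapped[removed_as_swapped].mean()) if n_rs else 1.0
    return {
        "precision": precision,
        "recall": recall,
        "n_swapped_in": n_swapped,
        "n_removed_swapped": n_rs,
        "n_removed_total": int(removed.sum()),
    }


def expected_chance_collisions(results: Sequence[DropletSimResult]) -> float:
    """Expected number of cross-sample key collisions absent any swapping.

    For two samples with c_a, c_b cells from a pool of N barcodes and mean
    molecule counts m_a, m_b, the expected number of (cell barcode, UMI,
    gene) keys appearing in both is approximately
    (c_a c_b / N) * m_a m_b * (sum_g p_g q_g) / 4^L — shared barcodes times
    per-molecule-pair probability of matching gene and UMI.  Summed over
    all unordered sample pairs across the given experiments.
    """
    entries = []
    for res in results:
        cfg = res.config
        for _ in range(cfg.n_samples):
            entries.append(
                (
                    cfg.cells_per_sample,
                    cfg.molecules_per_cell,
                    res.gene_probs,
                    cfg.pool_size,
                    cfg.umi_length,
                )
            )
    total = 0.0
    for i in range(len(entries)):
        for j in range(i + 1, len(entries)):
            c_a, m_a, p_a, pool_a, len_a = entries[i]
            c_b, m_b, p_b, pool_b, len_b = entries[j]
            if pool_a != pool_b or len_a != len_b:
                raise FormatError("experiments use incompatible barcode/UMI spaces")
            n = min(len(p_a), len(p_b))
            gene_match = float(np.sum(p_a[:n] * p_b[:n]))
            total += (c_a * c_b / pool_a) * m_a * m_b * gene_match / 4 ** len_a
    return total
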