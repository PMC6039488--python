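"""Readers and writers for the plain-text and HDF5 formats the types travel in.

Formats
-------
Plate design (``.txt``, tab-delimited, ``#`` comments)::

    P1	rows	R1,R2
    P1	cols	C1,C2
    P2	rows	R3,R4
    P2	cols	C3,C4

Combination counts (``.tsv``): header ``row_barcode  col_barcode  reads``,
one combination per line; combinations absent from the file get library
size zero.  Gene-level counts use MatrixMarket: ``<stem>.mtx`` (genes x
combinations) with sidecars ``<stem>.genes.txt`` (one gene per line) and
``<stem>.combos.txt`` (``row<TAB>col`` per line).

Molecule tables: tab-delimited with header
``cell_barcode  umi  gene  reads``, or an HDF5 layout (``.h5``/``.hdf5``)
with four parallel root datasets of those names (strings stored as
variable-length UTF-8), plus root attributes ``layout_version`` (``"1.0"``)
and optionally ``sample_id``.

Cleaned counts: one MatrixMarket gene x cell-barcode UMI-count matrix per
sample (``<sample>.mtx`` with ``<sample>.genes.txt`` and
``<sample>.barcodes.txt``).
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import h5py
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .types import (
    Combination,
    CombinationCounts,
    FormatError,
    MoleculeTable,
    PlateDesign,
)

__all__ = [
    "read_plate_design",
    "write_plate_design",
    "read_plate_counts",
    "write_plate_counts",
    "read_molecule_table",
    "write_molecule_table",
    "write_cleaned_counts",
]

HDF5_LAYOUT_VERSION = "1.0"


def _open_lines(path: Union[str, Path]) -> List[str]:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such file: {p}")
    with open(p) as fh:
        return [ln.rstrip("\n") for ln in fh]


def read_plate_design(path: Union[str, Path]) -> PlateDesign:
    """Parse the explicit plate/axis/barcode-list design format."""
    plates: List[str] = []
    rows: Dict[str, Tuple[str, ...]] = {}
    cols: Dict[str, Tuple[str, ...]] = {}
    for i, ln in enumerate(_open_lines(path), start=1):
        if not ln.strip() or ln.lstrip().startswith("#"):
            continue
        parts = ln.split("\t")
        if len(parts) != 3:
            raise FormatError(f"{path}:{i}: expected 'plate<TAB>axis<TAB>barcodes'")
        plate, axis, barcodes = (p.strip() for p in parts)
        if axis not in ("rows", "cols"):
            raise FormatError(f"{path}:{i}: axis must be 'rows' or 'cols', got {axis!r}")
        target = rows if axis == "rows" else cols
        if plate in target:
            raise FormatError(f"{path}:{i}: duplicate {axis} line for plate {plate!r}")
        target[plate] = tuple(b.strip() for b in barcodes.split(",") if b.strip())
        if plate not in plates:
            plates.append(plate)
    return PlateDesign(tuple(plates), rows, cols)


def write_plate_design(design: PlateDesign, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for p in design.plates:
            fh.write(f"{p}\trows\t{','.join(design.row_barcodes[p])}\n")
            fh.write(f"{p}\tcols\t{','.join(design.col_barcodes[p])}\n")


def _read_counts_tsv(design: PlateDesign, counts_path: Path) -> CombinationCounts:
    df = pd.read_csv(counts_path, sep="\t", dtype=str)
    for col in ("row_barcode", "col_barcode", "reads"):
        if col not in df.columns:
            raise FormatError(f"{counts_path}: missing column {col!r}")
    valid_rows = set(design.all_rows)
    valid_cols = set(design.all_cols)
    lib: Dict[Combination, int] = {}
    for _, rec in df.iterrows():
        r, c = rec["row_barcode"], rec["col_barcode"]
        if r not in valid_rows:
            raise FormatError(f"{counts_path}: unknown row barcode {r!r}")
        if c not in valid_cols:
            raise FormatError(f"{counts_path}: unknown column barcode {c!r}")
        if (r, c) in lib:
            raise FormatError(f"{counts_path}: duplicated combination ({r}, {c})")
        try:
            n = int(rec["reads"])
        except ValueError as exc:
            raise FormatError(f"{counts_path}: non-integer reads for ({r}, {c})") from exc
        lib[(r, c)] = n
    return CombinationCounts(design, lib)


def _read_counts_mtx(design: PlateDesign, counts_path: Path) -> CombinationCounts:
    stem = counts_path.with_suffix("")
    genes_path = Path(f"{stem}.genes.txt")
    combos_path = Path(f"{stem}.combos.txt")
    for p in (genes_path, combos_path):
        if not p.exists():
            raise FormatError(f"missing sidecar {p} for {counts_path}")
    genes = [ln for ln in _open_lines(genes_path) if ln.strip()]
    combos: List[Combination] = []
    for i, ln in enumerate(_open_lines(combos_path), start=1):
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{combos_path}:{i}: expected 'row<TAB>col'")
        combos.append((parts[0], parts[1]))
    if len(set(combos)) != len(combos):
        raise FormatError(f"{combos_path}: duplicated combination")
    valid = set(design.combinations)
    for combo in combos:
        if combo not in valid:
            raise FormatError(
                f"{combos_path}: combination {combo!r} not in the design"
            )
    mat = scipy.io.mmread(os.fspath(counts_path))
    mat = np.asarray(scipy.sparse.coo_matrix(mat).todense(), dtype=np.int64)
    if mat.shape != (len(genes), len(combos)):
        raise FormatError(
            f"{counts_path}: matrix is {mat.shape}, sidecars give "
            f"({len(genes)}, {len(combos)})"
        )
    gc = pd.DataFrame(mat, index=genes, columns=pd.MultiIndex.from_tuples(combos))
    lib = {combo: int(s) for combo, s in zip(combos, mat.sum(axis=0))}
    return CombinationCounts(design, lib, gene_counts=gc)


def read_plate_counts(
    design_path: Union[str, Path, PlateDesign], counts_path: Union[str, Path]
) -> CombinationCounts:
    """Read plate combination counts against a design.

    ``counts_path`` may be a ``.tsv`` of per-combination library sizes or a
    MatrixMarket ``.mtx`` of gene-level counts with index sidecars (library
    sizes are then the column sums).  Combinations absent from the file get
    library size zero.
    """
    design = (
        design_path
        if isinstance(design_path, PlateDesign)
        else read_plate_design(design_path)
    )
    counts_path = Path(counts_path)
    if not counts_path.exists():
        raise FileNotFoundError(f"no such file: {counts_path}")
    if counts_path.suffix == ".mtx":
        return _read_counts_mtx(design, counts_path)
    return _read_counts_tsv(design, counts_path)


def write_plate_counts(counts: CombinationCounts, path: Union[str, Path]) -> None:
    """Write per-combination library sizes as TSV (and gene counts as MTX).

    If ``counts.gene_counts`` is present and ``path`` ends in ``.mtx``, the
    gene-level matrix and its sidecars are written instead of the TSV.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        if counts.gene_counts is None:
            raise FormatError("no gene-level counts to write as MatrixMarket")
        gc = counts.gene_counts
        stem = path.with_suffix("")
        scipy.io.mmwrite(
            os.fspath(path),
            scipy.sparse.csc_matrix(gc.to_numpy(dtype=np.int64)),
            field="integer",
        )
        with open(f"{stem}.genes.txt", "w") as fh:
            fh.writelines(f"{g}\n" for g in gc.index)
        with open(f"{stem}.combos.txt", "w") as fh:
            fh.writelines(f"{r}\t{c}\n" for r, c in gc.columns)
        return
    with open(path, "w") as fh:
        fh.write("row_barcode\tcol_barcode\treads\n")
        for combo in counts.design.combinations:
            fh.write(f"{combo[0]}\t{combo[1]}\t{counts.library_size[combo]}\n")


# --------------------------------------------------------------------------- #
# molecule tables


def _read_molecules_tsv(path: Path, sample_id: str) -> MoleculeTable:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"reads": np.int64})
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["cell_barcode", "umi", "gene", "reads"])
    for col in ("cell_barcode", "umi", "gene", "reads"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if len(df) and (df["reads"] < 1).any():
        raise FormatError(f"{path}: reads must be >= 1")
    return MoleculeTable.from_records(
        sample_id,
        list(df[["cell_barcode", "umi", "gene", "reads"]].itertuples(index=False, name=None)),
    )


def _read_molecules_hdf5(path: Path, sample_id: Optional[str]) -> MoleculeTable:
    with h5py.File(path, "r") as fh:
        for name in ("cell_barcode", "umi", "gene", "reads"):
            if name not in fh:
                raise FormatError(f"{path}: missing dataset {name!r}")
        cb = [b.decode() if isinstance(b, bytes) else str(b) for b in fh["cell_barcode"][:]]
        umi = [b.decode() if isinstance(b, bytes) else str(b) for b in fh["umi"][:]]
        gene = [b.decode() if isinstance(b, bytes) else str(b) for b in fh["gene"][:]]
        reads = np.asarray(fh["reads"][:], dtype=np.int64)
        if sample_id is None:
            sample_id = fh.attrs.get("sample_id", path.stem)
    if len(reads) and (reads < 1).any():
        raise FormatError(f"{path}: reads must be >= 1")
    return MoleculeTable.from_records(
        str(sample_id), list(zip(cb, umi, gene, reads.tolist()))
    )


def read_molecule_table(
    path: Union[str, Path], sample_id: Optional[str] = None
) -> MoleculeTable:
    """Read a molecule table from TSV or the HDF5 parallel-array layout.

    Records sharing a (cell_barcode, umi, gene) key are aggregated by
    summing reads.  ``sample_id`` defaults to the file stem (or the HDF5
    ``sample_id`` attribute when present).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    if path.suffix.lower() in (".h5", ".hdf5"):
        return _read_molecules_hdf5(path, sample_id)
    return _read_molecules_tsv(path, sample_id or path.stem)


def write_molecule_table(table: MoleculeTable, path: Union[str, Path]) -> None:
    """Write a molecule table as TSV, or HDF5 if the suffix is .h5/.hdf5."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        str_dtype = h5py.string_dtype(encoding="utf-8")
        with h5py.File(path, "w") as fh:
            fh.attrs["layout_version"] = HDF5_LAYOUT_VERSION
            fh.attrs["sample_id"] = table.sample_id
            for col in ("cell_barcode", "umi", "gene"):
                fh.create_dataset(col, data=table.df[col].to_list(), dtype=str_dtype)
            fh.create_dataset("reads", data=table.df["reads"].to_numpy(np.int64))
        return
    table.df.to_csv(path, sep="\t", index=False)


def write_cleaned_counts(
    tables: Sequence[MoleculeTable], out_dir: Union[str, Path]
) -> Dict[str, Path]:
    """Write per-sample gene x cell-barcode UMI-count matrices.

    Entry (g, b) counts the distinct molecules — (cell_barcode, umi, gene)
    records — observed for gene g in barcode b, i.e. UMI counts rather than
    read counts.  Returns the mapping sample ID -> matrix path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: Dict[str, Path] = {}
    for table in tables:
        df = table.df
        genes = sorted(df["gene"].unique()) if len(df) else []
        barcodes = sorted(df["cell_barcode"].unique()) if len(df) else []
        gi = {g: i for i, g in enumerate(genes)}
        bi = {b: i for i, b in enumerate(barcodes)}
        if len(df):
            umis = df.groupby(["gene", "cell_barcode"]).size()
            rows = [gi[g] for g, _ in umis.index]
            cols = [bi[b] for _, b in umis.index]
            mat = scipy.sparse.coo_matrix(
                (umis.to_numpy(np.int64), (rows, cols)),
                shape=(len(genes), len(barcodes)),
            )
        else:
            mat = scipy.sparse.coo_matrix((0, 0), dtype=np.int64)
        mtx_path = out_dir / f"{table.sample_id}.mtx"
        scipy.io.mmwrite(os.fspath(mtx_path), mat.tocsc(), field="integer")
        with open(out_dir / f"{table.sample_id}.genes.txt", "w") as fh:
            fh.writelines(f"{g}\n" for g in genes)
        with open(out_dir / f"{table.sample_id}.barcodes.txt", "w") as fh:
            fh.writelines(f"{b}\n" for b in barcodes)
        written[table.sample_id] = mtx_path
    return written
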