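import pytest

from barcodeswap import CombinationCounts, MoleculeTable, PlateDesign


@pytest.fixture
def toy_design() -> PlateDesign:
    """Two 2x2 plates with disjoint barcode sets (16 combinations)."""
    return PlateDesign(
        plates=("P1", "P2"),
        row_barcodes={"P1": ("R1", "R2"), "P2": ("R3", "R4")},
        col_barcodes={"P1": ("C1", "C2"), "P2": ("C3", "C4")},
    )


@pytest.fixture
def toy_counts(toy_design) -> CombinationCounts:
    """All expected combinations at library size 10, impossibles at 0."""
    return CombinationCounts(
        toy_design, {combo: 10 for combo in toy_design.expected}
    )


@pytest.fixture
def tiny_tables():
    """Three tiny multiplexed samples exercising each cleaning rule."""
    a = MoleculeTable.from_records(
        "A",
        [
            ("AAAC", "U1", "G1", 8),   # majority here, minority in B
            ("AAAC", "U2", "G1", 5),   # even split with B
            ("AAAG", "U3", "G2", 4),   # only in A
        ],
    )
    b = MoleculeTable.from_records(
        "B",
        [
            ("AAAC", "U1", "G1", 2),
            ("AAAC", "U2", "G1", 5),
            ("CCCT", "U4", "G1", 1),   # only in B
        ],
    )
    c = MoleculeTable.from_records("C", [("GGGA", "U5", "G3", 3)])
    return [a, b, c]
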