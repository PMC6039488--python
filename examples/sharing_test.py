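"""Detect barcode swapping via excess cell-barcode sharing.

Simulates two multiplexed samples with and without read swapping and tests
each pair's barcode overlap against the hypergeometric null of independent
draws from the whitelist pool.  Swapped-in molecules carry donor barcodes
into recipient samples, inflating the overlap far beyond chance.
"""

from barcodeswap import DropletSimConfig, sharing_test, simulate_droplet

for f in (0.0, 0.02):
    res = simulate_droplet(
        DropletSimConfig(
            n_samples=2, cells_per_sample=500, pool_size=50_000,
            molecules_per_cell=50.0, swap_fraction=f, seed=4,
        )
    )
    sets = {t.sample_id: set(t.df["cell_barcode"]) for t in res.tables}
    table = sharing_test(sets, pool_size=50_000).table
    row = table.iloc[0]
    print(f"swap fraction {f:.2f}: overlap {row['overlap']:4d} "
          f"of {row['n_a']}/{row['n_b']} barcodes, p = {row['p_value']:.3g}")
# Without swapping the overlap is the handful expected by chance (p ~ 1);
# with 2% swapping nearly every barcode recurs and p underflows.
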