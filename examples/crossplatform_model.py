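"""Estimate swapping by comparing the same plate on two sequencers.

Simulates one 96-well plate sequenced on a swap-free reference platform
and on a patterned-flow-cell platform where 2.28% of reads move to cells
sharing exactly one barcode.  Each cell's swapped-platform profile is fit
as a nonnegative combination of its own reference profile, the pooled
share-one neighbours and the pooled non-sharing cells; the share of fitted
reads contributed by other cells is the plate's swapped fraction.
"""

from barcodeswap import (
    CrossPlatformSimConfig,
    estimate_swap_crossplatform,
    simulate_crossplatform,
)

pair = simulate_crossplatform(CrossPlatformSimConfig(swap_fraction=0.0228, seed=1))
est = estimate_swap_crossplatform(pair, n_boot=100, seed=2)

print(f"injected swap fraction : 0.0228")
print(f"estimated fraction     : {est.fraction:.4f} +/- {est.std_error:.4f} (bootstrap)")
print(f"coefficients           : self {est.diagnostics['coef_self']:.4f}, "
      f"share-one {est.diagnostics['coef_share_one']:.5f}, "
      f"share-none {est.diagnostics['coef_share_none']:.5f}")
# A share-none coefficient near zero reflects that double-barcode swaps
# are second order; nearly all mislabelled reads come from cells sharing
# exactly one barcode.
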