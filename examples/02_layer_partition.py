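"""Layer detection in depth: coverage curves, reslices, and edge cases.

Shows how the top/middle/bottom partition follows the fibronectin
stain-positive coverage curve, how an XZ orthogonal reslice visualizes the
same structure, and what happens when a heavily degraded matrix never
reaches full coverage (the flagged bottom fallback).

Run:  python examples/02_layer_partition.py
"""

import numpy as np

from ecmremodel import (
    coverage_profile,
    orthogonal_reslice,
    partition_from_coverage,
    preset,
    rescale_to_225,
    simulate_matrix_stack,
)

stack, _ = simulate_matrix_stack(preset("null", seed=3))
scaled = rescale_to_225(stack, "fixed-range", lo=0.0, hi=225.0)

# Per-plane fraction of pixels at or above the stain-positive cutoff (90).
cov = coverage_profile(scaled, "fibronectin")
print("plane  coverage   (plane 0 = topmost)")
for z, c in enumerate(cov):
    bar = "#" * int(round(40 * c))
    print(f"{z:>5}  {c:8.3f}  {bar}")

part = partition_from_coverage(cov)
print(
    f"\ntop = first plane >= 20% coverage plus one below     -> {part.top_planes}"
    f"\nbottom = first plane covering the entire field + one above -> "
    f"{part.bottom_planes}"
    f"\nmiddle = halfway plane(s) of the span {part.span}          -> "
    f"{part.middle_planes}"
)

# The XZ reslice (max over a 10-um band of rows) shows the same taper:
# sparse matrix at the top of the stack, saturated at the bottom.
res = orthogonal_reslice(scaled, "fibronectin", line=128, thickness_um=10.0)
frac_positive = (res >= 90.0).mean(axis=1)
print("\nXZ reslice row 128: stain-positive fraction per depth")
print(np.array2string(frac_positive, precision=2))

# Edge case: a matrix that never reaches full coverage triggers the
# flagged fallback (deepest maximum-coverage plane + one above).
degraded = np.array([0.0, 0.3, 0.6, 0.9, 0.9, 0.85])
fb = partition_from_coverage(degraded)
print(
    f"\ndegraded curve {degraded.tolist()} -> bottom {fb.bottom_planes} "
    f"(fallback flagged: {fb.bottom_fallback})"
)
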