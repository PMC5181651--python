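"""Aitchison geometry and pivot ilr coordinates on a toy composition.

A 3-part composition (say sand/silt/clay fractions of a soil sample) lives
on the simplex: only ratios matter.  This script shows the basic operations
and that the pivot ilr map preserves all metric structure.
"""

import numpy as np

import codaprop as cp

x = np.array([60.0, 30.0, 10.0])       # raw lab values, any scale
y = np.array([20.0, 50.0, 30.0])

print("closure(x, 1)      :", np.round(cp.closure(x), 4))
print("x (+) y            :", np.round(cp.perturb(x, y), 4))
print("0.5 (.) x          :", np.round(cp.power(0.5, x), 4))

z_x, z_y = cp.ilr_pivot(x), cp.ilr_pivot(y)
print("ilr(x)             :", np.round(z_x, 4))
print("ilr(100000 * x)    :", np.round(cp.ilr_pivot(1e5 * x), 4),
      "(scale invariant)")
print("clr(x)             :", np.round(cp.clr_coefficients(x), 4),
      "(sums to 0)")

d_simplex = cp.aitchison_distance(x, y)
d_coords = np.linalg.norm(z_x - z_y)
print(f"Aitchison distance : {d_simplex:.6f}")
print(f"ilr Euclidean dist : {d_coords:.6f}   (identical: isometry)")
print("round trip         :", np.round(cp.ilr_inverse(z_x), 4),
      "= closure(x)")

# The first pivot coordinate carries all relative information about the
# first part; putting another part first moves its information into z_1.
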