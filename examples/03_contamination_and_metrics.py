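"""Detection-limit and imprecision contamination, and what they distort.

Contaminate half the parts of a survey-like synthetic composition matrix
and quantify the damage with the four distortion measures: Spearman/MASD on
the first pivot coordinate (pivoting on an uncontaminated part) and on
robust Mahalanobis distances of all coordinates jointly.
"""

import codaprop as cp

X = cp.gemas_like_fixture(seed=7, scale="small")        # 300 x 10
dirty = tuple(X.columns[5:])                            # last 5 parts

Xdl, counts = cp.apply_detection_limit(
    X, cp.DLSpec(parts=dirty, quantile=0.25))
print("values replaced per part:", counts.to_dict())
print("resolved DL_j:", {k: round(v, 4)
                         for k, v in counts.attrs["dl_values"].items()})

Xir = cp.apply_imprecision(X, cp.IRSpec(parts=dirty, alpha=0.25), seed=7)

for name, Xstar in (("detection limit", Xdl), ("imprecision", Xir)):
    r = cp.distortion_report(X, Xstar, seed=0)
    print(f"\n{name} (25%):")
    print(f"  first coordinate : Spearman {r.spearman_first:.3f}, "
          f"MASD {r.masd_first:.3f}")
    print(f"  all coordinates  : Spearman {r.spearman_md:.3f}, "
          f"MASD {r.masd_md:.3f}  (robust Mahalanobis distances)")

# Spearman near 1 / MASD near 0 mean the ordering / the values survive;
# the first coordinate, pivoting on a clean part, is far more resistant
# than the joint multivariate structure.
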