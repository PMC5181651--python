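"""Aitchison geometry on the simplex and the pivot ilr / clr coordinate maps.

Compositions are vectors of strictly positive parts that carry only relative
information: two proportional vectors are the same composition.  The natural
geometry of this sample space (the simplex) is the Aitchison geometry, with
perturbation ``x (+) y = C(x1*y1, ..., xD*yD)`` playing the role of vector
addition, powering ``a (.) x = C(x1**a, ..., xD**a)`` the role of scalar
multiplication, and a log-ratio inner product inducing norm and distance.

The pivot isometric log-ratio (ilr) coordinates

    z_j = sqrt((D-j)/(D-j+1)) * ln( x_j / gm(x_{j+1}, ..., x_D) ),
    j = 1, ..., D-1,

with ``gm`` the geometric mean, map the simplex isometrically onto
``R^(D-1)``: Aitchison distances and inner products of compositions equal the
Euclidean ones of their coordinate images.  The first coordinate ``z_1``
carries all relative information about the first part (it is proportional to
that part's centered log-ratio coefficient), which is why a part of interest
is rotated to the front before analysis.

Vectors and matrices of compositions are plain numpy arrays or pandas
objects; all operations are vectorized over the last axis and preserve
labels where the input carries them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "closure", "perturb", "power", "aitchison_inner", "aitchison_norm",
    "aitchison_distance", "geometric_mean", "ilr_pivot", "ilr_inverse",
    "clr_coefficients", "pivot_to_front", "pivot_basis",
    "validate_composition_matrix", "default_labels",
]


def default_labels(D: int) -> list[str]:
    """Synthetic part names ``part_1 .. part_D`` for unlabeled input."""
    return [f"part_{j + 1}" for j in range(D)]


def _asarray(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.shape[-1] < 2:
        raise ValueError("a composition needs at least D = 2 parts")
    return arr


def _check_positive(arr: np.ndarray, what: str = "composition") -> None:
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{what} contains non-finite values")
    if np.any(arr <= 0):
        raise ValueError(f"{what} must be strictly positive; zero handling "
                         "is an explicit choice (see the contamination module)")


def _like(template, values: np.ndarray, columns=None):
    """Re-wrap ndarray results in the container type of *template*."""
    if isinstance(template, pd.DataFrame):
        cols = template.columns if columns is None else columns
        return pd.DataFrame(values, index=template.index, columns=cols)
    if isinstance(template, pd.Series):
        idx = template.index if columns is None else columns
        return pd.Series(values, index=idx)
    return values


def validate_composition_matrix(X) -> pd.DataFrame:
    """Coerce *X* to a validated n x D DataFrame of strictly positive parts.

    Unlabeled input (ndarray, list of rows) receives synthetic labels
    ``part_1 .. part_D``.  Any cell <= 0, NaN or infinity raises ``ValueError``
    with the offending cell's coordinates.
    """
    if isinstance(X, pd.DataFrame):
        df = X.astype(float).copy()
    else:
        arr = np.atleast_2d(np.asarray(X, dtype=float))
        df = pd.DataFrame(arr, columns=default_labels(arr.shape[1]))
    if df.shape[1] < 2:
        raise ValueError("a composition matrix needs at least D = 2 parts")
    vals = df.to_numpy()
    bad = ~(np.isfinite(vals) & (vals > 0))
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValueError(
            f"non-positive or missing cell at row {df.index[i]!r}, "
            f"column {df.columns[j]!r} (value {vals[i, j]!r}); compositional "
            "parts must be strictly positive")
    return df


def closure(x, kappa: float = 1.0):
    """Rescale a positive vector (or matrix of rows) to sum to *kappa*.

    Closure is a representation choice, not a transformation of information:
    all log-ratio quantities are invariant under it.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    arr = _asarray(x)
    _check_positive(arr)
    out = kappa * arr / arr.sum(axis=-1, keepdims=True)
    return _like(x, out)


def perturb(x, y):
    """Perturbation ``x (+) y``: closure of the componentwise product."""
    ax, ay = _asarray(x), _asarray(y)
    if ax.shape[-1] != ay.shape[-1]:
        raise ValueError(f"part count mismatch: {ax.shape[-1]} vs {ay.shape[-1]}")
    _check_positive(ax)
    _check_positive(ay)
    prod = ax * ay
    return _like(x, prod / prod.sum(axis=-1, keepdims=True))


def power(alpha: float, x):
    """Powering ``alpha (.) x``: closure of componentwise alpha-th powers."""
    arr = _asarray(x)
    _check_positive(arr)
    # computed in log space: x**a overflows for large |a| long before exp does
    logp = alpha * np.log(arr)
    logp -= logp.max(axis=-1, keepdims=True)
    p = np.exp(logp)
    return _like(x, p / p.sum(axis=-1, keepdims=True))


def aitchison_inner(x, y) -> float:
    """Aitchison inner product ``(1/2D) sum_jk ln(xj/xk) ln(yj/yk)``."""
    ax, ay = _asarray(x), _asarray(y)
    if ax.shape[-1] != ay.shape[-1]:
        raise ValueError(f"part count mismatch: {ax.shape[-1]} vs {ay.shape[-1]}")
    _check_positive(ax)
    _check_positive(ay)
    D = ax.shape[-1]
    lx, ly = np.log(ax), np.log(ay)
    # (1/2D) sum_jk (lx_j - lx_k)(ly_j - ly_k) = D<clrx,clry>/D = clr dot product
    cx = lx - lx.mean(axis=-1, keepdims=True)
    cy = ly - ly.mean(axis=-1, keepdims=True)
    return float(np.sum(cx * cy, axis=-1)) if ax.ndim == 1 else np.sum(cx * cy, axis=-1)


def aitchison_norm(x) -> float:
    """Aitchison norm: sqrt of the inner product of *x* with itself."""
    v = aitchison_inner(x, x)
    return float(np.sqrt(v)) if np.isscalar(v) or np.ndim(v) == 0 else np.sqrt(v)


def aitchison_distance(x, y) -> float:
    """Aitchison distance ``||x (+) (-1)(.)y||_A``.

    Equals the Euclidean distance between the ilr images of *x* and *y*.
    """
    ax, ay = _asarray(x), _asarray(y)
    if ax.shape[-1] != ay.shape[-1]:
        raise ValueError(f"part count mismatch: {ax.shape[-1]} vs {ay.shape[-1]}")
    _check_positive(ax)
    _check_positive(ay)
    lr = np.log(ax) - np.log(ay)
    c = lr - lr.mean(axis=-1, keepdims=True)
    v = np.sum(c * c, axis=-1)
    return float(np.sqrt(v)) if ax.ndim == 1 else np.sqrt(v)


def geometric_mean(x):
    """Geometric mean exp(mean(ln x)) of a strictly positive vector."""
    arr = np.asarray(x, dtype=float)
    _check_positive(arr, "geometric mean argument")
    return np.exp(np.mean(np.log(arr), axis=-1))


def pivot_basis(D: int) -> np.ndarray:
    """Contrast matrix Psi ((D-1) x D) of the pivot ilr basis.

    Row i is the logcontrast of the i-th pivot coordinate:
    ``z = Psi @ ln(x)``.  Rows are orthonormal and sum to zero.
    """
    if D < 2:
        raise ValueError("D must be >= 2")
    Psi = np.zeros((D - 1, D))
    for i in range(1, D):           # 1-based coordinate index
        r = np.sqrt((D - i) / (D - i + 1.0))
        Psi[i - 1, i - 1] = r
        Psi[i - 1, i:] = -r / (D - i)
    return Psi


def ilr_pivot(x):
    """Pivot ilr coordinates of a composition (or of each row of a matrix).

    ``z_j = sqrt((D-j)/(D-j+1)) * ln(x_j / gm(x_{j+1..D}))``.  The map is
    scale invariant and isometric; ``z_1`` carries all relative information
    about the first part.
    """
    arr = _asarray(x)
    _check_positive(arr)
    D = arr.shape[-1]
    z = np.log(arr) @ pivot_basis(D).T
    if isinstance(x, pd.DataFrame):
        return pd.DataFrame(z, index=x.index,
                            columns=[f"z_{j + 1}" for j in range(D - 1)])
    return z


def ilr_inverse(z, labels=None):
    """Composition (closed to kappa=1) whose pivot ilr coordinates are *z*."""
    arr = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("ilr coordinates must be finite")
    D = arr.shape[-1] + 1
    logx = arr @ pivot_basis(D)
    logx -= logx.max(axis=-1, keepdims=True)
    x = np.exp(logx)
    x /= x.sum(axis=-1, keepdims=True)
    if labels is None and isinstance(z, pd.DataFrame):
        labels = default_labels(D)
    if labels is not None and arr.ndim == 2:
        idx = z.index if isinstance(z, pd.DataFrame) else None
        return pd.DataFrame(x, index=idx, columns=labels)
    return x


def clr_coefficients(x):
    """Centered log-ratio coefficients ``ln(x_j / gm(x))``; they sum to zero.

    The first pivot ilr coordinate satisfies ``z_1 = sqrt(D/(D-1)) * clr_1``.
    """
    arr = _asarray(x)
    _check_positive(arr)
    lx = np.log(arr)
    return _like(x, lx - lx.mean(axis=-1, keepdims=True))


def pivot_to_front(X: pd.DataFrame, part: str) -> pd.DataFrame:
    """Reorder columns so *part* comes first (other order preserved).

    After this, the first pivot coordinate of ``ilr_pivot`` carries all
    relative information about *part*.
    """
    X = validate_composition_matrix(X)
    if part not in X.columns:
        raise KeyError(f"unknown part label {part!r}; have {list(X.columns)}")
    cols = [part] + [c for c in X.columns if c != part]
    return X[cols]
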