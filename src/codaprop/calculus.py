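"""First-order Taylor error propagation in Euclidean space and on the simplex.

In Euclidean space, a smooth function f of noisy inputs x = mu + eps has
output variance approximated by the quadratic form g' Sigma g of the gradient
at the center with the error covariance (first-order delta method).

On the simplex the analogue replaces vector addition by perturbation: a
scale-invariant f is C-differentiable with derivative matrix

    A[i, j] = x_j * ( df_i/dx_j - sum_k x_k df_i/dx_k ),  rows summing to 0,

and f(x (+) u) ~ f(x) + A ln(u).  For the pivot ilr coordinates the
C-derivative is a fixed logcontrast, so the expansion is exact: ilr
coordinates are additive with respect to multiplicative errors,
ilr(mu (+) eps) = ilr(mu) + ilr(eps).  The variance of coordinate z_j of a
composition x = mu (+) eps then decomposes into pairwise log-ratio variances
of the error:

    Var(z_j) = A - B,
    A = 1/(D-j+1)          * sum_{k>j} Var(ln eps_j/eps_k),
    B = 1/(2(D-j)(D-j+1))  * sum_{k>j} sum_{l>j} Var(ln eps_k/eps_l).

Terms involving the j-th error enter only A, so error confined to one part
mostly moves the coordinate pivoting on that part.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import closure, _asarray, _check_positive, pivot_basis

__all__ = [
    "ScaleInvariantFunction", "ErrorModel", "euclidean_taylor_variance",
    "c_derivative", "taylor_first_order", "ilr_c_partials",
    "ilr_error_variance", "log_ratio_variances",
]

# central differences on exponent perturbations: h ~ cbrt(eps) balances
# truncation against roundoff for second-order accurate stencils
_FD_STEP = float(np.cbrt(np.finfo(float).eps))


class ScaleInvariantFunction:
    """A function f: R^D_+ -> R^m with f(w) = f(k w) for all k > 0.

    Scale invariance is probed at construction on random positive rescalings
    of probe points; a violation raises (a non-scale-invariant f would make
    the C-derivative formula meaningless).

    Parameters
    ----------
    evaluator : callable
        Maps a positive length-D vector to a length-m vector (or scalar).
    m : int
        Output dimension.
    partials : callable, optional
        Analytic Jacobian: maps a positive length-D vector to an m x D
        matrix of ordinary partial derivatives df_i/dx_j.
    """

    def __init__(self, evaluator, m: int = 1, partials=None, *,
                 probe_D: int | None = None, rtol: float = 1e-8):
        self.evaluator = evaluator
        self.m = int(m)
        self.partials = partials
        self._rtol = rtol
        if probe_D is not None:
            self.check_scale_invariance(probe_D)

    def __call__(self, w) -> np.ndarray:
        out = np.atleast_1d(np.asarray(self.evaluator(np.asarray(w, float)),
                                       dtype=float))
        if out.shape != (self.m,):
            raise ValueError(f"evaluator returned shape {out.shape}, "
                             f"expected ({self.m},)")
        return out

    def jacobian(self, w) -> np.ndarray:
        if self.partials is None:
            raise ValueError("no analytic partials supplied")
        J = np.atleast_2d(np.asarray(self.partials(np.asarray(w, float)),
                                     dtype=float))
        if J.shape != (self.m, len(w)):
            raise ValueError(f"partials returned shape {J.shape}, "
                             f"expected ({self.m}, {len(w)})")
        return J

    def check_scale_invariance(self, D: int, n_probes: int = 5,
                               seed: int = 0) -> None:
        """Probe f(kw) = f(w) on random points/scales; raise on failure."""
        rng = np.random.default_rng(seed)
        for _ in range(n_probes):
            w = rng.lognormal(size=D)
            k = float(rng.lognormal(sigma=2.0))
            f0, fk = self(w), self(k * w)
            if not np.allclose(f0, fk, rtol=self._rtol,
                               atol=self._rtol * (1 + np.abs(f0).max())):
                raise ValueError(
                    "function is not scale invariant: f(w) != f(kw) "
                    f"(k={k:.4g}, |diff|={np.abs(f0 - fk).max():.3g})")


def euclidean_taylor_variance(partials_at_mu, error_cov) -> float:
    """First-order output variance g' Sigma g in Euclidean space.

    *partials_at_mu* is the gradient of f at the error-free center and
    *error_cov* the (symmetric PSD) covariance of the additive errors.
    A slightly indefinite covariance (numerical noise) triggers a warning
    and the result is clamped at zero.
    """
    g = np.asarray(partials_at_mu, dtype=float).ravel()
    S = np.atleast_2d(np.asarray(error_cov, dtype=float))
    if S.shape != (g.size, g.size):
        raise ValueError(f"gradient length {g.size} does not match "
                         f"covariance shape {S.shape}")
    if not np.allclose(S, S.T, atol=1e-10 * (1 + np.abs(S).max())):
        raise ValueError("error covariance must be symmetric")
    v = float(g @ S @ g)
    if v < 0:
        warnings.warn("negative variance from an indefinite covariance; "
                      "clamping to 0", RuntimeWarning, stacklevel=2)
        v = 0.0
    return v


def c_derivative(f: ScaleInvariantFunction, x, mode: str = "numeric") -> np.ndarray:
    """C-derivative matrix A (m x D) of a scale-invariant f at composition x.

    ``analytic`` evaluates A[i,j] = x_j (df_i/dx_j - sum_k x_k df_i/dx_k)
    at the closed representative of x; ``numeric`` uses central finite
    differences of f under multiplicative single-part perturbations
    x * exp(+-h e_j), which estimate column j of A directly because the
    rows of A annihilate the closure constant.
    """
    arr = _asarray(x)
    _check_positive(arr)
    if arr.ndim != 1:
        raise ValueError("c_derivative expects a single composition")
    D = arr.size
    f.check_scale_invariance(D)
    xc = np.asarray(closure(arr, 1.0), dtype=float)

    if mode == "analytic":
        J = f.jacobian(xc)
        inner = J @ xc                       # sum_k x_k df_i/dx_k, per row
        A = xc * (J - inner[:, None])
    elif mode == "numeric":
        h = _FD_STEP
        A = np.empty((f.m, D))
        for j in range(D):
            wp = xc.copy(); wp[j] *= np.exp(h)
            wm = xc.copy(); wm[j] *= np.exp(-h)
            A[:, j] = (f(wp) - f(wm)) / (2.0 * h)
    else:
        raise ValueError(f"mode must be 'analytic' or 'numeric', got {mode!r}")

    if not np.all(np.isfinite(A)):
        raise FloatingPointError("non-finite C-derivative")
    return A


def taylor_first_order(f: ScaleInvariantFunction, x, u,
                       mode: str = "numeric") -> np.ndarray:
    """First-order simplicial Taylor approximation of f(x (+) u).

    Returns f(x) + A ln(u) with A the C-derivative at x.  Exact whenever f
    is a logcontrast (in particular for every ilr coordinate).
    """
    au = _asarray(u)
    _check_positive(au, "perturbation")
    A = c_derivative(f, x, mode=mode)
    xc = np.asarray(closure(_asarray(x), 1.0), dtype=float)
    return f(xc) + A @ np.log(au)


def ilr_c_partials(D: int, i: int) -> np.ndarray:
    """C-derivative (logcontrast) of the i-th pivot ilr coordinate, 1-based.

    Component j equals 0 for j < i, sqrt((D-i)/(D-i+1)) for j = i and
    -sqrt((D-i)/(D-i+1))/(D-i) for j > i; the components sum to zero.
    """
    if not 1 <= i <= D - 1:
        raise ValueError(f"coordinate index i={i} out of range 1..{D - 1}")
    return pivot_basis(D)[i - 1].copy()


def log_ratio_variances(samples) -> np.ndarray:
    """D x D matrix of sample variances Var(ln s_k / s_l) (ddof=1)."""
    arr = np.atleast_2d(np.asarray(samples, dtype=float))
    _check_positive(arr, "sample matrix")
    L = np.log(arr)
    n, D = L.shape
    if n < 2:
        raise ValueError("need at least 2 sample rows to estimate variances")
    Lc = L - L.mean(axis=0)
    C = (Lc.T @ Lc) / (n - 1)            # log covariance
    d = np.diag(C)
    return d[:, None] + d[None, :] - 2.0 * C


@dataclass
class ErrorModel:
    """Multiplicative error model x = mu (+) eps around a compositional center.

    Only the pairwise log-ratio variances Var(ln eps_k/eps_l) of the error
    enter any ilr coordinate variance, so the model stores that D x D table
    (zero diagonal, symmetric).  Build it either from a known table or from
    a sample of error draws via :meth:`from_samples`.
    """

    log_ratio_variances: np.ndarray
    center: np.ndarray | None = None

    def __post_init__(self):
        V = np.atleast_2d(np.asarray(self.log_ratio_variances, dtype=float))
        if V.shape[0] != V.shape[1]:
            raise ValueError("log-ratio variance table must be square")
        if not np.allclose(V, V.T, atol=1e-10 * (1 + np.abs(V).max())):
            raise ValueError("log-ratio variance table must be symmetric")
        if np.any(np.diag(V) != 0):
            raise ValueError("diagonal of the log-ratio variance table must be 0")
        if np.any(V < 0):
            raise ValueError("log-ratio variances must be nonnegative")
        self.log_ratio_variances = V

    @property
    def D(self) -> int:
        return self.log_ratio_variances.shape[0]

    @classmethod
    def from_samples(cls, eps_samples, center=None) -> "ErrorModel":
        """Estimate the pairwise table from an n x D sample of error draws."""
        return cls(log_ratio_variances=log_ratio_variances(eps_samples),
                   center=center)

    @classmethod
    def iid(cls, D: int, sigma2: float) -> "ErrorModel":
        """Independent log-errors of equal variance: Var(ln e_k/e_l) = 2 sigma2."""
        V = np.full((D, D), 2.0 * float(sigma2))
        np.fill_diagonal(V, 0.0)
        return cls(log_ratio_variances=V)


def ilr_error_variance(model: ErrorModel, j: int) -> tuple[float, float, float]:
    """Variance decomposition Var(z_j) = A - B of the j-th pivot coordinate.

    Returns ``(A, B, var)`` where A averages the log-ratio variances that
    involve the pivot part j and B those among the remaining parts.  With a
    near-degenerate variance table sampling noise can push A - B slightly
    below zero; the raw value is returned and flagged via a warning rather
    than clamped, so callers can distinguish degeneracy from a true zero.
    """
    D = model.D
    if not 1 <= j <= D - 1:
        raise ValueError(f"coordinate index j={j} out of range 1..{D - 1}")
    V = model.log_ratio_variances
    jj = j - 1                              # 0-based pivot index
    rest = np.arange(jj + 1, D)
    A = V[jj, rest].sum() / (D - j + 1.0)
    B = V[np.ix_(rest, rest)].sum() / (2.0 * (D - j) * (D - j + 1.0))
    var = A - B
    if var < 0:
        warnings.warn(
            f"degenerate variance decomposition for j={j}: A - B = {var:.3g} "
            "< 0 (sampling noise or a variance table with no pivot-part "
            "contribution); reporting the raw value",
            RuntimeWarning, stacklevel=2)
    return float(A), float(B), float(var)
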