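"""Measurement-error generators: detection-limit rounding and imprecision.

Two contamination schemes mimic common data-quality problems in geochemical
and biomonitoring practice:

* **Detection limit (DL)** — every value of an affected part at or below a
  threshold DL_j (a quantile of that part, or an explicit limit) is replaced
  by (2/3) DL_j, the routine plug-in for values below detection.  This is a
  non-linear, asymmetric distortion.
* **Imprecision rate (IR)** — every cell of an affected part is multiplied
  by (1 + gamma) with gamma ~ U(-alpha_j, alpha_j).  The noise is
  multiplicative (equivalently additive with amplitude proportional to the
  value), symmetric, and leaves the expected value unchanged.

Both operate on a validated composition matrix and return one; DL reports
per-part replacement counts, IR is reproducible from a seed through
per-(replication, column) random streams.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import validate_composition_matrix

__all__ = ["DLSpec", "IRSpec", "apply_detection_limit", "apply_imprecision"]


@dataclass
class DLSpec:
    """Detection-limit contamination of the named parts.

    Either *quantile* (DL_j = that quantile of the part's uncontaminated
    values, linear/type-7 interpolation) or *limits* (explicit DL_j per
    part) must be given.  Values x <= DL_j become replacement_factor * DL_j.
    """

    parts: tuple[str, ...]
    quantile: float | None = None
    limits: dict[str, float] | None = None
    replacement_factor: float = 2.0 / 3.0

    def __post_init__(self):
        self.parts = tuple(self.parts)
        if (self.quantile is None) == (self.limits is None):
            raise ValueError("give exactly one of quantile= or limits=")
        if self.quantile is not None and not 0.0 <= self.quantile < 1.0:
            raise ValueError(f"quantile must be in [0, 1), got {self.quantile}")
        if self.limits is not None:
            for p, dl in self.limits.items():
                if dl <= 0:
                    raise ValueError(f"explicit detection limit for {p!r} "
                                     f"must be positive, got {dl}")

    def limit_for(self, part: str, column: np.ndarray) -> float:
        if self.limits is not None:
            return float(self.limits[part])
        return float(np.quantile(column, self.quantile))


@dataclass
class IRSpec:
    """Imprecision contamination: alpha_j per affected part (a single float
    applies to all named parts)."""

    parts: tuple[str, ...]
    alpha: float | dict[str, float] = 0.25

    def __post_init__(self):
        self.parts = tuple(self.parts)
        alphas = (self.alpha.values() if isinstance(self.alpha, dict)
                  else [self.alpha])
        if any(a < 0 for a in alphas):
            raise ValueError("imprecision rate alpha must be nonnegative")

    def alpha_for(self, part: str) -> float:
        if isinstance(self.alpha, dict):
            return float(self.alpha[part])
        return float(self.alpha)


def _check_parts(spec_parts, columns) -> None:
    missing = [p for p in spec_parts if p not in columns]
    if missing:
        raise KeyError(f"parts {missing} not among columns {list(columns)}")


def apply_detection_limit(X, spec: DLSpec):
    """Replace values at or below the detection limit by (2/3) DL_j.

    Returns ``(Xstar, n_replaced)`` where *n_replaced* is a per-part Series
    of replacement counts and a ``dl_values`` attribute on it records the
    resolved DL_j actually used.  The comparison is ``<=``, so with an
    explicit DL the operator is idempotent (the replacement 2/3 DL is again
    <= DL and maps to itself).
    """
    X = validate_composition_matrix(X)
    _check_parts(spec.parts, X.columns)
    Xstar = X.copy()
    counts = pd.Series(0, index=list(spec.parts), dtype=int)
    dl_values = {}
    for part in spec.parts:
        col = X[part].to_numpy()
        dl = spec.limit_for(part, col)
        dl_values[part] = dl
        below = col <= dl
        Xstar.loc[below, part] = spec.replacement_factor * dl
        counts[part] = int(below.sum())
    counts.attrs["dl_values"] = dl_values
    return Xstar, counts


def apply_imprecision(X, spec: IRSpec, seed: int, *, stream_key: int = 0):
    """Multiply each affected cell by (1 + gamma), gamma ~ U(-alpha, alpha).

    Each (stream_key, column) pair gets its own counter-based random stream
    derived from *seed*, so results are reproducible regardless of column
    evaluation order and parallel execution of replications.  For alpha >= 1
    a draw with 1 + gamma <= 0 is rejected and redrawn (truncated uniform):
    compositional parts must stay strictly positive.
    """
    X = validate_composition_matrix(X)
    _check_parts(spec.parts, X.columns)
    Xstar = X.copy()
    col_index = {c: k for k, c in enumerate(X.columns)}
    n = len(X)
    for part in spec.parts:
        alpha = spec.alpha_for(part)
        if alpha == 0:
            continue
        rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(stream_key, col_index[part])))
        gamma = rng.uniform(-alpha, alpha, size=n)
        bad = gamma <= -1.0
        while bad.any():                      # only reachable when alpha >= 1
            gamma[bad] = rng.uniform(-alpha, alpha, size=int(bad.sum()))
            bad = gamma <= -1.0
        Xstar[part] = X[part].to_numpy() * (1.0 + gamma)
    return Xstar
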