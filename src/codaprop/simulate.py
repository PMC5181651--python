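"""Monte-Carlo designs quantifying error propagation into ilr coordinates.

Four seeded designs measure, replication by replication, how detection-limit
(DL) or imprecision (IR) contamination of some parts distorts the pivot ilr
coordinates of a composition matrix:

1. *Incremental, one clean part* — permute the parts, keep the first
   uncontaminated, add contaminated parts one at a time (subcompositions of
   2..D parts); at each step compute the four distortion measures.
2. *Incremental, clean block of ten* — same, but a block of ten parts stays
   uncontaminated and up to ten contaminated parts are added.
3. *Amount sweep* — a random 10/10 clean/contaminated split; the
   contamination amount (DL quantile or alpha) is varied over a grid, paired
   within each replication.
4. *Sample-size sweep* — the 10/10 split at a fixed 25% contamination
   level while the number of observations is subsampled over a grid.

A fifth study decomposes the variance of the first coordinate into the
pairwise log-ratio contributions A (ratios with the pivot part) and B
(ratios among the remaining parts), comparing contaminated to
uncontaminated data.

Each replication draws its own counter-based random stream from the design
seed, so results are independent of execution order.  Results are tidy
DataFrames with columns (replication, step, measure, value) plus scheme
metadata — ready for boxplots or CSV export.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calculus import ErrorModel, ilr_error_variance
from .contamination import DLSpec, IRSpec, apply_detection_limit, apply_imprecision
from .core import validate_composition_matrix
from .metrics import distortion_report

__all__ = ["DesignConfig", "run_incremental_design", "run_amount_sweep",
           "run_samplesize_sweep", "variance_ratio_study"]

MEASURES = ("spearman_first", "masd_first", "spearman_md", "masd_md")


@dataclass
class DesignConfig:
    """Shared configuration of the simulation designs.

    *scheme* is ``"dl"`` (detection limit, *amount* = the DL quantile) or
    ``"ir"`` (imprecision, *amount* = alpha).  *steps* restricts an
    incremental design to a subset of its step grid; *grid* is the amount
    grid of the sweep design; *sizes* the subsample sizes of the
    sample-size design.  *n_clean* is the size of the uncontaminated block
    in the random-split designs.
    """

    scheme: str = "dl"
    amount: float = 0.25
    n_reps: int = 100
    seed: int = 0
    steps: tuple[int, ...] | None = None
    grid: tuple[float, ...] = tuple(np.round(np.arange(0.05, 0.951, 0.10), 2))
    sizes: tuple[int, ...] = (50, 100, 200, 500, 1000, 2107)
    n_clean: int = 10

    def __post_init__(self):
        if self.scheme not in ("dl", "ir"):
            raise ValueError(f"scheme must be 'dl' or 'ir', got {self.scheme!r}")
        if self.n_reps < 1:
            raise ValueError("need at least one replication")


def _rep_rng(seed: int, rep: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(rep,)))


def _contaminate(X: pd.DataFrame, parts, scheme: str, amount: float,
                 seed: int, stream_key: int) -> pd.DataFrame:
    """Contaminate *parts* of X; DL quantiles come from the clean columns."""
    if not parts:
        return X.copy()
    if scheme == "dl":
        Xstar, _ = apply_detection_limit(X, DLSpec(parts=tuple(parts),
                                                   quantile=amount))
        return Xstar
    return apply_imprecision(X, IRSpec(parts=tuple(parts), alpha=amount),
                             seed=seed, stream_key=stream_key)


def _tidy(records) -> pd.DataFrame:
    return pd.DataFrame.from_records(
        records, columns=["replication", "scheme", "step", "measure", "value"])


def _measure_rows(rep, scheme, step, X, Xstar, seed):
    try:
        rpt = distortion_report(X, Xstar, seed=seed)
        return [(rep, scheme, step, m, v) for m, v in rpt.as_dict().items()]
    except (ValueError, np.linalg.LinAlgError):
        # e.g. MCD infeasible on a tiny subsample: record the cells as missing
        return [(rep, scheme, step, m, np.nan) for m in MEASURES]


def run_incremental_design(X, clean_block: int, config: DesignConfig) -> pd.DataFrame:
    """Designs 1 and 2: growing subcompositions with a fixed clean block.

    Per replication the parts are permuted uniformly; the first *clean_block*
    columns stay uncontaminated and the following columns are contaminated.
    Step k analyses the subcomposition of the clean block plus the first k
    contaminated parts.  Measures at step k therefore refer to a
    (clean_block + k)-part composition.
    """
    X = validate_composition_matrix(X)
    D = X.shape[1]
    if not 1 <= clean_block < D:
        raise ValueError(f"clean_block must be in 1..{D - 1}")
    steps = config.steps or tuple(range(1, D - clean_block + 1))
    if max(steps) > D - clean_block:
        raise ValueError(f"step {max(steps)} exceeds the {D - clean_block} "
                         "available contaminated parts")
    records = []
    for rep in range(config.n_reps):
        rng = _rep_rng(config.seed, rep)
        order = rng.permutation(D)
        Xp = X.iloc[:, order]
        dirty = list(Xp.columns[clean_block:])
        Xp_star = _contaminate(Xp, dirty, config.scheme, config.amount,
                               seed=config.seed, stream_key=rep)
        md_seed = int(rng.integers(2**31))
        for k in steps:
            cols = list(Xp.columns[:clean_block + k])
            records += _measure_rows(rep, config.scheme, k,
                                     Xp[cols], Xp_star[cols], md_seed)
    return _tidy(records)


def _random_split(rng, columns, n_clean):
    """Random clean/contaminated split; a clean part is rotated to the front
    so the first pivot coordinate always pivots on an uncontaminated part."""
    order = rng.permutation(len(columns))
    cols = [columns[i] for i in order]
    return cols[:n_clean], cols[n_clean:]


def run_amount_sweep(X, config: DesignConfig) -> pd.DataFrame:
    """Design 3: fixed 10/10 split, contamination amount varied over a grid.

    The same replication (same permutation, same noise stream) is reused at
    every grid amount, so the sweep is paired.  The ``step`` column holds
    the amount.
    """
    X = validate_composition_matrix(X)
    D = X.shape[1]
    if D < config.n_clean + 1:
        raise ValueError(f"need more than n_clean = {config.n_clean} parts")
    records = []
    for rep in range(config.n_reps):
        rng = _rep_rng(config.seed, rep)
        clean, dirty = _random_split(rng, list(X.columns), config.n_clean)
        Xp = X[clean + dirty]
        md_seed = int(rng.integers(2**31))
        for amount in config.grid:
            Xp_star = _contaminate(Xp, dirty, config.scheme, amount,
                                   seed=config.seed, stream_key=rep)
            records += _measure_rows(rep, config.scheme, float(amount),
                                     Xp, Xp_star, md_seed)
    return _tidy(records)


def run_samplesize_sweep(X, config: DesignConfig) -> pd.DataFrame:
    """Design 4: 10/10 split at fixed 25% contamination, n varied.

    Rows are subsampled without replacement to each size in ``config.sizes``
    (sizes above n are skipped).  Subsamples where the MCD cannot be fitted
    are recorded as missing cells rather than aborting.  The ``step`` column
    holds the subsample size.
    """
    X = validate_composition_matrix(X)
    n, D = X.shape
    if D < config.n_clean + 1:
        raise ValueError(f"need more than n_clean = {config.n_clean} parts")
    sizes = [s for s in config.sizes if s <= n]
    records = []
    for rep in range(config.n_reps):
        rng = _rep_rng(config.seed, rep)
        clean, dirty = _random_split(rng, list(X.columns), config.n_clean)
        Xp = X[clean + dirty]
        Xp_star = _contaminate(Xp, dirty, config.scheme, config.amount,
                               seed=config.seed, stream_key=rep)
        md_seed = int(rng.integers(2**31))
        for size in sizes:
            idx = rng.choice(n, size=size, replace=False)
            records += _measure_rows(rep, config.scheme, int(size),
                                     Xp.iloc[idx], Xp_star.iloc[idx], md_seed)
    return _tidy(records)


def _first_coordinate_ab(X: pd.DataFrame) -> tuple[float, float]:
    """Empirical A/B decomposition of Var(z_1) from the data's log-ratios."""
    model = ErrorModel.from_samples(X.to_numpy())
    A, B, _ = ilr_error_variance(model, 1)
    return A, B


def variance_ratio_study(X, config: DesignConfig) -> pd.DataFrame:
    """A/B variance decomposition of z_1 with growing subcompositions.

    Follows the incremental one-clean-part design: per replication the parts
    are permuted and contaminated columns added one at a time.  At each step
    the decomposition Var(z_1) = A - B is computed empirically from the
    pairwise log-ratio sample variances of (a) the uncontaminated
    subcomposition, (b) its DL-contaminated version and (c) its
    IR-contaminated version (both at ``config.amount``).  Emitted measures:
    ``A``, ``B``, ``A_over_B`` and ``A_ratio`` (A contaminated / A
    uncontaminated; identically 1 for the uncontaminated scheme) per scheme
    in {none, dl, ir}.
    """
    X = validate_composition_matrix(X)
    D = X.shape[1]
    steps = config.steps or tuple(range(1, D))
    records = []
    for rep in range(config.n_reps):
        rng = _rep_rng(config.seed, rep)
        order = rng.permutation(D)
        Xp = X.iloc[:, order]
        dirty = list(Xp.columns[1:])
        versions = {
            "none": Xp,
            "dl": _contaminate(Xp, dirty, "dl", config.amount,
                               seed=config.seed, stream_key=rep),
            "ir": _contaminate(Xp, dirty, "ir", config.amount,
                               seed=config.seed, stream_key=rep),
        }
        for k in steps:
            cols = list(Xp.columns[:1 + k])
            ab = {}
            for scheme, Xv in versions.items():
                A, B = _first_coordinate_ab(Xv[cols])
                ab[scheme] = (A, B)
                records += [(rep, scheme, k, "A", A),
                            (rep, scheme, k, "B", B),
                            (rep, scheme, k, "A_over_B",
                             A / B if B > 0 else np.nan)]
            A0 = ab["none"][0]
            for scheme in ("none", "dl", "ir"):
                records.append((rep, scheme, k, "A_ratio",
                                ab[scheme][0] / A0 if A0 > 0 else np.nan))
    return _tidy(records)
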