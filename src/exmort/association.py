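"""Ecological association of excess mortality with reported COVID-19 burden,
and local Moran's I spatial clustering.

``correlate`` regresses per-unit excess death rates on a per-unit covariate
(cumulative reported cases or deaths per 100,000) by OLS and reports the
Pearson correlation with its exact two-sided t-test p-value (n-2 degrees of
freedom).

``local_morans_i`` is the Anselin local indicator of spatial association:
with row-standardized weights w_ij and deviations z_i = x_i - mean(x),

    I_i = z_i / m2 * sum_j w_ij z_j,      m2 = sum(z^2) / n

so that the mean of the defined I_i equals the global Moran's I.  Pseudo
p-values come from conditional permutation (the value at i is held fixed,
the remaining n-1 values are randomly reassigned to the other locations),
two-sided on |I|.  Units with no neighbours have undefined I_i and are
flagged and excluded from the global identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AssociationResult:
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n: int


def correlate(x, y) -> AssociationResult:
    """OLS of y on x plus Pearson correlation across units.

    Accepts aligned sequences or two pandas Series indexed by unit (inner
    join on the index in that case).
    """
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        joined = pd.concat({"x": x, "y": y}, axis=1, join="inner").dropna()
        x, y = joined["x"].to_numpy(), joined["y"].to_numpy()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be aligned")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 paired units, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y: correlation undefined")
    res = stats.linregress(x, y)
    return AssociationResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        n=n,
    )


def quarterly_association_profile(
    excess: pd.DataFrame, covariate: pd.DataFrame
) -> dict[str, AssociationResult]:
    """Per-period association between excess and a reported-burden covariate.

    ``excess`` has columns ``unit_id, period, excess_abs``; ``covariate`` has
    ``unit_id, value`` (or ``unit_id, period, value`` for period-specific
    covariates).  Returns one :class:`AssociationResult` per period present.
    """
    out = {}
    period_specific = "period" in covariate.columns
    for period, grp in excess.groupby("period"):
        cov = covariate[covariate["period"] == period] if period_specific else covariate
        merged = grp.merge(cov[["unit_id", "value"]], on="unit_id", how="inner")
        out[period] = correlate(
            merged["value"].to_numpy(), merged["excess_abs"].to_numpy()
        )
    return out


# ---------------------------------------------------------------------------
# Spatial weights and local Moran's I
# ---------------------------------------------------------------------------

@dataclass
class SpatialWeights:
    """Symmetric non-negative spatial weights with zero diagonal."""

    unit_ids: list[str]
    matrix: np.ndarray  # raw (pre-standardization) weights

    def __post_init__(self):
        W = np.asarray(self.matrix, dtype=float)
        n = len(self.unit_ids)
        if W.shape != (n, n):
            raise ValueError(f"weights must be {n}x{n}")
        if (W < 0).any():
            raise ValueError("weights must be non-negative")
        if np.diag(W).any():
            raise ValueError("weights must have a zero diagonal")
        if not np.allclose(W, W.T):
            raise ValueError("weights must be symmetric before row-standardization")
        self.matrix = W

    @property
    def n(self) -> int:
        return len(self.unit_ids)

    def row_standardized(self) -> np.ndarray:
        rs = self.matrix.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            W = np.where(rs > 0, self.matrix / rs, 0.0)
        return W

    @property
    def isolated(self) -> np.ndarray:
        return self.matrix.sum(axis=1) == 0


def weights_from_adjacency(
    edges: pd.DataFrame | str | Path, unit_ids: Sequence[str] | None = None
) -> SpatialWeights:
    """Build weights from an edge list ``unit_i, unit_j, weight``.

    Edges are symmetrized (each listed pair sets both w_ij and w_ji).
    """
    if not isinstance(edges, pd.DataFrame):
        edges = pd.read_csv(edges)
    required = ["unit_i", "unit_j", "weight"]
    missing = [c for c in required if c not in edges.columns]
    if missing:
        raise ValueError(f"adjacency table missing columns: {missing}")
    if unit_ids is None:
        unit_ids = sorted(set(edges["unit_i"]) | set(edges["unit_j"]))
    unit_ids = list(unit_ids)
    index = {u: i for i, u in enumerate(unit_ids)}
    W = np.zeros((len(unit_ids), len(unit_ids)))
    for ui, uj, w in edges[required].itertuples(index=False):
        if ui not in index or uj not in index:
            continue
        i, j = index[ui], index[uj]
        if i == j:
            raise ValueError(f"self-edge for unit {ui!r}")
        W[i, j] = w
        W[j, i] = w
    return SpatialWeights(unit_ids=unit_ids, matrix=W)


def grid_weights(nrow: int, ncol: int, prefix: str = "u") -> SpatialWeights:
    """Rook-adjacency weights on an nrow x ncol grid (test/simulation helper)."""
    ids = [f"{prefix}{r}_{c}" for r in range(nrow) for c in range(ncol)]
    n = nrow * ncol
    W = np.zeros((n, n))
    for r in range(nrow):
        for c in range(ncol):
            i = r * ncol + c
            if r + 1 < nrow:
                W[i, i + ncol] = W[i + ncol, i] = 1.0
            if c + 1 < ncol:
                W[i, i + 1] = W[i + 1, i] = 1.0
    return SpatialWeights(unit_ids=ids, matrix=W)


@dataclass
class LocalMoranResult:
    unit_ids: list[str]
    local_i: np.ndarray       # NaN for isolated units
    pseudo_p: np.ndarray      # NaN for isolated units
    quadrant: list[str]       # HH / LL / HL / LH / none
    global_i: float


def global_morans_i(values, weights: SpatialWeights) -> float:
    """Global Moran's I, (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2,
    with row-standardized weights (so S0 equals the number of units with at
    least one neighbour)."""
    x = np.asarray(values, dtype=float)
    W = weights.row_standardized()
    z = x - x.mean()
    s0 = W.sum()
    return float(weights.n / s0 * (z @ W @ z) / (z**2).sum())


def local_morans_i(
    values,
    weights: SpatialWeights,
    permutations: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
) -> LocalMoranResult:
    """Anselin local Moran's I with conditional-permutation pseudo p-values."""
    x = np.asarray(values, dtype=float)
    n = weights.n
    if x.size != n:
        raise ValueError("values must align with weights' unit_ids")
    if n < 4:
        raise ValueError("need at least 4 units")
    if np.ptp(x) == 0:
        raise ValueError("constant values: spatial autocorrelation undefined")

    W = weights.row_standardized()
    isolated = weights.isolated
    z = x - x.mean()
    m2 = (z**2).sum() / n
    lag = W @ z
    local_i = z * lag / m2
    local_i[isolated] = np.nan

    rng = np.random.default_rng(seed)
    pseudo_p = np.full(n, np.nan)
    quadrant = ["none"] * n
    all_idx = np.arange(n)
    for i in range(n):
        if isolated[i]:
            continue
        nbr = np.flatnonzero(W[i] > 0)
        wn = W[i, nbr]
        k = nbr.size
        others = z[all_idx != i]
        # conditional permutation: sample k of the n-1 other values without
        # replacement per replicate and apply this row's weights
        ridx = rng.random((permutations, n - 1)).argsort(axis=1)[:, :k]
        lag_perm = others[ridx] @ wn
        i_perm = z[i] * lag_perm / m2
        exceed = (np.abs(i_perm) >= abs(local_i[i])).sum()
        pseudo_p[i] = (1.0 + exceed) / (1.0 + permutations)
        if pseudo_p[i] < alpha:
            if z[i] >= 0:
                quadrant[i] = "HH" if lag[i] >= 0 else "HL"
            else:
                quadrant[i] = "LL" if lag[i] < 0 else "LH"

    # Anselin decomposition: the mean of the defined I_i is the global I
    global_i = float(np.nanmean(local_i))
    return LocalMoranResult(
        unit_ids=list(weights.unit_ids),
        local_i=local_i,
        pseudo_p=pseudo_p,
        quadrant=quadrant,
        global_i=global_i,
    )
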