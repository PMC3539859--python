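"""Distances, principal coordinates analysis and rank tests on axes.

The genetic distance is the Nei & Li / Dice complement
``d = 1 - 2*n11 / (2*n11 + n10 + n01)`` computed over jointly scored loci.
PCoA is classical metric scaling: double-centre ``-d**2/2``,
eigendecompose, scale eigenvectors by the square root of their (positive)
eigenvalues.  Negative eigenvalues are reported, not corrected, by default;
a Lingoes additive correction is available behind a flag.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ConfigError, GroupingError, MarkerMatrix


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray
    metric: str  # {nei_li, mismatch, geographic, euclidean, ...}

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ConfigError("distance matrix shape does not match ids")
        finite = ~np.isnan(v)
        if not np.allclose(v[finite & finite.T], v.T[finite & finite.T]):
            raise ConfigError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ConfigError("distance matrix diagonal must be zero")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return self.values[np.triu_indices(self.n, k=1)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def nei_li_distance(matrix: MarkerMatrix) -> DistanceMatrix:
    """1 minus the Dice similarity over jointly scored loci.

    For each pair: ``S = 2*n11 / (2*n11 + n10 + n01)``; pairs whose
    denominator is zero (no band on either side among shared scored loci)
    have undefined distance, recorded as NaN with a warning.
    """
    if matrix.n_samples < 2:
        raise ConfigError("distance needs >= 2 samples")
    B, S = matrix.band, matrix.scored
    both = S[:, None, :] & S[None, :, :]
    P = np.nan_to_num(B)  # 1 where present, 0 otherwise
    n11 = np.einsum("il,jl,ijl->ij", P, P, both.astype(float))
    pres_i = np.einsum("il,ijl->ij", P, both.astype(float))
    pres_j = np.einsum("jl,ijl->ij", P, both.astype(float))
    n10 = pres_i - n11
    n01 = pres_j - n11
    denom = 2 * n11 + n10 + n01
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(denom > 0, 1.0 - 2.0 * n11 / np.maximum(denom, 1e-300), np.nan)
    np.fill_diagonal(d, 0.0)
    if np.isnan(d[np.triu_indices_from(d, k=1)]).any():
        warnings.warn(
            "some sample pairs share no scored band; their Nei-Li distance "
            "is undefined (NaN)",
            stacklevel=2,
        )
    return DistanceMatrix(list(matrix.sample_ids), d, "nei_li")


def haversine_km(
    lat1: float, lon1: float, lat2: float, lon2: float, radius_km: float = 6371.0
) -> float:
    """Great-circle distance between two points in decimal degrees."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    return float(2 * radius_km * np.arcsin(np.sqrt(a)))


def geographic_distance_matrix(
    coords: pd.DataFrame, planar: bool = False
) -> DistanceMatrix:
    """Pairwise distances (km) between rows of a table indexed by unit id
    with ``latitude``/``longitude`` columns.  ``planar=True`` treats the
    coordinates as planar x/y instead of degrees."""
    ids = [str(i) for i in coords.index]
    lat = coords["latitude"].to_numpy(dtype=float)
    lon = coords["longitude"].to_numpy(dtype=float)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if planar:
                d[i, j] = np.hypot(lat[i] - lat[j], lon[i] - lon[j])
            else:
                d[i, j] = haversine_km(lat[i], lon[i], lat[j], lon[j])
            d[j, i] = d[i, j]
    return DistanceMatrix(ids, d, "geographic")


def population_distance_matrix(
    genetic: DistanceMatrix, population_of: dict[str, str]
) -> DistanceMatrix:
    """Population-level genetic distances: mean pairwise sample distance
    between (and zero within-diagonal for) populations."""
    pops = sorted(set(population_of.values()))
    idx_of = {s: i for i, s in enumerate(genetic.ids)}
    members = {p: [idx_of[s] for s, q in population_of.items() if q == p] for p in pops}
    n = len(pops)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            block = genetic.values[np.ix_(members[pops[i]], members[pops[j]])]
            out[i, j] = out[j, i] = float(np.nanmean(block))
    return DistanceMatrix(pops, out, genetic.metric)


@dataclass
class PcoaResult:
    ids: list[str]
    coordinates: np.ndarray  # samples x retained (positive-eigenvalue) axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    percent_variance: np.ndarray  # per retained axis, over positive sum
    n_negative: int

    def to_frame(self) -> pd.DataFrame:
        cols = [f"axis_{k+1}" for k in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.ids, columns=cols)


def pcoa(distance: DistanceMatrix, correction: str | None = None) -> PcoaResult:
    """Classical scaling of a complete distance matrix.

    ``correction='lingoes'`` adds the smallest constant to squared
    off-diagonal distances making the Gram matrix positive semidefinite;
    the default applies no correction and simply reports the count of
    negative eigenvalues.
    """
    D = distance.values
    if np.isnan(D).any():
        raise ConfigError(
            "distance matrix has undefined entries; impute them or subset "
            "the samples before ordination"
        )
    n = distance.n
    D2 = D**2
    if correction == "lingoes":
        J = np.eye(n) - np.ones((n, n)) / n
        G = -0.5 * J @ D2 @ J
        lam_min = np.linalg.eigvalsh(G).min()
        if lam_min < 0:
            c = -2.0 * lam_min
            D2 = D2 + c * (1 - np.eye(n))
    elif correction is not None:
        raise ConfigError(f"unknown eigenvalue correction {correction!r}")
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ D2 @ J
    eigval, eigvec = np.linalg.eigh((G + G.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    tol = max(abs(eigval[0]), 1.0) * 1e-10
    positive = eigval > tol
    n_negative = int((eigval < -tol).sum())
    coords = eigvec[:, positive] * np.sqrt(eigval[positive])
    pos_sum = eigval[positive].sum()
    pct = 100.0 * eigval[positive] / pos_sum if pos_sum > 0 else eigval[positive] * 0.0
    return PcoaResult(list(distance.ids), coords, eigval, pct, n_negative)


def axis_group_test(
    result: PcoaResult,
    grouping: dict[str, str],
    axes: tuple[int, ...] = (1, 2, 3),
) -> pd.DataFrame:
    """Rank tests comparing groups on PCoA axes (1-based axis numbers).

    Two groups: Mann-Whitney U with average-rank ties and the normal
    approximation; more: Kruskal-Wallis H.  Two-sided p per axis.
    """
    idx_of = {s: i for i, s in enumerate(result.ids)}
    groups: dict[str, list[int]] = {}
    for s, g in grouping.items():
        if s in idx_of:
            groups.setdefault(str(g), []).append(idx_of[s])
    if len(groups) < 2:
        raise GroupingError("axis test needs >= 2 groups")
    if any(len(v) == 0 for v in groups.values()):
        raise GroupingError("axis test groups must be non-empty")
    labels = sorted(groups)
    rows = []
    for ax in axes:
        if ax < 1 or ax > result.coordinates.shape[1]:
            continue
        vals = [result.coordinates[groups[g], ax - 1] for g in labels]
        if len(labels) == 2:
            stat, p = stats.mannwhitneyu(
                vals[0], vals[1], alternative="two-sided", method="asymptotic"
            )
            test = "mann-whitney"
        else:
            stat, p = stats.kruskal(*vals)
            test = "kruskal-wallis"
        rows.append(
            {"axis": ax, "test": test, "statistic": float(stat), "p_value": float(p)}
        )
    return pd.DataFrame(rows)
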