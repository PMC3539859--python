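"""Analysis of molecular variance on dominant marker data.

The decomposition follows the standard distance-based AMOVA: pairwise
squared distances are the number of mismatching scored loci (squared
Euclidean on 0/1 band vectors, the usual choice for AFLP; the Nei-Li
distance may be substituted), sums of squares come from within-group
distance sums, and variance components from the expected mean squares with
unequal group sizes.  Significance is assessed by permuting sample labels
at the tested level.

One-level designs yield phi_ST; two-level (groups containing populations)
designs additionally yield phi_CT (among groups) and phi_SC (among
populations within groups).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ConfigError, GroupingError, MarkerMatrix
from .ordination import nei_li_distance


@dataclass
class AmovaResult:
    rows: pd.DataFrame  # source, df, SS, sigma2, pct_variance
    phi: dict[str, float]
    n_samples: int
    metric: str
    p_values: dict[str, float] = field(default_factory=dict)
    n_permutations: int = 0
    seed: int | None = None

    @property
    def phi_st(self) -> float:
        return self.phi.get("phi_st", float("nan"))


def _squared_distance_matrix(matrix: MarkerMatrix, metric: str) -> np.ndarray:
    if metric == "mismatch":
        B, S = matrix.band, matrix.scored
        both = S[:, None, :] & S[None, :, :]
        with np.errstate(invalid="ignore"):
            neq = (B[:, None, :] != B[None, :, :]) & both
        return neq.sum(axis=2).astype(float)
    if metric == "nei_li":
        return nei_li_distance(matrix).values ** 2
    raise ConfigError(f"unknown AMOVA distance metric {metric!r}")


def _ss(d2: np.ndarray, idx: np.ndarray) -> float:
    """Within-set sum of squares: sum of pairwise d^2 over set size."""
    if len(idx) < 2:
        return 0.0
    block = d2[np.ix_(idx, idx)]
    return float(block[np.triu_indices(len(idx), k=1)].sum()) / len(idx)


def _one_level(
    d2: np.ndarray, labels: np.ndarray
) -> tuple[list[dict], dict[str, float]]:
    N = len(labels)
    groups = [np.flatnonzero(labels == g) for g in np.unique(labels)]
    G = len(groups)
    ss_total = _ss(d2, np.arange(N))
    ss_within = sum(_ss(d2, idx) for idx in groups)
    ss_among = ss_total - ss_within
    df_among, df_within = G - 1, N - G
    ms_among = ss_among / df_among if df_among else float("nan")
    ms_within = ss_within / df_within if df_within else float("nan")
    n0 = (N - sum(len(idx) ** 2 for idx in groups) / N) / (G - 1)
    sigma_within = ms_within
    sigma_among = (ms_among - ms_within) / n0
    rows = [
        {"source": "among_groups", "df": df_among, "SS": ss_among, "sigma2": sigma_among},
        {"source": "within_groups", "df": df_within, "SS": ss_within, "sigma2": sigma_within},
    ]
    total = sigma_among + sigma_within
    phi = {"phi_st": sigma_among / total if total > 0 else float("nan")}
    return rows, phi


def _two_level(
    d2: np.ndarray, group_labels: np.ndarray, pop_labels: np.ndarray
) -> tuple[list[dict], dict[str, float]]:
    N = len(group_labels)
    groups = {
        g: np.flatnonzero(group_labels == g) for g in np.unique(group_labels)
    }
    pops = {p: np.flatnonzero(pop_labels == p) for p in np.unique(pop_labels)}
    G, P = len(groups), len(pops)
    if P <= G:
        raise GroupingError("two-level design needs more populations than groups")

    ss_total = _ss(d2, np.arange(N))
    ss_wp = sum(_ss(d2, idx) for idx in pops.values())
    ss_wg = sum(_ss(d2, idx) for idx in groups.values())
    ss_ap = ss_wg - ss_wp  # among populations within groups
    ss_ag = ss_total - ss_wg

    df_ag, df_ap, df_wp = G - 1, P - G, N - P
    ms_ag = ss_ag / df_ag
    ms_ap = ss_ap / df_ap
    ms_wp = ss_wp / df_wp

    # unequal-size coefficients of the expected mean squares
    pop_sizes = {p: len(idx) for p, idx in pops.items()}
    group_of_pop = {}
    for p, idx in pops.items():
        gl = np.unique(group_labels[idx])
        if len(gl) != 1:
            raise GroupingError(f"population {p!r} spans more than one group")
        group_of_pop[p] = gl[0]
    group_sizes = {g: len(idx) for g, idx in groups.items()}
    sum_npsq_over_ng = sum(
        pop_sizes[p] ** 2 / group_sizes[group_of_pop[p]] for p in pops
    )
    sum_npsq_over_n = sum(s**2 for s in pop_sizes.values()) / N
    sum_ngsq_over_n = sum(s**2 for s in group_sizes.values()) / N
    n_c = (N - sum_npsq_over_ng) / df_ap
    n_cp = (sum_npsq_over_ng - sum_npsq_over_n) / df_ag
    n_cpp = (N - sum_ngsq_over_n) / df_ag

    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / n_c
    sigma_a = (ms_ag - sigma_c - n_cp * sigma_b) / n_cpp
    rows = [
        {"source": "among_groups", "df": df_ag, "SS": ss_ag, "sigma2": sigma_a},
        {"source": "among_populations_within_groups", "df": df_ap, "SS": ss_ap, "sigma2": sigma_b},
        {"source": "within_populations", "df": df_wp, "SS": ss_wp, "sigma2": sigma_c},
    ]
    total = sigma_a + sigma_b + sigma_c
    phi = {
        "phi_ct": sigma_a / total if total > 0 else float("nan"),
        "phi_sc": sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) > 0 else float("nan"),
        "phi_st": (sigma_a + sigma_b) / total if total > 0 else float("nan"),
    }
    return rows, phi


def amova(
    matrix: MarkerMatrix,
    groups: dict[str, str],
    populations: dict[str, str] | None = None,
    metric: str = "mismatch",
    truncate_negative: bool = True,
) -> AmovaResult:
    """Hierarchical AMOVA.

    ``groups`` maps sample -> group at the tested (top) level; when
    ``populations`` is also given the design is two-level with populations
    nested in groups.  Negative variance components are reported raw in the
    ``sigma2`` column; percent variance is computed after truncating them
    at zero unless ``truncate_negative=False``.
    """
    sample_ids = [s for s in matrix.sample_ids if s in groups]
    if len(set(groups[s] for s in sample_ids)) < 2:
        raise GroupingError("AMOVA needs >= 2 groups at the tested level")
    sub = matrix.subset(sample_ids)
    d2 = _squared_distance_matrix(sub, metric)
    glab = np.array([str(groups[s]) for s in sample_ids])
    if populations is None:
        rows, phi = _one_level(d2, glab)
    else:
        plab = np.array([str(populations[s]) for s in sample_ids])
        rows, phi = _two_level(d2, glab, plab)

    table = pd.DataFrame(rows)
    sig = table["sigma2"].to_numpy(dtype=float)
    disp = np.maximum(sig, 0.0) if truncate_negative else sig
    total = disp.sum()
    if total > 0:
        table["pct_variance"] = 100.0 * disp / total
    else:
        table["pct_variance"] = float("nan")
        warnings.warn(
            "total molecular variance is zero; phi statistics are undefined",
            stacklevel=2,
        )
    return AmovaResult(table, phi, len(sample_ids), metric)


def amova_permutation(
    matrix: MarkerMatrix,
    groups: dict[str, str],
    populations: dict[str, str] | None = None,
    n_perm: int = 999,
    seed: int | None = None,
    metric: str = "mismatch",
) -> AmovaResult:
    """AMOVA with permutation p-values.

    Sample labels are permuted among groups at the tested level and each
    phi statistic recomputed; ``p = (count >= observed + 1)/(n_perm + 1)``.
    For two-level designs: phi_CT permutes whole populations among groups,
    phi_SC permutes samples among populations within their group, phi_ST
    permutes samples freely.
    """
    if n_perm < 99:
        raise ConfigError("use at least 99 permutations")
    observed = amova(matrix, groups, populations, metric=metric)
    sample_ids = [s for s in matrix.sample_ids if s in groups]
    sub = matrix.subset(sample_ids)
    d2 = _squared_distance_matrix(sub, metric)
    glab = np.array([str(groups[s]) for s in sample_ids])
    rng = np.random.default_rng(seed)
    p_values: dict[str, float] = {}

    if populations is None:
        obs = observed.phi["phi_st"]
        if np.isnan(obs):
            # no molecular variance at all: nothing to reject
            p_values["phi_st"] = 1.0
        else:
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(len(glab))
                _, phi = _one_level(d2, glab[perm])
                if phi["phi_st"] >= obs:
                    count += 1
            p_values["phi_st"] = (count + 1) / (n_perm + 1)
    else:
        plab = np.array([str(populations[s]) for s in sample_ids])
        counts = {"phi_st": 0, "phi_sc": 0, "phi_ct": 0}
        uniq_pops = np.unique(plab)
        group_of_pop = {p: glab[plab == p][0] for p in uniq_pops}
        for _ in range(n_perm):
            # phi_ST: free permutation of samples
            perm = rng.permutation(len(glab))
            _, phi = _two_level(d2, glab[perm], plab[perm])
            if phi["phi_st"] >= observed.phi["phi_st"]:
                counts["phi_st"] += 1
            # phi_SC: permute samples within groups
            plab_w = plab.copy()
            for g in np.unique(glab):
                idx = np.flatnonzero(glab == g)
                plab_w[idx] = plab_w[idx[rng.permutation(len(idx))]]
            _, phi = _two_level(d2, glab, plab_w)
            if phi["phi_sc"] >= observed.phi["phi_sc"]:
                counts["phi_sc"] += 1
            # phi_CT: permute whole populations among groups
            perm_groups = rng.permutation([group_of_pop[p] for p in uniq_pops])
            gmap = dict(zip(uniq_pops, perm_groups))
            glab_p = np.array([gmap[p] for p in plab])
            try:
                _, phi = _two_level(d2, glab_p, plab)
                if phi["phi_ct"] >= observed.phi["phi_ct"]:
                    counts["phi_ct"] += 1
            except GroupingError:
                counts["phi_ct"] += 0
        for k, c in counts.items():
            p_values[k] = (c + 1) / (n_perm + 1)

    observed.p_values = p_values
    observed.n_permutations = n_perm
    observed.seed = seed
    return observed
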