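"""Reproductive-trait statistics and the trait-diversity correlation suite.

Pollen per flower is estimated with the dilution method: the mean of ten
1-ul aliquot counts multiplied by the dilution factor (1000).  The P/O
ratio divides pollen grains per flower by the flower's ovule count.  Group
comparisons use rank tests (Mann-Whitney U for two groups, Kruskal-Wallis
beyond); associations use Spearman rank correlations, and the genetic-vs-
geographic distance association is tested with a Mantel-style matrix
permutation because distance pairs are not independent observations.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ConfigError, FormatError, TraitTable, ALIQUOT_COLS
from .ordination import DistanceMatrix


def mutant_fraction(n_mutant: int, n_total: int) -> float:
    """Fraction of androecium-mutant flowers among observed flowers."""
    if n_total < 1:
        raise FormatError("mutant fraction needs >= 1 observed flower")
    if n_mutant > n_total:
        raise FormatError("more mutant flowers than observed flowers")
    return n_mutant / n_total


def mutant_flower_frequency(
    counts: pd.DataFrame, area_of: dict[str, str] | None = None
) -> tuple[pd.DataFrame, dict | None]:
    """Per-population mutant-flower fractions, optionally compared between
    areas by Mann-Whitney U on the per-population fractions.

    ``counts`` needs columns population, n_mutant, n_total.
    """
    out = counts.copy()
    out["mutant_fraction"] = [
        mutant_fraction(int(m), int(t))
        for m, t in zip(out["n_mutant"], out["n_total"])
    ]
    comparison = None
    if area_of is not None:
        out["area"] = out["population"].map(area_of)
        groups = out.dropna(subset=["area"]).groupby("area")["mutant_fraction"]
        vals = {a: g.to_numpy() for a, g in groups}
        if len(vals) == 2:
            (a0, x0), (a1, x1) = sorted(vals.items())
            u, p = stats.mannwhitneyu(
                x0, x1, alternative="two-sided", method="asymptotic"
            )
            comparison = {"groups": (a0, a1), "U": float(u), "p_value": float(p)}
    return out, comparison


def pollen_total(aliquots, dilution: float = 1000.0) -> float:
    """Grains per flower from ten aliquot counts times the dilution factor."""
    counts = np.asarray(list(aliquots), dtype=float)
    if counts.shape != (10,):
        raise FormatError("exactly ten aliquot counts are required per flower")
    if (counts < 0).any() or np.isnan(counts).any():
        raise FormatError("aliquot counts must be non-negative numbers")
    return float(counts.mean() * dilution)


def pollen_ovule_ratio(pollen: float, ovules: int) -> float:
    if ovules < 1:
        raise ConfigError("P/O ratio is undefined for ovule count < 1")
    return pollen / ovules


def bud_summaries(traits: TraitTable, dilution: float = 1000.0) -> pd.DataFrame:
    """Per-bud pollen totals, ovule counts and P/O ratios."""
    buds = traits.buds
    if not len(buds):
        return pd.DataFrame()
    rows = []
    for r in buds.itertuples():
        pollen = pollen_total([getattr(r, c) for c in ALIQUOT_COLS], dilution)
        ov = int(r.ovule_count)
        rows.append(
            {
                "population": r.population,
                "sample_id": r.sample_id,
                "pollen_per_flower": pollen,
                "ovule_count": ov,
                "pollen_ovule_ratio": pollen_ovule_ratio(pollen, ov) if ov >= 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def seed_summaries(
    traits: TraitTable, grouping: dict[str, str] | None = None
) -> pd.DataFrame:
    """Per-group seed statistics with count provenance.

    The size unit of analysis is the per-capsule mean seed width; viability
    and germination fractions are reported with their numerators and
    denominators.  ``grouping`` maps population -> group (default: each
    population is its own group).
    """
    seeds, capsules = traits.seeds, traits.capsules

    def group_of(pop: str) -> str:
        return str(grouping.get(pop, pop)) if grouping else str(pop)

    group_names = set()
    if len(seeds):
        group_names.update(group_of(p) for p in seeds["population"])
    if len(capsules):
        group_names.update(group_of(p) for p in capsules["population"])

    rows = []
    for g in sorted(group_names):
        row: dict = {"group": g}
        if len(capsules):
            sub = capsules[[group_of(p) == g for p in capsules["population"]]]
            row["n_capsules"] = len(sub)
            row["seeds_per_capsule_mean"] = (
                float(sub["seed_count"].mean()) if len(sub) else np.nan
            )
        if len(seeds):
            sub = seeds[[group_of(p) == g for p in seeds["population"]]]
            row["n_seeds"] = len(sub)
            if "width_mm" in sub.columns and "capsule_id" in sub.columns and len(sub):
                per_capsule = sub.groupby("capsule_id")["width_mm"].mean()
                row["capsule_mean_width_mm"] = float(per_capsule.mean())
            via = sub["viability"].dropna() if "viability" in sub.columns else pd.Series(dtype=str)
            row["n_viability_tested"] = int(len(via))
            for cls in ("viable", "abnormal", "dead"):
                row[f"n_{cls}"] = int((via == cls).sum())
                row[f"{cls}_fraction"] = (
                    row[f"n_{cls}"] / len(via) if len(via) else np.nan
                )
            germ = (
                sub["germination"].dropna()
                if "germination" in sub.columns
                else pd.Series(dtype=str)
            )
            row["n_germination_tested"] = int(len(germ))
            row["germination_fraction"] = (
                float((germ == "germinated").sum() / len(germ)) if len(germ) else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class CorrelationResult:
    x_label: str
    y_label: str
    r: float
    p_value: float
    n: int
    method: str  # {asymptotic, permutation}
    seed: int | None = None


def spearman(
    x,
    y,
    labels: tuple[str, str] = ("x", "y"),
    n_perm: int | None = None,
    seed: int | None = None,
) -> CorrelationResult:
    """Spearman rank correlation with average-rank ties.

    Default p is the asymptotic two-sided value; with ``n_perm`` the
    two-sided p comes from a seeded permutation of one variable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ConfigError("x and y must have equal length")
    if len(x) < 3:
        raise ConfigError("Spearman correlation needs n >= 3")
    r, p = stats.spearmanr(x, y)
    if n_perm is not None:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            rp, _ = stats.spearmanr(x, rng.permutation(y))
            if abs(rp) >= abs(r):
                count += 1
        p = (count + 1) / (n_perm + 1)
        return CorrelationResult(*labels, float(r), float(p), len(x), "permutation", seed)
    return CorrelationResult(*labels, float(r), float(p), len(x), "asymptotic")


def _rank(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v)


def mantel_spearman(
    a: DistanceMatrix,
    b: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    labels: tuple[str, str] = ("a", "b"),
) -> CorrelationResult:
    """Spearman correlation between two distance matrices with a
    Mantel-style permutation test (rows and columns of one matrix permuted
    together, preserving symmetry and the zero diagonal)."""
    if a.ids != b.ids:
        raise ConfigError("distance matrices must share the same unit set and order")
    iu = np.triu_indices(a.n, k=1)
    va = a.values[iu]
    r_obs, _ = stats.spearmanr(va, b.values[iu])
    rng = np.random.default_rng(seed)
    ra = _rank(va)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(a.n)
        B = b.values[np.ix_(perm, perm)]
        assert np.allclose(B, B.T) and np.allclose(np.diag(B), 0.0)
        rp = np.corrcoef(ra, _rank(B[iu]))[0, 1]
        if abs(rp) >= abs(r_obs) - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return CorrelationResult(
        *labels, float(r_obs), float(p), len(va), "permutation", seed
    )


def geo_genetic_correlation(
    geo: DistanceMatrix,
    gen: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
) -> CorrelationResult:
    """Association between geographic and genetic distances over all
    unordered population pairs (n = n_pops*(n_pops-1)/2 comparisons)."""
    if set(geo.ids) != set(gen.ids):
        raise ConfigError("geographic and genetic matrices cover different populations")
    order = [gen.ids.index(i) for i in geo.ids]
    gen_aligned = DistanceMatrix(
        list(geo.ids), gen.values[np.ix_(order, order)], gen.metric
    )
    return mantel_spearman(
        geo, gen_aligned, n_perm=n_perm, seed=seed, labels=("geographic", "genetic")
    )


#: variable pairs examined together in the ratchet correlation suite
SUITE_PAIRS = [
    ("pollen_per_flower", "frag_polymorphic"),
    ("pollen_per_flower", "hj"),
    ("pollen_per_flower", "frag_private"),
    ("pollen_per_flower", "frag_fixed"),
    ("pollen_per_flower", "clonal_fraction"),
    ("mutant_fraction", "pollen_per_flower"),
    ("mutant_fraction", "frag_polymorphic"),
    ("mutant_fraction", "frag_private"),
    ("hj", "clonal_fraction"),
    ("hj", "nonclonal_fraction"),
    ("ovules_per_flower", "mutant_fraction"),
]


def correlation_suite(
    population_table: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Spearman correlations for the trait-diversity pair list, one row per
    pair, with a Holm-adjusted column alongside the raw p-values.

    ``population_table`` is indexed by population and holds the genetic
    indices and trait summaries as columns; pairs with fewer than three
    populations sharing both values, or with a constant variable, are
    skipped with a warning.
    """
    pairs = pairs if pairs is not None else SUITE_PAIRS
    rows = []
    for xl, yl in pairs:
        if xl not in population_table.columns or yl not in population_table.columns:
            warnings.warn(f"suite pair ({xl}, {yl}) missing a column; skipped", stacklevel=2)
            continue
        sub = population_table[[xl, yl]].dropna()
        if len(sub) < 3:
            warnings.warn(
                f"suite pair ({xl}, {yl}) has < 3 shared populations; skipped",
                stacklevel=2,
            )
            continue
        x, y = sub[xl].to_numpy(float), sub[yl].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(
                f"suite pair ({xl}, {yl}) has a constant variable; skipped",
                stacklevel=2,
            )
            continue
        res = spearman(x, y, labels=(xl, yl))
        rows.append(
            {"x": xl, "y": yl, "r": res.r, "p_value": res.p_value, "n": res.n}
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_holm"] = multipletests(out["p_value"], method="holm")[1]
    return out
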