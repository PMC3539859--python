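"""Fragment classes, rare-fragment classification and Nei's gene diversity.

All statistics work on band-phenotype frequencies (the presence fraction of
a fragment among scored samples), which is assumption-free for clonal
dominant data.  A square-root transform to pure-recessive allele
frequencies is available as an option for users who prefer the
Hardy-Weinberg back-transformation.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .io import ConfigError, GroupingError, MarkerMatrix


def percent_polymorphic(n_polymorphic: int, n_loci: int) -> float:
    """Percentage of polymorphic fragments out of the total locus count."""
    if n_loci < 1:
        raise ConfigError("locus count must be >= 1")
    return 100.0 * n_polymorphic / n_loci


def fragment_classes(
    matrix: MarkerMatrix, grouping: dict[str, str]
) -> pd.DataFrame:
    """Per-group fragment counts.

    polymorphic — fragment both present and absent among the group's scored
    members; fixed — present in every scored member; private — present in
    at least one member of the group and absent from every scored sample
    outside it (over the whole matrix, grouped or not).
    """
    groups: dict[str, list[int]] = {}
    for s, g in grouping.items():
        groups.setdefault(str(g), []).append(matrix.index_of(s))
    if not groups:
        raise GroupingError("grouping is empty")
    for g, idx in groups.items():
        if not idx:
            raise GroupingError(f"group {g!r} is empty")

    B, S = matrix.band, matrix.scored
    present_any_all = np.nansum(B, axis=0) > 0  # presence anywhere in matrix

    rows = []
    for g in sorted(groups):
        idx = np.array(groups[g])
        sub, subS = B[idx], S[idx]
        n_scored = subS.sum(axis=0)
        n_present = np.nansum(sub, axis=0)
        scored_loci = n_scored > 0
        polymorphic = scored_loci & (n_present > 0) & (n_present < n_scored)
        fixed = scored_loci & (n_present == n_scored)

        outside = np.ones(matrix.n_samples, dtype=bool)
        outside[idx] = False
        out_present = (
            np.nansum(B[outside], axis=0) > 0
            if outside.any()
            else np.zeros(matrix.n_loci, dtype=bool)
        )
        private = (n_present > 0) & ~out_present

        rows.append(
            {
                "group": g,
                "n_samples": len(idx),
                "frag_polymorphic": int(polymorphic.sum()),
                "pct_polymorphic": percent_polymorphic(
                    int(polymorphic.sum()), matrix.n_loci
                ),
                "frag_fixed": int(fixed.sum()),
                "frag_private": int(private.sum()),
                "frag_absent": int((~present_any_all | (n_present == 0)).sum()),
            }
        )
    return pd.DataFrame(rows)


def rare_fragments(
    matrix: MarkerMatrix,
    area_of: dict[str, str],
    threshold: float = 0.15,
) -> pd.DataFrame:
    """Classify fragments as {area-specific, shared} x {rare, common}.

    A fragment's frequency in an area is its presence fraction among the
    area's scored samples; it is *rare* when that frequency lies below the
    threshold in every area where it is present.
    """
    if not 0 < threshold < 1:
        raise ConfigError("rare-fragment threshold must lie in (0, 1)")
    areas = sorted(set(area_of.values()))
    if len(areas) != 2:
        raise GroupingError("rare-fragment classification needs exactly two areas")

    freq = {}
    for a in areas:
        idx = [matrix.index_of(s) for s, ar in area_of.items() if ar == a]
        sub = matrix.band[idx]
        n_scored = (~np.isnan(sub)).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[a] = np.where(n_scored > 0, np.nansum(sub, axis=0) / np.maximum(n_scored, 1), 0.0)

    a0, a1 = areas
    p0, p1 = freq[a0] > 0, freq[a1] > 0
    specificity = np.where(
        p0 & p1, "shared", np.where(p0, f"{a0}_specific", np.where(p1, f"{a1}_specific", "absent"))
    )
    rare = np.zeros(matrix.n_loci, dtype=bool)
    present = p0 | p1
    below0 = ~p0 | (freq[a0] < threshold)
    below1 = ~p1 | (freq[a1] < threshold)
    rare[present] = (below0 & below1)[present]

    return pd.DataFrame(
        {
            "locus_id": matrix.locus_ids,
            f"freq_{a0}": freq[a0],
            f"freq_{a1}": freq[a1],
            "specificity": specificity,
            "rare": rare,
        }
    )


def gene_diversity_hj(
    matrix: MarkerMatrix,
    sample_ids: list[str],
    n_boot: int = 1000,
    seed: int | None = None,
    allele_freq: bool = False,
) -> tuple[float, float, float]:
    """Nei's gene diversity Hj for a sample set, with bootstrap SD/Var.

    Per locus the unbiased two-state diversity is
    ``h = n/(n-1) * (1 - p**2 - q**2)`` with ``p`` the band-presence
    fraction among the ``n`` scored members and ``q = 1 - p`` (note the
    small-sample correction can push ``h`` above 0.5 at tiny ``n``).
    ``Hj`` is the mean over loci; SD and Var come from a seeded bootstrap
    over loci.  With ``allele_freq=True`` the pure-recessive square-root
    transform ``q_allele = sqrt(q)`` replaces the phenotype frequency.
    """
    if len(sample_ids) < 2:
        raise ConfigError("gene diversity needs a group of >= 2 samples")
    sub = matrix.subset(list(sample_ids))
    B = sub.band
    n = (~np.isnan(B)).sum(axis=0).astype(float)
    usable = n >= 2
    if not usable.any():
        raise ConfigError("no locus is scored in >= 2 group members")
    n = n[usable]
    p = np.nansum(B[:, usable], axis=0) / n
    if allele_freq:
        q = np.sqrt(1.0 - p)
        p = 1.0 - q
    q = 1.0 - p
    h = n / (n - 1.0) * (1.0 - p**2 - q**2)

    hj = float(h.mean())
    rng = np.random.default_rng(seed)
    L = len(h)
    boot = rng.integers(0, L, size=(n_boot, L))
    means = h[boot].mean(axis=1)
    sd = float(means.std(ddof=1)) if n_boot > 1 else 0.0
    return hj, sd, sd**2


def diversity_table(
    matrix: MarkerMatrix,
    grouping: dict[str, str],
    n_boot: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Combined per-group fragment classes and gene diversity (one row per
    group, shaped like a population-genetic summary table)."""
    frag = fragment_classes(matrix, grouping).set_index("group")
    rows = []
    for g in frag.index:
        members = [s for s, gr in grouping.items() if str(gr) == g]
        if len(members) >= 2:
            hj, sd, var = gene_diversity_hj(matrix, members, n_boot=n_boot, seed=seed)
        else:
            hj = sd = var = float("nan")
        row = {"group": g, **frag.loc[g].to_dict(), "hj": hj, "hj_sd": sd, "hj_var": var}
        rows.append(row)
    return pd.DataFrame(rows)
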