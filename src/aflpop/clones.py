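"""Replicate-based genotyping error rate and clone calling.

Dominant fingerprints carry no allele dosage, so clonemates are recognised
operationally: two samples are placed in the same clonal lineage when the
fraction of loci at which their band patterns disagree falls *below* the
genotyping error rate estimated from replicate re-extractions.  Lineages
are the single-linkage (connected-component) closure of that relation;
triples violating transitivity are flagged rather than broken.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import ConfigError, MarkerMatrix, SampleFrame


@dataclass(frozen=True)
class ErrorRate:
    """Mismatch error rate from replicate pairs.

    ``rate = n_mismatches / (n_pairs * n_loci)`` — the denominator is the
    full locus count even when some replicate cells are missing; mismatches
    are only counted at loci scored in both members of a pair.
    """

    n_mismatches: int
    n_pairs: int
    n_loci: int

    def __post_init__(self) -> None:
        if self.n_pairs < 1 or self.n_loci < 1:
            raise ConfigError("error rate needs >= 1 replicate pair and >= 1 locus")
        if not 0 <= self.rate <= 1:
            raise ConfigError("error rate outside [0, 1]")

    @property
    def rate(self) -> float:
        return self.n_mismatches / (self.n_pairs * self.n_loci)

    @property
    def percent(self) -> float:
        return 100.0 * self.rate


def replicate_error_rate(
    matrix: MarkerMatrix, pairs: list[tuple[str, str]]
) -> ErrorRate:
    """Estimate the genotyping error rate from replicate pairs.

    ``pairs`` lists (original, replicate) sample ids, both present in
    ``matrix``.  Raises :class:`~aflpop.io.ConfigError` when no pair is
    supplied.
    """
    if not pairs:
        raise ConfigError("at least one replicate pair is required")
    mism = 0
    for a, b in pairs:
        ra, rb = matrix.row(a), matrix.row(b)
        both = ~np.isnan(ra) & ~np.isnan(rb)
        mism += int((ra[both] != rb[both]).sum())
    return ErrorRate(mism, len(pairs), matrix.n_loci)


@dataclass
class MismatchMatrix:
    """Pairwise per-locus mismatch fractions over jointly scored loci."""

    sample_ids: list[str]
    d: np.ndarray
    n_scored: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.sample_ids, columns=self.sample_ids)


def pairwise_mismatch(matrix: MarkerMatrix) -> MismatchMatrix:
    """d(i,j) = (# jointly scored loci with differing bands) / (# jointly
    scored loci).  Pairs with zero jointly scored loci are recorded as NaN
    with a warning and are excluded from clone calling.
    """
    if matrix.n_samples < 2:
        raise ConfigError("pairwise mismatch needs >= 2 samples")
    B = matrix.band
    S = matrix.scored
    both = S[:, None, :] & S[None, :, :]
    with np.errstate(invalid="ignore"):
        neq = (B[:, None, :] != B[None, :, :]) & both
    n_both = both.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(n_both > 0, neq.sum(axis=2) / np.maximum(n_both, 1), np.nan)
    np.fill_diagonal(d, 0.0)
    if (n_both[np.triu_indices_from(n_both, k=1)] == 0).any():
        warnings.warn(
            "some sample pairs share no scored locus; their mismatch is "
            "undefined and excluded from clone calling",
            stacklevel=2,
        )
    return MismatchMatrix(list(matrix.sample_ids), d, n_both)


@dataclass
class ClonePartition:
    """Sample -> clonal-lineage assignment under a mismatch threshold.

    Multi-member lineages are labelled c1, c2, ... in decreasing size order
    (ties broken by smallest member id); singletons keep their sample id as
    lineage id.  ``flagged_triples`` lists (a, b, c) where a-b and b-c are
    clone edges but a-c is not.
    """

    assignment: dict[str, str]
    threshold: float
    flagged_triples: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def lineage_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for lin in self.assignment.values():
            sizes[lin] = sizes.get(lin, 0) + 1
        return sizes

    def members(self, lineage: str) -> list[str]:
        return sorted(s for s, l in self.assignment.items() if l == lineage)

    def multi_member_lineages(self) -> list[str]:
        return sorted(
            (l for l, n in self.lineage_sizes.items() if n > 1),
            key=lambda l: (-self.lineage_sizes[l], min(self.members(l))),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sample_id": s, "lineage": l, "clonal": self.lineage_sizes[l] > 1}
            for s, l in sorted(self.assignment.items())
        ]
        return pd.DataFrame(rows)


def call_clones(mismatch: MismatchMatrix, error: ErrorRate | float) -> ClonePartition:
    """Partition samples into clonal lineages.

    An edge joins samples with ``d(i, j) < threshold`` (strict); lineages
    are the connected components of that graph, so clonehood is closed
    transitively even when an individual far pair sits above the threshold
    (such triples are flagged).
    """
    thr = error.rate if isinstance(error, ErrorRate) else float(error)
    ids = mismatch.sample_ids
    d = mismatch.d
    g = nx.Graph()
    g.add_nodes_from(ids)
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if not np.isnan(d[i, j]) and d[i, j] < thr:
                g.add_edge(ids[i], ids[j])

    components = [sorted(c) for c in nx.connected_components(g)]
    multi = sorted(
        (c for c in components if len(c) > 1), key=lambda c: (-len(c), c[0])
    )
    assignment: dict[str, str] = {}
    for k, comp in enumerate(multi, start=1):
        for s in comp:
            assignment[s] = f"c{k}"
    for comp in components:
        if len(comp) == 1:
            assignment[comp[0]] = comp[0]

    idx = {s: i for i, s in enumerate(ids)}
    flagged = []
    for comp in multi:
        for a_i, a in enumerate(comp):
            for c in comp[a_i + 1 :]:
                dac = d[idx[a], idx[c]]
                if np.isnan(dac) or dac < thr:
                    continue
                for b in comp:
                    if b in (a, c):
                        continue
                    dab = d[idx[a], idx[b]]
                    dbc = d[idx[b], idx[c]]
                    if (
                        not np.isnan(dab)
                        and dab < thr
                        and not np.isnan(dbc)
                        and dbc < thr
                    ):
                        flagged.append((a, b, c))
                        break
    return ClonePartition(assignment, thr, flagged)


def clonal_fraction(n_clonal: int, n_samples: int) -> float:
    """Fraction of samples that belong to multi-member lineages."""
    if n_samples < 1:
        raise ConfigError("clonal fraction needs >= 1 sample")
    return n_clonal / n_samples


def clonal_stats(
    partition: ClonePartition, samples: SampleFrame
) -> pd.DataFrame:
    """Per-population, per-area and overall clonality summary.

    ``n_clonal`` counts members of multi-member lineages (a lineage spanning
    several populations contributes members to each but is counted once in
    the global number of distinct lineages).
    """
    meta = samples.data.set_index("sample_id")
    unknown = [s for s in partition.assignment if s not in meta.index]
    if unknown:
        raise LookupError(f"sample {unknown[0]!r} missing from sample table")

    sizes = partition.lineage_sizes
    rows = []

    def _summarise(label_type: str, label: str, members: list[str]) -> dict:
        lineages = {partition.assignment[s] for s in members}
        clonal = [s for s in members if sizes[partition.assignment[s]] > 1]
        return {
            "level": label_type,
            "group": label,
            "n_samples": len(members),
            "n_clonal": len(clonal),
            "n_lineages": len(lineages),
            "n_multi_lineages": len(
                {l for l in lineages if sizes[l] > 1}
            ),
            "clonal_fraction": clonal_fraction(len(clonal), len(members))
            if members
            else float("nan"),
        }

    all_samples = sorted(partition.assignment)
    for pop, sub in meta.loc[all_samples].groupby("population", sort=True):
        rows.append(_summarise("population", str(pop), list(sub.index)))
    for area, sub in meta.loc[all_samples].groupby("area", sort=True):
        rows.append(_summarise("area", str(area), list(sub.index)))
    rows.append(_summarise("all", "all", all_samples))
    return pd.DataFrame(rows)
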