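"""Crossing-group inference from crossing outcomes.

In an obligate self-incompatible species, two populations that never set a
single seed when crossed with each other are inferred to share the same
S-alleles and belong to one *crossing group*.  Groups are therefore the
connected components of the incompatibility graph (an edge wherever a
tested pair produced no seeds).  Capsules without seeds do not confer
compatibility.  Mate availability is the fraction of grouped population
pairs lying in different groups.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .io import ConfigError, CrossTable

COMPATIBLE = "compatible"
INCOMPATIBLE = "incompatible"
UNTESTED = "untested"
UNKNOWN = "unknown"


def classify_cross(
    records: pd.DataFrame, min_flowers: int = 1
) -> str:
    """Outcome of one unordered population pair, reciprocal records pooled.

    compatible — total seeds > 0; incompatible — tested (>= ``min_flowers``
    flowers) with zero seeds; untested otherwise.
    """
    if len(records) == 0:
        return UNTESTED
    seeds = int(records["n_seeds"].sum())
    flowers = int(records["n_flowers"].sum())
    if seeds > 0:
        return COMPATIBLE
    if flowers >= min_flowers:
        return INCOMPATIBLE
    return UNTESTED


def pair_outcomes(
    table: CrossTable, min_flowers: int = 1, pooled: bool = True
) -> pd.DataFrame:
    """Classify every population pair appearing in the crossing table.

    With ``pooled=True`` (the default, matching the absence of a paternal
    effect) reciprocal directions are merged on the unordered pair; with
    ``pooled=False`` each direction is reported separately.
    """
    df = table.data
    rows = []
    if pooled:
        key = df.apply(
            lambda r: tuple(sorted((str(r.mother_population), str(r.father_population)))),
            axis=1,
        )
        for (a, b), sub in df.groupby(key):
            rows.append(
                {
                    "pop_a": a,
                    "pop_b": b,
                    "n_flowers": int(sub["n_flowers"].sum()),
                    "n_capsules": int(sub["n_capsules"].sum()),
                    "n_seeds": int(sub["n_seeds"].sum()),
                    "outcome": classify_cross(sub, min_flowers),
                    "intra_population": a == b,
                }
            )
    else:
        for (a, b), sub in df.groupby(["mother_population", "father_population"]):
            rows.append(
                {
                    "pop_a": str(a),
                    "pop_b": str(b),
                    "n_flowers": int(sub["n_flowers"].sum()),
                    "n_capsules": int(sub["n_capsules"].sum()),
                    "n_seeds": int(sub["n_seeds"].sum()),
                    "outcome": classify_cross(sub, min_flowers),
                    "intra_population": str(a) == str(b),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class CrossingGroupPartition:
    """Population -> crossing-group assignment.

    Populations without any flowering record stay ``unknown``; every group
    merge is backed by at least one incompatible cross.  ``conflicts``
    lists compatible pairs that fall inside one group (outcomes
    contradicting a shared-S-allele interpretation);
    ``self_incompatible_confirmed`` lists populations whose
    intra-population crossings set no seed.
    """

    assignment: dict[str, str]  # group id or UNKNOWN
    conflicts: list[tuple[str, str]] = field(default_factory=list)
    self_incompatible_confirmed: list[str] = field(default_factory=list)

    @property
    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for g in self.assignment.values():
            if g != UNKNOWN:
                sizes[g] = sizes.get(g, 0) + 1
        return sizes

    def grouped(self) -> list[str]:
        return sorted(p for p, g in self.assignment.items() if g != UNKNOWN)

    def members(self, group: str) -> list[str]:
        return sorted(p for p, g in self.assignment.items() if g == group)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"population": p, "crossing_group": g} for p, g in sorted(self.assignment.items())]
        )


def infer_crossing_groups(
    table: CrossTable,
    populations: list[str] | None = None,
    min_flowers: int = 1,
) -> CrossingGroupPartition:
    """Partition populations into crossing groups.

    ``populations`` may list extra populations beyond those in the table
    (e.g. ones that never flowered); they are assigned ``unknown``.
    Group ids are g1, g2, ... in decreasing size order (ties by smallest
    member name).
    """
    outcomes = pair_outcomes(table, min_flowers=min_flowers, pooled=True)
    pops = set(populations or [])
    flowering = set()
    for r in outcomes.itertuples():
        pops.update((r.pop_a, r.pop_b))
        if r.n_flowers >= 1:
            flowering.update((r.pop_a, r.pop_b))

    inter = outcomes[~outcomes["intra_population"]]
    g = nx.Graph()
    g.add_nodes_from(sorted(flowering))
    for r in inter.itertuples():
        if r.outcome == INCOMPATIBLE:
            g.add_edge(r.pop_a, r.pop_b)

    components = sorted(
        (sorted(c) for c in nx.connected_components(g)),
        key=lambda c: (-len(c), c[0]),
    )
    assignment = {p: UNKNOWN for p in sorted(pops)}
    comp_of: dict[str, int] = {}
    for k, comp in enumerate(components, start=1):
        for p in comp:
            assignment[p] = f"g{k}"
            comp_of[p] = k

    conflicts = [
        (r.pop_a, r.pop_b)
        for r in inter.itertuples()
        if r.outcome == COMPATIBLE
        and comp_of.get(r.pop_a) is not None
        and comp_of.get(r.pop_a) == comp_of.get(r.pop_b)
    ]
    selfed = sorted(
        r.pop_a
        for r in outcomes[outcomes["intra_population"]].itertuples()
        if r.outcome == INCOMPATIBLE
    )
    return CrossingGroupPartition(assignment, conflicts, selfed)


def mate_availability(partition: CrossingGroupPartition) -> float:
    """Fraction of unordered pairs of grouped populations whose members lie
    in different crossing groups (``unknown`` populations excluded)."""
    grouped = partition.grouped()
    n = len(grouped)
    if n < 2:
        raise ConfigError("mate availability needs >= 2 grouped populations")
    total = n * (n - 1) // 2
    within = sum(s * (s - 1) // 2 for s in partition.group_sizes.values())
    return (total - within) / total
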