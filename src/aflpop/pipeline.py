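"""End-to-end orchestration: run every stage of the analysis on one set of
input tables and collect the results in a run summary.

This is the glue behind the ``report`` subcommand and the reproduction
script; each stage simply calls the public API of the corresponding
module.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import amova as amova_mod
from . import clones, crossing, diversity, ordination, traits as traits_mod
from .io import CrossTable, MarkerMatrix, SampleFrame, TraitTable


def primary_matrix(marker: MarkerMatrix, samples: SampleFrame) -> MarkerMatrix:
    """Drop replicate re-scorings, keeping one row per individual."""
    primary_ids = [
        s for s in marker.sample_ids if s in set(samples.primary()["sample_id"])
    ]
    return marker.subset(primary_ids)


def population_summary_table(
    marker: MarkerMatrix,
    samples: SampleFrame,
    partition: clones.ClonePartition,
    traits: TraitTable,
    n_boot: int = 200,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-population genetic indices and trait summaries, the input of the
    trait-diversity correlation suite."""
    pop_of = samples.grouping("population", marker.sample_ids)
    div = diversity.diversity_table(marker, pop_of, n_boot=n_boot, seed=seed)
    div = div.set_index("group")

    cl = clones.clonal_stats(partition, samples)
    cl_pop = cl[cl["level"] == "population"].set_index("group")

    buds = traits_mod.bud_summaries(traits)
    flowers = traits.flowers
    out_rows = []
    for pop in div.index:
        row = {
            "population": pop,
            "frag_polymorphic": div.loc[pop, "frag_polymorphic"],
            "frag_fixed": div.loc[pop, "frag_fixed"],
            "frag_private": div.loc[pop, "frag_private"],
            "hj": div.loc[pop, "hj"],
        }
        if pop in cl_pop.index:
            row["clonal_fraction"] = cl_pop.loc[pop, "clonal_fraction"]
            row["nonclonal_fraction"] = 1.0 - row["clonal_fraction"]
        if len(buds):
            sub = buds[buds["population"] == pop]
            if len(sub):
                row["pollen_per_flower"] = float(sub["pollen_per_flower"].mean())
                row["ovules_per_flower"] = float(sub["ovule_count"].mean())
                row["pollen_ovule_ratio"] = float(sub["pollen_ovule_ratio"].mean())
        if len(flowers):
            sub = flowers[flowers["population"] == pop]
            if len(sub):
                mut = sub["flower_class"].str.startswith("mutant").sum()
                row["mutant_fraction"] = traits_mod.mutant_fraction(int(mut), len(sub))
        out_rows.append(row)
    return pd.DataFrame(out_rows).set_index("population")


def run_full_analysis(
    marker: MarkerMatrix,
    samples: SampleFrame,
    crosses: CrossTable,
    traits: TraitTable,
    populations: list[str] | None = None,
    n_perm: int = 999,
    n_boot: int = 200,
    seed: int | None = None,
) -> dict:
    """Run every pipeline stage; returns a dict of result tables plus a
    flat ``summary`` of headline quantities."""
    out: dict = {}
    summary: dict = {}
    rng = np.random.default_rng(seed)

    # genotyping error and clone calling (on primary samples only)
    pairs = samples.replicate_pairs()
    prim = primary_matrix(marker, samples)
    if pairs:
        err = clones.replicate_error_rate(marker, pairs)
        summary["replicate_error_rate_pct"] = err.percent
        mism = clones.pairwise_mismatch(prim)
        partition = clones.call_clones(mism, err)
        out["clone_partition"] = partition
        cstats = clones.clonal_stats(partition, samples)
        out["clonal_stats"] = cstats
        intro = cstats[(cstats["level"] == "area") & (cstats["group"] == "introduced")]
        if len(intro):
            summary["clonal_fraction_introduced_pct"] = float(
                100.0 * intro["clonal_fraction"].iloc[0]
            )
        summary["n_multi_member_lineages"] = len(partition.multi_member_lineages())
    else:
        partition = None

    # diversity
    pop_of = samples.grouping("population", prim.sample_ids)
    area_of = samples.grouping("area", prim.sample_ids)
    out["diversity_population"] = diversity.diversity_table(
        prim, pop_of, n_boot=n_boot, seed=int(rng.integers(2**31))
    )
    out["diversity_area"] = diversity.diversity_table(
        prim, area_of, n_boot=n_boot, seed=int(rng.integers(2**31))
    )
    whole = diversity.fragment_classes(prim, {s: "all" for s in prim.sample_ids})
    summary["pct_polymorphic"] = float(whole["pct_polymorphic"].iloc[0])
    summary["n_polymorphic"] = int(whole["frag_polymorphic"].iloc[0])
    rare = diversity.rare_fragments(prim, area_of)
    native_specific = rare[rare["specificity"] == "native_specific"]
    if len(native_specific):
        summary["native_specific_rare_pct"] = float(
            100.0 * native_specific["rare"].mean()
        )
    out["rare_fragments"] = rare

    # ordination
    gen_d = ordination.nei_li_distance(prim)
    out["nei_li"] = gen_d
    if not np.isnan(gen_d.condensed()).any():
        pc = ordination.pcoa(gen_d)
        out["pcoa"] = pc
        k = min(3, pc.coordinates.shape[1])
        summary["pcoa_first3_pct"] = float(pc.percent_variance[:k].sum())
        out["pcoa_area_test"] = ordination.axis_group_test(pc, area_of)

    # AMOVA
    am_area = amova_mod.amova_permutation(
        prim, area_of, n_perm=n_perm, seed=int(rng.integers(2**31))
    )
    out["amova_area"] = am_area
    summary["amova_among_area_pct"] = float(
        am_area.rows.loc[am_area.rows["source"] == "among_groups", "pct_variance"].iloc[0]
    )
    summary["phi_st_area"] = am_area.phi_st
    summary["amova_area_p"] = am_area.p_values.get("phi_st", float("nan"))

    intro_ids = [s for s in prim.sample_ids if area_of.get(s) == "introduced"]
    intro_pop_of = {s: pop_of[s] for s in intro_ids}
    if len(set(intro_pop_of.values())) >= 2:
        am_pop = amova_mod.amova(prim.subset(intro_ids), intro_pop_of)
        out["amova_introduced_population"] = am_pop
        summary["amova_among_introduced_pop_pct"] = float(
            am_pop.rows.loc[am_pop.rows["source"] == "among_groups", "pct_variance"].iloc[0]
        )
        summary["phi_st_introduced_population"] = am_pop.phi_st

    # crossing groups
    if len(crosses):
        part = crossing.infer_crossing_groups(crosses, populations=populations)
        out["crossing_groups"] = part
        sizes = sorted(part.group_sizes.values(), reverse=True)
        summary["n_crossing_groups"] = len(sizes)
        summary["largest_crossing_group"] = sizes[0] if sizes else 0
        summary["n_ungrouped_populations"] = sum(
            1 for g in part.assignment.values() if g == crossing.UNKNOWN
        )
        if len(part.grouped()) >= 2:
            summary["mate_availability"] = crossing.mate_availability(part)

    # traits
    if partition is not None:
        pop_table = population_summary_table(
            prim, samples, partition, traits, n_boot=n_boot,
            seed=int(rng.integers(2**31)),
        )
        out["population_table"] = pop_table
        suite = traits_mod.correlation_suite(pop_table)
        out["correlation_suite"] = suite
        if len(suite):
            for r in suite.itertuples():
                summary[f"spearman_{r.x}_vs_{r.y}"] = float(r.r)
        if "mutant_fraction" in pop_table.columns:
            pop_area = samples.primary().groupby("population")["area"].first()
            mf = pop_table["mutant_fraction"].dropna()
            intro_mf = mf[pop_area.reindex(mf.index) == "introduced"]
            native_mf = mf[pop_area.reindex(mf.index) == "native"]
            if len(intro_mf):
                summary["mutant_flower_pct_introduced"] = float(100 * intro_mf.mean())
            if len(native_mf):
                summary["mutant_flower_pct_native"] = float(100 * native_mf.mean())
        if "pollen_per_flower" in pop_table.columns:
            pop_area = samples.primary().groupby("population")["area"].first()
            pp = pop_table["pollen_per_flower"].dropna()
            for ar in ("introduced", "native"):
                vals = pp[pop_area.reindex(pp.index) == ar]
                if len(vals):
                    summary[f"pollen_per_flower_{ar}"] = float(vals.mean())

    seed_sum = traits_mod.seed_summaries(
        traits, grouping=samples.primary().groupby("population")["area"].first().to_dict()
    )
    out["seed_summary_area"] = seed_sum
    for r in seed_sum.itertuples():
        if getattr(r, "n_viability_tested", 0):
            summary[f"seed_viable_fraction_{r.group}"] = float(r.viable_fraction)
        if getattr(r, "n_germination_tested", 0):
            summary[f"germination_fraction_{r.group}"] = float(r.germination_fraction)

    # isolation by distance within the introduced area
    coords = samples.population_coordinates()
    intro_pops = sorted(set(intro_pop_of.values()))
    coords_intro = coords.loc[[p for p in intro_pops if p in coords.index]].dropna()
    if len(coords_intro) >= 4:
        geo = ordination.geographic_distance_matrix(coords_intro)
        pop_gen = ordination.population_distance_matrix(
            gen_d, {s: p for s, p in intro_pop_of.items()}
        )
        keep = [p for p in geo.ids if p in pop_gen.ids]
        idx = [pop_gen.ids.index(p) for p in keep]
        pop_gen = ordination.DistanceMatrix(
            keep, pop_gen.values[np.ix_(idx, idx)], pop_gen.metric
        )
        geo_idx = [geo.ids.index(p) for p in keep]
        geo = ordination.DistanceMatrix(
            keep, geo.values[np.ix_(geo_idx, geo_idx)], "geographic"
        )
        ibd = traits_mod.geo_genetic_correlation(
            geo, pop_gen, n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        out["isolation_by_distance"] = ibd
        summary["geo_genetic_spearman_r"] = ibd.r
        summary["geo_genetic_p"] = ibd.p_value
        summary["geo_genetic_n_pairs"] = ibd.n

    out["summary"] = summary
    return out
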