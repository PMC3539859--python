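"""Forward simulator of self-incompatible clonal colonization.

The generator emulates the data streams of a clonality study on an
introduced, obligately outcrossing creeping plant: a handful of genetically
divergent introductions found populations along a transect; populations
propagate clonally, accumulating somatic band flips and a latent
deleterious mutation load; every sample is scored for dominant markers
with per-locus error, replicate re-extractions carry extra noise; crossing
outcomes between populations follow the S-locus rule (identical unordered
S-genotype => no seeds, any allele difference => seeds); and reproductive
traits (pollen per flower, androecium-mutant frequency, ovule count, seed
width/viability/germination) decay with the accumulated load — a
phenotypic Muller's ratchet.

Every downstream stage of the pipeline can be validated against the
emitted ground truth: founder lineages, S-genotypes, crossing groups and
per-sample loads.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (
    ALIQUOT_COLS,
    ConfigError,
    CrossTable,
    MarkerMatrix,
    SampleFrame,
    TraitTable,
)


@dataclass
class PopulationSpec:
    """One population of the scenario: where it sits, how many samples are
    scored, which founder lineages seed it, and its crossing behaviour.

    ``crossing_group`` names the planted S-compatibility class; ``None``
    marks a population that never flowers (it enters no crossing record and
    must be recovered as "unknown").  ``lineages`` maps multi-member
    lineage name -> number of members sampled here; remaining samples are
    unique founder genotypes (singletons).  ``generations`` is the clonal
    age driving somatic divergence and mutation load.
    """

    name: str
    area: str  # native | introduced
    region: str
    n_samples: int
    latitude: float
    longitude: float
    introduction: str  # founder-pool (band-profile) key
    crossing_group: str | None = None
    lineages: dict[str, int] = field(default_factory=dict)
    generations: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ConfigError(f"population {self.name}: n_samples must be >= 1")
        if sum(self.lineages.values()) > self.n_samples:
            raise ConfigError(
                f"population {self.name}: lineage members exceed n_samples"
            )


@dataclass
class SimConfig:
    """Full parameterization of the synthetic colonization scenario.

    Rates are per locus; the scoring error applies to every scoring event,
    while ``replicate_extra_error`` is an additional flip rate applied only
    to replicate re-extractions (re-extraction noise dominates the
    replicate-based error estimate, leaving ordinary sample-to-sample
    comparisons cleaner than the threshold — the regime in which
    threshold-based clone calling works).
    """

    populations: list[PopulationSpec] | None = None
    n_loci: int = 294
    n_fixed_loci: int = 4
    n_native_only: int = 45
    n_native_only_rare: int = 40
    n_s_alleles: int = 12
    founder_divergence: float = 0.08
    somatic_rate: float = 0.0004
    scoring_error: float = 0.002
    replicate_extra_error: float = 0.0425
    missing_rate: float = 0.005
    n_replicate_pairs: int = 9
    load_per_generation: float = 0.4
    # trait models
    pollen_baseline: float = 13000.0
    pollen_load_decay: float = 0.08
    mutant_intercept: float = -4.2
    mutant_slope: float = 0.45
    ovule_mean: float = 10.0
    dead_intercept: float = -1.8
    dead_slope: float = 0.25
    abnormal_ratio: float = 0.5
    germ_intercept: float = 2.2
    germ_slope: float = 0.35
    seed_width_mm: float = 0.55
    seed_width_load_decay: float = 0.015
    seed_width_sd: float = 0.05
    seeds_per_capsule_mean: float = 5.0
    flowers_per_cross: int = 5
    n_flowers_observed: int = 80
    n_buds_per_population: int = 10
    dilution: float = 1000.0
    self_cross_populations: list[str] = field(default_factory=list)
    seed_cross_populations: list[str] = field(default_factory=list)
    n_field_capsules_per_native_pop: int = 10
    n_capsules_per_seed_cross: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "somatic_rate",
            "scoring_error",
            "replicate_extra_error",
            "missing_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]; got {v}")
        if self.n_loci < 1:
            raise ConfigError("n_loci must be >= 1")
        if self.n_fixed_loci + self.n_native_only > self.n_loci:
            raise ConfigError("fixed + native-only loci exceed n_loci")
        if self.populations is not None:
            groups = {
                p.crossing_group
                for p in self.populations
                if p.area == "introduced" and p.crossing_group is not None
            }
            max_pairs = self.n_s_alleles * (self.n_s_alleles - 1) // 2
            if len(groups) > max_pairs:
                raise ConfigError(
                    f"{len(groups)} distinct crossing groups requested but only "
                    f"{max_pairs} S-genotype combinations are available"
                )


@dataclass
class GroundTruth:
    """Planted truth: per-sample origins and loads, per-population
    crossing groups."""

    samples: pd.DataFrame  # sample_id, population, area, introduction,
    #                         lineage, s_allele_1, s_allele_2, load
    populations: pd.DataFrame  # population, area, region, crossing_group, ...
    genotypes: MarkerMatrix | None = None  # noise-free true band genotypes

    @property
    def lineage_of(self) -> dict[str, str]:
        return dict(zip(self.samples["sample_id"], self.samples["lineage"]))

    @property
    def crossing_group_of(self) -> dict[str, str | None]:
        return dict(
            zip(self.populations["population"], self.populations["crossing_group"])
        )

    def clonal_fraction(self, area: str | None = None) -> float:
        df = self.samples
        if area is not None:
            df = df[df["area"] == area]
        sizes = df["lineage"].value_counts()
        clonal = df["lineage"].map(sizes) > 1
        return float(clonal.mean())


@dataclass
class SimResult:
    marker: MarkerMatrix
    samples: SampleFrame
    crosses: CrossTable
    traits: TraitTable
    truth: GroundTruth
    config: SimConfig


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _locus_blocks(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic split of locus indices into fixed / native-only /
    variable blocks."""
    idx = np.arange(cfg.n_loci)
    fixed = idx[: cfg.n_fixed_loci]
    native_only = idx[cfg.n_fixed_loci : cfg.n_fixed_loci + cfg.n_native_only]
    variable = idx[cfg.n_fixed_loci + cfg.n_native_only :]
    return fixed, native_only, variable


def _band_profiles(
    cfg: SimConfig, pops: list[PopulationSpec], rng: np.random.Generator
) -> dict[str, tuple[str, np.ndarray]]:
    """Founder pools per introduction / native region over the variable
    loci.

    Native pools are band-presence probability vectors (diverse source
    populations).  Each introduced pool is a bottleneck: a single ancestor
    band genotype from which every founder diverges by a fixed flip rate —
    so founders of one introduction share most of their bands, the way a
    handful of closely related imported plants would.
    """
    _, _, variable = _locus_blocks(cfg)
    n_var = len(variable)
    intro_keys = sorted({p.introduction for p in pops if p.area == "introduced"})
    native_keys = sorted({p.introduction for p in pops if p.area == "native"})
    profiles: dict[str, tuple[str, np.ndarray]] = {}
    # the floor keeps variable fragments segregating in the introduced pool,
    # so that area-specific fragments are (almost) only the planted ones
    intro_base = np.clip(rng.beta(0.35, 1.4, size=n_var), 0.06, 1.0)
    for k in intro_keys:
        ancestor = (rng.random(n_var) < intro_base).astype(float)
        profiles[k] = ("ancestor", ancestor)
    native_base = rng.beta(0.8, 1.2, size=n_var)
    for k in native_keys:
        freqs = np.clip(native_base + rng.normal(0.0, 0.10, size=n_var), 0.0, 1.0)
        profiles[k] = ("freq", freqs)
    return profiles


def _draw_founder(
    cfg: SimConfig,
    profile: tuple[str, np.ndarray],
    fixed: np.ndarray,
    variable: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One founder band genotype over all loci."""
    kind, vec = profile
    g = np.zeros(cfg.n_loci)
    g[fixed] = 1.0
    if kind == "ancestor":
        bands = vec.copy()
        flips = rng.random(len(vec)) < cfg.founder_divergence
        bands[flips] = 1.0 - bands[flips]
        g[variable] = bands
    else:
        g[variable] = (rng.random(len(vec)) < vec).astype(float)
    return g


def _assign_s_genotypes(
    cfg: SimConfig, pops: list[PopulationSpec]
) -> dict[str, tuple[int, int]]:
    """One distinct unordered S-allele pair per planted crossing group."""
    groups = sorted(
        {
            p.crossing_group
            for p in pops
            if p.area == "introduced" and p.crossing_group is not None
        }
    )
    pairs = list(itertools.combinations(range(cfg.n_s_alleles), 2))
    if len(groups) > len(pairs):
        raise ConfigError("not enough S-genotype combinations for the crossing groups")
    return {g: pairs[i] for i, g in enumerate(groups)}


def simulate_dataset(cfg: SimConfig, seed: int | None = None) -> SimResult:
    """Run the forward scenario; identical config + seed gives
    byte-identical outputs."""
    if cfg.populations is None:
        raise ConfigError(
            "config carries no population layout; use default_study_scenario() "
            "or supply PopulationSpec entries"
        )
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    pops = cfg.populations
    fixed, native_only, variable = _locus_blocks(cfg)
    profiles = _band_profiles(cfg, pops, rng)
    s_of_group = _assign_s_genotypes(cfg, pops)

    # --- founder genotypes ------------------------------------------------
    lineage_founder: dict[str, np.ndarray] = {}
    lineage_intro: dict[str, str] = {}
    for p in pops:
        for lin in p.lineages:
            if lin not in lineage_founder:
                lineage_founder[lin] = _draw_founder(
                    cfg, profiles[p.introduction], fixed, variable, rng
                )
                lineage_intro[lin] = p.introduction

    # --- true per-sample genotypes, lineages, loads -----------------------
    sample_rows = []
    genotypes = []
    native_sample_slots: list[int] = []
    row = 0
    for p in pops:
        members: list[str | None] = []
        for lin, k in sorted(p.lineages.items()):
            members.extend([lin] * k)
        members.extend([None] * (p.n_samples - len(members)))
        s_pair = (
            s_of_group[p.crossing_group] if p.crossing_group is not None else None
        )
        for k, lin in enumerate(members, start=1):
            sid = f"{p.name}-{k}"
            if lin is None:
                g = _draw_founder(cfg, profiles[p.introduction], fixed, variable, rng)
                lineage = sid  # unique founder genotype: its own lineage
            else:
                g = lineage_founder[lin].copy()
                lineage = lin
            # somatic flips accumulated over the population's clonal age
            flip_p = min(p.generations * cfg.somatic_rate, 0.5)
            if flip_p > 0:
                flips = rng.random(cfg.n_loci) < flip_p
                g[flips] = 1.0 - g[flips]
            load = int(rng.poisson(p.generations * cfg.load_per_generation))
            sample_rows.append(
                {
                    "sample_id": sid,
                    "population": p.name,
                    "area": p.area,
                    "region": p.region,
                    "introduction": p.introduction,
                    "lineage": lineage,
                    "s_allele_1": s_pair[0] if s_pair else -1,
                    "s_allele_2": s_pair[1] if s_pair else -1,
                    "load": load,
                    "generations": p.generations,
                }
            )
            genotypes.append(g)
            if p.area == "native":
                native_sample_slots.append(row)
            row += 1
    genotypes = np.array(genotypes)
    n_primary = len(sample_rows)

    # --- native-only fragments (planted frequency pattern) ----------------
    if len(native_sample_slots) >= 2 and len(native_only):
        n_nat = len(native_sample_slots)
        for j, locus in enumerate(native_only):
            if j < cfg.n_native_only_rare:
                carriers = rng.choice(n_nat, size=int(rng.integers(1, 3)), replace=False)
            else:
                hi = max(3, int(0.5 * n_nat))
                carriers = rng.choice(
                    n_nat, size=int(rng.integers(3, hi + 1)), replace=False
                )
            genotypes[np.array(native_sample_slots)[carriers], locus] = 1.0

    truth_samples = pd.DataFrame(sample_rows)

    # --- scoring (primary + replicate re-extractions) ---------------------
    def _score(true_rows: np.ndarray, error: float) -> np.ndarray:
        scored = true_rows.copy()
        flips = rng.random(scored.shape) < error
        scored[flips] = 1.0 - scored[flips]
        if cfg.missing_rate > 0:
            miss = rng.random(scored.shape) < cfg.missing_rate
            # keep every row with at least one scored locus
            full = miss.all(axis=1)
            miss[full, 0] = False
            scored[miss] = np.nan
        return scored

    observed = _score(genotypes, cfg.scoring_error)

    n_rep = min(cfg.n_replicate_pairs, n_primary)
    rep_slots = np.sort(rng.choice(n_primary, size=n_rep, replace=False))
    rep_rows = _score(
        genotypes[rep_slots], cfg.scoring_error + cfg.replicate_extra_error
    )

    sample_ids = list(truth_samples["sample_id"])
    rep_ids = [f"{sample_ids[i]}.r" for i in rep_slots]
    marker = MarkerMatrix(
        sample_ids + rep_ids,
        [f"L{k+1}" for k in range(cfg.n_loci)],
        np.vstack([observed, rep_rows]) if n_rep else observed,
    )

    # --- sample metadata ---------------------------------------------------
    coord_of = {p.name: (p.latitude, p.longitude) for p in pops}
    meta_rows = []
    for r in truth_samples.itertuples():
        lat, lon = coord_of[r.population]
        meta_rows.append(
            {
                "sample_id": r.sample_id,
                "population": r.population,
                "region": r.region,
                "area": r.area,
                "latitude": lat,
                "longitude": lon,
                "replicate_of": np.nan,
                "external_cluster": r.introduction,
            }
        )
    for i, rid in zip(rep_slots, rep_ids):
        base = meta_rows[i]
        meta_rows.append({**base, "sample_id": rid, "replicate_of": base["sample_id"]})
    samples = SampleFrame(pd.DataFrame(meta_rows))

    # --- crossing records --------------------------------------------------
    flowering = [
        p for p in pops if p.area == "introduced" and p.crossing_group is not None
    ]
    cross_rows = []

    def _cross_record(mother: PopulationSpec, father: PopulationSpec) -> dict:
        compatible = (
            s_of_group[mother.crossing_group] != s_of_group[father.crossing_group]
        )
        flowers = cfg.flowers_per_cross
        if compatible:
            capsules = max(1, int(rng.binomial(flowers, 0.6)))
            seeds = int(
                capsules
                + rng.poisson(max(cfg.seeds_per_capsule_mean - 1.0, 0.0) * capsules)
            )
        else:
            capsules = int(rng.binomial(flowers, 0.15))
            seeds = 0
        return {
            "mother_population": mother.name,
            "father_population": father.name,
            "mother_sample": np.nan,
            "father_sample": np.nan,
            "n_flowers": flowers,
            "n_capsules": capsules,
            "n_seeds": seeds,
        }

    for a, b in itertools.combinations(flowering, 2):
        cross_rows.append(_cross_record(a, b))
        cross_rows.append(_cross_record(b, a))
    for name in cfg.self_cross_populations:
        spec = next((p for p in flowering if p.name == name), None)
        if spec is not None:
            cross_rows.append(
                {
                    "mother_population": name,
                    "father_population": name,
                    "mother_sample": np.nan,
                    "father_sample": np.nan,
                    "n_flowers": 41,
                    "n_capsules": int(rng.binomial(41, 0.1)),
                    "n_seeds": 0,
                }
            )
    crosses = CrossTable(
        pd.DataFrame(
            cross_rows,
            columns=[
                "mother_population",
                "father_population",
                "mother_sample",
                "father_sample",
                "n_flowers",
                "n_capsules",
                "n_seeds",
            ],
        )
    )

    # --- reproductive traits ----------------------------------------------
    load_of = dict(zip(truth_samples["sample_id"], truth_samples["load"]))
    pop_samples = {
        p.name: list(truth_samples[truth_samples["population"] == p.name]["sample_id"])
        for p in pops
    }
    pop_mean_load = truth_samples.groupby("population")["load"].mean().to_dict()

    flower_rows = []
    bud_rows = []
    for p in pops:
        sids = pop_samples[p.name]
        for k in range(cfg.n_flowers_observed):
            sid = sids[k % len(sids)]
            p_mut = _expit(cfg.mutant_intercept + cfg.mutant_slope * load_of[sid])
            mutant = rng.random() < p_mut
            if mutant:
                cls = ["mutant_no_filament", "mutant_one_stamen", "mutant_no_stamen"][
                    int(rng.integers(0, 3))
                ]
            else:
                cls = "normal"
            flower_rows.append(
                {"population": p.name, "sample_id": sid, "flower_class": cls}
            )
        for k in range(cfg.n_buds_per_population):
            sid = sids[k % len(sids)]
            pollen_true = cfg.pollen_baseline * (1.0 - cfg.pollen_load_decay) ** load_of[sid]
            aliquots = rng.poisson(pollen_true / cfg.dilution, size=10)
            bud = {
                "population": p.name,
                "sample_id": sid,
                "ovule_count": max(1, int(rng.poisson(cfg.ovule_mean))),
            }
            bud.update({c: int(v) for c, v in zip(ALIQUOT_COLS, aliquots)})
            bud_rows.append(bud)

    capsule_rows = []
    seed_rows = []
    capsule_counter = itertools.count(1)

    def _emit_capsules(mother: str, father: str | None, n_capsules: int) -> None:
        load = pop_mean_load[mother]
        for _ in range(n_capsules):
            cid = f"cap{next(capsule_counter)}"
            n_seed = max(1, int(rng.poisson(cfg.seeds_per_capsule_mean)))
            capsule_rows.append(
                {
                    "population": mother,
                    "father_population": father if father else np.nan,
                    "capsule_id": cid,
                    "seed_count": n_seed,
                }
            )
            p_dead = _expit(cfg.dead_intercept + cfg.dead_slope * load)
            p_abn = min(cfg.abnormal_ratio * p_dead, 1.0 - p_dead)
            p_germ = _expit(cfg.germ_intercept - cfg.germ_slope * load)
            width_mu = cfg.seed_width_mm * (1.0 - cfg.seed_width_load_decay * load)
            for _ in range(n_seed):
                u = rng.random()
                viability = (
                    "dead" if u < p_dead else "abnormal" if u < p_dead + p_abn else "viable"
                )
                seed_rows.append(
                    {
                        "population": mother,
                        "capsule_id": cid,
                        "width_mm": max(0.05, float(rng.normal(width_mu, cfg.seed_width_sd))),
                        "length_mm": max(
                            0.05, float(rng.normal(width_mu * 1.4, cfg.seed_width_sd))
                        ),
                        "viability": viability,
                        "germination": "germinated"
                        if rng.random() < p_germ
                        else "not_germinated",
                    }
                )

    for p in pops:
        if p.area == "native":
            _emit_capsules(p.name, None, cfg.n_field_capsules_per_native_pop)
    for a, b in itertools.permutations(cfg.seed_cross_populations, 2):
        specs = {p.name: p for p in flowering}
        if a in specs and b in specs:
            if s_of_group[specs[a].crossing_group] != s_of_group[specs[b].crossing_group]:
                _emit_capsules(a, b, cfg.n_capsules_per_seed_cross)

    traits = TraitTable(
        flowers=pd.DataFrame(flower_rows),
        buds=pd.DataFrame(bud_rows),
        capsules=pd.DataFrame(capsule_rows),
        seeds=pd.DataFrame(seed_rows),
    )

    truth_pops = pd.DataFrame(
        [
            {
                "population": p.name,
                "area": p.area,
                "region": p.region,
                "crossing_group": p.crossing_group,
                "introduction": p.introduction,
                "generations": p.generations,
                "mean_load": pop_mean_load[p.name],
            }
            for p in pops
        ]
    )
    true_marker = MarkerMatrix(
        sample_ids, [f"L{k+1}" for k in range(cfg.n_loci)], genotypes
    )
    truth = GroundTruth(truth_samples, truth_pops, true_marker)
    return SimResult(marker, samples, crosses, traits, truth, cfg)


# ---------------------------------------------------------------------------
# The documented colonization scenario
# ---------------------------------------------------------------------------

#: introduced populations: (name, n_samples, crossing group, founder pool,
#: multi-member lineages sampled here, transect position km)
_INTRODUCED = [
    ("Tp", 3, "blue", "introA", {"c2": 2}, 0.0),
    ("Tb", 9, "blue", "introA", {"c3": 5}, 2.0),
    ("Tl", 3, "red", "introB", {}, 4.0),
    ("Kt", 3, "green", "introC", {}, 8.0),
    ("Pl", 7, "blue", "introA", {"c4": 5}, 10.0),
    ("Bz", 4, "green", "introD", {"c1": 2}, 12.0),
    ("Re", 5, "green", "introD", {"c1": 5}, 14.0),
    ("Hw", 5, "green", "introB", {"c5": 4}, 30.0),
    ("Mu", 3, "pink", "introE", {}, 40.0),
    ("Mt", 3, "violet", "introE", {}, 45.0),
    ("Bl", 4, "green", "introD", {"c1": 3}, 55.0),
    ("U", 5, "green", "introD", {"c6": 4}, 70.0),
    ("Wi", 10, "green", "introD", {"c1": 4, "c7": 5}, 75.0),
    ("Il", 4, "green", "introD", {"c1": 2, "c9": 2}, 85.0),
    ("Gu", 4, "green", "introD", {"c1": 2}, 95.0),
    ("Bg", 4, "green", "introD", {"c1": 2}, 105.0),
    ("Zi", 3, "green", "introD", {"c1": 3}, 120.0),
    ("Gss", 6, None, "introD", {"c8": 2, "c10": 2}, 135.0),
    ("We", 4, "green", "introC", {}, 142.0),
    ("A", 4, "green", "introC", {}, 150.0),
]

_NATIVE = [
    ("UzT", 4, "Turkey-East", 40.62, 39.65),
    ("Kz9", 5, "Georgia-North", 42.66, 44.62),
    ("Bk10", 6, "Georgia-Central", 41.75, 43.50),
]


def default_study_scenario(seed: int = 0) -> SimConfig:
    """The documented scenario at the study's scale.

    Twenty introduced populations along a ~150 km transect (93 samples)
    plus three native populations (15 samples), 294 loci, nine replicate
    pairs, five planted crossing groups of sizes 13/3/1/1/1 with one
    additional population that never flowers, ten planted multi-member
    clonal lineages covering 54 of the 93 introduced samples (one of them
    spanning eight populations), and clonal ages that couple mutation load
    to clonality so the ratchet correlations are planted with the signs
    the analysis should recover.
    """
    pops: list[PopulationSpec] = []
    for name, n, group, intro, lineages, km in _INTRODUCED:
        clonal = sum(lineages.values()) / n
        pops.append(
            PopulationSpec(
                name=name,
                area="introduced",
                region="Germany-transect",
                n_samples=n,
                latitude=48.50 + 0.02 * math.sin(km / 17.0),
                longitude=9.05 + 1.85 * km / 150.0,
                introduction=intro,
                crossing_group=group,
                lineages=dict(lineages),
                generations=4 + round(10 * clonal),
            )
        )
    for name, n, region, lat, lon in _NATIVE:
        pops.append(
            PopulationSpec(
                name=name,
                area="native",
                region=region,
                n_samples=n,
                latitude=lat,
                longitude=lon,
                introduction=f"native_{region}",
                crossing_group=None,
                lineages={},
                generations=0,
            )
        )
    return SimConfig(
        populations=pops,
        self_cross_populations=["Pl"],
        seed_cross_populations=["Tl", "Pl", "Re"],
        seed=seed,
    )


def ratchet_off(cfg: SimConfig) -> SimConfig:
    """A copy of the scenario with every load-driven trait decay switched
    off: traits become independent of clonality and all planted
    trait-diversity correlations vanish."""
    return replace(
        cfg,
        pollen_load_decay=0.0,
        mutant_slope=0.0,
        dead_slope=0.0,
        germ_slope=0.0,
        seed_width_load_decay=0.0,
    )
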