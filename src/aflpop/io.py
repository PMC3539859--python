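"""Tabular input/output and the core data containers.

Every artifact of the pipeline is plain delimited text (UTF-8, LF): the
samples x loci band matrix (TSV with ``{0, 1, NA}`` cells), the sample
metadata table, the crossing-records table and the four reproductive-trait
tables.  Readers validate on construction and never silently coerce; writers
round-trip bit-exactly for integer cells.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

#: default missing-band code in marker files
MISSING = "NA"

#: closed vocabulary of flower classes; mutant subtypes are prefixed "mutant_"
FLOWER_CLASSES = frozenset(
    {
        "normal",
        "mutant_no_filament",
        "mutant_one_stamen",
        "mutant_unequal_stamens",
        "mutant_no_stamen",
        "mutant_three_stamens",
    }
)

VIABILITY_CLASSES = frozenset({"viable", "abnormal", "dead"})
GERMINATION_CLASSES = frozenset({"germinated", "not_germinated"})
AREAS = frozenset({"native", "introduced"})


class FormatError(ValueError):
    """A file or table violates the documented format contract."""


class ConfigError(ValueError):
    """An operation was invoked with an unusable configuration."""


class GroupingError(ValueError):
    """A grouping argument is empty, unknown, or inconsistent."""


# ---------------------------------------------------------------------------
# MarkerMatrix
# ---------------------------------------------------------------------------


@dataclass
class MarkerMatrix:
    """Binary band-presence matrix (samples x loci) with missing cells.

    ``band`` is a float array with entries 0.0 (absent), 1.0 (present) or
    NaN (missing / unscored).  Sample and locus identifiers are ordered and
    duplicate-free; every row must carry at least one scored locus.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    band: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.locus_ids = [str(l) for l in self.locus_ids]
        self.band = np.asarray(self.band, dtype=float)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids in marker matrix")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise FormatError("duplicate locus ids in marker matrix")
        if self.band.shape != (len(self.sample_ids), len(self.locus_ids)):
            raise FormatError(
                f"band matrix shape {self.band.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci"
            )
        scored = ~np.isnan(self.band)
        bad = scored & (self.band != 0.0) & (self.band != 1.0)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise FormatError(
                f"cell ({self.sample_ids[i]}, {self.locus_ids[j]}) is "
                f"{self.band[i, j]!r}; must be 0, 1 or missing"
            )
        if not scored.any(axis=1).all():
            i = int(np.flatnonzero(~scored.any(axis=1))[0])
            raise FormatError(f"sample {self.sample_ids[i]} has no scored locus")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def scored(self) -> np.ndarray:
        """Boolean mask of scored (non-missing) cells."""
        return ~np.isnan(self.band)

    def index_of(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    def row(self, sample_id: str) -> np.ndarray:
        return self.band[self.index_of(sample_id)]

    def subset(self, sample_ids: list[str]) -> "MarkerMatrix":
        idx = [self.index_of(s) for s in sample_ids]
        return MarkerMatrix(list(sample_ids), list(self.locus_ids), self.band[idx])

    def to_frame(self, missing: str = MISSING) -> pd.DataFrame:
        cells = np.where(
            np.isnan(self.band),
            missing,
            np.char.mod("%d", np.nan_to_num(self.band).astype(int)),
        )
        return pd.DataFrame(cells, index=self.sample_ids, columns=self.locus_ids)


def read_marker_matrix(path: str | Path, missing: str = MISSING) -> MarkerMatrix:
    """Read a samples x loci band matrix from tab- or comma-delimited text.

    First column holds sample ids, the header row locus ids; cells must be
    ``0``, ``1`` or the missing code.  Any other cell raises
    :class:`FormatError` naming the offending sample and locus.
    """
    df = pd.read_csv(
        path, sep=None, engine="python", index_col=0, dtype=str,
        keep_default_na=False,
    )
    sample_ids = [str(s) for s in df.index]
    locus_ids = [str(c) for c in df.columns]
    band = np.empty(df.shape, dtype=float)
    raw = df.to_numpy(dtype=str)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j].strip()
            if cell == missing:
                band[i, j] = np.nan
            elif cell == "0":
                band[i, j] = 0.0
            elif cell == "1":
                band[i, j] = 1.0
            else:
                raise FormatError(
                    f"cell ({sample_ids[i]}, {locus_ids[j]}) is {cell!r}; "
                    f"must be 0, 1 or {missing!r}"
                )
    return MarkerMatrix(sample_ids, locus_ids, band)


def write_marker_matrix(
    matrix: MarkerMatrix, path: str | Path, missing: str = MISSING, sep: str = "\t"
) -> None:
    matrix.to_frame(missing).to_csv(path, sep=sep, index_label="sample_id")


def export_dominant_diploid(
    matrix: MarkerMatrix, path: str | Path, unknown: str = "-9", sep: str = "\t"
) -> None:
    """Export the matrix in the two-row-per-individual dominant layout
    consumed by Bayesian clustering tools.

    Coding convention (a documented choice for dominant data): a present
    band is written as one dominant allele ``1`` plus one ``unknown`` allele
    (the second allele of a band-present phenotype is unobservable); an
    absent band as two recessive ``0`` alleles; a missing cell as two
    ``unknown`` alleles.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(sep.join(["sample_id"] + matrix.locus_ids) + "\n")
        for i, sid in enumerate(matrix.sample_ids):
            row = matrix.band[i]
            first = ["1" if v == 1.0 else "0" if v == 0.0 else unknown for v in row]
            second = [unknown if v == 1.0 else "0" if v == 0.0 else unknown for v in row]
            fh.write(sep.join([sid] + first) + "\n")
            fh.write(sep.join([sid] + second) + "\n")


# ---------------------------------------------------------------------------
# SampleFrame
# ---------------------------------------------------------------------------


@dataclass
class SampleFrame:
    """Per-sample metadata: population, region, area, coordinates,
    replicate annotation and optional external cluster label."""

    data: pd.DataFrame

    REQUIRED = ("sample_id", "population", "region", "area")
    OPTIONAL = ("latitude", "longitude", "replicate_of", "external_cluster")

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise FormatError(f"sample table lacks required column {col!r}")
        for col in self.OPTIONAL:
            if col not in df.columns:
                df[col] = np.nan
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample id {dup!r} in sample table")
        bad_area = ~df["area"].isin(AREAS)
        if bad_area.any():
            raise FormatError(
                f"area must be one of {sorted(AREAS)}; got "
                f"{df.loc[bad_area, 'area'].iloc[0]!r}"
            )
        known = set(df["sample_id"])
        reps = df["replicate_of"].dropna().astype(str)
        unknown = [r for r in reps if r not in known]
        if unknown:
            raise FormatError(
                f"replicate_of references unknown sample {unknown[0]!r}"
            )
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def primary(self) -> pd.DataFrame:
        """Rows that are not replicate re-scorings."""
        return self.data[self.data["replicate_of"].isna()]

    def replicate_pairs(self) -> list[tuple[str, str]]:
        """(original, replicate) sample-id pairs."""
        rep = self.data[self.data["replicate_of"].notna()]
        return [(str(r.replicate_of), str(r.sample_id)) for r in rep.itertuples()]

    def grouping(self, column: str, samples: list[str] | None = None) -> dict[str, str]:
        if column not in self.data.columns:
            raise GroupingError(f"unknown metadata column {column!r}")
        sub = self.data if samples is None else self.data[
            self.data["sample_id"].isin(samples)
        ]
        out = {}
        for r in sub.itertuples():
            val = getattr(r, column)
            if pd.notna(val):
                out[str(r.sample_id)] = str(val)
        return out

    def population_coordinates(self) -> pd.DataFrame:
        """Mean latitude/longitude per population (decimal degrees)."""
        prim = self.primary()
        return prim.groupby("population")[["latitude", "longitude"]].mean()


def read_samples(path: str | Path) -> SampleFrame:
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    for col in ("latitude", "longitude"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return SampleFrame(df)


def write_samples(samples: SampleFrame, path: str | Path) -> None:
    samples.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# CrossTable
# ---------------------------------------------------------------------------


@dataclass
class CrossTable:
    """Crossing records: one row per cross direction (mother pop x father
    pop), with flower, capsule and seed counts.  Reciprocal records are
    retained separately; intra-population crosses are flagged, not rejected.
    """

    data: pd.DataFrame

    REQUIRED = ("mother_population", "father_population", "n_flowers", "n_capsules", "n_seeds")

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise FormatError(f"crossing table lacks required column {col!r}")
        for col in ("mother_sample", "father_sample"):
            if col not in df.columns:
                df[col] = np.nan
        for col in ("n_flowers", "n_capsules", "n_seeds"):
            df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
            if (df[col] < 0).any():
                raise FormatError(f"negative count in column {col!r}")
        if len(df) and (df["n_flowers"] < 1).any():
            raise FormatError("every crossing record needs n_flowers >= 1")
        df["intra_population"] = df["mother_population"] == df["father_population"]
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def populations(self) -> list[str]:
        pops = set(self.data["mother_population"]) | set(self.data["father_population"])
        return sorted(str(p) for p in pops)


def read_crosses(path: str | Path) -> CrossTable:
    return CrossTable(pd.read_csv(path, sep=None, engine="python"))


def write_crosses(table: CrossTable, path: str | Path) -> None:
    table.data.drop(columns=["intra_population"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# TraitTable
# ---------------------------------------------------------------------------

ALIQUOT_COLS = [f"aliquot_{k}" for k in range(1, 11)]


@dataclass
class TraitTable:
    """Reproductive-trait observations, one sub-table per unit of record.

    ``flowers``  — one row per observed flower: population, sample_id,
                   flower_class (closed vocabulary).
    ``buds``     — one row per dissected bud: population, sample_id, ten
                   pollen aliquot counts, ovule_count.
    ``capsules`` — one row per capsule: population (maternal), capsule_id,
                   optional father_population, seed_count.
    ``seeds``    — one row per seed: population (maternal), capsule_id,
                   width_mm, length_mm, viability, germination.
    """

    flowers: pd.DataFrame = field(default_factory=pd.DataFrame)
    buds: pd.DataFrame = field(default_factory=pd.DataFrame)
    capsules: pd.DataFrame = field(default_factory=pd.DataFrame)
    seeds: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if len(self.flowers):
            bad = ~self.flowers["flower_class"].isin(FLOWER_CLASSES)
            if bad.any():
                raise FormatError(
                    f"unknown flower class "
                    f"{self.flowers.loc[bad, 'flower_class'].iloc[0]!r}"
                )
        if len(self.buds):
            missing = [c for c in ALIQUOT_COLS if c not in self.buds.columns]
            if missing:
                raise FormatError(
                    f"bud table needs exactly ten aliquot columns; missing {missing[0]}"
                )
            counts = self.buds[ALIQUOT_COLS].to_numpy(dtype=float)
            if np.isnan(counts).any() or (counts < 0).any():
                raise FormatError("aliquot counts must be ten non-negative integers")
        if len(self.seeds):
            for col in ("width_mm", "length_mm"):
                if col in self.seeds.columns:
                    vals = pd.to_numeric(self.seeds[col], errors="raise")
                    if (vals.dropna() <= 0).any():
                        raise FormatError(f"{col} must be > 0")
            if "viability" in self.seeds.columns:
                bad = ~self.seeds["viability"].dropna().isin(VIABILITY_CLASSES)
                if bad.any():
                    raise FormatError("viability outside {viable, abnormal, dead}")
            if "germination" in self.seeds.columns:
                bad = ~self.seeds["germination"].dropna().isin(GERMINATION_CLASSES)
                if bad.any():
                    raise FormatError(
                        "germination outside {germinated, not_germinated}"
                    )

    PARTS = ("flowers", "buds", "capsules", "seeds")


def read_traits(directory: str | Path) -> TraitTable:
    """Read the four trait CSVs (``flowers.csv`` etc.) from a directory;
    absent files yield empty sub-tables."""
    directory = Path(directory)
    parts = {}
    for name in TraitTable.PARTS:
        p = directory / f"{name}.csv"
        parts[name] = pd.read_csv(p) if p.exists() else pd.DataFrame()
    return TraitTable(**parts)


def write_traits(traits: TraitTable, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in TraitTable.PARTS:
        df = getattr(traits, name)
        if len(df):
            df.to_csv(directory / f"{name}.csv", index=False)


# ---------------------------------------------------------------------------
# Simulator / run configuration files
# ---------------------------------------------------------------------------


def read_config(path: str | Path) -> dict:
    """Flat key-value configuration (YAML; plain ``key: value`` suffices)."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise FormatError("config file must be a flat key-value mapping")
    return cfg


def write_run_summary(summary: dict, path: str | Path) -> None:
    """Machine-readable run summary (YAML)."""
    def _clean(obj):
        if isinstance(obj, dict):
            return {str(k): _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, (np.floating, float)):
            v = float(obj)
            return None if math.isnan(v) else v
        if isinstance(obj, (np.integer, int)):
            return int(obj)
        return obj

    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_clean(summary), fh, sort_keys=False)
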