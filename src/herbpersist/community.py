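"""Data model and I/O for repeated-survey community tables and mixed-type trait tables.

The canonical interchange format for survey data is a long CSV with columns
``site, unit, survey, species, cover``; rows absent from the file mean the
species was absent from that quadrat at that survey.  Trait tables are wide
CSVs, one row per species, one column per trait, with trait kinds declared by
a :class:`TraitSchema`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SurveySeries",
    "TraitDescriptor",
    "TraitTable",
    "DEFAULT_TRAIT_SCHEMA",
    "read_survey_csv",
    "write_survey_csv",
    "read_trait_csv",
    "write_trait_csv",
    "first_survey_abundance",
]


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class SurveySeries:
    """Occupancy and cover of each species in each sampling unit over Z surveys.

    Parameters
    ----------
    site_id:
        Label of the site (one series per site).
    surveys:
        Ordered sequence of Z >= 2 survey labels (e.g. years).  Consecutiveness
        for run counting is adjacency in this sequence, not calendar spacing.
    units, species:
        Sampling-unit and species labels; each unique within its axis.
    cover:
        Array of shape (n_units, n_species, Z) with percent cover in [0, 100].
    occupancy:
        Boolean array of the same shape.  If omitted it is derived as
        ``cover > 0``.  Presence with zero cover (a trace occurrence) is
        allowed, but cover > 0 with occupancy False is contradictory.
    """

    site_id: str
    surveys: list
    units: list
    species: list
    cover: np.ndarray
    occupancy: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.surveys = list(self.surveys)
        self.units = list(self.units)
        self.species = list(self.species)
        self.cover = np.asarray(self.cover, dtype=float)
        if len(self.surveys) < 2:
            raise ValidationError("a survey series needs Z >= 2 surveys")
        for name, labels in (("survey", self.surveys), ("unit", self.units),
                             ("species", self.species)):
            if len(set(labels)) != len(labels):
                raise ValidationError(f"duplicate {name} labels")
        shape = (len(self.units), len(self.species), len(self.surveys))
        if self.cover.shape != shape:
            raise ValidationError(
                f"cover has shape {self.cover.shape}, expected {shape}")
        if not np.all(np.isfinite(self.cover)):
            raise ValidationError("cover contains non-finite values")
        if self.cover.min() < 0 or self.cover.max() > 100:
            raise ValidationError("cover values must lie in [0, 100]")
        if self.occupancy is None:
            self.occupancy = self.cover > 0
        else:
            self.occupancy = np.asarray(self.occupancy, dtype=bool)
            if self.occupancy.shape != shape:
                raise ValidationError("occupancy shape does not match cover")
            if np.any((self.cover > 0) & ~self.occupancy):
                raise ValidationError(
                    "cover > 0 where occupancy is False: contradictory input")

    @property
    def n_surveys(self) -> int:
        return len(self.surveys)

    def unit_index(self, unit) -> int:
        return self.units.index(unit)

    def species_index(self, sp) -> int:
        return self.species.index(sp)

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format frame with one row per present (unit, species, survey)."""
        iu, isp, it = np.nonzero(self.occupancy)
        return pd.DataFrame({
            "site": self.site_id,
            "unit": [self.units[i] for i in iu],
            "survey": [self.surveys[i] for i in it],
            "species": [self.species[i] for i in isp],
            "cover": self.cover[iu, isp, it],
        })


@dataclass(frozen=True)
class TraitDescriptor:
    """One trait: its name, kind and unit; levels for categorical traits."""

    name: str
    kind: str  # quantitative | binary | categorical
    unit: str = ""
    levels: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in ("quantitative", "binary", "categorical"):
            raise ValidationError(f"unknown trait kind {self.kind!r}")
        if self.kind == "categorical" and not self.levels:
            raise ValidationError(f"categorical trait {self.name} needs levels")


#: The default five-trait schema: seed mass, perennial belowground bud bank,
#: specific leaf area, vegetative mobility and leaf anatomy.
DEFAULT_TRAIT_SCHEMA: tuple[TraitDescriptor, ...] = (
    TraitDescriptor("seed_mass", "quantitative", "mg"),
    TraitDescriptor("bud_bank", "binary"),
    TraitDescriptor("sla", "quantitative", "mm2/mg"),
    TraitDescriptor("vegetative_mobility", "categorical",
                    levels=("none", "slow", "fast")),
    TraitDescriptor("leaf_anatomy", "categorical",
                    levels=("helomorphic", "hygromorphic", "mesomorphic",
                            "scleromorphic")),
)


@dataclass
class TraitTable:
    """Species-by-trait table with declared kinds; missing values allowed.

    ``data`` is a DataFrame indexed by species with one column per trait.
    Quantitative traits are floats (NaN = missing), binary traits booleans
    (pd.NA = missing), categorical traits strings from the declared level set.
    """

    schema: tuple[TraitDescriptor, ...]
    data: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.schema = tuple(self.schema)
        names = [d.name for d in self.schema]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate trait names in schema")
        missing_cols = [n for n in names if n not in self.data.columns]
        if missing_cols:
            raise ValidationError(f"trait columns missing: {missing_cols}")
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate species labels in trait table")
        self.data = self.data[names]
        for d in self.schema:
            col = self.data[d.name]
            if d.kind == "quantitative":
                vals = pd.to_numeric(col, errors="coerce").astype(float)
                if np.any(np.isinf(vals.to_numpy(dtype=float, na_value=np.nan))):
                    raise ValidationError(
                        f"non-finite value in quantitative trait {d.name}")
                self.data[d.name] = vals
            elif d.kind == "categorical":
                bad = col.dropna()[~col.dropna().isin(d.levels)]
                if len(bad):
                    raise ValidationError(
                        f"trait {d.name}: value(s) {sorted(set(bad))} outside "
                        f"declared levels {list(d.levels)}")

    @property
    def species(self) -> list:
        return list(self.data.index)

    def descriptor(self, name: str) -> TraitDescriptor:
        for d in self.schema:
            if d.name == name:
                return d
        raise KeyError(name)

    def subset(self, species) -> "TraitTable":
        return TraitTable(self.schema, self.data.loc[list(species)].copy())


def read_survey_csv(path, site=None, occupancy_column: bool = False) -> SurveySeries | list[SurveySeries]:
    """Read a long-format survey CSV into one or more :class:`SurveySeries`.

    Expected columns: ``site, unit, survey, species, cover`` (and optionally
    ``present`` when *occupancy_column* is set, allowing trace occurrences
    recorded present with zero cover).  Rows absent from the file are absences.

    Parameters
    ----------
    site:
        If given, only that site is read and a single series returned;
        otherwise one series per site, in order of first appearance
        (a single series if the file holds one site).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = ["site", "unit", "survey", "species", "cover"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"survey CSV missing columns: {missing}")
    if df["species"].isna().any() or (df["species"].astype(str).str.strip() == "").any():
        bad = df.index[df["species"].isna() |
                       (df["species"].astype(str).str.strip() == "")][0]
        raise ValidationError(f"empty species label at data row {bad + 1}")
    covers = pd.to_numeric(df["cover"], errors="coerce")
    if covers.isna().any():
        bad = df.index[covers.isna()][0]
        raise ValidationError(f"unparseable cover at data row {bad + 1}")
    df["cover"] = covers
    if (covers < 0).any() or (covers > 100).any():
        bad = df.index[(covers < 0) | (covers > 100)][0]
        raise ValidationError(f"cover outside [0, 100] at data row {bad + 1}")
    if site is not None:
        df = df[df["site"] == site]
        if df.empty:
            raise ValidationError(f"no rows for site {site!r}")

    out = []
    for site_id, sub in df.groupby("site", sort=False):
        dups = sub.duplicated(subset=["unit", "survey", "species"])
        if dups.any():
            u, s, sp = sub.loc[dups.idxmax(), ["unit", "survey", "species"]]
            raise ValidationError(
                f"duplicate (unit={u!r}, species={sp!r}, survey={s!r}) rows "
                f"for site {site_id!r}")
        surveys = sorted(sub["survey"].unique())
        units = list(dict.fromkeys(sub["unit"]))
        species = list(dict.fromkeys(sub["species"]))
        cover = np.zeros((len(units), len(species), len(surveys)))
        occ = np.zeros_like(cover, dtype=bool) if occupancy_column else None
        ui = {u: i for i, u in enumerate(units)}
        si = {s: i for i, s in enumerate(species)}
        ti = {t: i for i, t in enumerate(surveys)}
        iu = sub["unit"].map(ui).to_numpy()
        isp = sub["species"].map(si).to_numpy()
        it = sub["survey"].map(ti).to_numpy()
        cover[iu, isp, it] = sub["cover"].to_numpy()
        if occupancy_column:
            if "present" not in sub.columns:
                raise ValidationError("occupancy_column=True but no 'present' column")
            occ[iu, isp, it] = sub["present"].astype(bool).to_numpy()
        out.append(SurveySeries(site_id, surveys, units, species, cover,
                                occupancy=occ))
    if site is not None or len(out) == 1:
        return out[0]
    return out


def write_survey_csv(series, path) -> None:
    """Write one series or a list of series as a long-format CSV."""
    if isinstance(series, SurveySeries):
        series = [series]
    pd.concat([s.to_long_frame() for s in series],
              ignore_index=True).to_csv(path, index=False)


def read_trait_csv(path, schema=DEFAULT_TRAIT_SCHEMA) -> TraitTable:
    """Read a wide species-by-trait CSV under the given schema.

    Unparseable quantitative entries become missing with a logged warning;
    categorical values outside the declared level set are an error.
    """
    df = pd.read_csv(path)
    if "species" not in df.columns:
        raise ValidationError("trait CSV has no 'species' column")
    df = df.set_index("species")
    for d in schema:
        if d.name not in df.columns:
            raise ValidationError(f"trait CSV missing column {d.name!r}")
        if d.kind == "quantitative":
            raw = df[d.name]
            num = pd.to_numeric(raw, errors="coerce")
            newly = num.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
            if newly.any():
                for sp in df.index[newly]:
                    logger.warning("trait %s: unparseable value %r for %s set "
                                   "to missing", d.name, raw[sp], sp)
                    warnings.warn(f"trait {d.name}: unparseable value for {sp} "
                                  "set to missing", stacklevel=2)
            df[d.name] = num
        elif d.kind == "binary":
            df[d.name] = df[d.name].map(
                {1: True, 0: False, "1": True, "0": False, True: True,
                 False: False, "true": True, "false": False})
    return TraitTable(tuple(schema), df)


def write_trait_csv(table: TraitTable, path) -> None:
    out = table.data.copy()
    for d in table.schema:
        if d.kind == "binary":
            out[d.name] = out[d.name].map({True: 1, False: 0})
    out.index.name = "species"
    out.to_csv(path)


def first_survey_abundance(series: SurveySeries) -> pd.DataFrame:
    """Unit-by-species cover at the first survey (the monitoring baseline)."""
    return pd.DataFrame(series.cover[:, :, 0], index=series.units,
                        columns=series.species)
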