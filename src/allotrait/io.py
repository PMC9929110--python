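"""Readers, writers and validation for the pipeline's tabular and tree inputs.

Conventions: CSV with a header row, UTF-8, ``.`` decimal separator; DBH in
cm, height and crown radius in m; newick with branch lengths.  Column names
are configurable through a schema map because upstream field databases name
columns differently; the defaults below are used throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .phylogeny import Phylogeny, PhylogenyError

#: the six species-mean functional traits carried through the analysis
TRAIT_COLUMNS = (
    "leaf_pct_n",   # leaf nitrogen, % dry mass
    "leaf_pct_p",   # leaf phosphorus, % dry mass
    "wood_density", # g/cm^3
    "leaf_area",    # cm^2
    "sla",          # specific leaf area, cm^2/g
    "seed_mass",    # g
)

DEFAULT_SCHEMA: dict[str, str] = {
    "species": "species",
    "dbh_cm": "dbh_cm",
    "height_m": "height_m",
    "crown_r1_m": "crown_r1_m",
    "crown_r2_m": "crown_r2_m",
    "crown_radius_m": "crown_radius_m",
}

# float formatting used by every writer; 12 significant digits round-trip
# cleanly through text for the magnitudes this pipeline produces
_FLOAT_FMT = "%.12g"


class FormatError(ValueError):
    """A file does not have the expected structure (columns, parse)."""


class ValidationError(ValueError):
    """A file parsed but contains invalid values; message names the culprit."""


@dataclass(frozen=True)
class AllometryObservation:
    """One measured tree.

    ``height_m`` and ``crown_radius_m`` are optional per record: a tree
    enters only the model(s) for which its response was measured.  When two
    perpendicular crown radii are supplied the stored value is their
    arithmetic mean.
    """

    species_code: str
    dbh_cm: float
    height_m: float | None = None
    crown_radius_m: float | None = None

    def __post_init__(self):
        if not self.species_code:
            raise ValidationError("empty species code")
        if not self.dbh_cm > 0:
            raise ValidationError(f"non-positive DBH {self.dbh_cm}")
        for name in ("height_m", "crown_radius_m"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValidationError(f"non-positive {name} {v}")


def _get(row, colname):
    v = row.get(colname)
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return float(v)


def read_allometry_csv(
    path, schema: Mapping[str, str] | None = None
) -> list[AllometryObservation]:
    """Read one-row-per-tree allometry data.

    The file must contain the species and DBH columns.  Crown size may be
    given either as a single pre-averaged radius column or as two
    perpendicular radius columns (averaged here); records carrying only one
    of the two radii use that single measurement.
    """
    sch = dict(DEFAULT_SCHEMA)
    if schema:
        sch.update(schema)
    try:
        df = pd.read_csv(path, dtype={sch["species"]: str})
    except Exception as exc:  # noqa: BLE001 - normalize parser errors
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    for required in ("species", "dbh_cm"):
        if sch[required] not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {sch[required]!r}")
    has_single = sch["crown_radius_m"] in df.columns
    has_pair = sch["crown_r1_m"] in df.columns or sch["crown_r2_m"] in df.columns
    if has_single and has_pair:
        raise FormatError(
            f"{path}: give crown radius either as one column or as two, not both"
        )
    out: list[AllometryObservation] = []
    for i, row in enumerate(df.to_dict("records")):
        species = row.get(sch["species"])
        if species is None or (isinstance(species, float) and math.isnan(species)):
            raise ValidationError(f"{path} row {i + 2}: missing species code")
        try:
            dbh = _get(row, sch["dbh_cm"])
            if dbh is None:
                raise ValidationError("missing DBH")
            height = _get(row, sch["height_m"])
            if has_single:
                crown = _get(row, sch["crown_radius_m"])
            else:
                r1 = _get(row, sch["crown_r1_m"])
                r2 = _get(row, sch["crown_r2_m"])
                for r in (r1, r2):
                    if r is not None and not r > 0:
                        raise ValidationError(f"non-positive crown radius {r}")
                if r1 is not None and r2 is not None:
                    crown = 0.5 * (r1 + r2)
                else:
                    crown = r1 if r1 is not None else r2
            obs = AllometryObservation(
                species_code=str(species), dbh_cm=dbh,
                height_m=height, crown_radius_m=crown,
            )
        except ValidationError as exc:
            # +2: header line and 1-based numbering, i.e. the line in the file
            raise ValidationError(f"{path} row {i + 2}: {exc}") from None
        out.append(obs)
    return out


def observations_to_frame(obs: Sequence[AllometryObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species": [o.species_code for o in obs],
            "dbh_cm": [o.dbh_cm for o in obs],
            "height_m": [o.height_m for o in obs],
            "crown_radius_m": [o.crown_radius_m for o in obs],
        }
    )


def write_allometry_csv(obs: Sequence[AllometryObservation], path) -> None:
    observations_to_frame(obs).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trait_csv(path) -> pd.DataFrame:
    """Read the species × trait table.

    Returns a DataFrame indexed by species code with exactly the six trait
    columns of :data:`TRAIT_COLUMNS`, in that order.
    """
    try:
        df = pd.read_csv(path, dtype={"species": str})
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if "species" not in df.columns:
        raise FormatError(f"{path}: missing 'species' column")
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing trait columns {missing}")
    dup = df["species"][df["species"].duplicated()]
    if len(dup):
        raise ValidationError(f"{path}: duplicate species {sorted(set(dup))}")
    table = df.set_index("species")[list(TRAIT_COLUMNS)]
    validate_trait_table(table, name=str(path))
    return table


def validate_trait_table(table: pd.DataFrame, name: str = "trait table") -> None:
    for species, row in table.iterrows():
        for trait in TRAIT_COLUMNS:
            v = row[trait]
            if pd.isna(v):
                raise ValidationError(f"{name}: species {species}: missing {trait}")
            if not v > 0:
                raise ValidationError(
                    f"{name}: species {species}: non-positive {trait} = {v}"
                )


def write_trait_csv(table: pd.DataFrame, path) -> None:
    out = table.reset_index()
    out.columns = ["species", *TRAIT_COLUMNS]
    out.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_newick(path) -> Phylogeny:
    """Read a rooted binary phylogeny with branch lengths from a newick file."""
    return Phylogeny.from_file(path)


def write_newick(tree: Phylogeny, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n", encoding="utf-8")


def write_result_tables(results: Mapping[str, pd.DataFrame], out_dir) -> dict[str, Path]:
    """Write the pipeline's result tables as CSV.

    ``results`` maps a table name (e.g. ``parameter_summary``,
    ``parameter_tau``, ``sizeclass_tau``, ``coupling_tau``, ``waic``) to a
    DataFrame; each is written as ``<name>.csv`` with its existing column
    order and 12-significant-digit floats, so a reread reproduces the values.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, df in results.items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False, float_format=_FLOAT_FMT)
        paths[name] = p
    return paths


__all__ = [
    "TRAIT_COLUMNS",
    "DEFAULT_SCHEMA",
    "AllometryObservation",
    "FormatError",
    "ValidationError",
    "Phylogeny",
    "PhylogenyError",
    "read_allometry_csv",
    "read_trait_csv",
    "read_newick",
    "validate_trait_table",
    "write_allometry_csv",
    "write_trait_csv",
    "write_newick",
    "write_result_tables",
    "observations_to_frame",
]
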