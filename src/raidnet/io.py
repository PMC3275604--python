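"""Validated CSV input for sightings and attribute tables.

Schemas
-------
sightings.csv  : sighting_id, date, male_id   (one row per group member)
attributes.csv : male_id, age_years, raider   (raider in {0, 1}, age >= 10)
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

__all__ = ["InputError", "read_inputs", "read_attributes", "read_sightings"]


class InputError(ValueError):
    """Malformed input table; the message names the offending rows."""


def read_attributes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"male_id", "age_years", "raider"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    df["male_id"] = df["male_id"].astype(str)
    dup = df[df["male_id"].duplicated()]
    if not dup.empty:
        raise InputError(
            f"{path}: duplicate male_id at rows {list(dup.index + 2)}"
        )
    bad = df[~df["raider"].isin([0, 1])]
    if not bad.empty:
        raise InputError(
            f"{path}: raider must be 0 or 1; offending rows {list(bad.index + 2)} "
            f"(values {bad['raider'].tolist()})"
        )
    young = df[df["age_years"] < 10]
    if not young.empty:
        raise InputError(
            f"{path}: age_years must be >= 10; offending rows {list(young.index + 2)}"
        )
    return df


def read_sightings(path, attributes: pd.DataFrame) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sighting_id", "male_id"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    df["male_id"] = df["male_id"].astype(str)
    df["sighting_id"] = df["sighting_id"].astype(str)
    known = set(attributes["male_id"])
    bad = df[~df["male_id"].isin(known)]
    if not bad.empty:
        raise InputError(
            f"{path}: unknown male_id at rows {list(bad.index + 2)} "
            f"({sorted(set(bad['male_id']))})"
        )
    dup = df.duplicated(subset=["sighting_id", "male_id"])
    if dup.any():
        warnings.warn(
            f"{path}: collapsed {int(dup.sum())} duplicate (sighting_id, male_id) rows",
            stacklevel=2,
        )
        df = df[~dup]
    sizes = df.groupby("sighting_id")["male_id"].nunique()
    lone = sizes[sizes < 2]
    if not lone.empty:
        warnings.warn(
            f"{path}: dropped {len(lone)} single-member sightings "
            f"(groups require >= 2 members): {sorted(lone.index)[:5]}...",
            stacklevel=2,
        )
        df = df[~df["sighting_id"].isin(set(lone.index))]
    return df.reset_index(drop=True)


def read_inputs(sightings_path, attributes_path) -> tuple:
    """Read and validate (sightings, attributes), enforcing both schemas."""
    attributes = read_attributes(Path(attributes_path))
    sightings = read_sightings(Path(sightings_path), attributes)
    return sightings, attributes
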