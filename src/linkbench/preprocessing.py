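"""Field harmonization and inpatient deduplication.

Two source systems rarely code identifiers the same way, so linkage starts by
harmonizing value coding (gender "1"/"2" vs "M"/"F", race vocabularies,
missing-value sentinels) and setting implausible values (e.g. ZIP codes
containing letters) to missing.  Names are deliberately left untouched — no
case folding, no suffix stripping, no nickname lookup — because the point of
the benchmark is to see how the linkage algorithms cope with raw names.

The inpatient dataset holds one row per admission, so the same person appears
many times; :func:`deduplicate` collapses rows that agree exactly on the full
identifier key (MRN, last name, first name, gender, YOB, race, ZIP), with one
refinement for missing ZIPs: a row whose only deficiency is a missing ZIP is
dropped whenever a sibling row, identical on every other key field, carries a
valid ZIP.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: the full deduplication key (spec order: MRN, last, first, gender, YOB, race, ZIP)
DEDUP_KEY = ["mrn", "last_name", "first_name", "gender", "yob", "race", "zip"]

_ZIP_RE = re.compile(r"^\d{5}$")

_DEFAULT_GENDER_RECODE = {
    "F": "F",
    "M": "M",
    "1": "M",
    "2": "F",
    "FEMALE": "F",
    "MALE": "M",
    "Female": "F",
    "Male": "M",
}

_DEFAULT_RACE_MAP = {
    "Asian": "Asian",
    "asian": "Asian",
    "black": "black",
    "Black": "black",
    "white": "white",
    "White": "white",
    "other": "other",
}

_DEFAULT_SENTINELS = ("", "NA", "N/A", "UNKNOWN", "missing")


@dataclass(frozen=True)
class SchemaMap:
    """Recode tables and plausibility rules used by :func:`harmonize`."""

    gender_recode: dict = field(default_factory=lambda: dict(_DEFAULT_GENDER_RECODE))
    race_map: dict = field(default_factory=lambda: dict(_DEFAULT_RACE_MAP))
    missing_sentinels: tuple = _DEFAULT_SENTINELS
    zip_pattern: str = _ZIP_RE.pattern
    age_cap: int = 90


def harmonize(records: pd.DataFrame, schema: SchemaMap | None = None) -> pd.DataFrame:
    """Recode gender/race, null implausible ZIPs, extract YOB from DOB.

    Unknown gender codes are set to missing and counted in the log.  Names
    pass through byte-for-byte.  Ages are capped (default 90).
    """
    schema = schema or SchemaMap()
    out = records.copy()

    for col in out.columns:
        if out[col].dtype == object:
            out[col] = out[col].where(~out[col].isin(schema.missing_sentinels))

    if "gender" in out:
        raw = out["gender"]
        recoded = raw.map(schema.gender_recode)
        unknown = raw.notna() & recoded.isna()
        if unknown.any():
            log.info("harmonize: %d unknown gender codes set to missing", unknown.sum())
        out["gender"] = recoded

    if "race" in out:
        raw = out["race"]
        mapped = raw.map(schema.race_map)
        # any non-missing value outside the vocabulary collapses to "other"
        mapped = mapped.where(mapped.notna() | raw.isna(), "other")
        out["race"] = mapped

    if "zip" in out:
        zre = re.compile(schema.zip_pattern)
        zips = out["zip"].astype(object)
        ok = zips.map(lambda z: isinstance(z, str) and bool(zre.match(z)))
        n_bad = int((zips.notna() & ~ok).sum())
        if n_bad:
            log.info("harmonize: %d implausible ZIPs set to missing", n_bad)
        out["zip"] = zips.where(ok)

    if "dob" in out:
        years = pd.to_datetime(out["dob"], errors="coerce").dt.year
        out["yob"] = years.astype("Int64")

    if "age" in out:
        out["age"] = pd.to_numeric(out["age"], errors="coerce").clip(
            upper=schema.age_cap
        )

    return out


def deduplicate(records: pd.DataFrame, key: list[str] | None = None) -> pd.DataFrame:
    """Collapse exact duplicates on the identifier key; prefer valid-ZIP rows.

    Rules applied in order:

    1. within each group agreeing on every key field except ZIP, rows with a
       missing ZIP are dropped if any sibling carries a valid ZIP;
    2. rows identical on the full key keep a single survivor (lowest
       ``record_id``).

    Missing values inside non-ZIP key fields compare as ordinary values (two
    missings agree).  Output is sorted by ``record_id``; the operation is
    idempotent.
    """
    key = list(key or DEDUP_KEY)
    if records.empty:
        return records.copy()
    df = records.sort_values("record_id", kind="stable").reset_index(drop=True)

    n_in = len(df)
    if "zip" in key:
        other = [k for k in key if k != "zip"]
        sentinel = df[other].astype(object).where(df[other].notna(), "\0NA")
        group = pd.MultiIndex.from_frame(sentinel)
        has_valid = df["zip"].notna().groupby(group).transform("any")
        drop_missing_zip = df["zip"].isna() & has_valid
        n_zip_dropped = int(drop_missing_zip.sum())
        df = df[~drop_missing_zip]
    else:
        n_zip_dropped = 0

    keyvals = df[key].astype(object).where(df[key].notna(), "\0NA")
    df = df[~keyvals.duplicated(keep="first")]
    out = df.reset_index(drop=True)
    log.info(
        "deduplicate: %d rows in, %d out (%d missing-ZIP siblings, %d exact dups)",
        n_in,
        len(out),
        n_zip_dropped,
        n_in - n_zip_dropped - len(out),
    )
    return out
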