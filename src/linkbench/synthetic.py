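"""Synthetic paired EHR identifier datasets with realistic error channels.

Emulates the situation of two noninteroperable electronic health record
systems covering overlapping patient populations: an inpatient dataset (IPD)
with one row per hospital admission (so repeatedly admitted patients carry
duplicate rows) and an outpatient dataset (OPD) with exactly one row per
person.  Each generated row carries the identifier fields used for linkage
(first name, last name, gender, DOB, YOB, age, race, ZIP, MRN) plus a hidden
``true_person_id`` that links back to the latent population and is used only
by oracle tests and evaluation, never by the linkage algorithms themselves.

Error channels, each with its own configurable rate:

* per-field typographic errors (one random substitution, insertion, deletion
  or adjacent transposition);
* newborn placeholder naming — infants recorded in the inpatient system as
  first name "Male"/"Female" with the mother's surname;
* compound-surname variants (hyphenated double surnames recorded
  inconsistently across systems);
* missing gender;
* MRN corruption of the gold standard itself, split across three channels
  (a different MRN, a missing MRN, a misassigned MRN belonging to another
  person), so that the gold standard is deliberately "alloyed" at a rate of
  roughly 0.5-1% like real enterprise MRN assignment.

Everything is deterministic given ``GeneratorConfig.seed``.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

ALPHABET = string.ascii_uppercase

#: salts for independent random streams derived from one seed
_SALT_POP, _SALT_SPLIT, _SALT_IPD, _SALT_OPD = 11, 13, 17, 19

RECORD_COLUMNS = [
    "record_id",
    "source",
    "first_name",
    "last_name",
    "gender",
    "dob",
    "yob",
    "age",
    "race",
    "zip",
    "mrn",
    "true_person_id",
]

RACE_LEVELS = ["Asian", "black", "white", "other"]


class DegenerateInputError(ValueError):
    """Raised when a corruption channel cannot produce a distance-1 edit."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic paired-dataset scenario.

    Rates are probabilities in [0, 1]; ``admission_rate`` is the mean number
    of admission rows per inpatient person (>= 1, extra admissions are
    Poisson); ``name_zipf_exponent`` controls how head-heavy the name
    frequency distributions are (larger => fewer distinct names in use).
    """

    n_persons: int = 20_000
    overlap_fraction: float = 0.3
    admission_rate: float = 1.5
    typo_rate_per_field: float = 0.02
    newborn_fraction: float = 0.05
    compound_surname_rate: float = 0.01
    missing_gender_rate: float = 0.002
    mrn_error_rate: float = 0.0075
    mrn_error_split: tuple[float, float, float] = (0.77, 0.22, 0.01)
    opd_missing_mrn_rate: float = 0.25
    opd_to_ipd_ratio: float = 2.5
    name_zipf_exponent: float = 1.4
    first_name_pool_size: int = 1_200
    last_name_pool_size: int = 5_000
    infant_fraction: float = 0.08
    max_age: int = 90
    reference_date: date = date(2015, 12, 31)
    zip_pool_size: int = 300
    missing_zip_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.n_persons) < 1:
            raise ValueError(f"n_persons must be >= 1, got {self.n_persons}")
        for name in (
            "overlap_fraction",
            "typo_rate_per_field",
            "newborn_fraction",
            "compound_surname_rate",
            "missing_gender_rate",
            "mrn_error_rate",
            "opd_missing_mrn_rate",
            "infant_fraction",
            "missing_zip_rate",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.admission_rate < 1.0:
            raise ValueError(
                f"admission_rate must be >= 1 (one row per admitted person), "
                f"got {self.admission_rate}"
            )
        if self.opd_to_ipd_ratio <= 0:
            raise ValueError(
                f"opd_to_ipd_ratio must be positive, got {self.opd_to_ipd_ratio}"
            )
        if self.name_zipf_exponent <= 0:
            raise ValueError(
                f"name_zipf_exponent must be positive, got {self.name_zipf_exponent}"
            )
        if abs(sum(self.mrn_error_split) - 1.0) > 1e-9:
            raise ValueError(
                f"mrn_error_split must sum to 1, got {self.mrn_error_split}"
            )


# ---------------------------------------------------------------------------
# name / value pools


def _make_name_pool(size: int, rng: np.random.Generator, min_len: int = 4,
                    max_len: int = 9) -> list[str]:
    """Distinct pseudo-names: capitalised random consonant/vowel strings."""
    vowels = np.array(list("AEIOU"))
    consonants = np.array(list("BCDFGHJKLMNPRSTVWZ"))
    pool: list[str] = []
    seen: set[str] = set()
    while len(pool) < size:
        n = size - len(pool)
        lengths = rng.integers(min_len, max_len + 1, size=n)
        for length in lengths:
            # alternate consonant/vowel for pronounceable tokens
            chars = []
            for i in range(length):
                src = consonants if i % 2 == 0 else vowels
                chars.append(src[rng.integers(0, len(src))])
            name = "".join(chars)
            if name not in seen:
                seen.add(name)
                pool.append(name)
    return pool


def _zipf_probs(size: int, exponent: float) -> np.ndarray:
    ranks = np.arange(1, size + 1, dtype=float)
    p = ranks ** (-exponent)
    return p / p.sum()


# ---------------------------------------------------------------------------
# population


def generate_population(config: GeneratorConfig) -> pd.DataFrame:
    """Draw the latent population of persons underlying both datasets.

    Names come from Zipf-ranked pools (the last-name pool is larger than the
    first-name pool, so last names carry more discriminating power, as in
    real identifier data).  Ages follow a two-part law with an explicit
    infant mode feeding the newborn-naming channel; DOB is drawn uniformly
    within the age stratum and YOB/age are derived from it at the fixed
    reference date, so the three are mutually consistent by construction.
    """
    rng = np.random.default_rng([_SALT_POP, config.seed])
    n = int(config.n_persons)

    first_pool = _make_name_pool(config.first_name_pool_size, rng)
    last_pool = _make_name_pool(config.last_name_pool_size, rng)
    first = rng.choice(
        first_pool, size=n, p=_zipf_probs(len(first_pool), config.name_zipf_exponent)
    )
    last = rng.choice(
        last_pool, size=n, p=_zipf_probs(len(last_pool), config.name_zipf_exponent)
    )
    # maternal surname for the newborn channel: any other pool surname
    pool_arr = np.array(last_pool, dtype=object)
    mat_idx = rng.integers(0, len(pool_arr), size=n)
    maternal = pool_arr[mat_idx]
    collide = maternal == last
    maternal[collide] = pool_arr[(mat_idx[collide] + 1) % len(pool_arr)]

    gender = rng.choice(["F", "M"], size=n)
    race = rng.choice(
        RACE_LEVELS + ["missing"], size=n, p=[0.09, 0.13, 0.55, 0.20, 0.03]
    )

    is_infant = rng.random(n) < config.infant_fraction
    target_age = np.where(
        is_infant, 0, rng.integers(1, config.max_age + 1, size=n)
    )
    ref = config.reference_date
    # dob uniform within the ~365-day window that yields the target age
    offsets = target_age * 365 + rng.integers(0, 365, size=n)
    dobs = np.array([ref - timedelta(days=int(d)) for d in offsets])
    yob = np.array([d.year for d in dobs])
    age = np.array(
        [
            ref.year - d.year - ((ref.month, ref.day) < (d.month, d.day))
            for d in dobs
        ]
    )
    age = np.minimum(age, config.max_age)

    zip_pool = np.array(
        ["%05d" % z for z in rng.integers(1000, 99999, size=config.zip_pool_size)]
    )
    zips = rng.choice(zip_pool, size=n).astype(object)
    zips[rng.random(n) < config.missing_zip_rate] = None

    persons = pd.DataFrame(
        {
            "person_id": [f"P{i:07d}" for i in range(n)],
            "first_name": first,
            "last_name": last,
            "maternal_surname": maternal,
            "gender": gender,
            "dob": [d.isoformat() for d in dobs],
            "yob": yob,
            "age": age,
            "race": race,
            "zip": zips,
            "mrn": [f"M{i:07d}" for i in range(n)],
        }
    )
    return persons


def _split_sources(persons: pd.DataFrame, config: GeneratorConfig):
    """Deterministic partition of persons into IPD-only / OPD-only / both.

    ``overlap_fraction`` of all persons appear in both sources; the remainder
    are allocated so that the outpatient population is ``opd_to_ipd_ratio``
    times the inpatient one (outpatient practices cover far more people than
    a hospital admits), clamped when the overlap already exceeds that shape.
    """
    rng = np.random.default_rng([_SALT_SPLIT, config.seed])
    n = len(persons)
    order = rng.permutation(n)
    n_both = int(round(config.overlap_fraction * n))
    n_rest = n - n_both
    # solve (both + opd_only) = ratio * (both + ipd_only) with
    # ipd_only + opd_only = n_rest
    r = config.opd_to_ipd_ratio
    n_ipd_only = int(round((n_both + n_rest - r * n_both) / (1.0 + r)))
    n_ipd_only = min(max(n_ipd_only, 0), n_rest)
    both = order[:n_both]
    ipd_only = order[n_both : n_both + n_ipd_only]
    opd_only = order[n_both + n_ipd_only :]
    return np.sort(np.concatenate([both, ipd_only])), np.sort(
        np.concatenate([both, opd_only])
    ), np.sort(both)


# ---------------------------------------------------------------------------
# field corruption


def corrupt_field(
    value: str,
    channel: str,
    rng: np.random.Generator,
    alphabet: str = ALPHABET,
) -> str:
    """Apply exactly one typographic edit of the named channel to ``value``.

    Channels: ``substitute``, ``insert``, ``delete``, ``transpose`` (adjacent
    swap).  The result always differs from the input by exactly one operation
    of that channel; inputs for which no such edit exists (empty strings, or
    all-identical characters under ``transpose``) raise
    :class:`DegenerateInputError`.
    """
    if channel not in ("substitute", "insert", "delete", "transpose"):
        raise ValueError(f"unknown corruption channel {channel!r}")
    if channel != "insert" and len(value) == 0:
        raise DegenerateInputError(f"cannot {channel} on an empty string")

    if channel == "substitute":
        pos = int(rng.integers(0, len(value)))
        choices = [c for c in alphabet if c != value[pos]]
        return value[:pos] + choices[int(rng.integers(0, len(choices)))] + value[pos + 1 :]
    if channel == "insert":
        pos = int(rng.integers(0, len(value) + 1))
        ch = alphabet[int(rng.integers(0, len(alphabet)))]
        return value[:pos] + ch + value[pos:]
    if channel == "delete":
        pos = int(rng.integers(0, len(value)))
        return value[:pos] + value[pos + 1 :]
    # transpose: need an adjacent unequal pair, otherwise the swap is a no-op
    positions = [i for i in range(len(value) - 1) if value[i] != value[i + 1]]
    if not positions:
        raise DegenerateInputError(
            f"no distance-1 transposition exists for {value!r}"
        )
    i = positions[int(rng.integers(0, len(positions)))]
    return value[:i] + value[i + 1] + value[i] + value[i + 2 :]


def _random_typo(value: str, rng: np.random.Generator) -> str:
    """One edit with a uniformly chosen channel, falling back on degenerate inputs."""
    channels = ["substitute", "insert", "delete", "transpose"]
    channel = channels[int(rng.integers(0, 4))]
    try:
        return corrupt_field(value, channel, rng)
    except DegenerateInputError:
        return corrupt_field(value, "insert", rng)


# ---------------------------------------------------------------------------
# datasets


def derive_inpatient(persons: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """One row per admission for the inpatient subset of the population.

    Each selected person contributes ``1 + Poisson(admission_rate - 1)`` rows;
    every row passes independently through the typo, compound-surname and
    missing-gender channels, and through MRN corruption (the channel that
    alloys the gold standard).  Infants flagged by the newborn channel are
    recorded with placeholder first name "Male"/"Female" and the maternal
    surname on all their admission rows.
    """
    rng = np.random.default_rng([_SALT_IPD, config.seed])
    ipd_idx, _, _ = _split_sources(persons, config)
    base = persons.iloc[ipd_idx].reset_index(drop=True)
    n_sel = len(base)

    # per-person decisions -------------------------------------------------
    n_rows = 1 + rng.poisson(config.admission_rate - 1.0, size=n_sel)
    newborn = (base["age"].to_numpy() < 1) & (
        rng.random(n_sel) < config.newborn_fraction
    )

    first = base["first_name"].to_numpy(object).copy()
    last = base["last_name"].to_numpy(object).copy()
    first[newborn] = np.where(
        base.loc[newborn, "gender"].to_numpy() == "M", "Male", "Female"
    )
    last[newborn] = base.loc[newborn, "maternal_surname"].to_numpy()

    rep = np.repeat(np.arange(n_sel), n_rows)
    rows = pd.DataFrame(
        {
            "first_name": first[rep],
            "last_name": last[rep],
            "gender": base["gender"].to_numpy()[rep].astype(object),
            "dob": base["dob"].to_numpy()[rep],
            "yob": base["yob"].to_numpy()[rep],
            "age": base["age"].to_numpy()[rep],
            "race": base["race"].to_numpy()[rep],
            "zip": base["zip"].to_numpy(object)[rep],
            "mrn": base["mrn"].to_numpy(object)[rep],
            "true_person_id": base["person_id"].to_numpy()[rep],
        }
    )
    m = len(rows)
    newborn_row = newborn[rep]

    # per-row channels -----------------------------------------------------
    for col in ("first_name", "last_name"):
        hit = np.flatnonzero(
            (rng.random(m) < config.typo_rate_per_field) & ~newborn_row
        )
        vals = rows[col].to_numpy(object)
        for i in hit:
            vals[i] = _random_typo(vals[i], rng)
        rows[col] = vals

    hit = np.flatnonzero(
        (rng.random(m) < config.compound_surname_rate) & ~newborn_row
    )
    if hit.size:
        extra = persons["last_name"].to_numpy()
        vals = rows["last_name"].to_numpy(object)
        picks = rng.integers(0, len(extra), size=hit.size)
        for i, k in zip(hit, picks):
            vals[i] = f"{vals[i]}-{extra[k]}"
        rows["last_name"] = vals

    gender = rows["gender"].to_numpy(object)
    gender[rng.random(m) < config.missing_gender_rate] = None
    rows["gender"] = gender

    # MRN corruption: different / missing / misassigned
    mrn = rows["mrn"].to_numpy(object)
    err = rng.random(m) < config.mrn_error_rate
    kinds = rng.choice(3, size=m, p=list(config.mrn_error_split))
    diff = np.flatnonzero(err & (kinds == 0))
    miss = np.flatnonzero(err & (kinds == 1))
    wrong = np.flatnonzero(err & (kinds == 2))
    for j, i in enumerate(diff):
        mrn[i] = f"X{j:07d}"  # an MRN outside the latent assignment
    mrn[miss] = None
    if wrong.size:
        other = rng.integers(0, len(persons), size=wrong.size)
        mrn[wrong] = persons["mrn"].to_numpy()[other]
    rows["mrn"] = mrn

    rows.insert(0, "record_id", [f"I{i:07d}" for i in range(m)])
    rows.insert(1, "source", "IPD")
    return rows[RECORD_COLUMNS]


def derive_outpatient(persons: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Exactly one row per outpatient person.

    The outpatient system stores each person's current demographic record, so
    fields are clean; the inpatient MRN, however, is only populated for
    persons known to the inpatient system — persons never admitted lose it
    with probability ``opd_missing_mrn_rate``.
    """
    rng = np.random.default_rng([_SALT_OPD, config.seed])
    _, opd_idx, both_idx = _split_sources(persons, config)
    base = persons.iloc[opd_idx].reset_index(drop=True)
    n = len(base)

    mrn = base["mrn"].to_numpy(object).copy()
    in_both = np.isin(opd_idx, both_idx)
    miss = (rng.random(n) < config.opd_missing_mrn_rate) & ~in_both
    mrn[miss] = None

    out = pd.DataFrame(
        {
            "record_id": [f"O{i:07d}" for i in range(n)],
            "source": "OPD",
            "first_name": base["first_name"].to_numpy(),
            "last_name": base["last_name"].to_numpy(),
            "gender": base["gender"].to_numpy(object),
            "dob": base["dob"].to_numpy(),
            "yob": base["yob"].to_numpy(),
            "age": base["age"].to_numpy(),
            "race": base["race"].to_numpy(),
            "zip": base["zip"].to_numpy(object),
            "mrn": mrn,
            "true_person_id": base["person_id"].to_numpy(),
        }
    )
    return out[RECORD_COLUMNS]


def generate_datasets(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full scenario: (IPD, OPD, truth sidecar mapping record -> person)."""
    persons = generate_population(config)
    ipd = derive_inpatient(persons, config)
    opd = derive_outpatient(persons, config)
    truth = pd.concat(
        [ipd[["record_id", "true_person_id"]], opd[["record_id", "true_person_id"]]],
        ignore_index=True,
    )
    return ipd, opd, truth


def write_datasets(
    ipd: pd.DataFrame, opd: pd.DataFrame, truth: pd.DataFrame, out_dir: str | Path
) -> dict[str, Path]:
    """Write ipd.csv / opd.csv (without the hidden id) and truth.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ipd": out / "ipd.csv",
        "opd": out / "opd.csv",
        "truth": out / "truth.csv",
    }
    public = [c for c in RECORD_COLUMNS if c != "true_person_id"]
    ipd[public].to_csv(paths["ipd"], index=False)
    opd[public].to_csv(paths["opd"], index=False)
    truth.to_csv(paths["truth"], index=False)
    return paths
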