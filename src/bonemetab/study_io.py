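"""Reading, validation and integration of the study tables.

The canonical modelling table is a pandas DataFrame with one row per animal
and a fixed column set:

* ``serum_id`` — serum sample identifier (join key, unique within a table);
* ``animal_id`` — animal identifier (opaque, optional);
* three binary experimental conditions (ECs): ``animal`` (fetus/mother),
  ``treat`` (control/restricted), ``period`` (middle/late gestation);
* six serum bone-turnover proteins: PTH (ng/mL), BALP (mU/mL), BGLAP (ng/mL),
  TRAP (U/L), INTP (ng/mL), CTX-I (ng/mL);
* six bone measurements: Fw/Hw (g), Fl/Hl (mm), Fd/Hd (mm) for femur and
  humerus weight, length and diameter.

Bone-only and serum-only tables use the same schema with the other variable
group absent or NaN; :func:`integrate` inner-joins them on
(serum_id, animal, treat, period) into the modelling table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PROTEINS = ["PTH", "BALP", "BGLAP", "TRAP", "INTP", "CTX-I"]
BONES = ["Fw", "Fl", "Fd", "Hw", "Hl", "Hd"]
EC_AXES = ["animal", "treat", "period"]

#: Canonical category values per EC axis, in fixed order.
EC_LEVELS = {
    "animal": ("fetus", "mother"),
    "treat": ("control", "restricted"),
    "period": ("middle", "late"),
}

#: Accepted spellings -> canonical category value (case-insensitive).
_CATEGORY_ALIASES = {
    "animal": {
        "fetus": "fetus", "foetus": "fetus", "f": "fetus",
        "mother": "mother", "mon": "mother", "maternal": "mother", "m": "mother",
    },
    "treat": {
        "control": "control", "con": "control", "c": "control",
        "restricted": "restricted", "res": "restricted", "r": "restricted",
        "restriction": "restricted",
    },
    "period": {
        "middle": "middle", "mid": "middle", "m": "middle",
        "late": "late", "l": "late",
    },
}

ID_COLUMNS = ["serum_id", "animal_id"]
ALL_COLUMNS = ID_COLUMNS + EC_AXES + PROTEINS + BONES


class SchemaError(ValueError):
    """A required column is missing or the schema map is invalid."""


class ParseError(ValueError):
    """A cell could not be parsed; the message names row and column."""


class IntegrityError(ValueError):
    """Duplicate keys or a one-to-many join match."""


@dataclass
class StudyRecord:
    """One animal: identifiers, ECs, protein panel and bone measurements.

    ``proteins`` / ``bones`` map variable name to value; missing
    measurements are simply absent from the map (never stored as 0).
    """

    serum_id: str
    animal: str
    treat: str
    period: str
    animal_id: str | None = None
    proteins: dict[str, float] = field(default_factory=dict)
    bones: dict[str, float] = field(default_factory=dict)


def canonical_category(axis: str, value: object) -> str:
    """Map a raw EC label (e.g. ``Mon``, ``Con``, ``Mid``) to its canonical value."""
    aliases = _CATEGORY_ALIASES[axis]
    key = str(value).strip().lower()
    if key not in aliases:
        raise ParseError(
            f"unrecognised {axis!r} category {value!r}; "
            f"accepted: {sorted(set(aliases))}"
        )
    return aliases[key]


def _coerce_numeric(df: pd.DataFrame, columns: list[str], required: bool) -> None:
    for col in columns:
        if col not in df.columns:
            continue
        raw = df[col]
        coerced = pd.to_numeric(raw, errors="coerce")
        bad = coerced.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric value {raw.iloc[row]!r} in column {col!r}, row {row}"
            )
        if required and (coerced.dropna() < 0).any():
            raise ParseError(f"negative concentration in column {col!r}")
        df[col] = coerced.astype(float)


def validate_study_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalise a study table in place-free fashion.

    Returns a copy with canonical EC labels, float measurement columns and
    the canonical column order. Raises :class:`SchemaError`,
    :class:`ParseError` or :class:`IntegrityError` on contract violations.
    """
    required = ["serum_id"] + EC_AXES
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")

    out = df.copy()
    out["serum_id"] = out["serum_id"].astype(str)
    if out["serum_id"].duplicated().any():
        dup = out["serum_id"][out["serum_id"].duplicated()].iloc[0]
        raise IntegrityError(f"duplicate serum_id {dup!r}")
    for axis in EC_AXES:
        out[axis] = [canonical_category(axis, v) for v in out[axis]]
    _coerce_numeric(out, PROTEINS, required=True)
    _coerce_numeric(out, BONES, required=False)
    if "animal_id" in out.columns:
        out["animal_id"] = out["animal_id"].astype(str)

    cols = [c for c in ALL_COLUMNS if c in out.columns]
    extra = [c for c in out.columns if c not in cols]
    return out[cols + extra].reset_index(drop=True)


def read_study_table(path, schema: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a CSV study table, mapping file columns to canonical roles.

    Parameters
    ----------
    path : str or Path
        CSV file with a header row.
    schema : dict, optional
        Map of canonical role (``serum_id``, ``animal``, ``PTH``, ``Fw``, ...)
        to the column name used in the file. Roles absent from the map are
        looked up under their canonical name.
    """
    raw = pd.read_csv(path)
    if schema:
        missing = [src for src in schema.values() if src not in raw.columns]
        if missing:
            raise SchemaError(f"schema maps to missing column(s): {missing}")
        raw = raw.rename(columns={src: role for role, src in schema.items()})
    return validate_study_table(raw)


def to_records(df: pd.DataFrame) -> list[StudyRecord]:
    """Convert a validated study table to a list of :class:`StudyRecord`."""
    records = []
    for _, row in df.iterrows():
        proteins = {p: float(row[p]) for p in PROTEINS
                    if p in row.index and pd.notna(row[p])}
        bones = {b: float(row[b]) for b in BONES
                 if b in row.index and pd.notna(row[b])}
        records.append(StudyRecord(
            serum_id=row["serum_id"],
            animal=row["animal"], treat=row["treat"], period=row["period"],
            animal_id=row.get("animal_id"),
            proteins=proteins, bones=bones,
        ))
    return records


def from_records(records: list[StudyRecord]) -> pd.DataFrame:
    """Inverse of :func:`to_records`."""
    rows = []
    for r in records:
        row = {"serum_id": r.serum_id, "animal_id": r.animal_id,
               "animal": r.animal, "treat": r.treat, "period": r.period}
        row.update(r.proteins)
        row.update(r.bones)
        rows.append(row)
    df = pd.DataFrame(rows)
    for col in PROTEINS + BONES:
        if col not in df.columns:
            df[col] = np.nan
    return validate_study_table(df)


JOIN_KEYS = ["serum_id"] + EC_AXES


def integrate(bone_table: pd.DataFrame, serum_table: pd.DataFrame) -> pd.DataFrame:
    """Inner-join bone and serum tables on (serum_id, animal, treat, period).

    Only rows with the complete six-protein panel and at least one bone
    measurement survive; the retained/dropped counts are logged. A join key
    matching more than one row on either side raises :class:`IntegrityError`.
    """
    bone = validate_study_table(bone_table)
    serum = validate_study_table(serum_table)
    for name, tab in (("bone", bone), ("serum", serum)):
        if tab.duplicated(JOIN_KEYS).any():
            raise IntegrityError(f"{name} table has duplicated join keys")

    bone_cols = JOIN_KEYS + (["animal_id"] if "animal_id" in bone.columns else [])
    bone_cols += [b for b in BONES if b in bone.columns]
    serum_cols = JOIN_KEYS + [p for p in PROTEINS if p in serum.columns]
    merged = bone[bone_cols].merge(serum[serum_cols], on=JOIN_KEYS, how="inner",
                                   validate="one_to_one")

    for p in PROTEINS:
        if p not in merged.columns:
            merged[p] = np.nan
    for b in BONES:
        if b not in merged.columns:
            merged[b] = np.nan
    complete_proteins = merged[PROTEINS].notna().all(axis=1)
    any_bone = merged[BONES].notna().any(axis=1)
    kept = merged[complete_proteins & any_bone]
    if kept.empty:
        logger.warning("integrate: empty intersection (bone %d x serum %d rows)",
                       len(bone), len(serum))
    logger.info("integrate: %d bone x %d serum rows -> %d integrated records",
                len(bone), len(serum), len(kept))
    return validate_study_table(kept)


def summarize_groups(df: pd.DataFrame,
                     group_by: list[str] | None = None,
                     variables: list[str] | None = None) -> pd.DataFrame:
    """Descriptive group summaries: mean, SEm and n per EC group per variable.

    SEm is the standard error of the mean, sd/sqrt(n) with the sample
    (n-1 denominator) standard deviation; for a group of size 1 it is
    reported as NaN (absent). ``group_by=None`` summarises the whole table
    as a single group.

    Returns a tidy DataFrame with the grouping columns, ``variable``,
    ``mean``, ``sem`` and ``n``.
    """
    table = validate_study_table(df)
    if variables is None:
        variables = [c for c in PROTEINS + BONES if c in table.columns]
    unknown = [v for v in variables if v not in table.columns]
    if unknown:
        raise SchemaError(f"unknown variable(s): {unknown}")
    if group_by:
        bad = [a for a in group_by if a not in EC_AXES]
        if bad:
            raise SchemaError(f"unknown grouping axis/axes: {bad}")
        grouped = table.groupby(list(group_by), observed=True, sort=True)
    else:
        grouped = [((), table)]

    rows = []
    for key, grp in grouped:
        if not isinstance(key, tuple):
            key = (key,)
        for var in variables:
            vals = grp[var].dropna()
            n = len(vals)
            if n == 0:
                continue
            mean = float(vals.mean())
            sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
            row = dict(zip(group_by or [], key))
            row.update({"variable": var, "mean": mean, "sem": sem, "n": n})
            rows.append(row)
    return pd.DataFrame(rows)
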