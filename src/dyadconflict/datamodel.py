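"""Canonical data model for the dyadic study design.

Three tables describe a study:

* ``adolescents.csv`` — family_id, age_years, gender ({female, male})
* ``parents.csv``     — parent_id, family_id, gender ({father, mother}),
  iip_01..iip_32 (ordinal 0-4), scl_01..scl_17 (ordinal 1-5)
* ``dyads.csv``       — family_id, parent_id, cbq_01..cbq_16 (dichotomous 0/1)

Missing cells are written empty and read as missing; the token ``NA`` is also
accepted on read.  Identifiers are opaque strings with no ordering semantics.
Validation never raises: it returns machine-readable issues (code + location).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

IIP_COLS = [f"iip_{i:02d}" for i in range(1, 33)]
SCL_COLS = [f"scl_{i:02d}" for i in range(1, 18)]
CBQ_COLS = [f"cbq_{i:02d}" for i in range(1, 17)]

_NA_TOKENS = ["", "NA"]


@dataclass
class AdolescentRecord:
    family_id: str
    age_years: int
    gender: str  # female | male

    def __post_init__(self) -> None:
        self.family_id = str(self.family_id)


@dataclass
class ParentRecord:
    parent_id: str
    family_id: str
    gender: str  # father | mother
    iipc_items: np.ndarray  # 32 floats, NaN = missing
    scl_items: np.ndarray  # 17 floats, NaN = missing

    def __post_init__(self) -> None:
        self.parent_id = str(self.parent_id)
        self.family_id = str(self.family_id)
        self.iipc_items = np.asarray(self.iipc_items, dtype=float).reshape(32)
        self.scl_items = np.asarray(self.scl_items, dtype=float).reshape(17)


@dataclass
class DyadRecord:
    family_id: str
    parent_id: str
    cbq_items: np.ndarray  # 16 floats in {0,1}, NaN = missing

    def __post_init__(self) -> None:
        self.family_id = str(self.family_id)
        self.parent_id = str(self.parent_id)
        self.cbq_items = np.asarray(self.cbq_items, dtype=float).reshape(16)


@dataclass
class StudyDataset:
    adolescents: list[AdolescentRecord] = field(default_factory=list)
    parents: list[ParentRecord] = field(default_factory=list)
    dyads: list[DyadRecord] = field(default_factory=list)

    @property
    def n_families(self) -> int:
        return len(self.adolescents)

    def adolescent_by_family(self) -> dict[str, AdolescentRecord]:
        return {a.family_id: a for a in self.adolescents}

    def parent_by_id(self) -> dict[str, ParentRecord]:
        return {p.parent_id: p for p in self.parents}


@dataclass(frozen=True)
class ValidationIssue:
    code: str
    location: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.code}] {self.location}: {self.message}"


class SchemaError(ValueError):
    """A table does not follow the documented column schema."""


class IntegrityError(ValueError):
    """Referential integrity or value-range violation on read."""


def _require_columns(df: pd.DataFrame, cols: Iterable[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing required columns {missing}")


def _check_range(df: pd.DataFrame, cols: list[str], lo: float, hi: float, table: str) -> None:
    block = df[cols].to_numpy(dtype=float)
    bad = np.where(~np.isnan(block) & ((block < lo) | (block > hi) | (block != np.floor(block))))
    if bad[0].size:
        r, c = int(bad[0][0]), int(bad[1][0])
        raise IntegrityError(
            f"{table} row {r}: column {cols[c]} value {block[r, c]} outside "
            f"integer range [{lo}, {hi}]"
        )


def read_dataset(
    adolescent_table: str | Path,
    parent_table: str | Path,
    dyad_table: str | Path,
) -> StudyDataset:
    """Read and validate the three study tables into a :class:`StudyDataset`.

    Missingness is preserved as NaN, never silently filled.  Raises
    :class:`SchemaError` or :class:`IntegrityError` with row locations on
    malformed input.
    """
    kw = dict(dtype={"family_id": str, "parent_id": str}, na_values=_NA_TOKENS,
              keep_default_na=False)
    adol = pd.read_csv(adolescent_table, **kw)
    par = pd.read_csv(parent_table, **kw)
    dy = pd.read_csv(dyad_table, **kw)

    _require_columns(adol, ["family_id", "age_years", "gender"], "adolescents")
    _require_columns(par, ["parent_id", "family_id", "gender"] + IIP_COLS + SCL_COLS, "parents")
    _require_columns(dy, ["family_id", "parent_id"] + CBQ_COLS, "dyads")

    if len(par):
        _check_range(par, IIP_COLS, 0, 4, "parents")
        _check_range(par, SCL_COLS, 1, 5, "parents")
    if len(dy):
        _check_range(dy, CBQ_COLS, 0, 1, "dyads")

    families = set(adol["family_id"])
    parent_ids = set(par["parent_id"])
    for i, row in par.iterrows():
        if row["family_id"] not in families:
            raise IntegrityError(
                f"parents row {i}: family_id {row['family_id']!r} has no adolescent"
            )
    for i, row in dy.iterrows():
        if row["parent_id"] not in parent_ids:
            raise IntegrityError(
                f"dyads row {i}: parent_id {row['parent_id']!r} matches no parent"
            )
        if row["family_id"] not in families:
            raise IntegrityError(
                f"dyads row {i}: family_id {row['family_id']!r} has no adolescent"
            )

    adolescents = [
        AdolescentRecord(r["family_id"], int(r["age_years"]), str(r["gender"]))
        for _, r in adol.iterrows()
    ]
    parents = [
        ParentRecord(
            r["parent_id"], r["family_id"], str(r["gender"]),
            r[IIP_COLS].to_numpy(dtype=float), r[SCL_COLS].to_numpy(dtype=float),
        )
        for _, r in par.iterrows()
    ]
    dyads = [
        DyadRecord(r["family_id"], r["parent_id"], r[CBQ_COLS].to_numpy(dtype=float))
        for _, r in dy.iterrows()
    ]
    return StudyDataset(adolescents, parents, dyads)


def validate_dataset(dataset: StudyDataset) -> list[ValidationIssue]:
    """Check all dataset invariants; returns an empty list iff all hold.

    Issue codes:
    ``DUP_FAMILY``, ``AGE_RANGE``, ``BAD_GENDER``, ``PARENT_CARDINALITY``,
    ``DUP_PARENT_GENDER``, ``ORPHAN_PARENT``, ``ORPHAN_DYAD``, ``DUP_DYAD``,
    ``PARENT_NO_DYAD``, ``ITEM_RANGE``, ``WHOLE_SCALE_MISSING`` (informational).
    """
    issues: list[ValidationIssue] = []
    seen_fam: set[str] = set()
    for a in dataset.adolescents:
        loc = f"adolescent family={a.family_id}"
        if a.family_id in seen_fam:
            issues.append(ValidationIssue("DUP_FAMILY", loc, "duplicate family_id"))
        seen_fam.add(a.family_id)
        if not 13 <= a.age_years <= 17:
            issues.append(ValidationIssue("AGE_RANGE", loc, f"age {a.age_years} outside [13, 17]"))
        if a.gender not in ("female", "male"):
            issues.append(ValidationIssue("BAD_GENDER", loc, f"gender {a.gender!r}"))

    per_family: dict[str, list[ParentRecord]] = {}
    for p in dataset.parents:
        per_family.setdefault(p.family_id, []).append(p)
        loc = f"parent id={p.parent_id}"
        if p.gender not in ("father", "mother"):
            issues.append(ValidationIssue("BAD_GENDER", loc, f"gender {p.gender!r}"))
        if p.family_id not in seen_fam:
            issues.append(ValidationIssue("ORPHAN_PARENT", loc, f"family {p.family_id} has no adolescent"))
        iip, scl = p.iipc_items, p.scl_items
        if np.any(~np.isnan(iip) & ((iip < 0) | (iip > 4))):
            issues.append(ValidationIssue("ITEM_RANGE", loc, "IIP-C item outside 0-4"))
        if np.any(~np.isnan(scl) & ((scl < 1) | (scl > 5))):
            issues.append(ValidationIssue("ITEM_RANGE", loc, "SCL item outside 1-5"))
        if np.all(np.isnan(iip)):
            issues.append(ValidationIssue("WHOLE_SCALE_MISSING", loc, "all 32 IIP-C items missing"))
        if np.all(np.isnan(scl)):
            issues.append(ValidationIssue("WHOLE_SCALE_MISSING", loc, "all 17 SCL items missing"))

    for fam, ps in per_family.items():
        if len(ps) > 2:
            issues.append(ValidationIssue(
                "PARENT_CARDINALITY", f"family={fam}", f"{len(ps)} parents (max 2)"))
        genders = [p.gender for p in ps]
        for g in ("father", "mother"):
            if genders.count(g) > 1:
                issues.append(ValidationIssue(
                    "DUP_PARENT_GENDER", f"family={fam}", f"more than one {g}"))

    parent_ids = {p.parent_id for p in dataset.parents}
    dyad_parents: set[str] = set()
    for d in dataset.dyads:
        loc = f"dyad family={d.family_id} parent={d.parent_id}"
        if d.parent_id not in parent_ids:
            issues.append(ValidationIssue("ORPHAN_DYAD", loc, "parent_id matches no parent"))
        if d.family_id not in seen_fam:
            issues.append(ValidationIssue("ORPHAN_DYAD", loc, "family_id has no adolescent"))
        if d.parent_id in dyad_parents:
            issues.append(ValidationIssue("DUP_DYAD", loc, "parent appears in more than one dyad"))
        dyad_parents.add(d.parent_id)
        cbq = d.cbq_items
        if np.any(~np.isnan(cbq) & (cbq != 0) & (cbq != 1)):
            issues.append(ValidationIssue("ITEM_RANGE", loc, "CBQ item not in {0, 1}"))
        if np.all(np.isnan(cbq)):
            issues.append(ValidationIssue("WHOLE_SCALE_MISSING", loc, "all 16 CBQ items missing"))

    for p in dataset.parents:
        if p.parent_id not in dyad_parents:
            issues.append(ValidationIssue(
                "PARENT_NO_DYAD", f"parent id={p.parent_id}", "parent has no dyad record"))
    return issues


def _fmt(v: float) -> str:
    return "" if np.isnan(v) else str(int(v))


def write_dataset(dataset: StudyDataset, directory: str | Path) -> dict[str, Path]:
    """Write adolescents/parents/dyads CSVs; round-trips exactly through
    :func:`read_dataset`, including missingness (written as empty cells)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    adol = pd.DataFrame(
        [(a.family_id, a.age_years, a.gender) for a in dataset.adolescents],
        columns=["family_id", "age_years", "gender"],
    )
    par = pd.DataFrame(
        [
            [p.parent_id, p.family_id, p.gender]
            + [_fmt(v) for v in p.iipc_items]
            + [_fmt(v) for v in p.scl_items]
            for p in dataset.parents
        ],
        columns=["parent_id", "family_id", "gender"] + IIP_COLS + SCL_COLS,
    )
    dy = pd.DataFrame(
        [
            [d.family_id, d.parent_id] + [_fmt(v) for v in d.cbq_items]
            for d in dataset.dyads
        ],
        columns=["family_id", "parent_id"] + CBQ_COLS,
    )
    paths = {
        "adolescents": directory / "adolescents.csv",
        "parents": directory / "parents.csv",
        "dyads": directory / "dyads.csv",
    }
    adol.to_csv(paths["adolescents"], index=False)
    par.to_csv(paths["parents"], index=False)
    dy.to_csv(paths["dyads"], index=False)
    return paths


def apply_cbq_keying(dataset: StudyDataset, keying: Iterable[int]) -> StudyDataset:
    """Recode conflict items so that 1 is always keyed toward conflict.

    ``keying`` holds +1 (keep) or -1 (reverse-worded: recode y -> 1 - y) per
    item.  The default convention everywhere else in the package is
    all-positive keying; translated forms with reverse-worded items supply
    their map in the config.  Returns a new dataset; missingness is preserved.
    """
    key = np.asarray(list(keying), dtype=int)
    if key.shape != (16,) or not set(np.unique(key)) <= {-1, 1}:
        raise ValueError("keying must give +1 or -1 for each of the 16 items")
    import copy

    out = copy.deepcopy(dataset)
    flip = key == -1
    for d in out.dyads:
        vals = d.cbq_items[flip]
        d.cbq_items[flip] = np.where(np.isnan(vals), np.nan, 1.0 - vals)
    return out


def read_dataset_dir(directory: str | Path) -> StudyDataset:
    """Read the three CSVs written by :func:`write_dataset` from a directory."""
    d = Path(directory)
    return read_dataset(d / "adolescents.csv", d / "parents.csv", d / "dyads.csv")
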