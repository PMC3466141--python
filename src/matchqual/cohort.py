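"""Cohort data model: participants, matched sets, CSV I/O, derived variables.

A cohort holds an index group of cancer survivors plus two candidate
comparison groups: peer-nominated subjects (each survivor may nominate up to
two peers) and a listed sample (at most one commercial-list match per
survivor). Comparison subjects carry a ``survivor_link`` naming the survivor
they are matched to; survivors link to themselves.

Missing values are empty CSV cells and propagate as ``None``; they are never
imputed — each analysis performs per-variable complete-case exclusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import DataError, LinkageError, RowValidationError, SchemaError

GROUPS = ("survivor", "peer", "listed")

#: Canonical participant CSV column order.
COLUMNS = (
    "subject_id",
    "group",
    "survivor_link",
    "sex",
    "race",
    "age",
    "education",
    "employment",
    "days_smoked_30",
    "age_first_cig",
    "age_last_cig",
    "is_current_smoker",
    "alc_freq_month",
    "alc_typical",
    "alc_six_freq",
    "cancer_history",
)

_TRUE = {"true", "t", "1", "yes", "y"}
_FALSE = {"false", "f", "0", "no", "n"}


def derive_smoking_duration(age_first_cig, age_last_cig, current_age, is_current_smoker):
    """Lifetime smoking duration in years, or ``None`` for never-smokers.

    Duration is the difference between age at first and age at last cigarette;
    for current smokers the current age stands in for the age at last
    cigarette. A former smoker with an unknown last age yields ``None``
    (complete-case handling), as does a missing first age.
    """
    if age_first_cig is None:
        return None
    if age_first_cig <= 0:
        raise DataError(f"age_first_cig must be positive, got {age_first_cig}")
    if is_current_smoker:
        if current_age is None:
            return None
        last = current_age
    else:
        if age_last_cig is None:
            return None
        last = age_last_cig
    duration = last - age_first_cig
    if duration < 0:
        raise DataError(
            f"negative smoking duration: first cigarette at {age_first_cig}, "
            f"last at {last}"
        )
    return duration


@dataclass
class Participant:
    """One subject: group label, matched-set linkage, matching variables."""

    subject_id: str
    group: str
    survivor_link: str
    sex: str | None = None
    race: str | None = None
    age: float | None = None
    education: str | None = None
    employment: str | None = None
    days_smoked_30: int | None = None
    age_first_cig: float | None = None
    age_last_cig: float | None = None
    is_current_smoker: bool | None = None
    alc_freq_month: float | None = None
    alc_typical: float | None = None
    alc_six_freq: float | None = None
    cancer_history: bool | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise RowValidationError(
                [(self.subject_id, "group", f"unknown group {self.group!r}")]
            )
        if self.group == "survivor" and not self.survivor_link:
            self.survivor_link = self.subject_id
        problems = []
        if self.age is not None and not self.age > 0:
            problems.append((self.subject_id, "age", f"must be positive, got {self.age}"))
        if self.days_smoked_30 is not None and not 0 <= self.days_smoked_30 <= 30:
            problems.append(
                (self.subject_id, "days_smoked_30", f"must be in [0, 30], got {self.days_smoked_30}")
            )
        for col in ("alc_freq_month", "alc_typical", "alc_six_freq"):
            v = getattr(self, col)
            if v is not None and v < 0:
                problems.append((self.subject_id, col, f"must be non-negative, got {v}"))
        if self.group != "survivor" and not self.survivor_link:
            problems.append((self.subject_id, "survivor_link", "required for comparison subjects"))
        if problems:
            raise RowValidationError(problems)

    @property
    def smoking_duration(self) -> float | None:
        return derive_smoking_duration(
            self.age_first_cig, self.age_last_cig, self.age, self.is_current_smoker
        )


def participant_value(p: Participant, variable: str):
    """Value of a (possibly derived) matching variable for one participant."""
    if variable == "smoking_duration":
        return p.smoking_duration
    if not hasattr(p, variable):
        raise SchemaError(f"unknown variable {variable!r}")
    return getattr(p, variable)


@dataclass(frozen=True)
class MatchedSet:
    """One survivor plus their completed peer(s) and listed match, if any."""

    survivor_id: str
    peer_ids: tuple[str, ...] = ()
    listed_id: str | None = None

    def __post_init__(self) -> None:
        if len(set(self.peer_ids)) != len(self.peer_ids):
            raise LinkageError(f"survivor {self.survivor_id}: duplicate peer ids")
        if len(self.peer_ids) > 2:
            raise LinkageError(
                f"survivor {self.survivor_id}: {len(self.peer_ids)} linked peers (max 2)"
            )


def build_matched_sets(participants) -> list[MatchedSet]:
    """Group validated participants into one MatchedSet per survivor.

    Deterministic and independent of input row order: survivors and peer ids
    are sorted by subject id. Survivors with no comparison subjects yield sets
    with empty match slots.
    """
    survivors = sorted(
        (p.subject_id for p in participants if p.group == "survivor")
    )
    survivor_set = set(survivors)
    peers: dict[str, list[str]] = {}
    listed: dict[str, list[str]] = {}
    for p in participants:
        if p.group == "survivor":
            continue
        if p.survivor_link not in survivor_set:
            raise LinkageError(
                f"{p.group} subject {p.subject_id} links to nonexistent survivor "
                f"{p.survivor_link!r}"
            )
        bucket = peers if p.group == "peer" else listed
        bucket.setdefault(p.survivor_link, []).append(p.subject_id)
    sets = []
    for sid in survivors:
        pid = sorted(peers.get(sid, ()))
        lid = sorted(listed.get(sid, ()))
        if len(pid) > 2:
            raise LinkageError(f"survivor {sid}: {len(pid)} linked peers (max 2)")
        if len(lid) > 1:
            raise LinkageError(f"survivor {sid}: {len(lid)} linked listed subjects (max 1)")
        sets.append(MatchedSet(sid, tuple(pid), lid[0] if lid else None))
    return sets


@dataclass
class CohortTable:
    """Validated participants plus their matched-set structure."""

    participants: dict[str, Participant]
    matched_sets: list[MatchedSet]
    exclusions: list[dict] = field(default_factory=list)

    @classmethod
    def from_participants(cls, participants, exclusions=None) -> "CohortTable":
        participants = list(participants)
        seen: dict[str, Participant] = {}
        for p in participants:
            if p.subject_id in seen:
                raise SchemaError(f"duplicate subject_id {p.subject_id!r}")
            seen[p.subject_id] = p
        sets = build_matched_sets(participants)
        return cls(seen, sets, list(exclusions or ()))

    def __len__(self) -> int:
        return len(self.participants)

    def group(self, name: str) -> list[Participant]:
        return [p for p in self.participants.values() if p.group == name]

    @property
    def survivors(self) -> list[Participant]:
        return self.group("survivor")

    def matched_set_for(self, survivor_id: str) -> MatchedSet:
        for s in self.matched_sets:
            if s.survivor_id == survivor_id:
                return s
        raise LinkageError(f"no matched set for survivor {survivor_id!r}")

    def value(self, subject_id: str, variable: str):
        return participant_value(self.participants[subject_id], variable)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.participants.values():
            rows.append({c: _format_cell(getattr(p, c)) for c in COLUMNS})
        return pd.DataFrame(rows, columns=list(COLUMNS))

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _format_cell(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        if math.isnan(v):
            return ""
        return repr(v)
    return str(v)


def _parse_float(raw: str):
    return float(raw)


def _parse_int(raw: str):
    f = float(raw)
    i = int(round(f))
    if abs(f - i) > 1e-9:
        raise ValueError(f"not an integer: {raw!r}")
    return i


def _parse_bool(raw: str):
    low = raw.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise ValueError(f"not a boolean: {raw!r}")


_PARSERS = {
    "age": _parse_float,
    "days_smoked_30": _parse_int,
    "age_first_cig": _parse_float,
    "age_last_cig": _parse_float,
    "is_current_smoker": _parse_bool,
    "alc_freq_month": _parse_float,
    "alc_typical": _parse_float,
    "alc_six_freq": _parse_float,
    "cancer_history": _parse_bool,
}


def read_cohort(path, varspecs=None) -> CohortTable:
    """Read and validate a participant CSV into a :class:`CohortTable`.

    Comparison-group rows reporting a cancer history fail the eligibility
    screen and are excluded; each exclusion is recorded on
    ``CohortTable.exclusions`` rather than silently dropped.

    Raises
    ------
    SchemaError
        If a required column is missing or a subject id is duplicated.
    RowValidationError
        If any cell fails to parse; lists every offending row.
    LinkageError
        If a comparison subject links to a nonexistent survivor, or matched-set
        cardinality rules are violated.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in COLUMNS if c not in frame.columns]
    if varspecs is not None:
        declared = [s.name for s in varspecs if s.name != "smoking_duration"]
        missing_cols += [c for c in declared if c not in frame.columns and c not in missing_cols]
    if missing_cols:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing_cols)}")

    participants: list[Participant] = []
    exclusions: list[dict] = []
    problems: list[tuple] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        raw = {c: getattr(row, c).strip() for c in COLUMNS}
        kwargs = {}
        row_ok = True
        for col in COLUMNS:
            cell = raw[col]
            if cell == "":
                kwargs[col] = None if col in _PARSERS else (cell if col in ("subject_id", "group", "survivor_link") else None)
                continue
            parser = _PARSERS.get(col)
            if parser is None:
                kwargs[col] = cell
                continue
            try:
                kwargs[col] = parser(cell)
            except ValueError as exc:
                problems.append((i, col, str(exc)))
                row_ok = False
        if not row_ok:
            continue
        if not kwargs.get("subject_id"):
            problems.append((i, "subject_id", "must be non-empty"))
            continue
        kwargs["survivor_link"] = kwargs.get("survivor_link") or ""
        try:
            p = Participant(**kwargs)
        except RowValidationError as exc:
            problems.extend((i, col, msg) for _, col, msg in exc.rows)
            continue
        if p.group != "survivor" and p.cancer_history is True:
            exclusions.append(
                {
                    "subject_id": p.subject_id,
                    "row": i,
                    "reason": "eligibility: comparison subject reports a cancer history",
                }
            )
            continue
        participants.append(p)
    if problems:
        raise RowValidationError(problems)
    return CohortTable.from_participants(participants, exclusions)


def write_cohort(cohort: CohortTable, path) -> None:
    """Write a cohort back to CSV (inverse of :func:`read_cohort`)."""
    cohort.write_csv(path)
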