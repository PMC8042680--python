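"""Rating records and the balanced crossed-design score cube.

Simulation-based assessments of physician performance collect one score per
(person, task, rater, measure): a person (the examinee) manages a simulated
clinical scenario (the task) and is scored by one or more raters on a 1-9
scale, separately for behavioural (non-technical) and technical performance.
Behavioural scores may come with four BARS dimension scores
(vigilance/situation awareness, decision-making, communication, teamwork)
whose mean defines the behavioural total.

The G-study machinery operates on a :class:`RatingCube`: a dense
person x task x rater array for a single measure, requiring the design to be
balanced and fully crossed.  Incomplete designs are a hard error — no
imputation is attempted.
"""

from __future__ import annotations

import csv
import io
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MEASURES",
    "DIMENSION_NAMES",
    "RatingRecord",
    "RatingCube",
    "PairingStudy",
    "SchemaError",
    "ValidationError",
    "DuplicateKeyError",
    "IncompleteDesignError",
    "bars_total",
    "read_ratings",
    "write_ratings",
    "build_cube",
    "cube_to_records",
]

MEASURES = ("behavioural", "technical")

DIMENSION_NAMES = (
    "dim_vigilance",
    "dim_decision",
    "dim_communication",
    "dim_teamwork",
)

DEFAULT_SCHEMA: dict[str, str] = {
    "person_id": "person_id",
    "task_id": "task_id",
    "rater_id": "rater_id",
    "measure": "measure",
    "score": "score",
    **{d: d for d in DIMENSION_NAMES},
}

_BARS_TOL = 1e-9


class SchemaError(ValueError):
    """A required column is missing from the input file."""


class ValidationError(ValueError):
    """A record violates the scale bounds or internal consistency rules."""


class DuplicateKeyError(ValueError):
    """Two records share the same (person, task, rater, measure) key."""


class IncompleteDesignError(ValueError):
    """The records do not form a complete balanced crossed design."""

    def __init__(self, missing: list[tuple[str, str, str]]):
        self.missing = missing
        preview = ", ".join(map(str, missing[:5]))
        more = "" if len(missing) <= 5 else f" (+{len(missing) - 5} more)"
        super().__init__(f"missing (person, task, rater) cells: {preview}{more}")


def bars_total(dimensions: Sequence[float]) -> float:
    """Behavioural total score: the arithmetic mean of the four BARS dimensions.

    Parameters
    ----------
    dimensions
        Exactly four scores, each on the 1-9 scale.
    """
    dims = list(dimensions)
    if len(dims) != 4:
        raise ValidationError(f"BARS requires exactly 4 dimension scores, got {len(dims)}")
    for d in dims:
        if not 1.0 <= float(d) <= 9.0:
            raise ValidationError(f"dimension score {d} outside [1, 9]")
    return float(sum(float(d) for d in dims) / 4.0)


@dataclass(frozen=True)
class RatingRecord:
    """One score given by one rater to one person on one task for one measure."""

    person_id: str
    task_id: str
    rater_id: str
    measure: str
    score: float
    dimensions: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValidationError(
                f"measure must be one of {MEASURES}, got {self.measure!r}"
            )
        if not 1.0 <= self.score <= 9.0:
            raise ValidationError(
                f"score {self.score} outside [1, 9] for "
                f"({self.person_id}, {self.task_id}, {self.rater_id})"
            )
        if self.dimensions is not None:
            expected = bars_total(self.dimensions)
            if abs(expected - self.score) > _BARS_TOL:
                raise ValidationError(
                    f"score {self.score} disagrees with BARS dimension mean "
                    f"{expected} for ({self.person_id}, {self.task_id}, {self.rater_id})"
                )

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.person_id, self.task_id, self.rater_id, self.measure)


@dataclass(frozen=True)
class RatingCube:
    """Balanced person x task x rater score array for a single measure.

    Axis order is (person, task, rater); axis labels are sorted
    lexicographically so every downstream table is deterministic.
    """

    persons: tuple[str, ...]
    tasks: tuple[str, ...]
    raters: tuple[str, ...]
    measure: str
    scores: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        expected = (len(self.persons), len(self.tasks), len(self.raters))
        if self.scores.shape != expected:
            raise ValueError(f"scores shape {self.scores.shape} != {expected}")
        if len(self.persons) < 2 or len(self.tasks) < 1 or len(self.raters) < 1:
            raise ValueError("need n_p >= 2, n_t >= 1, n_r >= 1")
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))

    @property
    def n_p(self) -> int:
        return len(self.persons)

    @property
    def n_t(self) -> int:
        return len(self.tasks)

    @property
    def n_r(self) -> int:
        return len(self.raters)


@dataclass(frozen=True)
class PairingStudy:
    """A scenario pairing: behavioural and technical cubes over the same design."""

    label: str
    cube_behavioural: RatingCube
    cube_technical: RatingCube

    def __post_init__(self) -> None:
        b, t = self.cube_behavioural, self.cube_technical
        if (b.persons, b.tasks, b.raters) != (t.persons, t.tasks, t.raters):
            raise ValueError("behavioural and technical cubes must share the same design")


def _parse_row(
    row: Mapping[str, str], schema: Mapping[str, str], line_no: int
) -> RatingRecord:
    def get(field_name: str) -> str:
        return row[schema[field_name]].strip()

    try:
        score = float(get("score"))
    except ValueError as exc:
        raise ValidationError(f"row {line_no}: score {row[schema['score']]!r} is not a number") from exc

    dims: tuple[float, float, float, float] | None = None
    dim_cols = [schema.get(d) for d in DIMENSION_NAMES]
    if all(c is not None and row.get(c, "").strip() != "" for c in dim_cols):
        try:
            dims = tuple(float(row[c].strip()) for c in dim_cols)  # type: ignore[assignment]
        except ValueError as exc:
            raise ValidationError(f"row {line_no}: non-numeric dimension score") from exc

    try:
        return RatingRecord(
            person_id=get("person_id"),
            task_id=get("task_id"),
            rater_id=get("rater_id"),
            measure=get("measure").lower(),
            score=score,
            dimensions=dims,
        )
    except ValidationError as exc:
        raise ValidationError(f"row {line_no}: {exc}") from exc


def read_ratings(
    path: str | Path | io.TextIOBase,
    schema: Mapping[str, str] | None = None,
) -> list[RatingRecord]:
    """Read and validate long-format rating records from a CSV file.

    The file must have a header row. ``schema`` maps logical field names
    (``person_id``, ``task_id``, ``rater_id``, ``measure``, ``score`` and the
    four optional BARS dimension columns) to the file's column names;
    unspecified entries fall back to the canonical names.

    Raises
    ------
    SchemaError
        if a required column is missing.
    ValidationError
        if a score is out of range or inconsistent with its dimensions.
    DuplicateKeyError
        if two rows share a (person, task, rater, measure) key.
    """
    full_schema = dict(DEFAULT_SCHEMA)
    if schema:
        full_schema.update(schema)

    if isinstance(path, (str, Path)):
        handle = open(path, newline="")
        close = True
    else:
        handle, close = path, False

    try:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise SchemaError("empty file: no header row")
        required = ["person_id", "task_id", "rater_id", "measure", "score"]
        missing = [
            full_schema[f] for f in required if full_schema[f] not in reader.fieldnames
        ]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")

        records: list[RatingRecord] = []
        seen: dict[tuple[str, str, str, str], int] = {}
        for line_no, row in enumerate(reader, start=2):
            rec = _parse_row(row, full_schema, line_no)
            if rec.key in seen:
                raise DuplicateKeyError(
                    f"row {line_no} duplicates key {rec.key} first seen at row {seen[rec.key]}"
                )
            seen[rec.key] = line_no
            records.append(rec)
        return records
    finally:
        if close:
            handle.close()


def write_ratings(records: Iterable[RatingRecord], path: str | Path | io.TextIOBase) -> None:
    """Write records to the canonical long-format CSV (round-trips with read_ratings)."""
    if isinstance(path, (str, Path)):
        handle = open(path, "w", newline="")
        close = True
    else:
        handle, close = path, False
    try:
        writer = csv.writer(handle)
        writer.writerow(list(DEFAULT_SCHEMA.values()))
        for rec in records:
            dims = ["", "", "", ""] if rec.dimensions is None else [repr(d) for d in rec.dimensions]
            writer.writerow(
                [rec.person_id, rec.task_id, rec.rater_id, rec.measure, repr(rec.score), *dims]
            )
    finally:
        if close:
            handle.close()


def build_cube(records: Iterable[RatingRecord], measure: str) -> RatingCube:
    """Assemble the dense crossed cube for one measure.

    Records for other measures are ignored.  Every (person, task, rater)
    combination implied by the observed identifier sets must be present
    exactly once; otherwise :class:`IncompleteDesignError` is raised listing
    the absent cells.
    """
    if measure not in MEASURES:
        raise ValidationError(f"measure must be one of {MEASURES}, got {measure!r}")
    subset = [r for r in records if r.measure == measure]
    if not subset:
        raise IncompleteDesignError([])

    persons = tuple(sorted({r.person_id for r in subset}))
    tasks = tuple(sorted({r.task_id for r in subset}))
    raters = tuple(sorted({r.rater_id for r in subset}))

    by_cell = {(r.person_id, r.task_id, r.rater_id): r.score for r in subset}
    if len(by_cell) != len(subset):
        raise DuplicateKeyError("duplicate (person, task, rater) cell within one measure")

    missing = [
        cell
        for cell in itertools.product(persons, tasks, raters)
        if cell not in by_cell
    ]
    if missing:
        raise IncompleteDesignError(missing)

    scores = np.empty((len(persons), len(tasks), len(raters)))
    for i, p in enumerate(persons):
        for j, t in enumerate(tasks):
            for k, r in enumerate(raters):
                scores[i, j, k] = by_cell[(p, t, r)]
    return RatingCube(persons=persons, tasks=tasks, raters=raters, measure=measure, scores=scores)


def cube_to_records(cube: RatingCube) -> list[RatingRecord]:
    """Flatten a cube back to long-format records (inverse of build_cube)."""
    return [
        RatingRecord(p, t, r, cube.measure, float(cube.scores[i, j, k]))
        for i, p in enumerate(cube.persons)
        for j, t in enumerate(cube.tasks)
        for k, r in enumerate(cube.raters)
    ]
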