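"""Decile scoring of immunohistochemical percent-positivity readings.

Each tumor specimen is stained for four proteins (p53, p16, p27 and
c-erbB2) and the percentage of immunopositive tumor cells is read in five
randomly selected high-power fields.  The five readings are averaged and
the average is binned onto an 11-point decile scale::

    0% -> 0,  (0, 10%] -> 10,  (10, 20%] -> 20,  ...,  (90, 100%] -> 100

Bins are half-open on the left so that fractional five-field averages are
always binnable; 0 is its own bin ("no staining").

This module provides the domain types (:class:`FieldPercentages`,
:class:`MarkerScore`, :class:`SpecimenProfile`), the scoring operations
and the tabular reader for specimen CSV/TSV files.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

N_FIELDS = 5
DECILE_SCORES = tuple(range(0, 101, 10))


class Marker(str, enum.Enum):
    """The four-protein panel used for clonality discrimination."""

    P53 = "p53"
    P16 = "p16"
    P27 = "p27"
    CERBB2 = "cerbB2"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Localization(str, enum.Enum):
    """Subcellular compartment in which positive staining is read."""

    NUCLEAR = "nuclear"
    MEMBRANE = "membrane"


#: Expected staining compartment per marker (metadata only; no
#: computation depends on it).
MARKER_LOCALIZATION: Mapping[Marker, Localization] = {
    Marker.P53: Localization.NUCLEAR,
    Marker.P16: Localization.NUCLEAR,
    Marker.P27: Localization.NUCLEAR,
    Marker.CERBB2: Localization.MEMBRANE,
}

_MARKER_ALIASES = {
    "p53": Marker.P53,
    "p16": Marker.P16,
    "p27": Marker.P27,
    "cerbb2": Marker.CERBB2,
    "c-erbb2": Marker.CERBB2,
    "erbb2": Marker.CERBB2,
    "her2": Marker.CERBB2,
}


def as_marker(value: "Marker | str") -> Marker:
    """Coerce a string (several common spellings accepted) to a Marker."""
    if isinstance(value, Marker):
        return value
    try:
        return _MARKER_ALIASES[str(value).strip().lower()]
    except KeyError:
        raise ValueError(f"unknown marker {value!r}") from None


class LesionRole(str, enum.Enum):
    PRIMARY = "primary"
    SECOND_LESION = "second_lesion"
    LYMPH_NODE_MET = "lymph_node_met"
    DISTANT_MET = "distant_met"


class ValidationError(ValueError):
    """Raised when an input violates a domain invariant."""


@dataclass(frozen=True)
class FieldPercentages:
    """Percent-immunopositive readings from five microscope fields.

    Parameters
    ----------
    values
        Exactly five percentages, each in [0, 100].
    """

    values: tuple[float, ...]

    def __init__(self, values: Iterable[float]):
        vals = tuple(float(v) for v in values)
        if len(vals) != N_FIELDS:
            raise ValidationError(
                f"expected exactly {N_FIELDS} field values, got {len(vals)}"
            )
        for i, v in enumerate(vals):
            if not (0.0 <= v <= 100.0) or math.isnan(v):
                raise ValidationError(
                    f"field {i + 1} value {v!r} outside [0, 100]"
                )
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class MarkerScore:
    """A decile-binned staining score for one marker in one specimen."""

    marker: Marker
    score: int
    localization: Localization | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "marker", as_marker(self.marker))
        if self.score not in DECILE_SCORES:
            raise ValidationError(
                f"score {self.score!r} is not a decile in {{0, 10, ..., 100}}"
            )
        expected = MARKER_LOCALIZATION[self.marker]
        if self.localization is None:
            object.__setattr__(self, "localization", expected)
        elif Localization(self.localization) is not expected:
            raise ValidationError(
                f"{self.marker.value} staining is read as {expected.value}, "
                f"not {Localization(self.localization).value}"
            )


@dataclass(frozen=True)
class SpecimenProfile:
    """The four-marker decile score vector for one lesion."""

    patient_id: str
    lesion_role: LesionRole
    scores: Mapping[Marker, MarkerScore] = field(hash=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "lesion_role", LesionRole(self.lesion_role))
        scores = {as_marker(m): s for m, s in dict(self.scores).items()}
        if len(scores) != len(dict(self.scores)):
            raise ValidationError("duplicate marker in profile")
        missing = [m.value for m in Marker if m not in scores]
        if missing:
            raise ValidationError(f"missing marker(s): {', '.join(missing)}")
        for m, s in scores.items():
            if s.marker is not m:
                raise ValidationError(
                    f"score for {s.marker.value} filed under key {m.value}"
                )
        object.__setattr__(self, "scores", scores)

    def score_of(self, marker: "Marker | str") -> int:
        return self.scores[as_marker(marker)].score


def average_fields(fields: "FieldPercentages | Iterable[float]") -> float:
    """Average the five per-field percent-positive readings.

    Returns the arithmetic mean, a percent in [0, 100].
    """
    if not isinstance(fields, FieldPercentages):
        fields = FieldPercentages(fields)
    return sum(fields.values) / N_FIELDS


def bin_percentage(pct: float) -> int:
    """Bin a percent-positive value onto the decile staining scale.

    0 maps to 0 ("no staining"); any positive percentage maps to
    ``10 * ceil(pct / 10)``, i.e. bins are the half-open intervals
    (0, 10], (10, 20], ..., (90, 100].
    """
    pct = float(pct)
    if not (0.0 <= pct <= 100.0) or math.isnan(pct):
        raise ValidationError(f"percentage {pct!r} outside [0, 100]")
    if pct == 0.0:
        return 0
    return 10 * math.ceil(pct / 10.0)


def score_specimen(
    raw: Mapping["Marker | str", "FieldPercentages | Iterable[float]"],
    patient_id: str,
    lesion_role: "LesionRole | str",
) -> SpecimenProfile:
    """Score a specimen from raw five-field readings for all four markers.

    Each marker's score is ``bin_percentage(average_fields(fields))``.
    Raises :class:`ValidationError` naming any missing or duplicated marker.
    """
    readings: dict[Marker, FieldPercentages] = {}
    for key, fields in raw.items():
        marker = as_marker(key)
        if marker in readings:
            raise ValidationError(f"duplicate readings for marker {marker.value}")
        if not isinstance(fields, FieldPercentages):
            fields = FieldPercentages(fields)
        readings[marker] = fields
    scores = {
        m: MarkerScore(m, bin_percentage(average_fields(f)))
        for m, f in readings.items()
    }
    return SpecimenProfile(patient_id=patient_id, lesion_role=lesion_role, scores=scores)


# ---------------------------------------------------------------------------
# Tabular input: one row per (patient, lesion, marker)
# ---------------------------------------------------------------------------

_FIELD_COLS = [f"field{i}" for i in range(1, 6)]


def _row_score(row: pd.Series, strict: bool) -> int:
    """Resolve one table row to a decile score.

    A row carries exactly one representation: field1..field5, a single
    ``percent``, or a pre-binned ``score``.
    """
    has_fields = all(c in row.index and pd.notna(row[c]) for c in _FIELD_COLS)
    has_pct = "percent" in row.index and pd.notna(row.get("percent"))
    has_score = "score" in row.index and pd.notna(row.get("score"))
    n_reps = sum([has_fields, has_pct, has_score])
    if n_reps != 1:
        raise ValidationError(
            "each row must carry exactly one of field1..field5 / percent / "
            f"score; got {n_reps} representations"
        )
    if has_fields:
        return bin_percentage(average_fields([row[c] for c in _FIELD_COLS]))
    if has_pct:
        return bin_percentage(float(row["percent"]))
    score = float(row["score"])
    if strict and (score != int(score) or int(score) not in DECILE_SCORES):
        raise ValidationError(
            f"pre-binned score {row['score']!r} is not a multiple of 10 in [0, 100]"
        )
    return bin_percentage(score)  # lenient mode re-bins off-scale scores


def read_specimen_table(
    source, *, strict: bool = False
) -> list[SpecimenProfile]:
    """Read specimen profiles from a CSV/TSV file or a DataFrame.

    The table has one row per (patient, lesion, marker) with columns
    ``patient_id``, ``lesion_role``, ``marker`` and exactly one score
    representation per row: ``field1..field5`` (percent per microscope
    field), ``percent`` (single averaged value), or ``score`` (pre-binned
    decile).  Mixed representations across rows are fine.

    With ``strict=True`` a pre-binned score that is not a multiple of 10
    is rejected instead of being re-binned.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep=None, engine="python")
    required = {"patient_id", "lesion_role", "marker"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"missing column(s): {', '.join(sorted(missing))}")

    profiles: list[SpecimenProfile] = []
    for (pid, role), group in df.groupby(["patient_id", "lesion_role"], sort=False):
        scores: dict[Marker, MarkerScore] = {}
        for _, row in group.iterrows():
            marker = as_marker(row["marker"])
            if marker in scores:
                raise ValidationError(
                    f"duplicate marker {marker.value} for patient {pid} ({role})"
                )
            scores[marker] = MarkerScore(marker, _row_score(row, strict))
        profiles.append(
            SpecimenProfile(patient_id=str(pid), lesion_role=LesionRole(role), scores=scores)
        )
    return profiles


def profiles_to_frame(profiles: Sequence[SpecimenProfile]) -> pd.DataFrame:
    """Serialize profiles back to the long table (``score`` representation)."""
    rows = [
        {
            "patient_id": p.patient_id,
            "lesion_role": p.lesion_role.value,
            "marker": m.value,
            "score": p.scores[m].score,
        }
        for p in profiles
        for m in Marker
    ]
    return pd.DataFrame(rows, columns=["patient_id", "lesion_role", "marker", "score"])
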