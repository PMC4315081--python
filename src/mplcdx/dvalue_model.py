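"""The differential-expression (D-value) model and cut-off-90 rule.

For a lesion pair (T1, T2) the per-marker D-value is the absolute
difference of the two decile staining scores, and the total D-value is
the unweighted four-marker sum::

    total = |p16_T1 - p16_T2| + |p27_T1 - p27_T2|
          + |c-erbB2_T1 - c-erbB2_T2| + |p53_T1 - p53_T2|

A pair whose total does not exceed the reference value of 90 is called
metastatic (clonally related, i.e. intrapulmonary metastasis); a total
above 90 is called MPLC (independent primaries).  The threshold and the
boundary rule are configurable but default to total <= 90 -> metastatic.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from typing import Iterator, Mapping

from .ihc_scoring import (
    DECILE_SCORES,
    Marker,
    MarkerScore,
    SpecimenProfile,
    ValidationError,
    as_marker,
)

DEFAULT_THRESHOLD = 90
MAX_TOTAL = 400


class Call(str, enum.Enum):
    """The model's diagnostic call for a lesion pair."""

    MPLC = "MPLC"
    METASTATIC = "metastatic"


class BoundaryRule(str, enum.Enum):
    """What happens when the total equals the threshold exactly.

    ``LE_IS_METASTATIC`` (default): total <= threshold -> metastatic.
    ``LT_IS_METASTATIC``: total < threshold -> metastatic (a total equal
    to the threshold is called MPLC).
    """

    LE_IS_METASTATIC = "le_is_metastatic"
    LT_IS_METASTATIC = "lt_is_metastatic"


@dataclass(frozen=True)
class PairDValue:
    """Per-marker absolute score differences and their sum for one pair."""

    patient_id: str
    per_marker: Mapping[Marker, int]
    total: int

    def __post_init__(self) -> None:
        per_marker = {as_marker(m): int(v) for m, v in dict(self.per_marker).items()}
        missing = [m.value for m in Marker if m not in per_marker]
        if missing:
            raise ValidationError(f"missing marker(s): {', '.join(missing)}")
        for m, v in per_marker.items():
            if v not in DECILE_SCORES:
                raise ValidationError(
                    f"{m.value} D-value {v} is not a decile in [0, 100]"
                )
        object.__setattr__(self, "per_marker", per_marker)
        object.__setattr__(self, "total", int(self.total))
        if self.total != sum(per_marker.values()):
            raise ValidationError(
                f"total {self.total} != sum of per-marker D-values "
                f"{sum(per_marker.values())}"
            )

    @classmethod
    def from_dvalues(
        cls, per_marker: Mapping["Marker | str", int], patient_id: str = ""
    ) -> "PairDValue":
        per_marker = {as_marker(m): int(v) for m, v in per_marker.items()}
        return cls(patient_id, per_marker, sum(per_marker.values()))


@dataclass(frozen=True)
class Classification:
    """A diagnostic call together with the threshold that produced it."""

    call: Call
    total: int
    threshold: int = DEFAULT_THRESHOLD
    boundary: BoundaryRule = BoundaryRule.LE_IS_METASTATIC


def marker_dvalue(s1: MarkerScore, s2: MarkerScore) -> int:
    """Absolute difference of two decile scores for the same marker."""
    if s1.marker is not s2.marker:
        raise ValidationError(
            f"marker mismatch: {s1.marker.value} vs {s2.marker.value}"
        )
    return abs(s1.score - s2.score)


def total_dvalue(
    t1: SpecimenProfile,
    t2: SpecimenProfile,
    *,
    allow_patient_mismatch: bool = False,
) -> PairDValue:
    """Per-marker D-values and their four-marker sum for a lesion pair.

    The two profiles must belong to the same patient unless
    ``allow_patient_mismatch`` is set (exploratory use).
    """
    if t1.patient_id != t2.patient_id and not allow_patient_mismatch:
        raise ValidationError(
            f"profiles belong to different patients "
            f"({t1.patient_id!r} vs {t2.patient_id!r})"
        )
    per_marker = {m: marker_dvalue(t1.scores[m], t2.scores[m]) for m in Marker}
    return PairDValue(t1.patient_id, per_marker, sum(per_marker.values()))


def classify(
    pair: "PairDValue | int",
    threshold: int = DEFAULT_THRESHOLD,
    boundary: "BoundaryRule | str" = BoundaryRule.LE_IS_METASTATIC,
) -> Classification:
    """Apply the cut-off rule to a pair's total D-value.

    With the defaults a total <= 90 is called metastatic and a total
    > 90 is called MPLC.  Accepts either a :class:`PairDValue` or a bare
    total.
    """
    threshold = int(threshold)
    if threshold < 0:
        raise ValidationError(f"threshold must be non-negative, got {threshold}")
    boundary = BoundaryRule(boundary)
    total = pair.total if isinstance(pair, PairDValue) else int(pair)
    if not (0 <= total <= MAX_TOTAL):
        raise ValidationError(f"total {total} outside [0, {MAX_TOTAL}]")
    if boundary is BoundaryRule.LE_IS_METASTATIC:
        is_met = total <= threshold
    else:
        is_met = total < threshold
    call = Call.METASTATIC if is_met else Call.MPLC
    return Classification(call=call, total=total, threshold=threshold, boundary=boundary)


def iter_dvalue_combinations() -> Iterator[PairDValue]:
    """Enumerate all 11**4 per-marker decile D-value combinations."""
    for combo in itertools.product(DECILE_SCORES, repeat=len(Marker)):
        yield PairDValue.from_dvalues(dict(zip(Marker, combo)))


def pair_profiles(
    profiles: "list[SpecimenProfile]",
) -> list[tuple[SpecimenProfile, SpecimenProfile]]:
    """Form (primary, other-lesion) pairs per patient.

    A patient with more than two lesions yields one pair per non-primary
    lesion; no patient-level call is synthesized from conflicting
    pairwise calls.
    """
    by_patient: dict[str, list[SpecimenProfile]] = {}
    for p in profiles:
        by_patient.setdefault(p.patient_id, []).append(p)
    pairs = []
    for pid, lesions in by_patient.items():
        primaries = [p for p in lesions if p.lesion_role.value == "primary"]
        others = [p for p in lesions if p.lesion_role.value != "primary"]
        if len(primaries) != 1 or not others:
            raise ValidationError(
                f"patient {pid}: need exactly one primary and >=1 other lesion "
                f"(got {len(primaries)} primary, {len(others)} other)"
            )
        pairs.extend((primaries[0], other) for other in others)
    return pairs


def min_mplc_total(threshold: int = DEFAULT_THRESHOLD) -> int:
    """Smallest achievable total D-value classified MPLC.

    Totals are sums of four decile values, hence multiples of 10 in
    [0, 400].  For a threshold that is itself a multiple of 10 this is
    ``10 * (threshold // 10 + 1)``.  Raises :class:`ValidationError` if
    no achievable total exceeds the threshold (threshold >= 400).
    """
    if threshold < 0:
        raise ValidationError(f"threshold must be non-negative, got {threshold}")
    achievable = range(0, MAX_TOTAL + 1, 10)
    for total in achievable:
        if classify(total, threshold).call is Call.MPLC:
            return total
    raise ValidationError(
        f"no achievable total (max {MAX_TOTAL}) exceeds threshold {threshold}"
    )
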