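"""Published control data, packaged as loadable fixtures.

Three printed tables from the source study are compiled in verbatim:

* the 30 lymph-node-metastasis control cases with per-marker and total
  D-values (the negative-control group used to calibrate the cut-off),
* the 2x2 reclassification table of model calls against the clinical
  Martini-Melamed diagnosis (56 multifocal patients), and
* the cohort group sizes.

One printed row is internally inconsistent (case 13: per-marker values
sum to 50 but the printed total is 30).  Both numbers are stored
verbatim; :func:`validate_totals` surfaces the discrepancy and all
downstream statistics use recomputed sums, never printed totals.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .dvalue_model import PairDValue
from .ihc_scoring import Marker, as_marker

# Per-case rows: (case_no, p16, erbB2, p27, p53, printed_total), in the
# column order of the published table.
_TABLE2_ROWS: tuple[tuple[int, int, int, int, int, int], ...] = (
    (1, 10, 10, 0, 0, 20),
    (2, 10, 10, 20, 20, 60),
    (3, 0, 20, 10, 10, 40),
    (4, 20, 10, 10, 0, 40),
    (5, 40, 10, 20, 20, 90),
    (6, 10, 0, 0, 30, 40),
    (7, 30, 0, 0, 10, 40),
    (8, 0, 0, 40, 40, 80),
    (9, 40, 0, 10, 0, 50),
    (10, 10, 0, 0, 0, 10),
    (11, 10, 0, 10, 40, 60),
    (12, 0, 10, 10, 0, 20),
    (13, 20, 10, 0, 20, 30),
    (14, 30, 10, 20, 0, 60),
    (15, 40, 0, 30, 10, 80),
    (16, 20, 0, 0, 40, 60),
    (17, 10, 0, 0, 0, 10),
    (18, 20, 0, 0, 0, 20),
    (19, 20, 10, 20, 20, 70),
    (20, 0, 0, 10, 0, 10),
    (21, 20, 20, 0, 0, 40),
    (22, 0, 0, 30, 10, 40),
    (23, 10, 20, 0, 0, 30),
    (24, 10, 0, 10, 0, 20),
    (25, 0, 30, 20, 30, 80),
    (26, 20, 0, 0, 20, 40),
    (27, 30, 0, 20, 10, 60),
    (28, 10, 10, 30, 30, 80),
    (29, 20, 0, 0, 0, 20),
    (30, 0, 0, 0, 20, 20),
)

# 2x2 reclassification counts, rows = model call, columns = clinical call.
_TABLE3_COUNTS = {
    ("MPLC", "MPLC"): 29,
    ("MPLC", "IPM"): 6,
    ("IPM", "MPLC"): 7,
    ("IPM", "IPM"): 14,
}


class CohortGroup(str, enum.Enum):
    INTRAPULMONARY_MET = "intrapulmonary_met"
    DISTANT_MET = "distant_met"
    LYMPH_NODE_MET = "lymph_node_met"
    MPLC_SAME_HISTOLOGY = "mplc_same_histology"
    MPLC_DIFFERENT_HISTOLOGY = "mplc_different_histology"


_COHORT_SIZES: Mapping[CohortGroup, int] = {
    CohortGroup.INTRAPULMONARY_MET: 20,
    CohortGroup.DISTANT_MET: 11,
    CohortGroup.LYMPH_NODE_MET: 30,
    CohortGroup.MPLC_SAME_HISTOLOGY: 36,
    CohortGroup.MPLC_DIFFERENT_HISTOLOGY: 14,
}


@dataclass(frozen=True)
class ControlCase:
    """One lymph-node-metastasis control pair, as printed."""

    case_no: int
    per_marker: Mapping[Marker, int]
    printed_total: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "per_marker", {as_marker(m): int(v) for m, v in dict(self.per_marker).items()}
        )
        for m, v in self.per_marker.items():
            if v % 10 or not (0 <= v <= 100):
                raise ValueError(f"case {self.case_no}: {m.value} D-value {v} off-scale")
        if self.printed_total % 10 or not (0 <= self.printed_total <= 400):
            raise ValueError(
                f"case {self.case_no}: printed total {self.printed_total} off-scale"
            )

    @property
    def recomputed_total(self) -> int:
        return sum(self.per_marker.values())

    def as_pair_dvalue(self) -> PairDValue:
        """The case as a model PairDValue (recomputed total, not printed)."""
        return PairDValue.from_dvalues(self.per_marker, patient_id=f"LN{self.case_no:02d}")


@dataclass(frozen=True)
class Discrepancy:
    """A case whose printed total disagrees with its printed row sum."""

    case_no: int
    recomputed: int
    printed: int


@dataclass(frozen=True)
class CohortSummary:
    group: CohortGroup
    n_patients: int

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")


def load_table2() -> list[ControlCase]:
    """The 30 lymph-node-metastasis control cases, values as printed."""
    return [
        ControlCase(
            case_no=no,
            per_marker={
                Marker.P16: p16,
                Marker.CERBB2: erbb2,
                Marker.P27: p27,
                Marker.P53: p53,
            },
            printed_total=total,
        )
        for no, p16, erbb2, p27, p53, total in _TABLE2_ROWS
    ]


def validate_totals(cases: Sequence[ControlCase]) -> list[Discrepancy]:
    """Flag every case whose printed total differs from its row sum.

    Downstream statistics always use recomputed sums; this check exists
    so the one known misprint is surfaced rather than silently fixed.
    """
    return [
        Discrepancy(c.case_no, c.recomputed_total, c.printed_total)
        for c in cases
        if c.recomputed_total != c.printed_total
    ]


def control_pair_dvalues() -> list[PairDValue]:
    """Table-2 controls as PairDValues with recomputed totals."""
    return [c.as_pair_dvalue() for c in load_table2()]


def load_table3():
    """The published 2x2 reclassification table (model call x clinical)."""
    from .concordance import ReclassificationTable

    return ReclassificationTable(counts=dict(_TABLE3_COUNTS))


def load_cohort_sizes() -> list[CohortSummary]:
    """Published group sizes of the five patient cohorts."""
    return [CohortSummary(g, n) for g, n in _COHORT_SIZES.items()]


def table2_to_specimen_frame() -> pd.DataFrame:
    """Export the control cases in the specimen-table CSV dialect.

    The raw per-specimen scores behind the control table were never
    published, so this is a synthetic score-preserving embedding: for
    each case the primary lesion carries the printed D-value as its
    score and the lymph-node lesion carries 0, which reproduces every
    per-marker D-value and total exactly when fed through the scoring
    pipeline.
    """
    rows = []
    for case in load_table2():
        pid = f"LN{case.case_no:02d}"
        for marker, dval in case.per_marker.items():
            rows.append((pid, "primary", marker.value, dval))
            rows.append((pid, "lymph_node_met", marker.value, 0))
    return pd.DataFrame(rows, columns=["patient_id", "lesion_role", "marker", "score"])
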