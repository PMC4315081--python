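"""Agreement between model calls and the clinical Martini-Melamed diagnosis.

Builds 2x2 reclassification tables (model call x clinical label),
computes percent agreement, Cohen's kappa and per-clinical-group
concordant fractions, and sweeps the classification threshold over the
two control groups to trace the classifier's operating characteristics.

Percent agreement and kappa are standard derived summaries of the
reclassification table; the source study reports only the raw counts
and per-group fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .dvalue_model import Call, Classification, PairDValue, classify
from .ihc_scoring import ValidationError

#: Clinical diagnosis labels. "IPM" is the clinical counterpart of the
#: model's "metastatic" call.
CLINICAL_LABELS = ("MPLC", "IPM")

_CALL_TO_LABEL = {Call.MPLC: "MPLC", Call.METASTATIC: "IPM"}


@dataclass(frozen=True)
class ReclassificationTable:
    """2x2 counts indexed (model call, clinical diagnosis) in {MPLC, IPM}."""

    counts: Mapping[tuple[str, str], int]

    def __post_init__(self) -> None:
        counts = {}
        for model in CLINICAL_LABELS:
            for clinical in CLINICAL_LABELS:
                v = int(dict(self.counts).get((model, clinical), 0))
                if v < 0:
                    raise ValidationError(f"negative count at ({model}, {clinical})")
                counts[(model, clinical)] = v
        extra = set(dict(self.counts)) - set(counts)
        if extra:
            raise ValidationError(f"unknown cell(s): {sorted(extra)}")
        object.__setattr__(self, "counts", counts)

    def __getitem__(self, key: tuple[str, str]) -> int:
        return self.counts[key]

    def model_margin(self, call: str) -> int:
        return sum(self.counts[(call, c)] for c in CLINICAL_LABELS)

    def clinical_margin(self, label: str) -> int:
        return sum(self.counts[(m, label)] for m in CLINICAL_LABELS)

    @property
    def grand_total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[self.counts[(m, c)] for c in CLINICAL_LABELS] for m in CLINICAL_LABELS],
            index=pd.Index(CLINICAL_LABELS, name="model"),
            columns=pd.Index(CLINICAL_LABELS, name="clinical"),
        )


@dataclass(frozen=True)
class AgreementReport:
    table: ReclassificationTable
    percent_agreement: float
    cohen_kappa: float
    per_group_fractions: Mapping[str, float]


@dataclass(frozen=True)
class SweepPoint:
    """Operating characteristics of the classifier at one threshold.

    Sensitivity is taken with "metastatic" as the positive class: the
    fraction of known-metastatic control pairs called metastatic.
    Specificity is the fraction of known-independent (MPLC) control
    pairs called MPLC.
    """

    threshold: int
    sensitivity_metastatic: float
    specificity_metastatic: float


def call_label(classification: Classification) -> str:
    """Map a model call onto the clinical label vocabulary (MPLC/IPM)."""
    return _CALL_TO_LABEL[classification.call]


def build_reclassification(
    calls: Sequence[Classification],
    clinical: Sequence[str],
) -> ReclassificationTable:
    """Cross-tabulate model calls against clinical diagnoses."""
    if len(calls) != len(clinical):
        raise ValidationError(
            f"{len(calls)} calls vs {len(clinical)} clinical labels"
        )
    counts = {(m, c): 0 for m in CLINICAL_LABELS for c in CLINICAL_LABELS}
    for call, label in zip(calls, clinical):
        if label not in CLINICAL_LABELS:
            raise ValidationError(f"unknown clinical label {label!r}")
        counts[(call_label(call), label)] += 1
    return ReclassificationTable(counts)


def agreement(table: ReclassificationTable) -> AgreementReport:
    """Percent agreement, Cohen's kappa and per-group concordant fractions.

    Kappa uses the standard chance-corrected 2x2 formula
    ``(po - pe) / (1 - pe)``; a degenerate table with ``pe == 1`` gets
    kappa 1.0 if agreement is perfect, else 0.0.
    """
    n = table.grand_total
    if n == 0:
        raise ValidationError("empty reclassification table")
    po = sum(table[(lab, lab)] for lab in CLINICAL_LABELS) / n
    pe = sum(
        table.model_margin(lab) * table.clinical_margin(lab) for lab in CLINICAL_LABELS
    ) / (n * n)
    if pe == 1.0:
        kappa = 1.0 if po == 1.0 else 0.0
    else:
        kappa = (po - pe) / (1.0 - pe)
    fractions = {}
    for lab in CLINICAL_LABELS:
        margin = table.clinical_margin(lab)
        if margin:
            fractions[lab] = table[(lab, lab)] / margin
    return AgreementReport(
        table=table,
        percent_agreement=100.0 * po,
        cohen_kappa=kappa,
        per_group_fractions=fractions,
    )


def threshold_sweep(
    metastatic_controls: Sequence[PairDValue],
    mplc_controls: Sequence[PairDValue],
    thresholds: Iterable[int] = range(0, 401, 10),
) -> list[SweepPoint]:
    """Sensitivity/specificity of the cut-off rule across thresholds.

    ``metastatic_controls`` are pairs of known shared clonality (lymph
    node / distant metastases); ``mplc_controls`` are pairs of known
    independent origin (different-histology MPLCs).  Thresholds should
    be multiples of 10 since every achievable total is; intermediate
    values are redundant.
    """
    metastatic_controls = list(metastatic_controls)
    mplc_controls = list(mplc_controls)
    if not metastatic_controls or not mplc_controls:
        raise ValidationError("both control groups must be non-empty")
    points = []
    for thr in thresholds:
        sens = sum(
            classify(p, thr).call is Call.METASTATIC for p in metastatic_controls
        ) / len(metastatic_controls)
        spec = sum(
            classify(p, thr).call is Call.MPLC for p in mplc_controls
        ) / len(mplc_controls)
        points.append(
            SweepPoint(threshold=int(thr), sensitivity_metastatic=sens, specificity_metastatic=spec)
        )
    return points


def sweep_to_frame(points: Sequence[SweepPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (p.threshold, p.sensitivity_metastatic, p.specificity_metastatic)
            for p in points
        ],
        columns=["threshold", "sensitivity_metastatic", "specificity_metastatic"],
    )
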