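"""Synthetic tumor-pair generator for pipeline testing and calibration.

Emulates the two mechanisms by which histologically similar multifocal
lung tumors arise.  A *clonal* pair (metastasis-like) shares one
underlying marker profile: the second lesion's percent positivity per
marker is the first lesion's value plus Gaussian drift, clipped to
[0, 100].  An *independent* pair (MPLC-like, field cancerization) draws
the two lesions' profiles separately from the same marker-specific
positivity laws.

Per-marker positivity follows a zero-inflated Beta law: with probability
``zero_inflation`` the specimen is fully negative (0%), otherwise the
percent positive is 100 * Beta(alpha, beta).  The default inflation
weights are loose translations of reported NSCLC marker prevalences
(p53 positive in ~50%, p16 ~50%, p27 retained in ~25%, c-erbB2 positive
in ~37%) with a dispersed Beta(0.8, 0.8) positive part.  These defaults
are a test harness, not a fitted model: the raw per-specimen scores
behind the published control groups were never released, so the
generator cannot be validated against real staining data.

All randomness flows from a single integer seed through one
``numpy.random.Generator``; cohorts are exactly reproducible.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .ihc_scoring import (
    LesionRole,
    Marker,
    SpecimenProfile,
    ValidationError,
    as_marker,
    score_specimen,
)

DEFAULT_DRIFT_SD = 5.0  # percent units


class PairRelation(str, enum.Enum):
    CLONAL = "clonal"  # shared origin -> metastasis-like
    INDEPENDENT = "independent"  # field cancerization -> MPLC-like


#: True label strings matching the clinical vocabulary used downstream.
RELATION_LABEL = {PairRelation.CLONAL: "IPM", PairRelation.INDEPENDENT: "MPLC"}


@dataclass(frozen=True)
class MarkerDistribution:
    """Zero-inflated Beta law for one marker's percent positivity."""

    marker: Marker
    zero_inflation: float
    alpha: float = 0.8
    beta: float = 0.8

    def __post_init__(self) -> None:
        object.__setattr__(self, "marker", as_marker(self.marker))
        if not (0.0 <= self.zero_inflation <= 1.0):
            raise ValidationError(
                f"zero_inflation {self.zero_inflation} outside [0, 1]"
            )
        if self.alpha <= 0 or self.beta <= 0:
            raise ValidationError("Beta shape parameters must be positive")


def default_marker_distributions() -> dict[Marker, MarkerDistribution]:
    """Synthetic default positivity laws for the four-marker panel."""
    inflation = {
        Marker.P53: 0.50,  # ~50% of NSCLC p53-positive
        Marker.P16: 0.50,
        Marker.P27: 0.75,  # p27 expression retained in only ~25%
        Marker.CERBB2: 0.63,  # c-erbB2 overexpressed in ~37%
    }
    return {m: MarkerDistribution(m, zero_inflation=z) for m, z in inflation.items()}


@dataclass(frozen=True)
class PairGenParams:
    """Generation settings for one lesion pair or a whole cohort."""

    relation: PairRelation = PairRelation.CLONAL
    drift_sd: float = DEFAULT_DRIFT_SD
    marker_dists: Mapping[Marker, MarkerDistribution] = field(
        default_factory=default_marker_distributions
    )
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "relation", PairRelation(self.relation))
        if self.drift_sd < 0:
            raise ValidationError(f"drift_sd must be >= 0, got {self.drift_sd}")
        dists = {as_marker(m): d for m, d in dict(self.marker_dists).items()}
        missing = [m.value for m in Marker if m not in dists]
        if missing:
            raise ValidationError(f"missing marker distribution(s): {', '.join(missing)}")
        object.__setattr__(self, "marker_dists", dists)


def sample_specimen_percent(dist: MarkerDistribution, rng: np.random.Generator) -> float:
    """Draw one specimen's percent positivity for one marker."""
    if rng.random() < dist.zero_inflation:
        return 0.0
    return float(100.0 * rng.beta(dist.alpha, dist.beta))


def _sample_profile_percents(
    params: PairGenParams, rng: np.random.Generator
) -> dict[Marker, float]:
    return {m: sample_specimen_percent(d, rng) for m, d in params.marker_dists.items()}


def generate_pair(
    params: PairGenParams,
    rng: np.random.Generator,
    patient_id: str = "S1",
) -> tuple[SpecimenProfile, SpecimenProfile, str]:
    """Generate one labeled lesion pair (T1 primary, T2 second lesion).

    Returns the two decile-scored profiles and the true label, "IPM" for
    clonal pairs and "MPLC" for independent pairs.
    """
    t1_pct = _sample_profile_percents(params, rng)
    if params.relation is PairRelation.CLONAL:
        t2_pct = {
            m: float(np.clip(p + rng.normal(0.0, params.drift_sd), 0.0, 100.0))
            if params.drift_sd > 0
            else p
            for m, p in t1_pct.items()
        }
    else:
        t2_pct = _sample_profile_percents(params, rng)
    t1 = score_specimen(
        {m: (p,) * 5 for m, p in t1_pct.items()}, patient_id, LesionRole.PRIMARY
    )
    t2 = score_specimen(
        {m: (p,) * 5 for m, p in t2_pct.items()}, patient_id, LesionRole.SECOND_LESION
    )
    return t1, t2, RELATION_LABEL[params.relation]


def generate_cohort(
    n_clonal: int,
    n_independent: int,
    params: PairGenParams | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a labeled cohort in the pipeline's tabular formats.

    Returns ``(specimens, labels)``: the specimen table (one row per
    patient/lesion/marker, ``score`` representation, two lesions per
    patient) and a sidecar with one row per patient carrying the true
    label.  The same seed always yields byte-identical tables.
    """
    if n_clonal < 0 or n_independent < 0:
        raise ValidationError("group sizes must be non-negative")
    if n_clonal + n_independent == 0:
        raise ValidationError("at least one pair must be requested")
    if params is None:
        params = PairGenParams()
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)

    spec_rows, label_rows = [], []
    plan = [(PairRelation.CLONAL, n_clonal), (PairRelation.INDEPENDENT, n_independent)]
    idx = 0
    for relation, count in plan:
        pair_params = replace(params, relation=relation)
        for _ in range(count):
            idx += 1
            pid = f"SIM{idx:04d}"
            t1, t2, label = generate_pair(pair_params, rng, patient_id=pid)
            for lesion in (t1, t2):
                for m in Marker:
                    spec_rows.append(
                        (pid, lesion.lesion_role.value, m.value, lesion.score_of(m))
                    )
            label_rows.append((pid, label, relation.value))
    specimens = pd.DataFrame(
        spec_rows, columns=["patient_id", "lesion_role", "marker", "score"]
    )
    labels = pd.DataFrame(label_rows, columns=["patient_id", "true_label", "relation"])
    return specimens, labels
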