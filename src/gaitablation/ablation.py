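"""The eight canonical sensor-ablation cases and effect-size comparison.

Each case restricts the 44-feature set to the features derived from a
subset of sensors, re-runs the full normalize -> PCA -> SVM pipeline
per subject, and the per-(subject, fold) accuracies of each case pair
are compared with Cohen's d (pooled-SD standardised mean difference).

Cases 1-6 keep every feature family of each retained combined
sEMG+accelerometer unit; Cases 7-8 are accelerometer-only (ACC
features).  Force-plate features appear only in Cases 1, 4 and 5.
The thigh accelerometer of Case 7 sits on the vastus medialis and the
shank accelerometer on the tibialis anterior (configurable via custom
cases).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classifier import CVResult, SVMConfig, cross_validate
from .features import FeatureMatrix, FeatureSpec, subset_features
from .synthetic_data import MUSCLE_SEGMENT, SIDES

__all__ = [
    "CaseDefinition",
    "AblationResult",
    "CANONICAL_CASES",
    "case_feature_spec",
    "run_ablation",
    "cohens_d",
    "effect_size_label",
]

_LOWER = ("gastrocnemius", "tibialis_anterior")
_UPPER = ("hamstring", "vastus_medialis")


def _units(muscles: Sequence[str]) -> tuple[tuple[str, str], ...]:
    return tuple((m, s) for m in muscles for s in SIDES)


@dataclass(frozen=True)
class CaseDefinition:
    """One ablation case: which units, families and plates survive."""

    case_id: int
    description: str
    accel_units: tuple[tuple[str, str], ...]  # (muscle, side) with ACC features
    semg_units: tuple[tuple[str, str], ...]  # (muscle, side) with MF + H bins
    force_plates: bool


CANONICAL_CASES: dict[int, CaseDefinition] = {
    1: CaseDefinition(1, "all sensors", _units(_LOWER + _UPPER), _units(_LOWER + _UPPER), True),
    2: CaseDefinition(2, "upper leg", _units(_UPPER), _units(_UPPER), False),
    3: CaseDefinition(3, "lower leg", _units(_LOWER), _units(_LOWER), False),
    4: CaseDefinition(4, "upper leg + force plates", _units(_UPPER), _units(_UPPER), True),
    5: CaseDefinition(5, "lower leg + force plates", _units(_LOWER), _units(_LOWER), True),
    6: CaseDefinition(6, "gastrocnemius only", _units(("gastrocnemius",)), _units(("gastrocnemius",)), False),
    7: CaseDefinition(
        7,
        "one accelerometer per leg segment",
        _units(("vastus_medialis", "tibialis_anterior")),
        (),
        False,
    ),
    8: CaseDefinition(8, "one accelerometer per shank", _units(("tibialis_anterior",)), (), False),
}


def case_feature_spec(case: CaseDefinition) -> list[FeatureSpec]:
    """Feature columns for one case, in canonical full-set order."""
    specs: list[FeatureSpec] = []
    for muscle, side in case.accel_units:
        cid = f"accel_{muscle}_{side}"
        specs.append(FeatureSpec(f"ACC_{cid}", "ACC", cid))
    if case.force_plates:
        for side in SIDES:
            specs.append(FeatureSpec(f"FPM_force_{side}", "FPM", f"force_{side}"))
        for side in SIDES:
            specs.append(FeatureSpec(f"FPSD_force_{side}", "FPSD", f"force_{side}"))
    for muscle, side in case.semg_units:
        cid = f"semg_{muscle}_{side}"
        specs.append(FeatureSpec(f"MF_{cid}", "MF", cid))
    for muscle, side in case.semg_units:
        cid = f"semg_{muscle}_{side}"
        specs += [FeatureSpec(f"{h}_{cid}", h, cid) for h in ("H1", "H2", "H3")]
    for muscle, _ in case.accel_units + case.semg_units:
        if muscle not in MUSCLE_SEGMENT:
            raise ValueError(f"unknown muscle {muscle!r}")
    return specs


@dataclass
class AblationResult:
    """Per-case CV results plus the pairwise effect-size table."""

    case_results: dict[int, dict[str, CVResult]]
    accuracies: pd.DataFrame  # columns: case, subject, fold, accuracy, accuracy_merged
    effect_sizes: pd.DataFrame = field(default_factory=pd.DataFrame)

    def case_median(self, case_id: int, merged: bool = True) -> float:
        col = "accuracy_merged" if merged else "accuracy"
        return float(self.accuracies.loc[self.accuracies["case"] == case_id, col].median())


def cohens_d(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Standardised mean difference with the pooled-SD denominator.

    d = (mean_a - mean_b) / s_p with
    s_p = sqrt(((n_a-1) s_a^2 + (n_b-1) s_b^2) / (n_a + n_b - 2)).
    Returns NaN (undefined) when the pooled SD is zero.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.sqrt(
        ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (a.size + b.size - 2)
    )
    if pooled == 0:
        return float("nan")
    return float((a.mean() - b.mean()) / pooled)


def effect_size_label(d: float) -> str:
    """Conventional magnitude labels: 0.2 / 0.5 / 0.8 boundaries."""
    m = abs(d)
    if np.isnan(m):
        return "undefined"
    if m < 0.2:
        return "negligible"
    if m < 0.5:
        return "small"
    if m < 0.8:
        return "medium"
    return "large"


def run_ablation(
    features_by_subject: Mapping[str, Sequence[FeatureMatrix]],
    cases: Sequence[CaseDefinition] | None = None,
    k_components: int = 3,
    svm: SVMConfig | None = None,
    seed: int = 0,
) -> AblationResult:
    """Run the per-case pipeline over every subject and compare cases.

    ``features_by_subject`` maps subject ids to their per-trial
    full-sensor feature matrices; each case subsets the columns and
    re-runs the fold-wise normalize -> PCA -> SVM pipeline, so running
    a single case reproduces the standalone classifier output.
    Effect sizes are computed on the pooled subject x fold accuracy
    samples, for both raw and run/sprint-merged scoring.
    """
    if cases is None:
        cases = [CANONICAL_CASES[i] for i in sorted(CANONICAL_CASES)]
    ss = np.random.SeedSequence(seed)
    case_seeds = ss.generate_state(len(cases) * max(len(features_by_subject), 1))

    rows = []
    case_results: dict[int, dict[str, CVResult]] = {}
    counter = 0
    for case in cases:
        spec_ids = [s.feature_id for s in case_feature_spec(case)]
        per_subject: dict[str, CVResult] = {}
        for subject_id, mats in features_by_subject.items():
            sub_mats = [subset_features(fm, spec_ids) for fm in mats]
            result = cross_validate(
                sub_mats, k_components=k_components, svm=svm, seed=int(case_seeds[counter])
            )
            counter += 1
            per_subject[subject_id] = result
            for fold, (acc, accm) in enumerate(
                zip(result.fold_accuracy, result.fold_accuracy_merged)
            ):
                rows.append(
                    {
                        "case": case.case_id,
                        "subject": subject_id,
                        "fold": result.fold_trials[fold],
                        "accuracy": acc,
                        "accuracy_merged": accm,
                    }
                )
        case_results[case.case_id] = per_subject

    accuracies = pd.DataFrame(rows)
    es_rows = []
    case_ids = [c.case_id for c in cases]
    for i, ca in enumerate(case_ids):
        for cb in case_ids[i + 1 :]:
            a = accuracies.loc[accuracies["case"] == ca]
            b = accuracies.loc[accuracies["case"] == cb]
            d_raw = cohens_d(a["accuracy"], b["accuracy"])
            d_merged = cohens_d(a["accuracy_merged"], b["accuracy_merged"])
            es_rows.append(
                {
                    "case_a": ca,
                    "case_b": cb,
                    "d_raw": d_raw,
                    "d_merged": d_merged,
                    "label_raw": effect_size_label(d_raw),
                    "label_merged": effect_size_label(d_merged),
                }
            )
    return AblationResult(
        case_results=case_results,
        accuracies=accuracies,
        effect_sizes=pd.DataFrame(es_rows),
    )
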