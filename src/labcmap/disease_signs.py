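"""Clinical disease sign vectors from case/control lab comparisons.

For every lab test, case and control values are compared with the Wilcoxon
rank-sum (Mann-Whitney U) test.  A lab whose two-sided p-value falls below
the significance threshold (0.05 by default) is assigned a direction by
comparing the group *means*: +1 when the disease group runs higher, -1 when
lower.  Everything else — including a significant test with exactly equal
means — is 0.  No multiple-testing correction is applied across labs; each
lab is judged at the raw threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from labcmap.connect import SignVector
from labcmap.datasets import CaseControlDataset

logger = logging.getLogger(__name__)

__all__ = [
    "RankSumResult",
    "rank_sum_test",
    "call_disease_direction",
    "build_disease_vector",
    "disease_stats_table",
]

#: largest group size at which the exact null distribution is used
EXACT_MAX_N = 20


@dataclass(frozen=True)
class RankSumResult:
    """Mann-Whitney U statistics and summary means for one lab."""

    U_case: float
    U_control: float
    pvalue: float
    mean_case: float
    mean_control: float
    n_case: int
    n_control: int


def rank_sum_test(case_values, control_values) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test of case vs control values.

    Missing values are dropped first.  The exact null distribution is used
    when both groups have at most 20 observations and there are no ties
    (reproducing a Mann-Whitney table look-up); otherwise the normal
    approximation with tie and continuity correction.
    """
    case = np.asarray(pd.Series(case_values).dropna(), dtype=float)
    control = np.asarray(pd.Series(control_values).dropna(), dtype=float)
    if case.size == 0:
        raise ValueError("case group is empty after dropping missing values")
    if control.size == 0:
        raise ValueError("control group is empty after dropping missing values")

    pooled = np.concatenate([case, control])
    has_ties = np.unique(pooled).size < pooled.size
    exact = max(case.size, control.size) <= EXACT_MAX_N and not has_ties
    res = stats.mannwhitneyu(
        case,
        control,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    u_case = float(res.statistic)
    return RankSumResult(
        U_case=u_case,
        U_control=case.size * control.size - u_case,
        pvalue=float(min(res.pvalue, 1.0)),
        mean_case=float(case.mean()),
        mean_control=float(control.mean()),
        n_case=int(case.size),
        n_control=int(control.size),
    )


def call_disease_direction(result: RankSumResult, alpha: float = 0.05) -> float:
    """Ternary direction for one lab: significance gate then mean comparison."""
    if result.pvalue >= alpha:
        return 0.0
    if result.mean_case > result.mean_control:
        return 1.0
    if result.mean_case < result.mean_control:
        return -1.0
    logger.info("significant test with exactly tied means; calling 0")
    return 0.0


def build_disease_vector(
    dataset: CaseControlDataset, disease_id: str, alpha: float = 0.05
) -> SignVector:
    """Disease sign vector over the dataset's lab catalog.

    Labs where either group is empty after dropping missing values get 0
    with a logged warning rather than failing the whole vector.
    """
    if disease_id not in dataset.diseases:
        raise KeyError(f"unknown disease {disease_id!r}")
    entries = {}
    for lab in dataset.labs:
        case, control = dataset.split(disease_id, lab)
        if case.size == 0 or control.size == 0:
            logger.warning(
                "disease %s lab %s: empty %s group, calling 0",
                disease_id, lab, "case" if case.size == 0 else "control",
            )
            entries[lab] = 0.0
            continue
        entries[lab] = call_disease_direction(rank_sum_test(case, control), alpha)
    return SignVector(
        entity_id=disease_id,
        entries=pd.Series(entries, index=list(dataset.labs), dtype=float),
    )


def disease_stats_table(
    dataset: CaseControlDataset, alpha: float = 0.05
) -> tuple[list[SignVector], pd.DataFrame]:
    """All disease vectors plus a companion per-(disease, lab) statistics table."""
    vectors = []
    rows = []
    for dz in dataset.diseases:
        vectors.append(build_disease_vector(dataset, dz, alpha=alpha))
        for lab in dataset.labs:
            case, control = dataset.split(dz, lab)
            if case.size == 0 or control.size == 0:
                continue
            r = rank_sum_test(case, control)
            rows.append(
                {
                    "disease_id": dz, "lab_id": lab,
                    "U_case": r.U_case, "U_control": r.U_control,
                    "pvalue": r.pvalue,
                    "mean_case": r.mean_case, "mean_control": r.mean_control,
                }
            )
    stats_df = pd.DataFrame(
        rows,
        columns=[
            "disease_id", "lab_id", "U_case", "U_control",
            "pvalue", "mean_case", "mean_control",
        ],
    )
    return vectors, stats_df


def write_disease_vectors(
    vectors: list[SignVector], path: str | Path
) -> None:
    """Write diseases x labs sign matrix as CSV with entries in {1,-1,0}."""
    df = pd.DataFrame(
        {v.entity_id: v.entries for v in vectors}
    ).T.astype(int)
    df.index.name = "disease_id"
    df.to_csv(path)
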