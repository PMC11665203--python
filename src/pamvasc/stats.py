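"""Group-level comparisons of per-subject vascular and plaque metrics."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from pamvasc.bins import bin_label
from pamvasc.morphometry import VLDProfile
from pamvasc.plaque import PlaqueResult

logger = logging.getLogger(__name__)


@dataclass
class GroupComparison:
    """One two-group comparison of a scalar metric."""

    metric: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    se_a: float
    se_b: float
    t_statistic: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value must lie in [0, 1]")
        if self.n_a < 2 or self.n_b < 2:
            raise ValueError("each group needs >= 2 subjects")


def unpaired_t_test(
    a: Sequence[float],
    b: Sequence[float],
    metric: str = "",
    labels: Tuple[str, str] = ("a", "b"),
    welch: bool = False,
) -> GroupComparison:
    """Two-sided unpaired Student's t-test (pooled variance, df = n_a + n_b - 2).

    Set ``welch=True`` for the unequal-variance variant. Degenerate input
    with zero pooled variance yields t = 0, p = 1 when the means agree and
    an error otherwise.
    """
    av = np.asarray(a, dtype=np.float64)
    bv = np.asarray(b, dtype=np.float64)
    if av.size < 2 or bv.size < 2:
        raise ValueError("each group needs >= 2 values")
    if not (np.all(np.isfinite(av)) and np.all(np.isfinite(bv))):
        raise ValueError("groups must contain only finite values")
    var_a, var_b = av.var(ddof=1), bv.var(ddof=1)
    if var_a == 0 and var_b == 0:
        if av.mean() == bv.mean():
            t_stat, p = 0.0, 1.0
        else:
            raise ValueError(
                "zero pooled variance with unequal means: t undefined"
            )
    else:
        res = sps.ttest_ind(av, bv, equal_var=not welch)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        metric=metric,
        group_a=labels[0],
        group_b=labels[1],
        n_a=int(av.size),
        n_b=int(bv.size),
        mean_a=float(av.mean()),
        mean_b=float(bv.mean()),
        sd_a=float(av.std(ddof=1)),
        sd_b=float(bv.std(ddof=1)),
        se_a=float(av.std(ddof=1) / math.sqrt(av.size)),
        se_b=float(bv.std(ddof=1) / math.sqrt(bv.size)),
        t_statistic=t_stat,
        p_value=p,
    )


@dataclass
class SubjectResult:
    """Per-subject metrics entering a cohort comparison."""

    label: str
    vld: VLDProfile
    plaque: Optional[PlaqueResult] = None


def compare_cohort(
    subjects: Sequence[SubjectResult],
    welch: bool = False,
) -> List[GroupComparison]:
    """All pairwise group comparisons, one per (metric, diameter bin).

    Metrics are VLD per bin, total VLD, and (when present for every subject
    in both groups) plaque density. Groups with fewer than two subjects are
    skipped with a logged warning.
    """
    groups: Dict[str, List[SubjectResult]] = {}
    for s in subjects:
        groups.setdefault(s.label, []).append(s)
    labels = list(groups)
    comparisons: List[GroupComparison] = []
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            ga, gb = groups[la], groups[lb]
            if len(ga) < 2 or len(gb) < 2:
                logger.warning(
                    "skipping %s vs %s: a group has fewer than 2 subjects", la, lb
                )
                continue
            bins = list(ga[0].vld.vld_per_bin)
            for b in bins:
                comparisons.append(
                    unpaired_t_test(
                        [s.vld.vld_per_bin[b] for s in ga],
                        [s.vld.vld_per_bin[b] for s in gb],
                        metric=f"vld[{bin_label(b)}]",
                        labels=(la, lb),
                        welch=welch,
                    )
                )
            comparisons.append(
                unpaired_t_test(
                    [s.vld.total_vld for s in ga],
                    [s.vld.total_vld for s in gb],
                    metric="vld[total]",
                    labels=(la, lb),
                    welch=welch,
                )
            )
            if all(s.plaque is not None for s in ga + gb):
                comparisons.append(
                    unpaired_t_test(
                        [s.plaque.density_per_mm2 for s in ga],  # type: ignore[union-attr]
                        [s.plaque.density_per_mm2 for s in gb],  # type: ignore[union-attr]
                        metric="plaque_density",
                        labels=(la, lb),
                        welch=welch,
                    )
                )
    return comparisons


def comparisons_to_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    """Tidy report table; adds a Holm-adjusted p column (extension, labeled)."""
    from statsmodels.stats.multitest import multipletests

    df = pd.DataFrame(
        [
            {
                "metric": c.metric,
                "group_a": c.group_a,
                "group_b": c.group_b,
                "n_a": c.n_a,
                "n_b": c.n_b,
                "mean_a": c.mean_a,
                "mean_b": c.mean_b,
                "sd_a": c.sd_a,
                "sd_b": c.sd_b,
                "se_a": c.se_a,
                "se_b": c.se_b,
                "t": c.t_statistic,
                "p": c.p_value,
            }
            for c in comparisons
        ]
    )
    if len(df):
        df["p_holm_extension"] = multipletests(df["p"], method="holm")[1]
    return df
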