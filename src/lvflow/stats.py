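"""Paired two-timepoint comparison of cohort metrics.

Each metric measured at two timepoints in the same subjects is compared
with a two-sided paired t-test; because cohorts in this setting are small,
a Wilcoxon signed-rank test is run alongside, and a Kolmogorov–Smirnov
test checks the normality of the paired differences.  Significance is
declared at α = 0.05; no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["PairedComparison", "paired_compare", "compare_metrics_tables"]


@dataclass
class PairedComparison:
    """Result of one paired two-timepoint metric comparison."""

    metric: str
    n: int
    mean_t1: float
    sd_t1: float
    mean_t2: float
    sd_t2: float
    mean_difference: float
    t_pvalue: float
    wilcoxon_pvalue: float
    normal_differences: bool
    significant: bool
    alpha: float = 0.05
    note: str = ""

    def summary(self) -> str:
        star = "*" if self.significant else ""
        return (
            f"{self.metric}: {self.mean_t1:.3g} ± {self.sd_t1:.3g} → "
            f"{self.mean_t2:.3g} ± {self.sd_t2:.3g} "
            f"(p_t={self.t_pvalue:.3g}, p_w={self.wilcoxon_pvalue:.3g}){star}"
        )


def paired_compare(
    values_t1: np.ndarray,
    values_t2: np.ndarray,
    alpha: float = 0.05,
    metric: str = "",
) -> PairedComparison:
    """Compare one metric across two paired timepoints.

    Runs a two-sided paired t-test and a two-sided Wilcoxon signed-rank
    test on the pairwise differences (zero differences dropped for
    Wilcoxon, exact null distribution up to n = 25), plus a
    Kolmogorov–Smirnov normality check of the differences.  If every
    difference is zero the tests are undefined; the comparison is flagged
    not significant with a note.
    """
    x1 = np.asarray(values_t1, dtype=float)
    x2 = np.asarray(values_t2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError(f"paired vectors differ in length: {x1.shape} vs {x2.shape}")
    n = len(x1)
    if n < 2:
        raise ValueError(f"need at least 2 pairs, got {n}")
    d = x2 - x1

    common = dict(
        metric=metric, n=n,
        mean_t1=float(x1.mean()), sd_t1=float(x1.std(ddof=1)),
        mean_t2=float(x2.mean()), sd_t2=float(x2.std(ddof=1)),
        mean_difference=float(d.mean()), alpha=alpha,
    )
    if np.all(d == 0):
        return PairedComparison(
            **common, t_pvalue=np.nan, wilcoxon_pvalue=np.nan,
            normal_differences=True, significant=False,
            note="all paired differences are zero; tests undefined",
        )

    t_res = sps.ttest_rel(x2, x1)
    nz = d[d != 0]
    mode = "exact" if len(nz) <= 25 else "approx"
    w_res = sps.wilcoxon(nz, alternative="two-sided", method=mode)
    # KS against a normal with the sample's own moments (no Lilliefors
    # correction; conservative, used only as a flag)
    sd = d.std(ddof=1)
    if sd > 0:
        ks = sps.kstest(d, "norm", args=(d.mean(), sd))
        normal = bool(ks.pvalue >= alpha)
    else:
        normal = True
    return PairedComparison(
        **common,
        t_pvalue=float(t_res.pvalue),
        wilcoxon_pvalue=float(w_res.pvalue),
        normal_differences=normal,
        significant=bool(t_res.pvalue < alpha),
    )


def compare_metrics_tables(
    table_t1: pd.DataFrame,
    table_t2: pd.DataFrame,
    metrics: list[str] | None = None,
    subject_col: str = "subject",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired comparison of every shared numeric metric across two exams.

    Both tables must carry one row per subject keyed by ``subject_col``;
    only subjects present at both timepoints enter the comparison.
    """
    t1 = table_t1.set_index(subject_col)
    t2 = table_t2.set_index(subject_col)
    shared = t1.index.intersection(t2.index)
    if len(shared) < 2:
        raise ValueError("need at least 2 subjects present at both timepoints")
    if metrics is None:
        metrics = [
            c for c in t1.columns
            if c in t2.columns and np.issubdtype(t1[c].dtype, np.number)
        ]
    rows = []
    for m in metrics:
        cmp = paired_compare(t1.loc[shared, m].to_numpy(),
                             t2.loc[shared, m].to_numpy(), alpha=alpha, metric=m)
        rows.append({
            "metric": m, "n": cmp.n,
            "mean_t1": cmp.mean_t1, "sd_t1": cmp.sd_t1,
            "mean_t2": cmp.mean_t2, "sd_t2": cmp.sd_t2,
            "mean_difference": cmp.mean_difference,
            "p_paired_t": cmp.t_pvalue, "p_wilcoxon": cmp.wilcoxon_pvalue,
            "normal_differences": cmp.normal_differences,
            "significant": cmp.significant,
        })
    return pd.DataFrame(rows)
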