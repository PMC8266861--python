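"""Association screening between clinical variables and response class.

Age (continuous) is tested with the Mann-Whitney test; every categorical
variable (race, ER, PgR, HER2, molecular subtype) with Pearson's
chi-square test on its contingency table against the two-level response
label, without continuity correction. Variables with p < 0.05 are the
ones integrated into the classification models. Rows with a missing value
are dropped per variable; a variable left with a single level is reported
as not testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AssociationReport", "VariableResult", "associate", "select_associated"]

DEFAULT_ALPHA = 0.05
CATEGORICAL = ("race", "er", "pgr", "her2", "subtype")


@dataclass
class VariableResult:
    variable: str
    test: str
    statistic: float | None
    pvalue: float | None
    n_used: int
    n_missing: int
    testable: bool
    low_expected_counts: bool = False
    table: pd.DataFrame | None = None

    def decision(self, alpha: float = DEFAULT_ALPHA) -> bool:
        return self.testable and self.pvalue is not None and self.pvalue < alpha


@dataclass
class AssociationReport:
    results: list = field(default_factory=list)
    alpha: float = DEFAULT_ALPHA

    def __getitem__(self, variable: str) -> VariableResult:
        for r in self.results:
            if r.variable == variable:
                return r
        raise KeyError(variable)

    def to_dict(self) -> dict:
        return {
            r.variable: {
                "test": r.test,
                "statistic": None if r.statistic is None else float(r.statistic),
                "pvalue": None if r.pvalue is None else float(r.pvalue),
                "n_used": r.n_used,
                "n_missing": r.n_missing,
                "testable": r.testable,
                "low_expected_counts": r.low_expected_counts,
                "selected": r.decision(self.alpha),
            }
            for r in self.results
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "variable": r.variable, "test": r.test, "statistic": r.statistic,
            "pvalue": r.pvalue, "n_used": r.n_used, "n_missing": r.n_missing,
            "selected": r.decision(self.alpha),
        } for r in self.results])


def _test_age(age: pd.Series, y: np.ndarray) -> VariableResult:
    ok = age.notna().to_numpy()
    a = age[ok & (y == 1)].to_numpy(float)
    b = age[ok & (y == 0)].to_numpy(float)
    if len(a) == 0 or len(b) == 0:
        return VariableResult("age", "mann-whitney", None, None, int(ok.sum()),
                              int((~ok).sum()), testable=False)
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return VariableResult("age", "mann-whitney", float(res.statistic),
                          float(res.pvalue), int(ok.sum()), int((~ok).sum()),
                          testable=True)


def _test_categorical(name: str, col: pd.Series, y: np.ndarray) -> VariableResult:
    ok = col.notna().to_numpy()
    tab = pd.crosstab(col[ok], pd.Series(y[ok], index=col.index[ok]))
    n_used, n_missing = int(ok.sum()), int((~ok).sum())
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        return VariableResult(name, "chi-square", None, None, n_used, n_missing,
                              testable=False, table=tab)
    chi2, p, _, expected = stats.chi2_contingency(tab.to_numpy(), correction=False)
    return VariableResult(name, "chi-square", float(chi2), float(p), n_used,
                          n_missing, testable=True,
                          low_expected_counts=bool((expected < 5).any()), table=tab)


def associate(clinical: pd.DataFrame, labels: np.ndarray | None = None,
              alpha: float = DEFAULT_ALPHA) -> AssociationReport:
    """Test each clinical variable against the response label.

    ``labels`` defaults to the table's ``pcr`` column. Variables are
    tested in table order: age with Mann-Whitney, the rest with Pearson's
    chi-square (no continuity correction; a low-expected-count flag is set
    whenever any expected cell is below 5).
    """
    y = np.asarray(clinical["pcr"] if labels is None else labels)
    if len(y) != len(clinical):
        raise ValueError("labels must align with the clinical table")
    if len(np.unique(y)) != 2:
        raise ValueError("labels must contain both classes")
    report = AssociationReport(alpha=alpha)
    for col in clinical.columns:
        if col in ("patient_id", "pcr"):
            continue
        if col == "age":
            report.results.append(_test_age(clinical[col], y))
        elif col in CATEGORICAL:
            report.results.append(_test_categorical(col, clinical[col], y))
    return report


def select_associated(report: AssociationReport, alpha: float = DEFAULT_ALPHA) -> list:
    """Variables significantly associated with response, order preserved."""
    return [r.variable for r in report.results if r.decision(alpha)]
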