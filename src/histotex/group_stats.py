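"""Per-component, per-feature two-sample t-tests and significance counts.

The inference design is deliberately plain: classical pooled-variance
two-sided Student's t-test per feature, alpha = 0.05, no multiplicity
correction.  Each choice is exposed as a parameter.  The headline output
is, per component, the number of the 14 Haralick features whose group
means differ significantly between the two subtypes (0..14), plus
significance flags for the three moment features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import COMPONENTS, SUBTYPES
from .texture import FEATURE_COLUMNS, HARALICK_NAMES, MOMENT_NAMES

__all__ = ["TestResult", "SignificanceReport", "student_t_test",
           "significance_report"]


@dataclass
class TestResult:
    component: str
    feature: str
    t_statistic: float
    p_value: float
    n_a: int
    n_b: int
    significant: bool
    alpha: float
    valid: bool = True
    degenerate: bool = False


def student_t_test(a, b, alpha: float = 0.05, component: str = "",
                   feature: str = "") -> TestResult:
    """Two-sided pooled-variance two-sample Student's t-test.

    Degenerate handling: zero pooled variance with equal means -> p = 1;
    zero pooled variance with unequal means -> p = 0 (flagged).  Fewer
    than two values in either sample -> invalid (missing) result.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        return TestResult(component, feature, np.nan, np.nan, n1, n2,
                          False, alpha, valid=False)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return TestResult(component, feature, 0.0, 1.0, n1, n2,
                              False, alpha, degenerate=True)
        t = np.inf if diff > 0 else -np.inf
        return TestResult(component, feature, float(t), 0.0, n1, n2,
                          0.0 < alpha, alpha, degenerate=True)
    t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TestResult(component, feature, float(t), p, n1, n2,
                      p < alpha, alpha)


@dataclass
class SignificanceReport:
    alpha: float
    haralick_counts: dict[str, int]
    moment_flags: dict[str, dict[str, bool]]
    tests: list[TestResult] = field(default_factory=list)

    def ranking(self) -> list[str]:
        """Components ordered by descending significant-Haralick count."""
        return sorted(self.haralick_counts,
                      key=lambda c: (-self.haralick_counts[c], c))

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"component": list(self.haralick_counts),
             "n_significant_haralick": list(self.haralick_counts.values())})

    def tests_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"component": r.component, "feature": r.feature,
             "t": r.t_statistic, "p": r.p_value, "n_N": r.n_a,
             "n_MN": r.n_b, "significant": r.significant}
            for r in self.tests])


def significance_report(table: pd.DataFrame, alpha: float = 0.05
                        ) -> SignificanceReport:
    """Run all per-component, per-feature subtype comparisons.

    ``table`` is the output of :func:`histotex.texture.build_feature_table`.
    Missing values are dropped pairwise per feature.  Components present
    in only one subtype are omitted with a warning.
    """
    counts: dict[str, int] = {}
    moment_flags: dict[str, dict[str, bool]] = {}
    tests: list[TestResult] = []
    for comp in COMPONENTS:
        sub = table[table["component"] == comp]
        grp = {s: sub[sub["subtype"] == s] for s in SUBTYPES}
        if any(len(g) == 0 for g in grp.values()):
            warnings.warn(f"component {comp} present in only one subtype; "
                          "omitted from the report")
            continue
        n_sig = 0
        flags: dict[str, bool] = {}
        for feature in FEATURE_COLUMNS:
            res = student_t_test(grp["N"][feature], grp["MN"][feature],
                                 alpha=alpha, component=comp,
                                 feature=feature)
            tests.append(res)
            if not res.valid:
                continue
            if feature in HARALICK_NAMES and res.significant:
                n_sig += 1
            if feature in MOMENT_NAMES:
                flags[feature] = bool(res.significant)
        counts[comp] = n_sig
        moment_flags[comp] = flags
    return SignificanceReport(alpha=alpha, haralick_counts=counts,
                              moment_flags=moment_flags, tests=tests)
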