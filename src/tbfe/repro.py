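"""Between-scanner reproducibility statistics.

Same-subject measures from two scanners (an n x 2 rating table) are compared
with the Pearson product-moment correlation and the intraclass correlation
coefficient (ICC) from the two-way ANOVA decomposition.  The default ICC form
is two-way mixed effects, absolute agreement, single measurement — ICC(A,1)
in McGraw & Wong's nomenclature — because the scanners are fixed conditions
and absolute agreement is the stricter cross-scanner claim.  Consistency and
average-measure forms are selectable; consistency ICC (and Pearson r) are
invariant under a common affine rescaling of both arms, absolute agreement is
not — a constant offset between scanners lowers it.

Paired t-tests (one-sample t on the differences) compare derived quantities
such as the loaded-bone fraction between loading conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError

log = logging.getLogger(__name__)

#: supported ICC forms (McGraw & Wong identifiers) -> description
ICC_FORMS = {
    "ICC(1,1)": "one-way random, single measurement",
    "ICC(A,1)": "two-way mixed/random, absolute agreement, single",
    "ICC(C,1)": "two-way mixed, consistency, single",
    "ICC(1,k)": "one-way random, average of k",
    "ICC(A,k)": "two-way mixed/random, absolute agreement, average",
    "ICC(C,k)": "two-way mixed, consistency, average",
}
DEFAULT_ICC_FORM = "ICC(A,1)"


@dataclass
class ReproRow:
    """Reproducibility summary for one measure."""

    measure: str
    lr_mean: float
    lr_std: float
    hr_mean: float
    hr_std: float
    pearson_r: float
    icc: float
    icc_form: str
    n: int


def pearson(x, y) -> float:
    """Product-moment correlation of paired samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise AnalysisError("pearson needs paired samples of equal length >= 2")
    if np.std(x) == 0 or np.std(y) == 0:
        raise AnalysisError("pearson undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def icc(x, y, form: str = DEFAULT_ICC_FORM) -> float:
    """Intraclass correlation of an n x 2 rating table (scanner 1 vs 2).

    Computed from the two-way ANOVA decomposition (via pingouin).  A
    degenerate table with no between-subject variance has no defined ICC and
    raises :class:`AnalysisError`; identical arms with subject variance give
    exactly 1.
    """
    import pingouin as pg

    if form not in ICC_FORMS:
        raise AnalysisError(f"unknown ICC form {form!r}; choose from {sorted(ICC_FORMS)}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise AnalysisError("icc needs paired samples of equal length >= 2")
    if np.allclose(x, x[0]) and np.allclose(y, y[0]):
        raise AnalysisError("degenerate rating table (all values identical); ICC undefined")
    n = x.size
    df = pd.DataFrame({
        "subject": np.tile(np.arange(n), 2),
        "rater": np.repeat(["A", "B"], n),
        "score": np.concatenate([x, y]),
    })
    res = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
    return float(res.loc[res["Type"] == form, "ICC"].iloc[0])


def paired_t(x, y):
    """Paired t-test: one-sample t on the differences x - y.

    Returns ``(t, p, degenerate)``; for zero-variance differences the test is
    degenerate and (0, 1) or (+/-inf, 0) is returned with the flag set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise AnalysisError("paired_t needs equal-length samples, n >= 2")
    d = x - y
    if np.std(d) == 0:
        if d[0] == 0:
            return 0.0, 1.0, True
        return float(np.sign(d[0]) * np.inf), 0.0, True
    t, p = stats.ttest_rel(x, y)
    return float(t), float(p), False


def build_report(lr: dict[str, np.ndarray], hr: dict[str, np.ndarray],
                 measures: list[str] | None = None,
                 icc_form: str = DEFAULT_ICC_FORM) -> pd.DataFrame:
    """Per-measure reproducibility table (mean±std per scanner, r, ICC).

    ``lr`` / ``hr`` map measure names to per-subject arrays in matching
    subject order.  Subjects with a missing value in either arm are dropped
    with a warning.  Returns a DataFrame with one row per measure.
    """
    if measures is None:
        measures = [m for m in lr if m in hr]
    rows = []
    for m in measures:
        x = np.asarray(lr[m], dtype=float)
        y = np.asarray(hr[m], dtype=float)
        if x.size != y.size:
            raise AnalysisError(f"measure {m!r}: LR and HR cohorts differ in size")
        ok = np.isfinite(x) & np.isfinite(y)
        if not ok.all():
            log.warning("measure %r: dropping %d subject(s) with missing values",
                        m, int((~ok).sum()))
            x, y = x[ok], y[ok]
        rows.append(ReproRow(
            measure=m,
            lr_mean=float(x.mean()), lr_std=float(x.std(ddof=1)),
            hr_mean=float(y.mean()), hr_std=float(y.std(ddof=1)),
            pearson_r=pearson(x, y), icc=icc(x, y, icc_form),
            icc_form=icc_form, n=int(x.size),
        ))
    return pd.DataFrame([r.__dict__ for r in rows])
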