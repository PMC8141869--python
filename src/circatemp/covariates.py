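"""Sex/age moderation of rhythm parameters and cohort-level statistics.

Phases are periodic on the 24-h clock, so before regression they are
mapped to a line by the unique linear clock-to-line map consistent with
the anchors 14:00 ↦ −10 and 10:00 ↦ +10 at one unit per hour::

    linearized = ((clock − 14) mod 24) − 10

Every rhythm response (SGC; chest/core mesor, amplitude and linearized
phase; PC scores) is regressed on ``[1, sex, age, sex×age]`` with sex
coded 0 for females and 1 for males; significance is the two-sided t-test
p-value of each coefficient.  No multiple-testing correction is applied by
default (an optional Benjamini–Hochberg column is available as an
extension); p-values below 5% are labelled significant and those between
5 and 10% as a trend.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

PHASE_ANCHOR_CLOCK = 14.0  # clock hour mapping to -10
PHASE_ANCHOR_VALUE = -10.0


def linearize_phase(clock_time):
    """Map a clock-hour phase to the line: 14:00 ↦ −10, 10:00 ↦ +10.

    Linear with slope 1 unit/hour starting at 14:00; midnight maps to 0.
    Clock times in (10:00, 14:00) fall outside the study's observed phase
    range and map beyond +10 (see :func:`phase_out_of_range`).
    Accepts scalars or arrays.
    """
    c = np.asarray(clock_time, dtype=float)
    if not np.all(np.isfinite(c)):
        raise ValueError("clock_time must be finite")
    value = ((c - PHASE_ANCHOR_CLOCK) % 24.0) + PHASE_ANCHOR_VALUE
    return float(value) if np.isscalar(clock_time) else value


def phase_out_of_range(clock_time) -> np.ndarray:
    """True where the linearized phase exceeds +10 (clock in (10:00, 14:00))."""
    v = np.asarray(linearize_phase(clock_time))
    return v > 10.0


@dataclass
class SubjectRecord:
    """Per-subject covariates; sex coded 0 = female, 1 = male."""

    subject_id: str
    sex: int
    age: float
    bmi: float | None = None
    chronotype: float | None = None
    medical_condition: bool | None = None
    medication: bool | None = None

    def __post_init__(self) -> None:
        if self.sex not in (0, 1):
            raise ValueError("sex must be 0 (female) or 1 (male)")
        if self.age <= 0:
            raise ValueError("age must be positive")


@dataclass
class RegressionResult:
    """OLS of one response on [1, sex, age, sex×age] with t-test p-values."""

    response: str
    coefficients: pd.Series  # index: const, sex, age, sex_age
    pvalues: pd.Series
    stderr: pd.Series
    nobs: int


def fit_sex_age_model(response, records) -> RegressionResult:
    """Fit the sex + age + sex×age regression for one response variable.

    ``records`` is a list of :class:`SubjectRecord` or a DataFrame with
    ``sex`` and ``age`` columns, aligned with ``response``.  Requires at
    least 5 subjects and both sexes (a single-sex cohort makes sex and the
    interaction collinear).
    """
    if isinstance(records, pd.DataFrame):
        sex = records["sex"].to_numpy(dtype=float)
        age = records["age"].to_numpy(dtype=float)
        label = getattr(response, "name", None) or "response"
    else:
        sex = np.array([r.sex for r in records], dtype=float)
        age = np.array([r.age for r in records], dtype=float)
        label = "response"
    y = np.asarray(response, dtype=float)
    keep = np.isfinite(y)
    y, sex, age = y[keep], sex[keep], age[keep]
    if len(y) < 5:
        raise ValueError("sex/age regression needs at least 5 subjects")
    if len(np.unique(sex)) < 2:
        raise ValueError("single-sex cohort: sex and sex×age are collinear")
    X = pd.DataFrame({"const": 1.0, "sex": sex, "age": age, "sex_age": sex * age})
    fit = sm.OLS(y, X).fit()
    return RegressionResult(
        response=label,
        coefficients=fit.params,
        pvalues=fit.pvalues,
        stderr=fit.bse,
        nobs=int(fit.nobs),
    )


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with tie-corrected p-value.

    Returns ``(nan, nan)`` with a warning for constant input (correlation
    undefined).  Pairs with a missing member are dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("Spearman correlation needs at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("constant input: Spearman correlation undefined", stacklevel=2)
        return (float("nan"), float("nan"))
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def welch_t(group_a, group_b, alternative: str = "two-sided") -> tuple[float, float]:
    """Welch's unequal-variance t-test (Satterthwaite df)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("Welch's t-test needs at least 3 observations per group")
    t, p = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return float(t), float(p)


def significance_label(p: float) -> str:
    """'significant' below 5%, 'trend' between 5 and 10%, '' otherwise."""
    if not np.isfinite(p):
        return ""
    if p < 0.05:
        return "significant"
    if p < 0.10:
        return "trend"
    return ""


#: responses regressed on sex/age/sex×age when present in the cohort table
REPORT_RESPONSES = [
    "chest_sgc",
    "chest_mesor",
    "chest_amplitude",
    "chest_acrophase_lin",
    "core_mesor",
    "core_amplitude",
    "core_bathyphase_lin",
    "PC1",
    "PC2",
    "PC3",
]

#: Spearman correlation panel: (x, y) column pairs
CORRELATION_PAIRS = [
    ("bmi", "chest_mesor"),
    ("chronotype", "chest_acrophase_lin"),
    ("chronotype", "core_bathyphase_lin"),
    ("activity_strength", "chest_mesor"),
    ("activity_strength", "chest_amplitude"),
    ("activity_strength", "core_amplitude"),
    ("activity_strength", "chest_sgc"),
    ("chest_mesor", "core_mesor"),
    ("chest_sgc", "chest_amplitude"),
]


@dataclass
class CohortReport:
    """Regression tables, correlation panel and assembly gaps."""

    regressions: pd.DataFrame
    correlations: pd.DataFrame
    gaps: list = field(default_factory=list)

    def summary(self) -> str:
        lines = ["Cohort sex/age regression report", "=" * 34]
        for resp, grp in self.regressions.groupby("response", sort=False):
            lines.append(f"\n{resp}:")
            for _, row in grp.iterrows():
                lines.append(
                    f"  {row['term']:>8s}: {row['coefficient']:+.4f}"
                    f"  (p={row['pvalue']:.4f}) {row['label']}"
                )
        if len(self.correlations):
            lines.append("\nSpearman correlation panel:")
            for _, row in self.correlations.iterrows():
                lines.append(
                    f"  {row['x']} ~ {row['y']}: rho={row['rho']:+.3f}"
                    f" (p={row['pvalue']:.4f}) {row['label']}"
                )
        if self.gaps:
            lines.append("\nMissing stages: " + ", ".join(self.gaps))
        return "\n".join(lines)


def build_cohort_table(
    records,
    cosinor_fits: dict | None = None,
    sgc: dict | None = None,
    pc_scores: pd.DataFrame | None = None,
    activity_strengths: dict | None = None,
) -> pd.DataFrame:
    """Assemble the per-subject table feeding the cohort report.

    ``cosinor_fits`` maps subject id -> {"chest": fit, "core": fit}; phases
    are linearized here (chest evening acrophase, core bathyphase).
    Missing stages simply leave their columns absent.
    """
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "sex": r.sex,
            "age": r.age,
            "bmi": r.bmi,
            "chronotype": r.chronotype,
            "medical_condition": r.medical_condition,
            "medication": r.medication,
        }
        if cosinor_fits and r.subject_id in cosinor_fits:
            pair = cosinor_fits[r.subject_id]
            chest, core = pair.get("chest"), pair.get("core")
            if chest is not None:
                row["chest_mesor"] = chest.M
                row["chest_amplitude"] = chest.amplitude
                if chest.acrophase is not None:
                    row["chest_acrophase_lin"] = linearize_phase(chest.acrophase)
            if core is not None:
                row["core_mesor"] = core.M
                row["core_amplitude"] = core.amplitude
                if core.bathyphase is not None:
                    row["core_bathyphase_lin"] = linearize_phase(core.bathyphase)
        if sgc and r.subject_id in sgc:
            row["chest_sgc"] = sgc[r.subject_id]
        if activity_strengths and r.subject_id in activity_strengths:
            row["activity_strength"] = activity_strengths[r.subject_id]
        rows.append(row)
    table = pd.DataFrame(rows).set_index("subject_id")
    if pc_scores is not None:
        table = table.join(pc_scores)
    return table


def cohort_report(table: pd.DataFrame, add_bh: bool = False) -> CohortReport:
    """Sex/age regression tables plus the Spearman correlation panel.

    One regression row per (response, term) for every response column
    present in ``table``; absent responses are listed as gaps rather than
    failing the whole report.  ``add_bh=True`` appends a Benjamini–Hochberg
    adjusted p-value column, clearly an extension beyond the unadjusted
    default.
    """
    reg_rows, gaps = [], []
    for resp in REPORT_RESPONSES:
        if resp not in table.columns or table[resp].notna().sum() < 5:
            gaps.append(resp)
            continue
        res = fit_sex_age_model(table[resp], table)
        for term in ("const", "sex", "age", "sex_age"):
            reg_rows.append(
                {
                    "response": resp,
                    "term": term,
                    "coefficient": res.coefficients[term],
                    "stderr": res.stderr[term],
                    "pvalue": res.pvalues[term],
                    "label": significance_label(res.pvalues[term]),
                }
            )
    regressions = pd.DataFrame(reg_rows)
    if add_bh and len(regressions):
        slope = regressions["term"] != "const"
        adj = np.full(len(regressions), np.nan)
        adj[slope.to_numpy()] = multipletests(
            regressions.loc[slope, "pvalue"].to_numpy(), method="fdr_bh"
        )[1]
        regressions["pvalue_bh"] = adj

    corr_rows = []
    for x, y in CORRELATION_PAIRS:
        if x not in table.columns or y not in table.columns:
            continue
        xv = pd.to_numeric(table[x], errors="coerce")
        yv = pd.to_numeric(table[y], errors="coerce")
        if (np.isfinite(xv) & np.isfinite(yv)).sum() < 3:
            continue
        rho, p = spearman(xv, yv)
        corr_rows.append(
            {"x": x, "y": y, "rho": rho, "pvalue": p, "label": significance_label(p)}
        )
    return CohortReport(
        regressions=regressions,
        correlations=pd.DataFrame(corr_rows),
        gaps=gaps,
    )
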