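"""Museum-specimen UCE capture statistics.

Quantifies how specimen age and preservation type (ethanol vs pinned)
affect the number of UCE loci captured: Welch's two-sample t-test
between preservation groups, a Gaussian GLM of locus count on age and
preservation, and a cross-study likelihood-ratio test of whether
logit-transformed capture fractions decline with age at a common rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

PRESERVATION_TYPES = ("ethanol", "pinned")


@dataclass
class SpecimenRecord:
    specimen_id: str
    age_years: float
    preservation: str
    loci_count: int
    study: str = "default"

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise ValueError(f"{self.specimen_id}: negative age")
        if self.loci_count < 0:
            raise ValueError(f"{self.specimen_id}: negative locus count")
        if self.preservation not in PRESERVATION_TYPES:
            raise ValueError(
                f"{self.specimen_id}: preservation must be one of {PRESERVATION_TYPES}"
            )


@dataclass
class CaptureFraction:
    specimen_id: str
    study: str
    age_years: float
    fraction: float
    logit_value: float


@dataclass
class ModelComparison:
    lnL_full: float
    lnL_reduced: float
    lr_stat: float
    df: int
    p_value: float


def read_specimen_table(path: str | Path, sequencing_year: int | None = None) -> list[SpecimenRecord]:
    """Read a specimen CSV/TSV with columns specimen_id, year_collected (or
    age_years), preservation, loci_count and optional study.  Ages are
    ``sequencing_year - year_collected`` when a collection year is given."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    table = pd.read_csv(path, sep=sep)
    records = []
    for row in table.itertuples(index=False):
        if hasattr(row, "age_years"):
            age = float(row.age_years)
        else:
            if sequencing_year is None:
                raise ValueError("sequencing_year required with year_collected column")
            age = float(sequencing_year - row.year_collected)
        records.append(
            SpecimenRecord(
                str(row.specimen_id), age, str(row.preservation),
                int(row.loci_count), str(getattr(row, "study", "default")),
            )
        )
    return records


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch two-sample t-test (unequal variances), two-sided.

    Returns (t, Welch-Satterthwaite df, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both groups need >= 2 observations")
    result = stats.ttest_ind(x, y, equal_var=False)
    return float(result.statistic), float(result.df), float(result.pvalue)


def fit_capture_glm(
    records: Sequence[SpecimenRecord], family: str = "gaussian"
) -> sm.regression.linear_model.RegressionResultsWrapper:
    """GLM of locus count on specimen age and preservation type.

    Identity-link Gaussian by default (Poisson with log link available);
    preservation is treatment-coded with ethanol as the reference level.
    Returns the fitted statsmodels results object (coefficients, standard
    errors, Wald p-values, ``llf``).
    """
    if len(records) < 4:
        raise ValueError("need >= 4 records")
    frame = pd.DataFrame(
        {
            "loci_count": [r.loci_count for r in records],
            "age_years": [r.age_years for r in records],
            "preservation": pd.Categorical(
                [r.preservation for r in records], categories=PRESERVATION_TYPES
            ),
        }
    )
    if family not in ("gaussian", "poisson"):
        raise ValueError(f"unknown GLM family: {family}")
    if frame["preservation"].nunique() > 1:
        formula = "loci_count ~ age_years + C(preservation, Treatment('ethanol'))"
    else:
        formula = "loci_count ~ age_years"
    if family == "gaussian":
        # identity-link Gaussian GLM is exactly OLS, and the OLS path is
        # robust to degenerate (zero-variance) responses
        model = smf.ols(formula, data=frame)
    else:
        model = smf.glm(formula, data=frame, family=sm.families.Poisson())
    try:
        result = model.fit()
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"degenerate design matrix: {exc}") from exc
    if np.isnan(result.params).any():
        raise ValueError("degenerate (collinear) design matrix")
    return result


def logit_capture_fraction(records: Sequence[SpecimenRecord]) -> list[CaptureFraction]:
    """Capture fraction per specimen (count / within-study maximum) on the
    logit scale.

    The within-study maximum has fraction exactly 1, whose logit is
    infinite; the squeeze transform p' = (p*(n-1) + 0.5)/n keeps every
    value finite while leaving mid-range fractions essentially unchanged.
    """
    out: list[CaptureFraction] = []
    by_study: dict[str, list[SpecimenRecord]] = {}
    for r in records:
        by_study.setdefault(r.study, []).append(r)
    for study, group in by_study.items():
        max_count = max(r.loci_count for r in group)
        if max_count == 0:
            raise ValueError(f"study {study}: all specimens have zero loci")
        n = len(group)
        for r in group:
            p = r.loci_count / max_count
            squeezed = (p * (n - 1) + 0.5) / n
            out.append(
                CaptureFraction(
                    r.specimen_id, study, r.age_years, p,
                    math.log(squeezed / (1 - squeezed)),
                )
            )
    return out


def common_slope_lrt(fractions: Sequence[CaptureFraction]) -> ModelComparison:
    """Likelihood-ratio test of per-study versus shared age slopes.

    FULL: logit fraction ~ per-study intercepts + per-study slopes;
    REDUCED: per-study intercepts + one common slope.  Both are Gaussian
    ML fits; the statistic 2(lnL_full - lnL_reduced) is referred to a
    chi-square with (#studies - 1) degrees of freedom.  A small p-value
    means capture declines with age at genuinely different rates.
    """
    frame = pd.DataFrame(
        {
            "logit_value": [f.logit_value for f in fractions],
            "age": [f.age_years for f in fractions],
            "study": [f.study for f in fractions],
        }
    )
    studies = frame["study"].unique()
    if len(studies) < 2:
        raise ValueError("common-slope test needs >= 2 studies")
    for study, group in frame.groupby("study"):
        if len(group) < 3 or group["age"].nunique() < 2:
            raise ValueError(f"study {study}: need >= 3 specimens with age variation")
    full = smf.ols("logit_value ~ C(study) + C(study):age", data=frame).fit()
    reduced = smf.ols("logit_value ~ C(study) + age", data=frame).fit()
    df = len(studies) - 1
    lr = max(2 * (full.llf - reduced.llf), 0.0)
    return ModelComparison(
        lnL_full=float(full.llf),
        lnL_reduced=float(reduced.llf),
        lr_stat=float(lr),
        df=df,
        p_value=float(stats.chi2.sf(lr, df)),
    )


def write_capture_report(
    records: Sequence[SpecimenRecord], out_path: str | Path
) -> dict:
    """Welch test, GLM and cross-study LRT rolled into one TSV report.

    Returns the headline numbers as a dict (also written to disk).
    """
    pinned = [r.loci_count for r in records if r.preservation == "pinned"]
    ethanol = [r.loci_count for r in records if r.preservation == "ethanol"]
    report: dict = {}
    if len(pinned) >= 2 and len(ethanol) >= 2:
        t, df, p = welch_t_test(ethanol, pinned)
        report.update(welch_t=t, welch_df=df, welch_p=p)
    glm = fit_capture_glm(records)
    report["glm_age_coef"] = float(glm.params["age_years"])
    report["glm_age_p"] = float(glm.pvalues["age_years"])
    report["glm_llf"] = float(glm.llf)
    studies = {r.study for r in records}
    if len(studies) >= 2:
        comparison = common_slope_lrt(logit_capture_fraction(records))
        report.update(lrt_stat=comparison.lr_stat, lrt_df=comparison.df, lrt_p=comparison.p_value)
    out = Path(out_path)
    out.parent.mkdir(parents=True, exist_ok=True)
    with open(out, "w") as fh:
        fh.write("statistic\tvalue\n")
        for key in sorted(report):
            fh.write(f"{key}\t{report[key]:.6g}\n")
    return report
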