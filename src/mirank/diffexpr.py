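"""Relative-expression group comparison for qPCR Cq data.

Implements the Livak 2^−ΔΔCq chain: per subject, ΔCq = target Cq − reference
Cq; the calibrator is (by default) the arithmetic mean of the control
group's ΔCq for the assay, so control-group relative quantities (rq) center
at 1 (their geometric mean is exactly 1); rq = 2^−(ΔCq − calibrator).
Amplification efficiency is fixed at 2 (perfect doubling per cycle).

Per assay, both groups are screened with the D'Agostino–Pearson omnibus
normality test (reported, never gating) and compared with the two-sided
Mann–Whitney U test.  The reported U is min(U1, U2); p-values are exact by
enumeration for small tie-free samples (both n ≤ 8) and use the
tie-corrected, continuity-corrected normal approximation otherwise.  No
multiple-testing correction is applied by default; Benjamini–Hochberg is
available as an opt-in.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("mirank")

CQ_COLUMNS = ["subject_id", "group", "assay_id", "cq_target", "cq_reference"]
NEAR_UNDETERMINED_CQ = 40.0
EXACT_N_MAX = 8  # exact Mann-Whitney p when both groups are at most this size
NORMALITY_MIN_N = 8  # omnibus statistic undefined below this


class DiffExprError(ValueError):
    """Fatal group-comparison problem (bad input contract)."""


def read_cq_table(path, replicate_column: str | None = None) -> pd.DataFrame:
    """Read a long-format Cq table; average technical replicates if a
    replicate column is present."""
    frame = pd.read_csv(path, sep="\t")
    missing = set(CQ_COLUMNS) - set(frame.columns)
    if missing:
        raise DiffExprError(f"Cq table missing columns: {sorted(missing)}")
    if replicate_column and replicate_column in frame.columns:
        frame = (frame.groupby(["subject_id", "group", "assay_id"],
                               as_index=False)[["cq_target", "cq_reference"]]
                 .mean())
    flagged = (frame[["cq_target", "cq_reference"]] >= NEAR_UNDETERMINED_CQ)
    if flagged.any().any():
        logger.warning("%d Cq values >= %g cycles (near-undetermined)",
                       int(flagged.sum().sum()), NEAR_UNDETERMINED_CQ)
    return frame[CQ_COLUMNS]


def relative_expression(records: pd.DataFrame,
                        calibrator_rule: str = "control-mean",
                        calibrator_sample: str | None = None) -> pd.DataFrame:
    """Compute per-subject ΔCq, ΔΔCq and rq = 2^−ΔΔCq for every assay.

    ``calibrator_rule`` picks the ΔCq anchor per assay: ``control-mean``
    (mean over the control group, the default), ``global-mean`` (mean over
    all subjects) or ``named-sample`` (one subject's ΔCq, via
    ``calibrator_sample``).  Subjects with a missing Cq are excluded with a
    warning.
    """
    frame = records.copy()
    incomplete = frame["cq_target"].isna() | frame["cq_reference"].isna()
    if incomplete.any():
        logger.warning("excluding %d records with missing Cq",
                       int(incomplete.sum()))
        frame = frame[~incomplete]
    frame["delta_cq"] = frame["cq_target"] - frame["cq_reference"]

    out = []
    for assay, sub in frame.groupby("assay_id", sort=True):
        if calibrator_rule == "control-mean":
            controls = sub.loc[sub["group"] == "control", "delta_cq"]
            if controls.empty:
                raise DiffExprError(
                    f"assay {assay!r}: control group empty under "
                    "control-mean calibrator rule"
                )
            calibrator = controls.mean()
        elif calibrator_rule == "global-mean":
            calibrator = sub["delta_cq"].mean()
        elif calibrator_rule == "named-sample":
            match = sub.loc[sub["subject_id"] == calibrator_sample, "delta_cq"]
            if match.empty:
                raise DiffExprError(
                    f"assay {assay!r}: calibrator sample "
                    f"{calibrator_sample!r} not found"
                )
            calibrator = float(match.iloc[0])
        else:
            raise DiffExprError(f"unknown calibrator rule {calibrator_rule!r}")
        sub = sub.copy()
        sub["delta_delta_cq"] = sub["delta_cq"] - calibrator
        sub["rq"] = np.exp2(-sub["delta_delta_cq"])
        out.append(sub)
    result = pd.concat(out, ignore_index=True)
    return result[["subject_id", "group", "assay_id",
                   "delta_cq", "delta_delta_cq", "rq"]]


# ---------------------------------------------------------------------------
# statistics

def skew_ztransform(values) -> float:
    """Z-score of the sample skewness under normality (D'Agostino 1970).

    Maps a sample skewness of exactly 0 to Z = 0, as the transform's
    lognormal approximation requires.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    m = x - x.mean()
    m2 = np.mean(m ** 2)
    b1 = np.mean(m ** 3) / m2 ** 1.5
    y = b1 * math.sqrt((n + 1) * (n + 3) / (6.0 * (n - 2)))
    beta2 = (3.0 * (n ** 2 + 27 * n - 70) * (n + 1) * (n + 3)
             / ((n - 2) * (n + 5) * (n + 7) * (n + 9)))
    w2 = -1.0 + math.sqrt(2.0 * (beta2 - 1.0))
    delta = 1.0 / math.sqrt(0.5 * math.log(w2))
    alpha = math.sqrt(2.0 / (w2 - 1.0))
    return delta * math.asinh(y / alpha)


def kurtosis_ztransform(values) -> float:
    """Z-score of the sample kurtosis under normality (Anscombe–Glynn 1983)."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    m = x - x.mean()
    m2 = np.mean(m ** 2)
    b2 = np.mean(m ** 4) / m2 ** 2
    e_b2 = 3.0 * (n - 1) / (n + 1)
    var_b2 = 24.0 * n * (n - 2) * (n - 3) / ((n + 1) ** 2 * (n + 3) * (n + 5))
    z = (b2 - e_b2) / math.sqrt(var_b2)
    sqrt_beta1 = (6.0 * (n * n - 5 * n + 2) / ((n + 7) * (n + 9))
                  * math.sqrt(6.0 * (n + 3) * (n + 5)
                              / (n * (n - 2) * (n - 3))))
    a = 6.0 + (8.0 / sqrt_beta1) * (2.0 / sqrt_beta1
                                    + math.sqrt(1.0 + 4.0 / sqrt_beta1 ** 2))
    term = (1.0 - 2.0 / a) / (1.0 + z * math.sqrt(2.0 / (a - 4.0)))
    root = math.copysign(abs(term) ** (1.0 / 3.0), term)
    return ((1.0 - 2.0 / (9.0 * a)) - root) / math.sqrt(2.0 / (9.0 * a))


def dagostino_pearson(values) -> tuple[float, float]:
    """D'Agostino–Pearson omnibus K² and its chi-square(2) p-value.

    K² = Z_skew² + Z_kurt² from the standard omnibus transforms.  Returns
    (nan, nan) — "not assessable" — for n < 8 or zero-variance input
    rather than raising.
    """
    arr = np.asarray(list(values), dtype=float)
    if len(arr) < NORMALITY_MIN_N or np.ptp(arr) == 0:
        return (math.nan, math.nan)
    k2 = skew_ztransform(arr) ** 2 + kurtosis_ztransform(arr) ** 2
    return float(k2), float(stats.chi2.sf(k2, df=2))


def mann_whitney_u(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test reporting U = min(U1, U2).

    Exact p by enumeration when both samples have at most
    ``EXACT_N_MAX`` observations and there are no ties; tie- and
    continuity-corrected normal approximation otherwise.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise DiffExprError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = ("exact" if tie_free and len(a) <= EXACT_N_MAX
              and len(b) <= EXACT_N_MAX else "asymptotic")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    u1 = float(res.statistic)
    u2 = len(a) * len(b) - u1
    return min(u1, u2), float(min(res.pvalue, 1.0))


def compare_groups(relexpr: pd.DataFrame, alpha: float = 0.05,
                   adjust: str | None = None) -> pd.DataFrame:
    """One comparison row per assay: medians, U, p, normality screens.

    Assays with only one group represented are skipped with a warning.
    ``adjust="bh"`` adds Benjamini–Hochberg adjusted p-values (off by
    default: an explorative screen reports raw p-values).
    """
    rows = []
    for assay, sub in relexpr.groupby("assay_id", sort=True):
        case = sub.loc[sub["group"] == "case", "rq"]
        control = sub.loc[sub["group"] == "control", "rq"]
        if case.empty or control.empty:
            logger.warning("assay %r has only one group; skipped", assay)
            continue
        u, p = mann_whitney_u(case, control)
        _, norm_case_p = dagostino_pearson(case)
        _, norm_control_p = dagostino_pearson(control)
        rows.append({
            "assay_id": assay,
            "median_case": float(case.median()),
            "median_control": float(control.median()),
            "u_statistic": u,
            "p_value": p,
            "normality_case_p": norm_case_p,
            "normality_control_p": norm_control_p,
            "n_case": len(case),
            "n_control": len(control),
            "significant": p < alpha,
        })
    result = pd.DataFrame(rows)
    if adjust == "bh" and not result.empty:
        result["p_adjusted"] = _benjamini_hochberg(result["p_value"].to_numpy())
        result["significant_adjusted"] = result["p_adjusted"] < alpha
    return result


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = len(pvals)
    adjusted = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        rank = i + 1
        running = min(running, pvals[order[i]] * m / rank)
        adjusted[order[i]] = running
    return adjusted
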