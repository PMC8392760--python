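"""Statistical comparison battery for input-function curves and CBF.

Curve agreement uses orthogonal (total least squares) regression on
point-by-point data after re-binning the 1-s curves back onto the
scanner frame grid; slope outliers are flagged by a 3-scaled-MAD rule.
Value agreement uses paired t-tests, mean ratios and Bland-Altman
limits of agreement.  ``run_case`` composes the three evaluation
designs: per-condition leave-one-out (case 1), train-on-baseline /
test-on-challenge transfer (case 2), and direct IDIF_10-driven kinetic
modelling with no GP at all (case 3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .carotid_segmentation import IdifSet
from .curves import TimeActivityCurve, default_frame_schedule, rebin_to_frames
from .gp_mlif import build_training_set, loo_cross_validate, predict, train
from .kinetics import fit_1tcm

__all__ = [
    "RegressionResult",
    "AgreementReport",
    "CaseDesign",
    "ScanRecord",
    "CaseReport",
    "orthogonal_regression",
    "flag_slope_outliers",
    "bland_altman",
    "paired_comparison",
    "run_case",
    "MAD_SCALE",
]

#: Normal-consistency factor turning a MAD into a sigma estimate.
MAD_SCALE = 1.4826


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r2: float


@dataclass(frozen=True)
class AgreementReport:
    bias: float
    loa_low: float
    loa_high: float
    t_stat: float
    p_value: float
    mean_ratio: float


@dataclass(frozen=True)
class CaseDesign:
    """One row of the evaluation design table.

    Case 1: per-condition leave-one-out GP models.
    Case 2: GP trained on all baseline scans, tested on challenge scans.
    Case 3: no GP — kinetic modelling driven directly by IDIF_10.
    """

    case_id: int

    def __post_init__(self) -> None:
        if self.case_id not in (1, 2, 3):
            raise ValueError("case_id must be 1, 2 or 3")


@dataclass(frozen=True)
class ScanRecord:
    """Everything the evaluation needs for one scan: the extracted IDIF
    channels, the blood-derived AIF, and the grey-matter tissue curve
    (all on the 0-360 s, 1-s grid)."""

    subject_id: int
    condition: str
    idifs: IdifSet
    aif: TimeActivityCurve
    gm_tac: TimeActivityCurve


@dataclass
class CaseReport:
    case_id: int
    cbf_ref: dict = field(default_factory=dict)  # condition -> array of AIF-based CBF
    cbf_test: dict = field(default_factory=dict)  # condition -> array per the case design
    curve_slopes: dict = field(default_factory=dict)
    slope_outliers: dict = field(default_factory=dict)
    pct_change_ref: float = np.nan
    pct_change_test: float = np.nan
    change_p_value: float = np.nan
    agreement: dict = field(default_factory=dict)  # condition -> AgreementReport
    regression: RegressionResult | None = None


def orthogonal_regression(x, y) -> RegressionResult:
    """Total-least-squares line through (x, y), equal error variances.

    The slope comes from the right singular vector of the centred data
    matrix associated with its smallest singular value (the direction of
    least perpendicular scatter); r^2 is the squared Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired points")
    xc, yc = x - x.mean(), y - y.mean()
    if np.allclose(xc, 0):
        raise ValueError("degenerate input: x has no variance")
    _, _, vt = np.linalg.svd(np.column_stack([xc, yc]), full_matrices=False)
    v = vt[-1]  # normal to the fitted line
    if v[1] == 0:
        raise ValueError("fitted line is vertical")
    slope = -v[0] / v[1]
    intercept = y.mean() - slope * x.mean()
    if np.allclose(yc, 0):
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
    return RegressionResult(slope=float(slope), intercept=float(intercept), r2=r2)


def flag_slope_outliers(slopes) -> np.ndarray:
    """Flag slopes more than 3 scaled MADs from the median slope.

    scaled MAD = 1.4826 * median(|s_i - median(s)|).  If the MAD is zero
    the rule degenerates: any value different from the median is flagged.
    """
    s = np.asarray(slopes, dtype=float)
    if len(s) < 3:
        raise ValueError("need >= 3 slopes")
    med = np.median(s)
    mad = MAD_SCALE * np.median(np.abs(s - med))
    if mad == 0:
        return s != med
    return np.abs(s - med) > 3.0 * mad


def bland_altman(a, b) -> tuple[float, float, float]:
    """Bias and 95% limits of agreement: mean(a-b) -+ 1.96 SD(a-b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired arrays must have equal length")
    if len(a) < 2:
        raise ValueError("need >= 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def paired_comparison(a, b) -> AgreementReport:
    """Two-sided paired t-test, mean per-pair ratio and Bland-Altman
    limits for two matched sets of values."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("need >= 2 pairs of equal length")
    if np.any(b == 0):
        raise ValueError("zero denominator in ratio calculation")
    d = a - b
    if np.allclose(d, d[0]) and np.allclose(d, 0):
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_rel(a, b)
        if not np.isfinite(t_stat):  # zero-variance differences
            t_stat, p = (0.0, 1.0) if np.allclose(d, 0) else (np.inf, 0.0)
    bias, lo, hi = bland_altman(a, b)
    return AgreementReport(
        bias=bias,
        loa_low=lo,
        loa_high=hi,
        t_stat=float(t_stat),
        p_value=float(p),
        mean_ratio=float(np.mean(a / b)),
    )


def _curve_slope(pred: TimeActivityCurve, ref: TimeActivityCurve) -> float:
    """Point-by-point orthogonal-regression slope of predicted vs
    reference curve, on the original scanner frame grid."""
    sched = default_frame_schedule()
    p = rebin_to_frames(pred, sched)
    r = rebin_to_frames(ref, sched)
    return orthogonal_regression(r.value, p.value).slope


def _fit_cbf(rec: ScanRecord, input_fn: TimeActivityCurve) -> float:
    return fit_1tcm(rec.gm_tac, input_fn).params.K1


def _pct_change(base: np.ndarray, chal: np.ndarray) -> float:
    """Mean per-subject percent change from baseline to challenge."""
    return float(np.mean(chal / base - 1.0) * 100.0)


def run_case(
    case: CaseDesign,
    cohort_baseline: list[ScanRecord],
    cohort_acz: list[ScanRecord],
) -> CaseReport:
    """Run one evaluation design on paired baseline/challenge cohorts.

    Scans must be paired by subject (same order, same subject_ids).
    The reference arm always fits CBF with the measured AIF; the test
    arm uses the case's input function (GP-predicted MLIF or IDIF_10).
    """
    ids_b = [r.subject_id for r in cohort_baseline]
    ids_a = [r.subject_id for r in cohort_acz]
    if ids_b != ids_a:
        raise ValueError("cohorts must be paired by subject, in the same order")
    report = CaseReport(case_id=case.case_id)
    conditions = {"baseline": cohort_baseline, "acetazolamide": cohort_acz}

    # reference arm: AIF-driven CBF for every scan
    for cond, recs in conditions.items():
        report.cbf_ref[cond] = np.array([_fit_cbf(r, r.aif) for r in recs])

    if case.case_id in (1, 2):
        mlif: dict[str, list[TimeActivityCurve]] = {}
        # baseline arm is leave-one-out in both cases
        preds_b = loo_cross_validate([(r.idifs, r.aif) for r in cohort_baseline])
        mlif["baseline"] = [p.mean for p in preds_b]
        if case.case_id == 1:
            preds_a = loo_cross_validate([(r.idifs, r.aif) for r in cohort_acz])
            mlif["acetazolamide"] = [p.mean for p in preds_a]
        else:
            # transfer model: trained on ALL baseline scans
            ts = build_training_set([(r.idifs, r.aif) for r in cohort_baseline])
            model = train(ts, t_grid=cohort_baseline[0].aif.t)
            mlif["acetazolamide"] = [predict(model, r.idifs).mean for r in cohort_acz]
        for cond, recs in conditions.items():
            report.cbf_test[cond] = np.array(
                [_fit_cbf(r, m) for r, m in zip(recs, mlif[cond])]
            )
            slopes = np.array(
                [_curve_slope(m, r.aif) for r, m in zip(recs, mlif[cond])]
            )
            report.curve_slopes[cond] = slopes
            report.slope_outliers[cond] = flag_slope_outliers(slopes)
            report.agreement[cond] = paired_comparison(
                report.cbf_test[cond], report.cbf_ref[cond]
            )
        all_ref = np.concatenate([report.cbf_ref[c] for c in conditions])
        all_test = np.concatenate([report.cbf_test[c] for c in conditions])
        report.regression = orthogonal_regression(all_ref, all_test)
    else:
        # case 3: IDIF_10 directly as input function, no GP
        for cond, recs in conditions.items():
            report.cbf_test[cond] = np.array([_fit_cbf(r, r.idifs.idif10) for r in recs])

    report.pct_change_ref = _pct_change(
        report.cbf_ref["baseline"], report.cbf_ref["acetazolamide"]
    )
    report.pct_change_test = _pct_change(
        report.cbf_test["baseline"], report.cbf_test["acetazolamide"]
    )
    _, p = stats.ttest_rel(report.cbf_test["acetazolamide"], report.cbf_test["baseline"])
    report.change_p_value = float(p)
    return report
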