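"""Calibration performance metrics: R^2, RMSE, RPD, CV%, ratings, paired t.

R^2 is the squared Pearson correlation between predicted and measured values
(the convention of calibration-software scatter plots); the alternative
1 - SSE/SST definition is available via ``r_squared(..., method="explained")``.
RPD is the reference standard deviation divided by the RMSE; model adequacy
tiers follow the usual chemometric bands (RPD > 4 and R^2 > 0.95 for an
"efficient" model, down to 1.75/0.7 for preliminary screening).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

RATING_ORDER = ("inadequate", "preliminary", "satisfactory", "successful", "efficient")


def rpd(sd: float, rmse: float) -> float:
    """Ratio of performance to deviation, SD/RMSE."""
    if rmse <= 0:
        raise ValueError("RMSE must be > 0 for an RPD (exact fit otherwise)")
    return float(sd) / float(rmse)


def cv_percent(mean: float, sd: float) -> float:
    """Coefficient of variation in percent, 100*SD/mean."""
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return 100.0 * float(sd) / float(mean)


def rmse(measured, predicted) -> float:
    measured = np.asarray(measured, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    return float(np.sqrt(np.mean((measured - predicted) ** 2)))


def r_squared(measured, predicted, method: str = "pearson") -> float:
    """R^2 between measured and predicted values.

    ``method="pearson"`` (default): squared Pearson correlation.
    ``method="explained"``: 1 - SSE/SST.
    """
    measured = np.asarray(measured, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if method == "explained":
        sst = np.sum((measured - measured.mean()) ** 2)
        if sst == 0:
            raise ValueError("zero-variance measured values")
        return float(1.0 - np.sum((measured - predicted) ** 2) / sst)
    if np.std(measured) == 0 or np.std(predicted) == 0:
        # perfectly constant predictions carry no correlation
        return 0.0
    r = np.corrcoef(measured, predicted)[0, 1]
    return float(r * r)


def paired_t(measured, predicted):
    """Classic paired t-test on measured - predicted differences.

    Returns ``(t, df, p)`` with a two-sided p-value; zero-variance nonzero-mean
    differences report an infinite t with p = 0.
    """
    measured = np.asarray(measured, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if measured.size != predicted.size or measured.size < 3:
        raise ValueError("paired t needs equal-length vectors of size >= 3")
    d = measured - predicted
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, n - 1, 1.0
        return math.copysign(math.inf, d.mean()), n - 1, 0.0
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), n - 1, float(p)


def rate_model(r2: float, rpd_value: float) -> str:
    """Adequacy tier from the (R^2, RPD) bands, conservatively.

    Bands: efficient (R^2 > 0.95, RPD > 4), successful (> 0.9, > 3),
    satisfactory (> 0.8, > 2.25), preliminary (> 0.7, > 1.75), else
    inadequate.  When the two indices fall in different tiers, the lower
    tier is returned.
    """
    if not 0 <= r2 <= 1:
        raise ValueError("R^2 must be in [0, 1]")
    if rpd_value <= 0:
        raise ValueError("RPD must be > 0")

    def tier_r2(v):
        return 4 if v > 0.95 else 3 if v > 0.9 else 2 if v > 0.8 else 1 if v > 0.7 else 0

    def tier_rpd(v):
        return 4 if v > 4 else 3 if v > 3 else 2 if v > 2.25 else 1 if v > 1.75 else 0

    return RATING_ORDER[min(tier_r2(r2), tier_rpd(rpd_value))]


def rating_rank(label: str) -> int:
    return RATING_ORDER.index(label)


@dataclass
class ModelReport:
    """Table-style summary of one calibrated model."""

    n_lv: int
    r2_cal: float
    rmse_cal: float
    sd_cal: float
    r2_cv: float
    rmse_cv: float
    rpd_cv: float
    r2_val: float
    rmse_val: float
    rpd_val: float
    sd_val: float
    t_stat: float
    t_df: int
    t_pvalue: float
    exact_fit: bool = False
    rating: str = field(default="")

    def as_dict(self) -> dict:
        return {
            "n_lv": self.n_lv,
            "r2_cal": self.r2_cal, "rmse_cal": self.rmse_cal, "sd_cal": self.sd_cal,
            "r2_cv": self.r2_cv, "rmse_cv": self.rmse_cv, "rpd_cv": self.rpd_cv,
            "r2_val": self.r2_val, "rmse_val": self.rmse_val, "rpd_val": self.rpd_val,
            "sd_val": self.sd_val, "t_stat": self.t_stat, "t_df": self.t_df,
            "t_pvalue": self.t_pvalue, "exact_fit": self.exact_fit, "rating": self.rating,
        }


def evaluate_model(model, X_cal, y_cal, X_val, y_val, cv_pred) -> ModelReport:
    """Assemble the full calibration / cross-validation / validation report.

    ``cv_pred`` holds the cross-validated predictions of the calibration
    samples at the model's latent-variable count.  SDs use the n-1
    denominator; RPDs divide the subset SD by the matching RMSE.
    """
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    y_val = np.asarray(y_val, dtype=float).ravel()
    if y_val.size < 3:
        raise ValueError("validation subset must have >= 3 samples")
    pred_cal = model.predict(X_cal)
    pred_val = model.predict(X_val)
    cv_pred = np.asarray(cv_pred, dtype=float).ravel()
    sd_cal = float(y_cal.std(ddof=1))
    sd_val = float(y_val.std(ddof=1))
    rmse_c = rmse(y_cal, pred_cal)
    rmse_cv = rmse(y_cal, cv_pred)
    rmse_v = rmse(y_val, pred_val)
    exact = rmse_v == 0 or rmse_cv == 0
    rpd_cv = math.inf if rmse_cv == 0 else rpd(sd_cal, rmse_cv)
    rpd_v = math.inf if rmse_v == 0 else rpd(sd_val, rmse_v)
    r2_v = r_squared(y_val, pred_val)
    t, df, p = paired_t(y_val, pred_val)
    report = ModelReport(
        n_lv=model.n_lv,
        r2_cal=r_squared(y_cal, pred_cal), rmse_cal=rmse_c, sd_cal=sd_cal,
        r2_cv=r_squared(y_cal, cv_pred), rmse_cv=rmse_cv, rpd_cv=rpd_cv,
        r2_val=r2_v, rmse_val=rmse_v, rpd_val=rpd_v, sd_val=sd_val,
        t_stat=t, t_df=df, t_pvalue=p, exact_fit=exact,
    )
    report.rating = rate_model(min(max(r2_v, 0.0), 1.0), rpd_v if rpd_v > 0 else 1e-12)
    return report
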