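"""Validation and reproducibility statistics for calibration models.

Conventions (test set of n samples, residuals e_i = pred_i - obs_i):

* bias        = mean(pred) - mean(obs)
* SEP_-b      = SD of residuals (n-1 denominator): the standard error of
                prediction corrected for bias
* RMSEP       = sqrt(mean(e_i^2))
* RPD         = SD(obs) / RMSEP
* R^2         = squared Pearson correlation of obs and pred (default), or
                1 - SSE/SST on request
* SEL         = sqrt(sum(eps_i^2) / 2n) over n duplicate pairs: the
                standard error of laboratory from replicate analyses

Bias and SEP_-b are the two independent components of the RMSEP; the exact
identity is RMSEP^2 = bias^2 + (n-1)/n * SEP_-b^2.
"""

from __future__ import annotations

import decimal
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedStatisticError

#: Published benchmark rows from the LUCAS continental-scale SOC calibration
#: study (best model per subset, with and without auxiliary predictors):
#: subset, treatment, family, predictor, SD, RMSEP, bias, SEP_-b, RPD, R2, N.
LUCAS_BENCHMARK = pd.DataFrame(
    [
        ("Cropland", "SG1", "svm", "spc", 8.6, 4.9, 0.2, 4.9, 1.74, 0.67, 2828),
        ("Cropland", "SG1+SNV", "svm", "rfe+clay", 8.6, 4.0, 0.1, 4.0, 2.17, 0.79, 2828),
        ("Grassland", "SG1", "svm", "spc", 17.4, 9.3, -0.9, 9.3, 1.86, 0.71, 1383),
        ("Grassland", "SG0", "cubist", "rfe+sand", 17.4, 6.4, 0.1, 6.4, 2.70, 0.87, 1383),
        ("Woodland", "SG1", "svm", "spc", 29.8, 15.0, 0.8, 15.0, 1.99, 0.75, 1564),
        ("Woodland", "SG0", "cubist", "rfe+sand", 29.8, 10.3, 1.1, 10.3, 2.88, 0.89, 1564),
        ("Mineral", "SG1", "svm", "spc", 19.1, 8.9, 0.2, 8.9, 2.13, 0.78, 6053),
        ("Mineral", "SG1", "svm", "rfe+sand", 19.1, 7.3, 0.1, 7.3, 2.62, 0.86, 6053),
        ("Organic", "SG1+SNV", "cubist", "spc", 100.8, 50.6, -10.9, 49.5, 1.99, 0.76, 368),
    ],
    columns=["subset", "treatment", "family", "predictor", "sd", "rmsep",
             "bias", "sep_b", "rpd", "r2", "n"],
)


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (report convention; numpy rounds half-even).

    Decimal arithmetic on the shortest repr avoids binary-float artefacts
    on exact halves (2.615 -> 2.62, not 2.61).
    """
    q = decimal.Decimal(1).scaleb(-decimals)
    d = decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)


@dataclass(frozen=True)
class ValidationStats:
    """Test-set performance of a calibration (all in g C kg^-1 except the
    dimensionless rpd and r2)."""

    n: int
    sd_obs: float
    bias: float
    sep_b: float
    rmsep: float
    rpd: float
    r2: float

    def as_dict(self) -> dict:
        return {"n": self.n, "sd_obs": self.sd_obs, "bias": self.bias,
                "sep_b": self.sep_b, "rmsep": self.rmsep, "rpd": self.rpd,
                "r2": self.r2}


def prediction_stats(obs, pred, r2_method: str = "pearson") -> ValidationStats:
    """Full validation suite on a test set.

    A perfect prediction has RMSEP 0; its RPD is reported as ``inf`` (the
    ratio is undefined as a finite number).  Constant observations are
    rejected: SD and RPD are then meaningless.
    """
    obs = np.asarray(obs, float).ravel()
    pred = np.asarray(pred, float).ravel()
    if obs.size != pred.size:
        raise UndefinedStatisticError("obs and pred lengths differ")
    n = obs.size
    if n < 3:
        raise UndefinedStatisticError("need at least 3 observations")
    sd_obs = float(np.std(obs, ddof=1))
    if sd_obs == 0:
        raise UndefinedStatisticError("constant observations: RPD undefined")

    e = pred - obs
    bias = float(np.mean(pred) - np.mean(obs))
    sep_b = float(np.std(e, ddof=1))
    rmsep = float(np.sqrt(np.mean(e**2)))
    rpd = math.inf if rmsep == 0 else sd_obs / rmsep

    if r2_method == "pearson":
        sd_pred = np.std(pred)
        r2 = float(np.corrcoef(obs, pred)[0, 1] ** 2) if sd_pred > 0 else 0.0
    elif r2_method == "ssr":
        sst = float(np.sum((obs - obs.mean()) ** 2))
        r2 = 1.0 - float(np.sum(e**2)) / sst
    else:
        raise UndefinedStatisticError(f"unknown r2_method {r2_method!r}")
    return ValidationStats(n=n, sd_obs=sd_obs, bias=bias, sep_b=sep_b,
                           rmsep=rmsep, rpd=rpd, r2=r2)


def sel(duplicates: Sequence[tuple[float, float]] | np.ndarray) -> float:
    """Standard error of laboratory from duplicate pairs:
    SEL = sqrt(sum(eps_i^2) / 2n), eps_i the within-pair difference."""
    pairs = np.asarray(duplicates, float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 1:
        raise UndefinedStatisticError(
            "duplicates must be an (n, 2) array of paired values"
        )
    if not np.all(np.isfinite(pairs)):
        raise UndefinedStatisticError("unpaired (missing) replicate values")
    eps = pairs[:, 0] - pairs[:, 1]
    return float(np.sqrt(np.sum(eps**2) / (2 * pairs.shape[0])))


def relative_rmsep_by_class(
    obs, pred,
    soc_bins: Sequence[float],
    covariate,
    cov_bins: Sequence[float],
    min_cell: int = 3,
) -> pd.DataFrame:
    """Relative RMSEP (RMSEP / mean observed SOC) per SOC x covariate cell.

    Cells with fewer than ``min_cell`` samples report NaN with their count;
    empty or undefined cells are data, not failures.
    """
    obs = np.asarray(obs, float).ravel()
    pred = np.asarray(pred, float).ravel()
    cov = np.asarray(covariate, float).ravel()
    df = pd.DataFrame({"obs": obs, "pred": pred, "cov": cov})
    df["soc_class"] = pd.cut(df["obs"], soc_bins, include_lowest=True)
    df["cov_class"] = pd.cut(df["cov"], cov_bins, include_lowest=True)

    rows = []
    for (sc, cc), g in df.groupby(["soc_class", "cov_class"], observed=False):
        count = len(g)
        if count >= min_cell and g["obs"].mean() != 0:
            rmsep = float(np.sqrt(np.mean((g["pred"] - g["obs"]) ** 2)))
            rel = rmsep / float(g["obs"].mean())
        else:
            rel = np.nan
        rows.append({"soc_class": str(sc), "cov_class": str(cc),
                     "n": count, "relative_rmsep": rel})
    return pd.DataFrame(rows)


REPORT_COLUMNS = ["Subset", "Treatment", "Family", "Predictor", "SD", "RMSEP",
                  "Bias", "SEP-b", "RPD", "R2", "N"]


def performance_report(rows: Sequence[dict]) -> pd.DataFrame:
    """Benchmark-style performance table: one row per model.

    Each input row needs subset/treatment/family/predictor labels and a
    :class:`ValidationStats`.  Values are rounded half away from zero, one
    decimal for the g C kg^-1 columns and two for RPD and R^2.
    """
    out = []
    for row in rows:
        s: ValidationStats = row["stats"]
        out.append({
            "Subset": row.get("subset", ""),
            "Treatment": row.get("treatment", ""),
            "Family": row.get("family", ""),
            "Predictor": row.get("predictor", "spc"),
            "SD": round_half_away(s.sd_obs, 1),
            "RMSEP": round_half_away(s.rmsep, 1),
            "Bias": round_half_away(s.bias, 1),
            "SEP-b": round_half_away(s.sep_b, 1),
            "RPD": round_half_away(s.rpd, 2) if math.isfinite(s.rpd) else math.inf,
            "R2": round_half_away(s.r2, 2),
            "N": s.n,
        })
    return pd.DataFrame(out, columns=REPORT_COLUMNS)


def format_report(table: pd.DataFrame) -> str:
    """Aligned plain-text rendering of a performance table."""
    return table.to_string(index=False)
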