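"""Quantitative endpoints: volume, Dice overlap, regression, agreement tests.

Volumes are voxel counts times voxel volume (mm^3). Concordance between
measured and reference volumes is summarised by ordinary least squares
(slope, intercept, R^2, RMSE, 95% t-intervals) and by Bland-Altman limits of
agreement [mean - 1.96 SD, mean + 1.96 SD] of the differences. Shape
agreement uses the Dice similarity coefficient 2|A n B| / (|A| + |B|);
profiles are compared with a two-tailed paired t-test after a
Kolmogorov-Smirnov check that the standardised differences are consistent
with a normal distribution. Sample standard deviations use the n-1
denominator throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .geometry import BinaryMask, same_grid, voxel_volume_mm3

__all__ = [
    "DiceResult",
    "RegressionResult",
    "BlandAltmanResult",
    "compute_volume",
    "dice_coefficient",
    "linear_regression",
    "bland_altman",
    "paired_t_test",
    "ks_normality",
    "evaluate_experiment",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiceResult:
    value: float
    size_a: int
    size_b: int
    intersection: int


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    rmse: float
    slope_ci_95: tuple[float, float]
    intercept_ci_95: tuple[float, float]


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float


def compute_volume(mask: BinaryMask) -> float:
    """Voxel count times voxel volume, in mm^3."""
    return mask.voxel_count * voxel_volume_mm3(mask)


def dice_coefficient(a: BinaryMask, b: BinaryMask) -> DiceResult:
    """Dice similarity 2|A n B| / (|A| + |B|) on a shared grid.

    Two empty masks are defined as Dice 1 (with a warning); mismatched grids
    raise.
    """
    if not same_grid(a, b):
        raise ValueError("masks must share shape, spacing and origin")
    na, nb = a.voxel_count, b.voxel_count
    inter = int((a.values & b.values).sum())
    if na + nb == 0:
        log.warning("both masks empty; Dice defined as 1")
        return DiceResult(1.0, 0, 0, 0)
    return DiceResult(2 * inter / (na + nb), na, nb, inter)


def linear_regression(reference, measured) -> RegressionResult:
    """OLS of measured on reference with classical 95% t-intervals.

    RMSE is the root mean squared residual (n denominator, a goodness-of-fit
    summary rather than an unbiased variance estimate).
    """
    x = np.asarray(reference, dtype=float)
    y = np.asarray(measured, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("reference and measured must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("need at least three points")
    if np.ptp(x) == 0:
        raise ValueError("reference values have zero variance")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    ci = fit.conf_int(alpha=0.05)
    rmse = float(np.sqrt(np.mean(fit.resid**2)))
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        rmse=rmse,
        slope_ci_95=(float(ci[1, 0]), float(ci[1, 1])),
        intercept_ci_95=(float(ci[0, 0]), float(ci[0, 1])),
    )


def bland_altman(measured, reference) -> BlandAltmanResult:
    """Limits of agreement of measured - reference: mean +/- 1.96 sample SD."""
    m = np.asarray(measured, dtype=float)
    r = np.asarray(reference, dtype=float)
    if m.shape != r.shape or m.ndim != 1 or m.size < 2:
        raise ValueError("need two equal-length samples with n >= 2")
    diff = m - r
    delta = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltmanResult(delta, sd, delta - 1.96 * sd, delta + 1.96 * sd)


def paired_t_test(a, b) -> tuple[float, float]:
    """Two-tailed paired t-test; returns (t, p) with n-1 degrees of freedom."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length samples with n >= 2")
    if np.ptp(a - b) == 0:
        raise ValueError("paired differences have zero variance")
    t, p = sps.ttest_rel(a, b)
    return float(t), float(p)


def ks_normality(differences) -> tuple[float, float]:
    """One-sample KS test of the standardised differences against N(0, 1).

    The sample is z-scored (mean 0, SD 1) before the test, so the check is
    of distributional shape rather than location/scale.
    """
    d = np.asarray(differences, dtype=float)
    if d.ndim != 1 or d.size < 3:
        raise ValueError("need at least three differences")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("differences have zero variance")
    z = (d - d.mean()) / sd
    stat, p = sps.kstest(z, "norm")
    return float(stat), float(p)


def evaluate_experiment(
    reference_volumes: dict[str, float],
    measured_volumes: dict[str, dict[str, list[float]]],
    dice_values: dict[str, dict[str, list[float]]],
) -> dict[str, pd.DataFrame]:
    """Assemble report tables from per-nodule, per-profile measurements.

    Parameters
    ----------
    reference_volumes : nodule name -> reference volume (mm^3).
    measured_volumes : profile -> nodule name -> volumes of each repeat.
    dice_values : profile -> nodule name -> Dice of each repeat.

    Returns tables: ``regression`` (per profile: slope/intercept with CIs,
    R^2, RMSE), ``bland_altman`` (per profile), ``dice`` (per nodule x
    profile, mean +/- SD over repeats), ``t_tests`` (pairwise profile
    comparisons of per-nodule mean Dice), and ``volumes`` (per nodule x
    profile, repeat-averaged). Missing cells are skipped with a warning.
    """
    nodules = list(reference_volumes)
    profiles = list(measured_volumes)

    vol_rows, dice_rows = {}, {}
    for prof in profiles:
        vols, dices = {}, {}
        for nod in nodules:
            reps = measured_volumes.get(prof, {}).get(nod)
            if not reps:
                log.warning("missing volume for nodule %r profile %r", nod, prof)
                continue
            vols[nod] = float(np.mean(reps))
            dreps = dice_values.get(prof, {}).get(nod, [])
            if dreps:
                dices[nod] = (float(np.mean(dreps)), float(np.std(dreps, ddof=1)))
        vol_rows[prof] = vols
        dice_rows[prof] = dices

    reg_records, ba_records = [], []
    for prof in profiles:
        common = [n for n in nodules if n in vol_rows[prof]]
        ref = [reference_volumes[n] for n in common]
        meas = [vol_rows[prof][n] for n in common]
        if len(common) >= 3:
            r = linear_regression(ref, meas)
            reg_records.append(
                {
                    "profile": prof,
                    "slope": r.slope,
                    "slope_ci_low": r.slope_ci_95[0],
                    "slope_ci_high": r.slope_ci_95[1],
                    "intercept_mm3": r.intercept,
                    "intercept_ci_low": r.intercept_ci_95[0],
                    "intercept_ci_high": r.intercept_ci_95[1],
                    "r_squared": r.r_squared,
                    "rmse_mm3": r.rmse,
                }
            )
        if len(common) >= 2:
            ba = bland_altman(meas, ref)
            ba_records.append(
                {
                    "profile": prof,
                    "mean_diff_mm3": ba.mean_diff,
                    "sd_diff_mm3": ba.sd_diff,
                    "loa_low_mm3": ba.loa_low,
                    "loa_high_mm3": ba.loa_high,
                }
            )

    dice_table = pd.DataFrame(
        {
            prof: {n: dice_rows[prof][n][0] for n in dice_rows[prof]}
            for prof in profiles
        }
    )
    dice_sd_table = pd.DataFrame(
        {
            prof: {n: dice_rows[prof][n][1] for n in dice_rows[prof]}
            for prof in profiles
        }
    )

    t_records = []
    for i, p1 in enumerate(profiles):
        for p2 in profiles[i + 1 :]:
            common = [n for n in nodules if n in dice_rows[p1] and n in dice_rows[p2]]
            if len(common) < 2:
                continue
            a = [dice_rows[p1][n][0] for n in common]
            b = [dice_rows[p2][n][0] for n in common]
            try:
                t, p = paired_t_test(a, b)
            except ValueError:
                t, p = float("nan"), 1.0
                log.warning("degenerate paired differences for %r vs %r", p1, p2)
            t_records.append({"profile_a": p1, "profile_b": p2, "t": t, "p": p})

    volumes_table = pd.DataFrame(vol_rows)
    volumes_table.insert(0, "reference_mm3", pd.Series(reference_volumes))
    return {
        "regression": pd.DataFrame(reg_records),
        "bland_altman": pd.DataFrame(ba_records),
        "dice": dice_table,
        "dice_sd": dice_sd_table,
        "t_tests": pd.DataFrame(t_records),
        "volumes": volumes_table,
    }
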