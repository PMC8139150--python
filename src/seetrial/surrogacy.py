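"""Trial-level surrogacy: weighted meta-regression of treatment effects.

Step 2 of the evaluation regresses the per-group true-endpoint effect on
the per-group surrogate-endpoint effect by weighted least squares, with
group subject counts as weights. Both effects enter on the log hazard
ratio scale (results are reported as hazard ratios). The strength of the
trial-level association is the coefficient of determination R²_group of
this regression — equivalently the squared weighted Pearson correlation —
with a 95% confidence interval from the delta-method variance

    Var(R²) = 4 R² (1 − R²)² / (n − 3),

clipped to [0, 1]. A group-level bootstrap interval is available as an
alternative.

The surrogate threshold effect (STE) is the least favourable surrogate
hazard ratio that still predicts a benefit on the true endpoint: the
point where the upper limit of the 95% prediction band for a new group
crosses a true-endpoint hazard ratio of 1.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import brentq


class SurrogacyError(ValueError):
    """The step-2 regression cannot be fitted or summarised."""


@dataclasses.dataclass(frozen=True)
class SurrogacyFit:
    """Weighted regression of true on surrogate log hazard ratios.

    Retains the regression inputs (``x`` = surrogate log HRs, ``y`` = true
    log HRs, ``w`` = group weights) so prediction bands, the surrogate
    threshold and leave-one-out refits can be derived without refitting
    from subject level.
    """

    n_groups: int
    slope: float
    intercept: float
    sigma2: float          # weighted residual variance, df = n - 2
    r2: float
    r2_ci: tuple[float, float] | None
    x: np.ndarray
    y: np.ndarray
    w: np.ndarray
    xtwx_inv: np.ndarray   # (X'WX)^-1 for the design [1, x]
    log_scale: bool = True

    @property
    def ste_hr(self) -> float | None:
        """Surrogate threshold effect on the HR scale, or None."""
        return surrogate_threshold(self).hr

    def predict(self, x0: np.ndarray | float) -> np.ndarray | float:
        return self.intercept + self.slope * np.asarray(x0, dtype=float)


def fit_weighted_regression(
    effects: pd.DataFrame,
    weight_column: str = "n_subjects",
    log_scale: bool = True,
    ci_level: float = 0.95,
) -> SurrogacyFit:
    """Fit the step-2 weighted least-squares regression across groups.

    Parameters
    ----------
    effects
        Per-group effect table with columns ``log_hr_surrogate``,
        ``log_hr_true``, ``usable`` and the weight column. Only rows with
        ``usable`` true enter the fit.
    log_scale
        Regress log hazard ratios (default). With ``False`` the raw
        hazard ratios are used instead (for comparison only).

    Notes
    -----
    R² is computed about the weighted mean, ``1 − SS_res,w / SS_tot,w``,
    identical to the squared weighted Pearson correlation of x and y.
    The confidence interval uses the delta-method formula and needs at
    least 4 groups; with 3 usable groups the fit succeeds with
    ``r2_ci=None``.
    """
    usable = effects[effects["usable"].astype(bool)] if "usable" in effects \
        else effects
    n = len(usable)
    if n < 3:
        raise SurrogacyError(
            f"need at least 3 usable groups for the regression, got {n}"
        )
    x = usable["log_hr_surrogate"].to_numpy(dtype=float)
    y = usable["log_hr_true"].to_numpy(dtype=float)
    if not log_scale:
        x, y = np.exp(x), np.exp(y)
    w = usable[weight_column].to_numpy(dtype=float)
    if np.any(w <= 0):
        raise SurrogacyError("group weights must be strictly positive")
    if np.allclose(x, x[0]):
        raise SurrogacyError(
            "all surrogate effects identical; slope is undefined"
        )

    design = sm.add_constant(x)
    res = sm.WLS(y, design, weights=w).fit()
    intercept, slope = (float(c) for c in res.params)
    sigma2 = float(res.scale)  # sum(w r^2) / (n - 2)

    if np.allclose(y, y[0]):
        warnings.warn("all true-endpoint effects identical; R² set to 0",
                      stacklevel=2)
        r2 = 0.0
    else:
        r2 = float(res.rsquared)
    r2 = min(max(r2, 0.0), 1.0)

    ci = r2_confidence_interval(r2, n, level=ci_level) if n >= 4 else None
    return SurrogacyFit(
        n_groups=n, slope=slope, intercept=intercept, sigma2=sigma2,
        r2=r2, r2_ci=ci, x=x, y=y, w=w,
        xtwx_inv=np.asarray(res.normalized_cov_params),
        log_scale=log_scale,
    )


def r2_confidence_interval(r2: float, n_groups: int, level: float = 0.95
                           ) -> tuple[float, float]:
    """Delta-method confidence interval for the trial-level R².

    ``Var(R²) = 4 R² (1 − R²)² / (n − 3)`` with normal quantiles, bounds
    clipped to [0, 1]. Requires at least 4 groups.
    """
    if n_groups <= 3:
        raise SurrogacyError("R² interval needs more than 3 groups")
    if not 0.0 <= r2 <= 1.0:
        raise SurrogacyError("R² must lie in [0, 1]")
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(4.0 * r2 * (1.0 - r2) ** 2 / (n_groups - 3))
    return (float(max(0.0, r2 - half)), float(min(1.0, r2 + half)))


def r2_bootstrap_interval(
    effects: pd.DataFrame,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int | None = None,
    weight_column: str = "n_subjects",
    log_scale: bool = True,
) -> tuple[float, float]:
    """Percentile bootstrap interval for R², resampling groups.

    Resamples usable groups with replacement; replicates with fewer than
    3 distinct surrogate effects are redrawn implicitly (skipped).
    """
    usable = effects[effects["usable"].astype(bool)] if "usable" in effects \
        else effects
    n = len(usable)
    if n < 4:
        raise SurrogacyError("bootstrap interval needs at least 4 groups")
    rng = np.random.default_rng(seed)
    r2s: list[float] = []
    while len(r2s) < n_boot:
        take = usable.iloc[rng.integers(0, n, size=n)]
        if take["log_hr_surrogate"].nunique() < 3:
            continue
        fit = fit_weighted_regression(
            take, weight_column=weight_column, log_scale=log_scale
        )
        r2s.append(fit.r2)
    lo, hi = np.quantile(r2s, [(1 - level) / 2, 0.5 + level / 2])
    return (float(max(0.0, lo)), float(min(1.0, hi)))


def prediction_interval(
    fit: SurrogacyFit,
    x0: float | np.ndarray,
    level: float = 0.95,
    w0: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Prediction interval for a new group's true-endpoint effect at x0.

    ``yhat(x0) ± t_{n−2} sqrt(sigma2 (1/w0 + leverage(x0)))`` with the
    usual weighted leverage ``[1, x0] (X'WX)^{-1} [1, x0]'``. The new
    group's weight ``w0`` defaults to the mean of the fitted group
    weights, keeping band widths comparable across grouping
    granularities.
    """
    if fit.n_groups < 3:
        raise SurrogacyError("prediction interval needs at least 3 groups")
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    if w0 is None:
        w0 = float(np.mean(fit.w))
    if w0 <= 0:
        raise SurrogacyError("new-group weight must be positive")
    design = np.column_stack([np.ones_like(x0), x0])
    leverage = np.einsum("ij,jk,ik->i", design, fit.xtwx_inv, design)
    tq = stats.t.ppf(0.5 + level / 2.0, df=fit.n_groups - 2)
    half = tq * np.sqrt(fit.sigma2 * (1.0 / w0 + leverage))
    yhat = fit.predict(x0)
    lo, hi = yhat - half, yhat + half
    if lo.size == 1:
        return float(lo[0]), float(hi[0])
    return lo, hi


class SurrogateThreshold(NamedTuple):
    """STE result: hazard ratio (or None) and, when absent, the reason."""

    hr: float | None
    reason: str | None


def surrogate_threshold(
    fit: SurrogacyFit,
    level: float = 0.95,
    w0: float | None = None,
    hr_range: tuple[float, float] = (0.05, 1.0),
) -> SurrogateThreshold:
    """Surrogate threshold effect from the upper prediction limit.

    Finds ``x*`` in ``[log hr_range[0], log hr_range[1]]`` where the upper
    limit of the ``level`` prediction band equals a true-endpoint log HR
    of 0, by bracketed root search (solved to well below 1e-6 on the log
    scale); the STE is ``exp(x*)``. Absent, with a reason, when the slope
    is not positive or the band does not cross 0 within the range (band
    too wide, or benefit predicted across the whole range).
    """
    if not fit.log_scale:
        raise SurrogacyError("STE is defined on the log-HR scale fit")
    if fit.slope <= 0:
        return SurrogateThreshold(
            None, f"non-positive slope ({fit.slope:.4g}); the surrogate does "
            "not predict the true endpoint in the protective direction"
        )

    def upper(x: float) -> float:
        return prediction_interval(fit, x, level=level, w0=w0)[1]

    lo_x, hi_x = np.log(hr_range[0]), np.log(hr_range[1])
    u_lo, u_hi = upper(lo_x), upper(hi_x)
    if u_lo >= 0.0:
        return SurrogateThreshold(
            None, "prediction interval too wide: upper limit stays above "
            f"HR 1 down to HR {hr_range[0]:g}"
        )
    if u_hi <= 0.0:
        return SurrogateThreshold(
            None, "upper prediction limit below HR 1 across the whole "
            "range; no crossing to locate"
        )
    x_star = brentq(upper, lo_x, hi_x, xtol=1e-10)
    return SurrogateThreshold(float(np.exp(x_star)), None)


def plot_surrogacy(
    fit: SurrogacyFit,
    path=None,
    level: float = 0.95,
    true_endpoint_label: str = "CV death",
    ax=None,
):
    """Scatter of group effects with regression line, prediction band, STE.

    Hazard-ratio axes; circle areas proportional to group weight (subject
    count). Returns the matplotlib Axes; saves to ``path`` when given.
    """
    import matplotlib
    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5.2, 4.6))
    xg = np.linspace(fit.x.min() - 0.15, fit.x.max() + 0.15, 200)
    lo, hi = prediction_interval(fit, xg, level=level)
    ax.fill_between(np.exp(xg), np.exp(lo), np.exp(hi), color="0.9")
    ax.plot(np.exp(xg), np.exp(fit.predict(xg)), "-", color="C0")
    ax.plot(np.exp(xg), np.exp(lo), "--", color="0.4", lw=0.9)
    ax.plot(np.exp(xg), np.exp(hi), "--", color="0.4", lw=0.9)
    area = 450.0 * fit.w / fit.w.max()
    ax.scatter(np.exp(fit.x), np.exp(fit.y), s=area, facecolors="none",
               edgecolors="C0")
    ax.axhline(1.0, color="0.6", lw=0.8)
    ste = surrogate_threshold(fit, level=level)
    if ste.hr is not None:
        ax.axvline(ste.hr, color="0.5", ls=":", lw=1.0)
        ax.annotate(f"STE {ste.hr:.2f}", (ste.hr, 1.0),
                    textcoords="offset points", xytext=(4, 6),
                    color="0.35", fontsize=9)
    ci_txt = ""
    if fit.r2_ci is not None:
        ci_txt = f" [{fit.r2_ci[0]:.2f}; {fit.r2_ci[1]:.2f}]"
    ax.set_title(f"$R^2_{{group}}$ = {fit.r2:.2f}{ci_txt}", fontsize=10)
    ax.set_xlabel("HR surrogate endpoint (first MACE)")
    ax.set_ylabel(f"HR true endpoint ({true_endpoint_label})")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
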