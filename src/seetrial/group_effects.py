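"""Per-group treatment effects from Cox proportional-hazards fits.

Step 1 of the two-step surrogacy evaluation: within each group of trial
units, estimate the log hazard ratio (active vs control) for the surrogate
composite endpoint and for the true endpoint, with a standard error from
the observed information.

The model has a single binary covariate, so the Cox partial likelihood is
one-dimensional and is maximised here directly by Newton's method with the
Efron correction for tied event times (a bracketed root search on the
score is the fallback). Degenerate groups — no events, or events confined
to one arm, where the partial likelihood is monotone and the hazard ratio
diverges — are signalled with distinct exceptions and flagged rather than
dropped silently.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .grouping import GroupAssignment
from .trial_data import ENDPOINT_COLUMNS, RegionMap, _unit_labels

logger = logging.getLogger(__name__)

EFFECT_COLUMNS = [
    "group_id", "n_subjects", "events_surrogate", "events_true",
    "log_hr_surrogate", "se_surrogate", "log_hr_true", "se_true", "usable",
]


class CoxFitError(ValueError):
    """Base class for degenerate or failed proportional-hazards fits."""


class NoEventsError(CoxFitError):
    """The endpoint has no observed events in the data supplied."""


class MonotoneLikelihoodError(CoxFitError):
    """All events fall in one arm; the partial likelihood has no maximum."""


def _efron_terms(time: np.ndarray, event: np.ndarray, arm: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-event-time quantities for the binary-covariate partial likelihood.

    Returns arrays over distinct event times: total deaths ``d``, active-arm
    deaths ``d1``, and at-risk counts ``n0``/``n1`` per arm (subjects with
    time >= the event time; ties between censoring and death keep the
    censored subject at risk, the usual convention).
    """
    order = np.argsort(time, kind="mergesort")
    t, e, z = time[order], event[order], arm[order]
    ev_times = np.unique(t[e == 1])
    n_total = len(t)
    left = np.searchsorted(t, ev_times, side="left")
    right = np.searchsorted(t, ev_times, side="right")
    # at-risk counts per arm: subjects with t >= event time
    cum1 = np.concatenate([[0], np.cumsum(z)])
    n1 = (cum1[n_total] - cum1[left]).astype(float)
    n0 = (n_total - left) - n1
    # death counts per arm at each event time
    is_ev = e == 1
    cum_e = np.concatenate([[0], np.cumsum(is_ev)])
    cum_e1 = np.concatenate([[0], np.cumsum(is_ev & (z == 1))])
    d = (cum_e[right] - cum_e[left]).astype(float)
    d1 = (cum_e1[right] - cum_e1[left]).astype(float)
    return d, d1, n0, n1


def _score_info(b: float, d: np.ndarray, d1: np.ndarray,
                n0: np.ndarray, n1: np.ndarray) -> tuple[float, float]:
    """Score and observed information of the Efron partial likelihood at b."""
    eb = math.exp(b)
    score = float(d1.sum())
    info = 0.0
    # Efron: for the k-th tied death (j = 0..d-1) subtract j/d of the tied
    # subjects' contributions from the risk-set sums.
    for dk, d1k, n0k, n1k in zip(d, d1, n0, n1):
        j = np.arange(dk) / dk
        a = (n0k + n1k * eb) - j * ((dk - d1k) + d1k * eb)
        bnum = n1k * eb - j * d1k * eb
        p = bnum / a
        score -= float(p.sum())
        info += float((p * (1.0 - p)).sum())
    return score, info


def _score_info_fast(b: float, d: np.ndarray, d1: np.ndarray,
                     n0: np.ndarray, n1: np.ndarray) -> tuple[float, float]:
    """Vectorised score/information when no event times are tied (d == 1)."""
    eb = math.exp(b)
    p = n1 * eb / (n0 + n1 * eb)
    return float(d1.sum() - p.sum()), float((p * (1.0 - p)).sum())


def fit_cox_hr(subjects: pd.DataFrame, endpoint: str,
               tol: float = 1e-8, max_iter: int = 50
               ) -> tuple[float, float]:
    """Maximum partial-likelihood log hazard ratio for one endpoint.

    Parameters
    ----------
    subjects
        Subject table (validated schema); the single covariate is ``arm``.
    endpoint
        ``surrogate``, ``cv_death`` or ``all_cause_death``.

    Returns
    -------
    ``(log_hr, se)`` — the estimate maximising the Efron-corrected Cox
    partial likelihood and its standard error from the observed
    information at the maximum.

    Raises
    ------
    NoEventsError
        If the endpoint has no events at all.
    MonotoneLikelihoodError
        If all events lie in one arm (the estimate diverges).
    """
    try:
        t_col, e_col = ENDPOINT_COLUMNS[endpoint]
    except KeyError:
        raise ValueError(f"unknown endpoint {endpoint!r}; expected one of "
                         f"{sorted(ENDPOINT_COLUMNS)}") from None
    time = subjects[t_col].to_numpy(dtype=float)
    event = subjects[e_col].to_numpy(dtype=int)
    arm = subjects["arm"].to_numpy(dtype=int)
    if event.sum() == 0:
        raise NoEventsError(f"no {endpoint} events in the data")
    ev_active = int(event[arm == 1].sum())
    ev_control = int(event[arm == 0].sum())
    if ev_active == 0 or ev_control == 0:
        raise MonotoneLikelihoodError(
            f"all {endpoint} events fall in the "
            f"{'control' if ev_active == 0 else 'active'} arm; "
            "the partial likelihood is monotone"
        )

    d, d1, n0, n1 = _efron_terms(time, event, arm)
    fn = _score_info_fast if bool(np.all(d == 1)) else _score_info

    b = 0.0
    for _ in range(max_iter):
        score, info = fn(b, d, d1, n0, n1)
        if abs(score) < tol:
            break
        if info <= 0:
            break
        step = score / info
        b += max(-2.0, min(2.0, step))  # damp huge early steps
    else:
        score, info = fn(b, d, d1, n0, n1)
    if abs(score) >= tol:
        # fallback: bracketed root search on the score
        lo, hi = -1.0, 1.0
        while fn(lo, d, d1, n0, n1)[0] < 0 and lo > -50:
            lo *= 2
        while fn(hi, d, d1, n0, n1)[0] > 0 and hi < 50:
            hi *= 2
        b = brentq(lambda x: fn(x, d, d1, n0, n1)[0], lo, hi, xtol=1e-12)
        _, info = fn(b, d, d1, n0, n1)
    if info <= 0:
        raise CoxFitError("non-positive observed information at the optimum")
    return float(b), float(1.0 / math.sqrt(info))


@dataclasses.dataclass(frozen=True)
class GroupEffect:
    """Estimated treatment effects for one group of units."""

    group_id: int
    n_subjects: int
    events_surrogate: int
    events_true: int
    log_hr_surrogate: float
    se_surrogate: float
    log_hr_true: float
    se_true: float
    usable: bool
    note: str = ""


def estimate_group_effects(
    subjects: pd.DataFrame,
    assignment: GroupAssignment,
    true_endpoint: str = "cv_death",
    unit: str = "country",
    region_map: RegionMap | None = None,
) -> pd.DataFrame:
    """Fit per-group Cox models for the surrogate and true endpoints.

    Subjects are mapped to groups through the unit labels of
    ``assignment``. Groups where either endpoint's fit is degenerate are
    returned with ``usable=False`` (and a warning logged), never dropped:
    the downstream regression must decide what to exclude.

    Returns a DataFrame with one row per group (:data:`EFFECT_COLUMNS`
    plus ``note``).
    """
    labels = _unit_labels(subjects, unit, region_map)
    group_of = assignment.group_of()
    unknown = set(labels.unique()) - set(group_of)
    if unknown:
        raise ValueError(
            f"subject units not covered by the assignment: {sorted(unknown)}"
        )
    gids = labels.map(group_of)
    _, e_true = ENDPOINT_COLUMNS[true_endpoint]
    rows: list[GroupEffect] = []
    for gid, df in subjects.groupby(gids, sort=True):
        vals: dict[str, float] = {}
        usable = True
        notes: list[str] = []
        for label, ep in (("surrogate", "surrogate"), ("true", true_endpoint)):
            try:
                loghr, se = fit_cox_hr(df, ep)
            except CoxFitError as err:
                usable = False
                loghr, se = math.nan, math.nan
                notes.append(f"{label}: {err}")
            vals[f"log_hr_{label}"] = loghr
            vals[f"se_{label}"] = se
        if not usable:
            logger.warning("group %s unusable: %s", gid, "; ".join(notes))
        rows.append(GroupEffect(
            group_id=int(gid),
            n_subjects=len(df),
            events_surrogate=int(df["e_surrogate"].sum()),
            events_true=int(df[e_true].sum()),
            usable=usable,
            note="; ".join(notes),
            **vals,
        ))
    return pd.DataFrame([dataclasses.asdict(r) for r in rows])


def read_group_effects(path) -> pd.DataFrame:
    """Read a per-group effect CSV written by :func:`write_group_effects`."""
    df = pd.read_csv(path)
    missing = [c for c in EFFECT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")
    df["usable"] = df["usable"].astype(bool)
    return df


def write_group_effects(effects: pd.DataFrame, path) -> None:
    cols = EFFECT_COLUMNS + (["note"] if "note" in effects.columns else [])
    effects[cols].to_csv(path, index=False)
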