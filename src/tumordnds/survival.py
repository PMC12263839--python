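"""Survival analysis of selection regimes: KM curves, log-rank scans, Cox drugs.

Two scanning statistics relate the selection regime to outcome:

* the *range scan* splits patients by whether their dN/dS falls inside
  [mu - sigma, mu + sigma] for every grid point (mu, sigma) and log-rank
  tests the two groups — significant cells at mu = 1 with the in-group
  doing worse flag the neutral regime as high tumor fitness;
* the *paired scan* classifies each patient pair as "neutral" (in or
  approaching the neutral regime after the later sample) or "escape" (far
  from it or leaving it) over a grid of thresholds on DIS = |1 - dN/dS2|
  and DELTA = dN/dS2 - dN/dS1, and log-rank tests the classes.

Group-wise prognosis direction is the sign of the difference in restricted
mean survival time (to the latest observed event), which stays defined under
heavy censoring where the median survival may not.

Drug effects are summarised by a Cox proportional-hazards model whose
duration variable is the post-treatment distance from neutrality (DIS, fully
observed, so every record is an event) and whose covariates are per-drug 0/1
exposure indicators: a hazard ratio above 1 means exposure is associated
with smaller DIS, i.e. the drug pushes tumors toward the neutral regime.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import restricted_mean_survival_time

from .cohort_io import ClinicalRecord
from .regression import PairedObservation

logger = logging.getLogger(__name__)

IN_GROUP_WORSE = "in_group_worse"
IN_GROUP_BETTER = "in_group_better"


class SurvivalDataError(ValueError):
    """Empty or inconsistent survival input."""


@dataclass
class SurvivalCurve:
    """Kaplan-Meier step function with at-risk counts and censor marks."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray

    def probability_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _durations_events(records) -> tuple[np.ndarray, np.ndarray]:
    records = list(records)
    if not records:
        return np.empty(0), np.empty(0, dtype=bool)
    if isinstance(records[0], ClinicalRecord):
        durations = np.array([r.survival_time for r in records], dtype=float)
        events = np.array([r.event for r in records], dtype=bool)
    else:
        arr = np.asarray(records, dtype=float)
        durations, events = arr[:, 0], arr[:, 1].astype(bool)
    return durations, events


def km_estimate(records) -> SurvivalCurve:
    """Product-limit survival estimate with right censoring."""
    durations, events = _durations_events(records)
    if len(durations) == 0:
        raise SurvivalDataError("empty survival input")
    if np.any(durations <= 0):
        raise SurvivalDataError("survival times must be positive")
    fitter = KaplanMeierFitter()
    fitter.fit(durations, events)
    times = fitter.survival_function_.index.to_numpy(dtype=float)
    survival = fitter.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = (
        fitter.event_table["at_risk"].reindex(fitter.survival_function_.index)
        .to_numpy(dtype=float)
    )
    return SurvivalCurve(
        times=times,
        survival=survival,
        at_risk=at_risk,
        censor_times=np.sort(durations[~events]),
    )


def logrank(group_a, group_b) -> tuple[float, float]:
    """Two-group log-rank statistic (1 df) and p-value."""
    dur_a, ev_a = _durations_events(group_a)
    dur_b, ev_b = _durations_events(group_b)
    if len(dur_a) == 0 or len(dur_b) == 0:
        raise SurvivalDataError("both groups must be non-empty")
    if ev_a.sum() == 0 or ev_b.sum() == 0:
        warnings.warn("log-rank with a group containing zero events", stacklevel=2)
    result = logrank_test(dur_a, dur_b, event_observed_A=ev_a, event_observed_B=ev_b)
    return float(result.test_statistic), float(result.p_value)


def _rmst_direction(group_in, group_out) -> str:
    """Prognosis direction from restricted mean survival time difference."""
    dur_in, ev_in = _durations_events(group_in)
    dur_out, ev_out = _durations_events(group_out)
    event_times = np.concatenate([dur_in[ev_in], dur_out[ev_out]])
    tau = float(event_times.max()) if len(event_times) else float(
        np.concatenate([dur_in, dur_out]).max()
    )
    km_in, km_out = KaplanMeierFitter(), KaplanMeierFitter()
    km_in.fit(dur_in, ev_in)
    km_out.fit(dur_out, ev_out)
    rmst_in = restricted_mean_survival_time(km_in, t=tau)
    rmst_out = restricted_mean_survival_time(km_out, t=tau)
    return IN_GROUP_WORSE if rmst_in < rmst_out else IN_GROUP_BETTER


@dataclass
class ScanResult:
    """Grid of log-rank tests in long format.

    ``cells`` columns: param1, param2, p, direction, n_in, n_out, masked.
    Cells where either group is smaller than the minimum size are masked and
    carry no p-value.
    """

    param1_name: str
    param2_name: str
    cells: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def unmasked(self) -> pd.DataFrame:
        return self.cells[~self.cells["masked"]]


def _scan(membership_fn, grid1, grid2, durations, events, min_group, p1, p2) -> ScanResult:
    n = len(durations)
    rows = []
    for v1 in grid1:
        for v2 in grid2:
            in_mask = membership_fn(v1, v2)
            n_in = int(in_mask.sum())
            n_out = n - n_in
            if min(n_in, n_out) < min_group:
                rows.append(dict(param1=v1, param2=v2, p=np.nan, direction="",
                                 n_in=n_in, n_out=n_out, masked=True))
                continue
            a = np.column_stack([durations[in_mask], events[in_mask]])
            b = np.column_stack([durations[~in_mask], events[~in_mask]])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, p = logrank(a, b)
                direction = _rmst_direction(a, b)
            rows.append(dict(param1=v1, param2=v2, p=p, direction=direction,
                             n_in=n_in, n_out=n_out, masked=False))
    cells = pd.DataFrame(rows)
    if not len(cells[~cells["masked"]]):
        warnings.warn("survival scan produced no unmasked cell", stacklevel=3)
    return ScanResult(param1_name=p1, param2_name=p2, cells=cells)


def range_scan(
    data: pd.DataFrame,
    mu_grid: Sequence[float],
    sigma_grid: Sequence[float],
    min_group: int = 5,
) -> ScanResult:
    """Systematic (mu +/- sigma) survival scan.

    ``data`` needs columns ``dnds``, ``time``, ``event``.  For every grid
    point, patients with dN/dS inside [mu - sigma, mu + sigma] are log-rank
    tested against those outside.
    """
    for column in ("dnds", "time", "event"):
        if column not in data.columns:
            raise SurvivalDataError(f"range_scan input lacks column {column!r}")
    if len(mu_grid) == 0 or len(sigma_grid) == 0:
        raise SurvivalDataError("empty scan grid")
    dnds = data["dnds"].to_numpy(dtype=float)
    durations = data["time"].to_numpy(dtype=float)
    events = data["event"].to_numpy(dtype=bool)

    def member(mu, sigma):
        return (dnds >= mu - sigma) & (dnds <= mu + sigma)

    return _scan(member, mu_grid, sigma_grid, durations, events, min_group, "mu", "sigma")


def classify_neutral_escape(
    pair: PairedObservation,
    dis_thr: float,
    delta_thr: float,
    signed_delta: bool = False,
) -> str:
    """Classify a patient pair as ``"neutral"`` or ``"escape"``.

    Escape means high distance from neutrality post treatment
    (DIS >= dis_thr), or a large change in dN/dS (|DELTA| >= delta_thr, or
    DELTA >= delta_thr when ``signed_delta``) that ends outside the strict
    neutral regime 1 +/- 0.1.  A large swing that lands inside the strict
    neutral band still counts as neutral.
    """
    if pair.dis >= dis_thr:
        return "escape"
    delta = pair.delta if signed_delta else abs(pair.delta)
    if delta >= delta_thr and (pair.dnds_2 < 0.9 or pair.dnds_2 > 1.1):
        return "escape"
    return "neutral"


def paired_scan(
    pairs: Sequence[PairedObservation],
    clinical: Mapping[str, ClinicalRecord] | Iterable[ClinicalRecord],
    dis_grid: Sequence[float],
    delta_grid: Sequence[float],
    min_group: int = 5,
    signed_delta: bool = False,
) -> ScanResult:
    """Paired (DIS, DELTA) survival scan: neutral class vs escape class.

    The in-group is the neutral class, so ``in_group_worse`` cells are the
    signature of the neutral/approaching regime carrying worse prognosis.
    """
    if not isinstance(clinical, Mapping):
        clinical = {r.patient_id: r for r in clinical}
    linked = [(p, clinical[p.patient_id]) for p in pairs if p.patient_id in clinical]
    if not linked:
        raise SurvivalDataError("no pair could be linked to a clinical record")
    if len(linked) < len(pairs):
        logger.info("paired_scan: %d pairs lack clinical records", len(pairs) - len(linked))
    durations = np.array([r.survival_time for _, r in linked])
    events = np.array([r.event for _, r in linked], dtype=bool)
    pair_list = [p for p, _ in linked]

    def member(dis_thr, delta_thr):
        return np.array([
            classify_neutral_escape(p, dis_thr, delta_thr, signed_delta) == "neutral"
            for p in pair_list
        ])

    return _scan(member, dis_grid, delta_grid, durations, events, min_group, "dis", "delta")


def cox_drug_effects(data: pd.DataFrame, drug_columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-drug hazard ratios for reaching neutrality.

    ``data`` needs a ``dis`` column (post-treatment distance from neutrality,
    a fully observed non-negative quantity used as the duration with every
    record an event) plus 0/1 drug indicator columns (auto-detected by the
    ``drug`` prefix when ``drug_columns`` is not given).  Returns a frame
    indexed by drug with columns ``hr``, ``ci_low``, ``ci_high``, ``p``,
    ``n_exposed``; drugs without both exposed and unexposed patients, or
    whose fit fails, are dropped with a warning.
    """
    if "dis" not in data.columns:
        raise SurvivalDataError("cox_drug_effects input lacks column 'dis'")
    if (data["dis"] < 0).any():
        raise SurvivalDataError("DIS must be non-negative")
    if drug_columns is None:
        drug_columns = [c for c in data.columns if c.lower().startswith("drug")]
    usable = []
    for drug in drug_columns:
        values = data[drug].astype(int)
        if values.nunique() < 2:
            warnings.warn(f"drug {drug!r} lacks exposed/unexposed contrast; dropped",
                          stacklevel=2)
            continue
        usable.append(drug)
    if len(usable) < 2:
        raise SurvivalDataError("need at least 2 drugs observed in both states")

    frame = data[["dis"] + usable].copy()
    frame["event"] = 1
    # tiny jitter-free tie handling is left to lifelines (Efron approximation)
    while usable:
        fitter = CoxPHFitter()
        try:
            fitter.fit(frame[["dis", "event"] + usable], duration_col="dis", event_col="event")
            break
        except Exception as exc:  # convergence / separation
            # drop the most imbalanced drug and retry
            worst = min(usable, key=lambda d: frame[d].astype(int).var())
            warnings.warn(f"Cox fit failed ({exc}); dropping drug {worst!r}", stacklevel=2)
            usable.remove(worst)
    else:
        raise SurvivalDataError("Cox model did not converge for any drug subset")

    summary = fitter.summary
    result = pd.DataFrame(
        {
            "hr": np.exp(summary["coef"]),
            "ci_low": np.exp(summary["coef lower 95%"]),
            "ci_high": np.exp(summary["coef upper 95%"]),
            "p": summary["p"],
            "n_exposed": [int(frame[d].astype(int).sum()) for d in summary.index],
        }
    )
    result.index.name = "drug"
    return result


def cox_survival_with_dis(
    data: pd.DataFrame,
    drug_columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Named variant: survival time as duration, DIS and drugs as covariates.

    Provided for sensitivity analysis next to :func:`cox_drug_effects`,
    whose duration variable is DIS itself.
    ``data`` needs ``time``, ``event``, ``dis`` and drug columns.
    """
    for column in ("time", "event", "dis"):
        if column not in data.columns:
            raise SurvivalDataError(f"input lacks column {column!r}")
    if drug_columns is None:
        drug_columns = [c for c in data.columns if c.lower().startswith("drug")]
    covariates = ["dis"] + [c for c in drug_columns if data[c].astype(int).nunique() == 2]
    fitter = CoxPHFitter()
    fitter.fit(data[["time", "event"] + covariates], duration_col="time", event_col="event")
    summary = fitter.summary
    return pd.DataFrame(
        {
            "hr": np.exp(summary["coef"]),
            "ci_low": np.exp(summary["coef lower 95%"]),
            "ci_high": np.exp(summary["coef upper 95%"]),
            "p": summary["p"],
        }
    )
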