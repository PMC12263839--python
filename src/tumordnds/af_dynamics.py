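"""Allele-frequency-resolved dN/dS vs N correlations within single patients.

Allele frequency orders mutations approximately in time: high-AF mutations
are enriched for early, clonal events and low-AF mutations for late,
subclonal ones.  For a patient with enough samples, sweeping an AF threshold
and correlating the per-sample mutation burden N with the per-sample dN/dS
inside each window yields a patient-level heatmap: positive correlations in
high-AF (early) windows reflect driver accumulation, negative correlations
in low-AF (late) windows reflect purifying selection against passengers.

Correlations are computed *across the samples of one patient*; samples are
never pooled across patients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import MutationRecord
from .selection import MIN_MUTATIONS, af_window_dnds
from .site_model import SiteTable

logger = logging.getLogger(__name__)

EARLY = "early"  # AF > t
LATE = "late"  # AF < t

#: Default AF threshold grid for both panels.
DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.05, 1.0, 0.05), 2))


class AfDynamicsError(ValueError):
    """Patient not eligible for the AF-resolved analysis."""


def pearson(xs: Sequence[float], ys: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation with two-sided p-value.

    Returns ``(nan, nan)`` when either input has zero variance (the
    correlation is undefined there); raises for n < 3.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if len(xs) < 3 or len(xs) != len(ys):
        raise AfDynamicsError(f"need matched inputs with n >= 3, got {len(xs)}, {len(ys)}")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return (float("nan"), float("nan"))
    result = stats.pearsonr(xs, ys)
    return float(result.statistic), float(result.pvalue)


@dataclass
class AfCorrelationMatrix:
    """Per-patient heatmap of Pearson r(N, dN/dS) over AF windows.

    ``cells`` columns: panel ("early" for AF > t, "late" for AF < t),
    threshold, r, p, n_used, valid.
    """

    patient_id: str
    thresholds: tuple[float, ...]
    cells: pd.DataFrame

    def panel(self, name: str) -> pd.DataFrame:
        return self.cells[self.cells["panel"] == name]


def af_correlation(
    patient_samples: Mapping[str, Sequence[MutationRecord]],
    site_table: SiteTable,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    min_mutations: int = MIN_MUTATIONS,
    min_samples: int = 3,
) -> AfCorrelationMatrix:
    """AF-windowed correlation matrix for one patient.

    For each threshold t and each panel, every sample's mutations are
    restricted to the window (early: AF > t, i.e. (t, 1]; late: AF < t,
    i.e. [0, t)), the windowed dN/dS is estimated under the usual mutation
    gate, and Pearson r is computed across the samples whose windowed
    estimate is valid.  A cell needs at least ``min_samples`` contributing
    samples to be valid.  Patients with fewer than 5 samples are rejected.
    """
    if len(patient_samples) < 5:
        raise AfDynamicsError(
            f"AF-resolved analysis needs >= 5 samples, got {len(patient_samples)}"
        )
    patient_ids = {recs[0].patient_id for recs in patient_samples.values() if recs}
    patient_id = patient_ids.pop() if len(patient_ids) == 1 else "?"

    rows = []
    for threshold in thresholds:
        for panel in (EARLY, LATE):
            xs, ys = [], []
            for records in patient_samples.values():
                if panel == EARLY:
                    if threshold >= 1.0:
                        continue
                    window = af_window_dnds(
                        records, site_table, threshold, 1.0, min_mutations
                    )
                else:
                    if threshold <= 0.0:
                        continue
                    window = af_window_dnds(
                        records, site_table, 0.0, threshold, min_mutations,
                        lower_inclusive=True, upper_inclusive=False,
                    )
                if window.estimate.valid:
                    xs.append(window.N)
                    ys.append(window.estimate.value)
            if len(xs) >= min_samples:
                r, p = pearson(xs, ys)
                valid = not np.isnan(r)
            else:
                r = p = float("nan")
                valid = False
            rows.append(dict(panel=panel, threshold=threshold, r=r, p=p,
                             n_used=len(xs), valid=valid))
    return AfCorrelationMatrix(
        patient_id=patient_id,
        thresholds=tuple(thresholds),
        cells=pd.DataFrame(rows),
    )


def cohort_af_correlations(
    cohort_samples: Mapping[str, Mapping[str, Sequence[MutationRecord]]],
    site_table: SiteTable,
    **kwargs,
) -> tuple[list[AfCorrelationMatrix], list[str]]:
    """Run :func:`af_correlation` over a cohort; skip ineligible patients."""
    matrices, skipped = [], []
    for patient_id, samples in cohort_samples.items():
        try:
            matrices.append(af_correlation(samples, site_table, **kwargs))
        except AfDynamicsError as exc:
            logger.info("skipping patient %s: %s", patient_id, exc)
            skipped.append(patient_id)
    return matrices, skipped
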