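"""Quantitative batch-cultivation metrics for PHB production.

Residual cell mass (RCM) is cell dry weight (CDW) minus PHB concentration;
PHB content (wt%) is 100 x PHB / CDW; volumetric productivity is the
maximum PHB concentration divided by the elapsed time from the first
sample to the sample where that maximum occurs (switchable to total run
time).  Metrics operate on the raw samples — no smoothing or
interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import CultureSeries

__all__ = ["CultureMetrics", "compute_metrics"]


@dataclass(frozen=True)
class CultureMetrics:
    rcm_series_gL: np.ndarray
    phb_content_series_wt_percent: np.ndarray
    max_phb_gL: float
    max_phb_content_wt_percent: float
    volumetric_productivity_gL_h: float


def compute_metrics(series: CultureSeries,
                    productivity_basis: str = "max") -> CultureMetrics:
    """Per-sample RCM and PHB content plus run-level maxima and productivity.

    ``productivity_basis="max"`` divides the maximum PHB concentration by
    the time from the first sample to that maximum; ``"end"`` divides by
    the whole sampled duration.
    """
    if productivity_basis not in ("max", "end"):
        raise ValueError("productivity_basis must be 'max' or 'end'")
    t = np.asarray(series.t_h, dtype=float)
    cdw = np.asarray(series.cdw_gL, dtype=float)
    phb = np.asarray(series.phb_gL, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 time points")
    if np.any((cdw <= 0) & (phb > 0)):
        raise ValueError("PHB > 0 with CDW = 0 violates PHB <= CDW")

    rcm = cdw - phb
    with np.errstate(divide="ignore", invalid="ignore"):
        content = np.where(cdw > 0, 100.0 * phb / np.where(cdw > 0, cdw, 1.0),
                           0.0)

    i_max = int(np.argmax(phb))
    max_phb = float(phb[i_max])
    if max_phb == 0.0:
        productivity = 0.0
    else:
        elapsed = (t[-1] - t[0]) if productivity_basis == "end" \
            else (t[i_max] - t[0])
        productivity = float("nan") if elapsed <= 0 else max_phb / elapsed

    return CultureMetrics(
        rcm_series_gL=rcm,
        phb_content_series_wt_percent=content,
        max_phb_gL=max_phb,
        max_phb_content_wt_percent=float(content.max()),
        volumetric_productivity_gL_h=productivity,
    )
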