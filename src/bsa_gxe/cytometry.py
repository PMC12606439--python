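"""Flow-cytometry event processing for tandem-timer UPS-activity reporters.

The raw readout per cell is the -log2(RFP/GFP) ratio of a GFP-RFP timer
fusion; because the two fluorophores mature at different rates, this ratio is
proportional to the construct's degradation rate.  Processing steps:

1. optionally select the lower FSC mode (low-nitrogen samples show two cell
   size peaks; only the smaller single-cell mode is analyzed);
2. gate to cells within +/-10% of the median forward scatter (a cell-size
   proxy that removes debris and aggregates);
3. regress the per-event ratio on acquisition time with a loess fit and take
   residuals, restoring the sample mean ("UPS activity" = the time-corrected
   ratio);
4. summarize each replicate by its median activity and median GFP, and
   exclude whole reporter/environment groups whose GFP falls below the
   negative (reporter-free) control.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from statsmodels.nonparametric.smoothers_lowess import lowess

REQUIRED_COLUMNS = ("time_s", "fsc", "gfp", "rfp")
MIN_EVENTS_FOR_FIT = 30


@dataclass
class ReplicateSummary:
    """Gated, time-corrected summary of one cytometry replicate."""

    strain: str
    reporter: str
    environment: str
    replicate: str
    plate: str = ""
    n_events_gated: int = 0
    median_gfp: float = float("nan")
    activity: float = float("nan")
    mean_activity: float = float("nan")
    excluded: bool = False
    exclusion_reason: str = ""


def _check_events(events: pd.DataFrame) -> None:
    if events.empty:
        raise ValueError("empty event table")
    missing = [c for c in REQUIRED_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")


def gate_size(events: pd.DataFrame) -> pd.DataFrame:
    """Keep events with FSC within +/-10% of the sample's median FSC.

    The median uses the midpoint-of-middle-two convention for even counts
    (numpy's default).
    """
    _check_events(events)
    m = float(np.median(events["fsc"].to_numpy()))
    keep = (events["fsc"] >= 0.9 * m) & (events["fsc"] <= 1.1 * m)
    return events.loc[keep]


def select_lower_fsc_mode(events: pd.DataFrame, grid_size: int = 512) -> pd.DataFrame:
    """Return the lower-FSC mode of a bimodal size distribution.

    The FSC density is estimated on the log scale with a Gaussian kernel
    (Silverman's bandwidth).  If at least two local maxima exist, events below
    the deepest local minimum between the two highest maxima are returned;
    a unimodal sample is returned unchanged.
    """
    _check_events(events)
    x = np.log(events["fsc"].to_numpy(dtype=float))
    if np.ptp(x) == 0:
        return events
    kde = gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), grid_size)
    dens = kde(grid)
    interior = np.arange(1, grid_size - 1)
    is_max = (dens[interior] > dens[interior - 1]) & (dens[interior] >= dens[interior + 1])
    maxima = interior[is_max]
    if maxima.size < 2:
        return events
    top_two = maxima[np.argsort(dens[maxima])[-2:]]
    lo, hi = int(top_two.min()), int(top_two.max())
    valley = lo + int(np.argmin(dens[lo:hi + 1]))
    split = grid[valley]
    return events.loc[x < split]


def time_corrected_activity(events: pd.DataFrame, span: float = 0.75) -> tuple[np.ndarray, int]:
    """Per-event UPS activity, corrected for acquisition-time drift.

    ``raw = -log2(rfp/gfp)``; a local-linear loess of ``raw`` on time with the
    given span is subtracted and the sample mean of ``raw`` added back, so
    that between-sample differences survive the correction.  The residuals are
    centered before the mean is restored, making mean preservation exact.

    Events with non-positive RFP or GFP are dropped and counted; the number
    dropped is returned alongside the corrected values.  Fewer than 30 usable
    events is an error (the fit is unstable).
    """
    _check_events(events)
    ok = (events["rfp"] > 0) & (events["gfp"] > 0)
    n_dropped = int((~ok).sum())
    ev = events.loc[ok]
    if len(ev) < MIN_EVENTS_FOR_FIT:
        raise ValueError(f"only {len(ev)} events with positive fluorescence; "
                         f">= {MIN_EVENTS_FOR_FIT} required for the time correction")
    t = ev["time_s"].to_numpy(dtype=float)
    raw = -np.log2(ev["rfp"].to_numpy(dtype=float) / ev["gfp"].to_numpy(dtype=float))
    fit = lowess(raw, t, frac=span, it=1, return_sorted=False)
    resid = raw - fit
    corrected = resid - resid.mean() + raw.mean()
    return corrected, n_dropped


def summarize_replicate(events: pd.DataFrame, *, strain: str, reporter: str,
                        environment: str, replicate: str, plate: str = "",
                        low_nitrogen: bool = False, span: float = 0.75) -> ReplicateSummary:
    """Gate, correct, and summarize one replicate's event table.

    Mode selection (for low-nitrogen samples) runs before the +/-10% size
    gate.  The central value is the median of the corrected activity; the
    mean is also recorded.
    """
    ev = select_lower_fsc_mode(events) if low_nitrogen else events
    ev = gate_size(ev)
    corrected, _ = time_corrected_activity(ev, span=span)
    return ReplicateSummary(
        strain=strain, reporter=reporter, environment=environment,
        replicate=replicate, plate=plate,
        n_events_gated=len(ev),
        median_gfp=float(np.median(ev["gfp"].to_numpy())),
        activity=float(np.median(corrected)),
        mean_activity=float(np.mean(corrected)),
    )


def apply_negative_control_exclusion(summaries: Iterable[ReplicateSummary],
                                     control_median_gfp: float) -> list[ReplicateSummary]:
    """Exclude whole reporter/environment groups with sub-control GFP.

    If any replicate in a (reporter, environment) group has median GFP
    strictly below the negative control's, the reporter cannot be measured in
    that environment and every replicate of the group is flagged excluded
    with reason ``gfp_below_control``.
    """
    summaries = list(summaries)
    bad_groups = {(s.reporter, s.environment)
                  for s in summaries if s.median_gfp < control_median_gfp}
    out = []
    for s in summaries:
        if (s.reporter, s.environment) in bad_groups:
            out.append(replace(s, excluded=True, exclusion_reason="gfp_below_control",
                               activity=float("nan"), mean_activity=float("nan")))
        else:
            out.append(s)
    return out


def summaries_to_frame(summaries: Sequence[ReplicateSummary]) -> pd.DataFrame:
    """Tabular view of replicate summaries (one row per replicate)."""
    return pd.DataFrame([vars(s) for s in summaries])
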