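"""Cq trajectories across an RBC-spike dilution series.

A graded spike of lysed red blood cells into clean plasma (0 to 0.125%
by volume) titrates the effect of contamination: RBC-enriched miRNAs
amplify earlier (Cq decreases) as the spike grows, while unaffected
species stay within ~1 cycle.  A miRNA is called *affected* only when
both a magnitude condition (Cq range over the series >= 1.1 cycles) and
a trend condition (Spearman rank correlation of Cq vs spike fraction
<= -0.8, the abundance-increase direction) hold — magnitude alone ignores
direction, and trend alone over-calls sub-cycle drifts that the
stability data show are noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .cq_data import CqTable, SampleSheet, collapse_replicates
from .errors import ConfigurationError, InsufficientDataError

#: Cycles of Cq range below which a trajectory is considered stable.
RANGE_THRESHOLD = 1.1

#: Spearman rho at or below which the trend counts as a monotone Cq decrease.
RHO_THRESHOLD = -0.8

#: Minimum detected points for trajectory statistics.
MIN_POINTS = 4

CALL_AFFECTED = "affected"
CALL_UNAFFECTED = "unaffected"
CALL_INSUFFICIENT = "insufficient_data"


@dataclass(frozen=True)
class DilutionSeries:
    """Mean Cq per miRNA at each RBC spike fraction.

    ``fractions`` are unique %RBC values in ascending order including the
    0% baseline; ``mean_cq`` is a miRNA x fraction frame where each cell
    averages the replicate-collapsed Cq over the independent series that
    detected the miRNA at that point (NaN when none did).
    """

    fractions: np.ndarray
    mean_cq: pd.DataFrame
    n_series: int = 1

    def __post_init__(self) -> None:
        fr = np.asarray(self.fractions, dtype=float)
        if fr.size < 2 or np.any(np.diff(fr) <= 0):
            raise ConfigurationError("fractions must be strictly increasing")
        if np.any(fr < 0):
            raise ConfigurationError("fractions must be non-negative")
        if fr[0] != 0.0:
            raise ConfigurationError("dilution series must include a 0% baseline")
        object.__setattr__(self, "fractions", fr)


@dataclass(frozen=True)
class TrajectoryStats:
    """Summary of one miRNA's Cq trajectory over the series."""

    mir_id: str
    cq_range: float  # max - min of mean Cq over detected points (cycles)
    rank_correlation: float  # Spearman rho of Cq vs %RBC (midrank ties)
    net_shift: float  # Cq at 0% minus Cq at max fraction; positive = more abundant
    n_points: int


def dilution_series_from_tables(table: CqTable, sheet: SampleSheet) -> DilutionSeries:
    """Assemble a :class:`DilutionSeries` from a Cq table + sample sheet.

    Replicates within a sample are collapsed first; samples sharing the
    same rbc_fraction (independent dilution series) are then averaged
    per point over whichever series detected the miRNA.
    """
    points = sheet.dilution_points()
    if points.empty:
        raise ConfigurationError("sample sheet contains no dilution samples")
    if not table.is_collapsed:
        table = collapse_replicates(table)
    frame = table.frame.copy()
    frame.columns = [s for s, _ in frame.columns]
    missing = [s for s in points["sample_id"] if s not in frame.columns]
    if missing:
        raise ConfigurationError(f"dilution samples absent from Cq table: {missing}")
    fractions = np.array(sorted(points["rbc_fraction"].unique()), dtype=float)
    cols = {}
    max_series = 0
    for f in fractions:
        samples = list(points.loc[points["rbc_fraction"] == f, "sample_id"])
        max_series = max(max_series, len(samples))
        cols[f] = frame[samples].mean(axis=1)  # mean of detected series
    mean_cq = pd.DataFrame(cols)
    mean_cq.index.name = "mir_id"
    return DilutionSeries(fractions=fractions, mean_cq=mean_cq, n_series=max_series)


def trajectory_stats(
    series: DilutionSeries, mir_id: str, min_points: int = MIN_POINTS
) -> TrajectoryStats:
    """Range, trend and endpoint shift of one miRNA's trajectory.

    Raises :class:`InsufficientDataError` when the miRNA is detected at
    fewer than ``min_points`` of the series' points.  A perfectly flat
    trajectory has rank correlation 0 (all Cq ranks tie).
    """
    if mir_id not in series.mean_cq.index:
        raise InsufficientDataError(f"{mir_id!r} not present in the dilution series")
    cq = series.mean_cq.loc[mir_id].to_numpy(dtype=float)
    fr = series.fractions
    det = np.isfinite(cq)
    if det.sum() < min_points:
        raise InsufficientDataError(
            f"{mir_id!r} detected at only {int(det.sum())} of {fr.size} points "
            f"(need {min_points})"
        )
    cq_d, fr_d = cq[det], fr[det]
    cq_range = float(cq_d.max() - cq_d.min())
    if np.ptp(cq_d) == 0.0:
        rho = 0.0
    else:
        rho = float(stats.spearmanr(fr_d, cq_d).statistic)
    if det[0] and det[-1]:
        net_shift = float(cq[0] - cq[det.nonzero()[0][-1]])
    else:
        net_shift = float("nan")
    return TrajectoryStats(
        mir_id=mir_id,
        cq_range=cq_range,
        rank_correlation=rho,
        net_shift=net_shift,
        n_points=int(det.sum()),
    )


def classify_trajectory(
    stats_: TrajectoryStats,
    range_threshold: float = RANGE_THRESHOLD,
    rho_threshold: float = RHO_THRESHOLD,
) -> str:
    """"affected" iff the Cq range reaches the threshold AND the trend is
    a monotone Cq decrease (rho <= rho_threshold); else "unaffected"."""
    affected = (
        stats_.cq_range >= range_threshold
        and stats_.rank_correlation <= rho_threshold
    )
    return CALL_AFFECTED if affected else CALL_UNAFFECTED


def analyze_dilution(
    table: CqTable,
    sheet: SampleSheet,
    range_threshold: float = RANGE_THRESHOLD,
    rho_threshold: float = RHO_THRESHOLD,
    min_points: int = MIN_POINTS,
) -> pd.DataFrame:
    """Trajectory statistics and calls for every miRNA in the table.

    Returns a frame indexed by mir_id with columns cq_range,
    rank_correlation, net_shift, n_points, call; miRNAs detected at too
    few points get call ``insufficient_data``.
    """
    series = dilution_series_from_tables(table, sheet)
    rows = {}
    for mir in series.mean_cq.index:
        try:
            st = trajectory_stats(series, mir, min_points=min_points)
        except InsufficientDataError:
            rows[mir] = {
                "cq_range": np.nan,
                "rank_correlation": np.nan,
                "net_shift": np.nan,
                "n_points": int(np.isfinite(series.mean_cq.loc[mir]).sum()),
                "call": CALL_INSUFFICIENT,
            }
            continue
        rows[mir] = {
            "cq_range": st.cq_range,
            "rank_correlation": st.rank_correlation,
            "net_shift": st.net_shift,
            "n_points": st.n_points,
            "call": classify_trajectory(st, range_threshold, rho_threshold),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "mir_id"
    return out
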