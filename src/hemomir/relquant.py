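"""Un-normalized 2^-dCq relative quantification for matched plasma pairs.

Relative abundance of a miRNA in the hemolyzed member of a matched pair
is 2^-(Cq_H - Cq_NH) — one cycle earlier amplification doubles the
estimate.  Deliberately *no* endogenous-control normalization is applied:
hemolysis itself perturbs candidate reference species, so raw paired
fold changes are the honest quantity.  Independent isolation runs give
per-run fold changes summarized as arithmetic mean +/- SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .cq_data import DETECT_CQ, CqTable, SampleSheet
from .errors import DesignError, UndetectedError

#: Heat-map clip limit in log2 units; 3.3 is roughly a 10-fold difference.
LOG2_CLIP = 3.3

#: Default assay ids for the RBC-contamination ratio indicator.
RATIO_AFFECTED = "hsa-miR-451"
RATIO_STABLE = "hsa-miR-23a"

STATUS_OK = "ok"
STATUS_HEMOLYZED_ONLY = "hemolyzed_only"
STATUS_NONHEMOLYZED_ONLY = "nonhemolyzed_only"
STATUS_BOTH_UNDETECTED = "both_undetected"


@dataclass(frozen=True)
class FoldChange:
    """Fold change of one miRNA in one matched pair (H relative to NH)."""

    mir_id: str
    pair_id: str
    run_fcs: tuple[float, ...] = ()
    mean_fc: Optional[float] = None
    sd_fc: Optional[float] = None
    status: str = STATUS_OK

    @property
    def fc(self) -> Optional[float]:
        return self.mean_fc

    @property
    def evaluable(self) -> bool:
        return self.status == STATUS_OK


def pair_fold_change(cq_hemolyzed: float, cq_nonhemolyzed: float) -> float:
    """2^-(Cq_H - Cq_NH) for a single detected pair of Cq values."""
    if cq_hemolyzed is None or not math.isfinite(cq_hemolyzed):
        raise UndetectedError("hemolyzed Cq is undetected")
    if cq_nonhemolyzed is None or not math.isfinite(cq_nonhemolyzed):
        raise UndetectedError("non-hemolyzed Cq is undetected")
    return float(2.0 ** (-(cq_hemolyzed - cq_nonhemolyzed)))


def fold_change_matrix(
    table: CqTable,
    sheet: SampleSheet,
    detect_cq: float = DETECT_CQ,
) -> list[FoldChange]:
    """Per-(miRNA, pair) fold changes across independent runs.

    The table's replicate columns are treated as independent runs (e.g.
    two separate RNA isolations).  For every run in which both members of
    a pair are detected (Cq < ``detect_cq``) a per-run fold change is
    computed; these are summarized as arithmetic mean +/- sample SD.
    Pairs with no evaluable run are assigned a one-sided status instead
    of a number — one-sided species are reported as qualitatively
    hemolysis-specific, never as pseudo-count fold changes.
    """
    pairs = sheet.pairs()
    if pairs.empty:
        raise DesignError("sample sheet defines no matched pairs")
    missing = [
        s
        for s in pd.unique(pairs[["nonhemolyzed", "hemolyzed"]].to_numpy().ravel())
        if s not in table.sample_ids
    ]
    if missing:
        raise DesignError(f"pair members absent from the Cq table: {missing}")

    out: list[FoldChange] = []
    for pid, row in pairs.iterrows():
        nh = table.sample_frame(row["nonhemolyzed"])
        h = table.sample_frame(row["hemolyzed"])
        shared = [r for r in nh.columns if r in set(h.columns)]
        for mir in table.mir_ids:
            fcs = []
            nh_any = False
            h_any = False
            for run in shared:
                cq_nh = nh.at[mir, run]
                cq_h = h.at[mir, run]
                nh_det = pd.notna(cq_nh) and cq_nh < detect_cq
                h_det = pd.notna(cq_h) and cq_h < detect_cq
                nh_any |= nh_det
                h_any |= h_det
                if nh_det and h_det:
                    fcs.append(pair_fold_change(float(cq_h), float(cq_nh)))
            if fcs:
                arr = np.asarray(fcs)
                sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
                out.append(
                    FoldChange(
                        mir_id=mir,
                        pair_id=str(pid),
                        run_fcs=tuple(float(v) for v in fcs),
                        mean_fc=float(arr.mean()),
                        sd_fc=sd,
                        status=STATUS_OK,
                    )
                )
            else:
                if h_any and not nh_any:
                    status = STATUS_HEMOLYZED_ONLY
                elif nh_any and not h_any:
                    status = STATUS_NONHEMOLYZED_ONLY
                else:
                    status = STATUS_BOTH_UNDETECTED
                out.append(FoldChange(mir_id=mir, pair_id=str(pid), status=status))
    return out


def geometric_mean_fc(run_fcs: Sequence[float]) -> float:
    """Geometric-mean alternative to the arithmetic run summary.

    Equals the fold change computed from run-averaged Cqs (an algebraic
    identity of 2^-dCq); exposed for users preferring the log-scale
    summary, not the default.
    """
    arr = np.asarray(run_fcs, dtype=float)
    if arr.size == 0 or np.any(arr <= 0):
        raise UndetectedError("geometric mean needs positive fold changes")
    return float(np.exp(np.mean(np.log(arr))))


def fold_changes_to_frame(fcs: Iterable[FoldChange]) -> pd.DataFrame:
    """Long-format view: mir_id, pair_id, mean_fc, sd_fc, status."""
    rows = [
        {
            "mir_id": f.mir_id,
            "pair_id": f.pair_id,
            "mean_fc": f.mean_fc,
            "sd_fc": f.sd_fc,
            "status": f.status,
        }
        for f in fcs
    ]
    return pd.DataFrame(rows, columns=["mir_id", "pair_id", "mean_fc", "sd_fc", "status"])


def log2_clip_matrix(fcs: Iterable[FoldChange], limit: float = LOG2_CLIP) -> pd.DataFrame:
    """Heat-map-ready wide matrix of clipped log2 fold changes.

    Values are clamp(log2(mean_fc), -limit, +limit); pairs without an
    evaluable fold change are missing (NaN) cells.
    """
    fcs = list(fcs)
    mirs = list(dict.fromkeys(f.mir_id for f in fcs))
    pairs = list(dict.fromkeys(f.pair_id for f in fcs))
    mat = pd.DataFrame(np.nan, index=mirs, columns=pairs)
    mat.index.name = "mir_id"
    for f in fcs:
        if f.evaluable and f.mean_fc is not None and f.mean_fc > 0:
            mat.at[f.mir_id, f.pair_id] = float(
                np.clip(np.log2(f.mean_fc), -limit, limit)
            )
    return mat


def hemolysis_ratio(cq_affected: float, cq_stable: float) -> float:
    """RBC-contamination indicator: Cq(stable) - Cq(affected).

    With the conventional assays (miR-451 as the RBC-enriched, strongly
    hemolysis-affected species; miR-23a as the stable comparator) a
    larger value means more red-cell signal.  No verdict threshold is
    attached — published cutoffs vary and this package reports the raw
    indicator.
    """
    if cq_affected is None or not math.isfinite(cq_affected):
        raise UndetectedError("affected-miRNA Cq is undetected")
    if cq_stable is None or not math.isfinite(cq_stable):
        raise UndetectedError("stable-miRNA Cq is undetected")
    return float(cq_stable) - float(cq_affected)


def hemolysis_ratio_table(
    table: CqTable,
    affected: str = RATIO_AFFECTED,
    stable: str = RATIO_STABLE,
) -> pd.Series:
    """Per-sample indicator from a collapsed Cq table (NaN when either
    assay is undetected in a sample)."""
    if affected not in table.mir_ids or stable not in table.mir_ids:
        raise DesignError(
            f"assays {affected!r} and {stable!r} must both be present in the table"
        )
    frame = table.frame.copy()
    frame.columns = [s for s, _ in frame.columns]
    out = frame.loc[stable] - frame.loc[affected]
    out.name = "delta_cq_indicator"
    return out
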