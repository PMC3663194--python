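"""Hemolysis-susceptibility tiering and biomarker/control subset selection.

Every detectable miRNA is placed in exactly one tier based on its paired
fold changes (hemolyzed vs non-hemolyzed):

* ``elevated_all_pairs`` / ``elevated_two_pairs`` / ``elevated_one_pair``
  — mean fold change >= 2 in all / >= 2 / exactly 1 of the study's pairs;
* ``stable`` — every evaluable pair within a symmetric multiplicative
  band (default [2/3, 1.5], i.e. "+/-1.5-fold");
* ``hemolysis_specific`` — never detected in clean plasma but present in
  red-blood-cell lysate and hemolyzed plasma;
* ``indeterminate`` — anything else (e.g. decreased species, or outside
  the band without clearing the elevation threshold).

The ">2-fold" criterion is implemented inclusively (mean_fc >= 2.0),
which reconciles the interchangeable phrasings ">2-fold" and "at least
twofold" used for the same rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .cq_data import DETECT_CQ, CqTable, SampleSheet, collapse_replicates, detection_mask
from .errors import ConfigurationError
from .relquant import STATUS_HEMOLYZED_ONLY, FoldChange

UP_THRESHOLD = 2.0
STABLE_BAND = 1.5
DEGREE_CUTOFF = 2.0

TIER_ELEVATED_ALL = "elevated_all_pairs"
TIER_ELEVATED_TWO = "elevated_two_pairs"
TIER_ELEVATED_ONE = "elevated_one_pair"
TIER_STABLE = "stable"
TIER_SPECIFIC = "hemolysis_specific"
TIER_INDETERMINATE = "indeterminate"

TIERS = (
    TIER_ELEVATED_ALL,
    TIER_ELEVATED_TWO,
    TIER_ELEVATED_ONE,
    TIER_STABLE,
    TIER_SPECIFIC,
    TIER_INDETERMINATE,
)


@dataclass(frozen=True)
class SusceptibilityReport:
    """Per-miRNA tier assignments with supporting fold changes.

    ``frame`` is indexed by mir_id with columns tier, n_pairs_elevated,
    n_pairs_evaluable, min_fc, max_fc and one ``fc_<pair>`` column per
    pair.  ``n_pairs_design`` is the number of matched pairs in the
    study, which anchors the meaning of "all pairs".
    """

    frame: pd.DataFrame
    n_pairs_design: int
    pair_ids: tuple[str, ...]

    def tier_counts(self) -> dict[str, int]:
        counts = self.frame["tier"].value_counts().to_dict()
        return {t: int(counts.get(t, 0)) for t in TIERS}

    def elevated_cumulative(self) -> dict[str, int]:
        """Nested elevation counts: all pairs <= >=2 pairs <= >=1 pair."""
        n = self.frame["n_pairs_elevated"]
        return {
            "all_pairs": int((n == self.n_pairs_design).sum()),
            "at_least_two": int((n >= 2).sum()),
            "at_least_one": int((n >= 1).sum()),
        }

    def mirs_in_tier(self, tier: str) -> list[str]:
        return list(self.frame.index[self.frame["tier"] == tier])


def _within_band(fc: float, stable_band: float) -> bool:
    return (1.0 / stable_band) <= fc <= stable_band


def tier_mirnas(
    fcs: Iterable[FoldChange],
    up_threshold: float = UP_THRESHOLD,
    stable_band: float = STABLE_BAND,
    specific_ids: Sequence[str] = (),
) -> SusceptibilityReport:
    """Assign every miRNA in the fold-change collection to one tier.

    ``specific_ids`` (typically the output of :func:`identify_specific`)
    pre-empts the numeric rules: those species are never quantifiable in
    clean plasma, so they are tiered ``hemolysis_specific`` regardless of
    their (one-sided) statuses.  Elevation counts use the mean fold
    change across runs.  In a single-pair design an elevated miRNA is
    tiered ``elevated_one_pair``.
    """
    if up_threshold <= 0 or stable_band <= 1.0:
        raise ConfigurationError(
            "up_threshold must be positive and stable_band must exceed 1"
        )
    fcs = list(fcs)
    specific = set(specific_ids)
    pair_ids = list(dict.fromkeys(f.pair_id for f in fcs))
    n_design = len(pair_ids)
    by_mir: dict[str, dict[str, FoldChange]] = {}
    for f in fcs:
        by_mir.setdefault(f.mir_id, {})[f.pair_id] = f

    rows = []
    for mir, per_pair in by_mir.items():
        ok = {p: f for p, f in per_pair.items() if f.evaluable}
        values = [f.mean_fc for f in ok.values()]
        n_eval = len(ok)
        n_elev = sum(v >= up_threshold for v in values)
        if mir in specific:
            tier = TIER_SPECIFIC
        elif n_eval == 0:
            tier = TIER_INDETERMINATE
        elif n_elev == n_design and n_design >= 2:
            tier = TIER_ELEVATED_ALL
        elif n_elev >= 2:
            tier = TIER_ELEVATED_TWO
        elif n_elev == 1:
            tier = TIER_ELEVATED_ONE
        elif all(_within_band(v, stable_band) for v in values):
            tier = TIER_STABLE
        else:
            tier = TIER_INDETERMINATE
        row = {
            "tier": tier,
            "n_pairs_elevated": n_elev,
            "n_pairs_evaluable": n_eval,
            "min_fc": min(values) if values else np.nan,
            "max_fc": max(values) if values else np.nan,
        }
        for p in pair_ids:
            f = per_pair.get(p)
            row[f"fc_{p}"] = f.mean_fc if (f is not None and f.evaluable) else np.nan
        rows.append((mir, row))

    frame = pd.DataFrame.from_dict(dict(rows), orient="index")
    frame.index.name = "mir_id"
    return SusceptibilityReport(
        frame=frame, n_pairs_design=n_design, pair_ids=tuple(pair_ids)
    )


def identify_specific(
    table: CqTable,
    sheet: SampleSheet,
    max_cq: float = DETECT_CQ,
) -> list[str]:
    """miRNAs present only in RBC lysate and hemolyzed plasma.

    Returns species detected (Cq < ``max_cq``) in at least one RBC
    sample and at least one hemolyzed plasma sample but in *no*
    non-hemolyzed plasma sample.  Species whose amplification never
    clears the detection limit anywhere are excluded by construction —
    a Cq >= 35 signal is not considered quantifiable evidence.
    """
    rbc = sheet.condition_samples("rbc")
    if not rbc:
        raise ConfigurationError("identify_specific requires an RBC-condition sample")
    if not table.is_collapsed:
        table = collapse_replicates(table)
    mask = detection_mask(table, max_cq=max_cq)
    hemolyzed = [s for s in sheet.condition_samples("hemolyzed") if s in mask.columns]
    nonhem = [s for s in sheet.condition_samples("non_hemolyzed") if s in mask.columns]
    rbc = [s for s in rbc if s in mask.columns]
    if not rbc:
        raise ConfigurationError("no RBC sample present in the Cq table")
    in_rbc = mask[rbc].any(axis=1)
    in_h = mask[hemolyzed].any(axis=1) if hemolyzed else pd.Series(False, index=mask.index)
    in_nh = mask[nonhem].any(axis=1) if nonhem else pd.Series(False, index=mask.index)
    keep = in_rbc & in_h & ~in_nh
    return list(mask.index[keep])


def select_subsets(
    fcs: Iterable[FoldChange],
    sheet: SampleSheet,
    degree_cutoff: float = DEGREE_CUTOFF,
    up_threshold: float = UP_THRESHOLD,
    stable_band: float = STABLE_BAND,
) -> dict[str, list[str]]:
    """Matched "changing" and "unaffected" subsets from extensively
    hemolyzed pairs.

    Restricting to pairs whose A414 degree of hemolysis is at least
    ``degree_cutoff``: *changing* species are >= ``up_threshold``-fold
    elevated in every selected pair with fold changes ordered
    concordantly with the pairs' degrees of hemolysis (with two pairs,
    the more hemolyzed pair must show the larger fold change);
    *unaffected* species stay inside the stability band in every
    selected pair.  These subsets are the candidate pools for biomarker
    and endogenous-control selection when hemolyzed samples cannot be
    discarded.
    """
    degrees = sheet.pair_degrees().dropna()
    selected = degrees[degrees >= degree_cutoff].sort_values()
    if len(selected) < 2:
        raise ConfigurationError(
            f"only {len(selected)} pair(s) reach an A414 degree of "
            f"{degree_cutoff:g}; lower degree_cutoff to select at least two"
        )
    order = list(selected.index)  # ascending degree of hemolysis

    by_mir: dict[str, dict[str, FoldChange]] = {}
    for f in fcs:
        by_mir.setdefault(f.mir_id, {})[f.pair_id] = f

    changing, unaffected = [], []
    for mir, per_pair in by_mir.items():
        sel = [per_pair.get(p) for p in order]
        if any(f is None or not f.evaluable for f in sel):
            continue
        values = [f.mean_fc for f in sel]
        if all(v >= up_threshold for v in values) and all(
            b >= a for a, b in zip(values, values[1:])
        ):
            changing.append(mir)
        elif all(_within_band(v, stable_band) for v in values):
            unaffected.append(mir)
    return {"changing": changing, "unaffected": unaffected}
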