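"""Cq tables and sample sheets: parsing, validation, replicate handling
and detectability filtering.

A Cq (quantification cycle) value is the PCR cycle at which a TaqMan
assay's fluorescence crosses a fixed threshold; lower Cq means higher
abundance and reactions that never cross by cycle 40 are *undetected*
("Undetermined" in instrument exports).  Detection for all downstream
analyses is strict: a collapsed Cq must be < 35 cycles to count, which
makes the per-sample rule ("Cq < 35") and the global exclusion rule
("Cq > 35 everywhere") consistent at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DesignError, FormatError, ValidationError

#: Cq values must lie in (0, MAX_CQ]; the thermocycler runs 40 cycles.
MAX_CQ = 40.0

#: Strict detection limit in cycles: detected iff Cq < DETECT_CQ.
DETECT_CQ = 35.0

#: Tokens mapped to the undetected state when parsing (case-insensitive).
UNDETECTED_TOKENS = frozenset({"undetermined", "na", "nan", ""})

#: Serialized form of the undetected state.
UNDETECTED_LABEL = "Undetermined"

CONDITIONS = ("non_hemolyzed", "hemolyzed", "rbc", "dilution")

SAMPLE_LEVEL = "sample_id"
REPLICATE_LEVEL = "replicate"


class CqTable:
    """Cq values per (miRNA assay, sample, replicate).

    Backed by a float DataFrame whose index holds unique assay names and
    whose columns form a two-level (sample_id, replicate) MultiIndex;
    NaN encodes the undetected state.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        if not isinstance(frame.columns, pd.MultiIndex):
            frame.columns = pd.MultiIndex.from_tuples(
                [(str(c), "1") for c in frame.columns],
                names=[SAMPLE_LEVEL, REPLICATE_LEVEL],
            )
        else:
            frame.columns = frame.columns.set_names([SAMPLE_LEVEL, REPLICATE_LEVEL])
        frame.index = frame.index.astype(str)
        frame.index.name = "mir_id"
        if frame.index.duplicated().any():
            dups = sorted(set(frame.index[frame.index.duplicated()]))
            raise FormatError(f"duplicate assay names: {dups}")
        if frame.columns.duplicated().any():
            dups = sorted(set(map(tuple, frame.columns[frame.columns.duplicated()])))
            raise FormatError(f"duplicate sample:replicate columns: {dups}")
        frame = frame.astype(float)
        bad = []
        values = frame.to_numpy()
        with np.errstate(invalid="ignore"):
            mask = np.isfinite(values) & ((values <= 0) | (values > MAX_CQ))
        if mask.any():
            for i, j in zip(*np.nonzero(mask)):
                bad.append((frame.index[i], *frame.columns[j], float(values[i, j])))
            raise ValidationError(
                f"Cq values outside (0, {MAX_CQ:g}]: {bad}"
            )
        self._frame = frame

    # -- basic accessors ---------------------------------------------------

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def mir_ids(self) -> list[str]:
        return list(self._frame.index)

    @property
    def sample_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s, _ in self._frame.columns:
            seen.setdefault(s, None)
        return list(seen)

    @property
    def is_collapsed(self) -> bool:
        counts = pd.Series(1, index=self._frame.columns).groupby(level=SAMPLE_LEVEL).sum()
        return bool((counts == 1).all())

    def replicates_of(self, sample_id: str) -> list[str]:
        return [r for s, r in self._frame.columns if s == sample_id]

    def sample_frame(self, sample_id: str) -> pd.DataFrame:
        """All replicate columns of one sample (columns = replicate labels)."""
        sub = self._frame.loc[:, [c for c in self._frame.columns if c[0] == sample_id]]
        sub.columns = [r for _, r in sub.columns]
        return sub

    def select_mirs(self, mir_ids: Sequence[str]) -> "CqTable":
        missing = [m for m in mir_ids if m not in self._frame.index]
        if missing:
            raise ValidationError(f"unknown assay names: {missing}")
        return CqTable(self._frame.loc[list(mir_ids)])

    def __eq__(self, other) -> bool:  # mainly for round-trip tests
        if not isinstance(other, CqTable):
            return NotImplemented
        return self._frame.equals(other._frame)

    def __repr__(self) -> str:
        return (
            f"CqTable({len(self.mir_ids)} assays x {len(self.sample_ids)} samples, "
            f"{self._frame.shape[1]} columns)"
        )


# ---------------------------------------------------------------------------
# Parsing / serialization


def _sniff_sep(path: Path) -> str:
    head = path.open().readline()
    return "\t" if "\t" in head else ","


def read_cq_table(path) -> CqTable:
    """Read a wide Cq table.

    First column holds assay names; remaining headers are either a bare
    sample id or ``sample:replicate``.  "Undetermined", "NA" and empty
    cells map to the undetected state; any other non-numeric cell is a
    format error, and numeric Cqs outside (0, 40] are validation errors.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=_sniff_sep(path), index_col=0, dtype=str,
                      keep_default_na=False)
    cols = []
    for c in raw.columns:
        c = str(c).strip()
        if ":" in c:
            sample, rep = c.split(":", 1)
        else:
            sample, rep = c, "1"
        cols.append((sample, rep))

    def parse_cell(v: str, where: tuple) -> float:
        v = v.strip()
        if v.lower() in UNDETECTED_TOKENS:
            return np.nan
        try:
            return float(v)
        except ValueError:
            raise FormatError(f"{path}: unparsable Cq cell {v!r} at {where}") from None

    data = np.empty(raw.shape, dtype=float)
    for i, mir in enumerate(raw.index):
        for j, col in enumerate(cols):
            data[i, j] = parse_cell(raw.iat[i, j], (mir, *col))
    frame = pd.DataFrame(
        data,
        index=raw.index.astype(str),
        columns=pd.MultiIndex.from_tuples(cols, names=[SAMPLE_LEVEL, REPLICATE_LEVEL]),
    )
    return CqTable(frame)


def write_cq_table(table: CqTable, path) -> None:
    """Write a wide TSV; undetected cells serialize as "Undetermined".

    Collapsed tables (one replicate per sample) use bare sample headers
    so the round trip is lossless in both layouts.
    """
    frame = table.frame
    if table.is_collapsed:
        headers = [s for s, _ in frame.columns]
    else:
        headers = [f"{s}:{r}" for s, r in frame.columns]
    out = frame.copy()
    out.columns = headers
    out = out.map(lambda v: UNDETECTED_LABEL if pd.isna(v) else f"{v:.6g}")
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Replicate collapsing and detection


def collapse_replicates(table: CqTable, policy: str = "undetected_dominates") -> CqTable:
    """Collapse replicate Cqs to one value per (miRNA, sample).

    Numeric replicates are averaged on the Cq scale.  Under the default
    ``undetected_dominates`` policy a single undetected replicate makes
    the collapsed value undetected — an undetected duplicate near the
    detection limit usually signals stochastic dropout, and trusting the
    remaining replicate inflates low-abundance calls.  ``detected_only``
    instead averages whatever amplified.  Collapsing a collapsed table is
    the identity.
    """
    if policy not in ("undetected_dominates", "detected_only"):
        raise ConfigurationError(f"unknown replicate policy {policy!r}")
    frame = table.frame
    samples = table.sample_ids
    out = pd.DataFrame(index=frame.index, dtype=float)
    for s in samples:
        sub = table.sample_frame(s)
        mean = sub.mean(axis=1)  # skips NaN -> mean of detected
        if policy == "undetected_dominates":
            mean = mean.mask(sub.isna().any(axis=1))
        else:
            mean = mean.mask(sub.isna().all(axis=1))
        out[s] = mean
    out.columns = pd.MultiIndex.from_tuples(
        [(s, "1") for s in samples], names=[SAMPLE_LEVEL, REPLICATE_LEVEL]
    )
    return CqTable(out)


def detection_mask(table: CqTable, max_cq: float = DETECT_CQ) -> pd.DataFrame:
    """Boolean miRNA x sample frame: detected iff numeric and Cq < max_cq."""
    if not table.is_collapsed:
        raise ValidationError("detection_mask requires a replicate-collapsed table")
    frame = table.frame.copy()
    frame.columns = [s for s, _ in frame.columns]
    return frame.notna() & (frame < max_cq)


def filter_detectable(
    table: CqTable,
    min_detected_samples: int = 4,
    sample_subset: Optional[Sequence[str]] = None,
    max_cq: float = DETECT_CQ,
) -> CqTable:
    """Keep miRNAs detected in enough samples of a subset.

    A miRNA survives when it is detected (Cq < ``max_cq``) in at least
    ``min_detected_samples`` of ``sample_subset`` (default: all samples).
    Independently, species never detected in *any* sample of the table
    are always removed.  The operation is idempotent.
    """
    if sample_subset is None:
        sample_subset = table.sample_ids
    sample_subset = list(sample_subset)
    if not sample_subset:
        raise ConfigurationError("sample_subset must be non-empty")
    unknown = [s for s in sample_subset if s not in table.sample_ids]
    if unknown:
        raise ConfigurationError(f"unknown samples in subset: {unknown}")
    if min_detected_samples > len(sample_subset):
        raise ConfigurationError(
            f"min_detected_samples={min_detected_samples} exceeds subset size "
            f"{len(sample_subset)}"
        )
    mask = detection_mask(table, max_cq=max_cq)
    keep = (mask[sample_subset].sum(axis=1) >= min_detected_samples) & mask.any(axis=1)
    return CqTable(table.frame.loc[keep.to_numpy()])


# ---------------------------------------------------------------------------
# Sample sheets


@dataclass(frozen=True)
class SampleSheet:
    """Study design: which sample is what.

    Columns: sample_id, subject_id, condition (non_hemolyzed / hemolyzed /
    rbc / dilution), pair_id (shared by the two members of a matched
    non-hemolyzed/hemolyzed pair, empty otherwise), a414 (optional OD),
    rbc_fraction (%RBC by volume, dilution samples only).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["sample_id", "subject_id", "condition", "pair_id", "a414", "rbc_fraction"]
        frame = self.frame.copy()
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns: {missing}")
        frame = frame[required]
        frame["sample_id"] = frame["sample_id"].astype(str)
        frame["subject_id"] = frame["subject_id"].astype(str)
        frame["condition"] = frame["condition"].astype(str)
        frame["pair_id"] = frame["pair_id"].fillna("").astype(str)
        frame["a414"] = pd.to_numeric(frame["a414"], errors="coerce")
        frame["rbc_fraction"] = pd.to_numeric(frame["rbc_fraction"], errors="coerce")
        if frame["sample_id"].duplicated().any():
            dups = sorted(set(frame.loc[frame["sample_id"].duplicated(), "sample_id"]))
            raise DesignError(f"duplicate sample ids: {dups}")
        bad_cond = sorted(set(frame["condition"]) - set(CONDITIONS))
        if bad_cond:
            raise ValidationError(
                f"unknown conditions {bad_cond}; expected one of {CONDITIONS}"
            )
        is_dil = frame["condition"] == "dilution"
        if frame.loc[is_dil, "rbc_fraction"].isna().any():
            raise ValidationError("dilution samples must carry an rbc_fraction")
        if (frame.loc[is_dil, "rbc_fraction"] < 0).any():
            raise ValidationError("rbc_fraction must be non-negative")
        if frame.loc[~is_dil, "rbc_fraction"].notna().any():
            raise ValidationError("rbc_fraction is only meaningful for dilution samples")
        for pid, grp in frame[frame["pair_id"] != ""].groupby("pair_id"):
            conds = sorted(grp["condition"])
            if conds != ["hemolyzed", "non_hemolyzed"]:
                raise DesignError(
                    f"pair {pid!r} must contain exactly one non_hemolyzed and one "
                    f"hemolyzed sample, found conditions {list(grp['condition'])}"
                )
        frame = frame.reset_index(drop=True)
        object.__setattr__(self, "frame", frame)

    # -- accessors ---------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def condition_samples(self, condition: str) -> list[str]:
        return list(self.frame.loc[self.frame["condition"] == condition, "sample_id"])

    @property
    def plasma_samples(self) -> list[str]:
        """Members of matched pairs (the profiling plasma samples)."""
        f = self.frame
        return list(f.loc[f["condition"].isin(["non_hemolyzed", "hemolyzed"]), "sample_id"])

    def pairs(self) -> pd.DataFrame:
        """One row per pair: columns nonhemolyzed, hemolyzed (sample ids)."""
        rows = {}
        f = self.frame
        for pid, grp in f[f["pair_id"] != ""].groupby("pair_id", sort=True):
            nh = grp.loc[grp["condition"] == "non_hemolyzed", "sample_id"].iloc[0]
            h = grp.loc[grp["condition"] == "hemolyzed", "sample_id"].iloc[0]
            rows[pid] = {"nonhemolyzed": nh, "hemolyzed": h}
        return pd.DataFrame.from_dict(rows, orient="index")

    def pair_degrees(self) -> pd.Series:
        """A414 ratio hemolyzed/non-hemolyzed per pair (NaN when missing)."""
        f = self.frame.set_index("sample_id")
        pairs = self.pairs()
        vals = {}
        for pid, row in pairs.iterrows():
            a_h = f.loc[row["hemolyzed"], "a414"]
            a_nh = f.loc[row["nonhemolyzed"], "a414"]
            if pd.notna(a_h) and pd.notna(a_nh) and a_nh > 0:
                vals[pid] = float(a_h) / float(a_nh)
            else:
                vals[pid] = np.nan
        return pd.Series(vals, name="degree")

    def dilution_points(self) -> pd.DataFrame:
        """Dilution samples sorted by rbc_fraction."""
        f = self.frame
        return (
            f[f["condition"] == "dilution"]
            .sort_values(["rbc_fraction", "sample_id"])
            .reset_index(drop=True)
        )


def read_sample_sheet(path) -> SampleSheet:
    path = Path(path)
    frame = pd.read_csv(path, sep=_sniff_sep(path))
    return SampleSheet(frame)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.frame.to_csv(path, sep="\t", index=False)
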