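"""Absorbance spectra and spectrophotometric hemolysis assessment.

Free hemoglobin released by ruptured red blood cells absorbs strongly at
414 nm (the Soret band); weaker Q-bands at 541 and 576 nm appear only at
high hemoglobin concentrations.  A plasma sample is called hemolyzed when
its optical density at 414 nm strictly exceeds a threshold (default 0.2),
and the degree of hemolysis is expressed relative to a non-hemolyzed
reference as an A414 ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    FormatError,
    InvalidReferenceError,
    ValidationError,
    WavelengthRangeError,
)

#: Default A414 threshold above which a sample is called hemolyzed (OD units).
A414_THRESHOLD = 0.2

#: Hemoglobin Q-band windows scanned for severe-hemolysis peaks, in nm.
Q_BAND_WINDOWS = ((536.0, 546.0), (571.0, 581.0))

#: Minimum height above the local linear baseline for a Q-band call (OD units).
Q_BAND_PROMINENCE = 0.02

#: Most negative optical density tolerated as instrument baseline drift.
MIN_OD = -0.05

SORET_NM = 414.0


@dataclass(frozen=True)
class AbsorbanceSpectrum:
    """An optical-density scan of one plasma sample.

    Parameters
    ----------
    wavelengths
        Strictly increasing wavelengths in nm.  Must bracket 414 nm.
    od
        Unitless optical densities, one per wavelength.  Values below
        ``MIN_OD`` are rejected as corrupt rather than clamped.
    sample_id
        Free-text sample identifier.
    """

    wavelengths: np.ndarray
    od: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        od = np.asarray(self.od, dtype=float)
        if wl.ndim != 1 or od.ndim != 1 or wl.size != od.size:
            raise ValidationError(
                "wavelengths and od must be one-dimensional and equally long"
            )
        if wl.size < 2:
            raise ValidationError("a spectrum needs at least two points")
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(od)):
            raise ValidationError("spectrum contains non-finite values")
        if np.any(np.diff(wl) <= 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if np.any(od < MIN_OD):
            bad = od[od < MIN_OD]
            raise ValidationError(
                f"optical densities below {MIN_OD} are treated as corrupt input "
                f"(worst: {bad.min():.4g})"
            )
        if not (wl[0] <= SORET_NM <= wl[-1]):
            raise ValidationError(
                f"spectrum [{wl[0]:g}, {wl[-1]:g}] nm does not cover "
                f"{SORET_NM:g} nm"
            )
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "od", od)

    @property
    def coverage(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])


@dataclass(frozen=True)
class HemolysisAssessment:
    """Outcome of assessing one sample for hemolysis."""

    a414: float
    label: str  # "hemolyzed" | "non_hemolyzed"
    degree_relative: Optional[float] = None
    severe: bool = False
    sample_id: str = ""


def absorbance_at(spectrum: AbsorbanceSpectrum, wavelength: float) -> float:
    """Optical density at ``wavelength``, linearly interpolated.

    Grid points are reproduced exactly; between grid points the two
    bracketing measurements are interpolated linearly, so 1-nm and 2-nm
    instrument grids agree on shared wavelengths.

    Raises
    ------
    WavelengthRangeError
        If ``wavelength`` lies outside the covered range.
    """
    lo, hi = spectrum.coverage
    if not (lo <= wavelength <= hi):
        raise WavelengthRangeError(
            f"{wavelength:g} nm outside covered range [{lo:g}, {hi:g}] nm"
        )
    return float(np.interp(wavelength, spectrum.wavelengths, spectrum.od))


def relative_degree(a414_sample: float, a414_reference: float) -> float:
    """Degree of hemolysis of a sample relative to a reference.

    Simply ``a414_sample / a414_reference``; a non-hemolyzed counterpart
    of the same collection is the usual reference.
    """
    if not np.isfinite(a414_reference) or a414_reference <= 0:
        raise InvalidReferenceError(
            f"reference A414 must be positive, got {a414_reference!r}"
        )
    if not np.isfinite(a414_sample) or a414_sample <= 0:
        raise ValidationError(f"sample A414 must be positive, got {a414_sample!r}")
    return float(a414_sample) / float(a414_reference)


def relative_degree_replicates(
    sample_ods: Sequence[float],
    reference_ods: Sequence[float],
    mode: str = "mean_of_ratios",
) -> float:
    """Degree of hemolysis from replicate A414 readings.

    ``mean_of_ratios`` pairs replicate readings, forms per-replicate
    ratios and averages them; ``ratio_of_means`` collapses each side to
    its mean first.  The two agree to within printed rounding on typical
    spectrophotometer replicates; both are exposed because neither is
    canonical.
    """
    s = np.asarray(sample_ods, dtype=float)
    r = np.asarray(reference_ods, dtype=float)
    if s.size == 0 or r.size == 0:
        raise InvalidReferenceError("replicate readings must be non-empty")
    if np.any(r <= 0):
        raise InvalidReferenceError("reference A414 readings must be positive")
    if mode == "ratio_of_means":
        return relative_degree(float(s.mean()), float(r.mean()))
    if mode == "mean_of_ratios":
        if s.size != r.size:
            raise ValidationError(
                "mean_of_ratios needs equally many sample and reference readings"
            )
        return float(np.mean(s / r))
    raise ConfigurationError(f"unknown averaging mode {mode!r}")


def detect_q_bands(
    spectrum: AbsorbanceSpectrum,
    windows: Iterable[tuple[float, float]] = Q_BAND_WINDOWS,
    prominence: float = Q_BAND_PROMINENCE,
) -> bool:
    """True if hemoglobin Q-bands are visible in every window.

    A window counts as banded when some interior point rises at least
    ``prominence`` OD above the straight line joining the window's
    endpoint absorbances — i.e. a genuine local maximum, not baseline
    tilt.  Flat or monotone spectra never fire.
    """
    lo_cov, hi_cov = spectrum.coverage
    for lo, hi in windows:
        if lo < lo_cov or hi > hi_cov:
            raise WavelengthRangeError(
                f"Q-band window [{lo:g}, {hi:g}] nm outside covered range "
                f"[{lo_cov:g}, {hi_cov:g}] nm"
            )
        od_lo = absorbance_at(spectrum, lo)
        od_hi = absorbance_at(spectrum, hi)
        inside = (spectrum.wavelengths > lo) & (spectrum.wavelengths < hi)
        wl_in = spectrum.wavelengths[inside]
        if wl_in.size == 0:
            wl_in = np.array([(lo + hi) / 2.0])
        od_in = np.array([absorbance_at(spectrum, w) for w in wl_in])
        baseline = od_lo + (od_hi - od_lo) * (wl_in - lo) / (hi - lo)
        if np.max(od_in - baseline) < prominence:
            return False
    return True


def assess_hemolysis(
    a414: float,
    threshold: float = A414_THRESHOLD,
    reference_a414: Optional[float] = None,
    spectrum: Optional[AbsorbanceSpectrum] = None,
    sample_id: str = "",
) -> HemolysisAssessment:
    """Classify a sample as hemolyzed / non-hemolyzed from its A414.

    The comparison is strict: ``a414`` exactly at the threshold is
    non-hemolyzed.  When a reference A414 is supplied the relative degree
    of hemolysis is attached; when the full spectrum is supplied the
    severe flag reports visible Q-bands.
    """
    if not np.isfinite(a414) or a414 < 0:
        raise ValidationError(f"A414 must be a non-negative number, got {a414!r}")
    if threshold <= 0:
        raise ValidationError(f"threshold must be positive, got {threshold!r}")
    degree: Optional[float] = None
    if reference_a414 is not None:
        if reference_a414 <= 0:
            raise InvalidReferenceError(
                f"reference A414 must be positive, got {reference_a414!r}"
            )
        degree = a414 / reference_a414
    severe = detect_q_bands(spectrum) if spectrum is not None else False
    label = "hemolyzed" if a414 > threshold else "non_hemolyzed"
    return HemolysisAssessment(
        a414=float(a414),
        label=label,
        degree_relative=degree,
        severe=severe,
        sample_id=sample_id,
    )


def assess_spectrum(
    spectrum: AbsorbanceSpectrum,
    threshold: float = A414_THRESHOLD,
    reference_a414: Optional[float] = None,
) -> HemolysisAssessment:
    """Convenience wrapper: extract A414 from a scan and assess it."""
    a414 = absorbance_at(spectrum, SORET_NM)
    return assess_hemolysis(
        a414,
        threshold=threshold,
        reference_a414=reference_a414,
        spectrum=spectrum,
        sample_id=spectrum.sample_id,
    )


# ---------------------------------------------------------------------------
# File I/O


def _sniff_sep(path: Path) -> str:
    head = path.open().readline()
    return "\t" if "\t" in head else ","


def read_spectrum(path, sample_id: Optional[str] = None) -> AbsorbanceSpectrum:
    """Read a two-column ``wavelength_nm``/``od`` delimited text file."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    df.columns = [str(c).strip().lower() for c in df.columns]
    if not {"wavelength_nm", "od"} <= set(df.columns):
        raise FormatError(
            f"{path}: expected columns 'wavelength_nm' and 'od', "
            f"found {list(df.columns)}"
        )
    sid = sample_id if sample_id is not None else path.stem
    return AbsorbanceSpectrum(
        wavelengths=df["wavelength_nm"].to_numpy(float),
        od=df["od"].to_numpy(float),
        sample_id=sid,
    )


def read_spectra_long(path) -> dict[str, AbsorbanceSpectrum]:
    """Read a long-format file with columns sample_id, wavelength_nm, od."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    df.columns = [str(c).strip().lower() for c in df.columns]
    required = {"sample_id", "wavelength_nm", "od"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    out = {}
    for sid, grp in df.groupby("sample_id", sort=False):
        grp = grp.sort_values("wavelength_nm")
        out[str(sid)] = AbsorbanceSpectrum(
            wavelengths=grp["wavelength_nm"].to_numpy(float),
            od=grp["od"].to_numpy(float),
            sample_id=str(sid),
        )
    return out


def write_spectra_long(spectra: Iterable[AbsorbanceSpectrum], path) -> None:
    frames = []
    for sp in spectra:
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": sp.sample_id,
                    "wavelength_nm": sp.wavelengths,
                    "od": sp.od,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def assessments_to_frame(assessments: Iterable[HemolysisAssessment]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": a.sample_id,
            "a414": a.a414,
            "label": a.label,
            "degree_relative": a.degree_relative,
            "severe": a.severe,
        }
        for a in assessments
    ]
    return pd.DataFrame(rows, columns=["sample_id", "a414", "label", "degree_relative", "severe"])


def write_assessments(assessments: Iterable[HemolysisAssessment], path) -> None:
    assessments_to_frame(assessments).to_csv(path, sep="\t", index=False)
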