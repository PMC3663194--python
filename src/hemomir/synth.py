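"""Synthetic RBC-contamination studies for end-to-end pipeline testing.

The generator plants a linear-abundance mixing model: lysing a volume
fraction ``f`` of red blood cells into clean plasma multiplies a miRNA's
linear abundance by ``1 + f * k``, where ``k`` is the species' RBC
enrichment factor (how much lysate contributes per unit volume fraction,
relative to the plasma baseline).  On the Cq scale this is

    Cq(f) = baseline_cq - log2(1 + f * k) + noise,

so noise-free paired fold changes are exactly ``1 + f * k`` — a closed
form every downstream statistic can be checked against.  Truth labels
(susceptible / stable / specific) are emitted for recovery tests.

Matching absorbance spectra come from a Soret-band model calibrated so
that A414 rises linearly with the spike: 0.143 OD at 0% RBC and 0.626 OD
at 0.125% RBC, with Q-band bumps at 541/576 nm at one tenth the Soret
amplitude.

Units: spectra and sample sheets speak %RBC by volume (the unit of the
dilution design); the mixing model takes a plain volume fraction.  The
single conversion constant is :data:`PERCENT_TO_FRACTION`.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .cq_data import (
    CqTable,
    SampleSheet,
    write_cq_table,
    write_sample_sheet,
)
from .errors import ConfigurationError, ValidationError
from .spectra import AbsorbanceSpectrum
from . import spectra as _spectra

#: %RBC by volume -> volume fraction. The only place the units meet.
PERCENT_TO_FRACTION = 0.01

#: Default %RBC spike levels of the six-point dilution design.
DILUTION_FRACTIONS_PERCENT = (0.0, 0.008, 0.016, 0.031, 0.0625, 0.125)

#: Default lysed-RBC volume fractions of the three hemolyzed pair members.
PAIR_FRACTIONS = (0.0005, 0.00125, 0.0025)

DEFAULT_LABEL_PROPORTIONS = {"susceptible": 0.5, "stable": 0.45, "specific": 0.05}

LABELS = ("susceptible", "stable", "specific")


# ---------------------------------------------------------------------------
# Model parameters


@dataclass(frozen=True)
class MixingModelParams:
    """Per-miRNA mixing-model parameters plus global noise/censoring.

    ``mirs`` is indexed by mir_id with columns baseline_cq (cycles in
    clean plasma), enrichment_k (unitless, >= 0) and truth_label.
    Specific species are absent from clean plasma: their baseline sits at
    or above the censoring limit and only the RBC contribution makes them
    amplify.  ``noise_sd`` is the SD in cycles of a single qPCR reaction;
    ``censor_cq`` is the last cycle the instrument runs; ``detect_cq`` is
    the strict detection limit used downstream.
    """

    mirs: pd.DataFrame
    noise_sd: float = 0.25
    censor_cq: float = 40.0
    detect_cq: float = 35.0

    def __post_init__(self) -> None:
        required = {"baseline_cq", "enrichment_k", "truth_label"}
        if not required <= set(self.mirs.columns):
            raise ConfigurationError(f"mirs frame needs columns {sorted(required)}")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        m = self.mirs
        if (m["enrichment_k"] < 0).any():
            raise ConfigurationError("enrichment_k must be >= 0")
        bad_label = sorted(set(m["truth_label"]) - set(LABELS))
        if bad_label:
            raise ConfigurationError(f"unknown truth labels: {bad_label}")
        specific = m["truth_label"] == "specific"
        if (m.loc[specific, "baseline_cq"] < self.censor_cq).any():
            raise ConfigurationError(
                "specific species must have baseline_cq >= censor_cq"
            )
        if (m.loc[specific, "enrichment_k"] <= 0).any():
            raise ConfigurationError("specific species need enrichment_k > 0")
        if ((m.loc[~specific, "baseline_cq"] <= 15)
                | (m.loc[~specific, "baseline_cq"] >= 40)).any():
            raise ConfigurationError(
                "plasma-detectable baseline Cqs must lie in (15, 40)"
            )

    @property
    def mir_ids(self) -> list[str]:
        return list(self.mirs.index)

    def truth_frame(self) -> pd.DataFrame:
        out = self.mirs[["truth_label", "enrichment_k", "baseline_cq"]].copy()
        out.index.name = "mir_id"
        return out


@dataclass(frozen=True)
class SpectrumModelParams:
    """Parameters of the synthetic hemoglobin absorbance model.

    The Soret Gaussian at 414 nm is scaled so the full spectrum evaluated
    at 414 nm reproduces ``baseline_a414 + slope_per_percent * %RBC``
    exactly; Q-band Gaussians at 541/576 nm carry one tenth of the Soret
    amplitude and only clear the prominence threshold at heavy
    contamination.
    """

    baseline_a414: float = 0.143
    slope_per_percent: float = 3.864  # OD per %RBC: (0.626 - 0.143) / 0.125
    flat_baseline: float = 0.10
    soret_center: float = 414.0
    soret_width: float = 15.0
    q_band_centers: tuple[float, float] = (541.0, 576.0)
    q_band_width: float = 4.0
    q_band_relative_amplitude: float = 0.1
    wavelength_start: float = 350.0
    wavelength_stop: float = 650.0
    wavelength_step: float = 1.0

    def a414(self, rbc_percent: float) -> float:
        """Closed-form A414 as a function of the %RBC spike."""
        return self.baseline_a414 + self.slope_per_percent * rbc_percent


def _gauss(x: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / width) ** 2)


def simulate_spectrum(
    params: SpectrumModelParams,
    rbc_percent: float,
    rng: Optional[np.random.Generator] = None,
    noise_sd: float = 0.0,
    sample_id: str = "",
) -> AbsorbanceSpectrum:
    """Synthesize a 350-650 nm scan for a given %RBC contamination."""
    if rbc_percent < 0:
        raise ValidationError("rbc_percent must be >= 0")
    wl = np.arange(
        params.wavelength_start,
        params.wavelength_stop + params.wavelength_step / 2,
        params.wavelength_step,
    )
    target = params.a414(rbc_percent)
    g_soret = _gauss(wl, params.soret_center, params.soret_width)
    g_q = sum(_gauss(wl, c, params.q_band_width) for c in params.q_band_centers)
    # amplitude solved exactly so od(414) == target including Q-band tails
    at414 = lambda g: float(np.interp(414.0, wl, g))
    amp = (target - params.flat_baseline) / (
        at414(g_soret) + params.q_band_relative_amplitude * at414(g_q)
    )
    od = params.flat_baseline + amp * (g_soret + params.q_band_relative_amplitude * g_q)
    if noise_sd > 0:
        if rng is None:
            raise ConfigurationError("measurement noise requires an rng")
        od = od + rng.normal(0.0, noise_sd, size=od.size)
    return AbsorbanceSpectrum(wavelengths=wl, od=od, sample_id=sample_id)


# ---------------------------------------------------------------------------
# Cq simulation


def expected_cq(params: MixingModelParams, mir_id: str, f: float) -> float:
    """Noise-free Cq under the mixing model (may exceed the censor limit)."""
    row = params.mirs.loc[mir_id]
    return float(row["baseline_cq"] - np.log2(1.0 + f * row["enrichment_k"]))


def simulate_cq(
    params: MixingModelParams,
    mir_id: str,
    f: float,
    rng: Optional[np.random.Generator] = None,
    n_reactions: int = 1,
) -> float:
    """One deposited Cq value at lysed-RBC volume fraction ``f``.

    Each of ``n_reactions`` qPCR reactions draws independent Gaussian
    noise on the Cq scale and is censored individually at ``censor_cq``
    (a reaction that never crosses threshold is undetected).  The
    deposited value is the mean of the detected reactions, mirroring how
    duplicate reactions are reported; NaN when none amplified.
    """
    if f < 0:
        raise ValidationError(f"RBC volume fraction must be >= 0, got {f!r}")
    if n_reactions < 1:
        raise ConfigurationError("n_reactions must be >= 1")
    raw = expected_cq(params, mir_id, f)
    if params.noise_sd > 0:
        if rng is None:
            raise ConfigurationError("noisy simulation requires an rng")
        values = raw + rng.normal(0.0, params.noise_sd, size=n_reactions)
    else:
        values = np.full(n_reactions, raw)
    detected = values[values <= params.censor_cq]
    if detected.size == 0:
        return float("nan")
    return float(np.clip(detected.mean(), 1e-6, params.censor_cq))


def sample_mixing_params(
    n_mirs: int,
    rng: np.random.Generator,
    label_proportions: Optional[Mapping[str, float]] = None,
    susceptible_k: tuple[float, float] = (800.0, 20000.0),
    stable_k: tuple[float, float] = (0.0, 80.0),
    specific_k: tuple[float, float] = (1e6, 1e7),
    baseline_range: tuple[float, float] = (24.0, 34.0),
    noise_sd: float = 0.25,
    censor_cq: float = 40.0,
    detect_cq: float = 35.0,
) -> MixingModelParams:
    """Draw per-miRNA parameters for a synthetic panel.

    Susceptible species get log-uniform enrichment factors in [800,
    20000] (1-4.7 cycle shifts at a 0.125% spike, bracketing the 1.5-2.4
    cycle decreases observed for validated susceptible miRNAs); stable
    species get uniform [0, 80] (under 0.15 cycles at that spike).
    Specific species sit above the censor limit in clean plasma with
    enrichment large enough to amplify clearly once lysate is present.
    """
    if n_mirs < 1:
        raise ConfigurationError("n_mirs must be >= 1")
    props = dict(label_proportions or DEFAULT_LABEL_PROPORTIONS)
    unknown = sorted(set(props) - set(LABELS))
    if unknown:
        raise ConfigurationError(f"unknown labels in proportions: {unknown}")
    total = sum(props.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(f"label proportions must sum to 1, got {total}")
    counts = {lab: int(round(props.get(lab, 0.0) * n_mirs)) for lab in LABELS}
    # largest-remainder fixup so counts sum to n_mirs
    drift = n_mirs - sum(counts.values())
    order = sorted(LABELS, key=lambda l: -props.get(l, 0.0))
    i = 0
    while drift != 0:
        lab = order[i % len(order)]
        if drift > 0:
            counts[lab] += 1
            drift -= 1
        elif counts[lab] > 0:
            counts[lab] -= 1
            drift += 1
        i += 1

    labels = [lab for lab in LABELS for _ in range(counts[lab])]
    rng.shuffle(labels)
    rows = []
    for idx, lab in enumerate(labels):
        mir = f"miR-synth-{idx + 1:04d}"
        if lab == "susceptible":
            k = float(np.exp(rng.uniform(np.log(susceptible_k[0]), np.log(susceptible_k[1]))))
            baseline = float(rng.uniform(*baseline_range))
        elif lab == "stable":
            k = float(rng.uniform(*stable_k))
            baseline = float(rng.uniform(*baseline_range))
        else:  # specific
            k = float(np.exp(rng.uniform(np.log(specific_k[0]), np.log(specific_k[1]))))
            baseline = float(censor_cq + rng.uniform(0.0, 2.0))
        rows.append({"mir_id": mir, "baseline_cq": baseline,
                     "enrichment_k": k, "truth_label": lab})
    mirs = pd.DataFrame(rows).set_index("mir_id")
    return MixingModelParams(
        mirs=mirs, noise_sd=noise_sd, censor_cq=censor_cq, detect_cq=detect_cq
    )


# ---------------------------------------------------------------------------
# Study generators


@dataclass(frozen=True)
class SyntheticStudy:
    """Everything a pipeline run needs, plus ground truth."""

    cq_table: CqTable
    sample_sheet: SampleSheet
    spectra: dict[str, AbsorbanceSpectrum]
    truth: pd.DataFrame
    mixing_params: MixingModelParams
    spectrum_params: SpectrumModelParams

    def write(self, outdir) -> dict[str, Path]:
        """Write the four study artifacts as TSV files."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "cq_table": outdir / "cq_table.tsv",
            "sample_sheet": outdir / "sample_sheet.tsv",
            "spectra": outdir / "spectra.tsv",
            "truth": outdir / "truth_labels.tsv",
        }
        write_cq_table(self.cq_table, paths["cq_table"])
        write_sample_sheet(self.sample_sheet, paths["sample_sheet"])
        _spectra.write_spectra_long(self.spectra.values(), paths["spectra"])
        self.truth.to_csv(paths["truth"], sep="\t")
        return paths


def _simulate_table(
    params: MixingModelParams,
    sample_fractions: Sequence[tuple[str, str, float]],
    rng: np.random.Generator,
    n_reactions: int,
) -> CqTable:
    """sample_fractions: (sample_id, replicate_label, volume fraction)."""
    cols = pd.MultiIndex.from_tuples(
        [(s, r) for s, r, _ in sample_fractions],
        names=["sample_id", "replicate"],
    )
    data = np.empty((len(params.mir_ids), len(sample_fractions)))
    for j, (_, _, f) in enumerate(sample_fractions):
        for i, mir in enumerate(params.mir_ids):
            data[i, j] = simulate_cq(params, mir, f, rng, n_reactions=n_reactions)
    frame = pd.DataFrame(data, index=params.mir_ids, columns=cols)
    return CqTable(frame)


def generate_paired_study(
    seed: int,
    n_mirs: int = 200,
    n_pairs: int = 3,
    hemolysis_fractions: Sequence[float] = PAIR_FRACTIONS,
    label_proportions: Optional[Mapping[str, float]] = None,
    noise_sd: float = 0.25,
    n_runs: int = 2,
    n_reactions: int = 2,
    params: Optional[MixingModelParams] = None,
    spectrum_params: Optional[SpectrumModelParams] = None,
) -> SyntheticStudy:
    """Simulate matched non-hemolyzed/hemolyzed plasma pairs + one RBC sample.

    Each pair's non-hemolyzed member is drawn at f = 0 and its hemolyzed
    member at the pair's lysed-RBC volume fraction; a pure-lysate RBC
    sample is drawn at f = 1.  ``n_runs`` independent isolations appear
    as replicate columns, each deposited value averaging ``n_reactions``
    simulated duplicate reactions.  Sample-sheet A414 values follow the
    closed-form spectrum model (no RBC-sample spectrum: pure lysate is
    not assessed spectrophotometrically).
    """
    if n_pairs < 1:
        raise ConfigurationError("n_pairs must be >= 1")
    fractions = list(hemolysis_fractions)
    if len(fractions) != n_pairs:
        raise ConfigurationError(
            f"need one hemolysis fraction per pair ({n_pairs}), got {len(fractions)}"
        )
    if any(f < 0 for f in fractions):
        raise ValidationError("hemolysis fractions must be >= 0")
    rng = np.random.default_rng(seed)
    if params is None:
        params = sample_mixing_params(
            n_mirs, rng, label_proportions=label_proportions, noise_sd=noise_sd
        )
    sp = spectrum_params or SpectrumModelParams()

    sample_fractions: list[tuple[str, str, float]] = []
    sheet_rows = []
    spectra: dict[str, AbsorbanceSpectrum] = {}
    for i, f in enumerate(fractions, start=1):
        pid = f"P{i}"
        for cond, suffix, fv in (
            ("non_hemolyzed", "NH", 0.0),
            ("hemolyzed", "H", float(f)),
        ):
            sid = f"{pid}_{suffix}"
            pct = fv / PERCENT_TO_FRACTION
            for r in range(1, n_runs + 1):
                sample_fractions.append((sid, f"run{r}", fv))
            spectra[sid] = simulate_spectrum(sp, pct, sample_id=sid)
            sheet_rows.append(
                {
                    "sample_id": sid,
                    "subject_id": f"S{i}",
                    "condition": cond,
                    "pair_id": pid,
                    "a414": sp.a414(pct),
                    "rbc_fraction": np.nan,
                }
            )
    for r in range(1, n_runs + 1):
        sample_fractions.append(("RBC", f"run{r}", 1.0))
    sheet_rows.append(
        {
            "sample_id": "RBC",
            "subject_id": "donor",
            "condition": "rbc",
            "pair_id": "",
            "a414": np.nan,
            "rbc_fraction": np.nan,
        }
    )

    table = _simulate_table(params, sample_fractions, rng, n_reactions)
    sheet = SampleSheet(pd.DataFrame(sheet_rows))
    return SyntheticStudy(
        cq_table=table,
        sample_sheet=sheet,
        spectra=spectra,
        truth=params.truth_frame(),
        mixing_params=params,
        spectrum_params=sp,
    )


def generate_dilution_series(
    seed: int,
    fractions_percent: Sequence[float] = DILUTION_FRACTIONS_PERCENT,
    n_series: int = 2,
    n_mirs: int = 24,
    label_proportions: Optional[Mapping[str, float]] = None,
    noise_sd: float = 0.25,
    n_replicates: int = 2,
    params: Optional[MixingModelParams] = None,
    spectrum_params: Optional[SpectrumModelParams] = None,
) -> SyntheticStudy:
    """Simulate independent RBC dilution series (default: the six-point
    0-0.125 %RBC design, prepared twice).

    Each series contributes one sample per spike level with
    ``n_replicates`` duplicate qPCR reactions as replicate columns.
    """
    fractions = list(fractions_percent)
    if len(set(fractions)) != len(fractions) or any(f < 0 for f in fractions):
        raise ConfigurationError("fractions must be unique and non-negative")
    if 0.0 not in fractions:
        raise ConfigurationError("dilution design must include the 0% baseline")
    if n_series < 1:
        raise ConfigurationError("n_series must be >= 1")
    rng = np.random.default_rng(seed)
    if params is None:
        params = sample_mixing_params(
            n_mirs, rng, label_proportions=label_proportions, noise_sd=noise_sd
        )
    sp = spectrum_params or SpectrumModelParams()

    sample_fractions: list[tuple[str, str, float]] = []
    sheet_rows = []
    spectra: dict[str, AbsorbanceSpectrum] = {}
    for s in range(1, n_series + 1):
        for pct in sorted(fractions):
            sid = f"D{s}_{pct:g}pct"
            fv = pct * PERCENT_TO_FRACTION
            for r in range(1, n_replicates + 1):
                sample_fractions.append((sid, f"rep{r}", fv))
            spectra[sid] = simulate_spectrum(sp, pct, sample_id=sid)
            sheet_rows.append(
                {
                    "sample_id": sid,
                    "subject_id": f"donor{s}",
                    "condition": "dilution",
                    "pair_id": "",
                    "a414": sp.a414(pct),
                    "rbc_fraction": pct,
                }
            )
    table = _simulate_table(params, sample_fractions, rng, n_reactions=1)
    sheet = SampleSheet(pd.DataFrame(sheet_rows))
    return SyntheticStudy(
        cq_table=table,
        sample_sheet=sheet,
        spectra=spectra,
        truth=params.truth_frame(),
        mixing_params=params,
        spectrum_params=sp,
    )


# ---------------------------------------------------------------------------
# Scenario configuration


@dataclass
class ScenarioConfig:
    """Flat, round-trippable description of a synthetic study."""

    kind: str = "paired"  # "paired" | "dilution"
    seed: int = 0
    n_mirs: int = 200
    n_pairs: int = 3
    hemolysis_fractions: tuple[float, ...] = PAIR_FRACTIONS
    fractions_percent: tuple[float, ...] = DILUTION_FRACTIONS_PERCENT
    n_series: int = 2
    proportion_susceptible: float = 0.5
    proportion_stable: float = 0.45
    proportion_specific: float = 0.05
    noise_sd: float = 0.25
    n_runs: int = 2
    n_reactions: int = 2

    def label_proportions(self) -> dict[str, float]:
        return {
            "susceptible": self.proportion_susceptible,
            "stable": self.proportion_stable,
            "specific": self.proportion_specific,
        }

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["hemolysis_fractions"] = list(self.hemolysis_fractions)
        d["fractions_percent"] = list(self.fractions_percent)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        d = yaml.safe_load(Path(path).read_text())
        if not isinstance(d, dict):
            raise ConfigurationError(f"{path}: expected a flat key-value mapping")
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ConfigurationError(f"unknown scenario keys: {unknown}")
        for key in ("hemolysis_fractions", "fractions_percent"):
            if key in d:
                d[key] = tuple(float(v) for v in d[key])
        return cls(**d)


def run_scenario(config: ScenarioConfig) -> SyntheticStudy:
    """Generate the study a :class:`ScenarioConfig` describes."""
    if config.kind == "paired":
        return generate_paired_study(
            seed=config.seed,
            n_mirs=config.n_mirs,
            n_pairs=config.n_pairs,
            hemolysis_fractions=config.hemolysis_fractions[: config.n_pairs],
            label_proportions=config.label_proportions(),
            noise_sd=config.noise_sd,
            n_runs=config.n_runs,
            n_reactions=config.n_reactions,
        )
    if config.kind == "dilution":
        return generate_dilution_series(
            seed=config.seed,
            fractions_percent=config.fractions_percent,
            n_series=config.n_series,
            n_mirs=config.n_mirs,
            label_proportions=config.label_proportions(),
            noise_sd=config.noise_sd,
            n_replicates=config.n_reactions,
        )
    raise ConfigurationError(f"unknown scenario kind {config.kind!r}")
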