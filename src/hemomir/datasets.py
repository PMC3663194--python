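"""Bundled reference measurements from a matched-pair hemolysis study.

Small published summary tables from a spectrophotometric + RT-qPCR study
of hemolysis in human plasma, included so examples and validation tests
run without external data:

* free-hemoglobin A414 readings (mean over replicate scans) for six
  matched non-hemolyzed/hemolyzed plasma pairs and a six-point RBC
  dilution series, with the study's own printed degree-of-hemolysis
  ratios;
* mean Cq trajectories of four hemolysis-stable miRNAs over the dilution
  series;
* mean +/- SD paired fold changes of biomarker/endogenous-control
  candidate miRNAs in the two most heavily hemolyzed pairs.

All values are printed summary statistics (replicate-level raw data were
not published); functions return fresh copies.
"""

from __future__ import annotations

import pandas as pd

#: Degrees of hemolysis of the two extensively hemolyzed pairs used for
#: subset selection (A414 ratio hemolyzed / non-hemolyzed).
SUBSET_PAIR_DEGREES = {"N1": 2.36, "MPM1": 4.53}


def paired_a414() -> pd.DataFrame:
    """A414 means for six matched plasma pairs.

    Columns: pair_id, a414_nonhemolyzed, a414_hemolyzed, degree (the
    study's printed hemolyzed/non-hemolyzed ratio, averaged over
    replicate scans before rounding).
    """
    rows = [
        ("N1", 0.174, 0.413, 2.36),
        ("N2", 0.153, 0.412, 2.68),
        ("MPM1", 0.124, 0.558, 4.53),
        ("CAD1", 0.184, 0.250, 1.37),
        ("CAD2", 0.127, 0.242, 1.90),
        ("CAD3", 0.143, 0.574, 4.01),
    ]
    return pd.DataFrame(
        rows, columns=["pair_id", "a414_nonhemolyzed", "a414_hemolyzed", "degree"]
    )


def dilution_a414() -> pd.DataFrame:
    """A414 means over the RBC dilution series (0 to 0.125 %RBC).

    Columns: rbc_percent, a414, degree (ratio to the 0% baseline; NaN
    for the baseline itself).
    """
    rows = [
        (0.0, 0.143, float("nan")),
        (0.008, 0.184, 1.29),
        (0.016, 0.245, 1.73),
        (0.031, 0.321, 2.28),
        (0.0625, 0.420, 2.96),
        (0.125, 0.626, 4.39),
    ]
    return pd.DataFrame(rows, columns=["rbc_percent", "a414", "degree"])


def stable_mir_dilution_cq() -> pd.DataFrame:
    """Mean Cq of four hemolysis-stable miRNAs over the dilution series.

    Indexed by rbc_percent; one column per assay.  These four species
    vary by less than 1.1 cycles across the whole spike range.
    """
    data = {
        "miR-1274B": [24.73, 25.00, 24.94, 24.70, 24.65, 24.82],
        "miR-142-3p": [24.33, 24.55, 24.34, 23.86, 23.65, 23.55],
        "miR-146a": [25.82, 26.02, 26.01, 25.84, 25.80, 26.00],
        "miR-122": [28.28, 28.59, 28.78, 28.18, 28.29, 28.63],
    }
    frame = pd.DataFrame(
        data, index=[0.0, 0.008, 0.016, 0.031, 0.0625, 0.125]
    )
    frame.index.name = "rbc_percent"
    return frame


def subset_candidate_fold_changes() -> pd.DataFrame:
    """Paired fold changes (hemolyzed vs non-hemolyzed) of subset candidates.

    Mean +/- SD over two independent isolations for the two extensively
    hemolyzed pairs N1 (degree 2.36) and MPM1 (degree 4.53).  ``group``
    records the study's own subset call: "changing" species rose at
    least twofold in both pairs following the degree of hemolysis;
    "unaffected" species stayed within +/-1.5-fold.
    """
    changing = [
        ("let-7b", 2.12, 0.43, 14.06, 9.83),
        ("miR-126#", 2.70, 1.03, 2.87, 1.00),
        ("miR-140-3p", 2.60, 0.70, 10.96, 3.69),
        ("miR-15a#", 2.92, 1.96, 2.00, 1.10),
        ("miR-15b#", 5.40, 4.17, 4.96, 2.04),
        ("miR-16", 3.55, 0.87, 10.18, 0.38),
        ("miR-193b", 5.26, 3.39, 6.16, 6.00),
        ("miR-194", 18.14, 14.34, 2.86, 2.21),
        ("miR-20a", 2.10, 0.83, 3.83, 0.37),
        ("miR-20b", 2.46, 1.80, 19.24, 3.30),
        ("miR-21", 2.57, 0.47, 2.90, 0.22),
        ("miR-210", 2.50, 1.01, 26.93, 7.48),
        ("miR-26b", 2.56, 0.48, 3.58, 1.29),
        ("miR-320", 2.25, 0.13, 3.32, 0.01),
        ("miR-320B", 2.28, 0.96, 3.66, 3.50),
        ("miR-324-3p", 3.30, 1.51, 9.12, 6.61),
        ("miR-331-5p", 3.54, 3.40, 22.65, 19.81),
        ("miR-340", 2.63, 1.43, 3.71, 1.20),
        ("miR-425-5p", 2.44, 0.90, 4.75, 3.74),
        ("miR-454", 4.62, 1.19, 6.15, 3.64),
        ("miR-484", 2.11, 0.12, 3.13, 0.09),
        ("miR-486-3p", 2.51, 1.32, 14.20, 5.57),
        ("miR-532-3p", 2.50, 2.05, 3.75, 2.71),
        ("miR-652", 3.08, 2.52, 3.45, 0.43),
        ("miR-140", 2.17, 0.18, 3.20, 0.56),
        ("miR-451", 2.38, 0.84, 15.27, 1.78),
    ]
    unaffected = [
        ("let-7a", 1.33, 1.30, 1.25, 0.71),
        ("let-7d", 1.49, 0.77, 0.97, 0.78),
        ("miR-1260", 1.37, 1.14, 1.23, 0.52),
        ("miR-127", 1.29, 0.68, 0.66, 0.86),
        ("miR-1274A", 1.14, 0.27, 1.20, 0.59),
        ("miR-1274B", 1.49, 0.39, 0.87, 0.06),
        ("miR-130b", 1.00, 0.38, 1.10, 0.33),
        ("miR-142-5p", 1.50, 1.04, 1.30, 0.43),
        ("miR-143", 0.89, 0.47, 1.09, 0.32),
        ("miR-146a", 1.29, 0.14, 1.49, 0.87),
        ("miR-221", 1.35, 0.58, 1.50, 0.93),
        ("miR-222", 1.26, 0.45, 1.38, 0.06),
        ("miR-27b", 1.49, 1.40, 1.27, 0.21),
        ("miR-324-5p", 1.20, 0.04, 1.08, 0.90),
        ("miR-338-5P", 0.76, 0.06, 1.41, 0.77),
        ("miR-339-5p", 1.29, 0.94, 1.04, 0.16),
        ("miR-340#", 0.94, 0.38, 0.80, 0.53),
        ("miR-425#", 1.10, 0.83, 0.96, 0.02),
        ("miR-744", 0.71, 0.21, 1.01, 0.31),
    ]
    rows = [(m, "changing", *vals) for m, *vals in changing]
    rows += [(m, "unaffected", *vals) for m, *vals in unaffected]
    return pd.DataFrame(
        rows,
        columns=["mir_id", "group", "fc_N1", "sd_N1", "fc_MPM1", "sd_MPM1"],
    )
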