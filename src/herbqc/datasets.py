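"""Bundled reference dataset from a published Turkish gall quality study.

Turkish gall (the dried gall of *Quercus infectoria*) is quantified for
four marker analytes — gallic acid (GA), 1,2,3,6-tetra-O-galloyl-beta-D-
glucose (TEGG), ellagic acid (EA) and 1,2,3,4,6-penta-O-galloyl-beta-D-
glucose (PEGG).  The loaders below expose the published compound table,
calibration parameters, spike-recovery design, durability series, batch
contents, and PCA summary used throughout the test-suite and the example
workflows.  All values are plain printed numbers; nothing is fetched.
"""

from __future__ import annotations

import pandas as pd

from .qams import CalibrationCurve, SamplePrep

__all__ = [
    "ANALYTES",
    "REFERENCE_ANALYTE",
    "load_sample_prep",
    "load_calibration_curves",
    "load_compound_table",
    "load_recovery_rows",
    "load_durability_rcf",
    "load_durability_rrt",
    "load_batch_contents",
    "load_pca_contributions",
    "load_pca_component_scores",
    "load_batch_groups",
]

ANALYTES = ["GA", "TEGG", "EA", "PEGG"]
REFERENCE_ANALYTE = "GA"

#: Published regression lines: (slope, intercept, range_low, range_high, r2).
_CALIBRATION = {
    "GA": (8.6962, 10.2544, 11.40625, 365.0, 0.9999),
    "TEGG": (6.84, -61.1284, 31.8125, 1018.0, 0.9995),
    "EA": (43.0207, -89.5458, 3.84375, 123.0, 0.9988),
    "PEGG": (5.6759, -50.9605, 13.625, 436.0, 0.9991),
}


def load_sample_prep() -> SamplePrep:
    """0.5 g powder brought to 100 ml, injected without further dilution."""
    return SamplePrep(mass=0.5, volume=100.0, dilution=1.0)


def load_calibration_curves() -> dict[str, CalibrationCurve]:
    return {
        name: CalibrationCurve(name, slope, intercept, r2, low, high)
        for name, (slope, intercept, low, high, r2) in _CALIBRATION.items()
    }


# Published compound table: peak number, retention time (min), observed m/z,
# adduct, molecular formula, printed mass error (mDa), name, class.
_COMPOUNDS = [
    (1, 0.34, 167.0322, "[M-H]-", "C8H8O4", -2.8, "3-Methoxy-4-hydroxybenzoic acid", "Organic acids"),
    (2, 0.78, 154.0612, "[M-H]-", "C6H9N3O2", -1.0, "Histidine", "Amino acids"),
    (3, 0.83, 132.0287, "[M-H]-", "C4H7NO4", -1.6, "Aspartic acid", "Amino acids"),
    (4, 0.87, 597.1071, "[M+HCOO]-", "C31H20O10", 3.2, "Isosalicylic acid biflavone", "Flavonoids"),
    (5, 0.92, 285.0224, "[M+HCOO]-", "C6H12N2O4S2", 0.4, "Cystine", "Amino acids"),
    (6, 0.95, 133.0131, "[M-H]-", "C4H6O5", -1.1, "2-Hydroxy-succinic acid", "Organic acids"),
    (7, 1.10, 331.0663, "[M-H]-", "C13H16O10", -0.8, "1-O-Galloyl glucose 1", "Tannins"),
    (8, 1.15, 175.0234, "[M-H]-", "C6H8O6", -1.4, "Ascorbic acid", "Steroids"),
    (9, 1.30, 169.0131, "[M-H]-", "C7H6O5", -2.6, "GA", "Phenolic acids and their esters"),
    (10, 1.61, 243.0498, "[M+HCOO]-", "C9H10O5", -1.3, "Syringic acid", "Phenolic acids and their esters"),
    (11, 1.72, 783.0677, "[M-H]-", "C34H24O22", -1.0, "Pedunculagin", "Tannins"),
    (12, 2.10, 483.0776, "[M-H]-", "C20H20O14", -0.5, "Di-O-galloyl glucose 1", "Tannins"),
    (13, 2.18, 633.0723, "[M-H]-", "C27H22O18", -1.2, "Galloyl hexahydroxybiphenyl glucose 1", "Tannins"),
    (14, 2.93, 321.0248, "[M-H]-", "C14H10O9", -0.5, "M-diGA or p-diGA", "Phenolic acids and their esters"),
    (15, 3.46, 483.0772, "[M-H]-", "C20H20O14", -0.8, "Di-O-galloyl glucose 2", "Tannins"),
    (16, 3.72, 321.0247, "[M-H]-", "C14H10O9", -0.5, "M-diGA or p-diGA", "Phenolic acids and their esters"),
    (17, 4.04, 183.0283, "[M-H]-", "C8H8O5", -1.6, "Methyl gallate", "Phenolic acids and their esters"),
    (18, 4.47, 633.0721, "[M-H]-", "C27H22O18", -1.2, "Galloyl hexahydroxybiphenyl glucose 2", "Tannins"),
    (19, 7.39, 483.0768, "[M-H]-", "C20H20O14", -1.2, "Di-O-galloyl glucose 3", "Tannins"),
    (20, 7.40, 635.0888, "[M-H]-", "C27H24O18", -0.1, "Tri-O-galloyl glucose 1", "Tannins"),
    (21, 9.99, 635.0892, "[M-H]-", "C27H24O18", 0.2, "Tri-O-galloyl glucose 2", "Tannins"),
    (22, 10.56, 635.0886, "[M-H]-", "C27H24O18", -0.4, "Tri-O-galloyl glucose 3", "Tannins"),
    (23, 11.80, 635.0886, "[M-H]-", "C27H24O18", -0.4, "Tri-O-galloyl glucose 4", "Tannins"),
    (25, 12.74, 635.0889, "[M-H]-", "C27H24O18", -0.1, "Tri-O-galloyl glucose 5", "Tannins"),
    (26, 13.19, 635.0882, "[M-H]-", "C27H24O18", -0.8, "Tri-O-galloyl glucose 6", "Tannins"),
    (27, 14.45, 331.0660, "[M-H]-", "C13H16O10", -1.1, "1-O-galloyl glucose 2", "Tannins"),
    (28, 14.50, 300.9987, "[M-H]-", "C14H6O8", -0.3, "EA", "Phenolic acids and their esters"),
    (29, 15.52, 787.0997, "[M-H]-", "C34H28O22", -0.3, "Tetra-O-galloyl glucose 1", "Tannins"),
    (30, 16.07, 463.0870, "[M-H]-", "C21H20O12", -1.2, "Isoquercitrin", "Flavonoids"),
    (31, 16.13, 483.0773, "[M-H]-", "C20H20O14", -1.0, "Di-O-galloyl glucose 4", "Tannins"),
    (32, 17.90, 939.1112, "[M-H]-", "C41H32O26", 0.3, "Penta-O-galloyl glucose 1", "Tannins"),
    (33, 18.27, 939.1105, "[M-H]-", "C41H32O26", -0.4, "Penta-O-galloyl glucose 2", "Tannins"),
    (34, 18.83, 939.1107, "[M-H]-", "C41H32O26", -0.2, "Penta-O-galloyl glucose 3", "Tannins"),
    (35, 18.84, 787.0998, "[M-H]-", "C34H28O22", -0.1, "Tetra-O-galloyl glucose 2", "Tannins"),
    (36, 27.48, 277.1434, "[M-H]-", "C16H22O4", -1.1, "Dibutyl phthalate", "Esters"),
]
# Peak 24 is omitted: its printed observed m/z (182.02006) is inconsistent
# with its formula (C14H10O9) and neighbouring duplicate rows.


def load_compound_table() -> pd.DataFrame:
    """Published compound annotations with their printed mass errors."""
    return pd.DataFrame(
        _COMPOUNDS,
        columns=[
            "peak_no",
            "rt_min",
            "observed_mz",
            "adduct",
            "formula",
            "reported_error_mda",
            "name",
            "class",
        ],
    )


# Spike-recovery rows: (sample mg, spiked mg, found mg) per analyte.
_RECOVERY = {
    "GA": [
        (4.2044, 1.9671, 6.1437), (4.2044, 1.9671, 6.1403), (4.2044, 1.9671, 6.1826),
        (4.2044, 2.4588, 6.6634), (4.2044, 2.4588, 6.6476), (4.2044, 2.4588, 6.6874),
        (4.2044, 2.9506, 7.2951), (4.2044, 2.9506, 7.3175), (4.2044, 2.9506, 7.3192),
    ],
    "TEGG": [
        (6.0999, 2.4447, 8.4336), (6.0999, 2.4447, 8.6334), (6.0999, 2.4447, 8.5268),
        (6.0999, 3.0559, 9.1762), (6.0999, 3.0559, 9.1190), (6.0999, 3.0559, 9.2265),
        (6.0999, 3.6671, 9.8868), (6.0999, 3.6671, 9.8274), (6.0999, 3.6671, 9.8325),
    ],
    "EA": [
        (0.5095, 0.3435, 0.8486), (0.5095, 0.3435, 0.8550), (0.5095, 0.3435, 0.8601),
        (0.5095, 0.4294, 0.9370), (0.5095, 0.4294, 0.9338), (0.5095, 0.4294, 0.9338),
        (0.5095, 0.5153, 0.9974), (0.5095, 0.5153, 0.9936), (0.5095, 0.5153, 0.9985),
    ],
    "PEGG": [
        (3.6109, 1.6894, 5.2590), (3.6109, 1.6894, 5.3795), (3.6109, 1.6894, 5.2563),
        (3.6109, 2.1118, 5.7668), (3.6109, 2.1118, 5.7444), (3.6109, 2.1118, 5.7147),
        (3.6109, 2.5341, 6.1903), (3.6109, 2.5341, 6.0287), (3.6109, 2.5341, 6.1097),
    ],
}


def load_recovery_rows(analyte: str | None = None):
    """Published spike-recovery triples (sample, spiked, found, in mg)."""
    if analyte is not None:
        return list(_RECOVERY[analyte])
    return {k: list(v) for k, v in _RECOVERY.items()}


# Durability series: relative correction factors (vs GA) under varied
# conditions.  Keys are condition sets; values map analyte to the series.
_DURABILITY_RCF = {
    "instruments": {"TEGG": [1.6102, 1.5406, 1.6157], "EA": [0.2650, 0.2614, 0.2692], "PEGG": [1.8912, 1.7386, 1.7370]},
    "columns": {"TEGG": [1.6102, 1.6042, 1.6993], "EA": [0.2650, 0.2630, 0.2844], "PEGG": [1.8912, 1.900, 1.9975]},
    "flow_rates": {"TEGG": [1.5568, 1.6102, 1.6086], "EA": [0.2503, 0.2650, 0.2641], "PEGG": [1.9329, 1.8912, 1.8895]},
    "temperatures": {"TEGG": [1.6391, 1.6125, 1.6102], "EA": [0.2685, 0.2654, 0.2650], "PEGG": [1.9068, 1.9007, 1.8912]},
    "wavelengths": {"TEGG": [1.6687, 1.6102, 1.5478], "EA": [0.2456, 0.2650, 0.2644], "PEGG": [1.9710, 1.8912, 1.8162]},
}

_DURABILITY_RRT = {
    "instruments": {"TEGG": [4.665, 4.410, 4.463], "EA": [4.865, 4.587, 4.730], "PEGG": [6.909, 6.685, 6.610]},
    "columns": {"TEGG": [4.665, 4.488, 4.736], "EA": [4.865, 4.799, 4.917], "PEGG": [6.909, 7.050, 7.284]},
}


def load_durability_rcf() -> dict[str, dict[str, list[float]]]:
    return {k: {a: list(v) for a, v in d.items()} for k, d in _DURABILITY_RCF.items()}


def load_durability_rrt() -> dict[str, dict[str, list[float]]]:
    return {k: {a: list(v) for a, v in d.items()} for k, d in _DURABILITY_RRT.items()}


# Published batch contents (w/w %): GA by the external-standard method only;
# TEGG/EA/PEGG by both methods plus the printed relative error.
_CONTENTS = [
    # batch, GA_esm, TEGG_esm, TEGG_qams, TEGG_re, EA_esm, EA_qams, EA_re, PEGG_esm, PEGG_qams, PEGG_re
    ("S1", 2.96, 5.79, 5.70, 1.52, 0.60, 0.60, 0.00, 2.82, 2.86, -1.40),
    ("S2", 3.88, 4.43, 4.36, 1.53, 0.69, 0.68, 1.47, 2.67, 2.71, -1.48),
    ("S3", 3.65, 6.78, 6.67, 1.65, 0.55, 0.55, 0.00, 3.36, 3.40, -1.18),
    ("S4", 8.58, 4.51, 4.44, 1.60, 0.98, 0.98, 0.00, 2.95, 2.99, -1.34),
    ("S5", 4.10, 4.43, 4.36, 1.49, 0.63, 0.63, 0.00, 3.05, 3.09, -1.29),
    ("S6", 3.51, 7.19, 7.07, 1.66, 0.45, 0.45, 0.00, 2.95, 2.99, -1.34),
    ("S7", 3.66, 5.56, 5.47, 1.63, 0.55, 0.55, 0.00, 3.21, 3.26, -1.53),
    ("S8", 3.20, 4.24, 4.17, 1.62, 0.64, 0.64, 0.00, 2.85, 2.89, -1.38),
    ("S9", 3.81, 4.83, 4.76, 1.54, 0.60, 0.60, 0.00, 2.67, 2.71, -1.48),
    ("S10", 4.18, 6.20, 6.10, 1.57, 0.52, 0.52, 0.00, 2.60, 2.64, -1.52),
    ("S11", 3.35, 5.43, 5.34, 1.67, 0.43, 0.43, 0.00, 2.93, 2.97, -1.35),
    ("S12", 4.97, 3.02, 2.97, 1.52, 0.89, 0.89, 0.00, 1.98, 2.01, -1.49),
    ("S13", 5.00, 4.66, 4.59, 1.62, 0.58, 0.58, 0.00, 2.43, 2.46, -1.22),
    ("S14", 4.15, 4.20, 4.14, 1.49, 0.35, 0.35, 0.00, 1.35, 1.37, -1.46),
]


def load_batch_contents() -> pd.DataFrame:
    """Published per-batch contents (w/w %) by both quantitation methods."""
    return pd.DataFrame(
        _CONTENTS,
        columns=[
            "batch_id",
            "GA_esm",
            "TEGG_esm", "TEGG_qams", "TEGG_re",
            "EA_esm", "EA_qams", "EA_re",
            "PEGG_esm", "PEGG_qams", "PEGG_re",
        ],
    )


def load_pca_contributions() -> list[float]:
    """Variance contribution rates (%) of the two retained components."""
    return [52.847, 32.571]


_COMPONENT_SCORES = {
    "S1": (-0.98, 0.17), "S2": (0.45, -0.15), "S3": (-1.59, 1.31),
    "S4": (3.26, 2.01), "S5": (0.21, 0.36), "S6": (-1.84, 0.45),
    "S7": (-0.90, 0.73), "S8": (0.05, -0.20), "S9": (-0.06, -0.25),
    "S10": (-0.80, 0.04), "S11": (-1.07, -0.04), "S12": (2.62, -0.90),
    "S13": (0.58, -0.50), "S14": (0.07, -3.02),
}


def load_pca_component_scores() -> pd.DataFrame:
    """Published per-batch scores on the two retained components."""
    return pd.DataFrame(
        [(k, *v) for k, v in _COMPONENT_SCORES.items()],
        columns=["batch_id", "PC1", "PC2"],
    ).set_index("batch_id")


def load_batch_groups() -> dict[str, list[str]]:
    """Cluster-analysis grouping of the batches (three batches ungrouped)."""
    return {
        "group1": ["S2", "S5", "S8", "S9", "S13"],
        "group2": ["S1", "S3", "S6", "S7", "S10", "S11"],
        "ungrouped": ["S4", "S12", "S14"],
    }
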