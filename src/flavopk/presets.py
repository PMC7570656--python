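"""Published method constants for the flavonoid LC-MS/MS assay.

These are the printed configuration tables and summary statistics of the
developed method: ESI source factor ranges for the screening and
optimization designs, the fitted quadratic response-surface model for the
source settings, MRM transition metadata, and the reported validation /
pharmacokinetic summary tables. They serve as reference inputs for the
worked examples and the reproduction scripts; none of them is used as a
hidden default inside the estimation code itself.
"""

from __future__ import annotations

from .doe import FactorDef

# --- ESI source factors -------------------------------------------------

#: Seven-factor screening ranges (Plackett-Burman), low/center/high.
PBD_FACTORS = [
    FactorDef("Gas temperature", "degC", 250.0, 300.0, 350.0),
    FactorDef("Gas flow", "mL/min", 4.0, 7.0, 10.0),
    FactorDef("Nebulizer", "psi", 30.0, 45.0, 60.0),
    FactorDef("Sheath gas temperature", "degC", 200.0, 250.0, 300.0),
    FactorDef("Sheath gas flow", "mL/min", 6.0, 9.0, 12.0),
    FactorDef("Capillary Voltage", "V", 3000.0, 3500.0, 4000.0),
    FactorDef("Nozzle Voltage", "V", 300.0, 500.0, 700.0),
]

#: Three-factor optimization ranges (Box-Behnken).  Row order fixes the
#: x1/x2/x3 assignment of the published quadratic model below.
BBD_FACTORS = [
    FactorDef("Nebulizer", "psi", 40.0, 50.0, 60.0),
    FactorDef("SGT", "degC", 300.0, 350.0, 400.0),
    FactorDef("Nozzle Voltage", "V", 700.0, 1100.0, 1500.0),
]

#: Coefficients of the published second-order model for the summed
#: flavonoid response over the BBD region (coded units):
#: Y = b0 + b1 x1 + b2 x2 + b3 x3 + b11 x1^2 + b22 x2^2 + b33 x3^2
#:       + b12 x1 x2 + b13 x1 x3 + b23 x2 x3
BBD_MODEL_COEFFICIENTS = {
    "b0": 2398.0,
    "linear": (-328.12, 121.5, 325.37),
    "quadratic": (35.87, -23.38, -74.63),
    "interaction": (-45.0, -52.75, 10.5),  # (x1x2, x1x3, x2x3)
}

# --- MRM acquisition metadata (stored verbatim; not used in computation) --

MRM_TRANSITIONS = [
    {
        "segment_min": (2.76, 4.0),
        "compound": "Hesperidin",
        "transition": "609.2 -> 301.1",
        "fragmentor_v": 80,
        "collision_energy_v": 30,
        "cell_accelerator_v": 5,
    },
    {
        "segment_min": (4.01, 5.65),
        "compound": "Quercetin (IS)",
        "transition": "301.1 -> 151.1",
        "fragmentor_v": 120,
        "collision_energy_v": 25,
        "cell_accelerator_v": 5,
    },
    {
        "segment_min": (5.66, 6.30),
        "compound": "Naringenin",
        "transition": "271.1 -> 151.1",
        "fragmentor_v": 120,
        "collision_energy_v": 20,
        "cell_accelerator_v": 5,
    },
]

#: On-column injection volume (uL) used for mass-based detection limits.
INJECTION_VOLUME_UL = 2.0

# --- Reported validation tables -----------------------------------------

#: Reported detection/quantification limits in concentration units (ng/mL).
REPORTED_LIMITS_NG_PER_ML = {
    "hesperidin": {"lod": 0.3, "loq": 1.1},
    "quercetin": {"lod": 0.1, "loq": 0.4},
    "naringenin": {"lod": 0.2, "loq": 0.5},
}

#: Reported QC table (nominal, measured mean, RSD%, accuracy%), intra-day
#: n=9 and inter-day n=27, per analyte.
REPORTED_QC_TABLE = {
    "hesperidin": [
        {"nominal": 2.50, "intra_mean": 2.24, "intra_rsd": 4.67, "intra_acc": 89.37,
         "inter_mean": 2.31, "inter_rsd": 9.44, "inter_acc": 92.44},
        {"nominal": 7.50, "intra_mean": 6.98, "intra_rsd": 3.95, "intra_acc": 93.02,
         "inter_mean": 6.92, "inter_rsd": 7.12, "inter_acc": 92.23},
        {"nominal": 12.50, "intra_mean": 11.63, "intra_rsd": 2.71, "intra_acc": 93.04,
         "inter_mean": 11.64, "inter_rsd": 4.86, "inter_acc": 93.12},
    ],
    "quercetin": [
        {"nominal": 2.50, "intra_mean": 2.17, "intra_rsd": 6.2, "intra_acc": 86.58,
         "inter_mean": 2.28, "inter_rsd": 5.78, "inter_acc": 91.09},
        {"nominal": 7.50, "intra_mean": 7.19, "intra_rsd": 5.93, "intra_acc": 95.84,
         "inter_mean": 6.95, "inter_rsd": 5.74, "inter_acc": 92.6},
        {"nominal": 12.50, "intra_mean": 11.99, "intra_rsd": 4.05, "intra_acc": 95.86,
         "inter_mean": 11.77, "inter_rsd": 5.56, "inter_acc": 94.16},
    ],
    "naringenin": [
        {"nominal": 2.50, "intra_mean": 2.22, "intra_rsd": 3.21, "intra_acc": 88.82,
         "inter_mean": 2.34, "inter_rsd": 8.33, "inter_acc": 93.65},
        {"nominal": 7.50, "intra_mean": 7.20, "intra_rsd": 3.19, "intra_acc": 96.03,
         "inter_mean": 7.17, "inter_rsd": 7.23, "inter_acc": 95.54},
        {"nominal": 12.50, "intra_mean": 12.05, "intra_rsd": 3.09, "intra_acc": 96.34,
         "inter_mean": 12.17, "inter_rsd": 4.82, "inter_acc": 97.32},
    ],
}

#: Reported recovery / matrix-effect peak-area means per QC level
#: (R1 pure standard, R2 post-extraction spike, R3 pre-extraction spike),
#: with the printed per-level recovery and matrix-effect percentages.
REPORTED_RECOVERY_TABLE = {
    "hesperidin": [
        {"level": 2.5, "r1": 266.0, "r2": 268.0, "r3": 250.0,
         "recovery_pct": 93, "matrix_effect_pct": 101},
        {"level": 25.0, "r1": 2472.0, "r2": 2596.0, "r3": 2315.0,
         "recovery_pct": 89, "matrix_effect_pct": 105},
        {"level": 250.0, "r1": 25957.0, "r2": 26476.0, "r3": 24800.0,
         "recovery_pct": 94, "matrix_effect_pct": 102},
    ],
    "quercetin": [
        {"level": 2.5, "r1": 330.0, "r2": 349.0, "r3": 309.0,
         "recovery_pct": 88, "matrix_effect_pct": 106},
        {"level": 25.0, "r1": 3065.0, "r2": 3249.0, "r3": 2929.0,
         "recovery_pct": 90, "matrix_effect_pct": 106},
        {"level": 250.0, "r1": 35704.0, "r2": 36418.0, "r3": 34747.0,
         "recovery_pct": 95, "matrix_effect_pct": 102},
    ],
    "naringenin": [
        {"level": 2.5, "r1": 1137.0, "r2": 1160.0, "r3": 1092.0,
         "recovery_pct": 94, "matrix_effect_pct": 102},
        {"level": 25.0, "r1": 10962.0, "r2": 11291.0, "r3": 10266.0,
         "recovery_pct": 91, "matrix_effect_pct": 103},
        {"level": 250.0, "r1": 128126.0, "r2": 133251.0, "r3": 122411.0,
         "recovery_pct": 92, "matrix_effect_pct": 104},
    ],
}

# --- Reported pharmacokinetic summary (mean, sd; n = 3 per arm) ----------

#: NCA parameter summaries per analyte and arm.  "single" is the analyte
#: dosed alone; "mixture" is the same analyte dosed in the two-flavonoid
#: mixture.  sd None means the table printed no dispersion for that cell.
REPORTED_PK_TABLE = {
    "hesperidin": {
        "single": {
            "t_half": (3.03, 0.71), "tmax": (4.67, 1.15), "cmax": (71.89, 9.60),
            "auc_0_24": (288.92, 35.14), "v_f": (0.34, 0.15), "cl_f": (0.08, 0.02),
            "mrt": (6.15, 0.79),
        },
        "mixture": {
            "t_half": (3.14, 0.72), "tmax": (4.63, 1.08), "cmax": (120.0, 72.46),
            "auc_0_24": (516.22, 271.70), "v_f": (0.20, 0.14), "cl_f": (0.04, 0.02),
            "mrt": (6.51, 1.08),
        },
    },
    "naringenin": {
        "single": {
            "t_half": (5.13, 2.00), "tmax": (1.67, 0.58), "cmax": (310.35, 103.27),
            "auc_0_24": (1006.11, 130.46), "v_f": (0.17, 0.07), "cl_f": (0.02, 0.00),
            "mrt": (4.45, 0.29),
        },
        "mixture": {
            "t_half": (4.09, 1.75), "tmax": (2.00, None), "cmax": (472.31, 92.19),
            "auc_0_24": (1538.14, 191.47), "v_f": (0.09, 0.02), "cl_f": (0.04, 0.01),
            "mrt": (4.38, 0.13),
        },
    },
}

#: Oral doses (mg per kg body weight) for the in-vivo study arms.
DOSES_MG_PER_KG = {"hesperidin": 69.0, "naringenin": 92.0, "mixture_total": 161.0}

#: Plasma sampling grid, hours (printed in minutes: 5, 15, 30, 60, 90, 120,
#: 180, 240, 300, 360, 420, 480, 540, 600, 720, 1080, 1440).
SAMPLING_GRID_H = tuple(
    m / 60.0
    for m in (5, 15, 30, 60, 90, 120, 180, 240, 300, 360, 420, 480, 540, 600,
              720, 1080, 1440)
)
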