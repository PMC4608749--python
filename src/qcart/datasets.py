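"""Reference values for the six-specimen goat osteochondrosis cohort.

A surgical goat model of osteochondrosis: focal ischemic necrosis was induced
in the epiphyseal cartilage of the medial femoral condyle at 4 days of age,
and specimens were harvested 3-10 weeks post-surgery. Large incisions
(5 x 5 mm) correspond to weeks 3, 5 and 9; small incisions (3 x 4 mm) to
weeks 4, 6 and 10. Ex vivo 9.4 T MRI mapped five relaxation parameters
(T1, T2, T1rho, adiabatic T1rho, T_RAFF) over articular cartilage, viable
epiphyseal cartilage and the necrotic lesion; safranin-O optical density
quantified proteoglycan content in matched histological sections.

This module holds the published per-ROI summary statistics (mean +/- SD) and
acquisition protocols. They serve two roles: ground truth for the synthetic
phantom generator, and printed-value inputs for the table/regression
reproduction analyses.
"""

from __future__ import annotations

from .protocols import AcquisitionProtocol

#: Weeks post-surgery at which specimens with large (5 x 5 mm) incisions were
#: harvested, and likewise for small (3 x 4 mm) incisions.
LARGE_LESION_WEEKS = (3, 5, 9)
SMALL_LESION_WEEKS = (4, 6, 10)
COHORT_WEEKS = (3, 4, 5, 6, 9, 10)

#: The five mapped relaxation parameters, in the published column order.
PARAMETERS = ("T1", "T2", "T1RHO", "AD_T1RHO", "RAFF")

ROIS = ("articular", "viable", "necrotic")

#: The week-6 specimen showed no histologically evident chondronecrosis; its
#: OD point is excluded from the time regressions by default.
WEEK_WITHOUT_NECROSIS = 6


def cohort_protocols() -> dict[str, AcquisitionProtocol]:
    """The five published magnetization-preparation protocols.

    T1: inversion recovery, TI = 70 ... 5120 ms; T2: double spin echo,
    TE = 4 ... 100 ms; T1rho: rectangular spin-lock, 0 ... 80 ms; adiabatic
    T1rho: train of 0-16 HS4 full-passage pulses of 6 ms; T_RAFF: train of
    0-32 RAFF pulses of 4.53 ms.  Pulse-power values (gamma*B1max) are carried
    as metadata only; they never enter the fitting.
    """
    return {
        "T1": AcquisitionProtocol(
            name="T1",
            model="INVERSION_RECOVERY",
            times_ms=[70.0, 80.0, 100.0, 160.0, 320.0, 640.0, 1280.0, 2560.0, 5120.0],
        ),
        "T2": AcquisitionProtocol(
            name="T2",
            model="MONOEXP",
            times_ms=[4.0, 20.0, 40.0, 60.0, 80.0, 100.0],
        ),
        "T1RHO": AcquisitionProtocol(
            name="T1RHO",
            model="MONOEXP",
            times_ms=[0.0, 10.0, 20.0, 40.0, 80.0],
            metadata={"gamma_b1_max_hz": 500.0, "pulse_family": "rect spin-lock"},
        ),
        "AD_T1RHO": AcquisitionProtocol(
            name="AD_T1RHO",
            model="MONOEXP",
            pulse_counts=[0, 4, 8, 12, 16],
            pulse_duration_ms=6.0,
            metadata={"gamma_b1_max_hz": 2500.0, "pulse_family": "AFP (HS4)"},
        ),
        "RAFF": AcquisitionProtocol(
            name="RAFF",
            model="MONOEXP",
            pulse_counts=[0, 8, 16, 24, 32],
            pulse_duration_ms=4.53,
            metadata={"gamma_b1_max_hz": 625.0, "pulse_family": "RAFF"},
        ),
    }


#: Published relaxation constants, week -> ROI -> parameter -> (mean, sd).
#: T1 in seconds; all other parameters in milliseconds.  The week-3 T2
#: measurement was invalid (technical problems) and is absent.
RELAXATION_STATS: dict[int, dict[str, dict[str, tuple[float, float]]]] = {
    3: {
        "articular": {"T1": (1.56, 0.14), "T1RHO": (133.7, 27.0), "AD_T1RHO": (275.8, 51.3), "RAFF": (248.7, 49.0)},
        "viable": {"T1": (1.23, 0.06), "T1RHO": (90.8, 7.4), "AD_T1RHO": (193.3, 14.5), "RAFF": (133.2, 12.3)},
        "necrotic": {"T1": (1.61, 0.08), "T1RHO": (137.9, 12.6), "AD_T1RHO": (288.8, 24.1), "RAFF": (244.0, 21.0)},
    },
    5: {
        "articular": {"T1": (1.51, 0.04), "T2": (92.5, 8.4), "T1RHO": (123.7, 12.4), "AD_T1RHO": (252.0, 29.1), "RAFF": (149.0, 9.9)},
        "viable": {"T1": (1.17, 0.03), "T2": (54.6, 4.4), "T1RHO": (88.0, 3.9), "AD_T1RHO": (180.2, 8.8), "RAFF": (102.4, 4.6)},
        "necrotic": {"T1": (1.91, 0.09), "T2": (106.6, 13.1), "T1RHO": (205.3, 18.1), "AD_T1RHO": (413.3, 42.1), "RAFF": (230.2, 22.4)},
    },
    9: {
        "articular": {"T1": (1.45, 0.07), "T2": (74.2, 7.4), "T1RHO": (99.2, 9.1), "AD_T1RHO": (188.9, 17.6), "RAFF": (143.0, 11.5)},
        "viable": {"T1": (1.31, 0.06), "T2": (59.6, 9.5), "T1RHO": (89.1, 7.4), "AD_T1RHO": (180.7, 14.7), "RAFF": (127.0, 11.3)},
        "necrotic": {"T1": (2.08, 0.08), "T2": (136.4, 17.9), "T1RHO": (207.3, 18.5), "AD_T1RHO": (414.3, 61.6), "RAFF": (286.4, 34.5)},
    },
    4: {
        "articular": {"T1": (1.62, 0.16), "T2": (68.4, 15.9), "T1RHO": (95.2, 24.2), "AD_T1RHO": (223.0, 48.3), "RAFF": (175.7, 35.9)},
        "viable": {"T1": (1.34, 0.06), "T2": (32.6, 8.7), "T1RHO": (57.2, 9.1), "AD_T1RHO": (157.9, 16.2), "RAFF": (100.8, 14.3)},
        "necrotic": {"T1": (1.38, 0.04), "T2": (44.0, 3.4), "T1RHO": (64.4, 3.5), "AD_T1RHO": (162.5, 10.4), "RAFF": (126.4, 5.1)},
    },
    6: {
        "articular": {"T1": (1.78, 0.24), "T2": (84.8, 16.9), "T1RHO": (100.1, 21.6), "AD_T1RHO": (283.2, 61.0), "RAFF": (144.1, 28.4)},
        "viable": {"T1": (1.29, 0.04), "T2": (22.8, 5.9), "T1RHO": (58.2, 4.3), "AD_T1RHO": (147.9, 9.9), "RAFF": (60.7, 9.6)},
        "necrotic": {"T1": (1.45, 0.05), "T2": (46.1, 4.8), "T1RHO": (79.7, 3.7), "AD_T1RHO": (181.7, 11.2), "RAFF": (100.1, 7.1)},
    },
    10: {
        "articular": {"T1": (1.58, 0.13), "T2": (61.9, 10.0), "T1RHO": (85.7, 13.9), "AD_T1RHO": (201.6, 37.0), "RAFF": (134.4, 19.4)},
        "viable": {"T1": (1.27, 0.04), "T2": (23.0, 5.9), "T1RHO": (53.5, 4.2), "AD_T1RHO": (134.7, 9.6), "RAFF": (69.0, 6.6)},
        "necrotic": {"T1": (1.56, 0.17), "T2": (38.9, 18.4), "T1RHO": (128.5, 19.5), "AD_T1RHO": (234.2, 35.4), "RAFF": (137.3, 11.2)},
    },
}

#: Published viable-vs-necrotic percent differences per week and parameter
#: (the relaxation-time "Difference" table as printed).
PRINTED_RELAXATION_DIFFERENCES: dict[int, dict[str, float]] = {
    3: {"T1": 26.9, "T1RHO": 41.2, "AD_T1RHO": 39.6, "RAFF": 58.7},
    5: {"T1": 47.9, "T2": 64.5, "T1RHO": 80.0, "AD_T1RHO": 78.6, "RAFF": 76.8},
    9: {"T1": 45.2, "T2": 78.4, "T1RHO": 79.8, "AD_T1RHO": 78.5, "RAFF": 77.1},
    4: {"T1": 3.3, "T2": 29.7, "T1RHO": 11.8, "AD_T1RHO": 2.8, "RAFF": 22.5},
    6: {"T1": 11.3, "T2": 67.8, "T1RHO": 31.2, "AD_T1RHO": 20.5, "RAFF": 49.1},
    10: {"T1": 20.9, "T2": 51.6, "T1RHO": 82.5, "AD_T1RHO": 54.0, "RAFF": 66.3},
}

#: Precision (decimal places) at which the relaxation means are printed, per
#: parameter.  T1 is printed in seconds to 2 decimals; the others in ms to 1.
PRINTED_DECIMALS: dict[str, int] = {"T1": 2, "T2": 1, "T1RHO": 1, "AD_T1RHO": 1, "RAFF": 1}

#: Published safranin-O optical density (absorbance, a.u., base-10) of the
#: epiphyseal cartilage: week -> {"viable": (mean, sd), "necrotic": (mean, sd),
#: "printed_difference": percent}.
OD_STATS: dict[int, dict] = {
    3: {"viable": (3.10, 0.63), "necrotic": (2.28, 0.39), "printed_difference": 30.5},
    4: {"viable": (2.71, 0.52), "necrotic": (1.95, 0.19), "printed_difference": 32.6},
    5: {"viable": (2.91, 0.60), "necrotic": (1.57, 0.42), "printed_difference": 59.8},
    6: {"viable": (2.52, 0.48), "necrotic": (1.96, 0.21), "printed_difference": 25.0},
    9: {"viable": (2.49, 0.35), "necrotic": (0.37, 0.09), "printed_difference": 148.2},
    10: {"viable": (2.98, 0.51), "necrotic": (0.26, 0.06), "printed_difference": 167.9},
}


def lesion_class(week: int) -> str:
    if week in LARGE_LESION_WEEKS:
        return "LARGE"
    if week in SMALL_LESION_WEEKS:
        return "SMALL"
    raise ValueError(f"week {week} is not part of the cohort")
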