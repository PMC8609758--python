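"""Published summary statistics of the reference ex-vivo accuracy experiment.

These constants describe the study the synthetic generator emulates: 117
guided access cavities drilled in three tooth groups — anterior teeth
(AT), premolars (P) and molars (M) mounted in six jaw models — with
per-group deviation summaries, canal-accessibility counts (size-10 K-file
test), the guide-sleeve geometry and the bur working length.  They are
calibration inputs and bookkeeping references, never quantities this
package claims to recompute from data.
"""

from __future__ import annotations

import numpy as np

from .core_geometry import SleeveSpec

#: Tooth groups in reporting order.
GROUPS = ("AT", "P", "M")

#: Guided access cavities per group (sums to 117).
GROUP_SIZES = {"AT": 36, "P": 33, "M": 48}

#: Cavities recorded as canal-inaccessible per group (sums to 23).
INACCESSIBLE_COUNTS = {"AT": 2, "P": 3, "M": 18}

#: Reported per-group deviation summaries: metric -> stat -> group -> value.
#: Linear deviations in mm, angular in degrees.
TABLE_SUMMARY = {
    "coronal_mm": {
        "mean": {"AT": 0.09, "P": 0.07, "M": 0.22, "Total": 0.13},
        "sd": {"AT": 0.16, "P": 0.15, "M": 0.25, "Total": 0.21},
        "min": {"AT": 0.0, "P": 0.0, "M": 0.0, "Total": 0.0},
        "max": {"AT": 0.54, "P": 0.49, "M": 0.97, "Total": 0.97},
    },
    "apical_mm": {
        "mean": {"AT": 0.28, "P": 0.40, "M": 0.64, "Total": 0.46},
        "sd": {"AT": 0.24, "P": 0.35, "M": 0.46, "Total": 0.40},
        "min": {"AT": 0.0, "P": 0.0, "M": 0.0, "Total": 0.0},
        "max": {"AT": 0.78, "P": 1.26, "M": 1.60, "Total": 1.60},
    },
    "angular_deg": {
        "mean": {"AT": 1.73, "P": 2.23, "M": 4.00, "Total": 2.80},
        "sd": {"AT": 1.97, "P": 1.97, "M": 2.86, "Total": 2.57},
        "min": {"AT": 0.0, "P": 0.0, "M": 0.0, "Total": 0.0},
        "max": {"AT": 5.90, "P": 6.50, "M": 11.60, "Total": 11.60},
    },
}

#: Reported discrimination of canal accessibility (area under the ROC curve).
REPORTED_AUC = {"angular_deg": 0.975, "apical_mm": 0.786, "coronal_mm": 0.562}

#: Guide-sleeve geometry of the study templates (mm).
STUDY_SLEEVE = SleeveSpec(inner_diameter_mm=1.09, bur_diameter_mm=1.0, height_mm=3.0)

#: Working length of the access bur (mm).
BUR_WORKING_LENGTH_MM = 16.0


def group_mean(metric: str, group: str) -> float:
    return TABLE_SUMMARY[metric]["mean"][group]


def calibrated_coronal_sd(group: str) -> float:
    """Per-axis sd of the 2-D base offset whose magnitude (Rayleigh) has the
    reported coronal mean: ``mean = sd * sqrt(pi/2)``."""
    return group_mean("coronal_mm", group) / np.sqrt(np.pi / 2.0)


def calibrated_tilt_scale(group: str) -> float:
    """Half-normal scale whose mean is the reported angular mean:
    ``mean = scale * sqrt(2/pi)`` (degrees)."""
    return group_mean("angular_deg", group) / np.sqrt(2.0 / np.pi)
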