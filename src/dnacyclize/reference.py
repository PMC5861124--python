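"""Reference profile-fit parameters for the canonical construct families.

Each table lists the best-fit parameters ``(phi, p, a, b, c)`` of the
periodic piecewise-quadratic profile form (see :mod:`dnacyclize.fitting`)
for one knob of the model swept at a time around the common reference
molecule: a planar 90-degree bend over 63 bp followed by a straight tail,
helical repeat 10.5, baseline stiffnesses with ``K3/K1 = 1.5`` and overall
scale ``beta = 1``.  Profiles were computed over N = 146..170 at full
accuracy (0.1 in log10 J), which is beyond a desk-scale run; the tables
therefore serve both as regression-test anchors for the fitting layer and
as the data behind the knob-response relations used for calibration.

``beta`` rows correspond to curvature-free persistence lengths of
40.3, 43.3, 46.3, 49.3 and 52.3 nm.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "bend_angle_fits",
    "stiffness_scale_fits",
    "helical_repeat_fits",
    "pitch_positive_fits",
    "pitch_negative_fits",
    "twist_stiffness_fits",
    "REFERENCE_FIT",
]

_COLS = ["knob", "phi", "p", "a", "b", "c"]


def _table(rows):
    return pd.DataFrame(rows, columns=_COLS)


#: Fit parameters of the reference molecule itself (the shared row).
REFERENCE_FIT = dict(phi=147.16, p=10.48, a=1.35, b=0.017, c=-0.112)

#: Planar bend angle (degrees) swept 15..120 over a 63-bp bend.
bend_angle_fits = _table(
    [
        (15, 147.24, 10.42, -0.74, 0.036, -0.113),
        (30, 147.12, 10.55, -0.30, 0.031, -0.112),
        (45, 147.33, 10.39, 0.18, 0.030, -0.121),
        (60, 147.20, 10.43, 0.63, 0.025, -0.113),
        (75, 147.22, 10.43, 1.02, 0.021, -0.117),
        (90, 147.16, 10.48, 1.35, 0.017, -0.112),
        (105, 147.16, 10.49, 1.64, 0.016, -0.111),
        (120, 147.19, 10.48, 1.92, 0.009, -0.112),
    ]
)

#: Overall stiffness scale beta applied to all six stiffnesses.
stiffness_scale_fits = _table(
    [
        (0.870, 147.17, 10.59, 1.89, 0.015, -0.093),
        (0.945, 147.23, 10.43, 1.65, 0.015, -0.104),
        (1.000, 147.16, 10.48, 1.35, 0.017, -0.112),
        (1.065, 147.08, 10.53, 1.04, 0.024, -0.121),
        (1.130, 147.16, 10.50, 0.75, 0.023, -0.121),
    ]
)

#: Helical repeat (bp per intrinsic twist turn).
helical_repeat_fits = _table(
    [
        (10.3, 144.40, 10.33, 1.15, 0.025, -0.112),
        (10.4, 145.68, 10.48, 1.32, 0.014, -0.112),
        (10.5, 147.16, 10.48, 1.35, 0.017, -0.112),
        (10.6, 148.60, 10.59, 1.28, 0.022, -0.102),
        (10.7, 150.07, 10.59, 1.35, 0.015, -0.102),
    ]
)

#: Pitch/circumference of a left-handed 90-degree helical bend (ratio >= 0).
pitch_positive_fits = _table(
    [
        (0.00, 147.16, 10.48, 1.35, 0.017, -0.112),
        (0.25, 147.79, 10.52, 1.30, 0.019, -0.110),
        (0.50, 148.33, 10.57, 1.24, 0.020, -0.108),
        (0.75, 149.02, 10.52, 1.18, 0.020, -0.107),
        (1.00, 149.65, 10.43, 1.07, 0.022, -0.112),
    ]
)

#: Pitch/circumference of a right-handed helical bend (ratio <= 0).
pitch_negative_fits = _table(
    [
        (0.00, 147.16, 10.48, 1.35, 0.017, -0.112),
        (-0.25, 146.53, 10.59, 1.30, 0.018, -0.109),
        (-0.50, 146.13, 10.40, 1.24, 0.021, -0.116),
        (-0.75, 145.33, 10.58, 1.19, 0.018, -0.114),
        (-1.00, 144.74, 10.62, 1.01, 0.021, -0.107),
    ]
)

#: Twist-to-bend stiffness ratio K3/K1, remaining stiffnesses fixed.
twist_stiffness_fits = _table(
    [
        (0.5, 147.45, 10.58, 1.03, 0.016, -0.036),
        (0.7, 147.37, 10.58, 1.17, 0.017, -0.053),
        (0.9, 147.37, 10.49, 1.21, 0.017, -0.069),
        (1.1, 147.11, 10.68, 1.28, 0.018, -0.081),
        (1.3, 147.30, 10.36, 1.30, 0.015, -0.101),
        (1.5, 147.16, 10.48, 1.35, 0.017, -0.112),
    ]
)
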