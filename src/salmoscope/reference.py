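"""Published treatment-level summaries for the six-population rearing study.

The study that this package's models and generators emulate published
treatment-level summary tables: growth rate (g/day) per population x
acclimation temperature, modeled critical thermal maximum (deg C), and the
aerobic-scope thermal optimum (deg C) with its acclimation shift.  Those
printed numbers serve as reference inputs for worked examples and for
checking the package's derived-cell arithmetic (acclimation capacity =
20 deg C cell minus 11 deg C cell; delta T_opt likewise); they are not
outputs of this package.

Printed derived cells are rounded from unrounded posteriors, so a few rows
are not self-consistent with their own printed treatment means; the
``*_SELF_CONSISTENT`` sets list the populations whose printed derived cell
equals the difference of its printed means at the printed precision.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "GROWTH_RATE_G_PER_DAY", "GROWTH_CAPACITY", "GROWTH_SELF_CONSISTENT",
    "CTMAX_MODELED_C", "CTMAX_CAPACITY", "CTMAX_SELF_CONSISTENT",
    "TOPT_C", "TOPT_SD_C", "DELTA_TOPT", "DELTA_TOPT_SELF_CONSISTENT",
    "AS_AT_TOPT", "reference_frame",
]

POPULATIONS = ("Coleman", "Elk River", "Feather River", "Priest Rapids",
               "Trask River", "Trinity River")

#: Treatment-level growth rate (g/day), keyed (population, acclim_temp_C).
GROWTH_RATE_G_PER_DAY = {
    ("Coleman", 11): 0.16, ("Coleman", 16): 0.23, ("Coleman", 20): 0.27,
    ("Elk River", 11): 0.17, ("Elk River", 16): 0.22, ("Elk River", 20): 0.21,
    ("Feather River", 11): 0.17, ("Feather River", 16): 0.17, ("Feather River", 20): 0.24,
    ("Priest Rapids", 11): 0.13, ("Priest Rapids", 16): 0.22, ("Priest Rapids", 20): 0.21,
    ("Trask River", 11): 0.16, ("Trask River", 16): 0.22, ("Trask River", 20): 0.18,
    ("Trinity River", 11): 0.06, ("Trinity River", 16): 0.07, ("Trinity River", 20): 0.12,
}

#: Printed growth acclimation capacity (delta g/day, 20C - 11C) per population.
GROWTH_CAPACITY = {
    "Coleman": 0.11, "Elk River": 0.04, "Feather River": 0.06,
    "Priest Rapids": 0.08, "Trask River": 0.02, "Trinity River": 0.06,
}
GROWTH_SELF_CONSISTENT = frozenset(
    {"Coleman", "Elk River", "Priest Rapids", "Trask River", "Trinity River"})

#: Modeled CT_max (deg C), keyed (population, acclim_temp_C).
CTMAX_MODELED_C = {
    ("Coleman", 11): 28.1, ("Coleman", 16): 29.3, ("Coleman", 20): 30.0,
    ("Elk River", 11): 27.9, ("Elk River", 16): 28.5, ("Elk River", 20): 29.5,
    ("Feather River", 11): 27.8, ("Feather River", 16): 29.0, ("Feather River", 20): 28.9,
    ("Priest Rapids", 11): 27.9, ("Priest Rapids", 16): 28.9, ("Priest Rapids", 20): 29.7,
    ("Trask River", 11): 28.0, ("Trask River", 16): 28.6, ("Trask River", 20): 30.1,
    ("Trinity River", 11): 28.4, ("Trinity River", 16): 28.9, ("Trinity River", 20): 29.2,
}

#: Printed CT_max acclimation capacity (deg C).
CTMAX_CAPACITY = {
    "Coleman": 1.9, "Elk River": 1.5, "Feather River": 1.1,
    "Priest Rapids": 1.8, "Trask River": 2.1, "Trinity River": 0.7,
}
CTMAX_SELF_CONSISTENT = frozenset(
    {"Coleman", "Feather River", "Priest Rapids", "Trask River"})

#: Thermal optimum of aerobic scope (deg C) and its posterior SD.
TOPT_C = {
    ("Coleman", 11): 18.75, ("Coleman", 16): 20.38, ("Coleman", 20): 22.19,
    ("Elk River", 11): 17.45, ("Elk River", 16): 18.33, ("Elk River", 20): 20.14,
    ("Feather River", 11): 20.48, ("Feather River", 16): 25.95, ("Feather River", 20): 19.57,
    ("Priest Rapids", 11): 20.07, ("Priest Rapids", 16): 20.51, ("Priest Rapids", 20): 22.71,
    ("Trask River", 11): 17.87, ("Trask River", 16): 17.59, ("Trask River", 20): 21.80,
    ("Trinity River", 11): 18.78, ("Trinity River", 16): 18.82, ("Trinity River", 20): 23.59,
}
TOPT_SD_C = {
    ("Coleman", 11): 0.64, ("Coleman", 16): 0.48, ("Coleman", 20): 0.89,
    ("Elk River", 11): 0.41, ("Elk River", 16): 0.28, ("Elk River", 20): 0.57,
    ("Feather River", 11): 0.69, ("Feather River", 16): 2.22, ("Feather River", 20): 0.48,
    ("Priest Rapids", 11): 0.58, ("Priest Rapids", 16): 0.54, ("Priest Rapids", 20): 1.11,
    ("Trask River", 11): 0.61, ("Trask River", 16): 0.33, ("Trask River", 20): 1.18,
    ("Trinity River", 11): 0.93, ("Trinity River", 16): 0.46, ("Trinity River", 20): 2.50,
}

#: Printed T_opt acclimation shift (20C - 11C, deg C).
DELTA_TOPT = {
    "Coleman": 3.44, "Elk River": 2.69, "Feather River": -0.91,
    "Priest Rapids": 2.63, "Trask River": 3.93, "Trinity River": 4.81,
}
DELTA_TOPT_SELF_CONSISTENT = frozenset(
    {"Coleman", "Elk River", "Feather River", "Trask River", "Trinity River"})

#: Aerobic scope at the thermal optimum (reported per hour in the source
#: table; numerically consistent with the per-minute rate equation — a
#: units discrepancy documented in docs/methods.md).
AS_AT_TOPT = {
    ("Coleman", 11): 8.92, ("Coleman", 16): 8.98, ("Coleman", 20): 8.76,
    ("Elk River", 11): 7.96, ("Elk River", 16): 8.89, ("Elk River", 20): 7.69,
    ("Feather River", 11): 10.96, ("Feather River", 16): 11.99, ("Feather River", 20): 7.97,
    ("Priest Rapids", 11): 10.47, ("Priest Rapids", 16): 9.47, ("Priest Rapids", 20): 8.70,
    ("Trask River", 11): 7.09, ("Trask River", 16): 6.99, ("Trask River", 20): 8.11,
    ("Trinity River", 11): 8.96, ("Trinity River", 16): 7.79, ("Trinity River", 20): 7.13,
}


def reference_frame() -> pd.DataFrame:
    """All reference summaries as one tidy frame (one row per treatment)."""
    rows = []
    for (pop, acc), g in GROWTH_RATE_G_PER_DAY.items():
        rows.append({"population": pop, "acclim_temp_C": acc,
                     "growth_rate_g_day": g,
                     "ctmax_C": CTMAX_MODELED_C[(pop, acc)],
                     "topt_C": TOPT_C[(pop, acc)],
                     "topt_sd_C": TOPT_SD_C[(pop, acc)],
                     "as_at_topt": AS_AT_TOPT[(pop, acc)]})
    return pd.DataFrame(rows).sort_values(["population", "acclim_temp_C"],
                                          ignore_index=True)
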