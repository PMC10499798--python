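"""Published global cassava marginal-land figures used as arithmetic cross-checks.

These are the printed continental area tables from the published global
cassava marginal-land assessment this pipeline re-implements: current
per-continent marginal-land areas (Mha), the printed current global total,
and per-continent areas and totals under three emission pathways (RCP4.5,
RCP6.0, RCP8.5) at three horizons. They are inputs for verifying the
reporting arithmetic (percentage shares, scenario net changes) — the model
outputs themselves are not desk-reproducible because they depend on
proprietary-scale input rasters.
"""

from __future__ import annotations

#: Current marginal land suitable for cassava by continent (Mha).
CURRENT_CONTINENT_MHA = {
    "Africa": 700.70,
    "South America": 464.60,
    "Asia": 90.07,
    "Oceania": 64.28,
    "North America": 36.68,
    "Europe": 0.92,
}

#: Printed current global total (Mha); the continent column sums to 1357.25
#: due to rounding of the printed cells.
CURRENT_TOTAL_MHA = 1357.24

#: Printed percent shares of the current global total.
CURRENT_CONTINENT_PCT = {
    "Africa": 51.63,
    "South America": 34.23,
    "Asia": 6.64,
    "Oceania": 4.74,
    "North America": 2.70,
    "Europe": 0.07,
}

#: Per-scenario continental areas (Mha) and printed totals.
SCENARIO_CONTINENT_MHA = {
    ("rcp45", "2030"): {"Africa": 722.74, "Asia": 91.07, "North America": 33.30,
                        "Oceania": 85.46, "South America": 463.59,
                        "Europe": 0.80},
    ("rcp45", "2050"): {"Africa": 726.60, "Asia": 94.81, "North America": 33.50,
                        "Oceania": 83.95, "South America": 456.59,
                        "Europe": 0.78},
    ("rcp45", "2080"): {"Africa": 747.76, "Asia": 97.56, "North America": 32.51,
                        "Oceania": 70.50, "South America": 448.09,
                        "Europe": 1.64},
    ("rcp60", "2030"): {"Africa": 749.32, "Asia": 92.02, "North America": 30.55,
                        "Oceania": 92.26, "South America": 458.46,
                        "Europe": 0.86},
    ("rcp60", "2050"): {"Africa": 750.27, "Asia": 104.27, "North America": 46.63,
                        "Oceania": 90.55, "South America": 448.37,
                        "Europe": 0.18},
    ("rcp60", "2080"): {"Africa": 776.31, "Asia": 101.52, "North America": 30.39,
                        "Oceania": 85.43, "South America": 461.95,
                        "Europe": 1.38},
    ("rcp85", "2030"): {"Africa": 730.02, "Asia": 90.34, "North America": 29.80,
                        "Oceania": 85.78, "South America": 460.02,
                        "Europe": 0.60},
    ("rcp85", "2050"): {"Africa": 743.84, "Asia": 101.07, "North America": 31.09,
                        "Oceania": 76.75, "South America": 458.39,
                        "Europe": 1.55},
    ("rcp85", "2080"): {"Africa": 742.84, "Asia": 108.58, "North America": 27.80,
                        "Oceania": 62.08, "South America": 433.00,
                        "Europe": 4.83},
}

#: Printed global totals per scenario (Mha).
SCENARIO_TOTAL_MHA = {
    ("rcp45", "2030"): 1396.95, ("rcp45", "2050"): 1396.22,
    ("rcp45", "2080"): 1398.06,
    ("rcp60", "2030"): 1423.45, ("rcp60", "2050"): 1440.26,
    ("rcp60", "2080"): 1456.98,
    ("rcp85", "2030"): 1396.55, ("rcp85", "2050"): 1412.67,
    ("rcp85", "2080"): 1379.11,
}

#: Published net changes vs the current total (Mha), as stated alongside the
#: scenario tables (e.g. +39.71 by 2030 under RCP4.5).
PUBLISHED_NET_CHANGE_MHA = {
    ("rcp45", "2030"): 39.71, ("rcp60", "2030"): 66.21, ("rcp85", "2030"): 39.31,
    ("rcp45", "2050"): 38.98, ("rcp60", "2050"): 83.02, ("rcp85", "2050"): 55.43,
    ("rcp45", "2080"): 40.82, ("rcp60", "2080"): 99.74, ("rcp85", "2080"): 21.87,
}

#: Ensemble cross-validated AUC reported for the published model.
PUBLISHED_CV_AUC = (0.998, 0.001)

#: Published mean relative contribution (%) of the dominant variable
#: (temperature annual range) with its 95% CI.
PUBLISHED_DOMINANT_RC = (76.06, 74.56, 77.55)
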