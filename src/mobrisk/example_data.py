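"""Bundled summary statistics from a two-site adolescent clinical cohort.

Printed site-comparison counts and group summaries (New York, n=84 vs
Pittsburgh, n=102; N=186) used by the examples and the descriptive-test
suite as known inputs with known published statistics.  Each contingency
table is rows = characteristic levels, columns = (NY, Pittsburgh).
"""

SITE_N = {"NY": 84, "PITT": 102}

# biological sex: rows male / female
SEX_BY_SITE = [[13, 25], [71, 77]]

# race, six categories by site
RACE_BY_SITE = [
    [1, 0],    # American Indian or Alaska Native
    [14, 5],   # Asian
    [16, 7],   # Black or African American
    [27, 79],  # White
    [12, 9],   # more than one race
    [14, 2],   # unknown / not reported
]

# Hispanic ethnicity: rows yes / no
HISPANIC_BY_SITE = [[26, 6], [58, 96]]

# current major depressive disorder: rows yes / no
MDD_BY_SITE = [[44, 68], [40, 34]]

# current substance use disorder: rows yes / no
SUD_BY_SITE = [[15, 5], [69, 97]]

# past-month suicidal ideation days: (n, mean, sd) per site
PAST_MONTH_IDEATION = {"NY": (84, 5.65, 10.48), "PITT": (102, 2.89, 5.92)}

# within-person homestay coefficient from the published weekly event model,
# on the log-odds scale per 1 SD above one's own mean (beta, SE)
HOMESTAY_EVENT_BETA = (0.69, 0.281)
IDEATION_HOMESTAY_BETA = (-0.02, 0.148)
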