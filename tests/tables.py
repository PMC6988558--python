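"""Published per-site trap-outcome margins used as test inputs.

Counts of trap nights by study site and outcome (TRAP = no capture) for
the North San Francisco Bay survey; row sums give the per-site trapping
effort and the outcome sums give the nine-species capture composition.
"""

SITE_OUTCOME_COUNTS = {
    "Benicia-Martinez Marsh": {"MUMU": 22, "TRAP": 623},
    "Corte Madera": {"MUMU": 1, "RE": 3, "REME": 1, "TRAP": 145},
    "Fagan": {"MICA": 16, "MUMU": 10, "RERA": 22, "SOOR": 1, "TRAP": 251},
    "Guadalcanal": {"MICA": 2, "MUMU": 156, "RERA": 19, "TRAP": 693},
    "Tolay Creek": {"MICA": 1437, "MUMU": 211, "PEMA": 181, "RANO": 4,
                    "REME": 33, "RERA": 546, "SOOR": 63, "TRAP": 5085},
    "Tubbs Island Setback": {"MICA": 110, "MUMU": 155, "PEMA": 252, "RANO": 10,
                             "RARA": 1, "RERA": 82, "SOOR": 1, "TRAP": 2269},
}

#: Published model-evaluation table for the binary-response suite:
#: model id -> (nodes, links, probabilities, overall, type1, type2, payoff).
BINARY_SUITE_METRICS = {
    1: (6, 9, 1400, 0.19, 0.22, 0.19, 0.849),
    2: (3, 3, 62, 0.20, 0.00, 0.20, 0.833),
    3: (5, 7, 272, 0.20, 1.00, 0.20, 0.828),
    4: (13, 22, 902, 0.44, 0.79, 0.20, 0.688),
    5: (5, 7, 170, 0.20, 0.00, 0.20, 0.832),
    6: (2, 1, 12, 0.20, 0.00, 0.20, 0.826),
    7: (3, 3, 62, 0.20, 0.00, 0.20, 0.832),
    8: (9, 15, 370, 0.21, 0.56, 0.17, 0.829),
    9: (7, 11, 262, 0.21, 0.56, 0.17, 0.827),
    10: (7, 11, 280, 0.21, 0.56, 0.18, 0.827),
    11: (13, 23, 682, 0.22, 0.57, 0.17, 0.825),
    12: (11, 19, 572, 0.21, 0.56, 0.17, 0.819),
    13: (11, 19, 612, 0.21, 0.56, 0.18, 0.819),
    14: (15, 27, 792, 0.22, 0.57, 0.17, 0.813),
    15: (18, 33, 4620, 0.19, 0.34, 0.19, 0.840),
    16: (16, 29, 4260, 0.19, 0.33, 0.19, 0.840),
    17: (16, 29, 4100, 0.19, 0.34, 0.19, 0.841),
    18: (20, 37, 5140, 0.19, 0.35, 0.19, 0.839),
    19: (23, 43, 1642, 0.47, 0.76, 0.15, 0.634),
}


def build_margin_casefile():
    """A case file whose site-by-outcome margins equal the published table."""
    from marshbn import CaseFile, TrapCase, default_catalog

    cases = []
    for site, counts in SITE_OUTCOME_COUNTS.items():
        for outcome, n in counts.items():
            cases.extend(
                TrapCase(site, 2000, "s", "grid", 38.0, -122.0, outcome, {})
                for _ in range(n)
            )
    return CaseFile(cases=cases, catalog=default_catalog())
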