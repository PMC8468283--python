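"""Published reference values for the Australian cancer reproduction.

Frozen from the national cost-of-illness tables the bundled fixture
encodes: annual savings per category and scenario (AUD million, colorectal
cancer at 2 decimals, total cancers at 1), and discounted savings per
5-year block, 20-year scenario totals and staged incremental totals.
``None`` marks cells published below the display floor ("<0.01" / "<0.1").
"""

SCENARIOS = ("very pessimistic", "pessimistic", "optimistic", "universal")

CRC = "colorectal cancer"
TC = "total cancers"

# category -> per-scenario (central, lower, upper)
ANNUAL_CRC = {
    "Allied health and other services": [
        (None, None, None), (None, None, None),
        (0.01, 0.01, 0.01), (0.02, 0.01, 0.02),
    ],
    "General practitioner services": [
        (0.04, 0.02, 0.05), (0.11, 0.07, 0.15),
        (0.38, 0.25, 0.50), (0.77, 0.50, 0.99),
    ],
    "Medical imaging": [
        (0.01, 0.01, 0.01), (0.02, 0.02, 0.03),
        (0.08, 0.05, 0.11), (0.17, 0.11, 0.22),
    ],
    "Pathology": [
        (0.01, 0.01, 0.01), (0.03, 0.02, 0.04),
        (0.10, 0.06, 0.13), (0.19, 0.13, 0.25),
    ],
    "Pharmaceutical benefits scheme": [
        (0.33, 0.21, 0.43), (0.99, 0.64, 1.28),
        (3.30, 2.14, 4.28), (6.61, 4.28, 8.55),
    ],
    "Private hospital services": [
        (0.57, 0.37, 0.73), (1.70, 1.10, 2.20),
        (5.67, 3.67, 7.33), (11.33, 7.33, 14.66),
    ],
    "Public hospital admitted patient": [
        (0.49, 0.32, 0.63), (1.47, 0.95, 1.90),
        (4.89, 3.17, 6.33), (9.79, 6.33, 12.66),
    ],
    "Public hospital emergency department": [
        (None, None, None), (None, None, 0.01),
        (0.02, 0.01, 0.02), (0.03, 0.02, 0.04),
    ],
    "Public hospital outpatient": [
        (0.30, 0.19, 0.39), (0.89, 0.58, 1.16),
        (2.98, 1.93, 3.86), (5.96, 3.86, 7.71),
    ],
    "Specialist services": [
        (0.12, 0.07, 0.15), (0.35, 0.22, 0.45),
        (1.16, 0.75, 1.50), (2.32, 1.50, 3.00),
    ],
}
ANNUAL_CRC_TOTAL = [
    (1.86, 1.20, 2.41), (5.58, 3.61, 7.22),
    (18.59, 12.03, 24.05), (37.17, 24.05, 48.11),
]

ANNUAL_TC = {
    "Allied health and other services": [
        (None, None, None), (None, None, 0.1),
        (0.1, 0.1, 0.2), (0.3, 0.2, 0.3),
    ],
    "General practitioner services": [
        (0.8, 0.5, 1.0), (2.3, 1.4, 3.1),
        (7.8, 4.7, 10.4), (15.5, 9.3, 20.7),
    ],
    "Medical imaging": [
        (0.2, 0.1, 0.3), (0.7, 0.4, 1.0),
        (2.4, 1.4, 3.2), (4.8, 2.9, 6.4),
    ],
    "Pathology": [
        (0.4, 0.2, 0.5), (1.1, 0.6, 1.4),
        (3.5, 2.1, 4.7), (7.0, 4.2, 9.4),
    ],
    "Pharmaceutical benefits scheme": [
        (3.3, 2.0, 4.4), (9.9, 5.9, 13.2),
        (32.9, 19.7, 43.9), (65.8, 39.5, 87.8),
    ],
    "Private hospital services": [
        (5.9, 3.6, 7.9), (17.8, 10.7, 23.7),
        (59.4, 35.6, 79.2), (118.7, 71.2, 158.3),
    ],
    "Public hospital admitted patient": [
        (5.4, 3.2, 7.2), (16.2, 9.7, 21.6),
        (53.9, 32.3, 71.8), (107.8, 64.7, 143.7),
    ],
    "Public hospital emergency department": [
        (0.1, None, 0.1), (0.2, 0.1, 0.3),
        (0.7, 0.4, 1.0), (1.5, 0.9, 2.0),
    ],
    "Public hospital outpatient": [
        (2.4, 1.5, 3.2), (7.3, 4.4, 9.7),
        (24.3, 14.6, 32.4), (48.6, 29.2, 64.8),
    ],
    "Specialist services": [
        (1.8, 1.1, 2.3), (5.3, 3.2, 7.0),
        (17.5, 10.5, 23.4), (35.1, 21.0, 46.8),
    ],
}
ANNUAL_TC_TOTAL = [
    (20.3, 12.2, 27.0), (60.8, 36.5, 81.0),
    (202.6, 121.5, 270.1), (405.1, 243.1, 540.1),
]

# block index -> condition -> per-scenario (central, lower, upper)
DISCOUNTED_BLOCKS = {
    0: {
        CRC: [(8.2, 5.3, 10.6), (24.5, 15.8, 31.7),
              (81.5, 52.8, 105.5), (163.1, 105.5, 211.1)],
        TC: [(88.9, 53.3, 118.5), (266.6, 160.0, 355.5),
             (888.6, 533.2, 1184.8), (1777.3, 1066.4, 2369.7)],
    },
    1: {
        CRC: [(5.8, 3.8, 7.5), (17.4, 11.3, 22.6),
              (58.1, 37.6, 75.2), (116.3, 75.2, 150.5)],
        # the optimistic central was published as 633.3, which contradicts
        # the table's own universal column (1267.2 / 2 = 633.6) and its CI
        # (380.1-844.8); 633.6 is the internally consistent value.
        TC: [(63.4, 38.0, 84.5), (190.1, 114.0, 253.4),
             (633.6, 380.1, 844.8), (1267.2, 760.3, 1689.6)],
    },
    2: {
        CRC: [(4.1, 2.7, 5.4), (12.4, 8.0, 16.1),
              (41.5, 26.8, 53.6), (82.9, 53.6, 107.3)],
        TC: [(45.2, 27.1, 60.2), (135.5, 81.3, 180.7),
             (451.7, 271.0, 602.3), (903.5, 542.1, 1204.6)],
    },
    3: {
        CRC: [(3.0, 1.9, 3.8), (8.9, 5.7, 11.5),
              (29.6, 19.1, 38.2), (59.1, 38.2, 76.5)],
        TC: [(32.2, 19.3, 42.9), (96.6, 58.0, 128.8),
             (322.1, 193.2, 429.4), (644.2, 386.5, 858.9)],
    },
}

# condition -> per-scenario 20-year discounted totals
DISCOUNTED_TOTALS = {
    CRC: [(21.1, 13.6, 27.3), (63.2, 40.9, 81.8),
          (210.7, 136.3, 272.7), (421.4, 272.7, 545.3)],
    TC: [(229.6, 137.8, 306.1), (688.8, 413.3, 918.4),
         (2296.0, 1377.6, 3061.4), (4592.1, 2755.2, 6122.8)],
}

# condition -> staged incremental-adoption discounted total
INCREMENTAL_TOTALS = {
    CRC: (126.2, 81.6, 163.3),
    TC: (1374.8, 824.9, 1833.1),
}

# published expenditure totals (AUD million); the total-cancers 2015-16
# categories as printed sum to 7908.7 against a printed total of 7908.8
# (rounding inside the source table), so base-column sums are compared
# at display-rounding tolerance while the 2020 sums are exact
EXPENDITURE_TOTALS = {
    CRC: {"2015-16": 640.3, "2020": 728.9},
    TC: {"2015-16": 7908.8, "2020": 9002.3},
}

RISK_REDUCTIONS_PCT = {
    CRC: (5.1, 3.3, 6.6),
    TC: (4.5, 2.7, 6.0),
}
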