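"""Embedded clinical fixtures: the 21-subject MS cohort.

Two tables transcribed verbatim from the study report this package
operationalises: demographics (age, sex, MS course, disease duration, EDSS)
and clinical assessment (ARAT total, 9HPT time and pegs/min, FTRS postural
and intention tremor ratings, and the published impairment-cluster label).

Notes kept as printed: the demographics table prints median EDSS 7 although
the median of the listed values is 6.5; subject S18's printed 5.4 pegs/min
is not reproduced from 105.9 s by the conversion that matches every other
row (which yields 4.8).  The printed values are stored unchanged.
"""

# subject, age [years], sex, MS course (RR/PP/SP), disease duration [years], EDSS
DEMOGRAPHICS = [
    ("S1", 69, "F", "RR", 31, 6.0),
    ("S2", 43, "M", "RR", 15, 4.5),
    ("S3", 57, "F", "RR", 32, 6.5),
    ("S4", 44, "M", "RR", 1, 6.5),
    ("S5", 51, "M", "SP", 29, 7.5),
    ("S6", 45, "M", "PP", 4, 6.0),
    ("S7", 58, "M", "SP", 14, 7.0),
    ("S8", 25, "F", "RR", 3, 2.5),
    ("S9", 51, "F", "SP", 25, 7.5),
    ("S10", 40, "M", "RR", 1, 2.0),
    ("S11", 39, "F", "SP", 23, 8.0),
    ("S12", 38, "F", "RR", 5, 6.5),
    ("S13", 44, "F", "SP", 23, 8.5),
    ("S14", 55, "M", "PP", 33, 6.0),
    ("S15", 50, "M", "PP", 18, 6.5),
    ("S16", 38, "M", "RR", 5, 6.0),
    ("S17", 54, "F", "RR", 27, 6.0),
    ("S18", 46, "F", "PP", 8, 7.5),
    ("S19", 61, "M", "SP", 31, 5.5),
    ("S20", 45, "M", "SP", 9, 6.5),
    ("S21", 43, "M", "RR", 2, 6.5),
]

# published cluster, subject, ARAT [0-57], 9HPT time [s] (None = unable),
# 9HPT [pegs/min] as printed, FTRS postural [0-4], FTRS intention [0-4]
CLINICAL = [
    ("mild", "S1", 57, 37.5, 14.4, 0, 1),
    ("mild", "S2", 56, 25.0, 21.6, 1, 1),
    ("mild", "S3", 57, 27.3, 19.8, 1, 0),
    ("mild", "S4", 57, 28.2, 19.2, 0, 0),
    ("mild", "S10", 55, 32.4, 16.8, 0, 0),
    ("mild", "S11", 57, 32.8, 16.2, 0, 0),
    ("mild", "S12", 55, 31.2, 17.4, 0, 0),
    ("mild", "S15", 57, 30.7, 17.4, 1, 0),
    ("mild", "S16", 57, 36.2, 15.0, 1, 0),
    ("mild", "S17", 54, 31.0, 17.4, 1, 2),
    ("mild", "S19", 55, 33.1, 16.2, 1, 1),
    ("mild", "S21", 56, 30.5, 18.0, 1, 1),
    ("moderate", "S6", 51, 49.9, 10.8, 2, 1),
    ("moderate", "S8", 39, 40.9, 13.2, 1, 1),
    ("moderate", "S9", 40, 44.9, 12.0, 2, 2),
    ("moderate", "S13", 49, 59.6, 9.0, 1, 1),
    ("moderate", "S14", 44, 44.9, 12.0, 0, 1),
    ("severe", "S5", 34, None, 0.0, 1, 3),
    ("severe", "S7", 37, None, 0.0, 1, 2),
    ("severe", "S18", 34, 105.9, 5.4, 2, 3),
    ("severe", "S20", 39, 159.5, 3.6, 1, 4),
]

#: subjects whose printed pegs/min is not reproduced by the rate conversion
CONVERSION_ANOMALIES = ("S18",)
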