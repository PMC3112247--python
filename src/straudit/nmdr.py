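"""Study design and reported reference values for the Norwegian minke whale
DNA register (NMDR) audit.

The NMDR stores ten-locus microsatellite profiles for every minke whale
landed by the Norwegian hunt since 1997.  Genotyping responsibility rotated
through four laboratories, and a re-genotyping audit of 240 archived tissue
samples (234 analyzable) quantified register-vs-truth discrepancies.  This
module collects the audit's design constants (loci, multiplexes, lab
schedule, sample sizes) and its published summary statistics (error tallies,
candidate-model AICs, selected-model coefficients and marginal rates) so
that downstream analyses can be reproduced or simulated without access to
the non-public register itself.
"""

from __future__ import annotations

# The ten register loci, in the order they are conventionally listed.
LOCI: list[str] = [
    "GT509", "GT310", "GT211", "GT575", "GT023",
    "GATA098", "GATA417", "GATA028", "EV001", "EV037",
]

# Observed allele-length extremes (bp) per locus.
ALLELE_RANGES: dict[str, tuple[int, int]] = {
    "GATA417": (223, 252),
    "EV037": (203, 211),
    "GATA028": (202, 223),
    "GT575": (155, 166),
    "GT509": (203, 217),
    "GT310": (117, 125),
    "GT211": (106, 116),
    "GT023": (103, 115),
    "GATA098": (93, 107),
    "EV001": (153, 175),
}

# Repeat-unit length (bp): tetranucleotide GATA markers, dinucleotide otherwise.
REPEAT_UNIT: dict[str, int] = {
    locus: (4 if locus.startswith("GATA") else 2) for locus in LOCI
}

# The markers were amplified in three multiplex PCR assays.  The exact
# assignment of loci to assays is a protocol detail not recoverable from the
# audit summary; this fixed partition is used throughout as the default.
MULTIPLEXES: dict[str, str] = {
    "GT509": "mp1", "GT310": "mp1", "GT211": "mp1",
    "GT575": "mp2", "GT023": "mp2", "GATA098": "mp2", "EV001": "mp2",
    "GATA417": "mp3", "GATA028": "mp3", "EV037": "mp3",
}

# Which laboratory genotyped each catch year.
LAB_OF_YEAR: dict[int, str] = {
    1997: "Lab1", 1998: "Lab1", 1999: "Lab1", 2000: "Lab1",
    2001: "Lab1", 2002: "Lab1",
    2003: "Lab2", 2004: "Lab2", 2005: "Lab2",
    2006: "Lab3",
    2007: "Lab4", 2008: "Lab4",
}

YEARS: list[int] = sorted(LAB_OF_YEAR)

# Analyzable re-genotyped samples per year.  20 samples per year were drawn;
# six failed to amplify and were excluded, leaving per-laboratory totals of
# 116 / 60 / 19 / 39 (= 234).
SAMPLES_PER_YEAR: dict[int, int] = {
    1997: 16, 1998: 20, 1999: 20, 2000: 20, 2001: 20, 2002: 20,
    2003: 20, 2004: 20, 2005: 20,
    2006: 19,
    2007: 20, 2008: 19,
}

SAMPLES_PER_LAB: dict[str, int] = {"Lab1": 116, "Lab2": 60, "Lab3": 19, "Lab4": 39}

# Audit error tally: per laboratory, per error class, counts split by
# whether every erroneous allele shifted exactly 1 bp or by more than 1 bp.
# (Lab 3 observed no errors at all.)
ERROR_TALLY: dict[str, dict[str, tuple[int, int]]] = {
    "Lab1": {
        "single_false_allele": (7, 3),
        "double_false_allele": (1, 5),
        "false_homozygote": (5, 4),
        "false_heterozygote": (0, 2),
    },
    "Lab2": {
        "single_false_allele": (0, 2),
        "double_false_allele": (0, 0),
        "false_homozygote": (1, 0),
        "false_heterozygote": (0, 0),
    },
    "Lab3": {},
    "Lab4": {
        "single_false_allele": (0, 0),
        "double_false_allele": (0, 0),
        "false_homozygote": (0, 0),
        "false_heterozygote": (0, 1),
    },
}

# Candidate-model AICs reported for the audit: (fixed terms, random term, AIC),
# ordered M1..M18.  YEAR and LAB are confounded (each lab served a contiguous
# block of years) and never co-occur.
CANDIDATE_AICS: list[tuple[str, frozenset, frozenset, float]] = [
    ("M1", frozenset({"LOCUS", "YEAR"}), frozenset({"IND"}), 295.7),
    ("M2", frozenset({"YEAR"}), frozenset({"IND"}), 297.5),
    ("M3", frozenset({"LAB", "LOCUS"}), frozenset({"IND"}), 299.3),
    ("M4", frozenset({"LAB"}), frozenset({"IND"}), 301.0),
    ("M5", frozenset({"LOCUS", "YEAR"}), frozenset(), 303.1),
    ("M6", frozenset({"LOCUS", "YEAR"}), frozenset({"MP:IND"}), 303.5),
    ("M7", frozenset({"YEAR"}), frozenset(), 303.6),
    ("M8", frozenset({"YEAR"}), frozenset({"MP:IND"}), 304.0),
    ("M9", frozenset({"LAB", "LOCUS"}), frozenset(), 307.1),
    ("M10", frozenset({"LAB", "LOCUS"}), frozenset({"MP:IND"}), 307.2),
    ("M11", frozenset({"LAB"}), frozenset(), 307.5),
    ("M12", frozenset({"LAB"}), frozenset({"MP:IND"}), 307.9),
    ("M13", frozenset({"LOCUS"}), frozenset({"IND"}), 308.3),
    ("M14", frozenset(), frozenset({"IND"}), 309.9),
    ("M15", frozenset({"LOCUS"}), frozenset({"MP:IND"}), 318.3),
    ("M16", frozenset(), frozenset({"MP:IND"}), 319.1),
    ("M17", frozenset({"LOCUS"}), frozenset(), 319.5),
    ("M18", frozenset(), frozenset(), 319.8),
]

# Selected-model (LOCUS + YEAR fixed, individual random intercept)
# coefficients on the logit scale.  YEAR is centered at 2001; EV001 showed
# zero errors and was excluded from the fit (its rate is reported as 0).
M1_INTERCEPT: float = -4.74
M1_YEAR_SLOPE: float = -0.36
M1_VAR_IND: float = 1.81
M1_LOCUS_COEF: dict[str, float] = {
    "GATA417": 1.59,
    "EV037": 0.40,
    "GATA028": 0.40,
    "GT575": 0.09,
    "GT509": -0.35,
    "GT310": -0.35,
    "GT211": -0.35,
    "GT023": -0.35,
    "GATA098": -1.08,
}
ERROR_FREE_LOCI: list[str] = ["EV001"]

CENTER_YEAR: int = 2001

# Population-averaged per-locus error rates under the selected model at the
# 2001 midpoint, as reported.
M1_MARGINAL_RATES_2001: dict[str, float] = {
    "GATA417": 0.0774,
    "EV037": 0.0283,
    "GATA028": 0.0283,
    "GT575": 0.0213,
    "GT509": 0.0141,
    "GT310": 0.0141,
    "GT211": 0.0141,
    "GT023": 0.0141,
    "GATA098": 0.0071,
    "EV001": 0.0,
}


def m1_predictors(year: int = CENTER_YEAR) -> dict[str, float]:
    """Per-locus linear predictors of the selected model at a calendar year.

    Returns ``intercept + locus coefficient + slope * (year - 2001)`` for the
    nine loci retained in the fit; error-free loci are omitted (their
    marginal rate is 0 by construction).
    """
    shift = M1_YEAR_SLOPE * (year - CENTER_YEAR)
    return {
        locus: M1_INTERCEPT + coef + shift for locus, coef in M1_LOCUS_COEF.items()
    }
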