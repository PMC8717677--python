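"""Published reference-cohort summary statistics.

These constants summarise the original metoprolol inpatient cohort on which
the attribute-spectrum method was developed: per-attribute group means on the
normalised [0, 1] scale, the successful-minus-unsuccessful mean differences as
published (4 dp), the visual three-way verdicts (symmetric / asymmetric with a
dominance breakpoint / asymmetric without) with 2-dp breakpoint estimates, and
the published importance flags.

They serve three purposes: calibrating the synthetic generator's default group
locations, validating the importance-support arithmetic, and providing the
breakpoint estimates used as simulation targets.  Note two quirks of the
published figures that the package reproduces rather than hides: HR is flagged
important although its |mean difference| (0.0185) is below the 0.05 support
threshold, and for Urea, Cys and FPG the published difference disagrees with
the published group means in the 4th decimal.
"""

from __future__ import annotations

from .normalize import ATTRIBUTE_ORDER

__all__ = [
    "REFERENCE_GROUP_MEANS",
    "REFERENCE_VALUE_DIFFERENCE",
    "REFERENCE_IMPORTANT",
    "REFERENCE_ASYMMETRIC",
    "REFERENCE_HAS_BREAKPOINT",
    "REFERENCE_BREAKPOINTS",
    "SELF_CONSISTENT_DIFFERENCE_ROWS",
]

#: name -> (all-patients mean, successful-group mean, unsuccessful-group mean),
#: normalised scale.
REFERENCE_GROUP_MEANS: dict[str, tuple[float, float, float]] = {
    "HCT": (0.5758, 0.5242, 0.5949),
    "HB": (0.5381, 0.4881, 0.5566),
    "PLT": (0.3462, 0.3620, 0.3404),
    "Cr": (0.1307, 0.2005, 0.1050),
    "Urea": (0.2254, 0.2897, 0.2017),
    "UA": (0.4491, 0.4559, 0.4466),
    "Cys": (0.1979, 0.2732, 0.1701),
    "TC": (0.4102, 0.4314, 0.4025),
    "LDL": (0.3362, 0.3545, 0.3295),
    "HDL": (0.4148, 0.4154, 0.4146),
    "K": (0.4352, 0.4428, 0.4324),
    "Na": (0.3469, 0.3430, 0.3483),
    "FPG": (0.2578, 0.2601, 0.2570),
    "Age": (0.5746, 0.5286, 0.5916),
    "Sex": (0.4362, 0.5044, 0.4110),
    "SBP": (0.3432, 0.4109, 0.3182),
    "DBP": (0.4028, 0.4447, 0.3874),
    "PP": (0.3697, 0.4161, 0.3527),
    "HR": (0.3999, 0.4134, 0.3949),
}

#: Published successful-minus-unsuccessful mean difference (4 dp).
REFERENCE_VALUE_DIFFERENCE: dict[str, float] = {
    "HCT": -0.0707, "HB": -0.0685, "PLT": 0.0216, "Cr": 0.0955,
    "Urea": 0.0881, "UA": 0.0093, "Cys": 0.1030, "TC": 0.0289,
    "LDL": 0.0250, "HDL": 0.0008, "K": 0.0104, "Na": -0.0053,
    "FPG": 0.0032, "Age": -0.0630, "Sex": 0.0934, "SBP": 0.0927,
    "DBP": 0.0573, "PP": 0.0634, "HR": 0.0185,
}

#: Rows whose published difference equals the difference of the published
#: group means at 4 dp (Urea, Cys and FPG disagree in the last digit).
SELF_CONSISTENT_DIFFERENCE_ROWS: tuple[str, ...] = tuple(
    n for n in ATTRIBUTE_ORDER if n not in ("Urea", "Cys", "FPG")
)

#: Published importance verdicts (asymmetric with a breakpoint).
REFERENCE_IMPORTANT: dict[str, bool] = {
    name: name in {
        "HCT", "HB", "Cr", "Urea", "Cys", "Age", "Sex", "SBP", "DBP", "PP", "HR",
    }
    for name in ATTRIBUTE_ORDER
}

#: Published visual asymmetry verdicts.
REFERENCE_ASYMMETRIC: dict[str, bool] = {
    name: name not in {"UA", "HDL", "Na", "FPG"} for name in ATTRIBUTE_ORDER
}

#: Published breakpoint verdicts; None where asymmetry was absent and the
#: question does not arise.
REFERENCE_HAS_BREAKPOINT: dict[str, bool | None] = {
    name: (None if not REFERENCE_ASYMMETRIC[name] else REFERENCE_IMPORTANT[name])
    for name in ATTRIBUTE_ORDER
}

#: Published 2-dp breakpoint estimates; Sex was flagged as having a breakpoint
#: but no numeric estimate (binary attribute, degenerate case).
REFERENCE_BREAKPOINTS: dict[str, float | None] = {
    "HCT": 0.58, "HB": 0.52, "Cr": 0.10, "Urea": 0.24, "Cys": 0.18,
    "Age": 0.58, "Sex": None, "SBP": 0.35, "DBP": 0.42, "PP": 0.35, "HR": 0.37,
}
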