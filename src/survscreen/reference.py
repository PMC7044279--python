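"""Reference contingency data for a published 232-patient AML cohort.

Subgroup characteristics of the GEO GSE6891 cohort split into WBP5 low
(n = 160) and high (n = 72) expressers: carrier counts per molecular /
karyotypic abnormality, FAB class and sex.  These printed counts serve as a
desk-checkable input for the Fisher-exact machinery — the pipeline's exact
tests, run on these 2x2 tables, must reproduce the published p-values.
"""

from __future__ import annotations

N_LOW = 160
N_HIGH = 72

#: covariate level -> (carriers among low, carriers among high)
SUBGROUP_COUNTS: dict[str, tuple[int, int]] = {
    "IDH1": (7, 4),
    "IDH2": (5, 6),
    "NPM1c": (24, 31),
    "FLT3-ITD": (22, 29),
    "FLT3-TKD": (17, 7),
    "NRAS": (22, 4),
    "KRAS": (4, 0),
    "EVI1": (2, 11),
    "CEBPA": (18, 0),
    "+8": (10, 4),
    "-5/7q": (6, 10),
    "-9q": (5, 0),
    "11q23": (5, 3),
    "complex": (8, 0),
    "NN": (50, 31),
    "idt(16)": (23, 1),
    "t(8;21)": (32, 0),
    "FAB M1": (25, 27),
    "FAB M2": (39, 20),
    "FAB M4": (36, 8),
    "FAB M5": (39, 8),
    "Male": (80, 31),
}


def contingency_table(level: str) -> list[list[int]]:
    """2x2 table [[carriers_low, rest_low], [carriers_high, rest_high]]."""
    lo, hi = SUBGROUP_COUNTS[level]
    return [[lo, N_LOW - lo], [hi, N_HIGH - hi]]
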