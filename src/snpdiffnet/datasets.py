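"""Bundled example data.

``bc_demographics`` returns the demographic/lifestyle contingency
tables of a hospital-based breast-cancer case–control cohort (953
cases, 963 controls; per-factor totals differ slightly because each
factor was recorded on its own non-missing subset). Columns are
(control, case); rows are the factor's categories. These tables are the
standard worked example for the chi-square screen.
"""

from __future__ import annotations

from .epi import ContingencyTable

__all__ = ["bc_demographics"]

_TABLES: dict[str, tuple[list[str], list[list[int]]]] = {
    "age": (
        ["25-", "35-", "45-", "55-", "65-"],
        [[76, 62], [329, 302], [352, 364], [183, 200], [23, 25]],
    ),
    "bmi": (["<=28", ">28"], [[849, 799], [85, 117]]),
    "whr": (["<0.85", ">=0.85"], [[458, 389], [393, 400]]),
    "age_at_menarche": (
        ["7-11", "12-13", ">=14"],
        [[16, 11], [231, 223], [715, 719]],
    ),
    "number_of_births": (["0", ">=1"], [[25, 20], [926, 918]]),
    "diabetes": (["yes", "no"], [[32, 34], [921, 906]]),
    "plasma_glucose": (["<7", ">=7"], [[739, 776], [29, 37]]),
    "smoking": (["yes", "no"], [[10, 18], [950, 932]]),
    "alcohol": (["yes", "no"], [[3, 9], [956, 939]]),
    "menopause": (["yes", "no"], [[260, 309], [665, 614]]),
    "cholesterol": (["<=5.18", ">5.18"], [[505, 500], [211, 221]]),
}


def bc_demographics() -> dict[str, ContingencyTable]:
    """All demographic factors as ready-to-test contingency tables."""
    return {
        name: ContingencyTable(factor_name=name, row_labels=rows, counts=counts)
        for name, (rows, counts) in _TABLES.items()
    }
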