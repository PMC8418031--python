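"""Published loquat study tables, as analysis-ready inputs.

These are the printed observations of the original loquat flesh-color study:
mean dosage statistics of the polyploid germplasm panel, flow-cytometry ploidy
counts of the F1 families from the 4x x 2x and 2x x 4x crosses, and the
observed red/white phenotype counts per progeny-ploidy class. They serve as
inputs for reanalysis (genotype calling, ploidy tabulation, segregation
testing); all derived quantities are recomputed by this package.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "polyploid_panel",
    "f1_ploidy_counts",
    "f1_flesh_color_counts",
]

# variety/line, ploidy, mean b +/- sd over qPCR replicates, marker-based genotype
_PANEL = [
    ("A313", 3, 1.30, 0.0068, "AAA"),
    ("A322", 3, 1.01, 0.0682, "AAA"),
    ("D6", 3, 1.22, 0.0508, "AAA"),
    ("DHZ_3x", 3, 1.17, 0.0101, "AAA"),
    ("K374", 3, 0.69, 0.0269, "AAa"),
    ("SW_3x", 3, 0.63, 0.0290, "AAa"),
    ("XZ_3x", 3, 0.68, 0.0776, "AAa"),
    ("B356", 3, 0.28, 0.0388, "Aaa"),
    ("D25", 3, 0.32, 0.0170, "Aaa"),
    ("D27", 3, 0.29, 0.0367, "Aaa"),
    ("FZ_3x", 3, 0.36, 0.0058, "Aaa"),
    ("GF_3x", 3, 0.00, 0.0005, "aaa"),
    ("Q11", 3, 0.00, 0.0006, "aaa"),
    ("Q27", 3, 0.00, 0.0002, "aaa"),
    ("B431", 4, 0.26, 0.0121, "Aaaa"),
    ("B432", 4, 0.27, 0.0165, "Aaaa"),
    ("B479", 4, 0.76, 0.0186, "AAAa"),
    ("B433", 4, 0.78, 0.0199, "AAAa"),
    ("B456", 4, 0.58, 0.0137, "AAaa"),
    ("H424", 4, 1.03, 0.0248, "AAAA"),
    ("K474", 4, 0.76, 0.0149, "AAAa"),
    ("2008No3", 4, 0.57, 0.0121, "AAaa"),
]


def polyploid_panel() -> pd.DataFrame:
    """Triploid and tetraploid germplasm panel: mean b and marker genotype."""
    return pd.DataFrame(
        _PANEL, columns=["sample_id", "ploidy", "b_mean", "b_sd", "genotype"]
    )


# flow-cytometry progeny ploidy counts per cross (female listed first)
_PLOIDY_COUNTS: dict[str, dict[int, int]] = {
    "B431 x GF": {2: 1, 3: 50},
    "B432 x BTZ": {2: 7, 3: 46, 4: 2},
    "B456 x HB1": {3: 80, 4: 2, 5: 3},
    "H424 x HB1": {3: 5},
    "GF x B431": {2: 9, 3: 10, 4: 2},
    "BTZ x B432": {2: 5, 3: 15, 4: 1},
    "HB1 x B456": {2: 3, 3: 10, 4: 4},
    "HB1 x H424": {2: 1, 3: 4, 4: 5},
}


def f1_ploidy_counts() -> dict[str, dict[int, int]]:
    """Progeny ploidy counts of the eight 4x/2x reciprocal cross families."""
    return {k: dict(v) for k, v in _PLOIDY_COUNTS.items()}


# observed red/white flesh counts per cross and progeny-ploidy class
_FLESH_COLOR = [
    # cross, female genotype, male genotype, progeny ploidy, red, white
    ("GF x B431", "aa", "Aaaa", 2, 4, 5),
    ("GF x B431", "aa", "Aaaa", 3, 5, 5),
    ("GF x B431", "aa", "Aaaa", 4, 2, 0),
    ("B431 x GF", "Aaaa", "aa", 2, 0, 1),
    ("B431 x GF", "Aaaa", "aa", 3, 20, 30),
    ("B431 x GF", "Aaaa", "aa", 4, 0, 0),
    ("BTZ x B432", "aa", "Aaaa", 2, 3, 2),
    ("BTZ x B432", "aa", "Aaaa", 3, 7, 8),
    ("BTZ x B432", "aa", "Aaaa", 4, 0, 1),
    ("B432 x BTZ", "Aaaa", "aa", 2, 3, 4),
    ("B432 x BTZ", "Aaaa", "aa", 3, 27, 19),
    ("B432 x BTZ", "Aaaa", "aa", 4, 1, 1),
    ("HB1 x B456", "aa", "AAaa", 2, 2, 1),
    ("HB1 x B456", "aa", "AAaa", 3, 10, 0),
    ("HB1 x B456", "aa", "AAaa", 4, 3, 1),
    ("B456 x HB1", "AAaa", "aa", 2, 0, 0),
    ("B456 x HB1", "AAaa", "aa", 3, 66, 14),
    ("B456 x HB1", "AAaa", "aa", 4, 1, 1),
    ("B456 x HB1", "AAaa", "aa", 5, 3, 0),
    ("HB1 x H424", "aa", "AAAA", 2, 1, 0),
    ("HB1 x H424", "aa", "AAAA", 3, 4, 0),
    ("HB1 x H424", "aa", "AAAA", 4, 5, 0),
    ("H424 x HB1", "AAAA", "aa", 2, 0, 0),
    ("H424 x HB1", "AAAA", "aa", 3, 5, 0),
    ("H424 x HB1", "AAAA", "aa", 4, 0, 0),
]


def f1_flesh_color_counts() -> pd.DataFrame:
    """Observed red/white progeny counts per cross and progeny-ploidy class."""
    return pd.DataFrame(
        _FLESH_COLOR,
        columns=[
            "cross",
            "female_genotype",
            "male_genotype",
            "progeny_ploidy",
            "observed_red",
            "observed_white",
        ],
    )
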