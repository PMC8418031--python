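"""Polysomic inheritance: gamete distributions, expected ratios, chi-square.

Autopolyploids such as natural tetraploid loquat segregate polysomically: at
meiosis all homologous chromosomes pair at random, so the number of dominant
(A) alleles in a gamete of ploidy g drawn from a parent of ploidy m carrying
nA dominant copies is hypergeometric,

    P(k) = C(nA, k) * C(m - nA, g - k) / C(m, g).

Double reduction and preferential pairing are not modeled. Offspring allele
counts are the convolution of the two parental gamete distributions; with a
fully dominant locus (white flesh iff zero A copies) this yields expected
red:white phenotype ratios per progeny-ploidy class, testable against
observed counts with a Pearson chi-square goodness-of-fit test (df = 1, no
continuity correction).

Probabilities are exact rationals (:class:`fractions.Fraction`) until the
final conversion, so gamete masses sum to 1 exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DegenerateDataError, InfeasibleCrossError
from .genotypes import AllelicConfiguration

__all__ = [
    "GameteDistribution",
    "CrossSpec",
    "SegregationTest",
    "gamete_frequencies",
    "offspring_distribution",
    "expected_phenotype_ratio",
    "chi_square_gof",
    "segregation_table",
    "ploidy_tabulation",
    "format_ratio",
]


@dataclass(frozen=True)
class GameteDistribution:
    """Probability mass over the number of A alleles in a gamete."""

    parent: AllelicConfiguration
    gamete_ploidy: int
    mass: Mapping[int, Fraction]

    def as_floats(self) -> dict[int, float]:
        return {k: float(v) for k, v in self.mass.items()}


def gamete_frequencies(
    parent: AllelicConfiguration, gamete_ploidy: int
) -> GameteDistribution:
    """Hypergeometric gamete distribution under random chromosome segregation."""
    m, na = parent.ploidy, parent.n_dominant
    g = gamete_ploidy
    if not 1 <= g <= m:
        raise InfeasibleCrossError(
            f"gamete ploidy {g} infeasible for a parent of ploidy {m}"
        )
    denom = math.comb(m, g)
    lo = max(0, g - (m - na))
    hi = min(g, na)
    mass = {
        k: Fraction(math.comb(na, k) * math.comb(m - na, g - k), denom)
        for k in range(lo, hi + 1)
    }
    assert sum(mass.values()) == 1
    return GameteDistribution(parent=parent, gamete_ploidy=g, mass=mass)


@dataclass(frozen=True)
class CrossSpec:
    """One cross and the progeny-ploidy class under consideration.

    By default the lower-ploidy parent contributes its normal reduced gamete
    (g = ploidy // 2, so a diploid gives 1) and the other parent contributes
    whatever ploidy the progeny class requires (progeny_ploidy - g); explicit
    ``female_gamete`` / ``male_gamete`` override that allocation, e.g. for
    unreduced gametes.
    """

    female: AllelicConfiguration
    male: AllelicConfiguration
    progeny_ploidy: int
    female_gamete: int | None = None
    male_gamete: int | None = None


def _allocate_gametes(cross: CrossSpec) -> tuple[int, int]:
    n = cross.progeny_ploidy
    gf, gm = cross.female_gamete, cross.male_gamete
    if gf is None and gm is not None:
        gf = n - gm
    elif gm is None and gf is not None:
        gm = n - gf
    elif gf is None and gm is None:
        if cross.female.ploidy <= cross.male.ploidy:
            gf = max(1, cross.female.ploidy // 2)
            gm = n - gf
        else:
            gm = max(1, cross.male.ploidy // 2)
            gf = n - gm
    if (
        gf + gm != n
        or not 1 <= gf <= cross.female.ploidy
        or not 1 <= gm <= cross.male.ploidy
    ):
        raise InfeasibleCrossError(
            f"no feasible gamete allocation for {cross.female.label} x "
            f"{cross.male.label} -> {n}x progeny (tried female g={gf}, male g={gm})"
        )
    return gf, gm


def offspring_distribution(cross: CrossSpec) -> dict[int, Fraction]:
    """Distribution of offspring A-allele counts: convolution of parental gametes."""
    gf, gm = _allocate_gametes(cross)
    female = gamete_frequencies(cross.female, gf)
    male = gamete_frequencies(cross.male, gm)
    out: dict[int, Fraction] = {}
    for kf, pf in female.mass.items():
        for km, pm in male.mass.items():
            out[kf + km] = out.get(kf + km, Fraction(0)) + pf * pm
    return dict(sorted(out.items()))


def expected_phenotype_ratio(cross: CrossSpec) -> tuple[int, int]:
    """Expected red:white ratio in least integer terms.

    Red flesh is dominant: an offspring is white iff it carries zero A copies.
    """
    dist = offspring_distribution(cross)
    white = dist.get(0, Fraction(0))
    red = 1 - white
    if white == 0:
        return (1, 0)
    if red == 0:
        return (0, 1)
    ratio = red / white
    return (ratio.numerator, ratio.denominator)


@dataclass(frozen=True)
class SegregationTest:
    """Pearson goodness-of-fit of observed red/white counts to an expected ratio."""

    observed_red: int
    observed_white: int
    expected_ratio: tuple[float, float]
    chi2: float
    df: int
    p: float
    flags: tuple[str, ...] = ()


def chi_square_gof(
    observed: tuple[int, int], expected_ratio: tuple[float, float]
) -> SegregationTest:
    """Pearson chi-square (no continuity correction) of a two-class ratio.

    Expected counts are the ratio rescaled to the observed total. A class with
    expected probability 0 contributes nothing when its observed count is also
    0 (flagged degenerate); an observation in a zero-expectation class makes
    the statistic infinite.
    """
    o = np.asarray(observed, dtype=float)
    if o.min() < 0 or o.sum() < 1:
        raise ValueError(f"observed counts must be nonnegative with total >= 1: {observed}")
    parts = np.asarray(expected_ratio, dtype=float)
    if parts.min() < 0 or parts.sum() <= 0:
        raise ValueError(f"invalid expected ratio {expected_ratio}")
    e = o.sum() * parts / parts.sum()
    flags: list[str] = []
    chi2 = 0.0
    for oi, ei in zip(o, e):
        if ei == 0.0:
            if oi == 0.0:
                flags.append("degenerate_class")
            else:
                chi2 = math.inf
                flags.append("observed_in_zero_expectation_class")
        else:
            chi2 += (oi - ei) ** 2 / ei
    p = 0.0 if math.isinf(chi2) else float(sps.chi2.sf(chi2, df=1))
    return SegregationTest(
        observed_red=int(observed[0]),
        observed_white=int(observed[1]),
        expected_ratio=(float(parts[0]), float(parts[1])),
        chi2=float(chi2),
        df=1,
        p=p,
        flags=tuple(flags),
    )


def format_ratio(red: float, white: float) -> str:
    """Ratio normalized so the smaller side is 1, at most 2 decimals."""

    def trim(x: float) -> str:
        return f"{x:.2f}".rstrip("0").rstrip(".")

    if red == 0 and white == 0:
        return "/"
    if white == 0:
        return "1:0"
    if red == 0:
        return "0:1"
    if red >= white:
        return f"{trim(red / white)}:1"
    return f"1:{trim(white / red)}"


def _coerce_config(value) -> AllelicConfiguration:
    if isinstance(value, AllelicConfiguration):
        return value
    return AllelicConfiguration.from_string(str(value))


def segregation_table(records) -> pd.DataFrame:
    """Full per-cross, per-ploidy-class segregation report.

    *records* is a DataFrame (or list of dicts) with columns cross,
    female_genotype, male_genotype, progeny_ploidy, observed_red,
    observed_white. One row is emitted per progeny-ploidy class plus a pooled
    ``Total`` row per cross whose expected counts are the class-size-weighted
    sums of the per-class expectations. Empty classes (0, 0) are reported with
    "/" placeholders.
    """
    df = pd.DataFrame(records)
    required = {
        "cross", "female_genotype", "male_genotype", "progeny_ploidy",
        "observed_red", "observed_white",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"segregation records lack columns: {sorted(missing)}")
    rows = []
    for cross_name in df["cross"].drop_duplicates():
        sub = df[df["cross"] == cross_name]
        pooled_o = np.zeros(2)
        pooled_e = np.zeros(2)
        female = _coerce_config(sub.iloc[0]["female_genotype"])
        male = _coerce_config(sub.iloc[0]["male_genotype"])
        for _, rec in sub.iterrows():
            ploidy = int(rec["progeny_ploidy"])
            red, white = int(rec["observed_red"]), int(rec["observed_white"])
            spec = CrossSpec(female=female, male=male, progeny_ploidy=ploidy)
            ratio = expected_phenotype_ratio(spec)
            row = {
                "cross": cross_name,
                "female": female.label,
                "male": male.label,
                "ploidy_class": f"{ploidy}x",
                "observed_red": red,
                "observed_white": white,
                "observed_ratio": format_ratio(red, white),
                "expected_ratio": f"{ratio[0]}:{ratio[1]}",
            }
            total = red + white
            if total == 0:
                row.update(
                    observed_ratio="/", expected_ratio="/",
                    chi2=np.nan, df=np.nan, p=np.nan, flags="",
                )
            else:
                test = chi_square_gof((red, white), ratio)
                e = total * np.asarray(ratio, float) / sum(ratio)
                pooled_o += (red, white)
                pooled_e += e
                row.update(
                    chi2=test.chi2, df=test.df, p=test.p, flags=";".join(test.flags)
                )
            rows.append(row)
        # pooled Total row, tested against the summed per-class expected counts
        flags: list[str] = []
        chi2 = 0.0
        for oi, ei in zip(pooled_o, pooled_e):
            if ei == 0.0:
                if oi == 0.0:
                    flags.append("degenerate_class")
                else:
                    chi2 = math.inf
                    flags.append("observed_in_zero_expectation_class")
            else:
                chi2 += (oi - ei) ** 2 / ei
        p = 0.0 if math.isinf(chi2) else float(sps.chi2.sf(chi2, df=1))
        rows.append(
            {
                "cross": cross_name,
                "female": female.label,
                "male": male.label,
                "ploidy_class": "Total",
                "observed_red": int(pooled_o[0]),
                "observed_white": int(pooled_o[1]),
                "observed_ratio": format_ratio(*pooled_o),
                "expected_ratio": format_ratio(*pooled_e),
                "chi2": float(chi2),
                "df": 1,
                "p": p,
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(rows)


def ploidy_tabulation(records: Mapping[str, Mapping[int, int]]) -> pd.DataFrame:
    """Counts and percentages of progeny by ploidy class, per cross.

    *records* maps cross name -> {ploidy: count}. Percentages are rounded to
    2 decimals and sum to 100 per cross within rounding.
    """
    rows = []
    for cross_name, counts in records.items():
        total = sum(counts.values())
        if total <= 0:
            raise DegenerateDataError(f"cross {cross_name!r} has no progeny counted")
        for ploidy in sorted(counts):
            count = counts[ploidy]
            if count < 0:
                raise ValueError(f"negative count for {cross_name!r} {ploidy}x")
            rows.append(
                {
                    "cross": cross_name,
                    "ploidy": ploidy,
                    "count": count,
                    "percent": round(100.0 * count / total, 2),
                }
            )
    return pd.DataFrame(rows)
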