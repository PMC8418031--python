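"""Allelic configurations and dosage-based genotype calling for polyploids.

A locus with a dominant allele A and a recessive allele a in an individual of
ploidy m has m + 1 possible allelic configurations (dosage classes), written
as canonical strings such as ``AAaa`` (two dominant copies in a tetraploid).
The relative allele-A signal b estimated from qPCR has expectation
``n_dominant / ploidy`` for each class, so calling a genotype amounts to
nearest-class assignment of b on the grid {0, 1/m, ..., 1}.

Class separability on simulated dosage libraries is quantified the way the
original analysis did: farthest-neighbour (complete-linkage) hierarchical
clustering of the scalar b values, and a one-way ANOVA across dosage classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy

from .exceptions import DegenerateDataError, InvalidGenotypeError

__all__ = [
    "AllelicConfiguration",
    "GenotypeCall",
    "AnovaResult",
    "SeparationReport",
    "expected_b",
    "call_genotype",
    "cluster_dosages",
    "anova_separation",
    "separation_report",
]


@dataclass(frozen=True, order=True)
class AllelicConfiguration:
    """Multiset of dominant/recessive alleles at one locus.

    Parameters
    ----------
    ploidy : int
        Total number of locus copies (>= 1).
    n_dominant : int
        Number of dominant (A) copies, 0..ploidy.
    """

    ploidy: int
    n_dominant: int

    def __post_init__(self) -> None:
        if self.ploidy < 1:
            raise InvalidGenotypeError(f"ploidy must be >= 1, got {self.ploidy}")
        if not 0 <= self.n_dominant <= self.ploidy:
            raise InvalidGenotypeError(
                f"n_dominant must be in 0..{self.ploidy}, got {self.n_dominant}"
            )

    @property
    def n_recessive(self) -> int:
        return self.ploidy - self.n_dominant

    @property
    def label(self) -> str:
        """Canonical string, dominant copies first (e.g. ``AAaa``)."""
        return "A" * self.n_dominant + "a" * self.n_recessive

    @property
    def a_fraction(self) -> float:
        """Fraction of locus copies that are allele A."""
        return self.n_dominant / self.ploidy

    @classmethod
    def from_string(cls, genotype: str, ploidy: int | None = None) -> "AllelicConfiguration":
        """Parse a genotype string over {A, a}, canonicalizing copy order.

        ``"AaAa"`` parses to the same configuration as ``"AAaa"``. If *ploidy*
        is given it must match the string length.
        """
        s = genotype.strip()
        if not s or any(c not in "Aa" for c in s):
            raise InvalidGenotypeError(
                f"genotype string must be non-empty over {{A, a}}, got {genotype!r}"
            )
        if ploidy is not None and len(s) != ploidy:
            raise InvalidGenotypeError(
                f"genotype {genotype!r} has {len(s)} copies but ploidy is {ploidy}"
            )
        return cls(ploidy=len(s), n_dominant=s.count("A"))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def expected_b(configuration: AllelicConfiguration) -> float:
    """Expected relative allele-A signal for a configuration: n_dominant/ploidy."""
    return configuration.n_dominant / configuration.ploidy


@dataclass(frozen=True)
class GenotypeCall:
    """Nearest-dosage-class assignment of a measured b value."""

    sample_id: str
    configuration: AllelicConfiguration
    b: float
    expected_b: float
    residual: float
    ambiguous: bool


def call_genotype(
    b: float,
    ploidy: int,
    sample_id: str = "",
    tie_tol: float = 1e-9,
) -> GenotypeCall:
    """Assign the allelic configuration whose expected b is nearest to *b*.

    Out-of-range b (below 0 or above 1, which occurs in practice through copy
    number variation or efficiency mismatch) clamps to the nearest extreme
    class. An exact midpoint between two classes resolves to the lower dosage
    and is flagged ambiguous.
    """
    if ploidy < 1:
        raise InvalidGenotypeError(f"ploidy must be >= 1, got {ploidy}")
    if not math.isfinite(b):
        raise ValueError(f"b must be finite, got {b!r}")
    dists = [abs(b - k / ploidy) for k in range(ploidy + 1)]
    best_k = int(np.argmin(dists))  # argmin takes the lowest k on ties
    order = sorted(range(ploidy + 1), key=dists.__getitem__)
    ambiguous = len(order) > 1 and dists[order[1]] - dists[order[0]] <= tie_tol
    config = AllelicConfiguration(ploidy=ploidy, n_dominant=best_k)
    exp = expected_b(config)
    return GenotypeCall(
        sample_id=sample_id,
        configuration=config,
        b=float(b),
        expected_b=exp,
        residual=abs(b - exp),
        ambiguous=bool(ambiguous),
    )


def cluster_dosages(b_values: Sequence[float], n_classes: int) -> np.ndarray:
    """Complete-linkage hierarchical clustering of scalar dosage values.

    Returns integer labels 0..n_classes-1, renumbered in ascending order of
    cluster mean so labelling is deterministic for a fixed input order.
    """
    values = np.asarray(list(b_values), dtype=float)
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    if values.size < n_classes:
        raise DegenerateDataError(
            f"cannot form {n_classes} classes from {values.size} values"
        )
    if n_classes == 1 or values.size == 1:
        return np.zeros(values.size, dtype=int)
    link = hierarchy.linkage(values.reshape(-1, 1), method="complete", metric="euclidean")
    raw = hierarchy.fcluster(link, t=n_classes, criterion="maxclust")
    # renumber clusters by ascending mean b
    means = {lab: values[raw == lab].mean() for lab in np.unique(raw)}
    rank = {lab: i for i, lab in enumerate(sorted(means, key=means.__getitem__))}
    return np.array([rank[lab] for lab in raw], dtype=int)


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA across dosage classes."""

    F: float
    p: float
    df_between: int
    df_within: int
    infinite: bool = False


def anova_separation(
    groups: Mapping[object, Sequence[float]] | Iterable[Sequence[float]],
) -> AnovaResult:
    """One-way ANOVA F = MS_between / MS_within over groups of b values.

    With zero within-group variance everywhere the classes are perfectly
    separated and F is reported as +inf with the ``infinite`` flag instead of
    dividing by zero.
    """
    if isinstance(groups, Mapping):
        arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        arrays = [np.asarray(v, dtype=float) for v in groups]
    if len(arrays) < 2:
        raise DegenerateDataError("ANOVA needs at least two groups")
    for i, arr in enumerate(arrays):
        if arr.size < 2:
            raise DegenerateDataError(f"ANOVA group {i} has fewer than 2 values")
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ssw == 0.0:
        return AnovaResult(
            F=math.inf, p=0.0, df_between=k - 1, df_within=n_total - k, infinite=True
        )
    f, p = stats.f_oneway(*arrays)
    return AnovaResult(
        F=float(f), p=float(p), df_between=k - 1, df_within=n_total - k
    )


@dataclass(frozen=True)
class SeparationReport:
    """Clustering assignments plus ANOVA for a dosage library."""

    group_assignments: np.ndarray
    F: float
    p: float
    anova: AnovaResult
    cluster_method: str = field(default="complete-linkage")


def separation_report(b_values: Sequence[float], n_classes: int) -> SeparationReport:
    """Cluster b values into n_classes and run ANOVA across the clusters."""
    labels = cluster_dosages(b_values, n_classes)
    values = np.asarray(list(b_values), dtype=float)
    groups = [values[labels == lab] for lab in np.unique(labels)]
    res = anova_separation(groups)
    return SeparationReport(
        group_assignments=labels, F=res.F, p=res.p, anova=res
    )
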