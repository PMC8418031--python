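"""Relative allele quantification from qPCR cycle thresholds.

The genotyping assay measures each gDNA sample with three primer pairs:

* a **reference** amplicon with a constant copy number per haploid genome
  (the CH03g12 locus in loquat), which normalizes DNA input;
* an **allele-A-specific** amplicon (primer q2A);
* a **combined** amplicon hitting both alleles (primer pair q2A/2Ad).

Relative copy numbers come from the 2^-ddCt method against a calibrator of
known genotype (by default a heterozygous diploid Aa). Because the reference
amplicon occurs once per haploid genome, 2^-ddCt values are per-haploid
relative dosages and are rescaled by the calibrator's known per-haploid
allele copies so that the calibrator itself reads a1 = 1, a3 = 2:

    a1 = relative copy number of allele A
    a3 = relative copy number of A and a combined
    a2 = a3 - a1           (relative copy number of allele a)
    b  = a1 / (a1 + a2)    (relative allele-A signal; expectation = A fraction)
    theta = arctan(a2/a1) in degrees, 0 for pure A, 90 for pure a
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import (
    DegenerateDataError,
    IncompletePlateError,
    InvalidGenotypeError,
)
from .genotypes import AllelicConfiguration

__all__ = [
    "ASSAY_REFERENCE",
    "ASSAY_ALLELE_A",
    "ASSAY_COMBINED",
    "VALID_ASSAYS",
    "DEFAULT_LOD",
    "CtRecord",
    "AssayPanel",
    "CalibratorSpec",
    "RelativeDosage",
    "relative_quantity",
    "allele_signals",
    "dosage_from_signals",
    "reference_stability",
]

ASSAY_REFERENCE = "reference"
ASSAY_ALLELE_A = "allele_A"
ASSAY_COMBINED = "combined"
VALID_ASSAYS = frozenset({ASSAY_REFERENCE, ASSAY_ALLELE_A, ASSAY_COMBINED})

#: Relative quantities below this fraction of the calibrator signal are treated
#: as no amplification (limit of detection); see docs/methods.md.
DEFAULT_LOD = 1e-3


@dataclass(frozen=True)
class CtRecord:
    """One well's cycle-threshold measurement."""

    sample_id: str
    assay: str
    replicate: int
    ct: float

    def __post_init__(self) -> None:
        if self.assay not in VALID_ASSAYS:
            raise ValueError(
                f"assay must be one of {sorted(VALID_ASSAYS)}, got {self.assay!r}"
            )
        if not isinstance(self.replicate, int) or self.replicate < 1:
            raise ValueError(f"replicate must be a positive integer, got {self.replicate!r}")
        if not (isinstance(self.ct, (int, float)) and math.isfinite(self.ct) and self.ct > 0):
            raise ValueError(f"ct must be a finite positive number, got {self.ct!r}")


@dataclass(frozen=True)
class AssayPanel:
    """Names and shared amplification efficiency of the three assays.

    ``efficiency`` is the per-cycle amplification factor: 2.0 means perfect
    doubling (100% efficiency).
    """

    reference_name: str = "CH03g12"
    allele_A_name: str = "q2A"
    combined_name: str = "q2A/2Ad"
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        names = {self.reference_name, self.allele_A_name, self.combined_name}
        if len(names) != 3:
            raise ValueError("the three assay names must be distinct")
        if not 1.0 < self.efficiency <= 2.0:
            raise ValueError(f"efficiency must be in (1, 2], got {self.efficiency}")


@dataclass(frozen=True)
class CalibratorSpec:
    """A sample of known genotype used to anchor relative copy numbers."""

    sample_id: str
    genotype: AllelicConfiguration
    ploidy: int

    def __post_init__(self) -> None:
        if self.genotype.ploidy != self.ploidy:
            raise InvalidGenotypeError(
                f"calibrator ploidy {self.ploidy} does not match genotype "
                f"{self.genotype.label!r}"
            )

    @classmethod
    def heterozygous_diploid(cls, sample_id: str = "calibrator") -> "CalibratorSpec":
        return cls(sample_id, AllelicConfiguration(ploidy=2, n_dominant=1), 2)


@dataclass(frozen=True)
class RelativeDosage:
    """Per-sample relative copy numbers and derived dosage statistics."""

    sample_id: str
    a1: float
    a2: float
    a3: float
    b: float
    theta: float
    flags: tuple[str, ...] = ()


def _mean_ct(records: Iterable[CtRecord], assay: str, sample_id: str) -> float:
    cts = [r.ct for r in records if r.assay == assay]
    if not cts:
        raise IncompletePlateError(
            f"incomplete plate: sample {sample_id!r} has no wells for assay {assay!r}"
        )
    return float(np.mean(cts))


def relative_quantity(
    sample_cts: Sequence[CtRecord],
    calibrator_cts: Sequence[CtRecord],
    assay: str,
    panel: AssayPanel,
) -> float:
    """Relative template quantity of *assay* in the sample vs the calibrator.

    Implements the 2^-ddCt method with a configurable amplification factor:
    replicate Cts are averaged per (sample, assay) before differencing, then

        ddCt = (Ct_assay,sample - Ct_ref,sample) - (Ct_assay,cal - Ct_ref,cal)

    and the result is ``efficiency ** -ddCt``.
    """
    sid = sample_cts[0].sample_id if sample_cts else "<empty>"
    cid = calibrator_cts[0].sample_id if calibrator_cts else "<empty>"
    d_sample = _mean_ct(sample_cts, assay, sid) - _mean_ct(sample_cts, ASSAY_REFERENCE, sid)
    d_cal = _mean_ct(calibrator_cts, assay, cid) - _mean_ct(calibrator_cts, ASSAY_REFERENCE, cid)
    return float(panel.efficiency ** -(d_sample - d_cal))


def dosage_from_signals(
    sample_id: str,
    a1: float,
    a3: float,
    flags: Sequence[str] = (),
) -> RelativeDosage:
    """Assemble a :class:`RelativeDosage` from the two scaled signals.

    a2 = a3 - a1 is retained even when negative (over-unity allele-A signals
    occur in real data) but flagged; theta is clamped to [0, 90] degrees.
    """
    flag_list = list(flags)
    a2 = a3 - a1
    if a2 < 0:
        flag_list.append("negative_a2")
    denom = a1 + a2  # == a3 by construction
    if denom > 0:
        b = a1 / denom
    else:
        b = math.nan
        flag_list.append("no_signal")
    if a1 <= 0 and a2 > 0:
        theta = 90.0
    elif a2 <= 0:
        theta = 0.0
    else:
        theta = math.degrees(math.atan2(a2, a1))
    return RelativeDosage(
        sample_id=sample_id,
        a1=float(a1),
        a2=float(a2),
        a3=float(a3),
        b=float(b),
        theta=float(theta),
        flags=tuple(flag_list),
    )


def allele_signals(
    sample_cts: Sequence[CtRecord],
    calibrator: CalibratorSpec,
    calibrator_cts: Sequence[CtRecord],
    panel: AssayPanel,
    lod: float = DEFAULT_LOD,
) -> RelativeDosage:
    """Calibrated relative allele copy numbers (a1, a2, a3) plus b and theta.

    The scaling contract: the reference amplicon has one copy per haploid
    genome at every ploidy, so 2^-ddCt against it yields per-haploid relative
    dosages. These are rescaled by the calibrator's known per-haploid allele
    copies so that a heterozygous-diploid calibrator reads a1 = 1 and a3 = 2
    against itself, which puts b on the 0..1 allele-A-fraction scale.

    Relative quantities below *lod* (limit of detection, relative to the
    calibrator) are treated as absent template and set to 0.
    """
    if calibrator.genotype.n_dominant == 0:
        raise InvalidGenotypeError(
            "calibrator must carry at least one copy of allele A to calibrate it"
        )
    sid = sample_cts[0].sample_id if sample_cts else "<empty>"
    rq_a = relative_quantity(sample_cts, calibrator_cts, ASSAY_ALLELE_A, panel)
    rq_c = relative_quantity(sample_cts, calibrator_cts, ASSAY_COMBINED, panel)
    flags: list[str] = []
    if rq_a < lod:
        rq_a = 0.0
        flags.append("below_lod_allele_A")
    if rq_c < lod:
        rq_c = 0.0
        flags.append("below_lod_combined")
    # calibrator A copies per haploid genome, times 2 (het-diploid convention)
    a1 = 2.0 * rq_a * calibrator.genotype.n_dominant / calibrator.ploidy
    # the combined amplicon occurs once per haploid genome in every sample
    a3 = 2.0 * rq_c
    return dosage_from_signals(sid, a1, a3, flags)


def reference_stability(
    ct_by_ploidy: Mapping[object, Sequence[CtRecord] | Sequence[float]],
    threshold: float = 3.0,
) -> tuple[dict, bool]:
    """Per-ploidy coefficient of variation (%) of reference-assay Ct values.

    Returns ``(cv_by_group, all_below)`` where ``all_below`` is True when every
    group's CV is strictly below *threshold* percent. A stable reference across
    ploidies (CV < 3% in the original screen) is what licenses per-haploid
    normalization.
    """
    cvs: dict = {}
    for group, values in ct_by_ploidy.items():
        cts = np.asarray(
            [v.ct if isinstance(v, CtRecord) else float(v) for v in values], dtype=float
        )
        if cts.size < 2:
            raise DegenerateDataError(
                f"reference CV needs >= 2 Ct values in group {group!r}, got {cts.size}"
            )
        cvs[group] = float(100.0 * cts.std(ddof=1) / cts.mean())
    return cvs, all(cv < threshold for cv in cvs.values())
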