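"""Simulation of homozygote DNA-mixture libraries and synthetic qPCR plates.

Mixing gDNA from an AA and an aa homozygote pool at mass ratio r:w produces a
template whose allele-A fraction among locus copies is p = r/(r+w) (both pools
being diploids of the same genome size, mass mixing equals copy mixing). The
standard 13-member library spans p = 1 down to p = 0 and contains surrogates
for every triploid (2:1, 1:2) and tetraploid (3:1, 1:1, 1:3) heterozygote.

Plate synthesis inverts the 2^-ddCt model: each well's Ct is a per-assay
baseline minus log_efficiency(template copies per haploid genome), plus
optional Gaussian cycle noise. Zero-template wells report the instrument's
cycle ceiling (40), which the analysis side maps back to zero through its
limit of detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateDataError
from .genotypes import AllelicConfiguration
from .qpcr import (
    ASSAY_ALLELE_A,
    ASSAY_COMBINED,
    ASSAY_REFERENCE,
    AssayPanel,
    CalibratorSpec,
    CtRecord,
    RelativeDosage,
)

__all__ = [
    "DEFAULT_RATIOS",
    "MixtureDesign",
    "NoiseModel",
    "RegressionSummary",
    "build_mixture_library",
    "simulate_sample_wells",
    "simulate_plate",
    "simulate_library",
    "proportion_dosage_regression",
    "REFERENCE_BASE_CT",
    "ALLELE_BASE_CT",
    "COMBINED_BASE_CT",
    "MAX_CYCLES",
]

#: red(AA) : white(aa) mass ratios of the 13-member library, pure pools included.
DEFAULT_RATIOS: tuple[tuple[int, int], ...] = (
    (1, 0),
    (9, 1),
    (5, 1),
    (3, 1),
    (2, 1),
    (3, 2),
    (1, 1),
    (2, 3),
    (1, 2),
    (1, 3),
    (1, 5),
    (1, 9),
    (0, 1),
)

# Ct synthesis baselines (cycles): Ct of a well whose target occurs once per
# haploid genome, at the plate's common DNA input. Values are arbitrary but
# realistic for 100 ng gDNA input.
REFERENCE_BASE_CT = 20.0
ALLELE_BASE_CT = 22.0
COMBINED_BASE_CT = 22.0
#: Instrument cycle ceiling; zero-template wells report this Ct.
MAX_CYCLES = 40.0


@dataclass(frozen=True)
class MixtureDesign:
    """Ordered list of (red_parts, white_parts) mass ratios."""

    ratios: tuple[tuple[int, int], ...] = DEFAULT_RATIOS

    def __post_init__(self) -> None:
        for r, w in self.ratios:
            if r < 0 or w < 0 or r + w == 0:
                raise ValueError(f"invalid mixing ratio {r}:{w}")


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian per-well Ct noise with a fixed seed for reproducibility."""

    ct_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ct_sd < 0:
            raise ValueError(f"ct_sd must be >= 0, got {self.ct_sd}")


def build_mixture_library(design: MixtureDesign | None = None) -> np.ndarray:
    """Allele-A fractions p = red/(red+white) implied by a mixture design."""
    design = design or MixtureDesign()
    return np.array([r / (r + w) for r, w in design.ratios], dtype=float)


def _well_ct(copies_per_haploid: float, base_ct: float, efficiency: float) -> float:
    if copies_per_haploid <= 0:
        return MAX_CYCLES
    return base_ct - math.log(copies_per_haploid) / math.log(efficiency)


def simulate_sample_wells(
    sample_id: str,
    p: float,
    panel: AssayPanel,
    rng: np.random.Generator,
    ct_sd: float,
    replicates: int,
) -> list[CtRecord]:
    """Synthesize the 3 x replicates wells of one sample with A-fraction *p*.

    Per haploid genome the sample carries p copies of allele A, one copy of
    the combined A/a target and one copy of the reference target.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"allele-A fraction must be in [0, 1], got {p}")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    wells = []
    for assay, copies, base in (
        (ASSAY_REFERENCE, 1.0, REFERENCE_BASE_CT),
        (ASSAY_ALLELE_A, p, ALLELE_BASE_CT),
        (ASSAY_COMBINED, 1.0, COMBINED_BASE_CT),
    ):
        ct0 = _well_ct(copies, base, panel.efficiency)
        for rep in range(1, replicates + 1):
            ct = ct0 + (rng.normal(0.0, ct_sd) if ct_sd > 0 else 0.0)
            wells.append(CtRecord(sample_id, assay, rep, float(ct)))
    return wells


def _as_fraction(p) -> float:
    if isinstance(p, AllelicConfiguration):
        return p.a_fraction
    return float(p)


def simulate_plate(
    p,
    noise: NoiseModel | None = None,
    panel: AssayPanel | None = None,
    replicates: int = 3,
    sample_id: str = "mix",
    calibrator: CalibratorSpec | None = None,
    include_calibrator: bool = True,
) -> list[CtRecord]:
    """Simulate one sample's plate, calibrator wells included.

    *p* may be an allele-A fraction in [0, 1] or an
    :class:`~polydose.genotypes.AllelicConfiguration`. Noise-free plates
    round-trip exactly: feeding the result to
    :func:`~polydose.qpcr.allele_signals` returns b = p.
    """
    noise = noise or NoiseModel()
    panel = panel or AssayPanel()
    calibrator = calibrator or CalibratorSpec.heterozygous_diploid()
    rng = np.random.default_rng(noise.seed)
    records: list[CtRecord] = []
    if include_calibrator:
        records += simulate_sample_wells(
            calibrator.sample_id, calibrator.genotype.a_fraction, panel, rng,
            noise.ct_sd, replicates,
        )
    records += simulate_sample_wells(
        sample_id, _as_fraction(p), panel, rng, noise.ct_sd, replicates
    )
    return records


def simulate_library(
    design: MixtureDesign | None = None,
    noise: NoiseModel | None = None,
    panel: AssayPanel | None = None,
    replicates: int = 3,
    calibrator: CalibratorSpec | None = None,
) -> tuple[list[CtRecord], pd.DataFrame]:
    """Simulate the full mixture library on one plate.

    Returns the plate records (calibrator wells first) and a truth table with
    one row per mixture: sample_id, red_parts, white_parts, a_fraction.
    """
    design = design or MixtureDesign()
    noise = noise or NoiseModel()
    panel = panel or AssayPanel()
    calibrator = calibrator or CalibratorSpec.heterozygous_diploid()
    rng = np.random.default_rng(noise.seed)
    records = simulate_sample_wells(
        calibrator.sample_id, calibrator.genotype.a_fraction, panel, rng,
        noise.ct_sd, replicates,
    )
    truth_rows = []
    for r, w in design.ratios:
        p = r / (r + w)
        sid = f"mix_{r}_{w}"
        records += simulate_sample_wells(sid, p, panel, rng, noise.ct_sd, replicates)
        truth_rows.append(
            {"sample_id": sid, "red_parts": r, "white_parts": w, "a_fraction": p}
        )
    return records, pd.DataFrame(truth_rows)


@dataclass(frozen=True)
class RegressionSummary:
    """OLS fits of b and theta against the known allele-A fraction."""

    slope_b: float
    intercept_b: float
    r_squared_b: float
    slope_theta: float
    intercept_theta: float
    r_squared_theta: float
    table: pd.DataFrame = field(repr=False)


def proportion_dosage_regression(
    library_results: Sequence[RelativeDosage],
    fractions: Sequence[float],
) -> RegressionSummary:
    """Regress measured b (and theta) on the known allele-A fractions.

    R-squared is the squared Pearson correlation of each OLS fit. The b fit is
    expected to be essentially the identity; theta responds nonlinearly
    (arctan), so its linear R-squared stays below 1 even without noise.
    """
    if len(library_results) != len(fractions):
        raise ValueError("library_results and fractions must have equal length")
    if len(fractions) < 3:
        raise DegenerateDataError("regression needs at least 3 points")
    p = np.asarray(fractions, dtype=float)
    if np.allclose(p, p[0]):
        raise DegenerateDataError("allele-A fractions are constant; cannot regress")
    b = np.array([d.b for d in library_results], dtype=float)
    theta = np.array([d.theta for d in library_results], dtype=float)
    fit_b = stats.linregress(p, b)
    fit_t = stats.linregress(p, theta)
    table = pd.DataFrame(
        {
            "a_fraction": p,
            "a1": [d.a1 for d in library_results],
            "a2": [d.a2 for d in library_results],
            "b": b,
            "theta": theta,
        }
    )
    return RegressionSummary(
        slope_b=float(fit_b.slope),
        intercept_b=float(fit_b.intercept),
        r_squared_b=float(fit_b.rvalue**2),
        slope_theta=float(fit_t.slope),
        intercept_theta=float(fit_t.intercept),
        r_squared_theta=float(fit_t.rvalue**2),
        table=table,
    )
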