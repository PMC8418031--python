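"""Modelling front end: build from data, fit, inspect results.

Two model classes mirror the two halves of the workflow:

* :class:`DosageGenotyper` turns a qPCR plate plus a sample sheet into
  calibrated relative allele dosages and genotype calls
  (:class:`GenotypingResults`).
* :class:`SegregationAnalysis` turns per-cross observed phenotype counts into
  model-derived expected ratios and chi-square goodness-of-fit tests
  (:class:`SegregationResults`).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError, PolydoseError
from .genotypes import (
    AllelicConfiguration,
    AnovaResult,
    SeparationReport,
    anova_separation,
    call_genotype,
    separation_report,
)
from .io import RunConfig, read_crosses, read_plate, read_samples, write_table
from .qpcr import (
    ASSAY_ALLELE_A,
    ASSAY_COMBINED,
    ASSAY_REFERENCE,
    AssayPanel,
    CalibratorSpec,
    CtRecord,
    allele_signals,
    dosage_from_signals,
    reference_stability,
    relative_quantity,
)
from .segregation import segregation_table

__all__ = [
    "DosageGenotyper",
    "GenotypingResults",
    "SegregationAnalysis",
    "SegregationResults",
]


class DosageGenotyper:
    """Allele-dosage genotyping model for one qPCR run.

    Parameters
    ----------
    plate : sequence of CtRecord
        All wells of the run (samples and calibrator).
    samples : DataFrame
        Sample sheet with columns sample_id, ploidy, role, known_genotype;
        exactly one row must have role ``calibrator`` with a known genotype.
    config : RunConfig, optional
        Assay panel, thresholds and tolerances.
    """

    def __init__(
        self,
        plate: Sequence[CtRecord],
        samples: pd.DataFrame,
        config: RunConfig | None = None,
    ):
        self.plate = list(plate)
        self.samples = samples.reset_index(drop=True)
        self.config = config or RunConfig()
        self.panel: AssayPanel = self.config.panel()
        cal_rows = self.samples[self.samples["role"] == "calibrator"]
        if len(cal_rows) != 1:
            raise PolydoseError(
                f"sample sheet must contain exactly one calibrator, found {len(cal_rows)}"
            )
        row = cal_rows.iloc[0]
        if not row["known_genotype"]:
            raise PolydoseError("the calibrator needs a known_genotype")
        self.calibrator = CalibratorSpec(
            sample_id=row["sample_id"],
            genotype=AllelicConfiguration.from_string(
                row["known_genotype"], ploidy=int(row["ploidy"])
            ),
            ploidy=int(row["ploidy"]),
        )

    @classmethod
    def from_files(
        cls, plate_path, samples_path, config: RunConfig | None = None
    ) -> "DosageGenotyper":
        return cls(read_plate(plate_path), read_samples(samples_path), config=config)

    def _wells(self, sample_id: str) -> list[CtRecord]:
        return [r for r in self.plate if r.sample_id == sample_id]

    def _replicate_bs(
        self, sample_cts: list[CtRecord], calibrator_cts: list[CtRecord]
    ) -> list[float]:
        """Per-replicate b values (calibrator kept at its replicate mean)."""
        reps = sorted(
            set.intersection(
                *(
                    {r.replicate for r in sample_cts if r.assay == assay}
                    for assay in (ASSAY_REFERENCE, ASSAY_ALLELE_A, ASSAY_COMBINED)
                )
            )
        )
        out = []
        for rep in reps:
            subset = [r for r in sample_cts if r.replicate == rep]
            rq_a = relative_quantity(subset, calibrator_cts, ASSAY_ALLELE_A, self.panel)
            rq_c = relative_quantity(subset, calibrator_cts, ASSAY_COMBINED, self.panel)
            if rq_a < self.config.lod:
                rq_a = 0.0
            if rq_c < self.config.lod:
                rq_c = 0.0
            a1 = 2.0 * rq_a * self.calibrator.genotype.n_dominant / self.calibrator.ploidy
            d = dosage_from_signals(subset[0].sample_id, a1, 2.0 * rq_c)
            out.append(d.b)
        return out

    def fit(self) -> "GenotypingResults":
        """Compute dosages and call genotypes for every non-calibrator sample."""
        calibrator_cts = self._wells(self.calibrator.sample_id)
        if not calibrator_cts:
            raise PolydoseError(
                f"plate has no wells for calibrator {self.calibrator.sample_id!r}"
            )
        rows = []
        ref_by_ploidy: dict[int, list[float]] = {}
        for rec in self.samples.itertuples(index=False):
            wells = self._wells(rec.sample_id)
            if rec.role == "calibrator":
                for w in wells:
                    if w.assay == ASSAY_REFERENCE:
                        ref_by_ploidy.setdefault(int(rec.ploidy), []).append(w.ct)
                continue
            dosage = allele_signals(
                wells, self.calibrator, calibrator_cts, self.panel, lod=self.config.lod
            )
            rep_bs = self._replicate_bs(wells, calibrator_cts)
            b_sd = float(np.std(rep_bs, ddof=1)) if len(rep_bs) >= 2 else np.nan
            call = call_genotype(
                dosage.b, int(rec.ploidy), sample_id=rec.sample_id,
                tie_tol=self.config.tie_tol,
            )
            known = rec.known_genotype or ""
            rows.append(
                {
                    "sample_id": rec.sample_id,
                    "ploidy": int(rec.ploidy),
                    "a1": dosage.a1,
                    "a2": dosage.a2,
                    "a3": dosage.a3,
                    "b": dosage.b,
                    "b_sd": b_sd,
                    "theta": dosage.theta,
                    "genotype": call.configuration.label,
                    "expected_b": call.expected_b,
                    "residual": call.residual,
                    "ambiguous": call.ambiguous,
                    "known_genotype": known,
                    "concordant": (call.configuration.label == known) if known else pd.NA,
                    "flags": ";".join(dosage.flags),
                }
            )
            for w in wells:
                if w.assay == ASSAY_REFERENCE:
                    ref_by_ploidy.setdefault(int(rec.ploidy), []).append(w.ct)
        table = pd.DataFrame(rows)
        groups = {k: v for k, v in ref_by_ploidy.items() if len(v) >= 2}
        if groups:
            ref_cv, ref_ok = reference_stability(
                groups, threshold=self.config.reference_cv_threshold
            )
        else:  # pragma: no cover - single-well runs
            ref_cv, ref_ok = {}, True
        return GenotypingResults(self, table, ref_cv, ref_ok)


class GenotypingResults:
    """Fitted dosages, genotype calls and diagnostics for one run."""

    def __init__(
        self,
        model: DosageGenotyper,
        table: pd.DataFrame,
        reference_cv: dict,
        reference_cv_ok: bool,
    ):
        self.model = model
        self.table = table
        self.reference_cv = reference_cv
        self.reference_cv_ok = reference_cv_ok

    @property
    def n_samples(self) -> int:
        return len(self.table)

    @property
    def concordance(self) -> float:
        """Fraction of samples with known genotype whose call matches it."""
        known = self.table["concordant"].dropna()
        if known.empty:
            return float("nan")
        return float(known.mean())

    def anova(self, ploidy: int | None = None) -> AnovaResult:
        """One-way ANOVA of b across called genotype classes."""
        sub = self.table if ploidy is None else self.table[self.table["ploidy"] == ploidy]
        groups = {
            g: v["b"].to_numpy() for g, v in sub.groupby("genotype") if len(v) >= 2
        }
        if len(groups) < 2:
            raise DegenerateDataError(
                "need >= 2 genotype classes with >= 2 samples each for ANOVA"
            )
        return anova_separation(groups)

    def cluster(self, n_classes: int, ploidy: int | None = None) -> SeparationReport:
        """Complete-linkage clustering diagnostics of the b values."""
        sub = self.table if ploidy is None else self.table[self.table["ploidy"] == ploidy]
        return separation_report(sub["b"].to_numpy(), n_classes)

    def summary(self) -> str:
        cv = ", ".join(f"{k}x: {v:.2f}%" for k, v in sorted(self.reference_cv.items()))
        cols = [
            "sample_id", "ploidy", "a1", "a2", "b", "b_sd", "theta",
            "genotype", "residual", "ambiguous", "flags",
        ]
        body = self.table[cols].to_string(
            index=False, float_format=lambda x: f"{x:.4f}",
        )
        lines = [
            "Allele dosage genotyping",
            "========================",
            f"samples: {self.n_samples}    calibrator: {self.model.calibrator.sample_id} "
            f"({self.model.calibrator.genotype.label})",
            f"reference CV by ploidy: {cv or 'n/a'}   "
            f"(all < {self.model.config.reference_cv_threshold:g}%: "
            f"{'yes' if self.reference_cv_ok else 'NO'})",
        ]
        known = self.table["concordant"].dropna()
        if not known.empty:
            lines.append(
                f"concordance with known genotypes: {100 * self.concordance:.1f}% "
                f"({int(known.sum())}/{len(known)})"
            )
        lines += ["", body]
        return "\n".join(lines)

    def to_csv(self, path, seed: int | None = None) -> None:
        write_table(self.table, path, seed=seed, config=self.model.config.as_dict())

    def to_json(self, path) -> None:
        self.table.to_json(path, orient="records", indent=2)

    def plot_dosages(self, ax=None):
        """Scatter of b per sample, grouped by ploidy, with class grid lines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        for ploidy, sub in self.table.groupby("ploidy"):
            ax.scatter([ploidy] * len(sub), sub["b"], label=f"{ploidy}x", alpha=0.7)
            for k in range(ploidy + 1):
                ax.hlines(k / ploidy, ploidy - 0.2, ploidy + 0.2,
                          colors="grey", linestyles=":", linewidth=0.8)
        ax.set_xlabel("ploidy")
        ax.set_ylabel("relative allele-A signal b")
        ax.legend(title="ploidy")
        return ax


class SegregationAnalysis:
    """Mendelian segregation analysis of dominant/recessive phenotype counts."""

    def __init__(self, crosses: pd.DataFrame):
        self.crosses = pd.DataFrame(crosses).reset_index(drop=True)

    @classmethod
    def from_files(cls, crosses_path) -> "SegregationAnalysis":
        return cls(read_crosses(crosses_path))

    def fit(self) -> "SegregationResults":
        return SegregationResults(self, segregation_table(self.crosses))


class SegregationResults:
    """Per-class expected ratios, chi-square statistics and pooled totals."""

    def __init__(self, model: SegregationAnalysis, table: pd.DataFrame):
        self.model = model
        self.table = table

    def summary(self) -> str:
        disp = self.table.copy()
        disp["chi2"] = disp["chi2"].map(
            lambda x: "/" if pd.isna(x) else ("inf" if np.isinf(x) else f"{x:.2f}")
        )
        disp["p"] = disp["p"].map(lambda x: "/" if pd.isna(x) else f"{x:.2f}")
        cols = [
            "cross", "ploidy_class", "observed_red", "observed_white",
            "observed_ratio", "expected_ratio", "chi2", "p", "flags",
        ]
        n_tested = self.table["chi2"].notna().sum()
        ok = (self.table["chi2"].dropna() < 3.84).sum()
        return "\n".join(
            [
                "Flesh color segregation (polysomic model, Pearson chi-square, df=1)",
                "====================================================================",
                f"classes tested: {n_tested}   chi2 < 3.84 (P > 0.05): {ok}",
                "",
                disp[cols].to_string(index=False),
            ]
        )

    def to_csv(self, path, seed: int | None = None) -> None:
        write_table(self.table, path, seed=seed)

    def to_json(self, path) -> None:
        self.table.replace([np.inf], "inf").to_json(path, orient="records", indent=2)
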