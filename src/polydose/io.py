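"""File parsing/writing, run configuration and synthetic fixture generation.

All three schemas are plain delimited text (comma by default, tab
auto-detected), UTF-8, header required, ``#`` comment lines allowed at the
top. Every file the package writes starts with a provenance header (tool
version, config hash, seed) and is byte-identical across reruns with the same
inputs.

Schemas
-------
plate:   sample_id, assay, replicate, ct          (assay in {reference, allele_A, combined})
samples: sample_id, ploidy, role, known_genotype  (role in {calibrator, unknown, control})
crosses: cross, female_genotype, male_genotype, progeny_ploidy, observed_red, observed_white
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .exceptions import ParseError, InvalidGenotypeError
from .genotypes import AllelicConfiguration
from .mixture import NoiseModel, simulate_sample_wells
from .qpcr import VALID_ASSAYS, AssayPanel, CtRecord, DEFAULT_LOD

__all__ = [
    "PLATE_COLUMNS",
    "SAMPLE_COLUMNS",
    "CROSS_COLUMNS",
    "SAMPLE_ROLES",
    "RunConfig",
    "FixtureSpec",
    "read_plate",
    "read_samples",
    "read_crosses",
    "write_plate",
    "write_table",
    "default_roster",
    "generate_fixture",
    "config_hash",
]

PLATE_COLUMNS = ("sample_id", "assay", "replicate", "ct")
SAMPLE_COLUMNS = ("sample_id", "ploidy", "role", "known_genotype")
CROSS_COLUMNS = (
    "cross",
    "female_genotype",
    "male_genotype",
    "progeny_ploidy",
    "observed_red",
    "observed_white",
)
SAMPLE_ROLES = frozenset({"calibrator", "unknown", "control"})


@dataclass(frozen=True)
class RunConfig:
    """Analysis settings shared across commands."""

    reference_name: str = "CH03g12"
    allele_A_name: str = "q2A"
    combined_name: str = "q2A/2Ad"
    efficiency: float = 2.0
    ct_sd: float = 0.05
    reference_cv_threshold: float = 3.0
    tie_tol: float = 1e-9
    lod: float = DEFAULT_LOD
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("reference_cv_threshold", "tie_tol", "lod"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def panel(self) -> AssayPanel:
        return AssayPanel(
            reference_name=self.reference_name,
            allele_A_name=self.allele_A_name,
            combined_name=self.combined_name,
            efficiency=self.efficiency,
        )

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ParseError("config file must be a flat key: value mapping", str(path))
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ParseError(f"unknown config keys: {sorted(unknown)}", str(path))
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)


def config_hash(config: Mapping | RunConfig | None) -> str:
    """Short stable hash of a configuration mapping."""
    if config is None:
        payload: Mapping = {}
    elif isinstance(config, RunConfig):
        payload = config.as_dict()
    else:
        payload = dict(config)
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# reading


def _sniff(path: Path) -> tuple[str, int]:
    """Return (separator, number of leading comment lines)."""
    n_comments = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                n_comments += 1
                continue
            if "\t" in line and "," not in line:
                return "\t", n_comments
            return ",", n_comments
    raise ParseError("file is empty", str(path))


def _read_frame(path: str | Path, columns: Sequence[str], optional: Sequence[str] = ()) -> tuple[pd.DataFrame, int]:
    path = Path(path)
    if not path.exists():
        raise ParseError("file does not exist", str(path))
    sep, n_comments = _sniff(path)
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    missing = set(columns) - set(optional) - set(df.columns)
    if missing:
        raise ParseError(f"missing required columns: {sorted(missing)}", str(path))
    # 1-based line of the first data row (header sits right after comments)
    return df, n_comments + 2


def _to_number(value: str, kind: str, path: str, line: int, column: str) -> float:
    try:
        x = float(value)
    except (TypeError, ValueError):
        raise ParseError(f"non-numeric {column} value {value!r}", path, line) from None
    if not math.isfinite(x):
        raise ParseError(f"non-finite {column} value {value!r}", path, line)
    if kind == "int":
        if x != int(x):
            raise ParseError(f"{column} must be an integer, got {value!r}", path, line)
        return int(x)
    return x


def read_plate(path: str | Path) -> list[CtRecord]:
    """Parse a qPCR plate file into validated :class:`CtRecord` objects."""
    df, first_line = _read_frame(path, PLATE_COLUMNS)
    records: list[CtRecord] = []
    seen: dict[tuple, int] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        line = first_line + i
        assay = row.assay.strip()
        if assay not in VALID_ASSAYS:
            raise ParseError(
                f"unknown assay label {assay!r} (expected one of {sorted(VALID_ASSAYS)})",
                str(path), line,
            )
        rep = int(_to_number(row.replicate, "int", str(path), line, "replicate"))
        ct = _to_number(row.ct, "float", str(path), line, "ct")
        key = (row.sample_id.strip(), assay, rep)
        if key in seen:
            raise ParseError(
                f"duplicate well {key} (first seen on line {seen[key]})", str(path), line
            )
        seen[key] = line
        try:
            records.append(CtRecord(key[0], assay, rep, ct))
        except ValueError as exc:
            raise ParseError(str(exc), str(path), line) from None
    return records


def read_samples(path: str | Path) -> pd.DataFrame:
    """Parse a sample sheet; genotype strings are canonicalized (AaAa -> AAaa)."""
    df, first_line = _read_frame(path, SAMPLE_COLUMNS, optional=("known_genotype",))
    if "known_genotype" not in df.columns:
        df["known_genotype"] = ""
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = first_line + i
        ploidy = int(_to_number(row.ploidy, "int", str(path), line, "ploidy"))
        if ploidy < 1:
            raise ParseError(f"ploidy must be >= 1, got {ploidy}", str(path), line)
        role = row.role.strip()
        if role not in SAMPLE_ROLES:
            raise ParseError(
                f"unknown role {role!r} (expected one of {sorted(SAMPLE_ROLES)})",
                str(path), line,
            )
        genotype = row.known_genotype.strip()
        if genotype:
            try:
                genotype = AllelicConfiguration.from_string(genotype, ploidy=ploidy).label
            except InvalidGenotypeError as exc:
                raise ParseError(str(exc), str(path), line) from None
        out.append(
            {
                "sample_id": row.sample_id.strip(),
                "ploidy": ploidy,
                "role": role,
                "known_genotype": genotype,
            }
        )
    return pd.DataFrame(out, columns=list(SAMPLE_COLUMNS))


def read_crosses(path: str | Path) -> pd.DataFrame:
    """Parse a cross file with observed red/white counts per progeny class."""
    df, first_line = _read_frame(path, CROSS_COLUMNS)
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = first_line + i
        try:
            female = AllelicConfiguration.from_string(row.female_genotype).label
            male = AllelicConfiguration.from_string(row.male_genotype).label
        except InvalidGenotypeError as exc:
            raise ParseError(str(exc), str(path), line) from None
        out.append(
            {
                "cross": row.cross.strip(),
                "female_genotype": female,
                "male_genotype": male,
                "progeny_ploidy": int(
                    _to_number(row.progeny_ploidy, "int", str(path), line, "progeny_ploidy")
                ),
                "observed_red": int(
                    _to_number(row.observed_red, "int", str(path), line, "observed_red")
                ),
                "observed_white": int(
                    _to_number(row.observed_white, "int", str(path), line, "observed_white")
                ),
            }
        )
    return pd.DataFrame(out, columns=list(CROSS_COLUMNS))


# ---------------------------------------------------------------------------
# writing


def _provenance(seed: int | None, config) -> str:
    return (
        f"# polydose {__version__}\n"
        f"# config_hash={config_hash(config)}\n"
        f"# seed={'none' if seed is None else seed}\n"
    )


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    config=None,
    float_format: str = "%.6g",
) -> Path:
    """Write a DataFrame as CSV with the provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_provenance(seed, config))
        df.to_csv(fh, index=False, float_format=float_format)
    return path


def write_plate(
    records: Sequence[CtRecord],
    path: str | Path,
    seed: int | None = None,
    config=None,
) -> Path:
    """Write CtRecords as a plate file (ct to 4 decimals, lossless to parse)."""
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "assay": [r.assay for r in records],
            "replicate": [r.replicate for r in records],
            "ct": [f"{r.ct:.4f}" for r in records],
        }
    )
    return write_table(df, path, seed=seed, config=config)


# ---------------------------------------------------------------------------
# fixtures


def default_roster() -> tuple[tuple[str, int, str], ...]:
    """Default fixture roster mirroring the published germplasm panel.

    8 tetraploids and 14 triploids with their marker-confirmed genotypes, plus
    one diploid of each dosage class.
    """
    from .datasets import polyploid_panel

    panel = polyploid_panel()
    roster = [
        (row.sample_id, int(row.ploidy), row.genotype)
        for row in panel.itertuples(index=False)
    ]
    roster += [("LQ1", 2, "AA"), ("ZZ6", 2, "Aa"), ("GF", 2, "aa")]
    return tuple(roster)


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic genotyping run (plate + sample sheet + truth)."""

    roster: tuple[tuple[str, int, str], ...] = field(default_factory=default_roster)
    replicates: int = 3
    ct_sd: float = 0.05
    seed: int = 0
    calibrator_id: str = "CAL_Aa"

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for sample_id, ploidy, genotype in self.roster:
            AllelicConfiguration.from_string(genotype, ploidy=ploidy)  # validates


def generate_fixture(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Write a seeded, reproducible synthetic plate, sample sheet and truth table.

    Returns the paths under keys ``plate``, ``samples``, ``truth``. The default
    noise (ct_sd = 0.05 cycles) keeps reference-assay CVs well under the 3%
    stability bound.
    """
    outdir = Path(outdir)
    rng = np.random.default_rng(spec.seed)
    panel = AssayPanel()
    records = simulate_sample_wells(
        spec.calibrator_id, 0.5, panel, rng, spec.ct_sd, spec.replicates
    )
    sample_rows = [
        {"sample_id": spec.calibrator_id, "ploidy": 2, "role": "calibrator",
         "known_genotype": "Aa"}
    ]
    truth_rows = []
    for sample_id, ploidy, genotype in spec.roster:
        config = AllelicConfiguration.from_string(genotype, ploidy=ploidy)
        records += simulate_sample_wells(
            sample_id, config.a_fraction, panel, rng, spec.ct_sd, spec.replicates
        )
        sample_rows.append(
            {"sample_id": sample_id, "ploidy": ploidy, "role": "unknown",
             "known_genotype": config.label}
        )
        truth_rows.append(
            {"sample_id": sample_id, "ploidy": ploidy, "genotype": config.label,
             "a_fraction": config.a_fraction}
        )
    cfg = dataclasses.asdict(spec)
    paths = {
        "plate": write_plate(records, outdir / "plate.csv", seed=spec.seed, config=cfg),
        "samples": write_table(
            pd.DataFrame(sample_rows), outdir / "samples.csv", seed=spec.seed, config=cfg
        ),
        "truth": write_table(
            pd.DataFrame(truth_rows), outdir / "truth.csv", seed=spec.seed, config=cfg
        ),
    }
    return paths
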