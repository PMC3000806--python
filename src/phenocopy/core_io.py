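"""Study data model, file formats and run configuration.

The central container is :class:`ExpressionStudy`: a genes x samples matrix of
log2 intensities plus one :class:`SampleRecord` per column describing the
experimental cell it came from (compound, concentration, time, +/- stimulus,
modulator type, replicate).  Every downstream stage — contrasts, signatures,
enrichment, ranking — selects sample groups through this design table, so the
readers here validate it strictly and fail loudly on inconsistencies.

Formats are deliberately plain: TSV expression matrix (gene IDs in the first
column), CSV design table with exactly the ``SampleRecord`` field names as
header, GMT gene-set collections, and a flat YAML run configuration.
Gene identifiers are opaque case-sensitive strings; no probe/symbol mapping is
attempted and missing values are rejected.
"""

from __future__ import annotations

import csv
import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SampleRecord",
    "ExpressionStudy",
    "GeneSet",
    "AnalysisConfig",
    "read_study",
    "write_study",
    "read_gmt",
    "write_gmt",
    "quantile_normalize",
    "load_config",
    "save_config",
    "get_logger",
]

MODULATORS = ("nce", "sirna", "none")
VEHICLES = ("dmso", "transfection", "none")

_DESIGN_FIELDS = (
    "sample_id",
    "modulator",
    "compound_id",
    "concentration_uM",
    "time_h",
    "stimulated",
    "vehicle",
    "replicate",
)


def get_logger(name: str = "phenocopy") -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


log = get_logger(__name__)


@dataclass(frozen=True)
class SampleRecord:
    """Annotation of one array/column of the expression matrix."""

    sample_id: str
    modulator: str  # nce | sirna | none
    compound_id: str | None
    concentration_uM: float | None
    time_h: float
    stimulated: bool
    vehicle: str  # dmso | transfection | none
    replicate: int

    def __post_init__(self) -> None:
        if self.modulator not in MODULATORS:
            raise ValueError(f"sample {self.sample_id!r}: unknown modulator {self.modulator!r}")
        if self.vehicle not in VEHICLES:
            raise ValueError(f"sample {self.sample_id!r}: unknown vehicle {self.vehicle!r}")
        if self.modulator == "nce":
            if self.compound_id is None or self.concentration_uM is None:
                raise ValueError(
                    f"sample {self.sample_id!r}: modulator 'nce' requires compound_id "
                    "and concentration_uM"
                )
        if self.modulator == "none" and self.compound_id is not None:
            raise ValueError(
                f"sample {self.sample_id!r}: modulator 'none' must not carry a compound_id"
            )
        if self.concentration_uM is not None and self.concentration_uM < 0:
            raise ValueError(f"sample {self.sample_id!r}: negative concentration")
        if self.time_h <= 0:
            raise ValueError(f"sample {self.sample_id!r}: time_h must be positive")
        if self.replicate < 1:
            raise ValueError(f"sample {self.sample_id!r}: replicate must be >= 1")

    def matches(self, **criteria) -> bool:
        """True if every criterion matches; values may be scalars or predicates."""
        for key, want in criteria.items():
            have = getattr(self, key)
            if callable(want):
                if not want(have):
                    return False
            elif isinstance(have, float) and isinstance(want, (int, float)):
                if not math.isclose(have, float(want), rel_tol=1e-9, abs_tol=1e-12):
                    return False
            elif have != want:
                return False
        return True


@dataclass
class ExpressionStudy:
    """Log2 expression matrix (genes x samples) plus its sample design."""

    genes: list[str]
    samples: list[SampleRecord]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        dup = _duplicates(self.genes)
        if dup:
            raise ValueError(f"duplicate gene IDs: {sorted(dup)}")
        dup = _duplicates([s.sample_id for s in self.samples])
        if dup:
            raise ValueError(f"duplicate sample IDs: {sorted(dup)}")
        if np.isnan(self.values).any():
            g, s = map(int, np.argwhere(np.isnan(self.values))[0])
            raise ValueError(
                f"missing value in matrix at gene {self.genes[g]!r}, "
                f"sample {self.samples[s].sample_id!r}"
            )

    # -- selection -----------------------------------------------------
    def select(self, **criteria) -> np.ndarray:
        """Column indices of samples matching the criteria (see SampleRecord.matches)."""
        return np.array(
            [i for i, s in enumerate(self.samples) if s.matches(**criteria)], dtype=int
        )

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def compounds(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            if s.modulator == "nce" and s.compound_id is not None:
                seen.setdefault(s.compound_id, None)
        return list(seen)

    def times(self) -> list[float]:
        return sorted({s.time_h for s in self.samples})

    def nce_concentrations(self) -> list[float]:
        return sorted({s.concentration_uM for s in self.samples if s.modulator == "nce"})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.genes, columns=[s.sample_id for s in self.samples]
        )

    def design_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(s) for s in self.samples])


def _duplicates(items: Sequence) -> set:
    seen, dup = set(), set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


# ---------------------------------------------------------------------------
# Study reader / writer


def read_study(matrix_path: str | Path, design_path: str | Path) -> ExpressionStudy:
    """Read a TSV expression matrix and CSV design table into an ExpressionStudy.

    The matrix's first column holds gene IDs; remaining columns are named by
    sample_id and every one of them must be covered by the design table.
    Column order of the matrix is preserved.
    """
    matrix_path, design_path = Path(matrix_path), Path(design_path)
    frame = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    genes = [str(g) for g in frame.index]
    dup = _duplicates(genes)
    if dup:
        raise ValueError(f"{matrix_path}: duplicate gene IDs: {sorted(dup)}")

    values = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        try:
            # str -> float via numpy's strtod: bit-exact round trip
            values[:, j] = np.asarray(frame[col], dtype=np.float64)
        except (ValueError, TypeError):
            bad = frame[col][pd.to_numeric(frame[col], errors="coerce").isna()]
            gene = bad.index[0]
            raise ValueError(
                f"{matrix_path}: non-numeric value {bad.iloc[0]!r} at gene {gene!r}, "
                f"sample {col!r}"
            ) from None
    if np.isnan(values).any():
        g, s = map(int, np.argwhere(np.isnan(values))[0])
        raise ValueError(
            f"{matrix_path}: missing value at gene {genes[g]!r}, sample {frame.columns[s]!r}"
        )

    records = _read_design(design_path)
    by_id = {r.sample_id: r for r in records}
    missing = [c for c in frame.columns if c not in by_id]
    if missing:
        raise ValueError(f"{design_path}: samples missing from design: {missing}")
    samples = [by_id[c] for c in frame.columns]
    study = ExpressionStudy(genes=genes, samples=samples, values=values)
    log.info(
        "read_study: %d genes x %d samples from %s", study.n_genes, study.n_samples, matrix_path
    )
    return study


def _read_design(design_path: Path) -> list[SampleRecord]:
    with open(design_path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(_DESIGN_FIELDS) - set(reader.fieldnames):
            missing = set(_DESIGN_FIELDS) - set(reader.fieldnames or [])
            raise ValueError(f"{design_path}: design header missing fields {sorted(missing)}")
        records = []
        for line, row in enumerate(reader, start=2):
            try:
                records.append(
                    SampleRecord(
                        sample_id=row["sample_id"],
                        modulator=row["modulator"],
                        compound_id=row["compound_id"] or None,
                        concentration_uM=(
                            float(row["concentration_uM"]) if row["concentration_uM"] else None
                        ),
                        time_h=float(row["time_h"]),
                        stimulated=_parse_bool(row["stimulated"]),
                        vehicle=row["vehicle"],
                        replicate=int(row["replicate"]),
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{design_path}:{line}: {exc}") from None
    dup = _duplicates([r.sample_id for r in records])
    if dup:
        raise ValueError(f"{design_path}: duplicate sample IDs: {sorted(dup)}")
    return records


def _parse_bool(text: str) -> bool:
    if text in ("1", "true", "True", "TRUE"):
        return True
    if text in ("0", "false", "False", "FALSE"):
        return False
    raise ValueError(f"cannot parse boolean {text!r}")


def write_study(study: ExpressionStudy, matrix_path: str | Path, design_path: str | Path) -> None:
    """Write matrix TSV + design CSV such that read_study round-trips losslessly."""
    frame = study.to_frame()
    # repr() of a float round-trips bit-exactly through float()
    with open(matrix_path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(frame.columns) + "\n")
        for i, gene in enumerate(study.genes):
            fh.write(gene + "\t" + "\t".join(repr(float(v)) for v in study.values[i]) + "\n")
    with open(design_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_DESIGN_FIELDS)
        for s in study.samples:
            writer.writerow(
                [
                    s.sample_id,
                    s.modulator,
                    s.compound_id or "",
                    "" if s.concentration_uM is None else repr(float(s.concentration_uM)),
                    repr(float(s.time_h)),
                    int(s.stimulated),
                    s.vehicle,
                    s.replicate,
                ]
            )


# ---------------------------------------------------------------------------
# Gene sets (GMT)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: name TAB description TAB member...

    Duplicate members within one set are deduplicated (first occurrence kept)
    with a logged warning; a line with fewer than three fields is an error.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, raw = fields[0], fields[1], [f for f in fields[2:] if f]
            members = list(dict.fromkeys(raw))
            if len(members) < len(raw):
                log.warning(
                    "read_gmt: set %r line %d: %d duplicate member(s) removed",
                    name, lineno, len(raw) - len(members),
                )
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets.append(GeneSet(name=name, description=desc, members=tuple(members)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


# ---------------------------------------------------------------------------
# Quantile normalization (convenience; inputs are normally pre-normalized log2)


def quantile_normalize(matrix):
    """Force identical column distributions (row-wise mean of sorted columns).

    Accepts an ndarray or DataFrame and returns the same type.  A single-column
    input is returned unchanged with a warning.  Ties share the mean of their
    would-be quantiles (average-rank convention).
    """
    frame = isinstance(matrix, pd.DataFrame)
    x = matrix.to_numpy(dtype=float) if frame else np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("quantile_normalize expects a 2-D matrix")
    if x.shape[1] < 2:
        log.warning("quantile_normalize: single column, returning input unchanged")
        return matrix
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        ranked = np.empty_like(ref)
        ranked[order] = ref
        # average reference values over tied observations
        uniq, inv = np.unique(col, return_inverse=True)
        if len(uniq) < len(col):
            sums = np.bincount(inv, weights=ranked)
            counts = np.bincount(inv)
            ranked = (sums / counts)[inv]
        out[:, j] = ranked
    if frame:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class AnalysisConfig:
    """Thresholds and knobs shared by the signature pipeline.

    alpha: significance threshold on BH-adjusted p-values.
    lr_min: absolute log2-ratio threshold for up/down calls (off-target rule).
    on_target_lr_min: |LR| threshold for the stimulation filter; the on-target
        derivation is significance-driven so this defaults to 0.
    offtarget_concentrations_uM: the two concentrations at which unstimulated
        compound arms exist and off-target membership is decided.
    enrichment_threshold: -log10 p cutoff for calling a gene set significant.
    permutations_B: Monte-Carlo permutations for the dose-trend test.
    """

    alpha: float = 0.01
    lr_min: float = 1.0
    on_target_lr_min: float = 0.0
    offtarget_concentrations_uM: tuple[float, ...] = (0.08, 2.0)
    enrichment_threshold: float = 2.0
    permutations_B: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.lr_min < 0 or self.on_target_lr_min < 0:
            raise ValueError("lr_min must be >= 0")
        if self.permutations_B < 99:
            raise ValueError("permutations_B must be >= 99")
        self.offtarget_concentrations_uM = tuple(
            sorted(float(c) for c in self.offtarget_concentrations_uM)
        )

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def load_config(path: str | Path) -> AnalysisConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return AnalysisConfig(**data)


def save_config(config: AnalysisConfig, path: str | Path) -> None:
    data = dataclasses.asdict(config)
    data["offtarget_concentrations_uM"] = list(config.offtarget_concentrations_uM)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
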