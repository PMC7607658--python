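"""Domain types and tab-separated readers/writers.

All tabular files are TSV, UTF-8, ``.`` decimal separator and ``NA`` for
missing values. Coordinates are 1-based inclusive. Validation errors always
name the offending row or cell.
"""

from __future__ import annotations

import hashlib
import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import yaml

from methdrift.errors import FormatError, ValidationError

logger = logging.getLogger("methdrift")

NA = "NA"

TIMEPOINTS = ("t1", "t2")
LOCATIONS = ("proximal", "distal")
ASPIRIN_LEVELS = ("nonuser", "long_term_user")
REGION_CLASSES = ("promoter", "enhancer", "weak_transcription", "other")
CGI_STATUSES = ("island", "non_island")
GENE_FLAGS = ("TSG", "oncogene", "epigenetic_regulator")


@contextmanager
def stage_timer(stage: str, **counts) -> Iterator[None]:
    """Log one structured line per pipeline stage with wall time and counts."""
    t0 = time.perf_counter()
    yield
    extra = " ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("stage=%s wall_s=%.3f %s", stage, time.perf_counter() - t0, extra)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    for i, x in enumerate(ids):
        if x in seen:
            raise FormatError(f"duplicate {what} {x!r} at positions {seen[x]} and {i}")
        seen[x] = i


# ---------------------------------------------------------------------------
# BetaMatrix
# ---------------------------------------------------------------------------


@dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation fractions in [0, 1].

    Missing entries are carried as NaN; they are never imputed at this layer.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        _check_unique(self.probe_ids, "probe id")
        _check_unique(self.sample_ids, "sample id")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"({len(self.probe_ids)} probes, {len(self.sample_ids)} samples)"
            )
        bad = np.where(~np.isnan(self.values) & ((self.values < 0) | (self.values > 1)))
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise ValidationError(
                f"beta value {self.values[i, j]!r} outside [0, 1] at "
                f"probe {self.probe_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BetaMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))

    def subset_probes(self, probe_ids: Sequence[str]) -> "BetaMatrix":
        index = {p: i for i, p in enumerate(self.probe_ids)}
        missing = [p for p in probe_ids if p not in index]
        if missing:
            raise ValidationError(f"unknown probe ids: {missing[:5]}")
        rows = [index[p] for p in probe_ids]
        return BetaMatrix(list(probe_ids), list(self.sample_ids), self.values[rows, :])

    def subset_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        index = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing[:5]}")
        cols = [index[s] for s in sample_ids]
        return BetaMatrix(list(self.probe_ids), list(sample_ids), self.values[:, cols])


def read_beta_matrix(path: str | Path) -> BetaMatrix:
    """Read a probes-x-samples TSV; first column probe ids, header sample ids.

    Out-of-range values raise :class:`ValidationError` naming the cell —
    never silent clipping.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA], keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if frame.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns found")
    try:
        values = frame.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric beta value ({exc})") from exc
    return BetaMatrix(list(frame.index.astype(str)), list(frame.columns.astype(str)), values)


def write_beta_matrix(beta: BetaMatrix, path: str | Path, float_format: str = "%.10g") -> None:
    frame = beta.to_frame()
    frame.index.name = "probe_id"
    frame.to_csv(path, sep="\t", na_rep=NA, float_format=float_format)


# ---------------------------------------------------------------------------
# SampleSheet
# ---------------------------------------------------------------------------

SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "subject_id",
    "timepoint",
    "location",
    "aspirin",
    "switched_at_t2",
    "age",
    "bmi",
    "polyps",
    "batch",
]


@dataclass
class SampleSheet:
    """Per-sample covariates and group labels.

    One subject contributes at most one sample per (timepoint, location)
    pair; ages are non-decreasing from t1 to t2 within a subject.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        self.frame = self.frame.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.frame
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"sample sheet missing required columns: {missing}")
        _check_unique(list(df["sample_id"].astype(str)), "sample id")
        for col, levels in [
            ("timepoint", TIMEPOINTS),
            ("location", LOCATIONS),
            ("aspirin", ASPIRIN_LEVELS),
        ]:
            bad = df.loc[~df[col].isin(levels)]
            if len(bad):
                row = bad.index[0]
                raise ValidationError(
                    f"row {row}: unknown {col} level {bad[col].iloc[0]!r} "
                    f"(expected one of {levels})"
                )
        dup = df.duplicated(subset=["subject_id", "timepoint", "location"], keep=False)
        if dup.any():
            rows = list(df.index[dup][:2])
            key = df.loc[rows[0], ["subject_id", "timepoint", "location"]].tolist()
            raise ValidationError(f"rows {rows}: duplicate (subject, timepoint, location) {key}")
        for subject, grp in df.groupby("subject_id"):
            a1 = grp.loc[grp["timepoint"] == "t1", "age"]
            a2 = grp.loc[grp["timepoint"] == "t2", "age"]
            if len(a1) and len(a2) and float(a2.min()) < float(a1.max()):
                raise ValidationError(f"subject {subject!r}: age at t2 < age at t1")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"].astype(str))

    def subset(self, mask: pd.Series) -> "SampleSheet":
        return SampleSheet(self.frame.loc[mask].copy())

    def location(self, location: str) -> "SampleSheet":
        if location not in LOCATIONS:
            raise ValidationError(f"unknown location {location!r}")
        return self.subset(self.frame["location"] == location)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    df["switched_at_t2"] = df["switched_at_t2"].astype(bool)
    df["polyps"] = df["polyps"].astype(bool)
    df["age"] = df["age"].astype(float)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    out = sheet.frame.copy()
    out["switched_at_t2"] = out["switched_at_t2"].astype(bool)
    out.to_csv(path, sep="\t", index=False, na_rep=NA)


# ---------------------------------------------------------------------------
# ProbeAnnotation
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = [
    "probe_id",
    "chromosome",
    "position",
    "gene_symbols",
    "region_class",
    "cgi_status",
    "flags",
    "genome_build",
]


@dataclass
class ProbeAnnotation:
    """Per-probe genomic annotation joined to beta matrices by probe id.

    ``gene_symbols`` and ``flags`` are list-valued columns (comma-separated
    on disk, possibly empty). Positions are 1-based.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        self.frame = self.frame.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.frame
        missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"probe annotation missing required columns: {missing}")
        _check_unique(list(df["probe_id"].astype(str)), "probe id")
        bad = df.loc[~df["region_class"].isin(REGION_CLASSES)]
        if len(bad):
            raise ValidationError(
                f"row {bad.index[0]}: unknown region_class {bad['region_class'].iloc[0]!r}"
            )
        bad = df.loc[~df["cgi_status"].isin(CGI_STATUSES)]
        if len(bad):
            raise ValidationError(
                f"row {bad.index[0]}: unknown cgi_status {bad['cgi_status'].iloc[0]!r}"
            )
        for row, flags in df["flags"].items():
            unknown = set(flags) - set(GENE_FLAGS)
            if unknown:
                raise ValidationError(f"row {row}: unknown flags {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.frame["probe_id"].astype(str))

    def genes_for(self, probes: Sequence[str]) -> set[str]:
        """Unique gene symbols annotated to any of the given probes."""
        probes = set(probes)
        genes: set[str] = set()
        for pid, syms in zip(self.frame["probe_id"], self.frame["gene_symbols"]):
            if pid in probes:
                genes.update(syms)
        return genes

    @property
    def universe(self) -> set[str]:
        """All genes represented on the array (the enrichment background)."""
        genes: set[str] = set()
        for syms in self.frame["gene_symbols"]:
            genes.update(syms)
        return genes


def _split_list(cell: object) -> list[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return []
    return [x.strip() for x in str(cell).split(",") if x.strip()]


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    df["gene_symbols"] = df["gene_symbols"].map(_split_list)
    df["flags"] = df["flags"].map(_split_list)
    df["position"] = df["position"].astype(int)
    return ProbeAnnotation(df)


def write_probe_annotation(ann: ProbeAnnotation, path: str | Path) -> None:
    out = ann.frame.copy()
    out["gene_symbols"] = out["gene_symbols"].map(",".join)
    out["flags"] = out["flags"].map(",".join)
    out.to_csv(path, sep="\t", index=False, na_rep=NA)


# ---------------------------------------------------------------------------
# AnalysisConfig
# ---------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    """Run configuration with the defaults used throughout the pipeline."""

    fdr_alpha: float = 0.05
    detection_p_threshold: float = 0.01
    beta_clamp_epsilon: float = 1e-07
    n_variable_cpgs_for_pca: int = 10_000
    knn_k: int = 10
    seed: int = 0
    beta_path: str = ""
    sample_sheet_path: str = ""
    annotation_path: str = ""
    clock_paths: list[str] = field(default_factory=list)
    detection_p_path: str = ""
    mask_path: str = ""
    gene_set_path: str = ""
    output_dir: str = "methdrift_out"

    def __post_init__(self) -> None:
        if not 0 < self.fdr_alpha < 1:
            raise ValidationError(f"fdr_alpha {self.fdr_alpha} must lie in (0, 1)")
        if not 0 < self.beta_clamp_epsilon < 0.5:
            raise ValidationError(
                f"beta_clamp_epsilon {self.beta_clamp_epsilon} must lie in (0, 0.5)"
            )
        if self.knn_k < 1:
            raise ValidationError(f"knn_k {self.knn_k} must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
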