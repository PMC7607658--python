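"""Beta/M transformations, probe filtering, variable-CpG selection and PCA."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from methdrift.core_io import BetaMatrix
from methdrift.errors import DomainError, ValidationError

DEFAULT_CLAMP_EPSILON = 1e-07


def beta_from_intensities(meth, unmeth):
    """Methylation fraction from signal intensities: meth / (meth + unmeth + 100)."""
    meth = np.asarray(meth, dtype=float)
    unmeth = np.asarray(unmeth, dtype=float)
    if np.any(meth < 0) or np.any(unmeth < 0):
        raise DomainError("intensities must be non-negative")
    return meth / (meth + unmeth + 100.0)


def clamp_beta(beta, epsilon: float = DEFAULT_CLAMP_EPSILON):
    """Pull betas away from exact 0/1 so the logit stays finite."""
    return np.clip(beta, epsilon, 1.0 - epsilon)


def m_from_beta(beta, epsilon: float = DEFAULT_CLAMP_EPSILON):
    """log2(beta / (1 - beta)) after clamping; strictly increasing, finite."""
    b = clamp_beta(np.asarray(beta, dtype=float), epsilon)
    return np.log2(b / (1.0 - b))


def beta_from_m(m):
    """Inverse of :func:`m_from_beta` on the clamped interval."""
    x = np.exp2(np.asarray(m, dtype=float))
    return x / (1.0 + x)


@dataclass
class MValueMatrix:
    """Probes x samples logit2-methylation values; every entry finite."""

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"M matrix shape {self.values.shape} does not match axes"
            )
        if not np.all(np.isfinite(self.values[~np.isnan(self.values)])):
            raise ValidationError("M matrix contains non-finite values")

    @classmethod
    def from_beta(
        cls, beta: BetaMatrix, epsilon: float = DEFAULT_CLAMP_EPSILON
    ) -> "MValueMatrix":
        return cls(list(beta.probe_ids), list(beta.sample_ids), m_from_beta(beta.values, epsilon))


@dataclass
class FilterReport:
    """Exact accounting of probe filtering: detection-p rule and mask rule."""

    n_input_probes: int
    failed_detection: list[str]
    masked: list[str]
    kept: list[str]

    @property
    def n_failed_detection(self) -> int:
        return len(self.failed_detection)

    @property
    def n_masked(self) -> int:
        return len(self.masked)

    @property
    def n_kept(self) -> int:
        return len(self.kept)

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [(p, "failed_detection") for p in self.failed_detection]
            + [(p, "masked") for p in self.masked]
            + [(p, "kept") for p in self.kept]
        )
        return pd.DataFrame(rows, columns=["probe_id", "status"])


def filter_probes(
    beta: BetaMatrix,
    detection_p: np.ndarray | pd.DataFrame | None = None,
    mask: set[str] | None = None,
    threshold: float = 0.01,
) -> tuple[BetaMatrix, FilterReport]:
    """Drop probes failing the detection-p rule or present in the mask list.

    A probe is removed iff any sample's detection p exceeds ``threshold``,
    or the probe is in ``mask``. Surviving probes keep their input order.
    """
    mask = mask or set()
    failed: set[str] = set()
    if detection_p is not None:
        if isinstance(detection_p, pd.DataFrame):
            if list(detection_p.index) != list(beta.probe_ids) or list(
                detection_p.columns
            ) != list(beta.sample_ids):
                raise ValidationError("detection-p axes do not match beta matrix")
            dp = detection_p.to_numpy(dtype=float)
        else:
            dp = np.asarray(detection_p, dtype=float)
            if dp.shape != beta.shape:
                raise ValidationError(
                    f"detection-p shape {dp.shape} does not match beta {beta.shape}"
                )
        bad_rows = np.any(dp > threshold, axis=1)
        failed = {beta.probe_ids[i] for i in np.flatnonzero(bad_rows)}
    removed = failed | mask
    kept = [p for p in beta.probe_ids if p not in removed]
    report = FilterReport(
        n_input_probes=len(beta.probe_ids),
        failed_detection=sorted(failed & set(beta.probe_ids)),
        masked=sorted(mask & set(beta.probe_ids)),
        kept=kept,
    )
    return beta.subset_probes(kept), report


def select_most_variable(beta: BetaMatrix, k: int = 10_000) -> list[str]:
    """The k probes with largest across-sample (unbiased) beta variance.

    Ties break toward the lexicographically smaller probe id so the
    selection is deterministic across platforms.
    """
    n = len(beta.probe_ids)
    if k > n:
        raise DomainError(f"k={k} exceeds number of probes ({n})")
    variances = np.nanvar(beta.values, axis=1, ddof=1)
    variances = np.where(np.isnan(variances), -np.inf, variances)
    order = sorted(range(n), key=lambda i: (-variances[i], beta.probe_ids[i]))
    return [beta.probe_ids[i] for i in order[:k]]


@dataclass
class PCAResult:
    sample_ids: list[str]
    scores: np.ndarray  # samples x components
    explained_variance_ratio: np.ndarray
    probe_subset: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        cols = {f"PC{i + 1}": self.scores[:, i] for i in range(self.scores.shape[1])}
        return pd.DataFrame({"sample_id": self.sample_ids, **cols})


def pca_scores(
    beta: BetaMatrix, probe_subset: list[str] | None = None, n_components: int = 2
) -> PCAResult:
    """PCA on probe-centered (un-scaled) beta values of the selected probes."""
    sub = beta if probe_subset is None else beta.subset_probes(probe_subset)
    X = sub.values.T  # samples x probes
    n_samples, n_probes = X.shape
    if n_samples < 2:
        raise DomainError("PCA requires at least two samples")
    if n_components > min(n_samples, n_probes):
        raise DomainError(
            f"n_components={n_components} exceeds min(samples, probes)="
            f"{min(n_samples, n_probes)}"
        )
    Xc = X - X.mean(axis=0, keepdims=True)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    scores = Xc @ vt[:n_components].T
    var = s**2
    ratio = var[:n_components] / var.sum() if var.sum() > 0 else np.zeros(n_components)
    return PCAResult(
        sample_ids=list(sub.sample_ids),
        scores=scores,
        explained_variance_ratio=ratio,
        probe_subset=list(sub.probe_ids),
    )
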