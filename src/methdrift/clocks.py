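"""Generic epigenetic-clock engine.

A clock is an intercept plus a probe-coefficient map, optionally followed by
an age transform. Methylation age (mAge) is computed on the unfiltered beta
matrix with k-NN imputation of missing clock probes; age-acceleration
residuals (AAR) come from regressing mAge on chronological age over the
full fitting set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from methdrift.core_io import BetaMatrix, SampleSheet
from methdrift.errors import DomainError, FormatError, ValidationError

IDENTITY = "identity"
LOG_LINEAR = "log_linear"


@dataclass
class ClockDefinition:
    """Intercept + probe weights + optional age transform defining one clock."""

    name: str
    intercept: float
    coefficients: dict[str, float]
    transform: str = IDENTITY
    adult_age: float = 20.0

    def __post_init__(self) -> None:
        if not self.coefficients:
            raise ValidationError(f"clock {self.name!r}: empty coefficient map")
        if self.transform not in (IDENTITY, LOG_LINEAR):
            raise ValidationError(f"clock {self.name!r}: unknown transform {self.transform!r}")
        if self.transform == LOG_LINEAR and self.adult_age <= 0:
            raise ValidationError(f"clock {self.name!r}: adult_age must be > 0")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.coefficients)

    @property
    def expected_probe_count(self) -> int:
        return len(self.coefficients)


def transform_forward(age, transform: str = LOG_LINEAR, adult_age: float = 20.0):
    """Age -> linear-predictor scale: log-linear below adult_age, linear above."""
    if transform == IDENTITY:
        return np.asarray(age, dtype=float)
    age = np.asarray(age, dtype=float)
    lo = np.log(age + 1.0) - math.log(adult_age + 1.0)
    hi = (age - adult_age) / (adult_age + 1.0)
    return np.where(age <= adult_age, lo, hi)


def transform_inverse(x, transform: str = LOG_LINEAR, adult_age: float = 20.0):
    """Linear-predictor value -> age in years (inverse of transform_forward)."""
    if transform == IDENTITY:
        return np.asarray(x, dtype=float)
    x = np.asarray(x, dtype=float)
    lo = np.exp(x + math.log(adult_age + 1.0)) - 1.0
    hi = x * (adult_age + 1.0) + adult_age
    return np.where(x < 0, lo, hi)


# ---------------------------------------------------------------------------
# Clock TSV schema: '#' header lines carry name/intercept/transform/adult_age,
# then a two-column probe_id / weight table.
# ---------------------------------------------------------------------------


def write_clock(clock: ClockDefinition, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# name: {clock.name}\n")
        fh.write(f"# intercept: {float(clock.intercept)!r}\n")
        fh.write(f"# transform: {clock.transform}\n")
        fh.write(f"# adult_age: {float(clock.adult_age)!r}\n")
        fh.write("probe_id\tweight\n")
        for probe, w in clock.coefficients.items():
            fh.write(f"{probe}\t{float(w)!r}\n")


def read_clock(path: str | Path) -> ClockDefinition:
    meta: dict[str, str] = {}
    rows: list[tuple[str, float]] = []
    header_seen = False
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition(":")
                meta[key.strip()] = value.strip()
                continue
            if not header_seen:
                if line.split("\t")[:2] != ["probe_id", "weight"]:
                    raise FormatError(f"{path}: expected 'probe_id\\tweight' header")
                header_seen = True
                continue
            probe, _, weight = line.partition("\t")
            rows.append((probe, float(weight)))
    if "name" not in meta or "intercept" not in meta:
        raise FormatError(f"{path}: missing '# name:' or '# intercept:' header line")
    return ClockDefinition(
        name=meta["name"],
        intercept=float(meta["intercept"]),
        coefficients=dict(rows),
        transform=meta.get("transform", IDENTITY),
        adult_age=float(meta.get("adult_age", 20.0)),
    )


# ---------------------------------------------------------------------------
# k-NN imputation (impute-by-similar-probe; sample mode behind a flag)
# ---------------------------------------------------------------------------


def knn_impute(
    beta: BetaMatrix,
    target_probes: list[str],
    k: int = 10,
    mode: str = "probe",
) -> BetaMatrix:
    """Complete a matrix over ``target_probes`` by k-nearest-neighbour averaging.

    In the default ``probe`` mode, a missing value for probe p in sample s is
    the mean over the k complete probes nearest to p (Euclidean distance on
    shared non-missing samples) of their values in s. Probes absent from the
    matrix entirely are imputed from the k globally nearest complete probes,
    i.e. the column-wise mean of those neighbours. Non-missing entries are
    never changed.
    """
    if mode not in ("probe", "sample"):
        raise DomainError(f"unknown imputation mode {mode!r}")
    if mode == "sample":
        transposed = BetaMatrix(beta.sample_ids, beta.probe_ids, beta.values.T)
        # impute every probe row of the transposed matrix, then restrict
        done = knn_impute(transposed, list(transposed.probe_ids), k, mode="probe")
        back = BetaMatrix(beta.probe_ids, beta.sample_ids, done.values.T)
        return back.subset_probes(target_probes)

    present = {p: i for i, p in enumerate(beta.probe_ids)}
    values = beta.values
    complete_idx = np.flatnonzero(~np.isnan(values).any(axis=1))
    if len(complete_idx) < k:
        raise DomainError(
            f"k-NN imputation needs at least k={k} complete probes, "
            f"found {len(complete_idx)}"
        )
    complete = values[complete_idx, :]

    out = np.empty((len(target_probes), len(beta.sample_ids)))
    for r, probe in enumerate(target_probes):
        if probe in present:
            row = values[present[probe], :].copy()
        else:
            row = np.full(len(beta.sample_ids), np.nan)
        if not np.isnan(row).any():
            out[r, :] = row
            continue
        observed = ~np.isnan(row)
        if observed.any():
            diffs = complete[:, observed] - row[observed]
            dist = np.sqrt((diffs**2).sum(axis=1))
        else:
            dist = np.zeros(len(complete_idx))
        # stable ties: numpy argsort is stable for kind='stable'
        nearest = np.argsort(dist, kind="stable")
        nearest = nearest[
            ~np.isin(complete_idx[nearest], [present.get(probe, -1)])
        ][:k]
        fill = complete[nearest, :].mean(axis=0)
        row[~observed] = fill[~observed]
        out[r, :] = row
    out = np.clip(out, 0.0, 1.0)
    return BetaMatrix(list(target_probes), list(beta.sample_ids), out)


# ---------------------------------------------------------------------------
# mAge / AAR
# ---------------------------------------------------------------------------


@dataclass
class MAgeTable:
    """Per-sample mAge, chronological age, AAR and clock-probe coverage."""

    clock_name: str
    frame: pd.DataFrame  # sample_id, mage, age, aar, n_found, n_required, n_imputed
    coverage: dict[str, int] = field(default_factory=dict)


def compute_mage(
    beta: BetaMatrix, clock: ClockDefinition, knn_k: int = 10
) -> MAgeTable:
    """Evaluate a clock on an (unfiltered) beta matrix, imputing missing probes."""
    probes = clock.probe_ids
    found = [p for p in probes if p in set(beta.probe_ids)]
    if not found:
        raise DomainError(f"clock {clock.name!r}: no clock probes present in matrix")
    n_missing_entries = 0
    sub_vals = beta.subset_probes(found).values
    missing_probes = [p for p in probes if p not in set(beta.probe_ids)]
    needs_imputation = bool(missing_probes) or np.isnan(sub_vals).any()
    if needs_imputation:
        completed = knn_impute(beta, probes, k=knn_k)
        n_missing_entries = int(np.isnan(sub_vals).sum()) + len(missing_probes) * len(
            beta.sample_ids
        )
        mat = completed.values
        order = completed.probe_ids
    else:
        mat = sub_vals
        order = found
    weights = np.array([clock.coefficients[p] for p in order])
    linpred = clock.intercept + weights @ mat
    mage = transform_inverse(linpred, clock.transform, clock.adult_age)
    frame = pd.DataFrame(
        {
            "sample_id": list(beta.sample_ids),
            "mage": mage,
            "n_found": len(found),
            "n_required": clock.expected_probe_count,
            "n_imputed": len(missing_probes),
        }
    )
    coverage = {
        "n_found": len(found),
        "n_required": clock.expected_probe_count,
        "n_imputed_probes": len(missing_probes),
        "n_imputed_entries": n_missing_entries,
    }
    return MAgeTable(clock_name=clock.name, frame=frame, coverage=coverage)


def age_acceleration(
    mage_table: MAgeTable, ages: pd.Series | dict[str, float]
) -> MAgeTable:
    """Attach chronological age and AAR (residual of mAge ~ age) columns.

    The regression uses every sample in the table as the fitting set, so
    residuals sum to zero and are uncorrelated with chronological age.
    """
    frame = mage_table.frame.copy()
    age_map = dict(ages) if not isinstance(ages, dict) else ages
    frame["age"] = frame["sample_id"].map(age_map).astype(float)
    if frame["age"].isna().any():
        missing = frame.loc[frame["age"].isna(), "sample_id"].tolist()
        raise ValidationError(f"missing chronological age for samples {missing[:5]}")
    if len(frame) < 3:
        raise DomainError("age-acceleration regression needs >= 3 samples")
    x = frame["age"].to_numpy()
    y = frame["mage"].to_numpy()
    if np.ptp(x) == 0:
        raise DomainError("constant chronological age: regression undefined")
    slope, intercept = np.polyfit(x, y, 1)
    frame["aar"] = y - (intercept + slope * x)
    return MAgeTable(
        clock_name=mage_table.clock_name, frame=frame, coverage=dict(mage_table.coverage)
    )


def clock_cpg_change(
    beta: BetaMatrix,
    sheet: SampleSheet,
    clock: ClockDefinition,
    group: str,
    location: str | None = None,
) -> pd.DataFrame:
    """Per clock-CpG percent methylation change (t2 - t1) within one group.

    Uses the matrix as given (the pipeline passes the filtered matrix here,
    in contrast to mAge which sees unfiltered betas).
    """
    df = sheet.frame
    sel = df["aspirin"] == group
    if location is not None:
        sel &= df["location"] == location
    sub = df.loc[sel]
    if not len(sub):
        raise DomainError(f"no samples for group {group!r}")
    probes = [p for p in clock.probe_ids if p in set(beta.probe_ids)]
    if not probes:
        raise DomainError(f"no clock probes of {clock.name!r} survive in the matrix")
    vals = beta.subset_probes(probes)
    t1_ids = sub.loc[sub["timepoint"] == "t1", "sample_id"].tolist()
    t2_ids = sub.loc[sub["timepoint"] == "t2", "sample_id"].tolist()
    if not t1_ids or not t2_ids:
        raise DomainError(f"group {group!r} lacks samples at one timepoint")
    m1 = vals.subset_samples(t1_ids).values.mean(axis=1)
    m2 = vals.subset_samples(t2_ids).values.mean(axis=1)
    return pd.DataFrame(
        {"probe_id": probes, "percent_change": 100.0 * (m2 - m1)}
    )
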