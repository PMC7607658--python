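"""Synthetic paired longitudinal cohorts with planted methylation effects.

The generator emulates the structure of a 31-subject, two-location,
two-timepoint screening cohort: aspirin-group-dependent gain/loss CpGs at
t2, age-linear clock CpGs, chip batch structure, and a ground-truth
registry for recovery scoring.

Beta noise is Beta-distributed around a per-sample mean (respecting [0,1]
support); within-subject correlation comes from a subject-level random
intercept on the logit scale, and batches add a logit-scale shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from methdrift.clocks import ClockDefinition, write_clock, read_clock
from methdrift.core_io import (
    BetaMatrix,
    ProbeAnnotation,
    SampleSheet,
    read_beta_matrix,
    read_probe_annotation,
    read_sample_sheet,
    write_beta_matrix,
    write_probe_annotation,
    write_sample_sheet,
)
from methdrift.errors import DomainError, ValidationError

EFFECT_CLASSES = ("nonuser_gain", "user_loss", "clock", "null")


@dataclass
class CohortSimSpec:
    """Parameters of one simulated cohort; defaults mirror the emulated study."""

    n_subjects: int = 31
    n_users_t1: int = 17
    n_users_t2: int = 20  # includes switchers (nonuser at t1, user at t2)
    age_min: float = 50.0
    age_max: float = 70.0
    followup_years: float = 10.0
    n_probes: int = 2000
    n_nonuser_gain: int = 100
    delta_beta_gain: float = 0.10
    n_user_loss: int = 100
    delta_beta_loss: float = 0.10
    n_clock_cpgs: int = 50
    clock_slope_min: float = 0.003
    clock_slope_max: float = 0.008
    clock_noise_sd: float = 0.01
    concentration: float = 100.0
    subject_sd: float = 0.1  # logit-scale random intercept sd
    n_batches: int = 4
    batch_sd: float = 0.1  # logit-scale per-batch shift sd
    user_t2_age_shift: float = 0.0  # planted mAge shift (years) in users at t2
    age_aspirin_confounding: float = 0.0  # 0 = assignment independent of age
    promoter_frac_planted: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_users_t1 <= self.n_users_t2 <= self.n_subjects:
            raise ValidationError(
                "need 0 <= n_users_t1 <= n_users_t2 <= n_subjects "
                f"(got {self.n_users_t1}, {self.n_users_t2}, {self.n_subjects})"
            )
        n_planted = self.n_nonuser_gain + self.n_user_loss + self.n_clock_cpgs
        if n_planted > self.n_probes:
            raise ValidationError(
                f"planted probes ({n_planted}) exceed n_probes ({self.n_probes})"
            )
        for name in ("delta_beta_gain", "delta_beta_loss"):
            d = getattr(self, name)
            if not 0 <= d < 0.6:
                raise ValidationError(f"{name}={d} would push expected betas out of (0,1)")
        if self.concentration <= 0 or self.clock_noise_sd <= 0:
            raise ValidationError("noise parameters must be positive")
        if self.n_batches < 1:
            raise ValidationError("n_batches must be >= 1")


@dataclass
class SyntheticTruth:
    """Planted-effect registry: one row per probe, null rows have delta 0."""

    frame: pd.DataFrame  # probe_id, effect_class, true_delta, clock_slope, clock_intercept
    seed: int

    def probes_of(self, effect_class: str) -> list[str]:
        if effect_class not in EFFECT_CLASSES:
            raise DomainError(f"unknown effect class {effect_class!r}")
        sel = self.frame["effect_class"] == effect_class
        return self.frame.loc[sel, "probe_id"].tolist()


@dataclass
class CohortBundle:
    beta: BetaMatrix
    sheet: SampleSheet
    annotation: ProbeAnnotation
    clock: ClockDefinition
    truth: SyntheticTruth


def _logit(x: np.ndarray) -> np.ndarray:
    return np.log(x / (1.0 - x))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(spec: CohortSimSpec) -> CohortBundle:
    """Draw a full cohort bundle; identical seeds give identical bundles."""
    rng = np.random.default_rng(spec.seed)
    S = spec.n_subjects
    subjects = [f"S{i + 1:03d}" for i in range(S)]

    # -- aspirin assignment (optionally age-confounded) and ages -------------
    ages_t1 = rng.uniform(spec.age_min, spec.age_max, size=S)
    if spec.age_aspirin_confounding > 0:
        score = spec.age_aspirin_confounding * (ages_t1 - ages_t1.mean()) / max(
            ages_t1.std(), 1e-9
        ) + rng.normal(size=S)
        order = np.argsort(-score, kind="stable")
    else:
        order = rng.permutation(S)
    users_t1 = set(order[: spec.n_users_t1])
    remaining = [i for i in order if i not in users_t1]
    switchers = set(remaining[: spec.n_users_t2 - spec.n_users_t1])

    subject_sigma = rng.normal(0.0, spec.subject_sd, size=S)

    # -- sample sheet --------------------------------------------------------
    bmi_t1 = rng.normal(25.0, 3.0, size=S)
    bmi_t2 = bmi_t1 + rng.normal(0.0, 1.0, size=S)
    polyps = rng.random(size=(S, 2)) < 0.3
    rows = []
    for i, subj in enumerate(subjects):
        for t_idx, tp in enumerate(("t1", "t2")):
            for loc in ("proximal", "distal"):
                is_user = i in users_t1 or (i in switchers and tp == "t2")
                rows.append(
                    {
                        "sample_id": f"{subj}_{tp}_{loc[:4]}",
                        "subject_id": subj,
                        "timepoint": tp,
                        "location": loc,
                        "aspirin": "long_term_user" if is_user else "nonuser",
                        "switched_at_t2": i in switchers,
                        "age": ages_t1[i] + (spec.followup_years if tp == "t2" else 0.0),
                        "bmi": (bmi_t1 if tp == "t1" else bmi_t2)[i],
                        "polyps": bool(polyps[i, t_idx]),
                        "batch": "",
                    }
                )
    sheet_df = pd.DataFrame(rows)
    n_samples = len(sheet_df)
    batch_labels = np.array([f"chip{b + 1:02d}" for b in range(spec.n_batches)])
    sheet_df["batch"] = batch_labels[rng.integers(0, spec.n_batches, size=n_samples)]

    # -- probe roles ---------------------------------------------------------
    P = spec.n_probes
    probe_ids = [f"cg{i + 1:08d}" for i in range(P)]
    role = np.full(P, "null", dtype=object)
    planted_idx = rng.permutation(P)
    i0 = 0
    gain_idx = planted_idx[i0 : i0 + spec.n_nonuser_gain]
    i0 += spec.n_nonuser_gain
    loss_idx = planted_idx[i0 : i0 + spec.n_user_loss]
    i0 += spec.n_user_loss
    clock_idx = planted_idx[i0 : i0 + spec.n_clock_cpgs]
    role[gain_idx] = "nonuser_gain"
    role[loss_idx] = "user_loss"
    role[clock_idx] = "clock"

    baseline = np.empty(P)
    baseline[:] = rng.uniform(0.05, 0.95, size=P)
    baseline[gain_idx] = rng.uniform(0.15, 0.85 - spec.delta_beta_gain, size=len(gain_idx))
    baseline[loss_idx] = rng.uniform(0.15 + spec.delta_beta_loss, 0.85, size=len(loss_idx))

    # clock probes: expected beta = a_p + s_p * age, kept inside (0.05, 0.95)
    age_lo = spec.age_min
    age_hi = spec.age_max + spec.followup_years + abs(spec.user_t2_age_shift) + 5.0
    slopes = np.zeros(P)
    intercepts = np.zeros(P)
    if len(clock_idx):
        mag = rng.uniform(spec.clock_slope_min, spec.clock_slope_max, size=len(clock_idx))
        sign = np.where(rng.random(len(clock_idx)) < 0.5, 1.0, -1.0)
        s = mag * sign
        a_lo = np.where(s > 0, 0.06 - s * age_lo, 0.06 - s * age_hi)
        a_hi = np.where(s > 0, 0.94 - s * age_hi, 0.94 - s * age_lo)
        if np.any(a_hi <= a_lo):
            raise ValidationError("clock slopes too steep for the age range")
        a = a_lo + rng.random(len(clock_idx)) * (a_hi - a_lo)
        slopes[clock_idx] = s
        intercepts[clock_idx] = a

    # -- per-sample expected means ------------------------------------------
    is_t2 = (sheet_df["timepoint"] == "t2").to_numpy()
    is_user = (sheet_df["aspirin"] == "long_term_user").to_numpy()
    subj_of = sheet_df["subject_id"].map({s: i for i, s in enumerate(subjects)}).to_numpy()
    sample_age = sheet_df["age"].to_numpy().copy()
    eff_age = sample_age + np.where(is_t2 & is_user, spec.user_t2_age_shift, 0.0)

    mean = np.tile(baseline[:, None], (1, n_samples))
    if len(gain_idx):
        mean[np.ix_(gain_idx, np.flatnonzero(is_t2 & ~is_user))] += spec.delta_beta_gain
    if len(loss_idx):
        mean[np.ix_(loss_idx, np.flatnonzero(is_t2 & is_user))] -= spec.delta_beta_loss
    if len(clock_idx):
        mean[clock_idx, :] = np.clip(
            intercepts[clock_idx, None] + slopes[clock_idx, None] * eff_age[None, :],
            0.02,
            0.98,
        )

    batch_shift = rng.normal(0.0, spec.batch_sd, size=spec.n_batches)
    batch_of = (
        sheet_df["batch"].map({b: i for i, b in enumerate(batch_labels)}).to_numpy()
    )
    shift = subject_sigma[subj_of] + batch_shift[batch_of]
    mu = _expit(_logit(np.clip(mean, 1e-4, 1 - 1e-4)) + shift[None, :])
    mu = np.clip(mu, 1e-4, 1 - 1e-4)

    conc = np.full((P, 1), spec.concentration)
    if len(clock_idx):
        # pick the concentration that gives the requested noise sd per entry
        c_clock = mu[clock_idx, :] * (1 - mu[clock_idx, :]) / spec.clock_noise_sd**2 - 1
        conc_matrix = np.broadcast_to(conc, mu.shape).copy()
        conc_matrix[clock_idx, :] = np.maximum(c_clock, 2.0)
    else:
        conc_matrix = np.broadcast_to(conc, mu.shape).copy()

    values = rng.beta(mu * conc_matrix, (1.0 - mu) * conc_matrix)
    beta = BetaMatrix(probe_ids, sheet_df["sample_id"].tolist(), values)

    # -- clock definition (exact inverse of the generative clock) ------------
    if len(clock_idx):
        K = len(clock_idx)
        weights = {probe_ids[i]: 1.0 / (K * slopes[i]) for i in clock_idx}
        clock_intercept = -sum(intercepts[i] / (K * slopes[i]) for i in clock_idx)
    else:
        weights = {probe_ids[0]: 0.0}
        clock_intercept = 0.0
    clock = ClockDefinition(
        name="synthetic-linear",
        intercept=float(clock_intercept),
        coefficients=weights,
        transform="identity",
    )

    # -- annotation ----------------------------------------------------------
    n_genes = max(P // 3, 1)
    genes = [f"GENE{g + 1:05d}" for g in range(n_genes)]
    gene_of = rng.integers(0, n_genes, size=P)
    flag_draw = rng.random(n_genes)
    gene_flags = [
        ["TSG"] if d < 0.05 else ["oncogene"] if d < 0.08 else ["epigenetic_regulator"] if d < 0.12 else []
        for d in flag_draw
    ]
    region_draw = rng.random(P)
    regions = np.select(
        [region_draw < 0.25, region_draw < 0.5, region_draw < 0.75],
        ["promoter", "enhancer", "weak_transcription"],
        default="other",
    ).astype(object)
    if spec.promoter_frac_planted is not None:
        planted = np.concatenate([gain_idx, loss_idx]).astype(int)
        promote = rng.random(len(planted)) < spec.promoter_frac_planted
        regions[planted[promote]] = "promoter"
    cgi = np.where(rng.random(P) < 0.4, "island", "non_island")
    ann_df = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chromosome": [f"chr{(i % 22) + 1}" for i in range(P)],
            "position": np.arange(1, P + 1) * 1000,
            "gene_symbols": [[genes[g]] for g in gene_of],
            "region_class": regions,
            "cgi_status": cgi,
            "flags": [list(gene_flags[g]) for g in gene_of],
            "genome_build": "hg38",
        }
    )

    truth_delta = np.zeros(P)
    truth_delta[gain_idx] = spec.delta_beta_gain
    truth_delta[loss_idx] = -spec.delta_beta_loss
    truth_df = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "effect_class": role,
            "true_delta": truth_delta,
            "clock_slope": slopes,
            "clock_intercept": intercepts,
        }
    )

    return CohortBundle(
        beta=beta,
        sheet=SampleSheet(sheet_df),
        annotation=ProbeAnnotation(ann_df),
        clock=clock,
        truth=SyntheticTruth(frame=truth_df, seed=spec.seed),
    )


# ---------------------------------------------------------------------------
# Bundle I/O
# ---------------------------------------------------------------------------

BUNDLE_FILES = {
    "beta": "beta.tsv",
    "samples": "samples.tsv",
    "annotation": "annotation.tsv",
    "clock": "clock.tsv",
    "truth": "truth.tsv",
}


def write_cohort(bundle: CohortBundle, directory: str | Path, overwrite: bool = False) -> dict[str, Path]:
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise DomainError(f"{directory} exists and is not empty (pass overwrite=True)")
    directory.mkdir(parents=True, exist_ok=True)
    paths = {k: directory / v for k, v in BUNDLE_FILES.items()}
    write_beta_matrix(bundle.beta, paths["beta"], float_format="%.8g")
    write_sample_sheet(bundle.sheet, paths["samples"])
    write_probe_annotation(bundle.annotation, paths["annotation"])
    write_clock(bundle.clock, paths["clock"])
    truth = bundle.truth.frame.copy()
    truth.insert(0, "seed", bundle.truth.seed)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def read_cohort(directory: str | Path) -> CohortBundle:
    directory = Path(directory)
    truth_df = pd.read_csv(directory / BUNDLE_FILES["truth"], sep="\t")
    seed = int(truth_df["seed"].iloc[0]) if len(truth_df) else 0
    truth_df = truth_df.drop(columns=["seed"])
    return CohortBundle(
        beta=read_beta_matrix(directory / BUNDLE_FILES["beta"]),
        sheet=read_sample_sheet(directory / BUNDLE_FILES["samples"]),
        annotation=read_probe_annotation(directory / BUNDLE_FILES["annotation"]),
        clock=read_clock(directory / BUNDLE_FILES["clock"]),
        truth=SyntheticTruth(frame=truth_df, seed=seed),
    )
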