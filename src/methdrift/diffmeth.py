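"""Paired multivariable differential methylation with empirical-Bayes moderation.

The inference scale is M values; reported effect sizes are beta-scale
percentage points (t2 - t1). Each colon location is fitted separately with
subject blocking; the two contrasts of interest are "t2 vs t1 within users"
and "t2 vs t1 within nonusers".

Variance moderation follows the scaled inverse-chi-square hierarchy: the
prior (d0, s0^2) is estimated by matching moments of log s^2 via
digamma/trigamma inversion, posterior variances are the df-weighted blend,
and moderated t statistics gain d0 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from methdrift.core_io import BetaMatrix, SampleSheet
from methdrift.errors import DesignError, DomainError, FitError, ValidationError
from methdrift.preprocess import MValueMatrix

D0_INFINITE_CAP = 1e6  # estimated d0 above this is treated as +infinity

USER = "long_term_user"
NONUSER = "nonuser"


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------


@dataclass
class Design:
    """Full-rank design matrix for one colon location plus contrast vectors."""

    matrix: np.ndarray
    columns: list[str]
    dropped: list[str]
    sample_ids: list[str]
    contrasts: dict[str, np.ndarray]

    @property
    def rank(self) -> int:
        return len(self.columns)


def _greedy_full_rank(
    columns: list[tuple[str, np.ndarray]], tol: float = 1e-8
) -> tuple[np.ndarray, list[str], list[str]]:
    """Keep columns in entry order, dropping any that are linear combinations
    of earlier kept columns (so later-entered aliased columns drop first)."""
    kept: list[np.ndarray] = []
    kept_names: list[str] = []
    dropped: list[str] = []
    q_basis: list[np.ndarray] = []
    for name, col in columns:
        v = col.astype(float).copy()
        for q in q_basis:
            v -= (q @ col) * q
        norm = np.linalg.norm(v)
        if norm > tol * max(1.0, np.linalg.norm(col)):
            q_basis.append(v / norm)
            kept.append(col.astype(float))
            kept_names.append(name)
        else:
            dropped.append(name)
    return np.column_stack(kept), kept_names, dropped


GROUP_LEVELS = {"user": USER, "nonuser": NONUSER}


def build_design(
    sheet: SampleSheet,
    covariates: tuple[str, ...] = ("bmi", "polyps", "age", "batch"),
    groups: tuple[str, ...] = ("user", "nonuser"),
) -> Design:
    """Design for one location: group x timepoint cells, subject indicators,
    covariates and batch indicators, with deterministic aliased-column drops.

    ``sheet`` must contain a single colon location. Contrast vectors address
    the t2 - t1 effect within each requested group. Cells and subject
    blocking take precedence in the column order, so exactly-aliased
    covariates (age, when the follow-up interval is constant) are the
    columns that get dropped and reported.
    """
    df = sheet.frame
    if df["location"].nunique() > 1:
        raise DesignError("build_design expects samples from a single colon location")
    cell_of = df["aspirin"].astype(str) + "." + df["timepoint"].astype(str)
    observed_cells = [
        f"{a}.{t}"
        for a in (NONUSER, USER)
        for t in ("t1", "t2")
        if f"{a}.{t}" in set(cell_of)
    ]
    for g in groups:
        level = GROUP_LEVELS[g]
        for needed in (f"{level}.t1", f"{level}.t2"):
            if needed not in observed_cells:
                raise DesignError(
                    f"no samples in cell {needed!r}: contrast {g!r} not estimable"
                )
        n_subj = df.loc[df["aspirin"] == level, "subject_id"].nunique()
        if n_subj < 2:
            raise DesignError(f"group {level!r} has fewer than 2 subjects")

    cols: list[tuple[str, np.ndarray]] = []
    for cell in observed_cells:
        cols.append((f"cell:{cell}", (cell_of == cell).to_numpy(dtype=float)))
    subjects = sorted(df["subject_id"].astype(str).unique())
    for s in subjects:
        cols.append(
            (f"subject:{s}", (df["subject_id"].astype(str) == s).to_numpy(dtype=float))
        )
    for cov in covariates:
        if cov == "batch":
            continue
        cols.append((f"cov:{cov}", df[cov].to_numpy(dtype=float)))
    if "batch" in covariates:
        batches = sorted(df["batch"].astype(str).unique())
        for b in batches[1:]:  # first level is the reference
            cols.append(
                (f"batch:{b}", (df["batch"].astype(str) == b).to_numpy(dtype=float))
            )

    matrix, names, dropped = _greedy_full_rank(cols)
    kept_batches = [n for n in names if n.startswith("batch:")]
    if "batch" in covariates and len(set(df["batch"])) > 1 and not kept_batches:
        raise DesignError(
            "batch indicators are completely aliased with group/subject "
            "structure (batch == group?): cannot adjust for batch"
        )

    def contrast(group_key: str) -> np.ndarray:
        level = GROUP_LEVELS[group_key]
        c = np.zeros(len(names))
        hi = f"cell:{level}.t2"
        lo = f"cell:{level}.t1"
        if hi not in names or lo not in names:
            raise DesignError(f"cells for group {level!r} were dropped as aliased")
        c[names.index(hi)] = 1.0
        c[names.index(lo)] = -1.0
        return c

    return Design(
        matrix=matrix,
        columns=names,
        dropped=dropped,
        sample_ids=list(df["sample_id"].astype(str)),
        contrasts={g: contrast(g) for g in groups},
    )


# ---------------------------------------------------------------------------
# Per-probe OLS
# ---------------------------------------------------------------------------


@dataclass
class ProbeFits:
    """Per-probe least-squares fits against a shared design."""

    probe_ids: list[str]
    coefficients: np.ndarray  # probes x columns
    sigma2: np.ndarray  # residual variances
    df_residual: int
    xtx_inv: np.ndarray
    design: Design


def fit_per_probe(m: MValueMatrix, design: Design) -> ProbeFits:
    """Ordinary least squares per probe; s^2 = RSS / (n - rank)."""
    if list(m.sample_ids) != list(design.sample_ids):
        raise ValidationError("M-matrix sample order does not match design rows")
    X = design.matrix
    n, p = X.shape
    df_resid = n - p
    if df_resid <= 0:
        raise FitError(f"non-positive residual df ({n} samples, rank {p})")
    Y = m.values  # probes x samples
    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    coef = Y @ X @ xtx_inv.T  # probes x p
    resid = Y - coef @ X.T
    rss = (resid**2).sum(axis=1)
    sigma2 = rss / df_resid
    return ProbeFits(
        probe_ids=list(m.probe_ids),
        coefficients=coef,
        sigma2=sigma2,
        df_residual=df_resid,
        xtx_inv=xtx_inv,
        design=design,
    )


# ---------------------------------------------------------------------------
# Empirical-Bayes variance moderation
# ---------------------------------------------------------------------------


@dataclass
class EBayesParams:
    """Prior df / variance and per-probe posterior variances."""

    d0: float  # may be +inf
    s02: float
    s2_post: np.ndarray


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_prior(sigma2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) from the ensemble of residual variances.

    Models s^2 ~ s0^2 F(df, d0) and matches mean/variance of log s^2 using
    digamma/trigamma identities. Returns d0 = +inf when the observed spread
    of log s^2 is no larger than the sampling spread at the given df.
    """
    s2 = np.asarray(sigma2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise DomainError("prior estimation needs >= 2 positive variances")
    z = np.log(s2[ok])
    if np.ptp(z) < 1e-12:  # no spread at all: the prior IS the common variance
        return np.inf, float(np.exp(z.mean()))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    n = len(e)
    evar = ((e - emean) ** 2).sum() / (n - 1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    half_d0 = _trigamma_inverse(float(evar))
    d0 = 2.0 * half_d0
    if d0 > D0_INFINITE_CAP:
        return np.inf, float(np.exp(emean))
    s02 = np.exp(emean + special.digamma(half_d0) - np.log(half_d0))
    return float(d0), float(s02)


def squeeze_variances(
    sigma2: np.ndarray, df: float, d0: float | None = None, s02: float | None = None
) -> EBayesParams:
    """Posterior variances s~^2 = (d0 s0^2 + df s^2) / (d0 + df)."""
    s2 = np.asarray(sigma2, dtype=float)
    if d0 is None or s02 is None:
        d0_est, s02_est = estimate_prior(s2, df)
        d0 = d0_est if d0 is None else d0
        s02 = s02_est if s02 is None else s02
    if np.isinf(d0):
        post = np.full_like(s2, s02)
    elif d0 == 0:
        post = s2.copy()
    else:
        post = (d0 * s02 + df * s2) / (d0 + df)
    return EBayesParams(d0=float(d0), s02=float(s02), s2_post=post)


def moderated_contrast(
    fits: ProbeFits, contrast: np.ndarray, params: EBayesParams
) -> pd.DataFrame:
    """Moderated t test of one contrast: t = c'b / (s~ * sqrt(c'(X'X)^-1 c))."""
    c = np.asarray(contrast, dtype=float)
    if c.shape != (fits.coefficients.shape[1],):
        raise ValidationError(
            f"contrast length {c.shape} does not match design rank "
            f"{fits.coefficients.shape[1]}"
        )
    estimate = fits.coefficients @ c
    unscaled = float(np.sqrt(c @ fits.xtx_inv @ c))
    se = np.sqrt(params.s2_post) * unscaled
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, estimate / se, 0.0)
    df_total = fits.df_residual + params.d0
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        p = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    return pd.DataFrame(
        {
            "probe_id": fits.probe_ids,
            "estimate": estimate,
            "se": se,
            "t": tstat,
            "p": p,
            "df_total": df_total,
        }
    )


def ebayes_moderate(
    fits: ProbeFits, d0: float | None = None, s02: float | None = None
) -> tuple[EBayesParams, dict[str, pd.DataFrame]]:
    """Moderate all design contrasts of a fit; d0/s02 may be forced for tests."""
    if len(fits.probe_ids) < 10 and d0 is None:
        raise DomainError("hyperparameter estimation needs >= 10 probes")
    params = squeeze_variances(fits.sigma2, fits.df_residual, d0=d0, s02=s02)
    tables = {
        name: moderated_contrast(fits, cvec, params)
        for name, cvec in fits.design.contrasts.items()
    }
    return params, tables


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise DomainError("bh_adjust expects a 1-d array")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise DomainError("p-values must lie in [0, 1]")
    n = len(p)
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# Differential methylation tables and the catalog
# ---------------------------------------------------------------------------


def _group_timepoint_means(
    beta: BetaMatrix, sheet: SampleSheet, group: str
) -> tuple[np.ndarray, np.ndarray]:
    df = sheet.frame
    sel = df["aspirin"] == group
    t1 = df.loc[sel & (df["timepoint"] == "t1"), "sample_id"].tolist()
    t2 = df.loc[sel & (df["timepoint"] == "t2"), "sample_id"].tolist()
    if not t1 or not t2:
        raise DomainError(f"group {group!r} lacks samples at one timepoint")
    m1 = beta.subset_samples(t1).values.mean(axis=1)
    m2 = beta.subset_samples(t2).values.mean(axis=1)
    return m1, m2


def probe_fit_table(
    moderated: pd.DataFrame,
    beta: BetaMatrix,
    sheet: SampleSheet,
    group: str,
) -> pd.DataFrame:
    """Attach BH-adjusted p and beta-scale percent change to a moderated table."""
    if list(moderated["probe_id"]) != list(beta.probe_ids):
        raise ValidationError("moderated table and beta matrix probe order differ")
    out = moderated.copy()
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    m1, m2 = _group_timepoint_means(beta, sheet, group)
    out["mean_beta_t1"] = m1
    out["mean_beta_t2"] = m2
    out["percent_change"] = 100.0 * (m2 - m1)
    return out


@dataclass
class LocationCatalog:
    """User-specific (U), nonuser-specific (Nu) and shared dmCpG sets for one
    colon location, with hyper/hypo direction from the beta-scale change."""

    u: pd.DataFrame
    nu: pd.DataFrame
    shared: pd.DataFrame
    n_zero_change: int = 0

    @property
    def union_probes(self) -> list[str]:
        return sorted(set(self.u["probe_id"]) | set(self.nu["probe_id"]))

    def counts(self) -> dict[str, int]:
        def split(df: pd.DataFrame) -> tuple[int, int]:
            return int((df["direction"] == "hyper").sum()), int(
                (df["direction"] == "hypo").sum()
            )

        u_hyper, u_hypo = split(self.u)
        nu_hyper, nu_hypo = split(self.nu)
        return {
            "u_hyper": u_hyper,
            "u_hypo": u_hypo,
            "nu_hyper": nu_hyper,
            "nu_hypo": nu_hypo,
            "shared": len(self.shared),
        }


def classify_dmcpgs(
    user_fit: pd.DataFrame, nonuser_fit: pd.DataFrame, alpha: float = 0.05
) -> LocationCatalog:
    """Split significant probes into U (users only), Nu (nonusers only) and
    shared sets; direction from the sign of the percent methylation change.

    Probes with exactly zero beta-scale change are excluded from the
    direction-labelled sets and counted.
    """
    if list(user_fit["probe_id"]) != list(nonuser_fit["probe_id"]):
        raise ValidationError("user and nonuser fits cover different probe sets")
    sig_u = user_fit["adj_p"].to_numpy() < alpha
    sig_n = nonuser_fit["adj_p"].to_numpy() < alpha

    def build(fit: pd.DataFrame, sel: np.ndarray) -> tuple[pd.DataFrame, int]:
        sub = fit.loc[sel, ["probe_id", "estimate", "adj_p", "percent_change"]].copy()
        zero = sub["percent_change"] == 0.0
        n_zero = int(zero.sum())
        sub = sub.loc[~zero]
        sub["direction"] = np.where(sub["percent_change"] > 0, "hyper", "hypo")
        return sub.reset_index(drop=True), n_zero

    u_df, z1 = build(user_fit, sig_u & ~sig_n)
    nu_df, z2 = build(nonuser_fit, sig_n & ~sig_u)
    shared = user_fit.loc[sig_u & sig_n, ["probe_id"]].reset_index(drop=True)
    return LocationCatalog(u=u_df, nu=nu_df, shared=shared, n_zero_change=z1 + z2)


def location_analysis(
    beta: BetaMatrix,
    sheet: SampleSheet,
    location: str,
    alpha: float = 0.05,
    epsilon: float = 1e-07,
) -> tuple[LocationCatalog, dict[str, pd.DataFrame], EBayesParams]:
    """One-stop paired analysis of a single colon location.

    Builds the design, fits every probe on the M scale, moderates variances,
    BH-adjusts both contrasts and classifies the dmCpG catalog.
    """
    from methdrift.preprocess import MValueMatrix

    loc_sheet = sheet.location(location)
    loc_beta = beta.subset_samples(loc_sheet.sample_ids)
    design = build_design(loc_sheet)
    fits = fit_per_probe(MValueMatrix.from_beta(loc_beta, epsilon), design)
    params, tables = ebayes_moderate(fits)
    full = {
        key: probe_fit_table(tables[key], loc_beta, loc_sheet, GROUP_LEVELS[key])
        for key in ("user", "nonuser")
    }
    catalog = classify_dmcpgs(full["user"], full["nonuser"], alpha=alpha)
    return catalog, full, params


def methylation_change(
    beta: BetaMatrix,
    sheet: SampleSheet,
    probes: list[str],
    group: str,
    per_subject: bool = False,
) -> pd.DataFrame:
    """Percent (t2 - t1) methylation change per probe within one group.

    Default is the group-mean definition; ``per_subject`` computes each
    subject's paired difference first and averages those.
    """
    if not probes:
        raise DomainError("empty probe list")
    sub = beta.subset_probes(probes)
    df = sheet.frame
    sel = df["aspirin"] == group
    if not sel.any():
        raise DomainError(f"group {group!r} is empty")
    if per_subject:
        diffs = []
        for _, grp in df.loc[sel].groupby("subject_id"):
            t1 = grp.loc[grp["timepoint"] == "t1", "sample_id"].tolist()
            t2 = grp.loc[grp["timepoint"] == "t2", "sample_id"].tolist()
            if t1 and t2:
                d = (
                    sub.subset_samples(t2).values.mean(axis=1)
                    - sub.subset_samples(t1).values.mean(axis=1)
                )
                diffs.append(d)
        if not diffs:
            raise DomainError(f"group {group!r} has no complete pairs")
        change = 100.0 * np.mean(diffs, axis=0)
    else:
        m1, m2 = _group_timepoint_means(sub, sheet, group)
        change = 100.0 * (m2 - m1)
    return pd.DataFrame({"probe_id": probes, "percent_change": change})


def change_summary(change: pd.DataFrame) -> dict[str, float]:
    """Median and max percent change, split by direction."""
    hyper = change.loc[change["percent_change"] > 0, "percent_change"]
    hypo = change.loc[change["percent_change"] < 0, "percent_change"]
    return {
        "median_hyper": float(hyper.median()) if len(hyper) else float("nan"),
        "max_hyper": float(hyper.max()) if len(hyper) else float("nan"),
        "median_hypo": float(hypo.median()) if len(hypo) else float("nan"),
        "max_hypo": float(hypo.min()) if len(hypo) else float("nan"),
    }


def methylation_index(
    beta: BetaMatrix,
    sheet: SampleSheet,
    catalogs: dict[str, LocationCatalog],
    exclude_switchers: bool = True,
) -> pd.DataFrame:
    """Per-sample MI: 100 x mean beta over the U+Nu union of the sample's
    colon location. Switcher subjects are dropped when the flag is set."""
    frames = []
    for location, catalog in catalogs.items():
        union = catalog.union_probes
        if not union:
            raise DomainError(f"location {location!r}: empty dmCpG union")
        df = sheet.frame
        sel = df["location"] == location
        if exclude_switchers:
            sel &= ~df["switched_at_t2"].astype(bool)
        loc_df = df.loc[sel]
        sub = beta.subset_probes(union).subset_samples(
            loc_df["sample_id"].astype(str).tolist()
        )
        mi = 100.0 * np.nanmean(sub.values, axis=0)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": loc_df["sample_id"].to_numpy(),
                    "subject_id": loc_df["subject_id"].to_numpy(),
                    "location": location,
                    "timepoint": loc_df["timepoint"].to_numpy(),
                    "aspirin": loc_df["aspirin"].to_numpy(),
                    "mi": mi,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
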