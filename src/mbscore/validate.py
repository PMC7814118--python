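"""Internal validation of a fitted score.

Three pieces: (1) unstratified bootstrap of the whole cohort with per-tier
Kaplan-Meier survival recomputed at fixed horizons (default 24 and 36
months), summarized by bias-corrected and accelerated (BCa) intervals with
jackknife acceleration; (2) a paired bootstrap of the AUC difference between
the score and a baseline (e.g., IPSS-R), with a percentile interval and a
symmetric tail-probability p-value; (3) the final multivariable Cox model of
the tier indicators against the clinical confounders, ranked by Wald
chi-square.

The cross-tier Kruskal-Wallis p-values compare the tier-wise *replicate*
distributions; replicates are resamples of one cohort, not independent
observations, so those p-values are descriptive, not inferential.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError
from .io import Cohort
from .model import TIERS, MBSModel, RiskAssignment
from .score import confounder_frame
from .stats import CoxFit, binary_auc, cox_fit, km_fit

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# BCa machinery
# ---------------------------------------------------------------------------

def bca_interval(
    replicates: np.ndarray,
    theta_hat: float,
    jackknife: np.ndarray | None,
    level: float = 0.95,
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap interval.

    ``replicates`` are the bootstrap estimates (NaNs ignored), ``theta_hat``
    the original-sample estimate, ``jackknife`` the leave-one-out estimates
    used for the acceleration term (``None`` or degenerate → a = 0).  When
    both the bias correction and the acceleration vanish the interval
    reduces to the percentile interval.
    """
    reps = np.asarray(replicates, dtype=float)
    reps = reps[np.isfinite(reps)]
    if reps.size == 0:
        return (float("nan"), float("nan"))
    if np.all(reps == reps[0]):
        return (float(reps[0]), float(reps[0]))
    alpha = (1.0 - level) / 2.0
    prop = np.mean(reps < theta_hat) + 0.5 * np.mean(reps == theta_hat)
    prop = min(max(prop, 1.0 / (reps.size + 1)), reps.size / (reps.size + 1.0))
    z0 = sps.norm.ppf(prop)
    a = 0.0
    if jackknife is not None:
        jk = np.asarray(jackknife, dtype=float)
        jk = jk[np.isfinite(jk)]
        if jk.size > 1:
            dev = jk.mean() - jk
            denom = (dev**2).sum() ** 1.5
            if denom > 0:
                a = float((dev**3).sum() / (6.0 * denom))
    zlo, zhi = sps.norm.ppf(alpha), sps.norm.ppf(1.0 - alpha)
    alo = sps.norm.cdf(z0 + (z0 + zlo) / (1.0 - a * (z0 + zlo)))
    ahi = sps.norm.cdf(z0 + (z0 + zhi) / (1.0 - a * (z0 + zhi)))
    lo, hi = np.quantile(reps, [alo, ahi])
    return (float(lo), float(hi))


# ---------------------------------------------------------------------------
# Bootstrap of tier-wise survival
# ---------------------------------------------------------------------------

@dataclass
class BootstrapSummary:
    """Bootstrap of per-tier survival at fixed horizons with BCa intervals."""

    R: int
    horizons: tuple[float, ...]
    tiers: list[str]
    original: pd.DataFrame     # tier x horizon point estimates
    means: pd.DataFrame        # replicate means
    lower: pd.DataFrame
    upper: pd.DataFrame
    cross_tier_p: dict         # horizon -> Kruskal-Wallis p over replicates
    n_missing: pd.DataFrame    # replicates lacking the (tier, horizon) cell
    seed: int

    def table(self) -> pd.DataFrame:
        """Long-format table: tier, horizon, original, mean, CI bounds."""
        rows = []
        for tier in self.tiers:
            for h in self.horizons:
                rows.append(
                    {
                        "tier": tier,
                        "horizon_months": h,
                        "survival": self.original.loc[tier, h],
                        "boot_mean": self.means.loc[tier, h],
                        "ci_lower": self.lower.loc[tier, h],
                        "ci_upper": self.upper.loc[tier, h],
                        "missing_replicates": int(self.n_missing.loc[tier, h]),
                        "cross_tier_p": self.cross_tier_p[h],
                    }
                )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.table().to_csv(path, sep="\t", index=False, float_format="%.6g")


def _tier_survival_at(times, events, mask, horizon) -> float:
    """KM survival of one tier at a horizon; NaN when the tier is absent.
    Beyond the tier's last observed time the last estimate is carried
    forward (step-function convention)."""
    if mask.sum() == 0:
        return float("nan")
    km = km_fit(times[mask], events[mask])
    return km.survival_at(horizon)


def bootstrap_km(
    cohort: Cohort,
    assignment: RiskAssignment,
    R: int = 1000,
    horizons: tuple[float, ...] = (24.0, 36.0),
    seed: int = 0,
    level: float = 0.95,
) -> BootstrapSummary:
    """Unstratified bootstrap of tier-wise KM survival at fixed horizons.

    Each replicate resamples the whole cohort with replacement (tier sizes
    vary across replicates), recomputes each tier's Kaplan-Meier survival at
    each horizon, and the per-cell intervals are BCa with jackknife
    acceleration from the original cohort.  Replicates lacking a tier are
    recorded as missing for that cell, not treated as errors.
    """
    if R < 100:
        warnings.warn(f"R={R} bootstrap replicates give unstable intervals", stacklevel=2)
    times, events = cohort.times, cohort.events
    tiers_present = [t for t in TIERS if t in set(assignment.tiers)]
    if len(tiers_present) < 2:
        raise ValidationError("bootstrap_km: need at least two tiers represented")
    tier_of = np.asarray(assignment.tiers)
    n = cohort.n

    original = pd.DataFrame(index=tiers_present, columns=list(horizons), dtype=float)
    for tier in tiers_present:
        mask = tier_of == tier
        for h in horizons:
            original.loc[tier, h] = _tier_survival_at(times, events, mask, h)

    # per-replicate sub-seed schedule: independent of execution details
    children = np.random.SeedSequence(seed).spawn(R)
    reps = np.full((R, len(tiers_present), len(horizons)), np.nan)
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        idx = rng.integers(0, n, size=n)
        bt, be, btier = times[idx], events[idx], tier_of[idx]
        for i, tier in enumerate(tiers_present):
            mask = btier == tier
            for j, h in enumerate(horizons):
                reps[r, i, j] = _tier_survival_at(bt, be, mask, h)

    # leave-one-out jackknife for the acceleration term
    jack = np.full((n, len(tiers_present), len(horizons)), np.nan)
    keep = np.ones(n, dtype=bool)
    for i_out in range(n):
        keep[i_out] = False
        for i, tier in enumerate(tiers_present):
            mask = (tier_of == tier) & keep
            for j, h in enumerate(horizons):
                jack[i_out, i, j] = _tier_survival_at(times, events, mask, h)
        keep[i_out] = True

    means = pd.DataFrame(index=tiers_present, columns=list(horizons), dtype=float)
    lower = pd.DataFrame(index=tiers_present, columns=list(horizons), dtype=float)
    upper = pd.DataFrame(index=tiers_present, columns=list(horizons), dtype=float)
    n_missing = pd.DataFrame(index=tiers_present, columns=list(horizons), dtype=float)
    for i, tier in enumerate(tiers_present):
        for j, h in enumerate(horizons):
            cell = reps[:, i, j]
            finite = cell[np.isfinite(cell)]
            n_missing.loc[tier, h] = R - finite.size
            means.loc[tier, h] = finite.mean() if finite.size else float("nan")
            lo, hi = bca_interval(
                cell, float(original.loc[tier, h]), jack[:, i, j], level=level
            )
            lower.loc[tier, h] = lo
            upper.loc[tier, h] = hi
    missing_total = int(n_missing.to_numpy().sum())
    if missing_total:
        logger.info("bootstrap_km: %d missing (tier, horizon) replicate cells", missing_total)

    cross_tier_p = {}
    for j, h in enumerate(horizons):
        samples = [
            reps[:, i, j][np.isfinite(reps[:, i, j])] for i in range(len(tiers_present))
        ]
        samples = [s for s in samples if s.size > 0]
        if len(samples) < 2:
            cross_tier_p[h] = float("nan")
        else:
            try:
                cross_tier_p[h] = float(sps.kruskal(*samples).pvalue)
            except ValueError:  # every replicate value identical
                cross_tier_p[h] = 1.0

    return BootstrapSummary(
        R=R,
        horizons=tuple(horizons),
        tiers=tiers_present,
        original=original,
        means=means,
        lower=lower,
        upper=upper,
        cross_tier_p=cross_tier_p,
        n_missing=n_missing,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Bootstrapped AUC difference
# ---------------------------------------------------------------------------

@dataclass
class AUCComparison:
    """Paired bootstrap comparison of two risk scores' AUCs.

    ``delta = auc_a - auc_b`` on the original cohort; positive values mean
    score A predicts the event better.
    """

    auc_a: float
    auc_b: float
    delta: float
    ci_lower: float
    ci_upper: float
    p_value: float
    R: int
    seed: int
    n_redrawn: int = 0
    replicates: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "auc_a": self.auc_a,
                    "auc_b": self.auc_b,
                    "delta_auc": self.delta,
                    "ci_lower": self.ci_lower,
                    "ci_upper": self.ci_upper,
                    "p_value": self.p_value,
                    "R": self.R,
                }
            ]
        )


def _rowwise_auc(labels: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """AUC per row of (replicates x subjects) label/score matrices, via the
    rank (Mann-Whitney) identity with midranks for ties."""
    ranks = sps.rankdata(scores, axis=1)
    n1 = labels.sum(axis=1)
    n0 = labels.shape[1] - n1
    rank_sum_pos = (ranks * labels).sum(axis=1)
    return (rank_sum_pos - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def compare_auc_bootstrap(
    labels,
    score_a,
    score_b,
    R: int = 10000,
    seed: int = 0,
    level: float = 0.95,
) -> AUCComparison:
    """Bootstrap the AUC difference of two scores for the same subjects.

    Each replicate resamples subjects with replacement and computes both
    AUCs on the same resample; the interval is the percentile interval of
    the replicate differences and the p-value the symmetric tail
    probability ``2 * min(P(delta* <= 0), P(delta* >= 0))``, floored at
    ``1/R``.  Single-class replicates are redrawn (capped at ``10 R`` draws).
    """
    y = np.asarray(labels, dtype=int)
    a = np.asarray(score_a, dtype=float)
    b = np.asarray(score_b, dtype=float)
    if not (y.shape == a.shape == b.shape):
        raise ValidationError("compare_auc_bootstrap: input lengths differ")
    auc_a = binary_auc(y, a).auc
    auc_b = binary_auc(y, b).auc
    delta = auc_a - auc_b

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = y.size
    # draw all replicates, redrawing single-class rows (cap 10R total draws)
    idx = rng.integers(0, n, size=(R, n))
    redrawn = 0
    draws = R
    while True:
        ys = y[idx]
        s = ys.sum(axis=1)
        bad = np.flatnonzero((s == 0) | (s == n))
        if bad.size == 0:
            break
        if draws + bad.size > 10 * R:
            raise ValidationError(
                "compare_auc_bootstrap: too many single-class replicates "
                f"({redrawn + bad.size} redraws)"
            )
        idx[bad] = rng.integers(0, n, size=(bad.size, n))
        redrawn += bad.size
        draws += bad.size
    deltas = _rowwise_auc(y[idx], a[idx]) - _rowwise_auc(y[idx], b[idx])
    if redrawn:
        logger.info("compare_auc_bootstrap: redrew %d single-class replicates", redrawn)

    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(deltas, [alpha, 1.0 - alpha])
    p = 2.0 * min(np.mean(deltas <= 0.0), np.mean(deltas >= 0.0))
    p = float(min(max(p, 1.0 / R), 1.0))
    return AUCComparison(
        auc_a=float(auc_a),
        auc_b=float(auc_b),
        delta=float(delta),
        ci_lower=float(lo),
        ci_upper=float(hi),
        p_value=p,
        R=R,
        seed=seed,
        n_redrawn=redrawn,
        replicates=deltas,
    )


# ---------------------------------------------------------------------------
# Final multivariable model
# ---------------------------------------------------------------------------

@dataclass
class MultivariableResult:
    """Final Cox model: tier indicators (reference = favourable) plus
    confounders, with covariates ranked by Wald chi-square."""

    fit: CoxFit
    ranking: pd.DataFrame
    profile_lower: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.ranking.to_csv(path, sep="\t", index=False, float_format="%.6g")


def final_multivariable(
    cohort: Cohort,
    assignment: RiskAssignment,
    ties: str = "efron",
) -> MultivariableResult:
    """Fit intermediate/adverse-vs-favourable indicators plus age, gender and
    binary IPSS-R in one Cox model; rank covariates by Wald chi-square.

    A zero-event reference tier makes the tier coefficients monotone
    (expected when no favourable-tier patient died); those coefficients are
    flagged and a profile-likelihood lower bound is reported instead of the
    Wald interval.
    """
    tiers = np.asarray(assignment.tiers)
    if (tiers == "favourable").sum() == 0:
        raise ValidationError("final_multivariable: favourable tier is empty")
    conf, mask = confounder_frame(cohort)
    design = pd.concat(
        [
            pd.DataFrame(
                {
                    "mbs_intermediate": (tiers == "intermediate").astype(float),
                    "mbs_adverse": (tiers == "adverse").astype(float),
                }
            ),
            conf,
        ],
        axis=1,
    ).loc[mask]
    fit = cox_fit(cohort.times[mask], cohort.events[mask], design, ties=ties)

    from .stats import profile_lower_bound  # local import avoids cycle at load

    profile_lower = {}
    for j, name in enumerate(fit.names):
        if fit.monotone_flags[j]:
            try:
                profile_lower[name] = profile_lower_bound(fit, j)
            except Exception:  # pragma: no cover - diagnostic fallback only
                profile_lower[name] = float("nan")

    ranking = fit.summary().sort_values("wald_chi2", ascending=False).reset_index(
        drop=True
    )
    return MultivariableResult(fit=fit, ranking=ranking, profile_lower=profile_lower)
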