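"""Construction of the count-based molecular score.

The procedure, gene by gene: (1) find the optimal expression cutpoint for
predicting death (ROC/Youden by default, concordance optionally); (2) test
the dichotomized gene against overall survival in a univariate Cox model,
and — for univariate survivors — in a multivariate Cox model adjusted for
age, gender and IPSS-R (binary low vs non-low); (3) assemble the selected
genes into a count score whose risk tiers are 0 → favourable,
1 → intermediate, ≥ 2 → adverse.

Throughout, the screening hazard ratios refer to the *high-expression*
indicator (HR > 1: higher expression predicts death; HR < 1: lower
expression does), and the risk direction of each score component is the
expression state whose adjusted HR exceeds one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UninformativeMarkerError, ValidationError
from .io import Cohort
from .model import (
    HIGH_IS_RISK,
    LOW_IS_RISK,
    CutpointResult,
    MBSComponent,
    MBSModel,
    RiskAssignment,
    TierRule,
)
from .stats import cox_fit, harrell_c

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Optimal cutpoint
# ---------------------------------------------------------------------------

def _youden_by_candidate(values, labels, candidates):
    """|TPR - FPR| of the high-expression indicator at each candidate,
    computed by sorting (O(n log n))."""
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1 = y.sum()
    n0 = y.size - n1
    order = np.argsort(v, kind="stable")
    vs, ys = v[order], y[order]
    # counts at or below each candidate
    pos_cum = np.cumsum(ys)
    idx = np.searchsorted(vs, candidates, side="right") - 1
    pos_le = np.where(idx >= 0, pos_cum[idx], 0)
    tot_le = idx + 1
    neg_le = tot_le - pos_le
    tpr = (n1 - pos_le) / n1  # P(v > c | death)
    fpr = (n0 - neg_le) / n0  # P(v > c | survivor)
    return np.abs(tpr - fpr)


def _binary_concordance(times, events, indicator) -> float:
    c = harrell_c(times, events, indicator.astype(float))
    return max(c, 1.0 - c)


def optimal_cutpoint(
    values,
    times,
    events,
    gene: str = "",
    min_group_frac: float = 0.10,
    metric: str = "youden",
) -> CutpointResult:
    """Optimal dichotomization of one gene's expression against survival.

    Candidates are midpoints between consecutive sorted unique expression
    values whose induced split leaves at least ``floor(min_group_frac * n)``
    patients on each side.  ``metric="youden"`` maximizes sensitivity +
    specificity - 1 of the indicator against the observed-death label;
    ``metric="concordance"`` maximizes the Harrell C of the indicator.  Ties
    break toward the more balanced split, then the smaller cutpoint.  The
    risk direction is the side whose univariate hazard ratio exceeds one.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    if not (v.shape == t.shape == d.shape):
        raise ValidationError("optimal_cutpoint: input lengths differ")
    n = v.size
    if n < 20:
        raise ValidationError(f"optimal_cutpoint: need >= 20 patients, got {n}")
    if d.sum() == 0:
        raise ValidationError("optimal_cutpoint: no events")
    if metric not in ("youden", "concordance"):
        raise ValidationError(f"unknown cutpoint metric {metric!r}")

    u = np.unique(v)
    if u.size < 2:
        raise UninformativeMarkerError(f"gene {gene!r}: constant expression")
    mids = (u[:-1] + u[1:]) / 2.0
    n_high = n - np.searchsorted(np.sort(v), mids, side="right")
    n_low = n - n_high
    floor_size = int(np.floor(min_group_frac * n))
    admissible = np.minimum(n_high, n_low) >= max(floor_size, 1)
    if not admissible.any():
        raise ValidationError(
            f"gene {gene!r}: no admissible cutpoint at min_group_frac={min_group_frac}"
        )
    cands = mids[admissible]
    nh, nl = n_high[admissible], n_low[admissible]

    if metric == "youden":
        scores = _youden_by_candidate(v, d, cands)
    else:
        scores = np.array(
            [_binary_concordance(t, d, v > c) for c in cands]
        )
    if np.ptp(scores) < 1e-12:
        raise UninformativeMarkerError(
            f"gene {gene!r}: metric constant over all admissible cutpoints"
        )
    best = scores.max()
    tied = np.flatnonzero(scores >= best - 1e-12)
    # tie-break: most balanced split, then smallest cutpoint
    imbalance = np.abs(nh[tied] - nl[tied])
    tied = tied[imbalance == imbalance.min()]
    pick = tied[np.argmin(cands[tied])]
    cut = float(cands[pick])

    high = (v > cut).astype(float)
    fit = cox_fit(t, d, high[:, None], names=["high"])
    direction = HIGH_IS_RISK if fit.beta[0] > 0 else LOW_IS_RISK
    if fit.beta[0] == 0.0:
        direction = HIGH_IS_RISK
    return CutpointResult(
        gene=gene,
        cutpoint=cut,
        direction=direction,
        metric=metric,
        metric_value=float(scores[pick]),
        n_high=int(nh[pick]),
        n_low=int(nl[pick]),
    )


# ---------------------------------------------------------------------------
# Confounder design
# ---------------------------------------------------------------------------

def confounder_frame(cohort: Cohort) -> tuple[pd.DataFrame, np.ndarray]:
    """Numeric confounder design (age, male, IPSS-R non-low) plus the
    complete-case mask.  IPSS-R enters as binary: non-low = intermediate,
    high or very-high versus low = very-low or low."""
    rows = []
    mask = []
    for r in cohort.clinical:
        ok = r.age is not None and r.gender is not None and r.ipssr is not None
        mask.append(ok)
        rows.append(
            {
                "age": r.age if r.age is not None else np.nan,
                "male": 1.0 if r.gender == "male" else 0.0,
                "ipssr_nonlow": (
                    np.nan
                    if r.ipssr is None
                    else float(r.ipssr in ("intermediate", "high", "very-high"))
                ),
            }
        )
    return pd.DataFrame(rows), np.asarray(mask, dtype=bool)


# ---------------------------------------------------------------------------
# Two-stage screening
# ---------------------------------------------------------------------------

@dataclass
class ScreeningTable:
    """Per-gene univariate and confounder-adjusted Cox summaries."""

    frame: pd.DataFrame
    alpha: float
    n_complete: int
    n_dropped: int

    @property
    def selected_genes(self) -> list[str]:
        return sorted(self.frame.loc[self.frame["selected"], "gene"])

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def screen_genes(
    cohort: Cohort,
    gene_list,
    cutpoints: dict,
    alpha: float = 0.05,
    ties: str = "efron",
) -> ScreeningTable:
    """Two-stage proportional-hazards screening of dichotomized genes.

    Stage 1 fits a univariate Cox model on each gene's high-expression
    indicator; genes with p <= alpha proceed to stage 2, one multivariate
    Cox model per gene with age, gender and binary IPSS-R as confounders
    (complete cases only).  A gene is selected when its adjusted p <= alpha.
    Non-convergent fits mark the gene failed and the screen continues.

    ``cutpoints`` maps gene → :class:`CutpointResult` (or a
    ``(cutpoint, direction)`` pair).
    """
    genes = list(gene_list)
    missing = [g for g in genes if g not in cutpoints]
    if missing:
        raise ValidationError(f"no cutpoint for genes: {missing}")
    times, events = cohort.times, cohort.events
    conf, mask = confounder_frame(cohort)
    n_dropped = int((~mask).sum())
    if n_dropped:
        logger.info("screening drops %d patients with incomplete confounders", n_dropped)

    rows = []
    for gene in genes:
        cp = cutpoints[gene]
        if not isinstance(cp, CutpointResult):
            cut, direction = cp
            cp = CutpointResult(
                gene=gene, cutpoint=float(cut), direction=direction,
                metric="given", metric_value=float("nan"), n_high=0, n_low=0,
            )
        high = cp.high_indicator(cohort.expression.gene_values(gene)).astype(float)
        row = {
            "gene": gene,
            "cutpoint": cp.cutpoint,
            "uni_hr": np.nan, "uni_lower": np.nan, "uni_upper": np.nan, "uni_p": np.nan,
            "multi_hr": np.nan, "multi_lower": np.nan, "multi_upper": np.nan,
            "multi_p": np.nan,
            "selected": False,
            "direction": "",
            "note": "",
        }
        try:
            uni = cox_fit(times, events, high[:, None], ties=ties, names=["high"])
        except Exception as exc:
            row["note"] = f"univariate fit failed: {exc}"
            warnings.warn(f"gene {gene}: {row['note']}", stacklevel=2)
            rows.append(row)
            continue
        row.update(
            uni_hr=float(uni.hazard_ratios[0]),
            uni_lower=float(uni.ci_lower[0]),
            uni_upper=float(uni.ci_upper[0]),
            uni_p=float(uni.p_values[0]),
        )
        if row["uni_p"] > alpha:
            rows.append(row)
            continue
        design = pd.concat(
            [pd.DataFrame({"high": high}), conf], axis=1
        ).loc[mask]
        try:
            multi = cox_fit(times[mask], events[mask], design, ties=ties)
        except Exception as exc:
            row["note"] = f"multivariate fit failed: {exc}"
            warnings.warn(f"gene {gene}: {row['note']}", stacklevel=2)
            rows.append(row)
            continue
        j = multi.names.index("high")
        row.update(
            multi_hr=float(multi.hazard_ratios[j]),
            multi_lower=float(multi.ci_lower[j]),
            multi_upper=float(multi.ci_upper[j]),
            multi_p=float(multi.p_values[j]),
        )
        if row["multi_p"] <= alpha:
            row["selected"] = True
            row["direction"] = (
                HIGH_IS_RISK if multi.beta[j] > 0 else LOW_IS_RISK
            )
        rows.append(row)
    frame = pd.DataFrame(rows)
    return ScreeningTable(
        frame=frame, alpha=alpha, n_complete=int(mask.sum()), n_dropped=n_dropped
    )


# ---------------------------------------------------------------------------
# Model assembly and scoring
# ---------------------------------------------------------------------------

def build_mbs(
    screening: ScreeningTable,
    metric: str = "youden",
    tier_rule: TierRule | None = None,
) -> MBSModel:
    """Assemble the count score from the screening table's selected genes.

    Each selected gene becomes one component whose risk direction is the
    expression state with adjusted HR > 1; components are ordered
    alphabetically.  Raises when nothing was selected.
    """
    sel = screening.frame.loc[screening.frame["selected"]]
    if sel.empty:
        raise ValidationError(
            "no genes passed screening; a score cannot be built"
        )
    components = tuple(
        MBSComponent(
            gene=row["gene"], cutpoint=float(row["cutpoint"]),
            direction=row["direction"],
        )
        for _, row in sel.iterrows()
    )
    return MBSModel(
        components=components,
        tier_rule=tier_rule or TierRule(),
        alpha=screening.alpha,
        metric=metric,
    )


def score_patients(model: MBSModel, cohort: Cohort) -> RiskAssignment:
    """Count risk factors per patient and map the count to a tier."""
    missing = [c.gene for c in model.components
               if c.gene not in cohort.expression.gene_ids]
    if missing:
        raise ValidationError(f"model genes absent from cohort: {missing}")
    scores = np.zeros(cohort.n, dtype=int)
    for c in model.components:
        scores += c.as_cutpoint().risk_indicator(
            cohort.expression.gene_values(c.gene)
        )
    tiers = [model.tier_rule.tier(int(s)) for s in scores]
    return RiskAssignment(
        patient_ids=cohort.patient_ids, scores=scores, tiers=tiers
    )


def tier_table(assignment: RiskAssignment) -> pd.DataFrame:
    """Tier counts with display percentages constrained to sum to 100.

    Each tier's share is rounded to the nearest integer; any rounding
    residual is absorbed by the largest tier so the printed column totals
    100%.
    """
    counts = {tier: 0 for tier in ("favourable", "intermediate", "adverse")}
    for t in assignment.tiers:
        counts[t] += 1
    n = sum(counts.values())
    names = list(counts)
    raw = np.array([counts[t] for t in names], dtype=float)
    pct = np.array([round(100.0 * c / n) for c in raw], dtype=int)
    residual = 100 - pct.sum()
    pct[int(np.argmax(raw))] += residual
    return pd.DataFrame({"tier": names, "n": raw.astype(int), "percent": pct})
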