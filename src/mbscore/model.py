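"""Score-model types: cutpoints, the fitted count score, and risk assignments.

The Molecular-Based Score (MBS) counts, per patient, how many of its component
genes sit on the risk side of their expression cutpoint.  "High expression"
means strictly above the cutpoint, "low expression" at or below it; a
component contributes 1 when the patient's expression state is the one
associated with increased death hazard.  Tiers partition the count:
0 → favourable, 1 → intermediate, ≥ 2 → adverse.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ModelFormatError, ValidationError

HIGH_IS_RISK = "high_is_risk"
LOW_IS_RISK = "low_is_risk"
DIRECTIONS = (HIGH_IS_RISK, LOW_IS_RISK)

TIERS = ("favourable", "intermediate", "adverse")

_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class CutpointResult:
    """Optimal dichotomization of one gene's expression.

    ``direction`` records which expression state carries risk: under
    ``high_is_risk`` the risk indicator is ``expression > cutpoint``; under
    ``low_is_risk`` it is ``expression <= cutpoint``.
    """

    gene: str
    cutpoint: float
    direction: str
    metric: str
    metric_value: float
    n_high: int
    n_low: int

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise ValidationError(f"unknown direction {self.direction!r}")

    def risk_indicator(self, values: np.ndarray) -> np.ndarray:
        """1 where the expression state is the risky one."""
        high = np.asarray(values, dtype=float) > self.cutpoint
        return (high if self.direction == HIGH_IS_RISK else ~high).astype(int)

    def high_indicator(self, values: np.ndarray) -> np.ndarray:
        """1 where expression is strictly above the cutpoint."""
        return (np.asarray(values, dtype=float) > self.cutpoint).astype(int)


@dataclass(frozen=True)
class TierRule:
    """Map a risk-factor count to a tier: < intermediate_min → favourable,
    < adverse_min → intermediate, else adverse."""

    intermediate_min: int = 1
    adverse_min: int = 2

    def __post_init__(self):
        if not (0 < self.intermediate_min < self.adverse_min):
            raise ValidationError(
                f"tier thresholds must satisfy 0 < intermediate_min < adverse_min, "
                f"got {self.intermediate_min}, {self.adverse_min}"
            )

    def tier(self, score: int) -> str:
        if score < self.intermediate_min:
            return "favourable"
        if score < self.adverse_min:
            return "intermediate"
        return "adverse"


@dataclass(frozen=True)
class MBSComponent:
    gene: str
    cutpoint: float
    direction: str

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise ValidationError(f"unknown direction {self.direction!r}")

    def as_cutpoint(self) -> CutpointResult:
        return CutpointResult(
            gene=self.gene,
            cutpoint=self.cutpoint,
            direction=self.direction,
            metric="model",
            metric_value=float("nan"),
            n_high=0,
            n_low=0,
        )


@dataclass(frozen=True)
class MBSModel:
    """A fitted count score: components sorted by gene, tier rule, provenance."""

    components: tuple[MBSComponent, ...]
    tier_rule: TierRule = field(default_factory=TierRule)
    alpha: float = 0.05
    metric: str = "youden"
    confounders: tuple[str, ...] = ("age", "gender", "ipssr")

    def __post_init__(self):
        if not self.components:
            raise ValidationError("a score model needs at least one component")
        genes = [c.gene for c in self.components]
        if len(set(genes)) != len(genes):
            raise ValidationError(f"duplicate component genes: {genes}")
        object.__setattr__(
            self, "components", tuple(sorted(self.components, key=lambda c: c.gene))
        )
        if len(self.components) < self.tier_rule.adverse_min:
            warnings.warn(
                f"score range is [0, {len(self.components)}]; the adverse tier "
                f"(count >= {self.tier_rule.adverse_min}) is unattainable",
                stacklevel=2,
            )

    @property
    def genes(self) -> list[str]:
        return [c.gene for c in self.components]

    @property
    def score_range(self) -> tuple[int, int]:
        return (0, len(self.components))


@dataclass
class RiskAssignment:
    """Per-patient integer score and tier (a deterministic function of score)."""

    patient_ids: list[str]
    scores: np.ndarray
    tiers: list[str]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"patient_id": self.patient_ids, "score": self.scores, "tier": self.tiers}
        )

    def to_tsv(self, path) -> None:
        self.frame().to_csv(path, sep="\t", index=False)

    def tier_members(self, tier: str) -> np.ndarray:
        return np.array([t == tier for t in self.tiers], dtype=bool)


# ---------------------------------------------------------------------------
# Serialization (JSON schema; round-trips cutpoints at full precision)
# ---------------------------------------------------------------------------

def write_model(model: MBSModel, path) -> None:
    payload = {
        "schema_version": _SCHEMA_VERSION,
        "kind": "molecular-based-score",
        "metric": model.metric,
        "alpha": model.alpha,
        "confounders": list(model.confounders),
        "tier_rule": {
            "intermediate_min": model.tier_rule.intermediate_min,
            "adverse_min": model.tier_rule.adverse_min,
        },
        "components": [
            {"gene": c.gene, "cutpoint": c.cutpoint, "direction": c.direction}
            for c in model.components
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_model(path) -> MBSModel:
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"model file {path} is not valid JSON: {exc}") from exc
    if payload.get("schema_version") != _SCHEMA_VERSION:
        raise ModelFormatError(
            f"unsupported model schema version {payload.get('schema_version')!r}"
        )
    try:
        components = tuple(
            MBSComponent(
                gene=str(c["gene"]),
                cutpoint=float(c["cutpoint"]),
                direction=c["direction"],
            )
            for c in payload["components"]
        )
        rule = TierRule(
            intermediate_min=int(payload["tier_rule"]["intermediate_min"]),
            adverse_min=int(payload["tier_rule"]["adverse_min"]),
        )
        model = MBSModel(
            components=components,
            tier_rule=rule,
            alpha=float(payload["alpha"]),
            metric=str(payload["metric"]),
            confounders=tuple(payload["confounders"]),
        )
    except (KeyError, TypeError, ValueError, ValidationError) as exc:
        raise ModelFormatError(f"model file {path} is invalid: {exc}") from exc
    return model
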