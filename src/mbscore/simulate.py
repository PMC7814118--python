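"""Synthetic MDS-like cohort generator.

Emulates the statistical structure the scoring pipeline assumes: a panel of
cellular-energetics genes measured as log-scale expression in CD34+ cells, a
small subset of which carries a true proportional-hazards effect expressed
through a threshold on expression; right-censored overall survival; and
correlated clinical confounders (age, gender, IPSS-R category) with effects
of their own.

The generative model is a Cox model with an exponential baseline hazard: per
patient, ``h = lambda0 * exp(sum_g beta_g * z_g + confounder terms)`` where
``z_g`` indicates expression on the risk side of the population ``q_g``
quantile; survival is exponential with rate ``h``, censoring the minimum of
an independent exponential and an administrative horizon.  Expression
marginals are Gaussian with unit variance on the log scale — the pipeline
only uses thresholds, so heavier tails would change nothing downstream.
Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps

from .errors import ConfigError
from .io import ClinicalRecord, Cohort, ExpressionMatrix, IPSSR_LEVELS
from .model import DIRECTIONS, HIGH_IS_RISK, LOW_IS_RISK

import pandas as pd

# The 37-gene cellular-energetics panel (glycolysis, TCA cycle, OXPHOS and
# supporting metabolism) interrogated by the score.
GENE_PANEL: tuple[str, ...] = (
    "ABAT", "ACLY", "ANPEP", "CAT", "CS", "DPYD", "ERCC2", "FASN", "GAD1",
    "GGCT", "GOT2", "GPX1", "GSR", "GSS", "GSTM1", "HK1", "HK2", "IDH1",
    "IDH2", "IDH3A", "IDH3B", "IDH3G", "LDHA", "LDHB", "MDH2", "ME1", "OGDH",
    "PANK1", "PFKL", "PFKP", "PKM", "PKMYT1", "SCD", "SDHA", "SLC25A5",
    "SLC2A5", "TALDO1",
)

# Reference five-gene signature: risky state is high expression for ANPEP and
# PKM, low expression for ACLY, PANK1 and SLC25A5.
REFERENCE_SIGNATURE: tuple[tuple[str, str], ...] = (
    ("ACLY", LOW_IS_RISK),
    ("ANPEP", HIGH_IS_RISK),
    ("PANK1", LOW_IS_RISK),
    ("PKM", HIGH_IS_RISK),
    ("SLC25A5", LOW_IS_RISK),
)

# IPSS-R category frequencies of the emulated cohort (very-low ... very-high).
IPSSR_FREQS: tuple[float, ...] = (27 / 159, 53 / 159, 44 / 159, 23 / 159, 12 / 159)


@dataclass(frozen=True)
class PrognosticGene:
    """One truly prognostic gene in the generative model."""

    index: int
    direction: str
    beta: float
    quantile: float = 0.5

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise ConfigError(f"unknown direction {self.direction!r}")
        if not 0.0 < self.quantile < 1.0:
            raise ConfigError(f"risk-threshold quantile must be in (0,1): {self.quantile}")


def default_prognostic_spec(beta: float = 0.8, risk_fraction: float = 0.28):
    """The reference five-gene signature as a generative spec.

    ``risk_fraction`` is the population prevalence of the risky expression
    state per gene; 0.28 reproduces a favourable/intermediate/adverse split
    near 18/38/44% for five independent components (counts ~ Binomial(5, p)).
    The threshold quantile is ``1 - p`` for high-risk genes and ``p`` for
    low-risk genes.
    """
    return tuple(
        PrognosticGene(
            index=GENE_PANEL.index(gene),
            direction=direction,
            beta=beta,
            quantile=(1.0 - risk_fraction) if direction == HIGH_IS_RISK else risk_fraction,
        )
        for gene, direction in REFERENCE_SIGNATURE
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for a synthetic cohort.

    Units: hazards are events per month, ``admin_horizon`` months, age years.
    Defaults emulate a mid-size MDS cohort: five truly prognostic genes with
    |log HR| = 0.8 and a risky-state prevalence of 0.28 each; baseline hazard
    0.003/month so the cohort-level median survival lands near 50 months once
    risk-factor and confounder effects are applied; random censoring at
    0.006/month plus a 120-month administrative horizon; age ~ N(67, 10)
    truncated to [19, 87]; roughly two-thirds male; IPSS-R drawn from the
    cohort frequencies with a monotone effect on the log hazard; and an age
    effect of 0.03 per year (hazard +3%/year).
    """

    n_patients: int
    n_genes: int = 37
    prognostic_spec: tuple[PrognosticGene, ...] = field(
        default_factory=default_prognostic_spec
    )
    baseline_hazard: float = 0.003
    censor_rate: float = 0.006
    admin_horizon: float = 120.0
    age_effect: float = 0.03
    male_effect: float = 0.0
    ipssr_effects: tuple[float, ...] = (0.0, 0.2, 0.5, 0.8, 1.1)
    n_healthy: int = 0
    healthy_shift: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.n_patients <= 0:
            raise ConfigError("n_patients must be positive")
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be > 0")
        if self.censor_rate < 0:
            raise ConfigError("censor_rate must be >= 0")
        if len(self.ipssr_effects) != len(IPSSR_LEVELS):
            raise ConfigError("ipssr_effects must have five entries")
        idxs = [g.index for g in self.prognostic_spec]
        if len(set(idxs)) != len(idxs):
            raise ConfigError("prognostic gene indices must be distinct")
        if any(i < 0 or i >= self.n_genes for i in idxs):
            raise ConfigError("prognostic gene index out of range")

    def gene_names(self) -> list[str]:
        if self.n_genes <= len(GENE_PANEL):
            return list(GENE_PANEL[: self.n_genes])
        return list(GENE_PANEL) + [
            f"GENE{i:03d}" for i in range(len(GENE_PANEL), self.n_genes)
        ]


@dataclass
class GroundTruth:
    """What the generator knows: the true gene set, thresholds and states."""

    genes: list[str]
    directions: list[str]
    cutpoints: list[float]
    betas: list[float]
    risk_indicators: np.ndarray  # patients x prognostic genes
    risk_counts: np.ndarray
    event_labels: np.ndarray

    def cutpoint_map(self) -> dict[str, tuple[float, str]]:
        return {
            g: (c, d)
            for g, c, d in zip(self.genes, self.cutpoints, self.directions)
        }


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, GroundTruth]:
    """Draw one cohort (and its ground truth) from the generative model."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    genes = config.gene_names()

    gene_means = rng.normal(7.0, 1.0, size=config.n_genes)
    expr = gene_means[:, None] + rng.normal(0.0, 1.0, size=(config.n_genes, n))

    # confounders
    a, b = (19.0 - 67.0) / 10.0, (87.0 - 67.0) / 10.0
    age = sps.truncnorm.rvs(a, b, loc=67.0, scale=10.0, size=n, random_state=rng)
    male = rng.random(n) < 102 / 159
    ipssr_idx = rng.choice(len(IPSSR_LEVELS), size=n, p=np.array(IPSSR_FREQS))

    # true risk indicators from population quantiles (config constants)
    k = len(config.prognostic_spec)
    z = np.zeros((n, k), dtype=int)
    cutpoints, directions, names, betas = [], [], [], []
    eta = (
        config.age_effect * (age - 67.0)
        + config.male_effect * male.astype(float)
        + np.asarray(config.ipssr_effects)[ipssr_idx]
    )
    for j, pg in enumerate(config.prognostic_spec):
        cut = gene_means[pg.index] + sps.norm.ppf(pg.quantile)
        high = expr[pg.index] > cut
        zj = high if pg.direction == HIGH_IS_RISK else ~high
        z[:, j] = zj.astype(int)
        eta = eta + pg.beta * z[:, j]
        cutpoints.append(float(cut))
        directions.append(pg.direction)
        names.append(genes[pg.index])
        betas.append(pg.beta)

    hazard = config.baseline_hazard * np.exp(eta)
    surv_time = rng.exponential(1.0 / hazard)
    if config.censor_rate > 0:
        censor = rng.exponential(1.0 / config.censor_rate, size=n)
    else:
        censor = np.full(n, np.inf)
    censor = np.minimum(censor, config.admin_horizon)
    os_time = np.minimum(surv_time, censor)
    os_event = (surv_time <= censor).astype(int)
    if not np.all(np.isfinite(os_time)):
        raise ConfigError(
            "censor_rate = 0 requires a finite admin_horizon"
        )

    patient_ids = [f"P{i + 1:04d}" for i in range(n)]
    clinical = [
        ClinicalRecord(
            patient_id=patient_ids[i],
            os_time=float(os_time[i]),
            os_event=int(os_event[i]),
            age=float(age[i]),
            gender="male" if male[i] else "female",
            ipssr=IPSSR_LEVELS[ipssr_idx[i]],
            group_label="patient",
        )
        for i in range(n)
    ]
    columns = list(patient_ids)
    values = expr

    if config.n_healthy > 0:
        expr_hd = gene_means[:, None] + rng.normal(
            0.0, 1.0, size=(config.n_genes, config.n_healthy)
        )
        # roughly half the panel is shifted in healthy donors, random sign
        shifted = rng.random(config.n_genes) < 0.5
        signs = rng.choice([-1.0, 1.0], size=config.n_genes)
        expr_hd += (shifted * signs * config.healthy_shift)[:, None]
        hd_ids = [f"HD{i + 1:03d}" for i in range(config.n_healthy)]
        columns += hd_ids
        values = np.concatenate([values, expr_hd], axis=1)
        clinical += [
            ClinicalRecord(
                patient_id=hid,
                os_time=config.admin_horizon if np.isfinite(config.admin_horizon) else 120.0,
                os_event=0,
                group_label="healthy-donor",
            )
            for hid in hd_ids
        ]

    frame = pd.DataFrame(values, index=genes, columns=columns)
    cohort = Cohort(expression=ExpressionMatrix(frame), clinical=clinical)
    truth = GroundTruth(
        genes=names,
        directions=directions,
        cutpoints=cutpoints,
        betas=betas,
        risk_indicators=z,
        risk_counts=z.sum(axis=1),
        event_labels=os_event,
    )
    return cohort, truth


def simulate_null_cohort(
    n: int,
    n_genes: int = 37,
    seed: int = 0,
    baseline_hazard: float = 0.008,
    censor_rate: float = 0.004,
    admin_horizon: float = 120.0,
) -> Cohort:
    """All-null shortcut: no gene carries an effect and confounders are inert,
    so survival is homogeneous exponential.  Used for type-I-error studies."""
    config = SimulationConfig(
        n_patients=n,
        n_genes=n_genes,
        prognostic_spec=(),
        baseline_hazard=baseline_hazard,
        censor_rate=censor_rate,
        admin_horizon=admin_horizon,
        age_effect=0.0,
        male_effect=0.0,
        ipssr_effects=(0.0, 0.0, 0.0, 0.0, 0.0),
        seed=seed,
    )
    cohort, _ = simulate_cohort(config)
    return cohort


def null_config(config: SimulationConfig) -> SimulationConfig:
    """A copy of ``config`` with every effect zeroed (same seed and sizes)."""
    return replace(
        config,
        prognostic_spec=(),
        age_effect=0.0,
        male_effect=0.0,
        ipssr_effects=(0.0, 0.0, 0.0, 0.0, 0.0),
    )
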