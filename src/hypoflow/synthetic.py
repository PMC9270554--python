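"""Synthetic data with known ground truth for every pipeline stage.

Three generators emulate the study's three data modalities:

* **Flow cytometry** — per-cell events drawn from a four-population
  log-normal mixture (dead Q1, live high-MMP Q2, live-apoptotic Q3, live
  collapsed-MMP Q4) whose mixture weights follow a median-effect
  dose-response with known slope and median-effect dose.  20,000 events per
  sample by default, matching the acquisition depth of the assay being
  emulated.
* **RNA-seq counts** — negative-binomial gene x sample count matrices for a
  3-vs-3 hypoxia/normoxia design with a planted fraction of differentially
  expressed genes at a known log2 fold change.
* **Patient cohort** — log-expression profiles over a gene signature for a
  three-class cohort (62 chronic-phase, 17 accelerated-phase, 32
  blast-crisis patients by default).  Blast-crisis columns carry a planted
  per-gene class effect; accelerated-phase patients are a two-component
  mixture of CP-like and BC-like profiles (default 46% BC-like), matching
  the observed heterogeneity of that clinical category.  An environment
  contrast vector can be calibrated to a target Spearman correlation with
  the class effect, emulating the inverse plasticity/reprogramming
  relationship.

All generators are deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .enrichment import ExpressionMatrix
from .flow import CHANNELS, QUADRANTS, EventTable


# ---------------------------------------------------------------------------
# flow cytometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationSpec:
    """Log-normal intensity model for one quadrant phenotype.

    ``channel_location`` is the median intensity per channel (arbitrary
    units); ``channel_cv`` the coefficient of variation of the log-normal
    intensity distribution, so the log-scale sigma is sqrt(ln(1 + cv^2)).
    """

    role: str
    channel_location: Mapping[str, float]
    channel_cv: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.role not in QUADRANTS:
            raise ValueError(f"role must be one of {QUADRANTS}, got {self.role!r}")
        for ch in CHANNELS:
            if self.channel_location.get(ch, 0) <= 0:
                raise ValueError(f"{self.role}: channel_location[{ch}] must be > 0")
            if self.channel_cv.get(ch, 0) <= 0:
                raise ValueError(f"{self.role}: channel_cv[{ch}] must be > 0")


def default_populations() -> tuple[PopulationSpec, ...]:
    """Well-separated quadrant phenotypes on a four-decade intensity scale.

    Q1 dead: PI bright, MMP lost; Q2 live: NAO and TMRE bright; Q3 live
    apoptotic: NAO dim (oxidized cardiolipin), PI negative; Q4 live with
    collapsed MMP: NAO bright, TMRE dim.  Dead cells are smaller/more
    granular on scatter.
    """
    cv = {ch: 0.4 for ch in CHANNELS}

    def loc(fsc, ssc, fl1, fl2, fl3):
        return dict(zip(CHANNELS, (fsc, ssc, fl1, fl2, fl3)))

    return (
        PopulationSpec("Q1", loc(400, 500, 2000, 60, 5000), cv),
        PopulationSpec("Q2", loc(1000, 600, 5000, 3000, 30), cv),
        PopulationSpec("Q3", loc(700, 550, 100, 120, 30), cv),
        PopulationSpec("Q4", loc(1000, 600, 5000, 80, 30), cv),
    )


@dataclass(frozen=True)
class FlowSimConfig:
    """Ground-truth description of a simulated drug/environment condition.

    The planted affected fraction at dose D composes an environment baseline
    with the drug's median-effect curve Fa_drug(D) = 1/(1 + (Dm/D)^m):

    * mode "cytotoxic":  fa = baseline_fa + (1 - baseline_fa) * Fa_drug(D)
    * mode "rescue":     fa = baseline_fa * (1 - Fa_drug(D)), i.e. the drug
      rescues a fraction of the environment-killed cells (the curve plays
      the role of a rescue fraction R(D)).

    Affected cells split q1_q3_split : (1 - q1_q3_split) between dead (Q1)
    and live-apoptotic (Q3); unaffected cells split q2_q4_split between
    high-MMP (Q2) and collapsed-MMP (Q4).
    """

    populations: tuple[PopulationSpec, ...] = field(default_factory=default_populations)
    truth_m: float = 2.0
    truth_Dm: float = 10.0
    q1_q3_split: float = 0.6
    q2_q4_split: float = 0.8
    baseline_fa: float = 0.0
    n_events: int = 20000
    mode: str = "cytotoxic"
    drug: str = "drug"
    environment: str = "normoxia"
    dose_unit: str = "uM"

    def __post_init__(self) -> None:
        roles = sorted(p.role for p in self.populations)
        if roles != sorted(QUADRANTS):
            raise ValueError(
                f"need exactly one population per quadrant {QUADRANTS}, got roles {roles}"
            )
        for name in ("q1_q3_split", "q2_q4_split", "baseline_fa"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.truth_m <= 0 or self.truth_Dm <= 0:
            raise ValueError("truth_m and truth_Dm must be > 0")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if self.mode not in ("cytotoxic", "rescue"):
            raise ValueError(f"mode must be 'cytotoxic' or 'rescue', got {self.mode!r}")

    def population(self, role: str) -> PopulationSpec:
        return next(p for p in self.populations if p.role == role)


@dataclass
class FlowTruth:
    """Planted ground truth for one simulated sample."""

    dose: float
    fa: float
    weights: Mapping[str, float]  # quadrant mixture weights, sum to 1


def planted_fa(config: FlowSimConfig, dose: float) -> float:
    """Exact planted affected fraction at a dose (on the median-effect
    curve, composed with the environment baseline per config.mode)."""
    if dose < 0:
        raise ValueError(f"dose must be >= 0, got {dose}")
    fa_drug = 0.0 if dose == 0 else 1.0 / (1.0 + (config.truth_Dm / dose) ** config.truth_m)
    if config.mode == "cytotoxic":
        return config.baseline_fa + (1 - config.baseline_fa) * fa_drug
    return config.baseline_fa * (1 - fa_drug)


def _quadrant_weights(config: FlowSimConfig, fa: float) -> dict[str, float]:
    return {
        "Q1": fa * config.q1_q3_split,
        "Q3": fa * (1 - config.q1_q3_split),
        "Q2": (1 - fa) * config.q2_q4_split,
        "Q4": (1 - fa) * (1 - config.q2_q4_split),
    }


def gen_flow_sample(
    config: FlowSimConfig, dose: float, seed: int, replicate: int = 1
) -> tuple[EventTable, FlowTruth]:
    """Draw one event table of ``config.n_events`` cells at a dose.

    Each event is assigned a quadrant by the exact planted mixture weights
    and its five channel intensities are drawn log-normally from that
    quadrant's population spec.  Identical (config, dose, seed) gives a
    bit-identical table.
    """
    fa = planted_fa(config, dose)
    weights = _quadrant_weights(config, fa)
    rng = np.random.default_rng(seed)
    roles = list(QUADRANTS)
    assignment = rng.choice(len(roles), size=config.n_events, p=[weights[q] for q in roles])
    data = np.empty((config.n_events, len(CHANNELS)))
    for qi, role in enumerate(roles):
        idx = np.flatnonzero(assignment == qi)
        if idx.size == 0:
            continue
        pop = config.population(role)
        for ci, ch in enumerate(CHANNELS):
            mu = np.log(pop.channel_location[ch])
            sigma = np.sqrt(np.log(1 + pop.channel_cv[ch] ** 2))
            data[idx, ci] = rng.lognormal(mean=mu, sigma=sigma, size=idx.size)
    events = EventTable(
        data=pd.DataFrame(data, columns=list(CHANNELS)),
        drug=config.drug,
        dose=dose,
        dose_unit=config.dose_unit,
        environment=config.environment,
        replicate=replicate,
    )
    return events, FlowTruth(dose=dose, fa=fa, weights=weights)


def derive_seed(master_seed: int, index: int) -> int:
    """Deterministic child seed for sample ``index`` of a series, below 2**31.
    Derived so that adding a dose to a series never perturbs earlier samples."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2**31))


def gen_dose_series(
    config: FlowSimConfig, doses: Sequence[float], seed: int
) -> tuple[list[EventTable], pd.DataFrame]:
    """One sample per dose with per-dose derived seeds.

    Duplicate doses are allowed (technical replicates) and numbered in the
    replicate column of the truth table.  Returns the event tables and a
    truth table of planted fa per dose.
    """
    if len(doses) == 0:
        raise ValueError("dose list must be non-empty")
    if any(d < 0 for d in doses):
        raise ValueError("doses must be >= 0")
    tables, truth_rows = [], []
    seen: dict[float, int] = {}
    for i, dose in enumerate(doses):
        seen[dose] = seen.get(dose, 0) + 1
        ev, truth = gen_flow_sample(
            config, dose, derive_seed(seed, i), replicate=seen[dose]
        )
        tables.append(ev)
        truth_rows.append(
            {"dose": dose, "replicate": seen[dose], "fa": truth.fa, **truth.weights}
        )
    return tables, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CountSimConfig:
    """Negative-binomial count simulation for a two-group design.

    Gene baseline abundances are log-normal (natural-log mean/sd of the
    mean count); a ``de_fraction`` of genes receive a +/- ``logfc_magnitude``
    log2 shift in group 1 (hypoxia); counts have variance
    mu + dispersion * mu^2; per-sample library-size factors are log-normal.
    """

    n_genes: int = 2000
    n_per_group: int = 3
    baseline_log_mean: float = 4.0
    baseline_log_sd: float = 1.5
    dispersion: float = 0.05
    de_fraction: float = 0.05
    logfc_magnitude: float = 2.0
    library_size_factor_sd: float = 0.1
    group1: str = "hypoxia"
    group2: str = "normoxia"

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2 (a group SD is needed)")


def gen_rnaseq_counts(
    config: CountSimConfig, seed: int
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a count matrix with planted differential expression.

    Returns the counts (genes x 2*n_per_group, group-1 columns first) and a
    truth table with one row per gene: is_de flag and signed planted log2
    fold change (group 1 over group 2).
    """
    rng = np.random.default_rng(seed)
    g, npg = config.n_genes, config.n_per_group
    genes = [f"g{i + 1:05d}" for i in range(g)]
    base = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=g)
    n_de = int(round(config.de_fraction * g))
    de_idx = rng.choice(g, size=n_de, replace=False)
    sign = rng.choice([-1.0, 1.0], size=n_de)
    log2fc = np.zeros(g)
    log2fc[de_idx] = sign * config.logfc_magnitude
    # split the fold change symmetrically so DE does not inflate abundance
    mu1 = base * 2.0 ** (log2fc / 2)
    mu2 = base * 2.0 ** (-log2fc / 2)
    sf = rng.lognormal(0.0, config.library_size_factor_sd, size=2 * npg)
    mu = np.concatenate(
        [np.outer(mu1, sf[:npg]), np.outer(mu2, sf[npg:])], axis=1
    )
    if config.dispersion > 0:
        shape = 1.0 / config.dispersion
        lam = rng.gamma(shape, mu * config.dispersion)
    else:
        lam = mu
    counts = rng.poisson(lam)
    cols = [f"{config.group1}_{i + 1}" for i in range(npg)] + [
        f"{config.group2}_{i + 1}" for i in range(npg)
    ]
    groups = pd.Series([config.group1] * npg + [config.group2] * npg, index=cols)
    matrix = ExpressionMatrix(
        values=pd.DataFrame(counts, index=genes, columns=cols),
        groups=groups,
        mode="counts",
    )
    truth = pd.DataFrame(
        {"gene": genes, "is_de": log2fc != 0, "log2fc": log2fc}
    ).set_index("gene")
    return matrix, truth


# ---------------------------------------------------------------------------
# patient cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSimConfig:
    """Three-class patient cohort over a gene signature.

    CP columns follow a per-gene baseline profile; BC columns are shifted by
    ``class_effect`` (log2 units); each AP patient is BC-like with
    probability ``ap_mixture_fraction`` and CP-like otherwise (a mixture,
    not an intermediate mean, reflecting the observed split of that class).
    ``env_effect`` is an independent hypoxia-vs-normoxia contrast vector
    emitted alongside for correlation analyses; see
    ``calibrate_env_effect`` for planting a target rank correlation.
    """

    signature_genes: tuple[str, ...]
    class_effect: tuple[float, ...]
    env_effect: tuple[float, ...]
    n_cp: int = 62
    n_ap: int = 17
    n_bc: int = 32
    ap_mixture_fraction: float = 0.46
    noise_sd: float = 1.0
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0

    def __post_init__(self) -> None:
        g = len(self.signature_genes)
        if g == 0:
            raise ValueError("signature_genes must be non-empty")
        if len(set(self.signature_genes)) != g:
            raise ValueError("signature_genes must be unique")
        if len(self.class_effect) != g or len(self.env_effect) != g:
            raise ValueError(
                "class_effect and env_effect must match signature_genes in length"
            )
        if not 0 <= self.ap_mixture_fraction <= 1:
            raise ValueError("ap_mixture_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class CohortTruth:
    ap_origin: pd.Series  # per-AP-sample origin: "BC-like" or "CP-like"
    origin: pd.Series  # per-sample planted profile origin ("CP" or "BC")
    class_effect: pd.Series
    env_effect: pd.Series


def gen_patient_cohort(
    config: CohortSimConfig, seed: int
) -> tuple[ExpressionMatrix, pd.Series, CohortTruth]:
    """Simulate the signature x patient log-expression matrix.

    Returns (matrix in log mode, clinical labels CP/AP/BC per sample, truth
    with per-AP-patient profile origin and the planted effect vectors).
    """
    rng = np.random.default_rng(seed)
    genes = list(config.signature_genes)
    g = len(genes)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=g)
    ce = np.asarray(config.class_effect, dtype=float)
    labels, origins = [], []
    for _ in range(config.n_cp):
        labels.append("CP"); origins.append("CP")
    for _ in range(config.n_ap):
        labels.append("AP")
        origins.append("BC" if rng.random() < config.ap_mixture_fraction else "CP")
    for _ in range(config.n_bc):
        labels.append("BC"); origins.append("BC")
    cols = [f"P{i + 1:03d}" for i in range(len(labels))]
    means = np.column_stack(
        [baseline + (ce if o == "BC" else 0.0) for o in origins]
    )
    values = means + rng.normal(0.0, config.noise_sd, size=means.shape)
    label_s = pd.Series(labels, index=cols, name="label")
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=cols),
        groups=label_s,
        mode="log",
    )
    origin_s = pd.Series(origins, index=cols, name="origin")
    ap_cols = [c for c, l in zip(cols, labels) if l == "AP"]
    truth = CohortTruth(
        ap_origin=origin_s[ap_cols].map({"BC": "BC-like", "CP": "CP-like"}),
        origin=origin_s,
        class_effect=pd.Series(ce, index=genes),
        env_effect=pd.Series(np.asarray(config.env_effect, float), index=genes),
    )
    return matrix, label_s, truth


def calibrate_env_effect(
    class_effect: Sequence[float],
    target_rho: float,
    seed: int,
    scale: float = 1.0,
) -> np.ndarray:
    """Construct an environment contrast with a target Spearman correlation
    against the class contrast.

    Uses a Gaussian copula: the class effect is mapped to normal scores via
    its ranks, mixed with independent Gaussian noise at Pearson correlation
    c = 2*sin(pi*target_rho/6) — the inverse of the bivariate-normal
    Spearman relation rho_S = (6/pi)*asin(c/2) — so the population Spearman
    correlation of the pair equals ``target_rho``.
    """
    if not -1 < target_rho < 1:
        raise ValueError("target_rho must lie in (-1, 1)")
    ce = np.asarray(class_effect, dtype=float)
    n = len(ce)
    ranks = pd.Series(ce).rank().to_numpy()
    z = norm.ppf((ranks - 0.5) / n)
    z = (z - z.mean()) / z.std()
    c = 2.0 * np.sin(np.pi * target_rho / 6.0)
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(n)
    eps = (eps - eps.mean()) / eps.std()
    # remove the component of eps along z so the mixing correlation is exact
    eps = eps - (eps @ z) / (z @ z) * z
    eps = eps / eps.std()
    return scale * (c * z + np.sqrt(1 - c**2) * eps)


def default_cohort_config(seed: int = 0, target_rho: float = -0.41) -> CohortSimConfig:
    """Study-shaped cohort: 62/17/32 CP/AP/BC patients, a 25-gene
    signature with per-gene class effects of SD 1.5 log2 units, unit noise,
    46% of AP patients BC-like, and an environment contrast calibrated to
    the target Spearman correlation with the class contrast."""
    rng = np.random.default_rng(seed)
    genes = tuple(f"MP{i + 1:02d}" for i in range(25))
    class_effect = rng.normal(0.0, 1.5, size=25)
    env_effect = calibrate_env_effect(class_effect, target_rho, seed=seed + 1, scale=1.0)
    return CohortSimConfig(
        signature_genes=genes,
        class_effect=tuple(class_effect),
        env_effect=tuple(env_effect),
    )
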