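"""Synthetic GWAS summary statistics and synthetic cohorts with known truth.

The GWAS generator draws three *disjoint* individual-level samples
(exposure, mediator, outcome) under a configurable causal chain

    X  ->  M  ->  Y        with direct path X -> Y and an unmeasured
    confounder U acting on all three,

and produces per-SNP summary statistics by actually regressing the
simulated phenotypes on the simulated genotypes within the appropriate
sample (single-SNP linear regressions; logistic for a binary outcome).
Summary statistics therefore carry realistic SE/p structure, including
weak-instrument behaviour, rather than being true effects plus noise.

Instrument SNPs are drawn in linkage equilibrium (independent binomial
genotypes); pleiotropy enters as per-SNP effects delta_j on the mediator,
reaching the outcome through the mediator path, drawn independently of the
instrument effects so the InSIDE condition holds.

The cohort generator emulates the observational arm: a Weibull
proportional-hazards event-time model with a binary exposure category, a
continuous mediator on the causal path, and a block of baseline
confounders, administratively censored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from bevmr.io_config import ConfigurationError, SummaryDataset

_ALLELE_PAIRS = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")]  # non-palindromic


@dataclass
class GwasSimConfig:
    """Generative parameters for the three-sample summary-statistic study.

    ``h2_x`` is split equally across the ``m_snps`` instruments; each
    gamma_j has magnitude sqrt(h2_x / (m * 2 p_j (1-p_j))) and random sign.
    ``pleiotropy_mode``: 'none', 'balanced' (delta_j ~ N(0, sd^2)) or
    'directional' (delta_j ~ N(sd, (sd/2)^2) on the exposure-increasing
    allele orientation, i.e. a nonzero-mean direct path).
    """

    m_snps: int = 50
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_exposure: int = 50_000
    n_mediator: int = 50_000
    n_outcome: int = 50_000
    beta_causal_xy: float = 0.3
    beta_xm: float = 0.0
    beta_my: float = 0.0
    pleiotropy_mode: str = "none"
    pleiotropy_sd: float = 0.0
    h2_x: float = 0.3
    m_snps_mediator: int = 0
    h2_m: float = 0.3
    outcome_type: str = "continuous"
    seed: int = 0
    confounding: float = 0.3  # share of non-genetic X variance from U

    def __post_init__(self) -> None:
        if self.m_snps < 1:
            raise ConfigurationError("m_snps must be >= 1")
        if self.m_snps_mediator < 0:
            raise ConfigurationError("m_snps_mediator must be >= 0")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        m_tot = self.m_snps + self.m_snps_mediator
        for name in ("n_exposure", "n_mediator", "n_outcome"):
            if getattr(self, name) <= m_tot:
                raise ConfigurationError(f"{name} must exceed the total SNP count")
        if not 0 < self.h2_x < 1:
            raise ConfigurationError(
                f"infeasible h2_x={self.h2_x}: must be in (0, 1) so residual "
                "phenotype variance stays positive"
            )
        if self.m_snps_mediator and not 0 < self.h2_m < 1:
            raise ConfigurationError("h2_m must be in (0, 1)")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ConfigurationError(
                f"unknown pleiotropy_mode {self.pleiotropy_mode!r}"
            )
        if self.pleiotropy_sd < 0:
            raise ConfigurationError("pleiotropy_sd must be nonnegative")
        if self.outcome_type not in ("continuous", "binary"):
            raise ConfigurationError(f"unknown outcome_type {self.outcome_type!r}")
        if not 0 <= self.confounding < 1:
            raise ConfigurationError("confounding must be in [0, 1)")


@dataclass
class CohortSimConfig:
    """Generative parameters for the synthetic survival cohort.

    Defaults emulate the study conditions of an elderly female cohort with
    a low-prevalence beverage exposure: ~13.6k subjects, ~11% exposed,
    15 years of administrative follow-up, a rare outcome (~2% cumulative
    incidence), 16 standard-normal baseline confounders, and a mediator
    carrying ~22% of the total log-hazard effect.
    """

    n_subjects: int = 13_567
    exposure_prevalence: float = 0.11
    hr_direct: float = 1.43
    mediator_effect_on_hazard: float = 0.26
    exposure_effect_on_mediator: float = 0.4
    baseline_scale: float = 580.0
    baseline_shape: float = 1.1
    censor_time: float = 15.0
    confounder_count: int = 16
    confounder_effect_mediator: float = 0.1
    confounder_effect_hazard: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        if not 0 < self.exposure_prevalence < 1:
            raise ConfigurationError("exposure_prevalence must be in (0, 1)")
        if self.hr_direct <= 0:
            raise ConfigurationError("hr_direct must be positive")
        if self.censor_time <= 0:
            raise ConfigurationError("censor_time must be positive")
        if self.baseline_scale <= 0 or self.baseline_shape <= 0:
            raise ConfigurationError("Weibull baseline parameters must be positive")
        if self.confounder_count < 0:
            raise ConfigurationError("confounder_count must be nonnegative")


def _single_snp_linear(G: np.ndarray, y: np.ndarray):
    """Per-SNP simple linear regression (with intercept), vectorized.

    Returns (beta, se, p) arrays of length m for genotype matrix G (n x m).
    """
    n = len(y)
    gbar = G.mean(axis=0)
    ybar = y.mean()
    yc = y - ybar
    sxx = np.einsum("ij,ij->j", G, G) - n * gbar**2
    sxy = G.T @ yc  # sum (g - gbar)(y - ybar) = g'yc because yc sums to zero
    beta = sxy / sxx
    syy = float(yc @ yc)
    sigma2 = (syy - beta * sxy) / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return beta, se, p


def _single_snp_logistic(G: np.ndarray, y: np.ndarray, n_iter: int = 25):
    """Per-SNP two-parameter logistic regressions, Newton-Raphson vectorized.

    Fits logit P(y=1) = a_j + b_j g_j independently for every SNP j.
    """
    n, m = G.shape
    a = np.full(m, logit(np.clip(y.mean(), 1e-9, 1 - 1e-9)))
    b = np.zeros(m)
    for _ in range(n_iter):
        eta = a[None, :] + b[None, :] * G
        mu = expit(eta)
        r = y[:, None] - mu
        wt = mu * (1.0 - mu)
        ga = r.sum(axis=0)
        gb = np.einsum("ij,ij->j", G, r)
        haa = wt.sum(axis=0)
        hab = np.einsum("ij,ij->j", G, wt)
        hbb = np.einsum("ij,ij,ij->j", G, G, wt)
        det = haa * hbb - hab**2
        da = (hbb * ga - hab * gb) / det
        db = (haa * gb - hab * ga) / det
        a += da
        b += db
        if max(np.abs(da).max(), np.abs(db).max()) < 1e-10:
            break
    eta = a[None, :] + b[None, :] * G
    wt = expit(eta) * (1.0 - expit(eta))
    haa = wt.sum(axis=0)
    hab = np.einsum("ij,ij->j", G, wt)
    hbb = np.einsum("ij,ij,ij->j", G, G, wt)
    se = np.sqrt(haa / (haa * hbb - hab**2))
    p = 2.0 * stats.norm.sf(np.abs(b / se))
    return b, se, p


def _summary_frame(snp_meta: pd.DataFrame, G, beta, se, p, n) -> pd.DataFrame:
    df = snp_meta.copy()
    df["eaf"] = G.mean(axis=0) / 2.0
    df["beta"] = beta
    df["se"] = se
    df["p"] = p
    df["n"] = float(n)
    return df


def simulate_gwas(config: GwasSimConfig):
    """Generate exposure, mediator and outcome summary datasets plus truth.

    Returns ``(exposure, mediator, outcome, truth)`` where the three
    :class:`SummaryDataset` objects come from disjoint samples and
    ``truth`` records the generative parameters, including the implied
    total exposure-outcome effect ``beta_causal_xy + beta_xm * beta_my``
    and the true mediated proportion.
    """
    rng = np.random.default_rng(config.seed)
    m_x = config.m_snps
    m_m = config.m_snps_mediator
    m = m_x + m_m

    maf = rng.uniform(*config.maf_range, size=m)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    snp_meta = pd.DataFrame(
        {
            "snp_id": [f"rs{j + 1}" for j in range(m)],
            "chrom": "1",
            "pos": [(j + 1) * 1_000_000 for j in range(m)],
            "effect_allele": [_ALLELE_PAIRS[i][0] for i in pair_idx],
            "other_allele": [_ALLELE_PAIRS[i][1] for i in pair_idx],
        }
    )

    geno_var = 2.0 * maf * (1.0 - maf)
    # first block instruments the exposure; second block (optional) acts
    # directly on the mediator so two-step MR has mediator-specific
    # instruments, as real anthropo-metabolic traits do
    gamma = np.zeros(m)
    gamma[:m_x] = rng.choice([-1.0, 1.0], size=m_x) * np.sqrt(
        config.h2_x / (m_x * geno_var[:m_x])
    )
    kappa = np.zeros(m)
    if m_m:
        kappa[m_x:] = rng.choice([-1.0, 1.0], size=m_m) * np.sqrt(
            config.h2_m / (m_m * geno_var[m_x:])
        )

    delta = np.zeros(m)
    if config.pleiotropy_sd > 0.0 and config.pleiotropy_mode == "balanced":
        delta[:m_x] = rng.normal(0.0, config.pleiotropy_sd, size=m_x)
    elif config.pleiotropy_sd > 0.0 and config.pleiotropy_mode == "directional":
        # directional: nonzero mean on the exposure-increasing allele
        # orientation (allele coding is arbitrary, so directionality is
        # defined relative to sign(gamma)); InSIDE still holds because the
        # magnitude of delta is independent of gamma
        delta[:m_x] = np.sign(gamma[:m_x]) * rng.normal(
            config.pleiotropy_sd, config.pleiotropy_sd / 2.0, size=m_x
        )

    resid_var = 1.0 - config.h2_x
    b_u = np.sqrt(config.confounding * resid_var)
    sd_ex = np.sqrt((1.0 - config.confounding) * resid_var)

    def draw_sample(n):
        G = rng.binomial(2, maf, size=(n, m)).astype(float)
        U = rng.normal(size=n)
        X = G @ gamma + b_u * U + rng.normal(scale=sd_ex, size=n)
        M = (
            config.beta_xm * X + G @ delta + G @ kappa + 0.3 * U
            + rng.normal(size=n)
        )
        eta = config.beta_causal_xy * X + config.beta_my * M + 0.3 * U
        if config.outcome_type == "binary":
            Y = rng.binomial(1, expit(eta)).astype(float)
        else:
            Y = eta + rng.normal(size=n)
        return G, X, M, Y

    G_a, X_a, _, _ = draw_sample(config.n_exposure)
    b, s, p = _single_snp_linear(G_a, X_a)
    exposure = SummaryDataset(
        "exposure",
        _summary_frame(snp_meta, G_a, b, s, p, config.n_exposure),
        sample_overlap_tag="sample_A",
    )

    G_b, _, M_b, _ = draw_sample(config.n_mediator)
    b, s, p = _single_snp_linear(G_b, M_b)
    mediator = SummaryDataset(
        "mediator",
        _summary_frame(snp_meta, G_b, b, s, p, config.n_mediator),
        sample_overlap_tag="sample_B",
    )

    G_c, _, _, Y_c = draw_sample(config.n_outcome)
    if config.outcome_type == "binary":
        b, s, p = _single_snp_logistic(G_c, Y_c)
    else:
        b, s, p = _single_snp_linear(G_c, Y_c)
    outcome = SummaryDataset(
        "outcome",
        _summary_frame(snp_meta, G_c, b, s, p, config.n_outcome),
        sample_overlap_tag="sample_C",
    )

    total = config.beta_causal_xy + config.beta_xm * config.beta_my
    truth = {
        "beta_causal_xy": config.beta_causal_xy,
        "beta_xm": config.beta_xm,
        "beta_my": config.beta_my,
        "total_effect_xy": total,
        "indirect_effect": config.beta_xm * config.beta_my,
        "pm_true": (config.beta_xm * config.beta_my / total) if total != 0 else np.nan,
        "gamma": gamma.tolist(),
        "kappa": kappa.tolist(),
        "delta": delta.tolist(),
        "exposure_instruments": snp_meta["snp_id"].iloc[:m_x].tolist(),
        "mediator_instruments": snp_meta["snp_id"].iloc[m_x:].tolist(),
        "maf": maf.tolist(),
        "h2_x": config.h2_x,
        "pleiotropy_mode": config.pleiotropy_mode,
        "outcome_type": config.outcome_type,
        "seed": config.seed,
    }
    return exposure, mediator, outcome, truth


def simulate_cohort(config: CohortSimConfig):
    """Generate a synthetic survival cohort and its ground truth.

    Event times follow a Weibull proportional-hazards model with linear
    predictor ``log(hr_direct) * exposure + mediator_effect_on_hazard * M``
    plus small confounder effects; the mediator is
    ``exposure_effect_on_mediator * exposure`` plus confounders and unit
    noise.  Follow-up is administratively censored at ``censor_time``.

    Returns ``(records, truth)`` where ``records`` is a DataFrame with
    columns id, time, event, exposure (0/1), exposure_level, mediator and
    conf_1..conf_K.
    """
    rng = np.random.default_rng(config.seed)
    n, c = config.n_subjects, config.confounder_count

    exposure = rng.binomial(1, config.exposure_prevalence, size=n).astype(float)
    conf = rng.normal(size=(n, c)) if c else np.zeros((n, 0))
    mediator = (
        config.exposure_effect_on_mediator * exposure
        + conf.sum(axis=1) * config.confounder_effect_mediator
        + rng.normal(size=n)
    )
    eta = (
        np.log(config.hr_direct) * exposure
        + config.mediator_effect_on_hazard * mediator
        + conf.sum(axis=1) * config.confounder_effect_hazard
    )
    # inverse-transform sample: S(t|eta) = exp(-(t/scale)^shape * e^eta)
    u = rng.uniform(size=n)
    t_event = config.baseline_scale * (
        -np.log(u) * np.exp(-eta)
    ) ** (1.0 / config.baseline_shape)
    time = np.minimum(t_event, config.censor_time)
    event = (t_event <= config.censor_time).astype(int)
    if event.sum() == 0:
        raise ConfigurationError(
            "configuration yields zero expected events; increase follow-up, "
            "baseline hazard or sample size"
        )

    records = pd.DataFrame(
        {
            "id": [f"S{i + 1:06d}" for i in range(n)],
            "time": time,
            "event": event,
            "exposure": exposure,
            "exposure_level": np.where(exposure > 0, ">=1", "<1"),
            "mediator": mediator,
        }
    )
    for j in range(c):
        records[f"conf_{j + 1}"] = conf[:, j]

    log_hr_direct = float(np.log(config.hr_direct))
    indirect = config.mediator_effect_on_hazard * config.exposure_effect_on_mediator
    total = log_hr_direct + indirect
    truth = {
        "log_hr_direct": log_hr_direct,
        "indirect_log_hr": indirect,
        "total_log_hr": total,
        "pm_true": indirect / total if total != 0 else np.nan,
        "n_events": int(event.sum()),
        "seed": config.seed,
    }
    return records, truth
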