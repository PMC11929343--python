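"""Two-sample Mendelian randomization estimators and pleiotropy diagnostics.

Given harmonized per-SNP exposure/outcome effects, the causal effect of the
exposure on the outcome is estimated by combining per-SNP Wald ratios
(beta_out / beta_exp) with inverse-variance weights.  The suite mirrors
standard summary-data MR practice:

* IVW, fixed effect or multiplicative random effects (the random-effects
  SE inflates the fixed SE by max(1, sqrt(Q/(k-1)))).
* Cochran's Q and the I^2 heterogeneity fraction.
* Weighted median (consistent when >= 50% of instrument weight is valid),
  with a seeded parametric-bootstrap SE.
* MR-Egger weighted regression with an unconstrained intercept; a nonzero
  intercept signals directional pleiotropy (t-test, k-2 df).
* MR-PRESSO: simulation-based global heterogeneity test, per-SNP outlier
  test (Bonferroni), outlier-corrected IVW and a distortion test.

Wald-ratio SEs use the first-order approximation se_out/|beta_exp|, which
ignores exposure-side uncertainty; this is standard when instruments pass
the F > 10 strength rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from bevmr.instruments import (
    HarmonizedSet,
    LDMatrix,
    clump,
    harmonize,
    instrument_strength,
    select_instruments,
)
from bevmr.io_config import PipelineConfig, SummaryDataset

Z95 = 1.959963984540054  # Phi^{-1}(0.975)


@dataclass(frozen=True)
class RatioEstimate:
    """Single-SNP Wald ratio with first-order standard error."""

    snp_id: str
    theta: float
    se_theta: float


@dataclass
class MREstimate:
    method: str
    theta: float
    se: float
    ci95: tuple[float, float]
    p: float
    k_snps: int
    q: float | None = None
    i2: float | None = None
    or_scale: tuple[float, float, float] | None = None  # (OR, lo, hi)

    def to_row(self) -> dict:
        row = {
            "method": self.method,
            "theta": self.theta,
            "se": self.se,
            "ci_lower": self.ci95[0],
            "ci_upper": self.ci95[1],
            "p": self.p,
            "k_snps": self.k_snps,
            "q": np.nan if self.q is None else self.q,
            "i2": np.nan if self.i2 is None else self.i2,
        }
        if self.or_scale is not None:
            row["or"], row["or_ci_lower"], row["or_ci_upper"] = self.or_scale
        return row


@dataclass
class EggerEstimate:
    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_p: float

    def to_row(self) -> dict:
        row = self.slope.to_row()
        row.update(
            intercept=self.intercept,
            intercept_se=self.intercept_se,
            intercept_p=self.intercept_p,
        )
        return row


@dataclass
class PressoResult:
    global_rss: float
    global_p: float
    outlier_snps: set[str]
    outlier_p: dict[str, float]
    corrected: MREstimate | None
    distortion_p: float | None
    n_sim: int
    seed: int

    def to_row(self) -> dict:
        row = {
            "method": "presso_corrected",
            "global_rss": self.global_rss,
            "global_p": self.global_p,
            "n_outliers": len(self.outlier_snps),
            "outliers": ",".join(sorted(self.outlier_snps)),
            "n_sim": self.n_sim,
            "seed": self.seed,
        }
        if self.corrected is not None:
            row.update(self.corrected.to_row())
            row["method"] = "presso_corrected"
        if self.distortion_p is not None:
            row["distortion_p"] = self.distortion_p
        return row


def _finish(method, theta, se, k, q=None, i2=None, binary=False, p=None):
    ci = (theta - Z95 * se, theta + Z95 * se)
    if p is None:
        p = 2.0 * stats.norm.sf(abs(theta) / se) if se > 0 else 0.0
    or_scale = (np.exp(theta), np.exp(ci[0]), np.exp(ci[1])) if binary else None
    return MREstimate(method, float(theta), float(se), ci, float(p), k, q, i2, or_scale)


def wald_ratio(pair) -> RatioEstimate:
    """Wald ratio for one harmonized SNP pair: beta_out / beta_exp.

    ``pair`` is a mapping or namedtuple with beta_exp, se_exp, beta_out,
    se_out and snp_id fields.
    """
    get = pair.get if hasattr(pair, "get") else lambda k: getattr(pair, k)
    beta_exp = float(get("beta_exp"))
    if beta_exp == 0.0:
        raise ZeroDivisionError(
            f"Wald ratio undefined for {get('snp_id')}: beta_exp = 0"
        )
    theta = float(get("beta_out")) / beta_exp
    se_theta = float(get("se_out")) / abs(beta_exp)
    return RatioEstimate(str(get("snp_id")), theta, se_theta)


def _ratios(hset: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectors (theta_j, se_j, w_j) of per-SNP ratios and IVW weights."""
    b_exp = hset.pairs["beta_exp"].to_numpy(dtype=float)
    if np.any(b_exp == 0.0):
        bad = hset.pairs.loc[b_exp == 0.0, "snp_id"].iloc[0]
        raise ZeroDivisionError(f"Wald ratio undefined for {bad}: beta_exp = 0")
    theta = hset.pairs["beta_out"].to_numpy(dtype=float) / b_exp
    se = hset.pairs["se_out"].to_numpy(dtype=float) / np.abs(b_exp)
    return theta, se, se**-2


def ivw(hset: HarmonizedSet, model: str = "random") -> MREstimate:
    """Inverse-variance-weighted meta-analysis of the per-SNP Wald ratios.

    ``model='fixed'`` uses se = (sum w)^(-1/2); ``model='random'`` applies
    multiplicative overdispersion, inflating the fixed SE by
    max(1, sqrt(Q/(k-1))) — never deflating it under-dispersion.  With a
    single SNP both reduce to the Wald ratio.
    """
    if model not in ("fixed", "random"):
        raise ValueError(f"unknown IVW model {model!r}")
    k = len(hset)
    if k == 0:
        raise ValueError("IVW requires at least one harmonized SNP")
    theta, se, w = _ratios(hset)
    est = float(np.sum(w * theta) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    if k >= 2:
        q = float(np.sum(w * (theta - est) ** 2))
        i2 = max(0.0, (q - (k - 1)) / q) if q > 0 else 0.0
    else:
        q = i2 = None
    if model == "random" and k >= 2:
        scale = max(1.0, np.sqrt(q / (k - 1)))
        se_est = se_fixed * scale
    else:
        se_est = se_fixed
    return _finish(f"ivw_{model}", est, se_est, k, q, i2, hset.outcome_binary)


def cochran_q(hset: HarmonizedSet, theta_ivw: float) -> tuple[float, float, float]:
    """Cochran's Q about ``theta_ivw``, I^2, and the chi-square p (k-1 df)."""
    k = len(hset)
    if k < 2:
        raise ValueError("Cochran's Q requires at least two SNPs")
    theta, se, w = _ratios(hset)
    q = float(np.sum(w * (theta - theta_ivw) ** 2))
    i2 = max(0.0, (q - (k - 1)) / q) if q > 0 else 0.0
    p_het = float(stats.chi2.sf(q, k - 1))
    return q, i2, p_het


def _weighted_median_point(theta: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta, kind="mergesort")
    t, ww = theta[order], w[order]
    s = np.cumsum(ww)
    pj = (s - ww / 2.0) / s[-1]
    if 0.5 <= pj[0]:
        return float(t[0])
    if 0.5 >= pj[-1]:
        return float(t[-1])
    j = int(np.searchsorted(pj, 0.5, side="right")) - 1
    frac = (0.5 - pj[j]) / (pj[j + 1] - pj[j])
    return float(t[j] + frac * (t[j + 1] - t[j]))


def weighted_median(
    hset: HarmonizedSet, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted-median estimate with parametric-bootstrap standard error.

    The point estimate interpolates the weighted empirical CDF of the
    ordered Wald ratios at probability 0.5 with IVW weights; the SE is the
    standard deviation of the estimate over ``n_boot`` parametric resamples
    theta_j* ~ Normal(theta_j, se_j), seeded for reproducibility.
    """
    k = len(hset)
    if k < 3:
        raise ValueError("weighted median requires at least three SNPs")
    theta, se, w = _ratios(hset)
    est = _weighted_median_point(theta, w)
    rng = np.random.default_rng(seed)
    draws = rng.normal(theta, se, size=(n_boot, k))
    boots = np.array([_weighted_median_point(d, w) for d in draws])
    se_est = float(boots.std(ddof=1))
    return _finish("weighted_median", est, se_est, k, binary=hset.outcome_binary)


def mr_egger(hset: HarmonizedSet) -> EggerEstimate:
    """MR-Egger: weighted regression of beta_out on beta_exp with intercept.

    Pairs are first oriented so every beta_exp >= 0 (flipping the signs of
    both effects where needed); weights are se_out^-2.  The slope is the
    pleiotropy-robust causal estimate under InSIDE; the intercept and its
    t-test (k-2 df) diagnose directional pleiotropy.
    """
    k = len(hset)
    if k < 3:
        raise ValueError("MR-Egger requires at least three SNPs")
    x = hset.pairs["beta_exp"].to_numpy(dtype=float).copy()
    y = hset.pairs["beta_out"].to_numpy(dtype=float).copy()
    flip = x < 0
    x[flip] *= -1.0
    y[flip] *= -1.0
    w = hset.pairs["se_out"].to_numpy(dtype=float) ** -2
    if np.allclose(x, x[0]):
        raise ValueError("MR-Egger undefined: no variance in beta_exp")

    sw = np.sum(w)
    xbar = np.sum(w * x) / sw
    ybar = np.sum(w * y) / sw
    sxx = np.sum(w * (x - xbar) ** 2)
    sxy = np.sum(w * (x - xbar) * (y - ybar))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - intercept - slope * x
    sigma2 = np.sum(w * resid**2) / (k - 2)
    se_slope = np.sqrt(sigma2 / sxx)
    se_int = np.sqrt(sigma2 * (1.0 / sw + xbar**2 / sxx))
    t = stats.t(df=k - 2)
    p_slope = 2.0 * t.sf(abs(slope) / se_slope) if se_slope > 0 else 0.0
    p_int = 2.0 * t.sf(abs(intercept) / se_int) if se_int > 0 else 0.0
    slope_est = _finish(
        "egger_slope", slope, se_slope, k, binary=hset.outcome_binary, p=p_slope
    )
    return EggerEstimate(slope_est, float(intercept), float(se_int), float(p_int))


def _loo_thetas(x, y_mat, w):
    """Leave-one-out origin-constrained IVW slopes, vectorized over rows of y.

    y_mat has shape (n_sim, k) (or (1, k) for the observed data); the
    returned array matches its shape: entry [m, j] is the IVW slope of the
    m-th dataset with SNP j removed.
    """
    wx2 = w * x**2
    s_wx2 = np.sum(wx2)
    wxy = w * x * y_mat  # (n_sim, k)
    s_wxy = wxy.sum(axis=1, keepdims=True)
    return (s_wxy - wxy) / (s_wx2 - wx2)


def mr_presso(
    hset: HarmonizedSet,
    n_sim: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> PressoResult:
    """MR-PRESSO global, outlier and distortion tests.

    The observed weighted residual sum of squares of leave-one-out IVW
    fits is compared against an empirical null built by simulating
    beta_out* ~ Normal(beta_exp * theta_loo, se_out) ``n_sim`` times.
    Outliers are detected iteratively: each round compares every remaining
    SNP's squared residual against its own simulated null distribution and
    removes the single worst SNP whose Bonferroni-corrected empirical p is
    below ``alpha``, then re-tests, so that one dominant outlier cannot
    contaminate the leave-one-out fits of valid instruments.  If outliers
    are found, IVW is re-estimated on the remaining SNPs; the distortion
    test compares the corrected-vs-full shift against removals of random
    same-size subsets.
    """
    k = len(hset)
    if k < 4:
        raise ValueError("MR-PRESSO requires at least four SNPs")
    rng = np.random.default_rng(seed)
    x = hset.pairs["beta_exp"].to_numpy(dtype=float)
    y = hset.pairs["beta_out"].to_numpy(dtype=float)
    se_out = hset.pairs["se_out"].to_numpy(dtype=float)
    w = se_out**-2
    snp_ids = hset.pairs["snp_id"].to_numpy()

    def _tests(active):
        """Observed/simulated LOO residuals restricted to ``active`` SNPs."""
        xa, ya, sa, wa = x[active], y[active], se_out[active], w[active]
        ka = active.sum()
        loo = _loo_thetas(xa, ya[None, :], wa)[0]
        r2_obs = wa * (ya - xa * loo) ** 2
        y_sim = rng.normal(xa * loo, sa, size=(n_sim, ka))
        loo_sim = _loo_thetas(xa, y_sim, wa)
        r2_sim = wa * (y_sim - xa * loo_sim) ** 2
        p_snp = (1 + (r2_sim >= r2_obs).sum(axis=0)) / (n_sim + 1)
        return r2_obs, r2_sim.sum(axis=1), p_snp

    active = np.ones(k, dtype=bool)
    resid2_obs, rss_sim, p_per_snp = _tests(active)
    rss_obs = float(resid2_obs.sum())
    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    outlier_p = {str(s): float(p) for s, p in zip(snp_ids, p_per_snp)}
    r2_now, p_now = resid2_obs, p_per_snp
    while active.sum() >= 4:
        ka = int(active.sum())
        flagged = p_now * ka < alpha
        if not flagged.any():
            break
        worst_local = int(np.argmax(np.where(flagged, r2_now, -np.inf)))
        worst_global = int(np.flatnonzero(active)[worst_local])
        outlier_p[str(snp_ids[worst_global])] = float(p_now[worst_local])
        active[worst_global] = False
        if active.sum() < 4:
            break
        r2_now, _, p_now = _tests(active)
    for idx in np.flatnonzero(active):
        local = int(np.flatnonzero(active).tolist().index(idx))
        outlier_p[str(snp_ids[idx])] = float(p_now[local])
    outlier_mask = ~active
    outliers = {str(s) for s in snp_ids[outlier_mask]}

    corrected = None
    distortion_p = None
    if outliers:
        keep = ~outlier_mask
        sub = HarmonizedSet(
            pairs=hset.pairs.loc[keep].reset_index(drop=True),
            dropped=dict(hset.dropped),
            exposure_label=hset.exposure_label,
            outcome_label=hset.outcome_label,
            outcome_binary=hset.outcome_binary,
        )
        corrected = ivw(sub, model="random")
        corrected.method = "presso_corrected"

        theta_full = float(np.sum(w * x * y) / np.sum(w * x**2))
        if theta_full != 0.0 and keep.sum() >= 1:
            d_obs = abs((corrected.theta - theta_full) / abs(theta_full))
            n_out = int(outlier_mask.sum())
            idx_all = np.arange(k)
            d_null = np.empty(n_sim)
            for m in range(n_sim):
                drop = rng.choice(idx_all, size=n_out, replace=False)
                mask = np.ones(k, dtype=bool)
                mask[drop] = False
                th = np.sum(w[mask] * x[mask] * y[mask]) / np.sum(
                    w[mask] * x[mask] ** 2
                )
                d_null[m] = abs((th - theta_full) / abs(theta_full))
            distortion_p = float((1 + np.sum(d_null >= d_obs)) / (n_sim + 1))

    return PressoResult(
        global_rss=rss_obs,
        global_p=global_p,
        outlier_snps=outliers,
        outlier_p=outlier_p,
        corrected=corrected,
        distortion_p=distortion_p,
        n_sim=n_sim,
        seed=seed,
    )


@dataclass
class MRReport:
    """Everything the univariable pipeline produced for one exposure/outcome."""

    exposure: str
    outcome: str
    k_selected: int
    k_harmonized: int
    mean_f: float
    weak_instruments: bool
    hset: HarmonizedSet
    estimates: dict[str, MREstimate] = field(default_factory=dict)
    egger: EggerEstimate | None = None
    presso: PressoResult | None = None
    q: float | None = None
    i2: float | None = None
    p_het: float | None = None

    def to_table(self) -> pd.DataFrame:
        rows = []
        for est in self.estimates.values():
            row = est.to_row()
            row.update(exposure=self.exposure, outcome=self.outcome, mean_f=self.mean_f)
            rows.append(row)
        if self.egger is not None:
            row = self.egger.to_row()
            row.update(exposure=self.exposure, outcome=self.outcome, mean_f=self.mean_f)
            rows.append(row)
        if self.presso is not None:
            row = self.presso.to_row()
            row.update(exposure=self.exposure, outcome=self.outcome, mean_f=self.mean_f)
            rows.append(row)
        return pd.DataFrame(rows)

    def per_snp_table(self) -> pd.DataFrame:
        theta, se, w = _ratios(self.hset)
        x = self.hset.pairs["beta_exp"].to_numpy(dtype=float)
        y = self.hset.pairs["beta_out"].to_numpy(dtype=float)
        loo = _loo_thetas(x, y[None, :], self.hset.pairs["se_out"].to_numpy() ** -2)[0]
        tab = pd.DataFrame(
            {
                "snp_id": self.hset.pairs["snp_id"],
                "ratio": theta,
                "se_ratio": se,
                "leave_one_out_ivw": loo,
            }
        )
        if self.presso is not None:
            tab["outlier_p"] = tab["snp_id"].map(self.presso.outlier_p)
        return tab


def run_univariable_mr(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    ld: LDMatrix,
    config: PipelineConfig | None = None,
    outcome_binary: bool = True,
) -> MRReport:
    """Full univariable pipeline: select, clump, harmonize, estimate.

    Runs every estimator the harmonized SNP count allows: IVW (random and
    fixed) always; Cochran's Q from k >= 2; weighted median and MR-Egger
    from k >= 3; MR-PRESSO from k >= 4.  With a single retained SNP the
    report contains only the Wald/IVW estimate and marks the diagnostics
    unavailable (None).
    """
    config = config or PipelineConfig()
    selected = select_instruments(exposure, config.p_threshold)
    if not selected:
        raise ValueError(
            f"no instruments for {exposure.trait_label!r} at "
            f"p < {config.p_threshold:g}"
        )
    kept = clump(selected, exposure, ld, config.clump_r2, config.clump_window_kb)
    strength = instrument_strength(exposure, kept)
    hset = harmonize(
        exposure, outcome, kept, config.palindromic_eaf_band, outcome_binary
    )
    k = len(hset)
    if k == 0:
        raise ValueError(
            f"no SNP survived harmonization for {exposure.trait_label!r}"
        )

    report = MRReport(
        exposure=exposure.trait_label,
        outcome=outcome.trait_label,
        k_selected=len(kept),
        k_harmonized=k,
        mean_f=strength.mean_f,
        weak_instruments=strength.weak,
        hset=hset,
    )
    est_random = ivw(hset, model="random")
    report.estimates["ivw_random"] = est_random
    report.estimates["ivw_fixed"] = ivw(hset, model="fixed")
    if k >= 2:
        report.q, report.i2, report.p_het = cochran_q(hset, est_random.theta)
    if k >= 3:
        report.estimates["weighted_median"] = weighted_median(
            hset, n_boot=config.n_boot, seed=config.seed
        )
        report.egger = mr_egger(hset)
    if k >= 4:
        report.presso = mr_presso(
            hset, n_sim=config.n_presso_sim, seed=config.seed, alpha=config.alpha
        )
    return report
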