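"""Observational arm: Cox proportional-hazards models, proportional-hazards
diagnostics, linear-regression mediator screening, and difference-method
mediation.

The Cox partial likelihood is maximized by Newton-Raphson with Efron's
approximation for tied event times and step-halving, converging when the
largest score component falls below 1e-8.  Mediation in this arm uses the
difference method: the proportion mediated is the relative attenuation of
the exposure's log hazard ratio when the mediator is added to the model,
with a subject-level nonparametric bootstrap for its confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

Z95 = 1.959963984540054


class ConvergenceError(RuntimeError):
    """The partial-likelihood maximization failed to converge."""


def build_design(records: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    """Expand model terms into a numeric design matrix.

    Categorical columns (object/category dtype) become indicator contrasts
    against their lowest (first sorted) level, matching the convention of
    reporting hazard ratios relative to the reference exposure category.
    """
    cols = {}
    for term in terms:
        if term not in records.columns:
            raise KeyError(f"term {term!r} not found in records")
        col = records[term]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = (
                list(col.cat.categories)
                if isinstance(col.dtype, pd.CategoricalDtype)
                else sorted(col.dropna().unique())
            )
            for lev in levels[1:]:
                cols[f"{term}[{lev}]"] = (col == lev).astype(float)
        else:
            cols[term] = col.astype(float)
    return pd.DataFrame(cols, index=records.index)


@dataclass
class CoxFit:
    coefficients: pd.Series
    covariance: pd.DataFrame
    hr: pd.DataFrame  # columns hr, ci_lower, ci_upper, p
    loglik: float
    n_events: int
    ties_method: str
    terms: list[str] = field(default_factory=list)
    n_iter: int = 0
    loglik_path: list[float] = field(default_factory=list)

    @property
    def se(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.covariance.to_numpy())),
            index=self.coefficients.index,
        )

    def to_row(self) -> dict:
        first = self.coefficients.index[0]
        return {
            "term": first,
            "coef": self.coefficients.iloc[0],
            "hr": self.hr.loc[first, "hr"],
            "ci_lower": self.hr.loc[first, "ci_lower"],
            "ci_upper": self.hr.loc[first, "ci_upper"],
            "p": self.hr.loc[first, "p"],
            "n_events": self.n_events,
        }


def _efron_quantities(beta, X, time, event):
    """Partial log-likelihood, score and information (Efron ties).

    Expects rows sorted by ascending time.  Risk-set sums are taken over
    suffix segments between successive unique event times.
    """
    n, p = X.shape
    eta = X @ beta
    eta -= eta.max()  # guard exp overflow; cancels in ratios and in loglik diffs
    w = np.exp(eta)

    ev_times = np.unique(time[event == 1])
    starts = np.searchsorted(time, ev_times, side="left")

    wx = w[:, None] * X
    wxx = wx[:, :, None] * X[:, None, :]
    seg_w = np.add.reduceat(w, starts)
    seg_wx = np.add.reduceat(wx, starts, axis=0)
    seg_wxx = np.add.reduceat(wxx, starts, axis=0)
    # suffix (risk-set) sums at each unique event time
    r_w = np.cumsum(seg_w[::-1])[::-1]
    r_wx = np.cumsum(seg_wx[::-1], axis=0)[::-1]
    r_wxx = np.cumsum(seg_wxx[::-1], axis=0)[::-1]

    loglik = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    for t_idx, t in enumerate(ev_times):
        dmask = (time == t) & (event == 1)
        d = int(dmask.sum())
        dw = w[dmask].sum()
        dwx = wx[dmask].sum(axis=0)
        dwxx = wxx[dmask].sum(axis=0)
        loglik += eta[dmask].sum()
        score += X[dmask].sum(axis=0)
        frac = np.arange(d) / d
        for f in frac:
            denom = r_w[t_idx] - f * dw
            num_x = r_wx[t_idx] - f * dwx
            num_xx = r_wxx[t_idx] - f * dwxx
            mu = num_x / denom
            loglik -= np.log(denom)
            score -= mu
            info += num_xx / denom - np.outer(mu, mu)
    return loglik, score, info


def fit_cox(
    records: pd.DataFrame,
    terms: list[str],
    duration_col: str = "time",
    event_col: str = "event",
    max_iter: int = 50,
    score_tol: float = 1e-8,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton-Raphson (Efron ties).

    Step-halving guarantees the partial likelihood never decreases between
    iterations; convergence requires max |score| < ``score_tol``.  Raises
    :class:`ConvergenceError` naming the offending term on monotone
    likelihood (perfect separation) and ``ValueError`` on fewer than two
    events or a constant term.
    """
    design = build_design(records, terms)
    names = list(design.columns)
    time = records[duration_col].to_numpy(dtype=float)
    event = records[event_col].to_numpy(dtype=int)
    if event.sum() < 2:
        raise ValueError("Cox fit requires at least two events")
    X = design.to_numpy(dtype=float)
    const = np.ptp(X, axis=0) == 0
    if const.any():
        raise ValueError(f"term {names[int(np.flatnonzero(const)[0])]!r} is constant")

    order = np.argsort(time, kind="mergesort")
    X, time, event = X[order], time[order], event[order]
    # center columns for numerical stability; slopes are unaffected
    X = X - X.mean(axis=0)

    p = X.shape[1]
    beta = np.zeros(p)
    loglik, score, info = _efron_quantities(beta, X, time, event)
    path = [loglik]
    n_iter = 0
    # float-noise allowance so step-halving cannot stall at the optimum
    ll_slack = 1e-9 * (1.0 + abs(loglik))
    converged = np.abs(score).max() < score_tol
    while not converged and n_iter < max_iter:
        n_iter += 1
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        new_beta = beta + step
        new_ll, new_score, new_info = _efron_quantities(new_beta, X, time, event)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < loglik - ll_slack) and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_score, new_info = _efron_quantities(new_beta, X, time, event)
            halvings += 1
        beta, loglik, score, info = new_beta, new_ll, new_score, new_info
        path.append(loglik)
        if np.abs(score).max() < score_tol:
            converged = True
            break
        if np.abs(beta).max() > 50.0:
            worst = names[int(np.abs(beta).argmax())]
            raise ConvergenceError(
                f"monotone likelihood (perfect separation?) in term {worst!r}"
            )
    if not converged and np.abs(score).max() >= np.sqrt(score_tol):
        worst = names[int(np.abs(beta).argmax())]
        raise ConvergenceError(
            f"no convergence in {max_iter} iterations (worst term {worst!r})"
        )
    # a "converged" coefficient this size means the likelihood flattened out
    # along a separating direction rather than attaining an interior maximum
    if np.abs(beta).max() > 15.0:
        worst = names[int(np.abs(beta).argmax())]
        raise ConvergenceError(
            f"monotone likelihood (perfect separation?) in term {worst!r}"
        )

    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    zp = 2.0 * stats.norm.sf(np.abs(beta) / se)
    hr = pd.DataFrame(
        {
            "hr": np.exp(beta),
            "ci_lower": np.exp(beta - Z95 * se),
            "ci_upper": np.exp(beta + Z95 * se),
            "p": zp,
        },
        index=names,
    )
    return CoxFit(
        coefficients=pd.Series(beta, index=names),
        covariance=pd.DataFrame(cov, index=names, columns=names),
        hr=hr,
        loglik=float(loglik),
        n_events=int(event.sum()),
        ties_method="efron",
        terms=list(terms),
        n_iter=n_iter,
        loglik_path=[float(v) for v in path],
    )


def schoenfeld_test(
    fit: CoxFit,
    records: pd.DataFrame,
    duration_col: str = "time",
    event_col: str = "event",
) -> pd.Series:
    """Scaled-Schoenfeld-residual test of proportional hazards.

    Correlates each term's scaled Schoenfeld residuals with event-time
    rank; returns per-term p-values plus a 'global' chi-square p.  Backed
    by lifelines' proportional-hazard machinery on the same design matrix.
    """
    from lifelines import CoxPHFitter
    from lifelines.statistics import proportional_hazard_test

    if int(records[event_col].sum()) < 2:
        raise ValueError("Schoenfeld test requires at least two events")
    design = build_design(records, fit.terms)
    frame = design.copy()
    frame[duration_col] = records[duration_col].to_numpy(dtype=float)
    frame[event_col] = records[event_col].to_numpy(dtype=int)
    cph = CoxPHFitter()
    cph.fit(frame, duration_col=duration_col, event_col=event_col)
    res = proportional_hazard_test(cph, frame, time_transform="rank")
    summary = res.summary
    pvals = summary["p"]
    pvals.index = [i[0] if isinstance(i, tuple) else i for i in summary.index]
    chi2 = float(summary["test_statistic"].sum())
    df = len(summary)
    out = pd.Series(pvals.to_dict())
    out["global"] = float(stats.chi2.sf(chi2, df))
    return out


def incidence_summary(
    records: pd.DataFrame,
    group: str | None = None,
    duration_col: str = "time",
    event_col: str = "event",
) -> pd.DataFrame:
    """Per-group person-years, events, incidence rate and mean follow-up.

    rate = events / person-years x 1000; mean follow-up = person-years /
    subjects.  With ``group=None`` a single overall row is returned.
    """
    if len(records) == 0:
        raise ValueError("incidence_summary requires a non-empty cohort")

    def summarize(df):
        py = float(df[duration_col].sum())
        ev = int(df[event_col].sum())
        return pd.Series(
            {
                "subjects": len(df),
                "events": ev,
                "person_years": py,
                "rate_per_1000py": 1000.0 * ev / py if py > 0 else 0.0,
                "mean_followup_years": py / len(df),
            }
        )

    if group is None:
        return summarize(records).to_frame(name="overall").T
    out = records.groupby(group, observed=True).apply(summarize, include_groups=False)
    out["subjects"] = out["subjects"].astype(int)
    out["events"] = out["events"].astype(int)
    return out


def screen_mediators_obs(
    records: pd.DataFrame,
    mediator: str,
    exposure: str,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """OLS screen: regress the mediator on exposure contrasts + covariates.

    Returns the exposure-contrast coefficients with 95% CIs and two-sided
    p-values; a mediator whose exposure contrast is significant is a
    candidate for :func:`difference_method`.  Raises on rank deficiency,
    naming the collinear terms.
    """
    import statsmodels.api as sm

    covariates = covariates or []
    design = build_design(records, [exposure] + covariates)
    Xmat = sm.add_constant(design.to_numpy(dtype=float))
    rank = np.linalg.matrix_rank(Xmat)
    if rank < Xmat.shape[1]:
        _, s, vt = np.linalg.svd(Xmat)
        null_vec = np.abs(vt[-1][1:])  # skip intercept entry
        worst = [design.columns[i] for i in np.argsort(null_vec)[-2:]]
        raise ValueError(f"rank-deficient design; collinear terms include {worst}")
    y = records[mediator].to_numpy(dtype=float)
    res = sm.OLS(y, Xmat).fit()
    names = ["const"] + list(design.columns)
    exp_cols = [
        i for i, nm in enumerate(names) if nm == exposure or nm.startswith(f"{exposure}[")
    ]
    ci = res.conf_int()
    rows = []
    for i in exp_cols:
        rows.append(
            {
                "term": names[i],
                "coef": res.params[i],
                "se": res.bse[i],
                "ci_lower": ci[i][0],
                "ci_upper": ci[i][1],
                "p": res.pvalues[i],
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ObsMediation:
    beta_total: float
    beta_direct: float
    pm: float  # reported (truncated at 0)
    pm_raw: float
    pm_ci95: tuple[float, float]
    truncated: bool
    n_boot: int
    n_boot_failed: int
    method: str = "difference"
    scale: str = "log_hr"

    def to_row(self) -> dict:
        return {
            "method": self.method,
            "beta_total": self.beta_total,
            "beta_direct": self.beta_direct,
            "pm_percent": 100.0 * self.pm,
            "pm_ci_lower_percent": 100.0 * self.pm_ci95[0],
            "pm_ci_upper_percent": 100.0 * self.pm_ci95[1],
            "truncated": self.truncated,
            "n_boot": self.n_boot,
            "n_boot_failed": self.n_boot_failed,
        }


def _pm_from_fits(beta_total: float, beta_direct: float, scale: str) -> float:
    if scale == "log_hr":
        return (beta_total - beta_direct) / beta_total
    if scale == "one_minus_hr":
        hr_t, hr_d = np.exp(beta_total), np.exp(beta_direct)
        return 1.0 - (hr_d - 1.0) / (hr_t - 1.0)
    raise ValueError(f"unknown pm scale {scale!r}")


def difference_method(
    records: pd.DataFrame,
    exposure: str,
    mediator: str,
    covariates: list[str] | None = None,
    n_boot: int = 500,
    seed: int = 0,
    duration_col: str = "time",
    event_col: str = "event",
    scale: str = "log_hr",
) -> ObsMediation:
    """Difference-method mediation on the log hazard-ratio scale.

    pm = (beta_total - beta_direct) / beta_total, comparing the exposure
    coefficient from Cox models without and with the mediator.  The CI is
    a seeded subject-level nonparametric bootstrap (percentile) of the
    whole two-model procedure; non-convergent replicates are dropped, and
    more than 5% dropped is an error.  Negative pm is reported as 0 with a
    truncation flag; the CI is reported untruncated.
    """
    covariates = covariates or []
    fit_total = fit_cox(records, [exposure] + covariates, duration_col, event_col)
    fit_direct = fit_cox(
        records, [exposure] + covariates + [mediator], duration_col, event_col
    )
    exp_term = fit_total.coefficients.index[0]
    beta_total = float(fit_total.coefficients[exp_term])
    beta_direct = float(fit_direct.coefficients[exp_term])
    if beta_total == 0.0:
        raise ZeroDivisionError("proportion mediated undefined: total log HR is 0")
    pm_raw = _pm_from_fits(beta_total, beta_direct, scale)

    rng = np.random.default_rng(seed)
    n = len(records)
    boots = []
    failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sample = records.iloc[idx].reset_index(drop=True)
        try:
            bt = float(
                fit_cox(sample, [exposure] + covariates, duration_col, event_col)
                .coefficients[exp_term]
            )
            bd = float(
                fit_cox(
                    sample,
                    [exposure] + covariates + [mediator],
                    duration_col,
                    event_col,
                ).coefficients[exp_term]
            )
            if bt == 0.0:
                raise ZeroDivisionError
            boots.append(_pm_from_fits(bt, bd, scale))
        except (ConvergenceError, ValueError, ZeroDivisionError, np.linalg.LinAlgError):
            failed += 1
    if n_boot > 0 and failed > 0.05 * n_boot:
        raise ConvergenceError(
            f"{failed}/{n_boot} bootstrap replicates failed to converge"
        )
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = np.nan
    truncated = pm_raw < 0.0
    return ObsMediation(
        beta_total=beta_total,
        beta_direct=beta_direct,
        pm=0.0 if truncated else float(pm_raw),
        pm_raw=float(pm_raw),
        pm_ci95=(float(lo), float(hi)),
        truncated=truncated,
        n_boot=n_boot,
        n_boot_failed=failed,
        scale=scale,
    )
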