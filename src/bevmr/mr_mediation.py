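"""Two-step MR mediation: mediator screening and product-of-coefficients
indirect effects with delta-method confidence intervals.

Step 1 estimates the exposure -> mediator effect with the exposure's own
instruments; step 2 estimates the mediator -> outcome effect with the
mediator's instruments.  Because the three GWAS samples are non-overlapping
the two step estimates are independent, so the delta-method variance of the
product theta1 * theta2 carries no covariance term:

    se(indirect)^2 = theta2^2 se1^2 + theta1^2 se2^2

The proportion mediated is indirect / total (on the log-odds scale for a
binary outcome); negative proportions are reported as 0% with a truncation
flag, while the confidence interval is left untruncated so the uncertainty
is not misrepresented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from bevmr.instruments import LDMatrix
from bevmr.io_config import PipelineConfig, SummaryDataset
from bevmr.mr_core import MREstimate, Z95, run_univariable_mr


@dataclass
class MediationEstimate:
    mediator: str
    total: MREstimate
    step1: MREstimate
    step2: MREstimate
    indirect: float
    indirect_se: float
    pm: float  # reported proportion mediated (truncated at 0)
    pm_raw: float  # untruncated
    pm_ci95: tuple[float, float]
    truncated: bool

    def to_row(self) -> dict:
        return {
            "mediator": self.mediator,
            "total_theta": self.total.theta,
            "total_se": self.total.se,
            "step1_theta": self.step1.theta,
            "step1_se": self.step1.se,
            "step2_theta": self.step2.theta,
            "step2_se": self.step2.se,
            "indirect": self.indirect,
            "indirect_se": self.indirect_se,
            "pm_percent": 100.0 * self.pm,
            "pm_ci_lower_percent": 100.0 * self.pm_ci95[0],
            "pm_ci_upper_percent": 100.0 * self.pm_ci95[1],
            "truncated": self.truncated,
        }


@dataclass
class MediatorScreenResult:
    """Step estimates and qualification flag for one candidate mediator."""

    mediator: str
    step1: MREstimate | None
    step2: MREstimate | None
    step1_egger_intercept_p: float | None
    step2_egger_intercept_p: float | None
    qualified: bool
    reason: str = ""


def screen_mediators(
    exposure: SummaryDataset,
    mediators: list[SummaryDataset],
    outcome: SummaryDataset,
    ld: LDMatrix,
    config: PipelineConfig | None = None,
    mediator_ld: dict[str, LDMatrix] | None = None,
) -> list[MediatorScreenResult]:
    """Screen candidate mediators for the two-step analysis.

    A mediator qualifies when both the exposure -> mediator and the
    mediator -> outcome IVW estimates are significant at ``config.alpha``,
    each step using that trait's own instruments (selected, clumped and
    harmonized independently).  Candidates whose instruments cannot be
    formed are recorded as unevaluable rather than raising.
    """
    config = config or PipelineConfig()
    results: list[MediatorScreenResult] = []
    for med in mediators:
        try:
            step1_rep = run_univariable_mr(
                exposure, med, ld, config, outcome_binary=False
            )
            step1 = step1_rep.estimates["ivw_random"]
            e1 = step1_rep.egger.intercept_p if step1_rep.egger else None
        except (ValueError, KeyError) as exc:
            results.append(
                MediatorScreenResult(
                    med.trait_label, None, None, None, None, False,
                    reason=f"step1 unevaluable: {exc}",
                )
            )
            continue
        try:
            med_ld = (mediator_ld or {}).get(med.trait_label)
            if med_ld is None:
                med_ld = LDMatrix.identity(med)
            step2_rep = run_univariable_mr(med, outcome, med_ld, config)
            step2 = step2_rep.estimates["ivw_random"]
            e2 = step2_rep.egger.intercept_p if step2_rep.egger else None
        except (ValueError, KeyError) as exc:
            results.append(
                MediatorScreenResult(
                    med.trait_label, step1, None, e1, None, False,
                    reason=f"step2 unevaluable: {exc}",
                )
            )
            continue
        qualified = step1.p < config.alpha and step2.p < config.alpha
        results.append(
            MediatorScreenResult(med.trait_label, step1, step2, e1, e2, qualified)
        )
    return results


def two_step_mediation(
    total: MREstimate,
    step1: MREstimate,
    step2: MREstimate,
    mediator: str = "",
) -> MediationEstimate:
    """Combine step estimates into an indirect effect and mediated proportion.

    indirect = theta1 * theta2 (product of coefficients);
    se(indirect) by the delta method with independent steps;
    pm = indirect / theta_total, with first-order delta SE treating
    (indirect, theta_total) as independent.  pm < 0 is reported as 0 with
    ``truncated`` set; its CI is reported untruncated.
    """
    if total.theta == 0.0:
        raise ZeroDivisionError("proportion mediated undefined: total effect is 0")
    t1, s1 = step1.theta, step1.se
    t2, s2 = step2.theta, step2.se
    indirect = t1 * t2
    indirect_se = float(np.sqrt(t2**2 * s1**2 + t1**2 * s2**2))
    pm_raw = indirect / total.theta
    if indirect == 0.0:
        pm_se = abs(indirect_se / total.theta)
    else:
        pm_se = abs(pm_raw) * float(
            np.sqrt(
                indirect_se**2 / indirect**2 + total.se**2 / total.theta**2
            )
        )
    ci = (pm_raw - Z95 * pm_se, pm_raw + Z95 * pm_se)
    truncated = pm_raw < 0.0
    return MediationEstimate(
        mediator=mediator,
        total=total,
        step1=step1,
        step2=step2,
        indirect=float(indirect),
        indirect_se=indirect_se,
        pm=0.0 if truncated else float(pm_raw),
        pm_raw=float(pm_raw),
        pm_ci95=ci,
        truncated=truncated,
    )


def mediation_report(results: list[MediationEstimate]) -> pd.DataFrame:
    """Per-mediator table: step estimates, indirect effect, PM% with CI."""
    if not results:
        raise ValueError("mediation_report requires a non-empty results list")
    rows = []
    for r in results:
        row = r.to_row()
        row["pm_display"] = (
            "0% (truncated)" if r.truncated else f"{100.0 * r.pm:.2f}%"
        )
        if r.total.or_scale is not None:
            row["total_or"] = r.total.or_scale[0]
        rows.append(row)
    return pd.DataFrame(rows)
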