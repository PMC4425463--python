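"""Causal-structure discrimination for marker, depression, adversity.

Three views of the same question — is a molecular marker's association
with stressful life events (SLE) a direct effect, a mediator of
depression (MD) risk, or contingent on the depressed state?

* :func:`summary_t` — two-sample t statistic from group summary
  statistics (means, standard errors, counts), as used when only a
  published summary table is available.
* :func:`stratified_table` — case-control marker contrasts within
  strata of SLE count (0, 1, 2, 3, ≥cap).
* :func:`conditional_regressions` — the decision procedure.  It fits
  (i) logistic ``MD ~ SLE + marker`` and (ii) linear
  ``marker ~ SLE + MD`` (each plus covariates) and reads the
  significance pattern:

  - ``STATE_DEPENDENT`` — SLE still predicts MD given the marker, the
    marker still predicts MD given SLE, the marker–SLE association
    disappears given MD, and the within-stratum case-control contrast
    persists.
  - ``MEDIATED`` — SLE no longer predicts MD once the marker is in the
    model, while the marker does.
  - ``INDEPENDENT`` — no within-stratum case-control contrast, but a
    marginal marker–SLE association exists.
  - ``INCONCLUSIVE`` — anything else.

  The verdict is a pure function of the stored p-values and alpha, so
  it is reproducible from the returned object alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .stats_assoc import _encode_covariates, linear_assoc
from .synthetic_data import ScenarioKind

__all__ = ["summary_t", "stratified_table", "conditional_regressions",
           "classify", "StratumSummary", "InferenceVerdict",
           "NORMAL_APPROX_CUTOFF"]

#: above this combined n, the summary-t p-value uses the normal
#: approximation; below it, Welch–Satterthwaite degrees of freedom
NORMAL_APPROX_CUTOFF = 100


def summary_t(m1: float, se1: float, n1: int,
              m2: float, se2: float, n2: int) -> Tuple[float, float]:
    """Two-sample t statistic and two-sided p from group summaries.

    ``t = (m1 - m2) / sqrt(se1^2 + se2^2)`` with the SEs being standard
    errors of the group means.  For ``n1 + n2 > 100`` the p-value uses
    the normal approximation; otherwise the Welch–Satterthwaite t
    distribution.  Antisymmetric under swapping the groups.
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    t = (m1 - m2) / math.hypot(se1, se2)
    if n1 + n2 > NORMAL_APPROX_CUTOFF:
        p = 2.0 * stats.norm.sf(abs(t))
    else:
        v1, v2 = se1 ** 2, se2 ** 2
        df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
        p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


@dataclass(frozen=True)
class StratumSummary:
    """Case-control marker contrast within one SLE stratum.

    Means and SEs (SD/√n) per group; ``t_stat``/``p`` compare control
    minus case and are NaN when either group is too small (< 2)."""

    label: str
    control_mean: float
    control_se: float
    control_n: int
    case_mean: float
    case_se: float
    case_n: int
    t_stat: float
    p: float


def _group_summary(values: np.ndarray) -> Tuple[float, float, int]:
    n = values.size
    if n == 0:
        return float("nan"), float("nan"), 0
    mean = float(values.mean())
    se = float(values.std(ddof=1) / math.sqrt(n)) if n >= 2 else float("nan")
    return mean, se, n


def stratified_table(markers, status, sle_counts,
                     cap: int = 4) -> List[StratumSummary]:
    """Per-SLE-stratum case-control summaries (strata 0..cap-1 and
    ``{cap}+``).  Group counts sum to the total sample size; strata
    where a group mean or SE is undefined carry NaN t/p."""
    markers = np.asarray(markers, dtype=float)
    status = np.asarray(status, dtype=int)
    sle = np.asarray(sle_counts, dtype=int)
    if np.any(sle < 0):
        raise ValueError("SLE counts must be non-negative")
    capped = np.minimum(sle, cap)
    out = []
    for level in range(cap + 1):
        label = f"{level}+" if level == cap else str(level)
        in_stratum = capped == level
        ctrl = markers[in_stratum & (status == 0)]
        case = markers[in_stratum & (status == 1)]
        cm, cse, cn = _group_summary(ctrl)
        km, kse, kn = _group_summary(case)
        if cn >= 2 and kn >= 2:
            t, p = summary_t(cm, cse, cn, km, kse, kn)
        else:
            t, p = float("nan"), float("nan")
        out.append(StratumSummary(label=label, control_mean=cm,
                                  control_se=cse, control_n=cn,
                                  case_mean=km, case_se=kse, case_n=kn,
                                  t_stat=t, p=p))
    return out


def strata_frame(strata: Sequence[StratumSummary]) -> pd.DataFrame:
    """Tabular view of :func:`stratified_table` output."""
    return pd.DataFrame([s.__dict__ for s in strata])


@dataclass(frozen=True)
class InferenceVerdict:
    """Decision-procedure output.

    ``md_sle_given_marker_p``: p of SLE in logistic MD ~ SLE + marker.
    ``md_marker_given_sle_p``: p of the marker in the same model.
    ``marker_sle_given_md_p``: p of SLE in linear marker ~ SLE + MD.
    ``marginal_marker_sle_p``: p of SLE in linear marker ~ SLE.
    ``stratum_ps``: per-stratum case-control p-values.
    """

    md_sle_given_marker_p: float
    md_marker_given_sle_p: float
    marker_sle_given_md_p: float
    marginal_marker_sle_p: float
    stratum_ps: Tuple[float, ...]
    classification: ScenarioKind | str
    alpha: float

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["classification"] = str(self.classification)
        d["stratum_ps"] = list(self.stratum_ps)
        return d


def classify(md_sle_given_marker_p: float, md_marker_given_sle_p: float,
             marker_sle_given_md_p: float, marginal_marker_sle_p: float,
             stratum_ps: Sequence[float], alpha: float = 0.05) -> str:
    """Map the p-value pattern to a causal-structure label.

    Pure function of its arguments (sample order can never matter).
    """
    finite = [p for p in stratum_ps if np.isfinite(p)]
    stratum_contrast = any(p < alpha for p in finite)
    if (md_sle_given_marker_p < alpha and md_marker_given_sle_p < alpha
            and marker_sle_given_md_p >= alpha and stratum_contrast):
        return ScenarioKind.STATE_DEPENDENT.value
    if md_sle_given_marker_p >= alpha and md_marker_given_sle_p < alpha:
        return ScenarioKind.MEDIATED.value
    if not stratum_contrast and marginal_marker_sle_p < alpha:
        return ScenarioKind.INDEPENDENT.value
    return "INCONCLUSIVE"


def _term_pvalues(fit, terms: Sequence[str]) -> dict:
    return {t: float(fit.pvalues[t]) for t in terms}


def conditional_regressions(markers, status, sle_counts,
                            covariates: Optional[pd.DataFrame] = None,
                            alpha: float = 0.05,
                            cap: int = 4) -> InferenceVerdict:
    """Fit the two conditional models and classify the causal structure.

    Model (i): logistic ``MD ~ SLE + marker (+ covariates)`` — does
    adversity still predict disease given the marker, and vice versa?
    Model (ii): linear ``marker ~ SLE + MD (+ covariates)`` — does
    adversity still predict the marker given disease state?
    """
    y = np.asarray(status, dtype=float)
    marker = np.asarray(markers, dtype=float)
    sle = np.asarray(sle_counts, dtype=float)

    base = pd.DataFrame({"sle": sle, "marker": marker})
    enc = _encode_covariates(covariates)
    if enc is not None:
        for col in enc.columns:
            base[col] = enc[col].to_numpy()

    design_i = sm.add_constant(base, has_constant="add").astype(float)
    fit_i = sm.Logit(y, design_i).fit(disp=0, maxiter=200)
    p_i = _term_pvalues(fit_i, ("sle", "marker"))

    base_ii = base.drop(columns="marker")
    base_ii["md"] = y
    design_ii = sm.add_constant(base_ii, has_constant="add").astype(float)
    fit_ii = sm.OLS(marker, design_ii).fit()
    p_ii = float(fit_ii.pvalues["sle"])

    marginal = linear_assoc(marker, sle, covariates).p
    strata = stratified_table(marker, status.astype(int)
                              if hasattr(status, "astype")
                              else np.asarray(status, int),
                              np.asarray(sle_counts, int), cap=cap)
    stratum_ps = tuple(s.p for s in strata)

    label = classify(p_i["sle"], p_i["marker"], p_ii, marginal,
                     stratum_ps, alpha=alpha)
    return InferenceVerdict(
        md_sle_given_marker_p=p_i["sle"],
        md_marker_given_sle_p=p_i["marker"],
        marker_sle_given_md_p=p_ii,
        marginal_marker_sle_p=marginal,
        stratum_ps=stratum_ps,
        classification=label, alpha=alpha)
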