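"""qPCR marker quantification: ΔΔCq relative copy number, MMQPCR T/S
telomere ratio, run-level QC, and fold-change normalisation.

Well tables carry one row per well (``well, sample, target, cq,
replicate_group, group``) with targets drawn from ``mito``,
``nuclear_ref``, ``telomere``, ``single_copy_gene`` and ``NTC``.
Run-level metrics (per-target amplification efficiency in %, standard
curve R², NTC Cq) accompany the wells in :class:`QpcrPlate`.

QC discards a run when any of the following holds (all thresholds
configurable): the no-template control amplifies early (NTC Cq below
38, contamination), any sample Cq exceeds 30 (too little template),
amplification efficiency falls outside 90–110%, the standard curve R²
is below 0.980, or any replicate group's Cq SD exceeds 0.20.

Relative quantification follows the efficiency-corrected ΔΔCq
convention: with per-cycle amplification ``1 + E`` (E = 1 is perfect
doubling), a sample's ratio is

    (1 + E_t)^(−ΔCq_t) / (1 + E_r)^(−ΔCq_r)

with each ΔCq taken relative to the baseline group's mean Cq for that
target.  At E = 1 this is exactly 2^(−ΔΔCq).  Baseline-group ratios
therefore have geometric mean 1; :func:`fold_change` provides the
exact arithmetic mean-1 normalisation used for time-course displays
("the baseline group's mean is set to 1").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = ["QpcrPlate", "QcThresholds", "QcReport", "qc_run",
           "replicate_means", "relative_quantity", "ts_ratio", "fold_change"]

WELL_COLUMNS = ("well", "sample", "target", "cq", "replicate_group", "group")


@dataclass
class QpcrPlate:
    """Well table plus run-level metrics.

    ``run_metrics`` keys: ``efficiency_pct`` (mapping target → %),
    ``standard_curve_r2``, ``ntc_cq``.  Missing metrics are tolerated
    (QC then flags the corresponding rule as not evaluable).
    """

    wells: pd.DataFrame
    run_metrics: Dict = field(default_factory=dict)

    def __post_init__(self):
        missing = set(WELL_COLUMNS) - set(self.wells.columns)
        if missing:
            raise ValueError(f"well table missing columns: {sorted(missing)}")
        if (self.wells["cq"] <= 0).any():
            raise ValueError("Cq values must be positive")

    @classmethod
    def from_tsv(cls, path, run_metrics: Optional[Dict] = None) -> "QpcrPlate":
        return cls(pd.read_csv(path, sep="\t"), run_metrics or {})


@dataclass(frozen=True)
class QcThresholds:
    """Run-discard thresholds (defaults per the standard criteria)."""

    ntc_min_cq: float = 38.0
    sample_max_cq: float = 30.0
    efficiency_pct: Tuple[float, float] = (90.0, 110.0)
    r2_min: float = 0.980
    replicate_sd_max: float = 0.20


@dataclass(frozen=True)
class QcReport:
    """QC outcome: ``passed`` iff ``failed_rules`` is empty.  Rules that
    could not be evaluated (missing metric) appear in ``failed_rules``
    with a ``_not_evaluable`` suffix, so a run with missing metrics is
    flagged rather than silently passed."""

    passed: bool
    failed_rules: Tuple[str, ...]


def qc_run(plate: QpcrPlate,
           thresholds: QcThresholds = QcThresholds()) -> QcReport:
    """Evaluate the run-discard rules against a plate."""
    failed: List[str] = []
    wells = plate.wells
    metrics = plate.run_metrics

    # NTC contamination: early amplification in the no-template control
    ntc_cq = metrics.get("ntc_cq")
    if ntc_cq is None:
        ntc_wells = wells.loc[wells["target"] == "NTC", "cq"]
        ntc_cq = float(ntc_wells.min()) if len(ntc_wells) else None
    if ntc_cq is None:
        failed.append("ntc_not_evaluable")
    elif ntc_cq < thresholds.ntc_min_cq:
        failed.append("ntc")

    # low-input samples
    sample_cq = wells.loc[wells["target"] != "NTC", "cq"]
    if len(sample_cq) == 0:
        failed.append("sample_cq_not_evaluable")
    elif (sample_cq > thresholds.sample_max_cq).any():
        failed.append("sample_cq")

    # amplification efficiency per target
    eff = metrics.get("efficiency_pct")
    if eff is None:
        failed.append("efficiency_not_evaluable")
    else:
        values = eff.values() if isinstance(eff, dict) else [eff]
        lo, hi = thresholds.efficiency_pct
        if any(not (lo <= e <= hi) for e in values):
            failed.append("efficiency")

    # standard curve fit
    r2 = metrics.get("standard_curve_r2")
    if r2 is None:
        failed.append("standard_curve_r2_not_evaluable")
    elif r2 < thresholds.r2_min:
        failed.append("standard_curve_r2")

    # replicate consistency
    rep = wells.loc[wells["target"] != "NTC"]
    if len(rep):
        sds = rep.groupby("replicate_group")["cq"].std(ddof=1).dropna()
        if (sds > thresholds.replicate_sd_max).any():
            failed.append("replicate_sd")

    return QcReport(passed=not failed, failed_rules=tuple(failed))


def replicate_means(wells: pd.DataFrame) -> pd.DataFrame:
    """Replicate-mean Cq per (sample, target), carrying the group
    label; NTC wells are dropped."""
    sub = wells.loc[wells["target"] != "NTC"]
    return (sub.groupby(["sample", "target"], as_index=False)
            .agg(cq=("cq", "mean"), group=("group", "first")))


def relative_quantity(wells: pd.DataFrame, *,
                      baseline_group: str,
                      target: str = "mito",
                      reference: str = "nuclear_ref",
                      efficiency_target: float = 1.0,
                      efficiency_ref: float = 1.0) -> pd.DataFrame:
    """Per-sample efficiency-corrected ΔΔCq ratio of ``target`` to
    ``reference``, relative to the ``baseline_group`` mean.

    Samples lacking the reference target are excluded with a warning.
    Returns columns ``sample, group, ratio``.
    """
    means = replicate_means(wells)
    t = means.loc[means["target"] == target, ["sample", "group", "cq"]]
    r = means.loc[means["target"] == reference, ["sample", "cq"]]
    merged = t.merge(r, on="sample", how="left", suffixes=("_t", "_r"))
    dropped = merged["cq_r"].isna()
    if dropped.any():
        warnings.warn(f"excluding {int(dropped.sum())} sample(s) lacking the "
                      f"reference target {reference!r}", stacklevel=2)
        merged = merged.loc[~dropped]
    baseline = merged.loc[merged["group"] == baseline_group]
    if baseline.empty:
        raise ValueError(f"baseline group {baseline_group!r} has no samples")
    d_t = merged["cq_t"] - baseline["cq_t"].mean()
    d_r = merged["cq_r"] - baseline["cq_r"].mean()
    ratio = ((1.0 + efficiency_target) ** (-d_t)
             / (1.0 + efficiency_ref) ** (-d_r))
    return pd.DataFrame({"sample": merged["sample"].to_numpy(),
                         "group": merged["group"].to_numpy(),
                         "ratio": ratio.to_numpy()})


def ts_ratio(wells: pd.DataFrame, *, baseline_group: str,
             efficiency_telomere: float = 1.0,
             efficiency_single_copy: float = 1.0) -> pd.DataFrame:
    """Monochrome-multiplex qPCR T/S ratio: telomere product over a
    single-copy nuclear gene, relative to the baseline group."""
    return relative_quantity(wells, baseline_group=baseline_group,
                             target="telomere",
                             reference="single_copy_gene",
                             efficiency_target=efficiency_telomere,
                             efficiency_ref=efficiency_single_copy)


def fold_change(values, groups, baseline_group) -> np.ndarray:
    """Divide every value by the baseline group's mean, so baseline
    values average exactly 1 and other groups read as fold changes."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    base = values[groups == baseline_group]
    if base.size == 0:
        raise ValueError(f"baseline group {baseline_group!r} is empty")
    mean = base.mean()
    if mean <= 0:
        raise ValueError("baseline group mean must be positive")
    return values / mean
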