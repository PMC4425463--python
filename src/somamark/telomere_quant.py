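"""Mean telomere length from telomeric-repeat read counting.

A read is *telomeric* when it contains at least ``k_min``
non-overlapping copies of the vertebrate telomere repeat (TTAGGG on
either strand).  The telomeric count t is put in ratio to a
GC-comparable coverage-reference count s (reads whose GC fraction lies
in a narrow window around the repeat's 50%), which cancels both overall
sequencing depth and first-order GC bias.  The ratio is scaled to a
per-end mean length in kb:

    length = (t / s) × genome_scale_kb / n_ends

with ``n_ends = 92`` telomeric tracts per diploid cell by default.  The
absolute kb calibration depends on ``genome_scale_kb`` (the effective
genome represented by s); rank and ratio properties of the estimate —
monotone in the true length, invariant under uniform depth rescaling —
hold regardless of it.

Normalisation across a cohort regresses lengths on batch and age and
inverse-normal transforms the residuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .exceptions import InvalidConfigError, NoSignalError
from .readset import AlignedReadSet
from .stats_assoc import inverse_normal, residualize
from .synthetic_data import TELOMERE_REPEAT, revcomp

__all__ = ["count_telomeric_reads", "gc_reference_count", "estimate_length",
           "normalize_marker", "quantify_sample", "TelomereEstimate",
           "K_MIN_DEFAULT", "GC_BOUNDS_DEFAULT", "N_ENDS_DEFAULT"]

K_MIN_DEFAULT = 7
GC_BOUNDS_DEFAULT = (0.48, 0.52)
N_ENDS_DEFAULT = 92


def _sequences(reads: Union[AlignedReadSet, Iterable[str]],
               exclude_refs: Tuple[str, ...] = ()) -> pd.Series:
    if isinstance(reads, AlignedReadSet):
        frame = reads.frame
        if exclude_refs:
            frame = frame.loc[~frame["ref"].isin(exclude_refs)]
        return frame["seq"].dropna().astype(str)
    return pd.Series([s for s in reads if s], dtype=object)


def _repeat_hits(seqs: pd.Series, repeat_unit: str, k_min: int) -> pd.Series:
    """Boolean per read: total non-overlapping forward + reverse-strand
    repeat occurrences reach ``k_min``."""
    if not repeat_unit:
        raise InvalidConfigError("repeat unit must be non-empty")
    unit = repeat_unit.upper()
    rc = revcomp(unit)
    counts = seqs.str.count(unit)
    if rc != unit:
        counts = counts + seqs.str.count(rc)
    return counts >= k_min


def count_telomeric_reads(reads: Union[AlignedReadSet, Iterable[str]],
                          repeat_unit: str = TELOMERE_REPEAT,
                          k_min: int = K_MIN_DEFAULT) -> int:
    """Number of reads containing ≥ ``k_min`` non-overlapping repeat
    units on either strand (TTAGGG or CCCTAA by default)."""
    seqs = _sequences(reads)
    if seqs.empty:
        return 0
    return int(_repeat_hits(seqs, repeat_unit, k_min).sum())


def gc_reference_count(reads: Union[AlignedReadSet, Iterable[str]],
                       gc_bounds: Tuple[float, float] = GC_BOUNDS_DEFAULT,
                       repeat_unit: str = TELOMERE_REPEAT,
                       k_min: int = K_MIN_DEFAULT,
                       exclude_refs: Tuple[str, ...] = ("MT",)) -> int:
    """Coverage-reference count s: reads whose GC fraction lies in
    ``gc_bounds``, excluding telomeric reads (whose repeat is itself
    50% GC and would otherwise leak into the denominator) and reads
    mapped to the references in ``exclude_refs``.  The mitochondrial
    reference is excluded by default because mtDNA depth varies
    enormously between samples and the denominator must track nuclear
    coverage only."""
    seqs = _sequences(reads, exclude_refs=exclude_refs)
    if seqs.empty:
        return 0
    gc = (seqs.str.count("G") + seqs.str.count("C")) / seqs.str.len()
    in_window = (gc >= gc_bounds[0]) & (gc <= gc_bounds[1])
    telomeric = _repeat_hits(seqs, repeat_unit, k_min)
    return int((in_window & ~telomeric).sum())


def estimate_length(t_count: int, s_count: int, genome_scale_kb: float,
                    n_ends: int = N_ENDS_DEFAULT) -> float:
    """Mean telomere length per chromosome end, kb.

    Linear in ``t_count``; invariant to uniform depth rescaling since t
    and s scale together.  Zero iff ``t_count`` is zero.

    Raises
    ------
    NoSignalError
        If ``s_count`` is zero (no coverage reference).
    """
    if s_count <= 0:
        raise NoSignalError("no coverage-reference reads; cannot scale the "
                            "telomeric count")
    if t_count < 0:
        raise ValueError("t_count must be non-negative")
    if n_ends <= 0 or genome_scale_kb <= 0:
        raise InvalidConfigError("genome_scale_kb and n_ends must be positive")
    return (t_count / s_count) * genome_scale_kb / n_ends


@dataclass(frozen=True)
class TelomereEstimate:
    """One sample's telomere quantities."""

    t_count: int
    s_count: int
    length_kb: float


def quantify_sample(reads: Union[AlignedReadSet, Iterable[str]], *,
                    genome_scale_kb: float,
                    repeat_unit: str = TELOMERE_REPEAT,
                    k_min: int = K_MIN_DEFAULT,
                    gc_bounds: Tuple[float, float] = GC_BOUNDS_DEFAULT,
                    n_ends: int = N_ENDS_DEFAULT,
                    exclude_refs: Tuple[str, ...] = ("MT",)) -> TelomereEstimate:
    """Full single-sample pipeline: count, reference, scale."""
    t = count_telomeric_reads(reads, repeat_unit=repeat_unit, k_min=k_min)
    s = gc_reference_count(reads, gc_bounds=gc_bounds,
                           repeat_unit=repeat_unit, k_min=k_min,
                           exclude_refs=exclude_refs)
    return TelomereEstimate(t_count=t, s_count=s,
                            length_kb=estimate_length(
                                t, s, genome_scale_kb, n_ends=n_ends))


def normalize_marker(lengths, batch, age, offset: float = 0.5) -> np.ndarray:
    """Normalised telomere score across a cohort: OLS on batch
    (categorical) and age, then rank-based inverse normal transform of
    the residuals."""
    covariates = pd.DataFrame({
        "batch": np.asarray(batch),
        "age": np.asarray(age, dtype=float),
    })
    resid = residualize(lengths, covariates, categorical=("batch",))
    return inverse_normal(resid, offset=offset)
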