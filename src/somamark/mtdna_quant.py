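"""Per-sample mtDNA abundance from aligned low-coverage reads.

The estimate proceeds in four steps:

1. :func:`filter_reads` — retain reads with MAPQ ≥ 59 whose FLAG has no
   bit in common with 1804 (unmapped, mate unmapped, secondary, QC
   fail, duplicate), removing contaminants and ambiguous alignments.
2. :func:`depth_profile` — mean read depth per 100-bp segment of the
   mitochondrial reference, before and after filtering.
3. :func:`numt_mask` — exclude segments whose unfiltered depth exceeds
   the filtered depth by more than 5% of the filtered depth; such
   segments most likely span NUMTs (nuclear copies of mitochondrial
   DNA) whose multi-mapping reads distort depth.
4. :func:`copy_number_raw` — mean filtered depth over retained
   segments, the raw per-sample measure; :func:`normalize_marker`
   regresses it on batch, age and nuclear (chromosome-20 proxy) depth
   and maps the residuals through the rank-based inverse normal
   transform.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import NoSignalError
from .readset import AlignedReadSet
from .stats_assoc import inverse_normal, residualize

__all__ = ["filter_reads", "depth_profile", "numt_mask", "copy_number_raw",
           "normalize_marker", "mean_depth", "quantify_sample",
           "DepthProfile", "MtEstimate",
           "MAPQ_MIN_DEFAULT", "FLAG_MASK_DEFAULT", "SEGMENT_SIZE_DEFAULT",
           "NUMT_THRESHOLD_DEFAULT"]

MAPQ_MIN_DEFAULT = 59
FLAG_MASK_DEFAULT = 1804  # unmapped | mate unmapped | secondary | QC fail | dup
SEGMENT_SIZE_DEFAULT = 100
NUMT_THRESHOLD_DEFAULT = 0.05


def filter_reads(reads: AlignedReadSet,
                 mapq_min: int = MAPQ_MIN_DEFAULT,
                 flag_mask: int = FLAG_MASK_DEFAULT) -> AlignedReadSet:
    """Retain reads with ``MAPQ >= mapq_min`` and ``FLAG & flag_mask == 0``.

    Idempotent; an empty input yields an empty output.
    """
    flag = reads.frame["flag"].to_numpy()
    mapq = reads.frame["mapq"].to_numpy()
    return reads.subset((mapq >= mapq_min) & ((flag & flag_mask) == 0))


@dataclass(frozen=True)
class DepthProfile:
    """Per-segment mean depths on the mitochondrial reference.

    ``unfiltered``/``filtered`` are mean depths per segment (the final
    partial segment is normalised by its true length);
    ``retained_mask`` is None until a NUMT mask is attached.
    """

    unfiltered: np.ndarray
    filtered: np.ndarray
    reference_length: int
    segment_size: int = SEGMENT_SIZE_DEFAULT
    retained_mask: Optional[np.ndarray] = None

    def __post_init__(self):
        if len(self.unfiltered) != len(self.filtered):
            raise ValueError("depth arrays must have equal length")
        expected = math.ceil(self.reference_length / self.segment_size)
        if len(self.unfiltered) != expected:
            raise ValueError("depth arrays inconsistent with reference length")

    @property
    def n_segments(self) -> int:
        return len(self.filtered)

    def segment_lengths(self) -> np.ndarray:
        lengths = np.full(self.n_segments, self.segment_size, dtype=float)
        remainder = self.reference_length % self.segment_size
        if remainder:
            lengths[-1] = remainder
        return lengths

    def with_mask(self, mask: np.ndarray) -> "DepthProfile":
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.filtered.shape:
            raise ValueError("mask shape mismatch")
        return replace(self, retained_mask=mask)


def _segment_depths(reads: AlignedReadSet, ref: str, ref_length: int,
                    segment_size: int) -> np.ndarray:
    """Mean depth per segment from summed per-base coverage."""
    sub = reads.on_reference(ref)
    pos = sub.frame["pos"].to_numpy()
    length = sub.frame["length"].to_numpy()
    start = pos.copy()
    end = pos + length
    if np.any(start < 0) or np.any(end > ref_length):
        warnings.warn("reads extending beyond the reference were clipped",
                      stacklevel=3)
        start = np.clip(start, 0, ref_length)
        end = np.clip(end, 0, ref_length)
    delta = np.zeros(ref_length + 1)
    np.add.at(delta, start, 1.0)
    np.add.at(delta, end, -1.0)
    per_base = np.cumsum(delta[:-1])
    n_segments = math.ceil(ref_length / segment_size)
    sums = np.zeros(n_segments)
    seg_index = np.arange(ref_length) // segment_size
    np.add.at(sums, seg_index, per_base)
    lengths = np.full(n_segments, segment_size, dtype=float)
    remainder = ref_length % segment_size
    if remainder:
        lengths[-1] = remainder
    return sums / lengths


def depth_profile(reads_unfiltered: AlignedReadSet,
                  reads_filtered: AlignedReadSet,
                  mito_length: int,
                  segment_size: int = SEGMENT_SIZE_DEFAULT,
                  mito_ref: str = "MT") -> DepthProfile:
    """Per-segment mean depths before and after filtering.

    Mean depth of a segment is the summed overlapping bases divided by
    the segment's true length (the final partial segment is shorter).
    Reads extending beyond the reference are clipped with a warning.
    """
    return DepthProfile(
        unfiltered=_segment_depths(reads_unfiltered, mito_ref, mito_length,
                                   segment_size),
        filtered=_segment_depths(reads_filtered, mito_ref, mito_length,
                                 segment_size),
        reference_length=mito_length, segment_size=segment_size)


def numt_mask(profile: DepthProfile,
              rel_threshold: float = NUMT_THRESHOLD_DEFAULT) -> np.ndarray:
    """Boolean retain-mask over segments.

    A segment is retained iff its depth excess
    ``unfiltered - filtered`` is at most ``rel_threshold`` of the
    filtered depth.  Zero-filtered-depth segments are excluded (the
    relative rule is undefined there and the segment carries no
    signal).
    """
    d_f = np.asarray(profile.filtered, dtype=float)
    d_u = np.asarray(profile.unfiltered, dtype=float)
    return (d_f > 0) & ((d_u - d_f) <= rel_threshold * d_f)


def copy_number_raw(profile: DepthProfile,
                    retained_mask: Optional[np.ndarray] = None) -> float:
    """Mean filtered depth across retained segments (the raw mtDNA
    abundance measure, in reads×bp/bp).

    The mask defaults to ``profile.retained_mask`` or, failing that, to
    :func:`numt_mask` at the default threshold.

    Raises
    ------
    NoSignalError
        If no segment is retained.
    """
    if retained_mask is None:
        retained_mask = (profile.retained_mask
                         if profile.retained_mask is not None
                         else numt_mask(profile))
    retained_mask = np.asarray(retained_mask, dtype=bool)
    if not retained_mask.any():
        raise NoSignalError("no depth segments retained; cannot estimate "
                            "mtDNA abundance")
    return float(profile.filtered[retained_mask].mean())


def mean_depth(reads: AlignedReadSet, ref: str, ref_length: int) -> float:
    """Mean depth of ``reads`` over a whole reference (clipped bases /
    reference length); used for the nuclear (chr20 proxy) covariate."""
    sub = reads.on_reference(ref)
    pos = sub.frame["pos"].to_numpy()
    length = sub.frame["length"].to_numpy()
    covered = np.clip(pos + length, 0, ref_length) - np.clip(pos, 0, ref_length)
    return float(covered.sum() / ref_length)


@dataclass(frozen=True)
class MtEstimate:
    """One sample's mtDNA quantities."""

    raw_mean_depth: float
    chr20_mean_depth: float
    n_segments_retained: int
    n_reads_filtered: int


def quantify_sample(reads: AlignedReadSet, *,
                    mito_length: int = 16_569,
                    mito_ref: str = "MT",
                    nuclear_ref: str = "chr20",
                    nuclear_length: int = 2_000_000,
                    mapq_min: int = MAPQ_MIN_DEFAULT,
                    flag_mask: int = FLAG_MASK_DEFAULT,
                    segment_size: int = SEGMENT_SIZE_DEFAULT,
                    numt_threshold: float = NUMT_THRESHOLD_DEFAULT
                    ) -> MtEstimate:
    """Full single-sample pipeline: filter, profile, mask, average."""
    filtered = filter_reads(reads, mapq_min=mapq_min, flag_mask=flag_mask)
    profile = depth_profile(reads, filtered, mito_length,
                            segment_size=segment_size, mito_ref=mito_ref)
    mask = numt_mask(profile, rel_threshold=numt_threshold)
    raw = copy_number_raw(profile, mask)
    chr20 = mean_depth(filtered, nuclear_ref, nuclear_length)
    return MtEstimate(raw_mean_depth=raw, chr20_mean_depth=chr20,
                      n_segments_retained=int(mask.sum()),
                      n_reads_filtered=len(filtered))


def normalize_marker(raw, batch, age, chr20_depth,
                     offset: float = 0.5) -> np.ndarray:
    """Normalised mtDNA score across a cohort.

    One joint OLS of the raw mean depth on sequencing batch
    (categorical), age, and mean filtered nuclear (chr20) depth;
    residuals are mapped through the rank-based inverse normal
    transform.  Constant covariates are dropped with a warning.
    """
    covariates = pd.DataFrame({
        "batch": np.asarray(batch),
        "age": np.asarray(age, dtype=float),
        "chr20_depth": np.asarray(chr20_depth, dtype=float),
    })
    resid = residualize(raw, covariates, categorical=("batch",))
    return inverse_normal(resid, offset=offset)
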