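"""Synthetic read-level and cohort-level inputs with known ground truth.

Two generators cover the two halves of the pipeline:

* :func:`simulate_reads` emits an :class:`~somamark.readset.AlignedReadSet`
  emulating the mixed origins seen when low-coverage whole-genome reads
  are mapped against a reference that includes the mitochondrial genome:
  nuclear reads on a "chromosome 20" proxy segment, mitochondrial reads
  at a depth set by the per-cell mtDNA copy number, NUMT-confounded
  reads (see below), bacterial contaminants, and telomeric-repeat reads.

* :func:`simulate_cohort` emits a case-control phenotype/marker table
  under one of three causal structures relating stressful life events
  (SLE), major depression (MD), and a molecular marker:

  - ``STATE_DEPENDENT`` — SLE raises MD risk; the marker shifts only
    with current MD status (marker ⫫ SLE given MD, by construction).
  - ``MEDIATED`` — SLE shifts the marker, the marker raises MD risk,
    and SLE has no direct effect on MD.
  - ``INDEPENDENT`` — SLE raises MD risk and shifts the marker through
    separate paths; marker and MD are conditionally unrelated.

NUMT emulation
--------------
Nuclear copies of mitochondrial DNA (NUMTs) confound depth-based copy
number estimates in two ways, both emulated here.  A read of true
mitochondrial origin that lies entirely within a NUMT-homologous
interval is ambiguous unless it samples at least one diverged site, so
it keeps its position but receives MAPQ 0 with probability
``(1 - divergence)**read_length``.  Reads of the nuclear NUMT copies
themselves additionally appear on the mitochondrial reference as
secondary alignments (FLAG 0x100, MAPQ 0) at the nuclear depth.  The
net effect — filtered depth drops and unfiltered depth rises inside
NUMT intervals — is what the downstream filtered-vs-unfiltered segment
mask detects.

All randomness flows from a single integer seed; independent
sub-streams are derived with fixed offsets, so equal configurations
give byte-identical outputs.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidConfigError
from .readset import (AlignedReadSet, FLAG_QCFAIL, FLAG_SECONDARY,
                      FLAG_SUPPLEMENTARY, FLAG_UNMAPPED)

# fixed sub-stream offsets (design: one global seed)
_S_NUCLEAR, _S_MITO, _S_NUMT, _S_CONTAM, _S_TELO, _S_COHORT, _S_PLATE = range(7)

_PAIRED_MAPPED_FLAG = 99  # paired, proper pair, mate reverse, first in pair

TELOMERE_REPEAT = "TTAGGG"

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMP)[::-1]


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stream])


def _random_seqs(rng: np.random.Generator, lengths: np.ndarray) -> list:
    """Uniform-random ACGT strings with the given lengths (vectorised)."""
    lengths = np.asarray(lengths, dtype=np.int64)
    total = int(lengths.sum())
    if total == 0:
        return [""] * len(lengths)
    letters = np.frombuffer(b"ACGT", dtype=np.uint8)
    flat = letters[rng.integers(0, 4, size=total)]
    text = flat.tobytes().decode("ascii")
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    return [text[offsets[i]:offsets[i + 1]] for i in range(len(lengths))]


# ---------------------------------------------------------------------------
# read-level simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadSimConfig:
    """Configuration of the read-level simulator.

    Attributes
    ----------
    mito_genome_length:
        Mitochondrial reference length in bp (human: 16,569).
    nuclear_proxy_length:
        Length of the stand-in "chromosome 20" nuclear segment, bp.
    numt_definitions:
        Sequence of ``((start, end), divergence)`` pairs: NUMT-homologous
        intervals on the mitochondrial reference (0-based, half-open)
        and the per-bp divergence of the nuclear copy.
    telomere_true_length:
        True mean telomere length per chromosome end, kb.
    telomere_ends:
        Number of telomeric tracts per diploid cell (46 chromosomes ×
        2 ends = 92).
    read_length:
        Read length, bp.
    nuclear_mean_depth:
        Mean haploid-reference depth of the nuclear genome (reads×bp/bp).
    mtdna_copies_per_cell:
        Mitochondrial genome copies per (diploid) cell.  Expected
        mitochondrial depth is ``nuclear_mean_depth × copies / 2``.
    contamination_fraction:
        Fraction of mitochondrion-aligned reads that are bacterial
        contaminants (emitted with low MAPQ and the QC-fail FLAG bit).
    emit_sequences:
        When False, nuclear/mitochondrial read sequences are omitted
        (depth-only studies run much faster); telomeric reads always
        carry sequence.
    """

    mito_genome_length: int = 16_569
    nuclear_proxy_length: int = 2_000_000
    numt_definitions: Tuple[Tuple[Tuple[int, int], float], ...] = (
        ((5_000, 5_600), 0.005),
        ((12_000, 12_400), 0.01),
    )
    telomere_true_length: float = 5.0
    telomere_ends: int = 92
    read_length: int = 100
    nuclear_mean_depth: float = 1.7
    mtdna_copies_per_cell: float = 120.0
    contamination_fraction: float = 0.01
    emit_sequences: bool = True
    seed: int = 0
    mito_ref: str = "MT"
    nuclear_ref: str = "chr20"

    def __post_init__(self):
        if self.mito_genome_length <= 0 or self.nuclear_proxy_length <= 0 \
                or self.read_length <= 0:
            raise InvalidConfigError("all lengths must be positive")
        if self.nuclear_mean_depth <= 0:
            raise InvalidConfigError("nuclear_mean_depth must be positive")
        if self.mtdna_copies_per_cell <= 0:
            raise InvalidConfigError("mtdna_copies_per_cell must be positive")
        if not 0 <= self.contamination_fraction < 1:
            raise InvalidConfigError(
                "contamination_fraction must lie in [0, 1)")
        if self.telomere_true_length < 0 or self.telomere_ends <= 0:
            raise InvalidConfigError("telomere configuration invalid")
        for (start, end), divergence in self.numt_definitions:
            if not (0 <= start < end <= self.mito_genome_length):
                raise InvalidConfigError(
                    f"NUMT interval ({start}, {end}) outside mitochondrial "
                    f"reference [0, {self.mito_genome_length})")
            if not 0 <= divergence <= 1:
                raise InvalidConfigError("divergence must lie in [0, 1]")

    @property
    def references(self) -> dict:
        """Reference name → length mapping for SAM headers."""
        return {self.mito_ref: self.mito_genome_length,
                self.nuclear_ref: self.nuclear_proxy_length}


def expected_read_counts(config: ReadSimConfig) -> dict:
    """Expected reads per truth-origin class under ``config``.

    Used by goodness-of-fit checks and for sizing; the actual counts
    are Poisson around these values.
    """
    L = config.read_length
    mito_depth = config.nuclear_mean_depth * config.mtdna_copies_per_cell / 2.0
    n_mito = mito_depth * config.mito_genome_length / L
    n_nuclear = config.nuclear_mean_depth * config.nuclear_proxy_length / L
    f = config.contamination_fraction
    n_contam = n_mito * f / (1.0 - f)
    n_numt = sum(config.nuclear_mean_depth * (end - start) / L
                 for (start, end), _ in config.numt_definitions
                 if end - start >= L)
    # read-start rate per diploid bp is depth / (2 * read_length)
    n_telo = (config.nuclear_mean_depth * config.telomere_ends
              * config.telomere_true_length * 1000.0 / (2.0 * L))
    return {"nuclear": n_nuclear, "mito": n_mito, "numt": n_numt,
            "contaminant": n_contam, "telomeric": n_telo}


def _telomere_templates(read_length: int) -> list:
    """The 12 distinct pure-repeat read sequences (6 phases × 2 strands)."""
    unit = TELOMERE_REPEAT
    tract = unit * (read_length // len(unit) + 2)
    out = []
    for phase in range(len(unit)):
        fwd = tract[phase:phase + read_length]
        out.append(fwd)
        out.append(revcomp(fwd))
    return out


def simulate_reads(config: ReadSimConfig) -> AlignedReadSet:
    """Draw one sample's aligned read set under ``config``.

    Expected mitochondrial depth is
    ``nuclear_mean_depth × mtdna_copies_per_cell / 2`` (diploid-nucleus
    convention).  The mitochondrial genome is treated as circular:
    reads spanning the origin are split into two aligned records.
    Every read carries its truth-origin tag in the ``origin`` column.
    """
    L = config.read_length
    M = config.mito_genome_length
    exp = expected_read_counts(config)
    blocks = []

    # nuclear proxy reads ------------------------------------------------
    rng = _rng(config.seed, _S_NUCLEAR)
    n_nuc = rng.poisson(exp["nuclear"])
    pos = rng.integers(0, max(config.nuclear_proxy_length - L, 0) + 1, n_nuc)
    seqs = _random_seqs(rng, np.full(n_nuc, L)) if config.emit_sequences else None
    blocks.append(AlignedReadSet.from_columns(
        name=[f"nuc{i}" for i in range(n_nuc)],
        flag=np.full(n_nuc, _PAIRED_MAPPED_FLAG),
        ref=np.full(n_nuc, config.nuclear_ref, dtype=object),
        pos=pos, mapq=np.full(n_nuc, 60), length=np.full(n_nuc, L),
        seq=seqs, origin=["nuclear"] * n_nuc))

    # mitochondrial reads (circular genome, wrap-split) -------------------
    rng = _rng(config.seed, _S_MITO)
    n_mito = rng.poisson(exp["mito"])
    start = rng.integers(0, M, n_mito)
    end = start + L
    mapq = np.full(n_mito, 60)
    # ambiguity inside NUMT-homologous intervals
    for (a, b), divergence in config.numt_definitions:
        contained = (start >= a) & (end <= b)
        p_ambiguous = (1.0 - divergence) ** L
        ambiguous = contained & (rng.random(n_mito) < p_ambiguous)
        mapq[ambiguous] = 0
    wrap = end > M
    piece_len = np.where(wrap, M - start, L)
    names = np.array([f"mito{i}" for i in range(n_mito)], dtype=object)
    rows = {
        "name": names, "pos": start, "length": piece_len,
        "flag": np.full(n_mito, _PAIRED_MAPPED_FLAG), "mapq": mapq,
    }
    n_wrap = int(wrap.sum())
    if n_wrap:
        rows = {k: np.concatenate([v, v[wrap]]) for k, v in rows.items()}
        rows["pos"][n_mito:] = 0
        rows["length"][n_mito:] = (end - M)[wrap]
        rows["flag"][n_mito:] |= FLAG_SUPPLEMENTARY
    n_rows = n_mito + n_wrap
    seqs = (_random_seqs(rng, rows["length"])
            if config.emit_sequences else None)
    blocks.append(AlignedReadSet.from_columns(
        name=rows["name"], flag=rows["flag"],
        ref=np.full(n_rows, config.mito_ref, dtype=object),
        pos=rows["pos"], mapq=rows["mapq"], length=rows["length"],
        seq=seqs, origin=["mito"] * n_rows))

    # secondary alignments of nuclear NUMT copies -------------------------
    rng = _rng(config.seed, _S_NUMT)
    for j, ((a, b), _divergence) in enumerate(config.numt_definitions):
        span = b - a
        if span < L:
            continue
        n_numt = rng.poisson(config.nuclear_mean_depth * span / L)
        pos = rng.integers(a, b - L + 1, n_numt)
        seqs = (_random_seqs(rng, np.full(n_numt, L))
                if config.emit_sequences else None)
        blocks.append(AlignedReadSet.from_columns(
            name=[f"numt{j}_{i}" for i in range(n_numt)],
            flag=np.full(n_numt, _PAIRED_MAPPED_FLAG | FLAG_SECONDARY),
            ref=np.full(n_numt, config.mito_ref, dtype=object),
            pos=pos, mapq=np.zeros(n_numt, dtype=int),
            length=np.full(n_numt, L),
            seq=seqs, origin=["numt"] * n_numt))

    # bacterial contaminants ----------------------------------------------
    rng = _rng(config.seed, _S_CONTAM)
    n_cont = rng.poisson(exp["contaminant"])
    pos = rng.integers(0, max(M - L, 0) + 1, n_cont)
    seqs = (_random_seqs(rng, np.full(n_cont, L))
            if config.emit_sequences else None)
    blocks.append(AlignedReadSet.from_columns(
        name=[f"bac{i}" for i in range(n_cont)],
        flag=np.full(n_cont, _PAIRED_MAPPED_FLAG | FLAG_QCFAIL),
        ref=np.full(n_cont, config.mito_ref, dtype=object),
        pos=pos, mapq=np.full(n_cont, 20), length=np.full(n_cont, L),
        seq=seqs, origin=["contaminant"] * n_cont))

    # telomeric-repeat reads (unplaced) ------------------------------------
    rng = _rng(config.seed, _S_TELO)
    n_telo = rng.poisson(exp["telomeric"])
    templates = _telomere_templates(L)
    choice = rng.integers(0, len(templates), n_telo)
    seqs = [templates[c] for c in choice]
    blocks.append(AlignedReadSet.from_columns(
        name=[f"telo{i}" for i in range(n_telo)],
        flag=np.full(n_telo, FLAG_UNMAPPED),
        ref=np.full(n_telo, "*", dtype=object),
        pos=np.full(n_telo, -1), mapq=np.zeros(n_telo, dtype=int),
        length=np.full(n_telo, L), seq=seqs, origin=["telomeric"] * n_telo))

    return AlignedReadSet.concat(blocks)


# ---------------------------------------------------------------------------
# cohort-level simulation
# ---------------------------------------------------------------------------

class ScenarioKind(str, enum.Enum):
    STATE_DEPENDENT = "STATE_DEPENDENT"
    MEDIATED = "MEDIATED"
    INDEPENDENT = "INDEPENDENT"


@dataclass(frozen=True)
class CausalScenario:
    """One causal structure relating SLE, MD, and a molecular marker.

    Only the parameters belonging to ``kind`` may be non-zero:

    ===============  =============================================
    STATE_DEPENDENT  ``beta_sle_md``, ``delta_md_marker``
    MEDIATED         ``beta_sle_marker``, ``beta_marker_md``
    INDEPENDENT      ``beta_sle_md``, ``beta_sle_marker``
    ===============  =============================================

    Marker effects are in SD units of the marker's noise; MD effects
    are log-odds.
    """

    kind: ScenarioKind
    beta_sle_md: float = 0.0
    delta_md_marker: float = 0.0
    beta_marker_md: float = 0.0
    beta_sle_marker: float = 0.0
    baseline_prevalence: float = 0.5

    def __post_init__(self):
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise InvalidConfigError("baseline_prevalence must be in (0, 1)")
        kind = ScenarioKind(self.kind)
        object.__setattr__(self, "kind", kind)
        active = {
            ScenarioKind.STATE_DEPENDENT: ("beta_sle_md", "delta_md_marker"),
            ScenarioKind.MEDIATED: ("beta_sle_marker", "beta_marker_md"),
            ScenarioKind.INDEPENDENT: ("beta_sle_md", "beta_sle_marker"),
        }[kind]
        for name in ("beta_sle_md", "delta_md_marker", "beta_marker_md",
                     "beta_sle_marker"):
            if name not in active and getattr(self, name) != 0.0:
                raise InvalidConfigError(
                    f"{name} is not a parameter of a {kind.value} scenario")
        if kind is ScenarioKind.MEDIATED and all(
                getattr(self, name) == 0.0 for name in active):
            warnings.warn("MEDIATED scenario with all-zero effects is "
                          "degenerate (no mediation path)", stacklevel=2)

    # convenience constructors -------------------------------------------

    @classmethod
    def state_dependent(cls, beta_sle_md: float = math.log(1.6),
                        delta_md_marker: float = math.log(1.33),
                        baseline_prevalence: float = 0.5) -> "CausalScenario":
        return cls(ScenarioKind.STATE_DEPENDENT, beta_sle_md=beta_sle_md,
                   delta_md_marker=delta_md_marker,
                   baseline_prevalence=baseline_prevalence)

    @classmethod
    def mediated(cls, beta_sle_marker: float = 0.1,
                 beta_marker_md: float = 0.3,
                 baseline_prevalence: float = 0.5) -> "CausalScenario":
        return cls(ScenarioKind.MEDIATED, beta_sle_marker=beta_sle_marker,
                   beta_marker_md=beta_marker_md,
                   baseline_prevalence=baseline_prevalence)

    @classmethod
    def independent(cls, beta_sle_md: float = math.log(1.6),
                    beta_sle_marker: float = 0.05,
                    baseline_prevalence: float = 0.5) -> "CausalScenario":
        return cls(ScenarioKind.INDEPENDENT, beta_sle_md=beta_sle_md,
                   beta_sle_marker=beta_sle_marker,
                   baseline_prevalence=baseline_prevalence)

    @classmethod
    def null(cls, baseline_prevalence: float = 0.5) -> "CausalScenario":
        """All effects zero (for calibration studies)."""
        return cls(ScenarioKind.INDEPENDENT,
                   baseline_prevalence=baseline_prevalence)


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of the cohort-level simulator.

    ``scenario`` drives both the MD outcome and the mtDNA marker; an
    optional ``telomere_scenario`` adds the telomere marker's effects
    (its MD-side terms are folded into the same logit; its
    ``baseline_prevalence`` is ignored in favour of the primary
    scenario's).  Covariates enter the markers with small configurable
    effects: per-batch offsets drawn N(0, ``batch_sd``), a linear age
    trend of ``age_beta`` SD/yr about the mid-range age, and
    ``pc_beta`` per principal-component unit.
    """

    n_samples: int
    scenario: CausalScenario
    telomere_scenario: Optional[CausalScenario] = None
    sle_rate: float = 1.2
    csa_probs: Tuple[float, float, float, float] = (0.938, 0.023, 0.024, 0.015)
    csa_beta_mtdna: float = 0.0
    csa_beta_telomere: float = 0.0
    n_batches: int = 4
    age_range: Tuple[int, int] = (40, 60)
    n_pcs: int = 3
    batch_sd: float = 0.05
    age_beta: float = 0.005
    pc_beta: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 2:
            raise InvalidConfigError("n_samples must be at least 2")
        if abs(sum(self.csa_probs) - 1.0) > 1e-9:
            raise InvalidConfigError("csa_probs must sum to 1")
        if self.sle_rate < 0 or self.n_batches < 1 or self.n_pcs < 0:
            raise InvalidConfigError("invalid cohort configuration")
        if self.age_range[0] > self.age_range[1]:
            raise InvalidConfigError("age_range must be (low, high)")


@dataclass
class CohortTruth:
    """Latent per-sample simulation state (test oracle only).

    ``frame`` holds, per sample: the MD probability behind the
    Bernoulli draw, the noiseless marker scores, and the scenario kind.
    """

    frame: pd.DataFrame
    scenario: CausalScenario
    telomere_scenario: Optional[CausalScenario]


def simulate_cohort(config: CohortConfig) -> Tuple[pd.DataFrame, CohortTruth]:
    """Draw a case-control cohort table under ``config``.

    Returns the phenotype/marker table (columns ``sample_id, md, sle,
    csa, age, batch, pc1..pcN, mtdna, telomere``) and the latent truth.
    Deterministic given ``(config, config.seed)``.
    """
    n = config.n_samples
    rng = _rng(config.seed, _S_COHORT)

    sle = rng.poisson(config.sle_rate, n)
    csa = rng.choice(len(config.csa_probs), size=n, p=config.csa_probs)
    age = rng.integers(config.age_range[0], config.age_range[1] + 1, n)
    batch = rng.integers(0, config.n_batches, n)
    pcs = rng.standard_normal((n, config.n_pcs))
    batch_offsets = rng.standard_normal(config.n_batches) * config.batch_sd
    age_mid = (config.age_range[0] + config.age_range[1]) / 2.0

    def covariate_shift():
        shift = batch_offsets[batch] + config.age_beta * (age - age_mid)
        if config.n_pcs:
            shift = shift + config.pc_beta * pcs.sum(axis=1)
        return shift

    noise_mtdna = rng.standard_normal(n)
    noise_telomere = rng.standard_normal(n)

    primary = config.scenario
    secondary = config.telomere_scenario

    # pre-MD marker values (everything except state-dependent shifts)
    mtdna = noise_mtdna + covariate_shift() + config.csa_beta_mtdna * csa
    telomere = (noise_telomere + covariate_shift()
                + config.csa_beta_telomere * csa)
    mtdna = mtdna + primary.beta_sle_marker * sle
    if secondary is not None:
        telomere = telomere + secondary.beta_sle_marker * sle

    # MD from the primary scenario's logit; mediated marker terms from
    # whichever scenario declares them
    eta = np.full(n, math.log(primary.baseline_prevalence
                              / (1.0 - primary.baseline_prevalence)))
    eta = eta + primary.beta_sle_md * sle
    eta = eta + primary.beta_marker_md * mtdna
    if secondary is not None:
        eta = eta + secondary.beta_sle_md * sle
        eta = eta + secondary.beta_marker_md * telomere
    md_prob = 1.0 / (1.0 + np.exp(-eta))
    md = (rng.random(n) < md_prob).astype(int)

    # state-dependent shifts apply to the realised disease state
    mtdna = mtdna + primary.delta_md_marker * md
    if secondary is not None:
        telomere = telomere + secondary.delta_md_marker * md

    sample_id = [f"S{i:05d}" for i in range(n)]
    phenotypes = pd.DataFrame({
        "sample_id": sample_id, "md": md, "sle": sle, "csa": csa,
        "age": age, "batch": batch,
    })
    for k in range(config.n_pcs):
        phenotypes[f"pc{k + 1}"] = pcs[:, k]
    phenotypes["mtdna"] = mtdna
    phenotypes["telomere"] = telomere

    truth = pd.DataFrame({
        "sample_id": sample_id, "md_prob": md_prob, "md_status": md,
        "sle_count": sle, "csa_category": csa,
        "true_mtdna_score": mtdna, "true_telomere_score": telomere,
        "batch": batch, "age": age,
    })
    return phenotypes, CohortTruth(truth, primary, secondary)


# ---------------------------------------------------------------------------
# qPCR plate simulation
# ---------------------------------------------------------------------------

def simulate_qpcr_plate(true_ratios: pd.DataFrame, *,
                        target: str = "mito",
                        reference: str = "nuclear_ref",
                        replicates: int = 2,
                        efficiency: float = 1.0,
                        cq_noise_sd: float = 0.05,
                        base_cq_target: float = 22.0,
                        base_cq_reference: float = 20.0,
                        ntc_cq: float = 40.0,
                        seed: int = 0) -> pd.DataFrame:
    """Simulate a qPCR plate from known relative template amounts.

    ``true_ratios`` needs columns ``sample``, ``group`` and ``ratio``
    (relative quantity of the target template; the reference template
    is constant across samples).  One Cq observation per replicate per
    target is emitted with independent Gaussian noise, plus an NTC
    well.  A quantity ``q`` of template lowers the target Cq by
    ``log(q) / log(1 + efficiency)`` cycles.

    Returns a well table with columns ``well, sample, target, cq,
    replicate_group, group`` suitable for
    :class:`somamark.qpcr_quant.QpcrPlate`.
    """
    rng = _rng(seed, _S_PLATE)
    log_base = math.log(1.0 + efficiency)
    rows = []
    well = 0
    for rec in true_ratios.itertuples(index=False):
        cq_t = base_cq_target - math.log(rec.ratio) / log_base
        for tgt, cq_mean in ((target, cq_t), (reference, base_cq_reference)):
            for r in range(replicates):
                rows.append({
                    "well": f"W{well:03d}", "sample": rec.sample,
                    "target": tgt,
                    "cq": cq_mean + rng.normal(0.0, cq_noise_sd),
                    "replicate_group": f"{rec.sample}:{tgt}",
                    "group": rec.group,
                })
                well += 1
    rows.append({"well": f"W{well:03d}", "sample": "NTC", "target": "NTC",
                 "cq": ntc_cq, "replicate_group": "NTC", "group": "NTC"})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# simulation-convention calibration helpers
# ---------------------------------------------------------------------------

def expected_gc_acceptance(read_length: int,
                           gc_bounds: Tuple[float, float] = (0.48, 0.52)
                           ) -> float:
    """P(GC fraction of a uniform-random read falls in ``gc_bounds``).

    Base composition of simulated non-telomeric reads is uniform, so
    the GC count is Binomial(read_length, 0.5).
    """
    lo = math.ceil(gc_bounds[0] * read_length)
    hi = math.floor(gc_bounds[1] * read_length)
    b = stats.binom(read_length, 0.5)
    return float(b.cdf(hi) - b.cdf(lo - 1))


def simulation_genome_scale_kb(config: ReadSimConfig,
                               gc_bounds: Tuple[float, float] = (0.48, 0.52)
                               ) -> float:
    """Calibration constant making the telomere length estimator's
    output approximately kb-scaled under this simulator's conventions.

    The coverage-reference count s is the GC-window acceptance fraction
    of the nuclear reads, which sample the diploid proxy segment, hence
    scale = P(GC accepted) × 2 × proxy length (kb).
    """
    p = expected_gc_acceptance(config.read_length, gc_bounds)
    return p * 2.0 * config.nuclear_proxy_length / 1000.0
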