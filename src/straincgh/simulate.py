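"""Synthetic array-CGH cohorts with planted structure.

Generates a gene-level log2-ratio matrix for a cohort of diploid strains
partitioned into species-like groups, with:

  * a per-gene additive reference bias shared by every strain (the stand-in
    for comparing each strain against one common laboratory reference, which
    cohort-average re-normalization must cancel exactly),
  * group-specific copy-number events concentrated in subtelomeric regions
    (gains in one group mirrored by losses in another, like the subtelomeric
    helicase-gene blocks that separate the two large species groups),
  * i.i.d. Gaussian per-entry noise,

plus a matched functional-term collection containing one term planted inside
the event regions, and per-strain electrophoretic band patterns carrying
group-specific marker bands.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .enrichment import Term, TermCollection
from .karyotype import BandPattern

__all__ = [
    "CNVEvent",
    "SimulationConfig",
    "SyntheticCohort",
    "default_events",
    "build_annotation",
    "simulate_cohort",
    "simulate_bands",
    "null_config",
]

# simulated chromosome sizes in kb.  Adjacent sizes are either close enough
# to always co-migrate into one bin under the default 5% binning tolerance
# (563/577, 760/775, 924/948, 1078/1091 — the last mimicking two large
# chromosomes that run together on a gel) or separated by > 12% so jitter
# cannot split a bin inconsistently across strains.
CHROMOSOME_SIZES_KB: tuple[float, ...] = (
    230.0, 924.0, 315.0, 1532.0, 577.0, 270.0, 1091.0, 563.0,
    440.0, 760.0, 667.0, 2190.0, 948.0, 775.0, 1078.0, 365.0,
)

# group-specific marker bands (kb); group 0 carries the ~1300 kb band that
# distinguishes its karyotype, the sizes all sit >5% away from any
# chromosome band so binning keeps them separate
DEFAULT_MARKER_BANDS: dict[int, tuple[float, ...]] = {
    0: (1300.0,),
    1: (500.0,),
    2: (1800.0,),
    3: (2500.0,),
}


@dataclass(frozen=True)
class CNVEvent:
    """One planted copy-number event: every gene of ``group_index`` strains
    whose midpoint falls in [start_bp, end_bp] (1-based, closed) on
    ``chromosome`` is shifted by ``delta_log2``."""

    group_index: int
    chromosome: int
    start_bp: int
    end_bp: int
    delta_log2: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.delta_log2 == 0:
            raise ValueError("delta_log2 must be non-zero")
        if self.start_bp > self.end_bp or self.start_bp < 1:
            raise ValueError("event region must be a valid 1-based closed interval")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 16
    genes_per_chromosome: int = 300
    # one length for all chromosomes, or a sequence of per-chromosome lengths
    chromosome_length_bp: int | tuple[int, ...] = 900_000
    subtelomere_length_bp: int = 30_000
    group_sizes: tuple[int, ...] = (7, 13, 1, 1)
    # None -> the default planted structure from default_events(); () -> none
    cnv_events: tuple[CNVEvent, ...] | None = None
    noise_sd: float = 0.15
    reference_bias_sd: float = 0.3
    n_terms: int = 40
    genes_per_term: int = 20
    band_jitter: float = 0.003
    # group index -> extra marker band sizes (kb); None -> default markers
    marker_bands: dict[int, tuple[float, ...]] | None = None

    def chromosome_lengths(self) -> tuple[int, ...]:
        if isinstance(self.chromosome_length_bp, int):
            return (self.chromosome_length_bp,) * self.n_chromosomes
        lengths = tuple(int(x) for x in self.chromosome_length_bp)
        if len(lengths) != self.n_chromosomes:
            raise ValueError(
                "chromosome_length_bp sequence length must equal n_chromosomes"
            )
        return lengths

    def n_strains(self) -> int:
        return sum(self.group_sizes)

    def validate(self) -> None:
        if self.n_chromosomes < 1 or self.genes_per_chromosome < 1:
            raise ValueError("need at least one chromosome and one gene each")
        if not self.group_sizes or any(g < 1 for g in self.group_sizes):
            raise ValueError("group sizes must be positive integers")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")
        if self.reference_bias_sd < 0:
            raise ValueError("reference_bias_sd must be >= 0")
        if self.band_jitter < 0:
            raise ValueError("band_jitter must be >= 0")
        lengths = self.chromosome_lengths()
        for c, length in enumerate(lengths, start=1):
            if not self.subtelomere_length_bp < length / 2:
                raise ValueError(
                    f"subtelomere_length_bp must be < chromosome length / 2 "
                    f"(chromosome {c}: {length} bp)"
                )
        for ev in self.resolved_events():
            if not 1 <= ev.chromosome <= self.n_chromosomes:
                raise ValueError(f"event on unknown chromosome {ev.chromosome}")
            if ev.end_bp > lengths[ev.chromosome - 1]:
                raise ValueError(
                    f"event [{ev.start_bp}, {ev.end_bp}] exceeds chromosome "
                    f"{ev.chromosome} length {lengths[ev.chromosome - 1]}"
                )
            if not 0 <= ev.group_index < len(self.group_sizes):
                raise ValueError(f"event references unknown group {ev.group_index}")

    def resolved_events(self) -> tuple[CNVEvent, ...]:
        if self.cnv_events is None:
            return tuple(default_events(self))
        return tuple(self.cnv_events)

    def resolved_markers(self) -> dict[int, tuple[float, ...]]:
        markers = (
            DEFAULT_MARKER_BANDS if self.marker_bands is None else self.marker_bands
        )
        return {
            g: tuple(sizes)
            for g, sizes in markers.items()
            if 0 <= g < len(self.group_sizes)
        }


@dataclass(frozen=True)
class SyntheticCohort:
    annotation: pd.DataFrame
    matrix: pd.DataFrame
    truth_divergent_genes: frozenset[str]
    truth_partition: dict[str, int]
    terms: TermCollection
    bands: tuple[BandPattern, ...]


def default_events(config: SimulationConfig, delta: float = 1.0) -> list[CNVEvent]:
    """The standard planted structure.

    Group 0 gains and group 1 loses the same left-subtelomeric block on the
    first (up to) eight chromosomes — the mirrored gain/loss motif — while
    groups 2 and 3, when present, each gain both subtelomeres of one private
    chromosome so every group is separable from every other.
    """
    lengths = config.chromosome_lengths()
    sub = config.subtelomere_length_bp
    events: list[CNVEvent] = []
    n_groups = len(config.group_sizes)
    shared = min(8, config.n_chromosomes)
    for c in range(1, shared + 1):
        events.append(CNVEvent(0, c, 1, sub, +delta, label="subtel_block_gain"))
        if n_groups > 1:
            events.append(CNVEvent(1, c, 1, sub, -delta, label="subtel_block_loss"))
    for group, chrom in ((2, shared + 1), (3, shared + 2)):
        if group < n_groups and chrom <= config.n_chromosomes:
            L = lengths[chrom - 1]
            events.append(
                CNVEvent(group, chrom, 1, sub, +delta, label="private_gain_left")
            )
            events.append(
                CNVEvent(group, chrom, L - sub + 1, L, +delta,
                         label="private_gain_right")
            )
    return events


def build_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Gene coordinates laid out uniformly along each chromosome; a gene is
    subtelomeric when its midpoint lies within subtelomere_length_bp of
    either chromosome end.  Coordinates 1-based, closed."""
    config.validate()
    lengths = config.chromosome_lengths()
    rows = []
    for c in range(1, config.n_chromosomes + 1):
        L = lengths[c - 1]
        n = config.genes_per_chromosome
        spacing = L / n
        for i in range(n):
            start = int(round(i * spacing)) + 1
            end = min(int(round((i + 1) * spacing)), L)
            end = max(end, start)
            mid = (start + end) / 2.0
            subtel = mid <= config.subtelomere_length_bp or mid > L - config.subtelomere_length_bp
            rows.append(
                (f"g{c:02d}_{i + 1:04d}", c, start, end, int(subtel))
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "chromosome", "start", "end", "subtelomeric"]
    )


def _strain_ids(config: SimulationConfig) -> list[str]:
    return [f"strain{i + 1:02d}" for i in range(config.n_strains())]


def _partition(config: SimulationConfig) -> dict[str, int]:
    ids = _strain_ids(config)
    out: dict[str, int] = {}
    pos = 0
    for group, count in enumerate(config.group_sizes):
        for _ in range(count):
            out[ids[pos]] = group
            pos += 1
    return out


def _event_deltas(
    config: SimulationConfig, annotation: pd.DataFrame
) -> tuple[np.ndarray, frozenset[str]]:
    """Per-(gene, group) delta matrix and the planted truth gene set."""
    G = len(annotation)
    n_groups = len(config.group_sizes)
    deltas = np.zeros((G, n_groups))
    covered = np.zeros((G, n_groups), dtype=int)
    mid = (annotation["start"].to_numpy() + annotation["end"].to_numpy()) / 2.0
    chrom = annotation["chromosome"].to_numpy()
    truth_mask = np.zeros(G, dtype=bool)
    for ev in config.resolved_events():
        mask = (chrom == ev.chromosome) & (mid >= ev.start_bp) & (mid <= ev.end_bp)
        deltas[mask, ev.group_index] += ev.delta_log2
        covered[mask, ev.group_index] += 1
        truth_mask |= mask
    if (covered > 1).any():
        n_over = int((covered > 1).sum())
        warnings.warn(
            f"{n_over} (gene, group) pair(s) covered by overlapping events; "
            "deltas were summed",
            stacklevel=3,
        )
    truth = frozenset(annotation.loc[truth_mask, "gene_id"])
    return deltas, truth


def _simulate_terms(
    config: SimulationConfig, gene_ids: list[str], truth: frozenset[str]
) -> TermCollection:
    rng = np.random.default_rng([config.seed, 1])
    terms: list[Term] = []
    size = min(config.genes_per_term, len(gene_ids))
    for t in range(config.n_terms):
        members = rng.choice(len(gene_ids), size=size, replace=False)
        terms.append(
            Term(
                term_id=f"T{t + 1:03d}",
                name=f"background set {t + 1}",
                members=frozenset(gene_ids[i] for i in members),
            )
        )
    if truth:
        pool = sorted(truth)
        planted_size = min(config.genes_per_term, len(pool))
        members = rng.choice(len(pool), size=planted_size, replace=False)
        terms.append(
            Term(
                term_id="PLANTED",
                name="planted divergent-region set",
                members=frozenset(pool[i] for i in members),
            )
        )
    return TermCollection(terms)


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate the full synthetic cohort.

    value[g, s] = bias[g] + sum of event deltas applying to (g, group(s))
                + Normal(0, noise_sd),
    with bias[g] ~ Normal(0, reference_bias_sd) shared across strains.
    Deterministic given the config (including seed).
    """
    config.validate()
    annotation = build_annotation(config)
    gene_ids = annotation["gene_id"].tolist()
    strains = _strain_ids(config)
    partition = _partition(config)
    deltas, truth = _event_deltas(config, annotation)

    rng = np.random.default_rng([config.seed, 0])
    G, S = len(gene_ids), len(strains)
    bias = rng.normal(0.0, config.reference_bias_sd, size=G)
    noise = rng.normal(0.0, config.noise_sd, size=(G, S))
    group_of = np.array([partition[s] for s in strains])
    values = bias[:, None] + deltas[:, group_of] + noise
    matrix = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                          columns=strains)

    terms = _simulate_terms(config, gene_ids, truth)
    bands = simulate_bands(config)
    return SyntheticCohort(
        annotation=annotation,
        matrix=matrix,
        truth_divergent_genes=truth,
        truth_partition=partition,
        terms=terms,
        bands=bands,
    )


def _band_sizes_kb(config: SimulationConfig) -> np.ndarray:
    if config.n_chromosomes == 16:
        return np.array(CHROMOSOME_SIZES_KB)
    return np.linspace(200.0, 2200.0, config.n_chromosomes)


def simulate_bands(config: SimulationConfig) -> tuple[BandPattern, ...]:
    """Per-strain electrophoretic band lists: the chromosome sizes (kb) under
    small multiplicative jitter, plus the strain's group marker bands.
    Co-migration of similar sizes is handled downstream by band binning."""
    config.validate()
    strains = _strain_ids(config)
    partition = _partition(config)
    markers = config.resolved_markers()
    base = _band_sizes_kb(config)
    rng = np.random.default_rng([config.seed, 2])
    patterns = []
    for strain in strains:
        jitter = rng.normal(1.0, config.band_jitter, size=base.size)
        sizes = list(base * jitter) + list(markers.get(partition[strain], ()))
        patterns.append(
            BandPattern(strain_id=strain, band_sizes_kb=tuple(sorted(sizes)))
        )
    return tuple(patterns)


def null_config(seed: int, **overrides) -> SimulationConfig:
    """A cohort with no planted CNVs, no planted term and no marker bands —
    the null for calibration tests."""
    base = SimulationConfig(seed=seed, cnv_events=(), marker_bands={})
    return replace(base, **overrides) if overrides else base
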