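"""Synthetic genomes and transposon libraries with known ground truth.

The generator emulates the study conditions of an in-planta TnSeq screen on
a multi-replicon rhizobial genome: a hyper-saturated input library (uniform
insertion sites at ~0.11 sites/bp over a tripartite ~6.7 Mb genome) passed
through a plant-nodule bottleneck that retains each neutral insertion with
probability ``1/l`` (neutral loss rate ``l ~ 6.84``) while insertions in
designated symbiosis genes are retained ``depletion_factor``-fold less
often, with losses biased toward contiguous runs.

Everything is driven by a single integer seed through one
``numpy.random.Generator``; identical config + seed gives byte-identical
output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from catchn.io import (
    INTERGENIC,
    CdsFeature,
    GenomeAnnotation,
    InsertionLibrary,
    assign_insertions,
)

__all__ = [
    "RepliconSpec",
    "SimulationConfig",
    "GroundTruth",
    "generate_genome",
    "generate_input_library",
    "simulate_nodule_selection",
]

_MIN_CDS_LEN = 60  # smallest CDS the generator will place


@dataclass(frozen=True)
class RepliconSpec:
    name: str
    length: int
    cds_count: int


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic screen.

    Defaults mirror the screen scale the statistics were designed for, with
    the genome shrunk to desk size: insertion density 0.11 sites/bp (the
    saturated-library regime), neutral loss rate ``l = 6.84``, and a 10%
    minority of symbiosis genes depleted 20-fold with fully contiguous loss
    runs.
    """

    replicon_specs: list[RepliconSpec] = field(
        default_factory=lambda: [
            RepliconSpec("chromosome", 400_000, 360),
            RepliconSpec("pSymA", 150_000, 140),
            RepliconSpec("pSymB", 180_000, 160),
        ]
    )
    insertion_density: float = 0.11
    neutral_loss_rate: float = 6.84
    depleted_gene_fraction: float = 0.10
    depletion_factor: float = 20.0
    contiguity_weight: float = 1.0
    mean_reads: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.replicon_specs:
            raise ValueError("replicon_specs must be nonempty")
        for spec in self.replicon_specs:
            if spec.length <= 0:
                raise ValueError(f"replicon {spec.name}: length must be > 0")
        if not (0 <= self.insertion_density < 1):
            raise ValueError("insertion_density must be in [0, 1)")
        if self.neutral_loss_rate < 1:
            raise ValueError("neutral_loss_rate must be >= 1")
        if self.depletion_factor < 1:
            raise ValueError("depletion_factor must be >= 1")
        if not (0 <= self.contiguity_weight <= 1):
            raise ValueError("contiguity_weight must be in [0, 1]")
        if not (0 <= self.depleted_gene_fraction <= 1):
            raise ValueError("depleted_gene_fraction must be in [0, 1]")


@dataclass
class GeneTruth:
    is_depleted: bool
    true_depletion_factor: float
    n_input: int
    i_recovered: int


@dataclass
class GroundTruth:
    """Per-gene truth for scoring benchmarks; every CDS appears once."""

    genes: dict[str, GeneTruth]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({g: asdict(t) for g, t in self.genes.items()}, fh, indent=1,
                      sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(genes={g: GeneTruth(**t) for g, t in raw.items()})

    @property
    def depleted_genes(self) -> set[str]:
        return {g for g, t in self.genes.items() if t.is_depleted}


def generate_genome(config: SimulationConfig) -> GenomeAnnotation:
    """Place non-overlapping CDS of realistic bacterial size on each replicon.

    Each replicon is split into ``cds_count`` equal blocks and one CDS of
    300-1500 bp (clipped to fit) is placed at a random offset inside each
    block, so intervals never overlap by construction.
    """
    rng = np.random.default_rng(config.seed)
    features: list[CdsFeature] = []
    replicons: dict[str, int] = {}
    for spec in config.replicon_specs:
        replicons[spec.name] = spec.length
        if spec.cds_count == 0:
            continue
        block = spec.length // spec.cds_count
        if block < _MIN_CDS_LEN + 2:
            raise ValueError(
                f"replicon {spec.name}: cannot place {spec.cds_count} CDS of >= "
                f"{_MIN_CDS_LEN} bp in {spec.length} bp"
            )
        for j in range(spec.cds_count):
            lo = j * block + 1  # 1-based block start
            max_len = min(1500, block - 2)
            min_len = min(300, max_len)
            length = int(rng.integers(min_len, max_len + 1))
            start = lo + int(rng.integers(0, block - length + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            features.append(
                CdsFeature(
                    id=f"{spec.name}_g{j + 1:05d}",
                    replicon=spec.name,
                    start=start,
                    end=start + length - 1,
                    strand=strand,
                )
            )
    return GenomeAnnotation(replicons=replicons, features=features)


def generate_input_library(
    annotation: GenomeAnnotation, config: SimulationConfig
) -> InsertionLibrary:
    """Draw unique insertion sites uniformly: each bp carries a site with
    probability ``insertion_density`` (independent Bernoulli, no strand
    bias), read counts geometric with the configured mean."""
    rng = np.random.default_rng(_derive_seed(config.seed, 1))
    frames = []
    for name, length in annotation.replicons.items():
        hit = rng.random(length) < config.insertion_density
        pos = np.flatnonzero(hit) + 1  # 1-based
        if len(pos) == 0:
            continue
        strand = np.where(rng.random(len(pos)) < 0.5, "+", "-")
        reads = rng.geometric(min(1.0, 1.0 / config.mean_reads), size=len(pos))
        frames.append(
            pd.DataFrame(
                {
                    "replicon": name,
                    "position": pos,
                    "strand": strand,
                    "library": "input",
                    "reads": reads,
                }
            )
        )
    if frames:
        sites = pd.concat(frames, ignore_index=True)
    else:
        sites = pd.DataFrame(
            {c: pd.Series(dtype=t) for c, t in
             zip(["replicon", "position", "strand", "library", "reads"],
                 [str, np.int64, str, str, np.int64])}
        )
    return InsertionLibrary(sites=sites, stage="input")


def _derive_seed(seed: int, stream: int) -> int:
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0] % (2**31))


def simulate_nodule_selection(
    annotation: GenomeAnnotation,
    input_library: InsertionLibrary,
    config: SimulationConfig,
) -> tuple[InsertionLibrary, GroundTruth]:
    """Pass the input library through the plant-nodule bottleneck.

    Neutral sites (including intergenic) survive independently with
    probability ``1/l``.  A random ``depleted_gene_fraction`` of genes is
    depleted: their sites survive with probability ``1/(l *
    depletion_factor)``, and with probability ``contiguity_weight`` the
    losses are taken as one contiguous run (length binomially matched to
    the marginal loss probability, start uniform within the gene) rather
    than independently.
    """
    if len(input_library) == 0:
        raise ValueError("input library is empty")
    rng = np.random.default_rng(_derive_seed(config.seed, 2))
    p_neutral = 1.0 / config.neutral_loss_rate
    p_depleted = p_neutral / config.depletion_factor

    assignment = assign_insertions(annotation, input_library)
    gene_ids = [f.id for f in annotation.features]
    n_depleted = int(round(config.depleted_gene_fraction * len(gene_ids)))
    depleted = set(
        rng.choice(gene_ids, size=n_depleted, replace=False)
    ) if n_depleted else set()

    # decide retention per site row; map (replicon, position) -> row index once
    sites = input_library.sites
    row_of = {
        (rep, int(posn)): idx
        for idx, (rep, posn) in enumerate(
            zip(sites["replicon"].to_numpy(), sites["position"].to_numpy())
        )
    }
    retained = np.zeros(len(sites), dtype=bool)
    decided = np.zeros(len(sites), dtype=bool)

    rep_of_gene = {f.id: f.replicon for f in annotation.features}
    truth: dict[str, GeneTruth] = {}
    for gene in gene_ids:
        pos = assignment.get(gene, np.array([], int))
        rep = rep_of_gene[gene]
        m = len(pos)
        is_dep = gene in depleted
        p = p_depleted if is_dep else p_neutral
        if m == 0:
            keep = np.array([], bool)
        elif is_dep and rng.random() < config.contiguity_weight:
            n_drop = int(rng.binomial(m, 1.0 - p))
            start = int(rng.integers(0, m - n_drop + 1))
            keep = np.ones(m, bool)
            keep[start:start + n_drop] = False
        else:
            keep = rng.random(m) < p
        for q, kp in zip(pos, keep):
            idx = row_of[(rep, int(q))]
            if decided[idx]:  # overlap double-assignment: first decision wins
                continue
            decided[idx] = True
            retained[idx] = bool(kp)
        truth[gene] = GeneTruth(
            is_depleted=is_dep,
            true_depletion_factor=config.depletion_factor if is_dep else 1.0,
            n_input=m,
            i_recovered=int(keep.sum()),
        )

    # intergenic sites are neutral
    undecided = ~decided
    retained[undecided] = rng.random(int(undecided.sum())) < p_neutral

    out = sites.loc[retained].copy()
    out["library"] = "output"
    out["reads"] = rng.geometric(min(1.0, 1.0 / config.mean_reads), size=len(out))
    out_lib = InsertionLibrary(sites=out.reset_index(drop=True), stage="output")
    return out_lib, GroundTruth(genes=truth)
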