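"""Per-CDS insertion statistics and essential/fitness classification.

A CDS is called *essential* when its insertion density falls below
``avg_density * essential_density_factor`` (default 1/6 of the genome-wide
average) **and** its insertion-free structure shows either a single gap
covering more than 60% of the CDS or two internal gaps jointly covering more
than 80%.  A CDS below ``avg_density * fitness_density_factor`` (default
1/4) that misses the gap criteria is a *fitness* gene; everything else is
*non-essential*.  The density factors are configurable, so the alternative
literal reading of the thresholds (factors of 6 and 4) remains selectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from catchn.io import CdsFeature, GenomeAnnotation, InsertionLibrary

__all__ = [
    "GapInterval",
    "GeneInsertionProfile",
    "EssentialityCall",
    "Thresholds",
    "gene_stats",
    "genome_average_density",
    "classify",
    "classify_genome",
]

CATEGORIES = ("essential", "fitness", "non_essential")


@dataclass(frozen=True)
class GapInterval:
    """A maximal insertion-free interval within a CDS (lengths in bp)."""

    length: int
    boundary: bool  # touches a CDS end (not flanked by two sites)


@dataclass
class GeneInsertionProfile:
    gene_id: str
    length: int
    n_sites: int
    density: float
    gaps: list[GapInterval] = field(default_factory=list)
    largest_gap_fraction: float = 0.0
    top2_internal_gap_fraction: float = 0.0
    low_confidence: bool = False


@dataclass(frozen=True)
class Thresholds:
    essential_density_factor: float = 1 / 6
    fitness_density_factor: float = 1 / 4
    single_gap_fraction: float = 0.60
    two_gap_fraction: float = 0.80
    min_length: int = 100

    def __post_init__(self) -> None:
        if min(
            self.essential_density_factor,
            self.fitness_density_factor,
            self.single_gap_fraction,
            self.two_gap_fraction,
        ) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class EssentialityCall:
    category: str
    density_below_essential: bool
    density_below_fitness: bool
    single_gap_hit: bool
    two_gap_hit: bool
    thresholds: Thresholds

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def gene_stats(
    gene: CdsFeature,
    sites: Sequence[int] | np.ndarray,
    min_length: int = 100,
) -> GeneInsertionProfile:
    """Insertion density and gap structure for one CDS.

    Gaps are maximal insertion-free intervals; a site occupies one base, so
    the gap between consecutive sites at p and q is ``q - p - 1`` bp.  Gaps
    touching either CDS end are *boundary* gaps; internal gaps are flanked
    by two sites.  With zero sites the whole CDS is one boundary gap.
    """
    pos = np.sort(np.asarray(list(sites), dtype=np.int64))
    if len(pos) and (pos[0] < gene.start or pos[-1] > gene.end):
        raise ValueError(f"sites outside CDS {gene.id} bounds")
    length = gene.length
    gaps: list[GapInterval] = []
    if len(pos) == 0:
        gaps.append(GapInterval(length=length, boundary=True))
    else:
        left = int(pos[0] - gene.start)
        if left > 0:
            gaps.append(GapInterval(length=left, boundary=True))
        for a, b in zip(pos[:-1], pos[1:]):
            g = int(b - a - 1)
            if g > 0:
                gaps.append(GapInterval(length=g, boundary=False))
        right = int(gene.end - pos[-1])
        if right > 0:
            gaps.append(GapInterval(length=right, boundary=True))
    largest = max((g.length for g in gaps), default=0) / length
    internal = sorted(
        (g.length for g in gaps if not g.boundary), reverse=True
    )
    top2 = sum(internal[:2]) / length
    return GeneInsertionProfile(
        gene_id=gene.id,
        length=length,
        n_sites=len(pos),
        density=len(pos) / length,
        gaps=gaps,
        largest_gap_fraction=largest,
        top2_internal_gap_fraction=top2,
        low_confidence=length < min_length,
    )


def genome_average_density(
    annotation: GenomeAnnotation, library: InsertionLibrary
) -> float:
    """Unique insertion sites per bp, pooled over all replicons."""
    total = annotation.total_length
    if total <= 0:
        raise ValueError("zero-length genome")
    return len(library) / total


def classify(
    profile: GeneInsertionProfile,
    avg_density: float,
    thresholds: Thresholds | None = None,
) -> EssentialityCall:
    """Apply the essential/fitness rules to one gene profile."""
    th = thresholds or Thresholds()
    below_ess = profile.density < avg_density * th.essential_density_factor
    below_fit = profile.density < avg_density * th.fitness_density_factor
    single = profile.largest_gap_fraction > th.single_gap_fraction
    two = profile.top2_internal_gap_fraction > th.two_gap_fraction
    if below_ess and (single or two):
        category = "essential"
    elif below_fit:
        category = "fitness"
    else:
        category = "non_essential"
    return EssentialityCall(
        category=category,
        density_below_essential=below_ess,
        density_below_fitness=below_fit,
        single_gap_hit=single,
        two_gap_hit=two,
        thresholds=th,
    )


def classify_genome(
    annotation: GenomeAnnotation,
    library: InsertionLibrary,
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Profile and classify every CDS; returns the standard report table."""
    from catchn.io import assign_insertions

    th = thresholds or Thresholds()
    avg = genome_average_density(annotation, library)
    assignment = assign_insertions(annotation, library)
    rows = []
    for feat in annotation.features:
        sites = assignment.get(feat.id, np.array([], int))
        prof = gene_stats(feat, sites, min_length=th.min_length)
        call = classify(prof, avg, th)
        rows.append(
            {
                "gene": feat.id,
                "replicon": feat.replicon,
                "length": prof.length,
                "n_sites": prof.n_sites,
                "density": prof.density,
                "largest_gap_frac": prof.largest_gap_fraction,
                "top2_internal_gap_frac": prof.top2_internal_gap_fraction,
                "category": call.category,
                "low_confidence": prof.low_confidence,
            }
        )
    return pd.DataFrame.from_records(rows).set_index("gene")
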