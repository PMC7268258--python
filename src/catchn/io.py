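"""Annotations, insertion-site tables, and site-to-gene assignment.

Genome annotations travel as GFF3 (replicon lengths in ``##sequence-region``
directives); insertion libraries as tab-separated text with one site per row:

    replicon  position  strand  library  reads

Positions are 1-based and refer to the first base of the duplicated target
site. Site/feature membership is 1-based inclusive and strand-insensitive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: reserved assignment key for sites falling outside every CDS
INTERGENIC = "__intergenic__"

INSERTION_COLUMNS = ["replicon", "position", "strand", "library", "reads"]


@dataclass(frozen=True)
class CdsFeature:
    """A protein-coding feature on one replicon (1-based inclusive coords)."""

    id: str
    replicon: str
    start: int
    end: int
    strand: str = "+"
    product: str = ""
    functional_category: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"feature {self.id}: invalid interval [{self.start}, {self.end}]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeAnnotation:
    """Replicon sizes plus the CDS features they carry."""

    replicons: dict[str, int]
    features: list[CdsFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, length in self.replicons.items():
            if length <= 0:
                raise ValueError(f"replicon {name}: non-positive length {length}")
        seen: set[str] = set()
        for f in self.features:
            if f.id in seen:
                raise ValueError(f"duplicate feature id {f.id}")
            seen.add(f.id)
            if f.replicon not in self.replicons:
                raise ValueError(f"feature {f.id}: unknown replicon {f.replicon}")
            if f.end > self.replicons[f.replicon]:
                raise ValueError(
                    f"feature {f.id}: end {f.end} exceeds replicon "
                    f"{f.replicon} length {self.replicons[f.replicon]}"
                )

    @property
    def total_length(self) -> int:
        return sum(self.replicons.values())

    def features_by_replicon(self) -> dict[str, list[CdsFeature]]:
        out: dict[str, list[CdsFeature]] = {name: [] for name in self.replicons}
        for f in self.features:
            out[f.replicon].append(f)
        for lst in out.values():
            lst.sort(key=lambda f: (f.start, f.end))
        return out


@dataclass
class InsertionLibrary:
    """A set of unique transposon insertion sites with read counts.

    ``sites`` is a DataFrame with columns ``replicon, position, strand,
    library, reads``; (replicon, position) pairs are unique within one
    library. ``stage`` labels the selection stage (``input`` or ``output``).
    """

    sites: pd.DataFrame
    stage: str = "input"

    def __post_init__(self) -> None:
        missing = [c for c in INSERTION_COLUMNS if c not in self.sites.columns]
        if missing:
            raise ValueError(f"insertion table missing columns: {missing}")
        self.sites = self.sites[INSERTION_COLUMNS].reset_index(drop=True)
        if (self.sites["position"] <= 0).any():
            bad = self.sites.loc[self.sites["position"] <= 0].index[0]
            raise ValueError(f"non-positive insertion position at row {bad}")
        if self.sites.duplicated(["replicon", "position"]).any():
            raise ValueError("duplicate (replicon, position) pairs in library")

    def __len__(self) -> int:
        return len(self.sites)

    def positions(self, replicon: str) -> np.ndarray:
        sel = self.sites.loc[self.sites["replicon"] == replicon, "position"]
        return np.sort(sel.to_numpy(dtype=np.int64))


def read_annotation(path) -> GenomeAnnotation:
    """Read a GFF3 annotation (CDS features only)."""
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="error", keep_order=True
    )
    replicons: dict[str, int] = {}
    for directive in db.directives:
        if directive.startswith("sequence-region"):
            parts = directive.split()
            if len(parts) != 4:
                raise ValueError(f"malformed directive: ##{directive}")
            replicons[parts[1]] = int(parts[3])
    features = []
    for f in db.features_of_type("CDS"):
        if f.seqid not in replicons:
            raise ValueError(
                f"feature {f.id} on line for replicon {f.seqid!r} lacks a "
                "##sequence-region directive"
            )
        features.append(
            CdsFeature(
                id=f.id,
                replicon=f.seqid,
                start=f.start,
                end=f.end,
                strand=f.strand if f.strand in "+-" else "+",
                product=f.attributes.get("product", [""])[0],
                functional_category=f.attributes.get("functional_category", [""])[0],
            )
        )
    return GenomeAnnotation(replicons=replicons, features=features)


def write_annotation(annotation: GenomeAnnotation, path) -> None:
    """Write an annotation as GFF3; round-trips through :func:`read_annotation`."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, length in annotation.replicons.items():
            fh.write(f"##sequence-region {name} 1 {length}\n")
        for f in annotation.features:
            attrs = [f"ID={f.id}"]
            if f.product:
                attrs.append(f"product={f.product}")
            if f.functional_category:
                attrs.append(f"functional_category={f.functional_category}")
            fh.write(
                "\t".join(
                    [
                        f.replicon,
                        "catchn",
                        "CDS",
                        str(f.start),
                        str(f.end),
                        ".",
                        f.strand,
                        "0",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_insertions(path, stage: str = "input",
                    annotation: GenomeAnnotation | None = None) -> InsertionLibrary:
    """Read an insertion table.

    Duplicate (replicon, position) rows are collapsed with summed read counts
    (a warning is logged). If ``annotation`` is given, replicon names and
    position bounds are validated against it.
    """
    df = pd.read_csv(path, sep="\t", dtype={"replicon": str})
    missing = [c for c in INSERTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if (df["position"] <= 0).any():
        raise ValueError(f"{path}: positions must be >= 1")
    dups = df.duplicated(["replicon", "position"], keep=False)
    if dups.any():
        logger.warning(
            "%s: %d duplicated site rows collapsed (reads summed)",
            path, int(dups.sum()),
        )
        df = (
            df.groupby(["replicon", "position"], as_index=False)
            .agg({"strand": "first", "library": "first", "reads": "sum"})
        )
    if annotation is not None:
        unknown = set(df["replicon"]) - set(annotation.replicons)
        if unknown:
            raise ValueError(f"{path}: unknown replicons {sorted(unknown)}")
        for name, length in annotation.replicons.items():
            sel = df.loc[df["replicon"] == name, "position"]
            if (sel > length).any():
                raise ValueError(f"{path}: position beyond {name} length {length}")
    return InsertionLibrary(sites=df, stage=stage)


def write_insertions(library: InsertionLibrary, path) -> None:
    library.sites.to_csv(path, sep="\t", index=False)


def assign_insertions(
    annotation: GenomeAnnotation, library: InsertionLibrary
) -> dict[str, np.ndarray]:
    """Map each insertion site to the CDS features containing it.

    Returns ``{feature id: sorted positions}`` plus the reserved key
    ``INTERGENIC`` holding sites outside every CDS. A site on an overlap of
    two CDS is assigned to both (double counting is deliberate and
    documented); otherwise every site appears exactly once.
    """
    unknown = set(library.sites["replicon"]) - set(annotation.replicons)
    if unknown:
        raise ValueError(f"library contains unknown replicons {sorted(unknown)}")
    assignment: dict[str, np.ndarray] = {}
    intergenic_parts: list[np.ndarray] = []
    by_rep = annotation.features_by_replicon()
    for rep, feats in by_rep.items():
        pos = library.positions(rep)
        covered = np.zeros(len(pos), dtype=bool)
        for f in feats:
            lo = np.searchsorted(pos, f.start, side="left")
            hi = np.searchsorted(pos, f.end, side="right")
            assignment[f.id] = pos[lo:hi]
            covered[lo:hi] = True
        intergenic_parts.append(pos[~covered])
    assignment[INTERGENIC] = (
        np.concatenate(intergenic_parts) if intergenic_parts else np.array([], int)
    )
    return assignment
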