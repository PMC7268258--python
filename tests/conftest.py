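import numpy as np
import pandas as pd
import pytest

from catchn.io import CdsFeature, GenomeAnnotation, InsertionLibrary
from catchn.synthetic import (
    RepliconSpec,
    SimulationConfig,
    generate_genome,
    generate_input_library,
    simulate_nodule_selection,
)


def make_library(rows, stage="input"):
    """Build an InsertionLibrary from (replicon, position[, strand, lib, reads])."""
    records = []
    for r in rows:
        rec = {"replicon": r[0], "position": r[1], "strand": "+",
               "library": stage, "reads": 1}
        if len(r) > 2:
            rec["strand"] = r[2]
        if len(r) > 3:
            rec["library"] = r[3]
        if len(r) > 4:
            rec["reads"] = r[4]
        records.append(rec)
    df = pd.DataFrame.from_records(
        records, columns=["replicon", "position", "strand", "library", "reads"]
    )
    if not records:
        df = df.astype({"position": np.int64, "reads": np.int64})
    return InsertionLibrary(sites=df, stage=stage)


@pytest.fixture
def toy_annotation():
    """Two replicons, three genes, including an overlapping pair."""
    return GenomeAnnotation(
        replicons={"chr": 10_000, "pA": 5_000},
        features=[
            CdsFeature("geneA", "chr", 100, 200, "+"),
            CdsFeature("geneB", "chr", 150, 400, "-"),  # overlaps geneA
            CdsFeature("geneC", "pA", 1000, 2000, "+"),
        ],
    )


@pytest.fixture(scope="session")
def screen_config():
    """Desk-scale replica of the study screen: 500 genes on three replicons,
    saturated input library, 10% of genes depleted 20-fold, l = 6.84."""
    return SimulationConfig(
        replicon_specs=[
            RepliconSpec("chromosome", 300_000, 300),
            RepliconSpec("pSymA", 120_000, 100),
            RepliconSpec("pSymB", 110_000, 100),
        ],
        seed=7,
    )


@pytest.fixture(scope="session")
def screen(screen_config):
    """(annotation, input library, output library, ground truth) for one run."""
    annotation = generate_genome(screen_config)
    input_lib = generate_input_library(annotation, screen_config)
    output_lib, truth = simulate_nodule_selection(
        annotation, input_lib, screen_config
    )
    return annotation, input_lib, output_lib, truth
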