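"""End-to-end orchestration: simulate -> classify -> score -> report.

Every run writes its resolved configuration next to its outputs; reruns
with the same configuration and seed are bit-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from catchn.depletion import DepletionModel
from catchn.essentiality import Thresholds, classify_genome
from catchn.io import write_annotation, write_insertions
from catchn.synthetic import (
    SimulationConfig,
    generate_genome,
    generate_input_library,
    simulate_nodule_selection,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "functional_rollup"]


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    alpha: float = 0.05
    correction: str = "none"
    loss_rate: float | None = None  # None: estimate from the data

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "simulation": asdict(self.simulation),
                    "thresholds": asdict(self.thresholds),
                    "alpha": self.alpha,
                    "correction": self.correction,
                    "loss_rate": self.loss_rate,
                },
                fh, sort_keys=True,
            )


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run the full synthetic screen and write all stage outputs.

    Produces ``annotation.gff3``, ``input.tsv``, ``output.tsv``,
    ``ground_truth.json``, ``essentiality.tsv``, ``scores.tsv``, the
    resolved ``config.yaml``, and ``summary.json`` with per-category and
    per-replicon roll-ups.  Returns the summary dict.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    summary: dict = {}

    def stage(name):
        logger.info("stage %s", name)
        return time.perf_counter()

    try:
        t0 = stage("simulate")
        annotation = generate_genome(config.simulation)
        input_lib = generate_input_library(annotation, config.simulation)
        output_lib, truth = simulate_nodule_selection(
            annotation, input_lib, config.simulation
        )
        write_annotation(annotation, out / "annotation.gff3")
        write_insertions(input_lib, out / "input.tsv")
        write_insertions(output_lib, out / "output.tsv")
        truth.to_json(out / "ground_truth.json")
        logger.info("simulate done in %.1fs", time.perf_counter() - t0)
    except Exception as err:
        raise RuntimeError(f"pipeline stage 'simulate' failed: {err}") from err

    try:
        t0 = stage("classify")
        ess = classify_genome(annotation, input_lib, config.thresholds)
        ess.to_csv(out / "essentiality.tsv", sep="\t")
        logger.info("classify done in %.1fs", time.perf_counter() - t0)
    except Exception as err:
        raise RuntimeError(f"pipeline stage 'classify' failed: {err}") from err

    try:
        t0 = stage("score")
        model = DepletionModel.from_libraries(annotation, input_lib, output_lib)
        results = model.fit(
            loss_rate=config.loss_rate,
            alpha=config.alpha,
            correction=config.correction,
        )
        results.calls.to_csv(out / "scores.tsv", sep="\t")
        logger.info("score done in %.1fs", time.perf_counter() - t0)
    except Exception as err:
        raise RuntimeError(f"pipeline stage 'score' failed: {err}") from err

    rep_of = {f.id: f.replicon for f in annotation.features}
    flagged = results.symbiosis_genes
    per_replicon: dict[str, int] = {}
    for g in flagged:
        per_replicon[rep_of[g]] = per_replicon.get(rep_of[g], 0) + 1
    summary = {
        "n_genes": len(annotation.features),
        "n_input_sites": len(input_lib),
        "n_output_sites": len(output_lib),
        "loss_rate": results.loss_rate,
        "essentiality_counts": ess["category"].value_counts().to_dict(),
        "n_symbiosis_genes": len(flagged),
        "symbiosis_genes_per_replicon": per_replicon,
        "n_true_depleted": len(truth.depleted_genes),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


def functional_rollup(
    calls: pd.DataFrame, category_column: str = "functional_category"
) -> pd.DataFrame:
    """Counts and percentages of flagged genes per functional category.

    ``calls`` holds one row per flagged gene with a category label (and
    optionally a ``replicon`` column for a per-replicon breakdown).
    Percentages are computed against the flagged-gene total and rounded to
    2 decimals.
    """
    if len(calls) == 0:
        return pd.DataFrame(columns=["category", "count", "percent"])
    total = len(calls)
    counts = calls[category_column].value_counts()
    rows = [
        {
            "category": cat,
            "count": int(cnt),
            "percent": round(cnt / total * 100, 2),
        }
        for cat, cnt in counts.items()
    ]
    return pd.DataFrame(rows, columns=["category", "count", "percent"])
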