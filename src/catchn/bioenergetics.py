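"""Bioenergetic accounting of candidate symbiotic nitrogen-fixation cycles.

The model: nitrogenase reduces one N2 at the cost of 16 ATP and 8
low-potential electrons.  Each catabolic NADH is split by the electron
bifurcation complex into one low-potential electron (to flavodoxin, then
nitrogenase) and one electron entering the quinone pool; each electron
passing from quinol to oxygen translocates 3 protons, i.e. just under one
ATP at the assumed H+/ATP stoichiometry of 10/3.  Quinol produced directly
by succinate dehydrogenase delivers both electrons to oxygen.  Cytosolic
enzymatic reactions (ammonia release, decarboxylations) consume further
protons, adding to the proton-motive influx.  The net ATP per N2 is then

    atp_net = (3 * e_oxidase + h_enzymatic) / (10/3)
              + substrate_level_atp - 16

with ``e_oxidase = nadh_bifurcated + 2 * qh2_catabolic + extra``.

All arithmetic is exact rational; rounding (2 decimals, half-up) happens
only in reports.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction
from numbers import Rational
from typing import Iterable, Mapping

import pandas as pd
import yaml

__all__ = [
    "EnergyConstants",
    "PathwayDefinition",
    "EnergyBudget",
    "NitrogenBudget",
    "builtin_pathways",
    "load_pathways",
    "energy_budget",
    "nadh_qh2_ratio",
    "nitrogen_yield",
    "table2_report",
]


def _frac(x) -> Fraction:
    """Parse YAML scalars to exact rationals ('1.6' -> 8/5, '2/15' -> 2/15)."""
    if isinstance(x, Rational):
        return Fraction(x)
    return Fraction(str(x))


@dataclass(frozen=True)
class EnergyConstants:
    """Fixed stoichiometry of nitrogenase and the bifurcated chain."""

    electrons_per_n2: int = 8
    atp_per_n2_nitrogenase: int = 16
    atp_per_fldhq: int = 2
    h_translocated_per_electron: int = 3
    electrons_per_o2: int = 4
    h_per_atp: Fraction = Fraction(10, 3)

    def __post_init__(self) -> None:
        vals = (
            self.electrons_per_n2,
            self.atp_per_n2_nitrogenase,
            self.atp_per_fldhq,
            self.h_translocated_per_electron,
            self.electrons_per_o2,
            self.h_per_atp,
        )
        if any(v <= 0 for v in vals):
            raise ValueError("all energy constants must be positive")
        if self.atp_per_n2_nitrogenase != self.electrons_per_n2 * self.atp_per_fldhq:
            raise ValueError(
                "nitrogenase ATP cost must equal electrons_per_n2 * atp_per_fldhq"
            )


@dataclass(frozen=True)
class PathwayDefinition:
    """Per-N2 stoichiometry of one candidate nitrogen-fixation cycle."""

    name: str
    substrates: Mapping[str, Fraction]
    products: Mapping[str, Fraction]
    reaction_steps: int
    nadh_total: Fraction
    nadh_bifurcated: Fraction
    qh2_catabolic: Fraction
    extra_electrons_to_oxidase: Fraction = Fraction(0)
    h_enzymatic: Fraction = Fraction(0)
    substrate_level_atp: Fraction = Fraction(0)
    amino_product: str | None = None
    transaminations_per_arginine: int = 2
    non_reconciled: bool = False

    def __post_init__(self) -> None:
        if self.nadh_bifurcated > self.nadh_total:
            raise ValueError(f"{self.name}: bifurcated NADH exceeds total NADH")
        for label, v in [
            ("nadh_total", self.nadh_total),
            ("qh2_catabolic", self.qh2_catabolic),
            ("h_enzymatic", self.h_enzymatic),
        ]:
            if v < 0:
                raise ValueError(f"{self.name}: {label} must be >= 0")
        for name, v in {**self.substrates, **self.products}.items():
            if v < 0:
                raise ValueError(f"{self.name}: negative stoichiometry for {name}")

    @property
    def electrons_to_nitrogenase(self) -> Fraction:
        return Fraction(self.nadh_bifurcated)


@dataclass(frozen=True)
class EnergyBudget:
    """Electron/oxygen/proton/ATP balance of one pathway per N2."""

    pathway: str
    electrons_to_nitrogenase: Fraction
    electrons_to_oxidase: Fraction
    o2_consumed: Fraction  # negative: Table-style consumption convention
    h_translocated: Fraction
    h_enzymatic: Fraction
    h_influx_total: Fraction
    atp_from_protons: Fraction
    substrate_level_atp: Fraction
    atp_net: Fraction
    self_sufficient: bool


@dataclass(frozen=True)
class NitrogenBudget:
    """Nitrogen bookkeeping per arginine consumed."""

    pathway: str
    n_in_organic: Fraction
    n_fixed: Fraction
    n_out_alanine: Fraction
    n_out_ammonium: Fraction
    n_yield_per_arginine: Fraction
    pct_vs_classical: Fraction


def load_pathways(path) -> list[PathwayDefinition]:
    """Load pathway definitions from a YAML file (documented schema in the
    shipped ``data/pathways.yaml``)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = []
    for entry in raw:
        out.append(
            PathwayDefinition(
                name=entry["name"],
                substrates={k: _frac(v) for k, v in entry["substrates"].items()},
                products={k: _frac(v) for k, v in entry["products"].items()},
                reaction_steps=int(entry["reaction_steps"]),
                nadh_total=_frac(entry["nadh_total"]),
                nadh_bifurcated=_frac(entry["nadh_bifurcated"]),
                qh2_catabolic=_frac(entry["qh2_catabolic"]),
                extra_electrons_to_oxidase=_frac(
                    entry.get("extra_electrons_to_oxidase", 0)
                ),
                h_enzymatic=_frac(entry.get("h_enzymatic", 0)),
                substrate_level_atp=_frac(entry.get("substrate_level_atp", 0)),
                amino_product=entry.get("amino_product"),
                transaminations_per_arginine=int(
                    entry.get("transaminations_per_arginine", 2)
                ),
                non_reconciled=bool(entry.get("non_reconciled", False)),
            )
        )
    return out


def builtin_pathways() -> list[PathwayDefinition]:
    """The six shipped cycle fixtures: CATCH-N1..4 plus the complete TCA
    cycle on malate and on succinate."""
    ref = importlib.resources.files("catchn.data") / "pathways.yaml"
    with importlib.resources.as_file(ref) as path:
        return load_pathways(path)


def energy_budget(
    pathway: PathwayDefinition, constants: EnergyConstants | None = None
) -> EnergyBudget:
    """Exact-rational electron, oxygen, proton and ATP balance per N2."""
    c = constants or EnergyConstants()
    e_nitrogenase = pathway.electrons_to_nitrogenase
    e_oxidase = (
        pathway.nadh_bifurcated
        + 2 * pathway.qh2_catabolic
        + pathway.extra_electrons_to_oxidase
    )
    o2 = -e_oxidase / c.electrons_per_o2
    h_trans = c.h_translocated_per_electron * e_oxidase
    h_influx = h_trans + pathway.h_enzymatic
    atp_protons = h_influx / c.h_per_atp
    atp_net = atp_protons + pathway.substrate_level_atp - c.atp_per_n2_nitrogenase
    return EnergyBudget(
        pathway=pathway.name,
        electrons_to_nitrogenase=e_nitrogenase,
        electrons_to_oxidase=e_oxidase,
        o2_consumed=o2,
        h_translocated=h_trans,
        h_enzymatic=pathway.h_enzymatic,
        h_influx_total=h_influx,
        atp_from_protons=atp_protons,
        substrate_level_atp=pathway.substrate_level_atp,
        atp_net=atp_net,
        self_sufficient=(e_nitrogenase == c.electrons_per_n2),
    )


def nadh_qh2_ratio(pathway: PathwayDefinition) -> Fraction:
    """Exact NADH : catabolic-QH2 ratio; infinite (raises) when no quinol
    is produced directly."""
    if pathway.qh2_catabolic == 0:
        raise ZeroDivisionError(f"{pathway.name}: no catabolic QH2")
    return pathway.nadh_total / pathway.qh2_catabolic


def nitrogen_yield(
    pathway: PathwayDefinition,
    classical_reference: int = 4,
    constants: EnergyConstants | None = None,
) -> NitrogenBudget:
    """Secreted nitrogen per arginine versus classical arginine catabolism.

    Per arginine: 4 organic N enter; the cycle's fixation share adds
    ``(e_nitrogenase / 8) * 2`` N spread over the arginine stoichiometry;
    each transamination secretes one N as the amino-acid product and the
    conservation remainder leaves as ammonium.
    """
    c = constants or EnergyConstants()
    arg = pathway.substrates.get("arginine", Fraction(0))
    if arg == 0:
        raise ValueError(f"{pathway.name}: pathway does not consume arginine")
    n_in = Fraction(4)
    n_fixed = (pathway.electrons_to_nitrogenase / c.electrons_per_n2) * 2 / arg
    n_amino = Fraction(pathway.transaminations_per_arginine)
    n_ammonium = n_in + n_fixed - n_amino
    if n_ammonium < 0:
        raise ValueError(
            f"{pathway.name}: nitrogen conservation violated "
            f"(amino-acid N {n_amino} exceeds available {n_in + n_fixed})"
        )
    total = n_amino + n_ammonium
    pct = (total - classical_reference) / classical_reference * 100
    return NitrogenBudget(
        pathway=pathway.name,
        n_in_organic=n_in,
        n_fixed=n_fixed,
        n_out_alanine=n_amino,
        n_out_ammonium=n_ammonium,
        n_yield_per_arginine=total,
        pct_vs_classical=pct,
    )


def _round2(x: Fraction) -> Decimal:
    return (Decimal(x.numerator) / Decimal(x.denominator)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )


def _fmt(x: Fraction) -> str:
    """Round half-up to 2 decimals, trimming trailing zeros ('56', '38.8')."""
    d = _round2(x)
    s = f"{d.normalize():f}"
    return s if s != "-0" else "0"


def _fmt2(x: Fraction) -> str:
    """Round half-up, always two decimals ('2.80', '-0.80')."""
    return str(_round2(x))


def table2_report(pathways: Iterable[PathwayDefinition] | None = None) -> pd.DataFrame:
    """Summary table of all pathway budgets (consumption negative, proton
    influx printed as ``total (translocated + enzymatic)``, two decimals)."""
    if pathways is None:
        pathways = builtin_pathways()
    rows = []
    for p in pathways:
        b = energy_budget(p)
        subs = ", ".join(f"{_fmt(v)}{k.capitalize()[:3]}" for k, v in p.substrates.items())
        prods = ", ".join(f"{_fmt(v)}{k.capitalize()[:3]}" for k, v in p.products.items())
        rows.append(
            {
                "pathway": p.name,
                "substrates": subs,
                "products": prods,
                "reaction_steps": p.reaction_steps,
                "sum_nadh": _fmt(p.nadh_total),
                "sum_qh2": _fmt(p.qh2_catabolic),
                "o2_per_n2": _fmt(b.o2_consumed),
                "influx_h": f"{_fmt(b.h_influx_total)} "
                            f"({_fmt(b.h_translocated)} + {_fmt(b.h_enzymatic)})",
                "atp_net_gain": _fmt2(b.atp_net),
            }
        )
    columns = [
        "pathway", "substrates", "products", "reaction_steps", "sum_nadh",
        "sum_qh2", "o2_per_n2", "influx_h", "atp_net_gain",
    ]
    return pd.DataFrame(rows, columns=columns)
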