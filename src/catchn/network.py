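"""The arginine-transamination reaction network: structure, kinetics, labels.

The network converts arginine to succinate in six consecutive enzymatic
steps through a redundant grid of intermediates (ornithine, agmatine,
5-guanidino-2-oxopentanoate, putrescine, 5-amino-oxopentanoate, the
guanidino/amino butyraldehydes, 4-guanidinobutanoate, GABA, succinic
semialdehyde).  Reaction classes carry fixed co-species patterns:

* aminotransferase — amino group to pyruvate, yielding alanine;
* decarboxylase — releases CO2;
* ureohydrolase — hydrolyses a guanidino group, releasing urea;
* dehydrogenase — aldehyde to acid, NAD+ to NADH;
* deiminase — hydrolyses arginine's guanidino N, releasing ammonium;
* urease — urea to 2 ammonium + CO2.

Every edge is checked for carbon and nitrogen balance including
co-species.  Kinetics are mass-action (bimolecular with pyruvate for
aminotransferases) with configurable order-of-magnitude rate constants;
the shipped scenario reproduces the in vitro reconstitution (2 mM
arginine, 20 mM pyruvate, 14 purified enzymes).  Label propagation
duplicates each backbone pool into labeled/unlabeled species sharing rate
constants, with source pools clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "Metabolite",
    "ReactionEdge",
    "NetworkModel",
    "TimeCourse",
    "LabelState",
    "METABOLITES",
    "default_network",
    "validate",
    "pyruvate_balance",
    "simulate",
    "propagate_labels",
]

REACTION_CLASSES = (
    "aminotransferase",
    "decarboxylase",
    "ureohydrolase",
    "dehydrogenase",
    "deiminase",
    "urease",
)


@dataclass(frozen=True)
class Metabolite:
    id: str
    carbons: int
    nitrogens: int
    guanidino: bool = False

    def __post_init__(self) -> None:
        if self.carbons < 0 or self.nitrogens < 0:
            raise ValueError(f"{self.id}: negative atom count")


#: atom bookkeeping for every species the network can touch
METABOLITES: dict[str, Metabolite] = {
    m.id: m
    for m in [
        Metabolite("ARG", 6, 4, guanidino=True),
        Metabolite("ORN", 5, 2),
        Metabolite("GOP", 6, 3, guanidino=True),
        Metabolite("AGM", 5, 4, guanidino=True),
        Metabolite("AOP", 5, 1),
        Metabolite("PUT", 4, 2),
        Metabolite("GBL", 5, 3, guanidino=True),
        Metabolite("ABL", 4, 1),
        Metabolite("GBA", 5, 3, guanidino=True),
        Metabolite("GABA", 4, 1),
        Metabolite("SSA", 4, 0),
        Metabolite("SUCC", 4, 0),
        Metabolite("CIT", 6, 3),
        Metabolite("PRO", 5, 1),
        Metabolite("GLU", 5, 1),
        Metabolite("PYR", 3, 0),
        Metabolite("ALA", 3, 1),
        Metabolite("UREA", 1, 2),
        Metabolite("NH4", 0, 1),
        Metabolite("CO2", 1, 0),
        Metabolite("NAD", 0, 0),
        Metabolite("NADH", 0, 0),
    ]
}

CORE_METABOLITES = (
    "ARG", "ORN", "GOP", "AGM", "AOP", "PUT",
    "GBL", "ABL", "GBA", "GABA", "SSA", "SUCC",
)


@dataclass(frozen=True)
class ReactionEdge:
    """One enzymatic conversion; the class fixes the co-species pattern."""

    substrate: str
    product: str
    klass: str
    enzymes: tuple[str, ...] = ()
    rate: float = 0.5  # per min (per mM per min for aminotransferases)

    def __post_init__(self) -> None:
        if self.klass not in REACTION_CLASSES:
            raise ValueError(f"unknown reaction class {self.klass!r}")
        if self.rate < 0:
            raise ValueError("rate must be >= 0")

    @property
    def id(self) -> str:
        return f"{self.substrate}->{self.product}"

    def stoichiometry(self) -> dict[str, int]:
        """Net species changes, co-species included."""
        s: dict[str, int] = {self.substrate: -1, self.product: +1}

        def add(sp: str, d: int) -> None:
            s[sp] = s.get(sp, 0) + d

        if self.klass == "aminotransferase":
            add("PYR", -1)
            add("ALA", +1)
        elif self.klass == "decarboxylase":
            add("CO2", +1)
        elif self.klass == "ureohydrolase":
            add("UREA", +1)
        elif self.klass == "dehydrogenase":
            add("NAD", -1)
            add("NADH", +1)
        elif self.klass == "deiminase":
            add("NH4", +1)
        elif self.klass == "urease":
            # UREA -> 2 NH4 + CO2; substrate/product slots carry UREA/NH4
            add("NH4", +1)
            add("CO2", +1)
        return s

    def atom_imbalance(self) -> tuple[int, int]:
        """(carbon, nitrogen) excess on the product side; (0, 0) if balanced."""
        dc = dn = 0
        for sp, d in self.stoichiometry().items():
            m = METABOLITES[sp]
            dc += d * m.carbons
            dn += d * m.nitrogens
        return dc, dn


# default rate constants: 0.5 /min first-order; aminotransferases carry a
# bimolecular 0.025 /(mM min) so the pseudo-first-order rate at the 20 mM
# pyruvate of the reconstitution assay matches the other steps
_K1 = 0.5
_K2 = 0.025


def _edges() -> list[ReactionEdge]:
    e = ReactionEdge
    return [
        e("ARG", "ORN", "ureohydrolase", ("ArgI1",), _K1),
        e("ARG", "GOP", "aminotransferase", ("AspC",), _K2),
        e("ARG", "AGM", "decarboxylase", ("arginine decarboxylase",), _K1),
        e("ORN", "AOP", "aminotransferase", ("DatA",), _K2),
        e("ORN", "PUT", "decarboxylase", ("OdcA",), _K1),
        e("GOP", "GBL", "decarboxylase", ("IlvB1",), _K1),
        e("GOP", "AOP", "ureohydrolase", ("SpeB2",), _K1),
        e("AGM", "PUT", "ureohydrolase", ("ArgI2", "SpeB"), _K1),
        e("AGM", "GBL", "aminotransferase", ("ArgD",), _K2),
        e("AOP", "ABL", "decarboxylase", ("OdcB",), _K1),
        e("PUT", "ABL", "aminotransferase", ("AatB",), _K2),
        e("GBL", "GBA", "dehydrogenase", ("GabD8", "GabD9"), _K1),
        e("GBL", "ABL", "ureohydrolase", ("SpeB2",), _K1),
        e("GBA", "GABA", "ureohydrolase", ("SpeB2",), _K1),
        e("ABL", "GABA", "dehydrogenase", ("GabD1", "GabD6", "GabD7"), _K1),
        e("GABA", "SSA", "aminotransferase", ("GabT2", "GabT3"), _K2),
        e("SSA", "SUCC", "dehydrogenase", ("GabD",), _K1),
    ]


@dataclass
class NetworkModel:
    """Metabolites, reaction edges, and the derived stoichiometric matrix."""

    edges: list[ReactionEdge]
    metabolites: dict[str, Metabolite] = field(
        default_factory=lambda: dict(METABOLITES)
    )

    def __post_init__(self) -> None:
        self.species = sorted(
            {sp for e in self.edges for sp in e.stoichiometry()}
        )
        self._index = {sp: i for i, sp in enumerate(self.species)}
        self.stoich_matrix = np.zeros((len(self.species), len(self.edges)))
        for j, e in enumerate(self.edges):
            for sp, d in e.stoichiometry().items():
                self.stoich_matrix[self._index[sp], j] = d

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for e in self.edges:
            g.add_edge(e.substrate, e.product, klass=e.klass, enzymes=e.enzymes)
        return g

    def paths(self, source: str = "ARG", target: str = "SUCC") -> list[list[str]]:
        return list(nx.all_simple_paths(self.graph(), source, target))

    def edge_between(self, a: str, b: str) -> ReactionEdge:
        for e in self.edges:
            if e.substrate == a and e.product == b:
                return e
        raise KeyError(f"no edge {a}->{b}")

    def with_rates(self, rates: dict[str, float]) -> "NetworkModel":
        """Copy with per-edge rates overridden by ``{'ARG->ORN': k, ...}``."""
        new = [
            replace(e, rate=rates.get(e.id, e.rate)) for e in self.edges
        ]
        return NetworkModel(edges=new, metabolites=dict(self.metabolites))


def default_network(
    include_deiminase: bool = False,
    include_classical: bool = False,
    include_urease: bool = False,
) -> NetworkModel:
    """The reconstructed arginine-to-succinate grid (12 core metabolites,
    17 edges, all irreversible).

    ``include_deiminase`` adds the off-path ARG -> CIT branch,
    ``include_classical`` the ORN -> PRO -> GLU branch (both used by the
    label-propagation demonstration), ``include_urease`` a urea -> 2
    ammonium + CO2 clean-up step.
    """
    edges = _edges()
    if include_deiminase:
        edges.append(ReactionEdge("ARG", "CIT", "deiminase", ("ArcA1", "ArcA2"),
                                  rate=0.05))
    if include_classical:
        # ornithine cyclodeaminase releases ammonia: deiminase co-pattern
        edges.append(ReactionEdge("ORN", "PRO", "deiminase", ("classical",),
                                  rate=0.05))
        edges.append(ReactionEdge("PRO", "GLU", "dehydrogenase", ("classical",),
                                  rate=0.05))
    if include_urease:
        edges.append(ReactionEdge("UREA", "NH4", "urease", ("UreABC",)))
    return NetworkModel(edges=edges)


def validate(model: NetworkModel) -> dict:
    """Check atom balance per edge and arginine-to-succinate reachability.

    Raises ``ValueError`` naming the offending edge on imbalance; returns a
    report dict on success.
    """
    for e in model.edges:
        dc, dn = e.atom_imbalance()
        if dc != 0 or dn != 0:
            raise ValueError(
                f"edge {e.id} ({e.klass}) unbalanced: dC={dc}, dN={dn}"
            )
    g = model.graph()
    if "ARG" not in g or "SUCC" not in g or not nx.has_path(g, "ARG", "SUCC"):
        raise ValueError("no directed path from ARG to SUCC")
    paths = model.paths()
    return {
        "n_edges": len(model.edges),
        "n_species": len(model.species),
        "n_arg_succ_paths": len(paths),
        "min_path_length": min(len(p) - 1 for p in paths),
    }


def pyruvate_balance(model: NetworkModel, path: list[str]) -> int:
    """Net pyruvate consumed along a directed ARG->SUCC path (each
    aminotransferase edge consumes one equivalent)."""
    consumed = 0
    for a, b in zip(path[:-1], path[1:]):
        e = model.edge_between(a, b)  # KeyError if not a path
        if e.klass == "aminotransferase":
            consumed += 1
    return consumed


@dataclass
class TimeCourse:
    """Simulated concentrations (mM) on a fixed time grid (min)."""

    time: np.ndarray
    concentrations: pd.DataFrame  # columns = species
    metadata: dict = field(default_factory=dict)

    def peak_time(self, species: str) -> float:
        y = self.concentrations[species].to_numpy()
        return float(self.time[int(np.argmax(y))])

    def final(self, species: str) -> float:
        return float(self.concentrations[species].iloc[-1])

    def to_long(self) -> pd.DataFrame:
        df = self.concentrations.copy()
        df.insert(0, "time", self.time)
        return df.melt(id_vars="time", var_name="species", value_name="mM")


RECONSTITUTION_INITIAL = {"ARG": 2.0, "PYR": 20.0, "NAD": 2.0}


def _rate_vector(model: NetworkModel, y: np.ndarray) -> np.ndarray:
    yc = np.maximum(y, 0.0)
    rates = np.empty(len(model.edges))
    for j, e in enumerate(model.edges):
        r = e.rate * yc[model._index[e.substrate]]
        if e.klass == "aminotransferase":
            r *= yc[model._index["PYR"]]
        rates[j] = r
    return rates


def simulate(
    model: NetworkModel,
    initial: dict[str, float] | None = None,
    t_end: float = 360.0,
    dt: float = 1.0,
    clamp: tuple[str, ...] = ("NAD",),
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> TimeCourse:
    """Integrate the mass-action ODE system.

    ``initial`` maps species to mM (defaults to the reconstitution
    scenario: 2 mM arginine, 20 mM pyruvate).  Species in ``clamp`` are
    held constant (NAD+ is assumed non-limiting by default, matching the
    assay's 2 mM NAD+ excess).
    """
    init = dict(RECONSTITUTION_INITIAL if initial is None else initial)
    for sp, v in init.items():
        if sp not in model._index:
            raise ValueError(f"unknown species {sp!r}")
        if v < 0:
            raise ValueError(f"negative initial concentration for {sp}")
    y0 = np.zeros(len(model.species))
    for sp, v in init.items():
        y0[model._index[sp]] = v
    clamped = {model._index[sp] for sp in clamp if sp in model._index}
    S = model.stoich_matrix

    def rhs(t, y):
        dy = S @ _rate_vector(model, y)
        for idx in clamped:
            dy[idx] = 0.0
        return dy

    t_eval = np.arange(0.0, t_end + dt / 2, dt)
    sol = solve_ivp(
        rhs, (0.0, t_end), y0, method="LSODA", t_eval=t_eval,
        rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    conc = pd.DataFrame(np.maximum(sol.y.T, 0.0), columns=model.species)
    return TimeCourse(
        time=sol.t,
        concentrations=conc,
        metadata={
            "initial": init,
            "t_end": t_end,
            "dt": dt,
            "clamped": sorted(clamp),
            "rates": {e.id: e.rate for e in model.edges},
        },
    )


def carbon_total(model: NetworkModel, tc: TimeCourse) -> np.ndarray:
    """Total carbon (mM of C) over all species at each time point; conserved
    by atom-balanced stoichiometry up to integration tolerance."""
    weights = np.array([METABOLITES[sp].carbons for sp in model.species], float)
    return tc.concentrations.to_numpy() @ weights


@dataclass
class LabelState:
    """Fractional labeling per backbone pool over time (0..1)."""

    time: np.ndarray
    fractions: pd.DataFrame  # columns = backbone pools
    sources: dict[str, float]


def propagate_labels(
    model: NetworkModel,
    clamped_sources: dict[str, float],
    t_end: float = 150.0,
    dt: float = 1.0,
    initial_unlabeled: dict[str, float] | None = None,
    pyruvate_mM: float = 20.0,
) -> LabelState:
    """Propagate an isotope label from clamped source pools.

    Each backbone pool is duplicated into labeled/unlabeled species sharing
    the edge rate constants; transamination transfers the backbone to the
    product (the alanine carbon comes from unlabeled pyruvate), so every
    edge moves label substrate -> product at the same per-molecule rate.
    Source pools are clamped at their given fraction.  Non-source pools
    default to a small unlabeled pre-fill (0.05 mM) so dilution is visible.
    """
    for sp, f in clamped_sources.items():
        if sp not in model._index:
            raise ValueError(f"unknown source id {sp!r}")
        if not (0.0 <= f <= 1.0):
            raise ValueError(f"source fraction for {sp} outside [0, 1]")
    backbone = [
        sp for sp in model.species
        if sp in METABOLITES and METABOLITES[sp].carbons > 0
        and sp not in ("PYR", "ALA", "UREA", "CO2")
    ]
    idx = {sp: i for i, sp in enumerate(backbone)}
    if initial_unlabeled is None:
        initial_unlabeled = {
            sp: (2.0 if sp in clamped_sources else 0.05) for sp in backbone
        }
    nL = len(backbone)
    y0 = np.zeros(2 * nL)  # [labeled..., unlabeled...]
    for sp, tot in initial_unlabeled.items():
        f = clamped_sources.get(sp, 0.0)
        y0[idx[sp]] = f * tot
        y0[nL + idx[sp]] = (1 - f) * tot
    src_idx = {idx[sp] for sp in clamped_sources}
    bb_edges = [
        e for e in model.edges if e.substrate in idx and e.product in idx
    ]

    def rhs(t, y):
        dy = np.zeros_like(y)
        yc = np.maximum(y, 0.0)
        for e in bb_edges:
            si, pi = idx[e.substrate], idx[e.product]
            k = e.rate * (pyruvate_mM if e.klass == "aminotransferase" else 1.0)
            for off in (0, nL):
                flux = k * yc[si + off]
                dy[si + off] -= flux
                dy[pi + off] += flux
        for i in src_idx:
            dy[i] = 0.0
            dy[nL + i] = 0.0
        return dy

    t_eval = np.arange(0.0, t_end + dt / 2, dt)
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA", t_eval=t_eval,
                    rtol=1e-9, atol=1e-12)
    if not sol.success:
        raise RuntimeError(f"label ODE integration failed: {sol.message}")
    lab = np.maximum(sol.y[:nL].T, 0.0)
    unl = np.maximum(sol.y[nL:].T, 0.0)
    tot = lab + unl
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(tot > 0, lab / np.maximum(tot, 1e-300), 0.0)
    frac = np.clip(frac, 0.0, 1.0)
    return LabelState(
        time=sol.t,
        fractions=pd.DataFrame(frac, columns=backbone),
        sources=dict(clamped_sources),
    )
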