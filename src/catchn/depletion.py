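"""Symbiosis impairment score from paired input/output insertion libraries.

For each gene with ``n`` input insertion sites of which ``i`` were recovered
after in-planta selection, the score is the product of two probabilities:

* ``p1`` — Poisson probability of recovering at most ``i`` insertions when
  ``lambda = n / l`` are expected under neutral sampling loss at rate ``l``;
* ``p2`` — probability, under uniform random choice of the ``i`` retained
  sites among the ``n`` ordered sites, that the longest run of consecutive
  lost sites is at least ``k`` (the run length actually observed).

A small score flags genes whose insertions were both fewer and more
contiguously lost than neutral sampling explains — the signature of a gene
required for symbiosis.

p2 estimators
-------------
Lost sites fall into the ``i + 1`` gaps delimited by retained sites, so the
run structure is a weak composition of ``n - i`` into ``i + 1`` parts.  With
``C`` the binomial coefficient, the number of retention patterns with at
least one run of length >= k is, by inclusion-exclusion over which gaps hold
a full run,

    h(n, i, k) = sum_{j >= 1} (-1)^(j+1) * C(i+1, j) * C(n - j*k, i)

out of ``C(n, i)`` patterns in total.  When ``k > (n - i) / 2`` at most one
run can reach ``k``, only the ``j = 1`` term survives, and the sum collapses
to the closed form ``(i+1) * C(n-k, i) / C(n, i)``.  Exhaustive enumeration
(small ``n``) and Monte-Carlo sampling (large ``n``) are kept as independent
cross-checks of the same quantity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DepletionScore",
    "DepletionModel",
    "DepletionResults",
    "p1_poisson",
    "p2",
    "p2_fraction",
    "max_loss_run",
    "estimate_loss_rate",
    "impairment_score",
    "call_symbiosis_genes",
]

# above this n, inclusion-exclusion switches from exact integers to log-gamma
_EXACT_N_LIMIT = 2000


# ---------------------------------------------------------------------------
# p1: Poisson recovery probability
# ---------------------------------------------------------------------------

def p1_poisson(lam: float, i: int) -> float:
    """Poisson probability of recovering at most ``i`` insertions.

    ``p1 = sum_{s=0}^{i} exp(-lam) lam^s / s!``, evaluated through the
    regularised incomplete gamma function so it stays accurate for large
    ``lam`` where naive term-by-term summation underflows.
    """
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    if i < 0:
        raise ValueError(f"i must be >= 0, got {i}")
    return float(stats.poisson.cdf(i, lam))


# ---------------------------------------------------------------------------
# (n, i, k) from site lists
# ---------------------------------------------------------------------------

def max_loss_run(
    input_sites: Sequence[int] | np.ndarray,
    output_sites: Iterable[int] | np.ndarray,
) -> tuple[int, int, int]:
    """Return ``(n, i, k)`` for one gene.

    ``input_sites`` are the insertion coordinates present before selection;
    ``output_sites`` those recovered afterwards (a subset, matched by
    position).  ``k`` is the longest run, in coordinate order, of input
    sites absent from the output.
    """
    inp = np.sort(np.asarray(list(input_sites), dtype=np.int64))
    out = set(int(p) for p in output_sites)
    extra = out - set(int(p) for p in inp)
    if extra:
        raise ValueError(
            f"output sites not present in input: {sorted(extra)[:5]}"
        )
    n = len(inp)
    i = len(out)
    k = run = 0
    for pos in inp:
        if int(pos) in out:
            run = 0
        else:
            run += 1
            k = max(k, run)
    return n, i, k


def _validate_nik(n: int, i: int, k: int) -> None:
    if n < 0 or i < 0 or k < 0:
        raise ValueError(f"n, i, k must be >= 0 (got {n}, {i}, {k})")
    if i > n:
        raise ValueError(f"i={i} exceeds n={n}")


# ---------------------------------------------------------------------------
# p2 estimators
# ---------------------------------------------------------------------------

def _h_count(n: int, i: int, k: int) -> int:
    """Exact number of retention patterns whose longest loss-run is >= k."""
    total = math.comb(n, i)
    if k == 0:
        return total
    if k > n - i:
        return 0
    acc = 0
    j = 1
    while n - j * k >= i and j <= i + 1:
        acc += (-1) ** (j + 1) * math.comb(i + 1, j) * math.comb(n - j * k, i)
        j += 1
    return acc


def _p2_inclusion_exclusion_log(n: int, i: int, k: int) -> float:
    """Inclusion-exclusion via log-gamma with compensated summation."""
    if k == 0:
        return 1.0
    if k > n - i:
        return 0.0
    log_total = gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1)
    terms = []
    j = 1
    while n - j * k >= i and j <= i + 1:
        log_t = (
            gammaln(i + 2) - gammaln(j + 1) - gammaln(i + 2 - j)
            + gammaln(n - j * k + 1) - gammaln(i + 1) - gammaln(n - j * k - i + 1)
            - log_total
        )
        terms.append((-1) ** (j + 1) * math.exp(log_t))
        j += 1
    return float(min(1.0, max(0.0, math.fsum(terms))))


def p2_fraction(n: int, i: int, k: int, method: str = "inclusion_exclusion") -> Fraction:
    """Exact rational p2 (test oracle; ``method`` in
    ``{inclusion_exclusion, enumeration, closed_form}``)."""
    _validate_nik(n, i, k)
    total = math.comb(n, i)
    if method == "inclusion_exclusion":
        return Fraction(_h_count(n, i, k), total)
    if method == "closed_form":
        if k == 0:
            return Fraction(1)
        if k > n - i:
            return Fraction(0)
        if 2 * k <= n - i:
            raise ValueError(
                f"closed form requires k > (n-i)/2 (n={n}, i={i}, k={k})"
            )
        return Fraction((i + 1) * math.comb(n - k, i), total)
    if method == "enumeration":
        if n > 22:
            raise ValueError("enumeration oracle limited to n <= 22")
        if k == 0:
            return Fraction(1)
        favorable = 0
        from itertools import combinations

        for retained in combinations(range(n), i):
            longest = run = 0
            prev = -1
            for r in retained:
                run = r - prev - 1
                longest = max(longest, run)
                prev = r
            longest = max(longest, n - 1 - prev)
            if longest >= k:
                favorable += 1
        return Fraction(favorable, total)
    raise ValueError(f"unknown exact method {method!r}")


def _p2_monte_carlo(
    n: int, i: int, k: int, reps: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Frequency of max loss-run >= k over random retention patterns."""
    if k == 0:
        return 1.0, 0.0
    if k > n - i:
        return 0.0, 0.0
    hits = 0
    chunk = max(1, min(reps, 20_000))
    done = 0
    while done < reps:
        c = min(chunk, reps - done)
        if i == 0:
            hits += c  # max run is n >= k here
        else:
            u = rng.random((c, n))
            idx = np.argpartition(u, i - 1, axis=1)[:, :i]
            idx.sort(axis=1)
            first = idx[:, 0]
            last = n - 1 - idx[:, -1]
            if i > 1:
                mid = np.diff(idx, axis=1) - 1
                runs = np.maximum(mid.max(axis=1), np.maximum(first, last))
            else:
                runs = np.maximum(first, last)
            hits += int((runs >= k).sum())
        done += c
    p = hits / reps
    se = math.sqrt(max(p * (1 - p), 1e-300) / reps)
    return p, se


def p2(
    n: int,
    i: int,
    k: int,
    method: str = "auto",
    reps: int = 100_000,
    seed: int | None = None,
) -> tuple[float, str, float | None]:
    """Probability that the longest loss-run is >= k; see module docstring.

    Returns ``(probability, method_used, standard_error)``; the standard
    error is ``None`` except for ``monte_carlo``.  ``auto`` uses exact
    inclusion-exclusion (integer arithmetic up to n = 2000, log-gamma
    beyond).  The historical branches — ``closed_form`` (valid only for
    ``k > (n-i)/2``), ``enumeration`` (n <= 22), ``monte_carlo`` — remain
    selectable as cross-checks.
    """
    _validate_nik(n, i, k)
    if method in ("auto", "inclusion_exclusion"):
        if n <= _EXACT_N_LIMIT:
            return float(p2_fraction(n, i, k)), "inclusion_exclusion", None
        return _p2_inclusion_exclusion_log(n, i, k), "inclusion_exclusion", None
    if method in ("closed_form", "enumeration"):
        return float(p2_fraction(n, i, k, method)), method, None
    if method == "monte_carlo":
        rng = np.random.default_rng(seed)
        p, se = _p2_monte_carlo(n, i, k, reps, rng)
        return p, "monte_carlo", se
    raise ValueError(f"unknown p2 method {method!r}")


# ---------------------------------------------------------------------------
# loss rate and the combined score
# ---------------------------------------------------------------------------

def estimate_loss_rate(
    genes: Mapping[str, tuple[int, int]] | pd.DataFrame,
    neutral_set: Iterable[str] | None = None,
) -> float:
    """Neutral loss rate ``l = sum(n) / sum(i)`` over the neutral gene set.

    ``genes`` maps gene id to ``(n, i)`` (or is a DataFrame with columns
    ``n`` and ``i`` indexed by gene).  Without a neutral set all genes are
    pooled — adequate when depleted genes are a small minority.
    """
    if isinstance(genes, pd.DataFrame):
        table = {g: (int(r["n"]), int(r["i"])) for g, r in genes.iterrows()}
    else:
        table = {g: (int(n), int(i)) for g, (n, i) in genes.items()}
    ids = list(neutral_set) if neutral_set is not None else list(table)
    total_n = sum(table[g][0] for g in ids)
    total_i = sum(table[g][1] for g in ids)
    if total_n <= 0:
        raise ValueError("neutral set has no input insertions")
    if total_i == 0:
        raise ValueError("no recovered insertions in the neutral set")
    return total_n / total_i


@dataclass(frozen=True)
class DepletionScore:
    """Impairment score for one gene: ``score = p1 * p2`` with provenance."""

    lam: float
    p1: float
    p2: float
    score: float
    p2_method: str
    mc_se: float | None = None

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "score"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


def impairment_score(
    n: int,
    i: int,
    k: int,
    loss_rate: float,
    p2_method: str = "auto",
    reps: int = 100_000,
    seed: int | None = None,
) -> DepletionScore:
    """Combined symbiosis impairment score for one gene.

    ``lambda = n / loss_rate``; requires ``loss_rate >= 1`` and ``n >= 1``
    (a gene without input insertions carries no information — callers flag
    it ``no_data`` instead).
    """
    if loss_rate < 1:
        raise ValueError(f"loss rate must be >= 1, got {loss_rate}")
    if n == 0:
        raise ValueError("n = 0: no input insertions (flag gene as no_data)")
    lam = n / loss_rate
    v1 = p1_poisson(lam, i)
    v2, used, se = p2(n, i, k, method=p2_method, reps=reps, seed=seed)
    return DepletionScore(
        lam=lam, p1=v1, p2=v2, score=v1 * v2, p2_method=used, mc_se=se
    )


def call_symbiosis_genes(
    scores: pd.DataFrame,
    alpha: float = 0.05,
    correction: str = "none",
) -> pd.DataFrame:
    """Flag genes whose (adjusted) score falls below ``alpha``.

    ``scores`` needs a ``score`` column indexed by gene.  Returns the table
    sorted ascending by score with ``adjusted`` and ``symbiosis_gene``
    columns added.
    """
    out = scores.copy()
    if correction == "none":
        out["adjusted"] = out["score"]
    elif correction == "benjamini_hochberg":
        out["adjusted"] = multipletests(out["score"].to_numpy(), method="fdr_bh")[1]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    out["symbiosis_gene"] = out["adjusted"] < alpha
    return out.sort_values("score", kind="mergesort")


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class DepletionModel:
    """Impairment-score model over paired input/output insertion libraries.

    Construct either from a per-gene ``(n, i, k)`` DataFrame or, with
    :meth:`from_libraries`, directly from an annotation and two
    :class:`~catchn.io.InsertionLibrary` objects.  :meth:`fit` estimates the
    neutral loss rate (unless supplied) and scores every gene.
    """

    def __init__(self, data: pd.DataFrame):
        required = {"n", "i", "k"}
        if not required <= set(data.columns):
            raise ValueError(f"need columns {sorted(required)}")
        bad = data[(data["i"] > data["n"]) | (data["k"] > data["n"] - data["i"])]
        if len(bad):
            raise ValueError(
                f"inconsistent (n, i, k) rows for genes {list(bad.index[:5])}"
            )
        self.data = data.copy()

    @classmethod
    def from_libraries(cls, annotation, input_library, output_library,
                       extra_columns: pd.DataFrame | None = None) -> "DepletionModel":
        from catchn.io import INTERGENIC, assign_insertions

        assign_in = assign_insertions(annotation, input_library)
        assign_out = assign_insertions(annotation, output_library)
        rows = {}
        for gene, sites_in in assign_in.items():
            if gene == INTERGENIC:
                continue
            sites_out = assign_out.get(gene, np.array([], int))
            n, i, k = max_loss_run(sites_in, sites_out)
            rows[gene] = {"n": n, "i": i, "k": k}
        data = pd.DataFrame.from_dict(rows, orient="index")
        if extra_columns is not None:
            data = data.join(extra_columns, how="left")
        return cls(data)

    def fit(
        self,
        loss_rate: float | None = None,
        neutral_set: Iterable[str] | None = None,
        alpha: float = 0.05,
        correction: str = "none",
        p2_method: str = "auto",
        reps: int = 100_000,
        seed: int | None = None,
    ) -> "DepletionResults":
        if loss_rate is None:
            loss_rate = estimate_loss_rate(self.data[["n", "i"]], neutral_set)
        records = []
        for gene, row in self.data.iterrows():
            n, i, k = int(row["n"]), int(row["i"]), int(row["k"])
            if n == 0:
                records.append(
                    {"gene": gene, "n": n, "i": i, "k": k, "lambda": 0.0,
                     "p1": np.nan, "p2": np.nan, "score": np.nan,
                     "method": "no_data"}
                )
                continue
            s = impairment_score(
                n, i, k, loss_rate, p2_method=p2_method, reps=reps, seed=seed
            )
            records.append(
                {"gene": gene, "n": n, "i": i, "k": k, "lambda": s.lam,
                 "p1": s.p1, "p2": s.p2, "score": s.score, "method": s.p2_method}
            )
        table = pd.DataFrame.from_records(records).set_index("gene")
        scored = table.dropna(subset=["score"])
        called = call_symbiosis_genes(scored, alpha=alpha, correction=correction)
        return DepletionResults(
            model=self, loss_rate=loss_rate, table=table, calls=called,
            alpha=alpha, correction=correction,
        )


@dataclass
class DepletionResults:
    """Fitted impairment scores plus the symbiosis-gene calls."""

    model: DepletionModel
    loss_rate: float
    table: pd.DataFrame
    calls: pd.DataFrame
    alpha: float
    correction: str

    @property
    def symbiosis_genes(self) -> list[str]:
        return list(self.calls.index[self.calls["symbiosis_gene"]])

    def summary(self) -> str:
        n_genes = len(self.table)
        n_nodata = int((self.table["method"] == "no_data").sum())
        n_flagged = len(self.symbiosis_genes)
        lines = [
            "Symbiosis impairment score",
            "=" * 40,
            f"genes scored            {n_genes - n_nodata}",
            f"genes without input data {n_nodata}",
            f"neutral loss rate l     {self.loss_rate:.4f}",
            f"alpha                   {self.alpha}",
            f"correction              {self.correction}",
            f"symbiosis genes flagged {n_flagged}",
        ]
        top = self.calls.head(10)
        if len(top):
            lines.append("-" * 40)
            lines.append("top-ranked genes (ascending score):")
            lines.append(
                top[["n", "i", "k", "score"]].to_string(float_format="%.3g")
            )
        return "\n".join(lines)
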