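"""Gene-set term enrichment with a resampling robustness null.

Each term is tested with a two-sided hypergeometric test (enrichment or
depletion; two-sided mass by the minimum-likelihood rule), family-wise
corrected with the Holm (Bonferroni step-down) procedure. The robustness
null re-runs the identical analysis on random gene sets drawn from the
universe minus the focal genes and reports, per term, in how many of the
random sets it comes out significant -- a term that is real should appear
in at most a handful of the random draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class TermMap:
    """gene id -> set of term ids, with optional term labels."""

    gene_terms: dict[str, set[str]]
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.term_genes: dict[str, set[str]] = {}
        for gene, terms in self.gene_terms.items():
            for t in terms:
                self.term_genes.setdefault(t, set()).add(gene)

    @property
    def terms(self) -> list[str]:
        return sorted(self.term_genes)

    def genes_with(self, term: str) -> set[str]:
        return self.term_genes.get(term, set())


def hypergeom_test(k: int, K: int, n: int, N: int) -> tuple[float, str]:
    """Two-sided hypergeometric p-value and direction for one term.

    k: set genes carrying the term, K: universe genes carrying it, n: set
    size, N: universe size. The two-sided p sums P(x) over all x with
    P(x) <= P(k) (minimum-likelihood definition); the direction compares k
    with its expectation nK/N, ties broken as "enriched".
    """
    if not (0 <= k <= min(K, n)) or K > N or n > N:
        raise ValueError("inconsistent hypergeometric counts")
    if K == 0 or K == N:
        return 1.0, "enriched"
    support = np.arange(max(0, n - (N - K)), min(K, n) + 1)
    pmf = hypergeom.pmf(support, N, K, n)
    p_obs = hypergeom.pmf(k, N, K, n)
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-9)].sum())
    direction = "depleted" if k < n * K / N else "enriched"
    return min(p, 1.0), direction


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    _, adjusted, _, _ = multipletests(p, method="holm")
    return adjusted


def enrich_gene_set(gene_set, universe, term_map: TermMap,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Holm-corrected two-sided hypergeometric enrichment of one gene set."""
    gene_set = set(gene_set)
    universe = set(universe)
    missing = gene_set - universe
    if missing:
        raise ValueError(f"{len(missing)} set genes absent from the universe")
    N, n = len(universe), len(gene_set)
    rows = []
    for term in term_map.terms:
        carriers = term_map.genes_with(term) & universe
        K = len(carriers)
        if K == 0:
            continue
        k = len(carriers & gene_set)
        p, direction = hypergeom_test(k, K, n, N)
        rows.append({"term": term,
                     "label": term_map.labels.get(term, term),
                     "k": k, "K": K, "n": n, "N": N,
                     "direction": direction, "p_two_sided": p})
    out = pd.DataFrame(rows, columns=["term", "label", "k", "K", "n", "N",
                                      "direction", "p_two_sided"])
    if len(out):
        out["p_adjusted"] = holm_adjust(out["p_two_sided"].to_numpy())
        out["significant"] = out["p_adjusted"] <= alpha
        out = out.sort_values("p_adjusted", kind="stable").reset_index(drop=True)
    else:
        out["p_adjusted"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out


def random_set_null(universe, excluded, set_size: int, term_map: TermMap,
                    n_sets: int = 50, alpha: float = 0.05,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-term significance frequency across random gene sets.

    Draws ``n_sets`` sets of ``set_size`` genes (without replacement within
    a set) from ``universe`` minus ``excluded`` and runs the identical
    Holm-corrected enrichment on each. Returns a term-indexed table with
    ``n_flagged`` = number of random sets in which the term was significant.
    """
    rng = rng if rng is not None else np.random.default_rng()
    pool = sorted(set(universe) - set(excluded))
    if len(pool) < set_size:
        raise ValueError(
            f"universe minus excluded has {len(pool)} genes < set size {set_size}")
    counts: dict[str, int] = {t: 0 for t in term_map.terms}
    for _ in range(n_sets):
        draw = rng.choice(len(pool), size=set_size, replace=False)
        res = enrich_gene_set([pool[i] for i in draw], universe, term_map, alpha)
        for term in res.loc[res["significant"], "term"]:
            counts[term] += 1
    return pd.DataFrame({"term": list(counts), "n_flagged": list(counts.values()),
                         "n_sets": n_sets}).set_index("term")
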