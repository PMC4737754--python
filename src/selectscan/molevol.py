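"""Evolutionary-rate estimation (NG86 dN/dS) and rate contrasts.

dN/dS (omega) is estimated with the Nei-Gojobori (1986) counting method:
synonymous/nonsynonymous site counts per codon (mutations to stop codons
count as nonsynonymous, so sites per codon always sum to 3), differences
counted by averaging over all shortest substitution pathways with equal
weights (pathways through stop codons are dropped; codon pairs with no
stop-free pathway are excluded entirely), and Jukes-Cantor correction
d = -3/4 ln(1 - 4p/3). This is a deliberate counting stand-in for a full
codon-model ML fit; site-model flags of positive selection are consumed as
inputs, never computed here.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy.stats import chi2_contingency, mannwhitneyu
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_TABLE.stop_codons)
_BASES = "ACGT"


def _aa(codon: str) -> str | None:
    return None if codon in _STOPS else _TABLE.forward_table[codon]


@lru_cache(maxsize=None)
def codon_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one codon; sums to 3."""
    if codon in _STOPS:
        raise ValueError(f"stop codon {codon} has no site counts")
    syn = 0.0
    for i in range(3):
        for b in _BASES:
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1:]
            if mut not in _STOPS and _aa(mut) == _aa(codon):
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def codon_path_counts(a: str, b: str) -> tuple[float, float] | None:
    """(syn, nonsyn) differences between codons a and b.

    Averages over all orderings of the differing positions; pathways passing
    through a stop codon are excluded. Returns None when every pathway is
    blocked (the codon pair is then dropped from both numerator and
    denominator by the caller).
    """
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = a
        syn = nonsyn = 0.0
        ok = True
        for i in order:
            nxt = cur[:i] + b[i] + cur[i + 1:]
            if nxt in _STOPS:
                ok = False
                break
            if _aa(cur) == _aa(nxt):
                syn += 1.0
            else:
                nonsyn += 1.0
            cur = nxt
        if ok:
            paths.append((syn, nonsyn))
    if not paths:
        return None
    arr = np.array(paths)
    return float(arr[:, 0].mean()), float(arr[:, 1].mean())


def jukes_cantor(p: float) -> float:
    """JC69 distance; NaN when saturated (p >= 3/4)."""
    if p >= 0.75:
        return float("nan")
    return -0.75 * float(np.log1p(-4.0 * p / 3.0))


@dataclass
class PairwiseRates:
    dN: float
    dS: float
    omega: float            # NaN when dS == 0 or saturated
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    n_codons: int           # codons actually compared
    saturated: bool = False


def _clean_codons(seq_a: str, seq_b: str):
    """Yield comparable codon pairs; skip gapped/ambiguous/stop codons."""
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    if len(seq_a) % 3:
        raise ValueError("aligned length must be divisible by 3")
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3], seq_b[i:i + 3]
        if any(ch not in _BASES for ch in ca + cb):
            continue
        if ca in _STOPS or cb in _STOPS:
            continue
        yield ca, cb


def ng86_pairwise(seq_a: str, seq_b: str) -> PairwiseRates:
    """NG86 dN, dS and omega for one aligned codon-sequence pair."""
    S_sites = N_sites = Sd = Nd = 0.0
    n_codons = 0
    for ca, cb in _clean_codons(seq_a, seq_b):
        path = codon_path_counts(ca, cb)
        if path is None:
            continue
        sa, na = codon_site_counts(ca)
        sb, nb = codon_site_counts(cb)
        S_sites += (sa + sb) / 2.0
        N_sites += (na + nb) / 2.0
        Sd += path[0]
        Nd += path[1]
        n_codons += 1
    if n_codons == 0:
        raise ValueError("no comparable codons between the two sequences")
    pS = Sd / S_sites if S_sites > 0 else 0.0
    pN = Nd / N_sites if N_sites > 0 else 0.0
    dS = jukes_cantor(pS)
    dN = jukes_cantor(pN)
    saturated = bool(np.isnan(dS) or np.isnan(dN))
    omega = dN / dS if (not saturated and dS > 0) else float("nan")
    return PairwiseRates(dN=dN, dS=dS, omega=omega,
                         syn_sites=S_sites, nonsyn_sites=N_sites,
                         syn_diffs=Sd, nonsyn_diffs=Nd,
                         n_codons=n_codons, saturated=saturated)


def triplet_omega(alignment: dict[str, str]) -> float:
    """Single omega for a small multi-taxon alignment.

    Combines all pairwise NG86 estimates: dN and dS are averaged with the
    pairwise nonsynonymous/synonymous site counts as weights, and omega is
    their ratio -- a counting proxy for a one-ratio codon-model fit.
    """
    if len(alignment) < 2:
        raise ValueError("need at least two sequences")
    dn_num = dn_den = ds_num = ds_den = 0.0
    for a, b in itertools.combinations(alignment.values(), 2):
        r = ng86_pairwise(a, b)
        if r.saturated:
            continue
        dn_num += r.nonsyn_sites * r.dN
        dn_den += r.nonsyn_sites
        ds_num += r.syn_sites * r.dS
        ds_den += r.syn_sites
    if dn_den == 0 or ds_den == 0:
        return float("nan")
    dN_bar = dn_num / dn_den
    dS_bar = ds_num / ds_den
    return dN_bar / dS_bar if dS_bar > 0 else float("nan")


@dataclass
class GeneEvolution:
    gene_id: str
    dN: float = float("nan")
    dS: float = float("nan")
    omega: float = float("nan")
    possel_flag: bool = False
    p_value: float = float("nan")
    q_flag: bool = False
    extra: dict = field(default_factory=dict)


def _exact_mwu_two_sided(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Exact two-sided p by enumerating all group labelings (handles ties)."""
    pooled = np.concatenate([a, b])
    n1 = a.size
    idx = range(pooled.size)
    mu = n1 * b.size / 2.0
    extreme = 0
    total = 0
    for comb in itertools.combinations(idx, n1):
        mask = np.zeros(pooled.size, dtype=bool)
        mask[list(comb)] = True
        ga, gb = pooled[mask], pooled[~mask]
        u = float(np.sum(ga[:, None] > gb[None, :])
                  + 0.5 * np.sum(ga[:, None] == gb[None, :]))
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            extreme += 1
        total += 1
    return extreme / total


def rate_contrast(omegas_a, omegas_b) -> tuple[float, float, float, float]:
    """Mann-Whitney U contrast of two omega groups.

    Returns (median_a, median_b, U, two-sided p). Undefined (NaN) omegas are
    excluded. The p-value is by exact enumeration over labelings when
    n_a + n_b <= 12, otherwise the normal approximation with tie correction.
    """
    a = np.asarray(omegas_a, dtype=float)
    b = np.asarray(omegas_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty after removing NaN")
    u_obs = float(np.sum(a[:, None] > b[None, :])
                  + 0.5 * np.sum(a[:, None] == b[None, :]))
    if np.all(np.concatenate([a, b]) == a[0]):
        p = 1.0
    elif a.size + b.size <= 12:
        p = _exact_mwu_two_sided(a, b, u_obs)
    else:
        p = float(mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic").pvalue)
    return float(np.median(a)), float(np.median(b)), u_obs, p


def possel_enrichment(table) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table of
    set membership versus positive-selection status."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    res = chi2_contingency(table, correction=False)
    if np.any(res.expected_freq < 5):
        warnings.warn("expected counts < 5; consider an exact test",
                      stacklevel=2)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values, fdr: float = 0.2) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (significance flags at ``fdr``, adjusted p)."""
    p = np.asarray(p_values, dtype=float)
    reject, adjusted, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return reject, adjusted


def lineage_profile(focal_seq: str,
                    panel: dict[str, str]) -> pd.DataFrame:
    """Pairwise NG86 rates of a focal sequence against each panel ortholog.

    Flags the maximum-omega pair (NaN omegas never win).
    """
    rows = []
    for taxon, seq in panel.items():
        r = ng86_pairwise(focal_seq, seq)
        rows.append({"taxon": taxon, "dN": r.dN, "dS": r.dS,
                     "omega": r.omega, "n_codons": r.n_codons})
    out = pd.DataFrame(rows)
    out["max_omega"] = False
    finite = out["omega"].notna()
    if finite.any():
        out.loc[out.loc[finite, "omega"].idxmax(), "max_omega"] = True
    return out
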