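"""Population-genetic substrate: genotype tables, outgroup polarization,
site frequency spectra, windowed diversity statistics and differentiation.

Conventions
-----------
Genotypes are stored as copies of the non-reference allele (0/1/2; -1 for
missing) for a panel of diploid individuals. Polarization against one or
more outgroup alleles follows maximum parsimony: when every non-missing
outgroup carries the same allele and that allele is one of the two focal
alleles, it is taken as ancestral; otherwise the site is kept but analysed
folded (minor-allele count). Sites with any missing focal genotype are
excluded from spectra and window statistics so that the haploid sample size
n is constant; every such exclusion is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

MISSING = -1


@dataclass
class VariantTable:
    """Per-site biallelic genotype calls plus outgroup alleles.

    Arrays are parallel over sites; positions are 0-based and strictly
    increasing within each chromosome.
    """

    chrom: np.ndarray            # object/str, per site
    pos: np.ndarray              # int64, 0-based
    ref: np.ndarray              # single characters
    alt: np.ndarray
    genotypes: np.ndarray        # (n_sites, n_individuals) int8, -1 missing
    outgroup_alleles: np.ndarray  # (n_sites, n_outgroups) '<U1', 'N' missing
    samples: list[str] = field(default_factory=list)
    outgroup_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.outgroup_alleles = np.asarray(self.outgroup_alleles, dtype="<U1")
        if self.genotypes.ndim != 2 or self.genotypes.shape[0] != self.pos.size:
            raise ValueError("genotypes must be (n_sites, n_individuals)")
        for name in np.unique(self.chrom):
            p = self.pos[self.chrom == name]
            if p.size > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {name}")

    @property
    def n_sites(self) -> int:
        return int(self.pos.size)

    @property
    def n_individuals(self) -> int:
        return int(self.genotypes.shape[1])

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def subset(self, mask: np.ndarray) -> "VariantTable":
        return VariantTable(
            self.chrom[mask], self.pos[mask], self.ref[mask], self.alt[mask],
            self.genotypes[mask], self.outgroup_alleles[mask],
            self.samples, self.outgroup_names)

    def by_chromosome(self):
        for name in self.chromosomes:
            yield name, self.subset(self.chrom == name)


@dataclass
class PolarizedSites:
    """Sites with derived (or folded minor) allele counts.

    ``derived_count`` holds the derived count where polarization succeeded
    (``folded`` False) and the minor-allele count otherwise.
    """

    chrom: np.ndarray
    pos: np.ndarray
    derived_count: np.ndarray   # int
    folded: np.ndarray          # bool
    n_called: np.ndarray        # haploid sample size at the site

    @property
    def n_sites(self) -> int:
        return int(self.pos.size)

    def subset(self, mask: np.ndarray) -> "PolarizedSites":
        return PolarizedSites(self.chrom[mask], self.pos[mask],
                              self.derived_count[mask], self.folded[mask],
                              self.n_called[mask])


@dataclass
class SiteFrequencySpectrum:
    """Counts of allele-frequency classes at haploid sample size n.

    Unfolded spectra have classes j = 1..n-1 (``counts[j-1]``); folded
    spectra have classes m = 1..floor(n/2).
    """

    n: int
    counts: np.ndarray
    folded: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        expected = self.n // 2 if self.folded else self.n - 1
        if self.counts.size != expected:
            raise ValueError(
                f"expected {expected} classes for n={self.n}, folded={self.folded}")
        if np.any(self.counts < 0):
            raise ValueError("negative SFS class count")

    def normalized(self, pseudocount: float = 0.0) -> np.ndarray:
        c = self.counts + pseudocount
        total = c.sum()
        if total <= 0:
            raise ValueError("cannot normalize an empty spectrum")
        return c / total

    def fold(self) -> "SiteFrequencySpectrum":
        if self.folded:
            return self
        n = self.n
        m = n // 2
        out = np.zeros(m)
        for j in range(1, n):
            k = min(j, n - j)
            out[k - 1] += self.counts[j - 1]
        return SiteFrequencySpectrum(n, out, folded=True)


def complete_sites(vt: VariantTable) -> VariantTable:
    """Drop sites with any missing focal genotype (keeps n constant)."""
    mask = np.all(vt.genotypes != MISSING, axis=1)
    dropped = int((~mask).sum())
    if dropped:
        logger.info("filter=complete_genotypes input=%d surviving=%d",
                    vt.n_sites, vt.n_sites - dropped)
    return vt.subset(mask)


def polarize_sites(vt: VariantTable) -> PolarizedSites:
    """Assign ancestral states by outgroup parsimony; fold the rest.

    Ancestral = the allele carried by all non-missing outgroups when they
    agree and it matches one of the two focal alleles. Disagreement, missing
    outgroups or an uninformative third allele leave the site folded.
    """
    called = vt.genotypes != MISSING
    n_called = 2 * called.sum(axis=1)
    alt_count = np.where(called, vt.genotypes, 0).sum(axis=1)

    n_sites = vt.n_sites
    folded = np.ones(n_sites, dtype=bool)
    count = np.minimum(alt_count, n_called - alt_count)  # folded default

    og = vt.outgroup_alleles
    if og.size:
        present = og != "N"
        any_present = present.any(axis=1)
        first = np.where(any_present, og[np.arange(n_sites),
                                         np.argmax(present, axis=1)], "N")
        agree = any_present.copy()
        for k in range(og.shape[1]):
            agree &= ~present[:, k] | (og[:, k] == first)
        anc_is_ref = agree & (first == vt.ref)
        anc_is_alt = agree & (first == vt.alt)
        informative = anc_is_ref | anc_is_alt
        folded[informative] = False
        count = np.where(anc_is_ref, alt_count, count)
        count = np.where(anc_is_alt, n_called - alt_count, count)

    logger.info("filter=polarized input=%d surviving=%d (rest folded)",
                n_sites, int((~folded).sum()))
    return PolarizedSites(vt.chrom.copy(), vt.pos.copy(),
                          count.astype(np.int64), folded,
                          n_called.astype(np.int64))


def build_sfs(sites: PolarizedSites, n: int,
              folded: bool = False) -> SiteFrequencySpectrum:
    """Tally an SFS from polarized sites at haploid sample size n.

    The unfolded spectrum uses polarizable segregating sites only; the
    folded spectrum includes all segregating sites. Sites whose called
    sample size differs from n are excluded (and logged).
    """
    if sites.n_sites == 0:
        raise ValueError("cannot build an SFS from zero sites")
    ok_n = sites.n_called == n
    if not np.all(ok_n):
        logger.info("filter=sfs_sample_size input=%d surviving=%d",
                    sites.n_sites, int(ok_n.sum()))
    if folded:
        m = n // 2
        cnt = np.minimum(sites.derived_count, n - sites.derived_count)
        use = ok_n & (cnt >= 1)
        counts = np.bincount(cnt[use], minlength=m + 1)[1:m + 1]
        return SiteFrequencySpectrum(n, counts.astype(float), folded=True)
    use = ok_n & ~sites.folded & (sites.derived_count >= 1) \
        & (sites.derived_count <= n - 1)
    counts = np.bincount(sites.derived_count[use], minlength=n)[1:n]
    return SiteFrequencySpectrum(n, counts.astype(float), folded=False)


def harmonic_number(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n)))


def watterson_theta(S: int, n: int, L: float) -> float:
    """Watterson's per-site estimator theta_W = S / (a1 * L)."""
    if n < 2:
        raise ValueError("watterson_theta needs n >= 2")
    if L <= 0:
        raise ValueError("surveyed length must be positive")
    return S / (harmonic_number(n) * L)


def pairwise_pi(counts: np.ndarray, n: int) -> float:
    """Sum over sites of 2 j (n-j) / (n (n-1)) from allele counts.

    Algebraically identical to averaging over all pairwise sequence
    comparisons, but O(S).
    """
    j = np.asarray(counts, dtype=float)
    return float(np.sum(2.0 * j * (n - j) / (n * (n - 1.0))))


def tajima_d_constants(n: int) -> dict[str, float]:
    a1 = harmonic_number(n)
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajima_d(counts: np.ndarray, n: int) -> float:
    """Tajima's D from per-site minor/derived allele counts.

    D is symmetric in j <-> n-j, so folded counts are fine. Returns NaN when
    S < 2 (variance estimate degenerate) -- callers flag such windows as
    undefined rather than zero.
    """
    counts = np.asarray(counts)
    counts = counts[(counts >= 1) & (counts <= n - 1)]
    S = counts.size
    if S < 2:
        return float("nan")
    k = tajima_d_constants(n)
    pi = pairwise_pi(counts, n)
    num = pi - S / k["a1"]
    var = k["e1"] * S + k["e2"] * S * (S - 1.0)
    return float(num / np.sqrt(var))


@dataclass
class WindowStat:
    interval_chrom: str
    start: int
    end: int
    surveyed_bp: int
    S: int
    theta_w: float
    pi: float
    tajima_d: float   # NaN when S < 2
    partial: bool


def sliding_windows(vt: VariantTable, chrom_lengths: dict[str, int],
                    window: int = 50_000, step: int = 10_000) -> list[WindowStat]:
    """Sliding-window S, theta_W, pi and Tajima's D.

    Windows tile [0, chrom_length) at ``step``; each site contributes to
    every window overlapping it; the last partial window is retained with
    its true surveyed length and flagged.
    """
    if window < step:
        raise ValueError("window must be >= step")
    vt = complete_sites(vt)
    n = 2 * vt.n_individuals
    out: list[WindowStat] = []
    for name, sub in vt.by_chromosome():
        L = chrom_lengths[name]
        alt = sub.genotypes.sum(axis=1)
        seg = (alt >= 1) & (alt <= n - 1)
        pos = sub.pos[seg]
        cnt = alt[seg]
        for start in range(0, L, step):
            end = min(start + window, L)
            lo, hi = np.searchsorted(pos, [start, end])
            c = cnt[lo:hi]
            S = int(c.size)
            surveyed = end - start
            out.append(WindowStat(
                name, start, end, surveyed, S,
                watterson_theta(S, n, surveyed),
                pairwise_pi(c, n) / surveyed,
                tajima_d(c, n),
                partial=(end - start) < window))
    return out


def hudson_fst(genotypes_a: np.ndarray,
               genotypes_b: np.ndarray) -> tuple[np.ndarray, float]:
    """Hudson's FST per site and as a ratio-of-sums average.

    Uses the standard unbiased per-site numerator/denominator
    (Hudson 1992 as usually written for sample allele frequencies):
    N = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1),
    D = p1(1-p2) + p2(1-p1); the multi-site estimate is sum(N)/sum(D).
    Sites monomorphic across both samples (or with <2 haploid calls in
    either) are skipped (NaN per site, excluded from the average).
    """
    ga = np.asarray(genotypes_a)
    gb = np.asarray(genotypes_b)
    ca = ga != MISSING
    cb = gb != MISSING
    na = 2.0 * ca.sum(axis=1)
    nb = 2.0 * cb.sum(axis=1)
    xa = np.where(ca, ga, 0).sum(axis=1)
    xb = np.where(cb, gb, 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pa = xa / na
        pb = xb / nb
        num = ((pa - pb) ** 2
               - pa * (1 - pa) / (na - 1)
               - pb * (1 - pb) / (nb - 1))
        den = pa * (1 - pb) + pb * (1 - pa)
        per_site = num / den
    poly = (xa + xb > 0) & (xa + xb < na + nb) & (na >= 2) & (nb >= 2)
    per_site = np.where(poly & (den != 0), per_site, np.nan)
    use = ~np.isnan(per_site)
    overall = float(num[use].sum() / den[use].sum()) if use.any() else float("nan")
    return per_site, overall
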