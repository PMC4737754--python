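"""Synthetic data generator for every input the pipeline consumes.

The generator emulates, with known ground truth, the six input kinds of a
songbird resequencing-plus-methylome study: a diploid genotype panel with
outgroup alleles, gene annotation, two-tissue bisulfite methylation calls,
per-gene expression, codon alignments and a gene-to-term annotation map.

Genotypes use a haplotype-free neutral SFS sampler: the number of
segregating sites is Poisson with the coalescent expectation
E[S] = a1 * theta * L (a1 the harmonic number of 2n-1, so Watterson's
estimator is unbiased for theta) and each site's derived count is drawn
from the standard neutral spectrum P(j) proportional to 1/j. A sweep at a
chromosome position applies the hitchhiking escape operator to every site
within its footprint: each of the 2n lineages escapes with probability
p_e = 1 - exp(-alpha * d) at distance d; escapees recombine off the sweep
and retain their own pre-sweep allele, while all non-escapees descend from
the single sweeping haplotype and share one hitchhiking allele drawn
uniformly from the pre-sweep lineages. Small alpha means lineages rarely escape
even far from the swept site (a wide, strong footprint); the footprint is
applied out to d = 10/alpha, beyond which escape is essentially certain.
This is intentionally the same operator the sweep scanner's alternative
model uses, so scan results are a parameter-recovery self-consistency
check; ``mismatched_sweep`` mode breaks the symmetry by replacing part of
the footprint with fresh uniform singletons.

Methylation levels are Beta-distributed per site, depressed at CpG islands
around the TSS, with brain-only non-CpG methylation at low mean; sweep
genes are offset additively (+ for CpG, - for non-CpG, brain only). Read
depths are Poisson and methylated-read counts Binomial. Expression couples
negatively to gene-body methylation on the log2 scale. Codon alignments
evolve three taxa on a fixed two-branch topology under a counting-friendly
codon process with per-gene omega (nonsynonymous proposals accepted with
probability omega) and transition/transversion bias kappa.

All randomness flows through numpy Generators seeded as
``default_rng([rng_seed, stream])`` with a fixed stream id per output kind:
identical SimParams yield byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GeneModel
from .popgen import VariantTable

_STREAM_GENOTYPES = 1
_STREAM_GENES = 2
_STREAM_METHYLOME = 3
_STREAM_EXPRESSION = 4
_STREAM_ALIGNMENTS = 5
_STREAM_TERMS = 6

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass(frozen=True)
class SweepSpec:
    chrom: str
    center_bp: int
    alpha: float    # escape rate per bp; smaller = wider/stronger footprint

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("sweep alpha must be >= 0")


def _default_sweeps() -> list[SweepSpec]:
    return [SweepSpec("chr1", 500_000, 1e-4),
            SweepSpec("chr4", 250_000, 1e-4),
            SweepSpec("chr7", 750_000, 1e-4)]


@dataclass
class SimParams:
    n_individuals: int = 29
    n_chromosomes: int = 10
    chrom_length_bp: int = 1_000_000
    theta_per_bp: float = 0.004
    sweep_specs: list[SweepSpec] = field(default_factory=_default_sweeps)
    outgroup_divergence: float = 0.05
    n_outgroups: int = 2
    polarization_error: float = 0.01
    mismatched_sweep: bool = False
    mismatch_singleton_prob: float = 0.1
    # genes
    n_genes: int = 200
    n_scaffold_genes: int = 10
    gene_length_median_bp: int = 3_000
    gene_length_sigma: float = 0.4
    # methylome
    cpg_density: float = 0.02
    island_cpg_density: float = 1.0 / 15.0
    noncpg_density: float = 0.05
    island_upstream_bp: int = 300
    tss_dip: float = 0.15
    depth_mean: float = 30.0
    cpg_beta: tuple[float, float] = (10.0, 5.0)
    noncpg_brain_beta: tuple[float, float] = (28.5, 490.0)
    noncpg_blood_beta: tuple[float, float] = (0.5, 150.0)
    # per-gene methylation propensity (one latent factor shifts both
    # contexts), the source of between-gene variation that expression and
    # evolutionary rates couple to
    gene_meth_sd_cpg: float = 0.012
    gene_meth_sd_noncpg: float = 0.005
    sweep_gene_cpg_delta: float = 0.05
    sweep_gene_noncpg_delta: float = -0.02
    # expression
    expr_coupling: float = 25.0
    expr_noise_sd: float = 0.25
    expr_intercept: float = 6.0
    # codon alignments
    codon_len: int = 300
    kappa: float = 2.0
    ingroup_branch: float = 0.04   # attempted mutations per nt site
    outgroup_branch: float = 0.08
    omega_log_mean: float = float(np.log(0.15))
    omega_log_sigma: float = 0.6
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.theta_per_bp <= 0:
            raise ValueError("theta_per_bp must be positive")
        for delta in (self.sweep_gene_cpg_delta, self.sweep_gene_noncpg_delta):
            if not (-1.0 < delta < 1.0):
                raise ValueError("methylation deltas must lie in (-1, 1)")
        chroms = set(self.chromosome_names)
        for s in self.sweep_specs:
            if s.alpha > 0 and s.chrom not in chroms:
                raise ValueError(f"sweep on unknown chromosome {s.chrom!r}")

    @property
    def chromosome_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.rng_seed, stream])


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _neutral_counts(rng, n_hap: int, size: int) -> np.ndarray:
    j = np.arange(1, n_hap)
    w = 1.0 / j
    return rng.choice(j, size=size, p=w / w.sum())


def _carrier_matrix(rng, counts: np.ndarray, n_hap: int) -> np.ndarray:
    """Random assignment of `counts[i]` derived alleles over n_hap lineages."""
    keys = rng.random((counts.size, n_hap))
    order = np.argsort(keys, axis=1)
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(n_hap)[None, :], axis=1)
    return ranks < counts[:, None]


def simulate_genotypes(params: SimParams) -> tuple[VariantTable, dict]:
    """Neutral-SFS genotype panel with injected sweep footprints.

    Returns the variant table and a truth record with sweep locations, true
    ancestral bases and true derived counts (post-sweep, pre-polarization).
    """
    rng = params.rng(_STREAM_GENOTYPES)
    n_hap = 2 * params.n_individuals
    all_chrom, all_pos, all_H = [], [], []
    a1 = float(np.sum(1.0 / np.arange(1, n_hap)))
    for chrom in params.chromosome_names:
        L = params.chrom_length_bp
        S = rng.poisson(a1 * params.theta_per_bp * L)
        pos = np.sort(rng.choice(L, size=min(S, L), replace=False))
        j0 = _neutral_counts(rng, n_hap, pos.size)
        H = _carrier_matrix(rng, j0, n_hap)
        for sw in params.sweep_specs:
            if sw.chrom != chrom or sw.alpha == 0:
                continue
            d = np.abs(pos - sw.center_bp).astype(float)
            aff = np.flatnonzero(d < 10.0 / sw.alpha)
            if aff.size == 0:
                continue
            p_e = -np.expm1(-sw.alpha * d[aff])
            esc = rng.random((aff.size, n_hap)) < p_e[:, None]
            # sweeping haplotype: one random non-escaping pre-sweep lineage
            keys = np.where(esc, -1.0, rng.random((aff.size, n_hap)))
            src = np.argmax(keys, axis=1)
            hitch = H[aff, src]
            all_escaped = esc.all(axis=1)
            H[aff] = np.where(esc | all_escaped[:, None], H[aff],
                              hitch[:, None])
            if params.mismatched_sweep:
                new = np.flatnonzero(
                    rng.random(aff.size) < params.mismatch_singleton_prob)
                for i in new:     # fresh post-sweep mutation: uniform singleton
                    row = np.zeros(n_hap, dtype=bool)
                    row[rng.integers(n_hap)] = True
                    H[aff[i]] = row
        seg = (H.sum(axis=1) >= 1) & (H.sum(axis=1) <= n_hap - 1)
        all_chrom.append(np.full(int(seg.sum()), chrom, dtype=object))
        all_pos.append(pos[seg])
        all_H.append(H[seg])

    chrom = np.concatenate(all_chrom)
    pos = np.concatenate(all_pos)
    H = np.concatenate(all_H, axis=0)
    S = pos.size
    derived = H.sum(axis=1).astype(np.int64)
    derived_geno = (H[:, 0::2].astype(np.int8) + H[:, 1::2].astype(np.int8))

    anc_idx = rng.integers(0, 4, size=S)
    der_idx = (anc_idx + rng.integers(1, 4, size=S)) % 4
    anc, der = _BASES[anc_idx], _BASES[der_idx]
    ref_is_anc = rng.random(S) < 0.5
    ref = np.where(ref_is_anc, anc, der)
    alt = np.where(ref_is_anc, der, anc)
    genotypes = np.where(ref_is_anc[:, None], derived_geno, 2 - derived_geno)

    outgroups = np.empty((S, params.n_outgroups), dtype="<U1")
    for k in range(params.n_outgroups):
        base = anc.copy()
        div = rng.random(S) < params.outgroup_divergence
        other = _BASES[(anc_idx + rng.integers(1, 4, size=S)) % 4]
        base = np.where(div, other, base)
        err = rng.random(S) < params.polarization_error
        outgroups[:, k] = np.where(err, der, base)

    vt = VariantTable(
        chrom=chrom, pos=pos, ref=ref, alt=alt,
        genotypes=genotypes.astype(np.int8), outgroup_alleles=outgroups,
        samples=[f"ind{i + 1:02d}" for i in range(params.n_individuals)],
        outgroup_names=[f"outgroup{k + 1}" for k in range(params.n_outgroups)])
    truth = {
        "sweeps": [(s.chrom, s.center_bp, s.alpha) for s in params.sweep_specs],
        "chrom_lengths": {c: params.chrom_length_bp
                          for c in params.chromosome_names},
        "ancestral": anc, "derived_count": derived,
    }
    return vt, truth


# ---------------------------------------------------------------------------
# genes
# ---------------------------------------------------------------------------

def simulate_genes(params: SimParams) -> list[GeneModel]:
    """Non-overlapping gene models spread over the chromosomes, plus a few
    genes on unplaced scaffolds (placed=False)."""
    rng = params.rng(_STREAM_GENES)
    margin = 11_000    # room for flanks and the TSS window
    genes: list[GeneModel] = []
    per = np.full(params.n_chromosomes, params.n_genes // params.n_chromosomes)
    per[: params.n_genes % params.n_chromosomes] += 1
    gid = 0
    for chrom, k in zip(params.chromosome_names, per):
        if k == 0:
            continue
        usable = params.chrom_length_bp - 2 * margin
        slot = usable / k
        for s in range(k):
            length = int(np.clip(
                rng.lognormal(np.log(params.gene_length_median_bp),
                              params.gene_length_sigma),
                600, max(600, slot - 500)))
            lo = margin + int(s * slot)
            start = int(lo + rng.integers(0, max(1, int(slot) - length - 200)))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"g{gid:04d}", chrom, start, start + length,
                                   strand, placed=True))
            gid += 1
    for j in range(params.n_scaffold_genes):
        length = int(np.clip(
            rng.lognormal(np.log(params.gene_length_median_bp),
                          params.gene_length_sigma), 600, 20_000))
        start = margin + int(rng.integers(0, 5_000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"g{gid:04d}", f"scaffold_{j + 1}",
                               start, start + length, strand, placed=False))
        gid += 1
    return genes


def genes_near_sweeps(genes: list[GeneModel], truth: dict,
                      within_bp: int = 25_000) -> list[str]:
    """Gene ids whose span lies within ``within_bp`` of a true sweep center."""
    out = []
    for g in genes:
        for chrom, center, alpha in truth["sweeps"]:
            if alpha > 0 and g.chrom == chrom \
                    and g.start - within_bp <= center < g.end + within_bp:
                out.append(g.gene_id)
                break
    return out


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------

def _positions(rng, start: int, end: int, density: float) -> np.ndarray:
    n = rng.poisson(max(0, end - start) * density)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    return np.unique(rng.integers(start, end, size=n))


def simulate_methylome(params: SimParams, genes: list[GeneModel],
                       sweep_gene_ids: set[str] | list[str]
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-tissue methylation call table plus per-gene baselines.

    Returns ``(sites, gene_info)``: ``sites`` is the wide per-site table;
    ``gene_info`` has one row per gene with the latent methylation
    propensity and the constitutive (baseline, pre-sweep-offset) mean body
    methylation that the expression generator couples to.

    Sites are generated across each gene's territory (gene span plus 10 kb
    flanks and the TSS window): CpG sites at ``cpg_density``, denser inside
    the CpG island, and non-CpG sites at a sampled subset density. The CpG
    island is the TSS-proximal compartment: it reaches
    ``island_upstream_bp`` upstream of the TSS and covers exactly the
    5'-most 5% of the gene that the body definition excludes, so island and
    body never overlap. Methylation inside the island is multiplied by
    ``tss_dip`` (the TSS dip) and the sweep offsets do not apply there; on
    every body and flank site of a sweep gene the configured additive
    offsets are planted on brain levels (CpG up, non-CpG down).
    """
    rng = params.rng(_STREAM_METHYLOME)
    sweep_gene_ids = set(sweep_gene_ids)
    frames = []
    gene_rows = []
    cpg_mean = params.cpg_beta[0] / sum(params.cpg_beta)
    for gene in genes:
        terr_lo = max(0, gene.start - 11_000)
        terr_hi = gene.end + 11_000
        trim = int(round(0.05 * len(gene)))
        if gene.strand == "+":
            isl_lo = gene.start - params.island_upstream_bp
            isl_hi = gene.start + trim
        else:
            isl_lo = gene.end - trim
            isl_hi = gene.end + params.island_upstream_bp
        cpg = np.concatenate([
            _positions(rng, terr_lo, terr_hi, params.cpg_density),
            _positions(rng, max(terr_lo, isl_lo), min(terr_hi, isl_hi),
                       params.island_cpg_density)])
        cpg = np.unique(cpg)
        nonc = _positions(rng, terr_lo, terr_hi, params.noncpg_density)
        is_sweep = gene.gene_id in sweep_gene_ids
        propensity = rng.normal()     # latent per-gene methylation factor
        gene_rows.append({
            "gene_id": gene.gene_id, "propensity": propensity,
            "mean_level": cpg_mean + params.gene_meth_sd_cpg * propensity,
            "sweep": is_sweep})
        for context, positions in (("CpG", cpg), ("nonCpG", nonc)):
            if positions.size == 0:
                continue
            in_island = (positions >= isl_lo) & (positions < isl_hi)
            if context == "CpG":
                shift = params.gene_meth_sd_cpg * propensity
                brain = rng.beta(*params.cpg_beta, size=positions.size) + shift
                blood = rng.beta(*params.cpg_beta, size=positions.size) + shift
                delta = params.sweep_gene_cpg_delta if is_sweep else 0.0
            else:
                shift = params.gene_meth_sd_noncpg * propensity
                brain = rng.beta(*params.noncpg_brain_beta,
                                 size=positions.size) + shift
                blood = rng.beta(*params.noncpg_blood_beta,
                                 size=positions.size)
                delta = params.sweep_gene_noncpg_delta if is_sweep else 0.0
            brain = np.clip(brain, 0.0, 1.0)
            blood = np.clip(blood, 0.0, 1.0)
            brain = np.where(in_island, brain * params.tss_dip,
                             np.clip(brain + delta, 0.0, 1.0))
            blood = np.where(in_island, blood * params.tss_dip, blood)
            depth_brain = np.maximum(1, rng.poisson(params.depth_mean,
                                                    positions.size))
            depth_blood = np.maximum(1, rng.poisson(params.depth_mean,
                                                    positions.size))
            frames.append(pd.DataFrame({
                "chrom": gene.chrom, "pos": positions,
                "strand": np.where(rng.random(positions.size) < 0.5, "+", "-"),
                "context": context,
                "meth_brain": rng.binomial(depth_brain, brain),
                "total_brain": depth_brain,
                "meth_blood": rng.binomial(depth_blood, blood),
                "total_blood": depth_blood,
            }))
    wide = pd.concat(frames, ignore_index=True)
    wide = wide.drop_duplicates(["chrom", "pos", "context"], keep="first")
    wide = wide.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return wide, pd.DataFrame(gene_rows)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(params: SimParams,
                        body_methylation: pd.DataFrame) -> pd.DataFrame:
    """Per-gene FPKM coupled negatively to gene-body methylation.

    ``body_methylation`` needs columns gene_id and mean_level;
    log2 FPKM = intercept - expr_coupling * level + Gaussian noise.

    For the study-condition simulation pass the ``gene_info`` table from
    :func:`simulate_methylome` (the constitutive, pre-sweep-offset levels):
    expression reflects a gene's baseline methylation state, and the
    sweep-associated offsets are independent of expression -- matching the
    observation that the sweep methylation contrast is not a by-product of
    expression differences.
    """
    rng = params.rng(_STREAM_EXPRESSION)
    level = body_methylation["mean_level"].to_numpy(dtype=float)
    log2 = (params.expr_intercept - params.expr_coupling * level
            + rng.normal(0.0, params.expr_noise_sd, size=level.size))
    return pd.DataFrame({"gene_id": body_methylation["gene_id"].to_numpy(),
                         "fpkm": np.exp2(log2)})


# ---------------------------------------------------------------------------
# codon alignments
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}
_SENSE = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
          if a + b + c not in _STOPS]

from Bio.Data import CodonTable as _CT  # noqa: E402
_AA = _CT.unambiguous_dna_by_id[1].forward_table


def _evolve(seq: list[str], t: float, omega: float, kappa: float, rng) -> list[str]:
    seq = list(seq)
    L = len(seq)
    n_events = rng.poisson(L * t)
    for _ in range(n_events):
        i = int(rng.integers(L))
        base = seq[i]
        others = [b for b in "ACGT" if b != base]
        w = np.array([kappa if b == _TRANSITION[base] else 1.0 for b in others])
        new = others[int(rng.choice(3, p=w / w.sum()))]
        c0 = 3 * (i // 3)
        codon = seq[c0:c0 + 3]
        mut = codon.copy()
        mut[i % 3] = new
        mut_s = "".join(mut)
        if mut_s in _STOPS:
            continue
        if _AA["".join(codon)] != _AA[mut_s] and rng.random() >= omega:
            continue
        seq[i] = new
    return seq


def simulate_codon_alignments(params: SimParams,
                              gene_ids: list[str] | None = None,
                              omegas: dict[str, float] | None = None
                              ) -> tuple[dict[str, dict[str, str]],
                                         dict[str, float]]:
    """Triplet codon alignments evolved under per-gene omega.

    Three taxa (focal, sister, outgroup) descend from a common root: the
    ingroup pair diverges by two ``ingroup_branch`` branches, the outgroup
    by ``outgroup_branch``. Returns (alignments, true omega per gene).
    """
    rng = params.rng(_STREAM_ALIGNMENTS)
    if gene_ids is None:
        gene_ids = [f"g{i:04d}" for i in range(params.n_genes)]
    if omegas is None:
        omegas = {g: float(np.clip(
            rng.lognormal(params.omega_log_mean, params.omega_log_sigma),
            0.01, 1.5)) for g in gene_ids}
    alignments = {}
    for g in gene_ids:
        root: list[str] = []
        for _ in range(params.codon_len):
            root.extend(_SENSE[int(rng.integers(len(_SENSE)))])
        w = omegas[g]
        anc = _evolve(root, params.outgroup_branch / 2.0, w, params.kappa, rng)
        alignments[g] = {
            "focal": "".join(_evolve(anc, params.ingroup_branch, w,
                                     params.kappa, rng)),
            "sister": "".join(_evolve(anc, params.ingroup_branch, w,
                                      params.kappa, rng)),
            "outgroup": "".join(_evolve(root, params.outgroup_branch / 2.0, w,
                                        params.kappa, rng)),
        }
    return alignments, dict(omegas)


# ---------------------------------------------------------------------------
# term map
# ---------------------------------------------------------------------------

def simulate_term_map(params: SimParams, genes: list[GeneModel],
                      planted_gene_ids: set[str] | list[str],
                      n_terms: int = 40,
                      planted_prevalence_in: float = 0.5,
                      planted_prevalence_bg: float = 0.05):
    """Gene-to-term map with one term enriched in the planted gene set.

    Background terms get uniform prevalences in [0.02, 0.12]; the planted
    term ("T_planted") is carried by planted genes with probability
    ``planted_prevalence_in`` and by everything else with
    ``planted_prevalence_bg``.
    """
    from .enrichment import TermMap

    rng = params.rng(_STREAM_TERMS)
    planted_gene_ids = set(planted_gene_ids)
    prevalence = rng.uniform(0.02, 0.12, size=n_terms)
    gene_terms: dict[str, set[str]] = {}
    for gene in genes:
        terms = {f"T{t:02d}" for t in range(n_terms)
                 if rng.random() < prevalence[t]}
        p = planted_prevalence_in if gene.gene_id in planted_gene_ids \
            else planted_prevalence_bg
        if rng.random() < p:
            terms.add("T_planted")
        gene_terms[gene.gene_id] = terms
    labels = {f"T{t:02d}": f"background term {t}" for t in range(n_terms)}
    labels["T_planted"] = "planted enriched term"
    return TermMap(gene_terms, labels)
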