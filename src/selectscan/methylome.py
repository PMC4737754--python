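"""Bisulfite methylation analysis: site filtering, gene-anchored regions,
metagene profiles, correlations with expression and evolutionary rates, and
sweep versus non-sweep contrasts.

Sites are whole-genome bisulfite calls (CpG or non-CpG context) with read
counts for two tissues; every analysis uses only sites covered by at least
``min_site_reads`` reads in BOTH tissues. Gene regions follow the published
definitions: the gene body is the annotated span minus its 5'-most 5%, the
TSS window runs 300 bp upstream to 50 bp downstream of the annotated start,
and flanks are 10 kb on either side of the body -- all computed in
transcript orientation and mapped back to genome coordinates. Region means
are reported only when at least half of the potential methylation sites in
the region are covered (TSS windows additionally need 10 covered sites).

The metagene profile subdivides each gene body into 40 length-proportional
bins whose cores are extended 125 bp each way (the 250 bp bin overlap),
plus 79 fixed 250 bp bins advancing by 125 bp across each 10 kb flank.
Sweep/non-sweep contrasts use an equal-variance t-test at the TSS and a
random-intercept linear mixed model (bin as the random factor, sweep status
as the fixed effect, ML fit, chi-square likelihood-ratio test) on bin-level
means elsewhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr, ttest_ind

from .config import RunConfig
from .genome import GeneModel, GenomicInterval
from .lmm import RandomInterceptFit, lrt_fixed_effect

logger = logging.getLogger(__name__)

CONTEXTS = ("CpG", "nonCpG")


# ---------------------------------------------------------------------------
# site tables
# ---------------------------------------------------------------------------

def pivot_tissues(long_df: pd.DataFrame) -> pd.DataFrame:
    """Long per-(site, tissue) calls -> one row per site with per-tissue counts.

    Expects columns chrom, pos, strand, context, tissue, meth_reads,
    total_reads (0-based positions, as produced by the I/O layer).
    """
    wide = long_df.pivot_table(
        index=["chrom", "pos", "strand", "context"],
        columns="tissue", values=["meth_reads", "total_reads"],
        aggfunc="first")
    wide.columns = [f"{a.removesuffix('_reads')}_{b}" for a, b in wide.columns]
    out = wide.reset_index().sort_values(["chrom", "pos"], kind="stable")
    return out.reset_index(drop=True)


def tissues_of(wide: pd.DataFrame) -> list[str]:
    return sorted(c.removeprefix("total_") for c in wide.columns
                  if c.startswith("total_"))


def filter_sites(wide: pd.DataFrame, min_reads: int = 10) -> pd.DataFrame:
    """Keep sites with >= min_reads total reads in every tissue (inclusive)."""
    mask = np.ones(len(wide), dtype=bool)
    for t in tissues_of(wide):
        mask &= wide[f"total_{t}"].fillna(0).to_numpy() >= min_reads
    out = wide[mask].reset_index(drop=True)
    logger.info("filter=min_site_reads input=%d surviving=%d", len(wide), len(out))
    return out


def site_levels(wide: pd.DataFrame, tissue: str) -> np.ndarray:
    return (wide[f"meth_{tissue}"] / wide[f"total_{tissue}"]).to_numpy()


# ---------------------------------------------------------------------------
# region definitions
# ---------------------------------------------------------------------------

@dataclass
class GeneRegions:
    gene_id: str
    tss: GenomicInterval
    body: GenomicInterval
    up10k: GenomicInterval | None
    down10k: GenomicInterval | None
    truncated: frozenset[str]

    def items(self):
        for name in ("tss", "body", "up10k", "down10k"):
            iv = getattr(self, name)
            if iv is not None:
                yield name, iv


def define_regions(gene: GeneModel, cfg: RunConfig = RunConfig(),
                   chrom_length: int | None = None) -> GeneRegions:
    """TSS window, trimmed gene body and 10 kb flanks for one gene."""
    if len(gene) < 20:
        raise ValueError(f"gene {gene.gene_id} shorter than 20 bp")
    trim = int(round(0.05 * len(gene)))
    up, down = cfg.tss_upstream_bp, cfg.tss_downstream_bp
    span = cfg.flank_span_bp
    if gene.strand == "+":
        body = (gene.start + trim, gene.end)
        tss = (gene.start - up, gene.start + down)
        up10k = (body[0] - span, body[0])
        down10k = (body[1], body[1] + span)
    else:
        body = (gene.start, gene.end - trim)
        tss = (gene.end - down, gene.end + up)
        up10k = (body[1], body[1] + span)
        down10k = (body[0] - span, body[0])

    truncated = set()

    def clamp(name, iv):
        s, e = iv
        cs = max(0, s)
        ce = e if chrom_length is None else min(e, chrom_length)
        if (cs, ce) != (s, e):
            truncated.add(name)
        if cs >= ce:
            return None
        return GenomicInterval(gene.chrom, cs, ce, gene.strand)

    tss_iv = clamp("tss", tss)
    body_iv = clamp("body", body)
    if tss_iv is None or body_iv is None:
        raise ValueError(f"gene {gene.gene_id}: TSS or body fell off the chromosome")
    return GeneRegions(gene.gene_id, tss_iv, body_iv,
                       clamp("up10k", up10k), clamp("down10k", down10k),
                       frozenset(truncated))


# ---------------------------------------------------------------------------
# region means
# ---------------------------------------------------------------------------

def _per_chrom_index(wide: pd.DataFrame, context: str, tissue: str,
                     min_reads: int):
    """chrom -> (all positions, covered mask, level-at-covered) for a context."""
    sub = wide[wide["context"] == context]
    out = {}
    for chrom, grp in sub.groupby("chrom", sort=False):
        grp = grp.sort_values("pos", kind="stable")
        pos = grp["pos"].to_numpy()
        covered = np.ones(len(grp), dtype=bool)
        for t in tissues_of(wide):
            covered &= grp[f"total_{t}"].fillna(0).to_numpy() >= min_reads
        with np.errstate(invalid="ignore", divide="ignore"):
            lev = (grp[f"meth_{tissue}"] / grp[f"total_{tissue}"]).to_numpy()
        out[chrom] = (pos, covered, lev)
    return out


def region_methylation(wide: pd.DataFrame, genes: list[GeneModel],
                       context: str, tissue: str,
                       cfg: RunConfig = RunConfig(),
                       chrom_lengths: dict[str, int] | None = None
                       ) -> pd.DataFrame:
    """Per-gene, per-region mean methylation with coverage bookkeeping.

    ``wide`` is the UNfiltered site table: the potential-site denominator is
    every reported context position in the region, while the mean uses only
    sites passing the coverage filter in all tissues. Rows failing the
    50%-of-potential-sites rule (or the 10-covered-site TSS rule) are
    suppressed and counted in the log.
    """
    index = _per_chrom_index(wide, context, tissue, cfg.min_site_reads)
    rows, suppressed = [], 0
    for gene in genes:
        if gene.chrom not in index:
            continue
        pos, covered, lev = index[gene.chrom]
        L = None if chrom_lengths is None else chrom_lengths.get(gene.chrom)
        regions = define_regions(gene, cfg, chrom_length=L)
        for name, iv in regions.items():
            lo, hi = np.searchsorted(pos, [iv.start, iv.end])
            n_potential = int(hi - lo)
            cov = covered[lo:hi]
            n_covered = int(cov.sum())
            if n_potential == 0:
                suppressed += 1
                continue
            if n_covered / n_potential < cfg.min_region_site_fraction:
                suppressed += 1
                continue
            if name == "tss" and n_covered < cfg.min_tss_sites:
                suppressed += 1
                continue
            rows.append({
                "gene_id": gene.gene_id, "region": name, "context": context,
                "mean_level": float(np.nanmean(lev[lo:hi][cov])),
                "n_covered_sites": n_covered,
                "n_potential_sites": n_potential,
                "placed": gene.placed,
            })
    logger.info("filter=region_site_fraction suppressed=%d emitted=%d",
                suppressed, len(rows))
    return pd.DataFrame(rows, columns=[
        "gene_id", "region", "context", "mean_level",
        "n_covered_sites", "n_potential_sites", "placed"])


# ---------------------------------------------------------------------------
# metagene profile
# ---------------------------------------------------------------------------

def n_flank_bins(cfg: RunConfig = RunConfig()) -> int:
    return (cfg.flank_span_bp - cfg.flank_bin_bp) // cfg.flank_bin_overlap_bp + 1


def _bin_edges(L: float, cfg: RunConfig) -> tuple[np.ndarray, np.ndarray]:
    """(starts, ends) of all bins on the transcript axis; 0 = body start."""
    F = n_flank_bins(cfg)
    half = cfg.body_bin_overlap_bp / 2.0
    up_s = -cfg.flank_span_bp + np.arange(F) * cfg.flank_bin_overlap_bp
    up_e = up_s + cfg.flank_bin_bp
    cores = np.arange(cfg.body_bins + 1) * (L / cfg.body_bins)
    body_s = np.maximum(cores[:-1] - half, 0.0)
    body_e = np.minimum(cores[1:] + half, L)
    down_s = L + np.arange(F) * cfg.flank_bin_overlap_bp
    down_e = down_s + cfg.flank_bin_bp
    return (np.concatenate([up_s, body_s, down_s]),
            np.concatenate([up_e, body_e, down_e]))


def bin_labels(cfg: RunConfig = RunConfig()) -> list[str]:
    F = n_flank_bins(cfg)
    return ([f"up{F - i:03d}" for i in range(F)]
            + [f"body{i:02d}" for i in range(cfg.body_bins)]
            + [f"down{i + 1:03d}" for i in range(F)])


def metagene_profile(genes: list[GeneModel], filtered: pd.DataFrame,
                     context: str, tissue: str,
                     cfg: RunConfig = RunConfig()) -> dict:
    """Per-gene metagene matrix plus the group mean curve and variance band.

    ``filtered`` must already have passed :func:`filter_sites`. Bins are
    ordered 5'->3' in transcript orientation: upstream flank, 40 body bins,
    downstream flank. A site inside two overlapping bins contributes to
    both; empty bins are NaN and the group statistics ignore them
    (mean/variance across genes).
    """
    sub = filtered[filtered["context"] == context]
    by_chrom = {}
    for chrom, grp in sub.groupby("chrom", sort=False):
        grp = grp.sort_values("pos", kind="stable")
        by_chrom[chrom] = (grp["pos"].to_numpy(),
                           (grp[f"meth_{tissue}"] / grp[f"total_{tissue}"]).to_numpy())
    F = n_flank_bins(cfg)
    nbins = 2 * F + cfg.body_bins
    mat = np.full((len(genes), nbins), np.nan)
    for gi, gene in enumerate(genes):
        if len(gene) < cfg.body_bins or gene.chrom not in by_chrom:
            continue
        pos, lev = by_chrom[gene.chrom]
        regions = define_regions(gene, cfg)
        body = regions.body
        # transcript-axis coordinate of each site (0 at body 5' end)
        if gene.strand == "+":
            t = pos - body.start
        else:
            t = (body.end - 1) - pos
        in_range = (t >= -cfg.flank_span_bp) & (t < len(body) + cfg.flank_span_bp)
        tt, ll = t[in_range], lev[in_range]
        order = np.argsort(tt, kind="stable")
        tt, ll = tt[order], ll[order]
        prefix = np.concatenate([[0.0], np.cumsum(ll)])
        starts, ends = _bin_edges(float(len(body)), cfg)
        si = np.searchsorted(tt, starts, side="left")
        ei = np.searchsorted(tt, ends, side="left")
        cnt = ei - si
        with np.errstate(invalid="ignore"):
            means = np.where(cnt > 0, (prefix[ei] - prefix[si]) / cnt, np.nan)
        mat[gi] = means
    with np.errstate(invalid="ignore"):
        group_mean = np.nanmean(mat, axis=0)
        group_var = np.nanvar(mat, axis=0, ddof=1)
    return {"matrix": mat, "labels": bin_labels(cfg),
            "gene_ids": [g.gene_id for g in genes],
            "group_mean": group_mean, "group_var": group_var}


def body_bin_table(genes: list[GeneModel], filtered: pd.DataFrame,
                   context: str, tissue: str, sweep_gene_ids: set[str],
                   cfg: RunConfig = RunConfig(),
                   include_unplaced: bool = False) -> pd.DataFrame:
    """Long (gene, bin, level, sweep) table of body-bin means for the LMM.

    Non-sweep genes on unplaced scaffolds are excluded by default because
    scaffolds are never scanned for sweeps.
    """
    use = [g for g in genes
           if include_unplaced or g.placed or g.gene_id in sweep_gene_ids]
    prof = metagene_profile(use, filtered, context, tissue, cfg)
    F = n_flank_bins(cfg)
    body = prof["matrix"][:, F:F + cfg.body_bins]
    rows = []
    for gi, gene in enumerate(use):
        for b in range(cfg.body_bins):
            v = body[gi, b]
            if np.isnan(v):
                continue
            rows.append({"gene_id": gene.gene_id, "bin": b, "level": v,
                         "sweep": gene.gene_id in sweep_gene_ids})
    return pd.DataFrame(rows, columns=["gene_id", "bin", "level", "sweep"])


# ---------------------------------------------------------------------------
# contrasts and correlations
# ---------------------------------------------------------------------------

def sweep_methylation_lmm(bin_table: pd.DataFrame
                          ) -> tuple[float, float, float, RandomInterceptFit]:
    """LMM contrast of sweep vs non-sweep methylation across bins.

    Model: level ~ 1 + sweep with a random intercept per bin, ML fit;
    returns (beta_sweep, LRT statistic, chi2_1 p-value, full fit).
    """
    if bin_table["bin"].nunique() < 2:
        raise ValueError("need at least 2 bins")
    if bin_table["sweep"].nunique() < 2:
        raise ValueError("need both sweep classes")
    y = bin_table["level"].to_numpy(dtype=float)
    sweep = bin_table["sweep"].to_numpy(dtype=float)
    X_full = np.column_stack([np.ones_like(y), sweep])
    X_null = np.ones((y.size, 1))
    fit, stat, p = lrt_fixed_effect(y, X_full, X_null,
                                    bin_table["bin"].to_numpy())
    return float(fit.beta[1]), stat, p, fit


def tss_ttest(tss_sweep, tss_non_sweep) -> tuple[float, float]:
    """Two-sided pooled-variance t-test on per-gene TSS methylation means."""
    res = ttest_ind(np.asarray(tss_sweep, dtype=float),
                    np.asarray(tss_non_sweep, dtype=float), equal_var=True)
    return float(res.statistic), float(res.pvalue)


def methylation_expression_corr(region_meth: pd.DataFrame,
                                expression: pd.DataFrame
                                ) -> tuple[float, float]:
    """Spearman correlation of per-gene region methylation with expression.

    ``region_meth`` is one region x context slice of
    :func:`region_methylation` output; ``expression`` has columns gene_id
    and fpkm. Ties get average ranks; the p-value uses the t approximation.
    """
    merged = region_meth.merge(expression, on="gene_id")
    if len(merged) < 3:
        raise ValueError("need at least 3 genes for a correlation")
    rho, p = spearmanr(merged["mean_level"], merged["fpkm"])
    return float(rho), float(p)


def quartile_rate_test(region_meth: pd.DataFrame,
                       omegas: dict[str, float]
                       ) -> tuple[float, float, float, float]:
    """Evolutionary-rate contrast between methylation quartiles.

    Upper (highly methylated) versus lower quartile of per-gene region
    means, compared on omega with the Mann-Whitney U-test. Returns
    (median_omega_high, median_omega_low, U, p).
    """
    from .molevol import rate_contrast

    merged = region_meth[region_meth["gene_id"].isin(omegas)].copy()
    merged["omega"] = merged["gene_id"].map(omegas)
    merged = merged.dropna(subset=["omega"])
    if len(merged) < 8:
        raise ValueError("need at least 8 genes to form quartiles")
    lo_q, hi_q = np.quantile(merged["mean_level"], [0.25, 0.75])
    high = merged.loc[merged["mean_level"] >= hi_q, "omega"].to_numpy()
    low = merged.loc[merged["mean_level"] <= lo_q, "omega"].to_numpy()
    med_hi, med_lo, U, p = rate_contrast(high, low)
    return med_hi, med_lo, U, p


def expression_tercile(expression: pd.DataFrame) -> pd.Series:
    """Label each gene 0/1/2 by expression tercile (gene_id-indexed)."""
    fpkm = expression.set_index("gene_id")["fpkm"]
    ranks = fpkm.rank(method="first")
    return pd.cut(ranks, bins=3, labels=False).astype(int)
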