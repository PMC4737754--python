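"""Independent brute-force oracles shared by the unit and acceptance tests.

Everything here is deliberately written from first principles (math.comb,
explicit loops, dense matrices) so that agreement with the vectorized
implementations is an informative check, not a tautology.
"""

import itertools
import math


# ---------------------------------------------------------------------------
# sweep likelihood by exhaustive summation
# ---------------------------------------------------------------------------

def sweep_site_distribution(d, alpha, phi, n):
    """P(count | polymorphic) by full enumeration over the pre-sweep count
    j', the escapee number k and the escapee derived count."""
    p_e = 1.0 - math.exp(-alpha * max(d, 1.0))
    mass = [0.0] * (n + 1)
    for jp in range(1, n):
        w_j = phi[jp - 1]
        for k in range(n + 1):
            w_k = math.comb(n, k) * p_e**k * (1 - p_e)**(n - k)
            if k == n:
                mass[jp] += w_j * w_k
                continue
            for x in range(max(0, k - (n - jp)), min(jp, k) + 1):
                hg = (math.comb(jp, x) * math.comb(n - jp, k - x)
                      / math.comb(n, k))
                p_src = (jp - x) / (n - k)
                mass[x] += w_j * w_k * hg * (1 - p_src)
                mass[x + n - k] += w_j * w_k * hg * p_src
    interior = mass[1:n]
    total = sum(interior)
    return [m / total for m in interior]


def sweep_loglik(alpha, sites, phi, n):
    """sites: iterable of (distance, count, folded)."""
    ll = 0.0
    for d, count, folded in sites:
        p = sweep_site_distribution(d, alpha, phi, n)
        if folded:
            m = count
            pr = p[m - 1] + (p[n - m - 1] if m != n - m else 0.0)
        else:
            pr = p[count - 1]
        ll += math.log(pr)
    return ll


# ---------------------------------------------------------------------------
# interval post-processing
# ---------------------------------------------------------------------------

def naive_merge(rows, grid, max_gap=1):
    """rows: (chrom, grid_pos, clr) triples -> (chrom, start, end, sum, k)."""
    rows = sorted(rows, key=lambda r: (r[0], r[1]))
    regions = []
    for chrom, pos, clr in rows:
        if regions and regions[-1][0] == chrom \
                and pos - regions[-1][2] <= max_gap * grid:
            regions[-1][2] = pos
            regions[-1][3] += clr
            regions[-1][4] += 1
        else:
            regions.append([chrom, pos, pos, clr, 1])
    return [(c, s, e + grid, score, k) for c, s, e, score, k in regions]


def naive_associate(regions, genes, flank, min_region, top_fraction):
    """Gene scores and the selected top set by explicit loops."""
    scored = {}
    for gene in genes:
        best, hits = None, 0
        for chrom, s, e, score, _ in regions:
            if e - s <= min_region or chrom != gene.chrom:
                continue
            if gene.start < e + flank and s - flank < gene.end:
                hits += 1
                best = score if best is None else max(best, score)
        if best is not None:
            scored[gene.gene_id] = (best, hits)
    k = max(1, math.ceil(top_fraction * len(genes)))
    ranked = sorted(scored.items(), key=lambda kv: -kv[1][0])
    if not ranked:
        return scored, set()
    if len(ranked) <= k:
        return scored, {g for g, _ in ranked}
    cutoff = ranked[k - 1][1][0]
    return scored, {g for g, (sc, _) in ranked if sc >= cutoff}


# ---------------------------------------------------------------------------
# classic statistics
# ---------------------------------------------------------------------------

def tajima_d_from_haplotypes(hap):
    """hap: list of S lists over n haplotypes (0/1)."""
    S = len(hap)
    n = len(hap[0])
    diffs = 0
    for i in range(n):
        for j in range(i + 1, n):
            diffs += sum(1 for s in range(S) if hap[s][i] != hap[s][j])
    pi = diffs / (n * (n - 1) / 2)
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1, e2 = c1 / a1, c2 / (a1**2 + a2)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1)), pi


def hypergeom_two_sided(k, K, n, N):
    def pmf(x):
        if x < max(0, n - (N - K)) or x > min(K, n):
            return 0.0
        return (math.comb(K, x) * math.comb(N - K, n - x)) / math.comb(N, n)

    pk = pmf(k)
    return min(1.0, sum(pmf(x) for x in range(0, n + 1)
                        if pmf(x) <= pk * (1 + 1e-9)))


def holm_stepdown(p_values):
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    out = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, p_values[i] * (m - rank))
        out[i] = min(running, 1.0)
    return out


def bh_stepup(p_values):
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    out = [0.0] * m
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, p_values[i] * m / (rank + 1))
        out[i] = running
    return out


def ng86_path_counts(a, b, translate):
    """Average pathway (syn, nonsyn) differences; None if all blocked."""
    stops = {"TAA", "TAG", "TGA"}
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return (0.0, 0.0)
    paths = []
    for order in itertools.permutations(diff):
        cur, s, ns, ok = a, 0, 0, True
        for i in order:
            nxt = cur[:i] + b[i] + cur[i + 1:]
            if nxt in stops:
                ok = False
                break
            if translate(cur) == translate(nxt):
                s += 1
            else:
                ns += 1
            cur = nxt
        if ok:
            paths.append((s, ns))
    if not paths:
        return None
    return (sum(p[0] for p in paths) / len(paths),
            sum(p[1] for p in paths) / len(paths))


def ng86_site_counts(codon, translate):
    """(syn, nonsyn) sites; mutations to stops count as nonsynonymous."""
    stops = {"TAA", "TAG", "TGA"}
    syn = 0
    for i in range(3):
        for b in "ACGT":
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1:]
            if mut not in stops and translate(mut) == translate(codon):
                syn += 1
    return syn / 3.0, 3.0 - syn / 3.0
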