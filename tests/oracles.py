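"""Independent, deliberately naive reference implementations used as
oracles by the test suite.  Everything here is written with explicit
loops over brute-force enumerations, sharing no code with the package's
vectorized implementations."""

from __future__ import annotations

import numpy as np

MISSING = -1


# ---------------------------------------------------------------------------
# sliding-window ROH oracle: explicit window enumeration
# ---------------------------------------------------------------------------

def sliding_runs_naive(g, pos, params):
    """All runs on one chromosome for one animal, per the sliding-window
    definition, via explicit enumeration.  Returns [(start_i, end_i)] SNP
    index pairs."""
    n = len(g)
    W = params.window_snps
    if n < W:
        return []
    windows = []
    for w in range(n - W + 1):
        win = g[w:w + W]
        n_het = sum(1 for x in win if x == 1)
        n_mis = sum(1 for x in win if x == MISSING)
        windows.append(n_het <= params.max_het and n_mis <= params.max_missing)
    candidate = []
    for i in range(n):
        covering = [w for w in range(len(windows)) if w <= i <= w + W - 1]
        hits = sum(1 for w in covering if windows[w])
        candidate.append(hits / len(covering) >= params.window_hit_proportion)
    # maximal candidate stretches, split at big gaps
    segments = []
    i = 0
    while i < n:
        if not candidate[i]:
            i += 1
            continue
        j = i
        while (j + 1 < n and candidate[j + 1]
               and pos[j + 1] - pos[j] <= params.max_gap_kb * 1000):
            j += 1
        segments.append((i, j))
        i = j + 1
    out = []
    for stretch in segments:
        pieces = [stretch] if params.window_only else \
            best_partition_naive(g, pos, *stretch,
                                 params.max_het, params.max_missing,
                                 params.min_snps,
                                 params.min_length_mb * 1e6)
        for s, e in pieces:
            n_snps = e - s + 1
            length = pos[e] - pos[s]
            seg = list(g[s:e + 1])
            n_het = sum(1 for x in seg if x == 1)
            n_mis = sum(1 for x in seg if x == MISSING)
            if n_snps < params.min_snps:
                continue
            if length < params.min_length_mb * 1e6:
                continue
            if length / 1000 / n_snps > params.density_kb_per_snp:
                continue
            out.append((s, e))
    return out


def best_partition_naive(g, pos, s, e, max_het, max_missing,
                         min_snps, min_len_bp):
    """Maximum-coverage disjoint feasible sub-segments of a candidate
    stretch, by exhaustive quadratic dynamic programming.  Feasible:
    homozygous non-missing endpoints, within the het/missing budgets, at
    least ``min_snps`` SNPs and ``min_len_bp`` span.  Ties broken toward
    fewer segments, then leftmost starts (skip preferred on exact
    ties)."""
    n = e - s + 1
    seq = [g[s + k] for k in range(n)]
    p = [int(pos[s + k]) for k in range(n)]
    is_hom = [x in (0, 2) for x in seq]
    f = [(0, 0)] * (n + 1)
    choice = [-1] * n
    for i in range(n):
        f[i + 1] = f[i]
        choice[i] = -1
        if not is_hom[i]:
            continue
        best = None
        best_s = None
        for s0 in range(i + 1):
            if not is_hom[s0]:
                continue
            if i - s0 + 1 < min_snps or p[i] - p[s0] < min_len_bp:
                continue
            window = seq[s0:i + 1]
            if sum(1 for x in window if x == 1) > max_het:
                continue
            if sum(1 for x in window if x == MISSING) > max_missing:
                continue
            cand = (f[s0][0] + p[i] - p[s0], f[s0][1] - 1)
            if best is None or cand > best:
                best = cand
                best_s = s0
        if best is not None and best > f[i]:
            f[i + 1] = best
            choice[i] = best_s
    pieces = []
    i = n - 1
    while i >= 0:
        if choice[i] == -1:
            i -= 1
        else:
            pieces.append((s + choice[i], s + i))
            i = choice[i] - 1
    pieces.reverse()
    return pieces


# ---------------------------------------------------------------------------
# consecutive-method oracle: explicit left-to-right scan
# ---------------------------------------------------------------------------

def consecutive_runs_naive(g, pos, params):
    """All runs on one chromosome for one animal per the consecutive
    method.  Returns [(start_i, end_i)] SNP index pairs (trimmed)."""
    def state(x):
        if x == MISSING:
            return "miss"
        if x == 1:
            return "het"
        return "hom"

    target = params.target
    opposite = "hom" if target == "het" else "het"
    runs = []

    def close(a, b):
        while a <= b and state(g[a]) != target:
            a += 1
        while b >= a and state(g[b]) != target:
            b -= 1
        if a > b:
            return
        n_snps = b - a + 1
        if n_snps < params.min_snps:
            return
        if pos[b] - pos[a] < params.min_length_kb * 1000:
            return
        runs.append((a, b))

    start = None
    n_opp = n_mis = 0
    for i in range(len(g)):
        if start is not None and pos[i] - pos[i - 1] > params.max_gap_kb * 1000:
            close(start, i - 1)
            start, n_opp, n_mis = None, 0, 0
        s = state(g[i])
        if start is None:
            if s == target:
                start = i
            continue
        if s == target:
            continue
        if s == opposite:
            if n_opp + 1 > params.max_opposite:
                close(start, i - 1)
                start, n_opp, n_mis = None, 0, 0
            else:
                n_opp += 1
        else:
            if n_mis + 1 > params.max_missing:
                close(start, i - 1)
                start, n_opp, n_mis = None, 0, 0
            else:
                n_mis += 1
    if start is not None:
        close(start, len(g) - 1)
    return runs


def runset_index_pairs(runset, marker_map, animal, chrom):
    """Detected runs of one animal/chromosome as SNP index pairs within
    the chromosome block, for comparison with the naive oracles."""
    blocks = dict(marker_map.chrom_blocks())
    idx = blocks[chrom]
    pos = marker_map.positions[idx]
    sel = runset.df[(runset.df["animal"] == animal)
                    & (runset.df["chrom"] == chrom)]
    pairs = []
    for r in sel.itertuples(index=False):
        s = int(np.searchsorted(pos, r.start_bp))
        e = int(np.searchsorted(pos, r.end_bp))
        pairs.append((s, e))
    return sorted(pairs)


# ---------------------------------------------------------------------------
# pedigree kinship by Monte-Carlo single-locus allele drop
# ---------------------------------------------------------------------------

def allele_drop_a_matrix(records, n_reps, rng):
    """Estimate the additive relationship matrix a(i,j) = 2 * P(IBD) by
    dropping one unlinked locus ``n_reps`` times through the pedigree.

    ``records``: [(animal, sire_or_None, dam_or_None)] topologically
    sorted.  Returns (labels, estimate, stderr) with stderr the
    per-entry Monte-Carlo standard error."""
    labels = [a for a, _, _ in records]
    pos = {a: i for i, a in enumerate(labels)}
    n = len(labels)
    hap = np.zeros((n, 2, n_reps), dtype=np.int64)
    next_allele = 0
    for a, s, d in records:
        i = pos[a]
        for which, parent in enumerate((s, d)):
            if parent is None:
                hap[i, which, :] = next_allele
                next_allele += 1
            else:
                j = pos[parent]
                pick = rng.integers(0, 2, size=n_reps)
                hap[i, which, :] = np.where(pick == 0, hap[j, 0], hap[j, 1])
    est = np.zeros((n, n))
    se = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            if i == j:
                per_rep = 0.5 * (1.0 + (hap[i, 0] == hap[i, 1]))
            else:
                per_rep = 0.25 * (
                    (hap[i, 0] == hap[j, 0]).astype(float)
                    + (hap[i, 0] == hap[j, 1])
                    + (hap[i, 1] == hap[j, 0])
                    + (hap[i, 1] == hap[j, 1]))
            est[i, j] = est[j, i] = 2.0 * per_rep.mean()
            se[i, j] = se[j, i] = 2.0 * per_rep.std() / np.sqrt(n_reps)
    return labels, est, se


# ---------------------------------------------------------------------------
# VanRaden G by explicit double loop
# ---------------------------------------------------------------------------

def vanraden_g_naive(values):
    """G matrix by the textbook double loop (no missing values)."""
    n, m = values.shape
    p = [sum(values[:, j]) / (2.0 * n) for j in range(m)]
    denom = 2.0 * sum(pj * (1 - pj) for pj in p)
    g = np.zeros((n, n))
    for i in range(n):
        for k in range(n):
            acc = 0.0
            for j in range(m):
                acc += (values[i, j] - 2 * p[j]) * (values[k, j] - 2 * p[j])
            g[i, k] = acc / denom
    return g


# ---------------------------------------------------------------------------
# interval helpers
# ---------------------------------------------------------------------------

def stab_count(intervals, point):
    """Number of [start, end] intervals containing a point."""
    return sum(1 for s, e in intervals if s <= point <= e)


def pairwise_overlap_bp(runs_i, runs_j):
    """Total overlap of two interval lists, intervals as half-open
    [start, end)."""
    total = 0
    for s1, e1 in runs_i:
        for s2, e2 in runs_j:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def population_overlap_denominator(runs_by_animal, n_animals):
    """Sum over constant-carrier-count regions of freq x length, by
    scanning every elementary breakpoint interval."""
    points = sorted({p for runs in runs_by_animal.values()
                     for s, e in runs for p in (s, e)})
    total = 0.0
    for lo, hi in zip(points, points[1:]):
        carriers = sum(
            1 for runs in runs_by_animal.values()
            if any(s <= lo and hi <= e for s, e in runs))
        total += (hi - lo) * carriers / n_animals
    return total


def quantile_type1(values, q):
    """Inverse empirical CDF quantile by explicit sorting."""
    s = sorted(values)
    k = int(np.ceil(q * len(s)))
    return s[max(k, 1) - 1]
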