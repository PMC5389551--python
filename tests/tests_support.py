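"""Independent oracles used by the test-suite.

These deliberately avoid the package's own code paths: the alignment
oracle is a plain-Python quadratic Gotoh DP, the quantile/threshold
oracle implements linear-interpolation quartiles by hand, and the LCA
oracle intersects full root paths.
"""


def random_instance(rng):
    """A small random seeding instance: genomes <= 200 bp, reads <= 50 bp,
    k <= 8, with occasional ambiguous bases."""
    k = int(rng.integers(3, 9))
    genomes = []
    for _ in range(int(rng.integers(1, 4))):
        L = int(rng.integers(k, 201))
        s = list("ACGT"[i] for i in rng.integers(0, 4, size=L))
        for pos in rng.integers(0, L, size=int(rng.integers(0, 3))):
            s[pos] = "N"
        genomes.append("".join(s))
    reads = []
    for _ in range(int(rng.integers(1, 6))):
        L = int(rng.integers(k, 51))
        g = genomes[int(rng.integers(0, len(genomes)))]
        if rng.random() < 0.7 and len(g) >= L:
            # plant a genuine substring so matches actually occur
            start = int(rng.integers(0, len(g) - L + 1))
            reads.append(g[start : start + L])
        else:
            reads.append("".join("ACGT"[i] for i in rng.integers(0, 4, size=L)))
    return genomes, reads, k


def sw_score_oracle(a, b, match=2, mismatch=2, gap_open=3, gap_extend=1):
    """Best local affine-gap alignment score by the quadratic Gotoh DP.
    A gap of length g costs gap_open + (g-1)*gap_extend."""
    m, n = len(a), len(b)
    NEG = -(10**9)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            d = H[i - 1][j - 1] + (match if a[i - 1] == b[j - 1] else -mismatch)
            H[i][j] = max(0, d, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def quartiles_oracle(xs):
    """Linear-interpolation ("type 7") quartiles, spelled out by hand."""
    xs = sorted(xs)
    n = len(xs)

    def q(p):
        h = (n - 1) * p
        lo = int(h)
        hi = min(lo + 1, n - 1)
        return xs[lo] + (h - lo) * (xs[hi] - xs[lo])

    return q(0.25), q(0.75)


def insert_screen_oracle(inserts):
    """Recompute the retained set, mu, sigma and the mu+6*sigma threshold
    independently; returns (threshold, kept_mask over the input order)."""
    import math

    q1, q3 = quartiles_oracle(inserts)
    bound = q3 + 2 * (q3 - q1)
    retained = [x for x in inserts if 0 <= x <= bound]
    mu = sum(retained) / len(retained)
    if len(retained) > 1:
        var = sum((x - mu) ** 2 for x in retained) / (len(retained) - 1)
        sigma = math.sqrt(var)
    else:
        sigma = 0.0
    thr = mu + 6 * sigma
    return thr, [x < thr for x in inserts]


def lca_oracle(tree, taxids):
    """Deepest node common to the full root paths of all taxids."""
    paths = [set(tree.path_to_root(t)) for t in set(taxids)]
    common = set.intersection(*paths)
    return max(common, key=tree.depth)
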