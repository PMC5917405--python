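"""Nei's standard genetic distance, neighbor-joining, and distance AMOVA.

``nei_distance`` works on individuals: each diploid genotype is read as an
allele-frequency vector (alt frequency = dosage/2), and Nei's 1972 identity
statistics are averaged over the loci non-missing in *both* members of a
pair.  ``amova`` is the one-level (among/within populations) variance
partition on squared pairwise distances with a permutation test for Phi_ST.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .formats_io import MISSING, GenotypeMatrix, PopulationMap


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distance matrix has non-finite entries")

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass
class AmovaResult:
    ssd_among: float
    ssd_within: float
    sigma2_among: float
    sigma2_within: float
    pct_among: float
    pct_within: float
    phi_st: float
    p_value: float
    n_perm: int


# ---------------------------------------------------------------------------
# Nei's standard genetic distance
# ---------------------------------------------------------------------------

def nei_distance(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise Nei (1972) standard distance between individuals.

    Per locus the individual's allele frequencies are (1 - dosage/2,
    dosage/2); with J_x = mean_l sum_a x_a^2, J_y likewise and
    J_xy = mean_l sum_a x_a * y_a over pairwise-complete loci,
    D = -ln( J_xy / sqrt(J_x * J_y) ).
    """
    nm = (matrix.calls != MISSING).astype(float)
    a = np.where(nm > 0, matrix.calls / 2.0, 0.0)       # alt-allele frequency
    alt_m = a * nm
    ref_m = (1.0 - a) * nm
    # products vanish unless the locus is non-missing in both samples
    s_xy = alt_m @ alt_m.T + ref_m @ ref_m.T            # sum_l sum_a x_a y_a
    shared = nm @ nm.T
    if np.any(shared[~np.eye(matrix.n_samples, dtype=bool)] == 0):
        i, j = np.argwhere((shared == 0) & ~np.eye(matrix.n_samples, dtype=bool))[0]
        raise ValueError(
            f"no shared non-missing loci for pair "
            f"({matrix.samples[i]}, {matrix.samples[j]})"
        )
    q = (a ** 2 + (1.0 - a) ** 2) * nm                  # per-call homozygosity
    j_self = q @ nm.T                                   # sum over shared loci
    with np.errstate(divide="ignore", invalid="ignore"):
        d = -np.log(s_xy / np.sqrt(j_self * j_self.T))
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    d = (d + d.T) / 2.0  # symmetrize away float noise
    return DistanceMatrix(labels=list(matrix.samples), d=d)


def nei_distance_populations(matrix: GenotypeMatrix,
                             popmap: PopulationMap) -> DistanceMatrix:
    """Nei's distance between populations from pooled group allele frequencies."""
    idx = popmap.indices_by_group(matrix.samples)
    groups = popmap.groups
    freqs = []
    for g in groups:
        calls = matrix.calls[idx[g], :]
        nm = calls != MISSING
        n_nm = nm.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(nm, calls, 0).sum(axis=0) / (2.0 * n_nm)
        freqs.append(np.where(n_nm == 0, np.nan, p))
    freqs = np.array(freqs)
    k = len(groups)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            ok = ~np.isnan(freqs[i]) & ~np.isnan(freqs[j])
            if not ok.any():
                raise ValueError(f"no shared loci for groups ({groups[i]}, {groups[j]})")
            pi, pj = freqs[i][ok], freqs[j][ok]
            jx = np.mean(pi ** 2 + (1 - pi) ** 2)
            jy = np.mean(pj ** 2 + (1 - pj) ** 2)
            jxy = np.mean(pi * pj + (1 - pi) * (1 - pj))
            d[i, j] = d[j, i] = max(0.0, -np.log(jxy / np.sqrt(jx * jy)))
    return DistanceMatrix(labels=groups, d=d)


def dosage_distance(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Euclidean distance between dosage vectors over pairwise-complete loci.

    The squared form of this distance is the classical AMOVA metric: its
    among/within variance components have closed-form expectations in the
    group allele frequencies, which makes parameter-recovery checks exact.
    Missing calls are excluded pairwise and the squared distance is rescaled
    to the full locus count.
    """
    calls = matrix.calls.astype(float)
    nm = (matrix.calls != MISSING).astype(float)
    x = np.where(nm > 0, calls, 0.0)
    # sum over shared loci of (x_i - x_j)^2, via expansion with masks
    x2 = (x ** 2) * nm
    sq = (x2 @ nm.T) + (nm @ x2.T) - 2.0 * (x @ x.T)
    shared = nm @ nm.T
    if np.any(shared[~np.eye(matrix.n_samples, dtype=bool)] == 0):
        i, j = np.argwhere((shared == 0) & ~np.eye(matrix.n_samples, dtype=bool))[0]
        raise ValueError(
            f"no shared non-missing loci for pair "
            f"({matrix.samples[i]}, {matrix.samples[j]})"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        sq = sq * (matrix.n_loci / shared)
    np.fill_diagonal(sq, 0.0)
    d = np.sqrt(np.clip(sq, 0.0, None))
    d = (d + d.T) / 2.0
    return DistanceMatrix(labels=list(matrix.samples), d=d)


# ---------------------------------------------------------------------------
# Neighbor-joining
# ---------------------------------------------------------------------------

class _Clade:
    """Working node during NJ agglomeration."""

    __slots__ = ("node", "key")

    def __init__(self, node: dendropy.Node, key: str):
        self.node = node
        self.key = key  # smallest leaf label in the clade, for tie-breaks


def neighbor_joining(dmatrix: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor-joining with deterministic tie-breaking.

    The pair minimising Q(i,j) = (n-2) d(i,j) - r_i - r_j is joined each
    round; ties go to the lexicographically smallest (label_i, label_j)
    pair.  A negative branch length is clamped to zero and its deficit
    moved onto the sibling branch so leaf-to-leaf path lengths are
    preserved.
    """
    labels = dmatrix.labels
    n0 = len(labels)
    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = False

    if n0 == 1:
        leaf = dendropy.Node(taxon=tns.get_taxon(labels[0]))
        leaf.edge.length = 0.0
        tree.seed_node.add_child(leaf)
        return tree

    clades = []
    for lab in labels:
        node = dendropy.Node(taxon=tns.get_taxon(lab))
        clades.append(_Clade(node, lab))
    d = dmatrix.d.astype(float).copy()

    def join(i: int, j: int, li: float, lj: float) -> None:
        """Replace active clades i<j with their new parent."""
        li, lj = _clamp_pair(li, lj)
        parent = dendropy.Node()
        ci, cj = clades[i], clades[j]
        parent.add_child(ci.node)
        ci.node.edge.length = li
        parent.add_child(cj.node)
        cj.node.edge.length = lj
        new = _Clade(parent, min(ci.key, cj.key))
        keep = [k for k in range(len(clades)) if k not in (i, j)]
        nonlocal d
        dnew = np.empty(len(keep))
        for t, k in enumerate(keep):
            dnew[t] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        d = d[np.ix_(keep, keep)]
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = dnew
        d[:-1, -1] = dnew
        clades[:] = [clades[k] for k in keep] + [new]

    while len(clades) > 3:
        m = len(clades)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = (q, *sorted((clades[i].key, clades[j].key)))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (d[i].sum() - d[j].sum()) / (2 * (m - 2))
        lj = d[i, j] - li
        join(i, j, li, lj)

    if len(clades) == 3:
        da, db, dc = d[0, 1], d[0, 2], d[1, 2]
        lengths = [0.5 * (da + db - dc), 0.5 * (da + dc - db), 0.5 * (db + dc - da)]
        center = dendropy.Node()
        for clade, length in zip(clades, lengths):
            center.add_child(clade.node)
            clade.node.edge.length = max(0.0, length)
        tree.seed_node = center
    else:  # exactly 2: the connecting edge (split across a degree-2 root)
        a, b = clades
        root = dendropy.Node()
        root.add_child(a.node)
        a.node.edge.length = d[0, 1] / 2.0
        root.add_child(b.node)
        b.node.edge.length = d[0, 1] / 2.0
        tree.seed_node = root
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def tree_path_lengths(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf patristic distances keyed by sorted label pairs."""
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    taxa = list(tree.taxon_namespace)
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1:]:
            key = tuple(sorted((t1.label, t2.label)))
            out[key] = pdm.patristic_distance(t1, t2)
    return out


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

def _ssd_within(d2: np.ndarray, group_idx: list[np.ndarray]) -> float:
    total = 0.0
    for idx in group_idx:
        sub = d2[np.ix_(idx, idx)]
        total += sub.sum() / (2.0 * len(idx))
    return total


def amova(dmatrix: DistanceMatrix, popmap: PopulationMap, n_perm: int = 999,
          seed: int | None = None, squared: bool = True) -> AmovaResult:
    """One-level AMOVA on a distance matrix with a permutation test.

    SSD_total = (1/N) sum_{i<j} d^2; SSD_within sums the analogous term per
    group with its own size; variance components follow the standard
    one-level expectation with n-bar = (N - sum n_g^2 / N)/(k-1).  The
    permutation p-value carries the +1 correction, so p is never 0.
    ``squared=False`` feeds raw distances into the SSD terms instead.
    """
    labels = dmatrix.labels
    n = dmatrix.n
    idx_by_group = popmap.indices_by_group(labels)
    sizes = {g: len(ix) for g, ix in idx_by_group.items()}
    if len(sizes) < 2:
        raise ValueError("AMOVA requires at least 2 groups")
    for g, s in sizes.items():
        if s < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    k = len(sizes)
    d2 = dmatrix.d ** 2 if squared else dmatrix.d.copy()

    ssd_total = d2.sum() / (2.0 * n)
    group_idx = list(idx_by_group.values())
    ssd_within = _ssd_within(d2, group_idx)
    ssd_among = ssd_total - ssd_within
    df_among = k - 1
    df_within = n - k
    sigma2_within = ssd_within / df_within
    n_bar = (n - sum(s * s for s in sizes.values()) / n) / (k - 1)
    sigma2_among = (ssd_among / df_among - sigma2_within) / n_bar
    sigma2_among = max(sigma2_among, 0.0)
    total_var = sigma2_among + sigma2_within
    phi = sigma2_among / total_var if total_var > 0 else 0.0

    group_sizes = [len(ix) for ix in group_idx]
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pos = 0
        perm_idx = []
        for s in group_sizes:
            perm_idx.append(perm[pos:pos + s])
            pos += s
        ssd_w = _ssd_within(d2, perm_idx)
        ssd_a = ssd_total - ssd_w
        s2w = ssd_w / df_within
        s2a = max((ssd_a / df_among - s2w) / n_bar, 0.0)
        phi_p = s2a / (s2a + s2w) if (s2a + s2w) > 0 else 0.0
        if phi_p >= phi:
            exceed += 1
    p_value = (exceed + 1) / (n_perm + 1)

    pct_among = 100.0 * phi
    return AmovaResult(
        ssd_among=ssd_among, ssd_within=ssd_within,
        sigma2_among=sigma2_among, sigma2_within=sigma2_within,
        pct_among=pct_among, pct_within=100.0 - pct_among,
        phi_st=phi, p_value=p_value, n_perm=n_perm,
    )
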