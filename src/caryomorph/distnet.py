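"""Between-group dissimilarity: Mahalanobis distances, neighbor-joining
networks, Sokal-Michener genetic distances, and the Mantel test.

Morphometric dissimilarity between varieties (or categories) is the
Mahalanobis distance between group mean shape vectors under the pooled
within-group covariance; genetic dissimilarity between varieties is one
minus the simple-matching coefficient of their binary SNP genotypes.
The two matrices are compared with a permutation Mantel test, and
either can be summarized as an unrooted neighbor-joining network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix", "SNPMatrix", "NJTree", "mahalanobis_groups",
    "neighbor_joining", "sokal_michener", "mantel", "export_newick",
    "read_newick",
]


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative dissimilarities between labelled groups."""

    labels: list[str]
    D: np.ndarray
    kind: str = "euclidean"

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        if D.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(D, D.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(D) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(D < 0):
            raise ValueError("distances must be nonnegative")
        self.D = D

    def condensed(self) -> np.ndarray:
        """Strictly-lower-triangle entries, row-major."""
        i, j = np.tril_indices(len(self.labels), k=-1)
        return self.D[i, j]

    def reorder(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(labels=list(labels), D=self.D[np.ix_(idx, idx)],
                              kind=self.kind)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.D, index=self.labels, columns=self.labels).to_csv(path)

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.D):
                fh.write(lab.replace(" ", "_") + "  " + "  ".join(f"{x:.9f}" for x in row) + "\n")


@dataclass
class SNPMatrix:
    """Varieties x markers binary genotypes with an optional missing mask."""

    varieties: list[str]
    genotypes: np.ndarray
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        G = np.asarray(self.genotypes)
        if G.ndim != 2 or G.shape[0] != len(self.varieties):
            raise ValueError("genotypes must be (n_varieties, n_markers)")
        if self.missing is None:
            self.missing = np.zeros(G.shape, dtype=bool)
        present = ~self.missing
        vals = G[present]
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("genotype entries must be 0/1 (or masked missing)")
        self.genotypes = G.astype(np.int8)

    def to_tsv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(
            np.where(self.missing, -1, self.genotypes),
            index=self.varieties,
            columns=[f"snp{j:04d}" for j in range(self.genotypes.shape[1])],
        )
        df.to_csv(path, sep="\t", index_label="variety")

    @classmethod
    def from_tsv(cls, path) -> "SNPMatrix":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0)
        arr = df.to_numpy(int)
        missing = arr < 0
        return cls(varieties=[str(v) for v in df.index],
                   genotypes=np.where(missing, 0, arr), missing=missing)


# ---------------------------------------------------------------------------
# Mahalanobis distances between group means
# ---------------------------------------------------------------------------

def mahalanobis_groups(
    features, grouping: str, var_threshold: float = 0.99
) -> DistanceMatrix:
    """Pairwise Mahalanobis distances between group mean feature vectors.

    D_ij = sqrt((mu_i - mu_j)' S^-1 (mu_i - mu_j)) with S the pooled
    within-group covariance.  When the feature matrix is rank-deficient
    (common for harmonic coefficient blocks), features are first reduced
    to centred principal components capturing ``var_threshold`` of the
    variance, never more than (n - n_groups) components.
    """
    X = np.asarray(features.values, dtype=float)
    y = np.asarray(features.labels[grouping]).astype(str)
    groups = sorted(set(y))
    counts = {g: int((y == g).sum()) for g in groups}
    small = [g for g, c in counts.items() if c < 2]
    if small:
        raise ValueError(
            f"groups with < 2 members have no within-group covariance: {small}"
        )
    n, p = X.shape
    max_rank = n - len(groups)
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    ev = s**2
    keep = ev > ev[0] * 1e-12 if len(ev) else np.array([], bool)
    frac = np.cumsum(ev) / ev.sum()
    n_comp = int(np.searchsorted(frac, var_threshold - 1e-12) + 1)
    n_comp = min(n_comp, max_rank, int(keep.sum()))
    n_comp = max(n_comp, 1)
    if n_comp < p:
        Z = Xc @ Vt[:n_comp].T
    else:
        Z = Xc
    means = np.array([Z[y == g].mean(axis=0) for g in groups])
    S = np.zeros((Z.shape[1], Z.shape[1]))
    for g in groups:
        Zg = Z[y == g]
        S += (Zg - Zg.mean(axis=0)).T @ (Zg - Zg.mean(axis=0))
    S /= n - len(groups)
    Sinv = np.linalg.pinv(S)
    diff = means[:, None, :] - means[None, :, :]
    D2 = np.einsum("ijk,kl,ijl->ij", diff, Sinv, diff)
    D = np.sqrt(np.maximum(D2, 0.0))
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    return DistanceMatrix(labels=groups, D=D, kind="mahalanobis_shape")


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class NJTree:
    """Unrooted neighbor-joining tree over group labels.

    Wraps a :mod:`dendropy` tree; ``raw_lengths`` records branch lengths
    before negative-length clamping for inspection.
    """

    tree: "object"  # dendropy.Tree
    labels: list[str]
    raw_lengths: list[float] = field(default_factory=list)

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def path_distance(self, a: str, b: str) -> float:
        pdm = self.tree.phylogenetic_distance_matrix()
        ta = self.tree.taxon_namespace.get_taxon(a)
        tb = self.tree.taxon_namespace.get_taxon(b)
        return float(pdm.distance(ta, tb))

    def path_distance_matrix(self) -> DistanceMatrix:
        pdm = self.tree.phylogenetic_distance_matrix()
        tn = {t.label: t for t in self.tree.taxon_namespace}
        n = len(self.labels)
        D = np.zeros((n, n))
        for i, a in enumerate(self.labels):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = float(pdm.distance(tn[a], tn[self.labels[j]]))
        return DistanceMatrix(labels=list(self.labels), D=D, kind="euclidean")


def neighbor_joining(dm: DistanceMatrix) -> NJTree:
    """Saitou-Nei neighbor joining on a dissimilarity matrix.

    Uses the rate-corrected selection criterion
    Q_ij = (m - 2) d_ij - r_i - r_j; ties are broken by the smallest
    (i, j) index pair for determinism.  Negative branch lengths are
    clamped to zero with the deficit transferred to the sibling edge
    (path lengths through the joined pair are preserved); the raw values
    are retained on the result for inspection.  On a tree-additive input
    the path-length metric of the output reproduces the input exactly.
    """
    import dendropy

    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 labels")

    tns = dendropy.TaxonNamespace([str(l) for l in dm.labels])
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes = []
    for lab in dm.labels:
        nd = dendropy.Node(taxon=tns.get_taxon(str(lab)))
        nodes.append(nd)
    D = dm.D.astype(float).copy()
    active = list(range(n))
    raw_lengths: list[float] = []

    def join(i_pos: int, j_pos: int, li: float, lj: float):
        raw_lengths.extend([li, lj])
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        ni, nj = nodes[i_pos], nodes[j_pos]
        parent.add_child(ni)
        parent.add_child(nj)
        ni.edge.length = float(li)
        nj.edge.length = float(lj)
        return parent

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = np.argmin(Q)  # row-major: smallest (i, j) on ties
        i, j = divmod(int(flat), m)
        if i > j:
            i, j = j, i
        d_ij = sub[i, j]
        li = 0.5 * d_ij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d_ij - li
        gi, gj = active[i], active[j]
        parent = join(gi, gj, li, lj)
        d_new = 0.5 * (D[gi, :] + D[gj, :] - d_ij)
        D = np.vstack([D, d_new[None, :]])
        D = np.hstack([D, np.append(d_new, 0.0)[:, None]])
        nodes.append(parent)
        active = [a for a in active if a not in (gi, gj)] + [len(nodes) - 1]

    # final three-way join
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    raw_lengths.extend([la, lb, lc])
    center = dendropy.Node()
    for pos, length in ((a, la), (b, lb), (c, lc)):
        center.add_child(nodes[pos])
        nodes[pos].edge.length = float(max(length, 0.0))
    tree.seed_node = center
    tree.is_rooted = False
    tree.update_bipartitions(suppress_unifurcations=False)
    return NJTree(tree=tree, labels=[str(l) for l in dm.labels],
                  raw_lengths=raw_lengths)


# ---------------------------------------------------------------------------
# Sokal-Michener distance
# ---------------------------------------------------------------------------

def sokal_michener(snps: SNPMatrix) -> DistanceMatrix:
    """1 - simple matching coefficient, with pairwise deletion of missing."""
    G = snps.genotypes.astype(float)
    present = (~snps.missing).astype(float)
    Gm = np.where(snps.missing, 0.0, G)
    # matches = agree on 1s + agree on 0s, counted over jointly present markers
    ones = Gm @ Gm.T
    zeros = ((1 - Gm) * present) @ ((1 - Gm) * present).T
    shared = present @ present.T
    if np.any(shared[~np.eye(len(shared), dtype=bool)] == 0):
        raise ValueError("a variety pair shares no non-missing markers")
    with np.errstate(invalid="ignore"):
        D = 1.0 - (ones + zeros) / shared
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    return DistanceMatrix(labels=list(snps.varieties), D=D, kind="sokal_michener_snp")


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    B: int = 999,
    seed: int = 0,
    tail: str = "greater",
):
    """Permutation Mantel test of association between two distance matrices.

    r is the Pearson correlation of strictly-lower-triangle entries; the
    null distribution is built by jointly permuting rows and columns of
    the second matrix.  The default tail is one-sided 'greater' (the
    working hypothesis is positive association between morphometric and
    genetic distance); 'two-sided' compares |r|.
    """
    from caryomorph.morphostats import TestResult

    if B < 99:
        raise ValueError("B must be >= 99")
    if set(d1.labels) != set(d2.labels):
        raise ValueError("label sets differ between the two matrices")
    if d2.labels != d1.labels:
        d2 = d2.reorder(d1.labels)
    v1 = d1.condensed()
    n = len(d1.labels)
    if np.std(v1) == 0 or np.std(d2.condensed()) == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")

    il, jl = np.tril_indices(n, k=-1)

    def corr(mat2: np.ndarray) -> float:
        v2 = mat2[il, jl]
        return float(np.corrcoef(v1, v2)[0, 1])

    r_obs = corr(d2.D)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(B):
        perm = rng.permutation(n)
        r_p = corr(d2.D[np.ix_(perm, perm)])
        if tail == "greater":
            count += r_p >= r_obs
        else:
            count += abs(r_p) >= abs(r_obs)
    p = (1.0 + count) / (1.0 + B)
    return TestResult(
        statistic_name="mantel_r", statistic=r_obs, p_value=p,
        permutations=B, note=f"tail={tail}, seed={seed}",
    )


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def export_newick(tree: NJTree, path) -> None:
    """Write the tree as Newick with branch lengths (round-trip safe)."""
    tree.tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_newick(path) -> "object":
    import dendropy

    return dendropy.Tree.get(path=str(path), schema="newick")
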