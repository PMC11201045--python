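"""Structure analysis: ordination, trees, and group assignment.

Distance-based views of a landrace panel: principal coordinate analysis
(classical metric scaling) of a distance matrix, Ward and neighbor-joining
trees, plus the plumbing around model-based clustering with an external
ancestry program — simulating individual genotypes from pool frequencies
under Hardy-Weinberg equilibrium, exporting PED/MAP, reading back a
Q-matrix, the membership > 0.6 assignment rule, and group allele-frequency
estimation from assigned landraces.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from ._utils import logger, rng_from_seed
from .diversity import DistanceMatrix
from .simulate import GroupModel

ADMIXED_LABEL = "admixed"


@dataclass
class PcoaResult:
    """Principal coordinates: entity scores, eigenvalues, percent variance."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    percent_variance: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class Tree:
    """A phylogenetic / dendrogram tree with labelled leaves.

    Wraps a dendropy tree; agglomerative trees also carry their merge
    heights (nondecreasing) and the scipy linkage matrix.
    """

    tree: dendropy.Tree
    merge_heights: np.ndarray | None = None
    linkage: np.ndarray | None = field(default=None, repr=False)

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def newick(self) -> str:
        return self.tree.as_string(schema="newick",
                                   suppress_rooting=True).strip()

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        t = dendropy.Tree.get(data=newick, schema="newick")
        return cls(tree=t)


@dataclass
class GenotypeMatrix:
    """Simulated individual genotypes: B-allele counts in {0, 1, 2}."""

    genotypes: pd.DataFrame  # individuals x loci, Int64 (missing allowed)
    landrace_map: pd.Series  # individual -> landrace

    def __post_init__(self) -> None:
        vals = self.genotypes.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("genotypes must be 0, 1 or 2")


def _as_square(d) -> tuple[np.ndarray, list]:
    if isinstance(d, DistanceMatrix):
        return d.to_numpy(), d.labels
    if isinstance(d, pd.DataFrame):
        return d.to_numpy(dtype=float), list(d.index)
    arr = np.asarray(d, dtype=float)
    return arr, list(range(arr.shape[0]))


def pcoa(d, n_axes: int | None = None) -> PcoaResult:
    """Classical metric scaling (Gower) of a distance matrix.

    Double-centers -1/2 d^2, eigendecomposes, and returns coordinates
    scaled by sqrt(eigenvalue) for the positive eigenvalues only; the
    percent-variance denominator is the sum of positive eigenvalues. Axis
    signs follow the convention that the first nonzero loading is positive.
    """
    dm, labels = _as_square(d)
    if np.abs(dm - dm.T).max() > 1e-8:
        raise ValueError("distance matrix must be symmetric")
    n = dm.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm ** 2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(np.abs(evals).max(), 1.0) * 1e-12
    pos = evals > tol
    lam = evals[pos]
    coords = evecs[:, pos] * np.sqrt(lam)
    for k in range(coords.shape[1]):  # sign convention
        nz = np.nonzero(np.abs(coords[:, k]) > 1e-12)[0]
        if nz.size and coords[nz[0], k] < 0:
            coords[:, k] *= -1.0
    if n_axes is not None:
        coords = coords[:, :n_axes]
        lam_axes = lam[:n_axes]
    else:
        lam_axes = lam
    pct = lam_axes / lam.sum() * 100.0 if lam.size else lam_axes
    cols = [f"PCo{k + 1}" for k in range(coords.shape[1])]
    return PcoaResult(pd.DataFrame(coords, index=labels, columns=cols),
                      eigenvalues=lam_axes, percent_variance=pct)


def _linkage_to_tree(Z: np.ndarray, labels: list) -> dendropy.Tree:
    """Dendrogram from a scipy linkage matrix, branch = height difference."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    taxa = dendropy.TaxonNamespace([str(lb) for lb in labels])
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = {}
    for i, lb in enumerate(labels):
        nd = dendropy.Node(taxon=taxa.get_taxon(str(lb)))
        nodes[i] = nd
    for step, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        parent = dendropy.Node()
        for child in (a, b):
            ch = nodes[child]
            ch.edge.length = float(h) - heights[child]
            parent.add_child(ch)
        new_id = n + step
        nodes[new_id] = parent
        heights[new_id] = float(h)
    tree.seed_node = nodes[n + len(Z) - 1]
    return tree


def ward_tree(d) -> Tree:
    """Agglomerative Ward tree (Ward.D2 convention) from a distance matrix."""
    dm, labels = _as_square(d)
    if dm.shape[0] < 2:
        raise ValueError("need at least two entities")
    condensed = dm[np.triu_indices(dm.shape[0], k=1)]
    Z = hierarchy.linkage(condensed, method="ward")
    return Tree(tree=_linkage_to_tree(Z, labels),
                merge_heights=Z[:, 2].copy(), linkage=Z)


def nj_tree(d) -> Tree:
    """Classic Saitou-Nei neighbor joining.

    Uses the standard Q-criterion with a deterministic (row-major) argmin;
    negative branch lengths are clamped to zero with the deficit moved to
    the sibling branch. Returns an unrooted tree (trifurcating root in the
    Newick serialization). Exact on additive distance matrices.
    """
    dm, labels = _as_square(d)
    n = dm.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 entities")
    D = dm.astype(float).copy()
    frags = [f"'{lb}'" if _needs_quotes(str(lb)) else str(lb) for lb in labels]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_loc, j_loc = np.unravel_index(np.argmin(q), q.shape)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = sub[i_loc, j_loc]
        li = dij / 2.0 + (r[i_loc] - r[j_loc]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj, li = lj + li, 0.0
        if lj < 0:
            li, lj = li + lj, 0.0
        # distances from the new node to the remaining entities
        new_d = np.zeros(D.shape[0])
        for k in active:
            if k not in (i, j):
                new_d[k] = (D[i, k] + D[j, k] - dij) / 2.0
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_d
        D[:-1, -1] = new_d
        frags.append(f"({frags[i]}:{li:.12g},{frags[j]}:{lj:.12g})")
        active = [k for k in active if k not in (i, j)] + [D.shape[0] - 1]
    a, b, c = active
    la = (D[a, b] + D[a, c] - D[b, c]) / 2.0
    lb = (D[a, b] + D[b, c] - D[a, c]) / 2.0
    lc = (D[a, c] + D[b, c] - D[a, b]) / 2.0
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    newick = (f"({frags[a]}:{la:.12g},{frags[b]}:{lb:.12g},"
              f"{frags[c]}:{lc:.12g});")
    return Tree.from_newick(newick)


def _needs_quotes(label: str) -> bool:
    return any(ch in label for ch in " ()[]':;,")


def simulate_individuals(panel, n_ind: int = 5, n_loci: int = 2500,
                         seed: int = 0, subset: str = "even") -> GenotypeMatrix:
    """Simulate individual genotypes from pool frequencies under HWE.

    ``n_loci`` loci are chosen by even spacing over the locus index (a
    proxy for picking independent SNPs; ``subset="random"`` draws a seeded
    random subset instead). Each individual's genotype at a locus is
    Binomial(2, p) with p the landrace pool frequency.
    """
    freq = panel.freq if hasattr(panel, "freq") else panel
    L = freq.shape[1]
    if n_loci > L:
        raise ValueError(f"n_loci={n_loci} exceeds available loci ({L})")
    rng = rng_from_seed(seed)
    if subset == "even":
        idx = np.round(np.linspace(0, L - 1, n_loci)).astype(int)
    elif subset == "random":
        idx = np.sort(rng.choice(L, size=n_loci, replace=False))
    else:
        raise ValueError("subset must be 'even' or 'random'")
    sub = freq.iloc[:, idx]
    p = sub.to_numpy(dtype=float)
    genos = np.full((len(sub) * n_ind, n_loci), np.nan)
    ind_ids, lr_ids = [], []
    for i, lr in enumerate(sub.index):
        ok = np.isfinite(p[i])
        draws = np.full((n_ind, n_loci), np.nan)
        if ok.any():
            draws[:, ok] = rng.binomial(2, p[i, ok], size=(n_ind, ok.sum()))
        genos[i * n_ind:(i + 1) * n_ind] = draws
        ind_ids += [f"{lr}_ind{j + 1}" for j in range(n_ind)]
        lr_ids += [lr] * n_ind
    gdf = pd.DataFrame(genos, index=ind_ids, columns=sub.columns).astype("Int64")
    return GenotypeMatrix(gdf, pd.Series(lr_ids, index=ind_ids, name="landrace"))


def write_ped_map(gm: GenotypeMatrix, prefix: str) -> tuple[str, str]:
    """PED/MAP export (alleles coded 1/2, missing 0 0) for external tools."""
    ped_path, map_path = f"{prefix}.ped", f"{prefix}.map"
    codes = {0: "1 1", 1: "1 2", 2: "2 2"}
    with open(ped_path, "w") as fh:
        for ind, row in gm.genotypes.iterrows():
            fam = gm.landrace_map[ind]
            alleles = " ".join(
                codes[int(v)] if pd.notna(v) else "0 0" for v in row)
            fh.write(f"{fam} {ind} 0 0 0 -9 {alleles}\n")
    with open(map_path, "w") as fh:
        for k, snp in enumerate(gm.genotypes.columns):
            fh.write(f"1 {snp} 0 {k + 1}\n")
    return ped_path, map_path


def read_q_matrix(path, gm: GenotypeMatrix):
    """Read an ancestry Q-matrix (individuals x K, whitespace-separated).

    Rows must follow the individual order of ``gm``; per-landrace admixture
    is the mean over each landrace's simulated individuals.
    """
    from .ancestry import AdmixtureCoefficients

    q = pd.read_csv(path, sep=r"\s+", header=None)
    if len(q) != len(gm.genotypes):
        raise ValueError("Q-matrix rows do not match individual count")
    q.index = gm.genotypes.index
    q.columns = [f"K{k + 1}" for k in range(q.shape[1])]
    by_lr = q.groupby(gm.landrace_map).mean()
    by_lr = by_lr.div(by_lr.sum(axis=1), axis=0)
    return AdmixtureCoefficients(by_lr)


def assign_groups(admix, threshold: float = 0.6) -> pd.DataFrame:
    """Assign each landrace to its dominant group, or 'admixed'.

    A landrace is assigned to the argmax group when that membership exceeds
    ``threshold``; otherwise (including ties at the maximum within 1e-12)
    it is labelled admixed.
    """
    coef = admix.coef if hasattr(admix, "coef") else admix
    vals = coef.to_numpy(dtype=float)
    sums = vals.sum(axis=1)
    if np.abs(sums - 1.0).max() > 1e-6:
        raise ValueError("admixture rows must sum to 1")
    best = vals.argmax(axis=1)
    best_val = vals[np.arange(len(vals)), best]
    tied = (np.abs(vals - best_val[:, None]) < 1e-12).sum(axis=1) > 1
    labels = np.where((best_val > threshold) & ~tied,
                      np.asarray(coef.columns)[best], ADMIXED_LABEL)
    return pd.DataFrame({"group": labels, "membership": best_val},
                        index=coef.index)


def estimate_group_frequencies(panel, assignment) -> GroupModel:
    """Per-group allele frequencies: unweighted mean over assigned members.

    ``assignment`` is the table from :func:`assign_groups` (or a Series of
    labels); admixed landraces are excluded. Raises if a named group has no
    assigned landrace.
    """
    freq = panel.freq if hasattr(panel, "freq") else panel
    labels = assignment["group"] if isinstance(assignment, pd.DataFrame) else assignment
    labels = labels.reindex(freq.index)
    groups = sorted(set(labels.dropna()) - {ADMIXED_LABEL})
    if not groups:
        raise ValueError("no landrace assigned to any group")
    rows = {}
    for g in groups:
        members = freq.loc[labels == g]
        if members.empty:
            raise ValueError(f"group {g} has no assigned landrace")
        rows[g] = members.mean(axis=0)
    gf = pd.DataFrame(rows).T
    return GroupModel(gf)
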