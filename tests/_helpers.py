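"""Shared independent oracles and generators used across test modules."""
import itertools

import numpy as np
import pandas as pd


def path_distances(tree):
    """Leaf-to-leaf path lengths of a Tree, as a labelled DataFrame."""
    pdm = tree.tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.tree.taxon_namespace, key=lambda t: t.label)
    out = pd.DataFrame(0.0, index=[t.label for t in taxa],
                       columns=[t.label for t in taxa])
    for t1 in taxa:
        for t2 in taxa:
            if t1 is not t2:
                out.loc[t1.label, t2.label] = pdm.distance(t1, t2)
    return out


def random_additive_tree(n_leaves, seed):
    """Random binary tree with positive branch lengths; returns its additive
    leaf distance matrix (built by accumulating path lengths directly)."""
    rng = np.random.default_rng(seed)
    labels = [f"t{i}" for i in range(n_leaves)]
    d = pd.DataFrame(0.0, index=labels, columns=labels)
    nodes = [{lb: 0.0} for lb in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        bu, bv = rng.uniform(0.1, 1.0, size=2)
        u, v = nodes[i], nodes[j]
        for lu, du in u.items():
            for lv, dv in v.items():
                dist = du + bu + dv + bv
                d.loc[lu, lv] = d.loc[lv, lu] = dist
        merged = {lb: dd + bu for lb, dd in u.items()}
        merged.update({lb: dd + bv for lb, dd in v.items()})
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(merged)
    return d


def simplex_grid_search(G, f, step):
    """Dense search over the probability simplex (oracle for small K)."""
    K = G.shape[1]
    best, best_obj = None, np.inf
    ticks = np.arange(0.0, 1.0 + step / 2, step)
    for combo in itertools.product(ticks, repeat=K - 1):
        s = sum(combo)
        if s > 1.0 + 1e-12:
            continue
        beta = np.array(list(combo) + [1.0 - s])
        obj = np.sum((f - G @ beta) ** 2)
        if obj < best_obj:
            best, best_obj = beta, obj
    return best, best_obj


def gaussian_blobs(k=15, per=12, sep=10.0, seed=0, dim=2):
    """k unit-variance Gaussian blobs on a grid with spacing ``sep``."""
    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(k)))
    centers = np.array([(i % side, i // side) for i in range(k)],
                       dtype=float) * sep
    if dim > 2:
        centers = np.hstack([centers, np.zeros((k, dim - 2))])
    pts, labels = [], []
    for i, c in enumerate(centers):
        pts.append(c + rng.normal(scale=1.0, size=(per, dim)))
        labels += [i] * per
    x = np.vstack(pts)
    return (pd.DataFrame(x, index=[f"e{i}" for i in range(len(x))]),
            np.array(labels))


def greedy_ward_merges(d):
    """Exhaustive greedy Ward.D2 agglomeration via explicit Lance-Williams
    recursion; returns the merge list [(i, j, height), ...]."""
    n = d.shape[0]
    clusters = {i: [i] for i in range(n)}
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    merges = []
    nxt = n
    while len(clusters) > 1:
        (i, j), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        merges.append((i, j, h))
        ni, nj = len(clusters[i]), len(clusters[j])
        new = {k: v for k, v in dist.items() if not set(k) & {i, j}}
        for k in clusters:
            if k in (i, j):
                continue
            nk = len(clusters[k])
            dik = dist[tuple(sorted((i, k)))]
            djk = dist[tuple(sorted((j, k)))]
            dij = dist[(i, j)]
            v = np.sqrt(((ni + nk) * dik ** 2 + (nj + nk) * djk ** 2
                         - nk * dij ** 2) / (ni + nj + nk))
            new[tuple(sorted((k, nxt)))] = v
        clusters[nxt] = clusters.pop(i) + clusters.pop(j)
        dist = new
        nxt += 1
    return merges
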