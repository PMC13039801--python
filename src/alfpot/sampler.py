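"""Diversity-aware sub-sampling (DAS): greedy farthest-point selection.

The pairwise metric is the rigid-superposition RMSD (optimal rotation +
translation, Kabsch).  Starting from a seed structure, the selector
first picks the pool geometry nearest the seed and then repeatedly
picks the geometry that maximizes its minimum RMSD to everything
already selected (greedy maximin, ties broken by lowest pool index).
The selected subset therefore preserves the structural diversity of
the pool: its directed Hausdorff distance to the pool is non-increasing
as more items are selected.
"""

from __future__ import annotations

import numpy as np

from .io import Geometry


def superposed_rmsd(coords_a, coords_b) -> float:
    """RMSD (Å) after optimal rigid superposition (Kabsch).

    The optimal proper rotation comes from the SVD of the covariance
    matrix; the residual is evaluated explicitly on the rotated
    coordinates, so identical or rigidly rotated inputs give an RMSD at
    machine precision.
    """
    P = np.asarray(coords_a, float)
    Q = np.asarray(coords_b, float)
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    U, _, Vt = np.linalg.svd(P.T @ Q)
    d = np.sign(np.linalg.det(U @ Vt))
    R = U @ np.diag([1.0, 1.0, d]) @ Vt
    return float(np.sqrt(np.mean(np.sum((P - Q @ R.T) ** 2, axis=1))))


def rmsd(a: Geometry, b: Geometry, heavy_only: bool = False) -> float:
    """Superposition RMSD between two geometries (Å)."""
    if a.elements != b.elements:
        raise ValueError("element lists differ")
    if heavy_only:
        sel = [i for i, e in enumerate(a.elements) if e != "H"]
        if not sel:
            raise ValueError("no heavy atoms for heavy-only RMSD")
        return superposed_rmsd(a.coords[sel], b.coords[sel])
    return superposed_rmsd(a.coords, b.coords)


def das_select(
    pool,
    seed_geometry: Geometry,
    k: int,
    heavy_only: bool = False,
) -> list[int]:
    """Greedy farthest-point selection of ``k`` pool indices.

    The seed geometry anchors the selection (it is treated as already
    selected but is not part of the returned indices): the first pick is
    the pool item nearest the seed, every later pick maximizes the
    minimum RMSD to the selected set.  Deterministic; ties break toward
    the lowest pool index.
    """
    pool = list(pool)
    if not pool:
        raise ValueError("empty pool")
    if not (1 <= k <= len(pool)):
        raise ValueError(f"k={k} must be in [1, {len(pool)}]")

    d_seed = np.array([rmsd(seed_geometry, g, heavy_only) for g in pool])
    first = int(np.argmin(d_seed))
    selected = [first]
    # min distance of every pool item to the selected set; selected items
    # are marked -1 so exact duplicates (min-dist 0) still rank above them
    min_dist = np.array([rmsd(pool[first], g, heavy_only) for g in pool])
    min_dist[first] = -1.0
    while len(selected) < k:
        nxt = int(np.argmax(min_dist))  # argmax takes the first max -> lowest index
        selected.append(nxt)
        d_new = np.array([rmsd(pool[nxt], g, heavy_only) for g in pool])
        min_dist = np.minimum(min_dist, d_new)
        min_dist[nxt] = -1.0
    return selected


def directed_hausdorff(pool, selected_indices, heavy_only: bool = False) -> float:
    """max over pool of the min RMSD to the selected set (coverage)."""
    sel = [pool[i] for i in selected_indices]
    return max(min(rmsd(g, s, heavy_only) for s in sel) for g in pool)
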