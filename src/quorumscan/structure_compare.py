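"""Structural superposition, RMSD matrices, networks and dendrograms.

CA-only Kabsch least-squares superposition over matched residue-range
selections; pairwise RMSD matrices feed a thresholded interaction network
and agglomerative dendrograms (UPGMA default, neighbor-joining optional,
optional midpoint rooting). A greedy identity/coverage clustering of
protein sequences (95%/95% by default) is provided for redundancy removal.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from ._align import global_align
from ._alphabet import encode_protein


@dataclasses.dataclass
class StructureSelection:
    structure_id: str
    chain: str
    residue_ranges: list[tuple[int, int]]  # inclusive residue-number ranges
    coords: np.ndarray  # (n, 3) CA coordinates

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n, 3)")
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")


@dataclasses.dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("matrix diagonal must be zero")
        if (m < -1e-12).any():
            raise ValueError("matrix must be non-negative")
        self.matrix = m


@dataclasses.dataclass
class Dendrogram:
    newick: str
    labels: list[str]
    method: str
    rooting: str


def selection_from_pdb(
    path: str,
    structure_id: str,
    chain: str,
    residue_ranges: Sequence[tuple[int, int]],
) -> StructureSelection:
    """CA coordinates of the given chain/residue ranges from a PDB/mmCIF file
    (first altloc, first model)."""
    from Bio.PDB import MMCIFParser, PDBParser

    parser = (
        MMCIFParser(QUIET=True) if str(path).endswith(".cif") else PDBParser(QUIET=True)
    )
    structure = parser.get_structure(structure_id, str(path))
    model = next(structure.get_models())
    coords = []
    wanted = [(int(a), int(b)) for a, b in residue_ranges]
    for residue in model[chain]:
        num = residue.id[1]
        if any(a <= num <= b for a, b in wanted) and "CA" in residue:
            coords.append(residue["CA"].get_coord())
    return StructureSelection(structure_id, chain, wanted, np.array(coords))


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------


def kabsch_superpose(
    coords_a: np.ndarray, coords_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of B onto A.

    Returns ``(rotation, translation, rmsd)`` with a proper rotation
    (det = +1) minimising RMSD over all rigid transforms of B.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"point counts differ: {A.shape} vs {B.shape}")
    if A.ndim != 2 or A.shape[1] != 3 or A.shape[0] < 3:
        raise ValueError("need >= 3 points of dimension 3")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    if np.linalg.matrix_rank(A0, tol=1e-9) < 2 or np.linalg.matrix_rank(B0, tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) point set")
    H = B0.T @ A0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    diff = A - (B @ R.T + t)
    rmsd = float(np.sqrt((diff**2).sum() / A.shape[0]))
    return R, t, rmsd


def rmsd_matrix(selections: Sequence[StructureSelection]) -> DistanceMatrix:
    """Pairwise least-squares RMSD between all selections."""
    n = len(selections)
    for i in range(n):
        for j in range(i + 1, n):
            if selections[i].coords.shape != selections[j].coords.shape:
                raise ValueError(
                    "incomparable selections: "
                    f"{selections[i].structure_id} ({selections[i].coords.shape[0]} CA) "
                    f"vs {selections[j].structure_id} "
                    f"({selections[j].coords.shape[0]} CA)"
                )
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, r = kabsch_superpose(selections[i].coords, selections[j].coords)
            m[i, j] = m[j, i] = r
    return DistanceMatrix([s.structure_id for s in selections], m)


def build_network(
    matrix: DistanceMatrix, threshold: float | None = None
) -> list[tuple[str, str, float]]:
    """Undirected edges (i, j, distance) for pairs at or below threshold.

    Default threshold: the median off-diagonal distance (reported via the
    returned edges only; pass an explicit value for reproducible cuts).
    """
    m = matrix.matrix
    if threshold is None:
        off = m[np.triu_indices_from(m, k=1)]
        threshold = float(np.median(off)) if off.size else 0.0
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    edges = []
    for i in range(len(matrix.labels)):
        for j in range(i + 1, len(matrix.labels)):
            if m[i, j] <= threshold:
                edges.append((matrix.labels[i], matrix.labels[j], float(m[i, j])))
    return edges


# ---------------------------------------------------------------------------
# dendrograms
# ---------------------------------------------------------------------------


def _upgma(labels: list[str], m: np.ndarray) -> str:
    """UPGMA with deterministic lexicographic tie-breaking; returns newick."""
    clusters = {i: (labels[i],) for i in range(len(labels))}
    newick = {i: labels[i] for i in range(len(labels))}
    heights = {i: 0.0 for i in range(len(labels))}
    sizes = {i: 1 for i in range(len(labels))}
    dist = {
        (i, j): float(m[i, j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    }
    next_id = len(labels)
    active = set(range(len(labels)))
    while len(active) > 1:
        best = None
        for (i, j), d in dist.items():
            key = (d, tuple(sorted(clusters[i] + clusters[j])))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        d = dist[(i, j)]
        h = d / 2.0
        a, b = sorted((i, j), key=lambda k: clusters[k])
        node = (
            f"({newick[a]}:{h - heights[a]:.10g},{newick[b]}:{h - heights[b]:.10g})"
        )
        k = next_id
        next_id += 1
        clusters[k] = tuple(sorted(clusters[i] + clusters[j]))
        newick[k] = node
        heights[k] = h
        sizes[k] = sizes[i] + sizes[j]
        for other in list(active):
            if other in (i, j):
                continue
            dij = lambda x, y: dist[(min(x, y), max(x, y))]
            d_new = (
                sizes[i] * dij(i, other) + sizes[j] * dij(j, other)
            ) / (sizes[i] + sizes[j])
            dist[(min(other, k), max(other, k))] = d_new
        active.discard(i)
        active.discard(j)
        active.add(k)
        dist = {
            (x, y): v for (x, y), v in dist.items() if x in active and y in active
        }
    root = active.pop()
    return newick[root] + ";"


def _nj(labels: list[str], m: np.ndarray) -> str:
    """Neighbor joining with lexicographic tie-breaking; returns an unrooted
    newick (trifurcating root). Exact branch lengths for additive matrices."""
    ids = list(range(len(labels)))
    leafset = {i: (labels[i],) for i in ids}
    newick = {i: labels[i] for i in ids}
    D = {(i, j): float(m[i, j]) for i in ids for j in ids if i < j}

    def d(i, j):
        return 0.0 if i == j else D[(min(i, j), max(i, j))]

    next_id = len(labels)
    while len(ids) > 3:
        n = len(ids)
        r = {i: sum(d(i, k) for k in ids) for i in ids}
        best = None
        for ii in range(n):
            for jj in range(ii + 1, n):
                i, j = ids[ii], ids[jj]
                q = (n - 2) * d(i, j) - r[i] - r[j]
                key = (q, tuple(sorted(leafset[i] + leafset[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * d(i, j) + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d(i, j) - li
        a, b = sorted((i, j), key=lambda x: leafset[x])
        la, lb = (li, lj) if a == i else (lj, li)
        k = next_id
        next_id += 1
        newick[k] = f"({newick[a]}:{la:.10g},{newick[b]}:{lb:.10g})"
        leafset[k] = tuple(sorted(leafset[i] + leafset[j]))
        for other in ids:
            if other in (i, j):
                continue
            D[(min(other, k), max(other, k))] = 0.5 * (
                d(i, other) + d(j, other) - d(i, j)
            )
        ids = [x for x in ids if x not in (i, j)] + [k]
    i, j, k = sorted(ids, key=lambda x: leafset[x])
    li = 0.5 * (d(i, j) + d(i, k) - d(j, k))
    lj = 0.5 * (d(i, j) + d(j, k) - d(i, k))
    lk = 0.5 * (d(i, k) + d(j, k) - d(i, j))
    return (
        f"({newick[i]}:{li:.10g},{newick[j]}:{lj:.10g},{newick[k]}:{lk:.10g});"
    )


def build_dendrogram(
    matrix: DistanceMatrix, method: str = "upgma", rooting: str = "none"
) -> Dendrogram:
    """Agglomerate a distance matrix into a dendrogram (newick).

    ``method``: 'upgma' or 'nj'; ``rooting``: 'none' or 'midpoint'
    (midpoint rooting delegates to dendropy).
    """
    if len(matrix.labels) < 3:
        raise ValueError("need at least 3 taxa")
    if method == "upgma":
        nwk = _upgma(matrix.labels, matrix.matrix)
    elif method == "nj":
        nwk = _nj(matrix.labels, matrix.matrix)
    else:
        raise ValueError(f"unknown method {method!r}")
    if rooting == "midpoint":
        import dendropy

        tree = dendropy.Tree.get(data=nwk, schema="newick")
        tree.reroot_at_midpoint(update_bipartitions=False)
        nwk = tree.as_string(schema="newick", suppress_rooting=True).strip()
    elif rooting != "none":
        raise ValueError(f"unknown rooting {rooting!r}")
    return Dendrogram(
        newick=nwk, labels=list(matrix.labels), method=method, rooting=rooting
    )


# ---------------------------------------------------------------------------
# greedy sequence clustering
# ---------------------------------------------------------------------------


def greedy_cluster(
    sequences: Mapping[str, str],
    identity: float = 0.95,
    coverage: float = 0.95,
) -> tuple[list[str], dict[str, str]]:
    """Single-pass greedy clustering, longest sequences first.

    Each sequence joins the first existing representative it matches at
    >= ``identity`` (matches / global-alignment columns) with length
    coverage >= ``coverage`` (shorter / longer length); otherwise it founds
    a new cluster. Returns (representatives, member -> representative).
    """
    if not sequences:
        raise ValueError("empty input")
    order = sorted(sequences, key=lambda k: (-len(sequences[k]), k))
    reps: list[str] = []
    encoded: dict[str, np.ndarray] = {}
    membership: dict[str, str] = {}
    for sid in order:
        seq = sequences[sid]
        enc = encode_protein(seq)
        placed = False
        for rep in reps:
            la, lb = len(sequences[rep]), len(seq)
            cov = min(la, lb) / max(la, lb)
            if cov < coverage:
                continue
            _, matches, cols = global_align(encoded[rep], enc)
            if cols and matches / cols >= identity:
                membership[sid] = rep
                placed = True
                break
        if not placed:
            reps.append(sid)
            encoded[sid] = enc
            membership[sid] = sid
    return reps, membership
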