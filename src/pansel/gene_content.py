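"""Gene-content analysis: presence/absence matrix, Jaccard distances, UPGMA tree.

The gene-content tree summarises genome relatedness including accessory
genes: genomes are rows of a binary genomes x families matrix, their
pairwise dissimilarity is the Jaccard distance 1 - |A∩B|/|A∪B| on
family sets, and average-linkage (UPGMA) clustering of that matrix gives
an ultrametric tree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pangenome import GeneFamily
from .tree import PhyloTree, TreeNode


@dataclass
class PresenceAbsenceMatrix:
    genome_ids: list[str]
    family_ids: list[str]
    values: np.ndarray  # shape (genomes, families), entries 0/1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.genome_ids), len(self.family_ids)):
            raise ValueError("matrix shape does not match label lists")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("presence/absence entries must be 0 or 1")
        empty = [g for g, row in zip(self.genome_ids, self.values) if row.sum() == 0]
        if empty:
            raise ValueError(f"genome(s) with no families: {empty}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genome_ids, columns=self.family_ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="genome")

    @classmethod
    def from_tsv(cls, path) -> "PresenceAbsenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), list(df.columns), df.to_numpy())


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if np.isnan(self.d).any():
            raise ValueError("NaN in distance matrix")
        if (self.d < 0).any():
            raise ValueError("negative distances")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("non-zero diagonal")

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.d[i, j])


def presence_matrix(families: list[GeneFamily], genome_ids: list[str]) -> PresenceAbsenceMatrix:
    """Binary genomes x families matrix; entry 1 iff the genome hosts a member."""
    fam_ids = [f.family_id for f in families]
    if len(fam_ids) != len(set(fam_ids)):
        raise ValueError("duplicate family_ids")
    known = set(genome_ids)
    values = np.zeros((len(genome_ids), len(families)), dtype=np.int8)
    gidx = {g: i for i, g in enumerate(genome_ids)}
    for j, fam in enumerate(families):
        missing = fam.genomes_present - known
        if missing:
            raise ValueError(f"family {fam.family_id} names unknown genomes {sorted(missing)}")
        for g in fam.genomes_present:
            values[gidx[g], j] = 1
    return PresenceAbsenceMatrix(list(genome_ids), fam_ids, values)


def jaccard_distance(matrix: PresenceAbsenceMatrix) -> DistanceMatrix:
    """Pairwise 1 - Jaccard coefficient between genome family sets."""
    if len(matrix.genome_ids) < 2:
        raise ValueError("need at least 2 genomes")
    X = matrix.values.astype(bool)
    n = X.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = np.logical_or(X[i], X[j]).sum()
            if union == 0:
                warnings.warn(f"genomes {matrix.genome_ids[i]} and {matrix.genome_ids[j]} "
                              "share an empty family union; distance set to 0")
                dij = 0.0
            else:
                inter = np.logical_and(X[i], X[j]).sum()
                dij = 1.0 - inter / union
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(list(matrix.genome_ids), d)


def upgma(dm: DistanceMatrix) -> PhyloTree:
    """Average-linkage hierarchical clustering into an ultrametric tree.

    Repeatedly merges the closest pair of clusters; the new node sits at
    height d/2 and subsequent distances are size-weighted averages.  Ties
    are broken by the lexicographically smallest (label, label) pair, so
    output is deterministic.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need at least 2 labels")
    # cluster state: key -> (node, size, height, min_label)
    nodes: dict[int, tuple[TreeNode, int, float, str]] = {}
    for i, lab in enumerate(dm.labels):
        nodes[i] = (TreeNode(lab), 1, 0.0, lab)
    dist: dict[frozenset[int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((i, j))] = float(dm.d[i, j])

    next_key = n
    while len(nodes) > 1:
        best = None
        for key, dij in dist.items():
            i, j = sorted(key, key=lambda k: nodes[k][3])
            tag = (dij, nodes[i][3], nodes[j][3])
            if best is None or tag < best[0]:
                best = (tag, i, j)
        (dij, _, _), i, j = best
        ni, si, hi, mi = nodes[i]
        nj, sj, hj, mj = nodes[j]
        height = dij / 2.0
        ni.length = max(height - hi, 0.0)
        nj.length = max(height - hj, 0.0)
        parent = TreeNode()
        parent.add_child(ni)
        parent.add_child(nj)
        new_min = min(mi, mj)
        for k in list(nodes):
            if k in (i, j):
                continue
            dik = dist.pop(frozenset((i, k)))
            djk = dist.pop(frozenset((j, k)))
            dist[frozenset((next_key, k))] = (si * dik + sj * djk) / (si + sj)
        dist.pop(frozenset((i, j)))
        del nodes[i], nodes[j]
        nodes[next_key] = (parent, si + sj, height, new_min)
        next_key += 1

    root = next(iter(nodes.values()))[0]
    return PhyloTree(root)
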