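"""Ortholog-family construction and pan-genome partitioning.

Proteomes are compared all-against-all by exact global alignment
(affine gaps, BLOSUM62), pairs passing identity and coverage thresholds
form a weighted similarity graph, and Markov clustering (MCL) of that
graph yields gene families.  Families are then classed as *core*
(present in every genome), *distributed* (2..n-1 genomes) or *unique*
(one genome).

A fast edit-distance prescreen (edlib) discards pairs whose identity
upper bound cannot reach the threshold before the exact alignment is
computed; the bound is exact, so the resulting graph is identical to the
one from aligning every pair.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import edlib
import networkx as nx
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from ._seq import translate_cds, validate_protein

QUALIFIER = "|"


def qualify(genome_id: str, gene_id: str) -> str:
    return f"{genome_id}{QUALIFIER}{gene_id}"


def split_qualified(qid: str) -> tuple[str, str]:
    genome, _, gene = qid.partition(QUALIFIER)
    return genome, gene


# --------------------------------------------------------------------------- types
@dataclass
class Proteome:
    """Per-genome protein and CDS sequences with matching gene ids."""

    genome_id: str
    proteins: list[tuple[str, str]]
    cds: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [g for g, _ in self.proteins]
        if len(ids) != len(set(ids)):
            dup = sorted({g for g in ids if ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids in genome {self.genome_id}: {dup}")
        cds_map = dict(self.cds)
        for gene_id, prot in self.proteins:
            if gene_id in cds_map:
                if translate_cds(cds_map[gene_id]) != prot.upper():
                    raise ValueError(
                        f"CDS of {self.genome_id}{QUALIFIER}{gene_id} does not translate to its protein"
                    )

    @property
    def cds_map(self) -> dict[str, str]:
        return dict(self.cds)


@dataclass(frozen=True)
class SimilarityEdge:
    gene_a: str
    gene_b: str
    identity: float
    coverage: float
    score: float

    def __post_init__(self) -> None:
        if not (0 <= self.identity <= 100 and 0 <= self.coverage <= 100):
            raise ValueError("identity and coverage must lie in [0, 100]")


@dataclass
class ClusteringConfig:
    min_protein_len: int = 50      # residues; proteins must be strictly longer
    min_identity: float = 70.0     # percent
    min_coverage: float = 70.0     # percent
    inflation: float = 2.0
    mcl_max_iter: int = 200
    mcl_convergence_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("MCL inflation must be > 1")
        for name in ("min_identity", "min_coverage"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must lie in [0, 100]")


@dataclass
class GeneFamily:
    family_id: str
    members: list[str]
    genomes_present: set[str] = field(default_factory=set)
    converged: bool = True

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"family {self.family_id} has no members")
        derived = {split_qualified(m)[0] for m in self.members}
        if not self.genomes_present:
            self.genomes_present = derived
        elif self.genomes_present != derived:
            raise ValueError(f"genomes_present inconsistent with members in {self.family_id}")


@dataclass
class PanGenomePartition:
    core: set[str]
    distributed: set[str]
    unique: set[str]
    n_genomes: int

    @property
    def counts(self) -> dict[str, int]:
        return {"core": len(self.core), "distributed": len(self.distributed),
                "unique": len(self.unique)}


# --------------------------------------------------------------------------- alignment
def _default_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def pairwise_similarity(a: str, b: str, aligner: Align.PairwiseAligner | None = None,
                        *, gene_a: str = "a", gene_b: str = "b") -> SimilarityEdge:
    """Globally align two protein sequences and report identity/coverage/score.

    identity  — identical residue pairs / alignment columns (no dual gaps in a
                global pairwise alignment), as a percentage;
    coverage  — ``100 * min(aligned_a/len(a), aligned_b/len(b))`` where
                *aligned* counts residues matched to a residue of the partner.
    """
    a, b = a.upper(), b.upper()
    if not a or not b:
        raise ValueError("empty protein sequence")
    validate_protein(a)
    validate_protein(b)
    if aligner is None:
        aligner = _default_aligner()
    aln = aligner.align(a, b)[0]
    blocks_a, blocks_b = aln.aligned
    aligned = int(sum(e - s for s, e in blocks_a))
    matches = 0
    for (sa, ea), (sb, _) in zip(blocks_a, blocks_b):
        matches += sum(a[sa + k] == b[sb + k] for k in range(ea - sa))
    n_columns = aln.length
    identity = 100.0 * matches / n_columns
    coverage = 100.0 * min(aligned / len(a), aligned / len(b))
    return SimilarityEdge(gene_a, gene_b, identity, coverage, float(aln.score))


def _prescreen(a: str, b: str, min_identity: float, min_coverage: float) -> bool:
    """Cheap exact upper bounds on identity and coverage; True = pair may pass."""
    la, lb = len(a), len(b)
    if 100.0 * min(la, lb) / max(la, lb) < min_coverage:
        return False
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    # any alignment with m matches over L columns has L - m >= edit distance
    # and L <= la + lb, hence identity <= 1 - d/(la+lb)
    return 100.0 * (1.0 - d / (la + lb)) >= min_identity


def build_similarity_graph(proteomes: list[Proteome], config: ClusteringConfig | None = None,
                           *, precomputed: list[SimilarityEdge] | None = None) -> nx.Graph:
    """Thresholded all-against-all similarity graph over qualified gene ids.

    Nodes are proteins strictly longer than ``min_protein_len``; an edge is
    present iff identity and coverage both reach their thresholds.  Paralog
    (within-genome) pairs are compared like any other pair.
    """
    if config is None:
        config = ClusteringConfig()
    if len(proteomes) < 2:
        raise ValueError("need at least 2 proteomes")
    graph = nx.Graph()
    seqs: dict[str, str] = {}
    for p in proteomes:
        for gene_id, seq in p.proteins:
            if len(seq) > config.min_protein_len:
                qid = qualify(p.genome_id, gene_id)
                graph.add_node(qid, genome=p.genome_id)
                seqs[qid] = seq.upper()
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph: every protein fell below the length threshold")

    if precomputed is not None:
        for e in precomputed:
            if (e.identity >= config.min_identity and e.coverage >= config.min_coverage
                    and e.gene_a in seqs and e.gene_b in seqs and e.gene_a != e.gene_b):
                graph.add_edge(e.gene_a, e.gene_b, weight=e.score,
                               identity=e.identity, coverage=e.coverage)
        return graph

    aligner = _default_aligner()
    for qa, qb in itertools.combinations(sorted(seqs), 2):
        a, b = seqs[qa], seqs[qb]
        if not _prescreen(a, b, config.min_identity, config.min_coverage):
            continue
        edge = pairwise_similarity(a, b, aligner, gene_a=qa, gene_b=qb)
        if edge.identity >= config.min_identity and edge.coverage >= config.min_coverage:
            graph.add_edge(qa, qb, weight=max(edge.score, 1e-6),
                           identity=edge.identity, coverage=edge.coverage)
    return graph


# --------------------------------------------------------------------------- MCL
def _mcl_component(nodes: list[str], graph: nx.Graph, config: ClusteringConfig
                   ) -> tuple[list[list[str]], bool]:
    n = len(nodes)
    if n == 1:
        return [nodes], True
    idx = {v: i for i, v in enumerate(nodes)}
    M = np.zeros((n, n))
    for u, v, data in graph.subgraph(nodes).edges(data=True):
        w = float(data.get("weight", 1.0))
        M[idx[u], idx[v]] = M[idx[v], idx[u]] = w
    # self-loops at the node's maximum incident weight stabilise the iteration
    loops = M.max(axis=0)
    np.fill_diagonal(M, np.where(loops > 0, loops, 1.0))
    M /= M.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(config.mcl_max_iter):
        expanded = M @ M
        inflated = expanded ** config.inflation
        colsum = inflated.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        inflated /= colsum
        inflated[inflated < 1e-12] = 0.0
        if np.max(np.abs(inflated - M)) < config.mcl_convergence_tol:
            M = inflated
            converged = True
            break
        M = inflated
    # attractor reading: connected components of the non-zero support
    support = nx.Graph()
    support.add_nodes_from(range(n))
    rows, cols = np.nonzero(M > 1e-9)
    support.add_edges_from(zip(rows.tolist(), cols.tolist()))
    clusters = [[nodes[i] for i in comp] for comp in nx.connected_components(support)]
    return clusters, converged


def mcl_cluster(graph: nx.Graph, config: ClusteringConfig | None = None) -> list[GeneFamily]:
    """Markov clustering of the similarity graph into gene families.

    Expansion (matrix squaring) alternates with inflation (entry-wise power
    and column renormalisation) until the matrix is stable; clusters are the
    connected components of the converged matrix's support.  Isolated nodes
    become singleton families.  Clustering each connected component
    separately is exact: MCL never joins disconnected components.
    """
    if config is None:
        config = ClusteringConfig()
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot cluster an empty graph")
    clusters: list[tuple[list[str], bool]] = []
    for comp in nx.connected_components(graph):
        for cluster, ok in zip(*_transpose(_mcl_component(sorted(comp), graph, config))):
            clusters.append((cluster, ok))
    clusters.sort(key=lambda c: min(c[0]))
    families = []
    n_bad = 0
    for i, (members, ok) in enumerate(clusters, start=1):
        families.append(GeneFamily(f"F{i:05d}", sorted(members), converged=ok))
        n_bad += not ok
    if n_bad:
        warnings.warn(f"MCL did not converge for {n_bad} component(s); "
                      "best-effort clusters flagged converged=False")
    return families


def _transpose(pair):
    clusters, ok = pair
    return clusters, [ok] * len(clusters)


# --------------------------------------------------------------------------- partition
def classify_pangenome(families: list[GeneFamily], n_genomes: int) -> PanGenomePartition:
    """Partition families into core / distributed / unique by genome presence."""
    if n_genomes < 2:
        raise ValueError("n_genomes must be >= 2")
    core, distributed, unique = set(), set(), set()
    for fam in families:
        k = len(fam.genomes_present)
        if k == 0:
            raise ValueError(f"family {fam.family_id} has empty genomes_present")
        if k > n_genomes:
            raise ValueError(f"family {fam.family_id} present in more genomes than exist")
        if k == n_genomes:
            core.add(fam.family_id)
        elif k == 1:
            unique.add(fam.family_id)
        else:
            distributed.add(fam.family_id)
    return PanGenomePartition(core, distributed, unique, n_genomes)


def subset_venn_counts(families: list[GeneFamily], genome_subset: set[str],
                       known_genomes: set[str] | None = None) -> dict[frozenset[str], int]:
    """Count families by exact presence pattern over a genome subset.

    The all-members pattern is the shared core of the subset.  Families
    absent from every subset genome are not counted.
    """
    if not genome_subset:
        raise ValueError("genome_subset must be non-empty")
    known = known_genomes if known_genomes is not None else \
        set().union(*(f.genomes_present for f in families))
    unknown = genome_subset - known
    if unknown:
        raise ValueError(f"unknown genome ids: {sorted(unknown)}")
    counts: dict[frozenset[str], int] = {}
    for fam in families:
        pattern = frozenset(fam.genomes_present & genome_subset)
        if pattern:
            counts[pattern] = counts.get(pattern, 0) + 1
    return counts


# --------------------------------------------------------------------------- IO
def write_families_tsv(families: list[GeneFamily], path) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\tgenome_id\tgene_id\n")
        for fam in families:
            for member in fam.members:
                genome, gene = split_qualified(member)
                fh.write(f"{fam.family_id}\t{genome}\t{gene}\n")


def read_families_tsv(path) -> list[GeneFamily]:
    groups: dict[str, list[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            fam_id, genome, gene = line.rstrip("\n").split("\t")
            groups.setdefault(fam_id, []).append(qualify(genome, gene))
    return [GeneFamily(fid, sorted(members)) for fid, members in sorted(groups.items())]


def read_similarity_tsv(path) -> list[SimilarityEdge]:
    edges = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            ga, gb, ident, cov, score = line.rstrip("\n").split("\t")
            edges.append(SimilarityEdge(ga, gb, float(ident), float(cov), float(score)))
    return edges
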