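"""Synthetic inputs with known ground truth for every pipeline stage.

Emulates, at desk scale, the data behind a multi-strain comparative-genomics
study: proteomes with planted ortholog families, gene presence/absence
produced by a gain/loss process on a known tree, codon alignments evolved
under neutral, purifying or positively selected regimes, and back-slopped
competition series with a planted relative fitness.

All generators are pure functions of (config, seed); independent random
substreams (numpy SeedSequence spawning) keep the regimes decoupled, so
changing one simulation never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._likelihood import ReversibleGenerator
from ._seq import CODON_TO_AA, SENSE_CODONS
from .core_phylogeny import CodonAlignment
from .fitness import CompetitionSeries, StandardCurve, apply_detection_limit
from .gene_content import PresenceAbsenceMatrix
from .pangenome import Proteome, qualify
from .selection import (CodonModelParams, branch_site_params, m1a_params,
                        m2a_params, uniform_codon_frequencies)
from .tree import PhyloTree, TreeNode


# --------------------------------------------------------------------------- config
@dataclass
class CompetitionConfig:
    w_true: float = 1.4
    cycles: int = 10
    inoculum_fraction: float = 0.05     # 1 g ripe dough into ~20 g fresh
    noise_sd: float = 0.05              # lognormal sd on measurements
    detection_limit: float = 1e2
    start_abundance: float = 1e7        # copies or CFU per g at inoculation
    growth_factor_y: float | None = None  # set to bypass the capacity model
                                          # with a fixed reference growth factor


@dataclass
class SimConfig:
    """Study conditions for the synthetic analogue of the 16-genome study."""

    seed: int
    n_genomes: int = 6
    gain_rate: float = 0.7      # events per unit branch length
    loss_rate: float = 0.7
    n_core_families: int = 200
    n_accessory_families: int = 300
    n_selected_genes: int = 3   # core genes planted under branch-site selection
    codon_length: int = 100      # codons per core gene (> 50-aa protein filter)
    kappa: float = 2.0
    omega_background: float = 0.2
    omega_selected: float = 10.0
    p_selected_sites: float = 0.3
    foreground: tuple[str, ...] = ("G4", "G5", "G6")
    tree: PhyloTree | None = None  # default: fixed 6-leaf genome tree


def paper_mini(seed: int) -> SimConfig:
    """The default desk-scale fixture: 6 genomes, 200 core + 300 accessory
    families, 3 genes under branch-site selection on a 3-leaf clade."""
    return SimConfig(seed=seed)


def fixed_genome_tree(n_genomes: int = 6) -> PhyloTree:
    """Fixed ultrametric genome tree; the (G4,G5,G6) clade mirrors the
    sourdough-lineage foreground of the real study."""
    if n_genomes == 6:
        newick = ("(((G1:0.04,G2:0.04):0.03,G3:0.07):0.05,"
                  "((G4:0.12,G5:0.12):0.05,G6:0.05):0.15);")
    elif n_genomes == 8:
        newick = ("(((t1:0.1,t2:0.1):0.15,(t3:0.15,t4:0.15):0.1):0.25,"
                  "((t5:0.12,t6:0.12):0.18,(t7:0.2,t8:0.2):0.1):0.2);")
    else:
        raise ValueError("fixed trees are provided for 6 or 8 genomes")
    return PhyloTree.from_newick(newick)


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# --------------------------------------------------------------------------- gene content
@dataclass
class GeneContentTruth:
    tree: PhyloTree
    matrix: PresenceAbsenceMatrix
    n_events: int
    dropped_families: list[str] = field(default_factory=list)


def _gain_loss_column(tree: PhyloTree, gain: float, loss: float,
                      rng: np.random.Generator) -> tuple[dict[str, int], int]:
    """One two-state (0 absent / 1 present) CTMC realisation along the tree.

    Jump times are simulated explicitly so realised event counts are exact.
    Root state is stationary.  Returns (leaf states, number of events).
    """
    total = gain + loss
    root_state = int(rng.random() < (gain / total)) if total > 0 else 1
    events = 0
    states: dict[str, int] = {}

    def walk(node: TreeNode, state: int) -> None:
        nonlocal events
        t = node.length or 0.0
        while t > 0:
            rate = gain if state == 0 else loss
            if rate <= 0:
                break
            wait = rng.exponential(1.0 / rate)
            if wait >= t:
                break
            state = 1 - state
            events += 1
            t -= wait
        if node.is_leaf:
            states[node.label] = state
        for child in node.children:
            walk(child, state)

    for child in tree.root.children:
        walk(child, root_state)
    if tree.root.is_leaf:
        states[tree.root.label] = root_state
    return states, events


def simulate_gene_content(config: SimConfig) -> tuple[PresenceAbsenceMatrix, GeneContentTruth]:
    """Presence/absence matrix from gain/loss evolution of accessory families.

    Core families are present everywhere; each accessory family evolves as a
    two-state process with the configured gain and loss rates.  Families
    observed in no genome are dropped (they cannot be observed) and listed
    in the truth record.
    """
    tree = config.tree or fixed_genome_tree(config.n_genomes)
    (rng,) = _substreams(config.seed, 1)
    genomes = sorted(tree.leaf_labels())
    fam_ids, columns, dropped = [], [], []
    n_events = 0
    for i in range(config.n_core_families):
        fam_ids.append(f"C{i + 1:04d}")
        columns.append([1] * len(genomes))
    for i in range(config.n_accessory_families):
        fid = f"A{i + 1:04d}"
        states, ev = _gain_loss_column(tree, config.gain_rate, config.loss_rate, rng)
        n_events += ev
        col = [states[g] for g in genomes]
        if sum(col) == 0:
            dropped.append(fid)
        else:
            fam_ids.append(fid)
            columns.append(col)
    values = np.array(columns, dtype=np.int8).T
    matrix = PresenceAbsenceMatrix(genomes, fam_ids, values)
    return matrix, GeneContentTruth(tree, matrix, n_events, dropped)


# --------------------------------------------------------------------------- codon alignments
@dataclass
class CodonAlignmentTruth:
    tree: PhyloTree
    params: CodonModelParams
    site_classes: np.ndarray  # per-site class index


def regime_params(regime: str, *, kappa: float = 2.0, omega0: float = 0.2,
                  p0: float = 0.8, omega2: float = 4.0, p2: float = 0.2,
                  freqs: np.ndarray | None = None) -> CodonModelParams:
    """True parameters for the named simulation regime."""
    F = uniform_codon_frequencies() if freqs is None else freqs
    if regime == "neutral":
        return CodonModelParams(kappa, F, [(1.0, 1.0, 1.0)], "M0")
    if regime == "purifying":
        return CodonModelParams(kappa, F, [(1.0, omega0, omega0)], "M0")
    if regime == "M1a":
        return m1a_params(p0, omega0, kappa, F)
    if regime == "M2a":
        p1 = max(1.0 - p0 - p2, 0.0)
        return m2a_params(p0, p1, omega0, omega2, kappa, F)
    if regime == "branch_site":
        p1 = max(1.0 - p0 - p2, 0.0)
        return branch_site_params(p0, p1, omega0, omega2, kappa, F)
    if regime == "branch_site_null":
        p1 = max(1.0 - p0 - p2, 0.0)
        return branch_site_params(p0, p1, omega0, 1.0, kappa, F, null=True)
    raise ValueError(f"unknown regime {regime!r}")


def simulate_codon_alignment(tree: PhyloTree, params: CodonModelParams,
                             n_codons: int, seed: int,
                             *, labels: list[str] | None = None
                             ) -> tuple[CodonAlignment, CodonAlignmentTruth]:
    """Evolve codon sites along the tree under a site-class mixture.

    Each site draws a class by its proportion; the root codon is stationary
    and substitutions follow the class's (foreground-aware) rate matrix.
    """
    if params.model_tag.startswith("branch_site") and \
            not any(n.foreground for n in tree.postorder()):
        raise ValueError("branch-site regime requires a foreground mark on the tree")
    rng = np.random.default_rng(seed)
    n_states = len(SENSE_CODONS)
    props = np.array([p for p, _, _ in params.site_classes])
    classes = rng.choice(len(props), size=n_codons, p=props / props.sum())

    # class generators share one time scale per branch type (the mixture's
    # average rate), matching the likelihood's convention
    from .selection import _gy_raw
    gens: dict[float, tuple[ReversibleGenerator, float]] = {}
    for _, wb, wf in params.site_classes:
        for w in (wb, wf):
            if w not in gens:
                Q, mu = _gy_raw(params.kappa, w, params.freqs)
                gens[w] = (ReversibleGenerator(Q / mu, params.freqs), mu)
    s_bg = sum(p * gens[wb][1] for p, wb, _ in params.site_classes)
    s_fg = sum(p * gens[wf][1] for p, _, wf in params.site_classes)

    states = {id(tree.root): rng.choice(n_states, size=n_codons, p=params.freqs)}
    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_states = states[id(node.parent)]
        child_states = parent_states.copy()
        t = node.length or 0.0
        if t > 0:
            for k, (_, wb, wf) in enumerate(params.site_classes):
                sel = classes == k
                if not sel.any():
                    continue
                if node.foreground:
                    gen, mu, s = *gens[wf], s_fg
                else:
                    gen, mu, s = *gens[wb], s_bg
                P = gen.transition_matrix(t * mu / s)
                cum = np.cumsum(P, axis=1)
                u = rng.random(sel.sum())
                rows = cum[parent_states[sel]]
                child_states[sel] = (u[:, None] < rows).argmax(axis=1)
        states[id(node)] = child_states

    leaf_order = labels if labels is not None else sorted(tree.leaf_labels())
    leaf_nodes = {n.label: n for n in tree.leaves()}
    rows = ["".join(SENSE_CODONS[s] for s in states[id(leaf_nodes[lab])])
            for lab in leaf_order]
    aln = CodonAlignment(list(leaf_order), rows)
    return aln, CodonAlignmentTruth(tree, params, classes)


# --------------------------------------------------------------------------- proteomes
@dataclass
class ProteomeTruth:
    tree: PhyloTree
    family_members: dict[str, list[str]]     # family id -> qualified gene ids
    presence: PresenceAbsenceMatrix
    selected_families: list[str]             # genes planted under selection
    alignments: dict[str, CodonAlignment]    # true per-family codon alignments
    site_classes: dict[str, np.ndarray]


def simulate_proteomes(config: SimConfig) -> tuple[list[Proteome], ProteomeTruth]:
    """Per-genome protein + CDS sets with planted ortholog families.

    Core families are codon alignments simulated on the genome tree (the
    planted selected genes use the branch-site regime on the configured
    foreground clade); accessory families follow the simulated gain/loss
    presence pattern.  Gene ids encode nothing about family membership.
    """
    tree = config.tree or fixed_genome_tree(config.n_genomes)
    rng_content, rng_seq = _substreams(config.seed, 2)
    genomes = sorted(tree.leaf_labels())
    content_cfg = replace(config, seed=int(rng_content.integers(2 ** 31)))
    presence, _ = simulate_gene_content(content_cfg)

    marked = tree.copy()
    if config.foreground:
        marked.mark_foreground(set(config.foreground) & set(genomes) or set(genomes[:1]),
                               clade=True)
    neutral = regime_params("purifying", kappa=config.kappa,
                            omega0=config.omega_background)
    selected = branch_site_params(
        1.0 - config.p_selected_sites - 0.05, 0.05, config.omega_background,
        config.omega_selected, config.kappa, uniform_codon_frequencies())

    fam_members: dict[str, list[str]] = {}
    alignments: dict[str, CodonAlignment] = {}
    site_classes: dict[str, np.ndarray] = {}
    selected_ids: list[str] = []
    per_genome_prot: dict[str, list[tuple[str, str]]] = {g: [] for g in genomes}
    per_genome_cds: dict[str, list[tuple[str, str]]] = {g: [] for g in genomes}
    counters = {g: 0 for g in genomes}

    for j, fid in enumerate(presence.family_ids):
        present = [g for g, v in zip(presence.genome_ids, presence.values[:, j]) if v]
        is_core = len(present) == len(genomes)
        is_selected = is_core and fid.startswith("C") and \
            len(selected_ids) < config.n_selected_genes and \
            j % max(config.n_core_families // max(config.n_selected_genes, 1), 1) == 0
        params = selected if is_selected else neutral
        aln, truth = simulate_codon_alignment(
            marked, params, config.codon_length, int(rng_seq.integers(2 ** 31)),
            labels=genomes)
        if is_selected:
            selected_ids.append(fid)
        alignments[fid] = aln
        site_classes[fid] = truth.site_classes
        members = []
        for g, row in zip(aln.labels, aln.rows):
            if g not in present:
                continue
            counters[g] += 1
            gene_id = f"{g.lower()}_{counters[g]:05d}"
            cds = row.replace("-", "")
            protein = "".join(CODON_TO_AA[cds[k:k + 3]] for k in range(0, len(cds), 3))
            per_genome_prot[g].append((gene_id, protein))
            per_genome_cds[g].append((gene_id, cds))
            members.append(qualify(g, gene_id))
        fam_members[fid] = members

    proteomes = [Proteome(g, per_genome_prot[g], per_genome_cds[g]) for g in genomes]
    truth = ProteomeTruth(marked, fam_members, presence, selected_ids,
                          alignments, site_classes)
    return proteomes, truth


def write_proteome_fastas(proteomes: list[Proteome], outdir) -> None:
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for p in proteomes:
        with open(outdir / f"{p.genome_id}.faa", "w") as fh:
            for gid, seq in p.proteins:
                fh.write(f">{gid}\n{seq}\n")
        with open(outdir / f"{p.genome_id}.fna", "w") as fh:
            for gid, seq in p.cds:
                fh.write(f">{gid}\n{seq}\n")


def read_proteome_fastas(indir) -> list[Proteome]:
    from pathlib import Path
    from Bio import SeqIO
    indir = Path(indir)
    proteomes = []
    for faa in sorted(indir.glob("*.faa")):
        genome = faa.stem
        proteins = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(faa, "fasta")]
        fna = indir / f"{genome}.fna"
        cds = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fna, "fasta")] \
            if fna.exists() else []
        proteomes.append(Proteome(genome, proteins, cds))
    return proteomes


# --------------------------------------------------------------------------- competition
@dataclass
class CompetitionTruth:
    w_true: float
    true_start: dict[str, list[float]]
    true_end: dict[str, list[float]]
    standard_curve: StandardCurve | None = None
    ct_end: dict[str, list[float]] | None = None  # Ct of uncensored end reads


def simulate_competition(config: CompetitionConfig, seed: int,
                         *, emit_ct: bool = False
                         ) -> tuple[CompetitionSeries, CompetitionTruth]:
    """Back-slopped competition with planted relative fitness.

    Within each cycle the strains grow to the substrate's carrying capacity
    (the total abundance returns to start_total / inoculum_fraction): strain
    y grows by a factor g and strain x by g**w_true, with g solved from the
    capacity constraint, so the realized log-growth ratio equals w_true
    exactly while the losing strain declines from cycle to cycle.  Dilution
    by the inoculum fraction links cycles; measurements get multiplicative
    lognormal noise and qPCR-style censoring below the detection limit.
    """
    from scipy.optimize import brentq

    if config.w_true <= 0:
        raise ValueError("w_true must be positive")
    if config.cycles < 1:
        raise ValueError("need at least one cycle")
    rng = np.random.default_rng(seed)
    capacity = 2.0 * config.start_abundance / config.inoculum_fraction
    if config.growth_factor_y is not None:
        capacity = None  # fixed reference growth instead of a capacity
    x, y = config.start_abundance, config.start_abundance
    true_start: dict[str, list[float]] = {"x": [], "y": []}
    true_end: dict[str, list[float]] = {"x": [], "y": []}
    meas_start: dict[str, list] = {"x": [], "y": []}
    meas_end: dict[str, list] = {"x": [], "y": []}
    truncated = False

    def measure(v: float):
        noisy = v * float(np.exp(rng.normal(0.0, config.noise_sd))) if config.noise_sd \
            else v
        return apply_detection_limit(noisy, config.detection_limit)

    w = config.w_true
    for _ in range(config.cycles):
        if min(x, y) < 1.0:
            truncated = True
            break
        if capacity is None:
            g = config.growth_factor_y
        else:
            # solve x * g**w + y * g = capacity for the cycle's growth factor
            g_hi = capacity / min(x, y) + 2.0
            g = brentq(lambda g_: x * g_ ** w + y * g_ - capacity, 1e-9, g_hi,
                       xtol=1e-12, rtol=1e-15)
        xf, yf = x * g ** w, y * g
        true_start["x"].append(x)
        true_start["y"].append(y)
        true_end["x"].append(xf)
        true_end["y"].append(yf)
        meas_start["x"].append(measure(x))
        meas_start["y"].append(measure(y))
        meas_end["x"].append(measure(xf))
        meas_end["y"].append(measure(yf))
        x, y = xf * config.inoculum_fraction, yf * config.inoculum_fraction

    series = CompetitionSeries("x", "y", meas_start, meas_end, source="qpcr",
                               detection_limit=config.detection_limit,
                               truncated=truncated)
    curve = ct_end = None
    if emit_ct:
        curve = StandardCurve(slope=-3.3219, intercept=38.0, r_squared=1.0)
        ct_end = {s: [curve.copies_to_ct(float(v)) for v in vals]
                  for s, vals in meas_end.items()}
    return series, CompetitionTruth(config.w_true, true_start, true_end,
                                    curve, ct_end)
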