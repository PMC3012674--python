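"""Seeded generators for synthetic genome panels, annotated genomes,
fragmented assemblies and tree-evolved alignments.

Each generator is deterministic given (config, seed) and returns a
machine-readable ground-truth record alongside the data, so recovery can be
asserted exactly.  One global seed fans out to independent per-generator
streams (via numpy SeedSequence with a fixed stream id per generator), so
changing one fixture leaves the others bit-identical.

The panel generator emulates the study design the comparative statistics
assume: a few hundred bacterial genomes of 2-10 Mbp whose category counts
grow linearly with genome size plus Gaussian noise, with one planted
outlier genome offset upward in every scored category.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import inventory as inv
from .annotation_io import CogAssignment, DomainHit, Gene, GenomeRecord
from .assembly_qc import CoverageTrack
from .panel_stats import PanelMatrix
from .phylo import Alignment, Node

_STREAM_IDS = {"panel": 1, "genome": 2, "assembly": 3, "alignment": 4}


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent generator for one fixture stream of a global seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _STREAM_IDS[stream]])
    )


# ---------------------------------------------------------------------------
# genome panel
# ---------------------------------------------------------------------------

@dataclass
class PanelSimConfig:
    """Linear count-vs-size panel with one planted outlier.

    Slopes/noise are per category, in genes per Mbp and genes respectively.
    One designated outlier genome is generated *at* ``outlier_offset_sd``
    panel-sd units above the panel mean in every category (panel sd = the
    empirical sd of the category's counts, which includes the size-driven
    spread).
    """

    n_genomes: int = 500
    size_min_bp: float = 2e6
    size_max_bp: float = 10e6
    slopes_per_mbp: dict = field(default_factory=lambda: {
        inv.TCS: 8.0, inv.TF: 26.0, inv.TRANSPORT: 50.0, inv.DEFENSE: 10.0,
    })
    noise_sd: dict = field(default_factory=lambda: {
        inv.TCS: 15.0, inv.TF: 40.0, inv.TRANSPORT: 60.0, inv.DEFENSE: 8.0,
    })
    outlier_offset_sd: float = 3.0


def gen_panel(
    cfg: PanelSimConfig | None = None, seed: int = 0
) -> tuple[PanelMatrix, dict]:
    """Panel of genomes with counts = round(slope * Mbp + noise), floored at 0."""
    if cfg is None:
        cfg = PanelSimConfig()
    if cfg.n_genomes < 2:
        raise ValueError("panel needs >= 2 genomes")
    rng = stream_rng(seed, "panel")
    ids = [f"G{i:04d}" for i in range(cfg.n_genomes)]
    sizes = rng.uniform(cfg.size_min_bp, cfg.size_max_bp, size=cfg.n_genomes)
    outlier_idx = int(rng.integers(cfg.n_genomes))
    counts = {}
    for cat, slope in cfg.slopes_per_mbp.items():
        sd = cfg.noise_sd[cat]
        x = slope * sizes / 1e6 + rng.normal(0.0, sd, size=cfg.n_genomes)
        if cfg.outlier_offset_sd:
            x[outlier_idx] = x.mean() + cfg.outlier_offset_sd * x.std(ddof=0)
        counts[cat] = np.maximum(np.round(x), 0).astype(int)
    panel = PanelMatrix(
        counts=pd.DataFrame(counts, index=ids),
        sizes_bp=pd.Series(sizes.round().astype(int), index=ids),
    )
    truth = {
        "outlier_id": ids[outlier_idx],
        "slopes_per_mbp": dict(cfg.slopes_per_mbp),
        "noise_sd": dict(cfg.noise_sd),
        "outlier_offset_sd": cfg.outlier_offset_sd,
    }
    return panel, truth


# ---------------------------------------------------------------------------
# annotated genome with planted TCS architecture
# ---------------------------------------------------------------------------

@dataclass
class GenomeSimConfig:
    """Gene layout with planted TCS pairs/orphans/clusters and category genes.

    Units (a pair, a cluster, an orphan, a planted category gene or a
    filler) are separated by ``between_unit_gap_bp`` which must exceed the
    pairing threshold so planted organization is unambiguous; genes inside a
    pair/cluster sit ``within_unit_gap_bp`` apart.
    """

    n_filler_genes: int = 60
    gene_len_bp: int = 900
    between_unit_gap_bp: int = 1000
    within_unit_gap_bp: int = 50
    n_pairs: int = 5
    n_orphans: int = 3
    n_clusters: int = 2
    cluster_size: int = 3
    n_tf: int = 5
    n_transport: int = 4
    n_defense: int = 3
    filler_cog_letters: str = "CEGKPRST"


_TF_PFAMS = sorted(inv.default_rules()[inv.TF].pfam_accessions)
_TRANSPORT_COGS = sorted(inv.default_rules()[inv.TRANSPORT].cog_ids)
_DEFENSE_COGS = sorted(inv.default_rules()[inv.DEFENSE].cog_ids)
_RR_OUTPUT_DOMAINS = ("PF00486", "PF00165", "PF00196")


def _tcs_hits(role: str, gene_id: str, rng: np.random.Generator) -> list[DomainHit]:
    hits = []
    if role in ("RR", "hybrid"):
        hits.append(DomainHit(gene_id, "PF00072", 1e-30, 120.0))
    if role == "RR":
        out = _RR_OUTPUT_DOMAINS[int(rng.integers(len(_RR_OUTPUT_DOMAINS)))]
        hits.append(DomainHit(gene_id, out, 1e-20, 80.0))
    if role in ("HK", "hybrid"):
        hits.append(DomainHit(gene_id, "PF00512", 1e-25, 95.0))
        hits.append(DomainHit(gene_id, "PF02518", 1e-22, 88.0))
    return hits


def gen_annotated_genome(
    cfg: GenomeSimConfig | None = None, seed: int = 0
) -> tuple[GenomeRecord, dict]:
    """An annotated genome whose TCS organization and category counts are known.

    Returns (record, truth); truth maps gene id to its planted role and
    organization and lists the planted members of every category.
    """
    if cfg is None:
        cfg = GenomeSimConfig()
    rng = stream_rng(seed, "genome")

    units: list[list[tuple[str, str]]] = []  # list of (kind, role) genes
    for _ in range(cfg.n_pairs):
        pair = [("tcs", "HK"), ("tcs", "RR")]
        if rng.random() < 0.5:
            pair.reverse()
        units.append(pair)
    for _ in range(cfg.n_orphans):
        role = ("HK", "RR", "hybrid")[int(rng.integers(3))]
        units.append([("tcs", role)])
    for _ in range(cfg.n_clusters):
        units.append([
            ("tcs", ("HK", "RR", "hybrid")[int(rng.integers(3))])
            for _ in range(cfg.cluster_size)
        ])
    units += [[("tf", "")] for _ in range(cfg.n_tf)]
    units += [[("transport", "")] for _ in range(cfg.n_transport)]
    units += [[("defense", "")] for _ in range(cfg.n_defense)]
    units += [[("filler", "")] for _ in range(cfg.n_filler_genes)]
    rng.shuffle(units)

    genes: list[Gene] = []
    hits: list[DomainHit] = []
    cogs: list[CogAssignment] = []
    truth_roles: dict[str, str] = {}
    truth_org: dict[str, str] = {}
    planted: dict[str, set[str]] = {
        inv.TCS: set(), inv.TF: set(), inv.TRANSPORT: set(), inv.DEFENSE: set(),
    }

    pos = cfg.between_unit_gap_bp
    gid_counter = 0
    for unit in units:
        org = (
            "paired" if len(unit) == 2
            else "complex" if len(unit) >= 3
            else "orphan"
        )
        for k, (kind, role) in enumerate(unit):
            gid = f"g{gid_counter:05d}"
            gid_counter += 1
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(Gene(gid, "chr", pos, pos + cfg.gene_len_bp, strand))
            if kind == "tcs":
                hits.extend(_tcs_hits(role, gid, rng))
                truth_roles[gid] = role
                truth_org[gid] = org
                planted[inv.TCS].add(gid)
            elif kind == "tf":
                pf = _TF_PFAMS[int(rng.integers(len(_TF_PFAMS)))]
                hits.append(DomainHit(gid, pf, 1e-15, 60.0))
                planted[inv.TF].add(gid)
            elif kind == "transport":
                cog = _TRANSPORT_COGS[int(rng.integers(len(_TRANSPORT_COGS)))]
                cogs.append(CogAssignment(gid, cog, frozenset("G")))
                planted[inv.TRANSPORT].add(gid)
            elif kind == "defense":
                cog = _DEFENSE_COGS[int(rng.integers(len(_DEFENSE_COGS)))]
                cogs.append(CogAssignment(gid, cog, frozenset("V")))
                planted[inv.DEFENSE].add(gid)
            else:
                letter = cfg.filler_cog_letters[
                    int(rng.integers(len(cfg.filler_cog_letters)))
                ]
                cogs.append(
                    CogAssignment(gid, f"COG9{gid_counter:03d}", frozenset(letter))
                )
            gap = (
                cfg.within_unit_gap_bp if k < len(unit) - 1
                else cfg.between_unit_gap_bp
            )
            pos += cfg.gene_len_bp + gap

    record = GenomeRecord(
        genome_id=f"sim{seed}",
        size_bp=pos,
        genes=genes,
        domain_hits=hits,
        cog_assignments=cogs,
        replicon_lengths={"chr": pos},
    )
    truth = {
        "roles": truth_roles,
        "organization": truth_org,
        "planted_members": {k: sorted(v) for k, v in planted.items()},
    }
    return record, truth


# ---------------------------------------------------------------------------
# fragmented assembly fixture
# ---------------------------------------------------------------------------

@dataclass
class ContigSetConfig:
    name: str
    contig_len_bp: int
    junction_offset_bp: int  # next start - prev end; negative = overlap
    mutation_rate: float     # per-base substitution probability


@dataclass
class AssemblySimConfig:
    """Reference + scaffold + two contig fragmentations + a coverage track.

    The reference carries one (collapsed) copy of a planted repeat unit; the
    coverage track multiplies the baseline depth by ``repeat_copy_number``
    over that locus, emulating reads from all copies mapping onto one.
    """

    ref_len_bp: int = 50_000
    repeat_len_bp: int = 2_000
    repeat_copy_number: int = 5
    depth: float = 100.0
    window_bp: int = 1_000
    contig_sets: list[ContigSetConfig] = field(default_factory=lambda: [
        ContigSetConfig("setA", 4000, -5, 0.0),
        ContigSetConfig("setB", 3500, 0, 0.002),
    ])


@dataclass
class AssemblyFixture:
    reference: str
    scaffolds: dict[str, str]
    contig_sets: dict[str, dict[str, str]]
    track: CoverageTrack
    truth: dict


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    if rate <= 0:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    where = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in where:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode(), len(where)


def gen_assembly_fixture(
    cfg: AssemblySimConfig | None = None, seed: int = 0
) -> AssemblyFixture:
    if cfg is None:
        cfg = AssemblySimConfig()
    if cfg.ref_len_bp < 10_000:
        raise ValueError("reference must be >= 10 kb for meaningful windows")
    rng = stream_rng(seed, "assembly")

    reference = _random_dna(rng, cfg.ref_len_bp)
    rpos = cfg.ref_len_bp // 2 - cfg.repeat_len_bp // 2
    # align the collapsed-repeat locus to window boundaries so the depth
    # ratio over its windows is exactly k in the noise-free expectation
    rpos -= rpos % cfg.window_bp
    repeat_region = (rpos, rpos + cfg.repeat_len_bp)

    contig_sets: dict[str, dict[str, str]] = {}
    truth_sets: dict[str, dict] = {}
    for scfg in cfg.contig_sets:
        bounds: list[tuple[int, int]] = []
        s = 0
        while s + scfg.contig_len_bp < cfg.ref_len_bp:
            bounds.append((s, s + scfg.contig_len_bp))
            s = s + scfg.contig_len_bp + scfg.junction_offset_bp
        if cfg.ref_len_bp - s >= 100:
            bounds.append((s, cfg.ref_len_bp))
        else:  # absorb a tiny remainder into the final contig
            bounds[-1] = (bounds[-1][0], cfg.ref_len_bp)
        contigs: dict[str, str] = {}
        n_mut_total = 0
        for i, (a, b) in enumerate(bounds):
            cseq, n_mut = _mutate(reference[a:b], scfg.mutation_rate, rng)
            n_mut_total += n_mut
            contigs[f"{scfg.name}_c{i:03d}"] = cseq
        contig_sets[scfg.name] = contigs
        truth_sets[scfg.name] = {
            "bounds": bounds,
            "junction_offset_bp": scfg.junction_offset_bp,
            "mutation_rate": scfg.mutation_rate,
            "n_mutations": n_mut_total,
            "total_contig_bp": sum(b - a for a, b in bounds),
        }

    depths = rng.poisson(cfg.depth, cfg.ref_len_bp).astype(float)
    depths[repeat_region[0]:repeat_region[1]] = rng.poisson(
        cfg.depth * cfg.repeat_copy_number,
        cfg.repeat_len_bp,
    )
    track = CoverageTrack.from_depths(depths, cfg.window_bp, "scaffold1")

    return AssemblyFixture(
        reference=reference,
        scaffolds={"scaffold1": reference},
        contig_sets=contig_sets,
        track=track,
        truth={
            "repeat_region": repeat_region,
            "repeat_copy_number": cfg.repeat_copy_number,
            "depth": cfg.depth,
            "contig_sets": truth_sets,
        },
    )


# ---------------------------------------------------------------------------
# alignments evolved on a tree
# ---------------------------------------------------------------------------

@dataclass
class AlignmentSimConfig:
    n_taxa: int = 8
    n_sites: int = 2000
    rate: float = 1.0            # multiplier on branch lengths
    branch_min: float = 0.02     # substitutions per site
    branch_max: float = 0.15
    tree: Node | None = None     # supply a topology, or None for random


def gen_random_tree(
    n_taxa: int,
    rng: np.random.Generator,
    branch_min: float = 0.02,
    branch_max: float = 0.15,
) -> Node:
    """Random unrooted binary topology with uniform branch lengths."""
    if n_taxa < 3:
        raise ValueError("tree needs >= 3 leaves")
    subtrees = [Node(name=f"T{i:02d}") for i in range(n_taxa)]
    for node in subtrees:
        node.length = float(rng.uniform(branch_min, branch_max))
    while len(subtrees) > 3:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        b = subtrees.pop(j)
        a = subtrees.pop(i)
        parent = Node(children=[a, b])
        parent.length = float(rng.uniform(branch_min, branch_max))
        subtrees.append(parent)
    return Node(children=subtrees)


def _evolve(seq: np.ndarray, branch_len: float, rng: np.random.Generator) -> np.ndarray:
    # Jukes-Cantor: P(site differs after branch b) = 3/4 (1 - e^{-4b/3})
    p = 0.75 * (1.0 - np.exp(-4.0 * branch_len / 3.0))
    out = seq.copy()
    hit = np.nonzero(rng.random(len(seq)) < p)[0]
    for i in hit:
        out[i] = (out[i] + 1 + rng.integers(3)) % 4
    return out


def gen_alignment(
    cfg: AlignmentSimConfig | None = None, seed: int = 0
) -> tuple[Alignment, Node]:
    """Sites evolved i.i.d. under Jukes-Cantor along a (possibly random) tree."""
    if cfg is None:
        cfg = AlignmentSimConfig()
    rng = stream_rng(seed, "alignment")
    tree = cfg.tree or gen_random_tree(
        cfg.n_taxa, rng, cfg.branch_min, cfg.branch_max
    )
    root_states = rng.integers(0, 4, size=cfg.n_sites)
    leaf_states: dict[str, np.ndarray] = {}

    def walk(node: Node, states: np.ndarray) -> None:
        if node.is_leaf:
            leaf_states[node.name] = states
            return
        for child in node.children:
            walk(child, _evolve(states, child.length * cfg.rate, rng))

    walk(tree, root_states)
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs = {
        name: alphabet[states].tobytes().decode()
        for name, states in leaf_states.items()
    }
    names = sorted(seqs)
    return Alignment(names=names, seqs=seqs), tree
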