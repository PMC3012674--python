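"""Rule-driven classification of genes into functional categories.

Four categories drive the panel-wide combined score: two-component system
(TCS) genes, transcription factors (TF), transport genes and defense genes.
TCS and TF membership is decided from Pfam-style domain hits; transport and
defense from COG ids and COG category letters.  The rule lists ship as an
editable YAML config; the built-in defaults approximate the published
methodology (receiver / kinase-core domains for TCS, common DNA-binding
families for TF, ABC-transporter and permease COGs for transport, defense
COGs plus COG category V) and are stand-ins for the original curated lists.

TCS role logic: a gene with a receiver domain only is a response regulator
(RR); kinase-core domain(s) only, a histidine kinase (HK); both on one
protein, a hybrid kinase.  A TCS gene never also counts as a TF, so the
four category counts are non-overlapping for TCS/TF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .annotation_io import CogAssignment, DomainHit, Gene, GenomeRecord

TCS = "tcs"
TF = "tf"
TRANSPORT = "transport"
DEFENSE = "defense"
DEFAULT_CATEGORIES = (TCS, TF, TRANSPORT, DEFENSE)

# response-regulator receiver domain
RECEIVER_DOMAINS = frozenset({"PF00072"})
# histidine-kinase core: dimerization/phosphoacceptor and ATPase domains
KINASE_CORE_DOMAINS = frozenset(
    {"PF00512", "PF07568", "PF07730", "PF07536", "PF02518", "PF06580"}
)


class ConfigurationError(ValueError):
    """Raised for empty or inconsistent rule sets."""


@dataclass(frozen=True)
class CategoryRules:
    """Membership rules for one category.

    At least one of the three id sets must be nonempty.  ``role_logic`` is
    only meaningful for the TCS category, where ``"tcs"`` switches on
    HK/RR/hybrid role resolution using the module-level domain sets.
    """

    category_name: str
    pfam_accessions: frozenset[str] = frozenset()
    cog_ids: frozenset[str] = frozenset()
    cog_categories: frozenset[str] = frozenset()
    role_logic: str | None = None

    def __post_init__(self) -> None:
        if not (self.pfam_accessions or self.cog_ids or self.cog_categories):
            raise ConfigurationError(
                f"category {self.category_name!r}: all id sets empty"
            )


def default_rules() -> dict[str, CategoryRules]:
    """Built-in stand-in rule lists for the four scored categories."""
    return {
        TCS: CategoryRules(
            TCS,
            pfam_accessions=RECEIVER_DOMAINS | KINASE_CORE_DOMAINS,
            role_logic="tcs",
        ),
        TF: CategoryRules(
            TF,
            pfam_accessions=frozenset({
                # common bacterial DNA-binding regulator families (HTH)
                "PF00126",  # LysR
                "PF00165",  # AraC
                "PF00356",  # LacI
                "PF00392",  # GntR
                "PF00440",  # TetR
                "PF01047",  # MarR
                "PF00325",  # Crp
                "PF01381",  # HTH_3 (Cro/CI)
                "PF04542",  # Sigma70_r2
                "PF00196",  # GerE (LuxR-type)
            }),
        ),
        TRANSPORT: CategoryRules(
            TRANSPORT,
            cog_ids=frozenset({
                "COG1131", "COG1132", "COG1136", "COG0577", "COG0842",
                "COG1653", "COG0395", "COG1175", "COG0765", "COG0834",
                "COG0601", "COG1173", "COG0444", "COG4166", "COG0609",
                "COG1629", "COG0477", "COG2814", "COG0531", "COG0697",
            }),
        ),
        DEFENSE: CategoryRules(
            DEFENSE,
            cog_ids=frozenset({
                "COG0745", "COG1680", "COG2367", "COG3173", "COG0790",
                "COG2197", "COG3764", "COG2602",
            }),
            cog_categories=frozenset({"V"}),
        ),
    }


def load_rules(path: str | Path) -> dict[str, CategoryRules]:
    """Load category rules from a YAML file.

    Format: one mapping per category with optional ``pfam``, ``cog_id``,
    ``cog_cat`` and ``role_logic`` keys, e.g.::

        tcs:
          pfam: [PF00072, PF00512, PF02518]
          role_logic: tcs
        transport:
          cog_id: [COG1131, COG1132]
          cog_cat: []
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not raw:
        raise ConfigurationError("empty rules file")
    rules: dict[str, CategoryRules] = {}
    for name, section in raw.items():
        section = section or {}
        rules[name] = CategoryRules(
            category_name=name,
            pfam_accessions=frozenset(section.get("pfam", [])),
            cog_ids=frozenset(section.get("cog_id", [])),
            cog_categories=frozenset(section.get("cog_cat", [])),
            role_logic=section.get("role_logic"),
        )
    return rules


def dump_rules(rules: dict[str, CategoryRules], path: str | Path) -> None:
    """Write rules back to the YAML dialect read by :func:`load_rules`."""
    doc = {}
    for name, r in rules.items():
        section: dict = {}
        if r.pfam_accessions:
            section["pfam"] = sorted(r.pfam_accessions)
        if r.cog_ids:
            section["cog_id"] = sorted(r.cog_ids)
        if r.cog_categories:
            section["cog_cat"] = sorted(r.cog_categories)
        if r.role_logic:
            section["role_logic"] = r.role_logic
        doc[name] = section
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


@dataclass
class CategoryInventory:
    """Per-genome category membership: gene-id sets, counts derived."""

    genome_id: str
    members: dict[str, set[str]] = field(default_factory=dict)
    #: TCS role per gene id (RR / HK / hybrid); empty unless TCS classified
    tcs_roles: dict[str, str] = field(default_factory=dict)

    def count(self, category: str) -> int:
        return len(self.members.get(category, set()))

    @property
    def counts(self) -> dict[str, int]:
        return {c: len(m) for c, m in self.members.items()}

    def role_count(self, role: str) -> int:
        return sum(1 for r in self.tcs_roles.values() if r == role)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CategoryInventory)
            and self.genome_id == other.genome_id
            and self.members == other.members
        )


def classify_gene(
    gene: Gene,
    hits: list[DomainHit],
    cogs: list[CogAssignment],
    rules: dict[str, CategoryRules],
) -> set[tuple[str, str | None]]:
    """Classify one gene; returns a set of (category, role) labels.

    ``hits``/``cogs`` must already be restricted to this gene.  Role is
    non-None only for the TCS category (RR, HK or hybrid).  A gene labeled
    TCS is excluded from the TF category.
    """
    if not rules:
        raise ConfigurationError("empty rule set")
    accs = {h.accession for h in hits}
    cog_ids = {c.cog_id for c in cogs}
    cats: set[str] = set()
    for c in cogs:
        cats |= c.categories

    labels: set[tuple[str, str | None]] = set()
    is_tcs = False
    for name, rule in rules.items():
        if rule.role_logic == "tcs":
            has_rec = bool(accs & RECEIVER_DOMAINS)
            has_kin = bool(accs & KINASE_CORE_DOMAINS)
            if has_rec and has_kin:
                labels.add((name, "hybrid"))
                is_tcs = True
            elif has_rec:
                labels.add((name, "RR"))
                is_tcs = True
            elif has_kin:
                labels.add((name, "HK"))
                is_tcs = True
            continue
        if (
            (rule.pfam_accessions and accs & rule.pfam_accessions)
            or (rule.cog_ids and cog_ids & rule.cog_ids)
            or (rule.cog_categories and cats & rule.cog_categories)
        ):
            labels.add((name, None))
    if is_tcs:
        labels.discard((TF, None))
    return labels


def build_inventory(
    genome: GenomeRecord,
    rules: dict[str, CategoryRules] | None = None,
) -> CategoryInventory:
    """Classify every gene of a genome and count members per category."""
    if rules is None:
        rules = default_rules()
    if not rules:
        raise ConfigurationError("empty rule set")
    hits_by = genome.hits_by_gene()
    cogs_by = genome.cogs_by_gene()
    inv = CategoryInventory(
        genome_id=genome.genome_id,
        members={name: set() for name in rules},
    )
    for gene in genome.genes:
        labels = classify_gene(
            gene, hits_by.get(gene.gene_id, []), cogs_by.get(gene.gene_id, []),
            rules,
        )
        for category, role in labels:
            inv.members[category].add(gene.gene_id)
            if role is not None:
                inv.tcs_roles[gene.gene_id] = role
    return inv


@dataclass(frozen=True)
class Locus:
    """A cluster of same-category genes on one replicon."""

    replicon_id: str
    start: int
    end: int
    gene_ids: tuple[str, ...]

    @property
    def span_bp(self) -> int:
        return self.end - self.start


def cluster_category_loci(
    genome: GenomeRecord,
    inventory: CategoryInventory,
    category: str,
    max_gap_bp: int = 5000,
) -> list[Locus]:
    """Group a category's genes into loci by transitive gap closure.

    Two same-category genes on the same replicon whose inter-gene gap
    (next.start - prev.end) is <= ``max_gap_bp`` share a locus.  Loci are
    returned in coordinate order with span = last end - first start.
    """
    if max_gap_bp <= 0:
        raise ValueError("max_gap_bp must be > 0")
    if category not in inventory.members:
        raise ConfigurationError(f"unknown category {category!r}")
    member_ids = inventory.members[category]
    genes = [g for g in genome.genes if g.gene_id in member_ids]
    loci: list[Locus] = []
    current: list[Gene] = []
    for g in genes:  # genome.genes already sorted by (replicon, start)
        if current and (
            g.replicon_id != current[-1].replicon_id
            or g.start - current[-1].end > max_gap_bp
        ):
            loci.append(_make_locus(current))
            current = []
        current.append(g)
    if current:
        loci.append(_make_locus(current))
    return loci


def _make_locus(genes: list[Gene]) -> Locus:
    return Locus(
        replicon_id=genes[0].replicon_id,
        start=genes[0].start,
        end=max(g.end for g in genes),
        gene_ids=tuple(g.gene_id for g in genes),
    )
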