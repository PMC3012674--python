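"""Chromosomal organization of two-component system genes.

Three analyses: structural family of each response regulator (from its
DNA-binding output domain), organization of TCS genes into paired / orphan /
complex arrangements by chromosomal proximity, and a functional profile of
the genes neighboring TCS loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotation_io import DomainHit, Gene, GenomeRecord

DEFAULT_PAIR_GAP_BP = 200
DEFAULT_WINDOW_GENES = 5

#: output-domain accession -> RR structural family (stand-in defaults)
DEFAULT_RR_FAMILY_MAP = {
    "PF00486": "OmpR-like",   # Trans_reg_C winged HTH
    "PF00165": "AraC-like",
    "PF00196": "NarL-like",   # GerE/LuxR-type HTH
    "PF04397": "LytTR-like",
    "PF01978": "PrrA-like",
}

#: COG category letter -> neighborhood functional class (stand-in defaults)
DEFAULT_FUNCTION_MAP = {
    "G": "transport", "E": "transport", "P": "transport", "U": "transport",
    "K": "regulatory", "T": "regulatory",
    "C": "energy metabolism",
}

#: order in which classes win when a neighbor's categories map to several
_CLASS_PRIORITY = ("transport", "regulatory", "energy metabolism", "other")


class ConsistencyError(ValueError):
    """TCS gene ids that do not exist in the genome."""


@dataclass
class TCSRecord:
    gene_id: str
    role: str  # HK, RR or hybrid
    rr_family: str | None = None
    organization: str | None = None  # paired, orphan or complex
    partner_ids: set[str] = field(default_factory=set)


def classify_rr_family(
    hits: list[DomainHit],
    family_map: dict[str, str] | None = None,
) -> str:
    """Family of the best-scoring output-domain hit; ``"other"`` if none."""
    if family_map is None:
        family_map = DEFAULT_RR_FAMILY_MAP
    mapped = [h for h in hits if h.accession in family_map]
    if not mapped:
        return "other"
    best = max(mapped, key=lambda h: h.bit_score)
    return family_map[best.accession]


def build_tcs_records(
    genome: GenomeRecord,
    tcs_roles: dict[str, str],
    family_map: dict[str, str] | None = None,
) -> list[TCSRecord]:
    """Make TCSRecords from role assignments, filling RR families."""
    hits_by = genome.hits_by_gene()
    records = []
    for gene_id, role in sorted(tcs_roles.items()):
        fam = None
        if role == "RR":
            fam = classify_rr_family(hits_by.get(gene_id, []), family_map)
        records.append(TCSRecord(gene_id=gene_id, role=role, rr_family=fam))
    return records


def organize_tcs(
    genome: GenomeRecord,
    tcs: list[TCSRecord],
    pair_gap_bp: int = DEFAULT_PAIR_GAP_BP,
) -> list[TCSRecord]:
    """Fill the organization field of each TCS record in place.

    TCS genes are walked in coordinate order per replicon; maximal runs with
    consecutive inter-gene gaps <= ``pair_gap_bp`` are formed.  A run of
    exactly one HK-like (HK or hybrid) and one RR gene is *paired*; a run of
    three or more genes is *complex*; every other run (singletons, and
    two-gene runs that are not one-HK-one-RR) leaves its members *orphan*.
    """
    if pair_gap_bp <= 0:
        raise ValueError("pair_gap_bp must be > 0")
    by_id = {r.gene_id: r for r in tcs}
    gene_by_id = {g.gene_id: g for g in genome.genes}
    missing = set(by_id) - set(gene_by_id)
    if missing:
        raise ConsistencyError(
            f"TCS gene ids missing from genome: {sorted(missing)}"
        )
    tcs_genes = [g for g in genome.genes if g.gene_id in by_id]

    runs: list[list[Gene]] = []
    current: list[Gene] = []
    for g in tcs_genes:
        if current and (
            g.replicon_id != current[-1].replicon_id
            or g.start - current[-1].end > pair_gap_bp
        ):
            runs.append(current)
            current = []
        current.append(g)
    if current:
        runs.append(current)

    for run in runs:
        recs = [by_id[g.gene_id] for g in run]
        roles = [r.role for r in recs]
        if len(run) == 2 and sorted(
            "HK" if r in ("HK", "hybrid") else r for r in roles
        ) == ["HK", "RR"]:
            recs[0].organization = recs[1].organization = "paired"
            recs[0].partner_ids = {recs[1].gene_id}
            recs[1].partner_ids = {recs[0].gene_id}
        elif len(run) >= 3:
            ids = {r.gene_id for r in recs}
            for r in recs:
                r.organization = "complex"
                r.partner_ids = ids - {r.gene_id}
        else:
            for r in recs:
                r.organization = "orphan"
                r.partner_ids = set()
    return tcs


def organization_counts(tcs: list[TCSRecord]) -> dict[str, int]:
    """Gene counts per organization class (paired + orphan + complex = total)."""
    out = {"paired": 0, "orphan": 0, "complex": 0}
    for r in tcs:
        if r.organization is None:
            raise ValueError(f"record {r.gene_id} not yet organized")
        out[r.organization] += 1
    return out


def neighborhood_profile(
    genome: GenomeRecord,
    tcs: list[TCSRecord],
    window_genes: int = DEFAULT_WINDOW_GENES,
    function_map: dict[str, str] | None = None,
) -> dict[str, dict[str, float]]:
    """Functional profile of genes surrounding TCS genes.

    The neighbor set is every non-TCS gene within ``window_genes`` positions
    (same replicon, coordinate order) of any TCS gene, deduplicated across
    overlapping windows.  Each neighbor with at least one COG category is
    assigned one class via ``function_map`` (ties broken by the fixed class
    priority transport > regulatory > energy metabolism); neighbors whose
    categories map to no class count as "other"; neighbors without COG
    assignments are left unclassified and excluded from the fractions.

    Returns ``{"counts": {...}, "fractions": {...}}``; fractions sum to 1
    over classified neighbors.
    """
    if window_genes < 1:
        raise ValueError("window_genes must be >= 1")
    if function_map is None:
        function_map = DEFAULT_FUNCTION_MAP
    tcs_ids = {r.gene_id for r in tcs}
    if not tcs_ids:
        return {"counts": {}, "fractions": {}}

    by_replicon: dict[str, list[Gene]] = {}
    for g in genome.genes:
        by_replicon.setdefault(g.replicon_id, []).append(g)

    neighbors: set[str] = set()
    for rep_genes in by_replicon.values():
        index = {g.gene_id: i for i, g in enumerate(rep_genes)}
        for r in tcs:
            i = index.get(r.gene_id)
            if i is None:
                continue
            lo = max(0, i - window_genes)  # window truncates at replicon edge
            hi = min(len(rep_genes), i + window_genes + 1)
            for g in rep_genes[lo:hi]:
                if g.gene_id not in tcs_ids:
                    neighbors.add(g.gene_id)

    cogs_by = genome.cogs_by_gene()
    counts: dict[str, int] = {}
    for gid in neighbors:
        cogs = cogs_by.get(gid, [])
        if not cogs:
            continue
        cats: set[str] = set()
        for c in cogs:
            cats |= c.categories
        classes = {function_map[c] for c in cats if c in function_map}
        cls = next((c for c in _CLASS_PRIORITY if c in classes), "other")
        counts[cls] = counts.get(cls, 0) + 1

    total = sum(counts.values())
    fractions = {k: v / total for k, v in counts.items()} if total else {}
    return {"counts": counts, "fractions": fractions}


def write_tcs_tsv(tcs: list[TCSRecord], path) -> None:
    """TSV report: gene_id, role, rr_family, organization, partners."""
    with open(path, "w") as fh:
        fh.write("gene_id\trole\trr_family\torganization\tpartners\n")
        for r in sorted(tcs, key=lambda r: r.gene_id):
            fh.write(
                f"{r.gene_id}\t{r.role}\t{r.rr_family or ''}\t"
                f"{r.organization or ''}\t{';'.join(sorted(r.partner_ids))}\n"
            )
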