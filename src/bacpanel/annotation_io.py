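"""Readers and writers for annotation bundles and the internal genome model.

Coordinates are stored 0-based half-open internally; every file format the
package reads or writes uses the 1-based inclusive convention of GFF3, and
the conversion happens exactly once, at I/O time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

logger = logging.getLogger(__name__)

#: Full-sequence e-value above which a domain hit is discarded at read time.
DEFAULT_EVALUE_THRESHOLD = 1e-5

# feature types counted as RNA genes on a GenomeRecord
_RNA_TYPES = {"rRNA", "ncRNA", "tRNA"}


class ParseError(ValueError):
    """Malformed input line; the message names the offending line number."""


class CoordinateError(ParseError):
    """Feature coordinates violate start <= end or exceed the replicon."""


@dataclass(frozen=True)
class Gene:
    """A gene (or CDS) feature on a named replicon.

    ``start``/``end`` are 0-based half-open; ``length`` is ``end - start``.
    """

    gene_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    product: str = ""
    is_cds: bool = True

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise CoordinateError(
                f"gene {self.gene_id}: start must be < end, got "
                f"({self.start}, {self.end})"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class DomainHit:
    """One protein-domain hit (hmmscan-style) attached to a gene."""

    gene_id: str
    accession: str
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError(f"e-value must be >= 0, got {self.e_value}")


@dataclass(frozen=True)
class CogAssignment:
    """A gene-to-COG mapping with its single-letter functional categories."""

    gene_id: str
    cog_id: str
    categories: frozenset[str]

    def __post_init__(self) -> None:
        if not self.cog_id:
            raise ValueError("cog_id must be nonempty")
        if not self.categories:
            raise ValueError(f"{self.gene_id}: categories must be nonempty")


@dataclass
class GenomeRecord:
    """A genome: ordered genes plus domain hits and COG assignments.

    ``genes`` are kept sorted by (replicon_id, start).  ``replicon_lengths``
    may carry per-replicon sizes (from ``##sequence-region`` pragmas); when
    absent, ``size_bp`` bounds all coordinates.
    """

    genome_id: str
    size_bp: int
    genes: list[Gene] = field(default_factory=list)
    domain_hits: list[DomainHit] = field(default_factory=list)
    cog_assignments: list[CogAssignment] = field(default_factory=list)
    rrna_count: int = 0
    ncrna_count: int = 0
    trna_count: int = 0
    replicon_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.size_bp <= 0:
            raise ValueError("size_bp must be positive")
        self.genes.sort(key=lambda g: (g.replicon_id, g.start))
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            bound = self.replicon_lengths.get(g.replicon_id, self.size_bp)
            if g.end > bound:
                raise CoordinateError(
                    f"gene {g.gene_id} end {g.end} exceeds replicon bound {bound}"
                )

    def hits_by_gene(self) -> dict[str, list[DomainHit]]:
        out: dict[str, list[DomainHit]] = {}
        for h in self.domain_hits:
            out.setdefault(h.gene_id, []).append(h)
        return out

    def cogs_by_gene(self) -> dict[str, list[CogAssignment]]:
        out: dict[str, list[CogAssignment]] = {}
        for c in self.cog_assignments:
            out.setdefault(c.gene_id, []).append(c)
        return out


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def _gff3_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for part in text.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def read_features(
    path: str | Path,
    fmt: str = "gff3",
    genome_id: str | None = None,
) -> GenomeRecord:
    """Read a feature table into a :class:`GenomeRecord`.

    ``fmt='gff3'`` reads standard 9-column GFF3 (CDS/gene features become
    genes; rRNA/ncRNA/tRNA features are counted).  ``fmt='genbank_table'``
    reads a simple headered TSV with columns
    ``replicon  start  end  strand  type  gene_id  product``.
    Coordinates in both dialects are 1-based inclusive and converted on read.
    """
    path = Path(path)
    if fmt == "gff3":
        return _read_gff3(path, genome_id)
    if fmt == "genbank_table":
        return _read_genbank_table(path, genome_id)
    raise ValueError(f"unknown feature format {fmt!r}")


def _convert_coords(start_1: str, end_1: str, lineno: int) -> tuple[int, int]:
    try:
        s1, e1 = int(start_1), int(end_1)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: non-integer coordinate") from exc
    if e1 < s1:
        raise CoordinateError(f"line {lineno}: end {e1} < start {s1}")
    return s1 - 1, e1  # 1-based inclusive -> 0-based half-open


def _read_gff3(path: Path, genome_id: str | None) -> GenomeRecord:
    genes: list[Gene] = []
    rna_counts = {t: 0 for t in _RNA_TYPES}
    replicon_lengths: dict[str, int] = {}
    seen_cds_for: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip()
            if not line:
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    replicon_lengths[parts[1]] = int(parts[3])
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(
                    f"line {lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            seqid, _source, ftype, start_1, end_1, _score, strand, _phase, attr = cols
            if ftype in _RNA_TYPES:
                rna_counts[ftype] += 1
                continue
            if ftype not in {"gene", "CDS"}:
                continue
            start, end = _convert_coords(start_1, end_1, lineno)
            if strand not in {"+", "-"}:
                raise ParseError(f"line {lineno}: strand must be '+' or '-'")
            attrs = _gff3_attributes(attr)
            gid = attrs.get("ID") or attrs.get("locus_tag")
            if gid is None:
                raise ParseError(f"line {lineno}: feature lacks ID/locus_tag")
            # a gene line followed by its CDS line describes one gene: keep one
            if gid in seen_cds_for:
                continue
            seen_cds_for.add(gid)
            genes.append(
                Gene(
                    gene_id=gid,
                    replicon_id=seqid,
                    start=start,
                    end=end,
                    strand=strand,
                    product=attrs.get("product", ""),
                    is_cds=(ftype == "CDS"),
                )
            )
    size_bp = sum(replicon_lengths.values()) if replicon_lengths else max(
        (g.end for g in genes), default=1
    )
    return GenomeRecord(
        genome_id=genome_id or path.stem,
        size_bp=size_bp,
        genes=genes,
        rrna_count=rna_counts["rRNA"],
        ncrna_count=rna_counts["ncRNA"],
        trna_count=rna_counts["tRNA"],
        replicon_lengths=replicon_lengths,
    )


def _read_genbank_table(path: Path, genome_id: str | None) -> GenomeRecord:
    genes: list[Gene] = []
    rna_counts = {t: 0 for t in _RNA_TYPES}
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if header is None:
                header = cols
                continue
            if len(cols) < 6:
                raise ParseError(f"line {lineno}: expected >= 6 columns")
            replicon, start_1, end_1, strand, ftype, gid = cols[:6]
            product = cols[6] if len(cols) > 6 else ""
            if ftype in _RNA_TYPES:
                rna_counts[ftype] += 1
                continue
            start, end = _convert_coords(start_1, end_1, lineno)
            genes.append(
                Gene(gid, replicon, start, end, strand, product, ftype == "CDS")
            )
    size_bp = max((g.end for g in genes), default=1)
    return GenomeRecord(
        genome_id=genome_id or path.stem,
        size_bp=size_bp,
        genes=genes,
        rrna_count=rna_counts["rRNA"],
        ncrna_count=rna_counts["ncRNA"],
        trna_count=rna_counts["tRNA"],
    )


def write_features_gff3(record: GenomeRecord, path: str | Path) -> None:
    """Write a GenomeRecord as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rep, length in record.replicon_lengths.items():
            fh.write(f"##sequence-region {rep} 1 {length}\n")
        if not record.replicon_lengths:
            reps = sorted({g.replicon_id for g in record.genes})
            for rep in reps:
                fh.write(f"##sequence-region {rep} 1 {record.size_bp}\n")
        for g in record.genes:
            attrs = f"ID={g.gene_id}"
            if g.product:
                attrs += f";product={g.product}"
            ftype = "CDS" if g.is_cds else "gene"
            fh.write(
                f"{g.replicon_id}\tbacpanel\t{ftype}\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# domain hits (hmmscan --tblout dialect)
# ---------------------------------------------------------------------------

def read_domain_hits(
    path: str | Path,
    evalue_threshold: float = DEFAULT_EVALUE_THRESHOLD,
    known_gene_ids: set[str] | None = None,
) -> list[DomainHit]:
    """Read an hmmscan-style whitespace table of per-gene domain hits.

    Columns follow ``hmmscan --tblout``: target name, target accession,
    query (gene) name, query accession, full-sequence e-value, full-sequence
    score, ...  Rows whose e-value exceeds ``evalue_threshold`` are dropped
    and the number dropped is logged.  When ``known_gene_ids`` is given,
    hits for unknown genes are retained but logged as unresolved.
    """
    hits: list[DomainHit] = []
    n_filtered = 0
    unknown: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 6:
                raise ParseError(f"line {lineno}: expected >= 6 columns")
            target_name, target_acc, query_name = cols[0], cols[1], cols[2]
            try:
                e_value = float(cols[4])
                bit_score = float(cols[5])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-numeric e-value/score") from exc
            if e_value < 0:
                raise ParseError(f"line {lineno}: negative e-value")
            accession = target_acc if target_acc != "-" else target_name
            # strip Pfam accession versions (PF00072.25 -> PF00072)
            accession = accession.split(".")[0]
            if e_value > evalue_threshold:
                n_filtered += 1
                continue
            if known_gene_ids is not None and query_name not in known_gene_ids:
                unknown.add(query_name)
            hits.append(DomainHit(query_name, accession, e_value, bit_score))
    if n_filtered:
        logger.info(
            "read_domain_hits: filtered %d hit(s) above e-value %.3g",
            n_filtered, evalue_threshold,
        )
    if unknown:
        logger.warning(
            "read_domain_hits: %d hit gene id(s) not in the genome: %s",
            len(unknown), ", ".join(sorted(unknown)[:5]),
        )
    return hits


def write_domain_hits(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write domain hits in the hmmscan --tblout column layout."""
    with open(path, "w") as fh:
        fh.write("# target_name target_accession query_name query_accession "
                 "evalue score\n")
        for h in hits:
            fh.write(
                f"{h.accession} {h.accession} {h.gene_id} - "
                f"{h.e_value:.3g} {h.bit_score:.1f}\n"
            )


# ---------------------------------------------------------------------------
# COG assignments
# ---------------------------------------------------------------------------

def read_cog_assignments(path: str | Path) -> list[CogAssignment]:
    """Read a 3-column TSV of gene_id, COG id, category letters.

    Multi-letter category strings (e.g. ``KT``) become a set of letters.
    Multiple rows per gene are preserved as distinct assignments.
    """
    out: list[CogAssignment] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"line {lineno}: expected 3 tab-separated columns")
            gene_id, cog_id, cats = cols[0], cols[1], cols[2].strip()
            if not cats:
                raise ParseError(f"line {lineno}: empty category field")
            out.append(CogAssignment(gene_id, cog_id, frozenset(cats)))
    return out


def write_cog_assignments(cogs: Iterable[CogAssignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in cogs:
            fh.write(f"{c.gene_id}\t{c.cog_id}\t{''.join(sorted(c.categories))}\n")


# ---------------------------------------------------------------------------
# inventory TSV (written here; the CategoryInventory type lives in inventory)
# ---------------------------------------------------------------------------

def write_inventory_tsv(inventory, path: str | Path) -> None:
    """Write a CategoryInventory as TSV with a deterministic column order.

    Columns: genome_id, category, count, gene_ids (semicolon-joined, sorted);
    rows sorted by category name.  ``read_inventory_tsv`` inverts this.
    """
    with open(path, "w") as fh:
        fh.write("genome_id\tcategory\tcount\tgene_ids\n")
        for category in sorted(inventory.members):
            members = sorted(inventory.members[category])
            fh.write(
                f"{inventory.genome_id}\t{category}\t{len(members)}\t"
                f"{';'.join(members)}\n"
            )


def read_inventory_tsv(path: str | Path):
    """Read a TSV written by :func:`write_inventory_tsv`."""
    from .inventory import CategoryInventory

    genome_id = ""
    members: dict[str, set[str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["genome_id", "category", "count"]:
            raise ParseError("line 1: unexpected inventory header")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n").rstrip()
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"line {lineno}: expected >= 3 columns")
            genome_id = cols[0]
            ids = cols[3].split(";") if len(cols) > 3 and cols[3] else []
            members[cols[1]] = set(ids)
            if int(cols[2]) != len(ids):
                raise ParseError(f"line {lineno}: count does not match gene_ids")
    return CategoryInventory(genome_id=genome_id, members=members)


# ---------------------------------------------------------------------------
# FASTA (thin wrappers over Biopython)
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, alphabet: str | None = "ACGTN") -> dict[str, str]:
    """Read FASTA into an ordered name -> sequence dict.

    With the default DNA alphabet, any other character is rejected.
    """
    from Bio import SeqIO

    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if alphabet is not None:
            bad = set(seq) - set(alphabet)
            if bad:
                raise ParseError(
                    f"sequence {rec.id!r}: characters {sorted(bad)} outside "
                    f"alphabet {alphabet!r}"
                )
        if rec.id in out:
            raise ParseError(f"duplicate sequence name {rec.id!r}")
        out[rec.id] = seq
    return out


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
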