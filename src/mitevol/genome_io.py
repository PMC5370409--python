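"""Reading annotated genomes and writing interchange artifacts.

GenBank flat files are parsed with Biopython into light
:class:`AnnotatedGenome` records; gene-order tables use the textual
convention of compact organellar-genome listings: one row per chromosome
with an ``L``/``C`` topology flag and space-separated gene names, a
leading ``*`` marking genes encoded on the complementary strand, and
``name#k`` disambiguating repeated gene names by occurrence index.

Coordinates are 1-based inclusive throughout the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from mitevol.chromosome import ChromosomeStructure, SignedGene

_KIND_BY_FEATURE = {"CDS": "protein", "rRNA": "rRNA", "tRNA": "tRNA"}


@dataclass
class GeneFeature:
    """One annotated gene.

    ``start``/``end`` are 1-based inclusive; a feature spanning the
    origin of a circular genome keeps a single record with ``wraps``
    set (its ``start`` is then greater than its ``end``).
    """

    gene_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    kind: str  # protein | rRNA | tRNA | other
    translation: Optional[str] = None
    wraps: bool = False

    def __post_init__(self):
        if self.start < 1:
            raise ValueError("start must be >= 1")
        if self.end < self.start and not self.wraps:
            raise ValueError("end < start only allowed for origin-wrapping features")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")


@dataclass
class AnnotatedGenome:
    accession: str
    organism: str
    sequence: str
    topology: str  # 'linear' or 'circular'
    features: list = field(default_factory=list)

    def __post_init__(self):
        if self.topology not in ("linear", "circular"):
            raise ValueError("topology must be 'linear' or 'circular'")
        n = len(self.sequence)
        for f in self.features:
            if f.end > n or f.start > n:
                raise ValueError(
                    f"feature {f.gene_id} [{f.start},{f.end}] outside sequence of length {n}")
        self.features.sort(key=lambda f: (f.start, f.end, f.gene_id))

    def proteins(self) -> list:
        return [f for f in self.features if f.kind == "protein"]


class GenBankParseError(ValueError):
    pass


def _feature_name(feat: SeqFeature, idx: int) -> str:
    for key in ("gene", "locus_tag", "product"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0]).replace(" ", "_")
    return f"feature_{idx}"


def read_genbank(path) -> AnnotatedGenome:
    """Parse one GenBank flat-file record.

    All CDS/rRNA/tRNA features are captured with strand and translation;
    topology comes from the LOCUS line.  A CDS without an annotated
    translation triggers a warning and the translation is synthesised
    from the nucleotide sequence with the record's translation table.
    """
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("LOCUS"):
            raise GenBankParseError(
                f"{path}: not a GenBank flat file; first line is {first.strip()!r}, "
                "expected a LOCUS line")
    try:
        record = SeqIO.read(path, "genbank")
    except ValueError as exc:
        raise GenBankParseError(f"{path}: truncated or malformed record: {exc}") from exc

    topology = record.annotations.get("topology", "linear")
    genome_len = len(record.seq)
    features = []
    for i, feat in enumerate(record.features):
        kind = _KIND_BY_FEATURE.get(feat.type)
        if kind is None:
            continue
        strand = "-" if feat.location.strand == -1 else "+"
        start = int(feat.location.start) + 1  # to 1-based inclusive
        end = int(feat.location.end)
        wraps = False
        parts = feat.location.parts
        if len(parts) > 1 and int(parts[0].start) > int(parts[-1].start):
            # compound location crossing the origin of a circular genome
            wraps = True
            start = int(parts[0].start) + 1
            end = int(parts[-1].end)
        translation = None
        if kind == "protein":
            if "translation" in feat.qualifiers:
                translation = str(feat.qualifiers["translation"][0])
            else:
                table = int(feat.qualifiers.get("transl_table", [1])[0])
                warnings.warn(
                    f"{record.id}: CDS {_feature_name(feat, i)} lacks a translation; "
                    f"synthesising with table {table}")
                translation = str(
                    feat.extract(record.seq).translate(table=table, to_stop=True))
        features.append(GeneFeature(
            gene_id=_feature_name(feat, i),
            start=start,
            end=end,
            strand=strand,
            kind=kind,
            translation=translation,
            wraps=wraps,
        ))
    return AnnotatedGenome(
        accession=record.id or record.name,
        organism=record.annotations.get("organism", ""),
        sequence=str(record.seq),
        topology=topology,
        features=features,
    )


def write_genbank(genome: AnnotatedGenome, path) -> None:
    """Serialise an :class:`AnnotatedGenome` as a GenBank flat file
    (round-trips through :func:`read_genbank`)."""
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.accession,
        name=genome.accession.split(".")[0][:16],
        description=f"{genome.organism} mitochondrion",
        annotations={
            "molecule_type": "DNA",
            "topology": genome.topology,
            "organism": genome.organism,
            "source": genome.organism,
            "date": "01-JAN-2000",  # fixed so output is reproducible
        },
    )
    type_by_kind = {"protein": "CDS", "rRNA": "rRNA", "tRNA": "tRNA"}
    for f in genome.features:
        loc = FeatureLocation(f.start - 1, f.end, strand=1 if f.strand == "+" else -1)
        qualifiers = {"gene": [f.gene_id]}
        if f.kind == "protein" and f.translation:
            qualifiers["translation"] = [f.translation]
            qualifiers["transl_table"] = ["4"]
        record.features.append(
            SeqFeature(loc, type=type_by_kind.get(f.kind, "misc_feature"),
                       qualifiers=qualifiers))
    SeqIO.write([record], path, "genbank")


def extract_structure(
    genome: AnnotatedGenome,
    kinds: Sequence[str] = ("protein", "rRNA"),
) -> ChromosomeStructure:
    """Project a genome onto its chromosome structure.

    One chromosome per record, topology preserved; genes ordered by
    start coordinate, strand mapped to orientation sign, and duplicate
    gene names disambiguated by occurrence index in positional order.
    tRNA genes are excluded by default (pass ``kinds`` to include them).
    """
    feats = [f for f in genome.features if f.kind in kinds]
    if not feats:
        raise ValueError(
            f"{genome.accession}: no features of kind {list(kinds)} to extract")
    feats.sort(key=lambda f: (f.start, f.end, f.gene_id))
    counts: dict = {}
    genes = []
    for f in feats:
        counts[f.gene_id] = counts.get(f.gene_id, 0) + 1
        genes.append(SignedGene(f.gene_id, counts[f.gene_id],
                                1 if f.strand == "+" else -1))
    topo = "C" if genome.topology == "circular" else "L"
    return ChromosomeStructure([(topo, genes)])


# ---------------------------------------------------------------------------
# Interchange writers


def write_matrix(matrix, path) -> None:
    """Write a presence/absence matrix as TSV: header row of element
    ids, first column of genome labels, cells 0/1."""
    rows = list(matrix.row_labels)
    cols = list(matrix.col_labels)
    if len(set(rows)) != len(rows) or len(set(cols)) != len(cols):
        raise ValueError("duplicate labels in matrix")
    with open(path, "w") as fh:
        fh.write("\t".join(["genome"] + [str(c) for c in cols]) + "\n")
        for lab, row in zip(rows, matrix.cells):
            fh.write("\t".join([str(lab)] + [str(int(v)) for v in row]) + "\n")


def write_newick(tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.as_string(schema="newick", suppress_rooting=True))


def read_newick(path):
    import dendropy

    tree = dendropy.Tree.get(path=str(path), schema="newick")
    tree.is_rooted = False
    return tree


def write_gene_orders(structures: dict, path) -> None:
    """Write chromosome structures as a gene-order table.

    One row per chromosome: genome label, ``L``/``C`` flag, and the gene
    list with a leading ``*`` for complementary-strand genes.
    """
    if len(set(structures)) != len(structures):
        raise ValueError("duplicate genome labels")
    with open(path, "w") as fh:
        fh.write("genome\ttopology\tgenes\n")
        for label in structures:
            for topo, genes in structures[label].chromosomes:
                fh.write(f"{label}\t{topo}\t" + " ".join(g.label for g in genes) + "\n")


def read_gene_orders(path) -> dict:
    """Parse a gene-order table back into structures (inverse of
    :func:`write_gene_orders`)."""
    chroms: dict = {}
    order: list = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["genome", "topology", "genes"]:
            raise ValueError("not a gene-order table (bad header)")
        for line in fh:
            if not line.strip():
                continue
            label, topo, genes = line.rstrip("\n").split("\t")
            if label not in chroms:
                chroms[label] = []
                order.append(label)
            chroms[label].append((topo, genes.split()))
    return {label: ChromosomeStructure(chroms[label]) for label in order}


def write_fasta(records: Iterable, path) -> None:
    """Write protein records as FASTA with ``accession|protein_id|gene``
    headers."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.genome}|{rec.protein_id}|{rec.gene_name}\n")
            seq = rec.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def read_fasta(path) -> list:
    """Read a protein FASTA written by :func:`write_fasta`."""
    from mitevol.proteins import ProteinRecord

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) == 3:
            genome, pid, gene = parts
        else:
            genome, pid, gene = "", rec.id, rec.id
        records.append(ProteinRecord(pid, genome, gene, str(rec.seq)))
    return records
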