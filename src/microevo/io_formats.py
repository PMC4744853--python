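"""Genome data model and readers/writers for FASTA, GFF3, Newick, and TSV.

All coordinates are 0-based half-open internally.  GFF3 files (1-based,
inclusive) are converted at the read/write boundary, so no other module
ever handles a 1-based coordinate.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq

DNA_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
GFF_VERSION_HEADER = "##gff-version 3"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class SequenceRecord:
    """A named nucleotide or amino-acid sequence.

    DNA sequences may contain N (assembly gaps); proteins may contain X.
    Sequences are stored uppercase.
    """

    id: str
    seq: str
    moltype: str = "dna"  # {"dna", "protein"}

    def __post_init__(self):
        if not self.id:
            raise FormatError("sequence record with empty id")
        self.seq = self.seq.upper()
        if not self.seq:
            raise FormatError(f"record {self.id!r}: empty sequence")
        if self.moltype not in ("dna", "protein"):
            raise FormatError(f"record {self.id!r}: unknown moltype {self.moltype!r}")
        alphabet = DNA_ALPHABET if self.moltype == "dna" else PROTEIN_ALPHABET
        bad = set(self.seq) - alphabet
        if bad:
            raise FormatError(
                f"record {self.id!r}: illegal {self.moltype} characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GeneFeature:
    """A protein-coding feature on a contig (0-based, half-open)."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    product: str = ""
    protein: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"feature {self.gene_id!r}: invalid span [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"feature {self.gene_id!r}: strand must be + or -")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Genome:
    """One strain: its contigs and annotated coding features."""

    strain_id: str
    contigs: list[SequenceRecord] = field(default_factory=list)
    features: list[GeneFeature] = field(default_factory=list)

    def contig_map(self) -> dict[str, SequenceRecord]:
        return {c.id: c for c in self.contigs}

    def validate(self) -> None:
        """Check referential integrity between features and contigs."""
        cmap = self.contig_map()
        if len(cmap) != len(self.contigs):
            raise FormatError(f"{self.strain_id}: duplicate contig ids")
        if sum(len(c) for c in self.contigs) == 0:
            raise FormatError(f"{self.strain_id}: empty genome")
        seen = set()
        for f in self.features:
            if f.gene_id in seen:
                raise FormatError(f"{self.strain_id}: duplicate gene id {f.gene_id!r}")
            seen.add(f.gene_id)
            if f.contig_id not in cmap:
                raise FormatError(
                    f"{self.strain_id}: feature {f.gene_id!r} references unknown "
                    f"contig {f.contig_id!r}"
                )
            if f.end > len(cmap[f.contig_id]):
                raise FormatError(
                    f"{self.strain_id}: feature {f.gene_id!r} extends past the end "
                    f"of contig {f.contig_id!r}"
                )

    def feature_seq(self, feat: GeneFeature) -> str:
        """Nucleotide sequence of a feature in reading orientation."""
        s = self.contig_map()[feat.contig_id].seq[feat.start : feat.end]
        return reverse_complement(s) if feat.strand == "-" else s

    def length(self) -> int:
        return sum(len(c) for c in self.contigs)


# ---------------------------------------------------------------------------
# sequence utilities

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_percent(seq: str) -> float:
    """GC content in percent over called (non-N) bases.

    Raises ValueError when no called base is present, rather than returning
    a silent 0 or NaN.
    """
    gc = seq.count("G") + seq.count("C")
    atgc = gc + seq.count("A") + seq.count("T")
    if atgc == 0:
        raise ValueError("GC content undefined: no called (non-N) bases")
    return 100.0 * gc / atgc


def translate_cds(nt: str) -> str:
    """Translate a CDS with the bacterial code; start codon rendered as M.

    A trailing stop codon is stripped; internal stops raise ValueError.
    """
    if len(nt) % 3 != 0:
        raise ValueError(f"CDS length {len(nt)} not a multiple of 3")
    aa = str(Seq(nt).translate(table=11))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise ValueError("internal stop codon in CDS")
    # alternative bacterial starts (GTG/TTG) are initiated as methionine
    if aa and nt[:3] in ("ATG", "GTG", "TTG"):
        aa = "M" + aa[1:]
    return aa


def n50(lengths: list[int]) -> int:
    """Contig length at which sorted-descending cumulative length reaches
    half the total; ties resolve to the larger contig."""
    if not lengths:
        raise ValueError("N50 of an empty assembly")
    total = sum(lengths)
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if 2 * acc >= total:
            return length
    raise AssertionError("unreachable")


def genome_stats(g: Genome) -> dict:
    """Assembly summary: size, GC%, contig count, N50, CDS count."""
    g.validate()
    lengths = [len(c) for c in g.contigs]
    all_seq = "".join(c.seq for c in g.contigs)
    return {
        "strain_id": g.strain_id,
        "length_bp": sum(lengths),
        "gc_percent": gc_percent(all_seq),
        "n_contigs": len(lengths),
        "n50_bp": n50(lengths),
        "n_cds": len(g.features),
    }


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path, moltype: str = "dna") -> list[SequenceRecord]:
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq), moltype))
    return records


def write_fasta(records, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# features (GFF3 and plain TSV dialects)

def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for part in text.strip().split(";"):
        if part and "=" in part:
            k, _, v = part.partition("=")
            attrs[k.strip()] = v.strip()
    return attrs


def read_features(path, dialect: str = "gff3", product_attr: str = "product") -> list[GeneFeature]:
    """Read coding features; GFF3 coordinates converted to 0-based half-open."""
    if dialect == "gff3":
        return _read_gff3(path, product_attr)
    if dialect == "tsv_table":
        return _read_feature_tsv(path)
    raise ValueError(f"unknown feature dialect {dialect!r}")


def _read_gff3(path, product_attr: str) -> list[GeneFeature]:
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            contig, _src, ftype, start1, end1, _score, strand, _phase, attr_text = cols
            if ftype not in ("CDS", "gene"):
                continue
            attrs = _parse_gff_attributes(attr_text)
            start = int(start1) - 1
            end = int(end1)
            if end <= start:
                raise FormatError(f"{path}:{lineno}: non-positive span after conversion")
            feats.append(
                GeneFeature(
                    gene_id=attrs.get("ID", f"feature_{lineno}"),
                    contig_id=contig,
                    start=start,
                    end=end,
                    strand=strand,
                    product=attrs.get(product_attr, ""),
                )
            )
    return feats


def _read_feature_tsv(path) -> list[GeneFeature]:
    feats = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            feats.append(
                GeneFeature(
                    gene_id=cols[idx["gene_id"]],
                    contig_id=cols[idx["contig_id"]],
                    start=int(cols[idx["start"]]),
                    end=int(cols[idx["end"]]),
                    strand=cols[idx["strand"]],
                    product=cols[idx["product"]] if "product" in idx else "",
                )
            )
    return feats


def write_gff3(features, path, source: str = "microevo") -> None:
    """Write CDS features as GFF3 (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write(GFF_VERSION_HEADER + "\n")
        for f in features:
            attrs = f"ID={f.gene_id}"
            if f.product:
                attrs += f";product={f.product}"
            fh.write(
                "\t".join(
                    [
                        f.contig_id,
                        source,
                        "CDS",
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        "0",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# genome-level convenience I/O

def write_genome(g: Genome, out_dir, stem: str | None = None) -> None:
    """Write <stem>.fna, <stem>.gff, <stem>.faa for one strain."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or g.strain_id
    write_fasta(g.contigs, out_dir / f"{stem}.fna")
    write_gff3(g.features, out_dir / f"{stem}.gff")
    prots = [
        SequenceRecord(f.gene_id, f.protein or translate_cds(g.feature_seq(f)), "protein")
        for f in g.features
    ]
    write_fasta(prots, out_dir / f"{stem}.faa")


def read_genome(dir_path, stem: str) -> Genome:
    """Read a strain written by :func:`write_genome` (or equivalent files)."""
    dir_path = Path(dir_path)
    contigs = read_fasta(dir_path / f"{stem}.fna", "dna")
    features = read_features(dir_path / f"{stem}.gff", "gff3")
    faa = dir_path / f"{stem}.faa"
    if faa.exists():
        prot_map = {r.id: r.seq for r in read_fasta(faa, "protein")}
        for f in features:
            f.protein = prot_map.get(f.gene_id, "")
    g = Genome(stem, contigs, features)
    g.validate()
    return g


def proteome(g: Genome) -> dict[str, str]:
    """gene_id -> protein sequence, translating from the CDS when absent."""
    out = {}
    for f in g.features:
        out[f.gene_id] = f.protein or translate_cds(g.feature_seq(f))
    return out


# ---------------------------------------------------------------------------
# Newick

def read_newick(source) -> dendropy.Tree:
    """Parse a Newick tree from a path or a string."""
    looks_like_tree = isinstance(source, str) and source.lstrip().startswith("(")
    if not looks_like_tree and Path(str(source)).exists():
        return dendropy.Tree.get(path=str(source), schema="newick", preserve_underscores=True)
    return dendropy.Tree.get(data=str(source), schema="newick", preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path=None) -> str:
    text = tree.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True)
    if path is not None:
        Path(path).write_text(text)
    return text
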