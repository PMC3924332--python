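"""Genome and annotation I/O, six-frame translation, ORF extraction.

Coordinate conventions used throughout the package:

* internal coordinates are 0-based, half-open, on the forward strand;
* GFF3 is read and written as 1-based inclusive;
* frames are numbered ``+1..+3`` for offsets 0..2 on the forward strand and
  ``-1..-3`` for offsets 0..2 on the reverse complement.

Trailing partial codons are dropped silently.  Codons containing ``N``
translate to ``X``; ``X`` does not terminate an ORF (hard-masked tracts
suppress signal in the downstream homology search instead of fragmenting
open reading frames).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Data import CodonTable

log = logging.getLogger(__name__)

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: codon -> amino acid map for the standard genetic code ('*' for stops)
STANDARD_CODE: dict[str, str] = dict(
    CodonTable.unambiguous_dna_by_id[1].forward_table
)
for _stop in CodonTable.unambiguous_dna_by_id[1].stop_codons:
    STANDARD_CODE[_stop] = "*"


def revcomp(nt: str) -> str:
    """Reverse complement of an ACGTN string."""
    return nt.translate(_COMPLEMENT)[::-1]


def translate_nt(nt: str, code: dict[str, str] | None = None) -> str:
    """Translate a nucleotide string codon-by-codon.

    Any codon not in the table (e.g. one containing ``N``) yields ``X``.
    A trailing partial codon is dropped.
    """
    table = code or STANDARD_CODE
    n = len(nt) - len(nt) % 3
    return "".join(table.get(nt[i : i + 3], "X") for i in range(0, n, 3))


@dataclass(frozen=True)
class GenomicSequence:
    id: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)

    def __post_init__(self) -> None:
        bad = set(self.residues) - _VALID
        if bad:
            raise ValueError(f"invalid residues in {self.id!r}: {sorted(bad)}")


@dataclass(frozen=True)
class FrameTranslation:
    """One of the six reading-frame translations of a genomic sequence.

    ``offset`` is the forward-strand genomic position (0-based) of the first
    base of the first codon.  For minus frames the translation reads the
    reverse complement, so ``offset`` is near the 3' end of the forward
    strand.  ``rc_offset`` is the offset within the reverse complement
    (0, 1 or 2) and ``seq_length`` the length of the source sequence; both
    are carried so amino-acid coordinates can be mapped back.
    """

    seq_id: str
    frame: int  # +1..+3, -1..-3
    aa: str
    offset: int
    rc_offset: int
    seq_length: int

    @property
    def strand(self) -> str:
        return "+" if self.frame > 0 else "-"


@dataclass(frozen=True)
class OrfRecord:
    orf_id: str
    seq_id: str
    frame: int
    aa_start: int  # half-open indices into the frame translation
    aa_end: int
    aa: str
    genomic_start: int  # 0-based half-open, forward strand
    genomic_end: int
    strand: str


@dataclass
class AnnotationModel:
    """A protein-coding gene model from an existing annotation."""

    gene_id: str
    seq_id: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)  # transcription order
    protein: str = ""
    translation_ok: bool = True

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def aa_to_genomic_blocks(self, aa_start: int, aa_end: int) -> list[tuple[int, int]]:
        """Map a protein interval to one forward-strand genomic block per exon."""
        want = (aa_start * 3, aa_end * 3)  # CDS-coordinate interval
        blocks: list[tuple[int, int]] = []
        cpos = 0
        for s, e in self.exons:
            ln = e - s
            lo = max(want[0], cpos)
            hi = min(want[1], cpos + ln)
            if lo < hi:
                if self.strand == "+":
                    blocks.append((s + (lo - cpos), s + (hi - cpos)))
                else:
                    # exon runs e..s in transcription direction
                    blocks.append((e - (hi - cpos), e - (lo - cpos)))
            cpos += ln
        return blocks


def read_genome(path) -> list[GenomicSequence]:
    """Read a (multi-)FASTA genome; uppercase, non-ACGTN mapped to N."""
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        raw = str(rec.seq).upper()
        cleaned = "".join(c if c in _VALID else "N" for c in raw)
        n_bad = sum(1 for a, b in zip(raw, cleaned) if a != b)
        if n_bad:
            log.warning("%s: %d non-ACGTN residues replaced with N", rec.id, n_bad)
        records.append(GenomicSequence(rec.id, cleaned))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def six_frame_translate(
    g: GenomicSequence, code: dict[str, str] | None = None
) -> list[FrameTranslation]:
    """Translate a genomic sequence in all six reading frames."""
    out = []
    rc = revcomp(g.residues)
    L = g.length
    for k in range(3):
        out.append(
            FrameTranslation(
                g.id, k + 1, translate_nt(g.residues[k:], code), k, k, L
            )
        )
    for k in range(3):
        # first codon of rc[k:] starts at forward-strand position L-1-k
        out.append(
            FrameTranslation(
                g.id, -(k + 1), translate_nt(rc[k:], code), max(L - 1 - k, 0), k, L
            )
        )
    return out


def map_aa_to_genomic(
    t: FrameTranslation, aa_start: int, aa_end: int
) -> tuple[int, int, str]:
    """Map a half-open aa interval of a frame translation to forward-strand
    genomic coordinates.  Returns ``(start, end, strand)``."""
    if not (0 <= aa_start <= aa_end <= len(t.aa)):
        raise IndexError(
            f"aa interval [{aa_start},{aa_end}) out of range for {t.seq_id} frame {t.frame}"
        )
    if t.frame > 0:
        k = t.rc_offset
        return k + 3 * aa_start, k + 3 * aa_end, "+"
    k = t.rc_offset
    L = t.seq_length
    # positions within the reverse complement
    rs, re_ = k + 3 * aa_start, k + 3 * aa_end
    return L - re_, L - rs, "-"


def extract_orfs(t: FrameTranslation, min_len: int = 15) -> list[OrfRecord]:
    """Split a frame translation on stop codons into maximal stop-free ORFs.

    Segments shorter than ``min_len`` residues (including those truncated by
    the sequence end) are dropped.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    out = []
    pos = 0
    for seg in t.aa.split("*"):
        if len(seg) >= min_len:
            gs, ge, strand = map_aa_to_genomic(t, pos, pos + len(seg))
            out.append(
                OrfRecord(
                    orf_id=f"{t.seq_id}|{t.frame:+d}|{pos}",
                    seq_id=t.seq_id,
                    frame=t.frame,
                    aa_start=pos,
                    aa_end=pos + len(seg),
                    aa=seg,
                    genomic_start=gs,
                    genomic_end=ge,
                    strand=strand,
                )
            )
        pos += len(seg) + 1
    return out


def read_annotation(gff_path, genome: list[GenomicSequence]) -> list[AnnotationModel]:
    """Load gene models (gene -> mRNA -> CDS) from a GFF3 file.

    CDS segments are assembled in transcription order and translated; models
    whose translation contains an internal stop are flagged via
    ``translation_ok`` but retained.
    """
    import gffutils

    by_id = {g.id: g for g in genome}
    try:
        db = gffutils.create_db(
            str(gff_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils reports the offending line
        raise ValueError(f"malformed GFF3 {gff_path}: {exc}") from exc

    models = []
    parents = list(db.features_of_type("mRNA")) or list(db.features_of_type("gene"))
    for mrna in sorted(parents, key=lambda f: (f.seqid, f.start, f.id or "")):
        cds = sorted(db.children(mrna, featuretype="CDS"), key=lambda c: c.start)
        if not cds:
            continue
        exons = [(c.start - 1, c.end) for c in cds]  # to 0-based half-open
        strand = mrna.strand
        if strand == "-":
            exons = exons[::-1]
        seq = by_id[mrna.seqid].residues
        parts = []
        for s, e in exons:
            chunk = seq[s:e]
            parts.append(chunk if strand == "+" else revcomp(chunk))
        cds_nt = "".join(parts)
        aa = translate_nt(cds_nt)
        if aa.endswith("*"):
            aa = aa[:-1]
        models.append(
            AnnotationModel(
                gene_id=mrna.id or f"{mrna.seqid}:{mrna.start}",
                seq_id=mrna.seqid,
                strand=strand,
                exons=exons,
                protein=aa,
                translation_ok="*" not in aa,
            )
        )
    return models


def write_gff3(models: list[AnnotationModel], path, source: str = "famfinder") -> None:
    """Write gene models as GFF3 (gene -> mRNA -> CDS, 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(models, key=lambda x: (x.seq_id, min(s for s, _ in x.exons))):
            lo = min(s for s, _ in m.exons) + 1
            hi = max(e for _, e in m.exons)
            attrs_gene = f"ID=gene:{m.gene_id}"
            attrs_mrna = f"ID={m.gene_id};Parent=gene:{m.gene_id}"
            for ftype, attrs in (("gene", attrs_gene), ("mRNA", attrs_mrna)):
                fh.write(
                    "\t".join(
                        [m.seq_id, source, ftype, str(lo), str(hi), ".", m.strand, ".", attrs]
                    )
                    + "\n"
                )
            cum = 0
            for i, (s, e) in enumerate(m.exons):  # transcription order
                phase = (3 - cum % 3) % 3
                fh.write(
                    "\t".join(
                        [
                            m.seq_id,
                            source,
                            "CDS",
                            str(s + 1),
                            str(e),
                            ".",
                            m.strand,
                            str(phase),
                            f"ID=cds:{m.gene_id}.{i};Parent={m.gene_id}",
                        ]
                    )
                    + "\n"
                )
                cum += e - s


def write_fasta(records: list[tuple[str, str]], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
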