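"""Synthetic genomes with planted family members and truth annotations.

The generator emulates the situation the finder targets: an intergenic
background of configurable GC content in which small secreted-peptide genes
are planted, each one ``ATG`` + an optional signal-peptide-like first
segment + the codon-encoding of a fresh draw from a protein family profile
+ a stop codon.  Two-exon genes are split by a single canonical GT..AG
intron (consensus-like donor context and pyrimidine-tract acceptor) at an
in-frame point in the central portion of the family-coding region, so that
both exons retain recognizable family signal.  Decoy pseudogenes carry one
induced premature in-frame stop; optional "diverged" decoys are drawn at
much lower conservation to populate the twilight zone between the relaxed
and strict E-value cutoffs.  Repeat tracts are rendered as hard-masked 'N'
runs.

All output is deterministic given the seed, byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hmm import AA, FamilyAlignment
from .seqio import AnnotationModel, GenomicSequence, revcomp, translate_nt

from .seqio import STANDARD_CODE

# codons per amino acid (standard code), sorted for determinism
_CODONS: dict[str, list[str]] = {}
for _c, _a in sorted(STANDARD_CODE.items()):
    _CODONS.setdefault(_a, []).append(_c)

STOP_CODONS = _CODONS["*"]

# signal-peptide building blocks: M-K-<10 hydrophobic>-A-X-A (no internal
# Met, so the true start codon is the nearest upstream in-frame ATG)
_HYDROPHOBIC = "LIVFA"
_CLEAVAGE_X = "STQN"


@dataclass
class FixtureSpec:
    seed: int = 1
    genome_length: int = 200_000
    gc: float = 0.40
    n_single_exon: int = 15
    n_two_exon: int = 15
    n_pseudogene: int = 10
    n_repeat_tracts: int = 0
    n_diverged: int = 0
    intron_len_range: tuple[int, int] = (80, 300)
    signal_peptide: bool = True
    family_members: int = 40
    family_length: int = 60
    family_conservation: float = 0.85
    diverged_conservation: float = 0.45
    repeat_tract_len: int = 300
    background_order: int = 0  # 0 = i.i.d.; 2 = order-2 Markov background
    family: FamilyAlignment | None = None


@dataclass
class PlantedGene:
    gene_id: str
    kind: str  # single | two_exon | pseudogene | diverged
    strand: str
    exons: list[tuple[int, int]]  # transcription order, forward-strand coords
    protein: str
    cds: str


@dataclass
class FixtureTruth:
    genome: GenomicSequence
    family: FamilyAlignment
    genes: list[PlantedGene] = field(default_factory=list)

    @property
    def annotation(self) -> list[AnnotationModel]:
        """Truth models: real planted genes only (decoys excluded)."""
        return [
            _to_annotation(self.genome.id, g)
            for g in self.genes
            if g.kind in ("single", "two_exon")
        ]

    @property
    def pseudogenes(self) -> list[AnnotationModel]:
        return [
            _to_annotation(self.genome.id, g)
            for g in self.genes
            if g.kind == "pseudogene"
        ]

    @property
    def diverged(self) -> list[AnnotationModel]:
        return [
            _to_annotation(self.genome.id, g)
            for g in self.genes
            if g.kind == "diverged"
        ]

    def write(self, outdir) -> None:
        import os

        from .seqio import write_fasta, write_gff3

        os.makedirs(outdir, exist_ok=True)
        write_fasta(
            [(self.genome.id, self.genome.residues)],
            os.path.join(outdir, "genome.fa"),
        )
        self.family.write(os.path.join(outdir, "family.afa"))
        write_fasta(
            [(g.gene_id, g.protein) for g in self.genes],
            os.path.join(outdir, "proteins.fa"),
        )
        write_gff3(self.annotation, os.path.join(outdir, "truth.gff3"))


def _to_annotation(seq_id: str, g: PlantedGene) -> AnnotationModel:
    return AnnotationModel(
        gene_id=g.gene_id,
        seq_id=seq_id,
        strand=g.strand,
        exons=list(g.exons),
        protein=g.protein,
        translation_ok="*" not in g.protein,
    )


def make_family(
    n_members: int = 40,
    length: int = 60,
    conservation: float = 0.85,
    seed: int = 0,
    cysteine_scaffold: bool = True,
) -> FamilyAlignment:
    """Sample a gap-free family alignment around a random consensus.

    Each member copies the consensus residue with probability
    ``conservation`` and otherwise substitutes a random different residue.
    With ``cysteine_scaffold`` six consensus positions are fixed cysteines
    (kept invariant in all members), mimicking the conserved scaffolds of
    small secreted peptide families.
    """
    if n_members < 2:
        raise ValueError("need at least 2 members")
    if not 0.0 <= conservation <= 1.0:
        raise ValueError("conservation must be in [0, 1]")
    rng = np.random.default_rng(seed)
    cons = [AA[i] for i in rng.integers(0, 20, size=length)]
    scaffold: set[int] = set()
    if cysteine_scaffold and length >= 12:
        pos = rng.choice(np.arange(2, length - 2), size=6, replace=False)
        scaffold = set(int(p) for p in pos)
        for p in scaffold:
            cons[p] = "C"
    members = []
    for m in range(n_members):
        seq = []
        for i, c in enumerate(cons):
            if i in scaffold or rng.random() < conservation:
                seq.append(c)
            else:
                alt = AA[rng.integers(0, 20)]
                while alt == c:
                    alt = AA[rng.integers(0, 20)]
                seq.append(alt)
        members.append((f"mem{m:03d}", "".join(seq)))
    return FamilyAlignment("synfam", members)


def _sample_member(rng, fam: FamilyAlignment, conservation: float) -> str:
    """A fresh family member: per-column majority consensus mutated at rate
    1 - conservation."""
    from .selection import family_consensus

    cons = family_consensus(fam).replace("-", "")
    out = []
    for c in cons:
        if rng.random() < conservation:
            out.append(c)
        else:
            alt = AA[rng.integers(0, 20)]
            while alt == c:
                alt = AA[rng.integers(0, 20)]
            out.append(alt)
    return "".join(out)


def _encode(rng, protein: str) -> str:
    """Encode a protein with uniformly sampled synonymous codons."""
    return "".join(
        _CODONS[a][rng.integers(0, len(_CODONS[a]))] for a in protein
    )


def _signal_prefix(rng) -> str:
    core = "".join(
        _HYDROPHOBIC[rng.integers(0, len(_HYDROPHOBIC))] for _ in range(10)
    )
    x = _CLEAVAGE_X[rng.integers(0, len(_CLEAVAGE_X))]
    return "MK" + core + "A" + x + "A"


def _background(rng, n: int, gc: float, order: int = 0) -> str:
    """Background sequence: i.i.d. by default, or an order-2 Markov chain
    whose transition rows are Dirichlet perturbations of the i.i.d. law."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    if order == 0 or n < 3:
        return "".join("ACGT"[i] for i in rng.choice(4, size=n, p=p))
    if order != 2:
        raise ValueError("background_order must be 0 or 2")
    trans = rng.dirichlet(p * 40, size=16)  # one row per dinucleotide context
    out = list(rng.choice(4, size=2, p=p))
    for _ in range(n - 2):
        ctx = out[-2] * 4 + out[-1]
        out.append(int(rng.choice(4, p=trans[ctx])))
    return "".join("ACGT"[i] for i in out)


def _intron(rng, length: int, gc: float) -> str:
    """GT..AG intron with consensus-like donor context and a pyrimidine
    tract before the acceptor."""
    head, tail = "GTAAGT", "".join(
        "TC"[rng.integers(0, 2)] for _ in range(8)
    ) + "CAG"
    core = _background(rng, length - len(head) - len(tail), gc)
    return head + core + tail


def plant_genome(spec: FixtureSpec) -> FixtureTruth:
    """Generate a genome with planted genes, decoys and truth annotation."""
    rng = np.random.default_rng(spec.seed)
    fam = spec.family or make_family(
        spec.family_members,
        spec.family_length,
        spec.family_conservation,
        seed=spec.seed,
    )
    ilo, ihi = spec.intron_len_range
    if ilo < 25:
        raise ValueError("intron_len_range minimum must be >= 25")

    # build each feature's nucleotide cassette (in transcription orientation)
    features = []  # (kind, strand, cassette, exon offsets within cassette, protein, cds)
    kinds = (
        ["single"] * spec.n_single_exon
        + ["two_exon"] * spec.n_two_exon
        + ["pseudogene"] * spec.n_pseudogene
        + ["diverged"] * spec.n_diverged
    )
    for kind in kinds:
        cons = (
            spec.diverged_conservation
            if kind == "diverged"
            else spec.family_conservation
        )
        member = _sample_member(rng, fam, cons)
        prefix = _signal_prefix(rng) if spec.signal_peptide else "M"
        protein = prefix + member
        codons = [_CODONS[a][rng.integers(0, len(_CODONS[a]))] for a in protein]
        if kind == "pseudogene":
            # premature stop early in the family-coding region
            j = len(prefix) + int(rng.integers(4, 13))
            codons[j] = STOP_CODONS[rng.integers(0, len(STOP_CODONS))]
            protein = protein[:j] + "*" + protein[j + 1 :]
        cds = "".join(codons) + STOP_CODONS[rng.integers(0, len(STOP_CODONS))]
        strand = "+" if rng.random() < 0.5 else "-"
        if kind == "two_exon":
            lo = len(prefix) + 12
            hi = len(protein) - 12
            split_codon = int(rng.integers(lo, hi))
            ilen = int(rng.integers(ilo, ihi + 1))
            intron = _intron(rng, ilen, spec.gc)
            cut = split_codon * 3
            cassette = cds[:cut] + intron + cds[cut:]
            exon_offsets = [(0, cut), (cut + ilen, len(cassette))]
        else:
            cassette = cds
            exon_offsets = [(0, len(cds))]
        features.append((kind, strand, cassette, exon_offsets, protein, cds))
    for _ in range(spec.n_repeat_tracts):
        features.append(("repeat", "+", "N" * spec.repeat_tract_len, [], "", ""))

    # place features without overlap, with clearance for windows/extension
    margin = 450
    occupied: list[tuple[int, int]] = []
    placements: list[int] = []
    for kind, strand, cassette, *_ in features:
        ln = len(cassette)
        pos = None
        for _try in range(2000):
            cand = int(rng.integers(margin, spec.genome_length - ln - margin))
            if all(
                cand + ln + margin <= s or e + margin <= cand
                for s, e in occupied
            ):
                pos = cand
                break
        if pos is None:
            raise RuntimeError(
                "could not place all features; genome too small for spec"
            )
        occupied.append((pos, pos + ln))
        placements.append(pos)

    genome = list(_background(rng, spec.genome_length, spec.gc, spec.background_order))
    genes: list[PlantedGene] = []
    order = sorted(range(len(features)), key=lambda i: placements[i])
    counter = 0
    for i in order:
        kind, strand, cassette, exon_offsets, protein, cds = features[i]
        pos = placements[i]
        insert = cassette if strand == "+" else revcomp(cassette)
        genome[pos : pos + len(cassette)] = insert
        if kind == "repeat":
            continue
        counter += 1
        if strand == "+":
            exons = [(pos + s, pos + e) for s, e in exon_offsets]
        else:
            end = pos + len(cassette)
            exons = [(end - e, end - s) for s, e in exon_offsets]
        genes.append(
            PlantedGene(
                gene_id=f"g{counter:04d}_{kind}",
                kind=kind,
                strand=strand,
                exons=exons,
                protein=protein,
                cds=cds,
            )
        )

    g = GenomicSequence("synchr1", "".join(genome))
    truth = FixtureTruth(genome=g, family=fam, genes=genes)
    _verify(truth)
    return truth


def _verify(truth: FixtureTruth) -> None:
    """By-construction check: every planted gene re-translates correctly."""
    seq = truth.genome.residues
    for gene in truth.genes:
        parts = []
        for s, e in gene.exons:
            chunk = seq[s:e]
            parts.append(chunk if gene.strand == "+" else revcomp(chunk))
        cds = "".join(parts)
        aa = translate_nt(cds)
        if not aa.endswith("*") or aa[:-1] != gene.protein:
            raise AssertionError(f"planted gene {gene.gene_id} failed re-translation")
        if len(gene.exons) == 2:
            a, b = gene.exons if gene.strand == "+" else gene.exons[::-1]
            intron = seq[a[1] : b[0]]
            if gene.strand == "-":
                intron = revcomp(intron)
            if not (intron.startswith("GT") and intron.endswith("AG")):
                raise AssertionError(f"{gene.gene_id}: non-canonical intron")
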