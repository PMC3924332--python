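"""Projection of profile hits to the genome and assembly of extended hits.

Profile hits live in protein space (translated-genome ORFs or annotated
proteins).  This module recovers their genomic coordinates, removes
low-significance hits, resolves overlapping hits from competing profiles,
and chains nearby partial hits - same family, same strand, hitting different
profile segments in an order collinear with transcription - into "extended
hits" whose blocks approximate the exons of the underlying gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .hmm import ProfileHit
from .seqio import AnnotationModel, OrfRecord, map_aa_to_genomic

DEFAULT_MERGE_GAP = 2500
DEFAULT_PROFILE_OVERLAP_TOL = 5


@dataclass(frozen=True)
class GenomicHit:
    family_id: str
    seq_id: str
    start: int  # forward-strand half-open
    end: int
    strand: str
    frame: int | None  # None for proteome-derived hits
    profile_interval: tuple[int, int]
    bit_score: float
    evalue: float
    source: str  # "translated-genome" | "proteome"

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class ExtendedHit:
    hit_id: str
    family_id: str
    seq_id: str
    strand: str
    blocks: list[tuple[int, int]]  # transcription order
    profile_intervals: list[tuple[int, int]]  # per block
    best_evalue: float
    members: list[GenomicHit] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        lo = min(s for s, _ in self.blocks)
        hi = max(e for _, e in self.blocks)
        return lo, hi


class MappingContext:
    """Resolves profile-hit target ids back to genomic coordinates."""

    def __init__(
        self,
        orfs: list[OrfRecord] | None = None,
        frames=None,
        annotations: list[AnnotationModel] | None = None,
    ):
        self.orfs = {o.orf_id: o for o in (orfs or [])}
        # (seq_id, frame) -> FrameTranslation
        self.frames = {(t.seq_id, t.frame): t for t in (frames or [])}
        self.annotations = {a.gene_id: a for a in (annotations or [])}

    def register_frames(self, frames) -> None:
        for t in frames:
            self.frames[(t.seq_id, t.frame)] = t


def project_hits(hits: list[ProfileHit], ctx: MappingContext) -> list[GenomicHit]:
    """Convert protein-space hits to forward-strand genomic hits.

    ORF hits map through their frame translation (one block).  Proteome hits
    map through the annotation's exon structure and are split into one
    GenomicHit per overlapped exon, each annotated with the profile segment
    it covers.
    """
    out: list[GenomicHit] = []
    for h in hits:
        if h.target_id in ctx.orfs:
            orf = ctx.orfs[h.target_id]
            t = ctx.frames[(orf.seq_id, orf.frame)]
            a0 = orf.aa_start + h.target_interval[0]
            a1 = orf.aa_start + h.target_interval[1]
            gs, ge, strand = map_aa_to_genomic(t, a0, a1)
            out.append(
                GenomicHit(
                    family_id=h.family_id,
                    seq_id=orf.seq_id,
                    start=gs,
                    end=ge,
                    strand=strand,
                    frame=orf.frame,
                    profile_interval=h.profile_interval,
                    bit_score=h.bit_score,
                    evalue=h.evalue,
                    source="translated-genome",
                )
            )
        elif h.target_id in ctx.annotations:
            ann = ctx.annotations[h.target_id]
            blocks = ann.aa_to_genomic_blocks(*h.target_interval)
            # apportion the profile interval over blocks by aa length
            p0, p1 = h.profile_interval
            total_aa = h.target_interval[1] - h.target_interval[0]
            done = 0.0
            for s, e in blocks:
                aa_here = (e - s) / 3.0
                q0 = p0 + round((p1 - p0) * done / total_aa)
                q1 = p0 + round((p1 - p0) * (done + aa_here) / total_aa)
                done += aa_here
                out.append(
                    GenomicHit(
                        family_id=h.family_id,
                        seq_id=ann.seq_id,
                        start=s,
                        end=e,
                        strand=ann.strand,
                        frame=None,
                        profile_interval=(q0, max(q1, q0 + 1)),
                        bit_score=h.bit_score,
                        evalue=h.evalue,
                        source="proteome",
                    )
                )
        else:
            raise KeyError(f"cannot resolve hit target {h.target_id!r}")
    return out


def significance_filter(
    hits: list[GenomicHit], e_keep: float = 0.1
) -> list[GenomicHit]:
    """Keep hits with E-value <= ``e_keep`` (drop low-significance hits)."""
    if e_keep <= 0:
        raise ValueError("e_keep must be > 0")
    return [h for h in hits if h.evalue <= e_keep]


def select_best_per_cluster(hits: list[GenomicHit]) -> list[GenomicHit]:
    """One best hit per cluster of genomically overlapping hits.

    Hits on the same sequence and strand are tiled by coordinate; connected
    components of the overlap graph form clusters, and each cluster's
    representative is chosen by lowest E-value, then highest bit score, then
    smallest start.
    """
    groups: dict[tuple[str, str], list[GenomicHit]] = {}
    for h in hits:
        groups.setdefault((h.seq_id, h.strand), []).append(h)
    out = []
    for key in sorted(groups):
        ghits = sorted(groups[key], key=lambda h: (h.start, h.end))
        cluster: list[GenomicHit] = []
        hi = -1
        for h in ghits:
            if cluster and h.start >= hi:
                out.append(_best(cluster))
                cluster = []
                hi = -1
            cluster.append(h)
            hi = max(hi, h.end)
        if cluster:
            out.append(_best(cluster))
    out.sort(key=lambda h: (h.seq_id, h.start, h.strand))
    return out


def _best(cluster: list[GenomicHit]) -> GenomicHit:
    return min(cluster, key=lambda h: (h.evalue, -h.bit_score, h.start))


def merge_partial_hits(
    hits: list[GenomicHit],
    max_gap: int = DEFAULT_MERGE_GAP,
    profile_overlap_tol: int = DEFAULT_PROFILE_OVERLAP_TOL,
) -> list[ExtendedHit]:
    """Chain nearby partial hits of one family into extended hits.

    Two hits are chained when they lie on the same sequence and strand,
    their genomic gap (in transcription direction) is within ``max_gap``,
    and the later-transcribed hit covers a later profile segment, with at
    most ``profile_overlap_tol`` match columns of overlap (alignment jitter
    at exon boundaries).  Unchained hits become single-block extended hits.
    Input order does not matter: hits are canonically sorted before
    chaining.
    """
    groups: dict[tuple[str, str, str], list[GenomicHit]] = {}
    for h in hits:
        groups.setdefault((h.family_id, h.seq_id, h.strand), []).append(h)
    chains: list[list[GenomicHit]] = []
    for key in sorted(groups):
        ghits = groups[key]
        minus = key[2] == "-"
        # transcription order: ascending start on +, descending end on -
        ghits.sort(key=lambda h: (-h.end, -h.start) if minus else (h.start, h.end))
        chain: list[GenomicHit] = []
        for h in ghits:
            if chain and _chainable(chain[-1], h, max_gap, profile_overlap_tol, minus):
                chain.append(h)
            else:
                if chain:
                    chains.append(chain)
                chain = [h]
        if chain:
            chains.append(chain)
    out = []
    chains.sort(key=lambda c: (c[0].seq_id, min(h.start for h in c), c[0].strand))
    for i, chain in enumerate(chains):
        out.append(
            ExtendedHit(
                hit_id=f"xh{i:04d}",
                family_id=chain[0].family_id,
                seq_id=chain[0].seq_id,
                strand=chain[0].strand,
                blocks=[h.interval for h in chain],
                profile_intervals=[h.profile_interval for h in chain],
                best_evalue=min(h.evalue for h in chain),
                members=list(chain),
            )
        )
    return out


def _chainable(
    prev: GenomicHit, nxt: GenomicHit, max_gap: int, tol: int, minus: bool
) -> bool:
    if minus:
        gap = prev.start - nxt.end
    else:
        gap = nxt.start - prev.end
    if gap < 0 or gap > max_gap:
        return False
    # the later-transcribed block must hit a later profile segment
    p_prev, p_next = prev.profile_interval, nxt.profile_interval
    if p_next[0] < p_prev[1] - tol:
        return False
    return p_next[1] > p_prev[1]


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_extended_hits(hits: list[ExtendedHit], path, n_db: int | None = None) -> None:
    """Extended hits as TSV (blocks and profile intervals as 's-e;s-e')."""
    with open(path, "w") as fh:
        if n_db is not None:
            fh.write(f"# n_db = {n_db}\n")
        fh.write("hit_id\tfamily\tseq_id\tstrand\tblocks\tprofile_intervals\tbest_evalue\n")
        for h in hits:
            blocks = ";".join(f"{s}-{e}" for s, e in h.blocks)
            pints = ";".join(f"{s}-{e}" for s, e in h.profile_intervals)
            fh.write(
                f"{h.hit_id}\t{h.family_id}\t{h.seq_id}\t{h.strand}\t"
                f"{blocks}\t{pints}\t{h.best_evalue:.6g}\n"
            )


def read_extended_hits(path) -> tuple[list[ExtendedHit], int | None]:
    hits: list[ExtendedHit] = []
    n_db = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# n_db"):
                n_db = int(line.split("=")[1])
                continue
            if not line or line.startswith(("#", "hit_id\t")):
                continue
            hid, fam, seq, strand, blocks, pints, ev = line.split("\t")
            parse = lambda s: [
                (int(a), int(b))
                for a, b in (x.split("-") for x in s.split(";") if x)
            ]
            hits.append(
                ExtendedHit(
                    hit_id=hid,
                    family_id=fam,
                    seq_id=seq,
                    strand=strand,
                    blocks=parse(blocks),
                    profile_intervals=parse(pints),
                    best_evalue=float(ev),
                )
            )
    return hits, n_db


def write_extended_hits_bed(hits: list[ExtendedHit], path) -> None:
    """BED12-style export: one record per extended hit with block structure."""
    with open(path, "w") as fh:
        for h in hits:
            lo, hi = h.span
            blocks = sorted(h.blocks)
            sizes = ",".join(str(e - s) for s, e in blocks)
            starts = ",".join(str(s - lo) for s, _ in blocks)
            fh.write(
                f"{h.seq_id}\t{lo}\t{hi}\t{h.family_id}:{h.hit_id}\t0\t{h.strand}\t"
                f"{lo}\t{hi}\t0\t{len(blocks)}\t{sizes}\t{starts}\n"
            )


def write_extended_hits_gff3(hits: list[ExtendedHit], path) -> None:
    """Intermediate GFF3 with match/match_part features per extended hit."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for h in hits:
            lo, hi = h.span
            fh.write(
                "\t".join([
                    h.seq_id, "famfinder", "match", str(lo + 1), str(hi),
                    f"{h.best_evalue:.3g}", h.strand, ".",
                    f"ID={h.hit_id};Name={h.family_id}",
                ]) + "\n"
            )
            for i, ((s, e), (p0, p1)) in enumerate(
                zip(h.blocks, h.profile_intervals)
            ):
                fh.write(
                    "\t".join([
                        h.seq_id, "famfinder", "match_part", str(s + 1), str(e),
                        ".", h.strand, ".",
                        f"ID={h.hit_id}.{i};Parent={h.hit_id};"
                        f"Target={h.family_id} {p0 + 1} {p1}",
                    ]) + "\n"
                )
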