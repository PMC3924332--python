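"""Splice-aware construction of candidate gene models around extended hits.

For each extended hit a genomic window is cut (2500 bp upstream of the hit,
1500 bp downstream, in transcription orientation), canonical splice sites
are located and scored with position weight matrices, and all complete one-
and two-exon gene models compatible with the hit reading frame(s) are
enumerated: exons must preserve the hit blocks' frames, introns must be
GT..AG (optionally GC..AG) within configured length bounds, and the coding
sequence is extended outward to the nearest in-frame start codon (scanning
stops at an in-frame stop) and the nearest in-frame stop codon.

Candidates with internal stop codons are flagged rather than dropped;
selection downstream decides their fate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .mining import ExtendedHit
from .seqio import GenomicSequence, revcomp, translate_nt

log = logging.getLogger(__name__)

DEFAULT_WINDOW_UP = 2500
DEFAULT_WINDOW_DOWN = 1500

STOPS = {"TAA", "TAG", "TGA"}

_BASE = {"A": 0, "C": 1, "G": 2, "T": 3}

# Donor weight matrix: exon[-3:] + intron[:6]; consensus cAG|GTAAGT.
# Probabilities per position over ACGT, scored as log-odds vs uniform 0.25.
DONOR_PWM = np.array(
    [
        [0.35, 0.40, 0.15, 0.10],  # -3
        [0.60, 0.12, 0.15, 0.13],  # -2
        [0.10, 0.04, 0.80, 0.06],  # -1
        [0.01, 0.01, 0.97, 0.01],  # +1 G
        [0.01, 0.02, 0.01, 0.96],  # +2 T
        [0.55, 0.05, 0.30, 0.10],  # +3
        [0.70, 0.07, 0.11, 0.12],  # +4
        [0.08, 0.05, 0.79, 0.08],  # +5
        [0.15, 0.16, 0.14, 0.55],  # +6
    ]
)

# Acceptor weight matrix: intron[-13:] + exon[:2]; pyrimidine tract + nCAG|Gn.
ACCEPTOR_PWM = np.array(
    [[0.10, 0.33, 0.09, 0.48]] * 8  # -13..-6 pyrimidine tract
    + [
        [0.10, 0.35, 0.07, 0.48],  # -5
        [0.23, 0.30, 0.07, 0.40],  # -4
        [0.05, 0.65, 0.05, 0.25],  # -3 C
        [0.97, 0.01, 0.01, 0.01],  # -2 A
        [0.01, 0.01, 0.97, 0.01],  # -1 G
        [0.25, 0.15, 0.50, 0.10],  # +1
        [0.30, 0.20, 0.25, 0.25],  # +2
    ]
)

_LOG_DONOR = np.log2(DONOR_PWM / 0.25)
_LOG_ACCEPTOR = np.log2(ACCEPTOR_PWM / 0.25)


@dataclass(frozen=True)
class GenomicWindow:
    """A hit-anchored genomic window, oriented in transcription direction.

    ``start``/``end`` are forward-strand contig coordinates; ``sequence`` is
    already reverse-complemented for minus-strand hits, and
    ``hit_blocks_local`` / all model-builder coordinates are offsets into
    ``sequence`` (i.e. transcription-direction coordinates).
    """

    seq_id: str
    start: int
    end: int
    strand: str
    sequence: str
    origin: str  # ExtendedHit id
    family_id: str
    hit_blocks_local: list[tuple[int, int]]
    profile_intervals: list[tuple[int, int]]

    def local_to_genomic(self, ls: int, le: int) -> tuple[int, int]:
        if self.strand == "+":
            return self.start + ls, self.start + le
        return self.end - le, self.end - ls


@dataclass(frozen=True)
class SpliceSite:
    kind: str  # "donor" | "acceptor"
    pos: int  # window coordinate of the intron boundary (half-open intron [d, a))
    dinucleotide: str
    pwm_score: float


@dataclass
class CandidateModel:
    model_id: str
    origin: str  # ExtendedHit id
    seq_id: str
    strand: str
    exons: list[tuple[int, int]]  # forward-strand genomic, transcription order
    exons_local: list[tuple[int, int]]  # window coordinates
    cds: str
    protein: str
    has_start: bool
    has_stop: bool
    has_internal_stop: bool
    splice_scores: list[float] = field(default_factory=list)

    @property
    def splice_score(self) -> float:
        return sum(self.splice_scores)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def genomic_span(self) -> tuple[int, int]:
        return min(s for s, _ in self.exons), max(e for _, e in self.exons)


@dataclass
class ModelBuilderConfig:
    min_intron: int = 40
    max_intron: int = 2500
    allow_gc_donor: bool = False
    max_candidates: int = 50  # cap on two-exon candidates, by splice score
    junction_slack: int = 9  # nt a splice may cut into a hit block


def extract_window(
    x: ExtendedHit,
    genome: dict[str, GenomicSequence] | list[GenomicSequence],
    up: int = DEFAULT_WINDOW_UP,
    down: int = DEFAULT_WINDOW_DOWN,
) -> GenomicWindow:
    """Cut the genomic window around an extended hit.

    ``up`` bases upstream of the hit span and ``down`` bases downstream are
    taken in *transcription* orientation (on the minus strand "upstream"
    means larger forward-strand coordinates) and clipped to the contig.
    """
    if isinstance(genome, list):
        genome = {g.id: g for g in genome}
    g = genome[x.seq_id]
    lo, hi = x.span
    if x.strand == "+":
        ws, we = max(0, lo - up), min(g.length, hi + down)
        seq = g.residues[ws:we]
        local = [(s - ws, e - ws) for s, e in x.blocks]
    else:
        ws, we = max(0, lo - down), min(g.length, hi + up)
        seq = revcomp(g.residues[ws:we])
        local = [(we - e, we - s) for s, e in x.blocks]
    return GenomicWindow(
        seq_id=x.seq_id,
        start=ws,
        end=we,
        strand=x.strand,
        sequence=seq,
        origin=x.hit_id,
        family_id=x.family_id,
        hit_blocks_local=local,
        profile_intervals=list(x.profile_intervals),
    )


def _pwm_score(seq: str, pos0: int, logm: np.ndarray) -> float:
    """Sum PWM log-odds over the window starting at pos0; positions outside
    the sequence or holding N contribute 0."""
    total = 0.0
    for j in range(logm.shape[0]):
        p = pos0 + j
        if 0 <= p < len(seq):
            b = _BASE.get(seq[p])
            if b is not None:
                total += logm[j, b]
    return total


def score_donor(seq: str, d: int) -> float:
    """PWM score of a donor whose intron starts at window position ``d``."""
    return _pwm_score(seq, d - 3, _LOG_DONOR)


def score_acceptor(seq: str, a: int) -> float:
    """PWM score of an acceptor whose intron ends (half-open) at ``a``."""
    return _pwm_score(seq, a - 13, _LOG_ACCEPTOR)


def scan_splice_sites(
    w: GenomicWindow, allow_gc_donor: bool = False
) -> list[SpliceSite]:
    """All canonical donor (GT, optionally GC) and acceptor (AG) sites."""
    seq = w.sequence
    sites: list[SpliceSite] = []
    donors = {"GT", "GC"} if allow_gc_donor else {"GT"}
    for i in range(len(seq) - 1):
        di = seq[i : i + 2]
        if di in donors:
            sites.append(SpliceSite("donor", i, di, score_donor(seq, i)))
        if di == "AG":
            sites.append(SpliceSite("acceptor", i + 2, di, score_acceptor(seq, i + 2)))
    return sites


def _scan_starts(seq: str, anchor: int) -> list[tuple[int, bool]]:
    """All reachable in-frame start codons upstream of ``anchor``.

    Scans from ``anchor`` (inclusive) upstream in steps of one codon,
    collecting every ATG, and halts at the first in-frame stop codon or the
    sequence edge.  Returns ``[(start, True), ...]`` nearest first, or
    ``[(anchor, False)]`` when no start codon is reachable.  Candidates are
    built for every reachable start; model selection arbitrates between
    them.
    """
    starts: list[tuple[int, bool]] = []
    p = anchor
    while p >= 0:
        c = seq[p : p + 3]
        if c == "ATG":
            starts.append((p, True))
        elif c in STOPS:
            break
        p -= 3
    return starts or [(anchor, False)]


def _scan_stop(seq: str, anchor: int) -> tuple[int, bool]:
    """First in-frame stop codon at or after ``anchor``; returns the CDS end
    (position just past the stop codon) and whether one was found."""
    p = anchor
    while p + 3 <= len(seq):
        if seq[p : p + 3] in STOPS:
            return p + 3, True
        p += 3
    return anchor + (len(seq) - anchor) // 3 * 3, False


def enumerate_models(
    w: GenomicWindow,
    sites: list[SpliceSite] | None = None,
    config: ModelBuilderConfig | None = None,
) -> list[CandidateModel]:
    """Enumerate complete candidate gene models for one window.

    Single-exon candidates treat the hit block span as one reading frame;
    two-exon candidates pair every donor in/near the inter-block gap with
    every acceptor before block 2 such that the intron is GT..AG (or GC..AG
    when configured), its length lies in ``[min_intron, max_intron]``, and
    the total exonic length up to block 2 keeps both blocks in frame.  Both
    kinds are extended to the nearest in-frame start/stop codons.  Two-exon
    candidates are capped at ``max_candidates`` by total splice PWM score.
    """
    cfg = config or ModelBuilderConfig()
    if sites is None:
        sites = scan_splice_sites(w, cfg.allow_gc_donor)
    blocks = sorted(w.hit_blocks_local)
    if not blocks:
        return []
    if len(blocks) > 2:
        keep = sorted(blocks, key=lambda b: b[1] - b[0], reverse=True)[:2]
        log.warning(
            "%s: %d hit blocks; trimming to the two longest", w.origin, len(blocks)
        )
        blocks = sorted(keep)
    seq = w.sequence
    out: list[CandidateModel] = []

    # ---- single-exon candidates --------------------------------------
    frames = {b[0] % 3 for b in blocks}
    if len(frames) == 1:
        span_s, span_e = blocks[0][0], blocks[-1][1]
        span_e = span_s + (span_e - span_s) // 3 * 3
        for si, (start, has_start) in enumerate(_scan_starts(seq, span_s)):
            end, has_stop = _scan_stop(seq, span_e)
            cds = seq[start:end]
            if not cds:
                continue
            prot = translate_nt(cds)
            if has_stop and prot.endswith("*"):
                prot = prot[:-1]
            out.append(
                CandidateModel(
                    model_id=f"{w.origin}.s{si}",
                    origin=w.origin,
                    seq_id=w.seq_id,
                    strand=w.strand,
                    exons=[w.local_to_genomic(start, end)],
                    exons_local=[(start, end)],
                    cds=cds,
                    protein=prot,
                    has_start=has_start,
                    has_stop=has_stop,
                    has_internal_stop="*" in prot,
                    splice_scores=[],
                )
            )

    # ---- two-exon candidates -----------------------------------------
    # (a) introns between two hit blocks; (b) frame-preserving introns
    # inside a single contiguous block: an in-frame, stop-free intron does
    # not interrupt the ORF, so the homology search reports one block with
    # the translated intron absorbed as inserts, and splitting it is the
    # model builder's job.
    slack = cfg.junction_slack
    pairs: list[tuple[SpliceSite, SpliceSite]] = []
    if len(blocks) == 2:
        b1, b2 = blocks
        anchor, tail_end = b1[0], b2[1]
        donors = [
            s
            for s in sites
            if s.kind == "donor"
            and max(b1[0] + 3, b1[1] - slack) <= s.pos < b2[0]
        ]
        acceptors = [
            s
            for s in sites
            if s.kind == "acceptor" and b1[1] <= s.pos <= b2[0] + slack
        ]
        for dsite in donors:
            for asite in acceptors:
                ilen = asite.pos - dsite.pos
                if not (cfg.min_intron <= ilen <= cfg.max_intron):
                    continue
                if ((dsite.pos - b1[0]) + (b2[0] - asite.pos)) % 3 != 0:
                    continue
                pairs.append((dsite, asite))
    else:
        b = blocks[0]
        anchor, tail_end = b[0], b[1]
        donors = [
            s for s in sites if s.kind == "donor" and b[0] + 3 <= s.pos < b[1] - 3
        ]
        acceptors = [
            s for s in sites if s.kind == "acceptor" and s.pos <= b[1] - 3
        ]
        for dsite in donors:
            for asite in acceptors:
                ilen = asite.pos - dsite.pos
                if not (cfg.min_intron <= ilen <= cfg.max_intron):
                    continue
                if ilen % 3 != 0:  # must preserve the single block's frame
                    continue
                pairs.append((dsite, asite))

    pairs.sort(
        key=lambda p: (-(p[0].pwm_score + p[1].pwm_score), p[0].pos, p[1].pos)
    )
    starts = _scan_starts(seq, anchor)
    idx = 0
    for dsite, asite in pairs[: cfg.max_candidates]:
        d, a = dsite.pos, asite.pos
        for start, has_start in starts:
            len_ex1 = d - start
            combined = seq[start:d] + seq[a:]
            scan_from = len_ex1 + (tail_end - a)
            scan_from -= scan_from % 3
            cds_end, has_stop = _scan_stop(combined, scan_from)
            cds = combined[:cds_end]
            if cds_end <= len_ex1:
                continue  # degenerate: model ends before the intron
            prot = translate_nt(cds)
            if has_stop and prot.endswith("*"):
                prot = prot[:-1]
            ex2_local = (a, a + (cds_end - len_ex1))
            out.append(
                CandidateModel(
                    model_id=f"{w.origin}.t{idx}",
                    origin=w.origin,
                    seq_id=w.seq_id,
                    strand=w.strand,
                    exons=[
                        w.local_to_genomic(start, d),
                        w.local_to_genomic(*ex2_local),
                    ],
                    exons_local=[(start, d), ex2_local],
                    cds=cds,
                    protein=prot,
                    has_start=has_start,
                    has_stop=has_stop,
                    has_internal_stop="*" in prot,
                    splice_scores=[dsite.pwm_score + asite.pwm_score],
                )
            )
            idx += 1
    return out


# ---------------------------------------------------------------------------
# external predictor seam
# ---------------------------------------------------------------------------

_PREDICTOR_REGISTRY: list = []


def register_external_predictor(adapter) -> None:
    """Register an adapter callable ``(window, hints) -> [CandidateModel]``."""
    _PREDICTOR_REGISTRY.append(adapter)


def clear_external_predictors() -> None:
    _PREDICTOR_REGISTRY.clear()


def external_predictor_seam(
    w: GenomicWindow, hints: dict | None = None
) -> list[CandidateModel]:
    """Collect candidates from registered external gene predictors.

    Adapter failures are logged and contained; with no adapters registered
    the result is empty and the native candidates stand alone.
    """
    out: list[CandidateModel] = []
    for adapter in _PREDICTOR_REGISTRY:
        try:
            out.extend(adapter(w, hints or {}))
        except Exception as exc:
            log.warning("external predictor %r failed: %s", adapter, exc)
    return out


def export_hints_gff(w: GenomicWindow) -> str:
    """Hit blocks as CDSpart hints (GFF dialect used by evidence-mode
    predictors), in window-local coordinates."""
    lines = []
    for i, (s, e) in enumerate(w.hit_blocks_local):
        lines.append(
            "\t".join(
                [
                    w.origin,
                    "famfinder",
                    "CDSpart",
                    str(s + 1),
                    str(e),
                    ".",
                    "+",
                    ".",
                    f"source=M;group=b{i}",
                ]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")
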