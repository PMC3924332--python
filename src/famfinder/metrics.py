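"""Prediction accuracy metrics against a truth annotation.

Sensitivity and specificity are computed at two levels:

* nucleotide level - per-base, strand-aware comparison of CDS coverage:
  ``TP`` bases coding in both prediction and truth, ``FN`` coding in truth
  only, ``FP`` coding in prediction only; ``Sn = TP/(TP+FN)``,
  ``Sp = TP/(TP+FP)``.
* exon level - an exon counts as correct only when both boundaries match a
  truth exon exactly on the same strand.

True negatives are deliberately not counted: a family-restricted gene
finder ignores all genes outside the profile's family, so the non-coding /
non-family complement is not a meaningful denominator.

``compare_annotation`` categorizes predictions against an existing (not
necessarily truth) annotation as exact / minor-conflict (same frame,
boundary shifts of fewer than 15 aa) / major-conflict / unannotated.
"""

from __future__ import annotations

from dataclasses import dataclass

MINOR_CONFLICT_AA = 15


@dataclass
class EvalCounts:
    level: str  # "nucleotide" | "exon"
    tp: int
    fp: int
    fn: int

    @property
    def sn(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def sp(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d else None


def _check_model(exons: list[tuple[int, int]], name: str) -> None:
    exs = sorted(exons)
    for (s1, e1), (s2, e2) in zip(exs, exs[1:]):
        if s2 < e1:
            raise ValueError(f"{name}: overlapping exons within one model")
    for s, e in exs:
        if e <= s:
            raise ValueError(f"{name}: empty or inverted exon interval")


def _coverage(models) -> dict[tuple[str, str], set[int]]:
    cov: dict[tuple[str, str], set[int]] = {}
    for m in models:
        _check_model(m.exons, getattr(m, "gene_id", "model"))
        key = (m.seq_id, m.strand)
        s = cov.setdefault(key, set())
        for a, b in m.exons:
            s.update(range(a, b))
    return cov


def nucleotide_metrics(pred, truth) -> EvalCounts:
    """Per-base strand-aware CDS coverage comparison.

    ``pred`` and ``truth`` are sequences of objects with ``seq_id``,
    ``strand`` and ``exons`` (forward-strand half-open intervals).
    """
    pc = _coverage(pred)
    tc = _coverage(truth)
    tp = fp = fn = 0
    for key in set(pc) | set(tc):
        p = pc.get(key, set())
        t = tc.get(key, set())
        tp += len(p & t)
        fp += len(p - t)
        fn += len(t - p)
    return EvalCounts("nucleotide", tp, fp, fn)


def exon_metrics(pred, truth) -> EvalCounts:
    """Exact-boundary exon matching (same sequence, strand, start and end)."""
    ps, ts = set(), set()
    for m in pred:
        _check_model(m.exons, getattr(m, "gene_id", "model"))
        ps.update((m.seq_id, m.strand, s, e) for s, e in m.exons)
    for m in truth:
        _check_model(m.exons, getattr(m, "gene_id", "model"))
        ts.update((m.seq_id, m.strand, s, e) for s, e in m.exons)
    tp = len(ps & ts)
    return EvalCounts("exon", tp, len(ps) - tp, len(ts) - tp)


# ---------------------------------------------------------------------------
# comparison against an existing annotation
# ---------------------------------------------------------------------------

def _cds_phase_at(exons: list[tuple[int, int]], strand: str, pos: int) -> int | None:
    """Coding phase (CDS offset mod 3) of a forward-strand base, or None if
    the base is non-coding in this model."""
    cpos = 0
    for s, e in exons:
        if s <= pos < e:
            off = (pos - s) if strand == "+" else (e - 1 - pos)
            return (cpos + off) % 3
        cpos += e - s
    return None


def _same_frame(a, b) -> bool:
    """True if the two models translate some shared base in the same frame."""
    for s, e in a.exons:
        for s2, e2 in b.exons:
            lo, hi = max(s, s2), min(e, e2)
            for pos in range(lo, min(hi, lo + 3)):
                if _cds_phase_at(a.exons, a.strand, pos) == _cds_phase_at(
                    b.exons, b.strand, pos
                ):
                    return True
    return False


def _boundary_shift(a, b) -> int:
    """Largest boundary disagreement in nt between two exon chains."""
    ab = sorted(x for s, e in a.exons for x in (s, e))
    bb = sorted(x for s, e in b.exons for x in (s, e))
    if len(ab) != len(bb):
        return max(
            abs(x - y) for x, y in zip((ab[0], ab[-1]), (bb[0], bb[-1]))
        ) + 3 * MINOR_CONFLICT_AA  # different exon counts: never minor
    return max(abs(x - y) for x, y in zip(ab, bb))


def compare_annotation(pred, annotation) -> dict:
    """Label each prediction against an existing annotation.

    Categories (mutually exclusive, precedence exact > minor > major >
    unannotated):

    * ``exact`` - identical exon boundaries on the same strand;
    * ``minor-conflict`` - same reading frame, every boundary within
      ``MINOR_CONFLICT_AA`` (15) amino acids;
    * ``major-conflict`` - CDS overlap in a different frame or with larger
      boundary conflicts;
    * ``unannotated`` - no CDS overlap with any annotated model.

    Returns ``{"labels": [(model, category, matched annotation or None)],
    "counts": {category: n}}``.
    """
    counts = {"exact": 0, "minor-conflict": 0, "major-conflict": 0, "unannotated": 0}
    labels = []
    for p in pred:
        cat, match = "unannotated", None
        for ann in annotation:
            if ann.seq_id != p.seq_id or ann.strand != p.strand:
                continue
            overlap = any(
                max(s, s2) < min(e, e2)
                for s, e in p.exons
                for s2, e2 in ann.exons
            )
            if not overlap:
                continue
            if sorted(p.exons) == sorted(ann.exons):
                cat, match = "exact", ann
                break
            shift = _boundary_shift(p, ann)
            if _same_frame(p, ann) and shift < 3 * MINOR_CONFLICT_AA:
                if cat != "exact":
                    cat, match = "minor-conflict", ann
            elif cat == "unannotated":
                cat, match = "major-conflict", ann
        counts[cat] += 1
        labels.append((p, cat, match))
    return {"labels": labels, "counts": counts}
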