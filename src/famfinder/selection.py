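"""Candidate-model scoring and best-model selection.

Each candidate protein receives three scores:

* **MSA score** - the candidate is aligned to the family alignment with a
  profile-guided global aligner (affine gaps), every (candidate, member)
  pair of rows is scored columnwise with BLOSUM80, and the mean over members
  is returned.  Residue-gap columns cost -8 at a gap opening and -1 per
  extension; gap-gap columns contribute 0.
* **HmmProb score** - the sum of per-residue posterior alignment
  probabilities of the protein against the family profile, over its best
  local alignment.
* **signal score** - a built-in signal-peptide propensity score in [0, 1]
  combining N-terminal positive charge, a hydrophobic core, and an A-X-A
  style cleavage motif.  It is an explicit stand-in for an external
  signal-peptide predictor; the ``signal_scorer`` seam accepts any callable
  ``protein -> [0, 1]`` and the 0.4 gate applies to whichever is plugged in.

Selection per extended hit: candidates must (1) pass the signal gate (when
enabled), (2) have proper start/stop codons and no premature stop, and
(3) maximize MSA score + HmmProb score.  The two scores are summed on their
native scales by default (an optional z-score normalization mode equalizes
their units across the candidates of one hit).  A final E-value filter
(default 0.001) rescored on the completed protein produces the output set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

from . import hmm as hmm_mod
from .hmm import FamilyAlignment, ProfileHMM
from .models import CandidateModel

GAP_OPEN = -8.0
GAP_EXTEND = -1.0

_B80 = substitution_matrices.load("BLOSUM80")


def blosum80(a: str, b: str) -> float:
    try:
        return float(_B80[a, b])
    except (KeyError, IndexError):
        return float(_B80["X", "X"])


@dataclass
class ModelScore:
    msa_score: float
    hmmprob_score: float
    signal_score: float
    final_evalue: float = float("nan")

    @property
    def combined(self) -> float:
        return self.msa_score + self.hmmprob_score


@dataclass
class SelectedModel:
    model: CandidateModel
    score: ModelScore
    family_id: str
    rank: int = 0


# ---------------------------------------------------------------------------
# MSA score
# ---------------------------------------------------------------------------

def _column_profile(fam: FamilyAlignment) -> tuple[np.ndarray, np.ndarray]:
    """Per-column residue counts (C, 20) and gap counts (C,)."""
    C = fam.columns
    counts = np.zeros((C, 20))
    gaps = np.zeros(C)
    for _, s in fam.members:
        for c, ch in enumerate(s):
            i = hmm_mod.AA_INDEX.get(ch)
            if i is None:
                gaps[c] += 1
            else:
                counts[c, i] += 1
    return counts, gaps


_B80_MATRIX = np.array(
    [[blosum80(a, b) for b in hmm_mod.AA] for a in hmm_mod.AA]
)


def align_to_family(
    protein: str, fam: FamilyAlignment
) -> list[tuple[int | None, int | None]]:
    """Globally align a protein to the columns of a family alignment.

    Returns a list of (column index | None, residue index | None) pairs in
    alignment order: (c, r) aligned, (c, None) column deleted from the
    candidate, (None, r) residue inserted relative to the family.  Scoring
    is the mean BLOSUM80 of the residue against the column's residues (gap
    members contribute the extension penalty), with affine gaps.
    """
    counts, gaps = _column_profile(fam)
    n_mem = len(fam.members)
    C, n = fam.columns, len(protein)
    res_idx = np.array([hmm_mod.AA_INDEX.get(ch, -1) for ch in protein])
    # position-specific score: S[c, i] = mean member score of residue i in col c
    sub = counts @ _B80_MATRIX  # (C, 20)
    S = (sub + gaps[:, None] * GAP_EXTEND) / n_mem  # (C, 20)
    Sx = np.concatenate([S, np.full((C, 1), GAP_EXTEND)], axis=1)  # X residues

    NEG = -1e18
    # affine DP over (columns, residues)
    Mm = np.full((C + 1, n + 1), NEG)
    Ix = np.full((C + 1, n + 1), NEG)  # gap in family (residue insert)
    Iy = np.full((C + 1, n + 1), NEG)  # gap in candidate (column delete)
    Pm = np.zeros((C + 1, n + 1), np.int8)
    Px = np.zeros((C + 1, n + 1), np.int8)
    Py = np.zeros((C + 1, n + 1), np.int8)
    Mm[0, 0] = 0.0
    for j in range(1, n + 1):
        Ix[0, j] = GAP_OPEN + GAP_EXTEND * (j - 1)
        Px[0, j] = 1 if j > 1 else 0
    for c in range(1, C + 1):
        Iy[c, 0] = GAP_OPEN + GAP_EXTEND * (c - 1)
        Py[c, 0] = 2 if c > 1 else 0
    for c in range(1, C + 1):
        srow = Sx[c - 1]
        for j in range(1, n + 1):
            s = srow[res_idx[j - 1]]
            best, arg = Mm[c - 1, j - 1], 0
            if Ix[c - 1, j - 1] > best:
                best, arg = Ix[c - 1, j - 1], 1
            if Iy[c - 1, j - 1] > best:
                best, arg = Iy[c - 1, j - 1], 2
            Mm[c, j] = best + s
            Pm[c, j] = arg
            a = Mm[c, j - 1] + GAP_OPEN
            b = Ix[c, j - 1] + GAP_EXTEND
            Ix[c, j], Px[c, j] = (a, 0) if a >= b else (b, 1)
            a = Mm[c - 1, j] + GAP_OPEN
            b = Iy[c - 1, j] + GAP_EXTEND
            Iy[c, j], Py[c, j] = (a, 0) if a >= b else (b, 2)
    # traceback from the best closing state
    c, j = C, n
    state = int(np.argmax([Mm[c, j], Ix[c, j], Iy[c, j]]))
    pairs: list[tuple[int | None, int | None]] = []
    while c > 0 or j > 0:
        if state == 0:
            pairs.append((c - 1, j - 1))
            state = Pm[c, j]
            c, j = c - 1, j - 1
        elif state == 1:
            pairs.append((None, j - 1))
            state = Px[c, j]
            j -= 1
        else:
            pairs.append((c - 1, None))
            state = Py[c, j]
            c -= 1
    pairs.reverse()
    return pairs


def score_emitted_alignment(
    pairs: list[tuple[int | None, int | None]],
    protein: str,
    fam: FamilyAlignment,
) -> float:
    """Mean pairwise columnwise BLOSUM80 score of the emitted alignment."""
    total = 0.0
    for _, member in fam.members:
        score = 0.0
        in_gap = False  # residue-gap run state for this pair of rows
        for c, r in pairs:
            mch = member[c] if c is not None else "-"
            rch = protein[r] if r is not None else "-"
            m_gap = mch in hmm_mod.GAP_CHARS or c is None
            r_gap = rch == "-" or r is None
            if m_gap and r_gap:
                continue  # gap-gap columns score 0 and do not break runs
            if m_gap or r_gap:
                score += GAP_EXTEND if in_gap else GAP_OPEN
                in_gap = True
            else:
                score += blosum80(rch, mch)
                in_gap = False
        total += score
    return total / len(fam.members)


def msa_score(
    protein: str, fam: FamilyAlignment
) -> float:
    """Mean pairwise BLOSUM80 alignment score of a candidate protein against
    all members of its family alignment (profile-guided global alignment)."""
    if not protein:
        raise ValueError("cannot score an empty protein")
    pairs = align_to_family(protein, fam)
    return score_emitted_alignment(pairs, protein, fam)


def hmmprob_score(protein: str, h: ProfileHMM) -> float:
    """Sum of per-residue posteriors over the best local alignment."""
    return hmm_mod.hmmprob_score(protein, h)


# ---------------------------------------------------------------------------
# signal-peptide propensity
# ---------------------------------------------------------------------------

# Kyte-Doolittle hydropathy
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}


def signal_score(protein: str) -> float:
    """Signal-peptide propensity in [0, 1] (built-in stand-in scorer).

    Combines positive charge among residues 2-5 (n-region), the best mean
    hydropathy of an 8-residue window within residues 6-20 (h-region), and
    the presence of a small-residue [AGS]-X-[AGS] cleavage-like motif in
    residues 10-30 (c-region).  Proteins shorter than 15 residues score 0.
    """
    if len(protein) < 15:
        return 0.0
    charge = sum(1 for c in protein[1:5] if c in "KR")
    n_term = min(charge / 2.0, 1.0)
    region = protein[5:20]
    windows = [region[i : i + 8] for i in range(len(region) - 7)]
    hydro = max(
        sum(_KD.get(c, -0.5) for c in win) / 8.0 for win in windows
    )
    h_core = min(max(hydro / 4.5, 0.0), 1.0)
    c_region = protein[9:30]
    motif = any(
        c_region[i] in "AGS" and c_region[i + 2] in "AGS"
        for i in range(max(len(c_region) - 2, 0))
    )
    return min(0.25 * n_term + 0.55 * h_core + 0.20 * motif, 1.0)


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

#: pluggable signal-peptide scorer (protein -> [0, 1]); the built-in
#: feature-based scorer by default
_SIGNAL_SCORER = [signal_score]


def set_signal_scorer(fn) -> None:
    """Install an external signal-peptide scorer (``protein -> [0, 1]``);
    pass ``None`` to restore the built-in scorer."""
    _SIGNAL_SCORER[0] = fn or signal_score


def active_signal_score(protein: str) -> float:
    return float(_SIGNAL_SCORER[0](protein))


def select_best(
    scored: list[tuple[CandidateModel, ModelScore]],
    signal_gate_on: bool = True,
    d_min: float = 0.4,
    normalize: bool = False,
) -> SelectedModel | None:
    """Pick the best candidate model for one extended hit.

    Candidates failing the signal gate (when on) or lacking proper
    start/stop codons or carrying a premature stop are excluded; among the
    survivors the highest (MSA score + HmmProb score) wins, with ties broken
    by higher HmmProb score, then shorter model, then leftmost position.
    With ``normalize=True`` the two scores are z-scored across the
    surviving candidates before summing, equalizing their very different
    native scales; the default keeps the native-scale sum.
    """
    survivors = []
    for cand, score in scored:
        if not (cand.has_start and cand.has_stop) or cand.has_internal_stop:
            continue
        if signal_gate_on and score.signal_score < d_min:
            continue
        survivors.append((cand, score))
    if not survivors:
        return None

    if normalize and len(survivors) > 1:
        msas = np.array([s.msa_score for _, s in survivors])
        hmms = np.array([s.hmmprob_score for _, s in survivors])
        z = lambda v: (v - v.mean()) / sd if (sd := v.std()) > 0 else v * 0.0
        combined = dict(zip((id(c) for c, _ in survivors), z(msas) + z(hmms)))
        rank_combined = lambda cs: combined[id(cs[0])]
    else:
        rank_combined = lambda cs: cs[1].combined

    span = lambda c: c.genomic_span[1] - c.genomic_span[0]
    best = min(
        survivors,
        key=lambda cs: (
            -rank_combined(cs),
            -cs[1].hmmprob_score,
            span(cs[0]),
            cs[0].genomic_span[0],
            cs[0].model_id,
        ),
    )
    cand, score = best
    return SelectedModel(model=cand, score=score, family_id="")


def final_filter(
    models: list[SelectedModel], e_max: float = 0.001
) -> list[SelectedModel]:
    """Keep models whose final (rescored) E-value is <= ``e_max``, sorted by
    genomic position."""
    kept = [m for m in models if m.score.final_evalue <= e_max]
    kept.sort(key=lambda m: (m.model.seq_id, m.model.genomic_span, m.model.strand))
    for i, m in enumerate(kept):
        m.rank = i
    return kept


def family_consensus(fam: FamilyAlignment) -> str:
    """Majority-rule consensus of the family alignment ('-' columns where
    gaps dominate)."""
    cols = []
    for c in range(fam.columns):
        col = [s[c] for _, s in fam.members]
        residues = [ch for ch in col if ch not in hmm_mod.GAP_CHARS]
        if len(residues) * 2 < len(col):
            cols.append("-")
        else:
            counts: dict[str, int] = {}
            for ch in residues:
                counts[ch] = counts.get(ch, 0) + 1
            cols.append(max(sorted(counts), key=lambda k: counts[k]))
    return "".join(cols)
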