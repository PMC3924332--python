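"""Profile hidden Markov models for protein-family homology search.

This module builds profile HMMs from family alignments and searches protein
databases with them, returning bit scores, decoy-calibrated E-values and
per-residue posterior alignment probabilities.

Generative model
----------------
The architecture is a local-alignment profile HMM (match / insert / delete
states per consensus column) with flanking background states, evaluated as a
log-odds ratio against an i.i.d. background null.  For a target sequence of
length ``L`` the model is, exactly:

* ``r = L / (L + 2)`` is the flank/null loop probability.
* Start in ``N``.  While in ``N``: with probability ``r`` emit one background
  residue and stay; with probability ``1 - r`` move to ``B``.
* ``B`` enters any match state ``M_k`` (``k = 0..M-1``) with uniform
  probability ``1/M``.
* ``M_k`` emits one residue from ``match_emissions[k]``.  From ``M_k`` with
  ``k < M-1``: exit to ``E`` with probability ``p_exit``, otherwise continue
  to ``M_{k+1}`` / ``I_k`` / ``D_{k+1}`` with the node's trained transition
  probabilities scaled by ``1 - p_exit``.  The last match state ``M_{M-1}``
  always moves to ``E``.
* ``I_k`` emits one background residue; continues to ``M_{k+1}`` with
  probability ``tim[k]`` or loops with ``tii[k]``.
* ``D_k`` (silent) moves to ``M_{k+1}`` with ``tdm[k]`` or ``D_{k+1}`` with
  ``tdd[k]``; ``D_{M-1}`` always moves to ``E``.
* ``E`` moves to ``C``; while in ``C``: with probability ``r`` emit one
  background residue and stay, with ``1 - r`` terminate.

The null model emits ``L`` i.i.d. background residues.  The bit score is
length-conditioned: ``score = log2( Odds(x) / Odds0(L) )`` where ``Odds(x)``
is the forward-summed path mass with per-residue emission odds
``em(state, x_i)/bg(x_i)`` and ``Odds0(L)`` is the same forward mass for a
length-``L`` sequence of wildcards (all emission odds 1).  The flank/null
geometric length terms cancel in this ratio, a sequence carrying no
emission information scores exactly 0, and scores are comparable across
target lengths.  ``X`` (and any non-standard residue) has emission odds 1
in every emitting state.

E-values come from a decoy calibration: forward bit scores of ``n`` i.i.d.
background sequences are fitted with a maximum-likelihood Gumbel, and
``E = N_db * P(S >= s)`` under that fit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}
GAP_CHARS = {"-", "."}

DEFAULT_P_EXIT = 0.05


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class FamilyAlignment:
    """A protein multiple sequence alignment for one family."""

    family_id: str
    members: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("alignment must have at least one member")
        widths = {len(s) for _, s in self.members}
        if len(widths) != 1:
            raise ValueError("aligned sequences must all have equal length")

    @property
    def columns(self) -> int:
        return len(self.members[0][1])

    @classmethod
    def read(cls, path, family_id: str | None = None, fmt: str | None = None):
        """Read an aligned FASTA or Stockholm file."""
        from Bio import AlignIO
        import os

        if fmt is None:
            fmt = "stockholm" if str(path).endswith((".sto", ".stk")) else "fasta"
        aln = AlignIO.read(str(path), fmt)
        fid = family_id or os.path.splitext(os.path.basename(str(path)))[0]
        return cls(fid, [(r.id, str(r.seq).upper()) for r in aln])

    def write(self, path) -> None:
        from .seqio import write_fasta

        write_fasta(self.members, path)


@dataclass(frozen=True)
class Calibration:
    mu: float
    lam: float
    decoy_n: int
    decoy_len: int


@dataclass
class ProfileHMM:
    family_id: str
    match_emissions: np.ndarray  # (M, 20)
    insert_emissions: np.ndarray  # (M+1, 20); background by construction
    background: np.ndarray  # (20,)
    tmm: np.ndarray  # internal node transitions, each (M-1,)
    tmi: np.ndarray
    tmd: np.ndarray
    tim: np.ndarray
    tii: np.ndarray
    tdm: np.ndarray
    tdd: np.ndarray
    p_exit: float = DEFAULT_P_EXIT
    match_columns: list[int] = field(default_factory=list)
    calibration: Calibration | None = None

    @property
    def M(self) -> int:
        return self.match_emissions.shape[0]

    @property
    def tme(self) -> np.ndarray:
        t = np.full(self.M, self.p_exit)
        t[-1] = 1.0
        return t

    def consensus(self) -> str:
        return "".join(AA[i] for i in np.argmax(self.match_emissions, axis=1))

    def _odds(self) -> np.ndarray:
        """(M, 21) emission odds; last column is the wildcard (odds 1)."""
        o = self.match_emissions / self.background[None, :]
        return np.concatenate([o, np.ones((self.M, 1))], axis=1)

    # ---- serialization (documented JSON text format) -------------------
    def to_json(self) -> str:
        d = {
            "family_id": self.family_id,
            "alphabet": AA,
            "match_emissions": self.match_emissions.tolist(),
            "insert_emissions": self.insert_emissions.tolist(),
            "background": self.background.tolist(),
            "transitions": {
                k: getattr(self, k).tolist()
                for k in ("tmm", "tmi", "tmd", "tim", "tii", "tdm", "tdd")
            },
            "p_exit": self.p_exit,
            "match_columns": self.match_columns,
            "calibration": None
            if self.calibration is None
            else {
                "mu": self.calibration.mu,
                "lam": self.calibration.lam,
                "decoy_n": self.calibration.decoy_n,
                "decoy_len": self.calibration.decoy_len,
            },
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ProfileHMM":
        d = json.loads(text)
        tr = {k: np.asarray(v, float) for k, v in d["transitions"].items()}
        cal = d.get("calibration")
        return cls(
            family_id=d["family_id"],
            match_emissions=np.asarray(d["match_emissions"], float),
            insert_emissions=np.asarray(d["insert_emissions"], float),
            background=np.asarray(d["background"], float),
            p_exit=float(d["p_exit"]),
            match_columns=list(d.get("match_columns", [])),
            calibration=None if cal is None else Calibration(**cal),
            **tr,
        )


@dataclass(frozen=True)
class ProfileHit:
    family_id: str
    target_id: str
    target_interval: tuple[int, int]  # half-open aa positions in the target
    profile_interval: tuple[int, int]  # half-open match-node positions
    bit_score: float
    evalue: float
    posteriors: np.ndarray  # per-aligned-residue core posterior, in [0, 1]


@dataclass(frozen=True)
class Decoded:
    """Viterbi alignment plus forward-backward posteriors for one target."""

    bit_score: float  # forward score
    viterbi_bits: float
    target_interval: tuple[int, int]
    profile_interval: tuple[int, int]
    post_core: np.ndarray  # (L,) P(residue emitted by any match/insert state)
    post_match: np.ndarray  # (L,) P(residue emitted by a match state)


# ---------------------------------------------------------------------------
# profile construction
# ---------------------------------------------------------------------------

def build_profile(
    aln: FamilyAlignment,
    background: np.ndarray | None = None,
    match_threshold: float = 0.5,
    p_exit: float = DEFAULT_P_EXIT,
) -> ProfileHMM:
    """Build a profile HMM from a family alignment.

    Match columns are those with at least ``match_threshold`` non-gap
    residues.  Emissions are observed frequencies blended with
    background-proportional pseudocounts of total weight 1; insert states
    emit the background.  Internal transitions are counted from the members'
    match/insert/delete paths with +1 pseudocounts.
    """
    bg = (
        np.full(20, 1.0 / 20)
        if background is None
        else np.asarray(background, float) / np.sum(background)
    )
    n_mem = len(aln.members)
    cols = aln.columns
    seqs = [s for _, s in aln.members]

    is_match = []
    for c in range(cols):
        non_gap = sum(1 for s in seqs if s[c] not in GAP_CHARS)
        is_match.append(non_gap >= match_threshold * n_mem)
    match_cols = [c for c, m in enumerate(is_match) if m]
    M = len(match_cols)
    if M == 0:
        raise ValueError(f"{aln.family_id}: no match columns (all-gap alignment?)")

    # emissions
    em = np.tile(bg, (M, 1)).copy()  # pseudocount mass, total weight 1
    counts = np.zeros((M, 20))
    for s in seqs:
        for k, c in enumerate(match_cols):
            a = AA_INDEX.get(s[c])
            if a is not None:
                counts[k, a] += 1.0
    tot = counts.sum(axis=1, keepdims=True) + 1.0
    em = (counts + bg[None, :]) / tot

    # transitions from member state paths, +1 pseudocounts per category
    cmm = np.ones(max(M - 1, 1))
    cmi = np.ones(max(M - 1, 1))
    cmd = np.ones(max(M - 1, 1))
    cim = np.ones(max(M - 1, 1))
    cii = np.ones(max(M - 1, 1))
    cdm = np.ones(max(M - 1, 1))
    cdd = np.ones(max(M - 1, 1))
    for s in seqs:
        path: list[tuple[str, int]] = []
        node = -1
        for c in range(cols):
            gap = s[c] in GAP_CHARS
            if is_match[c]:
                node += 1
                path.append(("D" if gap else "M", node))
            elif not gap and node >= 0:
                path.append(("I", node))
        for (s1, k1), (s2, k2) in zip(path, path[1:]):
            if k1 >= M - 1 and not (s1 == "M" and s2 == "I"):
                continue
            if s1 == "M" and s2 == "M":
                cmm[k1] += 1
            elif s1 == "M" and s2 == "I":
                if k1 < M - 1:
                    cmi[k1] += 1
            elif s1 == "M" and s2 == "D":
                cmd[k1] += 1
            elif s1 == "I" and s2 == "I":
                cii[k1] += 1
            elif s1 == "I" and s2 == "M":
                cim[k1] += 1
            elif s1 == "D" and s2 == "M":
                cdm[k1] += 1
            elif s1 == "D" and s2 == "D":
                cdd[k1] += 1

    msum = cmm + cmi + cmd
    tmm = (1.0 - p_exit) * cmm / msum
    tmi = (1.0 - p_exit) * cmi / msum
    tmd = (1.0 - p_exit) * cmd / msum
    isum = cim + cii
    tim, tii = cim / isum, cii / isum
    dsum = cdm + cdd
    tdm, tdd = cdm / dsum, cdd / dsum
    if M == 1:  # no internal nodes
        tmm = tmi = tmd = tim = tii = tdm = tdd = np.zeros(0)

    return ProfileHMM(
        family_id=aln.family_id,
        match_emissions=em,
        insert_emissions=np.tile(bg, (M + 1, 1)),
        background=bg,
        tmm=tmm,
        tmi=tmi,
        tmd=tmd,
        tim=tim,
        tii=tii,
        tdm=tdm,
        tdd=tdd,
        p_exit=p_exit,
        match_columns=match_cols,
    )


# ---------------------------------------------------------------------------
# dynamic programming
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    return np.fromiter(
        (AA_INDEX.get(c, 20) for c in seq), dtype=np.int64, count=len(seq)
    )


def _dscan(mc: np.ndarray, tmd: np.ndarray, tdd: np.ndarray) -> np.ndarray:
    """D[k] = M[k-1] tmd[k-1] + D[k-1] tdd[k-1], D[0] = 0, vectorized."""
    M = mc.shape[0]
    d = np.zeros(M)
    if M == 1:
        return d
    a = mc[:-1] * tmd
    with np.errstate(under="ignore", over="ignore", divide="ignore", invalid="ignore"):
        cd = np.cumprod(tdd)
        out = cd * np.cumsum(a / np.maximum(cd, 1e-290))
    if not np.all(np.isfinite(out)):  # pathological tdd; exact fallback
        for k in range(1, M):
            d[k] = mc[k - 1] * tmd[k - 1] + d[k - 1] * tdd[k - 1]
        return d
    d[1:] = out
    return d


def _raw_forward_bits(h: ProfileHMM, seq: str | None, L: int) -> float:
    """log2 of the forward odds mass; ``seq=None`` means all-wildcard."""
    M = h.M
    r = L / (L + 2.0)
    if seq is None:
        eo = np.ones((M, L))
    else:
        eo = h._odds()[:, _encode(seq)]
    tbm = 1.0 / M
    tme = h.tme
    mprev = np.zeros(M)
    iprev = np.zeros(M)
    dprev = np.zeros(M)
    xn, xc, logsc = 1.0, 0.0, 0.0
    for i in range(L):
        xb = xn * (1.0 - r)
        e = eo[:, i]
        mc = np.empty(M)
        mc[0] = e[0] * xb * tbm
        if M > 1:
            mc[1:] = e[1:] * (
                xb * tbm
                + mprev[:-1] * h.tmm
                + iprev[:-1] * h.tim
                + dprev[:-1] * h.tdm
            )
        ic = np.zeros(M)
        if M > 1:
            ic[:-1] = mprev[:-1] * h.tmi + iprev[:-1] * h.tii
        dc = _dscan(mc, h.tmd, h.tdd)
        xe = float(mc @ tme) + dc[-1]
        xc = xc * r + xe
        xn = xn * r
        mprev, iprev, dprev = mc, ic, dc
        s = max(mc.max(), xc, xn)
        if s > 1e100 or (s < 1e-100 and s > 0.0):
            mprev = mprev / s
            iprev = iprev / s
            dprev = dprev / s
            xc /= s
            xn /= s
            logsc += math.log2(s)
    f = xc * (1.0 - r)
    if f <= 0.0:
        return float("-inf")
    return math.log2(f) + logsc - (L * math.log2(r) + math.log2(1.0 - r))


def length_norm(h: ProfileHMM, L: int) -> float:
    """log2 forward odds of an all-wildcard length-``L`` sequence (cached).

    This is the model's length preference with all emission information
    removed; subtracting it conditions the score on the target length.
    """
    cache = getattr(h, "_len_norm", None)
    if cache is None:
        cache = {}
        object.__setattr__(h, "_len_norm", cache)
    if L not in cache:
        cache[L] = _raw_forward_bits(h, None, L)
    return cache[L]


def forward_score(h: ProfileHMM, seq: str) -> float:
    """Forward (log-sum) local-alignment log-odds score, in bits,
    normalized by the model's own length preference (see module docs)."""
    L = len(seq)
    if L == 0:
        raise ValueError("cannot score an empty sequence")
    M = h.M
    r = L / (L + 2.0)
    eo = h._odds()[:, _encode(seq)]  # (M, L)
    tbm = 1.0 / M
    tme = h.tme
    mprev = np.zeros(M)
    iprev = np.zeros(M)
    dprev = np.zeros(M)
    xn, xc, logsc = 1.0, 0.0, 0.0
    for i in range(L):
        xb = xn * (1.0 - r)
        e = eo[:, i]
        mc = np.empty(M)
        mc[0] = e[0] * xb * tbm
        if M > 1:
            mc[1:] = e[1:] * (
                xb * tbm
                + mprev[:-1] * h.tmm
                + iprev[:-1] * h.tim
                + dprev[:-1] * h.tdm
            )
        ic = np.zeros(M)
        if M > 1:
            ic[:-1] = mprev[:-1] * h.tmi + iprev[:-1] * h.tii
        dc = _dscan(mc, h.tmd, h.tdd)
        xe = float(mc @ tme) + dc[-1]
        xc = xc * r + xe
        xn = xn * r
        mprev, iprev, dprev = mc, ic, dc
        s = max(mc.max(), xc, xn)
        if s > 1e100 or (s < 1e-100 and s > 0.0):
            mprev = mprev / s
            iprev = iprev / s
            dprev = dprev / s
            xc /= s
            xn /= s
            logsc += math.log2(s)
    f = xc * (1.0 - r)
    if f <= 0.0:
        return float("-inf")
    raw = math.log2(f) + logsc - (L * math.log2(r) + math.log2(1.0 - r))
    return raw - length_norm(h, L)


def _forward_matrices(h: ProfileHMM, seq: str):
    """Log2-domain forward matrices (rows 1..L) and total log2 odds."""
    L, M = len(seq), h.M
    r = L / (L + 2.0)
    eo = h._odds()[:, _encode(seq)]
    tbm = 1.0 / M
    tme = h.tme
    FM = np.full((L + 1, M), -np.inf)
    FI = np.full((L + 1, M), -np.inf)
    FD = np.full((L + 1, M), -np.inf)
    mprev = np.zeros(M)
    iprev = np.zeros(M)
    dprev = np.zeros(M)
    xn, xc, logsc = 1.0, 0.0, 0.0
    scale = np.zeros(L + 1)  # cumulative log2 scale per row
    with np.errstate(divide="ignore"):
        for i in range(1, L + 1):
            xb = xn * (1.0 - r)
            e = eo[:, i - 1]
            mc = np.empty(M)
            mc[0] = e[0] * xb * tbm
            if M > 1:
                mc[1:] = e[1:] * (
                    xb * tbm
                    + mprev[:-1] * h.tmm
                    + iprev[:-1] * h.tim
                    + dprev[:-1] * h.tdm
                )
            ic = np.zeros(M)
            if M > 1:
                ic[:-1] = mprev[:-1] * h.tmi + iprev[:-1] * h.tii
            dc = _dscan(mc, h.tmd, h.tdd)
            xe = float(mc @ tme) + dc[-1]
            xc = xc * r + xe
            xn = xn * r
            mprev, iprev, dprev = mc, ic, dc
            s = max(mc.max(), xc, xn)
            if s > 1e100 or (s < 1e-100 and s > 0.0):
                mprev = mprev / s
                iprev = iprev / s
                dprev = dprev / s
                xc /= s
                xn /= s
                logsc += math.log2(s)
            scale[i] = logsc
            FM[i] = np.log2(np.maximum(mprev, 0)) + logsc
            FI[i] = np.log2(np.maximum(iprev, 0)) + logsc
            FD[i] = np.log2(np.maximum(dprev, 0)) + logsc
    f = xc * (1.0 - r)
    total = (math.log2(f) + logsc) if f > 0 else -np.inf
    return FM, FI, FD, total, r


def posterior_decode(h: ProfileHMM, seq: str) -> Decoded:
    """Forward-backward posterior decoding plus a Viterbi local alignment."""
    L, M = len(seq), h.M
    if L == 0:
        raise ValueError("cannot decode an empty sequence")
    FM, FI, FD, total, r = _forward_matrices(h, seq)
    BM, BI, BD = _backward(h, seq, r)
    with np.errstate(invalid="ignore"):
        pm = np.exp2(FM[1:] + BM[1 : L + 1] - total)  # (L, M)
        pi = np.exp2(FI[1:] + BI[1 : L + 1] - total)
    pm = np.nan_to_num(pm, nan=0.0, posinf=0.0)
    pi = np.nan_to_num(pi, nan=0.0, posinf=0.0)
    post_match = np.minimum(pm.sum(axis=1), 1.0)
    post_core = np.minimum(post_match + pi.sum(axis=1), 1.0)
    vit_bits, t_int, p_int = _viterbi(h, seq)
    return Decoded(
        bit_score=total - (L * math.log2(r) + math.log2(1 - r)) - length_norm(h, L),
        viterbi_bits=vit_bits,
        target_interval=t_int,
        profile_interval=p_int,
        post_core=post_core,
        post_match=post_match,
    )


def _backward(h: ProfileHMM, seq: str, r: float):
    """Backward pass, log2 domain.  Row i holds values conditional on having
    just emitted residue i (1-based)."""
    L, M = len(seq), h.M
    eo = h._odds()[:, _encode(seq)]
    with np.errstate(divide="ignore"):
        leo = np.log2(np.maximum(eo, 0))  # (M, L) column j = residue j+1
        ltme = np.log2(h.tme)
        if M > 1:
            ltmm, ltmi, ltmd = (
                np.log2(np.maximum(t, 0)) for t in (h.tmm, h.tmi, h.tmd)
            )
            ltim, ltii = (np.log2(np.maximum(t, 0)) for t in (h.tim, h.tii))
            ltdm, ltdd = (np.log2(np.maximum(t, 0)) for t in (h.tdm, h.tdd))
    log_r, log_1r = math.log2(r), math.log2(1.0 - r)
    BM = np.full((L + 1, M), -np.inf)
    BI = np.full((L + 1, M), -np.inf)
    BD = np.full((L + 1, M), -np.inf)
    neg = np.full(max(M - 1, 0), -np.inf)
    for i in range(L, 0, -1):
        be = (L - i) * log_r + log_1r
        have_next = i < L
        bm_next = BM[i + 1] if have_next else None
        bi_next = BI[i + 1] if have_next else None
        e_next = leo[:, i] if have_next else None  # residue i+1
        bd = np.full(M, -np.inf)
        bd[M - 1] = be
        for k in range(M - 2, -1, -1):
            via_m = (ltdm[k] + e_next[k + 1] + bm_next[k + 1]) if have_next else -np.inf
            bd[k] = np.logaddexp2(via_m, ltdd[k] + bd[k + 1])
        BD[i] = bd
        bm = np.full(M, -np.inf)
        bi = np.full(M, -np.inf)
        bm[-1] = ltme[-1] + be
        if M > 1:
            if have_next:
                cont_m = ltmm + e_next[1:] + bm_next[1:]
                cont_i = ltmi + bi_next[:-1]
                im_m = ltim + e_next[1:] + bm_next[1:]
                ii_i = ltii + bi_next[:-1]
            else:
                cont_m = cont_i = im_m = ii_i = neg
            core = np.logaddexp2(np.logaddexp2(cont_m, cont_i), ltmd + bd[1:])
            bm[:-1] = np.logaddexp2(ltme[:-1] + be, core)
            bi[:-1] = np.logaddexp2(im_m, ii_i)
        BM[i] = bm
        BI[i] = bi
    return BM, BI, BD


def _viterbi(h: ProfileHMM, seq: str):
    """Best local alignment; returns (bits, target_interval, profile_interval)."""
    L, M = len(seq), h.M
    r = L / (L + 2.0)
    eo = h._odds()[:, _encode(seq)]
    with np.errstate(divide="ignore"):
        leo = np.log2(np.maximum(eo, 0))
        ltme = np.log2(h.tme)
        ltbm = math.log2(1.0 / M)
        if M > 1:
            ltmm, ltmi, ltmd = (
                np.log2(np.maximum(t, 0)) for t in (h.tmm, h.tmi, h.tmd)
            )
            ltim, ltii = (np.log2(np.maximum(t, 0)) for t in (h.tim, h.tii))
            ltdm, ltdd = (np.log2(np.maximum(t, 0)) for t in (h.tdm, h.tdd))
    log_r, log_1r = math.log2(r), math.log2(1.0 - r)
    VM = np.full((L + 1, M), -np.inf)
    VI = np.full((L + 1, M), -np.inf)
    VD = np.full((L + 1, M), -np.inf)
    PM = np.zeros((L + 1, M), dtype=np.int8)  # 0=B,1=M,2=I,3=D
    PD = np.zeros((L + 1, M), dtype=np.int8)  # 0 from M, 1 from D
    PI = np.zeros((L + 1, M), dtype=np.int8)  # 0 from M, 1 from I
    best = (-np.inf, 0, 0)  # (score-to-E, i, k) ; k = -1 means D-exit
    for i in range(1, L + 1):
        xb = (i - 1) * log_r + log_1r  # N emitted i-1 residues, then N->B
        vm = np.full(M, -np.inf)
        vm[0] = leo[0, i - 1] + xb + ltbm
        if M > 1:
            cand = np.stack(
                [
                    np.full(M - 1, xb + ltbm),
                    VM[i - 1, :-1] + ltmm,
                    VI[i - 1, :-1] + ltim,
                    VD[i - 1, :-1] + ltdm,
                ]
            )
            choice = np.argmax(cand, axis=0)
            vm[1:] = leo[1:, i - 1] + cand[choice, np.arange(M - 1)]
            PM[i, 1:] = choice
            a = VM[i - 1, :-1] + ltmi
            b = VI[i - 1, :-1] + ltii
            vi = np.full(M, -np.inf)
            vi[:-1] = np.maximum(a, b)
            PI[i, :-1] = (b > a).astype(np.int8)
        else:
            vi = np.full(M, -np.inf)
        vd = np.full(M, -np.inf)
        for k in range(1, M):
            fm = vm[k - 1] + ltmd[k - 1]
            fd = vd[k - 1] + ltdd[k - 1]
            if fd > fm:
                vd[k] = fd
                PD[i, k] = 1
            else:
                vd[k] = fm
                PD[i, k] = 0
        VM[i], VI[i], VD[i] = vm, vi, vd
        # close the alignment after residue i
        tail = (L - i) * log_r + log_1r  # C emits the rest
        end_m = vm + ltme
        k_best = int(np.argmax(end_m))
        if end_m[k_best] + tail > best[0]:
            best = (end_m[k_best] + tail, i, k_best)
        if vd[M - 1] + tail > best[0]:
            best = (vd[M - 1] + tail, i, -1)
    null = L * log_r + log_1r
    bits = best[0] - null - length_norm(h, L)
    # traceback
    i, k = best[1], best[2]
    state = "D" if k == -1 else "M"
    if k == -1:
        k = M - 1
        # walk D chain back to its source M within row i
        while PD[i, k] == 1:
            k -= 1
        k -= 1
        state = "M"
    first_i = last_i = i
    first_k = last_k = k
    while True:
        if state == "M":
            first_i, first_k = i, k
            src = PM[i, k]
            if src == 0 or k == 0:
                break
            if src == 1:
                i, k, state = i - 1, k - 1, "M"
            elif src == 2:
                i, k, state = i - 1, k - 1, "I"
            else:
                # predecessor is D at (i-1, k-1); walk its chain to a match
                i, k = i - 1, k - 1
                while PD[i, k] == 1:
                    k -= 1
                k -= 1
                state = "M"
        elif state == "I":
            first_i = i
            if PI[i, k] == 0:
                i, state = i - 1, "M"
            else:
                i = i - 1
    return bits, (first_i - 1, last_i), (first_k, last_k + 1)


# ---------------------------------------------------------------------------
# calibration and search
# ---------------------------------------------------------------------------

def sample_background(
    rng: np.random.Generator, n: int, length: int, background: np.ndarray
) -> list[str]:
    idx = rng.choice(20, size=(n, length), p=background)
    return ["".join(AA[j] for j in row) for row in idx]


def calibrate(
    h: ProfileHMM,
    decoy_n: int = 4000,
    decoy_len: int = 60,
    seed: int = 0,
    tail_frac: float = 0.05,
) -> Calibration:
    """Fit a Gumbel to forward scores of i.i.d. background decoys (ML fit).

    By default the fit is a right-tail censored maximum-likelihood Gumbel fit
    using the top ``tail_frac`` of decoy scores (decoys should match the typical target length): forward (log-sum) scores of
    local alignments follow the Gumbel law only in their upper tail, and the
    tail is what E-values extrapolate from.  ``tail_frac=1`` gives the plain
    full-sample ML fit.  The fitted ``(mu, lambda)`` are stored on the
    profile and drive E-values as ``E = N_db * P(S >= s)``.  Deterministic
    given ``seed``.
    """
    if decoy_n < 100:
        raise ValueError("decoy_n must be >= 100")
    rng = np.random.default_rng(seed)
    scores = np.array(
        [forward_score(h, s) for s in sample_background(rng, decoy_n, decoy_len, h.background)]
    )
    if np.std(scores) == 0:
        raise CalibrationError("degenerate decoy score distribution")
    mu, lam = fit_gumbel(scores, tail_frac=tail_frac)
    cal = Calibration(mu=mu, lam=lam, decoy_n=decoy_n, decoy_len=decoy_len)
    h.calibration = cal
    return cal


def fit_gumbel(scores: np.ndarray, tail_frac: float = 1.0) -> tuple[float, float]:
    """Maximum-likelihood Gumbel fit; returns (mu, lambda) with
    survival P(S >= s) = 1 - exp(-exp(-lambda (s - mu))).

    With ``tail_frac < 1`` the likelihood treats scores at or below the
    ``1 - tail_frac`` quantile as censored at that threshold (right-tail
    censored ML), which is robust when only the upper tail is Gumbel.
    """
    scores = np.asarray(scores, float)
    if np.std(scores) == 0:
        raise CalibrationError("degenerate score distribution (zero variance)")
    loc0, scale0 = stats.gumbel_r.fit(scores)
    if tail_frac >= 1.0:
        return float(loc0), float(1.0 / scale0)
    t = float(np.quantile(scores, 1.0 - tail_frac))
    obs = scores[scores > t]
    n_cens = len(scores) - len(obs)
    if len(obs) < 10:
        raise CalibrationError("too few tail scores for a censored fit")

    def nll(p):
        mu, logb = p
        b = math.exp(logb)
        return -(
            np.sum(stats.gumbel_r.logpdf(obs, mu, b))
            + n_cens * stats.gumbel_r.logcdf(t, mu, b)
        )

    from scipy import optimize

    res = optimize.minimize(nll, [loc0, math.log(scale0)], method="Nelder-Mead")
    return float(res.x[0]), float(1.0 / math.exp(res.x[1]))


def gumbel_sf(score: float, mu: float, lam: float) -> float:
    return float(stats.gumbel_r.sf(score, loc=mu, scale=1.0 / lam))


def evalue(h: ProfileHMM, score: float, n_db: int) -> float:
    if h.calibration is None:
        raise RuntimeError(f"profile {h.family_id} is not calibrated")
    return n_db * gumbel_sf(score, h.calibration.mu, h.calibration.lam)


#: optional external search engine: callable (profile, db, e_max, n_db)
#: returning a ProfileHit list; None selects the native implementation
_SEARCH_ENGINE: list = [None]


def set_search_engine(fn) -> None:
    """Delegate ``search`` to an external hmmsearch-compatible engine
    (``(profile, db, e_max, n_db) -> [ProfileHit]``); ``None`` restores the
    native implementation."""
    _SEARCH_ENGINE[0] = fn


def search(
    h: ProfileHMM,
    db: list[tuple[str, str]],
    e_max: float = 10.0,
    n_db: int | None = None,
) -> list[ProfileHit]:
    """Search a protein database with one profile.

    ``n_db`` is the effective database size used in the E-value (defaults to
    ``len(db)``); hits with ``E <= e_max`` are decoded and returned sorted by
    E-value ascending.  A registered external engine, if any, handles the
    search instead.
    """
    if _SEARCH_ENGINE[0] is not None:
        return _SEARCH_ENGINE[0](h, db, e_max, len(db) if n_db is None else n_db)
    if h.calibration is None:
        raise RuntimeError(f"profile {h.family_id} is not calibrated")
    if e_max <= 0:
        raise ValueError("e_max must be > 0")
    n = len(db) if n_db is None else n_db
    hits = []
    for name, seq in db:
        if not seq:
            continue
        s = forward_score(h, seq)
        e = evalue(h, s, n)
        if e <= e_max:
            dec = posterior_decode(h, seq)
            i0, i1 = dec.target_interval
            hits.append(
                ProfileHit(
                    family_id=h.family_id,
                    target_id=name,
                    target_interval=dec.target_interval,
                    profile_interval=dec.profile_interval,
                    bit_score=s,
                    evalue=e,
                    posteriors=dec.post_core[i0:i1],
                )
            )
    hits.sort(key=lambda x: (x.evalue, -x.bit_score, x.target_id))
    return hits


def hmmprob_score(protein: str, h: ProfileHMM) -> float:
    """Sum of per-residue match-state posteriors over the best local
    alignment.

    Insert-state posteriors are deliberately excluded: residues inserted
    relative to the profile (e.g. translated intron retained in a wrong
    candidate model) would otherwise inflate the score of longer, worse
    models.  Returns 0 when no positive-scoring alignment exists.
    """
    if not protein:
        return 0.0
    dec = posterior_decode(h, protein)
    if dec.viterbi_bits <= 0:
        return 0.0
    i0, i1 = dec.target_interval
    return float(np.sum(dec.post_match[i0:i1]))
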