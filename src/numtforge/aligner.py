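"""Nucleotide local alignment: seed -> ungapped X-drop -> banded gapped X-drop.

The engine mirrors the classic blastn strategy: exact word seeds on both
strands (the query is reverse-complemented for the minus strand), ungapped
X-drop extension along the seed diagonal, and banded gapped extension with
affine gap costs around seeds whose ungapped score reaches a trigger.
E-values follow raw Karlin-Altschul theory, E = K*m*n*exp(-lambda*S), with
lambda and K solved for the ungapped scoring scheme against the subject's
base composition and n counting both strands.  Two documented divergences
from NCBI BLASTN: no effective-length (finite-size) correction, and gapped
scores are assessed with the ungapped lambda/K.  Threshold behaviour, not
bit-compatibility, is the design goal.

Gap cost model: a gap of length L costs gap_open + gap_extend*L.

N never matches and never seeds: words containing N are excluded from the
seed index and N-N or N-x pairs score as mismatches and are never counted
as matches in identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from numtforge.genome_io import AnnotatedGenome, Mitogenome

NEG = -(10 ** 9)

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_RC = str.maketrans("ACGTN", "TGCAN")


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 array, A=0 C=1 G=2 T=3, anything else 4 (N)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


class AlignerError(Exception):
    pass


class KarlinValidityError(AlignerError):
    """Scoring scheme/background with non-negative expected pair score."""


@dataclass(frozen=True)
class ScoringScheme:
    """blastn-task default parameterization: +2/-3, gap 5+2L, word 11.

    xdrop_ungapped / xdrop_gapped are the score drop-offs that terminate the
    two extension stages; gap_trigger is the ungapped score needed before a
    seed is gapped-extended; band_halfwidth bounds the diagonal drift of the
    gapped stage.
    """

    match_reward: int = 2
    mismatch_penalty: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    word_size: int = 11
    xdrop_ungapped: int = 30
    xdrop_gapped: int = 60
    gap_trigger: int = 45
    band_halfwidth: int = 32

    def __post_init__(self):
        if self.match_reward <= 0:
            raise ValueError("match_reward must be positive")
        if self.mismatch_penalty >= 0:
            raise ValueError("mismatch_penalty must be negative")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap costs must be positive")
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")


@dataclass(frozen=True)
class KarlinParams:
    lam: float
    K: float
    H: float
    background: tuple[float, float, float, float]


@dataclass
class AlignmentHit:
    """One local alignment (HSP).  Subject coordinates are always on the
    forward strand of the subject; strand is the subject strand relative to
    the query.  identity counts gap columns in the denominator."""

    query_start: int
    query_end: int
    scaffold_id: str
    subject_start: int
    subject_end: int
    strand: str
    raw_score: int
    aligned_columns: int
    matches: int
    evalue: float

    @property
    def identity(self) -> float:
        return self.matches / self.aligned_columns if self.aligned_columns else 0.0


# ---------------------------------------------------------------------------
# Karlin-Altschul statistics
# ---------------------------------------------------------------------------

def match_probability(background: Sequence[float]) -> float:
    p = np.asarray(background, dtype=float)
    return float(np.dot(p, p))


def estimate_background(genome: AnnotatedGenome) -> tuple[float, float, float, float]:
    """ACGT frequencies over all scaffolds, Ns excluded."""
    counts = np.zeros(5, dtype=np.int64)
    for s in genome.scaffolds:
        counts += np.bincount(encode(s.sequence), minlength=5)
    tot = counts[:4].sum()
    if tot == 0:
        raise AlignerError("genome contains no unambiguous bases")
    f = counts[:4] / tot
    return (float(f[0]), float(f[1]), float(f[2]), float(f[3]))


def _score_distribution(scoring: ScoringScheme, background) -> tuple[np.ndarray, int]:
    """Per-aligned-pair score distribution as (probs, lowest_score).

    Match/mismatch scoring depends only on whether the two bases are equal,
    so the distribution is two-point with match probability sum(p_i^2).
    """
    p = match_probability(background)
    lo = scoring.mismatch_penalty
    hi = scoring.match_reward
    probs = np.zeros(hi - lo + 1)
    probs[0] = 1.0 - p
    probs[-1] = p
    return probs, lo


def solve_karlin(
    scoring: ScoringScheme,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    max_terms: int = 60,
) -> KarlinParams:
    """Solve for the ungapped Karlin-Altschul parameters.

    lambda is the positive root of sum_ij p_i p_j exp(lambda*s(i,j)) = 1,
    found by bracketed root-finding to better than 1e-9.  K uses the
    lattice-case series of Karlin & Altschul (1990): with delta the span of
    the per-pair score lattice and S_j the j-fold sum of pair scores,

        sigma = sum_{j>=1} (1/j) [ E(e^{lambda*S_j}; S_j<0) + P(S_j>=0) ]
        K = delta*lambda*exp(-2*sigma) / (H*(1 - exp(-lambda*delta)))

    truncated at j = max_terms (terms decay geometrically; 60 terms puts the
    truncation error far below 1e-6 for blastn-like schemes).
    """
    bg = np.asarray(background, dtype=float)
    if bg.min() < 0 or not math.isclose(bg.sum(), 1.0, abs_tol=1e-8):
        raise ValueError("background must be a frequency vector summing to 1")
    probs, lo = _score_distribution(scoring, bg)
    values = np.arange(lo, lo + len(probs))
    expected = float(np.dot(probs, values))
    if expected >= 0:
        raise KarlinValidityError(
            f"expected pair score {expected:.4f} is non-negative; "
            "Karlin-Altschul statistics require negative drift"
        )

    def f(lam: float) -> float:
        return float(np.dot(probs, np.exp(lam * values))) - 1.0

    hi = 0.5
    while f(hi) <= 0:
        hi *= 2.0
        if hi > 100:
            raise AlignerError("failed to bracket lambda")
    lam = float(brentq(f, 1e-12, hi, xtol=1e-12, rtol=1e-14))

    conj = probs * np.exp(lam * values)
    H = float(lam * np.dot(values, conj))

    # lattice span: gcd of the support values (the score lattice itself)
    support = np.abs(values[probs > 0]).astype(int)
    delta = int(np.gcd.reduce(support)) if len(support) else 1
    delta = max(delta, 1)

    sigma = 0.0
    conv = np.array([1.0])
    conv_lo = 0
    for j in range(1, max_terms + 1):
        conv = np.convolve(conv, probs)
        conv_lo += lo
        k = np.arange(conv_lo, conv_lo + len(conv))
        neg = k < 0
        term = float(np.dot(conv[neg], np.exp(lam * k[neg])) + conv[~neg].sum())
        sigma += term / j
        if term / j < 1e-14:
            break

    K = delta * lam * math.exp(-2.0 * sigma) / (H * (1.0 - math.exp(-lam * delta)))
    return KarlinParams(lam=lam, K=K, H=H, background=tuple(float(x) for x in bg))


def evalue(
    raw_score: float,
    query_len: int,
    subject_len: int,
    karlin: KarlinParams,
    n_strands: int = 2,
) -> float:
    """E = K * m * n * exp(-lambda*S), n = subject_len * n_strands.

    No effective-length correction is applied; values are conservative
    relative to NCBI BLASTN.  Underflow returns 0.0.
    """
    if query_len <= 0 or subject_len <= 0:
        raise ValueError("lengths must be positive")
    x = -karlin.lam * raw_score
    try:
        e = karlin.K * query_len * (subject_len * n_strands) * math.exp(x)
    except OverflowError:
        return math.inf
    return e


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------

def _word_codes(arr: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 codes of all w-mers plus a validity mask (no N in window)."""
    n = len(arr) - w + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    codes = np.zeros(n, dtype=np.int64)
    a = np.where(arr < 4, arr, 0).astype(np.int64)
    for k in range(w):
        codes = codes * 4 + a[k : k + n]
    isn = (arr >= 4).astype(np.int32)
    cs = np.concatenate(([0], np.cumsum(isn)))
    valid = (cs[w:] - cs[:-w]) == 0
    return codes, valid


class _QueryIndex:
    def __init__(self, q4: np.ndarray, w: int):
        self.w = w
        codes, valid = _word_codes(q4, w)
        pos = np.nonzero(valid)[0]
        codes = codes[pos]
        order = np.argsort(codes, kind="stable")
        self.sorted_codes = codes[order]
        self.sorted_pos = pos[order]
        self.uniq, self.starts, self.counts = np.unique(
            self.sorted_codes, return_index=True, return_counts=True
        )
        # membership table over the 4^w code space for O(1) word lookup
        self.present = np.zeros(4 ** w, dtype=bool)
        self.present[self.uniq] = True

    def match(self, scodes: np.ndarray, svalid: np.ndarray):
        """Return (query_pos, subject_pos) arrays of all word matches."""
        if len(self.uniq) == 0 or len(scodes) == 0:
            z = np.empty(0, dtype=np.int64)
            return z, z
        hit = self.present[scodes] & svalid
        spos = np.nonzero(hit)[0]
        rank = np.searchsorted(self.uniq, scodes[spos])
        cnt = self.counts[rank]
        total = int(cnt.sum())
        if total == 0:
            z = np.empty(0, dtype=np.int64)
            return z, z
        rep_s = np.repeat(spos, cnt)
        base = np.repeat(self.starts[rank], cnt)
        within = np.arange(total) - np.repeat(np.cumsum(cnt) - cnt, cnt)
        rep_q = self.sorted_pos[base + within]
        return rep_q, rep_s


def _collapse_runs(qpos: np.ndarray, spos: np.ndarray):
    """Collapse diagonal runs of consecutive word matches into seed runs.

    Returns (run_q, run_s, run_words) sorted by (diagonal, subject start).
    """
    if len(qpos) == 0:
        z = np.empty(0, dtype=np.int64)
        return z, z, z
    diag = spos - qpos
    order = np.lexsort((spos, diag))
    q, s, d = qpos[order], spos[order], diag[order]
    new = np.ones(len(q), dtype=bool)
    new[1:] = (d[1:] != d[:-1]) | (s[1:] != s[:-1] + 1)
    starts = np.nonzero(new)[0]
    lens = np.diff(np.concatenate((starts, [len(q)])))
    return q[starts], s[starts], lens


# ---------------------------------------------------------------------------
# Ungapped X-drop extension (batched)
# ---------------------------------------------------------------------------

def _extend_right_batch(
    q4: np.ndarray,
    s4: np.ndarray,
    qpos: np.ndarray,
    spos: np.ndarray,
    scoring: ScoringScheme,
    chunk: int = 64,
    max_len: int = 60000,
):
    """Batched rightward ungapped X-drop extension.

    qpos/spos are the first positions to include.  Returns (gain, length):
    best prefix score (>= 0) and its length in bases.
    """
    n = len(qpos)
    gain = np.zeros(n, dtype=np.int32)
    length = np.zeros(n, dtype=np.int64)
    cur = np.zeros(n, dtype=np.int32)
    active = np.arange(n)
    offset = 0
    r, mm, X = scoring.match_reward, scoring.mismatch_penalty, scoring.xdrop_ungapped
    Lq, Ls = len(q4), len(s4)
    oob = np.int32(-(10 ** 6))  # forces an immediate X-drop stop
    # most seeds die within a few bases; start with small chunks
    schedule = iter([16, 16, 32])
    while active.size and offset < max_len:
        width = next(schedule, chunk)
        offs = np.arange(width)
        qi = qpos[active, None] + offset + offs[None, :]
        si = spos[active, None] + offset + offs[None, :]
        inb = (qi < Lq) & (si < Ls)
        qb = q4[np.minimum(qi, Lq - 1)]
        sb = s4[np.minimum(si, Ls - 1)]
        match = (qb == sb) & (qb < 4) & inb
        col = np.where(match, np.int32(r), np.int32(mm))
        col[~inb] = oob
        cum = cur[active, None] + np.cumsum(col, axis=1, dtype=np.int32)
        runmax = np.maximum(np.maximum.accumulate(cum, axis=1), gain[active, None])
        dropped = cum < runmax - X
        stops = dropped.any(axis=1)
        firstdrop = np.where(stops, dropped.argmax(axis=1), width)
        valid = offs[None, :] < firstdrop[:, None]
        masked = np.where(valid, cum, np.int32(-(2 ** 30)))
        cmax = masked.max(axis=1)
        carg = masked.argmax(axis=1)
        improve = cmax > gain[active]
        gain[active] = np.where(improve, cmax, gain[active])
        length[active] = np.where(improve, offset + carg + 1, length[active])
        cur[active] = cum[:, -1]
        active = active[~stops]
        offset += width
    return gain.astype(np.int64), length


# ---------------------------------------------------------------------------
# Banded gapped X-drop extension with traceback
# ---------------------------------------------------------------------------

def _gapped_extend_dir(
    q4: np.ndarray,
    s4: np.ndarray,
    scoring: ScoringScheme,
    max_rows: int = 100000,
):
    """Banded affine-gap extension of q4 vs s4 anchored at their origins.

    Returns (q_consumed, s_consumed, score, matches, aligned_columns) for
    the best-scoring cell reached before the X-drop terminates the band.
    Band columns index the diagonal offset d = j - i in
    [-band_halfwidth, band_halfwidth].
    """
    hb = scoring.band_halfwidth
    W = 2 * hb + 1
    X = scoring.xdrop_gapped
    go, ge = scoring.gap_open, scoring.gap_extend
    r, mm = scoring.match_reward, scoring.mismatch_penalty
    m, n = len(q4), len(s4)

    d_off = np.arange(W) - hb  # diagonal offset per band column
    H = np.full(W, NEG, dtype=np.int64)
    E = np.full(W, NEG, dtype=np.int64)
    F = np.full(W, NEG, dtype=np.int64)
    H[hb] = 0
    for b in range(hb + 1, W):
        d = b - hb
        if d > n:
            break
        H[b] = E[b] = -(go + ge * d)
    H_rows = [H.copy()]
    E_rows = [E.copy()]
    F_rows = [F.copy()]

    best = 0
    best_cell = (0, hb)
    ge_ramp = ge * np.arange(W)

    i = 0
    while i < m and i < max_rows:
        i += 1
        j = i + d_off  # subject consumed per band column
        valid = (j >= 0) & (j <= n)
        Hp = H
        # diagonal move: needs j >= 1
        jm1 = np.clip(j - 1, 0, max(n - 1, 0))
        sb = s4[jm1] if n else np.zeros(W, dtype=np.uint8)
        qb = q4[i - 1]
        sub = np.where((sb == qb) & (qb < 4), r, mm)
        M = np.where((j >= 1) & valid, Hp + sub, NEG)
        # vertical (consume query, gap in subject): from previous row, d+1
        Fp_s = np.concatenate((F[1:], [NEG]))
        Hp_s = np.concatenate((Hp[1:], [NEG]))
        F = np.where(valid, np.maximum(Fp_s - ge, Hp_s - go - ge), NEG)
        Htmp = np.maximum(M, F)
        # horizontal (consume subject) within the row via prefix-max scan
        A = Htmp + ge_ramp
        P = np.maximum.accumulate(A)
        E = np.full(W, NEG, dtype=np.int64)
        E[1:] = P[:-1] - go - ge_ramp[1:]
        E = np.where(valid & (j >= 1), E, NEG)
        H = np.maximum(Htmp, E)
        H = np.where(valid, H, NEG)
        rowmax = int(H.max())
        if rowmax > best:
            best = rowmax
            best_cell = (i, int(H.argmax()))
        H = np.where(H < best - X, NEG, H)
        E_rows.append(E.copy())
        F_rows.append(F.copy())
        H_rows.append(H.copy())
        if rowmax <= NEG // 2 or (H <= NEG // 2).all():
            break

    # Traceback from best_cell.  States: H (cell optimum), T (max(M, F), the
    # gap-openable part of H), E (horizontal gap run), F (vertical gap run).
    # M and Htmp are recomputed per cell from the stored H/F rows.
    def _sub(i: int, j: int) -> tuple[int, bool]:
        qb = q4[i - 1]
        sb = s4[j - 1] if 0 < j <= n else 255
        is_match = bool(sb == qb and qb < 4)
        return (r if is_match else mm), is_match

    def _M(i: int, b: int) -> int:
        j = i + (b - hb)
        if i < 1 or j < 1 or H_rows[i - 1][b] <= NEG // 2:
            return NEG
        return int(H_rows[i - 1][b] + _sub(i, j)[0])

    def _Htmp(i: int, b: int) -> int:
        return max(_M(i, b), int(F_rows[i][b]))

    bi, bb = best_cell
    matches = 0
    cols = 0
    state = "H"
    i, b = bi, bb
    while not (i == 0 and b == hb):
        j = i + (b - hb)
        if i == 0:
            cols += j  # leading subject-gap cells in row 0
            break
        if state == "H":
            state = "T" if H_rows[i][b] == _Htmp(i, b) else "E"
        elif state == "T":
            if _Htmp(i, b) == _M(i, b):
                cols += 1
                matches += _sub(i, j)[1]
                i -= 1
                state = "H"
            elif _Htmp(i, b) == F_rows[i][b]:
                state = "F"
            else:
                raise AlignerError("traceback inconsistency (T)")
        elif state == "E":
            # one gap column consuming subject base j-1
            cols += 1
            Ecur = int(E_rows[i][b])
            if b < 1:
                raise AlignerError("traceback inconsistency (E)")
            if Ecur == E_rows[i][b - 1] - ge:
                b -= 1
            elif Ecur == _Htmp(i, b - 1) - go - ge:
                b -= 1
                state = "T"
            else:
                raise AlignerError("traceback inconsistency (E)")
        else:  # F: one gap column consuming query base i-1
            cols += 1
            Fcur = int(F_rows[i][b])
            if b + 1 >= W:
                raise AlignerError("traceback inconsistency (F)")
            if Fcur == F_rows[i - 1][b + 1] - ge:
                i -= 1
                b += 1
            elif Fcur == H_rows[i - 1][b + 1] - go - ge:
                i -= 1
                b += 1
                state = "H"
            else:
                raise AlignerError("traceback inconsistency (F)")
    q_consumed = bi
    s_consumed = bi + (bb - hb)
    return q_consumed, s_consumed, best, matches, cols


def _gapped_hit(q4, s4, qa: int, sa: int, scoring: ScoringScheme):
    """Gapped extension both ways from an anchor known to lie on an exact
    match; returns (qs, qe, ss, se, score, matches, cols)."""
    qc_f, sc_f, sc_score_f, m_f, c_f = _gapped_extend_dir(q4[qa:], s4[sa:], scoring)
    qc_b, sc_b, sc_score_b, m_b, c_b = _gapped_extend_dir(
        q4[:qa][::-1], s4[:sa][::-1], scoring
    )
    return (
        qa - qc_b,
        qa + qc_f,
        sa - sc_b,
        sa + sc_f,
        int(sc_score_f + sc_score_b),
        int(m_f + m_b),
        int(c_f + c_b),
    )


# ---------------------------------------------------------------------------
# find_hits
# ---------------------------------------------------------------------------

def _search_one(
    q4: np.ndarray,
    qidx: _QueryIndex,
    s4: np.ndarray,
    scodes: np.ndarray,
    svalid: np.ndarray,
    scoring: ScoringScheme,
    gap_trigger: int,
):
    """All gapped HSPs of one query orientation against one scaffold.

    Returns a list of (qs, qe, ss, se, score, matches, cols).
    """
    w = scoring.word_size
    r = scoring.match_reward
    rep_q, rep_s = qidx.match(scodes, svalid)
    run_q, run_s, run_words = _collapse_runs(rep_q, rep_s)
    if len(run_q) == 0:
        return []
    span = run_words + w - 1  # matched bases per run
    # ungapped extension outward from each run
    q4r, s4r = q4[::-1], s4[::-1]
    gain_r, len_r = _extend_right_batch(
        q4, s4, run_q + span, run_s + span, scoring
    )
    gain_l, len_l = _extend_right_batch(
        q4r, s4r, len(q4) - run_q, len(s4) - run_s, scoring
    )
    score = r * span + gain_r + gain_l
    ext_qs = run_q - len_l
    ext_qe = run_q + span + len_r
    diag = run_s - run_q
    # collapse runs whose ungapped extensions coincide (same diagonal segment)
    order = np.lexsort((-run_words, ext_qs, diag))
    keep = np.ones(len(order), dtype=bool)
    keep[1:] = (diag[order][1:] != diag[order][:-1]) | (
        ext_qs[order][1:] != ext_qs[order][:-1]
    ) | (ext_qe[order][1:] != ext_qe[order][:-1])
    sel = order[keep]
    sel = sel[score[sel] >= gap_trigger]
    if len(sel) == 0:
        return []
    # highest ungapped score first; deterministic tie-breaks
    sel = sel[np.lexsort((run_s[sel], diag[sel], -score[sel]))]

    hits = []
    hb = scoring.band_halfwidth
    for k in sel:
        qa = int(run_q[k] + span[k] // 2)
        sa = int(run_s[k] + span[k] // 2)
        covered = False
        for (qs, qe, ss, se, *_rest) in hits:
            if qs <= qa < qe and ss <= sa < se:
                dmin = (ss - qs) - hb
                dmax = (se - qe) + hb
                if dmin <= sa - qa <= dmax:
                    covered = True
                    break
        if covered:
            continue
        hits.append(_gapped_hit(q4, s4, qa, sa, scoring))
    return [h for h in hits if h[4] > 0 and h[1] > h[0] and h[3] > h[2]]


def _dedup_hits(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Drop hits whose subject interval largely duplicates a better hit at
    the same locus and strand (>=50% of the shorter interval).  Tie-break:
    higher score, then smaller subject start, then strand +."""
    hits = sorted(
        hits,
        key=lambda h: (-h.raw_score, h.scaffold_id, h.subject_start, h.strand != "+"),
    )
    kept: list[AlignmentHit] = []
    for h in hits:
        dup = False
        for k in kept:
            if k.scaffold_id != h.scaffold_id or k.strand != h.strand:
                continue
            ov = min(k.subject_end, h.subject_end) - max(k.subject_start, h.subject_start)
            shorter = min(
                k.subject_end - k.subject_start, h.subject_end - h.subject_start
            )
            if ov > 0 and ov >= 0.5 * shorter:
                dup = True
                break
        if not dup:
            kept.append(h)
    kept.sort(
        key=lambda h: (
            h.scaffold_id,
            h.subject_start,
            h.subject_end,
            h.strand,
            -h.raw_score,
        )
    )
    return kept


def find_hits(
    query: str,
    subject_genome: AnnotatedGenome,
    scoring: Optional[ScoringScheme] = None,
    karlin: Optional[KarlinParams] = None,
    evalue_max: float = 6e-14,
    gap_trigger: Optional[int] = None,
    query_len_for_evalue: Optional[int] = None,
) -> list[AlignmentHit]:
    """Search the query on both strands of every scaffold.

    Karlin parameters default to the scheme solved against the subject's
    own base composition (AT-rich genomes get AT-aware statistics).  Only
    hits with E <= evalue_max are returned, in deterministic order.
    """
    scoring = scoring or ScoringScheme()
    if len(query) < scoring.word_size:
        raise AlignerError(
            f"query length {len(query)} shorter than word size {scoring.word_size}"
        )
    if karlin is None:
        karlin = solve_karlin(scoring, estimate_background(subject_genome))
    trigger = scoring.gap_trigger if gap_trigger is None else gap_trigger
    m = query_len_for_evalue or len(query)
    n_total = subject_genome.total_length

    oriented = {
        "+": query,
        "-": reverse_complement(query),
    }
    indices = {st: (_QueryIndex(encode(q), scoring.word_size), encode(q))
               for st, q in oriented.items()}

    raw: list[AlignmentHit] = []
    for scaf in subject_genome.scaffolds:
        s4 = encode(scaf.sequence)
        scodes, svalid = _word_codes(s4, scoring.word_size)
        for strand in ("+", "-"):
            qidx, q4 = indices[strand]
            for (qs, qe, ss, se, score, matches, cols) in _search_one(
                q4, qidx, s4, scodes, svalid, scoring, trigger
            ):
                if strand == "-":
                    qs, qe = len(q4) - qe, len(q4) - qs
                ev = evalue(score, m, n_total, karlin)
                if ev <= evalue_max:
                    raw.append(
                        AlignmentHit(
                            query_start=int(qs),
                            query_end=int(qe),
                            scaffold_id=scaf.id,
                            subject_start=int(ss),
                            subject_end=int(se),
                            strand=strand,
                            raw_score=int(score),
                            aligned_columns=int(cols),
                            matches=int(matches),
                            evalue=float(ev),
                        )
                    )
    return _dedup_hits(raw)


def align_circular_query(
    mito: Mitogenome,
    subject_genome: AnnotatedGenome,
    scoring: Optional[ScoringScheme] = None,
    karlin: Optional[KarlinParams] = None,
    evalue_max: float = 6e-14,
    gap_trigger: Optional[int] = None,
    wrap: int = 2000,
) -> list[AlignmentHit]:
    """find_hits for a circular query: the query is linearized with
    min(len, wrap) bp wrapped past the origin so origin-spanning copies are
    recovered as single hits.  Query coordinates are mapped back modulo the
    mitogenome length; a hit with query_end > length spans the origin.
    Duplicate hits arising from the duplicated wrap region are removed by
    identical subject interval."""
    L = mito.length
    if not mito.circular:
        return find_hits(
            mito.sequence, subject_genome, scoring, karlin, evalue_max, gap_trigger
        )
    wrap = min(L, wrap)
    extended = mito.sequence + mito.sequence[:wrap]
    hits = find_hits(
        extended,
        subject_genome,
        scoring,
        karlin,
        evalue_max,
        gap_trigger,
        query_len_for_evalue=L,
    )
    seen: set[tuple] = set()
    out: list[AlignmentHit] = []
    for h in hits:
        if h.query_start >= L:
            h.query_start -= L
            h.query_end -= L
        key = (h.scaffold_id, h.subject_start, h.subject_end, h.strand)
        if key in seen:
            continue
        seen.add(key)
        out.append(h)
    out.sort(
        key=lambda h: (
            h.scaffold_id,
            h.subject_start,
            h.subject_end,
            h.strand,
            -h.raw_score,
        )
    )
    return out
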