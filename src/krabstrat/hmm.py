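"""Profile hidden Markov models: build, score, calibrate, serialize.

The model follows the classic plan of match/insert/delete nodes with a
local-in-sequence, global-in-model alignment mode (domain-scan
semantics): flanking N/C states emit unaligned residues from the
background, while every model node must be traversed via a match or
delete state.  Scores are log-odds against a background null in bits.

Statistical significance uses a Gumbel (extreme-value) fit to scores of
background-sampled sequences; the E-value of a score ``s`` against a
database of ``n_db`` sequences is

    E(s) = n_db * (1 - exp(-exp(-lambda * (s - mu))))

Architecture per node k = 1..L:

    M_k -> {M_{k+1}, I_k, D_{k+1}}   (M_L -> E)
    I_k -> {M_{k+1}, I_k}            (k < L)
    D_k -> {M_{k+1}, D_{k+1}}        (D_L -> E)
    B   -> {M_1, D_1}

N and C flank states self-loop with the same geometric length parameter
as the null model (p = T/(T+1) for a sequence of length T), so flanking
background-typical residues change the bit score only through the two
fixed entry/exit transitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import gumbel_r

from .core import AA_INDEX, AMINO_ACIDS, is_gap, normalize_residue
from .errors import CalibrationError, DataError, ParseError, ValidationError

LOG2 = math.log(2.0)
_NEG_INF = -np.inf

#: Uniform background over the 20 amino acids (the default null composition).
UNIFORM_BACKGROUND = np.full(20, 1.0 / 20.0)


@dataclass(frozen=True)
class EVDParams:
    """Gumbel location/scale of the null score distribution."""

    mu: float
    lam: float
    n_calibration: int


@dataclass
class ProfileHMM:
    """A profile HMM over the 20-letter amino-acid alphabet.

    Emission and transition containers are numpy arrays:

    - ``match_emissions``: (L, 20)
    - ``insert_emissions``: (L, 20); row k used by insert state I_{k+1}
      (the last row is unused by the topology but kept for shape
      regularity)
    - ``t_m``: (L, 3) rows (M->M, M->I, M->D); last row is (1, 0, 0)
      meaning M_L -> E
    - ``t_i``: (L, 2) rows (I->M, I->I)
    - ``t_d``: (L, 2) rows (D->M, D->D); last row (1, 0) meaning D_L -> E
    - ``begin``: (2,) = (B->M1, B->D1)
    """

    n_match: int
    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    t_m: np.ndarray
    t_i: np.ndarray
    t_d: np.ndarray
    begin: np.ndarray
    background: np.ndarray
    evd: Optional[EVDParams] = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.n_match < 1:
            raise ValidationError("profile needs at least one match state")
        self.validate()

    def validate(self, atol: float = 1e-9) -> None:
        L = self.n_match
        shapes = {
            "match_emissions": (L, 20),
            "insert_emissions": (L, 20),
            "t_m": (L, 3),
            "t_i": (L, 2),
            "t_d": (L, 2),
            "begin": (2,),
            "background": (20,),
        }
        for attr, shape in shapes.items():
            arr = getattr(self, attr)
            if arr.shape != shape:
                raise ValidationError(f"{attr} has shape {arr.shape}, expected {shape}")
        for attr in ("match_emissions", "insert_emissions", "background", "begin"):
            arr = np.atleast_2d(getattr(self, attr))
            if np.any(arr <= 0):
                raise ValidationError(f"{attr} must be strictly positive")
            if not np.allclose(arr.sum(axis=-1), 1.0, atol=atol):
                raise ValidationError(f"{attr} rows must sum to 1 within {atol}")
        # Transition rows (interior rows fully used; terminal rows fixed).
        for attr, last in (("t_m", (1.0, 0.0, 0.0)), ("t_d", (1.0, 0.0))):
            arr = getattr(self, attr)
            if not np.allclose(arr.sum(axis=1), 1.0, atol=atol):
                raise ValidationError(f"{attr} rows must sum to 1 within {atol}")
            if not np.allclose(arr[-1], last, atol=atol):
                raise ValidationError(f"{attr} terminal row must be {last}")
            if np.any(arr[:-1] <= 0):
                raise ValidationError(f"{attr} interior rows must be strictly positive")
        if self.n_match > 1:
            if not np.allclose(self.t_i[:-1].sum(axis=1), 1.0, atol=atol):
                raise ValidationError("t_i rows must sum to 1")
            if np.any(self.t_i[:-1] <= 0):
                raise ValidationError("t_i interior rows must be strictly positive")

    @property
    def calibrated(self) -> bool:
        return self.evd is not None

    def consensus(self) -> str:
        """Most probable residue of each match state."""
        return "".join(AMINO_ACIDS[i] for i in self.match_emissions.argmax(axis=1))


@dataclass
class ScoreResult:
    """Score of one sequence against one model."""

    bit_score: float
    evalue: Optional[float] = None
    viterbi_path: Optional[List[str]] = None


# ----------------------------------------------------------------------
# Model construction
# ----------------------------------------------------------------------

def build_profile(
    alignment: Sequence[str],
    occupancy_threshold: float = 0.5,
    pseudocount_weight: float = 1.0,
    background: Optional[np.ndarray] = None,
    name: str = "",
) -> ProfileHMM:
    """Estimate a profile HMM from a gapped multiple alignment.

    Columns whose residue occupancy is at least ``occupancy_threshold``
    become match states.  Match emissions use background-proportional
    pseudocounts of total weight ``pseudocount_weight``; transitions are
    counted from the observed match/insert/delete usage of each row with
    Laplace (+1) smoothing.  Ambiguity-class residues (X) occupy columns
    but contribute no emission counts.
    """
    rows = [r for r in alignment]
    if not rows:
        raise DataError("empty alignment")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise DataError("alignment rows must have uniform length")
    if not 0.0 <= occupancy_threshold <= 1.0:
        raise ValidationError("occupancy_threshold must be in [0, 1]")
    if pseudocount_weight <= 0:
        raise ValidationError("pseudocount_weight must be positive")
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)

    n_rows = len(rows)
    occ = np.zeros(width)
    for r in rows:
        occ += np.array([0.0 if is_gap(c) else 1.0 for c in r])
    occ /= n_rows
    match_cols = [j for j in range(width) if occ[j] >= occupancy_threshold]
    if not match_cols:
        raise DataError("no column meets the occupancy threshold")
    L = len(match_cols)
    col_role = {}  # column -> node index k (1-based) for match columns
    for k, j in enumerate(match_cols, start=1):
        col_role[j] = k

    # Emission counts.
    m_counts = np.zeros((L, 20))
    i_counts = np.zeros((L, 20))  # inserts between node k and k+1 pool into row k-1
    # Transition counts (Laplace-smoothed below).
    c_mm = np.zeros(L); c_mi = np.zeros(L); c_md = np.zeros(L)
    c_im = np.zeros(L); c_ii = np.zeros(L)
    c_dm = np.zeros(L); c_dd = np.zeros(L)
    c_bm = 0.0; c_bd = 0.0

    first_col, last_col = match_cols[0], match_cols[-1]
    for r in rows:
        prev = ("B", 0)  # (state kind, node index)
        for j in range(first_col, last_col + 1):
            ch = r[j]
            gap = is_gap(ch)
            if j in col_role:
                k = col_role[j]
                kind = "D" if gap else "M"
                if not gap:
                    c = normalize_residue(ch)
                    if c != "X":
                        m_counts[k - 1, AA_INDEX[c]] += 1
                pk, pn = prev
                if pk == "B":
                    if kind == "M":
                        c_bm += 1
                    else:
                        c_bd += 1
                elif pk == "M":
                    (c_mm if kind == "M" else c_md)[pn - 1] += 1
                elif pk == "I":
                    # topology has no I->D; a rare insert-then-delete row is
                    # rewired through I->M counting (kept simple on purpose)
                    c_im[pn - 1] += 1
                elif pk == "D":
                    (c_dm if kind == "M" else c_dd)[pn - 1] += 1
                prev = (kind, k)
            else:
                if gap:
                    continue
                c = normalize_residue(ch)
                pk, pn = prev
                if pk == "M" and 1 <= pn < L:
                    c_mi[pn - 1] += 1
                    prev = ("I", pn)
                elif pk == "I":
                    c_ii[pn - 1] += 1
                else:
                    # insert following B or D: absorbed (no matching
                    # transition in the topology); emission still counted
                    pass
                if c != "X" and prev[0] == "I":
                    i_counts[prev[1] - 1, AA_INDEX[c]] += 1

    # Emissions with background-proportional pseudocounts.
    def _mix(counts: np.ndarray) -> np.ndarray:
        out = np.empty_like(counts)
        for k in range(counts.shape[0]):
            n = counts[k].sum()
            out[k] = (counts[k] + pseudocount_weight * bg) / (n + pseudocount_weight)
        return out

    match_e = _mix(m_counts)
    insert_e = _mix(i_counts)

    # Transitions with Laplace smoothing; terminal rows are structural.
    t_m = np.ones((L, 3))
    t_i = np.ones((L, 2))
    t_d = np.ones((L, 2))
    t_m[:, 0] += c_mm; t_m[:, 1] += c_mi; t_m[:, 2] += c_md
    t_i[:, 0] += c_im; t_i[:, 1] += c_ii
    t_d[:, 0] += c_dm; t_d[:, 1] += c_dd
    t_m /= t_m.sum(axis=1, keepdims=True)
    t_i /= t_i.sum(axis=1, keepdims=True)
    t_d /= t_d.sum(axis=1, keepdims=True)
    t_m[-1] = (1.0, 0.0, 0.0)
    t_d[-1] = (1.0, 0.0)
    begin = np.array([1.0 + c_bm, 1.0 + c_bd])
    begin /= begin.sum()

    return ProfileHMM(
        n_match=L,
        match_emissions=match_e,
        insert_emissions=insert_e,
        t_m=t_m,
        t_i=t_i,
        t_d=t_d,
        begin=begin,
        background=bg.copy(),
        name=name,
    )


# ----------------------------------------------------------------------
# Scoring
# ----------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    """Sequence -> residue indices; X-class residues get index -1."""
    idx = np.empty(len(seq), dtype=int)
    for i, ch in enumerate(seq):
        c = normalize_residue(ch)
        idx[i] = -1 if c == "X" else AA_INDEX[c]
    return idx


def _log_emission(emit: np.ndarray, bg: np.ndarray, code: int) -> Tuple[float, float]:
    """(log model emission, log background emission) for one residue code.

    X-class residues score as the background under both, i.e. they are
    neutral for the log-odds.
    """
    if code < 0:
        return 0.0, 0.0  # log-odds-neutral by construction
    return math.log(emit[code]), math.log(bg[code])


def _prepare(hmm: ProfileHMM, seq: str):
    codes = _encode(seq)
    T = len(codes)
    if T == 0:
        raise ValidationError("cannot score an empty sequence")
    L = hmm.n_match
    # Log emission odds per position: match (T, L) and insert (T, L).
    lm = np.full((T, L), 0.0)
    li = np.full((T, L), 0.0)
    lbg = np.zeros(T)
    log_match = np.log(hmm.match_emissions)  # (L, 20)
    log_ins = np.log(hmm.insert_emissions)
    log_bg = np.log(hmm.background)
    for t, code in enumerate(codes):
        if code < 0:
            continue  # X: neutral everywhere
        lm[t] = log_match[:, code] - log_bg[code]
        li[t] = log_ins[:, code] - log_bg[code]
        lbg[t] = 0.0  # background odds of a background emission
    p_loop = T / (T + 1.0)
    return codes, T, L, lm, li, math.log(p_loop), math.log1p(-p_loop)


def _forward_dp(hmm: ProfileHMM, seq: str) -> float:
    """Forward recursion in log-odds space; returns natural-log odds."""
    codes, T, L, lm, li, l_loop, l_move = _prepare(hmm, seq)
    with np.errstate(divide="ignore"):
        ltm = np.log(hmm.t_m)
        lti = np.log(hmm.t_i)
        ltd = np.log(hmm.t_d)
        lbeg = np.log(hmm.begin)

    # fN[t]: in N after emitting t flank residues (background emissions
    # cancel in the odds; only loop transitions remain).
    fN = np.array([t * l_loop for t in range(T + 1)])
    lB = fN + l_move  # entering B after t flank residues

    M = np.full((T + 1, L), _NEG_INF)
    I = np.full((T + 1, L), _NEG_INF)
    D = np.full((T + 1, L), _NEG_INF)
    fC = np.full(T + 1, _NEG_INF)

    # All-delete prefix at t = 0 (a path may traverse the whole model
    # without consuming residues; it scores poorly but is legal).
    D[0, 0] = lB[0] + lbeg[1]
    for k in range(1, L):
        D[0, k] = D[0, k - 1] + ltd[k - 1, 1]
    fC[0] = D[0, L - 1] + ltd[L - 1, 0]

    for t in range(1, T + 1):
        # Match states, vectorized over nodes.
        m_in = np.full(L, _NEG_INF)
        m_in[0] = lB[t - 1] + lbeg[0]
        if L > 1:
            prev = np.logaddexp(
                np.logaddexp(M[t - 1, :-1] + ltm[:-1, 0], I[t - 1, :-1] + lti[:-1, 0]),
                D[t - 1, :-1] + ltd[:-1, 0],
            )
            m_in[1:] = np.logaddexp(m_in[1:], prev)
        M[t] = m_in + lm[t - 1]
        # Insert states.
        I[t] = np.logaddexp(M[t - 1] + ltm[:, 1], I[t - 1] + lti[:, 1]) + li[t - 1]
        # Delete cascade (sequential in k).
        D[t, 0] = lB[t] + lbeg[1]
        for k in range(1, L):
            D[t, k] = np.logaddexp(M[t, k - 1] + ltm[k - 1, 2], D[t, k - 1] + ltd[k - 1, 1])
        # Exit through E into C after t consumed residues.
        lE = np.logaddexp(M[t, L - 1] + ltm[L - 1, 0], D[t, L - 1] + ltd[L - 1, 0])
        fC[t] = np.logaddexp(fC[t - 1] + l_loop, lE)

    # Subtract the null model's transition mass (p_loop^T * (1 - p_loop));
    # emission odds are already folded into lm/li.
    return float(fC[T] + l_move - (T * l_loop + l_move))


def forward_score(hmm: ProfileHMM, seq: str) -> float:
    """Forward (summed over all alignments) log-odds bit score."""
    return _forward_dp(hmm, seq) / LOG2


def viterbi_score(hmm: ProfileHMM, seq: str) -> ScoreResult:
    """Best single alignment log-odds bit score with the decoded path."""
    total, path = _viterbi_dp(hmm, seq)
    ev = evalue(hmm, total / LOG2) if hmm.calibrated else None
    return ScoreResult(bit_score=total / LOG2, evalue=ev, viterbi_path=path)


def _viterbi_dp(hmm: ProfileHMM, seq: str):
    """Viterbi with explicit tuple backpointers (clear decode)."""
    codes, T, L, lm, li, l_loop, l_move = _prepare(hmm, seq)
    with np.errstate(divide="ignore"):
        ltm = np.log(hmm.t_m)
        lti = np.log(hmm.t_i)
        ltd = np.log(hmm.t_d)
        lbeg = np.log(hmm.begin)

    fN = np.array([t * l_loop for t in range(T + 1)])
    lB = fN + l_move
    M = np.full((T + 1, L), _NEG_INF)
    I = np.full((T + 1, L), _NEG_INF)
    D = np.full((T + 1, L), _NEG_INF)
    bp: Dict[Tuple[str, int, int], Tuple[str, int, int]] = {}

    def better(cands):
        best = None
        for score, prev in cands:
            if best is None or score > best[0]:
                best = (score, prev)
        return best

    D[0, 0] = lB[0] + lbeg[1]
    bp[("D", 0, 0)] = ("B", 0, 0)
    for k in range(1, L):
        D[0, k] = D[0, k - 1] + ltd[k - 1, 1]
        bp[("D", 0, k)] = ("D", 0, k - 1)

    for t in range(1, T + 1):
        for k in range(L):
            cands = []
            if k == 0:
                cands.append((lB[t - 1] + lbeg[0], ("B", t - 1, 0)))
            else:
                cands.append((M[t - 1, k - 1] + ltm[k - 1, 0], ("M", t - 1, k - 1)))
                cands.append((I[t - 1, k - 1] + lti[k - 1, 0], ("I", t - 1, k - 1)))
                cands.append((D[t - 1, k - 1] + ltd[k - 1, 0], ("D", t - 1, k - 1)))
            s, prev = better(cands)
            M[t, k] = s + lm[t - 1, k]
            bp[("M", t, k)] = prev
        for k in range(L):
            s, prev = better([
                (M[t - 1, k] + ltm[k, 1], ("M", t - 1, k)),
                (I[t - 1, k] + lti[k, 1], ("I", t - 1, k)),
            ])
            I[t, k] = s + li[t - 1, k]
            bp[("I", t, k)] = prev
        D[t, 0] = lB[t] + lbeg[1]
        bp[("D", t, 0)] = ("B", t, 0)
        for k in range(1, L):
            s, prev = better([
                (M[t, k - 1] + ltm[k - 1, 2], ("M", t, k - 1)),
                (D[t, k - 1] + ltd[k - 1, 1], ("D", t, k - 1)),
            ])
            D[t, k] = s
            bp[("D", t, k)] = prev

    # End: E at some t, then C loops to T.
    best_end = None
    for t in range(T + 1):
        for kind, arr, trans in (("M", M, ltm[L - 1, 0]), ("D", D, ltd[L - 1, 0])):
            s = arr[t, L - 1] + trans + (T - t) * l_loop + l_move
            if best_end is None or s > best_end[0]:
                best_end = (s, ("E", t, kind))
    total, (_, t_end, end_kind) = best_end
    # Null transition mass, as in the forward recursion.
    total -= T * l_loop + l_move

    # Decode core path backwards from (end_kind, t_end, L-1).
    core: List[str] = []
    node: Tuple[str, int, int] = (end_kind, t_end, L - 1)
    while node[0] != "B":
        kind, t, k = node
        core.append(f"{kind}{k + 1}")
        node = bp[(kind, t, k)]
    path = ["N"] * node[1] + core[::-1] + ["C"] * (T - t_end)
    return total, path


def score(hmm: ProfileHMM, seq: str, n_db: Optional[int] = None) -> ScoreResult:
    """Forward bit score plus E-value when the model is calibrated."""
    bits = forward_score(hmm, seq)
    ev = evalue(hmm, bits, n_db=n_db or 1) if hmm.calibrated else None
    return ScoreResult(bit_score=bits, evalue=ev)


# ----------------------------------------------------------------------
# E-value calibration
# ----------------------------------------------------------------------

def sample_background_sequence(
    rng: np.random.Generator, length: int, background: np.ndarray
) -> str:
    codes = rng.choice(20, size=length, p=background)
    return "".join(AMINO_ACIDS[c] for c in codes)


def calibrate_evd(
    hmm: ProfileHMM,
    n_samples: int = 200,
    length_dist: Optional[Callable[[np.random.Generator], int]] = None,
    seed: int = 1072,
) -> ProfileHMM:
    """Fit Gumbel parameters to forward scores of background sequences.

    ``length_dist`` draws one sequence length per sample; by default all
    null sequences have the model's match length.  Returns a calibrated
    copy of the model.
    """
    if n_samples < 100:
        raise ValidationError("calibration needs n_samples >= 100")
    rng = np.random.default_rng(seed)
    draw_len = length_dist or (lambda r: hmm.n_match)
    scores = np.empty(n_samples)
    for i in range(n_samples):
        seq = sample_background_sequence(rng, max(1, draw_len(rng)), hmm.background)
        scores[i] = forward_score(hmm, seq)
    if np.ptp(scores) < 1e-12:
        raise CalibrationError("degenerate (zero-variance) null score distribution")
    loc, scale = gumbel_r.fit(scores)
    return replace(hmm, evd=EVDParams(mu=float(loc), lam=float(1.0 / scale),
                                      n_calibration=n_samples))


def evalue(hmm: ProfileHMM, bit_score: float, n_db: int = 1) -> float:
    """Expected number of >= bit_score hits among n_db null sequences."""
    if not hmm.calibrated:
        raise CalibrationError(f"model {hmm.name or '<unnamed>'} is not calibrated")
    if n_db < 1:
        raise ValidationError("n_db must be >= 1")
    x = -hmm.evd.lam * (bit_score - hmm.evd.mu)
    # P(S >= s) = 1 - exp(-exp(x)); -expm1 is the numerically stable form.
    p = -math.expm1(-math.exp(min(x, 700.0)))
    return max(n_db * p, 5e-324)


def evalue_of_sequence(hmm: ProfileHMM, seq: str, n_db: int = 1) -> float:
    return evalue(hmm, forward_score(hmm, seq), n_db=n_db)


# ----------------------------------------------------------------------
# Serialization (versioned text format, 6 significant digits)
# ----------------------------------------------------------------------

_MAGIC = "KRABSTRAT-HMM"
_VERSION = 1


def _fmt(values: np.ndarray) -> str:
    return " ".join(f"{v:.6g}" for v in np.atleast_1d(values))


def write_profile(hmm: ProfileHMM, path: str | Path) -> None:
    lines = [f"{_MAGIC} {_VERSION}", f"NAME {hmm.name}", f"NMATCH {hmm.n_match}",
             f"ALPHABET {AMINO_ACIDS}", f"BACKGROUND {_fmt(hmm.background)}",
             f"BEGIN {_fmt(hmm.begin)}"]
    if hmm.calibrated:
        lines.append(f"EVD {hmm.evd.mu:.6g} {hmm.evd.lam:.6g} {hmm.evd.n_calibration}")
    for k in range(hmm.n_match):
        lines.append(f"MATCH {k + 1} {_fmt(hmm.match_emissions[k])}")
        lines.append(f"INSERT {k + 1} {_fmt(hmm.insert_emissions[k])}")
        lines.append(
            f"TRANS {k + 1} {_fmt(hmm.t_m[k])} {_fmt(hmm.t_i[k])} {_fmt(hmm.t_d[k])}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_profile(path: str | Path) -> ProfileHMM:
    """Read a profile written by :func:`write_profile`.

    Emission rows are validated against normalization at serialization
    precision and renormalized exactly; anything worse raises.
    """
    text = Path(path).read_text().splitlines()
    if not text or not text[0].startswith(_MAGIC):
        raise ParseError(f"{path}: line 1: not a {_MAGIC} file")

    def fail(lineno: int, msg: str):
        raise ParseError(f"{path}: line {lineno}: {msg}")

    name = ""
    n_match = None
    background = begin = None
    evd = None
    match_rows: Dict[int, np.ndarray] = {}
    insert_rows: Dict[int, np.ndarray] = {}
    trans_rows: Dict[int, np.ndarray] = {}
    saw_end = False
    for lineno, raw in enumerate(text[1:], start=2):
        line = raw.strip()
        if not line:
            continue
        tag, _, rest = line.partition(" ")
        try:
            if tag == "NAME":
                name = rest.strip()
            elif tag == "NMATCH":
                n_match = int(rest)
            elif tag == "ALPHABET":
                if rest.strip() != AMINO_ACIDS:
                    fail(lineno, "unsupported alphabet")
            elif tag == "BACKGROUND":
                background = np.array([float(v) for v in rest.split()])
            elif tag == "BEGIN":
                begin = np.array([float(v) for v in rest.split()])
            elif tag == "EVD":
                mu, lam, n_cal = rest.split()
                evd = EVDParams(float(mu), float(lam), int(n_cal))
            elif tag == "MATCH":
                parts = rest.split()
                match_rows[int(parts[0])] = np.array([float(v) for v in parts[1:]])
            elif tag == "INSERT":
                parts = rest.split()
                insert_rows[int(parts[0])] = np.array([float(v) for v in parts[1:]])
            elif tag == "TRANS":
                parts = rest.split()
                trans_rows[int(parts[0])] = np.array([float(v) for v in parts[1:]])
            elif tag == "END":
                saw_end = True
                break
            else:
                fail(lineno, f"unknown record {tag!r}")
        except ParseError:
            raise
        except Exception as exc:
            fail(lineno, f"malformed {tag} record ({exc})")
    if not saw_end:
        raise ParseError(f"{path}: truncated file (missing END record)")
    if n_match is None or background is None or begin is None:
        raise ParseError(f"{path}: missing NMATCH/BACKGROUND/BEGIN records")
    if set(match_rows) != set(range(1, n_match + 1)) or \
       set(insert_rows) != set(range(1, n_match + 1)) or \
       set(trans_rows) != set(range(1, n_match + 1)):
        raise ParseError(f"{path}: incomplete state records for NMATCH={n_match}")

    def renorm(vec: np.ndarray, what: str, n: Optional[int] = None) -> np.ndarray:
        if n is not None and len(vec) != n:
            raise ParseError(f"{path}: {what} has {len(vec)} values, expected {n}")
        s = vec.sum()
        if abs(s - 1.0) > 1e-3 or np.any(vec <= 0):
            raise ParseError(f"{path}: {what} is not a probability vector (sum {s:.6g})")
        return vec / s

    me = np.vstack([renorm(match_rows[k], f"MATCH {k}", 20) for k in range(1, n_match + 1)])
    ie = np.vstack([renorm(insert_rows[k], f"INSERT {k}", 20) for k in range(1, n_match + 1)])
    t_m = np.empty((n_match, 3)); t_i = np.empty((n_match, 2)); t_d = np.empty((n_match, 2))
    for k in range(1, n_match + 1):
        row = trans_rows[k]
        if len(row) != 7:
            raise ParseError(f"{path}: TRANS {k} must carry 7 values")
        if k < n_match:
            t_m[k - 1] = renorm(row[0:3], f"TRANS {k} (match)")
            t_i[k - 1] = renorm(row[3:5], f"TRANS {k} (insert)")
            t_d[k - 1] = renorm(row[5:7], f"TRANS {k} (delete)")
        else:
            t_m[k - 1] = (1.0, 0.0, 0.0)
            t_i[k - 1] = row[3:5] / row[3:5].sum() if row[3:5].sum() > 0 else (0.5, 0.5)
            t_d[k - 1] = (1.0, 0.0)
    return ProfileHMM(
        n_match=n_match,
        match_emissions=me,
        insert_emissions=ie,
        t_m=t_m,
        t_i=t_i,
        t_d=t_d,
        begin=renorm(begin, "BEGIN", 2),
        background=renorm(background, "BACKGROUND", 20),
        evd=evd,
        name=name,
    )
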