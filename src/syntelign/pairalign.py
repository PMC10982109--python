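"""BLAST-like pairwise HSP detection.

An ungapped seed-and-extend engine in two modes:

* **nucleotide** -- exact word seeding on both strands followed by X-drop
  extension along the diagonal, match/mismatch scoring (BLASTn-like).
* **translated** -- both sequences translated in all six reading frames with
  the standard genetic code; exact amino-acid word seeding and X-drop
  extension under a substitution matrix, stop codons terminating extension;
  coordinates mapped back to the forward nucleotide strands (tBLASTx-like).

HSPs are assigned Karlin-Altschul bit scores and e-values,
``bit = (lambda*S - ln K)/ln 2`` and ``E = K*m*n*exp(-lambda*S)`` with the
search space ``m*n`` taken as the product of the two sequence lengths
(residues in translated mode). The engine is ungapped by design; gapped
hits can be imported from BLAST tabular output instead (`read_blast_tab`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .seqio import InputError, InputSet, SeqRecord

# ---------------------------------------------------------------------------
# scoring statistics

_AA_ORDER = "ARNDCQEGHILKMFPSTWYV"  # 20 standard residues, codes 0..19
_STOP_CODE = 20
_OTHER_CODE = 21
_STOP_SCORE = -10_000  # forces X-drop termination at stop codons

# Ungapped K constants (documented configuration values; lambda is solved
# numerically from the score system under uniform letter frequencies).
DEFAULT_K_NT = 0.46
DEFAULT_K_AA = 0.134


@lru_cache(maxsize=None)
def _solve_lambda_nt(match: int, mismatch: int) -> float:
    from scipy.optimize import brentq

    def f(lam: float) -> float:
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0

    return float(brentq(f, 1e-9, 10.0))


@lru_cache(maxsize=None)
def _aa_score_matrix(matrix_name: str) -> np.ndarray:
    """22x22 integer score matrix over encoded residues (incl. stop/other)."""
    sub = substitution_matrices.load(matrix_name)
    m = np.full((22, 22), -1, dtype=np.int32)
    for i, a in enumerate(_AA_ORDER):
        for j, b in enumerate(_AA_ORDER):
            m[i, j] = int(sub[a][b])
    m[_STOP_CODE, :] = _STOP_SCORE
    m[:, _STOP_CODE] = _STOP_SCORE
    return m


@lru_cache(maxsize=None)
def _solve_lambda_aa(matrix_name: str) -> float:
    from scipy.optimize import brentq

    scores = _aa_score_matrix(matrix_name)[:20, :20].astype(float)
    p = np.full(20, 1.0 / 20.0)

    def f(lam: float) -> float:
        return float((p[:, None] * p[None, :] * np.exp(lam * scores)).sum() - 1.0)

    return float(brentq(f, 1e-9, 5.0))


@dataclass
class AlignParams:
    """Engine parameters; defaults depend on the mode.

    ``lambda_`` and ``K`` are the Karlin-Altschul parameters used for
    bit-score and e-value conversion. If left unset, lambda is solved from
    the score system (uniform letter frequencies) and K falls back to the
    documented ungapped default for the mode.
    """

    mode: Literal["nucleotide", "translated"] = "nucleotide"
    word_size: int = 0  # 0 -> mode default (11 nt / 3 aa)
    match: int = 1
    mismatch: int = -2
    matrix_name: str = "BLOSUM62"
    xdrop: int = 0  # 0 -> mode default (20 nt / 15 aa)
    evalue_max: float = 1e-2
    lambda_: float = 0.0
    K: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("nucleotide", "translated"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.word_size == 0:
            self.word_size = 11 if self.mode == "nucleotide" else 3
        if self.xdrop == 0:
            self.xdrop = 20 if self.mode == "nucleotide" else 15
        min_word = 4 if self.mode == "nucleotide" else 2
        if self.word_size < min_word:
            raise ValueError(f"word_size must be >= {min_word} in {self.mode} mode")
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be > 0")
        if self.lambda_ == 0.0:
            self.lambda_ = (
                _solve_lambda_nt(self.match, self.mismatch)
                if self.mode == "nucleotide"
                else _solve_lambda_aa(self.matrix_name)
            )
        if self.K == 0.0:
            self.K = DEFAULT_K_NT if self.mode == "nucleotide" else DEFAULT_K_AA

    def bit_score(self, raw: float) -> float:
        return (self.lambda_ * raw - math.log(self.K)) / math.log(2.0)

    def evalue(self, raw: float, m: int, n: int) -> float:
        x = self.lambda_ * raw
        if x > 700:  # exp underflow guard
            return 0.0
        return self.K * m * n * math.exp(-x)


@dataclass
class Hsp:
    """One ungapped local similarity segment between two sequences.

    All coordinates are 0-based half-open on the *forward* strand of each
    sequence; ``subject_reversed`` marks hits to the subject's reverse
    complement.
    """

    query_id: str
    subject_id: str
    qstart: int
    qend: int
    sstart: int
    send: int
    subject_reversed: bool
    identity_pct: float
    raw_score: float
    bit_score: float
    evalue: float
    mode: Literal["nucleotide", "translated"] = "nucleotide"

    @property
    def length(self) -> int:
        """Alignment length in bp on the query."""
        return self.qend - self.qstart

    def swapped(self) -> "Hsp":
        """The same HSP with query and subject roles exchanged."""
        return replace(
            self,
            query_id=self.subject_id,
            subject_id=self.query_id,
            qstart=self.sstart,
            qend=self.send,
            sstart=self.qstart,
            send=self.qend,
        )


@dataclass
class HitSet:
    """All pairwise HSPs over an input set, keyed by unordered id pair."""

    pairs: dict[tuple[str, str], list[Hsp]] = field(default_factory=dict)
    params: AlignParams = field(default_factory=AlignParams)

    def get(self, query_id: str, subject_id: str) -> list[Hsp]:
        """HSPs for the pair, with ``query_id`` in the query role."""
        if (query_id, subject_id) in self.pairs:
            return self.pairs[(query_id, subject_id)]
        if (subject_id, query_id) in self.pairs:
            return [h.swapped() for h in self.pairs[(subject_id, query_id)]]
        return []

    def all_hsps(self) -> list[Hsp]:
        return [h for hsps in self.pairs.values() for h in hsps]


# ---------------------------------------------------------------------------
# sequence encoding and seeding

_NT_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _NT_ENC[ord(_b)] = _i

_AA_ENC = np.full(256, _OTHER_CODE, dtype=np.uint8)
for _i, _a in enumerate(_AA_ORDER):
    _AA_ENC[ord(_a)] = _i
_AA_ENC[ord("*")] = _STOP_CODE


def _encode_nt(seq: str) -> np.ndarray:
    return _NT_ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _encode_aa(seq: str) -> np.ndarray:
    return _AA_ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(codes: np.ndarray, k: int, alphabet: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed k-mer integer codes and a validity mask (no out-of-alphabet letter)."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    vals = codes.astype(np.int64)
    out = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        w = vals[j : j + n]
        ok = w < alphabet
        out = out * alphabet + np.where(ok, w, 0)
        valid &= ok
    return out, valid


def _seed_pairs(
    q: np.ndarray, s: np.ndarray, k: int, alphabet: int
) -> tuple[np.ndarray, np.ndarray]:
    """All (qpos, spos) with identical valid k-mers (sorted-join, no hashing)."""
    qk, qv = _kmer_codes(q, k, alphabet)
    sk, sv = _kmer_codes(s, k, alphabet)
    qi = np.nonzero(qv)[0]
    si = np.nonzero(sv)[0]
    if qi.size == 0 or si.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    qc, sc = qk[qi], sk[si]
    order = np.argsort(sc, kind="stable")
    sc_sorted, si_sorted = sc[order], si[order]
    left = np.searchsorted(sc_sorted, qc, side="left")
    right = np.searchsorted(sc_sorted, qc, side="right")
    counts = right - left
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    qpos = np.repeat(qi, counts)
    offsets = np.repeat(np.cumsum(counts) - counts, counts)
    within = np.arange(total, dtype=np.int64) - offsets
    spos = si_sorted[np.repeat(left, counts) + within]
    return qpos, spos


# ---------------------------------------------------------------------------
# diagonal extension

def _match_runs(m: np.ndarray, k: int) -> list[tuple[int, int]]:
    """Maximal runs of True in ``m`` with length >= k, as (start, end)."""
    if m.size == 0:
        return []
    d = np.diff(m.astype(np.int8))
    starts = np.nonzero(d == 1)[0] + 1
    ends = np.nonzero(d == -1)[0] + 1
    if m[0]:
        starts = np.concatenate(([0], starts))
    if m[-1]:
        ends = np.concatenate((ends, [m.size]))
    return [(int(a), int(b)) for a, b in zip(starts, ends) if b - a >= k]


def _xdrop_right(v: np.ndarray, xdrop: int) -> tuple[int, float]:
    """Best prefix extension of score vector ``v`` under X-drop; (length, gain)."""
    if v.size == 0:
        return 0, 0.0
    c = np.cumsum(v, dtype=np.int64)
    drop = np.maximum.accumulate(c) - c
    over = drop > xdrop
    stop = int(np.argmax(over)) if over.any() else c.size
    if stop == 0:
        return 0, 0.0
    seg = c[:stop]
    j = int(np.argmax(seg))
    if seg[j] <= 0:
        return 0, 0.0
    return j + 1, float(seg[j])


def _diagonal_hsps(
    vdiag: np.ndarray, mdiag: np.ndarray, k: int, xdrop: int
) -> list[tuple[int, int, float, int]]:
    """HSPs on one diagonal: (local_start, local_end, score, n_matches).

    Seeds are maximal match runs of length >= k; each is extended in both
    directions with X-drop. Overlapping results keep the higher score.
    """
    out: list[tuple[int, int, float, int]] = []
    covered = 0
    for rs, re_ in _match_runs(mdiag, k):
        if rs < covered:
            continue
        seed_score = float(vdiag[rs:re_].sum())
        rlen, rgain = _xdrop_right(vdiag[re_:], xdrop)
        llen, lgain = _xdrop_right(vdiag[:rs][::-1], xdrop)
        s, e = rs - llen, re_ + rlen
        score = seed_score + rgain + lgain
        nmatch = int(mdiag[s:e].sum())
        out.append((s, e, score, nmatch))
        covered = e
    # merge overlaps on the diagonal, keeping the higher score
    out.sort()
    merged: list[tuple[int, int, float, int]] = []
    for h in out:
        if merged and h[0] < merged[-1][1]:
            if h[2] > merged[-1][2]:
                merged[-1] = h
        else:
            merged.append(h)
    # bridge adjacent segments when the dip between them is within the
    # X-drop budget and the union scores higher than either piece alone;
    # interior dip shapes can stop extension even when the total drop is
    # small, and bridging restores the per-diagonal ungapped optimum there.
    # Deep dips (e.g. across an inverted region) stay split, as in X-drop
    # extension proper.
    changed = True
    while changed and len(merged) > 1:
        changed = False
        for i in range(len(merged) - 1):
            s1, e1, sc1, m1 = merged[i]
            s2, e2, sc2, m2 = merged[i + 1]
            gap = float(vdiag[e1:s2].sum())
            if gap > -xdrop and sc1 + gap + sc2 > max(sc1, sc2):
                merged[i : i + 2] = [
                    (s1, e2, sc1 + gap + sc2, int(mdiag[s1:e2].sum()))
                ]
                changed = True
                break
    return merged


def _dedup_hsps(hsps: list[Hsp]) -> list[Hsp]:
    """Drop HSPs overlapping an accepted one by > 50% on both axes.

    Acceptance order is descending raw score, ties by smaller qstart then
    sstart, which makes the result deterministic.
    """
    hsps = sorted(hsps, key=lambda h: (-h.raw_score, h.qstart, h.sstart))
    kept: list[Hsp] = []
    for h in hsps:
        redundant = False
        for g in kept:
            qo = min(h.qend, g.qend) - max(h.qstart, g.qstart)
            so = min(h.send, g.send) - max(h.sstart, g.sstart)
            if (
                qo > 0.5 * min(h.qend - h.qstart, g.qend - g.qstart)
                and so > 0.5 * min(h.send - h.sstart, g.send - g.sstart)
                and h.subject_reversed == g.subject_reversed
            ):
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return kept


def _scan_strand_nt(
    q: np.ndarray, s: np.ndarray, params: AlignParams
) -> list[tuple[int, int, int, int, float, int]]:
    """Raw nt HSPs vs one subject strand: (qstart, qend, sstart, send, score, nmatch)."""
    qpos, spos = _seed_pairs(q, s, params.word_size, 4)
    if qpos.size == 0:
        return []
    diags = np.unique(qpos - spos)
    la, lb = len(q), len(s)
    results = []
    for d in diags:
        d = int(d)
        q0 = max(0, d)
        s0 = q0 - d
        n = min(la - q0, lb - s0)
        qseg = q[q0 : q0 + n]
        sseg = s[s0 : s0 + n]
        m = (qseg == sseg) & (qseg < 4)  # N never matches, even N vs N
        v = np.where(m, params.match, params.mismatch).astype(np.int64)
        for ls, le, score, nmatch in _diagonal_hsps(v, m, params.word_size, params.xdrop):
            results.append((q0 + ls, q0 + le, s0 + ls, s0 + le, score, nmatch))
    return results


def find_hsps_nt(a: SeqRecord, b: SeqRecord, params: AlignParams) -> list[Hsp]:
    """Nucleotide-mode HSPs between ``a`` (query) and ``b`` (subject).

    Both strands of the subject are searched; subject coordinates are always
    reported on the forward strand with ``subject_reversed`` set for hits to
    the reverse complement. Only HSPs with e-value <= ``params.evalue_max``
    are returned, sorted by descending raw score.
    """
    if params.mode != "nucleotide":
        raise ValueError("find_hsps_nt requires nucleotide-mode params")
    qc = _encode_nt(a.sequence)
    m, n = a.length, b.length
    hsps: list[Hsp] = []
    for reversed_ in (False, True):
        subj = b.reverse_complement() if reversed_ else b.sequence
        sc = _encode_nt(subj)
        for qs, qe, ss, se, score, nmatch in _scan_strand_nt(qc, sc, params):
            ev = params.evalue(score, m, n)
            if ev > params.evalue_max:
                continue
            if reversed_:
                ss, se = n - se, n - ss
            hsps.append(
                Hsp(
                    query_id=a.id,
                    subject_id=b.id,
                    qstart=qs,
                    qend=qe,
                    sstart=ss,
                    send=se,
                    subject_reversed=reversed_,
                    identity_pct=100.0 * nmatch / (qe - qs),
                    raw_score=score,
                    bit_score=params.bit_score(score),
                    evalue=ev,
                    mode="nucleotide",
                )
            )
    hsps = _dedup_hsps(hsps)
    hsps.sort(key=lambda h: (-h.raw_score, h.qstart, h.sstart))
    return hsps


# ---------------------------------------------------------------------------
# translated (six-frame) mode

def _frames(seq: str) -> list[tuple[int, bool, str]]:
    """Six-frame translations: (frame offset 0-2, on_reverse_strand, protein)."""
    rc = str(Seq(seq).reverse_complement())
    out = []
    for strand_seq, rev in ((seq, False), (rc, True)):
        for f in range(3):
            sub = strand_seq[f:]
            sub = sub[: len(sub) - len(sub) % 3]
            if not sub:
                out.append((f, rev, ""))
                continue
            out.append((f, rev, str(Seq(sub).translate())))
    return out


def _aa_to_nt_interval(p1: int, p2: int, frame: int, rev: bool, nt_len: int) -> tuple[int, int]:
    """Map an aa interval [p1, p2) in a reading frame to forward-strand bp."""
    x1, x2 = frame + 3 * p1, frame + 3 * p2
    if not rev:
        return x1, x2
    return nt_len - x2, nt_len - x1


def find_hsps_tx(a: SeqRecord, b: SeqRecord, params: AlignParams) -> list[Hsp]:
    """Translated-mode (six-frame) HSPs between ``a`` and ``b``.

    The query is translated in its three forward frames and the subject in
    all six; a query hit on the reverse strand is equivalent to a subject
    reverse-frame hit with mirrored coordinates, so the 3x6 frame grid covers
    the full six-by-six comparison. Stop codons terminate extension. Frames
    shorter than the word size are skipped. Coordinates are reported in bp
    on the forward nucleotide strands; e-values use the search space in
    residues.
    """
    if params.mode != "translated":
        raise ValueError("find_hsps_tx requires translated-mode params")
    score_mat = _aa_score_matrix(params.matrix_name)
    k = params.word_size
    m_res, n_res = max(a.length // 3, 1), max(b.length // 3, 1)
    qframes = [(f, rev, p) for f, rev, p in _frames(a.sequence) if not rev]
    sframes = _frames(b.sequence)
    hsps: list[Hsp] = []
    for qf, _, qprot in qframes:
        if len(qprot) < k:
            continue
        qenc = _encode_aa(qprot)
        for sf, srev, sprot in sframes:
            if len(sprot) < k:
                continue
            senc = _encode_aa(sprot)
            qpos, spos = _seed_pairs(qenc, senc, k, 20)
            if qpos.size == 0:
                continue
            for d in np.unique(qpos - spos):
                d = int(d)
                q0 = max(0, d)
                s0 = q0 - d
                n = min(len(qenc) - q0, len(senc) - s0)
                qseg = qenc[q0 : q0 + n]
                sseg = senc[s0 : s0 + n]
                mm = (qseg == sseg) & (qseg < 20)
                v = score_mat[qseg, sseg].astype(np.int64)
                for ls, le, score, nmatch in _diagonal_hsps(v, mm, k, params.xdrop):
                    ev = params.evalue(score, m_res, n_res)
                    if ev > params.evalue_max:
                        continue
                    qs, qe = _aa_to_nt_interval(q0 + ls, q0 + le, qf, False, a.length)
                    ss, se = _aa_to_nt_interval(s0 + ls, s0 + le, sf, srev, b.length)
                    hsps.append(
                        Hsp(
                            query_id=a.id,
                            subject_id=b.id,
                            qstart=qs,
                            qend=qe,
                            sstart=ss,
                            send=se,
                            subject_reversed=srev,
                            identity_pct=100.0 * nmatch / (le - ls),
                            raw_score=float(score),
                            bit_score=params.bit_score(score),
                            evalue=ev,
                            mode="translated",
                        )
                    )
    hsps = _dedup_hsps(hsps)
    hsps.sort(key=lambda h: (-h.raw_score, h.qstart, h.sstart))
    return hsps


def find_hsps(a: SeqRecord, b: SeqRecord, params: AlignParams) -> list[Hsp]:
    if params.mode == "nucleotide":
        return find_hsps_nt(a, b, params)
    return find_hsps_tx(a, b, params)


def all_pairs(inputs: InputSet, params: AlignParams) -> HitSet:
    """HSPs for all n(n+1)/2 unordered pairs, including self-pairs.

    Self-pairs are needed to normalize the genome similarity score.
    Deterministic given the inputs and parameters.
    """
    pairs: dict[tuple[str, str], list[Hsp]] = {}
    recs = inputs.records
    for i, a in enumerate(recs):
        for b in recs[i:]:
            pairs[(a.id, b.id)] = find_hsps(a, b, params)
    return HitSet(pairs=pairs, params=params)


# ---------------------------------------------------------------------------
# BLAST tabular interchange (outfmt 6)

_BLAST6_COLS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast_tab(
    path: str | Path, records: list[SeqRecord], params: AlignParams
) -> HitSet:
    """Import hits from 12-column BLAST tabular output (outfmt 6).

    Coordinates are converted from 1-based inclusive to 0-based half-open;
    ``sstart > send`` encodes a reversed subject. Rows above the e-value
    threshold are dropped; ids not present in ``records`` are a hard error.
    Raw scores are back-computed from bit scores with the engine's
    Karlin-Altschul parameters.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=_BLAST6_COLS, dtype=str)
    except pd.errors.ParserError as exc:
        raise InputError(f"{path}: malformed BLAST tabular file: {exc}") from exc
    known = {r.id for r in records}
    pairs: dict[tuple[str, str], list[Hsp]] = {}
    ln2, lnK = math.log(2.0), math.log(params.K)
    for idx, row in df.iterrows():
        if row.isna().any():
            raise InputError(f"{path}: row {idx + 1}: expected 12 columns")
        q, s = row["qseqid"], row["sseqid"]
        for sid in (q, s):
            if sid not in known:
                raise InputError(f"{path}: row {idx + 1}: unknown sequence id {sid!r}")
        evalue = float(row["evalue"])
        if evalue > params.evalue_max:
            continue
        qs, qe = int(row["qstart"]) - 1, int(row["qend"])
        s1, s2 = int(row["sstart"]), int(row["send"])
        if s1 <= s2:
            ss, se, rev = s1 - 1, s2, False
        else:
            ss, se, rev = s2 - 1, s1, True
        bit = float(row["bitscore"])
        hsp = Hsp(
            query_id=q,
            subject_id=s,
            qstart=qs,
            qend=qe,
            sstart=ss,
            send=se,
            subject_reversed=rev,
            identity_pct=float(row["pident"]),
            raw_score=(bit * ln2 + lnK) / params.lambda_,
            bit_score=bit,
            evalue=evalue,
            mode=params.mode,
        )
        key = (q, s) if (q, s) in pairs or (s, q) not in pairs else (s, q)
        pairs.setdefault(key, [])
        pairs[key].append(hsp if key == (q, s) else hsp.swapped())
    return HitSet(pairs=pairs, params=params)


def write_blast_tab(hits: HitSet, path: str | Path) -> None:
    """Write a HitSet as 12-column BLAST tabular (outfmt 6)."""
    rows = []
    for (qid, _), hsps in sorted(hits.pairs.items()):
        for h in hsps:
            if h.subject_reversed:
                s1, s2 = h.send, h.sstart + 1
            else:
                s1, s2 = h.sstart + 1, h.send
            rows.append(
                (
                    h.query_id, h.subject_id, f"{h.identity_pct:.2f}",
                    h.qend - h.qstart, round((h.qend - h.qstart) * (1 - h.identity_pct / 100.0)),
                    0, h.qstart + 1, h.qend, s1, s2,
                    f"{h.evalue:.2e}", f"{h.bit_score:.1f}",
                )
            )
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")
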