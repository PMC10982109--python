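"""Synthetic sequence sets with planted structure and ground truth.

Generates families of related sequences for offline testing: a random root
sequence plus derived sequences with point substitutions at a controlled
rate (uniform across positions and target bases, Jukes-Cantor-like) and
structural operations — full or partial inversion, circular rotation,
duplication, deletion — applied after substitutions, in listed order. The
ground truth records every operation together with the layout transform a
correct automatic alignment is expected to recover, so recovery tests read
expectations from the truth object rather than re-deriving them.

All generators are pure functions of their seed and parameters.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .seqio import SeqRecord, write_fasta

_BASES = np.array(list("ACGT"))


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


@dataclass
class PlantedOp:
    kind: str  # inversion | rotation | duplication | deletion
    start: int | None = None  # bp, for interval ops
    end: int | None = None
    amount: int | None = None  # bp, for rotation


@dataclass
class SeqTruth:
    seq_id: str
    parent_id: str | None
    substitution_rate: float
    operations: list[PlantedOp] = field(default_factory=list)
    expected_inverted: bool = False
    expected_rotation: int = 0  # layout rotation aligning back to the parent
    anchor_strand: str = "+"


@dataclass
class PlantedTruth:
    seed: int
    per_seq: dict[str, SeqTruth] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "per_seq": {k: asdict(v) for k, v in self.per_seq.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Point substitutions at the given rate; mutated bases always change."""
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    idx = np.nonzero(hit)[0]
    for i in idx:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _resolve_bp(value: float | int, length: int) -> int:
    """Interpret a spec value as bp (int) or fraction of length (float < 1)."""
    if isinstance(value, float) and 0 < value < 1:
        return int(round(value * length))
    return int(value)


def make_related_set(
    n: int,
    length: int,
    identity: float,
    structure: list[dict] | None = None,
    seed: int = 0,
    circular: bool = False,
) -> tuple[list[SeqRecord], PlantedTruth]:
    """A root sequence plus n-1 derived sequences with planted operations.

    ``structure`` is a list of op specs, each a dict with ``op`` in
    {inversion, rotation, duplication, deletion}, an optional ``seq`` (index
    of the derived sequence it applies to, default 1) and op parameters:
    ``amount`` for rotation, ``start``/``end`` for interval ops (absent for a
    full-sequence inversion). Values in (0, 1) are fractions of the length.
    Rotation requires ``circular=True``. Derived sequence k differs from the
    root by substitutions at rate ``1 - identity`` plus its operations,
    applied after substitutions in listed order.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if length < 1000:
        raise ValueError("need length >= 1 kb")
    if not (0 < identity <= 1):
        raise ValueError("identity must be in (0, 1]")
    rng = np.random.default_rng(seed)
    rate = 1.0 - identity
    root_seq = random_sequence(length, rng)
    ids = [f"s{i + 1}" for i in range(n)]
    records = [SeqRecord(id=ids[0], sequence=root_seq, circular=circular)]
    truth = PlantedTruth(seed=seed)
    truth.per_seq[ids[0]] = SeqTruth(
        seq_id=ids[0], parent_id=None, substitution_rate=0.0
    )
    by_seq: dict[int, list[dict]] = {}
    for spec in structure or []:
        k = int(spec.get("seq", 1))
        if not (1 <= k < n):
            raise ValueError(f"structure spec targets sequence {k}, out of range")
        by_seq.setdefault(k, []).append(spec)

    for k in range(1, n):
        seq = _mutate(root_seq, rate, rng)
        L = len(seq)
        # expected inverse transform tracked as f(i) = (a + b*i) mod L
        a, b = 0, 1
        ops: list[PlantedOp] = []
        for spec in by_seq.get(k, []):
            op = spec["op"]
            if op == "rotation":
                if not circular:
                    raise ValueError("rotation requested on a linear sequence set")
                r = _resolve_bp(spec["amount"], L)
                seq = seq[r:] + seq[:r]
                a = (a + b * r) % L
                ops.append(PlantedOp(kind="rotation", amount=r))
            elif op == "inversion":
                if "start" in spec:
                    s0 = _resolve_bp(spec["start"], L)
                    s1 = _resolve_bp(spec["end"], L)
                    seq = seq[:s0] + _revcomp(seq[s0:s1]) + seq[s1:]
                    ops.append(PlantedOp(kind="inversion", start=s0, end=s1))
                else:
                    seq = _revcomp(seq)
                    a = (a + b * (L - 1)) % L
                    b = -b
                    ops.append(PlantedOp(kind="inversion"))
            elif op == "duplication":
                s0 = _resolve_bp(spec["start"], L)
                s1 = _resolve_bp(spec["end"], L)
                seq = seq[:s1] + seq[s0:s1] + seq[s1:]
                ops.append(PlantedOp(kind="duplication", start=s0, end=s1))
            elif op == "deletion":
                s0 = _resolve_bp(spec["start"], L)
                s1 = _resolve_bp(spec["end"], L)
                seq = seq[:s0] + seq[s1:]
                ops.append(PlantedOp(kind="deletion", start=s0, end=s1))
            else:
                raise ValueError(f"unknown structural op {op!r}")
        inverted = b == -1
        if circular:
            rotation = (a if inverted else (-a) % L) % L
        else:
            rotation = 0
        records.append(SeqRecord(id=ids[k], sequence=seq, circular=circular))
        truth.per_seq[ids[k]] = SeqTruth(
            seq_id=ids[k],
            parent_id=ids[0],
            substitution_rate=rate,
            operations=ops,
            expected_inverted=inverted,
            expected_rotation=rotation,
            anchor_strand="-" if inverted else "+",
        )
    return records, truth


def make_two_cluster_set(
    length: int = 2000,
    within_identity: float = 0.85,
    seed: int = 0,
) -> tuple[list[SeqRecord], set[frozenset[str]]]:
    """Two pairs of related sequences from two unrelated roots.

    Returns the four records (interleaved order, so contiguity is not
    trivially satisfied) and the set of true within-cluster id pairs.
    """
    rng = np.random.default_rng(seed)
    rate = 1.0 - within_identity
    roots = [random_sequence(length, rng) for _ in range(2)]
    recs = {
        "a1": roots[0],
        "a2": _mutate(roots[0], rate, rng),
        "b1": roots[1],
        "b2": _mutate(roots[1], rate, rng),
    }
    order = ["a1", "b1", "a2", "b2"]  # interleaved on purpose
    records = [SeqRecord(id=i, sequence=recs[i]) for i in order]
    clusters = {frozenset(("a1", "a2")), frozenset(("b1", "b2"))}
    return records, clusters


# ---------------------------------------------------------------------------
# ORF fixtures for translated-mode tests

ORF_FLANK = 15  # pyrimidine-only flanks, so the planted ORF stays maximal

_STOP_CODONS = set(standard_dna_table.stop_codons)
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOP_CODONS
]
_SYNONYMS: dict[str, list[str]] = {}
for _c in _CODONS:
    _aa = standard_dna_table.forward_table[_c]
    _SYNONYMS.setdefault(_aa, []).append(_c)


def make_orf_sequence(n_codons: int, seed: int = 0) -> SeqRecord:
    """A sequence whose single maximal ORF spans ``n_codons`` codons.

    The ORF (ATG start, no internal stops, stop codon) sits between short
    pyrimidine-only flanks at offset ``ORF_FLANK``.
    """
    if n_codons < 30:
        raise ValueError("need n_codons >= 30")
    rng = np.random.default_rng(seed)
    body_codons = [_CODONS[rng.integers(0, len(_CODONS))] for _ in range(n_codons - 1)]
    orf = "ATG" + "".join(body_codons) + "TAA"
    pyr = np.array(list("CT"))
    flank1 = "".join(pyr[rng.integers(0, 2, ORF_FLANK)])
    flank2 = "".join(pyr[rng.integers(0, 2, ORF_FLANK)])
    return SeqRecord(id=f"orf{n_codons}", sequence=flank1 + orf + flank2)


def orf_interval(rec: SeqRecord) -> tuple[int, int]:
    """The planted ORF's bp interval in a `make_orf_sequence` record."""
    return ORF_FLANK, rec.length - ORF_FLANK


def synonymous_variant(rec: SeqRecord, seed: int = 0) -> SeqRecord:
    """Recode every recodable ORF codon synonymously; identical translation."""
    rng = np.random.default_rng(seed)
    s0, s1 = orf_interval(rec)
    codons = [rec.sequence[i : i + 3] for i in range(s0, s1, 3)]
    out = []
    for c in codons:
        if c in _STOP_CODONS:
            out.append(c)
            continue
        aa = standard_dna_table.forward_table[c]
        alts = _SYNONYMS[aa]
        out.append(alts[rng.integers(0, len(alts))])
    new = rec.sequence[:s0] + "".join(out) + rec.sequence[s1:]
    return SeqRecord(id=rec.id + "_syn", sequence=new)


def missense_variant(rec: SeqRecord, seed: int = 0) -> SeqRecord:
    """One non-synonymous (non-stop) codon change inside the ORF."""
    rng = np.random.default_rng(seed)
    s0, s1 = orf_interval(rec)
    n_codons = (s1 - s0) // 3
    pos = int(rng.integers(1, n_codons - 1))  # keep start/stop codons
    i = s0 + 3 * pos
    old = rec.sequence[i : i + 3]
    old_aa = standard_dna_table.forward_table[old]
    while True:
        new = _CODONS[rng.integers(0, len(_CODONS))]
        if standard_dna_table.forward_table[new] != old_aa:
            break
    s = rec.sequence[:i] + new + rec.sequence[i + 3 :]
    return SeqRecord(id=rec.id + "_mis", sequence=s)


def write_fixture_set(
    records: list[SeqRecord], truth: PlantedTruth, outdir: str | Path, name: str
) -> tuple[Path, Path]:
    """Write a fixture set as FASTA plus a JSON truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / f"{name}.fasta"
    sidecar = outdir / f"{name}.truth.json"
    write_fasta(records, fasta)
    truth.to_json(sidecar)
    return fasta, sidecar
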