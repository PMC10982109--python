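import numpy as np
import pytest

from syntelign import AlignParams, SeqRecord
from syntelign.fixtures import random_sequence


@pytest.fixture
def nt_params():
    return AlignParams(mode="nucleotide")


@pytest.fixture
def tx_params():
    return AlignParams(mode="translated")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_record(seq_id: str, length: int, seed: int, circular: bool = False) -> SeqRecord:
    r = np.random.default_rng(seed)
    return SeqRecord(id=seq_id, sequence=random_sequence(length, r), circular=circular)


def brute_force_best_diag_score(
    qseq: str, sseq: str, diag: int, match: int = 1, mismatch: int = -2
) -> float:
    """Best ungapped segment score on one diagonal (max-subarray scan).

    Independent of the seed-and-extend engine: scores every position of the
    diagonal and takes the maximum-sum contiguous segment. N counts as a
    mismatch against everything, including itself.
    """
    q = np.frombuffer(qseq.encode(), dtype=np.uint8)
    s = np.frombuffer(sseq.encode(), dtype=np.uint8)
    q0 = max(0, diag)
    s0 = q0 - diag
    n = min(len(q) - q0, len(s) - s0)
    if n <= 0:
        return 0.0
    qseg, sseg = q[q0 : q0 + n], s[s0 : s0 + n]
    is_n = (qseg == ord("N")) | (sseg == ord("N"))
    v = np.where((qseg == sseg) & ~is_n, match, mismatch)
    best = cur = 0
    for x in v:
        cur = max(0, cur + int(x))
        best = max(best, cur)
    return float(best)
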