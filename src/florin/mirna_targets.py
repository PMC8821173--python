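"""Plant miRNA target (MRE) prediction by position-weighted complementarity.

The classic plant-target penalty scheme: each miRNA position scores 0 for a
Watson–Crick pair, 0.5 for a G:U wobble and 1 for a mismatch, with the
penalty doubled over positions 2–13 (the seed-extended core); a site passes
at total penalty <= 4.0 by default. Windows are ungapped and the miRNA is
read antiparallel to the transcript: miRNA position 1 pairs the window's
3' end.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .types import MreSite, Thresholds, TranscriptSeq

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3}

# penalty[mirna_base, target_base]; wobble = miRNA G with target T (=U) or
# miRNA U with target G
PENALTY = np.ones((4, 4))
for _m, _t in ((0, 3), (3, 0), (1, 2), (2, 1)):
    PENALTY[_m, _t] = 0.0
PENALTY[2, 3] = 0.5
PENALTY[3, 2] = 0.5

SEED_START, SEED_END = 2, 13  # 1-based miRNA positions with doubled penalty


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_ENC[c] for c in seq), dtype=np.int8, count=len(seq))


def _weights(length: int) -> np.ndarray:
    w = np.ones(length)
    w[SEED_START - 1:SEED_END] = 2.0
    return w


def score_site(mirna: TranscriptSeq, window: str) -> tuple[float, tuple[str, ...]]:
    """Score one window against a miRNA; returns (penalty, per-position labels).

    ``window`` is the transcript subsequence read 5'->3'; miRNA position i
    pairs window position len-i+1.
    """
    window = window.upper().replace("U", "T")
    if len(window) != len(mirna.seq):
        raise ValueError(f"window length {len(window)} != miRNA length {len(mirna.seq)}")
    m = _encode(mirna.seq)
    t = _encode(window)[::-1]  # align target 3'->5' against miRNA 5'->3'
    per_pos = PENALTY[m, t]
    score = float((per_pos * _weights(len(m))).sum())
    labels = tuple("match" if v == 0 else "wobble" if v == 0.5 else "mismatch" for v in per_pos)
    return score, labels


def _scan_scores(mirna_enc: np.ndarray, transcript_enc: np.ndarray) -> np.ndarray:
    """Penalty at every window start (0-based) of the transcript."""
    L = len(mirna_enc)
    T = len(transcript_enc)
    if T < L:
        return np.empty(0)
    # window start s: miRNA pos i pairs transcript index s + L - i
    # reindex by j = L - i: contribution w[L-j] * PENALTY[m[L-1-j], t[s+j]]
    w = _weights(L)[::-1]
    m_rev = mirna_enc[::-1]
    windows = np.lib.stride_tricks.sliding_window_view(transcript_enc, L)
    return (PENALTY[m_rev[None, :], windows] * w[None, :]).sum(axis=1)


def find_targets(mirnas: Sequence[TranscriptSeq], transcripts: Sequence[TranscriptSeq],
                 cutoff: float | None = None,
                 thresholds: Thresholds = Thresholds()) -> list[MreSite]:
    """Scan every transcript for qualifying miRNA sites.

    Overlapping qualifying windows of the same miRNA on the same transcript
    collapse to the lowest-scoring one (ties broken leftmost).
    """
    if cutoff is None:
        cutoff = thresholds.mre_cutoff
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    sites: list[MreSite] = []
    enc_tx = [(tx, _encode(tx.seq)) for tx in transcripts]
    for mirna in mirnas:
        m_enc = _encode(mirna.seq)
        L = len(m_enc)
        for tx, t_enc in enc_tx:
            scores = _scan_scores(m_enc, t_enc)
            hits = np.flatnonzero(scores <= cutoff)
            if hits.size == 0:
                continue
            # cluster transitively-overlapping windows, keep best per cluster
            cluster: list[int] = [int(hits[0])]
            for s in hits[1:]:
                if s - cluster[-1] < L:
                    cluster.append(int(s))
                else:
                    sites.append(_best_site(mirna, tx, scores, cluster))
                    cluster = [int(s)]
            sites.append(_best_site(mirna, tx, scores, cluster))
    return sites


def _best_site(mirna: TranscriptSeq, tx: TranscriptSeq,
               scores: np.ndarray, starts: list[int]) -> MreSite:
    best = min(starts, key=lambda s: (scores[s], s))
    L = len(mirna.seq)
    score, alignment = score_site(mirna, tx.seq[best:best + L])
    return MreSite(mirna.id, tx.id, best + 1, best + L, score, alignment)


def same_mre(a: MreSite, b: MreSite, strict: bool = False) -> bool:
    """Whether two sites represent the same miRNA's response element.

    Two sites on two different molecules cannot be coordinate-identical, so
    "same MRE" means the same miRNA's element is present on both partners.
    ``strict=True`` additionally requires an identical pairing pattern.
    """
    if a.mirna_id != b.mirna_id:
        return False
    return a.alignment == b.alignment if strict else True
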