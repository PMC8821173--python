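"""cis/trans lncRNA–mRNA target assignment.

cis: the lncRNA locus intersects a strand-aware window around an mRNA
(10 kb past the 5' end, 20 kb past the 3' end, boundary-inclusive) and the
expression profiles correlate (Spearman rho >= 0.6 and Pearson r >= 0.6).
trans: a non-cis pair whose best fully-paired antisense duplex has energy
below -30 under an additive per-pair model (G:C -3, A:T -2, G:U -1), with
the same dual correlation filter.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .types import ExpressionMatrix, GeneFeature, LncPair, Thresholds, TranscriptSeq

logger = logging.getLogger(__name__)

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3}

# energy of pairing base a (5'->3') with base b of the reversed partner;
# 0 marks a non-pairing combination (breaks the duplex)
PAIR_ENERGY = np.zeros((4, 4))
PAIR_ENERGY[2, 1] = PAIR_ENERGY[1, 2] = -3.0  # G:C
PAIR_ENERGY[0, 3] = PAIR_ENERGY[3, 0] = -2.0  # A:T(U)
PAIR_ENERGY[2, 3] = PAIR_ENERGY[3, 2] = -1.0  # G:U


def mrna_window(mrna: GeneFeature, thresholds: Thresholds = Thresholds()) -> tuple[int, int]:
    """Strand-aware cis window [start - up, end + down], pads swapped on '-'."""
    if mrna.strand == "+":
        lo = mrna.start - thresholds.cis_up
        hi = mrna.end + thresholds.cis_down
    else:
        lo = mrna.start - thresholds.cis_down
        hi = mrna.end + thresholds.cis_up
    return max(1, lo), hi


def cis_candidates(annotation: Sequence[GeneFeature],
                   thresholds: Thresholds = Thresholds()) -> list[tuple[str, str]]:
    """All (lncRNA, mRNA) pairs where the lncRNA intersects the mRNA's window."""
    mrnas = [f for f in annotation if f.biotype == "mRNA"]
    lncs = [f for f in annotation if f.biotype == "lncRNA"]
    pairs: list[tuple[str, str]] = []
    for m in mrnas:
        lo, hi = mrna_window(m, thresholds)
        for l in lncs:
            if l.chrom == m.chrom and l.start <= hi and l.end >= lo:
                pairs.append((l.id, m.id))
    return sorted(pairs)


def correlation_pair(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """(Spearman rho with midranks, Pearson r); NaN on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("expression vectors must be equal-length 1-D")
    if len(x) < 3:
        raise ValueError("need at least 3 samples for correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = float(stats.spearmanr(x, y).statistic)
        r = float(stats.pearsonr(x, y).statistic)
    return rho, r


def duplex_energy(a: TranscriptSeq, b: TranscriptSeq) -> float:
    """Energy of the best contiguous, fully-paired antisense duplex.

    Minimum over all offsets and sub-spans where every position pairs; 0 if
    no pairing exists anywhere. All pair energies are negative, so the best
    duplex is always a maximal run of pairing positions.
    """
    ea = np.fromiter((_ENC[c] for c in a.seq), dtype=np.int8, count=len(a.seq))
    # antiparallel: position i of a pairs position j of b with i+j constant,
    # i.e. a aligned against reversed b along matrix diagonals
    eb_rev = np.fromiter((_ENC[c] for c in b.seq), dtype=np.int8, count=len(b.seq))[::-1]
    m = PAIR_ENERGY[ea[:, None], eb_rev[None, :]]
    best = 0.0
    for off in range(-(len(ea) - 1), len(eb_rev)):
        diag = np.diagonal(m, offset=off)
        if diag.size == 0 or (diag == 0).all():
            continue
        # sum each maximal run of pairing entries
        breaks = np.flatnonzero(diag == 0)
        bounds = np.concatenate(([-1], breaks, [diag.size]))
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            if hi - lo > 1:
                best = min(best, float(diag[lo + 1:hi].sum()))
    return best


def classify_pairs(annotation: Sequence[GeneFeature],
                   expr_lnc: ExpressionMatrix, expr_mrna: ExpressionMatrix,
                   sequences: Mapping[str, TranscriptSeq] | Sequence[TranscriptSeq],
                   thresholds: Thresholds = Thresholds(),
                   include_none: bool = False) -> list[LncPair]:
    """Assign every lncRNA–mRNA pair to cis, trans or none.

    cis requires window membership plus the dual correlation filter; trans is
    evaluated only for non-cis pairs and requires duplex energy < energy_max
    plus the same correlation filter.
    """
    if expr_lnc.sample_ids != expr_mrna.sample_ids:
        raise ValueError("expression matrices must share sample ordering")
    if len(expr_lnc.sample_ids) < 6:
        logger.warning("classify_pairs: only %d samples; correlations are noisy",
                       len(expr_lnc.sample_ids))
    if not isinstance(sequences, Mapping):
        sequences = {s.id: s for s in sequences}
    lnc_ids = [f.id for f in annotation if f.biotype == "lncRNA"]
    mrna_ids = [f.id for f in annotation if f.biotype == "mRNA"]
    for fid in list(lnc_ids):
        if fid not in expr_lnc.feature_ids:
            logger.warning("classify_pairs: %s missing from lncRNA expression; skipped", fid)
            lnc_ids.remove(fid)
    for fid in list(mrna_ids):
        if fid not in expr_mrna.feature_ids:
            logger.warning("classify_pairs: %s missing from mRNA expression; skipped", fid)
            mrna_ids.remove(fid)
    cis_set = set(cis_candidates(annotation, thresholds))
    out: list[LncPair] = []
    for l in lnc_ids:
        xl = expr_lnc.data.loc[l].to_numpy(dtype=float)
        for m in mrna_ids:
            xm = expr_mrna.data.loc[m].to_numpy(dtype=float)
            rho, r = correlation_pair(xl, xm)
            correlated = (not np.isnan(rho) and rho >= thresholds.cor_min
                          and not np.isnan(r) and r >= thresholds.cor_min)
            if (l, m) in cis_set:
                relation = "cis" if correlated else "none"
                energy = float("nan")
            else:
                energy = float("nan")
                relation = "none"
                if correlated and l in sequences and m in sequences:
                    energy = duplex_energy(sequences[l], sequences[m])
                    if energy < thresholds.energy_max:
                        relation = "trans"
            if relation != "none" or include_none:
                out.append(LncPair(l, m, relation, rho, r, energy))
    return out
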