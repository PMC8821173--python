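"""Case/control SNP association scan and candidate-gene annotation.

QC keeps biallelic SNPs with missing rate < 0.2 and MAF > 0.05 (strict, MAF
on non-missing calls). Association uses the Cochran–Armitage trend test with
additive scores (0, 1, 2); genome-wide significance is the Bonferroni
threshold -log10(alpha / m). Candidate regions pad each significant SNP by
+/-10 kb and merge; genotype–phenotype concordance is the best two-group
genotype dichotomy; promoter hits of the G-box core (TACGTG by default) are
re-tested after substituting the alt allele to flag motif disruption.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
from scipy import stats

from .types import (
    AssociationResult,
    CandidateRegion,
    GeneFeature,
    GenotypeCalls,
    MotifHit,
    PhenotypeTable,
    Thresholds,
    TranscriptSeq,
)

logger = logging.getLogger(__name__)

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# QC and association
# ---------------------------------------------------------------------------

def qc_filter(genotypes: GenotypeCalls, thresholds: Thresholds = Thresholds()) -> GenotypeCalls:
    """Keep SNPs with missing rate < miss_max and MAF > maf_min (both strict)."""
    codes = genotypes.codes
    n_acc = len(genotypes.accessions)
    if genotypes.n_snps == 0:
        return genotypes
    missing = (codes == -1).sum(axis=1) / n_acc
    called = np.where(codes >= 0, codes, 0).sum(axis=1)
    n_called = (codes >= 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.where(n_called > 0, called / (2 * n_called), 0.0)
    maf = np.minimum(alt_freq, 1 - alt_freq)
    keep = (missing < thresholds.miss_max) & (maf > thresholds.maf_min)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("qc_filter: removed %d of %d SNPs", n_removed, genotypes.n_snps)
    return GenotypeCalls(
        genotypes.snps.loc[keep].reset_index(drop=True),
        codes[keep],
        genotypes.accessions,
        n_skipped=genotypes.n_skipped,
    )


def _trend_chi2(r: np.ndarray, n: np.ndarray, scores=(0.0, 1.0, 2.0)) -> float:
    """Cochran–Armitage chi-square from cases-per-genotype r and totals n."""
    s = np.asarray(scores)
    N = float(n.sum())
    R = float(r.sum())
    num = N * float((s * r).sum()) - R * float((s * n).sum())
    den = R * (N - R) * (N * float((s * s * n).sum()) - float((s * n).sum()) ** 2)
    if den == 0:
        return float("nan")
    return N * num * num / den


def trend_test(codes: np.ndarray, classes: np.ndarray,
               snp_index: int = 0, chrom: str = ".", pos: int = 1) -> AssociationResult:
    """Cochran–Armitage trend test for one SNP against the NF/LF classes.

    Missing calls are dropped; LF is the case class. A genotype constant
    across accessions yields an untestable result excluded from thresholding.
    """
    codes = np.asarray(codes)
    classes = np.asarray(classes)
    ok = codes >= 0
    codes, classes = codes[ok], classes[ok]
    case = classes == "LF"
    if case.sum() < 2 or (~case).sum() < 2:
        raise ValueError("need >= 2 accessions per class after dropping missing calls")
    r = np.array([(case & (codes == g)).sum() for g in (0, 1, 2)], dtype=float)
    n = np.array([(codes == g).sum() for g in (0, 1, 2)], dtype=float)
    chi2 = _trend_chi2(r, n)
    if math.isnan(chi2):
        return AssociationResult(snp_index, chrom, pos, float("nan"), float("nan"),
                                 float("nan"), untestable=True)
    p = float(stats.chi2.sf(chi2, df=1))
    p = max(p, np.nextafter(0, 1))
    return AssociationResult(snp_index, chrom, pos, chi2, p, -math.log10(p))


def association_scan(genotypes: GenotypeCalls, phenotypes: PhenotypeTable,
                     thresholds: Thresholds = Thresholds(),
                     alpha: float | None = None) -> tuple[list[AssociationResult], float]:
    """QC'd trend-test scan over all SNPs; returns (results, -log10 threshold).

    The Bonferroni threshold uses the number of testable SNPs and is applied
    unrounded.
    """
    classes = phenotypes.classes_for(genotypes.accessions)
    results = [
        trend_test(genotypes.codes[i], classes, snp_index=i,
                   chrom=str(row.chrom), pos=int(row.pos))
        for i, row in enumerate(genotypes.snps.itertuples(index=False))
    ]
    m = sum(1 for r in results if not r.untestable)
    threshold = bonferroni_threshold(thresholds.alpha if alpha is None else alpha, max(m, 1))
    for r in results:
        r.significant = (not r.untestable) and r.neg_log10_p >= threshold
    return results, threshold


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise -log10 significance cutoff -log10(alpha / m), full precision."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return -math.log10(alpha / m)


def threshold_display(value: float, decimals: int = 2) -> float:
    """Two-decimal display of a -log10 threshold, truncated as conventionally
    printed (e.g. 7.7157 -> 7.71); thresholding always uses full precision."""
    factor = 10 ** decimals
    return math.floor(value * factor) / factor


# ---------------------------------------------------------------------------
# Candidate regions
# ---------------------------------------------------------------------------

def candidate_regions(significant: Sequence[AssociationResult],
                      annotation: Sequence[GeneFeature] = (),
                      pad: int | None = None,
                      thresholds: Thresholds = Thresholds()) -> list[CandidateRegion]:
    """Pad significant SNPs by +/-pad, merge overlapping or touching regions,
    and attach overlapping genes by interval intersection."""
    if pad is None:
        pad = thresholds.region_pad
    if pad < 0:
        raise ValueError("pad must be >= 0")
    snps = sorted((r for r in significant), key=lambda r: (r.chrom, r.pos))
    regions: list[CandidateRegion] = []
    for r in snps:
        lo, hi = max(1, r.pos - pad), r.pos + pad
        if regions and regions[-1].chrom == r.chrom and lo <= regions[-1].end + 1:
            regions[-1].end = max(regions[-1].end, hi)
            regions[-1].member_snps.append(r.snp_index)
        else:
            regions.append(CandidateRegion(r.chrom, lo, hi, member_snps=[r.snp_index]))
    for region in regions:
        region.gene_ids = sorted(
            f.id for f in annotation
            if f.chrom == region.chrom and f.start <= region.end and f.end >= region.start
        )
    return regions


# ---------------------------------------------------------------------------
# Concordance and promoter motifs
# ---------------------------------------------------------------------------

_DICHOTOMIES = (({0}, {1, 2}), ({0, 1}, {2}), ({0, 2}, {1}))


def concordance(codes: np.ndarray, classes: np.ndarray) -> float:
    """Best genotype-dichotomy agreement with the two phenotype classes.

    Each of the three groupings of {0,1,2} into two sides is tried with both
    side-to-class assignments; the result is the maximal fraction of
    accessions whose side matches their class.
    """
    codes = np.asarray(codes)
    classes = np.asarray(classes)
    ok = codes >= 0
    codes, classes = codes[ok], classes[ok]
    if codes.size == 0:
        raise ValueError("all genotype calls missing")
    is_lf = classes == "LF"
    best = 0.0
    for side_a, _side_b in _DICHOTOMIES:
        in_a = np.isin(codes, list(side_a))
        agree = (in_a == is_lf).mean()
        best = max(best, float(agree), float(1 - agree))
    return best


def motif_scan(seq: TranscriptSeq, motifs: Sequence[str] = ("TACGTG",)) -> list[MotifHit]:
    """All exact motif occurrences on both strands, overlapping included.

    Reverse-strand matches are reported with strand '-' and coordinates on
    the given sequence; the motif text is the motif as given.
    """
    hits: list[MotifHit] = []
    s = seq.seq
    for motif in motifs:
        motif = motif.upper()
        for pattern, strand in ((motif, "+"), (revcomp(motif), "-")):
            start = s.find(pattern)
            while start != -1:
                hits.append(MotifHit(seq.id, start + 1, start + len(motif), strand, motif))
                start = s.find(pattern, start + 1)
    return sorted(hits, key=lambda h: (h.start, h.strand, h.motif))


def snp_motif_disruption(snp: tuple[int, str, str], hits: Sequence[MotifHit],
                         seq: TranscriptSeq,
                         motifs: Sequence[str] = ("TACGTG",)) -> list[tuple[MotifHit, bool]]:
    """Re-test each motif hit containing the SNP after substituting the alt
    allele; a hit is disrupted iff the substituted window matches no motif in
    the set (strand-aware)."""
    pos, ref, alt = snp
    if not 1 <= pos <= len(seq.seq):
        raise ValueError(f"SNP position {pos} outside sequence")
    if seq.seq[pos - 1] != ref.upper():
        raise ValueError(f"ref allele {ref!r} does not match sequence base "
                         f"{seq.seq[pos - 1]!r} at {pos}")
    motif_set = {m.upper() for m in motifs}
    out: list[tuple[MotifHit, bool]] = []
    for hit in hits:
        if not hit.start <= pos <= hit.end:
            continue
        window = list(seq.seq[hit.start - 1:hit.end])
        window[pos - hit.start] = alt.upper()
        window_s = "".join(window)
        oriented = window_s if hit.strand == "+" else revcomp(window_s)
        out.append((hit, oriented not in motif_set))
    return out
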