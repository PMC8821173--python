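"""Synthetic inputs with the statistical structure the pipeline assumes.

Everything the analysis consumes can be generated here: a genomic layout
with lncRNAs placed inside or outside mRNA cis windows, transcripts carrying
miRNA response elements with exactly planned penalty scores, negative-
binomial expression counts with planted differential effects and planted
lncRNA–miRNA–mRNA coupling (a shared per-sample latent factor raising the
miRNA and lowering both partners), and a 66-accession biallelic SNP panel
split 43 NF / 23 LF with one causal SNP sitting on the third nucleotide of a
promoter G-box. Outputs are fully determined by the design seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import lncrna_targets, mirna_targets
from .types import (
    ExpressionMatrix,
    GeneFeature,
    GenotypeCalls,
    PhenotypeTable,
    Thresholds,
    TranscriptSeq,
)

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_WOBBLE_PARTNER = {"G": "T", "T": "G"}  # miRNA base -> target base giving G:U

# slot layout used by simulate_annotation: one mRNA per slot, its cis window
# confined to the slot's middle, dead zones straddling slot boundaries
_SLOT = 80_000
_MRNA_OFFSET = 40_000


@dataclass
class CausalSnpSpec:
    """Where and how the causal SNP is planted.

    ``index`` is its row in the SNP table (default: the middle SNP);
    ``penetrance`` is the probability that the causal genotype matches the
    phenotype class; the SNP lands on nucleotide ``motif_offset`` of a
    ``motif`` occurrence in a ``promoter_length``-nt promoter sequence.
    """

    index: int | None = None
    penetrance: float = 0.9
    promoter_length: int = 2000
    motif: str = "TACGTG"
    motif_offset: int = 3


@dataclass
class SimulationDesign:
    seed: int = 0
    n_mrna: int = 30
    n_lncrna: int = 30
    n_mirna: int = 30
    mirna_length: int = 21
    chrom: str = "chr1"
    chrom_len: int = 5_000_000
    cis_fraction: float = 0.3
    n_reps_per_condition: int = 2
    nb_mean_log_range: tuple[float, float] = (3.0, 10.0)  # log2 baseline means
    nb_dispersion: float = 0.05
    planted_de: list[tuple[str, float, str]] = field(default_factory=list)
    planted_triplets: list[tuple[str, str, str, float]] = field(default_factory=list)
    n_accessions: int = 66
    n_cases: int = 23
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.05
    causal: CausalSnpSpec = field(default_factory=CausalSnpSpec)

    def __post_init__(self) -> None:
        if not 0 <= self.cis_fraction <= 1:
            raise ValueError("cis_fraction must lie in [0, 1]")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must lie in [0, 1]")
        if not 0.5 < self.causal.penetrance <= 1:
            raise ValueError("penetrance must lie in (0.5, 1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.n_cases >= self.n_accessions:
            raise ValueError("n_cases must be < n_accessions")
        for _, _, c in [(t[0], t[1], t[3]) for t in self.planted_triplets]:
            if not 0 < c <= 1:
                raise ValueError("triplet coupling must lie in (0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def simulate_annotation(design: SimulationDesign,
                        thresholds: Thresholds = Thresholds()) -> list[GeneFeature]:
    """Place mRNAs in disjoint slots and lncRNAs inside/outside cis windows.

    Exactly round(cis_fraction * n_lncrna) lncRNAs fall inside the cis window
    of at least one mRNA; the rest lie in dead zones outside every window.
    """
    rng = design.rng(1)
    n_cis = round(design.cis_fraction * design.n_lncrna)
    if design.n_mrna == 0 and n_cis > 0:
        raise ValueError("cannot place cis lncRNAs without mRNAs")
    needed = (design.n_mrna + 1) * _SLOT
    if design.n_mrna and design.chrom_len < needed:
        raise ValueError(f"chrom_len {design.chrom_len} too short; need >= {needed}")

    features: list[GeneFeature] = []
    windows: list[tuple[int, int]] = []
    for i in range(design.n_mrna):
        start = i * _SLOT + _MRNA_OFFSET
        length = int(rng.integers(1000, 3001))
        strand = "+" if rng.random() < 0.5 else "-"
        f = GeneFeature(f"mRNA_{i + 1:04d}", design.chrom, start, start + length - 1,
                        strand, "mRNA")
        features.append(f)
        windows.append(lncrna_targets.mrna_window(f, thresholds))

    # dead zones straddle slot boundaries, clear of every window
    zones = []
    for i in range(design.n_mrna + 1):
        lo = max(1000, i * _SLOT - 15_000)
        hi = min(design.chrom_len - 1000, i * _SLOT + 18_000)
        if hi - lo > 2000:
            zones.append((lo, hi))
    if design.n_mrna == 0:
        zones = [(1000, design.chrom_len - 1000)] if design.chrom_len > 4000 else []

    for j in range(design.n_lncrna):
        length = int(rng.integers(200, 1001))
        strand = "+" if rng.random() < 0.5 else "-"
        if j < n_cis:
            wlo, whi = windows[int(rng.integers(design.n_mrna))]
            wlo = max(1, wlo)
            start = int(rng.integers(wlo, whi - length + 2))
        else:
            if not zones:
                raise ValueError("no room to place lncRNAs outside cis windows")
            zlo, zhi = zones[int(rng.integers(len(zones)))]
            start = int(rng.integers(zlo, zhi - length + 2))
        features.append(GeneFeature(f"lnc_{j + 1:04d}", design.chrom, start,
                                    start + length - 1, strand, "lncRNA"))

    placed_cis = {l for l, _ in lncrna_targets.cis_candidates(features, thresholds)}
    if len(placed_cis) != n_cis:
        raise ValueError(f"infeasible placement: {len(placed_cis)} cis lncRNAs, wanted {n_cis}")
    return features


# ---------------------------------------------------------------------------
# miRNAs and MRE-bearing transcripts
# ---------------------------------------------------------------------------

def simulate_mirnas(design: SimulationDesign) -> list[TranscriptSeq]:
    rng = design.rng(2)
    return [TranscriptSeq(f"miR_{i + 1:03d}", _random_seq(rng, design.mirna_length))
            for i in range(design.n_mirna)]


def _build_site(mirna_seq: str, penalty: float, rng: np.random.Generator) -> str:
    """A target window scoring exactly ``penalty`` against the miRNA.

    Starts from the perfect reverse complement and degrades positions:
    non-seed wobble +0.5, non-seed mismatch +1, seed wobble +1, seed
    mismatch +2 (a wobble needs a G or U miRNA base). Raises if the penalty
    cannot be composed.
    """
    if penalty < 0 or round(penalty * 2) != penalty * 2:
        raise ValueError(f"penalty must be a multiple of 0.5, got {penalty}")
    L = len(mirna_seq)
    window = [_COMP[b] for b in reversed(mirna_seq)]  # window[L - i] pairs pos i

    seed = [i for i in range(mirna_targets.SEED_START, min(mirna_targets.SEED_END, L) + 1)]
    nonseed = [i for i in range(1, L + 1) if i not in seed]
    rng.shuffle(seed)
    rng.shuffle(nonseed)

    def set_pair(pos: int, kind: str) -> None:
        m = mirna_seq[pos - 1]
        if kind == "wobble":
            window[L - pos] = _WOBBLE_PARTNER[m]
        else:
            banned = {_COMP[m], _WOBBLE_PARTNER.get(m, "")}
            choices = [b for b in "ACGT" if b not in banned]
            window[L - pos] = choices[int(rng.integers(len(choices)))]

    halves = round(penalty * 2)
    if halves % 2:  # one non-seed wobble carries the 0.5
        pos = next((p for p in nonseed if mirna_seq[p - 1] in _WOBBLE_PARTNER), None)
        if pos is None:
            raise ValueError("penalty with .5 needs a G/U miRNA base outside the seed")
        nonseed.remove(pos)
        set_pair(pos, "wobble")
        halves -= 1
    units = halves // 2  # remaining integer penalty
    n_seed_mm = min(units // 2, len(seed))
    for _ in range(n_seed_mm):
        set_pair(seed.pop(), "mismatch")
    units -= 2 * n_seed_mm
    n_ns_mm = min(units, len(nonseed))
    for _ in range(n_ns_mm):
        set_pair(nonseed.pop(), "mismatch")
    units -= n_ns_mm
    while units > 0:
        pos = next((p for p in seed if mirna_seq[p - 1] in _WOBBLE_PARTNER), None)
        if pos is None:
            raise ValueError(f"cannot compose penalty {penalty} for this miRNA")
        seed.remove(pos)
        set_pair(pos, "wobble")
        units -= 1
    return "".join(window)


def simulate_transcripts(annotation: Sequence[GeneFeature],
                         mirnas: Sequence[TranscriptSeq],
                         mre_plan: Sequence[tuple[str, str, float]],
                         design: SimulationDesign,
                         ) -> tuple[list[TranscriptSeq], list[dict]]:
    """i.i.d.-uniform transcripts with planned MREs written in.

    Each plan entry (transcript id, miRNA id, penalty) yields a site scoring
    exactly the planned penalty at its planted offset. Returns the transcripts
    and the realised site records (transcript, mirna, start, penalty).
    """
    rng = design.rng(3)
    mirna_of = {m.id: m for m in mirnas}
    seqs: dict[str, list[str]] = {
        f.id: list(_random_seq(rng, f.length)) for f in annotation
    }
    occupied: dict[str, list[tuple[int, int]]] = {f.id: [] for f in annotation}
    planted: list[dict] = []
    for tx_id, mirna_id, penalty in mre_plan:
        if tx_id not in seqs:
            raise ValueError(f"unknown transcript {tx_id!r} in MRE plan")
        if mirna_id not in mirna_of:
            raise ValueError(f"unknown miRNA {mirna_id!r} in MRE plan")
        mirna = mirna_of[mirna_id]
        L = len(mirna.seq)
        tx_len = len(seqs[tx_id])
        if tx_len < L:
            raise ValueError(f"transcript {tx_id} shorter than miRNA {mirna_id}")
        window = _build_site(mirna.seq, penalty, rng)
        for _ in range(200):
            start = int(rng.integers(tx_len - L + 1))  # 0-based
            if all(start + L <= lo or start >= hi for lo, hi in occupied[tx_id]):
                break
        else:
            raise ValueError(f"no room for planned site on {tx_id}")
        occupied[tx_id].append((start, start + L))
        seqs[tx_id][start:start + L] = list(window)
        planted.append({"transcript_id": tx_id, "mirna_id": mirna_id,
                        "start": start + 1, "end": start + L, "penalty": penalty})
    transcripts = [TranscriptSeq(f.id, "".join(seqs[f.id])) for f in annotation]
    tx_of = {t.id: t for t in transcripts}
    for rec in planted:  # every planned site must score exactly as planned
        window = tx_of[rec["transcript_id"]].seq[rec["start"] - 1:rec["end"]]
        score, _ = mirna_targets.score_site(mirna_of[rec["mirna_id"]], window)
        if score != rec["penalty"]:
            raise ValueError(f"unsatisfiable plan: {rec} realised score {score}")
    return transcripts, planted


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(features: Mapping[str, int] | Sequence[tuple[str, int]],
                        design: SimulationDesign,
                        ) -> tuple[ExpressionMatrix, dict]:
    """Negative-binomial counts with planted DE and triplet coupling.

    Baseline log2 means are uniform on ``nb_mean_log_range``; a planted DE
    effect shifts the LF mean by the stated log2 amount; each planted triplet
    shares a per-sample standard-normal latent miRNA activity that scales the
    miRNA up and the coupled mRNA and lncRNA down by exp(+/- coupling * z).
    """
    if not isinstance(features, Mapping):
        features = dict(features)
    ids = list(features)
    for fid, _, _ in design.planted_de:
        if fid not in features:
            raise ValueError(f"planted DE feature {fid!r} not among features")
    for m, l, mi, _ in design.planted_triplets:
        for fid in (m, l, mi):
            if fid not in features:
                raise ValueError(f"planted triplet member {fid!r} not among features")
    rng = design.rng(4)
    reps = design.n_reps_per_condition
    samples = [f"NF_{i + 1}" for i in range(reps)] + [f"LF_{i + 1}" for i in range(reps)]
    condition_of = {s: s.split("_")[0] for s in samples}
    lf_cols = np.array([condition_of[s] == "LF" for s in samples])

    row = {fid: i for i, fid in enumerate(ids)}
    lo, hi = design.nb_mean_log_range
    base = 2.0 ** rng.uniform(lo, hi, size=len(ids))
    mu = np.tile(base[:, None], (1, len(samples)))
    for fid, effect, direction in design.planted_de:
        factor = 2.0 ** (effect if direction == "up" else -effect)
        mu[row[fid], lf_cols] *= factor
    latents = {}
    for m, l, mi, coupling in design.planted_triplets:
        z = rng.normal(size=len(samples))
        latents[(m, l, mi)] = z
        mu[row[mi]] *= np.exp(coupling * z)
        mu[row[m]] *= np.exp(-coupling * z)
        mu[row[l]] *= np.exp(-coupling * z)

    if design.nb_dispersion > 0:
        r = 1.0 / design.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)
    df = pd.DataFrame(counts.astype(float), index=ids, columns=samples)
    matrix = ExpressionMatrix(df, "count", condition_of)
    truth = {
        "planted_de": [list(t) for t in design.planted_de],
        "planted_triplets": [list(t) for t in design.planted_triplets],
        "baseline_log2_mean": {fid: float(np.log2(base[i])) for i, fid in enumerate(ids)},
        "noise_model": "negative binomial with shared-latent triplet coupling "
                       "(synthetic stand-in; no noise model is asserted for real data)",
    }
    return matrix, truth


# ---------------------------------------------------------------------------
# Genotypes, phenotypes and promoter
# ---------------------------------------------------------------------------

def simulate_genotypes(design: SimulationDesign,
                       ) -> tuple[GenotypeCalls, PhenotypeTable, TranscriptSeq, dict]:
    """Case/control SNP panel with one causal SNP inside a promoter G-box.

    Non-causal allele frequencies are uniform on ``maf_range`` independent of
    phenotype; the phenotype split is exactly n_cases LF vs the rest NF and
    the causal genotype matches the class with probability = penetrance.
    Missingness is i.i.d. except on the causal SNP. The returned promoter is
    the reference sequence around the causal SNP, which sits on nucleotide
    ``motif_offset`` of the planted motif.
    """
    rng = design.rng(5)
    n, n_snps = design.n_accessions, design.n_snps
    causal = design.causal
    accessions = [f"acc_{i + 1:03d}" for i in range(n)]

    lf_idx = rng.choice(n, size=design.n_cases, replace=False)
    is_lf = np.zeros(n, dtype=bool)
    is_lf[lf_idx] = True
    phenotypes = PhenotypeTable({a: ("LF" if is_lf[i] else "NF")
                                 for i, a in enumerate(accessions)})

    P = causal.promoter_length
    lo, hi = P, design.chrom_len - P
    positions = np.unique(rng.integers(lo, hi + 1, size=3 * n_snps))
    if len(positions) < n_snps:
        raise ValueError("chrom_len too small for n_snps distinct positions")
    positions = np.sort(rng.choice(positions, size=n_snps, replace=False))
    ci = causal.index if causal.index is not None else n_snps // 2
    if not 0 <= ci < n_snps:
        raise ValueError("causal index out of range")

    maf_lo, maf_hi = design.maf_range
    freqs = rng.uniform(maf_lo, maf_hi, size=n_snps)
    codes = rng.binomial(2, freqs[:, None], size=(n_snps, n)).astype(np.int8)
    match = rng.random(n) < causal.penetrance
    codes[ci] = np.where(is_lf == match, 2, 0)  # LF&match or NF&mismatch -> alt-hom

    if design.missing_rate > 0:
        mask = rng.random((n_snps, n)) < design.missing_rate
        mask[ci] = False
        codes[mask] = -1

    refs = rng.choice(_BASES, size=n_snps)
    alt_shift = rng.integers(1, 4, size=n_snps)
    base_index = {b: i for i, b in enumerate("ACGT")}
    alts = np.array([
        "ACGT"[(base_index[r] + s) % 4] for r, s in zip(refs, alt_shift)
    ])

    # promoter centred on the causal SNP; the motif's mutated nucleotide is
    # the causal reference base
    motif = causal.motif.upper()
    local_snp = P // 2  # 1-based position of the causal SNP in the promoter
    motif_start = local_snp - (causal.motif_offset - 1)
    promoter_seq = list(_random_seq(rng, P))
    promoter_seq[motif_start - 1:motif_start - 1 + len(motif)] = list(motif)
    ref_base = motif[causal.motif_offset - 1]
    refs[ci] = ref_base
    alt_choices = [b for b in "ACGT" if b != ref_base]
    alts[ci] = alt_choices[int(rng.integers(3))]
    promoter = TranscriptSeq("promoter_synthetic", "".join(promoter_seq))

    snps = pd.DataFrame({
        "chrom": design.chrom, "pos": positions.astype(int),
        "ref": refs, "alt": alts,
    })
    calls = GenotypeCalls(snps, codes, accessions)
    truth = {
        "causal_index": int(ci),
        "causal_pos": int(positions[ci]),
        "causal_ref": str(refs[ci]),
        "causal_alt": str(alts[ci]),
        "penetrance": causal.penetrance,
        "promoter_id": promoter.id,
        "promoter_genomic_start": int(positions[ci]) - local_snp + 1,
        "promoter_snp_pos": local_snp,
        "motif": motif,
        "motif_local_start": motif_start,
        "allele_freqs": [float(f) for f in freqs],
        "lf_accessions": [accessions[i] for i in np.flatnonzero(is_lf)],
    }
    return calls, phenotypes, promoter, truth
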