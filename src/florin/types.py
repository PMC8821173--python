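"""Shared domain types for the late-flowering integrative pipeline.

Coordinates are 1-based inclusive at every public interface (the GFF3/VCF
convention); any half-open arithmetic is internal to an operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-")
BIOTYPES = ("mRNA", "lncRNA")
EXPRESSION_UNITS = ("count", "FPKM", "TPM")
EDGE_KINDS = (
    "miRNA->mRNA",
    "miRNA->lncRNA",
    "lncRNA-mRNA(cis)",
    "lncRNA-mRNA(trans)",
)

_DNA = frozenset("ACGT")


@dataclass(frozen=True)
class GeneFeature:
    """A gene locus (mRNA or lncRNA) on the genome."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"{self.id}: start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValueError(f"{self.id}: start {self.start} > end {self.end}")
        if self.strand not in STRANDS:
            raise ValueError(f"{self.id}: unknown strand {self.strand!r}")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"{self.id}: unknown biotype {self.biotype!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TranscriptSeq:
    """A transcript sequence, stored on the DNA alphabet (U normalised to T)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        seq = self.seq.upper().replace("U", "T")
        if not seq:
            raise ValueError(f"{self.id}: empty sequence")
        if not _DNA.issuperset(seq):
            bad = sorted(set(seq) - _DNA)
            raise ValueError(f"{self.id}: non-ACGT(U) characters {bad}")
        object.__setattr__(self, "seq", seq)

    def __len__(self) -> int:
        return len(self.seq)


class ExpressionMatrix:
    """Features x samples expression values with a unit tag and condition labels.

    Thin wrapper over a pandas DataFrame; ``values`` is always non-negative and
    every sample carries a condition label (e.g. NF / LF).
    """

    def __init__(self, data: pd.DataFrame, unit: str, condition_of: Mapping[str, str]):
        if unit not in EXPRESSION_UNITS:
            raise ValueError(f"unknown expression unit {unit!r}")
        if data.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if data.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        arr = data.to_numpy(dtype=float)
        if arr.size and (np.isnan(arr).any() or (arr < 0).any()):
            raise ValueError("expression values must be non-negative and finite")
        missing = [s for s in data.columns if s not in condition_of]
        if missing:
            raise ValueError(f"samples without condition label: {missing}")
        self.data = data
        self.unit = unit
        self.condition_of = {s: condition_of[s] for s in data.columns}

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def samples_of(self, condition: str) -> list[str]:
        return [s for s, c in self.condition_of.items() if c == condition]

    def subset(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(feature_ids)], self.unit, self.condition_of)


@dataclass
class GenotypeCalls:
    """Biallelic SNP codes (alt-allele counts) for a panel of accessions.

    ``codes`` is SNPs x accessions with entries in {0, 1, 2} and -1 for missing.
    """

    snps: pd.DataFrame  # columns: chrom, pos, ref, alt
    codes: np.ndarray
    accessions: list[str]
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if len(set(self.accessions)) != len(self.accessions):
            raise ValueError("accession ids must be unique")
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.snps), len(self.accessions)):
            raise ValueError("codes shape inconsistent with snps/accessions")
        ok = np.isin(self.codes, (-1, 0, 1, 2))
        if not ok.all():
            raise ValueError("genotype codes must be in {0,1,2} or -1 (missing)")
        if len(self.snps) and (self.snps["pos"] < 1).any():
            raise ValueError("SNP positions must be >= 1")
        if len(self.snps) and (self.snps["ref"] == self.snps["alt"]).any():
            raise ValueError("ref and alt alleles must differ")

    @property
    def n_snps(self) -> int:
        return len(self.snps)


@dataclass
class PhenotypeTable:
    """Two-class flowering phenotype (NF = normal, LF = late) per accession."""

    class_of: dict[str, str]

    def __post_init__(self) -> None:
        bad = {c for c in self.class_of.values() if c not in ("NF", "LF")}
        if bad:
            raise ValueError(f"unknown phenotype classes {sorted(bad)}")

    def classes_for(self, accessions: Sequence[str]) -> np.ndarray:
        missing = [a for a in accessions if a not in self.class_of]
        if missing:
            raise ValueError(f"accessions without phenotype: {missing}")
        return np.array([self.class_of[a] for a in accessions])


@dataclass(frozen=True)
class Thresholds:
    """All pipeline cutoffs in one place.

    ``de_lfc_min`` and the class-specific q cutoffs drive differential
    expression; ``cor_min`` applies to both Spearman and Pearson; ``cis_up`` /
    ``cis_down`` are the genomic window pads around an mRNA; ``energy_max`` is
    the trans duplex-energy cutoff (surrogate units, negative); ``mre_cutoff``
    bounds the miRNA target penalty; ``alpha``/``maf_min``/``miss_max``/
    ``region_pad`` drive the association scan.
    """

    de_lfc_min: float = 1.0
    de_q_gene: float = 0.001
    de_q_mirna: float = 0.1
    cor_min: float = 0.6
    cis_up: int = 10_000
    cis_down: int = 20_000
    energy_max: float = -30.0
    mre_cutoff: float = 4.0
    alpha: float = 0.05
    maf_min: float = 0.05
    miss_max: float = 0.2
    region_pad: int = 10_000

    def __post_init__(self) -> None:
        for name in ("de_lfc_min", "de_q_gene", "de_q_mirna", "cor_min",
                     "cis_up", "cis_down", "mre_cutoff", "alpha", "maf_min",
                     "miss_max", "region_pad"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.energy_max >= 0:
            raise ValueError("energy_max must be negative")


@dataclass(frozen=True)
class NetworkEdge:
    source: str
    target: str
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in EDGE_KINDS:
            raise ValueError(f"unknown edge kind {self.kind!r}")
        if self.source == self.target:
            raise ValueError(f"self-edge on {self.source!r}")


# ---------------------------------------------------------------------------
# Stage result types
# ---------------------------------------------------------------------------

@dataclass
class DEResult:
    """One feature's differential-expression call (LF relative to NF)."""

    feature_id: str
    log2_ratio: float
    p_value: float
    q_value: float = float("nan")
    direction: str = "ns"  # up = higher in LF


@dataclass(frozen=True)
class MreSite:
    """A predicted miRNA response element on a transcript (1-based inclusive)."""

    mirna_id: str
    transcript_id: str
    start: int
    end: int
    score: float
    alignment: tuple[str, ...]  # per miRNA position 5'->3': match|wobble|mismatch

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.alignment):
            raise ValueError("site span must equal miRNA length")
        if self.score < 0:
            raise ValueError("penalty score must be >= 0")
        all_match = all(a == "match" for a in self.alignment)
        if (self.score == 0) != all_match:
            raise ValueError("score 0 iff perfect complementarity")


@dataclass
class LncPair:
    lncrna_id: str
    mrna_id: str
    relation: str  # cis | trans | none
    spearman_rho: float
    pearson_r: float
    energy: float = float("nan")


@dataclass(frozen=True)
class SharedMreTest:
    """Hypergeometric shared-miRNA test between one mRNA and one lncRNA.

    N miRNAs in the universe, K target the mRNA, n target the lncRNA,
    k are shared; p is the upper tail P(X >= k).
    """

    N: int
    K: int
    n: int
    k: int
    p_value: float


@dataclass
class CeRnaTriplet:
    mrna_id: str
    lncrna_id: str
    mirna_id: str
    shared_test: SharedMreTest
    directions: tuple[str, str, str]  # (mRNA, lncRNA, miRNA)
    mrna_mirna_cor: float = float("nan")
    lncrna_mirna_cor: float = float("nan")
    mrna_lncrna_cor: float = float("nan")


@dataclass
class AssociationResult:
    snp_index: int
    chrom: str
    pos: int
    chi_square: float
    p_value: float
    neg_log10_p: float
    significant: bool = False
    untestable: bool = False


@dataclass
class CandidateRegion:
    chrom: str
    start: int
    end: int
    member_snps: list[int] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start > end")


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    start: int
    end: int
    strand: str
    motif: str

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.motif):
            raise ValueError("hit span must equal motif length")
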