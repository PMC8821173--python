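"""Expression normalisation (FPKM/TPM) and differential-expression calling.

The two-replicate NF/LF design is handled with a deterministic pooled-count
statistic: counts are summed within condition and each feature is tested with
a two-sided exact conditional test on the 2x2 table (feature vs rest of
library, condition a vs b). Raw p-values are Benjamini–Hochberg corrected and
thresholded with inclusive cutoffs: |log2 ratio| >= 1 with q <= 0.001 for
genes (mRNA/lncRNA) and q <= 0.1 for miRNAs.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import DEResult, ExpressionMatrix, Thresholds

logger = logging.getLogger(__name__)


def _lengths_vector(matrix: ExpressionMatrix, lengths: Mapping[str, float]) -> np.ndarray:
    missing = [f for f in matrix.feature_ids if f not in lengths]
    if missing:
        raise ValueError(f"features without length: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    vec = np.array([float(lengths[f]) for f in matrix.feature_ids])
    if (vec <= 0).any():
        raise ValueError("all feature lengths must be > 0")
    return vec


def compute_fpkm(counts: ExpressionMatrix, lengths: Mapping[str, float]) -> ExpressionMatrix:
    """FPKM_is = counts_is * 1e9 / (length_i * libsize_s); libsize = column sum."""
    if counts.unit != "count":
        raise ValueError("compute_fpkm expects raw counts")
    length = _lengths_vector(counts, lengths)
    values = counts.values
    libsize = values.sum(axis=0)
    zero = libsize == 0
    if zero.any():
        logger.warning("compute_fpkm: %d sample(s) with zero library size", int(zero.sum()))
    safe = np.where(zero, 1.0, libsize)
    fpkm = values * 1e9 / (length[:, None] * safe[None, :])
    fpkm[:, zero] = 0.0
    df = pd.DataFrame(fpkm, index=counts.feature_ids, columns=counts.sample_ids)
    return ExpressionMatrix(df, "FPKM", counts.condition_of)


def compute_tpm(counts: ExpressionMatrix, lengths: Mapping[str, float]) -> ExpressionMatrix:
    """Length-normalised rates scaled so every nonzero sample sums to 1e6."""
    if counts.unit != "count":
        raise ValueError("compute_tpm expects raw counts")
    length = _lengths_vector(counts, lengths)
    rate = counts.values / length[:, None]
    denom = rate.sum(axis=0)
    zero = denom == 0
    if zero.any():
        logger.warning("compute_tpm: %d all-zero sample(s)", int(zero.sum()))
    safe = np.where(zero, 1.0, denom)
    tpm = rate / safe[None, :] * 1e6
    tpm[:, zero] = 0.0
    df = pd.DataFrame(tpm, index=counts.feature_ids, columns=counts.sample_ids)
    return ExpressionMatrix(df, "TPM", counts.condition_of)


def de_test(counts: ExpressionMatrix, group_a: str = "NF", group_b: str = "LF",
            pseudocount: float = 1.0) -> list[DEResult]:
    """Per-feature exact conditional test on pooled counts.

    log2_ratio is log2((pool_b + pc) / (pool_a + pc)) after scaling both pools
    to the mean library size; the pseudocount enters the ratio only, never the
    test. p is the two-sided exact conditional (minimum-likelihood) p on the
    2x2 table [pool, libsize - pool] x [a, b].
    """
    if counts.unit != "count":
        raise ValueError("de_test expects raw counts")
    samples_a = counts.samples_of(group_a)
    samples_b = counts.samples_of(group_b)
    if not samples_a or not samples_b:
        raise ValueError(f"unknown or empty condition label among {group_a!r}, {group_b!r}")
    vals = counts.data
    pool_a = vals[samples_a].sum(axis=1).round().astype(np.int64).to_numpy()
    pool_b = vals[samples_b].sum(axis=1).round().astype(np.int64).to_numpy()
    lib_a, lib_b = int(pool_a.sum()), int(pool_b.sum())
    mean_lib = (lib_a + lib_b) / 2.0
    scale_a = mean_lib / lib_a if lib_a else 0.0
    scale_b = mean_lib / lib_b if lib_b else 0.0
    results: list[DEResult] = []
    for i, fid in enumerate(counts.feature_ids):
        a, b = int(pool_a[i]), int(pool_b[i])
        lfc = float(np.log2((b * scale_b + pseudocount) / (a * scale_a + pseudocount)))
        table = [[a, lib_a - a], [b, lib_b - b]]
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        results.append(DEResult(fid, lfc, min(p, 1.0)))
    return results


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up q-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def attach_q_values(results: list[DEResult]) -> list[DEResult]:
    qs = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = q
    return results


def filter_de(results: Sequence[DEResult], feature_class: str,
              thresholds: Thresholds = Thresholds()) -> list[DEResult]:
    """Keep features with |log2 ratio| >= cutoff and q <= class cutoff (inclusive)."""
    if feature_class == "gene":
        q_max = thresholds.de_q_gene
    elif feature_class == "miRNA":
        q_max = thresholds.de_q_mirna
    else:
        raise ValueError(f"unknown feature class {feature_class!r}")
    kept: list[DEResult] = []
    for r in results:
        if np.isnan(r.q_value):
            raise ValueError("q_values must be populated before filtering")
        if abs(r.log2_ratio) >= thresholds.de_lfc_min and r.q_value <= q_max:
            r.direction = "up" if r.log2_ratio > 0 else "down"
            kept.append(r)
    return kept
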