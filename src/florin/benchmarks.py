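"""Planted-structure recovery benchmarks run end to end through the pipeline.

Each trial builds synthetic inputs under the study's design (two conditions,
66 accessions split 43 NF / 23 LF) and measures whether the pipeline recovers
what was planted. Shared by the test suite and the acceptance script.
"""

from __future__ import annotations

import numpy as np

from . import cerna, diffexpr, gwas, mirna_targets, simulate
from .simulate import CausalSnpSpec, SimulationDesign
from .types import Thresholds

#: planted log2 effect for recovery benchmarks; the triplet coupling latent
#: contributes ~1 log2 unit of pooled-ratio noise at 4 replicates, so the
#: planted shift is set well clear of the |log2 ratio| >= 1 filter
TRIPLET_EFFECT = 4.0
TRIPLET_COUPLING = 0.9
TRIPLET_REPS = 4

PLANTED_TRIPLET = ("mRNA_0001", "lnc_0001", "miR_001")


def triplet_design(seed: int) -> SimulationDesign:
    m, l, mi = PLANTED_TRIPLET
    return SimulationDesign(
        seed=seed,
        n_reps_per_condition=TRIPLET_REPS,
        planted_de=[(m, TRIPLET_EFFECT, "down"), (l, TRIPLET_EFFECT, "down"),
                    (mi, TRIPLET_EFFECT, "up")],
        planted_triplets=[(m, l, mi, TRIPLET_COUPLING)],
    )


def run_triplet_pipeline(design: SimulationDesign,
                         thresholds: Thresholds = Thresholds()) -> list:
    """Simulate inputs, call DE on the pooled library, scan MREs, select triplets.

    The MRE plan puts the planted miRNA's element on both partners (penalties
    0 and 1) and one decoy element of every other miRNA on its own mRNA, so
    the shared-MRE universe is the full miRNA panel.
    """
    m_id, l_id, mi_id = PLANTED_TRIPLET
    annotation = simulate.simulate_annotation(design)
    mirnas = simulate.simulate_mirnas(design)
    plan = [(m_id, mi_id, 0.0), (l_id, mi_id, 1.0)]
    plan += [(f"mRNA_{i:04d}", f"miR_{i:03d}", 2.0) for i in range(2, design.n_mirna + 1)]
    transcripts, _ = simulate.simulate_transcripts(annotation, mirnas, plan, design)
    sites = mirna_targets.find_targets(mirnas, transcripts, thresholds=thresholds)

    features = {f.id: f.length for f in annotation}
    features.update({m.id: len(m.seq) for m in mirnas})
    counts, _ = simulate.simulate_expression(features, design)
    results = diffexpr.attach_q_values(diffexpr.de_test(counts))
    by_id = {r.feature_id: r for r in results}
    de_mrna = diffexpr.filter_de(
        [by_id[f.id] for f in annotation if f.biotype == "mRNA"], "gene", thresholds)
    de_lnc = diffexpr.filter_de(
        [by_id[f.id] for f in annotation if f.biotype == "lncRNA"], "gene", thresholds)
    de_mir = diffexpr.filter_de([by_id[m.id] for m in mirnas], "miRNA", thresholds)
    return cerna.select_triplets(de_mrna, de_lnc, de_mir, sites, thresholds=thresholds)


def triplet_recovery_trial(seed: int) -> dict:
    triplets = run_triplet_pipeline(triplet_design(seed))
    keys = {(t.mrna_id, t.lncrna_id, t.mirna_id) for t in triplets}
    return {
        "recovered": PLANTED_TRIPLET in keys,
        "n_false": len(keys - {PLANTED_TRIPLET}),
    }


def causal_snp_trial(seed: int, n_snps: int = 2000, penetrance: float = 0.9) -> dict:
    """One GWAS round trip: simulate panel, QC, scan, regions, concordance."""
    design = SimulationDesign(seed=seed, n_snps=n_snps,
                              causal=CausalSnpSpec(penetrance=penetrance))
    calls, phenotypes, promoter, truth = simulate.simulate_genotypes(design)
    qc = gwas.qc_filter(calls)
    results, _threshold = gwas.association_scan(qc, phenotypes)
    testable = [r for r in results if not r.untestable]
    best = min(testable, key=lambda r: (r.p_value, r.pos))
    regions = gwas.candidate_regions([r for r in results if r.significant])
    causal_pos = truth["causal_pos"]
    causal_rows = np.flatnonzero(qc.snps["pos"].to_numpy() == causal_pos)
    concord = float("nan")
    if causal_rows.size:
        classes = phenotypes.classes_for(qc.accessions)
        concord = gwas.concordance(qc.codes[causal_rows[0]], classes)
    hits = gwas.motif_scan(promoter, motifs=[truth["motif"]])
    disruptions = gwas.snp_motif_disruption(
        (truth["promoter_snp_pos"], truth["causal_ref"], truth["causal_alt"]),
        hits, promoter, motifs=[truth["motif"]])
    return {
        "rank1": best.pos == causal_pos,
        "in_region": any(r.start <= causal_pos <= r.end for r in regions),
        "concordance": concord,
        "neg_log10_p": best.neg_log10_p,
        "gbox_disrupted": any(d for _h, d in disruptions),
    }


def trend_test_type1(seed: int, n_sims: int = 10_000, alpha: float = 0.05,
                     n_cases: int = 23, n_controls: int = 43) -> float:
    """Empirical type-I error of the trend test on phenotype-independent SNPs."""
    rng = np.random.default_rng(seed)
    classes = np.array(["LF"] * n_cases + ["NF"] * n_controls)
    n = n_cases + n_controls
    hits = 0
    tested = 0
    for _ in range(n_sims):
        q = rng.uniform(0.05, 0.5)
        codes = rng.binomial(2, q, size=n)
        result = gwas.trend_test(codes, classes)
        if result.untestable:
            continue
        tested += 1
        hits += result.p_value <= alpha
    return hits / tested
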