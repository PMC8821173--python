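"""Hypergeometric shared-MRE testing and ceRNA triplet assembly.

An mRNA and a lncRNA are tested for sharing more miRNA regulators than
chance: with N miRNAs in the universe (those with at least one predicted MRE
anywhere in the dataset), K targeting the mRNA, n targeting the lncRNA and k
shared, the p-value is the upper hypergeometric tail P(X >= k). A triplet
(mRNA, lncRNA, shared miRNA) is emitted when all three are differentially
expressed, the miRNA has an MRE on both partners, the mRNA and lncRNA move in
the same direction opposite to the miRNA, and the shared-MRE test passes.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .diffexpr import bh_adjust
from .lncrna_targets import correlation_pair
from .types import (
    CeRnaTriplet,
    DEResult,
    ExpressionMatrix,
    LncPair,
    MreSite,
    NetworkEdge,
    SharedMreTest,
    Thresholds,
)


def hypergeom_shared(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k), X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K, n <= N; got N={N}, K={K}, n={n}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}")
    if k == 0:
        return 1.0
    # survival function at k-1; scipy evaluates the tail in log space
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, np.nextafter(0, 1)), 1.0)


def targets_by_transcript(mres: Iterable[MreSite]) -> dict[str, set[str]]:
    """transcript id -> set of miRNA ids with at least one MRE on it."""
    out: dict[str, set[str]] = defaultdict(set)
    for site in mres:
        out[site.transcript_id].add(site.mirna_id)
    return dict(out)


def select_triplets(de_mrna: Sequence[DEResult], de_lncrna: Sequence[DEResult],
                    de_mirna: Sequence[DEResult], mres: Sequence[MreSite],
                    expr_mrna: ExpressionMatrix | None = None,
                    expr_lncrna: ExpressionMatrix | None = None,
                    expr_mirna: ExpressionMatrix | None = None,
                    thresholds: Thresholds = Thresholds(),
                    p_cutoff: float = 0.05,
                    focus_genes: Iterable[str] | None = None,
                    bh_across_pairs: bool = False) -> list[CeRnaTriplet]:
    """Assemble direction-constrained ceRNA triplets.

    ``de_*`` are the *filtered* DE sets (directions populated). ``focus_genes``
    restricts the mRNA side to a pathway of interest. With
    ``bh_across_pairs=True`` the shared-MRE p-values are BH-adjusted across
    all evaluated pairs before the cutoff is applied.
    """
    dir_mrna = {r.feature_id: r.direction for r in de_mrna}
    dir_lnc = {r.feature_id: r.direction for r in de_lncrna}
    dir_mir = {r.feature_id: r.direction for r in de_mirna}
    if focus_genes is not None:
        focus = set(focus_genes)
        dir_mrna = {f: d for f, d in dir_mrna.items() if f in focus}
    targets = targets_by_transcript(mres)
    universe = {s.mirna_id for s in mres}
    N = len(universe)
    if N == 0:
        return []

    candidates: list[tuple[str, str, SharedMreTest, list[str]]] = []
    for m_id, m_dir in sorted(dir_mrna.items()):
        t_m = targets.get(m_id, set())
        if not t_m:
            continue
        for l_id, l_dir in sorted(dir_lnc.items()):
            if l_dir != m_dir:
                continue  # criterion 3: partners move together
            t_l = targets.get(l_id, set())
            shared = t_m & t_l
            if not shared:
                continue
            opposite = "down" if m_dir == "up" else "up"
            shared_de = sorted(mi for mi in shared if dir_mir.get(mi) == opposite)
            if not shared_de:
                continue
            test = SharedMreTest(N, len(t_m), len(t_l), len(shared),
                                 hypergeom_shared(N, len(t_m), len(t_l), len(shared)))
            candidates.append((m_id, l_id, test, shared_de))

    if not candidates:
        return []
    p_eff = [c[2].p_value for c in candidates]
    if bh_across_pairs:
        p_eff = bh_adjust(p_eff)

    triplets: list[CeRnaTriplet] = []
    for (m_id, l_id, test, shared_de), p in zip(candidates, p_eff):
        if p > p_cutoff:
            continue
        for mi_id in shared_de:
            trip = CeRnaTriplet(
                m_id, l_id, mi_id, test,
                directions=(dir_mrna[m_id], dir_lnc[l_id], dir_mir[mi_id]),
            )
            _attach_correlations(trip, expr_mrna, expr_lncrna, expr_mirna)
            triplets.append(trip)
    return triplets


def _attach_correlations(trip: CeRnaTriplet,
                         expr_mrna: ExpressionMatrix | None,
                         expr_lncrna: ExpressionMatrix | None,
                         expr_mirna: ExpressionMatrix | None) -> None:
    """Pearson correlations across samples, reported for audit only."""

    def vec(matrix: ExpressionMatrix | None, fid: str) -> np.ndarray | None:
        if matrix is None or fid not in matrix.feature_ids:
            return None
        return matrix.data.loc[fid].to_numpy(dtype=float)

    xm = vec(expr_mrna, trip.mrna_id)
    xl = vec(expr_lncrna, trip.lncrna_id)
    xi = vec(expr_mirna, trip.mirna_id)
    if xm is not None and xi is not None:
        trip.mrna_mirna_cor = correlation_pair(xm, xi)[1]
    if xl is not None and xi is not None:
        trip.lncrna_mirna_cor = correlation_pair(xl, xi)[1]
    if xm is not None and xl is not None:
        trip.mrna_lncrna_cor = correlation_pair(xm, xl)[1]


def build_network(triplets: Sequence[CeRnaTriplet],
                  lnc_pairs: Sequence[LncPair] = ()) -> list[NetworkEdge]:
    """miRNA->partner edges per triplet plus cis/trans lncRNA–mRNA edges.

    A classified pair contributes an edge only when both endpoints are already
    nodes of the triplet network; duplicates collapse.
    """
    edges: dict[tuple[str, str, str], NetworkEdge] = {}
    nodes: set[str] = set()
    for t in triplets:
        nodes.update((t.mrna_id, t.lncrna_id, t.mirna_id))
        for e in (NetworkEdge(t.mirna_id, t.mrna_id, "miRNA->mRNA"),
                  NetworkEdge(t.mirna_id, t.lncrna_id, "miRNA->lncRNA")):
            edges[(e.source, e.target, e.kind)] = e
    for p in lnc_pairs:
        if p.relation not in ("cis", "trans"):
            continue
        if p.lncrna_id in nodes and p.mrna_id in nodes:
            e = NetworkEdge(p.lncrna_id, p.mrna_id, f"lncRNA-mRNA({p.relation})")
            edges[(e.source, e.target, e.kind)] = e
    return list(edges.values())
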