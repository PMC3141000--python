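"""Linkage-based fine-mapping of eQTLs from a sparse into a dense panel.

An eQTL tagged on a sparse genotyping panel is traced into a dense
(sequencing) panel by linkage: among dense variants whose own association
with the same feature reaches ``p <= p_link`` (default 1e-3) and whose D'
with the sparse tag is at least ``d_min`` (default 0.8), the smallest
p-value is taken as the dense representative of the same underlying effect.
The pair is then classified as the dense panel finding the identical
variant, a better association (smaller p at a different variant), a worse
one, or no linked variant at all.

D' and r^2 are computed directly from phased haplotype counts (phase is
given, so no EM is needed): D = p_AB - p_A p_B, D' = D / D_max with the
frequency-constrained maximum, r^2 = D^2 / (p_A p_a p_B p_b).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .eqtl import EqtlResultSet, _cis_sites, _feature_iter, _spearman_block
from .types import ExpressionBundle, PhasedHaplotypeSet


@dataclass
class LdPair:
    site_a: int
    site_b: int
    d: float
    d_prime: float
    r2: float
    n_haplotypes: int


def _ld_from_haplotype_vectors(ha: np.ndarray, hb: np.ndarray) -> tuple:
    """(D, D', r2) from two aligned 0/1 haplotype vectors."""
    n = len(ha)
    pA = ha.mean()
    pB = hb.mean()
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return np.nan, np.nan, np.nan
    pAB = np.mean((ha == 1) & (hb == 1))
    D = pAB - pA * pB
    pa, pb = 1.0 - pA, 1.0 - pB
    if D > 0:
        dmax = min(pA * pb, pa * pB)
    elif D < 0:
        dmax = min(pA * pB, pa * pb)
    else:
        dmax = 1.0
    d_prime = abs(D) / dmax if dmax > 0 else np.nan
    r2 = D * D / (pA * pa * pB * pb)
    return D, d_prime, r2


def ld_stats(haps: PhasedHaplotypeSet, site_a: int, site_b: int) -> LdPair:
    """Pairwise LD from the 2N phased haplotypes.  Monomorphic sites give an
    undefined (NaN) result."""
    flat = haps.haplotypes.reshape(-1, haps.n_sites)
    D, dp, r2 = _ld_from_haplotype_vectors(flat[:, site_a], flat[:, site_b])
    return LdPair(site_a=site_a, site_b=site_b, d=D, d_prime=dp, r2=r2,
                  n_haplotypes=flat.shape[0])


def cross_panel_dprime(
    haps_a: PhasedHaplotypeSet, site_a: int,
    haps_b: PhasedHaplotypeSet, site_b: int,
) -> float:
    """D' between a site in one panel and a site in another, using the
    individuals shared by both (haplotypes aligned by sample id and phase)."""
    shared = [s for s in haps_a.sample_ids if s in haps_b.sample_ids]
    ia = [haps_a.sample_index(s) for s in shared]
    ib = [haps_b.sample_index(s) for s in shared]
    ha = haps_a.haplotypes[ia, :, site_a].ravel()
    hb = haps_b.haplotypes[ib, :, site_b].ravel()
    return _ld_from_haplotype_vectors(ha, hb)[1]


@dataclass
class FineMapRecordSet:
    table: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return self.table

    def __len__(self) -> int:
        return len(self.table)


def fine_map(
    sparse_results: EqtlResultSet,
    sparse_haps: PhasedHaplotypeSet,
    dense_haps: PhasedHaplotypeSet,
    bundle: ExpressionBundle,
    d_min: float = 0.8,
    p_link: float = 1e-3,
    window_bp: float = 1_000_000,
    maf_min: float = 0.05,
    feature_kind: str = "gene",
) -> FineMapRecordSet:
    """Trace each significant sparse eQTL into the dense panel.

    Only sparse results flagged significant (at their permutation threshold)
    are fine-mapped.  For each, dense variants in the feature's cis window
    are associated with the same phenotype; those with p <= ``p_link`` and
    D' >= ``d_min`` to the sparse tag are candidates, the best being kept.
    Records the category, the change in distance to the TSS, and the
    conservation difference between the best and second-best linked dense
    associations (the two being required to be in mutual D' >= ``d_min``).
    A sparse tag absent from the dense panel is flagged; its linkage is
    computed across panels from the shared phased individuals.
    """
    feats = {fid: (y, anchor, gene)
             for fid, y, anchor, gene in _feature_iter(bundle, feature_kind)}
    dosage = dense_haps.dosage
    rows = []
    sig = sparse_results.table[sparse_results.table["significant"]]
    for _, r in sig.iterrows():
        fid = r["feature_id"]
        if fid not in feats or not np.isfinite(r["best_site"]):
            continue
        y, anchor, gene = feats[fid]
        sparse_site = int(r["best_site"])
        sparse_pos = int(sparse_haps.positions[sparse_site])
        sparse_p = float(r["p_value"])
        in_dense = np.flatnonzero(dense_haps.positions == sparse_pos)
        absent = len(in_dense) == 0

        sites = _cis_sites(dense_haps, anchor, window_bp, maf_min)
        if len(sites):
            rho, p = _spearman_block(dosage[:, sites], y)
            dp = np.array([
                cross_panel_dprime(sparse_haps, sparse_site, dense_haps, int(j))
                for j in sites
            ])
            linked = (p <= p_link) & (dp >= d_min) & ~np.isnan(p)
        else:
            linked = np.array([], dtype=bool)

        if not linked.any():
            rows.append((fid, feature_kind, sparse_site, sparse_pos, sparse_p,
                         np.nan, np.nan, np.nan, "not_found", np.nan, np.nan,
                         absent))
            continue
        lsites = sites[linked]
        lp = p[linked]
        order = np.lexsort((dense_haps.positions[lsites], lp))
        best = lsites[order[0]]
        best_p = float(lp[order[0]])
        best_pos = int(dense_haps.positions[best])
        if best_pos == sparse_pos:
            category = "same"
        elif best_p < sparse_p:
            category = "better"
        else:
            category = "worse"
        tss = feats[fid][2].tss
        delta_tss = abs(best_pos - tss) - abs(sparse_pos - tss)
        delta_cons = np.nan
        if len(order) > 1:
            second = lsites[order[1]]
            mutual = ld_stats(dense_haps, int(best), int(second)).d_prime
            if np.isfinite(mutual) and mutual >= d_min:
                delta_cons = (dense_haps.conservation_score[best]
                              - dense_haps.conservation_score[second])
        rows.append((fid, feature_kind, sparse_site, sparse_pos, sparse_p,
                     int(best), best_pos, best_p, category, float(delta_tss),
                     delta_cons, absent))
    return FineMapRecordSet(table=pd.DataFrame(
        rows, columns=["feature_id", "feature_kind", "sparse_site",
                       "sparse_pos", "sparse_p", "dense_best_site",
                       "dense_pos", "dense_p", "category",
                       "delta_tss_distance", "delta_conservation",
                       "sparse_absent_from_dense"]))


def category_tally(records: FineMapRecordSet) -> pd.DataFrame:
    """Counts and proportions per category, split by feature kind."""
    cats = ["better", "same", "worse", "not_found"]
    frame = records.table
    rows = []
    kinds = frame["feature_kind"].unique() if len(frame) else []
    for kind in kinds:
        sub = frame[frame["feature_kind"] == kind]
        n = len(sub)
        for c in cats:
            k = int((sub["category"] == c).sum())
            rows.append((kind, c, k, k / n if n else 0.0))
    if not rows:
        rows = [("all", c, 0, 0.0) for c in cats]
    return pd.DataFrame(rows, columns=["feature_kind", "category", "count",
                                       "proportion"])
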