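"""Rare regulatory effects: haplotype homozygosity and prSNP detection.

Two complementary analyses of rare allele-specific-expression (ASE) effects
shared among a few individuals:

*Haplotype homozygosity.*  If a shared ASE effect is driven by a shared rare
regulatory variant, the carrier haplotypes descend from a recent common
ancestor and are identical over an unusually long tract.  From a
heterozygous ASE marker, the tract is the physical distance along two phased
haplotypes until the first mismatching allele.  For each qualifying marker
the reference allele and scan direction are chosen to maximise the mean
pairwise tract, and mean tracts are compared between ASE-significant pairs
and significant/non-significant pairs.

*Putative regulatory SNPs (prSNPs).*  A candidate variant within 100 kb of
the TSS is perfectly concordant with a rare ASE effect shared by 1-3 of at
least 6 testable heterozygotes when it is heterozygous — with the same
allele on the over-expressed haplotype, assessed through phasing — in every
ASE individual, and homozygous in every testable non-ASE individual.  A
matched null reassigns the ASE labels to the least-significant heterozygotes
(directions drawn to match the real direction distribution) and reruns the
identical detection; the real excess over this null estimates how many
candidates are genuinely causal.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .ase import AseCallSet
from .types import FormatError, GeneModel, PhasedHaplotypeSet


# ---------------------------------------------------------------------------
# haplotype homozygosity


def tract_length(
    haps: PhasedHaplotypeSet,
    hap_a: tuple[int, int],
    hap_b: tuple[int, int],
    marker_index: int,
    direction: str,
) -> tuple[int, bool]:
    """Physical homozygosity tract length between two haplotypes.

    Scans from the marker in ``direction`` ("left" = decreasing positions,
    "right" = increasing) and returns ``(length_bp, censored)``: the distance
    from the marker to the first mismatching site, or to the terminal site
    (censored) when no mismatch occurs.  A marker already terminal in that
    direction gives ``(0, True)``.
    """
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    ia, ha = hap_a
    ib, hb = hap_b
    va = haps.haplotypes[ia, ha, :]
    vb = haps.haplotypes[ib, hb, :]
    pos = haps.positions
    m = marker_index
    if direction == "right":
        idx = np.arange(m + 1, haps.n_sites)
    else:
        idx = np.arange(m - 1, -1, -1)
    if len(idx) == 0:
        return 0, True
    mism = va[idx] != vb[idx]
    hit = np.flatnonzero(mism)
    if len(hit) == 0:
        return int(abs(pos[idx[-1]] - pos[m])), True
    return int(abs(pos[idx[hit[0]]] - pos[m])), False


def _mean_pairwise_tract(haps, carriers, marker, direction) -> float:
    pairs = list(combinations(carriers, 2))
    if not pairs:
        return np.nan
    return float(np.mean([
        tract_length(haps, a, b, marker, direction)[0] for a, b in pairs]))


def _cross_pair_tract(haps, group_a, group_b, marker, direction) -> float:
    vals = [tract_length(haps, a, b, marker, direction)[0]
            for a in group_a for b in group_b]
    return float(np.mean(vals)) if vals else np.nan


@dataclass
class TractComparisonSet:
    table: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return self.table

    def __len__(self) -> int:
        return len(self.table)


def shared_ase_homozygosity(
    callset: AseCallSet,
    haps: PhasedHaplotypeSet,
    min_total: int = 6,
    sig_range: tuple[int, int] = (2, 4),
    min_nonsig: int = 2,
) -> TractComparisonSet:
    """Haplotype-homozygosity comparison at shared-ASE markers.

    A marker qualifies with at least ``min_total`` testable heterozygotes of
    which between ``sig_range[0]`` and ``sig_range[1]`` are ASE-significant
    in the same direction and at least ``min_nonsig`` are non-significant.
    The carried allele and scan direction are chosen to maximise the mean
    pairwise tract over all carrier haplotypes; mean tracts are then
    reported within ASE-significant pairs and across significant /
    non-significant pairs, stratified by the number of significant
    haplotypes.
    """
    t = callset.table[callset.table["testable"]]
    rows = []
    for j, grp in t.groupby("site_index"):
        if len(grp) < min_total:
            continue
        sig = grp[grp["significant"]]
        nonsig = grp[~grp["significant"]]
        if len(nonsig) < min_nonsig:
            continue
        # same-direction significant group: take the larger direction class
        n_by_dir = sig.groupby("direction").size() if len(sig) else pd.Series()
        pick = None
        for d in ("ref_higher", "alt_higher"):
            k = int(n_by_dir.get(d, 0))
            if sig_range[0] <= k <= sig_range[1]:
                if pick is None or k > int(n_by_dir.get(pick, 0)):
                    pick = d
        if pick is None:
            continue
        sig = sig[sig["direction"] == pick]
        k = len(sig)

        samples = {s: haps.sample_index(s) for s in grp["sample_id"]}
        for allele in (0, 1):
            # each testable individual is het: exactly one haplotype carries
            # the chosen marker allele
            carrier_hap = {
                s: (i, int(np.flatnonzero(
                    haps.haplotypes[i, :, j] == allele)[0]))
                for s, i in samples.items()
            }
            for direction in ("left", "right"):
                allc = list(carrier_hap.values())
                mean_all = _mean_pairwise_tract(haps, allc, int(j), direction)
                rows.append((int(j), allele, direction, "all", mean_all, k,
                             np.nan, np.nan))
        sub = [r for r in rows if r[0] == int(j) and r[3] == "all"]
        best = max(sub, key=lambda r: (np.nan_to_num(r[4], nan=-1.0)))
        allele, direction = best[1], best[2]
        carrier_hap = {
            s: (i, int(np.flatnonzero(haps.haplotypes[i, :, j] == allele)[0]))
            for s, i in samples.items()
        }
        sig_haps = [carrier_hap[s] for s in sig["sample_id"]]
        non_haps = [carrier_hap[s] for s in nonsig["sample_id"]]
        ase_ase = _mean_pairwise_tract(haps, sig_haps, int(j), direction)
        ase_non = _cross_pair_tract(haps, sig_haps, non_haps, int(j), direction)
        rows = [r for r in rows if not (r[0] == int(j) and r[3] == "all")]
        rows.append((int(j), allele, direction, "chosen", best[4], k,
                     ase_ase, ase_non))
    return TractComparisonSet(table=pd.DataFrame(
        rows, columns=["site_index", "allele", "direction", "scope",
                       "mean_tract_all", "n_significant", "ase_ase_mean",
                       "ase_nonase_mean"]))


# ---------------------------------------------------------------------------
# prSNP detection


@dataclass
class PrSnpCallSet:
    table: pd.DataFrame  # gene_id, marker_site, candidate_site, ...
    skipped_markers: list = None

    def to_frame(self) -> pd.DataFrame:
        return self.table

    def __len__(self) -> int:
        return len(self.table)


_PRSNP_COLS = ["gene_id", "marker_site", "candidate_site", "n_ase_shared",
               "n_testable_het", "kind", "distance_to_tss"]


def _qualifying_markers(
    gene: GeneModel,
    callset: AseCallSet,
    share_range: tuple[int, int],
    min_testable: int,
):
    """Markers of this callset qualifying for prSNP detection: testable in at
    least ``min_testable`` individuals with a shared significant count inside
    ``share_range``.  Yields (site, testable subframe, significant subframe)."""
    t = callset.table[callset.table["testable"]]
    for j, grp in t.groupby("site_index"):
        if len(grp) < min_testable:
            continue
        sig = grp[grp["significant"]]
        if share_range[0] <= len(sig) <= share_range[1]:
            yield int(j), grp, sig


def _concordant_candidates(
    gene: GeneModel,
    haps: PhasedHaplotypeSet,
    marker: int,
    ase_rows: pd.DataFrame,
    nonase_rows: pd.DataFrame,
    window_bp: float,
    include_marker: bool,
) -> np.ndarray:
    """Sites perfectly concordant with the ASE labelling.

    Heterozygous with the same allele on the over-expressed haplotype in
    every ASE individual; homozygous in every testable non-ASE individual.
    """
    pos = haps.positions
    cand = np.flatnonzero(np.abs(pos - gene.tss) <= window_bp)
    if not include_marker:
        cand = cand[cand != marker]
    if len(cand) == 0:
        return cand
    ase_idx = haps.sample_indices(ase_rows["sample_id"])
    high = ase_rows["higher_haplotype"].to_numpy(dtype=int)
    non_idx = haps.sample_indices(nonase_rows["sample_id"])

    H = haps.haplotypes
    het_ase = H[ase_idx, 0][:, cand] != H[ase_idx, 1][:, cand]
    ok = het_ase.all(axis=0)
    # allele on the over-expressed haplotype, same across ASE individuals
    on_high = H[ase_idx, high][:, cand]
    ok &= (on_high == on_high[0]).all(axis=0)
    if len(non_idx):
        hom_non = H[non_idx, 0][:, cand] == H[non_idx, 1][:, cand]
        ok &= hom_non.all(axis=0)
    return cand[ok]


def detect_prsnps(
    gene: GeneModel,
    callset: AseCallSet,
    haps: PhasedHaplotypeSet,
    window_bp: float = 100_000,
    share_range: tuple[int, int] = (1, 3),
    min_testable: int = 6,
    include_marker: bool = False,
) -> PrSnpCallSet:
    """Candidate causal regulatory variants for each qualifying ASE marker
    of a gene (the real pass)."""
    if gene.tss is None:
        raise FormatError(f"gene {gene.gene_id} lacks a TSS annotation")
    rows = []
    sign = 1 if gene.strand == "+" else -1
    for marker, grp, sig in _qualifying_markers(gene, callset, share_range,
                                                min_testable):
        nonase = grp[~grp["significant"]]
        found = _concordant_candidates(gene, haps, marker, sig, nonase,
                                       window_bp, include_marker)
        for c in found:
            rows.append((gene.gene_id, marker, int(c), len(sig), len(grp),
                         "real",
                         sign * (int(haps.positions[c]) - gene.tss)))
    return PrSnpCallSet(table=pd.DataFrame(rows, columns=_PRSNP_COLS),
                        skipped_markers=[])


def build_null_prsnps(
    gene: GeneModel,
    callset: AseCallSet,
    haps: PhasedHaplotypeSet,
    seed=None,
    window_bp: float = 100_000,
    share_range: tuple[int, int] = (1, 3),
    min_testable: int = 6,
    include_marker: bool = False,
) -> PrSnpCallSet:
    """The matched opposite-direction null pass.

    For each marker qualifying in the real pass, ASE is reassigned to the k
    least-significant testable heterozygotes (k = the real significant
    count; significance ties broken by sample id).  Each null individual's
    direction (which haplotype is over-expressed, via which allele it
    carries) is drawn to match the multiset of real directions.  Detection
    is then rerun identically.  A marker where every heterozygote is
    significant cannot be reassigned and is skipped with a flag.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    rows = []
    skipped = []
    sign = 1 if gene.strand == "+" else -1
    for marker, grp, sig in _qualifying_markers(gene, callset, share_range,
                                                min_testable):
        k = len(sig)
        nonsig = grp[~grp["significant"]]
        if len(nonsig) < k:
            skipped.append((gene.gene_id, marker, "all_significant"))
            continue
        ordered = grp.sort_values(["p_value", "sample_id"],
                                  ascending=[False, True])
        null_ase = ordered.head(k).copy()
        # match the real direction distribution: permute the real marker
        # alleles-on-the-high-haplotype onto the null individuals
        real_high_allele = np.array([
            haps.haplotypes[haps.sample_index(s), h, marker]
            for s, h in zip(sig["sample_id"], sig["higher_haplotype"])
        ])
        drawn = real_high_allele[rng.permutation(k)]
        new_high = []
        for (s, _), allele in zip(null_ase[["sample_id", "site_index"]].values,
                                  drawn):
            i = haps.sample_index(s)
            new_high.append(int(np.flatnonzero(
                haps.haplotypes[i, :, marker] == allele)[0]))
        null_ase["higher_haplotype"] = new_high
        null_non = grp.drop(null_ase.index)
        found = _concordant_candidates(gene, haps, marker, null_ase, null_non,
                                       window_bp, include_marker)
        for c in found:
            rows.append((gene.gene_id, marker, int(c), k, len(grp), "null",
                         sign * (int(haps.positions[c]) - gene.tss)))
    return PrSnpCallSet(table=pd.DataFrame(rows, columns=_PRSNP_COLS),
                        skipped_markers=skipped)


def positional_enrichment(
    real_calls: PrSnpCallSet,
    null_calls: PrSnpCallSet,
    window_bp: float = 100_000,
    bin_bp: float = 5_000,
) -> pd.DataFrame:
    """Real vs null candidate counts around the TSS, per ``bin_bp`` window.

    Each bin is tested with Fisher's exact test on the 2x2 table (in-bin vs
    elsewhere) x (real vs null), Bonferroni-corrected over the bins.  With
    an empty null every test is undefined and flagged.
    """
    edges = np.arange(-window_bp, window_bp + bin_bp, bin_bp)
    rd = real_calls.table["distance_to_tss"].to_numpy(float)
    nd = null_calls.table["distance_to_tss"].to_numpy(float)
    n_real, n_null = len(rd), len(nd)
    n_bins = len(edges) - 1
    rows = []
    for b in range(n_bins):
        lo, hi = edges[b], edges[b + 1]
        r_in = int(((rd >= lo) & (rd < hi)).sum())
        u_in = int(((nd >= lo) & (nd < hi)).sum())
        if n_null == 0 or n_real == 0:
            rows.append((lo, hi, r_in, u_in, np.nan, False, True))
            continue
        _, p = stats.fisher_exact(
            [[r_in, n_real - r_in], [u_in, n_null - u_in]])
        rows.append((lo, hi, r_in, u_in, p, p * n_bins <= 0.05, False))
    return pd.DataFrame(rows, columns=["bin_lo", "bin_hi", "real_count",
                                       "null_count", "fisher_p",
                                       "significant", "undefined"])


def real_null_excess(
    genes: list[GeneModel],
    callsets: list[AseCallSet],
    haps_list: list[PhasedHaplotypeSet],
    seed=None,
    **kwargs,
) -> dict:
    """Mean per-gene difference between real and null prSNP counts.

    Runs the real and matched-null passes for each (gene, callset,
    haplotypes) triple and returns the per-gene counts and the mean
    difference — the statistic whose expectation is about one planted causal
    variant per rare ASE effect.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    real_counts, null_counts = [], []
    for gene, callset, haps in zip(genes, callsets, haps_list):
        real = detect_prsnps(gene, callset, haps, **kwargs)
        null = build_null_prsnps(gene, callset, haps, seed=rng, **kwargs)
        qual_real = {m for m, _, _ in _qualifying_markers(
            gene, callset, kwargs.get("share_range", (1, 3)),
            kwargs.get("min_testable", 6))}
        skipped = {m for _, m, _ in null.skipped_markers}
        markers = qual_real - skipped
        if not markers:
            continue
        rt, nt = real.table, null.table
        real_counts.append(int(rt[rt["marker_site"].isin(markers)].shape[0]))
        null_counts.append(int(nt[nt["marker_site"].isin(markers)].shape[0]))
    real_counts = np.array(real_counts, dtype=float)
    null_counts = np.array(null_counts, dtype=float)
    return {
        "n_genes": len(real_counts),
        "mean_real": float(real_counts.mean()) if len(real_counts) else np.nan,
        "mean_null": float(null_counts.mean()) if len(null_counts) else np.nan,
        "mean_difference": float((real_counts - null_counts).mean())
        if len(real_counts) else np.nan,
        "real_counts": real_counts,
        "null_counts": null_counts,
    }
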