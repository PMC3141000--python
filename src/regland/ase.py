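"""Allele-specific expression (ASE) calling and population-level summaries.

Per heterozygote, allelic imbalance is tested with an exact two-sided
binomial test whose null success probability is the lane's reference-allele
mapping bias.  The two-sided p-value uses the minimum-likelihood convention:
the sum of probabilities of all outcomes no more probable than the observed
one.  Effect size is reported as a bias-adjusted fold change
``max(r, 1/r)`` with ``r = (ref/alt) / (bias/(1-bias))``.

Site-level summaries give the proportion of heterozygous individuals with
significant ASE — a proxy for linkage disequilibrium between the coding
variant and unobserved cis-regulatory variants — stratified by derived
allele frequency, and rank-sum comparisons between variant classes in
overlapping DAF bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import AlleleCountTable, DataConsistencyError, PhasedHaplotypeSet

_REL_EPS = 1.0 + 1e-7  # pmf comparison guard against floating-point noise


def binom_p_two_sided(k, n, p) -> np.ndarray:
    """Vectorised exact two-sided binomial p-value (minimum-likelihood method).

    For each observation, sums the probabilities of all outcomes whose
    probability does not exceed that of the observed count.  Matches
    ``scipy.stats.binomtest(k, n, p).pvalue`` elementwise.
    """
    k = np.atleast_1d(np.asarray(k, dtype=int))
    n = np.atleast_1d(np.asarray(n, dtype=int))
    p = np.atleast_1d(np.asarray(p, dtype=float))
    k, n, p = np.broadcast_arrays(k, n, p)
    out = np.empty(k.shape, dtype=float)
    # group identical (n, p) pairs so each pmf table is built once
    flat_k, flat_n, flat_p = k.ravel(), n.ravel(), p.ravel()
    order = np.lexsort((flat_p, flat_n))
    i = 0
    while i < len(order):
        j = i
        ni, pi = flat_n[order[i]], flat_p[order[i]]
        while j < len(order) and flat_n[order[j]] == ni and flat_p[order[j]] == pi:
            j += 1
        pmf = stats.binom.pmf(np.arange(ni + 1), ni, pi)
        srt = np.sort(pmf)
        cum = np.cumsum(srt)
        obs = pmf[flat_k[order[i:j]]]
        # rightmost pmf value not exceeding obs*(1+eps)
        pos = np.searchsorted(srt, obs * _REL_EPS, side="right") - 1
        out.ravel()[order[i:j]] = np.minimum(cum[pos], 1.0)
        i = j
    return out


def test_ase(ref_count: int, alt_count: int, bias: float):
    """Exact ASE test for one heterozygote.

    Returns ``(p_value, fold_change, direction)``.  ``fold_change`` is the
    bias-adjusted allelic ratio folded to >= 1 (infinite when either count is
    zero); ``direction`` is ``"ref_higher"`` or ``"alt_higher"`` according to
    the sign of ``ref/total - bias``.  Both counts zero is an untestable
    signal: ``(nan, nan, None)``.
    """
    total = ref_count + alt_count
    if total == 0:
        return np.nan, np.nan, None
    if not 0.0 < bias < 1.0:
        raise ValueError("mapping bias must lie strictly inside (0, 1)")
    p = float(binom_p_two_sided(ref_count, total, bias)[0])
    if ref_count == 0 or alt_count == 0:
        fold = np.inf
    else:
        r = (ref_count / alt_count) / (bias / (1.0 - bias))
        fold = max(r, 1.0 / r)
    direction = "ref_higher" if ref_count / total >= bias else "alt_higher"
    return p, fold, direction


@dataclass
class AseCallSet:
    """Per-heterozygote ASE calls, aligned with an allelic count table.

    ``table`` columns: sample_id, site_index, ref_count, alt_count,
    mapping_bias, p_value, fold_change, direction, higher_haplotype,
    testable, significant.  ``higher_haplotype`` identifies which of the
    individual's two phased haplotypes carries the over-expressed allele.
    """

    table: pd.DataFrame
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return self.table

    def __len__(self) -> int:
        return len(self.table)


def call_ase_table(
    counts: AlleleCountTable,
    haps: PhasedHaplotypeSet,
    alpha: float = 0.05,
    require_both_alleles: bool = True,
) -> AseCallSet:
    """Call ASE for every row of an allelic count table.

    A row is testable when it has reads and — if ``require_both_alleles`` —
    both alleles are observed at least once (mono-allelic observations are
    otherwise indistinguishable from genotyping error).  Rows at
    non-heterozygous sites raise :class:`DataConsistencyError`.
    """
    t = counts.table
    counts.validate(haps)
    ref = t["ref_count"].to_numpy(dtype=int)
    alt = t["alt_count"].to_numpy(dtype=int)
    bias = t["mapping_bias"].to_numpy(dtype=float)
    total = ref + alt
    testable = total > 0
    if require_both_alleles:
        testable &= (ref > 0) & (alt > 0)

    pvals = np.full(len(t), np.nan)
    ok = total > 0
    pvals[ok] = binom_p_two_sided(ref[ok], total[ok], bias[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (ref / alt) / (bias / (1.0 - bias))
        fold = np.where(np.isfinite(r) & (r > 0), np.maximum(r, 1.0 / r), np.inf)
    fold = np.where(ok, fold, np.nan)
    frac = np.divide(ref, total, out=np.full(len(t), np.nan), where=ok)
    direction = np.where(frac >= bias, "ref_higher", "alt_higher")
    direction = np.where(ok, direction, "NA")

    rows = haps.sample_indices(t["sample_id"])
    sites = t["site_index"].to_numpy(dtype=int)
    # the haplotype carrying the over-expressed allele: for ref_higher the
    # haplotype whose allele is 0, else the one whose allele is 1
    hap0 = haps.haplotypes[rows, 0, sites]
    want = np.where(direction == "ref_higher", 0, 1)
    higher_hap = np.where(hap0 == want, 0, 1)
    higher_hap = np.where(ok, higher_hap, -1)

    significant = testable & (pvals <= alpha)
    out = t.copy()
    out["p_value"] = pvals
    out["fold_change"] = fold
    out["direction"] = direction
    out["higher_haplotype"] = higher_hap
    out["testable"] = testable
    out["significant"] = significant
    return AseCallSet(table=out, alpha=alpha)


# ---------------------------------------------------------------------------
# population-level ASE-proportion statistics


def ase_proportion_by_daf(
    callset: AseCallSet,
    haps: PhasedHaplotypeSet,
    min_het: int = 3,
    window_snps: int = 150,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-site ASE proportions and a DAF-ordered sliding-window summary.

    A record is emitted for every site with at least ``min_het`` testable
    heterozygotes: the proportion of them with significant ASE, the site's
    derived allele frequency and consequence class, and the derived allele's
    direction of effect (``loss`` if the derived allele is lower-expressed in
    every significant heterozygote, ``gain`` if higher in every one,
    ``mixed`` otherwise, ``unknown`` without ancestral information).

    The window summary orders records by DAF and reports, in sliding windows
    of ``window_snps`` records (count-based, step 1), the mean proportion and
    the 10% upper/lower quantiles.
    """
    t = callset.table[callset.table["testable"]]
    records = []
    daf = haps.daf
    for j, grp in t.groupby("site_index"):
        n_testable = len(grp)
        if n_testable < min_het:
            continue
        sig = grp[grp["significant"]]
        anc = haps.ancestral[j]
        if anc == "unknown":
            derived_dir = "unknown"
        elif len(sig) == 0:
            derived_dir = "unknown"
        else:
            # derived allele is alt when ancestral == ref
            derived_is_alt = anc == "ref"
            gain = (sig["direction"] == ("alt_higher" if derived_is_alt
                                         else "ref_higher")).to_numpy()
            if gain.all():
                derived_dir = "gain"
            elif (~gain).all():
                derived_dir = "loss"
            else:
                derived_dir = "mixed"
        records.append(
            (int(j), n_testable, int(len(sig)), len(sig) / n_testable,
             daf[j], haps.consequence[j], derived_dir)
        )
    rec = pd.DataFrame(
        records,
        columns=["site_index", "n_het_testable", "n_het_significant",
                 "proportion", "daf", "consequence", "derived_direction"],
    )
    if rec.empty:
        import logging
        logging.getLogger("regland").warning(
            "no site passes the min_het=%d filter", min_het)
        return rec, pd.DataFrame(
            columns=["daf_mean", "mean_proportion", "q10", "q90"])

    srt = rec.dropna(subset=["daf"]).sort_values("daf").reset_index(drop=True)
    w = min(window_snps, len(srt))
    wins = []
    for lo in range(0, len(srt) - w + 1):
        chunk = srt.iloc[lo:lo + w]
        wins.append((
            chunk["daf"].mean(),
            chunk["proportion"].mean(),
            chunk["proportion"].quantile(0.10),
            chunk["proportion"].quantile(0.90),
        ))
    windows = pd.DataFrame(wins, columns=["daf_mean", "mean_proportion",
                                          "q10", "q90"])
    return rec, windows


def compare_ase_proportions(
    records: pd.DataFrame,
    group_a: str,
    group_b: str,
    bin_width: float = 0.05,
    bin_step: float = 0.025,
) -> dict:
    """Rank-sum comparison of ASE proportions between two consequence classes.

    Returns the overall two-sided Mann-Whitney p-value plus per-bin tests in
    overlapping DAF bins (width ``bin_width``, step ``bin_step``).  Bins with
    fewer than 2 records in either group are kept in the output with a
    ``skipped`` flag.
    """
    a = records[records["consequence"] == group_a]
    b = records[records["consequence"] == group_b]
    if a.empty or b.empty:
        raise ValueError("both groups must be non-empty")
    overall = stats.mannwhitneyu(a["proportion"], b["proportion"],
                                 alternative="two-sided")
    bins = []
    lo = 0.0
    while lo < 1.0 - 1e-9:
        hi = lo + bin_width
        am = a[(a["daf"] >= lo) & (a["daf"] < hi)]["proportion"]
        bm = b[(b["daf"] >= lo) & (b["daf"] < hi)]["proportion"]
        if len(am) < 2 or len(bm) < 2:
            bins.append((lo, hi, len(am), len(bm), np.nan, "NA", True))
        else:
            res = stats.mannwhitneyu(am, bm, alternative="two-sided")
            dirn = "a_higher" if am.median() > bm.median() else "b_higher"
            bins.append((lo, hi, len(am), len(bm), res.pvalue, dirn, False))
        lo += bin_step
    return {
        "overall_p": float(overall.pvalue),
        "bins": pd.DataFrame(
            bins, columns=["daf_lo", "daf_hi", "n_a", "n_b", "p_value",
                           "direction", "skipped"]),
    }


def class_proportion_summary(callset: AseCallSet, haps: PhasedHaplotypeSet,
                             variant_class: str) -> dict:
    """Pooled ASE proportion for a consequence class: the number of
    significant testable heterozygotes over all testable heterozygotes at
    sites of that class (the statistic quoted per class, e.g. the fraction
    of stop-gained heterozygotes with detectable allelic imbalance)."""
    t = callset.table
    cls = haps.consequence[t["site_index"].to_numpy(dtype=int)] == variant_class
    sub = t[cls & t["testable"]]
    n_testable = len(sub)
    n_sig = int(sub["significant"].sum())
    return {
        "variant_class": variant_class,
        "n_testable": n_testable,
        "n_significant": n_sig,
        "proportion": n_sig / n_testable if n_testable else np.nan,
        "n_sites": sub["site_index"].nunique(),
    }


def pooled_proportion(n_significant: int, n_testable: int) -> float:
    """Proportion of testable heterozygotes with significant ASE."""
    if n_testable <= 0:
        raise ValueError("n_testable must be positive")
    if not 0 <= n_significant <= n_testable:
        raise ValueError("n_significant must be between 0 and n_testable")
    return n_significant / n_testable
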