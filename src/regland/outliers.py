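"""Coincidence of expression outliers with rare variants.

Expression is standardised per gene to Z-scores across individuals.  A
coincidence is a (gene, variant, individual) triple where the individual
carries at least one non-reference allele of a variant within a window of
the gene's TSS (optionally restricted to conserved-element variants) and the
individual's Z for that gene reaches the outlier threshold (one-tailed high,
Z >= 2, by default; two-sided optional).  Coincidences are binned by the
variant's non-reference allele count in the cohort (singletons, doubletons,
...), and the observed counts are compared with an envelope obtained by
permuting the individual labels of the expression matrix (genotypes fixed)
200 times, from which 90 and 95% one- and two-sided bounds, the permuted
mean, the excess and a per-individual rate are derived.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import ExpressionBundle, GeneModel, PhasedHaplotypeSet


def zscore_matrix(bundle_or_frame) -> pd.DataFrame:
    """Per-gene Z-scores across individuals ((x - mean) / SD, SD with n-1).

    Genes with zero variance are dropped (recorded in ``.attrs['dropped']``).
    Requires at least 3 individuals.
    """
    expr = (bundle_or_frame.gene_expr
            if isinstance(bundle_or_frame, ExpressionBundle)
            else pd.DataFrame(bundle_or_frame))
    if len(expr) < 3:
        raise ValueError("need at least 3 individuals per gene")
    sd = expr.std(axis=0, ddof=1)
    keep = sd > 0
    z = (expr.loc[:, keep] - expr.loc[:, keep].mean(axis=0)) / sd[keep]
    z.attrs["dropped"] = list(expr.columns[~keep])
    return z


@dataclass
class _Incidence:
    """Precomputed (variant-in-window, carrier) structure for fast counting."""

    pair_gene_col: np.ndarray   # per (gene, variant) pair: Z column index
    pair_bin: np.ndarray        # per pair: non-reference allele count
    carrier_pair: np.ndarray    # flat carrier list: pair index
    carrier_ind: np.ndarray     # flat carrier list: individual row index
    pair_gene_id: list
    pair_site: np.ndarray
    max_bin: int


def _build_incidence(
    Z: pd.DataFrame,
    haps: PhasedHaplotypeSet,
    annotation: list[GeneModel],
    window_bp: float,
    conserved_only: bool,
) -> _Incidence:
    rows = haps.sample_indices(Z.index)
    carriers_by_site = {}
    dosage = haps.dosage[rows]  # align to Z row order
    alt_count = haps.alt_count
    pos = haps.positions
    usable = alt_count > 0
    if conserved_only:
        usable &= haps.conserved_flag
    pair_gene_col, pair_bin, pair_site, pair_gene_id = [], [], [], []
    carrier_pair, carrier_ind = [], []
    col_of = {g: k for k, g in enumerate(Z.columns)}
    for gene in annotation:
        if gene.gene_id not in col_of:
            continue
        near = np.flatnonzero(usable & (np.abs(pos - gene.tss) <= window_bp))
        for j in near:
            if j not in carriers_by_site:
                carriers_by_site[j] = np.flatnonzero(dosage[:, j] >= 1)
            c = carriers_by_site[j]
            if len(c) == 0:
                continue
            pid = len(pair_gene_col)
            pair_gene_col.append(col_of[gene.gene_id])
            pair_bin.append(int(alt_count[j]))
            pair_site.append(int(j))
            pair_gene_id.append(gene.gene_id)
            carrier_pair.extend([pid] * len(c))
            carrier_ind.extend(c.tolist())
    return _Incidence(
        pair_gene_col=np.array(pair_gene_col, dtype=int),
        pair_bin=np.array(pair_bin, dtype=int),
        carrier_pair=np.array(carrier_pair, dtype=int),
        carrier_ind=np.array(carrier_ind, dtype=int),
        pair_gene_id=pair_gene_id,
        pair_site=np.array(pair_site, dtype=int),
        max_bin=int(alt_count.max()) if haps.n_sites else 0,
    )


def _count_bins(inc: _Incidence, outlier: np.ndarray,
                row_perm: np.ndarray | None = None) -> np.ndarray:
    """Coincidence count per allele-count bin for one (possibly permuted)
    outlier matrix.  ``row_perm[i]`` = which original individual's expression
    individual i now carries."""
    ind = inc.carrier_ind
    if row_perm is not None:
        ind = row_perm[ind]
    hits = outlier[ind, inc.pair_gene_col[inc.carrier_pair]]
    counts = np.zeros(inc.max_bin + 1, dtype=int)
    if hits.any():
        np.add.at(counts, inc.pair_bin[inc.carrier_pair[hits]], 1)
    return counts


def outlier_coincidence(
    Z: pd.DataFrame,
    haps: PhasedHaplotypeSet,
    annotation: list[GeneModel],
    window_bp: float = 100_000,
    z_min: float = 2.0,
    conserved_only: bool = False,
    two_sided: bool = False,
) -> tuple[pd.Series, pd.DataFrame]:
    """Observed coincidences per non-reference allele-count bin.

    Returns the per-bin counts (index = allele count, starting at 1 for
    singletons) and the table of coincident (gene, variant, individual)
    triples, which also supports a deduplicated (gene, individual) count.
    """
    inc = _build_incidence(Z, haps, annotation, window_bp, conserved_only)
    zv = Z.to_numpy(float)
    outlier = np.abs(zv) >= z_min if two_sided else zv >= z_min
    counts = _count_bins(inc, outlier)
    hits = outlier[inc.carrier_ind, inc.pair_gene_col[inc.carrier_pair]]
    hp = inc.carrier_pair[hits]
    triples = pd.DataFrame({
        "gene_id": [inc.pair_gene_id[p] for p in hp],
        "site_index": inc.pair_site[hp],
        "sample_id": [Z.index[i] for i in inc.carrier_ind[hits]],
        "allele_count": inc.pair_bin[hp],
    })
    series = pd.Series(counts[1:], index=pd.RangeIndex(1, len(counts),
                                                       name="allele_count"))
    return series, triples


def permutation_envelope(
    Z: pd.DataFrame,
    haps: PhasedHaplotypeSet,
    annotation: list[GeneModel],
    n_perm: int = 200,
    seed=None,
    window_bp: float = 100_000,
    z_min: float = 2.0,
    conserved_only: bool = False,
    two_sided_outlier: bool = False,
) -> pd.DataFrame:
    """Observed coincidences against a label-permutation envelope.

    Individual labels of the expression matrix are permuted ``n_perm`` times
    (default 200); per allele-count bin the table reports the observed
    count, the permuted mean, 90/95% one- and two-sided bounds, the excess
    (observed - permuted mean) and the per-individual rate.  The permutation
    leaves every (variant, carrier) pair intact — only the expression
    assignment moves — which the implementation asserts each round.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1 (default 200)")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    inc = _build_incidence(Z, haps, annotation, window_bp, conserved_only)
    zv = Z.to_numpy(float)
    outlier = np.abs(zv) >= z_min if two_sided_outlier else zv >= z_min
    observed = _count_bins(inc, outlier)
    n_pairs = len(inc.carrier_ind)
    perm_counts = np.empty((n_perm, len(observed)), dtype=int)
    for r in range(n_perm):
        perm = rng.permutation(len(Z))
        assert len(inc.carrier_ind) == n_pairs  # carrier structure untouched
        perm_counts[r] = _count_bins(inc, outlier, row_perm=perm)

    n_ind = len(Z)
    rows = []
    for b in range(1, len(observed)):
        pc = perm_counts[:, b]
        obs = int(observed[b])
        mean = float(pc.mean())
        rows.append({
            "allele_count": b,
            "observed": obs,
            "permuted_mean": mean,
            "lo90_two": float(np.quantile(pc, 0.05)),
            "hi90_two": float(np.quantile(pc, 0.95)),
            "lo95_two": float(np.quantile(pc, 0.025)),
            "hi95_two": float(np.quantile(pc, 0.975)),
            "hi90_one": float(np.quantile(pc, 0.90)),
            "hi95_one": float(np.quantile(pc, 0.95)),
            "excess": obs - mean,
            "per_individual_rate": (obs - mean) / n_ind,
            "outside_95_two": bool(obs < np.quantile(pc, 0.025)
                                   or obs > np.quantile(pc, 0.975)),
            "above_95_one": bool(obs > np.quantile(pc, 0.95)),
        })
    return pd.DataFrame(rows)
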