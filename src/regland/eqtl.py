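"""Cis-eQTL mapping: Spearman associations, permutation thresholds, FDR.

For every feature (gene, or exon for read-count data) all variants passing a
minor-allele-frequency filter within a cis window — anchored at the TSS for
genes and at the exon midpoint for exons — are tested by Spearman rank
correlation between genotype dosage (0/1/2) and the phenotype.  Feature-level
significance uses an empirical permutation threshold: the phenotype vector is
permuted across individuals (genotypes fixed, preserving LD), the best cis
p-value is recorded per permutation, and the threshold is the chosen quantile
(default 0.01) of that null minimum-p distribution.  The false discovery rate
at a p-value level is estimated as the mean number of significant features in
full permuted passes divided by the observed number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import ExpressionBundle, GeneModel, PhasedHaplotypeSet


def spearman_assoc(genotype_vector, phenotype_vector) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with the
    t-approximation p-value.  Zero variance in either vector returns
    ``(nan, nan)``."""
    g = np.asarray(genotype_vector, dtype=float)
    y = np.asarray(phenotype_vector, dtype=float)
    if g.shape != y.shape or g.ndim != 1 or len(g) < 4:
        raise ValueError("need two equal-length vectors of length >= 4")
    if np.ptp(g) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan
    rho, p = _spearman_block(g[:, None], y)
    return float(rho[0]), float(p[0])


def _t_sf_p(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t-approximation of Spearman's rho."""
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(rho), 1.0), 0.0, p)
    return np.where(np.isnan(rho), np.nan, np.minimum(p, 1.0))


def _spearman_block(G: np.ndarray, y: np.ndarray):
    """rho and p between one phenotype (n,) and each genotype column (n, V)."""
    n = len(y)
    rg = stats.rankdata(G, axis=0)
    ry = stats.rankdata(y)
    rg = rg - rg.mean(axis=0)
    ry = ry - ry.mean()
    denom = np.sqrt((rg**2).sum(axis=0) * (ry**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (ry @ rg) / denom
    rho = np.where(denom == 0, np.nan, rho)
    return rho, _t_sf_p(rho, n)


def _perm_min_p(G: np.ndarray, y: np.ndarray, n_perm: int,
                rng: np.random.Generator) -> np.ndarray:
    """Minimum cis p-value per phenotype permutation (vectorised)."""
    n, V = G.shape
    rg = stats.rankdata(G, axis=0)
    rg = rg - rg.mean(axis=0)
    sg = np.sqrt((rg**2).sum(axis=0))
    ry = stats.rankdata(y)
    ry = ry - ry.mean()
    sy = np.sqrt((ry**2).sum())
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    RY = ry[perms]  # (n_perm, n)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (RY @ rg) / (sy * sg)  # (n_perm, V)
    rho = np.where(sg == 0, np.nan, rho)
    p = _t_sf_p(rho, n)
    return np.nanmin(p, axis=1)


@dataclass
class EqtlResultSet:
    """Best cis association per feature with its permutation context.

    Columns: feature_id, feature_kind, best_site, position, rho, p_value,
    n_tested, perm_threshold, significant.
    """

    table: pd.DataFrame
    level: float = 0.01

    def to_frame(self) -> pd.DataFrame:
        return self.table

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, level: float = 0.01):
        return cls(table=frame.reset_index(drop=True), level=level)

    def __len__(self) -> int:
        return len(self.table)


def _feature_iter(bundle: ExpressionBundle, feature_kind: str):
    """Yield (feature_id, phenotype vector, anchor bp, tss, gene)."""
    if feature_kind == "gene":
        for g in bundle.annotation:
            if g.gene_id in bundle.gene_expr.columns:
                yield g.gene_id, bundle.gene_expr[g.gene_id].to_numpy(float), \
                    float(g.tss), g
    elif feature_kind == "exon":
        for g in bundle.annotation:
            for eid, mid in zip(g.exon_ids, g.exon_midpoints):
                if eid in bundle.exon_counts.columns:
                    yield eid, bundle.exon_counts[eid].to_numpy(float), \
                        float(mid), g
    else:
        raise ValueError(f"feature_kind must be 'gene' or 'exon', got {feature_kind!r}")


def _cis_sites(haps: PhasedHaplotypeSet, anchor: float, window_bp: float,
               maf_min: float) -> np.ndarray:
    near = np.abs(haps.positions - anchor) <= window_bp
    return np.flatnonzero(near & (haps.maf >= maf_min))


def map_cis(
    haps: PhasedHaplotypeSet,
    bundle: ExpressionBundle,
    window_bp: float = 1_000_000,
    maf_min: float = 0.05,
    feature_kind: str = "gene",
) -> EqtlResultSet:
    """Best Spearman association per feature over its cis window.

    Ties on p are broken by distance to the anchor (TSS or exon midpoint),
    then by position.  Features with no testable variant get a row with a
    missing ``best_site``.
    """
    rows = []
    dosage = haps.dosage
    for fid, y, anchor, gene in _feature_iter(bundle, feature_kind):
        sites = _cis_sites(haps, anchor, window_bp, maf_min)
        if len(sites) == 0 or np.ptp(y) == 0:
            rows.append((fid, feature_kind, np.nan, np.nan, np.nan, np.nan, 0))
            continue
        rho, p = _spearman_block(dosage[:, sites], y)
        ok = ~np.isnan(p)
        if not ok.any():
            rows.append((fid, feature_kind, np.nan, np.nan, np.nan, np.nan,
                         int(len(sites))))
            continue
        dist = np.abs(haps.positions[sites] - anchor)
        key = np.lexsort((haps.positions[sites], dist,
                          np.where(ok, p, np.inf)))
        b = key[0]
        rows.append((fid, feature_kind, int(sites[b]),
                     int(haps.positions[sites[b]]), float(rho[b]),
                     float(p[b]), int(ok.sum())))
    table = pd.DataFrame(
        rows, columns=["feature_id", "feature_kind", "best_site", "position",
                       "rho", "p_value", "n_tested"])
    table["perm_threshold"] = np.nan
    table["significant"] = False
    return EqtlResultSet(table=table)


def permutation_threshold(
    haps: PhasedHaplotypeSet,
    bundle: ExpressionBundle,
    feature_id: str,
    n_perm: int = 1000,
    level: float = 0.01,
    seed=None,
    window_bp: float = 1_000_000,
    maf_min: float = 0.05,
    feature_kind: str = "gene",
) -> float:
    """Empirical per-feature significance threshold: the ``level`` quantile
    of the null distribution of best cis p-values under phenotype
    permutation."""
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    for fid, y, anchor, gene in _feature_iter(bundle, feature_kind):
        if fid == feature_id:
            sites = _cis_sites(haps, anchor, window_bp, maf_min)
            if len(sites) == 0 or np.ptp(y) == 0:
                return np.nan
            minp = _perm_min_p(haps.dosage[:, sites], y, n_perm, rng)
            return float(np.quantile(minp, level))
    raise KeyError(feature_id)


def run_cis_eqtl(
    haps: PhasedHaplotypeSet,
    bundle: ExpressionBundle,
    window_bp: float = 1_000_000,
    maf_min: float = 0.05,
    feature_kind: str = "gene",
    n_perm: int = 1000,
    level: float = 0.01,
    seed=None,
) -> EqtlResultSet:
    """Map best cis associations and attach per-feature permutation
    thresholds; ``significant`` means observed best p <= threshold."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    res = map_cis(haps, bundle, window_bp, maf_min, feature_kind)
    thr = []
    dosage = haps.dosage
    for fid, y, anchor, gene in _feature_iter(bundle, feature_kind):
        sites = _cis_sites(haps, anchor, window_bp, maf_min)
        if len(sites) == 0 or np.ptp(y) == 0:
            thr.append(np.nan)
            continue
        minp = _perm_min_p(dosage[:, sites], y, n_perm, rng)
        thr.append(float(np.quantile(minp, level)))
    res.table["perm_threshold"] = thr
    res.table["significant"] = res.table["p_value"] <= res.table["perm_threshold"]
    res.level = level
    return res


def permute_bundle(bundle: ExpressionBundle, seed=None) -> ExpressionBundle:
    """One full permuted pass: shuffle individuals' expression labels
    (gene and exon matrices jointly), genotypes fixed."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    order = rng.permutation(len(bundle.gene_expr))
    ge = bundle.gene_expr.iloc[order].set_axis(bundle.gene_expr.index)
    ec = bundle.exon_counts.iloc[order].set_axis(bundle.exon_counts.index) \
        if not bundle.exon_counts.empty else bundle.exon_counts
    return ExpressionBundle(gene_expr=ge, exon_counts=ec,
                            annotation=bundle.annotation)


@dataclass
class FdrSummary:
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_frame(self) -> pd.DataFrame:
        return self.table


def estimate_fdr(
    observed_results: EqtlResultSet,
    permuted_results: list[EqtlResultSet],
    level_grid,
) -> FdrSummary:
    """Permutation-estimated FDR at each p-value level.

    FDR(level) = mean over permuted passes of the number of features with
    best p <= level, divided by the observed count (capped at 1).  Levels
    with zero observed significant features are flagged undefined.
    """
    if not permuted_results:
        raise ValueError("need at least one full permuted pass")
    obs_p = observed_results.table["p_value"].to_numpy(float)
    perm_p = [r.table["p_value"].to_numpy(float) for r in permuted_results]
    rows = []
    for level in level_grid:
        n_obs = int(np.nansum(obs_p <= level))
        mean_perm = float(np.mean([np.nansum(p <= level) for p in perm_p]))
        if n_obs == 0:
            rows.append((level, 0, mean_perm, np.nan, True))
        else:
            rows.append((level, n_obs, mean_perm,
                         min(mean_perm / n_obs, 1.0), False))
    return FdrSummary(table=pd.DataFrame(
        rows, columns=["level", "n_significant_observed",
                       "mean_n_significant_permuted", "fdr", "undefined"]))
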