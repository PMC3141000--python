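"""Synthetic cohorts with the statistical structure the analyses assume.

The generator emulates the data layout of a population cohort with phased
genome sequence and lymphoblastoid expression: phased haplotypes drawn from a
configurable site-frequency spectrum (including singletons), additive
cis-regulatory effects on gene expression, Poisson exon read counts with
optional allele-specific depletion of stop-gained haplotypes (an NMD-like
signal), and binomially sampled allelic read counts around a configurable
reference-mapping bias.  Sites are drawn independently (no background LD);
haplotype sharing is induced explicitly by copying a founder segment, which
gives the homozygosity and causal-variant analyses a controllable truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    AlleleCountTable,
    ExpressionBundle,
    GeneModel,
    PhasedHaplotypeSet,
)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class FrequencySpectrum:
    """Site-frequency spectrum: a singleton mass plus a grid of common
    alternate-allele frequencies with sampling probabilities.

    With probability ``singleton_proportion`` a site is a singleton (exactly
    one alternate haplotype in the cohort); otherwise its population
    frequency is drawn from ``(grid, probs)`` and the 2N haplotypes are
    i.i.d. Bernoulli draws at that frequency.
    """

    singleton_proportion: float = 0.0
    grid: np.ndarray = field(default_factory=lambda: np.arange(0.1, 0.91, 0.1))
    probs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.probs is None:
            self.probs = np.full(len(self.grid), 1.0 / len(self.grid))
        self.probs = np.asarray(self.probs, dtype=float)
        if not 0.0 <= self.singleton_proportion <= 1.0:
            raise ConfigError("singleton_proportion must be in [0, 1]")
        if len(self.probs) != len(self.grid):
            raise ConfigError("spectrum grid and probs differ in length")
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise ConfigError("spectrum probabilities must sum to 1")


@dataclass
class RegulatoryEffect:
    """Additive cis effect: expression += beta * alt-allele dosage."""

    gene_id: str
    site_index: int
    beta: float


@dataclass
class SimulationConfig:
    """Cohort-level defaults for the end-to-end synthetic pipeline.

    Defaults mirror the study conditions the analyses assume: 60 individuals
    (an RNA-sequenced European-sized panel), unit-variance expression noise,
    mean allelic read depth 50 and an unbiased reference-mapping rate of 0.5.
    """

    n_individuals: int = 60
    n_genes: int = 20
    n_sites_per_gene: int = 30
    span_bp: int = 2_000_000
    seed: int = 0
    singleton_proportion: float = 0.1
    effect_beta: float = 2.0
    effect_fraction: float = 0.5
    noise_sd: float = 1.0
    exon_base_depth: int = 100
    nmd_depletion: float = 0.0
    ase_depth: float = 50.0
    mapping_bias: float = 0.5
    n_outliers: int = 0
    outlier_z: float = 5.0

    def __post_init__(self) -> None:
        for name in ("singleton_proportion", "effect_fraction", "nmd_depletion"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.mapping_bias < 1.0:
            raise ConfigError("mapping_bias must lie strictly inside (0, 1)")
        if self.n_individuals < 2:
            raise ConfigError("need at least 2 individuals")


# ---------------------------------------------------------------------------
# haplotypes


def simulate_haplotypes(
    n_individuals: int,
    n_sites: int,
    seed=None,
    spectrum: FrequencySpectrum | None = None,
    span_bp: int = 1_000_000,
    start_pos: int = 1,
    chrom: str = "1",
    consequence: np.ndarray | None = None,
    positions: np.ndarray | None = None,
    ancestral_unknown: float = 0.0,
    ancestral_alt: float = 0.0,
    conserved_fraction: float = 0.0,
) -> PhasedHaplotypeSet:
    """Draw phased haplotypes site-wise from the configured spectrum.

    The alternate allele is treated as derived (``ancestral='ref'``) except
    for fractions relabelled as ``alt``-ancestral or ``unknown``, so the
    derived allele frequency of the output is known by construction.
    """
    if n_individuals < 2:
        raise ConfigError("need at least 2 individuals")
    rng = _rng(seed)
    spectrum = spectrum or FrequencySpectrum()
    n_hap = 2 * n_individuals

    if positions is None:
        positions = np.sort(
            rng.choice(np.arange(start_pos, start_pos + span_bp), size=n_sites,
                       replace=False)
        )
    positions = np.asarray(positions, dtype=np.int64)

    hap_flat = np.zeros((n_hap, n_sites), dtype=np.int8)
    is_singleton = rng.random(n_sites) < spectrum.singleton_proportion
    freqs = spectrum.grid[rng.choice(len(spectrum.grid), size=n_sites,
                                     p=spectrum.probs)]
    common = ~is_singleton
    hap_flat[:, common] = (
        rng.random((n_hap, int(common.sum()))) < freqs[common]
    ).astype(np.int8)
    for j in np.flatnonzero(is_singleton):
        hap_flat[rng.integers(n_hap), j] = 1

    anc = np.full(n_sites, "ref", dtype="U7")
    u = rng.random(n_sites)
    anc[u < ancestral_alt] = "alt"
    anc[(u >= ancestral_alt) & (u < ancestral_alt + ancestral_unknown)] = "unknown"

    cons_flag = rng.random(n_sites) < conserved_fraction
    haplotypes = hap_flat.reshape(n_individuals, 2, n_sites)
    return PhasedHaplotypeSet(
        sample_ids=[f"IND{i:03d}" for i in range(n_individuals)],
        chrom=chrom,
        positions=positions,
        alleles=[("A", "G")] * n_sites,
        haplotypes=haplotypes,
        ancestral=anc,
        consequence=consequence,
        conserved_flag=cons_flag,
    )


def plant_shared_segment(
    haps: PhasedHaplotypeSet,
    carriers: list[tuple[int, int]],
    site_lo: int,
    site_hi: int,
) -> PhasedHaplotypeSet:
    """Copy the first carrier's haplotype segment ``[site_lo, site_hi)`` onto
    the other carrier haplotypes, creating an identical-by-descent tract.

    ``carriers`` are (individual index, haplotype index 0/1) pairs.
    """
    out = np.array(haps.haplotypes, copy=True)
    founder_i, founder_h = carriers[0]
    seg = out[founder_i, founder_h, site_lo:site_hi]
    for i, h in carriers[1:]:
        out[i, h, site_lo:site_hi] = seg
    return PhasedHaplotypeSet(
        sample_ids=haps.sample_ids,
        chrom=haps.chrom,
        positions=haps.positions,
        alleles=haps.alleles,
        haplotypes=out,
        ancestral=haps.ancestral,
        consequence=haps.consequence,
        conserved_flag=haps.conserved_flag,
        conservation_score=haps.conservation_score,
    )


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    haps: PhasedHaplotypeSet,
    annotation: list[GeneModel],
    effects: list[RegulatoryEffect] | None = None,
    noise_sd: float = 1.0,
    seed=None,
    exon_base_depth: float = 100.0,
    nmd_depletion: float = 0.0,
) -> ExpressionBundle:
    """Additive expression with Gaussian noise plus Poisson exon counts.

    Gene value = sum(beta * alt dosage at the causal site) + N(0, noise_sd).
    Each exon's read count is Poisson with a per-haplotype mean of
    ``exon_base_depth / 2``; a haplotype carrying the alternate allele of a
    stop-gained site inside the gene contributes only a ``1 - nmd_depletion``
    fraction of its reads (the alternate allele is the premature stop).
    """
    effects = effects or []
    rng = _rng(seed)
    n = haps.n_samples
    expr = {}
    for g in annotation:
        y = rng.normal(0.0, noise_sd, size=n)
        for eff in effects:
            if eff.gene_id == g.gene_id:
                y = y + eff.beta * haps.dosage[:, eff.site_index]
        expr[g.gene_id] = y
    gene_expr = pd.DataFrame(expr, index=list(haps.sample_ids))

    exon_cols = {}
    pos = haps.positions
    for g in annotation:
        in_gene = np.zeros(haps.n_sites, dtype=bool)
        for s, e in g.exons:
            in_gene |= (pos >= s) & (pos <= e)
        stop_sites = np.flatnonzero(in_gene & (haps.consequence == "stop_gained"))
        # per-haplotype NMD factor
        factor = np.ones((n, 2))
        if len(stop_sites) and nmd_depletion > 0:
            carries = haps.haplotypes[:, :, stop_sites].max(axis=2) == 1
            factor[carries] = 1.0 - nmd_depletion
        lam = exon_base_depth / 2.0 * factor.sum(axis=1)
        for eid in g.exon_ids:
            exon_cols[eid] = rng.poisson(lam)
    exon_counts = pd.DataFrame(exon_cols, index=list(haps.sample_ids), dtype=np.int64)
    return ExpressionBundle(gene_expr=gene_expr, exon_counts=exon_counts,
                            annotation=annotation)


# ---------------------------------------------------------------------------
# allelic read counts


def ratio_to_ref_prob(ratio: float, bias: float) -> float:
    """Expected reference-read probability for a ref:alt expression ratio
    ``ratio`` on top of a mapping bias (the no-effect success probability)."""
    return bias * ratio / (bias * ratio + (1.0 - bias))


def nmd_imbalance_map(
    haps: PhasedHaplotypeSet, annotation: list[GeneModel], nmd_depletion: float
) -> dict[tuple[str, int], float]:
    """Ref:alt expression ratios implied by NMD at heterozygous stop-gained
    sites (the alternate allele carries the stop and is depleted)."""
    out = {}
    if nmd_depletion <= 0:
        return out
    pos = haps.positions
    in_exon = np.zeros(haps.n_sites, dtype=bool)
    for g in annotation:
        for s, e in g.exons:
            in_exon |= (pos >= s) & (pos <= e)
    stop_sites = np.flatnonzero(in_exon & (haps.consequence == "stop_gained"))
    ratio = 1.0 / (1.0 - nmd_depletion)
    for j in stop_sites:
        for i in np.flatnonzero(haps.is_het[:, j]):
            out[(haps.sample_ids[i], int(j))] = ratio
    return out


def simulate_allele_counts(
    haps: PhasedHaplotypeSet,
    depth: float,
    bias: float = 0.5,
    seed=None,
    site_indices: np.ndarray | None = None,
    imbalance: dict[tuple[str, int], float] | None = None,
) -> AlleleCountTable:
    """Binomial allelic read counts at heterozygous sites.

    For each heterozygous (individual, site) pair the total read count is
    Poisson(*depth*) and the reference count Binomial(total, p) with
    p = *bias* absent any planted effect; a planted ref:alt expression ratio
    for that pair (the ``imbalance`` map) shifts p through
    :func:`ratio_to_ref_prob`.  ``depth=0`` yields an empty table.
    """
    rng = _rng(seed)
    imbalance = imbalance or {}
    rows = []
    if depth > 0:
        if site_indices is None:
            site_indices = np.arange(haps.n_sites)
        het = haps.is_het
        for j in np.asarray(site_indices, dtype=int):
            for i in np.flatnonzero(het[:, j]):
                total = rng.poisson(depth)
                if total == 0:
                    continue
                sid = haps.sample_ids[i]
                ratio = imbalance.get((sid, int(j)), 1.0)
                p = ratio_to_ref_prob(ratio, bias)
                ref = rng.binomial(total, p)
                rows.append((sid, int(j), int(ref), int(total - ref), bias))
    return AlleleCountTable(
        pd.DataFrame(rows, columns=list(AlleleCountTable.COLUMNS))
    )


# ---------------------------------------------------------------------------
# expression outliers


def plant_outliers(
    bundle: ExpressionBundle,
    haps: PhasedHaplotypeSet,
    n_effects: int,
    z_offset: float,
    seed=None,
    window_bp: int = 100_000,
    conserved_only: bool = False,
) -> tuple[ExpressionBundle, pd.DataFrame]:
    """Shift singleton carriers' expression to create rare-variant outliers.

    For each planted effect, a singleton site within ``window_bp`` of a
    gene's TSS is chosen; its (single) carrier's expression for that gene is
    shifted by ``z_offset`` standard deviations of the gene's pre-shift
    expression.  Returns the modified bundle and a truth table of
    (gene_id, site_index, sample_id).  A ``z_offset`` of 0 leaves the bundle
    unchanged (the truth table still records the chosen sites).
    """
    rng = _rng(seed)
    singles = np.flatnonzero(haps.alt_count == 1)
    if conserved_only:
        singles = singles[haps.conserved_flag[singles]]
    pos = haps.positions
    candidates = []  # (gene_id, site) pairs
    for g in bundle.annotation:
        near = singles[np.abs(pos[singles] - g.tss) <= window_bp]
        candidates.extend((g.gene_id, int(j)) for j in near)
    if len(candidates) < n_effects:
        raise ConfigError(
            f"only {len(candidates)} singleton (gene, site) pairs within "
            f"{window_bp} bp of a TSS; cannot plant {n_effects} effects"
        )
    chosen = [candidates[k] for k in
              rng.choice(len(candidates), size=n_effects, replace=False)]
    expr = bundle.gene_expr.copy()
    truth = []
    for gene_id, j in chosen:
        hap_owner = int(np.flatnonzero(
            haps.haplotypes.reshape(-1, haps.n_sites)[:, j] == 1)[0]) // 2
        sid = haps.sample_ids[hap_owner]
        sd = expr[gene_id].std(ddof=1)
        expr.loc[sid, gene_id] = expr.loc[sid, gene_id] + z_offset * sd
        truth.append((gene_id, j, sid))
    truth = pd.DataFrame(truth, columns=["gene_id", "site_index", "sample_id"])
    return (
        ExpressionBundle(gene_expr=expr, exon_counts=bundle.exon_counts,
                         annotation=bundle.annotation),
        truth,
    )


# ---------------------------------------------------------------------------
# composed cohorts


def make_gene_models(
    n_genes: int, span_bp: int, seed=None, exons_per_gene: int = 1,
    exon_len: int = 200, strand_mix: bool = True
) -> list[GeneModel]:
    """Evenly spaced single- or multi-exon gene models over a span."""
    rng = _rng(seed)
    step = span_bp // max(n_genes, 1)
    genes = []
    for k in range(n_genes):
        left = 1 + k * step + step // 4
        exons = [
            (left + 2 * i * exon_len, left + (2 * i + 1) * exon_len - 1)
            for i in range(exons_per_gene)
        ]
        strand = "+" if (not strand_mix or rng.random() < 0.5) else "-"
        tss = exons[0][0] if strand == "+" else exons[-1][1]
        genes.append(GeneModel(gene_id=f"G{k:04d}", strand=strand, tss=tss,
                               exons=exons))
    return genes


def simulate_cohort(config: SimulationConfig) -> dict:
    """Full synthetic cohort: haplotypes, expression bundle, allelic counts
    and the planted-effect truth tables.  Deterministic given the seed."""
    rng = _rng(config.seed)
    n_sites = config.n_genes * config.n_sites_per_gene
    spectrum = FrequencySpectrum(singleton_proportion=config.singleton_proportion)
    consequence = np.array(
        ["nonsynonymous" if k % 5 == 0 else "other" for k in range(n_sites)]
    )
    haps = simulate_haplotypes(
        config.n_individuals, n_sites, seed=rng, spectrum=spectrum,
        span_bp=config.span_bp, consequence=consequence,
    )
    genes = make_gene_models(config.n_genes, config.span_bp,
                             seed=rng)
    pos = haps.positions
    effects = []
    for g in genes:
        if rng.random() >= config.effect_fraction:
            continue
        near = np.flatnonzero(np.abs(pos - g.tss) <= 1_000_000)
        near = near[haps.maf[near] >= 0.05]
        if len(near):
            effects.append(RegulatoryEffect(
                g.gene_id, int(near[rng.integers(len(near))]), config.effect_beta))
    bundle = simulate_expression(
        haps, genes, effects, noise_sd=config.noise_sd, seed=rng,
        exon_base_depth=config.exon_base_depth,
        nmd_depletion=config.nmd_depletion,
    )
    truth_outliers = pd.DataFrame(columns=["gene_id", "site_index", "sample_id"])
    if config.n_outliers:
        bundle, truth_outliers = plant_outliers(
            bundle, haps, config.n_outliers, config.outlier_z, seed=rng)
    coding = np.flatnonzero(haps.consequence != "other")
    imb = nmd_imbalance_map(haps, genes, config.nmd_depletion)
    counts = simulate_allele_counts(
        haps, depth=config.ase_depth, bias=config.mapping_bias, seed=rng,
        site_indices=coding, imbalance=imb,
    )
    return {
        "haps": haps,
        "bundle": bundle,
        "counts": counts,
        "effects": effects,
        "outlier_truth": truth_outliers,
    }


def simulate_prsnp_gene(
    seed=None,
    n_individuals: int = 60,
    n_background: int = 50,
    n_marker_het: int = 6,
    n_ase: int = 2,
    depth: float = 50.0,
    bias: float = 0.5,
    ase_ratio: float = 0.95,
    window_bp: int = 100_000,
) -> dict:
    """One synthetic gene for causal-regulatory-variant (prSNP) detection.

    Planted structure: a coding ASE marker heterozygous in ``n_marker_het``
    individuals; one causal regulatory variant heterozygous in exactly
    ``n_ase`` of them with its alternate allele phased onto the
    over-expressed haplotype (phase-concordant allelic imbalance of
    ``ase_ratio`` at the marker); ``n_background`` frequency-matched
    background variants (the same alternate-allele count as the causal,
    placed on random haplotypes) within ``window_bp`` of the TSS.
    """
    rng = _rng(seed)
    n_hap = 2 * n_individuals
    tss = window_bp + 50_000
    n_sites = 2 + n_background
    positions = np.sort(rng.choice(
        np.arange(tss - window_bp, tss + window_bp), size=n_sites, replace=False))
    # marker: the site closest to the TSS inside the (single) exon
    marker_j = int(np.argmin(np.abs(positions - tss)))
    others = [j for j in range(n_sites) if j != marker_j]
    causal_j = int(others[rng.integers(len(others))])

    hap = np.zeros((n_individuals, 2, n_sites), dtype=np.int8)
    het_inds = rng.choice(n_individuals, size=n_marker_het, replace=False)
    marker_hap = rng.integers(2, size=n_marker_het)
    hap[het_inds, marker_hap, marker_j] = 1

    ase_sel = rng.choice(n_marker_het, size=n_ase, replace=False)
    ase_inds = het_inds[ase_sel]
    # over-expressed haplotype per ASE individual; causal alt phased onto it
    high_hap = rng.integers(2, size=n_ase)
    hap[ase_inds, high_hap, causal_j] = 1

    causal_count = int(hap.reshape(n_hap, n_sites)[:, causal_j].sum())
    for j in others:
        if j == causal_j:
            continue
        spots = rng.choice(n_hap, size=causal_count, replace=False)
        hap.reshape(n_hap, n_sites)[spots, j] = 1

    consequence = np.full(n_sites, "other", dtype="U15")
    consequence[marker_j] = "nonsynonymous"
    haps = PhasedHaplotypeSet(
        sample_ids=[f"IND{i:03d}" for i in range(n_individuals)],
        chrom="1",
        positions=positions,
        alleles=[("A", "G")] * n_sites,
        haplotypes=hap,
        consequence=consequence,
    )
    exon = (int(positions[marker_j]) - 100, int(positions[marker_j]) + 100)
    gene = GeneModel(gene_id="G0000", strand="+", tss=exon[0], exons=[exon])

    # allelic counts at the marker: ASE carriers imbalanced toward the
    # haplotype carrying the causal allele, the rest at the mapping bias
    rows = []
    for k, i in enumerate(het_inds):
        total = rng.poisson(depth)
        if total == 0:
            continue
        if i in ase_inds:
            hh = high_hap[list(ase_inds).index(i)]
            ref_high = hap[i, hh, marker_j] == 0
            p = ase_ratio if ref_high else 1.0 - ase_ratio
            # fold the mapping bias into the shifted success probability
            r = p / (1.0 - p)
            p = ratio_to_ref_prob(r, bias)
        else:
            p = bias
        ref = rng.binomial(total, p)
        rows.append((haps.sample_ids[i], marker_j, int(ref), int(total - ref), bias))
    counts = AlleleCountTable(
        pd.DataFrame(rows, columns=list(AlleleCountTable.COLUMNS)))
    return {
        "haps": haps,
        "gene": gene,
        "counts": counts,
        "marker_site": marker_j,
        "causal_site": causal_j,
        "ase_samples": [haps.sample_ids[i] for i in ase_inds],
    }
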