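"""Functional enrichment of association signal via the 1 - pi0 statistic.

pi0, the estimated proportion of true null hypotheses in a set of p-values,
is computed with the Storey smoother: pi0(lambda) = #{p > lambda} /
(n (1 - lambda)) over a lambda grid, a cubic fit in lambda evaluated at the
grid maximum, clipped to [0, 1].  1 - pi0 for a functional variant class
(splice donor/acceptor, stop-gained) is compared against a matched
synonymous background as a log-ratio, within bins of exon read depth, and a
bin is reported only when it holds more than 30 associations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import GeneModel, PhasedHaplotypeSet

DEFAULT_LAMBDA_GRID = np.arange(0.05, 0.951, 0.05)
MIN_ASSOCIATIONS = 30


class SampleSizeError(ValueError):
    """Too few p-values for a stable pi0 estimate."""


def estimate_pi0(p_values, lambda_grid=None) -> float:
    """Storey pi0 with cubic smoothing in lambda.

    Parameters
    ----------
    p_values : array-like in [0, 1], length > 30
    lambda_grid : optional grid (default 0.05 .. 0.95 step 0.05)
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if len(p) < MIN_ASSOCIATIONS:
        raise SampleSizeError(
            f"need more than {MIN_ASSOCIATIONS} p-values, got {len(p)}")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    lam = np.asarray(lambda_grid if lambda_grid is not None
                     else DEFAULT_LAMBDA_GRID, dtype=float)
    pi0_lam = np.array([(p > l).mean() / (1.0 - l) for l in lam])
    coef = np.polyfit(lam, pi0_lam, 3)
    pi0 = float(np.polyval(coef, lam.max()))
    return float(np.clip(pi0, 0.0, 1.0))


# ---------------------------------------------------------------------------
# variant class assignment


@dataclass
class ClassAssignment:
    """Per-site functional class with the exon(s) its association targets."""

    table: pd.DataFrame  # site_index, variant_class, gene_id, target_exons

    def to_frame(self) -> pd.DataFrame:
        return self.table


def _flanking_exons(gene: GeneModel, position: int):
    """(upstream exon idx, downstream exon idx) around an intronic/nearby
    position, by genomic coordinate; None when off the end."""
    up = None
    down = None
    for k, (s, e) in enumerate(gene.exons):
        if e < position:
            up = k
        if s > position and down is None:
            down = k
        if s <= position <= e:
            return k, k
    return up, down


def class_assignment(
    haps: PhasedHaplotypeSet,
    annotation: list[GeneModel],
    essential_bp: int = 5,
    splice_bp: int = 100,
    background_min_bp: int = 15,
) -> ClassAssignment:
    """Resolve consequence labels against exon structure.

    Splice-labelled sites within ``essential_bp`` of an exon boundary become
    ``essential_splice`` and within ``splice_bp`` remain ``splice``; both are
    attached to their donor (5') and acceptor (3') exons, resolved by strand.
    Stop-gained / synonymous / nonsynonymous sites attach to the overlapping
    exon.  Synonymous sites within ``background_min_bp`` of a boundary are
    excluded from the matched background (class ``excluded``).  Splice labels
    with no exon within ``splice_bp`` are dropped with a warning.
    """
    import logging
    log = logging.getLogger("regland")
    rows = []
    for j in range(haps.n_sites):
        label = haps.consequence[j]
        if label == "other":
            continue
        pos = int(haps.positions[j])
        # nearest gene by boundary distance
        best_gene = None
        best_d = None
        for g in annotation:
            if not g.exons:
                continue
            d = g.boundary_distance(pos)
            if best_d is None or d < best_d:
                best_gene, best_d = g, d
        if best_gene is None:
            continue
        g = best_gene
        if label in ("splice", "essential_splice"):
            if best_d > splice_bp:
                log.warning("splice label at site %d with no exon within "
                            "%d bp; dropped", j, splice_bp)
                continue
            cls = "essential_splice" if best_d <= essential_bp else "splice"
            up, down = _flanking_exons(g, pos)
            flanks = [k for k in dict.fromkeys((up, down)) if k is not None]
            # donor exon is 5' of the intron, acceptor 3'; on the minus
            # strand the genomic order of the two is reversed
            if g.strand == "+":
                targets = [(g.exon_ids[k], "donor" if k == up else "acceptor")
                           for k in flanks]
            else:
                targets = [(g.exon_ids[k], "acceptor" if k == up else "donor")
                           for k in flanks]
            for eid, role in targets:
                rows.append((j, cls, g.gene_id, eid, role))
        else:
            overlapping = None
            for k, (s, e) in enumerate(g.exons):
                if s <= pos <= e:
                    overlapping = k
                    break
            if overlapping is None:
                continue
            if label == "synonymous" and best_d <= background_min_bp:
                rows.append((j, "excluded", g.gene_id,
                             g.exon_ids[overlapping], "overlap"))
                continue
            rows.append((j, label, g.gene_id, g.exon_ids[overlapping],
                         "overlap"))
    return ClassAssignment(table=pd.DataFrame(
        rows, columns=["site_index", "variant_class", "gene_id",
                       "target_exon", "exon_role"]))


def variant_exon_associations(
    haps: PhasedHaplotypeSet,
    bundle,
    assignment: ClassAssignment,
) -> pd.DataFrame:
    """Spearman association of each classified variant with its target
    exon's read counts, with the exon's mean read depth per individual.

    Returns a frame (site_index, variant_class, target_exon, p_value, rho,
    depth) ready for :func:`enrichment_curve` after grouping by class.
    """
    from .eqtl import spearman_assoc

    depth = bundle.exon_counts.mean(axis=0)
    dosage = haps.dosage
    rows = []
    for _, r in assignment.table.iterrows():
        eid = r["target_exon"]
        if eid not in bundle.exon_counts.columns:
            continue
        y = bundle.exon_counts[eid].to_numpy(float)
        rho, p = spearman_assoc(dosage[:, int(r["site_index"])], y)
        if np.isfinite(p):
            rows.append((int(r["site_index"]), r["variant_class"], eid,
                         p, rho, float(depth[eid])))
    return pd.DataFrame(rows, columns=["site_index", "variant_class",
                                       "target_exon", "p_value", "rho",
                                       "depth"])


# ---------------------------------------------------------------------------
# depth-binned enrichment curves


@dataclass
class EnrichmentCurve:
    variant_class: str
    table: pd.DataFrame  # depth_lo, depth_hi, n, pi0, one_minus_pi0, log_ratio

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out.insert(0, "variant_class", self.variant_class)
        return out


def enrichment_curve(
    assoc_by_class: dict[str, pd.DataFrame],
    bin_edges=None,
    background_class: str = "synonymous",
    min_bin: int = MIN_ASSOCIATIONS,
) -> list[EnrichmentCurve]:
    """Depth-binned 1 - pi0 per variant class, log-ratio'd to the background.

    ``assoc_by_class`` maps a class name to a frame with columns ``p_value``
    and ``depth`` (mean reads per exon per individual).  Bins default to 15
    log-spaced bins over 1-1000 reads.  A bin enters a curve only with more
    than ``min_bin`` associations in the class; the log-ratio additionally
    needs the background bin to qualify, else it is NaN with a flag.
    """
    if bin_edges is None:
        bin_edges = np.logspace(0, 3, 16)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if background_class not in assoc_by_class:
        raise KeyError(f"background class {background_class!r} missing")

    def binned(frame):
        out = {}
        depth = frame["depth"].to_numpy(float)
        for b in range(len(bin_edges) - 1):
            lo, hi = bin_edges[b], bin_edges[b + 1]
            m = (depth >= lo) & (depth < hi)
            if m.sum() > min_bin:
                out[b] = estimate_pi0(frame.loc[m, "p_value"])
            else:
                out[b] = None
        return out

    bg = binned(assoc_by_class[background_class])
    curves = []
    for cls, frame in assoc_by_class.items():
        own = binned(frame)
        rows = []
        for b in range(len(bin_edges) - 1):
            lo, hi = bin_edges[b], bin_edges[b + 1]
            if own[b] is None:
                continue
            pi0 = own[b]
            one_minus = 1.0 - pi0
            if bg[b] is None:
                ratio, flagged = np.nan, True
            else:
                bg1m = 1.0 - bg[b]
                if one_minus > 0 and bg1m > 0:
                    ratio, flagged = float(np.log(one_minus / bg1m)), False
                else:
                    ratio, flagged = np.nan, True
            n = int(((frame["depth"] >= lo) & (frame["depth"] < hi)).sum())
            rows.append((lo, hi, n, pi0, one_minus, ratio, flagged))
        curves.append(EnrichmentCurve(
            variant_class=cls,
            table=pd.DataFrame(rows, columns=[
                "depth_lo", "depth_hi", "n_associations", "pi0",
                "one_minus_pi0", "log_ratio", "ratio_undefined"])))
    return curves
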