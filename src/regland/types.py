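"""Shared domain containers for phased genotype + expression analyses.

All genomic coordinates are 1-based inclusive (VCF convention) and stored on
the forward strand; conversion to BED's 0-based half-open system happens only
at the I/O boundary (:mod:`regland.io`).  A :class:`PhasedHaplotypeSet` holds
a single chromosome, since every analysis in this package is *cis* (windows
of at most 1 Mb around a gene).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Recognised functional consequence labels for a variant site.
CONSEQUENCES = (
    "synonymous",
    "nonsynonymous",
    "stop_gained",
    "essential_splice",
    "splice",
    "other",
)

#: Ancestral-state labels: which of the two alleles is ancestral.
ANCESTRAL_STATES = ("ref", "alt", "unknown")


class FormatError(ValueError):
    """Malformed input data (bad coordinates, non-integer counts, ...)."""


class PhasingError(FormatError):
    """Unphased genotypes encountered where phase is required."""


class DataConsistencyError(ValueError):
    """Cross-container inconsistency (e.g. allelic counts at a hom site)."""


@dataclass
class PhasedHaplotypeSet:
    """Phased biallelic genotypes for one chromosome.

    Attributes
    ----------
    sample_ids : list of str
        Cohort individuals, in matrix row order.
    chrom : str
        Chromosome name.
    positions : ndarray of int, shape (n_sites,)
        1-based physical coordinates, strictly increasing.
    alleles : list of (ref, alt) tuples
        Allele strings per site.
    haplotypes : ndarray of int8, shape (n_samples, 2, n_sites)
        0 = reference allele, 1 = alternate allele.  Axis 1 indexes the two
        phased haplotypes of an individual.
    ancestral : ndarray of str, shape (n_sites,)
        One of ``{"ref", "alt", "unknown"}``; the derived allele frequency is
        defined only where this is not ``"unknown"``.
    consequence : ndarray of str, shape (n_sites,)
        Functional class per site (see :data:`CONSEQUENCES`).
    conserved_flag : ndarray of bool, shape (n_sites,)
        Membership in a conserved-element track.
    conservation_score : ndarray of float, shape (n_sites,)
        Base-wise conservation score; NaN when missing.
    """

    sample_ids: list[str]
    chrom: str
    positions: np.ndarray
    alleles: list[tuple[str, str]]
    haplotypes: np.ndarray
    ancestral: np.ndarray = None
    consequence: np.ndarray = None
    conserved_flag: np.ndarray = None
    conservation_score: np.ndarray = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        n = self.n_sites
        if self.ancestral is None:
            self.ancestral = np.full(n, "unknown", dtype="U7")
        else:
            self.ancestral = np.asarray(self.ancestral, dtype="U7")
        if self.consequence is None:
            self.consequence = np.full(n, "other", dtype="U15")
        else:
            self.consequence = np.asarray(self.consequence, dtype="U15")
        if self.conserved_flag is None:
            self.conserved_flag = np.zeros(n, dtype=bool)
        else:
            self.conserved_flag = np.asarray(self.conserved_flag, dtype=bool)
        if self.conservation_score is None:
            self.conservation_score = np.full(n, np.nan)
        else:
            self.conservation_score = np.asarray(self.conservation_score, dtype=float)
        self.validate()

    # -- basic shape ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[2]

    # -- derived quantities ----------------------------------------------
    @property
    def dosage(self) -> np.ndarray:
        """Alt-allele count per individual, shape (n_samples, n_sites)."""
        return self.haplotypes.sum(axis=1)

    @property
    def alt_freq(self) -> np.ndarray:
        """Alternate allele frequency over the 2N haplotypes."""
        return self.haplotypes.reshape(-1, self.n_sites).mean(axis=0)

    @property
    def alt_count(self) -> np.ndarray:
        """Number of alternate alleles over the 2N haplotypes."""
        return self.haplotypes.reshape(-1, self.n_sites).sum(axis=0).astype(np.int64)

    @property
    def maf(self) -> np.ndarray:
        f = self.alt_freq
        return np.minimum(f, 1.0 - f)

    @property
    def daf(self) -> np.ndarray:
        """Derived allele frequency (NaN where the ancestral state is unknown)."""
        f = self.alt_freq
        out = np.full(self.n_sites, np.nan)
        out[self.ancestral == "ref"] = f[self.ancestral == "ref"]
        out[self.ancestral == "alt"] = 1.0 - f[self.ancestral == "alt"]
        return out

    @property
    def is_het(self) -> np.ndarray:
        """Boolean (n_samples, n_sites): individual heterozygous at site."""
        return self.haplotypes[:, 0, :] != self.haplotypes[:, 1, :]

    def sample_index(self, sample_id: str) -> int:
        return self._sample_lookup()[sample_id]

    def sample_indices(self, sample_ids) -> np.ndarray:
        lut = self._sample_lookup()
        return np.array([lut[s] for s in sample_ids], dtype=int)

    def _sample_lookup(self) -> dict:
        lut = getattr(self, "_lut", None)
        if lut is None or len(lut) != len(self.sample_ids):
            lut = {s: i for i, s in enumerate(self.sample_ids)}
            object.__setattr__(self, "_lut", lut)
        return lut

    def validate(self) -> None:
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[1] != 2:
            raise FormatError("haplotypes must have shape (n_samples, 2, n_sites)")
        if len(self.sample_ids) != self.n_samples:
            raise FormatError("sample_ids length does not match haplotype matrix")
        if len(self.positions) != self.n_sites or len(self.alleles) != self.n_sites:
            raise FormatError("site metadata length does not match haplotype matrix")
        if self.n_sites and np.any(np.diff(self.positions) <= 0):
            raise FormatError("positions must be strictly increasing (one chromosome)")
        if self.n_sites and not np.isin(self.haplotypes, (0, 1)).all():
            raise FormatError("haplotype entries must be 0 (ref) or 1 (alt)")
        bad = ~np.isin(self.ancestral, ANCESTRAL_STATES)
        if bad.any():
            raise FormatError(f"unknown ancestral labels: {set(self.ancestral[bad])}")
        bad = ~np.isin(self.consequence, CONSEQUENCES)
        if bad.any():
            raise FormatError(f"unknown consequence labels: {set(self.consequence[bad])}")

    def __eq__(self, other) -> bool:
        if not isinstance(other, PhasedHaplotypeSet):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.chrom == other.chrom
            and np.array_equal(self.positions, other.positions)
            and list(self.alleles) == list(other.alleles)
            and np.array_equal(self.haplotypes, other.haplotypes)
            and np.array_equal(self.ancestral, other.ancestral)
            and np.array_equal(self.consequence, other.consequence)
            and np.array_equal(self.conserved_flag, other.conserved_flag)
            and np.array_equal(
                np.nan_to_num(self.conservation_score, nan=-9e9),
                np.nan_to_num(other.conservation_score, nan=-9e9),
            )
        )


@dataclass
class GeneModel:
    """Gene annotation: strand, transcription start site and exon intervals.

    Exons are 1-based inclusive ``(start, end)`` intervals, sorted and
    non-overlapping.  The TSS is the leftmost coordinate on the + strand and
    the rightmost on the − strand.
    """

    gene_id: str
    strand: str
    tss: int
    exons: list[tuple[int, int]]
    exon_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exon_ids:
            self.exon_ids = [f"{self.gene_id}:e{i}" for i in range(len(self.exons))]
        self.validate()

    def validate(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"strand must be '+' or '-', got {self.strand!r}")
        prev_end = -1
        for s, e in self.exons:
            if e < s:
                raise FormatError(f"exon interval end<start: ({s}, {e})")
            if s <= prev_end:
                raise FormatError("exons must be sorted and non-overlapping")
            prev_end = e
        if len(self.exon_ids) != len(self.exons):
            raise FormatError("exon_ids length does not match exons")
        if self.exons:
            anchor = self.exons[0][0] if self.strand == "+" else self.exons[-1][1]
            if self.tss != anchor:
                raise FormatError(
                    f"tss {self.tss} does not match {self.strand}-strand "
                    f"terminal exon coordinate {anchor}"
                )

    @property
    def exon_midpoints(self) -> np.ndarray:
        return np.array([(s + e) / 2.0 for s, e in self.exons])

    def boundary_distance(self, position: int) -> int:
        """bp distance from a position to the nearest exon boundary."""
        bounds = np.array([c for s, e in self.exons for c in (s, e)])
        return int(np.abs(bounds - position).min())


@dataclass
class ExpressionBundle:
    """Gene-level continuous expression plus exon-level integer read counts.

    ``gene_expr`` is individuals × genes (already normalised), ``exon_counts``
    individuals × exons with columns matching the concatenated ``exon_ids``
    of the annotation.
    """

    gene_expr: pd.DataFrame
    exon_counts: pd.DataFrame
    annotation: list[GeneModel]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.exon_counts.empty:
            vals = self.exon_counts.to_numpy()
            if not np.issubdtype(vals.dtype, np.integer):
                if not np.all(np.mod(vals, 1) == 0):
                    raise FormatError("exon counts must be integers")
                self.exon_counts = self.exon_counts.astype(np.int64)
            if (self.exon_counts.to_numpy() < 0).any():
                raise FormatError("exon counts must be non-negative")
            known = {eid for g in self.annotation for eid in g.exon_ids}
            unknown = [c for c in self.exon_counts.columns if c not in known]
            if unknown:
                raise FormatError(f"exon count columns not in annotation: {unknown[:5]}")
        if not self.gene_expr.index.equals(self.exon_counts.index) and not (
            self.exon_counts.empty or self.gene_expr.empty
        ):
            raise FormatError("gene_expr and exon_counts sample ordering differ")

    @property
    def sample_ids(self) -> list[str]:
        idx = self.gene_expr.index if not self.gene_expr.empty else self.exon_counts.index
        return list(idx)

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.annotation:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass
class AlleleCountTable:
    """Reference/alternate read counts at heterozygous coding sites.

    One row per (individual, site): ``sample_id``, ``site_index`` (index into
    the paired :class:`PhasedHaplotypeSet`), ``ref_count``, ``alt_count`` and
    the lane's reference-allele ``mapping_bias`` (the binomial null success
    probability, strictly inside (0, 1)).
    """

    table: pd.DataFrame

    COLUMNS = ("sample_id", "site_index", "ref_count", "alt_count", "mapping_bias")

    def __post_init__(self) -> None:
        self.table = pd.DataFrame(self.table, columns=list(self.COLUMNS))
        self.validate()

    def validate(self, haps: PhasedHaplotypeSet | None = None) -> None:
        t = self.table
        if len(t):
            for col in ("ref_count", "alt_count"):
                vals = t[col].to_numpy()
                if not np.all(np.mod(vals, 1) == 0):
                    raise FormatError(f"{col} must be integer read counts")
                if (vals < 0).any():
                    raise FormatError(f"{col} must be non-negative")
            bias = t["mapping_bias"].to_numpy(dtype=float)
            if ((bias <= 0) | (bias >= 1)).any():
                raise ValueError("mapping_bias must lie strictly inside (0, 1)")
        if haps is not None and len(t):
            het = haps.is_het
            rows = haps.sample_indices(t["sample_id"])
            cols = t["site_index"].to_numpy(dtype=int)
            if not het[rows, cols].all():
                bad = t.loc[~het[rows, cols]]
                raise DataConsistencyError(
                    f"allelic counts at non-heterozygous sites: "
                    f"{bad[['sample_id', 'site_index']].to_dict('records')[:3]}"
                )

    def __len__(self) -> int:
        return len(self.table)
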