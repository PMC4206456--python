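"""Core domain containers shared across the pipeline.

All genomic coordinates are 1-based inclusive (HapMap/NCBI convention);
the BED writer in :mod:`haplosweep.io_formats` converts on output.  Allele
matrices are ``int8`` with 0/1 for the two alleles of a biallelic SNP and
-1 for a missing call.  Rows are chromosomes (two per diploid individual),
columns are SNPs in genomic order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Sentinel for a missing allele call in a panel matrix.
MISSING: int = -1

BASES = frozenset("ACGT")


class HaplosweepError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(HaplosweepError):
    """A file could not be parsed; the message names the offending line."""


class ConfigurationError(HaplosweepError):
    """Inconsistent or incomplete configuration of an analysis step."""


class DomainError(HaplosweepError):
    """An input value is outside its mathematical domain."""


@dataclass(frozen=True)
class SnpMeta:
    """Metadata for one biallelic SNP.

    ``allele0``/``allele1`` are the bases encoded as 0 and 1 in panel
    matrices; ``cm_position`` is the genetic-map position used to measure
    haplotype lengths.
    """

    rsid: str
    chromosome: str
    position_bp: int
    allele0: str
    allele1: str
    cm_position: float = 0.0

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise DomainError(f"{self.rsid}: position_bp must be >= 1")
        if self.allele0 not in BASES or self.allele1 not in BASES:
            raise DomainError(f"{self.rsid}: alleles must be A/C/G/T")
        if self.allele0 == self.allele1:
            raise DomainError(f"{self.rsid}: alleles must be distinct")
        if self.cm_position < 0:
            raise DomainError(f"{self.rsid}: cm_position must be >= 0")

    def base_to_code(self, base: str) -> int:
        if base == self.allele0:
            return 0
        if base == self.allele1:
            return 1
        raise DomainError(
            f"{self.rsid}: base {base!r} is neither allele "
            f"({self.allele0}/{self.allele1})"
        )

    def code_to_base(self, code: int) -> str:
        if code == 0:
            return self.allele0
        if code == 1:
            return self.allele1
        raise DomainError(f"{self.rsid}: invalid allele code {code}")


@dataclass
class GeneticMap:
    """Piecewise-linear bp -> cM map for one chromosome.

    Queries outside the anchor range clamp to the terminal anchor's cM
    (constant extrapolation), which keeps genetic lengths finite and
    non-negative at chromosome ends.
    """

    chromosome: str
    anchors: Sequence[tuple[int, float]]

    def __post_init__(self) -> None:
        if len(self.anchors) < 2:
            raise ConfigurationError(
                f"genetic map for {self.chromosome} needs >= 2 anchors"
            )
        pos = np.asarray([a[0] for a in self.anchors], dtype=float)
        cm = np.asarray([a[1] for a in self.anchors], dtype=float)
        if np.any(np.diff(pos) <= 0):
            raise ConfigurationError("map anchors must be sorted by position")
        if np.any(np.diff(cm) < 0):
            raise ConfigurationError("map cM values must be non-decreasing")
        self._pos = pos
        self._cm = cm

    def interpolate(self, position_bp) -> float | np.ndarray:
        """Linear interpolation; clamps outside the anchor range."""
        out = np.interp(position_bp, self._pos, self._cm)
        return float(out) if np.isscalar(position_bp) else out


@dataclass
class HaplotypePanel:
    """Phased haplotype matrix for one population.

    ``alleles`` has one row per chromosome (2N for N diploids) and one
    column per SNP, values in {0, 1, -1(missing)}.
    """

    population: str
    snps: list[SnpMeta]
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise DomainError("panel allele matrix must be 2-D")
        if self.alleles.shape[1] != len(self.snps):
            raise DomainError("panel column count must match SNP count")
        if self.alleles.shape[0] % 2 != 0:
            raise DomainError("panel row count must be even (2 per diploid)")
        if self.alleles.shape[1] == 0:
            raise DomainError("empty panel: no SNPs")
        if np.any((self.alleles == MISSING).all(axis=0)):
            raise DomainError("panel has a fully missing SNP column")
        pos = [s.position_bp for s in self.snps]
        chroms = [s.chromosome for s in self.snps]
        for c in set(chroms):
            p = [x for x, cc in zip(pos, chroms) if cc == c]
            if any(b <= a for a, b in zip(p, p[1:])):
                raise DomainError(
                    f"SNP positions not strictly increasing on {c}"
                )

    @property
    def n_chromosomes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]

    def snp_index(self, rsid: str) -> int:
        for i, s in enumerate(self.snps):
            if s.rsid == rsid:
                return i
        raise KeyError(rsid)

    def allele_code_frequency(self, snp_index: int, code: int) -> float:
        """Frequency of an allele code among non-missing chromosomes."""
        col = self.alleles[:, snp_index]
        n = int((col != MISSING).sum())
        if n == 0:
            raise DomainError("SNP column entirely missing")
        return float((col == code).sum()) / n

    def allele_frequency(self, snp_index: int, base: str) -> float:
        """Frequency of a base among non-missing chromosomes.

        Raises :class:`DomainError` if the base matches neither allele of
        the SNP.
        """
        code = self.snps[snp_index].base_to_code(base)
        return self.allele_code_frequency(snp_index, code)


@dataclass(frozen=True)
class HaplotypeForm:
    """An allele-specified haplotype: ordered (snp_index, allele) pairs.

    ``sites`` indices refer to columns of the panel the form was derived
    from; the span endpoints are the basepair positions of the first and
    last site, and ``genetic_length_cm`` their cM separation.
    """

    chromosome: str
    sites: tuple[tuple[int, int], ...]
    span_start_bp: int
    span_end_bp: int
    genetic_length_cm: float
    snp_count: int
    carrier_frequency: float

    def __post_init__(self) -> None:
        if self.snp_count != len(self.sites) or self.snp_count < 1:
            raise DomainError("snp_count must equal the number of sites (>=1)")
        idx = [i for i, _ in self.sites]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise DomainError("form sites must be strictly increasing")
        if not (0.0 < self.carrier_frequency <= 1.0):
            raise DomainError("carrier_frequency must be in (0, 1]")
        if self.genetic_length_cm < 0:
            raise DomainError("genetic_length_cm must be >= 0")

    @property
    def site_indices(self) -> tuple[int, ...]:
        return tuple(i for i, _ in self.sites)

    def allele_at(self, snp_index: int) -> Optional[int]:
        for i, a in self.sites:
            if i == snp_index:
                return a
        return None

    @staticmethod
    def from_sites(
        snps: Sequence[SnpMeta],
        sites: Sequence[tuple[int, int]],
        carrier_frequency: float,
    ) -> "HaplotypeForm":
        """Build a form from site pairs, filling span and genetic length
        from SNP metadata."""
        sites = tuple(sorted(sites))
        first, last = snps[sites[0][0]], snps[sites[-1][0]]
        return HaplotypeForm(
            chromosome=first.chromosome,
            sites=sites,
            span_start_bp=first.position_bp,
            span_end_bp=last.position_bp,
            genetic_length_cm=last.cm_position - first.cm_position,
            snp_count=len(sites),
            carrier_frequency=carrier_frequency,
        )


#: Threshold below which a haploPS score flags positive selection (strict).
SCORE_THRESHOLD: float = 0.05


@dataclass
class SelectionSignal:
    """One putatively selected region in one population.

    ``p_cm`` and ``p_snp`` are genome-wide empirical rank p-values of the
    form's genetic length and SNP count among the ``n_f`` candidate forms
    at the same frequency bin; ``score = p_cm * p_snp * n_f``.  Fixture
    records loaded from published tables carry a score but no p-values
    (``p_cm``/``p_snp`` are ``None`` there).
    """

    population: str
    chromosome: str
    start_bp: int
    end_bp: int
    form: Optional[HaplotypeForm]
    frequency_bin: float
    n_f: int
    score: float
    p_cm: Optional[float] = None
    p_snp: Optional[float] = None
    significant: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.p_cm is not None and not (0.0 < self.p_cm <= 1.0):
            raise DomainError("p_cm must be in (0, 1]")
        if self.p_snp is not None and not (0.0 < self.p_snp <= 1.0):
            raise DomainError("p_snp must be in (0, 1]")
        if self.n_f < 1:
            raise DomainError("n_f must be >= 1")
        if self.form is not None:
            if (self.start_bp, self.end_bp) != (
                self.form.span_start_bp,
                self.form.span_end_bp,
            ):
                raise DomainError("signal region must equal the form span")
        self.significant = self.score < SCORE_THRESHOLD

    def overlaps(self, other: "SelectionSignal") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start_bp <= other.end_bp
            and other.start_bp <= self.end_bp
        )

    def contains(self, chromosome: str, position_bp: int) -> bool:
        return (
            self.chromosome == chromosome
            and self.start_bp <= position_bp <= self.end_bp
        )


@dataclass(frozen=True)
class GwasFixtureRow:
    """One GWAS-catalogue index SNP with its report annotations.

    Association statistics (p-value, odds ratio) are consumed as
    annotations; nothing here recomputes them.
    """

    rsid: str
    chromosome: str
    position_bp: int
    no_risk_allele: str
    risk_allele: str
    risk_allele_frequency: Optional[float]
    nearest_genes: tuple[str, ...]
    p_value: float
    odds_ratio: float
    trait: str
    reported_east_asian: bool
    reported_european: bool
    ancestral_allele: Optional[str] = None

    def __post_init__(self) -> None:
        if self.risk_allele == self.no_risk_allele:
            raise DomainError(f"{self.rsid}: risk and no-risk alleles equal")
        for b in (self.risk_allele, self.no_risk_allele):
            if b not in BASES:
                raise DomainError(f"{self.rsid}: invalid base {b!r}")
        if self.ancestral_allele is not None and self.ancestral_allele not in (
            self.risk_allele,
            self.no_risk_allele,
        ):
            raise DomainError(
                f"{self.rsid}: ancestral allele matches neither catalogued allele"
            )
        if self.p_value <= 0:
            raise DomainError(f"{self.rsid}: p-value must be positive")
        if self.odds_ratio <= 0:
            raise DomainError(f"{self.rsid}: odds ratio must be positive")


@dataclass(frozen=True)
class RegionRecord:
    """One published long-haplotype region row (selection evidence for one
    index SNP in one population)."""

    chromosome: str
    start_bp: int
    end_bp: int
    haplops_score: float
    population: str
    snp_position_bp: int
    rsid: str
    risk_allele: str
    risk_allele_is_ancestral: bool
    haplotype_frequency: float
    allele_frequency: float
    found_on_haplotype: bool
    nearest_genes: tuple[str, ...]


@dataclass(frozen=True)
class OutgroupAllele:
    """Ancestral base at a SNP inferred from an outgroup genome."""

    rsid: str
    base: Optional[str] = None

    def __post_init__(self) -> None:
        if self.base is not None and self.base not in BASES:
            raise DomainError(f"{self.rsid}: outgroup base must be A/C/G/T")


@dataclass
class HsiResult:
    """Haplotype similarity index between two selected forms."""

    value: float
    shared_snp_count: int
    classification: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0):
            raise DomainError("HSI value must be in [0, 1]")
        if self.classification not in {
            "shared_event",
            "convergent",
            "indeterminate",
            "no_overlap",
        }:
            raise DomainError(f"bad classification {self.classification!r}")


@dataclass
class FstResult:
    """Locus-specific fixation index for one SNP and one population pair."""

    rsid: str
    population_a: str
    population_b: str
    value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0):
            raise DomainError("F_ST must be in [0, 1]")


@dataclass
class EvaluationVerdict:
    """Outcome of the four-step evaluation for one index SNP.

    ``supports_thrifty`` is true only when the SNP lies in an
    East-Asian-specific selection region, the risk allele sits on the
    selected haplotype form, and the risk allele is the derived state.
    """

    rsid: str
    trait: str
    populations_with_signal: tuple[str, ...]
    overlaps_selection: bool
    east_asian_specific_association: bool
    east_asian_specific_selection: bool
    risk_on_haplotype: object  # True / False / "indeterminate"
    risk_is_derived: str  # "derived" / "ancestral" / "unknown"
    fst_values: list[FstResult]
    supports_thrifty: bool
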