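"""Synthetic multi-population phased panels with implanted hard sweeps.

The generator produces every input the pipeline consumes, with the
statistical structure the scan assumes:

* founder haplotypes drawn per-SNP from a bounded frequency spectrum,
  with per-population frequencies perturbed by a Balding–Nichols draw at
  a chosen divergence parameter;
* sampled chromosomes built as Li–Stephens-style mosaics of the founders,
  with switch points at a per-basepair rate, giving linkage
  disequilibrium that decays with distance;
* hard sweeps implanted post hoc: a single donor haplotype over a region
  is copied onto a chosen fraction of chromosomes (one donor shared
  across populations for a common origin, or an independent donor per
  population for convergent sweeps), optionally carrying a linked risk
  allele on or off the swept haplotype;
* a GWAS-catalogue-style table and an outgroup (ancestral allele) table
  matching the implanted truth.

Sweeps are implanted rather than forward-simulated under a selection
coefficient: this gives exact control of the two quantities the scan
estimates — carrier frequency and haplotype form — and an exact truth
record.  Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .types import (
    BASES,
    ConfigurationError,
    DomainError,
    GeneticMap,
    GwasFixtureRow,
    HaplotypeForm,
    HaplotypePanel,
    OutgroupAllele,
    SelectionSignal,
    SnpMeta,
)


@dataclass(frozen=True)
class RiskSnpSpec:
    """A GWAS-style risk SNP linked to an implanted sweep."""

    position_bp: int
    risk_base: str
    ancestral_base: str
    on_haplotype: bool
    p_value: float = 1e-9
    odds_ratio: float = 1.2
    trait: str = "T2D"
    reported_east_asian: bool = True
    reported_european: bool = False
    #: risk-base frequency among non-carrier chromosomes when the risk
    #: allele is placed off the swept haplotype
    background_risk_frequency: float = 0.5


@dataclass(frozen=True)
class SweepSpec:
    """One implanted hard sweep."""

    start_bp: int
    end_bp: int
    carrier_frequency: float
    populations: tuple[str, ...]
    shared_origin: bool = True
    linked_risk_snp: Optional[RiskSnpSpec] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.carrier_frequency <= 1.0):
            raise DomainError("carrier_frequency must be in (0, 1]")
        if self.end_bp <= self.start_bp:
            raise DomainError("sweep region must have positive length")


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults describe a desk-scale testbed: two populations of 100
    diploids (200 chromosomes), 400 SNPs at random positions over a 40 Mb
    chromosome with a uniform 1 cM/Mb map, 16 founder haplotypes, mosaic
    switch rate 3e-6 per bp (mean copied segment ~330 kb, a few marker
    intervals at the default density), allele frequencies bounded away
    from fixation by a 0.05 floor, and moderate population divergence
    (0.05).  The chromosome is deliberately much longer than any single
    sweep region so that the genome-wide candidate universe at each
    frequency bin is dominated by neutral forms.
    """

    seed: int = 0
    n_populations: int = 2
    population_labels: Optional[tuple[str, ...]] = None
    n_diploids: int = 100
    n_snps: int = 400
    chromosome: str = "1"
    chromosome_length_bp: int = 40_000_000
    recombination_rate_cm_per_mb: float = 1.0
    founder_haplotype_count: int = 16
    mosaic_switch_rate: float = 3e-6
    maf_floor: float = 0.05
    divergence: float = 0.05
    sweep_specs: tuple[SweepSpec, ...] = ()

    def __post_init__(self) -> None:
        for name in (
            "n_populations",
            "n_diploids",
            "n_snps",
            "chromosome_length_bp",
            "founder_haplotype_count",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not (0.0 < self.maf_floor < 0.5):
            raise ConfigurationError("maf_floor must be in (0, 0.5)")
        if not (0.0 <= self.divergence < 1.0):
            raise ConfigurationError("divergence must be in [0, 1)")
        if self.population_labels is None:
            self.population_labels = tuple(
                f"POP{i + 1}" for i in range(self.n_populations)
            )
        if len(self.population_labels) != self.n_populations:
            raise ConfigurationError("one label per population required")
        n_chrom = 2 * self.n_diploids
        for spec in self.sweep_specs:
            if spec.end_bp > self.chromosome_length_bp or spec.start_bp < 1:
                raise ConfigurationError("sweep region outside chromosome")
            if int(round(spec.carrier_frequency * n_chrom)) < 1:
                raise ConfigurationError(
                    "sweep carrier count rounds to zero chromosomes"
                )
            for pop in spec.populations:
                if pop not in self.population_labels:
                    raise ConfigurationError(
                        f"sweep names unknown population {pop!r}"
                    )


@dataclass
class SweepTruth:
    """Exact record of one implanted sweep."""

    spec: SweepSpec
    donor_forms: dict[str, HaplotypeForm]
    carrier_rows: dict[str, np.ndarray]
    risk_snp_index: Optional[int] = None
    risk_rsid: Optional[str] = None


@dataclass
class SimBundle:
    """A simulated dataset plus its truth record."""

    config: SimConfig
    panels: dict[str, HaplotypePanel]
    genetic_map: GeneticMap
    sweeps: list[SweepTruth] = field(default_factory=list)


_BASE_LIST = sorted(BASES)


def _draw_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    pos = np.unique(rng.integers(1, length + 1, size=4 * n))
    while pos.size < n:  # pragma: no cover - vanishingly unlikely
        pos = np.unique(
            np.concatenate([pos, rng.integers(1, length + 1, size=4 * n)])
        )
    return np.sort(rng.choice(pos, size=n, replace=False))


def _balding_nichols(
    rng: np.random.Generator, p_anc: np.ndarray, divergence: float
) -> np.ndarray:
    if divergence == 0.0:
        return p_anc.copy()
    scale = (1.0 - divergence) / divergence
    return rng.beta(p_anc * scale, (1.0 - p_anc) * scale)


def simulate_neutral_panels(config: SimConfig) -> SimBundle:
    """Neutral multi-population panels, genetic map, and truth record.

    Sweep specs in the config are ignored here; apply them with
    :func:`implant_sweep` or use :func:`simulate` for the full bundle.
    Identical configs produce byte-identical panels.
    """
    rng = np.random.default_rng(config.seed)
    L = config.chromosome_length_bp
    positions = _draw_positions(rng, config.n_snps, L)
    cm_per_bp = config.recombination_rate_cm_per_mb / 1e6
    gmap = GeneticMap(
        config.chromosome, [(1, 0.0), (L, (L - 1) * cm_per_bp)]
    )
    base_pairs = [
        tuple(rng.choice(_BASE_LIST, size=2, replace=False))
        for _ in range(config.n_snps)
    ]
    snps = [
        SnpMeta(
            rsid=f"rs{i + 1:06d}",
            chromosome=config.chromosome,
            position_bp=int(p),
            allele0=b0,
            allele1=b1,
            cm_position=float((p - 1) * cm_per_bp),
        )
        for i, (p, (b0, b1)) in enumerate(zip(positions, base_pairs))
    ]
    p_anc = rng.uniform(config.maf_floor, 1.0 - config.maf_floor, config.n_snps)
    gap_switch = 1.0 - np.exp(-config.mosaic_switch_rate * np.diff(positions))

    panels: dict[str, HaplotypePanel] = {}
    n_chrom = 2 * config.n_diploids
    K = config.founder_haplotype_count
    for label in config.population_labels:
        p_pop = _balding_nichols(rng, p_anc, config.divergence)
        founders = (rng.random((K, config.n_snps)) < p_pop).astype(np.int8)
        alleles = np.empty((n_chrom, config.n_snps), dtype=np.int8)
        for row in range(n_chrom):
            switches = rng.random(config.n_snps - 1) < gap_switch
            ids = rng.integers(0, K, size=int(switches.sum()) + 1)
            path = ids[np.concatenate([[0], np.cumsum(switches)])]
            alleles[row] = founders[path, np.arange(config.n_snps)]
        panels[label] = HaplotypePanel(label, snps, alleles)
    return SimBundle(config=config, panels=panels, genetic_map=gmap)


def implant_sweep(
    bundle: SimBundle, spec: SweepSpec, rng: np.random.Generator
) -> SweepTruth:
    """Copy a donor haplotype onto carrier chromosomes in place.

    The donor is a randomly chosen existing chromosome restricted to the
    sweep region (one donor for all populations under ``shared_origin``,
    an independent donor per population otherwise).  Exactly
    ``round(carrier_frequency * 2N)`` randomly chosen chromosomes per
    population receive the donor.  A linked risk SNP, when given, is
    placed on the donor (``on_haplotype``) or exclusively off it.
    """
    some_panel = next(iter(bundle.panels.values()))
    snps = some_panel.snps
    positions = np.array([s.position_bp for s in snps])
    region = np.nonzero(
        (positions >= spec.start_bp) & (positions <= spec.end_bp)
    )[0]
    if region.size == 0:
        raise ConfigurationError("sweep region contains no panel SNPs")
    for pop in spec.populations:
        if pop not in bundle.panels:
            raise ConfigurationError(f"no panel for population {pop!r}")

    risk = spec.linked_risk_snp
    risk_idx: Optional[int] = None
    if risk is not None:
        risk_idx = int(np.argmin(np.abs(positions - risk.position_bp)))
        other = (
            risk.ancestral_base
            if risk.ancestral_base != risk.risk_base
            else next(b for b in _BASE_LIST if b != risk.risk_base)
        )
        new_meta = SnpMeta(
            rsid=snps[risk_idx].rsid,
            chromosome=snps[risk_idx].chromosome,
            position_bp=snps[risk_idx].position_bp,
            allele0=other,
            allele1=risk.risk_base,
            cm_position=snps[risk_idx].cm_position,
        )
        for panel in bundle.panels.values():  # shared SNP metadata
            panel.snps[risk_idx] = new_meta
        if risk.on_haplotype and risk_idx not in region:
            raise ConfigurationError(
                "linked risk SNP marked on_haplotype lies outside the region"
            )

    shared_donor: Optional[np.ndarray] = None
    if spec.shared_origin:
        src = bundle.panels[spec.populations[0]]
        row = int(rng.integers(src.n_chromosomes))
        shared_donor = src.alleles[row, region].copy()

    truth = SweepTruth(spec=spec, donor_forms={}, carrier_rows={})
    truth.risk_snp_index = risk_idx
    truth.risk_rsid = snps[risk_idx].rsid if risk_idx is not None else None
    for pop in spec.populations:
        panel = bundle.panels[pop]
        if shared_donor is not None:
            donor = shared_donor.copy()
        else:
            row = int(rng.integers(panel.n_chromosomes))
            donor = panel.alleles[row, region].copy()
        if risk is not None and risk_idx in region:
            pos_in_region = int(np.nonzero(region == risk_idx)[0][0])
            donor[pos_in_region] = 1 if risk.on_haplotype else 0
        n_carriers = int(round(spec.carrier_frequency * panel.n_chromosomes))
        carriers = rng.choice(panel.n_chromosomes, n_carriers, replace=False)
        panel.alleles[np.ix_(carriers, region)] = donor
        if risk is not None and not risk.on_haplotype and risk_idx is not None:
            mask = np.ones(panel.n_chromosomes, dtype=bool)
            mask[carriers] = False
            off = np.nonzero(mask)[0]
            risk_rows = off[
                rng.random(off.size) < risk.background_risk_frequency
            ]
            panel.alleles[:, risk_idx][mask] = 0
            panel.alleles[risk_rows, risk_idx] = 1
        matched = int(
            (panel.alleles[:, region] == donor).all(axis=1).sum()
        )
        truth.donor_forms[pop] = HaplotypeForm.from_sites(
            panel.snps,
            [(int(i), int(a)) for i, a in zip(region, donor)],
            matched / panel.n_chromosomes,
        )
        truth.carrier_rows[pop] = np.sort(carriers)
    bundle.sweeps.append(truth)
    return truth


def simulate(config: SimConfig) -> SimBundle:
    """Neutral panels plus every sweep in the config, fully seeded."""
    bundle = simulate_neutral_panels(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    for spec in config.sweep_specs:
        implant_sweep(bundle, spec, rng)
    return bundle


def emit_catalog(
    bundle: SimBundle,
) -> tuple[list[GwasFixtureRow], dict[str, OutgroupAllele]]:
    """GWAS-catalogue rows and outgroup table matching the implanted truth.

    One catalogue row per linked risk SNP; the outgroup table designates
    an ancestral base for every panel SNP (the specified base at risk
    SNPs, the reference allele elsewhere).  Raises when no sweep carries
    a linked risk SNP.
    """
    linked = [t for t in bundle.sweeps if t.spec.linked_risk_snp is not None]
    if not linked:
        raise ConfigurationError("no implanted sweep carries a linked risk SNP")
    some_panel = next(iter(bundle.panels.values()))
    rows: list[GwasFixtureRow] = []
    outgroup: dict[str, OutgroupAllele] = {
        s.rsid: OutgroupAllele(s.rsid, s.allele0) for s in some_panel.snps
    }
    for i, truth in enumerate(linked):
        risk = truth.spec.linked_risk_snp
        idx = truth.risk_snp_index
        snp = some_panel.snps[idx]
        pop0 = truth.spec.populations[0]
        raf = bundle.panels[pop0].allele_frequency(idx, risk.risk_base)
        rows.append(
            GwasFixtureRow(
                rsid=snp.rsid,
                chromosome=snp.chromosome,
                position_bp=snp.position_bp,
                no_risk_allele=snp.allele0,
                risk_allele=risk.risk_base,
                risk_allele_frequency=round(raf, 4),
                nearest_genes=(f"SYNG{i + 1}",),
                p_value=risk.p_value,
                odds_ratio=risk.odds_ratio,
                trait=risk.trait,
                reported_east_asian=risk.reported_east_asian,
                reported_european=risk.reported_european,
                ancestral_allele=risk.ancestral_base,
            )
        )
        outgroup[snp.rsid] = OutgroupAllele(snp.rsid, risk.ancestral_base)
    return rows, outgroup


# ---------------------------------------------------------------------------
# synthetic stand-in panels for the published evidence tables
# ---------------------------------------------------------------------------

_EAST_ASIAN = ("CHB", "CHD", "CHS", "JPT")
_EUROPEAN = ("CEU", "TSI", "MXL")


def fixture_bundle(seed: int = 0):
    """Synthetic panels and signals matched to the packaged evidence tables.

    The published analysis does not deposit genotypes, so this builds
    *synthetic* stand-in panels that reproduce the printed evidence
    structure: for every published region a donor haplotype is implanted
    in the named population at the printed haplotype frequency, carrying
    the risk allele exactly when the table says the risk allele was found
    on the selected haplotype, with the index SNP's overall allele
    frequency steered to the printed value.  European panels carry no
    implant.  Returns ``(rows, signals, panels, outgroup)`` ready for
    :func:`haplosweep.catalog_eval.evaluate`.
    """
    from .io_formats import load_paper_fixtures

    rng = np.random.default_rng(seed)
    rows, regions = load_paper_fixtures()
    n_chrom = 200

    by_chrom: dict[str, list] = {}
    for reg in regions:
        by_chrom.setdefault(reg.chromosome, []).append(reg)

    panels: dict[str, list[HaplotypePanel]] = {
        p: [] for p in _EAST_ASIAN + _EUROPEAN
    }
    signals: list[SelectionSignal] = []
    for chrom in sorted(by_chrom, key=int):
        regs = by_chrom[chrom]
        snp_rows = [r for r in rows if r.chromosome == chrom]
        key_positions = sorted(
            {r.start_bp for r in regs}
            | {r.end_bp for r in regs}
            | {r.position_bp for r in snp_rows}
        )
        lo = min(key_positions) - 200_000
        hi = max(key_positions) + 200_000
        filler = np.linspace(lo, hi, 24).astype(int)
        positions = sorted(set(key_positions) | set(int(x) for x in filler))
        row_at = {r.position_bp: r for r in snp_rows}
        snps = []
        for i, pos in enumerate(positions):
            if pos in row_at:
                r = row_at[pos]
                a0, a1 = r.no_risk_allele, r.risk_allele
                rsid = r.rsid
            else:
                a0, a1 = rng.choice(_BASE_LIST, size=2, replace=False)
                rsid = f"chr{chrom}_fill{i:03d}"
            snps.append(
                SnpMeta(rsid, chrom, pos, a0, a1, cm_position=pos / 1e6)
            )
        p_bg = rng.uniform(0.1, 0.9, len(positions))
        pos_arr = np.array(positions)

        for pop in _EAST_ASIAN + _EUROPEAN:
            alleles = (
                rng.random((n_chrom, len(positions))) < p_bg
            ).astype(np.int8)
            # one implant per distinct (population, region); a region row
            # is printed once per index SNP it contains
            pop_regs = list(
                {
                    (r.start_bp, r.end_bp): r
                    for r in regs
                    if r.population == pop
                }.values()
            )
            panel = HaplotypePanel(pop, list(snps), alleles)
            for reg in pop_regs:
                region_idx = np.nonzero(
                    (pos_arr >= reg.start_bp) & (pos_arr <= reg.end_bp)
                )[0]
                donor = (rng.random(region_idx.size) < 0.5).astype(np.int8)
                covered = [
                    rr
                    for rr in regs
                    if rr.population == pop
                    and reg.start_bp <= rr.snp_position_bp <= reg.end_bp
                ]
                for rr in covered:
                    j = int(np.nonzero(pos_arr == rr.snp_position_bp)[0][0])
                    donor[region_idx == j] = 1 if rr.found_on_haplotype else 0
                cf = reg.haplotype_frequency
                k = int(round(cf * n_chrom))
                carriers = rng.choice(n_chrom, k, replace=False)
                alleles[np.ix_(carriers, region_idx)] = donor
                # steer index-SNP frequencies toward the printed values
                for rr in covered:
                    j = int(np.nonzero(pos_arr == rr.snp_position_bp)[0][0])
                    on = 1.0 if rr.found_on_haplotype else 0.0
                    q = (rr.allele_frequency - cf * on) / (1.0 - cf)
                    q = float(np.clip(q, 0.0, 1.0))
                    mask = np.ones(n_chrom, dtype=bool)
                    mask[carriers] = False
                    off = np.nonzero(mask)[0]
                    alleles[off, j] = (rng.random(off.size) < q).astype(
                        np.int8
                    )
                form = HaplotypeForm.from_sites(
                    snps,
                    [(int(i), int(a)) for i, a in zip(region_idx, donor)],
                    float(
                        (alleles[:, region_idx] == donor).all(axis=1).mean()
                    ),
                )
                signals.append(
                    SelectionSignal(
                        population=pop,
                        chromosome=chrom,
                        start_bp=reg.start_bp,
                        end_bp=reg.end_bp,
                        form=form,
                        frequency_bin=cf,
                        n_f=1,
                        score=reg.haplops_score,
                    )
                )
            panels[pop].append(panel)

    outgroup = {
        r.rsid: OutgroupAllele(r.rsid, r.ancestral_allele) for r in rows
    }
    # dedupe signals per (pop, region): one signal per published region
    seen = set()
    unique_signals = []
    for s in signals:
        key = (s.population, s.chromosome, s.start_bp, s.end_bp)
        if key not in seen:
            seen.add(key)
            unique_signals.append(s)
    return rows, unique_signals, panels, outgroup
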