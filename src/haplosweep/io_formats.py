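"""Readers and writers for every external format the pipeline touches.

Supported formats
-----------------
* phased VCF (biallelic SNPs, fully phased ``GT``) — read via :mod:`cyvcf2`,
  written as plain text;
* IMPUTE-style ``.hap`` + ``.legend`` pairs (one legend row per SNP, one
  ``.hap`` row per SNP with one column per chromosome);
* genetic-map text files with columns ``position  rate(cM/Mb)  cM``;
* GWAS-catalogue TSV of index SNPs and outgroup (ancestral allele) TSV;
* BED (0-based half-open) for selection regions, TSV for signals and the
  per-SNP verdict report.

Internal coordinates are 1-based inclusive throughout; only the BED writer
converts.  The published evidence tables used by the evaluation ship as
packaged fixtures and are loaded with :func:`load_paper_fixtures`.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .types import (
    MISSING,
    ConfigurationError,
    DomainError,
    EvaluationVerdict,
    FstResult,
    GeneticMap,
    GwasFixtureRow,
    HaplotypeForm,
    HaplotypePanel,
    OutgroupAllele,
    ParseError,
    RegionRecord,
    SelectionSignal,
    SnpMeta,
)

logger = logging.getLogger("haplosweep")


# ---------------------------------------------------------------------------
# phased panels
# ---------------------------------------------------------------------------

def read_phased_panel(
    path: str | Path,
    format_hint: Optional[str] = None,
    population: Optional[str] = None,
) -> HaplotypePanel:
    """Read a phased haplotype panel from VCF or a ``.hap``/``.legend`` pair.

    ``path`` is either a VCF file or the ``.hap`` member of a pair (the
    legend is found by swapping the extension).  Multi-allelic and
    unphased sites are dropped with a logged count.  Raises
    :class:`ParseError` on malformed input or when no phased biallelic
    site survives.
    """
    path = Path(path)
    fmt = format_hint
    if fmt is None:
        fmt = "hap-legend" if path.suffix in {".hap", ".legend"} else "vcf"
    if fmt == "vcf":
        return _read_vcf(path, population or path.stem)
    if fmt == "hap-legend":
        return _read_hap_legend(path, population)
    raise ConfigurationError(f"unknown panel format {fmt!r}")


def _read_vcf(path: Path, population: str) -> HaplotypePanel:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - cyvcf2 is a hard dep
        raise ConfigurationError("cyvcf2 is required for VCF input") from exc

    if not path.exists():
        raise ParseError(f"{path}: no such file")
    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise ParseError(f"{path}: not a readable VCF ({exc})") from exc

    snps: list[SnpMeta] = []
    columns: list[np.ndarray] = []
    dropped_multi = dropped_unphased = 0
    try:
        for var in vcf:
            if len(var.ALT) != 1 or not var.is_snp:
                dropped_multi += 1
                continue
            genotypes = var.genotypes  # [allele_a, allele_b, phased]
            if any(len(g) >= 3 and not g[2] for g in genotypes):
                dropped_unphased += 1
                continue
            col = np.empty(2 * len(genotypes), dtype=np.int8)
            for i, g in enumerate(genotypes):
                col[2 * i] = g[0] if g[0] >= 0 else MISSING
                col[2 * i + 1] = g[1] if g[1] >= 0 else MISSING
            rsid = var.ID or f"{var.CHROM}:{var.POS}"
            snps.append(
                SnpMeta(
                    rsid=rsid,
                    chromosome=str(var.CHROM),
                    position_bp=int(var.POS),
                    allele0=var.REF,
                    allele1=var.ALT[0],
                )
            )
            columns.append(col)
    except Exception as exc:
        if isinstance(exc, (ParseError, DomainError)):
            raise
        raise ParseError(f"{path}: malformed VCF record ({exc})") from exc

    if dropped_multi or dropped_unphased:
        logger.info(
            "%s: dropped %d multi-allelic/non-SNP and %d unphased sites",
            path,
            dropped_multi,
            dropped_unphased,
        )
    if not snps:
        raise ParseError(f"{path}: no phased biallelic SNPs (empty panel)")
    return HaplotypePanel(population, snps, np.column_stack(columns))


def _read_hap_legend(path: Path, population: Optional[str]) -> HaplotypePanel:
    hap_path = path if path.suffix == ".hap" else path.with_suffix(".hap")
    legend_path = hap_path.with_suffix(".legend")
    if not hap_path.exists() or not legend_path.exists():
        raise ParseError(f"{hap_path} / {legend_path}: missing pair member")

    snps: list[SnpMeta] = []
    with open(legend_path) as fh:
        for ln, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok:
                continue
            if ln == 1 and not tok[1].isdigit():
                continue  # header row
            if len(tok) < 4:
                raise ParseError(f"{legend_path}:{ln}: expected 4 columns")
            try:
                snps.append(
                    SnpMeta(
                        rsid=tok[0],
                        chromosome=tok[4] if len(tok) > 4 else "0",
                        position_bp=int(tok[1]),
                        allele0=tok[2],
                        allele1=tok[3],
                    )
                )
            except (ValueError, DomainError) as exc:
                raise ParseError(f"{legend_path}:{ln}: {exc}") from exc

    rows: list[np.ndarray] = []
    with open(hap_path) as fh:
        for ln, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok:
                continue
            try:
                rows.append(
                    np.array(
                        [MISSING if t in {"?", "."} else int(t) for t in tok],
                        dtype=np.int8,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{hap_path}:{ln}: non-allele token") from exc
    if len(rows) != len(snps):
        raise ParseError(
            f"{hap_path}: {len(rows)} haplotype rows but "
            f"{len(snps)} legend SNPs"
        )
    if not rows:
        raise ParseError(f"{hap_path}: empty panel")
    # .hap rows are SNPs, columns are chromosomes -> transpose
    alleles = np.vstack(rows).T
    return HaplotypePanel(population or hap_path.stem, snps, alleles)


def write_panel_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    """Write a panel as a minimal phased VCF (one diploid per row pair)."""
    path = Path(path)
    n_dip = panel.n_chromosomes // 2
    samples = [f"{panel.population}_{i:04d}" for i in range(n_dip)]
    contigs = sorted({s.chromosome for s in panel.snps})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=haplosweep\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for j, snp in enumerate(panel.snps):
            col = panel.alleles[:, j]
            gts = []
            for i in range(n_dip):
                a, b = col[2 * i], col[2 * i + 1]
                sa = "." if a == MISSING else str(int(a))
                sb = "." if b == MISSING else str(int(b))
                gts.append(f"{sa}|{sb}")
            fh.write(
                f"{snp.chromosome}\t{snp.position_bp}\t{snp.rsid}\t"
                f"{snp.allele0}\t{snp.allele1}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def write_panel_hap_legend(panel: HaplotypePanel, prefix: str | Path) -> None:
    """Write a panel as an IMPUTE-style ``.hap`` + ``.legend`` pair."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".legend"), "w") as fh:
        fh.write("id position allele0 allele1 chromosome\n")
        for s in panel.snps:
            fh.write(
                f"{s.rsid} {s.position_bp} {s.allele0} {s.allele1} "
                f"{s.chromosome}\n"
            )
    with open(prefix.with_suffix(".hap"), "w") as fh:
        for j in range(panel.n_snps):
            col = panel.alleles[:, j]
            fh.write(
                " ".join("?" if a == MISSING else str(int(a)) for a in col)
                + "\n"
            )


# ---------------------------------------------------------------------------
# genetic maps
# ---------------------------------------------------------------------------

def read_genetic_map(path: str | Path, chromosome: str) -> GeneticMap:
    """Read a genetic-map text file with columns (position, rate, cM)."""
    anchors: list[tuple[int, float]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok:
                continue
            if ln == 1 and not tok[0].lstrip("-").replace(".", "").isdigit():
                continue  # header
            if len(tok) < 3:
                raise ParseError(f"{path}:{ln}: expected 3 columns")
            try:
                anchors.append((int(tok[0]), float(tok[2])))
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: non-numeric field") from exc
    return GeneticMap(chromosome, anchors)


def write_genetic_map(gmap: GeneticMap, path: str | Path) -> None:
    anchors = list(gmap.anchors)
    with open(path, "w") as fh:
        fh.write("position rate(cM/Mb) cM\n")
        for i, (pos, cm) in enumerate(anchors):
            if i + 1 < len(anchors):
                npos, ncm = anchors[i + 1]
                rate = (ncm - cm) / max(npos - pos, 1) * 1e6
            else:
                rate = 0.0
            fh.write(f"{pos} {rate:.8f} {cm:.8f}\n")


def interpolate_cm(gmap: GeneticMap, position_bp) -> float:
    """Genetic-map position of ``position_bp``: linear interpolation between
    bracketing anchors, clamped to the terminal anchors outside the range."""
    return gmap.interpolate(position_bp)


def attach_genetic_map(panel: HaplotypePanel, gmap: GeneticMap) -> HaplotypePanel:
    """Return a copy of ``panel`` with SNP cM positions filled from ``gmap``."""
    chroms = {s.chromosome for s in panel.snps}
    if chroms - {gmap.chromosome}:
        raise ConfigurationError(
            f"map covers {gmap.chromosome} but panel has {sorted(chroms)}"
        )
    cms = gmap.interpolate([s.position_bp for s in panel.snps])
    snps = [
        SnpMeta(s.rsid, s.chromosome, s.position_bp, s.allele0, s.allele1, float(cm))
        for s, cm in zip(panel.snps, cms)
    ]
    return HaplotypePanel(panel.population, snps, panel.alleles.copy())


# ---------------------------------------------------------------------------
# packaged evidence tables
# ---------------------------------------------------------------------------

def _fixture_path(name: str):
    return resources.files("haplosweep.fixtures").joinpath(name)


def load_paper_fixtures() -> tuple[list[GwasFixtureRow], list[RegionRecord]]:
    """Load the packaged published evidence tables.

    Returns the six T2D index-SNP rows and the fifteen East-Asian
    long-haplotype region rows, verbatim as printed (including the
    chromosome-15 region whose printed coordinates do not contain the
    printed position of rs7172432 — the two appear to come from different
    genome builds and are stored unreconciled).
    """
    rows = read_gwas_catalog(_fixture_path("gwas_index_snps.tsv"))
    regions: list[RegionRecord] = []
    with _fixture_path("selected_regions.tsv").open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            d = dict(zip(header, line.rstrip("\n").split("\t")))
            regions.append(
                RegionRecord(
                    chromosome=d["chromosome"],
                    start_bp=int(d["start_bp"]),
                    end_bp=int(d["end_bp"]),
                    haplops_score=float(d["haplops_score"]),
                    population=d["population"],
                    snp_position_bp=int(d["snp_position_bp"]),
                    rsid=d["rsid"],
                    risk_allele=d["risk_allele"],
                    risk_allele_is_ancestral=d["risk_allele_is_ancestral"] == "Y",
                    haplotype_frequency=float(d["haplotype_frequency"]),
                    allele_frequency=float(d["allele_frequency"]),
                    found_on_haplotype=d["found_on_haplotype"] == "Y",
                    nearest_genes=tuple(d["nearest_genes"].split(",")),
                )
            )
    return rows, regions


# ---------------------------------------------------------------------------
# GWAS catalogue / outgroup tables
# ---------------------------------------------------------------------------

_CATALOG_COLUMNS = [
    "rsid",
    "chromosome",
    "position_bp",
    "no_risk_allele",
    "risk_allele",
    "risk_allele_frequency",
    "nearest_genes",
    "p_value",
    "odds_ratio",
    "trait",
    "reported_east_asian",
    "reported_european",
    "ancestral_allele",
]


def read_gwas_catalog(path) -> list[GwasFixtureRow]:
    """Read a GWAS-catalogue-style TSV of index SNPs."""
    rows: list[GwasFixtureRow] = []
    opener = path.open() if hasattr(path, "open") else open(path)
    with opener as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = set(_CATALOG_COLUMNS) - set(header)
        if missing:
            raise ParseError(f"{path}: missing columns {sorted(missing)}")
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            d = dict(zip(header, line.rstrip("\n").split("\t")))
            raf = d["risk_allele_frequency"]
            anc = d["ancestral_allele"]
            try:
                rows.append(
                    GwasFixtureRow(
                        rsid=d["rsid"],
                        chromosome=d["chromosome"],
                        position_bp=int(d["position_bp"]),
                        no_risk_allele=d["no_risk_allele"],
                        risk_allele=d["risk_allele"],
                        risk_allele_frequency=(
                            None if raf in {"", "NR", "NA"} else float(raf)
                        ),
                        nearest_genes=tuple(d["nearest_genes"].split(",")),
                        p_value=float(d["p_value"]),
                        odds_ratio=float(d["odds_ratio"]),
                        trait=d["trait"],
                        reported_east_asian=d["reported_east_asian"] == "Y",
                        reported_european=d["reported_european"] == "Y",
                        ancestral_allele=None if anc in {"", "NA"} else anc,
                    )
                )
            except (ValueError, DomainError) as exc:
                raise ParseError(f"{path}:{ln}: {exc}") from exc
    return rows


def write_gwas_catalog(rows: Iterable[GwasFixtureRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_CATALOG_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                "\t".join(
                    [
                        r.rsid,
                        r.chromosome,
                        str(r.position_bp),
                        r.no_risk_allele,
                        r.risk_allele,
                        "NR"
                        if r.risk_allele_frequency is None
                        else repr(r.risk_allele_frequency),
                        ",".join(r.nearest_genes),
                        repr(r.p_value),
                        repr(r.odds_ratio),
                        r.trait,
                        "Y" if r.reported_east_asian else "N",
                        "Y" if r.reported_european else "N",
                        r.ancestral_allele or "NA",
                    ]
                )
                + "\n"
            )


def read_outgroup_table(path: str | Path) -> dict[str, OutgroupAllele]:
    """Read a two-column TSV (rsid, ancestral base; '.'/'NA' = missing)."""
    table: dict[str, OutgroupAllele] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok or tok[0] == "rsid":
                continue
            if len(tok) < 2:
                raise ParseError(f"{path}:{ln}: expected 2 columns")
            base = None if tok[1] in {".", "NA", "-"} else tok[1]
            table[tok[0]] = OutgroupAllele(tok[0], base)
    return table


def write_outgroup_table(
    table: Mapping[str, OutgroupAllele], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("rsid\tancestral_base\n")
        for rsid in table:
            og = table[rsid]
            fh.write(f"{rsid}\t{og.base or '.'}\n")


# ---------------------------------------------------------------------------
# signals: BED + TSV
# ---------------------------------------------------------------------------

def region_to_bed(start_bp: int, end_bp: int) -> tuple[int, int]:
    """1-based inclusive region -> 0-based half-open BED interval."""
    return start_bp - 1, end_bp


def bed_to_region(bed_start: int, bed_end: int) -> tuple[int, int]:
    """0-based half-open BED interval -> 1-based inclusive region."""
    return bed_start + 1, bed_end


def write_signals_bed(signals: Sequence[SelectionSignal], path: str | Path) -> None:
    """Write signal regions as BED4 (name = population:bin)."""
    with open(path, "w") as fh:
        for s in signals:
            b0, b1 = region_to_bed(s.start_bp, s.end_bp)
            fh.write(
                f"{s.chromosome}\t{b0}\t{b1}\t"
                f"{s.population}:{s.frequency_bin:.2f}\n"
            )


_SIGNAL_COLUMNS = [
    "population",
    "chromosome",
    "start_bp",
    "end_bp",
    "frequency_bin",
    "n_f",
    "p_cm",
    "p_snp",
    "score",
    "significant",
    "carrier_frequency",
    "genetic_length_cm",
    "snp_count",
    "form_sites",
]


def _encode_sites(form: Optional[HaplotypeForm]) -> str:
    if form is None:
        return "."
    return ";".join(f"{i}:{a}" for i, a in form.sites)


def write_signals_tsv(
    signals: Sequence[SelectionSignal], path: str | Path
) -> None:
    """Write signals (columns mirror the published region table, plus the
    allele-specified form encoded as ``index:allele`` pairs)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_SIGNAL_COLUMNS) + "\n")
        for s in signals:
            fh.write(
                "\t".join(
                    [
                        s.population,
                        s.chromosome,
                        str(s.start_bp),
                        str(s.end_bp),
                        f"{s.frequency_bin:.2f}",
                        str(s.n_f),
                        "." if s.p_cm is None else repr(s.p_cm),
                        "." if s.p_snp is None else repr(s.p_snp),
                        repr(s.score),
                        "Y" if s.significant else "N",
                        "."
                        if s.form is None
                        else repr(s.form.carrier_frequency),
                        "." if s.form is None else repr(s.form.genetic_length_cm),
                        "." if s.form is None else str(s.form.snp_count),
                        _encode_sites(s.form),
                    ]
                )
                + "\n"
            )


def read_signals_tsv(path: str | Path) -> list[SelectionSignal]:
    """Re-read a signals TSV written by :func:`write_signals_tsv`."""
    signals: list[SelectionSignal] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            d = dict(zip(header, line.rstrip("\n").split("\t")))
            try:
                form = None
                if d["form_sites"] != ".":
                    sites = tuple(
                        (int(i), int(a))
                        for i, a in (
                            pair.split(":") for pair in d["form_sites"].split(";")
                        )
                    )
                    form = HaplotypeForm(
                        chromosome=d["chromosome"],
                        sites=sites,
                        span_start_bp=int(d["start_bp"]),
                        span_end_bp=int(d["end_bp"]),
                        genetic_length_cm=float(d["genetic_length_cm"]),
                        snp_count=int(d["snp_count"]),
                        carrier_frequency=float(d["carrier_frequency"]),
                    )
                signals.append(
                    SelectionSignal(
                        population=d["population"],
                        chromosome=d["chromosome"],
                        start_bp=int(d["start_bp"]),
                        end_bp=int(d["end_bp"]),
                        form=form,
                        frequency_bin=float(d["frequency_bin"]),
                        n_f=int(d["n_f"]),
                        score=float(d["score"]),
                        p_cm=None if d["p_cm"] == "." else float(d["p_cm"]),
                        p_snp=None if d["p_snp"] == "." else float(d["p_snp"]),
                    )
                )
            except (ValueError, DomainError) as exc:
                raise ParseError(f"{path}:{ln}: {exc}") from exc
    return signals


# ---------------------------------------------------------------------------
# verdict report
# ---------------------------------------------------------------------------

_REPORT_COLUMNS = [
    "rsid",
    "trait",
    "populations_with_signal",
    "overlaps_selection",
    "east_asian_specific_association",
    "east_asian_specific_selection",
    "risk_on_haplotype",
    "risk_is_derived",
    "fst_values",
    "supports_thrifty",
]


def _yn(flag: bool) -> str:
    return "Y" if flag else "N"


def write_report_tsv(
    verdicts: Sequence[EvaluationVerdict], path: str | Path
) -> None:
    """Write the per-index-SNP verdict table (one row per SNP)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_REPORT_COLUMNS) + "\n")
        for v in verdicts:
            roh = (
                "indeterminate"
                if v.risk_on_haplotype == "indeterminate"
                else _yn(bool(v.risk_on_haplotype))
            )
            fst = ";".join(
                f"{f.population_a}-{f.population_b}:{f.value:.6f}"
                for f in v.fst_values
            )
            fh.write(
                "\t".join(
                    [
                        v.rsid,
                        v.trait,
                        ",".join(v.populations_with_signal) or ".",
                        _yn(v.overlaps_selection),
                        _yn(v.east_asian_specific_association),
                        _yn(v.east_asian_specific_selection),
                        roh,
                        v.risk_is_derived,
                        fst or ".",
                        _yn(v.supports_thrifty),
                    ]
                )
                + "\n"
            )


def read_report_tsv(path: str | Path) -> list[EvaluationVerdict]:
    verdicts: list[EvaluationVerdict] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if not line.strip():
                continue
            d = dict(zip(header, line.rstrip("\n").split("\t")))
            fst: list[FstResult] = []
            if d["fst_values"] != ".":
                for item in d["fst_values"].split(";"):
                    pair, val = item.rsplit(":", 1)
                    a, b = pair.split("-")
                    fst.append(FstResult(d["rsid"], a, b, float(val)))
            roh: object = d["risk_on_haplotype"]
            if roh in {"Y", "N"}:
                roh = roh == "Y"
            verdicts.append(
                EvaluationVerdict(
                    rsid=d["rsid"],
                    trait=d["trait"],
                    populations_with_signal=(
                        ()
                        if d["populations_with_signal"] == "."
                        else tuple(d["populations_with_signal"].split(","))
                    ),
                    overlaps_selection=d["overlaps_selection"] == "Y",
                    east_asian_specific_association=(
                        d["east_asian_specific_association"] == "Y"
                    ),
                    east_asian_specific_selection=(
                        d["east_asian_specific_selection"] == "Y"
                    ),
                    risk_on_haplotype=roh,
                    risk_is_derived=d["risk_is_derived"],
                    fst_values=fst,
                    supports_thrifty=d["supports_thrifty"] == "Y",
                )
            )
    return verdicts
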