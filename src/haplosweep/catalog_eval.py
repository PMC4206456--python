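"""Four-step evaluation of GWAS index SNPs against selection signals.

The evaluation asks, for each index SNP robustly associated with type-2
diabetes or obesity:

(i)   does the SNP fall inside a region under putative positive selection,
      and is that selection specific to the East Asian populations;
(ii)  does the reported risk allele sit on the selected haplotype form;
(iii) is the risk allele the derived state relative to an outgroup
      (chimpanzee) base;
(iv)  how differentiated is the SNP between East Asian and European
      populations (locus F_ST).

A SNP supports the famine-selection (thrifty-gene) expectation only when
it lies in an East-Asian-specific selection region, its risk allele is on
the selected haplotype, and that allele is derived.  Association
statistics are consumed as annotations and never recomputed here.
"""

from __future__ import annotations

from collections import Counter
from typing import Mapping, Optional, Sequence

import numpy as np

from . import differentiation
from .types import (
    MISSING,
    ConfigurationError,
    EvaluationVerdict,
    GwasFixtureRow,
    HaplosweepError,
    HaplotypePanel,
    OutgroupAllele,
    SelectionSignal,
)

#: Genome-wide significance threshold for keeping an association (strict).
GENOME_WIDE_P: float = 5e-8

#: Default trait set of the evaluation.
DEFAULT_TRAITS: frozenset[str] = frozenset({"T2D", "obesity"})

#: Fraction of carrier chromosomes that must agree before the allele
#: carried by a selected form at a non-defining site is called.
DEFAULT_MAJORITY_THRESHOLD: float = 0.9


class SpanError(HaplosweepError):
    """The index SNP lies outside the selected haplotype's span."""


def filter_catalog(
    rows: Sequence[GwasFixtureRow],
    trait_set: frozenset[str] | set[str] = DEFAULT_TRAITS,
    p_threshold: float = GENOME_WIDE_P,
) -> list[GwasFixtureRow]:
    """Keep rows with a matching trait and p-value strictly below the
    threshold; duplicate rsIDs collapse to the most significant row."""
    best: dict[str, GwasFixtureRow] = {}
    for r in rows:
        if r.trait not in trait_set or not (r.p_value < p_threshold):
            continue
        if r.rsid not in best or r.p_value < best[r.rsid].p_value:
            best[r.rsid] = r
    return [best[k] for k in best]


def overlap_with_signals(
    row: GwasFixtureRow, signals: Sequence[SelectionSignal]
) -> list[SelectionSignal]:
    """Signals whose region contains the SNP (inclusive boundaries)."""
    return [
        s for s in signals if s.contains(row.chromosome, row.position_bp)
    ]


def _panel_snp_index(panel: HaplotypePanel, row: GwasFixtureRow) -> Optional[int]:
    try:
        return panel.snp_index(row.rsid)
    except KeyError:
        pass
    for i, s in enumerate(panel.snps):
        if s.chromosome == row.chromosome and s.position_bp == row.position_bp:
            return i
    return None


def risk_allele_on_haplotype(
    row: GwasFixtureRow,
    signal: SelectionSignal,
    panel: HaplotypePanel,
    majority_threshold: float = DEFAULT_MAJORITY_THRESHOLD,
):
    """Does the selected haplotype form carry the reported risk allele?

    If the SNP is one of the form's defining sites the answer is read off
    the form.  If it lies within the span but is not a defining site, the
    allele is called from the form's carrier chromosomes: the majority
    base is accepted when it reaches ``majority_threshold`` of the
    non-missing carriers, otherwise the result is ``"indeterminate"``.
    Raises :class:`SpanError` when the SNP is outside the form span.
    """
    form = signal.form
    if form is None:
        raise ConfigurationError(f"signal for {signal.population} has no form")
    if not (form.span_start_bp <= row.position_bp <= form.span_end_bp) or (
        form.chromosome != row.chromosome
    ):
        raise SpanError(
            f"{row.rsid} at {row.chromosome}:{row.position_bp} is outside "
            f"the selected span {form.chromosome}:"
            f"[{form.span_start_bp}, {form.span_end_bp}]"
        )
    idx = _panel_snp_index(panel, row)
    if idx is None:
        raise ConfigurationError(
            f"{row.rsid} absent from panel {panel.population}"
        )
    snp = panel.snps[idx]
    risk_code = snp.base_to_code(row.risk_allele)

    form_allele = form.allele_at(idx)
    if form_allele is not None:
        return form_allele == risk_code

    # not a defining site: read the allele off the carrier chromosomes
    carriers = np.ones(panel.n_chromosomes, dtype=bool)
    for i, a in form.sites:
        col = panel.alleles[:, i]
        carriers &= (col == a) | (col == MISSING)
    col = panel.alleles[carriers, idx]
    col = col[col != MISSING]
    if col.size == 0:
        return "indeterminate"
    counts = Counter(int(c) for c in col)
    code, top = counts.most_common(1)[0]
    if top / col.size >= majority_threshold:
        return code == risk_code
    return "indeterminate"


def classify_ancestral(
    row: GwasFixtureRow, outgroup: Optional[OutgroupAllele]
) -> str:
    """Ancestral/derived state of the risk allele against the outgroup base.

    ``unknown`` when the outgroup base is missing or matches neither
    catalogued allele (no strand flipping is attempted — silently flipping
    A/T and C/G SNPs is unsafe).
    """
    if outgroup is None or outgroup.base is None:
        return "unknown"
    if outgroup.base == row.risk_allele:
        return "ancestral"
    if outgroup.base == row.no_risk_allele:
        return "derived"
    return "unknown"


def east_asian_specific(
    row: GwasFixtureRow,
    overlapping_signals: Sequence[SelectionSignal],
    east_asian_labels: Sequence[str],
    known_labels: Optional[Sequence[str]] = None,
) -> tuple[bool, bool]:
    """(association specific to East Asians, selection specific to them).

    Association specificity is read from the report flags; selection
    specificity requires at least one overlapping significant signal in an
    East Asian population and none in any other population.
    """
    east = set(east_asian_labels)
    if known_labels is not None:
        known = set(known_labels) | east
        for s in overlapping_signals:
            if s.population not in known:
                raise ConfigurationError(
                    f"unknown population label {s.population!r}"
                )
    assoc = row.reported_east_asian and not row.reported_european
    sig = [s for s in overlapping_signals if s.significant]
    in_east = any(s.population in east for s in sig)
    outside = any(s.population not in east for s in sig)
    return assoc, in_east and not outside


def _aggregate_on_haplotype(results: Sequence[object]):
    assessable = [r for r in results if r is not None]
    if not assessable:
        return "indeterminate"
    if all(r is True for r in assessable):
        return True
    if all(r is False for r in assessable):
        return False
    return "indeterminate"


def evaluate(
    rows: Sequence[GwasFixtureRow],
    signals: Sequence[SelectionSignal],
    panels: Mapping[str, Sequence[HaplotypePanel]],
    outgroup_table: Mapping[str, OutgroupAllele],
    fst_pairs: Sequence[tuple[str, str]] = (),
    east_asian_labels: Sequence[str] = ("CHB", "CHD", "CHS", "JPT"),
    majority_threshold: float = DEFAULT_MAJORITY_THRESHOLD,
    trait_set: frozenset[str] | set[str] = DEFAULT_TRAITS,
    p_threshold: float = GENOME_WIDE_P,
) -> list[EvaluationVerdict]:
    """Run the four-step evaluation; one verdict per filtered catalogue row.

    ``panels`` maps population label to its (per-chromosome) panels; F_ST
    is attached for rows whose risk allele is found on a selected
    haplotype (the rows where selection and association evidence
    converge).
    """
    verdicts: list[EvaluationVerdict] = []
    for row in filter_catalog(rows, trait_set, p_threshold):
        overlapping = overlap_with_signals(row, signals)
        sig = [s for s in overlapping if s.significant]
        overlaps = bool(sig)
        assoc_specific, sel_specific = east_asian_specific(
            row, overlapping, east_asian_labels
        )

        on_hap: object = False
        if overlaps:
            results = []
            for s in sig:
                panel = _panel_for(panels, s.population, row)
                if panel is None or s.form is None:
                    results.append(None)
                    continue
                try:
                    results.append(
                        risk_allele_on_haplotype(
                            row, s, panel, majority_threshold
                        )
                    )
                except SpanError:
                    results.append(None)
            on_hap = _aggregate_on_haplotype(results)

        derived = classify_ancestral(row, outgroup_table.get(row.rsid))

        fst_values = []
        if overlaps and on_hap is True and fst_pairs:
            table = differentiation.panel_frequency_table(
                panels, {row.rsid: row.risk_allele}
            )
            matrix = differentiation.fst_matrix(table, fst_pairs)
            fst_values = differentiation.fst_results(matrix, row.rsid)

        supports = (
            overlaps
            and sel_specific
            and on_hap is True
            and derived == "derived"
        )
        verdicts.append(
            EvaluationVerdict(
                rsid=row.rsid,
                trait=row.trait,
                populations_with_signal=tuple(
                    sorted({s.population for s in sig})
                ),
                overlaps_selection=overlaps,
                east_asian_specific_association=assoc_specific,
                east_asian_specific_selection=sel_specific,
                risk_on_haplotype=on_hap,
                risk_is_derived=derived,
                fst_values=fst_values,
                supports_thrifty=supports,
            )
        )
    return verdicts


def _panel_for(
    panels: Mapping[str, Sequence[HaplotypePanel]],
    population: str,
    row: GwasFixtureRow,
) -> Optional[HaplotypePanel]:
    for panel in panels.get(population, ()):  # per-chromosome panels
        if _panel_snp_index(panel, row) is not None:
            return panel
    return None
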