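"""Long-haplotype positive-selection scan on a phased panel.

The scan locates, at each carrier-frequency bin of a fixed grid
(0.05, 0.10, ..., 0.95), haplotype forms that are uncharacteristically long
relative to all other forms found genome-wide at the same frequency.  A
form's length is measured two ways — genetic distance spanned (cM) and
number of SNPs — and each measure is ranked against the candidate universe
at the bin to give an empirical p-value.  The score of a form is

    score = p_cm * p_snp * n_f

where ``n_f`` is the number of candidate forms at the bin; scores below
0.05 (strict) flag putative positive selection.  Because a site carrying a
long haplotype at frequency f usually also carries long haplotypes at
lower frequencies, overlapping significant signals are collapsed to the
one at the highest frequency bin, whose form is taken to carry the
advantageous allele.

Search strategy
---------------
From every seed (SNP, allele) whose allele frequency reaches the bin, the
scan extends the haplotype outwards SNP by SNP, keeping the set of carrier
chromosomes (those matching every accepted site; missing genotypes count
as matching).  Whenever *both* alleles of the next SNP would keep the
carrier fraction at or above the bin frequency the search forks and
follows both branches, so the extension is exhaustive over allele choices
rather than greedily committing to the majority allele.  With no skip
allowance this recovers exactly the maximal allele-specified contiguous
windows whose carrier fraction reaches the bin.  An optional per-side skip
allowance lets the extension step over single SNPs that would otherwise
end it, which tolerates genotyping error.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

import numpy as np

from .types import (
    MISSING,
    SCORE_THRESHOLD,
    ConfigurationError,
    DomainError,
    GeneticMap,
    HaplotypeForm,
    HaplotypePanel,
    SelectionSignal,
)

#: The canonical frequency grid: 0.05 .. 0.95 in steps of 0.05.
FREQUENCY_GRID: tuple[float, ...] = tuple(
    round(0.05 * i, 2) for i in range(1, 20)
)

#: Safety cap on simultaneously explored extension branches per seed; the
#: number of live branches is bounded by the number of distinct haplotype
#: groups at the bin (~1/f on missing-free data) so the cap only binds on
#: pathological missingness patterns, where the larger-carrier branch wins.
MAX_BRANCHES: int = 512


def min_carrier_count(f: float, n_chromosomes: int) -> int:
    """Smallest carrier count whose fraction of ``n_chromosomes`` is >= f."""
    return max(1, int(math.ceil(f * n_chromosomes - 1e-9)))


def _match_mask(column: np.ndarray, allele: int) -> np.ndarray:
    # missing counts as matching (optimistic carrier assignment)
    return (column == allele) | (column == MISSING)


def _extend(
    alleles: np.ndarray,
    carriers: np.ndarray,
    start: int,
    step: int,
    min_carriers: int,
    skip_allowance: int,
) -> list[tuple[tuple[tuple[int, int], ...], np.ndarray]]:
    """All maximal one-directional extensions from ``start`` (exclusive).

    Returns (sites, final_carrier_mask) leaves; sites are in visit order.
    """
    n_snps = alleles.shape[1]
    results: list[tuple[tuple[tuple[int, int], ...], np.ndarray]] = []
    stack: list[tuple[int, np.ndarray, tuple, int]] = [
        (start, carriers, (), 0)
    ]
    while stack:
        pos, carr, sites, skips = stack.pop()
        if pos < 0 or pos >= n_snps:
            results.append((sites, carr))
            continue
        col = alleles[:, pos]
        branches = []
        for allele in (0, 1):
            m = carr & _match_mask(col, allele)
            if int(m.sum()) >= min_carriers:
                branches.append((allele, m))
        if not branches:
            if skips < skip_allowance:
                stack.append((pos + step, carr, sites, skips + 1))
            else:
                results.append((sites, carr))
            continue
        if len(branches) > 1 and len(stack) + len(results) >= MAX_BRANCHES:
            # cap reached: fall back to the majority-allele branch
            branches = [max(branches, key=lambda b: int(b[1].sum()))]
        for allele, m in branches:
            stack.append((pos + step, m, sites + ((pos, allele),), skips))
    return results


def _extend_states(
    alleles: np.ndarray,
    carriers: np.ndarray,
    start: int,
    step: int,
    min_carriers: int,
    skip_allowance: int,
) -> list[tuple[tuple[tuple[int, int], ...], np.ndarray]]:
    """Every one-directional extension state (all prefixes of all branches),
    including the empty extension."""
    n_snps = alleles.shape[1]
    states: list[tuple[tuple[tuple[int, int], ...], np.ndarray]] = []
    stack: list[tuple[int, np.ndarray, tuple, int]] = [
        (start, carriers, (), 0)
    ]
    seen: set[tuple] = set()
    while stack:
        pos, carr, sites, skips = stack.pop()
        if sites not in seen:
            seen.add(sites)
            states.append((sites, carr))
        if pos < 0 or pos >= n_snps:
            continue
        col = alleles[:, pos]
        advanced = False
        for allele in (0, 1):
            m = carr & _match_mask(col, allele)
            if int(m.sum()) >= min_carriers:
                stack.append((pos + step, m, sites + ((pos, allele),), skips))
                advanced = True
        if not advanced and skips < skip_allowance:
            stack.append((pos + step, carr, sites, skips + 1))
    return states


def _grow_all(
    panel: HaplotypePanel,
    seed_snp_index: int,
    seed_allele: int,
    f: float,
    skip_allowance: int = 0,
) -> list[tuple[tuple[tuple[int, int], ...], int]]:
    """All maximal bidirectional extensions of a seed; (sites, carriers)."""
    n = panel.n_chromosomes
    need = min_carrier_count(f, n)
    col = panel.alleles[:, seed_snp_index]
    carriers0 = _match_mask(col, seed_allele)
    if int(carriers0.sum()) < need:
        return []
    out: dict[tuple, int] = {}
    right = _extend(
        panel.alleles, carriers0, seed_snp_index + 1, +1, need, skip_allowance
    )
    for r_sites, r_carr in right:
        left = _extend(
            panel.alleles, r_carr, seed_snp_index - 1, -1, need, skip_allowance
        )
        for l_sites, l_carr in left:
            sites = tuple(
                sorted(l_sites + ((seed_snp_index, seed_allele),) + r_sites)
            )
            count = int(l_carr.sum())
            if sites not in out or count > out[sites]:
                out[sites] = count
    return list(out.items())


def grow_longest_form(
    panel: HaplotypePanel,
    seed_snp_index: int,
    seed_allele: int,
    f: float,
    skip_allowance: int = 0,
) -> Optional[HaplotypeForm]:
    """Longest haplotype form through a seed site at frequency bin ``f``.

    Returns ``None`` when the seed allele's frequency among non-missing
    chromosomes is below ``f``.  The search is exhaustive over both allele
    choices and right-hand stopping points (stopping the rightward
    extension early can leave more carriers for the leftward one), so the
    returned form is a genuinely longest valid window through the seed.
    Ties between equally long extensions are broken by genetic length,
    then leftmost start.
    """
    if not (0 <= seed_snp_index < panel.n_snps):
        raise IndexError(f"seed index {seed_snp_index} out of range")
    if seed_allele not in (0, 1):
        raise DomainError("seed allele must be 0 or 1")
    if panel.allele_code_frequency(seed_snp_index, seed_allele) < f - 1e-12:
        return None
    n = panel.n_chromosomes
    need = min_carrier_count(f, n)
    col = panel.alleles[:, seed_snp_index]
    carriers0 = _match_mask(col, seed_allele)
    if int(carriers0.sum()) < need:
        return None
    grown: dict[tuple, int] = {}
    right_states = _extend_states(
        panel.alleles, carriers0, seed_snp_index + 1, +1, need, skip_allowance
    )
    for r_sites, r_carr in right_states:
        for l_sites, l_carr in _extend(
            panel.alleles, r_carr, seed_snp_index - 1, -1, need, skip_allowance
        ):
            sites = tuple(
                sorted(l_sites + ((seed_snp_index, seed_allele),) + r_sites)
            )
            count = int(l_carr.sum())
            if sites not in grown or count > grown[sites]:
                grown[sites] = count
    forms = [
        HaplotypeForm.from_sites(panel.snps, sites, count / n)
        for sites, count in grown.items()
    ]
    return max(
        forms,
        key=lambda fo: (
            fo.snp_count,
            fo.genetic_length_cm,
            -fo.span_start_bp,
        ),
    )


def _maximal_only(
    forms: dict[tuple, int]
) -> list[tuple[tuple[tuple[int, int], ...], int]]:
    """Drop forms whose site set is a subset of another form's."""
    items = sorted(forms.items(), key=lambda kv: -len(kv[0]))
    kept: list[tuple[tuple, int, frozenset]] = []
    for sites, count in items:
        fs = frozenset(sites)
        lo, hi = sites[0][0], sites[-1][0]
        dominated = False
        for ks, _, kfs in kept:
            if ks[0][0] <= lo and ks[-1][0] >= hi and fs <= kfs:
                dominated = True
                break
        if not dominated:
            kept.append((sites, count, fs))
    return [(s, c) for s, c, _ in kept]


def scan_population(
    panel: HaplotypePanel,
    bins: Sequence[float] = FREQUENCY_GRID,
    skip_allowance: int = 0,
) -> dict[float, list[HaplotypeForm]]:
    """Candidate haplotype forms per frequency bin, deduplicated to maximal
    forms only.

    Every (seed SNP, allele) whose allele frequency reaches the bin is
    grown; forms whose site set is contained in another form's at the same
    bin are discarded.  SNP cM positions must already be attached (see
    :func:`haplosweep.io_formats.attach_genetic_map`); a panel whose SNPs
    all carry cM 0 is accepted but genetic lengths will be zero.
    """
    if panel.n_snps == 0:
        raise ConfigurationError("cannot scan an empty panel")
    n = panel.n_chromosomes
    # per-SNP allele frequencies among non-missing chromosomes
    a = panel.alleles
    nonmiss = (a != MISSING).sum(axis=0)
    freq1 = (a == 1).sum(axis=0) / np.maximum(nonmiss, 1)
    freq0 = (a == 0).sum(axis=0) / np.maximum(nonmiss, 1)

    out: dict[float, list[HaplotypeForm]] = {}
    for f in bins:
        found: dict[tuple, int] = {}
        for allele, freqs in ((0, freq0), (1, freq1)):
            for seed in np.nonzero(freqs >= f - 1e-12)[0]:
                for sites, count in _grow_all(
                    panel, int(seed), allele, f, skip_allowance
                ):
                    if sites not in found or count > found[sites]:
                        found[sites] = count
        out[f] = [
            HaplotypeForm.from_sites(panel.snps, sites, count / n)
            for sites, count in _maximal_only(found)
        ]
    return out


def empirical_pvalues(
    target_form: HaplotypeForm, all_forms_at_bin: Sequence[HaplotypeForm]
) -> tuple[float, float]:
    """Genome-wide empirical rank p-values of a form at its frequency bin.

    ``p_cm`` is the proportion of candidate forms spanning a genetic
    distance at least as large as the target's; ``p_snp`` the proportion
    spanning at least as many SNPs.  Ties count toward the numerator and
    the target counts itself, so both values lie in (0, 1].
    """
    if not all_forms_at_bin:
        raise DomainError("empty candidate list")
    n = len(all_forms_at_bin)
    p_cm = (
        sum(
            1
            for fo in all_forms_at_bin
            if fo.genetic_length_cm >= target_form.genetic_length_cm
        )
        / n
    )
    p_snp = (
        sum(1 for fo in all_forms_at_bin if fo.snp_count >= target_form.snp_count)
        / n
    )
    return p_cm, p_snp


def haplops_score(p_cm: float, p_snp: float, n_f: int) -> tuple[float, bool]:
    """Selection score and significance flag.

    The score is the product of the two empirical p-values and the
    genome-wide candidate count at the bin; values strictly below 0.05
    flag positive selection.
    """
    if not (0.0 < p_cm <= 1.0 and 0.0 < p_snp <= 1.0):
        raise DomainError("empirical p-values must be in (0, 1]")
    if n_f < 1:
        raise DomainError("n_f must be >= 1")
    score = p_cm * p_snp * n_f
    return score, score < SCORE_THRESHOLD


def score_signals(
    forms_by_bin: dict[float, list[HaplotypeForm]], population: str
) -> list[SelectionSignal]:
    """Rank every candidate form within its bin and build signals."""
    signals: list[SelectionSignal] = []
    for f in sorted(forms_by_bin):
        forms = forms_by_bin[f]
        n_f = len(forms)
        for form in forms:
            p_cm, p_snp = empirical_pvalues(form, forms)
            score, _ = haplops_score(p_cm, p_snp, n_f)
            signals.append(
                SelectionSignal(
                    population=population,
                    chromosome=form.chromosome,
                    start_bp=form.span_start_bp,
                    end_bp=form.span_end_bp,
                    form=form,
                    frequency_bin=f,
                    n_f=n_f,
                    score=score,
                    p_cm=p_cm,
                    p_snp=p_snp,
                )
            )
    return signals


def collapse_to_highest_frequency(
    significant_signals: Sequence[SelectionSignal],
) -> list[SelectionSignal]:
    """Report each selected region only at its highest frequency bin.

    Signals from one population whose regions overlap by at least one
    basepair on the same chromosome (transitively) are grouped, and only
    the signal at the highest frequency bin is kept; ties are broken by
    larger genetic length, then smaller start position.
    """
    pops = {s.population for s in significant_signals}
    if len(pops) > 1:
        raise ConfigurationError(
            "collapse expects signals from a single population"
        )
    by_chrom: dict[str, list[SelectionSignal]] = {}
    for s in significant_signals:
        by_chrom.setdefault(s.chromosome, []).append(s)

    kept: list[SelectionSignal] = []
    for chrom in sorted(by_chrom):
        sigs = sorted(by_chrom[chrom], key=lambda s: (s.start_bp, s.end_bp))
        cluster: list[SelectionSignal] = []
        reach = -1
        for s in sigs:
            if cluster and s.start_bp > reach:
                kept.append(_best_of(cluster))
                cluster = []
                reach = -1
            cluster.append(s)
            reach = max(reach, s.end_bp)
        if cluster:
            kept.append(_best_of(cluster))
    kept.sort(key=lambda s: (s.chromosome, s.start_bp))
    return kept


def _best_of(cluster: Sequence[SelectionSignal]) -> SelectionSignal:
    def key(s: SelectionSignal):
        length = s.form.genetic_length_cm if s.form is not None else 0.0
        return (s.frequency_bin, length, -s.start_bp)

    return max(cluster, key=key)


def allele_frequency_on_panel(
    panel: HaplotypePanel, snp_index: int, allele_base: str
) -> float:
    """Fraction of non-missing chromosomes carrying ``allele_base``."""
    return panel.allele_frequency(snp_index, allele_base)
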