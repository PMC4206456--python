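"""Locus-specific F_ST from population allele frequencies.

The fixation index used here is the ratio of the observed variance of the
per-population allele frequencies to the maximum variance possible under
the pooled (unweighted mean) frequency:

    p_bar = mean(p_1, ..., p_k)
    F_ST  = mean((p_i - p_bar)^2) / (p_bar * (1 - p_bar))

Sample sizes are ignored (the populations enter with equal weight) and no
small-sample correction is applied; the statistic is a pure function of
the frequencies.  When the pooled frequency is 0 or 1 no variance is
possible and the value is defined as 0.

Note on simulated divergence: when two populations are drawn
independently around an ancestral frequency with Balding–Nichols
inflation F, the *expected* locus F_ST above is close to F/2, not F —
each population contributes variance F·p(1−p) but the mean of squared
deviations from the two-sample mean halves it.
:func:`divergence_estimate` inverts this moment relation to recover the
Balding–Nichols parameter from a mean locus F_ST.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import DomainError, FstResult, HaplotypePanel


def locus_fst(freqs: Sequence[float]) -> float:
    """F_ST at one locus from per-population allele frequencies.

    Requires at least two frequencies, each in [0, 1].  Symmetric in the
    populations and invariant under swapping the allele labels
    (p -> 1-p everywhere).
    """
    p = np.asarray(freqs, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise DomainError("locus_fst needs >= 2 population frequencies")
    if np.any((p < 0) | (p > 1)):
        raise DomainError("allele frequencies must lie in [0, 1]")
    p_bar = p.mean()
    denom = p_bar * (1.0 - p_bar)
    if denom == 0.0:
        return 0.0
    variance = np.mean((p - p_bar) ** 2)
    # variance <= denom by construction; clip guards float round-off only
    return float(min(variance / denom, 1.0))


def fst_matrix(
    frequencies: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Pairwise locus F_ST for a table of SNP x population frequencies.

    ``frequencies`` has one row per SNP (index = rsid) and one column per
    population; entries may be NaN where a SNP is absent from a panel, in
    which case the pair value is NaN (flagged missing, never fabricated).
    Columns of the result are labelled ``"A-B"`` in the order given.
    """
    out = {}
    for a, b in pairs:
        for pop in (a, b):
            if pop not in frequencies.columns:
                raise DomainError(f"no frequencies for population {pop!r}")
        col = []
        for rsid in frequencies.index:
            pa, pb = frequencies.loc[rsid, a], frequencies.loc[rsid, b]
            if pd.isna(pa) or pd.isna(pb):
                col.append(np.nan)
            else:
                col.append(locus_fst([pa, pb]))
        out[f"{a}-{b}"] = col
    return pd.DataFrame(out, index=frequencies.index)


def panel_frequency_table(
    panels: Mapping[str, Sequence[HaplotypePanel]],
    rsid_to_base: Mapping[str, str],
) -> pd.DataFrame:
    """Risk-allele frequencies of chosen SNPs across population panels.

    ``rsid_to_base`` names the allele whose frequency is tabulated.
    Missing (SNP not in any of a population's panels) becomes NaN.
    """
    pops = sorted(panels)
    table = pd.DataFrame(
        np.nan, index=list(rsid_to_base), columns=pops, dtype=float
    )
    for pop in pops:
        for panel in panels[pop]:
            for rsid, base in rsid_to_base.items():
                try:
                    idx = panel.snp_index(rsid)
                except KeyError:
                    continue
                table.loc[rsid, pop] = panel.allele_frequency(idx, base)
    return table


def fst_results(
    matrix: pd.DataFrame, rsid: str
) -> list[FstResult]:
    """Flatten one row of an :func:`fst_matrix` table into result records."""
    out = []
    for pair in matrix.columns:
        a, b = pair.split("-")
        v = matrix.loc[rsid, pair]
        if not pd.isna(v):
            out.append(FstResult(rsid, a, b, float(v)))
    return out


def divergence_estimate(
    mean_locus_fst: float, n_populations: int = 2
) -> float:
    """Moment estimate of the Balding–Nichols divergence parameter.

    For k populations drawn independently with inflation F around shared
    ancestral frequencies, E[numerator] = F·p(1−p)·(k−1)/k and
    E[denominator] ≈ p(1−p)·(1 − F/k), so the mean locus F_ST R satisfies
    R ≈ F(k−1)/k / (1 − F/k), inverted here as F = k·R / (k − 1 + R).
    """
    if n_populations < 2:
        raise DomainError("need >= 2 populations")
    if not (0.0 <= mean_locus_fst <= 1.0):
        raise DomainError("mean locus F_ST must be in [0, 1]")
    k = n_populations
    return k * mean_locus_fst / (k - 1 + mean_locus_fst)
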