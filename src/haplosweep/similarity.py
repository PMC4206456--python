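"""Haplotype similarity index (HSI) between selected haplotype forms.

A selection signal present in several populations can stem from a single
mutation event in their common ancestor or from convergent evolution on
different haplotype backgrounds.  The HSI between the selected forms
separates the two: over the SNPs present in both forms, it is the
fraction carrying identical alleles.  Values above 0.98 indicate a shared
event, values below 0.9 convergent evolution; the closed interval
[0.9, 0.98] is reported as indeterminate.

Forms must come from panels sharing the same SNP ordering and allele
coding (true for panels cut from one consensus SNP set, and for the
synthetic generator), since sites are matched by SNP index.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .types import DomainError, HaplotypeForm, HsiResult, SelectionSignal

SHARED_EVENT_THRESHOLD = 0.98  # HSI strictly above -> single mutation event
CONVERGENT_THRESHOLD = 0.9  # HSI strictly below -> convergent evolution


def classify(value: float, shared_snp_count: int) -> str:
    if shared_snp_count == 0:
        return "no_overlap"
    if value > SHARED_EVENT_THRESHOLD:
        return "shared_event"
    if value < CONVERGENT_THRESHOLD:
        return "convergent"
    return "indeterminate"


def hsi(form_a: HaplotypeForm, form_b: HaplotypeForm) -> HsiResult:
    """Similarity of two selected haplotype forms.

    Computed over the intersection of the two forms' SNP sets; an empty
    intersection yields value 0 with classification ``no_overlap``.
    Symmetric and invariant under site re-ordering.
    """
    if form_a.chromosome != form_b.chromosome:
        raise DomainError(
            f"forms on different chromosomes "
            f"({form_a.chromosome} vs {form_b.chromosome})"
        )
    a = dict(form_a.sites)
    b = dict(form_b.sites)
    shared = set(a) & set(b)
    if not shared:
        return HsiResult(0.0, 0, "no_overlap")
    matches = sum(1 for i in shared if a[i] == b[i])
    value = matches / len(shared)
    return HsiResult(value, len(shared), classify(value, len(shared)))


def pairwise_hsi_matrix(
    signals: Sequence[SelectionSignal],
) -> tuple[pd.DataFrame, dict[tuple[str, str], HsiResult]]:
    """Pairwise HSI between the forms of overlapping signals.

    Returns a symmetric value matrix (diagonal 1.0) labelled by
    population, plus the full per-pair results.  Signals must carry forms.
    """
    if any(s.form is None for s in signals):
        raise DomainError("pairwise HSI needs signals with haplotype forms")
    labels = [s.population for s in signals]
    n = len(signals)
    values = np.ones((n, n))
    results: dict[tuple[str, str], HsiResult] = {}
    for i in range(n):
        for j in range(i, n):
            r = hsi(signals[i].form, signals[j].form)
            values[i, j] = values[j, i] = r.value
            results[(labels[i], labels[j])] = r
            results[(labels[j], labels[i])] = r
    return pd.DataFrame(values, index=labels, columns=labels), results
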