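"""Independent brute-force oracles used to check the scan.

Everything here is deliberately naive: enumerate all O(M^2) contiguous
windows, group chromosomes by their exact haplotype over each window, and
keep forms whose carrier count reaches the bin.  No code is shared with
the package's search.
"""

import numpy as np

from haplosweep.haploscan import min_carrier_count


def enumerate_valid_forms(alleles: np.ndarray, f: float) -> set:
    """Every allele-specified contiguous window carried by >= f of the
    chromosomes (missing-free panels only)."""
    n, m = alleles.shape
    need = min_carrier_count(f, n)
    valid = set()
    for i in range(m):
        for j in range(i, m):
            window = alleles[:, i : j + 1]
            haps, counts = np.unique(window, axis=0, return_counts=True)
            for h, c in zip(haps, counts):
                if c >= need:
                    valid.add(
                        tuple((i + k, int(h[k])) for k in range(j - i + 1))
                    )
    return valid


def maximal_forms(alleles: np.ndarray, f: float) -> set:
    """The maximal elements of :func:`enumerate_valid_forms` under site-set
    inclusion."""
    valid = enumerate_valid_forms(alleles, f)
    out = set()
    for s in valid:
        ss = set(s)
        if not any(ss < set(t) for t in valid if len(t) > len(s)):
            out.add(s)
    return out


def longest_window_through(alleles: np.ndarray, f: float, seed: int, allele: int):
    """Longest valid window whose form carries ``allele`` at ``seed``;
    ties broken like the scan (SNP count, then leftmost)."""
    best = None
    for s in enumerate_valid_forms(alleles, f):
        if (seed, allele) not in s:
            continue
        if best is None or (len(s), -s[0][0]) > (len(best), -best[0][0]):
            best = s
    return best
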