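"""Independent brute-force alignment oracle.

Scores every monotone gapped alignment of a read against a labelled
reference by direct recursion over the three column types (match/mismatch,
read base over reference gap, reference base over read gap), memoised on
(read offset, reference offset, previous column type).  Written without
reference to the package's dynamic program; shares only the published
substitution contract, re-stated here from scratch.
"""

from functools import lru_cache

# reference label characters as rendered by ConvertedReference.sequence:
# A, G, T plain; h = T derived from a CpH cytosine; g = T derived from a CpG
_EQUIV = {
    "A": {"A"},
    "G": {"G"},
    "T": {"T"},
    "h": {"T", "C"},  # converted CpH, or unconverted (scored as match)
    "g": {"T", "C"},  # unmethylated or methylated CpG
}


def bruteforce_best_score(
    read: str,
    ref_labels: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
) -> float:
    """Best score over all alignments, global in the read, with affine gaps
    (first gap base costs gap_open, each further base gap_extend) and free
    gaps at the read's 3' end (leftover reference costs nothing)."""
    n, m = len(read), len(ref_labels)

    @lru_cache(maxsize=None)
    def best(i: int, j: int, prev: str) -> float:
        if i == n:
            return 0.0  # trailing reference is clipped for free
        options = []
        if j < m:
            sub = match if read[i] in _EQUIV[ref_labels[j]] else mismatch
            options.append(sub + best(i + 1, j + 1, "d"))
            options.append(
                (gap_extend if prev == "l" else gap_open) + best(i, j + 1, "l")
            )
        options.append((gap_extend if prev == "u" else gap_open) + best(i + 1, j, "u"))
        return max(options)

    return best(0, 0, "d")
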