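"""Independent brute-force oracles used by the test suite only."""

from rnamct.folding import MIN_LOOP, PAIRABLE


def enumerate_max_pairs(seq: str) -> int:
    """Maximum number of admissible base pairs over all nested structures
    with hairpin loops >= MIN_LOOP, by explicit exhaustive enumeration.

    Exponential-time; intended for sequences of length <= 12.  Kept free of
    any dynamic programming so it is independent of the folder it checks.
    """

    def rec(positions: tuple) -> int:
        if not positions:
            return 0
        i, rest = positions[0], positions[1:]
        best = rec(rest)  # i unpaired
        for idx, j in enumerate(rest):
            if j - i > MIN_LOOP and (seq[i - 1], seq[j - 1]) in PAIRABLE:
                inside = tuple(p for p in rest[:idx] if i < p < j)
                outside = tuple(p for p in rest[idx + 1 :])
                best = max(best, 1 + rec(inside) + rec(outside))
        return best

    return rec(tuple(range(1, len(seq) + 1)))
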