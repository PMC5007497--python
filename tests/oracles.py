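"""Independent brute-force oracles used by the tests.

Deliberately naive: direct symbol-by-symbol comparison at every
(position, spacer) pair, no masks, no vectorisation.  These stay
independent of the scanning implementation they check.
"""

from p53re.sequence_io import iupac_matches


def naive_scan(seq: str, pattern) -> list[tuple[int, int, int]]:
    """Every (start, end, spacer) satisfying the bipartite pattern."""
    hits = []
    n = len(seq)
    h1, h2 = pattern.h1, pattern.h2
    for start in range(n):
        for spacer in range(pattern.spacer_min, pattern.spacer_max + 1):
            end = start + h1 + spacer + h2
            if end > n:
                break
            if not all(
                iupac_matches(s, seq[start + j]) for j, s in enumerate(pattern.half1)
            ):
                break  # half1 fails for every spacer at this start
            if all(
                iupac_matches(s, seq[start + h1 + spacer + j])
                for j, s in enumerate(pattern.half2)
            ):
                hits.append((start, end, spacer))
    return hits
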