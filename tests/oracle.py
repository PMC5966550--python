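"""Independent reference implementations used only as test oracles.

These are deliberately literal, unoptimized transcriptions of the
published procedures, kept free of any code from the package so they can
arbitrate its behavior.
"""

from __future__ import annotations

from itertools import product

Interval = tuple[int, int]  # (start, end), 1-based inclusive


def reference_detect(genes: list[Interval], min_trnas: int,
                     min_density: float) -> list[tuple[int, int]]:
    """Step-by-step simulation of the expanding-window scan.

    ``genes`` are (start, end) pairs sorted by start. Returns the detected
    arrays as (i, j) index windows into ``genes``.

    The procedure: open a window holding the minimum gene count; if its
    density is below threshold advance the window one position at both
    ends; otherwise register it as a partial array and advance only the
    right end, re-registering while density stays at or above threshold;
    the first failing extension (or running out of genes) makes the last
    registered partial the final array, and the scan resumes after it.
    """
    n = len(genes)
    results: list[tuple[int, int]] = []
    first = 0
    while first + min_trnas - 1 <= n - 1:
        last = first + min_trnas - 1
        length = genes[last][1] - genes[first][0] + 1
        density = (last - first + 1) / (length / 1000)
        if density < min_density:
            first = first + 1  # advance relative to the first and last tRNA
            continue
        partial = (first, last)
        while True:
            last = last + 1  # advance relative only to the last tRNA
            if last > n - 1:
                break
            length = genes[last][1] - genes[first][0] + 1
            density = (last - first + 1) / (length / 1000)
            if density >= min_density:
                partial = (first, last)  # new current partial array
            else:
                break  # the partial registered early is the final array
        results.append(partial)
        first = partial[1] + 1
    return results


def qualifying_windows(genes: list[Interval], min_trnas: int,
                       min_density: float) -> set[tuple[int, int]]:
    """Exhaustive enumeration of every (i, j) window meeting both the
    size and density thresholds."""
    out = set()
    n = len(genes)
    for i in range(n):
        for j in range(i + min_trnas - 1, n):
            span = genes[j][1] - genes[i][0] + 1
            if (j - i + 1) / (span / 1000) >= min_density:
                out.add((i, j))
    return out


def enumerate_alignments(a: str, b: str):
    """Yield every global alignment of a and b as (gapped_a, gapped_b),
    never producing a gap-gap column. Exponential; strings must be tiny."""
    if not a and not b:
        yield ("", "")
        return
    if a and b:
        for ta, tb in enumerate_alignments(a[1:], b[1:]):
            yield (a[0] + ta, b[0] + tb)
    if a:
        for ta, tb in enumerate_alignments(a[1:], b):
            yield (a[0] + ta, "-" + tb)
    if b:
        for ta, tb in enumerate_alignments(a, b[1:]):
            yield ("-" + ta, b[0] + tb)


def alignment_score(ga: str, gb: str) -> int:
    """+1 per match, −1 per mismatch or gap column."""
    score = 0
    for x, y in zip(ga, gb):
        if x == "-" or y == "-":
            score -= 1
        elif x == y:
            score += 1
        else:
            score -= 1
    return score


def best_alignment_score(a: str, b: str) -> int:
    return max(alignment_score(ga, gb)
               for ga, gb in enumerate_alignments(a, b))


def all_short_string_pairs(alphabet: str, max_len: int):
    """Every ordered pair of non-empty strings over ``alphabet`` with
    lengths up to ``max_len``."""
    strings = [
        "".join(chars)
        for n in range(1, max_len + 1)
        for chars in product(alphabet, repeat=n)
    ]
    return [(x, y) for x in strings for y in strings]
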