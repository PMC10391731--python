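"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations


def levenshtein(a: str, b: str) -> int:
    """Plain quadratic dynamic-programming unit-cost edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(
                min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
            )
        prev = cur
    return prev[-1]


def infix_distance(query: str, target: str) -> int:
    """Edit distance of query against target with free end-gaps on target."""
    prev = [0] * (len(target) + 1)  # leading target gap is free
    for i, cq in enumerate(query, 1):
        cur = [i]
        for j, ct in enumerate(target, 1):
            cur.append(
                min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (cq != ct))
            )
        prev = cur
    return min(prev)  # trailing target gap is free


def adapter_offset_bruteforce(
    bases: str, adapter: str, min_overlap: int, max_error_rate: float
) -> int | None:
    """Leftmost valid adapter occurrence by exhaustive scan over offsets."""
    n, a = len(bases), len(adapter)
    for j in range(n):
        k = min(a, n - j)
        if k < min_overlap:
            continue
        mism = sum(bases[j + i] != adapter[i] for i in range(k))
        if mism <= int(max_error_rate * k):
            return j
    return None
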