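"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately recompute results by exhaustive enumeration (no shared
code paths with the package implementation) so agreement is meaningful.
"""

from __future__ import annotations

from quantmir.fold import can_pair


def brute_max_pairs(seq: str, min_loop: int = 3) -> int:
    """Maximum base pairs by plain recursion over the leftmost base.

    Enumerates every non-crossing pairing (leftmost base unpaired, or paired
    with each admissible partner) without memoization; independent of the
    package's rightmost-base dynamic program.
    """
    s = seq.upper().replace("U", "T")

    def rec(i: int, j: int) -> int:
        if j - i < min_loop + 1:
            return 0
        best = rec(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if can_pair(s[i], s[k]):
                best = max(best, 1 + rec(i + 1, k - 1) + rec(k + 1, j))
        return best

    return rec(0, len(s) - 1)


def enumerate_isomir_decompositions(insert: str, windows,
                                    max_offset5=2, max_trim3=4, max_ext3=4,
                                    max_tail=3):
    """All admissible (ref_id, offset5, trim3, ext3, tail) decompositions.

    ``windows`` is a list of (ref_id, template, mature_start0, mature_len).
    A decomposition is admissible when the body (insert minus tail) matches
    the template exactly at the offset anchor, the 3' geometry is within
    bounds, and a non-empty tail starts with a base that disagrees with (or
    lies beyond) the template.  Enumeration is over *all* tuples — the
    package's maximal-prefix search is never consulted.
    """
    L = len(insert)
    out = []
    for rid, tpl, s0, mlen in windows:
        e0 = s0 + mlen
        for off in range(-max_offset5, max_offset5 + 1):
            a = s0 + off
            if a < 0:
                continue
            for tail_len in range(0, max_tail + 1):
                body = insert[: L - tail_len]
                tail = insert[L - tail_len :] if tail_len else ""
                if not body:
                    continue
                if any(a + i >= len(tpl) or body[i] != tpl[a + i]
                       for i in range(len(body))):
                    continue
                end = a + len(body)
                if tail and end < len(tpl) and tail[0] == tpl[end]:
                    continue  # first tail base is templated: not a valid tail
                trim3 = max(0, e0 - end)
                ext3 = max(0, end - e0)
                if trim3 > max_trim3 or ext3 > max_ext3:
                    continue
                out.append((rid, off, trim3, ext3, tail))
    return out


def oracle_best(insert: str, windows, **bounds):
    """Minimal-cost decomposition(s): (best list, ambiguous flag)."""
    decs = enumerate_isomir_decompositions(insert, windows, **bounds)
    if not decs:
        return [], False
    def key(d):
        rid, off, trim3, ext3, tail = d
        cost = abs(off) + trim3 + ext3 + len(tail)
        return (cost, abs(off), off < 0, trim3, ext3, len(tail), rid)
    decs.sort(key=key)
    best_cost = key(decs[0])[0]
    rivals = {d[0] for d in decs if key(d)[0] == best_cost}
    return decs, len(rivals) > 1


def expected_distinct_umis(n: int, space: int = 4 ** 10) -> float:
    """Closed-form birthday expectation: distinct values after n uniform draws."""
    return space * (1.0 - (1.0 - 1.0 / space) ** n)
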