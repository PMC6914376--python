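"""Independent brute-force oracles used across the test suite.

These deliberately share no code with the implementation paths they check:
variant equivalence is decided by applying edits to the contig string and
comparing the results, and the canonical representation is found by
exhaustive enumeration of every (pos, ref, alt) whose application reproduces
the same edited sequence.
"""

from __future__ import annotations


def apply_edit(contig: str, pos: int, ref: str, alt: str) -> str:
    i = pos - 1
    assert contig[i : i + len(ref)] == ref
    return contig[:i] + alt + contig[i + len(ref) :]


def enumerate_equivalents(contig: str, pos: int, ref: str, alt: str) -> list[tuple[int, str, str]]:
    """Every representation (p, r, a), with non-empty alleles and r != a,
    whose application to ``contig`` yields the same edited sequence."""
    edited = apply_edit(contig, pos, ref, alt)
    n, m = len(contig), len(edited)
    reps = []
    for p in range(1, n + 1):
        if contig[: p - 1] != edited[: p - 1]:
            break  # a representation at p cannot leave a differing prefix intact
        for lr in range(1, n - p + 2):
            la = m - (n - lr)
            if la < 1:
                continue
            r = contig[p - 1 : p - 1 + lr]
            a = edited[p - 1 : p - 1 + la]
            if r != a and contig[p - 1 + lr :] == edited[p - 1 + la :]:
                reps.append((p, r, a))
    return reps


def is_parsimonious_rep(rep: tuple[int, str, str]) -> bool:
    _, r, a = rep
    if r[-1] == a[-1]:
        return False
    if len(r) >= 2 and len(a) >= 2 and r[0] == a[0]:
        return False
    return True


def canonical_by_enumeration(contig: str, pos: int, ref: str, alt: str) -> tuple[int, str, str] | None:
    """The minimal-length, leftmost equivalent representation, or None when no
    parsimonious representation exists (edit runs into the contig start)."""
    reps = enumerate_equivalents(contig, pos, ref, alt)
    assert reps, "an edit must have at least its own representation"
    best = min(reps, key=lambda t: (len(t[1]) + len(t[2]), t[0]))
    if not is_parsimonious_rep(best):
        return None
    return best


def brute_force_in_panel(contig: str, pos: int, ref: str, intervals) -> bool:
    """Per-base membership check of a variant footprint against intervals."""
    for p0 in range(pos - 1, pos - 1 + len(ref)):
        for iv in intervals:
            if iv.contig == contig and iv.start <= p0 < iv.end:
                return True
    return False
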