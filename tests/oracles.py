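"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: normalization is
checked by exhaustive enumeration of equivalent representations, voting by
literal re-encodings of the rules, merging by plain set algebra.
"""

from __future__ import annotations


def apply_edit(seq: str, pos: int, ref: str, alt: str) -> str:
    """Apply a (1-based pos, ref, alt) edit to a context string."""
    assert seq[pos - 1 : pos - 1 + len(ref)] == ref, "edit does not match context"
    return seq[: pos - 1] + alt + seq[pos - 1 + len(ref) :]


def enumerate_equivalents(seq: str, pos: int, ref: str, alt: str) -> list[tuple[int, str, str]]:
    """All (pos', ref', alt') representations producing the same edited
    sequence, by exhaustive enumeration over the context."""
    target = apply_edit(seq, pos, ref, alt)
    length = len(seq)
    out = []
    for p in range(1, length + 1):
        for ref_len in range(1, length - p + 2):
            alt_len = len(target) - (length - ref_len)
            if alt_len < 1:
                continue
            r = seq[p - 1 : p - 1 + ref_len]
            a = target[p - 1 : p - 1 + alt_len]
            if r == a:
                continue
            if seq[: p - 1] + a + seq[p - 1 + ref_len :] != target:
                continue
            out.append((p, r, a))
    return out


def leftmost_minimal(seq: str, pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """The left-most minimal equivalent representation.

    Candidates sharing a trailing base are non-parsimonious (trimmable)
    unless stuck at the contig start with a length-1 allele; candidates
    sharing a leading base with both alleles longer than one are
    trimmable.  Among parsimonious candidates, smallest position wins,
    then smallest total allele length.
    """
    parsimonious = []
    for p, r, a in enumerate_equivalents(seq, pos, ref, alt):
        if r[-1] == a[-1] and not (p == 1 and (len(r) == 1 or len(a) == 1)):
            continue
        if len(r) > 1 and len(a) > 1 and r[0] == a[0]:
            continue
        parsimonious.append((p, r, a))
    assert parsimonious, "no parsimonious equivalent found"
    return min(parsimonious, key=lambda c: (c[0], len(c[1]) + len(c[2]), c[1], c[2]))


def literal_adaptive_vote(support_names: set, vaf, n_callers: int) -> bool:
    """Literal re-encoding of the three adaptive PASS conditions:
    (1) called by Strelka and MuTect2 and 0.03 <= VAF <= 0.1;
    (2) VAF < 0.03 and called by MuTect2;
    (3) called by >= 50% of callers."""
    cond1 = (
        "Strelka" in support_names
        and "MuTect2" in support_names
        and vaf is not None
        and 0.03 <= vaf <= 0.1
    )
    cond2 = vaf is not None and vaf < 0.03 and "MuTect2" in support_names
    cond3 = 2 * len(support_names) >= n_callers
    return cond1 or cond2 or cond3


def literal_majority_vote(n_support: int, n_callers: int) -> bool:
    """Called by >= 50% of callers."""
    return 2 * n_support >= n_callers


def literal_vardict_reject(af, dp, mq, nm, qual) -> bool:
    """Literal transcription of the hard-filter expression."""
    return (af * dp < 6) and (
        (mq < 55.0 and nm > 1.0) or (mq < 60.0 and nm > 2.0) or (dp < 10) or (qual < 45)
    )
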