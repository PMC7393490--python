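"""Variant identity, classification and allele normalization.

Somatic callers emit the same underlying mutation in different textual
representations (anchored indels shifted within repeats, padded alleles,
multiallelic rows).  Everything downstream — merging, voting, truth-set
comparison — keys variants by ``(contig, pos, ref, alt)``, so records must
first be reduced to a canonical form: multiallelics split, alleles
left-aligned against the reference and trimmed to minimal length.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from enum import Enum
from typing import Callable, Iterable, Sequence

import pyfaidx

__all__ = [
    "VariantKey",
    "VariantClass",
    "ReferenceContext",
    "FastaReference",
    "InMemoryReference",
    "ReferenceMismatchError",
    "classify",
    "normalize",
    "split_multiallelic",
    "harmonize_contig",
    "contig_sort_key",
    "variant_sort_key",
]

logger = logging.getLogger(__name__)

_ALPHABET = frozenset("ACGTN")
_SYMBOLIC = re.compile(r"[<>\[\]*.]")


class ReferenceMismatchError(ValueError):
    """REF allele disagrees with the reference sequence at its position."""


@dataclass(frozen=True)
class VariantKey:
    """Canonical identity of a single-ALT variant.

    ``pos`` is the 1-based coordinate of the first REF base, as in VCF.
    """

    contig: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) is not a variant")
        for allele in (self.ref, self.alt):
            if not set(allele) <= _ALPHABET:
                raise ValueError(f"allele {allele!r} outside alphabet ACGTN")

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.contig}:{self.pos}:{self.ref}>{self.alt}"


class VariantClass(Enum):
    SNV = "SNV"
    INDEL = "INDEL"


def classify(key: VariantKey) -> VariantClass:
    """SNV iff both alleles are single bases; everything else (including
    equal-length multi-base substitutions) is grouped with INDEL for
    scheme selection."""
    if len(key.ref) == 1 and len(key.alt) == 1:
        return VariantClass.SNV
    return VariantClass.INDEL


def contig_sort_key(contig: str) -> tuple:
    """Natural sort so chr2 < chr10; non-numeric contigs sort after."""
    parts = re.split(r"(\d+)", contig)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def variant_sort_key(key: VariantKey) -> tuple:
    return (contig_sort_key(key.contig), key.pos, key.ref, key.alt)


def harmonize_contig(contig: str, style: str | None = None) -> str:
    """Strip or add the ``chr`` prefix.

    style=None leaves the name alone; "chr" forces the prefix on,
    "nochr" forces it off.  Callers run on one BAM can still emit
    header-dependent names, so merging keys on a single style.
    """
    if style is None:
        return contig
    has = contig.startswith("chr")
    if style == "chr":
        return contig if has else "chr" + contig
    if style == "nochr":
        return contig[3:] if has else contig
    raise ValueError(f"unknown contig style {style!r} (use 'chr' or 'nochr')")


class ReferenceContext:
    """1-based inclusive access to one contig's sequence."""

    def __init__(self, contig: str, fetch: Callable[[int, int], str], length: int | None = None):
        self.contig = contig
        self._fetch = fetch
        self.length = length

    def fetch(self, start: int, end: int) -> str:
        """Return uppercase bases for the 1-based inclusive interval."""
        if start < 1 or end < start:
            raise ValueError(f"bad interval {start}-{end}")
        seq = self._fetch(start, end).upper()
        if len(seq) != end - start + 1:
            raise ValueError(
                f"reference window {self.contig}:{start}-{end} returned {len(seq)} bases"
            )
        return seq

    @classmethod
    def from_sequence(cls, contig: str, sequence: str) -> "ReferenceContext":
        seq = sequence.upper()
        return cls(contig, lambda s, e: seq[s - 1 : e], length=len(seq))


class InMemoryReference:
    """Reference backed by a dict of contig -> sequence strings."""

    def __init__(self, sequences: dict[str, str]):
        self._ctx = {c: ReferenceContext.from_sequence(c, s) for c, s in sequences.items()}

    def context(self, contig: str) -> ReferenceContext | None:
        return self._ctx.get(contig)


class FastaReference:
    """Reference backed by an indexed FASTA on disk."""

    def __init__(self, path):
        self._fasta = pyfaidx.Fasta(str(path), sequence_always_upper=True)

    def context(self, contig: str) -> ReferenceContext | None:
        if contig not in self._fasta:
            return None
        rec = self._fasta[contig]
        return ReferenceContext(
            contig, lambda s, e: str(rec[s - 1 : e]), length=len(rec)
        )


def _trim_only(key: VariantKey) -> VariantKey:
    """Trailing then leading trim without left-shifting (no reference)."""
    pos, ref, alt = key.pos, key.ref, key.alt
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return VariantKey(key.contig, pos, ref, alt)


def normalize(key: VariantKey, ref_ctx: ReferenceContext | None = None) -> VariantKey:
    """Left-align and trim to the left-most minimal equivalent representation.

    The procedure is the standard one: repeatedly drop a shared trailing
    base, left-extending both alleles with the reference base at pos-1
    whenever one would become empty, until the alleles end in different
    bases; then drop shared leading bases (advancing pos) while both
    alleles are longer than one base.  Idempotent by construction.

    Without a reference context only the trims are applied (sufficient for
    SNVs and already-anchored indels) and a debug diagnostic is logged.

    Raises
    ------
    ReferenceMismatchError
        if ``key.ref`` disagrees with the reference at ``key.pos``.
    """
    if classify(key) is VariantClass.SNV:
        return key
    if ref_ctx is None:
        logger.debug("no reference for %s; trim-only normalization", key)
        return _trim_only(key)

    observed = ref_ctx.fetch(key.pos, key.pos + len(key.ref) - 1)
    if observed != key.ref:
        raise ReferenceMismatchError(
            f"{key}: REF {key.ref!r} does not match reference {observed!r}"
        )

    pos, ref, alt = key.pos, key.ref, key.alt
    while ref[-1] == alt[-1]:
        nref, nalt = ref[:-1], alt[:-1]
        if not nref or not nalt:
            if pos == 1:
                break  # contig start: cannot left-extend further
            base = ref_ctx.fetch(pos - 1, pos - 1)
            pos -= 1
            ref, alt = base + nref, base + nalt
        else:
            ref, alt = nref, nalt
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return VariantKey(key.contig, pos, ref, alt)


def split_multiallelic(
    contig: str, pos: int, ref: str, alts: Sequence[str]
) -> list[VariantKey]:
    """One :class:`VariantKey` per concrete ALT; symbolic ALTs (``<DEL>``,
    breakends, spanning-deletion ``*``) are dropped with a diagnostic."""
    if not alts:
        raise ValueError("alts must be non-empty")
    keys: list[VariantKey] = []
    for alt in alts:
        if alt is None or _SYMBOLIC.search(alt) or not alt:
            logger.debug("dropping symbolic/blank ALT %r at %s:%s", alt, contig, pos)
            continue
        try:
            keys.append(VariantKey(contig, pos, ref.upper(), alt.upper()))
        except ValueError as exc:
            logger.debug("dropping unrepresentable ALT %r at %s:%s (%s)", alt, contig, pos, exc)
    return keys
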