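"""Reading per-caller somatic VCF dialects into comparable records.

Each supported caller encodes the tumor variant-allele fraction (VAF)
differently: VarScan writes a percent string (``FREQ=25%``), Strelka writes
tier-1 base counts (``AU/CU/GU/TU`` for SNVs, ``TAR/TIR`` for indels) and no
AF field at all, LoFreq writes ``INFO/AF`` with no sample columns, the
MuTect family and VarDict carry FORMAT ``FA``/``AF`` floats, and MuSE only
exposes allelic depths.  This module knows those dialects, resolves which
sample column is the tumor, and reduces every record to a
:class:`CallerRecord` keyed by a normalized :class:`~somaticmerge.variants.VariantKey`.

The VarDict hard filter applied here is the post-calling expression used to
clean standalone VarDict output::

    (AF*DP < 6) && ((MQ < 55.0 && NM > 1.0) || (MQ < 60.0 && NM > 2.0)
                    || (DP < 10) || (QUAL < 45))
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pysam

from .variants import (
    ReferenceMismatchError,
    VariantKey,
    classify,
    VariantClass,
    harmonize_contig,
    normalize,
    split_multiallelic,
)

__all__ = [
    "CallerId",
    "CallerRecord",
    "CallSet",
    "VarDictMetrics",
    "read_caller_vcf",
    "extract_tumor_vaf",
    "resolve_tumor_sample",
    "vardict_hard_filter",
]

logger = logging.getLogger(__name__)


class CallerId(str, Enum):
    """The seven supported tumor-normal callers."""

    LOFREQ = "LoFreq"
    MUSE = "MuSE"
    MUTECT = "MuTect"
    MUTECT2 = "MuTect2"
    STRELKA = "Strelka"
    VARDICT = "VarDict"
    VARSCAN = "VarScan"

    @classmethod
    def parse(cls, name: str) -> "CallerId":
        for member in cls:
            if member.value.lower() == name.strip().lower():
                return member
        valid = ", ".join(m.value for m in cls)
        raise ValueError(f"unknown caller {name!r}; valid callers are: {valid}")

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class CallerRecord:
    """One caller's assertion about one variant."""

    key: VariantKey
    caller: CallerId
    tumor_vaf: float | None
    passed_native_filter: bool = True
    native_metrics: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tumor_vaf is not None and not (0.0 <= self.tumor_vaf <= 1.0):
            raise ValueError(f"tumor_vaf {self.tumor_vaf} outside [0, 1]")


@dataclass
class CallSet:
    caller: CallerId
    records: dict[VariantKey, CallerRecord]
    source_path: str = "<memory>"

    def __len__(self) -> int:
        return len(self.records)

    @property
    def keys(self) -> set[VariantKey]:
        return set(self.records)

    @classmethod
    def from_records(
        cls, caller: CallerId, records: Iterable[CallerRecord], source_path: str = "<memory>"
    ) -> "CallSet":
        """Collapse duplicate keys (first record wins, logged)."""
        table: dict[VariantKey, CallerRecord] = {}
        for rec in records:
            if rec.key in table:
                logger.warning("%s: duplicate record for %s dropped", caller, rec.key)
                continue
            table[rec.key] = rec
        return cls(caller, table, source_path)


@dataclass(frozen=True)
class VarDictMetrics:
    af: float
    dp: float
    mq: float
    nm: float
    qual: float

    def __post_init__(self) -> None:
        for name in ("af", "dp", "mq", "nm", "qual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def vardict_hard_filter(m: VarDictMetrics) -> bool:
    """True to keep the record, False to reject it.

    Rejects low-evidence calls (fewer than ~6 supporting reads) that also
    show a mapping-quality/mismatch pathology, shallow depth, or low
    variant quality.
    """
    low_support = m.af * m.dp < 6
    pathology = (
        (m.mq < 55.0 and m.nm > 1.0)
        or (m.mq < 60.0 and m.nm > 2.0)
        or (m.dp < 10)
        or (m.qual < 45)
    )
    return not (low_support and pathology)


# ---------------------------------------------------------------------------
# tumor-sample resolution

_TUMOR_LITERAL = "TUMOR"


def resolve_tumor_sample(
    vcf: pysam.VariantFile, caller: CallerId, explicit: str | None = None
) -> str | None:
    """Pick the tumor sample column.

    Order: an explicit name; a sample literally called ``TUMOR``; a
    ``##tumor_sample=`` header line; otherwise the last sample column.
    Returns None for sample-free VCFs (LoFreq somatic output).
    """
    samples = list(vcf.header.samples)
    if explicit is not None:
        if explicit not in samples:
            raise ValueError(
                f"tumor sample {explicit!r} not among samples {samples} "
                f"in {vcf.filename!r}; pass --tumor-sample with one of these names"
            )
        return explicit
    if not samples:
        return None
    if _TUMOR_LITERAL in samples:
        return _TUMOR_LITERAL
    for record in vcf.header.records:
        if record.key == "tumor_sample" and record.value in samples:
            logger.debug("%s: tumor sample %r from header line", caller, record.value)
            return record.value
    logger.info(
        "%s: assuming last sample column %r is the tumor; "
        "pass tumor_sample explicitly to override", caller, samples[-1]
    )
    return samples[-1]


# ---------------------------------------------------------------------------
# VAF extraction


def _scalar(value, alt_index: int = 0):
    """Unpack pysam's tuples for Number!=1 fields."""
    if isinstance(value, (tuple, list)):
        if not value:
            return None
        return value[alt_index] if alt_index < len(value) else value[0]
    return value


def _clamp_fraction(value) -> float | None:
    try:
        v = float(value)
    except (TypeError, ValueError):
        return None
    if not (0.0 <= v <= 1.0):
        return None
    return v


def _ad_ratio(sample, alt_index: int) -> float | None:
    ad = sample.get("AD") if "AD" in sample else None
    if not isinstance(ad, (tuple, list)) or len(ad) < 2:
        return None
    try:
        ref_n = float(ad[0])
        alt_n = float(ad[1 + alt_index])
    except (TypeError, ValueError, IndexError):
        return None
    denom = ref_n + alt_n
    if denom <= 0:
        return None
    return _clamp_fraction(alt_n / denom)


def _tier1(value) -> float | None:
    """Strelka count fields are (tier1, tier2) pairs; use tier 1."""
    v = _scalar(value, 0)
    try:
        return float(v)
    except (TypeError, ValueError):
        return None


def _strelka_vaf(rec: pysam.VariantRecord, sample, alt: str) -> float | None:
    if len(rec.ref) == 1 and len(alt) == 1:  # SNV: per-base tier-1 counts
        counts = {}
        for base in "ACGT":
            fld = base + "U"
            if fld not in sample:
                return None
            counts[base] = _tier1(sample[fld])
        if any(c is None for c in counts.values()):
            return None
        total = sum(counts.values())
        if total <= 0 or alt not in counts:
            return None
        return _clamp_fraction(counts[alt] / total)
    # indel: tier-1 TIR / (TIR + TAR)
    if "TIR" not in sample or "TAR" not in sample:
        return None
    tir = _tier1(sample["TIR"])
    tar = _tier1(sample["TAR"])
    if tir is None or tar is None or tir + tar <= 0:
        return None
    return _clamp_fraction(tir / (tir + tar))


def extract_tumor_vaf(
    rec: pysam.VariantRecord,
    caller: CallerId,
    tumor_sample: str | None,
    alt_index: int = 0,
) -> float | None:
    """Tumor VAF for one ALT of a raw record, per the caller's dialect.

    Returns None when no rule applies — a missing VAF is a valid outcome
    and is never fabricated.
    """
    alt = rec.alts[alt_index] if rec.alts and alt_index < len(rec.alts) else None

    if caller is CallerId.LOFREQ:
        af = rec.info.get("AF") if "AF" in rec.info else None
        return _clamp_fraction(_scalar(af, alt_index))

    if tumor_sample is None or tumor_sample not in rec.samples:
        return None
    sample = rec.samples[tumor_sample]

    if caller is CallerId.VARSCAN:
        freq = _scalar(sample.get("FREQ") if "FREQ" in sample else None, alt_index)
        if freq is None:
            return _ad_ratio(sample, alt_index)
        text = str(freq).strip()
        if text.endswith("%"):
            try:
                return _clamp_fraction(float(text[:-1]) / 100.0)
            except ValueError:
                return None
        return _clamp_fraction(text)

    if caller is CallerId.STRELKA:
        if alt is None:
            return None
        return _strelka_vaf(rec, sample, alt.upper())

    if caller is CallerId.MUTECT:
        fa = _scalar(sample.get("FA") if "FA" in sample else None, alt_index)
        v = _clamp_fraction(fa)
        return v if v is not None else _ad_ratio(sample, alt_index)

    if caller in (CallerId.MUTECT2, CallerId.VARDICT):
        af = _scalar(sample.get("AF") if "AF" in sample else None, alt_index)
        v = _clamp_fraction(af)
        return v if v is not None else _ad_ratio(sample, alt_index)

    # MuSE and any future dialect: allelic-depth ratio fallback
    vaf = _ad_ratio(sample, alt_index)
    if vaf is None:
        logger.debug("%s: no VAF rule matched at %s:%s", caller, rec.contig, rec.pos)
    return vaf


# ---------------------------------------------------------------------------
# VCF reading

_METRIC_FIELDS = ("DP", "MQ", "NM", "SSC", "QSS", "TLOD")


def _native_metrics(rec: pysam.VariantRecord, sample_name: str | None) -> dict[str, str]:
    metrics: dict[str, str] = {}
    if rec.qual is not None:
        metrics["QUAL"] = f"{rec.qual:g}"
    for fld in _METRIC_FIELDS:
        if fld in rec.info:
            metrics[fld] = _format_value(rec.info[fld])
        elif sample_name and sample_name in rec.samples and fld in rec.samples[sample_name]:
            metrics[fld] = _format_value(rec.samples[sample_name][fld])
    return metrics


def _format_value(value) -> str:
    if isinstance(value, (tuple, list)):
        return ",".join(_format_value(v) for v in value)
    if isinstance(value, float):
        return f"{value:g}"
    if isinstance(value, bytes):
        return value.decode()
    return str(value)


def _vardict_metrics(rec: pysam.VariantRecord, vaf: float | None, sample_name: str | None) -> VarDictMetrics | None:
    sample = rec.samples[sample_name] if sample_name and sample_name in rec.samples else None

    def grab(fld):
        if fld in rec.info:
            return _scalar(rec.info[fld])
        if sample is not None and fld in sample:
            return _scalar(sample[fld])
        return None

    dp, mq, nm = grab("DP"), grab("MQ"), grab("NM")
    if vaf is None or dp is None or mq is None or nm is None or rec.qual is None:
        return None
    try:
        return VarDictMetrics(float(vaf), float(dp), float(mq), float(nm), float(rec.qual))
    except (TypeError, ValueError):
        return None


def read_caller_vcf(
    path,
    caller: CallerId,
    tumor_sample: str | None = None,
    keep_filtered: bool = False,
    reference=None,
    contig_style: str | None = None,
    apply_vardict_filter: bool = True,
) -> CallSet:
    """Read one caller's VCF into a :class:`CallSet`.

    Multiallelic rows are split, keys are normalized (left-align + trim when
    ``reference`` provides the contig, trim-only otherwise), the tumor VAF
    is extracted per the caller's dialect, and by default only records whose
    FILTER is PASS or "." are kept.  For VarDict the post-calling hard
    filter is additionally applied when its five metrics are present.

    ``reference`` may be a :class:`~somaticmerge.variants.FastaReference`,
    an :class:`~somaticmerge.variants.InMemoryReference`, or a FASTA path.
    """
    if isinstance(reference, (str, Path)):
        from .variants import FastaReference

        reference = FastaReference(reference)

    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read VCF {path}: {exc}") from exc

    with vcf:
        sample_name = resolve_tumor_sample(vcf, caller, tumor_sample)
        records: list[CallerRecord] = []
        for rec in vcf:
            filters = list(rec.filter.keys())
            native_pass = not filters or filters == ["PASS"]
            if not native_pass and not keep_filtered:
                continue
            if rec.alts is None:
                continue
            contig = harmonize_contig(rec.contig, contig_style)
            keys = split_multiallelic(contig, rec.pos, rec.ref, list(rec.alts))
            ctx = reference.context(contig) if reference is not None else None
            for alt_index, key in enumerate(keys):
                try:
                    norm = normalize(key, ctx)
                except ReferenceMismatchError as exc:
                    logger.warning("%s: dropping record (%s)", caller, exc)
                    continue
                vaf = extract_tumor_vaf(rec, caller, sample_name, alt_index)
                metrics = _native_metrics(rec, sample_name)
                if not native_pass:
                    metrics["FILTER"] = ";".join(filters)
                if caller is CallerId.VARDICT and apply_vardict_filter:
                    vdm = _vardict_metrics(rec, vaf, sample_name)
                    if vdm is None:
                        logger.warning(
                            "VarDict metrics incomplete at %s; record kept unfiltered", norm
                        )
                    elif not vardict_hard_filter(vdm):
                        continue
                records.append(
                    CallerRecord(norm, caller, vaf, native_pass, metrics)
                )
    return CallSet.from_records(caller, records, source_path=str(path))
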