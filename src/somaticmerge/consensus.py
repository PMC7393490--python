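"""Merging call sets and deciding variants by majority or VAF-adaptive voting.

The ensemble takes the union of all callers' variants (keyed on normalized
``contig:pos:ref>alt``) and decides each one:

* **majority voting** — PASS when the variant was called by at least a
  cutoff fraction (default 50%, with ceiling: 4 of 7) or an absolute
  minimum count of the configured callers;

* **VAF-adaptive voting** (SNVs only) — PASS when any of three conditions
  holds, tested in order:

  1. both anchor callers (Strelka and MuTect2 by default) called it and
     the tumor VAF lies in [low_vaf, mid_vaf] (default [0.03, 0.1]);
  2. the tumor VAF is below low_vaf and MuTect2 called it;
  3. the plain majority rule passes.

  Rules 1–2 exist because only a few callers detect low and ultra-low VAF
  SNVs reliably; a hard majority cutoff would reject those sites outright.

The reported tumor VAF is taken from the highest-priority supporting
caller that produced one, and the confidence is tagged in FILTER:
``PASS`` (majority consensus), ``LowVAF`` (rescued by rules 1–2 only),
``Rejected`` otherwise.
"""

from __future__ import annotations

import logging
import math
import urllib.parse
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pysam

from .callers import CallerId, CallerRecord, CallSet
from .variants import VariantClass, VariantKey, classify, variant_sort_key

__all__ = [
    "Scheme",
    "Confidence",
    "VotingConfig",
    "MergedVariant",
    "MergedTable",
    "merge",
    "majority_vote",
    "vaf_adaptive_vote",
    "select_reported_vaf",
    "decide_all",
    "write_merged_vcf",
    "read_merged_vcf",
]

logger = logging.getLogger(__name__)

DEFAULT_PRIORITY: tuple[CallerId, ...] = (
    CallerId.MUTECT2,
    CallerId.STRELKA,
    CallerId.LOFREQ,
    CallerId.MUSE,
    CallerId.MUTECT,
    CallerId.VARDICT,
    CallerId.VARSCAN,
)


class Scheme(str, Enum):
    MAJORITY = "majority"
    VAF_ADAPTIVE = "vaf_adaptive"


class Confidence(str, Enum):
    CONSENSUS = "CONSENSUS"
    LOWVAF = "LOWVAF"
    REJECT = "REJECT"


@dataclass(frozen=True)
class VotingConfig:
    """Voting scheme, caller sets and thresholds for one merge run."""

    snv_callers: tuple[CallerId, ...]
    indel_callers: tuple[CallerId, ...]
    snv_scheme: Scheme = Scheme.MAJORITY
    indel_scheme: Scheme = Scheme.MAJORITY
    cutoff: float = 0.5
    min_callers: int | None = None
    anchor_callers: frozenset[CallerId] = frozenset({CallerId.STRELKA, CallerId.MUTECT2})
    low_vaf_anchor: CallerId = CallerId.MUTECT2
    low_vaf: float = 0.03
    mid_vaf: float = 0.1
    priority: tuple[CallerId, ...] = DEFAULT_PRIORITY
    min_tumor_vaf: float | None = None

    def __post_init__(self) -> None:
        if not self.snv_callers and not self.indel_callers:
            raise ValueError("at least one caller set must be non-empty")
        for name, callers in (("snv_callers", self.snv_callers), ("indel_callers", self.indel_callers)):
            if len(set(callers)) != len(callers):
                raise ValueError(f"{name} contains duplicates")
        if not (0.0 < self.low_vaf < self.mid_vaf < 1.0):
            raise ValueError("need 0 < low_vaf < mid_vaf < 1")
        if self.min_callers is None:
            if not (0.0 < self.cutoff <= 1.0):
                raise ValueError("fraction cutoff must be in (0, 1]")
        elif self.min_callers < 1:
            raise ValueError("min_callers must be >= 1")
        if self.snv_scheme is Scheme.VAF_ADAPTIVE and self.snv_callers:
            if not self.anchor_callers <= set(self.snv_callers):
                raise ValueError(
                    "anchor callers must be a subset of snv_callers under the adaptive scheme"
                )

    def callers_for(self, vclass: VariantClass) -> tuple[CallerId, ...]:
        return self.snv_callers if vclass is VariantClass.SNV else self.indel_callers

    def scheme_for(self, vclass: VariantClass) -> Scheme:
        return self.snv_scheme if vclass is VariantClass.SNV else self.indel_scheme

    @classmethod
    def preset(cls, name: str, **overrides) -> "VotingConfig":
        """Recommended caller-set presets.

        ``wgs``  — SNV majority with LoFreq+MuSE+MuTect2+Strelka; INDEL
        majority with LoFreq+MuTect2+Strelka.

        ``deep`` — for deep targeted / exome data: SNV VAF-adaptive with
        LoFreq+MuTect2+Strelka+VarDict; INDEL majority with
        LoFreq+MuTect2+VarDict.
        """
        presets = {
            "wgs": dict(
                snv_scheme=Scheme.MAJORITY,
                snv_callers=(CallerId.LOFREQ, CallerId.MUSE, CallerId.MUTECT2, CallerId.STRELKA),
                indel_scheme=Scheme.MAJORITY,
                indel_callers=(CallerId.LOFREQ, CallerId.MUTECT2, CallerId.STRELKA),
            ),
            "deep": dict(
                snv_scheme=Scheme.VAF_ADAPTIVE,
                snv_callers=(CallerId.LOFREQ, CallerId.MUTECT2, CallerId.STRELKA, CallerId.VARDICT),
                indel_scheme=Scheme.MAJORITY,
                indel_callers=(CallerId.LOFREQ, CallerId.MUTECT2, CallerId.VARDICT),
            ),
        }
        if name not in presets:
            raise ValueError(f"unknown preset {name!r}; available: {sorted(presets)}")
        params = dict(presets[name])
        params.update(overrides)
        return cls(**params)


@dataclass
class MergedVariant:
    key: VariantKey
    vclass: VariantClass
    support: dict[CallerId, CallerRecord]
    tumor_vaf: float | None = None
    decision: bool = False
    confidence: Confidence = Confidence.REJECT
    vote_rule: int | None = None
    reject_reason: str | None = None

    @property
    def n_support(self) -> int:
        return len(self.support)


@dataclass
class MergedTable:
    variants: dict[VariantKey, MergedVariant]
    config: VotingConfig

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        for key in sorted(self.variants, key=variant_sort_key):
            yield self.variants[key]

    def passing(self) -> list[MergedVariant]:
        return [v for v in self if v.decision]


# ---------------------------------------------------------------------------
# voting primitives


def majority_vote(
    n_support: int, n_callers: int, cutoff: float = 0.5, min_count: int | None = None
) -> bool:
    """PASS iff support reaches the cutoff.

    Fraction mode uses a ceiling — 50% of 7 callers means at least 4.
    """
    if n_support < 0 or n_callers < 1:
        raise ValueError("need n_support >= 0 and n_callers >= 1")
    if min_count is not None:
        return n_support >= min_count
    threshold = math.ceil(cutoff * n_callers - 1e-9)
    return n_support >= max(threshold, 1)


def vaf_adaptive_vote(
    support: Iterable[CallerId],
    tumor_vaf: float | None,
    config: VotingConfig,
    n_callers: int,
) -> tuple[bool, int | None]:
    """Apply the three adaptive PASS conditions in order; return
    (decision, first satisfied rule or None).

    A missing tumor VAF disables rules 1–2; rule 3 (plain majority) still
    applies.
    """
    supporters = set(support)
    if tumor_vaf is not None:
        if config.anchor_callers <= supporters and config.low_vaf <= tumor_vaf <= config.mid_vaf:
            return True, 1
        if tumor_vaf < config.low_vaf and config.low_vaf_anchor in supporters:
            return True, 2
    if majority_vote(len(supporters), n_callers, config.cutoff, config.min_callers):
        return True, 3
    return False, None


def select_reported_vaf(
    support: Mapping[CallerId, CallerRecord], priority: Sequence[CallerId]
) -> float | None:
    """Tumor VAF of the highest-priority supporting caller that has one."""
    if not support:
        raise ValueError("support must be non-empty")
    ordered = [c for c in priority if c in support]
    ordered += [c for c in support if c not in priority]  # unprioritized last
    for caller in ordered:
        vaf = support[caller].tumor_vaf
        if vaf is not None:
            return vaf
    return None


# ---------------------------------------------------------------------------
# merge + decide


def merge(callsets: Sequence[CallSet], config: VotingConfig) -> MergedTable:
    """Union of all call sets, restricted to the configured caller set for
    each variant's class; support lists exactly the callers that called it."""
    if len(callsets) < 2:
        raise ValueError("need at least two call sets to combine")
    seen: set[CallerId] = set()
    for cs in callsets:
        if cs.caller in seen:
            raise ValueError(f"duplicate call set for caller {cs.caller}")
        seen.add(cs.caller)
        if cs.caller not in set(config.snv_callers) | set(config.indel_callers):
            raise ValueError(
                f"caller {cs.caller} does not appear in the voting configuration"
            )

    variants: dict[VariantKey, MergedVariant] = {}
    for cs in callsets:
        for key, rec in cs.records.items():
            vclass = classify(key)
            if cs.caller not in config.callers_for(vclass):
                continue
            mv = variants.get(key)
            if mv is None:
                mv = MergedVariant(key, vclass, {})
                variants[key] = mv
            mv.support[cs.caller] = rec
    return decide_all(MergedTable(variants, config))


def decide_all(table: MergedTable) -> MergedTable:
    """Fill decision, confidence, vote rule and reported VAF for every variant."""
    config = table.config
    for mv in table.variants.values():
        callers = config.callers_for(mv.vclass)
        n_callers = len(callers)
        mv.tumor_vaf = select_reported_vaf(mv.support, config.priority) if mv.support else None

        maj = majority_vote(mv.n_support, n_callers, config.cutoff, config.min_callers)
        if config.scheme_for(mv.vclass) is Scheme.VAF_ADAPTIVE and mv.vclass is VariantClass.SNV:
            decision, rule = vaf_adaptive_vote(mv.support, mv.tumor_vaf, config, n_callers)
        else:
            decision, rule = maj, (3 if maj else None)

        mv.decision = decision
        mv.vote_rule = rule
        mv.reject_reason = None
        if decision:
            mv.confidence = Confidence.CONSENSUS if maj else Confidence.LOWVAF
        else:
            mv.confidence = Confidence.REJECT
            mv.reject_reason = "vote"
        # optional min-VAF demotion, applied after voting
        if (
            mv.decision
            and config.min_tumor_vaf is not None
            and mv.tumor_vaf is not None
            and mv.tumor_vaf < config.min_tumor_vaf
        ):
            mv.decision = False
            mv.confidence = Confidence.REJECT
            mv.reject_reason = "min_tumor_vaf"
    return table


# ---------------------------------------------------------------------------
# VCF output

_FILTER_LABEL = {
    Confidence.CONSENSUS: "PASS",
    Confidence.LOWVAF: "LowVAF",
    Confidence.REJECT: "Rejected",
}


def _sanitize(value: str) -> str:
    """INFO-safe string: percent-encode VCF metacharacters."""
    return urllib.parse.quote(str(value), safe="abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789.+-*/_:|%")


def write_merged_vcf(table: MergedTable, path, emit_all: bool = True) -> None:
    """Write the decided table as a sorted VCF v4.2.

    INFO carries CALLERS, NCALLERS, TVAF, VOTE_RULE plus the per-caller
    native metrics namespaced ``<CALLER>_<KEY>``; FILTER carries the
    confidence tag.  With ``emit_all=False`` only PASS/LowVAF records are
    written.
    """
    header = pysam.VariantHeader()
    header.add_line('##source=somaticmerge')
    for contig in sorted({mv.key.contig for mv in table.variants.values()},
                         key=lambda c: variant_sort_key(VariantKey(c, 1, "A", "C"))[0]):
        header.add_line(f"##contig=<ID={contig}>")
    header.add_line('##FILTER=<ID=LowVAF,Description="Rescued by the VAF-adaptive rules only">')
    header.add_line('##FILTER=<ID=Rejected,Description="Failed the configured voting scheme">')
    header.add_line('##INFO=<ID=CALLERS,Number=.,Type=String,Description="Supporting callers">')
    header.add_line('##INFO=<ID=NCALLERS,Number=1,Type=Integer,Description="Number of supporting callers">')
    header.add_line('##INFO=<ID=TVAF,Number=1,Type=Float,Description="Selected tumor variant allele fraction">')
    header.add_line('##INFO=<ID=VOTE_RULE,Number=1,Type=String,Description="First satisfied voting rule (1|2|3|none)">')

    metric_keys: list[tuple[CallerId, str]] = []
    seen_mk: set[str] = set()
    for mv in table.variants.values():
        for caller, rec in mv.support.items():
            for mkey in rec.native_metrics:
                name = f"{caller.value.upper()}_{mkey}"
                if name not in seen_mk:
                    seen_mk.add(name)
                    metric_keys.append((caller, mkey))
                    header.add_line(
                        f'##INFO=<ID={name},Number=1,Type=String,'
                        f'Description="{caller.value} native {mkey}">'
                    )

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for mv in table:
            if not emit_all and not mv.decision:
                continue
            rec = out.new_record(
                contig=mv.key.contig,
                start=mv.key.pos - 1,
                alleles=(mv.key.ref, mv.key.alt),
            )
            rec.filter.add(_FILTER_LABEL[mv.confidence])
            ordered = [c for c in table.config.priority if c in mv.support]
            ordered += [c for c in mv.support if c not in table.config.priority]
            rec.info["CALLERS"] = ",".join(c.value for c in ordered)
            rec.info["NCALLERS"] = mv.n_support
            if mv.tumor_vaf is not None:
                rec.info["TVAF"] = float(mv.tumor_vaf)
            rec.info["VOTE_RULE"] = str(mv.vote_rule) if mv.vote_rule else "none"
            for caller in ordered:
                for mkey, mval in mv.support[caller].native_metrics.items():
                    rec.info[f"{caller.value.upper()}_{mkey}"] = _sanitize(mval)
            out.write(rec)


def read_merged_vcf(path) -> list[dict]:
    """Re-read a merged VCF into plain dicts (round-trip/inspection aid)."""
    rows: list[dict] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            rows.append(
                {
                    "key": VariantKey(rec.contig, rec.pos, rec.ref, rec.alts[0]),
                    "filter": list(rec.filter.keys())[0] if list(rec.filter.keys()) else "PASS",
                    "callers": tuple(CallerId.parse(c) for c in info["CALLERS"]),
                    "ncallers": int(info["NCALLERS"]),
                    "tvaf": float(info["TVAF"]) if "TVAF" in info else None,
                    "vote_rule": info["VOTE_RULE"],
                }
            )
    return rows


def summarize(table: MergedTable) -> dict:
    """Run summary: counts per FILTER label, per vote rule, and an
    NCALLERS histogram."""
    by_filter: dict[str, int] = {}
    by_rule: dict[str, int] = {}
    ncallers: dict[int, int] = {}
    for mv in table.variants.values():
        lab = _FILTER_LABEL[mv.confidence]
        by_filter[lab] = by_filter.get(lab, 0) + 1
        rule = str(mv.vote_rule) if mv.vote_rule else "none"
        by_rule[rule] = by_rule.get(rule, 0) + 1
        ncallers[mv.n_support] = ncallers.get(mv.n_support, 0) + 1
    return {
        "n_variants": len(table),
        "by_filter": dict(sorted(by_filter.items())),
        "by_rule": dict(sorted(by_rule.items())),
        "ncallers_histogram": {str(k): v for k, v in sorted(ncallers.items())},
    }
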