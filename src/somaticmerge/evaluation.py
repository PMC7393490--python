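"""Benchmarking call sets against a truth set within comparison regions.

Matching is exact on the normalized ``(contig, pos, ref, alt)`` key for
both SNVs and indels.  Counting the truth-set variants as the positives:

* recall    = TP / (TP + FN)
* precision = TP / (TP + FP)
* FDR       = 1 - precision
* FNR       = 1 - recall
* F1        = 2 * precision * recall / (precision + recall)

Evaluation can be restricted to comparison regions (e.g. the intersection
of capture targets and high-confidence regions), supplied as BED
(0-based half-open) and applied to the 1-based VCF anchor base.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pysam

from .variants import (
    VariantClass,
    VariantKey,
    classify,
    harmonize_contig,
    normalize,
    split_multiallelic,
    ReferenceMismatchError,
)

__all__ = [
    "RegionSet",
    "EvalReport",
    "intersect_regions",
    "restrict",
    "compare",
    "load_keys",
    "stratify_by_class",
    "make_vaf_stratifier",
    "write_reports",
]

logger = logging.getLogger(__name__)


class RegionSet:
    """Per-contig collection of merged, sorted 0-based half-open intervals."""

    def __init__(self, intervals: Mapping[str, Iterable[tuple[int, int]]]):
        self._by_contig: dict[str, list[tuple[int, int]]] = {}
        for contig, ivs in intervals.items():
            merged = self._merge(list(ivs))
            if merged:
                self._by_contig[contig] = merged

    @staticmethod
    def _merge(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
        out: list[tuple[int, int]] = []
        for start, end in sorted(ivs):
            if end <= start:
                continue
            if out and start <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], end))
            else:
                out.append((start, end))
        return out

    @classmethod
    def from_intervals(cls, intervals: Iterable[tuple[str, int, int]]) -> "RegionSet":
        table: dict[str, list[tuple[int, int]]] = {}
        for contig, start, end in intervals:
            table.setdefault(contig, []).append((start, end))
        return cls(table)

    @classmethod
    def from_bed(cls, path) -> "RegionSet":
        intervals = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"{path}: malformed BED line {line!r}")
                intervals.append((fields[0], int(fields[1]), int(fields[2])))
        return cls.from_intervals(intervals)

    @property
    def contigs(self) -> list[str]:
        return sorted(self._by_contig)

    def intervals(self, contig: str) -> list[tuple[int, int]]:
        return list(self._by_contig.get(contig, []))

    def __eq__(self, other) -> bool:
        return isinstance(other, RegionSet) and self._by_contig == other._by_contig

    def __bool__(self) -> bool:
        return bool(self._by_contig)

    def total_length(self) -> int:
        return sum(e - s for ivs in self._by_contig.values() for s, e in ivs)

    def contains(self, contig: str, pos: int) -> bool:
        """True when the 1-based position's base (0-based pos-1) lies in a
        region, i.e. start < pos <= end."""
        import bisect

        ivs = self._by_contig.get(contig)
        if not ivs:
            return False
        i = bisect.bisect_right(ivs, (pos - 1, float("inf"))) - 1
        return i >= 0 and ivs[i][0] <= pos - 1 < ivs[i][1]


def intersect_regions(a: RegionSet, b: RegionSet) -> RegionSet:
    """Interval intersection by a two-pointer sweep over merged intervals."""
    out: dict[str, list[tuple[int, int]]] = {}
    for contig in a.contigs:
        xs, ys = a.intervals(contig), b.intervals(contig)
        i = j = 0
        acc: list[tuple[int, int]] = []
        while i < len(xs) and j < len(ys):
            start = max(xs[i][0], ys[j][0])
            end = min(xs[i][1], ys[j][1])
            if start < end:
                acc.append((start, end))
            if xs[i][1] <= ys[j][1]:
                i += 1
            else:
                j += 1
        if acc:
            out[contig] = acc
    return RegionSet(out)


def restrict(calls: Iterable[VariantKey], regions: RegionSet | None) -> set[VariantKey]:
    """Keep keys whose anchor base lies inside the regions."""
    if regions is None:
        return set(calls)
    return {k for k in calls if regions.contains(k.contig, k.pos)}


@dataclass(frozen=True)
class EvalReport:
    """Counts and derived metrics for one stratum.

    ``recall``/``fnr``/``f1`` are None when the truth set is empty (the
    rates are undefined; the counts are still reported).  ``precision`` is
    0 by convention when there are no calls.
    """

    stratum: str
    tp: int
    fp: int
    fn: int
    recall: float | None
    precision: float
    fdr: float
    fnr: float | None
    f1: float | None

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int, stratum: str = "ALL") -> "EvalReport":
        precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
        recall = tp / (tp + fn) if (tp + fn) > 0 else None
        fnr = None if recall is None else 1.0 - recall
        if recall is None:
            f1 = None
        elif precision + recall == 0:
            f1 = 0.0
        else:
            f1 = 2 * precision * recall / (precision + recall)
        return cls(stratum, tp, fp, fn, recall, precision, 1.0 - precision, fnr, f1)

    def to_dict(self) -> dict:
        return {
            "stratum": self.stratum,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "recall": self.recall,
            "precision": self.precision,
            "fdr": self.fdr,
            "fnr": self.fnr,
            "f1": self.f1,
        }


def compare(
    calls: Iterable[VariantKey],
    truth: Iterable[VariantKey],
    regions: RegionSet | None = None,
    stratifier: Callable[[VariantKey], str] | None = None,
) -> list[EvalReport]:
    """Exact-key comparison of calls against truth inside the regions.

    Returns an overall "ALL" report first, followed by per-stratum
    reports when a stratifier is given.
    """
    call_set = restrict(calls, regions)
    truth_set = restrict(truth, regions)

    tp_keys = call_set & truth_set
    fp_keys = call_set - truth_set
    fn_keys = truth_set - call_set

    reports = [EvalReport.from_counts(len(tp_keys), len(fp_keys), len(fn_keys), "ALL")]
    if stratifier is not None:
        strata = sorted(
            {stratifier(k) for k in call_set | truth_set}
        )
        for label in strata:
            reports.append(
                EvalReport.from_counts(
                    sum(1 for k in tp_keys if stratifier(k) == label),
                    sum(1 for k in fp_keys if stratifier(k) == label),
                    sum(1 for k in fn_keys if stratifier(k) == label),
                    label,
                )
            )
    return reports


def stratify_by_class(key: VariantKey) -> str:
    return classify(key).value


def make_vaf_stratifier(
    vaf_by_key: Mapping[VariantKey, float], bins: Sequence[float] = (0.01, 0.03, 0.1, 0.3)
) -> Callable[[VariantKey], str]:
    """Label keys by the VAF bin of their (truth or reported) VAF;
    keys without a VAF go to "VAF:unknown"."""

    def stratifier(key: VariantKey) -> str:
        vaf = vaf_by_key.get(key)
        if vaf is None:
            return "VAF:unknown"
        lo = 0.0
        for edge in bins:
            if vaf < edge:
                return f"VAF:[{lo:g},{edge:g})"
            lo = edge
        return f"VAF:[{lo:g},1]"

    return stratifier


def load_keys(
    path,
    reference=None,
    contig_style: str | None = None,
    accept_filters: Sequence[str] = ("PASS",),
    include_filtered: bool = False,
) -> set[VariantKey]:
    """Caller-agnostic key loading for truth or merged call VCFs.

    Records whose FILTER is "." or in ``accept_filters`` are kept (all
    records with ``include_filtered``); multiallelics are split and keys
    normalized (trim-only without a reference).
    """
    if isinstance(reference, (str, Path)):
        from .variants import FastaReference

        reference = FastaReference(reference)
    keys: set[VariantKey] = set()
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            filters = list(rec.filter.keys())
            ok = not filters or all(f in accept_filters for f in filters)
            if not ok and not include_filtered:
                continue
            if rec.alts is None:
                continue
            contig = harmonize_contig(rec.contig, contig_style)
            ctx = reference.context(contig) if reference is not None else None
            for key in split_multiallelic(contig, rec.pos, rec.ref, list(rec.alts)):
                try:
                    keys.add(normalize(key, ctx))
                except ReferenceMismatchError as exc:
                    logger.warning("dropping truth/call record: %s", exc)
    return keys


def write_reports(reports: Sequence[EvalReport], tsv_path=None, json_path=None) -> None:
    """One row per stratum, as TSV and/or JSON."""
    rows = [r.to_dict() for r in reports]
    if tsv_path is not None:
        with open(tsv_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0]), delimiter="\t")
            writer.writeheader()
            for row in rows:
                writer.writerow(
                    {
                        k: (f"{v:.6f}" if isinstance(v, float) else ("NA" if v is None else v))
                        for k, v in row.items()
                    }
                )
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(rows, fh, indent=2)
            fh.write("\n")
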