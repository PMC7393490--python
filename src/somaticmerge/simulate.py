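"""Seeded synthetic data: reference, truth set and per-caller VCF dialects.

The generator emulates the setting the ensemble is designed for — a
tumor-normal pair with somatic variants across a wide VAF range, called by
several callers with different sensitivity-vs-VAF behavior:

* a pseudo-random reference contig with implanted homopolymer and
  dinucleotide repeats (so indel left-alignment is actually exercised);
* a truth set whose VAF distribution mimics a dilution series: the
  default strata are the expected heterozygous VAFs of 1–50% spike-in
  mixtures (0.005, 0.01, 0.025, 0.05, 0.1, 0.25), allocated exactly
  (largest-remainder) for reproducibility;
* one VCF per caller in that caller's native dialect (Strelka tier
  counts, VarScan FREQ percent strings, LoFreq INFO-only AF, FORMAT
  AF/FA/AD for the rest), with per-caller logistic sensitivity curves,
  Gaussian reported-VAF noise and Poisson false positives.

Caller detections are independent given the truth — a deliberate
simplification (real callers are correlated through the reads).
Every output records the seed in its header; identical seeds give
byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pyfaidx

from .callers import CallerId
from .variants import ReferenceContext, VariantClass, VariantKey, classify, normalize

__all__ = [
    "CallerProfile",
    "TruthSpec",
    "TruthSet",
    "SimulatedCalls",
    "SimulatedDataset",
    "DEFAULT_PROFILES",
    "DILUTION_STRATA",
    "make_reference",
    "make_truth",
    "make_caller_vcfs",
    "simulate_dataset",
]

_BASES = np.array(list("ACGT"))

#: expected heterozygous VAFs of a 1..50% two-sample dilution series
DILUTION_STRATA: tuple[tuple[float, float], ...] = tuple(
    (v, 1.0 / 6.0) for v in (0.005, 0.01, 0.025, 0.05, 0.1, 0.25)
)


@dataclass(frozen=True)
class CallerProfile:
    """Logistic sensitivity-vs-VAF curve plus error rates for one caller.

    Detection probability at true VAF v is
    ``sens_max / (1 + exp(-sens_slope * (v - sens_midpoint)))``;
    ``fp_rate`` is expected false positives per megabase.
    """

    caller: CallerId
    sens_midpoint: float = 0.02
    sens_slope: float = 150.0
    sens_max: float = 0.95
    fp_rate: float = 3.0
    vaf_noise_sd: float = 0.004

    def __post_init__(self) -> None:
        if not (0.0 <= self.sens_max <= 1.0):
            raise ValueError("sens_max must be in [0, 1]")
        if self.fp_rate < 0 or self.vaf_noise_sd < 0:
            raise ValueError("fp_rate and vaf_noise_sd must be non-negative")

    def detection_prob(self, vaf: float) -> float:
        z = self.sens_slope * (vaf - self.sens_midpoint)
        z = max(min(z, 700.0), -700.0)
        return self.sens_max / (1.0 + math.exp(-z))

    @classmethod
    def constant(cls, caller: CallerId, sensitivity: float, fp_rate: float = 0.0) -> "CallerProfile":
        """VAF-independent detection probability (midpoint 0 with a steep
        slope, so any positive VAF sits on the plateau)."""
        return cls(caller, sens_midpoint=0.0, sens_slope=1e6, sens_max=sensitivity,
                   fp_rate=fp_rate, vaf_noise_sd=0.0)

    @classmethod
    def perfect(cls, caller: CallerId) -> "CallerProfile":
        return cls.constant(caller, 1.0, 0.0)


#: defaults emulating the qualitative behavior seen in deep targeted data:
#: MuTect2 retains sensitivity at ultra-low VAF, Strelka is precise with few
#: false positives, VarDict is sensitive but noisier, VarScan loses
#: sensitivity below ~10% VAF.
DEFAULT_PROFILES: dict[CallerId, CallerProfile] = {
    CallerId.LOFREQ: CallerProfile(CallerId.LOFREQ, 0.02, 150.0, 0.95, 3.0, 0.004),
    CallerId.MUSE: CallerProfile(CallerId.MUSE, 0.03, 120.0, 0.92, 2.0, 0.004),
    CallerId.MUTECT: CallerProfile(CallerId.MUTECT, 0.03, 120.0, 0.90, 5.0, 0.005),
    CallerId.MUTECT2: CallerProfile(CallerId.MUTECT2, 0.008, 250.0, 0.95, 4.0, 0.004),
    CallerId.STRELKA: CallerProfile(CallerId.STRELKA, 0.015, 180.0, 0.97, 1.0, 0.003),
    CallerId.VARDICT: CallerProfile(CallerId.VARDICT, 0.01, 150.0, 0.97, 12.0, 0.006),
    CallerId.VARSCAN: CallerProfile(CallerId.VARSCAN, 0.08, 80.0, 0.90, 8.0, 0.005),
}


@dataclass(frozen=True)
class TruthSpec:
    contig_length: int = 100_000
    n_snv: int = 300
    n_indel: int = 60
    vaf_strata: tuple[tuple[float, float], ...] = DILUTION_STRATA
    max_indel_len: int = 6
    seed: int = 2020
    contig: str = "sim1"

    def __post_init__(self) -> None:
        total = sum(p for _, p in self.vaf_strata)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"stratum proportions sum to {total}, not 1")
        if any(not (0.0 < v <= 1.0) for v, _ in self.vaf_strata):
            raise ValueError("stratum VAFs must be in (0, 1]")
        if self.contig_length < 1000:
            raise ValueError("contig_length must be >= 1000")
        if self.max_indel_len < 1:
            raise ValueError("max_indel_len must be >= 1")


@dataclass
class TruthSet:
    contig: str
    contig_length: int
    records: list[tuple[VariantKey, float]]  # sorted by position
    seed: int

    @property
    def keys(self) -> set[VariantKey]:
        return {k for k, _ in self.records}

    @property
    def vaf_by_key(self) -> dict[VariantKey, float]:
        return dict(self.records)

    def write_vcf(self, path) -> None:
        lines = [
            "##fileformat=VCFv4.2",
            "##source=somaticmerge-simulator",
            f"##simulation_seed={self.seed}",
            f"##contig=<ID={self.contig},length={self.contig_length}>",
            '##INFO=<ID=TVAF,Number=1,Type=Float,Description="True tumor variant allele fraction">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
        ]
        for key, vaf in self.records:
            lines.append(
                f"{key.contig}\t{key.pos}\t.\t{key.ref}\t{key.alt}\t.\tPASS\tTVAF={vaf:.6f}"
            )
        Path(path).write_text("\n".join(lines) + "\n")

    def write_table(self, path) -> None:
        lines = ["contig\tpos\tref\talt\tvaf\tclass"]
        for key, vaf in self.records:
            lines.append(
                f"{key.contig}\t{key.pos}\t{key.ref}\t{key.alt}\t{vaf:.6f}\t{classify(key).value}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


def make_reference(
    length: int, seed: int, contig: str = "sim1", out_path=None
) -> tuple[ReferenceContext, Path | None]:
    """Deterministic pseudo-random DNA with implanted repeats.

    Homopolymer runs (6–12 bases, every ~1 kb) and dinucleotide repeats
    (every ~1.7 kb) are written over the random background so that indel
    representations are genuinely ambiguous and left-alignment matters.
    """
    if length < 1000:
        raise ValueError("length must be >= 1000")
    rng = np.random.default_rng(seed)
    seq = rng.choice(_BASES, size=length)
    for start in range(200, length - 20, 997):
        run_len = int(rng.integers(6, 13))
        base = str(rng.choice(_BASES))
        seq[start : start + run_len] = base
    for start in range(700, length - 24, 1709):
        pair = "".join(rng.choice(_BASES, size=2))
        if pair[0] == pair[1]:
            pair = pair[0] + ("T" if pair[0] != "T" else "A")
        n_rep = int(rng.integers(4, 8))
        repeat = list(pair * n_rep)
        seq[start : start + len(repeat)] = repeat
    sequence = "".join(seq)

    path = None
    if out_path is not None:
        path = Path(out_path)
        with open(path, "w") as fh:
            fh.write(f">{contig}\n")
            for i in range(0, length, 60):
                fh.write(sequence[i : i + 60] + "\n")
        pyfaidx.Faidx(str(path))  # write the .fai alongside
    return ReferenceContext.from_sequence(contig, sequence), path


def _stratum_counts(n: int, strata: Sequence[tuple[float, float]]) -> list[int]:
    """Deterministic largest-remainder allocation of n across strata."""
    raw = [n * p for _, p in strata]
    counts = [int(math.floor(x)) for x in raw]
    remainder = n - sum(counts)
    order = sorted(range(len(strata)), key=lambda i: (raw[i] - counts[i], i), reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def make_truth(spec: TruthSpec, ref: ReferenceContext) -> TruthSet:
    """Draw unique, normalized truth variants with exact stratum allocation."""
    rng = np.random.default_rng(spec.seed)
    length = spec.contig_length
    n_total = spec.n_snv + spec.n_indel
    if n_total > (length - 200) // 4:
        raise ValueError("variant density infeasible for this contig length")

    occupied: set[int] = set()

    def reserve(key: VariantKey) -> bool:
        span = range(key.pos - 1, key.pos + len(key.ref) + 1)
        if any(p in occupied for p in span):
            return False
        occupied.update(span)
        return True

    keys: list[VariantKey] = []
    attempts = 0
    while len(keys) < spec.n_snv:
        attempts += 1
        if attempts > 200 * n_total:
            raise RuntimeError("could not place truth SNVs; lower the density")
        pos = int(rng.integers(100, length - 100))
        ref_base = ref.fetch(pos, pos)
        if ref_base == "N":
            continue
        alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
        key = VariantKey(spec.contig, pos, ref_base, alt)
        if reserve(key):
            keys.append(key)

    n_indels = 0
    while n_indels < spec.n_indel:
        attempts += 1
        if attempts > 400 * n_total:
            raise RuntimeError("could not place truth indels; lower the density")
        pos = int(rng.integers(100, length - 100))
        size = int(rng.integers(1, spec.max_indel_len + 1))
        anchor = ref.fetch(pos, pos)
        if rng.random() < 0.5:  # insertion
            ins = "".join(rng.choice(_BASES, size=size))
            key = VariantKey(spec.contig, pos, anchor, anchor + ins)
        else:  # deletion
            ref_allele = ref.fetch(pos, pos + size)
            key = VariantKey(spec.contig, pos, ref_allele, anchor)
        key = normalize(key, ref)
        if reserve(key):
            keys.append(key)
            n_indels += 1

    # exact per-class stratum allocation, shuffled assignment
    snv_keys = [k for k in keys if classify(k) is VariantClass.SNV]
    indel_keys = [k for k in keys if classify(k) is VariantClass.INDEL]
    records: list[tuple[VariantKey, float]] = []
    for class_keys in (snv_keys, indel_keys):
        vafs: list[float] = []
        for (vaf, _), count in zip(spec.vaf_strata, _stratum_counts(len(class_keys), spec.vaf_strata)):
            vafs.extend([vaf] * count)
        order = rng.permutation(len(class_keys))
        for idx, key in zip(order, class_keys):
            records.append((key, vafs[int(idx)]))

    records.sort(key=lambda kv: (kv[0].pos, kv[0].ref, kv[0].alt))
    return TruthSet(spec.contig, length, records, spec.seed)


# ---------------------------------------------------------------------------
# per-caller dialect VCFs


@dataclass
class SimulatedCalls:
    caller: CallerId
    path: Path
    #: the VAF each record actually encodes after dialect quantization
    #: (count ratios for Strelka/MuSE, rounded percent for VarScan, ...)
    encoded_vafs: dict[VariantKey, float]
    n_false_positives: int


_HEADERS: dict[CallerId, tuple[list[str], list[str] | None]] = {
    CallerId.LOFREQ: (
        [
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="Raw depth">',
            '##INFO=<ID=AF,Number=1,Type=Float,Description="Allele frequency">',
        ],
        None,  # no sample columns
    ),
    CallerId.MUTECT: (
        [
            "##tumor_sample=SPL_T",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
            '##FORMAT=<ID=FA,Number=A,Type=Float,Description="Allele fraction">',
        ],
        ["SPL_T", "SPL_N"],  # tumor first: resolved via the header line
    ),
    CallerId.MUTECT2: (
        [
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
            '##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele fraction">',
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        ],
        ["NORMAL_X", "TUMOR_Y"],  # tumor resolved as the last column
    ),
    CallerId.MUSE: (
        [
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        ],
        ["TUMOR", "NORMAL"],
    ),
    CallerId.STRELKA: (
        [
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
            '##FORMAT=<ID=AU,Number=2,Type=Integer,Description="A counts tier1,tier2">',
            '##FORMAT=<ID=CU,Number=2,Type=Integer,Description="C counts tier1,tier2">',
            '##FORMAT=<ID=GU,Number=2,Type=Integer,Description="G counts tier1,tier2">',
            '##FORMAT=<ID=TU,Number=2,Type=Integer,Description="T counts tier1,tier2">',
            '##FORMAT=<ID=TAR,Number=2,Type=Integer,Description="Ref-supporting reads tier1,tier2">',
            '##FORMAT=<ID=TIR,Number=2,Type=Integer,Description="Indel-supporting reads tier1,tier2">',
        ],
        ["NORMAL", "TUMOR"],
    ),
    CallerId.VARDICT: (
        [
            '##INFO=<ID=MQ,Number=1,Type=Float,Description="Mean mapping quality">',
            '##INFO=<ID=NM,Number=1,Type=Float,Description="Mean mismatches in reads">',
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
            '##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele fraction">',
        ],
        ["TUMOR", "NORMAL"],
    ),
    CallerId.VARSCAN: (
        [
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
            '##FORMAT=<ID=FREQ,Number=1,Type=String,Description="Variant allele frequency (percent)">',
        ],
        ["NORMAL", "TUMOR"],
    ),
}


def _dialect_row(caller: CallerId, key: VariantKey, vaf: float, dp: int) -> tuple[str, float]:
    """One VCF body line in the caller's dialect plus the VAF it encodes."""
    alt_n = int(round(vaf * dp))
    alt_n = min(max(alt_n, 1), dp)
    ref_n = dp - alt_n
    base = f"{key.contig}\t{key.pos}\t.\t{key.ref}\t{key.alt}"

    if caller is CallerId.LOFREQ:
        enc = float(f"{vaf:.6f}")
        return f"{base}\t120\tPASS\tDP={dp};AF={vaf:.6f}", enc
    if caller is CallerId.MUTECT:
        enc = float(f"{vaf:.6f}")
        line = (
            f"{base}\t.\tPASS\t.\tGT:AD:DP:FA\t"
            f"0/1:{ref_n},{alt_n}:{dp}:{vaf:.6f}\t0/0:{dp},0:{dp}:0.00"
        )
        return line, enc
    if caller is CallerId.MUTECT2:
        enc = float(f"{vaf:.6f}")
        line = (
            f"{base}\t.\tPASS\t.\tGT:AD:AF:DP\t"
            f"0/0:{dp},0:0.00:{dp}\t0/1:{ref_n},{alt_n}:{vaf:.6f}:{dp}"
        )
        return line, enc
    if caller is CallerId.MUSE:
        enc = alt_n / dp
        line = (
            f"{base}\t.\tPASS\t.\tGT:AD:DP\t"
            f"0/1:{ref_n},{alt_n}:{dp}\t0/0:{dp},0:{dp}"
        )
        return line, enc
    if caller is CallerId.STRELKA:
        enc = alt_n / dp
        if classify(key) is VariantClass.SNV:
            counts = {b: 0 for b in "ACGT"}
            counts[key.ref] = ref_n
            counts[key.alt] = alt_n
            tumor = f"{dp}:" + ":".join(f"{counts[b]},{counts[b]}" for b in "ACGT")
            ncounts = {b: 0 for b in "ACGT"}
            ncounts[key.ref] = dp
            normal = f"{dp}:" + ":".join(f"{ncounts[b]},{ncounts[b]}" for b in "ACGT")
            return f"{base}\t.\tPASS\t.\tDP:AU:CU:GU:TU\t{normal}\t{tumor}", enc
        tumor = f"{dp}:{ref_n},{ref_n}:{alt_n},{alt_n}"
        normal = f"{dp}:{dp},{dp}:0,0"
        return f"{base}\t.\tPASS\t.\tDP:TAR:TIR\t{normal}\t{tumor}", enc
    if caller is CallerId.VARDICT:
        enc = float(f"{vaf:.6f}")
        line = (
            f"{base}\t120\tPASS\tMQ=60.0;NM=0.5\tGT:DP:AF\t"
            f"0/1:{dp}:{vaf:.6f}\t0/0:{dp}:0.00"
        )
        return line, enc
    if caller is CallerId.VARSCAN:
        pct = f"{vaf * 100:.4f}"
        enc = float(pct) / 100.0
        line = (
            f"{base}\t.\tPASS\t.\tGT:DP:FREQ\t"
            f"0/0:{dp}:0.0000%\t0/1:{dp}:{pct}%"
        )
        return line, enc
    raise ValueError(f"no dialect writer for {caller}")


def make_caller_vcfs(
    truth: TruthSet,
    profiles: Sequence[CallerProfile],
    ref: ReferenceContext,
    out_dir,
    seed: int,
    depth: int = 1600,
) -> dict[CallerId, SimulatedCalls]:
    """Emit one dialect-faithful VCF per caller profile.

    Each truth variant is detected by caller c with probability
    ``c.detection_prob(true VAF)`` independently across callers; reported
    VAFs get Gaussian noise (clamped into (0, 1]); false positives are
    SNVs placed uniformly at unused positions, ``fp_rate`` per megabase.
    """
    callers = [p.caller for p in profiles]
    if len(set(callers)) != len(callers):
        raise ValueError("profiles must cover distinct callers")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    truth_positions = {
        p for key, _ in truth.records for p in range(key.pos - 1, key.pos + len(key.ref) + 1)
    }
    children = np.random.SeedSequence(seed).spawn(len(profiles))
    out: dict[CallerId, SimulatedCalls] = {}
    for profile, child in zip(profiles, children):
        rng = np.random.default_rng(child)
        rows: list[tuple[int, str, str, str, float]] = []  # pos, ref, alt, line, enc
        encoded: dict[VariantKey, float] = {}

        for key, true_vaf in truth.records:
            if rng.random() >= profile.detection_prob(true_vaf):
                continue
            vaf = true_vaf
            if profile.vaf_noise_sd > 0:
                vaf = float(np.clip(true_vaf + rng.normal(0.0, profile.vaf_noise_sd), 1e-4, 1.0))
            dp = max(50, int(rng.poisson(depth)))
            line, enc = _dialect_row(profile.caller, key, vaf, dp)
            rows.append((key.pos, key.ref, key.alt, line, enc))
            encoded[key] = enc

        n_fp = int(rng.poisson(profile.fp_rate * truth.contig_length / 1e6))
        placed = 0
        fp_used: set[int] = set()
        while placed < n_fp:
            pos = int(rng.integers(100, truth.contig_length - 100))
            if pos in truth_positions or pos in fp_used:
                continue
            ref_base = ref.fetch(pos, pos)
            if ref_base == "N":
                continue
            alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
            key = VariantKey(truth.contig, pos, ref_base, alt)
            vaf = float(rng.uniform(0.005, 0.15))
            dp = max(50, int(rng.poisson(depth)))
            line, enc = _dialect_row(profile.caller, key, vaf, dp)
            rows.append((pos, ref_base, alt, line, enc))
            encoded[key] = enc
            fp_used.add(pos)
            placed += 1

        rows.sort(key=lambda r: (r[0], r[1], r[2]))
        info_lines, samples = _HEADERS[profile.caller]
        header = [
            "##fileformat=VCFv4.2",
            "##source=somaticmerge-simulator",
            f"##simulation_seed={seed}",
            f"##simulated_caller={profile.caller.value}",
            f"##contig=<ID={truth.contig},length={truth.contig_length}>",
            *info_lines,
        ]
        columns = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
        if samples is not None:
            columns += "\tFORMAT\t" + "\t".join(samples)
        header.append(columns)

        path = out_dir / f"{profile.caller.value.lower()}.vcf"
        path.write_text("\n".join(header + [r[3] for r in rows]) + "\n")
        out[profile.caller] = SimulatedCalls(profile.caller, path, encoded, n_fp)
    return out


@dataclass
class SimulatedDataset:
    reference_path: Path
    reference: ReferenceContext
    truth: TruthSet
    truth_vcf: Path
    truth_table: Path
    calls: dict[CallerId, SimulatedCalls]


def simulate_dataset(
    out_dir,
    spec: TruthSpec | None = None,
    profiles: Sequence[CallerProfile] | None = None,
    depth: int = 1600,
) -> SimulatedDataset:
    """Reference + truth + per-caller VCFs under one output directory.

    The caller-VCF seed is derived from ``spec.seed`` so the whole dataset
    is a function of a single integer.
    """
    spec = spec or TruthSpec()
    if profiles is None:
        profiles = [DEFAULT_PROFILES[c] for c in CallerId]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    ref, ref_path = make_reference(
        spec.contig_length, spec.seed, spec.contig, out_dir / "reference.fa"
    )
    truth = make_truth(spec, ref)
    truth_vcf = out_dir / "truth.vcf"
    truth_table = out_dir / "truth.tsv"
    truth.write_vcf(truth_vcf)
    truth.write_table(truth_table)
    caller_seed = int(np.random.SeedSequence(spec.seed).spawn(1)[0].generate_state(1)[0] % (2**31))
    calls = make_caller_vcfs(truth, profiles, ref, out_dir, caller_seed, depth)
    return SimulatedDataset(ref_path, ref, truth, truth_vcf, truth_table, calls)
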