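"""Somatic-variant filtering, sgRNA-region exclusion, burden and
trinucleotide mutation spectra.

Two built-in filter profiles:

* ``MURINE`` — tumor coverage strictly > 20x, normal coverage strictly
  > 10x, tumor VAF >= 0.1.
* ``MSK`` — tumor coverage >= 10x with >= 5 alt reads, tumor VAF >= 5%,
  matched-normal VAF < 7%.

Indel calls additionally pass a tandem-repeat screen on the 20 nucleotides
immediately downstream: a call fails if any motif of length <= 6 occurs as
three or more consecutive tandem copies within that window (the classic
microsatellite false-positive signature). Mutations falling in sgRNA-
targeted regions (padded) are excluded as engineered drivers before any
evolutionary analysis.

Spectra: somatic SNVs are mapped to the 96 pyrimidine-context classes
(purine-reference variants are reverse-complemented), deduplicated within
each mouse across its samples, and counted per cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "VariantCall",
    "FilterProfile",
    "FilterResult",
    "MURINE",
    "MSK",
    "Vaf",
    "TrinucSpectrum",
    "SPECTRUM_CLASSES",
    "rederive_vaf",
    "apply_filter",
    "repeat_filter",
    "exclude_sgrna_regions",
    "mutational_burden",
    "trinuc_class",
    "trinuc_spectrum",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class VariantCall:
    """One candidate somatic mutation with tumor/normal read support."""

    chrom: str
    pos: int  # 1-based (VCF convention)
    ref: str
    alt: str
    variant_class: str  # SNV | insertion | deletion
    tumor_depth: int
    tumor_alt: int
    normal_depth: int
    normal_alt: int
    caller: str = "unknown"
    downstream_20nt: Optional[str] = None
    exonic: bool = True
    trinuc_context: Optional[str] = None  # 3-mer centered on the SNV base

    def __post_init__(self) -> None:
        if not (0 <= self.tumor_alt <= self.tumor_depth):
            raise ValueError(
                f"{self.chrom}:{self.pos} tumor_alt must lie in [0, tumor_depth]"
            )
        if not (0 <= self.normal_alt <= self.normal_depth):
            raise ValueError(
                f"{self.chrom}:{self.pos} normal_alt must lie in [0, normal_depth]"
            )
        if self.downstream_20nt is not None and len(self.downstream_20nt) != 20:
            raise ValueError("downstream_20nt must be exactly 20 nucleotides")
        if self.variant_class not in ("SNV", "insertion", "deletion"):
            raise ValueError(f"unknown variant_class {self.variant_class!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def tumor_vaf(self) -> float:
        return rederive_vaf(self.tumor_alt, self.tumor_depth).value

    @property
    def normal_vaf(self) -> float:
        return rederive_vaf(self.normal_alt, self.normal_depth).value


class Vaf(NamedTuple):
    value: float
    zero_depth: bool


def rederive_vaf(alt: int, depth: int) -> Vaf:
    """Variant allele fraction alt/depth; zero depth yields 0.0 with a flag."""
    if depth < 0 or alt < 0:
        raise ValueError("counts must be non-negative")
    if alt > depth:
        raise ValueError(f"alt reads ({alt}) exceed depth ({depth})")
    if depth == 0:
        return Vaf(0.0, True)
    return Vaf(alt / depth, False)


@dataclass(frozen=True)
class FilterProfile:
    """Threshold set for somatic-variant filtering.

    ``strict_depth`` selects strict ``>`` comparison for the depth
    thresholds (murine profile) versus inclusive ``>=`` (human MSK profile).
    ``max_normal_vaf`` of ``None`` disables the matched-normal VAF cap.
    """

    name: str
    min_tumor_depth: int
    min_normal_depth: int
    min_tumor_alt: int
    min_tumor_vaf: float
    max_normal_vaf: Optional[float] = None
    strict_depth: bool = False

    def __post_init__(self) -> None:
        if min(self.min_tumor_depth, self.min_normal_depth, self.min_tumor_alt) < 0:
            raise ValueError("thresholds must be non-negative")
        if not (0 <= self.min_tumor_vaf <= 1):
            raise ValueError("min_tumor_vaf must lie in [0, 1]")


MURINE = FilterProfile(
    name="murine",
    min_tumor_depth=20,
    min_normal_depth=10,
    min_tumor_alt=0,
    min_tumor_vaf=0.1,
    max_normal_vaf=None,
    strict_depth=True,
)

MSK = FilterProfile(
    name="msk",
    min_tumor_depth=10,
    min_normal_depth=0,
    min_tumor_alt=5,
    min_tumor_vaf=0.05,
    max_normal_vaf=0.07,
    strict_depth=False,
)

PROFILES = {"murine": MURINE, "msk": MSK}


@dataclass
class FilterResult:
    kept: list[VariantCall]
    rejected: list[tuple[VariantCall, str]]  # (variant, first failing rule id)

    @property
    def reasons(self) -> pd.Series:
        return pd.Series([r for _, r in self.rejected], dtype=object).value_counts()


def _first_failure(v: VariantCall, p: FilterProfile) -> Optional[str]:
    deep_enough = (lambda x, t: x > t) if p.strict_depth else (lambda x, t: x >= t)
    if not deep_enough(v.tumor_depth, p.min_tumor_depth):
        return "tumor_depth"
    if not deep_enough(v.normal_depth, p.min_normal_depth):
        return "normal_depth"
    if v.tumor_alt < p.min_tumor_alt:
        return "tumor_alt"
    if v.tumor_vaf < p.min_tumor_vaf:
        return "tumor_vaf"
    if p.max_normal_vaf is not None and not (v.normal_vaf < p.max_normal_vaf):
        return "normal_vaf"
    return None


def apply_filter(
    variants: Iterable[VariantCall], profile: FilterProfile
) -> FilterResult:
    """Keep variants passing every enabled threshold; rejected variants carry
    the id of the first failing rule (tumor_depth, normal_depth, tumor_alt,
    tumor_vaf, normal_vaf). Idempotent: filtering the kept set again changes
    nothing."""
    kept, rejected = [], []
    for v in variants:
        reason = _first_failure(v, profile)
        if reason is None:
            kept.append(v)
        else:
            rejected.append((v, reason))
    return FilterResult(kept, rejected)


def repeat_filter(downstream_20nt: str, mode: str = "tandem") -> bool:
    """Screen the 20 nt downstream of an indel for repetitive sequence.

    Returns True (pass) unless some motif of length 1..6 is repeated more
    than two times, i.e. occurs three or more times. In the default
    ``tandem`` mode the copies must be consecutive and lie entirely within
    the window; ``mode="any"`` counts occurrences anywhere in the window
    (a far stricter sensitivity-analysis setting). ``N`` never matches.
    """
    seq = downstream_20nt.upper()
    if len(seq) != 20:
        raise ValueError("downstream context must be exactly 20 nucleotides")
    if set(seq) - set("ACGTN"):
        raise ValueError(f"invalid nucleotides in {downstream_20nt!r}")
    if mode not in ("tandem", "any"):
        raise ValueError("mode must be 'tandem' or 'any'")
    n = len(seq)
    for k in range(1, 7):
        if mode == "tandem":
            for start in range(0, n - 3 * k + 1):
                motif = seq[start : start + k]
                if "N" in motif:
                    continue
                if seq[start : start + 3 * k] == motif * 3:
                    return False
        else:
            counts: dict[str, int] = {}
            for start in range(0, n - k + 1):
                motif = seq[start : start + k]
                if "N" in motif:
                    continue
                counts[motif] = counts.get(motif, 0) + 1
                if counts[motif] >= 3:
                    return False
    return True


def exclude_sgrna_regions(
    variants: Sequence[VariantCall],
    targeted_regions: Sequence[tuple[str, int, int]],
    pad: int = 50,
) -> list[VariantCall]:
    """Drop variants overlapping any sgRNA-targeted interval padded by
    ``pad`` bases; targeted regions are BED-style 0-based half-open. The
    variant's reference span [pos-1, pos-1+len(ref)) is used for overlap."""
    if pad < 0:
        raise ValueError("pad must be non-negative")
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in targeted_regions:
        if end <= start:
            raise ValueError(f"malformed interval {chrom}:{start}-{end}")
        trees.setdefault(chrom, IntervalTree()).addi(max(0, start - pad), end + pad)
    if not trees:
        return list(variants)
    kept = []
    for v in variants:
        tree = trees.get(v.chrom)
        span0 = v.pos - 1
        if tree is None or not tree.overlap(span0, span0 + max(1, len(v.ref))):
            kept.append(v)
    return kept


def mutational_burden(n_kept_exonic: int, callable_size_mb: float) -> float:
    """Somatic exonic mutations per callable megabase."""
    if callable_size_mb <= 0:
        raise ValueError("callable_size_mb must be positive")
    if n_kept_exonic < 0:
        raise ValueError("mutation count must be non-negative")
    return n_kept_exonic / callable_size_mb


def callable_size_mb(targets: Sequence[tuple[str, int, int]]) -> float:
    """Total span of BED target intervals in Mb."""
    return sum(end - start for _, start, end in targets) / 1e6


# ---------------------------------------------------------------------------
# Trinucleotide spectra
# ---------------------------------------------------------------------------

_SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

SPECTRUM_CLASSES: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in _SUBSTITUTIONS
    for five in "ACGT"
    for three in "ACGT"
)


def trinuc_class(ref: str, alt: str, context: str) -> str:
    """Map an SNV to its pyrimidine-context class, e.g. ``A[C>T]G``.

    ``context`` is the reference 3-mer centered on the variant base. Purine
    reference alleles are reverse-complemented onto the pyrimidine strand.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(ref) != 1 or len(alt) != 1 or len(context) != 3:
        raise ValueError("SNV requires 1-base ref/alt and a 3-mer context")
    if context[1] != ref:
        raise ValueError(f"context {context} does not center on ref {ref}")
    if ref in "AG":
        ref, alt, context = _revcomp(ref), _revcomp(alt), _revcomp(context)
    cls = f"{context[0]}[{ref}>{alt}]{context[2]}"
    if cls not in _CLASS_SET:
        raise ValueError(f"invalid trinucleotide class {cls}")
    return cls


_CLASS_SET = frozenset(SPECTRUM_CLASSES)


@dataclass
class TrinucSpectrum:
    """Counts and frequencies over the 96 pyrimidine-context SNV classes."""

    cohort: str
    counts: pd.Series  # indexed by SPECTRUM_CLASSES

    @property
    def frequencies(self) -> pd.Series:
        total = self.counts.sum()
        if total == 0:
            return self.counts.astype(float)
        return self.counts / total

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"class": self.counts.index, "count": self.counts.values,
             "frequency": self.frequencies.values}
        )


def trinuc_spectrum(
    records: Sequence[tuple[str, VariantCall]],
    mouse_of: Mapping[str, str],
    cohort_of: Mapping[str, str] | None = None,
) -> dict[str, TrinucSpectrum]:
    """Build per-cohort trinucleotide spectra from SNV calls.

    Parameters
    ----------
    records
        Sequence of (sample_id, VariantCall) pairs; non-SNV records are
        ignored.
    mouse_of
        sample id -> mouse id. Identical (chrom, pos, ref, alt) mutations
        observed in several samples of one mouse count once.
    cohort_of
        sample id -> cohort label (e.g. ``metastatic`` vs
        ``primary+cell-line``). Omit for a single pooled ``ALL`` cohort.
        A pooled ``ALL`` spectrum (counts summed over cohorts after
        per-mouse dedup) is always included when cohorts are given.
    """
    seen: dict[str, set] = {}
    per_cohort: dict[str, pd.Series] = {}
    pooled_seen: set = set()
    pooled = pd.Series(0, index=list(SPECTRUM_CLASSES), dtype=int)
    for sample, v in records:
        if v.variant_class != "SNV":
            continue
        if v.trinuc_context is None:
            raise ValueError(f"SNV {v.chrom}:{v.pos} lacks a trinucleotide context")
        mouse = mouse_of[sample]
        cohort = "ALL" if cohort_of is None else cohort_of[sample]
        cls = trinuc_class(v.ref, v.alt, v.trinuc_context)
        dedup_key = (mouse,) + v.key
        if dedup_key not in seen.setdefault(cohort, set()):
            seen[cohort].add(dedup_key)
            per_cohort.setdefault(
                cohort, pd.Series(0, index=list(SPECTRUM_CLASSES), dtype=int)
            )[cls] += 1
        if dedup_key not in pooled_seen:
            pooled_seen.add(dedup_key)
            pooled[cls] += 1
    out = {c: TrinucSpectrum(c, counts) for c, counts in per_cohort.items()}
    if cohort_of is not None:
        out["ALL"] = TrinucSpectrum("ALL", pooled)
    return out
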