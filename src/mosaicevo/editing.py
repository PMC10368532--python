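"""sgRNA editing-efficiency scoring from cut-site pileups.

For every base position in a window centered on the expected Cas9 cut site,
the tumor/normal excess of altered reads is summarized as the log odds ratio
of a 2x2 table (tumor ref/alt vs normal ref/alt). Log odds ratios are
z-transformed against all window positions of the same gene, and the z scores
near the cut site are averaged over genes to give one editing-efficiency
score per sample. A separate rule calls an individual targeted gene
"altered" from read-level evidence: either a reproducible alteration pattern
(>= 2 reads with the identical pattern) at the cut site, or a coverage drop
below half of the healthy-control median over the targeted region.

Notes on conventions
--------------------
* The odds ratio is the closed-form sample odds ratio with a
  Haldane-Anscombe +0.5 correction applied to all four cells whenever any
  cell is zero; the two-sided Fisher exact p-value is computed alongside and
  carried in the result but does not enter the score.
* The z-transform uses the population (n-denominator) standard deviation
  over a gene's window positions; a zero-variance gene maps to all-zero z.
* Because z scores of a gene average to zero over its whole window by
  construction, the per-gene summary averages z only over the central
  positions (default |offset| <= 2, where Cas9 indels concentrate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CutSitePileup",
    "PositionOdds",
    "EditingScoreResult",
    "GeneAlteredCall",
    "UndefinedPositionError",
    "position_log_odds",
    "gene_z_scores",
    "sample_editing_score",
    "score_pileups",
    "call_gene_altered",
]


class UndefinedPositionError(ValueError):
    """All four counts of a 2x2 position table are zero."""


@dataclass
class CutSitePileup:
    """Per-position ref/alt read counts in a window around a cut site.

    ``offsets`` run contiguously from -W to +W (0 = expected cut site);
    ``compartment`` is ``"tumor"`` or ``"normal"``.
    """

    gene: str
    sample: str
    compartment: str
    offsets: np.ndarray
    ref_count: np.ndarray
    alt_count: np.ndarray

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=int)
        self.ref_count = np.asarray(self.ref_count, dtype=int)
        self.alt_count = np.asarray(self.alt_count, dtype=int)
        if self.compartment not in ("tumor", "normal"):
            raise ValueError(f"compartment must be tumor|normal, got {self.compartment!r}")
        if not (len(self.offsets) == len(self.ref_count) == len(self.alt_count)):
            raise ValueError("offsets/ref_count/alt_count length mismatch")
        if (self.ref_count < 0).any() or (self.alt_count < 0).any():
            raise ValueError("read counts must be non-negative")
        w = self.offsets.max()
        if not np.array_equal(self.offsets, np.arange(-w, w + 1)):
            raise ValueError("offsets must be contiguous and symmetric around 0")

    @property
    def halfwidth(self) -> int:
        return int(self.offsets.max())


class PositionOdds(NamedTuple):
    ln_odds_ratio: float
    p_value: float


def position_log_odds(
    tumor_ref: int, tumor_alt: int, normal_ref: int, normal_alt: int
) -> PositionOdds:
    """Natural-log sample odds ratio for one window position.

    OR = (tumor_alt * normal_ref) / (tumor_ref * normal_alt), with 0.5 added
    to every cell when any cell is zero. The two-sided Fisher exact p-value
    of the uncorrected table is returned alongside.

    Raises
    ------
    UndefinedPositionError
        If all four counts are zero.
    """
    cells = (tumor_ref, tumor_alt, normal_ref, normal_alt)
    if any(c < 0 for c in cells):
        raise ValueError("counts must be non-negative")
    if all(c == 0 for c in cells):
        raise UndefinedPositionError("all four counts are zero; odds ratio undefined")
    _, p = stats.fisher_exact([[tumor_ref, tumor_alt], [normal_ref, normal_alt]])
    tr, ta, nr, na = (float(c) for c in cells)
    if min(cells) == 0:
        tr, ta, nr, na = tr + 0.5, ta + 0.5, nr + 0.5, na + 0.5
    return PositionOdds(math.log((ta * nr) / (tr * na)), float(p))


def gene_z_scores(ln_odds_ratios: Sequence[float]) -> np.ndarray:
    """z-transform per-position log odds ratios against the gene's window.

    Uses the mean and population standard deviation over the gene's own
    window positions; if the sd is zero every z is zero.
    """
    x = np.asarray(ln_odds_ratios, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 window positions to z-transform")
    sd = x.std()  # population (ddof=0) convention
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def sample_editing_score(
    z_by_gene: Mapping[str, Mapping[int, float]], central_halfwidth: int = 2
) -> float:
    """Overall per-sample editing efficiency.

    Mean over genes of the mean z score at offsets |offset| <=
    ``central_halfwidth``. Each gene must provide z values covering the
    central offsets.
    """
    if not z_by_gene:
        raise ValueError("empty gene set")
    gene_means = []
    for gene, zmap in z_by_gene.items():
        central = [z for off, z in zmap.items() if abs(off) <= central_halfwidth]
        if not central:
            raise ValueError(f"gene {gene}: no z values within +/-{central_halfwidth}")
        gene_means.append(float(np.mean(central)))
    return float(np.mean(gene_means))


@dataclass
class EditingScoreResult:
    """Editing score for one sample: per-position table (gene, offset,
    ln_odds_ratio, p_value, z), per-gene central z, and the sample score."""

    per_position: pd.DataFrame
    gene_central_z: pd.Series
    sample_score: float
    central_halfwidth: int = 2


def score_pileups(
    pairs: Mapping[str, tuple[CutSitePileup, CutSitePileup]],
    central_halfwidth: int = 2,
) -> EditingScoreResult:
    """Score one sample from per-gene (tumor, normal) pileup pairs.

    Positions where both compartments have zero coverage are dropped before
    the z-transform (they carry no information and their OR is undefined).
    """
    rows = []
    z_by_gene: dict[str, dict[int, float]] = {}
    for gene, (tumor, normal) in pairs.items():
        if tumor.compartment != "tumor" or normal.compartment != "normal":
            raise ValueError(f"gene {gene}: expected (tumor, normal) pileup pair")
        if not np.array_equal(tumor.offsets, normal.offsets):
            raise ValueError(f"gene {gene}: tumor/normal windows differ")
        keep, lnors, pvals = [], [], []
        for i, off in enumerate(tumor.offsets):
            try:
                odds = position_log_odds(
                    tumor.ref_count[i], tumor.alt_count[i],
                    normal.ref_count[i], normal.alt_count[i],
                )
            except UndefinedPositionError:
                continue
            keep.append(int(off))
            lnors.append(odds.ln_odds_ratio)
            pvals.append(odds.p_value)
        z = gene_z_scores(lnors)
        z_by_gene[gene] = dict(zip(keep, z))
        for off, lor, p, zi in zip(keep, lnors, pvals, z):
            rows.append((gene, off, lor, p, zi))
    table = pd.DataFrame(
        rows, columns=["gene", "offset", "ln_odds_ratio", "p_value", "z"]
    )
    score = sample_editing_score(z_by_gene, central_halfwidth)
    central = pd.Series(
        {
            g: float(np.mean([z for o, z in zm.items() if abs(o) <= central_halfwidth]))
            for g, zm in z_by_gene.items()
        },
        name="central_z",
    )
    return EditingScoreResult(table, central, score, central_halfwidth)


@dataclass
class GeneAlteredCall:
    gene: str
    altered: bool
    evidence: tuple[str, ...] = field(default_factory=tuple)
    supporting_read_count: int = 0
    coverage_fraction_of_control_median: float = float("nan")


def call_gene_altered(
    gene: str,
    cut_site_read_patterns: Iterable[str],
    region_coverage: float,
    control_median_coverage: float,
    combine: str = "or",
) -> GeneAlteredCall:
    """Call a targeted gene altered from read-level cut-site evidence.

    Two evidence modes: ``pattern_reads`` — at least two reads share the
    identical base-alteration pattern at the cut site; ``coverage_drop`` —
    region coverage below 50% of the healthy-control median. By default the
    clauses combine with OR (frameshift indels need not depress coverage and
    homozygous deletions need not leave altered reads); ``combine="and"``
    gives the strict conjunctive reading.
    """
    if control_median_coverage <= 0:
        raise ValueError("control_median_coverage must be positive")
    if combine not in ("or", "and"):
        raise ValueError("combine must be 'or' or 'and'")
    counts: dict[str, int] = {}
    for pat in cut_site_read_patterns:
        counts[pat] = counts.get(pat, 0) + 1
    best = max(counts.values(), default=0)
    frac = region_coverage / control_median_coverage
    pattern_hit = best >= 2
    coverage_hit = frac < 0.5
    altered = (pattern_hit or coverage_hit) if combine == "or" else (
        pattern_hit and coverage_hit
    )
    evidence = tuple(
        name
        for name, hit in (("pattern_reads", pattern_hit), ("coverage_drop", coverage_hit))
        if hit
    )
    return GeneAlteredCall(
        gene=gene,
        altered=altered,
        evidence=evidence if altered else (),
        supporting_read_count=best,
        coverage_fraction_of_control_median=frac,
    )
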