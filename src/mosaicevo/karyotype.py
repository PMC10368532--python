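"""Copy-number, aneuploidy, ploidy/WGD and allelic-imbalance profiling.

Inputs are per-exon log2 tumor/normal read-depth ratios (SEG-like table),
a chromosome-arm definition table, an optional per-SNP B-allele-frequency
table and an optional cellularity-ploidy probability grid.

Calling logic
-------------
* Focal events: a region is amplified (deleted) only if *every* exon
  spanning it has |log2 ratio| >= 0.4 with a consistent sign; mixed-sign
  regions are neutral.
* Arm-level events: the weight-weighted mean exon log2 ratio per arm,
  thresholded at +/-0.2 (inclusive). Log ratios are median-centered per
  sample first so a genome-wide ploidy shift does not saturate every arm.
* Aneuploidy score: the number of arms called gained or lost. fCNA is the
  arm-length-weighted fraction of the genome in altered arms (an arm-count
  mode is available for cross-checks).
* Ploidy: at the grid cellularity nearest the purity estimate, the ploidy
  with maximal probability (ties -> lowest ploidy). WGD is called at
  ploidy >= 3.0 by default.
* Allelic imbalance: heterozygous SNPs are those with normal-compartment
  0.2 < BAF < 0.8 (strict) and >= 15x normal coverage; a segment's
  imbalance is the mean mirrored deviation |tumor BAF - 0.5|.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome import ArmDefinition

__all__ = [
    "KaryotypeProfile",
    "focal_call",
    "arm_calls",
    "aneuploidy_and_fcna",
    "select_ploidy",
    "call_wgd",
    "select_het_snps",
    "allelic_imbalance",
    "median_center",
    "karyotype_profile",
]

SEG_COLUMNS = ["chrom", "start", "end", "weight", "log2"]


def _check_seg(exons: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SEG_COLUMNS if c not in exons.columns]
    if missing:
        raise ValueError(f"exon table missing columns: {missing}")
    if (exons["end"] <= exons["start"]).any():
        raise ValueError("exon intervals must satisfy end > start")
    if (exons["weight"] < 0).any():
        raise ValueError("exon weights must be non-negative")
    return exons


def focal_call(exons_in_region: pd.DataFrame, threshold: float = 0.4) -> str:
    """Call a focal region amplification/deletion/neutral.

    Amplified iff every exon's log2 >= +threshold; deleted iff every exon's
    log2 <= -threshold; anything else (including mixed signs) is neutral.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    _check_seg(exons_in_region)
    if len(exons_in_region) == 0:
        raise ValueError("focal region contains no exons")
    log2 = exons_in_region["log2"].to_numpy(dtype=float)
    if (log2 >= threshold).all():
        return "amplification"
    if (log2 <= -threshold).all():
        return "deletion"
    return "neutral"


def _assign_arms(
    exons: pd.DataFrame, arms: Sequence[ArmDefinition]
) -> pd.Series:
    """Map each exon (by midpoint) to an arm id, or NA if unassigned."""
    for i, a in enumerate(arms):
        for b in arms[i + 1 :]:
            if a.chrom == b.chrom and a.start < b.end and b.start < a.end:
                raise ValueError(f"overlapping arm definitions: {a.arm} and {b.arm}")
    mid = (exons["start"] + exons["end"]) // 2
    out = pd.Series(pd.NA, index=exons.index, dtype=object)
    for a in arms:
        mask = (exons["chrom"] == a.chrom) & (mid >= a.start) & (mid < a.end)
        out[mask] = a.arm
    return out


def arm_calls(
    exons: pd.DataFrame,
    arms: Sequence[ArmDefinition],
    broad_threshold: float = 0.2,
) -> pd.DataFrame:
    """Per-arm gain/loss/neutral calls from the weighted mean exon log2.

    Returns a frame indexed by arm id with columns ``mean_log2``,
    ``n_exons`` and ``call`` (gain | loss | neutral | no_call). Thresholds
    are inclusive: mean >= +0.2 is a gain, <= -0.2 a loss.
    """
    _check_seg(exons)
    arm_of = _assign_arms(exons, arms)
    rows = []
    for a in arms:
        sub = exons[arm_of == a.arm]
        if len(sub) == 0:
            rows.append((a.arm, np.nan, 0, "no_call"))
            continue
        w = sub["weight"].to_numpy(dtype=float)
        if w.sum() == 0:
            w = np.ones_like(w)
        mean = float(np.average(sub["log2"].to_numpy(dtype=float), weights=w))
        if mean >= broad_threshold:
            call = "gain"
        elif mean <= -broad_threshold:
            call = "loss"
        else:
            call = "neutral"
        rows.append((a.arm, mean, len(sub), call))
    return pd.DataFrame(
        rows, columns=["arm", "mean_log2", "n_exons", "call"]
    ).set_index("arm")


def aneuploidy_and_fcna(
    calls: pd.DataFrame,
    arms: Sequence[ArmDefinition],
    mode: str = "length",
) -> tuple[int, float]:
    """Aneuploidy score (count of gained+lost arms) and fraction of genome
    altered. ``mode="length"`` weights altered arms by their length over the
    total arm span; ``mode="count"`` uses the altered-arm fraction."""
    if mode not in ("length", "count"):
        raise ValueError("mode must be 'length' or 'count'")
    length_of = {a.arm: a.length for a in arms}
    altered = calls.index[calls["call"].isin(["gain", "loss"])]
    score = len(altered)
    if mode == "count":
        fcna = score / len(arms)
    else:
        fcna = sum(length_of[a] for a in altered) / sum(length_of.values())
    return score, float(fcna)


GRID_COLUMNS = ["cellularity", "ploidy", "probability"]


def select_ploidy(grid: pd.DataFrame, purity_estimate: float) -> float:
    """Pick the ploidy with the largest predicted probability at the grid
    cellularity nearest the externally estimated purity; ties resolve to the
    lowest ploidy."""
    missing = [c for c in GRID_COLUMNS if c not in grid.columns]
    if missing:
        raise ValueError(f"grid missing columns: {missing}")
    if len(grid) == 0:
        raise ValueError("empty cellularity-ploidy grid")
    if not (0 < purity_estimate <= 1):
        raise ValueError("purity_estimate must lie in (0, 1]")
    if (grid["probability"] < 0).any():
        raise ValueError("grid probabilities must be non-negative")
    cells = grid["cellularity"].to_numpy(dtype=float)
    nearest = cells[np.argmin(np.abs(cells - purity_estimate))]
    at = grid[np.isclose(grid["cellularity"], nearest)]
    best = at["probability"].max()
    return float(at.loc[np.isclose(at["probability"], best), "ploidy"].min())


def call_wgd(ploidy: float, cutoff: float = 3.0) -> bool:
    """Whole-genome doubling: ploidy at or above the cutoff (default 3.0)."""
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    return ploidy >= cutoff


BAF_COLUMNS = [
    "chrom", "pos", "normal_ref", "normal_alt", "tumor_ref", "tumor_alt",
]


def _with_bafs(records: pd.DataFrame) -> pd.DataFrame:
    records = records.copy()
    ncov = records["normal_ref"] + records["normal_alt"]
    tcov = records["tumor_ref"] + records["tumor_alt"]
    with np.errstate(invalid="ignore", divide="ignore"):
        records["baf_normal"] = np.where(ncov > 0, records["normal_alt"] / ncov, np.nan)
        records["baf_tumor"] = np.where(tcov > 0, records["tumor_alt"] / tcov, np.nan)
    records["normal_coverage"] = ncov
    records["tumor_coverage"] = tcov
    return records


def select_het_snps(records: pd.DataFrame, min_coverage: int = 15) -> pd.DataFrame:
    """Heterozygous SNPs: normal coverage >= min_coverage and strictly
    0.2 < normal BAF < 0.8."""
    missing = [c for c in BAF_COLUMNS[:4] if c not in records.columns]
    if missing:
        raise ValueError(f"BAF table missing columns: {missing}")
    records = _with_bafs(records)
    keep = (
        (records["normal_coverage"] >= min_coverage)
        & (records["baf_normal"] > 0.2)
        & (records["baf_normal"] < 0.8)
    )
    return records[keep].reset_index(drop=True)


def allelic_imbalance(het_records: pd.DataFrame) -> Optional[float]:
    """Mean mirrored tumor-BAF deviation |BAF - 0.5| over heterozygous SNPs
    of a segment; 0.0 indicates allelic balance. Returns None (no-call) for
    an empty segment."""
    if len(het_records) == 0:
        return None
    baf = (
        het_records["baf_tumor"]
        if "baf_tumor" in het_records.columns
        else _with_bafs(het_records)["baf_tumor"]
    )
    return float(np.nanmean(np.abs(baf.to_numpy(dtype=float) - 0.5)))


def median_center(exons: pd.DataFrame) -> pd.DataFrame:
    """Subtract the weighted median log2 ratio (per sample) so arm calls are
    relative to the sample's modal copy state."""
    _check_seg(exons)
    out = exons.copy()
    vals = out["log2"].to_numpy(dtype=float)
    w = out["weight"].to_numpy(dtype=float)
    if w.sum() == 0:
        w = np.ones_like(w)
    order = np.argsort(vals)
    cw = np.cumsum(w[order])
    med = vals[order][np.searchsorted(cw, cw[-1] / 2)]
    out["log2"] = vals - med
    return out


@dataclass
class KaryotypeProfile:
    """Arm-level copy-number summary of one tumor sample."""

    sample: str
    arm_calls: pd.DataFrame
    aneuploidy_score: int
    fcna: float
    ploidy: float
    wgd: bool
    purity: float
    allelic_imbalance: Optional[float] = None

    def to_row(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{
                "sample": self.sample,
                "aneuploidy_score": self.aneuploidy_score,
                "fcna": self.fcna,
                "ploidy": self.ploidy,
                "wgd": self.wgd,
                "purity": self.purity,
                "allelic_imbalance": self.allelic_imbalance,
            }]
        )


def karyotype_profile(
    sample: str,
    exons: pd.DataFrame,
    arms: Sequence[ArmDefinition],
    grid: pd.DataFrame,
    purity: float,
    baf_records: Optional[pd.DataFrame] = None,
    broad_threshold: float = 0.2,
    wgd_cutoff: float = 3.0,
    center: bool = True,
) -> KaryotypeProfile:
    """Full per-sample karyotype: arm calls, aneuploidy score, fCNA, ploidy,
    WGD flag and (if BAF records are given) genome-wide allelic imbalance."""
    if center:
        exons = median_center(exons)
    calls = arm_calls(exons, arms, broad_threshold=broad_threshold)
    score, fcna = aneuploidy_and_fcna(calls, arms)
    ploidy = select_ploidy(grid, purity)
    imbalance = None
    if baf_records is not None and len(baf_records) > 0:
        het = select_het_snps(baf_records)
        imbalance = allelic_imbalance(het)
    return KaryotypeProfile(
        sample=sample,
        arm_calls=calls,
        aneuploidy_score=score,
        fcna=fcna,
        ploidy=ploidy,
        wgd=call_wgd(ploidy, wgd_cutoff),
        purity=purity,
        allelic_imbalance=imbalance,
    )
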