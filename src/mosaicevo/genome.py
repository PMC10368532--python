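"""Chromosome-arm definition tables.

Two built-in genome models:

* ``mm10`` — the mouse autosomes. Mouse chromosomes are acrocentric, so each
  of the 19 autosomes contributes a single "q" arm spanning the whole
  chromosome (19 arms total).
* ``grch37`` — the human autosomes, split at the centromere into p and q
  arms; the p arms of the acrocentric chromosomes (13, 14, 15, 21, 22) are
  excluded, giving the conventional 39 arms used for aneuploidy scoring.

Coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["ArmDefinition", "load_arms", "arms_to_frame", "BUILDS"]


@dataclass(frozen=True)
class ArmDefinition:
    """One chromosome arm: ``arm`` id (e.g. ``"5q"`` or ``"chr5q"``), contig,
    half-open interval and derived length in bases."""

    arm: str
    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"arm {self.arm}: end must exceed start")


# mm10 chromosome sizes (UCSC), one q arm per acrocentric autosome.
_MM10_SIZES = {
    "chr1": 195471971, "chr2": 182113224, "chr3": 160039680,
    "chr4": 156508116, "chr5": 151834684, "chr6": 149736546,
    "chr7": 145441459, "chr8": 129401213, "chr9": 124595110,
    "chr10": 130694993, "chr11": 122082543, "chr12": 120129022,
    "chr13": 120421639, "chr14": 124902244, "chr15": 104043685,
    "chr16": 98207768, "chr17": 94987271, "chr18": 90702639,
    "chr19": 61431566,
}

# GRCh37 autosome sizes and approximate centromere midpoints (UCSC gap track).
_GRCH37 = {
    "chr1": (249250621, 125000000), "chr2": (243199373, 93300000),
    "chr3": (198022430, 91000000), "chr4": (191154276, 50400000),
    "chr5": (180915260, 48400000), "chr6": (171115067, 61000000),
    "chr7": (159138663, 59900000), "chr8": (146364022, 45600000),
    "chr9": (141213431, 49000000), "chr10": (135534747, 40200000),
    "chr11": (135006516, 53700000), "chr12": (133851895, 35800000),
    "chr13": (115169878, 17900000), "chr14": (107349540, 17600000),
    "chr15": (102531392, 19000000), "chr16": (90354753, 36600000),
    "chr17": (81195210, 24000000), "chr18": (78077248, 17200000),
    "chr19": (59128983, 26500000), "chr20": (63025520, 27500000),
    "chr21": (48129895, 13200000), "chr22": (51304566, 14700000),
}

_ACROCENTRIC_HUMAN = {"chr13", "chr14", "chr15", "chr21", "chr22"}


def _mm10_arms() -> list[ArmDefinition]:
    return [
        ArmDefinition(arm=f"{c.removeprefix('chr')}q", chrom=c, start=0, end=n)
        for c, n in _MM10_SIZES.items()
    ]


def _grch37_arms() -> list[ArmDefinition]:
    arms = []
    for c, (size, cen) in _GRCH37.items():
        name = c.removeprefix("chr")
        if c not in _ACROCENTRIC_HUMAN:
            arms.append(ArmDefinition(arm=f"{name}p", chrom=c, start=0, end=cen))
        arms.append(ArmDefinition(arm=f"{name}q", chrom=c, start=cen, end=size))
    return arms


BUILDS = {"mm10": _mm10_arms, "grch37": _grch37_arms}


def load_arms(build: str) -> list[ArmDefinition]:
    """Return the arm table for a built-in genome build (``mm10``/``grch37``)."""
    try:
        return BUILDS[build]()
    except KeyError:
        raise ValueError(
            f"unknown genome build {build!r}; available: {sorted(BUILDS)}"
        ) from None


def arms_to_frame(arms: list[ArmDefinition]) -> pd.DataFrame:
    return pd.DataFrame(
        [(a.arm, a.chrom, a.start, a.end, a.length) for a in arms],
        columns=["arm", "chrom", "start", "end", "length"],
    )
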