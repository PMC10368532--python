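"""Synthetic somatic-mosaic tumor cohort generator.

Emulates the data shape of a multi-sample murine tumor study driven by in
vivo CRISPR editing: each mouse carries one clonal tree (a truncal trunk of
mutations shared by every sample, optionally two nested sample clades, and
a private leaf branch per sample), a karyotype with configurable arm-level
gains/losses and optional whole-genome doubling, a tumor purity, and
sgRNA cut-site editing at a configurable efficiency. Every quantity the
downstream modules estimate (arm states, ploidy, WGD, truncal/private
assignment, editing rate, signature mix) is retained as ground truth.

Model summary
-------------
* A heterozygous mutation with multiplicity m on a region of tumor total
  copy number C in a tumor of purity p has expected variant allele fraction
  ``p*m / (2*(1-p) + p*C)``; observed alt counts are binomial draws at that
  fraction with Poisson-distributed depth.
* Per-exon log2 read-depth ratios on an arm of tumor copy number C center
  on ``log2((2*(1-p) + p*C) / 2)`` with Gaussian noise.
* Heterozygous-SNP B-allele fractions in the tumor follow
  ``((1-p) + p*b) / (2*(1-p) + p*C)`` where b is the number of retained
  B-allele copies (which haplotype an arm loss removes is random per SNP).
* Cut-site pileups carry a flat background alteration rate (default 0.2%
  per base) everywhere and an editing excess confined to +/-2 bp around the
  expected cut site.
* Under whole-genome doubling, truncal mutations predate the doubling and
  carry multiplicity 2; private mutations stay at multiplicity 1.

All randomness flows from ``CohortConfig.seed`` through spawned
``numpy.random.Generator`` substreams, so a fixed config reproduces the
cohort byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .editing import CutSitePileup
from .filters import SPECTRUM_CLASSES, VariantCall, _revcomp
from .genome import ArmDefinition, load_arms

__all__ = [
    "CohortConfig",
    "CohortBundle",
    "MouseData",
    "SampleData",
    "ConfigError",
    "TrinucSnv",
    "default_signature_mix",
    "expected_vaf",
    "simulate_cohort",
    "simulate_cutsite_pileup",
    "simulate_trinuc_mutations",
    "simulate_allele_counts",
]


class ConfigError(ValueError):
    """Invalid cohort configuration; the message names the offending field."""


def default_signature_mix() -> dict[str, float]:
    """Aging-like default mix: 60% of mass on C>T transitions, weighted 3x
    toward CpG contexts (spontaneous cytidine deamination), remainder flat
    over the other 80 classes."""
    weights = {}
    for cls in SPECTRUM_CLASSES:
        if "[C>T]" in cls:
            weights[cls] = 3.0 if cls.endswith("G") else 1.0
        else:
            weights[cls] = 0.0
    ct_total = sum(weights.values())
    mix = {}
    for cls in SPECTRUM_CLASSES:
        if "[C>T]" in cls:
            mix[cls] = 0.6 * weights[cls] / ct_total
        else:
            mix[cls] = 0.4 / 80
    return mix


@dataclass
class CohortConfig:
    """Study-condition parameters for one simulated cohort.

    Defaults describe a realistic exome-sequenced mouse cohort: ~4 samples
    per mouse at 80x, purity 0.7, a truncal trunk of 50 mutations plus 20
    private mutations per sample, the recurrent arm events chr5 gain and
    chr12/chr16 loss, and 50% cut-site editing.
    """

    n_mice: int = 3
    samples_per_mouse: int = 4
    n_truncal_mutations: int = 50
    n_private_mutations_per_sample: int = 20
    purity: float = 0.7
    mean_depth: float = 80.0
    arm_events: tuple[tuple[str, int], ...] = (
        ("chr5", 3), ("chr12", 1), ("chr16", 1),
    )
    wgd: bool = False
    editing_rate: float = 0.5
    signature_mix: dict[str, float] = field(default_factory=default_signature_mix)
    noise_sd_log2: float = 0.1
    seed: int = 0
    # shape and nuisance knobs
    genome_build: str = "mm10"
    indel_fraction: float = 0.1
    repeat_context_fraction: float = 0.0
    background_alteration_rate: float = 0.002
    window_halfwidth: int = 25
    nested_clades: bool = False
    n_clade_mutations: int = 20
    n_exons_per_arm: int = 40
    n_baf_snps_per_arm: int = 30
    target_genes: tuple[str, ...] = ("Nf2", "Cdkn2a")
    include_driver_indels: bool = True

    def validate(self) -> None:
        counts = {
            "n_mice": self.n_mice,
            "samples_per_mouse": self.samples_per_mouse,
            "n_truncal_mutations": self.n_truncal_mutations,
            "n_private_mutations_per_sample": self.n_private_mutations_per_sample,
            "n_clade_mutations": self.n_clade_mutations,
            "n_exons_per_arm": self.n_exons_per_arm,
            "n_baf_snps_per_arm": self.n_baf_snps_per_arm,
        }
        for name, value in counts.items():
            if value < 0:
                raise ConfigError(f"{name} must be >= 0 (got {value})")
        if self.n_mice == 0 or self.samples_per_mouse == 0:
            raise ConfigError("n_mice and samples_per_mouse must be positive")
        if not (0 < self.purity <= 1):
            raise ConfigError(f"purity must lie in (0, 1] (got {self.purity})")
        if self.mean_depth <= 0:
            raise ConfigError(f"mean_depth must be positive (got {self.mean_depth})")
        if not (0 <= self.editing_rate <= 1):
            raise ConfigError(f"editing_rate must lie in [0, 1] (got {self.editing_rate})")
        if abs(sum(self.signature_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("signature_mix probabilities must sum to 1")
        if self.noise_sd_log2 < 0:
            raise ConfigError("noise_sd_log2 must be >= 0")
        if not (0 <= self.indel_fraction <= 1):
            raise ConfigError("indel_fraction must lie in [0, 1]")
        arms = {a.chrom for a in load_arms(self.genome_build)}
        for chrom, copy in self.arm_events:
            if chrom not in arms:
                raise ConfigError(f"arm_events: unknown chromosome {chrom!r}")
            if copy < 0:
                raise ConfigError(f"arm_events: negative copy number for {chrom}")


def expected_vaf(purity: float, copy_number: int, multiplicity: int = 1) -> float:
    """Expected VAF of a clonal heterozygous mutation: p*m / (2(1-p) + p*C)."""
    denom = 2 * (1 - purity) + purity * copy_number
    if denom == 0:
        return 0.0
    return purity * multiplicity / denom


def simulate_allele_counts(
    vaf: float, mean_depth: float, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (depths, alt counts): depth ~ Poisson(mean_depth) floored at 1,
    alt ~ Binomial(depth, vaf)."""
    depths = np.maximum(rng.poisson(mean_depth, size=n), 1)
    alts = rng.binomial(depths, vaf)
    return depths, alts


class TrinucSnv(NamedTuple):
    """One simulated SNV: reference-strand ref/alt and centered 3-mer
    context, plus its pyrimidine-normalized class label."""

    ref: str
    alt: str
    context: str
    trinuc_class: str


def simulate_trinuc_mutations(
    signature_mix: dict[str, float],
    n: int,
    seed: int | np.random.Generator = 0,
    purine_strand_fraction: float = 0.0,
) -> list[TrinucSnv]:
    """Draw n SNVs from a 96-class trinucleotide signature mix.

    A fraction of variants (default 0) is reported on the purine strand
    (reverse-complemented ref/alt/context) to exercise downstream
    pyrimidine normalization; the class label always names the pyrimidine
    representation.
    """
    if abs(sum(signature_mix.values()) - 1.0) > 1e-9:
        raise ValueError("signature mix must sum to 1")
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    classes = [c for c in SPECTRUM_CLASSES if signature_mix.get(c, 0.0) > 0]
    probs = np.array([signature_mix[c] for c in classes])
    probs = probs / probs.sum()
    out = []
    if n == 0:
        return out
    draws = rng.choice(len(classes), size=n, p=probs)
    flips = rng.random(n) < purine_strand_fraction
    for idx, flip in zip(draws, flips):
        cls = classes[idx]
        five, ref, alt, three = cls[0], cls[2], cls[4], cls[6]
        context = five + ref + three
        if flip:
            ref, alt, context = _revcomp(ref), _revcomp(alt), _revcomp(context)
        out.append(TrinucSnv(ref, alt, context, cls))
    return out


def simulate_cutsite_pileup(
    editing_rate: float,
    depth: float,
    window_halfwidth: int = 25,
    seed: int | np.random.Generator = 0,
    background_rate: float = 0.002,
    gene: str = "gene",
    sample: str = "sample",
) -> tuple[CutSitePileup, CutSitePileup]:
    """Simulate paired (tumor, normal) pileups around an expected cut site.

    The normal shows only the background per-base alteration rate; the
    tumor additionally carries edited reads at positions within +/-2 of the
    cut site, so its central alteration rate is
    ``editing_rate + (1 - editing_rate) * background_rate``.
    """
    if not (0 <= editing_rate <= 1):
        raise ValueError("editing_rate must lie in [0, 1]")
    if depth <= 0:
        raise ValueError("depth must be positive")
    if window_halfwidth < 1:
        raise ValueError("window_halfwidth must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    offsets = np.arange(-window_halfwidth, window_halfwidth + 1)
    central = np.abs(offsets) <= 2
    rate_tumor = np.where(
        central, editing_rate + (1 - editing_rate) * background_rate, background_rate
    )
    pileups = []
    for compartment, rates in (("tumor", rate_tumor),
                               ("normal", np.full_like(rate_tumor, background_rate))):
        total = np.maximum(rng.poisson(depth, size=offsets.size), 1)
        alt = rng.binomial(total, rates)
        pileups.append(
            CutSitePileup(
                gene=gene, sample=sample, compartment=compartment,
                offsets=offsets, ref_count=total - alt, alt_count=alt,
            )
        )
    return pileups[0], pileups[1]


# ---------------------------------------------------------------------------
# Whole-cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class SampleData:
    sample: str
    mouse: str
    site_class: str
    purity: float
    variants: list[VariantCall]
    pileups: dict[str, tuple[CutSitePileup, CutSitePileup]]
    exon_ratios: pd.DataFrame
    baf: pd.DataFrame
    grid: pd.DataFrame


@dataclass
class MouseTruth:
    truncal_keys: frozenset
    clade_keys: dict[frozenset, frozenset]  # sample clade -> mutation keys
    private_keys: dict[str, frozenset]  # sample -> mutation keys
    driver_keys: frozenset
    arm_copy_numbers: dict[str, int]  # arm id -> tumor total copy number
    wgd: bool
    ploidy: float
    clades: tuple[frozenset, ...]


@dataclass
class MouseData:
    mouse: str
    samples: list[SampleData]
    truth: MouseTruth


@dataclass
class CohortBundle:
    config: CohortConfig
    arms: list[ArmDefinition]
    mice: list[MouseData]
    target_regions: list[tuple[str, int, int]]  # BED 0-based half-open

    @property
    def samples(self) -> list[SampleData]:
        return [s for m in self.mice for s in m.samples]


def _arm_states(config: CohortConfig, arms: Sequence[ArmDefinition]) -> dict[str, int]:
    events = dict(config.arm_events)
    states = {}
    for a in arms:
        c = events.get(a.chrom, events.get(a.arm, 2))
        states[a.arm] = c * 2 if config.wgd else c
    return states


def _target_regions(config: CohortConfig, arms) -> dict[str, tuple[str, int, int]]:
    """Place each targeted gene's cut-site region on successive chromosomes."""
    regions = {}
    for i, gene in enumerate(config.target_genes):
        arm = arms[(7 * i + 3) % len(arms)]
        cut = arm.start + arm.length // 3 + i
        regions[gene] = (arm.chrom, cut - config.window_halfwidth,
                         cut + config.window_halfwidth + 1)
    return regions


_BASES = "ACGT"


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _downstream_context(rng: np.random.Generator, repeat_fraction: float) -> str:
    """Uniform 20-mer, or (with the given probability) a forced tandem
    repeat so the microsatellite screen has positive cases."""
    if rng.random() < repeat_fraction:
        k = int(rng.integers(1, 7))
        motif = _random_seq(rng, k)
        reps = (motif * math.ceil(20 / k))[:20]
        return reps
    return _random_seq(rng, 20)


def _place_mutation(
    rng: np.random.Generator, arms: Sequence[ArmDefinition], lengths: np.ndarray
) -> tuple[ArmDefinition, int]:
    idx = rng.choice(len(arms), p=lengths / lengths.sum())
    arm = arms[idx]
    pos = int(rng.integers(arm.start + 1, arm.end + 1))  # 1-based
    return arm, pos


def _make_mutation(
    rng: np.random.Generator,
    config: CohortConfig,
    arms: Sequence[ArmDefinition],
    lengths: np.ndarray,
    snv_pool: list[TrinucSnv],
) -> dict:
    arm, pos = _place_mutation(rng, arms, lengths)
    is_indel = rng.random() < config.indel_fraction
    if is_indel:
        size = int(rng.integers(1, 6))
        anchor = _random_seq(rng, 1)
        if rng.random() < 0.5:
            ref, alt, vclass = anchor + _random_seq(rng, size), anchor, "deletion"
        else:
            ref, alt, vclass = anchor, anchor + _random_seq(rng, size), "insertion"
        return dict(
            chrom=arm.chrom, arm=arm.arm, pos=pos, ref=ref, alt=alt,
            variant_class=vclass, trinuc_context=None,
            downstream_20nt=_downstream_context(rng, config.repeat_context_fraction),
        )
    snv = snv_pool.pop()
    return dict(
        chrom=arm.chrom, arm=arm.arm, pos=pos, ref=snv.ref, alt=snv.alt,
        variant_class="SNV", trinuc_context=snv.context, downstream_20nt=None,
    )


def _simulate_mouse(
    mouse_id: str,
    config: CohortConfig,
    arms: list[ArmDefinition],
    target_regions: dict[str, tuple[str, int, int]],
    rng: np.random.Generator,
) -> MouseData:
    lengths = np.array([a.length for a in arms], dtype=float)
    states = _arm_states(config, arms)
    total_len = lengths.sum()
    ploidy = float(
        sum(states[a.arm] * a.length for a in arms) / total_len
    )
    sample_ids = [f"{mouse_id}_T{i + 1}" for i in range(config.samples_per_mouse)]
    site_class = {
        s: ("primary" if i == 0 else "metastasis") for i, s in enumerate(sample_ids)
    }

    # mutation catalog: trunk, optional two clades, one private branch/sample
    n_clades = 2 if config.nested_clades and config.samples_per_mouse >= 4 else 0
    n_snvs_needed = (
        config.n_truncal_mutations
        + n_clades * config.n_clade_mutations
        + config.samples_per_mouse * config.n_private_mutations_per_sample
    )
    snv_pool = simulate_trinuc_mutations(
        config.signature_mix, n_snvs_needed, rng, purine_strand_fraction=0.5
    )
    make = lambda: _make_mutation(rng, config, arms, lengths, snv_pool)
    truncal = [make() for _ in range(config.n_truncal_mutations)]
    clades: tuple[frozenset, ...]
    clade_muts: dict[frozenset, list[dict]] = {}
    if n_clades:
        half = config.samples_per_mouse // 2
        clades = (frozenset(sample_ids[:half]), frozenset(sample_ids[half:]))
        for cl in clades:
            clade_muts[cl] = [make() for _ in range(config.n_clade_mutations)]
    else:
        clades = ()
    private = {s: [make() for _ in range(config.n_private_mutations_per_sample)]
               for s in sample_ids}

    drivers = []
    if config.include_driver_indels:
        for gene in config.target_genes:
            chrom, start, end = target_regions[gene]
            cut = (start + end) // 2
            anchor = "C"
            drivers.append(dict(
                chrom=chrom, arm=next(a.arm for a in arms if a.chrom == chrom),
                pos=cut + 1, ref=anchor + "TG", alt=anchor,
                variant_class="deletion", trinuc_context=None,
                downstream_20nt=_random_seq(rng, 20),
            ))

    def key_of(m: dict) -> tuple:
        return (m["chrom"], m["pos"], m["ref"], m["alt"])

    truth = MouseTruth(
        truncal_keys=frozenset(key_of(m) for m in truncal),
        clade_keys={cl: frozenset(key_of(m) for m in ms)
                    for cl, ms in clade_muts.items()},
        private_keys={s: frozenset(key_of(m) for m in ms)
                      for s, ms in private.items()},
        driver_keys=frozenset(key_of(m) for m in drivers),
        arm_copy_numbers=states,
        wgd=config.wgd,
        ploidy=ploidy,
        clades=clades,
    )

    trunk_mult = 2 if config.wgd else 1
    samples = []
    for s in sample_ids:
        carried: list[tuple[dict, int]] = [(m, trunk_mult) for m in truncal + drivers]
        for cl, ms in clade_muts.items():
            if s in cl:
                carried.extend((m, 1) for m in ms)
        carried.extend((m, 1) for m in private[s])
        variants = []
        for m, mult in carried:
            c = states[m["arm"]]
            vaf = expected_vaf(config.purity, c, mult)
            (t_depth,), (t_alt,) = simulate_allele_counts(vaf, config.mean_depth, 1, rng)
            (n_depth,), (n_alt,) = simulate_allele_counts(0.001, config.mean_depth, 1, rng)
            variants.append(VariantCall(
                chrom=m["chrom"], pos=m["pos"], ref=m["ref"], alt=m["alt"],
                variant_class=m["variant_class"],
                tumor_depth=int(t_depth), tumor_alt=int(t_alt),
                normal_depth=int(n_depth), normal_alt=int(n_alt),
                caller="simulated", downstream_20nt=m["downstream_20nt"],
                exonic=True, trinuc_context=m["trinuc_context"],
            ))
        exon_ratios = _simulate_exon_ratios(config, arms, states, rng)
        baf = _simulate_baf(config, arms, states, rng)
        grid = _make_grid(config.purity, ploidy)
        pileups = {
            gene: simulate_cutsite_pileup(
                config.editing_rate, config.mean_depth, config.window_halfwidth,
                rng, config.background_alteration_rate, gene=gene, sample=s,
            )
            for gene in config.target_genes
        }
        samples.append(SampleData(
            sample=s, mouse=mouse_id, site_class=site_class[s],
            purity=config.purity, variants=variants, pileups=pileups,
            exon_ratios=exon_ratios, baf=baf, grid=grid,
        ))
    return MouseData(mouse=mouse_id, samples=samples, truth=truth)


def _simulate_exon_ratios(
    config: CohortConfig,
    arms: Sequence[ArmDefinition],
    states: dict[str, int],
    rng: np.random.Generator,
) -> pd.DataFrame:
    rows = []
    p = config.purity
    for a in arms:
        c = states[a.arm]
        mean = math.log2((2 * (1 - p) + p * c) / 2) if (2 * (1 - p) + p * c) > 0 else -8.0
        step = a.length // (config.n_exons_per_arm + 1)
        for i in range(config.n_exons_per_arm):
            start = a.start + (i + 1) * step
            rows.append((
                a.chrom, start, start + 200, 1.0,
                mean + rng.normal(0.0, config.noise_sd_log2),
            ))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "weight", "log2"])


def _simulate_baf(
    config: CohortConfig,
    arms: Sequence[ArmDefinition],
    states: dict[str, int],
    rng: np.random.Generator,
) -> pd.DataFrame:
    rows = []
    p = config.purity
    for a in arms:
        c = states[a.arm]
        base = c // 2 if config.wgd else c
        for _ in range(config.n_baf_snps_per_arm):
            pos = int(rng.integers(a.start + 1, a.end + 1))
            # which haplotype gained/lost is random per SNP
            if base == 2:
                b = 1
            elif base < 2:
                b = int(rng.integers(0, 2)) if base == 1 else 0
            else:
                b = int(rng.integers(1, base))  # 1..base-1 retained B copies
            if config.wgd:
                b *= 2
            denom = 2 * (1 - p) + p * c
            tumor_baf = ((1 - p) + p * b) / denom if denom > 0 else 0.0
            n_depth = max(int(rng.poisson(config.mean_depth)), 1)
            n_alt = int(rng.binomial(n_depth, 0.5))
            t_depth = max(int(rng.poisson(config.mean_depth)), 1)
            t_alt = int(rng.binomial(t_depth, tumor_baf))
            rows.append((a.chrom, pos, n_depth - n_alt, n_alt, t_depth - t_alt, t_alt))
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "normal_ref", "normal_alt", "tumor_ref", "tumor_alt"],
    )


def _make_grid(purity: float, ploidy: float) -> pd.DataFrame:
    """Cellularity-ploidy probability surface peaked at the true solution,
    shaped like the output grids of allele-specific CNA fitters."""
    cells = np.round(np.arange(0.05, 1.0001, 0.05), 2)
    ploidies = np.round(np.arange(1.0, 8.0001, 0.5), 1)
    rows = []
    for c in cells:
        for pl in ploidies:
            prob = math.exp(
                -((c - purity) ** 2 / (2 * 0.05**2) + (pl - ploidy) ** 2 / (2 * 0.25**2))
            )
            rows.append((c, pl, prob))
    grid = pd.DataFrame(rows, columns=["cellularity", "ploidy", "probability"])
    grid["probability"] /= grid["probability"].sum()
    return grid


def simulate_cohort(config: CohortConfig) -> CohortBundle:
    """Simulate a full cohort with ground truth. Deterministic per seed."""
    config.validate()
    arms = load_arms(config.genome_build)
    target_regions = _target_regions(config, arms)
    root = np.random.SeedSequence(config.seed)
    mouse_seeds = root.spawn(config.n_mice)
    mice = []
    for i, ss in enumerate(mouse_seeds):
        mouse_id = f"M{i + 1}"
        rng = np.random.default_rng(ss)
        mice.append(_simulate_mouse(mouse_id, config, arms, target_regions, rng))
    return CohortBundle(
        config=config,
        arms=arms,
        mice=mice,
        target_regions=sorted(target_regions.values()),
    )
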