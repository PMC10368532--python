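"""End-to-end pipeline: simulate -> editing score -> somatic filters ->
spectrum -> karyotype -> progression trees, with a JSON run manifest."""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
import pandas as pd
import yaml

from . import __version__
from .editing import score_pileups
from .filters import PROFILES, apply_filter, exclude_sgrna_regions, repeat_filter, trinuc_spectrum
from .genome import load_arms
from .io import write_cohort, write_newick
from .karyotype import karyotype_profile
from .simulate import CohortConfig, simulate_cohort
from .tree import (
    assign_branches,
    build_tree,
    collapse_zero_branches,
    truncal_private_fractions,
    variant_sets_from_calls,
)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("mosaicevo")


@dataclass
class RunConfig:
    """Whole-run configuration; serializes losslessly to/from YAML."""

    seed: int = 0
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides
    filter_profile: str = "murine"
    central_halfwidth: int = 2
    sgrna_pad: int = 50
    arm_table: str = "mm10"
    wgd_cutoff: float = 3.0
    min_alt_reads: int = 2
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def cohort_config(self) -> CohortConfig:
        fields = dict(self.cohort)
        unknown = set(fields) - set(CohortConfig.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown cohort config fields: {sorted(unknown)}")
        fields.setdefault("seed", self.seed)
        cfg = CohortConfig(**fields)
        cfg.validate()
        return cfg


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run all stages on a freshly simulated cohort; returns the manifest.

    Stage outputs land under ``outdir``; the manifest (versions, seeds,
    per-stage record counts) is written as ``manifest.json``. Deterministic
    for a fixed config."""
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(name)s %(levelname)s [%(stage)s] %(message)s",
    )
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if config.filter_profile not in PROFILES:
        raise ValueError(f"unknown filter profile {config.filter_profile!r}")
    profile = PROFILES[config.filter_profile]
    arms = load_arms(config.arm_table)
    manifest: dict = {
        "tool": "mosaicevo",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "stages": {},
        "status": "running",
    }

    def stage(name: str, **counts) -> None:
        manifest["stages"][name] = counts
        log.info("done: %s", counts, extra={"stage": name})

    try:
        cohort_cfg = config.cohort_config()
        bundle = simulate_cohort(cohort_cfg)
        write_cohort(bundle, out / "cohort")
        stage("simulate", mice=len(bundle.mice), samples=len(bundle.samples),
              variants=sum(len(s.variants) for s in bundle.samples))

        # editing scores
        score_rows = []
        for s in bundle.samples:
            res = score_pileups(s.pileups, config.central_halfwidth)
            score_rows.append((s.sample, res.sample_score))
        scores = pd.DataFrame(score_rows, columns=["sample", "editing_score"])
        scores.to_csv(out / "editing_scores.tsv", sep="\t", index=False)
        stage("edit_score", samples=len(scores))

        # somatic filtering + driver-region exclusion + indel repeat screen
        filtered: dict[str, list] = {}
        n_in = n_kept = 0
        for s in bundle.samples:
            n_in += len(s.variants)
            res = apply_filter(s.variants, profile)
            kept = [
                v for v in res.kept
                if v.downstream_20nt is None or repeat_filter(v.downstream_20nt)
            ]
            kept = exclude_sgrna_regions(kept, bundle.target_regions, pad=config.sgrna_pad)
            filtered[s.sample] = kept
            n_kept += len(kept)
        (out / "filtered").mkdir(exist_ok=True)
        from .io import write_variants_tsv

        for sample, kept in filtered.items():
            write_variants_tsv(kept, out / "filtered" / f"{sample}.tsv")
        stage("filter", variants_in=n_in, variants_kept=n_kept,
              profile=profile.name)

        # trinucleotide spectrum over the filtered SNVs
        mouse_of = {s.sample: s.mouse for s in bundle.samples}
        cohort_of = {
            s.sample: ("metastatic" if s.site_class == "metastasis"
                       else "primary+cell-line")
            for s in bundle.samples
        }
        records = [(sample, v) for sample, kept in filtered.items() for v in kept]
        spectra = trinuc_spectrum(records, mouse_of, cohort_of)
        for label, spec in spectra.items():
            safe = label.replace("+", "_").replace("/", "_")
            spec.to_frame().to_csv(out / f"spectrum_{safe}.tsv", sep="\t", index=False)
        stage("spectrum", cohorts=len(spectra),
              mutations=int(spectra["ALL"].total) if "ALL" in spectra else 0)

        # karyotype profiles
        profiles = []
        (out / "karyotype").mkdir(exist_ok=True)
        for s in bundle.samples:
            prof = karyotype_profile(
                s.sample, s.exon_ratios, arms, s.grid, s.purity,
                baf_records=s.baf, wgd_cutoff=config.wgd_cutoff,
            )
            prof.arm_calls.to_csv(out / "karyotype" / f"{s.sample}.arms.tsv", sep="\t")
            profiles.append(prof.to_row())
        pd.concat(profiles, ignore_index=True).to_csv(
            out / "karyotype" / "profiles.tsv", sep="\t", index=False
        )
        stage("karyotype", samples=len(profiles))

        # per-mouse progression trees
        (out / "trees").mkdir(exist_ok=True)
        site_of = {s.sample: s.site_class for s in bundle.samples}
        frac_frames = []
        for m in bundle.mice:
            calls_by_sample = {s.sample: filtered[s.sample] for s in m.samples}
            sets = variant_sets_from_calls(
                calls_by_sample, mouse_of, site_of, config.min_alt_reads
            )
            tree = collapse_zero_branches(build_tree(sets))
            write_newick(tree, out / "trees" / f"{m.mouse}.nwk")
            assignment = assign_branches(tree, sets)
            fr = truncal_private_fractions(assignment, sets)
            fr.insert(0, "mouse", m.mouse)
            frac_frames.append(fr)
        pd.concat(frac_frames, ignore_index=True).to_csv(
            out / "trees" / "truncal_private_fractions.tsv", sep="\t", index=False
        )
        stage("tree", mice=len(bundle.mice))
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
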