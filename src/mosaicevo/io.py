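"""Readers and writers for the pipeline's on-disk formats.

Variant tables travel as minimal VCF v4.2 (per-sample DP and AD for a
TUMOR and a NORMAL column, simulator annotations in INFO) or as TSV; exon
log ratios as SEG-like TSV (chrom, start, end, weight, log2); BAF and
cellularity-ploidy grids as TSV; targets as BED (0-based half-open);
trees as Newick with branch lengths; ground truth as JSON. All writers are
deterministic so a fixed-seed cohort serializes byte-identically.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .filters import VariantCall
from .simulate import CohortBundle
from .tree import SampleTree, TreeNode

__all__ = [
    "read_variants_tsv",
    "write_variants_tsv",
    "read_variants_vcf",
    "write_variants_vcf",
    "read_variants",
    "read_bed",
    "write_bed",
    "read_seg",
    "read_baf",
    "read_grid",
    "newick_string",
    "write_newick",
    "read_newick",
    "write_cohort",
]

VARIANT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "variant_class",
    "tumor_depth", "tumor_alt", "normal_depth", "normal_alt",
    "caller", "downstream_20nt", "exonic", "trinuc_context",
]


def _variant_to_row(v: VariantCall) -> dict:
    return {
        "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
        "variant_class": v.variant_class,
        "tumor_depth": v.tumor_depth, "tumor_alt": v.tumor_alt,
        "normal_depth": v.normal_depth, "normal_alt": v.normal_alt,
        "caller": v.caller,
        "downstream_20nt": v.downstream_20nt or ".",
        "exonic": int(v.exonic),
        "trinuc_context": v.trinuc_context or ".",
    }


def write_variants_tsv(variants: Sequence[VariantCall], path: str | Path) -> None:
    pd.DataFrame(
        [_variant_to_row(v) for v in variants], columns=VARIANT_COLUMNS
    ).to_csv(path, sep="\t", index=False)


def read_variants_tsv(path: str | Path) -> list[VariantCall]:
    """Read a variant TSV; malformed rows raise with their line number."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns: {missing}")
    out = []
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        try:
            out.append(VariantCall(
                chrom=row["chrom"], pos=int(row["pos"]),
                ref=row["ref"], alt=row["alt"],
                variant_class=row["variant_class"],
                tumor_depth=int(row["tumor_depth"]),
                tumor_alt=int(row["tumor_alt"]),
                normal_depth=int(row["normal_depth"]),
                normal_alt=int(row["normal_alt"]),
                caller=row["caller"],
                downstream_20nt=None if row["downstream_20nt"] == "." else row["downstream_20nt"],
                exonic=bool(int(row["exonic"])),
                trinuc_context=None if row["trinuc_context"] == "." else row["trinuc_context"],
            ))
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}: malformed variant at line {line_no}: {exc}") from exc
    return out


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=mosaicevo
##INFO=<ID=VC,Number=1,Type=String,Description="Variant class">
##INFO=<ID=TNC,Number=1,Type=String,Description="Trinucleotide context">
##INFO=<ID=DS20,Number=1,Type=String,Description="20nt downstream context">
##INFO=<ID=CALLER,Number=1,Type=String,Description="Originating caller">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\tNORMAL
"""


def write_variants_vcf(variants: Sequence[VariantCall], path: str | Path) -> None:
    """Write a minimal VCF v4.2 with TUMOR and NORMAL sample columns."""
    lines = [_VCF_HEADER]
    order = sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    for v in order:
        info = f"VC={v.variant_class};CALLER={v.caller}"
        if v.trinuc_context:
            info += f";TNC={v.trinuc_context}"
        if v.downstream_20nt:
            info += f";DS20={v.downstream_20nt}"
        tumor = f"{v.tumor_depth}:{v.tumor_depth - v.tumor_alt},{v.tumor_alt}"
        normal = f"{v.normal_depth}:{v.normal_depth - v.normal_alt},{v.normal_alt}"
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t{info}\tDP:AD\t{tumor}\t{normal}\n"
        )
    Path(path).write_text("".join(lines))


def read_variants_vcf(path: str | Path) -> list[VariantCall]:
    """Read a VCF v4.2 with per-sample DP/AD via cyvcf2 (TUMOR, NORMAL)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for required in ("TUMOR", "NORMAL"):
        if required not in samples:
            raise ValueError(f"{path}: VCF lacks a {required} sample column")
    ti, ni = samples.index("TUMOR"), samples.index("NORMAL")
    out = []
    for rec in vcf:
        dp = rec.format("DP")
        ad = rec.format("AD")
        if dp is None or ad is None:
            raise ValueError(f"{path}: record {rec.CHROM}:{rec.POS} lacks DP/AD")
        out.append(VariantCall(
            chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=rec.ALT[0],
            variant_class=rec.INFO.get("VC", "SNV"),
            tumor_depth=int(dp[ti][0]), tumor_alt=int(ad[ti][1]),
            normal_depth=int(dp[ni][0]), normal_alt=int(ad[ni][1]),
            caller=rec.INFO.get("CALLER", "unknown"),
            downstream_20nt=rec.INFO.get("DS20"),
            trinuc_context=rec.INFO.get("TNC"),
        ))
    return out


def read_variants(path: str | Path, fmt: Optional[str] = None) -> list[VariantCall]:
    """Dispatch on ``fmt`` (``vcf``/``tsv``) or the file suffix."""
    fmt = fmt or ("vcf" if str(path).endswith(".vcf") else "tsv")
    if fmt == "vcf":
        return read_variants_vcf(path)
    if fmt == "tsv":
        return read_variants_tsv(path)
    raise ValueError(f"unknown variant format {fmt!r}")


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """BED intervals, 0-based half-open."""
    out = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: line {i}: expected >= 3 BED columns")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        if end <= start:
            raise ValueError(f"{path}: line {i}: end must exceed start")
        out.append((chrom, start, end))
    return out


def write_bed(intervals: Sequence[tuple[str, int, int]], path: str | Path) -> None:
    lines = [f"{c}\t{s}\t{e}\n" for c, s, e in intervals]
    Path(path).write_text("".join(lines))


def read_seg(path: str | Path) -> pd.DataFrame:
    """SEG-like exon log-ratio TSV: chrom, start, end, weight, log2."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("chrom", "start", "end", "weight", "log2") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if (df["end"] <= df["start"]).any():
        bad = df.index[df["end"] <= df["start"]][0] + 2
        raise ValueError(f"{path}: line {bad}: end must exceed start")
    if (df["weight"] < 0).any():
        raise ValueError(f"{path}: negative exon weight")
    return df


def read_baf(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = ["chrom", "pos", "normal_ref", "normal_alt", "tumor_ref", "tumor_alt"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if (df[required[2:]] < 0).to_numpy().any():
        raise ValueError(f"{path}: negative allele counts")
    return df


def read_grid(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("cellularity", "ploidy", "probability") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if (df["probability"] < 0).any():
        raise ValueError(f"{path}: negative probability")
    return df


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def newick_string(tree: SampleTree) -> str:
    """Newick with branch lengths = parent height - child height."""

    def render(node: TreeNode, parent_height: float) -> str:
        bl = parent_height - node.height
        if node.is_leaf:
            return f"{node.name}:{bl:.10g}"
        inner = ",".join(render(c, node.height) for c in node.children)
        return f"({inner}):{bl:.10g}"

    root = tree.root
    if root.is_leaf:
        return f"{root.name}:0;"
    inner = ",".join(render(c, root.height) for c in root.children)
    return f"({inner});"


def write_newick(tree: SampleTree, path: str | Path) -> None:
    Path(path).write_text(newick_string(tree) + "\n")


def read_newick(path_or_string: str | Path, mouse: str = "") -> SampleTree:
    """Parse Newick (via dendropy) back into a height-annotated SampleTree.

    Heights are reconstructed as (max root-to-leaf distance) minus each
    node's root distance, which inverts ``newick_string`` for ultrametric
    dendrograms.
    """
    import dendropy

    source = path_or_string
    if isinstance(source, Path) or ("(" not in str(source) and Path(source).exists()):
        text = Path(source).read_text()
    else:
        text = str(source)
    dt = dendropy.Tree.get(data=text, schema="newick")
    dt.calc_node_root_distances(return_leaf_distances_only=False)
    height_total = max(leaf.root_distance for leaf in dt.leaf_node_iter())

    def convert(node) -> TreeNode:
        dist = node.root_distance or 0.0
        h = max(height_total - dist, 0.0)
        if node.is_leaf():
            return TreeNode(height=0.0, name=node.taxon.label.replace(" ", "_"))
        return TreeNode(height=h, children=tuple(convert(c) for c in node.child_nodes()))

    return SampleTree(root=convert(dt.seed_node), mouse=mouse)


# ---------------------------------------------------------------------------
# Cohort serialization
# ---------------------------------------------------------------------------


def _pileup_frame(bundle: CohortBundle) -> pd.DataFrame:
    rows = []
    for s in bundle.samples:
        for gene, (tumor, normal) in sorted(s.pileups.items()):
            for p in (tumor, normal):
                for off, r, a in zip(p.offsets, p.ref_count, p.alt_count):
                    rows.append((s.sample, gene, int(off), int(r), int(a), p.compartment))
    return pd.DataFrame(
        rows,
        columns=["sample", "gene", "position_offset", "ref_count", "alt_count", "compartment"],
    )


def write_cohort(bundle: CohortBundle, outdir: str | Path) -> Path:
    """Serialize a simulated cohort: per-sample variant VCF+TSV, SEG, BAF
    and grid TSVs, one pooled pileup TSV, the sgRNA-target BED, a sample
    map, and the ground truth as JSON. Returns the output directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "variants").mkdir(exist_ok=True)
    (out / "seg").mkdir(exist_ok=True)
    (out / "baf").mkdir(exist_ok=True)
    (out / "grid").mkdir(exist_ok=True)
    sample_rows = []
    for m in bundle.mice:
        for s in m.samples:
            write_variants_vcf(s.variants, out / "variants" / f"{s.sample}.vcf")
            write_variants_tsv(s.variants, out / "variants" / f"{s.sample}.tsv")
            s.exon_ratios.to_csv(out / "seg" / f"{s.sample}.seg.tsv", sep="\t", index=False)
            s.baf.to_csv(out / "baf" / f"{s.sample}.baf.tsv", sep="\t", index=False)
            s.grid.to_csv(out / "grid" / f"{s.sample}.grid.tsv", sep="\t", index=False)
            sample_rows.append((s.sample, s.mouse, s.site_class, s.purity))
    pd.DataFrame(
        sample_rows, columns=["sample", "mouse", "site_class", "purity"]
    ).to_csv(out / "samples.tsv", sep="\t", index=False)
    _pileup_frame(bundle).to_csv(out / "pileups.tsv", sep="\t", index=False)
    write_bed(bundle.target_regions, out / "sgrna_targets.bed")
    truth = {
        m.mouse: {
            "truncal": sorted(map(list, m.truth.truncal_keys)),
            "private": {s: sorted(map(list, ks)) for s, ks in m.truth.private_keys.items()},
            "clades": [sorted(c) for c in m.truth.clades],
            "clade_mutations": {
                "|".join(sorted(c)): sorted(map(list, ks))
                for c, ks in m.truth.clade_keys.items()
            },
            "drivers": sorted(map(list, m.truth.driver_keys)),
            "arm_copy_numbers": dict(sorted(m.truth.arm_copy_numbers.items())),
            "wgd": m.truth.wgd,
            "ploidy": m.truth.ploidy,
        }
        for m in bundle.mice
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return out
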