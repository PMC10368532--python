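"""Somatic filter rules, the tandem-repeat screen, sgRNA-region exclusion,
burden and trinucleotide spectra."""

from pathlib import Path

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mosaicevo import (
    MSK,
    MURINE,
    apply_filter,
    exclude_sgrna_regions,
    mutational_burden,
    rederive_vaf,
    repeat_filter,
    simulate_trinuc_mutations,
    trinuc_class,
    trinuc_spectrum,
)
from mosaicevo.filters import SPECTRUM_CLASSES, callable_size_mb
from mosaicevo.io import read_variants_tsv

from conftest import make_variant

DATA = Path(__file__).parent / "data"


class TestVaf:
    def test_arithmetic(self):
        assert rederive_vaf(3, 30).value == pytest.approx(0.1)
        assert rederive_vaf(0, 50) == (0.0, False)

    def test_zero_depth_flagged(self):
        assert rederive_vaf(0, 0) == (0.0, True)

    def test_alt_exceeding_depth_rejected(self):
        with pytest.raises(ValueError):
            rederive_vaf(5, 3)


class TestFilterProfiles:
    def test_boundary_fixture_keeps_exact_hand_derived_set(self):
        variants = read_variants_tsv(DATA / "boundary_variants.tsv")
        murine = [v for v in variants if v.chrom == "chr1"]
        msk = [v for v in variants if v.chrom == "chr2"]
        kept_murine = {v.pos for v in apply_filter(murine, MURINE).kept}
        kept_msk = {v.pos for v in apply_filter(msk, MSK).kept}
        # murine: depth strictly >20/>10, VAF >= 0.1 inclusive
        assert kept_murine == {100, 500, 600}
        # MSK: >=10x tumor, >=5 alt, VAF >= 0.05, normal VAF strictly < 0.07
        assert kept_msk == {100, 400}

    def test_rejection_reasons_name_first_failing_rule(self):
        variants = read_variants_tsv(DATA / "boundary_variants.tsv")
        reasons = {
            v.pos: r for v, r in apply_filter(variants[:6], MURINE).rejected
        }
        assert reasons == {200: "tumor_depth", 300: "normal_depth", 400: "tumor_vaf"}

    def test_murine_boundary_depth_is_strict(self):
        v = make_variant(tumor_depth=20, tumor_alt=5, normal_depth=12)
        assert apply_filter([v], MURINE).rejected[0][1] == "tumor_depth"

    def test_empty_input(self):
        res = apply_filter([], MURINE)
        assert res.kept == [] and res.rejected == []

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(
            st.tuples(
                st.integers(0, 60), st.integers(0, 60),
                st.integers(0, 30), st.integers(0, 5),
            ),
            max_size=30,
        )
    )
    def test_filter_idempotent(self, rows):
        variants = [
            make_variant(pos=i, tumor_depth=max(td, ta), tumor_alt=ta,
                         normal_depth=max(nd, na), normal_alt=na)
            for i, (td, ta, nd, na) in enumerate(rows, start=1)
        ]
        for profile in (MURINE, MSK):
            once = apply_filter(variants, profile).kept
            twice = apply_filter(once, profile).kept
            assert twice == once


def oracle_repeat(seq):
    """Brute force: every motif length 1-6 at every start, >= 3 tandem copies."""
    for k in range(1, 7):
        for s in range(len(seq)):
            motif = seq[s : s + k]
            if len(motif) < k or "N" in motif:
                continue
            if seq[s : s + 3 * k] == motif * 3:
                return False
    return True


class TestRepeatFilter:
    @pytest.mark.parametrize(
        "window,expected",
        [
            ("ACACACACACGTGTTCCGAT", False),  # AC x5 tandem
            ("AAATGCGTCGATCGGTCCAG", False),  # A x3 tandem
            ("ACGTGATCGTAGCTGACTGA", True),
        ],
    )
    def test_worked_examples_match_oracle(self, window, expected):
        assert oracle_repeat(window) is expected
        assert repeat_filter(window) is expected

    def test_agrees_with_bruteforce_on_random_windows(self, rng):
        bases = np.array(list("ACGTN"))
        for _ in range(300):
            seq = "".join(bases[rng.integers(0, 5, size=20)])
            assert repeat_filter(seq) is oracle_repeat(seq), seq

    def test_n_never_matches(self):
        assert repeat_filter("NNNNNNNNNNNNNNNNNNNN") is True

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            repeat_filter("ACGT")

    def test_any_occurrence_mode_is_stricter(self):
        # three dispersed (non-tandem) copies of a 3-mer
        seq = "ACGTTACGTTACGAAGGCCA"
        assert repeat_filter(seq, mode="tandem") is True
        assert repeat_filter(seq, mode="any") is False


class TestSgrnaExclusion:
    def test_variant_inside_padded_target_removed(self):
        v = make_variant(chrom="chr4", pos=1000)
        assert exclude_sgrna_regions([v], [("chr4", 950, 1050)]) == []

    def test_variant_outside_kept(self):
        v = make_variant(chrom="chr4", pos=2000)
        assert exclude_sgrna_regions([v], [("chr4", 950, 1050)], pad=50) == [v]

    def test_pad_extends_interval(self):
        v = make_variant(chrom="chr4", pos=1090)  # 0-based 1089 < 1050+50
        assert exclude_sgrna_regions([v], [("chr4", 950, 1050)], pad=50) == []
        assert exclude_sgrna_regions([v], [("chr4", 950, 1050)], pad=0) == [v]

    def test_empty_target_set_is_identity(self):
        vs = [make_variant(pos=p) for p in (1, 2, 3)]
        assert exclude_sgrna_regions(vs, []) == vs

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError):
            exclude_sgrna_regions([], [("chr1", 100, 100)])


class TestBurden:
    @pytest.mark.parametrize("count,mb,expected", [(34, 100, 0.34), (0, 10, 0.0), (17, 50, 0.34)])
    def test_mutations_per_mb(self, count, mb, expected):
        assert mutational_burden(count, mb) == pytest.approx(expected)

    def test_callable_size_from_bed(self):
        assert callable_size_mb([("chr1", 0, 500_000), ("chr2", 100, 600_100)]) == pytest.approx(1.1)

    def test_zero_callable_size_rejected(self):
        with pytest.raises(ValueError):
            mutational_burden(5, 0)


class TestTrinucSpectrum:
    def test_pyrimidine_normalization(self):
        assert trinuc_class("C", "T", "ACA") == "A[C>T]A"
        assert trinuc_class("G", "A", "TGT") == "A[C>T]A"  # reverse complement

    def test_invalid_context_rejected(self):
        with pytest.raises(ValueError):
            trinuc_class("C", "T", "AAA")

    def test_per_mouse_dedup_counts_shared_mutation_once(self):
        v = make_variant(chrom="chr3", pos=77, ref="C", alt="T", trinuc_context="ACA")
        records = [(f"s{i}", v) for i in range(3)]
        spec = trinuc_spectrum(records, {f"s{i}": "m1" for i in range(3)})["ALL"]
        assert spec.counts["A[C>T]A"] == 1
        assert spec.total == 1

    def test_same_mutation_in_two_mice_counts_twice(self):
        v = make_variant(chrom="chr3", pos=77, ref="C", alt="T", trinuc_context="ACA")
        spec = trinuc_spectrum([("s1", v), ("s2", v)], {"s1": "m1", "s2": "m2"})["ALL"]
        assert spec.counts["A[C>T]A"] == 2

    def test_frequencies_normalized(self):
        v1 = make_variant(pos=1, ref="C", alt="T", trinuc_context="ACA")
        v2 = make_variant(pos=2, ref="C", alt="G", trinuc_context="TCT")
        spec = trinuc_spectrum([("s", v1), ("s", v2)], {"s": "m"})["ALL"]
        assert spec.frequencies["A[C>T]A"] == 0.5
        assert spec.frequencies.sum() == pytest.approx(1.0, abs=1e-9)

    def test_cohort_split_and_pooled_mode(self):
        v1 = make_variant(pos=1, ref="C", alt="T", trinuc_context="ACA")
        v2 = make_variant(pos=2, ref="C", alt="A", trinuc_context="GCG")
        specs = trinuc_spectrum(
            [("p", v1), ("m", v2)],
            {"p": "m1", "m": "m1"},
            {"p": "primary+cell-line", "m": "metastatic"},
        )
        assert specs["primary+cell-line"].total == 1
        assert specs["metastatic"].total == 1
        assert specs["ALL"].total == 2

    def test_known_mix_recovered(self, rng):
        mix = {c: 0.0 for c in SPECTRUM_CLASSES}
        mix["A[C>T]G"] = 0.5
        mix["T[C>A]T"] = 0.3
        mix["G[T>C]C"] = 0.2
        muts = simulate_trinuc_mutations(mix, 1000, seed=rng, purine_strand_fraction=0.5)
        records = [
            (
                "s1",
                make_variant(pos=i + 1, ref=m.ref, alt=m.alt,
                             trinuc_context=m.context),
            )
            for i, m in enumerate(muts)
        ]
        spec = trinuc_spectrum(records, {"s1": "m1"})["ALL"]
        assert spec.total == 1000  # conservation: unique mutations all counted
        truth = np.array([mix[c] for c in SPECTRUM_CLASSES])
        obs = spec.frequencies.to_numpy()
        cosine = obs @ truth / (np.linalg.norm(obs) * np.linalg.norm(truth))
        assert cosine >= 0.95
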