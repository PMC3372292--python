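"""Sequence-parameter computations: direct examples, oracles, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pescore as p
from pescore.features import (
    AA_COLUMNS,
    CORE_COLUMNS,
    compute_feature_vector,
    featurize,
)
from pescore.records import AnnotationRequiredError, CdsMismatchError
from pescore.scales import STANDARD_AA, ScaleConfig

from conftest import random_records


def rec(seq, **kw):
    return p.ProteinRecord(id="t", aa_seq=seq, **kw)


class TestFractions:
    @pytest.mark.parametrize("seq,expected", [
        ("AAK", {"A": 2 / 3, "K": 1 / 3}),
        ("R", {"R": 1.0}),
        ("RKDE", {"R": 0.25, "K": 0.25, "D": 0.25, "E": 0.25}),
    ])
    def test_direct_counts(self, seq, expected):
        frac = p.amino_acid_fractions(rec(seq))
        for aa in STANDARD_AA:
            assert frac[aa] == pytest.approx(expected.get(aa, 0.0))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            p.ProteinRecord(id="t", aa_seq="")

    def test_nonstandard_residues_count_in_length_only(self):
        with pytest.warns(UserWarning):
            frac = p.amino_acid_fractions(rec("AAXX"))
        assert frac["A"] == pytest.approx(0.5)
        assert sum(frac.values()) == pytest.approx(0.5)


class TestExposureSplit:
    def test_two_residue_split(self):
        split = p.exposure_split_fractions(rec("AK", exposure="BE"))
        assert split["A"] == (0.5, 0.0)
        assert split["K"] == (0.0, 0.5)

    def test_all_buried(self):
        split = p.exposure_split_fractions(rec("LLLL", exposure="BBBB"))
        assert split["L"] == (1.0, 0.0)

    def test_chain_length_denominator(self):
        split = p.exposure_split_fractions(rec("DKDK", exposure="EEBB"))
        assert split["D"] == (0.25, 0.25)
        assert split["K"] == (0.25, 0.25)

    def test_missing_annotation_errors(self):
        with pytest.raises(AnnotationRequiredError):
            p.exposure_split_fractions(rec("AK"))


class TestGravy:
    def test_single_residue_published_value(self):
        assert p.gravy(rec("A")) == pytest.approx(1.8)

    def test_hand_mean_of_published_values(self):
        # KD values: A 1.8, I 4.5, L 3.8, V 4.2 -> mean 3.575
        assert p.gravy(rec("AILV")) == pytest.approx(3.575)

    def test_mean_invariance_under_repetition(self):
        assert p.gravy(rec("W" * 37)) == pytest.approx(p.gravy(rec("W")))

    def test_zero_scale_gives_zero(self, rng):
        zero = ScaleConfig(hydropathy={aa: 0.0 for aa in STANDARD_AA})
        for r in random_records(rng, 5, with_annotations=False):
            assert p.gravy(r, zero) == 0.0


class TestSidechainEntropy:
    def test_homopolymer_equals_scale_value(self):
        scale = p.DEFAULT_SCALES
        r = rec("KKKK", exposure="EEEE")
        assert p.sidechain_entropy(r, scale) == pytest.approx(scale.sce["K"])
        assert p.sidechain_entropy(r, scale, exposed_only=True) == \
            pytest.approx(scale.sce["K"])

    def test_single_exposed_residue(self):
        r = rec("GK", exposure="BE")
        assert p.sidechain_entropy(r, exposed_only=True) == \
            pytest.approx(p.DEFAULT_SCALES.sce["K"])

    def test_exposed_mean_matches_bruteforce(self, rng):
        scale = p.DEFAULT_SCALES
        for r in random_records(rng, 10):
            expected = np.mean([scale.sce[aa] for aa, lab
                                in zip(r.aa_seq, r.exposure) if lab == "E"])
            assert p.sidechain_entropy(r, exposed_only=True) == \
                pytest.approx(expected)

    def test_no_exposed_residues_is_nan_with_warning(self):
        with pytest.warns(UserWarning):
            out = p.sidechain_entropy(rec("GG", exposure="BB"),
                                      exposed_only=True)
        assert np.isnan(out)


class TestChargeMetrics:
    @pytest.mark.parametrize("seq,num,net,fracnum,fracnet", [
        ("RKDE", 4, 0, 1.0, 0.0),
        ("RRKDA", 4, 2, 0.8, 0.4),
        ("GGGG", 0, 0, 0.0, 0.0),
    ])
    def test_counts_and_fractions(self, seq, num, net, fracnum, fracnet):
        m = p.charge_metrics(rec(seq))
        assert m["numcharge"] == num
        assert m["netcharge"] == net
        assert m["absnetcharge"] == abs(net)
        assert m["fracnumcharge"] == pytest.approx(fracnum)
        assert m["fracnetcharge"] == pytest.approx(fracnet)
        assert m["fracabsnetcharge"] == pytest.approx(abs(fracnet))


class TestIsoelectricPoint:
    def test_zero_charge_at_returned_pi(self, rng):
        from pescore.features import net_charge_at_ph
        for r in random_records(rng, 10, with_annotations=False):
            pi = p.isoelectric_point(r)
            assert abs(net_charge_at_ph(r, pi)) < 1e-3

    def test_monotone_in_basic_residues(self, rng):
        for r in random_records(rng, 5, with_annotations=False):
            more_basic = rec("K" + r.aa_seq)
            assert p.isoelectric_point(more_basic) > p.isoelectric_point(r)

    def test_agrees_with_bruteforce_grid(self, rng):
        # independent oracle: dense pH grid at 1e-5 resolution
        from pescore.features import net_charge_at_ph
        grid = np.arange(0.0, 14.0, 1e-5)
        for r in random_records(rng, 8, length_range=(5, 40),
                                with_annotations=False):
            charges = np.array([net_charge_at_ph(r, ph)
                                for ph in np.arange(0, 14.01, 0.5)])
            # bracket the sign change coarsely, then refine on the fine grid
            coarse = np.arange(0, 14.01, 0.5)
            i = int(np.searchsorted(-charges, 0.0)) - 1
            lo, hi = coarse[max(i, 0)], coarse[min(i + 1, len(coarse) - 1)]
            fine = grid[(grid >= lo - 0.5) & (grid <= hi + 0.5)]
            vals = np.abs([net_charge_at_ph(r, ph) for ph in fine[::50]])
            oracle_pi = fine[::50][int(np.argmin(vals))]
            assert p.isoelectric_point(r) == pytest.approx(oracle_pi, abs=1e-2)


class TestDisorderAndCodons:
    @pytest.mark.parametrize("labels,expected", [
        ("O" * 10, 0.0), ("D" * 10, 1.0), ("DDDOOOOOOO", 0.3),
    ])
    def test_disorder_fraction(self, labels, expected):
        assert p.disorder_fraction(rec("A" * 10, disorder=labels)) == \
            pytest.approx(expected)

    def test_rare_common_classification(self):
        # CGT is a common Arg codon, AGA a rare one
        r = rec("RR", cds="CGTAGA")
        split = p.rare_codon_split(r)
        assert split["R"] == (0.5, 0.5)

    def test_no_rilp_residues_all_zero(self):
        r = rec("MK", cds="ATGAAA")
        split = p.rare_codon_split(r)
        assert all(v == (0.0, 0.0) for v in split.values())

    def test_translation_mismatch_names_codon(self):
        with pytest.raises(CdsMismatchError, match="codon 1"):
            p.ProteinRecord(id="t", aa_seq="I", cds="ATG")


class TestFeatureVector:
    def test_core_parameter_count(self, annotated_record):
        fv = compute_feature_vector(annotated_record)
        assert len([k for k in fv if k in CORE_COLUMNS]) == 72

    def test_partial_computation_without_exposure(self):
        fv = compute_feature_vector(rec("MKLIV"))
        assert "ab" not in fv and "esce" not in fv and "diso" not in fv
        assert "gravy" in fv and "a" in fv

    def test_matches_single_purpose_recomputation(self, annotated_record):
        r = annotated_record
        fv = compute_feature_vector(r)
        frac = p.amino_acid_fractions(r)
        split = p.exposure_split_fractions(r)
        for aa in STANDARD_AA:
            assert fv[aa.lower()] == pytest.approx(frac[aa])
            assert fv[aa.lower() + "b"] == pytest.approx(split[aa][0])
            assert fv[aa.lower() + "e"] == pytest.approx(split[aa][1])
        assert fv["gravy"] == pytest.approx(p.gravy(r))
        assert fv["sce"] == pytest.approx(p.sidechain_entropy(r))
        assert fv["esce"] == pytest.approx(
            p.sidechain_entropy(r, exposed_only=True))
        assert fv["pi"] == pytest.approx(p.isoelectric_point(r), abs=1e-3)
        assert fv["diso"] == pytest.approx(p.disorder_fraction(r))
        for key, value in p.charge_metrics(r).items():
            assert fv[key] == pytest.approx(value)

    def test_featurizer_agrees_with_per_record_computation(self, rng):
        records = random_records(rng, 6, with_cds=True)
        table = featurize(records)
        for r in records:
            fv = compute_feature_vector(r)
            for key, value in fv.items():
                got = table.loc[r.id, key]
                if np.isnan(value):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(value, abs=1e-6), key


@st.composite
def sequences(draw):
    return "".join(draw(st.lists(st.sampled_from(STANDARD_AA),
                                 min_size=1, max_size=60)))


class TestInvariants:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(sequences())
    def test_fraction_closure(self, seq):
        frac = p.amino_acid_fractions(rec(seq))
        assert sum(frac.values()) == pytest.approx(1.0, abs=1e-9)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(sequences())
    def test_duplication_invariance(self, seq):
        fv1 = compute_feature_vector(rec(seq))
        fv2 = compute_feature_vector(rec(seq + seq))
        for key in AA_COLUMNS + ["gravy", "sce", "fracnumcharge",
                                 "fracnetcharge", "fracabsnetcharge"]:
            assert fv2[key] == pytest.approx(fv1[key], abs=2e-4), key
        # pI is excluded: it is not a fractional parameter — the fixed
        # termini ionize against a doubled number of side chains, which
        # genuinely moves the zero-charge pH (drastically for tiny peptides)
        assert fv2["length"] == 2 * fv1["length"]
        assert fv2["numcharge"] == 2 * fv1["numcharge"]
        assert fv2["netcharge"] == 2 * fv1["netcharge"]

    def test_split_and_codon_closure(self, rng):
        for r in random_records(rng, 15, with_cds=True):
            fv = compute_feature_vector(r)
            for aa in STANDARD_AA:
                col = aa.lower()
                assert fv[col] == pytest.approx(fv[col + "b"] + fv[col + "e"])
            for aa in "rilp":
                assert fv[f"{aa}_rare"] + fv[f"{aa}_common"] == \
                    pytest.approx(fv[aa])
            assert fv["absnetcharge"] == abs(fv["netcharge"])
            assert fv["fracnumcharge"] >= abs(fv["fracnetcharge"]) - 1e-12
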