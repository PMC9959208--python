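"""Precursor segmentation, amidation, naming, and peptide masses."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from _oracles import composition_mass

from venomest.catalog import family_templates
from venomest.precursor import (
    PeptideMass,
    apply_amidation,
    assign_name,
    call_propeptide,
    call_signal_peptide,
    peptide_mass,
    segment_precursor,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"




class TestSignalPeptide:
    def test_recovers_template_cleavage_sites(self):
        for tpl in family_templates():
            assert call_signal_peptide(tpl.precursor()) == len(tpl.signal), tpl.entry_id

    def test_no_methionine_start(self):
        tpl = family_templates()[0]
        assert call_signal_peptide(tpl.precursor()[5:]) is None

    def test_hydrophilic_n_terminus_rejected(self):
        seq = "M" + "DEDEDKDKDEDKDEDKDEDKDKDEDEDK" + "SASA"
        assert call_signal_peptide(seq) is None

    def test_too_short(self):
        assert call_signal_peptide("MKLLLLVVVVAASA") is None


class TestPropeptide:
    def test_pqm_cleaves_after_arginine(self):
        assert call_propeptide("DDQNELLQSEERAFCDD") == 12

    def test_no_glutamate_no_cleavage(self):
        assert call_propeptide("DDQNLLLQSSSRAFCDD") is None

    def test_two_sites_takes_last_before_first_cysteine(self):
        seq = "NEERQQDDSEERAFCDD"
        assert call_propeptide(seq) == 12

    def test_sites_after_first_cysteine_ignored(self):
        assert call_propeptide("DDQNCAASEERAF") is None


class TestAmidation:
    @pytest.mark.parametrize(
        "raw, expected, amidated",
        [
            ("ACDKFNG", "ACDKFN", True),
            ("ACDKFNGK", "ACDKFN", True),
            ("ACDKFNGGK", "ACDKFNG", True),
            ("ACDKFNF", "ACDKFNF", False),
            ("ACDKFNK", "ACDKFNK", False),
        ],
    )
    def test_motifs(self, raw, expected, amidated):
        assert apply_amidation(raw) == (expected, amidated)

    def test_degenerate_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            apply_amidation("G")


class TestNaming:
    @pytest.mark.parametrize(
        "serial, partial, tx, expected",
        [
            (64, False, False, "LcTx-64"),
            (1436, True, True, "LcTx-1436-P-T"),
            (1421, False, True, "LcTx-1421-T"),
            (1127, True, False, "LcTx-1127-P"),
        ],
    )
    def test_patterns(self, serial, partial, tx, expected):
        assert assign_name(serial, partial, tx) == expected

    def test_serial_must_be_positive(self):
        with pytest.raises(ValueError):
            assign_name(0)


class TestSegmentation:
    def test_template_precursors_segment_exactly(self):
        for tpl in family_templates():
            prec = segment_precursor(tpl.precursor())
            assert prec.signal == (0, len(tpl.signal)), tpl.entry_id
            start = len(tpl.signal) + len(tpl.propeptide)
            assert prec.mature[0] == start, tpl.entry_id
            assert prec.amidated == tpl.amidated, tpl.entry_id
            if tpl.propeptide:
                assert prec.propeptide == (len(tpl.signal), start)

    def test_truncated_precursor_flagged_partial(self):
        tpl = family_templates()[0]
        prec = segment_precursor(tpl.precursor()[10:], has_start=False)
        assert prec.partial_n_terminus
        assert prec.signal is None and prec.propeptide is None


class TestPeptideMass:
    def test_frozen_dipeptide_values(self):
        assert peptide_mass("AG").monoisotopic_da == pytest.approx(146.0691, abs=1e-3)
        assert peptide_mass("CC", n_disulfides=1).monoisotopic_da == pytest.approx(
            222.0133, abs=1e-3
        )
        assert peptide_mass("AG", amidated=True).monoisotopic_da == pytest.approx(
            145.0851, abs=1e-3
        )

    def test_against_composition_oracle(self):
        rng = random.Random(17)
        for _ in range(40):
            seq = "".join(rng.choice(AA20) for _ in range(rng.randint(2, 60)))
            n_ss = rng.randint(0, seq.count("C") // 2)
            amid = rng.random() < 0.5
            pm = peptide_mass(seq, n_disulfides=n_ss, amidated=amid)
            assert pm.monoisotopic_da == pytest.approx(
                composition_mass(seq, n_ss, amid), abs=2e-3
            )
            assert pm.average_da == pytest.approx(
                composition_mass(seq, n_ss, amid, average=True), rel=2e-4
            )

    def test_mono_below_average(self):
        pm = peptide_mass("ACDEFGHIKLMNPQRSTVWY")
        assert pm.monoisotopic_da < pm.average_da

    @given(
        p=st.text(alphabet=AA20, min_size=1, max_size=30),
        q=st.text(alphabet=AA20, min_size=1, max_size=30),
    )
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_mass_additivity(self, p, q):
        water = 18.010565
        whole = peptide_mass(p + q).monoisotopic_da
        parts = peptide_mass(p).monoisotopic_da + peptide_mass(q).monoisotopic_da
        assert whole == pytest.approx(parts - water, abs=1e-6)

    def test_disulfide_delta_constant(self):
        base = peptide_mass("ACCA").monoisotopic_da
        bonded = peptide_mass("ACCA", n_disulfides=1).monoisotopic_da
        assert base - bonded == pytest.approx(2.015650, abs=1e-6)

    def test_nonstandard_residue_rejected(self):
        with pytest.raises(ValueError, match="B"):
            peptide_mass("ABC")

    def test_too_many_disulfides_rejected(self):
        with pytest.raises(ValueError):
            peptide_mass("ACA", n_disulfides=1)
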