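"""Lipid parsing, monoisotopic masses, fragment prediction, sn-position calls."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brainlipid.chem import (
    Chain,
    Formula,
    LipidParseError,
    MsmsSpectrum,
    PROTON_MASS,
    SnPosition,
    assign_sn_position,
    format_lipid_name,
    molecular_formula,
    monoisotopic_mz,
    nominal_mz,
    parse_lipid_name,
    predict_lyso_fragments,
)
from brainlipid.simulate import generate_spectra


class TestParsing:
    @pytest.mark.parametrize(
        "name,cls,chains,totals",
        [
            ("LPE 22:6", "LPE", [(22, 6)], (22, 6)),
            ("TAG 18:0_18:1_20:4", "TAG", [(18, 0), (18, 1), (20, 4)], (56, 5)),
            ("PC 16:0_18:1", "PC", [(16, 0), (18, 1)], (34, 1)),
            ("LPC 20:4", "LPC", [(20, 4)], (20, 4)),
        ],
    )
    def test_chain_level_names(self, name, cls, chains, totals):
        sp = parse_lipid_name(name)
        assert sp.lipid_class == cls
        assert [(c.carbons, c.double_bonds) for c in sp.chains] == chains
        assert (sp.total_carbons, sp.total_double_bonds) == totals
        assert sp.chain_level_known

    def test_species_level_sum_composition(self):
        sp = parse_lipid_name("TAG 56:5")
        assert not sp.chain_level_known
        assert sp.chains == ()
        assert (sp.total_carbons, sp.total_double_bonds) == (56, 5)

    def test_ether_flag(self):
        assert parse_lipid_name("LPE 18:1e").ether
        assert parse_lipid_name("PE_p 16:0_20:4").plasmalogen

    def test_sn_annotation_preserved(self):
        sp = parse_lipid_name("LPE 22:6 [sn-1]")
        assert sp.sn_annotation == "sn-1"
        assert format_lipid_name(sp) == "LPE 22:6 [sn-1]"

    def test_deuterated_standard(self):
        sp = parse_lipid_name("LPE 18:1D7")
        assert sp.chains[0].deuterium == 7

    @pytest.mark.parametrize("bad", ["FOO 1:2", "", "LPE", "LPE x:y", "PC 16:0_18:1_20:0"])
    def test_unparseable_names(self, bad):
        with pytest.raises(LipidParseError):
            parse_lipid_name(bad)

    @given(
        cls=st.sampled_from(["LPE", "LPC", "PC", "PE", "PG", "PS", "PI", "TAG"]),
        chains=st.lists(
            st.tuples(st.integers(2, 30), st.integers(0, 6)), min_size=1, max_size=3
        ),
    )
    @settings(max_examples=150, deadline=None)
    def test_roundtrip_parse_format(self, cls, chains):
        from brainlipid.chem import LIPID_CLASS_CHAINS

        if len(chains) != LIPID_CLASS_CHAINS[cls]:
            return
        name = f"{cls} " + "_".join(f"{c}:{min(d, c // 2)}" for c, d in chains)
        sp = parse_lipid_name(name)
        assert parse_lipid_name(format_lipid_name(sp)) == sp


class TestFormulasAndMasses:
    def test_lpe_formulas_match_backbone_accounting(self):
        # oracle: backbone C5H14NO6P + acyl CnH(2n-2d)O2 - H2O, computed independently
        for name, expected in [("LPE 22:6", "C27H44NO7P"), ("LPE 18:0", "C23H48NO7P")]:
            assert molecular_formula(parse_lipid_name(name)).hill() == expected

    def test_species_level_formula_rejected(self):
        with pytest.raises(ValueError):
            molecular_formula(parse_lipid_name("PC 34:1"))

    def test_unsupported_class_rejected(self):
        with pytest.raises(NotImplementedError):
            molecular_formula(parse_lipid_name("TAG 18:0_18:1_20:4"))

    def test_proton_mz(self):
        assert monoisotopic_mz(Formula(), "[M+H]+") == pytest.approx(1.00728, abs=1e-5)

    def test_lpe_226_deprotonated_ion(self):
        mz = monoisotopic_mz(molecular_formula(parse_lipid_name("LPE 22:6")), "[M-H]-")
        assert mz == pytest.approx(524.278, abs=5e-4)
        assert nominal_mz(mz) == 524

    def test_dha_carboxylate_anion(self):
        mz = monoisotopic_mz(Formula(C=22, H=31, O=2, charge=-1), "fragment_anion")
        assert mz == pytest.approx(327.233, abs=5e-4)
        assert nominal_mz(mz) == 327

    def test_zero_charge_fragment_rejected(self):
        with pytest.raises(ValueError):
            monoisotopic_mz(Formula(C=1, H=4), "fragment_anion")

    @given(
        c=st.integers(0, 40), h=st.integers(0, 80), n=st.integers(0, 3),
        o=st.integers(0, 12), p=st.integers(0, 2),
    )
    @settings(max_examples=100, deadline=None)
    def test_protonation_symmetry(self, c, h, n, o, p):
        """[M+H]+ and [M-H]- differ by exactly two proton masses."""
        f = Formula(C=c, H=h, N=n, O=o, P=p)
        lo = monoisotopic_mz(f, "[M-H]-")
        hi = monoisotopic_mz(f, "[M+H]+")
        assert hi - lo == pytest.approx(2 * PROTON_MASS, abs=1e-4)


class TestFragmentPrediction:
    def test_lpe_226_fragment_set(self):
        frags = {f.label: f.mz for f in predict_lyso_fragments(parse_lipid_name("LPE 22:6"))}
        assert frags["[M-H]-"] == pytest.approx(524.278, abs=5e-4)
        assert frags["acyl anion"] == pytest.approx(327.233, abs=5e-4)
        assert frags["acyl-CO2"] == pytest.approx(283.243, abs=5e-4)
        assert frags["sn1 headgroup diagnostic"] == pytest.approx(196.038, abs=5e-4)

    def test_diagnostic_is_deuterium_insensitive(self):
        """The headgroup fragment of the 18:1D7 standard keeps m/z 196; the acyl shifts."""
        plain = {f.label: f.mz for f in predict_lyso_fragments(parse_lipid_name("LPE 18:1"))}
        deut = {f.label: f.mz for f in predict_lyso_fragments(parse_lipid_name("LPE 18:1D7"))}
        assert deut["sn1 headgroup diagnostic"] == pytest.approx(
            plain["sn1 headgroup diagnostic"], abs=1e-9
        )
        d_minus_h = 2.01410177785 - 1.00782503207
        assert deut["acyl anion"] - plain["acyl anion"] == pytest.approx(7 * d_minus_h, abs=1e-4)

    def test_lpc_has_no_sn1_diagnostic(self):
        frags = predict_lyso_fragments(parse_lipid_name("LPC 22:6"))
        assert not any(f.diagnostic_sn1 for f in frags)
        assert {f.label for f in frags} == {"[M-H]-", "acyl anion", "acyl-CO2"}

    @pytest.mark.parametrize("name", ["LPE 22:6", "LPE 20:4", "LPC 22:6", "LPE 18:1"])
    def test_fragment_mass_relations(self, name):
        frags = {f.label: f.mz for f in predict_lyso_fragments(parse_lipid_name(name))}
        assert frags["acyl anion"] < frags["[M-H]-"]
        assert frags["acyl anion"] - frags["acyl-CO2"] == pytest.approx(43.98983, abs=1e-4)

    def test_unsupported_class(self):
        with pytest.raises(NotImplementedError):
            predict_lyso_fragments(parse_lipid_name("PC 16:0_18:1"))


def _spectrum(mzs, polarity="-", rt=None):
    return MsmsSpectrum(
        precursor_mz=max(mzs) if mzs else 0.0,
        polarity=polarity,
        peaks=[(m, 100.0) for m in mzs],
        retention_time=rt,
    )


class TestSnAssignment:
    def test_full_fragment_set_calls_sn1(self):
        sp = parse_lipid_name("LPE 22:6")
        call = assign_sn_position(_spectrum([524.278, 327.233, 283.243, 196.038]), sp)
        assert call.call is SnPosition.SN1
        assert any(m.diagnostic_sn1 for m in call.evidence)

    def test_missing_diagnostic_calls_sn2(self):
        sp = parse_lipid_name("LPE 22:6")
        call = assign_sn_position(_spectrum([524.278, 327.233, 283.243]), sp)
        assert call.call is SnPosition.SN2

    def test_empty_spectrum_is_ambiguous(self):
        call = assign_sn_position(_spectrum([]), parse_lipid_name("LPE 22:6"))
        assert call.call is SnPosition.AMBIGUOUS

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValueError):
            assign_sn_position(_spectrum([524.278]), parse_lipid_name("LPE 22:6"), ppm_tol=0)

    def test_retention_rule_used_when_spectrum_uninformative(self):
        """Later-eluting isomer of an observed pair is labelled sn-1."""
        sp = parse_lipid_name("LPC 22:6")
        later = assign_sn_position(_spectrum([]), sp, rt_context=(7.4, 7.0))
        earlier = assign_sn_position(_spectrum([]), sp, rt_context=(7.0, 7.4))
        assert later.call is SnPosition.SN1 and later.rt_rule_applied
        assert earlier.call is SnPosition.SN2 and earlier.rt_rule_applied

    def test_spectral_diagnostic_outranks_retention_order(self):
        sp = parse_lipid_name("LPE 22:6")
        call = assign_sn_position(
            _spectrum([524.278, 327.233, 283.243, 196.038]), sp, rt_context=(7.0, 7.4)
        )
        assert call.call is SnPosition.SN1
        assert not call.rt_rule_applied
        assert "conflict" in call.note

    def test_peak_deletion_degrades_to_ambiguous_never_flips(self):
        """Removing required peaks can only make the call ambiguous, not wrong."""
        sp = parse_lipid_name("LPE 22:6")
        full = [524.278, 327.233, 283.243, 196.038]
        for drop in range(3):  # drop intact, then acyl peaks
            peaks = [m for i, m in enumerate(full) if i != drop]
            call = assign_sn_position(_spectrum(peaks), sp)
            assert call.call in (SnPosition.SN1, SnPosition.AMBIGUOUS)
        call = assign_sn_position(_spectrum([196.038]), sp)
        assert call.call is SnPosition.AMBIGUOUS

    def test_generated_spectra_roundtrip(self):
        """Generator spectra with jitter and decoys are always called correctly."""
        pairs = [("LPE 22:6", "sn1"), ("LPE 22:6", "sn2"), ("LPE 20:4", "sn1"),
                 ("LPE 18:1", "sn2")] * 5
        spectra, truth = generate_spectra(pairs, ppm_jitter=10.0, n_decoys=20, seed=5)
        for spec in spectra:
            name = spec.title.split("|")[1]
            call = assign_sn_position(spec, parse_lipid_name(name), ppm_tol=10.0)
            assert call.call.value == truth[spec.title]
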