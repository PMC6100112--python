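"""Generative model: references, truth profiles, and trinomial count draws."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hmucall import simdata
from hmucall.simdata import ConversionModel, ModificationProfile, ModSite


class TestConversionModel:
    def test_presets_match_amplicon_rates(self):
        m1 = simdata.preset("ODN1_site1")
        assert (m1.p_conv, m1.p_other_mod, m1.p_ctrl_c) == (0.394, 0.099, 0.022)
        m2 = simdata.preset("ODN1_site2")
        assert (m2.p_conv, m2.p_other_mod, m2.p_ctrl_c) == (0.303, 0.046, 0.027)
        assert m1.p_bg_c == 0.014

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"p_conv": -0.1, "p_other_mod": 0.0},
            {"p_conv": 0.7, "p_other_mod": 0.5},
            {"p_conv": 0.1, "p_other_mod": 0.0, "p_bg_c": 1.5},
        ],
    )
    def test_invalid_rates_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ConversionModel(**kwargs)

    def test_unknown_preset(self):
        with pytest.raises(ValueError, match="unknown preset"):
            simdata.preset("ODN9")

    def test_level_mixes_rates_linearly(self, site1_model):
        # effective C rate = level * p_conv + (1 - level) * p_bg_c
        _, p_c, _ = simdata.site_rates(0.5, site1_model, "treated")
        assert p_c == pytest.approx(0.5 * 0.394 + 0.5 * 0.014)
        _, p_c0, _ = simdata.site_rates(0.0, site1_model, "treated")
        assert p_c0 == pytest.approx(0.014)
        _, p_ctrl, _ = simdata.site_rates(1.0, site1_model, "control")
        assert p_ctrl == pytest.approx(0.022)


class TestMakeOdn:
    def test_unknown_model_id(self):
        with pytest.raises(ValueError, match="unknown ODN model"):
            simdata.make_odn("ODN99", seed=1)

    def test_deterministic(self):
        r1, p1 = simdata.make_odn("ODN1", seed=1)
        r2, p2 = simdata.make_odn("ODN1", seed=1)
        assert [str(a.seq) for a in r1] == [str(b.seq) for b in r2]
        assert p1.entries == p2.entries

    def test_odn1_structure(self, odn1):
        records, profile = odn1
        seq = str(records[0].seq)
        assert len(profile) == 2
        assert all(e.level == 1.0 for e in profile)
        unmodified_ts = seq.count("T") - len(profile)
        assert unmodified_ts >= 7
        for e in profile:
            assert seq[e.pos0] == "T"

    def test_odn2_levels_in_titration_range(self):
        _, profile = simdata.make_odn("ODN2", seed=3)
        assert all(0.0 <= e.level <= 0.26 for e in profile)
        assert len(profile) == 2

    def test_odn3_enumerates_all_16_contexts(self):
        records, profile = simdata.make_odn("ODN3", seed=7)
        assert len(records) == len(profile) == 16
        seqs = {r.id: str(r.seq) for r in records}
        contexts = {(seqs[e.ref][e.pos0 - 1], seqs[e.ref][e.pos0 + 1]) for e in profile}
        assert contexts == {(a, b) for a in "ACGT" for b in "ACGT"}

    def test_genome_sites_are_ts(self):
        records, profile = simdata.make_genome(length=5000, n_sites=5, seed=2)
        seq = str(records[0].seq)
        assert len(profile) == 5
        assert all(seq[e.pos0] == "T" for e in profile)


class TestProfileValidation:
    def test_non_t_position_rejected(self):
        profile = ModificationProfile([ModSite("r", 0, "+", 1.0)])
        with pytest.raises(ValueError, match="expected 'T'"):
            simdata.simulate_counts(
                {"r": "GATTA"}, profile, simdata.preset("ODN1_site1"), 10, 1, "treated", 1
            )

    def test_reverse_strand_requires_a(self):
        profile = ModificationProfile([ModSite("r", 1, "-", 1.0)])
        profile.validate({"r": "GATTA"})  # A at pos 1
        bad = ModificationProfile([ModSite("r", 2, "-", 1.0)])
        with pytest.raises(ValueError, match="expected 'A'"):
            bad.validate({"r": "GATTA"})


class TestSimulateCounts:
    def test_conservation_and_determinism(self, odn1, site1_model):
        records, profile = odn1
        df = simdata.simulate_counts(records, profile, site1_model, 500, 3, "treated", 9)
        assert ((df.n_T + df.n_C + df.n_other) == df.depth).all()
        assert (df.depth == 500).all()
        df2 = simdata.simulate_counts(records, profile, site1_model, 500, 3, "treated", 9)
        pd.testing.assert_frame_equal(df, df2)

    def test_large_depth_recovers_generative_rates(self, site1_model):
        """Law of large numbers: depth 1e6 C fraction within 0.002 of p_conv."""
        refs = {"amp": "AAATAAA"}
        profile = ModificationProfile([ModSite("amp", 3, "+", 1.0)])
        df = simdata.simulate_counts(refs, profile, site1_model, 10**6, 1, "treated", 5)
        assert df.n_C[0] / df.depth[0] == pytest.approx(0.394, abs=0.002)
        ctrl = simdata.simulate_counts(refs, profile, site1_model, 10**6, 1, "control", 5)
        assert ctrl.n_C[0] / ctrl.depth[0] == pytest.approx(0.022, abs=0.001)

    def test_zero_background_gives_zero_c(self):
        model = ConversionModel(p_conv=0.4, p_other_mod=0.0, p_bg_c=0.0, p_bg_other=0.0)
        refs = {"amp": "AATAA"}
        profile = ModificationProfile([ModSite("amp", 2, "+", 0.0)])  # unmodified
        for cond in simdata.CONDITIONS:
            df = simdata.simulate_counts(refs, profile, model, 10_000, 2, cond, 3)
            assert (df.n_C == 0).all()

    def test_expected_c_fraction_monotone_in_level(self, site1_model):
        refs = {"amp": "AATAA"}
        fracs = []
        for level in [0.0, 0.05, 0.1, 0.2, 0.5, 1.0]:
            profile = ModificationProfile([ModSite("amp", 2, "+", level)])
            df = simdata.simulate_counts(refs, profile, site1_model, 200_000, 1, "treated", 4)
            fracs.append(df.n_C[0] / df.depth[0])
        assert all(a < b for a, b in zip(fracs, fracs[1:]))

    def test_treated_control_identical_in_law_at_unmodified_sites(self, site1_model):
        """KS on per-replicate C counts at a level-0 site must not reject."""
        refs = {"amp": "AATAA"}
        profile = ModificationProfile([ModSite("amp", 2, "+", 0.0)])
        t = simdata.simulate_counts(refs, profile, site1_model, 1000, 300, "treated", 11)
        c = simdata.simulate_counts(refs, profile, site1_model, 1000, 300, "control", 12)
        res = stats.ks_2samp(t.n_C, c.n_C)
        assert res.pvalue > 0.001

    def test_poisson_depth_mode_varies_depth(self, odn1, site1_model):
        records, profile = odn1
        df = simdata.simulate_counts(
            records, profile, site1_model, 200, 2, "treated", 9, poisson_depth=True
        )
        assert df.depth.nunique() > 1
        assert ((df.n_T + df.n_C + df.n_other) == df.depth).all()


class TestReadEmission:
    def test_deterministic_limit_all_reads_converted(self):
        """p_conv=1 and zero noise: every read shows C at the modified site only."""
        model = ConversionModel(p_conv=1.0, p_other_mod=0.0, p_bg_c=0.0, p_bg_other=0.0)
        refs = {"amp": "GTATTG"}
        profile = ModificationProfile([ModSite("amp", 3, "+", 1.0)])
        counts = simdata.simulate_counts(refs, profile, model, 100, 1, "treated", 2)
        reads = simdata.reads_from_counts(refs, counts, seed=2)
        assert len(reads[1]) == 100
        for r in reads[1]:
            assert r[3] == "C"
            assert r[1] == "T" and r[4] == "T"

    def test_truth_bed_cardinality_and_score(self, odn1):
        _, profile = odn1
        bed = simdata.truth_bed(profile)
        assert len(bed) == len(profile)
        assert (bed.end - bed.start == 1).all()
        assert (bed.score == 1000).all()  # level 1.0 scaled by 1000

    def test_mixed_condition_table_rejected(self, odn1_experiment):
        both = pd.concat([odn1_experiment.treated, odn1_experiment.control])
        with pytest.raises(ValueError, match="mixes conditions"):
            simdata.reads_from_counts(odn1_experiment.references, both, seed=1)
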