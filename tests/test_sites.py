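import logging

import numpy as np
import pytest

from cleavemap import (
    Reference,
    SiteCallConfig,
    build_motif,
    call_candidates,
    export_logo,
    export_pfm,
    load_pfm,
)
from cleavemap.mapping import CoverageProfile
from cleavemap.sites import CleavageCandidate
from oracles import information_content_by_hand


def profile(coverage, ref_id="r"):
    cov = np.asarray(coverage, dtype=np.int64)
    return CoverageProfile(ref_id, cov, np.zeros_like(cov))


def window(seq):
    return CleavageCandidate("r", 5, 2.0, 2000, seq)


class TestCallCandidates:
    def test_flat_profile_ties_break_to_smallest_position(self):
        ref = Reference("r", "ACGUACGUAC")
        cands = call_candidates(profile([2000] * 10), ref, SiteCallConfig())
        assert [c.zero_pos for c in cands] == [1, 2, 3, 4, 5]
        assert all(c.rci_value == 1.0 for c in cands)

    def test_step_passes_filter_at_stepped_position(self):
        # 500 -> 5000 step: only the stepped-up position exceeds the
        # coverage threshold, and it does so at position n, not n-1
        ref = Reference("r", "ACGUACGU")
        cands = call_candidates(
            profile([500] * 7 + [5000]), ref, SiteCallConfig(min_coverage=1000)
        )
        assert len(cands) == 1
        assert cands[0].zero_pos == 7
        assert cands[0].rci_value == pytest.approx(10.0)
        assert cands[0].coverage_at_zero == 5000

    def test_strict_threshold_excludes_exact_value(self):
        ref = Reference("r", "ACGUACGU")
        cov = [1000] * 8
        assert call_candidates(profile(cov), ref, SiteCallConfig()) == []
        relaxed = SiteCallConfig(strict_coverage=False)
        assert len(call_candidates(profile(cov), ref, relaxed)) == 5

    def test_rci_ranking_selects_largest_steps(self):
        ref = Reference("r", "ACGUACGUACGUACGUACGU")
        cov = [1500] * 20
        cov[5], cov[6] = 1500, 6000  # rci 4 at 6
        cov[10], cov[11] = 1500, 3000  # rci 2 at 11
        cands = call_candidates(
            profile(cov), ref, SiteCallConfig(top_k_per_ref=2)
        )
        assert [c.zero_pos for c in cands] == [6, 11]

    def test_edge_window_is_n_padded(self):
        ref = Reference("r", "ACGUACGUACGUACGUACGU")
        cov = [2000] * 20
        cands = call_candidates(profile(cov), ref, SiteCallConfig(top_k_per_ref=1))
        (cand,) = cands
        assert cand.zero_pos == 1
        assert cand.window == "NNNN" + ref.sequence[0:7]

    def test_undefined_rci_positions_are_never_candidates(self):
        ref = Reference("r", "ACGUACGU")
        cands = call_candidates(
            profile([0, 0, 5000, 5000, 5000, 0, 0, 0]), ref, SiteCallConfig()
        )
        assert [c.zero_pos for c in cands] == [3, 4]  # pos 2 follows zero coverage

    def test_warns_when_fewer_than_top_k_qualify(self, caplog):
        ref = Reference("r", "ACGUACGU")
        with caplog.at_level(logging.WARNING, logger="cleavemap.sites"):
            call_candidates(profile([500] * 7 + [5000]), ref, SiteCallConfig())
        assert "only 1 of 5" in caplog.text


class TestBuildMotif:
    def test_unanimous_windows_are_fully_conserved(self):
        motif = build_motif([window("GGUUAACAGCU") for _ in range(25)], flank=5)
        f = motif.frequencies()
        ic = motif.information_content()
        assert f[0, 5] == 1.0  # A at position 0
        assert ic[5] == pytest.approx(2.0)
        assert motif.consensus[5] == "A"
        assert motif.n_windows == 25

    def test_ic_matches_hand_computation(self):
        # column counts A=13, C=4, G=4, U=4 at position 0
        windows = (
            [window("NNNNNANNNNN")] * 13
            + [window("NNNNNCNNNNN")] * 4
            + [window("NNNNNGNNNNN")] * 4
            + [window("NNNNNUNNNNN")] * 4
        )
        motif = build_motif(windows, flank=5)
        expected = information_content_by_hand({"A": 13, "C": 4, "G": 4, "U": 4})
        assert motif.information_content()[5] == pytest.approx(expected, abs=1e-12)
        # all-N columns carry no information and zero totals
        assert motif.column_totals[0] == 0
        assert motif.information_content()[0] == 0.0

    def test_uniform_windows_have_near_zero_ic(self, rng):
        bases = np.array(list("ACGU"))
        windows = [
            window("".join(rng.choice(bases, size=11))) for _ in range(4000)
        ]
        motif = build_motif(windows, flank=5)
        assert motif.information_content().max() < 0.01
        assert motif.motif is None
        assert "no conserved motif" in motif.report_line()

    def test_small_sample_correction_lowers_ic(self):
        motif = build_motif([window("GGUUAACAGCU")] * 25, flank=5)
        corrected = build_motif(
            [window("GGUUAACAGCU")] * 25, flank=5, small_sample_correction=True
        )
        assert corrected.information_content()[5] < motif.information_content()[5]

    def test_consensus_run_must_contain_position_zero(self):
        # conserved bases only at positions +3..+4: no motif is called even
        # though those columns individually pass the thresholds
        wins = [window("NNNNNNNNACN") for _ in range(25)]
        motif = build_motif(wins, flank=5)
        assert motif.called_columns()[8:10].all()
        assert motif.motif is None

    def test_motif_anchored_at_minus_one_when_zero_uncalled(self):
        # conserved U at position -1 only (cut-side base), position 0 mixed
        wins = [window("NNNNU" + b + "NNNNN") for b in "ACGU" * 6 + "A"]
        motif = build_motif(wins, flank=5)
        assert motif.motif == "U"
        assert motif.motif_span == (-1, -1)

    def test_zero_candidates_is_an_error(self):
        with pytest.raises(ValueError, match="zero candidates"):
            build_motif([], flank=5)

    def test_report_line_names_cut_site(self):
        motif = build_motif([window("GGUUAACAGCU")] * 25, flank=5)
        line = motif.report_line()
        assert "cut between -1 and 0" in line
        assert "support 25 windows" in line


class TestExport:
    def test_pfm_roundtrip_is_exact(self, tmp_path):
        motif = build_motif(
            [window("GGUUAACAGCU")] * 13 + [window("CCAAUUGGCCA")] * 12, flank=5
        )
        path = tmp_path / "pfm.tsv"
        export_pfm(motif, path)
        assert np.array_equal(load_pfm(path), motif.pfm)
        header = path.read_text().splitlines()[0]
        assert header.split("\t")[1:3] == ["-5", "-4"]

    def test_logo_written(self, tmp_path):
        motif = build_motif([window("GGUUAACAGCU")] * 25, flank=5)
        path = tmp_path / "logo.png"
        assert export_logo(motif, path)
        assert path.stat().st_size > 0
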