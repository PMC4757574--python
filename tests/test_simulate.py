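import numpy as np
import pytest

from cleavemap import (
    DEFAULT_ANCHOR,
    DEFAULT_BARCODE,
    Reference,
    SimulationConfig,
    digest,
    digest_molecule,
    generate_references,
    simulate_library,
)
from cleavemap.simulate import nonspecific_control_config


def small_cfg(**kw):
    params = dict(
        n_refs=2,
        ref_length=120,
        n_molecules=20,
        n_read_pairs=500,
        read_length=80,
        seed=3,
    )
    params.update(kw)
    return SimulationConfig(**params)


class TestGenerateReferences:
    def test_default_geometry_is_1033_nt(self):
        cfg = SimulationConfig(seed=0)
        refs, _ = generate_references(cfg, np.random.default_rng(0))
        assert len(refs) == 5
        assert all(len(r) == 1033 for r in refs)
        assert all(r.sequence.startswith("GGG") for r in refs)
        assert all(r.sequence.endswith("A" * 30) for r in refs)
        assert refs.alphabet == "RNA"

    def test_diverse_region_composition_near_uniform(self):
        cfg = SimulationConfig(seed=0)
        refs, _ = generate_references(cfg, np.random.default_rng(1))
        # binomial 3-sigma band around 250 per base in a 1000-nt region
        sigma = np.sqrt(1000 * 0.25 * 0.75)
        for ref in refs:
            body = ref.sequence[3:-30]
            for base in "ACGU":
                assert abs(body.count(base) - 250) < 3 * sigma + 1

    def test_ground_truth_sites_match_independent_scan(self):
        cfg = SimulationConfig(seed=0, motif="UAC", cut_offset=1)
        refs, sites = generate_references(cfg, np.random.default_rng(5))
        by_ref = {}
        for site in sites:
            by_ref.setdefault(site.ref_id, []).append(site)
        for ref in refs:
            seq = ref.sequence.replace("U", "T")
            expected = [
                i for i in range(len(seq) - 2) if seq[i : i + 3] == "TAC"
            ]
            got = sorted(s.motif_start for s in by_ref.get(ref.id, []))
            assert got == expected
            assert all(s.cut_pos == s.motif_start + 1 for s in sites)

    def test_site_count_in_poisson_band(self):
        # a 3-mer occurs ~1000/64 times per diverse region on average
        cfg = SimulationConfig(seed=0)
        counts = []
        for seed in range(8):
            refs, sites = generate_references(cfg, np.random.default_rng(seed))
            counts.append(len(sites) / len(refs))
        mean = np.mean(counts)
        expect = 1000 / 64
        assert expect - 5 < mean < expect + 5


class TestDigest:
    def test_deterministic_single_cut(self):
        ref = Reference("r", "GGGGGACAGGGGGGGGGGGG")
        cfg = small_cfg(p_cleave=1.0, background_break_rate=0.0)
        frags = digest_molecule(ref, [5], cfg, np.random.default_rng(0))
        assert [(f.start, f.end) for f in frags] == [(0, 5), (5, 20)]
        assert frags[1].five_prime_is_cleavage
        assert not frags[0].five_prime_is_cleavage

    def test_no_cleavage_returns_whole_molecule(self):
        ref = Reference("r", "GGGGGACAGGGGGGGGGGGG")
        cfg = small_cfg(p_cleave=0.0, background_break_rate=0.0)
        frags = digest_molecule(ref, [5], cfg, np.random.default_rng(0))
        assert [(f.start, f.end) for f in frags] == [(0, 20)]

    def test_sequence_conservation(self):
        cfg = small_cfg(background_break_rate=0.01)
        rng = np.random.default_rng(11)
        refs, sites = generate_references(cfg, rng)
        cuts = [s.cut_pos for s in sites if s.ref_id == refs.ids()[0]]
        ref = refs.references[0]
        for _ in range(20):
            frags = digest_molecule(ref, cuts, cfg, rng)
            assert frags[0].start == 0 and frags[-1].end == len(ref)
            joined = "".join(
                ref.sequence[f.start : f.end] for f in frags
            )
            assert joined == ref.sequence

    def test_mean_fragment_count_matches_binomial_expectation(self):
        # 10 sites at p=0.5 -> 1 + 5 expected fragments per molecule
        ref = Reference("r", "A" * 200)
        cfg = small_cfg(p_cleave=0.5, background_break_rate=0.0)
        rng = np.random.default_rng(2)
        cuts = list(range(10, 110, 10))
        counts = [
            len(digest_molecule(ref, cuts, cfg, rng)) for _ in range(2000)
        ]
        assert np.mean(counts) == pytest.approx(6.0, abs=0.2)


class TestMakeLibrary:
    def test_barcode_default_ends_with_anchor(self):
        assert len(DEFAULT_BARCODE) == 45
        assert DEFAULT_BARCODE.endswith(DEFAULT_ANCHOR)
        assert SimulationConfig(seed=0).anchor == DEFAULT_ANCHOR

    def test_zero_ligation_means_no_anchored_reads(self):
        sim = simulate_library(small_cfg(ligation_efficiency=0.0))
        for r1, r2, _ in sim.library.iter_pairs():
            assert DEFAULT_ANCHOR not in r1.sequence
            assert DEFAULT_ANCHOR not in r2.sequence

    def test_full_ligation_prefixes_every_r1_with_barcode(self):
        sim = simulate_library(small_cfg(ligation_efficiency=1.0))
        for r1, _, _ in sim.library.iter_pairs():
            assert r1.sequence.startswith(DEFAULT_BARCODE[: len(r1.sequence)])
            if len(r1.sequence) >= 45:
                assert r1.sequence[30:45] == DEFAULT_ANCHOR

    def test_fixed_seed_reproduces_byte_identical_fastq(self, tmp_path):
        for name in ("a", "b"):
            sim = simulate_library(small_cfg())
            sim.library.write(tmp_path / name)
        for fname in ("reads_R1.fastq", "reads_R2.fastq", "references.fasta", "truth.tsv"):
            assert (tmp_path / "a" / fname).read_bytes() == (
                tmp_path / "b" / fname
            ).read_bytes()

    def test_different_seeds_differ_in_reads_not_geometry(self, tmp_path):
        sims = [simulate_library(small_cfg(seed=s)) for s in (1, 2)]
        assert [len(r) for r in sims[0].refs] == [len(r) for r in sims[1].refs]
        reads_a = [r1.sequence for r1, _, _ in sims[0].library.iter_pairs()]
        reads_b = [r1.sequence for r1, _, _ in sims[1].library.iter_pairs()]
        assert reads_a != reads_b

    def test_aggregated_pairs_equal_per_read_multiset(self):
        sim = simulate_library(small_cfg())
        from collections import Counter

        per_read = Counter(
            (r1.sequence, r2.sequence) for r1, r2, _ in sim.library.iter_pairs()
        )
        aggregated = Counter()
        for r1, r2, count in sim.library.aggregated_pairs():
            aggregated[(r1.sequence, r2.sequence)] += count
        assert aggregated == per_read

    def test_aggregation_refuses_error_model(self):
        sim = simulate_library(small_cfg(error_rate=0.01))
        with pytest.raises(ValueError, match="aggregation"):
            sim.library.aggregated_pairs()
        # the error model itself stays deterministic per configuration
        a = [r1.sequence for r1, _, _ in sim.library.iter_pairs()]
        b = [r1.sequence for r1, _, _ in sim.library.iter_pairs()]
        assert a == b

    def test_nonspecific_control_has_no_motif_sites(self):
        cfg = nonspecific_control_config(n_refs=2, ref_length=100, seed=4,
                                         n_molecules=10, n_read_pairs=100)
        rng = np.random.default_rng(cfg.seed)
        refs, sites = generate_references(cfg, rng)
        assert sites == []
        frags = digest(refs, sites, cfg, rng)
        assert all(not f.five_prime_is_cleavage for f in frags)
        assert len(frags) > cfg.n_molecules * len(refs)  # background broke some
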