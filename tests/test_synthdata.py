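"""The synthetic superfamily generator against independent oracles."""

import numpy as np
import pytest

from famforge.formats import AMINO_ACIDS
from famforge.motifarch import scan_zipper
from famforge.synthdata import (CONSERVED_RATE, BenchmarkConfig,
                                SyntheticFamilySpec, generate_background,
                                generate_benchmark, generate_decoys,
                                generate_superfamily, generate_tandem)


def aligned_identity(row_a: str, row_b: str) -> float:
    pairs = [(a, b) for a, b in zip(row_a, row_b) if a != "-" and b != "-"]
    return sum(a == b for a, b in pairs) / len(pairs)


class TestSuperfamily:
    def test_zero_divergence_members_identical_to_ancestor(self):
        spec = SyntheticFamilySpec(n_subfamilies=2, members_per_subfamily=3,
                                   inter_sub_divergence=0.0,
                                   intra_sub_divergence=0.0, seed=3)
        recs, _ = generate_superfamily(spec)
        assert len({r.residues for r in recs}) == 1

    def test_same_seed_byte_identical(self):
        spec = SyntheticFamilySpec(seed=9)
        a, ta = generate_superfamily(spec)
        b, tb = generate_superfamily(spec)
        assert [r.residues for r in a] == [r.residues for r in b]
        assert ta.tree_newick == tb.tree_newick
        assert ta.alignment == tb.alignment

    def test_zipper_too_large_for_helix(self):
        with pytest.raises(ValueError, match="zipper"):
            SyntheticFamilySpec(tm_len=8, zippers_per_helix=1)

    def test_zipper_columns_inside_tm_columns(self):
        spec = SyntheticFamilySpec(members_per_subfamily=4, seed=5)
        recs, truth = generate_superfamily(spec)
        # zipper columns must carry G in most members (conserved motif)
        for c in truth.zipper_columns:
            col = [truth.alignment.rows[r.id][c] for r in recs]
            non_gap = [ch for ch in col if ch != "-"]
            assert sum(ch == "G" for ch in non_gap) / len(non_gap) > 0.5

    def test_intra_identity_matches_monte_carlo_oracle(self):
        """Mean within-subfamily identity equals a direct simulation of the
        same substitution process (+- 2 percentage points, 50 replicates)."""
        d = 0.4
        spec = SyntheticFamilySpec(n_subfamilies=1, members_per_subfamily=2,
                                   inter_sub_divergence=0.0,
                                   intra_sub_divergence=d)
        observed = []
        for seed in range(50):
            recs, truth = generate_superfamily(
                SyntheticFamilySpec(**{**spec.__dict__, "seed": seed}))
            a, b = (truth.alignment.rows[r.id] for r in recs)
            observed.append(aligned_identity(a, b))

        # oracle: two lineages diverge from a common site by d/2 each,
        # Poisson substitution counts, uniform replacement among 19;
        # conserved sites at 1/10 rate with the generator's architecture
        L = 4 * spec.tm_len + 5 * spec.loop_len
        n_conserved = 4 * spec.zippers_per_helix * 3 + 2
        rng = np.random.default_rng(12345)
        n_sites = 200_000
        rates = np.where(rng.random(n_sites) < n_conserved / L, CONSERVED_RATE, 1.0)
        start = rng.integers(0, 20, size=n_sites)
        seqs = []
        for _branch in range(2):
            cur = start.copy()
            n_sub = rng.poisson(d / 2 * rates)
            for k in range(1, n_sub.max() + 1):
                idx = np.nonzero(n_sub >= k)[0]
                shift = rng.integers(1, 20, size=idx.size)
                cur[idx] = (cur[idx] + shift) % 20
            seqs.append(cur)
        expected = float((seqs[0] == seqs[1]).mean())
        assert abs(np.mean(observed) - expected) <= 0.02

    def test_zipper_conservation_exceeds_background_positions(self):
        """Fraction of members retaining ancestral G at zipper positions >=
        fraction retaining the ancestral residue at non-motif positions."""
        spec = SyntheticFamilySpec(members_per_subfamily=20, seed=17)
        recs, truth = generate_superfamily(spec)
        aln = truth.alignment
        ids = [r.id for r in recs]
        zset = set(truth.zipper_columns)

        def retention(col):
            residues = [aln.rows[i][col] for i in ids]
            non_gap = [ch for ch in residues if ch != "-"]
            if not non_gap:
                return None
            # ancestral state approximated by the majority residue
            top = max(set(non_gap), key=non_gap.count)
            return non_gap.count(top) / len(non_gap)

        z_ret = np.mean([retention(c) for c in truth.zipper_columns])
        rng = np.random.default_rng(0)
        others = [c for c in range(aln.n_cols) if c not in zset]
        sample = rng.choice(others, size=100, replace=False)
        o_ret = np.mean([r for c in sample if (r := retention(int(c))) is not None])
        assert z_ret >= o_ret


class TestDecoys:
    def test_every_decoy_has_two_zipper_matches(self):
        for d in generate_decoys(30, seed=4):
            assert len(scan_zipper(d)) >= 2

    def test_n_one(self):
        assert len(generate_decoys(1, seed=0)) == 1

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            generate_decoys(0, seed=0)

    def test_identity_to_family_outside_zippers_is_background(self):
        """Position-wise identity decoy-vs-member away from the implanted
        zipper positions ~ 1/20, the i.i.d. uniform expectation, by direct
        counting on 20 random pairs."""
        recs, _ = generate_superfamily(SyntheticFamilySpec(seed=2))
        decoys = generate_decoys(20, seed=6)
        rng = np.random.default_rng(8)
        idents = []
        for _ in range(20):
            d = decoys[rng.integers(len(decoys))]
            f = recs[rng.integers(len(recs))]
            zipper_pos = {p for m in scan_zipper(d) for p in range(m.start, m.end)}
            pairs = [(a, b) for i, (a, b) in enumerate(zip(d.residues, f.residues))
                     if i not in zipper_pos]
            idents.append(sum(a == b for a, b in pairs) / len(pairs))
        assert abs(np.mean(idents) - 0.05) < 0.02


class TestTandem:
    def test_concatenation_length(self):
        recs, _ = generate_superfamily(SyntheticFamilySpec(seed=1))
        tds, parts = generate_tandem(recs, seed=5, n=4)
        by_id = {r.id: r for r in recs}
        for t in tds:
            a, b = parts[t.id]
            linker = len(t.residues) - len(by_id[a]) - len(by_id[b])
            assert 10 <= linker <= 30

    def test_same_seed_same_linkers(self):
        recs, _ = generate_superfamily(SyntheticFamilySpec(seed=1))
        t1, _ = generate_tandem(recs, seed=5, n=3)
        t2, _ = generate_tandem(recs, seed=5, n=3)
        assert [t.residues for t in t1] == [t.residues for t in t2]

    def test_too_few_inputs(self):
        recs, _ = generate_superfamily(
            SyntheticFamilySpec(n_subfamilies=1, members_per_subfamily=1, seed=1))
        with pytest.raises(ValueError):
            generate_tandem(recs[:1], seed=0)

    def test_both_halves_pass_validation(self, pipeline_state, db_map, truth):
        """Each half of a tandem record, cut at the true junction, is
        accepted by masked profile-profile validation."""
        from famforge.iterpipe import PipelineParams, build_master_profile
        from famforge.profcomp import self_calibrate_master, validate_candidate
        from famforge.profilehmm import profile_from_sequence
        from famforge.formats import ProteinRecord

        master = build_master_profile(pipeline_state, PipelineParams())
        self_calibrate_master(master, pipeline_state.master_alignment, seed=99)
        tid = sorted(truth.tandem_parts)[0]
        a_id, b_id = truth.tandem_parts[tid]
        rec = db_map[tid]
        la = len(db_map[a_id].residues)
        halves = [rec.residues[:la], rec.residues[-len(db_map[b_id].residues):]]
        for k, half in enumerate(halves):
            cand = profile_from_sequence(ProteinRecord(id=f"{tid}_h{k}", residues=half))
            accepted, _ = validate_candidate(cand, master)
            assert accepted


class TestBenchmark:
    def test_truth_arithmetic_and_partition(self, tmp_path):
        cfg = BenchmarkConfig(members_per_subfamily_per_proteome=10,
                              decoys_per_proteome=20, background_per_proteome=200,
                              tandems_per_proteome=0, seed=2)
        proteomes, truth = generate_benchmark(cfg, out_dir=tmp_path / "b")
        assert sum(len(v) for v in proteomes.values()) == 750
        lines = (tmp_path / "b" / "truth.tsv").read_text().strip().splitlines()
        assert len(lines) - 1 == 750
        ids = [ln.split("\t")[0] for ln in lines[1:]]
        assert len(ids) == len(set(ids))  # labels partition record ids
        assert set(ids) == set(truth.labels)

    def test_refuses_nonempty_dir_without_force(self, tmp_path):
        out = tmp_path / "b"
        out.mkdir()
        (out / "junk.txt").write_text("x")
        with pytest.raises(FileExistsError):
            generate_benchmark(BenchmarkConfig(seed=2), out_dir=out)

    def test_regeneration_byte_identical(self, tmp_path):
        cfg = BenchmarkConfig(members_per_subfamily_per_proteome=3,
                              decoys_per_proteome=3, background_per_proteome=10,
                              seed=4)
        generate_benchmark(cfg, out_dir=tmp_path / "a")
        generate_benchmark(cfg, out_dir=tmp_path / "b")
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()


def test_background_lengths_in_range():
    for r in generate_background(20, seed=3, length_range=(50, 80)):
        assert 50 <= len(r.residues) <= 80
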