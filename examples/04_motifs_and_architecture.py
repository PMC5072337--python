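"""Motif scanning, transmembrane prediction and tandem-domain splitting.

Scans the PRAT pattern ([GA]-x-x-[FY]-x(10)-R-x(3)-D-x(6)-[GAS]-G-x(3)-G)
and the glycine zipper, predicts TM segments by Kyte-Doolittle hydropathy,
and splits a two-domain tandem protein by score-mask-rescore against the
family profile.
"""

from famforge import (BenchmarkConfig, SyntheticFamilySpec, generate_benchmark,
                      generate_superfamily, seed_alignment)
from famforge.iterpipe import PipelineParams, build_master_profile, run_pipeline
from famforge.motifarch import predict_tm, scan_prat, scan_zipper, split_tandem
from famforge.profilehmm import calibrate

prat_hit = "GAAYAAAAAAAAAARAAADAAAAAAGGAAAG"
print(f"PRAT scan of the canonical 31-mer: {len(scan_prat(prat_hit))} match")

# TM architecture of a family at modest divergence
recs, truth = generate_superfamily(SyntheticFamilySpec(
    n_subfamilies=1, members_per_subfamily=5, inter_sub_divergence=0.0,
    intra_sub_divergence=0.3, seed=11))
r = recs[0]
segs = predict_tm(r.residues)
print(f"{r.id}: {len(scan_zipper(r))} zippers, "
      f"{len(segs)} predicted TM segments "
      f"(true helices: {truth.tm_segments[r.id]})")
for t in segs:
    print(f"  TM {t.start:3d}-{t.end:3d}  mean hydropathy {t.mean_hydropathy:+.2f}")

# tandem splitting on the benchmark
proteomes, btruth = generate_benchmark(BenchmarkConfig(seed=1))
db = {x.id: x for pid in sorted(proteomes) for x in proteomes[pid]}
state = run_pipeline(seed_alignment(btruth, "subfamily_1", 5), db.values(),
                     PipelineParams(seed=1))
prof = build_master_profile(state, PipelineParams(), masked=False)
calibrate(prof, seed=19)
tid = sorted(btruth.tandem_parts)[0]
arch = split_tandem(db[tid], prof, db_size=len(db))
print(f"{tid} ({btruth.tandem_parts[tid][0]}+{btruth.tandem_parts[tid][1]}): "
      f"{arch.n_tim17_domains} family domains at {arch.domain_envelopes}, "
      f"{len(arch.tm_segments)} TM segments")
# A tandem record carries two linked family domains; each envelope will
# enter the tree separately as id#N and id#C.
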