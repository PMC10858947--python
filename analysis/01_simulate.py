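"""Generate the standard synthetic experiments and write them to disk.

Produces the planted-truth Hi-C experiment (3v3 replicates, checkerboard
compartments, 30 planted loops) and the fragment-coverage experiment (40
peaks, 10 differential) under results/data/.
"""

import argparse
from pathlib import Path

from loopshift.io_formats import write_contact_map, write_intervals
from loopshift.synthetic_data import (
    default_frag_params,
    default_hic_params,
    simulate_fragment_experiment,
    simulate_hic_experiment,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    params = default_hic_params(seed=args.seed)
    maps, truth = simulate_hic_experiment(params)
    for (cond, rep, chrom), cmap in maps.items():
        stem = args.outdir / f"hic_{cond}_rep{rep + 1}"
        write_contact_map({chrom: cmap}, f"{stem}.matrix.tsv", f"{stem}.bins.bed")
    truth.to_json(args.outdir / "truth_hic.json")
    n_diff = len(truth.differential_loops())
    print(f"wrote {len(maps)} contact maps ({params.n_bins('chrS')} bins at "
          f"{params.bin_size} bp); {len(truth.loops)} planted loops "
          f"({n_diff} condition-specific)")

    fparams = default_frag_params(seed=args.seed)
    samples, ftruth = simulate_fragment_experiment(fparams)
    for s in samples.values():
        write_intervals(s.fragments, args.outdir / f"fragments_{s.sample_id}.bed")
    ftruth.to_json(args.outdir / "truth_fragments.json")
    n_dp = sum(1 for _, d in ftruth.differential_peaks if d != "unchanged")
    print(f"wrote {len(samples)} fragment samples "
          f"({sum(s.n for s in samples.values())} fragments total); "
          f"{len(ftruth.differential_peaks)} peaks, {n_dp} differential")


if __name__ == "__main__":
    main()
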