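"""Integration statistics: peak-to-gene scores, anchor annotation, and the
loop gain/loss bias table.

Ties the differential-loop calls to the fragment-coverage analysis: loop
anchors are classified as promoter/enhancer against synthetic gene models
and pooled peaks, flagged with differential-occupancy changes, and the
gain/loss bias per category is reported with a one-sided rank-sum
comparison.
"""

import argparse
from pathlib import Path

from loopshift.annotation_integration import (
    annotate_loop_anchors,
    gain_loss_bias,
    score_genes_from_peaks,
)
from loopshift.coverage_normalization import normalize_experiment
from loopshift.differential_binding import differential_regions
from loopshift.differential_loops import differential_loop_meta, score_union_loops
from loopshift.hic_loops import call_loops, oe_normalize, smooth_impute
from loopshift.pipeline import _genes_from_tss
from loopshift.synthetic_data import (
    default_frag_params,
    default_hic_params,
    simulate_fragment_experiment,
    simulate_hic_experiment,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results/integration"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    # differential loops on the Hi-C side
    hic = default_hic_params(seed=args.seed)
    maps, truth = simulate_hic_experiment(hic)
    smoothed, calls = {}, {}
    for (cond, rep, _c), cmap in maps.items():
        sm = smooth_impute(oe_normalize(cmap))
        smoothed[(cond, rep)] = sm
        calls[(cond, rep)] = call_loops(sm, obs_map=cmap)
    cands, scores = score_union_loops(smoothed, calls)
    diffs = differential_loop_meta(scores, conditions=("cond1", "cond2"),
                                   candidates=cands)

    # differential occupancy on the fragment side
    fparams = default_frag_params(seed=args.seed)
    samples, _ = simulate_fragment_experiment(fparams)
    thinned, peaks_p, _, _ = normalize_experiment(
        samples, fparams.genome_length, assay="atac", seed=args.seed
    )
    sf = {s.sample_id: 1.0 for s in thinned.values()}
    dregions = differential_regions(thinned, sf, genome_len=fparams.genome_length)

    genes = _genes_from_tss(truth.tss_positions)
    table = score_genes_from_peaks(
        [r for r in dregions if r.direction != "unchanged"], genes
    )
    with open(args.outdir / "gene_scores.tsv", "w") as fh:
        fh.write("gene\tscore\n")
        for gid, sc in table.ranked():
            fh.write(f"{gid}\t{sc:.2f}\n")
    top = table.ranked()[:3]
    print(f"peak-to-gene scoring: {len(table.scores)} genes scored; top: "
          + ", ".join(f"{g} ({s:.1f})" for g, s in top))

    k27_like = [iv for iv, _ in peaks_p]
    dsets = {"dOcc": (dregions, "any")}
    annos = annotate_loop_anchors(diffs, hic.bin_size, genes, k27_like, dsets)
    categories = {
        "promoter": lambda a: "promoter" in a.classes,
        "enhancer": lambda a: "enhancer" in a.classes,
        "all_anchors": lambda a: True,
    }
    bias = gain_loss_bias(diffs, annos, hic.bin_size, categories)
    with open(args.outdir / "gain_loss_bias.tsv", "w") as fh:
        fh.write("category\tgained\tlost\tbias\n")
        for b in bias:
            fh.write(f"{b.category}\t{b.gained}\t{b.lost}\t"
                     f"{'NA' if b.bias is None else f'{b.bias:.3f}'}\n")
    for b in bias:
        if b.versus is None:
            bias_s = "undefined" if b.bias is None else f"{b.bias:.2f}"
            print(f"{b.category}: {b.gained}:{b.lost} gained:lost (bias {bias_s})")


if __name__ == "__main__":
    main()
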