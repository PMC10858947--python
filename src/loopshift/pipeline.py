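"""End-to-end pipeline orchestration from a single YAML configuration.

Stages run in dependency order (simulate -> normalize -> diffbind -> loops ->
diffloops -> compartments -> bias); every output file is listed in a JSON
manifest with its stage, parameters and SHA-256 checksum.  One global seed is
expanded into independent per-stage substreams, so reruns with the same
config reproduce identical results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .annotation_integration import (
    GeneAnnotation,
    annotate_loop_anchors,
    gain_loss_bias,
)
from .compartments import compartment_pc1, saddle_analysis, saddle_diff, switching_fraction
from .coverage_normalization import normalize_experiment, size_factors_median_of_ratios
from .differential_binding import differential_regions
from .differential_loops import (
    differential_loop_meta,
    interaction_change_summary,
    loop_anchor_intervals,
    score_union_loops,
)
from .hic_loops import DEFAULTS, call_loops, oe_normalize, smooth_impute
from .io_formats import (
    BinnedContactMap,
    write_bedgraph,
    write_contact_map,
    write_intervals,
    write_longrange,
)
from .synthetic_data import (
    default_frag_params,
    default_hic_params,
    simulate_fragment_experiment,
    simulate_hic_experiment,
)

__all__ = ["run_pipeline", "demo_config", "load_config"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "normalize", "diffbind", "loops", "diffloops", "compartments", "bias")


def demo_config(outdir="results/demo", seed: int = 0) -> dict:
    """The bundled all-synthetic demo configuration."""
    return {
        "seed": int(seed),
        "outdir": str(outdir),
        "hic": {"simulate": True},
        "fragments": {"simulate": True, "assay": "atac"},
        "loops": dict(DEFAULTS),
        "diffloops": {"mode": "all_combinations", "alpha": 0.05},
        "compartments": {"n_groups": 100},
    }


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _validate(config: dict) -> dict:
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping")
    for key in ("seed", "outdir"):
        if key not in config:
            raise ValueError(f"config missing required key {key!r}")
    if not isinstance(config["seed"], int):
        raise ValueError("seed must be an integer")
    for block in ("hic", "fragments"):
        sub = config.get(block, {})
        if not (sub.get("simulate") or sub.get("paths")):
            raise ValueError(f"config block {block!r} needs simulate: true or paths")
        if sub.get("paths"):
            for p in sub["paths"]:
                if not Path(p).exists():
                    raise ValueError(f"input path {p} does not exist")
    return config


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config) -> dict:
    """Run all stages from a config dict or YAML path; returns the manifest."""
    if not isinstance(config, dict):
        config = load_config(config)
    config = _validate(config)
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)

    seed = config["seed"]
    streams = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(STAGES, np.random.SeedSequence(seed).spawn(len(STAGES)))
    }

    manifest = {
        "version": __version__,
        "seed": seed,
        "stage_seeds": streams,
        "completed_stages": [],
        "artifacts": [],
    }
    manifest_path = outdir / "manifest.json"

    def record(stage, path, **params):
        manifest["artifacts"].append(
            {"stage": stage, "path": str(path), "sha256": _sha256(Path(path)),
             "params": params}
        )

    def done(stage, t0):
        manifest["completed_stages"].append(stage)
        logger.info("stage %s done in %.1f s", stage, time.time() - t0)

    try:
        # --- simulate -------------------------------------------------------
        t0 = time.time()
        hic_params = default_hic_params(seed=streams["simulate"])
        maps, hic_truth = simulate_hic_experiment(hic_params)
        frag_params = default_frag_params(seed=streams["simulate"])
        frag_samples, frag_truth = simulate_fragment_experiment(frag_params)

        truth_path = outdir / "truth_hic.json"
        hic_truth.to_json(truth_path)
        record("simulate", truth_path, kind="hic_truth")
        frag_truth_path = outdir / "truth_fragments.json"
        frag_truth.to_json(frag_truth_path)
        record("simulate", frag_truth_path, kind="fragment_truth")

        chrom = next(iter(hic_params.chrom_lengths))
        rep_map_path = outdir / "hic_cond1_rep1.matrix.tsv"
        rep_bins_path = outdir / "hic_cond1_rep1.bins.bed"
        write_contact_map({chrom: maps[("cond1", 0, chrom)]}, rep_map_path, rep_bins_path)
        record("simulate", rep_map_path, condition="cond1", replicate=1)
        record("simulate", rep_bins_path, condition="cond1", replicate=1)
        for key, s in frag_samples.items():
            p = outdir / f"fragments_{s.sample_id}.bed"
            write_intervals(s.fragments, p, kind="bed")
            record("simulate", p, sample=s.sample_id)
        done("simulate", t0)

        # --- normalize ------------------------------------------------------
        t0 = time.time()
        assay = config.get("fragments", {}).get("assay", "atac")
        thinned, peaks_p, flanks, sf = normalize_experiment(
            frag_samples, frag_params.genome_length, assay=assay,
            seed=streams["normalize"],
        )
        sf_path = outdir / "size_factors.tsv"
        with open(sf_path, "w") as fh:
            fh.write("sample\tsize_factor\n")
            for sid, v in sf.items():
                fh.write(f"{sid}\t{v:.6f}\n")
        record("normalize", sf_path, assay=assay)
        peak_path = outdir / "pooled_peaks.bed"
        write_intervals([iv for iv, _ in peaks_p], peak_path)
        record("normalize", peak_path, n_peaks=len(peaks_p))
        done("normalize", t0)

        # --- diffbind -------------------------------------------------------
        t0 = time.time()
        sf_thinned = {s.sample_id: 1.0 for s in thinned.values()}
        diff_regions = differential_regions(
            thinned, sf_thinned, alpha=0.05, genome_len=frag_params.genome_length
        )
        db_path = outdir / "differential_binding.tsv"
        with open(db_path, "w") as fh:
            fh.write("chrom\tstart\tend\tlog2fc\tp\tpadj\tdirection\n")
            for r in diff_regions:
                fh.write(
                    f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t"
                    f"{r.log2fc:.4f}\t{r.p:.3e}\t{r.padj:.3e}\t{r.direction}\n"
                )
        record("diffbind", db_path, n_regions=len(diff_regions))
        done("diffbind", t0)

        # --- loops ----------------------------------------------------------
        t0 = time.time()
        loop_cfg = {**DEFAULTS, **config.get("loops", {})}
        smoothed = {}
        calls = {}
        for (cond, rep, chrom_), cmap in maps.items():
            sm = smooth_impute(oe_normalize(cmap))
            smoothed[(cond, rep)] = sm
            calls[(cond, rep)] = call_loops(
                sm, p=loop_cfg["p"], w=loop_cfg["w"], m_min=loop_cfg["m_min"],
                d_min=loop_cfg["d_min"], d_max=loop_cfg["d_max"],
                score_min=loop_cfg["score_min"],
            )
        bs = hic_params.bin_size
        calls_path = outdir / "loop_calls_per_sample.tsv"
        with open(calls_path, "w") as fh:
            fh.write("sample\tchrom\ti\tj\tscore\n")
            for (cond, rep), lst in sorted(calls.items()):
                for sl in lst:
                    fh.write(
                        f"{cond}_rep{rep + 1}\t{sl.candidate.chrom}\t{sl.candidate.i}\t"
                        f"{sl.candidate.j}\t{sl.score:.3f}\n"
                    )
        record("loops", calls_path, **loop_cfg)
        done("loops", t0)

        # --- diffloops ------------------------------------------------------
        t0 = time.time()
        dl_cfg = config.get("diffloops", {})
        candidates, sample_scores = score_union_loops(
            smoothed, calls, p=loop_cfg["p"], w=loop_cfg["w"], m_min=loop_cfg["m_min"]
        )
        diffs = differential_loop_meta(
            sample_scores, mode=dl_cfg.get("mode", "all_combinations"),
            alpha=dl_cfg.get("alpha", 0.05), conditions=("cond1", "cond2"),
            candidates=candidates,
        )
        dl_path = outdir / "differential_loops.tsv"
        with open(dl_path, "w") as fh:
            fh.write("chrom\ti\tj\tZ\tp\tdirection\n")
            for d in diffs:
                fh.write(
                    f"{d.candidate.chrom}\t{d.candidate.i}\t{d.candidate.j}\t"
                    f"{d.z_meta:.4f}\t{d.p:.3e}\t{d.direction}\n"
                )
        record("diffloops", dl_path, n_candidates=len(diffs))

        for direction, sign in (("gained", 1), ("lost", -1)):
            track = [
                (*loop_anchor_intervals(d, bs), sign * abs(d.z_meta))
                for d in diffs
                if d.direction == direction
            ]
            p = outdir / f"loops_{direction}.longrange"
            write_longrange(track, p)
            record("diffloops", p, direction=direction, n=len(track))

        genes = _genes_from_tss(hic_truth.tss_positions)
        per_chrom, ranked, hotspots = interaction_change_summary(
            diffs, genes, bin_size=bs, hotspot_window=250_000
        )
        sum_path = outdir / "diffloop_summaries.tsv"
        with open(sum_path, "w") as fh:
            fh.write("# significant differential loops per chromosome\n")
            for c, k in sorted(per_chrom.items()):
                fh.write(f"chrom\t{c}\t{k}\n")
            fh.write("# top promoters by differential interactions\n")
            for gid, k in ranked[:20]:
                fh.write(f"promoter\t{gid}\t{k}\n")
            fh.write("# top rearrangement hotspots\n")
            for iv, k in hotspots[:10]:
                fh.write(f"hotspot\t{iv.chrom}:{iv.start}-{iv.end}\t{k}\n")
        record("diffloops", sum_path)
        done("diffloops", t0)

        # --- compartments ---------------------------------------------------
        t0 = time.time()
        comp_cfg = config.get("compartments", {})
        pooled = {}
        for cond in ("cond1", "cond2"):
            vals = None
            for (c, r, ch), cmap in maps.items():
                if c != cond:
                    continue
                add = np.nan_to_num(cmap.values)
                vals = add if vals is None else vals + add
            cov = vals.sum(axis=1)
            valid = cov > 0
            v = vals.astype(float)
            v[~valid, :] = np.nan
            v[:, ~valid] = np.nan
            pooled[cond] = BinnedContactMap(chrom, bs, v, valid)

        tss = hic_truth.tss_positions[chrom]
        tracks = {c: compartment_pc1(pooled[c], tss) for c in pooled}
        saddles = {
            c: saddle_analysis({chrom: pooled[c]}, {chrom: tracks[c]},
                               n_groups=comp_cfg.get("n_groups", 100))
            for c in pooled
        }
        sd = saddle_diff(saddles["cond2"], saddles["cond1"])
        sw = switching_fraction(tracks["cond1"], tracks["cond2"])

        for c, tr in tracks.items():
            p = outdir / f"pc1_{c}.bedgraph"
            ok = ~np.isnan(tr.pc1)
            idx = np.flatnonzero(ok)
            write_bedgraph(chrom, idx * bs, (idx + 1) * bs, tr.pc1[idx], p)
            record("compartments", p, condition=c)
        comp_path = outdir / "compartment_summary.tsv"
        with open(comp_path, "w") as fh:
            fh.write("condition\tAA\tBB\tAB\n")
            for c, s in saddles.items():
                fh.write(f"{c}\t{s.AA:.4f}\t{s.BB:.4f}\t{s.AB:.4f}\n")
            fh.write(f"switching_fraction\t{sw:.4f}\t\t\n")
            fh.write(f"saddle_log2fc_mean_abs\t{np.nanmean(np.abs(sd)):.4f}\t\t\n")
        record("compartments", comp_path)
        done("compartments", t0)

        # --- bias -----------------------------------------------------------
        t0 = time.time()
        k27_like = [iv for iv, _ in peaks_p]
        dsets = {"dOcc": (diff_regions, "any")}
        annos = annotate_loop_anchors(diffs, bs, genes, k27_like, dsets)
        categories = {
            "promoter": lambda a: "promoter" in a.classes,
            "enhancer": lambda a: "enhancer" in a.classes,
            "any": lambda a: True,
        }
        bias = gain_loss_bias(diffs, annos, bs, categories)
        bias_path = outdir / "gain_loss_bias.tsv"
        with open(bias_path, "w") as fh:
            fh.write("category\tgained\tlost\tbias\n")
            for b in bias:
                bias_s = f"{b.bias:.3f}" if b.bias is not None else "NA"
                fh.write(f"{b.category}\t{b.gained}\t{b.lost}\t{bias_s}\n")
        record("bias", bias_path)
        done("bias", t0)
    finally:
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)

    return manifest


def _genes_from_tss(tss_positions: dict, body: int = 2_000):
    """Synthetic gene models from simulated TSS positions (all + strand)."""
    genes = []
    k = 0
    for chrom in sorted(tss_positions):
        for t in np.asarray(tss_positions[chrom], dtype=int):
            genes.append(GeneAnnotation(f"gene{k:05d}", chrom, "+", int(t), int(t) + body))
            k += 1
    return genes
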