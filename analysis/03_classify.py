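"""Pleiotropy classification of candidate SNPs and genes, with overlap nulls.

Assigns each background's SNPs to synergistic (SP), antagonistic (AP),
private-cold and private-hot classes from replicate-concordant frequency
change at the relaxed 1st/99th-percentile threshold, maps classified SNPs
onto protein-coding genes, counts cross-background overlaps (upset-style),
computes Jaccard indices, and compares the observed sharing of private-hot
SNPs against forward drift simulations.

Writes results/classify/{snp_classes.tsv,gene_classes.tsv,overlap.json}.
"""
import argparse
import json
from pathlib import Path

import evorepeat.classify as classify
import evorepeat.io as io
import evorepeat.pipeline as pipeline


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--sim", default="results/sim")
    ap.add_argument("--out", default="results/classify")
    ap.add_argument("--iterations", type=int, default=200,
                    help="drift-simulation iterations for the overlap null")
    ap.add_argument("--snps-per-iteration", type=int, default=2000)
    args = ap.parse_args()

    sim, out = Path(args.sim), Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    cfg = io.PipelineConfig(out_dir=str(out), seed=args.seed)

    sync = io.read_sync(sim / "panel.sync")
    design = io.read_design_table(sim / "design.tsv")
    panel = io.sync_to_panel(sync, [s for s in sync.samples if "_anc_" in s])
    genes = io.read_gff3(sim / "genes.gff3")

    det = pipeline.detect_stage(panel, design, cfg)
    calls, gene_sets, jaccards = pipeline.classify_stage(det, cfg, genes)
    calls.to_csv(out / "snp_classes.tsv", sep="\t", index=False)

    mapped = classify.map_snps_to_genes(calls, genes)
    mapped.to_csv(out / "gene_classes.tsv", sep="\t", index=False)

    backgrounds = sorted(design["background"].unique())
    report = {"jaccard_gene_overlaps": jaccards, "upset": {}}
    for cl in ("SP", "AP", "PrivateCold", "PrivateHot"):
        sets = {bg: gene_sets[(bg, cl)] for bg in backgrounds}
        report["upset"][cl] = classify.overlap_counts(sets).to_dict("records")

    # drift-simulation null for cross-background sharing of PrivateHot SNPs
    shared_obs = 0
    masks = [(calls[calls["background"] == bg]["class"] == "PrivateHot")
             .to_numpy() for bg in backgrounds]
    shared = masks[0]
    for m in masks[1:]:
        shared = shared & m
    shared_obs = int(shared.sum())
    p0_by_bg = {bg: panel.freqs[[f"{bg}_anc_1", f"{bg}_anc_2"]]
                .mean(axis=1).to_numpy() for bg in backgrounds}
    line_params = design[design["regime"].isin(("cold", "hot"))].copy()
    line_params["Ne"] = line_params["line_id"].map(det.ne_of)
    line_params["t"] = line_params["line_id"].map(det.t_of)
    null = classify.expected_overlap_by_drift(
        p0_by_bg, line_params, shared_obs,
        per_tail_probability=cfg.class_q, snp_class="PrivateHot",
        iterations=args.iterations,
        snps_per_iteration=args.snps_per_iteration,
        pool_size=int(design["pool_size"].iloc[0]), seed=cfg.seed + 11)
    report["private_hot_sharing"] = {
        "observed": null.observed, "expected_under_drift": null.expected,
        "pvalue": null.pvalue, "iterations": null.iterations}

    with open(out / "overlap.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    counts = (calls[calls["class"] != "None"]
              .groupby(["background", "class"]).size())
    print(counts.to_string())
    print(json.dumps(report["private_hot_sharing"], indent=2))
    if jaccards:
        top = dict(sorted(jaccards.items(), key=lambda kv: -kv[1])[:6])
        print("top gene-overlap Jaccard indices:", json.dumps(top, indent=2))


if __name__ == "__main__":
    main()
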