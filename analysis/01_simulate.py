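"""Generate the synthetic evolve-and-resequence experiment used downstream.

Emulates the study design — three differentiated genetic backgrounds, two
thermal regimes, two replicate lines per cell, pool-seq of 60 diploids at
~50x depth, ancestor proxies sampled at generation 3 of the heat lines —
with a polygenic architecture of synergistic, antagonistic and private
selected SNPs among a neutral majority, plus seven-trait phenotype panels.

Writes sync/TSV/GFF3 inputs for the later stages under results/sim/.
"""
import argparse
import json
from pathlib import Path

import evorepeat.io as io
import evorepeat.pipeline as pipeline
from evorepeat.synth import synthetic_gene_annotation


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-snps", type=int, default=20000)
    ap.add_argument("--out", default="results/sim")
    args = ap.parse_args()

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    cfg = io.PipelineConfig(out_dir=str(out), seed=args.seed)
    cfg.simulate["n_snps"] = args.n_snps
    exp = pipeline.simulate_stage(cfg)

    io.write_sync(io.panel_to_sync(exp.snp_panel), out / "panel.sync")
    io.write_trait_table(exp.trait_panel, out / "traits.tsv")
    io.write_design_table(exp.design_table, out / "design.tsv")
    exp.architecture.to_table().to_csv(out / "architecture.tsv", sep="\t",
                                       index=False)
    genes = synthetic_gene_annotation(exp.snp_panel.loci, seed=cfg.seed + 3)
    io.write_gff3(genes, out / "genes.gff3")
    cfg.to_yaml(out / "scenario.yaml")

    counts = {c: int((exp.architecture.class_of_snp == c).sum())
              for c in ("SP", "AP", "PrivateCold", "PrivateHot", "Neutral")}
    print(f"simulated {exp.snp_panel.n_snps} SNPs x "
          f"{len(exp.snp_panel.samples)} pool-seq samples "
          f"and {len(exp.trait_panel)} trait cells -> {out}")
    print("planted architecture:", json.dumps(counts))


if __name__ == "__main__":
    main()
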