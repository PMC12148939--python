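"""End-to-end orchestration: simulate -> detect -> classify -> geometry -> offsets.

Each stage is a plain function over the library so that the numbered
analysis drivers, the CLI and the tests can run any subset; ``run_pipeline``
chains them, writes every stage artifact (TSV/JSON) under the configured
output directory and returns the machine-readable summary.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as _classify
from . import drift, geometry, io, offsets
from .core import REGIMES, TRAITS, SNPPanel
from .synth import (ExperimentDesign, SimulatedExperiment, assign_architecture,
                    draw_ancestral_frequencies, generate_experiment,
                    synthetic_gene_annotation)

log = logging.getLogger("evorepeat")

__all__ = ["DetectionResult", "simulate_stage", "detect_stage",
           "classify_stage", "geometry_stage", "offsets_stage",
           "run_pipeline"]


def _timed(stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", stage)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is None:
                log.info("stage %s: done in %.2fs", stage, dt)
            else:
                log.error("stage %s: FAILED after %.2fs: %s", stage, dt, exc)
            return False
    return _Timer()


def simulate_stage(config: io.PipelineConfig) -> SimulatedExperiment:
    """Generate the synthetic experiment described by the config scenario."""
    with _timed("simulate"):
        sc = config.simulate
        design = ExperimentDesign()
        pool = draw_ancestral_frequencies(
            int(sc["n_snps"]), len(design.backgrounds),
            float(sc["differentiation"]), seed=config.seed,
            backgrounds=design.backgrounds)
        arch = assign_architecture(
            int(sc["n_snps"]), dict(sc["class_fractions"]),
            float(sc["s_magnitude"]), seed=config.seed + 1)
        exp = generate_experiment(design, pool, arch,
                                  trait_noise=float(sc["trait_noise"]),
                                  seed=config.seed + 2)
    return exp


@dataclass
class DetectionResult:
    """Per-SNP, per-line drift-null tests and derived candidate calls."""

    panel: SNPPanel
    design_table: pd.DataFrame
    ancestor_of: dict[str, str]  # evolved line -> paired ancestor sample
    t_of: dict[str, int]  # adjusted generations per line
    ne_of: dict[str, float]
    pvalues: pd.DataFrame  # loci x lines (NaN where uninformative)
    directions: pd.DataFrame
    s_hat: pd.DataFrame

    def candidates(self, q: float, mode: str = "per_tail") -> pd.DataFrame:
        return drift.detect_candidates(self.pvalues.fillna(1.0),
                                       self.directions, q, mode=mode)


def detect_stage(panel: SNPPanel, design_table: pd.DataFrame,
                 config: io.PipelineConfig) -> DetectionResult:
    """Estimate Ne per line and test every SNP against the drift null.

    Each evolved line is paired with the ancestor-proxy sample of the same
    replicate index in its background; generations are proxy-adjusted
    (+3 cold / -3 hot by default).  Loci where the paired ancestor sample
    is not polymorphic are uninformative (NaN p-values).
    """
    with _timed("detect"):
        evolved = design_table[design_table["regime"].isin(REGIMES)]
        ancestor_of, t_of, ne_of = {}, {}, {}
        pvals, dirs, sels = {}, {}, {}
        rng = np.random.default_rng(np.random.SeedSequence(config.seed + 17))
        for row in evolved.itertuples():
            line = row.line_id
            anc = f"{row.background}_anc_{row.replicate}"
            if anc not in panel.samples:
                raise ValueError(f"missing ancestor sample {anc!r} for {line!r}")
            ancestor_of[line] = anc
            t = drift.adjust_generations(int(row.sampling_generation),
                                         row.regime, config.proxy_offset)
            t_of[line] = t
            f0, ft = panel.freq(anc), panel.freq(line)
            d0, dt = panel.depth(anc), panel.depth(line)
            if line in config.ne_overrides:
                ne = float(config.ne_overrides[line])
            else:
                est = drift.estimate_Ne(f0, ft, d0, dt, int(row.pool_size), t)
                if est.no_drift:
                    raise ValueError(f"no detectable drift for line {line!r}")
                ne = est.ne
            ne_of[line] = ne
            informative = (f0 > 0) & (f0 < 1)
            r0 = np.rint(f0 * d0).astype(int)
            rt = np.rint(ft * dt).astype(int)
            p = np.full(panel.n_snps, np.nan)
            d = np.zeros(panel.n_snps, dtype=int)
            p_i, d_i = drift.sampling_aware_pvalues(
                r0[informative], d0[informative], rt[informative],
                dt[informative], ne, t, int(row.pool_size),
                drift_model=config.drift_model, seed=rng)
            p[informative] = p_i
            d[informative] = d_i
            pvals[line] = p
            dirs[line] = d
            sels[line] = drift.estimate_selection_coefficient(
                f0, ft, t, int(row.pool_size)).s
        idx = panel.loci.index
        return DetectionResult(
            panel=panel,
            design_table=design_table,
            ancestor_of=ancestor_of,
            t_of=t_of,
            ne_of=ne_of,
            pvalues=pd.DataFrame(pvals, index=idx),
            directions=pd.DataFrame(dirs, index=idx),
            s_hat=pd.DataFrame(sels, index=idx),
        )


def detection_table(det: DetectionResult) -> pd.DataFrame:
    """Long per-SNP TSV: locus, line, p0, pt, direction, pvalue, s."""
    rows = []
    for line, anc in det.ancestor_of.items():
        df = det.panel.loci[["scaffold", "pos"]].copy()
        df["line"] = line
        df["p0"] = det.panel.freq(anc)
        df["pt"] = det.panel.freq(line)
        df["direction"] = det.directions[line]
        df["pvalue"] = det.pvalues[line]
        df["s"] = det.s_hat[line]
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def classify_stage(det: DetectionResult, config: io.PipelineConfig,
                   genes: pd.DataFrame | None = None):
    """Pleiotropy classes per background, with gene mapping and overlaps."""
    with _timed("classify"):
        calls_frames = []
        backgrounds = sorted(det.design_table["background"].unique())
        for bg in backgrounds:
            pv = {r: [] for r in REGIMES}
            dr = {r: [] for r in REGIMES}
            sub = det.design_table[
                (det.design_table["background"] == bg)
                & det.design_table["regime"].isin(REGIMES)
            ].sort_values(["regime", "replicate"])
            for row in sub.itertuples():
                pv[row.regime].append(
                    det.pvalues[row.line_id].fillna(1.0).to_numpy())
                dr[row.regime].append(det.directions[row.line_id].to_numpy())
            calls = _classify.classify_snps(pv, dr, config.class_q)
            calls["background"] = bg
            calls["scaffold"] = det.panel.loci["scaffold"].to_numpy()
            calls["pos"] = det.panel.loci["pos"].to_numpy()
            calls_frames.append(calls)
        calls = pd.concat(calls_frames, ignore_index=True)

        gene_sets = None
        jaccards = None
        if genes is not None:
            mapped = _classify.map_snps_to_genes(calls, genes)
            gene_sets = {
                (bg, cl): set(mapped[(mapped["background"] == bg)
                                     & (mapped["class"] == cl)]["gene_id"])
                for bg in backgrounds
                for cl in ("SP", "AP", "PrivateCold", "PrivateHot")
            }
            jaccards = {}
            for cl in ("SP", "AP", "PrivateCold", "PrivateHot"):
                for i, a in enumerate(backgrounds):
                    for b in backgrounds[i + 1:]:
                        jaccards[f"{cl}:{a}&{b}"] = _classify.jaccard(
                            gene_sets[(a, cl)], gene_sets[(b, cl)])
        return calls, gene_sets, jaccards


def _trait_vectors(scaled: pd.DataFrame, det: DetectionResult,
                   regime: str, temp: float) -> list[geometry.ChangeVector]:
    """Trait change vectors of one regime's lines at one assay temperature."""
    vectors = []
    sub = det.design_table[det.design_table["regime"] == regime]
    for row in sub.itertuples():
        anc_id = f"{row.background}_anc"
        anc = scaled[(scaled["line_id"] == anc_id)
                     & (scaled["assay_temp"] == temp)].set_index("trait")
        evo = scaled[(scaled["line_id"] == row.line_id)
                     & (scaled["assay_temp"] == temp)].set_index("trait")
        if anc.empty or evo.empty:
            raise ValueError(f"trait panel lacks {anc_id!r} or {row.line_id!r}"
                             f" at {temp} C")
        traits = list(TRAITS)
        vectors.append(geometry.change_vector(
            anc.loc[traits, "mean"].to_numpy(),
            anc.loc[traits, "se"].to_numpy(),
            evo.loc[traits, "mean"].to_numpy(),
            evo.loc[traits, "se"].to_numpy(),
            t=det.t_of[row.line_id],
            shared_ancestor_id=f"{row.background}@{temp}",
            label=row.line_id, background=row.background, regime=regime,
        ))
    return vectors


def _genomic_vectors(det: DetectionResult, union: np.ndarray
                     ) -> list[geometry.ChangeVector]:
    """Allele-frequency change vectors on the candidate union set.

    No shared-ancestor error correction is applied in frequency space:
    with replicate ancestral samples per background, the correction is
    left off and vectors are treated as having independent ancestors.
    """
    vectors = []
    zeros = np.zeros(int(union.sum()))
    for line, anc in det.ancestor_of.items():
        row = det.design_table.set_index("line_id").loc[line]
        vec = det.panel.freq(line)[union] - det.panel.freq(anc)[union]
        vectors.append(geometry.ChangeVector(
            values=vec, anc_errors=zeros, evo_errors=zeros,
            t=det.t_of[line], shared_ancestor_id=None, label=line,
            background=row["background"], regime=row["regime"]))
    return vectors


def _angle_stats(vectors: list[geometry.ChangeVector],
                 correction: str) -> dict:
    """Mean pairwise angles, split within/between background."""
    within, between, n_undef = [], [], 0
    for i in range(len(vectors)):
        for j in range(i + 1, len(vectors)):
            res = geometry.pairwise_angle(vectors[i], vectors[j], correction)
            if not res.defined:
                n_undef += 1
                continue
            if vectors[i].background == vectors[j].background:
                within.append(res.theta)
            else:
                between.append(res.theta)
    both = within + between
    return {
        "mean_angle": float(np.mean(both)) if both else None,
        "mean_angle_within": float(np.mean(within)) if within else None,
        "mean_angle_between": float(np.mean(between)) if between else None,
        "n_undefined": n_undef,
    }


def geometry_stage(det: DetectionResult, trait_panel: pd.DataFrame,
                   config: io.PipelineConfig) -> dict:
    """Rates, angles and divergence in trait and allele-frequency space."""
    with _timed("geometry"):
        scaled = geometry.mean_scale_traits(trait_panel)
        out: dict = {"traits": {}, "genomic": {}}

        trait_vecs: dict[str, list] = {}
        for regime, temp in (("cold", 23.0), ("hot", 35.0)):
            trait_vecs[regime] = _trait_vectors(scaled, det, regime, temp)
        all_rates = [geometry.evolutionary_rate(v).raw_rate
                     for vs in trait_vecs.values() for v in vs]
        max_rate = max(all_rates)
        for regime in REGIMES:
            vecs = trait_vecs[regime]
            stats = _angle_stats(vecs, correction="full")
            rates = [geometry.evolutionary_rate(v, max_rate).scaled_rate
                     for v in vecs]
            raw = [geometry.evolutionary_rate(v).raw_rate for v in vecs]
            stats["mean_scaled_rate"] = float(np.mean(rates))
            stats["mean_raw_rate"] = float(np.mean(raw))
            if stats["mean_angle"] is not None:
                null = geometry.random_angle_null(
                    dim=len(TRAITS), n_pairs=1, iterations=10000,
                    seed=config.seed + 23, observed_mean=stats["mean_angle"])
                stats["random_angle_p"] = null.pvalue
            out["traits"][regime] = stats
        both = trait_vecs["cold"] + trait_vecs["hot"]
        perm = geometry.permutation_regime_test(
            both, statistic="angle", iterations=1000, seed=config.seed + 29)
        out["traits"]["regime_permutation"] = {
            "statistic": "mean pairwise angle, hot - cold",
            "observed": perm.observed, "pvalue": perm.pvalue}

        cand = det.candidates(config.detection_q, config.tail_mode)
        union = cand.any(axis=1).to_numpy()
        out["genomic"]["n_candidate_union"] = int(union.sum())
        if union.sum() >= 2:
            gvecs = _genomic_vectors(det, union)
            g_rates = [geometry.evolutionary_rate(v).raw_rate for v in gvecs]
            gmax = max(g_rates)
            for regime in REGIMES:
                vecs = [v for v in gvecs if v.regime == regime]
                stats = _angle_stats(vecs, correction="none")
                stats["mean_scaled_rate"] = float(np.mean(
                    [geometry.evolutionary_rate(v, gmax).scaled_rate
                     for v in vecs]))
                out["genomic"][regime] = stats
        return out


def offsets_stage(det: DetectionResult, trait_panel: pd.DataFrame,
                  config: io.PipelineConfig) -> dict:
    """Reference-anchored offsets and their within/between correlations."""
    with _timed("offsets"):
        temp = config.assay_temp
        regime = "hot" if temp >= 29 else "cold"
        scaled = geometry.mean_scale_traits(trait_panel)
        fitness = offsets.fitness_from_traits(trait_panel, temp)

        background_of = {}
        for row in det.design_table.itertuples():
            background_of[row.line_id] = row.background
            background_of[f"{row.background}_anc"] = row.background

        references = {}
        for bg in sorted(det.design_table["background"].unique()):
            lines = det.design_table[
                (det.design_table["background"] == bg)
                & (det.design_table["regime"] == regime)]["line_id"]
            ref, _tie = offsets.select_reference(fitness[list(lines)])
            references[bg] = ref

        informative = {ln: det.pvalues[ln].notna() for ln in det.ancestor_of}
        candidate_sets = {}
        for bg, ref in references.items():
            pv = det.pvalues[ref][informative[ref]]
            loci, weights, _tie = offsets.reference_candidate_set(
                pv, config.offset_quantile, det.s_hat[ref])
            candidate_sets[ref] = (loci, weights)

        sub = scaled[scaled["assay_temp"] == temp]
        wide = sub.pivot_table(index="line_id", columns="trait", values="mean")
        trait_vectors = {ln: wide.loc[ln, list(TRAITS)].to_numpy()
                         for ln in wide.index}

        # ancestor pseudo-lines: genomic state = mean of the background's
        # two ancestor-proxy pools
        freqs = det.panel.freqs.copy()
        for bg in references:
            anc_cols = [c for c in freqs.columns if c.startswith(f"{bg}_anc_")]
            if anc_cols and f"{bg}_anc" not in freqs.columns:
                freqs[f"{bg}_anc"] = freqs[anc_cols].mean(axis=1)

        table = offsets.build_offset_table(
            references, freqs, candidate_sets, trait_vectors,
            fitness, background_of)
        correlations, tests = offsets.offset_correlation(table)

        # random-SNP control: same set size, unit weights
        control = {}
        for bg, ref in references.items():
            n = len(candidate_sets[ref][0])
            within_tests = [ln for ln in trait_vectors
                            if background_of[ln] == bg and ln != ref]
            ctrl = offsets.random_snp_offsets(
                freqs, n, ref, within_tests, iterations=50,
                seed=config.seed + 31)
            fit_off = np.array([offsets.fitness_offset(fitness[ln], fitness[ref])
                                for ln in within_tests])
            rs = [np.corrcoef(ctrl.iloc[i].to_numpy(), fit_off)[0, 1]
                  for i in range(len(ctrl))
                  if np.std(ctrl.iloc[i].to_numpy()) > 0]
            control[bg] = float(np.mean(rs)) if rs else None

        return {
            "assay_temp": temp,
            "references": references,
            "candidate_set_sizes": {r: len(c[0])
                                    for r, c in candidate_sets.items()},
            "table": table,
            "correlations": [c.__dict__ for c in correlations],
            "interaction_tests": {k: v.__dict__ for k, v in tests.items()},
            "control_within_r_fit": control,
        }


def run_pipeline(config: io.PipelineConfig) -> dict:
    """Execute every stage and write all artifacts under ``config.out_dir``.

    Returns the summary dictionary (also written as ``summary.json``).
    Re-running with the same config and seed reproduces every artifact
    byte for byte.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genes = None
    if config.sync_path is None:
        exp = simulate_stage(config)
        panel, trait_panel = exp.snp_panel, exp.trait_panel
        design_table = exp.design_table
        io.write_sync(io.panel_to_sync(panel), out / "panel.sync")
        io.write_trait_table(trait_panel, out / "traits.tsv")
        io.write_design_table(design_table, out / "design.tsv")
        exp.architecture.to_table().to_csv(out / "architecture.tsv",
                                           sep="\t", index=False)
        genes = synthetic_gene_annotation(panel.loci, seed=config.seed + 3)
        io.write_gff3(genes, out / "genes.gff3")
    else:
        sync = io.read_sync(config.sync_path)
        design_table = io.read_design_table(config.design_path)
        anc = [s for s in sync.samples if "_anc_" in s]
        panel = io.sync_to_panel(sync, anc or None)
        trait_panel = io.read_trait_table(config.traits_path)
        if config.gff3_path:
            genes = io.read_gff3(config.gff3_path)

    det = detect_stage(panel, design_table, config)
    detection_table(det).to_csv(out / "snp_tests.tsv", sep="\t", index=False)

    calls, gene_sets, jaccards = classify_stage(det, config, genes)
    calls.to_csv(out / "snp_classes.tsv", sep="\t", index=False)

    geo = geometry_stage(det, trait_panel, config)
    offs = offsets_stage(det, trait_panel, config)
    offs_table = offs.pop("table")
    offs_table.to_csv(out / "offsets.tsv", sep="\t", index=False)

    cand_detect = det.candidates(config.detection_q, config.tail_mode)
    cand_class = det.candidates(config.class_q, config.tail_mode)
    class_counts = (calls.groupby(["background", "class"]).size()
                    .unstack(fill_value=0).to_dict())

    summary = {
        "seed": config.seed,
        "n_snps": panel.n_snps,
        "ne_per_line": {k: round(v, 3) for k, v in det.ne_of.items()},
        "adjusted_generations": det.t_of,
        "candidate_counts_detection": {c: int(cand_detect[c].sum())
                                       for c in cand_detect.columns},
        "candidate_counts_class": {c: int(cand_class[c].sum())
                                   for c in cand_class.columns},
        "candidate_union_detection": int(cand_detect.any(axis=1).sum()),
        "class_counts": {str(k): {str(kk): int(vv) for kk, vv in v.items()}
                         for k, v in class_counts.items()},
        "jaccard_gene_overlaps": jaccards,
        "geometry": geo,
        "offsets": offs,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    log.info("pipeline complete; artifacts in %s", out)
    return summary
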