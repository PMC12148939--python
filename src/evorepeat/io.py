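"""Readers and writers for the pipeline's file formats.

Formats handled:

* PoPoolation2 ``sync`` — tab-separated, one row per site: scaffold,
  1-based position, reference base, then one ``A:T:C:G:N:del`` count
  sextet per sample.  ``N`` and ``del`` counts are excluded from depth for
  frequency purposes (frequencies concern called bases).
* long-format trait TSV — line_id, background, regime, replicate,
  assay_temp, trait, mean, se, n.
* design TSV — one row per experimental unit.
* GFF3 gene annotations — 1-based inclusive coordinates, converted to the
  internal 0-based half-open convention at this boundary only.
* YAML pipeline configuration.

Readers validate and reject malformed input (reporting offending line
numbers) rather than silently coercing; every writer's output is
re-readable by its reader.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import SYNC_BASES, TRAITS, SNPPanel

__all__ = [
    "SyncTable",
    "read_sync",
    "write_sync",
    "panel_to_sync",
    "sync_to_panel",
    "read_trait_table",
    "write_trait_table",
    "read_design_table",
    "write_design_table",
    "read_gff3",
    "write_gff3",
    "rolling_log10p",
    "PipelineConfig",
]


@dataclass
class SyncTable:
    """Parsed sync file: per-site, per-sample base-count sextets."""

    loci: pd.DataFrame  # scaffold, pos (0-based), ref
    counts: np.ndarray  # (n_sites, n_samples, 6), order A:T:C:G:N:del
    samples: list[str]

    def __post_init__(self):
        if self.counts.ndim != 3 or self.counts.shape[2] != 6:
            raise ValueError("counts must be (n_sites, n_samples, 6)")
        if self.counts.shape[0] != len(self.loci):
            raise ValueError("counts and loci row counts differ")
        if self.counts.shape[1] != len(self.samples):
            raise ValueError("counts and samples disagree on sample count")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")

    @property
    def depths(self) -> np.ndarray:
        """Called-base depth per site and sample (A+T+C+G, no N/del)."""
        return self.counts[:, :, :4].sum(axis=2)


def read_sync(path, samples: list[str] | None = None) -> SyncTable:
    """Parse a PoPoolation2 sync file.

    ``samples`` names the count columns (defaults to ``sample1..``).
    Malformed lines (ragged rows, non-integer counts) raise with their
    1-based line numbers.  An empty file yields an empty table.
    """
    path = Path(path)
    scaffolds, positions, refs = [], [], []
    rows = []
    n_samples = None
    header_samples = None
    bad: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                # optional header comment carrying sample names
                fields = line.lstrip("#").split("\t")
                if header_samples is None and len(fields) >= 4:
                    header_samples = fields[3:]
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                bad.append(f"line {lineno}: fewer than 4 columns")
                continue
            if n_samples is None:
                n_samples = len(parts) - 3
            elif len(parts) - 3 != n_samples:
                bad.append(f"line {lineno}: ragged row "
                           f"({len(parts) - 3} samples, expected {n_samples})")
                continue
            try:
                pos = int(parts[1])
                sextets = [[int(x) for x in p.split(":")] for p in parts[3:]]
            except ValueError:
                bad.append(f"line {lineno}: non-integer position or count")
                continue
            if any(len(s) != 6 for s in sextets):
                bad.append(f"line {lineno}: sextet does not have 6 fields")
                continue
            scaffolds.append(parts[0])
            positions.append(pos - 1)  # to 0-based
            refs.append(parts[2])
            rows.append(sextets)
    if bad:
        raise ValueError("malformed sync input:\n" + "\n".join(bad))
    if n_samples is None:
        n_samples = 0
    if samples is None and header_samples is not None \
            and len(header_samples) == n_samples:
        samples = header_samples
    if samples is None:
        samples = [f"sample{i+1}" for i in range(n_samples)]
    elif len(samples) != n_samples and rows:
        raise ValueError(f"{len(samples)} sample names for {n_samples} columns")
    counts = (np.asarray(rows, dtype=np.int64)
              if rows else np.zeros((0, len(samples), 6), dtype=np.int64))
    loci = pd.DataFrame({"scaffold": scaffolds, "pos": positions, "ref": refs})
    return SyncTable(loci=loci, counts=counts, samples=list(samples))


def write_sync(sync: SyncTable, path) -> None:
    """Write a sync table in canonical A:T:C:G:N:del order.

    A header comment carries the sample names (ignored by PoPoolation2
    tooling, recovered by :func:`read_sync`).
    """
    with open(path, "w") as fh:
        fh.write("#scaffold\tpos\tref\t" + "\t".join(sync.samples) + "\n")
        for i in range(len(sync.loci)):
            row = sync.loci.iloc[i]
            sextets = "\t".join(
                ":".join(str(int(c)) for c in sync.counts[i, j])
                for j in range(len(sync.samples))
            )
            fh.write(f"{row.scaffold}\t{row.pos + 1}\t{row.ref}\t{sextets}\n")


def panel_to_sync(panel: SNPPanel) -> SyncTable:
    """Encode a frequency/depth panel as base counts.

    The tracked allele is written as ``A`` and the alternative as ``C``
    (reference base ``C``), with ``round(freq * depth)`` tracked reads per
    sample — the encoding a pool-seq caller would produce for a biallelic
    site, and exactly invertible by :func:`sync_to_panel`.
    """
    n, m = panel.n_snps, len(panel.samples)
    counts = np.zeros((n, m, 6), dtype=np.int64)
    freqs = panel.freqs.to_numpy(float)
    depths = panel.depths.to_numpy(np.int64)
    a = np.rint(freqs * depths).astype(np.int64)
    counts[:, :, 0] = a
    counts[:, :, 2] = depths - a
    loci = panel.loci[["scaffold", "pos"]].copy()
    loci["ref"] = "C"
    return SyncTable(loci=loci, counts=counts, samples=list(panel.samples))


def sync_to_panel(sync: SyncTable,
                  ancestor_samples: list[str] | None = None) -> SNPPanel:
    """Tracked-allele frequencies and depths from base counts.

    The tracked allele is resolved per locus as the *minor* called allele
    of the pooled ancestral samples (all samples when ``ancestor_samples``
    is None), fixing one orientation that every downstream direction sign
    refers to.  Sites with fewer than two called alleles in the ancestors
    keep the overall minor allele.
    """
    if len(sync.loci) == 0:
        raise ValueError("empty sync table")
    idx = ([sync.samples.index(s) for s in ancestor_samples]
           if ancestor_samples else list(range(len(sync.samples))))
    pooled = sync.counts[:, idx, :4].sum(axis=1)  # called bases only
    order = np.argsort(pooled, axis=1)  # ascending
    major = order[:, -1]
    # minor = second-most-common called allele; fall back to overall counts
    second = order[:, -2]
    overall = sync.counts[:, :, :4].sum(axis=1)
    no_second = pooled[np.arange(len(pooled)), second] == 0
    if np.any(no_second):
        alt = np.argsort(overall, axis=1)[:, -2]
        second = np.where(no_second, alt, second)
        second = np.where(second == major, (major + 1) % 4, second)
    tracked = second
    depth = sync.counts[:, :, :4].sum(axis=2)
    if np.any(depth < 1):
        raise ValueError("site with zero called-base depth")
    tr = sync.counts[np.arange(len(sync.loci))[:, None],
                     np.arange(len(sync.samples))[None, :], tracked[:, None]]
    freqs = tr / depth
    loci = sync.loci[["scaffold", "pos"]].copy()
    return SNPPanel(
        loci=loci,
        freqs=pd.DataFrame(freqs, columns=sync.samples, index=loci.index),
        depths=pd.DataFrame(depth, columns=sync.samples, index=loci.index),
    )


_TRAIT_COLUMNS = ["line_id", "background", "regime", "replicate",
                  "assay_temp", "trait", "mean", "se", "n"]


def read_trait_table(path, traits: tuple[str, ...] = TRAITS) -> pd.DataFrame:
    """Read and validate a long-format trait panel TSV."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_TRAIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trait table lacks columns: {sorted(missing)}")
    unknown = set(df["trait"]) - set(traits)
    if unknown:
        raise ValueError(f"unknown trait names: {sorted(unknown)}")
    dup = df.duplicated(subset=["line_id", "assay_temp", "trait"])
    if dup.any():
        cells = df.loc[dup, ["line_id", "assay_temp", "trait"]]
        raise ValueError(f"duplicate trait cells:\n{cells.to_string(index=False)}")
    return df


def write_trait_table(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, sep="\t", index=False, columns=_TRAIT_COLUMNS)


def read_design_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"line_id", "background", "regime", "replicate",
                "sampling_generation", "pool_size"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design table lacks columns: {sorted(missing)}")
    return df


def write_design_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_gff3(path, *, protein_coding_only: bool = True,
              cds_level: bool = False) -> pd.DataFrame:
    """Gene intervals from a GFF3 annotation.

    Returns a frame with columns ``seqid``, ``start``, ``end`` (1-based
    inclusive, as in the file), ``gene_id`` and ``biotype``.  By default
    one interval per ``gene`` feature (the full CDS-bearing gene body);
    with ``cds_level=True``, one interval per ``CDS`` feature instead,
    attributed to its parent gene.  ``protein_coding_only`` drops genes
    whose declared biotype is not protein-coding (genes without a biotype
    attribute are kept).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"line {lineno}: expected 9 GFF3 columns")
            seqid, _, ftype, start, end, _, _, _, attrs = parts
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ValueError(f"line {lineno}: non-integer coordinates")
            if end_i < start_i:
                raise ValueError(f"line {lineno}: end < start")
            attrd = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attrd[k.strip()] = v.strip()
            rows.append({"seqid": seqid, "type": ftype, "start": start_i,
                         "end": end_i,
                         "id": attrd.get("ID", ""),
                         "parent": attrd.get("Parent", ""),
                         "biotype": attrd.get("gene_biotype",
                                              attrd.get("biotype", ""))})
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=["seqid", "start", "end", "gene_id", "biotype"])
    genes = df[df["type"] == "gene"].copy()
    if protein_coding_only:
        genes = genes[(genes["biotype"] == "") |
                      (genes["biotype"] == "protein_coding")]
    genes = genes.rename(columns={"id": "gene_id"})
    if not cds_level:
        return genes[["seqid", "start", "end", "gene_id", "biotype"]] \
            .reset_index(drop=True)
    keep = set(genes["gene_id"])
    cds = df[df["type"] == "CDS"].copy()
    # CDS Parent may be an mRNA; map through one level if needed
    mrna = df[df["type"].isin(("mRNA", "transcript"))].set_index("id")["parent"]
    parent_gene = cds["parent"].map(lambda p: mrna.get(p, p))
    cds["gene_id"] = parent_gene
    cds = cds[cds["gene_id"].isin(keep)]
    bio = genes.set_index("gene_id")["biotype"]
    cds["biotype"] = cds["gene_id"].map(bio)
    return cds[["seqid", "start", "end", "gene_id", "biotype"]] \
        .reset_index(drop=True)


def write_gff3(genes: pd.DataFrame, path) -> None:
    """Write gene intervals as a minimal GFF3 annotation."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples():
            bio = getattr(row, "biotype", "protein_coding") or "protein_coding"
            fh.write(f"{row.seqid}\tevorepeat\tgene\t{row.start}\t{row.end}"
                     f"\t.\t+\t.\tID={row.gene_id};gene_biotype={bio}\n")


def rolling_log10p(
    pvalues: pd.DataFrame,
    window: int = 20,
    quantile: float = 0.999,
) -> tuple[pd.DataFrame, float]:
    """Rolling-mean -log10 p track per scaffold, with its outlier threshold.

    ``pvalues`` needs columns ``scaffold``, ``pos``, ``pvalue`` with
    positions sorted within each scaffold.  Windows of ``window``
    consecutive SNPs never span scaffolds; each scaffold contributes
    ``max(0, n - window + 1)`` windows centred on the middle SNP.  The
    returned threshold is the upper ``1 - quantile`` empirical quantile of
    the window means (top 0.1% by default), the line drawn on
    Manhattan-style plots.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    out = []
    for scf, sub in pvalues.groupby("scaffold", sort=False):
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"positions not sorted within scaffold {scf!r}")
        logs = -np.log10(sub["pvalue"].to_numpy(float))
        if len(logs) < window:
            continue
        kernel = np.ones(window) / window
        track = np.convolve(logs, kernel, mode="valid")
        centers = pos[window // 2: window // 2 + len(track)]
        out.append(pd.DataFrame({"scaffold": scf, "pos": centers,
                                 "track": track}))
    if not out:
        return pd.DataFrame(columns=["scaffold", "pos", "track"]), math.nan
    track_df = pd.concat(out, ignore_index=True)
    threshold = float(np.quantile(track_df["track"].to_numpy(), quantile))
    return track_df, threshold


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "results/pipeline"
    seed: int = 0
    # input paths; None for stages fed by the simulation step
    sync_path: str | None = None
    traits_path: str | None = None
    design_path: str | None = None
    gff3_path: str | None = None
    # simulation scenario (used when sync_path is None)
    simulate: dict = field(default_factory=lambda: {
        "n_snps": 20000,
        "differentiation": 0.1,
        "class_fractions": {"SP": 0.01, "AP": 0.01,
                            "PrivateCold": 0.02, "PrivateHot": 0.02},
        "s_magnitude": 0.1,
        "trait_noise": 0.2,
    })
    # thresholds
    detection_q: float = 1e-4
    class_q: float = 1e-2
    offset_quantile: float = 0.001
    tail_mode: str = "per_tail"  # or "two_sided"
    drift_model: str = "wf_exact"  # or "beta"
    proxy_offset: int = 3
    assay_temp: float = 35.0
    ne_overrides: dict = field(default_factory=dict)  # line_id -> Ne

    def validate(self) -> None:
        for name, val, hi in (("detection_q", self.detection_q, 0.5),
                              ("class_q", self.class_q, 0.5),
                              ("offset_quantile", self.offset_quantile, 1.0)):
            if not 0 < val < hi:
                raise ValueError(f"{name} must lie in (0, {hi}), got {val}")
        if self.tail_mode not in ("per_tail", "two_sided"):
            raise ValueError(f"unknown tail_mode {self.tail_mode!r}")
        if self.drift_model not in ("wf_exact", "beta"):
            raise ValueError(f"unknown drift_model {self.drift_model!r}")
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")
        if self.proxy_offset < 0:
            raise ValueError("proxy_offset must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        data = {k: getattr(self, k) for k in self.__dataclass_fields__}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
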