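"""Shared containers and constants for the evolve-and-resequence pipeline.

Conventions used throughout the package:

* Allele frequencies refer to one *tracked* allele per locus, chosen once
  (the minor allele of the pooled ancestral samples of a background) and
  used consistently for direction signs.
* Genomic coordinates are 0-based half-open internally; sync and GFF3
  files use their native 1-based inclusive convention and are converted
  at the I/O boundary only.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

REGIMES = ("cold", "hot")
#: SNP pleiotropy classes: synergistic, antagonistic, regime-private, neutral.
SNP_CLASSES = ("SP", "AP", "PrivateCold", "PrivateHot", "Neutral")
#: The seven female life-history traits assayed in the experiment.
TRAITS = (
    "lrs",
    "adult_weight",
    "dev_time",
    "weight_loss",
    "water_loss",
    "early_fecundity",
    "metabolic_rate",
)
ASSAY_TEMPS = (23.0, 35.0)
DEFAULT_BACKGROUNDS = ("Brazil", "California", "Yemen")

#: Column order of a PoPoolation2 sync count sextet.
SYNC_BASES = ("A", "T", "C", "G", "N", "del")


def rng_from(seed) -> np.random.Generator:
    """Return ``seed`` itself if it is already a Generator, else seed one."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_rngs(seed, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent substreams from a master seed.

    Uses :class:`numpy.random.SeedSequence` spawning so that per-line,
    per-stage streams are reproducible piecewise from one master seed.
    """
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


@dataclass(frozen=True)
class LineRecord:
    """One experimental unit of the design."""

    line_id: str
    background: str
    regime: str  # "cold" | "hot" | "ancestor"
    replicate: int
    sampling_generation: int  # nominal generation at which the pool was taken
    pool_size: int  # diploid individuals in the sequencing pool

    def __post_init__(self):
        if self.regime not in REGIMES + ("ancestor",):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if self.sampling_generation < 0:
            raise ValueError("sampling_generation must be >= 0")


@dataclass
class SNPPanel:
    """Per-SNP, per-sample tracked-allele frequency and read depth.

    ``loci`` has columns ``scaffold`` and ``pos`` (0-based); ``freqs`` and
    ``depths`` share its index and have one column per sample.
    """

    loci: pd.DataFrame
    freqs: pd.DataFrame
    depths: pd.DataFrame

    def __post_init__(self):
        for col in ("scaffold", "pos"):
            if col not in self.loci.columns:
                raise ValueError(f"loci table lacks required column {col!r}")
        if not (self.loci.index.equals(self.freqs.index)
                and self.loci.index.equals(self.depths.index)):
            raise ValueError("loci, freqs and depths must share an index")
        if list(self.freqs.columns) != list(self.depths.columns):
            raise ValueError("freqs and depths must have identical sample columns")
        f = self.freqs.to_numpy(float)
        if np.any((f < 0) | (f > 1)):
            raise ValueError("frequencies must lie in [0, 1]")
        if np.any(self.depths.to_numpy() < 1):
            raise ValueError("depths must be >= 1")

    @property
    def samples(self) -> list[str]:
        return list(self.freqs.columns)

    @property
    def n_snps(self) -> int:
        return len(self.loci)

    def freq(self, sample: str) -> np.ndarray:
        return self.freqs[sample].to_numpy(float)

    def depth(self, sample: str) -> np.ndarray:
        return self.depths[sample].to_numpy()


def lines_to_table(lines: Iterable[LineRecord]) -> pd.DataFrame:
    """Design table (one row per experimental unit) from line records."""
    return pd.DataFrame(
        [
            {
                "line_id": ln.line_id,
                "background": ln.background,
                "regime": ln.regime,
                "replicate": ln.replicate,
                "sampling_generation": ln.sampling_generation,
                "pool_size": ln.pool_size,
            }
            for ln in lines
        ]
    )


def table_to_lines(table: pd.DataFrame) -> list[LineRecord]:
    required = {"line_id", "background", "regime", "replicate",
                "sampling_generation", "pool_size"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"design table lacks columns: {sorted(missing)}")
    return [
        LineRecord(
            line_id=str(r.line_id),
            background=str(r.background),
            regime=str(r.regime),
            replicate=int(r.replicate),
            sampling_generation=int(r.sampling_generation),
            pool_size=int(r.pool_size),
        )
        for r in table.itertuples()
    ]
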