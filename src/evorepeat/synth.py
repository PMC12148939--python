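"""Synthetic evolve-and-resequence experiments.

Generates complete experiments — pooled allele-frequency panels, seven-trait
phenotype panels and design tables — with the statistical structure the
downstream analysis assumes: three differentiated ancestral backgrounds with
shared and private polymorphism, forward Wright-Fisher evolution under
regime-specific selection classes, two-stage pool-seq sampling noise, and
per-line trait means with reported standard errors at two assay temperatures.

The generator is single-locus (free recombination, no linkage): the drift
null tested downstream is itself single-locus, so linked selection is out of
scope here. Epistasis and sex chromosomes are likewise not simulated.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    ASSAY_TEMPS,
    DEFAULT_BACKGROUNDS,
    REGIMES,
    SNP_CLASSES,
    TRAITS,
    LineRecord,
    SNPPanel,
    lines_to_table,
    rng_from,
)

__all__ = [
    "ExperimentDesign",
    "Architecture",
    "AncestralPool",
    "SimulatedExperiment",
    "draw_ancestral_frequencies",
    "assign_architecture",
    "simulate_wf_trajectory",
    "sample_poolseq",
    "generate_experiment",
    "background_private_scenario",
    "synthetic_gene_annotation",
]


@dataclass(frozen=True)
class ExperimentDesign:
    """The 3-background x 2-regime x 2-replicate design.

    ``generations`` holds the *divergence* time per regime between the
    ancestor-proxy sample and the evolved sample (cold 60, hot 64 by
    default).  Because the ancestor proxy is itself taken at generation
    ``ancestor_proxy_generation`` of the heat-adapting lines, the nominal
    forward-simulation span of a line is ``generations - proxy`` for cold
    lines and ``generations + proxy`` for hot lines (57 and 67 by default).

    ``Ne`` gives the true effective size per regime used by the simulator;
    the defaults put stronger drift in the hot regime, with a study-wide
    mean close to 215 diploids.
    """

    backgrounds: tuple[str, ...] = DEFAULT_BACKGROUNDS
    replicates_per_cell: int = 2
    generations: dict = field(default_factory=lambda: {"cold": 60, "hot": 64})
    pool_size: int = 60
    mean_depth: int = 50
    ancestor_proxy_generation: int = 3
    Ne: dict = field(default_factory=lambda: {"cold": 250, "hot": 180})

    def __post_init__(self):
        if self.replicates_per_cell < 1:
            raise ValueError("replicates_per_cell must be >= 1")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if self.mean_depth < 1:
            raise ValueError("mean_depth must be >= 1")
        for regime in REGIMES:
            if self.generations.get(regime, 0) < 1:
                raise ValueError(f"generations[{regime!r}] must be >= 1")
        if self.nominal_generation("cold") < 0:
            raise ValueError("ancestor proxy generation exceeds cold divergence time")

    def nominal_generation(self, regime: str) -> int:
        """Generation at which a line of ``regime`` is actually sampled."""
        proxy = self.ancestor_proxy_generation
        if regime == "cold":
            return self.generations["cold"] - proxy
        if regime == "hot":
            return self.generations["hot"] + proxy
        raise ValueError(f"unknown regime {regime!r}")

    def lines(self) -> list[LineRecord]:
        out = []
        for bg in self.backgrounds:
            for regime in REGIMES:
                for rep in range(1, self.replicates_per_cell + 1):
                    out.append(
                        LineRecord(
                            line_id=f"{bg}_{regime}_{rep}",
                            background=bg,
                            regime=regime,
                            replicate=rep,
                            sampling_generation=self.nominal_generation(regime),
                            pool_size=self.pool_size,
                        )
                    )
        return out


@dataclass
class AncestralPool:
    """Per-background, per-SNP ancestral allele frequencies."""

    backgrounds: tuple[str, ...]
    p0: np.ndarray  # shape (n_backgrounds, n_snps)
    differentiation: float = 0.0

    def __post_init__(self):
        self.p0 = np.asarray(self.p0, float)
        if self.p0.ndim != 2 or self.p0.shape[0] != len(self.backgrounds):
            raise ValueError("p0 must be (n_backgrounds, n_snps)")
        if np.any((self.p0 < 0) | (self.p0 > 1)):
            raise ValueError("ancestral frequencies must lie in [0, 1]")

    @property
    def n_snps(self) -> int:
        return self.p0.shape[1]

    @property
    def shared_mask(self) -> np.ndarray:
        """True where the locus is polymorphic in every background."""
        return np.all((self.p0 > 0) & (self.p0 < 1), axis=0)

    def freq(self, background: str) -> np.ndarray:
        return self.p0[self.backgrounds.index(background)]


@dataclass
class Architecture:
    """Per-SNP selection classes, coefficients and additive trait effects.

    Class invariants: SP has equal-sign nonzero coefficients in both
    regimes, AP opposite signs, Private* a nonzero coefficient in exactly
    one regime, Neutral zero in both.  ``trait_effects`` maps unit
    allele-frequency change to mean-scaled trait units and is nonzero only
    for non-neutral loci.
    """

    class_of_snp: np.ndarray  # dtype str, values in SNP_CLASSES
    s_cold: np.ndarray
    s_hot: np.ndarray
    trait_effects: np.ndarray  # shape (n_snps, len(TRAITS))

    def __post_init__(self):
        n = len(self.class_of_snp)
        self.s_cold = np.asarray(self.s_cold, float)
        self.s_hot = np.asarray(self.s_hot, float)
        self.trait_effects = np.asarray(self.trait_effects, float)
        if self.s_cold.shape != (n,) or self.s_hot.shape != (n,):
            raise ValueError("selection coefficient arrays must match n_snps")
        if self.trait_effects.shape != (n, len(TRAITS)):
            raise ValueError("trait_effects must be (n_snps, n_traits)")
        cls = np.asarray(self.class_of_snp)
        checks = [
            ("SP", (self.s_cold * self.s_hot > 0)),
            ("AP", (self.s_cold * self.s_hot < 0)),
            ("PrivateCold", (self.s_cold != 0) & (self.s_hot == 0)),
            ("PrivateHot", (self.s_cold == 0) & (self.s_hot != 0)),
            ("Neutral", (self.s_cold == 0) & (self.s_hot == 0)),
        ]
        for name, ok in checks:
            if not np.all(ok[cls == name]):
                raise ValueError(f"selection coefficients violate the {name} invariant")

    @property
    def n_snps(self) -> int:
        return len(self.class_of_snp)

    def s_for(self, regime: str) -> np.ndarray:
        if regime == "cold":
            return self.s_cold
        if regime == "hot":
            return self.s_hot
        raise ValueError(f"unknown regime {regime!r}")

    def to_table(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "snp": np.arange(self.n_snps),
                "class": self.class_of_snp,
                "s_cold": self.s_cold,
                "s_hot": self.s_hot,
            }
        )
        for j, trait in enumerate(TRAITS):
            df[f"effect_{trait}"] = self.trait_effects[:, j]
        return df


def draw_ancestral_frequencies(
    n_snps: int,
    n_backgrounds: int = 3,
    differentiation: float = 0.1,
    seed=0,
    *,
    low: float = 0.05,
    high: float = 0.95,
    founder_size: int = 300,
    backgrounds: tuple[str, ...] | None = None,
) -> AncestralPool:
    """Draw differentiated ancestral frequencies around a common ancestor.

    A common frequency is drawn uniformly on ``[low, high]`` per locus, and
    each background draws around it from a Balding-Nichols beta whose
    F_ST-like parameter is ``differentiation``.  Draws are then discretised
    through a founder population of ``founder_size`` diploids (mirroring the
    few-hundred-individual census of laboratory stocks), which produces the
    differential fixation between backgrounds that the offset analysis needs.
    With ``differentiation == 0`` all backgrounds are identical copies of
    the common frequency.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if not 0 <= differentiation < 1:
        raise ValueError("differentiation must lie in [0, 1)")
    if backgrounds is None:
        backgrounds = tuple(DEFAULT_BACKGROUNDS[:n_backgrounds]) \
            if n_backgrounds <= len(DEFAULT_BACKGROUNDS) \
            else tuple(f"bg{i+1}" for i in range(n_backgrounds))
    if len(backgrounds) != n_backgrounds:
        raise ValueError("backgrounds labels must match n_backgrounds")
    rng = rng_from(seed)
    common = rng.uniform(low, high, n_snps)
    if differentiation == 0:
        p = np.tile(common, (n_backgrounds, 1))
    else:
        f = differentiation
        a = common * (1 - f) / f
        b = (1 - common) * (1 - f) / f
        p = rng.beta(a, b, size=(n_backgrounds, n_snps))
        p = rng.binomial(2 * founder_size, p) / (2 * founder_size)
    return AncestralPool(backgrounds=tuple(backgrounds), p0=p,
                         differentiation=differentiation)


def assign_architecture(
    n_snps: int,
    class_fractions: dict[str, float],
    s_magnitude: float = 0.05,
    seed=0,
    *,
    trait_effect_scale: float = 0.05,
) -> Architecture:
    """Assign pleiotropy classes and selection coefficients to loci.

    ``class_fractions`` maps class name to the fraction of loci it receives
    (``floor(fraction * n_snps)`` loci each, remainder Neutral).  Signs of
    the selected allele are random per locus; SP loci share the sign across
    regimes, AP loci flip it.  Trait effects are Gaussian with s.d.
    ``trait_effect_scale`` for non-neutral loci and exactly zero otherwise.
    """
    fracs = {k: float(v) for k, v in class_fractions.items()}
    unknown = set(fracs) - set(SNP_CLASSES)
    if unknown:
        raise ValueError(f"unknown SNP classes: {sorted(unknown)}")
    if any(v < 0 for v in fracs.values()):
        raise ValueError("class fractions must be >= 0")
    if sum(fracs.values()) > 1 + 1e-12:
        raise ValueError("class fractions must sum to <= 1")
    n_selected = sum(
        int(np.floor(fracs.get(c, 0.0) * n_snps)) for c in SNP_CLASSES if c != "Neutral"
    )
    if n_selected > 0 and s_magnitude <= 0:
        raise ValueError("s_magnitude must be > 0 when non-neutral classes are present")

    rng = rng_from(seed)
    cls = np.full(n_snps, "Neutral", dtype=object)
    s_cold = np.zeros(n_snps)
    s_hot = np.zeros(n_snps)
    order = rng.permutation(n_snps)
    cursor = 0
    for name in ("SP", "AP", "PrivateCold", "PrivateHot"):
        k = int(np.floor(fracs.get(name, 0.0) * n_snps))
        idx = order[cursor:cursor + k]
        cursor += k
        cls[idx] = name
        sign = rng.choice((-1.0, 1.0), size=k)
        if name == "SP":
            s_cold[idx] = sign * s_magnitude
            s_hot[idx] = sign * s_magnitude
        elif name == "AP":
            s_cold[idx] = sign * s_magnitude
            s_hot[idx] = -sign * s_magnitude
        elif name == "PrivateCold":
            s_cold[idx] = sign * s_magnitude
        else:  # PrivateHot
            s_hot[idx] = sign * s_magnitude
    effects = np.zeros((n_snps, len(TRAITS)))
    nonneutral = cls != "Neutral"
    effects[nonneutral] = rng.normal(0.0, trait_effect_scale,
                                     size=(int(nonneutral.sum()), len(TRAITS)))
    return Architecture(class_of_snp=cls.astype(str), s_cold=s_cold,
                        s_hot=s_hot, trait_effects=effects)


def _selection_update(p: np.ndarray, s) -> np.ndarray:
    # Deterministic one-generation response for a haploid-equivalent
    # coefficient: p' = p(1+s) / (1 + ps).
    return p * (1 + s) / (1 + p * s)


def simulate_wf_trajectory(p0, Ne: float, s, t: int, seed=0) -> np.ndarray:
    """Evolve allele frequencies forward under selection and drift.

    Each generation applies the deterministic selection update
    ``p' = p(1+s)/(1+ps)`` followed by binomial drift sampling of ``2*Ne``
    chromosomes.  0 and 1 are absorbing.  ``p0`` and ``s`` may be arrays
    (broadcast together); returns the frequency after ``t`` generations.
    """
    p = np.asarray(p0, dtype=float)
    scalar = p.ndim == 0
    p = np.atleast_1d(p).copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p0 must lie in [0, 1]")
    if Ne < 1:
        raise ValueError("Ne must be >= 1")
    if t < 0:
        raise ValueError("t must be >= 0")
    rng = rng_from(seed)
    n_chrom = int(round(2 * Ne))
    for _ in range(int(t)):
        p = _selection_update(p, s)
        p = rng.binomial(n_chrom, p) / n_chrom
    return p[0] if scalar else p


def _wf_path(p0: np.ndarray, Ne: float, s, t: int,
             record_at: set[int], rng: np.random.Generator) -> dict[int, np.ndarray]:
    """Forward simulation recording the state at selected generations."""
    p = np.asarray(p0, float).copy()
    n_chrom = int(round(2 * Ne))
    states = {}
    if 0 in record_at:
        states[0] = p.copy()
    for g in range(1, int(t) + 1):
        p = _selection_update(p, s)
        p = rng.binomial(n_chrom, p) / n_chrom
        if g in record_at:
            states[g] = p.copy()
    return states


def sample_poolseq(p_true, pool_size: int, depth, seed=0):
    """Two-stage pool-seq sampling of a true allele frequency.

    Stage one draws ``k ~ Binom(2*pool_size, p_true)`` chromosomes into the
    pool; stage two draws ``r ~ Binom(depth, k / (2*pool_size))`` reads.
    Returns ``(r/depth, depth)``.
    """
    p = np.asarray(p_true, float)
    scalar = p.ndim == 0
    p = np.atleast_1d(p)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p_true must lie in [0, 1]")
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    d = np.broadcast_to(np.atleast_1d(np.asarray(depth, int)), p.shape)
    if np.any(d < 1):
        raise ValueError("depth must be >= 1")
    rng = rng_from(seed)
    k = rng.binomial(2 * pool_size, p)
    r = rng.binomial(d, k / (2 * pool_size))
    freq = r / d
    if scalar:
        return float(freq[0]), int(d[0])
    return freq, d.copy()


@dataclass
class SimulatedExperiment:
    """Bundle of everything one synthetic experiment produces."""

    design: ExperimentDesign
    snp_panel: SNPPanel
    trait_panel: pd.DataFrame
    design_table: pd.DataFrame
    architecture: Architecture
    pool: AncestralPool
    true_freqs: pd.DataFrame  # noiseless frequencies per sample
    true_traits: pd.DataFrame  # noiseless trait means per line


def _default_loci(n_snps: int, n_scaffolds: int = 10, spacing: int = 100) -> pd.DataFrame:
    per = int(np.ceil(n_snps / n_scaffolds))
    scaffold = [f"scf{i // per + 1}" for i in range(n_snps)]
    pos = [(i % per) * spacing for i in range(n_snps)]
    return pd.DataFrame({"scaffold": scaffold, "pos": pos})


def generate_experiment(
    design: ExperimentDesign,
    pool: AncestralPool,
    arch: Architecture,
    trait_noise: float = 0.2,
    seed=0,
) -> SimulatedExperiment:
    """Simulate a full experiment from ancestral frequencies and architecture.

    Every line evolves all loci with its regime's selection coefficients at
    the design's per-regime Ne.  The two heat-adapting replicates of each
    background double as the ancestor proxies: their states at
    ``ancestor_proxy_generation`` are pool-sequenced as the ancestral
    samples (``<bg>_anc_<rep>``).  All emitted frequencies carry two-stage
    pool-seq noise with Poisson-distributed depths around ``mean_depth``.

    Trait means are ``ancestral baseline + effects^T (p_line - p0_bg)`` on
    the true (noiseless) frequencies, identical at both assay temperatures,
    plus Gaussian measurement error with standard deviation ``trait_noise``
    (also the reported per-cell standard error).
    """
    if pool.n_snps != arch.n_snps:
        raise ValueError("ancestral pool and architecture disagree on n_snps")
    if tuple(pool.backgrounds) != tuple(design.backgrounds):
        raise ValueError("ancestral pool and design disagree on backgrounds")
    if trait_noise < 0:
        raise ValueError("trait_noise must be >= 0")

    master = np.random.SeedSequence(seed)
    n_bg = len(design.backgrounds)
    reps = design.replicates_per_cell
    # One stream per background per regime-replicate path, plus one for
    # depths/traits bookkeeping.
    streams = iter(np.random.default_rng(c)
                   for c in master.spawn(n_bg * reps * 2 + 2))
    depth_rng = next(streams)
    trait_rng = next(streams)

    g_cold = design.nominal_generation("cold")
    g_hot = design.nominal_generation("hot")
    g_proxy = design.ancestor_proxy_generation

    loci = _default_loci(pool.n_snps)
    obs_freq: dict[str, np.ndarray] = {}
    obs_depth: dict[str, np.ndarray] = {}
    true_freq: dict[str, np.ndarray] = {}

    def emit(sample: str, p_true: np.ndarray) -> None:
        depth = np.clip(depth_rng.poisson(design.mean_depth, pool.n_snps), 1, None)
        f, d = sample_poolseq(p_true, design.pool_size, depth, depth_rng)
        obs_freq[sample] = f
        obs_depth[sample] = d
        true_freq[sample] = p_true

    for bg in design.backgrounds:
        p0 = pool.freq(bg)
        for rep in range(1, reps + 1):
            path = _wf_path(p0, design.Ne["hot"], arch.s_hot, g_hot,
                            {g_proxy, g_hot}, next(streams))
            emit(f"{bg}_anc_{rep}", path[g_proxy])
            emit(f"{bg}_hot_{rep}", path[g_hot])
        for rep in range(1, reps + 1):
            path = _wf_path(p0, design.Ne["cold"], arch.s_cold, g_cold,
                            {g_cold}, next(streams))
            emit(f"{bg}_cold_{rep}", path[g_cold])

    order = [f"{bg}_{kind}_{rep}"
             for bg in design.backgrounds
             for kind in ("anc", "cold", "hot")
             for rep in range(1, reps + 1)]
    panel = SNPPanel(
        loci=loci,
        freqs=pd.DataFrame({s: obs_freq[s] for s in order}, index=loci.index),
        depths=pd.DataFrame({s: obs_depth[s] for s in order}, index=loci.index),
    )

    # --- trait panel -----------------------------------------------------
    # Ancestral baselines: a fixed per-trait constant with a small
    # multiplicative background deviation, so ancestors are differentiated
    # in trait space (needed by the divergence scaling).
    base = dict(zip(TRAITS, (30.0, 5.0, 25.0, 2.0, 1.5, 40.0, 0.8)))
    bg_dev = {bg: trait_rng.normal(0.0, 0.03, len(TRAITS))
              for bg in design.backgrounds}

    rows, true_rows = [], []

    def trait_rows(line_id, bg, regime, rep, dp):
        shift = arch.trait_effects.T @ dp  # per-trait additive change
        for temp in ASSAY_TEMPS:
            for j, trait in enumerate(TRAITS):
                mu = base[trait] * (1 + bg_dev[bg][j]) + shift[j]
                obs = mu + (trait_rng.normal(0.0, trait_noise) if trait_noise else 0.0)
                rows.append({"line_id": line_id, "background": bg,
                             "regime": regime, "replicate": rep,
                             "assay_temp": temp, "trait": trait,
                             "mean": obs, "se": trait_noise, "n": 20})
                true_rows.append({"line_id": line_id, "background": bg,
                                  "regime": regime, "replicate": rep,
                                  "assay_temp": temp, "trait": trait,
                                  "mean": mu})

    for bg in design.backgrounds:
        p0 = pool.freq(bg)
        trait_rows(f"{bg}_anc", bg, "ancestor", 0, np.zeros(pool.n_snps))
        for regime in REGIMES:
            for rep in range(1, reps + 1):
                line_id = f"{bg}_{regime}_{rep}"
                dp = true_freq[line_id] - p0
                trait_rows(line_id, bg, regime, rep, dp)

    lines = design.lines()
    return SimulatedExperiment(
        design=design,
        snp_panel=panel,
        trait_panel=pd.DataFrame(rows),
        design_table=lines_to_table(lines),
        architecture=arch,
        pool=pool,
        true_freqs=pd.DataFrame(true_freq, index=loci.index)[order],
        true_traits=pd.DataFrame(true_rows),
    )


def background_private_scenario(
    n_selected_per_background: int = 100,
    n_neutral: int = 20000,
    s: float = 0.1,
    seed=0,
    *,
    differentiation: float = 0.1,
    leak_fraction: float = 0.2,
    lrs_effect: float = 0.05,
    design: ExperimentDesign | None = None,
) -> tuple[ExperimentDesign, AncestralPool, Architecture]:
    """Scenario with disjoint heat-selected loci per genetic background.

    Each background carries its own block of ``n_selected_per_background``
    PrivateHot loci segregating at intermediate frequency there, while in
    the other backgrounds those loci are fixed absent (a ``leak_fraction``
    of them segregates at low frequency instead, so cross-background
    offsets are not strictly degenerate).  Selected alleles raise lifetime
    reproductive success and shorten development time, tying genomic
    adaptation to the laboratory-fitness proxy.  A shared block of neutral
    Balding-Nichols loci completes the panel.
    """
    if design is None:
        design = ExperimentDesign()
    rng = rng_from(seed)
    n_bg = len(design.backgrounds)
    n_sel = n_selected_per_background * n_bg
    n = n_sel + n_neutral

    p0 = np.zeros((n_bg, n))
    cls = np.full(n, "Neutral", dtype=object)
    s_hot = np.zeros(n)
    effects = np.zeros((n, len(TRAITS)))

    for b in range(n_bg):
        lo = b * n_selected_per_background
        hi = lo + n_selected_per_background
        p0[b, lo:hi] = rng.uniform(0.2, 0.5, n_selected_per_background)
        for other in range(n_bg):
            if other == b:
                continue
            leak = rng.random(n_selected_per_background) < leak_fraction
            p0[other, lo:hi] = np.where(
                leak, rng.uniform(0.02, 0.08, n_selected_per_background), 0.0)
        cls[lo:hi] = "PrivateHot"
        s_hot[lo:hi] = s
        effects[lo:hi, TRAITS.index("lrs")] = np.abs(
            rng.normal(lrs_effect, lrs_effect / 3, n_selected_per_background))
        effects[lo:hi, TRAITS.index("dev_time")] = -np.abs(
            rng.normal(lrs_effect / 3, lrs_effect / 9, n_selected_per_background))

    neutral_pool = draw_ancestral_frequencies(
        n_neutral, n_bg, differentiation, rng, backgrounds=design.backgrounds)
    p0[:, n_sel:] = neutral_pool.p0

    pool = AncestralPool(backgrounds=tuple(design.backgrounds), p0=p0,
                         differentiation=differentiation)
    arch = Architecture(class_of_snp=cls.astype(str), s_cold=np.zeros(n),
                        s_hot=s_hot, trait_effects=effects)
    return design, pool, arch


def synthetic_gene_annotation(
    loci: pd.DataFrame,
    gene_length: int = 500,
    gene_spacing: int = 1500,
    seed=0,
) -> pd.DataFrame:
    """Synthetic protein-coding gene intervals tiling the loci's scaffolds.

    Returns a table with 1-based inclusive ``start``/``end`` columns (GFF3
    convention) suitable for :func:`evorepeat.io.write_gff3`.
    """
    rng = rng_from(seed)
    rows = []
    gid = 0
    for scf, sub in loci.groupby("scaffold", sort=False):
        span = int(sub["pos"].max()) + gene_length
        start = int(rng.integers(0, gene_spacing))
        while start < span:
            gid += 1
            rows.append({"seqid": scf, "start": start + 1,
                         "end": start + gene_length,
                         "gene_id": f"gene{gid:05d}",
                         "biotype": "protein_coding"})
            start += gene_length + int(rng.integers(gene_spacing // 2, gene_spacing))
    return pd.DataFrame(rows)
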