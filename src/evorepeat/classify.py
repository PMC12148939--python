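"""Pleiotropy classes of candidate SNPs and genes, and overlap statistics.

Within one genetic background, a thermal regime scores a "hit" at a SNP
when *both* replicate lines of that regime change beyond the relaxed null
threshold (per-tail probability q, default 1e-2) in the *same* direction.
SNPs are then classified as:

* ``SP``  — synergistic pleiotropy: hits in both regimes, same direction;
* ``AP``  — antagonistic pleiotropy: hits in both regimes, opposite
  directions;
* ``PrivateCold`` / ``PrivateHot`` — a hit in exactly one regime;
* ``None`` — anything weaker.

Genes inherit the classes of the SNPs falling inside their protein-coding
span, and cross-background repeatability is quantified by upset-style
intersection counts, Jaccard indices, and a forward drift-simulation null
for the expected overlap.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import REGIMES, rng_from
from .drift import sampling_aware_pvalues
from .synth import sample_poolseq, simulate_wf_trajectory

__all__ = [
    "classify_snps",
    "map_snps_to_genes",
    "jaccard",
    "overlap_counts",
    "expected_overlap_by_drift",
    "OverlapReport",
]

CLASS_NONE = "None"


def _regime_hits(pvals: list[np.ndarray], dirs: list[np.ndarray],
                 q: float) -> tuple[np.ndarray, np.ndarray]:
    """Concordant two-replicate hits: both tails beyond q, same direction."""
    beyond = [(p / 2.0 < q) & (d != 0) for p, d in zip(pvals, dirs)]
    hit = beyond[0] & beyond[1] & (dirs[0] == dirs[1])
    direction = np.where(hit, dirs[0], 0)
    return hit, direction


def classify_snps(
    pvalues: dict[str, list[np.ndarray]],
    directions: dict[str, list[np.ndarray]],
    per_tail_probability: float = 1e-2,
) -> pd.DataFrame:
    """Classify the SNPs of one background from its four lines' tests.

    ``pvalues`` and ``directions`` map each regime (``"cold"``, ``"hot"``)
    to the two replicate lines' per-SNP two-sided p-values and change
    directions.  Returns a frame with the class and the per-regime hit
    direction for every SNP; classes are mutually exclusive by
    construction.
    """
    q = float(per_tail_probability)
    if not 0 < q < 0.5:
        raise ValueError("per_tail_probability must lie in (0, 0.5)")
    for mapping in (pvalues, directions):
        for regime in REGIMES:
            if len(mapping.get(regime, [])) != 2:
                raise ValueError(f"need exactly 2 replicate lines for {regime!r}")
    hit_c, dir_c = _regime_hits(pvalues["cold"], directions["cold"], q)
    hit_h, dir_h = _regime_hits(pvalues["hot"], directions["hot"], q)

    cls = np.full(hit_c.shape, CLASS_NONE, dtype=object)
    both = hit_c & hit_h
    cls[both & (dir_c == dir_h)] = "SP"
    cls[both & (dir_c != dir_h)] = "AP"
    cls[hit_c & ~hit_h] = "PrivateCold"
    cls[hit_h & ~hit_c] = "PrivateHot"
    return pd.DataFrame({
        "class": cls.astype(str),
        "dir_cold": dir_c,
        "dir_hot": dir_h,
    })


def map_snps_to_genes(
    calls: pd.DataFrame,
    genes: pd.DataFrame,
) -> pd.DataFrame:
    """Assign classified SNPs to the protein-coding genes containing them.

    ``calls`` needs columns ``scaffold``, ``pos`` (0-based), ``background``
    and ``class``; ``genes`` needs ``seqid``, ``start``, ``end`` (1-based
    inclusive, GFF3 convention) and ``gene_id``.  A SNP is assigned to
    *every* gene whose span contains it (overlapping genes each receive
    it), and a gene inherits the SNP's class for that background.  Returns
    a long frame (gene_id, background, class, scaffold, pos): one row per
    gene-SNP assignment, so a gene can appear in several classes only via
    distinct SNPs.
    """
    if np.any(genes["end"] < genes["start"]):
        bad = genes[genes["end"] < genes["start"]]
        raise ValueError(f"malformed gene intervals (end < start): "
                         f"{bad['gene_id'].tolist()[:5]}")
    trees: dict[str, IntervalTree] = {}
    for row in genes.itertuples():
        # 1-based inclusive -> 0-based half-open
        trees.setdefault(row.seqid, IntervalTree()).addi(
            row.start - 1, row.end, row.gene_id)
    rows = []
    hits = calls[calls["class"] != CLASS_NONE]
    for scaffold, pos, background, cls in zip(
            hits["scaffold"], hits["pos"], hits["background"], hits["class"]):
        tree = trees.get(scaffold)
        if tree is None:
            continue
        for iv in tree.at(pos):
            rows.append({"gene_id": iv.data, "background": background,
                         "class": cls, "scaffold": scaffold, "pos": pos})
    cols = ["gene_id", "background", "class", "scaffold", "pos"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows, columns=cols).drop_duplicates(ignore_index=True)


def jaccard(a: set, b: set) -> float:
    """Jaccard index |A n B| / |A u B|; 0 when both sets are empty."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def overlap_counts(gene_sets: dict[str, set]) -> pd.DataFrame:
    """Upset-style exclusive intersection counts across backgrounds.

    For every non-empty combination of backgrounds, counts the elements
    present in exactly those sets; the counts sum to the size of the
    union (inclusion-exclusion consistent by construction).
    """
    names = list(gene_sets)
    universe = set().union(*gene_sets.values()) if gene_sets else set()
    membership = {g: frozenset(n for n in names if g in gene_sets[n])
                  for g in universe}
    rows = []
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            fs = frozenset(combo)
            exclusive = sum(1 for m in membership.values() if m == fs)
            total = len(set.intersection(*(gene_sets[n] for n in combo)))
            rows.append({"backgrounds": "&".join(combo), "degree": k,
                         "exclusive": exclusive, "intersection": total})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class OverlapReport:
    """Observed versus drift-expected cross-background sharing."""

    observed: int
    expected: float
    pvalue: float
    iterations: int
    null_counts: np.ndarray


def expected_overlap_by_drift(
    p0_by_background: dict[str, np.ndarray],
    line_params: pd.DataFrame,
    observed: int,
    *,
    per_tail_probability: float = 1e-2,
    snp_class: str = "PrivateHot",
    iterations: int = 1000,
    snps_per_iteration: int = 10000,
    pool_size: int = 60,
    depth: int = 50,
    seed=0,
) -> OverlapReport:
    """Null distribution of cross-background shared classified SNPs.

    Each iteration samples ``snps_per_iteration`` loci from each
    background's ancestral frequencies, evolves every line *neutrally*
    (each line with its own Ne and generation count from ``line_params``:
    columns ``background``, ``regime``, ``replicate``, ``Ne``, ``t``),
    applies pool-seq sampling and the same classification used on data,
    and counts the SNPs assigned to ``snp_class`` in all backgrounds
    simultaneously.  The expectation is the null mean; the p-value is the
    (k+1)/(n+1)-corrected fraction of iterations with at least the
    observed shared count.
    """
    if iterations < 100:
        raise ValueError("iterations must be >= 100")
    backgrounds = list(p0_by_background)
    for bg in backgrounds:
        sub = line_params[line_params["background"] == bg]
        for regime in REGIMES:
            if (sub["regime"] == regime).sum() != 2:
                raise ValueError(f"need 2 {regime} lines for background {bg!r}")
    n_loci = {len(np.asarray(v)) for v in p0_by_background.values()}
    if len(n_loci) != 1:
        raise ValueError("all backgrounds must provide the same loci")
    n_loci = n_loci.pop()
    rng = rng_from(seed)
    counts = np.empty(iterations, dtype=int)
    for it in range(iterations):
        # the same random loci parameterize every background and line
        take = rng.choice(n_loci, size=snps_per_iteration,
                          replace=n_loci < snps_per_iteration)
        shared: np.ndarray | None = None
        for bg in backgrounds:
            p0 = np.asarray(p0_by_background[bg], float)
            p0s = p0[take]
            anc_obs, _ = sample_poolseq(p0s, pool_size, depth, rng)
            r0 = np.rint(anc_obs * depth).astype(int)
            pv: dict[str, list[np.ndarray]] = {r: [] for r in REGIMES}
            dr: dict[str, list[np.ndarray]] = {r: [] for r in REGIMES}
            sub = line_params[line_params["background"] == bg]
            for row in sub.itertuples():
                if int(row.t) == 0:
                    # no drift elapsed: nothing can exceed the null
                    pv[row.regime].append(np.ones(snps_per_iteration))
                    dr[row.regime].append(np.zeros(snps_per_iteration, int))
                    continue
                pt = simulate_wf_trajectory(p0s, row.Ne, 0.0, int(row.t), rng)
                obs, _ = sample_poolseq(pt, pool_size, depth, rng)
                rt = np.rint(obs * depth).astype(int)
                p, d = sampling_aware_pvalues(
                    r0, depth, rt, depth, row.Ne, int(row.t), pool_size,
                    seed=rng)
                pv[row.regime].append(p)
                dr[row.regime].append(d)
            calls = classify_snps(pv, dr, per_tail_probability)
            mask = (calls["class"] == snp_class).to_numpy()
            shared = mask if shared is None else (shared & mask)
        counts[it] = int(shared.sum())
    expected = float(counts.mean())
    p = (int(np.sum(counts >= observed)) + 1) / (iterations + 1)
    return OverlapReport(observed=int(observed), expected=expected,
                         pvalue=float(p), iterations=iterations,
                         null_counts=counts)
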