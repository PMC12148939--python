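"""Genomic, phenotypic and fitness offsets, and how well they correlate.

An *offset* measures maladaptation relative to the best-adapted reference
line of a background-regime cell, chosen as the replicate with the highest
laboratory fitness (lifetime adult offspring per couple divided by
egg-to-adult development time) at the temperature it adapted to.

* genomic offset   — ``Sum_SNP |p_ref - p_test| * |s_ref|`` over the
  reference line's candidate SNPs (its smallest 0.1% of p-values by
  default), weighting each frequency difference by the absolute selection
  coefficient estimated in the reference;
* phenotypic offset — Euclidean distance to the reference in the seven
  mean-scaled traits at one assay temperature;
* fitness offset    — the test line's laboratory fitness relative to the
  reference's.

Random-SNP control offsets (uniformly drawn loci, unit weights, since no
selection coefficient is defined for non-candidate loci) benchmark how
much of the predictive signal comes from candidate status.  Correlations
between offsets are reported separately for within- and between-background
test lines, with the group contrast tested by a linear model with a
genomic-offset x group interaction (ANCOVA-style F test).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .core import TRAITS, rng_from

__all__ = [
    "laboratory_fitness",
    "fitness_from_traits",
    "select_reference",
    "reference_candidate_set",
    "genomic_offset",
    "phenotypic_offset",
    "fitness_offset",
    "random_snp_offsets",
    "offset_correlation",
    "build_offset_table",
]


def laboratory_fitness(lrs: float, dev_time: float) -> float:
    """Laboratory-fitness proxy: adult offspring per couple per day.

    ``LRS / dev_time`` approximates the intrinsic population growth rate,
    since egg-to-adult development time is a good proxy for generation
    time under laboratory rearing.
    """
    if dev_time <= 0:
        raise ValueError("dev_time must be > 0")
    if lrs < 0:
        raise ValueError("LRS must be >= 0")
    return lrs / dev_time


def fitness_from_traits(trait_panel: pd.DataFrame, assay_temp: float) -> pd.Series:
    """Per-line laboratory fitness from a long-format trait panel."""
    sub = trait_panel[trait_panel["assay_temp"] == assay_temp]
    wide = sub.pivot_table(index="line_id", columns="trait", values="mean")
    for col in ("lrs", "dev_time"):
        if col not in wide.columns:
            raise ValueError(f"trait panel lacks trait {col!r}")
    fitness = wide["lrs"] / wide["dev_time"]
    fitness.name = "fitness"
    return fitness


def select_reference(fitness: pd.Series) -> tuple[str, bool]:
    """Choose the reference line: the replicate with the highest fitness.

    ``fitness`` maps candidate line ids to laboratory fitness at the local
    temperature.  Exact ties break lexicographically by line id and are
    flagged.  Returns ``(line_id, tie_flag)``.
    """
    if len(fitness) == 0:
        raise ValueError("no candidate lines to choose a reference from")
    best = fitness.max()
    winners = sorted(fitness.index[fitness == best])
    return str(winners[0]), len(winners) > 1


def reference_candidate_set(
    pvalues: pd.Series,
    quantile_fraction: float = 0.001,
    s: pd.Series | None = None,
) -> tuple[pd.Index, pd.Series | None, bool]:
    """Candidate SNPs of a reference line: its smallest p-value quantile.

    Takes the smallest ``quantile_fraction`` of the line's *empirical*
    p-value distribution (the top-0.001th-quantile rule), including ties
    with the cut value (flagged when ties extend the set).  When ``s`` is
    given, the set carries ``|s|`` weights.  Returns
    ``(index, weights, tie_flag)``.
    """
    if not 0 < quantile_fraction < 1:
        raise ValueError("quantile_fraction must lie in (0, 1)")
    if len(pvalues) == 0:
        raise ValueError("empty p-value table")
    k = max(1, int(np.ceil(quantile_fraction * len(pvalues))))
    cut = np.partition(pvalues.to_numpy(), k - 1)[k - 1]
    chosen = pvalues.index[pvalues <= cut]
    tie_flag = len(chosen) > k
    weights = None
    if s is not None:
        weights = s.loc[chosen].abs()
    return chosen, weights, tie_flag


def genomic_offset(ref_freqs: pd.Series, test_freqs: pd.Series,
                   weights: pd.Series) -> float:
    """Weighted L1 distance in allele-frequency space over candidate SNPs."""
    if not ref_freqs.index.equals(test_freqs.index):
        raise ValueError("reference and test lines must share the SNP set "
                         "(same loci, same allele orientation)")
    if not ref_freqs.index.equals(weights.index):
        raise ValueError("weights must cover exactly the shared SNP set")
    return float(np.sum(np.abs(ref_freqs.to_numpy() - test_freqs.to_numpy())
                        * weights.to_numpy()))


def phenotypic_offset(ref_traits, test_traits) -> float:
    """Euclidean distance between two mean-scaled trait vectors."""
    a = np.asarray(ref_traits, float)
    b = np.asarray(test_traits, float)
    if a.shape != b.shape:
        raise ValueError("trait vectors have mismatched dimensions")
    return float(np.linalg.norm(a - b))


def fitness_offset(test_fitness: float, ref_fitness: float) -> float:
    """Relative fitness of a test line: ``fitness_test / fitness_ref``."""
    if ref_fitness <= 0:
        raise ValueError("reference fitness must be > 0")
    return float(test_fitness) / float(ref_fitness)


def random_snp_offsets(
    freqs: pd.DataFrame,
    n: int,
    reference: str,
    test_lines: list[str],
    iterations: int = 100,
    seed=0,
) -> pd.DataFrame:
    """Control genomic offsets from random SNP sets with unit weights.

    Each iteration draws ``n`` loci uniformly without replacement from
    ``freqs`` (loci x samples) and computes the unweighted L1 offset from
    ``reference`` to every test line.  Returns a frame (iteration x test
    line) of control offsets.
    """
    if n > len(freqs):
        raise ValueError("n exceeds the number of available SNPs")
    rng = rng_from(seed)
    ref = freqs[reference].to_numpy()
    tests = {ln: freqs[ln].to_numpy() for ln in test_lines}
    rows = []
    for it in range(iterations):
        # sorted so the summation order (hence the float result) does not
        # depend on the draw order
        take = np.sort(rng.choice(len(freqs), size=n, replace=False))
        rows.append({ln: float(np.sum(np.abs(ref[take] - tests[ln][take])))
                     for ln in test_lines})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class OffsetCorrelation:
    group: str
    n: int
    r_pheno: float | None  # genomic vs phenotypic offset
    r_fit: float | None    # genomic vs fitness offset
    degenerate: bool       # constant genomic offset: r undefined


@dataclass(frozen=True)
class GroupInteractionTest:
    response: str
    F: float
    pvalue: float
    df_num: int
    df_den: int


def _pearson(x: np.ndarray, y: np.ndarray) -> float | None:
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def offset_correlation(
    table: pd.DataFrame,
) -> tuple[list[OffsetCorrelation], dict[str, GroupInteractionTest]]:
    """Per-group offset correlations and the ANCOVA-style group contrast.

    ``table`` needs columns ``genomic``, ``phenotypic``, ``fitness`` and
    ``group`` (within/between background).  Pearson correlations of the
    genomic offset with the phenotypic and fitness offsets are computed
    per group; the within-versus-between contrast is tested by an OLS
    model ``response ~ genomic * group`` and the F test of the
    interaction term (slope difference, covariance adjusted).
    """
    for col in ("genomic", "phenotypic", "fitness", "group"):
        if col not in table.columns:
            raise ValueError(f"offset table lacks column {col!r}")
    correlations = []
    for group, sub in table.groupby("group", sort=False):
        if len(sub) < 3:
            raise ValueError(f"need >= 3 offset points per group, "
                             f"{group!r} has {len(sub)}")
        g = sub["genomic"].to_numpy()
        correlations.append(OffsetCorrelation(
            group=str(group),
            n=len(sub),
            r_pheno=_pearson(g, sub["phenotypic"].to_numpy()),
            r_fit=_pearson(g, sub["fitness"].to_numpy()),
            degenerate=np.std(g) == 0,
        ))
    tests = {}
    if table["group"].nunique() == 2:
        for response in ("phenotypic", "fitness"):
            model = smf.ols(f"{response} ~ genomic * group", data=table).fit()
            name = [c for c in model.params.index if ":" in c]
            ftest = model.f_test(f"{name[0]} = 0")
            tests[response] = GroupInteractionTest(
                response=response,
                F=float(ftest.fvalue),
                pvalue=float(ftest.pvalue),
                df_num=int(ftest.df_num),
                df_den=int(ftest.df_denom),
            )
    return correlations, tests


def build_offset_table(
    references: dict[str, str],
    freqs: pd.DataFrame,
    candidate_sets: dict[str, tuple[pd.Index, pd.Series]],
    trait_vectors: dict[str, np.ndarray],
    fitness: pd.Series,
    background_of: dict[str, str],
) -> pd.DataFrame:
    """Offsets of every test line against every reference.

    ``references`` maps background to its reference line id;
    ``candidate_sets`` maps each reference line to its (loci, |s| weights);
    ``trait_vectors`` holds mean-scaled trait vectors per line at the
    assay temperature of interest; ``fitness`` the laboratory fitness per
    line.  Test lines are all lines present in ``trait_vectors`` other
    than the reference itself; the ``group`` column marks whether test and
    reference share a genetic background.
    """
    rows = []
    for ref_bg, ref in references.items():
        loci, weights = candidate_sets[ref]
        ref_f = freqs.loc[loci, ref]
        for test in trait_vectors:
            if test == ref:
                continue
            rows.append({
                "reference": ref,
                "test": test,
                "group": "within" if background_of[test] == ref_bg else "between",
                "genomic": genomic_offset(ref_f, freqs.loc[loci, test], weights),
                "phenotypic": phenotypic_offset(trait_vectors[ref],
                                                trait_vectors[test]),
                "fitness": fitness_offset(fitness[test], fitness[ref]),
            })
    return pd.DataFrame(rows)
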