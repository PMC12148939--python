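"""Change-vector geometry: angles, divergence, rates, and their null tests.

The same machinery serves trait space (7 mean-scaled life-history traits)
and allele-frequency space (candidate-SNP frequency changes): a change
vector is the difference between an evolved sample and its ancestor, and
repeatability is quantified by pairwise angles

    theta = arccos( a . b / (|a| |b|) )

(0 deg parallel, 90 deg uncorrelated, 180 deg anti-parallel), by
evolutionary rates |a| / t, and by divergence E_d - S_d, the change in the
Euclidean distance between two lineages from the start (between ancestors)
to the end (between evolved lines) of the experiment.

When two change vectors are computed against the *same* measured ancestor,
the shared measurement error inflates their similarity: the observed dot
product gains Sum_i se_i^2 and each observed squared norm gains the same
term.  ``correction="full"`` (default) subtracts the shared-error component
from the numerator and both norms, which is unbiased to second order;
``"numerator"`` subtracts it from the dot product only (biased towards
larger angles); ``"none"`` applies no correction.  When the error exceeds
the signal (a corrected squared norm <= 0, or a corrected cosine outside
[-1, 1] beyond tolerance) the angle is reported as undefined rather than
guessed — the same rule the divergence applies by flooring E_d at zero.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core import REGIMES, rng_from

__all__ = [
    "ChangeVector",
    "AngleResult",
    "DivergenceResult",
    "RateResult",
    "mean_scale_traits",
    "change_vector",
    "evolutionary_rate",
    "pairwise_angle",
    "divergence",
    "ancestor_scale",
    "random_angle_null",
    "permutation_regime_test",
]

@dataclass
class ChangeVector:
    """Per-dimension change values plus the error terms for bias correction."""

    values: np.ndarray
    anc_errors: np.ndarray  # per-dimension ancestor standard errors
    evo_errors: np.ndarray  # per-dimension evolved-line standard errors
    t: int  # generations elapsed
    shared_ancestor_id: str | None = None
    label: str | None = None
    background: str | None = None
    regime: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        self.anc_errors = np.asarray(self.anc_errors, float)
        self.evo_errors = np.asarray(self.evo_errors, float)
        shape = self.values.shape
        if self.anc_errors.shape != shape or self.evo_errors.shape != shape:
            raise ValueError("values and error vectors must share a shape")
        if not (np.all(np.isfinite(self.values))
                and np.all(np.isfinite(self.anc_errors))
                and np.all(np.isfinite(self.evo_errors))):
            raise ValueError("values and errors must be finite")
        if np.any(self.anc_errors < 0) or np.any(self.evo_errors < 0):
            raise ValueError("errors must be >= 0")
        if self.t < 1:
            raise ValueError("t must be >= 1")

    @property
    def dim(self) -> int:
        return self.values.size

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.values))


@dataclass(frozen=True)
class AngleResult:
    theta: float | None  # degrees in [0, 180]; None when undefined
    corrected: bool
    undefined_reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.theta is not None


@dataclass(frozen=True)
class DivergenceResult:
    S_d: float
    E_d: float
    floored: bool  # error correction drove E_d^2 below 0
    scale: float | None = None

    @property
    def div(self) -> float:
        return self.E_d - self.S_d

    @property
    def div_scaled(self) -> float | None:
        if self.scale is None:
            return None
        return self.div / self.scale


@dataclass(frozen=True)
class RateResult:
    raw_rate: float  # |change| per generation
    scaled_rate: float | None  # relative to the dataset maximum


def mean_scale_traits(panel: pd.DataFrame) -> pd.DataFrame:
    """Mean-scale a long-format trait panel to unitless measurements.

    Divides every mean and standard error by the grand mean of the
    ancestral lines for the same trait and assay temperature, so that
    rates of evolution read as proportional change relative to ancestral
    trait means.  The two assay temperatures scale independently.
    """
    required = {"regime", "trait", "assay_temp", "mean", "se"}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"trait panel lacks columns: {sorted(missing)}")
    anc = panel[panel["regime"] == "ancestor"]
    if anc.empty:
        raise ValueError("panel contains no ancestor rows to scale by")
    grand = anc.groupby(["trait", "assay_temp"])["mean"].mean()
    if np.any(grand == 0):
        zeros = grand[grand == 0].index.tolist()
        raise ValueError(f"zero ancestral grand mean for {zeros}")
    out = panel.copy()
    denom = pd.MultiIndex.from_frame(out[["trait", "assay_temp"]]).map(grand)
    denom = np.asarray(denom, float)
    if np.any(~np.isfinite(denom)):
        raise ValueError("trait/assay_temp combination missing from ancestors")
    out["mean"] = out["mean"] / denom
    out["se"] = out["se"] / denom
    return out


def change_vector(
    ancestor_means,
    ancestor_se,
    evolved_means,
    evolved_se,
    t: int,
    shared_ancestor_id: str | None = None,
    **meta,
) -> ChangeVector:
    """Change vector from an ancestral to an evolved sample.

    Errors are carried through unchanged; nothing is combined at this
    stage.  Works identically for 7-trait input and n-SNP frequency input.
    """
    a = np.asarray(ancestor_means, float)
    e = np.asarray(evolved_means, float)
    if a.shape != e.shape:
        raise ValueError("ancestor and evolved dimensions differ")
    return ChangeVector(
        values=e - a,
        anc_errors=np.asarray(ancestor_se, float),
        evo_errors=np.asarray(evolved_se, float),
        t=t,
        shared_ancestor_id=shared_ancestor_id,
        **meta,
    )


def evolutionary_rate(vec: ChangeVector, dataset_max: float | None = None) -> RateResult:
    """Euclidean norm of the change vector per generation.

    ``dataset_max`` (the largest raw rate in the dataset) scales the rate
    onto [0, 1] for cross-line comparison.
    """
    raw = vec.norm / vec.t
    scaled = None if dataset_max is None else raw / dataset_max
    return RateResult(raw_rate=raw, scaled_rate=scaled)


def pairwise_angle(
    a: ChangeVector,
    b: ChangeVector,
    correction: str = "full",
) -> AngleResult:
    """Angle between two change vectors, shared-ancestor error corrected.

    With independent ancestors the cosine is the plain normalized dot
    product.  With a shared ancestor the expected contribution of the
    shared measurement error, ``Sum_i anc_se_i^2``, is subtracted from the
    dot product and (``correction="full"``) from each squared norm.
    Returns an undefined result with reason ``"error exceeds signal"``
    when the correction exhausts a vector's norm or pushes the cosine
    outside [-1, 1].
    """
    if correction not in ("full", "numerator", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    if a.dim != b.dim:
        raise ValueError("change vectors have mismatched dimensions")
    na2 = float(a.values @ a.values)
    nb2 = float(b.values @ b.values)
    if na2 == 0 or nb2 == 0:
        raise ValueError("cannot measure an angle to a zero-length vector")
    dot = float(a.values @ b.values)
    shared = (a.shared_ancestor_id is not None
              and a.shared_ancestor_id == b.shared_ancestor_id)
    apply = shared and correction != "none"
    if not apply:
        cos = dot / np.sqrt(na2 * nb2)
        cos = float(np.clip(cos, -1.0, 1.0))
        return AngleResult(theta=float(np.degrees(np.arccos(cos))), corrected=False)

    err = float(a.anc_errors @ b.anc_errors)
    num = dot - err
    ca2 = na2 - float(a.anc_errors @ a.anc_errors)
    cb2 = nb2 - float(b.anc_errors @ b.anc_errors)
    if ca2 <= 0 or cb2 <= 0:
        return AngleResult(theta=None, corrected=True,
                           undefined_reason="error exceeds signal")
    denom2 = ca2 * cb2 if correction == "full" else na2 * nb2
    cos = num / np.sqrt(denom2)
    if abs(cos) > 1.0 + 1e-6:
        return AngleResult(theta=None, corrected=True,
                           undefined_reason="error exceeds signal")
    cos = float(np.clip(cos, -1.0, 1.0))
    return AngleResult(theta=float(np.degrees(np.arccos(cos))), corrected=True)


def divergence(
    ancestor_a,
    ancestor_b,
    evolved_a: ChangeVector | np.ndarray,
    evolved_b: ChangeVector | np.ndarray,
    *,
    evolved_a_se=None,
    evolved_b_se=None,
    shared_ancestor: bool = False,
    scale: float | None = None,
) -> DivergenceResult:
    """Convergence/divergence of two lineages: Div = E_d - S_d.

    ``S_d`` is the Euclidean distance between the two ancestors and
    ``E_d`` the distance between the two evolved lines.  When the evolved
    lines share one measured ancestor, within-pair distances are inflated
    by measurement error, and the error term ``Sum_i (ae_i^2 + be_i^2)``
    is subtracted under the square root; a negative corrected square is
    floored at zero and flagged.  ``scale`` (typically the distance
    between the two most differentiated ancestors, see
    :func:`ancestor_scale`) yields ``div_scaled``.

    The evolved endpoints may be passed either as absolute positions
    (arrays, with ``evolved_*_se``) or as :class:`ChangeVector` objects,
    in which case positions are ``ancestor + values`` and the evolved
    standard errors are taken from the vectors.
    """
    anc_a = np.asarray(ancestor_a, float)
    anc_b = np.asarray(ancestor_b, float)
    if isinstance(evolved_a, ChangeVector):
        evo_a = anc_a + evolved_a.values
        se_a = evolved_a.evo_errors
    else:
        evo_a = np.asarray(evolved_a, float)
        se_a = np.zeros_like(evo_a) if evolved_a_se is None else np.asarray(evolved_a_se, float)
    if isinstance(evolved_b, ChangeVector):
        evo_b = anc_b + evolved_b.values
        se_b = evolved_b.evo_errors
    else:
        evo_b = np.asarray(evolved_b, float)
        se_b = np.zeros_like(evo_b) if evolved_b_se is None else np.asarray(evolved_b_se, float)
    if not (anc_a.shape == anc_b.shape == evo_a.shape == evo_b.shape):
        raise ValueError("dimension mismatch between ancestors and evolved lines")

    S_d = float(np.linalg.norm(anc_a - anc_b))
    e2 = float(np.sum((evo_a - evo_b) ** 2))
    floored = False
    if shared_ancestor:
        e2 -= float(np.sum(se_a ** 2) + np.sum(se_b ** 2))
        if e2 < 0:
            e2 = 0.0
            floored = True
    E_d = float(np.sqrt(e2))
    return DivergenceResult(S_d=S_d, E_d=E_d, floored=floored, scale=scale)


def ancestor_scale(ancestors: Sequence[np.ndarray]) -> float:
    """Distance between the two most differentiated ancestors."""
    ancestors = [np.asarray(a, float) for a in ancestors]
    if len(ancestors) < 2:
        raise ValueError("need at least two ancestors to compute a scale")
    best = 0.0
    for i in range(len(ancestors)):
        for j in range(i + 1, len(ancestors)):
            best = max(best, float(np.linalg.norm(ancestors[i] - ancestors[j])))
    if best == 0:
        raise ValueError("all ancestors are identical: scale undefined")
    return best


@dataclass(frozen=True)
class NullTestResult:
    observed: float
    null_mean: float
    null_sd: float
    pvalue: float
    iterations: int


def random_angle_null(
    dim: int,
    n_pairs: int,
    iterations: int = 100_000,
    seed=0,
    observed_mean: float | None = None,
) -> NullTestResult | np.ndarray:
    """Monte-Carlo null of mean pairwise angles between random directions.

    Each iteration draws ``n_pairs`` independent pairs of isotropic unit
    vectors in ``dim`` dimensions (standard-normal components, normalized)
    and records the mean pairwise angle.  With ``observed_mean`` given,
    returns the two-sided tail probability of the observed mean under the
    null (with the (k+1)/(n+1) correction); otherwise returns the null
    sample itself.
    """
    if dim < 2:
        raise ValueError("dim must be >= 2")
    if iterations < 1000:
        raise ValueError("iterations must be >= 1000")
    rng = rng_from(seed)
    # cosine of the angle between two isotropic unit vectors, per pair
    means = np.empty(iterations)
    chunk = max(1, int(2e6 // max(n_pairs, 1)))
    done = 0
    while done < iterations:
        m = min(chunk, iterations - done)
        u = rng.normal(size=(m, n_pairs, 2, dim))
        u /= np.linalg.norm(u, axis=-1, keepdims=True)
        cos = np.einsum("ipd,ipd->ip", u[:, :, 0, :], u[:, :, 1, :])
        ang = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
        means[done:done + m] = ang.mean(axis=1)
        done += m
    if observed_mean is None:
        return means
    k_low = int(np.sum(means <= observed_mean))
    k_high = int(np.sum(means >= observed_mean))
    p = 2.0 * (min(k_low, k_high) + 1) / (iterations + 1)
    return NullTestResult(
        observed=float(observed_mean),
        null_mean=float(means.mean()),
        null_sd=float(means.std(ddof=1)),
        pvalue=float(min(p, 1.0)),
        iterations=iterations,
    )


def _pair_stat_matrix(
    vectors: Sequence[ChangeVector],
    pair_stat: Callable[[ChangeVector, ChangeVector], float | None],
) -> np.ndarray:
    """Precomputed symmetric matrix of pairwise statistics (NaN = undefined)."""
    n = len(vectors)
    M = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            v = pair_stat(vectors[i], vectors[j])
            if v is not None:
                M[i, j] = M[j, i] = v
    return M


def permutation_regime_test(
    vectors: Sequence[ChangeVector],
    statistic: str = "angle",
    iterations: int = 1000,
    seed=0,
    *,
    correction: str = "full",
    pair_stat: Callable[[ChangeVector, ChangeVector], float | None] | None = None,
) -> NullTestResult:
    """Permutation test for a hot-versus-cold difference in repeatability.

    The observed statistic is ``mean(stat among hot lines) - mean(stat
    among cold lines)``, where the statistic is the pairwise angle
    (``statistic="angle"``), the per-line evolutionary rate (``"rate"``),
    or any custom pairwise callable (``pair_stat``, e.g. a divergence
    closure).  The null permutes regime labels across lines *within each
    genetic background*, preserving the background structure; pairwise
    statistics are precomputed once, since relabeling does not change
    them.  Two-sided p with the (k+1)/(n+1) correction.
    """
    regs = [v.regime for v in vectors]
    if any(r not in REGIMES for r in regs):
        raise ValueError("every vector needs a regime label of 'cold' or 'hot'")
    for regime in REGIMES:
        if sum(r == regime for r in regs) < 2:
            raise ValueError(f"need >= 2 lines per regime, lacking {regime!r}")
    rng = rng_from(seed)
    labels = np.asarray(regs)
    backgrounds = np.asarray([v.background or "" for v in vectors])

    if statistic == "rate":
        per_line = np.array([evolutionary_rate(v).raw_rate for v in vectors])

        def stat_for(lab: np.ndarray) -> float:
            return float(per_line[lab == "hot"].mean() - per_line[lab == "cold"].mean())
    elif statistic in ("angle", "custom"):
        if statistic == "angle":
            def pair_stat_fn(x, y):
                r = pairwise_angle(x, y, correction=correction)
                return r.theta
        else:
            if pair_stat is None:
                raise ValueError("statistic='custom' requires pair_stat")
            pair_stat_fn = pair_stat
        M = _pair_stat_matrix(vectors, pair_stat_fn)

        def group_mean(lab: np.ndarray, regime: str) -> float:
            idx = np.flatnonzero(lab == regime)
            sub = M[np.ix_(idx, idx)]
            vals = sub[np.triu_indices(len(idx), k=1)]
            vals = vals[~np.isnan(vals)]
            if len(vals) == 0:
                return np.nan
            return float(vals.mean())

        def stat_for(lab: np.ndarray) -> float:
            return group_mean(lab, "hot") - group_mean(lab, "cold")
    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    observed = stat_for(labels)
    if np.isnan(observed):
        raise ValueError("observed statistic undefined for these vectors")
    null = np.empty(iterations)
    for it in range(iterations):
        perm = labels.copy()
        for bg in np.unique(backgrounds):
            idx = np.flatnonzero(backgrounds == bg)
            perm[idx] = perm[idx[rng.permutation(len(idx))]]
        null[it] = stat_for(perm)
    valid = null[~np.isnan(null)]
    k = int(np.sum(np.abs(valid) >= abs(observed)))
    p = (k + 1) / (len(valid) + 1)
    return NullTestResult(
        observed=float(observed),
        null_mean=float(valid.mean()),
        null_sd=float(valid.std(ddof=1)) if len(valid) > 1 else 0.0,
        pvalue=float(p),
        iterations=len(valid),
    )
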