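"""Co-occurrence network inference core.

The significance scheme follows the resampling ("ReBoot") logic: for each
candidate ESV pair and each association measure (Spearman rank correlation
and Bray-Curtis similarity), a permutation null distribution and a bootstrap
distribution of the score are generated (default 1000 iterations each); the
p-value is the two-sided Gaussian tail probability of the null mean under a
normal fitted to the bootstrap mean and standard deviation.  Permutations
for the Spearman measure include a renormalization step: after shuffling the
pair's counts, relative abundances are recomputed against the perturbed
sample totals, so the null preserves the compositional structure of the
data.  The two measure-specific p-values are merged with Brown's method
(scaled chi-square with empirically estimated covariance of the log
p-values), adjusted with Benjamini-Hochberg, and edges are retained only
when the adjusted merged p-value passes, both measures individually support
the edge, and the scores exceed random-matrix-theory (RMT) thresholds.
Network deconvolution (alpha=1, beta=0.9) annotates each retained edge with
its indirect-association-corrected score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from coocnet.io_model import AbundanceTable, CooccurrenceNetwork, UNCLASSIFIED

__all__ = [
    "InferenceConfig",
    "EdgeCandidate",
    "RmtResult",
    "spearman_score",
    "braycurtis_similarity",
    "spearman_matrix",
    "braycurtis_matrix",
    "permutation_null",
    "bootstrap_distribution",
    "reboot_pvalue",
    "browns_merge",
    "empirical_brown_covariance",
    "bh_adjust",
    "rmt_threshold",
    "both_measure_support",
    "deconvolve",
    "infer_environment_network",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class DeconvolutionParams:
    alpha: float = 1.0   # fraction of edges kept
    beta: float = 0.9    # eigenvalue scaling target

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        if not 0.0 < self.beta < 1.0:
            raise ValueError("beta must be in (0, 1)")


@dataclass
class InferenceConfig:
    """Tunable parameters of :func:`infer_environment_network`."""

    n_iter: int = 1000
    fdr_alpha: float = 0.05
    rmt_start: float = 0.30
    rmt_stop: float = 0.95
    rmt_step: float = 0.01
    rmt_bins: int = 30
    rmt_crit_level: float = 0.001
    rmt_fallback: float | None = None       # None -> scan start
    deconvolution: DeconvolutionParams = field(default_factory=DeconvolutionParams)
    seed: int = 0
    exhaustive: bool = False                # force resampling p for every pair
    renormalize: bool = True                # renormalized Spearman permutations


# ---------------------------------------------------------------------------
# association measures
# ---------------------------------------------------------------------------

def _rowwise_spearman(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Spearman rho for each row pair of two equally shaped (m, n) arrays."""
    rx = stats.rankdata(x, axis=-1).astype(float)
    ry = stats.rankdata(y, axis=-1).astype(float)
    rx -= rx.mean(axis=-1, keepdims=True)
    ry -= ry.mean(axis=-1, keepdims=True)
    num = (rx * ry).sum(axis=-1)
    den = np.sqrt((rx ** 2).sum(axis=-1) * (ry ** 2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return out


def spearman_score(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns ``nan`` (undefined marker) when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    return float(_rowwise_spearman(x[None, :], y[None, :])[0])


def _rowwise_bc(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    num = np.abs(x - y).sum(axis=-1)
    den = (x + y).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, 1.0 - num / np.where(den > 0, den, 1.0), np.nan)


def braycurtis_similarity(x: Sequence[float], y: Sequence[float]) -> float:
    """Bray-Curtis similarity 1 - sum|x-y| / sum(x+y) on non-negative vectors.

    Returns ``nan`` when both vectors are all-zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("need two equal-length vectors")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("Bray-Curtis requires non-negative entries")
    return float(_rowwise_bc(x[None, :], y[None, :])[0])


def spearman_matrix(rel: np.ndarray) -> np.ndarray:
    """Pairwise Spearman correlation matrix over rows (nan for constant rows)."""
    ranks = stats.rankdata(rel, axis=1).astype(float)
    sd = ranks.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(ranks)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, 1.0)
    return corr


def braycurtis_matrix(rel: np.ndarray) -> np.ndarray:
    """Pairwise Bray-Curtis similarity matrix over rows (unit diagonal)."""
    if rel.shape[0] < 2:
        return np.ones((rel.shape[0], rel.shape[0]))
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = 1.0 - squareform(pdist(rel, metric="braycurtis"))
    np.fill_diagonal(sim, 1.0)
    return sim


# ---------------------------------------------------------------------------
# resampling distributions
# ---------------------------------------------------------------------------

def _pair_rows(table: AbundanceTable, pair: tuple[str, str]) -> tuple[int, int]:
    index = {e: i for i, e in enumerate(table.esv_ids)}
    try:
        return index[pair[0]], index[pair[1]]
    except KeyError as exc:
        raise KeyError(f"pair ESV {exc.args[0]!r} not in table") from None


def _pair_rng(seed: int, i: int, j: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF,
                               spawn_key=(i, j, stream))
    )


def permutation_null(
    table: AbundanceTable,
    pair: tuple[str, str],
    measure: str = "spearman",
    n_iter: int = 1000,
    renormalize: bool = True,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Permutation null distribution of a pair's association score.

    Each iteration independently shuffles the two ESVs' counts across
    samples.  With ``renormalize`` (required for the Spearman measure, to
    counter compositionality bias), relative abundances are recomputed
    against the perturbed per-sample totals before scoring; otherwise the
    pair's relative-abundance profiles are shuffled directly.
    """
    if n_iter <= 0:
        raise ValueError("n_iter must be positive")
    i, j = _pair_rows(table, pair)
    if rng is None:
        rng = _pair_rng(seed, i, j, stream=0)
    counts_i = table.counts[i].astype(float)
    counts_j = table.counts[j].astype(float)
    totals = table.counts.sum(axis=0).astype(float)

    if renormalize:
        perm_i = rng.permuted(np.tile(counts_i, (n_iter, 1)), axis=1)
        perm_j = rng.permuted(np.tile(counts_j, (n_iter, 1)), axis=1)
        new_totals = totals[None, :] - counts_i - counts_j + perm_i + perm_j
        safe = np.where(new_totals > 0, new_totals, 1.0)
        prof_i, prof_j = perm_i / safe, perm_j / safe
    else:
        # plain shuffle of the pair's relative-abundance profiles; dividing
        # permuted counts by the fixed per-sample totals would couple the
        # two profiles through the shared denominator
        safe = np.where(totals > 0, totals, 1.0)
        prof_i = rng.permuted(np.tile(counts_i / safe, (n_iter, 1)), axis=1)
        prof_j = rng.permuted(np.tile(counts_j / safe, (n_iter, 1)), axis=1)
    if measure == "spearman":
        return _rowwise_spearman(prof_i, prof_j)
    if measure == "bc":
        return _rowwise_bc(prof_i, prof_j)
    raise ValueError(f"unknown measure: {measure!r}")


def bootstrap_distribution(
    table: AbundanceTable,
    pair: tuple[str, str],
    measure: str = "spearman",
    n_iter: int = 1000,
    seed: int = 0,
    rng: np.random.Generator | None = None,
    max_retries: int = 10,
) -> np.ndarray:
    """Bootstrap distribution of a pair's score (resample samples with replacement).

    Iterations whose resample has fewer than 3 distinct samples are redrawn
    (at most ``max_retries`` times) so the measure stays defined.
    """
    if n_iter <= 0:
        raise ValueError("n_iter must be positive")
    n = table.n_samples
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")
    i, j = _pair_rows(table, pair)
    if rng is None:
        rng = _pair_rng(seed, i, j, stream=1)
    rel = table.relative_abundance()
    rel_i, rel_j = rel[i], rel[j]

    idx = rng.integers(0, n, size=(n_iter, n))
    for _ in range(max_retries):
        distinct = np.array([len(np.unique(row)) for row in idx])
        bad = distinct < 3
        if not bad.any():
            break
        idx[bad] = rng.integers(0, n, size=(int(bad.sum()), n))
    if measure == "spearman":
        return _rowwise_spearman(rel_i[idx], rel_j[idx])
    if measure == "bc":
        return _rowwise_bc(rel_i[idx], rel_j[idx])
    raise ValueError(f"unknown measure: {measure!r}")


def reboot_pvalue(null_values: np.ndarray, boot_values: np.ndarray) -> float:
    """Two-sided Gaussian-tail p-value of the null mean under the bootstrap fit.

    ``z = (mean(null) - mean(boot)) / sd(boot)``; ``p = 2 (1 - Phi(|z|))``.
    Degenerate bootstrap (sd = 0): p = 1 when the means coincide, else 0.
    """
    null_values = np.asarray(null_values, dtype=float)
    boot_values = np.asarray(boot_values, dtype=float)
    null_mean = float(np.nanmean(null_values))
    boot_mean = float(np.nanmean(boot_values))
    boot_sd = float(np.nanstd(boot_values, ddof=1))
    if boot_sd == 0.0:
        return 1.0 if null_mean == boot_mean else 0.0
    z = (null_mean - boot_mean) / boot_sd
    return float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# p-value merging and adjustment
# ---------------------------------------------------------------------------

_P_FLOOR = 1e-300


def browns_merge(p1: float, p2: float, covariance: float = 0.0) -> float:
    """Brown's method for two dependent p-values.

    ``T = -2(ln p1 + ln p2)`` is referred to a scaled chi-square whose scale
    and degrees of freedom are matched to ``E[T] = 4`` and
    ``Var[T] = 8 + 2 cov(-2 ln p1, -2 ln p2)``.  With zero covariance this is
    exactly Fisher's method.
    """
    covariance = float(np.clip(covariance, 0.0, 4.0))
    p1 = max(float(p1), _P_FLOOR)
    p2 = max(float(p2), _P_FLOOR)
    if not (p1 <= 1.0 and p2 <= 1.0):
        raise ValueError("p-values must be in (0, 1]")
    t = -2.0 * (math.log(p1) + math.log(p2))
    expected = 4.0
    variance = 8.0 + 2.0 * covariance
    scale = variance / (2.0 * expected)
    df = 2.0 * expected ** 2 / variance
    return float(stats.chi2.sf(t / scale, df))


def empirical_brown_covariance(p1s: Sequence[float], p2s: Sequence[float]) -> float:
    """Covariance of (-2 ln p1, -2 ln p2) across tested pairs, clamped to [0, 4]."""
    p1s = np.clip(np.asarray(p1s, dtype=float), _P_FLOOR, 1.0)
    p2s = np.clip(np.asarray(p2s, dtype=float), _P_FLOOR, 1.0)
    if p1s.size < 2:
        return 0.0
    cov = float(np.cov(-2.0 * np.log(p1s), -2.0 * np.log(p2s))[0, 1])
    return float(np.clip(cov, 0.0, 4.0))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# random-matrix-theory threshold
# ---------------------------------------------------------------------------

@dataclass
class RmtResult:
    threshold: float
    trace: list[tuple[float, float]]
    fallback_used: bool = False


def _unfolded_spacings(eigenvalues: np.ndarray, degree: int = 5) -> np.ndarray:
    """Unfold a spectrum via a polynomial fit of the cumulative density.

    Duplicate eigenvalues must already be removed.  The fitted cumulative
    spectral function is forced monotone, and spacings are normalized to
    unit mean.
    """
    e = np.sort(eigenvalues)
    n = e.size
    cdf = np.arange(1, n + 1) / n
    deg = min(degree, n - 1)
    coeffs = np.polyfit(e, cdf, deg)
    smooth = np.polyval(coeffs, e) * n
    smooth = np.maximum.accumulate(smooth)
    spacings = np.diff(smooth)
    mean = spacings.mean()
    return spacings / mean if mean > 0 else spacings


def _nnsd_chi2(spacings: np.ndarray, bins: int) -> tuple[float, float, int]:
    """Binned chi-square of spacings vs the Poisson and GOE (Wigner) laws.

    Bins are equal-probability under the law being tested, so expected
    counts are uniform; the bin count adapts to the spacing sample size
    (about 5 spacings per bin, at least 5 bins, at most ``bins``) to keep
    the statistic calibrated on small spectra.  Returns
    ``(chi2_poisson, chi2_goe, bins_used)``.
    """
    n = spacings.size
    bins_used = int(min(bins, max(5, n // 5)))
    qs = np.linspace(0.0, 1.0, bins_used + 1)[1:-1]
    expected = n / bins_used

    def chi2_stat(edges_interior: np.ndarray) -> float:
        edges = np.concatenate([[0.0], edges_interior, [np.inf]])
        observed, _ = np.histogram(spacings, bins=edges)
        return float(((observed - expected) ** 2 / expected).sum())

    poisson_edges = -np.log1p(-qs)                       # inverse of 1 - e^-s
    goe_edges = np.sqrt(-4.0 * np.log1p(-qs) / np.pi)    # inverse Wigner CDF
    return chi2_stat(poisson_edges), chi2_stat(goe_edges), bins_used


def rmt_threshold(
    score_matrix: np.ndarray,
    start: float = 0.30,
    stop: float = 0.95,
    step: float = 0.01,
    bins: int = 30,
    crit_level: float = 0.001,
    fallback: float | None = None,
    min_eigenvalues: int = 10,
) -> RmtResult:
    """Scan for the score threshold where the spectrum turns Poisson.

    For each candidate threshold ``t`` entries with ``|score| < t`` are
    zeroed, the eigenvalue nearest-neighbor spacing distribution (NNSD) of
    the thresholded matrix is computed (after deduplication and polynomial
    unfolding), and its fit to the Poisson law ``exp(-s)`` is compared with
    the Wigner-Dyson (GOE) law by binned chi-square.  The returned threshold
    is the smallest ``t`` at which the Poisson law fits better than GOE and
    the Poisson chi-square is below the critical value (``df = bins - 1`` at
    ``crit_level``).  A thresholded matrix with no off-diagonal entries left
    has trivially uncorrelated spectrum and qualifies immediately.  When no
    ``t`` qualifies, the configured fallback (default: scan start) is
    returned with ``fallback_used=True``.
    """
    m = np.asarray(score_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("score matrix must be square")
    if not np.allclose(m, m.T, atol=1e-10, equal_nan=True):
        raise ValueError("score matrix must be symmetric")
    m = np.nan_to_num(m, nan=0.0)
    trace: list[tuple[float, float]] = []
    thresholds = np.arange(start, stop + step / 2.0, step)
    for k, t in enumerate(thresholds):
        thresholded = np.where(np.abs(m) >= t, m, 0.0)
        np.fill_diagonal(thresholded, 1.0)
        off = thresholded - np.diag(np.diag(thresholded))
        if not np.any(off):
            if k == 0:
                # no off-diagonal signal at all: trivially uncorrelated
                trace.append((float(t), 0.0))
                return RmtResult(float(t), trace)
            break  # spectrum exhausted mid-scan without a qualifying t
        eigs = np.linalg.eigvalsh(thresholded)
        uniq = np.unique(np.round(eigs, 8))
        if uniq.size < min_eigenvalues:
            trace.append((float(t), float("nan")))
            continue
        spacings = _unfolded_spacings(uniq)
        chi_poisson, chi_goe, bins_used = _nnsd_chi2(spacings, bins)
        trace.append((float(t), chi_poisson))
        crit = stats.chi2.isf(crit_level, df=bins_used - 1)
        if chi_poisson < chi_goe and chi_poisson < crit:
            return RmtResult(float(t), trace)
    return RmtResult(float(start if fallback is None else fallback), trace,
                     fallback_used=True)


# ---------------------------------------------------------------------------
# edge candidates, support rule, deconvolution
# ---------------------------------------------------------------------------

@dataclass
class EdgeCandidate:
    key: tuple[str, str]
    rho: float
    bc_sim: float
    p_spearman: float = 1.0
    p_bc: float = 1.0
    p_merged: float = 1.0
    p_adjusted: float = 1.0
    p_spearman_adj: float = 1.0
    p_bc_adj: float = 1.0
    retained: bool = False

    @property
    def sign(self) -> int:
        return 1 if self.rho > 0 else (-1 if self.rho < 0 else 0)


def both_measure_support(
    cand: EdgeCandidate,
    rho_threshold: float,
    bc_threshold: float,
    alpha: float = 0.05,
) -> bool:
    """True iff both measures back the edge.

    Requires ``|rho| >= rho_threshold``, per-measure adjusted significance at
    ``alpha`` for both measures, and the Bray-Curtis criterion: similarity at
    least ``bc_threshold`` for positive edges, or at most
    ``1 - bc_threshold`` (strong dissimilarity, i.e. mutual exclusion) for
    negative edges.
    """
    if not np.isfinite(cand.rho) or cand.rho == 0 or not np.isfinite(cand.bc_sim):
        return False
    if abs(cand.rho) < rho_threshold:
        return False
    if cand.rho > 0:
        if cand.bc_sim < bc_threshold:
            return False
    else:
        if cand.bc_sim > 1.0 - bc_threshold:
            return False
    return cand.p_spearman_adj <= alpha and cand.p_bc_adj <= alpha


def deconvolve(score_matrix: np.ndarray,
               params: DeconvolutionParams | None = None) -> np.ndarray:
    """Network deconvolution: remove transitive (indirect) association weight.

    The observed matrix is linearly scaled so that its extreme eigenvalues
    respect the beta bound (largest positive eigenvalue maps to
    ``beta/(1-beta)``), then every eigenvalue is transformed
    ``lambda -> lambda / (1 + lambda)`` and the matrix reconstructed.  With
    ``alpha = 1`` every entry is retained; ``alpha < 1`` zeroes all but the
    top-alpha fraction of entries by observed magnitude before deconvolution.
    """
    params = params or DeconvolutionParams()
    g = np.asarray(score_matrix, dtype=float).copy()
    if g.ndim != 2 or g.shape[0] != g.shape[1]:
        raise ValueError("score matrix must be square")
    if not np.allclose(g, g.T, atol=1e-10):
        raise ValueError("score matrix must be symmetric")
    np.fill_diagonal(g, 0.0)
    if params.alpha < 1.0:
        iu = np.triu_indices_from(g, k=1)
        mags = np.abs(g[iu])
        nonzero = mags[mags > 0]
        if nonzero.size:
            cutoff = np.quantile(nonzero, 1.0 - params.alpha)
            g[np.abs(g) < cutoff] = 0.0
            g = np.triu(g, 1) + np.triu(g, 1).T
    if not np.any(g):
        return g
    eigs = np.linalg.eigvalsh(g)
    lam_pos = max(float(eigs.max()), 0.0)
    lam_neg = abs(min(float(eigs.min()), 0.0))
    beta = params.beta
    m = max(lam_pos * (1.0 - beta) / beta, lam_neg * (1.0 + beta) / beta)
    if m <= 0:
        return g
    vals, vecs = np.linalg.eigh(g / m)
    direct = (vecs * (vals / (1.0 + vals))) @ vecs.T
    return (direct + direct.T) / 2.0


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def infer_environment_network(
    table: AbundanceTable,
    config: InferenceConfig | None = None,
    taxonomy: Mapping[str, Sequence[str]] | None = None,
    environment: str | None = None,
) -> CooccurrenceNetwork:
    """Infer the co-occurrence network of one environment's count table.

    Orchestrates: relative abundances -> pairwise Spearman and Bray-Curtis
    score matrices -> RMT thresholds per measure -> permutation/bootstrap
    p-values per candidate pair and measure -> Brown's merge -> BH
    adjustment -> retention (adjusted p and both-measure support) -> network
    deconvolution annotation.  By default the resampling machinery runs only
    for pairs whose scores pass the RMT thresholds; since retention requires
    passing those thresholds anyway, the retained edge set is unchanged, and
    all other pairs enter the BH step with p = 1.  Set
    ``config.exhaustive=True`` to force resampling for every pair.

    A provenance log of per-stage counts is stored in
    ``net.graph.graph["provenance"]``.
    """
    config = config or InferenceConfig()
    if environment is None:
        envs = {table.environment_of[s] for s in table.sample_ids
                if s in table.environment_of}
        environment = envs.pop() if len(envs) == 1 else "environment"
    if table.n_samples < 3:
        raise ValueError("need at least 3 samples for network inference")

    rel = table.relative_abundance()
    nonconstant = np.array([len(np.unique(row)) > 1 for row in rel])
    n = table.n_esvs

    rho_mat = spearman_matrix(rel)
    bc_mat = braycurtis_matrix(rel)

    rmt_kwargs = dict(start=config.rmt_start, stop=config.rmt_stop,
                      step=config.rmt_step, bins=config.rmt_bins,
                      crit_level=config.rmt_crit_level,
                      fallback=config.rmt_fallback)
    rho_rmt = rmt_threshold(np.abs(np.nan_to_num(rho_mat)), **rmt_kwargs)
    bc_rmt = rmt_threshold(bc_mat, **rmt_kwargs)
    rho_thr, bc_thr = rho_rmt.threshold, bc_rmt.threshold

    pairs: list[tuple[int, int]] = [
        (i, j) for i in range(n) for j in range(i + 1, n)
        if nonconstant[i] and nonconstant[j]
    ]
    candidates: dict[tuple[int, int], EdgeCandidate] = {}
    tested: list[tuple[int, int]] = []
    for i, j in pairs:
        rho = float(rho_mat[i, j])
        bc = float(bc_mat[i, j])
        if not np.isfinite(rho) or not np.isfinite(bc):
            continue
        score_pass = abs(rho) >= rho_thr and (
            bc >= bc_thr if rho > 0 else bc <= 1.0 - bc_thr
        )
        if config.exhaustive or score_pass:
            tested.append((i, j))
        candidates[(i, j)] = EdgeCandidate(
            key=(table.esv_ids[i], table.esv_ids[j]), rho=rho, bc_sim=bc
        )

    for i, j in tested:
        cand = candidates[(i, j)]
        pair = cand.key
        rng_perm = _pair_rng(config.seed, i, j, stream=0)
        rng_boot = _pair_rng(config.seed, i, j, stream=1)
        null_s = permutation_null(table, pair, "spearman", config.n_iter,
                                  renormalize=config.renormalize, rng=rng_perm)
        null_b = permutation_null(table, pair, "bc", config.n_iter,
                                  renormalize=False, rng=rng_perm)
        boot_s = bootstrap_distribution(table, pair, "spearman", config.n_iter,
                                        rng=rng_boot)
        boot_b = bootstrap_distribution(table, pair, "bc", config.n_iter,
                                        rng=rng_boot)
        cand.p_spearman = reboot_pvalue(null_s, boot_s)
        cand.p_bc = reboot_pvalue(null_b, boot_b)

    cov = empirical_brown_covariance(
        [candidates[p].p_spearman for p in tested],
        [candidates[p].p_bc for p in tested],
    )
    for i, j in tested:
        cand = candidates[(i, j)]
        cand.p_merged = browns_merge(cand.p_spearman, cand.p_bc, cov)

    order = sorted(candidates)
    merged_adj = bh_adjust([candidates[p].p_merged for p in order])
    spearman_adj = bh_adjust([candidates[p].p_spearman for p in order])
    bc_adj = bh_adjust([candidates[p].p_bc for p in order])
    for k, p in enumerate(order):
        cand = candidates[p]
        cand.p_adjusted = float(merged_adj[k])
        cand.p_spearman_adj = float(spearman_adj[k])
        cand.p_bc_adj = float(bc_adj[k])
        cand.retained = (
            cand.p_adjusted <= config.fdr_alpha
            and both_measure_support(cand, rho_thr, bc_thr, config.fdr_alpha)
        )

    retained = [candidates[p] for p in order if candidates[p].retained]

    # deconvolution annotation on the retained signed score matrix
    direct_mat = np.zeros((n, n))
    if retained:
        obs = np.zeros((n, n))
        index = {e: i for i, e in enumerate(table.esv_ids)}
        for cand in retained:
            i, j = index[cand.key[0]], index[cand.key[1]]
            obs[i, j] = obs[j, i] = cand.rho
        direct_mat = deconvolve(obs, config.deconvolution)
        if config.deconvolution.alpha < 1.0:
            keep_n = max(1, int(round(len(retained) * config.deconvolution.alpha)))
            retained = sorted(retained, key=lambda c: -abs(c.rho))[:keep_n]

    mean_abund = table.mean_relative_abundance()
    net = CooccurrenceNetwork(environment=environment)
    index = {e: i for i, e in enumerate(table.esv_ids)}
    for cand in retained:
        for esv in cand.key:
            if esv not in net.graph:
                lineage = (taxonomy or {}).get(esv)
                net.add_vertex(
                    esv,
                    taxonomy=";".join(lineage) if lineage else UNCLASSIFIED,
                    mean_abundance=mean_abund.get(esv, 0.0),
                    environments=(environment,),
                )
        i, j = index[cand.key[0]], index[cand.key[1]]
        net.add_edge(
            cand.key[0], cand.key[1],
            sign=cand.sign, rho=cand.rho, bc_sim=cand.bc_sim,
            p_spearman=cand.p_spearman, p_bc=cand.p_bc,
            p_merged=cand.p_merged, p_adjusted=cand.p_adjusted,
            direct_score=float(direct_mat[i, j]),
            environments=(environment,),
        )
    net.finalize()
    net.graph.graph["provenance"] = {
        "environment": environment,
        "n_esvs": n,
        "n_samples": table.n_samples,
        "n_constant_esvs_excluded": int((~nonconstant).sum()),
        "n_pairs": len(pairs),
        "n_pairs_scored": len(candidates),
        "n_pairs_resampled": len(tested),
        "rho_threshold": rho_thr,
        "bc_threshold": bc_thr,
        "rho_threshold_fallback": rho_rmt.fallback_used,
        "bc_threshold_fallback": bc_rmt.fallback_used,
        "brown_covariance": cov,
        "n_edges_retained": net.n_edges,
    }
    return net
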