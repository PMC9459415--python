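"""Count quantification and differential statistics.

Regions (gene bodies, consensus peaks, promoters) are quantified into an
integer region x sample count matrix.  Differential analysis uses a
deliberately transparent negative-binomial framework:

* size factors by the median-of-ratios definition (per sample, the median
  over all-positive rows of count / row geometric mean, rescaled to
  geometric mean 1);
* a two-group NB Wald test — per-region method-of-moments dispersion shared
  between groups, delta-method standard error of the log2 fold change,
  two-sided normal p-value;
* a one-factor NB likelihood-ratio test for >= 3 conditions — full model
  with one mean per condition versus a single shared mean, chi-square
  reference with (levels - 1) degrees of freedom;
* Benjamini-Hochberg step-up adjustment, significance at FDR < 0.05.

There is no dispersion shrinkage, outlier filtering or independent
filtering: the tests are calibrated stand-ins chosen for auditability, not a
re-implementation of any particular release of a differential-expression
package.

Trajectory clustering follows the divisive (DIANA) scheme on a Kendall
rank-correlation distance: d(g, h) = 1 - tau_b(profile_g, profile_h),
so genes with concordant trajectories across conditions sit close together
regardless of amplitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .density import DensityTrack, Position
from .regions import GenomicInterval

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8


@dataclass
class CountMatrix:
    """Integer counts (regions x samples) plus the sample -> condition map."""

    counts: pd.DataFrame
    conditions: dict[str, str]

    def __post_init__(self):
        missing = set(self.counts.columns) - set(self.conditions)
        if missing:
            raise ValueError(f"samples without condition: {sorted(missing)}")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")


# ---------------------------------------------------------------------------
# Quantification
# ---------------------------------------------------------------------------

def count_reads_in_regions(
    sample_data: Mapping[str, object],
    regions: Sequence[GenomicInterval],
    region_ids: Sequence[str],
    conditions: Mapping[str, str],
    mode: str = "five_prime_sense",
) -> CountMatrix:
    """Quantify regions into a count matrix.

    mode='five_prime_sense': each sample is a raw-count stranded
    :class:`DensityTrack` (or an iterable of (chrom, pos, strand) tuples);
    the count is the number of sense 5' ends inside the region.

    mode='fragment_overlap': each sample is an iterable of fragment
    :class:`GenomicInterval`; the count is the number of fragments with
    >= 1 bp overlap — a fragment spanning two regions is counted in both.
    """
    if mode not in ("five_prime_sense", "fragment_overlap"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "fragment_overlap":
        _warn_if_overlapping(regions)

    columns = {}
    for sample, data in sample_data.items():
        if mode == "five_prime_sense":
            track = data if isinstance(data, DensityTrack) else _positions_to_track(data)
            col = [
                track.region_sum(r, strand=r.strand if r.strand != "." else ".")
                for r in regions
            ]
        else:
            col = _fragment_counts(list(data), regions)
        columns[sample] = np.asarray(col)
    counts = pd.DataFrame(columns, index=list(region_ids)).astype(int)
    return CountMatrix(counts=counts, conditions=dict(conditions))


def _positions_to_track(positions: Iterable[Position]) -> DensityTrack:
    from .density import build_density

    return build_density(positions, library_size=1, mode="raw")


def _warn_if_overlapping(regions: Sequence[GenomicInterval]) -> None:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    for spans in by_chrom.values():
        spans.sort()
        for (s1, e1), (s2, _e2) in zip(spans, spans[1:]):
            if s2 < e1:
                logger.warning(
                    "overlapping regions in fragment mode: double counting possible"
                )
                return


def _fragment_counts(
    fragments: list[GenomicInterval], regions: Sequence[GenomicInterval]
) -> list[int]:
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for i, frag in enumerate(fragments):
        trees.setdefault(frag.chrom, IntervalTree()).addi(frag.start, frag.end, i)
    out = []
    for region in regions:
        tree = trees.get(region.chrom)
        out.append(len(tree.overlap(region.start, region.end)) if tree else 0)
    return out


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def median_of_ratios(matrix: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Only rows with all-positive counts enter the medians.
    """
    counts = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    values = counts.values.astype(float)
    positive = (values > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no row with all-positive counts; size factors undefined")
    sub = values[positive]
    log_geomean = np.log(sub).mean(axis=1)
    ratios = np.log(sub) - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    factors = factors / np.exp(np.log(factors).mean())  # geometric mean 1
    return pd.Series(factors, index=counts.columns, name="size_factor")


# ---------------------------------------------------------------------------
# NB tests
# ---------------------------------------------------------------------------

DISPERSION_PRIOR_DF = 20


def _mom_dispersion(groups: list[np.ndarray]) -> np.ndarray:
    """Moderated method-of-moments NB dispersion per region.

    The raw per-region estimate is the pooled within-group
    (s^2 - mu) / mu^2 with (n_g - 1)-df weights.  With few replicates this
    is far too noisy to calibrate a Wald test, so it is shrunk toward the
    across-region mean excess with ``DISPERSION_PRIOR_DF`` prior degrees of
    freedom (information sharing across regions, in the spirit of
    count-model packages), then floored at ``DISPERSION_FLOOR`` — the floor
    is the Poisson fallback.
    """
    num = np.zeros(groups[0].shape[0])
    den = np.zeros_like(num)
    for g in groups:
        n = g.shape[1]
        if n < 2:
            continue
        mu = g.mean(axis=1)
        var = g.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            excess = np.where(mu > 0, (var - mu) / mu**2, 0.0)
        num += excess * (n - 1)
        den += n - 1
    raw = np.where(den > 0, num / np.maximum(den, 1), 0.0)
    prior = max(float(raw.mean()), 0.0) if raw.size else 0.0
    df = float(den.max()) if den.size else 0.0
    moderated = (df * raw + DISPERSION_PRIOR_DF * prior) / (df + DISPERSION_PRIOR_DF)
    return np.maximum(moderated, DISPERSION_FLOOR)


def _result_frame(
    index: pd.Index,
    base_mean: np.ndarray,
    log2fc: np.ndarray,
    statistic: np.ndarray,
    pvalues: np.ndarray,
    all_zero: np.ndarray,
    fdr: float,
) -> pd.DataFrame:
    qvalues = bh_adjust(pvalues)
    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FC": log2fc,
            "stat": statistic,
            "pvalue": pvalues,
            "qvalue": qvalues,
            "significant": qvalues < fdr,
            "all_zero": all_zero,
        },
        index=index,
    )


def nb_wald_test(
    matrix: CountMatrix,
    contrast: tuple[str, str],
    size_factors: pd.Series | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Two-group NB Wald test of condition b versus condition a.

    Counts are normalized by size factors; per-region dispersion is the
    pooled within-group method-of-moments estimate; the Wald statistic is
    log2FC / SE(log2FC) with a delta-method SE, referred to a standard
    normal.  All-zero regions get p = 1, log2FC = 0 and are flagged.
    """
    cond_a, cond_b = contrast
    samples_a = [s for s, c in matrix.conditions.items() if c == cond_a]
    samples_b = [s for s, c in matrix.conditions.items() if c == cond_b]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("need >= 2 replicates per condition")
    if size_factors is None:
        size_factors = median_of_ratios(matrix)

    norm = matrix.counts / size_factors
    a = norm[samples_a].values
    b = norm[samples_b].values
    mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
    n_a, n_b = a.shape[1], b.shape[1]
    alpha = _mom_dispersion([a, b])

    all_zero = (mu_a == 0) & (mu_b == 0)
    # half-minimum pseudo-mean keeps the SE finite for one-sided zero groups
    pseudo = 0.5
    mu_a_s = np.maximum(mu_a, pseudo)
    mu_b_s = np.maximum(mu_b, pseudo)
    log2fc = np.where(all_zero, 0.0, np.log2(mu_b_s / mu_a_s))
    var_log_a = 1.0 / (n_a * mu_a_s) + alpha / n_a
    var_log_b = 1.0 / (n_b * mu_b_s) + alpha / n_b
    se_log2fc = np.sqrt(var_log_a + var_log_b) / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(all_zero, 0.0, log2fc / se_log2fc)
    pvalues = np.where(all_zero, 1.0, 2 * stats.norm.sf(np.abs(z)))
    base_mean = norm.values.mean(axis=1)
    return _result_frame(matrix.counts.index, base_mean, log2fc, z, pvalues, all_zero, fdr)


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB2 log-likelihood summed over columns; continuous counts allowed
    (normalized counts via the gamma-function form of the pmf)."""
    mu = np.maximum(mu, 1e-12)
    r = 1.0 / alpha[:, None]
    mu2 = mu if mu.ndim == 2 else mu[:, None]
    ll = (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1)
        + r * np.log(r / (r + mu2))
        + y * np.log(mu2 / (r + mu2))
    )
    return ll.sum(axis=1)


def nb_lrt_test(
    matrix: CountMatrix,
    size_factors: pd.Series | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """One-factor NB likelihood-ratio test across >= 3 conditions.

    Full model: one mean per condition; reduced: single shared mean; shared
    per-region method-of-moments dispersion.  The statistic is referred to
    chi-square with (levels - 1) df.  The reported log2FC is last condition
    versus first (condition order = first appearance in the sample map).
    """
    cond_levels = list(dict.fromkeys(matrix.conditions.values()))
    if len(cond_levels) < 3:
        raise ValueError("LRT requires >= 3 condition levels")
    if size_factors is None:
        size_factors = median_of_ratios(matrix)
    norm = matrix.counts / size_factors
    groups = {
        c: norm[[s for s, cc in matrix.conditions.items() if cc == c]].values
        for c in cond_levels
    }
    alpha = _mom_dispersion(list(groups.values()))

    y_all = norm.values
    ll_full = np.zeros(y_all.shape[0])
    for g in groups.values():
        ll_full += _nb_loglik(g, g.mean(axis=1), alpha)
    ll_reduced = _nb_loglik(y_all, y_all.mean(axis=1), alpha)
    lrt = np.maximum(2 * (ll_full - ll_reduced), 0.0)
    df = len(cond_levels) - 1
    pvalues = stats.chi2.sf(lrt, df)

    mu_first = np.maximum(groups[cond_levels[0]].mean(axis=1), 0.5)
    mu_last = np.maximum(groups[cond_levels[-1]].mean(axis=1), 0.5)
    all_zero = (y_all.sum(axis=1) == 0)
    pvalues = np.where(all_zero, 1.0, pvalues)
    log2fc = np.where(all_zero, 0.0, np.log2(mu_last / mu_first))
    base_mean = y_all.mean(axis=1)
    return _result_frame(matrix.counts.index, base_mean, log2fc, lrt, pvalues, all_zero, fdr)


# ---------------------------------------------------------------------------
# Classical tests
# ---------------------------------------------------------------------------

def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, monotone, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def two_proportion_z_test(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Two-sided two-proportion z-test with pooled variance."""
    for x, n in ((x1, n1), (x2, n2)):
        if not (0 <= x <= n) or n <= 0:
            raise ValueError("need 0 <= x <= n and n > 0")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise ValueError("degenerate pooled proportion; z undefined")
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (x1 / n1 - x2 / n2) / se
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Tie-corrected normal approximation with continuity correction; returns
    (U statistic for x, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Trajectory clustering
# ---------------------------------------------------------------------------

def zscore_profiles(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-scores ((x - mean) / sample sd); constant rows dropped."""
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 conditions to z-score")
    sd = matrix.std(axis=1, ddof=1)
    keep = sd > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("zscore_profiles: %d constant rows excluded", dropped)
    sub = matrix.loc[keep]
    return sub.sub(sub.mean(axis=1), axis=0).div(sd[keep], axis=0)


def kendall_distance_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise d = 1 - tau_b between gene profiles across conditions.

    Constant profiles (tau undefined) are excluded with a log message.
    Distances lie in [0, 2]; the diagonal is 0.
    """
    if profiles.shape[1] < 2:
        raise ValueError("profiles need >= 2 conditions")
    variable = profiles.std(axis=1) > 0
    dropped = int((~variable).sum())
    if dropped:
        logger.info("kendall_distance_matrix: %d constant profiles excluded", dropped)
    sub = profiles.loc[variable]
    values = sub.values
    n = len(sub)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            tau = stats.kendalltau(values[i], values[j]).statistic
            d = 1.0 - tau
            dist[i, j] = dist[j, i] = d
    return pd.DataFrame(dist, index=sub.index, columns=sub.index)


def _diana_split(dist: np.ndarray, members: list[int]) -> tuple[list[int], list[int]]:
    """One divisive step: splinter group versus remainder.

    Seed = member with maximal average dissimilarity to the rest (tie:
    lowest index).  Members then migrate to the splinter while their average
    dissimilarity to the remainder exceeds that to the splinter group.
    """
    m = len(members)
    sub = dist[np.ix_(members, members)]
    avg = sub.sum(axis=1) / (m - 1)
    seed = int(np.argmax(avg))  # argmax takes the first (lowest index) on ties
    splinter = [seed]
    remainder = [i for i in range(m) if i != seed]
    while len(remainder) > 1:
        best_gain, best_obj = 0.0, None
        for i in remainder:
            d_rem = sum(sub[i, j] for j in remainder if j != i) / (len(remainder) - 1)
            d_spl = sum(sub[i, j] for j in splinter) / len(splinter)
            gain = d_rem - d_spl
            if gain > best_gain:
                best_gain, best_obj = gain, i
        if best_obj is None:
            break
        splinter.append(best_obj)
        remainder.remove(best_obj)
    return [members[i] for i in splinter], [members[i] for i in remainder]


def diana_clustering(dist: pd.DataFrame, k: int) -> pd.Series:
    """Divisive hierarchical clustering cut at ``k`` clusters.

    Repeatedly splits the cluster with the largest diameter using the
    splinter procedure.  Deterministic: all ties break to the lowest index.
    Labels are 1..k, numbered by each cluster's lowest member index.
    """
    d = dist.values
    n = d.shape[0]
    if d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if not (2 <= k <= n):
        raise ValueError(f"need 2 <= k <= {n}")

    clusters: list[list[int]] = [list(range(n))]
    while len(clusters) < k:
        diameters = [
            d[np.ix_(c, c)].max() if len(c) > 1 else 0.0 for c in clusters
        ]
        target = int(np.argmax(diameters))
        if diameters[target] == 0.0:
            # all remaining clusters are singletons/identical: split largest
            target = int(np.argmax([len(c) for c in clusters]))
            if len(clusters[target]) < 2:
                raise ValueError("cannot reach k clusters: too few distinct objects")
            left = [clusters[target][0]]
            right = clusters[target][1:]
        else:
            left, right = _diana_split(d, clusters[target])
        clusters[target : target + 1] = [left, right]

    clusters.sort(key=min)
    labels = np.empty(n, dtype=int)
    for label, members in enumerate(clusters, start=1):
        labels[members] = label
    return pd.Series(labels, index=dist.index, name="cluster")
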