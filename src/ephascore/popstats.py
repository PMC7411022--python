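"""Population-level statistics on normalized clustering-score distributions.

Covers the three analyses the phenotyping assay runs on score distributions:

* distribution-shape comparison between cell populations (two-sample
  Kolmogorov–Smirnov, pairwise matrices with multiple-testing correction,
  Kruskal–Wallis omnibus with Dunn's tie-corrected post-hoc z-tests);
* clonal-colony inheritance: what fraction of colony pairs differ
  significantly at a given day, whether colony means converge back toward
  the unsorted baseline, and a bootstrap test of whether a colony's scores
  could be a random subset of the baseline population;
* correlation of population-mean scores with external phenotypes (migration
  speed, EMT score), optionally split into low/high-score groups at a
  threshold.

Dunn's post-hoc test is implemented here directly: on the pooled mid-ranks,
z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)) with the
tie correction T = sum(t^3 - t) / (12 (N-1)), two-sided normal p-values,
Bonferroni-adjusted over the unordered pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class ScoreDistribution:
    """A population's vector of (normalized) clustering scores."""

    population_id: str
    scores: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float).ravel()
        if self.scores.size < 2:
            raise ValueError("a score distribution needs at least 2 cells")

    @property
    def n(self) -> int:
        return self.scores.size

    @property
    def mean(self) -> float:
        return float(self.scores.mean())

    @property
    def sd(self) -> float:
        return float(self.scores.std(ddof=1))

    @property
    def cv(self) -> float:
        m = self.mean
        if m <= 0:
            raise ValueError("CV undefined for non-positive mean")
        return self.sd / m


@dataclass
class ColonySeries:
    """One clonal colony's score distributions at day 10 and day 20.

    ``baseline`` is the unsorted parent population the founder was picked
    from; it is shared across the colonies of one experiment.
    """

    colony_id: str
    day10: ScoreDistribution
    day20: ScoreDistribution
    baseline: ScoreDistribution
    founder_score: float | None = None

    def at_day(self, day: int) -> ScoreDistribution:
        if day == 10:
            return self.day10
        if day == 20:
            return self.day20
        raise ValueError("day must be 10 or 20")


@dataclass
class CorrelationReport:
    overall_r: float
    overall_p: float
    threshold: float
    group_low_r: float | None
    group_high_r: float | None
    low_members: list[str]
    high_members: list[str]


@dataclass
class ConvergenceSummary:
    """Per-colony means/CVs at both days plus convergence diagnostics."""

    table: pd.DataFrame
    baseline_mean: float
    max_abs_dev_day20: float
    cv_ratio_min: float
    cv_ratio_max: float


def ks_compare(
    a: ScoreDistribution, b: ScoreDistribution, min_n: int = 5
) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov D and p between two score distributions.

    Probes changes in the *shape* of the distribution, not just its mean.
    Uses the exact null distribution for n*m <= 10^4, asymptotic otherwise.
    ``min_n`` guards against uninterpretably small samples.
    """
    if a.n < min_n or b.n < min_n:
        raise ValueError(f"KS comparison requires n >= {min_n} per sample")
    method = "exact" if a.n * b.n <= 10_000 else "asymp"
    res = sps.ks_2samp(a.scores, b.scores, method=method)
    return float(res.statistic), float(res.pvalue)


def pairwise_ks_matrix(
    distributions: list[ScoreDistribution],
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> tuple[pd.DataFrame, float]:
    """All-pairs KS tests with multiple-testing correction.

    Returns the symmetric raw p-value matrix (unit diagonal) and the fraction
    of unordered pairs significant after correction — the assay's measure of
    how distinguishable the populations are from score distributions alone.
    """
    if len(distributions) < 2:
        raise ValueError("need at least 2 distributions")
    ids = [d.population_id for d in distributions]
    k = len(ids)
    pmat = pd.DataFrame(np.ones((k, k)), index=ids, columns=ids)
    raw = []
    pairs = list(combinations(range(k), 2))
    for i, j in pairs:
        _, p = ks_compare(distributions[i], distributions[j])
        pmat.iloc[i, j] = pmat.iloc[j, i] = p
        raw.append(p)
    reject, _, _, _ = multipletests(raw, alpha=alpha, method=correction)
    return pmat, float(np.mean(reject))


def _dunn_pairwise(groups: list[np.ndarray]) -> np.ndarray:
    """Tie-corrected Dunn z-test p-values (Bonferroni-adjusted), as a matrix."""
    k = len(groups)
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    sizes = [g.size for g in groups]
    mean_ranks = []
    start = 0
    for n in sizes:
        mean_ranks.append(ranks[start : start + n].mean())
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    m = k * (k - 1) // 2
    padj = np.ones((k, k))
    for i, j in combinations(range(k), 2):
        var = base_var * (1.0 / sizes[i] + 1.0 / sizes[j])
        if var <= 0:  # fully tied data
            p = 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(var)
            p = min(1.0, 2.0 * sps.norm.sf(abs(z)) * m)
        padj[i, j] = padj[j, i] = p
    return padj


def kw_dunn(
    groups: list[np.ndarray],
    alpha: float = 0.05,
) -> tuple[float, np.ndarray, set[tuple[int, int]]]:
    """Kruskal–Wallis omnibus plus Dunn's Bonferroni-adjusted pairwise tests.

    Returns (omnibus p, adjusted pairwise p matrix, set of significant
    (i, j) index pairs with adjusted p < alpha).  Fully tied data yields an
    omnibus p of 1 with a warning.
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2 or any(g.size < 5 for g in groups):
        raise ValueError("need >= 2 groups with n >= 5 each")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        warnings.warn("all observations tied; omnibus p set to 1", stacklevel=2)
        return 1.0, np.ones((len(groups), len(groups))), set()
    _, omnibus_p = sps.kruskal(*groups)
    padj = _dunn_pairwise(groups)
    significant = {
        (i, j) for i, j in combinations(range(len(groups)), 2) if padj[i, j] < alpha
    }
    return float(omnibus_p), padj, significant


def colony_divergence_fraction(
    colonies: list[ColonySeries],
    day: int,
    alpha: float = 0.05,
) -> float:
    """Fraction of colony pairs whose score distributions differ at ``day``.

    The inheritance signature: a high fraction at day 10 (colonies retain
    their founder's phenotype) that drops by day 20 as distributions converge
    back toward the population baseline.  Pairs are tested with Kruskal–
    Wallis + Dunn over all colonies at once; invariant to colony ordering.
    """
    if len(colonies) < 2:
        raise ValueError("need at least 2 colonies")
    groups = [c.at_day(day).scores for c in colonies]
    _, _, significant = kw_dunn(groups, alpha=alpha)
    n_pairs = len(colonies) * (len(colonies) - 1) // 2
    return len(significant) / n_pairs


def bootstrap_subset_test(
    colony,
    baseline,
    n_iter: int = 10_000,
    seed: int = 0,
    statistic: str = "mean",
) -> float:
    """Test whether a colony's scores could be a random subset of the baseline.

    Null: the colony is a size-|colony| draw *without replacement* from the
    unsorted baseline.  Statistic: |mean(draw) - mean(baseline)| (or the KS
    distance to the baseline with ``statistic="ks"``).  The p-value uses the
    add-one convention (k+1)/(n_iter+1), so it is never exactly 0 and equals
    1 when the colony is the baseline itself.  A colony is "not a random
    subset" at confidence c when p < 1 - c (the assay used c = 0.995).
    """
    colony = np.asarray(colony, dtype=float).ravel()
    baseline = np.asarray(baseline, dtype=float).ravel()
    if colony.size > baseline.size:
        raise ValueError("colony cannot be larger than the baseline")
    if n_iter < 1000:
        raise ValueError("n_iter must be >= 1000")
    rng = np.random.default_rng(seed)
    k, n = colony.size, baseline.size

    if statistic == "mean":
        base_mean = baseline.mean()
        observed = abs(colony.mean() - base_mean)

        def stat(draws):  # draws: (chunk, k)
            return np.abs(draws.mean(axis=1) - base_mean)

    elif statistic == "ks":
        observed = sps.ks_2samp(colony, baseline).statistic

        def stat(draws):
            return np.array([sps.ks_2samp(d, baseline).statistic for d in draws])

    else:
        raise ValueError("statistic must be 'mean' or 'ks'")

    exceed = 0
    chunk = max(1, min(n_iter, 50_000_000 // max(n, 1)))
    done = 0
    while done < n_iter:
        m = min(chunk, n_iter - done)
        keys = rng.random((m, n))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        draws = baseline[idx]
        exceed += int(np.count_nonzero(stat(draws) >= observed))
        done += m
    return (exceed + 1) / (n_iter + 1)


def convergence_summary(colonies: list[ColonySeries]) -> ConvergenceSummary:
    """Per-colony means and CVs at both days, plus convergence diagnostics.

    Convergence of the phenotype back to the population distribution shows up
    as |mean20 - baseline mean| < |mean10 - baseline mean| together with CV
    ratios (cv20/cv10) above 1.
    """
    if not colonies:
        raise ValueError("no colonies given")
    baseline_mean = colonies[0].baseline.mean
    rows = []
    for c in colonies:
        rows.append(
            {
                "colony_id": c.colony_id,
                "mean10": c.day10.mean,
                "mean20": c.day20.mean,
                "cv10": c.day10.cv,
                "cv20": c.day20.cv,
                "abs_dev10": abs(c.day10.mean - baseline_mean),
                "abs_dev20": abs(c.day20.mean - baseline_mean),
            }
        )
    table = pd.DataFrame(rows)
    ratios = table["cv20"] / table["cv10"]
    return ConvergenceSummary(
        table=table,
        baseline_mean=baseline_mean,
        max_abs_dev_day20=float(table["abs_dev20"].max()),
        cv_ratio_min=float(ratios.min()),
        cv_ratio_max=float(ratios.max()),
    )


def pearson_with_split(
    x: dict[str, float],
    y: dict[str, float],
    threshold: float = 0.4,
) -> CorrelationReport:
    """Pearson correlation of per-population mean scores with a phenotype.

    ``x`` maps population -> mean normalized score, ``y`` maps population ->
    phenotype value (migration speed, EMT score, ...).  Besides the overall
    correlation, populations are split at ``threshold`` on the score axis and
    within-group correlations are reported for groups with >= 3 members —
    phenotypes whose relation to clustering differs between low- and
    high-clustering lines show much higher within-group correlations.
    """
    common = sorted(set(x) & set(y))
    if len(common) < 3:
        raise ValueError("need >= 3 populations present in both x and y")
    xv = np.array([x[p] for p in common])
    yv = np.array([y[p] for p in common])
    if xv.std() == 0 or yv.std() == 0:
        raise ValueError("zero-variance input: correlation undefined")
    r, p = sps.pearsonr(xv, yv)
    low = [pop for pop, v in zip(common, xv) if v < threshold]
    high = [pop for pop, v in zip(common, xv) if v >= threshold]

    def group_r(members: list[str]) -> float | None:
        if len(members) < 3:
            return None
        gx = np.array([x[m] for m in members])
        gy = np.array([y[m] for m in members])
        if gx.std() == 0 or gy.std() == 0:
            return None
        return float(sps.pearsonr(gx, gy).statistic)

    return CorrelationReport(
        overall_r=float(r),
        overall_p=float(p),
        threshold=threshold,
        group_low_r=group_r(low),
        group_high_r=group_r(high),
        low_members=low,
        high_members=high,
    )
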