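"""Rank-based statistical comparison of forecasting models.

Model families are compared per cohort with the Friedman omnibus test on
within-patient ranks; when it signals a difference at the 5% level, the
post-hoc Nemenyi test compares the families pairwise, the Holm step-down
procedure controls the family-wise error, and the critical difference (CD)
summarises the minimum significant average-rank gap for CD diagrams.
Univariate-versus-multivariate input comparisons use the exact two-sided
Wilcoxon signed-rank test with zero differences dropped.

The Friedman p-value uses the chi-square approximation with the standard
tie correction — the convention that reproduces this benchmark's reference
p-values — and a full within-block permutation null is available for
small instances via ``method="permutation"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import permutations, product

import numpy as np
from scipy import stats as sps

__all__ = [
    "BlockedMetricMatrix",
    "ComparisonReport",
    "friedman_test",
    "nemenyi_pairwise",
    "holm_adjust",
    "critical_difference",
    "wilcoxon_signed_rank",
    "build_model_comparison",
    "build_input_comparison",
]

_TR_DF = np.inf  # studentized range at infinite degrees of freedom


@dataclass(frozen=True)
class BlockedMetricMatrix:
    """One metric per (patient block, treatment) cell.

    ``better_direction`` records whether smaller values are better (RMSE,
    MAE, SE) or larger ones (MCC); ranking always assigns rank 1 to the
    best treatment within each block.
    """

    patients: tuple[str, ...]
    treatments: tuple[str, ...]
    values: np.ndarray
    better_direction: str = "lower"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.patients), len(self.treatments)):
            raise ValueError("values shape must be (n_patients, "
                             "n_treatments)")
        if len(self.patients) < 2 or len(self.treatments) < 2:
            raise ValueError("need at least 2 blocks and 2 treatments")
        if np.isnan(v).any():
            raise ValueError("missing cells are not allowed")
        if self.better_direction not in ("lower", "higher"):
            raise ValueError("better_direction must be 'lower' or 'higher'")

    @property
    def n(self) -> int:
        return len(self.patients)

    @property
    def k(self) -> int:
        return len(self.treatments)


@dataclass
class ComparisonReport:
    """Friedman omnibus result with optional post-hoc layer."""

    friedman_chi2: float
    friedman_p: float
    avg_ranks: dict[str, float]
    alpha: float
    cd_value: float | None = None
    pairwise: list[dict] = field(default_factory=list)
    meta: dict = field(default_factory=dict)


def _block_ranks(matrix: BlockedMetricMatrix) -> np.ndarray:
    v = matrix.values if matrix.better_direction == "lower" \
        else -matrix.values
    return np.apply_along_axis(sps.rankdata, 1, v)


def _friedman_statistic(ranks: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square from a (n, k) rank matrix."""
    n, k = ranks.shape
    rank_sums = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * np.sum(rank_sums ** 2) \
        - 3.0 * n * (k + 1)
    # tie correction: one term per tied group in each block
    tie_term = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts ** 3 - counts))
    correction = 1.0 - tie_term / (n * (k ** 3 - k))
    if correction <= 0:
        return 0.0
    return stat / correction


def friedman_test(matrix: BlockedMetricMatrix,
                  method: str = "chi2"
                  ) -> tuple[float, float, dict[str, float]]:
    """Friedman omnibus test on within-block ranks.

    Returns ``(chi2, p, avg_ranks)``.  ``method="chi2"`` (default) takes
    the p-value from the chi-square distribution with k-1 df;
    ``method="permutation"`` enumerates every within-block column
    permutation (k!^n arrangements, feasible for small instances only) and
    reports the exact null fraction with statistic at least as large.
    """
    ranks = _block_ranks(matrix)
    avg = {t: float(r) for t, r in zip(matrix.treatments,
                                       ranks.mean(axis=0))}
    stat = _friedman_statistic(ranks)
    if stat == 0.0 and np.allclose(ranks, ranks[:, :1]):
        warnings.warn("all ranks tied in every block; Friedman test carries "
                      "no information", stacklevel=2)
        return 0.0, 1.0, avg
    if method == "chi2":
        p = float(sps.chi2.sf(stat, matrix.k - 1))
    elif method == "permutation":
        n, k = matrix.n, matrix.k
        perms = list(permutations(range(k)))
        if len(perms) ** n > 500_000:
            raise ValueError("permutation null infeasible at this size")
        count = total = 0
        for combo in product(perms, repeat=n):
            permuted = np.vstack([ranks[i, list(pi)]
                                  for i, pi in enumerate(combo)])
            total += 1
            if _friedman_statistic(permuted) >= stat - 1e-9:
                count += 1
        p = count / total
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(stat), p, avg


def nemenyi_pairwise(avg_ranks: dict[str, float], n: int,
                     k: int | None = None) -> list[dict]:
    """Pairwise Nemenyi p-values from average ranks.

    The statistic for a pair is |R_i - R_j| / sqrt(k(k+1)/(6n)); its
    p-value comes from the studentized-range distribution (q = stat *
    sqrt(2)) with k groups at infinite df.  Symmetric in the pair and
    invariant to the ranking direction.
    """
    names = list(avg_ranks)
    k = k if k is not None else len(names)
    if k < 2 or n < 1:
        raise ValueError("need k >= 2 treatments and n >= 1 blocks")
    scale = np.sqrt(k * (k + 1) / (6.0 * n))
    out = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            stat = abs(avg_ranks[a] - avg_ranks[b]) / scale
            p = float(sps.studentized_range.sf(stat * np.sqrt(2.0), k,
                                               _TR_DF))
            out.append({"pair": (a, b), "statistic": float(stat),
                        "p": min(1.0, p)})
    return out


def holm_adjust(p_values, alpha: float = 0.05) -> list[bool]:
    """Holm step-down decisions at family level ``alpha``.

    The i-th smallest p-value is compared to ``alpha / (m - i + 1)``;
    rejections proceed until the first failure and every later hypothesis
    is retained.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    m = p.size
    reject = np.zeros(m, dtype=bool)
    for i, idx in enumerate(order):
        if p[idx] <= alpha / (m - i):
            reject[idx] = True
        else:
            break
    return reject.tolist()


def critical_difference(n: int, k: int, alpha: float = 0.05) -> float:
    """Minimum significant average-rank gap for a CD diagram.

    CD = q_alpha(k) / sqrt(2) * sqrt(k(k+1) / (6n)) with q_alpha the
    studentized-range critical value at infinite df.
    """
    if n < 1 or k < 2:
        raise ValueError("need n >= 1 and k >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    q = float(sps.studentized_range.ppf(1.0 - alpha, k, _TR_DF))
    if not np.isfinite(q):
        raise ValueError(f"studentized-range quantile unavailable for "
                         f"k={k}, alpha={alpha}")
    return q / np.sqrt(2.0) * np.sqrt(k * (k + 1) / (6.0 * n))


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p by enumerating the 2^n sign assignments.

    Implemented as a subset-sum convolution over doubled (hence integer)
    ranks, equivalent to full enumeration.
    """
    scaled = np.round(ranks * 2).astype(int)
    total = scaled.sum()
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in scaled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:counts.size - r]
        counts = counts + shifted
    counts /= counts.sum()
    w = int(round(w_plus * 2))
    lower = counts[: w + 1].sum()
    upper = counts[w:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_signed_rank(paired_a, paired_b,
                         exact_limit: int = 25) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped before ranking; absolute differences are
    ranked with average ranks on ties.  The p-value is exact (full
    enumeration of sign assignments) when the effective sample size is at
    most ``exact_limit`` and uses the tie-corrected normal approximation
    beyond.  All differences zero yields p = 1 with a warning.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("paired samples must be equal-length 1-D arrays")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero", stacklevel=2)
        return 1.0
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    n = d.size
    if n <= exact_limit:
        return _exact_signed_rank_p(ranks, w_plus)
    mean = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie = float(np.sum(counts ** 3 - counts))
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie / 48.0
    z = (w_plus - mean) / np.sqrt(var)
    return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def build_model_comparison(matrix: BlockedMetricMatrix,
                           alpha: float = 0.05,
                           gate_posthoc: bool = True) -> ComparisonReport:
    """Friedman omnibus, then Nemenyi + Holm + CD only when it signals.

    The post-hoc layer is computed only when the Friedman p-value falls
    below ``alpha`` (set ``gate_posthoc=False`` to force it).
    """
    chi2, p, avg = friedman_test(matrix)
    report = ComparisonReport(friedman_chi2=chi2, friedman_p=p,
                              avg_ranks=avg, alpha=alpha,
                              meta={"n": matrix.n, "k": matrix.k,
                                    "direction": matrix.better_direction})
    if p < alpha or not gate_posthoc:
        pairwise = nemenyi_pairwise(avg, matrix.n, matrix.k)
        decisions = holm_adjust([row["p"] for row in pairwise], alpha)
        m = len(pairwise)
        order = np.argsort([row["p"] for row in pairwise], kind="stable")
        steps = {int(idx): alpha / (m - rank)
                 for rank, idx in enumerate(order)}
        for i, row in enumerate(pairwise):
            row["holm_alpha"] = steps[i]
            row["significant"] = decisions[i]
        report.pairwise = pairwise
        report.cd_value = critical_difference(matrix.n, matrix.k, alpha)
    return report


def build_input_comparison(univariate, multivariate) -> float:
    """Paired Wilcoxon p for univariate-vs-multivariate metric values."""
    return wilcoxon_signed_rank(univariate, multivariate)


def rank_cliques(avg_ranks: dict[str, float], cd_value: float
                 ) -> list[tuple[str, ...]]:
    """Maximal groups of treatments whose average ranks differ by < CD.

    These are the groups joined by a horizontal bar in a CD diagram.
    """
    names = sorted(avg_ranks, key=avg_ranks.get)
    cliques: list[tuple[str, ...]] = []
    for i in range(len(names)):
        group = [names[i]]
        for j in range(i + 1, len(names)):
            if avg_ranks[names[j]] - avg_ranks[names[i]] < cd_value:
                group.append(names[j])
            else:
                break
        if len(group) > 1 and not any(set(group) <= set(c)
                                      for c in cliques):
            cliques.append(tuple(group))
    return cliques


def plot_cd_diagram(avg_ranks: dict[str, float], cd_value: float, path,
                    title: str | None = None):
    """Render a critical-difference diagram.

    Treatments sit on a rank axis (best to the left); bars join groups
    whose average-rank differences fall below the critical difference.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    names = sorted(avg_ranks, key=avg_ranks.get)
    k = len(names)
    fig, ax = plt.subplots(figsize=(6, 1.8 + 0.4 * k))
    lo = np.floor(min(avg_ranks.values()))
    hi = np.ceil(max(avg_ranks.values()))
    ax.set_xlim(lo - 0.2, hi + 0.2)
    ax.set_ylim(-1.2 - 0.5 * k, 1.2)
    ax.axhline(0, color="black", lw=1)
    for x in np.arange(lo, hi + 0.5, 0.5):
        ax.plot([x, x], [0, 0.1], color="black", lw=1)
    for i, name in enumerate(names):
        x = avg_ranks[name]
        y = -0.5 - 0.45 * i
        ax.plot([x, x], [0, y + 0.1], color="black", lw=0.8)
        ax.text(x, y, f" {name} ({x:.2f})", va="center", fontsize=9)
    for i, clique in enumerate(rank_cliques(avg_ranks, cd_value)):
        xs = [avg_ranks[n] for n in clique]
        y = 0.35 + 0.3 * i
        ax.plot([min(xs), max(xs)], [y, y], color="black", lw=3,
                solid_capstyle="round")
    ax.plot([lo, lo + cd_value], [1.05, 1.05], color="black", lw=1.5)
    ax.text(lo + cd_value / 2, 1.12, f"CD = {cd_value:.3f}", ha="center",
            fontsize=8)
    if title:
        ax.set_title(title, fontsize=10)
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
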