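"""Hypothesis-testing machinery: PERMANOVA, paired Wilcoxon, BH adjustment,
Spearman correlation, and a two-class LEfSe-style discriminant analysis.

PERMANOVA partitions the squared-dissimilarity sum of squares by a single
grouping factor and assesses the pseudo-F statistic by label permutation.
LEfSe gates taxa by a rank test, then scores effect sizes with bootstrapped
one-axis linear discriminant analysis on a log10 scale.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .data import DistanceMatrix, ValidationError


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PermanovaResult:
    factor: str
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int


def _permanova_ss(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    """(SS_total, SS_within, SS_between) for one labelling."""
    n = len(labels)
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub.sum() / 2.0 / len(idx)
    return ss_total, ss_within, ss_total - ss_within


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, n_groups: int) -> tuple[float, float]:
    n = len(labels)
    ss_total, ss_within, ss_between = _permanova_ss(d2, labels)
    if ss_within <= 1e-300:
        return math.inf, (ss_between / ss_total if ss_total > 0 else 0.0)
    f = (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return f, r2


def permanova(
    d: DistanceMatrix,
    groups: Mapping[str, str] | pd.Series,
    n_perm: int = 999,
    seed: int = 0,
    factor: str = "group",
    exhaustive: bool = False,
) -> PermanovaResult:
    """Single-factor permutational multivariate ANOVA on a distance matrix.

    The statistic is pseudo-F from the between/within partition of squared
    dissimilarities; the p-value counts permuted labellings with F at least
    the observed value, with the observed labelling included
    ((1 + exceedances) / (1 + n_perm)). With ``exhaustive=True`` every
    distinct ordering of the label vector is enumerated instead and the
    p-value is the exact exceedance fraction (feasible only for small n).
    """
    labels = np.array([str(groups[s]) for s in d.sample_ids])
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValidationError("PERMANOVA needs at least two groups")
    if not exhaustive and n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    d2 = d.values**2
    f_obs, r2 = _pseudo_f(d2, labels, len(uniq))

    def at_least(f: float) -> bool:
        return f >= f_obs - 1e-12 if math.isfinite(f_obs) else math.isinf(f)

    if exhaustive:
        total = exceed = 0
        for perm in itertools.permutations(labels):
            f, _ = _pseudo_f(d2, np.array(perm), len(uniq))
            total += 1
            exceed += at_least(f)
        return PermanovaResult(factor, f_obs, r2, exceed / total, total)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        f, _ = _pseudo_f(d2, rng.permutation(labels), len(uniq))
        exceed += at_least(f)
    p = (1 + exceed) / (1 + n_perm)
    return PermanovaResult(factor, f_obs, r2, p, n_perm)


# ---------------------------------------------------------------------------
# Paired Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def _signed_rank_exact_p(ranks: np.ndarray, w_obs: float) -> float:
    """Exact two-sided p for the signed-rank sum under random sign flips.

    Handles tied (half-integer) mid-ranks by doubling them to integers and
    convolving the sign-flip distribution of the positive-rank sum; the
    two-sided p doubles the smaller tail (capped at 1).
    """
    r2 = np.round(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    top = 0
    for r in r2:
        counts[r : top + r + 1] += counts[: top + 1]
        top += r
    counts /= counts.sum()
    w2 = int(round(2 * w_obs))
    lo = counts[: w2 + 1].sum()
    hi = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(lo, hi)))


def paired_wilcoxon(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (Wilcoxon's original treatment). For up to
    25 non-zero pairs the exact sign-flip distribution of the positive-rank
    sum is used, with mid-ranks for ties; beyond that, the tie-corrected
    normal approximation. All-zero differences give (0, 1) with a warning.
    The statistic reported is min(T+, T-).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("paired vectors must be 1-D and equal length")
    diff = x - y
    diff = diff[diff != 0]
    if diff.size == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return 0.0, 1.0
    ranks = scipy.stats.rankdata(np.abs(diff))
    t_plus = float(ranks[diff > 0].sum())
    t_minus = float(ranks.sum() - t_plus)
    statistic = min(t_plus, t_minus)
    if diff.size <= 25:
        p = _signed_rank_exact_p(ranks, t_plus)
    else:
        res = scipy.stats.wilcoxon(
            diff, zero_method="wilcox", alternative="two-sided",
            method="approx", correction=False,
        )
        p = float(res.pvalue)
    return statistic, p


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Step-up false-discovery-rate adjustment, original order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of mid-ranks. For n <= 9 the p-value is
    the exact permutation probability of |rho| at least as large; for
    larger n the usual t approximation on n - 2 degrees of freedom is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValidationError("spearman needs equal-length 1-D vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("spearman undefined for a constant vector")
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if n <= 9:
        cx = rx - rx.mean()
        cy = ry - ry.mean()
        perms = np.array(list(itertools.permutations(range(n))))
        rho_perm = (cy[perms] @ cx) / np.sqrt((cx @ cx) * (cy @ cy))
        p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
    elif abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1 - rho**2))
        p = float(2 * scipy.stats.t.sf(abs(t), n - 2))
    return rho, p


# ---------------------------------------------------------------------------
# LEfSe (two-class)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class LefseResult:
    """Per-taxon discriminant scores for the taxa passing the rank-test gate.

    ``scores`` has one row per gated taxon: favoured class, LDA score
    (log10 scale) and the gating p-value. ``discoveries()`` applies the
    score threshold.
    """

    scores: pd.DataFrame  # index taxon; columns: class, lda_score, p_value
    alpha: float
    lda_threshold: float

    def discoveries(self) -> pd.DataFrame:
        return self.scores[self.scores["lda_score"] > self.lda_threshold]


def lefse(
    table: pd.DataFrame,
    classes: Mapping[str, str] | pd.Series,
    alpha: float = 0.05,
    lda_threshold: float = 3.0,
    n_boot: int = 30,
    seed: int = 0,
    rescale_total: float = 1e6,
) -> LefseResult:
    """Two-class linear discriminant analysis effect size.

    Stage 1 gates each taxon with a two-class Kruskal-Wallis test (identical
    to the Wilcoxon rank-sum test for two classes) at ``alpha``. Stage 2
    rescales each sample's abundances to ``rescale_total``, then over
    ``n_boot`` bootstrap rounds (resampling ceil(2n/3) samples per class)
    fits a one-axis regularised LDA; a taxon's per-round effect is the mean
    of (a) the class-mean difference along the discriminant axis scaled by
    the taxon's unit-norm coefficient and (b) the raw class-mean
    difference. The LDA score is log10(1 + mean effect).
    """
    labels = pd.Series({s: str(classes[s]) for s in table.columns})
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValidationError(f"LEfSe here is two-class only; got classes {uniq}")
    for cls in uniq:
        if (labels == cls).sum() < 2:
            raise ValidationError(f"class {cls!r} has fewer than 2 samples")

    a_samples = list(labels.index[labels == uniq[0]])
    b_samples = list(labels.index[labels == uniq[1]])

    # Stage 1: rank-test gate.
    gated: list[str] = []
    p_values: dict[str, float] = {}
    for taxon in table.index:
        va = table.loc[taxon, a_samples].to_numpy(dtype=float)
        vb = table.loc[taxon, b_samples].to_numpy(dtype=float)
        if np.ptp(np.concatenate([va, vb])) == 0:
            p = 1.0
        else:
            p = float(scipy.stats.kruskal(va, vb).pvalue)
        if p < alpha:
            gated.append(taxon)
            p_values[taxon] = p
    if not gated:
        return LefseResult(
            pd.DataFrame(columns=["class", "lda_score", "p_value"]),
            alpha,
            lda_threshold,
        )

    # Stage 2: bootstrapped LDA effect sizes on rescaled abundances.
    scaled = table * (rescale_total / table.sum(axis=0))
    x_all = scaled.loc[gated].to_numpy(dtype=float).T  # samples x taxa
    y_all = labels[list(table.columns)].to_numpy()
    idx_a = np.flatnonzero(y_all == uniq[0])
    idx_b = np.flatnonzero(y_all == uniq[1])
    take_a = math.ceil(2 * len(idx_a) / 3)
    take_b = math.ceil(2 * len(idx_b) / 3)

    rng = np.random.default_rng(seed)
    effects = np.zeros((n_boot, len(gated)))
    for r in range(n_boot):
        sa = rng.choice(idx_a, size=take_a, replace=False)
        sb = rng.choice(idx_b, size=take_b, replace=False)
        rows = np.concatenate([sa, sb])
        x, y = x_all[rows], y_all[rows]
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lda.fit(x, y)
        w = lda.coef_[0]
        norm = np.linalg.norm(w)
        w_unit = w / norm if norm > 0 else w
        proj = x @ w_unit
        proj_gap = abs(proj[y == uniq[0]].mean() - proj[y == uniq[1]].mean())
        raw_gap = np.abs(x[y == uniq[0]].mean(axis=0) - x[y == uniq[1]].mean(axis=0))
        effects[r] = 0.5 * (np.abs(w_unit) * proj_gap + raw_gap)

    mean_effect = effects.mean(axis=0)
    mean_a = scaled.loc[gated, a_samples].mean(axis=1)
    mean_b = scaled.loc[gated, b_samples].mean(axis=1)
    favoured = np.where(mean_a.to_numpy() >= mean_b.to_numpy(), uniq[0], uniq[1])
    scores = pd.DataFrame(
        {
            "class": favoured,
            "lda_score": np.log10(1.0 + mean_effect),
            "p_value": [p_values[t] for t in gated],
        },
        index=pd.Index(gated, name="taxon"),
    )
    return LefseResult(scores, alpha, lda_threshold)
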