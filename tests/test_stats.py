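"""PERMANOVA, Wilcoxon, BH, Spearman and LEfSe against independent oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

import ffpe16s as f
from ffpe16s.data import DistanceMatrix


def _euclidean_dm(points, ids):
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    d = d / (d.max() * 1.001) if d.max() > 0 else d
    return DistanceMatrix(d, ids, "bray_curtis")


def _permanova_oracle(d, labels):
    """Brute-force pseudo-F and exhaustive permutation p."""
    n = len(labels)
    d2 = d**2

    def pseudo_f(lab):
        sst = sum(d2[i][j] for i in range(n) for j in range(i + 1, n)) / n
        ssw = 0.0
        for g in set(lab):
            idx = [i for i in range(n) if lab[i] == g]
            ssw += sum(d2[i][j] for i in idx for j in idx if i < j) / len(idx)
        a = len(set(lab))
        ssb = sst - ssw
        return (ssb / (a - 1)) / (ssw / (n - a)) if ssw > 0 else math.inf

    f_obs = pseudo_f(labels)
    fs = [pseudo_f(p) for p in itertools.permutations(labels)]
    p = np.mean([x >= f_obs - 1e-12 for x in fs])
    return f_obs, float(p)


def test_permanova_matches_exhaustive_enumeration():
    rng = np.random.default_rng(0)
    ids = [f"s{i}" for i in range(6)]
    labels = ["A", "A", "A", "B", "B", "B"]
    for shift in (0.0, 0.5, 2.0):
        pts = rng.normal(size=(6, 2))
        pts[:3, 0] += shift
        d = _euclidean_dm(pts, ids)
        res = f.permanova(d, dict(zip(ids, labels)), exhaustive=True)
        f_oracle, p_oracle = _permanova_oracle(d.values, labels)
        assert res.pseudo_f == pytest.approx(f_oracle, rel=1e-12)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)
        assert 0 <= res.r_squared <= 1


def test_permanova_agrees_with_skbio_pseudo_f(cohort):
    skbio = pytest.importorskip("skbio")
    relab = f.to_relative_abundance(cohort.table.drop_samples(["NTC"]))
    d = f.distance_matrix(relab, "bray_curtis")
    groups = {
        s: cohort.metadata.preservation(s) for s in d.sample_ids
    }
    ours = f.permanova(d, groups, n_perm=99, seed=0)
    theirs = skbio.stats.distance.permanova(
        skbio.DistanceMatrix(d.values, ids=d.sample_ids),
        [groups[s] for s in d.sample_ids],
        permutations=99,
    )
    assert ours.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-9)


def test_permanova_no_structure_when_all_distances_equal():
    n = 6
    d = np.full((n, n), 0.5)
    np.fill_diagonal(d, 0.0)
    ids = [f"s{i}" for i in range(n)]
    res = f.permanova(
        DistanceMatrix(d, ids, "jaccard"),
        dict(zip(ids, ["A"] * 3 + ["B"] * 3)),
        exhaustive=True,
    )
    assert res.p_value == pytest.approx(1.0)


def test_permanova_requires_two_groups():
    d = DistanceMatrix(np.zeros((3, 3)), ["a", "b", "c"], "jaccard")
    with pytest.raises(f.ValidationError, match="two groups"):
        f.permanova(d, {"a": "X", "b": "X", "c": "X"})


def test_permanova_invariant_to_label_names_and_sample_order():
    rng = np.random.default_rng(8)
    pts = rng.normal(size=(8, 3))
    ids = [f"s{i}" for i in range(8)]
    labels = ["A"] * 4 + ["B"] * 4
    d = _euclidean_dm(pts, ids)
    r1 = f.permanova(d, dict(zip(ids, labels)), n_perm=99, seed=1)
    renamed = {s: {"A": "x", "B": "y"}[l] for s, l in zip(ids, labels)}
    r2 = f.permanova(d, renamed, n_perm=99, seed=1)
    assert r1.r_squared == pytest.approx(r2.r_squared, rel=1e-12)
    order = rng.permutation(8)
    d3 = DistanceMatrix(
        d.values[np.ix_(order, order)], [ids[i] for i in order], "bray_curtis"
    )
    r3 = f.permanova(d3, dict(zip(ids, labels)), n_perm=99, seed=1)
    assert r3.r_squared == pytest.approx(r1.r_squared, rel=1e-12)
    assert r3.pseudo_f == pytest.approx(r1.pseudo_f, rel=1e-12)


def _wilcoxon_oracle(diff):
    diff = diff[diff != 0]
    r = scipy.stats.rankdata(np.abs(diff))
    w_obs = r[diff > 0].sum()
    ws = np.array(
        [
            sum(ri for ri, s in zip(r, signs) if s)
            for signs in itertools.product([0, 1], repeat=len(diff))
        ]
    )
    lo = np.mean(ws <= w_obs + 1e-9)
    hi = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(lo, hi))


def test_wilcoxon_examples():
    x = np.arange(1.0, 6.0)
    with pytest.warns(UserWarning, match="zero"):
        assert f.paired_wilcoxon(x, x) == (0.0, 1.0)
    stat, p = f.paired_wilcoxon(x + 10, x)  # all differences positive
    assert stat == 0.0  # min(T+, T-) = T- = 0
    assert p == pytest.approx(0.0625, abs=1e-12)


def test_wilcoxon_matches_enumeration_with_ties():
    rng = np.random.default_rng(12)
    for _ in range(150):
        n = int(rng.integers(4, 11))
        x = rng.integers(0, 6, n).astype(float)
        y = rng.integers(0, 6, n).astype(float)
        if np.all(x == y):
            continue
        _, p = f.paired_wilcoxon(x, y)
        assert p == pytest.approx(_wilcoxon_oracle(x - y), abs=1e-12)


def test_bh_adjust_step_up():
    out = f.bh_adjust([0.01, 0.02, 0.03])
    np.testing.assert_allclose(out, [0.03, 0.03, 0.03])
    assert f.bh_adjust([0.2]).tolist() == [0.2]
    with pytest.raises(f.ValidationError):
        f.bh_adjust([0.5, 1.2])


def test_bh_matches_statsmodels_and_never_decreases():
    statsmodels = pytest.importorskip("statsmodels.stats.multitest")
    rng = np.random.default_rng(13)
    for _ in range(20):
        p = rng.uniform(size=rng.integers(1, 15))
        ours = f.bh_adjust(p)
        theirs = statsmodels.multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, theirs, atol=1e-12)
        assert (ours >= p - 1e-15).all()
        assert (ours <= 1.0).all()


def test_spearman_endpoints():
    x = np.arange(10.0)
    assert f.spearman(x, -x)[0] == pytest.approx(-1.0)
    assert f.spearman(x, x)[0] == pytest.approx(1.0)
    with pytest.raises(f.ValidationError, match="constant"):
        f.spearman(x, np.zeros(10))


def test_spearman_exact_p_matches_enumeration():
    rng = np.random.default_rng(14)
    for _ in range(5):
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        rho, p = f.spearman(x, y)
        rx, ry = scipy.stats.rankdata(x), scipy.stats.rankdata(y)
        assert rho == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-12)
        cx, cy = rx - rx.mean(), ry - ry.mean()
        rhos = [
            np.dot(cx, cy[list(perm)]) / math.sqrt(np.dot(cx, cx) * np.dot(cy, cy))
            for perm in itertools.permutations(range(8))
        ]
        p_oracle = np.mean([abs(r) >= abs(rho) - 1e-12 for r in rhos])
        assert p == pytest.approx(p_oracle, abs=1e-12)


def test_spearman_large_n_t_approximation():
    rng = np.random.default_rng(15)
    x = rng.normal(size=30)
    y = x + rng.normal(scale=2.0, size=30)
    rho, p = f.spearman(x, y)
    rho_sp, p_sp = scipy.stats.spearmanr(x, y)
    assert rho == pytest.approx(rho_sp, abs=1e-12)
    assert p == pytest.approx(p_sp, rel=1e-6)


def _two_class_table(rng, n_per_class, base, enriched=None, fold=1.0):
    profile = np.asarray(base, dtype=float)
    other = profile.copy()
    if enriched is not None:
        other[enriched] *= fold
    other /= other.sum()
    a = rng.dirichlet(500 * profile, n_per_class).T
    b = rng.dirichlet(500 * other, n_per_class).T
    cols = [f"A{i}" for i in range(n_per_class)] + [f"B{i}" for i in range(n_per_class)]
    frame = pd.DataFrame(
        np.hstack([a, b]) * 100,
        index=[f"t{i}" for i in range(len(profile))],
        columns=cols,
    )
    classes = {c: ("FF" if c.startswith("A") else "FFPE") for c in cols}
    return frame, classes


def test_lefse_identical_distributions_gate_empty():
    rng = np.random.default_rng(16)
    frame, classes = _two_class_table(rng, 5, [0.4, 0.3, 0.2, 0.1])
    # make the two classes literally identical per taxon
    for i in range(5):
        frame[f"B{i}"] = frame[f"A{i}"]
    res = f.lefse(frame, classes, seed=0)
    assert res.scores.empty


def test_lefse_gate_excludes_high_p_regardless_of_fold():
    # one sample flipped so the rank test cannot reach alpha, despite a
    # large mean difference driven by a single outlier
    frame = pd.DataFrame(
        {
            "A0": [99.0, 1.0],
            "A1": [1.0, 99.0],
            "A2": [50.0, 50.0],
            "B0": [60.0, 40.0],
            "B1": [40.0, 60.0],
            "B2": [50.0, 50.0],
        },
        index=["t0", "t1"],
    )
    classes = {c: ("FF" if c.startswith("A") else "FFPE") for c in frame.columns}
    res = f.lefse(frame, classes, seed=0)
    for taxon in res.scores.index:
        assert res.scores.loc[taxon, "p_value"] < 0.05


def test_lefse_score_monotone_in_fold_change():
    scores = []
    for fold in (5.0, 50.0, 500.0):
        rng = np.random.default_rng(17)
        frame, classes = _two_class_table(
            rng, 10, [0.5, 0.3, 0.15, 0.049, 0.001], enriched=4, fold=fold
        )
        res = f.lefse(frame, classes, seed=1)
        scores.append(
            res.scores.loc["t4", "lda_score"] if "t4" in res.scores.index else 0.0
        )
    assert scores[0] <= scores[1] <= scores[2]


def test_lefse_requires_two_classes_with_samples():
    frame = pd.DataFrame({"A0": [1.0], "A1": [1.0]}, index=["t0"])
    with pytest.raises(f.ValidationError, match="two-class"):
        f.lefse(frame, {"A0": "FF", "A1": "FF"})


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
def test_bh_property_bounded_and_rank_monotone(p_values):
    out = f.bh_adjust(p_values)
    assert ((0 <= out) & (out <= 1)).all()
    order = np.argsort(p_values, kind="stable")
    assert (np.diff(out[order]) >= -1e-15).all()
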