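"""The filtering cascade, rarefaction, normalisation and BLAST filtering."""

import numpy as np
import pandas as pd
import pytest

import ffpe16s as f
from ffpe16s.data import BlastHit


def _table(d, index):
    return f.AsvTable(pd.DataFrame(d, index=index))


def test_eukaryote_filter_direct_and_identity(tiny_tables):
    table, tax, _ = tiny_tables
    assert f.filter_eukaryotes(table, tax) == table  # no eukaryotes: unchanged

    counts = _table({"s1": [1, 2, 3, 4, 5]}, ["e1", "e2", "e3", "b1", "b2"])
    lineages = pd.DataFrame(
        [["Eukaryota"] + [f.UNASSIGNED] * 5] * 3 + [["Bacteria"] + [f.UNASSIGNED] * 5] * 2,
        index=["e1", "e2", "e3", "b1", "b2"],
        columns=list(f.RANKS),
    )
    out = f.filter_eukaryotes(counts, f.TaxonomyTable(lineages))
    assert out.asv_ids == ["b1", "b2"]


def test_eukaryote_removed_mass_matches_injected_fractions(cohort):
    report = f.PreprocessReport()
    f.filter_eukaryotes(cohort.table, cohort.taxonomy, report)
    removed = report.steps[0].removed_reads_per_sample
    sizes = cohort.table.library_sizes()
    for group, target in (("FF", 0.156), ("FFPE", 0.18)):
        for sample in cohort.metadata.samples_of(group):
            assert removed[sample] / sizes[sample] == pytest.approx(target, abs=0.01)
    assert removed["NTC"] == 0


def test_control_subtraction_removes_shared_identities():
    table = _table({"NTC": [3, 1, 0], "s1": [5, 5, 5]}, ["a", "b", "c"])
    out = f.subtract_control_asvs(table, "NTC")
    assert out.asv_ids == ["c"]
    assert out.sample_ids == ["s1"]
    # all-zero control: only the column is dropped
    table0 = _table({"NTC": [0, 0], "s1": [1, 2]}, ["a", "b"])
    out0 = f.subtract_control_asvs(table0, "NTC")
    assert out0.asv_ids == ["a", "b"] and out0.sample_ids == ["s1"]
    with pytest.raises(f.ValidationError, match="'nope'"):
        f.subtract_control_asvs(table, "nope")


def test_control_subtraction_reduces_contaminant_mass(cohort):
    """NTC-shared contaminant ASVs disappear; contamination shrinks but
    survives in every FFPE sample (environment-type ASVs stay)."""
    truth = cohort.ground_truth
    report = f.PreprocessReport()
    out = f.subtract_control_asvs(cohort.table, "NTC", report)
    removed = set(report.steps[0].removed_asvs)
    in_ntc = set(
        cohort.table.counts.index[cohort.table.counts["NTC"] > 0]
    )
    assert removed == in_ntc
    assert removed <= set(truth.ntc_shared_asvs)
    pool = set(truth.contaminant_asvs)
    for sample in cohort.metadata.samples_of("FFPE"):
        pre = cohort.table.counts[sample]
        post = out.counts[sample]
        pre_mass = pre[[a in pool for a in pre.index]].sum() / pre.sum()
        post_mass = post[[a in pool for a in post.index]].sum() / post.sum()
        assert 0 < post_mass < pre_mass


def test_singleton_removal_boundary_and_ground_truth(cohort):
    table = _table({"s1": [1, 1, 0], "s2": [0, 1, 5]}, ["single", "double", "big"])
    out = f.remove_singletons(table)
    assert out.asv_ids == ["double", "big"]  # total 2 is kept

    report = f.PreprocessReport()
    f.remove_singletons(cohort.table, report)
    removed = set(report.steps[0].removed_asvs)
    injected = {
        a for lst in cohort.ground_truth.singleton_asvs.values() for a in lst
    }
    assert removed == injected


def test_cascade_order_recorded(preprocessed):
    _, report, _ = preprocessed
    assert report.step_names == [
        "filter_eukaryotes",
        "subtract_control_asvs",
        "remove_singletons",
    ]


def test_cascade_never_negative(preprocessed):
    table, _, _ = preprocessed
    assert (table.counts.to_numpy() >= 0).all()


def test_rarefy_exact_depth_and_reproducibility(cohort):
    depth = 5808
    a = f.rarefy(cohort.table, depth, seed=9)
    b = f.rarefy(cohort.table, depth, seed=9)
    assert a == b
    assert (a.library_sizes() == depth).all()
    c = f.rarefy(cohort.table, depth, seed=10)
    assert (c.library_sizes() == depth).all()
    assert c != a


def test_rarefy_noop_at_full_depth():
    table = _table({"s1": [7, 3]}, ["a", "b"])
    assert f.rarefy(table, 10, seed=0) == table


def test_rarefy_rejects_shallow_samples():
    table = _table({"deep": [50, 50], "shallow": [2, 1]}, ["a", "b"])
    with pytest.raises(f.ValidationError, match="shallow"):
        f.rarefy(table, 10)


def test_rarefy_matches_hypergeometric_expectation():
    table = _table({"s1": [900, 100]}, ["a", "b"])
    means = np.mean(
        [f.rarefy(table, 100, seed=s).counts.loc["a", "s1"] for s in range(200)]
    )
    assert means == pytest.approx(90, abs=3)


def test_relative_abundance_examples_and_idempotence():
    table = _table({"s1": [1, 1, 0], "s2": [6, 0, 2]}, ["a", "b", "c"])
    rel = f.to_relative_abundance(table)
    assert rel["s1"].tolist() == [50.0, 50.0, 0.0]
    assert rel["s2"].tolist() == [75.0, 0.0, 25.0]
    pd.testing.assert_frame_equal(f.to_relative_abundance(rel), rel)
    with pytest.raises(f.ValidationError, match="all-zero"):
        f.to_relative_abundance(_table({"s1": [0, 0]}, ["a", "b"]))


def test_aggregate_taxa_conserves_mass(cohort):
    agg = f.aggregate_taxa(cohort.table, cohort.taxonomy, "genus")
    pd.testing.assert_series_equal(
        agg.sum(axis=0), cohort.table.counts.sum(axis=0), check_dtype=False
    )
    # two ASVs of one genus sum
    lineage = ["Bacteria", "p", "c", "o", "fam", "Blautia"]
    tax = f.TaxonomyTable(
        pd.DataFrame([lineage, lineage], index=["a", "b"], columns=list(f.RANKS))
    )
    agg2 = f.aggregate_taxa(_table({"s1": [3, 4]}, ["a", "b"]), tax, "genus")
    assert agg2.loc["Blautia", "s1"] == 7


def test_aggregate_pools_unassigned_into_na_bucket():
    rows = [
        ["Bacteria", "p", "c", "o1", "f1", "g1"],
        ["Bacteria"] + [f.UNASSIGNED] * 5,
        ["Bacteria", "p", "c", "o2"] + [f.UNASSIGNED] * 2,
    ]
    tax = f.TaxonomyTable(
        pd.DataFrame(rows, index=["a", "b", "c"], columns=list(f.RANKS))
    )
    agg = f.aggregate_taxa(_table({"s1": [1, 2, 4]}, ["a", "b", "c"]), tax, "genus")
    assert agg.loc[f.NA_BUCKET, "s1"] == 6
    assert agg.loc["g1", "s1"] == 1


def test_top_taxa_deterministic_lexicographic_ties():
    frame = pd.DataFrame({"s1": [5, 5, 5, 1]}, index=["b", "a", "c", "d"])
    assert f.top_taxa(frame, 2) == ["a", "b"]
    assert f.top_taxa(frame, 3) == ["a", "b", "c"]


def _hit(q, ident, cov, evalue, bits=100.0):
    return BlastHit(q, "acc", ident, 200, 0, 0, 1, 200, 1, 200, evalue, bits, cov)


def test_blast_filter_thresholds_and_best_hit():
    hits = [
        _hit("asv1", 97.9, 95.0, 1e-60),  # identity below threshold
        _hit("asv1", 99.0, 95.0, 1e-40),
        _hit("asv1", 99.0, 95.0, 1e-50),
        _hit("asv2", 99.0, 89.0, 1e-80),  # coverage below threshold
    ]
    best, unassigned = f.filter_blast_hits(hits)
    assert best["asv1"].evalue == 1e-50
    assert unassigned == ["asv2"]


def test_blast_filter_matches_brute_force_oracle():
    rng = np.random.default_rng(1)
    hits = [
        _hit(
            f"asv{rng.integers(4)}",
            float(rng.uniform(95, 100)),
            float(rng.uniform(80, 100)),
            float(10.0 ** -rng.integers(10, 100)),
            float(rng.uniform(100, 500)),
        )
        for _ in range(200)
    ]
    best, unassigned = f.filter_blast_hits(hits)
    queries = {h.qseqid for h in hits}
    for q in queries:
        ok = [
            h for h in hits
            if h.qseqid == q and h.pident >= 98.0 and h.qcovs >= 90.0
        ]
        if not ok:
            assert q in unassigned
        else:
            expect = min(ok, key=lambda h: (h.evalue, -h.bitscore))
            assert best[q] == expect
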