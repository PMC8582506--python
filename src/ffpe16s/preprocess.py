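"""The filtering cascade applied to raw ASV tables before any statistics.

Order is fixed: eukaryote removal, then in-silico subtraction of
no-template-control (NTC) ASVs, then singleton removal. Rarefaction,
percentage normalisation, taxonomic aggregation and BLAST-hit filtering are
provided as separate steps used where the downstream analysis requires
them. Each cascade step records what it removed in a provenance report.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import (
    RANKS,
    UNASSIGNED,
    AsvTable,
    BlastHit,
    TaxonomyTable,
    ValidationError,
)

#: Label of the pooled bucket for ASVs unassigned at the aggregation rank.
NA_BUCKET = "NA"


@dataclasses.dataclass
class StepRecord:
    """What one cascade step removed."""

    step: str
    removed_asvs: list[str]
    removed_reads_per_sample: dict[str, int]


@dataclasses.dataclass
class PreprocessReport:
    """Ordered provenance log of the cascade."""

    steps: list[StepRecord] = dataclasses.field(default_factory=list)

    @property
    def step_names(self) -> list[str]:
        return [s.step for s in self.steps]

    def to_dict(self) -> dict:
        return {
            "steps": [
                {
                    "step": s.step,
                    "n_removed_asvs": len(s.removed_asvs),
                    "removed_asvs": s.removed_asvs,
                    "removed_reads_per_sample": s.removed_reads_per_sample,
                }
                for s in self.steps
            ]
        }


def _removed_reads(table: AsvTable, removed: Sequence[str]) -> dict[str, int]:
    if not removed:
        return {s: 0 for s in table.sample_ids}
    sub = table.counts.loc[list(removed)]
    return {s: int(v) for s, v in sub.sum(axis=0).items()}


def filter_eukaryotes(
    table: AsvTable, tax: TaxonomyTable, report: PreprocessReport | None = None
) -> AsvTable:
    """Drop ASVs whose kingdom is Eukaryota (host and other non-microbial
    reads); everything else, including kingdom-unassigned ASVs, is kept."""
    tax.covers(table)
    kingdom = tax.rank("kingdom")
    removed = [a for a in table.asv_ids if kingdom[a] == "Eukaryota"]
    if report is not None:
        report.steps.append(
            StepRecord("filter_eukaryotes", removed, _removed_reads(table, removed))
        )
    return AsvTable(table.counts.drop(index=removed))


def subtract_control_asvs(
    table: AsvTable, control_sample: str, report: PreprocessReport | None = None
) -> AsvTable:
    """In-silico decontamination: every ASV present (count > 0) in the
    control is removed from all samples, and the control column is dropped."""
    if control_sample not in table.sample_ids:
        raise ValidationError(f"control sample {control_sample!r} not in table")
    control = table.counts[control_sample]
    removed = [a for a in table.asv_ids if control[a] > 0]
    out = table.counts.drop(index=removed).drop(columns=[control_sample])
    if report is not None:
        report.steps.append(
            StepRecord("subtract_control_asvs", removed, _removed_reads(table, removed))
        )
    return AsvTable(out)


def remove_singletons(
    table: AsvTable, report: PreprocessReport | None = None
) -> AsvTable:
    """Drop ASVs with a cohort-wide total of exactly one read."""
    totals = table.counts.sum(axis=1)
    removed = [a for a in table.asv_ids if totals[a] == 1]
    if report is not None:
        report.steps.append(
            StepRecord("remove_singletons", removed, _removed_reads(table, removed))
        )
    return AsvTable(table.counts.drop(index=removed))


def run_preprocessing(
    table: AsvTable,
    tax: TaxonomyTable,
    control_sample: str | None,
) -> tuple[AsvTable, PreprocessReport]:
    """The full fixed-order cascade with its provenance report."""
    report = PreprocessReport()
    table = filter_eukaryotes(table, tax, report)
    if control_sample is not None:
        table = subtract_control_asvs(table, control_sample, report)
    table = remove_singletons(table, report)
    return table, report


def rarefy(table: AsvTable, depth: int, seed: int = 0) -> AsvTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Each column is a multivariate-hypergeometric draw, so repeated runs
    with the same seed are identical and column sums equal ``depth``
    exactly.
    """
    if depth <= 0:
        raise ValidationError("rarefaction depth must be positive")
    sizes = table.library_sizes()
    shallow = sorted(sizes.index[sizes < depth])
    if shallow:
        raise ValidationError(
            f"samples shallower than depth {depth}: {shallow}"
        )
    rng = np.random.default_rng(seed)
    out = {}
    for sample in table.sample_ids:
        col = table.counts[sample].to_numpy()
        if col.sum() == depth:
            out[sample] = col
        else:
            out[sample] = rng.multivariate_hypergeometric(col, depth)
    return AsvTable(pd.DataFrame(out, index=table.asv_ids))


def to_relative_abundance(table: AsvTable | pd.DataFrame) -> pd.DataFrame:
    """Percentages per sample: 100 * x / sum(x), columns summing to 100."""
    counts = table.counts if isinstance(table, AsvTable) else table
    sums = counts.sum(axis=0)
    zero = sorted(sums.index[sums == 0])
    if zero:
        raise ValidationError(f"all-zero sample column(s): {zero}")
    return 100.0 * counts / sums


def aggregate_taxa(
    table: AsvTable | pd.DataFrame, tax: TaxonomyTable, rank: str
) -> pd.DataFrame:
    """Sum abundances over ASVs sharing a rank label; ASVs unassigned at
    that rank pool into the explicit :data:`NA_BUCKET` row. Column totals
    are conserved."""
    if rank not in RANKS:
        raise ValidationError(f"unknown rank {rank!r}")
    frame = table.counts if isinstance(table, AsvTable) else table
    labels = tax.rank(rank).reindex(frame.index)
    if labels.isna().any():
        missing = sorted(frame.index[labels.isna()])
        raise ValidationError(f"ASVs missing from taxonomy: {missing[:5]}")
    labels = labels.replace({UNASSIGNED: NA_BUCKET})
    return frame.groupby(labels, sort=True).sum()


def top_taxa(aggregated: pd.DataFrame, n: int, exclude_na: bool = False) -> list[str]:
    """The n most abundant taxa by total abundance, ties broken
    lexicographically; optionally excluding the unassigned bucket."""
    totals = aggregated.sum(axis=1)
    if exclude_na and NA_BUCKET in totals.index:
        totals = totals.drop(NA_BUCKET)
    ordered = totals.to_frame("total").reset_index(names="taxon")
    ordered = ordered.sort_values(["total", "taxon"], ascending=[False, True])
    return list(ordered["taxon"].head(n))


def filter_blast_hits(
    hits: Sequence[BlastHit],
    min_identity: float = 98.0,
    min_coverage: float = 90.0,
    query_lengths: Mapping[str, int] | None = None,
) -> tuple[dict[str, BlastHit], list[str]]:
    """Best hit per query after identity/coverage thresholds.

    Hits below ``min_identity`` percent identity or ``min_coverage`` percent
    query coverage are discarded; survivors are sorted by ascending e-value
    (bitscore descending as tie-break) and the first per query wins.
    Returns (best-hit map, queries left unassigned).
    """
    survivors: dict[str, list[BlastHit]] = {}
    queries: list[str] = []
    for hit in hits:
        if hit.qseqid not in survivors:
            queries.append(hit.qseqid)
            survivors[hit.qseqid] = []
        qlen = query_lengths.get(hit.qseqid) if query_lengths else None
        if hit.pident >= min_identity and hit.coverage(qlen) >= min_coverage:
            survivors[hit.qseqid].append(hit)
    best: dict[str, BlastHit] = {}
    unassigned: list[str] = []
    for q in queries:
        if survivors[q]:
            best[q] = min(survivors[q], key=lambda h: (h.evalue, -h.bitscore))
        else:
            unassigned.append(q)
    return best, unassigned
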