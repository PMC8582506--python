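"""FFPE comparability index: dominance of the matched-FF top orders,
contaminant prevalence, dissimilarity correlation, and high/low calls.

The index asks, for each FF/FFPE pair: how much of the FFPE community is
still made of the two orders that dominate the matched FF sample
("dominance"), and how much is recognisable reagent/environmental
contamination? Pairs whose dominance stays above a cutoff and whose
contaminant load stays low are called "high" comparability; across a
cohort, dominance should correlate negatively with pair dissimilarity if
contamination is what drives FF/FFPE discordance.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .data import (
    METRICS,
    AsvTable,
    SampleMetadata,
    TaxonomyTable,
    ValidationError,
)
from .diversity import pairwise
from .preprocess import NA_BUCKET, aggregate_taxa, rarefy, to_relative_abundance
from .stats import bh_adjust, spearman

#: Genera treated as typical sequencing contaminants by default.
DEFAULT_CONTAMINANT_GENERA = (
    "Rhizobium",
    "Acinetobacter",
    "Lysinibacillus",
    "Delftia",
    "Paracoccus",
    "Sphingomonas",
    "Pseudomonas",
    "Aquipuribacter",
)

#: Orders used as a fallback when a contaminant's genus is not listed or
#: not assigned.
DEFAULT_CONTAMINANT_ORDERS = ("Rhodobacterales", "Sphingomonadales")

#: A pair is "high" comparability when FFPE dominance exceeds this percent...
DEFAULT_DOMINANCE_CUTOFF = 50.0
#: ...and its contaminant prevalence does not exceed this percent. The
#: dominance cutoff is the published convention; the contaminant cutoff is
#: a package default, exposed because no published value exists.
DEFAULT_CONTAMINANT_CUTOFF = 25.0


@dataclasses.dataclass
class PairQcRecord:
    """Comparability bookkeeping for one FF/FFPE pair."""

    patient_id: str
    top2_orders: tuple[str, ...]
    dominance_ffpe: float  # percent in [0, 100]
    dissimilarity: dict[str, float]  # metric -> value
    contaminant_prevalence_ffpe: float  # percent in [0, 100]
    comparability: str  # "high" | "low"


def top2_orders(
    order_relabund: pd.Series, exclude: Sequence[str] = ()
) -> tuple[str, ...]:
    """The two most abundant assigned orders of one FF sample.

    The unassigned bucket is never eligible; extra orders (e.g. archaeal
    ones) can be excluded via ``exclude``. Ties break lexicographically.
    Fewer than two eligible orders returns what exists, with a warning.
    """
    drop = set(exclude) | {NA_BUCKET}
    eligible = order_relabund.drop(index=[i for i in order_relabund.index if i in drop])
    ordered = eligible.to_frame("abund").reset_index(names="order")
    ordered = ordered.sort_values(["abund", "order"], ascending=[False, True])
    top = tuple(ordered["order"].head(2))
    if len(top) < 2:
        warnings.warn("fewer than two assigned orders available for top-2")
    return top


def dominance_in_ffpe(ffpe_order_relabund: pd.Series, top2: Sequence[str]) -> float:
    """Summed FFPE relative abundance (percent) of the FF top-2 orders;
    an order absent from the FFPE sample contributes zero."""
    return float(sum(ffpe_order_relabund.get(o, 0.0) for o in top2))


def contaminant_prevalence(
    ffpe_relabund: pd.Series,
    tax: TaxonomyTable,
    genera: Sequence[str] = DEFAULT_CONTAMINANT_GENERA,
    orders: Sequence[str] = DEFAULT_CONTAMINANT_ORDERS,
) -> float:
    """Percent of an FFPE sample assigned to listed contaminant taxa.

    An ASV counts once if its genus is listed, or — fallback — its order
    is listed.
    """
    if not genera and not orders:
        raise ValidationError("contaminant list is empty")
    genus = tax.rank("genus").reindex(ffpe_relabund.index)
    order = tax.rank("order").reindex(ffpe_relabund.index)
    mask = genus.isin(set(genera)) | order.isin(set(orders))
    return float(ffpe_relabund[mask.to_numpy()].sum())


def classify_comparability(
    dominance_ffpe: float,
    contaminant_prevalence_ffpe: float,
    dominance_cutoff: float = DEFAULT_DOMINANCE_CUTOFF,
    contaminant_cutoff: float = DEFAULT_CONTAMINANT_CUTOFF,
) -> str:
    """"high" iff dominance exceeds its cutoff and contaminant prevalence
    stays at or below its cutoff; "low" otherwise."""
    high = (
        dominance_ffpe > dominance_cutoff
        and contaminant_prevalence_ffpe <= contaminant_cutoff
    )
    return "high" if high else "low"


def compute_pair_qc(
    table: AsvTable,
    tax: TaxonomyTable,
    meta: SampleMetadata,
    rarefy_depth: int | None = None,
    seed: int = 0,
    metrics: Sequence[str] = METRICS,
    contaminant_genera: Sequence[str] = DEFAULT_CONTAMINANT_GENERA,
    contaminant_orders: Sequence[str] = DEFAULT_CONTAMINANT_ORDERS,
    dominance_cutoff: float = DEFAULT_DOMINANCE_CUTOFF,
    contaminant_cutoff: float = DEFAULT_CONTAMINANT_CUTOFF,
) -> list[PairQcRecord]:
    """Build one :class:`PairQcRecord` per FF/FFPE pair.

    The table (already decontaminated) is rarefied to ``rarefy_depth`` —
    by default the minimum library size — then converted to percentages.
    Dissimilarities are taken at the ASV level on the rarefied relative
    abundances; dominance and prevalence at order/genus level. Archaeal
    orders are excluded from top-2 candidacy.
    """
    tax.covers(table)
    depth = int(table.library_sizes().min()) if rarefy_depth is None else rarefy_depth
    rarefied = rarefy(table, depth, seed=seed)
    relab = to_relative_abundance(rarefied)
    order_rel = aggregate_taxa(relab, tax, "order")
    kingdom = tax.rank("kingdom").reindex(relab.index)
    order = tax.rank("order").reindex(relab.index)
    archaeal_orders = sorted(set(order[kingdom == "Archaea"]) - {NA_BUCKET})

    records = []
    for patient, (ff, ffpe) in meta.pairs().items():
        top2 = top2_orders(order_rel[ff], exclude=archaeal_orders)
        dom = dominance_in_ffpe(order_rel[ffpe], top2)
        diss = {
            m: pairwise(relab[ff].to_numpy(), relab[ffpe].to_numpy(), m)
            for m in metrics
        }
        prev = contaminant_prevalence(
            relab[ffpe], tax, contaminant_genera, contaminant_orders
        )
        records.append(
            PairQcRecord(
                patient_id=patient,
                top2_orders=top2,
                dominance_ffpe=dom,
                dissimilarity=diss,
                contaminant_prevalence_ffpe=prev,
                comparability=classify_comparability(
                    dom, prev, dominance_cutoff, contaminant_cutoff
                ),
            )
        )
    return records


def dominance_dissimilarity_correlation(
    records: Sequence[PairQcRecord], metrics: Sequence[str] = METRICS
) -> pd.DataFrame:
    """Spearman correlation of dominance against each pair dissimilarity.

    Returns one row per metric with rho, the raw p-value, and the p-value
    BH-adjusted across the requested metrics (that trio is the multiple-
    testing family).
    """
    if len(records) < 4:
        raise ValidationError("need at least four pairs to correlate")
    dominance = np.array([r.dominance_ffpe for r in records])
    if np.ptp(dominance) == 0:
        raise ValidationError("dominance is constant across pairs")
    rows = []
    for m in metrics:
        diss = np.array([r.dissimilarity[m] for r in records])
        rho, p = spearman(dominance, diss)
        rows.append({"metric": m, "rho": rho, "p_value": p})
    out = pd.DataFrame(rows).set_index("metric")
    out["p_adjusted"] = bh_adjust(out["p_value"].to_numpy())
    return out


def records_to_frame(records: Sequence[PairQcRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "top2_orders": ";".join(r.top2_orders),
            "dominance_ffpe": r.dominance_ffpe,
            "contaminant_prevalence_ffpe": r.contaminant_prevalence_ffpe,
            "comparability": r.comparability,
        }
        for m, v in r.dissimilarity.items():
            row[f"dissimilarity_{m}"] = v
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient_id")
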