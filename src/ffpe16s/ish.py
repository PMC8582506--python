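"""RNA-ISH count QC, presence calling, and 16S/ISH concordance tables.

RNA in situ hybridisation (RNAscope-style) quantifies bacterial rRNA as
signal counts inside tissue regions of interest. This module models the
count-level logic only: quality filtering of low-signal samples, binary
presence calls for both the ISH and 16S platforms, pair-level concordance
tables, and tumor-versus-adjacent-mucosa enrichment tests.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import ValidationError
from .stats import paired_wilcoxon

#: Probes with 16S counterparts analysed throughout.
PROBES = ("total_bacteria", "Fusobacterium", "Bacteroides", "Propionibacterium")

#: Genera that have both an ISH probe and a 16S counterpart.
GENERA = ("Bacteroides", "Fusobacterium", "Propionibacterium")

#: Regions a count can be attributed to.
REGIONS = ("tumor", "normal", "total")

#: Presence thresholds: at least this many counts means "present".
ISH_PRESENCE_THRESHOLD = 100
SEQ_PRESENCE_THRESHOLD = 10

#: Samples with fewer total-bacteria counts than this fail ISH quality control.
ISH_QC_MIN_TOTAL = 100

#: Platform identifiers used in concordance tables.
PLATFORMS = ("ish_ffpe", "seq_ffpe", "seq_ff")


class IshCountTable:
    """Signal counts per sample x probe x region.

    Stored wide: a MultiIndex (sample_id, probe) with integer columns
    ``tumor``, ``normal``, ``total``. ``total`` covers the whole section, so
    it is never smaller than either region count.
    """

    def __init__(self, frame: pd.DataFrame):
        need = {"tumor", "normal", "total"}
        if not need.issubset(frame.columns):
            raise ValidationError(f"ISH table needs columns {sorted(need)}")
        frame = frame.loc[:, ["tumor", "normal", "total"]].astype(np.int64)
        if (frame.to_numpy() < 0).any():
            raise ValidationError("negative ISH count")
        short = frame[frame["total"] < frame[["tumor", "normal"]].max(axis=1)]
        if len(short):
            raise ValidationError(
                f"total count below a region count at {short.index[0]}"
            )
        self.frame = frame

    @property
    def sample_ids(self) -> list[str]:
        return sorted({s for s, _ in self.frame.index})

    def count(self, sample_id: str, probe: str, region: str = "total") -> int:
        if region not in REGIONS:
            raise ValidationError(f"unknown region {region!r}")
        try:
            return int(self.frame.loc[(sample_id, probe), region])
        except KeyError:
            raise ValidationError(f"no ISH entry for ({sample_id!r}, {probe!r})") from None

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        out = self.frame.reset_index()
        out.columns = ["sample_id", "probe", "tumor", "normal", "total"]
        out.to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def from_tsv(cls, path: str | Path) -> "IshCountTable":
        raw = pd.read_csv(path, sep="\t")
        return cls(raw.set_index(["sample_id", "probe"]))


def ish_qc_filter(table: IshCountTable) -> tuple[list[str], list[str]]:
    """Split samples into (evaluable, excluded) by total-bacteria signal.

    A sample is evaluable only if its whole-section total-bacteria count is
    at least :data:`ISH_QC_MIN_TOTAL`; low-signal sections cannot be scored
    reliably and are dropped from every downstream summary.
    """
    evaluable, excluded = [], []
    for sample in table.sample_ids:
        total = table.count(sample, "total_bacteria", "total")
        (evaluable if total >= ISH_QC_MIN_TOTAL else excluded).append(sample)
    return evaluable, excluded


def call_presence(count: int, platform: str) -> bool:
    """Binary presence from a count: >=100 for ISH, >=10 for 16S."""
    if count < 0:
        raise ValidationError(f"negative count {count}")
    if platform == "ish":
        return count >= ISH_PRESENCE_THRESHOLD
    if platform == "seq":
        return count >= SEQ_PRESENCE_THRESHOLD
    raise ValidationError(f"platform must be 'ish' or 'seq', got {platform!r}")


class ConcordanceTable:
    """Per-pair, per-genus presence flags for the three platform readouts.

    One row per (pair, genus) with boolean columns ``ish_ffpe``,
    ``seq_ffpe``, ``seq_ff``; a missing platform readout is NA, never
    silently treated as absent.
    """

    def __init__(self, frame: pd.DataFrame):
        need = {"pair_id", "genus", *PLATFORMS}
        if not need.issubset(frame.columns):
            raise ValidationError(f"concordance table needs columns {sorted(need)}")
        frame = frame.loc[:, ["pair_id", "genus", *PLATFORMS]].copy()
        for col in PLATFORMS:
            frame[col] = frame[col].astype("boolean")
        self.frame = frame.reset_index(drop=True)

    @property
    def pair_ids(self) -> list[str]:
        return sorted(set(self.frame["pair_id"].astype(str)))

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        out = self.frame.copy()
        for col in PLATFORMS:
            out[col] = out[col].map({True: "+", False: "-"}).fillna("NA")
        out.to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def from_flag_tsv(cls, path: str | Path) -> "ConcordanceTable":
        """Read a table whose platform cells are '+', '-' or 'NA'."""
        raw = pd.read_csv(path, sep="\t", dtype=str)
        for col in PLATFORMS:
            raw[col] = raw[col].map({"+": True, "-": False, "NA": pd.NA})
        return cls(raw)


def build_concordance_table(
    ish: IshCountTable,
    seq_ffpe_counts: Mapping[str, Mapping[str, int]],
    seq_ff_counts: Mapping[str, Mapping[str, int]],
    genera: Sequence[str] = GENERA,
) -> ConcordanceTable:
    """Threshold ISH and 16S counts into one presence row per evaluable pair.

    Parameters
    ----------
    ish
        ISH counts for the FFPE sections; the QC filter is applied here, so
        pairs whose section fails QC are excluded entirely.
    seq_ffpe_counts, seq_ff_counts
        pair_id -> genus -> 16S read count for the FFPE and FF samples.
        A pair/genus missing from a mapping yields an NA flag.
    """
    evaluable, _ = ish_qc_filter(ish)
    rows = []
    for pair in evaluable:
        for genus in genera:
            try:
                ish_flag: object = call_presence(ish.count(pair, genus, "tumor"), "ish")
            except ValidationError:
                ish_flag = pd.NA
            seq_flags = []
            for source in (seq_ffpe_counts, seq_ff_counts):
                if pair in source and genus in source[pair]:
                    seq_flags.append(call_presence(int(source[pair][genus]), "seq"))
                else:
                    seq_flags.append(pd.NA)
            rows.append(
                {
                    "pair_id": pair,
                    "genus": genus,
                    "ish_ffpe": ish_flag,
                    "seq_ffpe": seq_flags[0],
                    "seq_ff": seq_flags[1],
                }
            )
    return ConcordanceTable(pd.DataFrame(rows))


def concordance_summary(
    ct: ConcordanceTable, genus: str, reference_platform: str, query_platform: str
) -> tuple[int, int]:
    """(k, n): of n reference-platform positives, k are query-positive too.

    Rows with a missing flag on either platform are ignored.
    """
    for p in (reference_platform, query_platform):
        if p not in PLATFORMS:
            raise ValidationError(f"unknown platform {p!r}; expected one of {PLATFORMS}")
    sub = ct.frame[ct.frame["genus"] == genus]
    if sub.empty:
        raise ValidationError(f"genus {genus!r} absent from concordance table")
    sub = sub.dropna(subset=[reference_platform, query_platform])
    ref_pos = sub[sub[reference_platform].astype(bool)]
    n = len(ref_pos)
    k = int(ref_pos[query_platform].astype(bool).sum())
    return k, n


def presence_count(ct: ConcordanceTable, genus: str, platform: str) -> tuple[int, int]:
    """(k, n): k positive calls for *genus* on *platform* among n evaluable pairs."""
    if platform not in PLATFORMS:
        raise ValidationError(f"unknown platform {platform!r}")
    sub = ct.frame[ct.frame["genus"] == genus].dropna(subset=[platform])
    if sub.empty:
        raise ValidationError(f"genus {genus!r} absent from concordance table")
    return int(sub[platform].astype(bool).sum()), len(sub)


def load_reference_concordance() -> ConcordanceTable:
    """Published presence/absence pattern for the seven evaluable FF/FFPE
    pairs across the three probed genera; used as an exact regression
    fixture for the concordance summaries."""
    ref = importlib.resources.files("ffpe16s").joinpath(
        "data/reference_presence_7pairs.tsv"
    )
    with importlib.resources.as_file(ref) as path:
        return ConcordanceTable.from_flag_tsv(path)


def tumor_enrichment(
    ish: IshCountTable, probe: str
) -> tuple[pd.DataFrame, float, float]:
    """Paired tumor-vs-normal comparison of ISH counts for one probe.

    Returns (per-sample counts, Wilcoxon statistic, two-sided p). Only
    QC-evaluable samples enter the test.
    """
    evaluable, _ = ish_qc_filter(ish)
    rows = []
    for sample in evaluable:
        rows.append(
            {
                "sample_id": sample,
                "tumor": ish.count(sample, probe, "tumor"),
                "normal": ish.count(sample, probe, "normal"),
            }
        )
    frame = pd.DataFrame(rows)
    if len(frame) < 3:
        raise ValidationError(
            f"tumor enrichment needs >=3 evaluable samples, got {len(frame)}"
        )
    stat, p = paired_wilcoxon(frame["tumor"].to_numpy(), frame["normal"].to_numpy())
    return frame, stat, p
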