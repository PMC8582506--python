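"""Domain types and TSV readers/writers for paired FF/FFPE 16S datasets.

All tables are thin, validated wrappers around :class:`pandas.DataFrame`.
The on-disk dialect is UTF-8 TSV, first column the row identifier, no
quoting; rows and columns are normalised to lexicographic order on read so
that downstream results never depend on file ordering.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Canonical in-memory marker for a taxonomy rank without an assignment.
#: Encoded as an empty cell on disk, so a genus literally named "NA" or
#: "unassigned" never collides with it.
UNASSIGNED = "__unassigned__"

#: Ranked lineage levels, coarsest first.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

#: Allowed preservation classes.
PRESERVATIONS = ("FF", "FFPE", "NTC")

#: Metrics a DistanceMatrix may be tagged with.
METRICS = ("bray_curtis", "jaccard", "jensen_shannon")


class ValidationError(ValueError):
    """A table violates one of its structural invariants."""


class ParseError(ValueError):
    """A file cell could not be parsed; message names row and column."""


def _check_unique(ids: Iterable[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} id: {i!r}")
        seen.add(i)
    return ids


class AsvTable:
    """Integer ASV-by-sample count matrix; the unit every stage consumes.

    Parameters
    ----------
    counts
        DataFrame with ASV ids as index, sample ids as columns, and
        non-negative integer counts.
    """

    def __init__(self, counts: pd.DataFrame):
        _check_unique(counts.index, "ASV")
        _check_unique(counts.columns, "sample")
        values = counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValidationError("counts must be integers")
            counts = counts.round().astype(np.int64)
        if values.size and (counts.to_numpy() < 0).any():
            bad = counts.stack()
            bad = bad[bad < 0].index[0]
            raise ValidationError(f"negative count at ASV {bad[0]!r}, sample {bad[1]!r}")
        self.counts = counts.astype(np.int64) if counts.size else counts.astype(np.int64)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def library_sizes(self) -> pd.Series:
        """Total reads per sample (column sums)."""
        return self.counts.sum(axis=0)

    def sorted(self) -> "AsvTable":
        """Copy with rows and columns in lexicographic order."""
        return AsvTable(self.counts.sort_index(axis=0).sort_index(axis=1))

    def drop_samples(self, samples: Sequence[str]) -> "AsvTable":
        return AsvTable(self.counts.drop(columns=list(samples)))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, AsvTable) and self.counts.equals(other.counts)

    def __repr__(self) -> str:
        return f"AsvTable({len(self.asv_ids)} ASVs x {len(self.sample_ids)} samples)"


class TaxonomyTable:
    """Per-ASV ranked lineage (kingdom..genus) with explicit unassigned ranks.

    An unassigned rank is only valid if every deeper rank is also
    unassigned, i.e. :data:`UNASSIGNED` occupies a suffix of the lineage.
    """

    def __init__(self, lineages: pd.DataFrame):
        _check_unique(lineages.index, "ASV")
        missing = [r for r in RANKS if r not in lineages.columns]
        if missing:
            raise ValidationError(f"taxonomy missing rank columns: {missing}")
        lineages = lineages.loc[:, list(RANKS)].astype(str)
        lineages = lineages.replace({"": UNASSIGNED})
        arr = lineages.to_numpy()
        unassigned = arr == UNASSIGNED
        for i, asv in enumerate(lineages.index):
            row = unassigned[i]
            if row.any() and not row[np.argmax(row):].all():
                raise ValidationError(
                    f"ASV {asv!r}: assigned rank below an unassigned one"
                )
        self.lineages = lineages

    @property
    def asv_ids(self) -> list[str]:
        return list(self.lineages.index)

    def rank(self, rank: str) -> pd.Series:
        if rank not in RANKS:
            raise ValidationError(f"unknown rank {rank!r}; expected one of {RANKS}")
        return self.lineages[rank]

    def covers(self, table: AsvTable) -> None:
        """Raise unless every ASV in *table* has a lineage."""
        missing = set(table.asv_ids) - set(self.asv_ids)
        if missing:
            raise ValidationError(f"ASVs missing from taxonomy: {sorted(missing)[:5]}")

    def subset(self, asv_ids: Sequence[str]) -> "TaxonomyTable":
        return TaxonomyTable(self.lineages.loc[list(asv_ids)])

    def sorted(self) -> "TaxonomyTable":
        return TaxonomyTable(self.lineages.sort_index())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TaxonomyTable) and self.lineages.equals(other.lineages)


class SampleMetadata:
    """Sample-to-patient map with preservation class (FF / FFPE / NTC).

    Every non-NTC patient id must appear with exactly one FF and one FFPE
    sample; NTC samples carry no patient id.
    """

    def __init__(self, frame: pd.DataFrame):
        _check_unique(frame.index, "sample")
        for col in ("patient_id", "preservation"):
            if col not in frame.columns:
                raise ValidationError(f"metadata missing column {col!r}")
        frame = frame.loc[:, ["patient_id", "preservation"]].copy()
        frame["patient_id"] = frame["patient_id"].fillna("").astype(str)
        bad = set(frame["preservation"]) - set(PRESERVATIONS)
        if bad:
            raise ValidationError(f"unknown preservation class(es): {sorted(bad)}")
        ntc = frame[frame["preservation"] == "NTC"]
        if (ntc["patient_id"] != "").any():
            raise ValidationError("NTC samples must not carry a patient_id")
        tissue = frame[frame["preservation"] != "NTC"]
        if (tissue["patient_id"] == "").any():
            offender = tissue.index[tissue["patient_id"] == ""][0]
            raise ValidationError(f"tissue sample {offender!r} lacks a patient_id")
        for patient, grp in tissue.groupby("patient_id"):
            kinds = sorted(grp["preservation"])
            if kinds != ["FF", "FFPE"]:
                raise ValidationError(
                    f"patient {patient!r} must have exactly one FF and one FFPE "
                    f"sample, got {kinds}"
                )
        self.frame = frame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def preservation(self, sample_id: str) -> str:
        return str(self.frame.loc[sample_id, "preservation"])

    def samples_of(self, preservation: str) -> list[str]:
        return list(self.frame.index[self.frame["preservation"] == preservation])

    def pairs(self) -> dict[str, tuple[str, str]]:
        """patient_id -> (ff_sample, ffpe_sample), patients sorted."""
        tissue = self.frame[self.frame["preservation"] != "NTC"]
        out: dict[str, tuple[str, str]] = {}
        for patient, grp in tissue.groupby("patient_id"):
            ff = grp.index[grp["preservation"] == "FF"][0]
            ffpe = grp.index[grp["preservation"] == "FFPE"][0]
            out[str(patient)] = (str(ff), str(ffpe))
        return dict(sorted(out.items()))

    def ntc_samples(self) -> list[str]:
        return self.samples_of("NTC")

    def sorted(self) -> "SampleMetadata":
        return SampleMetadata(self.frame.sort_index())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SampleMetadata) and self.frame.equals(other.frame)


class DistanceMatrix:
    """Symmetric pairwise dissimilarity matrix tagged with its metric."""

    def __init__(self, values: np.ndarray, sample_ids: Sequence[str], metric: str):
        if metric not in METRICS:
            raise ValidationError(f"unknown metric {metric!r}; expected one of {METRICS}")
        values = np.asarray(values, dtype=float)
        ids = _check_unique(sample_ids, "sample")
        n = len(ids)
        if values.shape != (n, n):
            raise ValidationError(f"distance matrix shape {values.shape} != ({n}, {n})")
        if not np.allclose(values, values.T, atol=1e-12):
            raise ValidationError("distance matrix not symmetric")
        if not np.allclose(np.diag(values), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal not zero")
        if values.size and (values.min() < -1e-12 or values.max() > 1 + 1e-12):
            raise ValidationError("distances must lie in [0, 1]")
        self.values = np.clip((values + values.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(self.values, 0.0)
        self.sample_ids = ids
        self.metric = metric

    def between(self, a: str, b: str) -> float:
        i, j = self.sample_ids.index(a), self.sample_ids.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


@dataclasses.dataclass(frozen=True)
class BlastHit:
    """One row of tabular BLAST output (12 standard columns, optional qcovs)."""

    qseqid: str
    sseqid: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    qcovs: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pident <= 100.0:
            raise ValidationError(f"pident {self.pident} outside [0, 100]")
        if self.qcovs is not None and not 0.0 <= self.qcovs <= 100.0:
            raise ValidationError(f"qcovs {self.qcovs} outside [0, 100]")
        if self.evalue < 0:
            raise ValidationError(f"negative e-value {self.evalue}")

    def coverage(self, query_length: int | None = None) -> float:
        """Query coverage in percent: qcovs if present, else aligned span
        over the supplied query length."""
        if self.qcovs is not None:
            return self.qcovs
        if query_length is None:
            raise ValidationError(
                f"hit for {self.qseqid!r} has no qcovs column and no query "
                "length was supplied; cannot compute coverage"
            )
        return 100.0 * (abs(self.qend - self.qstart) + 1) / query_length


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)


def read_asv_table(path: str | Path) -> AsvTable:
    raw = _read_tsv(path)
    counts = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=np.int64)
    for col in raw.columns:
        for row, cell in raw[col].items():
            try:
                counts.loc[row, col] = int(cell)
            except ValueError:
                raise ParseError(
                    f"non-integer count {cell!r} at ASV {row!r}, sample {col!r} "
                    f"in {path}"
                ) from None
    return AsvTable(counts.astype(np.int64)).sorted()


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    return TaxonomyTable(_read_tsv(path)).sorted()


def read_metadata(path: str | Path) -> SampleMetadata:
    return SampleMetadata(_read_tsv(path)).sorted()


def read_dataset(
    asv_path: str | Path, taxonomy_path: str | Path, metadata_path: str | Path
) -> tuple[AsvTable, TaxonomyTable, SampleMetadata]:
    """Read and cross-validate the count/taxonomy/metadata triple."""
    table = read_asv_table(asv_path)
    tax = read_taxonomy(taxonomy_path)
    meta = read_metadata(metadata_path)
    tax.covers(table)
    extra = set(table.sample_ids) - set(meta.sample_ids)
    if extra:
        raise ValidationError(f"samples missing from metadata: {sorted(extra)}")
    return table, tax, meta


def write_asv_table(table: AsvTable, path: str | Path) -> Path:
    path = Path(path)
    frame = table.sorted().counts
    frame.to_csv(path, sep="\t", index_label="asv_id")
    return path


def write_taxonomy(tax: TaxonomyTable, path: str | Path) -> Path:
    path = Path(path)
    frame = tax.sorted().lineages.replace({UNASSIGNED: ""})
    frame.to_csv(path, sep="\t", index_label="asv_id")
    return path


def write_metadata(meta: SampleMetadata, path: str | Path) -> Path:
    path = Path(path)
    meta.sorted().frame.to_csv(path, sep="\t", index_label="sample_id")
    return path


def write_dataset(
    table: AsvTable,
    tax: TaxonomyTable,
    meta: SampleMetadata,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the triple as asv_table.tsv / taxonomy.tsv / metadata.tsv.

    Row and column order is lexicographic by id, so output is stable
    across runs for equal tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    return {
        "asv_table": write_asv_table(table, outdir / "asv_table.tsv"),
        "taxonomy": write_taxonomy(tax, outdir / "taxonomy.tsv"),
        "metadata": write_metadata(meta, outdir / "metadata.tsv"),
    }


def write_distance_matrix(d: DistanceMatrix, path: str | Path) -> Path:
    path = Path(path)
    d.to_frame().to_csv(path, sep="\t", index_label=f"metric={d.metric}")
    return path


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    raw = pd.read_csv(path, sep="\t", index_col=0)
    label = str(raw.index.name or "")
    metric = label.split("=", 1)[1] if "=" in label else "bray_curtis"
    return DistanceMatrix(raw.to_numpy(dtype=float), list(raw.columns), metric)


def read_blast_hits(path: str | Path) -> list[BlastHit]:
    """Parse 12-column tabular BLAST output, with qcovs as an optional 13th."""
    hits: list[BlastHit] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) not in (12, 13):
            raise ParseError(f"{path}:{lineno}: expected 12 or 13 columns, got {len(parts)}")
        try:
            hits.append(
                BlastHit(
                    qseqid=parts[0],
                    sseqid=parts[1],
                    pident=float(parts[2]),
                    length=int(parts[3]),
                    mismatch=int(parts[4]),
                    gapopen=int(parts[5]),
                    qstart=int(parts[6]),
                    qend=int(parts[7]),
                    sstart=int(parts[8]),
                    send=int(parts[9]),
                    evalue=float(parts[10]),
                    bitscore=float(parts[11]),
                    qcovs=float(parts[12]) if len(parts) == 13 else None,
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
    return hits
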