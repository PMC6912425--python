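"""Readers and writers for the tabular formats used by the pipeline.

All genomic intervals are 0-based half-open internally (the BED
convention).  GTF input (1-based, inclusive) is converted at the boundary
by shifting starts by -1.  Readers validate and reject malformed input
rather than coercing it; every writer/reader pair round-trips.

Column contracts
----------------
counts TSV       feature ids in the first column, one sample per column,
                 non-negative integers.
sample table CSV columns ``sample_id, time_h, stage, assay, target, arm,
                 quality_flag``.
annotation TSV   columns ``gene_id, chrom, strand, start, end, tss,
                 utr5_start, utr5_end, utr3_start, utr3_end``.
BED / narrowPeak >= 3 columns; column 4 is the peak id; extra narrowPeak
                 columns are ignored.
GMT              one set per line: name, description, members (tabs).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from autoreg.errors import ParseError

__all__ = [
    "GeneSetCollection",
    "read_counts", "write_counts",
    "read_sample_table", "write_sample_table",
    "read_annotation_tsv", "write_annotation_tsv",
    "read_gtf_minimal", "write_gtf",
    "read_bed", "write_bed",
    "read_gmt", "write_gmt",
]

ANNOTATION_COLUMNS = [
    "gene_id", "chrom", "strand", "start", "end", "tss",
    "utr5_start", "utr5_end", "utr3_start", "utr3_end",
]


class GeneSetCollection:
    """Named gene sets with free-text descriptions (GMT semantics)."""

    def __init__(self, sets: dict[str, list[str]] | None = None,
                 descriptions: dict[str, str] | None = None) -> None:
        self._sets: dict[str, list[str]] = {}
        self._descriptions: dict[str, str] = {}
        for name, members in (sets or {}).items():
            self.add(name, members, (descriptions or {}).get(name, ""))

    def add(self, name: str, members: list[str], description: str = "") -> None:
        uniq = list(dict.fromkeys(members))
        if len(uniq) != len(members):
            raise ValueError(f"gene set {name!r} contains duplicate member ids")
        self._sets[name] = uniq
        self._descriptions[name] = description

    def __getitem__(self, name: str) -> list[str]:
        return self._sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self):
        return iter(self._sets)

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneSetCollection) and self._sets == other._sets

    def names(self) -> list[str]:
        return list(self._sets)

    def description(self, name: str) -> str:
        return self._descriptions[name]

    def items(self):
        return self._sets.items()


# ---------------------------------------------------------------------------
# count matrices


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a counts TSV into a features x samples integer DataFrame."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    n_cols = len(header)
    if n_cols < 2:
        raise ParseError(f"{path}: header has no sample columns")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        raise ParseError(f"{path}: duplicate sample ids in header")
    feature_ids: list[str] = []
    rows: list[list[int]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != n_cols:
            raise ParseError(
                f"{path}:{lineno}: expected {n_cols} columns, found {len(parts)}"
            )
        feature_ids.append(parts[0])
        row = []
        for value in parts[1:]:
            try:
                x = int(value)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer count {value!r}"
                ) from None
            if x < 0:
                raise ParseError(f"{path}:{lineno}: negative count {x}")
            row.append(x)
        rows.append(row)
    if len(set(feature_ids)) != len(feature_ids):
        seen: set[str] = set()
        dup = next(f for f in feature_ids if f in seen or seen.add(f))
        raise ParseError(f"{path}: duplicate feature id {dup!r}")
    cm = pd.DataFrame(np.asarray(rows, dtype=np.int64),
                      index=pd.Index(feature_ids, name="feature_id"),
                      columns=sample_ids)
    return cm


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    validate_counts(counts)
    counts.to_csv(path, sep="\t", index_label="feature_id")


def validate_counts(counts: pd.DataFrame) -> None:
    """Raise ``ValueError`` when the CountMatrix invariants are violated."""
    if counts.index.duplicated().any():
        raise ValueError("duplicate feature ids")
    if counts.columns.duplicated().any():
        raise ValueError("duplicate sample ids")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        if not np.allclose(values, np.round(values)):
            raise ValueError("counts are not integers")
    if (values < 0).any():
        raise ValueError("negative counts")


# ---------------------------------------------------------------------------
# sample tables


def read_sample_table(path: str | Path) -> pd.DataFrame:
    st = pd.read_csv(path, dtype={"sample_id": str, "stage": str, "assay": str,
                                  "target": str, "arm": str})
    st["quality_flag"] = st["quality_flag"].astype(bool)
    st["time_h"] = st["time_h"].astype(float)
    return st


def write_sample_table(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# gene annotation


def validate_annotation(ann: pd.DataFrame) -> None:
    missing = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing:
        raise ValueError(f"annotation is missing columns: {sorted(missing)}")
    if ann["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ids in annotation")
    if not ann["strand"].isin(["+", "-"]).all():
        bad = ann.loc[~ann["strand"].isin(["+", "-"]), "strand"].unique()
        raise ValueError(f"unknown strand symbol(s): {bad}")
    if (ann["end"] <= ann["start"]).any():
        raise ValueError("gene end <= start")
    plus = ann["strand"] == "+"
    if not (ann.loc[plus, "tss"] == ann.loc[plus, "start"]).all():
        raise ValueError("TSS must equal start on + strand")
    if not (ann.loc[~plus, "tss"] == ann.loc[~plus, "end"]).all():
        raise ValueError("TSS must equal end on - strand")


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    validate_annotation(ann)
    return ann


def write_annotation_tsv(ann: pd.DataFrame, path: str | Path) -> None:
    ann[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gtf_minimal(path: str | Path) -> pd.DataFrame:
    """Parse a minimal GTF (gene + UTR features) into a gene annotation.

    GTF coordinates are 1-based inclusive; they are converted to 0-based
    half-open by shifting starts by -1.  Requires ``gene_id "..."`` in the
    attributes field.
    """
    genes: dict[str, dict] = {}
    utrs: list[tuple[str, str, int, int]] = []
    path = Path(path)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            raise ParseError(f"{path}:{lineno}: expected 9 GTF columns")
        chrom, _source, feature, start1, end1, _score, strand, _frame, attrs = parts
        try:
            start = int(start1) - 1
            end = int(end1)
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
        if end <= start:
            raise ParseError(f"{path}:{lineno}: end <= start after conversion")
        if strand not in ("+", "-"):
            raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
        gene_id = _gtf_attr(attrs, "gene_id")
        if gene_id is None:
            raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
        if feature == "gene":
            genes[gene_id] = {
                "gene_id": gene_id, "chrom": chrom, "strand": strand,
                "start": start, "end": end,
                "tss": start if strand == "+" else end,
                "utr5_start": -1, "utr5_end": -1,
                "utr3_start": -1, "utr3_end": -1,
            }
        elif feature in ("five_prime_utr", "5UTR"):
            utrs.append((gene_id, "utr5", start, end))
        elif feature in ("three_prime_utr", "3UTR"):
            utrs.append((gene_id, "utr3", start, end))
    for gene_id, kind, start, end in utrs:
        if gene_id not in genes:
            raise ParseError(f"{path}: UTR for unknown gene {gene_id!r}")
        genes[gene_id][f"{kind}_start"] = start
        genes[gene_id][f"{kind}_end"] = end
    ann = pd.DataFrame(list(genes.values()), columns=ANNOTATION_COLUMNS)
    validate_annotation(ann)
    return ann


def write_gtf(ann: pd.DataFrame, path: str | Path, source: str = "autoreg") -> None:
    """Write annotation as GTF (gene + UTR features, 1-based inclusive)."""
    lines = []
    for _, g in ann.iterrows():
        attrs = f'gene_id "{g.gene_id}";'
        lines.append("\t".join([
            str(g.chrom), source, "gene", str(int(g.start) + 1), str(int(g.end)),
            ".", g.strand, ".", attrs,
        ]))
        for kind, feat in (("utr5", "five_prime_utr"), ("utr3", "three_prime_utr")):
            s, e = int(g[f"{kind}_start"]), int(g[f"{kind}_end"])
            if s >= 0 and e > s:
                lines.append("\t".join([
                    str(g.chrom), source, feat, str(s + 1), str(e),
                    ".", g.strand, ".", attrs,
                ]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# peaks (BED / narrowPeak)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3/BED6/narrowPeak into a peak table (0-based half-open)."""
    path = Path(path)
    records = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}:{lineno}: fewer than 3 BED columns")
        chrom = parts[0]
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
        if end <= start:
            raise ParseError(f"{path}:{lineno}: end <= start")
        name = parts[3] if len(parts) > 3 else f"peak_{lineno}"
        score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
        strand = parts[5] if len(parts) > 5 else "."
        if strand not in ("+", "-", "."):
            raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
        records.append((name, chrom, start, end, score, strand))
    peaks = pd.DataFrame(records, columns=["peak_id", "chrom", "start", "end",
                                           "score", "strand"])
    if peaks["peak_id"].duplicated().any():
        dup = peaks.loc[peaks["peak_id"].duplicated(), "peak_id"].iloc[0]
        raise ParseError(f"{path}: duplicate peak id {dup!r}")
    return peaks


def write_bed(peaks: pd.DataFrame, path: str | Path,
              name_column: str = "peak_id") -> None:
    """Write a peak table as 6-column BED; *name_column* fills column 4."""
    out = peaks.copy()
    if "score" not in out.columns:
        out["score"] = 0
    if "strand" not in out.columns:
        out["strand"] = "."
    cols = ["chrom", "start", "end", name_column, "score", "strand"]
    out[cols].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path: str | Path) -> GeneSetCollection:
    coll = GeneSetCollection()
    path = Path(path)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}:{lineno}: GMT line needs name, description "
                             "and at least one member")
        name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
        if name in coll:
            raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
        try:
            coll.add(name, members, desc)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for name, members in coll.items():
        if not members:
            warnings.warn(f"gene set {name!r} is empty; omitted from GMT")
            continue
        lines.append("\t".join([name, coll.description(name), *members]))
    Path(path).write_text("\n".join(lines) + "\n")


def _gtf_attr(attrs: str, key: str) -> str | None:
    for field in attrs.split(";"):
        field = field.strip()
        if field.startswith(key + " "):
            return field[len(key):].strip().strip('"')
    return None
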