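"""Readers and writers for the formats the pipeline touches.

Formats: GenomeDiff (breseq's tab-delimited mutation description format),
GFF3 genome annotation, expression-matrix TSV with sample sheet and probe
map, and long-format growth-curve / halo tables.

Coordinates are 1-based inclusive on disk (GFF3 and GenomeDiff convention)
and 0-based half-open in memory; conversion happens only here, at the I/O
boundary. Readers validate and raise rather than silently coerce.
"""

from __future__ import annotations

import dataclasses
import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO

#: GenomeDiff three-letter mutation codes this pipeline interprets.
MUTATION_TYPES = ("SNP", "INS", "DEL", "SUB", "MOB", "AMP")

#: Columns following ``type id parent_ids`` for each parsed entry type.
_GD_FIELDS: dict[str, tuple[str, ...]] = {
    "SNP": ("seqid", "position", "new_seq"),
    "INS": ("seqid", "position", "new_seq"),
    "DEL": ("seqid", "position", "size"),
    "SUB": ("seqid", "position", "size", "new_seq"),
    "MOB": ("seqid", "position", "repeat_name", "strand", "duplication_size"),
    "AMP": ("seqid", "position", "size", "new_copy_number"),
}
_GD_INT_FIELDS = {"position", "size", "strand", "duplication_size", "new_copy_number"}


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


@dataclass
class MutationRecord:
    """One GenomeDiff entry (mutation or opaque evidence line).

    ``position`` is 0-based internally. ``raw_fields`` is set only for entry
    types outside :data:`MUTATION_TYPES`, which are carried verbatim.
    """

    type: str
    record_id: str = "."
    parent_ids: str = "."
    seqid: str | None = None
    position: int | None = None
    lineage: str | None = None
    new_seq: str | None = None
    size: int | None = None
    repeat_name: str | None = None
    strand: int | None = None
    duplication_size: int | None = None
    new_copy_number: int | None = None
    extra: dict[str, str] = field(default_factory=dict)
    raw_fields: tuple[str, ...] | None = None
    # annotation slots, filled by evomex.mutations
    target: str | None = None
    relation: str | None = None
    coding_effect: str | None = None

    @property
    def is_mutation(self) -> bool:
        return self.type in MUTATION_TYPES

    @property
    def end(self) -> int | None:
        """Exclusive end of the affected reference interval."""
        if self.position is None:
            return None
        if self.type in ("DEL", "SUB", "AMP") and self.size is not None:
            return self.position + self.size
        return self.position + 1

    @property
    def mutant_read_fraction(self) -> float | None:
        """Fraction of reads supporting the mutant allele, if recorded.

        Derived from ``new_read_count`` / ``ref_read_count`` key-value pairs
        when both are present, else from a ``frequency`` pair.
        """
        new = self.extra.get("new_read_count")
        ref = self.extra.get("ref_read_count")
        if new is not None and ref is not None:
            new_n, ref_n = float(new), float(ref)
            if new_n + ref_n == 0:
                return None
            return new_n / (new_n + ref_n)
        freq = self.extra.get("frequency")
        return float(freq) if freq is not None else None

    def allele_key(self) -> tuple:
        """Identity of the allele irrespective of lineage and bookkeeping ids."""
        return (
            self.type,
            self.seqid,
            self.position,
            self.new_seq,
            self.size,
            self.repeat_name,
            self.strand,
            self.new_copy_number,
        )


@dataclass(frozen=True)
class Feature:
    """A genome feature with 0-based half-open coordinates."""

    feature_id: str
    type: str
    seqid: str
    start: int
    end: int
    strand: str = "."
    locus_tag: str | None = None
    product: str | None = None
    attributes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.feature_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"feature {self.feature_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end


@dataclass
class GenomeAnnotation:
    """Sequence regions plus features; optionally the region sequences."""

    regions: dict[str, int]
    features: list[Feature] = field(default_factory=list)
    sequences: dict[str, str] | None = None

    def __post_init__(self) -> None:
        for feat in self.features:
            length = self.regions.get(feat.seqid)
            if length is None:
                raise ValueError(f"feature {feat.feature_id}: unknown region {feat.seqid}")
            if feat.end > length:
                raise ValueError(
                    f"feature {feat.feature_id}: end {feat.end} beyond region "
                    f"length {length}"
                )

    def features_of_type(self, *types: str) -> list[Feature]:
        return [f for f in self.features if f.type in types]

    def genes(self) -> list[Feature]:
        return self.features_of_type("gene", "CDS")

    def overlapping(self, seqid: str, start: int, end: int) -> list[Feature]:
        """Features overlapping the 0-based half-open interval [start, end)."""
        return [
            f
            for f in self.features
            if f.seqid == seqid and f.start < end and f.end > start
        ]

    def contains_position(self, seqid: str, position: int) -> bool:
        length = self.regions.get(seqid)
        return length is not None and 0 <= position < length


# ---------------------------------------------------------------------------
# GenomeDiff
# ---------------------------------------------------------------------------

def read_genomediff(path: str | Path, lineage: str | None = None) -> list[MutationRecord]:
    """Parse a GenomeDiff file into :class:`MutationRecord` entries.

    Entry types outside :data:`MUTATION_TYPES` (evidence lines such as RA or
    MC, or newer mutation codes) are preserved as opaque records and survive
    a write/read round trip unchanged.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("#=GENOME_DIFF"):
        raise ParseError(f"{path}: line 1: missing '#=GENOME_DIFF' header")
    records: list[MutationRecord] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}: line {lineno}: fewer than 3 columns")
        etype, rec_id, parents = fields[0], fields[1], fields[2]
        if etype not in _GD_FIELDS:
            records.append(
                MutationRecord(
                    type=etype,
                    record_id=rec_id,
                    parent_ids=parents,
                    raw_fields=tuple(fields[3:]),
                    lineage=lineage,
                )
            )
            continue
        names = _GD_FIELDS[etype]
        positional = fields[3 : 3 + len(names)]
        if len(positional) < len(names):
            raise ParseError(
                f"{path}: line {lineno}: {etype} entry needs {len(names)} "
                f"positional columns, got {len(positional)}"
            )
        kwargs: dict = {"type": etype, "record_id": rec_id, "parent_ids": parents}
        for name, value in zip(names, positional):
            if name in _GD_INT_FIELDS:
                try:
                    parsed: int | str = int(value)
                except ValueError as exc:
                    raise ParseError(
                        f"{path}: line {lineno}: column {name} not an integer: {value!r}"
                    ) from exc
                kwargs[name] = parsed
            else:
                kwargs[name] = value
        kwargs["position"] = kwargs["position"] - 1  # to 0-based
        extra: dict[str, str] = {}
        for token in fields[3 + len(names) :]:
            if "=" not in token:
                raise ParseError(
                    f"{path}: line {lineno}: trailing column {token!r} is not key=value"
                )
            key, _, value = token.partition("=")
            extra[key] = value
        records.append(MutationRecord(lineage=lineage, extra=extra, **kwargs))
    return records


def write_genomediff(
    path: str | Path,
    records: Iterable[MutationRecord],
    provenance: str | None = None,
) -> None:
    path = Path(path)
    out = ["#=GENOME_DIFF\t1.0"]
    if provenance:
        out.append(f"#=COMMENT\t{provenance}")
    for rec in records:
        if rec.raw_fields is not None:
            out.append("\t".join([rec.type, rec.record_id, rec.parent_ids, *rec.raw_fields]))
            continue
        if not rec.is_mutation:
            raise ValueError(f"cannot serialise record of type {rec.type!r}")
        fields = [rec.type, rec.record_id, rec.parent_ids]
        for name in _GD_FIELDS[rec.type]:
            value = getattr(rec, name)
            if value is None:
                raise ValueError(f"{rec.type} record missing field {name}")
            if name == "position":
                value = value + 1  # back to 1-based
            fields.append(str(value))
        fields.extend(f"{k}={v}" for k, v in sorted(rec.extra.items()))
        out.append("\t".join(fields))
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# GFF3 + FASTA
# ---------------------------------------------------------------------------

_FEATURE_ATTRS = ("ID", "locus_tag", "product", "family", "Name")


def read_gff3(path: str | Path, fasta: str | Path | None = None) -> GenomeAnnotation:
    """Load a GFF3 file (and optional FASTA) into a :class:`GenomeAnnotation`."""
    path = Path(path)
    directives = [
        line[2:].strip()
        for line in path.read_text().splitlines()
        if line.startswith("##") and not line.startswith("###")
    ]
    regions: dict[str, int] = {}
    for directive in directives:
        if directive.startswith("sequence-region"):
            parts = directive.split()
            if len(parts) != 4:
                raise ParseError(f"{path}: malformed directive '##{directive}'")
            regions[parts[1]] = int(parts[3])
    features: list[Feature] = []
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
        db_features = list(db.all_features(order_by=("seqid", "start")))
    except gffutils.exceptions.EmptyInputError:
        db_features = []  # a header-only file is a valid, featureless annotation
    for feat in db_features:
        attrs = {k: feat.attributes[k][0] for k in feat.attributes if feat.attributes[k]}
        if feat.seqid not in regions:
            # tolerate files without sequence-region pragmas
            regions[feat.seqid] = max(regions.get(feat.seqid, 0), feat.end)
        features.append(
            Feature(
                feature_id=feat.id,
                type=feat.featuretype,
                seqid=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else ".",
                locus_tag=attrs.get("locus_tag"),
                product=attrs.get("product"),
                attributes=attrs,
            )
        )
    sequences = None
    if fasta is not None:
        sequences = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
        for seqid, seq in sequences.items():
            regions.setdefault(seqid, len(seq))
    return GenomeAnnotation(regions=regions, features=features, sequences=sequences)


def write_gff3(
    path: str | Path,
    annotation: GenomeAnnotation,
    provenance: str | None = None,
) -> None:
    path = Path(path)
    out = ["##gff-version 3"]
    if provenance:
        out.append(f"# {provenance}")
    for seqid, length in annotation.regions.items():
        out.append(f"##sequence-region {seqid} 1 {length}")
    for feat in annotation.features:
        attrs = dict(feat.attributes)
        attrs.setdefault("ID", feat.feature_id)
        if feat.locus_tag:
            attrs.setdefault("locus_tag", feat.locus_tag)
        if feat.product:
            attrs.setdefault("product", feat.product)
        attr_str = ";".join(f"{k}={v}" for k, v in attrs.items())
        out.append(
            "\t".join(
                [
                    feat.seqid,
                    "evomex",
                    feat.type,
                    str(feat.start + 1),
                    str(feat.end),
                    ".",
                    feat.strand,
                    ".",
                    attr_str,
                ]
            )
        )
    path.write_text("\n".join(out) + "\n")


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for seqid, seq in sequences.items():
            fh.write(f">{seqid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """log2 intensities (probes x samples) with sample sheet and probe map."""

    values: pd.DataFrame
    samples: pd.DataFrame  # indexed by sample; columns: group, lineage
    probe_map: pd.Series  # probe -> locus

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        dup_rows = self.values.index[self.values.index.duplicated()].tolist()
        if dup_rows:
            raise ValueError(f"duplicate probe ids: {sorted(set(dup_rows))}")
        dup_cols = self.values.columns[self.values.columns.duplicated()].tolist()
        if dup_cols:
            raise ValueError(f"duplicate sample ids: {sorted(set(dup_cols))}")
        missing_samples = [s for s in self.values.columns if s not in self.samples.index]
        if missing_samples:
            raise ValueError(f"samples missing from sample sheet: {missing_samples}")
        unmapped = [p for p in self.values.index if p not in self.probe_map.index]
        if unmapped:
            raise ValueError(f"probes missing from probe map: {unmapped}")

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.samples["group"]))

    def group_columns(self, group: str) -> list[str]:
        cols = [s for s in self.values.columns if self.samples.loc[s, "group"] == group]
        if not cols:
            raise KeyError(f"no samples in group {group!r}")
        return cols

    def group_values(self, group: str) -> pd.DataFrame:
        return self.values[self.group_columns(group)]


def read_expression(
    matrix_path: str | Path,
    samplesheet_path: str | Path,
    probemap_path: str | Path,
) -> ExpressionMatrix:
    values = pd.read_csv(
        matrix_path, sep="\t", index_col=0, comment="#", float_precision="round_trip"
    )
    samples = pd.read_csv(samplesheet_path, index_col=0, comment="#", dtype=str)
    if "group" not in samples.columns:
        raise ParseError(f"{samplesheet_path}: sample sheet needs a 'group' column")
    if "lineage" not in samples.columns:
        samples["lineage"] = ""
    samples["lineage"] = samples["lineage"].fillna("")
    probe_map = pd.read_csv(probemap_path, sep="\t", index_col=0, comment="#").iloc[:, 0]
    return ExpressionMatrix(values=values, samples=samples, probe_map=probe_map)


def write_expression(
    matrix: ExpressionMatrix,
    matrix_path: str | Path,
    samplesheet_path: str | Path,
    probemap_path: str | Path,
    provenance: str | None = None,
) -> None:
    _write_table(matrix.values, matrix_path, sep="\t", provenance=provenance)
    _write_table(matrix.samples, samplesheet_path, sep=",", provenance=provenance)
    _write_table(matrix.probe_map.to_frame("locus"), probemap_path, sep="\t", provenance=provenance)


def _write_table(
    frame: pd.DataFrame,
    path: str | Path,
    sep: str = "\t",
    provenance: str | None = None,
    index: bool = True,
) -> None:
    buf = _stdio.StringIO()
    if provenance:
        buf.write(f"# {provenance}\n")
    frame.to_csv(buf, sep=sep, index=index)
    Path(path).write_text(buf.getvalue())


def write_table(
    frame: pd.DataFrame,
    path: str | Path,
    sep: str = "\t",
    provenance: str | None = None,
    index: bool = True,
) -> None:
    """Write a DataFrame with an optional '#'-prefixed provenance header."""
    _write_table(frame, path, sep=sep, provenance=provenance, index=index)


def read_table(path: str | Path, sep: str = "\t", index_col=None) -> pd.DataFrame:
    return pd.read_csv(
        path, sep=sep, comment="#", index_col=index_col, float_precision="round_trip"
    )


def records_to_frame(records: Sequence[MutationRecord]) -> pd.DataFrame:
    """Tabular view of mutation records (annotated fields included)."""
    rows = [dataclasses.asdict(rec) for rec in records]
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame = frame.drop(columns=["extra", "raw_fields"])
    return frame
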