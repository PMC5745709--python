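"""Readers/writers for the external formats and the annotation data model.

Everything downstream consumes these types:

* :class:`SequenceRecord` — a (possibly circular) nucleotide sequence.
* :class:`FeatureAnnotation` — one annotated feature in 0-based half-open
  coordinates; origin-wrapping features on circular sequences are encoded
  with ``end > genome length`` (reduced mod length on use).
* :class:`DepthTrack` — per-base read depth.

On disk: FASTA for sequences (circularity declared with a ``circular=true``
header token), a 9-column GFF3-subset tab table for features (1-based
inclusive coordinates, ``label=``/``paralog_tag=`` attributes), and a
4-column BED-like table for depth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "SequenceRecord",
    "FeatureAnnotation",
    "DepthTrack",
    "FastaParseError",
    "FeatureTableError",
    "FEATURE_CLASSES",
    "read_fasta",
    "write_fasta",
    "read_feature_table",
    "write_feature_table",
    "read_depth_track",
    "extract_feature_sequence",
    "reverse_complement",
    "json_report",
]

TOOL_VERSION = "0.1.0"

FEATURE_CLASSES = frozenset(
    {"protein", "rRNA", "tRNA", "spacer", "control_region", "pseudogene"}
)

_VALID_RESIDUES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class FastaParseError(ValueError):
    """Malformed FASTA input; message names the offending line."""


class FeatureTableError(ValueError):
    """Malformed feature-table input."""


@dataclass(frozen=True)
class SequenceRecord:
    """A nucleotide sequence over {A,C,G,T,N}, optionally circular."""

    identifier: str
    residues: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"empty sequence for record {self.identifier!r}")
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            raise ValueError(
                f"illegal residue(s) {sorted(bad)} in record {self.identifier!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class FeatureAnnotation:
    """One annotated feature, 0-based half-open, strand +1/-1.

    ``end > genome length`` is legal only on circular sequences and means
    the feature wraps the origin; the effective end is ``end % length``.
    """

    seq_id: str
    label: str
    feature_class: str
    start: int
    end: int
    strand: int = 1
    paralog_tag: str | None = None

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise FeatureTableError(
                f"unknown feature class {self.feature_class!r} for {self.label!r}"
            )
        if self.strand not in (1, -1):
            raise ValueError(f"strand must be +1 or -1, got {self.strand!r}")
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"bad span [{self.start}, {self.end}) for {self.label!r}"
            )

    @property
    def span_length(self) -> int:
        return self.end - self.start

    def wraps_origin(self, genome_length: int) -> bool:
        return self.end > genome_length


@dataclass(frozen=True)
class DepthTrack:
    """Per-position read depth for one sequence."""

    seq_id: str
    depths: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.depths):
            raise ValueError("depths must be non-negative")

    def __len__(self) -> int:
        return len(self.depths)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse a FASTA file into :class:`SequenceRecord` objects.

    Residues are uppercased and U is mapped to T.  A ``circular=true``
    token in the header description marks the record circular.  Duplicate
    identifiers, headerless leading sequence, and residues outside
    {A,C,G,T,N,U} raise :class:`FastaParseError` naming the line number.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    ident: str | None = None
    circular = False
    chunks: list[str] = []

    def flush(line_no: int) -> None:
        nonlocal ident, circular, chunks
        if ident is None:
            return
        residues = "".join(chunks)
        if not residues:
            raise FastaParseError(f"{path}: record {ident!r} has no sequence")
        records.append(SequenceRecord(ident, residues, circular))
        ident, circular, chunks = None, False, []

    with open(path) as handle:
        for line_no, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no)
                header = line[1:].strip()
                if not header:
                    raise FastaParseError(f"{path}: empty header at line {line_no}")
                tokens = header.split()
                ident = tokens[0]
                if ident in seen:
                    raise FastaParseError(
                        f"{path}: duplicate identifier {ident!r} at line {line_no}"
                    )
                seen.add(ident)
                circular = any(t.lower() == "circular=true" for t in tokens[1:])
            else:
                if ident is None:
                    raise FastaParseError(
                        f"{path}: sequence before any header at line {line_no}"
                    )
                seq = line.upper().replace("U", "T")
                bad = set(seq) - _VALID_RESIDUES
                if bad:
                    raise FastaParseError(
                        f"{path}: illegal residue(s) {sorted(bad)} at line {line_no}"
                    )
                chunks.append(seq)
    flush(-1)
    if not records:
        raise FastaParseError(f"{path}: no records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as handle:
        for rec in records:
            header = f">{rec.identifier}"
            if rec.circular:
                header += " circular=true"
            handle.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                handle.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Feature tables (GFF3 subset)

_GFF_COLUMNS = 9


def read_feature_table(path: str | Path) -> list[FeatureAnnotation]:
    """Read a tab-delimited GFF3-subset feature table.

    Columns: seqid, source, type, start (1-based inclusive), end, score,
    strand, frame, attributes.  The type column holds the feature class;
    attributes carry ``label=`` and optional ``paralog_tag=``.  Coordinates
    are converted to 0-based half-open; ``end < start`` rows are rejected
    (origin-wrapping is encoded as end > genome length, which keeps
    end >= start).
    """
    path = Path(path)
    features: list[FeatureAnnotation] = []
    with open(path) as handle:
        for line_no, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _GFF_COLUMNS:
                raise FeatureTableError(
                    f"{path}: expected {_GFF_COLUMNS} columns at line {line_no}, got {len(cols)}"
                )
            seqid, _source, ftype, start_s, end_s, _score, strand_s, _frame, attrs = cols
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise FeatureTableError(
                    f"{path}: non-integer coordinate at line {line_no}"
                ) from exc
            if start1 < 1 or end1 < start1:
                raise FeatureTableError(
                    f"{path}: bad coordinates {start1}..{end1} at line {line_no} "
                    "(origin-wrapping features use end > genome length)"
                )
            if strand_s not in ("+", "-"):
                raise FeatureTableError(
                    f"{path}: strand must be + or - at line {line_no}"
                )
            attr_map = _parse_attributes(attrs, path, line_no)
            label = attr_map.get("label")
            if not label:
                raise FeatureTableError(f"{path}: missing label attribute at line {line_no}")
            features.append(
                FeatureAnnotation(
                    seq_id=seqid,
                    label=label,
                    feature_class=ftype,
                    start=start1 - 1,
                    end=end1,
                    strand=1 if strand_s == "+" else -1,
                    paralog_tag=attr_map.get("paralog_tag"),
                )
            )
    return features


def _parse_attributes(attrs: str, path: Path, line_no: int) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in attrs.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise FeatureTableError(
                f"{path}: malformed attribute {chunk!r} at line {line_no}"
            )
        key, value = chunk.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def write_feature_table(features: Iterable[FeatureAnnotation], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for feat in features:
            attrs = f"label={feat.label}"
            if feat.paralog_tag:
                attrs += f";paralog_tag={feat.paralog_tag}"
            handle.write(
                "\t".join(
                    [
                        feat.seq_id,
                        "mitodrl",
                        feat.feature_class,
                        str(feat.start + 1),
                        str(feat.end),
                        ".",
                        "+" if feat.strand == 1 else "-",
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Depth tracks

def read_depth_track(path: str | Path, genome_length: int, seq_id: str | None = None) -> DepthTrack:
    """Read a 4-column BED-like depth table (seqid, start, end, depth).

    Intervals are 0-based half-open and must tile [0, genome_length)
    without overlap; positions not covered default to depth 0.
    """
    path = Path(path)
    depths = [0] * genome_length
    track_id: str | None = seq_id
    with open(path) as handle:
        for line_no, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise ValueError(f"{path}: expected 4 columns at line {line_no}")
            sid, start_s, end_s, depth_s = cols
            if track_id is None:
                track_id = sid
            elif sid != track_id:
                continue
            start, end, depth = int(start_s), int(end_s), int(depth_s)
            if depth < 0 or start < 0 or end > genome_length or end <= start:
                raise ValueError(f"{path}: bad interval at line {line_no}")
            for i in range(start, end):
                depths[i] = depth
    if track_id is None:
        raise ValueError(f"{path}: empty depth track")
    return DepthTrack(track_id, tuple(depths))


# ---------------------------------------------------------------------------
# Feature sequence extraction

def extract_feature_sequence(record: SequenceRecord, feature: FeatureAnnotation) -> str:
    """Return the feature's nucleotide sequence from ``record``.

    Minus-strand features are reverse-complemented.  On circular records a
    span with ``end > len(record)`` wraps the origin and is concatenated
    across it.
    """
    n = len(record)
    if feature.start >= n:
        raise ValueError(
            f"feature {feature.label!r} start {feature.start} beyond sequence length {n}"
        )
    if feature.end <= n:
        seq = record.residues[feature.start : feature.end]
    else:
        if not record.circular:
            raise ValueError(
                f"feature {feature.label!r} runs off the end of linear sequence "
                f"{record.identifier!r}"
            )
        wrapped_end = feature.end % n
        seq = record.residues[feature.start :] + record.residues[:wrapped_end]
    if feature.strand == -1:
        seq = reverse_complement(seq)
    return seq


# ---------------------------------------------------------------------------
# JSON reports

def json_report(
    inputs: dict,
    parameters: dict,
    results: dict,
    path: str | Path | None = None,
) -> dict:
    """Assemble (and optionally write) the fixed-schema JSON report."""
    report = {
        "tool_version": TOOL_VERSION,
        "inputs": inputs,
        "parameters": parameters,
        "results": results,
    }
    if path is not None:
        with open(path, "w") as handle:
            json.dump(report, handle, indent=2, sort_keys=True)
            handle.write("\n")
    return report
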