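"""Synthetic annotated mitogenomes evolving under duplication-random-loss.

The generator builds a circular vertebrate-style mitochondrial genome
(13 protein-coding + 2 rRNA + 22 tRNA genes in the typical order, plus an
intergenic spacer and control region), applies tandem duplication of a
contiguous gene arc, evolves chosen features under a Jukes-Cantor
substitution process with Poisson indels, and applies large segmental
deletions — recording every event in a :class:`TruthRecord` whose replay
reproduces the final genome byte-for-byte.

Internally an annotated genome is a list of :class:`Segment` objects that
tile the circle exactly; features never leave gaps, so duplication and
deletion are exact sequence surgery.  All randomness flows from one seeded
``numpy`` generator per run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome_io import (
    FeatureAnnotation,
    SequenceRecord,
    reverse_complement,
    write_fasta,
    write_feature_table,
)
from .gene_order import DRLScenario, GeneOrder, replay_scenario

__all__ = [
    "GenomeSpec",
    "MutationParams",
    "TruthRecord",
    "Segment",
    "TYPICAL_VERTEBRATE_ORDER",
    "make_reference_genome",
    "apply_duplication",
    "evolve",
    "apply_segmental_deletion",
    "simulate_dataset",
    "simulate_aneides_scenario",
    "plant_edits",
    "evolve_jc_pair",
    "random_drl_order_scenario",
    "segments_from",
    "segments_to_record",
]

_BASES = np.array(list("ACGT"))

#: the typical vertebrate mitochondrial order: (label, feature class, strand).
#: ND6 and eight tRNAs lie on the minus strand; an intergenic spacer (IGS)
#: between trnT and trnP and the control region (CR) complete the circle.
TYPICAL_VERTEBRATE_ORDER: tuple[tuple[str, str, int], ...] = (
    ("trnF", "tRNA", 1),
    ("rrnS", "rRNA", 1),
    ("trnV", "tRNA", 1),
    ("rrnL", "rRNA", 1),
    ("trnL2", "tRNA", 1),
    ("ND1", "protein", 1),
    ("trnI", "tRNA", 1),
    ("trnQ", "tRNA", -1),
    ("trnM", "tRNA", 1),
    ("ND2", "protein", 1),
    ("trnW", "tRNA", 1),
    ("trnA", "tRNA", -1),
    ("trnN", "tRNA", -1),
    ("trnC", "tRNA", -1),
    ("trnY", "tRNA", -1),
    ("COX1", "protein", 1),
    ("trnS2", "tRNA", -1),
    ("trnD", "tRNA", 1),
    ("COX2", "protein", 1),
    ("trnK", "tRNA", 1),
    ("ATP8", "protein", 1),
    ("ATP6", "protein", 1),
    ("COX3", "protein", 1),
    ("trnG", "tRNA", 1),
    ("ND3", "protein", 1),
    ("trnR", "tRNA", 1),
    ("ND4L", "protein", 1),
    ("ND4", "protein", 1),
    ("trnH", "tRNA", 1),
    ("trnS1", "tRNA", 1),
    ("trnL1", "tRNA", 1),
    ("ND5", "protein", 1),
    ("ND6", "protein", -1),
    ("trnE", "tRNA", -1),
    ("CYTB", "protein", 1),
    ("trnT", "tRNA", 1),
    ("IGS", "spacer", 1),
    ("trnP", "tRNA", -1),
    ("CR", "control_region", 1),
)

GENE_CLASSES = frozenset({"protein", "rRNA", "tRNA"})

from .paralog_decay import MITO_START_CODONS, MITO_STOP_CODONS


@dataclass(frozen=True)
class GenomeSpec:
    """Composition of the synthetic reference mitogenome."""

    n_protein: int = 13
    n_rrna: int = 2
    n_trna: int = 22
    protein_length: tuple[int, int] = (300, 1800)
    rrna_length: tuple[int, int] = (800, 1700)
    trna_length: tuple[int, int] = (65, 75)
    spacer_length: tuple[int, int] = (40, 120)
    control_region_length: tuple[int, int] = (800, 1500)
    circular: bool = True
    #: optional per-label length overrides (protein lengths are rounded to
    #: a multiple of 3)
    gene_lengths: tuple[tuple[str, int], ...] = ()
    #: label the order starts at (representation only; the genome is circular)
    start_label: str = "trnF"

    def __post_init__(self) -> None:
        for lo, hi in (
            self.protein_length,
            self.rrna_length,
            self.trna_length,
            self.spacer_length,
            self.control_region_length,
        ):
            if lo < 1 or hi < lo:
                raise ValueError("length ranges must be positive and ordered")


@dataclass(frozen=True)
class MutationParams:
    """Per-site substitution and indel rates for :func:`evolve`."""

    substitution_rate: float = 0.02
    indel_rate: float = 0.001
    indel_mean_length: float = 2.0
    insertion_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.substitution_rate < 0 or self.indel_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.indel_mean_length < 1:
            raise ValueError("geometric indel mean must be >= 1")


@dataclass
class Segment:
    """One feature occupying a contiguous stretch of the genome.

    ``seq`` is stored in genome orientation; minus-strand coding sequences
    are the reverse complement of ``seq``.
    """

    label: str
    feature_class: str
    strand: int
    seq: str
    paralog_tag: str | None = None
    status: str = "intact"  # intact | pseudogene | deleted

    @property
    def key(self) -> tuple[str, str | None]:
        return (self.label, self.paralog_tag)

    def coding_seq(self) -> str:
        return reverse_complement(self.seq) if self.strand == -1 else self.seq


@dataclass
class TruthRecord:
    """Ground truth for one simulated history.

    ``events`` is the ordered list of sequence-level operations; replaying
    them on the ancestral residues reproduces the final residues exactly
    (:meth:`replay`).  ``edit_counts`` accumulates planted edits per
    (label, paralog_tag).
    """

    duplicated_span: tuple[str, ...] = ()
    events: list[dict] = field(default_factory=list)
    edit_counts: dict[tuple[str, str | None], dict[str, int]] = field(default_factory=dict)
    segmental_deletions: list[tuple[int, int]] = field(default_factory=list)
    final_status: dict[tuple[str, str | None], str] = field(default_factory=dict)

    def bump(self, key: tuple[str, str | None], **deltas: int) -> None:
        counts = self.edit_counts.setdefault(
            key,
            {
                "substitutions": 0,
                "insertion_events": 0,
                "insertion_bp": 0,
                "deletion_events": 0,
                "deletion_bp": 0,
            },
        )
        for k, v in deltas.items():
            counts[k] += v

    def extend(self, other: "TruthRecord") -> None:
        if other.duplicated_span and not self.duplicated_span:
            self.duplicated_span = other.duplicated_span
        self.events.extend(other.events)
        for key, counts in other.edit_counts.items():
            self.bump(key, **counts)
        self.segmental_deletions.extend(other.segmental_deletions)
        self.final_status.update(other.final_status)

    @staticmethod
    def replay(ancestral_residues: str, events: Sequence[dict]) -> str:
        """Apply the recorded events in order; byte-exact reconstruction."""
        seq = ancestral_residues
        for ev in events:
            kind = ev["type"]
            if kind == "duplication":
                s, e = ev["start"], ev["end"]
                seq = seq[:e] + seq[s:e] + seq[e:]
            elif kind == "substitution":
                p = ev["pos"]
                if seq[p] != ev["ref"]:
                    raise ValueError(f"replay mismatch at {p}: {seq[p]} != {ev['ref']}")
                seq = seq[:p] + ev["alt"] + seq[p + 1 :]
            elif kind == "insertion":
                p = ev["pos"]
                seq = seq[:p] + ev["seq"] + seq[p:]
            elif kind == "deletion":
                p, L = ev["pos"], ev["length"]
                if seq[p : p + L] != ev["seq"]:
                    raise ValueError(f"replay deletion mismatch at {p}")
                seq = seq[:p] + seq[p + L :]
            elif kind == "segmental_deletion":
                s, e = ev["start"], ev["end"]
                if seq[s:e] != ev["seq"]:
                    raise ValueError(f"replay segmental deletion mismatch at {s}")
                seq = seq[:s] + seq[e:]
            elif kind == "rotation":
                k = ev["offset"]
                seq = seq[k:] + seq[:k]
            else:
                raise ValueError(f"unknown event type {kind!r}")
        return seq

    def to_json(self) -> dict:
        return {
            "duplicated_span": list(self.duplicated_span),
            "events": self.events,
            "edit_counts": {
                f"{label}|{tag or ''}": counts
                for (label, tag), counts in self.edit_counts.items()
            },
            "segmental_deletions": [list(r) for r in self.segmental_deletions],
            "final_status": {
                f"{label}|{tag or ''}": status
                for (label, tag), status in self.final_status.items()
            },
        }


# ---------------------------------------------------------------------------
# Segment <-> (record, features) conversion

def segments_to_record(
    segments: Sequence[Segment], identifier: str, circular: bool = True
) -> tuple[SequenceRecord, list[FeatureAnnotation]]:
    residues = "".join(seg.seq for seg in segments)
    features = []
    pos = 0
    for seg in segments:
        fclass = "pseudogene" if seg.status == "pseudogene" else seg.feature_class
        features.append(
            FeatureAnnotation(
                seq_id=identifier,
                label=seg.label,
                feature_class=fclass,
                start=pos,
                end=pos + len(seg.seq),
                strand=seg.strand,
                paralog_tag=seg.paralog_tag,
            )
        )
        pos += len(seg.seq)
    return SequenceRecord(identifier, residues, circular), features


def segments_from(
    record: SequenceRecord, features: Sequence[FeatureAnnotation]
) -> list[Segment]:
    """Rebuild the segment view; features must tile the genome exactly."""
    feats = sorted(features, key=lambda f: f.start)
    pos = 0
    segments = []
    for f in feats:
        if f.start != pos:
            raise ValueError(
                f"features do not tile the genome: gap/overlap at {pos} vs {f.start}"
            )
        if f.end > len(record):
            raise ValueError("origin-wrapping features not supported in the simulator")
        segments.append(
            Segment(
                label=f.label,
                feature_class=f.feature_class,
                strand=f.strand,
                seq=record.residues[f.start : f.end],
                paralog_tag=f.paralog_tag,
                status="pseudogene" if f.feature_class == "pseudogene" else "intact",
            )
        )
        pos = f.end
    if pos != len(record):
        raise ValueError("features do not cover the genome end")
    return segments


# ---------------------------------------------------------------------------
# Reference genome

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _random_protein_gene(rng: np.random.Generator, length: int) -> str:
    """A valid ORF: start codon, no internal stop, terminal stop codon."""
    if length % 3:
        raise ValueError("protein gene length must be a multiple of 3")
    n_codons = length // 3
    if n_codons < 3:
        raise ValueError("protein gene must have at least 3 codons")
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = _random_seq(rng, 3)
        if c not in MITO_STOP_CODONS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _draw_length(rng: np.random.Generator, lo_hi: tuple[int, int]) -> int:
    lo, hi = lo_hi
    return int(rng.integers(lo, hi + 1))


def make_reference_genome(
    spec: GenomeSpec | None = None,
    seed: int = 0,
    identifier: str = "ref_mito",
) -> tuple[SequenceRecord, list[FeatureAnnotation]]:
    """Build the circular 37-gene vertebrate-style reference mitogenome.

    Protein genes are valid ORFs under the vertebrate mitochondrial code;
    the same spec and seed always give byte-identical output.
    """
    if spec is None:
        spec = GenomeSpec()
    rng = np.random.default_rng(seed)
    overrides = dict(spec.gene_lengths)
    order = list(TYPICAL_VERTEBRATE_ORDER)
    if spec.start_label not in [lab for lab, _, _ in order]:
        raise ValueError(f"unknown start label {spec.start_label!r}")
    while order[0][0] != spec.start_label:
        order.append(order.pop(0))

    n_prot = sum(1 for _, c, _ in order if c == "protein")
    n_rrna = sum(1 for _, c, _ in order if c == "rRNA")
    n_trna = sum(1 for _, c, _ in order if c == "tRNA")
    if (n_prot, n_rrna, n_trna) != (spec.n_protein, spec.n_rrna, spec.n_trna):
        raise ValueError(
            "GenomeSpec gene counts must match the built-in vertebrate template "
            f"(13/2/22), got {spec.n_protein}/{spec.n_rrna}/{spec.n_trna}"
        )

    # lengths are drawn in template order (not rotated order) so the same
    # seed yields the same gene sequences regardless of start_label
    lengths: dict[str, int] = {}
    seqs: dict[str, str] = {}
    for label, fclass, _strand in TYPICAL_VERTEBRATE_ORDER:
        if fclass == "protein":
            L = overrides.get(label, _draw_length(rng, spec.protein_length))
            L -= L % 3
            seqs[label] = _random_protein_gene(rng, max(L, 9))
        elif fclass == "rRNA":
            L = overrides.get(label, _draw_length(rng, spec.rrna_length))
            seqs[label] = _random_seq(rng, L)
        elif fclass == "tRNA":
            L = overrides.get(label, _draw_length(rng, spec.trna_length))
            seqs[label] = _random_seq(rng, L)
        elif fclass == "spacer":
            L = overrides.get(label, _draw_length(rng, spec.spacer_length))
            seqs[label] = _random_seq(rng, L)
        else:  # control region
            L = overrides.get(label, _draw_length(rng, spec.control_region_length))
            seqs[label] = _random_seq(rng, L)
        lengths[label] = len(seqs[label])

    segments = []
    for label, fclass, strand in order:
        seq = seqs[label]
        if strand == -1:
            seq = reverse_complement(seq)
        segments.append(Segment(label, fclass, strand, seq))
    return segments_to_record(segments, identifier, circular=spec.circular)


# ---------------------------------------------------------------------------
# Tandem duplication

def apply_duplication(
    record: SequenceRecord,
    features: Sequence[FeatureAnnotation],
    span: Sequence[str],
) -> tuple[SequenceRecord, list[FeatureAnnotation], TruthRecord]:
    """Duplicate the contiguous arc of features named in ``span`` in tandem.

    The span sequence is inserted immediately after itself; duplicated
    features are tagged ``copy1``/``copy2`` and downstream coordinates
    shift by the span length.  ``span`` labels must name a contiguous run
    of the annotated order (not wrapping the origin of the representation).
    """
    segments = segments_from(record, features)
    labels = [seg.label for seg in segments]
    span = list(span)
    idx = _find_contiguous(labels, span)
    truth = TruthRecord(duplicated_span=tuple(span))
    start_bp = sum(len(s.seq) for s in segments[: idx])
    end_bp = start_bp + sum(len(s.seq) for s in segments[idx : idx + len(span)])
    truth.events.append({"type": "duplication", "start": start_bp, "end": end_bp})
    copy1 = []
    copy2 = []
    for seg in segments[idx : idx + len(span)]:
        copy1.append(replace(seg, paralog_tag="copy1"))
        copy2.append(replace(seg, paralog_tag="copy2"))
    new_segments = segments[:idx] + copy1 + copy2 + segments[idx + len(span) :]
    rec, feats = segments_to_record(new_segments, record.identifier, record.circular)
    return rec, feats, truth


def _find_contiguous(labels: Sequence[str], span: Sequence[str]) -> int:
    n, k = len(labels), len(span)
    for i in range(n - k + 1):
        if list(labels[i : i + k]) == list(span):
            return i
    raise ValueError(f"span {span} is not a contiguous arc of the annotated order")


# ---------------------------------------------------------------------------
# Sequence evolution

def evolve(
    record: SequenceRecord,
    features: Sequence[FeatureAnnotation],
    params: MutationParams,
    targets: Iterable[tuple[str, str | None]],
    rng: np.random.Generator,
    mark_pseudogene: bool = False,
    plant_premature_stop: bool = False,
) -> tuple[SequenceRecord, list[FeatureAnnotation], TruthRecord]:
    """Mutate the targeted features in place on the genome.

    Substitutions are Jukes-Cantor (each site independently, uniform choice
    among the three other bases); indel events are Poisson with geometric
    lengths (mean ``indel_mean_length``).  Every edit is recorded with its
    genome coordinate at application time, so replay is exact.  Targets are
    ``(label, paralog_tag)`` keys; ``plant_premature_stop`` forces one
    in-frame TAA early in each targeted protein gene for deterministic
    loss-of-function tests.
    """
    segments = segments_from(record, features)
    target_set = {tuple(t) for t in targets}
    truth = TruthRecord()
    for seg_idx, seg in enumerate(segments):
        if seg.key not in target_set:
            continue
        offset = sum(len(s.seq) for s in segments[:seg_idx])
        seq = seg.seq
        # --- substitutions
        if params.substitution_rate > 0:
            hits = np.nonzero(
                rng.random(len(seq)) < params.substitution_rate
            )[0]
            chars = list(seq)
            for p in hits:
                old = chars[p]
                alts = [b for b in "ACGT" if b != old]
                new = alts[int(rng.integers(0, 3))]
                truth.events.append(
                    {"type": "substitution", "pos": int(offset + p), "ref": old, "alt": new}
                )
                chars[p] = new
            if len(hits):
                truth.bump(seg.key, substitutions=int(len(hits)))
            seq = "".join(chars)
        # --- indels (applied right-to-left so earlier positions stay valid)
        if params.indel_rate > 0:
            n_events = int(rng.poisson(params.indel_rate * len(seq)))
            positions = sorted(
                (int(rng.integers(0, len(seq) + 1)) for _ in range(n_events)),
                reverse=True,
            )
            p_geom = 1.0 / params.indel_mean_length
            for p in positions:
                L = int(rng.geometric(p_geom))
                if rng.random() < params.insertion_fraction:
                    ins = _random_seq(rng, L)
                    truth.events.append(
                        {"type": "insertion", "pos": int(offset + p), "seq": ins}
                    )
                    truth.bump(seg.key, insertion_events=1, insertion_bp=L)
                    seq = seq[:p] + ins + seq[p:]
                else:
                    L = min(L, len(seq) - p)
                    if L <= 0:
                        continue
                    truth.events.append(
                        {
                            "type": "deletion",
                            "pos": int(offset + p),
                            "length": L,
                            "seq": seq[p : p + L],
                        }
                    )
                    truth.bump(seg.key, deletion_events=1, deletion_bp=L)
                    seq = seq[:p] + seq[p + L :]
        # --- forced premature stop (deterministic loss-of-function)
        if plant_premature_stop and seg.feature_class == "protein":
            coding = reverse_complement(seq) if seg.strand == -1 else seq
            codon_idx = max(1, (len(coding) // 3) // 4)
            cp = 3 * codon_idx
            new_coding = coding[:cp] + "TAA" + coding[cp + 3 :]
            new_seq = (
                reverse_complement(new_coding) if seg.strand == -1 else new_coding
            )
            for rel, (old, new) in enumerate(zip(seq, new_seq)):
                if old != new:
                    truth.events.append(
                        {"type": "substitution", "pos": int(offset + rel), "ref": old, "alt": new}
                    )
                    truth.bump(seg.key, substitutions=1)
            seq = new_seq
        seg.seq = seq
        if mark_pseudogene:
            seg.status = "pseudogene"
        truth.final_status[seg.key] = seg.status
    rec, feats = segments_to_record(segments, record.identifier, record.circular)
    return rec, feats, truth


# ---------------------------------------------------------------------------
# Segmental deletion

def apply_segmental_deletion(
    record: SequenceRecord,
    features: Sequence[FeatureAnnotation],
    region: tuple[int, int],
) -> tuple[SequenceRecord, list[FeatureAnnotation], TruthRecord]:
    """Excise ``region`` (0-based half-open genome coordinates).

    Features fully inside the region become status "deleted" (dropped from
    the annotation, recorded in the truth); features partially overlapping
    are truncated and marked pseudogene candidates.  A zero-length region
    is the identity; deleting the whole genome is an error.
    """
    start, end = region
    n = len(record)
    if not (0 <= start <= end <= n):
        raise ValueError(f"region {region} outside genome of length {n}")
    if end - start >= n:
        raise ValueError("cannot delete the entire genome")
    truth = TruthRecord()
    if end == start:
        return record, list(features), truth
    segments = segments_from(record, features)
    truth.events.append(
        {
            "type": "segmental_deletion",
            "start": start,
            "end": end,
            "seq": record.residues[start:end],
        }
    )
    truth.segmental_deletions.append((start, end))
    new_segments: list[Segment] = []
    pos = 0
    for seg in segments:
        s0, s1 = pos, pos + len(seg.seq)
        pos = s1
        if s1 <= start or s0 >= end:
            new_segments.append(seg)
            continue
        if s0 >= start and s1 <= end:
            truth.final_status[seg.key] = "deleted"
            truth.bump(seg.key, deletion_events=1, deletion_bp=len(seg.seq))
            continue
        # partial overlap: truncate and flag
        kept = seg.seq[: max(0, start - s0)] + seg.seq[max(0, start - s0) + (min(s1, end) - max(s0, start)) :]
        removed = (min(s1, end) - max(s0, start))
        truncated = replace(seg, seq=kept)
        if truncated.feature_class in GENE_CLASSES:
            truncated.status = "pseudogene"
            truth.final_status[truncated.key] = "pseudogene"
        truth.bump(seg.key, deletion_events=1, deletion_bp=removed)
        new_segments.append(truncated)
    rec, feats = segments_to_record(new_segments, record.identifier, record.circular)
    return rec, feats, truth


# ---------------------------------------------------------------------------
# Deterministic edit planting (bypasses the aligner to build truth alignments)

def plant_edits(
    reference: str,
    n_substitutions: int = 0,
    insertion_lengths: Sequence[int] = (),
    deletion_lengths: Sequence[int] = (),
    rng: np.random.Generator | None = None,
    min_gap: int = 8,
) -> tuple[str, str, str]:
    """Plant well-separated edits into ``reference``.

    Returns ``(mutated, row_ref, row_qry)`` where the two rows are the truth
    alignment built by replaying the edits (no aligner involved).  Edits
    are placed at least ``min_gap`` unedited sites apart, deletions are
    pinned so their gaps cannot slide, and inserted bases differ from both
    flanks; the default spacing keeps nearby insertion/deletion pairs from
    collapsing into an equal-scoring run of substitutions, so an optimal
    aligner recovers the planted counts exactly.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    n_edits = n_substitutions + len(insertion_lengths) + len(deletion_lengths)
    footprint = n_substitutions + sum(deletion_lengths)
    space_needed = footprint + (n_edits + 1) * min_gap
    if space_needed > len(reference):
        raise ValueError("reference too short for the requested edits")

    kinds = (
        ["sub"] * n_substitutions
        + [("ins", L) for L in insertion_lengths]
        + [("del", L) for L in deletion_lengths]
    )
    order = rng.permutation(len(kinds))
    kinds = [kinds[i] for i in order]

    # choose edit anchor positions left to right with spacing; deletion
    # anchors additionally avoid flanks that would let the gap slide to an
    # equal-scoring alignment
    sizes = [1 if k == "sub" else (k[1] if k[0] == "del" else 0) for k in kinds]
    anchors = []
    cursor = min_gap
    free = len(reference) - space_needed
    per_edit = free // max(1, len(kinds))
    for kind, size in zip(kinds, sizes):
        jump = int(rng.integers(0, min(per_edit, free) + 1)) if free > 0 else 0
        free -= jump
        cursor += jump
        if kind != "sub" and kind[0] == "del":
            L = kind[1]
            while free > 0 and not _deletion_is_pinned(reference, cursor, L):
                cursor += 1
                free -= 1
            if not _deletion_is_pinned(reference, cursor, L):
                raise ValueError("could not place a slide-proof deletion")
        anchors.append(cursor)
        cursor += size + min_gap

    row_ref: list[str] = []
    row_qry: list[str] = []
    pos = 0
    for kind, anchor in zip(kinds, anchors):
        row_ref.extend(reference[pos:anchor])
        row_qry.extend(reference[pos:anchor])
        pos = anchor
        if kind == "sub":
            old = reference[pos]
            alts = [b for b in "ACGT" if b != old]
            new = alts[int(rng.integers(0, 3))]
            row_ref.append(old)
            row_qry.append(new)
            pos += 1
        elif kind[0] == "ins":
            L = kind[1]
            flanks = {reference[pos], reference[pos - 1] if pos else ""}
            choices = [b for b in "ACGT" if b not in flanks]
            ins = "".join(
                choices[int(rng.integers(0, len(choices)))] for _ in range(L)
            )
            row_ref.extend("-" * L)
            row_qry.extend(ins)
        else:
            L = kind[1]
            row_ref.extend(reference[pos : pos + L])
            row_qry.extend("-" * L)
            pos += L
    row_ref.extend(reference[pos:])
    row_qry.extend(reference[pos:])
    ref_row = "".join(row_ref)
    qry_row = "".join(row_qry)
    return qry_row.replace("-", ""), ref_row, qry_row


def _deletion_is_pinned(reference: str, p: int, L: int) -> bool:
    """True when deleting reference[p:p+L] admits no equal-score gap slide
    (flanking bases differ from the run's ends)."""
    if p <= 0 or p + L >= len(reference):
        return False
    return reference[p - 1] != reference[p + L - 1] and reference[p] != reference[p + L]


def evolve_jc_pair(
    length: int, distance: float, rng: np.random.Generator
) -> tuple[str, str]:
    """Two sequences at expected JC distance ``distance``.

    A root sequence evolves independently down two branches of length
    d/2 each; per-branch substitutions are Poisson per site with uniform
    base choice (multiple hits allowed), i.e. the JC process itself.
    """
    root = _random_seq(rng, length)
    return _evolve_branch(root, distance / 2, rng), _evolve_branch(
        root, distance / 2, rng
    )


def evolve_jc_groups(
    length: int,
    d_between: float,
    d_within: float,
    n_per_group: int,
    rng: np.random.Generator,
) -> tuple[list[str], list[str]]:
    """Two groups of sequences with planted between-group JC divergence.

    Two group ancestors separated by ``d_between - d_within`` expected
    substitutions per site; each tip hangs off its ancestor on a branch of
    ``d_within / 2``, so expected between-group pairwise divergence is
    ``d_between`` and within-group divergence is ``d_within``.
    """
    if d_within > d_between:
        raise ValueError("within-group divergence cannot exceed between-group")
    root = _random_seq(rng, length)
    t_anc = (d_between - d_within) / 2
    anc_a = _evolve_branch(root, t_anc, rng)
    anc_b = _evolve_branch(root, t_anc, rng)
    tip = d_within / 2
    group_a = [_evolve_branch(anc_a, tip, rng) for _ in range(n_per_group)]
    group_b = [_evolve_branch(anc_b, tip, rng) for _ in range(n_per_group)]
    return group_a, group_b


def _evolve_branch(seq: str, branch_length: float, rng: np.random.Generator) -> str:
    chars = list(seq)
    n_events = rng.poisson(branch_length * len(seq))
    for _ in range(n_events):
        p = int(rng.integers(0, len(chars)))
        alts = [b for b in "ACGT" if b != chars[p]]
        chars[p] = alts[int(rng.integers(0, 3))]
    return "".join(chars)


# ---------------------------------------------------------------------------
# Order-level random DRL scenarios (for the inference test battery)

def random_drl_order_scenario(
    n: int, rng: np.random.Generator
) -> tuple[GeneOrder, DRLScenario, GeneOrder]:
    """Random ancestral order of ``n`` uniquely labelled genes, a random
    single-DRL scenario, and the derived order from forward replay."""
    labels = [f"g{i}" for i in range(n)]
    order = GeneOrder(tuple((lab, 1) for lab in labels), circular=True)
    start = int(rng.integers(0, n))
    length = int(rng.integers(1, n + 1))
    retention = []
    psi = []
    for j in range(length):
        r = ["first", "second", "both", "remnant"][int(rng.integers(0, 4))]
        retention.append(r)
        if r == "remnant":
            psi.append((j, int(rng.integers(1, 3))))
    scenario = DRLScenario(
        span=(start, length), retention=tuple(retention), pseudogene_copy=tuple(psi)
    )
    derived = replay_scenario(order, scenario)
    return order, scenario, derived


# ---------------------------------------------------------------------------
# Dataset presets

#: representative gene lengths used by the preset so the planted decay
#: numbers live on realistically sized genes
_ANEIDES_GENE_LENGTHS = (
    ("ND6", 519),
    ("ND1", 960),
    ("rrnS", 930),
    ("trnV", 70),
    ("rrnL", 1520),
    ("trnL2", 73),
    ("trnF", 70),
    ("trnE", 70),
    ("trnP", 69),
    ("CYTB", 1140),
    ("trnT", 72),
    ("IGS", 80),
    ("CR", 1000),
)


@dataclass
class AneidesSimulation:
    """Everything the two-event salamander-style preset produced."""

    reference: SequenceRecord
    reference_features: list[FeatureAnnotation]
    after_event1: SequenceRecord
    after_event1_features: list[FeatureAnnotation]
    final: SequenceRecord
    final_features: list[FeatureAnnotation]
    truth: TruthRecord
    span1: tuple[str, ...]
    span2: tuple[str, ...]


def simulate_aneides_scenario(
    seed: int = 0,
    decay_params: MutationParams | None = None,
) -> AneidesSimulation:
    """Two-event history mirroring the genus-level and within-species
    duplications: a basal duplication of (ND6, trnE, CYTB, trnT, IGS, trnP)
    resolving to the derived order with CYTB preceding ND6, then a recent
    duplication of the (ND6 ... ND1) arc with pseudogenization of one ND6
    and one ND1 copy, near-complete deletion of the duplicate rRNA block
    (111-bp remnant), and intact duplicate tRNAs.
    """
    rng = np.random.default_rng(seed)
    if decay_params is None:
        decay_params = MutationParams(substitution_rate=0.02, indel_rate=0.0015)
    spec = GenomeSpec(gene_lengths=_ANEIDES_GENE_LENGTHS, start_label="trnI")
    ref, ref_feats = make_reference_genome(spec, seed=seed, identifier="sim_mito")
    truth = TruthRecord()

    # ---- event 1 (basal): duplicate ND6..trnP, excise copy1 ND6+trnE and
    # copy2 CYTB+trnT, decay copy1 trnP to a recognizable pseudogene
    span1 = ("ND6", "trnE", "CYTB", "trnT", "IGS", "trnP")
    rec, feats, t = apply_duplication(ref, ref_feats, span1)
    truth.extend(t)
    rec, feats = _excise_features(rec, feats, [("ND6", "copy1"), ("trnE", "copy1")], truth)
    rec, feats = _excise_features(rec, feats, [("CYTB", "copy2"), ("trnT", "copy2")], truth)
    rec, feats, t = evolve(
        rec,
        feats,
        MutationParams(substitution_rate=0.08, indel_rate=0.002),
        targets=[("trnP", "copy1")],
        rng=rng,
        mark_pseudogene=True,
    )
    truth.extend(t)
    # surviving copies of the basal event keep their tags cleared so the
    # recent event can re-tag its own copies
    rec, feats = _clear_tags(rec, feats, keep_psi=True)
    after1, after1_feats = rec, feats

    # ---- event 2 (recent, within-species): duplicate ND6..ND1
    span2 = (
        "ND6", "trnE", "IGS", "trnP", "CR", "trnF",
        "rrnS", "trnV", "rrnL", "trnL2", "ND1",
    )
    rec, feats, t = apply_duplication(rec, feats, span2)
    truth.extend(t)

    # pseudogenize copy1 ND6: substitutions + one short insertion
    rec, feats, t = evolve(
        rec, feats,
        MutationParams(substitution_rate=0.02, indel_rate=0.0),
        targets=[("ND6", "copy1")], rng=rng,
        mark_pseudogene=True, plant_premature_stop=True,
    )
    truth.extend(t)
    rec, feats, t = _planted_insertion(rec, feats, ("ND6", "copy1"), 2, rng)
    truth.extend(t)

    # truncate copy1 ND1 to its first 682 bp, then decay it
    rec, feats, t = _truncate_feature_to(rec, feats, ("ND1", "copy1"), keep=682)
    truth.extend(t)
    rec, feats, t = evolve(
        rec, feats, decay_params,
        targets=[("ND1", "copy1")], rng=rng,
        mark_pseudogene=True, plant_premature_stop=True,
    )
    truth.extend(t)

    # near-complete deletion of the duplicate rRNA block: keep only a
    # 111-bp remnant of (rrnS + trnV + rrnL) copy1, decayed beyond
    # recognition
    rec, feats, t = _delete_rrna_block(rec, feats, remnant=111, rng=rng)
    truth.extend(t)

    # light decay on the duplicated tRNA copies that stay functional
    rec, feats, t = evolve(
        rec, feats,
        MutationParams(substitution_rate=0.015, indel_rate=0.0),
        targets=[("trnL2", "copy1"), ("trnF", "copy1")], rng=rng,
    )
    truth.extend(t)

    for f in feats:
        key = (f.label, f.paralog_tag)
        truth.final_status.setdefault(
            key, "pseudogene" if f.feature_class == "pseudogene" else "intact"
        )
    return AneidesSimulation(
        reference=ref,
        reference_features=ref_feats,
        after_event1=after1,
        after_event1_features=after1_feats,
        final=rec,
        final_features=feats,
        truth=truth,
        span1=span1,
        span2=span2,
    )


def _feature_region(
    record: SequenceRecord,
    features: Sequence[FeatureAnnotation],
    keys: Sequence[tuple[str, str | None]],
) -> tuple[int, int]:
    sel = [f for f in features if (f.label, f.paralog_tag) in set(keys)]
    if len(sel) != len(keys):
        raise ValueError(f"features {keys} not found exactly once each")
    start = min(f.start for f in sel)
    end = max(f.end for f in sel)
    return start, end


def _excise_features(record, features, keys, truth: TruthRecord):
    region = _feature_region(record, features, keys)
    rec, feats, t = apply_segmental_deletion(record, features, region)
    truth.extend(t)
    return rec, feats


def _clear_tags(record, features, keep_psi=True):
    segments = segments_from(record, features)
    for seg in segments:
        seg.paralog_tag = None
    return segments_to_record(segments, record.identifier, record.circular)


def _planted_insertion(record, features, key, length, rng):
    segments = segments_from(record, features)
    truth = TruthRecord()
    offset = 0
    for seg in segments:
        if seg.key == key:
            p = len(seg.seq) // 2
            ins = _random_seq(rng, length)
            truth.events.append(
                {"type": "insertion", "pos": offset + p, "seq": ins}
            )
            truth.bump(key, insertion_events=1, insertion_bp=length)
            seg.seq = seg.seq[:p] + ins + seg.seq[p:]
            break
        offset += len(seg.seq)
    rec, feats = segments_to_record(segments, record.identifier, record.circular)
    return rec, feats, truth


def _truncate_feature_to(record, features, key, keep: int):
    """Drop everything after the first ``keep`` coding bases of a feature."""
    segments = segments_from(record, features)
    offset = 0
    for seg in segments:
        if seg.key == key:
            if len(seg.seq) <= keep:
                return record, list(features), TruthRecord()
            if seg.strand == -1:
                region = (offset, offset + len(seg.seq) - keep)
            else:
                region = (offset + keep, offset + len(seg.seq))
            return apply_segmental_deletion(record, features, region)
        offset += len(seg.seq)
    raise ValueError(f"feature {key} not found")


def _delete_rrna_block(record, features, remnant: int, rng: np.random.Generator):
    keys = [("rrnS", "copy1"), ("trnV", "copy1"), ("rrnL", "copy1")]
    start, end = _feature_region(record, features, keys)
    if end - start <= remnant:
        raise ValueError("rRNA block shorter than requested remnant")
    rec, feats, truth = apply_segmental_deletion(record, features, (start, end - remnant))
    # the remnant decays beyond recognition
    segments = segments_from(rec, feats)
    for seg in segments:
        if seg.key == ("rrnL", "copy1"):
            seg.label = "REP_rrn"
            seg.feature_class = "spacer"
            seg.status = "intact"
            seg.paralog_tag = None
    rec2, feats2 = segments_to_record(segments, rec.identifier, rec.circular)
    rec2, feats2, t = evolve(
        rec2, feats2,
        MutationParams(substitution_rate=0.6, indel_rate=0.0),
        targets=[("REP_rrn", None)], rng=rng,
    )
    truth.extend(t)
    return rec2, feats2, truth


# ---------------------------------------------------------------------------
# File-emitting driver

def simulate_dataset(config: Mapping, seed: int, outdir: str | Path) -> list[dict]:
    """Write FASTA + feature table + truth JSON per replicate.

    ``config`` keys: ``preset`` ("aneides" or "reference"), ``replicates``
    (default 1).  Identical config and seed give byte-identical files.
    Returns one manifest dict per replicate.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    preset = config.get("preset", "reference")
    n_rep = int(config.get("replicates", 1))
    manifests = []
    for i in range(n_rep):
        rep_seed = (seed + 1009 * i) % (2**31)
        stem = outdir / f"rep{i:03d}"
        if preset == "aneides":
            sim = simulate_aneides_scenario(seed=rep_seed)
            record, feats, truth = sim.final, sim.final_features, sim.truth
            ancestral_fasta = str(stem) + ".ancestral.fasta"
            extra = {
                "span1": list(sim.span1),
                "span2": list(sim.span2),
                "ancestral_fasta": Path(ancestral_fasta).name,
            }
            write_fasta([sim.reference], ancestral_fasta)
        elif preset == "reference":
            record, feats = make_reference_genome(seed=rep_seed)
            truth = TruthRecord()
            extra = {}
        else:
            raise ValueError(f"unknown preset {preset!r}")
        fasta = str(stem) + ".fasta"
        gff = str(stem) + ".gff"
        tjson = str(stem) + ".truth.json"
        write_fasta([record], fasta)
        write_feature_table(feats, gff)
        with open(tjson, "w") as fh:
            json.dump({**truth.to_json(), **extra}, fh, indent=2)
            fh.write("\n")
        manifests.append(
            {"fasta": fasta, "features": gff, "truth": tjson, "seed": rep_seed}
        )
    return manifests
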