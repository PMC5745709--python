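"""Circular gene orders and single tandem-duplication–random-loss inference.

A :class:`GeneOrder` is an ordered sequence of ``(label, strand)`` elements,
circular by default for mitochondrial genomes.  Pseudogene copies carry a
``psi_`` prefix on the label (helpers :func:`mark_pseudogene`,
:func:`base_label`, :func:`is_pseudogene`).

The duplication-random-loss (DRL) model: a contiguous arc of genes is
duplicated in tandem, then for each gene one copy (or neither) is deleted;
the surviving-copy pattern determines the final order.
:func:`infer_single_drl` recovers every containment-minimal duplicated span
that explains a derived order by a single DRL event, verifying each
candidate by forward replay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy.stats import trim_mean

from .genome_io import DepthTrack, FeatureAnnotation

__all__ = [
    "GeneOrder",
    "DRLScenario",
    "PSEUDOGENE_PREFIX",
    "mark_pseudogene",
    "base_label",
    "is_pseudogene",
    "extract_gene_order",
    "canonicalize",
    "orders_equivalent",
    "infer_single_drl",
    "replay_scenario",
    "depth_ratio",
]

PSEUDOGENE_PREFIX = "psi_"

#: default canonicalization anchor: tRNA-Phe, the conventional first gene of
#: the vertebrate mitochondrial order
DEFAULT_ANCHOR = "trnF"

Element = tuple[str, int]


def mark_pseudogene(label: str) -> str:
    return label if label.startswith(PSEUDOGENE_PREFIX) else PSEUDOGENE_PREFIX + label


def base_label(label: str) -> str:
    return label[len(PSEUDOGENE_PREFIX):] if label.startswith(PSEUDOGENE_PREFIX) else label


def is_pseudogene(label: str) -> bool:
    return label.startswith(PSEUDOGENE_PREFIX)


@dataclass(frozen=True)
class GeneOrder:
    """Strand-signed ordered sequence of gene labels, optionally circular."""

    elements: tuple[Element, ...]
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("GeneOrder must be non-empty")
        for label, strand in self.elements:
            if strand not in (1, -1):
                raise ValueError(f"strand must be +1/-1 for {label!r}")

    def __len__(self) -> int:
        return len(self.elements)

    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.elements)

    def rotated(self, k: int) -> "GeneOrder":
        if not self.circular:
            raise ValueError("cannot rotate a linear order")
        k %= len(self.elements)
        return GeneOrder(self.elements[k:] + self.elements[:k], circular=True)


@dataclass(frozen=True)
class DRLScenario:
    """One single-DRL explanation of a derived order.

    ``span`` is ``(start index, length)`` on the ancestral order.
    ``retention`` maps each span offset (0..length-1) to one of
    ``first``/``second``/``both``/``remnant``; for ``remnant`` positions
    ``pseudogene_copy`` records which tandem copy (1 or 2) decayed to a
    pseudogene.  ``identity_consistent`` is true when forward replay
    reproduces the ancestral order itself.
    """

    span: tuple[int, int]
    retention: tuple[str, ...]
    pseudogene_copy: tuple[tuple[int, int], ...] = ()
    identity_consistent: bool = False

    def __post_init__(self) -> None:
        if self.span[1] < 1:
            raise ValueError("span length must be >= 1")
        if len(self.retention) != self.span[1]:
            raise ValueError("retention must cover every span position")
        for r in self.retention:
            if r not in ("first", "second", "both", "remnant"):
                raise ValueError(f"bad retention value {r!r}")


# ---------------------------------------------------------------------------
# Extraction from annotations

_OVERLAP_TOLERANCE = 10
_STRICT_CLASSES = frozenset({"protein", "rRNA", "tRNA"})


def extract_gene_order(
    features: Sequence[FeatureAnnotation],
    genome_length: int,
    circular: bool = True,
    include_repeats: bool = True,
    anchor: str = DEFAULT_ANCHOR,
) -> GeneOrder:
    """Build the canonical :class:`GeneOrder` from annotated features.

    Features are sorted by start position around the circle; pseudogene
    features enter the order with the ``psi_`` label mark.  Two features of
    class protein/rRNA/tRNA overlapping by more than 10 bp raise an error
    (annotated pseudogene/spacer overlaps are tolerated).  Set
    ``include_repeats=False`` to drop spacer/control-region elements, e.g.
    when unrecognizable repeat tracts should not participate in inference.
    """
    if not features:
        raise ValueError("no features supplied")
    seq_ids = {f.seq_id for f in features}
    if len(seq_ids) > 1:
        raise ValueError(f"features span multiple sequences: {sorted(seq_ids)}")
    feats = sorted(features, key=lambda f: (f.start, f.end))
    for a, b in zip(feats, feats[1:]):
        if (
            a.feature_class in _STRICT_CLASSES
            and b.feature_class in _STRICT_CLASSES
            and a.end - b.start > _OVERLAP_TOLERANCE
        ):
            raise ValueError(
                f"features {a.label!r} and {b.label!r} overlap by {a.end - b.start} bp"
            )
    elements: list[Element] = []
    for f in feats:
        if not include_repeats and f.feature_class in ("spacer", "control_region"):
            continue
        label = mark_pseudogene(f.label) if f.feature_class == "pseudogene" else f.label
        elements.append((label, f.strand))
    if not elements:
        raise ValueError("no order elements after filtering")
    return canonicalize(GeneOrder(tuple(elements), circular=circular), anchor=anchor)


# ---------------------------------------------------------------------------
# Canonical form & equivalence

def canonicalize(order: GeneOrder, anchor: str = DEFAULT_ANCHOR) -> GeneOrder:
    """Rotate a circular order to its canonical starting element.

    The order starts at the anchor label (default ``trnF``) if present,
    otherwise at the lexicographically smallest label; among tied starting
    positions the rotation with the lexicographically smallest element tuple
    wins, so the result is rotation-invariant and idempotent.  Linear orders
    are returned unchanged.
    """
    if not order.circular or len(order) == 1:
        return order
    labels = order.labels()
    start_label = anchor if anchor in labels else min(labels)
    candidates = [
        order.rotated(i).elements
        for i, lab in enumerate(labels)
        if lab == start_label
    ]
    return GeneOrder(min(candidates), circular=True)


def orders_equivalent(a: GeneOrder, b: GeneOrder) -> bool:
    """Rotation-invariant equality of labels and strands."""
    if a.circular != b.circular or len(a) != len(b):
        return False
    if not a.circular:
        return a.elements == b.elements
    # anchor-free minimal rotation, so equivalence never depends on the anchor
    return _min_rotation(a.elements) == _min_rotation(b.elements)


def _min_rotation(elements: tuple[Element, ...]) -> tuple[Element, ...]:
    n = len(elements)
    return min(elements[i:] + elements[:i] for i in range(n))


# ---------------------------------------------------------------------------
# Single-DRL inference

def replay_scenario(ancestral: GeneOrder, scenario: DRLScenario) -> GeneOrder:
    """Apply a DRL scenario forward: tandem-duplicate the span, then keep
    the copies its retention map dictates (pseudogene copies get the
    ``psi_`` mark).  Returns the resulting order, rotated so the block of
    surviving span copies sits where the ancestral span began."""
    n = len(ancestral)
    s, length = scenario.span
    if not 1 <= length <= n:
        raise ValueError("span length out of range")
    span_elems = [ancestral.elements[(s + j) % n] for j in range(length)]
    psi_copy = dict(scenario.pseudogene_copy)
    copy1: list[Element] = []
    copy2: list[Element] = []
    for j, (elem, ret) in enumerate(zip(span_elems, scenario.retention)):
        label, strand = elem
        if ret in ("first", "both"):
            copy1.append((label, strand))
        if ret in ("second", "both"):
            copy2.append((label, strand))
        if ret == "remnant":
            which = psi_copy.get(j)
            if which not in (1, 2):
                raise ValueError(
                    f"remnant position {j} needs pseudogene_copy of 1 or 2"
                )
            marked = (mark_pseudogene(label), strand)
            if which == 1:
                copy1.append(marked)
                copy2.append((label, strand))
            else:
                copy1.append((label, strand))
                copy2.append(marked)
    rest = [ancestral.elements[(s + length + j) % n] for j in range(n - length)]
    return GeneOrder(tuple(copy1 + copy2 + rest), circular=ancestral.circular)


def infer_single_drl(ancestral: GeneOrder, derived: GeneOrder) -> list[DRLScenario]:
    """Find every containment-minimal single-DRL scenario turning
    ``ancestral`` into ``derived``.

    The derived order must be obtainable by duplicating one contiguous arc
    in tandem and deleting (or pseudogenizing) per-gene copies; pseudogene
    copies in ``derived`` carry the ``psi_`` label mark.  Any strand
    difference for a shared label rejects the pair (DRL does not invert
    genes).  An empty list means no single DRL event explains the
    derivation; a label in ``derived`` absent from ``ancestral`` raises.
    """
    anc_labels = ancestral.labels()
    if len(set(anc_labels)) != len(anc_labels):
        raise ValueError("DRL inference requires unique labels in the ancestral order")
    anc_index = {lab: i for i, lab in enumerate(anc_labels)}
    anc_strand = {lab: st for lab, st in ancestral.elements}
    for lab, st in derived.elements:
        base = base_label(lab)
        if base not in anc_index:
            raise ValueError(f"label {base!r} present in derived but not ancestral")
        if st != anc_strand[base]:
            return []  # strand changes are outside the DRL model

    if not ancestral.circular:
        # embed linear orders in a circle with a sentinel pinning the ends;
        # spans never include the sentinel, so linear semantics are exact
        sentinel = ("__linear_end__", 1)
        anc_c = GeneOrder(ancestral.elements + (sentinel,), circular=True)
        der_c = GeneOrder(derived.elements + (sentinel,), circular=True)
        out = []
        for scen in infer_single_drl(anc_c, der_c):
            start, length = scen.span
            if length <= len(ancestral) and all(
                (start + j) % len(anc_c) != len(ancestral) for j in range(length)
            ):
                out.append(scen)
        return out

    n = len(ancestral)
    scenarios: list[DRLScenario] = []
    for start in range(n):
        for length in range(1, n + 1):
            scen = _try_span(ancestral, derived, start, length)
            if scen is not None:
                scenarios.append(scen)
    return _minimal_spans(scenarios, n, ancestral.circular)


def _try_span(
    ancestral: GeneOrder, derived: GeneOrder, start: int, length: int
) -> DRLScenario | None:
    n = len(ancestral)
    anc_labels = ancestral.labels()
    span_labels = [anc_labels[(start + j) % n] for j in range(length)]
    span_pos = {lab: j for j, lab in enumerate(span_labels)}
    out_labels = [anc_labels[(start + length + j) % n] for j in range(n - length)]

    counts: dict[str, int] = {}
    marked_counts: dict[str, int] = {}
    for lab, _ in derived.elements:
        b = base_label(lab)
        counts[b] = counts.get(b, 0) + 1
        if is_pseudogene(lab):
            marked_counts[b] = marked_counts.get(b, 0) + 1
    for lab in out_labels:
        if counts.get(lab, 0) != 1 or marked_counts.get(lab, 0):
            return None
    for lab in span_labels:
        c = counts.get(lab, 0)
        if c not in (1, 2):
            return None
        m = marked_counts.get(lab, 0)
        if c == 1 and m:          # no functional copy would survive
            return None
        if c == 2 and m > 1:      # at most one copy decays to a pseudogene
            return None

    # The surviving span copies must form one contiguous block positioned
    # where the ancestral span was: derived (as a rotation if circular) must
    # read  block + out_labels.
    der = derived.elements
    m = len(der)
    block_len = m - len(out_labels)
    rotations = range(m) if derived.circular else [0]
    for rot in rotations:
        rotated = der[rot:] + der[:rot]
        block = rotated[:block_len]
        tail = [base_label(lab) for lab, _ in rotated[block_len:]]
        if tail != out_labels:
            continue
        if any(base_label(lab) not in span_pos for lab, _ in block):
            continue
        positions = [span_pos[base_label(lab)] for lab, _ in block]
        scen = _merge_assignment(block, positions, start, length)
        if scen is not None:
            ident = orders_equivalent(replay_scenario(ancestral, scen), ancestral)
            scen = DRLScenario(
                span=scen.span,
                retention=scen.retention,
                pseudogene_copy=scen.pseudogene_copy,
                identity_consistent=ident,
            )
            # forward-replay verification (the invariant the type promises)
            if orders_equivalent(replay_scenario(ancestral, scen), derived):
                return scen
    return None


def _merge_assignment(
    block: tuple[Element, ...], positions: list[int], start: int, length: int
) -> DRLScenario | None:
    """Split the block into tandem-copy-1 then tandem-copy-2 survivors.

    Both parts must be strictly increasing in span order; the split point is
    scanned greedily from the longest increasing prefix backwards (ties in
    split placement cannot change the retention classes, only which copy a
    doubly-absent... single-occurrence gene is attributed to — the first
    valid split is kept for determinism)."""
    m = len(positions)
    # longest strictly-increasing prefix / suffix bounds for valid splits
    pref = 1 if m else 0
    while pref < m and positions[pref] > positions[pref - 1]:
        pref += 1
    suff_start = m - 1 if m else 0
    while suff_start > 0 and positions[suff_start] > positions[suff_start - 1]:
        suff_start -= 1
    for k in range(pref, suff_start - 1, -1):
        part1, part2 = positions[:k], positions[k:]
        retention = []
        psi_copy: list[tuple[int, int]] = []
        ok = True
        for j in range(length):
            in1, in2 = j in part1, j in part2
            if not in1 and not in2:
                ok = False  # span gene with no surviving copy: not single-DRL
                break
            if in1 and in2:
                i1 = positions.index(j)
                i2 = k + part2.index(j)
                m1 = is_pseudogene(block[i1][0])
                m2 = is_pseudogene(block[i2][0])
                if m1 and m2:
                    ok = False
                    break
                if m1 or m2:
                    retention.append("remnant")
                    psi_copy.append((j, 1 if m1 else 2))
                else:
                    retention.append("both")
            elif in1:
                if is_pseudogene(block[positions.index(j)][0]):
                    ok = False
                    break
                retention.append("first")
            else:
                if is_pseudogene(block[k + part2.index(j)][0]):
                    ok = False
                    break
                retention.append("second")
        if ok:
            return DRLScenario(
                span=(start, length),
                retention=tuple(retention),
                pseudogene_copy=tuple(psi_copy),
            )
    return None


def _minimal_spans(
    scenarios: list[DRLScenario], n: int, circular: bool
) -> list[DRLScenario]:
    """Keep only spans that do not strictly contain another reported span."""

    def arc(s: DRLScenario) -> set[int]:
        start, length = s.span
        return {(start + j) % n for j in range(length)} if circular else set(
            range(start, start + length)
        )

    arcs = [arc(s) for s in scenarios]
    keep = []
    for i, s in enumerate(scenarios):
        if any(j != i and arcs[j] < arcs[i] for j in range(len(scenarios))):
            continue
        keep.append(s)
    return keep


# ---------------------------------------------------------------------------
# Depth-ratio screen for putative duplications

def depth_ratio(
    track: DepthTrack,
    region: tuple[int, int],
    background_exclusions: Iterable[tuple[int, int]] = (),
    trim: float = 0.05,
    threshold: float = 2.0,
) -> tuple[float, bool]:
    """Mean read depth in ``region`` over the trimmed-mean background depth.

    Background = genome minus the region minus ``background_exclusions``,
    summarized by a trimmed mean (``trim`` fraction per tail) to resist
    control-region pileups.  Returns ``(ratio, flag)`` where the flag marks
    ``ratio >= threshold`` (default 2.0) as consistent with >= 2 copies.
    """
    n = len(track)
    start, end = region
    if not (0 <= start < end <= n):
        raise ValueError(f"region {region} outside genome of length {n}")
    excluded = set(range(start, end))
    for a, b in background_exclusions:
        excluded.update(range(a, b))
    background = [track.depths[i] for i in range(n) if i not in excluded]
    if not background:
        raise ValueError("background is empty")
    bg_mean = float(trim_mean(background, trim))
    if bg_mean == 0:
        raise ValueError("background mean depth is zero")
    region_mean = sum(track.depths[start:end]) / (end - start)
    ratio = region_mean / bg_mean
    return ratio, ratio >= threshold
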