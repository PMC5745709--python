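"""Quantify divergence between a functional gene and its duplicate copy.

The pipeline is: global affine-gap alignment (Needleman-Wunsch/Gotoh,
implemented here), column-wise difference classification
(:func:`summarize_differences`), open-reading-frame scanning under the
vertebrate mitochondrial code (:func:`scan_orfs`), and a three-way paralog
status call (:func:`classify_paralog`).

Conventions: the *reference* row is the functional copy; an insertion is
extra bases in the candidate (gap in the reference row), a deletion is
bases missing from the candidate (gap in the query row).  Identity is
matches / total alignment columns, gap columns included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "ScoringScheme",
    "PairwiseAlignment",
    "DifferenceSummary",
    "OrfReport",
    "Orf",
    "ParalogStatus",
    "ClassificationThresholds",
    "global_align",
    "summarize_differences",
    "scan_orfs",
    "classify_paralog",
    "MITO_STOP_CODONS",
    "MITO_START_CODONS",
]

#: vertebrate mitochondrial code: AGA/AGG are stops, not arginine
MITO_STOP_CODONS = frozenset({"TAA", "TAG", "AGA", "AGG"})
#: start codons in common vertebrate mitochondrial usage
MITO_START_CODONS = frozenset({"ATG", "ATA", "GTG"})

_GAP = "-"
_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap scoring; a length-L gap run costs gap_open + L*gap_extend."""

    match: int = 1
    mismatch: int = -1
    gap_open: int = -2
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("penalties must be <= 0")

    def pair_score(self, a: str, b: str) -> int:
        if a == "N" or b == "N":
            return 0  # unknown bases are scored neutrally
        return self.match if a == b else self.mismatch


@dataclass(frozen=True)
class PairwiseAlignment:
    """Two equal-length gapped rows plus the achieved score."""

    row_ref: str
    row_qry: str
    score: int

    def __post_init__(self) -> None:
        if len(self.row_ref) != len(self.row_qry):
            raise ValueError("alignment rows differ in length")
        for a, b in zip(self.row_ref, self.row_qry):
            if a == _GAP and b == _GAP:
                raise ValueError("gap/gap column in alignment")

    @property
    def reference(self) -> str:
        return self.row_ref.replace(_GAP, "")

    @property
    def query(self) -> str:
        return self.row_qry.replace(_GAP, "")


@dataclass(frozen=True)
class DifferenceSummary:
    columns: int
    matches: int
    substitutions: int
    insertion_events: int
    insertion_bp: int
    deletion_events: int
    deletion_bp: int
    identity: float


@dataclass(frozen=True)
class Orf:
    frame: int
    start: int          # 0-based nucleotide offset of the start codon
    aa_length: int      # codons from start up to but excluding the stop
    open_ended: bool    # ran off the sequence end without a stop


@dataclass(frozen=True)
class OrfReport:
    orfs: tuple[Orf, ...]
    longest_aa: int


@dataclass(frozen=True)
class ClassificationThresholds:
    intact_identity: float = 0.98
    recognizable_identity: float = 0.50
    length_ratio_min: float = 0.9


@dataclass(frozen=True)
class ParalogStatus:
    call: str  # intact | pseudogene | unrecognizable
    identity: float
    premature_stop: bool
    length_ratio: float


# ---------------------------------------------------------------------------
# Global affine-gap alignment (Gotoh)

def global_align(reference: str, query: str, scoring: ScoringScheme | None = None) -> PairwiseAlignment:
    """Optimal global alignment with affine gap costs.

    Deterministic traceback tie-break, evaluated top-down: diagonal first,
    then gap-in-query (deletion from the candidate), then gap-in-reference
    (insertion into the candidate).
    """
    if scoring is None:
        scoring = ScoringScheme()
    if not reference or not query:
        raise ValueError("sequences must be non-empty")
    for seq, name in ((reference, "reference"), (query, "query")):
        bad = set(seq) - _ALPHABET
        if bad:
            raise ValueError(f"illegal residues {sorted(bad)} in {name}")

    n, m = len(reference), len(query)
    NEG = float("-inf")
    go, ge = scoring.gap_open, scoring.gap_extend

    # M: ref[i] aligned to qry[j]; X: gap in query row (deletion, consumes ref);
    # Y: gap in reference row (insertion, consumes qry)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0
    for i in range(1, n + 1):
        X[i][0] = go + ge * i
    for j in range(1, m + 1):
        Y[0][j] = go + ge * j

    for i in range(1, n + 1):
        ri = reference[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, m + 1):
            s = scoring.pair_score(ri, query[j - 1])
            diag = Mp[j - 1]
            if Xp[j - 1] > diag:
                diag = Xp[j - 1]
            if Yp[j - 1] > diag:
                diag = Yp[j - 1]
            Mi[j] = diag + s
            xo = Mp[j] + go + ge
            xe = Xp[j] + ge
            ya = Yp[j] + go + ge
            Xi[j] = xo if xo >= xe else xe
            if ya > Xi[j]:
                Xi[j] = ya
            yo = Mi[j - 1] + go + ge
            ye = Yi[j - 1] + ge
            xa = Xi[j - 1] + go + ge
            Yi[j] = yo if yo >= ye else ye
            if xa > Yi[j]:
                Yi[j] = xa

    score = max(M[n][m], X[n][m], Y[n][m])
    row_ref, row_qry = _traceback(reference, query, scoring, M, X, Y)
    return PairwiseAlignment(row_ref, row_qry, int(score))


def _traceback(reference, query, scoring, M, X, Y):
    go, ge = scoring.gap_open, scoring.gap_extend
    n, m = len(reference), len(query)
    i, j = n, m
    # state choice at the end: same precedence (M, X, Y)
    end = max(M[n][m], X[n][m], Y[n][m])
    state = "M" if M[n][m] == end else ("X" if X[n][m] == end else "Y")
    ref_row: list[str] = []
    qry_row: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            s = scoring.pair_score(reference[i - 1], query[j - 1])
            target = M[i][j] - s
            ref_row.append(reference[i - 1])
            qry_row.append(query[j - 1])
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            state = (
                "M" if M[i][j] == target
                else "X" if X[i][j] == target
                else "Y"
            )
        elif state == "X":
            ref_row.append(reference[i - 1])
            qry_row.append(_GAP)
            i -= 1
            # was this gap opened here or extended?
            if M[i][j] + go + ge == X[i + 1][j]:
                state = "M"
            elif X[i][j] + ge == X[i + 1][j]:
                state = "X"
            else:
                state = "Y"
        else:  # Y
            ref_row.append(_GAP)
            qry_row.append(query[j - 1])
            j -= 1
            if M[i][j] + go + ge == Y[i][j + 1]:
                state = "M"
            elif Y[i][j] + ge == Y[i][j + 1]:
                state = "Y"
            else:
                state = "X"
    return "".join(reversed(ref_row)), "".join(reversed(qry_row))


# ---------------------------------------------------------------------------
# Difference classification

def summarize_differences(alignment: PairwiseAlignment) -> DifferenceSummary:
    """Column-wise counts of matches, substitutions, and indel events/bp.

    A maximal run of gaps in the reference row is one insertion event; in
    the query row, one deletion event.  Columns containing N count toward
    total columns but toward neither matches nor substitutions.  Identity
    is matches / columns (gap columns included).
    """
    ref, qry = alignment.row_ref, alignment.row_qry
    columns = len(ref)
    matches = substitutions = 0
    ins_events = ins_bp = del_events = del_bp = 0
    in_ins = in_del = False
    for a, b in zip(ref, qry):
        if a == _GAP:
            ins_bp += 1
            if not in_ins:
                ins_events += 1
            in_ins, in_del = True, False
        elif b == _GAP:
            del_bp += 1
            if not in_del:
                del_events += 1
            in_del, in_ins = True, False
        else:
            in_ins = in_del = False
            if a == "N" or b == "N":
                continue
            if a == b:
                matches += 1
            else:
                substitutions += 1
    identity = matches / columns if columns else 0.0
    return DifferenceSummary(
        columns=columns,
        matches=matches,
        substitutions=substitutions,
        insertion_events=ins_events,
        insertion_bp=ins_bp,
        deletion_events=del_events,
        deletion_bp=del_bp,
        identity=identity,
    )


# ---------------------------------------------------------------------------
# ORF scanning (vertebrate mitochondrial code, forward frames)

def scan_orfs(seq: str, min_aa: int = 2, scan_reverse: bool = False) -> OrfReport:
    """Scan the three forward frames for ORFs under the vertebrate
    mitochondrial code (stops TAA/TAG/AGA/AGG; starts ATG/ATA/GTG).

    ``aa_length`` counts codons from the start codon up to but excluding
    the stop; ORFs reaching the sequence end without a stop are flagged
    ``open_ended``.  Reverse-strand scanning (off by default: tandem
    paralogs retain the functional copy's strand) scans the reverse
    complement, reporting frames 0-2 on that strand.
    """
    if _GAP in seq:
        raise ValueError("sequence must be gap-free")
    orfs = list(_scan_forward(seq, min_aa))
    if scan_reverse:
        from .genome_io import reverse_complement

        orfs.extend(_scan_forward(reverse_complement(seq), min_aa))
    longest = max((o.aa_length for o in orfs), default=0)
    return OrfReport(orfs=tuple(orfs), longest_aa=longest)


def _scan_forward(seq: str, min_aa: int):
    for frame in range(3):
        start: int | None = None
        pos = frame
        while pos + 3 <= len(seq):
            codon = seq[pos : pos + 3]
            if codon in MITO_STOP_CODONS:
                if start is not None:
                    aa = (pos - start) // 3
                    if aa >= min_aa:
                        yield Orf(frame, start, aa, open_ended=False)
                    start = None
            elif start is None and codon in MITO_START_CODONS:
                start = pos
            pos += 3
        if start is not None:
            aa = (pos - start) // 3
            if aa >= min_aa:
                yield Orf(frame, start, aa, open_ended=True)


# ---------------------------------------------------------------------------
# Paralog status calls

def classify_paralog(
    functional: str,
    candidate: str,
    scoring: ScoringScheme | None = None,
    thresholds: ClassificationThresholds | None = None,
    is_protein: bool = True,
) -> ParalogStatus:
    """Call a duplicate copy intact, pseudogene, or unrecognizable.

    * intact: identity >= ``intact_identity`` and, for protein features, an
      undisrupted full-length reading frame (no premature stop, no
      frameshifting indel).
    * pseudogene: identity >= ``recognizable_identity`` with a premature
      stop, a frameshifting indel, or length ratio < ``length_ratio_min``.
    * unrecognizable: identity below ``recognizable_identity``.
    """
    if thresholds is None:
        thresholds = ClassificationThresholds()
    aln = global_align(functional, candidate, scoring)
    summary = summarize_differences(aln)
    identity = summary.identity
    length_ratio = len(candidate) / len(functional)
    premature = (
        _stops_earlier_than(candidate, functional) if is_protein else False
    )
    frameshift = (summary.insertion_bp - summary.deletion_bp) % 3 != 0

    if identity < thresholds.recognizable_identity:
        call = "unrecognizable"
    else:
        disrupted = premature or (is_protein and frameshift)
        truncated = length_ratio < thresholds.length_ratio_min
        if identity >= thresholds.intact_identity and not disrupted and not truncated:
            call = "intact"
        elif disrupted or truncated or identity < thresholds.intact_identity:
            call = "pseudogene"
        else:
            call = "intact"
    return ParalogStatus(
        call=call,
        identity=identity,
        premature_stop=premature,
        length_ratio=length_ratio,
    )


def _first_stop_codon(seq: str) -> float:
    """Frame-0 index of the first stop codon before the terminal one."""
    n_codons = len(seq) // 3
    for k in range(n_codons - 1):
        if seq[3 * k : 3 * k + 3] in MITO_STOP_CODONS:
            return k
    return float("inf")


def _stops_earlier_than(candidate: str, functional: str) -> bool:
    """Premature stop relative to the functional copy: the candidate's
    reading frame terminates strictly earlier than the functional one."""
    return _first_stop_codon(candidate) < _first_stop_codon(functional)
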