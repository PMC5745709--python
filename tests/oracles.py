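"""Independent brute-force oracles used by the test suite.

These deliberately share no algorithmic machinery with the implementation
paths they check: alignment scores come from exhaustive path enumeration,
DRL span sets from enumeration of every span and retention assignment, and
Fitch counts from enumeration of every internal state assignment.
"""

from __future__ import annotations

import itertools
from math import inf

from mitodrl.gene_order import (
    DRLScenario,
    GeneOrder,
    base_label,
    orders_equivalent,
    replay_scenario,
)
from mitodrl.paralog_decay import ScoringScheme


def brute_force_align_score(ref: str, qry: str, scoring: ScoringScheme) -> int:
    """Max affine-gap global score over all alignments, by path enumeration."""
    n, m = len(ref), len(qry)
    go, ge = scoring.gap_open, scoring.gap_extend
    best = [-inf]

    def step(i: int, j: int, prev: str, acc: int) -> None:
        if i == n and j == m:
            if acc > best[0]:
                best[0] = acc
            return
        if i < n and j < m:
            step(i + 1, j + 1, "M", acc + scoring.pair_score(ref[i], qry[j]))
        if i < n:
            step(i + 1, j, "X", acc + (ge if prev == "X" else go + ge))
        if j < m:
            step(i, j + 1, "Y", acc + (ge if prev == "Y" else go + ge))

    step(0, 0, "", 0)
    return int(best[0])


def exhaustive_drl_spans(
    ancestral: GeneOrder, derived: GeneOrder
) -> set[tuple[int, int]]:
    """Every containment-minimal span explainable by some single-DRL
    retention assignment, found by enumerating all 5^S assignments and
    replaying each."""
    n = len(ancestral)
    anc_labels = ancestral.labels()
    der_counts: dict[str, int] = {}
    for lab, _ in derived.elements:
        b = base_label(lab)
        der_counts[b] = der_counts.get(b, 0) + 1

    feasible_spans: list[tuple[int, int]] = []
    starts = range(n) if ancestral.circular else range(n)
    for start in starts:
        for length in range(1, n + 1):
            if not ancestral.circular and start + length > n:
                break
            span_set = {anc_labels[(start + j) % n] for j in range(length)}
            # quick multiset feasibility: outside genes once, span genes 1-2
            if any(
                der_counts.get(lab, 0) != 1
                for lab in anc_labels
                if lab not in span_set
            ):
                continue
            if any(der_counts.get(lab, 0) not in (1, 2) for lab in span_set):
                continue
            if _some_assignment_works(ancestral, derived, start, length):
                feasible_spans.append((start, length))
    return _minimal(feasible_spans, n, ancestral.circular)


_CHOICES = ("first", "second", "both", ("remnant", 1), ("remnant", 2))


def _some_assignment_works(ancestral, derived, start, length) -> bool:
    for combo in itertools.product(_CHOICES, repeat=length):
        retention = []
        psi = []
        for j, c in enumerate(combo):
            if isinstance(c, tuple):
                retention.append("remnant")
                psi.append((j, c[1]))
            else:
                retention.append(c)
        scen = DRLScenario(
            span=(start, length), retention=tuple(retention), pseudogene_copy=tuple(psi)
        )
        try:
            replayed = replay_scenario(ancestral, scen)
        except ValueError:
            continue
        if orders_equivalent(replayed, derived):
            return True
    return False


def _minimal(spans, n, circular):
    def arc(span):
        s, L = span
        return (
            {(s + j) % n for j in range(L)} if circular else set(range(s, s + L))
        )

    arcs = {span: arc(span) for span in spans}
    return {
        span
        for span in spans
        if not any(other != span and arcs[other] < arcs[span] for other in spans)
    }


def exhaustive_fitch_min(tree, states) -> int:
    """Minimum changes over all internal-node state assignments."""
    dtree = tree._tree
    state_space = sorted(set(states.values()))
    internals = [nd for nd in dtree.preorder_node_iter() if not nd.is_leaf()]
    edges = []
    for nd in dtree.preorder_node_iter():
        for child in nd.child_nodes():
            edges.append((nd, child))

    def node_state(nd, assignment):
        if nd.is_leaf():
            return states[nd.taxon.label]
        return assignment[id(nd)]

    best = inf
    for combo in itertools.product(state_space, repeat=len(internals)):
        assignment = {id(nd): s for nd, s in zip(internals, combo)}
        changes = sum(
            1
            for parent, child in edges
            if node_state(parent, assignment) != node_state(child, assignment)
        )
        best = min(best, changes)
    return int(best)
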