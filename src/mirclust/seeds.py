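"""Dominant mature products, seed extraction and seed-innovation events.

The seed is nucleotides 2-8 of the mature sequence.  Two seed-innovation
modes are distinguished between species:

* arm switching — the dominant product moves to the other hairpin arm,
  replacing the seed entirely;
* seed shifting — the dominant processing register moves along the same
  arm (Drosha/Dicer offset change), shifting which 7-mer is the seed.

Same-register seed differences are point substitutions.  Events are placed
on tree branches by small parsimony (Fitch) over the composite (arm, seed)
state; when several branch placements are equally parsimonious the event is
reported with the full candidate set and ``resolved=False``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

from .io import SpeciesTree
from .validation import HairpinFold, ReadProfile

MAX_SHIFT = 5  # |register shift| beyond this is not called a seed shift


@dataclass(frozen=True)
class MatureAssignment:
    """Dominant mature product of one member in one species."""

    species: str
    member: str
    arm: str  # "5p" | "3p"
    start: int  # 0-based offset on the precursor
    mature_seq: str

    def __post_init__(self) -> None:
        if self.arm not in ("5p", "3p"):
            raise ValueError(f"invalid arm {self.arm!r}")
        if not 18 <= len(self.mature_seq) <= 26:
            raise ValueError(
                f"mature length {len(self.mature_seq)} outside 18-26 nt"
            )

    @property
    def seed(self) -> str:
        return extract_seed(self.mature_seq)

    @property
    def state(self) -> tuple[str, str]:
        """Composite character used for parsimony."""
        return (self.arm, self.seed)


def extract_seed(mature_seq: str) -> str:
    """Nucleotides 2-8 (1-based) of the mature sequence: a 7-mer."""
    if len(mature_seq) < 8:
        raise ValueError(f"mature sequence too short for a seed: {mature_seq!r}")
    return mature_seq[1:8]


def dominant_mature(
    profile: ReadProfile,
    fold: HairpinFold,
    precursor_seq: str,
    species: str = "",
    member: str = "",
) -> MatureAssignment:
    """The highest-count isomiR of a hairpin, with its arm.

    Ties within one arm are broken by (start asc, length asc); a count tie
    between the two arms is ambiguous and raises.  Reads lying entirely in
    the hairpin loop have no arm and are ignored; if nothing else remains
    the profile is unusable.
    """
    if not profile.reads:
        raise ValueError(f"{profile.hairpin_id}: empty read profile")
    loop_lo, loop_hi = fold.loop_bounds()
    loop_mid = (loop_lo + loop_hi) / 2

    iso: dict[tuple[int, int], int] = {}
    for r in profile.reads:
        if r.start >= loop_lo and r.end <= loop_hi:
            continue  # loop-only read: no arm
        iso[(r.start, r.length)] = iso.get((r.start, r.length), 0) + r.count
    if not iso:
        raise ValueError(f"{profile.hairpin_id}: reads only in loop region")

    top = max(iso.values())
    winners = sorted([k for k, c in iso.items() if c == top])
    arms = {
        "5p" if (s + s + ln) / 2 < loop_mid else "3p" for s, ln in winners
    }
    if len(arms) > 1:
        raise ValueError(
            f"{profile.hairpin_id}: dominant-read tie between arms; "
            "resolve manually"
        )
    start, length = winners[0]
    arm = arms.pop()
    mature = precursor_seq[start : start + length]
    return MatureAssignment(species, member or profile.hairpin_id, arm, start, mature)


def _is_shift(a: MatureAssignment, b: MatureAssignment) -> bool:
    """True when b's seed is a's mature read out at a shifted register."""
    for shift in range(-MAX_SHIFT, MAX_SHIFT + 1):
        if shift == 0:
            continue
        lo = 1 + shift
        if lo < 0 or lo + 7 > len(a.mature_seq):
            continue
        if a.mature_seq[lo : lo + 7] == b.seed:
            return True
    return False


def classify_change(a: MatureAssignment, b: MatureAssignment) -> str:
    """Classify the seed difference between two species' assignments.

    Returns one of ``none``, ``arm_switch``, ``seed_shift``,
    ``substitution``.  Symmetric up to direction.
    """
    if a.member != b.member:
        raise ValueError(f"different members: {a.member!r} vs {b.member!r}")
    if a.arm != b.arm:
        return "arm_switch"
    if a.seed == b.seed:
        return "none"
    if _is_shift(a, b) or _is_shift(b, a):
        return "seed_shift"
    if a.start != b.start and not _is_shift(a, b) and not _is_shift(b, a):
        if abs(a.start - b.start) > MAX_SHIFT:
            warnings.warn(
                f"{a.member}: registers differ by more than {MAX_SHIFT} nt; "
                "classified as substitution-type divergence"
            )
    return "substitution"


def summarize_changes(assignments: dict[str, "MatureAssignment"]) -> set[str]:
    """Event types observed across all species pairs (composite summary).

    A member showing both components across a triple (the arm-switch-plus-
    seed-shift case) yields both labels.
    """
    types = set()
    for sa, sb in itertools.combinations(sorted(assignments), 2):
        t = classify_change(assignments[sa], assignments[sb])
        if t != "none":
            types.add(t)
    return types


@dataclass(frozen=True)
class SeedChangeEvent:
    member: str
    type: str
    branches: frozenset[str]  # candidate branch ids (child-node ids)

    @property
    def resolved(self) -> bool:
        return len(self.branches) == 1


def _restrict(tree: SpeciesTree, keep: set[str]) -> tuple[dict[str, list[str]], str]:
    """Induced topology on a leaf subset.

    Returns (children map, root).  Unifurcations are suppressed; surviving
    nodes keep their original ids.
    """
    relevant: dict[str, list[str]] = {}
    for node in tree.nodes():  # postorder
        if tree.is_leaf(node):
            if node in keep:
                relevant[node] = []
            continue
        kids = [c for c in tree.children(node) if c in relevant]
        if kids:
            relevant[node] = kids

    def resolve(node: str) -> str:
        while len(relevant[node]) == 1:
            node = relevant[node][0]
        return node

    children: dict[str, list[str]] = {}

    def build(node: str) -> str:
        node = resolve(node)
        children[node] = [build(c) for c in relevant[node]]
        return node

    root = build(tree.root)
    return children, root


def place_events(
    assignments: dict[str, MatureAssignment], tree: SpeciesTree
) -> list[SeedChangeEvent]:
    """Place seed-innovation events on the tree by small parsimony.

    The character is the composite (arm, seed) state; the tree is restricted
    to species bearing the member.  All maximum-parsimony ancestral labelings
    are enumerated exhaustively (state and species counts are tiny) and the
    change edges pooled: a change whose branch differs between labelings is
    reported with every candidate branch and ``resolved=False``.
    """
    species = set(assignments)
    if len(species) < 2:
        return []
    missing = species - set(tree.leaves)
    if missing:
        raise ValueError(f"species not in tree: {sorted(missing)}")
    member = next(iter(assignments.values())).member
    if any(a.member != member for a in assignments.values()):
        raise ValueError("assignments span multiple members")

    children, root = _restrict(tree, species)
    leaf_state = {sp: assignments[sp].state for sp in species}
    states = sorted(set(leaf_state.values()))
    if len(states) == 1:
        return []
    rep: dict[tuple[str, str], MatureAssignment] = {}
    for sp in sorted(assignments):
        rep.setdefault(assignments[sp].state, assignments[sp])

    internal = [n for n, kids in children.items() if kids]
    parent_of = {c: p for p, kids in children.items() for c in kids}

    best: int | None = None
    labelings: list[dict] = []  # full node->state maps of MP labelings
    for combo in itertools.product(states, repeat=len(internal)):
        full = {**leaf_state, **dict(zip(internal, combo))}
        k = sum(1 for c, p in parent_of.items() if full[c] != full[p])
        if best is None or k < best:
            best, labelings = k, [full]
        elif k == best:
            labelings.append(full)

    change_sets = [
        frozenset(c for c, p in parent_of.items() if lab[c] != lab[p])
        for lab in labelings
    ]

    def edge_event(lab: dict, edge: str, branches: frozenset[str]) -> SeedChangeEvent:
        etype = classify_change(rep[lab[parent_of[edge]]], rep[lab[edge]])
        return SeedChangeEvent(member, etype, branches)

    if all(cs == change_sets[0] for cs in change_sets):
        return [
            edge_event(labelings[0], e, frozenset([e]))
            for e in sorted(change_sets[0])
        ]

    # Ambiguous placement: cluster the union of candidate edges by node
    # adjacency; each component is one event whose branch is uncertain.
    all_edges = sorted(set().union(*change_sets))
    adj: dict[str, set[str]] = {e: set() for e in all_edges}
    for e1, e2 in itertools.combinations(all_edges, 2):
        if {e1, parent_of.get(e1)} & {e2, parent_of.get(e2)}:
            adj[e1].add(e2)
            adj[e2].add(e1)
    components: list[set[str]] = []
    seen: set[str] = set()
    for e in all_edges:
        if e in seen:
            continue
        comp, stack = set(), [e]
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(adj[x] - comp)
        seen |= comp
        components.append(comp)

    events = []
    for comp in components:
        # classify from any MP labeling that places a change on this component
        for lab, cs in zip(labelings, change_sets):
            hit = sorted(cs & comp)
            if hit:
                events.append(edge_event(lab, hit[0], frozenset(comp)))
                break
    return events
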