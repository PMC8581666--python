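"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates a testes-expressed miRNA cluster evolving on a
species tree: each member originates once (Dollo) and is lost independently
on scheduled branches; each present (species, member) pair gets a hairpin
read profile with a dominant mature product, isomiR spread around it, miR*
reads at the duplex partner position and a small background; per-species
3'UTR sets carry planted seed-match sites (and no accidental ones); and
paired control/overexpression expression matrices apply a weak
multiplicative repression to the true targets.

Precursors are perfect-stem hairpins (5' arm + unpaired loop + reverse
complement of the arm), so duplex geometry is exact by construction:
the miR* window of a mature product at offset ``s`` is
``(L - s - mlen + 2, L - s + 2)`` — the duplex partner span with the
canonical 2-nt 3' overhangs.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SequenceRecord, SpeciesTree, parse_newick, reverse_complement
from .overlap import OrthologMap
from .io import ExpressionTable
from .seeds import MatureAssignment
from .targets import find_sites
from .validation import ReadAln, ReadProfile

# hairpin geometry (nt)
ARM_LEN = 33
LOOP_LEN = 15
MATURE_LEN = 22
FIVE_START = 5  # canonical 5p mature offset
PRECURSOR_LEN = 2 * ARM_LEN + LOOP_LEN
THREE_START = PRECURSOR_LEN - FIVE_START - MATURE_LEN + 2  # duplex partner + overhang

EVENT_TYPES = ("arm_switch", "seed_shift", "substitution")


def star_window(start: int, precursor_len: int = PRECURSOR_LEN,
                mature_len: int = MATURE_LEN) -> tuple[int, int]:
    """miR* window opposite a mature product on a perfect-stem hairpin."""
    return (precursor_len - start - mature_len + 2, precursor_len - start + 2)


@dataclass(frozen=True)
class MemberSpec:
    name: str
    origin: str  # node id, or comma-separated leaf labels resolved to the MRCA
    losses: frozenset[str] = frozenset()  # branch ids (child-node ids)


@dataclass(frozen=True)
class SeedEvent:
    member: str
    branch: str  # child-node id; applies to every leaf below
    event_type: str

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")


@dataclass(frozen=True)
class ReadParams:
    depth: float = 1000.0  # mean mapped reads per hairpin
    dispersion: float = 10.0  # negative-binomial size parameter
    mir_star_ratio: float = 10.0  # expected miR : miR* read ratio
    isomir_concentration: float = 100.0  # Dirichlet mass on the canonical isomiR
    background_fraction: float = 0.02

    def __post_init__(self) -> None:
        if self.mir_star_ratio <= 0 or self.dispersion <= 0:
            raise ValueError("ratio and dispersion must be positive")
        if not 0 <= self.background_fraction <= 1:
            raise ValueError("background_fraction must be in [0, 1]")


@dataclass(frozen=True)
class UtrParams:
    n_genes: int = 300
    utr_length: int = 400
    au_content: float = 0.60  # fly 3'UTRs are AU-rich
    planted_per_member: int = 10
    shared_fraction: float = 0.5  # fraction of planted targets shared across species
    site_class: str = "8mer"
    max_attempts: int = 200


@dataclass(frozen=True)
class RepressionParams:
    fold: float = 1.3  # multiplicative repression factor f >= 1 (weak, miRNA-like)
    noise_sd: float = 0.25  # sd of lognormal noise on log scale
    n_control: int = 2
    n_treatment: int = 2

    def __post_init__(self) -> None:
        if self.fold < 1:
            raise ValueError("repression factor must be >= 1")


@dataclass
class SimConfig:
    tree: str = "(((dmel,dsim),dpse),dvir);"
    members: tuple[MemberSpec, ...] = (
        MemberSpec("mem-old1", "dmel,dsim,dpse,dvir", frozenset({"dpse"})),
        MemberSpec("mem-old2", "dmel,dsim,dpse,dvir", frozenset({"dpse"})),
        MemberSpec("mem-new1", "dmel,dsim"),
        MemberSpec("mem-new2", "dmel"),
    )
    events: tuple[SeedEvent, ...] = (
        SeedEvent("mem-old1", "dvir", "arm_switch"),
        SeedEvent("mem-old2", "dsim", "seed_shift"),
        SeedEvent("mem-new1", "dsim", "substitution"),
    )
    read_params: ReadParams = ReadParams()
    utr_params: UtrParams = UtrParams()
    repression_params: RepressionParams = RepressionParams()
    rng_seed: int = 0


@dataclass
class GroundTruth:
    presence: pd.DataFrame  # members x species booleans
    origins: dict[str, str]
    losses: dict[str, frozenset[str]]
    # species -> member -> dominant assignment (only where present)
    assignments: dict[str, dict[str, MatureAssignment]] = field(default_factory=dict)
    precursors: dict[str, dict[str, SequenceRecord]] = field(default_factory=dict)
    # species -> member -> set of true target gene ids
    targets: dict[str, dict[str, set[str]]] = field(default_factory=dict)


def _resolve_node(tree: SpeciesTree, spec: str) -> str:
    if "," in spec:
        return tree.mrca([s.strip() for s in spec.split(",")])
    if spec not in tree:
        raise ValueError(f"node {spec!r} not in tree")
    return spec


def simulate_cluster_history(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Presence matrix implied by per-member origins and loss branches.

    A member is present exactly in the leaves descending from its origin
    and not below any loss branch.  Loss branches must descend from the
    member's origin.
    """
    tree = parse_newick(config.tree)
    presence = pd.DataFrame(
        False, index=[m.name for m in config.members], columns=tree.leaves
    )
    origins: dict[str, str] = {}
    losses: dict[str, frozenset[str]] = {}
    for mem in config.members:
        origin = _resolve_node(tree, mem.origin)
        lost_leaves: set[str] = set()
        for br in mem.losses:
            if br not in tree or not tree.is_descendant(br, origin):
                raise ValueError(
                    f"{mem.name}: loss branch {br!r} is not under origin {origin!r}"
                )
            lost_leaves |= tree.leaf_labels(br)
        for leaf in tree.leaf_labels(origin) - lost_leaves:
            presence.loc[mem.name, leaf] = True
        origins[mem.name] = origin
        losses[mem.name] = frozenset(mem.losses)
    return presence, GroundTruth(presence=presence, origins=origins, losses=losses)


def _random_seq(rng: np.random.Generator, length: int, au: float = 0.5) -> str:
    p = [au / 2, au / 2, (1 - au) / 2, (1 - au) / 2]
    return "".join(rng.choice(["A", "U", "C", "G"], size=length, p=p))


def _node_depth(tree: SpeciesTree, node: str) -> int:
    d = 0
    cur = tree.parent(node)
    while cur is not None:
        d += 1
        cur = tree.parent(cur)
    return d


def simulate_assignments(
    config: SimConfig, truth: GroundTruth, rng: np.random.Generator
) -> GroundTruth:
    """Per-species precursors and dominant mature products under the schedule.

    Each member starts from one ancestral perfect-stem precursor with the
    canonical 5p product; scheduled events are applied root-to-tip to every
    leaf below their branch (arm switches flip the dominant arm, seed shifts
    move the register by +2 nt, substitutions mutate one seed base with a
    compensatory change on the partner strand).
    """
    tree = parse_newick(config.tree)
    events = sorted(config.events, key=lambda e: (_node_depth(tree, e.branch), e.member))
    truth.assignments = {sp: {} for sp in tree.leaves}
    truth.precursors = {sp: {} for sp in tree.leaves}

    for mem in config.members:
        arm5 = _random_seq(rng, ARM_LEN)
        loop = _random_seq(rng, LOOP_LEN)
        ancestral = arm5 + loop + reverse_complement(arm5)
        # per-leaf mutable state
        state = {
            sp: {"arm": "5p", "start": FIVE_START, "seq": ancestral}
            for sp in tree.leaves
        }
        for ev in events:
            if ev.member != mem.name:
                continue
            if ev.branch not in tree:
                raise ValueError(f"event branch {ev.branch!r} not in tree")
            below = tree.leaf_labels(ev.branch)
            if ev.event_type == "substitution":
                # one deterministic draw per event so all leaves below share it
                pos_in_seed = int(rng.integers(2, 7))  # mature offset 2..6 (seed)
                new_base = None
            for sp in sorted(below):
                st = state[sp]
                if ev.event_type == "arm_switch":
                    st["arm"] = "3p" if st["arm"] == "5p" else "5p"
                    st["start"] = star_window(st["start"])[0]
                elif ev.event_type == "seed_shift":
                    st["start"] += 2
                else:  # substitution (compensatory on the partner strand)
                    pos = st["start"] + pos_in_seed
                    old = st["seq"][pos]
                    if new_base is None:
                        choices = [b for b in "ACGU" if b != old]
                        new_base = str(rng.choice(choices))
                    partner = PRECURSOR_LEN - 1 - pos
                    seq = list(st["seq"])
                    seq[pos] = new_base
                    if 0 <= partner < PRECURSOR_LEN and partner != pos:
                        seq[partner] = reverse_complement(new_base)
                    st["seq"] = "".join(seq)
        for sp in tree.leaves:
            if not bool(truth.presence.loc[mem.name, sp]):
                continue
            st = state[sp]
            mature = st["seq"][st["start"] : st["start"] + MATURE_LEN]
            truth.assignments[sp][mem.name] = MatureAssignment(
                sp, mem.name, st["arm"], st["start"], mature
            )
            truth.precursors[sp][mem.name] = SequenceRecord(
                f"{sp}|{mem.name}", st["seq"]
            )
    return truth


def simulate_read_profile(
    assignment: MatureAssignment,
    read_params: ReadParams,
    rng: np.random.Generator,
    precursor_len: int = PRECURSOR_LEN,
) -> ReadProfile:
    """A hairpin read profile around one dominant mature product.

    Total depth is negative-binomial; duplex reads split between the miR
    and miR* windows at the configured ratio; miR-arm reads spread over
    isomiRs within +/-3 nt of the canonical product by a
    Dirichlet-multinomial concentrated on the canonical (start, length);
    background reads fall entirely outside both windows.
    """
    p = read_params
    if precursor_len < MATURE_LEN + 20:
        raise ValueError("precursor too short for a mature product and duplex")
    hid = f"{assignment.species}|{assignment.member}"
    if p.depth <= 0:
        return ReadProfile(hid, [])
    nb_p = p.dispersion / (p.dispersion + p.depth)
    total = int(rng.negative_binomial(p.dispersion, nb_p))
    if total == 0:
        return ReadProfile(hid, [])

    n_bg = int(rng.binomial(total, p.background_fraction))
    duplex = total - n_bg
    n_mir = int(rng.binomial(duplex, p.mir_star_ratio / (1 + p.mir_star_ratio)))
    n_star = duplex - n_mir

    s0, len0 = assignment.start, len(assignment.mature_seq)
    mir_win = (s0, s0 + len0)
    star_win = star_window(s0, precursor_len, len0)

    reads: list[ReadAln] = []
    if n_mir:
        variants = [(0, 0)] + [
            (ds, dl)
            for ds, dl in itertools.product(range(-3, 4), repeat=2)
            if (ds, dl) != (0, 0)
            and 0 <= s0 + ds
            and s0 + ds + len0 + dl <= precursor_len
            and len0 + dl >= 18
        ]
        if np.isinf(p.isomir_concentration):
            counts = np.zeros(len(variants), dtype=int)
            counts[0] = n_mir
        else:
            alpha = np.full(len(variants), 0.1)
            alpha[0] = p.isomir_concentration
            probs = rng.dirichlet(alpha)
            counts = rng.multinomial(n_mir, probs)
        for (ds, dl), c in zip(variants, counts):
            if c > 0:
                reads.append(ReadAln(s0 + ds, len0 + dl, int(c)))
    if n_star:
        reads.append(ReadAln(star_win[0], star_win[1] - star_win[0], n_star))
    if n_bg:
        bg_len = 15
        valid = [
            s
            for s in range(precursor_len - bg_len + 1)
            if (s + bg_len <= mir_win[0] or s >= mir_win[1])
            and (s + bg_len <= star_win[0] or s >= star_win[1])
        ]
        if valid:
            picks = rng.multinomial(n_bg, np.full(len(valid), 1 / len(valid)))
            for s, c in zip(valid, picks):
                if c > 0:
                    reads.append(ReadAln(s, bg_len, int(c)))
    return ReadProfile(hid, reads)


def simulate_read_profiles(
    config: SimConfig, truth: GroundTruth, rng: np.random.Generator
) -> dict[str, dict[str, ReadProfile]]:
    """Read profiles for every present (species, member) pair."""
    out: dict[str, dict[str, ReadProfile]] = {}
    for sp in sorted(truth.assignments):
        out[sp] = {}
        for mem in sorted(truth.assignments[sp]):
            out[sp][mem] = simulate_read_profile(
                truth.assignments[sp][mem], config.read_params, rng
            )
    return out


def _has_any_site(seq: str, seeds: list[str]) -> bool:
    """Any qualifying site (all three classes screened) for any seed."""
    rec = SequenceRecord("tmp", seq)
    return any(find_sites(rec, s) for s in seeds)


def _plant(seq: str, seed: str, site_class: str, pos: int) -> str:
    site = reverse_complement(seed)
    if site_class == "8mer":
        site = site + "A"
    elif site_class == "7mer-1A":
        site = site[1:] + "A"
    return seq[:pos] + site + seq[pos + len(site):]


def simulate_utrs(
    config: SimConfig, truth: GroundTruth, rng: np.random.Generator
) -> tuple[dict[str, list[SequenceRecord]], OrthologMap]:
    """Per-species 3'UTR sets with planted targets and a one-to-one map.

    Non-target UTRs are rejection-sampled so that no member's seed has any
    qualifying site (8mer, 7mer-m8 or 7mer-1A) anywhere in them; each
    planted target carries at least one exact site of the configured class
    for its member's seed in that species, and none for the other members.
    Orthologs share gene ids across species (identity map).
    """
    up = config.utr_params
    species = sorted(truth.assignments)
    genes = [f"g{i:04d}" for i in range(up.n_genes)]
    members = sorted({m for sp in species for m in truth.assignments[sp]})
    n_planted_total = len(members) * up.planted_per_member
    if 2 * n_planted_total > up.n_genes:
        raise ValueError(
            "planted-target pools exceed the gene universe; raise n_genes or "
            "lower planted_per_member"
        )

    # assign disjoint target gene pools per member; a configured fraction is
    # planted in every species (shared orthologous targets), the rest are
    # species-specific picks from the member's pool
    n_shared = int(round(up.planted_per_member * up.shared_fraction))
    gene_iter = iter(rng.permutation(genes))
    pools: dict[str, list[str]] = {}
    shared_genes: dict[str, list[str]] = {}
    for mem in members:
        pool = [next(gene_iter) for _ in range(up.planted_per_member * 2)]
        pools[mem] = pool
        shared_genes[mem] = pool[:n_shared]

    truth.targets = {sp: {m: set() for m in truth.assignments[sp]} for sp in species}
    planted: dict[str, dict[str, str]] = {sp: {} for sp in species}  # gene -> member
    for sp in species:
        for mem in sorted(truth.assignments[sp]):
            chosen = list(shared_genes[mem])
            extra = [g for g in pools[mem][n_shared:]]
            k = up.planted_per_member - len(chosen)
            idx = rng.choice(len(extra), size=k, replace=False)
            chosen += [extra[i] for i in sorted(idx)]
            for g in chosen:
                planted[sp][g] = mem
            truth.targets[sp][mem] = set(chosen)

    utrs: dict[str, list[SequenceRecord]] = {}
    for sp in species:
        seeds = {m: truth.assignments[sp][m].seed for m in truth.assignments[sp]}
        all_seeds = sorted(seeds.values())
        recs = []
        for g in genes:
            target_of = planted[sp].get(g)
            for attempt in range(up.max_attempts):
                seq = _random_seq(rng, up.utr_length, au=up.au_content)
                if target_of is None:
                    if not _has_any_site(seq, all_seeds):
                        break
                else:
                    pos = int(rng.integers(10, up.utr_length - 20))
                    seq = _plant(seq, seeds[target_of], up.site_class, pos)
                    others = [s for m, s in seeds.items() if m != target_of]
                    if not _has_any_site(seq, others):
                        break
            else:
                raise ValueError(
                    f"rejection sampling exceeded {up.max_attempts} attempts for "
                    f"{g} in {sp}; use longer UTRs or fewer members"
                )
            recs.append(SequenceRecord(g, seq))
        utrs[sp] = recs
    omap = OrthologMap.identity(genes, species)
    return utrs, omap


def simulate_expression(
    target_genes: set[str],
    genes: list[str],
    params: RepressionParams,
    rng: np.random.Generator,
) -> tuple[ExpressionTable, ExpressionTable]:
    """Paired control/overexpression tables with multiplicative repression.

    Per-gene baseline means are lognormal; treatment means of true targets
    are the control means divided by the repression factor f; every
    measurement carries multiplicative lognormal noise.
    """
    n = len(genes)
    baseline = rng.lognormal(mean=3.0, sigma=1.0, size=n)
    is_target = np.array([g in target_genes for g in genes])
    treat_mean = np.where(is_target, baseline / params.fold, baseline)

    def table(means: np.ndarray, n_rep: int, prefix: str) -> ExpressionTable:
        cols = {}
        for r in range(n_rep):
            noise = rng.lognormal(mean=0.0, sigma=params.noise_sd, size=n)
            cols[f"{prefix}{r + 1}"] = means * noise
        return ExpressionTable(pd.DataFrame(cols, index=genes), unit="TPM")

    control = table(baseline, params.n_control, "ctrl")
    treatment = table(treat_mean, params.n_treatment, "oe")
    return control, treatment


@dataclass
class SimulatedData:
    config: SimConfig
    truth: GroundTruth
    profiles: dict[str, dict[str, ReadProfile]]
    utrs: dict[str, list[SequenceRecord]]
    ortholog_map: OrthologMap


def simulate_all(config: SimConfig) -> SimulatedData:
    """Run the full generator: history, assignments, reads, UTRs."""
    rng = np.random.default_rng(config.rng_seed)
    presence, truth = simulate_cluster_history(config)
    truth = simulate_assignments(config, truth, rng)
    profiles = simulate_read_profiles(config, truth, rng)
    utrs, omap = simulate_utrs(config, truth, rng)
    return SimulatedData(config, truth, profiles, utrs, omap)
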