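"""Expression-based miRNA validation from hairpin read profiles.

A candidate hairpin passes when all five criteria hold:

1. at least one read on the miR* (passenger) window;
2. at least 20 reads on miR and miR* combined;
3. at least 13 base pairs between the miR and miR* windows in the
   hairpin fold;
4. the top three isomiRs carry at least 85% of the miR-arm reads;
5. more duplex (miR + miR*) reads than background reads.

Folding is base-pair-maximization dynamic programming (Watson-Crick plus
G.U wobble, minimum hairpin loop of 3 unpaired nt); an externally computed
dot-bracket string may be supplied instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

from .io import SequenceRecord, normalize_rna

_CANONICAL = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
MIN_LOOP = 3  # no pair (i, j) with j - i < MIN_LOOP + 1


def can_pair(a: str, b: str) -> bool:
    return (a, b) in _CANONICAL


@dataclass(frozen=True)
class ReadAln:
    """One collapsed small-RNA read mapped onto a precursor."""

    start: int  # 0-based offset on the precursor
    length: int
    count: int

    def __post_init__(self) -> None:
        if self.length < 1 or self.count < 1 or self.start < 0:
            raise ValueError(f"invalid read {self!r}")

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class ReadProfile:
    hairpin_id: str
    reads: list[ReadAln]

    def total(self) -> int:
        return sum(r.count for r in self.reads)


@dataclass
class HairpinFold:
    """Secondary structure of a precursor as a position pairing."""

    precursor_id: str
    pairs: dict[int, int]  # symmetric: pairs[i] = j and pairs[j] = i
    dot_bracket: str

    @property
    def n_pairs(self) -> int:
        return len(self.pairs) // 2

    def partner(self, i: int) -> int | None:
        return self.pairs.get(i)

    def loop_bounds(self) -> tuple[int, int]:
        """Half-open interval of the (main) hairpin loop.

        Taken between the innermost pair: the pair (i, j) with the largest
        5'-side index i.  Falls back to the sequence midpoint when the fold
        has no pairs.
        """
        left = [i for i, j in self.pairs.items() if i < j]
        if not left:
            mid = len(self.dot_bracket) // 2
            return mid, mid
        i = max(left)
        return i + 1, self.pairs[i]


def fold_hairpin(precursor: SequenceRecord | str, precursor_id: str = "") -> HairpinFold:
    """Maximum base-pairing fold of a precursor (Nussinov DP).

    Pairs are Watson-Crick or G.U; hairpin loops keep at least
    ``MIN_LOOP`` unpaired nucleotides.  Ties in the traceback are broken
    deterministically (leave i unpaired before pairing it, pair with the
    smallest admissible k).
    """
    if isinstance(precursor, SequenceRecord):
        seq, pid = precursor.seq, precursor.id
    else:
        seq, pid = normalize_rna(precursor), precursor_id or "hairpin"
    n = len(seq)
    if n and seq.count("N") / n > 0.20:
        raise ValueError(f"{pid}: more than 20% ambiguous bases; refusing to fold")

    # F[i][j] = max pairs in seq[i..j]
    F = [[0] * n for _ in range(n)]
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = F[i + 1][j]
            for k in range(i + MIN_LOOP + 1, j + 1):
                if can_pair(seq[i], seq[k]):
                    left = F[i + 1][k - 1] if k - 1 >= i + 1 else 0
                    right = F[k + 1][j] if k + 1 <= j else 0
                    cand = 1 + left + right
                    if cand > best:
                        best = cand
            F[i][j] = best

    pairs: dict[int, int] = {}
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i < MIN_LOOP + 1:
            continue
        if F[i][j] == F[i + 1][j]:
            stack.append((i + 1, j))
            continue
        for k in range(i + MIN_LOOP + 1, j + 1):
            if can_pair(seq[i], seq[k]):
                left = F[i + 1][k - 1] if k - 1 >= i + 1 else 0
                right = F[k + 1][j] if k + 1 <= j else 0
                if F[i][j] == 1 + left + right:
                    pairs[i] = k
                    pairs[k] = i
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    break

    db = ["." for _ in range(n)]
    for i, j in pairs.items():
        if i < j:
            db[i], db[j] = "(", ")"
    return HairpinFold(pid, pairs, "".join(db))


def parse_dot_bracket(precursor_id: str, db: str) -> HairpinFold:
    """Build a :class:`HairpinFold` from an externally supplied structure."""
    pairs: dict[int, int] = {}
    stack: list[int] = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket")
            j = stack.pop()
            pairs[j] = i
            pairs[i] = j
        elif c != ".":
            raise ValueError(f"invalid dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket")
    return HairpinFold(precursor_id, pairs, db)


def locate_star(fold: HairpinFold, mir: tuple[int, int]) -> tuple[int, int]:
    """Place the miR* window opposite *mir* on the hairpin.

    The miR* is the contiguous span of duplex partners of the miR
    positions, shifted by +2 so each duplex strand carries the canonical
    2-nt 3' overhang.  Raises ``ValueError("no duplex")`` when fewer than
    half the miR positions are paired.
    """
    s, e = mir
    partners = [fold.pairs[i] for i in range(s, e) if i in fold.pairs]
    if len(partners) < (e - s) / 2:
        raise ValueError("no duplex")
    lo, hi = min(partners), max(partners) + 1
    n = len(fold.dot_bracket)
    return max(0, lo + 2), min(n, hi + 2)


def duplex_pair_count(fold: HairpinFold, mir: tuple[int, int], star: tuple[int, int]) -> int:
    """Number of miR positions paired to a position inside the miR* window."""
    s, e = mir
    return sum(
        1
        for i in range(s, e)
        if i in fold.pairs and star[0] <= fold.pairs[i] < star[1]
    )


def _overlaps(read: ReadAln, window: tuple[int, int] | None) -> bool:
    """A read maps to a window when it overlaps it by >= 50% of its length."""
    if window is None:
        return False
    ov = min(read.end, window[1]) - max(read.start, window[0])
    return ov >= read.length / 2


@dataclass
class ValidationReport:
    hairpin_id: str
    c1: bool
    c2: bool
    c3: bool
    c4: bool
    c5: bool
    metrics: dict = field(default_factory=dict)

    @property
    def verdict(self) -> bool:
        return self.c1 and self.c2 and self.c3 and self.c4 and self.c5

    def to_dict(self) -> dict:
        return {
            "hairpin_id": self.hairpin_id,
            "c1_star_read": self.c1,
            "c2_total_reads": self.c2,
            "c3_duplex_pairs": self.c3,
            "c4_top3_isomir": self.c4,
            "c5_background_ratio": self.c5,
            "verdict": self.verdict,
            **self.metrics,
        }


def dominant_read(profile: ReadProfile) -> ReadAln:
    """Highest-count read; ties broken by (start asc, length asc)."""
    if not profile.reads:
        raise ValueError(f"{profile.hairpin_id}: empty read profile")
    return min(profile.reads, key=lambda r: (-r.count, r.start, r.length))


def validate_mirna(
    profile: ReadProfile,
    fold: HairpinFold,
    mir: tuple[int, int] | None = None,
    min_total: int = 20,
    min_duplex_pairs: int = 13,
    top3_fraction: float = 0.85,
) -> ValidationReport:
    """Apply the five expression criteria to one hairpin.

    When *mir* is not annotated, the dominant read defines the miR window.
    A hairpin whose miR cannot form a duplex fails criterion 3 but the
    remaining criteria are still evaluated (with an empty miR* window).
    """
    if not profile.reads:
        raise ValueError(f"{profile.hairpin_id}: empty read profile")
    if mir is None:
        top = dominant_read(profile)
        mir = (top.start, top.end)

    star: tuple[int, int] | None
    try:
        star = locate_star(fold, mir)
        pairs13 = duplex_pair_count(fold, mir, star)
    except ValueError:
        star = None
        pairs13 = 0

    mir_reads = [r for r in profile.reads if _overlaps(r, mir)]
    star_reads = [r for r in profile.reads if _overlaps(r, star) and not _overlaps(r, mir)]
    duplex_ids = {id(r) for r in mir_reads} | {id(r) for r in star_reads}
    background = [r for r in profile.reads if id(r) not in duplex_ids]

    star_count = sum(r.count for r in star_reads)
    mir_count = sum(r.count for r in mir_reads)
    duplex_count = mir_count + star_count
    bg_count = sum(r.count for r in background)
    ratio = math.inf if bg_count == 0 else duplex_count / bg_count

    # isomiRs: unique (start, length) on the miR arm, ranked by
    # (count desc, start asc, length asc)
    iso: dict[tuple[int, int], int] = {}
    for r in mir_reads:
        iso[(r.start, r.length)] = iso.get((r.start, r.length), 0) + r.count
    ranked = sorted(iso.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1]))
    top3 = sum(c for _, c in ranked[:3])
    top3_frac = top3 / mir_count if mir_count else 0.0

    return ValidationReport(
        hairpin_id=profile.hairpin_id,
        c1=star_count >= 1,
        c2=duplex_count >= min_total,
        c3=pairs13 >= min_duplex_pairs,
        c4=top3_frac >= top3_fraction,
        c5=ratio > 1,
        metrics={
            "mir_window": list(mir),
            "star_window": list(star) if star else None,
            "star_read_count": star_count,
            "mir_read_count": mir_count,
            "duplex_read_count": duplex_count,
            "duplex_paired_nt": pairs13,
            "top3_isomir_fraction": top3_frac,
            "background_count": bg_count,
            "duplex_background_ratio": ratio,
        },
    )
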