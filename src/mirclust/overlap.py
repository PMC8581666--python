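"""Cross-species target-set sharing via one-to-one ortholog projection.

Target genes are projected into ortholog-tuple space before comparison;
genes without an ortholog tuple stay in the species-specific set sizes but
cannot be shared.  The headline overlap percentage is shared/union
("Jaccard x 100"); per-species percentages (shared/|set_s|) are reported
alongside because published Venn-diagram percentages do not always state
their denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .targets import TargetSet


class OrthologMap:
    """One-to-one ortholog tuples across species.

    Constructed from a DataFrame with one column per species and one row
    per tuple; missing members are NaN/empty.  No gene may appear in two
    tuples.
    """

    def __init__(self, table: pd.DataFrame):
        self.species = list(table.columns)
        self._to_tuple: dict[str, dict[str, int]] = {sp: {} for sp in self.species}
        for idx, row in enumerate(table.itertuples(index=False)):
            filled = 0
            for sp, gene in zip(self.species, row):
                if pd.isna(gene) or gene == "":
                    continue
                gene = str(gene)
                if gene in self._to_tuple[sp]:
                    raise ValueError(
                        f"gene {gene!r} appears in two ortholog tuples ({sp})"
                    )
                self._to_tuple[sp][gene] = idx
                filled += 1
            if filled < 2:
                raise ValueError(f"ortholog tuple {idx} spans fewer than 2 species")
        self.n_tuples = len(table)

    @classmethod
    def identity(cls, genes: Iterable[str], species: Sequence[str]) -> "OrthologMap":
        """Map where every gene keeps the same id in every species."""
        genes = list(genes)
        return cls(pd.DataFrame({sp: genes for sp in species}))

    def project(self, genes: Iterable[str], species: str) -> set[int]:
        """Tuple ids of the mapped genes; unmapped genes are dropped."""
        if species not in self._to_tuple:
            raise ValueError(f"species {species!r} not covered by the map")
        lut = self._to_tuple[species]
        return {lut[g] for g in genes if g in lut}

    def gene_of(self, tuple_id: int, species: str) -> str | None:
        for g, t in self._to_tuple[species].items():
            if t == tuple_id:
                return g
        return None


@dataclass
class OverlapResult:
    scope: str  # member id or "pooled"
    species: tuple[str, ...]
    shared_count: int
    set_sizes: dict[str, int]
    pct_union: float
    pct_per_species: dict[str, float]
    shared_tuples: frozenset[int] = frozenset()
    member_attribution: dict[int, dict[str, list[str]]] = field(default_factory=dict)


def _overlap(
    sets_by_species: Mapping[str, set[str]], omap: OrthologMap, scope: str
) -> OverlapResult:
    species = tuple(sorted(sets_by_species))
    projected = {sp: omap.project(sets_by_species[sp], sp) for sp in species}
    shared = set.intersection(*projected.values()) if projected else set()
    union = set.union(*projected.values()) if projected else set()
    sizes = {sp: len(sets_by_species[sp]) for sp in species}
    pct_union = 100.0 * len(shared) / len(union) if union else 0.0
    pct_per = {
        sp: (100.0 * len(shared) / sizes[sp]) if sizes[sp] else 0.0 for sp in species
    }
    return OverlapResult(
        scope=scope,
        species=species,
        shared_count=len(shared),
        set_sizes=sizes,
        pct_union=pct_union,
        pct_per_species=pct_per,
        shared_tuples=frozenset(shared),
    )


def pairwise_overlap(
    a: TargetSet | set[str],
    b: TargetSet | set[str],
    omap: OrthologMap,
    species: tuple[str, str] | None = None,
    scope: str | None = None,
) -> OverlapResult:
    """Shared-target statistics for two species' sets.

    Accepts :class:`TargetSet` objects (species and member taken from them)
    or raw gene sets with an explicit *species* pair.
    """
    if isinstance(a, TargetSet) and isinstance(b, TargetSet):
        sets = {a.species: a.genes, b.species: b.genes}
        scope = scope or a.member
    else:
        if species is None:
            raise ValueError("raw gene sets need an explicit species pair")
        sets = {species[0]: set(a), species[1]: set(b)}  # type: ignore[arg-type]
        scope = scope or "set"
    if len(sets) != 2:
        raise ValueError("the two target sets must come from different species")
    return _overlap(sets, omap, scope)


def multiway_overlap(
    sets_by_species: Mapping[str, set[str]], omap: OrthologMap, scope: str = "set"
) -> OverlapResult:
    """Shared-target statistics over two or more species."""
    if len(sets_by_species) < 2:
        raise ValueError("need at least two species")
    return _overlap(dict(sets_by_species), omap, scope)


def pooled_overlap(
    sets_by_member: Mapping[str, Mapping[str, TargetSet]], omap: OrthologMap
) -> OverlapResult:
    """Overlap of the pooled (union over members) cluster target sets.

    *sets_by_member* maps species -> member -> TargetSet.  In addition to
    the shared counts, reports which member(s) target each shared gene in
    each species — a gene may be shared at the cluster level while no single
    member shares it.
    """
    species = sorted(sets_by_member)
    if len(species) < 2:
        raise ValueError("need at least two species")
    pooled_sets = {
        sp: set().union(*(ts.genes for ts in sets_by_member[sp].values()))
        for sp in species
    }
    result = _overlap(pooled_sets, omap, scope="pooled")
    for t in sorted(result.shared_tuples):
        attribution: dict[str, list[str]] = {}
        for sp in species:
            members = [
                m
                for m, ts in sorted(sets_by_member[sp].items())
                if t in omap.project(ts.genes, sp)
            ]
            attribution[sp] = members
        result.member_attribution[t] = attribution
    return result


def target_fraction(target_genes: set[str], transcriptome: set[str]) -> float:
    """Percentage of the transcriptome covered by a target set."""
    if not transcriptome:
        raise ValueError("empty transcriptome")
    extra = set(target_genes) - transcriptome
    if extra:
        raise ValueError(
            f"target genes outside the transcriptome: {sorted(extra)[:5]} ..."
        )
    return 100.0 * len(target_genes) / len(transcriptome)
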