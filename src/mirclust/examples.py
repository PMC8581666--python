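"""Worked example data: the Drosophila mir-972 cluster (mir-972C).

mir-972C is a young, testes-expressed miRNA cluster on the D. melanogaster
X chromosome with 12 members in three tight sub-clusters plus one orphan.
Expression of individual members was verified from testes small-RNA
libraries in four species; this module encodes that presence/absence
evidence, the four-species tree, and locus coordinates consistent with the
cluster's published extent (three sub-clusters each spanning under 1 kb,
within a 10.8-kb region).

Coordinates are illustrative offsets within the cluster region (the
sub-cluster grouping, not the exact base positions, is the datum).
"""

from __future__ import annotations

import pandas as pd

from .io import GenomicInterval, SpeciesTree, parse_newick

#: Species tree of the four assayed species; the Sophophora/Drosophila
#: split is the root (dvir is the subgenus Drosophila representative).
TREE_NEWICK = "(((dmel,dsim),dpse),dvir);"

#: Expression-verified presence of each member (testes small-RNA evidence).
#: Sequence homologs without verified expression count as absent.
PRESENCE = {
    # member: (dmel, dsim, dpse, dvir)
    "mir-972": (1, 1, 0, 0),
    "mir-9369": (1, 1, 0, 0),
    "mir-973": (1, 1, 0, 1),
    "mir-974": (1, 1, 0, 1),
    "mir-4966-1": (1, 1, 0, 0),
    "mir-4966-2": (1, 1, 0, 0),
    "mir-975": (1, 1, 0, 1),
    "mir-976": (1, 1, 0, 1),
    "mir-977": (1, 1, 0, 1),
    "mir-978": (1, 1, 0, 1),
    "mir-979": (1, 0, 0, 0),
    "mir-2499": (1, 1, 0, 0),
}

#: Illustrative cluster-relative coordinates: three sub-clusters
#: (mir-972/9369/973/974 | mir-4966-1/4966-2/975/976/977 | mir-978/979)
#: each spanning < 1 kb, orphan mir-2499, total extent 10.8 kb.
LOCI = [
    ("mir-972", 0, 90),
    ("mir-9369", 240, 330),
    ("mir-973", 480, 570),
    ("mir-974", 720, 810),
    ("mir-4966-1", 2500, 2590),
    ("mir-4966-2", 2720, 2810),
    ("mir-975", 2940, 3030),
    ("mir-976", 3160, 3250),
    ("mir-977", 3380, 3470),
    ("mir-978", 5500, 5590),
    ("mir-979", 5740, 5830),
    ("mir-2499", 10710, 10800),
]


def species_tree() -> SpeciesTree:
    return parse_newick(TREE_NEWICK)


def presence_matrix() -> pd.DataFrame:
    """Members x species boolean presence matrix."""
    df = pd.DataFrame.from_dict(
        PRESENCE, orient="index", columns=["dmel", "dsim", "dpse", "dvir"]
    )
    return df.astype(bool)


def cluster_loci() -> list[tuple[str, GenomicInterval]]:
    return [(name, GenomicInterval("X", s, e)) for name, s, e in LOCI]


def downregulated_sets() -> tuple[set[str], set[str]]:
    """Down-regulated target sets of the melanogaster/simulans comparison.

    36 genes down-regulated in one species and 35 in the other with 6
    orthologous genes in common (set contents are placeholders; the sizes
    and intersection are the data).
    """
    shared = {f"shared{i}" for i in range(6)}
    a = shared | {f"melonly{i}" for i in range(30)}
    b = shared | {f"simonly{i}" for i in range(29)}
    return a, b
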