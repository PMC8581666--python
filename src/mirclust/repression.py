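"""Target-repression tests on control vs miRNA-overexpression expression data.

Replicates are averaged per condition, genes with zero mean in either
condition are dropped, and the per-gene log2 fold change (treatment over
control) feeds a two-sample Kolmogorov-Smirnov comparison of predicted
targets against the non-target background plus a fold-change cutoff call of
down-regulated targets.  A separate analysis counts the UTR base pairing
mature nucleotide 9 at each predicted site and compares its composition
between species with Fisher's exact test.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionTable, SequenceRecord
from .overlap import OrthologMap, OverlapResult, pairwise_overlap
from .seeds import MatureAssignment
from .targets import SeedSite


@dataclass
class DiffExprResult:
    lfc: pd.Series  # gene -> log2(treatment mean / control mean)
    excluded: list[str]  # zero-expression genes removed


def log2_fold_changes(
    control: ExpressionTable, treatment: ExpressionTable
) -> DiffExprResult:
    """Per-gene log2 fold change of replicate-averaged expression.

    Genes with a zero mean in either condition are excluded (non-expressed)
    and listed in the result.
    """
    common = [g for g in control.genes if g in set(treatment.genes)]
    if not common:
        raise ValueError("control and treatment share no genes")
    c = control.data.loc[common].mean(axis=1)
    t = treatment.data.loc[common].mean(axis=1)
    ok = (c > 0) & (t > 0)
    excluded = [g for g in common if not ok[g]]
    lfc = np.log2(t[ok] / c[ok])
    return DiffExprResult(lfc=lfc, excluded=excluded)


@dataclass(frozen=True)
class KSResult:
    statistic: float  # sup |ECDF_x - ECDF_y|
    p_value: float
    n_x: int
    n_y: int
    method: str

    def __post_init__(self) -> None:
        if not 0 <= self.statistic <= 1 or not 0 <= self.p_value <= 1:
            raise ValueError("KS statistic and p-value must lie in [0, 1]")


def ks_two_sample(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> KSResult:
    """Two-sample two-sided Kolmogorov-Smirnov test.

    ``method="auto"`` uses the exact null distribution of D when
    min(n) < 10 and the asymptotic Kolmogorov distribution (with effective
    n = n_x n_y / (n_x + n_y)) otherwise; ``"exact"``/``"asymp"`` force a
    choice and ``"permutation"`` enumerates or samples label permutations.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if method == "auto":
        method = "exact" if min(x.size, y.size) < 10 else "asymp"
    if method in ("exact", "asymp"):
        res = stats.ks_2samp(x, y, alternative="two-sided", method=method)
        return KSResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                        x.size, y.size, method)
    if method == "permutation":
        res = stats.ks_2samp(x, y, alternative="two-sided", method="asymp")
        d_obs = float(res.statistic)
        rng = np.random.default_rng(0)
        pooled = np.concatenate([x, y])
        n_iter = 2000
        hits = 0
        for _ in range(n_iter):
            perm = rng.permutation(pooled)
            d = stats.ks_2samp(perm[: x.size], perm[x.size :]).statistic
            if d >= d_obs - 1e-12:
                hits += 1
        return KSResult(d_obs, hits / n_iter, x.size, y.size, "permutation")
    raise ValueError(f"unknown method {method!r}")


def call_downregulated(dx: DiffExprResult, fold_cutoff: float = 1.2) -> set[str]:
    """Genes repressed by at least *fold_cutoff* (LFC <= -log2(cutoff))."""
    if fold_cutoff <= 1:
        raise ValueError("fold_cutoff must be > 1")
    thr = -math.log2(fold_cutoff)
    return set(dx.lfc.index[dx.lfc <= thr + 1e-12])


def shared_downregulated(
    sets_by_species: Mapping[str, set[str]], omap: OrthologMap
) -> list[OverlapResult]:
    """Pairwise shared down-regulated targets across species."""
    species = sorted(sets_by_species)
    if len(species) < 2:
        raise ValueError("need at least two species")
    out = []
    for i, sa in enumerate(species):
        for sb in species[i + 1 :]:
            out.append(
                pairwise_overlap(
                    sets_by_species[sa],
                    sets_by_species[sb],
                    omap,
                    species=(sa, sb),
                    scope="downregulated",
                )
            )
    return out


@dataclass(frozen=True)
class Fisher2x2Result:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_two_sided: float


def fisher_exact(table: Sequence[Sequence[int]]) -> Fisher2x2Result:
    """Two-sided Fisher's exact test on a 2x2 table.

    The p-value sums the hypergeometric probabilities of every table with
    the same margins whose probability does not exceed the observed one.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer entries")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin in 2x2 table")
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return Fisher2x2Result(
        ((int(t[0, 0]), int(t[0, 1])), (int(t[1, 0]), int(t[1, 1]))),
        float(odds),
        float(p),
    )


def position9_composition(
    sites: Iterable[SeedSite],
    utrs: Mapping[str, SequenceRecord] | Iterable[SequenceRecord],
) -> tuple[Counter, int]:
    """Base composition at the UTR position pairing mature nucleotide 9.

    The seed match pairs mature nt 2-8 antiparallel to the UTR, so mature
    nt 9 pairs the base immediately 5' of the match start: position p-1 for
    8mer/7mer-m8 sites at p, and p-2 for 7mer-1A sites (whose match starts
    at the nt-7 pairing base).  Sites at the UTR boundary lacking that
    context are excluded and counted.
    """
    if not isinstance(utrs, Mapping):
        utrs = {u.id: u for u in utrs}
    counts: Counter = Counter()
    excluded = 0
    for site in sites:
        offset = 1 if site.site_class in ("8mer", "7mer-m8") else 2
        pos = site.utr_position - offset
        if pos < 0 or site.gene not in utrs:
            excluded += 1
            continue
        counts[utrs[site.gene].seq[pos]] += 1
    return counts, excluded


def compare_position9(
    counts_a: Counter, counts_b: Counter, base: str
) -> Fisher2x2Result:
    """Fisher test of one base's enrichment between two species' sites."""
    a_hit = counts_a.get(base, 0)
    b_hit = counts_b.get(base, 0)
    a_rest = sum(counts_a.values()) - a_hit
    b_rest = sum(counts_b.values()) - b_hit
    return fisher_exact([[a_hit, a_rest], [b_hit, b_rest]])
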