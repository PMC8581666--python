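"""Canonical seed-match target prediction on expressed 3'UTRs.

Site classes follow the canonical hierarchy.  With the seed being mature
nucleotides 2-8 and M its reverse complement on the UTR:

* 8mer     — exact match to M followed by an A (opposite mature nt 1);
* 7mer-m8  — exact match to M (pairs mature nt 2-8);
* 7mer-1A  — exact match to M without its 5'-most base (pairs mature nt
  2-7) followed by an A.

Each UTR position is reported once with its most specific class
(8mer > 7mer-m8 > 7mer-1A).  Scanning is strand-specific (sense UTR only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import ExpressionTable, SequenceRecord, reverse_complement

SITE_CLASSES = ("8mer", "7mer-m8", "7mer-1A")
DEFAULT_CLASSES = ("8mer", "7mer-m8")


def compute_tpm(counts: ExpressionTable, lengths: Mapping[str, float]) -> ExpressionTable:
    """Transcripts-per-million normalization of a count matrix.

    TPM_g = (count_g / length_kb_g) / sum_h (count_h / length_kb_h) * 1e6,
    per sample; every column sums to 1e6.
    """
    if counts.unit != "counts":
        raise ValueError(f"expected a counts table, got unit {counts.unit!r}")
    missing = set(counts.genes) - set(lengths)
    if missing:
        raise ValueError(f"missing lengths for genes: {sorted(missing)[:5]} ...")
    kb = pd.Series({g: lengths[g] / 1000.0 for g in counts.genes})
    if (kb <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.data.div(kb, axis=0)
    total = rate.sum(axis=0)
    if (total == 0).any():
        raise ValueError("sample with zero total rate; cannot normalize")
    return ExpressionTable(rate.div(total, axis=1) * 1e6, unit="TPM")


def filter_expressed(tpm: ExpressionTable, threshold: float = 1.0) -> set[str]:
    """Genes whose mean expression across samples is at or above *threshold*.

    With the default threshold of 1, genes with mean TPM < 1 are removed.
    """
    means = tpm.data.mean(axis=1)
    return set(means.index[means >= threshold])


@dataclass(frozen=True)
class SeedSite:
    gene: str
    utr_position: int  # 0-based start of the match on the UTR
    site_class: str

    def __post_init__(self) -> None:
        if self.site_class not in SITE_CLASSES:
            raise ValueError(f"unknown site class {self.site_class!r}")


def find_sites(
    utr: SequenceRecord,
    seed: str,
    site_classes: Sequence[str] = SITE_CLASSES,
    collapse: bool = True,
) -> list[SeedSite]:
    """Scan one UTR for seed-match sites.

    With ``collapse=True`` (default) each physical site is reported once
    under its most specific class; with ``collapse=False`` every class whose
    pattern matches is reported independently (an 8mer position then also
    yields a 7mer-m8 site).
    """
    if len(seed) != 7:
        raise ValueError(f"seed must be 7 nt, got {len(seed)}")
    if set(seed) - set("ACGU"):
        raise ValueError(f"ambiguous base in seed {seed!r}")
    m = reverse_complement(seed)  # pairs mature nt 8..2, 5'->3' on the UTR
    m6 = m[1:]  # pairs mature nt 7..2
    s = utr.seq
    n = len(s)
    sites: list[SeedSite] = []
    for p in range(n):
        is_m8 = s[p : p + 7] == m
        is_8mer = is_m8 and p + 7 < n and s[p + 7] == "A"
        is_1a = s[p : p + 6] == m6 and p + 6 < n and s[p + 6] == "A"
        if collapse:
            if is_8mer and "8mer" in site_classes:
                sites.append(SeedSite(utr.id, p, "8mer"))
            elif is_m8 and "7mer-m8" in site_classes:
                sites.append(SeedSite(utr.id, p, "7mer-m8"))
            elif (
                is_1a
                and "7mer-1A" in site_classes
                and not (p > 0 and s[p - 1] == m[0])
            ):
                # guard: a 7mer-1A preceded by the m8 base is the same
                # physical site as the 7mer-m8/8mer starting one base 5'
                sites.append(SeedSite(utr.id, p, "7mer-1A"))
        else:
            if is_8mer and "8mer" in site_classes:
                sites.append(SeedSite(utr.id, p, "8mer"))
            if is_m8 and "7mer-m8" in site_classes:
                sites.append(SeedSite(utr.id, p, "7mer-m8"))
            if is_1a and "7mer-1A" in site_classes:
                sites.append(SeedSite(utr.id, p, "7mer-1A"))
    return sites


@dataclass
class TargetSet:
    species: str
    member: str  # member id or "cluster-pooled"
    genes: set[str] = field(default_factory=set)
    sites: list[SeedSite] = field(default_factory=list)


def predict_targets(
    seeds: Mapping[str, str],
    utrs: Iterable[SequenceRecord],
    expressed: set[str] | None,
    species: str = "",
    site_classes: Sequence[str] = DEFAULT_CLASSES,
) -> tuple[dict[str, TargetSet], TargetSet]:
    """Per-member target sets and the pooled cluster set for one species.

    Genes outside *expressed* (when given) are excluded before scanning.
    The pooled set is the union of the member sets.
    """
    utr_list = [u for u in utrs if expressed is None or u.id in expressed]
    per_member: dict[str, TargetSet] = {}
    pooled = TargetSet(species, "cluster-pooled")
    for member in sorted(seeds):
        ts = TargetSet(species, member)
        for utr in utr_list:
            hits = find_sites(utr, seeds[member], site_classes)
            if hits:
                ts.genes.add(utr.id)
                ts.sites.extend(hits)
        per_member[member] = ts
        pooled.genes |= ts.genes
        pooled.sites.extend(ts.sites)
    return per_member, pooled
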