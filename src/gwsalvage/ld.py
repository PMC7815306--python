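"""Linkage-disequilibrium operations: proxy expansion, exclusion of signals in
LD with established genome-wide-significant hits, and locus clustering.

All r² thresholds are strict (``r² > t``); boundary equality fails the test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping

from .io import LdPanel

logger = logging.getLogger(__name__)

R2_PROXY = 0.8
R2_EXCLUDE = 0.1
R2_CLUSTER = 0.4


@dataclass(frozen=True, slots=True)
class ProxyExpansion:
    """Result of proxy expansion: one proxy set per sentinel.

    ``no_ld`` flags sentinels with no pairs recorded in the panel; such
    sentinels carry only themselves as proxies and the pipeline drops them,
    since signals without LD information cannot be clustered or matched.
    """

    proxies: dict[str, set[str]]
    no_ld: frozenset[str]

    def __getitem__(self, sentinel: str) -> set[str]:
        return self.proxies[sentinel]

    def pool(self, drop_no_ld: bool = False) -> set[str]:
        """Union of proxy sets over sentinels — the candidate pool."""
        out: set[str] = set()
        for sentinel, members in self.proxies.items():
            if drop_no_ld and sentinel in self.no_ld:
                continue
            out |= members
        return out


@dataclass(frozen=True)
class Locus:
    """An independent cluster of surviving SNPs.

    ``members`` are the surviving SNPs themselves; ``extended_members`` add,
    once, every panel SNP in LD (r² above the clustering threshold) with any
    member. The extension is applied a single time — it is used for locus
    identity/overlap only and is never re-expanded.
    """

    members: frozenset[str]
    extended_members: frozenset[str]
    representative: str
    bin: str = ""
    cell_types: frozenset[str] = frozenset()
    contacted_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.members <= self.extended_members:
            raise ValueError("members must be a subset of extended_members")

    def annotate(self, **kwargs) -> "Locus":
        return replace(self, **kwargs)


def find_proxies(
    sentinels: set[str], panel: LdPanel, r2_min: float = R2_PROXY
) -> ProxyExpansion:
    """Expand each sentinel to its proxies at ``r² > r2_min`` (self included)."""
    if not (0.0 <= r2_min < 1.0):
        raise ValueError(f"r2_min must be in [0, 1), got {r2_min}")
    proxies = {s: panel.query(s, r2_min) for s in sentinels}
    no_ld = frozenset(s for s in sentinels if not panel.has_ld(s))
    if no_ld:
        logger.info("%d sentinels carry no LD information", len(no_ld))
    return ProxyExpansion(proxies=proxies, no_ld=no_ld)


def exclude_gws_ld(
    candidates: set[str],
    gws_snps: set[str],
    panel: LdPanel,
    r2_max: float = R2_EXCLUDE,
) -> set[str]:
    """Drop candidates in even modest LD (r² > ``r2_max``) with any GWS SNP.

    GWS SNPs themselves are always removed: the aim is to salvage signals not
    already represented by an established genome-wide-significant locus.
    """
    survivors = set()
    for c in candidates:
        if c in gws_snps:
            continue
        if any(panel.r2(c, g) > r2_max for g in gws_snps):
            continue
        survivors.add(c)
    return survivors


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra

    def groups(self):
        out: dict[str, set[str]] = {}
        for x in self.parent:
            out.setdefault(self.find(x), set()).add(x)
        return list(out.values())


def cluster_loci(
    survivors: set[str],
    panel: LdPanel,
    r2_cluster: float = R2_CLUSTER,
    pvalues: Mapping[str, float] | None = None,
) -> list[Locus]:
    """Group surviving SNPs into independent loci by their pairwise LD.

    The procedure is:

    1. connected components of the ``r² > r2_cluster`` graph restricted to
       the survivors (components, not greedy clumping, so the result is
       independent of input order);
    2. one extension pass adding every panel SNP with ``r² > r2_cluster``
       against any component member to ``extended_members``;
    3. a single merge pass joining loci whose extended member sets overlap.

    The extension is deliberately not iterated: SNPs reachable only through
    chains of non-member proxies do not merge loci (a transitive closure
    would), keeping loci local to their LD neighbourhood.

    The representative is the member with the lowest p-value when ``pvalues``
    is given (ties broken lexicographically by rsid), else the
    lexicographically smallest member.
    """
    if not survivors:
        return []
    uf = _UnionFind(survivors)
    for s in survivors:
        for b, r2 in panel.partners(s).items():
            if b in survivors and r2 > r2_cluster:
                uf.union(s, b)
    components = uf.groups()

    extended = []
    for comp in components:
        ext = set(comp)
        for s in comp:
            ext.update(b for b, r2 in panel.partners(s).items() if r2 > r2_cluster)
        extended.append((comp, ext))

    # single merge pass over loci whose extensions overlap
    merge_uf = _UnionFind(range(len(extended)))
    owner: dict[str, int] = {}
    for i, (_, ext) in enumerate(extended):
        for snp in ext:
            if snp in owner:
                merge_uf.union(owner[snp], i)
            else:
                owner[snp] = i
    merged: dict[int, tuple[set[str], set[str]]] = {}
    for i, (comp, ext) in enumerate(extended):
        root = merge_uf.find(i)
        if root not in merged:
            merged[root] = (set(), set())
        merged[root][0].update(comp)
        merged[root][1].update(ext)

    def representative(members: set[str]) -> str:
        if pvalues is None:
            return min(members)
        return min(members, key=lambda r: (pvalues.get(r, 1.0), r))

    loci = [
        Locus(
            members=frozenset(comp),
            extended_members=frozenset(ext),
            representative=representative(comp),
        )
        for comp, ext in merged.values()
    ]
    return sorted(loci, key=lambda l: min(l.members))
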