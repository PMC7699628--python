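"""Rule-based BGC calling, family assignment and cluster matching.

Hits are chained per contig left to right: a new hit-bearing ORF joins
the open chain whenever the nucleotide gap to the previous hit-bearing
ORF is at most the chaining gap, otherwise the chain is closed and a new
one opened.  A chain becomes a BGC iff at least one cluster rule is
satisfied (enough domains, required families present).  Chains touching
a contig edge are still reported, flagged ``possibly_truncated``, since
fragmented assemblies routinely split clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .domains import DomainHit
from .knowledgebase import ClusterRule, Knowledgebase
from .seqio import Orf

HYBRID = "hybrid"
OTHER = "other"


@dataclass
class Bgc:
    contig_id: str
    start: int
    end: int
    orfs: list[Orf]
    hits: list[DomainHit]
    families: set[str] = field(default_factory=set)
    category: str = OTHER
    possibly_truncated: bool = False
    label: str | None = None      # explicit id (synthetic clusters)

    @property
    def bgc_id(self) -> str:
        return self.label or f"{self.contig_id}:{self.start}-{self.end}"


def _rule_satisfied(rule: ClusterRule, hit_families: list[str]) -> bool:
    if len(hit_families) < rule.min_domains:
        return False
    present = set(hit_families)
    return all(any(f in present for f in any_of)
               for any_of in rule.required)


def assign_family(bgc: Bgc, rules: list[ClusterRule],
                  kb: Knowledgebase) -> tuple[set[str], str]:
    """Families of every satisfied rule, plus the derived category.

    Two or more families make the cluster ``hybrid``; a single family
    outside the structure-predictable set maps to category ``other``.
    """
    hit_families = [kb.models[h.model_id].family for h in bgc.hits]
    families = {rule.family for rule in rules
                if _rule_satisfied(rule, hit_families)}
    predictable = {r.family for r in rules if r.predictable}
    if len(families) >= 2:
        category = HYBRID
    elif len(families) == 1:
        fam = next(iter(families))
        category = fam if fam in predictable else OTHER
    else:
        category = OTHER
    return families, category


def call_clusters(hits: list[DomainHit], rules: list[ClusterRule],
                  kb: Knowledgebase,
                  contig_lengths: dict[str, int] | None = None,
                  edge_margin: int = 50) -> list[Bgc]:
    """Chain hits into candidate clusters and keep those satisfying a rule.

    Each hit belongs to at most one cluster; cluster boundaries are the
    union of member ORF extents.
    """
    max_gap = max((r.max_gap_nt for r in rules), default=10000)
    by_contig: dict[str, list[DomainHit]] = {}
    for hit in hits:
        by_contig.setdefault(hit.orf.contig_id, []).append(hit)
    clusters: list[Bgc] = []
    for contig_id in sorted(by_contig):
        chits = sorted(by_contig[contig_id],
                       key=lambda h: (h.orf.start, h.orf.end, h.model_id))
        chains: list[list[DomainHit]] = []
        current: list[DomainHit] = []
        prev_end: int | None = None
        for hit in chits:
            if prev_end is not None and hit.orf.start - prev_end > max_gap:
                chains.append(current)
                current = []
            current.append(hit)
            prev_end = max(prev_end or 0, hit.orf.end)
        if current:
            chains.append(current)
        for chain in chains:
            orfs: list[Orf] = []
            seen: set[str] = set()
            for hit in chain:
                if hit.orf.orf_id not in seen:
                    seen.add(hit.orf.orf_id)
                    orfs.append(hit.orf)
            start = min(o.start for o in orfs)
            end = max(o.end for o in orfs)
            bgc = Bgc(contig_id=contig_id, start=start, end=end,
                      orfs=orfs, hits=chain)
            families, category = assign_family(bgc, rules, kb)
            if not families:
                continue
            bgc.families = families
            bgc.category = category
            if contig_lengths and contig_id in contig_lengths:
                clen = contig_lengths[contig_id]
                bgc.possibly_truncated = (start <= edge_margin
                                          or end >= clen - edge_margin)
            clusters.append(bgc)
    return clusters


@dataclass
class MatchResult:
    matched: list[tuple[Bgc, Bgc]]
    a_only: list[Bgc]
    b_only: list[Bgc]


def match_clusters(set_a: list[Bgc], set_b: list[Bgc]) -> MatchResult:
    """Pair clusters whose intervals overlap by >= 1 nt on one contig.

    A cluster may match multiple counterparts.
    """
    matched: list[tuple[Bgc, Bgc]] = []
    a_hit: set[int] = set()
    b_hit: set[int] = set()
    for i, a in enumerate(set_a):
        for j, b in enumerate(set_b):
            if a.contig_id != b.contig_id:
                continue
            if min(a.end, b.end) - max(a.start, b.start) >= 1:
                matched.append((a, b))
                a_hit.add(i)
                b_hit.add(j)
    return MatchResult(
        matched=matched,
        a_only=[a for i, a in enumerate(set_a) if i not in a_hit],
        b_only=[b for j, b in enumerate(set_b) if j not in b_hit])
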