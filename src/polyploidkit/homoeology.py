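"""Collinearity, homoeologous quartets and tandem gene arrays.

Distances here are gene-rank differences on a chromosome, never base pairs:
the chaining parameters (maximum gap of 20 genes between consecutive
matches, minimum 10 aligned pairs per block) and the tandem rule (maximum
distance of 10 genes between same-family neighbours) are all expressed in
gene units.

Order of operations: tandem arrays are detected first and their non-primary
members removed from the match set before synteny chaining, so local
duplications do not fragment collinear blocks.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError
from .model import GenomeLayout

__all__ = [
    "MatchPair",
    "SyntenyBlock",
    "TandemArray",
    "HomoeologQuartet",
    "matches_from_families",
    "chain_synteny",
    "detect_tandem",
    "remove_tandem_matches",
    "map_quartets",
    "gene_content_profile",
    "expressed_fraction",
]


@dataclass(frozen=True)
class MatchPair:
    gene_a: str
    gene_b: str
    chrom_a: str
    chrom_b: str
    rank_a: int
    rank_b: int
    score: float = 1.0


@dataclass
class SyntenyBlock:
    chrom_a: str
    chrom_b: str
    pairs: list[MatchPair]
    inverted: bool

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def score(self) -> float:
        return float(sum(p.score for p in self.pairs))

    @property
    def span(self) -> int:
        ra = [p.rank_a for p in self.pairs]
        rb = [p.rank_b for p in self.pairs]
        return (max(ra) - min(ra)) + (max(rb) - min(rb))


@dataclass
class TandemArray:
    chrom: str
    family: str
    members: list[str]  # gene ids ordered by rank

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class HomoeologQuartet:
    """One collinear position across the four copies of a quartet.

    ``copies`` maps copy index (1..4) to the syntenic gene id, or None when
    the copy lost the gene (fractionation).
    """

    region_id: int
    quartet_id: int
    copies: dict[int, str | None] = field(default_factory=dict)

    @property
    def n_present(self) -> int:
        return sum(1 for g in self.copies.values() if g is not None)

    @property
    def complete(self) -> bool:
        return self.n_present == 4


def matches_from_families(layout: GenomeLayout) -> list[MatchPair]:
    """All-vs-all within-family match pairs across different chromosomes.

    Stands in for a sequence self-alignment when genes carry family labels
    (the synthetic path); real match tables can be supplied instead.
    """
    by_family: dict[str, list] = {}
    for g in layout.genes:
        by_family.setdefault(g.family, []).append(g)
    pairs = []
    for members in by_family.values():
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                if a.chrom_id == b.chrom_id:
                    continue
                if (a.chrom_id, a.rank) > (b.chrom_id, b.rank):
                    a, b = b, a
                pairs.append(MatchPair(a.gene_id, b.gene_id, a.chrom_id, b.chrom_id,
                                       a.rank, b.rank))
    pairs.sort(key=lambda p: (p.chrom_a, p.chrom_b, p.rank_a, p.rank_b, p.gene_a, p.gene_b))
    return pairs


# ---------------------------------------------------------------------------
# Synteny chaining


def chain_sort_key(chain: list[MatchPair]) -> tuple:
    """Total order over candidate chains: longest first, then smallest
    total rank span, then smallest first gene_a id, then lexicographic on
    the full pair sequence. Monotone under extension, so dynamic
    programming over chain prefixes is exact."""
    span = _chain_span(chain)
    seq = tuple((p.rank_a, p.rank_b, p.gene_a, p.gene_b) for p in chain)
    return (-len(chain), span, chain[0].gene_a, seq)


def _best_chain(pairs: list[MatchPair], max_gap: int, inverted: bool):
    """Best chain by dynamic programming over pairs on one chromosome pair.

    Chains are strictly monotone in rank_a and in rank_b (decreasing in
    rank_b when inverted) with consecutive pairs at most max_gap ranks
    apart on both chromosomes. Each state keeps the best chain ending at
    that pair under :func:`chain_sort_key`; the key is preserved by
    appending a common element, so local choices are globally optimal.
    """
    sign = -1 if inverted else 1
    order = sorted(range(len(pairs)),
                   key=lambda i: (pairs[i].rank_a, sign * pairs[i].rank_b,
                                  pairs[i].gene_a, pairs[i].gene_b))
    best_at: dict[int, list[MatchPair]] = {}
    for oi, j in enumerate(order):
        pj = pairs[j]
        best = [pj]
        best_key = chain_sort_key(best)
        for i in order[:oi]:
            pi = pairs[i]
            da = pj.rank_a - pi.rank_a
            db = sign * (pj.rank_b - pi.rank_b)
            if da <= 0 or db <= 0 or da > max_gap or db > max_gap:
                continue
            cand = best_at[i] + [pj]
            key = chain_sort_key(cand)
            if key < best_key:
                best, best_key = cand, key
        best_at[j] = best
    return min(best_at.values(), key=chain_sort_key)


def chain_synteny(pairs: list[MatchPair], max_gap: int = 20,
                  min_pairs: int = 10,
                  layout: GenomeLayout | None = None) -> list[SyntenyBlock]:
    """Chain match pairs into collinear synteny blocks.

    Per chromosome pair, the maximal chain (same or inverted orientation)
    under the gap constraint is extracted, its matches removed, and the
    search repeated; chains shorter than ``min_pairs`` are discarded. Each
    match therefore belongs to at most one block.
    """
    if layout is not None:
        for p in pairs:
            layout.gene(p.gene_a)
            layout.gene(p.gene_b)
    by_cpair: dict[tuple[str, str], list[MatchPair]] = {}
    for p in pairs:
        by_cpair.setdefault((p.chrom_a, p.chrom_b), []).append(p)
    blocks: list[SyntenyBlock] = []
    for (ca, cb), plist in sorted(by_cpair.items()):
        remaining = list(plist)
        while len(remaining) >= min_pairs:
            fwd = _best_chain(remaining, max_gap, inverted=False)
            rev = _best_chain(remaining, max_gap, inverted=True)
            chain, inverted = min(
                ((fwd, False), (rev, True)),
                key=lambda ci: (*chain_sort_key(ci[0]), ci[1]),
            )
            if len(chain) < min_pairs:
                break
            blocks.append(SyntenyBlock(ca, cb, chain, inverted))
            used = {(p.gene_a, p.gene_b) for p in chain}
            remaining = [p for p in remaining if (p.gene_a, p.gene_b) not in used]
    return blocks


def _chain_span(chain: list[MatchPair]) -> int:
    ra = [p.rank_a for p in chain]
    rb = [p.rank_b for p in chain]
    return (max(ra) - min(ra)) + (max(rb) - min(rb))


# ---------------------------------------------------------------------------
# Tandem arrays


def detect_tandem(layout: GenomeLayout,
                  max_tandem_distance: int = 10) -> list[TandemArray]:
    """Detect tandem arrays: same-family genes on one chromosome linked when
    their rank distance is <= max_tandem_distance; arrays are the transitive
    closures of that relation with >= 2 members.
    """
    groups: dict[tuple[str, str], list] = {}
    for g in layout.genes:
        groups.setdefault((g.chrom_id, g.family), []).append(g)
    arrays = []
    for (chrom, family), members in sorted(groups.items()):
        members.sort(key=lambda g: g.rank)
        run = [members[0]]
        for g in members[1:]:
            if g.rank - run[-1].rank <= max_tandem_distance:
                run.append(g)
            else:
                if len(run) >= 2:
                    arrays.append(TandemArray(chrom, family, [x.gene_id for x in run]))
                run = [g]
        if len(run) >= 2:
            arrays.append(TandemArray(chrom, family, [x.gene_id for x in run]))
    return arrays


def tandem_size_histogram(arrays: list[TandemArray]) -> dict[int, int]:
    hist: dict[int, int] = {}
    for a in arrays:
        hist[a.size] = hist.get(a.size, 0) + 1
    return dict(sorted(hist.items()))


def remove_tandem_matches(pairs: list[MatchPair],
                          arrays: list[TandemArray]) -> list[MatchPair]:
    """Drop matches involving non-primary tandem members.

    The lowest-rank member of each array represents it; matches touching the
    other members are removed before chaining.
    """
    drop = set()
    for arr in arrays:
        drop.update(arr.members[1:])
    return [p for p in pairs if p.gene_a not in drop and p.gene_b not in drop]


# ---------------------------------------------------------------------------
# Quartet mapping and gene-content profiles


def map_quartets(blocks: list[SyntenyBlock], layout: GenomeLayout) -> list[HomoeologQuartet]:
    """Group synteny-matched genes into collinear positions across the four
    copies of each chromosome quartet.

    Matched pairs from blocks connecting copies of the same quartet are
    merged by union-find; each component is one collinear position. When a
    component holds more than one gene for a copy (ambiguous pairing), the
    gene from the higher-scoring block wins.
    """
    chrom_info = {c.chrom_id: c for c in layout.chromosomes}
    parent: dict[str, str] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    gene_block_score: dict[str, float] = {}
    for b in blocks:
        qa = chrom_info[b.chrom_a].quartet_id
        qb = chrom_info[b.chrom_b].quartet_id
        if qa != qb:
            continue
        for p in b.pairs:
            for g in (p.gene_a, p.gene_b):
                parent.setdefault(g, g)
                gene_block_score[g] = max(gene_block_score.get(g, 0.0), b.score)
            union(p.gene_a, p.gene_b)

    components: dict[str, list[str]] = {}
    for g in parent:
        components.setdefault(find(g), []).append(g)

    quartets = []
    items = []
    for genes in components.values():
        rep = layout.gene(min(genes, key=lambda g: (chrom_info[layout.gene(g).chrom_id].copy_index,
                                                    layout.gene(g).rank)))
        items.append((chrom_info[rep.chrom_id].quartet_id, rep.rank, genes))
    items.sort(key=lambda t: (t[0], t[1], t[2][0]))
    for region_id, (qid, _rank, genes) in enumerate(items, start=1):
        copies: dict[int, str | None] = {1: None, 2: None, 3: None, 4: None}
        for g in genes:
            copy = chrom_info[layout.gene(g).chrom_id].copy_index
            if copies[copy] is None:
                copies[copy] = g
            else:  # ambiguity: resolve by higher block score, then gene id
                incumbent = copies[copy]
                if (gene_block_score.get(g, 0.0), incumbent) > \
                        (gene_block_score.get(incumbent, 0.0), g):
                    copies[copy] = g
        q = HomoeologQuartet(region_id=region_id, quartet_id=qid, copies=copies)
        if q.n_present >= 2:
            quartets.append(q)
    return quartets


def gene_content_profile(quartets: list[HomoeologQuartet],
                         window: int = 100) -> pd.DataFrame:
    """Retained-gene counts per copy along windows of collinear regions.

    Returns one row per (quartet_id, window) with the number of regions in
    which each copy retains a gene, plus per-copy totals computable by
    summation.
    """
    rows = []
    by_quartet: dict[int, list[HomoeologQuartet]] = {}
    for q in quartets:
        by_quartet.setdefault(q.quartet_id, []).append(q)
    for qid, qs in sorted(by_quartet.items()):
        qs.sort(key=lambda q: q.region_id)
        for w0 in range(0, len(qs), window):
            chunk = qs[w0:w0 + window]
            counts = {c: sum(1 for q in chunk if q.copies.get(c) is not None)
                      for c in (1, 2, 3, 4)}
            rows.append({"quartet_id": qid, "window_start": w0 + 1,
                         "n_regions": len(chunk),
                         **{f"copy{c}": counts[c] for c in (1, 2, 3, 4)}})
    return pd.DataFrame(rows)


def expressed_fraction(gene_ids, fpkm: pd.DataFrame, threshold: float = 0.0,
                       library_subset=None) -> float:
    """Fraction of the given genes expressed (FPKM strictly above
    ``threshold``) in at least one library of the subset.

    With the default threshold 0 this is the 'detected at all' rule.
    """
    gene_ids = list(gene_ids)
    if not gene_ids:
        raise ValidationError("empty gene subset")
    missing = set(gene_ids) - set(fpkm.index)
    if missing:
        raise ValidationError(f"genes absent from FPKM matrix: {sorted(missing)[:5]}")
    cols = list(fpkm.columns) if library_subset is None else list(library_subset)
    if not cols:
        raise ValidationError("empty library subset")
    sub = fpkm.loc[gene_ids, cols]
    return float((sub > threshold).any(axis=1).mean())
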