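"""Second assembly layer: string-overlap meta-assembly of pooled contigs.

The first layer produces one assembly per k; a given genomic locus is
typically covered by near-identical contigs from several k values, broken
at different points. The second layer pools them, removes exact duplicates
and contained sequences, greedily merges unambiguously overlapping pairs,
builds an exact suffix-prefix overlap graph, removes transitive edges, and
spells the maximal unbranched paths into the final contigs. Overlaps are
exact (assembly consensus has already averaged out sequencing errors) and
contigs below a final length cutoff (default 1,000 bp) are discarded.

Orientation convention: an oriented contig is (id, orient) with orient 0 for
the stored sequence and 1 for its reverse complement. An edge
(a, ao) -> (b, bo) of length ov means the last ov bases of a (as oriented)
equal the first ov bases of b (as oriented); its mirror image
(b, 1-bo) -> (a, 1-ao) is always present too.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .layer1 import Contig
from .seq import revcomp

DEFAULT_MIN_OVERLAP = 45
DEFAULT_MIN_FINAL_LENGTH = 1000
_CONTAIN_SEED = 31

Oriented = tuple[str, int]


def _oriented(seq: str, orient: int) -> str:
    return seq if orient == 0 else revcomp(seq)


# ---------------------------------------------------------------------------
# Pooling and duplicate removal
# ---------------------------------------------------------------------------

def pool_contigs(assemblies: Sequence[tuple[int, Sequence[Contig]]]) -> list[Contig]:
    """Concatenate per-k assemblies into one pool with unique ids."""
    pooled: list[Contig] = []
    seen: set[str] = set()
    for _k, contigs in assemblies:
        for contig in contigs:
            if contig.id in seen:
                raise ValueError(f"duplicate contig id in pool: {contig.id}")
            seen.add(contig.id)
            pooled.append(contig)
    return pooled


def remove_duplicates(contigs: Sequence[Contig]) -> list[Contig]:
    """Drop exact duplicates and contigs contained in a longer contig
    (either strand). Among exact duplicates the lexicographically smallest
    id survives."""
    order = sorted(contigs, key=lambda c: (-len(c.sequence), c.id))
    kept: list[Contig] = []
    index: dict[str, list[tuple[int, int]]] = {}  # seed -> [(kept idx, pos)]

    def contained(seq: str) -> bool:
        if len(seq) < _CONTAIN_SEED:
            return any(seq in k.sequence or revcomp(seq) in k.sequence for k in kept)
        for query in (seq, revcomp(seq)):
            for ki, pos in index.get(query[:_CONTAIN_SEED], ()):
                target = kept[ki].sequence
                if target[pos:pos + len(query)] == query:
                    return True
        return False

    for contig in order:
        if contained(contig.sequence):
            continue
        ki = len(kept)
        kept.append(contig)
        seq = contig.sequence
        for pos in range(len(seq) - _CONTAIN_SEED + 1):
            index.setdefault(seq[pos:pos + _CONTAIN_SEED], []).append((ki, pos))
    kept.sort(key=lambda c: c.id)
    return kept


# ---------------------------------------------------------------------------
# Exact suffix-prefix overlap detection
# ---------------------------------------------------------------------------

class _OverlapIndex:
    """All-pairs exact suffix-prefix overlaps >= min_overlap via a prefix
    seed index; output is identical to the quadratic all-pairs scan."""

    def __init__(self, seqs: dict[str, str], min_overlap: int):
        self.min_overlap = min_overlap
        self.seqs = dict(seqs)
        self.alive: set[str] = set(seqs)
        self.prefix: dict[str, list[Oriented]] = {}
        for cid in sorted(seqs):
            self._index(cid)

    def _index(self, cid: str) -> None:
        for orient in (0, 1):
            os = _oriented(self.seqs[cid], orient)
            if len(os) >= self.min_overlap:
                self.prefix.setdefault(os[:self.min_overlap], []).append((cid, orient))

    def add(self, cid: str, seq: str) -> None:
        self.seqs[cid] = seq
        self.alive.add(cid)
        self._index(cid)

    def remove(self, cid: str) -> None:
        self.alive.discard(cid)

    def oriented_seq(self, node: Oriented) -> str:
        return _oriented(self.seqs[node[0]], node[1])

    def edges_from(self, cid: str) -> dict[tuple[Oriented, Oriented], int]:
        """Longest proper overlap from each orientation of ``cid`` to every
        other live oriented contig."""
        mo = self.min_overlap
        edges: dict[tuple[Oriented, Oriented], int] = {}
        for orient in (0, 1):
            src: Oriented = (cid, orient)
            os = _oriented(self.seqs[cid], orient)
            n = len(os)
            for p in range(1, n - mo + 1):  # p ascending == overlap descending
                ov = n - p
                for tgt in self.prefix.get(os[p:p + mo], ()):
                    bid, _bo = tgt
                    if bid == cid or bid not in self.alive:
                        continue
                    if ov >= len(self.seqs[bid]):
                        continue  # containment, handled upstream
                    if (src, tgt) in edges:
                        continue
                    if os[p:] == self.oriented_seq(tgt)[:ov]:
                        edges[(src, tgt)] = ov
        return edges

    def all_edges(self) -> dict[tuple[Oriented, Oriented], int]:
        edges: dict[tuple[Oriented, Oriented], int] = {}
        for cid in sorted(self.alive):
            edges.update(self.edges_from(cid))
        return edges


def find_overlaps(
    contigs: Sequence[Contig], min_overlap: int
) -> dict[tuple[Oriented, Oriented], int]:
    """All exact suffix-prefix overlaps >= min_overlap between oriented
    contigs (longest per oriented pair, mirror edges included)."""
    return _OverlapIndex(
        {c.id: c.sequence for c in contigs}, min_overlap
    ).all_edges()


# ---------------------------------------------------------------------------
# Unambiguous greedy merging (FM-merge style)
# ---------------------------------------------------------------------------

def fm_merge(
    contigs: Sequence[Contig], min_overlap: int = DEFAULT_MIN_OVERLAP
) -> list[Contig]:
    """Iteratively merge pairs whose overlap is unambiguous on both sides.

    A is merged with B when B is A's only overlap partner at A's 3' end and
    A is B's only partner at B's 5' end. Runs to a fixpoint; because every
    merge is forced, the resulting sequence multiset is independent of the
    processing order.
    """
    ids = [c.id for c in contigs]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate contig ids")
    meta = {c.id: c for c in contigs}
    parents: dict[str, tuple[str, ...]] = {c.id: (c.id,) for c in contigs}
    index = _OverlapIndex({c.id: c.sequence for c in contigs}, min_overlap)
    edges = index.all_edges()
    serial = 0
    while True:
        out: dict[Oriented, list[tuple[Oriented, int]]] = {}
        for (src, tgt), ov in edges.items():
            if src[0] in index.alive and tgt[0] in index.alive:
                out.setdefault(src, []).append((tgt, ov))
        merge: tuple[Oriented, Oriented, int] | None = None
        for src in sorted(out):
            if len(out[src]) != 1:
                continue
            (tgt, ov) = out[src][0]
            back = out.get((tgt[0], 1 - tgt[1]), [])
            if len(back) == 1 and back[0][0] == (src[0], 1 - src[1]):
                merge = (src, tgt, ov)
                break
        if merge is None:
            break
        src, tgt, ov = merge
        new_seq = index.oriented_seq(src) + index.oriented_seq(tgt)[ov:]
        new_id = f"M{serial}|{min(src[0], tgt[0])}"
        serial += 1
        parents[new_id] = parents[src[0]] + parents[tgt[0]]
        index.remove(src[0])
        index.remove(tgt[0])
        edges = {
            key: ov2
            for key, ov2 in edges.items()
            if key[0][0] in index.alive and key[1][0] in index.alive
        }
        index.add(new_id, new_seq)
        new_edges = index.edges_from(new_id)
        edges.update(new_edges)
        # mirror edges (x -> new) so other nodes see the new contig too
        for (src2, tgt2), ov2 in new_edges.items():
            edges[((tgt2[0], 1 - tgt2[1]), (src2[0], 1 - src2[1]))] = ov2
    result = []
    for cid in sorted(index.alive):
        seq = index.seqs[cid]
        rc = revcomp(seq)
        if cid in meta and len(parents[cid]) == 1:
            result.append(meta[cid])
        else:
            result.append(
                Contig(
                    id=cid,
                    sequence=min(seq, rc),
                    provenance=(2, "merge", "+".join(sorted(parents[cid]))),
                )
            )
    result.sort(key=lambda c: c.id)
    return result


# ---------------------------------------------------------------------------
# Overlap graph, transitive reduction and path spelling
# ---------------------------------------------------------------------------

@dataclass
class OverlapEdge:
    a: Oriented
    b: Oriented
    length: int
    reducible: bool = False


@dataclass
class OverlapGraph:
    contigs: dict[str, Contig]
    edges: list[OverlapEdge] = field(default_factory=list)
    min_overlap: int = DEFAULT_MIN_OVERLAP

    def irreducible_out(self) -> dict[Oriented, list[tuple[Oriented, int]]]:
        out: dict[Oriented, list[tuple[Oriented, int]]] = {}
        for edge in self.edges:
            if not edge.reducible:
                out.setdefault(edge.a, []).append((edge.b, edge.length))
        for nbrs in out.values():
            nbrs.sort(key=lambda item: (-item[1], item[0]))
        return out


def build_overlap_graph(
    contigs: Sequence[Contig], min_overlap: int = DEFAULT_MIN_OVERLAP
) -> OverlapGraph:
    """Overlap graph over oriented contigs with transitive edges marked.

    An edge a->c is reducible when some b gives a->b->c with consistent
    overlap lengths (ov_bc == len(b) - ov_ab + ov_ac), i.e. the direct
    overlap is implied by the two shorter consecutive ones.
    """
    raw = find_overlaps(contigs, min_overlap)
    lengths = {c.id: len(c.sequence) for c in contigs}
    out: dict[Oriented, dict[Oriented, int]] = {}
    for (a, b), ov in raw.items():
        out.setdefault(a, {})[b] = ov
    reducible: set[tuple[Oriented, Oriented]] = set()
    for a, nbrs in out.items():
        for c, ov_ac in nbrs.items():
            for b, ov_ab in nbrs.items():
                if b == c or ov_ab <= ov_ac:
                    continue
                implied = lengths[b[0]] - ov_ab + ov_ac
                if out.get(b, {}).get(c) == implied:
                    reducible.add((a, c))
                    reducible.add(((c[0], 1 - c[1]), (a[0], 1 - a[1])))
                    break
    edges = [
        OverlapEdge(a, b, ov, (a, b) in reducible)
        for (a, b), ov in sorted(raw.items())
    ]
    return OverlapGraph(
        contigs={c.id: c for c in contigs}, edges=edges, min_overlap=min_overlap
    )


def assemble_paths(
    graph: OverlapGraph, min_final_length: int = DEFAULT_MIN_FINAL_LENGTH
) -> list[Contig]:
    """Spell maximal unbranched paths over irreducible edges.

    Interior steps require a unique outgoing edge whose target has a unique
    incoming edge; branch nodes terminate paths. Every contig lands in
    exactly one path. Contigs shorter than ``min_final_length`` are dropped
    from the output; orientation and ordering are canonical.
    """
    out = graph.irreducible_out()
    seqs = {cid: c.sequence for cid, c in graph.contigs.items()}

    def unique_next(node: Oriented) -> tuple[Oriented, int] | None:
        nbrs = out.get(node, [])
        if len(nbrs) != 1:
            return None
        tgt, ov = nbrs[0]
        back = out.get((tgt[0], 1 - tgt[1]), [])
        if len(back) == 1 and back[0][0] == (node[0], 1 - node[1]):
            return tgt, ov
        return None

    visited: set[str] = set()
    spelled: list[str] = []
    for cid in sorted(seqs):
        if cid in visited:
            continue
        path_ids = {cid}
        # walk left: follow unique predecessors via the flipped orientation
        cur: Oriented = (cid, 1)
        while True:
            step = unique_next(cur)
            if step is None or step[0][0] in visited or step[0][0] in path_ids:
                break
            cur = step[0]
            path_ids.add(cur[0])
        first: Oriented = (cur[0], 1 - cur[1])
        seq = _oriented(seqs[first[0]], first[1])
        node = first
        walked = {first[0]}
        while True:
            step = unique_next(node)
            if step is None or step[0][0] in visited or step[0][0] in walked:
                break
            node, ov = step
            walked.add(node[0])
            seq += _oriented(seqs[node[0]], node[1])[ov:]
        visited |= walked
        spelled.append(min(seq, revcomp(seq)))
    spelled = sorted(s for s in spelled if len(s) >= min_final_length)
    return [
        Contig(id=f"L2|{i}|len={len(s)}", sequence=s, provenance=(2, "merge", "layer2"))
        for i, s in enumerate(spelled)
    ]


def second_layer(
    assemblies: Sequence[tuple[int, Sequence[Contig]]],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_final_length: int = DEFAULT_MIN_FINAL_LENGTH,
) -> list[Contig]:
    """Full second layer: pool, deduplicate, merge, graph, spell, filter."""
    pooled = pool_contigs(assemblies)
    unique = remove_duplicates(pooled)
    merged = fm_merge(unique, min_overlap)
    graph = build_overlap_graph(merged, min_overlap)
    return assemble_paths(graph, min_final_length)
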