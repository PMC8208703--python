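"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the library's own interval algebra and graph
helpers: Jaccard is computed on explicit base-pair sets, clustering by
transitive closure over pairwise checks with a hand-rolled union-find, and
path enumeration by a naive recursive DFS.
"""

from __future__ import annotations


def bitset_jaccard(a, b) -> float:
    """Jaccard index over explicit bp membership sets (strand-aware)."""
    if a.strand != b.strand:
        return 0.0
    sa = set(range(a.start, a.end + 1))
    sb = set(range(b.start, b.end + 1))
    union = sa | sb
    return len(sa & sb) / len(union) if union else 0.0


class UnionFind:
    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a, b):
        self.parent[self.find(a)] = self.find(b)

    def components(self):
        comps = {}
        for i in self.parent:
            comps.setdefault(self.find(i), set()).add(i)
        return sorted(comps.values(), key=lambda s: sorted(s))


def naive_scan(sequence: str, query: str) -> list:
    """All exact occurrences of query on both strands by position-by-position
    comparison; returns (start0, strand) pairs."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[c] for c in reversed(query))
    hits = []
    for i in range(len(sequence) - len(query) + 1):
        window = sequence[i : i + len(query)]
        if window == query:
            hits.append((i, "+"))
        if window == rc and rc != query:
            hits.append((i, "-"))
    return hits


def brute_rfam_filter(hits, e_cut, require_ga):
    """Exhaustive clustering (transitive closure on pairwise >=40 bp
    same-strand overlap) plus per-cluster argmin selection."""
    kept = [
        h
        for h in hits
        if h.e_value < e_cut and (not require_ga or h.bit_score >= h.gathering_score)
    ]
    uf = UnionFind(range(len(kept)))
    for i in range(len(kept)):
        for j in range(i + 1, len(kept)):
            a, b = kept[i].interval, kept[j].interval
            if a.strand != b.strand:
                continue
            ov = min(a.end, b.end) - max(a.start, b.start) + 1
            if ov >= 40:
                uf.union(i, j)
    out = []
    for comp in uf.components():
        members = [kept[i] for i in comp]
        out.append(
            min(
                members,
                key=lambda h: (h.e_value, -h.bit_score, h.interval.start, h.family_id),
            )
        )
    return sorted(out, key=lambda h: (h.interval.start, h.interval.end, h.family_id))


def closure_site_groups(sites):
    """Site grouping by exhaustive pairwise window-overlap closure."""
    uf = UnionFind(range(len(sites)))
    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            a, b = sites[i], sites[j]
            if a.strand != b.strand or a.site_type != b.site_type:
                continue
            alo, ahi = a.window
            blo, bhi = b.window
            if max(alo, blo) <= min(ahi, bhi):
                uf.union(i, j)
    return [
        sorted(sites[i].id for i in comp) for comp in uf.components()
    ]


def dfs_paths(edges, sources, sinks):
    """All simple source-to-sink paths via a naive recursive DFS."""
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
    sinks = set(sinks)
    paths = []

    def walk(node, path):
        if node in sinks:
            paths.append(tuple(path))
            return
        for nxt in adj.get(node, []):
            if nxt not in path:
                walk(nxt, path + [nxt])

    for s in sources:
        walk(s, [s])
    return sorted(paths)


def brute_name_match(queries, genes):
    """Exhaustive cross-product resolution of name-set queries."""
    out = []
    for names in queries:
        lowered = {n.lower() for n in names}
        hits = [
            g
            for g in genes
            if lowered & {n.lower() for n in (g.names | g.locus_tags)}
        ]
        ids = {g.id for g in hits}
        if not ids:
            out.append("unmatched")
        elif len(ids) > 1:
            out.append("ambiguous")
        else:
            out.append(hits[0].id)
    return out


def brute_associate(sites, genes, cutoff, orphan_cutoff, tol):
    """Exhaustive nearest-neighbour site-to-gene association."""
    out = {}
    for s in sites:
        limit = orphan_cutoff if s.orphan else cutoff
        best = None
        for g in genes:
            if g.interval.strand != s.strand:
                continue
            if g.interval.strand == "+":
                anchor = g.interval.start if s.site_type == "TSS" else g.interval.end
                gap = anchor - s.position if s.site_type == "TSS" else s.position - anchor
            else:
                anchor = g.interval.end if s.site_type == "TSS" else g.interval.start
                gap = s.position - anchor if s.site_type == "TSS" else anchor - s.position
            if gap < -tol or gap > limit:
                continue
            key = (abs(gap), g.interval.start, g.id)
            if best is None or key < best[0]:
                best = (key, g.id, gap)
        out[s.id] = None if best is None else (best[1], best[2])
    return out
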