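"""Taxonomy container and Wu-Palmer similarity.

The taxonomy is a rooted tree given as a child -> parent map.  Depths are
node counts along the path from the root, root depth 1, so that
``wup(a, a) = 1`` under the Wu-Palmer formula

    sim(a, b) = 2 * depth(LCS) / (depth(a) + depth(b))

where the LCS (least common subsumer) is the deepest node having both
``a`` and ``b`` as descendants, a node counting as its own descendant.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from ._text import tokenize


class Taxonomy:
    """Rooted tree over string node ids with per-node labels."""

    def __init__(self, parent: Mapping[str, str | None], labels: Mapping[str, str]):
        self.parent: dict[str, str | None] = dict(parent)
        self.labels: dict[str, str] = dict(labels)
        roots = [n for n, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        for n, p in self.parent.items():
            if p is not None and p not in self.parent:
                raise ValueError(f"node {n!r} has unknown parent {p!r}")
        g = nx.DiGraph((p, c) for c, p in self.parent.items() if p is not None)
        g.add_node(self.root)
        if g.number_of_edges() and not nx.is_arborescence(g):
            raise ValueError("taxonomy edges do not form a rooted tree")
        self._depth: dict[str, int] = {}
        for n in nx.topological_sort(g):
            p = self.parent[n]
            self._depth[n] = 1 if p is None else self._depth[p] + 1
        if len(self._depth) != len(self.parent):
            raise ValueError("some nodes are unreachable from the root")

    def __contains__(self, node: str) -> bool:
        return node in self.parent

    def __len__(self) -> int:
        return len(self.parent)

    @property
    def nodes(self) -> list[str]:
        return list(self.parent)

    def depth(self, node: str) -> int:
        """Node-count depth from the root (root has depth 1)."""
        return self._depth[node]

    def ancestors(self, node: str) -> list[str]:
        """Path from ``node`` up to the root, inclusive of both ends."""
        if node not in self.parent:
            raise KeyError(f"node {node!r} not in taxonomy")
        chain = [node]
        while (p := self.parent[chain[-1]]) is not None:
            chain.append(p)
        return chain

    def lcs(self, a: str, b: str) -> str:
        """Deepest node having both ``a`` and ``b`` as descendants."""
        up_a = set(self.ancestors(a))
        for n in self.ancestors(b):  # walks b upward: first hit is deepest
            if n in up_a:
                return n
        raise ValueError("no common ancestor (disconnected taxonomy)")

    def leaves(self) -> list[str]:
        parents = {p for p in self.parent.values() if p is not None}
        return [n for n in self.parent if n not in parents]

    def edges(self) -> list[tuple[str, str | None, str]]:
        return [(n, self.parent[n], self.labels.get(n, "")) for n in self.parent]


def load_taxonomy(path: str | Path) -> Taxonomy:
    """Read a TSV edge list ``child_id<TAB>parent_id<TAB>label``; the single
    root row has an empty parent field."""
    parent: dict[str, str | None] = {}
    labels: dict[str, str] = {}
    with Path(path).open(encoding="utf-8", newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or not row[0].strip():
                continue
            child = row[0].strip()
            par = row[1].strip() if len(row) > 1 and row[1].strip() else None
            parent[child] = par
            labels[child] = row[2].strip() if len(row) > 2 else ""
    return Taxonomy(parent, labels)


def write_taxonomy(tax: Taxonomy, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for child, par, label in tax.edges():
            writer.writerow([child, par or "", label])


def wup_similarity(tax: Taxonomy, a: str, b: str) -> float:
    """Wu-Palmer similarity of two taxonomy nodes, in (0, 1]."""
    if a not in tax:
        raise KeyError(f"node {a!r} not in taxonomy")
    if b not in tax:
        raise KeyError(f"node {b!r} not in taxonomy")
    lcs = tax.lcs(a, b)
    return 2.0 * tax.depth(lcs) / (tax.depth(a) + tax.depth(b))


WordMap = Mapping[str, Sequence[str]]


def word_map_from_labels(tax: Taxonomy) -> dict[str, list[str]]:
    """Token -> node-ids map built from the taxonomy's own labels.

    A label shared by several nodes maps the token to all of them (handled
    downstream by the max-sense rule).  The root label is excluded: it
    subsumes everything and carries no discriminative signal.
    """
    wm: dict[str, list[str]] = {}
    for node, label in tax.labels.items():
        if node == tax.root:
            continue
        for token in tokenize(label):
            wm.setdefault(token, []).append(node)
    for nodes in wm.values():
        nodes.sort()
    return wm


def _token_wup(tax: Taxonomy, word_map: WordMap, ta: str, tb: str) -> float:
    # max-sense: a token ambiguous between several nodes takes the most
    # favourable sense pair
    return max(
        wup_similarity(tax, na, nb) for na in word_map[ta] for nb in word_map[tb]
    )


def wup_phrase_similarity(
    tax: Taxonomy, word_map: WordMap, a: str, b: str
) -> tuple[float, bool]:
    """Bidirectional greedy aggregation of token-level Wu-Palmer scores.

    Each resolvable token in one phrase takes its best match among the
    other phrase's resolvable tokens; the two directional averages are then
    averaged.  Returns ``(score, unresolved_flag)``; the flag is set (and
    the score is 0) when either side has no resolvable token.
    """
    ta = sorted({t for t in tokenize(a) if t in word_map and word_map[t]})
    tb = sorted({t for t in tokenize(b) if t in word_map and word_map[t]})
    if not ta or not tb:
        return 0.0, True
    fwd = sum(max(_token_wup(tax, word_map, x, y) for y in tb) for x in ta) / len(ta)
    bwd = sum(max(_token_wup(tax, word_map, y, x) for x in ta) for y in tb) / len(tb)
    return (fwd + bwd) / 2.0, False
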