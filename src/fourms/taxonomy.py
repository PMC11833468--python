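"""Four-level per-class taxonomy induction from expression embeddings.

Pipeline: embed expressions with a pluggable sentence embedder, remove
near-duplicates by cosine similarity (threshold 0.95), cluster each 4M class
with agglomerative Ward linkage on Euclidean distance, cut the dendrogram at
four strictly decreasing distance thresholds to obtain nested hierarchy
levels, and label every cluster through a pluggable labeler with a
duplicate-resolving loop (labels whose embeddings are cosine-identical at
0.9999 force a re-label).

Threshold selection is programmatic: :func:`suggest_thresholds` scans the
dendrogram for the cut that best matches a target cluster count per level,
replacing manual visual review of dendrograms.
"""

from __future__ import annotations

import json
import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Protocol, Sequence

import numpy as np
from scipy.cluster import hierarchy as sch

from .extraction import M_CLASSES, MClass

logger = logging.getLogger(__name__)

DEDUP_THRESHOLD = 0.95
LABEL_DUP_THRESHOLD = 0.9999
#: members shown to the labeler, most central first
LABEL_MEMBER_CAP = 50


class Embedder(Protocol):
    """Plug-in contract: deterministic text -> fixed-dimension vector."""

    def __call__(self, text: str) -> np.ndarray: ...


Labeler = Callable[..., str]  # (member_texts, avoid=[...]) -> short label


@dataclass
class Expression:
    """A deduplicated (text, class, vector, provenance) unit — the atom of
    taxonomy building. Provenance lists the source message ids."""

    text: str
    m_class: MClass
    vector: np.ndarray | None = None
    provenance: list[str] = field(default_factory=list)


@dataclass
class LinkageTree:
    """Agglomerative merge sequence in the standard linkage-matrix layout:
    node ids 0..n-1 are leaves, merge i creates node n+i."""

    n_leaves: int
    merges: list[tuple[int, int, float, int]]

    def __post_init__(self) -> None:
        if self.n_leaves >= 1 and len(self.merges) != self.n_leaves - 1:
            raise ValueError("a linkage over n leaves must contain n-1 merges")

    @property
    def max_height(self) -> float:
        return self.merges[-1][2] if self.merges else 0.0

    def to_matrix(self) -> np.ndarray:
        """4-column linkage matrix for interoperability with dendrogram tooling."""
        return np.array(self.merges, dtype=float).reshape(len(self.merges), 4)

    @classmethod
    def from_matrix(cls, Z: np.ndarray) -> "LinkageTree":
        n = Z.shape[0] + 1
        merges = [(int(a), int(b), float(h), int(s)) for a, b, h, s in Z]
        return cls(n, merges)


def embed_expressions(
    expressions: Sequence[Expression], embedder: Embedder
) -> list[Expression]:
    """Attach a vector to every expression; the dimension must be constant."""
    out: list[Expression] = []
    dim: int | None = None
    for e in expressions:
        v = np.asarray(embedder(e.text), dtype=float)
        if dim is None:
            dim = v.size
        elif v.size != dim:
            raise ValueError(
                f"embedder dimension changed: {dim} -> {v.size} for {e.text!r}"
            )
        out.append(Expression(e.text, e.m_class, v, list(e.provenance)))
    return out


def semantic_dedup(
    expressions: Sequence[Expression], threshold: float = DEDUP_THRESHOLD
) -> tuple[list[Expression], dict[int, int]]:
    """Greedy first-kept cosine deduplication in input order.

    An expression whose cosine similarity to any already-kept expression is at
    or above ``threshold`` is folded into the earliest such kept expression
    (its provenance is unioned); otherwise it is kept. The merge map sends
    each input index to the input index of its surviving representative.
    Idempotent: no two kept expressions are within ``threshold`` of each other.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    kept: list[Expression] = []
    kept_input_idx: list[int] = []
    unit_rows: list[np.ndarray] = []
    merge_map: dict[int, int] = {}
    for i, e in enumerate(expressions):
        if e.vector is None:
            raise ValueError(f"expression {e.text!r} has no vector")
        norm = float(np.linalg.norm(e.vector))
        if norm == 0.0:
            raise ValueError(f"zero-norm embedding for expression {e.text!r}")
        u = np.asarray(e.vector, dtype=float) / norm
        if unit_rows:
            sims = np.vstack(unit_rows) @ u
            hits = np.nonzero(sims >= threshold - 1e-12)[0]
        else:
            hits = np.array([], dtype=int)
        if hits.size:
            j = int(hits[0])  # earliest kept wins
            kept[j].provenance.extend(p for p in e.provenance if p not in kept[j].provenance)
            merge_map[i] = kept_input_idx[j]
        else:
            kept.append(Expression(e.text, e.m_class, np.asarray(e.vector, dtype=float),
                                   list(e.provenance)))
            kept_input_idx.append(i)
            unit_rows.append(u)
            merge_map[i] = i
    return kept, merge_map


def ward_linkage(vectors: Sequence[np.ndarray] | np.ndarray) -> LinkageTree:
    """Agglomerative Ward linkage on Euclidean distance.

    Each merge joins the pair of clusters whose union minimally increases the
    total within-cluster variance; heights are on the Euclidean-commensurate
    scale (the square root of twice the variance increase), so they are
    directly comparable to pairwise distances. Heights are non-decreasing
    (Ward is monotone).
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    if X.shape[0] < 1:
        raise ValueError("at least one vector required")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in embedding matrix")
    if X.shape[0] == 1:
        return LinkageTree(1, [])
    Z = sch.linkage(X, method="ward")
    return LinkageTree.from_matrix(Z)


def cut_tree(tree: LinkageTree, threshold: float) -> np.ndarray:
    """Partition the leaves by applying every merge with height strictly below
    ``threshold``; cluster ids are ordered by smallest member leaf index.

    Threshold 0 yields all singletons; any threshold above the maximum merge
    height yields one cluster.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    n = tree.n_leaves
    parent = list(range(n + len(tree.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    # monotone heights: if a merge is applied, every merge below it was too,
    # so its children are already connected components rooted at real nodes
    for k, (a, b, h, _size) in enumerate(tree.merges):
        if h < threshold:
            node = n + k
            parent[find(a)] = node
            parent[find(b)] = node
    roots = [find(i) for i in range(n)]
    first_leaf: dict[int, int] = {}
    for leaf, r in enumerate(roots):
        first_leaf.setdefault(r, leaf)
    order = {r: rank for rank, r in enumerate(sorted(first_leaf, key=first_leaf.get))}
    return np.array([order[r] for r in roots], dtype=int)


def n_clusters_at(tree: LinkageTree, threshold: float) -> int:
    """Cluster count produced by :func:`cut_tree` at ``threshold``; with
    monotone heights this is ``n_leaves`` minus the merges below it."""
    return tree.n_leaves - sum(1 for m in tree.merges if m[2] < threshold)


@dataclass
class LevelThresholds:
    """Per-class quadruples of strictly decreasing distance thresholds, one
    per hierarchy level (coarse level 1 to fine level 4)."""

    per_class: dict[MClass, tuple[float, float, float, float]]

    def __post_init__(self) -> None:
        for c, ts in self.per_class.items():
            if len(ts) != 4 or not all(a > b for a, b in zip(ts, ts[1:])) or ts[-1] <= 0:
                raise ValueError(
                    f"{c.value}: thresholds must be four strictly decreasing positive values, got {ts}"
                )


def suggest_thresholds(
    tree: LinkageTree, target_counts: Sequence[int]
) -> tuple[float, ...]:
    """Pick one threshold per level whose cut yields the cluster count closest
    to each target (ties resolved toward the larger threshold).

    ``target_counts`` must be increasing (coarse to fine); a target above the
    leaf count is unsatisfiable and fatal. This is the programmatic
    replacement for choosing thresholds by visual dendrogram review.
    """
    targets = list(target_counts)
    if any(a >= b for a, b in zip(targets, targets[1:])):
        raise ValueError("target counts must be strictly increasing")
    if targets[-1] > tree.n_leaves:
        raise ValueError(f"target {targets[-1]} exceeds leaf count {tree.n_leaves}")
    heights = [m[2] for m in tree.merges]
    # candidate thresholds: one per achievable count, placed mid-interval
    candidates = [0.0]
    for lo, hi in zip(heights, heights[1:]):
        if hi > lo:
            candidates.append((lo + hi) / 2.0)
    if heights:
        candidates.append(heights[-1] * 1.01 + 1.0)
    chosen: list[float] = []
    prev: float | None = None
    for target in targets:
        feasible = [t for t in candidates if prev is None or t < prev]
        if not feasible:
            raise ValueError("thresholds cannot strictly decrease for these targets")
        best = min(
            feasible,
            key=lambda t: (abs(n_clusters_at(tree, t) - target), -t),
        )
        chosen.append(best)
        prev = best
    return tuple(chosen)


@dataclass
class TaxonomyNode:
    """Labeled cluster at one hierarchy level under a class root (level 0)."""

    node_id: str
    label: str
    level: int
    m_class: MClass
    children: list[str] = field(default_factory=list)
    members: list[int] = field(default_factory=list)  # indices into Taxonomy.expressions[m_class]
    flags: list[str] = field(default_factory=list)


@dataclass
class Taxonomy:
    """Per-class four-level hierarchy with a level-0 class root per class."""

    nodes: dict[str, TaxonomyNode]
    roots: dict[MClass, str]
    expressions: dict[MClass, list[Expression]]

    def children_of(self, node_id: str) -> list[TaxonomyNode]:
        return [self.nodes[c] for c in self.nodes[node_id].children]

    def parent_of(self, node_id: str) -> str | None:
        for nid, node in self.nodes.items():
            if node_id in node.children:
                return nid
        return None

    def nodes_at_level(self, m_class: MClass, level: int) -> list[TaxonomyNode]:
        return [
            n for n in self.nodes.values() if n.m_class == m_class and n.level == level
        ]

    def level_counts(self, m_class: MClass) -> dict[int, int]:
        return {lvl: len(self.nodes_at_level(m_class, lvl)) for lvl in range(5)}

    def ancestors(self, node_id: str) -> list[str]:
        chain = []
        cur = self.parent_of(node_id)
        while cur is not None:
            chain.append(cur)
            cur = self.parent_of(cur)
        return chain

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "roots": {c.value: self.roots[c] for c in self.roots},
            "nodes": {
                nid: {
                    "label": n.label,
                    "level": n.level,
                    "class": n.m_class.value,
                    "children": n.children,
                    "members": n.members,
                    "flags": n.flags,
                }
                for nid, n in sorted(self.nodes.items())
            },
            "expressions": {
                c.value: [
                    {"text": e.text, "provenance": e.provenance}
                    for e in self.expressions.get(c, [])
                ]
                for c in M_CLASSES
            },
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "Taxonomy":
        nodes = {
            nid: TaxonomyNode(
                node_id=nid,
                label=rec["label"],
                level=int(rec["level"]),
                m_class=MClass(rec["class"]),
                children=list(rec["children"]),
                members=list(rec["members"]),
                flags=list(rec.get("flags", [])),
            )
            for nid, rec in payload["nodes"].items()
        }
        expressions = {
            MClass(cv): [
                Expression(rec["text"], MClass(cv), None, list(rec["provenance"]))
                for rec in recs
            ]
            for cv, recs in payload["expressions"].items()
        }
        roots = {MClass(cv): nid for cv, nid in payload["roots"].items()}
        return cls(nodes, roots, expressions)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "Taxonomy":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def summary_table(self) -> "pd.DataFrame":
        """Flat per-class table: level-1 cluster label, unique-expression
        count, and cluster counts at levels 2-4."""
        import pandas as pd

        rows = []
        for c in M_CLASSES:
            counts = self.level_counts(c)
            for node in sorted(self.nodes_at_level(c, 1), key=lambda n: -len(n.members)):
                rows.append(
                    {
                        "class": c.value,
                        "level1_label": node.label,
                        "unique_expressions": len(node.members),
                        "n_clusters_level2": counts[2],
                        "n_clusters_level3": counts[3],
                        "n_clusters_level4": counts[4],
                    }
                )
        return pd.DataFrame(rows)


ROOT_LABELS = {
    MClass.WHAT_MATTERS: "What Matters",
    MClass.MEDICATION: "Medication",
    MClass.MENTATION: "Mentation",
    MClass.MOBILITY: "Mobility",
}


def build_class_hierarchy(
    expressions: Sequence[Expression],
    tree: LinkageTree,
    thresholds: Sequence[float],
    m_class: MClass,
) -> Taxonomy:
    """Cut one class's dendrogram at four decreasing thresholds and assemble
    the nested node structure under a level-0 class root.

    Because every level is a cut of the same tree, each level-(k+1) cluster
    lies inside exactly one level-k cluster (nesting is structural).
    """
    ts = list(thresholds)
    if len(ts) != 4 or not all(a > b for a, b in zip(ts, ts[1:])):
        raise ValueError(f"thresholds must be four strictly decreasing values, got {ts}")
    if len(expressions) != tree.n_leaves:
        raise ValueError("expression count does not match the linkage tree")
    root_id = f"{m_class.value}/root"
    nodes: dict[str, TaxonomyNode] = {
        root_id: TaxonomyNode(root_id, ROOT_LABELS[m_class], 0, m_class,
                              members=list(range(len(expressions))))
    }
    leaf_parent_at_prev = {i: root_id for i in range(len(expressions))}
    for level, t in enumerate(ts, start=1):
        labels = cut_tree(tree, t)
        by_cluster: dict[int, list[int]] = {}
        for leaf, cid in enumerate(labels):
            by_cluster.setdefault(int(cid), []).append(leaf)
        leaf_parent: dict[int, str] = {}
        for cid, members in sorted(by_cluster.items()):
            node_id = f"{m_class.value}/L{level}/{cid:03d}"
            parent_id = leaf_parent_at_prev[members[0]]
            nodes[node_id] = TaxonomyNode(node_id, node_id, level, m_class, members=members)
            nodes[parent_id].children.append(node_id)
            for leaf in members:
                leaf_parent[leaf] = node_id
        leaf_parent_at_prev = leaf_parent
    return Taxonomy(nodes, {m_class: root_id}, {m_class: list(expressions)})


def build_taxonomy(
    per_class_expressions: Mapping[MClass, Sequence[Expression]],
    thresholds: LevelThresholds | None = None,
    target_counts: Mapping[MClass, Sequence[int]] | None = None,
) -> tuple[Taxonomy, dict[MClass, LinkageTree]]:
    """Cluster every class and merge the per-class hierarchies into one
    taxonomy. Thresholds come either from ``thresholds`` or, when absent,
    from :func:`suggest_thresholds` with the given per-class target counts."""
    if thresholds is None and target_counts is None:
        raise ValueError("provide thresholds or target_counts")
    merged_nodes: dict[str, TaxonomyNode] = {}
    roots: dict[MClass, str] = {}
    exprs: dict[MClass, list[Expression]] = {}
    trees: dict[MClass, LinkageTree] = {}
    for c, expressions in per_class_expressions.items():
        if not expressions:
            continue
        X = np.vstack([e.vector for e in expressions])
        tree = ward_linkage(X)
        trees[c] = tree
        if thresholds is not None:
            ts = thresholds.per_class[c]
        else:
            ts = suggest_thresholds(tree, list(target_counts[c]))
        part = build_class_hierarchy(expressions, tree, ts, c)
        merged_nodes.update(part.nodes)
        roots.update(part.roots)
        exprs.update(part.expressions)
    return Taxonomy(merged_nodes, roots, exprs), trees


def _central_members(
    node: TaxonomyNode, expressions: Sequence[Expression], cap: int = LABEL_MEMBER_CAP
) -> list[str]:
    texts = [expressions[i].text for i in node.members]
    vectors = [expressions[i].vector for i in node.members]
    if len(texts) <= cap or any(v is None for v in vectors):
        return texts[:cap]
    X = np.vstack(vectors)
    d = np.linalg.norm(X - X.mean(axis=0), axis=1)
    order = np.argsort(d, kind="stable")[:cap]
    return [texts[i] for i in order]


def label_clusters(
    taxonomy: Taxonomy,
    labeler: Labeler,
    embedder: Embedder,
    dup_threshold: float = LABEL_DUP_THRESHOLD,
    max_rounds: int = 5,
) -> Taxonomy:
    """Assign labels breadth-first with a duplicate-resolving loop.

    A proposed label whose embedding is cosine-similar (≥ ``dup_threshold``,
    i.e. near-verbatim) to an already accepted label at the same class and
    level triggers a re-label with the colliding labels passed to the labeler
    as the ``avoid`` list. After ``max_rounds`` unresolved rounds a
    deterministic numeric suffix is appended and the node flagged. A labeler
    failure yields the placeholder ``Unlabeled-<node_id>`` plus a flag.
    Labels are assigned in place (the same Taxonomy object is returned).
    """

    def unit(text: str) -> np.ndarray:
        v = np.asarray(embedder(text), dtype=float)
        n = np.linalg.norm(v)
        return v / n if n > 0 else v

    for c in taxonomy.roots:
        accepted: dict[int, list[tuple[str, np.ndarray]]] = {}
        queue = deque(taxonomy.children_of(taxonomy.roots[c]))
        while queue:
            node = queue.popleft()
            queue.extend(taxonomy.children_of(node.node_id))
            texts = _central_members(node, taxonomy.expressions[c])
            level_accepted = accepted.setdefault(node.level, [])
            avoid: list[str] = []
            label: str | None = None
            for _round in range(max_rounds):
                try:
                    proposal = labeler(texts, avoid=list(avoid))
                except Exception as exc:
                    node.flags.append(f"labeler_error: {exc}")
                    proposal = f"Unlabeled-{node.node_id}"
                    label = proposal
                    break
                u = unit(proposal)
                dup = [lab for lab, lu in level_accepted if float(lu @ u) >= dup_threshold]
                if not dup:
                    label = proposal
                    break
                avoid.extend(d for d in dup if d not in avoid)
                label = proposal
            if label is None:
                label = f"Unlabeled-{node.node_id}"
            existing = {lab for lab, _ in level_accepted}
            if label in existing or any(
                float(lu @ unit(label)) >= dup_threshold for _, lu in level_accepted
            ):
                base, k = label, 2
                while f"{base}-{k}" in existing:
                    k += 1
                label = f"{base}-{k}"
                node.flags.append("label_suffix_disambiguated")
            node.label = label
            level_accepted.append((label, unit(label)))
    return taxonomy
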