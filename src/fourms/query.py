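"""Taxonomy exploration: concept queries, network export, corpus summaries.

A concept query (e.g. "pain") finds every expression that either quotes the
term directly (normalized substring) or is related to it in embedding space
(cosine similarity at or above a configurable threshold), then assembles the
matches with their full ancestor chains into a concept network — one
connected component per 4M class root, linked only through shared clusters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from ._text import normalize_text
from .corpus import LinkedCorpus, Message
from .extraction import M_CLASSES, ExtractionResult, MClass
from .taxonomy import Embedder, Taxonomy

RELATEDNESS_THRESHOLD = 0.6


@dataclass
class ConceptGraph:
    """Directed (parent -> child) concept network for one query term."""

    graph: nx.DiGraph
    query_term: str
    per_class_counts: dict[MClass, int]
    flags: list[str] = field(default_factory=list)


def query_concept(
    taxonomy: Taxonomy,
    term: str,
    embedder: Embedder | None = None,
    relatedness_threshold: float = RELATEDNESS_THRESHOLD,
) -> ConceptGraph:
    """Query the taxonomy for a concept by direct quotation and related terms.

    An expression matches when the normalized term occurs inside its
    normalized text, or when its embedding's cosine similarity to the term's
    embedding reaches ``relatedness_threshold`` (requires an embedder and
    expression vectors; lowering the threshold never removes a match). The
    returned graph holds every match with its complete ancestor chain up to
    its class root; class roots are always present, and a query with no match
    at all is flagged.
    """
    term_norm = normalize_text(term)
    if not term_norm:
        raise ValueError("query term is empty after normalization")
    term_vec: np.ndarray | None = None
    if embedder is not None:
        v = np.asarray(embedder(term), dtype=float)
        n = float(np.linalg.norm(v))
        if n == 0.0:
            raise ValueError(f"query term {term!r} embeds to the zero vector")
        term_vec = v / n
    G = nx.DiGraph(query_term=term)
    for c, root_id in taxonomy.roots.items():
        root = taxonomy.nodes[root_id]
        G.add_node(root_id, kind="class_root", label=root.label, level=0, m_class=c.value)
    per_class_counts = {c: 0 for c in M_CLASSES}
    flags: list[str] = []
    for c, root_id in taxonomy.roots.items():
        for idx, expr in enumerate(taxonomy.expressions[c]):
            matched = term_norm in normalize_text(expr.text)
            if not matched and term_vec is not None and expr.vector is not None:
                ev = np.asarray(expr.vector, dtype=float)
                en = float(np.linalg.norm(ev))
                if en > 0 and float(term_vec @ (ev / en)) >= relatedness_threshold:
                    matched = True
            if not matched:
                continue
            per_class_counts[c] += 1
            expr_id = f"expr:{c.value}:{idx}"
            G.add_node(expr_id, kind="expression", label=expr.text, level=5, m_class=c.value)
            # deepest cluster containing this expression, then its ancestors
            leaf_cluster = None
            for node in taxonomy.nodes_at_level(c, 4):
                if idx in node.members:
                    leaf_cluster = node
                    break
            chain = []
            if leaf_cluster is not None:
                chain = [leaf_cluster.node_id] + taxonomy.ancestors(leaf_cluster.node_id)
            else:
                chain = [root_id]
            prev = expr_id
            for nid in chain:
                node = taxonomy.nodes[nid]
                kind = "class_root" if node.level == 0 else "cluster"
                G.add_node(nid, kind=kind, label=node.label, level=node.level, m_class=c.value)
                G.add_edge(nid, prev)
                prev = nid
    if sum(per_class_counts.values()) == 0:
        flags.append("no_matches")
    return ConceptGraph(G, term, per_class_counts, flags)


def export_graph(cg: ConceptGraph, path: str | Path, format: str = "graphml") -> None:
    """Write a concept graph losslessly as GraphML or a node-link JSON file."""
    path = Path(path)
    if format == "graphml":
        G = cg.graph.copy()
        G.graph["query_term"] = cg.query_term
        G.graph["per_class_counts"] = json.dumps({c.value: n for c, n in cg.per_class_counts.items()})
        G.graph["flags"] = json.dumps(cg.flags)
        nx.write_graphml(G, path)
    elif format == "node_link":
        payload = {
            "query_term": cg.query_term,
            "per_class_counts": {c.value: n for c, n in cg.per_class_counts.items()},
            "flags": cg.flags,
            "graph": nx.node_link_data(cg.graph, edges="edges"),
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ValueError(f"unsupported graph format {format!r}")


def load_graph(path: str | Path, format: str = "graphml") -> ConceptGraph:
    path = Path(path)
    if format == "graphml":
        G = nx.read_graphml(path)
        # GraphML stores everything as typed attributes; levels come back as ints
        H = nx.DiGraph()
        for node, attrs in G.nodes(data=True):
            H.add_node(node, kind=attrs["kind"], label=attrs["label"],
                       level=int(attrs["level"]), m_class=attrs["m_class"])
        H.add_edges_from(G.edges())
        counts = {MClass(k): int(v) for k, v in json.loads(G.graph["per_class_counts"]).items()}
        return ConceptGraph(H, G.graph["query_term"], counts, json.loads(G.graph["flags"]))
    if format == "node_link":
        payload = json.loads(path.read_text())
        G = nx.node_link_graph(payload["graph"], directed=True, edges="edges")
        counts = {MClass(k): int(v) for k, v in payload["per_class_counts"].items()}
        return ConceptGraph(G, payload["query_term"], counts, list(payload["flags"]))
    raise ValueError(f"unsupported graph format {format!r}")


def draw_graph(cg: ConceptGraph, path: str | Path, seed: int = 0) -> None:
    """Optional static rendering with a fixed spring-layout seed."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pos = nx.spring_layout(cg.graph, seed=seed)
    fig, ax = plt.subplots(figsize=(10, 8))
    colors = {"class_root": "#d62728", "cluster": "#1f77b4", "expression": "#2ca02c"}
    node_colors = [colors[cg.graph.nodes[n]["kind"]] for n in cg.graph]
    nx.draw_networkx(cg.graph, pos=pos, ax=ax, node_color=node_colors, with_labels=False,
                     node_size=60, arrows=False, width=0.5)
    ax.set_title(f"Concept network: {cg.query_term!r}")
    ax.axis("off")
    fig.savefig(path, dpi=120)
    plt.close(fig)


@dataclass
class CorpusSummary:
    """Descriptive statistics of validated extractions over a linked corpus."""

    totals_per_class: dict[MClass, int]
    messages_with_content: int
    n_messages: int
    sender_role_counts: dict[str, int]
    sender_role_percent: dict[str, float]
    cross_tab_percent: dict[tuple[str, str, MClass], float]

    @property
    def total_extractions(self) -> int:
        return sum(self.totals_per_class.values())

    def to_frames(self) -> dict[str, pd.DataFrame]:
        totals = pd.DataFrame(
            {"class": [c.value for c in M_CLASSES],
             "extractions": [self.totals_per_class[c] for c in M_CLASSES]}
        )
        roles = pd.DataFrame(
            {"sender_role": list(self.sender_role_counts),
             "extractions": list(self.sender_role_counts.values()),
             "percent": [self.sender_role_percent[r] for r in self.sender_role_counts]}
        )
        cross = pd.DataFrame(
            [
                {"sender_role": s, "receiver_role": r, "class": c.value, "percent": pct}
                for (s, r, c), pct in sorted(self.cross_tab_percent.items(),
                                             key=lambda kv: -kv[1])
            ]
        )
        return {"totals": totals, "sender_roles": roles, "cross_tab": cross}

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        for name, frame in self.to_frames().items():
            frame.to_csv(directory / f"summary_{name}.csv", index=False)


def summarize_corpus(
    results: Iterable[ExtractionResult],
    corpus: LinkedCorpus | Sequence[Message],
) -> CorpusSummary:
    """Tally validated extractions by class and sender/receiver roles.

    Totals are conserved: the per-class totals sum over messages' validated
    counts, and every percentage distribution refers to the same extraction
    universe (full precision kept; round only for display).
    """
    messages = corpus.messages if isinstance(corpus, LinkedCorpus) else list(corpus)
    by_id = {m.message_id: m for m in messages}
    totals = {c: 0 for c in M_CLASSES}
    role_counts: dict[str, int] = {}
    cross: dict[tuple[str, str, MClass], int] = {}
    messages_with_content = 0
    n_messages = 0
    for r in results:
        m = by_id.get(r.message_id)
        if m is None:
            continue
        n_messages += 1
        if r.total_count > 0:
            messages_with_content += 1
        for c in M_CLASSES:
            k = r.counts[c]
            if k == 0:
                continue
            totals[c] += k
            role_counts[m.sender_role] = role_counts.get(m.sender_role, 0) + k
            key = (m.sender_role, m.receiver_role, c)
            cross[key] = cross.get(key, 0) + k
    grand = sum(totals.values())
    role_pct = {r: (100.0 * n / grand if grand else 0.0) for r, n in role_counts.items()}
    cross_pct = {k: (100.0 * n / grand if grand else 0.0) for k, n in cross.items()}
    return CorpusSummary(
        totals_per_class=totals,
        messages_with_content=messages_with_content,
        n_messages=n_messages,
        sender_role_counts=role_counts,
        sender_role_percent=role_pct,
        cross_tab_percent=cross_pct,
    )
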