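"""Knowledge-graph relation annotation of co-occurrence results.

A precomputed triples file (subject, subject type, relation label, object,
object type, evidence PMIDs) is loaded into a directed multigraph; node
names are normalized with exactly the corpus tokenizer so entity-term
matching has the same case/punctuation-insensitive semantics as abstract
matching.  Annotation is a pure decoration: it attaches typed relation
labels and their evidence PMIDs to significant pairs without touching
p-values, scores, or ranks.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import IO, Iterable, Sequence

import networkx as nx

from skimlbd.engine import SkimHit
from skimlbd.terms import TermSpec
from skimlbd.textnorm import normalize_phrase

logger = logging.getLogger(__name__)

ENTITY_TYPES = frozenset({"GGP", "CONDITION", "CHEMICAL", "BIO_PROCESS", "DRUG"})

RELATION_LABELS = frozenset(
    {
        "ACTIVATES",
        "INHIBITS",
        "REGULATES",
        "POS_ASSOCIATION",
        "NEG_ASSOCIATION",
        "COREF",
        "BINDS",
        "DRUG_INTERACTION_WITH",
        "TREATS",
        "MUTATION_AFFECTS",
    }
)

#: Labels whose direction carries no meaning for display.
SYMMETRIC_LABELS = frozenset({"COREF", "POS_ASSOCIATION", "NEG_ASSOCIATION"})

RELATIONS_COLUMNS = ["subject", "subject_type", "relation", "object", "object_type", "pmids"]


@dataclass(frozen=True)
class Annotation:
    """A typed relation found between a result pair's two terms.

    ``direction`` is "forward" when the stored edge runs x -> y for the
    queried pair (x, y), "reverse" otherwise.  For symmetric labels the
    direction is still reported but is not meaningful.
    """

    direction: str
    label: str
    pmids: frozenset[int]

    @property
    def symmetric(self) -> bool:
        return self.label in SYMMETRIC_LABELS


class KnowledgeGraph:
    """Typed entities (nodes) and typed directed relations (edges).

    Backed by a :class:`networkx.MultiDiGraph` keyed by normalized entity
    name; each edge carries a relation label and a non-empty evidence set.
    """

    def __init__(self) -> None:
        self.graph = nx.MultiDiGraph()
        # (subject, object, label) -> edge key, for evidence merging
        self._edge_keys: dict[tuple[str, str, str], int] = {}

    @property
    def n_entities(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_relations(self) -> int:
        return self.graph.number_of_edges()

    def add_relation(
        self,
        subject: str,
        subject_type: str,
        relation: str,
        obj: str,
        object_type: str,
        pmids: Iterable[int],
    ) -> None:
        """Add one triple; duplicate triples merge their evidence sets."""
        if subject_type not in ENTITY_TYPES:
            raise ValueError(f"unknown entity type {subject_type!r}")
        if object_type not in ENTITY_TYPES:
            raise ValueError(f"unknown entity type {object_type!r}")
        if relation not in RELATION_LABELS:
            raise ValueError(f"unknown relation label {relation!r}")
        pmids = frozenset(int(p) for p in pmids)
        if not pmids:
            raise ValueError("relation carries no evidence PMIDs")
        subj_name = normalize_phrase(subject)
        obj_name = normalize_phrase(obj)
        self.graph.add_node(subj_name, type=subject_type)
        self.graph.add_node(obj_name, type=object_type)
        triple = (subj_name, obj_name, relation)
        if triple in self._edge_keys:
            key = self._edge_keys[triple]
            merged = self.graph.edges[subj_name, obj_name, key]["pmids"] | pmids
            self.graph.edges[subj_name, obj_name, key]["pmids"] = merged
        else:
            key = self.graph.add_edge(subj_name, obj_name, label=relation, pmids=pmids)
            self._edge_keys[triple] = key

    def edges_between(self, x_names: set[str], y_names: set[str]):
        """Edges running between the two normalized-name sets, either way."""
        for u, v, data in self.graph.edges(data=True):
            if u in x_names and v in y_names:
                yield "forward", data
            elif u in y_names and v in x_names:
                yield "reverse", data


def load_relations(source: str | Path | IO[str]) -> KnowledgeGraph:
    """Load a relation-triples TSV into a knowledge graph.

    Columns: subject, subject_type, relation, object, object_type, pmids
    (comma-separated integers).  Rows with an unknown entity type or
    relation label, or with no evidence PMIDs, are skipped with a warning.
    Duplicate (subject, relation, object) rows merge their evidence.
    """
    close = False
    if isinstance(source, (str, Path)):
        handle: IO[str] = open(source, "r", encoding="utf-8", newline="")
        close = True
    else:
        handle = source
    graph = KnowledgeGraph()
    try:
        lines = [ln for ln in handle if ln.strip() and not ln.startswith("#")]
    finally:
        if close:
            handle.close()
    if not lines:
        return graph
    reader = csv.DictReader(lines, delimiter="\t", fieldnames=None)
    fieldnames = reader.fieldnames or []
    missing = [col for col in RELATIONS_COLUMNS if col not in fieldnames]
    if missing:
        raise ValueError(f"relations file missing required column(s) {missing}")
    for lineno, row in enumerate(reader, start=2):
        try:
            pmids = [int(p) for p in (row["pmids"] or "").split(",") if p.strip()]
            graph.add_relation(
                row["subject"], row["subject_type"], row["relation"],
                row["object"], row["object_type"], pmids,
            )
        except ValueError as exc:
            logger.warning("relations line %d skipped: %s", lineno, exc)
    return graph


def annotate_pair(
    graph: KnowledgeGraph, x: TermSpec | str, y: TermSpec | str
) -> list[Annotation]:
    """Relations whose endpoints match the two terms' synonym sets.

    Matching is the exact normalized-string match used everywhere else; an
    empty list simply means the pair lacks annotations.
    """
    x_names = {normalize_phrase(s) for s in TermSpec.coerce(x).synonyms}
    y_names = {normalize_phrase(s) for s in TermSpec.coerce(y).synonyms}
    annotations = [
        Annotation(direction=direction, label=data["label"], pmids=data["pmids"])
        for direction, data in graph.edges_between(x_names, y_names)
    ]
    annotations.sort(key=lambda ann: (ann.label, ann.direction))
    return annotations


def annotate_hits(
    hits: Sequence[SkimHit],
    graph: KnowledgeGraph | None,
    terms: dict[str, TermSpec] | None = None,
) -> list[SkimHit]:
    """Attach A-B and B-C annotations to hits, preserving everything else.

    ``terms`` may map labels back to their full synonym sets; otherwise a
    hit's labels are matched as single-synonym terms.  With no graph, hits
    pass through with empty annotation lists.
    """
    terms = terms or {}

    def term_for(label: str) -> TermSpec:
        return terms.get(label, TermSpec(label))

    annotated: list[SkimHit] = []
    for hit in hits:
        if graph is None:
            ab_ann: tuple = ()
            bc_ann: tuple = ()
        else:
            ab_ann = tuple(annotate_pair(graph, term_for(hit.a_label), term_for(hit.b_label)))
            bc_ann = tuple(annotate_pair(graph, term_for(hit.b_label), term_for(hit.c_label)))
        annotated.append(replace(hit, ab_annotations=ab_ann, bc_annotations=bc_ann))
    return annotated


def hits_to_json(hits: Sequence[SkimHit]) -> list[dict]:
    """JSON-serializable form of (annotated) hits."""
    def ann_json(anns: tuple) -> list[dict]:
        return [
            {"direction": a.direction, "label": a.label, "pmids": sorted(a.pmids)}
            for a in anns
        ]

    return [
        {
            "a_label": hit.a_label,
            "b_label": hit.b_label,
            "c_label": hit.c_label,
            "ab_p": hit.ab.p_value,
            "bc_p": hit.bc.p_value,
            "bc_ratio": hit.bc.ratio,
            "prediction_score": hit.prediction_score,
            "rank": hit.rank,
            "ab_evidence_pmids": sorted(hit.ab.pmid_evidence),
            "bc_evidence_pmids": sorted(hit.bc.pmid_evidence),
            "ab_annotations": ann_json(hit.ab_annotations),
            "bc_annotations": ann_json(hit.bc_annotations),
        }
        for hit in hits
    ]
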