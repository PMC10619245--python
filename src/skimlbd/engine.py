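"""The serial two-stage (A -> B -> C) discovery search.

Open discovery: every A-B pair is tested; pairs passing the significance
threshold (default p < 1e-5, strict) survive, capped at the 300 smallest
p-values; each surviving B is then paired with every C term, and the
(A, B, C) chains are ranked by a prediction score.  The score is the
significance-gated B-C ratio: n_both / n_c when the B-C p-value is below
the significance threshold, else 0 — coverage of the C term's literature
by the linking B term.

Closed discovery: given A and C, report B terms significantly linked to
both, ordered by the weaker of the two p-values.
"""

from __future__ import annotations

import json
import logging
import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import IO, Any, Sequence

from skimlbd import stats
from skimlbd.index import CorpusIndex, load_index, build_index
from skimlbd.corpus import parse_pubmed_xml, read_jsonl_corpus
from skimlbd.stats import PairResult, format_p, km_query, pair_result
from skimlbd.terms import TermSpec, coerce_terms, read_term_list

logger = logging.getLogger(__name__)

SKIM_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class SearchParams:
    """Tunable filtering and ranking parameters for a search.

    ``ab_p_threshold``: strict upper bound for a significant A-B pair
    (default 1e-5).  ``max_b_pairs``: at most this many A-B pairs, the
    smallest by p, proceed to stage two (default 300).  ``bc_p_threshold``:
    significance bound gating the B-C prediction score.
    """

    ab_p_threshold: float = 1e-5
    max_b_pairs: int = 300
    bc_p_threshold: float = 1e-5
    cutoff_year: int | None = None
    association_measure: str = "fet"
    top_n: int | None = None

    def __post_init__(self) -> None:
        for name in ("ab_p_threshold", "bc_p_threshold"):
            value = getattr(self, name)
            if not (0.0 < value <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {value}")
        if self.max_b_pairs < 1:
            raise ValueError("max_b_pairs must be >= 1")
        if self.association_measure not in ("fet", "chi2"):
            raise ValueError(f"unknown association measure {self.association_measure!r}")
        if self.top_n is not None and self.top_n < 1:
            raise ValueError("top_n must be >= 1 when given")


@dataclass(frozen=True)
class SkimHit:
    """One A-B-C chain: a significant A-B pair joined to a B-C pair."""

    a_label: str
    b_label: str
    c_label: str
    ab: PairResult
    bc: PairResult
    prediction_score: float
    rank: int
    ab_annotations: tuple = ()
    bc_annotations: tuple = ()


@dataclass(frozen=True)
class ClosedLink:
    """A B term significantly linked to both ends of a closed search."""

    b_label: str
    ab: PairResult
    bc: PairResult


def prediction_score(bc: PairResult, significance_threshold: float = 1e-5) -> float:
    """Significance-gated B-C ratio.

    When the B-C pair is significant (p strictly below the threshold), the
    score is n_both / n_c — the fraction of the C term's abstracts that the
    linking B term also appears in.  Non-significant pairs score 0.
    """
    if bc.p_value < significance_threshold:
        return bc.ratio
    return 0.0


def select_top_pairs(
    pairs: Sequence[PairResult], threshold: float, cap: int
) -> list[PairResult]:
    """Stage-one filter: strict p < threshold, then keep the ``cap`` smallest
    by p (deterministic tie-break)."""
    surviving = sorted(
        (p for p in pairs if p.p_value < threshold), key=PairResult.sort_key
    )
    return surviving[:cap]


def _hit_order(hit: SkimHit) -> tuple:
    return (
        -hit.prediction_score,
        hit.bc.p_value,
        hit.a_label,
        hit.b_label,
        hit.c_label,
    )


def skim_open(
    a_term: TermSpec | str,
    b_terms: Sequence[TermSpec | str],
    c_terms: Sequence[TermSpec | str],
    index: CorpusIndex,
    params: SearchParams | None = None,
) -> list[SkimHit]:
    """Open discovery: propose C terms linked to A through some B.

    Returns ranked hits (rank 1-based, gapless), ordered descending by
    prediction score with ascending B-C p-value and labels as tie-breaks.
    Trivial self-links (B and C the same label) are suppressed.
    """
    params = params or SearchParams()
    if not b_terms or not c_terms:
        raise ValueError("skim_open requires non-empty B and C term lists")
    a_term = TermSpec.coerce(a_term)
    b_terms = coerce_terms(b_terms)
    c_terms = coerce_terms(c_terms)

    ab_pairs = km_query(
        [a_term], b_terms, index,
        cutoff_year=params.cutoff_year, measure=params.association_measure,
    )
    surviving = select_top_pairs(ab_pairs, params.ab_p_threshold, params.max_b_pairs)
    logger.info(
        "stage 1: %d A-B pairs tested, %d pass p < %g, %d after cap of %d",
        len(ab_pairs),
        sum(1 for p in ab_pairs if p.p_value < params.ab_p_threshold),
        params.ab_p_threshold,
        len(surviving),
        params.max_b_pairs,
    )
    if not surviving:
        logger.info("no A-B pair passed the significance threshold; empty result")
        return []

    b_by_label = {term.label: term for term in b_terms}
    hits: list[SkimHit] = []
    n_bc_tested = 0
    for ab in surviving:
        b_term = b_by_label[ab.y_label]
        for c_term in c_terms:
            if c_term.label == b_term.label:
                logger.info("suppressing trivial self-link B=C=%r", c_term.label)
                continue
            bc = pair_result(
                index, b_term, c_term,
                cutoff_year=params.cutoff_year, measure=params.association_measure,
            )
            n_bc_tested += 1
            hits.append(
                SkimHit(
                    a_label=a_term.label,
                    b_label=b_term.label,
                    c_label=c_term.label,
                    ab=ab,
                    bc=bc,
                    prediction_score=prediction_score(bc, params.bc_p_threshold),
                    rank=0,
                )
            )
    hits.sort(key=_hit_order)
    if params.top_n is not None:
        hits = hits[: params.top_n]
    hits = [replace(hit, rank=i) for i, hit in enumerate(hits, start=1)]
    logger.info("stage 2: %d B-C pairs tested, %d hits reported", n_bc_tested, len(hits))
    return hits


def skim_closed(
    a_term: TermSpec | str,
    c_term: TermSpec | str,
    b_terms: Sequence[TermSpec | str],
    index: CorpusIndex,
    params: SearchParams | None = None,
) -> list[ClosedLink]:
    """Closed discovery: B terms significantly linked to both A and C.

    A B term is reported when its A-B p-value is below ``ab_p_threshold``
    and its B-C p-value is below ``bc_p_threshold`` (both strict); links
    are sorted ascending by the weaker (larger) of the two p-values.  B-C
    p-values are computed identically to the open-discovery path.
    """
    params = params or SearchParams()
    if not b_terms:
        raise ValueError("skim_closed requires a non-empty B term list")
    a_term = TermSpec.coerce(a_term)
    c_term = TermSpec.coerce(c_term)
    b_terms = coerce_terms(b_terms)

    links: list[ClosedLink] = []
    for b_term in b_terms:
        ab = pair_result(
            index, a_term, b_term,
            cutoff_year=params.cutoff_year, measure=params.association_measure,
        )
        bc = pair_result(
            index, b_term, c_term,
            cutoff_year=params.cutoff_year, measure=params.association_measure,
        )
        if ab.p_value < params.ab_p_threshold and bc.p_value < params.bc_p_threshold:
            links.append(ClosedLink(b_label=b_term.label, ab=ab, bc=bc))
    links.sort(key=lambda ln: (max(ln.ab.p_value, ln.bc.p_value), ln.b_label))
    logger.info(
        "closed search: %d B terms tested, %d significant on both sides",
        len(b_terms), len(links),
    )
    if params.top_n is not None:
        links = links[: params.top_n]
    return links


# ---------------------------------------------------------------------------
# Result serialization
# ---------------------------------------------------------------------------

SKIM_COLUMNS = [
    "a_label", "b_label", "c_label",
    "ab_p", "ab_p_display", "bc_p", "bc_p_display",
    "bc_ratio", "prediction_score", "rank",
    "ab_evidence_pmids", "bc_evidence_pmids",
]


def write_skim_tsv(
    hits: Sequence[SkimHit], dest: str | Path | IO[str], max_evidence: int = 20
) -> None:
    """Write SKiM hits as TSV with a versioned header comment line."""
    close = False
    if isinstance(dest, (str, Path)):
        handle: IO[str] = open(dest, "w", encoding="utf-8", newline="")
        close = True
    else:
        handle = dest
    try:
        handle.write(f"# skimlbd skim-results v{SKIM_SCHEMA_VERSION}\n")
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(SKIM_COLUMNS)
        for hit in hits:
            writer.writerow(
                [
                    hit.a_label, hit.b_label, hit.c_label,
                    repr(hit.ab.p_value), format_p(hit.ab.p_value),
                    repr(hit.bc.p_value), format_p(hit.bc.p_value),
                    f"{hit.bc.ratio:.6g}", f"{hit.prediction_score:.6g}", hit.rank,
                    ",".join(str(p) for p in sorted(hit.ab.pmid_evidence)[:max_evidence]),
                    ",".join(str(p) for p in sorted(hit.bc.pmid_evidence)[:max_evidence]),
                ]
            )
    finally:
        if close:
            handle.close()


def read_skim_tsv(source: str | Path | IO[str]) -> list[dict[str, str]]:
    """Read a SKiM results TSV back as row dicts (schema-checked)."""
    close = False
    if isinstance(source, (str, Path)):
        handle: IO[str] = open(source, "r", encoding="utf-8", newline="")
        close = True
    else:
        handle = source
    try:
        lines = [ln for ln in handle if not ln.startswith("#")]
    finally:
        if close:
            handle.close()
    reader = csv.DictReader(lines, delimiter="\t")
    fieldnames = reader.fieldnames or []
    for column in ("a_label", "b_label", "c_label"):
        if column not in fieldnames:
            raise ValueError(f"results file missing required column {column!r}")
    return list(reader)


# ---------------------------------------------------------------------------
# Declarative query plans
# ---------------------------------------------------------------------------


def _load_plan(plan: dict[str, Any] | str | Path) -> dict[str, Any]:
    if isinstance(plan, (str, Path)):
        with open(plan, "r", encoding="utf-8") as handle:
            return json.load(handle)
    return dict(plan)


def _load_corpus_index(plan: dict[str, Any]) -> CorpusIndex:
    if "index" in plan:
        return load_index(plan["index"])
    corpus_path = Path(plan["corpus"])
    fmt = plan.get("corpus_format", "auto")
    if fmt == "auto":
        fmt = "xml" if corpus_path.suffix.lower() == ".xml" else "jsonl"
    docs = parse_pubmed_xml(corpus_path) if fmt == "xml" else read_jsonl_corpus(corpus_path)
    return build_index(docs)


def run_query_plan(plan: dict[str, Any] | str | Path) -> Path:
    """Execute a declarative search plan and write its result file.

    The plan names the corpus or index, the term-list files, the mode
    (``km`` | ``skim-open`` | ``skim-closed``), the search parameters, and
    the output path.  Configuration problems (missing files, unknown mode)
    raise before any computation starts; per-stage counts are logged.
    Returns the output path.
    """
    plan = _load_plan(plan)
    mode = plan.get("mode")
    if mode not in ("km", "skim-open", "skim-closed"):
        raise ValueError(f"unknown mode {mode!r}; expected km, skim-open or skim-closed")
    required = ["a_terms", "b_terms"] if mode != "skim-open" else ["a_terms", "b_terms", "c_terms"]
    if mode == "skim-closed":
        required.append("c_terms")
    for key in required + (["index"] if "index" in plan else ["corpus"]):
        if key not in plan:
            raise ValueError(f"plan is missing required key {key!r}")
        if not Path(plan[key]).exists():
            raise FileNotFoundError(f"plan {key}: no such file {plan[key]!r}")
    if "output" not in plan:
        raise ValueError("plan is missing required key 'output'")

    params = SearchParams(
        ab_p_threshold=plan.get("ab_p_threshold", 1e-5),
        max_b_pairs=plan.get("max_b_pairs", 300),
        bc_p_threshold=plan.get("bc_p_threshold", plan.get("ab_p_threshold", 1e-5)),
        cutoff_year=plan.get("cutoff_year"),
        association_measure=plan.get("association_measure", "fet"),
        top_n=plan.get("top_n"),
    )
    a_terms = read_term_list(plan["a_terms"])
    b_terms = read_term_list(plan["b_terms"])
    c_terms = read_term_list(plan["c_terms"]) if "c_terms" in plan else []
    logger.info(
        "terms loaded: %d A, %d B, %d C", len(a_terms), len(b_terms), len(c_terms)
    )
    index = _load_corpus_index(plan)
    out_path = Path(plan["output"])

    if mode == "km":
        results = km_query(
            a_terms, b_terms, index,
            cutoff_year=params.cutoff_year, measure=params.association_measure,
        )
        if params.top_n is not None:
            results = results[: params.top_n]
        stats.write_results_tsv(results, out_path)
    elif mode == "skim-open":
        # one A concept per search; multiple A terms run independently and
        # their ranked outputs are concatenated, tagged by a_label
        all_hits: list[SkimHit] = []
        for a_term in a_terms:
            all_hits.extend(skim_open(a_term, b_terms, c_terms, index, params))
        write_skim_tsv(all_hits, out_path)
    else:
        rows: list[SkimHit] = []
        for a_term in a_terms:
            for c_term in c_terms:
                links = skim_closed(a_term, c_term, b_terms, index, params)
                for i, link in enumerate(links, start=1):
                    rows.append(
                        SkimHit(
                            a_label=a_term.label,
                            b_label=link.b_label,
                            c_label=c_term.label,
                            ab=link.ab,
                            bc=link.bc,
                            prediction_score=prediction_score(
                                link.bc, params.bc_p_threshold
                            ),
                            rank=i,
                        )
                    )
        write_skim_tsv(rows, out_path)
    logger.info("results written to %s", out_path)
    return out_path
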