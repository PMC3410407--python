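"""Semi-automatic curation of motif-screen candidates.

The screen is deliberately permissive, so raw candidate lists contain
fragments and chance matches.  Curation proceeds in four steps:

1. a length filter against the mean span between the outermost motif
   hits in reference (Arabidopsis-type) transporters — candidates
   shorter than a fraction (default 70%) of that span are discarded;
2. all-vs-all optimal global alignment (BLOSUM62, gap open 10,
   extension 0.5) scoring each pair as percent identity over the
   shorter sequence;
3. pruning: pairs scoring 100 are treated as duplicates (the
   lexicographically larger id is dropped), pairs under a minimum score
   (default 20) are deleted; connected components of the surviving
   similarity graph fragment the candidates into groups;
4. the group with the highest mean similarity to the reference
   proteins is selected.

The original procedure's "ClustalW2 score" is not a published formula;
here the score is defined reproducibly as 100 x identities / min(len),
with identities taken from an optimal global alignment (maximizing the
identity count among enumerated optimal alignments, so ties are
resolved deterministically).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

from .motifs import MotifPattern, scan
from .seqio import ProteinRecord


@dataclass(frozen=True)
class CurationParams:
    length_fraction: float = 0.70
    min_pair_score: float = 20.0
    identical_score: float = 100.0

    def __post_init__(self):
        if not 0 < self.length_fraction <= 1:
            raise ValueError("length_fraction must be in (0, 1]")
        if not 0 <= self.min_pair_score < self.identical_score <= 100:
            raise ValueError("require 0 <= min_pair_score < identical_score <= 100")


@dataclass(frozen=True)
class SimilarityEdge:
    """Percent identity between an unordered pair (id_a < id_b)."""

    id_a: str
    id_b: str
    score: float

    def __post_init__(self):
        if self.id_a >= self.id_b:
            raise ValueError("edges must satisfy id_a < id_b")


@dataclass
class CurationReport:
    discarded_short: dict  # id -> reason
    removed_identical: list
    components: list  # list of sorted id lists
    selected_component: list
    reference_similarity: list  # mean score to reference, parallel to components
    duplicate_of: dict = field(default_factory=dict)  # removed id -> kept twin

    def surviving_ids(self) -> list[str]:
        return sorted(itertools.chain.from_iterable(self.components))


def make_aligner() -> Align.PairwiseAligner:
    """Global BLOSUM62 aligner, affine gaps (open 10, extend 0.5)."""
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    return aligner


def _alignment_identities(alignment) -> int:
    count = 0
    target, query = alignment.target, alignment.query
    for (t0, t1), (q0, q1) in zip(*alignment.aligned):
        count += sum(1 for a, b in zip(target[t0:t1], query[q0:q1]) if a == b)
    return count


def pair_score(
    seq_a: str, seq_b: str, aligner: Align.PairwiseAligner | None = None, max_alternates: int = 64
) -> float:
    """Percent identity over the shorter sequence, optimal global alignment.

    Among co-optimal alignments (enumerated deterministically, capped at
    ``max_alternates``) the one with the most identities defines the
    score.  Rounded to 2 decimals.
    """
    if aligner is None:
        aligner = make_aligner()
    alignments = aligner.align(seq_a, seq_b)
    best = 0
    for alignment in itertools.islice(alignments, max_alternates):
        best = max(best, _alignment_identities(alignment))
    return round(100.0 * best / min(len(seq_a), len(seq_b)), 2)


def reference_span(
    reference_proteins: list[ProteinRecord], motif_library: list[MotifPattern]
) -> float:
    """Mean distance between the outermost motif hits in the references.

    References with fewer than two hits across the library are excluded;
    if none remain the threshold is undefined and an error is raised.
    """
    spans = []
    for protein in reference_proteins:
        hits = []
        for pattern in motif_library:
            hits.extend(scan(protein, pattern))
        if len(hits) < 2:
            continue
        first = min(h.start for h in hits)
        last = max(h.end for h in hits)
        spans.append(last - first)
    if not spans:
        raise ValueError(
            "no reference protein carries >= 2 motif hits; length threshold undefined"
        )
    return sum(spans) / len(spans)


def length_filter(
    candidates: list[ProteinRecord], span: float, params: CurationParams = CurationParams()
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Keep candidates with length >= length_fraction * span (boundary kept)."""
    if span <= 0:
        raise ValueError("span must be positive")
    threshold = params.length_fraction * span
    kept = [c for c in candidates if len(c) >= threshold]
    discarded = [c for c in candidates if len(c) < threshold]
    return kept, discarded


def pairwise_scores(
    proteins: list[ProteinRecord], aligner: Align.PairwiseAligner | None = None
) -> list[SimilarityEdge]:
    """All n(n-1)/2 similarity edges among the proteins."""
    if len(proteins) < 2:
        raise ValueError("need >= 2 proteins for pairwise scoring")
    if aligner is None:
        aligner = make_aligner()
    edges = []
    for rec_a, rec_b in itertools.combinations(sorted(proteins, key=lambda p: p.id), 2):
        edges.append(
            SimilarityEdge(
                id_a=rec_a.id,
                id_b=rec_b.id,
                score=pair_score(rec_a.sequence, rec_b.sequence, aligner),
            )
        )
    return edges


def prune_and_fragment(
    edges: list[SimilarityEdge], ids: list[str], params: CurationParams = CurationParams()
) -> CurationReport:
    """Drop duplicates (score == identical_score), prune weak edges, fragment.

    For every identical pair the lexicographically larger id is removed
    from the analysis; edges below min_pair_score are deleted; connected
    components of the remainder are the candidate groups (isolated ids
    form singletons).
    """
    removed: set[str] = set()
    duplicate_of: dict[str, str] = {}
    # sorted processing makes the rule order-independent; a pair that could
    # remove id_a sorts before any pair where id_a is the keeper
    for edge in sorted(edges, key=lambda e: (e.id_a, e.id_b)):
        if edge.score >= params.identical_score:
            if edge.id_a not in removed and edge.id_b not in removed:
                removed.add(edge.id_b)
                duplicate_of[edge.id_b] = edge.id_a
    graph = nx.Graph()
    graph.add_nodes_from(i for i in ids if i not in removed)
    for edge in edges:
        if edge.id_a in removed or edge.id_b in removed:
            continue
        if edge.score >= params.identical_score or edge.score < params.min_pair_score:
            continue
        graph.add_edge(edge.id_a, edge.id_b)
    components = sorted((sorted(c) for c in nx.connected_components(graph)), key=lambda c: c[0])
    return CurationReport(
        discarded_short={},
        removed_identical=sorted(removed),
        components=components,
        selected_component=[],
        reference_similarity=[],
        duplicate_of=duplicate_of,
    )


def select_group(
    components: list[list[str]],
    members: dict[str, ProteinRecord],
    reference_proteins: list[ProteinRecord],
    aligner: Align.PairwiseAligner | None = None,
) -> tuple[list[str], list[float]]:
    """Pick the component most similar to the reference proteins.

    Similarity of a component is the mean pair_score over all
    (member, reference) pairs.  Ties break toward the larger component,
    then the lexicographically smallest member id.
    """
    if not reference_proteins:
        raise ValueError("need >= 1 reference protein")
    if not components:
        return [], []
    if aligner is None:
        aligner = make_aligner()
    similarities = []
    for component in components:
        scores = [
            pair_score(members[mid].sequence, ref.sequence, aligner)
            for mid in component
            for ref in reference_proteins
        ]
        similarities.append(sum(scores) / len(scores))
    best = sorted(
        range(len(components)),
        key=lambda i: (-similarities[i], -len(components[i]), components[i][0]),
    )[0]
    return components[best], similarities


def curate(
    candidates: list[ProteinRecord],
    reference_proteins: list[ProteinRecord],
    motif_library: list[MotifPattern],
    params: CurationParams = CurationParams(),
) -> CurationReport:
    """Run the full curation chain and return an auditable report."""
    span = reference_span(reference_proteins, motif_library)
    kept, discarded = length_filter(candidates, span, params)
    report_discarded = {
        c.id: f"length {len(c)} < {params.length_fraction:.0%} of reference span {span:.1f}"
        for c in discarded
    }
    if not kept:
        return CurationReport(report_discarded, [], [], [], [])
    if len(kept) == 1:
        report = CurationReport(report_discarded, [], [[kept[0].id]], [kept[0].id], [])
        return report
    aligner = make_aligner()
    edges = pairwise_scores(kept, aligner)
    report = prune_and_fragment(edges, [c.id for c in kept], params)
    report.discarded_short = report_discarded
    members = {c.id: c for c in kept}
    selected, similarities = select_group(report.components, members, reference_proteins, aligner)
    report.selected_component = selected
    report.reference_similarity = similarities
    return report
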