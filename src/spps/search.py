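"""Partner search: the two query modes of the prediction engine.

Single Query screens one protein sequence against a whole
species-specific database and ranks candidate partners whose calibrated
interaction probability exceeds 50%, in descending order.  Multiple
Query scores one candidate pair directly and, optionally, searches for
indirect interactions — chains through one or two intermediate database
proteins in which every edge clears the same 50% threshold.

The 50% rule is strict (probability == 0.5 is excluded), matching the
positive-classification convention used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from .classifier import TrainedModel
from .exceptions import ValidationError
from .protein_db import ProteinDatabase

PROBABILITY_THRESHOLD = 0.5


@dataclass(frozen=True)
class PartnerHit:
    """One ranked candidate partner from a Single Query search."""

    partner_id: str
    entry_name: str
    probability: float
    rank: int


@dataclass(frozen=True)
class InteractionPath:
    """A chain query A -> [intermediates] -> query B with per-edge
    probabilities; path_score is the product of the edge probabilities."""

    nodes: Tuple[str, ...]
    edge_probabilities: Tuple[float, ...]
    path_score: float

    @property
    def n_intermediates(self) -> int:
        return len(self.nodes) - 2


def single_query(
    query_sequence: str,
    db: ProteinDatabase,
    model: TrainedModel,
    query_id: Optional[str] = None,
) -> List[PartnerHit]:
    """Rank database partners of one query sequence.

    Every database protein is scored with the symmetrized calibrated
    probability; hits with probability strictly above 0.5 are returned
    in descending order, ties broken by accession so the output is
    independent of database storage order.  If *query_id* names a
    database protein, that self-match is excluded.
    """
    if len(db) == 0:
        raise ValidationError("cannot search an empty database")
    scored = []
    for rec in db:
        if query_id is not None and rec.id == query_id:
            continue
        p = model.predict_probability(query_sequence, rec.sequence, symmetrize=True)
        if p > PROBABILITY_THRESHOLD:
            scored.append((rec.id, rec.entry_name, p))
    scored.sort(key=lambda t: (-t[2], t[0]))
    return [
        PartnerHit(partner_id=pid, entry_name=name, probability=p, rank=i + 1)
        for i, (pid, name, p) in enumerate(scored)
    ]


def direct_interaction(
    seqA: str, seqB: str, model: TrainedModel
) -> float:
    """Symmetrized interaction probability of one candidate pair.

    The pair is classified as interacting iff the value exceeds 0.5.
    """
    return model.predict_probability(seqA, seqB, symmetrize=True)


class _EdgeScorer:
    """Caches symmetrized probabilities between named nodes.

    Query endpoints carry synthetic node keys so they never collide
    with database accessions.  When *use_known_ppi* is on, an edge
    between two database proteins recorded as known partners scores
    1.0 regardless of the model.
    """

    def __init__(self, model: TrainedModel, sequences: Dict[str, str],
                 db: Optional[ProteinDatabase] = None,
                 use_known_ppi: bool = False) -> None:
        self.model = model
        self.sequences = sequences
        self.db = db
        self.use_known_ppi = use_known_ppi
        self._cache: Dict[frozenset, float] = {}

    def prob(self, u: str, v: str) -> float:
        key = frozenset((u, v))
        if key not in self._cache:
            if (
                self.use_known_ppi
                and self.db is not None
                and u in self.db
                and v in self.db
                and v in self.db.annotation(u).known_partners
            ):
                self._cache[key] = 1.0
            else:
                self._cache[key] = self.model.predict_probability(
                    self.sequences[u], self.sequences[v], symmetrize=True
                )
        return self._cache[key]


def indirect_interaction(
    seqA: str,
    seqB: str,
    db: ProteinDatabase,
    model: TrainedModel,
    max_intermediates: int = 2,
    exclude_ids: Tuple[str, ...] = (),
    use_known_ppi: bool = False,
) -> List[InteractionPath]:
    """Chains A - C (- D) - B through database intermediates.

    One-intermediate paths require P(A,C) > 0.5 and P(C,B) > 0.5;
    two-intermediate paths additionally require P(C,D) > 0.5, with C and
    D distinct database proteins.  Ids listed in *exclude_ids* (e.g. the
    queries' own database entries) are never used as intermediates.
    Paths are sorted by path_score (product of edge probabilities)
    descending; at equal score shorter paths come first, then node
    order lexicographically.

    With *use_known_ppi* on, known-PPI edges between database proteins
    count as probability 1.0 instead of the predicted value.
    """
    if max_intermediates not in (1, 2):
        raise ValidationError("max_intermediates must be 1 or 2")
    if len(db) == 0:
        raise ValidationError("cannot search an empty database")

    sequences = {rec.id: rec.sequence for rec in db}
    a_key, b_key = "\x00queryA", "\x00queryB"
    sequences[a_key] = seqA
    sequences[b_key] = seqB
    scorer = _EdgeScorer(model, sequences, db=db, use_known_ppi=use_known_ppi)

    candidates = [rec.id for rec in db if rec.id not in exclude_ids]
    paths: List[InteractionPath] = []

    # Edges from the queries, computed once
    pa = {c: scorer.prob(a_key, c) for c in candidates}
    pb = {c: scorer.prob(c, b_key) for c in candidates}

    for c in candidates:
        if pa[c] > PROBABILITY_THRESHOLD and pb[c] > PROBABILITY_THRESHOLD:
            probs = (pa[c], pb[c])
            paths.append(InteractionPath(
                nodes=("A", c, "B"),
                edge_probabilities=probs,
                path_score=probs[0] * probs[1],
            ))

    if max_intermediates == 2:
        viable_from_a = [c for c in candidates if pa[c] > PROBABILITY_THRESHOLD]
        viable_to_b = [c for c in candidates if pb[c] > PROBABILITY_THRESHOLD]
        for c in viable_from_a:
            for d in viable_to_b:
                if c == d:
                    continue
                p_cd = scorer.prob(c, d)
                if p_cd > PROBABILITY_THRESHOLD:
                    probs = (pa[c], p_cd, pb[d])
                    paths.append(InteractionPath(
                        nodes=("A", c, d, "B"),
                        edge_probabilities=probs,
                        path_score=probs[0] * probs[1] * probs[2],
                    ))

    paths.sort(key=lambda p: (-p.path_score, len(p.nodes), p.nodes))
    return paths


def hits_to_table(hits: List[PartnerHit], db: Optional[ProteinDatabase] = None):
    """Ranked hits as a DataFrame mirroring the partner-list report
    (rank, probability to 4 decimals, accession, entry name)."""
    import pandas as pd

    rows = []
    for h in hits:
        rows.append({
            "rank": h.rank,
            "probability": round(h.probability, 4),
            "partner_id": h.partner_id,
            "entry_name": h.entry_name,
        })
    return pd.DataFrame(rows, columns=["rank", "probability", "partner_id", "entry_name"])
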