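"""Synthetic proteomes, interactomes and annotations with planted signal.

The generator emulates, at desk scale, the kind of data the search
engine is meant for: a species-specific sequence database, a labeled
interaction collection for training, and per-protein annotations.  The
planted interaction rule is *complementary motifs*: a random subset of
proteins carries motif A or motif B spliced into its sequence, and a
pair interacts iff one member carries A and the other carries B.
Because the motifs are short, class-distinctive peptides, their triad
content is exactly what the conjoint-triad featurization measures —
the planted signal is learnable by construction, so classifier tests
exercise real discrimination rather than chance.

Labels are then flipped independently with a configurable noise rate,
emulating the false positives/negatives of high-throughput interaction
screens.  All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .classifier import NEGATIVE_LABEL, POSITIVE_LABEL, PPIDataset
from .exceptions import ValidationError
from .protein_db import AnnotationRecord, ProteinDatabase, ProteinRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Approximate residue frequencies of globular proteins, for the
#: natural-composition background mode.
NATURAL_FREQUENCIES = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0137,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}

TISSUE_VOCABULARY = ("Liver", "Brain", "Kidney", "Heart", "Lung", "Muscle")

#: Default complementary motif pair.  Each motif alternates two residues
#: from rarely co-occurring physicochemical classes (C/K: cysteine and
#: basic; D/W: acidic and aromatic-polar), so its triad signature stands
#: out sharply against a random background.
DEFAULT_MOTIF_PAIR = ("CKCKCKCKC", "DWDWDWDWD")


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic dataset.

    Defaults produce the benchmark used throughout the test-bed: 200
    proteins of 80-160 residues, 60% of them motif carriers, 800
    labeled pairs at 1:1 class balance, and a 5% label-flip rate.
    """

    n_proteins: int = 200
    length_range: Tuple[int, int] = (80, 160)
    motif_pairs: Tuple[Tuple[str, str], ...] = (DEFAULT_MOTIF_PAIR,)
    carrier_fraction: float = 0.6
    n_pairs: int = 800
    positive_fraction: float = 0.5
    noise_rate: float = 0.05
    known_ppi_fraction: float = 0.25
    background: str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 9 or hi < lo:
            raise ValidationError("sequence lengths must be >= 9 and min <= max")
        for ma, mb in self.motif_pairs:
            if min(len(ma), len(mb)) < 3:
                raise ValidationError("motifs must be at least 3 residues long")
            if max(len(ma), len(mb)) + 2 > lo:
                raise ValidationError("motifs must fit strictly inside sequences")
        if not 0.0 <= self.noise_rate < 0.5:
            raise ValidationError("noise_rate must lie in [0, 0.5)")
        if not 0.0 < self.positive_fraction < 1.0:
            raise ValidationError("positive_fraction must lie in (0, 1)")
        if self.background not in ("uniform", "natural"):
            raise ValidationError(f"unknown background {self.background!r}")


def _rng(seed: int, salt: int) -> np.random.Generator:
    return np.random.default_rng((seed * 1_000_003 + salt) % (2**31 - 1))


def _carrier_table(spec: FixtureSpec) -> dict:
    """Seeded random carrier assignment: index -> (pair_index, side, motif).

    A random ``carrier_fraction`` subset of proteins carries a motif;
    carriers alternate between the A and B sides of successive motif
    pairs so both sides are equally populated.  Pure function of the
    spec (own rng stream), so the ground-truth interaction rule can be
    reconstructed by any generator without shared state.
    """
    rng = _rng(spec.seed, 0)
    n_carriers = int(round(spec.carrier_fraction * spec.n_proteins))
    carriers = sorted(
        rng.choice(spec.n_proteins, size=n_carriers, replace=False).tolist()
    )
    table = {}
    for rank, index in enumerate(carriers):
        pair_idx = (rank // 2) % len(spec.motif_pairs)
        side = "A" if rank % 2 == 0 else "B"
        motif = spec.motif_pairs[pair_idx][0 if side == "A" else 1]
        table[index] = (pair_idx, side, motif)
    return table


def generate_proteome(spec: FixtureSpec) -> List[ProteinRecord]:
    """Draw random sequences and splice motifs into the carrier subset.

    Sequences are i.i.d. over the 20 residues (uniform by default,
    natural composition optionally) at lengths uniform in
    ``length_range``; a carrier's motif overwrites a window at a random
    interior position, keeping length fixed.  Ids are "SYN0001"... with
    entry names "SYN0001_SYNTH".  Deterministic given the seed.
    """
    rng = _rng(spec.seed, 1)
    lo, hi = spec.length_range
    if spec.background == "uniform":
        probs = None
    else:
        probs = np.array([NATURAL_FREQUENCIES[a] for a in AMINO_ACIDS])
        probs = probs / probs.sum()
    letters = np.array(list(AMINO_ACIDS))
    carriers = _carrier_table(spec)
    records = []
    for i in range(spec.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(letters, size=length, p=probs))
        motif = carriers[i][2] if i in carriers else None
        if motif is not None:
            pos = int(rng.integers(1, length - len(motif)))
            seq = seq[:pos] + motif + seq[pos + len(motif):]
        pid = f"SYN{i + 1:04d}"
        records.append(ProteinRecord(
            id=pid, sequence=seq, entry_name=f"{pid}_SYNTH", species="synthetic",
        ))
    return records


def _complementary_pairs(spec: FixtureSpec) -> List[Tuple[str, str]]:
    """All unordered (A-carrier, B-carrier) pairs within a motif pair —
    the ground-truth positive interactions, derivable from the spec."""
    sides: dict = {}
    for i, (pair_idx, side, _) in sorted(_carrier_table(spec).items()):
        sides.setdefault(pair_idx, {"A": [], "B": []})[side].append(f"SYN{i + 1:04d}")
    out = []
    for pair_idx in sorted(sides):
        for a in sides[pair_idx]["A"]:
            for b in sides[pair_idx]["B"]:
                out.append((a, b))
    return out


def true_positive_pairs(spec: FixtureSpec) -> List[Tuple[str, str]]:
    """Public view of the planted ground-truth interactions."""
    return _complementary_pairs(spec)


def generate_interactome(
    proteome: Sequence[ProteinRecord], spec: FixtureSpec
) -> PPIDataset:
    """Sample a labeled pair collection from the planted rule.

    ``round(n_pairs * positive_fraction)`` positives are drawn from the
    complementary-motif pairs and the remainder from non-interacting
    pairs; every label is then flipped independently with probability
    ``noise_rate``.  Deterministic given the seed.
    """
    rng = _rng(spec.seed, 2)
    ids = [rec.id for rec in proteome]
    pos_pool = _complementary_pairs(spec)
    n_pos = int(round(spec.n_pairs * spec.positive_fraction))
    n_neg = spec.n_pairs - n_pos
    if len(pos_pool) < n_pos:
        raise ValidationError(
            f"only {len(pos_pool)} complementary pairs constructible, "
            f"{n_pos} positives requested"
        )
    pos_idx = rng.choice(len(pos_pool), size=n_pos, replace=False)
    positives = [pos_pool[i] for i in sorted(pos_idx)]

    pos_set = {frozenset(p) for p in pos_pool}
    negatives: List[Tuple[str, str]] = []
    chosen = set()
    while len(negatives) < n_neg:
        a, b = rng.choice(len(ids), size=2, replace=False)
        key = frozenset((ids[a], ids[b]))
        if key in pos_set or key in chosen:
            continue
        chosen.add(key)
        negatives.append((ids[a], ids[b]))

    # randomize orientation so neither motif side is systematically first
    pairs = [
        (a, b, POSITIVE_LABEL) if rng.random() < 0.5 else (b, a, POSITIVE_LABEL)
        for a, b in positives
    ]
    pairs += [(a, b, NEGATIVE_LABEL) for a, b in negatives]
    if spec.noise_rate > 0:
        flips = rng.random(len(pairs)) < spec.noise_rate
        pairs = [
            (a, b, 1 - y if flip else y)
            for (a, b, y), flip in zip(pairs, flips)
        ]
    return PPIDataset(pairs)


def generate_annotations(
    proteome: Sequence[ProteinRecord], spec: FixtureSpec
) -> List[AnnotationRecord]:
    """Draw tissue labels and a known-PPI subset of the ground truth.

    Tissue labels come from a small vocabulary; ``known_ppi_fraction``
    of the true positive pairs are marked as experimentally known, as a
    symmetric partner relation.  Deterministic given the seed.
    """
    rng = _rng(spec.seed, 3)
    tissues = {
        rec.id: TISSUE_VOCABULARY[int(rng.integers(len(TISSUE_VOCABULARY)))]
        for rec in proteome
    }
    pos_pool = _complementary_pairs(spec)
    n_known = int(round(spec.known_ppi_fraction * len(pos_pool)))
    known_idx = set(
        rng.choice(len(pos_pool), size=n_known, replace=False).tolist()
    ) if n_known else set()
    partners: dict = {rec.id: set() for rec in proteome}
    for i in sorted(known_idx):
        a, b = pos_pool[i]
        partners[a].add(b)
        partners[b].add(a)
    return [
        AnnotationRecord(
            protein_id=rec.id,
            function="synthetic benchmark protein",
            tissue_specificity=tissues[rec.id],
            known_partners=partners[rec.id],
        )
        for rec in proteome
    ]


def generate_database(spec: FixtureSpec) -> Tuple[ProteinDatabase, PPIDataset]:
    """Convenience: proteome + annotations as a ProteinDatabase, plus the
    labeled interactome."""
    proteome = generate_proteome(spec)
    annotations = generate_annotations(proteome, spec)
    dataset = generate_interactome(proteome, spec)
    db = ProteinDatabase(proteome, annotations, species="synthetic")
    return db, dataset
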