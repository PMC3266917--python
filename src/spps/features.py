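"""Conjoint-triad featurization of protein sequences.

The 20 standard amino acids are reduced to 7 physicochemical classes
(grouped by dipole moment and side-chain volume).  A sequence is then
described by the spectrum of class *triads*: every window of three
consecutive residues contributes one count to the triad it maps to,
giving a 343-dimensional (7**3) count vector.  Counts are min-max
normalized, ``d = (f - min f) / max f``, to remove the dependence on
sequence length.

The default class table groups {A,G,V}, {I,L,F,P}, {Y,M,T,S}, {H,N,Q,W},
{R,K}, {D,E} and {C} (cysteine alone).  It ships as an editable TSV so
alternative groupings can be configured; a trained model records a
fingerprint of the table it was built with and refuses to mix tables.

Ambiguity codes (B, J, O, U, X, Z) carry no class.  Under the default
``"skip"`` policy, windows containing one are simply not counted; under
``"strict"`` the sequence is rejected.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

import numpy as np

from .exceptions import ValidationError

N_CLASSES = 7
N_TRIADS = N_CLASSES**3  # 343

#: Residue letters tolerated in input but carrying no physicochemical class.
AMBIGUITY_CODES = frozenset("BJOUXZ")

#: Sentinel returned by :func:`classify_residue` for an ambiguity code
#: under the "skip" policy.
UNCLASSIFIED = None


def _load_default_table() -> dict[str, int]:
    ref = resources.files("spps.data").joinpath("residue_classes.tsv")
    with ref.open("r", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        return {row["residue"]: int(row["class"]) for row in reader}


@dataclass(frozen=True)
class ResidueClassMap:
    """Total mapping from the 20 standard residues to class indices 1..7.

    Parameters
    ----------
    mapping
        Residue letter -> class index.  Must cover all 20 standard
        residues and use exactly 7 classes.
    ambiguity_policy
        ``"skip"`` (default): ambiguity codes are unclassified and triad
        windows containing them are dropped.  ``"strict"``: sequences
        containing an ambiguity code are rejected.
    """

    mapping: dict[str, int] = field(default_factory=_load_default_table)
    ambiguity_policy: str = "skip"

    def __post_init__(self) -> None:
        standard = set("ACDEFGHIKLMNPQRSTVWY")
        missing = standard - set(self.mapping)
        if missing:
            raise ValidationError(
                f"residue class map misses standard residues: {sorted(missing)}"
            )
        classes = set(self.mapping.values())
        if classes != set(range(1, N_CLASSES + 1)):
            raise ValidationError(
                f"residue class map must use exactly classes 1..{N_CLASSES}, "
                f"got {sorted(classes)}"
            )
        if self.ambiguity_policy not in ("skip", "strict"):
            raise ValidationError(
                f"unknown ambiguity policy {self.ambiguity_policy!r}"
            )

    @classmethod
    def default(cls) -> "ResidueClassMap":
        return cls()

    @classmethod
    def from_tsv(cls, path, ambiguity_policy: str = "skip") -> "ResidueClassMap":
        """Load a ``residue<TAB>class`` table from *path*."""
        with open(path, encoding="utf-8") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            mapping = {row["residue"]: int(row["class"]) for row in reader}
        return cls(mapping=mapping, ambiguity_policy=ambiguity_policy)

    @property
    def alphabet(self) -> frozenset:
        """Letters accepted in a sequence (mapped residues + ambiguity codes)."""
        return frozenset(self.mapping) | AMBIGUITY_CODES

    def fingerprint(self) -> str:
        """Stable hash of the table and policy, recorded in trained models."""
        payload = ";".join(
            f"{aa}:{cls}" for aa, cls in sorted(self.mapping.items())
        )
        payload += f"|policy={self.ambiguity_policy}|norm=minmax|k=3"
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def classify_residue(aa: str, cmap: Optional[ResidueClassMap] = None):
    """Class index (1..7) of a single residue letter.

    Returns :data:`UNCLASSIFIED` for an ambiguity code under the "skip"
    policy; raises :class:`ValidationError` for any letter outside the
    tolerated alphabet, or for an ambiguity code under "strict".
    """
    cmap = cmap or ResidueClassMap.default()
    try:
        return cmap.mapping[aa]
    except KeyError:
        pass
    if aa in AMBIGUITY_CODES:
        if cmap.ambiguity_policy == "strict":
            raise ValidationError(f"ambiguity code {aa!r} rejected under strict policy")
        return UNCLASSIFIED
    raise ValidationError(f"residue {aa!r} is not in the tolerated alphabet")


@dataclass(frozen=True)
class TriadVector:
    """343-dimensional conjoint-triad descriptor of one sequence.

    ``raw_counts[i]`` counts windows mapping to the triad with flat index
    ``i = 49*(c1-1) + 7*(c2-1) + (c3-1)``; ``values`` are the min-max
    normalized counts.
    """

    values: np.ndarray
    raw_counts: np.ndarray
    source_length: int

    def __post_init__(self) -> None:
        if self.values.shape != (N_TRIADS,) or self.raw_counts.shape != (N_TRIADS,):
            raise ValidationError("triad vectors must have 343 components")


@dataclass(frozen=True)
class PairVector:
    """Concatenated descriptor [vA || vB] of an ordered protein pair."""

    values: np.ndarray
    symmetrized: bool = False

    def __post_init__(self) -> None:
        if self.values.shape != (2 * N_TRIADS,):
            raise ValidationError("pair vectors must have 686 components")


def triad_index(c1: int, c2: int, c3: int) -> int:
    """Flat index of the triad (c1, c2, c3), classes in 1..7."""
    return 49 * (c1 - 1) + 7 * (c2 - 1) + (c3 - 1)


def _class_sequence(sequence: str, cmap: ResidueClassMap) -> list:
    return [classify_residue(aa, cmap) for aa in sequence]


def triad_vector(sequence: str, cmap: Optional[ResidueClassMap] = None) -> TriadVector:
    """Conjoint-triad spectrum of *sequence*.

    Every length-3 window (stride 1) whose residues are all classified
    adds one raw count to its triad; windows touching a skipped
    ambiguity code are dropped.  Normalized values are
    ``(raw - min(raw)) / max(raw)`` when any window was counted, else
    all zero.

    Raises
    ------
    ValidationError
        If the sequence has fewer than 3 classified residues, or
        contains a letter outside the tolerated alphabet.
    """
    cmap = cmap or ResidueClassMap.default()
    classes = _class_sequence(sequence, cmap)
    effective = sum(1 for c in classes if c is not UNCLASSIFIED)
    if effective < 3:
        raise ValidationError(
            f"sequence too short for triad encoding "
            f"(needs >= 3 classified residues, got {effective})"
        )
    raw = np.zeros(N_TRIADS, dtype=np.int64)
    for i in range(len(classes) - 2):
        c1, c2, c3 = classes[i], classes[i + 1], classes[i + 2]
        if UNCLASSIFIED in (c1, c2, c3):
            continue
        raw[triad_index(c1, c2, c3)] += 1
    vmax = raw.max()
    if vmax > 0:
        values = (raw - raw.min()) / vmax
    else:
        values = np.zeros(N_TRIADS)
    return TriadVector(values=values.astype(float), raw_counts=raw,
                       source_length=len(sequence))


def pair_vector(vA: TriadVector, vB: TriadVector) -> PairVector:
    """Ordered concatenation [vA || vB] of two triad vectors.

    Order invariance is handled downstream: prediction averages the
    scores of both orderings when symmetrization is requested.
    """
    return PairVector(values=np.concatenate([vA.values, vB.values]))


def feature_matrix(sequences: Iterable[str],
                   cmap: Optional[ResidueClassMap] = None) -> np.ndarray:
    """Stack normalized triad vectors of *sequences* into an (n, 343) array."""
    cmap = cmap or ResidueClassMap.default()
    return np.vstack([triad_vector(s, cmap).values for s in sequences])
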