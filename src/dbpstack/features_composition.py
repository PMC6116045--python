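"""Sequence-composition and physiochemical descriptors (188-D).

The descriptor concatenates:

* the 20 amino-acid frequencies (alphabetical residue order), and
* for each of eight physiochemical properties whose three classes
  partition the 20-letter alphabet, a 21-value
  composition/transition/distribution (CTD) block:
  3 class frequencies, 3 between-class adjacent-pair transition
  frequencies (divisor L - 1), and 15 distribution values — for each
  class the 1-based positions of its first, 25th-, 50th-, 75th-percentile
  and last occurrence, each divided by L (absent class: five zeros).

Total: 20 + 8 * 21 = 188. An alternative "chunks" distribution variant
(class frequency within five equal sequence chunks) is available through
the ``distribution`` argument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_formats import ALPHABET, STANDARD_RESIDUES, FeatureBlock


@dataclass(frozen=True)
class PropertyPartition:
    """Three disjoint residue classes covering all 20 standard residues."""

    property_name: str
    classes: tuple[frozenset, frozenset, frozenset]

    def __post_init__(self) -> None:
        classes = tuple(frozenset(c) for c in self.classes)
        object.__setattr__(self, "classes", classes)
        if len(classes) != 3:
            raise ValueError(f"{self.property_name}: need exactly 3 classes")
        union = classes[0] | classes[1] | classes[2]
        if union != STANDARD_RESIDUES:
            raise ValueError(
                f"{self.property_name}: classes must cover the 20 residues"
            )
        if sum(len(c) for c in classes) != 20:
            raise ValueError(f"{self.property_name}: classes must be disjoint")


def _partition(name: str, c1: str, c2: str, c3: str) -> PropertyPartition:
    return PropertyPartition(name, (frozenset(c1), frozenset(c2), frozenset(c3)))


#: The eight built-in property partitions, in fixed table order.
PROPERTY_TABLE: tuple[PropertyPartition, ...] = (
    _partition("hydrophobicity", "RKEDQN", "GASTPHY", "CVLIMFW"),
    _partition("vdw_volume", "GASCTPD", "NVEQIL", "MHKFRYW"),
    _partition("polarity", "LIFWCMVY", "PATGS", "HQRKNED"),
    _partition("polarizability", "GASDT", "CPNVEQIL", "KMHFRYW"),
    _partition("charge", "KR", "ANCQGHILMFPSTWYV", "DE"),
    _partition("surface_tension", "GQDNAHR", "KTSEC", "ILMFPWYV"),
    _partition("secondary_structure", "EALMQKRH", "VIYCWFT", "GNPSD"),
    _partition("solvent_accessibility", "ALFCGIVW", "RKQEND", "MPSTHY"),
)

_TRANSITION_PAIRS = ((0, 1), (0, 2), (1, 2))
_QUANTILES = (0.25, 0.5, 0.75)


def amino_acid_composition(seq: str) -> np.ndarray:
    """Residue frequencies in alphabetical order; sums to 1."""
    if not seq:
        raise ValueError("empty sequence")
    length = len(seq)
    return np.array([seq.count(res) / length for res in ALPHABET])


def ctd_block(
    seq: str, part: PropertyPartition, distribution: str = "percentile"
) -> np.ndarray:
    """The 21-value composition/transition/distribution block of one property."""
    if not seq:
        raise ValueError("empty sequence")
    length = len(seq)
    lookup = {res: c for c, members in enumerate(part.classes) for res in members}
    codes = [lookup[res] for res in seq]

    comp = [codes.count(c) / length for c in range(3)]

    counts = dict.fromkeys(_TRANSITION_PAIRS, 0)
    for a, b in zip(codes, codes[1:]):
        if a != b:
            counts[(min(a, b), max(a, b))] += 1
    trans = (
        [counts[pair] / (length - 1) for pair in _TRANSITION_PAIRS]
        if length > 1
        else [0.0, 0.0, 0.0]
    )

    dist: list[float] = []
    if distribution == "percentile":
        for c in range(3):
            positions = [i + 1 for i, code in enumerate(codes) if code == c]
            if not positions:
                dist.extend([0.0] * 5)
                continue
            count = len(positions)
            picks = [1] + [math.ceil(q * count) for q in _QUANTILES] + [count]
            dist.extend(positions[p - 1] / length for p in picks)
    elif distribution == "chunks":
        edges = [round(i * length / 5) for i in range(6)]
        for c in range(3):
            for lo, hi in zip(edges, edges[1:]):
                chunk = codes[lo:hi]
                dist.append(chunk.count(c) / len(chunk) if chunk else 0.0)
    else:
        raise ValueError(f"unknown distribution variant {distribution!r}")
    return np.array(comp + trans + dist)


def _ctd_labels(name: str, distribution: str) -> list[str]:
    labels = [f"{name}.comp{c}" for c in (1, 2, 3)]
    labels += [f"{name}.trans{a + 1}{b + 1}" for a, b in _TRANSITION_PAIRS]
    if distribution == "percentile":
        points = ("first", "q25", "q50", "q75", "last")
        labels += [f"{name}.dist{c}.{p}" for c in (1, 2, 3) for p in points]
    else:
        labels += [f"{name}.dist{c}.chunk{i}" for c in (1, 2, 3) for i in range(1, 6)]
    return labels


def features_188d(seq: str, distribution: str = "percentile") -> FeatureBlock:
    """The full 188-D composition + physiochemical descriptor."""
    values = [amino_acid_composition(seq)]
    labels = [f"aac.{res}" for res in ALPHABET]
    for part in PROPERTY_TABLE:
        values.append(ctd_block(seq, part, distribution))
        labels.extend(_ctd_labels(part.property_name, distribution))
    return FeatureBlock("d188", np.concatenate(values), tuple(labels))
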