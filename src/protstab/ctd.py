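"""CTD (composition / transition / distribution) sequence descriptors.

A protein sequence is recoded through a residue-category grouping (e.g.
hydrophobicity: polar / neutral / hydrophobic) into a category string, from
which three groups of global descriptors are computed:

* **Composition** — the fraction of positions carrying each category.
* **Transition** — for each unordered category pair, the fraction of
  adjacent differing positions whose two letters form that pair.
* **Distribution** — for each category, the positions (as fractions of the
  sequence length, 1-based) at which the first, 25%, 50%, 75% and 100% of
  that category's occurrences are found.  The quantile occurrence index is
  ``ceil(q * n_c)`` clamped to at least 1, so e.g. the 25% point of a
  category with 10 occurrences is its 3rd occurrence.

A three-category grouping yields 3 + 3 + 15 = 21 components.  The
two-category solvent-accessibility grouping is stored compactly as 7
components: composition of the first category (hidden), the single
transition fraction, and the distribution 5-tuple of the first category
(the second category's composition and distribution are redundant or
near-redundant and are not stored).

The biochemical/physicochemical block of the full feature vector
concatenates, in fixed order: hydrophobicity (21), secondary structure
(21), solvent accessibility (7), normalized van der Waals volume (21),
polarity (21), polarizability (21), and the 20 amino-acid composition
fractions — 132 components in total.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

from .records import (
    HYDROPHOBICITY,
    POLARITY,
    POLARIZABILITY,
    SECONDARY_STRUCTURE,
    SOLVENT_ACCESSIBILITY,
    VDW_VOLUME,
    PropertyGrouping,
    ProteinRecord,
    propensity_tracks,
)

#: Residue order of the amino-acid-composition block.
AAC_ORDER = "RKEDQNGASTPHYCVLIMFW"

#: Fixed order of the six CTD groupings in the biochemical block.
BIOCHEMICAL_GROUPINGS = (
    HYDROPHOBICITY,
    SECONDARY_STRUCTURE,
    SOLVENT_ACCESSIBILITY,
    VDW_VOLUME,
    POLARITY,
    POLARIZABILITY,
)

#: Length of the biochemical/physicochemical block (5*21 + 7 + 20).
N_BIOCHEMICAL = 132


class EncodingError(ValueError):
    """Raised when a sequence or track cannot be coded through a grouping."""


def _source_string(record: ProteinRecord, grouping: PropertyGrouping) -> str:
    if grouping.source == "sequence":
        return record.sequence
    track = record.ss_track if grouping.source == "ss" else record.acc_track
    if track is None:
        raise EncodingError(
            f"record {record.id!r}: grouping {grouping.name!r} requires the "
            f"{grouping.source!r} annotation track, which is missing"
        )
    return track


def encode_sequence(record: ProteinRecord, grouping: PropertyGrouping) -> str:
    """Recode a record's sequence (or annotation track) as a category string.

    For sequence-derived groupings each residue is replaced by its category
    label; for track groupings the track letters are their own categories.

    Raises
    ------
    EncodingError
        If a letter is outside the grouping's alphabet (the 1-based offending
        position is named) or a required annotation track is missing.
    """
    source = _source_string(record, grouping)
    assign = grouping.assignment
    try:
        return "".join(assign[c] for c in source)
    except KeyError:
        i, c = next((i, c) for i, c in enumerate(source) if c not in assign)
        raise EncodingError(
            f"record {record.id!r}: letter {c!r} at position {i + 1} is not "
            f"in the alphabet of grouping {grouping.name!r}"
        ) from None


def composition(coded: str, categories: tuple[str, ...]) -> np.ndarray:
    """Per-category fraction of positions, in the grouping's category order."""
    if not coded:
        raise EncodingError("composition of an empty string is undefined")
    n = len(coded)
    return np.array([coded.count(c) / n for c in categories])


def transition(coded: str, categories: tuple[str, ...]) -> np.ndarray:
    """Per-unordered-pair transition fractions.

    Pairs are ordered ``(c1,c2), (c1,c3), (c2,c3)`` following the category
    order.  The denominator is the total number of adjacent differing
    positions; a string with no transitions yields an all-zero block.
    """
    if not coded:
        raise EncodingError("transition of an empty string is undefined")
    pairs = list(combinations(categories, 2))
    counts = dict.fromkeys((frozenset(p) for p in pairs), 0)
    total = 0
    for a, b in zip(coded, coded[1:]):
        if a != b:
            total += 1
            counts[frozenset((a, b))] += 1
    if total == 0:
        return np.zeros(len(pairs))
    return np.array([counts[frozenset(p)] / total for p in pairs])


def distribution(coded: str, categories: tuple[str, ...]) -> np.ndarray:
    """Distribution 5-tuples (first/25%/50%/75%/100% occurrence positions).

    Returns a flat array, category-major: for each category in order, the
    five normalized positions.  A category with no occurrences contributes
    ``(0, 0, 0, 0, 0)``.
    """
    if not coded:
        raise EncodingError("distribution of an empty string is undefined")
    n = len(coded)
    out = np.zeros(5 * len(categories))
    for ci, cat in enumerate(categories):
        positions = [i + 1 for i, c in enumerate(coded) if c == cat]  # 1-based
        if not positions:
            continue
        nc = len(positions)
        for qi, q in enumerate((0.0, 0.25, 0.50, 0.75, 1.0)):
            k = max(1, math.ceil(q * nc))
            out[5 * ci + qi] = positions[k - 1] / n
    return out


def ctd_block(record: ProteinRecord, grouping: PropertyGrouping) -> np.ndarray:
    """Full CTD block for one grouping: C, then T, then D.

    21 components for a three-category grouping; the two-category
    solvent-accessibility layout stores 7 (see module docstring).
    """
    coded = encode_sequence(record, grouping)
    cats = grouping.categories
    comp = composition(coded, cats)
    tran = transition(coded, cats)
    dist = distribution(coded, cats)
    if len(cats) == 2:
        return np.concatenate([comp[:1], tran, dist[:5]])
    return np.concatenate([comp, tran, dist])


def aac_vector(record: ProteinRecord) -> np.ndarray:
    """Amino-acid-composition: the 20 residue occurrence frequencies.

    Ordered per :data:`AAC_ORDER`; sums to 1 for any non-empty sequence.
    """
    if not record.sequence:
        raise EncodingError(f"record {record.id!r}: empty sequence")
    n = len(record.sequence)
    return np.array([record.sequence.count(r) / n for r in AAC_ORDER])


def biochemical_vector(record: ProteinRecord, *, annotate: bool = False) -> np.ndarray:
    """The 132-component biochemical/physicochemical descriptor.

    Requires both annotation tracks.  With ``annotate=True`` a missing track
    is filled by the deterministic propensity stand-in
    (:func:`protstab.records.propensity_tracks`), which only serves to keep
    synthetic pipelines self-contained.
    """
    if annotate and (record.ss_track is None or record.acc_track is None):
        ss, acc = propensity_tracks(record.sequence)
        record = ProteinRecord(
            id=record.id,
            sequence=record.sequence,
            ss_track=record.ss_track or ss,
            acc_track=record.acc_track or acc,
        )
    blocks = [ctd_block(record, g) for g in BIOCHEMICAL_GROUPINGS]
    blocks.append(aac_vector(record))
    vec = np.concatenate(blocks)
    assert vec.shape == (N_BIOCHEMICAL,)
    return vec


def _ctd_names(grouping: PropertyGrouping) -> list[str]:
    cats = grouping.categories
    g = grouping.name
    if len(cats) == 2:
        a, b = cats
        return (
            [f"{g}.C.{a}", f"{g}.T.{a}{b}"]
            + [f"{g}.D.{a}.{q}" for q in ("first", "25", "50", "75", "100")]
        )
    names = [f"{g}.C.{c}" for c in cats]
    names += [f"{g}.T.{a}{b}" for a, b in combinations(cats, 2)]
    for c in cats:
        names += [f"{g}.D.{c}.{q}" for q in ("first", "25", "50", "75", "100")]
    return names


def biochemical_feature_names() -> list[str]:
    """Descriptive names for the 132 biochemical components, in vector order."""
    names: list[str] = []
    for g in BIOCHEMICAL_GROUPINGS:
        names += _ctd_names(g)
    names += [f"aac.{r}" for r in AAC_ORDER]
    return names
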