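"""Protein records and residue-category groupings.

A :class:`ProteinRecord` holds an amino-acid sequence plus optional
per-residue annotation tracks: a secondary-structure string over
``{H, E, C}`` (helix / strand / coil) and a solvent-accessibility string
over ``{H, E}`` (hidden / exposed), each aligned 1:1 with the sequence.

A :class:`PropertyGrouping` partitions an alphabet (the 20 canonical
residues, or an annotation alphabet) into 2-3 ordered categories; coding a
sequence through a grouping is the first step of the CTD
(composition / transition / distribution) descriptor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

log = logging.getLogger(__name__)

#: The 20 canonical amino acids (one-letter codes).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Letters silently removable in sanitize mode (ambiguity codes, selenocysteine,
#: pyrrolysine, stop/gap marks).
NONSTANDARD = set("BZXUJO*-.")


class SequenceError(ValueError):
    """Raised for sequences or tracks that violate the record invariants."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: identifier, sequence and optional annotation tracks.

    Parameters
    ----------
    id
        Unique identifier (first whitespace-delimited FASTA token).
    sequence
        Amino-acid sequence over the 20 canonical one-letter codes.
    ss_track
        Optional secondary-structure string over ``{H, E, C}``, same length
        as ``sequence``.
    acc_track
        Optional solvent-accessibility string over ``{H, E}``
        (hidden / exposed), same length as ``sequence``.
    """

    id: str
    sequence: str
    ss_track: str | None = None
    acc_track: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        bad = next(
            ((i, c) for i, c in enumerate(self.sequence) if c not in AMINO_ACIDS),
            None,
        )
        if bad is not None:
            raise SequenceError(
                f"record {self.id!r}: non-canonical residue {bad[1]!r} "
                f"at position {bad[0] + 1} (use sanitize=True to drop it)"
            )
        for name, track, alphabet in (
            ("ss_track", self.ss_track, "HEC"),
            ("acc_track", self.acc_track, "HE"),
        ):
            if track is None:
                continue
            if len(track) != len(self.sequence):
                raise SequenceError(
                    f"record {self.id!r}: {name} length {len(track)} != "
                    f"sequence length {len(self.sequence)}"
                )
            badt = next(((i, c) for i, c in enumerate(track) if c not in alphabet), None)
            if badt is not None:
                raise SequenceError(
                    f"record {self.id!r}: {name} letter {badt[1]!r} at "
                    f"position {badt[0] + 1} not in {{{','.join(alphabet)}}}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def make_record(
    id: str,
    sequence: str,
    ss_track: str | None = None,
    acc_track: str | None = None,
    *,
    sanitize: bool = False,
) -> ProteinRecord:
    """Build a :class:`ProteinRecord`, optionally dropping nonstandard residues.

    In sanitize mode, letters in :data:`NONSTANDARD` are removed from the
    sequence together with the aligned track positions, with a logged
    warning.  Any other unknown letter is still rejected.
    """
    sequence = sequence.upper()
    if sanitize:
        keep = [i for i, c in enumerate(sequence) if c not in NONSTANDARD]
        if len(keep) != len(sequence):
            log.warning(
                "record %r: dropped %d nonstandard residue(s) during sanitization",
                id,
                len(sequence) - len(keep),
            )
            sequence = "".join(sequence[i] for i in keep)
            if ss_track is not None:
                ss_track = "".join(ss_track[i] for i in keep)
            if acc_track is not None:
                acc_track = "".join(acc_track[i] for i in keep)
    return ProteinRecord(id=id, sequence=sequence, ss_track=ss_track, acc_track=acc_track)


@dataclass(frozen=True)
class PropertyGrouping:
    """A named partition of an alphabet into 2-3 ordered categories.

    ``source`` names where the letters come from: ``"sequence"`` for the
    residue alphabet, ``"ss"`` / ``"acc"`` for the annotation tracks.
    """

    name: str
    categories: tuple[str, ...]
    assignment: dict[str, str] = field(hash=False)
    source: str = "sequence"

    def __post_init__(self) -> None:
        if not 2 <= len(self.categories) <= 3:
            raise ValueError(f"grouping {self.name!r}: need 2 or 3 categories")
        used = set(self.assignment.values())
        if used != set(self.categories):
            raise ValueError(
                f"grouping {self.name!r}: categories {set(self.categories) - used} unused"
            )
        if self.source == "sequence" and set(self.assignment) != set(AMINO_ACIDS):
            raise ValueError(
                f"grouping {self.name!r}: assignment must cover exactly the 20 residues"
            )

    @property
    def alphabet(self) -> set[str]:
        return set(self.assignment)


def _grouping(name: str, cats: dict[str, str], source: str = "sequence") -> PropertyGrouping:
    assignment = {letter: cat for cat, letters in cats.items() for letter in letters}
    return PropertyGrouping(
        name=name, categories=tuple(cats), assignment=assignment, source=source
    )


# Residue groupings.  Category order fixes the layout of the stored feature
# vector (composition order, transition-pair order, distribution order).
HYDROPHOBICITY = _grouping(
    "hydrophobicity",
    {"P": "RKEDQN", "N": "GASTPHY", "H": "CVLIMFW"},  # polar / neutral / hydrophobic
)
VDW_VOLUME = _grouping(
    "van_der_waals_volume",
    {"H": "GASCTDP", "E": "NVEQIL", "C": "MHKFRYW"},  # 0-2.78 / 2.95-4.0 / 4.43-8.08
)
POLARITY = _grouping(
    "polarity",
    {"H": "LIFWCMVY", "E": "GATPS", "C": "HQRKNED"},  # 4.9-6.2 / 8.0-9.2 / 10.4-13.0
)
POLARIZABILITY = _grouping(
    "polarizability",
    {"H": "GASDT", "E": "CPNVEQIL", "C": "KMHFRYW"},  # 0-0.108 / 0.128-0.186 / 0.219-0.409
)

# Annotation-track groupings: the coded string is the track itself.
SECONDARY_STRUCTURE = _grouping(
    "secondary_structure", {"H": "H", "E": "E", "C": "C"}, source="ss"
)
SOLVENT_ACCESSIBILITY = _grouping(
    "solvent_accessibility", {"H": "H", "E": "E"}, source="acc"  # hidden / exposed
)

#: All built-in groupings keyed by name.
GROUPINGS: dict[str, PropertyGrouping] = {
    g.name: g
    for g in (
        HYDROPHOBICITY,
        SECONDARY_STRUCTURE,
        SOLVENT_ACCESSIBILITY,
        VDW_VOLUME,
        POLARITY,
        POLARIZABILITY,
    )
}


# Crude per-residue propensities used only by the optional stand-in annotator:
# most-likely secondary-structure state per residue (helix/strand formers vs
# breakers) and buried-vs-exposed by hydrophobicity.  This is a synthetic
# deterministic fallback so the pipeline is self-contained without structure
# predictors; it is NOT equivalent to a trained predictor.
_SS_PROPENSITY = {
    **{r: "H" for r in "AELMQKRH"},
    **{r: "E" for r in "VIYCWFT"},
    **{r: "C" for r in "GNPSD"},
}


def propensity_tracks(sequence: str) -> tuple[str, str]:
    """Deterministic stand-in (ss_track, acc_track) from sequence alone.

    Secondary structure uses a per-residue most-likely-state table;
    accessibility marks hydrophobic residues (C,V,L,I,M,F,W) as hidden.
    Purely a self-containment device for synthetic pipelines.
    """
    ss = "".join(_SS_PROPENSITY[c] for c in sequence)
    acc = "".join("H" if HYDROPHOBICITY.assignment[c] == "H" else "E" for c in sequence)
    return ss, acc
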