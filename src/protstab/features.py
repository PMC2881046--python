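"""Assembly of the 376-component protein feature space.

Each protein is represented by a fixed-order vector:

======================  =========  ==========================================
block                   positions  content
======================  =========  ==========================================
biochemical             V1-V132    CTD descriptors + amino-acid composition
length                  V133       sequence length (residues)
subcellular location    V134-V155  22 binary location flags (multi-label)
KEGG enrichment         V156-V375  220 pathway enrichment scores
protein complexes       V376       number of complexes the protein joins
======================  =========  ==========================================

The KEGG enrichment score of a protein is ``-log10`` of the upper-tail
hypergeometric p-value for the overlap between the protein's network
neighborhood (the protein plus its interaction neighbors) and one pathway's
member set; larger means stronger overrepresentation.

Before classification every component is standardized to zero mean and
unit standard deviation using statistics of the *training* samples only;
constant components map to zero.  Half-life class labels derive from the
protein stability index (PSI): short (PSI<2), medium (2<=PSI<3),
long (3<=PSI<4), extra-long (PSI>=4).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from .records import ProteinRecord

N_FEATURES = 376
N_LOCATIONS = 22
N_PATHWAYS = 220

#: Feature names V1..V376 (the conventional index naming).
FEATURE_NAMES = [f"V{i}" for i in range(1, N_FEATURES + 1)]

#: Name -> 0-based position in the feature vector.
INDEX_MAP = {name: i for i, name in enumerate(FEATURE_NAMES)}

# 0-based slices of the blocks.
BIOCHEMICAL_SLICE = slice(0, 132)
LENGTH_INDEX = 132
LOCATION_SLICE = slice(133, 155)
KEGG_SLICE = slice(155, 375)
COMPLEX_INDEX = 375


class HalfLife(enum.IntEnum):
    """Four half-life classes, ordered by increasing stability."""

    SHORT = 0
    MEDIUM = 1
    LONG = 2
    EXTRA_LONG = 3

    @property
    def label(self) -> str:
        return self.name.lower()

    @property
    def coarse(self) -> str:
        """Binary stage-1 label: short/medium vs long/extra-long."""
        return "short_medium" if self <= HalfLife.MEDIUM else "long_extra_long"


def psi_to_class(psi: float) -> HalfLife:
    """Map a protein stability index to its half-life class.

    short: PSI < 2; medium: 2 <= PSI < 3; long: 3 <= PSI < 4;
    extra-long: PSI >= 4.
    """
    if not math.isfinite(psi):
        raise ValueError(f"PSI must be finite, got {psi!r}")
    if psi < 2:
        return HalfLife.SHORT
    if psi < 3:
        return HalfLife.MEDIUM
    if psi < 4:
        return HalfLife.LONG
    return HalfLife.EXTRA_LONG


MIN_LENGTH = 50
MAX_LENGTH = 2700


def length_filter(
    records: list[ProteinRecord],
    min_length: int = MIN_LENGTH,
    max_length: int = MAX_LENGTH,
) -> tuple[list[ProteinRecord], list[tuple[str, int, str]]]:
    """Drop sequences shorter than 50 or longer than 2700 residues.

    Bounds are inclusive (a 50-mer and a 2700-mer are kept).  Returns the
    retained records and an exclusion log of ``(id, length, reason)``.
    """
    kept: list[ProteinRecord] = []
    excluded: list[tuple[str, int, str]] = []
    for rec in records:
        n = len(rec)
        if n < min_length:
            excluded.append((rec.id, n, f"shorter than {min_length}"))
        elif n > max_length:
            excluded.append((rec.id, n, f"longer than {max_length}"))
        else:
            kept.append(rec)
    return kept, excluded


@dataclass
class PathwayUniverse:
    """A gene universe with pathway member sets and per-protein neighbor sets.

    ``pathways`` is an *ordered* mapping pathway id -> member set (220 for
    the full feature space); ``neighbors`` maps protein id -> its network
    neighborhood (the protein itself plus its interaction partners).
    """

    universe: frozenset[str]
    pathways: dict[str, frozenset[str]]
    neighbors: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, members in self.pathways.items():
            if not members <= self.universe:
                raise ValueError(f"pathway {pid!r} has members outside the universe")

    def scores_for(self, protein_id: str) -> np.ndarray:
        """Enrichment score vector over all pathways, in pathway order.

        Vectorized over pathways; agrees with per-pathway calls to
        :func:`kegg_enrichment_score`.
        """
        neigh = self.neighbors.get(protein_id, frozenset())
        if not neigh:
            return np.zeros(len(self.pathways))
        members = list(self.pathways.values())
        overlap = np.array([len(neigh & m) for m in members])
        sizes = np.array([len(m) for m in members])
        p = hypergeom.sf(overlap - 1, len(self.universe), sizes, len(neigh))
        p = np.clip(p, np.nextafter(0, 1), 1.0)
        return -np.log10(p)


def kegg_enrichment_score(
    neighbors: frozenset[str] | set[str],
    pathway: frozenset[str] | set[str],
    universe_size: int,
) -> float:
    """Pathway-overrepresentation score of a protein neighborhood.

    ``-log10 P(X >= k)`` under a hypergeometric null: drawing
    ``|neighbors|`` genes from a universe of ``universe_size`` containing
    ``|pathway|`` pathway members, where ``k`` is the observed overlap.
    An empty neighborhood scores 0 for every pathway.
    """
    if len(pathway) > universe_size:
        raise ValueError("pathway larger than the universe")
    if not neighbors:
        return 0.0
    if len(neighbors) > universe_size:
        raise ValueError("neighbor set larger than the universe")
    k = len(set(neighbors) & set(pathway))
    # sf(k-1) = P(X >= k); k = 0 gives p = 1, score 0.
    p = hypergeom.sf(k - 1, universe_size, len(pathway), len(neighbors))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return float(-np.log10(p))


def assemble_feature_vector(
    record: ProteinRecord,
    biochemical: np.ndarray,
    location_flags: np.ndarray,
    kegg_scores: np.ndarray,
    complex_count: int,
) -> np.ndarray:
    """Concatenate the blocks into the fixed-order 376-component vector."""
    biochemical = np.asarray(biochemical, dtype=float)
    location_flags = np.asarray(location_flags, dtype=float)
    kegg_scores = np.asarray(kegg_scores, dtype=float)
    if biochemical.shape != (132,):
        raise ValueError(f"biochemical block must have 132 components, got {biochemical.shape}")
    if location_flags.shape != (N_LOCATIONS,):
        raise ValueError(
            f"location block must have {N_LOCATIONS} components, got {location_flags.shape}"
        )
    if not np.isin(location_flags, (0.0, 1.0)).all():
        raise ValueError("location flags must be binary")
    if kegg_scores.shape != (N_PATHWAYS,):
        raise ValueError(f"KEGG block must have {N_PATHWAYS} components, got {kegg_scores.shape}")
    if (kegg_scores < 0).any():
        raise ValueError("KEGG enrichment scores must be nonnegative")
    if complex_count < 0 or int(complex_count) != complex_count:
        raise ValueError(f"complex count must be a nonnegative integer, got {complex_count!r}")
    vec = np.concatenate(
        [
            biochemical,
            [float(len(record))],
            location_flags,
            kegg_scores,
            [float(complex_count)],
        ]
    )
    assert vec.shape == (N_FEATURES,)
    return vec


@dataclass
class StandardizationParams:
    """Per-component mean and standard deviation fitted on a training matrix."""

    mean: np.ndarray
    sd: np.ndarray

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Standardize a vector or matrix with the fitted training statistics.

        Components with zero training variance map to zero.
        """
        x = np.asarray(x, dtype=float)
        safe_sd = np.where(self.sd > 0, self.sd, 1.0)
        z = (x - self.mean) / safe_sd
        return np.where(self.sd > 0, z, 0.0)


def standardize(matrix: np.ndarray) -> tuple[np.ndarray, StandardizationParams]:
    """Zero-mean / unit-sd conversion of each column of a training matrix.

    Uses population standard deviation, which makes the conversion
    idempotent: standardizing an already-standardized matrix returns it
    unchanged.  Constant columns become all-zero.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError("standardization needs a matrix with at least 2 rows")
    params = StandardizationParams(mean=matrix.mean(axis=0), sd=matrix.std(axis=0, ddof=0))
    return params.apply(matrix), params
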