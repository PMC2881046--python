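"""Self-contained synthetic benchmarks with planted half-life signal.

Real benchmarks for this predictor require sequences plus several external
annotation layers (structure predictors, interaction networks, pathway
memberships, complex catalogues).  This module generates all of them
jointly so that every pipeline stage — encoding, enrichment scoring,
feature assembly, mRMR, IFS, hierarchical prediction — runs end to end
with no downloads, with class signal planted where the field expects it:

* sequences are drawn from per-class residue multinomials whose
  hydrophobic-group mass shifts monotonically with the class;
* annotation tracks are first-order Markov chains with mean run length ~5,
  mimicking secondary-structure segments;
* a synthetic gene universe carries 220 pathways; each class's proteins
  preferentially pick network neighbors from one signature pathway, so
  enrichment scores separate classes;
* subcellular-location flag probabilities and complex counts drift with
  the class; PSI values are drawn inside each class's defining bin so
  labels and PSI are consistent by construction.

Default class proportions follow the benchmark composition
223 : 446 : 706 : 496 (short : medium : long : extra-long).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .features import N_LOCATIONS, N_PATHWAYS, HalfLife, PathwayUniverse
from .records import AMINO_ACIDS, HYDROPHOBICITY, ProteinRecord

#: Benchmark class composition (short, medium, long, extra-long).
DEFAULT_CLASS_COUNTS = (223, 446, 706, 496)

_PSI_BINS = {  # sampling ranges inside each class's PSI bin
    HalfLife.SHORT: (0.5, 2.0),
    HalfLife.MEDIUM: (2.0, 3.0),
    HalfLife.LONG: (3.0, 4.0),
    HalfLife.EXTRA_LONG: (4.0, 5.5),
}

_GROUP_RESIDUES = {
    c: [r for r, g in HYDROPHOBICITY.assignment.items() if g == c] for c in "PNH"
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generator; the seed fixes all randomness.

    ``hydrophobic_shift`` is the composition effect: the hydrophobic-group
    probability moves by up to +/- this amount across the four classes.
    ``location_effect`` similarly tilts the first four location flags;
    ``kegg_effect`` in [0, 1] is the fraction of neighbors drawn from the
    class's signature pathway; ``complex_effect`` is the per-class increment
    of the mean complex count.
    """

    n: int = 200
    class_proportions: tuple[float, float, float, float] = DEFAULT_CLASS_COUNTS
    length_range: tuple[int, int] = (50, 2700)
    hydrophobic_shift: float = 0.10
    location_effect: float = 0.20
    kegg_effect: float = 0.5
    complex_effect: float = 1.0
    universe_size: int = 2000
    n_pathways: int = N_PATHWAYS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError("need n >= 4 (one protein per class)")
        props = np.asarray(self.class_proportions, dtype=float)
        if len(props) != 4 or (props < 0).any() or props.sum() <= 0:
            raise ValueError("class_proportions must be 4 nonnegative weights")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid length range {self.length_range}")
        if not 0 <= self.hydrophobic_shift < 0.25:
            raise ValueError("hydrophobic_shift must be in [0, 0.25)")
        if not 0 <= self.kegg_effect <= 1:
            raise ValueError("kegg_effect must be in [0, 1]")

    def class_counts(self) -> np.ndarray:
        """Integer class sizes by largest-remainder apportionment of n."""
        props = np.asarray(self.class_proportions, dtype=float)
        props = props / props.sum()
        raw = props * self.n
        counts = np.floor(raw).astype(int)
        rem = self.n - counts.sum()
        counts[np.argsort(-(raw - counts))[:rem]] += 1
        # every class must be populated for the hierarchical stages
        while (counts == 0).any():
            counts[np.argmin(counts)] += 1
            counts[np.argmax(counts)] -= 1
        return counts


@dataclass
class SyntheticBenchmark:
    """Generated records plus all metadata the pipeline consumes."""

    config: SyntheticConfig
    records: list[ProteinRecord]
    classes: np.ndarray  # (n,) HalfLife integer values
    psi: np.ndarray
    location_flags: np.ndarray  # (n, 22) in {0,1}
    complex_counts: np.ndarray  # (n,) nonnegative ints
    universe: PathwayUniverse
    kegg_scores: np.ndarray = field(init=False)  # (n, 220)

    def __post_init__(self) -> None:
        self.kegg_scores = np.vstack(
            [self.universe.scores_for(r.id) for r in self.records]
        )

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]


def _class_residue_probs(cls: int, shift: float) -> np.ndarray:
    """Residue distribution for one class: hydrophobic mass tilted by class."""
    group_p = {"P": 0.30, "N": 0.35, "H": 0.35}
    delta = shift * (cls - 1.5) / 1.5  # -shift .. +shift across classes
    group_p["H"] += delta
    group_p["P"] -= delta
    probs = np.zeros(len(AMINO_ACIDS))
    for gi, g in enumerate("PNH"):
        members = _GROUP_RESIDUES[g]
        for r in members:
            probs[AMINO_ACIDS.index(r)] = group_p[g] / len(members)
    return probs / probs.sum()


def _markov_track(rng: np.random.Generator, n: int, letters: str,
                  base: np.ndarray, stay: float = 0.8) -> str:
    """Segmental annotation track: geometric run lengths, mean 1/(1-stay)."""
    out = [letters[rng.choice(len(letters), p=base)]]
    for _ in range(n - 1):
        if rng.random() < stay:
            out.append(out[-1])
        else:
            out.append(letters[rng.choice(len(letters), p=base)])
    return "".join(out)


def generate_pathway_universe(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> PathwayUniverse:
    """Synthetic gene universe with ``n_pathways`` random pathways.

    Pathway sizes are uniform in [10, 100] (capped by the universe).  The
    first four pathways serve as per-class signature pathways when neighbor
    sets are planted.
    """
    rng = rng or np.random.default_rng(config.seed)
    genes = [f"g{i:05d}" for i in range(config.universe_size)]
    universe = frozenset(genes)
    pathways: dict[str, frozenset[str]] = {}
    for p in range(config.n_pathways):
        size = int(rng.integers(10, min(101, config.universe_size + 1)))
        members = rng.choice(config.universe_size, size=size, replace=False)
        pathways[f"path{p:03d}"] = frozenset(genes[i] for i in members)
    return PathwayUniverse(universe=universe, pathways=pathways)


def generate_benchmark(config: SyntheticConfig) -> SyntheticBenchmark:
    """Generate a labeled benchmark; deterministic given the config seed."""
    rng = np.random.default_rng(config.seed)
    counts = config.class_counts()
    classes = np.repeat(np.arange(4), counts)

    universe = generate_pathway_universe(config, rng)
    genes = sorted(universe.universe)
    pathway_lists = [sorted(m) for m in universe.pathways.values()]

    lo, hi = config.length_range
    # log-uniform lengths: most proteins a few hundred residues long
    lengths = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n)).astype(int)
    lengths = np.clip(lengths, lo, hi)

    ss_base = np.array([0.4, 0.25, 0.35])  # helix / strand / coil
    acc_base = np.array([0.45, 0.55])  # hidden / exposed

    records: list[ProteinRecord] = []
    psi = np.empty(config.n)
    flags = np.zeros((config.n, N_LOCATIONS), dtype=int)
    complexes = np.empty(config.n, dtype=int)
    neighbors: dict[str, frozenset[str]] = {}
    for i, cls in enumerate(classes):
        pid = f"syn{i:05d}"
        probs = _class_residue_probs(int(cls), config.hydrophobic_shift)
        seq = "".join(
            AMINO_ACIDS[j] for j in rng.choice(len(AMINO_ACIDS), size=lengths[i], p=probs)
        )
        ss = _markov_track(rng, lengths[i], "HEC", ss_base)
        acc = _markov_track(rng, lengths[i], "HE", acc_base)
        records.append(ProteinRecord(id=pid, sequence=seq, ss_track=ss, acc_track=acc))

        psi[i] = rng.uniform(*_PSI_BINS[HalfLife(int(cls))])

        p_flag = np.full(N_LOCATIONS, 0.15)
        delta = config.location_effect * (cls - 1.5) / 1.5
        p_flag[:4] = np.clip(p_flag[:4] + delta, 0.01, 0.99)
        flags[i] = rng.random(N_LOCATIONS) < p_flag

        complexes[i] = rng.poisson(1.0 + config.complex_effect * cls)

        n_neigh = int(rng.poisson(20)) + 1
        signature = pathway_lists[int(cls)]
        n_sig = int(round(config.kegg_effect * n_neigh))
        n_sig = min(n_sig, len(signature))
        sig = rng.choice(len(signature), size=n_sig, replace=False)
        rest = rng.choice(len(genes), size=n_neigh - n_sig, replace=False)
        neighbors[pid] = frozenset(
            [signature[j] for j in sig] + [genes[j] for j in rest]
        )

    universe.neighbors = neighbors
    return SyntheticBenchmark(
        config=config,
        records=records,
        classes=classes,
        psi=psi,
        location_flags=flags,
        complex_counts=complexes,
        universe=universe,
    )


def planted_feature_matrix(
    n: int = 500,
    m: int = 50,
    n_informative: int = 5,
    effect: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Feature-level benchmark: Gaussian noise with class-shifted lead features.

    Balanced binary labels; features ``0..n_informative-1`` have their
    class-1 mean raised by ``effect`` standard deviations, the rest are pure
    noise.  Used to test signal recovery by mRMR and IFS.
    """
    if not 0 < n_informative <= m:
        raise ValueError("need 0 < n_informative <= m")
    rng = np.random.default_rng(seed)
    y = np.zeros(n, dtype=int)
    y[n // 2:] = 1
    X = rng.standard_normal((n, m))
    X[:, :n_informative] += effect * y[:, None]
    return X, y


# ---------------------------------------------------------------------------
# File emission (the formats the CLI pipeline consumes)

def write_benchmark(bench: SyntheticBenchmark, out_dir: str | Path) -> dict[str, Path]:
    """Write FASTA, track TSV, metadata TSV, label TSV and a manifest."""
    from . import io as pio  # local import to avoid a cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "sequences.fasta",
        "tracks": out / "tracks.tsv",
        "metadata": out / "metadata.tsv",
        "labels": out / "labels.tsv",
        "manifest": out / "manifest.json",
    }
    pio.write_fasta(bench.records, paths["fasta"])
    pio.write_tracks(bench.records, paths["tracks"])
    pio.write_metadata(
        bench.ids,
        bench.psi,
        bench.location_flags,
        bench.kegg_scores,
        bench.complex_counts,
        paths["metadata"],
    )
    pio.write_labels(bench.ids, bench.classes, paths["labels"])
    manifest = {"config": asdict(bench.config), "n": bench.config.n}
    paths["manifest"].write_text(json.dumps(manifest, indent=2) + "\n")
    return paths
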