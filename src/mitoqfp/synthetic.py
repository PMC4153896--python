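"""Synthetic circular genomes and deletion sets.

The generators emulate the study conditions the statistics are designed for:
a circular genome with strand-asymmetric base composition (the deposited
strand G-poor, so its complement is the G-rich "heavy" strand), planted
motif sequences at known positions, composition-preserving shuffles, and
deletion sets whose breakpoints are either uniform on the circle (the null)
or displaced from motif midpoints by a stated distribution (the
alternative the association tests should detect).

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .breakpoints import DeletionRecord
from .genome import CircularGenome, canonical_position
from .motifs import MotifSet, RepeatPair

#: mtDNA-like deposited-strand composition: G-poor (the rCRS-deposited light
#: strand frame), configurable rather than a fixed fact.
MTDNA_LIKE_COMPOSITION = {"A": 0.309, "C": 0.313, "G": 0.131, "T": 0.247}
UNIFORM_COMPOSITION = {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}


@dataclass(frozen=True)
class GenomeSpec:
    L: int
    composition: dict = field(default_factory=lambda: dict(MTDNA_LIKE_COMPOSITION))
    seed: int = 0
    id: str = "synthetic"

    def probabilities(self) -> np.ndarray:
        p = np.array([self.composition.get(b, 0.0) for b in "ACGT"], dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"composition must be non-negative and sum to 1, got {self.composition}"
            )
        return p


@dataclass(frozen=True)
class Displacement:
    """Breakpoint displacement distribution: 'constant' (value = d),
    'uniform' on [0, d_max], or 'geometric' with success probability p
    (support 0, 1, 2, ...).  The sign is uniform +/-."""

    kind: str = "uniform"
    param: float = 5.0

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "constant":
            mag = np.full(n, float(self.param))
        elif self.kind == "uniform":
            mag = rng.uniform(0.0, float(self.param), size=n)
        elif self.kind == "geometric":
            mag = rng.geometric(float(self.param), size=n) - 1.0
        else:
            raise ValueError(f"unknown displacement kind {self.kind!r}")
        sign = rng.choice([-1.0, 1.0], size=n)
        return sign * mag


@dataclass(frozen=True)
class DeletionSimSpec:
    n: int
    mode: str = "uniform"  # uniform | motif_associated | repeat_mediated
    motif_set: MotifSet | None = None
    repeat_pairs: tuple[RepeatPair, ...] | None = None
    displacement: Displacement = Displacement()
    seed: int = 0


def generate_genome(spec: GenomeSpec) -> CircularGenome:
    """i.i.d. random circular genome with the spec's base composition."""
    if spec.L < 1:
        raise ValueError("L must be >= 1")
    rng = np.random.default_rng(spec.seed)
    p = spec.probabilities()
    bases = rng.choice(np.array(list("ACGT")), size=spec.L, p=p)
    return CircularGenome(id=spec.id, sequence="".join(bases))


def shuffle_genome(genome: CircularGenome, seed: int) -> CircularGenome:
    """Uniformly random permutation of the base multiset; composition is
    conserved exactly."""
    rng = np.random.default_rng(seed)
    arr = np.array(list(genome.sequence))
    rng.shuffle(arr)
    return CircularGenome(id=f"{genome.id}_shuffled", sequence="".join(arr))


def plant_sequence(genome: CircularGenome, seq: str,
                   position: float) -> CircularGenome:
    """Overwrite bases circularly with ``seq`` starting at 1-based
    ``position``; wraps the origin if needed."""
    return plant_sequences(genome, [(seq, position)])


def plant_sequences(genome: CircularGenome,
                    plants: Sequence[tuple[str, float]]) -> CircularGenome:
    """Plant several sequences; overlapping plants demanding different bases
    at the same position are rejected."""
    L = len(genome)
    arr = list(genome.sequence)
    written: dict[int, str] = {}
    for seq, position in plants:
        seq = seq.upper()
        if len(seq) > L:
            raise ValueError("planted sequence longer than genome")
        start = int(round(position)) - 1
        for off, base in enumerate(seq):
            i = (start + off) % L
            if i in written and written[i] != base:
                raise ValueError(
                    f"conflicting plants at position {i + 1}: "
                    f"{written[i]!r} vs {base!r}"
                )
            written[i] = base
            arr[i] = base
    return CircularGenome(id=genome.id, sequence="".join(arr))


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def simulate_deletions(spec: DeletionSimSpec, L: int) -> list[DeletionRecord]:
    """Simulate deletion records under the spec's breakpoint model.

    uniform: both breakpoints uniform without replacement, ordered so
    bp5 < bp3.  motif_associated: each breakpoint is a uniformly chosen motif
    midpoint plus a signed displacement, rounded half-away-from-zero and
    canonicalized.  repeat_mediated: the two ends of each record sit at the
    unit midpoints of a uniformly chosen repeat pair (plus displacement).
    """
    if spec.n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(spec.seed)
    records: list[DeletionRecord] = []
    if spec.mode == "uniform":
        for i in range(spec.n):
            a, b = rng.choice(L, size=2, replace=False) + 1
            lo, hi = (int(a), int(b)) if a < b else (int(b), int(a))
            records.append(DeletionRecord(id=f"u{i}", bp5=lo, bp3=hi))
    elif spec.mode == "motif_associated":
        if spec.motif_set is None or len(spec.motif_set) == 0:
            raise ValueError("motif_associated mode requires a nonempty motif_set")
        mids = np.asarray(spec.motif_set.midpoints, dtype=float)
        i = 0
        while len(records) < spec.n:
            picks = mids[rng.integers(0, len(mids), size=2)]
            disp = spec.displacement.sample(rng, 2)
            pos = _round_half_away(picks - 1.0 + disp) % L + 1
            bp5, bp3 = int(pos[0]), int(pos[1])
            if bp5 == bp3:
                continue
            if bp5 > bp3:
                bp5, bp3 = bp3, bp5
            records.append(DeletionRecord(id=f"m{i}", bp5=bp5, bp3=bp3))
            i += 1
    elif spec.mode == "repeat_mediated":
        if not spec.repeat_pairs:
            raise ValueError("repeat_mediated mode requires repeat_pairs")
        pairs = list(spec.repeat_pairs)
        i = 0
        while len(records) < spec.n:
            pr = pairs[rng.integers(0, len(pairs))]
            disp = spec.displacement.sample(rng, 2)
            p5 = int(_round_half_away(np.array([pr.unit5.midpoint - 1.0 + disp[0]]))[0]) % L + 1
            p3 = int(_round_half_away(np.array([pr.unit3.midpoint - 1.0 + disp[1]]))[0]) % L + 1
            if p5 == p3:
                continue
            records.append(DeletionRecord(id=f"r{i}", bp5=p5, bp3=p3))
            i += 1
    else:
        raise ValueError(f"unknown simulation mode {spec.mode!r}")
    return records
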