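import itertools

import numpy as np
import pytest

from mitoqfp import CircularGenome, plant_sequence
from mitoqfp.genome import circular_distance, rotate_positions

# Representative 2G QFP oligos and their G->A mutated controls used in the
# in-vitro folding panel; each test oligo carries four G-runs of length >= 2,
# each control has at most three.
OLIGO_PANEL = {
    "A": "GGATGGGGTGGGGAGG",
    "B": "GGGGGATGCGGGGG",
    "C": "GGAGGGTGGATGG",
}
CONTROL_PANEL = {
    "Ac": "AGATGGAGTGGAGAGG",
    "Bc": "AGGAGATGCAGGAG",
    "Cc": "AGAGGGTAGATGG",
}


@pytest.fixture
def oligo_panel():
    return dict(OLIGO_PANEL)


@pytest.fixture
def control_panel():
    return dict(CONTROL_PANEL)


def planted_genome(seq: str, position: int = 50, L: int = 200,
                   background: str = "A") -> CircularGenome:
    return plant_sequence(CircularGenome("planted", background * L), seq, position)


# ---------------------------------------------------------------------------
# independent brute-force oracles (deliberately naive)
# ---------------------------------------------------------------------------

def brute_min_distance(a, point_set, L):
    return min(circular_distance(a, b, L) for b in point_set)


def brute_mean_min_distance(from_set, to_set, L):
    return float(np.mean([brute_min_distance(a, to_set, L) for a in from_set]))


def brute_mda(from_set, to_set, L):
    """Exhaustive rotation null: (actual, control list for r=1..L-1, p)."""
    actual = brute_mean_min_distance(from_set, to_set, L)
    controls = [
        brute_mean_min_distance(from_set, rotate_positions(to_set, r, L), L)
        for r in range(1, L)
    ]
    p = sum(c <= actual + 1e-12 for c in controls) / (L - 1)
    return actual, controls, p


def brute_chance_probability(to_set, D, L):
    return sum(
        brute_min_distance(x, to_set, L) <= D + 1e-12 for x in range(1, L + 1)
    ) / L


def brute_qfp_candidates(seq, min_run, max_span=33, min_loop=1):
    """Exhaustive 4-tract tuple enumeration on a linear sequence; returns
    {(first_start, last_end): best min tract length} in 1-based coordinates."""
    n = len(seq)
    subtracts = []
    for s in range(n):
        ln = 0
        while s + ln < n and seq[s + ln] == "G":
            ln += 1
            if ln >= min_run:
                subtracts.append((s, s + ln - 1, ln))
    best = {}
    for combo in itertools.combinations(subtracts, 4):
        combo = sorted(combo)
        if not all(combo[i][1] + min_loop < combo[i + 1][0] for i in range(3)):
            continue
        if combo[3][1] - combo[0][0] + 1 > max_span:
            continue
        key = (combo[0][0] + 1, combo[3][1] + 1)
        v = min(c[2] for c in combo)
        best[key] = max(best.get(key, 0), v)
    return best


def brute_circular_qfp_candidates(seq, min_run, max_span=33, min_loop=1):
    """Circular variant: enumerate on the extended string, keep starts within
    one period."""
    L = len(seq)
    span = min(max_span, L)
    ext = seq + seq[: span - 1]
    return {
        (s, e): v
        for (s, e), v in brute_qfp_candidates(ext, min_run, span, min_loop).items()
        if s <= L
    }


def brute_repeat_qualifying(seq, k, repeat_class):
    """All-pairs comparison: 1-based circular window starts whose transformed
    word occurs at another start."""
    from mitoqfp.motifs import repeat_transform

    L = len(seq)
    d = seq + seq[: k - 1]
    words = [d[i : i + k] for i in range(L)]
    qual = set()
    for i in range(L):
        if "N" in words[i]:
            continue
        t = repeat_transform(words[i], repeat_class)
        for j in range(L):
            if i != j and "N" not in words[j] and t == words[j]:
                qual.add(i + 1)
                break
    return qual
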