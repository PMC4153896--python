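"""Proximity statistics between motif midpoints and deletion breakpoints on a
circular genome.

Three procedures share one null model — rigid rotation of a feature set
around the circle in 1-nt increments (the identity rotation excluded, giving
L - 1 distribution-matched controls):

* **Minimal Distance Analysis (MDA)** — compares the mean nearest-neighbour
  circular distance from one point set to another against the same quantity
  under every rotation of the target set.  The p-value is the fraction of
  rotations whose mean is smaller than or equal to the actual mean (ties count
  against the alternative, so reported p-values are conservative).  The
  analysis is asymmetric and is run reciprocally: breakpoints-to-motifs and
  motifs-to-breakpoints answer different questions when the set sizes differ.

* **Individual enrichment** — for each distance threshold D, the number K of
  points within D of the target set is compared with a binomial
  Binom(N, P) null, where the chance probability P is the fraction of genome
  positions within D of the target set (exactly the rotation-averaged
  probability for a single point).

* **Both-ends proximity** — a deletion counts as "close" when both its 5' and
  3' breakpoints are within D (default 10 nt) of the motif set, or, in the
  paired-repeat variant, when some repeat pair has its 5' unit within D of
  the 5' breakpoint and its 3' unit within D of the 3' breakpoint.

All distances use motif midpoints (possibly half-integers); internally every
position is mapped onto a half-unit integer grid of size 2L so that means and
tie comparisons are exact integer arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .breakpoints import DeletionRecord, breakpoint_arrays
from .motifs import RepeatPair

BP_TO_MOTIF = "from_breakpoints_to_motifs"
MOTIF_TO_BP = "from_motifs_to_breakpoints"


# ---------------------------------------------------------------------------
# distance profiles on the half-unit grid
# ---------------------------------------------------------------------------

def _half_indices(points: Sequence[float], L: int) -> np.ndarray:
    arr = np.asarray(list(points), dtype=float)
    if arr.size == 0:
        raise ValueError("point set is empty")
    return np.rint(2.0 * (arr - 1.0)).astype(np.int64) % (2 * L)


def _half_profile(points: Sequence[float], L: int) -> np.ndarray:
    """Distance (in half-units, integer) from every half-grid index
    0..2L-1 to the nearest point of the set."""
    M = 2 * L
    pts = np.unique(_half_indices(points, L))
    ext = np.concatenate([pts - M, pts, pts + M])
    x = np.arange(M, dtype=np.int64)
    j = np.searchsorted(ext, x)
    left = x - ext[j - 1]
    right = ext[j] - x
    return np.minimum(left, right)


def min_distance_profile(motif_midpoints: Sequence[float], L: int) -> np.ndarray:
    """Circular minimal distance from every integer genome position 1..L to
    the nearest motif midpoint (half-integer midpoints handled exactly)."""
    prof2 = _half_profile(motif_midpoints, L)
    return prof2[::2] / 2.0


def mean_min_distance(from_set: Sequence[float], to_set: Sequence[float],
                      L: int) -> float:
    """Mean over ``from_set`` of the circular minimal distance to ``to_set``.
    Asymmetric in its arguments."""
    prof2 = _half_profile(to_set, L)
    idx = _half_indices(from_set, L)
    return float(prof2[idx].sum()) / (2.0 * len(idx))


def _control_sums(prof2: np.ndarray, from_idx: np.ndarray, L: int) -> np.ndarray:
    """sum over the from-set of the half-unit distance to the to-set rotated
    by r, for every integer rotation r = 0..L-1.

    Rotating the to-set by +r shifts its profile, so the needed quantity is a
    circular cross-correlation of the from-set histogram with the profile;
    both are integer sequences, so rounding the FFT product recovers the exact
    integer sums (values stay far below 2^52).
    """
    M = 2 * L
    hist = np.bincount(from_idx, minlength=M).astype(float)
    corr = np.fft.irfft(np.fft.rfft(hist).conj() * np.fft.rfft(prof2.astype(float)), M)
    # corr[s] = sum_x hist[x] * prof2[(x + s) mod M]; rotation r needs shift -2r
    sums = corr[(-2 * np.arange(L)) % M]
    return np.rint(sums).astype(np.int64)


@dataclass
class MdaResult:
    """Minimal Distance Analysis outcome for one direction.

    ``control_means`` has one entry per rotation r = 1..L-1; ``p_value`` is
    the fraction of controls with mean <= ``actual_mean``.  A p of exactly 0
    means no rotation did as well; it is best reported as "< 1/(L-1)".
    """

    direction: str
    actual_mean: float
    control_means: np.ndarray
    p_value: float
    n_from: int
    n_to: int
    L: int

    @property
    def control_mean(self) -> float:
        return float(np.mean(self.control_means))

    @property
    def n_rotations(self) -> int:
        return len(self.control_means)

    def p_display(self) -> str:
        if self.p_value == 0.0:
            return f"< {1.0 / (self.L - 1):.2e}"
        return f"{self.p_value:.4g}"


def mda(from_set: Sequence[float], to_set: Sequence[float], L: int,
        direction: str = BP_TO_MOTIF) -> MdaResult:
    """MDA of ``from_set`` against ``to_set`` with L-1 rotational controls.

    The to-set is rotated in 1-nt increments (identity excluded); each
    rotation contributes one control mean.  Tie rotations (control == actual)
    count toward the p-value.
    """
    prof2 = _half_profile(to_set, L)
    from_idx = _half_indices(from_set, L)
    sums = _control_sums(prof2, from_idx, L)
    actual_sum = int(prof2[from_idx].sum())
    control_sums = sums[1:]  # r = 1..L-1
    n = len(from_idx)
    p = float(np.count_nonzero(control_sums <= actual_sum)) / (L - 1)
    return MdaResult(
        direction=direction,
        actual_mean=actual_sum / (2.0 * n),
        control_means=control_sums / (2.0 * n),
        p_value=p,
        n_from=n,
        n_to=len(np.asarray(list(to_set))),
        L=L,
    )


# ---------------------------------------------------------------------------
# individual enrichment
# ---------------------------------------------------------------------------

def chance_proximity_probability(to_set: Sequence[float], D: float, L: int) -> float:
    """Fraction of integer genome positions within circular distance D of the
    target set — the single-point chance probability of the rotational null."""
    if D < 0:
        raise ValueError("D must be non-negative")
    prof2 = _half_profile(to_set, L)
    prof_int = prof2[::2]  # integer genome positions only
    return float(np.count_nonzero(prof_int <= 2.0 * D + 1e-9)) / L


def enrichment_pvalue(K: int, N: int, P: float,
                      convention: str = "at_least_K") -> float:
    """Binomial upper-tail p-value for K of N points within distance D.

    ``at_least_K`` (default): P(X >= K) = 1 - F(K-1; N, P).
    ``greater_than_K``: 1 - F(K; N, P), which is 0 whenever K = N.
    """
    if not 0 <= K <= N:
        raise ValueError("K must satisfy 0 <= K <= N")
    if not 0.0 <= P <= 1.0:
        raise ValueError("P must be a probability")
    if convention == "at_least_K":
        return float(stats.binom.sf(K - 1, N, P))
    if convention == "greater_than_K":
        return float(stats.binom.sf(K, N, P))
    raise ValueError(f"unknown convention {convention!r}")


@dataclass
class EnrichmentPoint:
    D: float
    K: int
    N: int
    P: float
    expected: float
    p_value: float
    p_value_literal: float


@dataclass
class EnrichmentCurve:
    """Observed vs. expected counts within distance D, for D = 0..D_max."""

    direction: str
    points: list[EnrichmentPoint]
    overall_actual_mean: float
    overall_control_mean: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([vars(p) for p in self.points])


def enrichment_curve(from_set: Sequence[float], to_set: Sequence[float],
                     L: int, d_max: int = 50,
                     direction: str = BP_TO_MOTIF) -> EnrichmentCurve:
    """Cumulative distance distribution with per-D binomial p-values."""
    prof2 = _half_profile(to_set, L)
    from_idx = _half_indices(from_set, L)
    dists2 = prof2[from_idx]
    prof_int2 = prof2[::2]
    N = len(from_idx)
    points = []
    for D in range(int(d_max) + 1):
        K = int(np.count_nonzero(dists2 <= 2 * D))
        P = float(np.count_nonzero(prof_int2 <= 2 * D)) / L
        points.append(EnrichmentPoint(
            D=float(D), K=K, N=N, P=P, expected=N * P,
            p_value=enrichment_pvalue(K, N, P, "at_least_K"),
            p_value_literal=enrichment_pvalue(K, N, P, "greater_than_K"),
        ))
    sums = _control_sums(prof2, from_idx, L)
    overall_control = float(sums[1:].mean()) / (2.0 * N)
    return EnrichmentCurve(
        direction=direction,
        points=points,
        overall_actual_mean=float(dists2.sum()) / (2.0 * N),
        overall_control_mean=overall_control,
    )


# ---------------------------------------------------------------------------
# both-ends proximity
# ---------------------------------------------------------------------------

@dataclass
class BothEndsResult:
    """Count of deletions with both breakpoints within D of a motif source,
    with the rotation-averaged chance probability and binomial p-values."""

    D: float
    n_close: int
    N: int
    P: float
    p_value: float
    p_value_literal: float
    mode: str  # "single_motif_set" | "paired_repeats"
    control_counts: np.ndarray | None = None

    @property
    def expected(self) -> float:
        return self.N * self.P


def _deletion_arrays(deletions) -> tuple[np.ndarray, np.ndarray]:
    if len(deletions) and isinstance(deletions[0], DeletionRecord):
        return breakpoint_arrays(list(deletions))
    arr = np.asarray(deletions, dtype=np.int64)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("deletions must be records or an (n, 2) array")
    return arr[:, 0], arr[:, 1]


def both_ends_enrichment(deletions, motif_midpoints: Sequence[float], L: int,
                         D: float = 10.0) -> BothEndsResult:
    """Deletions whose 5' AND 3' breakpoints both lie within D of the motif
    set, against the exhaustive rotational null (motif set rotated r=1..L-1)."""
    bp5, bp3 = _deletion_arrays(deletions)
    N = len(bp5)
    if N == 0:
        raise ValueError("deletion list is empty")
    prof2 = _half_profile(motif_midpoints, L)
    close = prof2[::2] <= 2.0 * D + 1e-9  # integer positions within D
    W = np.flatnonzero(close)
    counts = np.zeros(L, dtype=np.int64)
    mask5 = np.empty(L, dtype=bool)
    mask3 = np.empty(L, dtype=bool)
    for b5, b3 in zip(bp5, bp3):
        # rotations r for which breakpoint b is close: r = (b-1) - w (mod L)
        mask5[:] = False
        mask5[(b5 - 1 - W) % L] = True
        mask3[:] = False
        mask3[(b3 - 1 - W) % L] = True
        counts += mask5 & mask3
    n_close = int(counts[0])
    P = float(counts[1:].sum()) / ((L - 1) * N)
    return BothEndsResult(
        D=D, n_close=n_close, N=N, P=P,
        p_value=enrichment_pvalue(n_close, N, P, "at_least_K"),
        p_value_literal=enrichment_pvalue(n_close, N, P, "greater_than_K"),
        mode="single_motif_set", control_counts=counts[1:],
    )


def paired_repeat_both_ends(deletions, repeat_pairs: Sequence[RepeatPair],
                            L: int, D: float = 10.0) -> BothEndsResult:
    """Deletions for which SOME repeat pair has its 5' unit within D of the
    5' breakpoint and its 3' unit within D of the 3' breakpoint.

    The control rotates the repeat-unit set rigidly (pairs preserved) through
    r = 1..L-1.
    """
    if not repeat_pairs:
        raise ValueError("repeat pair list is empty")
    bp5, bp3 = _deletion_arrays(deletions)
    N = len(bp5)
    if N == 0:
        raise ValueError("deletion list is empty")
    M = 2 * L
    m5 = np.rint(2.0 * (np.asarray([p.unit5.midpoint for p in repeat_pairs]) - 1.0)).astype(np.int64) % M
    m3 = np.rint(2.0 * (np.asarray([p.unit3.midpoint for p in repeat_pairs]) - 1.0)).astype(np.int64) % M
    a5 = (2 * (bp5[:, None] - 1) - m5[None, :]) % M  # (n_del, n_pairs)
    a3 = (2 * (bp3[:, None] - 1) - m3[None, :]) % M
    d2 = int(round(2 * D))
    Q = np.zeros((N, L), dtype=bool)
    rows = np.broadcast_to(np.arange(N)[:, None], a5.shape)
    for off in range(-d2, d2 + 1):
        t = (a5 - off) % M
        even = (t % 2) == 0
        v = (a3 - (a5 - off)) % M
        ok3 = np.minimum(v, M - v) <= d2
        sel = even & ok3
        if sel.any():
            Q[rows[sel], (t[sel] // 2) % L] = True
    counts = Q.sum(axis=0)
    n_close = int(counts[0])
    P = float(counts[1:].sum()) / ((L - 1) * N)
    return BothEndsResult(
        D=D, n_close=n_close, N=N, P=P,
        p_value=enrichment_pvalue(n_close, N, P, "at_least_K"),
        p_value_literal=enrichment_pvalue(n_close, N, P, "greater_than_K"),
        mode="paired_repeats", control_counts=counts[1:],
    )


# ---------------------------------------------------------------------------
# model / results layer
# ---------------------------------------------------------------------------

def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


class MotifBreakpointAssociation:
    """Association model between a motif midpoint set and a breakpoint set on
    a circular genome of length L.

    ``fit`` runs the reciprocal MDA (both directions) and the enrichment
    curves; the returned results object carries the means, rotational control
    distributions, p-values and a ``summary`` table.
    """

    def __init__(self, motif_midpoints: Sequence[float],
                 breakpoints: Sequence[float], L: int, *,
                 motif_name: str = "motifs",
                 breakpoint_name: str = "breakpoints"):
        self.motif_midpoints = np.asarray(list(motif_midpoints), dtype=float)
        self.breakpoints = np.asarray(list(breakpoints), dtype=float)
        if self.motif_midpoints.size == 0 or self.breakpoints.size == 0:
            raise ValueError("both point sets must be nonempty")
        self.L = int(L)
        self.motif_name = motif_name
        self.breakpoint_name = breakpoint_name

    @classmethod
    def from_sets(cls, motif_set, breakpoint_set, L: int):
        return cls(motif_set.midpoints, breakpoint_set.as_array(), L,
                   motif_name=motif_set.name,
                   breakpoint_name=breakpoint_set.end)

    def fit(self, d_max: int = 50) -> "AssociationResults":
        bp2m = mda(self.breakpoints, self.motif_midpoints, self.L, BP_TO_MOTIF)
        m2bp = mda(self.motif_midpoints, self.breakpoints, self.L, MOTIF_TO_BP)
        curve_bp2m = enrichment_curve(self.breakpoints, self.motif_midpoints,
                                      self.L, d_max, BP_TO_MOTIF)
        curve_m2bp = enrichment_curve(self.motif_midpoints, self.breakpoints,
                                      self.L, d_max, MOTIF_TO_BP)
        return AssociationResults(model=self, mda_bp_to_motif=bp2m,
                                  mda_motif_to_bp=m2bp,
                                  enrichment_bp_to_motif=curve_bp2m,
                                  enrichment_motif_to_bp=curve_m2bp)


@dataclass
class AssociationResults:
    model: MotifBreakpointAssociation
    mda_bp_to_motif: MdaResult
    mda_motif_to_bp: MdaResult
    enrichment_bp_to_motif: EnrichmentCurve
    enrichment_motif_to_bp: EnrichmentCurve

    def summary_row(self) -> dict:
        m = self.model
        b2m, m2b = self.mda_bp_to_motif, self.mda_motif_to_bp
        return {
            "motif_set": m.motif_name,
            "breakpoint_set": m.breakpoint_name,
            "n_motifs": len(m.motif_midpoints),
            "n_breakpoints": len(m.breakpoints),
            "bp_to_motif_actual": b2m.actual_mean,
            "bp_to_motif_control": b2m.control_mean,
            "bp_to_motif_p": b2m.p_value,
            "bp_to_motif_sig": _stars(b2m.p_value),
            "motif_to_bp_actual": m2b.actual_mean,
            "motif_to_bp_control": m2b.control_mean,
            "motif_to_bp_p": m2b.p_value,
            "motif_to_bp_sig": _stars(m2b.p_value),
        }

    def summary(self) -> str:
        r = self.summary_row()
        lines = [
            f"Motif-breakpoint association: {r['motif_set']} vs "
            f"{r['breakpoint_set']} (L = {self.model.L}, "
            f"{self.mda_bp_to_motif.n_rotations} rotational controls)",
            f"  motifs: {r['n_motifs']}   breakpoints: {r['n_breakpoints']}",
            "  direction         actual/control mean (nt)      p-value",
            f"  b-p -> motif      {round(r['bp_to_motif_actual']):>6d}/"
            f"{round(r['bp_to_motif_control']):<10d}"
            f"    {self.mda_bp_to_motif.p_display()} {r['bp_to_motif_sig']}",
            f"  motif -> b-p      {round(r['motif_to_bp_actual']):>6d}/"
            f"{round(r['motif_to_bp_control']):<10d}"
            f"    {self.mda_motif_to_bp.p_display()} {r['motif_to_bp_sig']}",
        ]
        return "\n".join(lines)

    def plot_enrichment(self, ax=None, direction: str = BP_TO_MOTIF):
        """Cumulative count of distances <= D for observed data (solid) and
        the rotational expectation (dashed)."""
        import matplotlib.pyplot as plt

        curve = (self.enrichment_bp_to_motif if direction == BP_TO_MOTIF
                 else self.enrichment_motif_to_bp)
        if ax is None:
            _, ax = plt.subplots()
        Ds = [p.D for p in curve.points]
        ax.plot(Ds, [p.K for p in curve.points], "-", label="observed")
        ax.plot(Ds, [p.expected for p in curve.points], "--", label="control")
        ax.set_xlabel("minimal distance D (nt)")
        ax.set_ylabel("count with distance <= D")
        ax.legend()
        return ax


class DeletionProximityModel:
    """Both-ends proximity model: are deletions bounded by motifs at both
    breakpoints more often than rotational chance?

    ``motif_source`` is either a midpoint sequence / MotifSet
    (``single_motif_set`` mode) or a list of RepeatPair (``paired_repeats``).
    """

    def __init__(self, deletions, motif_source, L: int, D: float = 10.0):
        self.deletions = deletions
        self.L = int(L)
        self.D = float(D)
        if isinstance(motif_source, (list, tuple)) and motif_source and \
                isinstance(motif_source[0], RepeatPair):
            self.pairs = list(motif_source)
            self.midpoints = None
        else:
            mids = getattr(motif_source, "midpoints", motif_source)
            self.midpoints = np.asarray(list(mids), dtype=float)
            self.pairs = None

    def fit(self) -> BothEndsResult:
        if self.pairs is not None:
            return paired_repeat_both_ends(self.deletions, self.pairs,
                                           self.L, self.D)
        return both_ends_enrichment(self.deletions, self.midpoints,
                                    self.L, self.D)
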