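"""Scanners for quadruplex-forming-potential (QFP) elements and exact repeats.

A QFP element is a stretch of at most 33 nt containing four disjoint runs of
guanine ("G-tracts"), each at least 2 (tier ``2G``) or 3 (tier ``3G``) bases
long, with at least one loop nucleotide between consecutive tracts.  Loops may
themselves contain G, so a long run such as ``GGGGG`` can donate two 2-nt
tracts split by a one-base G loop.  Intrastrand elements live on a single
strand; duplex-derived interstrand (ddi) elements assemble their four tracts
from G-runs on either strand of the duplex (a complement-strand G-tract reads
as a C-run in the reference frame) and must use both strands.

Repeats are exact k-mer matches (default k = 11) under one of four class
transforms: direct (identity), inverted (reversal), complementary (base-wise
complement) and inverted-complementary (reverse complement).  Runs of
consecutive qualifying k-mer starts are merged into maximal repeat units.

Every element is reduced to its midpoint for the downstream distance
statistics; overlapping QFP candidates are resolved to a non-overlapping set
by preferring shorter elements, then more tetrads, with a median-midpoint rule
for exact ties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import (
    CircularGenome,
    GenomeError,
    canonical_position,
    complement,
    reverse_complement,
)

MAX_QFP_SPAN = 33
MIN_LOOP = 1


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GTract:
    """A maximal run of consecutive G on one strand (1-based inclusive)."""

    start: int
    end: int
    strand: str = "reference"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class QfpElement:
    """A located QFP element.

    ``start`` is canonical (1-based, in [1, L]); ``end = start + span - 1`` may
    exceed L for elements wrapping the origin.  ``tetrads`` is the maximum over
    the element's legal 4-tract selections of the minimum tract length.
    ``midpoint`` is canonical and may be a half-integer; for merged tie groups
    it is the median of the members' midpoints.
    """

    start: float
    end: float
    strand: str  # reference | complement | interstrand
    tier: str  # "2G" | "3G"
    tetrads: int
    midpoint: float
    merged: int = 1  # number of tied candidates this element represents

    @property
    def span(self) -> int:
        return int(self.end - self.start + 1)


@dataclass(frozen=True)
class RepeatUnit:
    """A maximal block of consecutive qualifying k-mer starts of one class.

    ``member_starts`` are the qualifying window starts merged into this unit;
    ``member_partners`` (aligned with ``member_starts``) hold, per member, the
    starts of its class-transformed exact matches elsewhere in the genome.
    ``partner_starts`` is their union.  ``sequence`` is the unit's bases, so
    the matched word of any member is recoverable.
    """

    start: float
    unit_length: int
    k: int
    repeat_class: str
    midpoint: float
    partner_starts: tuple[int, ...]
    member_starts: tuple[int, ...] = ()
    member_partners: tuple[tuple[int, ...], ...] = ()
    sequence: str = ""

    @property
    def end(self) -> float:
        return self.start + self.unit_length - 1


@dataclass(frozen=True)
class RepeatPair:
    """Two repeat units carrying class-transform-matched words.

    ``unit5`` precedes ``unit3`` in the canonical linearization from
    position 1 (by midpoint).
    """

    unit5: RepeatUnit
    unit3: RepeatUnit
    word: str


@dataclass
class MotifSet:
    """A named set of motif midpoints on one genome."""

    name: str
    genome_id: str
    midpoints: np.ndarray
    elements: list = field(default_factory=list)
    L: int | None = None

    def __post_init__(self) -> None:
        self.midpoints = np.sort(np.asarray(self.midpoints, dtype=float))

    def __len__(self) -> int:
        return len(self.midpoints)

    def to_frame(self) -> pd.DataFrame:
        if self.elements:
            rows = []
            for el in self.elements:
                if isinstance(el, QfpElement):
                    rows.append(
                        dict(name=self.name, start=el.start, end=el.end,
                             strand=el.strand, kind=el.tier, tetrads=el.tetrads,
                             midpoint=el.midpoint)
                    )
                else:
                    rows.append(
                        dict(name=self.name, start=el.start, end=el.end,
                             strand="reference", kind=el.repeat_class,
                             tetrads=np.nan, midpoint=el.midpoint)
                    )
            return pd.DataFrame(rows)
        return pd.DataFrame(
            dict(name=self.name, start=np.nan, end=np.nan, strand=np.nan,
                 kind=np.nan, tetrads=np.nan, midpoint=self.midpoints)
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_bed(self, path: str | Path, L: int | None = None) -> None:
        """Midpoints as 0-based half-open point intervals (floor of midpoint)."""
        with open(path, "w") as fh:
            for m in self.midpoints:
                p0 = int(np.floor(m)) - 1  # 1-based -> 0-based
                fh.write(f"{self.genome_id}\t{p0}\t{p0 + 1}\t{self.name}\n")


def read_midpoints_tsv(path: str | Path, name: str | None = None,
                       genome_id: str = "") -> MotifSet:
    """Read an externally computed midpoint list (TSV with a ``midpoint``
    column, or a single unnamed column of positions)."""
    df = pd.read_csv(path, sep=r"[\t,]", engine="python")
    if "midpoint" in df.columns:
        mids = df["midpoint"].astype(float).to_numpy()
    elif df.shape[1] == 1:
        mids = df.iloc[:, 0].astype(float).to_numpy()
    else:
        raise ValueError(f"{path}: no 'midpoint' column found")
    return MotifSet(name=name or Path(path).stem, genome_id=genome_id,
                    midpoints=mids)


# ---------------------------------------------------------------------------
# G-tract and QFP candidate enumeration
# ---------------------------------------------------------------------------

def find_g_tracts(seq: str, min_len: int) -> list[GTract]:
    """All maximal runs of >= ``min_len`` consecutive G in a linear sequence."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    seq = seq.upper()
    tracts: list[GTract] = []
    i, n = 0, len(seq)
    while i < n:
        if seq[i] == "G":
            j = i
            while j < n and seq[j] == "G":
                j += 1
            if j - i >= min_len:
                tracts.append(GTract(start=i + 1, end=j))
            i = j
        else:
            i += 1
    return tracts


def _run_lengths(seq: str, base: str) -> np.ndarray:
    """reach[i] = number of consecutive ``base`` characters starting at i."""
    n = len(seq)
    reach = np.zeros(n + 1, dtype=np.int64)
    for i in range(n - 1, -1, -1):
        reach[i] = reach[i + 1] + 1 if seq[i] == base else 0
    return reach[:n]


def _window_tracts(reach: np.ndarray, lo: int, hi: int, min_run: int):
    """All sub-tracts (s, e, length) with lo <= s, e < hi, length >= min_run."""
    out = []
    for s in range(lo, hi):
        r = int(reach[s]) if s < len(reach) else 0
        if r >= min_run:
            for ln in range(min_run, min(r, hi - s) + 1):
                out.append((s, s + ln - 1, ln))
    return out


def enumerate_qfp_candidates(seq: str, min_run: int,
                             max_span: int = MAX_QFP_SPAN,
                             min_loop: int = MIN_LOOP,
                             tier: str | None = None,
                             strand: str = "reference") -> list[QfpElement]:
    """Enumerate QFP candidate elements in a linear sequence.

    A candidate is keyed by (start of first tract, end of last tract) over all
    selections of four disjoint G-sub-tracts of length >= ``min_run`` with at
    least ``min_loop`` nt between consecutive tracts and total span
    <= ``max_span``.  Its ``tetrads`` value is the best (max over selections of
    the min tract length) achievable for that key.
    """
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    seq = seq.upper()
    n = len(seq)
    reach = _run_lengths(seq, "G")
    tier = tier or f"{min_run}G"
    out: list[QfpElement] = []
    for s1 in range(n):
        if reach[s1] < min_run:
            continue
        hi = min(n, s1 + max_span)
        tracts = _window_tracts(reach, s1, hi, min_run)
        # layer 1: tracts starting exactly at s1
        layer = {}
        for (s, e, ln) in tracts:
            if s == s1:
                layer[e] = max(layer.get(e, 0), ln)
        for _ in range(3):
            nxt: dict[int, int] = {}
            for (s, e, ln) in tracts:
                best_prev = 0
                for pe, pv in layer.items():
                    if pe + min_loop < s and pv > best_prev:
                        best_prev = pv
                if best_prev:
                    v = min(best_prev, ln)
                    if v > nxt.get(e, 0):
                        nxt[e] = v
            layer = nxt
            if not layer:
                break
        for e, v in layer.items():
            out.append(
                QfpElement(start=s1 + 1, end=e + 1, strand=strand, tier=tier,
                           tetrads=v, midpoint=(s1 + 1 + e + 1) / 2.0)
            )
    return out


def enumerate_ddi_candidates(seq: str, min_run: int,
                             max_span: int = MAX_QFP_SPAN,
                             min_loop: int = MIN_LOOP) -> list[QfpElement]:
    """Candidates whose four tracts may sit on either strand (G- or C-runs in
    the reference frame), requiring at least one tract from each strand."""
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    seq = seq.upper()
    n = len(seq)
    reach_g = _run_lengths(seq, "G")
    reach_c = _run_lengths(seq, "C")
    tier = f"{min_run}G"
    out: list[QfpElement] = []
    for s1 in range(n):
        first_types = []
        if reach_g[s1] >= min_run:
            first_types.append(1)  # bit 1: used a reference G-tract
        if reach_c[s1] >= min_run:
            first_types.append(2)  # bit 2: used a complement tract (C-run)
        if not first_types:
            continue
        hi = min(n, s1 + max_span)
        tr_g = [(s, e, ln, 1) for (s, e, ln) in _window_tracts(reach_g, s1, hi, min_run)]
        tr_c = [(s, e, ln, 2) for (s, e, ln) in _window_tracts(reach_c, s1, hi, min_run)]
        tracts = tr_g + tr_c
        # layer keyed by (end, strand-usage flags) -> best min tract length
        layer: dict[tuple[int, int], int] = {}
        for (s, e, ln, bit) in tracts:
            if s == s1:
                key = (e, bit)
                layer[key] = max(layer.get(key, 0), ln)
        for _ in range(3):
            nxt: dict[tuple[int, int], int] = {}
            for (s, e, ln, bit) in tracts:
                for (pe, pflags), pv in layer.items():
                    if pe + min_loop < s:
                        key = (e, pflags | bit)
                        v = min(pv, ln)
                        if v > nxt.get(key, 0):
                            nxt[key] = v
            layer = nxt
            if not layer:
                break
        best: dict[int, int] = {}
        for (e, flags), v in layer.items():
            if flags == 3:  # both strands represented
                best[e] = max(best.get(e, 0), v)
        for e, v in best.items():
            out.append(
                QfpElement(start=s1 + 1, end=e + 1, strand="interstrand",
                           tier=tier, tetrads=v,
                           midpoint=(s1 + 1 + e + 1) / 2.0)
            )
    return out


# ---------------------------------------------------------------------------
# overlap resolution
# ---------------------------------------------------------------------------

def _circ_overlap(a: QfpElement, b: QfpElement, L: int) -> bool:
    """Do two circular intervals share at least one base?"""
    sa, sb = (a.start - 1) % L, (b.start - 1) % L
    return ((sb - sa) % L) < a.span or ((sa - sb) % L) < b.span


def resolve_overlaps(candidates: Sequence[QfpElement], L: int) -> list[QfpElement]:
    """Reduce candidates to a non-overlapping set.

    Iterative greedy: the best remaining candidate by (span ascending, tetrads
    descending, start ascending) is emitted; if the top rank is shared by
    several mutually overlapping candidates with equal span and tetrads, the
    one whose midpoint is closest to the group's median is emitted with its
    midpoint replaced by that median.  All candidates overlapping the emitted
    element are then discarded, and the process repeats.
    """
    remaining = sorted(candidates, key=lambda c: (c.span, -c.tetrads, c.start))
    out: list[QfpElement] = []
    while remaining:
        b = remaining[0]
        tied = [c for c in remaining
                if c.span == b.span and c.tetrads == b.tetrads
                and _circ_overlap(c, b, L)]
        group = [b]
        for c in tied:
            if c is b:
                continue
            if all(_circ_overlap(c, g, L) for g in group):
                group.append(c)
        if len(group) > 1:
            # unwrap midpoints around b's midpoint before taking the median
            ref = b.midpoint
            unwrapped = [ref + ((c.midpoint - ref + L / 2.0) % L) - L / 2.0
                         for c in group]
            med = float(np.median(unwrapped))
            pick = min(zip(group, unwrapped),
                       key=lambda cu: (abs(cu[1] - med), cu[0].start))[0]
            emit = replace(pick, midpoint=canonical_position(med, L),
                           merged=len(group))
        else:
            emit = b
        out.append(emit)
        remaining = [c for c in remaining if not _circ_overlap(c, emit, L)]
    return out


# ---------------------------------------------------------------------------
# genome-level QFP scans
# ---------------------------------------------------------------------------

def _circular_candidates(seq: str, min_run: int, ddi: bool = False,
                         strand: str = "reference",
                         max_span: int = MAX_QFP_SPAN,
                         min_loop: int = MIN_LOOP) -> list[QfpElement]:
    """Enumerate candidates on a circular sequence; starts restricted to one
    period, windows allowed to wrap the origin."""
    L = len(seq)
    max_span = min(max_span, L)  # a window cannot wrap past itself
    ext = seq + seq[: max(0, max_span - 1)]
    if ddi:
        cands = enumerate_ddi_candidates(ext, min_run, max_span, min_loop)
    else:
        cands = enumerate_qfp_candidates(ext, min_run, max_span, min_loop,
                                         strand=strand)
    out = []
    for c in cands:
        if c.start <= L:
            out.append(replace(c, midpoint=canonical_position(c.midpoint, L)))
    return out


def _map_complement_frame(c: QfpElement, L: int) -> QfpElement:
    """Map an element located on the reverse complement back to reference
    coordinates (position p' on the complement scan is L - p' + 1)."""
    start = canonical_position(L - c.end + 1, L)
    end = start + c.span - 1
    return replace(c, start=start, end=end,
                   midpoint=canonical_position((start + end) / 2.0, L))


def find_intrastrand_qfp(genome: CircularGenome, min_run: int,
                         max_span: int = MAX_QFP_SPAN,
                         min_loop: int = MIN_LOOP) -> MotifSet:
    """Non-overlapping intrastrand QFP elements on both strands, in reference
    coordinates.  Overlap resolution is per strand; the returned set is the
    union over both strands."""
    if min_run not in (2, 3):
        raise ValueError("min_run must be 2 or 3")
    L = len(genome)
    ref = _circular_candidates(genome.sequence, min_run, strand="reference",
                               max_span=max_span, min_loop=min_loop)
    rc = reverse_complement(genome.sequence)
    comp = [_map_complement_frame(c, L)
            for c in _circular_candidates(rc, min_run, strand="complement",
                                          max_span=max_span, min_loop=min_loop)]
    elements = resolve_overlaps(ref, L) + resolve_overlaps(comp, L)
    elements.sort(key=lambda e: (e.start, e.strand))
    return MotifSet(
        name=f"{min_run}G_QFP",
        genome_id=genome.id,
        midpoints=[e.midpoint for e in elements],
        elements=elements,
        L=L,
    )


def find_ddi_qfp(genome: CircularGenome, min_run: int,
                 intrastrand: MotifSet,
                 max_span: int = MAX_QFP_SPAN,
                 min_loop: int = MIN_LOOP) -> MotifSet:
    """Duplex-derived interstrand QFP elements, with candidates overlapping
    any intrastrand element removed before overlap resolution."""
    if min_run not in (2, 3):
        raise ValueError("min_run must be 2 or 3")
    L = len(genome)
    cands = _circular_candidates(genome.sequence, min_run, ddi=True,
                                 max_span=max_span, min_loop=min_loop)
    intra = list(intrastrand.elements)
    kept = [c for c in cands
            if not any(_circ_overlap(c, e, L) for e in intra)]
    elements = resolve_overlaps(kept, L)
    elements.sort(key=lambda e: e.start)
    return MotifSet(
        name=f"ddi_{min_run}G_QFP",
        genome_id=genome.id,
        midpoints=[e.midpoint for e in elements],
        elements=elements,
        L=L,
    )


# ---------------------------------------------------------------------------
# exact repeats
# ---------------------------------------------------------------------------

REPEAT_CLASSES = ("direct", "inverted", "complementary", "inverted_complementary")


def repeat_transform(word: str, repeat_class: str) -> str:
    """The class transform applied to a k-mer before exact matching:
    direct -> identity, inverted -> reversal, complementary -> base-wise
    complement, inverted_complementary -> reverse complement."""
    if repeat_class == "direct":
        return word
    if repeat_class == "inverted":
        return word[::-1]
    if repeat_class == "complementary":
        return complement(word)
    if repeat_class == "inverted_complementary":
        return reverse_complement(word)
    raise ValueError(f"unknown repeat class {repeat_class!r}")


def find_repeats(genome: CircularGenome, k: int = 11,
                 repeat_class: str = "direct") -> list[RepeatUnit]:
    """Repeat units of one class: maximal runs of circular k-mer window starts
    whose class-transformed word occurs elsewhere on the reference strand.

    k-mers containing N never match.  A fully repetitive genome (every window
    qualifies) collapses to one genome-wide unit with a warning.
    """
    L = len(genome)
    if not 1 <= k <= L:
        raise GenomeError(f"k={k} out of range for genome of length {L}")
    if repeat_class not in REPEAT_CLASSES:
        raise ValueError(f"unknown repeat class {repeat_class!r}")
    doubled = genome.sequence + genome.sequence[: k - 1]
    words = [doubled[i : i + k] for i in range(L)]
    occ: dict[str, list[int]] = {}
    for i, w in enumerate(words):
        if "N" not in w:
            occ.setdefault(w, []).append(i)
    partners: dict[int, list[int]] = {}
    qualifying = np.zeros(L, dtype=bool)
    for i, w in enumerate(words):
        if "N" in w:
            continue
        t = repeat_transform(w, repeat_class)
        hits = [j for j in occ.get(t, ()) if j != i]
        if hits:
            qualifying[i] = True
            partners[i] = hits

    if not qualifying.any():
        return []
    if qualifying.all():
        warnings.warn(
            "every k-mer window qualifies; genome is fully repetitive — "
            "emitting a single genome-wide repeat unit"
        )
        allp = sorted({j + 1 for js in partners.values() for j in js})
        members = tuple(range(1, L + 1))
        return [RepeatUnit(start=1.0, unit_length=L, k=k,
                           repeat_class=repeat_class,
                           midpoint=canonical_position((1 + L) / 2.0, L),
                           partner_starts=tuple(allp),
                           member_starts=members,
                           member_partners=tuple(
                               tuple(j + 1 for j in partners[m - 1])
                               for m in members),
                           sequence=genome.sequence)]

    # maximal circular runs of qualifying starts
    idx = np.flatnonzero(qualifying)
    runs: list[list[int]] = []
    cur = [int(idx[0])]
    for i in idx[1:]:
        if i == cur[-1] + 1:
            cur.append(int(i))
        else:
            runs.append(cur)
            cur = [int(i)]
    runs.append(cur)
    if len(runs) > 1 and runs[0][0] == 0 and runs[-1][-1] == L - 1:
        runs[0] = runs.pop() + runs[0]  # wrap-around merge
    units = []
    for run in runs:
        start = run[0] + 1
        unit_length = len(run) + k - 1
        end = start + unit_length - 1
        mids = canonical_position((start + end) / 2.0, L)
        members = tuple(m % L + 1 for m in run)
        ps = sorted({j + 1 for m in run for j in partners[m % L]})
        units.append(RepeatUnit(start=float(start), unit_length=unit_length,
                                k=k, repeat_class=repeat_class, midpoint=mids,
                                partner_starts=tuple(ps),
                                member_starts=members,
                                member_partners=tuple(
                                    tuple(j + 1 for j in partners[m - 1])
                                    for m in members),
                                sequence=doubled[run[0]: run[0] + unit_length]))
    units.sort(key=lambda u: u.start)
    return units


def enumerate_repeat_pairs(units: Sequence[RepeatUnit]) -> list[RepeatPair]:
    """All unordered unit pairs sharing a class-transformed word match,
    oriented so unit5 precedes unit3 in the canonical linearization."""
    if not units:
        return []
    start_to_unit: dict[int, int] = {}
    for ui, u in enumerate(units):
        for s in u.member_starts:
            start_to_unit[s] = ui
    seen: dict[tuple[int, int], str] = {}
    for ui, u in enumerate(units):
        for s, plist in zip(u.member_starts, u.member_partners):
            for j in plist:
                vi = start_to_unit.get(j)
                if vi is None or vi == ui:
                    continue
                key = (min(ui, vi), max(ui, vi))
                if key not in seen:
                    off = int(s - u.start)
                    word = u.sequence[off: off + u.k] if u.sequence else ""
                    seen[key] = word
    pairs = []
    for (ui, vi), word in sorted(seen.items()):
        a, b = units[ui], units[vi]
        u5, u3 = (a, b) if a.midpoint <= b.midpoint else (b, a)
        pairs.append(RepeatPair(unit5=u5, unit3=u3, word=word))
    return pairs


def repeat_units_to_motifset(units: Sequence[RepeatUnit], genome_id: str,
                             L: int | None = None,
                             name: str | None = None) -> MotifSet:
    if units:
        name = name or f"{units[0].repeat_class}_repeats_k{units[0].k}"
    return MotifSet(name=name or "repeats", genome_id=genome_id,
                    midpoints=[u.midpoint for u in units],
                    elements=list(units), L=L)
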