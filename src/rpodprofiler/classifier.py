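"""Paired-end amplicon read classification against a reference database.

2x300 nt reads of a ~760 nt amplicon do not overlap, so merge-then-cluster
(OTU/ASV) pipelines do not apply.  Instead each read pair is treated like
a paired RNA-seq fragment: both mates are aligned to every reference
amplicon, only *concordant* placements are kept (both mates on the same
reference, forward-reverse orientation, plausible fragment length), and a
pair is assigned to the best reference's species only when the placement
is sufficiently *unique* — the combined-score separation between the best
and second-best concordant reference must exceed a threshold (Q > 10 by
default, capped at 42).  Ties give Q = 0 and stay unassigned.

Per-sample species counts are reported raw and, for cross-sample
comparison, scaled so every sample sums to a common depth (100,000 reads
by default).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from . import _align
from .amplicon_db import AmpliconDatabase
from .iupac_pcr import reverse_complement

DEFAULT_DEPTH = 100_000
DEFAULT_Q_THRESHOLD = 10.0
DEFAULT_FRAG_WINDOW = (400, 1000)
Q_CAP = 42.0
Q_SCALE = 1.0  # c: converts combined-score separation into Q units


def reads_in_pairs(n_pairs: int) -> int:
    """Number of individual reads represented by ``n_pairs`` read pairs."""
    if n_pairs < 0:
        raise ValueError("pair count must be >= 0")
    return 2 * n_pairs


@dataclass
class ReadPair:
    """Two mates with Phred qualities and (post-demux) sample provenance."""

    pair_id: str
    seq1: str
    qual1: Sequence[int]
    seq2: str
    qual2: Sequence[int]
    sample: str | None = None

    def __post_init__(self) -> None:
        if not self.seq1 or not self.seq2:
            raise ValueError(f"pair {self.pair_id!r}: empty mate")
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(
                f"pair {self.pair_id!r}: quality/sequence length mismatch")


@dataclass(frozen=True)
class MateHit:
    """One mate's placement on one reference."""

    reference_id: str
    score: float
    target_start: int  # 0-based inclusive
    target_end: int    # 0-based inclusive
    exact: bool        # True if refined with the Gotoh kernel


@dataclass(frozen=True)
class PairAlignment:
    """A concordant placement of a whole pair on one reference."""

    reference_id: str
    score1: float
    score2: float
    fragment_length: int

    @property
    def combined_score(self) -> float:
        return self.score1 + self.score2


@dataclass(frozen=True)
class Assignment:
    pair_id: str
    status: str  # assigned | ambiguous | discordant | no_hit
    species: str | None = None
    reference_id: str | None = None
    q: float = 0.0


# ---------------------------------------------------------------------------
# demultiplexing and quality filtering


def demultiplex(pairs: Iterable[ReadPair], barcodes: Mapping[str, str],
                ) -> tuple[dict[str, list[ReadPair]], list[ReadPair]]:
    """Assign pairs to samples by exact barcode prefix of mate 1.

    Barcodes must be unique and of equal length; matched barcodes are
    stripped from the sequence and quality of mate 1.
    """
    if not barcodes:
        raise ValueError("barcode sheet is empty")
    values = list(barcodes.values())
    if len(set(values)) != len(values):
        raise ValueError("duplicate barcodes in sheet")
    if len({len(b) for b in values}) != 1:
        raise ValueError("barcodes must be of equal length")
    blen = len(values[0])
    lookup = {b.upper(): sample for sample, b in barcodes.items()}
    assigned: dict[str, list[ReadPair]] = {s: [] for s in barcodes}
    unassigned: list[ReadPair] = []
    for pair in pairs:
        sample = lookup.get(pair.seq1[:blen].upper())
        if sample is None or len(pair.seq1) <= blen:
            unassigned.append(pair)
            continue
        assigned[sample].append(
            replace(pair, seq1=pair.seq1[blen:], qual1=pair.qual1[blen:],
                    sample=sample))
    return assigned, unassigned


def _trim_index(qual: Sequence[int], window: int, window_q: float) -> int:
    """First index where a full sliding window's mean quality drops below
    ``window_q``; len(qual) if none does."""
    q = np.asarray(qual, dtype=float)
    if len(q) < window:
        return len(q)
    means = np.convolve(q, np.ones(window) / window, mode="valid")
    bad = np.nonzero(means < window_q)[0]
    return int(bad[0]) if len(bad) else len(q)


def quality_filter(pair: ReadPair, min_len: int = 100,
                   window_q: float = 20.0, window: int = 4,
                   ) -> ReadPair | None:
    """3' sliding-window quality trim; discard the pair if either mate
    falls below ``min_len`` after trimming."""
    t1 = _trim_index(pair.qual1, window, window_q)
    t2 = _trim_index(pair.qual2, window, window_q)
    if t1 < min_len or t2 < min_len:
        return None
    if t1 == len(pair.seq1) and t2 == len(pair.seq2):
        return pair
    return replace(pair, seq1=pair.seq1[:t1], qual1=pair.qual1[:t1],
                   seq2=pair.seq2[:t2], qual2=pair.qual2[:t2])


# ---------------------------------------------------------------------------
# alignment against the database


class DatabaseIndex:
    """Pre-encoded reference sequences for repeated mate alignment."""

    def __init__(self, db: AmpliconDatabase):
        self.db = db
        self.ids = [r.record_id for r in db]
        self.seqs = [r.sequence for r in db]
        self.encoded = [_align.encode(s) for s in self.seqs]

    def __len__(self) -> int:
        return len(self.ids)


def align_mate(mate: str, index: DatabaseIndex,
               floor_fraction: float = 0.6,
               refine_margin: float = 60.0) -> list[MateHit]:
    """Score one mate against every reference; drop hits below the floor.

    The score floor is ``floor_fraction`` of the maximal score (2 x mate
    length).  Screening is end-to-end (edlib infix mode); contenders within
    ``refine_margin`` of the best screening bound get exact banded Gotoh
    scores, the rest keep the screening bound.  Hits are returned in
    descending score order.
    """
    length = len(mate)
    max_score = _align.MATCH * length
    floor = floor_fraction * max_score
    # each unit edit costs at least (MATCH - MISMATCH) = 5 score units
    k = int((max_score - floor) // (_align.MATCH - _align.MISMATCH))
    q_enc = _align.encode(mate)
    raw: list[tuple[int, float, int, int]] = []
    for i in range(len(index)):
        res = edlib.align(mate, index.seqs[i], mode="HW",
                          task="locations", k=k)
        d = res["editDistance"]
        if d < 0:
            continue
        ls, le = res["locations"][0]
        bound = max_score - (_align.MATCH - _align.MISMATCH) * d
        raw.append((i, float(bound), ls, le))
    if not raw:
        return []
    best_bound = max(r[1] for r in raw)
    hits: list[MateHit] = []
    for i, bound, ls, le in raw:
        if bound >= best_bound - refine_margin:
            score = float(_align.refine_score(q_enc, index.encoded[i],
                                              ls, le))
            exact = True
        else:
            score, exact = bound, False
        if score >= floor:
            hits.append(MateHit(index.ids[i], score, ls, le, exact))
    hits.sort(key=lambda h: (-h.score, h.reference_id))
    return hits


def classify_pair(pair: ReadPair, index: DatabaseIndex,
                  q_threshold: float = DEFAULT_Q_THRESHOLD,
                  frag_window: tuple[int, int] = DEFAULT_FRAG_WINDOW,
                  floor_fraction: float = 0.6) -> Assignment:
    """Classify one quality-filtered pair.

    Mate 1 is aligned forward, mate 2 reverse complemented first (the
    expected forward-reverse amplicon orientation).  Concordant references
    are ranked by combined score; uniqueness Q = c*(S_best - S_second)
    capped at 42, with the per-pair floor standing in for S_second when
    only one concordant reference exists.  The pair is assigned iff
    Q > ``q_threshold`` (strict); exact ties give Q = 0.
    """
    hits1 = align_mate(pair.seq1, index, floor_fraction)
    hits2 = align_mate(reverse_complement(pair.seq2), index, floor_fraction)
    if not hits1 or not hits2:
        return Assignment(pair.pair_id, "no_hit")
    by_ref2 = {h.reference_id: h for h in hits2}
    lo, hi = frag_window
    concordant: list[PairAlignment] = []
    for h1 in hits1:
        h2 = by_ref2.get(h1.reference_id)
        if h2 is None:
            continue
        frag = (h2.target_end + 1) - h1.target_start
        if lo <= frag <= hi:
            concordant.append(PairAlignment(h1.reference_id, h1.score,
                                            h2.score, frag))
    if not concordant:
        return Assignment(pair.pair_id, "discordant")
    concordant.sort(key=lambda a: (-a.combined_score, a.reference_id))
    best = concordant[0]
    floor2 = floor_fraction * _align.MATCH * (len(pair.seq1) + len(pair.seq2))
    s_second = (concordant[1].combined_score if len(concordant) > 1
                else floor2)
    sep = best.combined_score - s_second
    if len(concordant) > 1 and sep == 0:
        return Assignment(pair.pair_id, "ambiguous", q=0.0)
    q = min(Q_CAP, Q_SCALE * sep)
    if q > q_threshold:
        return Assignment(pair.pair_id, "assigned",
                          index.db.species_of(best.reference_id),
                          best.reference_id, q)
    return Assignment(pair.pair_id, "ambiguous", q=q)


# ---------------------------------------------------------------------------
# tabulation and normalisation


@dataclass
class AbundanceTable:
    """Samples x species count matrix with explicit normalisation state."""

    data: pd.DataFrame  # index: sample, columns: species
    state: str = "raw"  # raw | normalized_to_depth
    depth: float | None = None

    def __post_init__(self) -> None:
        if (self.data.values < 0).any():
            raise ValueError("abundance counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def species(self) -> list[str]:
        return list(self.data.columns)


def tabulate(assignments: Mapping[str, Sequence[Assignment]],
             ) -> tuple[AbundanceTable, dict[str, int]]:
    """Count assigned pairs per (sample, species).

    Each pair contributes at most one count; non-assigned pairs are
    returned as a per-sample unassigned tally.
    """
    counts: dict[str, Counter] = {}
    unassigned: dict[str, int] = {}
    for sample, asgs in assignments.items():
        c: Counter = Counter()
        un = 0
        for a in asgs:
            if a.status == "assigned":
                c[a.species] += 1
            else:
                un += 1
        counts[sample] = c
        unassigned[sample] = un
    species = sorted({sp for c in counts.values() for sp in c})
    df = pd.DataFrame(
        [[counts[s].get(sp, 0) for sp in species] for s in counts],
        index=list(counts), columns=species,
        dtype=float)
    df.index.name = "sample"
    return AbundanceTable(df, "raw"), unassigned


def normalize_to_depth(table: AbundanceTable,
                       depth: float = DEFAULT_DEPTH) -> AbundanceTable:
    """Scale each sample row to sum to ``depth`` (fractional values kept).

    Scaling, not rarefaction: relative composition is preserved exactly.
    """
    totals = table.data.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"cannot normalize zero-total sample(s): "
                         f"{list(zero.index)}")
    scaled = table.data.mul(depth / totals, axis=0)
    return AbundanceTable(scaled, "normalized_to_depth", depth)


def rarefy_to_depth(table: AbundanceTable, depth: int,
                    seed: int) -> AbundanceTable:
    """Alternative normalisation: random subsampling without replacement."""
    rng = np.random.default_rng(seed)
    rows = []
    for sample in table.samples:
        counts = table.data.loc[sample].to_numpy()
        total = int(counts.sum())
        if total < depth:
            raise ValueError(f"sample {sample!r} has fewer than {depth} reads")
        pool = np.repeat(np.arange(len(counts)), counts.astype(int))
        pick = rng.choice(pool, size=depth, replace=False)
        rows.append(np.bincount(pick, minlength=len(counts)))
    df = pd.DataFrame(rows, index=table.samples, columns=table.species,
                      dtype=float)
    df.index.name = "sample"
    return AbundanceTable(df, "normalized_to_depth", depth)


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass
class StageCounts:
    """Machine-auditable per-sample bookkeeping at every filter stage."""

    input_pairs: int = 0
    qc_discarded: int = 0
    no_hit: int = 0
    discordant: int = 0
    ambiguous: int = 0
    assigned: int = 0

    @property
    def input_reads(self) -> int:
        return reads_in_pairs(self.input_pairs)

    def conserved(self) -> bool:
        return (self.qc_discarded + self.no_hit + self.discordant
                + self.ambiguous + self.assigned) == self.input_pairs

    def as_dict(self) -> dict[str, int]:
        return {"input_pairs": self.input_pairs,
                "input_reads": self.input_reads,
                "qc_discarded": self.qc_discarded,
                "no_hit": self.no_hit,
                "discordant": self.discordant,
                "ambiguous": self.ambiguous,
                "assigned": self.assigned}


def classify_sample(pairs: Sequence[ReadPair], index: DatabaseIndex,
                    q_threshold: float = DEFAULT_Q_THRESHOLD,
                    frag_window: tuple[int, int] = DEFAULT_FRAG_WINDOW,
                    min_len: int = 100, window_q: float = 20.0,
                    ) -> tuple[list[Assignment], StageCounts]:
    """Quality-filter and classify one sample's pairs with full
    bookkeeping.  Output is sorted by pair id, so it does not depend on
    input order."""
    counts = StageCounts(input_pairs=len(pairs))
    assignments: list[Assignment] = []
    for pair in sorted(pairs, key=lambda p: p.pair_id):
        kept = quality_filter(pair, min_len=min_len, window_q=window_q)
        if kept is None:
            counts.qc_discarded += 1
            continue
        a = classify_pair(kept, index, q_threshold, frag_window)
        assignments.append(a)
        setattr(counts, a.status, getattr(counts, a.status) + 1)
    return assignments, counts
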