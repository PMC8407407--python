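"""Degenerate-primer in-silico PCR.

Pseudomonas species cannot be resolved with 16S rRNA amplicons, so
species-level profiling relies on housekeeping genes such as *rpoD* (the
sigma-70 factor of RNA polymerase).  Before a primer pair is used at the
bench it is benchmarked *in silico*: every template in a genome collection
is searched for degenerate (IUPAC-encoded) primer sites under a small edit
budget, virtual amplicons are extracted, and the pair is scored by the
fraction of target genomes amplified, the fraction of negative-control
genomes amplified, and any products far from the expected length.

Primer-site matching is an anchored, edit-style alignment of the primer
against the template: at most ``max_mismatch`` substitutions and at most
``max_indel`` single-base insertions/deletions, counted as separate
budgets.  A degenerate primer code matches a template base iff the base is
in the code's set; ambiguity codes in the *template* never match (a run of
N from a contig gap must not create a spurious site).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

#: IUPAC nucleotide codes -> the set of concrete bases each stands for.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

# bitmask encoding: A=1, C=2, G=4, T=8; degenerate code = OR of its bases.
_BASE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
_CODE_BITS = {c: sum(_BASE_BITS[b] for b in bases)
              for c, bases in IUPAC_CODES.items()}

#: Published primers used throughout the toolkit (name -> (sequence, role)).
#: PsEG30F/PsEG790R bracket the 736 nt rpoD fragment; PsJL490R and PsJL628R
#: are alternative rpoD reverse primers; 341F/805R are the universal
#: 16S rRNA V3-V4 pair.
KNOWN_PRIMERS: dict[str, tuple[str, str]] = {
    "PsEG30F": ("ATYGAAATCGCCAARCG", "forward"),
    "PsEG790R": ("CGGTTGATKTCCTTGA", "reverse"),
    "PsJL490R": ("AGYTTGATYGGGATGAA", "reverse"),
    "PsJL628R": ("GGGAACWKGCGCAGGAARTC", "reverse"),
    "341F": ("CCTACGGGNGGCWGCAG", "forward"),
    "805R": ("GACTACHVGGGTATCTAATCC", "reverse"),
}


def reverse_complement(seq: str) -> str:
    """Reverse complement, preserving IUPAC degeneracy codes."""
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_iupac(seq: str, what: str = "sequence") -> str:
    seq = seq.upper()
    for i, ch in enumerate(seq):
        if ch not in IUPAC_CODES:
            raise ValueError(
                f"invalid IUPAC character {ch!r} at position {i} in {what}")
    return seq


def encode_mask(seq: str) -> np.ndarray:
    """Encode a primer as per-position base bitmasks (uint8).

    Characters outside the IUPAC alphabet encode as 0 and therefore match
    nothing.
    """
    return np.array([_CODE_BITS.get(c, 0) for c in seq.upper()],
                    dtype=np.uint8)


_TEMPLATE_BITS = np.zeros(256, dtype=np.uint8)
for _b, _v in _BASE_BITS.items():
    _TEMPLATE_BITS[ord(_b)] = _v
    _TEMPLATE_BITS[ord(_b.lower())] = _v


def encode_template_mask(seq: str) -> np.ndarray:
    """Encode a template strictly: only A/C/G/T match; ambiguity codes
    (N etc.) encode as 0 and count as mismatches against any primer code —
    contig gaps must not create spurious sites."""
    return _TEMPLATE_BITS[np.frombuffer(seq.encode("ascii"),
                                        dtype=np.uint8)]


@dataclass(frozen=True)
class Primer:
    """A (possibly degenerate) PCR primer with its orientation role."""

    name: str
    sequence: str
    role: str  # "forward" | "reverse"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"primer {self.name!r} has empty sequence")
        object.__setattr__(self, "sequence",
                           _validate_iupac(self.sequence,
                                           f"primer {self.name!r}"))
        if self.role not in ("forward", "reverse"):
            raise ValueError(f"primer role must be forward|reverse, "
                             f"got {self.role!r}")

    @property
    def degeneracy(self) -> int:
        """Product of per-position code cardinalities (>= 1)."""
        d = 1
        for c in self.sequence:
            d *= len(IUPAC_CODES[c])
        return d

    def __len__(self) -> int:
        return len(self.sequence)


def known_primer(name: str) -> Primer:
    seq, role = KNOWN_PRIMERS[name]
    return Primer(name, seq, role)


@dataclass(frozen=True)
class PrimerMatch:
    """A primer binding site on a template (0-based half-open coords)."""

    template_id: str
    start: int
    end: int
    strand: str  # "+" | "-"
    mismatches: int
    indels: int

    @property
    def edits(self) -> int:
        return self.mismatches + self.indels

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("invalid match coordinates")


@dataclass(frozen=True)
class Amplicon:
    """A virtual PCR product, including both primer footprints."""

    template_id: str
    fwd_match: PrimerMatch
    rev_match: PrimerMatch
    sequence: str
    strand: str = "+"  # "+": fwd site on plus strand; "-": product from RC

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def start(self) -> int:
        return min(self.fwd_match.start, self.rev_match.start)

    @property
    def end(self) -> int:
        return max(self.fwd_match.end, self.rev_match.end)

    @property
    def trimmed_sequence(self) -> str:
        """Product with both primer footprints removed."""
        flen = self.fwd_match.end - self.fwd_match.start
        rlen = self.rev_match.end - self.rev_match.start
        return self.sequence[flen:len(self.sequence) - rlen]


@dataclass
class PrimerPairMetrics:
    """Benchmark of one primer pair over a genome collection."""

    collection_id: str
    n_templates: int
    n_amplified: int
    n_negative_templates: int = 0
    n_negative_amplified: int = 0
    length_anomalies: list[tuple[str, int]] = field(default_factory=list)

    @property
    def fraction_amplified(self) -> float:
        return self.n_amplified / self.n_templates

    @property
    def fraction_negative(self) -> float:
        if self.n_negative_templates == 0:
            return 0.0
        return self.n_negative_amplified / self.n_negative_templates


def expand_iupac(sequence: str, limit: int = 1_000_000) -> set[str]:
    """All concrete DNA expansions of a degenerate IUPAC sequence.

    The cardinality of the result equals the product of per-position code
    sizes.  ``limit`` guards against accidental explosion (e.g. poly-N).
    """
    seq = _validate_iupac(sequence)
    d = 1
    for c in seq:
        d *= len(IUPAC_CODES[c])
    if d > limit:
        raise ValueError(f"degeneracy {d} exceeds expansion limit {limit}")
    return {"".join(p) for p in
            itertools.product(*(IUPAC_CODES[c] for c in seq))}


def _anchored_alignments(pmask: np.ndarray, tmask: np.ndarray, pos: int,
                         max_mismatch: int, max_indel: int):
    """Enumerate anchored primer-vs-template alignments starting at ``pos``.

    Yields (mismatches, indels, end) for every alignment within budget.
    Exhaustive over the small budget space; memoised on visited states.
    """
    m, n = len(pmask), len(tmask)
    seen: set[tuple[int, int, int, int]] = set()
    out: list[tuple[int, int, int]] = []

    stack = [(0, pos, 0, 0)]
    while stack:
        i, j, mm, ind = stack.pop()
        if (i, j, mm, ind) in seen:
            continue
        seen.add((i, j, mm, ind))
        if i == m:
            if j > pos and j <= n:
                out.append((mm, ind, j))
            continue
        # consume one template base (match or substitution)
        if j < n:
            cost = 0 if (pmask[i] & tmask[j]) else 1
            if mm + cost <= max_mismatch:
                stack.append((i + 1, j + 1, mm + cost, ind))
        if ind < max_indel:
            # deletion: primer base aligned to a gap
            stack.append((i + 1, j, mm, ind + 1))
            # insertion: template base skipped
            if j < n:
                stack.append((i, j + 1, mm, ind + 1))
    return out


def iupac_match_at(primer: Primer, template: str, position: int,
                   max_mismatch: int = 1, max_indel: int = 1,
                   template_id: str = "", strand: str = "+",
                   ) -> PrimerMatch | None:
    """Best primer match anchored at ``position``, or None.

    Among in-budget alignments the one with fewest total edits, then fewest
    indels, then smallest end coordinate is returned.
    """
    if max_mismatch < 0 or max_indel < 0:
        raise ValueError("budgets must be >= 0")
    if not (0 <= position < len(template)):
        raise ValueError("position outside template")
    pmask = encode_mask(primer.sequence)
    tmask = encode_template_mask(template)
    cands = _anchored_alignments(pmask, tmask, position,
                                 max_mismatch, max_indel)
    if not cands:
        return None
    mm, ind, end = min(cands, key=lambda c: (c[0] + c[1], c[1], c[2]))
    return PrimerMatch(template_id, position, end, strand, mm, ind)


def _scan_strand_fast(pmask: np.ndarray, tmask: np.ndarray,
                      max_mismatch: int, max_indel: int,
                      ) -> list[tuple[int, int, int, int]]:
    """Vectorised single-strand scan for budgets with ``max_indel <= 1``.

    With at most one indel every anchored alignment is "exact shift up to a
    split point s, then shift +-1", so per-position minimum mismatch counts
    follow from prefix sums of three shifted mismatch matrices.  Returns
    (start, end, mismatches, indels) tuples, one best per start position.
    """
    m, n = len(pmask), len(tmask)
    if n == 0:
        return []
    pad = np.zeros(n + m + 2, dtype=np.uint8)
    pad[:n] = tmask
    pos = np.arange(n)
    idx = pos[None, :] + np.arange(m)[:, None]          # (m, n)
    mis0 = ((pmask[:, None] & pad[idx]) == 0).astype(np.int32)
    mis_p = ((pmask[:, None] & pad[idx + 1]) == 0).astype(np.int32)
    mis_m = ((pmask[:, None] & pad[np.maximum(idx - 1, 0)]) == 0).astype(np.int32)

    z = np.zeros((1, n), dtype=np.int32)
    c0 = np.concatenate([z, np.cumsum(mis0, axis=0)])    # c0[i] = mm of p[:i]
    cp = np.concatenate([z, np.cumsum(mis_p, axis=0)])
    cm = np.concatenate([z, np.cumsum(mis_m, axis=0)])

    ham0 = c0[m]                                         # no indel
    # insertion of template base at split s in 0..m-1: p[:s] shift0, skip
    # t[pos+s], p[s:] at shift +1
    s = np.arange(m)[:, None]
    ins = c0[:m] + (cp[m][None, :] - cp[:m][np.arange(m)])
    ins_mm = ins.min(axis=0)
    # deletion: primer base s gapped: p[:s] shift0, p[s+1:] at shift -1
    dele = c0[:m] + (cm[m][None, :] - cm[1:m + 1][np.arange(m)])
    del_mm = dele.min(axis=0)

    out = []
    for p in range(n):
        cands = []
        if ham0[p] <= max_mismatch and p + m <= n:
            cands.append((int(ham0[p]), 0, p + m))
        if max_indel >= 1:
            if ins_mm[p] <= max_mismatch and p + m + 1 <= n:
                cands.append((int(ins_mm[p]), 1, p + m + 1))
            if del_mm[p] <= max_mismatch and p + m - 1 <= n:
                cands.append((int(del_mm[p]), 1, p + m - 1))
        if cands:
            mm, ind, end = min(cands, key=lambda c: (c[0] + c[1], c[1], c[2]))
            out.append((p, end, mm, ind))
    return out


def _dedupe(matches: list[PrimerMatch]) -> list[PrimerMatch]:
    """Collapse overlapping same-strand matches: keep lowest-edit, then
    leftmost."""
    out: list[PrimerMatch] = []
    for strand in ("+", "-"):
        group: list[PrimerMatch] = []
        for mt in sorted((m for m in matches if m.strand == strand),
                         key=lambda m: (m.start, m.end)):
            if group and mt.start < max(g.end for g in group):
                group.append(mt)
            else:
                if group:
                    out.append(min(group,
                                   key=lambda g: (g.edits, g.start, g.indels)))
                group = [mt]
        if group:
            out.append(min(group, key=lambda g: (g.edits, g.start, g.indels)))
    return sorted(out, key=lambda m: (m.start, m.strand))


def scan_template(primer: Primer, template: str,
                  max_mismatch: int = 1, max_indel: int = 1,
                  template_id: str = "", dedupe: bool = True,
                  ) -> list[PrimerMatch]:
    """All primer sites on both strands, sorted by start coordinate.

    Reverse-strand sites are matches of the primer against the reverse
    complement, reported in forward-strand coordinates.  Overlapping
    same-strand matches at adjacent offsets are deduplicated (lowest edit
    count, then leftmost) unless ``dedupe=False``.
    """
    if not template:
        return []
    template = template.upper()
    pmask = encode_mask(primer.sequence)
    matches: list[PrimerMatch] = []

    def one_strand(tseq: str, strand: str) -> None:
        tmask = encode_template_mask(tseq)
        n = len(tseq)
        if max_indel <= 1:
            raw = _scan_strand_fast(pmask, tmask, max_mismatch, max_indel)
        else:
            raw = []
            for p in range(n):
                cands = _anchored_alignments(pmask, tmask, p,
                                             max_mismatch, max_indel)
                if cands:
                    mm, ind, end = min(cands,
                                       key=lambda c: (c[0] + c[1], c[1], c[2]))
                    raw.append((p, end, mm, ind))
        for p, end, mm, ind in raw:
            if strand == "+":
                matches.append(PrimerMatch(template_id, p, end, "+", mm, ind))
            else:
                matches.append(PrimerMatch(template_id, n - end, n - p,
                                           "-", mm, ind))

    one_strand(template, "+")
    one_strand(reverse_complement(template), "-")
    if dedupe:
        return _dedupe(matches)
    return sorted(matches, key=lambda m: (m.start, m.strand))


def amplify(pair: tuple[Primer, Primer], template: str,
            max_mismatch: int = 1, max_indel: int = 1,
            max_len: int = 5000, template_id: str = "",
            pairing: str = "nearest") -> list[Amplicon]:
    """Virtual PCR of a forward/reverse primer pair on one template.

    A product arises from a forward-primer site and a reverse-primer site on
    the opposite strand downstream.  Under ``pairing="nearest"`` (PCR's
    dominant short product) each forward site pairs only with the closest
    compatible reverse site; ``pairing="all"`` reports every compatible
    combination with length <= ``max_len`` (useful for anomaly hunting).
    Both template orientations are considered; minus-orientation product
    sequences are reverse complemented so they always begin with the
    forward primer footprint.
    """
    fwd, rev = pair
    if max_len <= len(fwd) + len(rev):
        raise ValueError("max_len must exceed combined primer length")
    template = template.upper()
    fsites = scan_template(fwd, template, max_mismatch, max_indel, template_id)
    rsites = scan_template(rev, template, max_mismatch, max_indel, template_id)

    products: list[Amplicon] = []

    def emit(f: PrimerMatch, r: PrimerMatch, orient: str) -> None:
        if orient == "+":
            seq = template[f.start:r.end]
        else:
            seq = reverse_complement(template[r.start:f.end])
        products.append(Amplicon(template_id, f, r, seq, orient))

    # plus orientation: forward site (+) upstream of reverse site (-)
    r_minus = sorted((r for r in rsites if r.strand == "-"),
                     key=lambda r: r.start)
    for f in (f for f in fsites if f.strand == "+"):
        compat = [r for r in r_minus
                  if r.start >= f.end and r.end - f.start <= max_len]
        if not compat:
            continue
        if pairing == "nearest":
            emit(f, compat[0], "+")
        else:
            for r in compat:
                emit(f, r, "+")

    # minus orientation: reverse site (+) upstream of forward site (-)
    r_plus = sorted((r for r in rsites if r.strand == "+"),
                    key=lambda r: r.start, reverse=True)
    for f in (f for f in fsites if f.strand == "-"):
        compat = [r for r in r_plus
                  if r.end <= f.start and f.end - r.start <= max_len]
        if not compat:
            continue
        if pairing == "nearest":
            emit(f, compat[0], "-")
        else:
            for r in compat:
                emit(f, r, "-")

    products.sort(key=lambda a: (a.start, a.end))
    return products


def evaluate_primer_pair(pair: tuple[Primer, Primer],
                         targets: Mapping[str, str],
                         negatives: Mapping[str, str] | None = None,
                         expected_length_window: tuple[int, int] | None = None,
                         max_mismatch: int = 1, max_indel: int = 1,
                         max_len: int = 5000,
                         collection_id: str = "targets",
                         ) -> PrimerPairMetrics:
    """Benchmark a primer pair over target and negative-control collections.

    A template counts as amplified iff it yields at least one product;
    target products outside ``expected_length_window`` are recorded as
    length anomalies.
    """
    if not targets:
        raise ValueError("target collection is empty")
    negatives = negatives or {}
    metrics = PrimerPairMetrics(collection_id=collection_id,
                                n_templates=len(targets), n_amplified=0,
                                n_negative_templates=len(negatives))
    for tid, seq in targets.items():
        amps = amplify(pair, seq, max_mismatch, max_indel, max_len, tid)
        if amps:
            metrics.n_amplified += 1
            if expected_length_window is not None:
                lo, hi = expected_length_window
                for a in amps:
                    if not lo <= a.length <= hi:
                        metrics.length_anomalies.append((tid, a.length))
    for tid, seq in negatives.items():
        if amplify(pair, seq, max_mismatch, max_indel, max_len, tid):
            metrics.n_negative_amplified += 1
    return metrics
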