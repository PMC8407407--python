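"""Primer-trimmed, taxonomy-labelled amplicon reference database.

The classifier assigns read pairs to species by aligning them against a
database of reference amplicons.  Each reference is the virtual PCR
product of the chosen primer pair on one source gene/genome, with both
primer footprints trimmed away, labelled with species / group / subgroup
taxonomy (the hierarchical Pseudomonas framework of groups such as
P. fluorescens and subgroups such as P. jessenii).

Because the paired reads do not overlap, no OTU clustering is done at
classification time; identity clustering is used only to *audit* the
database: species whose references exceed a similarity threshold (97% by
default) land in one cluster and are mutually confusable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np

from .iupac_pcr import Primer, amplify

_HEADER_SEP = "|"


@dataclass(frozen=True)
class TaxonomyRecord:
    """Species-level taxonomy with optional group/subgroup membership."""

    species: str
    group: str = ""
    subgroup: str = ""
    type_strain: bool = False


@dataclass(frozen=True)
class AmpliconRecord:
    """One primer-trimmed reference sequence with its taxonomy."""

    record_id: str
    taxonomy: TaxonomyRecord
    sequence: str
    source_template_id: str = ""

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def species(self) -> str:
        return self.taxonomy.species

    def header(self) -> str:
        """The FASTA header dialect shared across the toolkit."""
        parts = [self.record_id, self.taxonomy.species,
                 self.taxonomy.group, self.taxonomy.subgroup]
        if any(_HEADER_SEP in p for p in parts):
            raise ValueError(f"'{_HEADER_SEP}' not allowed in header fields")
        return _HEADER_SEP.join(p.replace(" ", "_") for p in parts)


def record_from_header(header: str, sequence: str) -> AmpliconRecord:
    """Parse an ``id|species|group|subgroup`` FASTA header."""
    parts = header.split(_HEADER_SEP)
    if len(parts) != 4:
        raise ValueError(f"malformed database header {header!r} "
                         "(expected id|species|group|subgroup)")
    rid, species, group, subgroup = parts
    return AmpliconRecord(rid, TaxonomyRecord(species, group, subgroup),
                          sequence.upper(), rid)


class AmpliconDatabase:
    """Indexed collection of reference amplicons."""

    def __init__(self, records: Sequence[AmpliconRecord]):
        if not records:
            raise ValueError("database must contain at least one record")
        ids = [r.record_id for r in records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record ids in database")
        self.records = list(records)
        self.by_id = {r.record_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def species_of(self, record_id: str) -> str:
        return self.by_id[record_id].species

    @property
    def species(self) -> list[str]:
        return sorted({r.species for r in self.records})


def build_database(templates: Mapping[str, str],
                   taxonomy: Mapping[str, TaxonomyRecord],
                   pair: tuple[Primer, Primer],
                   max_mismatch: int = 1, max_indel: int = 1,
                   max_len: int = 5000,
                   length_window: tuple[int, int] | None = None,
                   ) -> tuple[AmpliconDatabase, list[str]]:
    """Virtually amplify every template and keep one trimmed product each.

    Per template the shortest product (ties: first) is retained, primers
    trimmed.  Templates yielding no product — or only products outside
    ``length_window`` — are returned in the rejects list.  Every template
    id must have a taxonomy row.
    """
    missing = [t for t in templates if t not in taxonomy]
    if missing:
        raise ValueError(f"templates missing taxonomy rows: {missing[:5]}")
    records: list[AmpliconRecord] = []
    rejects: list[str] = []
    for tid, seq in templates.items():
        amps = amplify(pair, seq, max_mismatch, max_indel, max_len, tid)
        if length_window is not None:
            lo, hi = length_window
            amps = [a for a in amps if lo <= a.length <= hi]
        if not amps:
            rejects.append(tid)
            continue
        best = min(amps, key=lambda a: (a.length, a.start))
        records.append(AmpliconRecord(tid, taxonomy[tid],
                                      best.trimmed_sequence, tid))
    if not records:
        raise ValueError("no template produced an amplicon")
    return AmpliconDatabase(records), rejects


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment columns.

    Unit-cost global (Needleman-Wunsch) alignment; the denominator counts
    every alignment column including gap columns, a conservative choice.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    res = edlib.align(a.upper(), b.upper(), mode="NW", task="path")
    columns = sum(int(n) for n, op in _parse_cigar(res["cigar"]))
    return (columns - res["editDistance"]) / columns


def _parse_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield num, ch
            num = ""


def cluster_at_threshold(records: Sequence[AmpliconRecord],
                         threshold: float = 0.97,
                         ) -> list[list[AmpliconRecord]]:
    """Greedy length-ordered identity clustering.

    Records are seeded in order of descending length (ties broken
    lexicographically by id); each record joins the first existing centroid
    with identity >= ``threshold``, otherwise founds a new cluster.  The
    ordering rule makes the result deterministic.
    """
    if not records:
        raise ValueError("no records to cluster")
    ordered = sorted(records, key=lambda r: (-len(r), r.record_id))
    centroids: list[AmpliconRecord] = []
    clusters: list[list[AmpliconRecord]] = []
    for rec in ordered:
        for i, c in enumerate(centroids):
            if pairwise_identity(rec.sequence, c.sequence) >= threshold:
                clusters[i].append(rec)
                break
        else:
            centroids.append(rec)
            clusters.append([rec])
    return clusters


@dataclass
class DiscriminabilityReport:
    """Which species the database can resolve at a similarity threshold."""

    threshold: float
    resolvable: dict[str, bool]
    confusable_sets: list[set[str]] = field(default_factory=list)


def discriminability_report(records: Sequence[AmpliconRecord],
                            threshold: float = 0.97,
                            ) -> DiscriminabilityReport:
    """Flag species whose references co-cluster at ``threshold``.

    Species sharing a cluster with another species are mutually confusable
    (e.g. near-identical P. putida / P. monteilii reference pairs); all
    others are resolvable.
    """
    clusters = cluster_at_threshold(records, threshold)
    confusable: list[set[str]] = []
    unresolved: set[str] = set()
    for cl in clusters:
        species = {r.species for r in cl}
        if len(species) > 1:
            confusable.append(species)
            unresolved |= species
    resolvable = {sp: sp not in unresolved
                  for sp in sorted({r.species for r in records})}
    return DiscriminabilityReport(threshold, resolvable, confusable)
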