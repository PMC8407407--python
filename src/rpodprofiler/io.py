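"""Format readers and writers shared by all pipeline stages.

FASTA/FASTQ go through Biopython; abundance tables are TSV with samples
as rows and species as columns.  The reference-database FASTA header
dialect is ``>id|species|group|subgroup`` (spaces within a field written
as underscores) — the single cross-module contract between database
construction and classification.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .amplicon_db import AmpliconDatabase, AmpliconRecord, record_from_header
from .classifier import AbundanceTable, Assignment, ReadPair

_WRAP = 80


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> dict[str, str]:
    """Read a (possibly gzipped) FASTA into an ordered id -> sequence map.

    Sequences are uppercased; duplicate ids and empty sequences are
    rejected by name.
    """
    records: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in records:
                raise ValueError(f"duplicate FASTA id {rec.id!r}")
            seq = str(rec.seq).upper()
            if not seq:
                raise ValueError(f"empty sequence for record {rec.id!r}")
            records[rec.id] = seq
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: dict[str, str] | Iterable[tuple[str, str]],
                path) -> None:
    """Write FASTA wrapped at 80 columns (gzip if the path ends in .gz)."""
    items = records.items() if isinstance(records, dict) else records
    with _open_text(path, "wt") as fh:
        for rid, seq in items:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), _WRAP):
                fh.write(seq[i:i + _WRAP] + "\n")


def write_database(db: AmpliconDatabase, fasta_path,
                   taxonomy_path=None) -> None:
    """Serialize a reference database with ``id|species|group|subgroup``
    headers, plus an optional sidecar taxonomy TSV."""
    write_fasta(((r.header(), r.sequence) for r in db), fasta_path)
    if taxonomy_path is not None:
        rows = [{"record_id": r.record_id, "species": r.species,
                 "group": r.taxonomy.group, "subgroup": r.taxonomy.subgroup,
                 "type_strain": r.taxonomy.type_strain} for r in db]
        pd.DataFrame(rows).to_csv(taxonomy_path, sep="\t", index=False)


def read_database(fasta_path) -> AmpliconDatabase:
    """Load a reference database from its header-dialect FASTA."""
    raw = read_fasta(fasta_path)
    return AmpliconDatabase([record_from_header(h, s)
                             for h, s in raw.items()])


def read_fastq_paired(r1_path, r2_path) -> Iterator[ReadPair]:
    """Stream synchronized paired FASTQ files as ReadPair objects.

    Mate ids must agree up to a trailing ``/1``/``/2``; a length mismatch
    between the files is reported at the offending record index.
    """
    def strip(rid: str) -> str:
        return rid[:-2] if rid.endswith(("/1", "/2")) else rid

    with _open_text(r1_path) as f1, _open_text(r2_path) as f2:
        it1 = SeqIO.parse(f1, "fastq")
        it2 = SeqIO.parse(f2, "fastq")
        i = 0
        while True:
            rec1 = next(it1, None)
            rec2 = next(it2, None)
            if rec1 is None and rec2 is None:
                return
            if rec1 is None or rec2 is None:
                short = r2_path if rec2 is None else r1_path
                raise ValueError(f"paired FASTQ out of sync: {short} "
                                 f"truncated at record index {i}")
            id1, id2 = strip(rec1.id), strip(rec2.id)
            if id1 != id2:
                raise ValueError(f"mate id mismatch at record {i}: "
                                 f"{rec1.id!r} vs {rec2.id!r}")
            yield ReadPair(id1, str(rec1.seq).upper(),
                           rec1.letter_annotations["phred_quality"],
                           str(rec2.seq).upper(),
                           rec2.letter_annotations["phred_quality"])
            i += 1


def write_fastq_paired(pairs: Iterable[ReadPair], r1_path, r2_path) -> None:
    with _open_text(r1_path, "wt") as f1, _open_text(r2_path, "wt") as f2:
        for p in pairs:
            for fh, seq, qual, mate in ((f1, p.seq1, p.qual1, 1),
                                        (f2, p.seq2, p.qual2, 2)):
                rec = SeqRecord(Seq(seq), id=f"{p.pair_id}/{mate}",
                                description="")
                rec.letter_annotations["phred_quality"] = list(qual)
                SeqIO.write(rec, fh, "fastq")


def read_abundance_table(path) -> AbundanceTable:
    """Read a samples x species TSV (header row mandatory, first column =
    sample id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.empty or df.index.name is None:
        raise ValueError("abundance table must have a header row with a "
                         "sample-id column")
    if (df.values < 0).any():
        raise ValueError("negative values in abundance table")
    df.index = df.index.astype(str)
    df.index.name = "sample"
    return AbundanceTable(df, "raw")


def write_abundance_table(table: AbundanceTable, path) -> None:
    """Write the table as TSV preserving >= 6 significant digits."""
    table.data.to_csv(path, sep="\t", float_format="%.10g")


def write_assignments(assignments: Iterable[Assignment], path) -> None:
    rows = [{"pair_id": a.pair_id, "status": a.status,
             "species": a.species or "", "reference_id": a.reference_id or "",
             "q": a.q} for a in assignments]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_barcodes(path) -> dict[str, str]:
    """Barcode sheet TSV with columns sample, barcode."""
    df = pd.read_csv(path, sep="\t")
    if not {"sample", "barcode"} <= set(df.columns):
        raise ValueError("barcode sheet needs 'sample' and 'barcode' columns")
    return dict(zip(df["sample"].astype(str),
                    df["barcode"].astype(str).str.upper()))


def read_primer_sheet(path) -> dict[str, tuple[str, str]]:
    """Primer sheet TSV with columns name, sequence, role."""
    df = pd.read_csv(path, sep="\t")
    need = {"name", "sequence", "role"}
    if not need <= set(df.columns):
        raise ValueError("primer sheet needs name/sequence/role columns")
    return {str(r["name"]): (str(r["sequence"]), str(r["role"]))
            for _, r in df.iterrows()}


def write_run_log(log: dict, path) -> None:
    """Machine-readable per-stage counts for post-hoc conservation audits."""
    with open(path, "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")
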