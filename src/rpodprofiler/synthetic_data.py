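"""Synthetic fixtures: reference databases, primer-bearing templates, and
error-bearing paired amplicon reads with ground truth.

The generator emulates the study design this toolkit targets: a reference
database of 166 species-level amplicon sequences (736 nt, the
PsEG30F/PsEG790R product size), non-overlapping 2x300 nt paired reads with
independent substitution errors, and mock (equimolar) or soil-like
(log-normal) community mixtures.  Sequences are evolved from a single
random ancestor by per-site substitution until a minimum pairwise
divergence is reached, which gives direct control over how confusable the
database is.  Every output is reproducible bit-for-bit from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .amplicon_db import AmpliconDatabase, AmpliconRecord, TaxonomyRecord
from .classifier import ReadPair
from .iupac_pcr import Primer, expand_iupac, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def uncovered_interior_gap(amplicon_length: int, read_length: int) -> int:
    """Interior bases of an amplicon covered by neither mate of a pair.

    For a 760 nt amplicon and 2x300 nt reads this is 160 nt; non-positive
    values mean the mates overlap.
    """
    if amplicon_length <= 0 or read_length <= 0:
        raise ValueError("lengths must be positive")
    return amplicon_length - 2 * read_length


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Defaults mirror the targeted design: a 166-entry database of 736 nt
    amplicons at >= 3% minimum pairwise divergence, 2x300 nt reads with a
    0.5% substitution error rate, and 16,000 pairs per sample (1,000 per
    species of a 16-member mock community).
    """

    seed: int
    n_species: int = 166
    divergence: float = 0.03        # minimum pairwise divergence (fraction)
    amplicon_length: int = 736
    read_length: int = 300
    error_rate: float = 0.005       # per-base substitution probability
    reads_per_sample: int = 16_000
    profile: str = "equimolar"      # equimolar | specified | lognormal
    specified_proportions: tuple[float, ...] | None = None
    lognormal_sigma: float = 1.5
    base_quality: int = 37
    quality_decay: int = 0          # linear 3' drop in Phred units
    flank: int = 200                # template flank length for implantation

    def __post_init__(self) -> None:
        if not 0.0 < self.divergence < 1.0:
            raise ValueError("divergence must be in (0, 1)")
        if self.read_length > self.amplicon_length:
            raise ValueError("read length must not exceed amplicon length")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error rate must be in [0, 1)")


@dataclass
class GroundTruth:
    """What the simulator actually emitted, for recovery checks."""

    proportions: dict[str, float]        # species -> intended proportion
    read_sources: dict[str, str]         # pair id -> source record id
    pair_counts: dict[str, int]          # record id -> pairs emitted

    def species_pair_counts(self, db: AmpliconDatabase) -> dict[str, int]:
        out: dict[str, int] = {}
        for rid, n in self.pair_counts.items():
            sp = db.species_of(rid)
            out[sp] = out.get(sp, 0) + n
        return out


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: np.ndarray,
            rate: float) -> np.ndarray:
    """Substitute each site with probability ``rate`` (always to a
    different base)."""
    out = seq.copy()
    hit = np.nonzero(rng.random(len(seq)) < rate)[0]
    if len(hit):
        shift = rng.integers(1, 4, size=len(hit))
        out[hit] = (out[hit] + shift) % 4
    return out


def simulate_reference_db(config: SimulationConfig,
                          ) -> tuple[AmpliconDatabase, str]:
    """Evolve ``n_species`` amplicon references from one random ancestor.

    Per-site substitutions are applied independently per species at a rate
    chosen to exceed the requested minimum pairwise divergence; the draw
    is repeated (still seed-deterministic) until the realised minimum
    divergence meets the target.  Taxonomy labels with a group/subgroup
    hierarchy are synthesised.  Returns the database and the ancestor.
    """
    if config.divergence > 0.35:
        # two independently mutated lineages saturate near 75% divergence;
        # beyond ~2*0.35 the retry loop cannot be expected to converge
        raise ValueError(f"unreachable divergence target "
                         f"{config.divergence}")
    rng = np.random.default_rng(config.seed)
    ancestor = rng.choice(4, size=config.amplicon_length).astype(np.uint8)
    mu = min(0.45, config.divergence * 1.2)
    for _attempt in range(20):
        seqs = np.stack([_mutate(rng, ancestor, mu)
                         for _ in range(config.n_species)])
        if config.n_species == 1:
            break
        div = _min_pairwise_divergence(seqs)
        if div >= config.divergence:
            break
    else:
        raise ValueError(f"unreachable divergence target "
                         f"{config.divergence} after 20 draws")
    records = []
    n_groups = max(1, min(8, config.n_species // 4 or 1))
    for i in range(config.n_species):
        group = f"Group_{chr(ord('A') + i % n_groups)}"
        subgroup = f"{group}_sg{i % 3}" if i % 3 != 2 else ""
        records.append(AmpliconRecord(
            record_id=f"SP{i + 1:03d}",
            taxonomy=TaxonomyRecord(f"Species_{i + 1:03d}", group, subgroup,
                                    type_strain=True),
            sequence=_BASES[seqs[i]].tobytes().decode(),
            source_template_id=f"T{i + 1:03d}"))
    return AmpliconDatabase(records), _BASES[ancestor].tobytes().decode()


def _min_pairwise_divergence(seqs: np.ndarray) -> float:
    n, length = seqs.shape
    best = 1.0
    for i in range(n - 1):
        diff = (seqs[i + 1:] != seqs[i]).mean(axis=1)
        best = min(best, float(diff.min()))
    return best


def implant_primer_sites(record: AmpliconRecord,
                         pair: tuple[Primer, Primer],
                         flank: int = 200,
                         seed: int = 0,
                         ablate_forward: bool = False) -> str:
    """Wrap a reference in a template that the primer pair amplifies.

    template = random 5' flank + concrete forward site + record sequence +
    reverse-complemented concrete reverse site + random 3' flank.  Virtual
    PCR on the result yields exactly one product of length
    ``len(record) + len(fwd) + len(rev)``.  ``ablate_forward`` replaces the
    forward site with random bases to build non-amplifiable templates.
    """
    fwd, rev = pair
    rng = np.random.default_rng(seed)
    fwd_choices = sorted(expand_iupac(fwd.sequence))
    rev_choices = sorted(expand_iupac(rev.sequence))
    fwd_site = fwd_choices[rng.integers(len(fwd_choices))]
    rev_site = rev_choices[rng.integers(len(rev_choices))]
    if ablate_forward:
        fwd_site = _random_sequence(rng, len(fwd_site))
    left = _random_sequence(rng, flank)
    right = _random_sequence(rng, flank)
    return (left + fwd_site + record.sequence
            + reverse_complement(rev_site) + right)


def simulate_community_profile(config: SimulationConfig,
                               n_species: int | None = None,
                               ) -> np.ndarray:
    """Species proportions for one sample, summing to 1.

    ``equimolar`` gives 1/n each; ``specified`` echoes (and renormalises)
    the configured proportions; ``lognormal`` draws a rank-skewed,
    soil-like profile with the configured sigma.
    """
    n = n_species if n_species is not None else config.n_species
    if config.profile == "equimolar":
        return np.full(n, 1.0 / n)
    if config.profile == "specified":
        if config.specified_proportions is None:
            raise ValueError("specified profile requires proportions")
        p = np.asarray(config.specified_proportions, dtype=float)
        if (p < 0).any():
            raise ValueError("proportions must be non-negative")
        if p.sum() == 0:
            raise ValueError("proportions sum to zero")
        return p / p.sum()
    if config.profile == "lognormal":
        rng = np.random.default_rng(config.seed)
        draws = rng.lognormal(mean=0.0, sigma=config.lognormal_sigma, size=n)
        return draws / draws.sum()
    raise ValueError(f"unknown profile kind {config.profile!r}")


def _apportion(proportions: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder rounding of ``proportions * total`` to integers."""
    raw = proportions * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:short]] += 1
    return base


def simulate_read_pairs(records: Sequence[AmpliconRecord],
                        proportions: Sequence[float],
                        config: SimulationConfig,
                        sample: str = "S1",
                        barcode: str | None = None,
                        ) -> tuple[list[ReadPair], GroundTruth]:
    """Paired reads from a set of reference amplicons with ground truth.

    mate 1 is the first ``read_length`` nt of the amplicon and mate 2 the
    reverse complement of the last ``read_length`` nt (non-overlapping for
    amplicons longer than twice the read length).  Substitution errors are
    i.i.d. per base at ``error_rate``; qualities are constant at
    ``base_quality`` with an optional linear 3' decay.  ``barcode`` is
    prepended to mate 1 for demultiplexing fixtures.
    """
    p = np.asarray(proportions, dtype=float)
    if len(p) != len(records):
        raise ValueError("one proportion per record required")
    if (p < 0).any() or p.sum() == 0:
        raise ValueError("invalid proportions")
    p = p / p.sum()
    rl = config.read_length
    for rec in records:
        if len(rec.sequence) < rl:
            raise ValueError(f"amplicon {rec.record_id} shorter than "
                             f"read length {rl}")
    rng = np.random.default_rng(config.seed + 1)
    counts = _apportion(p, config.reads_per_sample)

    qual = np.full(rl, config.base_quality, dtype=int)
    if config.quality_decay:
        qual = qual - np.round(
            np.linspace(0, config.quality_decay, rl)).astype(int)
    qual_list = qual.tolist()
    bc_qual = ([config.base_quality] * len(barcode) if barcode else [])

    pairs: list[ReadPair] = []
    sources: dict[str, str] = {}
    k = 0
    for rec, n in zip(records, counts):
        if n == 0:
            continue
        fwd = _align_codes(rec.sequence[:rl])
        rev = _align_codes(reverse_complement(rec.sequence[-rl:]))
        m1 = np.tile(fwd, (n, 1))
        m2 = np.tile(rev, (n, 1))
        for mat in (m1, m2):
            hit = rng.random(mat.shape) < config.error_rate
            shift = rng.integers(1, 4, size=mat.shape)
            mat[hit] = (mat[hit] + shift[hit]) % 4
        for row1, row2 in zip(m1, m2):
            pid = f"{sample}_p{k:06d}"
            k += 1
            s1 = _BASES[row1].tobytes().decode()
            s2 = _BASES[row2].tobytes().decode()
            if barcode:
                s1 = barcode + s1
                q1 = bc_qual + qual_list
            else:
                q1 = qual_list
            pairs.append(ReadPair(pid, s1, q1, s2, qual_list, sample))
            sources[pid] = rec.record_id
    truth = GroundTruth(
        proportions={rec.species: float(pi)
                     for rec, pi in zip(records, p)},
        read_sources=sources,
        pair_counts={rec.record_id: int(n)
                     for rec, n in zip(records, counts)})
    return pairs, truth


def _align_codes(seq: str) -> np.ndarray:
    lookup = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lookup[ord(b)] = i
    return lookup[np.frombuffer(seq.encode(), dtype=np.uint8)].astype(np.int64)


def mock16(config: SimulationConfig,
           ) -> tuple[AmpliconDatabase, list[AmpliconRecord],
                      list[ReadPair], GroundTruth]:
    """The 16-member mock-community preset.

    Builds the full reference database, picks 16 well-spread members
    (seed-deterministic), and simulates an equimolar paired-read sample
    from them.  Returns (database, chosen records, pairs, ground truth).
    """
    db, _ = simulate_reference_db(config)
    rng = np.random.default_rng(config.seed + 2)
    if len(db) < 16:
        raise ValueError("mock16 needs a database of >= 16 records")
    chosen_idx = sorted(rng.choice(len(db), size=16, replace=False))
    chosen = [db.records[i] for i in chosen_idx]
    proportions = np.full(16, 1.0 / 16)
    pairs, truth = simulate_read_pairs(chosen, proportions, config,
                                       sample="mock")
    return db, chosen, pairs, truth
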