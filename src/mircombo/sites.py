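"""Canonical miRNA seed-site scanning of transcript sequences.

Canonical target sites are perfect Watson-Crick matches in the target to the
miRNA seed (positions 2-8, counted 1-based from the miRNA 5' end):

* ``8mer``     -- match to positions 2-8 followed by an adenine across from
  miRNA position 1 (the "A1" anchor);
* ``7mer-m8``  -- match to positions 2-8, no A1 anchor;
* ``7mer-A1``  -- match to positions 2-7 plus the A1 anchor;
* ``6mer``     -- match to positions 2-7 only (off by default; high
  false-positive rate).

Only the provided (sense) strand is scanned; no wobble pairing, 3'
supplementary pairing or energy model is applied. Coordinates are 0-based
half-open on the target sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

DEFAULT_SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")
ALL_SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")

SITE_LENGTH = {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7, "6mer": 6}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class SequenceAlphabetError(ValueError):
    """A sequence contains a character outside the nucleotide alphabet."""


@dataclass(frozen=True)
class SeedSite:
    """One canonical seed match on a target sequence."""

    sequence_id: str
    mirna: str
    site_type: str
    start: int
    end: int
    matched_subsequence: str


def normalize_sequence(seq: str, *, name: str = "sequence") -> str:
    """Uppercase and convert RNA to DNA alphabet; reject anything else."""
    out = seq.upper().replace("U", "T")
    for pos, ch in enumerate(out):
        if ch not in "ACGT":
            raise SequenceAlphabetError(
                f"{name} has non-nucleotide character {ch!r} at position {pos}"
            )
    return out


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def seed_match_core(mirna_seq: str) -> str:
    """Reverse complement of seed positions 2-7: the 6mer core every
    canonical site contains."""
    m = normalize_sequence(mirna_seq, name="miRNA")
    if len(m) < 8:
        raise ValueError(f"miRNA sequence must be >= 8 nt, got {len(m)}")
    return reverse_complement(m[1:7])


def scan_sites(
    mirna_seq: str,
    target_seq: str,
    *,
    mirna: str = "miRNA",
    sequence_id: str = "target",
    types: Sequence[str] = DEFAULT_SITE_TYPES,
    ) -> list[SeedSite]:
    """Report every canonical seed match of ``mirna_seq`` on ``target_seq``.

    All occurrences are reported, including overlapping ones, in
    left-to-right order of their start coordinate. Each 6mer-core occurrence
    is classified into exactly one site type by the presence of the m8 match
    (target base pairing miRNA position 8, immediately 5' of the core on the
    target) and of the A1 anchor (adenine immediately 3' of the core).
    """
    bad = set(types) - set(ALL_SITE_TYPES)
    if bad:
        raise ValueError(f"unknown site types: {sorted(bad)}")
    m = normalize_sequence(mirna_seq, name="miRNA")
    if len(m) < 8:
        raise ValueError(f"miRNA sequence must be >= 8 nt, got {len(m)}")
    t = normalize_sequence(target_seq, name=f"sequence {sequence_id!r}")

    core = reverse_complement(m[1:7])  # pairs positions 2-7
    m8_base = m[7].translate(_COMPLEMENT)  # target base pairing position 8

    sites: list[SeedSite] = []
    i = t.find(core)
    while i != -1:
        has_m8 = i > 0 and t[i - 1] == m8_base
        has_a1 = i + 6 < len(t) and t[i + 6] == "A"
        if has_m8 and has_a1:
            site_type, start, end = "8mer", i - 1, i + 7
        elif has_m8:
            site_type, start, end = "7mer-m8", i - 1, i + 6
        elif has_a1:
            site_type, start, end = "7mer-A1", i, i + 7
        else:
            site_type, start, end = "6mer", i, i + 6
        if site_type in types:
            sites.append(
                SeedSite(sequence_id, mirna, site_type, start, end, t[start:end])
            )
        i = t.find(core, i + 1)
    sites.sort(key=lambda s: (s.start, s.mirna, s.site_type))
    return sites


def _as_sequence_dict(sequences) -> dict[str, str]:
    """Accept a FASTA path, an iterable of SeqRecords, or a mapping."""
    if isinstance(sequences, Mapping):
        return {str(k): str(v) for k, v in sequences.items()}
    if isinstance(sequences, (str, Path)):
        records = SeqIO.parse(str(sequences), "fasta")
    else:
        records = sequences
    out = {}
    for rec in records:
        out[rec.id.split()[0] if " " in rec.id else rec.id] = str(rec.seq)
    return out


def scan_fasta(
    sequences,
    mirnas: Mapping[str, str],
    *,
    types: Sequence[str] = DEFAULT_SITE_TYPES,
) -> pd.DataFrame:
    """Scan every sequence for every miRNA; return a tidy site table."""
    seqs = _as_sequence_dict(sequences)
    rows = []
    for seq_id, seq in seqs.items():
        for name, mseq in mirnas.items():
            for s in scan_sites(
                mseq, seq, mirna=name, sequence_id=seq_id, types=types
            ):
                rows.append(s.__dict__)
    return pd.DataFrame(
        rows,
        columns=[
            "sequence_id",
            "mirna",
            "site_type",
            "start",
            "end",
            "matched_subsequence",
        ],
    )


def triple_targeted(
    sequences,
    mirnas: Mapping[str, str],
    *,
    types: Sequence[str] = DEFAULT_SITE_TYPES,
) -> tuple[list[str], pd.DataFrame]:
    """Sequences carrying at least one site for *each* supplied miRNA.

    Returns the sorted id list and a (sequence, miRNA) site-count table.
    """
    seqs = _as_sequence_dict(sequences)
    if not seqs:
        raise ValueError("no sequences supplied (empty FASTA?)")
    if len(mirnas) < 2:
        raise ValueError("need at least two miRNAs for an intersection")
    seeds = {seed_match_core(s) for s in mirnas.values()}
    if len(seeds) < len(mirnas):
        warnings.warn(
            "two or more miRNAs share an identical seed; their site sets "
            "are indistinguishable",
            stacklevel=2,
        )
    table = scan_fasta(seqs, mirnas, types=types)
    if table.empty:
        counts = pd.DataFrame(columns=["sequence_id", "mirna", "n_sites"])
        return [], counts
    counts = (
        table.groupby(["sequence_id", "mirna"], as_index=False)
        .size()
        .rename(columns={"size": "n_sites"})
    )
    per_seq = counts.groupby("sequence_id")["mirna"].nunique()
    ids = sorted(per_seq.index[per_seq == len(mirnas)])
    return ids, counts
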