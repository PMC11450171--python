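"""Candidate pools, ordered pair designs and construct references.

A screen starts from a pool of fixed-length candidate sequences (enhancers
spanning a wide activity range plus random negative controls).  Every
ordered 5'x3' combination of candidates, joined by a transcriptionally
inert spacer, forms one fusion construct; an n-candidate pool therefore
yields n^2 ordered pairs (enhancer/enhancer, enhancer/control,
control/enhancer and control/control).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CANDIDATE_LENGTH = 249
CLASSES = ("enhancer", "control")
PROGRAMS = ("developmental", "housekeeping", "shared", "inducible", "osc-specific", "none")
_META_COLUMNS = ["id", "cls", "program", "chrom", "start", "end", "assembly"]


@dataclass
class CandidateSequence:
    """One candidate sequence whose individual activity is inferred.

    ``cls`` distinguishes putative enhancers from random negative controls;
    ``program`` records the transcriptional program label.  ``origin`` fields
    are optional genome coordinates (0-based half-open).
    """

    id: str
    sequence: str
    cls: str = "enhancer"
    program: str = "none"
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    assembly: str | None = None
    variant_length: bool = False  # True for designed variants of non-standard length

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if set(self.sequence) - set("ACGT"):
            bad = sorted(set(self.sequence) - set("ACGT"))
            raise ValueError(f"candidate {self.id!r}: non-ACGT characters {bad}")
        if self.cls not in CLASSES:
            raise ValueError(f"candidate {self.id!r}: unknown class {self.cls!r}")
        if self.program not in PROGRAMS:
            raise ValueError(f"candidate {self.id!r}: unknown program {self.program!r}")
        if len(self.sequence) != CANDIDATE_LENGTH and not self.variant_length:
            raise ValueError(
                f"candidate {self.id!r}: length {len(self.sequence)} != {CANDIDATE_LENGTH} "
                "(set variant_length=True for designed variants)")


class Pool:
    """A collection of candidate sequences with unique ids."""

    def __init__(self, candidates: Iterable[CandidateSequence]):
        candidates = list(candidates)
        dup = [i for i, n in Counter(c.id for c in candidates).items() if n > 1]
        if dup:
            raise ValueError(f"duplicate candidate ids: {sorted(dup)}")
        if not candidates:
            raise ValueError("pool is empty")
        self._by_id = {c.id: c for c in candidates}

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self):
        return iter(self._by_id.values())

    def __getitem__(self, cid: str) -> CandidateSequence:
        return self._by_id[cid]

    def __contains__(self, cid: str) -> bool:
        return cid in self._by_id

    @property
    def ids(self) -> list[str]:
        return sorted(self._by_id)

    @property
    def control_ids(self) -> list[str]:
        return sorted(c.id for c in self if c.cls == "control")

    @property
    def enhancer_ids(self) -> list[str]:
        return sorted(c.id for c in self if c.cls == "enhancer")

    def sequences(self) -> dict[str, str]:
        return {c.id: c.sequence for c in self}

    def classes(self) -> pd.Series:
        return pd.Series({c.id: c.cls for c in self}, name="cls")

    @classmethod
    def from_fasta(cls, fasta: str | Path, meta: str | Path | None = None,
                   **candidate_kwargs) -> "Pool":
        meta_df = None
        if meta is not None:
            meta_df = pd.read_csv(meta, sep="\t", dtype={"id": str}).set_index("id")
        cands = []
        for rec in SeqIO.parse(str(fasta), "fasta"):
            kw = dict(candidate_kwargs)
            if meta_df is not None and rec.id in meta_df.index:
                row = meta_df.loc[rec.id]
                kw.update(cls=row.get("cls", "enhancer"), program=row.get("program", "none"))
                for key in ("chrom", "start", "end", "assembly"):
                    val = row.get(key)
                    if pd.notna(val):
                        kw[key] = int(val) if key in ("start", "end") else val
            cands.append(CandidateSequence(rec.id, str(rec.seq), **kw))
        return cls(cands)

    def to_fasta(self, path: str | Path) -> None:
        records = [SeqRecord(Seq(self[i].sequence), id=i, description="") for i in self.ids]
        SeqIO.write(records, str(path), "fasta")

    def to_meta_tsv(self, path: str | Path) -> None:
        rows = [{"id": c.id, "cls": c.cls, "program": c.program, "chrom": c.chrom,
                 "start": c.start, "end": c.end, "assembly": c.assembly}
                for c in sorted(self, key=lambda c: c.id)]
        pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, sep="\t", index=False)


def pair_id(id5: str, id3: str) -> str:
    """Deterministic, sortable pair identifier."""
    return f"{id5}__{id3}"


@dataclass
class PairDesign:
    """Ordered (5' candidate, 3' candidate, spacer) design rows.

    ``table`` columns: pair_id, id5, id3, spacer_id, homotypic.
    ``spacers`` maps spacer_id to the spacer DNA sequence.
    """

    table: pd.DataFrame
    spacers: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in ("pair_id", "id5", "id3", "spacer_id", "homotypic")
                   if c not in self.table.columns]
        if missing:
            raise ValueError(f"design table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def pair_ids(self) -> pd.Series:
        return self.table["pair_id"]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, spacers: Mapping[str, str] | None = None) -> "PairDesign":
        tab = pd.read_csv(path, sep="\t", dtype={"pair_id": str, "id5": str, "id3": str,
                                                 "spacer_id": str})
        tab["homotypic"] = tab["homotypic"].astype(bool)
        return cls(tab, dict(spacers or {}))


def enumerate_pairs(pool: Pool, spacer_id: str = "spacer300",
                    spacer_seq: str | None = None) -> PairDesign:
    """All |pool|^2 ordered (5', 3') combinations, lexicographic by id5 then id3.

    Homotypic rows (id5 == id3) are flagged; the downstream count filter
    removes them before activity computation.
    """
    ids = np.array(pool.ids, dtype=object)
    n = len(ids)
    id5 = np.repeat(ids, n)
    id3 = np.tile(ids, n)
    pid = np.char.add(np.char.add(id5.astype(str), "__"), id3.astype(str))
    tab = pd.DataFrame({
        "pair_id": pid,
        "id5": id5,
        "id3": id3,
        "spacer_id": spacer_id,
        "homotypic": id5 == id3,
    })
    spacers = {spacer_id: spacer_seq} if spacer_seq is not None else {}
    return PairDesign(tab, spacers)


def build_reference(design: PairDesign, pool: Pool, flank5: str = "",
                    flank3: str = "") -> dict[str, str]:
    """Full construct sequence per pair: flank5 + seq5 + spacer + seq3 + flank3."""
    seqs = pool.sequences()
    out: dict[str, str] = {}
    for row in design.table.itertuples(index=False):
        if row.id5 not in seqs or row.id3 not in seqs:
            missing = [i for i in (row.id5, row.id3) if i not in seqs]
            raise KeyError(f"design references unknown candidate ids: {missing}")
        if row.spacer_id not in design.spacers:
            raise KeyError(f"spacer {row.spacer_id!r} not registered in design")
        out[row.pair_id] = (flank5 + seqs[row.id5] + design.spacers[row.spacer_id]
                            + seqs[row.id3] + flank3)
    return out


def write_reference_fasta(reference: Mapping[str, str], path: str | Path) -> None:
    """Byte-stable FASTA of construct records (headers are pair ids)."""
    with open(path, "w") as fh:
        for pid in reference:
            fh.write(f">{pid}\n{reference[pid]}\n")
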