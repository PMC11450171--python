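"""From paired reads to UMI-collapsed counts per construct.

Constructs are short, known and enumerable, so reads are assigned by direct
end-matching against the construct reference with a substitution (Hamming)
budget instead of a general-purpose aligner: read 1 must match a construct's
5' end in forward orientation and read 2 the 3' end in reverse-complement
orientation, both within ``max_mismatches`` substitutions, identifying the
same designed pair.  Reads matching more than one candidate end at the same
minimal mismatch count are discarded as ambiguous.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .motifs import encode_sequence, reverse_complement
from .pool import PairDesign, Pool

DEFAULT_MAX_MISMATCHES = 3
DEFAULT_MIN_INPUT = 5


class ConstructReference:
    """Indexed construct ends for read-pair assignment.

    Built from the construct sequences (pair_id -> sequence).  Because every
    construct sharing a 5' candidate has the same 5' end, matching is done
    against the distinct 5'-end and 3'-end sequences, then the (id5, id3)
    combination is required to exist in the design.
    """

    def __init__(self, reference: Mapping[str, str], design: PairDesign, read_length: int):
        if not reference:
            raise ValueError("empty construct reference")
        self.read_length = read_length
        tab = design.table
        seq_of = dict(reference)
        missing = [p for p in tab["pair_id"] if p not in seq_of]
        if missing:
            raise KeyError(f"design pairs missing from reference: {missing[:5]}")
        # distinct 5' ends keyed by id5, distinct 3' ends keyed by id3
        ends5: dict[str, str] = {}
        ends3: dict[str, str] = {}
        for row in tab.itertuples(index=False):
            seq = seq_of[row.pair_id]
            if len(seq) < read_length:
                raise ValueError(f"construct {row.pair_id} shorter than read length")
            e5 = seq[:read_length]
            e3 = reverse_complement(seq[-read_length:])
            if ends5.setdefault(row.id5, e5) != e5 or ends3.setdefault(row.id3, e3) != e3:
                raise ValueError("inconsistent construct ends for one candidate id")
        self.ids5 = list(ends5)
        self.ids3 = list(ends3)
        self._mat5 = np.stack([encode_sequence(ends5[i]) for i in self.ids5])
        self._mat3 = np.stack([encode_sequence(ends3[i]) for i in self.ids3])
        self._exact5 = {ends5[i]: i for i in self.ids5}
        self._exact3 = {ends3[i]: i for i in self.ids3}
        self.valid_pairs = dict(zip(zip(tab["id5"], tab["id3"]), tab["pair_id"]))

    def _match_end(self, read: str, mat: np.ndarray, ids: list[str], exact: dict[str, str],
                   max_mismatches: int) -> str | None:
        read = read[: self.read_length].upper()
        if len(read) < self.read_length:
            return None
        hit = exact.get(read)
        if hit is not None:
            return hit
        codes = encode_sequence(read)
        mm = (mat != codes).sum(axis=1)
        best = int(mm.min())
        if best > max_mismatches:
            return None
        winners = np.nonzero(mm == best)[0]
        if len(winners) != 1:
            return None  # ambiguous across constructs
        return ids[int(winners[0])]

    def assign(self, read1: str, read2: str,
               max_mismatches: int = DEFAULT_MAX_MISMATCHES) -> str | None:
        id5 = self._match_end(read1, self._mat5, self.ids5, self._exact5, max_mismatches)
        if id5 is None:
            return None
        id3 = self._match_end(read2, self._mat3, self.ids3, self._exact3, max_mismatches)
        if id3 is None:
            return None
        return self.valid_pairs.get((id5, id3))


def assign_read_pair(read1: str, read2: str, reference: ConstructReference,
                     max_mismatches: int = DEFAULT_MAX_MISMATCHES) -> str | None:
    """Pair id for a read pair, or None if unassigned (mismatches/ambiguity)."""
    return reference.assign(read1, read2, max_mismatches)


def _parse_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    with open(path) as fh:
        while True:
            header = fh.readline().rstrip()
            if not header:
                return
            seq = fh.readline().rstrip()
            fh.readline()
            fh.readline()
            yield header[1:], seq


def umi_from_header(header: str) -> str:
    """UMI parsed from the read name after the last ':'."""
    return header.split()[0].rsplit(":", 1)[-1]


def assign_fastq(r1_path: str | Path, r2_path: str | Path, reference: ConstructReference,
                 channel: str, replicate: int,
                 max_mismatches: int = DEFAULT_MAX_MISMATCHES
                 ) -> Iterator[tuple[str, int, str, str]]:
    """Stream (pair_id, replicate, channel, umi) records from one paired sample."""
    for (h1, s1), (h2, s2) in zip(_parse_fastq(r1_path), _parse_fastq(r2_path)):
        if h1.split()[0] != h2.split()[0]:
            raise ValueError(f"unsynchronised FASTQ pair: {h1!r} vs {h2!r}")
        pid = reference.assign(s1, s2, max_mismatches)
        if pid is not None:
            yield pid, replicate, channel, umi_from_header(h1)


def collapse_umis(assignments: Iterable[tuple[str, int, str, str]]) -> pd.DataFrame:
    """UMI-collapsed counts: distinct UMIs per (pair_id, replicate, channel).

    UMIs containing N are dropped; collapse is by exact string identity,
    order-independent.  Raises on inconsistent UMI lengths.
    """
    seen: dict[tuple[str, int, str], set[str]] = {}
    umi_len: int | None = None
    for pid, rep, channel, umi in assignments:
        umi = umi.upper()
        if umi_len is None:
            umi_len = len(umi)
        elif len(umi) != umi_len:
            raise ValueError(f"inconsistent UMI lengths: {umi_len} vs {len(umi)}")
        if "N" in umi:
            continue
        seen.setdefault((pid, int(rep), channel), set()).add(umi)
    rows = [(pid, rep, channel, len(umis))
            for (pid, rep, channel), umis in sorted(seen.items())]
    return pd.DataFrame(rows, columns=["pair_id", "replicate", "channel", "umi_count"])


def filter_pairs(table: pd.DataFrame, design: PairDesign,
                 min_input: int = DEFAULT_MIN_INPUT) -> pd.DataFrame:
    """Keep heterotypic pairs with >= ``min_input`` UMIs in every input replicate.

    RNA counts of retained pairs pass through untouched.  A pair absent from
    an input replicate counts as 0 there and is removed.  Raises if the table
    references a pair not present in the design.
    """
    if table.empty:
        return table.copy()
    tab = design.table.set_index("pair_id")
    unknown = set(table["pair_id"]) - set(tab.index)
    if unknown:
        raise KeyError(f"pairs missing from design: {sorted(unknown)[:5]}")
    heterotypic = set(tab.index[~tab["homotypic"]])
    inputs = table[table["channel"] == "input"]
    wide = inputs.pivot_table(index="pair_id", columns="replicate", values="umi_count",
                              fill_value=0)
    ok = wide.index[(wide >= min_input).all(axis=1)]
    keep = heterotypic & set(ok)
    return table[table["pair_id"].isin(keep)].reset_index(drop=True)


def quantify_fastq(samples: Mapping[tuple[str, int], tuple[str | Path, str | Path]],
                   reference: Mapping[str, str], design: PairDesign,
                   max_mismatches: int = DEFAULT_MAX_MISMATCHES,
                   read_length: int | None = None) -> pd.DataFrame:
    """End-to-end: assign paired FASTQ samples and collapse UMIs to a count table.

    ``samples`` maps (channel, replicate) to (R1 path, R2 path).
    """
    if read_length is None:
        first_r1 = next(iter(samples.values()))[0]
        read_length = len(next(_parse_fastq(first_r1))[1])
    ref = ConstructReference(reference, design, read_length)

    def stream():
        for (channel, rep), (r1, r2) in samples.items():
            yield from assign_fastq(r1, r2, ref, channel, rep, max_mismatches)

    return collapse_umis(stream())
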