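"""Designed sequence variants: motif mutation and motif pasting.

Variants preserve sequence length.  Mutating replaces each motif match
interval with random bases, rejection-sampled until no forbidden PWM
matches overlap the replaced interval.  Pasting overwrites the bases at
uniformly sampled non-overlapping positions with a motif consensus,
rejection-sampled so no *new* forbidden-PWM matches appear outside the
pasted copies themselves.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .motifs import PWM, DEFAULT_P_CUTOFF, find_matches

_BASES = np.array(list("ACGT"))


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent (start, end) intervals (0-based half-open)."""
    if not intervals:
        return []
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(iv) for iv in merged]


def _overlapping_matches(seq: str, pwms: Sequence[PWM], start: int, end: int,
                         p_cutoff: float) -> bool:
    for pwm in pwms:
        for s, e, _strand in find_matches(seq, pwm, p_cutoff):
            if s < end and e > start:
                return True
    return False


def mutate_motifs(seq: str, matches: Sequence[tuple[int, int]], forbidden_pwms: Sequence[PWM],
                  rng_seed: int, p_cutoff: float = DEFAULT_P_CUTOFF,
                  max_attempts: int = 1000) -> str:
    """Replace motif match intervals with random bases free of forbidden motifs.

    Overlapping intervals are merged before replacement (replacement of
    overlapping windows would otherwise be order-dependent).  Deterministic
    given ``rng_seed``.
    """
    intervals = merge_intervals(matches)
    if intervals and (intervals[0][0] < 0 or intervals[-1][1] > len(seq)):
        raise ValueError("match interval out of sequence bounds")
    rng = np.random.default_rng(rng_seed)
    out = list(seq.upper())
    for s, e in intervals:
        for _ in range(max_attempts):
            out[s:e] = rng.choice(_BASES, size=e - s)
            if not _overlapping_matches("".join(out), forbidden_pwms, s, e, p_cutoff):
                break
        else:
            raise RuntimeError(
                f"could not find a motif-free replacement for interval ({s}, {e}) "
                f"within {max_attempts} attempts")
    return "".join(out)


def paste_motifs(seq: str, motif_consensus: str, n_copies: int,
                 forbidden_pwms: Sequence[PWM] = (), rng_seed: int = 0,
                 p_cutoff: float = DEFAULT_P_CUTOFF, max_attempts: int = 1000) -> str:
    """Overwrite ``n_copies`` non-overlapping positions with a motif consensus.

    Positions are sampled uniformly among all placements not overlapping
    previously chosen copies.  The result keeps the original length, carries
    the consensus verbatim at every chosen position, and creates no new
    forbidden-PWM matches outside the pasted copies.  Deterministic given
    ``rng_seed``.
    """
    motif = motif_consensus.upper()
    m = len(motif)
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    if m > len(seq):
        raise ValueError("motif does not fit in the sequence")
    seq = seq.upper()
    original_matches = {
        (pwm.name, s, e, st)
        for pwm in forbidden_pwms for s, e, st in find_matches(seq, pwm, p_cutoff)
    }
    rng = np.random.default_rng(rng_seed)
    for _ in range(max_attempts):
        # sample non-overlapping placements one at a time, uniformly among
        # the positions still available
        available = np.ones(len(seq) - m + 1, dtype=bool)
        chosen: list[int] = []
        failed = False
        for _k in range(n_copies):
            idx = np.nonzero(available)[0]
            if len(idx) == 0:
                failed = True
                break
            p = int(rng.choice(idx))
            chosen.append(p)
            lo = max(0, p - m + 1)
            available[lo:p + m] = False
        if failed:
            raise RuntimeError(
                f"cannot place {n_copies} non-overlapping copies of a {m}-bp motif "
                f"in a {len(seq)}-bp sequence")
        out = list(seq)
        for p in chosen:
            out[p:p + m] = motif
        candidate = "".join(out)
        pasted = [(p, p + m) for p in chosen]
        new_matches = {
            (pwm.name, s, e, st)
            for pwm in forbidden_pwms for s, e, st in find_matches(candidate, pwm, p_cutoff)
            if not any(s < pe and e > ps for ps, pe in pasted)
        }
        if new_matches <= original_matches:
            return candidate
    raise RuntimeError(
        f"could not paste {n_copies} copies without creating forbidden motif matches "
        f"within {max_attempts} attempts")
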