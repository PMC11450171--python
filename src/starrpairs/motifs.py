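"""Transcription-factor motif analysis for paired-reporter screens.

PWM scanning uses score thresholds calibrated to an exact null p-value:
the distribution of the (discretised) log-odds score of a random window
drawn from the background base composition is computed by dynamic
programming, and the match threshold is the smallest score whose null
exceedance probability does not exceed ``p_cutoff``.  Both strands are
scanned and overlapping windows are counted independently, following the
convention of background-calibrated motif-matching tools.

Downstream analyses: Fisher-test enrichment of motifs in candidate groups
versus random controls, pairwise motif-combination effects on pair
activity and model residuals, and an L1-regularised (LASSO) regression
predicting activity from motif counts with nested cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

#: score lattice granularity (log2-odds units per lattice step)
DEFAULT_GRANULARITY = 1e-4
DEFAULT_P_CUTOFF = 5e-4


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string as integer codes A=0 C=1 G=2 T=3 (other -> -1)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, code in _BASE_INDEX.items():
        out[arr == ord(base)] = code
    return out


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(str.maketrans("ACGT", "TGCA"))[::-1]


@dataclass
class PWM:
    """A position weight matrix of per-position base probabilities.

    Parameters
    ----------
    name : str
        Motif identifier.
    matrix : ndarray, shape (length, 4)
        Per-position probabilities over A, C, G, T; rows sum to 1.
    background : ndarray, shape (4,)
        Background base frequencies (defaults to uniform).
    pseudo_prob : float
        Small probability added to every cell (then renormalised) before
        taking log-odds, so zero cells have finite scores.
    """

    name: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudo_prob: float = 1e-3

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or len(self.matrix) < 1:
            raise ValueError(f"PWM {self.name!r}: matrix must be (length >= 1, 4)")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.name!r}: position probabilities must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.name!r}: background must sum to 1")

    def __len__(self) -> int:
        return len(self.matrix)

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))

    def quantized_log_odds(self, granularity: float = DEFAULT_GRANULARITY) -> np.ndarray:
        """Integer log2-odds scores on a lattice of step ``granularity``."""
        p = self.matrix + self.pseudo_prob
        p /= p.sum(axis=1, keepdims=True)
        lo = np.log2(p / self.background)
        return np.rint(lo / granularity).astype(np.int64)

    @classmethod
    def from_consensus(cls, name: str, consensus: str, certainty: float = 0.997,
                       background: np.ndarray | None = None) -> "PWM":
        """Build a near-deterministic PWM from a consensus string."""
        rest = (1.0 - certainty) / 3.0
        mat = np.full((len(consensus), 4), rest)
        for i, base in enumerate(consensus.upper()):
            mat[i, _BASE_INDEX[base]] = certainty
        kwargs = {} if background is None else {"background": np.asarray(background)}
        return cls(name, mat, **kwargs)


def read_pwm_file(path: str | Path) -> list[PWM]:
    """Parse PWMs from simple matrix text: ``>name`` then rows of A C G T."""
    pwms: list[PWM] = []
    name, rows = None, []
    def flush():
        if name is not None:
            if not rows:
                raise ValueError(f"PWM {name!r} has no matrix rows")
            pwms.append(PWM(name, np.array(rows, dtype=float)))
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                name, rows = line[1:].strip(), []
            else:
                vals = [float(x) for x in line.split()]
                if len(vals) != 4:
                    raise ValueError(f"PWM row must have 4 columns, got {line!r}")
                rows.append(vals)
    flush()
    return pwms


def read_pwm_dir(path: str | Path) -> list[PWM]:
    pwms = []
    for f in sorted(Path(path).glob("*")):
        if f.is_file():
            pwms.extend(read_pwm_file(f))
    return pwms


def write_pwm_file(pwms: Iterable[PWM], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name}\n")
            for row in pwm.matrix:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")


def null_score_distribution(pwm: PWM, granularity: float = DEFAULT_GRANULARITY
                            ) -> tuple[int, np.ndarray]:
    """Exact null distribution of the quantised window score.

    Returns ``(min_score, probs)`` where ``probs[k]`` is the probability,
    under i.i.d. background bases, that a random window scores exactly
    ``min_score + k`` lattice units.
    """
    q = pwm.quantized_log_odds(granularity)
    lo = int(q.min(axis=1).sum())
    hi = int(q.max(axis=1).sum())
    dist = np.zeros(hi - lo + 1)
    dist[0] = 1.0
    offset = 0  # current dist[k] = P(score_so_far == current_min + k)
    width = 1
    for i in range(len(q)):
        qmin = int(q[i].min())
        new_width = width + int(q[i].max()) - qmin
        new = np.zeros(new_width)
        for b in range(4):
            shift = int(q[i, b]) - qmin
            new[shift:shift + width] += dist[:width] * pwm.background[b]
        dist = new
        width = new_width
        offset += qmin
    assert offset == lo and width == hi - lo + 1
    return lo, dist


def score_threshold(pwm: PWM, p_cutoff: float = DEFAULT_P_CUTOFF,
                    granularity: float = DEFAULT_GRANULARITY) -> tuple[int, float]:
    """Smallest lattice score whose null exceedance probability is <= p_cutoff.

    Returns ``(threshold, exceedance)`` where ``exceedance`` is the exact
    null probability of a window scoring >= ``threshold``.
    """
    if not 0.0 < p_cutoff <= 1.0:
        raise ValueError("p_cutoff must be in (0, 1]")
    lo, dist = null_score_distribution(pwm, granularity)
    tail = np.cumsum(dist[::-1])[::-1]  # tail[k] = P(score >= lo + k)
    ok = np.nonzero(tail <= p_cutoff)[0]
    if len(ok) == 0:
        # even the maximal score is too likely; only max-score windows match
        return lo + len(dist) - 1, float(tail[-1])
    k = int(ok[0])
    return lo + k, float(tail[k])


def _window_scores(codes: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Quantised scores of every window of len(q) in an encoded sequence."""
    L = len(q)
    if len(codes) < L:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (win >= 0).all(axis=1)
    safe = np.where(win >= 0, win, 0)
    scores = q[np.arange(L), safe].sum(axis=1)
    scores[~valid] = np.iinfo(np.int64).min
    return scores


def find_matches(seq: str, pwm: PWM, p_cutoff: float = DEFAULT_P_CUTOFF,
                 granularity: float = DEFAULT_GRANULARITY) -> list[tuple[int, int, str]]:
    """All windows matching ``pwm`` on either strand.

    Returns ``(start, end, strand)`` intervals in forward-sequence
    coordinates (0-based half-open); ``strand`` is '+' or '-'.
    """
    L = len(pwm)
    if L > len(seq):
        warnings.warn(f"PWM {pwm.name!r} (len {L}) longer than sequence (len {len(seq)})")
        return []
    thr, _ = score_threshold(pwm, p_cutoff, granularity)
    q = pwm.quantized_log_odds(granularity)
    codes = encode_sequence(seq)
    out: list[tuple[int, int, str]] = []
    fwd = _window_scores(codes, q)
    for i in np.nonzero(fwd >= thr)[0]:
        out.append((int(i), int(i) + L, "+"))
    # reverse strand: score forward windows with the reverse-complement matrix
    q_rc = q[::-1, ::-1]
    rev = _window_scores(codes, q_rc)
    for i in np.nonzero(rev >= thr)[0]:
        out.append((int(i), int(i) + L, "-"))
    return sorted(out)


def scan_motifs(seq: str, pwm: PWM, p_cutoff: float = DEFAULT_P_CUTOFF,
                granularity: float = DEFAULT_GRANULARITY) -> int:
    """Number of background-calibrated matches to ``pwm`` on both strands."""
    return len(find_matches(seq, pwm, p_cutoff, granularity))


def count_matrix(sequences: Mapping[str, str], pwms: Sequence[PWM],
                 p_cutoff: float = DEFAULT_P_CUTOFF) -> pd.DataFrame:
    """Motif-match count matrix: candidates (rows) x PWMs (columns)."""
    ids = list(sequences)
    data = {pwm.name: [scan_motifs(sequences[i], pwm, p_cutoff) for i in ids]
            for pwm in pwms}
    return pd.DataFrame(data, index=pd.Index(ids, name="candidate_id"))


def select_informative_motifs(counts: pd.DataFrame, group_labels: Mapping[str, str] | pd.Series,
                              control_counts: pd.DataFrame,
                              fdr_cutoff: float = 1e-5, min_total: int = 5) -> set[str]:
    """Motifs over- or under-represented in any candidate group vs controls.

    Per motif and group, a two-tailed Fisher exact test on the 2x2 table of
    (sequences with >= 1 match vs without) x (group vs control); BH-FDR across
    all motif x group tests. A motif is retained iff any group has
    FDR < ``fdr_cutoff`` and the motif has >= ``min_total`` matches in total
    across the candidate pool.
    """
    labels = pd.Series(group_labels)
    if labels.empty:
        raise ValueError("at least one candidate group is required")
    if control_counts.empty:
        raise ValueError("control count matrix is empty")
    groups = labels.groupby(labels).groups
    n_ctrl = len(control_counts)
    ctrl_with = (control_counts >= 1).sum(axis=0)
    tests = []  # (motif, group, p)
    for g, idx in groups.items():
        sub = counts.loc[list(idx)]
        if sub.empty:
            raise ValueError(f"group {g!r} has no candidate sequences")
        n_g = len(sub)
        g_with = (sub >= 1).sum(axis=0)
        for m in counts.columns:
            a, c = int(g_with[m]), int(ctrl_with.get(m, 0))
            table = [[a, n_g - a], [c, n_ctrl - c]]
            p = stats.fisher_exact(table, alternative="two-sided")[1]
            tests.append((m, g, p))
    pvals = np.array([t[2] for t in tests])
    fdr = multipletests(pvals, method="fdr_bh")[1]
    totals = counts.sum(axis=0)
    keep: set[str] = set()
    for (m, _g, _p), q in zip(tests, fdr):
        if q < fdr_cutoff and totals[m] >= min_total:
            keep.add(m)
    return keep


def pair_motif_effect(pairs: pd.DataFrame, counts5: pd.DataFrame, counts3: pd.DataFrame,
                      motifs: Sequence[str], min_pairs: int = 5) -> pd.DataFrame:
    """Mean effect of each 5'x3' motif combination on activity and residuals.

    For motifs (m, n): the *with* group is the pairs whose 5' candidate has
    >= 1 match to m and whose 3' candidate has >= 1 match to n; the *without*
    group is the pairs whose 5' candidate lacks m and 3' candidate lacks n.
    The effect is mean(with) - mean(without), in log2 units, computed for the
    pair activity and (when present) the model residual.  Entries where either
    group is smaller than ``min_pairs`` are NaN.

    Parameters
    ----------
    pairs : DataFrame with columns id5, id3, log2_activity and optionally residual.
    counts5, counts3 : candidate x PWM match-count matrices for each side.
    """
    motifs = list(motifs)
    h5 = (counts5.loc[pairs["id5"], motifs].to_numpy() >= 1)
    h3 = (counts3.loc[pairs["id3"], motifs].to_numpy() >= 1)
    out = {}
    n_with = h5.T.astype(float) @ h3
    n_without = (~h5).T.astype(float) @ (~h3)
    defined = (n_with >= min_pairs) & (n_without >= min_pairs)
    for col, key in (("log2_activity", "activity_effect"), ("residual", "residual_effect")):
        if col not in pairs.columns:
            continue
        y = pairs[col].to_numpy(dtype=float)
        s_with = h5.T @ (h3 * y[:, None])
        s_without = (~h5).T @ ((~h3) * y[:, None])
        with np.errstate(invalid="ignore", divide="ignore"):
            eff = s_with / n_with - s_without / n_without
        eff[~defined] = np.nan
        out[key] = eff
    m5, m3 = np.meshgrid(np.arange(len(motifs)), np.arange(len(motifs)), indexing="ij")
    grid = pd.DataFrame({
        "motif5": [motifs[i] for i in m5.ravel()],
        "motif3": [motifs[j] for j in m3.ravel()],
        "n_pairs_with": n_with.ravel().astype(int),
        "n_pairs_without": n_without.ravel().astype(int),
    })
    for key, eff in out.items():
        grid[key] = eff.ravel()
    return grid


def default_lambda_grid() -> np.ndarray:
    """Penalty grid 10^(2, 1.9, ..., -3)."""
    return 10.0 ** np.arange(2.0, -3.0 - 1e-9, -0.1)


@dataclass
class L1Fit:
    """Results of the nested cross-validated LASSO on motif counts."""

    lambda_grid: np.ndarray
    chosen_lambda: float
    coefficients: pd.Series  # original feature scale; exact zeros preserved
    intercept: float
    cv_r2_mean: float
    cv_r2_sd: float
    fold_r2: np.ndarray
    n_samples: int

    def summary(self) -> str:
        nz = self.coefficients[self.coefficients != 0.0]
        lines = [
            "L1-regularised motif regression",
            f"  n samples:        {self.n_samples}",
            f"  chosen lambda:    {self.chosen_lambda:.4g}",
            f"  held-out R^2:     {self.cv_r2_mean:.3f} +/- {self.cv_r2_sd:.3f} "
            f"({len(self.fold_r2)}-fold CV)",
            f"  nonzero features: {len(nz)} / {len(self.coefficients)}",
        ]
        for name, val in nz.sort_values(key=np.abs, ascending=False).head(10).items():
            lines.append(f"    {name:<24s} {val:+.4f}")
        return "\n".join(lines)


def _standardize(train: np.ndarray, other: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (other - mu) / sd, sd


def _inner_cv_lambda(x: np.ndarray, y: np.ndarray, grid: np.ndarray,
                     n_folds: int, rng_seed: int, rule: str = "1se") -> float:
    """Penalty selection by K-fold CV: minimum CV error or the one-SE rule.

    The one-SE rule (default) takes the largest penalty whose CV error is
    within one standard error of the minimum, trading a sliver of accuracy
    for a sparser, more stable motif set.
    """
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=rng_seed)
    mse = np.zeros((n_folds, len(grid)))
    for f, (tr, te) in enumerate(kf.split(x)):
        xtr, xte, _ = _standardize(x[tr], x[te])
        for j, lam in enumerate(grid):
            model = Lasso(alpha=lam, max_iter=50_000)
            model.fit(xtr, y[tr])
            mse[f, j] = np.mean((y[te] - model.predict(xte)) ** 2)
    mean = mse.mean(axis=0)
    best = int(np.argmin(mean))
    if rule == "min":
        return float(grid[best])
    se = mse[:, best].std(ddof=1) / np.sqrt(n_folds)
    ok = np.nonzero(mean <= mean[best] + se)[0]
    # grid is descending, so the first qualifying index is the largest penalty
    return float(grid[int(ok[0])])


def l1_regression(features: pd.DataFrame, target: Sequence[float],
                  lambda_grid: np.ndarray | None = None,
                  inner_folds: int = 5, outer_folds: int = 9, seed: int = 0,
                  selection: str = "1se") -> L1Fit:
    """LASSO prediction of pair activity (or residuals) from motif counts.

    Features are standardised to unit variance within each training set; the
    penalty is chosen from ``lambda_grid`` by ``inner_folds``-fold CV; model
    performance is the mean R^2 over ``outer_folds`` non-overlapping held-out
    test sets.  Reported coefficients come from a final full-data fit at the
    full-data inner-CV penalty, back-transformed to the original feature scale.
    """
    grid = default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid, float)
    x = features.to_numpy(dtype=float)
    y = np.asarray(target, dtype=float)
    if len(x) != len(y):
        raise ValueError("features and target lengths differ")
    if len(x) <= outer_folds:
        raise ValueError("need more samples than outer folds")
    if not np.all(np.isfinite(x)):
        raise ValueError("features must be finite")
    names = list(features.columns)
    if np.ptp(y) == 0.0:
        warnings.warn("constant target: intercept-only fit, CV R^2 reported as 0")
        coefs = pd.Series(0.0, index=names)
        return L1Fit(grid, float(grid[0]), coefs, float(y[0]) if len(y) else 0.0,
                     0.0, 0.0, np.zeros(outer_folds), len(y))

    outer = KFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    fold_r2 = []
    for k, (tr, te) in enumerate(outer.split(x)):
        lam = _inner_cv_lambda(x[tr], y[tr], grid, inner_folds, seed + 1 + k, selection)
        xtr, xte, _ = _standardize(x[tr], x[te])
        model = Lasso(alpha=lam, max_iter=50_000)
        model.fit(xtr, y[tr])
        fold_r2.append(r2_score(y[te], model.predict(xte)))
    fold_r2 = np.asarray(fold_r2)

    lam_full = _inner_cv_lambda(x, y, grid, inner_folds, seed, selection)
    x_std, _, sd = _standardize(x, x)
    final = Lasso(alpha=lam_full, max_iter=50_000)
    final.fit(x_std, y)
    coefs = pd.Series(final.coef_ / sd, index=names)
    intercept = float(final.intercept_ - np.sum(final.coef_ * x.mean(axis=0) / sd))
    return L1Fit(grid, lam_full, coefs, intercept,
                 float(fold_r2.mean()), float(fold_r2.std(ddof=1)), fold_r2, len(y))


def synthetic_pwm_collection(n_random: int = 18, length: int = 8, seed: int = 0,
                             certainty: float = 0.95) -> list[PWM]:
    """A small synthetic PWM collection for fixtures and demonstrations.

    Includes a GAGA-factor-like (Trl) and an E-box (Twist, CAYATG) consensus
    alongside ``n_random`` random-consensus matrices.  Synthetic stand-ins,
    not curated biological motifs.
    """
    rng = np.random.default_rng(seed)
    pwms = [PWM.from_consensus("Trl_like", "GAGAG", certainty=certainty),
            PWM.from_consensus("Twist_like", "CATATG", certainty=certainty)]
    for i in range(n_random):
        cons = "".join(rng.choice(list(_BASES), size=length))
        pwms.append(PWM.from_consensus(f"synth_{i:02d}", cons, certainty=certainty))
    return pwms
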