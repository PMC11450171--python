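"""Synthetic paired-reporter screens with known ground truth.

The generator emulates the statistical structure of a paired-enhancer
reporter screen: a pool of candidates (enhancers spanning a wide activity
range plus negative controls pinned at activity 0), the full ordered pair
design, and negative-binomially dispersed UMI counts for two input and two
RNA replicates whose RNA means scale with the true pair activity.  Pair
activities follow one of four cooperativity regimes:

* additive       — log2(2^a5 + 2^a3 - 1)
* multiplicative — a5 + a3
* interaction    — b0 + b1*a5 + b2*a3 + b3*a5*a3 (enhancer/enhancer pairs;
  pairs containing a control combine multiplicatively, keeping the
  control/control baseline at zero, which is how the assay defines zero)
* saturating     — soft-min cap: log2(2^(a5+a3) * 2^cap / (2^(a5+a3) + 2^cap)),
  smooth, monotone, and multiplicative far below the cap

Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .coopmodel import predict_additive, predict_multiplicative
from .pool import CandidateSequence, PairDesign, Pool, enumerate_pairs
from .motifs import reverse_complement

REGIMES = ("additive", "multiplicative", "interaction", "saturating")
_BASES = np.array(list("ACGT"))


@dataclass
class TrueActivityModel:
    """Ground-truth law mapping two individual activities to a pair activity.

    ``beta*`` are used by the interaction regime (log2 units), ``cap`` is the
    log2 ceiling of the saturating regime, ``noise_sd`` the biological log2
    noise added to the pair activity per RNA replicate.
    """

    regime: str = "multiplicative"
    beta0: float = 0.0
    beta1: float = 1.0
    beta2: float = 1.0
    beta3: float = 0.0
    cap: float | None = None
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; expected one of {REGIMES}")
        if self.regime == "saturating" and (self.cap is None or not np.isfinite(self.cap)):
            raise ValueError("saturating regime requires a finite cap")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def combined_activity(a5, a3, model: TrueActivityModel):
    """True log2 pair activity under the model's regime (pure function)."""
    a5 = np.asarray(a5, dtype=float)
    a3 = np.asarray(a3, dtype=float)
    if model.regime == "additive":
        out = predict_additive(a5, a3)
    elif model.regime == "multiplicative":
        out = predict_multiplicative(a5, a3)
    elif model.regime == "interaction":
        out = model.beta0 + model.beta1 * a5 + model.beta2 * a3 + model.beta3 * a5 * a3
    elif model.regime == "saturating":
        s = a5 + a3
        out = s + model.cap - np.logaddexp2(s, model.cap)
    else:  # pragma: no cover - guarded in __post_init__
        raise ValueError(f"unknown regime {model.regime!r}")
    out = np.asarray(out)
    return out if out.ndim else float(out)


@dataclass
class SimulationConfig:
    """Study conditions of a simulated screen.

    ``activity_law`` is a distribution spec for true enhancer log2 activities
    (controls are fixed at 0): ("uniform", lo, hi), ("normal", mu, sd) or
    ("point", value).  ``mean_input_depth`` is the expected input UMIs per
    pair; ``nb_dispersion`` d gives count variance mu + mu^2 * d (d = 0 is
    Poisson).  ``abundance_sd`` is the log2 SD of the log-normal library
    representation skew across pairs.
    """

    n_enhancers: int = 300
    n_controls: int = 100
    activity_law: tuple = ("uniform", 0.0, 4.0)
    n_input_reps: int = 2
    n_rna_reps: int = 2
    mean_input_depth: float = 100.0
    mean_rna_depth: float | None = None  # defaults to mean_input_depth
    nb_dispersion: float = 0.1
    abundance_sd: float = 0.25
    umi_length: int = 10
    candidate_length: int = 249
    spacer_length: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_enhancers < 0 or self.n_controls < 0 or self.n_enhancers + self.n_controls == 0:
            raise ValueError("pool must contain at least one candidate")
        if self.n_input_reps < 2 or self.n_rna_reps < 2:
            raise ValueError("at least two replicates per channel are required")
        if self.mean_input_depth <= 0:
            raise ValueError("mean_input_depth must be positive")
        if self.mean_rna_depth is not None and self.mean_rna_depth <= 0:
            raise ValueError("mean_rna_depth must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")

    @property
    def rna_depth(self) -> float:
        return self.mean_input_depth if self.mean_rna_depth is None else self.mean_rna_depth


def _draw_law(law: tuple, size: int, rng: np.random.Generator) -> np.ndarray:
    kind = law[0]
    if kind == "uniform":
        return rng.uniform(law[1], law[2], size)
    if kind == "normal":
        return rng.normal(law[1], law[2], size)
    if kind == "point":
        return np.full(size, float(law[1]))
    raise ValueError(f"unknown activity law {law!r}")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def make_pool(config: SimulationConfig, rng: np.random.Generator | None = None) -> Pool:
    """Random-sequence pool: ENH_#### enhancers and CTL_#### controls."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    cands = []
    for i in range(config.n_enhancers):
        cands.append(CandidateSequence(
            f"ENH_{i:04d}", _random_seq(rng, config.candidate_length),
            cls="enhancer", program="developmental",
            variant_length=config.candidate_length != 249))
    for i in range(config.n_controls):
        cands.append(CandidateSequence(
            f"CTL_{i:04d}", _random_seq(rng, config.candidate_length),
            cls="control", program="none",
            variant_length=config.candidate_length != 249))
    return Pool(cands)


def simulate_true_activities(pool: Pool, config: SimulationConfig,
                             rng: np.random.Generator | None = None) -> pd.Series:
    """True individual log2 activities: controls exactly 0, enhancers i.i.d."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    act = pd.Series(0.0, index=pd.Index(pool.ids, name="candidate_id"), name="true_activity")
    enh = pool.enhancer_ids
    act.loc[enh] = _draw_law(config.activity_law, len(enh), rng)
    return act


def simulate_pair_activities(design: PairDesign, activities: pd.Series,
                             model: TrueActivityModel, pool: Pool) -> pd.Series:
    """True log2 pair activity per design row.

    The interaction regime's coefficient map describes how two *enhancers*
    combine; pairs containing a control combine multiplicatively (the control
    contributes activity 0), so control/control pairs stay at the basal zero
    the assay is anchored to.  Other regimes already leave a zero-activity
    partner neutral and are applied to every pair.
    """
    a5 = design.table["id5"].map(activities).to_numpy(dtype=float)
    a3 = design.table["id3"].map(activities).to_numpy(dtype=float)
    if model.regime == "interaction":
        classes = pool.classes()
        both_enh = ((design.table["id5"].map(classes) == "enhancer")
                    & (design.table["id3"].map(classes) == "enhancer")).to_numpy()
        out = np.where(both_enh, combined_activity(a5, a3, model),
                       predict_multiplicative(a5, a3))
    else:
        out = combined_activity(a5, a3, model)
    return pd.Series(out, index=pd.Index(design.table["pair_id"].to_numpy(), name="pair_id"),
                     name="true_pair_activity")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mu + mu^2 * dispersion (Poisson at 0)."""
    mu = np.asarray(mu, dtype=float)
    if dispersion == 0.0:
        return rng.poisson(mu)
    n = 1.0 / dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def simulate_counts(design: PairDesign, pair_activities: pd.Series, config: SimulationConfig,
                    model: TrueActivityModel | None = None,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Replicate UMI count table for every design row.

    Input counts ~ NB(abundance * input depth); RNA counts ~ NB(abundance *
    rna depth * 2^(pair activity + per-replicate Normal(0, noise_sd))).
    Library abundances are log-normal around equal representation.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    noise_sd = 0.0 if model is None else model.noise_sd
    pids = design.table["pair_id"].to_numpy()
    act = pair_activities.reindex(pids)
    if act.isna().any():
        missing = act[act.isna()].index[:5].tolist()
        raise ValueError(f"design rows without a true pair activity, e.g. {missing}")
    act = act.to_numpy(dtype=float)
    n = len(pids)
    abundance = np.exp2(rng.normal(0.0, config.abundance_sd, n))
    blocks = []
    for r in range(1, config.n_input_reps + 1):
        mu = abundance * config.mean_input_depth
        blocks.append(pd.DataFrame({"pair_id": pids, "replicate": r, "channel": "input",
                                    "umi_count": _nb_draw(rng, mu, config.nb_dispersion)}))
    for r in range(1, config.n_rna_reps + 1):
        noise = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else 0.0
        mu = abundance * config.rna_depth * np.exp2(act + noise)
        blocks.append(pd.DataFrame({"pair_id": pids, "replicate": r, "channel": "rna",
                                    "umi_count": _nb_draw(rng, mu, config.nb_dispersion)}))
    return pd.concat(blocks, ignore_index=True)


@dataclass
class SimulatedDataset:
    """A complete simulated screen plus its ground truth and provenance."""

    pool: Pool
    design: PairDesign
    activities: pd.Series        # true individual log2 activities
    pair_activities: pd.Series   # true pair log2 activities
    counts: pd.DataFrame
    config: SimulationConfig
    model: TrueActivityModel

    def provenance(self) -> dict:
        return {"config": asdict(self.config), "model": asdict(self.model)}

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.pool.to_fasta(outdir / "pool.fa")
        self.pool.to_meta_tsv(outdir / "pool.tsv")
        self.design.to_tsv(outdir / "design.tsv")
        self.counts.to_csv(outdir / "counts.tsv", sep="\t", index=False)
        self.activities.rename("true_activity").to_csv(outdir / "true_activities.tsv", sep="\t")
        self.pair_activities.rename("true_activity").to_csv(
            outdir / "true_pair_activities.tsv", sep="\t")
        with open(outdir / "provenance.yaml", "w") as fh:
            yaml.safe_dump(self.provenance(), fh)


def simulate_dataset(config: SimulationConfig, model: TrueActivityModel) -> SimulatedDataset:
    """Generate pool, full pair design, truth and counts in one deterministic pass."""
    rng = np.random.default_rng(config.seed)
    pool = make_pool(config, rng)
    spacer = _random_seq(rng, config.spacer_length)
    design = enumerate_pairs(pool, spacer_id=f"spacer{config.spacer_length}", spacer_seq=spacer)
    activities = simulate_true_activities(pool, config, rng)
    pair_act = simulate_pair_activities(design, activities, model, pool)
    counts = simulate_counts(design, pair_act, config, model, rng)
    return SimulatedDataset(pool, design, activities, pair_act, counts, config, model)


def _distinct_umis(rng: np.random.Generator, k: int, length: int) -> list[str]:
    space = 4 ** length
    if k > space:
        raise ValueError(f"cannot draw {k} distinct UMIs of length {length}")
    seen: dict[int, None] = {}
    while len(seen) < k:
        for v in rng.integers(0, space, size=max(2 * (k - len(seen)), 4)):
            if int(v) not in seen:
                seen[int(v)] = None
                if len(seen) == k:
                    break
    out = []
    for v in seen:
        umi = []
        for _ in range(length):
            umi.append("ACGT"[v % 4])
            v //= 4
        out.append("".join(umi))
    return out


def _add_errors(rng: np.random.Generator, read: str, rate: float) -> str:
    if rate <= 0:
        return read
    arr = np.frombuffer(read.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        cur = chr(arr[i])
        alt = [b for b in "ACGT" if b != cur]
        arr[i] = ord(alt[int(rng.integers(0, 3))])
    return arr.tobytes().decode("ascii")


def emit_reads(counts: pd.DataFrame, reference: Mapping[str, str], outdir: str | Path,
               read_length: int = 36, duplicates: int = 1, error_rate: float = 0.0,
               umi_length: int = 10, seed: int = 0) -> dict[tuple[str, int], tuple[Path, Path]]:
    """Paired FASTQ per sample reproducing a UMI count table.

    For each count unit a distinct UMI is drawn and ``duplicates`` read pairs
    sharing it are emitted; read 1 is the construct 5' end (forward), read 2
    the reverse complement of the 3' end.  Per-base substitution errors at
    ``error_rate``.  The UMI sits after the last ':' of the read header.
    Returns {(channel, replicate): (r1_path, r2_path)}.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    short = [pid for pid, seq in reference.items() if len(seq) < read_length]
    if short:
        raise ValueError(f"read length {read_length} exceeds construct length for {short[:5]}")
    rng = np.random.default_rng(seed)
    paths: dict[tuple[str, int], tuple[Path, Path]] = {}
    samples = counts[["channel", "replicate"]].drop_duplicates().sort_values(
        ["channel", "replicate"])
    for channel, replicate in samples.itertuples(index=False):
        sub = counts[(counts["channel"] == channel) & (counts["replicate"] == replicate)]
        sub = sub.sort_values("pair_id")
        r1p = outdir / f"{channel}_rep{replicate}_R1.fastq"
        r2p = outdir / f"{channel}_rep{replicate}_R2.fastq"
        serial = 0
        with open(r1p, "w") as f1, open(r2p, "w") as f2:
            for row in sub.itertuples(index=False):
                if row.umi_count <= 0:
                    continue
                construct = reference[row.pair_id]
                r1_t = construct[:read_length]
                r2_t = reverse_complement(construct[-read_length:])
                for umi in _distinct_umis(rng, int(row.umi_count), umi_length):
                    for _ in range(duplicates):
                        serial += 1
                        name = f"sim:{channel}:{replicate}:{serial}:{umi}"
                        r1 = _add_errors(rng, r1_t, error_rate)
                        r2 = _add_errors(rng, r2_t, error_rate)
                        f1.write(f"@{name}\n{r1}\n+\n{'I' * read_length}\n")
                        f2.write(f"@{name}\n{r2}\n+\n{'I' * read_length}\n")
        paths[(channel, int(replicate))] = (r1p, r2p)
    return paths
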