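"""Pair and individual enhancer activities from UMI count tables.

Activities are log2 fold changes of RNA over input, computed with a single
pseudocount and median-of-ratios size factors, then shifted by one scalar so
the mean activity of control/control pairs is exactly zero — activities are
thus fold changes over the basal core-promoter output, in log2.

A candidate's *individual* activity on one side is the mean activity of its
pairs with robust controls on the opposite side.  Robust controls are the
negative controls whose mean control/control activity has |z| <= 1 across
controls of that side.  A candidate is *active* when its log2 activity
exceeds 1 and a one-tailed Fisher exact test (candidate-vs-control pairs
against control/control pairs, RNA vs input UMI totals) is significant after
Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .pool import PairDesign, Pool


def size_factors(matrix: pd.DataFrame, pseudocount: int = 1) -> pd.Series:
    """Median-of-ratios size factors per sample (columns) over pairs (rows)."""
    counts = matrix.to_numpy(dtype=float) + pseudocount
    log_ref = np.log(counts).mean(axis=1)  # geometric-mean reference per pair
    sf = np.exp(np.median(np.log(counts) - log_ref[:, None], axis=0))
    return pd.Series(sf, index=matrix.columns, name="size_factor")


def normalize_activities(counts: pd.DataFrame, design: PairDesign, pool: Pool,
                         pseudocount: int = 1) -> pd.DataFrame:
    """Normalized log2 pair activities, centred on control/control pairs.

    Per sample s: norm_s = (count + pseudocount) / size_factor_s; the pair
    activity is mean over RNA replicates of log2(norm) minus the mean over
    input replicates, minus the scalar mean activity of control/control pairs.

    Requires >= 2 replicates per channel and at least one control/control
    pair (the zero point is otherwise undefined).
    """
    wide = counts.pivot_table(index="pair_id", columns=["channel", "replicate"],
                              values="umi_count", fill_value=0)
    channels = wide.columns.get_level_values(0)
    n_input = int((channels == "input").sum())
    n_rna = int((channels == "rna").sum())
    if n_input < 2 or n_rna < 2:
        raise ValueError(f"need >= 2 replicates per channel, got {n_input} input / {n_rna} rna")
    sf = size_factors(wide, pseudocount)
    log_norm = np.log2(wide + pseudocount) - np.log2(sf)
    act = (log_norm.loc[:, "rna"].mean(axis=1) - log_norm.loc[:, "input"].mean(axis=1))

    tab = design.table.set_index("pair_id")
    ids5 = tab.loc[act.index, "id5"]
    ids3 = tab.loc[act.index, "id3"]
    classes = pool.classes()
    ctrl_ctrl = (ids5.map(classes) == "control") & (ids3.map(classes) == "control")
    if not ctrl_ctrl.any():
        raise ValueError("no control/control pairs observed; activity scaling is undefined")
    act = act - act[ctrl_ctrl].mean()

    return pd.DataFrame({
        "pair_id": act.index,
        "id5": ids5.to_numpy(),
        "id3": ids3.to_numpy(),
        "log2_activity": act.to_numpy(),
        "n_replicates_used": n_input + n_rna,
    }).reset_index(drop=True)


def zwindow_retain(means: pd.Series, z_lo: float = -1.0, z_hi: float = 1.0) -> pd.Series:
    """Retain entries whose sample z-score lies in [z_lo, z_hi].

    Uses the sample (n-1) standard deviation; if the SD is zero, all entries
    are retained.
    """
    sd = means.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return pd.Series(True, index=means.index)
    z = (means - means.mean()) / sd
    return (z >= z_lo) & (z <= z_hi)


@dataclass
class ControlSet:
    """Robust negative controls per side with their summary statistics."""

    table: pd.DataFrame  # side, control_id, mean_activity, zscore, retained

    def retained(self, side: str) -> list[str]:
        t = self.table
        return sorted(t.loc[(t["side"] == side) & t["retained"], "control_id"])


def select_robust_controls(activities: pd.DataFrame, pool: Pool,
                           min_controls: int = 3) -> ControlSet:
    """Negative controls whose control/control mean activity has |z| <= 1.

    Per side (5' and 3'), each control's activity is its mean over its
    control/control pairs; activities are standardised per side and controls
    with z in [-1, 1] are retained.
    """
    classes = pool.classes()
    cc = activities[(activities["id5"].map(classes) == "control")
                    & (activities["id3"].map(classes) == "control")]
    rows = []
    for side, key in (("5p", "id5"), ("3p", "id3")):
        means = cc.groupby(key)["log2_activity"].mean()
        if len(means) < min_controls:
            raise ValueError(f"side {side}: only {len(means)} controls with control "
                             f"partners (need >= {min_controls})")
        retained = zwindow_retain(means)
        sd = means.std(ddof=1)
        z = (means - means.mean()) / sd if sd > 0 else pd.Series(0.0, index=means.index)
        for cid in means.index:
            rows.append({"side": side, "control_id": cid, "mean_activity": means[cid],
                         "zscore": z[cid], "retained": bool(retained[cid])})
    return ControlSet(pd.DataFrame(rows))


def individual_activity(activities: pd.DataFrame, controls: ControlSet, pool: Pool,
                        min_partners: int = 10) -> pd.DataFrame:
    """Per-candidate, per-side individual activities from control pairings.

    5' activity of a candidate = mean activity of its pairs with retained 3'
    controls; symmetrically for the 3' side.  Candidates with fewer than
    ``min_partners`` such pairs are discarded.
    """
    rows = []
    for side, own_key, partner_key, partner_side in (("5p", "id5", "id3", "3p"),
                                                     ("3p", "id3", "id5", "5p")):
        robust = set(controls.retained(partner_side))
        sub = activities[activities[partner_key].isin(robust)]
        grp = sub.groupby(own_key)["log2_activity"].agg(["mean", "size"])
        grp = grp[grp["size"] >= min_partners]
        for cid, row in grp.iterrows():
            rows.append({"candidate_id": cid, "side": side,
                         "log2_activity": float(row["mean"]),
                         "n_control_partners": int(row["size"])})
    return pd.DataFrame(rows, columns=["candidate_id", "side", "log2_activity",
                                       "n_control_partners"])


def fisher_greater(table: np.ndarray) -> float:
    """One-tailed Fisher exact p (alternative 'greater') for a 2x2 table.

    The p-value is the hypergeometric upper tail P(X >= a) with X the
    top-left cell at fixed margins.
    """
    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    if a + b + c + d == 0:
        return 1.0  # empty table carries no evidence
    return float(stats.hypergeom.sf(a - 1, a + b + c + d, a + b, a + c))


def call_active(counts: pd.DataFrame, activities: pd.DataFrame, individual: pd.DataFrame,
                controls: ControlSet, pool: Pool, alpha: float = 0.05,
                activity_threshold: float = 1.0, per_side: bool = True) -> pd.DataFrame:
    """Active/inactive classification of candidates with FDR control.

    Per candidate and side, a 2x2 contingency table compares that candidate's
    pairs with robust controls against the control/control pairs: rows are
    the two pair groups, columns the summed RNA and input UMI counts over
    those pairs and all replicates.  One-tailed Fisher tests (greater RNA
    proportion in the candidate row) are BH-corrected per side.  A candidate
    is active iff log2 activity > ``activity_threshold`` and FDR < ``alpha``.
    """
    classes = pool.classes()
    totals = counts.groupby(["pair_id", "channel"])["umi_count"].sum().unstack(fill_value=0)
    for col in ("rna", "input"):
        if col not in totals.columns:
            totals[col] = 0
    act_idx = activities.set_index("pair_id")

    def group_sums(pair_ids: pd.Index) -> tuple[int, int]:
        sub = totals.reindex(pair_ids).fillna(0)
        return int(sub["rna"].sum()), int(sub["input"].sum())

    results = individual.copy()
    results["fdr"] = np.nan
    results["active"] = False
    for side, own_key, partner_key, partner_side in (("5p", "id5", "id3", "3p"),
                                                     ("3p", "id3", "id5", "5p")):
        robust = set(controls.retained(partner_side))
        robust_own = set(controls.retained(side))
        cc = act_idx[(act_idx["id5"].map(classes) == "control")
                     & (act_idx["id3"].map(classes) == "control")
                     & act_idx[own_key].isin(robust_own)
                     & act_idx[partner_key].isin(robust)]
        if cc.empty:
            raise ValueError(f"side {side}: no control/control reference pairs")
        rna_cc, in_cc = group_sums(cc.index)
        mask = results["side"] == side
        cands = results.loc[mask, "candidate_id"]
        sub = act_idx[act_idx[partner_key].isin(robust)]
        sums = totals.reindex(sub.index).fillna(0).groupby(sub[own_key].to_numpy()).sum()
        rna_c = sums["rna"].reindex(cands).fillna(0).to_numpy(dtype=np.int64)
        in_c = sums["input"].reindex(cands).fillna(0).to_numpy(dtype=np.int64)
        # vectorised hypergeometric upper tail, same table layout as fisher_greater
        pvals = stats.hypergeom.sf(rna_c - 1, rna_c + in_c + rna_cc + in_cc,
                                   rna_c + in_c, rna_c + rna_cc)
        if per_side:
            fdr = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else []
            results.loc[mask, "fdr"] = fdr
        else:
            results.loc[mask, "fdr"] = pvals  # corrected jointly below
    if not per_side:
        results["fdr"] = multipletests(results["fdr"].to_numpy(), method="fdr_bh")[1]
    results["active"] = (results["log2_activity"] > activity_threshold) & \
                        (results["fdr"] < alpha)
    return results


def run_activity_pipeline(counts: pd.DataFrame, design: PairDesign, pool: Pool,
                          min_partners: int = 10, alpha: float = 0.05
                          ) -> tuple[pd.DataFrame, pd.DataFrame, ControlSet]:
    """Normalize, select robust controls, infer and classify individual activities.

    Returns (pair activities, individual activities with fdr/active, control set).
    """
    acts = normalize_activities(counts, design, pool)
    controls = select_robust_controls(acts, pool)
    indiv = individual_activity(acts, controls, pool, min_partners=min_partners)
    indiv = call_active(counts, acts, indiv, controls, pool, alpha=alpha)
    return acts, indiv, controls
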