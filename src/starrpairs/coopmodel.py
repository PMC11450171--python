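"""Enhancer-enhancer cooperativity models.

Given individual log2 activities A (5' candidate) and B (3' candidate) of
the two enhancers in a fusion construct, the combined activity of the pair
is predicted under two fixed laws and one fitted law:

* additive      — RNA outputs add:      P = log2(2^A + 2^B - 1)
* multiplicative — fold-changes multiply: P = A + B
* fitted         — OLS with interaction:  P = b0 + b1*A + b2*B + b3*A*B + e

Model performance is R^2 = 1 - SS_residual/SS_total (adjusted for the
fitted model), and the fraction of pairs for which the multiplicative
prediction beats the additive one summarises which law dominates.  The
saturation analysis asks whether pairs anchored by a very strong enhancer
still gain activity from a stronger partner, which they should not if the
core promoter saturates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

ADDITIVE_FLOOR = 2.0 ** -30


def predict_additive(A, B, floor: float = ADDITIVE_FLOOR):
    """Additive prediction log2(2^A + 2^B - 1); symmetric in (A, B).

    The log argument is positive whenever max(A, B) >= 0; for deeply negative
    activity pairs it can reach zero and is clamped at ``floor`` with a warning.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    arg = np.exp2(A) + np.exp2(B) - 1.0
    if np.any(arg <= floor):
        warnings.warn("additive prediction clamped at floor for deeply negative activities")
        arg = np.maximum(arg, floor)
    out = np.log2(arg)
    return out if out.ndim else float(out)


def predict_multiplicative(A, B):
    """Multiplicative prediction A + B; symmetric."""
    out = np.asarray(A, dtype=float) + np.asarray(B, dtype=float)
    return out if out.ndim else float(out)


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot.

    May be negative for predictors worse than the observed mean (fixed-law
    predictions are not fitted, so nothing forces them above zero).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted lengths differ")
    if obs.size < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observed values have zero variance")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass
class InteractionFit:
    """OLS fit of observed pair activity on (1, A, B, A*B)."""

    beta0: float
    beta1: float
    beta2: float
    beta3: float
    bse: np.ndarray
    residuals: pd.Series  # indexed by pair_id
    r2_adjusted: float
    n_pairs: int

    @property
    def params(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2, self.beta3])

    def predict(self, A, B):
        A = np.asarray(A, dtype=float)
        B = np.asarray(B, dtype=float)
        return self.beta0 + self.beta1 * A + self.beta2 * B + self.beta3 * A * B


def fit_interaction_model(pairs: pd.DataFrame) -> InteractionFit:
    """Fit the multiplicative model with interaction term by OLS.

    ``pairs`` needs columns A, B, observed, and is indexed (or carries a
    column) pair_id.  The adjusted R^2 uses p = 3 predictors:
    1 - (1 - R^2)(n - 1)/(n - p - 1).
    """
    if len(pairs) < 5:
        raise ValueError("need at least 5 pairs to fit the interaction model")
    A = pairs["A"].to_numpy(dtype=float)
    B = pairs["B"].to_numpy(dtype=float)
    y = pairs["observed"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(A), A, B, A * B])
    rank = np.linalg.matrix_rank(X)
    if rank < 4:
        names = np.array(["intercept", "A", "B", "A*B"])
        # identify columns not adding rank, in order
        keep: list[int] = []
        for j in range(4):
            if np.linalg.matrix_rank(X[:, keep + [j]]) > len(keep):
                keep.append(j)
        collinear = [n for j, n in enumerate(names) if j not in keep]
        raise ValueError(f"rank-deficient design: collinear columns {collinear}")
    res = sm.OLS(y, X).fit()
    index = pairs["pair_id"] if "pair_id" in pairs.columns else pairs.index
    resid = pd.Series(res.resid, index=index, name="residual")
    return InteractionFit(*[float(b) for b in res.params], bse=np.asarray(res.bse),
                          residuals=resid, r2_adjusted=float(res.rsquared_adj),
                          n_pairs=len(pairs))


@dataclass
class ModelComparison:
    """Fixed-law R^2 values and the best-model fraction over a pair subset."""

    r2_additive: float
    r2_multiplicative: float
    r2_fitted_adjusted: float
    frac_multiplicative_better: float
    subset: str
    n_pairs: int


def compare_models(pred: pd.DataFrame, both_active_only: bool = False,
                   r2_fitted_adjusted: float = float("nan")) -> ModelComparison:
    """Compare additive vs multiplicative predictions of pair activity.

    ``pred`` needs columns observed, pred_additive, pred_multiplicative and,
    when ``both_active_only``, a boolean both_active column.  A pair counts
    as multiplicative-better iff |obs - mult| < |obs - add| strictly; ties go
    to additive (conservative for the super-additivity direction).
    """
    sub = pred
    label = "all pairs"
    if both_active_only:
        if "both_active" not in pred.columns:
            raise ValueError("both_active flags required for the both-active subset")
        sub = pred[pred["both_active"].astype(bool)]
        label = "both-active pairs"
    if sub.empty:
        raise ValueError(f"empty subset: {label}")
    obs = sub["observed"].to_numpy(dtype=float)
    add = sub["pred_additive"].to_numpy(dtype=float)
    mult = sub["pred_multiplicative"].to_numpy(dtype=float)
    frac = float(np.mean(np.abs(obs - mult) < np.abs(obs - add)))
    return ModelComparison(
        r2_additive=r_squared(obs, add),
        r2_multiplicative=r_squared(obs, mult),
        r2_fitted_adjusted=r2_fitted_adjusted,
        frac_multiplicative_better=frac,
        subset=label,
        n_pairs=len(sub),
    )


def saturation_curves(pairs: pd.DataFrame, individual: pd.DataFrame,
                      weak_range: tuple[float, float] = (1.0, 1.5),
                      strong_margin: float = 1.0) -> pd.DataFrame:
    """Mean pair activity per partner, anchored by weak or strong enhancers.

    Anchors: *weak* = log2 individual activity in ``weak_range``; *strong* =
    above max(individual activity) - ``strong_margin``.  Anchors on either
    side qualify; for each anchor class, the mean observed pair activity is
    computed per partner (the other enhancer in the pair).  Partners with no
    qualifying pair are omitted.

    Returns columns: anchor_class, partner_id, partner_activity, mean_activity,
    n_pairs.
    """
    act5 = individual[individual["side"] == "5p"].set_index("candidate_id")["log2_activity"]
    act3 = individual[individual["side"] == "3p"].set_index("candidate_id")["log2_activity"]
    amax = float(pd.concat([act5, act3]).max())

    def anchor_class(a: pd.Series) -> pd.Series:
        # weak takes precedence if the activity range is so narrow the classes overlap
        cls = pd.Series(pd.NA, index=a.index, dtype=object)
        cls[a > amax - strong_margin] = "strong"
        cls[(a > weak_range[0]) & (a <= weak_range[1])] = "weak"
        return cls

    cls5 = anchor_class(act5)
    cls3 = anchor_class(act3)

    records = []
    # anchor at 5', partner at 3'
    d5 = pairs.assign(anchor_class=pairs["id5"].map(cls5),
                      partner_id=pairs["id3"],
                      partner_activity=pairs["id3"].map(act3))
    # anchor at 3', partner at 5'
    d3 = pairs.assign(anchor_class=pairs["id3"].map(cls3),
                      partner_id=pairs["id5"],
                      partner_activity=pairs["id5"].map(act5))
    both = pd.concat([d5, d3], ignore_index=True)
    both = both.dropna(subset=["anchor_class", "partner_activity"])
    for cls_name in ("weak", "strong"):
        sub = both[both["anchor_class"] == cls_name]
        if sub.empty:
            warnings.warn(f"no {cls_name} anchors found; class omitted from saturation curves")
            continue
        grp = sub.groupby("partner_id").agg(
            partner_activity=("partner_activity", "mean"),
            mean_activity=("log2_activity", "mean"),
            n_pairs=("log2_activity", "size"),
        ).reset_index()
        grp.insert(0, "anchor_class", cls_name)
        records.append(grp)
    if not records:
        return pd.DataFrame(columns=["anchor_class", "partner_id", "partner_activity",
                                     "mean_activity", "n_pairs"])
    return pd.concat(records, ignore_index=True)


def saturation_slopes(curves: pd.DataFrame) -> dict[str, float]:
    """Least-squares slope of mean pair activity vs partner activity per class."""
    out: dict[str, float] = {}
    for cls_name, sub in curves.groupby("anchor_class"):
        x = sub["partner_activity"].to_numpy(dtype=float)
        y = sub["mean_activity"].to_numpy(dtype=float)
        if len(x) < 2 or np.ptp(x) == 0:
            continue
        out[str(cls_name)] = float(np.polyfit(x, y, 1)[0])
    return out


class PairCooperativityModel:
    """Cooperativity model of pair activities from individual activities.

    Built from a tidy frame of enhancer/enhancer pairs with columns
    pair_id, id5, id3, A (5' log2 individual activity), B (3'), observed
    (log2 pair activity) and optionally both_active.  ``fit()`` runs the
    fixed additive/multiplicative predictions and the OLS interaction fit
    and returns a :class:`CooperativityResults`.
    """

    def __init__(self, data: pd.DataFrame):
        required = {"pair_id", "id5", "id3", "A", "B", "observed"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"model data missing columns: {sorted(missing)}")
        self.data = data.reset_index(drop=True)

    @classmethod
    def from_tables(cls, pair_activities: pd.DataFrame, individual: pd.DataFrame,
                    pool=None) -> "PairCooperativityModel":
        """Assemble model data from pipeline outputs.

        Pairs containing a negative control sequence are discarded (when a
        ``pool`` with class labels is given), and each pair is joined with
        the 5' and 3' individual activities and active flags of its members;
        pairs whose members lack a reported individual activity are dropped.
        """
        pairs = pair_activities.copy()
        if pool is not None:
            classes = pool.classes()
            keep = (pairs["id5"].map(classes) == "enhancer") & \
                   (pairs["id3"].map(classes) == "enhancer")
            pairs = pairs[keep]
        a5 = individual[individual["side"] == "5p"].set_index("candidate_id")
        a3 = individual[individual["side"] == "3p"].set_index("candidate_id")
        data = pd.DataFrame({
            "pair_id": pairs["pair_id"].to_numpy(),
            "id5": pairs["id5"].to_numpy(),
            "id3": pairs["id3"].to_numpy(),
            "A": pairs["id5"].map(a5["log2_activity"]).to_numpy(),
            "B": pairs["id3"].map(a3["log2_activity"]).to_numpy(),
            "observed": pairs["log2_activity"].to_numpy(),
        })
        if "active" in individual.columns:
            data["both_active"] = (
                pairs["id5"].map(a5["active"]).eq(True).to_numpy()
                & pairs["id3"].map(a3["active"]).eq(True).to_numpy())
        data = data.dropna(subset=["A", "B", "observed"]).reset_index(drop=True)
        return cls(data)

    def fit(self) -> "CooperativityResults":
        fit = fit_interaction_model(self.data)
        return CooperativityResults(self, fit)


class CooperativityResults:
    """Fitted cooperativity model: coefficients, predictions and diagnostics."""

    def __init__(self, model: PairCooperativityModel, fit: InteractionFit):
        self.model = model
        self.interaction_fit = fit
        d = model.data
        self.params = pd.Series(fit.params, index=["beta0", "beta1", "beta2", "beta3"])
        self.bse = pd.Series(fit.bse, index=self.params.index)
        self.resid = fit.residuals
        self.rsquared_adj = fit.r2_adjusted
        self.nobs = fit.n_pairs
        self._pred = pd.DataFrame({
            "pair_id": d["pair_id"],
            "id5": d["id5"],
            "id3": d["id3"],
            "A": d["A"],
            "B": d["B"],
            "observed": d["observed"],
            "pred_additive": predict_additive(d["A"], d["B"]),
            "pred_multiplicative": predict_multiplicative(d["A"], d["B"]),
            "pred_fitted": fit.predict(d["A"], d["B"]),
        })
        self._pred["residual"] = self._pred["observed"] - self._pred["pred_fitted"]
        if "both_active" in d.columns:
            self._pred["both_active"] = d["both_active"]

    @property
    def predictions(self) -> pd.DataFrame:
        return self._pred

    @property
    def r2_additive(self) -> float:
        return r_squared(self._pred["observed"], self._pred["pred_additive"])

    @property
    def r2_multiplicative(self) -> float:
        return r_squared(self._pred["observed"], self._pred["pred_multiplicative"])

    def compare_models(self, both_active_only: bool = True) -> ModelComparison:
        return compare_models(self._pred, both_active_only=both_active_only,
                              r2_fitted_adjusted=self.rsquared_adj)

    def saturation_curves(self, individual: pd.DataFrame, **kwargs) -> pd.DataFrame:
        pairs = self._pred.rename(columns={"observed": "log2_activity"})
        return saturation_curves(pairs, individual, **kwargs)

    def summary(self) -> str:
        both = (f"{float(self._pred['both_active'].mean()):.1%}"
                if "both_active" in self._pred.columns else "n/a")
        lines = [
            "Pair cooperativity model (OLS with interaction)",
            f"  pairs:                 {self.nobs} (both active: {both})",
            f"  adj. R^2 (fitted):     {self.rsquared_adj:.3f}",
            f"  R^2 additive:          {self.r2_additive:.3f}",
            f"  R^2 multiplicative:    {self.r2_multiplicative:.3f}",
            "  coefficients (log2 activity units):",
        ]
        for name, val, se in zip(self.params.index, self.params, self.bse):
            lines.append(f"    {name:<6s} {val:+.4f}  (se {se:.4f})")
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Observed vs fitted scatter (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self._pred["pred_fitted"], self._pred["observed"], s=4, alpha=0.3)
        lim = [self._pred[["pred_fitted", "observed"]].min().min(),
               self._pred[["pred_fitted", "observed"]].max().max()]
        ax.plot(lim, lim, ls=":", c="k")
        ax.set_xlabel("fitted pair activity (log2)")
        ax.set_ylabel("observed pair activity (log2)")
        ax.set_title(f"adj. R$^2$ = {self.rsquared_adj:.2f}")
        return ax
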