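"""Secretion, gene-expression and calcium-response statistics.

Covers the hormone-assay side of the analysis: protein-normalized
secretion fold changes with Dunn post-hoc tests and inter-hormone Pearson
correlations; qPCR relative expression (2^dCT against a housekeeper, with
undetermined CTs set to the 40-cycle ceiling) compared between groups by a
ratio paired t-test; and per-cell calcium fold responses tested against 1
with a Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic import SecretionRecord

UNDETERMINED_CT = 40.0


def records_to_frame(records: Iterable[SecretionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "culture_id": r.culture_id,
                "condition": r.condition,
                "hormone": r.hormone,
                "peak_area": r.peak_area,
                "protein_mg": r.protein_mg,
                "replicate": r.replicate,
            }
            for r in records
        ]
    )


def fold_change(
    records: Iterable[SecretionRecord] | pd.DataFrame,
    control_label: str = "control",
) -> pd.DataFrame:
    """Protein-normalized secretion fold change vs same-culture controls.

    Peak areas are first divided by protein content; each well is then
    divided by the mean of the protein-normalized control wells of the
    same culture (and hormone).  Control wells therefore average to fold 1
    within each culture.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df = df.copy()
    if df["protein_mg"].le(0).any():
        raise ValueError("protein_mg must be > 0")
    df["normalized"] = df["peak_area"] / df["protein_mg"]
    ctrl = (
        df[df["condition"] == control_label]
        .groupby(["culture_id", "hormone"])["normalized"]
        .mean()
        .rename("control_mean")
    )
    out = df.join(ctrl, on=["culture_id", "hormone"])
    if out["control_mean"].isna().any():
        missing = out.loc[out["control_mean"].isna(), "culture_id"].unique()
        raise ValueError(f"no {control_label!r} wells for cultures: {list(missing)}")
    if out["control_mean"].eq(0).any():
        raise ValueError("control mean is zero; fold change undefined")
    out["fold"] = out["normalized"] / out["control_mean"]
    return out[
        ["culture_id", "condition", "hormone", "replicate", "fold"]
    ].reset_index(drop=True)


def _dunn_z(rank_means: np.ndarray, ns: np.ndarray, n_total: int, ties_term: float,
            i: int, j: int) -> float:
    var = (n_total * (n_total + 1) / 12.0 - ties_term) * (1.0 / ns[i] + 1.0 / ns[j])
    if var <= 0:
        return 0.0
    return float((rank_means[i] - rank_means[j]) / np.sqrt(var))


def dunn_vs_control(
    folds: Mapping[str, Sequence[float]] | pd.DataFrame,
    control_label: str = "control",
    adjust: str = "holm",
    value_col: str = "fold",
) -> pd.DataFrame:
    """Dunn's post-hoc test of every condition against the control.

    Values from all conditions are pooled and ranked once (the
    Kruskal-Wallis ranking, with tie correction); each condition is
    compared with the control through the two-sided normal z-statistic on
    mean ranks.  P-values are Holm-adjusted by default (``adjust`` may be
    ``"holm"``, ``"bonferroni"`` or ``"none"``).
    """
    if isinstance(folds, pd.DataFrame):
        groups = {k: g[value_col].to_numpy() for k, g in folds.groupby("condition")}
    else:
        groups = {k: np.asarray(v, dtype=float) for k, v in folds.items()}
    if control_label not in groups:
        raise ValueError(f"missing control group {control_label!r}")
    labels = list(groups)
    values = np.concatenate([groups[k] for k in labels])
    ns = np.array([len(groups[k]) for k in labels])
    n_total = len(values)
    ranks = stats.rankdata(values)
    rank_means = np.array(
        [ranks[start : start + n].mean() for start, n in zip(np.cumsum(ns) - ns, ns)]
    )
    _, tie_counts = np.unique(values, return_counts=True)
    ties_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))

    ctrl_idx = labels.index(control_label)
    rows = []
    for i, lab in enumerate(labels):
        if lab == control_label:
            continue
        z = _dunn_z(rank_means, ns, n_total, ties_term, i, ctrl_idx)
        p = 2.0 * stats.norm.sf(abs(z)) if z != 0 else 1.0
        rows.append({"condition": lab, "z": z, "p_raw": min(p, 1.0)})
    result = pd.DataFrame(rows)
    if result.empty:
        return result.assign(p_adjusted=pd.Series(dtype=float))
    if adjust == "none":
        result["p_adjusted"] = result["p_raw"]
    else:
        result["p_adjusted"] = multipletests(result["p_raw"], method=adjust)[1]
    return result


def hormone_correlation(
    x: Sequence[float], y: Sequence[float], log: bool = False
) -> float:
    """Pearson product-moment correlation of matched fold values.

    Pairs are matched by culture x condition x replicate upstream; with
    ``log=True`` folds are log-transformed first.  Returns NaN when either
    side has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired values")
    if log:
        x, y = np.log(x), np.log(y)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def hormone_correlation_matrix(folds: pd.DataFrame, log: bool = False) -> pd.DataFrame:
    """Pairwise Pearson R between hormones on matched fold values."""
    wide = folds.pivot_table(
        index=["culture_id", "condition", "replicate"],
        columns="hormone",
        values="fold",
    ).dropna()
    hormones = list(wide.columns)
    out = pd.DataFrame(np.eye(len(hormones)), index=hormones, columns=hormones)
    for i, a in enumerate(hormones):
        for b in hormones[i + 1 :]:
            r = hormone_correlation(wide[a], wide[b], log=log)
            out.loc[a, b] = out.loc[b, a] = r
    return out


# ---------------------------------------------------------------------------
# qPCR relative expression

@dataclass(frozen=True)
class ExpressionRecord:
    """One sample's CT values for one gene plus the housekeeper."""

    sample_id: str
    group: str  # e.g. GFPpos / GFPneg
    gene: str
    ct: float | None  # None = undetermined (no amplification in 40 cycles)
    housekeeper_ct: float


def relative_expression(
    records: Iterable[ExpressionRecord],
    group_a: str = "GFPpos",
    group_b: str = "GFPneg",
) -> pd.DataFrame:
    """Per-gene 2^dCT expression and ratio paired t-test between groups.

    dCT = housekeeper CT - gene CT; undetermined gene CTs are substituted
    with the 40-cycle ceiling first.  The ratio paired t-test is realized
    as a paired t-test on log expression; samples are paired by sample_id
    across groups, and unpaired samples are an error.
    """
    rows = []
    for r in records:
        ct = UNDETERMINED_CT if r.ct is None else float(r.ct)
        if not 0 < ct <= UNDETERMINED_CT:
            raise ValueError(f"CT {ct} outside (0, {UNDETERMINED_CT}]")
        delta = r.housekeeper_ct - ct
        rows.append(
            {
                "sample_id": r.sample_id,
                "group": r.group,
                "gene": r.gene,
                "delta_ct": delta,
                "expression": 2.0**delta,
            }
        )
    df = pd.DataFrame(rows)
    results = []
    for gene, g in df.groupby("gene"):
        wide = g.pivot_table(index="sample_id", columns="group", values="expression")
        if group_a not in wide or group_b not in wide or wide[[group_a, group_b]].isna().any().any():
            raise ValueError(f"gene {gene}: samples are not fully paired across groups")
        la = np.log(wide[group_a].to_numpy())
        lb = np.log(wide[group_b].to_numpy())
        if np.allclose(la, lb):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(la, lb)
        results.append(
            {
                "gene": gene,
                "n_pairs": len(wide),
                f"mean_expression_{group_a}": float(wide[group_a].mean()),
                f"mean_expression_{group_b}": float(wide[group_b].mean()),
                "ratio_t": float(t),
                "p_value": float(p),
            }
        )
    return pd.DataFrame(results)


# ---------------------------------------------------------------------------
# calcium imaging fold responses

@dataclass
class CaTrace:
    """One cell's background-subtracted fluorescence time series."""

    cell_id: str
    times_s: np.ndarray
    fluorescence: np.ndarray
    application_window_s: tuple[float, float]
    washout_time_s: float

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.times_s.shape != self.fluorescence.shape:
            raise ValueError("times and fluorescence must align")
        lo, hi = self.application_window_s
        if not (self.times_s[0] <= lo < hi <= self.times_s[-1]):
            raise ValueError("application window outside the trace")


def ca_response(trace: CaTrace, baseline_s: float = 30.0) -> float:
    """Fold calcium response of one cell to one drug application.

    Maximum fluorescence during application divided by the average of the
    maxima over the ``baseline_s`` windows immediately before application
    and immediately after washout.  NaN with a zero denominator.
    """
    t, f = trace.times_s, trace.fluorescence
    lo, hi = trace.application_window_s
    during = f[(t >= lo) & (t <= hi)]
    pre = f[(t >= lo - baseline_s) & (t < lo)]
    post = f[(t >= trace.washout_time_s) & (t <= trace.washout_time_s + baseline_s)]
    if len(during) == 0 or len(pre) == 0 or len(post) == 0:
        raise ValueError("empty application/baseline window")
    denom = 0.5 * (pre.max() + post.max())
    if denom == 0:
        return float("nan")
    return float(during.max() / denom)


def ca_cohort_test(folds: Sequence[float]) -> dict:
    """Two-sided Wilcoxon signed-rank test of cohort folds against 1."""
    folds = np.asarray(folds, dtype=float)
    diffs = folds - 1.0
    if np.all(diffs == 0):
        return {"n": len(folds), "statistic": float("nan"), "p_value": 1.0, "significant": False}
    res = stats.wilcoxon(diffs, alternative="two-sided")
    return {
        "n": int(len(folds)),
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "significant": bool(res.pvalue < 0.05),
    }


def responder_mask(
    positive_control_folds: Sequence[Sequence[float]], cutoff: float = 1.1
) -> np.ndarray:
    """Cells responding (fold > cutoff) to at least one positive control."""
    arr = np.asarray(positive_control_folds, dtype=float)
    return np.any(arr > cutoff, axis=0)
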