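"""Repeated-measures statistics: one-way within-subject ANOVA with
sphericity diagnostics, partial eta squared, and Holm-corrected pairwise
post-hoc t-tests.

The design is a complete subjects x conditions matrix for one outcome.
The ANOVA decomposes total variability into condition, subject and
residual sums of squares; sphericity is assessed with Mauchly's W and a
Greenhouse-Geisser epsilon-corrected p value is reported alongside the
uncorrected one.  Post-hoc comparisons are all pairwise two-sided paired
t-tests with Bonferroni-Holm step-down familywise correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class RepeatedMeasuresDesign:
    """Complete subjects x conditions outcome matrix."""

    values: np.ndarray          # (n_subjects, n_conditions)
    conditions: list[str]
    outcome: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x conditions)")
        n, k = self.values.shape
        if k != len(self.conditions):
            raise ValueError("condition labels must match columns")
        if k < 2:
            raise ValueError("need >= 2 conditions")
        if n < 3:
            raise ValueError("need >= 3 subjects")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("design contains missing or non-finite cells")

    @classmethod
    def from_table(cls, table: pd.DataFrame, value_col: str,
                   outcome: str = "") -> "RepeatedMeasuresDesign":
        """Pivot a tidy (subject, condition, value) table into a design."""
        wide = table.pivot_table(index="subject", columns="condition",
                                 values=value_col, sort=False)
        conditions = list(dict.fromkeys(table["condition"]))
        wide = wide[conditions]
        if wide.isna().any().any():
            raise ValueError("incomplete design: missing subject/condition cells")
        return cls(values=wide.to_numpy(), conditions=conditions,
                   outcome=outcome or value_col)


@dataclass
class PairwiseComparison:
    pair: tuple[str, str]
    t: float
    df: int
    p_raw: float
    p_holm: float
    significant: bool
    note: str = ""


@dataclass
class RmAnovaResult:
    outcome: str
    F: float
    df_effect: float
    df_error: float
    p: float
    partial_eta2: float
    mauchly_W: float
    mauchly_chi2: float
    mauchly_df: float
    mauchly_p: float
    gg_epsilon: float
    df_effect_gg: float
    df_error_gg: float
    p_gg: float
    posthoc: list[PairwiseComparison] = field(default_factory=list)

    @property
    def p_selected(self) -> float:
        """GG-corrected p if Mauchly rejects sphericity, else uncorrected."""
        return self.p_gg if self.mauchly_p < 0.05 else self.p

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "outcome", "F", "df_effect", "df_error", "p", "partial_eta2",
            "mauchly_W", "mauchly_chi2", "mauchly_df", "mauchly_p",
            "gg_epsilon", "df_effect_gg", "df_error_gg", "p_gg")}
        d["p_selected"] = self.p_selected
        d["posthoc"] = [
            {"pair": list(c.pair), "t": c.t, "df": c.df, "p_raw": c.p_raw,
             "p_holm": c.p_holm, "significant": c.significant, "note": c.note}
            for c in self.posthoc
        ]
        return d


def _sphericity(values: np.ndarray) -> tuple[float, float, float, float, float]:
    """Mauchly's W with chi-square approximation, and GG epsilon.

    Both are computed from the covariance of the condition scores
    projected onto an orthonormal contrast basis.
    """
    n, k = values.shape
    cov = np.cov(values, rowvar=False, ddof=1)
    # orthonormal contrasts: basis of the space orthogonal to the unit vector
    full = np.linalg.qr(np.column_stack(
        [np.ones(k) / np.sqrt(k), np.eye(k)[:, : k - 1]]))[0]
    m = full[:, 1:].T                             # (k-1, k)
    t_mat = m @ cov @ m.T
    eig = np.linalg.eigvalsh(t_mat)
    eig = np.clip(eig, 0.0, None)
    d = k - 1
    mean_eig = eig.mean()
    if mean_eig <= 0:
        raise ValueError("degenerate covariance: no within-subject variance")
    W = float(np.prod(eig / mean_eig))
    df = d * (d + 1) / 2 - 1
    f_corr = 1.0 - (2 * d ** 2 + d + 2) / (6.0 * d * (n - 1))
    chi2 = -f_corr * (n - 1) * np.log(W) if W > 0 else np.inf
    if df > 0:
        # chi-square approximation with the standard second-order
        # refinement (as in SPSS / ezANOVA)
        w2 = ((d + 2) * (d - 1) * (d - 2) * (2 * d ** 3 + 6 * d ** 2 + 3 * k + 2)
              / (288.0 * ((n - 1) * d * f_corr) ** 2))
        p1 = float(sps.chi2.sf(chi2, df))
        p2 = float(sps.chi2.sf(chi2, df + 4))
        p = p1 + w2 * (p2 - p1)
    else:
        p = 1.0
    gg = float(eig.sum() ** 2 / (d * (eig ** 2).sum()))
    return W, float(chi2), float(df), p, gg


def rm_anova(design: RepeatedMeasuresDesign) -> RmAnovaResult:
    """One-way within-subject ANOVA for the condition factor."""
    x = design.values
    n, k = x.shape
    grand = x.mean()
    ss_total = float(((x - grand) ** 2).sum())
    ss_subj = float(k * ((x.mean(axis=1) - grand) ** 2).sum())
    ss_cond = float(n * ((x.mean(axis=0) - grand) ** 2).sum())
    ss_err = ss_total - ss_subj - ss_cond
    if ss_cond + ss_err <= 0:
        raise ValueError("degenerate outcome: no within-subject variance")
    df_c = k - 1
    df_e = (k - 1) * (n - 1)
    ms_cond = ss_cond / df_c
    ms_err = ss_err / df_e
    if ms_err <= 0:
        raise ValueError("zero residual variance")
    F = ms_cond / ms_err
    p = float(sps.f.sf(F, df_c, df_e))
    partial_eta2 = ss_cond / (ss_cond + ss_err)

    W, chi2, mdf, mp, gg = _sphericity(x)
    df_c_gg = gg * df_c
    df_e_gg = gg * df_e
    p_gg = float(sps.f.sf(F, df_c_gg, df_e_gg))

    return RmAnovaResult(
        outcome=design.outcome, F=float(F), df_effect=float(df_c),
        df_error=float(df_e), p=p, partial_eta2=float(partial_eta2),
        mauchly_W=W, mauchly_chi2=chi2, mauchly_df=mdf, mauchly_p=mp,
        gg_epsilon=gg, df_effect_gg=float(df_c_gg), df_error_gg=float(df_e_gg),
        p_gg=p_gg,
    )


def holm_adjust(p_raw: np.ndarray) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p values.

    p_(i) sorted ascending; adjusted p_(i) = max_{j<=i} min(1, (m-j+1) p_(j)).
    """
    p_raw = np.asarray(p_raw, dtype=np.float64)
    m = p_raw.size
    order = np.argsort(p_raw, kind="stable")
    adj_sorted = np.minimum(1.0, (m - np.arange(m)) * p_raw[order])
    adj_sorted = np.maximum.accumulate(adj_sorted)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def holm_posthoc(design: RepeatedMeasuresDesign,
                 alpha: float = 0.05) -> list[PairwiseComparison]:
    """All pairwise two-sided paired t-tests with Holm correction."""
    x = design.values
    n, k = x.shape
    pairs = list(combinations(range(k), 2))
    t_vals, p_vals, notes = [], [], []
    for i, j in pairs:
        diff = x[:, i] - x[:, j]
        if np.ptp(diff) < 1e-12 * max(1.0, float(np.abs(diff).max())):
            t_vals.append(0.0)
            p_vals.append(1.0)
            notes.append("zero-variance difference; p set to 1")
            continue
        t, p = sps.ttest_rel(x[:, i], x[:, j])
        t_vals.append(float(t))
        p_vals.append(float(p))
        notes.append("")
    p_holm = holm_adjust(np.array(p_vals))
    return [
        PairwiseComparison(
            pair=(design.conditions[i], design.conditions[j]),
            t=t_vals[idx], df=n - 1, p_raw=p_vals[idx],
            p_holm=float(p_holm[idx]),
            significant=bool(p_holm[idx] < alpha), note=notes[idx],
        )
        for idx, (i, j) in enumerate(pairs)
    ]


def run_full_stats(metric_table: pd.DataFrame, outcomes: list[str],
                   alpha: float = 0.05,
                   min_conditions: int = 2) -> dict[str, RmAnovaResult]:
    """One rmANOVA per outcome; post hocs only on significant main effects.

    ``metric_table`` is a tidy table with subject, condition, band and
    metric columns (e.g. from :func:`rsnet.graph.normalize_metrics`);
    each outcome is "<metric>:<band>", e.g. "swi:theta".
    """
    results: dict[str, RmAnovaResult] = {}
    for outcome in outcomes:
        metric, _, band = outcome.partition(":")
        sub = metric_table[metric_table["band"] == band] if band else metric_table
        if sub.empty:
            raise ValueError(f"no rows for outcome {outcome!r}")
        # "cc"/"pl" refer to the normalized columns of the metric table
        col = metric if metric in sub.columns else f"{metric}_norm"
        if col not in sub.columns:
            raise ValueError(f"metric table has no column for {metric!r}")
        design = RepeatedMeasuresDesign.from_table(sub, col, outcome=outcome)
        res = rm_anova(design)
        if res.p_selected < alpha:
            res.posthoc = holm_posthoc(design, alpha=alpha)
        results[outcome] = res
    return results


def format_results(results: dict[str, RmAnovaResult]) -> str:
    """Human-readable summary, one ANOVA line per outcome."""
    lines = []
    for name, r in results.items():
        lines.append(
            f"{name}: F({r.df_effect:.0f}, {r.df_error:.0f}) = {r.F:.2f}, "
            f"p = {r.p:.4g} (GG p = {r.p_gg:.4g}), "
            f"partial eta^2 = {r.partial_eta2:.3f}, "
            f"Mauchly W = {r.mauchly_W:.3f} (p = {r.mauchly_p:.3g})"
        )
        for c in r.posthoc:
            if c.significant:
                lines.append(
                    f"    {c.pair[0]} vs {c.pair[1]}: t({c.df}) = {c.t:.2f},"
                    f" Holm p = {c.p_holm:.4g} *"
                )
    return "\n".join(lines)
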