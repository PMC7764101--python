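"""Group-level inference: factorial ANOVA and Bonferroni post-hoc tests.

Each quantitative measure (striatal SDI, midbrain SDI, FA) is fitted with a
fixed-effects three-way ANOVA with side, parcel and diagnosis as crossed
factors, using Type III sums of squares (sum-to-zero contrasts), which is
well defined for the unbalanced HC/SZ design.  Partial effect sizes are
reported as partial eta squared, SS_effect / (SS_effect + SS_error).
Observation rows (subject x side x parcel) are treated as independent,
matching the residual degrees of freedom of the original design.

Post-hoc pairwise comparisons use the model's residual mean square, with
Bonferroni adjustment (adjusted p = raw p times the number of pairs).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

DEFAULT_FACTORS = ("side", "parcel", "diagnosis")
_SS_TOL = 1e-10


@dataclass
class AnovaResult:
    """Per-term F, degrees of freedom, p, and partial eta squared."""

    table: pd.DataFrame          # index: term names; columns below
    df_resid: float
    ss_resid: float
    mse: float
    measure: str = ""

    def term(self, name):
        return self.table.loc[name]

    def to_dict(self):
        return {
            "measure": self.measure,
            "df_resid": self.df_resid,
            "terms": {
                t: {k: (None if pd.isna(v) else float(v))
                    for k, v in row.items()}
                for t, row in self.table.iterrows()
            },
        }


@dataclass
class PosthocResult:
    factor: str
    table: pd.DataFrame          # level_a, level_b, mean_diff, t, p_raw, p_adj
    n_comparisons: int
    alpha: float = 0.05
    measure: str = ""

    def to_dict(self):
        return {
            "measure": self.measure, "factor": self.factor,
            "n_comparisons": self.n_comparisons, "alpha": self.alpha,
            "pairs": self.table.to_dict(orient="records"),
        }


def _check_design(table, measure, factors):
    sub = table[table["measure"] == measure] if "measure" in table else table
    if len(sub) == 0:
        raise ValueError(f"no rows for measure {measure!r}")
    levels = {}
    for f in factors:
        levels[f] = sorted(sub[f].unique())
        if len(levels[f]) < 2:
            raise ValueError(f"factor {f!r} has fewer than two levels")
    for combo in product(*levels.values()):
        m = np.ones(len(sub), dtype=bool)
        for f, lev in zip(factors, combo):
            m &= (sub[f] == lev).to_numpy()
        if not m.any():
            cell = ", ".join(f"{f}={lev}" for f, lev in zip(factors, combo))
            raise ValueError(f"design cell ({cell}) is empty")
    return sub.reset_index(drop=True)


def _fit_full_model(sub, factors):
    rhs = " * ".join(f"C({f}, Sum)" for f in factors)
    model = smf.ols(f"value ~ {rhs}", data=sub)
    return model.fit()


def _term_label(raw, factors):
    parts = []
    for piece in raw.split(":"):
        for f in factors:
            if f"C({f}, Sum)" == piece.strip():
                parts.append(f)
    return ":".join(parts) if parts else raw


def fit_anova(table, measure, factors=DEFAULT_FACTORS,
              ss_type=3) -> AnovaResult:
    """Full-factorial fixed-effects ANOVA for one measure.

    Type III sums of squares by default (sensible for the unbalanced HC/SZ
    design); Type II is a switch.  Degenerate designs are handled
    explicitly: with zero residual variance, terms with positive SS get
    F = inf (p = 0) and terms with zero SS get F = 0 (p = 1).
    """
    sub = _check_design(table, measure, factors)
    fit = _fit_full_model(sub, factors)
    at = anova_lm(fit, typ=ss_type)
    if "Intercept" not in at.index:
        at.loc["Intercept"] = 0.0   # typ=2 omits it; unify the layout
    ss_resid = float(at.loc["Residual", "sum_sq"])
    df_resid = float(at.loc["Residual", "df"])
    mse = ss_resid / df_resid if df_resid > 0 else np.nan

    scale = max(float(np.var(sub["value"])) * len(sub), 1.0)
    rows = {}
    for raw, r in at.iterrows():
        if raw in ("Residual", "Intercept"):
            continue
        name = _term_label(raw, factors)
        ss, df = float(r["sum_sq"]), float(r["df"])
        if ss_resid <= _SS_TOL * scale:
            if ss <= _SS_TOL * scale:
                F, p, eta = 0.0, 1.0, 0.0
            else:
                F, p, eta = np.inf, 0.0, 1.0
        else:
            F = (ss / df) / mse
            p = float(sps.f.sf(F, df, df_resid))
            eta = ss / (ss + ss_resid)
        rows[name] = dict(F=F, df_num=df, df_den=df_resid, p=p,
                          partial_eta_sq=eta, sum_sq=ss)
    out = pd.DataFrame(rows).T[["F", "df_num", "df_den", "p",
                                "partial_eta_sq", "sum_sq"]]
    return AnovaResult(table=out, df_resid=df_resid, ss_resid=ss_resid,
                       mse=mse, measure=measure)


def posthoc_bonferroni(table, factor, measure, factors=DEFAULT_FACTORS,
                       alpha=0.05) -> PosthocResult:
    """All pairwise level contrasts of one factor, Bonferroni adjusted.

    The standard error uses the residual mean square of the full factorial
    model (the error term of the ANOVA), as classical post-hoc tests do.
    """
    sub = _check_design(table, measure, factors)
    levels = sorted(sub[factor].unique())
    pairs = list(combinations(levels, 2))
    k = len(pairs)
    anova = fit_anova(table, measure, factors)
    mse, dfr = anova.mse, anova.df_resid
    rows = []
    for a, b in pairs:
        va = sub.loc[sub[factor] == a, "value"]
        vb = sub.loc[sub[factor] == b, "value"]
        diff = float(va.mean() - vb.mean())
        se = np.sqrt(mse * (1.0 / len(va) + 1.0 / len(vb)))
        if se <= 0 or not np.isfinite(se):
            t = np.inf if abs(diff) > 0 else 0.0
            p = 0.0 if abs(diff) > 0 else 1.0
        else:
            t = diff / se
            p = 2.0 * float(sps.t.sf(abs(t), dfr))
        rows.append(dict(level_a=a, level_b=b, mean_diff=diff, t=t,
                         p_raw=p, p_adj=min(1.0, p * k),
                         significant=min(1.0, p * k) < alpha))
    return PosthocResult(factor=factor, table=pd.DataFrame(rows),
                         n_comparisons=k, alpha=alpha, measure=measure)


@dataclass
class GroupReport:
    """Per-measure ANOVA + post-hocs + Table-2-style cell summaries."""

    anovas: dict = dc_field(default_factory=dict)
    posthocs: dict = dc_field(default_factory=dict)     # (measure, factor)
    summaries: dict = dc_field(default_factory=dict)    # measure -> DataFrame
    missing_subjects: list = dc_field(default_factory=list)

    def to_dict(self):
        return {
            "missing_subjects": self.missing_subjects,
            "anova": {m: a.to_dict() for m, a in self.anovas.items()},
            "posthoc": {f"{m}:{f}": p.to_dict()
                        for (m, f), p in self.posthocs.items()},
            "summary": {m: s.to_dict(orient="records")
                        for m, s in self.summaries.items()},
        }


def summarize_cells(table, measure):
    """Mean and SD per parcel x diagnosis x side cell (Table-2 layout)."""
    sub = table[table["measure"] == measure]
    g = (sub.groupby(["parcel", "diagnosis", "side"])["value"]
         .agg(["mean", "std", "count"]).reset_index())
    return g.rename(columns={"mean": "mean", "std": "sd", "count": "n"})


def run_group_analysis(table, measures=None, factors=DEFAULT_FACTORS,
                       posthoc_factors=("parcel",), alpha=0.05,
                       ss_type=3, expected_subjects=None) -> GroupReport:
    """ANOVA + Bonferroni post-hocs + cell summaries for every measure.

    ``expected_subjects`` lists subjects that should be present; missing
    ones are recorded and the analysis proceeds as long as each diagnosis
    group retains at least two subjects.
    """
    report = GroupReport()
    if expected_subjects is not None:
        present = set(table["subject"].unique())
        report.missing_subjects = sorted(set(expected_subjects) - present)
    for dx in table["diagnosis"].unique():
        n = table.loc[table["diagnosis"] == dx, "subject"].nunique()
        if n < 2:
            raise ValueError(f"diagnosis group {dx!r} has fewer than two "
                             "subjects; cannot run group analysis")
    if measures is None:
        measures = list(table["measure"].unique())
    for m in measures:
        report.anovas[m] = fit_anova(table, m, factors, ss_type=ss_type)
        for f in posthoc_factors:
            report.posthocs[(m, f)] = posthoc_bonferroni(
                table, f, m, factors, alpha)
        report.summaries[m] = summarize_cells(table, m)
    return report


def simulate_measure_table(parcel_means, sd, n_hc, n_sz, rng, measure="sdi",
                           diagnosis_offset=0.0, side_offset=0.0):
    """Synthetic long-format measure table for power/calibration studies.

    Draws one value per subject x side x parcel from Normal(mean, sd) where
    the mean is the parcel's injected mean plus optional diagnosis and side
    shifts.  Used to probe the inference layer at known effect sizes.
    """
    rows = []
    for i in range(n_hc + n_sz):
        dx = "HC" if i < n_hc else "SZ"
        subject = f"{dx}{(i if dx == 'HC' else i - n_hc) + 1:02d}"
        for side in ("L", "R"):
            for parcel, mu in parcel_means.items():
                mean = mu
                if dx == "SZ":
                    mean += diagnosis_offset
                if side == "R":
                    mean += side_offset
                rows.append(dict(subject=subject, diagnosis=dx, side=side,
                                 parcel=parcel, measure=measure,
                                 value=rng.normal(mean, sd)))
    return pd.DataFrame(rows)
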