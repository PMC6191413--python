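"""Cluster-mean extraction, repeated-measures ANOVA and paired tests.

Cell tables are tidy DataFrames — one row per subject × cluster × factor
cell — fed into a balanced within-subject ANOVA (every factor varies
within subjects, one observation per cell). Each effect is tested
against its interaction with subjects, and effect size is reported as
partial eta squared, SS_effect / (SS_effect + SS_error). No sphericity
correction is applied. Display error bars use the within-participant
95% CI of the condition difference divided by √2, so that the interval
drawn on each of the two condition means reflects the paired contrast.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import ClusterSet


@dataclass
class AnovaResult:
    """Within-subject ANOVA results with the full SS bookkeeping."""

    table: pd.DataFrame  # effect, ss, df_num, df_den, F, p, partial_eta_sq, ss_error
    ss_subject: float
    ss_total: float
    n_subjects: int

    def effect(self, name: str) -> pd.Series:
        row = self.table[self.table["effect"] == name]
        if row.empty:
            raise KeyError(f"no effect named {name!r}; have {list(self.table['effect'])}")
        return row.iloc[0]

    def summary(self) -> str:
        lines = [f"Repeated-measures ANOVA (N = {self.n_subjects})"]
        for _, r in self.table.iterrows():
            lines.append(
                f"  {r['effect']:<30s} F({r['df_num']:d},{r['df_den']:d}) = {r['F']:.3f}, "
                f"p = {r['p']:.4f}, partial eta^2 = {r['partial_eta_sq']:.3f}"
            )
        return "\n".join(lines)


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    degenerate: bool = False  # zero-variance differences


def _effect_ss(Y: np.ndarray, axes: tuple[int, ...]) -> float:
    """Sum of squares for the effect spanned by ``axes`` of a full tensor.

    Yates-style inclusion–exclusion over marginal means: the effect term
    at each cell of the spanned axes is the alternating sum of marginal
    means of its subsets, and the SS weights each squared term by the
    number of observations collapsed over.
    """
    all_axes = tuple(range(Y.ndim))
    term = np.zeros([Y.shape[a] if a in axes else 1 for a in all_axes])
    for r in range(len(axes) + 1):
        for sub in itertools.combinations(axes, r):
            collapse = tuple(a for a in all_axes if a not in sub)
            marg = Y.mean(axis=collapse, keepdims=True)
            term = term + ((-1) ** (len(axes) - len(sub))) * marg
    weight = np.prod([Y.shape[a] for a in all_axes if a not in axes])
    return float(weight * np.sum(term**2))


def rm_anova(
    table: pd.DataFrame,
    factors: list[str],
    subject: str = "subject_id",
    value: str = "value",
) -> AnovaResult:
    """Balanced within-subject ANOVA for 1–3 (or more) crossed factors.

    Every subject must contribute exactly one value per factor-level
    combination; missing cells are an error listing the gaps. F for each
    effect uses the effect × subject interaction as its error term.
    """
    if not factors:
        raise ValueError("at least one factor is required")
    subjects = sorted(table[subject].unique())
    levels = {f: sorted(table[f].unique()) for f in factors}

    expected = set(itertools.product(subjects, *(levels[f] for f in factors)))
    got = set(map(tuple, table[[subject, *factors]].itertuples(index=False)))
    missing = expected - got
    if missing:
        raise ValueError(f"cell table is not fully crossed; missing cells: {sorted(missing)[:10]}")
    if len(got) != len(table):
        dup = table[table.duplicated([subject, *factors], keep=False)]
        raise ValueError(f"duplicate observations per cell:\n{dup.head()}")

    shape = [len(subjects)] + [len(levels[f]) for f in factors]
    Y = np.full(shape, np.nan)
    sub_ix = {s: i for i, s in enumerate(subjects)}
    lev_ix = [{l: i for i, l in enumerate(levels[f])} for f in factors]
    for row in table.itertuples(index=False):
        d = row._asdict()
        idx = (sub_ix[d[subject]], *(lev_ix[i][d[f]] for i, f in enumerate(factors)))
        Y[idx] = d[value]

    rows = []
    factor_axes = {f: i + 1 for i, f in enumerate(factors)}
    for r in range(1, len(factors) + 1):
        for combo in itertools.combinations(factors, r):
            axes = tuple(factor_axes[f] for f in combo)
            ss = _effect_ss(Y, axes)
            ss_err = _effect_ss(Y, (0, *axes))
            df_num = int(np.prod([len(levels[f]) - 1 for f in combo]))
            df_den = df_num * (len(subjects) - 1)
            ms, ms_err = ss / df_num, ss_err / df_den
            if ms_err > 0:
                F = ms / ms_err
            else:
                F = 0.0 if ms <= 1e-24 else np.inf  # no effect and no error → F = 0
            p = float(stats.f.sf(F, df_num, df_den)) if np.isfinite(F) else 0.0
            rows.append(
                {
                    "effect": " x ".join(combo),
                    "ss": ss,
                    "ss_error": ss_err,
                    "df_num": df_num,
                    "df_den": df_den,
                    "F": F,
                    "p": p,
                    "partial_eta_sq": ss / (ss + ss_err) if (ss + ss_err) > 0 else 0.0,
                }
            )
    return AnovaResult(
        table=pd.DataFrame(rows),
        ss_subject=_effect_ss(Y, (0,)),
        ss_total=float(np.sum((Y - Y.mean()) ** 2)),
        n_subjects=len(subjects),
    )


def paired_t(x: np.ndarray, y: np.ndarray) -> TTestResult:
    """Two-sided paired t test on per-subject values."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("paired_t needs two equal-length 1-D arrays of length >= 2")
    d = x - y
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return TTestResult(t=0.0, df=n - 1, p=1.0, degenerate=True)
        return TTestResult(t=float(np.sign(d.mean()) * np.inf), df=n - 1, p=0.0, degenerate=True)
    res = stats.ttest_rel(x, y)
    return TTestResult(t=float(res.statistic), df=n - 1, p=float(res.pvalue))


def within_subject_ci(
    table: pd.DataFrame,
    factor: str,
    subject: str = "subject_id",
    value: str = "value",
) -> pd.DataFrame:
    """Within-participant 95% CI half-widths for a two-level factor.

    Half-width = t₀.₉₇₅,ₙ₋₁ · SD(per-subject difference)/√n ÷ √2,
    computed separately within every combination of the remaining
    grouping columns and applied to both cells of the factor.
    """
    lv = sorted(table[factor].unique())
    if len(lv) != 2:
        raise ValueError(f"within-subject CI is defined for a 2-level factor; {factor} has levels {lv}")
    others = [c for c in table.columns if c not in (factor, subject, value)]

    def half(grp: pd.DataFrame) -> float:
        wide = grp.pivot_table(index=subject, columns=factor, values=value)
        d = (wide[lv[0]] - wide[lv[1]]).to_numpy(float)
        n = len(d)
        tq = stats.t.ppf(0.975, n - 1)
        return float(tq * d.std(ddof=1) / np.sqrt(n) / np.sqrt(2.0))

    if others:
        out = table.groupby(others, sort=True).apply(half, include_groups=False).rename("ci_half_width").reset_index()
    else:
        out = pd.DataFrame({"ci_half_width": [half(table)]})
    return out


def extract_cluster_means(
    volumes: dict[str, dict[tuple, np.ndarray]],
    rois: ClusterSet,
    factor_names: list[str],
) -> pd.DataFrame:
    """Cluster-mean values per subject × cluster × cell.

    ``volumes[subject][cell]`` is a 3-D volume, with ``cell`` a tuple of
    factor levels named by ``factor_names``. A cluster voxel falling on a
    non-finite value (outside the volume's mask) is an error.
    """
    rows = []
    for subject, cells in sorted(volumes.items()):
        for cell, vol in sorted(cells.items()):
            cell = cell if isinstance(cell, tuple) else (cell,)
            if len(cell) != len(factor_names):
                raise ValueError(f"cell {cell} does not match factors {factor_names}")
            for cl in rois:
                vals = np.asarray([vol[v] for v in cl.voxels], float)
                if not np.all(np.isfinite(vals)):
                    raise ValueError(
                        f"cluster {cl.label} has voxels outside the valid mask for subject {subject}"
                    )
                rows.append(
                    {
                        "subject_id": subject,
                        "cluster": cl.label,
                        **dict(zip(factor_names, cell)),
                        "value": float(vals.mean()),
                    }
                )
    return pd.DataFrame(rows)
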