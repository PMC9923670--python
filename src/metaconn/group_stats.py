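"""Bootstrap-resampled factorial ANOVA with Sidak-corrected pairwise tests.

Two designs are covered: a split-plot (mixed) two-way ANOVA with one
within-subject factor (e.g. hemisphere or timepoint, two or more levels)
crossed with a between-subject factor (treatment), and an ordinary
one-way ANOVA.  F statistics come from the classical decompositions;
p-values are additionally obtained from a bootstrap null built by
resampling full-model residuals onto the fit of the model *without* the
tested effect (per-effect nulls), which keeps the factorial structure
at the small sample sizes typical of animal studies.  Case resampling
is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class FactorialDesign:
    """Long-format split-plot design.

    ``data`` columns: subject, group (between factor), within (within
    factor level), value.  Every subject must have exactly one value per
    within level; every group needs at least two subjects.
    """

    data: pd.DataFrame
    subject_col: str = "subject"
    group_col: str = "group"
    within_col: str = "within"
    value_col: str = "value"

    def __post_init__(self) -> None:
        d = self.data
        levels = sorted(d[self.within_col].unique())
        bad = []
        for s, sub in d.groupby(self.subject_col):
            if sorted(sub[self.within_col]) != levels:
                bad.append(s)
        if bad:
            raise ValueError(
                f"subjects with incomplete within-factor data: {bad}"
            )
        counts = d.groupby(self.group_col)[self.subject_col].nunique()
        small = counts[counts < 2]
        if len(small):
            raise ValueError(f"groups with < 2 subjects: {dict(small)}")

    def to_matrix(self) -> tuple[np.ndarray, np.ndarray, list, list]:
        """(subjects x within-levels value matrix, per-subject group index,
        group labels, within labels)."""
        d = self.data
        wide = d.pivot_table(
            index=self.subject_col, columns=self.within_col,
            values=self.value_col, sort=True,
        )
        groups = d.drop_duplicates(self.subject_col).set_index(self.subject_col)[
            self.group_col
        ]
        group_labels = sorted(groups.unique())
        gidx = np.array([group_labels.index(groups[s]) for s in wide.index])
        return wide.to_numpy(float), gidx, group_labels, list(wide.columns)


@dataclass
class AnovaResult:
    effects: pd.DataFrame  # effect, F, df1, df2, p_classical, p_boot
    pairwise: pd.DataFrame  # contrast columns + t, p, p_sidak
    n_boot: int
    seed: int
    scheme: str  # residual | case

    def effect(self, name: str) -> pd.Series:
        return self.effects.set_index("effect").loc[name]


def _split_plot_F(y: np.ndarray, gidx: np.ndarray, n_groups: int):
    """Classical split-plot F statistics for a subjects x levels matrix.

    Returns ((F_between, df...), (F_within, ...), (F_interaction, ...)).
    Zero mean squares yield F = 0 (constant data), not NaN.
    """
    n, w = y.shape
    grand = y.mean()
    subj_means = y.mean(axis=1)
    group_sizes = np.bincount(gidx, minlength=n_groups).astype(float)
    group_means = np.bincount(gidx, weights=subj_means, minlength=n_groups) / group_sizes

    ss_between = w * float(np.sum(group_sizes * (group_means - grand) ** 2))
    ss_subj = w * float(np.sum((subj_means - group_means[gidx]) ** 2))
    df_between, df_subj = n_groups - 1, n - n_groups

    d = y - subj_means[:, None]  # within-subject deviations
    cell = np.zeros((n_groups, w))
    for g in range(n_groups):
        cell[g] = d[gidx == g].mean(axis=0)
    level_means = (group_sizes @ cell) / n
    ss_within = n * float(np.sum(level_means**2))
    ss_inter = float(np.sum(group_sizes[:, None] * (cell - level_means) ** 2))
    ss_err = float(np.sum((d - cell[gidx]) ** 2))
    df_within = w - 1
    df_inter = (w - 1) * (n_groups - 1)
    df_err = (w - 1) * (n - n_groups)

    def f(ss, df, ss_e, df_e):
        ms, ms_e = ss / df, ss_e / df_e
        return ms / ms_e if ms_e > 0 else 0.0

    return {
        "between": (f(ss_between, df_between, ss_subj, df_subj), df_between, df_subj),
        "within": (f(ss_within, df_within, ss_err, df_err), df_within, df_err),
        "interaction": (f(ss_inter, df_inter, ss_err, df_err), df_inter, df_err),
    }


def _reduced_fixed_fit(y, gidx, n_groups, effect):
    """Fixed-effects fit of the split-plot model with one effect removed.

    Subject random effects are excluded; they are resampled separately
    in the bootstrap (two error strata).
    """
    n, w = y.shape
    grand = y.mean()
    subj_means = y.mean(axis=1)
    group_sizes = np.bincount(gidx, minlength=n_groups).astype(float)
    group_means = np.bincount(gidx, weights=subj_means, minlength=n_groups) / group_sizes
    d = y - subj_means[:, None]
    cell = np.zeros((n_groups, w))
    for g in range(n_groups):
        cell[g] = d[gidx == g].mean(axis=0)
    level = (group_sizes @ cell) / n
    inter = cell - level
    a = (group_means - grand)[gidx][:, None]
    if effect == "between":
        return grand + cell[gidx]
    if effect == "within":
        return grand + a + inter[gidx]
    if effect == "interaction":
        return grand + a + level[None, :]
    raise ValueError(effect)


def mixed_anova_boot(
    design: FactorialDesign,
    n_boot: int = 10000,
    seed: int = 0,
    scheme: str = "residual",
) -> AnovaResult:
    """Split-plot two-way ANOVA with bootstrap p-values.

    F statistics use the classical decomposition (between-group effect
    tested against subjects-within-groups; within and interaction
    against the subject-by-within residual).  For each effect the
    bootstrap null rebuilds data as the reduced fixed-effects fit
    lacking that effect plus resampled subject-level residuals plus
    resampled within-subject residuals (the design's two error strata),
    then recomputes F; p = (1 + #{F* >= F_obs}) / (n_boot + 1).
    Classical parametric p-values are reported alongside.
    """
    if scheme not in ("residual", "case"):
        raise ValueError("scheme must be 'residual' or 'case'")
    y, gidx, group_labels, within_labels = design.to_matrix()
    n_groups = len(group_labels)
    obs = _split_plot_F(y, gidx, n_groups)

    # full-model residuals: y - (subject mean + group cell deviation)
    subj_means = y.mean(axis=1)
    d = y - subj_means[:, None]
    cell = np.zeros((n_groups, y.shape[1]))
    for g in range(n_groups):
        cell[g] = d[gidx == g].mean(axis=0)
    resid = d - cell[gidx]

    rng = np.random.default_rng(seed)
    exceed = {e: 0 for e in obs}
    flat = resid.ravel()
    reduced = {e: _reduced_fixed_fit(y, gidx, n_groups, e) for e in obs}
    group_sizes = np.bincount(gidx, minlength=n_groups).astype(float)
    group_means = np.bincount(gidx, weights=subj_means, minlength=n_groups) / group_sizes
    subj_resid = subj_means - group_means[gidx]  # subject-level stratum
    # data with all fixed effects removed, subject variability kept
    y_null = y - cell[gidx] - (group_means[gidx] - y.mean())[:, None]
    for _ in range(n_boot):
        if scheme == "residual":
            s_star = rng.choice(subj_resid, size=len(y), replace=True)
            e_star = rng.choice(flat, size=y.shape, replace=True)
            noise = s_star[:, None] + e_star
            for effect in obs:
                f_star = _split_plot_F(reduced[effect] + noise, gidx, n_groups)
                if f_star[effect][0] >= obs[effect][0] - 1e-12:
                    exceed[effect] += 1
        else:  # case resampling of null-centred subjects within groups
            idx = np.concatenate([
                rng.choice(np.where(gidx == g)[0], size=(gidx == g).sum())
                for g in range(n_groups)
            ])
            f_stars = _split_plot_F(y_null[idx], gidx, n_groups)
            for effect in obs:
                if f_stars[effect][0] >= obs[effect][0] - 1e-12:
                    exceed[effect] += 1

    rows = []
    for effect, (F, df1, df2) in obs.items():
        p_cl = float(stats.f.sf(F, df1, df2)) if F > 0 else 1.0
        rows.append(
            (effect, F, df1, df2, p_cl, (1 + exceed[effect]) / (n_boot + 1))
        )
    effects = pd.DataFrame(
        rows, columns=["effect", "F", "df1", "df2", "p_classical", "p_boot"]
    )
    pairwise = _mixed_pairwise(y, gidx, group_labels, within_labels)
    return AnovaResult(effects, pairwise, n_boot, seed, scheme)


def _mixed_pairwise(y, gidx, group_labels, within_labels) -> pd.DataFrame:
    """Sidak-corrected pairwise contrasts within one split-plot ANOVA.

    Family: between-group comparisons at each within level (Welch t)
    plus within-level comparisons inside each group (paired t).
    """
    rows = []
    n_groups = len(group_labels)
    for w, wl in enumerate(within_labels):
        for g1 in range(n_groups):
            for g2 in range(g1 + 1, n_groups):
                a, b = y[gidx == g1, w], y[gidx == g2, w]
                t, p = stats.ttest_ind(a, b, equal_var=False)
                rows.append((f"{group_labels[g1]} vs {group_labels[g2]} @ {wl}",
                             float(t), float(p)))
    for g in range(n_groups):
        sub = y[gidx == g]
        for w1 in range(len(within_labels)):
            for w2 in range(w1 + 1, len(within_labels)):
                t, p = stats.ttest_rel(sub[:, w1], sub[:, w2])
                rows.append(
                    (f"{within_labels[w1]} vs {within_labels[w2]} "
                     f"@ {group_labels[g]}", float(t), float(p))
                )
    df = pd.DataFrame(rows, columns=["contrast", "t", "p"])
    df["p_sidak"] = sidak_adjust(df["p"].to_numpy(), len(df))
    return df


def oneway_anova_boot(
    values_by_group: dict[str, np.ndarray],
    n_boot: int = 10000,
    seed: int = 0,
) -> AnovaResult:
    """One-way ANOVA with a residual-resampling bootstrap null.

    The null is built by centring every group (removing group means) and
    resampling the pooled residuals onto the grand mean, preserving the
    group sizes; F is recomputed per bootstrap sample.
    """
    labels = list(values_by_group)
    groups = [np.asarray(values_by_group[g], float) for g in labels]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    sizes = np.array([len(g) for g in groups])
    y = np.concatenate(groups)
    gidx = np.repeat(np.arange(len(groups)), sizes)

    def f_stat(v):
        means = np.array([v[gidx == g].mean() for g in range(len(groups))])
        grand = v.mean()
        ss_b = float(np.sum(sizes * (means - grand) ** 2))
        ss_w = float(np.sum((v - means[gidx]) ** 2))
        df1, df2 = len(groups) - 1, len(v) - len(groups)
        ms_b, ms_w = ss_b / df1, ss_w / df2
        return (ms_b / ms_w if ms_w > 0 else 0.0), df1, df2

    F, df1, df2 = f_stat(y)
    resid = y - np.array([g.mean() for g in groups])[gidx]
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_boot):
        y_star = y.mean() + rng.choice(resid, size=len(y), replace=True)
        if f_stat(y_star)[0] >= F - 1e-12:
            count += 1
    p_boot = (1 + count) / (n_boot + 1)
    p_cl = float(stats.f.sf(F, df1, df2)) if F > 0 else 1.0
    effects = pd.DataFrame(
        [("between", F, df1, df2, p_cl, p_boot)],
        columns=["effect", "F", "df1", "df2", "p_classical", "p_boot"],
    )
    rows = []
    pairs = [(i, j) for i in range(len(groups)) for j in range(i + 1, len(groups))]
    for i, j in pairs:
        t, p = stats.ttest_ind(groups[i], groups[j], equal_var=False)
        rows.append((f"{labels[i]} vs {labels[j]}", float(t), float(p)))
    pairwise = pd.DataFrame(rows, columns=["contrast", "t", "p"])
    pairwise["p_sidak"] = sidak_adjust(pairwise["p"].to_numpy(), len(pairs))
    return AnovaResult(effects, pairwise, n_boot, seed, "residual")


def sidak_adjust(p, m: int):
    """Sidak multiplicity adjustment: 1 - (1 - p)^m, capped at 1."""
    if m < 1:
        raise ValueError("m must be >= 1")
    p = np.asarray(p, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, 1.0 - (1.0 - p) ** m)
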