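"""Nested two-way linear-model comparisons of phenotypes between species.

For a trait measured on individuals with sex and group (species) labels,
we fit the nested ordinary-least-squares models

    Group,  Sex,  Sex + Group,  Sex * Group

and report F-tests built from residual sums of squares:

* ``group_effect`` -- the group term corrected for sex: incremental SS of
  Group over Sex on 1 df, against the full-model (Sex * Group) mean square.
* ``sex_any`` -- any sex effect in at least one group: Sex * Group vs
  Group (2 df).
* ``interaction`` -- sex effect differing between groups: Sex * Group vs
  Sex + Group (1 df).

Post-hoc per-group two-sample t-tests (equal variance) compare the sexes
within each group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class FTest:
    F: float
    df1: int
    df2: int
    p: float


@dataclass
class PosthocT:
    group: object
    t: float
    df: int
    p: float
    direction: str  # e.g. "F > M" for the sign of (mean_F - mean_M)


@dataclass
class AnovaResult:
    group_effect: FTest
    sex_any: FTest
    interaction: FTest
    posthoc: list[PosthocT]
    n: int
    group_means: dict


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _design(sex01: np.ndarray, grp01: np.ndarray, terms: str) -> np.ndarray:
    ones = np.ones_like(sex01, dtype=float)
    cols = {"1": ones, "s": sex01.astype(float), "g": grp01.astype(float),
            "sg": (sex01 * grp01).astype(float)}
    model_cols = {
        "group": ["1", "g"],
        "sex": ["1", "s"],
        "additive": ["1", "s", "g"],
        "full": ["1", "s", "g", "sg"],
    }[terms]
    return np.column_stack([cols[c] for c in model_cols])


def nested_anova(values, sex, group) -> AnovaResult:
    """Nested-model F-tests for a trait against sex and group.

    Individuals with a missing trait value or unknown sex are excluded.
    Requires exactly 2 groups and both sexes present overall.  Post-hoc
    t-tests are NA for a group containing a single sex.
    """
    df = pd.DataFrame({"y": values, "sex": sex, "group": group})
    df = df[df["y"].notna() & df["sex"].isin(["F", "M"])]
    groups = sorted(df["group"].unique().tolist(), key=str)
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    if df["sex"].nunique() < 2:
        raise ValueError("both sexes must be present")
    y = df["y"].to_numpy(dtype=float)
    sex01 = (df["sex"] == "M").to_numpy()
    grp01 = (df["group"] == groups[1]).to_numpy()
    n = len(y)

    rss = {t: _rss(y, _design(sex01, grp01, t)) for t in ("group", "sex", "additive", "full")}
    df_full = n - 4
    mse_full = rss["full"] / df_full

    def ftest(rss_red: float, rss_sub: float, df1: int) -> FTest:
        F = ((rss_red - rss_sub) / df1) / mse_full
        p = float(stats.f.sf(F, df1, df_full))
        return FTest(F=float(F), df1=df1, df2=df_full, p=p)

    group_effect = ftest(rss["sex"], rss["additive"], 1)
    sex_any = ftest(rss["group"], rss["full"], 2)
    interaction = ftest(rss["additive"], rss["full"], 1)

    posthoc = []
    means: dict = {}
    for g in groups:
        sub = df[df["group"] == g]
        means[g] = float(sub["y"].mean())
        yf = sub.loc[sub["sex"] == "F", "y"].to_numpy(dtype=float)
        ym = sub.loc[sub["sex"] == "M", "y"].to_numpy(dtype=float)
        if len(yf) < 2 or len(ym) < 2:
            posthoc.append(PosthocT(group=g, t=np.nan, df=0, p=np.nan, direction="NA"))
            continue
        t, p = stats.ttest_ind(yf, ym, equal_var=True)
        posthoc.append(
            PosthocT(
                group=g,
                t=float(t),
                df=len(yf) + len(ym) - 2,
                p=float(p),
                direction="F > M" if yf.mean() > ym.mean() else "M > F",
            )
        )
    return AnovaResult(
        group_effect=group_effect,
        sex_any=sex_any,
        interaction=interaction,
        posthoc=posthoc,
        n=n,
        group_means=means,
    )


def screen_outliers(values, group, k: float = 3.0) -> list:
    """Flag extreme low values within each group: below Q1 - k * IQR.

    A reproducible stand-in for a visual screen of outlying points; the
    default k = 3 flags only gross outliers.  Returns the index labels of
    flagged observations.
    """
    s = pd.Series(values).astype(float)
    g = pd.Series(group, index=s.index)
    flagged = []
    for label in g.dropna().unique():
        sub = s[(g == label) & s.notna()]
        if len(sub) < 5:
            continue
        q1, q3 = sub.quantile([0.25, 0.75])
        lo = q1 - k * (q3 - q1)
        flagged.extend(sub[sub < lo].index.tolist())
    return flagged
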