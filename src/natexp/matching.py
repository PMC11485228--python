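"""Cohort balancing: propensity-score and coarsened exact matching.

The propensity score is the modeled probability of belonging to the
primary-era cohort given baseline covariates (logistic regression on
indicator-expanded covariates; age enters as 2-year-bin indicators,
65–66 … 93–94 with 95+ pooled).  Matching is greedy 1:1 nearest
neighbor without replacement over a seed-randomized processing order,
with a caliper on the raw propensity-score scale (an SD-of-logit
dialect is available).  Balance is assessed with standardized mean
differences; < 0.1 is treated as well matched.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AGE_BIN_POOL = 95  # ages >= 95 share one bin
COEF_CAP = 15.0


@dataclass(frozen=True)
class PropensityModel:
    coefficients: dict[str, float]
    intercept: float
    scores: pd.Series  # patient_id -> P(primary era)
    feature_names: tuple[str, ...] = ()
    separation_flag: bool = False


@dataclass
class MatchedCohorts:
    """1:1 matched pairs with a pre/post SMD balance table.

    ``pairs`` columns: pair_id, comparator_id, primary_id, ps_a, ps_b,
    stratum (stratum is the CEM signature; empty for PS matching).
    """

    pairs: pd.DataFrame
    unmatched: list[str]
    balance_table: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def matched_ids(self) -> np.ndarray:
        return np.concatenate(
            [self.pairs["comparator_id"].to_numpy(), self.pairs["primary_id"].to_numpy()]
        ) if len(self.pairs) else np.empty(0, dtype=object)


@dataclass(frozen=True)
class CoarseningSpec:
    """Variables and bin rules for coarsened exact matching.

    ``age_years`` is coarsened into 2-year bins (65–66, 67–68, …) with
    95 and older pooled; every other listed variable is matched on its
    exact level.
    """

    variables: tuple[str, ...]
    age_bin_width: int = 2
    age_pool_at: int = AGE_BIN_POOL


def age_bin(age, width: int = 2, pool_at: int = AGE_BIN_POOL):
    """2-year age-bin index used both by the PS design and by CEM."""
    a = np.minimum(np.asarray(age, int), pool_at)
    return (a - 65) // width


def build_design(df: pd.DataFrame, covariate_list) -> pd.DataFrame:
    """Indicator-expanded design matrix (age → 2-year-bin indicators,
    categoricals → level indicators including any explicit 'missing'
    level, binaries as 0/1)."""
    forbidden = [c for c in covariate_list if c.endswith(("_time", "_event"))]
    if forbidden:
        raise ValueError(f"outcome columns may not enter matching: {forbidden}")
    parts = []
    for cov in covariate_list:
        col = df[cov]
        if cov == "age_years":
            bins = pd.Series(age_bin(col), index=df.index, name="age_bin").astype(str)
            dummies = pd.get_dummies(bins, prefix="age_bin", dtype=float)
            parts.append(dummies.iloc[:, 1:])  # drop one bin as reference
        elif col.dtype == object or str(col.dtype) == "category":
            dummies = pd.get_dummies(col.astype(str), prefix=cov, dtype=float)
            parts.append(dummies.iloc[:, 1:])
        else:
            parts.append(col.astype(float).to_frame(cov))
    X = pd.concat(parts, axis=1)
    # drop constant columns (no information, would be unidentifiable)
    keep = X.columns[X.nunique() > 1]
    return X[keep]


def fit_propensity(df: pd.DataFrame, covariate_list) -> PropensityModel:
    """Logistic regression of primary-era membership on the covariates.

    Maximizes the unpenalized binomial likelihood; perfect or
    near-perfect separation is flagged and coefficients are capped.
    """
    from sklearn.linear_model import LogisticRegression

    for era in ("comparator", "primary"):
        if (df["era"] == era).sum() < 2:
            raise ValueError(f"need at least 2 records in era {era!r}")
    X = build_design(df, covariate_list)
    y = (df["era"] == "primary").to_numpy(int)
    lr = LogisticRegression(penalty=None, solver="lbfgs", max_iter=5000, tol=1e-10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lr.fit(X.to_numpy(float), y)
    coef = lr.coef_[0].copy()
    intercept = float(lr.intercept_[0])
    runaway = np.abs(coef) > COEF_CAP
    separated = bool(runaway.any() or abs(intercept) > COEF_CAP)
    if separated:
        # warn only when a non-negligible cell separates; a runaway
        # coefficient on a handful of subjects is just a sparse cell
        counts = X.to_numpy(float)[:, runaway].sum(axis=0) if runaway.any() else []
        if abs(intercept) > COEF_CAP or np.any(np.asarray(counts) >= 10):
            warnings.warn(
                "possible separation in the propensity model; coefficients capped"
            )
        coef = np.clip(coef, -COEF_CAP, COEF_CAP)
        intercept = float(np.clip(intercept, -COEF_CAP, COEF_CAP))
    lin = X.to_numpy(float) @ coef + intercept
    scores = pd.Series(1.0 / (1.0 + np.exp(-lin)), index=df["patient_id"].to_numpy())
    return PropensityModel(
        coefficients=dict(zip(X.columns, coef.tolist())),
        intercept=intercept,
        scores=scores,
        feature_names=tuple(X.columns),
        separation_flag=separated,
    )


def standardized_mean_difference(values_a, values_b, kind: str = "continuous") -> float:
    """Absolute standardized mean difference between two groups.

    binary:     |p_a − p_b| / sqrt((p_a(1−p_a) + p_b(1−p_b)) / 2)
    continuous: |m_a − m_b| / sqrt((v_a + v_b) / 2)

    Returns 0 for identical degenerate groups, +inf when the pooled
    variance is zero but the means differ.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if kind == "binary":
        pa, pb = a.mean(), b.mean()
        pooled = (pa * (1 - pa) + pb * (1 - pb)) / 2.0
        num = abs(pa - pb)
    elif kind == "continuous":
        pooled = (a.var(ddof=1) + b.var(ddof=1)) / 2.0 if min(len(a), len(b)) > 1 else 0.0
        num = abs(a.mean() - b.mean())
    else:
        raise ValueError("kind must be 'binary' or 'continuous'")
    if pooled <= 0:
        return 0.0 if num == 0 else float("inf")
    return float(num / np.sqrt(pooled))


def _covariate_smd(df_a: pd.DataFrame, df_b: pd.DataFrame, cov: str) -> float:
    col_a, col_b = df_a[cov], df_b[cov]
    if col_a.dtype == object or str(col_a.dtype) == "category":
        levels = sorted(set(col_a.astype(str)) | set(col_b.astype(str)))
        return max(
            standardized_mean_difference(
                (col_a.astype(str) == lv).to_numpy(float),
                (col_b.astype(str) == lv).to_numpy(float),
                "binary",
            )
            for lv in levels
        )
    vals = set(pd.concat([col_a, col_b]).unique())
    kind = "binary" if vals <= {0, 1} else "continuous"
    return standardized_mean_difference(col_a.to_numpy(float), col_b.to_numpy(float), kind)


def balance_table(
    df: pd.DataFrame, covariate_list, matched: "MatchedCohorts | None" = None
) -> pd.DataFrame:
    """Per-covariate SMD before and (if pairs given) after matching."""
    comp = df[df["era"] == "comparator"]
    prim = df[df["era"] == "primary"]
    rows = []
    if matched is not None and matched.n_pairs:
        by_id = df.set_index("patient_id")
        comp_m = by_id.loc[matched.pairs["comparator_id"]]
        prim_m = by_id.loc[matched.pairs["primary_id"]]
    else:
        comp_m = prim_m = None
    for cov in covariate_list:
        before = _covariate_smd(comp, prim, cov)
        after = _covariate_smd(comp_m, prim_m, cov) if comp_m is not None else np.nan
        rows.append(
            {
                "covariate": cov,
                "smd_before": before,
                "smd_after": after,
                "flag_well_matched": bool(after < 0.1) if np.isfinite(after) else False,
            }
        )
    return pd.DataFrame(rows)


def match_nearest(
    era: pd.Series,
    scores: pd.Series,
    caliper: float = 0.1,
    seed: int = 0,
    caliper_scale: str = "raw",
) -> MatchedCohorts:
    """Greedy 1:1 nearest-neighbor caliper matching without replacement.

    Primary-era patients are processed in a seed-randomized order; each
    is matched to the nearest still-unmatched comparator within the
    caliper (ties broken by the comparators' randomized positions).
    ``caliper_scale='sd_logit'`` interprets the caliper as a multiple of
    the SD of the logit propensity score.
    """
    if caliper < 0:
        raise ValueError("caliper must be >= 0")
    ids = scores.index.to_numpy()
    ps = scores.to_numpy(float)
    era = np.asarray(era)
    if caliper_scale == "sd_logit":
        logit = np.log(ps / (1 - ps))
        cal = caliper * float(np.std(logit, ddof=1))
        metric = logit
    elif caliper_scale == "raw":
        cal = caliper
        metric = ps
    else:
        raise ValueError("caliper_scale must be 'raw' or 'sd_logit'")

    rng = np.random.default_rng(seed)
    comp_idx = np.flatnonzero(era == "comparator")
    prim_idx = np.flatnonzero(era == "primary")
    prim_order = prim_idx[rng.permutation(len(prim_idx))]
    comp_priority = rng.permutation(len(comp_idx))  # tie-break ranks

    # comparators sorted by score; "next/previous alive" with path
    # compression makes the greedy pass near-linear
    order = np.argsort(metric[comp_idx], kind="stable")
    sorted_comp = comp_idx[order]
    sorted_scores = metric[sorted_comp]
    sorted_prio = comp_priority[order]
    m = len(sorted_comp)
    nxt = list(range(m + 1))           # nxt[j]: smallest alive index >= j (m = none)
    prv = list(range(m))               # prv[j]: largest alive index <= j (-1 = none)

    def find_right(j):
        path = []
        while j < m and nxt[j] != j:
            path.append(j)
            j = nxt[j]
        for q in path:
            nxt[q] = j
        return j

    def find_left(j):
        path = []
        while j >= 0 and prv[j] != j:
            path.append(j)
            j = prv[j]
        for q in path:
            prv[q] = j
        return j

    pairs = []
    for pi in prim_order:
        s = metric[pi]
        pos = int(np.searchsorted(sorted_scores, s))
        lj = find_left(pos - 1) if pos > 0 else -1
        rj = find_right(pos) if pos < m else m
        cand = []
        if lj >= 0:
            cand.append((abs(s - sorted_scores[lj]), sorted_prio[lj], lj))
        if rj < m:
            cand.append((abs(s - sorted_scores[rj]), sorted_prio[rj], rj))
        if not cand:
            continue
        dist, _, j = min(cand)
        if dist <= cal + 1e-15:
            nxt[j] = j + 1
            prv[j] = j - 1
            ci = sorted_comp[j]
            pairs.append((ids[ci], ids[pi], ps[ci], ps[pi]))

    pair_df = pd.DataFrame(
        pairs, columns=["comparator_id", "primary_id", "ps_a", "ps_b"]
    )
    pair_df.insert(0, "pair_id", np.arange(len(pair_df)))
    pair_df["stratum"] = ""
    matched_set = set(pair_df["comparator_id"]) | set(pair_df["primary_id"])
    unmatched = [i for i in ids if i not in matched_set]
    return MatchedCohorts(pairs=pair_df, unmatched=unmatched)


def coarsened_exact_match(
    df: pd.DataFrame, spec: CoarseningSpec, seed: int = 0
) -> MatchedCohorts:
    """Exact 1:1 matching on the joint coarsened covariate signature.

    Within each stratum, min(#comparator, #primary) random pairs are
    drawn under the seed; the stratum set itself is seed-invariant.
    """
    missing = [v for v in spec.variables if v not in df.columns]
    if missing:
        raise ValueError(f"coarsening variables not in table: {missing}")
    sig_parts = []
    for v in spec.variables:
        if v == "age_years":
            sig_parts.append(
                pd.Series(age_bin(df[v], spec.age_bin_width, spec.age_pool_at), index=df.index)
                .astype(str)
            )
        else:
            sig_parts.append(df[v].astype(str))
    signature = sig_parts[0].str.cat(sig_parts[1:], sep="|") if len(sig_parts) > 1 else sig_parts[0]
    rng = np.random.default_rng(seed)
    pairs = []
    work = pd.DataFrame(
        {"patient_id": df["patient_id"].to_numpy(), "era": df["era"].to_numpy(),
         "sig": signature.to_numpy()}
    )
    for sig, grp in work.groupby("sig", sort=True):
        comp = grp.loc[grp["era"] == "comparator", "patient_id"].to_numpy()
        prim = grp.loc[grp["era"] == "primary", "patient_id"].to_numpy()
        k = min(len(comp), len(prim))
        if k == 0:
            continue
        comp = rng.permutation(comp)[:k]
        prim = rng.permutation(prim)[:k]
        for a, b in zip(comp, prim):
            pairs.append((a, b, sig))
    pair_df = pd.DataFrame(pairs, columns=["comparator_id", "primary_id", "stratum"])
    pair_df.insert(0, "pair_id", np.arange(len(pair_df)))
    pair_df["ps_a"] = np.nan
    pair_df["ps_b"] = np.nan
    pair_df = pair_df[["pair_id", "comparator_id", "primary_id", "ps_a", "ps_b", "stratum"]]
    matched_set = set(pair_df["comparator_id"]) | set(pair_df["primary_id"])
    unmatched = [i for i in df["patient_id"] if i not in matched_set]
    return MatchedCohorts(pairs=pair_df, unmatched=unmatched)
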