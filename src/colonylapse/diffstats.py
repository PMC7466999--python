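"""Replicate filtering, robust Z-scoring and treatment-response nomination.

Per-strain replicate values of lagVstall and colony fitness from untreated
(UT) and treated (e.g. UVR) plates are compared by a two-sided pooled-
variance t-test; false discovery is controlled with Storey q-values (pFDR
with a smoothed pi0 estimate).  Robust Z-scores — (x - median)/MAD, MAD
unscaled so the scored population has median 0 and median absolute
deviation exactly 1 — are computed per plate x condition and summarized
per strain by the replicate median; the treated-minus-untreated difference
of these medians (delta_z) gives each hit its direction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KeyCollisionError",
    "DegenerateScaleError",
    "NominationSets",
    "merge_duplicates",
    "filter_replicates",
    "robust_z",
    "two_sample_t",
    "storey_qvalues",
    "differential_table",
    "nominate",
    "tail_select",
    "replicate_correlation",
    "DEFAULT_MIN_REPLICATES",
    "DEFAULT_Q_CUTOFF",
    "METRICS",
]

DEFAULT_MIN_REPLICATES = 6
DEFAULT_Q_CUTOFF = 0.05
METRICS = ("lag_v_stall", "colony_fitness")

# direction of a hit from the sign of delta_z = treated - untreated median Z.
# Colony fitness: drop under treatment = sensitive.  lagVstall: a deepening
# stall (delta_z > 0) marks sensitivity; a weakening stall (delta_z < 0)
# marks resistance.
_DIRECTION = {
    "colony_fitness": lambda dz: "sensitive" if dz < 0 else "resistant",
    "lag_v_stall": lambda dz: "sensitive" if dz > 0 else "resistant",
}


class KeyCollisionError(ValueError):
    """Duplicate (strain, condition, replicate) keys that cannot be merged."""


class DegenerateScaleError(ValueError):
    """MAD (or variance) of zero where a scale is required."""


def merge_duplicates(table: pd.DataFrame) -> pd.DataFrame:
    """Pool colonies of one strain arrayed at multiple positions.

    Rows carrying position columns (``plate_id``/``row``/``col``) are
    re-indexed deterministically in position order; each strain's colonies
    become consecutive replicates within each condition.  Without position
    columns, duplicated (strain_id, condition, replicate) keys are ambiguous
    and raise :class:`KeyCollisionError`.
    """
    keys = ["strain_id", "condition", "replicate"]
    pos_cols = [c for c in ("plate_id", "row", "col") if c in table.columns]
    if not pos_cols:
        if table.duplicated(subset=keys).any():
            dupes = table[table.duplicated(subset=keys, keep=False)]
            raise KeyCollisionError(
                "duplicate (strain, condition, replicate) keys without "
                f"position columns to disambiguate:\n{dupes[keys].to_string()}"
            )
        return table.copy()
    out = table.sort_values(pos_cols + ["replicate"], kind="stable").copy()
    out["replicate"] = out.groupby(["strain_id", "condition"], sort=False).cumcount()
    return out.reset_index(drop=True)


def filter_replicates(table: pd.DataFrame, min_reps: int = DEFAULT_MIN_REPLICATES) -> pd.DataFrame:
    """Drop strains with fewer than ``min_reps`` replicates in EITHER condition."""
    if min_reps < 1:
        raise ValueError("min_reps must be >= 1")
    counts = table.groupby(["strain_id", "condition"]).size().unstack(fill_value=0)
    ok = counts.index[(counts >= min_reps).all(axis=1) & (counts.shape[1] >= 2)]
    if counts.shape[1] < 2:
        ok = counts.index[:0]
    out = table[table["strain_id"].isin(ok)].reset_index(drop=True)
    if out.empty:
        warnings.warn("replicate filter removed every strain", stacklevel=2)
    return out


def robust_z(values: np.ndarray) -> np.ndarray:
    """(x - median)/MAD with MAD = median(|x - median|), unscaled.

    The scored population then has median exactly 0 and median absolute
    deviation exactly 1.  No normal-consistency (1.4826) factor is applied.
    """
    x = np.asarray(values, dtype=float)
    if np.unique(x).size < 2:
        raise DegenerateScaleError("robust_z needs at least 2 distinct values")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        raise DegenerateScaleError("median absolute deviation is zero")
    return (x - med) / mad


def two_sample_t(ut: np.ndarray, treated: np.ndarray) -> tuple[float, float]:
    """Two-sided, unpaired, pooled-variance t-test; returns (t, p).

    Degenerate zero-variance groups: equal means give (0, 1); unequal means
    give (+/-inf, 0), the boundary case.
    """
    a = np.asarray(ut, dtype=float)
    b = np.asarray(treated, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 replicates")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return 0.0, 1.0
        return math.copysign(math.inf, a[0] - b[0]), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def storey_qvalues(
    p: np.ndarray,
    pi0: float | None = None,
    lambdas: np.ndarray | None = None,
) -> np.ndarray:
    """Storey pFDR q-values.

    pi0 is estimated from pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on
    lambda = 0, 0.01, ..., 0.90, smoothed with a cubic polynomial and
    evaluated at the largest lambda, then clipped to (0, 1].  q-values are
    the step-up minima of pi0 * m * p / rank, monotone in p and <= 1.
    Passing ``pi0=1`` reduces exactly to Benjamini-Hochberg.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        if lambdas is None:
            lambdas = np.arange(0.0, 0.9001, 0.01)
        lambdas = np.asarray(lambdas, dtype=float)
        pi0_l = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
        if lambdas.size >= 4:
            coeffs = np.polyfit(lambdas, pi0_l, 3)
            pi0 = float(np.polyval(coeffs, lambdas.max()))
        else:
            pi0 = float(pi0_l[-1])
        pi0 = min(pi0, 1.0)
        pi0 = max(pi0, 1.0 / m)  # guard: at least one test's worth of nulls
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def _strain_median_z(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Robust Z per plate x condition, then per-strain median of replicate Zs."""
    df = table.reset_index(drop=True).copy()
    z = np.full(len(df), np.nan)
    groups = (df.groupby(["plate_id", "condition"], sort=False)
              if "plate_id" in df.columns else df.groupby("condition", sort=False))
    for _, group in groups:
        vals = group[metric].to_numpy(dtype=float)
        try:
            z[group.index.to_numpy()] = robust_z(vals)
        except DegenerateScaleError:
            z[group.index.to_numpy()] = np.nan
    df["_z"] = z
    return df.groupby(["strain_id", "condition"])["_z"].median().unstack()


def differential_table(
    table: pd.DataFrame,
    *,
    untreated: str = "untreated",
    treated: str = "treated",
    metrics: tuple[str, ...] = METRICS,
) -> pd.DataFrame:
    """Per-strain, per-metric t statistics, p, Storey q, delta_z, direction.

    ``table`` is a replicate table (one row per colony) with ``strain_id``,
    ``condition``, ``replicate`` and the metric columns; a ``plate_id``
    column, if present, scopes the robust Z-scoring population.  t-tests run
    on the raw replicate metric values; Z-scores only set direction and
    delta_z.  q-values are computed separately per metric (each metric is
    its own hypothesis family).
    """
    conditions = set(table["condition"].unique())
    if not {untreated, treated} <= conditions:
        raise ValueError(f"need conditions {untreated!r} and {treated!r}; have {sorted(conditions)}")
    records = []
    for metric in metrics:
        med_z = _strain_median_z(table, metric)
        sub = table[["strain_id", "condition", metric]]
        grouped = {
            (s, c): g[metric].to_numpy(dtype=float)
            for (s, c), g in sub.groupby(["strain_id", "condition"], sort=True)
        }
        strains = sorted({s for s, _ in grouped})
        rows = []
        for s in strains:
            ut = grouped.get((s, untreated))
            tr = grouped.get((s, treated))
            if ut is None or tr is None or ut.size < 2 or tr.size < 2:
                continue
            t, p = two_sample_t(ut, tr)
            dz = float(med_z.loc[s, treated] - med_z.loc[s, untreated]) if s in med_z.index else np.nan
            rows.append((s, metric, ut.size, tr.size, t, p, dz))
        if not rows:
            continue
        df = pd.DataFrame(rows, columns=["strain_id", "metric", "n_ut", "n_treated",
                                         "t", "p", "delta_z"])
        df["q"] = storey_qvalues(df["p"].to_numpy())
        df["direction"] = [_DIRECTION[metric](dz) if np.isfinite(dz) else "unknown"
                           for dz in df["delta_z"]]
        records.append(df)
    out = pd.concat(records, ignore_index=True)
    return out[["strain_id", "metric", "n_ut", "n_treated", "t", "p", "q",
                "delta_z", "direction"]]


@dataclass(frozen=True)
class NominationSets:
    """Strains nominated at a q-value cutoff, per metric and combined."""

    by_cf: frozenset[str]
    by_lvs: frozenset[str]

    @property
    def union(self) -> frozenset[str]:
        return self.by_cf | self.by_lvs

    @property
    def intersection(self) -> frozenset[str]:
        return self.by_cf & self.by_lvs

    def counts(self) -> dict[str, int]:
        """Total, per-metric, exclusive and overlap accounting."""
        return {
            "total": len(self.union),
            "by_lvs": len(self.by_lvs),
            "by_cf": len(self.by_cf),
            "both": len(self.intersection),
            "lvs_only": len(self.by_lvs - self.by_cf),
            "cf_only": len(self.by_cf - self.by_lvs),
        }


def nominate(results: pd.DataFrame, q_cutoff: float = DEFAULT_Q_CUTOFF) -> NominationSets:
    """Strain sets with q < cutoff, per metric (q computed per metric)."""
    hit = results[results["q"] < q_cutoff]
    by_cf = frozenset(hit.loc[hit["metric"] == "colony_fitness", "strain_id"])
    by_lvs = frozenset(hit.loc[hit["metric"] == "lag_v_stall", "strain_id"])
    return NominationSets(by_cf=by_cf, by_lvs=by_lvs)


def tail_select(
    values: pd.Series,
    lower_pct: float = 5.0,
    upper_pct: float = 95.0,
) -> tuple[list[str], list[str]]:
    """Strains in the lower and upper tails of a per-strain metric.

    Tail size is ceil(pct/100 * N) (e.g. N=4294 at 5%/95% gives 215 per
    tail); ties break deterministically by strain identifier.
    Returns (lower_tail, upper_tail) strain lists.
    """
    if not 0 < lower_pct < upper_pct < 100:
        raise ValueError("need 0 < lower_pct < upper_pct < 100")
    s = values.dropna()
    n = len(s)
    k_lo = math.ceil(lower_pct / 100.0 * n)
    k_hi = math.ceil((100.0 - upper_pct) / 100.0 * n)
    frame = pd.DataFrame({"strain_id": s.index.astype(str), "value": s.to_numpy()})
    lo = frame.sort_values(["value", "strain_id"], kind="stable").head(k_lo)
    hi = frame.sort_values(["value", "strain_id"], ascending=[False, True],
                           kind="stable").head(k_hi)
    return lo["strain_id"].tolist(), hi["strain_id"].tolist()


def replicate_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of per-strain median Z-scores, matched by strain."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need >= 3 matched strains")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateScaleError("zero variance: correlation undefined")
    return float(stats.pearsonr(a, b)[0])
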