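"""Resampling inference: two-sample permutation test and BH-FDR.

The permutation test probes H0: mu1 - mu2 = 0 with the difference of
means as the statistic.  Labels are re-assigned uniformly at random
(default 1600 draws); when the number of distinct splits is small the
test switches to exhaustive enumeration and the p-value is exact.
Multiplicity across EEG electrodes is controlled per band with the
Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

__all__ = ["PermutationResult", "permutation_test", "bh_fdr", "compare_periods",
           "derive_seed"]

#: tolerance when comparing permuted statistics against the observed one,
#: so float round-off cannot break exact ties (integer-valued data)
_TIE_EPS = 1e-12


@dataclass(frozen=True)
class PermutationResult:
    observed: float          # mean(x) - mean(y)
    p_value: float           # two-sided
    n_permutations: int      # draws used (or distinct splits if exhaustive)
    seed: int | None
    exhaustive: bool
    note: str = ""


def derive_seed(global_seed: int, *tokens: object) -> int:
    """Stable per-comparison seed from a global seed and string tokens.

    Hash-based so results do not depend on the order comparisons run in.
    Kept below 2**31.
    """
    h = zlib.crc32(repr(tuple(str(t) for t in tokens)).encode())
    return int(np.random.SeedSequence([int(global_seed), h]).generate_state(1)[0] % (2**31))


def permutation_test(
    x,
    y,
    n_perm: int = 1600,
    seed: int | None = None,
) -> PermutationResult:
    """Two-sided permutation test of equal means.

    Exhaustive when C(n+m, n) <= n_perm (exact p = proportion of splits
    with |T*| >= |T_obs|); otherwise Monte-Carlo with the +1-corrected
    estimate p = (1 + #extreme) / (1 + n_perm), which can never be 0.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples contain NaN/inf")
    t_obs = float(x.mean() - y.mean())
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    if np.ptp(pooled) == 0:
        return PermutationResult(t_obs, 1.0, 0, seed, True,
                                 note="degenerate: all values identical")
    n_splits = comb(n + m, n)
    thresh = abs(t_obs) - _TIE_EPS
    if n_splits <= n_perm:
        total = pooled.sum()
        count = 0
        for idx in combinations(range(n + m), n):
            sx = pooled[list(idx)].sum()
            t = sx / n - (total - sx) / m
            if abs(t) >= thresh:
                count += 1
        return PermutationResult(t_obs, count / n_splits, n_splits, seed, True)
    rng = np.random.default_rng(seed)
    count = 0
    # vectorised in blocks: permute the pooled sample, first n go to "x"
    block = 200
    done = 0
    while done < n_perm:
        k = min(block, n_perm - done)
        perms = rng.permuted(np.broadcast_to(pooled, (k, n + m)), axis=1)
        t = perms[:, :n].mean(axis=1) - perms[:, n:].mean(axis=1)
        count += int(np.sum(np.abs(t) >= thresh))
        done += k
    return PermutationResult(t_obs, (1 + count) / (1 + n_perm), n_perm, seed, False)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = p_(i) * m / i on the sorted p's, then a running minimum from
    the largest rank down enforces monotonicity; capped at 1.
    """
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p.copy()
    if np.any(p <= 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    out = np.empty_like(p)
    out[order] = adjusted_sorted
    return out


def compare_periods(
    values: pd.DataFrame,
    pairs: tuple[tuple[str, str], ...] = (("MTI", "PRE"), ("POST", "PRE"), ("MTI", "POST")),
    n_perm: int = 1600,
    seed: int = 0,
    alpha: float = 0.05,
    fdr_groups: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Pairwise period comparisons for a per-recording feature table.

    ``values`` is tidy with columns ``recording``, ``period``, ``feature``,
    ``value`` — one number per recording per period per feature (period
    means are the exchangeable units).  Each pair (A, B) is tested with
    the unpaired permutation test on the per-recording values of A vs B;
    the reported change is mean(A) - mean(B) and its SD is the SD of the
    paired per-recording differences where both periods are present.

    ``fdr_groups`` maps a group label to the features adjusted together
    (EEG usage: one group per band holding its 8 electrode features);
    features outside every group keep their raw p as adjusted p.
    """
    required = {"recording", "period", "feature", "value"}
    if not required.issubset(values.columns):
        raise ValueError(f"values table needs columns {sorted(required)}")
    rows = []
    for feature, sub in values.groupby("feature", sort=True):
        wide = sub.pivot_table(index="recording", columns="period", values="value")
        for a, b in pairs:
            if a not in wide.columns or b not in wide.columns:
                continue
            va = wide[a].dropna().to_numpy()
            vb = wide[b].dropna().to_numpy()
            if len(va) < 2 or len(vb) < 2:
                raise ValueError(f"feature {feature}: fewer than 2 recordings per period")
            res = permutation_test(
                va, vb, n_perm=n_perm,
                seed=derive_seed(seed, feature, f"{a}-{b}"),
            )
            diff = (wide[a] - wide[b]).dropna().to_numpy()
            rows.append({
                "feature": feature,
                "pair": f"{a}-{b}",
                "mean_change": float(np.mean(va) - np.mean(vb)),
                "sd_change": float(np.std(diff, ddof=0)) if len(diff) else np.nan,
                "p": res.p_value,
                "n_permutations": res.n_permutations,
                "exhaustive": res.exhaustive,
            })
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["p_adjusted"] = out["p"]
    if fdr_groups:
        for _, members in fdr_groups.items():
            for pair in out["pair"].unique():
                mask = out["feature"].isin(members) & (out["pair"] == pair)
                if mask.sum() > 1:
                    out.loc[mask, "p_adjusted"] = bh_fdr(out.loc[mask, "p"].to_numpy())
    out["significant"] = out["p_adjusted"] < alpha
    return out
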