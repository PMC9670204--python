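"""Group-comparison tests and small assay normalisations.

Implements the comparison procedures used for grouped scalar readouts:

* Wilcoxon rank-sum (two samples; exact by enumeration for small n,
  normal approximation with midrank tie correction otherwise),
* Dunnett's many-to-one parametric test (adjusted p from the equicorrelated
  multivariate-t distribution of the max |t|, evaluated by seeded Monte
  Carlo, which handles unbalanced group sizes exactly as defined),
* Tukey-Kramer all-pairs test (studentized-range distribution),
* Steel's many-to-one rank test (pairwise rank sums vs control; family-wise
  adjustment from the permutation null of the standardised max statistic),

plus the LDH cytotoxicity percentage and the LC3-II autophagic-flux index.

All tests are two-sided.  Monte-Carlo and permutation procedures are
seed-deterministic, and treatment groups are ordered canonically by their
data content before seeding so that relabelling groups changes no p-value.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps


@dataclass
class Comparison:
    pair: tuple[str, str]
    statistic: float
    p_adjusted: float


@dataclass
class ComparisonResult:
    test_name: str
    comparisons: list[Comparison]
    alpha: float = 0.05
    method: dict = field(default_factory=dict)

    def p_value(self, pair: tuple[str, str] | None = None) -> float:
        if pair is None:
            if len(self.comparisons) != 1:
                raise ValueError("pair required when there are several comparisons")
            return self.comparisons[0].p_adjusted
        for c in self.comparisons:
            if c.pair == pair or c.pair == pair[::-1]:
                return c.p_adjusted
        raise KeyError(pair)

    @property
    def min_p(self) -> float:
        return min(c.p_adjusted for c in self.comparisons)


def _as_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    out = {}
    for label, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size == 0:
            raise ValueError(f"group {label!r} is empty")
        out[label] = arr
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    return out


def _pooled_sd(groups: dict[str, np.ndarray]) -> tuple[float, int]:
    df = sum(len(g) - 1 for g in groups.values())
    if df <= 0:
        raise ValueError("each group needs n >= 2 for parametric tests")
    ss = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
    s2 = ss / df
    if s2 <= 0:
        raise ValueError("zero pooled variance")
    return float(np.sqrt(s2)), df


def _canonical_order(labels: Sequence[str], groups: dict[str, np.ndarray]) -> list[str]:
    """Order treatments by data content (size, then sorted values): invariant
    under relabelling, so the Monte-Carlo stream does not depend on names."""
    return sorted(labels, key=lambda l: (len(groups[l]), tuple(np.sort(groups[l]))))


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def _rank_sum_moments(pooled_ranks: np.ndarray, n_x: int) -> tuple[float, float]:
    """Exact mean/variance of the rank sum of n_x values drawn WOR from the
    pooled (midrank) multiset; handles ties exactly."""
    n = len(pooled_ranks)
    mean = n_x * pooled_ranks.mean()
    pop_var = pooled_ranks.var()
    var = n_x * (n - n_x) / (n - 1) * pop_var
    return float(mean), float(var)


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float],
                      alternative: str = "two-sided",
                      exact: bool | None = None) -> ComparisonResult:
    """Rank-sum test with midrank ties.

    Exact p by enumeration of all C(n, n_x) rank assignments when
    n_x + n_y <= 10 (unless overridden), normal approximation with tie
    correction and continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n_x, n_y = len(x), len(y)
    n = n_x + n_y
    ranks = sps.rankdata(np.concatenate([x, y]))
    w = float(ranks[:n_x].sum())
    mean, var = _rank_sum_moments(ranks, n_x)
    if exact is None:
        exact = n <= 10
    eps = 1e-9
    if exact:
        sums = np.fromiter(
            (sum(ranks[list(c)]) for c in itertools.combinations(range(n), n_x)),
            dtype=float,
        )
        total = len(sums)
        if alternative == "greater":
            p = float((sums >= w - eps).sum()) / total
        elif alternative == "less":
            p = float((sums <= w + eps).sum()) / total
        else:
            p = float((np.abs(sums - mean) >= abs(w - mean) - eps).sum()) / total
        method = {"mode": "exact", "n_assignments": total}
    else:
        sd = np.sqrt(var)
        if sd == 0:
            p = 1.0
        elif alternative == "greater":
            p = float(sps.norm.sf((w - mean - 0.5) / sd))
        elif alternative == "less":
            p = float(sps.norm.cdf((w - mean + 0.5) / sd))
        else:
            z = (abs(w - mean) - 0.5) / sd
            p = float(min(1.0, 2.0 * sps.norm.sf(max(z, 0.0))))
        method = {"mode": "normal-approx", "tie_corrected": True}
    return ComparisonResult(
        test_name="wilcoxon_rank_sum",
        comparisons=[Comparison(pair=("x", "y"), statistic=w, p_adjusted=min(p, 1.0))],
        method={**method, "alternative": alternative, "rank_sum_mean": mean},
    )


# ---------------------------------------------------------------------------
# Dunnett (many-to-one, parametric)


def _dunnett_null_max_abs_t(ns: Sequence[int], n_control: int, df: int,
                            reps: int, rng: np.random.Generator) -> np.ndarray:
    """Monte-Carlo sample of max_i |t_i| under the global null.

    t_i = (Z_i/sqrt(n_i) - Z_0/sqrt(n_c)) / (S * sqrt(1/n_i + 1/n_c)) with a
    shared control variate Z_0 and S^2 ~ chi2_df/df, which realises the
    equicorrelated multivariate t exactly.
    """
    ns = np.asarray(ns, dtype=float)
    z0 = rng.standard_normal(reps)
    zi = rng.standard_normal((reps, len(ns)))
    s = np.sqrt(rng.chisquare(df, size=reps) / df)
    num = zi / np.sqrt(ns) - z0[:, None] / np.sqrt(n_control)
    t = num / (s[:, None] * np.sqrt(1.0 / ns + 1.0 / n_control))
    return np.abs(t).max(axis=1)


def dunnett(groups: Mapping[str, Sequence[float]], control: str,
            reps: int = 100_000, seed: int = 0) -> ComparisonResult:
    """Dunnett's two-sided many-to-one comparisons against ``control``.

    Adjusted p-values come from the joint null distribution of max |t|
    (seeded Monte Carlo, ``reps`` draws), so unbalanced designs are handled
    without table lookup.
    """
    g = _as_groups(groups)
    if control not in g:
        raise ValueError(f"control group {control!r} missing")
    sp, df = _pooled_sd(g)
    treatments = [l for l in g if l != control]
    canon = _canonical_order(treatments, g)
    ns = [len(g[l]) for l in canon]
    n_c = len(g[control])
    m_c = g[control].mean()

    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 202)))
    null_max = _dunnett_null_max_abs_t(ns, n_c, df, reps, rng)

    comparisons = []
    for label in treatments:
        d = (g[label].mean() - m_c) / (sp * np.sqrt(1.0 / len(g[label]) + 1.0 / n_c))
        p = (1.0 + float((null_max >= abs(d)).sum())) / (reps + 1.0)
        comparisons.append(Comparison(pair=(label, control), statistic=float(d),
                                      p_adjusted=min(p, 1.0)))
    return ComparisonResult(
        test_name="dunnett", comparisons=comparisons,
        method={"df": df, "pooled_sd": sp, "monte_carlo_reps": reps, "seed": seed,
                "sides": 2},
    )


# ---------------------------------------------------------------------------
# Tukey-Kramer (all pairs)


def _tukey_q(groups: dict[str, np.ndarray]) -> tuple[list[tuple[tuple[str, str], float]], int]:
    sp, df = _pooled_sd(groups)
    qs = []
    labels = list(groups)
    for a, b in itertools.combinations(labels, 2):
        ga, gb = groups[a], groups[b]
        se = sp * np.sqrt(0.5 * (1.0 / len(ga) + 1.0 / len(gb)))
        qs.append(((a, b), float(abs(ga.mean() - gb.mean()) / se)))
    return qs, df


def tukey_kramer(groups: Mapping[str, Sequence[float]]) -> ComparisonResult:
    """All-pairs comparisons with studentized-range adjusted p-values.

    q_ij = |m_i - m_j| / sqrt(s_p^2/2 * (1/n_i + 1/n_j)); p from the
    studentized-range distribution with k groups and pooled df.
    """
    g = _as_groups(groups)
    qs, df = _tukey_q(g)
    k = len(g)
    comparisons = [
        Comparison(pair=pair, statistic=q,
                   p_adjusted=float(np.clip(sps.studentized_range.sf(q, k, df), 0.0, 1.0)))
        for pair, q in qs
    ]
    return ComparisonResult(test_name="tukey_kramer", comparisons=comparisons,
                            method={"df": df, "k": k})


def tukey_critical_q(k: int, df: int, alpha: float = 0.05) -> float:
    """Studentized-range critical value; min adjusted p <= alpha iff
    max q >= this value (used for fast family-wise calibration)."""
    return float(sps.studentized_range.ppf(1.0 - alpha, k, df))


# ---------------------------------------------------------------------------
# Steel (many-to-one, nonparametric)


def _pair_z(values: np.ndarray, n_control: int, n_treat: int) -> float:
    """Standardised rank sum of the treatment block within one pair.

    ``values``: concatenated (control, treatment) values.  Midranks; the
    exact finite-population moments handle ties.
    """
    ranks = sps.rankdata(values)
    w = ranks[n_control:].sum()
    mean, var = _rank_sum_moments(ranks, n_treat)
    if var <= 0:
        return 0.0
    return float((w - mean) / np.sqrt(var))


def steel(groups: Mapping[str, Sequence[float]], control: str,
          reps: int = 10_000, seed: int = 0) -> ComparisonResult:
    """Steel's two-sided many-to-one rank test against ``control``.

    For each treatment the rank-sum statistic vs the control is computed on
    that pair only; the family-wise adjusted p for each comparison is the
    permutation tail probability of the standardised max |z| under ``reps``
    seeded permutations of the pooled observations.
    """
    g = _as_groups(groups)
    if control not in g:
        raise ValueError(f"control group {control!r} missing")
    treatments = [l for l in g if l != control]
    canon = _canonical_order(treatments, g)
    n_c = len(g[control])
    pooled = np.concatenate([g[control]] + [g[l] for l in canon])
    sizes = [n_c] + [len(g[l]) for l in canon]
    offsets = np.cumsum([0] + sizes)

    z_obs = {l: _pair_z(np.concatenate([g[control], g[l]]), n_c, len(g[l]))
             for l in treatments}

    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 303)))
    # permute pooled labels: each row of idx is one permutation
    idx = np.argsort(rng.random((reps, len(pooled))), axis=1)
    perm_vals = pooled[idx]
    max_abs_z = np.zeros(reps)
    for j, label in enumerate(canon, start=1):
        n_t = sizes[j]
        block = np.concatenate([perm_vals[:, :n_c],
                                perm_vals[:, offsets[j]:offsets[j + 1]]], axis=1)
        ranks = sps.rankdata(block, axis=1)
        w = ranks[:, n_c:].sum(axis=1)
        mean = n_t * ranks.mean(axis=1)
        var = n_t * (n_c) / (n_c + n_t - 1) * ranks.var(axis=1)
        z = np.where(var > 0, (w - mean) / np.sqrt(np.where(var > 0, var, 1.0)), 0.0)
        np.maximum(max_abs_z, np.abs(z), out=max_abs_z)

    comparisons = []
    for label in treatments:
        p = (1.0 + float((max_abs_z >= abs(z_obs[label]) - 1e-12).sum())) / (reps + 1.0)
        comparisons.append(Comparison(pair=(label, control), statistic=z_obs[label],
                                      p_adjusted=min(p, 1.0)))
    return ComparisonResult(
        test_name="steel", comparisons=comparisons,
        method={"permutations": reps, "seed": seed, "sides": 2},
    )


# ---------------------------------------------------------------------------
# Assay normalisations


def ldh_cytotoxicity(sample_abs: float, background_abs: float, total_abs: float) -> float:
    """LDH cytotoxicity percentage.

    100 * (sample - background) / (total - background): the released-LDH
    absorbance corrected for the background control and normalised to total
    lysis.  Negative values are clipped to 0 with a warning.
    """
    if total_abs <= background_abs:
        raise ValueError("total absorbance must exceed background")
    pct = 100.0 * (sample_abs - background_abs) / (total_abs - background_abs)
    if pct < 0:
        warnings.warn("negative LDH cytotoxicity clipped to 0", stacklevel=2)
        return 0.0
    return float(pct)


def flux_index(lc3ii_with_bma: float, loading: float,
               lc3ii_without_bma: float | None = None, mode: str = "level") -> dict:
    """Autophagic-flux index from LC3-II densitometry.

    ``level`` mode (default): LC3-II(+bafilomycin A1) / loading control.
    ``difference`` mode: (LC3-II(+BMA) - LC3-II(-BMA)) / loading.  The mode
    is echoed in the output because the two readouts are not interchangeable.
    """
    if loading <= 0:
        raise ValueError("loading control must be > 0")
    if mode == "level":
        value = lc3ii_with_bma / loading
    elif mode == "difference":
        if lc3ii_without_bma is None:
            raise ValueError("difference mode needs lc3ii_without_bma")
        value = (lc3ii_with_bma - lc3ii_without_bma) / loading
    else:
        raise ValueError(f"unknown flux mode {mode!r}")
    return {"flux": float(value), "mode": mode}
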