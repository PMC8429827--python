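"""Group comparison machinery.

Network measures are compared between outcome groups with label-
permutation tests: under the null that outcome is unrelated to the
covariance structure, group labels are exchangeable, so the full
pipeline (residualization on age and sex, partial correlation, weight
policy, measure) is re-run on every relabeling and the observed
poor-minus-good difference is referred to that null distribution.  The
p-value uses the add-one convention, p = (1 + #{|d*| >= |d_obs|}) /
(n_valid + 1), so the smallest attainable p with 1,000 permutations is
1/1001.

Regional volumes are compared per region with a Student's t-test when
both groups pass Shapiro-Wilk normality at 0.05, otherwise Mann-Whitney
U (exact for small untied samples, normal approximation with tie
correction otherwise), with Bonferroni correction over the per-structure
family (18 amygdala, 42 hippocampal, 50 thalamic tests across both
hemispheres; 12 for network measures).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import Cohort, NormalizedVolumeMatrix, lateralize, normalize_volumes
from .errors import (
    ComputationError,
    DegenerateTableError,
    InsufficientSampleError,
    ValidationError,
)
from .measures import (
    MEASURE_NAMES,
    NullModelSpec,
    clustering_and_transitivity,
    local_efficiency,
    modularity,
    path_measures,
    small_worldness,
    strength_and_assortativity,
)
from .network import apply_weight_policy, pcorr_array
from .seeds import derive_stage_seeds

#: Bonferroni family sizes: volume tests per structure (both hemispheres)
#: and the network-measure family.
BONFERRONI_FAMILIES = {
    "amygdala": 18,
    "hippocampus": 42,
    "thalamus": 50,
    "network": 12,
}

_PATH_MEASURES = {
    "radius", "diameter", "eccentricity",
    "characteristic_path_length", "global_efficiency",
}


def bonferroni_alpha(alpha: float, family_size: int) -> float:
    """Bonferroni-corrected per-test threshold alpha / family size."""
    if family_size < 1:
        raise ValidationError("family size must be >= 1")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    return alpha / family_size


def chi_squared_2x2(a, b, c, d) -> tuple[float, float]:
    """Pearson chi-squared on a 2x2 table, 1 df, no continuity correction.

    Table layout: rows are groups, columns are category counts
    ``[[a, b], [c, d]]``.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if (cells < 0).any():
        raise ValidationError("cell counts must be non-negative")
    n = cells.sum()
    if n <= 0:
        raise ValidationError("table total must be positive")
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise DegenerateTableError("zero marginal in 2x2 table")
    stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(stat), float(stats.chi2.sf(stat, df=1))


# --------------------------------------------------------- volume comparison


@dataclass(frozen=True)
class VolumeComparisonRow:
    region: str
    mean_poor: float
    sd_poor: float
    mean_good: float
    sd_good: float
    difference: float  # poor - good
    test: str  # "t" | "mann-whitney"
    statistic: float
    p_value: float
    family_size: int
    significant: bool


def _two_sample_test(x: np.ndarray, y: np.ndarray) -> tuple[str, float, float]:
    normal = (
        stats.shapiro(x).pvalue > 0.05 and stats.shapiro(y).pvalue > 0.05
    )
    if normal:
        res = stats.ttest_ind(x, y, equal_var=True)
        return "t", float(res.statistic), float(res.pvalue)
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return "mann-whitney", float(res.statistic), float(res.pvalue)


def compare_volume_distributions(
    cohort: Cohort | NormalizedVolumeMatrix,
    region: str,
    alpha: float = 0.05,
    family_size: int = 1,
) -> VolumeComparisonRow:
    """Compare one region's normalized volume between the groups.

    ``region`` is a lateralized column key
    (``structure_{ipsi|contra}_region``); a Cohort input is normalized
    and lateralized first.  The normality gate is per-group
    Shapiro-Wilk at 0.05.
    """
    nvm = _as_lateralized(cohort)
    x = nvm.values.loc[(nvm.group == "poor").to_numpy(), region].to_numpy()
    y = nvm.values.loc[(nvm.group == "good").to_numpy(), region].to_numpy()
    if len(x) < 3 or len(y) < 3:
        raise InsufficientSampleError("need >= 3 subjects per group")
    test, statistic, p = _two_sample_test(x, y)
    threshold = bonferroni_alpha(alpha, family_size)
    return VolumeComparisonRow(
        region=region,
        mean_poor=float(x.mean()),
        sd_poor=float(x.std(ddof=1)),
        mean_good=float(y.mean()),
        sd_good=float(y.std(ddof=1)),
        difference=float(x.mean() - y.mean()),
        test=test,
        statistic=statistic,
        p_value=p,
        family_size=family_size,
        significant=bool(p < threshold),
    )


def volume_comparison_table(
    cohort: Cohort | NormalizedVolumeMatrix, alpha: float = 0.05
) -> list[VolumeComparisonRow]:
    """All per-region comparisons, Bonferroni family per structure."""
    nvm = _as_lateralized(cohort)
    rows = []
    for col in nvm.values.columns:
        structure = col.split("_", 1)[0]
        rows.append(
            compare_volume_distributions(
                nvm, col, alpha, BONFERRONI_FAMILIES[structure]
            )
        )
    return rows


def _as_lateralized(cohort) -> NormalizedVolumeMatrix:
    if isinstance(cohort, NormalizedVolumeMatrix):
        if not cohort.lateralized:
            return lateralize(cohort)
        return cohort
    return lateralize(normalize_volumes(cohort))


# ------------------------------------------------------- permutation testing


@dataclass(frozen=True)
class PermutationOutcome:
    measure: str
    observed: float  # poor - good
    n_perm: int
    n_valid: int  # permutations yielding a defined measure
    null_mean: float
    null_sd: float
    null_q025: float
    null_q500: float
    null_q975: float
    p_value: float
    seed: int

    def as_dict(self) -> dict:
        return {
            "measure": self.measure,
            "observed": self.observed,
            "n_perm": self.n_perm,
            "n_valid": self.n_valid,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "null_q025": self.null_q025,
            "null_q500": self.null_q500,
            "null_q975": self.null_q975,
            "p_value": self.p_value,
            "seed": self.seed,
        }


def _compute_measures(
    w: np.ndarray, names: tuple[str, ...], seed: int, null_spec: NullModelSpec
) -> dict[str, float]:
    """Compute the requested measures, sharing the distance matrix work.

    Undefined measures come back as NaN so ensemble dropout can be
    accounted without aborting a permutation run.
    """
    out: dict[str, float] = {}
    if _PATH_MEASURES & set(names):
        try:
            pm = path_measures(w)
        except ComputationError:
            pm = {k: float("nan") for k in _PATH_MEASURES}
        for k in _PATH_MEASURES & set(names):
            out[k] = pm[k]
    if {"average_strength", "assortativity_coefficient"} & set(names):
        s, a = strength_and_assortativity(w)
        out["average_strength"] = s
        out["assortativity_coefficient"] = a
    if {"mean_clustering_coefficient", "transitivity"} & set(names):
        c, t = clustering_and_transitivity(w)
        out["mean_clustering_coefficient"] = c
        out["transitivity"] = t
    if "local_efficiency" in names:
        try:
            out["local_efficiency"] = local_efficiency(w)
        except ComputationError:
            out["local_efficiency"] = float("nan")
    if "modularity" in names:
        try:
            out["modularity"] = modularity(w, seed=derive_stage_seeds(seed, "q"))
        except ComputationError:
            out["modularity"] = float("nan")
    if "small_worldness_index" in names:
        try:
            out["small_worldness_index"] = small_worldness(
                w,
                NullModelSpec(
                    null_spec.n_random,
                    null_spec.n_iter,
                    derive_stage_seeds(seed, "sw"),
                ),
            )
        except ComputationError:
            out["small_worldness_index"] = float("nan")
    return {k: out[k] for k in names}


def network_group_differences(
    cohort: Cohort | NormalizedVolumeMatrix,
    structure: str,
    hemisphere: str,
    measures: tuple[str, ...] = MEASURE_NAMES,
    n_perm: int = 1000,
    seed: int = 0,
    policy: str = "zero",
    null_spec: NullModelSpec | None = None,
    min_group: int = 2,
) -> dict[str, PermutationOutcome]:
    """Permutation tests for several measures of one network at once.

    For every permutation the group labels are shuffled preserving group
    sizes and both group networks are rebuilt from scratch
    (residualization included) before the measures are recomputed, so
    the complete statistic stays exchangeable under the null.
    Permutations on which a measure is undefined (degenerate network)
    are dropped for that measure and ``n_valid`` reports the count used.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    unknown = set(measures) - set(MEASURE_NAMES)
    if unknown:
        raise ValidationError(f"unknown measures {sorted(unknown)}")
    null_spec = null_spec or NullModelSpec()
    nvm = _as_lateralized(cohort)
    cols = nvm.columns_for(structure, hemisphere)
    X = nvm.values[cols].to_numpy(float)
    C = nvm.covariates[["age", "sex"]].to_numpy(float)
    is_poor = (nvm.group == "poor").to_numpy()
    n, n_poor = len(is_poor), int(is_poor.sum())
    if min(n_poor, n - n_poor) < min_group:
        raise InsufficientSampleError(
            f"both groups must have >= {min_group} subjects"
        )

    def group_stat(mask: np.ndarray, stat_seed: int) -> dict[str, float]:
        vals = {}
        for label, m in (("poor", mask), ("good", ~mask)):
            w = apply_weight_policy(pcorr_array(X[m], C[m], cols), policy)
            vals[label] = _compute_measures(
                w, tuple(measures), derive_stage_seeds(stat_seed, label), null_spec
            )
        return {
            k: vals["poor"][k] - vals["good"][k] for k in measures
        }

    observed = group_stat(is_poor, derive_stage_seeds(seed, "observed"))
    rng = np.random.default_rng(derive_stage_seeds(seed, "permutation"))
    null = np.full((n_perm, len(measures)), np.nan)
    for b in range(n_perm):
        perm = rng.permutation(n)
        mask = np.zeros(n, dtype=bool)
        mask[perm[:n_poor]] = True
        try:
            diffs = group_stat(mask, derive_stage_seeds(seed, f"perm:{b}"))
        except ComputationError:
            continue  # whole permutation degenerate: dropout for all measures
        null[b] = [diffs[k] for k in measures]

    outcomes = {}
    for j, name in enumerate(measures):
        obs = observed[name]
        col = null[:, j]
        valid = col[np.isfinite(col)]
        n_valid = int(valid.size)
        if not np.isfinite(obs) or n_valid == 0:
            p = float("nan")
        else:
            p = (1.0 + float((np.abs(valid) >= abs(obs)).sum())) / (n_valid + 1.0)
        q = (
            np.quantile(valid, [0.025, 0.5, 0.975])
            if n_valid
            else np.array([np.nan] * 3)
        )
        outcomes[name] = PermutationOutcome(
            measure=name,
            observed=float(obs),
            n_perm=n_perm,
            n_valid=n_valid,
            null_mean=float(valid.mean()) if n_valid else float("nan"),
            null_sd=float(valid.std(ddof=1)) if n_valid > 1 else float("nan"),
            null_q025=float(q[0]),
            null_q500=float(q[1]),
            null_q975=float(q[2]),
            p_value=p,
            seed=int(seed),
        )
    return outcomes


def network_group_difference(
    cohort,
    structure: str,
    hemisphere: str,
    measure: str,
    n_perm: int = 1000,
    seed: int = 0,
    policy: str = "zero",
    null_spec: NullModelSpec | None = None,
) -> PermutationOutcome:
    """Permutation test for a single measure of one network."""
    return network_group_differences(
        cohort, structure, hemisphere, (measure,), n_perm, seed, policy, null_spec
    )[measure]
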