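"""Synthetic two-group cohort generator.

Emulates the statistical structure the covariance analysis assumes: a
cohort of two outcome groups (default sizes 29 poor / 40 good), regional
volumes on the percent-of-ICV scale (means spanning roughly 0.0004-0.05,
the scale of real subregion volumetry), a block-structured inter-region
correlation topology, linear age and sex confounding of volumes, and
ICV scaling back to raw mm^3 per subject.  Group effects are expressed
either as a correlation inflation for the poor group (a network-level
effect with no mean difference) or as per-region mean shifts in SD
units; both default to zero so the default cohort is an exchangeable
null.

Volumes are generated on the percent-ICV scale and multiplied out to
mm^3 through each subject's eTIV, so ICV normalization downstream
recovers the generated values exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from .atlas import DEFAULT_ATLAS, HEMISPHERES, STRUCTURES, atlas_regions
from .cohort import Cohort, Subject
from .errors import TemplateInvalidError, ValidationError


def covariance_template(
    n_regions: int,
    rho_within: float,
    rho_between: float,
    modules: np.ndarray | None = None,
) -> np.ndarray:
    """Block-structured correlation matrix: ``rho_within`` inside a
    module, ``rho_between`` across modules, unit diagonal.

    ``modules`` assigns each region an integer module id; by default
    regions are split into 3 nearly equal contiguous blocks.  The result
    must be positive definite, otherwise the parameterization is
    rejected.
    """
    if not (abs(rho_within) < 1 and abs(rho_between) < 1):
        raise ValidationError("|rho| must be < 1")
    if modules is None:
        modules = default_modules(n_regions)
    modules = np.asarray(modules)
    if modules.shape != (n_regions,):
        raise ValidationError("module assignment length mismatch")
    same = modules[:, None] == modules[None, :]
    r = np.where(same, rho_within, rho_between)
    np.fill_diagonal(r, 1.0)
    min_eig = float(np.linalg.eigvalsh(r)[0])
    if min_eig <= 0:
        raise TemplateInvalidError(
            f"template not positive definite (min eigenvalue {min_eig:.3g}) "
            f"for rho_within={rho_within}, rho_between={rho_between}, "
            f"{len(np.unique(modules))} modules, n={n_regions}"
        )
    return r


def default_modules(n_regions: int, n_modules: int = 3) -> np.ndarray:
    """Contiguous near-equal module assignment."""
    n_modules = max(1, min(n_modules, n_regions))
    sizes = [len(b) for b in np.array_split(np.arange(n_regions), n_modules)]
    return np.repeat(np.arange(n_modules), sizes)


def default_region_means(n_regions: int) -> np.ndarray:
    """Default per-region mean volumes in percent ICV, log-spaced over
    the realistic subregion range 0.0004-0.05."""
    if n_regions == 1:
        return np.array([0.005])
    return np.logspace(np.log10(4e-4), np.log10(5e-2), n_regions)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic cohort.

    Defaults mirror the study conditions: group sizes 29/40, age about
    37 +/- 10 years truncated to [18, 70], 38% male, roughly balanced
    sclerosis side, eTIV about 1.5e6 +/- 1.5e5 mm^3, block correlation
    topology (rho 0.5 within / 0.2 between, 3 modules), mild age-related
    volume decline and a small sex offset, and no group effect (null).
    """

    n_poor: int = 29
    n_good: int = 40
    structures: tuple[str, ...] = STRUCTURES
    rho_within: float = 0.5
    rho_between: float = 0.2
    n_modules: int = 3
    #: added to rho_within for the poor group (network-level effect)
    corr_inflation_poor: float = 0.0
    #: per-region mean shift for the poor group, in SD units
    mean_shift_sd_poor: float = 0.0
    #: fractional volume change per year of age away from age_mean
    age_slope_frac: float = -0.004
    #: fractional male-minus-female volume offset
    sex_offset_frac: float = 0.05
    age_mean: float = 37.0
    age_sd: float = 10.0
    age_range: tuple[float, float] = (18.0, 70.0)
    p_male: float = 0.38
    p_right_hs: float = 0.46
    etiv_mean: float = 1.5e6
    etiv_sd: float = 1.5e5
    #: SD of each region as a fraction of its mean
    region_sd_frac: float = 0.2
    #: optional override: column key -> (mean pct, sd pct)
    region_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_poor < 0 or self.n_good < 0:
            raise ValidationError("group sizes must be non-negative")
        for p in (self.p_male, self.p_right_hs):
            if not 0 <= p <= 1:
                raise ValidationError("probabilities must be in [0, 1]")
        if self.region_sd_frac <= 0 or self.age_sd <= 0 or self.etiv_sd <= 0:
            raise ValidationError("SDs must be strictly positive")


def generate_cohort(spec: SyntheticSpec, seed: int) -> Cohort:
    """Draw a cohort from the spec; fully reproducible from the seed.

    Covariates are drawn first (age, sex, HS side, eTIV per subject),
    then per structure x hemisphere the percent-ICV volumes as a
    multivariate normal around covariate-adjusted means with the group's
    correlation template scaled by region SDs.  Negative draws are
    truncated at 0; the truncation rate is recorded in
    ``cohort.meta['truncation_rate']``.
    """
    rng = np.random.default_rng(seed)
    atlas = DEFAULT_ATLAS.subset(spec.structures)
    n = spec.n_poor + spec.n_good
    groups = ["poor"] * spec.n_poor + ["good"] * spec.n_good

    lo, hi = spec.age_range
    a, b = (lo - spec.age_mean) / spec.age_sd, (hi - spec.age_mean) / spec.age_sd
    age = truncnorm.rvs(a, b, loc=spec.age_mean, scale=spec.age_sd,
                        size=n, random_state=rng)
    sex = (rng.random(n) < spec.p_male).astype(int)  # 1 = male
    hs = np.where(rng.random(n) < spec.p_right_hs, "right", "left")
    etiv = truncnorm.rvs(
        (1e5 - spec.etiv_mean) / spec.etiv_sd, np.inf,
        loc=spec.etiv_mean, scale=spec.etiv_sd, size=n, random_state=rng,
    )

    pct = {}  # column key -> length-n array of percent-ICV values
    n_trunc = 0
    n_cells = 0
    slices = {"poor": slice(0, spec.n_poor), "good": slice(spec.n_poor, n)}
    for structure in atlas.structures:
        for hemi in HEMISPHERES:
            regions = atlas_regions(structure, hemi, atlas)
            p = len(regions)
            keys = [f"{structure}_{hemi}_{r}" for r in regions]
            base_mean = default_region_means(p).copy()
            base_sd = spec.region_sd_frac * base_mean
            for i, key in enumerate(keys):
                if key in spec.region_params:
                    base_mean[i], base_sd[i] = spec.region_params[key]
            modules = default_modules(p, spec.n_modules)
            vals = np.empty((n, p))
            for g in ("poor", "good"):
                rho_w = spec.rho_within + (
                    spec.corr_inflation_poor if g == "poor" else 0.0
                )
                template = covariance_template(p, rho_w, spec.rho_between, modules)
                chol = np.linalg.cholesky(template)
                sl = slices[g]
                ng = sl.stop - sl.start
                z = rng.standard_normal((ng, p)) @ chol.T
                mean = base_mean[None, :] * (
                    1.0
                    + spec.age_slope_frac * (age[sl, None] - spec.age_mean)
                    + spec.sex_offset_frac * sex[sl, None]
                )
                if g == "poor":
                    mean = mean + spec.mean_shift_sd_poor * base_sd[None, :]
                vals[sl] = mean + z * base_sd[None, :]
            n_trunc += int((vals < 0).sum())
            n_cells += vals.size
            vals = np.maximum(vals, 0.0)
            for i, key in enumerate(keys):
                pct[key] = vals[:, i]

    subjects = []
    width = len(str(n))
    for idx in range(n):
        volumes = {key: pct[key][idx] / 100.0 * etiv[idx] for key in pct}
        subjects.append(
            Subject(
                subject_id=f"S{idx + 1:0{width}d}",
                group=groups[idx],
                age=float(age[idx]),
                sex="male" if sex[idx] else "female",
                hs_side=str(hs[idx]),
                etiv_mm3=float(etiv[idx]),
                volumes=volumes,
            )
        )
    cohort = Cohort(
        subjects, atlas,
        meta={"truncation_rate": n_trunc / n_cells if n_cells else 0.0,
              "seed": int(seed)},
    )
    cohort.validate()
    return cohort
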