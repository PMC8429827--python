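"""End-to-end pipeline: load or simulate a cohort, normalize and
lateralize volumes, build per-group covariance networks, compute the
twelve graph measures, and run the permutation, volume and clinical
comparisons, writing a plain-text report bundle.

Everything stochastic is keyed off a single master seed through
:func:`~scnet.seeds.derive_stage_seeds`, so two runs with the same seed
and config produce byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field

import yaml

from . import __version__
from .atlas import LATERALIZED
from .cohort import (
    Cohort,
    lateralize,
    load_cohort_table,
    normalize_volumes,
    save_cohort_table,
)
from .errors import ConfigError
from .inference import (
    PermutationOutcome,
    VolumeComparisonRow,
    _two_sample_test,
    chi_squared_2x2,
    network_group_differences,
    volume_comparison_table,
)
from .measures import MEASURE_NAMES, MeasureSet, NullModelSpec, measure_set
from .network import MIN_GROUP_SIZE, build_group_network
from .seeds import derive_stage_seeds
from .synthetic import SyntheticSpec, generate_cohort

log = logging.getLogger("scnet")

ALL_STAGES = ("networks", "measures", "compare")


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run."""

    input_table: str | None = None  # None -> synthetic cohort
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    structures: tuple[str, ...] | None = None  # None -> all in the atlas
    policy: str = "zero"  # negative-weight policy: zero | abs
    n_random: int = 100  # random references for small-worldness
    n_iter: int = 10  # rewiring iterations per edge
    n_perm: int = 1000
    alpha: float = 0.05
    seed: int = 0
    outdir: str = "scnet_out"

    def __post_init__(self):
        if self.n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = dict(raw)
        if isinstance(kwargs.get("synthetic"), dict):
            syn_known = {f.name for f in dataclasses.fields(SyntheticSpec)}
            syn_unknown = set(kwargs["synthetic"]) - syn_known
            if syn_unknown:
                raise ConfigError(
                    f"unknown synthetic key(s): {sorted(syn_unknown)}"
                )
            syn = dict(kwargs["synthetic"])
            if "structures" in syn:
                syn["structures"] = tuple(syn["structures"])
            kwargs["synthetic"] = SyntheticSpec(**syn)
        if kwargs.get("structures") is not None:
            kwargs["structures"] = tuple(kwargs["structures"])
        return cls(**kwargs)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"] = dataclasses.asdict(self.synthetic)
        return d


@dataclass
class ReportBundle:
    cohort: Cohort
    measures: dict  # (structure, hemisphere, group) -> MeasureSet
    permutations: dict  # (structure, hemisphere) -> {measure: PermutationOutcome}
    volume_rows: list[VolumeComparisonRow]
    clinical_rows: list[dict]
    manifest: dict
    outdir: str


def _resolve_cohort(config: RunConfig) -> Cohort:
    if config.input_table:
        return load_cohort_table(config.input_table)
    return generate_cohort(
        config.synthetic, derive_stage_seeds(config.seed, "simulate")
    )


def run_pipeline(
    config: RunConfig, stages: tuple[str, ...] = ALL_STAGES
) -> ReportBundle:
    """Run the requested stages and write the report bundle to
    ``config.outdir``.  Network construction always runs; ``measures``
    and ``compare`` can be skipped for partial runs."""
    t0 = time.perf_counter()
    os.makedirs(config.outdir, exist_ok=True)
    cohort = _resolve_cohort(config)
    if not config.input_table:
        save_cohort_table(cohort, os.path.join(config.outdir, "cohort.csv"))
    sizes = cohort.group_sizes
    log.info("cohort: %d subjects %s", len(cohort), sizes)
    if min(sizes.values()) < MIN_GROUP_SIZE:
        log.warning(
            "a group has fewer than %d subjects; covariance estimates will "
            "have wide variance", MIN_GROUP_SIZE,
        )
    nvm = lateralize(normalize_volumes(cohort))
    structures = config.structures or cohort.atlas.structures
    null_spec = NullModelSpec(config.n_random, config.n_iter)

    conn_dir = os.path.join(config.outdir, "connectivity")
    os.makedirs(conn_dir, exist_ok=True)
    measures: dict[tuple, MeasureSet] = {}
    permutations: dict[tuple, dict[str, PermutationOutcome]] = {}
    for structure in structures:
        for hemi in LATERALIZED:
            for group in ("poor", "good"):
                conn = build_group_network(
                    nvm, structure, hemi, group, config.policy
                )
                conn.provenance["master_seed"] = config.seed
                conn.to_tsv(
                    os.path.join(conn_dir, f"{structure}_{hemi}_{group}.tsv")
                )
                if "measures" in stages:
                    ms = measure_set(
                        conn,
                        null_spec,
                        derive_stage_seeds(
                            config.seed, f"measures:{structure}:{hemi}:{group}"
                        ),
                    )
                    measures[(structure, hemi, group)] = ms
            if "compare" in stages:
                permutations[(structure, hemi)] = network_group_differences(
                    nvm,
                    structure,
                    hemi,
                    MEASURE_NAMES,
                    n_perm=config.n_perm,
                    seed=derive_stage_seeds(
                        config.seed, f"perm:{structure}:{hemi}"
                    ),
                    policy=config.policy,
                    null_spec=null_spec,
                )
            log.info(
                "%s/%s done (%.1fs elapsed)", structure, hemi,
                time.perf_counter() - t0,
            )

    volume_rows: list[VolumeComparisonRow] = []
    clinical_rows: list[dict] = []
    if "compare" in stages:
        volume_rows = volume_comparison_table(nvm, config.alpha)
        clinical_rows = _clinical_table(cohort)

    manifest = {
        "package": "scnet",
        "version": __version__,
        "seed": config.seed,
        "config": config.echo(),
        "n_subjects": len(cohort),
        "group_sizes": sizes,
        "cohort_meta": cohort.meta,
        "measure_names": list(MEASURE_NAMES),
    }
    bundle = ReportBundle(
        cohort, measures, permutations, volume_rows, clinical_rows,
        manifest, config.outdir,
    )
    _write_bundle(bundle, stages)
    log.info("pipeline finished in %.1fs", time.perf_counter() - t0)
    return bundle


def _clinical_table(cohort: Cohort) -> list[dict]:
    """Between-group tests on demographics: age (t or Mann-Whitney by
    normality), sex and HS side (chi-squared)."""
    import numpy as np

    groups = cohort.group_labels()
    age = np.array([s.age for s in cohort.subjects])
    rows = []
    test, stat, p = _two_sample_test(age[groups == "poor"], age[groups == "good"])
    rows.append({"variable": "age", "test": test, "statistic": stat, "p_value": p})
    for var, getter, positive in (
        ("sex_male", lambda s: s.sex == "male", "male"),
        ("hs_side_right", lambda s: s.hs_side == "right", "right"),
    ):
        a = sum(1 for s in cohort.subjects if s.group == "poor" and getter(s))
        b = sum(1 for s in cohort.subjects if s.group == "poor" and not getter(s))
        c = sum(1 for s in cohort.subjects if s.group == "good" and getter(s))
        d = sum(1 for s in cohort.subjects if s.group == "good" and not getter(s))
        try:
            stat, p = chi_squared_2x2(a, b, c, d)
            rows.append(
                {"variable": var, "test": "chi-squared", "statistic": stat,
                 "p_value": p}
            )
        except Exception:
            rows.append(
                {"variable": var, "test": "chi-squared",
                 "statistic": float("nan"), "p_value": float("nan")}
            )
    return rows


def _write_bundle(bundle: ReportBundle, stages) -> None:
    out = bundle.outdir
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(bundle.manifest, fh, indent=1, sort_keys=True)
    if bundle.measures:
        with open(os.path.join(out, "measures.tsv"), "w") as fh:
            fh.write(
                "structure\themisphere\tgroup\t"
                + "\t".join(MEASURE_NAMES) + "\n"
            )
            for (s, h, g), ms in sorted(bundle.measures.items()):
                vals = "\t".join(repr(v) for v in ms.as_dict().values())
                fh.write(f"{s}\t{h}\t{g}\t{vals}\n")
    if bundle.permutations:
        payload = {
            f"{s}:{h}": {m: o.as_dict() for m, o in outs.items()}
            for (s, h), outs in sorted(bundle.permutations.items())
        }
        with open(os.path.join(out, "permutations.json"), "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
    if bundle.volume_rows:
        with open(os.path.join(out, "volumes.tsv"), "w") as fh:
            cols = [f.name for f in dataclasses.fields(VolumeComparisonRow)]
            fh.write("\t".join(cols) + "\n")
            for row in bundle.volume_rows:
                fh.write(
                    "\t".join(repr(getattr(row, c)) for c in cols) + "\n"
                )
    if bundle.clinical_rows:
        with open(os.path.join(out, "clinical.tsv"), "w") as fh:
            fh.write("variable\ttest\tstatistic\tp_value\n")
            for row in bundle.clinical_rows:
                fh.write(
                    f"{row['variable']}\t{row['test']}\t"
                    f"{row['statistic']!r}\t{row['p_value']!r}\n"
                )
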