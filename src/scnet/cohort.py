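"""Subject-level volume I/O, validation, ICV normalization and
ipsi/contra lateralization.

A cohort is a set of subjects, each carrying demographics (age, sex),
the outcome group label (``poor``/``good``), the side of hippocampal
sclerosis, the estimated total intracranial volume (eTIV, mm^3) and one
raw volume (mm^3) per atlas region.  Volumes are normalized to percent
of ICV (``100 * raw / etiv``) and relabeled from left/right to
ipsilateral/contralateral relative to each subject's sclerosis side
before any network is built.
"""

from __future__ import annotations

import csv
import io
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atlas import DEFAULT_ATLAS, HEMISPHERES, LATERALIZED, RegionAtlas
from .errors import ParseError, SchemaError, ValidationError

GROUPS = ("poor", "good")
SEXES = ("male", "female")
#: Covariate encoding used throughout: sex 0 = female, 1 = male.
SEX_CODE = {"female": 0, "male": 1}

REQUIRED_COLUMNS = ("subject_id", "group", "age", "sex", "hs_side", "etiv_mm3")


@dataclass
class Subject:
    subject_id: str
    group: str
    age: float
    sex: str
    hs_side: str
    etiv_mm3: float
    volumes: dict[str, float]  # "structure_hemisphere_region" -> mm^3

    def validate(self, atlas: RegionAtlas) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"{self.subject_id}: unknown group {self.group!r}"
            )
        if not self.age > 0:
            raise ValidationError(f"{self.subject_id}: age must be > 0")
        if self.sex not in SEXES:
            raise ValidationError(f"{self.subject_id}: unknown sex {self.sex!r}")
        if self.hs_side not in HEMISPHERES:
            raise ValidationError(
                f"{self.subject_id}: hs_side must be left or right"
            )
        if not self.etiv_mm3 > 0:
            raise ValidationError(f"{self.subject_id}: eTIV must be > 0")
        expected = atlas.column_keys()
        missing = [k for k in expected if k not in self.volumes]
        if missing:
            raise ValidationError(
                f"{self.subject_id}: missing region volumes, e.g. {missing[:3]}"
            )
        extra = [k for k in self.volumes if k not in set(expected)]
        if extra:
            raise ValidationError(
                f"{self.subject_id}: unknown region volumes, e.g. {extra[:3]}"
            )
        for key, v in self.volumes.items():
            if not np.isfinite(v) or v < 0:
                raise ValidationError(
                    f"{self.subject_id}: invalid volume {v!r} for {key}"
                )


@dataclass
class Cohort:
    subjects: list[Subject]
    atlas: RegionAtlas = field(default_factory=lambda: DEFAULT_ATLAS)
    meta: dict = field(default_factory=dict)  # e.g. generator truncation rate

    def validate(self) -> None:
        seen = set()
        for s in self.subjects:
            if s.subject_id in seen:
                raise ValidationError(f"duplicate subject id {s.subject_id!r}")
            seen.add(s.subject_id)
            s.validate(self.atlas)

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def group_sizes(self) -> dict[str, int]:
        sizes = {g: 0 for g in GROUPS}
        for s in self.subjects:
            sizes[s.group] += 1
        return sizes

    def group_labels(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects])


def load_cohort_table(path, atlas: RegionAtlas = DEFAULT_ATLAS) -> Cohort:
    """Read a cohort from a delimited text table.

    Two layouts are accepted:

    * wide: one column per ``structure_hemisphere_region`` volume in mm^3;
    * manifest: a ``stats_path`` column pointing to per-subject two-column
      stats files (``label  volume``, whitespace separated; label equals
      the same ``structure_hemisphere_region`` key), resolved relative to
      the manifest's directory.
    """
    if os.path.getsize(path) == 0:
        raise ParseError(f"{path}: empty file")
    with open(path, newline="") as fh:
        sample = fh.read(65536)
    delim = "\t" if sample.splitlines()[0].count("\t") else ","
    header = next(csv.reader(io.StringIO(sample), delimiter=delim))
    dup = {c for c in header if header.count(c) > 1}
    if dup:
        raise SchemaError(f"{path}: duplicate columns {sorted(dup)}")
    try:
        df = pd.read_csv(
            path, sep=delim, dtype={"subject_id": str},
            float_precision="round_trip",
        )
    except Exception as exc:  # malformed beyond the duplicate check
        raise ParseError(f"{path}: {exc}") from exc
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")

    expected = atlas.column_keys()
    manifest = "stats_path" in df.columns
    if not manifest:
        missing_regions = [k for k in expected if k not in df.columns]
        if missing_regions:
            raise SchemaError(
                f"{path}: missing region columns, e.g. {missing_regions[:3]}"
            )

    base = os.path.dirname(os.path.abspath(path))
    subjects = []
    for _, row in df.iterrows():
        if manifest:
            stats = os.path.join(base, str(row["stats_path"]))
            volumes = _read_stats_file(stats)
        else:
            volumes = {}
            for key in expected:
                val = row[key]
                try:
                    volumes[key] = float(val)
                except (TypeError, ValueError):
                    raise ValidationError(
                        f"{row['subject_id']}: non-numeric volume {val!r} "
                        f"for {key}"
                    ) from None
        subjects.append(
            Subject(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]).strip().lower(),
                age=float(row["age"]),
                sex=str(row["sex"]).strip().lower(),
                hs_side=str(row["hs_side"]).strip().lower(),
                etiv_mm3=float(row["etiv_mm3"]),
                volumes=volumes,
            )
        )
    cohort = Cohort(subjects, atlas)
    cohort.validate()
    return cohort


def _read_stats_file(path) -> dict[str, float]:
    volumes: dict[str, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 'label volume'")
            label, value = parts
            if label in volumes:
                raise ValidationError(f"{path}: duplicate region {label!r}")
            try:
                volumes[label] = float(value)
            except ValueError:
                raise ValidationError(
                    f"{path}:{lineno}: non-numeric volume {value!r}"
                ) from None
    return volumes


def save_cohort_table(cohort: Cohort, path) -> None:
    """Write the wide-table format; round-trips exactly (repr floats)."""
    keys = cohort.atlas.column_keys()
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(REQUIRED_COLUMNS) + keys)
        for s in cohort.subjects:
            writer.writerow(
                [s.subject_id, s.group, repr(float(s.age)), s.sex, s.hs_side,
                 repr(float(s.etiv_mm3))]
                + [repr(float(s.volumes[k])) for k in keys]
            )


@dataclass
class NormalizedVolumeMatrix:
    """Subjects x regions matrix of ICV-normalized volumes (percent of ICV).

    ``values`` columns are ``structure_hemisphere_region`` keys; hemisphere
    is ``left``/``right`` before lateralization and ``ipsi``/``contra``
    after.  ``covariates`` holds ``age`` and ``sex`` (0 = female, 1 = male)
    indexed like ``values``; ``hs_side`` and ``group`` are carried for
    downstream lateralization and group splits.
    """

    values: pd.DataFrame
    covariates: pd.DataFrame
    hs_side: pd.Series
    group: pd.Series
    atlas: RegionAtlas
    lateralized: bool = False

    def columns_for(self, structure: str, hemisphere: str) -> list[str]:
        from .atlas import atlas_regions

        want = LATERALIZED if self.lateralized else HEMISPHERES
        if hemisphere not in want:
            raise ValidationError(
                f"hemisphere {hemisphere!r} not available "
                f"(matrix lateralized={self.lateralized})"
            )
        return [
            f"{structure}_{hemisphere}_{r}"
            for r in atlas_regions(structure, hemisphere, self.atlas)
        ]

    def copy(self) -> "NormalizedVolumeMatrix":
        return replace(
            self,
            values=self.values.copy(),
            covariates=self.covariates.copy(),
            hs_side=self.hs_side.copy(),
            group=self.group.copy(),
        )


def normalize_volumes(cohort: Cohort) -> NormalizedVolumeMatrix:
    """ICV-normalize raw volumes: each cell is ``100 * raw / etiv``.

    Passing an already normalized matrix is a type error by construction;
    this guards against silently dividing by ICV twice.
    """
    if isinstance(cohort, NormalizedVolumeMatrix):
        raise ValidationError("input is already normalized")
    cohort.validate()
    keys = cohort.atlas.column_keys()
    ids = [s.subject_id for s in cohort.subjects]
    raw = np.array([[s.volumes[k] for k in keys] for s in cohort.subjects])
    etiv = np.array([s.etiv_mm3 for s in cohort.subjects])
    values = pd.DataFrame(100.0 * raw / etiv[:, None], index=ids, columns=keys)
    covariates = pd.DataFrame(
        {
            "age": [s.age for s in cohort.subjects],
            "sex": [SEX_CODE[s.sex] for s in cohort.subjects],
        },
        index=ids,
        dtype=float,
    )
    hs_side = pd.Series([s.hs_side for s in cohort.subjects], index=ids)
    group = pd.Series([s.group for s in cohort.subjects], index=ids)
    return NormalizedVolumeMatrix(
        values, covariates, hs_side, group, cohort.atlas, lateralized=False
    )


def lateralize(matrix: NormalizedVolumeMatrix) -> NormalizedVolumeMatrix:
    """Relabel left/right columns to ipsilateral/contralateral per subject.

    The ipsilateral hemisphere is the side of the hippocampal sclerosis.
    Values are permuted within each subject's row, never altered.
    """
    if matrix.lateralized:
        raise ValidationError("matrix is already lateralized")
    if matrix.hs_side.isna().any():
        raise ValidationError("missing hs_side for some subjects")
    left_is_ipsi = (matrix.hs_side == "left").to_numpy()
    out = {}
    for s in matrix.atlas.structures:
        for r in matrix.atlas.regions[(s, "left")]:
            lv = matrix.values[f"{s}_left_{r}"].to_numpy()
            rv = matrix.values[f"{s}_right_{r}"].to_numpy()
            out[f"{s}_ipsi_{r}"] = np.where(left_is_ipsi, lv, rv)
            out[f"{s}_contra_{r}"] = np.where(left_is_ipsi, rv, lv)
    cols = matrix.atlas.column_keys(LATERALIZED)
    values = pd.DataFrame(out, index=matrix.values.index)[cols]
    return replace(matrix, values=values, lateralized=True)


def delateralize(matrix: NormalizedVolumeMatrix) -> NormalizedVolumeMatrix:
    """Inverse of :func:`lateralize`: restore left/right column labels."""
    if not matrix.lateralized:
        raise ValidationError("matrix is not lateralized")
    left_is_ipsi = (matrix.hs_side == "left").to_numpy()
    out = {}
    for s in matrix.atlas.structures:
        for r in matrix.atlas.regions[(s, "left")]:
            iv = matrix.values[f"{s}_ipsi_{r}"].to_numpy()
            cv = matrix.values[f"{s}_contra_{r}"].to_numpy()
            out[f"{s}_left_{r}"] = np.where(left_is_ipsi, iv, cv)
            out[f"{s}_right_{r}"] = np.where(left_is_ipsi, cv, iv)
    cols = matrix.atlas.column_keys(HEMISPHERES)
    values = pd.DataFrame(out, index=matrix.values.index)[cols]
    return replace(matrix, values=values, lateralized=False)
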