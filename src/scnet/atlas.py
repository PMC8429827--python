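"""Canonical region atlas for amygdala nuclei, hippocampal subfields and
thalamic nuclei.

The default label sets follow the FreeSurfer v7 subregional segmentation
streams (``segmentHA_T1`` for amygdala/hippocampus, the thalamic-nuclei
module for the thalamus): 9 amygdala nuclei, 21 hippocampal subfields
(including the whole-head/whole-body aggregates that stream emits) and
25 thalamic nuclei per hemisphere.  The counts are contractual; the names
are interchangeable labels and can be overridden from a plain-text atlas
file (see :func:`load_atlas_file`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import UnknownStructureError, ValidationError

STRUCTURES = ("amygdala", "hippocampus", "thalamus")
HEMISPHERES = ("left", "right")
#: Lateralized hemisphere labels used after ipsi/contra relabeling.
LATERALIZED = ("ipsi", "contra")

EXPECTED_COUNTS = {"amygdala": 9, "hippocampus": 21, "thalamus": 25}

_AMYGDALA = (
    "Lateral-nucleus",
    "Basal-nucleus",
    "Accessory-Basal-nucleus",
    "Anterior-amygdaloid-area-AAA",
    "Central-nucleus",
    "Medial-nucleus",
    "Cortical-nucleus",
    "Corticoamygdaloid-transitio",
    "Paralaminar-nucleus",
)

_HIPPOCAMPUS = (
    "Hippocampal-tail",
    "subiculum-head",
    "subiculum-body",
    "CA1-head",
    "CA1-body",
    "CA3-head",
    "CA3-body",
    "CA4-head",
    "CA4-body",
    "presubiculum-head",
    "presubiculum-body",
    "parasubiculum",
    "molecular-layer-HP-head",
    "molecular-layer-HP-body",
    "GC-ML-DG-head",
    "GC-ML-DG-body",
    "fimbria",
    "HATA",
    "hippocampal-fissure",
    "Whole-hippocampal-head",
    "Whole-hippocampal-body",
)

_THALAMUS = (
    "AV", "CeM", "CL", "CM", "LD", "LGN", "LP", "L-Sg", "MDl", "MDm",
    "MGN", "MV-Re", "Pc", "Pf", "Pt", "PuA", "PuI", "PuL", "PuM", "VA",
    "VAmc", "VLa", "VLp", "VM", "VPL",
)

_DEFAULT_REGIONS = {
    "amygdala": _AMYGDALA,
    "hippocampus": _HIPPOCAMPUS,
    "thalamus": _THALAMUS,
}


@dataclass(frozen=True)
class RegionAtlas:
    """Ordered region names per (structure, hemisphere).

    ``regions`` maps ``(structure, hemisphere)`` to an ordered tuple of
    region names.  Counts are enforced: 9 amygdala, 21 hippocampus, 25
    thalamus regions per hemisphere; names must be unique within a
    structure+hemisphere.  An atlas may cover a subset of structures
    (e.g. amygdala only) but always both hemispheres of each structure
    it covers.
    """

    regions: Mapping[tuple[str, str], tuple[str, ...]] = field(
        default_factory=lambda: {
            (s, h): _DEFAULT_REGIONS[s] for s in STRUCTURES for h in HEMISPHERES
        }
    )

    def __post_init__(self):
        structures = {s for s, _ in self.regions}
        for s in structures:
            if s not in EXPECTED_COUNTS:
                raise UnknownStructureError(f"unknown structure {s!r}")
            for h in HEMISPHERES:
                if (s, h) not in self.regions:
                    raise ValidationError(f"atlas misses hemisphere {h!r} of {s!r}")
                names = self.regions[(s, h)]
                if len(names) != EXPECTED_COUNTS[s]:
                    raise ValidationError(
                        f"{s} must have {EXPECTED_COUNTS[s]} regions per "
                        f"hemisphere, got {len(names)}"
                    )
                if len(set(names)) != len(names):
                    raise ValidationError(f"duplicate region names in {s}/{h}")

    @property
    def structures(self) -> tuple[str, ...]:
        return tuple(s for s in STRUCTURES if (s, "left") in self.regions)

    def column_keys(self, hemispheres: Iterable[str] = HEMISPHERES) -> list[str]:
        """All ``structure_hemisphere_region`` column keys, in atlas order."""
        keys = []
        for s in self.structures:
            for h in hemispheres:
                src_h = h if (s, h) in self.regions else "left"
                for r in self.regions[(s, src_h)]:
                    keys.append(f"{s}_{h}_{r}")
        return keys

    def subset(self, structures: Iterable[str]) -> "RegionAtlas":
        """A new atlas restricted to the given structures."""
        structures = tuple(structures)
        for s in structures:
            if (s, "left") not in self.regions:
                raise UnknownStructureError(f"structure {s!r} not in atlas")
        return RegionAtlas(
            {k: v for k, v in self.regions.items() if k[0] in structures}
        )


DEFAULT_ATLAS = RegionAtlas()


def atlas_regions(
    structure: str, hemisphere: str, atlas: RegionAtlas = DEFAULT_ATLAS
) -> tuple[str, ...]:
    """Canonical ordered region list for one structure and hemisphere.

    ``hemisphere`` may be an anatomical label (``left``/``right``) or a
    lateralized one (``ipsi``/``contra``); the region names are the same.
    """
    if hemisphere in LATERALIZED:
        hemisphere = "left"
    if hemisphere not in HEMISPHERES:
        raise UnknownStructureError(f"unknown hemisphere {hemisphere!r}")
    key = (structure, hemisphere)
    if key not in atlas.regions:
        raise UnknownStructureError(f"unknown structure {structure!r}")
    return tuple(atlas.regions[key])


def load_atlas_file(path) -> RegionAtlas:
    """Parse a plain-text atlas override.

    Format: section headers ``[structure]`` or ``[structure hemisphere]``,
    followed by one region name per line.  A ``[structure]`` section applies
    to both hemispheres.  Blank lines and ``#`` comments are ignored.
    """
    regions: dict[tuple[str, str], list[str]] = {}
    current: list[tuple[str, str]] | None = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("[") and line.endswith("]"):
                parts = line[1:-1].split()
                if len(parts) == 1:
                    current = [(parts[0], h) for h in HEMISPHERES]
                elif len(parts) == 2:
                    current = [(parts[0], parts[1])]
                else:
                    raise ValidationError(f"bad atlas section header: {line}")
                for key in current:
                    regions.setdefault(key, [])
            else:
                if current is None:
                    raise ValidationError("region name before any section header")
                for key in current:
                    regions[key].append(line)
    if not regions:
        raise ValidationError(f"atlas file {path} defines no regions")
    return RegionAtlas({k: tuple(v) for k, v in regions.items()})
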