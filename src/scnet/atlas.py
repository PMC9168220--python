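"""Region atlases for regional morphometry tables.

The analysis operates on a fixed parcelation: 68 cortical regions (the
Desikan-Killiany parcelation, 34 per hemisphere) described by cortical
thickness, surface area and mean curvature, plus 19 non-cortical
(subcortical, cerebellar and brainstem) regions described by their volume.
A :class:`RegionAtlas` carries the region names, hemisphere, a coarse lobe
assignment used for display grouping, and the cortical/non-cortical split.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import ConfigurationError

#: the 34 Desikan-Killiany cortical parcels per hemisphere, with lobe labels
_DK_PARCELS = [
    ("bankssts", "temporal"),
    ("caudalanteriorcingulate", "cingulate"),
    ("caudalmiddlefrontal", "frontal"),
    ("cuneus", "occipital"),
    ("entorhinal", "temporal"),
    ("fusiform", "temporal"),
    ("inferiorparietal", "parietal"),
    ("inferiortemporal", "temporal"),
    ("isthmuscingulate", "cingulate"),
    ("lateraloccipital", "occipital"),
    ("lateralorbitofrontal", "frontal"),
    ("lingual", "occipital"),
    ("medialorbitofrontal", "frontal"),
    ("middletemporal", "temporal"),
    ("parahippocampal", "temporal"),
    ("paracentral", "frontal"),
    ("parsopercularis", "frontal"),
    ("parsorbitalis", "frontal"),
    ("parstriangularis", "frontal"),
    ("pericalcarine", "occipital"),
    ("postcentral", "parietal"),
    ("posteriorcingulate", "cingulate"),
    ("precentral", "frontal"),
    ("precuneus", "parietal"),
    ("rostralanteriorcingulate", "cingulate"),
    ("rostralmiddlefrontal", "frontal"),
    ("superiorfrontal", "frontal"),
    ("superiorparietal", "parietal"),
    ("superiortemporal", "temporal"),
    ("supramarginal", "parietal"),
    ("frontalpole", "frontal"),
    ("temporalpole", "temporal"),
    ("transversetemporal", "temporal"),
    ("insula", "insula"),
]

#: the 19 non-cortical volume parcels (Freesurfer aseg naming)
_NONCORTICAL = [
    ("Left-Thalamus-Proper", "left", "subcortical"),
    ("Left-Caudate", "left", "subcortical"),
    ("Left-Putamen", "left", "subcortical"),
    ("Left-Pallidum", "left", "subcortical"),
    ("Left-Hippocampus", "left", "subcortical"),
    ("Left-Amygdala", "left", "subcortical"),
    ("Left-Accumbens-area", "left", "subcortical"),
    ("Left-VentralDC", "left", "subcortical"),
    ("Left-Cerebellum-Cortex", "left", "cerebellum"),
    ("Right-Thalamus-Proper", "right", "subcortical"),
    ("Right-Caudate", "right", "subcortical"),
    ("Right-Putamen", "right", "subcortical"),
    ("Right-Pallidum", "right", "subcortical"),
    ("Right-Hippocampus", "right", "subcortical"),
    ("Right-Amygdala", "right", "subcortical"),
    ("Right-Accumbens-area", "right", "subcortical"),
    ("Right-VentralDC", "right", "subcortical"),
    ("Right-Cerebellum-Cortex", "right", "cerebellum"),
    ("Brain-Stem", "midline", "brainstem"),
]


@dataclass(frozen=True)
class Region:
    """One atlas parcel."""

    region_id: int
    name: str
    hemisphere: str  # {"left", "right", "midline"}
    lobe: str
    cortical: bool


class RegionAtlas:
    """Ordered collection of regions with a cortical / non-cortical split.

    Region order is the canonical order of every regional value table in the
    pipeline: cortical regions first (0-based indices ``0 .. n_cortical-1``),
    then non-cortical regions.
    """

    def __init__(self, regions: Sequence[Region]):
        names = [r.name for r in regions]
        if len(set(names)) != len(names):
            raise ConfigurationError("atlas region names must be unique")
        if [r.region_id for r in regions] != list(range(len(regions))):
            raise ConfigurationError("atlas region_ids must be 0..P-1 in order")
        n_c = sum(r.cortical for r in regions)
        if any(r.cortical != (r.region_id < n_c) for r in regions):
            raise ConfigurationError("cortical regions must precede non-cortical ones")
        self._regions = tuple(regions)

    def __len__(self) -> int:
        return len(self._regions)

    def __iter__(self):
        return iter(self._regions)

    def __getitem__(self, i: int) -> Region:
        return self._regions[i]

    @property
    def n_cortical(self) -> int:
        return sum(r.cortical for r in self._regions)

    @property
    def n_noncortical(self) -> int:
        return len(self) - self.n_cortical

    @property
    def names(self) -> list[str]:
        return [r.name for r in self._regions]

    @property
    def cortical_names(self) -> list[str]:
        return [r.name for r in self._regions if r.cortical]

    @property
    def noncortical_names(self) -> list[str]:
        return [r.name for r in self._regions if not r.cortical]

    def index_of(self, name: str) -> int:
        for r in self._regions:
            if r.name == name:
                return r.region_id
        raise KeyError(name)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": [r.region_id for r in self._regions],
                "name": self.names,
                "hemisphere": [r.hemisphere for r in self._regions],
                "lobe": [r.lobe for r in self._regions],
                "cortical": [int(r.cortical) for r in self._regions],
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "RegionAtlas":
        regions = [
            Region(int(row.region_id), str(row.name_), str(row.hemisphere), str(row.lobe), bool(row.cortical))
            for row in df.rename(columns={"name": "name_"}).itertuples(index=False)
        ]
        return cls(regions)


def homotopic_pairs(atlas: RegionAtlas) -> list[tuple[int, int]]:
    """Left/right homologous region pairs, by name matching.

    Names of the form ``lh_x`` / ``rh_x`` or ``Left-X`` / ``Right-X`` are
    matched by their stem; atlases without such names (synthetic ones) fall
    back to pairing consecutive regions of opposite hemisphere within the
    cortical and non-cortical blocks.  Unmatched (midline) regions stay
    unpaired.
    """

    def stem(name: str) -> str | None:
        if name.startswith(("lh_", "rh_")):
            return name[3:]
        if name.startswith("Left-"):
            return name[5:]
        if name.startswith("Right-"):
            return name[6:]
        return None

    by_stem: dict[str, list[int]] = {}
    named = set()
    for r in atlas:
        s = stem(r.name)
        if s is not None:
            by_stem.setdefault(s, []).append(r.region_id)
            named.add(r.region_id)
    pairs = [tuple(sorted(v)) for v in by_stem.values() if len(v) == 2]
    # fallback: consecutive opposite-hemisphere regions not already matched
    for block in (range(atlas.n_cortical), range(atlas.n_cortical, len(atlas))):
        ids = [i for i in block if i not in named]
        for a, b in zip(ids[::2], ids[1::2]):
            if atlas[a].hemisphere != atlas[b].hemisphere:
                pairs.append((a, b))
    return sorted(pairs)


def desikan_killiany_atlas() -> RegionAtlas:
    """The 87-region atlas: 68 DK cortical parcels + 19 non-cortical volumes."""
    regions = []
    for hemi, prefix in (("left", "lh"), ("right", "rh")):
        for name, lobe in _DK_PARCELS:
            regions.append(
                Region(len(regions), f"{prefix}_{name}", hemi, lobe, cortical=True)
            )
    for name, hemi, lobe in _NONCORTICAL:
        regions.append(Region(len(regions), name, hemi, lobe, cortical=False))
    return RegionAtlas(regions)


def synthetic_atlas(n_cortical: int = 68, n_noncortical: int = 19) -> RegionAtlas:
    """A generic atlas for simulations that do not use the standard parcelation.

    Region names are ``ctx-0001 ...`` and ``sub-0001 ...``; hemispheres
    alternate left/right purely for display purposes.
    """
    if n_cortical == 68 and n_noncortical == 19:
        return desikan_killiany_atlas()
    if n_cortical < 2 or n_noncortical < 0:
        raise ConfigurationError("need at least 2 cortical regions")
    regions = []
    for i in range(n_cortical):
        hemi = "left" if i % 2 == 0 else "right"
        regions.append(
            Region(len(regions), f"ctx-{i + 1:04d}", hemi, f"lobe-{i // 8 + 1}", True)
        )
    for i in range(n_noncortical):
        hemi = "left" if i % 2 == 0 else "right"
        regions.append(
            Region(len(regions), f"sub-{i + 1:04d}", hemi, f"sublobe-{i // 8 + 1}", False)
        )
    return RegionAtlas(regions)
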