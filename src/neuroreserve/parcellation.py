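"""Parcellation schemes: the named grey-matter measures the pipeline operates on.

The default scheme follows the lobar/subcortical parcellation used in
multicentre genetic-FTD imaging studies: six cortical lobes and seven
subcortical structures per hemisphere, plus a single bilateral cerebellum
measure — 27 volumes in all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["Region", "ParcellationScheme", "default_scheme"]

CORTICAL_STRUCTURES = ("frontal", "temporal", "parietal", "occipital", "cingulate", "insula")
SUBCORTICAL_STRUCTURES = (
    "hippocampus", "amygdala", "caudate", "putamen", "accumbens", "pallidum", "thalamus",
)


@dataclass(frozen=True)
class Region:
    """One grey-matter measure.

    Parameters
    ----------
    name
        Unique column name, e.g. ``"frontal_l"``.
    hemisphere
        ``"left"``, ``"right"`` or ``"bilateral"``.
    tissue_class
        ``"cortical"``, ``"subcortical"`` or ``"cerebellar"``.
    structure
        Anatomical label shared by left/right homologues, e.g. ``"frontal"``.
    """

    name: str
    hemisphere: str
    tissue_class: str
    structure: str

    def __post_init__(self) -> None:
        if self.hemisphere not in ("left", "right", "bilateral"):
            raise ValueError(f"invalid hemisphere {self.hemisphere!r} for region {self.name!r}")
        if self.tissue_class not in ("cortical", "subcortical", "cerebellar"):
            raise ValueError(f"invalid tissue_class {self.tissue_class!r} for region {self.name!r}")


@dataclass(frozen=True)
class ParcellationScheme:
    """Ordered collection of grey-matter measures.

    Every unilateral region must have exactly one contralateral homologue
    (same ``structure``, opposite hemisphere). Bilateral measures (the
    cerebellum in the default scheme) stand alone.
    """

    regions: tuple[Region, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique")
        for region in self.regions:
            if region.hemisphere == "bilateral":
                continue
            mates = [
                r for r in self.regions
                if r.structure == region.structure and r.hemisphere not in ("bilateral", region.hemisphere)
            ]
            if len(mates) != 1:
                raise ValueError(
                    f"region {region.name!r} has {len(mates)} contralateral homologues; expected exactly 1"
                )

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    def __len__(self) -> int:
        return len(self.regions)

    def __getitem__(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)

    def homologue_pairs(self) -> list[tuple[str, str]]:
        """(left, right) name pairs for all unilateral structures."""
        pairs = []
        for r in self.regions:
            if r.hemisphere == "left":
                mate = next(
                    m for m in self.regions
                    if m.structure == r.structure and m.hemisphere == "right"
                )
                pairs.append((r.name, mate.name))
        return pairs


def default_scheme() -> ParcellationScheme:
    """The 27-measure lobar + subcortical + cerebellum scheme."""
    regions = []
    for structure in CORTICAL_STRUCTURES:
        for hemi, suffix in (("left", "l"), ("right", "r")):
            regions.append(Region(f"{structure}_{suffix}", hemi, "cortical", structure))
    for structure in SUBCORTICAL_STRUCTURES:
        for hemi, suffix in (("left", "l"), ("right", "r")):
            regions.append(Region(f"{structure}_{suffix}", hemi, "subcortical", structure))
    regions.append(Region("cerebellum", "bilateral", "cerebellar", "cerebellum"))
    return ParcellationScheme(tuple(regions))
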