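"""The unit of analysis: one seed in one view."""

from __future__ import annotations

from dataclasses import dataclass

from .geometry import Contour, ShapeDescriptors, compute_descriptors
from .silhouette_io import BinaryMask


@dataclass
class SeedRecord:
    """One seed x one view, with its silhouette and measurements."""

    seed_id: str
    species: str
    view: str
    group: str
    contour: Contour
    mask: BinaryMask | None = None
    descriptors: ShapeDescriptors | None = None

    def __post_init__(self):
        if self.descriptors is None:
            self.descriptors = compute_descriptors(self.contour)

    def as_row(self) -> dict:
        row = {
            "seed_id": self.seed_id,
            "species": self.species,
            "view": self.view,
            "group": self.group,
        }
        row.update(self.descriptors.as_dict())
        return row
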