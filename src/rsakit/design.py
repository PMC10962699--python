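"""The 48-stimulus design and the dummy-coded model RDMs used as RSA predictors.

The design crosses six object types (graspable food items, three kinds of
tools, manipulable non-tool objects, and animals) with a binary aspect-ratio
(elongation) factor, eight exemplars per type, four of each aspect ratio.
Two model RDMs are derived from it: an object-type model in which food items
are intermediate in similarity between artefacts and animals, and a binary
shape model driven purely by aspect ratio.  With the counterbalanced design
the two models are nearly orthogonal, so they can serve as separable
predictors in representational similarity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rdm import RDM

__all__ = [
    "OBJECT_TYPES",
    "SUPERCLASS",
    "Stimulus",
    "StimulusSet",
    "build_default_design",
    "make_type_model_rdm",
    "make_shape_model_rdm",
    "DEFAULT_TYPE_CODING",
]

OBJECT_TYPES = (
    "FoodItem",
    "FoodTool",
    "OtherTool",
    "SelfTool",
    "ManipulableObject",
    "Animal",
)

#: superclass used by the object-type model: food vs artefact vs animal
SUPERCLASS = {
    "FoodItem": "Food",
    "FoodTool": "Artefact",
    "OtherTool": "Artefact",
    "SelfTool": "Artefact",
    "ManipulableObject": "Artefact",
    "Animal": "Animal",
}

ASPECT_RATIOS = ("high", "low")

#: default dissimilarity levels of the intermediate-similarity type model:
#: same superclass 0, food vs artefact 1, animal vs anything else 2.  Spearman
#: comparisons are invariant to any order-preserving relabeling of the levels.
DEFAULT_TYPE_CODING = {
    frozenset({"Food"}): 0.0,
    frozenset({"Artefact"}): 0.0,
    frozenset({"Animal"}): 0.0,
    frozenset({"Food", "Artefact"}): 1.0,
    frozenset({"Food", "Animal"}): 2.0,
    frozenset({"Artefact", "Animal"}): 2.0,
}


@dataclass(frozen=True)
class Stimulus:
    stimulus_id: str
    object_type: str
    aspect_ratio: str
    display_label: str = ""

    def __post_init__(self) -> None:
        if self.object_type not in OBJECT_TYPES:
            raise ValueError(f"unknown object type {self.object_type!r}")
        if self.aspect_ratio not in ASPECT_RATIOS:
            raise ValueError(f"unknown aspect ratio {self.aspect_ratio!r}")


class StimulusSet:
    """An ordered collection of stimuli with type and aspect-ratio labels."""

    def __init__(self, stimuli: list[Stimulus]):
        ids = [s.stimulus_id for s in stimuli]
        if len(set(ids)) != len(ids):
            raise ValueError("stimulus_ids must be unique")
        self.stimuli = list(stimuli)

    def __len__(self) -> int:
        return len(self.stimuli)

    def __iter__(self):
        return iter(self.stimuli)

    def __getitem__(self, i: int) -> Stimulus:
        return self.stimuli[i]

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(s.stimulus_id for s in self.stimuli)

    @property
    def object_types(self) -> np.ndarray:
        return np.array([s.object_type for s in self.stimuli])

    @property
    def aspect_ratios(self) -> np.ndarray:
        return np.array([s.aspect_ratio for s in self.stimuli])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stimulus_id": self.ids,
                "object_type": self.object_types,
                "aspect_ratio": self.aspect_ratios,
                "display_label": [s.display_label for s in self.stimuli],
            }
        )

    @staticmethod
    def from_frame(df: pd.DataFrame) -> "StimulusSet":
        labels = (
            df["display_label"] if "display_label" in df else [""] * len(df)
        )
        return StimulusSet(
            [
                Stimulus(str(i), str(t), str(a), str(l))
                for i, t, a, l in zip(
                    df["stimulus_id"], df["object_type"], df["aspect_ratio"], labels
                )
            ]
        )


def build_default_design() -> StimulusSet:
    """The 48-stimulus design: 6 object types x 8 exemplars.

    Within each object type, exemplars 1-4 are high aspect ratio (elongated)
    and 5-8 are low (stubby).  Ordering is type-major, aspect-ratio-minor,
    which fixes a reproducible serialization of every matrix built from it.
    """
    stimuli = []
    for otype in OBJECT_TYPES:
        for k in range(8):
            ar = "high" if k < 4 else "low"
            sid = f"{otype}_{k + 1:02d}"
            stimuli.append(
                Stimulus(sid, otype, ar, display_label=f"{otype} exemplar {k + 1}")
            )
    return StimulusSet(stimuli)


def make_type_model_rdm(
    design: StimulusSet, coding: dict | None = None
) -> RDM:
    """Dummy-coded object-type model RDM over a stimulus design.

    Pair dissimilarity depends only on the superclass pair (food, artefact,
    animal).  The default coding places food intermediate between artefacts
    and animals: within-superclass 0, food-artefact 1, animal-anything 2.
    """
    coding = dict(DEFAULT_TYPE_CODING) if coding is None else dict(coding)
    supers = []
    for s in design:
        if s.object_type not in SUPERCLASS:
            raise ValueError(f"unknown object type {s.object_type!r} in design")
        supers.append(SUPERCLASS[s.object_type])
    n = len(design)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            key = frozenset({supers[i], supers[j]})
            if key not in coding:
                raise ValueError(f"coding missing level for pair {set(key)}")
            values[i, j] = values[j, i] = coding[key]
    return RDM(values, design.ids, source="model", distance_name="type-dummy")


def make_shape_model_rdm(design: StimulusSet) -> RDM:
    """Binary shape model RDM: 0 for same aspect ratio, 1 otherwise."""
    ar = design.aspect_ratios
    values = (ar[:, None] != ar[None, :]).astype(float)
    return RDM(values, design.ids, source="model", distance_name="shape-binary")
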