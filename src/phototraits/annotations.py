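"""High-level photograph features from content and face annotations.

These features sit at the level of human perception: what a photograph
is about (a content sub-category drawn from a large vision-API-style
taxonomy, recoded to 15 top categories) and who is in it (per-face
vectors giving the relative strength of eight emotions, summing to 1).
The annotation tables are the interface that replaces live computer
vision / emotion API calls, which are out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "TOP_CATEGORIES",
    "EMOTIONS",
    "FaceAnnotation",
    "PhotoAnnotation",
    "CategoryProfile",
    "FaceProfile",
    "recode_category",
    "category_profile",
    "gini_coefficient",
    "face_profile",
]

#: The 15 top-level content categories, in canonical (alphabetical-ish,
#: fixed) order used for all share vectors and output columns.
TOP_CATEGORIES = (
    "abstract", "animal", "building", "dark", "drink", "food", "indoor",
    "others", "outdoor", "people", "plant", "object", "sky", "text",
    "transportation",
)

#: The eight facial emotions, each face's strengths summing to 1.
EMOTIONS = (
    "anger", "contempt", "disgust", "fear", "happiness", "neutral",
    "sadness", "surprise",
)

#: Default aliases for sub-category prefixes that abbreviate their top
#: category (editable; unknown prefixes fall back to "others").
DEFAULT_ALIASES: dict[str, str] = {
    "trans": "transportation",
    "abs": "abstract",
    "obj": "object",
    "veh": "transportation",
}


@dataclass(frozen=True)
class FaceAnnotation:
    """Relative strengths of the eight emotions on one detected face."""

    emotion: tuple[float, ...]

    def __post_init__(self):
        e = np.asarray(self.emotion, dtype=float)
        if e.shape != (8,):
            raise ValueError("emotion vector must have 8 entries")
        if (e < 0).any() or (e > 1).any() or abs(e.sum() - 1.0) > 1e-6:
            raise ValueError("emotion strengths must be in [0,1] and sum to 1")


@dataclass(frozen=True)
class PhotoAnnotation:
    """Content sub-category of a photo plus its detected faces."""

    subcategory: str
    faces: tuple[FaceAnnotation, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if not self.subcategory:
            raise ValueError("subcategory must be a non-empty label")


@dataclass(frozen=True)
class CategoryProfile:
    """A user's distribution over the 15 categories and its Gini."""

    share: tuple[float, ...]
    gini: float


@dataclass(frozen=True)
class FaceProfile:
    """Per-user face statistics; emotion_mean is None when no faces exist."""

    avg_n_faces: float
    one_faced_share: float
    emotion_mean: tuple[float, ...] | None


def recode_category(
    subcategory: str,
    mapping: Mapping[str, str] | None = None,
    aliases: Mapping[str, str] | None = None,
) -> str:
    """Recode a taxonomy sub-category label into one of the 15 top
    categories.

    Resolution order: an explicit ``mapping`` entry for the full label;
    otherwise the token before the first underscore, resolved through
    ``aliases`` (e.g. ``trans_car`` → transportation); labels that still
    do not name a top category fall back to ``"others"``.
    """
    if mapping and subcategory in mapping:
        return mapping[subcategory]
    prefix = subcategory.split("_", 1)[0].lower()
    aliases = DEFAULT_ALIASES if aliases is None else aliases
    prefix = aliases.get(prefix, prefix)
    return prefix if prefix in TOP_CATEGORIES else "others"


def gini_coefficient(x: Sequence[float]) -> float:
    """Gini coefficient of a nonnegative vector.

    G = Σᵢⱼ |xᵢ − xⱼ| / (2 n Σₖ xₖ) — the normalised mean absolute
    difference.  0 for a perfectly even vector, 1 − 1/n for a point
    mass; scale invariant.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("x must be a non-empty 1-D vector")
    if (x < 0).any():
        raise ValueError("x must be nonnegative")
    total = x.sum()
    if total <= 0:
        raise ValueError("x must have positive total mass")
    # O(n log n) via the sorted-rank identity, equal to the pairwise sum
    xs = np.sort(x)
    n = x.size
    ranks = np.arange(1, n + 1)
    g = float(((2 * ranks - n - 1) * xs).sum() / (n * total))
    return max(g, 0.0)  # guard float round-off on near-uniform vectors


def category_profile(
    photos: Iterable[PhotoAnnotation | str],
    mapping: Mapping[str, str] | None = None,
) -> CategoryProfile:
    """Share of each top category among a user's photos, plus the Gini
    coefficient of that distribution.

    ``photos`` may be annotations or bare sub-category labels.
    """
    labels = [
        p.subcategory if isinstance(p, PhotoAnnotation) else str(p) for p in photos
    ]
    if not labels:
        raise ValueError("need at least one annotated photo")
    counts = dict.fromkeys(TOP_CATEGORIES, 0)
    for lab in labels:
        counts[recode_category(lab, mapping)] += 1
    share = np.array([counts[c] for c in TOP_CATEGORIES], dtype=float) / len(labels)
    return CategoryProfile(share=tuple(share.tolist()), gini=gini_coefficient(share))


def face_profile(photos: Iterable[PhotoAnnotation]) -> FaceProfile:
    """Per-user face statistics.

    avg_n_faces = total faces / photos; one_faced_share = share of photos
    with exactly one face (the selfie proxy); emotion_mean pools every
    face across every photo (faces weigh equally, not photos) and is
    None for users with no detected faces.
    """
    photos = list(photos)
    if not photos:
        raise ValueError("need at least one photo")
    n_faces = [len(p.faces) for p in photos]
    all_faces = [np.asarray(f.emotion, float) for p in photos for f in p.faces]
    if all_faces:
        emotion_mean = tuple(np.mean(all_faces, axis=0).tolist())
    else:
        emotion_mean = None
    return FaceProfile(
        avg_n_faces=float(np.sum(n_faces)) / len(photos),
        one_faced_share=sum(1 for k in n_faces if k == 1) / len(photos),
        emotion_mean=emotion_mean,
    )
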