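"""Per-user feature assembly.

Joins the per-photo pixel features, content annotations and face
annotations into one row per user, applying the study inclusion rule
(users with fewer than ``min_photos`` uploads are dropped).  Real photo
crawls are ragged, so a photo missing its annotation row still counts
toward the pixel averages and vice versa; each feature family uses its
own photo denominator.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .annotations import EMOTIONS, TOP_CATEGORIES, category_profile
from .imaging import PIXEL_FEATURE_COLUMNS

__all__ = ["USER_FEATURE_COLUMNS", "build_user_features"]

log = logging.getLogger(__name__)

#: Stable output column order: user_id, photo count, category shares +
#: gini, face statistics, emotion means, averaged pixel features (45).
USER_FEATURE_COLUMNS = (
    ("user_id", "n_photos")
    + TOP_CATEGORIES
    + ("gini", "avg_n_faces", "one_faced_share")
    + EMOTIONS
    + PIXEL_FEATURE_COLUMNS
)


def build_user_features(
    manifest: pd.DataFrame,
    pixel_features: pd.DataFrame,
    annotations: pd.DataFrame,
    faces: pd.DataFrame,
    min_photos: int = 30,
) -> pd.DataFrame:
    """Build the per-user feature table.

    Parameters
    ----------
    manifest : DataFrame with columns user_id, photo_id (one row per photo).
    pixel_features : DataFrame with user_id, photo_id and the 17 pixel
        feature columns.
    annotations : DataFrame with user_id, photo_id, subcategory.
    faces : DataFrame with user_id, photo_id, face_id and the eight
        emotion columns (one row per detected face; photos with no faces
        simply have no rows).
    min_photos : inclusion threshold on the manifest photo count.

    Returns one row per retained user with :data:`USER_FEATURE_COLUMNS`;
    emotion means are NaN for users with zero detected faces.
    """
    manifest = manifest.copy()
    n_photos = manifest.groupby("user_id").size()
    keep = n_photos[n_photos >= min_photos].index
    dropped = n_photos.index.difference(keep)
    if len(dropped):
        log.warning(
            "dropping %d user(s) below min_photos=%d", len(dropped), min_photos
        )
    known = set(manifest["photo_id"])
    for name, tab in (("pixel_features", pixel_features),
                      ("annotations", annotations), ("faces", faces)):
        orphans = set(tab["photo_id"]) - known
        if orphans:
            log.warning("%s: %d photo id(s) not in manifest", name, len(orphans))

    rows = []
    ann_by_user = dict(tuple(annotations.groupby("user_id")))
    pix_by_user = dict(tuple(pixel_features.groupby("user_id")))
    face_by_user = dict(tuple(faces.groupby("user_id")))
    for user in sorted(keep):
        row: dict[str, object] = {"user_id": user, "n_photos": int(n_photos[user])}

        ann = ann_by_user.get(user)
        if ann is not None and len(ann):
            prof = category_profile(ann["subcategory"].tolist())
            row.update(dict(zip(TOP_CATEGORIES, prof.share)))
            row["gini"] = prof.gini
            n_ann = len(ann)
            f = face_by_user.get(user)
            if f is not None and len(f):
                per_photo = f.groupby("photo_id").size()
                counts = per_photo.reindex(ann["photo_id"], fill_value=0)
                row["avg_n_faces"] = float(counts.sum()) / n_ann
                row["one_faced_share"] = float((counts == 1).sum()) / n_ann
                row.update(f[list(EMOTIONS)].mean().to_dict())
            else:
                row["avg_n_faces"] = 0.0
                row["one_faced_share"] = 0.0
                row.update(dict.fromkeys(EMOTIONS, np.nan))
        else:
            log.warning("user %s has no annotations; category/face features NaN",
                        user)
            row.update(dict.fromkeys(TOP_CATEGORIES + ("gini", "avg_n_faces",
                                                       "one_faced_share"), np.nan))
            row.update(dict.fromkeys(EMOTIONS, np.nan))

        pix = pix_by_user.get(user)
        if pix is not None and len(pix):
            row.update(pix[list(PIXEL_FEATURE_COLUMNS)].mean().to_dict())
        else:
            log.warning("user %s has no pixel features", user)
            row.update(dict.fromkeys(PIXEL_FEATURE_COLUMNS, np.nan))
        rows.append(row)

    return pd.DataFrame(rows, columns=USER_FEATURE_COLUMNS)
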