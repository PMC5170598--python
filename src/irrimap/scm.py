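"""Spectral Correlation Mapper classification of NDVI temporal profiles.

Each crop class is represented by an end-member signature: the
composite-wise mean NDVI profile of its training samples.  Every masked
pixel is scored against every signature with the Spectral Correlation
Mapper (SCM) — the Pearson correlation between the two T-dimensional
temporal vectors, i.e. the Spectral Angle Mapper cosine after centering
both vectors on their means.  Centering is what lets SCM tell apart
positively and negatively correlated profiles, which SAM (absolute
angles only) cannot; a pixel is assigned to its best-scoring class, and
never on a non-positive best score.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .phenology import TrainingSample
from .raster import CategoricalMap, GridSpec, NdviStack

__all__ = [
    "ConstantVectorError",
    "EndMemberSignature",
    "CropClassMap",
    "scm_score",
    "sam_angle",
    "build_signatures",
    "classify_pixels",
    "UNCLASSIFIED",
]

#: Reserved class code for pixels with no acceptable match.
UNCLASSIFIED = 0


class ConstantVectorError(ValueError):
    """SCM is undefined for a constant vector (zero variance)."""


@dataclass
class EndMemberSignature:
    class_id: int
    crop_name: str
    reference: np.ndarray
    n_members: int

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float)
        if self.reference.ndim != 1 or self.reference.size < 2:
            raise ValueError("reference profile must be 1-D with T >= 2")
        if np.ptp(self.reference) == 0:
            raise ConstantVectorError(f"signature {self.crop_name!r} is constant")


@dataclass
class CropClassMap:
    """Per-pixel crop class (0 = unclassified) and best SCM score."""

    class_map: CategoricalMap
    score: np.ndarray
    signatures: list[EndMemberSignature]

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=np.float32)
        if self.score.shape != self.class_map.grid.shape:
            raise ValueError("score shape does not match grid")

    @property
    def grid(self) -> GridSpec:
        return self.class_map.grid

    @property
    def codes(self) -> np.ndarray:
        return self.class_map.codes

    def legend(self) -> dict[int, str]:
        return {s.class_id: s.crop_name for s in self.signatures}


def scm_score(x: Sequence[float], r: Sequence[float]) -> float:
    """Spectral Correlation Mapper similarity in [-1, 1].

    The centered, normalised inner product of the two temporal vectors
    (the Pearson correlation coefficient).  Either vector being
    constant leaves the score undefined.
    """
    x = np.asarray(x, dtype=float)
    r = np.asarray(r, dtype=float)
    if x.shape != r.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("vectors must be 1-D of equal length T >= 2")
    xc = x - x.mean()
    rc = r - r.mean()
    nx, nr = np.linalg.norm(xc), np.linalg.norm(rc)
    if nx == 0 or nr == 0:
        raise ConstantVectorError("SCM undefined for a constant vector")
    return float(np.clip(xc @ rc / (nx * nr), -1.0, 1.0))


def sam_angle(x: Sequence[float], r: Sequence[float]) -> float:
    """Spectral Angle Mapper angle in radians, [0, pi].

    arccos of the *uncentered* normalised inner product; kept for
    comparison with SCM — it cannot separate negatively correlated
    profiles from positively correlated ones.
    """
    x = np.asarray(x, dtype=float)
    r = np.asarray(r, dtype=float)
    if x.shape != r.shape or x.ndim != 1:
        raise ValueError("vectors must be 1-D of equal length")
    nx, nr = np.linalg.norm(x), np.linalg.norm(r)
    if nx == 0 or nr == 0:
        raise ValueError("SAM undefined for a zero vector")
    return float(np.arccos(np.clip(x @ r / (nx * nr), -1.0, 1.0)))


def build_signatures(
    samples: Sequence[TrainingSample], min_members: int = 3
) -> tuple[list[EndMemberSignature], dict]:
    """Mean member profile per crop; crops below min_members are dropped.

    Class ids are assigned 1, 2, ... in alphabetical crop order (0 is
    reserved for unclassified).  Returns the signatures and a report of
    member counts and dropped crops.
    """
    by_crop: dict[str, list[np.ndarray]] = {}
    for s in samples:
        by_crop.setdefault(s.crop_name, []).append(np.asarray(s.profile, dtype=float))
    report = {"n_members": {c: len(p) for c, p in by_crop.items()}, "dropped": []}
    signatures = []
    class_id = 0
    for crop in sorted(by_crop):
        profiles = by_crop[crop]
        if len(profiles) < min_members:
            report["dropped"].append(crop)
            continue
        class_id += 1
        signatures.append(
            EndMemberSignature(class_id, crop, np.mean(profiles, axis=0), len(profiles))
        )
    if not signatures:
        raise ValueError("no crop reached the minimum member count")
    return signatures, report


def signatures_to_frame(signatures: Sequence[EndMemberSignature]) -> pd.DataFrame:
    rows = []
    for s in signatures:
        row = {"class_id": s.class_id, "crop_name": s.crop_name, "n_members": s.n_members}
        row.update({f"t{i:02d}": v for i, v in enumerate(s.reference)})
        rows.append(row)
    return pd.DataFrame(rows)


def signatures_from_frame(df: pd.DataFrame) -> list[EndMemberSignature]:
    tcols = sorted(c for c in df.columns if c.startswith("t") and c[1:].isdigit())
    return [
        EndMemberSignature(
            int(r["class_id"]), str(r["crop_name"]),
            r[tcols].to_numpy(dtype=float), int(r["n_members"]),
        )
        for _, r in df.iterrows()
    ]


def classify_pixels(
    ndvic: NdviStack,
    signatures: Sequence[EndMemberSignature],
    mask: np.ndarray | None = None,
    min_score: float = 0.5,
) -> CropClassMap:
    """Assign every masked pixel to its best-SCM-scoring crop class.

    A pixel is assigned the signature maximising the SCM score, with
    ties broken toward the lowest class id.  Assignment never happens
    on a non-positive best score (negative correlation is excluded) nor
    below ``min_score``; such pixels, constant profiles, and profiles
    with nodata keep the reserved unclassified code 0.
    """
    if not signatures:
        raise ValueError("no signatures supplied")
    sigs = sorted(signatures, key=lambda s: s.class_id)
    T, H, W = ndvic.values.shape
    if mask is None:
        mask = np.ones((H, W), dtype=bool)
    codes = np.full((H, W), UNCLASSIFIED, dtype=np.int32)
    scores = np.full((H, W), np.nan, dtype=np.float32)

    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        cmap = CategoricalMap(ndvic.grid, codes, {s.class_id: s.crop_name for s in sigs}, UNCLASSIFIED)
        return CropClassMap(cmap, scores, list(sigs))

    X = ndvic.values[:, rows, cols].T.astype(float)  # (N, T)
    valid = np.all(np.isfinite(X) & (X != ndvic.grid.nodata), axis=1)
    Xc = X - X.mean(axis=1, keepdims=True)
    xnorm = np.linalg.norm(Xc, axis=1)
    valid &= xnorm > 0

    R = np.stack([s.reference for s in sigs])  # (K, T)
    Rc = R - R.mean(axis=1, keepdims=True)
    Rc /= np.linalg.norm(Rc, axis=1, keepdims=True)

    S = np.zeros((X.shape[0], len(sigs)))
    vi = np.nonzero(valid)[0]
    S[vi] = (Xc[vi] / xnorm[vi, None]) @ Rc.T
    best_k = np.argmax(S, axis=1)  # first max -> lowest class_id on ties
    best_score = S[np.arange(S.shape[0]), best_k]
    assigned = valid & (best_score > 0) & (best_score >= min_score)

    class_ids = np.array([s.class_id for s in sigs])
    codes[rows[assigned], cols[assigned]] = class_ids[best_k[assigned]]
    scores[rows[valid], cols[valid]] = best_score[valid]

    cmap = CategoricalMap(ndvic.grid, codes, {s.class_id: s.crop_name for s in sigs}, UNCLASSIFIED)
    return CropClassMap(cmap, scores, list(sigs))
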