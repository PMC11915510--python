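"""Nucleus label masks: a classical fallback segmenter plus external-mask ingestion.

The pipelines only require *some* nucleus labelling backend.  Trained
pixel-classifier models (Cellpose, Ilastik) are routinely used on real data;
this module provides a deterministic classical pipeline
(smooth -> Otsu -> fill -> distance-watershed split) behind the same contract,
and an ingestion path for externally produced integer-label TIFFs so users can
substitute their own models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
import tifffile
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .errors import ContractError, FormatError

#: default minimum object size, pixels (2D) / voxels (3D)
MIN_AREA_2D = 200
MIN_AREA_3D = 2000

#: fraction of the per-object distance-transform maximum used to build
#: watershed markers; one marker blob per convex body, two for touching pairs
_MARKER_LEVEL = 0.6


@dataclass
class LabelMask:
    """Integer-labelled segmentation raster; 0 is background.

    Labels are consecutive positive integers after any post-processing that
    removes objects (``relabel``), except where a parent/child operation
    documents that original ids are preserved.
    """

    labels: np.ndarray
    provenance: str = "classical"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ContractError("label mask must have an integer dtype")
        if self.labels.ndim not in (2, 3):
            raise ContractError("label mask must be 2D or 3D")

    @property
    def n_objects(self) -> int:
        return int(len(np.unique(self.labels[self.labels > 0])))

    @property
    def ids(self) -> np.ndarray:
        return np.unique(self.labels[self.labels > 0])


def relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    """Map the positive labels onto 1..N preserving their sorted order."""
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(np.unique(labels[labels > 0]), start=1):
        out[labels == old] = new
    return out


def _connectivity(ndim: int) -> np.ndarray:
    # 4-connected in 2D, 6-connected in 3D
    return ndi.generate_binary_structure(ndim, 1)


def segment_nuclei(
    dye_img: np.ndarray,
    min_area: int | None = None,
    smooth_sigma: float = 2.0,
) -> LabelMask:
    """Classical nucleus segmentation of a nuclear-dye channel (2D or 3D).

    Steps: normalize -> Gaussian smooth -> Otsu threshold -> fill holes ->
    distance-transform watershed to split touching objects -> drop objects
    below ``min_area`` -> relabel consecutively.  Operating on the normalized
    image makes the label result invariant to global intensity rescaling.
    """
    dye_img = np.asarray(dye_img, dtype=float)
    if dye_img.ndim not in (2, 3):
        raise ContractError("dye image must be 2D or 3D")
    if min_area is None:
        min_area = MIN_AREA_2D if dye_img.ndim == 2 else MIN_AREA_3D

    ptp = dye_img.max() - dye_img.min()
    if ptp == 0:
        warnings.warn("uniform dye image: empty nucleus mask", stacklevel=2)
        return LabelMask(np.zeros(dye_img.shape, dtype=np.int32))

    norm = (dye_img - dye_img.min()) / ptp
    smooth = ndi.gaussian_filter(norm, smooth_sigma)
    binary = smooth > threshold_otsu(smooth)
    binary = ndi.binary_fill_holes(binary)
    if not binary.any():
        warnings.warn("no foreground after thresholding", stacklevel=2)
        return LabelMask(np.zeros(dye_img.shape, dtype=np.int32))

    conn = _connectivity(dye_img.ndim)
    dist = ndi.distance_transform_edt(binary)
    comp, n_comp = ndi.label(binary, structure=conn)
    # markers: core of each component where the distance transform is near its
    # per-component maximum; touching convex bodies contribute one core each
    maxd = ndi.maximum(dist, labels=comp, index=np.arange(1, n_comp + 1))
    core = np.zeros(binary.shape, dtype=bool)
    for idx in range(1, n_comp + 1):
        core |= (comp == idx) & (dist > _MARKER_LEVEL * maxd[idx - 1])
    markers, _ = ndi.label(core, structure=conn)
    labels = watershed(-dist, markers, mask=binary, connectivity=conn)

    sizes = np.bincount(labels.ravel())
    small = np.flatnonzero(sizes < min_area)
    labels[np.isin(labels, small[small > 0])] = 0
    labels = relabel_consecutive(labels)
    if labels.max() == 0:
        warnings.warn("all objects below min_area: empty mask", stacklevel=2)
    return LabelMask(labels, provenance="classical")


def load_external_labels(path, expect_shape: tuple[int, ...] | None = None) -> LabelMask:
    """Ingest an externally produced integer-label TIFF (e.g. Cellpose export).

    Labels are renumbered consecutively while preserving geometry; provenance
    is recorded as ``external``.
    """
    try:
        arr = tifffile.imread(str(path))
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot read label mask {path}: {exc}") from exc
    if np.issubdtype(arr.dtype, np.floating):
        if not np.all(np.mod(arr, 1) == 0):
            raise FormatError(f"{path} contains non-integer label values")
        arr = arr.astype(np.int64)
    elif not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"{path} has non-numeric dtype {arr.dtype}")
    if np.any(arr < 0):
        raise FormatError(f"{path} contains negative labels")
    if expect_shape is not None and tuple(arr.shape) != tuple(expect_shape):
        raise FormatError(
            f"label mask shape {arr.shape} does not match expected {tuple(expect_shape)}"
        )
    return LabelMask(relabel_consecutive(arr), provenance="external")


def nucleoplasm_mask(nuclei: LabelMask, subregions: LabelMask) -> LabelMask:
    """Nucleus pixels not covered by any subregion, keeping per-nucleus labels.

    Together with ``subregions ∩ nuclei`` this partitions each nucleus
    pixelwise.  Subregion pixels outside every nucleus are ignored.  Nuclei
    fully covered by subregions end up with an empty nucleoplasm and are
    flagged with a warning.  Original nucleus ids are retained (this operation
    deliberately does not relabel, so ids stay aligned with the parent mask).
    """
    if nuclei.labels.shape != subregions.labels.shape:
        raise ContractError(
            f"shape mismatch: nuclei {nuclei.labels.shape} vs "
            f"subregions {subregions.labels.shape}"
        )
    out = nuclei.labels.copy()
    out[subregions.labels > 0] = 0
    lost = set(nuclei.ids.tolist()) - set(np.unique(out[out > 0]).tolist())
    if lost:
        warnings.warn(
            f"nuclei {sorted(lost)} have empty nucleoplasm (fully covered)",
            stacklevel=2,
        )
    return LabelMask(out, provenance=nuclei.provenance)
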