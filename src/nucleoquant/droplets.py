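"""In vitro phase-separation assay quantification.

Droplets are segmented from the protein (488) channel with an adaptive
local-mean (Bradley) threshold that tolerates inhomogeneous background: a
pixel is foreground when its intensity reaches ``k`` times the mean over the
surrounding ``neighbourhood`` window, with ``k = 2 * (1 - sensitivity)`` so
the default sensitivity of 0.4 demands 120% of the local mean.  Speckles are
then removed from foreground and background alike at the ``min_size`` scale.
The condensed fraction is the exact pixel-count ratio of droplet area to
image area; partition ratios divide each droplet's mean intensity by the mean
over the background pixels, using the protein-channel mask for both the
protein and the probe channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage import measure
from skimage.morphology import remove_small_holes, remove_small_objects

from .errors import ContractError
from .nuclei import LabelMask


@dataclass
class DropletParams:
    """Adaptive-threshold and cleanup parameters."""

    sensitivity: float = 0.4
    neighbourhood: int = 99
    min_size: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.sensitivity <= 1.0:
            raise ContractError("sensitivity must be in [0, 1]")
        if self.neighbourhood < 3 or self.neighbourhood % 2 == 0:
            raise ContractError("neighbourhood must be odd and >= 3")
        if self.min_size < 0:
            raise ContractError("min_size must be non-negative")

    @property
    def threshold_factor(self) -> float:
        return 2.0 * (1.0 - self.sensitivity)


@dataclass
class DropletTable:
    """Per-droplet measurements plus the per-field condensed fraction.

    ``droplets`` columns: droplet_id, area, protein_partition,
    probe_partition (NaN when no probe channel was supplied).
    """

    droplets: pd.DataFrame
    condensed_fraction: float
    params: DropletParams


def segment_droplets(
    protein_img: np.ndarray,
    params: DropletParams | None = None,
) -> tuple[np.ndarray, LabelMask]:
    """Adaptive-mean binarization of the protein channel, speckle-cleaned.

    Returns the binary droplet mask and an 8-connected label image.  A
    uniform image produces no droplets (no pixel exceeds ``k`` times the local
    mean for ``k > 1``).
    """
    if params is None:
        params = DropletParams()
    img = np.asarray(protein_img, dtype=float)
    if img.ndim != 2:
        raise ContractError("protein image must be 2D")
    if min(img.shape) < params.neighbourhood:
        raise ContractError(
            f"image {img.shape} smaller than neighbourhood {params.neighbourhood}"
        )
    local_mean = ndi.uniform_filter(img, size=params.neighbourhood, mode="mirror")
    mask = img >= params.threshold_factor * local_mean
    if params.threshold_factor <= 1.0 and mask.all():
        # sensitivity >= 0.5 accepts a perfectly uniform image wholesale;
        # treat that as no droplets rather than one field-sized droplet
        mask = np.zeros_like(mask)
    if params.min_size > 1:
        # drop components / fill holes strictly smaller than min_size
        mask = remove_small_objects(mask, max_size=params.min_size - 1, connectivity=2)
        mask = remove_small_holes(mask, max_size=params.min_size - 1, connectivity=2)
    labels = measure.label(mask, connectivity=2).astype(np.int32)
    return mask, LabelMask(labels)


def condensed_fraction(mask: np.ndarray) -> float:
    """Droplet pixels over total pixels — an exact count ratio in [0, 1]."""
    mask = np.asarray(mask, dtype=bool)
    return float(mask.sum() / mask.size)


def partition_ratio(
    channel_img: np.ndarray,
    droplet_labels: LabelMask,
) -> pd.DataFrame:
    """Per-droplet mean intensity divided by the field background mean.

    The background is every pixel not inside any droplet, computed once per
    field, so the ratio is invariant under multiplying the channel by any
    positive constant.  For a probe channel, pass the label mask derived from
    the protein channel.
    """
    img = np.asarray(channel_img, dtype=float)
    if img.shape != droplet_labels.labels.shape:
        raise ContractError("channel and label shapes differ")
    background = img[droplet_labels.labels == 0]
    if background.size == 0:
        raise ContractError("no background pixels")
    bg_mean = float(background.mean())
    if bg_mean == 0:
        raise ContractError("zero background mean")
    rows = []
    for region in measure.regionprops(droplet_labels.labels, intensity_image=img):
        rows.append(
            {
                "droplet_id": int(region.label),
                "area": int(region.area),
                "ratio": float(region.intensity_mean / bg_mean),
            }
        )
    return pd.DataFrame(rows, columns=["droplet_id", "area", "ratio"])


def analyze_droplet_field(
    protein_img: np.ndarray,
    probe_img: np.ndarray | None = None,
    params: DropletParams | None = None,
) -> DropletTable:
    """Full per-field analysis: segmentation, condensed fraction, partitions."""
    if params is None:
        params = DropletParams()
    mask, labels = segment_droplets(protein_img, params)
    cf = condensed_fraction(mask)
    prot = partition_ratio(protein_img, labels) if labels.n_objects else pd.DataFrame(
        columns=["droplet_id", "area", "ratio"]
    )
    table = prot.rename(columns={"ratio": "protein_partition"})
    if probe_img is not None and labels.n_objects:
        probe = partition_ratio(probe_img, labels)
        table["probe_partition"] = probe["ratio"].to_numpy()
    else:
        table["probe_partition"] = np.nan
    return DropletTable(droplets=table, condensed_fraction=cf, params=params)


def normalize_condensed_fractions(values) -> np.ndarray:
    """Presentation-only normalization: divide by the within-experiment maximum.

    Raw condensed fractions are the authoritative quantity; this helper only
    mirrors the common display convention for dose series.
    """
    arr = np.asarray(values, dtype=float)
    top = np.nanmax(arr) if arr.size else np.nan
    if not np.isfinite(top) or top == 0:
        raise ContractError("cannot normalize: empty or all-zero series")
    return arr / top
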