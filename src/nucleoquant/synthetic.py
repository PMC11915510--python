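"""Ground-truthed synthetic microscopy scenes for every pipeline in the package.

Each generator paints geometric objects (elliptical nuclei, nested nucleolar
substructures, droplet disks) into float rasters, adds Gaussian read noise
(optionally Poisson shot noise) and returns the image together with a
:class:`SceneTruth` whose expected metrics are computable in closed form from
the object parameters alone.  All randomness flows from an explicit seed
through one ``numpy`` generator, so scenes are byte-identical across calls.

Geometry is in 0-based pixel coordinates, y-down raster convention.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .errors import ContractError, PlacementError
from .io import ImageStack

# -- study-condition defaults -------------------------------------------------
#: nucleolar enrichment of the tracked protein (~40% above nucleoplasm)
DEFAULT_R0 = 1.4
#: live-cell frame interval, minutes
FRAME_INTERVAL_MIN = 5.0
#: read-noise sigma for the focus channel, a.u.
FOCI_NOISE_SIGMA = 10.0


@dataclass
class SceneTruth:
    """Ground truth for one synthetic scene.

    ``expected_metrics`` are closed-form functions of ``object_params`` (true
    counts, fractions, ratios, onset frames); nothing in them depends on the
    rendered pixels.
    """

    object_params: dict
    expected_metrics: dict
    seed: int
    noise_model: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(f"not JSON serializable: {type(o)}")

        return json.dumps(
            {
                "object_params": self.object_params,
                "expected_metrics": self.expected_metrics,
                "seed": self.seed,
                "noise_model": self.noise_model,
            },
            default=_default,
            indent=2,
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())


# -- geometry helpers ---------------------------------------------------------


def _grid_layout(n: int, shape: tuple[int, int]) -> list[tuple[float, float, float, float]]:
    """Cell centers and half-sizes of a jitter-free grid covering ``shape``."""
    h, w = shape
    n_cols = max(1, int(math.ceil(math.sqrt(n * w / h))))
    n_rows = int(math.ceil(n / n_cols))
    ch, cw = h / n_rows, w / n_cols
    cells = []
    for i in range(n):
        r, c = divmod(i, n_cols)
        cells.append(((r + 0.5) * ch, (c + 0.5) * cw, ch / 2, cw / 2))
    return cells


def _ellipse_mask(shape, cy, cx, ry, rx, angle=0.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    y, x = yy - cy, xx - cx
    ca, sa = math.cos(angle), math.sin(angle)
    u = (ca * x + sa * y) / rx
    v = (-sa * x + ca * y) / ry
    return u * u + v * v <= 1.0


def _ellipsoid_mask(shape, cz, cy, cx, rz, ry, rx):
    zz, yy, xx = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
    return (
        ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
    ) <= 1.0


def _add_gaussian_spot(img, cy, cx, sigma, amplitude, cutoff=5.0):
    """Additively paint an isotropic 2D Gaussian, windowed at ``cutoff`` sigma."""
    h, w = img.shape
    r = int(math.ceil(cutoff * sigma))
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amplitude * np.exp(
        -((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2)
    )


def _add_gaussian_blob3d(img, c, sigmas, amplitude, cutoff=4.0):
    cz, cy, cx = c
    sz, sy, sx = sigmas
    d, h, w = img.shape
    rz, ry, rx = (int(math.ceil(cutoff * s)) for s in sigmas)
    z0, z1 = max(0, int(cz) - rz), min(d, int(cz) + rz + 1)
    y0, y1 = max(0, int(cy) - ry), min(h, int(cy) + ry + 1)
    x0, x1 = max(0, int(cx) - rx), min(w, int(cx) + rx + 1)
    zz, yy, xx = np.mgrid[z0:z1, y0:y1, x0:x1]
    img[z0:z1, y0:y1, x0:x1] += amplitude * np.exp(
        -(
            ((zz - cz) / sz) ** 2
            + ((yy - cy) / sy) ** 2
            + ((xx - cx) / sx) ** 2
        )
        / 2.0
    )


def _texture(rng, shape, sigma=8.0, strength=0.1):
    """Smooth multiplicative texture field around 1."""
    t = ndi.gaussian_filter(rng.normal(0.0, 1.0, shape), sigma)
    s = t.std()
    if s > 0:
        t = t / s * strength
    return 1.0 + t


def _apply_noise(rng, img, sigma, poisson=False):
    out = img.astype(float)
    if poisson:
        out = rng.poisson(np.clip(out, 0, None)).astype(float)
    if sigma > 0:
        out = out + rng.normal(0.0, sigma, img.shape)
    return out


# -- DNA-damage foci fields ---------------------------------------------------


def gen_foci_field(
    n_nuclei: int,
    foci_per_nucleus,
    spot_sigma: float = 3.0,
    snr: float = 10.0,
    shape: tuple[int, int] = (1024, 1024),
    seed: int = 0,
    noise_sigma: float = FOCI_NOISE_SIGMA,
    poisson: bool = False,
) -> tuple[ImageStack, SceneTruth]:
    """Nuclei with Gaussian foci at known counts and signal-to-noise ratio.

    ``snr`` is the spot amplitude divided by the read-noise sigma.  Foci are
    placed inside their nucleus with a 2-sigma margin and at least 6-sigma
    pairwise separation so each spot is a distinct object.  Channels:
    ``hoechst`` (nuclear dye) and ``foci``.
    """
    if n_nuclei < 0:
        raise ContractError("n_nuclei must be non-negative")
    counts = (
        [int(foci_per_nucleus)] * n_nuclei
        if np.isscalar(foci_per_nucleus)
        else [int(k) for k in foci_per_nucleus]
    )
    if len(counts) != n_nuclei:
        raise ContractError("foci_per_nucleus list length must equal n_nuclei")

    rng = np.random.default_rng(seed)
    cells = _grid_layout(n_nuclei, shape) if n_nuclei else []
    min_half = min((min(ch, cw) for _, _, ch, cw in cells), default=np.inf)
    if n_nuclei and min_half < max(12.0, 3.0 * spot_sigma + 6.0):
        raise PlacementError(
            f"shape {shape} too small to place {n_nuclei} nuclei with "
            f"spot_sigma={spot_sigma}"
        )

    dye = np.zeros(shape)
    spots = np.zeros(shape)
    amplitude = snr * noise_sigma
    nuclei_params, foci_params = [], []
    for (cy0, cx0, ch, cw), k in zip(cells, counts):
        cy = cy0 + rng.uniform(-0.05, 0.05) * ch
        cx = cx0 + rng.uniform(-0.05, 0.05) * cw
        ry = rng.uniform(0.62, 0.78) * ch
        rx = rng.uniform(0.62, 0.78) * cw
        angle = rng.uniform(0, math.pi)
        mask = _ellipse_mask(shape, cy, cx, ry, rx, angle)
        dye[mask] = 200.0
        nuclei_params.append(
            {"center": [cy, cx], "radii": [ry, rx], "angle": angle}
        )
        # rejection-sample spot centers inside the eroded (rotated) ellipse
        centers: list[tuple[float, float]] = []
        margin_y, margin_x = ry - 2.5 * spot_sigma, rx - 2.5 * spot_sigma
        ca, sa = math.cos(angle), math.sin(angle)
        tries = 0
        while len(centers) < k:
            tries += 1
            if tries > 20000:
                raise PlacementError(
                    f"cannot place {k} foci inside nucleus of radii "
                    f"({ry:.0f}, {rx:.0f})"
                )
            t = rng.uniform(0, 2 * math.pi)
            rad = math.sqrt(rng.uniform(0, 1))
            u = rad * margin_x * math.cos(t)  # ellipse frame -> raster frame
            v = rad * margin_y * math.sin(t)
            py = cy + sa * u + ca * v
            px = cx + ca * u - sa * v
            if all(
                (py - qy) ** 2 + (px - qx) ** 2 >= (6 * spot_sigma) ** 2
                for qy, qx in centers
            ):
                centers.append((py, px))
        for py, px in centers:
            _add_gaussian_spot(spots, py, px, spot_sigma, amplitude)
        foci_params.append([[py, px] for py, px in centers])

    dye *= _texture(rng, shape)
    dye = _apply_noise(rng, dye + 10.0, 5.0)
    focus_channel = _apply_noise(rng, spots + 20.0, noise_sigma, poisson)

    stack = ImageStack.from_array(
        np.stack([dye, focus_channel]), "CYX", ["hoechst", "foci"]
    )
    truth = SceneTruth(
        object_params={
            "nuclei": nuclei_params,
            "foci_centers": foci_params,
            "spot_sigma": spot_sigma,
            "spot_amplitude": amplitude,
        },
        expected_metrics={
            "foci_count_per_nucleus": counts,
            "total_foci": int(sum(counts)),
        },
        seed=seed,
        noise_model={"gaussian_sigma": noise_sigma, "poisson": poisson, "snr": snr},
    )
    return stack, truth


# -- nucleolar FC/DFC + nascent-RNA fields ------------------------------------


def gen_fc_eu_field(
    n_cells: int,
    fc_per_cell: int = 3,
    eu_fc_level: float = 100.0,
    eu_nucleoplasm_level: float = 40.0,
    shape3d: tuple[int, int, int] = (12, 288, 384),
    seed: int = 0,
    noise_sigma: float = 2.0,
) -> tuple[ImageStack, SceneTruth]:
    """3D nuclei with nested DFC bodies, FC puncta and a programmable EU channel.

    Channels: ``hoechst`` (nuclear dye), ``ubf488`` (FC marker), ``fib647``
    (DFC marker), ``eu594`` (nascent RNA).  The EU channel is uniform at
    ``eu_nucleoplasm_level`` inside the nucleus and at ``eu_fc_level`` inside
    the true FC voxels, so the true per-cell FC mean equals ``eu_fc_level``.
    """
    if eu_fc_level < 0 or eu_nucleoplasm_level < 0:
        raise ContractError("EU levels must be non-negative")
    if fc_per_cell < 0:
        raise ContractError("fc_per_cell must be non-negative")
    nz, ny, nx = shape3d
    rng = np.random.default_rng(seed)
    cells = _grid_layout(n_cells, (ny, nx))
    min_half = min((min(ch, cw) for _, _, ch, cw in cells), default=np.inf)
    if n_cells and (min_half < 34 or nz < 9):
        raise PlacementError(f"shape3d {shape3d} too small for {n_cells} cells")

    hoechst = np.full(shape3d, 5.0)
    ubf = np.full(shape3d, 5.0)
    fib = np.full(shape3d, 5.0)
    eu = np.full(shape3d, 2.0)

    rz_nuc = min(4.0, (nz - 1) / 2.0 - 0.5)
    cz = (nz - 1) / 2.0
    fc_radii = (1.5, 2.5, 2.5)  # FC ellipsoid semi-axes (z, y, x)
    cell_params = []
    for cy0, cx0, ch, cw in cells:
        cy = cy0 + rng.uniform(-0.04, 0.04) * ch
        cx = cx0 + rng.uniform(-0.04, 0.04) * cw
        ry = rng.uniform(0.68, 0.8) * ch
        rx = rng.uniform(0.68, 0.8) * cw
        nuc = _ellipsoid_mask(shape3d, cz, cy, cx, rz_nuc, ry, rx)
        hoechst[nuc] = 120.0
        eu[nuc] = eu_nucleoplasm_level
        fib[nuc] = 20.0
        ubf[nuc] = 15.0
        # DFC: smaller co-centred ellipsoid, offset within the nucleus
        dfc_ry, dfc_rx = 0.48 * ry, 0.48 * rx
        dfc_rz = max(2.5, 0.75 * rz_nuc)
        off_y = rng.uniform(-0.25, 0.25) * ry
        off_x = rng.uniform(-0.25, 0.25) * rx
        dfc = _ellipsoid_mask(shape3d, cz, cy + off_y, cx + off_x, dfc_rz, dfc_ry, dfc_rx)
        dfc &= nuc
        fib[dfc] = 120.0
        # FC puncta in the DFC mid-plane, min 7 px in-plane separation; the
        # whole FC ellipsoid must sit strictly inside the DFC ellipsoid so
        # the painted EU support is never clipped (closed-form truth)
        # sufficient containment condition in DFC-normalized coordinates:
        # centre norm + worst-axis FC extent <= 1 keeps the whole FC ellipsoid
        # strictly inside the DFC ellipsoid
        fc_extent = max(
            fc_radii[0] / dfc_rz, fc_radii[1] / dfc_ry, fc_radii[2] / dfc_rx
        )
        max_u = 0.98 - fc_extent
        if max_u <= 0:
            raise PlacementError("DFC body too small to contain an FC")
        fc_sep = 6.5  # minimum in-plane centre separation, px
        fc_centers: list[tuple[float, float, float]] | None = None
        for _ in range(200):  # restart if a greedy placement dead-ends
            pts: list[tuple[float, float, float]] = []
            for _ in range(fc_per_cell):
                for _ in range(500):
                    t = rng.uniform(0, 2 * math.pi)
                    rad = math.sqrt(rng.uniform(0, 1)) * max_u
                    py = cy + off_y + rad * dfc_ry * math.sin(t)
                    px = cx + off_x + rad * dfc_rx * math.cos(t)
                    if all(
                        (py - q[1]) ** 2 + (px - q[2]) ** 2 >= fc_sep**2
                        for q in pts
                    ):
                        pts.append((cz, py, px))
                        break
                else:
                    break
            if len(pts) == fc_per_cell:
                fc_centers = pts
                break
        if fc_centers is None:
            raise PlacementError("cannot place FCs inside DFC body")
        # UBF marker and EU elevation share the same FC support, so the
        # marker-driven segmentation measures exactly the painted EU body
        fc_mask_cell = np.zeros(shape3d, dtype=bool)
        for c in fc_centers:
            fc_mask_cell |= _ellipsoid_mask(shape3d, *c, *fc_radii)
        fc_mask_cell &= dfc
        ubf[fc_mask_cell] += 150.0
        eu[fc_mask_cell] = eu_fc_level
        cell_params.append(
            {
                "center": [cz, cy, cx],
                "radii": [rz_nuc, ry, rx],
                "dfc_center": [cz, cy + off_y, cx + off_x],
                "dfc_radii": [dfc_rz, dfc_ry, dfc_rx],
                "fc_centers": [list(c) for c in fc_centers],
                "fc_radii": list(fc_radii),
            }
        )

    # light optical blur on the marker channels (they only drive segmentation);
    # the EU channel keeps its programmed levels exactly so the closed-form
    # truth (mean EU in FC voxels == eu_fc_level) holds by construction
    blur = 0.6
    chans = [
        _apply_noise(rng, ndi.gaussian_filter(hoechst, blur), noise_sigma),
        _apply_noise(rng, ndi.gaussian_filter(ubf, blur), noise_sigma),
        _apply_noise(rng, ndi.gaussian_filter(fib, blur), noise_sigma),
        _apply_noise(rng, eu, noise_sigma),
    ]
    stack = ImageStack.from_array(
        np.stack(chans, axis=1), "ZCYX", ["hoechst", "ubf488", "fib647", "eu594"]
    )
    truth = SceneTruth(
        object_params={"cells": cell_params},
        expected_metrics={
            "fc_per_cell": fc_per_cell,
            "mean_eu_in_fc": eu_fc_level,
            "eu_nucleoplasm_level": eu_nucleoplasm_level,
        },
        seed=seed,
        noise_model={"gaussian_sigma": noise_sigma},
    )
    return stack, truth


# -- live-cell depletion time-lapse -------------------------------------------


def depletion_ratio(frames: np.ndarray, r0: float, t0: float, tau: float) -> np.ndarray:
    """Programmed nucleolus/nucleoplasm ratio r(t) = 1 + (r0-1) exp(-(t-t0)/tau)."""
    frames = np.asarray(frames, dtype=float)
    r = np.full(frames.shape, float(r0))
    late = frames >= t0
    r[late] = 1.0 + (r0 - 1.0) * np.exp(-(frames[late] - t0) / tau)
    return r


def gen_timelapse(
    n_cells: int,
    n_frames: int,
    r0: float = DEFAULT_R0,
    t0: float = 36.0,
    tau: float = 10.0,
    group: str = "treated",
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    nucleoli_per_cell: int = 1,
    noise_sigma: float = 1.5,
    frame_interval_min: float = FRAME_INTERVAL_MIN,
) -> tuple[ImageStack, SceneTruth]:
    """Time-lapse where nucleolar signal redistributes to the nucleoplasm.

    Treated cells follow ``r(t) = 1 + (r0-1) exp(-(t-t0)/tau)`` for frames
    ``t >= t0`` and ``r0`` before; controls stay at ``r0``.  The total painted
    nuclear intensity is held exactly constant per frame (signal moves, it
    does not disappear).  Channels: ``gfp`` (fluorescence) and ``phase``
    (phase contrast; nucleoli rendered as dark disks on a brighter
    nucleoplasm).
    """
    if r0 < 1.0:
        raise ContractError("r0 must be >= 1 (nucleolar enrichment assumed)")
    if group not in ("control", "treated"):
        raise ContractError(f"unknown group {group!r}")
    if n_frames < 1:
        raise ContractError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    cells = _grid_layout(n_cells, shape)
    min_half = min((min(ch, cw) for _, _, ch, cw in cells), default=np.inf)
    if n_cells and min_half < 24:
        raise PlacementError(f"shape {shape} too small for {n_cells} cells")

    frames_idx = np.arange(n_frames)
    r_t = (
        np.full(n_frames, float(r0))
        if group == "control"
        else depletion_ratio(frames_idx, r0, t0, tau)
    )

    # static geometry; per-frame intensities follow r(t) with exact conservation
    nuc_masks, nol_masks, cell_params = [], [], []
    for cy0, cx0, chh, cww in cells:
        cy = cy0 + rng.uniform(-0.03, 0.03) * chh
        cx = cx0 + rng.uniform(-0.03, 0.03) * cww
        ry = rng.uniform(0.6, 0.72) * chh
        rx = rng.uniform(0.6, 0.72) * cww
        nuc = _ellipse_mask(shape, cy, cx, ry, rx)
        nols = np.zeros(shape, dtype=bool)
        nol_list = []
        for j in range(nucleoli_per_cell):
            nr = rng.uniform(0.26, 0.32) * min(ry, rx)
            t = 2 * math.pi * (j + rng.uniform(0.1, 0.4)) / max(nucleoli_per_cell, 1)
            ncy = cy + 0.45 * ry * math.sin(t)
            ncx = cx + 0.45 * rx * math.cos(t)
            nol = _ellipse_mask(shape, ncy, ncx, nr, nr)
            nols |= nol & nuc
            nol_list.append({"center": [ncy, ncx], "radius": nr})
        nuc_masks.append(nuc)
        nol_masks.append(nols & nuc)
        cell_params.append(
            {"center": [cy, cx], "radii": [ry, rx], "nucleoli": nol_list}
        )

    gfp = np.zeros((n_frames,) + shape)
    phase = np.zeros((n_frames,) + shape)
    base_np = 100.0
    for i, (nuc, nols) in enumerate(zip(nuc_masks, nol_masks)):
        a_nol = int(nols.sum())
        a_np = int(nuc.sum()) - a_nol
        total = base_np * (a_np + r0 * a_nol)  # conserved per frame
        for f in range(n_frames):
            i_np = total / (a_np + r_t[f] * a_nol)
            gfp[f][nuc] = i_np
            gfp[f][nols] = r_t[f] * i_np
        phase[:, nuc] = 150.0
        phase[:, nols] = 60.0
    phase[:, ~np.logical_or.reduce(nuc_masks) if nuc_masks else slice(None)] = 120.0

    gfp = _apply_noise(rng, gfp, noise_sigma)
    phase = _apply_noise(rng, phase, 3.0)
    stack = ImageStack.from_array(
        np.stack([gfp, phase], axis=1), "TCYX", ["gfp", "phase"]
    )
    truth = SceneTruth(
        object_params={"cells": cell_params, "base_nucleoplasm": base_np},
        expected_metrics={
            "r0": r0,
            "t0": t0 if group == "treated" else None,
            "tau": tau if group == "treated" else None,
            "ratio_per_frame": r_t.tolist(),
            "group": group,
            "frame_interval_min": frame_interval_min,
        },
        seed=seed,
        noise_model={"gaussian_sigma": noise_sigma},
    )
    return stack, truth


# -- in vitro droplet fields --------------------------------------------------


def gen_droplet_field(
    n_droplets: int,
    radius_range: tuple[float, float] = (8.0, 20.0),
    protein_enrichment: float = 5.0,
    probe_partition: float = 3.0,
    background: float = 50.0,
    shape: tuple[int, int] = (512, 512),
    seed: int = 0,
    noise_sigma: float = 0.0,
) -> tuple[ImageStack, SceneTruth]:
    """Two-channel droplet field with known enrichment and probe partitioning.

    Droplet interiors are ``background * enrichment`` in the protein channel
    and ``probe_background * probe_partition`` in the probe channel.  The true
    condensed fraction is the closed form sum of disk areas over the image
    area.  Channels: ``gfp488`` and ``cy647``.
    """
    if n_droplets < 0:
        raise ContractError("n_droplets must be non-negative")
    rmin, rmax = radius_range
    if rmin <= 0 or rmax < rmin:
        raise ContractError("invalid radius_range")
    h, w = shape
    if 2 * rmax + 4 > min(h, w):
        raise PlacementError(f"radius {rmax} does not fit in field {shape}")
    rng = np.random.default_rng(seed)

    disks: list[tuple[float, float, float]] = []
    tries = 0
    while len(disks) < n_droplets:
        tries += 1
        if tries > 20000 * max(n_droplets, 1):
            raise PlacementError(
                f"cannot place {n_droplets} non-overlapping droplets in {shape}"
            )
        r = rng.uniform(rmin, rmax)
        cy = rng.uniform(r + 2, h - r - 2)
        cx = rng.uniform(r + 2, w - r - 2)
        if all(
            (cy - qy) ** 2 + (cx - qx) ** 2 >= (r + qr + 3) ** 2
            for qy, qx, qr in disks
        ):
            disks.append((cy, cx, r))

    probe_bg = 30.0
    protein = np.full(shape, float(background))
    probe = np.full(shape, probe_bg)
    for cy, cx, r in disks:
        m = _ellipse_mask(shape, cy, cx, r, r)
        protein[m] = background * protein_enrichment
        probe[m] = probe_bg * probe_partition

    protein = _apply_noise(rng, protein, noise_sigma)
    probe = _apply_noise(rng, probe, noise_sigma)
    stack = ImageStack.from_array(
        np.stack([protein, probe]), "CYX", ["gfp488", "cy647"]
    )
    truth = SceneTruth(
        object_params={
            "disks": [{"center": [cy, cx], "radius": r} for cy, cx, r in disks],
            "background": background,
            "probe_background": probe_bg,
        },
        expected_metrics={
            "condensed_fraction": float(
                sum(math.pi * r**2 for _, _, r in disks) / (h * w)
            ),
            "protein_partition": float(protein_enrichment),
            "probe_partition": float(probe_partition),
        },
        seed=seed,
        noise_model={"gaussian_sigma": noise_sigma},
    )
    return stack, truth


# -- null ratio datasets for ANOVA validation ---------------------------------


def gen_null_ratio_dataset(
    n_cells: int,
    n_frames: int,
    noise_sd: float,
    n_reps: int,
    seed: int = 0,
    r0: float = DEFAULT_R0,
    frame_interval_min: float = FRAME_INTERVAL_MIN,
) -> list[pd.DataFrame]:
    """Replicated two-group ratio tables with no group effect.

    Both "groups" are drawn from the same constant-ratio process ``r0`` plus
    iid Gaussian noise, which makes the collection suitable for estimating the
    type-I error of the repeated-measures ANOVA stage.
    """
    if n_frames < 2:
        raise ContractError("n_frames must be >= 2")
    if n_cells < 2:
        raise ContractError("need >= 2 cells per group")
    if noise_sd < 0:
        raise ContractError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_reps):
        rows = []
        for grp in ("control", "treated"):
            for cell in range(n_cells):
                ratios = r0 + rng.normal(0.0, noise_sd, n_frames)
                for f in range(n_frames):
                    rows.append(
                        (cell, 0, f, f * frame_interval_min, ratios[f], grp)
                    )
        reps.append(
            pd.DataFrame(
                rows,
                columns=[
                    "cell_id",
                    "nucleolus_id",
                    "frame",
                    "time_min",
                    "ratio",
                    "group",
                ],
            )
        )
    return reps
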