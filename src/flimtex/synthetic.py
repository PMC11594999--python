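"""Synthetic single-cell FLIM lifetime matrices for three RBC phenotypes.

No patient data are deposited for the study conditions this package
emulates, so every downstream stage is exercised on generated cells:

* ``control`` — round cell, homogeneous cytoplasm, no foci;
* ``nonsickled`` — round SCD cell carrying 0-3 small high-lifetime dots;
* ``sickled`` — elongated/crescent cell with an irregular high-lifetime
  patch grown from the cell boundary (the polymerized-hemoglobin
  surrogate), plus dots.

Calibration contract: the per-cell ROI pixel mean equals the class mean
(default 175.5 / 193.9 / 253.3 ps) plus a per-cell jitter, and the ROI
pixel SD equals the class SD (30.2 / 28.1 / 58.6 ps) in expectation.  The
generator achieves this exactly by (i) standardising the noise field to
zero mean / unit SD over the ROI, (ii) subtracting the ROI mean of the
planted offsets from the base level, and (iii) assigning the offsets'
ROI variance a capped share of the variance budget and giving the rest to
pixel noise (offsets are rescaled if they would exceed the cap).

Texture: the real class contrast in LBP features comes from sub-resolution
changes in the hemoglobin matrix, which no generator can copy from the
study conditions alone.  It is emulated with two per-class texture knobs —
the spatial correlation length of the noise field (``texture_sigma_px``)
and the amplitude of an additive large-scale structure field
(``texture_wave_amp``) — each with per-cell log-normal jitter, so that the
class contrast is carried by the LBP summary features in a tunable,
two-dimensional way.

All randomness flows from one seed through ``numpy.random.SeedSequence``
substreams, one per patient and per cell, so cohorts are reproducible and
individual cells can be regenerated in isolation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io import CellRecord, ROIRect, manifest_frame, write_lifetime_matrix, write_manifest

__all__ = [
    "CLASSES",
    "GeneratorParams",
    "SyntheticCohort",
    "default_params",
    "generate_cell",
    "generate_cohort",
]

CLASSES = ("control", "nonsickled", "sickled")


def _class_map(value) -> dict:
    return dict(value)


@dataclass
class GeneratorParams:
    """Tunable parameters of the synthetic FLIM cell generator.

    Lifetime units are picoseconds throughout.  Class means/SDs are the
    per-cell ROI pixel statistics the generator is calibrated to.
    """

    cell_diameter_px: int = 60
    background_lifetime_ps: float = 400.0  # plasma; above all cytoplasm means
    class_means_ps: dict = field(
        default_factory=lambda: {"control": 175.5, "nonsickled": 193.9, "sickled": 253.3}
    )
    class_sds_ps: dict = field(
        default_factory=lambda: {"control": 30.2, "nonsickled": 28.1, "sickled": 58.6}
    )
    dot_count_range: tuple = (0, 3)
    dot_radius_px: float = 2.0
    dot_lifetime_offset_ps: float = 150.0
    patch_area_fraction: tuple = (0.10, 0.30)
    patch_lifetime_offset_ps: tuple = (80.0, 200.0)
    pixel_noise_model: str = "gaussian"  # or "shot-like"
    # texture knobs (see module docstring)
    texture_sigma_px: dict = field(
        default_factory=lambda: {"control": 0.70, "nonsickled": 0.78, "sickled": 0.90}
    )
    texture_wave_amp: dict = field(
        default_factory=lambda: {"control": 0.25, "nonsickled": 0.75, "sickled": 0.90}
    )
    texture_wave_sigma_px: float = 6.0
    texture_jitter: float = 0.15  # lognormal sigma on both texture knobs, per cell
    cell_mean_jitter_ps: float = 8.0  # between-cell SD of the ROI mean within a class
    patient_mean_sd_ps: float = 5.0  # between-patient random shift of the mean
    patient_texture_jitter: float = 0.05  # lognormal sigma on texture knobs, per patient
    offset_variance_cap: float = 0.8  # max share of the variance budget for offsets
    seed: int = 0

    def validate(self) -> "GeneratorParams":
        if self.cell_diameter_px < 20:
            raise ValueError("cell_diameter_px must be >= 20")
        for name in ("class_means_ps", "class_sds_ps", "texture_sigma_px", "texture_wave_amp"):
            m = getattr(self, name)
            missing = [c for c in CLASSES if c not in m]
            if missing:
                raise ValueError(f"{name} missing classes {missing}")
        if any(v <= 0 for v in self.class_means_ps.values()):
            raise ValueError("class means must be strictly positive")
        if any(v <= 0 for v in self.class_sds_ps.values()):
            raise ValueError("class SDs must be strictly positive")
        if self.background_lifetime_ps <= max(self.class_means_ps.values()):
            raise ValueError("background (plasma) lifetime must exceed all cytoplasm means")
        lo, hi = self.dot_count_range
        if not (0 <= lo <= hi):
            raise ValueError("dot_count_range must be a nonnegative ordered pair")
        if self.dot_radius_px <= 0 or self.dot_lifetime_offset_ps <= 0:
            raise ValueError("dot geometry parameters must be positive")
        flo, fhi = self.patch_area_fraction
        if not (0 < flo <= fhi < 1):
            raise ValueError("patch_area_fraction must lie in (0, 1), ordered")
        plo, phi = self.patch_lifetime_offset_ps
        if not (0 < plo <= phi):
            raise ValueError("patch_lifetime_offset_ps must be positive, ordered")
        if self.pixel_noise_model not in {"gaussian", "shot-like"}:
            raise ValueError(f"unknown pixel_noise_model {self.pixel_noise_model!r}")
        if not 0 < self.offset_variance_cap < 1:
            raise ValueError("offset_variance_cap must lie in (0, 1)")
        return self


def default_params() -> GeneratorParams:
    """The calibrated defaults (see module docstring); validated."""
    return GeneratorParams().validate()


@dataclass
class SyntheticCohort:
    cells: list  # list of (CellRecord, np.ndarray)
    manifest: "object"  # pandas DataFrame
    params: GeneratorParams


# ---------------------------------------------------------------------------
# geometry


def _round_footprint(size: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    cx = cy = (size - 1) / 2
    theta = np.arctan2(yy - cy, xx - cx)
    # mild low-order boundary irregularity so round cells are not perfect discs
    a1, a2 = rng.uniform(0.0, 0.03, size=2)
    p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
    r = radius * (1 + a1 * np.cos(2 * theta + p1) + a2 * np.cos(3 * theta + p2))
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2


def _sickled_footprint(size: int, diameter: int, rng: np.random.Generator) -> np.ndarray:
    """Bent thin ellipse (axis ratio >= 3) at a random orientation."""
    a = 0.55 * diameter  # long semi-axis
    b = a / rng.uniform(3.0, 4.0)  # thin
    k = rng.uniform(0.1, 0.25) * b / a**2  # curvature of the centerline
    phi = rng.uniform(0, np.pi)
    yy, xx = np.mgrid[0:size, 0:size]
    cx = cy = (size - 1) / 2
    x, y = xx - cx, yy - cy
    u = x * np.cos(phi) + y * np.sin(phi)
    v = -x * np.sin(phi) + y * np.cos(phi)
    v = v - k * u**2  # bend
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _inscribed_rect(mask: np.ndarray, min_side: int = 8) -> ROIRect:
    """A large axis-aligned rectangle strictly inside the footprint.

    Seeded at the deepest interior point, then greedily expanded one pixel
    per side while the rectangle stays inside the mask.
    """
    dt = ndimage.distance_transform_edt(mask)
    cy, cx = np.unravel_index(np.argmax(dt), dt.shape)
    r = max(int(dt[cy, cx] / np.sqrt(2)) - 1, 1)
    h, w = mask.shape
    x0, x1 = cx - r, cx + r + 1
    y0, y1 = cy - r, cy + r + 1

    def inside(x0, y0, x1, y1):
        return 0 <= x0 and 0 <= y0 and x1 <= w and y1 <= h and mask[y0:y1, x0:x1].all()

    while not inside(x0, y0, x1, y1) and (x1 - x0) > 2:
        x0 += 1
        x1 -= 1
        y0 += 1
        y1 -= 1
    grew = True
    while grew:
        grew = False
        for dx0, dy0, dx1, dy1 in ((-1, 0, 0, 0), (0, -1, 0, 0), (0, 0, 1, 0), (0, 0, 0, 1)):
            if inside(x0 + dx0, y0 + dy0, x1 + dx1, y1 + dy1):
                x0, y0, x1, y1 = x0 + dx0, y0 + dy0, x1 + dx1, y1 + dy1
                grew = True
    if (x1 - x0) < min_side or (y1 - y0) < min_side:
        raise ValueError(f"cell footprint too small for a {min_side}px ROI")
    return ROIRect(x0, y0, x1, y1)


def _place_dots(
    mask: np.ndarray, n: int, radius: float, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Dot centres inside the eroded footprint, non-overlapping."""
    if n == 0:
        return []
    erode_iters = int(np.ceil(radius)) + 1
    interior = ndimage.binary_erosion(mask, iterations=erode_iters)
    ys, xs = np.nonzero(interior)
    if ys.size == 0:
        return []
    centers: list[tuple[int, int]] = []
    min_sep2 = (2 * radius + 2) ** 2
    for _ in range(200):
        if len(centers) == n:
            break
        j = rng.integers(ys.size)
        cy, cx = int(ys[j]), int(xs[j])
        if all((cy - py) ** 2 + (cx - px) ** 2 >= min_sep2 for py, px in centers):
            centers.append((cy, cx))
    return centers


def _grow_patch(mask: np.ndarray, area: int, rng: np.random.Generator) -> np.ndarray:
    """Random blob grown from a boundary seed pixel, confined to the mask."""
    boundary = mask & ~ndimage.binary_erosion(mask)
    ys, xs = np.nonzero(boundary)
    j = rng.integers(ys.size)
    patch = np.zeros_like(mask)
    patch[ys[j], xs[j]] = True
    struct = ndimage.generate_binary_structure(2, 2)
    while patch.sum() < area:
        frontier = ndimage.binary_dilation(patch, structure=struct) & mask & ~patch
        fy, fx = np.nonzero(frontier)
        if fy.size == 0:
            break
        take = max(1, int(0.7 * fy.size))
        pick = rng.choice(fy.size, size=take, replace=False)
        patch[fy[pick], fx[pick]] = True
    return patch


# ---------------------------------------------------------------------------
# noise fields


def _smooth_unit_field(shape, sigma: float, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(shape)
    if sigma > 0.05:
        return ndimage.gaussian_filter(white, sigma)
    return white


def _standardize_over(field: np.ndarray, sel: np.ndarray) -> np.ndarray:
    mu = field[sel].mean()
    sd = field[sel].std()
    if sd == 0:
        raise RuntimeError("degenerate noise field")
    return (field - mu) / sd


# ---------------------------------------------------------------------------
# cell generation


def generate_cell(
    cell_class: str,
    params: GeneratorParams | None = None,
    seed=0,
    *,
    patient_mean_shift_ps: float = 0.0,
    patient_texture_factor: float = 1.0,
    return_mask: bool = False,
) -> tuple[np.ndarray, CellRecord]:
    """Generate one cell image and its record.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``.  The two
    keyword arguments let :func:`generate_cohort` impose shared
    patient-level effects; standalone calls leave them neutral.

    The record's ``extra`` dict logs the ground truth (planted dot count
    and centres, patch area, texture knobs, noise SD) used by tests and by
    the foci-detection validation.
    """
    if cell_class not in CLASSES:
        raise ValueError(f"unknown cell class {cell_class!r}; expected one of {CLASSES}")
    params = (params or default_params()).validate()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    D = params.cell_diameter_px
    margin = 8
    if cell_class == "sickled":
        size = int(np.ceil(2 * 0.55 * D)) + 2 * margin
        mask = _sickled_footprint(size, D, rng)
    else:
        size = D + 2 * margin
        mask = _round_footprint(size, D / 2, rng)
    roi = _inscribed_rect(mask)
    roi_sel = np.zeros_like(mask)
    roi_sel[roi.y0 : roi.y1, roi.x0 : roi.x1] = True

    # --- planted offsets -------------------------------------------------
    offsets = np.zeros(mask.shape)
    n_dots = 0
    dot_centers: list[tuple[int, int]] = []
    if cell_class in ("nonsickled", "sickled"):
        lo, hi = params.dot_count_range
        n_dots = int(rng.integers(lo, hi + 1))
        dot_centers = _place_dots(mask, n_dots, params.dot_radius_px, rng)
        n_dots = len(dot_centers)
        yy, xx = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
        for cy, cx in dot_centers:
            disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= params.dot_radius_px**2
            offsets[disc] += params.dot_lifetime_offset_ps

    patch_area = 0
    patch_offset = 0.0
    if cell_class == "sickled":
        flo, fhi = params.patch_area_fraction
        frac = rng.uniform(flo, fhi)
        patch = _grow_patch(mask, int(frac * mask.sum()), rng)
        plo, phi = params.patch_lifetime_offset_ps
        patch_offset = float(rng.uniform(plo, phi))
        offsets[patch] += patch_offset
        patch_area = int(patch.sum())

    # large-scale structure field, part of the offset budget
    sd_target = params.class_sds_ps[cell_class]
    amp = params.texture_wave_amp[cell_class] * float(
        np.exp(params.texture_jitter * rng.standard_normal())
    )
    amp *= patient_texture_factor
    wave = _standardize_over(
        _smooth_unit_field(mask.shape, params.texture_wave_sigma_px, rng), roi_sel
    )
    offsets += amp * sd_target * wave

    # --- variance budget --------------------------------------------------
    off_roi = offsets[roi_sel]
    v_off = float(off_roi.var())
    target_var = sd_target**2
    cap = params.offset_variance_cap * target_var
    offset_scale = 1.0
    if v_off > cap:
        offset_scale = float(np.sqrt(cap / v_off))
        offsets *= offset_scale
        off_roi = offsets[roi_sel]
        v_off = float(off_roi.var())
    noise_sd = float(np.sqrt(max(target_var - v_off, 0.0)))

    # --- pixel noise ------------------------------------------------------
    sigma = params.texture_sigma_px[cell_class] * float(
        np.exp(params.texture_jitter * rng.standard_normal())
    )
    sigma *= patient_texture_factor
    noise = _standardize_over(_smooth_unit_field(mask.shape, sigma, rng), roi_sel)

    mean_target = (
        params.class_means_ps[cell_class]
        + patient_mean_shift_ps
        + float(rng.normal(0.0, params.cell_mean_jitter_ps))
    )
    base = mean_target - float(off_roi.mean())

    cell_values = base + offsets + noise_sd * noise
    if params.pixel_noise_model == "shot-like":
        # photon-limited flavour: noise amplitude tracks sqrt(local level)
        level = np.clip(base + offsets, 1.0, None)
        weights = np.sqrt(level / level[roi_sel].mean())
        shot = _standardize_over(noise * weights, roi_sel)
        cell_values = base + offsets + noise_sd * shot

    # plasma background with its own mild noise
    bg = params.background_lifetime_ps * (1.0 + 0.03 * rng.standard_normal(mask.shape))
    out = np.where(mask, cell_values, bg)
    out = np.clip(out, 0.0, None)

    record = CellRecord(
        cell_id=f"{cell_class}_{ss.entropy % 10**8:08d}",
        patient_id="",
        group="control" if cell_class == "control" else "scd",
        subtype=cell_class,
        shape_class="sickled" if cell_class == "sickled" else "round",
        roi=roi,
        extra={
            "cell_area_px": int(mask.sum()),
            "n_dots": n_dots,
            "dot_centers": ";".join(f"{cy},{cx}" for cy, cx in dot_centers),
            "patch_area_px": patch_area,
            "patch_offset_ps": round(patch_offset * offset_scale, 3),
            "texture_sigma": round(sigma, 4),
            "texture_wave_amp": round(amp, 4),
            "noise_sd_ps": round(noise_sd, 3),
            "offset_scale": round(offset_scale, 4),
        },
    )
    if return_mask:
        return out, record, mask
    return out, record


def generate_cohort(
    n_per_group: dict | None = None,
    cells_per_patient: dict | None = None,
    params: GeneratorParams | None = None,
    seed: int = 0,
    out_dir=None,
    matrix_format: str = "tsv",
) -> SyntheticCohort:
    """Generate a full cohort with patients nested in groups.

    Defaults mirror the study conditions: 27 control subjects x 10 cells,
    45 SCD patients x 10 non-sickled + 5 sickled cells.  If ``out_dir`` is
    given, every matrix and the manifest are written there.
    """
    params = (params or default_params()).validate()
    n_per_group = dict(n_per_group or {"control": 27, "scd": 45})
    cells_per_patient = dict(
        cells_per_patient or {"control": 10, "nonsickled": 10, "sickled": 5}
    )
    for g, n in n_per_group.items():
        if n <= 0:
            raise ValueError(f"group {g!r}: need at least one patient")
        if g not in ("control", "scd"):
            raise ValueError(f"unknown group {g!r}")

    ss_root = np.random.SeedSequence(seed)
    cells: list[tuple[CellRecord, np.ndarray]] = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        (out_dir / "matrices").mkdir(parents=True, exist_ok=True)

    group_specs = {
        "control": [("control", cells_per_patient.get("control", 0))],
        "scd": [
            ("nonsickled", cells_per_patient.get("nonsickled", 0)),
            ("sickled", cells_per_patient.get("sickled", 0)),
        ],
    }
    patient_index = 0
    for group in ("control", "scd"):
        if group not in n_per_group:
            continue
        prefix = "C" if group == "control" else "P"
        for p in range(n_per_group[group]):
            patient_index += 1
            pid = f"{prefix}{p + 1:03d}"
            ss_pat = np.random.SeedSequence(
                entropy=ss_root.entropy, spawn_key=(patient_index,)
            )
            rng_pat = np.random.default_rng(ss_pat)
            mean_shift = float(rng_pat.normal(0.0, params.patient_mean_sd_ps))
            tex_factor = float(
                np.exp(params.patient_texture_jitter * rng_pat.standard_normal())
            )
            cell_counter = 0
            for subtype, n_cells in group_specs[group]:
                for c in range(n_cells):
                    cell_counter += 1
                    ss_cell = np.random.SeedSequence(
                        entropy=ss_root.entropy, spawn_key=(patient_index, cell_counter)
                    )
                    matrix, rec = generate_cell(
                        subtype,
                        params,
                        seed=ss_cell,
                        patient_mean_shift_ps=mean_shift,
                        patient_texture_factor=tex_factor,
                    )
                    rec.cell_id = f"{pid}_{subtype}_{c + 1:02d}"
                    rec.patient_id = pid
                    if out_dir is not None:
                        fname = f"matrices/{rec.cell_id}.{ 'tsv' if matrix_format == 'tsv' else 'tiff'}"
                        write_lifetime_matrix(matrix, out_dir / fname, format=matrix_format)
                        rec.path = fname
                    cells.append((rec, matrix))

    manifest = manifest_frame([rec for rec, _ in cells])
    if out_dir is not None:
        write_manifest(manifest, out_dir / "manifest.tsv")
    return SyntheticCohort(cells=cells, manifest=manifest, params=params)
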