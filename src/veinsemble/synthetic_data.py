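"""Seeded generator of synthetic NIR-like finger-vein datasets.

Real finger-vein acquisitions are restricted-access, so every other module
is exercised against images produced here: dark curvilinear vessels on a
non-uniform bright background, organized as identity classes captured in
two "sessions" with session-level drift (rotation, translation,
illumination, blur) and sample-level sensor noise.  The single-sample
protocol splits each class into one enrollment image (first sample of the
first session) and later-session test images.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
from PIL import Image
from scipy.interpolate import make_interp_spline
from scipy.ndimage import distance_transform_edt, gaussian_filter

MIN_CANVAS = (32, 64)
DEFAULT_CANVAS = (64, 128)

#: gray-level depth of the vessel profile below the local background
VESSEL_CONTRAST = 60.0
#: background base gray level
BACKGROUND_LEVEL = 190.0


@dataclass(frozen=True)
class SessionParams:
    """Acquisition drift shared by all samples of one (class, session)."""

    rotation_deg: float = 0.0
    translation_px: tuple[float, float] = (0.0, 0.0)  # (dy, dx)
    brightness_offset: float = 0.0
    blur_sigma: float = 0.0
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.rotation_deg) > 10:
            raise ValueError(
                f"|rotation_deg| must be <= 10, got {self.rotation_deg}"
            )


IDENTITY_SESSION = SessionParams()


@dataclass(frozen=True)
class FingerTemplate:
    """Fixed vascular layout of one finger identity.

    ``branches`` holds one dense polyline per vessel as an (m, 2) float
    array of (row, col) points; ``vessel_radii`` gives the half-width in
    pixels of each branch.  ``texture_seed`` drives the deterministic
    low-frequency background texture of this finger.
    """

    class_id: int
    branches: tuple[np.ndarray, ...]
    vessel_radii: tuple[float, ...]
    canvas_size: tuple[int, int]
    texture_seed: int

    @property
    def skeleton(self) -> np.ndarray:
        """All skeleton points stacked into one (m, 2) array."""
        return np.vstack(self.branches)


@dataclass
class VeinSample:
    """One grayscale image with its class label and acquisition indices."""

    image: np.ndarray  # uint8 (H, W)
    mask: np.ndarray  # bool (H, W), True on vessel
    class_id: int
    session: int
    sample_index: int
    seed: int = 0
    path: str | None = None
    mask_path: str | None = None


@dataclass
class SyntheticDataset:
    samples: list[VeinSample]
    manifest: pd.DataFrame
    n_classes: int
    master_seed: int

    @property
    def masks(self) -> list[np.ndarray]:
        return [s.mask for s in self.samples]

    def sspp_split(self) -> tuple[list[VeinSample], list[VeinSample]]:
        """Single-sample split: first sample of session 1 enrolls each
        class; every later-session sample is a probe."""
        train = [
            s for s in self.samples if s.session == 1 and s.sample_index == 1
        ]
        train.sort(key=lambda s: s.class_id)
        test = [s for s in self.samples if s.session >= 2]
        return train, test


def _smooth_polyline(control: np.ndarray, n_dense: int = 200) -> np.ndarray:
    """Interpolate control points (k, 2) into a dense smooth polyline."""
    k = len(control)
    t = np.linspace(0.0, 1.0, k)
    deg = min(3, k - 1)
    spline = make_interp_spline(t, control, k=deg)
    return spline(np.linspace(0.0, 1.0, n_dense))


def generate_template(
    class_id: int,
    master_seed: int,
    canvas_size: tuple[int, int] = DEFAULT_CANVAS,
) -> FingerTemplate:
    """Generate the fixed vessel layout of one finger class.

    Deterministic in ``(class_id, master_seed)``.  The layout is a bundle
    of 3-6 smooth, mostly horizontal vessels (one per random-walk control
    polygon) with per-branch radii of 1.2-2.6 px.
    """
    h, w = canvas_size
    if h < MIN_CANVAS[0] or w < MIN_CANVAS[1]:
        raise ValueError(
            f"canvas_size {canvas_size} too small; minimum is {MIN_CANVAS}"
        )
    rng = np.random.default_rng([int(master_seed), int(class_id)])
    n_branches = int(rng.integers(3, 7))
    margin_y = 0.14 * h
    branches: list[np.ndarray] = []
    radii: list[float] = []
    base_rows = np.sort(rng.uniform(margin_y, h - margin_y, size=n_branches))
    for b in range(n_branches):
        n_ctrl = int(rng.integers(5, 8))
        cols = np.linspace(0.06 * w, 0.94 * w, n_ctrl)
        cols += rng.uniform(-0.02 * w, 0.02 * w, size=n_ctrl)
        rows = base_rows[b] + np.cumsum(rng.normal(0.0, 0.055 * h, size=n_ctrl))
        rows = np.clip(rows, margin_y, h - margin_y)
        control = np.column_stack([rows, cols])
        branches.append(_smooth_polyline(control))
        radii.append(float(rng.uniform(1.2, 2.6)))
    texture_seed = int(rng.integers(0, 2**31 - 1))
    return FingerTemplate(
        class_id=int(class_id),
        branches=tuple(branches),
        vessel_radii=tuple(radii),
        canvas_size=(h, w),
        texture_seed=texture_seed,
    )


def _transform_points(
    points: np.ndarray, session: SessionParams, canvas: tuple[int, int]
) -> np.ndarray:
    h, w = canvas
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    theta = np.deg2rad(session.rotation_deg)
    c, s = np.cos(theta), np.sin(theta)
    dy, dx = session.translation_px
    ry = points[:, 0] - cy
    rx = points[:, 1] - cx
    rows = cy + c * ry - s * rx + dy
    cols = cx + s * ry + c * rx + dx
    return np.column_stack([rows, cols])


def _rasterize_branch(
    points: np.ndarray, radius: float, canvas: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Return (mask, darkness) for one branch via a distance transform."""
    h, w = canvas
    skel = np.ones((h, w), dtype=bool)
    rr = np.rint(points[:, 0]).astype(int)
    cc = np.rint(points[:, 1]).astype(int)
    keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    skel[rr[keep], cc[keep]] = False
    if skel.all():
        return np.zeros((h, w), bool), np.zeros((h, w))
    dist = distance_transform_edt(skel)
    mask = dist <= radius
    darkness = VESSEL_CONTRAST * np.exp(-((dist / (radius + 0.5)) ** 2))
    return mask, darkness


def _background(template: FingerTemplate) -> np.ndarray:
    """Bright non-uniform background: horizontal illumination gradient
    plus a smooth low-frequency texture fixed per finger."""
    h, w = template.canvas_size
    x = np.linspace(-1.0, 1.0, w)
    gradient = 18.0 * np.cos(np.pi * x / 2.0)  # brighter at the center
    rng = np.random.default_rng(template.texture_seed)
    texture = gaussian_filter(rng.standard_normal((h, w)), sigma=9.0)
    texture *= 12.0 / max(texture.std(), 1e-9)
    return BACKGROUND_LEVEL + gradient[None, :] + texture


def render_sample(
    template: FingerTemplate,
    session: SessionParams = IDENTITY_SESSION,
    sample_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one acquisition of a finger.

    Session parameters perturb geometry and illumination; ``sample_seed``
    controls only the additive sensor-noise realization, so two samples of
    the same session share an identical vessel mask.  Vessel pixels are
    rendered strictly darker on average than the background.

    Returns ``(image uint8, mask bool)``.
    """
    h, w = template.canvas_size
    clean = _background(template)
    mask = np.zeros((h, w), dtype=bool)
    for points, radius in zip(template.branches, template.vessel_radii):
        moved = _transform_points(points, session, (h, w))
        bmask, darkness = _rasterize_branch(moved, radius, (h, w))
        mask |= bmask
        clean -= darkness
    clean += session.brightness_offset
    if session.blur_sigma > 0:
        clean = gaussian_filter(clean, session.blur_sigma)
    if session.noise_sigma > 0:
        rng = np.random.default_rng([int(sample_seed)])
        clean = clean + rng.normal(0.0, session.noise_sigma, size=clean.shape)
    image = np.clip(np.rint(clean), 0, 255).astype(np.uint8)
    return image, mask


def template_mask(template: FingerTemplate) -> np.ndarray:
    """Ground-truth vessel mask of the untransformed template."""
    return render_sample(template, IDENTITY_SESSION, 0)[1]


def _session_params(
    class_id: int, session: int, master_seed: int
) -> SessionParams:
    """Draw the drift of one (class, session) acquisition.

    Session 1 is close to the canonical pose; later sessions drift more,
    emulating a re-acquisition after a long interval.
    """
    rng = np.random.default_rng(
        [int(master_seed), 7919, int(class_id), int(session)]
    )
    mild = session == 1
    rot = float(rng.uniform(-1.0, 1.0) if mild else rng.uniform(-3.0, 3.0))
    shift = 1.0 if mild else 3.0
    dy = float(rng.uniform(-shift, shift))
    dx = float(rng.uniform(-shift, shift))
    bright = float(rng.uniform(-4, 4) if mild else rng.uniform(-12, 12))
    blur = float(rng.uniform(0.3, 0.6) if mild else rng.uniform(0.4, 1.0))
    noise = float(rng.uniform(2.0, 4.0) if mild else rng.uniform(3.0, 6.0))
    return SessionParams(
        rotation_deg=rot,
        translation_px=(dy, dx),
        brightness_offset=bright,
        blur_sigma=blur,
        noise_sigma=noise,
    )


def _sample_seed(
    master_seed: int, class_id: int, session: int, sample: int
) -> int:
    ss = np.random.SeedSequence(
        [int(master_seed), int(class_id), int(session), int(sample)]
    )
    return int(ss.generate_state(1)[0])


def _write_png(path: Path, array: np.ndarray) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(array).save(path, format="PNG")


def generate_dataset(
    n_classes: int,
    sessions: int = 2,
    samples_per_session: int = 6,
    master_seed: int = 0,
    out_dir: str | os.PathLike | None = None,
    canvas_size: tuple[int, int] = DEFAULT_CANVAS,
) -> SyntheticDataset:
    """Generate a full multi-class, multi-session dataset.

    When ``out_dir`` is given, images and masks are written as 8-bit PNGs
    under ``class_XXXX/session_Y/sample_Z.png`` and a ``manifest.csv``
    with relative paths is placed at the root; re-running with identical
    arguments reproduces identical bytes.  With ``out_dir=None`` the
    dataset is kept in memory only.
    """
    if n_classes < 2:
        raise ValueError(f"n_classes must be >= 2, got {n_classes}")
    if sessions < 1 or samples_per_session < 1:
        raise ValueError("sessions and samples_per_session must be >= 1")
    root = None
    if out_dir is not None:
        root = Path(out_dir)
        try:
            root.mkdir(parents=True, exist_ok=True)
            probe = root / ".write_probe"
            probe.write_text("")
            probe.unlink()
        except OSError as exc:
            raise OSError(f"output directory {root} is not writable: {exc}")

    samples: list[VeinSample] = []
    rows = []
    for class_id in range(n_classes):
        template = generate_template(class_id, master_seed, canvas_size)
        for session in range(1, sessions + 1):
            params = _session_params(class_id, session, master_seed)
            for k in range(1, samples_per_session + 1):
                seed = _sample_seed(master_seed, class_id, session, k)
                image, mask = render_sample(template, params, seed)
                rel = f"class_{class_id:04d}/session_{session}/sample_{k}.png"
                rel_mask = (
                    f"class_{class_id:04d}/session_{session}/sample_{k}_mask.png"
                )
                sample = VeinSample(
                    image=image,
                    mask=mask,
                    class_id=class_id,
                    session=session,
                    sample_index=k,
                    seed=seed,
                )
                if root is not None:
                    _write_png(root / rel, image)
                    _write_png(root / rel_mask, mask.astype(np.uint8) * 255)
                    sample.path = rel
                    sample.mask_path = rel_mask
                samples.append(sample)
                rows.append(
                    {
                        "class_id": class_id,
                        "session": session,
                        "sample": k,
                        "path": rel,
                        "mask_path": rel_mask,
                        "seed": seed,
                    }
                )
    manifest = pd.DataFrame(rows)
    if root is not None:
        manifest.to_csv(root / "manifest.csv", index=False)
    return SyntheticDataset(
        samples=samples,
        manifest=manifest,
        n_classes=n_classes,
        master_seed=master_seed,
    )
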