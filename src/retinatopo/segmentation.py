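"""PCA sliding-window segmentation of vertical sprouts versus plexuses.

A cubic window slides over the binary stack at a fixed stride.  Within each
window holding enough foreground, the top principal component of the
foreground-voxel coordinates gives the local vessel orientation (sign-free).
The angle θ between that orientation and the local radial direction — the
ray from the origin (foreground centre of mass, or a fixed +z axis in flat
fixtures) to the window centre — classifies the window: θ ≤ cutoff votes
*sprout*, otherwise *plexus*.  Near-isotropic windows (λ₁/λ₂ below
``anisotropy_min``, typically bifurcations or crossings of differently
oriented vessels) vote *ambiguous* and never force a sprout call.  Because
the stride is below the window size, a voxel is covered by several windows;
its label is the majority of the sprout/plexus votes covering it, ties and
ambiguous-only coverage falling back to plexus.
"""

from __future__ import annotations

import dataclasses
from itertools import product

import numpy as np

from .volume import BACKGROUND, PLEXUS, SPROUT, LabelVolume, VolumeImage

_AMBIGUOUS, _PLEXUS_VOTE, _SPROUT_VOTE = 0, 1, 2
_VERDICT_NAMES = {_AMBIGUOUS: "ambiguous", _PLEXUS_VOTE: "plexus", _SPROUT_VOTE: "sprout"}


class InsufficientSupportError(ValueError):
    """Too few foreground points to estimate an orientation."""


class UndefinedFractionError(ValueError):
    """Sprout volume fraction is undefined on an all-background volume."""


@dataclasses.dataclass(frozen=True)
class SegmentationParams:
    window_um: float = 40.0
    shift_um: float = 20.0
    cutoff_deg: float = 35.0
    min_voxels: int = 10
    anisotropy_min: float = 2.0
    origin_mode: str = "center_of_mass"  # or "fixed_axis"

    def __post_init__(self) -> None:
        if not 0 < self.shift_um <= self.window_um:
            raise ValueError("need 0 < shift_um <= window_um")
        if not 0 < self.cutoff_deg < 90:
            raise ValueError("cutoff_deg must lie strictly between 0 and 90")
        if self.min_voxels < 1:
            raise ValueError("min_voxels must be >= 1")
        if self.anisotropy_min < 1:
            raise ValueError("anisotropy_min must be >= 1")
        if self.origin_mode not in ("center_of_mass", "fixed_axis"):
            raise ValueError(f"unknown origin_mode {self.origin_mode!r}")


@dataclasses.dataclass
class WindowVote:
    center_um: np.ndarray
    principal: np.ndarray | None  # sign-free unit vector; None when ambiguous
    theta_deg: float  # NaN when ambiguous
    verdict: str  # sprout | plexus | ambiguous


def principal_orientation(
    coords: np.ndarray, min_points: int = 2
) -> tuple[np.ndarray, float]:
    """Top covariance eigenvector (sign-free) and the anisotropy ratio λ₁/λ₂.

    ``coords`` is an (n, 3) µm point set; perfectly collinear sets yield an
    infinite ratio.  Raises :class:`InsufficientSupportError` below
    ``min_points``.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    if len(coords) < max(min_points, 2):
        raise InsufficientSupportError(
            f"{len(coords)} points < required {max(min_points, 2)}"
        )
    centred = coords - coords.mean(axis=0)
    cov = centred.T @ centred / len(coords)
    evals, evecs = np.linalg.eigh(cov)
    top, second = float(evals[2]), float(evals[1])
    vec = evecs[:, 2]
    scale = max(float(evals[2]), 1e-30)
    if second <= 1e-12 * scale:
        ratio = float("inf") if top > 0 else 1.0
    else:
        ratio = top / second
    return vec / np.linalg.norm(vec), ratio


def radial_angle(center: np.ndarray, principal: np.ndarray, origin: np.ndarray) -> float:
    """Sign-free angle (degrees, in [0, 90]) between a vessel orientation and
    the radial ray from ``origin`` to ``center``."""
    center = np.asarray(center, dtype=float)
    principal = np.asarray(principal, dtype=float)
    radial = center - np.asarray(origin, dtype=float)
    nr = np.linalg.norm(radial)
    npv = np.linalg.norm(principal)
    if nr == 0:
        raise ValueError("window centre coincides with the origin: radial undefined")
    if npv == 0:
        raise ValueError("principal vector must be nonzero")
    cosang = abs(float(radial @ principal)) / (nr * npv)
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def segment_sprouts(
    volume: VolumeImage,
    params: SegmentationParams = SegmentationParams(),
    origin_um: np.ndarray | None = None,
) -> tuple[LabelVolume, list[WindowVote]]:
    """Classify foreground voxels as sprout or plexus by window voting.

    ``origin_um`` overrides the radial origin (used e.g. to pass the true
    hemisphere centre); otherwise it follows ``params.origin_mode``.
    """
    if not volume.is_binary():
        raise ValueError("segmentation requires a binary volume")
    data = volume.data.astype(bool)
    labels = LabelVolume(
        np.zeros_like(data, dtype=np.uint8),
        volume.voxel_size_um,
        origin_um=volume.origin_um.copy(),
    )
    fg = np.argwhere(data)
    if len(fg) == 0:
        return labels, []

    voxel = volume.voxel_size_um
    w_vox = max(int(round(params.window_um / voxel)), 1)
    s_vox = max(int(round(params.shift_um / voxel)), 1)
    centers = volume.voxel_centers(fg)  # (n, 3) world xyz

    fixed_axis = params.origin_mode == "fixed_axis" and origin_um is None
    if origin_um is None and not fixed_axis:
        origin_um = centers.mean(axis=0)

    # windows per axis: start = k * s_vox, k = 0 .. ceil(dim / s) - 1
    n_win = [int(np.ceil(dim / s_vox)) for dim in data.shape]
    n_phase = int(np.ceil(w_vox / s_vox))

    # (voxel, window) incidence pairs
    pair_vox: list[np.ndarray] = []
    pair_win: list[np.ndarray] = []
    idx = fg  # (n, 3) zyx
    for offs in product(range(n_phase), repeat=3):
        k = idx // s_vox - np.asarray(offs)
        valid = (k >= 0).all(axis=1)
        inside = ((idx - k * s_vox) < w_vox).all(axis=1)
        m = valid & inside
        if not m.any():
            continue
        flat = (k[m, 0] * n_win[1] + k[m, 1]) * n_win[2] + k[m, 2]
        pair_vox.append(np.nonzero(m)[0])
        pair_win.append(flat)
    pair_vox = np.concatenate(pair_vox)
    pair_win = np.concatenate(pair_win)

    order = np.argsort(pair_win, kind="stable")
    pair_vox = pair_vox[order]
    pair_win = pair_win[order]
    win_ids, starts, counts = np.unique(
        pair_win, return_index=True, return_counts=True
    )

    # batched per-window covariance via reduceat on the sorted point list
    pts = centers[pair_vox]
    sums = np.add.reduceat(pts, starts, axis=0)
    outer = pts[:, :, None] * pts[:, None, :]
    sq = np.add.reduceat(outer.reshape(len(pts), 9), starts, axis=0)
    n = counts.astype(float)[:, None]
    mean = sums / n
    cov = sq.reshape(-1, 3, 3) / n[:, :, None] - mean[:, :, None] * mean[:, None, :]

    eligible = counts >= params.min_voxels
    verdicts = np.full(len(win_ids), _AMBIGUOUS, dtype=np.uint8)
    thetas = np.full(len(win_ids), np.nan)
    principals = np.full((len(win_ids), 3), np.nan)

    if eligible.any():
        evals, evecs = np.linalg.eigh(cov[eligible])
        evals = np.maximum(evals, 0.0)
        top, second = evals[:, 2], evals[:, 1]
        vecs = evecs[:, :, 2]
        scale = np.maximum(top, 1e-30)
        ratio = np.where(second <= 1e-12 * scale, np.inf, top / np.maximum(second, 1e-300))

        # window centres in world coordinates
        kz = win_ids[eligible] // (n_win[1] * n_win[2])
        ky = (win_ids[eligible] // n_win[2]) % n_win[1]
        kx = win_ids[eligible] % n_win[2]
        start_zyx = np.stack([kz, ky, kx], axis=1) * s_vox
        center_world = volume.origin_um + (
            start_zyx[:, ::-1].astype(float) + w_vox / 2.0
        ) * voxel

        if fixed_axis:
            radial = np.tile(np.array([0.0, 0.0, 1.0]), (len(center_world), 1))
            r_ok = np.ones(len(center_world), dtype=bool)
        else:
            radial = center_world - origin_um
            norms = np.linalg.norm(radial, axis=1)
            r_ok = norms > 1e-9
            radial[r_ok] /= norms[r_ok, None]

        cosang = np.abs(np.einsum("ij,ij->i", radial, vecs))
        theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        trusted = (ratio >= params.anisotropy_min) & (top > 0) & r_ok

        v = np.where(theta <= params.cutoff_deg, _SPROUT_VOTE, _PLEXUS_VOTE)
        v = np.where(trusted, v, _AMBIGUOUS).astype(np.uint8)
        verdicts[eligible] = v
        thetas[eligible] = np.where(trusted, theta, np.nan)
        principals[eligible] = vecs

    # fuse votes per voxel
    win_pos = np.searchsorted(win_ids, pair_win)
    pair_verdict = verdicts[win_pos]
    sprout_votes = np.zeros(len(fg), dtype=np.int32)
    plexus_votes = np.zeros(len(fg), dtype=np.int32)
    np.add.at(sprout_votes, pair_vox[pair_verdict == _SPROUT_VOTE], 1)
    np.add.at(plexus_votes, pair_vox[pair_verdict == _PLEXUS_VOTE], 1)
    voxel_label = np.where(sprout_votes > plexus_votes, SPROUT, PLEXUS).astype(np.uint8)
    labels.data[tuple(fg.T)] = voxel_label

    votes = []
    all_centers = _window_centers(win_ids, n_win, s_vox, w_vox, voxel, volume.origin_um)
    for i in range(len(win_ids)):
        if counts[i] < params.min_voxels:
            continue
        votes.append(
            WindowVote(
                center_um=all_centers[i],
                principal=None if np.isnan(principals[i]).any() else principals[i],
                theta_deg=float(thetas[i]),
                verdict=_VERDICT_NAMES[int(verdicts[i])],
            )
        )
    return labels, votes


def _window_centers(win_ids, n_win, s_vox, w_vox, voxel, origin):
    kz = win_ids // (n_win[1] * n_win[2])
    ky = (win_ids // n_win[2]) % n_win[1]
    kx = win_ids % n_win[2]
    start_zyx = np.stack([kz, ky, kx], axis=1) * s_vox
    return origin + (start_zyx[:, ::-1].astype(float) + w_vox / 2.0) * voxel


def sprout_volume_fraction(labels: LabelVolume) -> float:
    """Sprout voxels over all foreground voxels, in [0, 1]."""
    counts = labels.class_counts()
    sprout = counts.get(SPROUT, 0)
    plexus = counts.get(PLEXUS, 0)
    total = sprout + plexus
    if total == 0:
        raise UndefinedFractionError("no foreground voxels: fraction undefined")
    return sprout / total
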