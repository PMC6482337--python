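"""In-memory containers for voxel data and subject bundles.

Motion parameters are plain ``(T, 6)`` float arrays in the SPM realignment
convention: columns are X, Y, Z translations in mm followed by pitch, yaw,
roll rotations in radians.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GridMismatchError

#: Integer tissue codes used in label volumes and per-voxel label arrays.
GM, WM, CSF = 1, 2, 3

TISSUE_NAMES = {GM: "GM", WM: "WM", CSF: "CSF"}


@dataclass
class BoldDataset:
    """Voxel-by-time BOLD matrix with tissue labels and voxel coordinates.

    Parameters
    ----------
    data
        ``(V, T)`` array of signal values, one row per voxel.
    tissue
        ``(V,)`` integer array with values in ``{GM, WM, CSF}``.
    coords
        ``(V, 3)`` array of voxel coordinates in mm.
    """

    data: np.ndarray
    tissue: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.tissue = np.asarray(self.tissue)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a (V, T) matrix")
        if self.tissue.shape != (self.data.shape[0],):
            raise ValueError("tissue labels must have one entry per voxel")
        if self.coords.shape != (self.data.shape[0], 3):
            raise ValueError("coords must be (V, 3)")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]

    def mask(self, *labels: int) -> np.ndarray:
        """Boolean voxel mask selecting the given tissue codes."""
        return np.isin(self.tissue, labels)

    def non_gm(self) -> np.ndarray:
        """The ``(V_nonGM, T)`` sub-matrix of WM and CSF voxel series."""
        return self.data[self.mask(WM, CSF)]


@dataclass
class SubjectBundle:
    """Everything needed to run the pipeline on one subject."""

    bold: np.ndarray            # 4-D (nx, ny, nz, T)
    affine: np.ndarray          # 4x4 voxel-to-world transform
    masks: dict                 # tissue code -> 3-D boolean volume
    motion: np.ndarray          # (T, 6) realignment parameters
    atlas: np.ndarray | None = None  # 3-D integer label volume
    header: object | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.bold.ndim != 4:
            raise GridMismatchError("BOLD image must be 4-D")
        grid = self.bold.shape[:3]
        for code, m in self.masks.items():
            if m.shape != grid:
                raise GridMismatchError(
                    f"{TISSUE_NAMES.get(code, code)} mask grid {m.shape} does "
                    f"not match BOLD grid {grid}"
                )
        if self.atlas is not None and self.atlas.shape != grid:
            raise GridMismatchError(
                f"atlas grid {self.atlas.shape} does not match BOLD grid {grid}"
            )
        t_img, t_mot = self.bold.shape[3], self.motion.shape[0]
        if t_mot != t_img:
            raise GridMismatchError(
                f"motion file has {t_mot} rows but BOLD image has {t_img} "
                f"volumes; note that dummy volumes discarded from the image "
                f"(commonly the first five) must also be dropped from the "
                f"realignment-parameter file"
            )

    def to_dataset(self) -> BoldDataset:
        """Flatten masked voxels into a :class:`BoldDataset`.

        Voxel coordinates are world coordinates (mm) obtained from the
        affine; voxels appear GM first, then WM, then CSF.
        """
        rows, labels, coords = [], [], []
        for code in (GM, WM, CSF):
            m = self.masks.get(code)
            if m is None:
                continue
            idx = np.argwhere(m)
            if idx.size == 0:
                continue
            rows.append(self.bold[m])
            labels.append(np.full(len(idx), code))
            world = (self.affine @ np.c_[idx, np.ones(len(idx))].T).T[:, :3]
            coords.append(world)
        return BoldDataset(
            data=np.vstack(rows),
            tissue=np.concatenate(labels),
            coords=np.vstack(coords),
        )
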