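"""Standard-format I/O, mask erosion and the end-to-end pipeline.

Formats: NIfTI-1 for 4-D BOLD and 3-D masks/atlas (via nibabel), the SPM
``rp_*.txt`` dialect for realignment parameters (6 whitespace-separated
columns: translations in mm, rotations in radians), TSV with header rows
for regressor/QC tables, JSON for summaries. Voxel indices are 0-based
internally; world coordinates come from the NIfTI affine.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from . import cnn, network, nuisance, qc
from .containers import BoldDataset, CSF, GM, SubjectBundle, TISSUE_NAMES, WM
from .errors import DegenerateDataError, MotregressError
from .regressors import (
    FAMILY_SIZES,
    RegressorSet,
    build_regressor_set,
    tissue_mean_regressors,
)

_SLAB_CROSS = 16      # y/z cross-section of the synthetic voxel slabs
_VOXEL_MM = 3.0

#: minimum WM voxels kept when eroding the WM mask
WM_MIN_VOXELS = 10000


# ---------------------------------------------------------------------------
# synthetic-subject layout and round trip


def slab_layout(tissue: np.ndarray) -> tuple:
    """Deterministic placement of flat voxel lists into disjoint 3-D slabs.

    Tissues occupy consecutive x-slabs (GM, WM, CSF order) of cross
    section 16 x 16, separated by one empty plane. Returns
    ``(indices, grid_shape)`` with ``indices`` of shape ``(V, 3)``.
    """
    indices = np.zeros((len(tissue), 3), dtype=int)
    x0 = 0
    for code in (GM, WM, CSF):
        sel = np.flatnonzero(tissue == code)
        if sel.size == 0:
            continue
        local = np.arange(sel.size)
        indices[sel, 0] = x0 + local // (_SLAB_CROSS**2)
        rem = local % (_SLAB_CROSS**2)
        indices[sel, 1] = rem // _SLAB_CROSS
        indices[sel, 2] = rem % _SLAB_CROSS
        x0 = indices[sel, 0].max() + 2      # one-plane gap between tissues
    shape = (int(indices[:, 0].max()) + 1, _SLAB_CROSS, _SLAB_CROSS)
    return indices, shape


def subject_to_bundle(subject) -> SubjectBundle:
    """Pack a :class:`~motregress.synthetic.SyntheticSubject` onto a 3-D
    grid as a :class:`SubjectBundle` (without touching the disk)."""
    data = subject.data
    indices, shape = slab_layout(data.tissue)
    T = data.n_volumes
    bold = np.zeros(shape + (T,))
    bold[indices[:, 0], indices[:, 1], indices[:, 2]] = data.data
    masks = {}
    for code in (GM, WM, CSF):
        m = np.zeros(shape, dtype=bool)
        sel = data.tissue == code
        m[indices[sel, 0], indices[sel, 1], indices[sel, 2]] = True
        masks[code] = m
    affine = np.diag([_VOXEL_MM, _VOXEL_MM, _VOXEL_MM, 1.0])
    return SubjectBundle(bold=bold, affine=affine, masks=masks,
                         motion=subject.motion)


def make_atlas(bundle: SubjectBundle, n_rois: int = 20) -> np.ndarray:
    """Partition the GM mask into ``n_rois`` contiguous label blocks."""
    gm_idx = np.argwhere(bundle.masks[GM])
    if len(gm_idx) < n_rois:
        raise ValueError("fewer GM voxels than requested ROIs")
    atlas = np.zeros(bundle.bold.shape[:3], dtype=np.int32)
    splits = np.array_split(np.arange(len(gm_idx)), n_rois)
    for lab, chunk in enumerate(splits, start=1):
        v = gm_idx[chunk]
        atlas[v[:, 0], v[:, 1], v[:, 2]] = lab
    return atlas


# ---------------------------------------------------------------------------
# on-disk formats


def read_motion(path) -> np.ndarray:
    """Read an SPM-style rp_*.txt realignment-parameter file."""
    M = np.loadtxt(path, ndmin=2)
    if M.shape[1] != 6:
        raise MotregressError(
            f"motion file {path} has {M.shape[1]} columns; expected 6 "
            f"(X Y Z pitch yaw roll)"
        )
    return M


def write_motion(path, M: np.ndarray) -> None:
    np.savetxt(path, np.asarray(M, dtype=float), fmt="%.10e")


def read_subject(
    bold_path, mask_paths: dict, motion_path, atlas_path=None
) -> SubjectBundle:
    """Load and validate a subject from disk.

    ``mask_paths`` maps tissue names ('GM', 'WM', 'CSF') or codes to
    NIfTI paths. Grid or volume-count mismatches raise with both counts
    named.
    """
    img = nib.load(str(bold_path))
    bold = np.asarray(img.dataobj, dtype=float)
    name_to_code = {v: k for k, v in TISSUE_NAMES.items()}
    masks = {}
    for key, p in mask_paths.items():
        code = name_to_code.get(key, key)
        masks[code] = np.asarray(nib.load(str(p)).dataobj) > 0.5
    motion = read_motion(motion_path)
    atlas = None
    if atlas_path is not None:
        atlas = np.asarray(nib.load(str(atlas_path)).dataobj).astype(np.int32)
    return SubjectBundle(
        bold=bold, affine=img.affine, masks=masks, motion=motion,
        atlas=atlas, header=img.header,
    )


def write_subject(subject, outdir) -> dict:
    """Write a synthetic subject as NIfTI volumes plus a motion text file.

    Returns a dict of written paths, suitable for :func:`read_subject`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = subject_to_bundle(subject)
    paths = {}
    nib.save(nib.Nifti1Image(bundle.bold.astype(np.float32), bundle.affine),
             str(outdir / "bold.nii"))
    paths["bold"] = outdir / "bold.nii"
    for code, m in bundle.masks.items():
        name = TISSUE_NAMES[code].lower()
        nib.save(nib.Nifti1Image(m.astype(np.uint8), bundle.affine),
                 str(outdir / f"mask_{name}.nii"))
        paths[f"mask_{name}"] = outdir / f"mask_{name}.nii"
    write_motion(outdir / "rp_motion.txt", subject.motion)
    paths["motion"] = outdir / "rp_motion.txt"
    atlas = make_atlas(bundle, n_rois=min(20, int((subject.data.tissue == GM).sum())))
    nib.save(nib.Nifti1Image(atlas, bundle.affine), str(outdir / "atlas.nii"))
    paths["atlas"] = outdir / "atlas.nii"
    return paths


def save_residual_image(path, residuals: np.ndarray, bundle: SubjectBundle,
                        dataset: BoldDataset) -> None:
    """Write voxel residuals back onto the bundle's grid with its affine."""
    indices, _ = slab_layout(dataset.tissue)
    vol = np.zeros(bundle.bold.shape[:3] + (residuals.shape[1],),
                   dtype=np.float32)
    vol[indices[:, 0], indices[:, 1], indices[:, 2]] = residuals
    nib.save(nib.Nifti1Image(vol, bundle.affine), str(path))


# ---------------------------------------------------------------------------
# mask erosion


def erode_mask(
    mask: np.ndarray,
    iterations: int | None = 1,
    min_voxels: int | None = None,
) -> np.ndarray:
    """6-connectivity morphological erosion.

    Without ``min_voxels``, erodes exactly ``iterations`` times. With
    ``min_voxels``, erosion repeats (up to ``iterations`` if given) only
    while the *next* erosion would still leave at least ``min_voxels``
    voxels, so the result never drops below the floor — if even one
    erosion would, the input mask is returned unchanged.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise DegenerateDataError("cannot erode an empty mask")
    structure = ndimage.generate_binary_structure(3, 1)   # 6-connectivity
    if min_voxels is None:
        if iterations is None:
            raise ValueError("iterations required when min_voxels is unset")
        if iterations == 0:
            return mask.copy()
        return ndimage.binary_erosion(mask, structure, iterations=iterations)
    out = mask.copy()
    done = 0
    while iterations is None or done < iterations:
        nxt = ndimage.binary_erosion(out, structure)
        if nxt.sum() < min_voxels:
            break
        out = nxt
        done += 1
    return out


# ---------------------------------------------------------------------------
# pipeline


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _prepare_masks(bundle: SubjectBundle) -> SubjectBundle:
    """Erode CSF once and WM down to the 10,000-voxel floor (partial-volume
    control); a mask that erosion would empty is kept un-eroded with a
    warning."""
    masks = dict(bundle.masks)
    if WM in masks:
        masks[WM] = erode_mask(masks[WM], iterations=None,
                               min_voxels=WM_MIN_VOXELS)
    if CSF in masks:
        eroded = erode_mask(masks[CSF], iterations=1)
        if eroded.any():
            masks[CSF] = eroded
        else:
            warnings.warn(
                "eroding the CSF mask once would empty it; keeping the "
                "un-eroded mask", stacklevel=2,
            )
    return SubjectBundle(bold=bundle.bold, affine=bundle.affine, masks=masks,
                         motion=bundle.motion, atlas=bundle.atlas,
                         header=bundle.header)


def build_family(
    family: str,
    bundle: SubjectBundle,
    dataset: BoldDataset,
    train_config: cnn.TrainConfig | None = None,
) -> RegressorSet:
    """Resolve a family name ('mot6'...'mot36' or 'cnn12') to regressors."""
    if family in FAMILY_SIZES:
        return build_regressor_set(bundle.motion, family)
    if family == "cnn12":
        model = cnn.train(bundle.motion, dataset.non_gm(), train_config)
        return model.regressors
    raise ValueError(f"unknown regressor family {family!r}")


def run_pipeline(
    bundle: SubjectBundle,
    outdir,
    families=("mot12", "cnn12"),
    seed: int = 0,
    tissue_regressors: bool = False,
    train_config: cnn.TrainConfig | None = None,
    n_louvain_runs: int = 20,
) -> dict:
    """Erode masks, build regressors, regress, and emit QC/FC summaries.

    Writes, per family: the regressor TSV, the residual NIfTI, a QC TSV;
    plus a comparison JSON with median remaining variance, QC ratios,
    modularity Q and distance-dependence statistics, and a run log with
    the seed and a config hash. Returns the comparison dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = {"families": list(families), "seed": seed,
           "tissue_regressors": tissue_regressors}
    if train_config is None:
        train_config = cnn.TrainConfig(seed=seed)

    bundle = _prepare_masks(bundle)
    dataset = bundle.to_dataset()
    Y = dataset.data

    # QC is computed on percent signal change when the data are raw
    # intensities; already-centred (synthetic/residual) data pass through.
    if (Y.mean(axis=1) > 0).all():
        Y_norm = qc.percent_signal_change(Y)
    else:
        Y_norm = Y
    summary_raw = qc.qc_summary(bundle.motion, Y_norm)
    pd.DataFrame({
        "fd": summary_raw.fd,
        "rmsfd": summary_raw.rmsfd,
        "dvars": summary_raw.dvars,
    }).to_csv(outdir / "qc_raw.tsv", sep="\t", index=False,
              float_format="%.10g")

    atlas_available = bundle.atlas is not None
    results = {
        "seed": seed,
        "config_hash": _config_hash(cfg),
        "motion_group": summary_raw.motion_group,
        "mean_fd": summary_raw.mean_fd,
        "raw": {
            "mean_dvars": summary_raw.mean_dvars,
            "mean_whole_brain_variance": summary_raw.mean_whole_brain_variance,
        },
        "families": {},
    }
    if atlas_available:
        ts, ids, coords = network.roi_time_series(bundle.bold, bundle.atlas)
        world = (bundle.affine @ np.c_[coords, np.ones(len(coords))].T).T[:, :3]
        fc_raw = network.fc_matrix(ts, ids, world)
        q_raw, _ = network.modularity_q(fc_raw, runs=n_louvain_runs, seed=seed)
        results["raw"]["modularity_q"] = q_raw
        np.savetxt(outdir / "fc_raw.tsv", fc_raw.values, delimiter="\t")

    for family in families:
        rset = build_family(family, bundle, dataset, train_config)
        if tissue_regressors:
            rset = rset.hstack(tissue_mean_regressors(dataset))
        rset.to_tsv(outdir / f"regressors_{family}.tsv")

        fit = nuisance.regress_out(Y, rset)
        save_residual_image(outdir / f"residuals_{family}.nii", fit.residuals,
                            bundle, dataset)
        res_norm = fit.residuals if Y_norm is Y else \
            qc.percent_signal_change(fit.residuals + Y.mean(axis=1, keepdims=True))
        dv = qc.dvars(res_norm)
        fam = {
            "median_remaining_variance": float(
                np.median(fit.remaining_variance_fraction)
            ),
            "mean_whole_brain_variance": qc.mean_whole_brain_variance(res_norm),
            "dvars_ratio": qc.metric_ratio(
                summary_raw.mean_dvars, float(dv.mean())
            ) if summary_raw.mean_dvars > 0 else None,
        }
        fam["variance_ratio"] = qc.metric_ratio(
            results["raw"]["mean_whole_brain_variance"],
            fam["mean_whole_brain_variance"],
        ) if results["raw"]["mean_whole_brain_variance"] > 0 else None

        if atlas_available:
            res_vol = np.zeros_like(bundle.bold)
            idx, _ = slab_layout(dataset.tissue)
            res_vol[idx[:, 0], idx[:, 1], idx[:, 2]] = fit.residuals
            ts_f, ids_f, coords_f = network.roi_time_series(res_vol, bundle.atlas)
            world_f = (bundle.affine @ np.c_[coords_f, np.ones(len(coords_f))].T).T[:, :3]
            fc_f = network.fc_matrix(ts_f, ids_f, world_f)
            q_f, _ = network.modularity_q(fc_f, runs=n_louvain_runs, seed=seed)
            dfit = network.distance_dependence(fc_f, fc_raw)
            fam["modularity_q"] = q_f
            fam["delta_r_slope"] = dfit.slope
            fam["delta_r_intercept"] = dfit.intercept
        results["families"][family] = fam

    with open(outdir / "comparison.json", "w") as fh:
        json.dump(results, fh, indent=2)
    with open(outdir / "run_log.json", "w") as fh:
        json.dump({"seed": seed, "config_hash": results["config_hash"],
                   "config": cfg}, fh, indent=2)
    return results
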