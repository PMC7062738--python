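"""Correlation of electric-field magnitude maps with an EEG outcome.

Per-subject 3-D field-magnitude volumes (V/m, shared grid) are correlated
voxelwise (Pearson) with a per-subject scalar EEG change, restricted to
voxels whose across-subject mean magnitude exceeds a physiological
threshold (default 0.5 V/m).  Voxels beyond an uncorrected |r| cutoff form
positive and negative masks; the overall strength of each signed mask is
its mean correlation coefficient, tested by shuffling subject outcomes.
The shuffle null re-derives the signed masks for every permutation, so
the selection step cannot double-dip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sst

from .synth import FieldMapSet


@dataclass
class CorrelationMap:
    r: np.ndarray  # full grid, nan outside the inclusion mask
    mask: np.ndarray  # inclusion (mean field > threshold)
    pos_mask: np.ndarray  # r > +cutoff
    neg_mask: np.ndarray  # r < -cutoff
    r_cutoff: float
    flagged_voxels: int = 0  # zero-variance voxels, r forced to 0


def critical_r(n: int, p: float = 0.01, two_sided: bool = True) -> float:
    """Analytic Pearson-r cutoff at significance p for sample size n."""
    if n < 4:
        raise ValueError("need at least 4 subjects")
    df = n - 2
    q = 1 - p / 2 if two_sided else 1 - p
    t = sst.t.ppf(q, df)
    return float(t / np.sqrt(t**2 + df))


def field_mask(maps: FieldMapSet, threshold: float = 0.5) -> np.ndarray:
    """Voxels whose across-subject mean magnitude exceeds ``threshold`` V/m."""
    if maps.n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    return maps.fields.mean(axis=0) > threshold


def _standardize_columns(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    ok = sd > 0
    z = np.where(ok, (x - mu) / np.where(ok, sd, 1.0), 0.0)
    return z, ok


def voxel_correlation(
    maps: FieldMapSet,
    outcomes: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    threshold: float = 0.5,
    r_cutoff: float | None = None,
    cutoff_p: float = 0.01,
) -> CorrelationMap:
    """Voxelwise Pearson r of in-mask field magnitudes against outcomes.

    ``r_cutoff`` defaults to the analytic two-sided critical r at
    ``cutoff_p`` for the actual N; pass a literal value to override.
    Zero-variance voxels get r = 0 and are counted as flagged.
    """
    outcomes = maps.outcomes if outcomes is None else np.asarray(outcomes, float)
    n = maps.n_subjects
    if n < 4:
        raise ValueError("need at least 4 subjects")
    if outcomes.shape != (n,):
        raise ValueError("outcomes must have one scalar per subject")
    if outcomes.std() == 0:
        raise ValueError("constant outcome: correlations undefined")
    if mask is None:
        mask = field_mask(maps, threshold)
    if mask.shape != maps.fields.shape[1:]:
        raise ValueError("mask grid does not match the field grid")
    if r_cutoff is None:
        r_cutoff = critical_r(n, cutoff_p, two_sided=True)

    flat = maps.fields[:, mask]  # (n, V)
    zf, ok = _standardize_columns(flat)
    zo = (outcomes - outcomes.mean()) / outcomes.std()
    rvec = zo @ zf / n
    rvec[~ok] = 0.0

    r = np.full(maps.fields.shape[1:], np.nan)
    r[mask] = rvec
    pos = np.zeros_like(mask)
    neg = np.zeros_like(mask)
    pos[mask] = rvec > r_cutoff
    neg[mask] = rvec < -r_cutoff
    return CorrelationMap(r, mask, pos, neg, float(r_cutoff), int((~ok).sum()))


def mean_corr_test(
    maps: FieldMapSet,
    outcomes: np.ndarray | None = None,
    threshold: float = 0.5,
    r_cutoff: float | None = None,
    cutoff_p: float = 0.01,
    n_perm: int = 10000,
    seed: int = 0,
) -> dict:
    """Shuffle test on the mean correlation within the signed masks.

    For every permutation of subject outcomes the voxelwise correlations
    and the signed masks are recomputed; the null statistic is the mean r
    over the re-derived mask (0 when empty).  The returned dict carries,
    per sign, the observed mean r, the permutation p-value and the mask
    size; a side with an empty observed mask is reported as skipped.
    """
    outcomes = maps.outcomes if outcomes is None else np.asarray(outcomes, float)
    cmap = voxel_correlation(
        maps, outcomes, threshold=threshold, r_cutoff=r_cutoff, cutoff_p=cutoff_p
    )
    cutoff = cmap.r_cutoff
    n = maps.n_subjects

    flat = maps.fields[:, cmap.mask]
    zf, ok = _standardize_columns(flat)
    zo = (outcomes - outcomes.mean()) / outcomes.std()

    rng = np.random.default_rng(seed)
    perms = np.stack([zo[rng.permutation(n)] for _ in range(n_perm)])
    null_r = perms @ zf / n  # (n_perm, V)
    null_r[:, ~ok] = 0.0

    def _mean_in(rows: np.ndarray, mask2d: np.ndarray) -> np.ndarray:
        counts = mask2d.sum(axis=1)
        sums = np.where(mask2d, rows, 0.0).sum(axis=1)
        return np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)

    null_pos = _mean_in(null_r, null_r > cutoff)
    null_neg = _mean_in(null_r, null_r < -cutoff)

    out = {"r_cutoff": cutoff, "n_perm": int(n_perm), "seed": int(seed)}
    rvec = cmap.r[cmap.mask]
    for sign, mask3d, null in (
        ("positive", cmap.pos_mask, null_pos),
        ("negative", cmap.neg_mask, null_neg),
    ):
        size = int(mask3d.sum())
        if size == 0:
            out[sign] = {"skipped": True, "n_voxels": 0}
            continue
        obs = float(rvec[mask3d[cmap.mask]].mean())
        if sign == "positive":
            count = int((null >= obs - 1e-12).sum())
        else:
            count = int((null <= obs + 1e-12).sum())
        out[sign] = {
            "skipped": False,
            "n_voxels": size,
            "mean_r": obs,
            "p_value": (1 + count) / (n_perm + 1),
        }
    return out


def save_field_maps(maps: FieldMapSet, path) -> None:
    """Write the per-subject volumes as a 4-D NIfTI (x, y, z, subject) with
    outcomes and the hotspot region in a JSON sidecar."""
    import json
    from pathlib import Path

    import nibabel as nib

    img = nib.Nifti1Image(np.moveaxis(maps.fields, 0, -1), affine=np.eye(4))
    nib.save(img, str(path))
    sidecar = Path(str(path)).with_suffix("").with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "outcomes": [float(o) for o in maps.outcomes],
                "region": [[int(i) for i in idx] for idx in np.argwhere(maps.region)],
            }
        )
    )


def load_field_maps(path) -> FieldMapSet:
    import json
    from pathlib import Path

    import nibabel as nib

    vol = np.asarray(nib.load(str(path)).dataobj)
    fields = np.moveaxis(vol, -1, 0)
    sidecar = Path(str(path)).with_suffix("").with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    region = np.zeros(fields.shape[1:], bool)
    for idx in meta["region"]:
        region[tuple(idx)] = True
    return FieldMapSet(
        fields=fields, outcomes=np.asarray(meta["outcomes"]), region=region
    )
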