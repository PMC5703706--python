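"""Group-level statistics on lag maps.

Three analyses, mirroring a pre/post intervention study with an aging
control cohort:

- ``paired_contrast``: voxel-wise paired t-test on (post − pre) lag with
  cluster-extent inference.  Cluster-level p-values come from a
  sign-flipping permutation null of the maximum cluster size (exhaustive
  over all 2^n sign assignments when n ≤ 12), with a liberal height
  threshold (p < 0.005 uncorrected) and a conservative cluster criterion
  (corrected p < 0.005).
- ``roi_group_compare``: per-subject ROI phase (mean lag over valid ROI
  voxels) compared across groups with Welch's t-test, or within subjects
  with a paired t-test.
- ``age_regression``: voxel-wise OLS of lag on [intercept, age, sex],
  two-sided t on the age coefficient, Benjamini–Hochberg FDR across
  voxels, and removal of small clusters; positive and negative age
  effects are reported separately.

Voxels flagged invalid by lag mapping (the −7 sentinel) are excluded from
all statistics: carrying the sentinel into means would corrupt every test.
Cluster connectivity is 6-neighbour (face) throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DesignError, LagflowError, ParameterError
from .lagmap import LagMap, relative_phase

__all__ = [
    "smooth_gaussian",
    "paired_contrast",
    "roi_group_compare",
    "age_regression",
    "ClusterResult",
    "PairedContrastResult",
    "RoiCompareResult",
    "RegressionResult",
    "cluster_voxels_for_volume",
]

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def cluster_voxels_for_volume(volume_mm3: float, voxel_sizes_mm: np.ndarray | float) -> int:
    """Convert a cluster-volume threshold (mm³) into a voxel count.

    The canonical 200-voxel threshold is defined on 2 mm isotropic maps
    (1600 mm³); this helper keeps the *volume* criterion fixed when maps
    use a different voxel size.
    """
    v = np.prod(np.broadcast_to(np.asarray(voxel_sizes_mm, float), (3,)))
    return max(1, int(round(volume_mm3 / v)))


# ---------------------------------------------------------------------------
def smooth_gaussian(
    data: np.ndarray | LagMap,
    fwhm: float = 6.0,
    voxel_sizes: np.ndarray | float | None = None,
    valid: np.ndarray | None = None,
) -> np.ndarray:
    """Mask-normalized Gaussian smoothing (FWHM in mm) over valid voxels.

    Invalid voxels neither contribute to nor receive smoothed values; the
    kernel weights are renormalized over the valid neighbourhood, so
    constant fields pass through unchanged.  ``fwhm=0`` is the identity.
    Returns an array that is 0 outside the valid set.
    """
    if isinstance(data, LagMap):
        valid = data.valid if valid is None else valid
        if voxel_sizes is None:
            voxel_sizes = np.sqrt((data.affine[:3, :3] ** 2).sum(axis=0))
        data = data.lag
    data = np.asarray(data, dtype=float)
    if valid is None:
        valid = np.ones(data.shape, dtype=bool)
    if voxel_sizes is None:
        raise ParameterError("voxel_sizes (or a LagMap with affine) is required")
    vs = np.broadcast_to(np.asarray(voxel_sizes, dtype=float), (3,))
    if fwhm < 0:
        raise ParameterError("fwhm must be non-negative")
    if fwhm == 0:
        return np.where(valid, data, 0.0)
    if fwhm < vs.min():
        warnings.warn(
            f"FWHM {fwhm} mm is below the voxel size {vs}; smoothing will do little",
            stacklevel=2,
        )
    sigma_vox = (fwhm * FWHM_TO_SIGMA) / vs
    w = valid.astype(float)
    num = ndimage.gaussian_filter(np.where(valid, data, 0.0), sigma=sigma_vox)
    den = ndimage.gaussian_filter(w, sigma=sigma_vox)
    out = np.zeros_like(data)
    np.divide(num, den, out=out, where=den > 1e-12)
    out[~valid] = 0.0
    return out


# ---------------------------------------------------------------------------
@dataclass
class ClusterResult:
    """Supra-threshold clusters from one contrast direction."""

    label_map: np.ndarray  # int labels, 0 = background
    table: pd.DataFrame  # cluster_id, size, peak_stat, p_corr, centroid columns
    height_threshold: float  # t threshold applied
    direction: str  # 'decrease' | 'increase' | 'positive' | 'negative'

    @property
    def significant(self) -> pd.DataFrame:
        if "significant" in self.table:
            return self.table[self.table["significant"]]
        return self.table

    @property
    def n_significant(self) -> int:
        return int(len(self.significant))

    def significant_mask(self) -> np.ndarray:
        mask = np.zeros(self.label_map.shape, dtype=bool)
        for cid in self.significant.get("cluster_id", []):
            mask |= self.label_map == cid
        return mask


@dataclass
class PairedContrastResult:
    t_map: np.ndarray
    df: int
    decrease: ClusterResult  # post < pre (shortened drainage time)
    increase: ClusterResult  # post > pre
    n_permutations: int
    exhaustive: bool


def _as_stack(maps) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Stack LagMaps/arrays -> (n, X, Y, Z) plus conjunction valid mask."""
    arrs, valids, affine = [], [], None
    for m in maps:
        if isinstance(m, LagMap):
            arrs.append(m.lag)
            valids.append(m.valid & m.mask)
            affine = m.affine
        else:
            arrs.append(np.asarray(m, dtype=float))
            valids.append(np.ones(arrs[-1].shape, dtype=bool))
    stack = np.stack(arrs)
    valid = np.logical_and.reduce(valids)
    return stack, valid, affine


_T_CAP = 1e4  # cap for infinite t (zero residual variance) in cluster masses


def _cluster_table(
    stat: np.ndarray, supra: np.ndarray, affine: np.ndarray | None
) -> tuple[np.ndarray, pd.DataFrame]:
    labels, n = ndimage.label(supra, structure=_FACE_STRUCT)
    capped = np.minimum(stat, _T_CAP)
    rows = []
    for cid in range(1, n + 1):
        sel = labels == cid
        size = int(sel.sum())
        peak = float(stat[sel].max())
        cent = np.array(ndimage.center_of_mass(sel))
        row = {
            "cluster_id": cid,
            "size": size,
            "mass": float(capped[sel].sum()),
            "peak_stat": peak,
            "centroid_x": cent[0],
            "centroid_y": cent[1],
            "centroid_z": cent[2],
        }
        if affine is not None:
            world = affine @ np.array([*cent, 1.0])
            row.update(
                centroid_mm_x=world[0], centroid_mm_y=world[1], centroid_mm_z=world[2]
            )
        rows.append(row)
    cols = ["cluster_id", "size", "mass", "peak_stat",
            "centroid_x", "centroid_y", "centroid_z"]
    table = pd.DataFrame(rows) if rows else pd.DataFrame(columns=cols)
    return labels, table


def _paired_t(diffs: np.ndarray) -> np.ndarray:
    """Paired t per column of an (n, V) difference matrix; 0/0 -> 0."""
    n = diffs.shape[0]
    m = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    se = sd / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / se
    t = np.where(se == 0, np.where(m == 0, 0.0, np.sign(m) * np.inf), t)
    return t


def check_pairing(design: pd.DataFrame) -> None:
    """Ensure each subject contributes exactly one pre and one post map."""
    counts = design.groupby(["subject_id", "session"]).size().unstack(fill_value=0)
    for sess in ("pre", "post"):
        if sess not in counts.columns or not (counts[sess] == 1).all():
            raise DesignError(
                "paired analysis needs exactly one pre and one post map per subject"
            )


def paired_contrast(
    pre_maps,
    post_maps,
    design: pd.DataFrame | None = None,
    height_p: float = 0.005,
    cluster_p: float = 0.005,
    n_perm: int = 2000,
    mask: np.ndarray | None = None,
    affine: np.ndarray | None = None,
    seed: int | None = 0,
    cluster_stat: str = "mass",
) -> PairedContrastResult:
    """Voxel-wise paired t-test with sign-flipping cluster-level inference.

    ``pre_maps``/``post_maps`` are matched lists of smoothed maps (arrays)
    or LagMaps.  Both contrast directions are computed: ``decrease``
    (post − pre < 0, shortened drainage time) and ``increase``.  With
    n ≤ 12 subjects all 2^n sign assignments are enumerated and cluster
    p-values are exact; otherwise ``n_perm`` random sign flips are drawn.

    ``cluster_stat`` selects the cluster-level statistic compared against
    the permutation null of its maximum: ``"mass"`` (sum of suprathreshold
    t, the default) or ``"extent"`` (voxel count).  Mass is the default
    because extent is coarse-grained under exhaustive sign flipping at
    small n: near-complete flip patterns reproduce almost the same
    suprathreshold footprint as the identity, putting a floor of roughly
    ``2(n + 1)/2^n`` on the corrected p of a strong homogeneous effect —
    above stringent cluster thresholds at n ≈ 11.  Mass separates the
    identity from near-flips by the statistic's magnitude and does not
    suffer this floor.  Cluster tables always report both size and mass.
    """
    if cluster_stat not in ("mass", "extent"):
        raise ParameterError("cluster_stat must be 'mass' or 'extent'")
    if len(pre_maps) != len(post_maps) or len(pre_maps) == 0:
        raise DesignError("pre and post map lists must be matched and non-empty")
    if design is not None:
        check_pairing(design)
    n = len(pre_maps)
    pre_stack, pre_valid, aff = _as_stack(pre_maps)
    post_stack, post_valid, aff2 = _as_stack(post_maps)
    affine = affine if affine is not None else (aff or aff2)
    valid = pre_valid & post_valid
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    if not valid.any():
        raise DesignError("no jointly valid voxels across the cohort")

    exhaustive = n <= 12
    if exhaustive:
        signs = np.array(
            [[1 if (i >> j) & 1 else -1 for j in range(n)] for i in range(2**n)],
            dtype=float,
        )
        n_used = signs.shape[0]
        min_p = 1.0 / n_used
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        n_used = n_perm
        min_p = 1.0 / (n_perm + 1)
    if min_p > cluster_p:
        raise DesignError(
            f"{n} pairs admit a minimum attainable cluster p of {min_p:.3g}, "
            f"which cannot reach cluster_p={cluster_p}; more subjects or "
            "permutations are required"
        )

    diffs = (post_stack - pre_stack)[:, valid]  # (n, V)
    t_obs = _paired_t(diffs)
    df = n - 1
    t_thr = float(sps.t.isf(height_p, df))

    # permutation t-matrix: the per-voxel sum of squares is sign-invariant
    ss = (diffs**2).sum(axis=0)
    means = signs @ diffs / n  # (P, V)
    with np.errstate(divide="ignore", invalid="ignore"):
        var = (ss[None, :] - n * means**2) / (n - 1)
        var = np.maximum(var, 0.0)
        t_perm = means / np.sqrt(var / n)
    t_perm = np.where(
        var == 0, np.where(means == 0, 0.0, np.sign(means) * np.inf), t_perm
    )

    shape = valid.shape
    results = {}
    for direction, sgn in (("decrease", -1.0), ("increase", 1.0)):
        stat_v = sgn * t_obs
        stat3d = np.zeros(shape)
        stat3d[valid] = stat_v
        supra = np.zeros(shape, dtype=bool)
        supra[valid] = stat_v > t_thr
        labels, table = _cluster_table(stat3d, supra, affine)

        # permutation null of the maximum cluster statistic
        perm_stat = np.minimum(sgn * t_perm, _T_CAP)  # (P, V)
        perm_supra = perm_stat > t_thr
        null_max = np.zeros(n_used)
        buf = np.zeros(shape, dtype=bool)
        sbuf = np.zeros(shape)
        for p_i in range(n_used):
            buf[:] = False
            buf[valid] = perm_supra[p_i]
            lab, nlab = ndimage.label(buf, structure=_FACE_STRUCT)
            if not nlab:
                continue
            if cluster_stat == "extent":
                null_max[p_i] = np.bincount(lab.ravel())[1:].max()
            else:
                sbuf[:] = 0.0
                sbuf[valid] = perm_stat[p_i]
                null_max[p_i] = ndimage.sum_labels(
                    sbuf, lab, index=np.arange(1, nlab + 1)
                ).max()

        if len(table):
            obs_stat = table["size"] if cluster_stat == "extent" else table["mass"]
            if exhaustive:
                pvals = [float(np.mean(null_max >= s)) for s in obs_stat]
            else:
                pvals = [
                    float((1 + np.sum(null_max >= s)) / (n_used + 1)) for s in obs_stat
                ]
            table["p_corr"] = pvals
            table["significant"] = table["p_corr"] < cluster_p
        else:
            table["p_corr"] = pd.Series(dtype=float)
            table["significant"] = pd.Series(dtype=bool)
        results[direction] = ClusterResult(
            label_map=labels, table=table, height_threshold=t_thr, direction=direction
        )

    t_map = np.zeros(shape)
    t_map[valid] = t_obs
    return PairedContrastResult(
        t_map=t_map,
        df=df,
        decrease=results["decrease"],
        increase=results["increase"],
        n_permutations=n_used,
        exhaustive=exhaustive,
    )


# ---------------------------------------------------------------------------
@dataclass
class RoiCompareResult:
    values: dict[str, np.ndarray]  # group label -> per-subject ROI phases (s)
    means: dict[str, float]
    difference: float  # first group mean - second group mean
    t: float
    p: float
    paired: bool


def roi_group_compare(
    maps,
    roi: np.ndarray,
    design: pd.DataFrame,
    groups: tuple[str, str] | None = None,
    paired: bool = False,
) -> RoiCompareResult:
    """Compare ROI phase (mean valid lag, s) between two groups or sessions.

    Unpaired comparisons use Welch's two-sample t-test between the two
    ``groups`` labels of ``design['group']``; ``paired=True`` compares the
    two ``design['session']`` labels within subjects with a paired t-test.
    ``maps`` is ordered like the rows of ``design``.
    """
    if len(maps) != len(design):
        raise DesignError("one map per design row is required")
    phases = np.array([relative_phase(m, roi) for m in maps])
    col = "session" if paired else "group"
    if groups is None:
        labels = list(pd.unique(design[col]))
        if len(labels) != 2:
            raise DesignError(f"expected exactly two {col} labels, found {labels}")
        groups = (labels[0], labels[1])
    a = phases[(design[col] == groups[0]).to_numpy()]
    b = phases[(design[col] == groups[1]).to_numpy()]
    if len(a) < 2 or len(b) < 2:
        raise DesignError("each group needs at least two subjects")
    if paired:
        if len(a) != len(b):
            raise DesignError("paired comparison needs equal session counts")
        t, p = sps.ttest_rel(a, b)
    else:
        t, p = sps.ttest_ind(a, b, equal_var=False)
    return RoiCompareResult(
        values={groups[0]: a, groups[1]: b},
        means={groups[0]: float(a.mean()), groups[1]: float(b.mean())},
        difference=float(a.mean() - b.mean()),
        t=float(t),
        p=float(p),
        paired=paired,
    )


# ---------------------------------------------------------------------------
@dataclass
class RegressionResult:
    beta_age: np.ndarray  # s per year
    t_age: np.ndarray
    p_age: np.ndarray
    fdr_significant: np.ndarray  # bool, before cluster-size filtering
    positive: ClusterResult  # age-positive effects after size filtering
    negative: ClusterResult
    valid: np.ndarray
    df_resid: int

    def significant_mask(self) -> np.ndarray:
        return self.positive.significant_mask() | self.negative.significant_mask()


def _design_matrix(design: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    age = design["age"].to_numpy(dtype=float)
    sex = pd.Categorical(design["sex"]).codes.astype(float)
    X = np.column_stack([np.ones(len(design)), age, sex])
    return X, ["intercept", "age", "sex"]


def age_regression(
    maps,
    design: pd.DataFrame,
    fdr_q: float = 0.05,
    min_cluster: int = 200,
    mask: np.ndarray | None = None,
) -> RegressionResult:
    """Voxel-wise OLS of lag on [intercept, age, sex] with FDR + size filter.

    Two-sided t on the age coefficient, Benjamini–Hochberg FDR at
    ``fdr_q`` over jointly valid in-mask voxels, then face-connected
    clusters smaller than ``min_cluster`` voxels are discarded.  Positive
    (drainage time extends with age) and negative effects are reported as
    separate cluster sets.
    """
    if len(maps) != len(design):
        raise DesignError("one map per design row is required")
    X, names = _design_matrix(design)
    n, k = X.shape
    if n < k + 2:
        raise DesignError(
            f"regression needs at least {k + 2} subjects for {k} model columns, got {n}"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(X[:, 1:], rowvar=False)
        bad = [
            f"{names[1 + i]}~{names[1 + j]}"
            for i in range(corr.shape[0])
            for j in range(i + 1, corr.shape[0])
            if abs(corr[i, j]) > 0.999
        ]
        degenerate = [names[1 + i] for i in range(k - 1) if np.ptp(X[:, 1 + i]) == 0]
        culprit = ", ".join(bad + degenerate) or "unknown columns"
        raise DesignError(f"design matrix is rank-deficient (collinear: {culprit})")

    stack, valid, affine = _as_stack(maps)
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    if not valid.any():
        raise DesignError("no jointly valid voxels across the cohort")
    Y = stack[:, valid]  # (n, V)

    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y  # (k, V)
    resid = Y - X @ beta
    dfree = n - k
    sigma2 = (resid**2).sum(axis=0) / dfree
    se_age = np.sqrt(sigma2 * XtX_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t_age = beta[1] / se_age
    t_age = np.where(se_age == 0, 0.0, t_age)
    p_age = 2.0 * sps.t.sf(np.abs(t_age), dfree)

    rejected, _, _, _ = multipletests(p_age, alpha=fdr_q, method="fdr_bh")[:4]

    shape = valid.shape
    beta3d = np.zeros(shape)
    t3d = np.zeros(shape)
    p3d = np.ones(shape)
    sig3d = np.zeros(shape, dtype=bool)
    beta3d[valid] = beta[1]
    t3d[valid] = t_age
    p3d[valid] = p_age
    sig3d[valid] = rejected

    results = {}
    for direction, sel in (
        ("positive", sig3d & (t3d > 0)),
        ("negative", sig3d & (t3d < 0)),
    ):
        stat = t3d if direction == "positive" else -t3d
        labels, table = _cluster_table(stat, sel, affine)
        if len(table):
            table["significant"] = table["size"] >= min_cluster
        else:
            table["significant"] = pd.Series(dtype=bool)
        keep = np.isin(labels, table.loc[table["significant"], "cluster_id"].to_numpy())
        labels = np.where(keep, labels, 0)
        results[direction] = ClusterResult(
            label_map=labels, table=table, height_threshold=np.nan, direction=direction
        )

    return RegressionResult(
        beta_age=beta3d,
        t_age=t3d,
        p_age=p3d,
        fdr_significant=sig3d,
        positive=results["positive"],
        negative=results["negative"],
        valid=valid,
        df_resid=dfree,
    )
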