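"""Synthetic cohorts, phantoms and immunofluorescence fixtures.

Everything here generates data with *known ground truth* so the
downstream statistics (rank correlations, edge tests, graph metrics,
ANOVAs) can be validated end-to-end without acquisition data.

The cohort generator draws multivariate Gaussian uptake vectors whose
rank-correlation structure is controlled exactly: Spearman targets are
converted to the Pearson correlations of the generating Gaussian with
the closed form ``r_pearson = 2 sin(pi r_spearman / 6)``, so the
configured values are recoverable by the Spearman stage at large n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pandas as pd

from .regions import RegionSet, default_region_set
from .tables import UptakeTable

#: units tag for generated cohorts: drawn on the ratio-to-global scale but
#: not re-projected to per-subject mean exactly 1 (see docs/methods.md)
UNITS_SIMULATED = "simulated_ratio"


def spearman_to_pearson(rho_s):
    """Pearson correlation of a bivariate Gaussian with Spearman rho_s."""
    return 2.0 * np.sin(np.pi * np.asarray(rho_s) / 6.0)


def pearson_to_spearman(r):
    """Population Spearman correlation of a bivariate Gaussian with Pearson r."""
    return (6.0 / np.pi) * np.arcsin(np.asarray(r) / 2.0)


@dataclass(frozen=True)
class LesionEffect:
    """Regional mean shifts plus edge-level correlation overrides.

    ``mean_shift`` maps region code -> additive shift on the uptake scale.
    ``edge_overrides`` is a list of ``(region_a, region_b, target_spearman)``
    replacing the block value for that pair.
    """

    mean_shift: dict[str, float] = field(default_factory=dict)
    edge_overrides: tuple[tuple[str, str, float], ...] = ()


@dataclass
class CohortConfig:
    region_set: RegionSet
    group_labels: list[str]
    n_per_group: dict[str, int]
    base_means: dict[str, float]
    #: target Spearman correlations: (within-cortical, within-subcortical,
    #: cortico-subcortical), each in (-1, 1)
    block_correlations: tuple[float, float, float]
    #: baseline edge-level overrides applied to every group after the block
    #: fill (e.g. to wire a hub into the healthy network)
    base_edge_overrides: tuple[tuple[str, str, float], ...] = ()
    lesion_effect: LesionEffect = field(default_factory=LesionEffect)
    #: fraction in [0, 1] by which lesion shifts/overrides are reverted in
    #: treated lesioned groups
    treatment_effect: float = 0.0
    lesioned_groups: tuple[str, ...] = ()
    treated_groups: tuple[str, ...] = ()
    noise_sd: dict[str, float] | float = 0.08
    seed: int = 0
    #: maximum Frobenius distance tolerated for the nearest-PSD repair
    max_repair_distance: float = 0.5

    def __post_init__(self) -> None:
        for g in self.group_labels:
            n = self.n_per_group.get(g, 0)
            if n < 4:
                raise ValueError(
                    f"group {g!r} has n={n}; need >= 4 (the Fisher Z test "
                    "variance 1/(n-3) requires n > 3)"
                )
        for r in self.block_correlations:
            if not -1.0 < r < 1.0:
                raise ValueError(f"block correlation {r} outside (-1, 1)")
        if not 0.0 <= self.treatment_effect <= 1.0:
            raise ValueError("treatment_effect must be in [0, 1]")
        missing = [c for c in self.base_means if c not in self.region_set.codes]
        if missing:
            raise ValueError(f"base_means references unknown regions {missing}")

    def noise_sd_vector(self) -> np.ndarray:
        codes = self.region_set.codes
        if isinstance(self.noise_sd, dict):
            sd = np.array([self.noise_sd.get(c, 0.0) for c in codes], float)
        else:
            sd = np.full(len(codes), float(self.noise_sd))
        if np.any(sd < 0):
            raise ValueError("noise_sd must be non-negative")
        return sd


def nearest_psd(corr: np.ndarray, tol: float = 1e-8) -> tuple[np.ndarray, float]:
    """Eigenvalue-clipping nearest-PSD repair of a correlation matrix.

    Returns the repaired matrix (unit diagonal restored) and the Frobenius
    distance from the input.
    """
    corr = np.asarray(corr, float)
    sym = (corr + corr.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() >= -tol:
        fixed = sym
    else:
        clipped = np.clip(vals, tol, None)
        fixed = (vecs * clipped) @ vecs.T
        d = np.sqrt(np.diag(fixed))
        fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed, float(np.linalg.norm(fixed - corr, "fro"))


def _group_spearman_target(config: CohortConfig, group: str) -> np.ndarray:
    """Block-fill the group's target Spearman matrix, then apply overrides.

    Overrides from the lesion effect are interpolated toward the block
    value by ``treatment_effect`` in treated lesioned groups, applied
    after the block fill and before PSD repair.
    """
    codes = config.region_set.codes
    idx = {c: i for i, c in enumerate(codes)}
    r_cc, r_ss, r_cs = config.block_correlations
    is_cortical = np.array(
        [r.region_class == "cortical" for r in config.region_set], bool
    )
    rho = np.where(
        np.outer(is_cortical, is_cortical), r_cc,
        np.where(np.outer(~is_cortical, ~is_cortical), r_ss, r_cs),
    ).astype(float)
    np.fill_diagonal(rho, 1.0)

    for a, b, value in config.base_edge_overrides:
        i, j = idx[a], idx[b]
        rho[i, j] = rho[j, i] = value

    if group in config.lesioned_groups:
        revert = config.treatment_effect if group in config.treated_groups else 0.0
        for a, b, target in config.lesion_effect.edge_overrides:
            i, j = idx[a], idx[b]
            base = rho[i, j]
            value = base + (target - base) * (1.0 - revert)
            rho[i, j] = rho[j, i] = value
    return rho


def _group_means(config: CohortConfig, group: str) -> np.ndarray:
    codes = config.region_set.codes
    mu = np.array([config.base_means.get(c, 1.0) for c in codes], float)
    if group in config.lesioned_groups:
        revert = config.treatment_effect if group in config.treated_groups else 0.0
        for c, shift in config.lesion_effect.mean_shift.items():
            mu[codes.index(c)] += shift * (1.0 - revert)
    return mu


def group_target_matrices(config: CohortConfig, group: str):
    """(target Spearman, generating Pearson after PSD repair, repair distance)."""
    rho_s = _group_spearman_target(config, group)
    r_p = spearman_to_pearson(rho_s)
    np.fill_diagonal(r_p, 1.0)
    r_p, dist = nearest_psd(r_p)
    if dist > config.max_repair_distance:
        raise ValueError(
            f"target correlation matrix for group {group!r} is indefinite "
            f"beyond repair (Frobenius repair distance {dist:.3g} > "
            f"{config.max_repair_distance}); check block correlations "
            f"{config.block_correlations} and edge overrides"
        )
    return rho_s, r_p, dist


def generate_cohort(config: CohortConfig) -> UptakeTable:
    """Draw a deterministic multi-group cohort table.

    One row per subject; marginal means equal the configured (group)
    means in expectation and exactly when ``noise_sd`` is zero.  The same
    ``config.seed`` always yields a bit-identical table.
    """
    sd = config.noise_sd_vector()
    rows = []
    for gi, group in enumerate(config.group_labels):
        n = config.n_per_group[group]
        mu = _group_means(config, group)
        _, r_p, _ = group_target_matrices(config, group)
        cov = r_p * np.outer(sd, sd)
        rng = np.random.default_rng([config.seed, gi])
        # eigen-based square root keeps sampling well-defined at zero noise
        vals, vecs = np.linalg.eigh(cov)
        root = vecs * np.sqrt(np.clip(vals, 0.0, None))
        z = rng.standard_normal((n, len(mu)))
        samples = mu + z @ root.T
        for si in range(n):
            rows.append([f"{group}_{si + 1:02d}", group, *samples[si]])
    df = pd.DataFrame(rows, columns=["subject_id", "group", *config.region_set.codes])
    return UptakeTable(df, config.region_set, units=UNITS_SIMULATED)


def default_cohort_config(seed: int = 0, n_per_group: int = 8) -> CohortConfig:
    """Study-style default: four groups (pre/post lesion x vehicle/treated).

    The block signs mirror the baseline covariance pattern of regional
    glucose uptake (positive cortico-cortical and subcortico-subcortical
    coupling, negative cortico-subcortical coupling); the lesion lowers
    uptake in the right striatum and right motor / somatosensory /
    orbitofrontal cortices and strengthens specific cortical and
    olfactory-hypothalamic edges; treatment reverts most of both.
    """
    rs = default_region_set()
    groups = ["pre_VEH", "pre_MLK", "QA_VEH", "QA_MLK"]
    base = {c: (1.05 if rs.by_code(c).region_class == "cortical" else 0.95)
            for c in rs.codes}
    lesion = LesionEffect(
        mean_shift={"R_S": -0.15, "R_MC": -0.08, "R_SSC": -0.08, "R_OFC": -0.08},
        edge_overrides=(
            ("R_Front", "R_SSC", 0.9),
            ("R_Front", "R_MC", 0.9),
            ("L_OlfB", "L_HTha", 0.3),
            ("R_HTha", "R_OFC", 0.25),
        ),
    )
    return CohortConfig(
        region_set=rs,
        group_labels=groups,
        n_per_group={g: n_per_group for g in groups},
        base_means=base,
        block_correlations=(0.5, 0.5, -0.3),
        lesion_effect=lesion,
        treatment_effect=0.8,
        lesioned_groups=("QA_VEH", "QA_MLK"),
        treated_groups=("QA_MLK",),
        noise_sd=0.08,
        seed=seed,
    )


def null_cohort_config(seed: int = 0, n_per_group: int = 8,
                       group_labels: tuple[str, str] = ("A", "B")) -> CohortConfig:
    """Two groups drawn from the same block covariance (global null)."""
    rs = default_region_set()
    return CohortConfig(
        region_set=rs,
        group_labels=list(group_labels),
        n_per_group={g: n_per_group for g in group_labels},
        base_means={c: 1.0 for c in rs.codes},
        block_correlations=(0.5, 0.5, -0.3),
        noise_sd=0.08,
        seed=seed,
    )


def injected_edge_config(
    seed: int = 0,
    n_per_group: int = 30,
    edge: tuple[str, str] = ("L_Front", "L_SSC"),
    target_rho: float = 0.8,
) -> CohortConfig:
    """Two otherwise-uncorrelated groups differing at one injected edge.

    Group "A" carries the edge at ``target_rho``; group "B" at 0.  Used
    for edge-detection power studies with known ground truth.
    """
    rs = default_region_set()
    return CohortConfig(
        region_set=rs,
        group_labels=["A", "B"],
        n_per_group={g: n_per_group for g in ("A", "B")},
        base_means={c: 1.0 for c in rs.codes},
        block_correlations=(0.0, 0.0, 0.0),
        lesion_effect=LesionEffect(edge_overrides=((edge[0], edge[1], target_rho),)),
        lesioned_groups=("A",),
        noise_sd=0.1,
        seed=seed,
    )


def hub_degradation_config(
    seed: int = 0,
    n_per_group: int = 20,
    hub: str = "R_AntHip",
    background: float = 0.6,
    hub_rho: float = 0.75,
) -> CohortConfig:
    """Two groups where the lesion decouples one hub node entirely.

    The healthy network ("A") carries uniform background coupling with
    one hub wired above it to every other region; in the degraded group
    ("B") the hub's edges are severed (target 0).  The hub elevation is
    kept within the positive-semidefinite envelope of the background
    (roughly hub_rho^2 <= background), so the configured targets are
    realised without repair distortion.
    """
    rs = default_region_set()
    others = [c for c in rs.codes if c != hub]
    return CohortConfig(
        region_set=rs,
        group_labels=["A", "B"],
        n_per_group={g: n_per_group for g in ("A", "B")},
        base_means={c: 1.0 for c in rs.codes},
        block_correlations=(background, background, background),
        base_edge_overrides=tuple((hub, c, hub_rho) for c in others),
        lesion_effect=LesionEffect(
            edge_overrides=tuple((hub, c, 0.0) for c in others)
        ),
        lesioned_groups=("B",),
        noise_sd=0.1,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Phantom volumes


@dataclass
class PhantomSpec:
    """Digital activity phantom: labelled VOIs at known activities.

    Labels are rendered as disjoint axis-aligned boxes; by default the
    volume is split into equal slabs along the first axis, one per label,
    so disjointness holds by construction.  Activities in kBq/cc.
    """

    shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    activities: dict[int, float] = field(default_factory=dict)
    background: float = 0.0
    injected_dose_MBq: float = 10.0
    time_offset_min: float = 0.0
    #: optional explicit placement: label -> ((x0,x1),(y0,y1),(z0,z1))
    boxes: dict[int, tuple[tuple[int, int], ...]] | None = None

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.activities.values()):
            raise ValueError("activities must be non-negative")
        if self.background < 0:
            raise ValueError("background must be non-negative")
        if 0 in self.activities:
            raise ValueError("label 0 is reserved for background")

    @property
    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.voxel_size_mm)) / 1000.0


def generate_phantom(spec: PhantomSpec) -> tuple[nib.Nifti1Image, nib.Nifti1Image]:
    """Render (intensity volume, integer label volume) on a shared grid.

    Every voxel of label k carries exactly the specified activity (no
    partial-volume mixing); all other voxels carry the background value.
    """
    intensity = np.full(spec.shape, spec.background, dtype=np.float64)
    labels = np.zeros(spec.shape, dtype=np.int16)
    label_values = sorted(spec.activities)

    if spec.boxes is not None:
        for k in label_values:
            (x0, x1), (y0, y1), (z0, z1) = spec.boxes[k]
            region = labels[x0:x1, y0:y1, z0:z1]
            if np.any(region != 0):
                raise ValueError(f"label {k} overlaps a previously placed label")
            labels[x0:x1, y0:y1, z0:z1] = k
            intensity[x0:x1, y0:y1, z0:z1] = spec.activities[k]
    elif label_values:
        # equal slabs along axis 0 with a one-voxel background margin
        nlab = len(label_values)
        slab = spec.shape[0] // nlab
        if slab < 3:
            raise ValueError(f"grid too small for {nlab} slab labels")
        for i, k in enumerate(label_values):
            x0, x1 = i * slab + 1, (i + 1) * slab - 1
            labels[x0:x1] = k
            intensity[x0:x1] = spec.activities[k]

    affine = np.diag([*spec.voxel_size_mm, 1.0])
    return (
        nib.Nifti1Image(intensity, affine),
        nib.Nifti1Image(labels, affine),
    )


# ---------------------------------------------------------------------------
# Immunofluorescence fixtures


def generate_ifl_image(
    shape: tuple[int, int],
    positive_fraction: float,
    contrast: float = 1.0,
    seed: int = 0,
    background: float = 0.2,
) -> tuple[np.ndarray, float]:
    """Two-level image with an exact count of immunopositive pixels.

    Exactly ``round(positive_fraction * n_pixels)`` pixels sit at
    ``background + contrast``; the rest at ``background``.  Returns the
    image and the realised fraction (count / n_pixels).
    """
    if not 0.0 <= positive_fraction <= 1.0:
        raise ValueError("positive_fraction must be in [0, 1]")
    if contrast <= 0:
        raise ValueError("contrast must be positive")
    n_pixels = int(np.prod(shape))
    count = int(round(positive_fraction * n_pixels))
    image = np.full(n_pixels, background, dtype=np.float64)
    rng = np.random.default_rng(seed)
    if count:
        bright = rng.choice(n_pixels, size=count, replace=False)
        image[bright] = background + contrast
    return image.reshape(shape), count / n_pixels
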