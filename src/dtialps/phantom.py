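"""Synthetic diffusion-MRI phantoms and simulated cohorts.

Two generators make the whole pipeline testable without any image data:

* :func:`generate_phantom` builds a periventricular tensor field with
  projection-fiber slabs (principal axis craniocaudal, z), association-fiber
  slabs (principal axis anterior-posterior, y) and a tunable additive
  right-left (x) perivascular diffusivity component inside both fiber
  regions, then synthesises DWI volumes through the tensor forward model.
  The phantom's ground-truth ALPS index has the closed form
  ``(lambda_perp + boost) / lambda_perp``.

* :func:`generate_cohort` simulates subject tables with the group structure
  of the meningioma study: meningiomas without peritumoral brain edema
  (PTBE), meningiomas with PTBE, and normal controls, with per-group ALPS
  means/SDs, a truncated-normal PTBE-volume marginal and a configurable
  Pearson correlation between PTBE volume and the tumor-side ALPS index
  (Gaussian copula with analytic attenuation correction, so the configured
  rho is the actual Pearson rho of the generated pairs).

Default parameter values are the study's printed group parameters; see the
methods note for the provenance of every default.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import alps as alps_mod
from .tensor import AcquisitionScheme, TensorField, synthesize_signals

__all__ = [
    "PhantomConfig",
    "PhantomData",
    "GroupSpec",
    "CohortConfig",
    "generate_phantom",
    "generate_cohort",
    "simulate_two_observers",
    "draw_correlated_alps_ptbe",
    "phantom_roi_pair",
    "default_cohort_config",
    "right_side_cohort_config",
    "left_side_cohort_config",
    "reference_cohort",
    "cohort_to_csv",
    "cohort_from_csv",
    "COHORT_COLUMNS",
    "GROUP_NO_PTBE",
    "GROUP_PTBE",
    "GROUP_CONTROL",
    "FIBER_LABELS",
]

GROUP_NO_PTBE = "meningioma_no_ptbe"
GROUP_PTBE = "meningioma_ptbe"
GROUP_CONTROL = "control"

#: Label values written into the phantom's fiber-ROI volume.
FIBER_LABELS = {
    "projection_right": 1,
    "association_right": 2,
    "projection_left": 3,
    "association_left": 4,
}

#: Fixed cohort CSV schema (one subject per row).
COHORT_COLUMNS = [
    "subject_id", "age", "sex", "group", "tumor_side", "tumor_grade",
    "ki67", "location", "tumor_volume", "ptbe_volume",
    "alps_right", "alps_left",
]


# ---------------------------------------------------------------------------
# Diffusion phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, diffusivities and noise of the periventricular phantom.

    Diffusivities are in mm^2/s. ``perivascular_boost`` is added to the
    x-diagonal tensor element inside both fiber regions; ``snr = 0``
    disables noise. ``n_averages`` emulates repeated signal acquisition
    (the study protocol acquired 4 averages).
    """

    grid_shape: tuple[int, int, int] = (96, 96, 4)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    lambda_parallel: float = 1.4e-3
    lambda_perp: float = 0.4e-3
    perivascular_boost: float = 0.2e-3
    background_diffusivity: float = 0.7e-3
    s0: float = 100.0
    snr: float = 30.0
    n_averages: int = 4
    b_value: float = 1000.0
    n_directions: int = 20
    n_b0: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.lambda_parallel >= self.lambda_perp > 0):
            raise ValueError("need lambda_parallel >= lambda_perp > 0")
        if self.perivascular_boost < 0:
            raise ValueError("perivascular_boost must be >= 0")
        if self.background_diffusivity <= 0:
            raise ValueError("background_diffusivity must be > 0")
        if any(g < 1 for g in self.grid_shape):
            raise ValueError("grid_shape entries must be >= 1")
        if self.snr < 0:
            raise ValueError("snr must be >= 0 (0 disables noise)")
        if self.n_averages < 1:
            raise ValueError("n_averages must be >= 1")
        if self.s0 <= 0:
            raise ValueError("s0 must be positive")

    @property
    def ground_truth_alps(self) -> float:
        """Closed-form ALPS of the phantom: (lambda_perp + boost) / lambda_perp."""
        return (self.lambda_perp + self.perivascular_boost) / self.lambda_perp


def _fiber_boxes(grid_shape) -> dict[str, tuple[slice, slice]]:
    """Axis-aligned fiber slabs at fixed fractional coordinates.

    The projection fibers sit medially (next to the ventricle), the
    association fibers laterally; the right hemisphere occupies low x.
    Slabs span all z so any axial slice carries the full geometry.
    """
    nx, ny, _ = grid_shape

    def xs(f0: float, f1: float) -> slice:
        return slice(int(round(f0 * nx)), int(round(f1 * nx)))

    ys = slice(int(round(0.3 * ny)), int(round(0.7 * ny)))
    boxes = {
        "association_right": (xs(0.10, 0.25), ys),
        "projection_right": (xs(0.25, 0.40), ys),
        "projection_left": (xs(0.60, 0.75), ys),
        "association_left": (xs(0.75, 0.90), ys),
    }
    for name, (sx, sy) in boxes.items():
        if sx.stop <= sx.start or sy.stop <= sy.start:
            raise ValueError(
                f"grid_shape {tuple(grid_shape)} too small to place fiber "
                f"region '{name}'"
            )
    return boxes


@dataclass
class PhantomData:
    """Output bundle of :func:`generate_phantom`."""

    dwi: np.ndarray                # (nx, ny, nz, n_volumes)
    scheme: AcquisitionScheme
    truth: TensorField             # noise-free ground-truth tensors
    labels: np.ndarray             # (nx, ny, nz) int fiber-ROI labels
    config: PhantomConfig

    @property
    def ground_truth_alps(self) -> float:
        return self.config.ground_truth_alps


def generate_phantom(config: PhantomConfig) -> PhantomData:
    """Build the periventricular phantom and synthesise its DWI signals.

    Projection-fiber voxels carry ``diag(lperp + boost, lperp, lpar)``
    (principal axis z), association-fiber voxels
    ``diag(lperp + boost, lpar, lperp)`` (principal axis y), the background
    is isotropic. Noise is additive Gaussian with sd ``s0 / snr`` per
    acquired average (a Rician approximation adequate at SNR >= 10);
    ``n_averages`` noisy copies are averaged. Identical configs give
    bit-identical outputs.
    """
    scheme = AcquisitionScheme.default(
        b=config.b_value, n_directions=config.n_directions, n_b0=config.n_b0
    )
    nx, ny, nz = config.grid_shape
    lpar, lperp = config.lambda_parallel, config.lambda_perp
    boost = config.perivascular_boost

    tensors = np.zeros((nx, ny, nz, 3, 3))
    for i in range(3):
        tensors[..., i, i] = config.background_diffusivity
    labels = np.zeros((nx, ny, nz), dtype=int)

    proj_diag = np.array([lperp + boost, lperp, lpar])
    assoc_diag = np.array([lperp + boost, lpar, lperp])
    for name, (sx, sy) in _fiber_boxes(config.grid_shape).items():
        diag = proj_diag if name.startswith("projection") else assoc_diag
        for i in range(3):
            tensors[sx, sy, :, i, i] = diag[i]
        labels[sx, sy, :] = FIBER_LABELS[name]

    s0 = np.full((nx, ny, nz), config.s0)
    truth = TensorField(tensors=tensors, s0=s0, voxel_size=config.voxel_size)

    clean = synthesize_signals(tensors, s0, scheme)
    if config.snr > 0:
        rng = np.random.default_rng(config.seed)
        sigma = config.s0 / config.snr
        noise = rng.normal(0.0, sigma, size=(*clean.shape, config.n_averages))
        dwi = clean + noise.mean(axis=-1)
    else:
        dwi = clean.copy()

    return PhantomData(dwi=dwi, scheme=scheme, truth=truth, labels=labels,
                       config=config)


def phantom_roi_pair(labels: np.ndarray, hemisphere: str,
                     slice_index: int | None = None
                     ) -> tuple[alps_mod.RoiMask, alps_mod.RoiMask]:
    """Single-slice (projection, association) ROI pair from a label volume."""
    proj = alps_mod.RoiMask.from_label_volume(
        labels, FIBER_LABELS[f"projection_{hemisphere}"], "projection",
        hemisphere, slice_index)
    assoc = alps_mod.RoiMask.from_label_volume(
        labels, FIBER_LABELS[f"association_{hemisphere}"], "association",
        hemisphere, slice_index)
    return proj, assoc


# ---------------------------------------------------------------------------
# Cohort simulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSpec:
    """One simulated group: sizes, ALPS marginals and demographics."""

    name: str                       # GROUP_NO_PTBE / GROUP_PTBE / GROUP_CONTROL
    n: int
    tumor_side: str                 # "right", "left" or "none"
    alps_right: tuple[float, float]  # (mean, sd)
    alps_left: tuple[float, float]
    age: tuple[float, float] = (58.8, 13.5)
    prop_man: float = 37.0 / 80.0

    def __post_init__(self) -> None:
        if self.name not in (GROUP_NO_PTBE, GROUP_PTBE, GROUP_CONTROL):
            raise ValueError(f"unknown group name {self.name!r}")
        if self.n < 2:
            raise ValueError("group sample size must be >= 2")
        for pair in (self.alps_right, self.alps_left, self.age):
            if pair[1] <= 0:
                raise ValueError("distribution SDs must be > 0")
        if self.tumor_side not in ("right", "left", "none"):
            raise ValueError("tumor_side must be right/left/none")
        if (self.name == GROUP_CONTROL) != (self.tumor_side == "none"):
            raise ValueError("controls (and only controls) have tumor_side 'none'")
        if not 0.0 <= self.prop_man <= 1.0:
            raise ValueError("prop_man must be in [0, 1]")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level parameters shared across groups.

    Defaults are the study cohort's printed parameters: PTBE volume
    67.1 +/- 46.8 cm^3 (truncated at 0), ALPS-PTBE Pearson rho = -0.68,
    tumor volume 58.6 +/- 45.3 cm^3, Ki-67 4.8 +/- 3.1 % (range 1-12),
    19/80 grade II/III tumors and 15/80 skull-base locations.
    """

    groups: tuple[GroupSpec, ...] = ()
    ptbe_volume: tuple[float, float] = (67.1, 46.8)
    rho_alps_ptbe: float = -0.68
    tumor_volume: tuple[float, float] = (58.6, 45.3)
    ki67: tuple[float, float] = (4.8, 3.1)
    prop_grade_high: float = 19.0 / 80.0
    prop_skull_base: float = 15.0 / 80.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("cohort config needs at least one group")
        if not -1.0 <= self.rho_alps_ptbe <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")
        for pair in (self.ptbe_volume, self.tumor_volume, self.ki67):
            if pair[1] <= 0:
                raise ValueError("distribution SDs must be > 0")


def right_side_cohort_config(seed: int = 0) -> CohortConfig:
    """Right-side meningioma groups plus controls at the printed parameters."""
    return CohortConfig(
        groups=(
            GroupSpec(GROUP_NO_PTBE, 13, "right", (1.502, 0.089), (1.353, 0.213)),
            GroupSpec(GROUP_PTBE, 31, "right", (1.260, 0.112), (1.263, 0.173)),
            GroupSpec(GROUP_CONTROL, 44, "none", (1.215, 0.093), (1.273, 0.105),
                      age=(53.3, 10.0), prop_man=23.0 / 44.0),
        ),
        seed=seed,
    )


def left_side_cohort_config(seed: int = 0) -> CohortConfig:
    """Left-side meningioma groups plus controls at the printed parameters."""
    return CohortConfig(
        groups=(
            GroupSpec(GROUP_NO_PTBE, 11, "left", (1.272, 0.167), (1.513, 0.198)),
            GroupSpec(GROUP_PTBE, 25, "left", (1.198, 0.204), (1.304, 0.178)),
            GroupSpec(GROUP_CONTROL, 44, "none", (1.215, 0.093), (1.273, 0.105),
                      age=(53.3, 10.0), prop_man=23.0 / 44.0),
        ),
        seed=seed,
    )


def default_cohort_config(seed: int = 0) -> CohortConfig:
    """Full study structure: both tumor sides (80 patients) plus 44 controls."""
    right = right_side_cohort_config().groups[:2]
    left = left_side_cohort_config().groups[:2]
    control = right_side_cohort_config().groups[2]
    return CohortConfig(groups=(*right, *left, control), seed=seed)


@lru_cache(maxsize=32)
def _copula_attenuation(mu: float, sd: float) -> float:
    """corr(Z, g(Z)) where g maps a standard normal through the Gaussian
    copula onto a normal(mu, sd) truncated at 0 (Gauss-Hermite quadrature)."""
    x, w = np.polynomial.hermite_e.hermegauss(151)
    w = w / np.sqrt(2.0 * np.pi)
    u = np.clip(sps.norm.cdf(x), 1e-15, 1.0 - 1e-15)
    g = sps.truncnorm.ppf(u, -mu / sd, np.inf, loc=mu, scale=sd)
    m = float(np.sum(w * g))
    var = float(np.sum(w * g * g)) - m * m
    cov = float(np.sum(w * x * g))
    return cov / np.sqrt(var)


def draw_correlated_alps_ptbe(n: int, alps_mean: float, alps_sd: float,
                              ptbe_mean: float, ptbe_sd: float, rho: float,
                              rng: np.random.Generator
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Draw (ALPS, PTBE-volume) pairs with Pearson correlation ``rho``.

    A Gaussian copula links a normal ALPS marginal to a PTBE marginal that
    is normal(ptbe_mean, ptbe_sd) truncated at 0. Because the truncation
    attenuates the Pearson correlation, the latent normal correlation is
    inflated to ``rho / lambda`` where ``lambda = corr(Z, g(Z))`` is
    computed by quadrature, so the configured rho is the actual Pearson rho
    of the generated pairs (up to sampling error).
    """
    lam = _copula_attenuation(float(ptbe_mean), float(ptbe_sd))
    latent = rho / lam
    if not -1.0 <= latent <= 1.0:
        raise ValueError(
            f"requested Pearson rho {rho} is unreachable through the "
            f"truncated-normal marginal (attenuation factor {lam:.4f})"
        )
    z1 = rng.standard_normal(n)
    z2 = latent * z1 + np.sqrt(1.0 - latent ** 2) * rng.standard_normal(n)
    alps = alps_mean + alps_sd * z1
    u = np.clip(sps.norm.cdf(z2), 1e-15, 1.0 - 1e-15)
    ptbe = sps.truncnorm.ppf(u, -ptbe_mean / ptbe_sd, np.inf,
                             loc=ptbe_mean, scale=ptbe_sd)
    return np.maximum(alps, 1e-6), ptbe


def _truncated_normal(rng: np.random.Generator, n: int, mean: float, sd: float,
                      low: float, high: float = np.inf) -> np.ndarray:
    a, b = (low - mean) / sd, (high - mean) / sd
    u = rng.uniform(size=n)
    return sps.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Simulate one cohort table (one :data:`COHORT_COLUMNS` row per subject).

    Within each group the two ALPS indices are drawn from the configured
    normal marginals; in PTBE+ groups the tumor-side ALPS and the PTBE
    volume are drawn jointly at Pearson rho via
    :func:`draw_correlated_alps_ptbe`. Ages are normal truncated to
    [18, 95], sex is Bernoulli, Ki-67 is truncated to its reported range
    [1, 12] and tumor volume to >= 1 cm^3. Seed-reproducible.
    """
    rng = np.random.default_rng(config.seed)
    rows: list[dict] = []
    counter = 0
    for grp in config.groups:
        n = grp.n
        age = _truncated_normal(rng, n, grp.age[0], grp.age[1], 18.0, 95.0)
        sex = np.where(rng.uniform(size=n) < grp.prop_man, "man", "woman")
        alps_r = np.maximum(grp.alps_right[0]
                            + grp.alps_right[1] * rng.standard_normal(n), 1e-6)
        alps_l = np.maximum(grp.alps_left[0]
                            + grp.alps_left[1] * rng.standard_normal(n), 1e-6)
        ptbe = np.zeros(n)
        if grp.name == GROUP_PTBE:
            side_mean, side_sd = (grp.alps_right if grp.tumor_side == "right"
                                  else grp.alps_left)
            ipsi, ptbe = draw_correlated_alps_ptbe(
                n, side_mean, side_sd, config.ptbe_volume[0],
                config.ptbe_volume[1], config.rho_alps_ptbe, rng)
            if grp.tumor_side == "right":
                alps_r = ipsi
            else:
                alps_l = ipsi

        if grp.name == GROUP_CONTROL:
            tumor_vol = np.zeros(n)
            grade = np.full(n, "none")
            location = np.full(n, "none")
            ki67 = np.full(n, np.nan)
        else:
            tumor_vol = _truncated_normal(rng, n, config.tumor_volume[0],
                                          config.tumor_volume[1], 1.0)
            grade = np.where(rng.uniform(size=n) < config.prop_grade_high,
                             "II_III", "I")
            location = np.where(rng.uniform(size=n) < config.prop_skull_base,
                                "skull_base", "non_skull_base")
            ki67 = _truncated_normal(rng, n, config.ki67[0], config.ki67[1],
                                     1.0, 12.0)

        for i in range(n):
            counter += 1
            rows.append({
                "subject_id": f"S{counter:04d}",
                "age": float(age[i]),
                "sex": str(sex[i]),
                "group": grp.name,
                "tumor_side": grp.tumor_side,
                "tumor_grade": str(grade[i]),
                "ki67": float(ki67[i]),
                "location": str(location[i]),
                "tumor_volume": float(tumor_vol[i]),
                "ptbe_volume": float(ptbe[i]),
                "alps_right": float(alps_r[i]),
                "alps_left": float(alps_l[i]),
            })
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def simulate_two_observers(truth: np.ndarray, noise_sd: float,
                           bias: float = 0.0, seed: int = 0
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Two independent noisy measurement vectors of the same underlying truth.

    Observer 1 is unbiased; ``bias`` is added to observer 2 only. With
    ``noise_sd = 0`` both observers reproduce the truth exactly (plus the
    fixed bias for observer 2).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    truth = np.asarray(truth, dtype=float)
    rng = np.random.default_rng(seed)
    obs1 = truth + rng.normal(0.0, noise_sd, truth.shape) if noise_sd else truth.copy()
    obs2 = truth + bias
    if noise_sd:
        obs2 = obs2 + rng.normal(0.0, noise_sd, truth.shape)
    return obs1, obs2


# ---------------------------------------------------------------------------
# Deterministic reference cohort (descriptive fixture)
# ---------------------------------------------------------------------------

_SITES = (
    ["sphenoid_ridge"] * 12 + ["parasellar"] * 1 + ["frontal_base"] * 2
    + ["convexity"] * 39 + ["parasagittal"] * 23 + ["intraventricular"] * 2
    + ["tentorium"] * 1
)
_SKULL_BASE_SITES = {"sphenoid_ridge", "parasellar", "frontal_base",
                     "tuberculum_sellae"}


def reference_cohort() -> pd.DataFrame:
    """Deterministic 80-patient table reproducing the study's descriptive margins.

    Marginal counts: 37 men / 43 women; tumor sites 12 sphenoid ridge,
    1 parasellar, 2 frontal base, 39 convexity, 23 parasagittal,
    2 intraventricular, 1 tentorium; WHO grades 61/15/4 (I/II/III); tumor
    volume bins 7/15/28/22/8 and edema volume bins 24/15/15/17/9 (zero
    edema in 24/80 = 30%); 44 right-side and 36 left-side tumors. Columns
    are assigned independently (the study publishes margins, not the joint
    table), with representative in-bin values, so bin counts are exact.
    """
    n = 80
    edema = np.array([0.0] * 24 + [14.0] * 15 + [45.0] * 15 + [90.0] * 17
                     + [150.0] * 9)
    # 13 right / 11 left among edema-free, 31 right / 25 left among edema+
    side = np.array(["right"] * 13 + ["left"] * 11 + ["right"] * 31
                    + ["left"] * 25)
    group = np.where(edema == 0.0, GROUP_NO_PTBE, GROUP_PTBE)
    tumor_vol = np.array([4.5] * 7 + [17.0] * 15 + [45.0] * 28 + [90.0] * 22
                         + [150.0] * 8)
    sex = np.array(["man"] * 37 + ["woman"] * 43)
    who = np.array(["I"] * 61 + ["II"] * 15 + ["III"] * 4)
    site = np.array(_SITES)
    alps_by = {
        ("right", GROUP_NO_PTBE): (1.502, 1.353),
        ("right", GROUP_PTBE): (1.260, 1.263),
        ("left", GROUP_NO_PTBE): (1.272, 1.513),
        ("left", GROUP_PTBE): (1.198, 1.304),
    }
    alps_r = np.array([alps_by[(s, g)][0] for s, g in zip(side, group)])
    alps_l = np.array([alps_by[(s, g)][1] for s, g in zip(side, group)])
    df = pd.DataFrame({
        "subject_id": [f"P{i + 1:03d}" for i in range(n)],
        "age": np.round(np.linspace(24.0, 90.0, n), 1),
        "sex": sex,
        "group": group,
        "tumor_side": side,
        "tumor_grade": np.where(who == "I", "I", "II_III"),
        "ki67": np.round(np.linspace(1.0, 12.0, n), 1),
        "location": np.where(np.isin(site, sorted(_SKULL_BASE_SITES)),
                             "skull_base", "non_skull_base"),
        "tumor_volume": tumor_vol,
        "ptbe_volume": edema,
        "alps_right": alps_r,
        "alps_left": alps_l,
        "site": site,
        "who_grade": who,
    })
    return df


def cohort_to_csv(df: pd.DataFrame, path) -> None:
    """Write a cohort table with the fixed column schema first."""
    cols = COHORT_COLUMNS + [c for c in df.columns if c not in COHORT_COLUMNS]
    df.loc[:, cols].to_csv(path, index=False)


def cohort_from_csv(path) -> pd.DataFrame:
    """Read a cohort table, checking the fixed schema."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV is missing required columns: {missing}")
    return df
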