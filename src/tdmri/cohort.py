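"""Synthetic lesion cohorts and DWI phantoms with known ground truth.

No public imaging data accompany the clinical study this package targets,
so every downstream stage (fitting, ROI summaries, group statistics) is
exercised on simulated cohorts whose group-level parameter distributions
reproduce the published malignant/benign statistics:

    malignant (n = 27): d = 17.26 ± 2.88 μm, ν_in = 0.38 ± 0.10,
                        D_ex = 1.88 ± 0.25 μm²/ms
    benign    (n = 18): d = 24.13 ± 4.54 μm, ν_in = 0.24 ± 0.10,
                        D_ex = 2.24 ± 0.17 μm²/ms

Lesion parameters are independent truncated-normal draws inside the
fitting bounds (the published table reports no covariances; consequences
of the independence assumption are discussed in docs/methods.md).
Phantoms place ellipsoidal lesions (≥ 30 voxels) on a free-water
background, jitter voxel truths with a 10% coefficient of variation,
evaluate the forward IMPULSED model per voxel, and add Rician noise
scaled by 1/√nsa per acquisition.

Immunohistochemical labels (ER/PR/HER2, Ki67 dichotomized at 14%) are
assigned to malignant lesions with the study's marginal frequencies and,
by default, independently of the diffusion parameters; an optional
effect configuration shifts ν_in in PR-negative lesions to give the
subgroup tests something to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .acquisition import Protocol
from .impulsed import MicrostructureParams, DEFAULT_D_IN, impulsed_signal
from .mapfit import DWIStack, FIT_BOUNDS

__all__ = [
    "GroupDistribution",
    "SyntheticLesion",
    "MALIGNANT_DEFAULTS",
    "BENIGN_DEFAULTS",
    "ADC_REFERENCE",
    "IHC_MARGINALS",
    "draw_cohort",
    "render_phantom",
    "summarize_truth",
    "draw_adc_scores",
]

#: Free-water diffusivity used for the phantom background, μm²/ms.
FREE_WATER_D = 3.0

#: Within-lesion heterogeneity: coefficient of variation of voxel truths.
LESION_CV = 0.10

#: Default b = 0 signal-to-noise ratio of the phantom.
DEFAULT_SNR = 25.0


@dataclass(frozen=True)
class GroupDistribution:
    """Group-level microstructure distribution for cohort simulation."""

    label: str
    d_mean: float
    d_sd: float
    v_in_mean: float
    v_in_sd: float
    d_ex_mean: float
    d_ex_sd: float
    n_lesions: int

    def __post_init__(self) -> None:
        if self.label not in ("malignant", "benign"):
            raise ValueError("label must be 'malignant' or 'benign'")
        if min(self.d_sd, self.v_in_sd, self.d_ex_sd) < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.n_lesions < 1:
            raise ValueError("n_lesions must be positive")


MALIGNANT_DEFAULTS = GroupDistribution(
    label="malignant", d_mean=17.26, d_sd=2.88, v_in_mean=0.38, v_in_sd=0.10,
    d_ex_mean=1.88, d_ex_sd=0.25, n_lesions=27,
)
BENIGN_DEFAULTS = GroupDistribution(
    label="benign", d_mean=24.13, d_sd=4.54, v_in_mean=0.24, v_in_sd=0.10,
    d_ex_mean=2.24, d_ex_sd=0.17, n_lesions=18,
)

#: Published group ADC distributions (mean, sd) in ×10⁻³ mm²/s, used when a
#: test or benchmark needs ADC scores without rendering a phantom.
ADC_REFERENCE = {
    "malignant": {"adc_0hz": (0.88, 0.12), "adc_25hz": (1.30, 0.19),
                  "adc_50hz": (1.81, 0.28)},
    "benign": {"adc_0hz": (1.24, 0.21), "adc_25hz": (1.77, 0.18),
               "adc_50hz": (2.16, 0.24)},
}

#: Marginal frequencies of positive immunohistochemical status among the
#: malignant lesions (Ki67 positive means >= 14%).
IHC_MARGINALS = {"ER": 14 / 27, "PR": 11 / 27, "HER2": 11 / 27, "Ki67": 23 / 27}


@dataclass
class SyntheticLesion:
    """One simulated lesion: scalar truth, labels and (after rendering)
    voxel-level truths and a mask into the phantom grid."""

    lesion_id: int
    group: str
    truth: MicrostructureParams
    ihc: dict[str, bool] = field(default_factory=dict)
    seed: int = 0
    voxel_mask: np.ndarray | None = None       # boolean, phantom grid
    voxel_truth: pd.DataFrame | None = None    # per-voxel jittered truth


def _truncnorm_draw(rng, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def draw_cohort(
    groups: tuple[GroupDistribution, ...] = (MALIGNANT_DEFAULTS, BENIGN_DEFAULTS),
    seed: int | np.random.Generator = 0,
    d_in: float = DEFAULT_D_IN,
    pr_negative_v_in_shift: float = 0.0,
) -> list[SyntheticLesion]:
    """Draw a lesion cohort: independent truncated-normal (d, ν_in, D_ex)
    per lesion, truncated to the fitting bounds so recovery is well posed.

    ``pr_negative_v_in_shift`` optionally raises ν_in of PR-negative
    malignant lesions (re-truncated), linking one marker to the
    microstructure for subgroup-test power experiments.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lesions: list[SyntheticLesion] = []
    lid = 0
    for grp in groups:
        n = grp.n_lesions
        d = _truncnorm_draw(rng, grp.d_mean, grp.d_sd, *FIT_BOUNDS["d"], n)
        v = _truncnorm_draw(rng, grp.v_in_mean, grp.v_in_sd, *FIT_BOUNDS["v_in"], n)
        de = _truncnorm_draw(rng, grp.d_ex_mean, grp.d_ex_sd, *FIT_BOUNDS["d_ex"], n)
        for i in range(n):
            ihc = {}
            if grp.label == "malignant":
                ihc = {m: bool(rng.random() < p) for m, p in IHC_MARGINALS.items()}
                if pr_negative_v_in_shift and not ihc["PR"]:
                    v[i] = float(np.clip(v[i] + pr_negative_v_in_shift,
                                         *FIT_BOUNDS["v_in"]))
            lesions.append(SyntheticLesion(
                lesion_id=lid, group=grp.label,
                truth=MicrostructureParams(d=float(d[i]), v_in=float(v[i]),
                                           d_ex=float(de[i]), d_in=d_in),
                ihc=ihc, seed=int(rng.integers(2**31 - 1)),
            ))
            lid += 1
    return lesions


def _ellipsoid_mask(shape, center, semi) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return r2 <= 1.0


def render_phantom(
    lesions: list[SyntheticLesion],
    protocol: Protocol,
    grid_shape: tuple[int, int, int] | None = None,
    snr: float = DEFAULT_SNR,
    seed: int = 0,
    min_voxels: int = 30,
) -> tuple[DWIStack, np.ndarray, pd.DataFrame]:
    """Render lesions into a noisy 4D DWI stack.

    Lesions are ellipsoids (semi-axes jittered around 2.6×2.6×1.9 voxels,
    inflated until each holds ≥ ``min_voxels`` voxels) laid out on a block
    lattice over a free-water background (D = 3.0 μm²/ms). Voxel-level
    truths are the lesion truth with 10% CV Gaussian jitter, truncated to
    the fitting bounds. Signals come from the forward IMPULSED model with
    S(b=0) = 1; Rician noise uses σ = S(0)/(snr·√nsa) per acquisition
    (``snr=np.inf`` disables noise). Returns the stack, an integer label
    volume (0 = background, lesion_id + 1 inside lesions) and the
    ground-truth table from :func:`summarize_truth`.
    """
    rng = np.random.default_rng(seed)
    n = len(lesions)
    block = (9, 9, 7)
    ncol = int(np.ceil(np.sqrt(n)))
    nrow = int(np.ceil(n / ncol))
    if grid_shape is None:
        grid_shape = (ncol * block[0], nrow * block[1], block[2])
    label_vol = np.zeros(grid_shape, dtype=np.int16)
    index = [(s.label, b) for s in protocol.sequences for b in s.b_values]
    nsa = np.array([protocol[lab].nsa[protocol[lab].b_values.index(b)]
                    for lab, b in index], dtype=float)
    n_acq = len(index)
    data = np.empty(grid_shape + (n_acq,), dtype=float)

    # background: free water, no restriction
    bg = np.array([np.exp(-b * FREE_WATER_D * 1e-3) for _, b in index])
    data[:] = bg

    for k, lesion in enumerate(lesions):
        ci = (k % ncol) * block[0] + block[0] // 2
        cj = (k // ncol) * block[1] + block[1] // 2
        ck = block[2] // 2
        semi = np.array([rng.uniform(2.3, 2.9), rng.uniform(2.3, 2.9),
                         rng.uniform(1.7, 2.1)])
        mask = _ellipsoid_mask(grid_shape, (ci, cj, ck), semi)
        while mask.sum() < min_voxels:
            semi *= 1.05
            mask = _ellipsoid_mask(grid_shape, (ci, cj, ck), semi)
        if ci + semi[0] >= grid_shape[0] or cj + semi[1] >= grid_shape[1]:
            raise ValueError("lesions do not fit in the requested grid")
        nv = int(mask.sum())
        lesion.voxel_mask = mask
        label_vol[mask] = lesion.lesion_id + 1

        t = lesion.truth
        lrng = np.random.default_rng(lesion.seed)
        vox = {}
        for name, mean in (("d", t.d), ("v_in", t.v_in), ("d_ex", t.d_ex)):
            vox[name] = _truncnorm_draw(lrng, mean, LESION_CV * mean,
                                        *FIT_BOUNDS[name], nv)
        lesion.voxel_truth = pd.DataFrame(vox)
        sig = np.empty((nv, n_acq))
        for vi in range(nv):
            pv = MicrostructureParams(d=vox["d"][vi], v_in=vox["v_in"][vi],
                                      d_ex=vox["d_ex"][vi], d_in=t.d_in)
            col = 0
            for s in protocol.sequences:
                bs = np.array(s.b_values)
                sig[vi, col:col + bs.size] = impulsed_signal(pv, s, bs)
                col += bs.size
        data[mask] = sig

    if np.isfinite(snr):
        sigma = 1.0 / (snr * np.sqrt(nsa))
        eps1 = rng.normal(0.0, 1.0, data.shape) * sigma
        eps2 = rng.normal(0.0, 1.0, data.shape) * sigma
        data = np.sqrt((data + eps1) ** 2 + eps2**2)

    stack = DWIStack(data=data, index=index)
    return stack, label_vol, summarize_truth(lesions)


def summarize_truth(lesions: list[SyntheticLesion]) -> pd.DataFrame:
    """Per-lesion ground-truth table (the oracle for recovery experiments).

    Cellularity is the mean of voxelwise ν_in/d × 100 when voxel truths
    exist (rendered phantoms), else the scalar-truth ratio.
    """
    rows = []
    for les in lesions:
        if les.voxel_truth is not None:
            vt = les.voxel_truth
            d, v, de = vt["d"].mean(), vt["v_in"].mean(), vt["d_ex"].mean()
            cell = (vt["v_in"] / vt["d"] * 100.0).mean()
        else:
            d, v, de = les.truth.d, les.truth.v_in, les.truth.d_ex
            cell = les.truth.cellularity
        row = {"lesion_id": les.lesion_id, "group": les.group,
               "d": d, "v_in": v, "d_ex": de, "cellularity": cell}
        for m in IHC_MARGINALS:
            row[m] = les.ihc.get(m)
        rows.append(row)
    return pd.DataFrame(rows)


def draw_adc_scores(
    group: str, key: str, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw per-lesion ADC values (×10⁻³ mm²/s) from the published group
    distributions; ``key`` is one of adc_0hz / adc_25hz / adc_50hz."""
    mean, sd = ADC_REFERENCE[group][key]
    return np.clip(rng.normal(mean, sd, n), 0.0, None)
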