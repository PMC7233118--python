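"""Synthetic multiparametric-MRI cohorts for the lymph-node pipeline.

The real study data (post-neoadjuvant rectal MRI with pathological node
labels) are private, so every downstream stage is exercised on cohorts
generated here.  A cohort emulates the structure the analysis assumes:

* four co-registered 2D sequences (T1w, T2w, CE-T1w, ADC) per patient,
  each a stationary correlated Gaussian random field;
* one elliptical tumour ROI mask shared by all sequences;
* a class signal injected only inside the mask — a mean shift
  (detectable by first-order features) and a change of the field's
  correlation length (detectable by co-occurrence / size-zone texture),
  with the T1w channel always uninformative;
* clinical covariates whose association with the node label mirrors the
  study population: radiologist node restaging (ymrN) reproduces a fixed
  sensitivity/specificity, tumour restaging (ymrT) is positively
  associated with the label, and sex/age/CEA/radiation are independent
  of it;
* ~22% prevalence of pathological node metastasis (LNM+) and a frozen
  2:1 primary:validation split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

SEQUENCES: Tuple[str, ...] = ("T1w", "T2w", "CET1w", "ADC")

#: ymrT stage distribution conditional on node label (study population).
_YMRT_GIVEN_POS = {1: 0.02, 2: 0.19, 3: 0.62, 4: 0.17}
_YMRT_GIVEN_NEG = {1: 0.12, 2: 0.27, 3: 0.52, 4: 0.09}
#: among radiologist-positive reads, fraction staged N1 (rest N2)
_N1_FRAC_POS = 0.56
_N1_FRAC_NEG = 0.84
#: label-independent covariate marginals
_P_MALE = 0.71
_P_CEA_POS = 0.20
_P_RADIATION = 0.41
_CT_MARGINAL = {2: 0.06, 3: 0.74, 4: 0.20}
_CN_MARGINAL = {0: 0.21, 1: 0.40, 2: 0.39}


def _effect_map(value) -> Dict[str, float]:
    """Expand a scalar or partial mapping to a per-sequence dict; T1w pinned to 0."""
    if isinstance(value, Mapping):
        out = {s: float(value.get(s, 0.0)) for s in SEQUENCES}
    else:
        out = {s: float(value) for s in SEQUENCES}
    out["T1w"] = 0.0
    return out


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one synthetic cohort.

    ``texture_effect`` scales the relative increase of the random-field
    correlation length inside the tumour mask for LNM+ patients;
    ``intensity_effect`` is the LNM+ mean shift inside the mask in units
    of the field standard deviation.  Either may be a scalar (applied to
    T2w/CE-T1w/ADC) or a per-sequence mapping; the T1w entry is forced
    to 0 so that channel carries no class signal.
    """

    n_patients: int = 391
    prevalence: float = 87 / 391
    image_size: int = 64
    texture_effect: object = 0.5
    intensity_effect: object = 0.5
    radiologist_sens: float = 0.563
    radiologist_spec: float = 0.707
    split_ratio: float = 2.0  # primary : validation
    seed: int = 0
    base_corr_length: float = 2.0
    #: SD of the per-patient, per-sequence random offset of the ROI mean, in
    #: units of the field SD.  Biological heterogeneity of this size keeps the
    #: class shift only partially detectable, as in real tumour cohorts.
    patient_sd: float = 1.0
    #: SD of the per-patient log correlation-length multiplier.  Texture
    #: features estimate the correlation length with little sampling error
    #: over a whole ROI, so without this spread any nonzero texture effect
    #: would separate the classes perfectly.
    texture_sd: float = 0.6

    def __post_init__(self):
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be strictly in (0, 1)")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        object.__setattr__(self, "texture_effect", _effect_map(self.texture_effect))
        object.__setattr__(self, "intensity_effect", _effect_map(self.intensity_effect))

    @classmethod
    def strong_effect(cls, **kw) -> "CohortConfig":
        """Large, easily detectable class signal on every informative sequence."""
        kw.setdefault("texture_effect", 1.0)
        kw.setdefault("intensity_effect", 1.0)
        return cls(**kw)

    @classmethod
    def zero_effect(cls, **kw) -> "CohortConfig":
        """No class signal anywhere: downstream discrimination must be chance."""
        kw.update(texture_effect=0.0, intensity_effect=0.0)
        return cls(**kw)


@dataclass(frozen=True)
class ClinicalRecord:
    sex: str  # "male" / "female"
    age: float  # years
    cea: int  # 1 if >= 5 ng/ml
    concurrent_radiation: int
    cT: int  # in {2, 3, 4}
    cN: int  # in {0, 1, 2}
    ymrT: int  # in {1, 2, 3, 4}
    ymrN: int  # in {0, 1, 2}

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        for name, val, levels in (
            ("cT", self.cT, (2, 3, 4)),
            ("cN", self.cN, (0, 1, 2)),
            ("ymrT", self.ymrT, (1, 2, 3, 4)),
            ("ymrN", self.ymrN, (0, 1, 2)),
        ):
            if val not in levels:
                raise ValueError(f"{name}={val} outside levels {levels}")


@dataclass
class MRISample:
    """One patient: four sequence images, per-sequence ROI masks, clinical record, label."""

    patient_id: str
    images: Dict[str, np.ndarray]
    masks: Dict[str, np.ndarray]
    clinical: ClinicalRecord
    label: int  # 1 = LNM+

    def validate(self) -> None:
        for seq in SEQUENCES:
            if seq not in self.images:
                raise ValueError(f"missing sequence {seq}")
            img, msk = self.images[seq], self.masks[seq]
            if img.shape != msk.shape:
                raise ValueError("mask shape must equal image shape")
            if int(msk.sum()) < 16:
                raise ValueError("mask must contain >= 16 foreground pixels")


def generate_tumor_mask(image_size: int, seed: int) -> np.ndarray:
    """Filled-ellipse tumour ROI: random centre, axes in [size/8, size/3], random tilt.

    A filled ellipse is a single 8-connected region by construction.
    """
    if image_size < 32:
        raise ValueError("image_size must be >= 32")
    rng = np.random.default_rng(seed)
    a = rng.uniform(image_size / 8, image_size / 3)
    b = rng.uniform(image_size / 8, image_size / 3)
    theta = rng.uniform(0, math.pi)
    margin = image_size / 3 + 1
    cx = rng.uniform(margin, image_size - margin)
    cy = rng.uniform(margin, image_size - margin)
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    xr = (xx - cx) * math.cos(theta) + (yy - cy) * math.sin(theta)
    yr = -(xx - cx) * math.sin(theta) + (yy - cy) * math.cos(theta)
    return (xr**2 / a**2 + yr**2 / b**2) <= 1.0


def _correlated_field(rng: np.random.Generator, size: int, corr_length: float) -> np.ndarray:
    """Unit-variance stationary Gaussian field with Gaussian covariance of scale corr_length."""
    white = rng.standard_normal((size, size))
    f = ndimage.gaussian_filter(white, corr_length, mode="wrap")
    # gaussian_filter of white noise has sd ~ 1/(2*sqrt(pi)*corr_length); renormalize empirically
    return (f - f.mean()) / f.std()


def _sample_images(
    rng: np.random.Generator, cfg: CohortConfig, mask: np.ndarray, label: int
) -> Dict[str, np.ndarray]:
    images = {}
    for seq in SEQUENCES:
        tex = cfg.texture_effect[seq]
        inten = cfg.intensity_effect[seq]
        outside = _correlated_field(rng, cfg.image_size, cfg.base_corr_length)
        ell = cfg.base_corr_length * (1.0 + tex * label)
        ell *= math.exp(cfg.texture_sd * rng.standard_normal())
        ell = float(np.clip(ell, 0.5, 8.0))
        inside = _correlated_field(rng, cfg.image_size, ell)
        shift = inten * label + cfg.patient_sd * rng.standard_normal()
        img = np.where(mask, inside + shift, outside)
        # arbitrary scanner units: per-sequence affine rescale
        images[seq] = 100.0 + 20.0 * img
    return images


def _draw_categorical(rng, levels, probs) -> int:
    p = np.asarray(probs, dtype=float)
    return int(rng.choice(levels, p=p / p.sum()))


def _sample_clinical(rng: np.random.Generator, cfg: CohortConfig, label: int) -> ClinicalRecord:
    ymrt_dist = _YMRT_GIVEN_POS if label else _YMRT_GIVEN_NEG
    ymrT = _draw_categorical(rng, list(ymrt_dist), list(ymrt_dist.values()))
    # radiologist node read: fixed sensitivity / specificity w.r.t. the label
    if label:
        positive_read = rng.random() < cfg.radiologist_sens
    else:
        positive_read = rng.random() >= cfg.radiologist_spec
    if positive_read:
        n1_frac = _N1_FRAC_POS if label else _N1_FRAC_NEG
        ymrN = 1 if rng.random() < n1_frac else 2
    else:
        ymrN = 0
    return ClinicalRecord(
        sex="male" if rng.random() < _P_MALE else "female",
        age=float(np.clip(rng.normal(54.0, 12.0), 25.0, 88.0)),
        cea=int(rng.random() < _P_CEA_POS),
        concurrent_radiation=int(rng.random() < _P_RADIATION),
        cT=_draw_categorical(rng, list(_CT_MARGINAL), list(_CT_MARGINAL.values())),
        cN=_draw_categorical(rng, list(_CN_MARGINAL), list(_CN_MARGINAL.values())),
        ymrT=ymrT,
        ymrN=ymrN,
    )


def generate_cohort(config: CohortConfig) -> Tuple[List[MRISample], List[str]]:
    """Generate a cohort and its frozen 2:1 split.

    Returns ``(samples, split)`` where ``split[i]`` is ``"primary"`` or
    ``"validation"``.  Exactly ``round(n * prevalence)`` patients are
    LNM+; the split is stratified by label so both cohorts contain both
    classes.  Fully determined by ``config.seed``.
    """
    n = config.n_patients
    if n < 20:
        raise ValueError("n_patients must be >= 20 (selection stages undefined below)")
    n_pos = int(round(n * config.prevalence))
    if n_pos < 5:
        raise ValueError("prevalence yields < 5 positives; refuse")
    rng = np.random.default_rng(config.seed)
    labels = np.zeros(n, dtype=int)
    labels[rng.choice(n, size=n_pos, replace=False)] = 1

    samples: List[MRISample] = []
    for i in range(n):
        mask = generate_tumor_mask(config.image_size, seed=int(rng.integers(2**31)))
        images = _sample_images(rng, config, mask, int(labels[i]))
        clin = _sample_clinical(rng, config, int(labels[i]))
        samples.append(
            MRISample(
                patient_id=f"P{i:04d}",
                images=images,
                masks={s: mask.copy() for s in SEQUENCES},
                clinical=clin,
                label=int(labels[i]),
            )
        )

    # stratified 2:1 split, frozen at generation time
    frac_primary = config.split_ratio / (config.split_ratio + 1.0)
    split = np.array(["validation"] * n, dtype=object)
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        k = int(round(len(idx) * frac_primary))
        split[idx[:k]] = "primary"
    return samples, list(split)


def cohort_table(samples: Sequence[MRISample], split: Sequence[str]) -> pd.DataFrame:
    """Clinical covariate table, one row per patient."""
    rows = []
    for s, sp in zip(samples, split):
        c = s.clinical
        rows.append(
            dict(
                patient_id=s.patient_id,
                split=sp,
                label=s.label,
                sex=c.sex,
                age=c.age,
                cea=c.cea,
                radiation=c.concurrent_radiation,
                cT=c.cT,
                cN=c.cN,
                ymrT=c.ymrT,
                ymrN=c.ymrN,
            )
        )
    return pd.DataFrame(rows)


def write_cohort(samples: Sequence[MRISample], split: Sequence[str], out_dir) -> Path:
    """Serialize a cohort: one NIfTI per patient per sequence plus a mask, and the CSV table."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in samples:
        pdir = out / s.patient_id
        pdir.mkdir(exist_ok=True)
        for seq in SEQUENCES:
            nib.save(
                nib.Nifti1Image(s.images[seq].astype(np.float32), np.eye(4)),
                pdir / f"{seq}.nii.gz",
            )
        nib.save(
            nib.Nifti1Image(s.masks[SEQUENCES[0]].astype(np.uint8), np.eye(4)),
            pdir / "mask.nii.gz",
        )
    cohort_table(samples, split).to_csv(out / "cohort.csv", index=False)
    return out


def read_cohort(in_dir) -> Tuple[List[MRISample], List[str]]:
    """Load a cohort written by :func:`write_cohort`."""
    import nibabel as nib

    in_dir = Path(in_dir)
    table = pd.read_csv(in_dir / "cohort.csv")
    samples, split = [], []
    for _, row in table.iterrows():
        pdir = in_dir / str(row.patient_id)
        images = {
            seq: np.asarray(nib.load(pdir / f"{seq}.nii.gz").dataobj, dtype=float)
            for seq in SEQUENCES
        }
        mask = np.asarray(nib.load(pdir / "mask.nii.gz").dataobj) > 0
        clin = ClinicalRecord(
            sex=row.sex,
            age=float(row.age),
            cea=int(row.cea),
            concurrent_radiation=int(row.radiation),
            cT=int(row.cT),
            cN=int(row.cN),
            ymrT=int(row.ymrT),
            ymrN=int(row.ymrN),
        )
        samples.append(
            MRISample(
                patient_id=str(row.patient_id),
                images=images,
                masks={s: mask.copy() for s in SEQUENCES},
                clinical=clin,
                label=int(row.label),
            )
        )
        split.append(str(row.split))
    return samples, split
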