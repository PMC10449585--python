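"""Conventional CT body-composition quantification at L3.

Tissue masks come from predefined Hounsfield-unit windows applied inside the
anatomical compartment labels (skeletal muscle -29..150 HU, visceral adipose
tissue -150..-50 HU, subcutaneous adipose tissue -190..-30 HU, all bounds
inclusive).  Cross-sectional areas (cm²) are divided by height² to give the
stature-normalized indices SMI/VATI/SATI (cm²/m²); skeletal-muscle radiation
attenuation (SM-RA) is the mean HU over the muscle mask.  Because body
composition differs strongly by sex, indices are also expressed as
sex-specific Z-scores with statistics estimated on the training split only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .phantom import BACKGROUND, MUSCLE, SAT, VAT_REGION, PhantomSlice

__all__ = [
    "HUWindow",
    "TissueMask",
    "CompositionResult",
    "HU_WINDOWS",
    "segment_tissue",
    "segment_all",
    "composition_summary",
    "compute_zscores",
    "SexZScorer",
    "composition_table",
]


@dataclass(frozen=True)
class HUWindow:
    low: float
    high: float

    def __post_init__(self):
        if self.low > self.high:
            raise ValueError("HU window requires low <= high")


HU_WINDOWS = {
    "SM": HUWindow(-29, 150),
    "VAT": HUWindow(-150, -50),
    "SAT": HUWindow(-190, -30),
}

_TISSUE_REGION = {"SM": MUSCLE, "VAT": VAT_REGION, "SAT": SAT}


@dataclass
class TissueMask:
    mask: np.ndarray
    spacing: tuple
    tissue: str


@dataclass
class CompositionResult:
    sma: float
    vat_area: float
    sat_area: float
    smi: float
    vati: float
    sati: float
    smra: float  # NaN when the muscle mask is empty
    z_smi: float = np.nan
    z_vati: float = np.nan
    z_sati: float = np.nan
    z_smra: float = np.nan


def segment_tissue(slice_: PhantomSlice, tissue: str,
                   window: HUWindow | None = None) -> TissueMask:
    """HU-window segmentation inside the tissue's anatomical compartment.

    Mirrors the manual workflow: the compartment contour (here the phantom's
    ground-truth label) restricts the region, then the inclusive HU window
    selects tissue pixels within it.
    """
    if tissue not in _TISSUE_REGION:
        raise ValueError(f"unknown tissue {tissue!r}; expected SM/VAT/SAT")
    if slice_.labels is None:
        raise ValueError("slice has no label map; compartment labels are "
                         "required in place of manual contours")
    window = window or HU_WINDOWS[tissue]
    region = slice_.labels == _TISSUE_REGION[tissue]
    hu = slice_.hu_image
    mask = region & (hu >= window.low) & (hu <= window.high)
    return TissueMask(mask=mask, spacing=slice_.spacing, tissue=tissue)


def segment_all(slice_: PhantomSlice) -> dict:
    return {t: segment_tissue(slice_, t) for t in ("SM", "VAT", "SAT")}


def mask_area_cm2(mask: TissueMask) -> float:
    """Pixel count × pixel area, in cm²."""
    return float(mask.mask.sum() * mask.spacing[0] * mask.spacing[1] / 100.0)


def composition_summary(slice_: PhantomSlice, masks: dict,
                        height: float) -> CompositionResult:
    """Areas, stature-normalized indices and SM-RA for one patient."""
    if height <= 0:
        raise ValueError("height must be > 0")
    sma = mask_area_cm2(masks["SM"])
    vat = mask_area_cm2(masks["VAT"])
    sat = mask_area_cm2(masks["SAT"])
    h2 = height ** 2
    sm_mask = masks["SM"].mask
    smra = float(slice_.hu_image[sm_mask].mean()) if sm_mask.any() else np.nan
    return CompositionResult(
        sma=sma, vat_area=vat, sat_area=sat,
        smi=sma / h2, vati=vat / h2, sati=sat / h2, smra=smra,
    )


class SexZScorer(TransformerMixin, BaseEstimator):
    """Sex-stratified Z-scoring with train-only statistics.

    ``fit(X, sex)`` learns per-column, per-sex means and SDs on the training
    patients; ``transform`` standardizes any patients (training or holdout)
    against those frozen statistics.
    """

    def fit(self, X: pd.DataFrame, sex):
        sex = pd.Series(np.asarray(sex), index=X.index)
        stats = {}
        for s, grp in X.groupby(sex):
            if len(grp) < 2:
                raise ValueError(
                    f"sex group {s!r} has {len(grp)} training patients; "
                    "need >= 2 for an SD"
                )
            stats[s] = (grp.mean(), grp.std(ddof=1))
        self.columns_ = list(X.columns)
        self.stats_ = stats
        return self

    def transform(self, X: pd.DataFrame, sex=None) -> pd.DataFrame:
        if sex is None:
            raise ValueError("SexZScorer.transform requires the sex labels")
        sex = pd.Series(np.asarray(sex), index=X.index)
        out = pd.DataFrame(index=X.index, columns=self.columns_, dtype=float)
        for s, grp_idx in sex.groupby(sex).groups.items():
            if s not in self.stats_:
                raise ValueError(f"sex {s!r} unseen during fit")
            mean, sd = self.stats_[s]
            out.loc[grp_idx] = (X.loc[grp_idx, self.columns_] - mean) / sd
        return out


def compute_zscores(values, sex, train_stats=None, train_index=None):
    """Functional wrapper: Z-score a Series per sex using training stats.

    ``train_stats`` is a fitted :class:`SexZScorer`; when None, one is fitted
    on ``train_index`` rows (or all rows).
    """
    df = values.to_frame() if isinstance(values, pd.Series) else values
    if train_stats is None:
        idx = train_index if train_index is not None else df.index
        sex_s = pd.Series(np.asarray(sex), index=df.index)
        train_stats = SexZScorer().fit(df.loc[idx], sex_s.loc[idx])
    out = train_stats.transform(df, sex)
    return out.iloc[:, 0] if isinstance(values, pd.Series) else out


def composition_table(patients, slices, zscorer: SexZScorer | None = None,
                      train_ids=None) -> pd.DataFrame:
    """Per-patient body-composition table, optionally with sex Z-scores.

    Z statistics are fitted on ``train_ids`` (all patients if omitted) and
    applied unchanged everywhere.
    """
    rows = []
    for p, s in zip(patients, slices):
        res = composition_summary(s, segment_all(s), height=p.height)
        rows.append({
            "id": p.id, "sex": p.sex,
            "sma_cm2": res.sma, "vat_cm2": res.vat_area, "sat_cm2": res.sat_area,
            "smi": res.smi, "vati": res.vati, "sati": res.sati, "smra": res.smra,
        })
    df = pd.DataFrame(rows).set_index("id")
    zcols = ["smi", "vati", "sati", "smra"]
    if zscorer is None:
        idx = df.index if train_ids is None else pd.Index(train_ids)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            zscorer = SexZScorer().fit(df.loc[idx, zcols], df.loc[idx, "sex"])
    z = zscorer.transform(df[zcols], df["sex"])
    for c in zcols:
        df[f"z_{c}"] = z[c]
    return df.reset_index()
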