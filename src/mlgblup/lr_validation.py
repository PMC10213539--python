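"""Forward validation splits and LR-method statistics.

The LR (linear regression) method compares predictions from the whole data
(subscript w) with predictions from reduced data in which the validation
animals' phenotypes are removed (subscript r):

* accuracy  acc = sqrt( cov(u_w, u_r) / ((1 - Fbar) sigma_u^2) ),
* bias      mu_wr = mean(u_r) - mean(u_w), standardised by sigma_u,
* dispersion b1 = cov(u_w, u_r) / var(u_r), the slope of regressing u_w on
  u_r; 1 under neither over- nor under-dispersion.

Validation sets mimic selection-candidate evaluation: genotyped members of
last-generation litters with at least five full sibs; the training side
keeps only genotyped animals whose pedigree relationship with every test
animal is below 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import Pedigree, relationship_columns


class LRError(ValueError):
    pass


@dataclass
class SplitSpec:
    min_full_sibs: int = 5
    max_relationship: float = 0.5     # training excluded at >= this value
    litter_col: str = "litter"

    def __post_init__(self):
        if self.min_full_sibs < 1:
            raise LRError("min_full_sibs must be >= 1")
        if not 0.0 < self.max_relationship <= 2.0:
            raise LRError("max_relationship out of range")


@dataclass
class Split:
    training: np.ndarray     # animal ids
    test: np.ndarray


def make_split(ped: Pedigree, genotyped_ids, spec: SplitSpec | None = None
               ) -> Split:
    """Paper-style forward split of the genotyped animals.

    Test: genotyped members of last-generation litters (maximum birth year)
    with at least ``min_full_sibs`` genotyped members.  Training: remaining
    genotyped animals whose pedigree relationship with every test animal is
    strictly below ``max_relationship``.
    """
    spec = spec or SplitSpec()
    if ped.litter is None:
        raise LRError("pedigree carries no litter codes")
    gset = list(dict.fromkeys(genotyped_ids))
    codes = ped.codes(gset)
    last_year = int(ped.birth_year[codes].max())
    is_last = ped.birth_year[codes] == last_year
    litters = pd.Series(ped.litter[codes[is_last]])
    sizes = litters.value_counts()
    ok_litters = set(sizes[sizes >= spec.min_full_sibs].index)
    test_mask = np.zeros(len(gset), dtype=bool)
    test_mask[np.flatnonzero(is_last)] = [
        lt in ok_litters for lt in litters]
    if not test_mask.any():
        raise LRError(
            "empty test set: no last-generation litter has "
            f"{spec.min_full_sibs}+ genotyped full sibs; lower min_full_sibs")
    test_codes = codes[test_mask]
    rest_codes = codes[~test_mask]
    # relationship screen of the remaining animals against the test set
    R = relationship_columns(ped, test_codes)      # test x all animals
    max_rel = R[:, rest_codes].max(axis=0)
    keep = max_rel < spec.max_relationship
    garr = np.array(gset, dtype=object)
    return Split(training=garr[~test_mask][keep], test=garr[test_mask])


@dataclass
class LRReport:
    accuracy: float
    bias: float                  # standardised: (mean u_r - mean u_w)/sigma_u
    dispersion: float            # b1
    n_validation: int
    f_bar: float
    negative_covariance: bool = False

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "bias": self.bias,
                "dispersion": self.dispersion,
                "n_validation": self.n_validation, "f_bar": self.f_bar,
                "negative_covariance": self.negative_covariance}


def lr_statistics(gebv_whole: np.ndarray, gebv_reduced: np.ndarray,
                  f_bar: float, sigma2_u: float) -> LRReport:
    """LR accuracy, standardised bias and dispersion over validation animals.

    Both GEBV vectors must cover the same validation animals in the same
    order.  A negative covariance makes the accuracy radicand negative; the
    accuracy is then reported as 0 with a flag.
    """
    uw = np.asarray(gebv_whole, float)
    ur = np.asarray(gebv_reduced, float)
    if uw.shape != ur.shape:
        raise LRError("GEBV vectors differ in length")
    if len(uw) < 10:
        raise LRError(f"only {len(uw)} validation animals (< 10)")
    if sigma2_u <= 0:
        raise LRError("additive variance must be positive")
    cov = float(np.cov(uw, ur, ddof=1)[0, 1])
    var_r = float(np.var(ur, ddof=1))
    if var_r <= 0:
        raise LRError("reduced GEBV have zero variance")
    neg = cov < 0
    acc = 0.0 if neg else float(np.sqrt(cov / ((1.0 - f_bar) * sigma2_u)))
    bias = float((ur.mean() - uw.mean()) / np.sqrt(sigma2_u))
    b1 = cov / var_r
    return LRReport(accuracy=acc, bias=bias, dispersion=b1,
                    n_validation=len(uw), f_bar=float(f_bar),
                    negative_covariance=neg)
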