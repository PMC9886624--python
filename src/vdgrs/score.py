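"""Weighted genetic risk score computation.

The score for individual *i* is the weighted allele count

    GRS_i = sum_j X_ij * beta_j,          j = 1..m  (m = 6 for the panel)

where X_ij is the effect-allele dosage in [0, 2] and beta_j the per-allele
weight on the vitamin D Z-score scale.  Negative weights may equivalently be
carried as positive weights on the non-effect allele (X' = 2 - X), which
shifts every complete-genotype score by the constant 2 * sum |beta_neg|
without changing its Z-scored form — :func:`flip_negative_weights` implements
that reparameterization.

Missing dosages are handled by a selectable policy; the default mean-imputes
with twice the effect-allele frequency of the non-missing samples, matching
common scoring-tool behaviour.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .qc import DosageMatrix
from .weights import MissingVariantError, VariantWeight, WeightTable

MISSING_POLICIES = ("mean_impute", "skip_variant", "drop_sample")


class DegenerateInputError(ValueError):
    """Z-scoring is undefined: fewer than two values or zero variance."""


@dataclass
class ScoreResult:
    """Per-sample raw and Z-scored GRS with provenance.

    ``frame`` columns: raw_grs, grs_z, n_variants_used, n_imputed.  Samples
    with every panel dosage missing keep NaN scores and are flagged in
    ``all_missing``.
    """

    frame: pd.DataFrame
    variants_used: list[str]
    missing_policy: str

    @property
    def raw(self) -> pd.Series:
        return self.frame["raw_grs"]

    @property
    def z(self) -> pd.Series:
        return self.frame["grs_z"]

    @property
    def all_missing(self) -> list[str]:
        return list(self.frame.index[self.frame["raw_grs"].isna()])

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t")


def flip_negative_weights(weights: WeightTable) -> WeightTable:
    """Carry negative weights on the non-effect allele instead.

    Entries with beta < 0 get their effect/other alleles swapped and the beta
    negated, so every returned beta is positive.
    """
    flipped = []
    for w in weights:
        if w.beta < 0:
            proxy = w.proxy
            flipped.append(
                replace(w, effect_allele=w.other_allele, other_allele=w.effect_allele,
                        beta=-w.beta, proxy=proxy)
            )
        else:
            flipped.append(w)
    return WeightTable(tuple(flipped))


def zscore(values) -> pd.Series:
    """Standardize to mean 0, sample (n-1) SD 1; NaNs propagate."""
    s = pd.Series(np.asarray(values, dtype=float)) if not isinstance(values, pd.Series) else values.astype(float)
    ok = s.dropna()
    if len(ok) < 2:
        raise DegenerateInputError("zscore needs at least 2 non-missing values")
    sd = ok.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateInputError("zscore undefined for zero-variance input")
    return (s - ok.mean()) / sd


def compute_raw_score(
    matrix: DosageMatrix,
    weights: WeightTable,
    missing_policy: str = "mean_impute",
) -> ScoreResult:
    """Raw weighted scores for every sample (no Z-scoring).

    Requires every weight-table variant to be a column of ``matrix`` (proxy
    resolution and harmonization happen upstream, in
    :func:`vdgrs.qc.read_genotypes`).  Missing dosages:

    - ``mean_impute``: substitute 2 x effect-allele frequency of the
      non-missing samples at that variant (default);
    - ``skip_variant``: omit the variant from that sample's sum;
    - ``drop_sample``: samples with any missing dosage get NaN scores.

    A sample missing every panel variant is flagged absent (NaN) under all
    policies.
    """
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(f"unknown missing policy {missing_policy!r}; choose from {MISSING_POLICIES}")
    absent = [w.rsid for w in weights if w.rsid not in matrix.dosages.columns]
    if absent:
        raise MissingVariantError(f"weight-table variant(s) absent from dosage matrix: {absent}")
    rsids = weights.rsids
    X = matrix.dosages[rsids].to_numpy(dtype=float)
    beta = np.array([w.beta for w in weights])
    miss = np.isnan(X)
    n_used = (~miss).sum(axis=1)
    all_missing = n_used == 0

    if missing_policy == "mean_impute":
        with np.errstate(invalid="ignore"):
            col_mean = np.nanmean(np.where(all_missing[:, None], np.nan, X), axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)  # variant missing everywhere
        Xf = np.where(miss, col_mean[None, :], X)
        raw = Xf @ beta
        n_imputed = miss.sum(axis=1)
    elif missing_policy == "skip_variant":
        raw = np.where(miss, 0.0, X) @ beta
        n_imputed = np.zeros(len(X), dtype=int)
    else:  # drop_sample
        raw = X @ beta  # NaN propagates for any missing dosage
        n_imputed = np.zeros(len(X), dtype=int)

    raw = np.where(all_missing, np.nan, raw)
    frame = pd.DataFrame(
        {
            "raw_grs": raw,
            "grs_z": np.nan,
            "n_variants_used": n_used,
            "n_imputed": np.where(all_missing, 0, n_imputed),
        },
        index=matrix.dosages.index,
    )
    return ScoreResult(frame, rsids, missing_policy)


def score_cohort(
    matrix: DosageMatrix,
    weights: WeightTable,
    missing_policy: str = "mean_impute",
) -> ScoreResult:
    """Raw scores plus cohort-wide Z-scored GRS (``grs_z``)."""
    result = compute_raw_score(matrix, weights, missing_policy)
    result.frame["grs_z"] = zscore(result.frame["raw_grs"])
    return result
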