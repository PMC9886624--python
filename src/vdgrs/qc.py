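"""Genotype input and quality control for the score panel.

Genotypes enter as a VCF (hard calls in GT, or dosages in DS) or as a
samples-by-variants dosage TSV, and are turned into a :class:`DosageMatrix`
of effect-allele dosages in [0, 2] — proxy substitution and allele
harmonization (see :mod:`vdgrs.weights`) happen on the way in, so the matrix
columns are always the canonical panel rsids.

Variant-level filters mirror standard biobank score QC: minor allele
frequency >= 0.01, Hardy–Weinberg equilibrium p >= 1e-5, call rate >= 90%,
imputation info score >= 0.3 when available.  Sample-level QC removes
individuals missing more than 10% of panel variants.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .weights import (
    AMBIGUOUS_PALINDROMIC,
    MISMATCH,
    HarmonizationError,
    MissingVariantError,
    WeightTable,
    harmonize_alleles,
    resolve_proxy,
)

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {
    "maf_min": 0.01,
    "hwe_min_p": 1e-5,
    "call_rate_min": 0.90,
    "info_min": 0.3,
}
DEFAULT_SAMPLE_MISSINGNESS = 0.10


@dataclass
class DosageMatrix:
    """Samples x variants effect-allele dosages with per-variant metadata.

    ``dosages``: DataFrame indexed by sample id, columns = canonical panel
    rsids, values in [0, 2] or NaN (missing).  ``variant_meta``: DataFrame
    indexed by the same rsids with at least ``ref``/``alt`` (the genotyped
    orientation); optionally ``source_rsid`` (the proxy actually genotyped),
    ``orientation`` and ``info`` (imputation quality in [0, 1]).
    """

    dosages: pd.DataFrame
    variant_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.dosages.index.duplicated().any():
            raise ValueError("duplicate sample ids in dosage matrix")
        if self.dosages.columns.duplicated().any():
            raise ValueError("duplicate variant ids in dosage matrix")
        vals = self.dosages.to_numpy(dtype=float)
        bad = (vals < -1e-9) | (vals > 2 + 1e-9)
        if np.any(bad & ~np.isnan(vals)):
            raise ValueError("dosages outside [0, 2]")
        if list(self.variant_meta.index) != list(self.dosages.columns):
            self.variant_meta = self.variant_meta.reindex(self.dosages.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.dosages.columns)

    @property
    def n_samples(self) -> int:
        return len(self.dosages.index)

    @property
    def n_variants(self) -> int:
        return len(self.dosages.columns)

    def subset(self, samples=None, variants=None) -> "DosageMatrix":
        d = self.dosages
        if samples is not None:
            d = d.loc[list(samples)]
        if variants is not None:
            d = d[list(variants)]
        return DosageMatrix(d.copy(), self.variant_meta.reindex(d.columns).copy())

    def is_hard_called(self) -> pd.Series:
        """Per variant: every non-missing dosage is an integer 0/1/2."""
        vals = self.dosages.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            integral = np.isclose(vals, np.round(vals), atol=1e-6) | np.isnan(vals)
        return pd.Series(integral.all(axis=0), index=self.dosages.columns)


@dataclass
class VariantQCReport:
    frame: pd.DataFrame  # index rsid; maf, hwe_p, call_rate, info, pass, reasons
    thresholds: dict = field(default_factory=dict)

    @property
    def passing(self) -> list[str]:
        return list(self.frame.index[self.frame["pass"]])

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t")


@dataclass
class SampleQCReport:
    frame: pd.DataFrame  # index sample id; missingness, pass
    threshold: float = DEFAULT_SAMPLE_MISSINGNESS

    @property
    def passing(self) -> list[str]:
        return list(self.frame.index[self.frame["pass"]])

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# input


def read_genotypes(
    source,
    weights: WeightTable,
    *,
    allow_palindromic=(),
    info_keys=("INFO", "R2", "DR2"),
) -> DosageMatrix:
    """Read panel genotypes into an effect-allele :class:`DosageMatrix`.

    ``source`` may be a VCF (``.vcf``/``.vcf.gz``) or a dosage TSV.  Panel
    variants absent from the file are substituted by their declared proxy
    when genotyped; columns of the result are always the canonical panel
    rsids.  ``allow_palindromic`` whitelists rsids whose A/T–C/G ambiguity is
    accepted (genotyping strand known).
    """
    path = Path(source)
    if path.suffix == ".gz" or path.suffix == ".vcf" or "".join(path.suffixes[-2:]) == ".vcf.gz":
        raw, meta = _read_vcf(path, weights, info_keys)
    else:
        raw, meta = _read_dosage_tsv(path, weights)
    return _assemble(raw, meta, weights, set(allow_palindromic))


def _wanted_rsids(weights: WeightTable) -> set[str]:
    wanted = set(weights.rsids)
    for w in weights:
        if w.proxy is not None:
            wanted.add(w.proxy.proxy_rsid)
    return wanted


def _read_vcf(path: Path, weights: WeightTable, info_keys):
    from cyvcf2 import VCF

    wanted = _wanted_rsids(weights)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: dict[str, np.ndarray] = {}
    meta_rows: dict[str, dict] = {}
    for rec in vcf:
        rid = rec.ID
        if rid is None or rid not in wanted:
            continue
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            logger.warning("skipping non-biallelic-SNP record %s (%s>%s)", rid, rec.REF, rec.ALT)
            continue
        if rid in columns:
            logger.warning("skipping duplicate VCF record for %s", rid)
            continue
        ds = None
        try:
            ds_arr = rec.format("DS")
        except Exception:
            ds_arr = None
        if ds_arr is not None:
            ds = np.asarray(ds_arr, dtype=float).reshape(len(samples))
            ds = np.where((ds < 0) | (ds > 2), np.nan, ds)
        else:
            gt = np.asarray(rec.gt_types)  # 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
            ds = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        info = None
        for key in info_keys:
            v = rec.INFO.get(key)
            if v is not None:
                try:
                    info = float(v)
                except (TypeError, ValueError):
                    info = None
                break
        columns[rid] = ds
        meta_rows[rid] = {"ref": rec.REF, "alt": rec.ALT[0], "info": info}
    if not columns:
        raise MissingVariantError(f"no panel variants (or proxies) found in {path}")
    raw = pd.DataFrame(columns, index=pd.Index(samples, name="sample_id"))
    meta = pd.DataFrame.from_dict(meta_rows, orient="index")
    return raw, meta


def _read_dosage_tsv(path: Path, weights: WeightTable):
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["", "NA", "na", "."])
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    wanted = _wanted_rsids(weights)
    keep = [c for c in df.columns if c in wanted]
    if not keep:
        raise MissingVariantError(f"no panel variants (or proxies) found in {path}")
    raw = df[keep].astype(float)
    # TSV carries no REF/ALT: dosages are effect-allele counts in the weight
    # table's own orientation (alt := effect allele of the matching entry).
    meta_rows = {}
    by_rsid = {w.rsid: w for w in weights}
    by_proxy = {w.proxy.proxy_rsid: w for w in weights if w.proxy is not None}
    for rid in keep:
        if rid in by_rsid:
            w = by_rsid[rid]
            meta_rows[rid] = {"ref": w.other_allele, "alt": w.effect_allele, "info": None}
        else:
            w = by_proxy[rid]
            amap = w.proxy.allele_map
            meta_rows[rid] = {
                "ref": amap[w.other_allele],
                "alt": amap[w.effect_allele],
                "info": None,
            }
    return raw, pd.DataFrame.from_dict(meta_rows, orient="index")


def _assemble(raw: pd.DataFrame, meta: pd.DataFrame, weights: WeightTable, whitelist: set):
    cols = {}
    meta_rows = {}
    errors = []
    for w in weights:
        try:
            eff = resolve_proxy(w, raw.columns)
        except MissingVariantError as exc:
            errors.append(str(exc))
            continue
        ref, alt = meta.loc[eff.rsid, "ref"], meta.loc[eff.rsid, "alt"]
        orient = harmonize_alleles(
            eff, ref, alt, allow_palindromic=(w.rsid in whitelist or eff.rsid in whitelist)
        )
        if orient.status == AMBIGUOUS_PALINDROMIC:
            raise HarmonizationError(
                f"{w.rsid}: palindromic alleles {eff.effect_allele}/{eff.other_allele}; "
                "strand is ambiguous — add the rsid to the palindromic whitelist to use it"
            )
        if orient.status == MISMATCH:
            raise HarmonizationError(
                f"{w.rsid}: weight alleles {eff.effect_allele}/{eff.other_allele} do not match "
                f"genotyped REF/ALT {ref}/{alt} (directly or strand-flipped)"
            )
        cols[w.rsid] = orient.apply(raw[eff.rsid].to_numpy(dtype=float))
        meta_rows[w.rsid] = {
            "ref": ref,
            "alt": alt,
            "source_rsid": eff.rsid,
            "orientation": orient.status,
            "info": meta.loc[eff.rsid].get("info"),
        }
    if not cols:
        raise MissingVariantError("no panel variants found after proxy resolution: " + "; ".join(errors))
    for msg in errors:
        logger.warning("%s", msg)
    dos = pd.DataFrame(cols, index=raw.index)
    return DosageMatrix(dos, pd.DataFrame.from_dict(meta_rows, orient="index"))


# ---------------------------------------------------------------------------
# filters


def hwe_test(n_hom_effect: int, n_het: int, n_hom_other: int) -> float:
    """Hardy–Weinberg goodness-of-fit p-value (1-df chi-square).

    Observed genotype counts are compared with the p^2 / 2pq / q^2
    expectations at the sample allele frequency; one degree of freedom is
    left after fitting that frequency.  Monomorphic samples trivially fit
    (statistic 0, p = 1).
    """
    counts = np.array([n_hom_effect, n_het, n_hom_other], dtype=float)
    if np.any(counts < 0):
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise ValueError("HWE test undefined for zero total genotype count")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    expected = n * np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2])
    mask = expected > 0
    stat = float(np.sum((counts[mask] - expected[mask]) ** 2 / expected[mask]))
    return float(stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0


def folded_maf(dosages: np.ndarray) -> float:
    """Minor allele frequency from mean dosage / 2, folded to [0, 0.5]."""
    freq = float(np.nanmean(dosages)) / 2.0
    return min(freq, 1.0 - freq)


def variant_qc(matrix: DosageMatrix, thresholds: dict | None = None) -> VariantQCReport:
    """Flag each variant against MAF / HWE / call-rate / info thresholds.

    HWE is computed for hard-called variants only (fractional dosages carry
    no genotype counts); the info check is skipped when no score is present.
    The report never removes anything — pair with :func:`apply_qc`.
    """
    thr = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    hard = matrix.is_hard_called()
    rows = {}
    for rid in matrix.variant_ids:
        x = matrix.dosages[rid].to_numpy(dtype=float)
        n = x.size
        n_called = int(np.sum(~np.isnan(x)))
        call_rate = n_called / n if n else 0.0
        maf = folded_maf(x) if n_called else float("nan")
        hwe_p = math.nan
        if hard[rid] and n_called:
            g = np.round(x[~np.isnan(x)]).astype(int)
            hwe_p = hwe_test(int(np.sum(g == 2)), int(np.sum(g == 1)), int(np.sum(g == 0)))
        info = matrix.variant_meta.loc[rid].get("info") if "info" in matrix.variant_meta.columns else None
        reasons = []
        if not n_called or not (maf >= thr["maf_min"]):
            reasons.append(f"MAF < {thr['maf_min']}")
        if call_rate < thr["call_rate_min"]:
            reasons.append(f"missingness > {100 * (1 - thr['call_rate_min']):g}%")
        if not math.isnan(hwe_p) and hwe_p < thr["hwe_min_p"]:
            reasons.append(f"HWE p < {thr['hwe_min_p']:g}")
        if info is not None and not pd.isna(info) and info < thr["info_min"]:
            reasons.append(f"info < {thr['info_min']}")
        rows[rid] = {
            "maf": maf,
            "hwe_p": hwe_p,
            "call_rate": call_rate,
            "info": info if info is not None else math.nan,
            "pass": not reasons,
            "reasons": ";".join(reasons),
        }
    return VariantQCReport(pd.DataFrame.from_dict(rows, orient="index"), thr)


def sample_qc(matrix: DosageMatrix, threshold: float = DEFAULT_SAMPLE_MISSINGNESS) -> SampleQCReport:
    """Flag samples missing more than ``threshold`` of the panel variants."""
    miss = matrix.dosages.isna().mean(axis=1)
    frame = pd.DataFrame({"missingness": miss, "pass": miss <= threshold})
    return SampleQCReport(frame, threshold)


def apply_qc(
    matrix: DosageMatrix,
    variant_report: VariantQCReport | None = None,
    sample_report: SampleQCReport | None = None,
) -> DosageMatrix:
    """Drop failing variants and samples, logging counts before and after."""
    variants = variant_report.passing if variant_report else matrix.variant_ids
    samples = sample_report.passing if sample_report else matrix.sample_ids
    out = matrix.subset(samples=samples, variants=variants)
    logger.info(
        "QC: %d/%d variants, %d/%d samples retained",
        out.n_variants, matrix.n_variants, out.n_samples, matrix.n_samples,
    )
    return out
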