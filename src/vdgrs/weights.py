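"""Weight table for the 6-SNP vitamin D genetic risk score.

The score is a fixed panel of six SNPs from a vitamin D GWAS, each with an
effect allele and a per-allele weight (beta, in units of serum 25(OH)D3
Z-score per allele copy).  This module owns the bookkeeping that makes those
weights applicable to arbitrary genotype files:

* loading and validating the weight table (the panel ships as a package
  fixture, :func:`packaged_weight_table`);
* proxy substitution — genotyping a high-LD stand-in SNP in place of an
  absent panel SNP, with an explicit allele correspondence;
* allele harmonization — reconciling the table's effect/other alleles with a
  VCF's REF/ALT orientation, including reverse-complement (strand) flips and
  refusal of strand-ambiguous palindromic variants unless whitelisted.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterator, Mapping

import pandas as pd

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: harmonization outcomes
EFFECT_IS_ALT = "effect_is_alt"
EFFECT_IS_REF = "effect_is_ref"
STRAND_FLIPPED_ALT = "strand_flipped_alt"
STRAND_FLIPPED_REF = "strand_flipped_ref"
AMBIGUOUS_PALINDROMIC = "ambiguous_palindromic"
MISMATCH = "mismatch"

IDENTITY = "identity"
TWO_MINUS = "2-x"


class WeightTableError(ValueError):
    """Invalid weight-table content (duplicate rsid, bad allele, zero beta...)."""


class HarmonizationError(ValueError):
    """Weight alleles cannot be reconciled with the genotyped REF/ALT pair."""


class MissingVariantError(KeyError):
    """Neither a panel variant nor its proxy is present in the genotype source."""

    def __str__(self) -> str:  # KeyError quotes its message otherwise
        return self.args[0] if self.args else ""


def _check_allele(a: str, what: str) -> None:
    if a not in VALID_ALLELES:
        raise WeightTableError(f"{what} {a!r} is not a single base in A/C/G/T")


@dataclass(frozen=True)
class ProxyMap:
    """A stand-in SNP for a panel variant, with its allele correspondence.

    ``allele_map`` maps each allele of the *target* (panel) variant to the
    corresponding allele of the proxy; ``r2`` is the squared LD correlation
    between the two and is informational only — no LD is computed here.
    """

    proxy_rsid: str
    allele_map: Mapping[str, str]
    r2: float | None = None

    def __post_init__(self) -> None:
        if not self.proxy_rsid:
            raise WeightTableError("proxy_rsid must be non-empty")
        keys, vals = set(self.allele_map), set(self.allele_map.values())
        if len(self.allele_map) != 2 or len(vals) != 2:
            raise WeightTableError(
                f"proxy allele map for {self.proxy_rsid} must be a bijection "
                f"over exactly two alleles, got {dict(self.allele_map)!r}"
            )
        for a in keys | vals:
            _check_allele(a, "proxy map allele")


@dataclass(frozen=True)
class VariantWeight:
    """One panel SNP: effect allele, other allele, and per-allele beta."""

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    gene_label: str | None = None
    proxy: ProxyMap | None = None

    def __post_init__(self) -> None:
        if not self.rsid:
            raise WeightTableError("rsid must be non-empty")
        _check_allele(self.effect_allele, f"{self.rsid} effect allele")
        _check_allele(self.other_allele, f"{self.rsid} other allele")
        if self.effect_allele == self.other_allele:
            raise WeightTableError(f"{self.rsid}: effect and other allele are identical")
        beta = float(self.beta)
        if not (beta == beta) or beta in (float("inf"), float("-inf")) or beta == 0.0:
            raise WeightTableError(f"{self.rsid}: beta must be finite and nonzero, got {self.beta!r}")

    @property
    def is_palindromic(self) -> bool:
        """True for strand-ambiguous A/T or C/G variants."""
        return COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass(frozen=True)
class WeightTable:
    """Ordered collection of :class:`VariantWeight` defining the score."""

    entries: tuple[VariantWeight, ...]

    def __post_init__(self) -> None:
        if len(self.entries) == 0:
            raise WeightTableError("weight table has zero entries; at least one SNP is required")
        rsids = [w.rsid for w in self.entries]
        dupes = {r for r in rsids if rsids.count(r) > 1}
        if dupes:
            raise WeightTableError(f"duplicate rsid(s) in weight table: {sorted(dupes)}")

    def __iter__(self) -> Iterator[VariantWeight]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, rsid: str) -> VariantWeight:
        for w in self.entries:
            if w.rsid == rsid:
                return w
        raise KeyError(rsid)

    @property
    def rsids(self) -> list[str]:
        return [w.rsid for w in self.entries]

    @property
    def betas(self) -> pd.Series:
        return pd.Series({w.rsid: w.beta for w in self.entries}, name="beta")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for w in self.entries:
            rows.append(
                {
                    "rsid": w.rsid,
                    "effect_allele": w.effect_allele,
                    "other_allele": w.other_allele,
                    "beta": w.beta,
                    "gene_label": w.gene_label,
                    "proxy_rsid": w.proxy.proxy_rsid if w.proxy else None,
                    "proxy_r2": w.proxy.r2 if w.proxy else None,
                    "proxy_allele_map": _format_allele_map(w.proxy.allele_map) if w.proxy else None,
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class AlleleOrientation:
    """How to turn a stored ALT dosage into an effect-allele dosage.

    ``dosage_transform`` is ``"identity"`` when the effect allele is (possibly
    after a strand flip) the ALT allele, ``"2-x"`` when it is REF, and absent
    for mismatches and non-whitelisted palindromic variants.
    """

    status: str
    dosage_transform: str | None = None

    def __post_init__(self) -> None:
        if self.status in (MISMATCH, AMBIGUOUS_PALINDROMIC) and self.dosage_transform is not None:
            raise ValueError(f"status {self.status} admits no dosage transform")

    @property
    def usable(self) -> bool:
        return self.dosage_transform is not None

    def apply(self, alt_dosage):
        """Apply the transform to an ALT-allele dosage (scalar or array)."""
        if self.dosage_transform == IDENTITY:
            return alt_dosage
        if self.dosage_transform == TWO_MINUS:
            return 2.0 - alt_dosage
        raise HarmonizationError(f"orientation {self.status} has no usable dosage transform")


def _parse_allele_map(text: str) -> dict[str, str]:
    # "C=T,T=G" -> {"C": "T", "T": "G"} (target allele = proxy allele)
    out: dict[str, str] = {}
    for pair in text.replace(" ", "").split(","):
        if not pair:
            continue
        left, _, right = pair.partition("=")
        if not right:
            raise WeightTableError(f"cannot parse proxy allele map entry {pair!r}")
        out[left.upper()] = right.upper()
    return out


def _format_allele_map(m: Mapping[str, str]) -> str:
    return ",".join(f"{k}={v}" for k, v in m.items())


REQUIRED_COLUMNS = ("rsid", "effect_allele", "other_allele", "beta")


def load_weight_table(path) -> WeightTable:
    """Load a tab-separated weight table.

    Required columns: rsid, effect_allele, other_allele, beta.  Optional:
    gene_label, proxy_rsid, proxy_r2, proxy_allele_map (e.g. ``"C=T,T=G"``,
    mapping target alleles to proxy alleles).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise WeightTableError(f"weight file {path} lacks required column(s) {missing}")
    if len(df) == 0:
        raise WeightTableError(f"weight file {path} has zero entries; at least one SNP is required")
    entries = []
    for _, row in df.iterrows():
        beta_raw = row["beta"]
        if pd.isna(beta_raw) or str(beta_raw).strip() == "":
            raise WeightTableError(f"{row['rsid']}: missing beta")
        try:
            beta = float(beta_raw)
        except ValueError as exc:
            raise WeightTableError(f"{row['rsid']}: unparseable beta {beta_raw!r}") from exc
        proxy = None
        proxy_rsid = row.get("proxy_rsid")
        if isinstance(proxy_rsid, str) and proxy_rsid.strip():
            amap_raw = row.get("proxy_allele_map")
            if not (isinstance(amap_raw, str) and amap_raw.strip()):
                raise WeightTableError(f"{row['rsid']}: proxy {proxy_rsid} given without an allele map")
            r2_raw = row.get("proxy_r2")
            r2 = float(r2_raw) if isinstance(r2_raw, str) and r2_raw.strip() else None
            proxy = ProxyMap(proxy_rsid.strip(), _parse_allele_map(amap_raw), r2)
        gene = row.get("gene_label")
        entries.append(
            VariantWeight(
                rsid=str(row["rsid"]).strip(),
                effect_allele=str(row["effect_allele"]).strip().upper(),
                other_allele=str(row["other_allele"]).strip().upper(),
                beta=beta,
                gene_label=gene.strip() if isinstance(gene, str) and gene.strip() else None,
                proxy=proxy,
            )
        )
    return WeightTable(tuple(entries))


def packaged_weight_table() -> WeightTable:
    """The packaged 6-SNP panel (AMDHD1, DHCR7, CYP2R1, CYP24A1, SEC23A, GC)."""
    with resources.as_file(resources.files("vdgrs.data") / "weights_6snp.tsv") as p:
        return load_weight_table(p)


def resolve_proxy(weight: VariantWeight, available_rsids) -> VariantWeight:
    """Re-key a weight to its proxy SNP when the target is not genotyped.

    If ``weight.rsid`` is among ``available_rsids`` the weight is returned
    unchanged.  Otherwise, if a proxy is declared and genotyped, the weight is
    re-keyed to the proxy with both alleles translated through the allele map
    and the beta untouched.  If neither is available a
    :class:`MissingVariantError` is raised.
    """
    available = set(available_rsids)
    if weight.rsid in available:
        return weight
    if weight.proxy is not None and weight.proxy.proxy_rsid in available:
        amap = weight.proxy.allele_map
        try:
            effect = amap[weight.effect_allele]
            other = amap[weight.other_allele]
        except KeyError as exc:
            raise HarmonizationError(
                f"{weight.rsid}: allele {exc.args[0]} absent from proxy map to {weight.proxy.proxy_rsid}"
            ) from exc
        return replace(
            weight,
            rsid=weight.proxy.proxy_rsid,
            effect_allele=effect,
            other_allele=other,
            proxy=None,
        )
    wanted = weight.rsid if weight.proxy is None else f"{weight.rsid} (proxy {weight.proxy.proxy_rsid})"
    raise MissingVariantError(f"panel variant not genotyped: {wanted}")


def harmonize_alleles(
    weight: VariantWeight,
    genotyped_ref: str,
    genotyped_alt: str,
    *,
    allow_palindromic: bool = False,
) -> AlleleOrientation:
    """Orient a weight's effect/other alleles against a genotyped REF/ALT pair.

    Tries a direct label match first, then a reverse-complement (strand flip)
    match.  Palindromic weights (A/T, C/G) are refused as
    ``ambiguous_palindromic`` unless ``allow_palindromic`` — a strand flip is
    undetectable from the allele labels of such variants, so they are only
    safe when the genotyping strand is known (e.g. assay-based genotyping).
    """
    ref, alt = genotyped_ref.upper(), genotyped_alt.upper()
    for a, what in ((ref, "REF"), (alt, "ALT")):
        if a not in VALID_ALLELES:
            raise HarmonizationError(f"{weight.rsid}: genotyped {what} {a!r} is not a single base")
    e, o = weight.effect_allele, weight.other_allele

    if weight.is_palindromic:
        if not allow_palindromic:
            return AlleleOrientation(AMBIGUOUS_PALINDROMIC)
        # strand asserted known: direct label match only
        if (e, o) == (alt, ref):
            return AlleleOrientation(EFFECT_IS_ALT, IDENTITY)
        if (e, o) == (ref, alt):
            return AlleleOrientation(EFFECT_IS_REF, TWO_MINUS)
        return AlleleOrientation(MISMATCH)

    if (e, o) == (alt, ref):
        return AlleleOrientation(EFFECT_IS_ALT, IDENTITY)
    if (e, o) == (ref, alt):
        return AlleleOrientation(EFFECT_IS_REF, TWO_MINUS)
    ec, oc = COMPLEMENT[e], COMPLEMENT[o]
    if (ec, oc) == (alt, ref):
        return AlleleOrientation(STRAND_FLIPPED_ALT, IDENTITY)
    if (ec, oc) == (ref, alt):
        return AlleleOrientation(STRAND_FLIPPED_REF, TWO_MINUS)
    return AlleleOrientation(MISMATCH)
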