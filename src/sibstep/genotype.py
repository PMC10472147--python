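"""Genotype I/O, SNP quality control, the genomic relationship matrix, and
single-step H-inverse assembly.

Dosages are additive counts of the second allele (0/1/2, NaN = missing).
QC applies the standard marker filters (minor-allele frequency, per-SNP
missingness, Hardy-Weinberg exact test) and mean-imputes surviving missing
calls.  G follows VanRaden's first method: centred dosages scaled by
``2 * sum p_j (1 - p_j)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .exceptions import GenotypeError
from .relmatrix import RelationshipMatrix


@dataclass
class GenotypeMatrix:
    """Animals x SNP additive dosage matrix with per-SNP allele frequencies."""

    ids: tuple[str, ...]
    snp_ids: tuple[str, ...]
    dosages: np.ndarray  # float, NaN = missing
    freqs: np.ndarray  # second-allele frequency p_j, NaN if no calls

    @property
    def n_animals(self) -> int:
        return len(self.ids)

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)

    def missing_fraction(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.dosages, columns=list(self.snp_ids))
        df.insert(0, "animal_id", list(self.ids))
        return df

    def write_tsv(self, path) -> None:
        df = self.to_frame()
        # integral dosages are written as 0/1/2, not 0.0/1.0/2.0
        df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def compute_freqs(dosages: np.ndarray) -> np.ndarray:
    """Second-allele frequency per SNP: allele count / (2 * non-missing).

    All-missing SNPs get NaN (flagged for removal by QC).
    """
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(dosages, axis=0) / 2.0


def _from_frame(ids, snp_ids, dosages) -> GenotypeMatrix:
    return GenotypeMatrix(
        ids=tuple(str(i) for i in ids),
        snp_ids=tuple(str(s) for s in snp_ids),
        dosages=dosages,
        freqs=compute_freqs(dosages),
    )


def read_genotypes(source) -> GenotypeMatrix:
    """Read a simple TSV dosage table: ``animal_id`` + one column per SNP.

    Cells must be 0, 1, 2 or NA; anything else is a hard error naming the
    offending row and column.
    """
    df = pd.read_csv(source, sep="\t", dtype=str)
    if df.columns[0] != "animal_id":
        raise GenotypeError("genotype TSV must start with an 'animal_id' column")
    ids = df.iloc[:, 0].astype(str).tolist()
    snp_ids = list(df.columns[1:])
    raw = df.iloc[:, 1:].to_numpy(dtype=object)
    dosages = np.full(raw.shape, np.nan)
    allowed = {"0": 0.0, "1": 1.0, "2": 2.0, "0.0": 0.0, "1.0": 1.0, "2.0": 2.0}
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                continue
            s = str(cell).strip()
            if s in ("NA", "na", ""):
                continue
            if s not in allowed:
                raise GenotypeError(
                    f"invalid dosage {s!r} at animal {ids[i]!r}, SNP {snp_ids[j]!r}"
                )
            dosages[i, j] = allowed[s]
    return _from_frame(ids, snp_ids, dosages)


def read_plink_raw(source) -> GenotypeMatrix:
    """Read a PLINK ``.raw`` additive export.

    Expects the standard header ``FID IID PAT MAT SEX PHENOTYPE SNP1_A ...``;
    animal ids are taken from IID, the six leading columns are otherwise
    ignored, count columns are parsed with NA as missing.
    """
    df = pd.read_csv(source, sep=r"\s+", dtype=str)
    lead = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    if list(df.columns[:6]) != lead:
        raise GenotypeError(
            "not a PLINK .raw additive export (expected header "
            "'FID IID PAT MAT SEX PHENOTYPE ...')"
        )
    ids = df["IID"].astype(str).tolist()
    snp_ids = list(df.columns[6:])
    dosages = np.full((len(ids), len(snp_ids)), np.nan)
    for j, col in enumerate(snp_ids):
        vals = df[col].to_numpy(dtype=object)
        for i, cell in enumerate(vals):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                continue
            s = str(cell).strip()
            if s in ("NA", "na", ""):
                continue
            if s not in ("0", "1", "2"):
                raise GenotypeError(
                    f"invalid dosage {s!r} at animal {ids[i]!r}, SNP {col!r}"
                )
            dosages[i, j] = float(s)
    return _from_frame(ids, snp_ids, dosages)


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------


def hwe_exact_pvalue(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided Hardy-Weinberg exact test p-value on genotype counts.

    Sums the probabilities of all heterozygote counts no more likely than the
    observed one, conditional on the allele counts (the usual exact HWE test
    used by genotype-QC tools).
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    hom_rare = (n_rare - hets) // 2
    hom_common = n - hets - hom_rare
    logp = (
        hets * np.log(2.0)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hets == n_het][0]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def hwe_chisq_pvalue(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """One-df chi-square HWE test (available behind a flag; exact is default)."""
    from scipy.stats import chi2

    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    p = (2 * n_hom_ref + n_het) / (2 * n)
    q = 1 - p
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.nansum(np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0))
    return float(chi2.sf(stat, df=1))


@dataclass
class QcReport:
    """Per-filter SNP removal accounting for one :func:`qc_filter` run."""

    n_snp_in: int
    n_snp_out: int
    removed_maf: list[str] = field(default_factory=list)
    removed_missing: list[str] = field(default_factory=list)
    removed_hwe: list[str] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    @property
    def n_removed_maf(self) -> int:
        return len(self.removed_maf)

    @property
    def n_removed_missing(self) -> int:
        return len(self.removed_missing)

    @property
    def n_removed_hwe(self) -> int:
        return len(self.removed_hwe)

    @property
    def removed_union(self) -> set[str]:
        return set(self.removed_maf) | set(self.removed_missing) | set(self.removed_hwe)

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [("maf", s) for s in self.removed_maf]
            + [("missing", s) for s in self.removed_missing]
            + [("hwe", s) for s in self.removed_hwe]
        )
        return pd.DataFrame(rows, columns=["filter", "snp_id"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def log_text(self) -> str:
        t = self.thresholds
        return (
            f"SNP QC: {self.n_snp_in} in, {self.n_snp_out} out\n"
            f"  removed by MAF < {t.get('maf_min')}: {self.n_removed_maf}\n"
            f"  removed by missingness >= {t.get('miss_max')}: {self.n_removed_missing}\n"
            f"  removed by HWE p < {t.get('hwe_p_min')}: {self.n_removed_hwe}\n"
        )


def qc_filter(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    miss_max: float = 0.10,
    hwe_p_min: float = 1e-6,
    hwe_method: str = "exact",
    impute: bool = True,
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the marker QC filters and mean-impute surviving missing calls.

    Removes SNPs with minor-allele frequency below ``maf_min`` (monomorphic
    and all-missing SNPs included), missing fraction at or above ``miss_max``,
    or HWE test p-value below ``hwe_p_min``.  Remaining missing dosages are
    imputed to ``2 * p_j`` so downstream centring sends them to zero.
    """
    pvalue = hwe_exact_pvalue if hwe_method == "exact" else hwe_chisq_pvalue
    freqs = g.freqs
    miss = g.missing_fraction()
    with np.errstate(invalid="ignore"):
        maf = np.minimum(freqs, 1.0 - freqs)
    bad_maf = np.isnan(maf) | (maf < maf_min)
    bad_miss = miss >= miss_max
    bad_hwe = np.zeros(g.n_snp, dtype=bool)
    for j in range(g.n_snp):
        if bad_maf[j] or bad_miss[j]:
            continue  # already gone; skip the (relatively costly) exact test
        col = g.dosages[:, j]
        counts = [int(np.sum(col == k)) for k in (0.0, 1.0, 2.0)]
        if pvalue(counts[0], counts[1], counts[2]) < hwe_p_min:
            bad_hwe[j] = True

    keep = ~(bad_maf | bad_miss | bad_hwe)
    snp_arr = np.array(g.snp_ids)
    report = QcReport(
        n_snp_in=g.n_snp,
        n_snp_out=int(keep.sum()),
        removed_maf=snp_arr[bad_maf].tolist(),
        removed_missing=snp_arr[bad_miss].tolist(),
        removed_hwe=snp_arr[bad_hwe].tolist(),
        thresholds={
            "maf_min": maf_min,
            "miss_max": miss_max,
            "hwe_p_min": hwe_p_min,
            "hwe_method": hwe_method,
        },
    )
    if report.n_snp_out == 0:
        raise GenotypeError(
            "no SNP survived QC; review the maf/missingness/HWE thresholds"
        )
    dosages = g.dosages[:, keep].copy()
    kept_freqs = freqs[keep]
    if impute:
        nan_r, nan_c = np.nonzero(np.isnan(dosages))
        dosages[nan_r, nan_c] = 2.0 * kept_freqs[nan_c]
    return (
        GenotypeMatrix(
            ids=g.ids,
            snp_ids=tuple(snp_arr[keep].tolist()),
            dosages=dosages,
            freqs=kept_freqs,
        ),
        report,
    )


# ---------------------------------------------------------------------------
# genomic relationship matrix and H-inverse
# ---------------------------------------------------------------------------


def build_G(
    g: GenotypeMatrix,
    freq_source: str = "observed",
    freqs: np.ndarray | None = None,
) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix.

    ``G = Zc Zc' / (2 * sum_j p_j (1 - p_j))`` where ``Zc = M - P``,
    ``M`` recodes dosages to -1/0/1 and row ``j`` of ``P`` is
    ``2 (p_j - 0.5)``, so ``Zc = dosage - 2 p_j``.

    Parameters
    ----------
    freq_source
        ``"observed"`` uses frequencies computed from this matrix (its
        default QC-time frequencies); ``"supplied"`` uses the ``freqs``
        argument (e.g. base-population frequencies).
    """
    if freq_source == "observed":
        p = g.freqs
    elif freq_source == "supplied":
        if freqs is None:
            raise GenotypeError("freq_source='supplied' requires freqs")
        p = np.asarray(freqs, dtype=float)
        if p.shape != (g.n_snp,):
            raise GenotypeError("supplied freqs length does not match SNP count")
    else:
        raise GenotypeError(f"unknown freq_source {freq_source!r}")
    if np.isnan(g.dosages).any():
        raise GenotypeError("build_G requires complete dosages; run qc_filter first")
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise GenotypeError("all SNPs monomorphic: G scaling denominator is zero")
    zc = g.dosages - 2.0 * p  # == (dosages - 1) - 2 (p - 0.5)
    gmat = (zc @ zc.T) / denom
    gmat = (gmat + gmat.T) / 2.0
    return RelationshipMatrix(
        kind="G",
        ids=g.ids,
        values=gmat,
        meta={"freq_source": freq_source, "denominator": denom},
    )


def build_H_inverse(
    Ainv: RelationshipMatrix,
    A22: RelationshipMatrix,
    G: RelationshipMatrix,
    blend_weight: float = 0.95,
) -> RelationshipMatrix:
    """Single-step H-inverse: A-inverse plus the genotyped-block correction.

    ``H^-1 = A^-1 + [0 0; 0 (G*)^-1 - A22^-1]`` with
    ``G* = blend_weight * G + (1 - blend_weight) * A22`` guarding
    invertibility.  The genotyped block is aligned to ``G.ids``, which must
    equal ``A22.ids`` exactly.
    """
    if G.ids != A22.ids:
        raise GenotypeError("G and A22 id order mismatch; H-inverse needs exact agreement")
    missing = set(G.ids) - set(Ainv.ids)
    if missing:
        raise GenotypeError(f"genotyped ids absent from A-inverse: {sorted(missing)[:5]}")
    if not 0.0 < blend_weight <= 1.0:
        raise GenotypeError("blend_weight must be in (0, 1]")
    gdense = G.to_dense()
    a22 = A22.to_dense()
    if np.array_equal(gdense, a22):
        # correction block cancels exactly; skip blending round-off
        gstar = a22.copy()
    else:
        gstar = blend_weight * gdense + (1.0 - blend_weight) * a22
    try:
        gstar_inv = np.linalg.inv(gstar)
    except np.linalg.LinAlgError as exc:
        raise GenotypeError(
            "blended G is singular; try a lower blend_weight"
        ) from exc
    a22_inv = np.linalg.inv(a22)
    gstar_inv = (gstar_inv + gstar_inv.T) / 2.0
    a22_inv = (a22_inv + a22_inv.T) / 2.0
    h = Ainv.to_dense()
    idx = Ainv.index_of(G.ids)
    h[np.ix_(idx, idx)] += gstar_inv - a22_inv
    return RelationshipMatrix(
        kind="H_inverse",
        ids=Ainv.ids,
        values=h,
        meta={"blend_weight": blend_weight, "genotyped_ids": list(G.ids)},
    )
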