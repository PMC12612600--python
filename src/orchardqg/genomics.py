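"""SNP quality control and genomic relationship matrices for clonal material.

Genotypes are biallelic dosages (0/1/2 copies of the counted allele) on
clones, not ramets: every grafted ramet of a clone carries the same genotype,
so relatedness is estimated once per clone.  The relationship estimator is
the marker-based GRM of Yang et al. (the "GCTA" estimator), which standardizes
each SNP by its sample allele frequency and uses a frequency-corrected
diagonal so that an outbred, unrelated sample has mean diagonal ~1 and mean
off-diagonal ~0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


class GenomicsError(ValueError):
    """Raised for invalid genotype inputs or degenerate filtering outcomes."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class SnpMatrix:
    """Clones x markers dosage matrix with missing values as NaN.

    Parameters
    ----------
    clone_ids
        Unique clone identifiers, one per row.
    snp_ids
        Unique marker identifiers, one per column.
    dosages
        Float array of shape ``(n_clones, n_snps)`` with entries in
        ``{0, 1, 2, NaN}``.
    metadata
        Per-SNP summary table (call rate, allele frequency, observed
        heterozygosity, HWE p-value); populated by :func:`snp_summaries`.
    """

    clone_ids: np.ndarray
    snp_ids: np.ndarray
    dosages: np.ndarray
    metadata: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.clone_ids = np.asarray(self.clone_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (self.clone_ids.size, self.snp_ids.size):
            raise GenomicsError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{self.clone_ids.size} clones x {self.snp_ids.size} SNPs"
            )
        if len(set(self.clone_ids)) != self.clone_ids.size:
            raise GenomicsError("duplicate clone identifiers")
        if len(set(self.snp_ids)) != self.snp_ids.size:
            raise GenomicsError("duplicate SNP identifiers")
        with np.errstate(invalid="ignore"):
            bad = ~(np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0)))
        if bad.any():
            raise GenomicsError("dosage entries must be 0, 1, 2 or missing (NaN)")

    @property
    def n_clones(self) -> int:
        return self.clone_ids.size

    @property
    def n_snps(self) -> int:
        return self.snp_ids.size


@dataclass(frozen=True)
class FilterThresholds:
    """SNP quality thresholds.

    Defaults operationalize "low quality" as call rate < 0.90 and "low minor
    allele frequency" as MAF < 0.01; HWE and heterozygosity thresholds follow
    the usual array-QC convention (HWE p < 0.001 removed, observed
    heterozygosity above 60% removed).
    """

    min_call_rate: float = 0.90
    min_maf: float = 0.01
    hwe_alpha: float = 0.001
    max_heterozygosity: float = 0.60

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_maf", "hwe_alpha", "max_heterozygosity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GenomicsError(f"{name}={v} outside [0, 1]")


@dataclass
class GrMatrix:
    """Symmetric clones x clones genomic relationship matrix."""

    clone_ids: np.ndarray
    values: np.ndarray
    n_snps_used: int
    stabilized: bool = False

    def __post_init__(self) -> None:
        self.clone_ids = np.asarray(self.clone_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        n = self.clone_ids.size
        if self.values.shape != (n, n):
            raise GenomicsError("GRM must be square with one row per clone")
        if not np.all(np.isfinite(self.values)):
            raise GenomicsError("GRM contains non-finite entries")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise GenomicsError("GRM must be symmetric")
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n_clones(self) -> int:
        return self.clone_ids.size


# ---------------------------------------------------------------------------
# per-SNP summaries and Hardy-Weinberg tests
# ---------------------------------------------------------------------------


def snp_summaries(geno: SnpMatrix, hwe_method: str = "exact") -> SnpMatrix:
    """Populate per-SNP call rate, allele frequency, heterozygosity and HWE p.

    Allele frequency is the counted-allele frequency ``p = mean(dosage)/2``
    over non-missing calls; SNPs with no calls get ``p = NaN`` (flagged, never
    silently 0) and HWE p-value 1.
    """
    if geno.n_clones < 1 or geno.n_snps < 1:
        raise GenomicsError("need at least one clone and one SNP")
    d = geno.dosages
    obs = ~np.isnan(d)
    n_obs = obs.sum(axis=0)
    call_rate = n_obs / geno.n_clones
    with np.errstate(invalid="ignore"):
        freq = np.where(n_obs > 0, np.nansum(d, axis=0) / (2 * np.maximum(n_obs, 1)), np.nan)
        het = np.where(n_obs > 0, np.nansum(d == 1, axis=0) / np.maximum(n_obs, 1), np.nan)
    n_het = np.nansum(d == 1, axis=0).astype(int)
    n_alt = np.nansum(d == 2, axis=0).astype(int)
    n_ref = (n_obs - n_het - n_alt).astype(int)
    pvals = np.array(
        [
            hwe_test(r, h, a, method=hwe_method) if (r + h + a) > 0 else 1.0
            for r, h, a in zip(n_ref, n_het, n_alt)
        ]
    )
    meta = pd.DataFrame(
        {
            "snp_id": geno.snp_ids,
            "call_rate": call_rate,
            "freq": freq,
            "het": het,
            "hwe_p": pvals,
        }
    ).set_index("snp_id")
    return replace(geno, metadata=meta)


def hwe_test(n_hom_ref: int, n_het: int, n_hom_alt: int, method: str = "exact") -> float:
    """Hardy-Weinberg equilibrium p-value for one biallelic SNP.

    ``exact`` sums, conditional on the allele counts, the probabilities of
    all heterozygote counts no more probable than the observed one (the
    standard exact HWE test).  ``chi2`` is the 1-df goodness-of-fit test
    against expected HWE genotype counts.  Monomorphic SNPs return 1 by
    convention.
    """
    for c in (n_hom_ref, n_het, n_hom_alt):
        if c < 0 or int(c) != c:
            raise GenomicsError("genotype counts must be non-negative integers")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise GenomicsError("at least one genotyped individual required")
    n_minor = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if n_minor == 0:
        return 1.0
    if method == "chi2":
        from scipy import stats

        p = (2 * n_hom_alt + n_het) / (2 * n)
        exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
        obs = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0).sum()
        return float(stats.chi2.sf(stat, df=1))
    if method != "exact":
        raise GenomicsError(f"unknown HWE method {method!r}")
    return _hwe_exact(n, n_minor, n_het)


def _hwe_exact(n: int, n_minor: int, n_het_obs: int) -> float:
    # log-probability of each heterozygote count given n diploids and
    # n_minor minor alleles, then sum over counts with prob <= observed
    hets = [h for h in range(n_minor % 2, n_minor + 1, 2) if (n_minor - h) // 2 + h <= n]
    logp = []
    for h in hets:
        a = (n_minor - h) // 2  # minor homozygotes
        b = n - a - h  # major homozygotes
        lp = (
            math.lgamma(n + 1)
            - math.lgamma(a + 1)
            - math.lgamma(h + 1)
            - math.lgamma(b + 1)
            + h * math.log(2)
            + math.lgamma(n_minor + 1)
            + math.lgamma(2 * n - n_minor + 1)
            - math.lgamma(2 * n + 1)
        )
        logp.append(lp)
    logp = np.array(logp)
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs_idx = hets.index(n_het_obs)
    return float(min(1.0, probs[probs <= probs[obs_idx] * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def filter_snps(geno: SnpMatrix, t: FilterThresholds) -> SnpMatrix:
    """Retain SNPs passing all quality thresholds.

    A SNP is kept iff call rate >= ``min_call_rate``, minor allele frequency
    >= ``min_maf``, HWE p >= ``hwe_alpha`` and observed heterozygosity <=
    ``max_heterozygosity``.  Removal tallies (first-failure and any-failure)
    are attached to the result as ``filter_log``.
    """
    g = geno if geno.metadata is not None else snp_summaries(geno)
    m = g.metadata
    with np.errstate(invalid="ignore"):
        maf = np.minimum(m["freq"].to_numpy(), 1 - m["freq"].to_numpy())
    checks = {
        "call_rate": m["call_rate"].to_numpy() >= t.min_call_rate,
        "maf": np.nan_to_num(maf, nan=-1.0) >= t.min_maf,
        "hwe": m["hwe_p"].to_numpy() >= t.hwe_alpha,
        "het": np.nan_to_num(m["het"].to_numpy(), nan=2.0) <= t.max_heterozygosity,
    }
    keep = np.logical_and.reduce(list(checks.values()))
    any_fail = {k: int((~v).sum()) for k, v in checks.items()}
    first_fail: dict[str, int] = {k: 0 for k in checks}
    for j in range(g.n_snps):
        for k, v in checks.items():
            if not v[j]:
                first_fail[k] += 1
                break
    if not keep.any():
        raise GenomicsError(
            "no SNPs survive filtering; review thresholds "
            f"(removed any-failure tallies: {any_fail})"
        )
    out = SnpMatrix(
        clone_ids=g.clone_ids,
        snp_ids=g.snp_ids[keep],
        dosages=g.dosages[:, keep],
        metadata=m.loc[keep],
    )
    out.filter_log = {  # type: ignore[attr-defined]
        "n_in": g.n_snps,
        "n_out": int(keep.sum()),
        "removed_any": any_fail,
        "removed_first": first_fail,
    }
    return out


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------


def grm_yang(geno: SnpMatrix, min_freq_guard: float = 0.005) -> GrMatrix:
    """Yang et al. genomic relationship matrix from filtered dosages.

    Off-diagonals: ``A_jk = (1/m) sum_i (x_ij - 2p_i)(x_ik - 2p_i) /
    (2 p_i (1 - p_i))``.  Diagonals use the frequency-corrected form
    ``A_jj = 1 + (1/m) sum_i (x_ij^2 - (1 + 2p_i) x_ij + 2p_i^2) /
    (2 p_i (1-p_i))``.  Missing dosages are imputed to ``2 p_i`` (which zeroes
    their contribution); SNPs with sample frequency outside
    ``(min_freq_guard, 1 - min_freq_guard)`` are excluded.
    """
    if geno.n_clones < 2:
        raise GenomicsError("GRM requires at least two clones")
    d = geno.dosages
    obs = ~np.isnan(d)
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(n_obs > 0, np.nansum(d, axis=0) / (2 * np.maximum(n_obs, 1)), np.nan)
    usable = (p > min_freq_guard) & (p < 1 - min_freq_guard)
    if usable.sum() < 1:
        raise GenomicsError("fewer than one usable SNP for the GRM")
    x = d[:, usable]
    p = p[usable]
    m = int(usable.sum())
    denom = 2 * p * (1 - p)
    xc = np.where(np.isnan(x), 0.0, x - 2 * p)  # imputation to 2p => centered 0
    w = xc / np.sqrt(denom)
    a = (w @ w.T) / m
    # replace the diagonal with the inbreeding-corrected estimator
    x0 = np.where(np.isnan(x), 2 * p, x)
    diag = 1 + ((x0**2 - (1 + 2 * p) * x0 + 2 * p**2) / denom).sum(axis=1) / m
    np.fill_diagonal(a, diag)
    return GrMatrix(clone_ids=geno.clone_ids, values=a, n_snps_used=m)


def stabilize_psd(grm: GrMatrix, jitter: float = 1e-6) -> GrMatrix:
    """Add ``jitter * I`` only if the smallest eigenvalue is below ``jitter``.

    REML needs an invertible genetic covariance; marker-based GRMs on small
    samples can be rank-deficient.  The ``stabilized`` flag records whether
    anything was changed.
    """
    w = np.linalg.eigvalsh(grm.values)
    if w.min() >= jitter:
        return replace(grm, stabilized=False)
    shift = jitter - w.min()
    return GrMatrix(
        clone_ids=grm.clone_ids,
        values=grm.values + shift * np.eye(grm.n_clones),
        n_snps_used=grm.n_snps_used,
        stabilized=True,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_plink_raw(path) -> SnpMatrix:
    """Read a PLINK ``.raw`` additive-dosage file (FID IID PAT MAT SEX PHENOTYPE
    then one column per SNP; NA = missing).  IID is used as the clone id."""
    df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
    lead = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE") if c in df.columns]
    if "IID" not in lead:
        raise GenomicsError("PLINK .raw file lacks an IID column")
    snp_cols = [c for c in df.columns if c not in lead]
    return SnpMatrix(
        clone_ids=df["IID"].astype(str).to_numpy(),
        snp_ids=np.array(snp_cols, dtype=object),
        dosages=df[snp_cols].to_numpy(dtype=float),
    )


def write_plink_raw(geno: SnpMatrix, path) -> None:
    df = pd.DataFrame(geno.dosages, columns=list(geno.snp_ids))
    df.insert(0, "PHENOTYPE", -9)
    df.insert(0, "SEX", 0)
    df.insert(0, "MAT", 0)
    df.insert(0, "PAT", 0)
    df.insert(0, "IID", list(geno.clone_ids))
    df.insert(0, "FID", list(geno.clone_ids))
    with open(path, "w") as fh:
        df.to_csv(fh, sep=" ", index=False, na_rep="NA", float_format="%g")


def read_dosage_csv(path) -> SnpMatrix:
    """Read a simple CSV dialect: clones as rows (first column = clone id),
    SNPs as columns, NA for missing."""
    df = pd.read_csv(path, index_col=0, na_values=["NA"])
    return SnpMatrix(
        clone_ids=df.index.astype(str).to_numpy(),
        snp_ids=df.columns.to_numpy(dtype=object),
        dosages=df.to_numpy(dtype=float),
    )


def read_vcf_dosages(path) -> SnpMatrix:
    """Reduce a VCF to a dosage matrix (ALT-allele counts) via cyvcf2."""
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise GenomicsError("VCF ingestion requires the cyvcf2 package") from exc
    vcf = VCF(str(path))
    samples = np.array(vcf.samples, dtype=object)
    ids, rows = [], []
    for var in vcf:
        ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        gt = np.asarray(var.gt_types, dtype=float)  # 0=hom ref,1=het,2=unknown,3=hom alt
        row = np.where(gt == 3, 2.0, gt)
        row[gt == 2] = np.nan
        rows.append(row)
    return SnpMatrix(
        clone_ids=samples, snp_ids=np.array(ids, dtype=object), dosages=np.array(rows).T
    )


def write_grm_csv(grm: GrMatrix, path) -> None:
    pd.DataFrame(grm.values, index=list(grm.clone_ids), columns=list(grm.clone_ids)).to_csv(path)


def read_grm_csv(path) -> GrMatrix:
    df = pd.read_csv(path, index_col=0)
    return GrMatrix(
        clone_ids=df.index.astype(str).to_numpy(),
        values=df.to_numpy(dtype=float),
        n_snps_used=0,
    )


def write_grm_triplets(grm: GrMatrix, path) -> None:
    """Write the lower triangle as (id1, id2, value) rows."""
    with open(path, "w") as fh:
        fh.write("id1,id2,value\n")
        for i in range(grm.n_clones):
            for j in range(i + 1):
                fh.write(f"{grm.clone_ids[i]},{grm.clone_ids[j]},{grm.values[i, j]:.10g}\n")
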