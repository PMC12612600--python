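"""Needle functional traits and reflectance preprocessing.

Covers the laboratory side of the phenotyping: pigment concentrations from
spectrophotometric absorbances of N,N-dimethylformamide extracts (Wellburn
coefficient set for DMF), structural and water traits (LMA, NWC, EWT) from
fresh/dry mass and projected area, and the spectral preprocessing used for
needle-level (contact probe, ratio to a white reference, median of five
scans) and canopy-level (pair-averaged, head/tail-trimmed bands) reflectance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class PhenotypeError(ValueError):
    pass


# Wellburn pigment equations for N,N-dimethylformamide extracts, ug/mL.
# Pinned here so an alternate solvent set can be swapped in one place.
WELLBURN_DMF = {
    "chl_a": (11.65, -2.69),  # * A664', * A647'
    "chl_b": (-4.53, 20.81),
    "car": (1000.0, -0.89, -52.02, 245.0),  # (1000*A480' + c2*chla + c3*chlb)/c4
}


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PigmentAssay:
    """Extract absorbances (480/647/664/750 nm), extract volume and dry mass."""

    a480: float
    a647: float
    a664: float
    a750: float
    extract_volume_ml: float
    dry_mass_g: float

    def __post_init__(self) -> None:
        if min(self.a480, self.a647, self.a664, self.a750) < 0:
            raise PhenotypeError("absorbances must be non-negative")
        if self.extract_volume_ml <= 0 or self.dry_mass_g <= 0:
            raise PhenotypeError("extract volume and dry mass must be positive")


@dataclass(frozen=True)
class NeedleSample:
    """Fresh/dry mass (g), projected area (cm^2) and needle length (cm)."""

    fresh_mass_g: float
    dry_mass_g: float
    projected_area_cm2: float
    needle_length_cm: float

    def __post_init__(self) -> None:
        if not 0 < self.dry_mass_g <= self.fresh_mass_g:
            raise PhenotypeError("need 0 < dry mass <= fresh mass")
        if self.projected_area_cm2 <= 0:
            raise PhenotypeError("projected area must be positive")


NFT_COLUMNS = [
    "chl_a_M", "chl_b_M", "chl_T_M", "car_M",
    "chl_a_A", "chl_b_A", "chl_T_A", "car_A",
    "car_chlT_ratio", "LMA", "NWC", "EWT", "NL",
]


@dataclass
class NftRecord:
    """One ramet's needle functional traits.

    Mass-based pigments in mg/g dry mass, area-based in ug/cm^2; LMA and EWT
    in g/cm^2, NWC in percent of fresh mass, NL in cm.  ``car_chlT_ratio`` is
    NaN-flagged (``ratio_defined=False``) when total chlorophyll is zero.
    """

    chl_a_M: float
    chl_b_M: float
    chl_T_M: float
    car_M: float
    chl_a_A: float
    chl_b_A: float
    chl_T_A: float
    car_A: float
    car_chlT_ratio: float
    LMA: float
    NWC: float
    EWT: float
    NL: float
    ratio_defined: bool = True

    def __post_init__(self) -> None:
        for name in NFT_COLUMNS:
            v = getattr(self, name)
            if name == "car_chlT_ratio" and not self.ratio_defined:
                continue
            if not np.isfinite(v) or v < 0:
                raise PhenotypeError(f"{name}={v} violates non-negativity")
        for suffix in ("M", "A"):
            tot = getattr(self, f"chl_T_{suffix}")
            parts = getattr(self, f"chl_a_{suffix}") + getattr(self, f"chl_b_{suffix}")
            if abs(tot - parts) > 1e-9 * max(1.0, abs(tot)):
                raise PhenotypeError("chl_T must equal chl_a + chl_b")
        if not 0 <= self.NWC < 100:
            raise PhenotypeError("NWC must lie in [0, 100)")


@dataclass
class SpectraTable:
    """Ramets x wavelengths reflectance table.

    Reflectance is nominally in [0, 1]; small excursions above 1 occur in
    real data (bright references) and are tolerated up to 1.1 by the
    validity screen.
    """

    ramet_ids: np.ndarray
    wavelengths: np.ndarray
    reflectance: np.ndarray
    level: str = "needle"
    genetic_values: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.ramet_ids = np.asarray(self.ramet_ids, dtype=object)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.level not in ("needle", "canopy"):
            raise PhenotypeError("level must be 'needle' or 'canopy'")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise PhenotypeError("wavelengths must be strictly increasing")
        if self.reflectance.shape != (self.ramet_ids.size, self.wavelengths.size):
            raise PhenotypeError("reflectance shape mismatch")

    @property
    def n_bands(self) -> int:
        return self.wavelengths.size


# ---------------------------------------------------------------------------
# spectra operations
# ---------------------------------------------------------------------------


def reflectance_from_radiance(sample_radiance, white_radiance) -> np.ndarray:
    """Per-band reflectance as the sample/white-reference radiance ratio."""
    s = np.asarray(sample_radiance, dtype=float)
    w = np.asarray(white_radiance, dtype=float)
    if s.shape != w.shape:
        raise PhenotypeError("sample and white reference must share the band grid")
    bad = np.flatnonzero(w <= 0)
    if bad.size:
        raise PhenotypeError(f"non-positive white-reference radiance at band index {bad[0]}")
    return s / w


def median_needle_spectrum(scans) -> np.ndarray:
    """Per-band median over repeated scans of one sample (median of five in
    the standard protocol; an even scan count uses the mean of the middle
    two, the usual median convention)."""
    arrs = [np.asarray(s, dtype=float) for s in scans]
    if not arrs:
        raise PhenotypeError("need at least one scan")
    if len({a.shape for a in arrs}) != 1:
        raise PhenotypeError("scans have ragged band grids")
    return np.median(np.stack(arrs), axis=0)


def preprocess_canopy_bands(
    raw: SpectraTable, head_drop: int = 13, tail_drop: int = 36
) -> SpectraTable:
    """Pair-average neighboring bands and trim noisy head/tail bands.

    Every band i is replaced by the mean of bands (i, i+1), the last band is
    kept as-is (count preserved), then the first ``head_drop`` and last
    ``tail_drop`` bands are dropped.  A 269-band camera cube therefore yields
    exactly 220 analysis bands.
    """
    n = raw.n_bands
    if n < head_drop + tail_drop + 1:
        raise PhenotypeError(f"{n} bands too few for head_drop={head_drop}, tail_drop={tail_drop}")
    r = raw.reflectance
    smoothed = r.copy()
    smoothed[:, :-1] = 0.5 * (r[:, :-1] + r[:, 1:])
    sl = slice(head_drop, n - tail_drop if tail_drop else None)
    return SpectraTable(
        ramet_ids=raw.ramet_ids,
        wavelengths=raw.wavelengths[sl],
        reflectance=smoothed[:, sl],
        level=raw.level,
    )


def screen_reflectance(table: SpectraTable, lo: float = 0.0, hi: float = 1.1,
                       max_flag_fraction: float = 0.05) -> tuple[SpectraTable, pd.DataFrame]:
    """Flag out-of-range cells and drop rows with > 5% flagged cells."""
    flags = (table.reflectance < lo) | (table.reflectance > hi)
    frac = flags.mean(axis=1)
    keep = frac <= max_flag_fraction
    report = pd.DataFrame(
        {"ramet_id": table.ramet_ids, "flagged_fraction": frac, "kept": keep}
    )
    out = SpectraTable(
        ramet_ids=table.ramet_ids[keep],
        wavelengths=table.wavelengths,
        reflectance=table.reflectance[keep],
        level=table.level,
    )
    return out, report


# ---------------------------------------------------------------------------
# needle functional traits
# ---------------------------------------------------------------------------


def pigment_concentrations(assay: PigmentAssay) -> dict[str, float]:
    """Mass-based pigment contents from a DMF extract.

    The 750-nm absorbance is treated as a turbidity blank and subtracted
    from the other readings (clipped at zero with a warning if a corrected
    absorbance would go negative).  Concentrations in the extract (ug/mL)
    follow the DMF coefficient set; conversion to mg per g dry needle mass is
    ``ug/mL * extract volume (mL) / dry mass (g) / 1000``.
    """
    a480, a647, a664 = (max_or_warn(a - assay.a750) for a in (assay.a480, assay.a647, assay.a664))
    ca, cb = WELLBURN_DMF["chl_a"], WELLBURN_DMF["chl_b"]
    chl_a = ca[0] * a664 + ca[1] * a647
    chl_b = cb[0] * a664 + cb[1] * a647
    chl_a, chl_b = max(chl_a, 0.0), max(chl_b, 0.0)
    k1000, c2, c3, c4 = WELLBURN_DMF["car"]
    car = max((k1000 * a480 + c2 * chl_a + c3 * chl_b) / c4, 0.0)
    to_mg_per_g = assay.extract_volume_ml / assay.dry_mass_g / 1000.0
    chl_a_m, chl_b_m, car_m = (v * to_mg_per_g for v in (chl_a, chl_b, car))
    chl_t_m = chl_a_m + chl_b_m
    ratio = car_m / chl_t_m if chl_t_m > 0 else float("nan")
    return {
        "chl_a_M": chl_a_m,
        "chl_b_M": chl_b_m,
        "chl_T_M": chl_t_m,
        "car_M": car_m,
        "car_chlT_ratio": ratio,
        "ratio_defined": chl_t_m > 0,
    }


def max_or_warn(value: float) -> float:
    if value < 0:
        warnings.warn("turbidity-corrected absorbance below zero; clipped", stacklevel=3)
        return 0.0
    return value


def structural_traits(s: NeedleSample) -> dict[str, float]:
    """LMA (g/cm^2), NWC (% of fresh mass), EWT (g/cm^2) and needle length."""
    water = s.fresh_mass_g - s.dry_mass_g
    return {
        "LMA": s.dry_mass_g / s.projected_area_cm2,
        "NWC": 100.0 * water / s.fresh_mass_g,
        "EWT": water / s.projected_area_cm2,
        "NL": s.needle_length_cm,
    }


def area_based_pigments(mass_based: dict[str, float], lma: float) -> dict[str, float]:
    """Convert mg/g pigment contents to ug/cm^2 via LMA (g/cm^2)."""
    if lma <= 0:
        raise PhenotypeError("LMA must be positive")
    out = {}
    for key in ("chl_a", "chl_b", "chl_T", "car"):
        out[f"{key}_A"] = mass_based[f"{key}_M"] * lma * 1000.0
    return out


def nft_record(assay: PigmentAssay, sample: NeedleSample) -> NftRecord:
    """Full per-ramet trait record from one pigment assay and one needle sample."""
    pig = pigment_concentrations(assay)
    struct = structural_traits(sample)
    area = area_based_pigments(pig, struct["LMA"])
    ratio_defined = bool(pig.pop("ratio_defined"))
    ratio = pig.pop("car_chlT_ratio")
    return NftRecord(
        **{k: pig[k] for k in ("chl_a_M", "chl_b_M", "chl_T_M", "car_M")},
        **area,
        car_chlT_ratio=ratio if ratio_defined else float("nan"),
        ratio_defined=ratio_defined,
        **struct,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_spectra_wide(table: SpectraTable, path) -> None:
    df = pd.DataFrame(
        table.reflectance, columns=[f"{w:g}" for w in table.wavelengths]
    )
    df.insert(0, "ramet_id", list(table.ramet_ids))
    df.to_csv(path, index=False)


def read_spectra_wide(path, level: str = "needle") -> SpectraTable:
    df = pd.read_csv(path)
    wl_cols = [c for c in df.columns if c != "ramet_id"]
    return SpectraTable(
        ramet_ids=df["ramet_id"].astype(str).to_numpy(),
        wavelengths=np.array([float(c) for c in wl_cols]),
        reflectance=df[wl_cols].to_numpy(dtype=float),
        level=level,
    )


def write_spectra_long(table: SpectraTable, path) -> None:
    n, b = table.reflectance.shape
    pd.DataFrame(
        {
            "ramet_id": np.repeat(table.ramet_ids, b),
            "wavelength": np.tile(table.wavelengths, n),
            "reflectance": table.reflectance.ravel(),
        }
    ).to_csv(path, index=False)


def nft_table(records: dict[str, NftRecord]) -> pd.DataFrame:
    """Assemble per-ramet records into a CSV-ready trait table."""
    rows = {rid: {c: getattr(rec, c) for c in NFT_COLUMNS} for rid, rec in records.items()}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "ramet_id"
    return df
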