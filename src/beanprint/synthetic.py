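"""Seeded generator of NIR-like green-coffee spectra.

Real spectra of whole green beans show broad overlapping absorbance bands
from O-H, C-H and N-H overtone/combination vibrations, with origin-dependent
amplitude differences concentrated above 1400 nm, plus three nuisance layers
the preprocessing chain is designed to remove: multiplicative scatter between
replicate scans, additive baseline offset/slope drift, and white detector
noise. The generator reproduces exactly that structure:

    A(s, r, lam) = scatter_r * [ base(lam) * ramp(lam)
                                 + sum_b m_class(b) * G_b(lam)
                                 + sample_effect_s(lam) ]
                   + offset_r + slope_r * (lam - lam_0) + noise

* ``G_b`` are Gaussian bands (in nm) at the canonical green-coffee peak
  positions 920, 1000, 1200, 1470, 1700, 1760, 1900, 2130 and 2400 nm.
* Class structure enters only through per-band amplitude multipliers
  ``m_class``, by default confined to bands at or above 1400 nm with the
  continent ordering Africa > South America > Asia > Central America > Yemen.
* The sample effect — shared by all replicates of a sample and mimicking
  within-origin biological variation — is a smooth low-frequency curve (sum
  of three wide random Gaussians). Being smooth, it is essentially erased by
  the second-derivative pre-treatment, so replicates of one sample carry no
  exploitable sample-specific signature in the processed domain and a
  dataset without a class effect classifies at chance. An optional
  ``band_jitter_sd`` adds per-sample compositional variation of the band
  amplitudes (off by default); turning it on makes replicate spectra
  sample-identifiable after preprocessing.
* Scatter, baseline and noise are drawn independently per replicate scan.

True NIR band shapes live in the wavenumber domain; Gaussians in nm are an
adequate statistical stand-in for testing the analysis chain and are not
meant to be spectroscopically exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import LabelScheme, META_COLUMNS, SpectralDataset

#: canonical absorbance peak positions (nm) for whole green coffee beans
DEFAULT_BAND_CENTERS = (920, 1000, 1200, 1470, 1700, 1760, 1900, 2130, 2400)


@dataclass
class BandDef:
    """One Gaussian absorbance band: centre (nm), width (Gaussian sd, nm),
    base amplitude (AU)."""

    center_nm: float
    width_nm: float
    base_amplitude: float

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ValueError("band width must be positive")
        if self.base_amplitude < 0:
            raise ValueError("band amplitude must be non-negative")


def default_bands() -> list[BandDef]:
    widths = (28, 32, 45, 40, 38, 30, 55, 60, 60)
    amplitudes = (0.12, 0.18, 0.28, 0.32, 0.40, 0.36, 0.52, 0.48, 0.42)
    return [
        BandDef(c, w, a)
        for c, w, a in zip(DEFAULT_BAND_CENTERS, widths, amplitudes)
    ]


def graded_multipliers(
    classes: list[str],
    bands: list[BandDef],
    above_nm: float = 1400.0,
    step: float = 0.04,
) -> dict[str, np.ndarray]:
    """Per-class band multipliers: 1 below ``above_nm``, graded steps above.

    The first class gets multiplier 1.0 on the high-wavelength bands, the
    second 1 + step, and so on — encoding an absorbance ordering like
    Yemen < Central America < Asia < South America < Africa.
    """
    high = np.array([b.center_nm >= above_nm for b in bands])
    out = {}
    for i, c in enumerate(classes):
        m = np.ones(len(bands))
        m[high] = 1.0 + step * i
        out[c] = m
    return out


@dataclass
class SyntheticSpec:
    """Full description of one synthetic dataset.

    Defaults reproduce the acquisition design the analysis expects: a
    949-point grid over 866-2532 nm, 4 replicate scans per sample, two
    origin classes of 50 samples whose band amplitudes differ by 10% above
    1400 nm, smooth per-sample biological variation, and replicate-level
    scatter/baseline/noise nuisance.
    """

    classes: list[str] = field(default_factory=lambda: ["Yemen", "Other"])
    class_multipliers: dict[str, np.ndarray] | None = None
    n_samples_per_class: int | dict[str, int] = 50
    n_replicates: int = 4
    grid: tuple[float, float, int] = (866.0, 2532.0, 949)
    bands: list[BandDef] = field(default_factory=default_bands)
    base_level: float = 0.25
    ramp: tuple[float, float] = (1.0, 1.8)  # base continuum multiplier ends
    sample_effect_sd: float = 0.01
    band_jitter_sd: float = 0.0
    replicate_noise_sd: float = 5e-5
    scatter_range: tuple[float, float] = (0.95, 1.05)
    baseline_offset_range: tuple[float, float] = (-0.02, 0.02)
    baseline_slope_range: tuple[float, float] = (-2e-5, 2e-5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid[2] < 2 or self.grid[0] >= self.grid[1]:
            raise ValueError("grid must be (lo < hi, >= 2 points)")
        if self.class_multipliers is None:
            self.class_multipliers = graded_multipliers(
                self.classes, self.bands, step=0.10 if len(self.classes) == 2 else 0.04
            )
        for c, m in self.class_multipliers.items():
            m = np.asarray(m, dtype=float)
            if m.shape != (len(self.bands),) or np.any(m <= 0):
                raise ValueError(f"class {c!r}: need {len(self.bands)} positive multipliers")
            self.class_multipliers[c] = m

    def samples_for(self, c: str) -> int:
        if isinstance(self.n_samples_per_class, dict):
            return int(self.n_samples_per_class[c])
        return int(self.n_samples_per_class)

    def wavelengths(self) -> np.ndarray:
        lo, hi, n = self.grid
        return np.linspace(lo, hi, int(n))


def _class_mean_clean(spec: SyntheticSpec, cls: str) -> np.ndarray:
    """Noise-free class mean spectrum (continuum + class-scaled bands)."""
    wl = spec.wavelengths()
    ramp = np.interp(wl, [wl[0], wl[-1]], spec.ramp)
    signal = spec.base_level * ramp
    for b, m in zip(spec.bands, spec.class_multipliers[cls]):
        signal = signal + m * b.base_amplitude * np.exp(
            -0.5 * ((wl - b.center_nm) / b.width_nm) ** 2
        )
    return signal


def generate_dataset(spec: SyntheticSpec) -> tuple[SpectralDataset, LabelScheme]:
    """Draw one dataset; byte-identical for identical specs (same seed)."""
    wl = spec.wavelengths()
    rng = np.random.default_rng(spec.seed)
    rows, meta_rows = [], []
    for cls in spec.classes:
        n_samples = spec.samples_for(cls)
        if n_samples <= 0:
            raise ValueError(f"class {cls!r}: zero samples requested")
        ramp = np.interp(wl, [wl[0], wl[-1]], spec.ramp)
        continuum = spec.base_level * ramp
        multipliers = spec.class_multipliers[cls]
        for s in range(n_samples):
            sample_id = f"{cls}_{s + 1:03d}"
            # smooth per-sample biological variation: 3 wide random Gaussians
            effect = np.zeros_like(wl)
            for _ in range(3):
                center = rng.uniform(wl[0], wl[-1])
                width = rng.uniform(150.0, 400.0)
                amp = rng.normal(0.0, spec.sample_effect_sd)
                effect += amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
            # compositional variation: jitter each band's amplitude per sample
            jitter = 1.0 + rng.normal(0.0, spec.band_jitter_sd, len(spec.bands))
            sample_signal = continuum + effect
            for b, m, j in zip(spec.bands, multipliers, jitter):
                sample_signal = sample_signal + m * j * b.base_amplitude * np.exp(
                    -0.5 * ((wl - b.center_nm) / b.width_nm) ** 2
                )
            for r in range(1, spec.n_replicates + 1):
                scatter = rng.uniform(*spec.scatter_range)
                offset = rng.uniform(*spec.baseline_offset_range)
                slope = rng.uniform(*spec.baseline_slope_range)
                noise = rng.normal(0.0, spec.replicate_noise_sd, wl.size)
                rows.append(
                    scatter * sample_signal + offset + slope * (wl - wl[0]) + noise
                )
                meta_rows.append(
                    {
                        "spectrum_id": f"{sample_id}_r{r}",
                        "sample_id": sample_id,
                        "replicate": r,
                        "country": cls,
                        "region": "",
                        "variety": "synthetic",
                        "process": "synthetic",
                    }
                )
    if not rows:
        raise ValueError("spec produced zero spectra")
    meta = pd.DataFrame(meta_rows, columns=META_COLUMNS)
    ds = SpectralDataset(wl, np.array(rows), meta)
    mapping = {
        sid: cls
        for sid, cls in meta.drop_duplicates("sample_id")[["sample_id", "country"]]
        .to_numpy()
    }
    scheme = LabelScheme("country-set", list(spec.classes), mapping)
    return ds, scheme


def inject_adulteration(
    ds: SpectralDataset,
    fraction: float,
    donor_class: str,
    victim_class: str,
    seed: int = 0,
) -> tuple[SpectralDataset, list[str]]:
    """Relabel a random fraction of donor-class samples as the victim class.

    Emulates origin fraud (e.g. non-Yemeni beans re-exported under a Yemeni
    label): whole samples flip label with all their replicates; the true
    labels are returned separately as the list of relabelled sample ids.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    table = ds.sample_table()
    donors = table.index[table["country"] == donor_class].to_numpy()
    if donors.size == 0:
        raise ValueError(f"no samples of donor class {donor_class!r}")
    n_flip = int(round(fraction * donors.size))
    if n_flip == 0:
        raise ValueError(
            f"fraction {fraction} of {donors.size} samples rounds to zero"
        )
    rng = np.random.default_rng(seed)
    flipped = sorted(rng.choice(donors, size=n_flip, replace=False).tolist())
    meta = ds.meta.copy()
    meta.loc[meta["sample_id"].isin(flipped), "country"] = victim_class
    return SpectralDataset(ds.wavelengths_nm.copy(), ds.absorbance.copy(), meta), flipped


def five_origin_spec(seed: int = 0, n_samples_per_class: int = 15) -> SyntheticSpec:
    """Convenience spec with the five-continent class structure."""
    classes = ["Yemen", "C_America", "Asia", "S_America", "Africa"]
    return SyntheticSpec(
        classes=classes,
        n_samples_per_class=n_samples_per_class,
        seed=seed,
    )
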