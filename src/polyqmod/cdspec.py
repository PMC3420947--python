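"""Circular-dichroism spectrum processing and the 222/208 nm ratio.

Far-UV CD spectra distinguish secondary-structure content of purified
proteins.  For coiled coils the diagnostic is the ratio of mean residue
ellipticities at 222 and 208 nm: isolated alpha helices have
|[theta]208| > |[theta]222| (ratio < 1), whereas packing of helices into
a coiled coil deepens the 222 nm band, pushing [theta]222/[theta]208
above 1.0.

Processing steps:

* normalisation of raw machine ellipticity (millidegrees) to mean residue
  ellipticity  [theta] = theta_mdeg / (10 * l_cm * c_M * n_residues)
  in deg cm^2 dmol^-1 residue^-1,
* light smoothing with a centred moving average,
* subtraction of a fusion-tag spectrum (e.g. GST) from a tag-domain
  fusion spectrum to isolate the domain signal — performed in per-mole
  ellipticity space and only then renormalised by the domain's residue
  count, because the fusion and the tag have different residue numbers so
  subtracting MREs directly would be dimensionally wrong,
* read-off of the [theta]222/[theta]208 ratio, with ratio > 1.0 (strict)
  calling a coiled-coil conformation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "RawSpectrum",
    "MRESpectrum",
    "CDResult",
    "mre_normalize",
    "smooth",
    "subtract_tag",
    "ellipticity_ratio",
]


def _check_grid(wavelengths: np.ndarray) -> np.ndarray:
    wl = np.asarray(wavelengths, dtype=float)
    d = np.diff(wl)
    if len(wl) < 2 or not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("wavelength grid must be strictly monotone with >= 2 points")
    return wl


@dataclass
class RawSpectrum:
    """Machine-units CD spectrum (millidegrees) with sample metadata."""

    wavelengths: np.ndarray  # nm
    ellipticity: np.ndarray  # millidegrees
    concentration: float  # molar
    path_length: float  # cm
    n_residues: int
    name: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = _check_grid(self.wavelengths)
        self.ellipticity = np.asarray(self.ellipticity, dtype=float)
        if self.ellipticity.shape != self.wavelengths.shape:
            raise ValueError("wavelengths and ellipticity must have equal length")
        if not (self.concentration > 0 and self.path_length > 0):
            raise ValueError("concentration and path_length must be positive")
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")


@dataclass
class MRESpectrum:
    """Mean residue ellipticity, deg cm^2 dmol^-1 residue^-1."""

    wavelengths: np.ndarray
    mre: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = _check_grid(self.wavelengths)
        self.mre = np.asarray(self.mre, dtype=float)
        if self.mre.shape != self.wavelengths.shape:
            raise ValueError("wavelengths and mre must have equal length")
        if not np.all(np.isfinite(self.mre)):
            raise ValueError("mre values must be finite")


@dataclass
class CDResult:
    theta222: float
    theta208: float
    ratio: float
    cc_call: bool


def mre_normalize(raw: RawSpectrum) -> MRESpectrum:
    """Normalise millidegrees to mean residue ellipticity.

    [theta](lambda) = theta_mdeg / (10 * path_length_cm * c_M * n_residues).
    """
    denom = 10.0 * raw.path_length * raw.concentration * raw.n_residues
    return MRESpectrum(raw.wavelengths.copy(), raw.ellipticity / denom, name=raw.name)


def smooth(spectrum, window: int = 3):
    """Centred moving average; edges use shrunken (one-sided) windows.

    Accepts a RawSpectrum or MRESpectrum and returns the same type.
    ``window`` must be odd and no longer than the grid.
    """
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    values = spectrum.ellipticity if isinstance(spectrum, RawSpectrum) else spectrum.mre
    n = len(values)
    if window > n:
        raise ValueError("smoothing window exceeds grid length")
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = values[lo:hi].mean()
    if isinstance(spectrum, RawSpectrum):
        return replace(spectrum, ellipticity=out)
    return replace(spectrum, mre=out)


def subtract_tag(
    fusion: RawSpectrum,
    tag: RawSpectrum,
    domain_n_residues: int,
    concentration_rtol: float = 1e-3,
) -> MRESpectrum:
    """Isolate a domain spectrum by subtracting the tag from the fusion.

    Both spectra must be equimolar (concentrations equal within
    ``concentration_rtol``).  The tag spectrum is brought to the fusion's
    path length and concentration in per-mole ellipticity space, linearly
    interpolated onto the fusion grid (which must lie within the tag
    grid), subtracted, and the difference normalised by the domain's own
    residue count.
    """
    if domain_n_residues < 1:
        raise ValueError("domain_n_residues must be >= 1")
    if not np.isclose(fusion.concentration, tag.concentration, rtol=concentration_rtol):
        raise ValueError(
            f"concentration mismatch: fusion {fusion.concentration} M vs "
            f"tag {tag.concentration} M"
        )
    wl_f = fusion.wavelengths
    wl_t = tag.wavelengths
    lo, hi = min(wl_t[0], wl_t[-1]), max(wl_t[0], wl_t[-1])
    if wl_f.min() < lo - 1e-9 or wl_f.max() > hi + 1e-9:
        raise ValueError("fusion grid is not covered by the tag grid")
    # per-mole molar ellipticity: theta_mdeg / (10 * l * c)
    fus_molar = fusion.ellipticity / (10.0 * fusion.path_length * fusion.concentration)
    tag_molar = tag.ellipticity / (10.0 * tag.path_length * tag.concentration)
    order = np.argsort(wl_t)
    tag_on_fusion = np.interp(wl_f, wl_t[order], tag_molar[order])
    domain_molar = fus_molar - tag_on_fusion
    return MRESpectrum(
        wl_f.copy(),
        domain_molar / domain_n_residues,
        name=fusion.name + "-minus-" + (tag.name or "tag"),
    )


def ellipticity_ratio(
    spectrum: MRESpectrum, lambda_num: float = 222.0, lambda_den: float = 208.0
) -> CDResult:
    """[theta]222/[theta]208 with the strict > 1.0 coiled-coil call.

    Values are read off by linear interpolation on the MRE grid; the grid
    must cover both wavelengths.
    """
    wl = spectrum.wavelengths
    lo, hi = wl.min(), wl.max()
    if not (lo <= lambda_num <= hi and lo <= lambda_den <= hi):
        raise ValueError(
            f"grid [{lo}, {hi}] nm does not cover {lambda_den} and {lambda_num} nm"
        )
    order = np.argsort(wl)
    theta222 = float(np.interp(lambda_num, wl[order], spectrum.mre[order]))
    theta208 = float(np.interp(lambda_den, wl[order], spectrum.mre[order]))
    if theta208 == 0:
        raise ValueError("[theta]208 is zero; ratio undefined")
    ratio = theta222 / theta208
    return CDResult(theta222, theta208, ratio, bool(ratio > 1.0))
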