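"""1-D turbid-medium canopy bidirectional reflectance (SAIL family).

Four-stream scattering by arbitrarily inclined leaves: the canopy is a
horizontally homogeneous layer of leaf area index ``LAI`` whose leaf normals
follow an ellipsoidal inclination distribution parameterized by the average
leaf angle, bounded below by a Lambertian soil.  The model propagates direct
solar flux, two hemispherical diffuse fluxes and the flux in the observer
direction, including the hot-spot correction for the correlation between
sunlit and viewed leaf area.

Inputs are the leaf reflectance/transmittance spectra, a soil reflectance
spectrum on the same wavelength grid, canopy structure and sun/view geometry;
the output is the canopy bidirectional reflectance factor (BRF) per
wavelength for direct solar illumination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .prospect import LeafOptics

__all__ = ["CanopyParams", "ViewGeometry", "sail4", "ellipsoidal_lidf"]


@dataclass(frozen=True)
class CanopyParams:
    """Canopy structure.

    LAI        : leaf area index, m^2/m^2
    ALA        : average leaf inclination angle, degrees
    HotS       : hot-spot parameter (leaf size / canopy height), m/m
    alpha_soil : soil brightness scaling factor in [0, 1]
    """

    LAI: float
    ALA: float
    HotS: float
    alpha_soil: float

    def __post_init__(self) -> None:
        if self.LAI < 0:
            raise ValueError("LAI must be non-negative")
        if not 0.0 < self.ALA < 90.0:
            raise ValueError("ALA must be in (0, 90) degrees")
        if self.HotS < 0:
            raise ValueError("HotS must be non-negative")
        if not 0.0 <= self.alpha_soil <= 1.0:
            raise ValueError("alpha_soil must be in [0, 1]")


@dataclass(frozen=True)
class ViewGeometry:
    """Sun/view geometry in degrees; defaults match the simulation setup."""

    SZA: float = 30.0
    OZA: float = 0.0
    rel_azimuth: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.SZA < 90.0 or not 0.0 <= self.OZA < 90.0:
            raise ValueError("zenith angles must be in [0, 90)")


_LIDF_ANGLES_DEG = np.arange(5.0, 90.0, 10.0)  # 9 bins of 10 degrees


def ellipsoidal_lidf(ala_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Ellipsoidal (Campbell-type) leaf inclination distribution.

    Returns bin-center angles (deg) and frequencies summing to 1 for nine
    10-degree inclination bins.  The ellipsoid eccentricity is tied to the
    average leaf angle by the standard empirical polynomial.
    """
    ala = float(ala_deg)
    excent = np.exp(-1.6184e-5 * ala**3 + 2.1145e-3 * ala**2 - 1.2390e-1 * ala + 3.2491)
    tl1 = np.radians(_LIDF_ANGLES_DEG + 5.0)
    tl2 = np.radians(_LIDF_ANGLES_DEG - 5.0)
    x1 = excent / np.sqrt(1.0 + excent**2 * np.tan(tl1) ** 2)
    x2 = excent / np.sqrt(1.0 + excent**2 * np.tan(tl2) ** 2)
    if abs(excent - 1.0) < 1e-9:
        freq = np.abs(np.cos(tl1) - np.cos(tl2))
    else:
        alpha = excent / np.sqrt(abs(1.0 - excent**2))
        alpha2 = alpha**2
        if excent > 1.0:
            alpx1 = np.sqrt(alpha2 + x1**2)
            alpx2 = np.sqrt(alpha2 + x2**2)
            dump = x1 * alpx1 + alpha2 * np.log(x1 + alpx1)
            freq = np.abs(dump - (x2 * alpx2 + alpha2 * np.log(x2 + alpx2)))
        else:
            almx1 = np.sqrt(alpha2 - x1**2)
            almx2 = np.sqrt(alpha2 - x2**2)
            dump = x1 * almx1 + alpha2 * np.arcsin(x1 / alpha)
            freq = np.abs(dump - (x2 * almx2 + alpha2 * np.arcsin(x2 / alpha)))
    return _LIDF_ANGLES_DEG.copy(), freq / freq.sum()


def _volscatt(tts: float, tto: float, psi: float, ttl: float):
    """Geometric extinction and volume-scattering factors for one leaf angle.

    All angles in radians; returns (chi_s, chi_o, frho, ftau).
    """
    costs, costo = np.cos(tts), np.cos(tto)
    sints, sinto = np.sin(tts), np.sin(tto)
    cospsi = np.cos(psi)
    costl, sintl = np.cos(ttl), np.sin(ttl)
    cs = costl * costs
    co = costl * costo
    ss = sintl * sints
    so = sintl * sinto
    cosbts = -cs / ss if abs(ss) > 1e-6 else 5.0
    cosbto = -co / so if abs(so) > 1e-6 else 5.0
    if abs(cosbts) < 1.0:
        bts = np.arccos(cosbts)
        ds = ss
    else:
        bts = np.pi
        ds = cs
    chi_s = 2.0 / np.pi * ((bts - np.pi * 0.5) * cs + np.sin(bts) * ss)
    if abs(cosbto) < 1.0:
        bto = np.arccos(cosbto)
        do_ = so
    elif tto < np.pi / 2.0:
        bto = np.pi
        do_ = co
    else:
        bto = 0.0
        do_ = -co
    chi_o = 2.0 / np.pi * ((bto - np.pi * 0.5) * co + np.sin(bto) * so)
    btran1 = abs(bts - bto)
    btran2 = 2.0 * np.pi - bts - bto
    if psi <= btran1:
        bt1, bt2, bt3 = psi, btran1, btran2
    elif psi <= btran2:
        bt1, bt2, bt3 = btran1, psi, btran2
    else:
        bt1, bt2, bt3 = btran1, btran2, psi
    t1 = 2.0 * cs * co + ss * so * cospsi
    t2 = np.sin(bt2) * (2.0 * ds * do_ + ss * so * np.cos(bt1) * np.cos(bt3)) if bt2 > 0 else 0.0
    denom = 2.0 * np.pi**2
    frho = max(((np.pi - bt2) * t1 + t2) / denom, 0.0)
    ftau = max((-bt2 * t1 + t2) / denom, 0.0)
    return chi_s, chi_o, frho, ftau


def _jfunc1(k: float, m: np.ndarray, lai: float) -> np.ndarray:
    d = (k - m) * lai
    out = np.empty_like(m)
    small = np.abs(d) < 1e-3
    out[~small] = (np.exp(-m[~small] * lai) - np.exp(-k * lai)) / (k - m[~small])
    out[small] = (
        0.5 * lai * (np.exp(-k * lai) + np.exp(-m[small] * lai)) * (1.0 - d[small] ** 2 / 12.0)
    )
    return out


def _jfunc2(k: float, m: np.ndarray, lai: float) -> np.ndarray:
    return (1.0 - np.exp(-(k + m) * lai)) / (k + m)


def sail4(
    canopy: CanopyParams,
    optics: LeafOptics,
    soil_reflectance: np.ndarray,
    geom: ViewGeometry = ViewGeometry(),
) -> np.ndarray:
    """Canopy bidirectional reflectance factor for direct solar illumination.

    ``soil_reflectance`` must be sampled on the wavelength grid of ``optics``.
    The vanishing-LAI limit returns the soil spectrum.
    """
    rho = np.asarray(optics.reflectance, dtype=float)
    tau = np.asarray(optics.transmittance, dtype=float)
    rsoil = np.asarray(soil_reflectance, dtype=float)
    if rsoil.shape != rho.shape:
        raise ValueError("soil spectrum must be on the leaf optics wavelength grid")
    lai = canopy.LAI
    if lai < 1e-8:
        return rsoil.copy()

    tts = np.radians(geom.SZA)
    tto = np.radians(geom.OZA)
    psi = np.radians(geom.rel_azimuth)
    cts, cto = np.cos(tts), np.cos(tto)
    ctscto = cts * cto
    tants, tanto = np.tan(tts), np.tan(tto)
    dso = np.sqrt(tants**2 + tanto**2 - 2.0 * tants * tanto * np.cos(psi))

    angles, freq = ellipsoidal_lidf(canopy.ALA)
    ks = ko = bf = sob = sof = 0.0
    for ang, f in zip(np.radians(angles), freq):
        chi_s, chi_o, frho, ftau = _volscatt(tts, tto, psi, ang)
        ks += f * chi_s / cts
        ko += f * chi_o / cto
        bf += f * np.cos(ang) ** 2
        sob += f * frho * np.pi / ctscto
        sof += f * ftau * np.pi / ctscto

    sdb, sdf = 0.5 * (ks + bf), 0.5 * (ks - bf)
    dob, dof = 0.5 * (ko + bf), 0.5 * (ko - bf)
    ddb, ddf = 0.5 * (1.0 + bf), 0.5 * (1.0 - bf)

    sigb = ddb * rho + ddf * tau
    sigf = ddf * rho + ddb * tau
    att = 1.0 - sigf
    m2 = np.clip((att + sigb) * (att - sigb), 1e-12, None)
    m = np.sqrt(m2)
    sb = sdb * rho + sdf * tau
    sf = sdf * rho + sdb * tau
    vb = dob * rho + dof * tau
    vf = dof * rho + dob * tau
    w = sob * rho + sof * tau

    e1 = np.exp(-m * lai)
    e2 = e1**2
    rinf = (att - m) / sigb
    rinf2 = rinf * rinf
    re = rinf * e1
    denom = 1.0 - rinf2 * e2

    J1ks = _jfunc1(ks, m, lai)
    J2ks = _jfunc2(ks, m, lai)
    J1ko = _jfunc1(ko, m, lai)
    J2ko = _jfunc2(ko, m, lai)

    Ps = (sf + sb * rinf) * J1ks
    Qs = (sf * rinf + sb) * J2ks
    Pv = (vf + vb * rinf) * J1ko
    Qv = (vf * rinf + vb) * J2ko

    rdd = rinf * (1.0 - e2) / denom
    tdd = (1.0 - rinf2) * e1 / denom
    tsd = (Ps - re * Qs) / denom
    rsd = (Qs - re * Ps) / denom
    tdo = (Pv - re * Qv) / denom
    rdo = (Qv - re * Pv) / denom

    tss = np.exp(-ks * lai)
    too = np.exp(-ko * lai)
    z = _jfunc2(ks, np.full_like(m, ko), lai)
    g1 = (z - J1ks * too) / (ko + m)
    g2 = (z - J1ko * tss) / (ks + m)
    Tv1 = (vf * rinf + vb) * g1
    Tv2 = (vf + vb * rinf) * g2
    T1 = Tv1 * (sf + sb * rinf)
    T2 = Tv2 * (sf * rinf + sb)
    T3 = (rdo * Qs + tdo * Ps) * rinf
    rsod = (T1 + T2 - T3) / (1.0 - rinf2)

    # Hot-spot: single-scattering integral along the sun-view correlation.
    alf = 1e36
    if canopy.HotS > 0:
        alf = (dso / canopy.HotS) * 2.0 / (ks + ko)
    if alf == 0.0:  # exact backscatter
        tsstoo = tss
        sumint = (1.0 - tss) / (ks * lai)
    else:
        alf = min(alf, 200.0)
        fhot = lai * np.sqrt(ko * ks)
        x1 = y1 = 0.0
        f1 = 1.0
        fint = (1.0 - np.exp(-alf)) * 0.05
        sumint = 0.0
        for istep in range(1, 21):
            x2 = 1.0 if istep == 20 else -np.log(1.0 - istep * fint) / alf
            y2 = -(ko + ks) * lai * x2 + fhot * (1.0 - np.exp(-alf * x2)) / alf
            f2 = np.exp(y2)
            sumint += (f2 - f1) * (x2 - x1) / (y2 - y1)
            x1, y1, f1 = x2, y2, f2
        tsstoo = f1
    rsos = w * lai * sumint
    rso = rsos + rsod

    # Couple the layer with the soil lower boundary.
    dn = 1.0 - rsoil * rdd
    rdot = rdo + tdd * rsoil * (tdo + too) / dn
    rsodt = ((tss + tsd) * tdo + (tsd + tss * rsoil * rdd) * too) * rsoil / dn
    rsost = rso + tsstoo * rsoil
    rsot = rsost + rsodt
    del rdot  # hemispherical-directional term, not used for direct-sun BRF
    return np.clip(rsot, 0.0, 1.0)
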