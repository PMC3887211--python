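"""Seeded synthetic-data generators for every pipeline input.

Fingerprint spectra (jittered singly protonated digest masses with dropout
and uniform noise peaks), CID MS/MS spectra (jittered b/y ladders), and
kinetic datasets (linear time courses, power-law rate-vs-concentration
tables, Michaelis-Menten curves with optional substrate inhibition), all
generated from known ground truth as pure functions of (parameters, seed).
Noise on kinetic signals is multiplicative Gaussian (CV-style), emulating
densitometry/scintillation error that scales with signal; spectral noise
peaks are uniform in m/z with exponential (or uniform) intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import Modification, ModifiedPeptide, peptide_mz, peptide_neutral_mass, mz
from .digestion import PeptideRecord, ProteaseRule, TRYPSIN, digest
from .errors import InputError
from .kinetics import TimeCourse, michaelis_menten, substrate_inhibition
from .msms import predict_fragments
from .peaks import PeakList


@dataclass
class SpectrumSimConfig:
    """Measurement-error model for simulated spectra.

    ``mz_sigma`` is Gaussian m/z jitter (Da); ``dropout_p`` the per-peak
    dropout probability; ``n_noise_peaks`` uniform-m/z noise peaks are added
    over ``noise_mz_range`` with ``intensity_model`` intensities.
    """

    mz_sigma: float = 0.0
    dropout_p: float = 0.0
    n_noise_peaks: int = 0
    noise_mz_range: tuple[float, float] = (200.0, 2000.0)
    intensity_model: str = "exponential"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mz_sigma < 0:
            raise InputError("mz_sigma must be >= 0")
        if not 0 <= self.dropout_p < 1:
            raise InputError("dropout_p must be in [0, 1)")
        if self.n_noise_peaks < 0:
            raise InputError("n_noise_peaks must be >= 0")
        if self.intensity_model not in ("uniform", "exponential"):
            raise InputError(f"unknown intensity_model {self.intensity_model!r}")


@dataclass
class KineticSimConfig:
    """Noise and design grid for simulated kinetic data.

    ``noise_cv`` is the coefficient of variation of multiplicative Gaussian
    noise; ``grid`` the design points (times in hours, or concentrations in
    uM), strictly increasing and non-negative. ``grid=None`` lets each
    generator use its conventional default design.
    """

    noise_cv: float = 0.0
    grid: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise InputError("noise_cv must be >= 0")
        if self.grid is not None:
            g = np.asarray(self.grid, dtype=float)
            if np.any(np.diff(g) <= 0):
                raise InputError("grid must be strictly increasing")
            if np.any(g < 0):
                raise InputError("grid must be non-negative")
            self.grid = tuple(float(x) for x in g)


def _noise_peaks(rng: np.random.Generator, cfg: SpectrumSimConfig):
    lo, hi = cfg.noise_mz_range
    noise_mz = rng.uniform(lo, hi, size=cfg.n_noise_peaks)
    if cfg.intensity_model == "exponential":
        noise_int = rng.exponential(scale=1.0, size=cfg.n_noise_peaks)
    else:
        noise_int = rng.uniform(0.0, 1.0, size=cfg.n_noise_peaks)
    return noise_mz, noise_int


def _jitter_dropout(
    mzs: np.ndarray, rng: np.random.Generator, cfg: SpectrumSimConfig
) -> np.ndarray:
    keep = rng.uniform(size=len(mzs)) >= cfg.dropout_p
    kept = mzs[keep]
    return kept + rng.normal(0.0, cfg.mz_sigma, size=len(kept)) if cfg.mz_sigma else kept


def simulate_pmf(
    parent: str,
    rule: ProteaseRule = TRYPSIN,
    true_mods: list[tuple[int, Modification]] = (),
    cfg: SpectrumSimConfig = SpectrumSimConfig(),
    max_missed: int = 0,
    parent_offset: int = 1,
) -> PeakList:
    """Simulate a MALDI fingerprint of a digested, possibly modified parent.

    ``true_mods`` places ground-truth modifications at 1-based *parent*
    positions; every digest peptide spanning such a position appears at its
    modified [M+H]+ (the unmodified form is absent, emulating complete
    modification). Jitter, dropout and noise peaks follow ``cfg``.
    """
    for pos, mod in true_mods:
        if not 1 <= pos <= len(parent):
            raise InputError(f"true modification position {pos} outside parent")
        if parent[pos - 1] not in mod.targets:
            raise InputError(
                f"parent residue {parent[pos - 1]!r} at {pos} is not a target of "
                f"{mod.name!r}"
            )
    rng = np.random.default_rng(cfg.seed)
    records = digest(parent, rule, max_missed, parent_offset=parent_offset)
    theoretical = []
    for rec in records:
        local = tuple(
            (pos - rec.start + 1, mod)
            for pos, mod in true_mods
            if rec.start <= pos <= rec.end
        )
        theoretical.append(peptide_mz(ModifiedPeptide(rec.sequence, local), 1))
    kept = _jitter_dropout(np.asarray(theoretical), rng, cfg)
    intensity = np.full(len(kept), 100.0)
    noise_mz, noise_int = _noise_peaks(rng, cfg)
    return PeakList(
        mz=np.concatenate([kept, noise_mz]),
        intensity=np.concatenate([intensity, noise_int]),
        ms_level=1,
        title="simulated fingerprint",
    )


def simulate_msms(
    peptide: ModifiedPeptide,
    cfg: SpectrumSimConfig = SpectrumSimConfig(),
    precursor_charge: int = 2,
) -> PeakList:
    """Simulate a CID MS/MS spectrum of a (modified) peptide.

    All singly charged b/y fragments, jittered and dropped per ``cfg``;
    precursor m/z is set from the modified peptide at ``precursor_charge``.
    """
    rng = np.random.default_rng(cfg.seed)
    frags = predict_fragments(peptide, charges=(1,))
    kept = _jitter_dropout(np.asarray([f.mz for f in frags]), rng, cfg)
    intensity = np.full(len(kept), 100.0)
    noise_mz, noise_int = _noise_peaks(rng, cfg)
    return PeakList(
        mz=np.concatenate([kept, noise_mz]),
        intensity=np.concatenate([intensity, noise_int]),
        ms_level=2,
        precursor_mz=mz(peptide_neutral_mass(peptide), precursor_charge),
        precursor_charge=precursor_charge,
        title="simulated CID spectrum",
    )


def _multiplicative(rng: np.random.Generator, mean: np.ndarray, cv: float) -> np.ndarray:
    return mean * (1.0 + rng.normal(0.0, cv, size=mean.shape)) if cv else mean.copy()


DEFAULT_TIME_GRID = (0.0, 0.8, 1.6, 2.4, 3.2, 4.0)  # hours, 6 points over 0-4 h
DEFAULT_CONC_GRID = (1.0, 3.0, 10.0, 30.0)  # uM enzyme
DEFAULT_ADOMET_GRID = (1.0, 2.5, 5.0, 10.0, 20.0, 50.0, 100.0)  # uM AdoMet


def simulate_timecourse(
    true_slope: float,
    cfg: KineticSimConfig = KineticSimConfig(),
    label: str = "",
    signal_kind: str = "relative_intensity",
) -> TimeCourse:
    """Linear methylation time course signal = slope * t with CV noise."""
    if true_slope <= 0:
        raise InputError("true_slope must be > 0")
    rng = np.random.default_rng(cfg.seed)
    t = np.asarray(cfg.grid if cfg.grid is not None else DEFAULT_TIME_GRID)
    signal = _multiplicative(rng, true_slope * t, cfg.noise_cv)
    return TimeCourse(t=t, signal=signal, label=label, signal_kind=signal_kind)


def simulate_order_data(
    k: float, n: float, cfg: KineticSimConfig = KineticSimConfig()
) -> pd.DataFrame:
    """(concentration, rate) table following rate = k * E^n with CV noise."""
    if k <= 0 or n <= 0:
        raise InputError("k and n must be > 0")
    rng = np.random.default_rng(cfg.seed)
    conc = np.asarray(cfg.grid if cfg.grid is not None else DEFAULT_CONC_GRID)
    if np.any(conc <= 0):
        raise InputError("concentrations must be > 0")
    rate = _multiplicative(rng, k * conc**n, cfg.noise_cv)
    return pd.DataFrame({"conc": conc, "rate": rate})


def simulate_mm_data(
    vmax: float,
    km: float,
    cfg: KineticSimConfig = KineticSimConfig(),
    ki: float | None = None,
) -> pd.DataFrame:
    """(AdoMet concentration, rate) table from a Michaelis-Menten curve.

    With ``ki`` set, the mean follows the substrate-inhibition form
    v = Vmax*S/(Km + S*(1 + S/Ki)); with ``ki=None`` the plain hyperbola.
    """
    if vmax <= 0 or km <= 0:
        raise InputError("vmax and km must be > 0")
    if ki is not None and ki <= 0:
        raise InputError("ki must be > 0 when given")
    rng = np.random.default_rng(cfg.seed)
    s = np.asarray(cfg.grid if cfg.grid is not None else DEFAULT_ADOMET_GRID)
    if np.any(s <= 0):
        raise InputError("concentrations must be > 0")
    mean = substrate_inhibition(s, vmax, km, ki) if ki is not None else michaelis_menten(s, vmax, km)
    rate = _multiplicative(rng, mean, cfg.noise_cv)
    return pd.DataFrame({"conc": s, "rate": rate})
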