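"""Resonance model and closed-form signal equations for water/fat MRS.

This module holds the static description of a water + multi-peak-fat
spectrum (peak positions, pseudo-Voigt shape fractions, triglyceride
amplitude constraints, relaxation-group structure) and the scalar signal
equations used both to synthesize data and to fit it:

* stimulated-echo amplitude decay  ``A0 * exp(-TE/T2)``
* inversion recovery with finite TR and inversion efficiency beta,
  ``A0 * (1 - 2*beta*exp(-TI/T1) + exp(-TR/T1))``
* proton density fat fraction  ``PDFF = sum(F0) / (W0 + sum(F0))``
* linewidth-to-R2* conversion  ``R2* = pi * LW``

Lineshapes are pseudo-Voigt: ``LSF * L + (1 - LSF) * G`` with both the
Lorentzian and the Gaussian area-normalized and sharing the same FWHM,
so a fitted linewidth feeds the R2* relation unchanged regardless of the
shape fraction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Resonance",
    "FattyAcidComposition",
    "ResonanceModel",
    "RelaxationState",
    "AcquisitionContext",
    "pseudo_voigt",
    "lorentzian",
    "gaussian",
    "ste_signal",
    "sti_signal",
    "ste_weight",
    "sti_weight",
    "ti_null",
    "hamilton_amplitudes",
    "compute_pdff",
    "linewidth_to_r2star",
    "r2star_to_linewidth",
    "default_marrow_model",
    "DEFAULT_COMPOSITION",
]

_LN2 = math.log(2.0)

# Proton-count rules of the generic-triglyceride model: each fat peak's
# amplitude is linear in chain length CL, double bonds ndb and
# methylene-interrupted double bonds nmidb.  Rules are plain expressions in
# (CL, ndb, nmidb) so user-supplied models can define their own.
_RULE_NAMES = ("CL", "ndb", "nmidb")


def _eval_rule(rule: str, CL: float, ndb: float, nmidb: float) -> float:
    return float(
        eval(rule, {"__builtins__": {}}, {"CL": CL, "ndb": ndb, "nmidb": nmidb})
    )


@dataclass(frozen=True)
class Resonance:
    """A single spectral peak.

    ``amplitude_rule`` is either ``"free"`` (water) or an expression in
    ``CL``/``ndb``/``nmidb`` giving the relative proton count.
    """

    name: str
    ppm: float
    lsf: float
    lw_group: str
    t1_group: str
    t2_group: str
    amplitude_rule: str = "free"

    def __post_init__(self) -> None:
        if not 0.0 <= self.lsf <= 1.0:
            raise ValueError(f"LSF must be in [0, 1], got {self.lsf}")


@dataclass(frozen=True)
class FattyAcidComposition:
    """Triglyceride composition: chain length and double-bond counts."""

    CL: float = 17.5
    ndb: float = 2.7
    nmidb: float = 0.7

    def __post_init__(self) -> None:
        if self.CL <= 4:
            raise ValueError("chain length CL must exceed 4")
        if not 0.0 <= self.nmidb <= self.ndb:
            raise ValueError("need 0 <= nmidb <= ndb")


DEFAULT_COMPOSITION = FattyAcidComposition()


@dataclass(frozen=True)
class ResonanceModel:
    """Ordered set of resonances with rigidly linked fat frequencies.

    All fat peaks keep fixed chemical-shift offsets relative to the methyl
    peak; only the methyl and water frequencies are free during fitting.
    """

    resonances: tuple[Resonance, ...]
    water_index: int
    composition: FattyAcidComposition = DEFAULT_COMPOSITION

    def __post_init__(self) -> None:
        waters = [i for i, r in enumerate(self.resonances) if r.amplitude_rule == "free"]
        if waters != [self.water_index]:
            raise ValueError("exactly one free-amplitude (water) resonance expected")

    @property
    def water(self) -> Resonance:
        return self.resonances[self.water_index]

    @property
    def fat_indices(self) -> tuple[int, ...]:
        return tuple(i for i in range(len(self.resonances)) if i != self.water_index)

    @property
    def methyl_index(self) -> int:
        """Lowest-ppm fat peak (the frequency anchor for the linked fats)."""
        fats = self.fat_indices
        if not fats:
            return self.water_index
        return min(fats, key=lambda i: self.resonances[i].ppm)

    def groups(self, kind: str) -> tuple[str, ...]:
        attr = {"t1": "t1_group", "t2": "t2_group", "lw": "lw_group"}[kind]
        seen: dict[str, None] = {}
        for r in self.resonances:
            seen.setdefault(getattr(r, attr), None)
        return tuple(seen)

    def names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.resonances)

    def index(self, name: str) -> int:
        return self.names().index(name)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "resonances": [asdict(r) for r in self.resonances],
            "water_index": self.water_index,
            "composition": asdict(self.composition),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: Mapping) -> "ResonanceModel":
        return cls(
            resonances=tuple(Resonance(**r) for r in d["resonances"]),
            water_index=int(d["water_index"]),
            composition=FattyAcidComposition(**d["composition"]),
        )

    @classmethod
    def from_json(cls, text_or_path) -> "ResonanceModel":
        try:
            d = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                d = json.load(fh)
        return cls.from_dict(d)


@dataclass
class RelaxationState:
    """Ground-truth (or fitted) relaxation and amplitude parameters.

    ``t1``/``t2``/``lw`` map group labels to values (ms, ms, Hz); ``a0``
    maps resonance names to fully relaxed, T2-corrected amplitudes.
    """

    t1: dict[str, float]
    t2: dict[str, float]
    lw: dict[str, float]
    a0: dict[str, float]
    beta: float = 1.0

    def __post_init__(self) -> None:
        for label, d in (("T1", self.t1), ("T2", self.t2), ("LW", self.lw)):
            for k, v in d.items():
                if v <= 0:
                    raise ValueError(f"{label}[{k}] must be positive, got {v}")
        for k, v in self.a0.items():
            if v < 0:
                raise ValueError(f"A0[{k}] must be nonnegative, got {v}")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"inversion efficiency beta must be in [0, 1], got {self.beta}")

    def t1_of(self, r: Resonance) -> float:
        return self.t1[r.t1_group]

    def t2_of(self, r: Resonance) -> float:
        return self.t2[r.t2_group]

    def lw_of(self, r: Resonance) -> float:
        return self.lw[r.lw_group]


@dataclass(frozen=True)
class AcquisitionContext:
    """Timing and sampling of one STEAM acquisition.

    Times in ms, dwell in s, transmitter frequency in MHz.  The chemical
    shift axis is referenced to water at ``ref_ppm`` (carrier on water),
    so a resonance at ``p`` ppm sits at ``(p - ref_ppm) * f_transmitter``
    Hz in the rotating frame.
    """

    te: float = 20.0
    ti: float | None = None
    tr: float = 3500.0
    tm: float = 10.0
    dwell: float = 1.0 / 2400.0
    n_points: int = 2048
    f_transmitter: float = 127.73
    ref_ppm: float = 4.7

    def __post_init__(self) -> None:
        if self.te >= self.tr:
            raise ValueError("TE must be shorter than TR")

    @property
    def sweep_width(self) -> float:
        return 1.0 / self.dwell

    @property
    def duration(self) -> float:
        return self.dwell * self.n_points

    def time_axis(self) -> np.ndarray:
        return np.arange(self.n_points) * self.dwell

    def freq_axis(self) -> np.ndarray:
        """Frequency axis (Hz) matching an unshifted FFT of the FID."""
        return np.fft.fftfreq(self.n_points, self.dwell)

    def ppm_to_hz(self, ppm) -> np.ndarray | float:
        return (np.asarray(ppm, dtype=float) - self.ref_ppm) * self.f_transmitter

    def hz_to_ppm(self, hz) -> np.ndarray | float:
        return np.asarray(hz, dtype=float) / self.f_transmitter + self.ref_ppm


# ---------------------------------------------------------------------------
# Lineshapes
# ---------------------------------------------------------------------------

def lorentzian(axis: np.ndarray, f0: float, lw: float) -> np.ndarray:
    """Area-normalized Lorentzian with FWHM ``lw`` (Hz) centred at ``f0``."""
    if lw <= 0:
        raise ValueError("linewidth must be positive")
    hwhm = lw / 2.0
    return (hwhm / math.pi) / ((np.asarray(axis) - f0) ** 2 + hwhm**2)


def gaussian(axis: np.ndarray, f0: float, lw: float) -> np.ndarray:
    """Area-normalized Gaussian with FWHM ``lw`` (Hz) centred at ``f0``."""
    if lw <= 0:
        raise ValueError("linewidth must be positive")
    sigma = lw / (2.0 * math.sqrt(2.0 * _LN2))
    x = (np.asarray(axis) - f0) / sigma
    return np.exp(-0.5 * x**2) / (sigma * math.sqrt(2.0 * math.pi))


def pseudo_voigt(f0: float, lw: float, lsf: float, axis: np.ndarray) -> np.ndarray:
    """Pseudo-Voigt absorption profile, unit area over a wide axis.

    ``lsf`` is the Lorentzian shape fraction; both components share the
    FWHM ``lw`` so the profile's width parameter is ``lw`` for any
    ``lsf``.
    """
    if not 0.0 <= lsf <= 1.0:
        raise ValueError("Lorentzian shape fraction must be in [0, 1]")
    return lsf * lorentzian(axis, f0, lw) + (1.0 - lsf) * gaussian(axis, f0, lw)


# ---------------------------------------------------------------------------
# Signal equations
# ---------------------------------------------------------------------------

def ste_weight(a0: float, t2: float, te: float) -> float:
    """Stimulated-echo amplitude ``A0 * exp(-TE/T2)`` (times in ms)."""
    if te <= 0:
        raise ValueError("TE must be positive")
    return a0 * math.exp(-te / t2)


def sti_weight(a0: float, t1: float, beta: float, ti: float, tr: float) -> float:
    """Inversion-recovery amplitude ``A0*(1 - 2*beta*e^(-TI/T1) + e^(-TR/T1))``.

    The finite-TR term makes the long-TI limit ``1 + exp(-TR/T1)`` rather
    than 1; the expression is signed and crosses zero at the null point.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError("inversion efficiency beta must be in [0, 1]")
    if ti <= 0 or tr <= 0:
        raise ValueError("TI and TR must be positive")
    return a0 * (1.0 - 2.0 * beta * math.exp(-ti / t1) + math.exp(-tr / t1))


def ti_null(t1: float, beta: float, tr: float) -> float:
    """TI at which the inversion-recovery factor crosses zero (ms)."""
    return t1 * math.log(2.0 * beta / (1.0 + math.exp(-tr / t1)))


def _resonance_hz(model: ResonanceModel, acq: AcquisitionContext) -> np.ndarray:
    return np.array([acq.ppm_to_hz(r.ppm) for r in model.resonances])


def ste_signal(
    state: RelaxationState,
    model: ResonanceModel,
    te: float,
    axis: np.ndarray,
    acq: AcquisitionContext | None = None,
) -> np.ndarray:
    """Real absorption spectrum of the multi-TE experiment at echo time ``te``.

    ``axis`` is in Hz relative to the carrier (water) unless ``acq`` is
    omitted, in which case a default context supplies the ppm->Hz mapping.
    """
    acq = acq or AcquisitionContext(te=te)
    freqs = _resonance_hz(model, acq)
    out = np.zeros_like(np.asarray(axis, dtype=float))
    for r, f in zip(model.resonances, freqs):
        w = ste_weight(state.a0[r.name], state.t2_of(r), te)
        out += w * pseudo_voigt(f, state.lw_of(r), r.lsf, axis)
    return out


def sti_signal(
    state: RelaxationState,
    model: ResonanceModel,
    ti: float,
    tr: float,
    axis: np.ndarray,
    acq: AcquisitionContext | None = None,
) -> np.ndarray:
    """Signed absorption spectrum of the inversion-recovery experiment."""
    acq = acq or AcquisitionContext(ti=ti, tr=tr)
    freqs = _resonance_hz(model, acq)
    out = np.zeros_like(np.asarray(axis, dtype=float))
    for r, f in zip(model.resonances, freqs):
        w = sti_weight(state.a0[r.name], state.t1_of(r), state.beta, ti, tr)
        out += w * pseudo_voigt(f, state.lw_of(r), r.lsf, axis)
    return out


def hamilton_amplitudes(
    comp: FattyAcidComposition, model: ResonanceModel | None = None
) -> dict[str, float]:
    """Relative proton amplitudes of the constrained fat peaks.

    Evaluates each fat resonance's amplitude rule at the given
    composition.  Raises if any rule turns negative (invalid
    composition), naming the offending peak.
    """
    model = model or default_marrow_model(comp)
    out: dict[str, float] = {}
    for r in model.resonances:
        if r.amplitude_rule == "free":
            continue
        a = _eval_rule(r.amplitude_rule, comp.CL, comp.ndb, comp.nmidb)
        if a < 0:
            raise ValueError(
                f"composition {comp} gives negative amplitude for peak '{r.name}'"
            )
        out[r.name] = a
    return out


def compute_pdff(amplitudes: Mapping[str, float] | Sequence[float], water_index) -> float:
    """Proton density fat fraction from T2-corrected amplitudes, in [0, 1].

    ``water_index`` is the water resonance's name (mapping input) or
    positional index (sequence input).
    """
    if isinstance(amplitudes, Mapping):
        water = float(amplitudes[water_index])
        fat = float(sum(v for k, v in amplitudes.items() if k != water_index))
    else:
        arr = np.asarray(amplitudes, dtype=float)
        water = float(arr[water_index])
        fat = float(arr.sum() - water)
    if water < 0 or fat < 0:
        raise ValueError("amplitudes must be nonnegative")
    total = water + fat
    if total == 0:
        raise ValueError("PDFF undefined: water and fat amplitudes are all zero")
    return fat / total


def linewidth_to_r2star(lw) -> np.ndarray | float:
    """R2* (s^-1) from a spectral FWHM linewidth (Hz): ``R2* = pi * LW``."""
    lw = np.asarray(lw, dtype=float)
    if np.any(lw < 0):
        raise ValueError("linewidth must be nonnegative")
    out = math.pi * lw
    return float(out) if out.ndim == 0 else out


def r2star_to_linewidth(r2s) -> np.ndarray | float:
    """Inverse of :func:`linewidth_to_r2star`."""
    r2s = np.asarray(r2s, dtype=float)
    if np.any(r2s < 0):
        raise ValueError("R2* must be nonnegative")
    out = r2s / math.pi
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Default model
# ---------------------------------------------------------------------------

# Water is a 50:50 Lorentzian/Gaussian mix (robust to sclerotic
# broadening); fat peaks are 20:80.  Relaxation groups: unique T1 for
# methyl, methylene, the 2.03+2.25 ppm composite, diacyl, olefin and
# water; unique T2 for methylene, composite and water; linewidths for
# water, methylene and one shared group for the remaining fat peaks.
# Every unlisted fat peak inherits the methylene relaxation groups.
_WATER_LSF = 0.5
_FAT_LSF = 0.2

_DEFAULT_PEAKS = [
    # name, ppm, t1_group, t2_group, lw_group, amplitude rule (protons)
    ("methyl", 0.90, "methyl", "methylene", "other_fat", "9"),
    ("methylene", 1.30, "methylene", "methylene", "methylene", "6*(CL-4) - 8*ndb + 2*nmidb"),
    ("beta_carboxyl", 1.60, "methylene", "methylene", "other_fat", "6"),
    ("alpha_olefinic", 2.03, "composite", "composite", "other_fat", "4*(ndb - nmidb)"),
    ("alpha_carboxyl", 2.25, "composite", "composite", "other_fat", "6"),
    ("diacyl", 2.77, "diacyl", "methylene", "other_fat", "2*nmidb"),
    ("glycerol_a", 4.15, "methylene", "methylene", "other_fat", "2"),
    ("glycerol_b", 4.30, "methylene", "methylene", "other_fat", "2"),
    ("glycerol_c", 5.21, "methylene", "methylene", "other_fat", "1"),
    ("olefinic", 5.31, "olefin", "methylene", "other_fat", "2*ndb"),
]


def default_marrow_model(
    composition: FattyAcidComposition = DEFAULT_COMPOSITION,
) -> ResonanceModel:
    """The 10-peak fat + water model used throughout the package.

    Peak positions and proton-count rules follow the generic-triglyceride
    description of fat; they are configuration data and can be replaced
    wholesale via :meth:`ResonanceModel.from_json`.
    """
    res = [
        Resonance(name, ppm, _FAT_LSF, lwg, t1g, t2g, rule)
        for name, ppm, t1g, t2g, lwg, rule in _DEFAULT_PEAKS
    ]
    res.append(Resonance("water", 4.70, _WATER_LSF, "water", "water", "water", "free"))
    return ResonanceModel(tuple(res), water_index=len(res) - 1, composition=composition)
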