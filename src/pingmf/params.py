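"""Model constants, nondimensionalization, and Lorentzian heterogeneity.

The spiking network and its mean-field reduction share a single
nondimensional parameter set (:class:`ReducedParams`).  Membrane potentials
are mapped so that the leak reversal and the firing threshold sit at -1 and
+1; conductances are expressed in units of the leak conductance; time stays
in milliseconds with the membrane time constant ``tau = C / gl``.

Quenched heterogeneity (synaptic strengths and tonic drives varying across
neurons) is Lorentzian (Cauchy) distributed, which is what makes the exact
mean-field closure possible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

__all__ = [
    "BiophysParams",
    "SynapseKinetics",
    "CouplingParams",
    "DriveParams",
    "ReducedParams",
    "nondimensionalize",
    "dimensionalize",
    "sample_lorentzian",
    "reference_config",
    "synergy_config",
    "load_config",
    "save_config",
    "PATHWAY_ALIASES",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BiophysParams:
    """Dimensional single-neuron constants of the QIF membrane equation.

    Parameters
    ----------
    C : float
        Membrane capacitance (uF/cm^2).
    gl : float
        Leak conductance (mS/cm^2).
    Vl, VT : float
        Leak reversal and firing threshold (mV); the quadratic nonlinearity
        vanishes at both.
    Vex, Vin : float
        Glutamatergic (AMPA/NMDA) and GABAergic reversal potentials (mV).
    Vspike, VR : float
        Spike cutoff and reset.  ``+inf``/``-inf`` (the defaults) give the
        theta-neuron equivalence used by the mean-field reduction.
    """

    C: float = 1.0
    gl: float = 0.1
    Vl: float = -65.0
    VT: float = -50.0
    Vex: float = 0.0
    Vin: float = -70.0
    Vspike: float = np.inf
    VR: float = -np.inf

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError(f"C must be positive, got {self.C}")
        if self.gl <= 0:
            raise ValueError(f"gl must be positive, got {self.gl}")
        if self.VT == self.Vl:
            raise ValueError(
                "VT == Vl: threshold and leak reversal coincide, the "
                "nondimensionalization divides by VT - Vl"
            )
        if not (self.Vl < self.VT):
            raise ValueError(f"require Vl < VT, got Vl={self.Vl}, VT={self.VT}")
        if not (self.Vin <= self.Vl < self.VT < self.Vex):
            raise ValueError(
                "require Vin <= Vl < VT < Vex, got "
                f"Vin={self.Vin}, Vl={self.Vl}, VT={self.VT}, Vex={self.Vex}"
            )


@dataclass(frozen=True)
class SynapseKinetics:
    """First-order synaptic gating kinetics (all times in ms).

    AMPA and GABA gates decay exponentially and are kicked by presynaptic
    spikes; the NMDA gate is a logistic variable driven by the AMPA gate
    (``ds_n/dt = a_n s_e (1 - s_n) - s_n / tau_n``), so ``tau_n`` must be
    markedly slower than ``tau_e`` for the closure to be a good
    approximation.
    """

    tau_e: float = 2.0
    tau_n: float = 90.0
    tau_i: float = 8.0
    a_n: float = 0.05

    def __post_init__(self) -> None:
        for name in ("tau_e", "tau_n", "tau_i", "a_n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.tau_n <= self.tau_e:
            raise ValueError(
                f"NMDA decay tau_n={self.tau_n} must exceed AMPA decay tau_e={self.tau_e}"
            )


@dataclass(frozen=True)
class CouplingParams:
    """Lorentzian modes and half-widths of the synaptic conductances.

    Fields are named ``<stat>_<postsynaptic pop>_<receptor>`` and are
    nondimensional (units of the leak conductance).  The three pathways
    manipulated in the disease analysis are AMPA E->I (``gbar_i_ampa``),
    NMDA E->I (``gbar_i_nmda``) and GABA I->E (``gbar_e_gaba``), with
    matching half-widths ``gamma_*``.
    """

    gbar_e_ampa: float = 0.0   # recurrent E->E, AMPA
    gbar_e_nmda: float = 0.0   # recurrent E->E, NMDA
    gbar_e_gaba: float = 0.0   # I->E
    gbar_i_ampa: float = 0.0   # E->I
    gbar_i_nmda: float = 0.0   # N->I
    gbar_i_gaba: float = 0.0   # recurrent I->I
    gamma_e_ampa: float = 0.0
    gamma_e_nmda: float = 0.0
    gamma_e_gaba: float = 0.0
    gamma_i_ampa: float = 0.0
    gamma_i_nmda: float = 0.0
    gamma_i_gaba: float = 0.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ValueError(f"{f.name} must be >= 0, got {v}")


@dataclass(frozen=True)
class DriveParams:
    """Lorentzian mode/half-width of the tonic drive, per population.

    Nondimensional (``Ihat = 2 I / (gl (VT - Vl))``).  In the reference
    setup the drive is applied to the excitatory population only.
    """

    Ibar_e: float = 2.0
    Delta_e: float = 0.02
    Ibar_i: float = 0.0
    Delta_i: float = 0.0

    def __post_init__(self) -> None:
        if self.Delta_e < 0 or self.Delta_i < 0:
            raise ValueError("drive half-widths must be >= 0")


@dataclass(frozen=True)
class ReducedParams:
    """Complete nondimensional parameter set of the two-population model."""

    tau: float = 10.0
    Vhat_ex: float = 23.0 / 3.0
    Vhat_in: float = -5.0 / 3.0
    coupling: CouplingParams = field(default_factory=CouplingParams)
    kinetics: SynapseKinetics = field(default_factory=SynapseKinetics)
    drive: DriveParams = field(default_factory=DriveParams)
    biophys: BiophysParams | None = None

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if not (self.Vhat_in < -1.0 < 1.0 < self.Vhat_ex):
            raise ValueError(
                "nondimensional reversals must satisfy Vhat_in < -1 < 1 < Vhat_ex, "
                f"got Vhat_in={self.Vhat_in}, Vhat_ex={self.Vhat_ex}"
            )

    # -- flat parameter addressing (used by sweeps and the CLI) -------------

    def get_param(self, name: str) -> float:
        group, attr = self._resolve(name)
        return getattr(group if group is not None else self, attr)

    def with_param(self, name: str, value: float) -> "ReducedParams":
        """Return a copy with one flat-named parameter replaced.

        ``name`` may be a field of any sub-block (``gbar_i_ampa``,
        ``tau_i``, ``Ibar_e`` ...), a top-level field (``tau``), or a
        pathway alias such as ``g_EtoI``.
        """
        group, attr = self._resolve(name)
        if group is None:
            return dataclasses.replace(self, **{attr: value})
        for holder in ("coupling", "kinetics", "drive"):
            blk = getattr(self, holder)
            if blk is group:
                return dataclasses.replace(
                    self, **{holder: dataclasses.replace(blk, **{attr: value})}
                )
        raise AssertionError("unreachable")

    def with_params(self, updates: Mapping[str, float]) -> "ReducedParams":
        p = self
        for k, v in updates.items():
            p = p.with_param(k, v)
        return p

    def _resolve(self, name: str):
        name = PATHWAY_ALIASES.get(name, name)
        if name in ("tau", "Vhat_ex", "Vhat_in"):
            return None, name
        for holder in (self.coupling, self.kinetics, self.drive):
            if name in {f.name for f in dataclasses.fields(holder)}:
                return holder, name
        raise KeyError(f"unknown parameter name: {name!r}")


#: Results-section pathway names -> flat field names.
PATHWAY_ALIASES: dict[str, str] = {
    "g_EtoI": "gbar_i_ampa",
    "g_NtoI": "gbar_i_nmda",
    "g_ItoE": "gbar_e_gaba",
    "gamma_EtoI": "gamma_i_ampa",
    "gamma_NtoI": "gamma_i_nmda",
    "gamma_ItoE": "gamma_e_gaba",
}


# ---------------------------------------------------------------------------
# nondimensionalization
# ---------------------------------------------------------------------------

def nondimensionalize(
    p: BiophysParams,
    I_appl: float,
    *,
    coupling: CouplingParams | None = None,
    kinetics: SynapseKinetics | None = None,
    Delta: float = 0.0,
) -> ReducedParams:
    """Map dimensional constants to the nondimensional parameter set.

    Potentials map via ``V = (VT+Vl)/2 + u (VT-Vl)/2`` so that the leak
    reversal and threshold sit at u = -1, +1:

    - ``Vhat_ex = 2 (Vex - (VT+Vl)/2) / (VT-Vl)`` (and analogously Vhat_in),
    - ``Ihat   = 2 I / (gl (VT-Vl))``,
    - ``tau    = C / gl``; conductances divide by ``gl``.

    The tonic drive is applied to the excitatory population.
    """
    half = 0.5 * (p.VT - p.Vl)
    mid = 0.5 * (p.VT + p.Vl)
    scale_I = 2.0 / (p.gl * (p.VT - p.Vl))
    return ReducedParams(
        tau=p.C / p.gl,
        Vhat_ex=(p.Vex - mid) / half,
        Vhat_in=(p.Vin - mid) / half,
        coupling=coupling if coupling is not None else CouplingParams(),
        kinetics=kinetics if kinetics is not None else SynapseKinetics(),
        drive=DriveParams(Ibar_e=I_appl * scale_I, Delta_e=Delta * scale_I,
                          Ibar_i=0.0, Delta_i=0.0),
        biophys=p,
    )


def dimensionalize(rp: ReducedParams) -> tuple[BiophysParams, float]:
    """Invert :func:`nondimensionalize`, returning ``(biophys, I_appl)``.

    The potential map has two anchor constants (the midpoint and half-width
    of the (Vl, VT) interval) that the reduction deliberately forgets, so
    inversion uses the ``biophys`` block carried on the reduced set.
    """
    if rp.biophys is None:
        raise ValueError("ReducedParams does not carry a BiophysParams anchor")
    b = rp.biophys
    half = 0.5 * (b.VT - b.Vl)
    mid = 0.5 * (b.VT + b.Vl)
    gl = b.C / rp.tau
    Vex = mid + rp.Vhat_ex * half
    Vin = mid + rp.Vhat_in * half
    I_appl = rp.drive.Ibar_e * gl * (b.VT - b.Vl) / 2.0
    return (
        BiophysParams(C=b.C, gl=gl, Vl=b.Vl, VT=b.VT, Vex=Vex, Vin=Vin,
                      Vspike=b.Vspike, VR=b.VR),
        I_appl,
    )


# ---------------------------------------------------------------------------
# Lorentzian sampling
# ---------------------------------------------------------------------------

def sample_lorentzian(
    mode: float,
    half_width: float,
    n: int,
    seed: int | np.random.Generator,
    *,
    truncate_at_zero: bool = False,
) -> np.ndarray:
    """Draw ``n`` quenched parameter values from a Lorentzian distribution.

    Uses the inverse CDF, ``mode + half_width * tan(pi (U - 1/2))``, so the
    same seed reproduces the same draws bit for bit.  Draws may be negative
    (the Lorentzian is heavy-tailed on both sides); the mean-field theory
    integrates over the full real line, so negative draws are kept by
    default.  ``truncate_at_zero=True`` resamples negative values, which
    breaks the exactness of the reduction and exists only for comparison
    experiments.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if half_width < 0:
        raise ValueError(f"half_width must be >= 0, got {half_width}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.random(n)
    x = mode + half_width * np.tan(np.pi * (u - 0.5))
    if truncate_at_zero and half_width > 0:
        bad = x < 0
        while np.any(bad):
            u = rng.random(int(bad.sum()))
            x[bad] = mode + half_width * np.tan(np.pi * (u - 0.5))
            bad = x < 0
    return x


# ---------------------------------------------------------------------------
# config I/O
# ---------------------------------------------------------------------------

_REFERENCE_PATH = Path(__file__).parent / "config" / "reference.yaml"
_SYNERGY_PATH = Path(__file__).parent / "config" / "synergy.yaml"

_SECTION_TYPES = {
    "biophysics": BiophysParams,
    "kinetics": SynapseKinetics,
    "coupling": CouplingParams,
    "drive": DriveParams,
}

#: free-form sections whose keys are validated against these names only
_PLAIN_SECTIONS = {
    "reduced": ("tau", "Vhat_ex", "Vhat_in"),
    "simulation": ("duration", "dt_out", "transient", "dt", "N_e", "N_i", "seed"),
    "spectral": ("fs", "band", "nperseg", "overlap", "transient_discard",
                 "noise_floor", "metric"),
    "meta": ("name", "version", "comment", "calibration"),
}


def _build_section(cls, data: Mapping[str, Any]):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys in {cls.__name__} section: {sorted(unknown)}")
    return cls(**{k: float(v) for k, v in data.items()})


def load_config(path: str | Path) -> tuple[ReducedParams, dict[str, Any]]:
    """Load a YAML/JSON config; returns ``(ReducedParams, extra_sections)``.

    Recognised sections: ``biophysics``, ``kinetics``, ``coupling``,
    ``drive``, ``reduced`` (overrides for tau / reversals), ``simulation``,
    ``spectral``, ``meta``.  Unknown sections or keys raise ``ValueError``.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"config root must be a mapping, got {type(doc).__name__}")
    unknown = set(doc) - set(_SECTION_TYPES) - set(_PLAIN_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    for sec, allowed in _PLAIN_SECTIONS.items():
        extra_keys = set(doc.get(sec, {}) or {}) - set(allowed)
        if extra_keys:
            raise ValueError(f"unknown keys in section {sec!r}: {sorted(extra_keys)}")

    biophys = _build_section(BiophysParams, doc.get("biophysics", {}) or {})
    kinetics = _build_section(SynapseKinetics, doc.get("kinetics", {}) or {})
    coupling = _build_section(CouplingParams, doc.get("coupling", {}) or {})
    drive = _build_section(DriveParams, doc.get("drive", {}) or {})

    reduced = doc.get("reduced", {}) or {}
    half = 0.5 * (biophys.VT - biophys.Vl)
    mid = 0.5 * (biophys.VT + biophys.Vl)
    rp = ReducedParams(
        tau=float(reduced.get("tau", biophys.C / biophys.gl)),
        Vhat_ex=float(reduced.get("Vhat_ex", (biophys.Vex - mid) / half)),
        Vhat_in=float(reduced.get("Vhat_in", (biophys.Vin - mid) / half)),
        coupling=coupling,
        kinetics=kinetics,
        drive=drive,
        biophys=biophys,
    )
    extras = {sec: doc.get(sec, {}) or {} for sec in ("simulation", "spectral", "meta")}
    return rp, extras


def save_config(rp: ReducedParams, path: str | Path,
                extras: Mapping[str, Mapping[str, Any]] | None = None) -> None:
    """Write a ReducedParams (plus optional simulation/spectral/meta blocks)."""
    doc: dict[str, Any] = {}
    if rp.biophys is not None:
        doc["biophysics"] = {
            k: (float(v) if np.isfinite(v) else str(v))
            for k, v in dataclasses.asdict(rp.biophys).items()
        }
    doc["reduced"] = {"tau": float(rp.tau), "Vhat_ex": float(rp.Vhat_ex),
                      "Vhat_in": float(rp.Vhat_in)}
    doc["kinetics"] = {k: float(v) for k, v in dataclasses.asdict(rp.kinetics).items()}
    doc["coupling"] = {k: float(v) for k, v in dataclasses.asdict(rp.coupling).items()}
    doc["drive"] = {k: float(v) for k, v in dataclasses.asdict(rp.drive).items()}
    if extras:
        for sec, blk in extras.items():
            doc[sec] = dict(blk)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def reference_config() -> ReducedParams:
    """The calibrated reference configuration shipped with the package.

    Baseline constants (including the unpublished baseline coupling values
    that the 1D sweeps are centred on) were calibrated once against the
    published sweep landmarks (see the synergy module) and frozen.
    """
    rp, _ = load_config(_REFERENCE_PATH)
    return rp


def synergy_config() -> ReducedParams:
    """The calibrated configuration of the disease-synergy analysis.

    The published sweep landmarks and the published healthy-state optimum
    are not attainable under one constant set in this model family (see
    docs/methods.md), so the disease pipeline ships its own calibration,
    in which the healthy synaptic state sits at a gamma-power optimum of
    the tied two-parameter strength search.
    """
    rp, _ = load_config(_SYNERGY_PATH)
    return rp
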