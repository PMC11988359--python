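"""Diffusion acquisition definitions: sequences, waveforms, b-value math.

A time-dependent diffusion protocol combines pulsed gradient spin echo
(PGSE, long effective diffusion time) with cosine-modulated oscillating
gradient spin echo (OGSE, short effective diffusion time) acquisitions.
This module holds the sequence descriptors, builds idealized effective
gradient waveforms (sign-inverted after the refocusing pulse), converts
b-values to gradient amplitudes and back, and computes effective
diffusion times.

User-facing units are ms / Hz / s·mm⁻² / T·m⁻¹; all internal waveform
integrals are done in SI to keep the unit conversions in one place.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
import numpy as np
from scipy.integrate import cumulative_trapezoid, trapezoid

__all__ = [
    "GAMMA_PROTON",
    "SequenceSpec",
    "Protocol",
    "Waveform",
    "effective_diffusion_time",
    "gradient_amplitude_from_b",
    "b_value_of_waveform",
    "build_waveform",
    "breast_protocol",
    "load_protocol",
    "save_protocol",
]

#: Gyromagnetic ratio of ¹H, rad·s⁻¹·T⁻¹.
GAMMA_PROTON = 2.6751525e8

_MS = 1e-3          # ms -> s
_B_SI = 1e6         # s/mm² -> s/m²


@dataclass(frozen=True)
class SequenceSpec:
    """One diffusion-weighting sequence.

    Parameters
    ----------
    kind:
        ``"pgse"`` (rectangular lobes) or ``"ogse_cos"`` (cosine lobes).
    delta:
        Gradient lobe duration δ, ms.
    Delta:
        Lobe separation Δ (leading edge to leading edge), ms.
    te:
        Echo time, ms. Both lobes must fit inside TE.
    b_values:
        Nominal b-values, s/mm²; the first entry must be 0.
    nsa:
        Number of signal averages per b-value (same length as b_values).
    f:
        Oscillation frequency, Hz (0 for pgse). For ``ogse_cos`` the lobe
        holds exactly ``n_cycles`` full periods, so f = n_cycles/δ.
    n_cycles:
        Full cosine periods per lobe (ogse_cos only).
    label:
        Unique name used to index acquisitions (e.g. ``"ogse25"``).
    """

    kind: str
    delta: float
    Delta: float
    te: float
    b_values: tuple[float, ...]
    nsa: tuple[int, ...]
    f: float = 0.0
    n_cycles: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("pgse", "ogse_cos"):
            raise ValueError(f"unknown sequence kind {self.kind!r}")
        object.__setattr__(self, "b_values", tuple(float(b) for b in self.b_values))
        object.__setattr__(self, "nsa", tuple(int(n) for n in self.nsa))
        if not self.label:
            object.__setattr__(self, "label", self.kind)
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if len(self.nsa) != len(self.b_values):
            raise ValueError("nsa must have one entry per b-value")
        if len(self.b_values) == 0 or self.b_values[0] != 0.0:
            raise ValueError("b_values must start with b = 0")
        if any(b < 0 for b in self.b_values):
            raise ValueError("b_values must be non-negative")
        if self.Delta < self.delta:
            raise ValueError("Delta must be >= delta (lobes may not overlap)")
        if self.te < self.Delta + self.delta:
            raise ValueError("te too short to contain both gradient lobes")
        if self.kind == "ogse_cos":
            if self.n_cycles < 1:
                raise ValueError("ogse_cos needs n_cycles >= 1")
            f_exact = 1e3 * self.n_cycles / self.delta
            if not math.isclose(self.f, f_exact, rel_tol=1e-9):
                raise ValueError(
                    f"ogse_cos requires f = n_cycles/delta: expected {f_exact} Hz, got {self.f}"
                )

    @property
    def omega(self) -> float:
        """Angular oscillation frequency, rad/s (0 for pgse)."""
        return 2.0 * math.pi * self.f

    def segments(self):
        """Effective-gradient lobes as (t0_s, dur_s, omega_rad_s, sign).

        Unit amplitude; the second lobe carries sign −1 because the
        refocusing pulse inverts the effective gradient. Lobes are placed
        symmetrically inside TE.
        """
        delta_s = self.delta * _MS
        Delta_s = self.Delta * _MS
        t0 = (self.te * _MS - (Delta_s + delta_s)) / 2.0
        omega = self.omega
        return [
            (t0, delta_s, omega, +1.0),
            (t0 + Delta_s, delta_s, omega, -1.0),
        ]


@dataclass(frozen=True)
class Protocol:
    """An ordered set of diffusion sequences plus physical constants."""

    sequences: tuple[SequenceSpec, ...]
    gamma: float = GAMMA_PROTON

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequences", tuple(self.sequences))
        labels = [s.label for s in self.sequences]
        if len(set(labels)) != len(labels):
            raise ValueError("sequence labels must be unique")
        kinds = {s.kind for s in self.sequences}
        if not {"pgse", "ogse_cos"} <= kinds:
            raise ValueError(
                "protocol needs at least one pgse and one ogse_cos sequence "
                "for joint microstructure fitting"
            )

    def __getitem__(self, label: str) -> SequenceSpec:
        for s in self.sequences:
            if s.label == label:
                return s
        raise KeyError(label)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.sequences)


@dataclass
class Waveform:
    """A sampled effective gradient waveform.

    ``g_eff`` is the effective gradient (T/m) on the time grid ``times``
    (ms), already sign-inverted after the refocusing pulse, so the spin
    phase is simply γ∫g_eff·x dt.
    """

    times: np.ndarray
    g_eff: np.ndarray
    seq: SequenceSpec | None = None
    g: float = 0.0


def effective_diffusion_time(seq: SequenceSpec) -> float:
    """Effective diffusion time in ms: Δ − δ/3 for PGSE, 1/(4f) for cosine OGSE."""
    if seq.kind == "pgse":
        return seq.Delta - seq.delta / 3.0
    if seq.kind == "ogse_cos":
        return 1e3 / (4.0 * seq.f)
    raise ValueError(f"unknown sequence kind {seq.kind!r}")


def _b_per_g2(seq: SequenceSpec) -> float:
    """b (SI, s/m²) per unit g² (T²/m²) for the sequence's waveform shape."""
    delta_s = seq.delta * _MS
    if seq.kind == "pgse":
        Delta_s = seq.Delta * _MS
        return GAMMA_PROTON**2 * delta_s**2 * (Delta_s - delta_s / 3.0)
    if seq.kind == "ogse_cos":
        # q(t) = γ g sin(ωt)/ω inside each lobe; both lobes together give
        # b = γ² g² δ/ω² for an integer number of cycles per lobe.
        return GAMMA_PROTON**2 * delta_s / seq.omega**2
    raise ValueError(f"unknown sequence kind {seq.kind!r}")


def gradient_amplitude_from_b(
    seq: SequenceSpec, b: float, gamma: float = GAMMA_PROTON
) -> float:
    """Gradient amplitude (T/m) that realizes b (s/mm²) for this sequence."""
    if b < 0:
        raise ValueError("b must be non-negative")
    if b == 0:
        return 0.0
    if seq.delta <= 0:
        raise ValueError("cannot realize b > 0 with zero-duration lobes")
    scale = _b_per_g2(seq) * (gamma / GAMMA_PROTON) ** 2
    return math.sqrt(b * _B_SI / scale)


def build_waveform(
    seq: SequenceSpec, g: float, dt: float = 0.005
) -> Waveform:
    """Sample the effective gradient waveform on a uniform grid.

    ``dt`` is in ms and must resolve every oscillation period with at
    least 100 samples.
    """
    if seq.kind == "ogse_cos":
        period_ms = 1e3 / seq.f
        if period_ms / dt < 100:
            raise ValueError("dt too coarse: need >= 100 samples per oscillation period")
    times_ms = np.arange(0.0, seq.te + dt / 2, dt)
    t_s = times_ms * _MS
    g_eff = np.zeros_like(t_s)
    for (t0, dur, omega, sign) in seq.segments():
        inside = (t_s >= t0) & (t_s < t0 + dur)
        if omega == 0.0:
            g_eff[inside] = sign * g
        else:
            g_eff[inside] = sign * g * np.cos(omega * (t_s[inside] - t0))
    return Waveform(times=times_ms, g_eff=g_eff, seq=seq, g=g)


def b_value_of_waveform(wf: Waveform, gamma: float = GAMMA_PROTON) -> float:
    """b-value (s/mm²) of a sampled waveform via the q-space integral.

    b = ∫|q(t)|² dt with q(t) = γ∫₀ᵗ g_eff dt′; numerical trapezoids.
    Serves as the independent oracle for the closed-form amplitude math.
    """
    t_s = wf.times * _MS
    q = gamma * cumulative_trapezoid(wf.g_eff, t_s, initial=0.0)
    return trapezoid(q**2, t_s) / _B_SI


# ---------------------------------------------------------------------------
# The clinical 3T breast protocol shipped with the package
# ---------------------------------------------------------------------------

def breast_protocol() -> Protocol:
    """The combined OGSE/PGSE breast protocol used throughout the package.

    OGSE at 25 Hz (one cycle per lobe, t_diff = 10 ms) and 50 Hz (two
    cycles, t_diff = 5 ms) plus PGSE at t_diff = 78.4 ms, TE = 105 ms.
    PGSE lobe timings (δ = 12 ms, Δ = 82.4 ms) are chosen to satisfy
    Δ − δ/3 = 78.4 ms within the echo time; OGSE lobes last n_cycles/f.
    """
    return load_protocol(Path(__file__).parent / "data" / "breast_protocol.json")


def _seq_from_dict(d: dict) -> SequenceSpec:
    return SequenceSpec(
        kind=d["kind"],
        delta=float(d["delta"]),
        Delta=float(d["Delta"]),
        te=float(d["te"]),
        b_values=tuple(d["b_values"]),
        nsa=tuple(d["nsa"]),
        f=float(d.get("f", 0.0)),
        n_cycles=int(d.get("n_cycles", 0)),
        label=d.get("label", ""),
    )


def load_protocol(path: str | Path) -> Protocol:
    """Read a protocol from a JSON or YAML document."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        doc = yaml.safe_load(text)
    else:
        doc = json.loads(text)
    return Protocol(
        sequences=tuple(_seq_from_dict(d) for d in doc["sequences"]),
        gamma=float(doc.get("gamma", GAMMA_PROTON)),
    )


def save_protocol(protocol: Protocol, path: str | Path) -> None:
    """Write a protocol to JSON or YAML (by extension)."""
    path = Path(path)
    doc = {
        "gamma": protocol.gamma,
        "sequences": [asdict(s) for s in protocol.sequences],
    }
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    else:
        path.write_text(json.dumps(doc, indent=2))
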