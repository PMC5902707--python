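"""The stochastic fixed-point leaky integrate-and-fire neuron.

A neuron carries just 8 bits of state: a signed 4-bit post-synaptic current
code (``psc``; excitatory positive, inhibitory negative) and a signed 4-bit
membrane offset ``u`` measured from the configurable initial voltage
(``u = 0`` means "at rest").  Each 1 ms step the PSC generator decays the
current with a dithered exponential and adds the gained synaptic drive
``g_syn * W``; the soma then decays ``u`` and integrates ``g_psc * PSC``.
A spike is emitted when the un-clamped membrane sum overflows the 4-bit
range *and* the PSC is excitatory, after which ``u`` is reset into the
refractory range (``u < 0``) from which it stochastically decays back to 0.

This module is the scalar reference semantics; the simulation engine uses a
vectorized twin (:mod:`cortexsim.engine`) that is property-tested against it.
"""

from __future__ import annotations

from dataclasses import dataclass

from .fixedpoint import decay_step, saturate, tau_to_leak

__all__ = [
    "Q4_MIN",
    "Q4_MAX",
    "NeuronState",
    "NeuronTypeParams",
    "gain_code",
    "gain_value",
    "apply_gain",
    "psc_update",
    "soma_update",
    "neuron_step",
    "pack_state",
    "unpack_state",
]

Q4_MIN, Q4_MAX = -8, 7


@dataclass(frozen=True)
class NeuronState:
    """8-bit packed neuron state: PSC code and membrane offset, both Q4."""

    psc: int = 0
    u: int = 0

    def __post_init__(self) -> None:
        if not (Q4_MIN <= self.psc <= Q4_MAX and Q4_MIN <= self.u <= Q4_MAX):
            raise ValueError(f"state codes out of Q4 range: {self}")


def gain_code(gain: float) -> int:
    """Nearest 8-bit code for a synaptic gain; value = (code + 1) / 16.

    The mapping covers [1/16, 16] so the endpoints of the published gain
    range (~0.06 and 16) are representable exactly.
    """
    code = int(round(16.0 * gain)) - 1
    if not 0 <= code <= 255:
        raise ValueError(f"gain {gain} outside representable range [0.0625, 16]")
    return code


def gain_value(code: int) -> float:
    if not 0 <= code <= 255:
        raise ValueError("gain code must be 8-bit")
    return (code + 1) / 16.0


def apply_gain(code: int, x: int) -> int:
    """Full-precision gain product rounded to nearest, ties away from zero."""
    num = (code + 1) * x
    # round-half-away-from-zero of num / 16
    if num >= 0:
        return (num + 8) >> 4
    return -((-num + 8) >> 4)


@dataclass(frozen=True)
class NeuronTypeParams:
    """Per-type fixed-point parameters.

    ``L_*`` are 8-bit leak factors (retention ``L/256``); ``g_*_code`` are
    8-bit gain codes (gain ``(code+1)/16``); ``u_reset`` is the refractory
    entry point (default −8, the bottom of the Q4 range).
    """

    L_epsc: int
    L_ipsc: int
    L_mem: int
    L_rfc: int
    g_syn_code: int
    g_psc_code: int
    u_reset: int = -8

    def __post_init__(self) -> None:
        for name in ("L_epsc", "L_ipsc", "L_mem", "L_rfc"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name}={v} not an 8-bit leak factor")
        for name in ("g_syn_code", "g_psc_code"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name}={v} not an 8-bit gain code")
        if not Q4_MIN <= self.u_reset <= -1:
            raise ValueError("u_reset must lie in the refractory range [-8, -1]")

    @classmethod
    def from_time_constants(
        cls,
        tau_epsc: float,
        tau_ipsc: float,
        tau_mem: float,
        tau_rfc: float,
        g_syn: float = 1.0,
        g_psc: float = 1.0,
        u_reset: int = -8,
    ) -> "NeuronTypeParams":
        """Build from time constants in ms (1 step = 1 ms) and real gains."""
        return cls(
            L_epsc=tau_to_leak(tau_epsc),
            L_ipsc=tau_to_leak(tau_ipsc),
            L_mem=tau_to_leak(tau_mem),
            L_rfc=tau_to_leak(tau_rfc),
            g_syn_code=gain_code(g_syn),
            g_psc_code=gain_code(g_psc),
            u_reset=u_reset,
        )


def psc_update(state: NeuronState, W: int, p: NeuronTypeParams, r: int) -> int:
    """PSC generator step: dithered decay plus gained synaptic drive.

    The decay time constant is chosen by the *current* sign of the PSC
    (excitatory vs inhibitory); a single accumulator ``W`` may carry mixed
    drive.  Result saturates into the Q4 range.
    """
    if not Q4_MIN <= W <= Q4_MAX:
        raise ValueError("W outside Q4 range")
    L = p.L_epsc if state.psc >= 0 else p.L_ipsc
    decayed = decay_step(state.psc, L, r)
    drive = saturate(apply_gain(p.g_syn_code, W), Q4_MIN, Q4_MAX)
    return saturate(decayed + drive, Q4_MIN, Q4_MAX)


def soma_update(
    state: NeuronState, psc_new: int, p: NeuronTypeParams, r: int
) -> tuple[int, bool]:
    """Soma step: returns ``(u_new, spiked)``.

    Active state (``u >= 0``): the membrane decays toward 0 and integrates the
    gained PSC.  If the un-clamped sum overflows above 7 while the PSC is
    excitatory, a spike is emitted and ``u`` resets to ``u_reset``; an
    inhibitory underflow below −8 resets without a spike.  Refractory state
    (``u < 0``): the PSC is discarded and ``|u|`` decays toward 0.
    """
    if state.u < 0:  # refractory: discard PSC, decay magnitude toward rest
        return -decay_step(-state.u, p.L_rfc, r), False
    decayed = decay_step(state.u, p.L_mem, r)
    total = decayed + apply_gain(p.g_psc_code, psc_new)
    if total > Q4_MAX:
        if psc_new > 0:
            return p.u_reset, True
        return Q4_MAX, False  # unreachable with a non-excitatory PSC; kept for safety
    if total < Q4_MIN:
        return p.u_reset, False
    return total, False


def neuron_step(
    state: NeuronState, W: int, p: NeuronTypeParams, r1: int, r2: int
) -> tuple[NeuronState, bool]:
    """One 1 ms update: PSC generator then soma, with independent dithers."""
    psc_new = psc_update(state, W, p, r1)
    u_new, spiked = soma_update(state, psc_new, p, r2)
    return NeuronState(psc=psc_new, u=u_new), spiked


def pack_state(state: NeuronState) -> int:
    """Pack into one byte: PSC nibble in the high 4 bits, u in the low 4."""
    return ((state.psc & 0xF) << 4) | (state.u & 0xF)


def unpack_state(b: int) -> NeuronState:
    if not 0 <= b <= 255:
        raise ValueError("packed state must be one byte")
    psc = (b >> 4) & 0xF
    u = b & 0xF
    return NeuronState(psc=psc - 16 if psc >= 8 else psc, u=u - 16 if u >= 8 else u)
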