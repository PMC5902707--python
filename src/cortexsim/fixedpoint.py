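"""Deterministic pseudo-random bit streams and dithered fixed-point kernels.

Everything downstream of this module — post-synaptic current decay, membrane
leak, delay readout, destination selection — consumes random bits from
Fibonacci linear feedback shift registers (LFSRs) and performs its arithmetic
on small signed fixed-point codes.  The central trick is *stochastic
rounding*: a product is truncated to its most significant bits and the lost
low bits are replaced by a uniform dither, so that the rounding is exactly
unbiased in expectation while each individual trajectory is randomized.  This
both shrinks per-neuron storage to a few bits and decorrelates otherwise
identical neurons.

Conventions
-----------
* LFSRs are Fibonacci, left-shift, feedback into the LSB: the feedback bit is
  the XOR of the tap bits of the *old* state, the new state is
  ``((old << 1) | feedback) & mask``.  With this convention, after stepping
  ``n`` times the low ``n`` bits of the state are the last ``n`` output bits.
* 4-bit signed codes (``Q4``) live in ``[-8, 7]`` and are interpreted as
  ``code / 8``, i.e. normalized to ``[-1, 0.875]``.
* 8-bit leak factors ``L`` encode a per-step retention ``L/256 ~= tau/(tau+1)``.
* The dither is 5 bits (``1/32`` resolution), which caps the largest cleanly
  representable retention at ``31/32`` and hence the effective time constant
  at roughly 31 steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PRIMITIVE_TAPS",
    "Lfsr",
    "lfsr_next",
    "draw_bits",
    "lfsr_step_array",
    "draw_bits_array",
    "stochastic_round",
    "decay_step",
    "saturate",
    "tau_to_leak",
    "leak_to_tau",
    "splitmix64",
    "seed_lfsr_state",
    "DITHER_BITS",
    "DITHER_RANGE",
]

DITHER_BITS = 5
DITHER_RANGE = 1 << DITHER_BITS  # 32

#: Default primitive feedback polynomials, as tap bit positions of the old
#: state XORed into the feedback bit.  width 4: x^4+x^3+1; width 8:
#: x^8+x^6+x^5+x^4+1; width 10: x^10+x^7+1; width 20: x^20+x^3+1;
#: width 32: x^32+x^22+x^2+x+1.  All are maximal-period.
PRIMITIVE_TAPS: dict[int, tuple[int, ...]] = {
    4: (3, 2),
    8: (7, 5, 4, 3),
    10: (9, 6),
    20: (19, 2),
    32: (31, 21, 1, 0),
}


class ZeroStateError(ValueError):
    """An LFSR reached (or was constructed with) the absorbing all-zero state."""


@dataclass
class Lfsr:
    """State of a Fibonacci LFSR.

    Parameters
    ----------
    width:
        Register width in bits (4–32).
    state:
        Current register contents; must never be zero.
    taps:
        Bit positions (of the old state) XORed to form the feedback bit.
        Defaults to the primitive polynomial for ``width`` if available.
    """

    width: int
    state: int
    taps: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not 2 <= self.width <= 32:
            raise ValueError(f"LFSR width {self.width} outside [2, 32]")
        if not self.taps:
            try:
                self.taps = PRIMITIVE_TAPS[self.width]
            except KeyError:
                raise ValueError(
                    f"no default taps for width {self.width}; pass taps explicitly"
                ) from None
        mask = (1 << self.width) - 1
        self.state &= mask
        if self.state == 0:
            raise ZeroStateError("LFSR state must be nonzero")

    @property
    def mask(self) -> int:
        return (1 << self.width) - 1

    def next_bit(self) -> int:
        """Advance one step, returning the feedback/output bit."""
        fb = 0
        s = self.state
        for t in self.taps:
            fb ^= (s >> t) & 1
        self.state = ((s << 1) | fb) & self.mask
        return fb

    def draw_bits(self, n: int) -> int:
        """Advance ``n`` steps and return the ``n`` fresh bits as an integer.

        Because new bits shift in at the LSB, the low ``n`` bits of the state
        after ``n`` steps are exactly the last ``n`` output bits.
        """
        if n <= 0:
            raise ValueError("n must be positive")
        for _ in range(n):
            self.next_bit()
        return self.state & ((1 << n) - 1)


def lfsr_next(s: Lfsr) -> tuple[Lfsr, int]:
    """Functional single-step: return ``(new_lfsr, output_bit)``."""
    new = Lfsr(s.width, s.state, s.taps)
    bit = new.next_bit()
    return new, bit


def draw_bits(s: Lfsr, n: int) -> tuple[Lfsr, int]:
    """Functional ``n``-bit draw: return ``(new_lfsr, value)``."""
    new = Lfsr(s.width, s.state, s.taps)
    value = new.draw_bits(n)
    return new, value


# -- vectorized LFSR lanes ---------------------------------------------------

def lfsr_step_array(states: np.ndarray, taps: tuple[int, ...], width: int) -> np.ndarray:
    """Advance an array of same-polynomial LFSRs by one step (in place).

    ``states`` is any-shape ``uint32``/``uint64`` array of nonzero states.
    """
    fb = (states >> taps[0]) & 1
    for t in taps[1:]:
        fb ^= (states >> t) & 1
    np.left_shift(states, 1, out=states)
    np.bitwise_or(states, fb, out=states)
    np.bitwise_and(states, (1 << width) - 1, out=states)
    return states


def draw_bits_array(
    states: np.ndarray, n: int, taps: tuple[int, ...], width: int
) -> np.ndarray:
    """Advance every lane ``n`` steps; return the fresh ``n``-bit values."""
    for _ in range(n):
        lfsr_step_array(states, taps, width)
    return states & ((1 << n) - 1)


# -- dithered fixed-point kernels -------------------------------------------

def saturate(x, lo: int, hi: int):
    """Clamp ``x`` (scalar or array) into ``[lo, hi]``."""
    if lo > hi:
        raise ValueError(f"empty saturation range [{lo}, {hi}]")
    if isinstance(x, np.ndarray):
        return np.clip(x, lo, hi)
    return min(max(int(x), lo), hi)


def stochastic_round(q, r):
    """Unbiased truncation of a nonnegative quantity in 1/32 units.

    Returns ``floor((q + r) / 32)``.  Over ``r`` uniform on ``{0..31}`` the
    expectation is exactly ``q / 32``: the discarded low bits are replaced by
    the dither rather than being rounded deterministically.
    """
    if isinstance(q, np.ndarray) or isinstance(r, np.ndarray):
        return (q + r) >> DITHER_BITS
    if q < 0:
        raise ValueError("q must be nonnegative (handle sign externally)")
    if not 0 <= r < DITHER_RANGE:
        raise ValueError("r must be a 5-bit dither")
    return (q + r) >> DITHER_BITS


def decay_step(code, L, r):
    """One dithered exponential-decay step of a signed 4-bit code.

    Sign-magnitude: the magnitude is multiplied by ``L`` (8-bit retention,
    ``L/256``), truncated to 1/32 units (``floor(m * L / 8)``) and
    stochastically rounded; the sign is reattached.  The result's magnitude
    never exceeds the input's, so decay is monotone and ``0`` is absorbing.

    Works elementwise on numpy arrays.
    """
    if isinstance(code, np.ndarray):
        m = np.abs(code.astype(np.int32))
        q = (m * L) >> 3
        d = (q + r) >> DITHER_BITS
        return np.sign(code) * d
    m = abs(int(code))
    q = (m * int(L)) >> 3
    d = stochastic_round(q, r)
    return d if code >= 0 else -d


def tau_to_leak(tau_ms: float) -> int:
    """Map a time constant in ms (= steps) to the nearest 8-bit leak factor.

    ``L = round(256 * tau / (tau + 1))``, clamped to ``[0, 255]``: ``L/256``
    is the per-step retention of a discretized exponential with constant
    ``tau``.  ``tau = 0`` maps to ``L = 0`` (instant decay).
    """
    if tau_ms < 0:
        raise ValueError("time constant must be nonnegative")
    return min(255, int(round(256.0 * tau_ms / (tau_ms + 1.0))))


def leak_to_tau(L: int) -> float:
    """Inverse of :func:`tau_to_leak` on the retention scale: ``tau = L/(256-L)``."""
    if not 0 <= L <= 255:
        raise ValueError("L must be 8-bit")
    return L / (256.0 - L)


def measure_decay_tau(
    L: int,
    n: int = 10_000,
    steps: int = 100,
    seed: int = 0,
    start: int = 7,
) -> float:
    """Effective time constant (in steps) of the dithered decay at leak ``L``.

    Simulates ``n`` independent trajectories from ``start`` for ``steps``
    steps with fresh uniform dithers, and fits an exponential to the
    ensemble-mean trajectory (log-linear least squares over the bins where
    the mean is well above the quantization floor).  At the slowest cleanly
    representable setting ``L = 248`` (retention 31/32) this comes out near
    ``-1/ln(31/32) ~= 31.5`` — the ceiling imposed by the 5-bit dither.
    """
    rng = np.random.default_rng(seed % (1 << 31))
    codes = np.full(n, start, dtype=np.int32)
    means = [float(start)]
    for _ in range(steps):
        r = rng.integers(0, DITHER_RANGE, size=n, dtype=np.int32)
        codes = (((codes * L) >> 3) + r) >> DITHER_BITS
        means.append(float(codes.mean()))
    y = np.asarray(means)
    keep = y > 0.05 * start
    t = np.arange(len(y))[keep]
    slope = np.polyfit(t, np.log(y[keep]), 1)[0]
    return float(-1.0 / slope)


# -- seeding -----------------------------------------------------------------

_MASK64 = (1 << 64) - 1


def splitmix64(x: int) -> int:
    """One splitmix64 mixing round; used to derive independent stream seeds."""
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & _MASK64
    return x ^ (x >> 31)


def seed_lfsr_state(global_seed: int, stream_id: int, width: int) -> int:
    """Derive a nonzero ``width``-bit LFSR state for stream ``stream_id``."""
    mask = (1 << width) - 1
    s = splitmix64(splitmix64(global_seed) ^ stream_id) & mask
    return s if s != 0 else 1


def splitmix64_array(x: np.ndarray) -> np.ndarray:
    """Vectorized :func:`splitmix64` on a uint64 array."""
    x = x.astype(np.uint64, copy=True)
    with np.errstate(over="ignore"):
        x += np.uint64(0x9E3779B97F4A7C15)
        x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return x ^ (x >> np.uint64(31))
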