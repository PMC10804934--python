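"""Fixed-point encoding of real tensors into a prime ring, and the ring
arithmetic the secure-aggregation protocol builds on.

Model weights are real-valued, but additive secret sharing works over the
integers modulo a public prime ``Q``.  A real value ``x`` is therefore encoded
as ``round(x * 10**p) mod Q`` for a decimal precision ``p``; the signed value
is recovered by lifting residues above ``(Q-1)/2`` to negatives and dividing
by the scale.  With ``p = 13`` the round-trip is lossless relative to
single-precision inputs, which is what makes the encrypted aggregation
numerically equivalent to its plaintext counterpart.

The modulus is sized so that the *plain integer* sum of up to ``max_parties``
residues stays below ``2**63``: the aggregation server adds submissions as
ordinary signed 64-bit integers without knowing ``Q``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import sympy

__all__ = [
    "Modulus",
    "FixedPointCodec",
    "RingTensor",
    "generate_modulus",
    "encode",
    "decode",
    "ring_add",
    "ring_tensor_to_bytes",
    "ring_tensor_from_bytes",
]

_I64_MAX = 2**63


@dataclass(frozen=True)
class Modulus:
    """A public prime modulus with a 64-bit-sum safety bound.

    Parameters
    ----------
    Q : int
        Prime modulus; all ring values live in ``[0, Q)``.
    bit_length : int
        Exact bit length of ``Q``.
    max_parties : int
        Largest number of parties whose residues may be summed without
        modular reduction while still fitting a signed 64-bit integer.
    """

    Q: int
    bit_length: int
    max_parties: int

    def __post_init__(self) -> None:
        if self.Q.bit_length() != self.bit_length:
            raise ValueError(
                f"Q has bit length {self.Q.bit_length()}, expected {self.bit_length}"
            )
        if not sympy.isprime(self.Q):
            raise ValueError(f"Q = {self.Q} is not prime")
        if self.max_parties * (self.Q - 1) >= _I64_MAX:
            raise ValueError(
                f"{self.max_parties} x (Q-1) does not fit a signed 64-bit integer"
            )


@dataclass(frozen=True)
class FixedPointCodec:
    """Base-10 fixed-point codec over a prime ring.

    ``precision`` is the number of retained decimal digits ``p``; reals are
    scaled by ``10**p``, rounded half-to-even and reduced modulo ``Q``.
    """

    precision: int
    modulus: Modulus
    scale: int = field(init=False)

    def __post_init__(self) -> None:
        if self.precision < 0:
            raise ValueError("precision must be non-negative")
        object.__setattr__(self, "scale", 10**self.precision)

    @property
    def max_magnitude(self) -> float:
        """Largest representable |value|: ``(Q - 1) / (2 * scale)``."""
        return (self.modulus.Q - 1) / (2 * self.scale)


@dataclass(frozen=True)
class RingTensor:
    """Integer tensor with entries in ``[0, Q)`` — an encrypted-space tensor.

    Values are stored flat as int64; ``shape`` carries the logical extents.
    """

    shape: tuple[int, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.ascontiguousarray(self.values, dtype=np.int64).ravel()
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        expected = 1
        for s in self.shape:
            expected *= s
        if v.size != expected:
            raise ValueError(
                f"flat size {v.size} does not match shape {self.shape}"
            )

    def check_range(self, modulus: Modulus) -> None:
        if self.values.size and (
            self.values.min() < 0 or self.values.max() >= modulus.Q
        ):
            raise ValueError("ring tensor entries outside [0, Q)")

    def reshaped(self) -> np.ndarray:
        return self.values.reshape(self.shape)


def generate_modulus(bit_length: int, max_parties: int, seed: int) -> Modulus:
    """Draw a prime of exactly ``bit_length`` bits, deterministically from ``seed``.

    The crypto provider's role: pick a public prime such that the plain sum of
    ``max_parties`` residues fits a signed 64-bit integer.

    Raises
    ------
    ValueError
        If no prime of that bit length can satisfy
        ``max_parties * (Q - 1) < 2**63``, or the bit length is out of range.
    """
    if not (4 <= bit_length <= 62):
        raise ValueError("bit_length must be in [4, 62]")
    if max_parties < 2:
        raise ValueError("max_parties must be >= 2")
    lo, hi = 1 << (bit_length - 1), (1 << bit_length) - 1
    # Largest admissible Q under the 64-bit sum bound.
    q_cap = (_I64_MAX - 1) // max_parties + 1  # need Q - 1 <= (2^63-1)//max_parties
    q_cap = min(hi, q_cap)
    if q_cap < lo:
        raise ValueError(
            f"no {bit_length}-bit prime satisfies {max_parties} x (Q-1) < 2**63"
        )
    rng = np.random.default_rng(seed)
    for _ in range(10_000):
        cand = int(rng.integers(lo, q_cap, endpoint=True, dtype=np.uint64))
        q = sympy.nextprime(cand - 1)
        if q > q_cap or q.bit_length() != bit_length:
            continue
        if max_parties * (q - 1) < _I64_MAX:
            return Modulus(Q=int(q), bit_length=bit_length, max_parties=max_parties)
    raise ValueError(
        f"no {bit_length}-bit prime satisfies {max_parties} x (Q-1) < 2**63"
    )


def default_codec(
    precision: int = 13, bit_length: int = 61, max_parties: int = 4, seed: int = 0
) -> FixedPointCodec:
    """Default crypto parameters: p = 13, 61-bit prime, up to 4 parties."""
    return FixedPointCodec(
        precision=precision,
        modulus=generate_modulus(bit_length, max_parties, seed),
    )


def encode(value, codec: FixedPointCodec):
    """Encode real value(s) into ring residue(s).

    ``m = round_half_even(value * 10**p)``; negatives map to ``Q - |m|`` so
    the result always lies in ``[0, Q)``.  Scalar in, int out; array in,
    RingTensor out.
    """
    arr = np.asarray(value, dtype=np.float64)
    if np.any(np.abs(arr) > codec.max_magnitude):
        bad = float(np.max(np.abs(arr)))
        raise OverflowError(
            f"magnitude {bad} exceeds representable bound {codec.max_magnitude}"
        )
    scaled = np.rint(arr * codec.scale)  # rint = round half to even
    m = scaled.astype(np.int64)
    residues = np.mod(m, codec.modulus.Q)  # numpy % is non-negative for Q > 0
    if arr.ndim == 0:
        return int(residues)
    return RingTensor(shape=arr.shape, values=residues)


def decode(m, codec: FixedPointCodec):
    """Decode ring residue(s) back to real value(s) via the signed lift.

    ``s = m`` if ``m <= (Q-1)/2`` else ``m - Q``; returns ``s / 10**p``.
    """
    Q = codec.modulus.Q
    if isinstance(m, RingTensor):
        vals = m.reshaped()
    else:
        vals = np.asarray(m, dtype=np.int64)
    if vals.size and (vals.min() < 0 or vals.max() >= Q):
        raise ValueError("residue outside [0, Q)")
    half = (Q - 1) // 2
    signed = np.where(vals > half, vals - Q, vals)
    out = signed.astype(np.float64) / codec.scale
    if np.ndim(out) == 0 and not isinstance(m, RingTensor):
        return float(out)
    return out


def reduce_mod(values: np.ndarray, modulus: Modulus) -> np.ndarray:
    """Reduce arbitrary int64 values into ``[0, Q)``."""
    return np.mod(np.asarray(values, dtype=np.int64), modulus.Q)


def ring_add(a: RingTensor, b: RingTensor, modulus: Modulus) -> RingTensor:
    """Elementwise ``(a + b) mod Q`` — homomorphic addition of residues."""
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    # Each operand < Q < 2^62, so the plain sum fits int64 before reduction.
    s = np.mod(a.values + b.values, modulus.Q)
    return RingTensor(shape=a.shape, values=s)


# ---------------------------------------------------------------------------
# Wire form: header record + little-endian signed 64-bit payload.  Matches the
# transmission constraint that encrypted weights travel as 64-bit integers.
# ---------------------------------------------------------------------------

_MAGIC = b"SHEFL1\n"


def ring_tensor_to_bytes(
    name: str, tensor: RingTensor, precision: int, modulus_id: str
) -> bytes:
    """Serialize one named ring tensor: JSON header line + int64 LE payload."""
    header = json.dumps(
        {
            "tensor": name,
            "shape": list(tensor.shape),
            "precision": precision,
            "modulus_id": modulus_id,
        }
    ).encode()
    payload = tensor.values.astype("<i8").tobytes()
    return _MAGIC + header + b"\n" + payload


def ring_tensor_from_bytes(blob: bytes) -> tuple[str, RingTensor, int, str]:
    """Inverse of :func:`ring_tensor_to_bytes`."""
    if not blob.startswith(_MAGIC):
        raise ValueError("not a ring-tensor wire message")
    rest = blob[len(_MAGIC):]
    nl = rest.index(b"\n")
    header = json.loads(rest[:nl].decode())
    values = np.frombuffer(rest[nl + 1:], dtype="<i8").astype(np.int64)
    rt = RingTensor(shape=tuple(header["shape"]), values=values)
    return header["tensor"], rt, header["precision"], header["modulus_id"]
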