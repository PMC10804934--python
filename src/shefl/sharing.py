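"""Additive secret sharing of ring tensors (SPDZ-style, no MACs / ZK proofs).

A secret residue tensor ``x`` is split among ``N`` holders: the first ``N-1``
shares are i.i.d. uniform on ``[0, Q)`` and the last is
``(x - x_1 - ... - x_{N-1}) mod Q``, so the modular sum of all shares
reconstructs ``x`` exactly.  Any ``N-1`` shares are uniformly distributed and
carry no information about the secret — this is the masking that blinds the
honest-but-curious aggregation server.

Shares support the two homomorphic operations the aggregation step needs:
holder-wise addition and multiplication by a public integer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .crypto_ring import Modulus, RingTensor, ring_add

__all__ = ["ShareSet", "make_shares", "reconstruct", "add_sharesets", "public_scalar_mul"]


@dataclass(frozen=True)
class ShareSet:
    """``N`` ring tensors that additively reconstruct a secret modulo ``Q``."""

    holders: int
    shares: tuple[RingTensor, ...]
    modulus: Modulus

    def __post_init__(self) -> None:
        if self.holders < 2:
            raise ValueError("a share set needs at least 2 holders")
        if len(self.shares) != self.holders:
            raise ValueError("number of shares does not match holder count")
        shapes = {s.shape for s in self.shares}
        if len(shapes) != 1:
            raise ValueError(f"shares have inconsistent shapes: {shapes}")


def make_shares(
    secret: RingTensor, n_holders: int, modulus: Modulus, rng_seed
) -> ShareSet:
    """Split a secret residue tensor into ``n_holders`` additive shares.

    ``rng_seed`` may be an int or a sequence (e.g. ``(scenario_seed, site, round)``)
    accepted by :func:`numpy.random.default_rng`; the split is deterministic
    given the seed.
    """
    if n_holders < 2:
        raise ValueError("n_holders must be >= 2")
    secret.check_range(modulus)
    rng = np.random.default_rng(rng_seed)
    Q = modulus.Q
    shares = []
    acc = np.zeros(secret.values.shape, dtype=np.int64)
    for _ in range(n_holders - 1):
        r = rng.integers(0, Q, size=secret.values.shape, dtype=np.int64)
        shares.append(RingTensor(shape=secret.shape, values=r))
        acc = np.mod(acc + r, Q)
    last = np.mod(secret.values - acc, Q)
    shares.append(RingTensor(shape=secret.shape, values=last))
    return ShareSet(holders=n_holders, shares=tuple(shares), modulus=modulus)


def reconstruct(share_set: ShareSet) -> RingTensor:
    """Modular sum of all shares: recovers the secret exactly."""
    Q = share_set.modulus.Q
    acc = np.zeros(share_set.shares[0].values.shape, dtype=np.int64)
    for s in share_set.shares:
        acc = np.mod(acc + s.values, Q)
    return RingTensor(shape=share_set.shares[0].shape, values=acc)


def _check_compatible(a: ShareSet, b: ShareSet) -> None:
    if a.holders != b.holders:
        raise ValueError("share sets have different holder counts")
    if a.modulus != b.modulus:
        raise ValueError("share sets use different moduli")
    if a.shares[0].shape != b.shares[0].shape:
        raise ValueError("share sets have different tensor shapes")


def add_sharesets(a: ShareSet, b: ShareSet) -> ShareSet:
    """Holder-wise homomorphic addition: reconstructs to the modular sum."""
    _check_compatible(a, b)
    summed = tuple(
        ring_add(sa, sb, a.modulus) for sa, sb in zip(a.shares, b.shares)
    )
    return ShareSet(holders=a.holders, shares=summed, modulus=a.modulus)


def public_scalar_mul(a: ShareSet, k: int) -> ShareSet:
    """Multiply every share by a public non-negative integer ``k`` mod Q.

    Reconstructs to ``(k * secret) mod Q``.  The product is formed with
    arbitrary-precision integers before reduction, so large ``Q``/``k`` are
    safe from 64-bit overflow.
    """
    if k < 0:
        raise ValueError("public scalar must be non-negative")
    Q = a.modulus.Q
    km = k % Q
    out = []
    for s in a.shares:
        prod = (s.values.astype(object) * km) % Q
        out.append(
            RingTensor(shape=s.shape, values=prod.astype(np.int64))
        )
    return ShareSet(holders=a.holders, shares=tuple(out), modulus=a.modulus)
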